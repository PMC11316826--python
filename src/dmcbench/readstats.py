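"""Read-set QC statistics, filtering, and seeded subsampling for FASTQ data.

Mock-community read sets collected from different studies differ in yield,
read length and quality; before classification they are equalized by
(1) subsampling each set to a common base total with a fixed seed,
(2) optionally matching a read-length distribution across flowcell
chemistries, and (3) filtering to reads longer than 1000 bases with mean
Phred quality above 7. The summary statistics mirror the standard seqkit
column set: read count, base total, length min/mean/max, length quartiles,
N50, and the percentage of bases at Q20/Q30.

Mean read quality averages per-base error probabilities before converting
back to the Phred scale (the nanopore community convention); a plain
arithmetic mean of Phred values is available via ``method="arithmetic"``.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReadRecord",
    "ReadSetStats",
    "MatchResult",
    "read_fastq",
    "write_fastq",
    "compute_read_stats",
    "mean_read_quality",
    "filter_reads",
    "subsample_to_bases",
    "match_length_distribution",
    "RNG_ALGORITHM",
]

# named, versioned generator so seeded byte-reproducibility is a contract
RNG_ALGORITHM = "numpy-PCG64"


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: {len(self.sequence)} bases vs "
                f"{len(self.qualities)} quality values"
            )
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.read_id}: negative Phred value")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadSetStats:
    """Summary statistics of a read set (seqkit-style column set)."""

    num_seqs: int
    sum_len: int
    min_len: int
    avg_len: float
    max_len: int
    q1_len: float
    median_len: float
    q3_len: float
    n50: int
    q20_pct: float
    q30_pct: float


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a FASTQ file (plain or gzip)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt", encoding="utf-8") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield ReadRecord(
                read_id=rec.id,
                sequence=str(rec.seq),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
            )


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write reads as plain FASTQ; returns the number written."""
    path = Path(path)
    n = 0
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for read in reads:
            rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(read.qualities)
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


def compute_read_stats(reads: Iterable[ReadRecord]) -> ReadSetStats | None:
    """Compute the summary-statistics row for a read set.

    N50 is the smallest length L such that reads of length >= L together
    contain at least half of the total bases. Q20/Q30 percentages count
    bases with Phred >= 20 / >= 30. Returns None for an empty stream.
    """
    lengths: list[int] = []
    q20 = q30 = 0
    for read in reads:
        lengths.append(len(read))
        quals = np.asarray(read.qualities)
        q20 += int((quals >= 20).sum())
        q30 += int((quals >= 30).sum())
    if not lengths:
        return None
    arr = np.sort(np.asarray(lengths))
    total = int(arr.sum())
    # cumulative bases over descending lengths; N50 where it crosses half
    desc = arr[::-1]
    cum = np.cumsum(desc)
    n50 = int(desc[np.searchsorted(cum, total / 2.0)])
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return ReadSetStats(
        num_seqs=len(arr),
        sum_len=total,
        min_len=int(arr[0]),
        avg_len=float(total / len(arr)),
        max_len=int(arr[-1]),
        q1_len=float(q1),
        median_len=float(med),
        q3_len=float(q3),
        n50=n50,
        q20_pct=100.0 * q20 / total,
        q30_pct=100.0 * q30 / total,
    )


def mean_read_quality(read: ReadRecord, method: str = "error_probability") -> float:
    """Mean quality of one read on the Phred scale.

    ``error_probability`` (default) averages per-base error probabilities
    and converts back: -10*log10(mean(10^(-q/10))). ``arithmetic`` averages
    the Phred values directly.
    """
    if not read.qualities:
        raise ValueError(f"read {read.read_id} has no quality values")
    if method == "error_probability":
        probs = np.power(10.0, -np.asarray(read.qualities, dtype=float) / 10.0)
        return float(-10.0 * math.log10(float(probs.mean())))
    if method == "arithmetic":
        return float(np.mean(read.qualities))
    raise ValueError(f"unknown mean-quality method {method!r}")


def filter_reads(
    reads: Iterable[ReadRecord],
    min_len: int = 1000,
    min_mean_q: float = 7.0,
    quality_method: str = "error_probability",
) -> Iterator[ReadRecord]:
    """Keep reads with length > min_len AND mean quality > min_mean_q.

    Both comparisons are strict: a 1000-base read or a mean-Q7.0 read is
    removed. Idempotent.
    """
    for read in reads:
        if len(read) > min_len and mean_read_quality(read, quality_method) > min_mean_q:
            yield read


def subsample_to_bases(
    reads: Iterable[ReadRecord], target_bases: int, seed: int
) -> list[ReadRecord]:
    """Randomly subsample a read set down to a base-count target.

    Reads are shuffled by a seeded PCG64 generator and accumulated until the
    cumulative base count reaches the target; the last selected read may
    overshoot. If the input holds fewer bases than the target, all reads are
    returned (shuffled) and a warning states the shortfall. Deterministic
    for fixed seed and input order.
    """
    if target_bases <= 0:
        raise ValueError(f"target_bases must be positive, got {target_bases}")
    pool = list(reads)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    total = sum(len(r) for r in pool)
    if total < target_bases:
        warnings.warn(
            f"input holds {total} bases, {target_bases - total} short of the "
            f"{target_bases}-base target; returning all reads",
            stacklevel=2,
        )
        return [pool[i] for i in order]
    selected: list[ReadRecord] = []
    acc = 0
    for i in order:
        selected.append(pool[i])
        acc += len(pool[i])
        if acc >= target_bases:
            break
    return selected


@dataclass
class MatchResult:
    """Reads selected by length-distribution matching, plus per-bin shortfalls."""

    reads: list[ReadRecord]
    shortfalls: dict[int, int]  # bin index -> missing read count


def match_length_distribution(
    candidates: Iterable[ReadRecord],
    reference_lengths: Sequence[int],
    seed: int,
    bins: int = 20,
) -> MatchResult:
    """Subsample candidates to match a reference read-length distribution.

    The reference lengths are split into ``bins`` quantile bins; within each
    bin, candidates whose length falls in the bin are sampled without
    replacement to match the reference bin count. Candidates outside the
    reference length range never match any bin. Bins with too few
    candidates contribute everything they have and the deficit is reported
    per bin, so the output count equals the reference count minus the total
    shortfall. Deterministic under a fixed seed.
    """
    if not reference_lengths:
        return MatchResult(reads=[], shortfalls={})
    ref = np.asarray(sorted(reference_lengths))
    # internal bin edges at quantiles 1/bins .. (bins-1)/bins
    edges = np.quantile(ref, [i / bins for i in range(1, bins)]) if bins > 1 else np.array([])
    ref_counts = np.bincount(np.searchsorted(edges, ref, side="right"), minlength=bins)

    lo, hi = int(ref[0]), int(ref[-1])
    pool = list(candidates)
    by_bin: dict[int, list[int]] = {}
    for idx, read in enumerate(pool):
        if not (lo <= len(read) <= hi):  # outside the reference length range
            continue
        b = int(np.searchsorted(edges, len(read), side="right"))
        by_bin.setdefault(b, []).append(idx)

    rng = np.random.default_rng(seed)
    selected_idx: list[int] = []
    shortfalls: dict[int, int] = {}
    for b in range(bins):
        want = int(ref_counts[b])
        if want == 0:
            continue
        have = by_bin.get(b, [])
        if len(have) < want:
            shortfalls[b] = want - len(have)
            take = list(have)
        else:
            take = list(rng.choice(len(have), size=want, replace=False))
            take = [have[i] for i in take]
        selected_idx.extend(take)
    selected_idx.sort()  # preserve input order in the output
    return MatchResult(reads=[pool[i] for i in selected_idx], shortfalls=shortfalls)


def stats_to_tsv_row(label: str, stats: ReadSetStats) -> str:
    """One TSV row in the summary-table column order."""
    return "\t".join(
        [
            label,
            str(stats.num_seqs),
            str(stats.sum_len),
            str(stats.min_len),
            f"{stats.avg_len:.1f}",
            str(stats.max_len),
            f"{stats.q1_len:.1f}",
            f"{stats.median_len:.1f}",
            f"{stats.q3_len:.1f}",
            str(stats.n50),
            f"{stats.q20_pct:.2f}",
            f"{stats.q30_pct:.2f}",
        ]
    )
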