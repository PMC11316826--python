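"""Readers and writers for classifier output profiles and ground-truth tables.

Three input dialects are supported:

* kraken-style reports (``kreport``) as emitted by Kraken2/Bracken/Centrifuge:
  percent, clade reads, direct reads, rank code, taxid, indented name;
* mpa-style clade-string profiles (``k__...|g__...|s__...`` plus percent) as
  emitted by MetaPhlAn/mOTUs;
* a generic TSV profile dialect that doubles as the canonical on-disk form
  (KMA/CCMetagen/Kaiju summaries are converted to it; see docs/methods.md).

Ground truths (one row per expected taxon, optional sequence abundance and
genome length) use a small TSV with a ``dmc_id`` column. All formats are
tab-separated UTF-8 with ``#`` comment lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

__all__ = [
    "ProfileEntry",
    "Profile",
    "GroundTruthEntry",
    "GroundTruth",
    "ProfileParseError",
    "ProfileValidationError",
    "read_kreport",
    "read_mpa",
    "read_generic_profile",
    "read_ground_truth",
    "write_profile",
    "write_ground_truth",
]


class ProfileParseError(Exception):
    """Malformed input file; message carries file and line number."""


class ProfileValidationError(Exception):
    """Parsed content violates a profile/ground-truth invariant."""


@dataclass(frozen=True)
class ProfileEntry:
    """One taxon of a classifier profile.

    At least one of ``taxid``/``name`` and one of ``count``/``fraction``
    must be present; ``fraction`` is on [0, 1] of total reads.
    """

    taxid: Optional[int] = None
    name: Optional[str] = None
    rank: str = "no rank"
    count: Optional[int] = None
    fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.taxid is None and not self.name:
            raise ProfileValidationError("profile entry needs a taxid or a name")
        if self.count is None and self.fraction is None:
            raise ProfileValidationError("profile entry needs a count or a fraction")
        if self.count is not None and self.count < 0:
            raise ProfileValidationError(f"negative count {self.count}")
        if self.fraction is not None and not (0.0 <= self.fraction <= 1.0):
            raise ProfileValidationError(f"fraction {self.fraction} outside [0, 1]")


@dataclass
class Profile:
    """One classifier's output for one sample."""

    sample_id: str
    classifier_id: str
    entries: list[ProfileEntry] = field(default_factory=list)
    unclassified_count: Optional[int] = None
    unclassified_fraction: Optional[float] = None


@dataclass(frozen=True)
class GroundTruthEntry:
    taxid: Optional[int] = None
    name: Optional[str] = None
    fraction: Optional[float] = None
    genome_length: Optional[int] = None

    @property
    def key(self):
        return self.taxid if self.taxid is not None else self.name


@dataclass
class GroundTruth:
    """A DMC's expected composition.

    ``has_abundances`` is False when the community's exact relative
    abundances are unknown (possible for real DMCs); such truths are
    excluded from L1-distance computation but still support detection
    metrics.
    """

    dmc_id: str
    entries: list[GroundTruthEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [e.key for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ProfileValidationError(f"ground truth {self.dmc_id} has duplicate taxa")
        fracs = [e.fraction for e in self.entries if e.fraction is not None]
        if fracs:
            if len(fracs) != len(self.entries):
                raise ProfileValidationError(
                    f"ground truth {self.dmc_id}: abundances must be given for all taxa or none"
                )
            total = sum(fracs)
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ProfileValidationError(
                    f"ground truth {self.dmc_id}: fractions sum to {total}, expected 1"
                )

    @property
    def has_abundances(self) -> bool:
        return bool(self.entries) and self.entries[0].fraction is not None


# rank-code -> rank-label mapping for kreport files; suffixed codes (G1, S2,
# ...) denote clades between the named ranks and map to "no rank".
_KREPORT_RANKS = {
    "U": "unclassified",
    "R": "root",
    "D": "superkingdom",
    "K": "kingdom",
    "P": "phylum",
    "C": "class",
    "O": "order",
    "F": "family",
    "G": "genus",
    "S": "species",
}

_MPA_RANKS = {
    "k": "kingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
    "t": "strain",
}


def _noncomment_lines(path: Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_kreport(path: str | Path, sample_id: str, classifier_id: str) -> Profile:
    """Parse a kraken-style report into a :class:`Profile`.

    Counts are taken from the clade-reads column (reads at or below the
    taxon). An optional ``U`` row populates ``unclassified_count``; the root
    row is skipped (it aggregates everything classified).
    """
    path = Path(path)
    profile = Profile(sample_id=sample_id, classifier_id=classifier_id)
    for lineno, line in _noncomment_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ProfileParseError(f"{path}:{lineno}: expected >=6 tab-separated fields")
        _, clade_reads_s, _, rank_code, taxid_s, name = fields[:6]
        try:
            clade_reads = int(clade_reads_s)
            taxid = int(taxid_s)
        except ValueError as exc:
            raise ProfileParseError(f"{path}:{lineno}: non-numeric count/taxid field") from exc
        rank_code = rank_code.strip()
        base_code = rank_code[:1]
        if base_code not in _KREPORT_RANKS:
            raise ProfileParseError(f"{path}:{lineno}: unknown rank code {rank_code!r}")
        if base_code == "U":
            profile.unclassified_count = clade_reads
            continue
        if base_code == "R" and len(rank_code) == 1:
            continue
        rank = _KREPORT_RANKS[base_code] if len(rank_code) == 1 else "no rank"
        profile.entries.append(
            ProfileEntry(taxid=taxid, name=name.strip(), rank=rank, count=clade_reads)
        )
    return profile


def read_mpa(path: str | Path, sample_id: str, classifier_id: str) -> Profile:
    """Parse an mpa-style clade-string profile.

    Each line carries a clade string (``k__...|g__...|s__...``) and a percent
    abundance; only the deepest level of each line becomes an entry, so
    higher-rank summary lines (whose abundances double-count their children)
    are represented by their own lines, not duplicated. An
    ``UNCLASSIFIED``/``unassigned`` line populates ``unclassified_fraction``.
    """
    path = Path(path)
    profile = Profile(sample_id=sample_id, classifier_id=classifier_id)
    for lineno, line in _noncomment_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ProfileParseError(f"{path}:{lineno}: expected clade string and abundance")
        clade, pct_s = fields[0].strip(), fields[1]
        try:
            pct = float(pct_s)
        except ValueError as exc:
            raise ProfileParseError(f"{path}:{lineno}: non-numeric abundance {pct_s!r}") from exc
        if clade.upper() in ("UNCLASSIFIED", "UNASSIGNED", "UNKNOWN"):
            profile.unclassified_fraction = pct / 100.0
            continue
        deepest = clade.split("|")[-1]
        if len(deepest) < 3 or deepest[1:3] != "__":
            raise ProfileParseError(f"{path}:{lineno}: malformed clade level {deepest!r}")
        prefix = deepest[0]
        if prefix not in _MPA_RANKS:
            raise ProfileParseError(f"{path}:{lineno}: unknown clade prefix {prefix!r}")
        name = deepest[3:].replace("_", " ").strip()
        profile.entries.append(
            ProfileEntry(name=name, rank=_MPA_RANKS[prefix], fraction=pct / 100.0)
        )
    return profile


_GENERIC_COLUMNS = ["sample_id", "classifier_id", "taxid", "name", "rank", "count", "fraction"]


def read_generic_profile(path: str | Path) -> Profile:
    """Read the canonical generic TSV profile dialect.

    Header columns: sample_id, classifier_id, taxid, name, rank, count,
    fraction. Empty cells become absent fields. Rows named
    ``__unclassified__`` carry the unclassified count/fraction.
    """
    path = Path(path)
    rows = list(_noncomment_lines(path))
    if not rows:
        raise ProfileParseError(f"{path}: empty file")
    header = rows[0][1].split("\t")
    if header != _GENERIC_COLUMNS:
        raise ProfileParseError(
            f"{path}: bad header {header!r}, expected {_GENERIC_COLUMNS!r}"
        )
    profile: Optional[Profile] = None
    for lineno, line in rows[1:]:
        cells = line.split("\t")
        if len(cells) != len(_GENERIC_COLUMNS):
            raise ProfileParseError(f"{path}:{lineno}: expected {len(_GENERIC_COLUMNS)} cells")
        row = dict(zip(_GENERIC_COLUMNS, cells))
        if profile is None:
            profile = Profile(sample_id=row["sample_id"], classifier_id=row["classifier_id"])
        count = int(row["count"]) if row["count"] else None
        fraction = float(row["fraction"]) if row["fraction"] else None
        if row["name"] == "__unclassified__":
            profile.unclassified_count = count
            profile.unclassified_fraction = fraction
            continue
        try:
            profile.entries.append(
                ProfileEntry(
                    taxid=int(row["taxid"]) if row["taxid"] else None,
                    name=row["name"] or None,
                    rank=row["rank"] or "no rank",
                    count=count,
                    fraction=fraction,
                )
            )
        except ProfileValidationError as exc:
            raise ProfileValidationError(f"{path}:{lineno}: {exc}") from exc
    if profile is None:
        raise ProfileParseError(f"{path}: header-only file carries no sample/classifier ids")
    return profile


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_profile(profile: Profile, path: str | Path) -> None:
    """Write the canonical generic TSV dialect.

    Entries are sorted by descending fraction (then count), then ascending
    taxid/name, so two writes of the same profile are byte-identical and
    ``read_generic_profile(write_profile(p)) == p``.
    """
    path = Path(path)

    def sort_key(e: ProfileEntry):
        return (
            -(e.fraction if e.fraction is not None else -1.0),
            -(e.count if e.count is not None else -1),
            e.taxid if e.taxid is not None else 0,
            e.name or "",
        )

    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(_GENERIC_COLUMNS) + "\n")
        rows = []
        if profile.unclassified_count is not None or profile.unclassified_fraction is not None:
            rows.append(
                [profile.sample_id, profile.classifier_id, "", "__unclassified__",
                 "unclassified", _fmt(profile.unclassified_count),
                 _fmt(profile.unclassified_fraction)]
            )
        for e in sorted(profile.entries, key=sort_key):
            rows.append(
                [profile.sample_id, profile.classifier_id, _fmt(e.taxid), e.name or "",
                 e.rank, _fmt(e.count), _fmt(e.fraction)]
            )
        for row in rows:
            fh.write("\t".join(row) + "\n")


_TRUTH_COLUMNS = ["dmc_id", "taxid", "name", "fraction", "genome_length"]


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Read a DMC composition table.

    All-absent fractions are permitted (the truth is then flagged as lacking
    abundances); otherwise fractions must be present for every taxon and sum
    to 1 within 1e-6.
    """
    path = Path(path)
    rows = list(_noncomment_lines(path))
    if not rows:
        raise ProfileParseError(f"{path}: empty file")
    header = rows[0][1].split("\t")
    if header != _TRUTH_COLUMNS:
        raise ProfileParseError(f"{path}: bad header {header!r}, expected {_TRUTH_COLUMNS!r}")
    dmc_id = None
    entries = []
    for lineno, line in rows[1:]:
        cells = line.split("\t")
        if len(cells) != len(_TRUTH_COLUMNS):
            raise ProfileParseError(f"{path}:{lineno}: expected {len(_TRUTH_COLUMNS)} cells")
        row = dict(zip(_TRUTH_COLUMNS, cells))
        dmc_id = dmc_id or row["dmc_id"]
        fraction = float(row["fraction"]) if row["fraction"] else None
        if fraction is not None and not (0.0 <= fraction <= 1.0):
            raise ProfileValidationError(f"{path}:{lineno}: fraction {fraction} outside [0, 1]")
        entries.append(
            GroundTruthEntry(
                taxid=int(row["taxid"]) if row["taxid"] else None,
                name=row["name"] or None,
                fraction=fraction,
                genome_length=int(row["genome_length"]) if row["genome_length"] else None,
            )
        )
    if dmc_id is None:
        raise ProfileParseError(f"{path}: no data rows")
    return GroundTruth(dmc_id=dmc_id, entries=entries)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write a DMC composition table in the dialect `read_ground_truth` reads."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for e in truth.entries:
            fh.write(
                "\t".join(
                    [truth.dmc_id, _fmt(e.taxid), e.name or "", _fmt(e.fraction),
                     _fmt(e.genome_length)]
                )
                + "\n"
            )
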