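"""Rank projection and relative-abundance normalization.

Evaluation happens at genus and species rank only. Classifier entries below
the target rank are projected upward via the taxonomy and merged by
summation; entries classified only to genus receive, at species rank, a
"<Genus> unclassified" designation whose mass is tracked separately (it
names no species, so it can match no ground-truth species); entries above
genus are set aside as higher-rank mass. Relative abundances are always
computed over classified reads only — the unclassified fraction is omitted
from every denominator.

Sequence abundance (fraction of reads) over-represents large genomes;
:func:`sequence_to_taxonomic` applies the genome-length correction that
turns it into taxonomic abundance (fraction of organisms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from dmcbench.profile_io import Profile, ProfileEntry
from dmcbench.taxonomy import TaxonomyRef, ancestor_at_rank

__all__ = [
    "AbundanceVector",
    "RankProfile",
    "project_to_rank",
    "renormalize_classified",
    "sequence_to_taxonomic",
]

EVALUATION_RANKS = ("genus", "species")

# ranks strictly above genus in the standard lineage; entries at these ranks
# carry no genus/species information and become higher-rank mass
_ABOVE_GENUS = {
    "root", "superkingdom", "domain", "kingdom", "subkingdom", "phylum",
    "subphylum", "superclass", "class", "subclass", "order", "suborder",
    "superfamily", "family", "subfamily", "tribe",
}


@dataclass
class AbundanceVector:
    """Relative abundances over taxa at one rank.

    Weights are non-negative and sum to 1 (within 1e-9) unless the vector is
    empty. Taxon identity is the synchronized taxid (or name when no taxid
    exists, e.g. marker-profiler output evaluated by name).
    """

    rank: str
    weights: dict = field(default_factory=dict)

    def validate(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("negative abundance weight")
        if self.weights:
            total = sum(self.weights.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"abundance weights sum to {total}, expected 1")


@dataclass
class RankProfile:
    """A profile projected to a single evaluation rank.

    ``entries`` hold taxa resolved at the rank; ``unclassified_at_rank``
    holds, keyed by genus taxid, mass classified to a genus but not further
    (species rank only); ``higher_rank_mass`` is mass classified above genus.
    Count mass is conserved exactly across the three buckets.
    """

    sample_id: str
    classifier_id: str
    rank: str
    entries: list[ProfileEntry] = field(default_factory=list)
    unclassified_at_rank: dict = field(default_factory=dict)
    higher_rank_mass: float = 0.0
    higher_rank_count: int = 0
    unclassified_count: Optional[int] = None
    unclassified_fraction: Optional[float] = None


def project_to_rank(profile: Profile, ref: TaxonomyRef, rank: str) -> RankProfile:
    """Project a synchronized profile to genus or species rank.

    Entries at or below the target rank map to their ancestor at that rank
    and are merged by summing counts/fractions. At species rank, entries
    whose deepest resolvable rank is genus become "<Genus> unclassified"
    pseudo-mass keyed by the genus taxid. Entries above genus (or whose
    lineage lacks the target rank entirely) contribute to higher-rank mass.
    """
    if rank not in EVALUATION_RANKS:
        raise ValueError(f"rank must be one of {EVALUATION_RANKS}, got {rank!r}")

    out = RankProfile(
        sample_id=profile.sample_id,
        classifier_id=profile.classifier_id,
        rank=rank,
        unclassified_count=profile.unclassified_count,
        unclassified_fraction=profile.unclassified_fraction,
    )
    merged: dict[int, ProfileEntry] = {}
    for entry in profile.entries:
        if entry.taxid is None or entry.taxid not in ref.nodes:
            # unsynchronized leftovers carry no lineage: higher-rank bucket
            _add_higher(out, entry)
            continue
        target = ancestor_at_rank(ref, entry.taxid, rank)
        if target is not None:
            node = ref.nodes[target]
            projected = ProfileEntry(
                taxid=target, name=node.scientific_name, rank=rank,
                count=entry.count, fraction=entry.fraction,
            )
            if target in merged:
                merged[target] = _sum_entries(merged[target], projected)
            else:
                merged[target] = projected
            continue
        if rank == "species":
            genus = ancestor_at_rank(ref, entry.taxid, "genus")
            if genus is not None:
                bucket = out.unclassified_at_rank.setdefault(
                    genus, {"count": 0, "fraction": 0.0}
                )
                bucket["count"] += entry.count or 0
                bucket["fraction"] += entry.fraction or 0.0
                continue
        _add_higher(out, entry)
    out.entries = list(merged.values())
    return out


def _sum_entries(a: ProfileEntry, b: ProfileEntry) -> ProfileEntry:
    count = None
    if a.count is not None or b.count is not None:
        count = (a.count or 0) + (b.count or 0)
    fraction = None
    if a.fraction is not None or b.fraction is not None:
        fraction = (a.fraction or 0.0) + (b.fraction or 0.0)
    return ProfileEntry(taxid=a.taxid, name=a.name, rank=a.rank, count=count, fraction=fraction)


def _add_higher(out: RankProfile, entry: ProfileEntry) -> None:
    out.higher_rank_count += entry.count or 0
    out.higher_rank_mass += entry.fraction or 0.0


def renormalize_classified(profile: RankProfile) -> AbundanceVector:
    """Build a classified-only abundance vector from a rank profile.

    The denominator excludes the unclassified fraction, higher-rank mass and
    the "<Genus> unclassified" pseudo-mass: only taxa actually named at the
    rank enter the vector. Exact fractions are preferred when every entry
    carries one (counts are integer-quantized); otherwise counts are used.
    All reads unclassified yields an empty vector, not an error.
    """
    entries = profile.entries
    if not entries:
        return AbundanceVector(rank=profile.rank)
    use_fractions = all(e.fraction is not None for e in entries)
    if use_fractions:
        raw = {e.taxid if e.taxid is not None else e.name: e.fraction for e in entries}
    else:
        if not all(e.count is not None for e in entries):
            raise ValueError("entries mix counts and fractions; cannot normalize")
        raw = {e.taxid if e.taxid is not None else e.name: float(e.count) for e in entries}
    total = sum(raw.values())
    if total <= 0:
        return AbundanceVector(rank=profile.rank)
    vec = AbundanceVector(rank=profile.rank, weights={k: v / total for k, v in raw.items()})
    vec.validate()
    return vec


def sequence_to_taxonomic(
    vector: AbundanceVector, genome_lengths: Mapping
) -> AbundanceVector:
    """Convert sequence abundance to taxonomic abundance.

    Each weight is divided by its taxon's genome length and the vector is
    renormalized: w'_i = (w_i / L_i) / sum_j (w_j / L_j). Scale-invariant in
    the lengths. Raises ValueError listing taxa with missing or non-positive
    lengths.
    """
    if not vector.weights:
        return AbundanceVector(rank=vector.rank)
    bad = [
        t for t in vector.weights
        if t not in genome_lengths or genome_lengths[t] is None or genome_lengths[t] <= 0
    ]
    if bad:
        raise ValueError(f"missing or non-positive genome length for taxa: {bad}")
    corrected = {t: w / genome_lengths[t] for t, w in vector.weights.items()}
    total = sum(corrected.values())
    out = AbundanceVector(
        rank=vector.rank, weights={t: w / total for t, w in corrected.items()}
    )
    out.validate()
    return out
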