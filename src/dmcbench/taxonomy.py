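"""NCBI-style taxonomy handling: taxdump loading, taxid resolution, rank walks.

Reference databases and mock-community ground truths are rarely built against
the same NCBI Taxonomy snapshot; taxids get merged into others or deleted
outright between snapshots. Comparing classifier output to a ground truth
without synchronizing identifiers produces spurious false positives and
negatives, so every profile is passed through :func:`sync_profile` before
evaluation.

The taxdump dialect is the standard four-file distribution (nodes.dmp,
names.dmp, merged.dmp, delnodes.dmp): fields separated by ``\\t|\\t``,
records terminated by ``\\t|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

from dmcbench.profile_io import Profile, ProfileEntry


class TaxonomyError(Exception):
    """Structural problem in a taxonomy dump or resolution request."""


class TaxdumpParseError(TaxonomyError):
    """Malformed taxdump record; message names file and line."""


@dataclass(frozen=True)
class TaxonNode:
    """One node of the taxonomy graph."""

    taxid: int
    parent_taxid: int
    rank: str
    scientific_name: str


@dataclass
class TaxonomyRef:
    """A loaded taxonomy snapshot.

    Attributes
    ----------
    nodes : dict[int, TaxonNode]
        Current taxids.
    merged : dict[int, int]
        old taxid -> current taxid remappings.
    deleted : set[int]
        Taxids removed from the taxonomy.
    name_index : dict[str, int]
        Lower-cased scientific name -> taxid (scientific-name class only).
    """

    nodes: dict[int, TaxonNode] = field(default_factory=dict)
    merged: dict[int, int] = field(default_factory=dict)
    deleted: set[int] = field(default_factory=set)
    name_index: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if 1 not in self.nodes:
            raise TaxonomyError("taxonomy has no root node (taxid 1)")
        for node in self.nodes.values():
            if node.parent_taxid not in self.nodes:
                raise TaxonomyError(
                    f"node {node.taxid} references missing parent {node.parent_taxid}"
                )
        overlap = self.merged.keys() & self.nodes.keys()
        if overlap:
            raise TaxonomyError(f"merged taxids also present as nodes: {sorted(overlap)[:5]}")
        bad_deleted = self.deleted & (self.nodes.keys() | self.merged.keys())
        if bad_deleted:
            raise TaxonomyError(
                f"deleted taxids also present as nodes/merged: {sorted(bad_deleted)[:5]}"
            )


def _iter_dmp_records(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.endswith("\t|"):
                line = line[: -len("\t|")]
            yield lineno, line.split("\t|\t")


def load_taxonomy(
    nodes_path: str | Path,
    names_path: str | Path,
    merged_path: str | Path,
    delnodes_path: str | Path,
) -> TaxonomyRef:
    """Load a taxdump file set into a :class:`TaxonomyRef`.

    Only ``scientific name`` class entries from names.dmp populate the
    name index. Raises :class:`TaxdumpParseError` on malformed records and
    :class:`TaxonomyError` if the root (taxid 1) is missing or a parent
    link dangles.
    """
    nodes_path, names_path = Path(nodes_path), Path(names_path)
    merged_path, delnodes_path = Path(merged_path), Path(delnodes_path)

    ref = TaxonomyRef()
    ranks: dict[int, tuple[int, str]] = {}
    for lineno, fields in _iter_dmp_records(nodes_path):
        if len(fields) < 3:
            raise TaxdumpParseError(f"{nodes_path}:{lineno}: expected >=3 fields, got {len(fields)}")
        try:
            taxid, parent = int(fields[0]), int(fields[1])
        except ValueError as exc:
            raise TaxdumpParseError(f"{nodes_path}:{lineno}: non-integer taxid field") from exc
        ranks[taxid] = (parent, fields[2].strip())

    names: dict[int, str] = {}
    for lineno, fields in _iter_dmp_records(names_path):
        if len(fields) < 4:
            raise TaxdumpParseError(f"{names_path}:{lineno}: expected >=4 fields, got {len(fields)}")
        try:
            taxid = int(fields[0])
        except ValueError as exc:
            raise TaxdumpParseError(f"{names_path}:{lineno}: non-integer taxid field") from exc
        if fields[3].strip() == "scientific name":
            names[taxid] = fields[1].strip()

    for taxid, (parent, rank) in ranks.items():
        name = names.get(taxid, f"taxid:{taxid}")
        ref.nodes[taxid] = TaxonNode(taxid=taxid, parent_taxid=parent, rank=rank, scientific_name=name)
        ref.name_index[name.lower()] = taxid

    for lineno, fields in _iter_dmp_records(merged_path):
        if len(fields) < 2:
            raise TaxdumpParseError(f"{merged_path}:{lineno}: expected 2 fields, got {len(fields)}")
        try:
            ref.merged[int(fields[0])] = int(fields[1])
        except ValueError as exc:
            raise TaxdumpParseError(f"{merged_path}:{lineno}: non-integer taxid field") from exc

    for lineno, fields in _iter_dmp_records(delnodes_path):
        try:
            ref.deleted.add(int(fields[0]))
        except ValueError as exc:
            raise TaxdumpParseError(f"{delnodes_path}:{lineno}: non-integer taxid field") from exc

    ref.validate()
    return ref


ResolutionStatus = Literal["current", "merged", "deleted", "unknown"]


@dataclass(frozen=True)
class Resolution:
    status: ResolutionStatus
    current_taxid: Optional[int] = None


def resolve_taxid(ref: TaxonomyRef, taxid: int) -> Resolution:
    """Resolve a possibly outdated taxid against a taxonomy snapshot.

    Merged chains are followed transitively with a visited-set cycle guard;
    real dumps are single-hop but robustness is cheap.
    """
    if taxid in ref.nodes:
        return Resolution("current", taxid)
    if taxid in ref.merged:
        seen = {taxid}
        current = ref.merged[taxid]
        while current not in ref.nodes:
            if current in seen:
                raise TaxonomyError(f"merged chain cycle at taxid {current}")
            seen.add(current)
            if current in ref.merged:
                current = ref.merged[current]
            elif current in ref.deleted:
                return Resolution("deleted")
            else:
                return Resolution("unknown")
        return Resolution("merged", current)
    if taxid in ref.deleted:
        return Resolution("deleted")
    return Resolution("unknown")


def ancestor_at_rank(ref: TaxonomyRef, taxid: int, rank: str) -> Optional[int]:
    """Walk parent links from ``taxid`` and return the first node at ``rank``.

    The resolved node itself counts if its rank matches. Returns None when the
    walk reaches the root without a match (higher ranks are never substituted
    downward). Raises :class:`TaxonomyError` for unresolvable taxids.
    """
    res = resolve_taxid(ref, taxid)
    if res.current_taxid is None:
        raise TaxonomyError(f"taxid {taxid} not resolvable ({res.status})")
    current = res.current_taxid
    while True:
        node = ref.nodes[current]
        if node.rank == rank:
            return node.taxid
        if node.parent_taxid == node.taxid:  # root
            return None
        current = node.parent_taxid


@dataclass
class SyncResult:
    """Outcome of synchronizing a profile against a taxonomy snapshot."""

    profile: Profile
    dropped_entries: int
    dropped_count: int
    dropped_fraction: float


def _merge_entries(a: ProfileEntry, b: ProfileEntry) -> ProfileEntry:
    count = None
    if a.count is not None or b.count is not None:
        count = (a.count or 0) + (b.count or 0)
    fraction = None
    if a.fraction is not None or b.fraction is not None:
        fraction = (a.fraction or 0.0) + (b.fraction or 0.0)
    return ProfileEntry(taxid=a.taxid, name=a.name, rank=a.rank, count=count, fraction=fraction)


def sync_profile(ref: TaxonomyRef, profile: Profile) -> SyncResult:
    """Remap a profile's taxids onto a taxonomy snapshot.

    Merged taxids are rewritten to their current ids; entries that collide
    after remapping are combined by summing counts and fractions. Deleted or
    unknown taxids (and entries without a taxid) fall back to an exact,
    case-insensitive scientific-name lookup; entries that still cannot be
    placed are dropped and tallied. Abundance mass is conserved:
    output mass + dropped mass = input mass.
    """
    kept: dict[int, ProfileEntry] = {}
    dropped_entries = 0
    dropped_count = 0
    dropped_fraction = 0.0
    for entry in profile.entries:
        target: Optional[int] = None
        if entry.taxid is not None:
            res = resolve_taxid(ref, entry.taxid)
            target = res.current_taxid
        if target is None and entry.name:
            target = ref.name_index.get(entry.name.strip().lower())
        if target is None:
            dropped_entries += 1
            dropped_count += entry.count or 0
            dropped_fraction += entry.fraction or 0.0
            continue
        node = ref.nodes[target]
        synced = ProfileEntry(
            taxid=target,
            name=node.scientific_name,
            rank=node.rank,
            count=entry.count,
            fraction=entry.fraction,
        )
        if target in kept:
            kept[target] = _merge_entries(kept[target], synced)
        else:
            kept[target] = synced

    out = Profile(
        sample_id=profile.sample_id,
        classifier_id=profile.classifier_id,
        entries=list(kept.values()),
        unclassified_count=profile.unclassified_count,
        unclassified_fraction=profile.unclassified_fraction,
    )
    return SyncResult(
        profile=out,
        dropped_entries=dropped_entries,
        dropped_count=dropped_count,
        dropped_fraction=dropped_fraction,
    )
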