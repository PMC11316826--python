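"""Detection metrics, L1 abundance distance, PR curves and AUPRC.

A taxon predicted by a classifier is a true positive (TP) if it is present
in the mock community, a false positive (FP) otherwise; a community taxon
the classifier misses is a false negative (FN). From these:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

with the convention that an empty denominator yields 0.

Abundance accuracy is the L1 distance between the truth and predicted
relative-abundance vectors over their union support; it ranges from 0
(every TP at its exact abundance) to 2 (no TPs at all).

Because false positives concentrate at low relative abundance, a detection
threshold t removes every taxon whose classified-only abundance falls below
it. Sweeping t traces a precision-recall curve, summarized by the area
under it (AUPRC, trapezoid rule): 1 means some threshold separates TPs from
FPs perfectly, 0 means no threshold recovers any community taxon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from dmcbench.abundance import AbundanceVector
from dmcbench.profile_io import GroundTruth
from dmcbench.taxonomy import TaxonomyRef, ancestor_at_rank, resolve_taxid

__all__ = [
    "DetectionOutcome",
    "ConfusionMetrics",
    "PRPoint",
    "PRCurve",
    "EvaluationError",
    "detection_sets",
    "confusion_metrics",
    "l1_distance",
    "apply_abundance_filter",
    "pr_curve",
    "auprc",
    "threshold_sweep_table",
    "truth_taxa_at_rank",
    "truth_abundance_vector",
    "DEFAULT_THRESHOLD_GRID",
]

# 0% to 1.20% in 0.05% steps, stored as fractions: 25 thresholds
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = tuple(
    round(0.0005 * i, 10) for i in range(25)
)


class EvaluationError(Exception):
    """A truth or prediction taxon could not be resolved for evaluation."""


@dataclass(frozen=True)
class DetectionOutcome:
    """TP/FP/FN taxon sets for one prediction against one truth."""

    tp: frozenset
    fp: frozenset
    fn: frozenset


@dataclass(frozen=True)
class ConfusionMetrics:
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    precision: float
    recall: float
    tp_count: int
    fp_count: int
    fn_count: int


@dataclass(frozen=True)
class PRCurve:
    points: tuple[PRPoint, ...]
    auprc: float


def truth_taxa_at_rank(truth: GroundTruth, ref: TaxonomyRef, rank: str) -> dict:
    """Resolve ground-truth taxa at the target rank.

    Returns a mapping of rank-level taxid -> list of truth entries that
    project there (a species truth maps to its genus at rank=genus; several
    species can share one genus). Raises :class:`EvaluationError` naming any
    unresolvable taxon.
    """
    resolved: dict = {}
    for entry in truth.entries:
        taxid = None
        if entry.taxid is not None:
            res = resolve_taxid(ref, entry.taxid)
            taxid = res.current_taxid
        if taxid is None and entry.name:
            taxid = ref.name_index.get(entry.name.strip().lower())
        if taxid is None:
            raise EvaluationError(
                f"ground-truth taxon not resolvable: taxid={entry.taxid} name={entry.name!r}"
            )
        at_rank = ancestor_at_rank(ref, taxid, rank)
        if at_rank is None:
            raise EvaluationError(
                f"ground-truth taxon {entry.name!r} (taxid {taxid}) has no {rank}-rank ancestor"
            )
        resolved.setdefault(at_rank, []).append(entry)
    return resolved


def truth_abundance_vector(
    truth: GroundTruth, ref: TaxonomyRef, rank: str
) -> Optional[AbundanceVector]:
    """Truth relative abundances at the target rank, or None when unavailable.

    Species sharing a genus have their fractions summed at rank=genus.
    """
    if not truth.has_abundances:
        return None
    resolved = truth_taxa_at_rank(truth, ref, rank)
    weights = {
        taxid: sum(e.fraction for e in entries) for taxid, entries in resolved.items()
    }
    vec = AbundanceVector(rank=rank, weights=weights)
    vec.validate()
    return vec


def _canonical_predicted(predicted: AbundanceVector, ref: TaxonomyRef) -> dict:
    """Map predicted vector keys onto synchronized taxids (name fallback)."""
    out: dict = {}
    for key, weight in predicted.weights.items():
        taxid = None
        if isinstance(key, int):
            taxid = resolve_taxid(ref, key).current_taxid
        else:
            taxid = ref.name_index.get(str(key).strip().lower())
        ident = taxid if taxid is not None else key
        out[ident] = out.get(ident, 0.0) + weight
    return out


def detection_sets(
    predicted: AbundanceVector, truth: GroundTruth, ref: TaxonomyRef, rank: str
) -> DetectionOutcome:
    """Compare predicted taxa to the mock community at one rank.

    Identities are synchronized taxids, with case-insensitive scientific-name
    fallback for entries without a usable taxid.
    """
    truth_taxa = frozenset(truth_taxa_at_rank(truth, ref, rank))
    pred_taxa = frozenset(_canonical_predicted(predicted, ref))
    return DetectionOutcome(
        tp=pred_taxa & truth_taxa,
        fp=pred_taxa - truth_taxa,
        fn=truth_taxa - pred_taxa,
    )


def confusion_metrics(outcome: DetectionOutcome) -> ConfusionMetrics:
    """Precision, recall and F1 from TP/FP/FN counts (0 on empty denominators)."""
    tp, fp, fn = len(outcome.tp), len(outcome.fp), len(outcome.fn)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return ConfusionMetrics(precision=precision, recall=recall, f1=f1)


def l1_distance(p: AbundanceVector, q: AbundanceVector) -> float:
    """L1 distance between two abundance vectors over their union support.

    Absent taxa contribute 0; the result lies in [0, 2] for vectors on the
    simplex and is symmetric in its arguments.
    """
    if p.rank != q.rank:
        raise ValueError(f"rank mismatch: {p.rank!r} vs {q.rank!r}")
    support = set(p.weights) | set(q.weights)
    return float(sum(abs(p.weights.get(t, 0.0) - q.weights.get(t, 0.0)) for t in support))


def apply_abundance_filter(v: AbundanceVector, t: float) -> AbundanceVector:
    """Remove taxa with abundance strictly below threshold t.

    Taxa at exactly t are retained ("below this threshold" implies
    strict-less removal). Weights are NOT renormalized: detection after
    filtering is about which taxa survive, and the surviving weights keep
    their classified-only scale.
    """
    if not (0.0 <= t <= 1.0):
        raise ValueError(f"threshold {t} outside [0, 1]")
    return AbundanceVector(
        rank=v.rank, weights={k: w for k, w in v.weights.items() if w >= t}
    )


def auprc(points: Sequence[tuple[float, float]]) -> float:
    """Area under a precision-recall point set by the trapezoid rule.

    For each distinct recall the maximum precision is kept; points are
    sorted by ascending recall and an anchor at recall 0 (carrying the
    precision of the smallest-recall point) is prepended before trapezoid
    integration over recall. With this construction a perfectly separable
    prediction attains 1 and a truth-free prediction attains 0.
    """
    if not points:
        raise ValueError("auprc needs at least one (precision, recall) point")
    best: dict[float, float] = {}
    for precision, recall in points:
        if recall not in best or precision > best[recall]:
            best[recall] = precision
    recalls = sorted(best)
    precisions = [best[r] for r in recalls]
    if recalls[0] > 0.0:
        recalls.insert(0, 0.0)
        precisions.insert(0, precisions[0])
    return float(np.trapezoid(precisions, recalls))


def pr_curve(
    predicted: AbundanceVector, truth: GroundTruth, ref: TaxonomyRef, rank: str
) -> PRCurve:
    """PR curve over all observed abundances of the predicted vector.

    Thresholds are {0} plus each distinct predicted weight; each threshold is
    evaluated by filter -> detection -> confusion metrics. Recall is
    non-increasing along ascending thresholds.
    """
    thresholds = sorted({0.0} | set(predicted.weights.values()))
    points = []
    for t in thresholds:
        filtered = apply_abundance_filter(predicted, t)
        outcome = detection_sets(filtered, truth, ref, rank)
        cm = confusion_metrics(outcome)
        points.append(
            PRPoint(
                threshold=t,
                precision=cm.precision,
                recall=cm.recall,
                tp_count=len(outcome.tp),
                fp_count=len(outcome.fp),
                fn_count=len(outcome.fn),
            )
        )
    area = auprc([(p.precision, p.recall) for p in points])
    return PRCurve(points=tuple(points), auprc=area)


def threshold_sweep_table(
    predicted: AbundanceVector,
    truth: GroundTruth,
    ref: TaxonomyRef,
    rank: str,
    grid: Iterable[float] = DEFAULT_THRESHOLD_GRID,
) -> list[dict]:
    """Fixed-grid threshold sweep (default 0% to 1.20% in 0.05% steps).

    Returns one row per threshold with precision, recall and F1 after
    filtering at that threshold.
    """
    rows = []
    for t in grid:
        filtered = apply_abundance_filter(predicted, t)
        cm = confusion_metrics(detection_sets(filtered, truth, ref, rank))
        rows.append(
            {"threshold": float(t), "precision": cm.precision,
             "recall": cm.recall, "f1": cm.f1}
        )
    return rows
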