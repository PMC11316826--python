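"""Detection metrics, L1 distance, threshold filtering, PR curves, AUPRC."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dmcbench import (
    AbundanceVector,
    GroundTruth,
    GroundTruthEntry,
    apply_abundance_filter,
    auprc,
    confusion_metrics,
    detection_sets,
    l1_distance,
    pr_curve,
    threshold_sweep_table,
)
from dmcbench.metrics import DEFAULT_THRESHOLD_GRID, DetectionOutcome, EvaluationError


def _outcome(tp, fp, fn):
    return DetectionOutcome(tp=frozenset(tp), fp=frozenset(fp), fn=frozenset(fn))


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "tp,fp,fn,precision,recall,f1",
        [
            (3, 1, 0, 0.75, 1.0, 6 / 7),
            (0, 5, 2, 0.0, 0.0, 0.0),
            (4, 0, 0, 1.0, 1.0, 1.0),
            (0, 0, 0, 0.0, 0.0, 0.0),
            (2, 2, 2, 0.5, 0.5, 0.5),
        ],
    )
    def test_forced_arithmetic(self, tp, fp, fn, precision, recall, f1):
        out = _outcome(range(tp), range(100, 100 + fp), range(200, 200 + fn))
        cm = confusion_metrics(out)
        assert cm.precision == pytest.approx(precision)
        assert cm.recall == pytest.approx(recall)
        assert cm.f1 == pytest.approx(f1)

    def test_f1_is_harmonic_mean(self):
        cm = confusion_metrics(_outcome(range(3), range(100, 102), range(200, 201)))
        expected = 2 * cm.precision * cm.recall / (cm.precision + cm.recall)
        assert cm.f1 == pytest.approx(expected, abs=1e-12)


class TestDetectionSets:
    def test_set_algebra(self, mini_ref, even_truth):
        truth_taxids = [e.taxid for e in even_truth.entries]
        decoy = next(
            n.taxid for n in mini_ref.nodes.values()
            if n.rank == "species" and n.taxid not in truth_taxids
        )
        vec = AbundanceVector(
            rank="species",
            weights={truth_taxids[0]: 0.5, truth_taxids[1]: 0.3, decoy: 0.2},
        )
        out = detection_sets(vec, even_truth, mini_ref, "species")
        assert out.tp == {truth_taxids[0], truth_taxids[1]}
        assert out.fp == {decoy}
        assert out.fn == set(truth_taxids[2:])

    def test_empty_prediction(self, mini_ref, even_truth):
        out = detection_sets(AbundanceVector(rank="species"), even_truth, mini_ref, "species")
        assert not out.tp and not out.fp
        assert len(out.fn) == len(even_truth.entries)

    def test_perfect_prediction(self, mini_ref, even_truth):
        vec = AbundanceVector(
            rank="species", weights={e.taxid: e.fraction for e in even_truth.entries}
        )
        out = detection_sets(vec, even_truth, mini_ref, "species")
        assert not out.fp and not out.fn

    def test_name_fallback_matches(self, mini_ref, even_truth):
        vec = AbundanceVector(rank="species", weights={"escherichia coli": 1.0})
        out = detection_sets(vec, even_truth, mini_ref, "species")
        assert len(out.tp) == 1

    def test_genus_rank_maps_truth_species_to_genus(self, mini_ref, even_truth):
        genus = mini_ref.nodes[
            mini_ref.nodes[even_truth.entries[0].taxid].parent_taxid
        ]
        vec = AbundanceVector(rank="genus", weights={genus.taxid: 1.0})
        out = detection_sets(vec, even_truth, mini_ref, "genus")
        assert genus.taxid in out.tp

    def test_unresolvable_truth_taxon_raises(self, mini_ref):
        truth = GroundTruth(
            dmc_id="bad", entries=[GroundTruthEntry(taxid=777777777, name="Ghost organism")]
        )
        vec = AbundanceVector(rank="species")
        with pytest.raises(EvaluationError, match="Ghost organism|777777777"):
            detection_sets(vec, truth, mini_ref, "species")


class TestL1Distance:
    def test_identical_vectors_zero(self):
        p = AbundanceVector(rank="species", weights={1: 0.6, 2: 0.4})
        assert l1_distance(p, p) == 0.0

    def test_disjoint_supports_two(self):
        p = AbundanceVector(rank="species", weights={1: 0.6, 2: 0.4})
        q = AbundanceVector(rank="species", weights={3: 1.0})
        assert l1_distance(p, q) == pytest.approx(2.0)

    def test_forced_arithmetic(self):
        p = AbundanceVector(rank="species", weights={"A": 1.0})
        q = AbundanceVector(rank="species", weights={"A": 0.5, "B": 0.5})
        assert l1_distance(p, q) == pytest.approx(1.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 9), st.floats(0.01, 1.0), st.floats(0.01, 1.0),
                      st.floats(0.01, 1.0)),
            min_size=1, max_size=8, unique_by=lambda t: t[0],
        )
    )
    def test_metric_properties(self, data):
        """Symmetry, non-negativity, triangle inequality on the simplex."""
        def normalize(idx):
            total = sum(row[idx] for row in data)
            return AbundanceVector(
                rank="species", weights={row[0]: row[idx] / total for row in data}
            )
        p, q, r = normalize(1), normalize(2), normalize(3)
        assert l1_distance(p, q) == pytest.approx(l1_distance(q, p))
        assert l1_distance(p, q) >= 0.0
        assert l1_distance(p, r) <= l1_distance(p, q) + l1_distance(q, r) + 1e-12
        assert l1_distance(p, q) <= 2.0 + 1e-12


class TestAbundanceFilter:
    def test_zero_threshold_identity(self):
        v = AbundanceVector(rank="species", weights={1: 0.6, 2: 0.4})
        assert apply_abundance_filter(v, 0.0).weights == v.weights

    def test_low_abundance_taxa_removed(self):
        v = AbundanceVector(rank="species", weights={"A": 0.6, "B": 0.05, "C": 0.0004})
        out = apply_abundance_filter(v, 0.0005)
        assert set(out.weights) == {"A", "B"}

    def test_exact_threshold_retained(self):
        v = AbundanceVector(rank="species", weights={"A": 0.999, "B": 0.001})
        assert "B" in apply_abundance_filter(v, 0.001).weights

    def test_threshold_out_of_range(self):
        v = AbundanceVector(rank="species", weights={"A": 1.0})
        with pytest.raises(ValueError):
            apply_abundance_filter(v, 1.5)


def auprc_oracle(points, refinement=200_000):
    """Rectangle-refinement integration of the max-precision step envelope."""
    best = {}
    for precision, recall in points:
        best[recall] = max(best.get(recall, 0.0), precision)
    recalls = sorted(best)
    precisions = [best[r] for r in recalls]
    if recalls[0] > 0.0:
        recalls.insert(0, 0.0)
        precisions.insert(0, precisions[0])
    if len(recalls) == 1:
        return 0.0
    total = 0.0
    for (r0, p0), (r1, p1) in zip(zip(recalls, precisions), zip(recalls[1:], precisions[1:])):
        if r1 == r0:
            continue
        n = max(2, int(refinement * (r1 - r0)))
        xs = np.linspace(r0, r1, n)
        ys = p0 + (xs - r0) * (p1 - p0) / (r1 - r0)
        total += float(np.trapezoid(ys, xs))
    return total


class TestAuprc:
    def test_single_zero_point(self):
        assert auprc([(0.0, 0.0)]) == 0.0

    def test_perfect_curve(self):
        assert auprc([(1.0, 0.5), (1.0, 1.0)]) == pytest.approx(1.0)

    def test_hand_trapezoid(self):
        # anchor at recall 0 carries precision 1.0; area = 0.5 + 0.375
        assert auprc([(1.0, 0.5), (0.5, 1.0)]) == pytest.approx(0.875)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_refinement_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 12))
        points = [(float(rng.random()), float(rng.random())) for _ in range(n)]
        assert auprc(points) == pytest.approx(auprc_oracle(points), abs=1e-6)


class TestPrCurve:
    def _vector(self, truth, extras):
        weights = {e.taxid: e.fraction for e in truth.entries}
        weights.update(extras)
        total = sum(weights.values())
        return AbundanceVector(
            rank="species", weights={k: v / total for k, v in weights.items()}
        )

    def test_separable_prediction_attains_perfect_point(self, mini_ref, even_truth):
        decoys = [
            n.taxid for n in mini_ref.nodes.values()
            if n.rank == "species" and n.taxid not in {e.taxid for e in even_truth.entries}
        ][:4]
        vec = self._vector(even_truth, {d: 0.001 for d in decoys})
        curve = pr_curve(vec, even_truth, mini_ref, "species")
        assert any(p.precision == 1.0 and p.recall == 1.0 for p in curve.points)
        assert curve.auprc == pytest.approx(1.0)

    def test_disjoint_prediction_all_zero(self, mini_ref, even_truth):
        decoys = [
            n.taxid for n in mini_ref.nodes.values()
            if n.rank == "species" and n.taxid not in {e.taxid for e in even_truth.entries}
        ][:4]
        vec = AbundanceVector(rank="species", weights={d: 0.25 for d in decoys})
        curve = pr_curve(vec, even_truth, mini_ref, "species")
        assert all(p.precision == 0.0 and p.recall == 0.0 for p in curve.points)
        assert curve.auprc == 0.0

    def test_empty_prediction_single_point(self, mini_ref, even_truth):
        curve = pr_curve(AbundanceVector(rank="species"), even_truth, mini_ref, "species")
        assert len(curve.points) == 1
        assert curve.points[0].threshold == 0.0 and curve.points[0].recall == 0.0

    def test_recall_non_increasing_in_threshold(self, mini_ref, even_truth):
        rng = np.random.default_rng(3)
        decoys = [
            n.taxid for n in mini_ref.nodes.values()
            if n.rank == "species" and n.taxid not in {e.taxid for e in even_truth.entries}
        ]
        vec = self._vector(even_truth, {d: float(w) for d, w in
                                        zip(decoys, rng.uniform(0.0001, 0.5, len(decoys)))})
        curve = pr_curve(vec, even_truth, mini_ref, "species")
        recalls = [p.recall for p in curve.points]
        fps = [p.fp_count for p in curve.points]
        assert recalls == sorted(recalls, reverse=True)
        assert fps == sorted(fps, reverse=True)


class TestThresholdSweep:
    def test_default_grid_has_25_rows(self, mini_ref, even_truth):
        vec = AbundanceVector(
            rank="species", weights={e.taxid: e.fraction for e in even_truth.entries}
        )
        rows = threshold_sweep_table(vec, even_truth, mini_ref, "species")
        assert len(rows) == 25
        assert rows[0]["threshold"] == 0.0
        assert rows[-1]["threshold"] == pytest.approx(0.012)

    def test_grid_zero_matches_unfiltered_metrics(self, mini_ref, even_truth):
        vec = AbundanceVector(
            rank="species", weights={e.taxid: e.fraction for e in even_truth.entries}
        )
        rows = threshold_sweep_table(vec, even_truth, mini_ref, "species", grid=[0.0])
        cm = confusion_metrics(detection_sets(vec, even_truth, mini_ref, "species"))
        assert rows[0]["precision"] == cm.precision
        assert rows[0]["recall"] == cm.recall

    def test_monotone_recall_down_the_table(self, mini_ref, even_truth):
        rng = np.random.default_rng(9)
        weights = {e.taxid: float(w) for e, w in
                   zip(even_truth.entries, rng.uniform(0.001, 1.0, len(even_truth.entries)))}
        total = sum(weights.values())
        vec = AbundanceVector(
            rank="species", weights={k: v / total for k, v in weights.items()}
        )
        rows = threshold_sweep_table(vec, even_truth, mini_ref, "species")
        recalls = [r["recall"] for r in rows]
        assert recalls == sorted(recalls, reverse=True)

    def test_default_grid_is_percent_steps(self):
        grid = np.asarray(DEFAULT_THRESHOLD_GRID)
        assert np.allclose(np.diff(grid), 0.0005)
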