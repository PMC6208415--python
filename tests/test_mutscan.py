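"""Mutant classification, inverse-CDF curves, the permutation test and the
pathway-network hull volume."""

import numpy as np
import pytest

from infostery.mutscan import (
    HIGHLY_DELETERIOUS,
    NEUTRAL,
    MutantStats,
    classify_mutants,
    icdf_curves,
    label_from_deltaE,
    pathway_hull_volume,
    permutation_curve_test,
)
from infostery.pathways import Pathway, PathwaySet


def stats(mid, n_hc, label=None, delta_e=None):
    return MutantStats(
        mutation_id=mid,
        n_pathways_gt={3: n_hc, 4: n_hc, 5: 0, 6: 0},
        n_highly_connected=n_hc,
        delta_e=delta_e,
        label=label,
    )


class TestLabels:
    @pytest.mark.parametrize(
        "de,expected",
        [
            (-1.89, HIGHLY_DELETERIOUS),
            (-1.01, HIGHLY_DELETERIOUS),
            (-1.0, "deleterious"),
            (-0.5, "deleterious"),
            (-0.2, NEUTRAL),  # inclusive boundary
            (0.0, NEUTRAL),
            (0.34, NEUTRAL),  # beneficial folds into neutral
        ],
    )
    def test_deltaE_class_thresholds(self, de, expected):
        assert label_from_deltaE(de) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            label_from_deltaE(float("nan"))


class TestClassifier:
    def test_strict_inequality_call(self):
        wt = stats("WT", 10)
        res = classify_mutants([stats("a", 13), stats("b", 12)], wt, x=1.2)
        assert res.calls["a"] == HIGHLY_DELETERIOUS
        assert res.calls["b"] == NEUTRAL

    def test_monotone_in_x(self):
        wt = stats("WT", 10)
        muts = [stats(f"m{k}", k) for k in range(5, 30, 2)]
        called = []
        for x in (1.0, 1.4, 1.8, 2.2):
            res = classify_mutants(muts, wt, x=x)
            called.append(
                {m for m, c in res.calls.items() if c == HIGHLY_DELETERIOUS}
            )
        for a, b in zip(called, called[1:]):
            assert b <= a

    def test_confusion_against_labels(self):
        wt = stats("WT", 10)
        muts = [
            stats("d1", 20, label=HIGHLY_DELETERIOUS),
            stats("d2", 11, label=HIGHLY_DELETERIOUS),
            stats("n1", 9, label=NEUTRAL),
            stats("n2", 14, label=NEUTRAL),
        ]
        res = classify_mutants(muts, wt, x=1.2)
        c = res.confusion
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 1)

    def test_x_grid_row_structure(self):
        wt = stats("WT", 10)
        muts = [stats(f"m{k}", n, label=HIGHLY_DELETERIOUS if n > 15 else NEUTRAL)
                for k, n in enumerate([8, 12, 14, 18, 22, 26])]
        rows = {}
        for x in np.arange(1.0, 2.5, 0.2):
            res = classify_mutants(muts, wt, x=round(float(x), 1))
            rows[round(float(x), 1)] = res.metrics["sens"]
        # sensitivity never increases as the threshold rises
        vals = [rows[k] for k in sorted(rows)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestCurves:
    def test_left_of_support_is_hundred(self):
        curves = icdf_curves(np.array([1.0, 2.0, 3.0]), ["a", "a", "a"])
        xs, ys = curves["a"]
        assert ys[0] == pytest.approx(100 * 2 / 3)  # at x=1, strictly above
        assert (np.array([100.0 * (np.array([1, 2, 3]) > 0).mean()])) == 100.0

    def test_at_max_value_is_zero(self):
        curves = icdf_curves(np.array([1.0, 2.0, 3.0]), ["a", "a", "a"])
        xs, ys = curves["a"]
        assert ys[-1] == 0.0

    def test_strict_counting_at_ties(self):
        curves = icdf_curves(np.array([1.0, 2, 2, 5]), ["a"] * 4)
        xs, ys = curves["a"]
        assert ys[list(xs).index(2.0)] == pytest.approx(25.0)

    def test_curves_non_increasing(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 40, size=30).astype(float)
        labels = ["a"] * 15 + ["b"] * 15
        for xs, ys in icdf_curves(vals, labels).values():
            assert all(a >= b - 1e-12 for a, b in zip(ys, ys[1:]))


class TestPermutationTest:
    def test_perfect_separation_gives_small_p(self):
        vals = np.array([1.0, 2, 3, 10, 11, 12])
        labels = ["a"] * 3 + ["b"] * 3
        _, p = permutation_curve_test(vals, labels, "a", "b", 999, seed=0)
        # C(6,3) = 20 label splits; only the 2 extreme ones reach the
        # observed statistic -> p near 0.1 at best for n=6
        assert p <= 0.15

    def test_identical_multisets_give_p_one(self):
        vals = np.array([1.0, 2, 3, 1, 2, 3])
        labels = ["a"] * 3 + ["b"] * 3
        obs, p = permutation_curve_test(vals, labels, "a", "b", 499, seed=1)
        assert obs == 0.0
        assert p == 1.0

    def test_symmetric_in_class_order(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=12)
        labels = ["a"] * 6 + ["b"] * 6
        _, p1 = permutation_curve_test(vals, labels, "a", "b", 299, seed=7)
        _, p2 = permutation_curve_test(vals, labels, "b", "a", 299, seed=7)
        assert p1 == p2

    def test_p_value_range(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=10)
        labels = ["a"] * 5 + ["b"] * 5
        _, p = permutation_curve_test(vals, labels, "a", "b", 99, seed=2)
        assert 1 / 100 <= p <= 1

    def test_degenerate_class_rejected(self):
        with pytest.raises(ValueError):
            permutation_curve_test(
                np.array([1.0, 2, 3]), ["a", "b", "b"], "a", "b", 99
            )

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=14)
        labels = ["a"] * 7 + ["b"] * 7
        r1 = permutation_curve_test(vals, labels, "a", "b", 199, seed=42)
        r2 = permutation_curve_test(vals, labels, "a", "b", 199, seed=42)
        assert r1 == r2


class TestHullVolume:
    def test_unit_cube_volume(self):
        corners = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
            dtype=float,
        )
        # pathways covering all 8 corners with every vertex at degree >= 2
        ps = PathwaySet(
            [Pathway((0, 2, 6, 4, 5, 7, 3, 1)), Pathway((1, 0, 4, 6))],
            n_residues=8,
        )
        vol = pathway_hull_volume(ps, corners)
        assert vol == pytest.approx(1.0)

    def test_chain_graph_prunes_to_nothing(self):
        ps = PathwaySet([Pathway((0, 2, 4, 6))], n_residues=8)
        coords = np.random.default_rng(0).normal(size=(8, 3))
        with pytest.raises(ValueError):
            pathway_hull_volume(ps, coords)

    def test_cycle_graph_keeps_all_edges(self):
        # pathway whose pair graph is a cycle: nothing pruned
        ps = PathwaySet(
            [Pathway((0, 2, 4, 6)), Pathway((4, 6, 0, 2))], n_residues=8
        )
        # edges: 0-2,2-4,4-6 and 4-6,6-0,0-2 -> cycle 0-2-4-6-0
        coords = np.array(
            [[0.0, 0, 0], [9, 9, 9], [4, 0, 0], [9, 9, 9],
             [4, 4, 0], [9, 9, 9], [0, 4, 4], [9, 9, 9]]
        )
        vol = pathway_hull_volume(ps, coords)
        assert vol > 0

    def test_short_pathways_ignored(self):
        ps = PathwaySet([Pathway((0, 2, 4))], n_residues=8)
        with pytest.raises(ValueError):
            pathway_hull_volume(ps, np.zeros((8, 3)))
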