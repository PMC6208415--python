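"""Fluctuation correlations, independent cliques and dynamical units."""

import numpy as np
import pytest

from infostery.cliques import (
    dynamical_units,
    fluctuation_correlation,
    independent_cliques,
)
from infostery.pathways import Pathway, PathwaySet

from conftest import ca_ensemble


class TestCorrelation:
    def base(self, n_frames=200, n_res=6, seed=0):
        rng = np.random.default_rng(seed)
        mean = rng.normal(size=(n_res, 3)) * 20
        return mean, rng

    def test_identical_translation_gives_unit_correlation(self):
        mean, rng = self.base()
        disp = rng.normal(size=(200, 1, 3))
        coords = mean + np.repeat(disp, 6, axis=1)
        # anchor residues so the superposition fit stays near identity
        coords[:, 4:, :] = mean[4:] + 0.01 * rng.normal(size=(200, 2, 3))
        corr = fluctuation_correlation(ca_ensemble(coords), superposed=True)
        assert corr[0, 1] > 0.99

    def test_antiphase_motion_is_minus_one(self):
        mean, rng = self.base()
        amp = rng.normal(size=(200, 1, 1)) * np.array([[[1.0, 0, 0]]])
        coords = np.repeat(mean[None], 200, axis=0).astype(float)
        coords[:, 0:1, :] = mean[0] + amp
        coords[:, 1:2, :] = mean[1] - amp
        corr = fluctuation_correlation(ca_ensemble(coords), superposed=True)
        assert corr[0, 1] == pytest.approx(-1.0, abs=1e-9)

    def test_independent_noise_has_small_correlation(self):
        mean, rng = self.base(seed=42)
        coords = mean + rng.normal(size=(1000, 6, 3)) * 0.5
        corr = fluctuation_correlation(ca_ensemble(coords), superposed=True)
        off = corr[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.15

    def test_diagonal_is_one(self):
        mean, rng = self.base()
        coords = mean + rng.normal(size=(50, 6, 3))
        corr = fluctuation_correlation(ca_ensemble(coords), superposed=True)
        assert np.allclose(np.diag(corr), 1.0)

    def test_too_few_frames_rejected(self):
        mean, rng = self.base()
        with pytest.raises(ValueError):
            fluctuation_correlation(
                ca_ensemble(mean + rng.normal(size=(5, 6, 3)))
            )


class TestIndependentCliques:
    def test_planted_flexible_loop_found_as_clique(self, helix_ensemble):
        from infostery.pipeline import EnsembleAnalysis

        ens, truth = helix_ensemble
        a = EnsembleAnalysis(ens)
        cliques = a.cliques_at()
        loop = truth.loop_residues()[0]
        assert any(c == frozenset(loop) for c in cliques)

    def test_rigid_ensemble_has_no_cliques(self):
        from dataclasses import replace

        from infostery.pipeline import EnsembleAnalysis
        from infostery.synthetic import generate_ensemble, unit_recovery_spec

        spec = unit_recovery_spec(n_frames=200)
        blocks = (spec.blocks[0],)  # helix only, no loop
        ens, _ = generate_ensemble(replace(spec, blocks=blocks), seed=1)
        a = EnsembleAnalysis(ens)
        assert a.cliques_at() == []

    def test_two_independent_loops_give_two_cliques(self):
        from dataclasses import replace

        from infostery.pipeline import EnsembleAnalysis
        from infostery.synthetic import LoopBlock, generate_ensemble, unit_recovery_spec

        spec = unit_recovery_spec(n_frames=400)
        blocks = spec.blocks + (LoopBlock(4, center=(-8.0, 0.0, -6.0)),)
        ens, truth = generate_ensemble(replace(spec, blocks=blocks), seed=3)
        cliques = EnsembleAnalysis(ens).cliques_at()
        loops = truth.loop_residues()
        assert frozenset(loops[0]) in cliques
        assert frozenset(loops[1]) in cliques
        assert not any(set(loops[0]) & c and set(loops[1]) & c for c in cliques
                       if c not in (frozenset(loops[0]), frozenset(loops[1])))

    def test_relabeling_invariance(self):
        # clique membership depends on geometry/correlation, not labels:
        # shuffle residue order and compare
        rng = np.random.default_rng(8)
        mean = rng.normal(size=(9, 3)) * 15
        mean[:3] = [[0, 0, 0], [3.4, 0, 0], [1.7, 2.9, 0]]
        shared = rng.normal(size=(400, 1, 3)) * 1.5
        coords = np.repeat(mean[None], 400, axis=0)
        coords = coords + rng.normal(size=(400, 9, 3)) * 0.05
        coords[:, :3, :] += shared
        e = ca_ensemble(coords)
        corr = fluctuation_correlation(e, superposed=True)
        rmsf = np.sqrt(((coords - coords.mean(0)) ** 2).sum(2).mean(0))
        cl = independent_cliques(e, corr, rmsf, corr_cut=0.5)
        assert cl == [frozenset({0, 1, 2})]


class TestDynamicalUnits:
    def ps(self, paths, n=12):
        return PathwaySet([Pathway(tuple(p)) for p in paths], n_residues=n)

    def test_pathway_components(self):
        units = dynamical_units(self.ps([(1, 3, 5), (2, 6)]), [])
        assert [sorted(u.members) for u in units.pathway_units] == [
            [1, 3, 5], [2, 6],
        ]
        assert units.clique_units == []

    def test_cliques_sharing_members_merge(self):
        units = dynamical_units(
            self.ps([]), [frozenset({4, 7, 9}), frozenset({9, 11, 12})]
        )
        assert [sorted(u.members) for u in units.clique_units] == [
            [4, 7, 9, 11, 12]
        ]

    def test_empty_inputs_empty_decomposition(self):
        units = dynamical_units(self.ps([]), [])
        assert units.pathway_units == [] and units.clique_units == []

    def test_unit_ids_ordered_by_smallest_member(self):
        units = dynamical_units(self.ps([(8, 10), (1, 3)]), [])
        assert [min(u.members) for u in units.pathway_units] == [1, 8]
        assert [u.id for u in units.pathway_units] == [0, 1]


class TestPersistency:
    def test_always_in_unit_scores_one(self, helix_ensemble):
        from infostery.pipeline import EnsembleAnalysis

        ens, truth = helix_ensemble
        pt = EnsembleAnalysis(ens).persistency()
        helix = sorted(truth.helix_residues()[0])
        loop = sorted(truth.loop_residues()[0])
        assert (pt.pathway_score[helix] == 1.0).all()
        assert (pt.clique_score[loop] == 1.0).all()

    def test_never_in_unit_scores_zero(self):
        # a lone rigid helix has no flexible residues: clique scores vanish
        from dataclasses import replace

        from infostery.pipeline import EnsembleAnalysis
        from infostery.synthetic import generate_ensemble, unit_recovery_spec

        spec = unit_recovery_spec(n_frames=200)
        ens, _ = generate_ensemble(
            replace(spec, blocks=(spec.blocks[0],)), seed=6
        )
        pt = EnsembleAnalysis(ens).persistency()
        assert (pt.clique_score == 0.0).all()

    def test_loop_never_joins_the_helix_unit(self, helix_ensemble):
        # correlated loop residues may form pathways among themselves, but
        # their communication with the rigid helix stays inefficient
        from infostery.pipeline import EnsembleAnalysis

        ens, truth = helix_ensemble
        a = EnsembleAnalysis(ens)
        helix = truth.helix_residues()[0]
        loop = truth.loop_residues()[0]
        for q in a.cp_sweep_grid():
            unit = a.pathways_at(q).unit_of()
            helix_units = {unit[r] for r in helix if unit[r] >= 0}
            loop_units = {unit[r] for r in loop if unit[r] >= 0}
            assert not helix_units & loop_units

    def test_scores_within_unit_interval(self, bridge_analysis):
        a, _ = bridge_analysis
        pt = a.persistency()
        assert ((0 <= pt.pathway_score) & (pt.pathway_score <= 1)).all()
        assert ((0 <= pt.clique_score) & (pt.clique_score <= 1)).all()
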