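"""End-to-end orchestration of the communication analysis of one ensemble.

:class:`EnsembleAnalysis` caches every ensemble-derived quantity (secondary
structure, CP matrix, stable interactions, displacement correlations, RMSF,
burial) and exposes the composite computations: pathways and dot plots at
any CP_cut quantile, dynamical units, persistency scores over threshold
sweeps, the three bridge strategies, and the pathway-concentration
statistics used for mutant classification.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from . import burial as burial_mod
from . import cliques as cliques_mod
from . import communication as comm
from . import interactions as inter_mod
from . import pathways as path_mod
from . import sensitive as sens_mod
from .cliques import PersistencyTable, UnitDecomposition
from .ensemble import (
    Ensemble,
    SSMatrix,
    assign_secondary_structure,
    mean_structure,
    rmsd_rmsf,
    select_analysis_window,
    superpose,
)
from .mutscan import MutantStats
from .pathways import DotPlot, PathwaySet
from .sensitive import BridgePrediction

__all__ = ["AnalysisConfig", "EnsembleAnalysis"]


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable thresholds of the pipeline in one document."""

    discard_leading: float = 0.0  # fraction of each replicate dropped
    # interactions
    hbond_dist_A: float = 3.5
    hbond_angle_deg: float = 120.0
    hydrophobic_dist_A: float = 4.5
    s_min: float = 0.5
    # communication
    cp_quantile: float | None = None  # None -> measured p_ss
    cp_quantile_max: float = 0.80
    sweep_step: float = 0.05
    fallback_q: float = 0.5
    min_ligand_chain: int = 9
    # cliques
    corr_cut: float = 0.5
    corr_sweep_step: float = 0.05
    corr_sweep_settings: int = 6  # floor 0.25: above the corr noise floor
    clique_dist_A: float = 3.7
    flex_percentile: float = 70.0
    independence_bound: float = 0.3
    min_clique_size: int = 3
    # burial
    r_c: float = 20.0
    cv_cut: float = 0.6
    # dot plot / motifs
    far_sep: int = 4
    motif_max_black: int = 5
    motif_max_colored: int = 4
    motif_neighbourhood: int = 8
    # bridges & mutants
    persistency_min: float = 0.8
    k_connected: int = 70
    x_coefficient: float = 1.2
    max_pathways: int = 500_000


class EnsembleAnalysis:
    """Lazy, cached communication analysis of a single ensemble."""

    def __init__(self, ensemble: Ensemble, config: AnalysisConfig | None = None):
        self.config = config or AnalysisConfig()
        if self.config.discard_leading > 0:
            ensemble = select_analysis_window(
                ensemble, self.config.discard_leading
            )
        self.ensemble = ensemble
        self._cache: dict = {}

    def _get(self, key, fn):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    # -- ensemble-level descriptors ------------------------------------

    @property
    def superposed(self) -> Ensemble:
        return self._get("superposed", lambda: superpose(self.ensemble))

    @property
    def mean_coords(self) -> np.ndarray:
        return self._get(
            "mean", lambda: mean_structure(self.superposed, superposed=True)
        )

    def mean_ca_coords(self) -> np.ndarray:
        ca = self.ensemble.topology.ca_indices()
        return self.mean_coords[ca]

    @property
    def ss(self) -> SSMatrix:
        return self._get("ss", lambda: assign_secondary_structure(self.ensemble))

    @property
    def rmsd(self) -> np.ndarray:
        return self._rmsd_rmsf()[0]

    @property
    def rmsf(self) -> np.ndarray:
        return self._rmsd_rmsf()[1]

    def _rmsd_rmsf(self):
        return self._get("rmsd_rmsf", lambda: rmsd_rmsf(self.ensemble))

    @property
    def cp(self) -> comm.CPMatrix:
        cfg = self.config
        return self._get(
            "cp",
            lambda: comm.compute_cp(
                self.ensemble,
                ss=self.ss,
                q=cfg.cp_quantile,
                min_ligand_chain=cfg.min_ligand_chain,
                fallback_q=cfg.fallback_q,
            ),
        )

    @property
    def interactions(self) -> inter_mod.InteractionSet:
        cfg = self.config
        return self._get(
            "interactions",
            lambda: inter_mod.stable_interactions(
                self.ensemble,
                s_min=cfg.s_min,
                hbond_dist=cfg.hbond_dist_A,
                hbond_angle_deg=cfg.hbond_angle_deg,
                hydrophobic_dist=cfg.hydrophobic_dist_A,
            ),
        )

    @property
    def correlation(self) -> np.ndarray:
        return self._get(
            "corr",
            lambda: cliques_mod.fluctuation_correlation(
                self.superposed, superposed=True
            ),
        )

    @property
    def cv_profile(self) -> burial_mod.CVProfile:
        cfg = self.config
        return self._get(
            "cv",
            lambda: burial_mod.residue_cv(
                self.mean_coords,
                self.ensemble.topology,
                r_c=cfg.r_c,
                cv_cut=cfg.cv_cut,
            ),
        )

    @property
    def buried(self) -> set[int]:
        return self._get(
            "buried", lambda: burial_mod.buried_residues(self.cv_profile)
        )

    # -- threshold machinery -------------------------------------------

    def _mcp_include(self) -> np.ndarray:
        return comm._mcp_include_mask(
            self.ensemble, self.config.min_ligand_chain
        )

    def cp_cut_at(self, q: float | None = None) -> float:
        """CP_cut at quantile q of the MCP distribution (default: p_ss)."""
        if q is None:
            return self.cp.cp_cut
        return comm.cp_threshold(self.cp.mcp[self._mcp_include()], q)

    def cp_sweep_grid(self) -> list[float]:
        """CP_cut quantile levels: default up to the cap in 5%-point steps.

        The sweep stops early (inclusively) at the first setting where a
        single pathway-based unit spans every protein residue.
        """
        cfg = self.config
        q0 = self.cp.quantile_q
        grid = []
        q = q0
        while q < cfg.cp_quantile_max - 1e-9:
            grid.append(round(q, 10))
            q += cfg.sweep_step
        grid.append(cfg.cp_quantile_max)
        is_lig = self.ensemble.topology.is_ligand_residue()
        n_protein = int((~is_lig).sum())
        out = []
        for q in grid:
            out.append(q)
            ps = self.pathways_at(q)
            units = [c for c in _components(ps) if len(c) > 1]
            if units and max(len(u & set(np.nonzero(~is_lig)[0])) for u in units) == n_protein:
                break
        return out

    def corr_sweep_grid(self) -> list[float]:
        """Correlation thresholds stepping down from the default."""
        cfg = self.config
        return [
            round(cfg.corr_cut - k * cfg.corr_sweep_step, 10)
            for k in range(cfg.corr_sweep_settings)
            if cfg.corr_cut - k * cfg.corr_sweep_step > 0
        ]

    # -- composite computations ----------------------------------------

    def pathways_at(self, q: float | None = None) -> PathwaySet:
        key = ("pathways", q)
        cut = self.cp_cut_at(q)

        def build():
            eff = comm.efficient_pairs(self.cp.cp, cut)
            return path_mod.enumerate_pathways(
                self.interactions,
                eff,
                self.ensemble.topology,
                max_pathways=self.config.max_pathways,
            )

        return self._get(key, build)

    def cliques_at(self, corr_cut: float | None = None):
        cfg = self.config
        cut = cfg.corr_cut if corr_cut is None else corr_cut
        key = ("cliques", cut)
        return self._get(
            key,
            lambda: cliques_mod.independent_cliques(
                self.ensemble,
                self.correlation,
                self.rmsf,
                corr_cut=cut,
                dist_cut=cfg.clique_dist_A,
                flex_percentile=cfg.flex_percentile,
                independence_bound=cfg.independence_bound,
                min_size=cfg.min_clique_size,
            ),
        )

    def units_at(
        self, q: float | None = None, corr_cut: float | None = None
    ) -> UnitDecomposition:
        return cliques_mod.dynamical_units(
            self.pathways_at(q), self.cliques_at(corr_cut)
        )

    def dotplot_at(self, q: float | None = None) -> DotPlot:
        ps = self.pathways_at(q)
        return path_mod.dotplot(
            ps,
            self.ensemble.topology,
            far_sep=self.config.far_sep,
            cp_quantile=q if q is not None else self.cp.quantile_q,
        )

    def persistency(self) -> PersistencyTable:
        """Unit-membership fraction per residue over the threshold sweeps.

        Pathway-based units depend only on CP_cut and clique-based units
        only on the correlation threshold, so each kind is scored on its
        own one-dimensional grid.
        """
        n = self.ensemble.n_residues
        cp_grid = self.cp_sweep_grid()
        p_score = np.zeros(n)
        for q in cp_grid:
            member = self.pathways_at(q).unit_of() >= 0
            p_score += member
        p_score /= len(cp_grid)

        corr_grid = self.corr_sweep_grid()
        c_score = np.zeros(n)
        for cut in corr_grid:
            in_clique = np.zeros(n, dtype=bool)
            for cl in self.cliques_at(cut):
                for r in cl:
                    in_clique[r] = True
            c_score += in_clique
        c_score /= max(len(corr_grid), 1)
        return PersistencyTable(pathway_score=p_score, clique_score=c_score)

    # -- bridge strategies ---------------------------------------------

    def bridge_unit_overlap(self) -> set[int]:
        pt = self.persistency()
        out = sens_mod.bridge_unit_overlap(pt, self.config.persistency_min)
        return out & self.buried

    def ligand_direct(self) -> set[int]:
        return sens_mod.ligand_direct(
            self.pathways_at(), self.ensemble.topology
        )

    def isolated_direct_communications(self) -> set[tuple[int, int]]:
        """Union over the CP_cut sweep of isolated direct communications.

        At every sweep setting the dot plot is rebuilt and its isolated
        black dots collected; black dots are by construction far in
        sequence and direct, and direct partners always share a
        pathway-based unit at the producing setting.  Pairs with any
        non-buried residue are dropped.
        """
        cfg = self.config
        found: set[tuple[int, int]] = set()
        for q in self.cp_sweep_grid():
            dp = self.dotplot_at(q)
            ps = self.pathways_at(q)
            unit = ps.unit_of()
            for i, j in sens_mod.isolated_black_dots(
                dp,
                max_black=cfg.motif_max_black,
                max_colored=cfg.motif_max_colored,
                neighbourhood=cfg.motif_neighbourhood,
            ):
                assert (i, j) in ps.direct and unit[i] == unit[j] >= 0
                found.add((i, j))
        buried = self.buried
        return {
            (i, j) for i, j in found if i in buried and j in buried
        }

    def predict_sensitive(self) -> BridgePrediction:
        """Union of the three bridge strategies with per-residue labels."""
        labels: dict[int, set[str]] = {}

        def add(residues, tag):
            for r in residues:
                labels.setdefault(int(r), set()).add(tag)

        add(self.bridge_unit_overlap(), "unit_overlap")
        add(self.ligand_direct(), "ligand_direct")
        pairs = self.isolated_direct_communications()
        add({r for p in pairs for r in p}, "isolated_direct")
        return BridgePrediction(
            strategies=labels,
            isolated_pairs=pairs,
            parameters=asdict(self.config),
        )

    # -- mutant statistics ---------------------------------------------

    def mutant_stats(
        self,
        mutation_id: str,
        k: int | None = None,
        delta_e: float | None = None,
        label: str | None = None,
    ) -> MutantStats:
        ps = self.pathways_at()
        counts = path_mod.pathway_counts(ps, (3, 4, 5, 6))
        k = self.config.k_connected if k is None else k
        n_hc = len(path_mod.highly_connected_residues(ps, k))
        return MutantStats(
            mutation_id=mutation_id,
            n_pathways_gt=counts,
            n_highly_connected=n_hc,
            delta_e=delta_e,
            label=label,
        )


def _components(ps: PathwaySet) -> list[set[int]]:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(ps.n_residues))
    g.add_edges_from(ps.direct)
    return [set(c) for c in nx.connected_components(g)]
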