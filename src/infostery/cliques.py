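"""Clique-based dynamical units from concerted high fluctuations, the
pathway/clique unit decomposition, and persistency scores over threshold
sweeps.

A clique groups residues that are (i) proximal in 3D (time-averaged minimum
heavy-atom distance below 3.7 A), (ii) highly flexible relative to the rest
of the protein, (iii) fluctuate in a concerted way between themselves, and
(iv) independently from everything else.  Dynamical units of each kind are
the connected components of the corresponding membership graph; the
persistency score of a residue is the fraction of threshold settings in a
sweep at which it belongs to a unit of that kind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import Ensemble, superpose

__all__ = [
    "DynamicalUnit",
    "UnitDecomposition",
    "PersistencyTable",
    "fluctuation_correlation",
    "independent_cliques",
    "dynamical_units",
]


@dataclass(frozen=True)
class DynamicalUnit:
    members: frozenset[int]
    kind: str  # "pathway_based" | "clique_based"
    id: int


@dataclass
class UnitDecomposition:
    pathway_units: list[DynamicalUnit]
    clique_units: list[DynamicalUnit]
    n_residues: int

    def __post_init__(self) -> None:
        for units in (self.pathway_units, self.clique_units):
            seen: set[int] = set()
            for u in units:
                if seen & u.members:
                    raise AssertionError("units of one kind must be disjoint")
                seen |= u.members

    def membership(self, kind: str) -> np.ndarray:
        units = self.pathway_units if kind == "pathway_based" else self.clique_units
        out = np.full(self.n_residues, -1, dtype=int)
        for u in units:
            for r in u.members:
                out[r] = u.id
        return out


@dataclass
class PersistencyTable:
    pathway_score: np.ndarray  # per residue in [0, 1]
    clique_score: np.ndarray

    def __post_init__(self) -> None:
        for s in (self.pathway_score, self.clique_score):
            if np.any(s < 0) or np.any(s > 1):
                raise ValueError("persistency scores lie in [0, 1]")


def fluctuation_correlation(e: Ensemble, superposed: bool = False) -> np.ndarray:
    """Pearson correlation of per-frame CA displacement vectors.

    Displacements are taken from the ensemble-mean structure after
    superposition; the correlation of residues i and j is the normalised
    cross-correlation <di . dj> / sqrt(<|di|^2><|dj|^2>).  A residue with
    zero displacement variance gets correlation 0 with everything.
    """
    if e.n_frames < 10:
        raise ValueError("correlation needs at least 10 frames")
    es = e if superposed else superpose(e)
    ca = es.ca_coords()
    d = ca - ca.mean(axis=0)  # (F, N, 3)
    inner = np.einsum("fix,fjx->ij", d, d) / d.shape[0]
    var = np.diag(inner).copy()
    zero = var <= 1e-12
    if zero.any():
        import warnings

        warnings.warn(
            f"{int(zero.sum())} residue(s) have zero displacement variance",
            stacklevel=2,
        )
        var[zero] = 1.0
    corr = inner / np.sqrt(np.outer(var, var))
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def mean_min_heavy_distance(
    e: Ensemble, candidates: np.ndarray
) -> np.ndarray:
    """Time-averaged minimum heavy-atom distance between candidate residues.

    Returns a (n_cand, n_cand) matrix over ``candidates`` (residue indices).
    """
    heavy = [
        [i for i in g if e.topology.atoms[i].element.upper() != "H"]
        for g in e.topology.residue_atom_indices()
    ]
    k = len(candidates)
    out = np.zeros((k, k))
    for a in range(k):
        ia = heavy[candidates[a]]
        ca_ = e.coords[:, ia, :]  # (F, na, 3)
        for b in range(a + 1, k):
            ib = heavy[candidates[b]]
            cb = e.coords[:, ib, :]
            diff = ca_[:, :, None, :] - cb[:, None, :, :]
            dmin = np.sqrt((diff ** 2).sum(axis=-1)).min(axis=(1, 2))
            out[a, b] = out[b, a] = dmin.mean()
    return out


def independent_cliques(
    e: Ensemble,
    corr: np.ndarray,
    rmsf: np.ndarray,
    corr_cut: float = 0.5,
    dist_cut: float = 3.7,
    flex_percentile: float = 70.0,
    independence_bound: float = 0.3,
    min_size: int = 3,
) -> list[frozenset[int]]:
    """Maximal cliques of proximal, concertedly fluctuating residues.

    Candidate residues are the flexible ones (RMSF above the
    ``flex_percentile`` percentile of the per-residue RMSF distribution).
    Edges require mean minimum heavy-atom distance < ``dist_cut`` and
    displacement correlation > ``corr_cut``.  Cliques smaller than
    ``min_size`` are ignored, and a clique whose mean |correlation| to
    non-clique residues exceeds ``independence_bound`` is discarded as not
    independent.  An empty list is a valid outcome (rigid systems).
    """
    import networkx as nx

    rmsf = np.asarray(rmsf, dtype=float)
    cut = np.percentile(rmsf[np.isfinite(rmsf)], flex_percentile)
    cand = np.nonzero(rmsf > cut)[0]
    if cand.size < min_size:
        return []
    dmat = mean_min_heavy_distance(e, cand)
    g = nx.Graph()
    g.add_nodes_from(cand.tolist())
    for a in range(cand.size):
        for b in range(a + 1, cand.size):
            i, j = int(cand[a]), int(cand[b])
            if dmat[a, b] < dist_cut and corr[i, j] > corr_cut:
                g.add_edge(i, j)
    n = e.n_residues
    out = []
    for clique in nx.find_cliques(g):
        if len(clique) < min_size:
            continue
        members = frozenset(int(c) for c in clique)
        outside = np.array(sorted(set(range(n)) - members), dtype=int)
        inside = np.array(sorted(members), dtype=int)
        mean_out = float(np.abs(corr[np.ix_(inside, outside)]).mean())
        if mean_out < independence_bound:
            out.append(members)
    out.sort(key=lambda c: (min(c), sorted(c)))
    return out


def dynamical_units(ps, cliques: list[frozenset[int]]) -> UnitDecomposition:
    """Connected components of the pathway/clique membership graphs.

    Pathway-based units connect residues adjacent in a pathway; clique-based
    units connect residues sharing a clique.  Unit ids are ordered by
    smallest member within each kind.
    """
    import networkx as nx

    n = ps.n_residues
    gp = nx.Graph()
    gp.add_edges_from(ps.direct)
    pu = [c for c in nx.connected_components(gp) if len(c) > 1]
    pu.sort(key=min)
    pathway_units = [
        DynamicalUnit(frozenset(c), "pathway_based", i) for i, c in enumerate(pu)
    ]

    gc = nx.Graph()
    for cl in cliques:
        members = sorted(cl)
        gc.add_nodes_from(members)
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                gc.add_edge(members[a], members[b])
    cu = sorted(nx.connected_components(gc), key=min)
    clique_units = [
        DynamicalUnit(frozenset(c), "clique_based", i) for i, c in enumerate(cu)
    ]
    return UnitDecomposition(pathway_units, clique_units, n_residues=n)
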