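"""Mutant-ensemble comparison against the wild type.

Each mutant ensemble is reduced to pathway-concentration statistics (number
of pathways longer than L residues; number of highly connected residues,
i.e. residues crossed by more than k pathways).  A mutant is called highly
deleterious when its highly-connected-residue count exceeds x times the
wild-type count (strict inequality; recommended x = 1.2).  Group-level
differences are assessed with inverse-CDF curves per experimental class and
a label-permutation test on the maximal vertical curve difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import Confusion, confusion, metrics_from_confusion

__all__ = [
    "MutantStats",
    "ClassificationResult",
    "label_from_deltaE",
    "classify_mutants",
    "icdf_curves",
    "permutation_curve_test",
    "pathway_hull_volume",
]

NEUTRAL, DELETERIOUS, HIGHLY_DELETERIOUS = (
    "neutral",
    "deleterious",
    "highly_deleterious",
)


@dataclass
class MutantStats:
    mutation_id: str
    n_pathways_gt: dict[int, int]
    n_highly_connected: int
    delta_e: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        counts = [self.n_pathways_gt[k] for k in sorted(self.n_pathways_gt)]
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError("pathway counts must be non-increasing in L")
        if self.label is None and self.delta_e is not None:
            self.label = label_from_deltaE(self.delta_e)


def label_from_deltaE(delta_e: float) -> str:
    """Experimental class from a binding-affinity change in kcal/mol.

    Highly deleterious below -1.0, deleterious below -0.2, neutral at or
    above -0.2 (beneficial mutations fold into the neutral class).
    """
    if not np.isfinite(delta_e):
        raise ValueError("deltaE must be finite")
    if delta_e < -1.0:
        return HIGHLY_DELETERIOUS
    if delta_e < -0.2:
        return DELETERIOUS
    return NEUTRAL


@dataclass
class ClassificationResult:
    n_res_wt: int
    x: float
    calls: dict[str, str]  # mutation id -> predicted class
    confusion: Confusion | None = None
    metrics: dict | None = None


def classify_mutants(
    stats: list[MutantStats],
    wt: MutantStats,
    x: float = 1.2,
) -> ClassificationResult:
    """Call mutants highly deleterious when n_res > x * n_res_wt (strict).

    When experimental labels are present, deleterious-but-not-highly mutants
    are left out of the confusion (two-class setup: highly deleterious vs
    neutral), matching the way such classifiers are benchmarked.
    """
    if x <= 0:
        raise ValueError("x must be positive")
    thr = x * wt.n_highly_connected
    calls = {
        s.mutation_id: (
            HIGHLY_DELETERIOUS if s.n_highly_connected > thr else NEUTRAL
        )
        for s in stats
    }
    res = ClassificationResult(wt.n_highly_connected, x, calls)
    labelled = [s for s in stats if s.label in (NEUTRAL, HIGHLY_DELETERIOUS)]
    if labelled:
        tp = sum(
            1
            for s in labelled
            if s.label == HIGHLY_DELETERIOUS
            and calls[s.mutation_id] == HIGHLY_DELETERIOUS
        )
        fp = sum(
            1
            for s in labelled
            if s.label == NEUTRAL and calls[s.mutation_id] == HIGHLY_DELETERIOUS
        )
        fn = sum(1 for s in labelled if s.label == HIGHLY_DELETERIOUS) - tp
        tn = sum(1 for s in labelled if s.label == NEUTRAL) - fp
        res.confusion = Confusion(tp=tp, fp=fp, tn=tn, fn=fn)
        res.metrics = metrics_from_confusion(res.confusion)
    return res


def icdf_curves(
    values: np.ndarray, labels: list[str]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-class inverse cumulative curves on the pooled value support.

    For each class, y(x) is the percentage of class members with value
    strictly greater than x, evaluated at every distinct pooled value.
    """
    values = np.asarray(values, dtype=float)
    support = np.unique(values)
    out = {}
    for cls in dict.fromkeys(labels):  # preserve first-seen order
        vals = values[np.array([l == cls for l in labels], dtype=bool)]
        if vals.size == 0:
            import warnings

            warnings.warn(f"class {cls!r} is empty; omitted", stacklevel=2)
            continue
        y = np.array([100.0 * (vals > x).mean() for x in support])
        out[cls] = (support, y)
    return out


def _max_curve_gap(values: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray,
                   support: np.ndarray) -> float:
    ya = (values[mask_a][:, None] > support[None, :]).mean(axis=0)
    yb = (values[mask_b][:, None] > support[None, :]).mean(axis=0)
    return float(np.abs(ya - yb).max()) * 100.0


def permutation_curve_test(
    values: np.ndarray,
    labels: list[str],
    class_a: str,
    class_b: str,
    n_permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Label-permutation test on the maximal inverse-CDF curve difference.

    The statistic is the largest vertical difference (percentage points)
    between the two class curves over the pooled support.  Labels of the
    two classes are permuted ``n_permutations`` times; the p-value is
    (#{permuted >= observed} + 1) / (n_permutations + 1).

    Returns (observed statistic, p-value).
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    values = np.asarray(values, dtype=float)
    sel = np.array([l in (class_a, class_b) for l in labels], dtype=bool)
    vals = values[sel]
    labs = [l for l in labels if l in (class_a, class_b)]
    n_a = sum(1 for l in labs if l == class_a)
    n_b = len(labs) - n_a
    if n_a < 2 or n_b < 2:
        raise ValueError("each class needs at least 2 members")
    support = np.unique(vals)
    mask_a = np.array([l == class_a for l in labs], dtype=bool)
    observed = _max_curve_gap(vals, mask_a, ~mask_a, support)
    rng = np.random.default_rng(seed)
    count = 0
    idx = np.arange(len(labs))
    for _ in range(n_permutations):
        rng.shuffle(idx)
        perm_a = np.zeros(len(labs), dtype=bool)
        perm_a[idx[:n_a]] = True
        stat = _max_curve_gap(vals, perm_a, ~perm_a, support)
        if stat >= observed - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return observed, float(p)


def pathway_hull_volume(ps, mean_ca_coords: np.ndarray) -> float:
    """Convex-hull volume (A^3) of the pruned pathway network.

    Pathways with more than 3 residues define a pair graph; edges with an
    endpoint of degree 1 are deleted iteratively until a fixpoint, and the
    hull is taken over the CA coordinates of the remaining vertices.
    """
    import networkx as nx
    from scipy.spatial import ConvexHull, QhullError

    g = nx.Graph()
    for p in ps.pathways:
        if len(p) > 3:
            r = p.residues
            g.add_edges_from(zip(r, r[1:]))
    changed = True
    while changed:
        changed = False
        for u, v in list(g.edges):
            if g.degree(u) == 1 or g.degree(v) == 1:
                g.remove_edge(u, v)
                changed = True
        g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    verts = sorted(g.nodes)
    if len(verts) < 4:
        raise ValueError("fewer than 4 vertices remain; hull volume undefined")
    pts = np.asarray(mean_ca_coords, dtype=float)[verts]
    try:
        return float(ConvexHull(pts).volume)
    except QhullError as err:
        raise ValueError("remaining vertices are degenerate (coplanar)") from err
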