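"""Communication propensity (CP), local backbone propensity (MCP) and the
data-driven efficiency threshold CP_cut.

CP(i, j) is the population variance over frames of the CA-CA distance of a
residue pair; residues that move together have low CP and are said to
communicate efficiently.  MCP(i) averages CP(i, j) over sequence neighbours
within +/-4 of i on the same chain (divided by a literal 8 even at chain
termini).  CP_cut is the p_ss-quantile of the MCP distribution, where p_ss
is the fraction of residues holding stable secondary structure: backbone
stretches in well-formed secondary structure are expected to communicate
efficiently, so their local propensities calibrate the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import Ensemble, SSMatrix

__all__ = [
    "CPMatrix",
    "cp_matrix",
    "mcp",
    "ss_fraction",
    "cp_threshold",
    "efficient_pairs",
    "compute_cp",
]


@dataclass
class CPMatrix:
    """CP matrix with its derived MCP vector and threshold."""

    cp: np.ndarray  # (N, N) symmetric, A^2
    mcp: np.ndarray  # (N,), A^2
    p_ss: float
    cp_cut: float
    quantile_q: float

    def efficient(self, cut: float | None = None) -> np.ndarray:
        return efficient_pairs(self.cp, self.cp_cut if cut is None else cut)


def cp_matrix(e: Ensemble) -> np.ndarray:
    """Pairwise CA-CA distance variance over frames (population variance)."""
    ca = e.ca_coords()  # (F, N, 3); raises if a residue lacks CA
    diff = ca[:, :, None, :] - ca[:, None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))  # (F, N, N)
    cp = d.var(axis=0)
    np.fill_diagonal(cp, 0.0)
    return cp


def mcp(
    cp: np.ndarray,
    chain_codes: np.ndarray,
    resids: np.ndarray | None = None,
    window: int = 4,
    divisor: float | None = 8.0,
) -> np.ndarray:
    """Local backbone communication propensity.

    Sums CP(i, j) over sequence neighbours j within ``window`` residues of i
    (by author residue number), j != i, restricted to the same chain, and
    divides by a literal ``divisor`` (default 8) regardless of how many
    terms exist at chain termini.  Pass ``divisor=None`` to normalise by the
    actual neighbour count instead.
    """
    n = cp.shape[0]
    if resids is None:
        resids = np.arange(n)
    out = np.zeros(n)
    for i in range(n):
        js = [
            j
            for j in range(max(0, i - window), min(n, i + window + 1))
            if j != i
            and chain_codes[j] == chain_codes[i]
            and abs(int(resids[j]) - int(resids[i])) <= window
        ]
        total = float(cp[i, js].sum()) if js else 0.0
        if divisor is None:
            out[i] = total / len(js) if js else 0.0
        else:
            out[i] = total / divisor
    return out


def ss_fraction(ss: SSMatrix, include: np.ndarray | None = None) -> float:
    """Fraction of residues with stable secondary structure.

    A residue counts when it carries an H/E/T label in strictly more than
    half of the frames.  ``include`` restricts the residue set (used to
    leave short ligand chains out of the calibration).
    """
    pers = ss.persistence
    if include is not None:
        pers = pers[include]
    if pers.size == 0:
        return 0.0
    return float((pers > 0.5).mean())


def cp_threshold(mcp_values: np.ndarray, q: float) -> float:
    """Empirical q-quantile of the MCP distribution (linear interpolation)."""
    if not 0 < q < 1:
        raise ValueError("quantile level q must lie in (0, 1)")
    return float(np.quantile(np.asarray(mcp_values, dtype=float), q))


def efficient_pairs(
    cp: np.ndarray, cp_cut: float, strict: bool = False
) -> np.ndarray:
    """Boolean matrix of efficiently communicating pairs (CP <= CP_cut).

    The tie rule is inclusive by default for robustness to floating-point
    equality; ``strict=True`` switches to CP < CP_cut.
    """
    eff = cp < cp_cut if strict else cp <= cp_cut
    eff = np.array(eff, dtype=bool)
    np.fill_diagonal(eff, False)
    return eff


def _mcp_include_mask(e: Ensemble, min_ligand_chain: int = 9) -> np.ndarray:
    """Residues entering the MCP distribution and p_ss.

    Protein residues always; ligand residues only when their chain holds at
    least ``min_ligand_chain`` residues (peptide ligands count as chains).
    """
    topo = e.topology
    is_lig = topo.is_ligand_residue()
    include = ~is_lig
    if is_lig.any():
        from collections import Counter

        sizes = Counter(r.chain_id for r in topo.residues)
        for i, r in enumerate(topo.residues):
            if is_lig[i] and sizes[r.chain_id] >= min_ligand_chain:
                include[i] = True
    return include


def compute_cp(
    e: Ensemble,
    ss: SSMatrix | None = None,
    q: float | None = None,
    min_ligand_chain: int = 9,
    fallback_q: float = 0.5,
) -> CPMatrix:
    """Full CP computation: matrix, MCP, p_ss and CP_cut in one object.

    ``q`` overrides the quantile level (default: the measured p_ss).  When
    the ensemble holds no stable secondary structure at all (p_ss = 0, which
    would make the quantile undefined), ``fallback_q`` is used instead.
    """
    from .ensemble import assign_secondary_structure

    cp = cp_matrix(e)
    codes = e.topology.chain_codes()
    mcp_v = mcp(cp, codes, e.topology.resids())
    if ss is None:
        ss = assign_secondary_structure(e)
    include = _mcp_include_mask(e, min_ligand_chain)
    p_ss = ss_fraction(ss, include)
    level = q if q is not None else (p_ss if 0 < p_ss < 1 else fallback_q)
    cut = cp_threshold(mcp_v[include], level)
    return CPMatrix(cp=cp, mcp=mcp_v, p_ss=p_ss, cp_cut=cut, quantile_q=level)
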