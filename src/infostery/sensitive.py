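"""Prediction of mutation-sensitive positions from a wild-type ensemble.

Three complementary strategies identify residues acting as communication
bridges:

1. *unit overlap* - residues persistently detected in both a pathway-based
   and a clique-based dynamical unit (persistency scores above 0.8);
2. *ligand direct* - protein residues in direct communication (adjacent in
   a pathway) with a ligand residue;
3. *isolated direct communication* - sequence-distant residue pairs whose
   direct communication appears as an isolated black dot on the
   communication dot plot at some threshold of a CP_cut sweep: a strong
   pairwise signal against a quiet local background.

Strategies 1 and 3 keep only buried residues; ligand-facing residues are
exempt from the burial filter because interface residues are partially
exposed by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .pathways import BLACK, GREY, DotPlot, PathwaySet

__all__ = [
    "BridgePrediction",
    "bridge_unit_overlap",
    "ligand_direct",
    "motif_decomposition",
    "isolated_black_dots",
]


@dataclass
class BridgePrediction:
    """Predicted sensitive positions with per-residue strategy labels."""

    strategies: dict[int, set[str]]  # residue -> subset of strategy names
    isolated_pairs: set[tuple[int, int]] = field(default_factory=set)
    parameters: dict = field(default_factory=dict)

    @property
    def residues(self) -> set[int]:
        return set(self.strategies)


def bridge_unit_overlap(pt, min_score: float = 0.8) -> set[int]:
    """Residues in both unit kinds with persistency strictly above ``min_score``."""
    import numpy as np

    mask = (np.asarray(pt.pathway_score) > min_score) & (
        np.asarray(pt.clique_score) > min_score
    )
    return set(np.nonzero(mask)[0].tolist())


def ligand_direct(ps: PathwaySet, topology) -> set[int]:
    """Protein residues adjacent to a ligand residue in some pathway.

    Direct communication is stronger than physical contact: the pair must
    also communicate efficiently, which is already guaranteed for pathway
    members.
    """
    is_lig = topology.is_ligand_residue()
    if not is_lig.any():
        import warnings

        warnings.warn("no ligand chain flagged; empty result", stacklevel=2)
        return set()
    out = set()
    for i, j in ps.direct:
        if is_lig[i] != is_lig[j]:
            out.add(int(i) if not is_lig[i] else int(j))
    return out


def motif_decomposition(
    dp: DotPlot, neighbourhood: int = 8
) -> list[set[tuple[int, int]]]:
    """Connected groups of dots (all classes) in (i, j) index space.

    Adjacency is Chebyshev distance 1 (8-neighbour) by default, or
    von Neumann (4-neighbour) with ``neighbourhood=4``; computed on the
    upper triangle.  Singleton dots form their own motif.
    """
    if neighbourhood not in (4, 8):
        raise ValueError("neighbourhood must be 4 or 8")
    dots = set(dp.dots)
    if neighbourhood == 8:
        steps = [
            (di, dj)
            for di in (-1, 0, 1)
            for dj in (-1, 0, 1)
            if (di, dj) != (0, 0)
        ]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen: set[tuple[int, int]] = set()
    motifs = []
    for start in sorted(dots):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        seen.add(start)
        while stack:
            i, j = stack.pop()
            for di, dj in steps:
                nb = (i + di, j + dj)
                if nb in dots and nb not in seen:
                    seen.add(nb)
                    comp.add(nb)
                    stack.append(nb)
        motifs.append(comp)
    return motifs


def isolated_black_dots(
    dp: DotPlot,
    max_black: int = 5,
    max_colored: int = 4,
    neighbourhood: int = 8,
) -> set[tuple[int, int]]:
    """Black dots that stand out against a quiet neighbourhood.

    A black dot is isolated when it is a singleton motif, or when its motif
    contains at most ``max_black`` black dots, no grey dot, and at most
    ``max_colored`` colored dots.
    """
    out: set[tuple[int, int]] = set()
    for motif in motif_decomposition(dp, neighbourhood):
        classes = [dp.dots[p] for p in motif]
        n_black = sum(1 for c in classes if c == BLACK)
        n_grey = sum(1 for c in classes if c == GREY)
        n_colored = sum(1 for c in classes if c >= 0)
        if n_black == 0:
            continue
        if n_black <= max_black and n_grey == 0 and n_colored <= max_colored:
            out |= {p for p in motif if dp.dots[p] == BLACK}
    return out
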