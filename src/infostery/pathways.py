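"""Communication pathways: maximal chains of mutually efficient residues.

A pathway is an ordered chain of residues in which (i) consecutive members
are not sequence-adjacent (|i - j| >= 2 on one chain; inter-chain steps are
always allowed), (ii) consecutive members form a stable non-covalent
interaction, and (iii) every pair of members, adjacent or not, communicates
efficiently (CP <= CP_cut).  Only maximal chains are kept: a contiguous
sub-sequence of a retained pathway (in either orientation) is discarded.

Residues adjacent in some pathway are in *direct* communication; residues
sharing a pathway without being adjacent are in *indirect* communication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import Topology
from .interactions import InteractionSet

__all__ = [
    "Pathway",
    "PathwaySet",
    "DotPlot",
    "PathwayExplosionError",
    "enumerate_pathways",
    "pathway_counts",
    "highly_connected_residues",
    "dotplot",
]


class PathwayExplosionError(RuntimeError):
    """Raised when enumeration exceeds the configured pathway budget."""


@dataclass(frozen=True)
class Pathway:
    residues: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError("a pathway has at least 2 residues")
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("a pathway visits each residue once")

    def __len__(self) -> int:
        return len(self.residues)

    def canonical(self) -> "Pathway":
        r = self.residues
        return self if r[0] <= r[-1] else Pathway(tuple(reversed(r)))


@dataclass
class PathwaySet:
    pathways: list[Pathway]
    n_residues: int
    direct: set[tuple[int, int]] = field(init=False)
    indirect: set[tuple[int, int]] = field(init=False)
    traversal: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.direct = set()
        self.indirect = set()
        self.traversal = np.zeros(self.n_residues, dtype=int)
        for p in self.pathways:
            r = p.residues
            for a, b in zip(r, r[1:]):
                self.direct.add((min(a, b), max(a, b)))
            for k, a in enumerate(r):
                for b in r[k + 2:]:
                    self.indirect.add((min(a, b), max(a, b)))
            for a in r:
                self.traversal[a] += 1

    def __len__(self) -> int:
        return len(self.pathways)

    def co_members(self) -> set[tuple[int, int]]:
        return self.direct | self.indirect

    def unit_of(self) -> np.ndarray:
        """Pathway-based unit id per residue (-1 outside every pathway).

        Units are the connected components of the pathway-adjacency graph,
        numbered by smallest member.
        """
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_residues))
        g.add_edges_from(self.direct)
        out = np.full(self.n_residues, -1, dtype=int)
        comps = [c for c in nx.connected_components(g) if len(c) > 1]
        comps.sort(key=min)
        for uid, comp in enumerate(comps):
            for r in comp:
                out[r] = uid
        return out


def _valid_step(topology: Topology, a: int, b: int) -> bool:
    """Consecutive pathway members: different chains or sequence sep >= 2."""
    sep = topology.sequence_separation(a, b)
    return sep is None or sep >= 2


def enumerate_pathways(
    interactions: InteractionSet,
    efficient: np.ndarray,
    topology: Topology,
    max_pathways: int = 500_000,
    max_length: int | None = None,
) -> PathwaySet:
    """All maximal pairwise-efficient simple paths over stable interactions.

    Depth-first enumeration from every residue, visiting neighbours in
    index order so output is canonical; a candidate extension is pruned as
    soon as it is inefficient with any current member.  Pathways are
    deduplicated by orientation, then contiguous subpaths of longer
    retained pathways are discarded.
    """
    n = topology.n_residues
    eff = np.asarray(efficient, dtype=bool)

    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in interactions.pairs:
        if _valid_step(topology, a, b) and eff[a, b]:
            adj[a].append(b)
            adj[b].append(a)
    for lst in adj:
        lst.sort()

    raw: set[tuple[int, ...]] = set()
    budget = max_pathways

    def extend(path: list[int], members: set[int]) -> None:
        nonlocal budget
        tail = path[-1]
        extended = False
        for nxt in adj[tail]:
            if nxt in members:
                continue
            if max_length is not None and len(path) >= max_length:
                break
            if all(eff[nxt, m] for m in members):
                extended = True
                path.append(nxt)
                members.add(nxt)
                extend(path, members)
                members.remove(nxt)
                path.pop()
        if not extended and len(path) >= 2:
            t = tuple(path)
            if t[0] > t[-1]:
                t = tuple(reversed(t))
            if t not in raw:
                raw.add(t)
                budget -= 1
                if budget < 0:
                    raise PathwayExplosionError(
                        f"more than {max_pathways} pathways; raise CP_cut "
                        "restraint or the max_pathways budget"
                    )

    for start in range(n):
        if adj[start]:
            extend([start], {start})

    kept = _drop_contiguous_subpaths(sorted(raw))
    return PathwaySet([Pathway(t) for t in kept], n_residues=n)


def _drop_contiguous_subpaths(paths: list[tuple[int, ...]]) -> list[tuple[int, ...]]:
    """Remove tuples that appear as contiguous subsequences of longer ones
    (both orientations considered)."""
    by_len = sorted(paths, key=len, reverse=True)
    kept: list[tuple[int, ...]] = []
    windows: set[tuple[int, ...]] = set()
    for p in by_len:
        if p in windows or tuple(reversed(p)) in windows:
            continue
        kept.append(p)
        L = len(p)
        for w in range(2, L + 1):
            for s in range(L - w + 1):
                windows.add(p[s:s + w])
    kept.sort()
    return kept


def pathway_counts(ps: PathwaySet, min_lengths=(3, 4, 5, 6)) -> dict[int, int]:
    """Number of pathways with more than L residues, for each L."""
    lengths = np.array([len(p) for p in ps.pathways], dtype=int)
    return {int(L): int((lengths > L).sum()) for L in min_lengths}


def highly_connected_residues(ps: PathwaySet, k: int = 70) -> set[int]:
    """Residues crossed by strictly more than k pathways."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return set(np.nonzero(ps.traversal >= 1)[0].tolist())
    return set(np.nonzero(ps.traversal > k)[0].tolist())


GREY, BLACK = -2, -1  # colored dots carry the (non-negative) unit id


@dataclass
class DotPlot:
    """Symmetric map of communicating residue pairs to display classes.

    Classes are mutually exclusive per pair: grey (same chain, sequence
    separation below ``far_sep``), black (direct communication, not grey),
    or a pathway-based unit id (indirect communication, not grey).
    """

    dots: dict[tuple[int, int], int]  # (i, j) with i < j -> class code
    n_residues: int
    cp_quantile: float | None = None

    def black_dots(self) -> set[tuple[int, int]]:
        return {p for p, c in self.dots.items() if c == BLACK}

    def grey_dots(self) -> set[tuple[int, int]]:
        return {p for p, c in self.dots.items() if c == GREY}

    def colored_dots(self) -> dict[tuple[int, int], int]:
        return {p: c for p, c in self.dots.items() if c >= 0}


def dotplot(
    ps: PathwaySet,
    topology: Topology,
    far_sep: int = 4,
    cp_quantile: float | None = None,
    unit_of: np.ndarray | None = None,
) -> DotPlot:
    """Dot plot of all direct and indirect communications.

    ``far_sep`` is the sequence-separation bound below which a same-chain
    pair is drawn grey regardless of its communication class.
    """
    if unit_of is None:
        unit_of = ps.unit_of()
    dots: dict[tuple[int, int], int] = {}
    for i, j in ps.co_members():
        sep = topology.sequence_separation(i, j)
        if sep is not None and sep < far_sep:
            dots[(i, j)] = GREY
        elif (i, j) in ps.direct:
            dots[(i, j)] = BLACK
        else:
            ui, uj = unit_of[i], unit_of[j]
            assert ui == uj and ui >= 0, "indirect pair must share one unit"
            dots[(i, j)] = int(ui)
    return DotPlot(dots, n_residues=ps.n_residues, cp_quantile=cp_quantile)
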