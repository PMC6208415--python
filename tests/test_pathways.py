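"""Pathway enumeration, maximality, counts and the dot plot."""

import itertools

import numpy as np
import pytest

from infostery.interactions import InteractionRecord, InteractionSet
from infostery.pathways import (
    BLACK,
    GREY,
    PathwaySet,
    dotplot,
    enumerate_pathways,
    highly_connected_residues,
    pathway_counts,
)

from conftest import make_topology


def interaction_set(pairs):
    records = [
        InteractionRecord((min(a, b), max(a, b)), "hbond", 1.0) for a, b in pairs
    ]
    return InteractionSet(sorted(records, key=lambda r: r.pair), s_min=0.5)


def eff_matrix(n, inefficient=()):
    eff = np.ones((n, n), dtype=bool)
    np.fill_diagonal(eff, False)
    for a, b in inefficient:
        eff[a, b] = eff[b, a] = False
    return eff


def oracle_enumerate(n, edges, eff, chain=None):
    """Exhaustive maximal pairwise-efficient simple-path search."""
    chain = chain if chain is not None else np.zeros(n, dtype=int)
    adj = {i: set() for i in range(n)}
    for a, b in edges:
        if (chain[a] != chain[b] or abs(a - b) >= 2) and eff[a, b]:
            adj[a].add(b)
            adj[b].add(a)

    def valid(path):
        return all(eff[a, b] for a, b in itertools.combinations(path, 2))

    # all simple paths by brute-force DFS over every ordering
    all_paths = set()

    def grow(path):
        all_paths.add(tuple(path))
        for nxt in adj[path[-1]]:
            if nxt not in path and valid(path + [nxt]):
                grow(path + [nxt])

    for s in range(n):
        grow([s])
    all_paths = {p for p in all_paths if len(p) >= 2}

    def extendable(p):
        for end, rest in ((p[-1], p), (p[0], tuple(reversed(p)))):
            for nxt in adj[end]:
                if nxt not in p and valid(list(rest) + [nxt]):
                    return True
        return False

    maximal = {p for p in all_paths if not extendable(p)}
    canon = {p if p[0] <= p[-1] else tuple(reversed(p)) for p in maximal}

    def windows(p):
        for w in range(2, len(p) + 1):
            for s in range(len(p) - w + 1):
                yield p[s:s + w]

    out = set()
    for p in canon:
        contained = any(
            p != q and (p in set(windows(q)) or tuple(reversed(p)) in set(windows(q)))
            for q in canon
        )
        if not contained:
            out.add(p)
    return out


class TestEnumeration:
    def test_subpath_of_longer_pathway_discarded(self):
        topo = make_topology(7)
        ia = interaction_set([(1, 3), (3, 5), (2, 6)])
        ps = enumerate_pathways(ia, eff_matrix(7), topo)
        assert {p.residues for p in ps.pathways} == {(1, 3, 5), (2, 6)}

    def test_inefficient_endpoint_pair_splits_pathway(self):
        topo = make_topology(7)
        ia = interaction_set([(1, 3), (3, 5), (2, 6)])
        eff = eff_matrix(7, inefficient=[(1, 5)])
        ps = enumerate_pathways(ia, eff, topo)
        assert {p.residues for p in ps.pathways} == {(1, 3), (3, 5), (2, 6)}

    def test_empty_interaction_set_gives_empty_pathways(self):
        ps = enumerate_pathways(interaction_set([]), eff_matrix(5), make_topology(5))
        assert len(ps) == 0

    def test_sequence_adjacent_steps_excluded(self):
        topo = make_topology(4)
        ia = interaction_set([(0, 1), (1, 3)])
        ps = enumerate_pathways(ia, eff_matrix(4), topo)
        assert {p.residues for p in ps.pathways} == {(1, 3)}

    def test_inter_chain_steps_always_allowed(self):
        topo = make_topology(3)
        # make residue 2 a separate chain adjacent in index
        from infostery.ensemble import Atom, Residue, Topology

        residues = [Residue("A", 1, "ALA"), Residue("A", 2, "ALA"),
                    Residue("B", 1, "ALA")]
        atoms = [Atom("CA", "C", i, True) for i in range(3)]
        topo = Topology(residues, atoms)
        ia = interaction_set([(1, 2)])
        ps = enumerate_pathways(ia, eff_matrix(3), topo)
        assert {p.residues for p in ps.pathways} == {(1, 2)}

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        topo = make_topology(n)
        edges = [
            (a, b)
            for a in range(n)
            for b in range(a + 2, n)
            if rng.random() < 0.3
        ]
        bad = [
            (a, b)
            for a in range(n)
            for b in range(a + 1, n)
            if rng.random() < 0.3
        ]
        eff = eff_matrix(n, inefficient=bad)
        ps = enumerate_pathways(interaction_set(edges), eff, topo)
        assert {p.residues for p in ps.pathways} == oracle_enumerate(n, edges, eff)

    def test_deterministic_and_edge_order_independent(self):
        topo = make_topology(9)
        edges = [(0, 2), (2, 4), (4, 6), (6, 8), (1, 5), (3, 7), (0, 4)]
        eff = eff_matrix(9, inefficient=[(0, 6), (2, 8)])
        a = enumerate_pathways(interaction_set(edges), eff, topo)
        b = enumerate_pathways(interaction_set(list(reversed(edges))), eff, topo)
        assert [p.residues for p in a.pathways] == [p.residues for p in b.pathways]

    def test_numbering_reversal_gives_mirrored_pathways(self):
        n = 8
        topo = make_topology(n)
        edges = [(0, 2), (2, 5), (5, 7), (1, 4)]
        eff = eff_matrix(n, inefficient=[(0, 7)])
        fwd = enumerate_pathways(interaction_set(edges), eff, topo)
        redges = [(n - 1 - a, n - 1 - b) for a, b in edges]
        reff = eff[::-1, ::-1].copy()
        rev = enumerate_pathways(interaction_set(redges), reff, topo)
        mirrored = {
            tuple(sorted((tuple(n - 1 - r for r in p.residues),
                          tuple(reversed([n - 1 - r for r in p.residues]))))[0])
            for p in rev.pathways
        }
        orig = {
            tuple(sorted((p.residues, tuple(reversed(p.residues))))[0])
            for p in fwd.pathways
        }
        assert orig == mirrored


class TestCountsAndConnectivity:
    def make_ps(self, paths, n=40):
        from infostery.pathways import Pathway

        return PathwaySet([Pathway(tuple(p)) for p in paths], n_residues=n)

    def test_counts_by_length_threshold(self):
        ps = self.make_ps(
            [(0, 2, 4, 6), (1, 3, 5, 7), (8, 10, 12, 14, 16),
             (9, 11, 13, 15, 17, 19, 21)]
        )
        counts = pathway_counts(ps, (3, 4, 5, 6))
        assert counts == {3: 4, 4: 2, 5: 1, 6: 1}

    def test_threshold_above_longest_gives_zero(self):
        ps = self.make_ps([(0, 2, 4)])
        assert pathway_counts(ps, (10,)) == {10: 0}

    def test_counts_non_increasing(self):
        ps = self.make_ps([(0, 2, 4, 6, 8), (1, 3, 5), (7, 9, 11, 13)])
        counts = pathway_counts(ps, (2, 3, 4, 5, 6))
        vals = [counts[k] for k in sorted(counts)]
        assert vals == sorted(vals, reverse=True)

    def test_highly_connected_strict_boundary(self):
        ps = self.make_ps([(0, 2)] , n=5)
        ps.traversal = np.array([71, 70, 0, 1, 0])
        assert highly_connected_residues(ps, 70) == {0}

    def test_k_zero_returns_all_traversed(self):
        ps = self.make_ps([(0, 2, 4), (1, 3)], n=6)
        assert highly_connected_residues(ps, 0) == {0, 1, 2, 3, 4}


class TestDotPlot:
    def test_direct_far_pair_is_black(self):
        topo = make_topology(45)
        ps = TestCountsAndConnectivity().make_ps([(10, 40)], n=45)
        dp = dotplot(ps, topo)
        assert dp.dots[(10, 40)] == BLACK

    def test_direct_near_pair_is_grey(self):
        topo = make_topology(45)
        ps = TestCountsAndConnectivity().make_ps([(10, 12)], n=45)
        dp = dotplot(ps, topo)
        assert dp.dots[(10, 12)] == GREY

    def test_indirect_pair_carries_unit_id(self):
        topo = make_topology(45)
        ps = TestCountsAndConnectivity().make_ps([(5, 20, 40)], n=45)
        dp = dotplot(ps, topo)
        assert dp.dots[(5, 20)] == BLACK
        assert dp.dots[(20, 40)] == BLACK
        assert dp.dots[(5, 40)] == 0  # indirect endpoints, unit id 0

    def test_cross_chain_pair_never_grey(self):
        from infostery.ensemble import Atom, Residue, Topology

        residues = [Residue("A", i + 1, "ALA") for i in range(3)]
        residues += [Residue("B", 1, "ALA")]
        atoms = [Atom("CA", "C", i, True) for i in range(4)]
        topo = Topology(residues, atoms)
        ps = TestCountsAndConnectivity().make_ps([(2, 3)], n=4)
        dp = dotplot(ps, topo)
        assert dp.dots[(2, 3)] == BLACK
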