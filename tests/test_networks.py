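"""Interaction persistence matrices and residue-graph analysis."""

import itertools
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from idpens.ensemble_io import EnsembleError
from idpens.networks import (
    PersistenceMatrix,
    build_interaction_graph,
    connected_components,
    contact_persistence,
    enumerate_paths,
    find_hubs,
)
from idpens.synthetic import (
    ContactPair,
    ContactSchedule,
    EnsembleSpec,
    generate_ensemble,
    plant_contacts,
)

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_hubs(g, min_degree):
    return sorted(n for n in g.nodes if sum(1 for _ in g.neighbors(n)) >= min_degree)


def brute_components(g):
    """Transitive closure by repeated adjacency expansion."""
    nodes = [n for n in g.nodes if any(True for _ in g.neighbors(n))]
    comps = []
    seen = set()
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        while True:
            grown = set(comp)
            for u in comp:
                grown.update(g.neighbors(u))
            if grown == comp:
                break
            comp = grown
        comps.append(comp)
        seen |= comp
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def brute_paths(g, s, t):
    """All simple paths by permutation enumeration over intermediate nodes."""
    others = [n for n in g.nodes if n not in (s, t)]
    found = []
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            seq = [s, *mid, t]
            if all(g.has_edge(a, b) for a, b in zip(seq, seq[1:])):
                found.append(seq)
    return sorted(found)


def random_graph(rng, n_nodes, p=0.4):
    g = nx.Graph()
    g.add_nodes_from(range(1, n_nodes + 1))
    for i in range(1, n_nodes + 1):
        for j in range(i + 1, n_nodes + 1):
            if rng.random() < p:
                g.add_edge(i, j, weight=rng.uniform(0.2, 1.0))
    return g


class TestContactPersistence:
    def test_planted_fraction_exact_rational(self):
        ens, _ = generate_ensemble(EnsembleSpec(
            n_residues=30, n_frames=10, helical_segments=[], seed=1))
        mask = np.zeros(10, dtype=bool)
        mask[[0, 5]] = True
        planted, _ = plant_contacts(
            ens, ContactSchedule([ContactPair(2, 18, 0.2, mask=mask)]))
        pm = contact_persistence(planted, "salt_bridge", 0.5)
        assert pm.persistence(2, 18) == Fraction(1, 5)

    def test_zero_cutoff_gives_empty_matrix(self):
        ens, _ = generate_ensemble(EnsembleSpec(
            n_residues=30, n_frames=5, helical_segments=[], seed=1))
        pm = contact_persistence(ens, "salt_bridge", 0.0)
        assert pm.matrix.sum() == 0

    def test_matrix_symmetric_bounded_zero_diagonal(self):
        ens, _ = generate_ensemble(EnsembleSpec(
            n_residues=30, n_frames=20, helical_segments=[],
            states=[("compact", 1.0, 0.8)], seed=2))
        for cls in ("salt_bridge", "aromatic", "amino_aromatic", "hydrophobic"):
            pm = contact_persistence(ens, cls)
            assert np.allclose(pm.matrix, pm.matrix.T)
            assert np.all(np.diag(pm.matrix) == 0)
            assert pm.matrix.min() >= 0 and pm.matrix.max() <= 1
            np.testing.assert_array_equal(pm.matrix * pm.n_frames, pm.counts)

    def test_hydrophobic_requires_sequence_separation(self):
        ens, _ = generate_ensemble(EnsembleSpec(
            n_residues=30, n_frames=5, helical_segments=[],
            states=[("compact", 1.0, 0.8)], seed=3))
        pm = contact_persistence(ens, "hydrophobic", 0.5)
        pos = {r: k for k, r in enumerate(pm.residue_ids)}
        for i in pm.residue_ids:
            for j in pm.residue_ids:
                if abs(i - j) < 2:
                    assert pm.matrix[pos[i], pos[j]] == 0

    def test_edge_count_monotone_in_distance_cutoff(self):
        ens, _ = generate_ensemble(EnsembleSpec(
            n_residues=40, n_frames=10, helical_segments=[],
            states=[("compact", 1.0, 0.8)], seed=4))
        totals = [contact_persistence(ens, "hydrophobic", c).counts.sum()
                  for c in (0.8, 0.6, 0.45, 0.3)]
        assert all(b <= a for a, b in zip(totals, totals[1:]))

    def test_missing_class_atoms_rejected(self):
        ens, _ = generate_ensemble(EnsembleSpec(
            n_residues=10, n_frames=2, helical_segments=[],
            sequence="G" * 10, seed=0))
        with pytest.raises(EnsembleError):
            contact_persistence(ens, "aromatic")


class TestInteractionGraph:
    def _matrix(self, entries, n=6):
        m = np.zeros((n, n))
        counts = np.zeros((n, n), dtype=np.int64)
        for i, j, v in entries:
            m[i, j] = m[j, i] = v
            counts[i, j] = counts[j, i] = int(round(v * 100))
        return PersistenceMatrix(m, counts, list(range(1, n + 1)),
                                 "salt_bridge", 0.5, 100)

    def test_single_edge_above_threshold(self):
        g = build_interaction_graph(self._matrix([(0, 3, 0.25)]), 0.20)
        assert g.edges == [(1, 4, 0.25)]

    def test_all_below_threshold_empty(self):
        g = build_interaction_graph(self._matrix([(0, 3, 0.1), (1, 2, 0.19)]), 0.20)
        assert g.edges == []

    def test_edge_count_monotone_in_threshold(self, rng):
        entries = [(i, j, rng.uniform(0, 1))
                   for i in range(6) for j in range(i + 1, 6)]
        pm = self._matrix(entries)
        counts = [len(build_interaction_graph(pm, t).edges)
                  for t in (0.0, 0.2, 0.5, 0.8, 1.01)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 0


class TestGraphAnalysis:
    def test_star_center_is_only_hub(self):
        g = nx.star_graph(4)  # center 0, degree 4
        assert find_hubs(g, 3) == [0]
        assert find_hubs(g, 4) == [0]

    def test_cycle_has_no_hubs(self):
        assert find_hubs(nx.cycle_graph(6), 3) == []

    def test_planted_high_degree_nodes_recovered(self, rng):
        g = nx.Graph()
        g.add_nodes_from(range(30))
        for hub in (3, 11, 22):
            for other in rng.choice([n for n in range(30) if n != hub],
                                    size=6, replace=False):
                g.add_edge(hub, int(other))
        hubs = find_hubs(g, 5)
        assert set((3, 11, 22)) <= set(hubs)

    def test_components_two_disjoint_edges(self):
        g = nx.Graph([(1, 2), (5, 6)])
        assert connected_components(g) == [{1, 2}, {5, 6}]

    def test_components_chain(self):
        g = nx.path_graph([1, 2, 3, 4, 5])
        assert connected_components(g) == [{1, 2, 3, 4, 5}]

    def test_components_sorted_descending(self, rng):
        g = random_graph(rng, 12, p=0.15)
        comps = connected_components(g)
        sizes = [len(c) for c in comps]
        assert sizes == sorted(sizes, reverse=True)

    def test_triangle_paths_exhaustive(self):
        g = nx.Graph([(1, 2), (2, 3), (1, 3)])
        ps = enumerate_paths(g, 1, 3)
        assert ps.paths == [[1, 2, 3], [1, 3]]
        assert not ps.truncated

    def test_disconnected_pair_has_no_paths(self):
        g = nx.Graph([(1, 2), (3, 4)])
        assert enumerate_paths(g, 1, 4).paths == []

    def test_truncation_flagged(self):
        g = nx.complete_graph(range(1, 8))
        ps = enumerate_paths(g, 1, 7, max_paths=5)
        assert ps.truncated and len(ps.paths) == 5

    def test_absent_node_rejected(self):
        with pytest.raises(EnsembleError):
            enumerate_paths(nx.Graph([(1, 2)]), 1, 99)

    def test_same_source_target_rejected(self):
        with pytest.raises(EnsembleError):
            enumerate_paths(nx.Graph([(1, 2)]), 1, 1)

    def test_small_graphs_match_brute_force(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 9))
            g = random_graph(rng, n)
            assert find_hubs(g, 3) == brute_hubs(g, 3)
            assert connected_components(g) == brute_components(g)
            s, t = 1, n
            ps = enumerate_paths(g, s, t)
            assert sorted(ps.paths) == brute_paths(g, s, t)
            # lexicographic emission order
            assert ps.paths == sorted(ps.paths)


class TestCompactVsExtendedContrast:
    def test_compact_network_denser_than_extended(self):
        # many high-persistence planted pairs in the compact ensemble,
        # few in the extended one -> more hubs and a larger main component
        F = 42

        def mask(offset, step):
            m = np.zeros(F, dtype=bool)
            m[offset::step] = True
            return m

        def build(pairs, seed):
            ens, _ = generate_ensemble(EnsembleSpec(
                n_residues=70, n_frames=F, helical_segments=[], seed=seed))
            planted, _ = plant_contacts(ens, ContactSchedule(pairs, seed=seed))
            pm = contact_persistence(planted, "salt_bridge", 0.5)
            return build_interaction_graph(pm, 0.20)

        # hub residue 7 (Arg) touches three Glu/Asp partners on disjoint
        # frame sets (one atom cannot hold two contacts in the same frame)
        compact = build([
            ContactPair(7, 4, 1 / 3, mask=mask(0, 3)),
            ContactPair(7, 18, 1 / 3, mask=mask(1, 3)),
            ContactPair(7, 32, 1 / 3, mask=mask(2, 3)),
            ContactPair(21, 33, 0.5, mask=mask(0, 2)),
            ContactPair(21, 46, 0.5, mask=mask(1, 2)),
            ContactPair(35, 47, 0.5, mask=mask(0, 2)),
        ], seed=5)
        extended = build([ContactPair(2, 4, 0.5)], seed=6)
        assert len(find_hubs(compact, 3)) > len(find_hubs(extended, 3))
        c_sizes = [len(c) for c in connected_components(compact)]
        e_sizes = [len(c) for c in connected_components(extended)]
        assert max(c_sizes) > max(e_sizes)
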