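"""Coupling-graph construction, max-product pathway search, ensemble census."""

import math

import networkx as nx
import numpy as np
import pytest

from conftest import make_snapshot, random_rigid_transform
from spinpath.errors import DegenerateInputError, NoPathError, ValidationError
from spinpath.pathways import (
    PathwayParams,
    build_coupling_graph,
    census,
    coupling_ratio,
    strongest_pathway,
)
from spinpath.structures import Ensemble


def brute_force_max_product(g, donor, acceptor):
    """Independent oracle: exhaustive enumeration of all simple paths."""
    best = 0.0
    for path in nx.all_simple_paths(g, donor, acceptor):
        eps = math.prod(g.edges[u, v]["epsilon"] for u, v in zip(path, path[1:]))
        best = max(best, eps)
    return best


def random_epsilon_graph(rng, n_nodes):
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    for i in range(n_nodes):
        g.nodes[i].update(residue_name="UNK", residue_seq=i)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < 0.45:
                g.add_edge(i, j, kind="through_space",
                           epsilon=float(rng.uniform(0.05, 1.0)))
    return g


class TestGraphConstruction:
    def test_single_covalent_bond_gets_default_epsilon(self):
        s = make_snapshot(
            [(1, "C", "C1", "UNK", 1, (0, 0, 0)),
             (2, "C", "C2", "UNK", 1, (1.5, 0, 0))],
            bonds={(1, 2)},
        )
        g = build_coupling_graph(s)
        assert g.edges[1, 2]["kind"] == "covalent"
        assert g.edges[1, 2]["epsilon"] == pytest.approx(0.6)

    def test_through_space_at_r0_is_prefactor_times_covalent(self):
        p = PathwayParams()
        s = make_snapshot(
            [(1, "C", "C1", "UNK", 1, (0, 0, 0)),
             (2, "C", "C2", "UNK", 2, (p.r0_ts, 0, 0))],
        )
        g = build_coupling_graph(s, p)
        assert g.edges[1, 2]["kind"] == "through_space"
        assert g.edges[1, 2]["epsilon"] == pytest.approx(
            p.prefactor_ts * p.eps_covalent
        )

    def test_pair_beyond_cutoff_has_no_edge(self):
        s = make_snapshot(
            [(1, "C", "C1", "UNK", 1, (0, 0, 0)),
             (2, "C", "C2", "UNK", 2, (7.0, 0, 0))],
        )
        g = build_coupling_graph(s)
        assert g.number_of_edges() == 0

    def test_oxygen_pair_in_range_is_hydrogen_bond(self):
        p = PathwayParams()
        s = make_snapshot(
            [(1, "O", "O", "HOH", 1, (0, 0, 0)),
             (2, "O", "O", "HOH", 2, (2.8, 0, 0))],
        )
        g = build_coupling_graph(s, p)
        assert g.edges[1, 2]["kind"] == "hbond"
        assert g.edges[1, 2]["epsilon"] == pytest.approx(p.eps_covalent**2)

    def test_epsilon_clamped_to_one(self):
        s = make_snapshot(
            [(1, "C", "C1", "UNK", 1, (0, 0, 0)),
             (2, "C", "C2", "UNK", 2, (0.3, 0, 0))],
        )
        g = build_coupling_graph(s)
        assert g.edges[1, 2]["epsilon"] <= 1.0

    def test_empty_snapshot_rejected(self):
        with pytest.raises(ValidationError):
            build_coupling_graph(make_snapshot([]))

    def test_graph_invariant_under_rigid_transform(self, template):
        rng = np.random.default_rng(21)
        g0 = build_coupling_graph(template)
        rot, shift = random_rigid_transform(rng)
        g1 = build_coupling_graph(
            template.with_coords(template.coords_array() @ rot.T + shift)
        )
        assert set(g0.edges) == set(g1.edges)
        for e in g0.edges:
            assert g1.edges[e]["epsilon"] == pytest.approx(
                g0.edges[e]["epsilon"], rel=1e-9
            )


class TestStrongestPathway:
    def test_single_edge_identity(self):
        g = nx.Graph()
        g.add_node(1, residue_name="A", residue_seq=1)
        g.add_node(2, residue_name="B", residue_seq=2)
        g.add_edge(1, 2, kind="through_space", epsilon=0.3)
        pw = strongest_pathway(g, 1, 2)
        assert pw.atom_sequence == [1, 2]
        assert pw.epsilon_total == pytest.approx(0.3)

    def test_covalent_chain_beats_weak_direct_jump(self):
        g = nx.Graph()
        for i in range(1, 5):
            g.add_node(i, residue_name="UNK", residue_seq=i)
        for u, v in ((1, 2), (2, 3), (3, 4)):
            g.add_edge(u, v, kind="covalent", epsilon=0.6)
        g.add_edge(1, 4, kind="through_space", epsilon=0.05)
        pw = strongest_pathway(g, 1, 4)
        assert pw.atom_sequence == [1, 2, 3, 4]
        assert pw.epsilon_total == pytest.approx(0.216)
        # oracle agrees
        assert brute_force_max_product(g, 1, 4) == pytest.approx(0.216)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(150):
            n = int(rng.integers(2, 11))
            g = random_epsilon_graph(rng, n)
            if not nx.has_path(g, 0, n - 1):
                with pytest.raises(NoPathError):
                    strongest_pathway(g, 0, n - 1)
                continue
            pw = strongest_pathway(g, 0, n - 1)
            assert pw.epsilon_total == pytest.approx(
                brute_force_max_product(g, 0, n - 1), rel=1e-9
            )
            checked += 1
        assert checked > 50

    def test_epsilon_total_equals_product_of_edges(self, template):
        g = build_coupling_graph(template)
        pw = strongest_pathway(
            g, template.site_tags["donor"], template.site_tags["acceptor"]
        )
        prod = math.prod(
            g.edges[u, v]["epsilon"]
            for u, v in zip(pw.atom_sequence, pw.atom_sequence[1:])
        )
        assert pw.epsilon_total == pytest.approx(prod, rel=1e-12)
        assert 0 < pw.epsilon_total <= 1

    def test_adding_edges_never_increases_product(self):
        # any prefix of the optimal path has a product >= the full path
        g = nx.Graph()
        for i in range(6):
            g.add_node(i, residue_name="UNK", residue_seq=i)
        rng = np.random.default_rng(5)
        for i in range(5):
            g.add_edge(i, i + 1, kind="covalent",
                       epsilon=float(rng.uniform(0.1, 1.0)))
        pw = strongest_pathway(g, 0, 5)
        running = 1.0
        for u, v in zip(pw.atom_sequence, pw.atom_sequence[1:]):
            nxt = running * g.edges[u, v]["epsilon"]
            assert nxt <= running + 1e-15
            running = nxt

    def test_tie_break_prefers_fewer_edges_then_lexicographic(self):
        g = nx.Graph()
        for i in range(1, 6):
            g.add_node(i, residue_name="UNK", residue_seq=i)
        # two exact-tie routes 1-2-5 and 1-3-4-5 with equal products
        g.add_edge(1, 2, kind="covalent", epsilon=0.6)
        g.add_edge(2, 5, kind="covalent", epsilon=0.6)
        g.add_edge(1, 3, kind="covalent", epsilon=0.6)
        g.add_edge(3, 4, kind="covalent", epsilon=1.0)
        g.add_edge(4, 5, kind="covalent", epsilon=0.6)
        pw = strongest_pathway(g, 1, 5)
        assert pw.atom_sequence == [1, 2, 5]
        # equal length ties: smallest atom sequence
        g.add_edge(1, 4, kind="covalent", epsilon=0.6)
        pw2 = strongest_pathway(g, 1, 5)
        assert pw2.atom_sequence == [1, 2, 5]

    def test_disconnected_raises(self):
        g = nx.Graph()
        g.add_node(1, residue_name="A", residue_seq=1)
        g.add_node(2, residue_name="B", residue_seq=2)
        with pytest.raises(NoPathError):
            strongest_pathway(g, 1, 2)


def _two_conformation_ensemble(n_a=6, n_b=4):
    """Ensemble whose strongest route alternates between two mediators."""
    base = [
        (1, "Ru", "RU", "RU", 201, (0.0, 0, 0)),
        (2, "C", "CA", "GLY", 2, (2.0, 0.9, 0)),
        (3, "C", "CA", "ALA", 3, (2.0, -1.0, 0)),
        (4, "Cu", "CU", "CU", 130, (4.0, 0, 0)),
    ]
    tags = {"donor": 1, "acceptor": 4}
    snap_a = make_snapshot(base, tags=tags)          # GLY route shorter
    moved = [list(r) for r in base]
    moved[1][5] = (2.0, 1.8, 0.0)                    # GLY pushed away
    moved[2][5] = (2.0, -0.4, 0.0)                   # ALA pulled in
    snap_b = make_snapshot([tuple(r) for r in moved], tags=tags)
    snaps = []
    for i in range(n_a + n_b):
        src = snap_a if i < n_a else snap_b
        snaps.append(src.with_coords(src.coords_array(), model_index=i))
    return Ensemble(snapshots=snaps)


class TestCensus:
    def test_identical_snapshots_single_signature(self, template):
        ens = Ensemble([template.with_coords(template.coords_array(),
                                             model_index=i) for i in range(4)])
        c = census(ens)
        assert len(c.fractions) == 1
        assert list(c.fractions.values()) == [pytest.approx(1.0)]
        assert sum(c.counts.values()) == 4

    def test_sixty_forty_split_exact(self):
        c = census(_two_conformation_ensemble(6, 4))
        fracs = sorted(c.fractions.values(), reverse=True)
        assert fracs == [pytest.approx(0.6), pytest.approx(0.4)]
        assert sum(c.counts.values()) == c.n_snapshots == 10

    def test_fractions_sum_to_one_and_permutation_invariant(self):
        ens = _two_conformation_ensemble(6, 4)
        c1 = census(ens)
        shuffled = Ensemble(list(reversed(ens.snapshots)))
        c2 = census(shuffled)
        assert sum(c1.fractions.values()) == pytest.approx(1.0)
        assert c1.fractions == c2.fractions
        assert c1.mean_square_decay == pytest.approx(c2.mean_square_decay)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValidationError):
            Ensemble(snapshots=[])

    def test_disconnected_snapshots_reported_not_dropped(self):
        near = make_snapshot(
            [(1, "Ru", "RU", "RU", 1, (0, 0, 0)),
             (2, "Cu", "CU", "CU", 2, (3.0, 0, 0))],
            tags={"donor": 1, "acceptor": 2},
        )
        far = near.with_coords(np.array([[0, 0, 0], [50.0, 0, 0]]),
                               model_index=1)
        c = census(Ensemble([near, far]))
        assert c.n_disconnected == 1
        assert c.strongest[1] is None
        assert sum(c.counts.values()) == 1


class TestCouplingRatio:
    def test_identical_censuses_give_unity(self, template):
        ens = Ensemble([template])
        c = census(ens)
        assert coupling_ratio(c, c) == pytest.approx(1.0)

    def test_doubling_epsilon_quadruples_ratio(self, template):
        ens = Ensemble([template])
        c1 = census(ens)
        import copy

        c2 = copy.deepcopy(c1)
        c2.mean_square_decay = c1.mean_square_decay / 4.0  # eps halved
        assert coupling_ratio(c1, c2) == pytest.approx(4.0)

    def test_zero_denominator_rejected(self, template):
        import copy

        c1 = census(Ensemble([template]))
        c0 = copy.deepcopy(c1)
        c0.mean_square_decay = 0.0
        with pytest.raises(DegenerateInputError):
            coupling_ratio(c1, c0)

    def test_hot_vs_cold_synthetic_ratio_matches_recomputation(self):
        from spinpath.synthetic import EnsembleSpec, make_toy_azurin

        hot = census(make_toy_azurin(EnsembleSpec(n_snapshots=40, seed=8,
                                                  temperature=290.0)))
        cold = census(make_toy_azurin(EnsembleSpec(n_snapshots=40, seed=8,
                                                   temperature=250.0)))
        r = coupling_ratio(hot, cold)
        # oracle: recompute from the per-snapshot pathway lists
        msd = [float(np.mean([p.epsilon_total**2 for p in c.strongest
                              if p is not None])) for c in (hot, cold)]
        assert r == pytest.approx(msd[0] / msd[1], rel=1e-12)
        assert r > 1.0  # hotter ensemble couples more strongly on average
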