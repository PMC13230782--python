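import numpy as np
import pytest

from cosref import (ContagionConfig, Regime, RegulationMatrix, classify_regime,
                    mixing_parameter, mt19937, run_cascade, seed_initial)
from cosref.empirical_io import (assign_overlaps, build_subnetwork, empirical_stats,
                                 make_snap_fixture, read_communities, read_edge_list,
                                 select_community_pair, write_communities,
                                 write_edge_list)
from cosref.errors import ParameterError


class TestEdgeListIO:
    def test_dedup_and_comments(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("# comment\n1 2\n2\t1\n")
        edges = read_edge_list(p)
        assert edges.tolist() == [[1, 2]]

    def test_self_loop_dropped(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("3 3\n1 2\n")
        assert read_edge_list(p).tolist() == [[1, 2]]

    def test_malformed_line(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("1 2\nbroken\n")
        with pytest.raises(ParameterError, match=":2"):
            read_edge_list(p)

    def test_round_trip(self, tmp_path, rng):
        edges = np.unique(rng.integers(0, 60, size=(100, 2)), axis=0)
        edges = edges[edges[:, 0] != edges[:, 1]]
        edges = np.sort(edges, axis=1)
        edges = np.unique(edges, axis=0)
        p = tmp_path / "e.txt"
        write_edge_list(p, edges, comment="round trip")
        assert np.array_equal(read_edge_list(p), edges)


class TestCommunityIO:
    def test_shared_node_and_round_trip(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("1 2 3\n3\t4\t5\n")
        comms = read_communities(p)
        assert comms == [{1, 2, 3}, {3, 4, 5}]
        q = tmp_path / "c2.txt"
        write_communities(q, comms)
        assert read_communities(q) == comms

    def test_empty_file_and_blank_lines(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("")
        assert read_communities(p) == []
        p.write_text("1 2\n\n3 4\n")
        assert read_communities(p) == [{1, 2}, {3, 4}]


class TestSelection:
    def test_connectivity_constraint_dominates_size(self):
        a = set(range(0, 100))
        b = set(range(100, 190))
        c = set(range(200, 280))
        edges = np.array([[0, 200], [1, 201], [2, 202]])  # only A-C connected
        assert select_community_pair(edges, [a, b, c], min_inter_edges=3) == (0, 2)

    def test_no_qualifying_pair(self):
        edges = np.empty((0, 2), dtype=int)
        with pytest.raises(ParameterError, match="candidates"):
            select_community_pair(edges, [{1, 2}, {3, 4}], min_inter_edges=1)

    def test_planted_fixture_pair_recovered(self, tmp_path, rng):
        info = make_snap_fixture(tmp_path / "fx", (40, 40), p_intra=0.2,
                                 p_inter=0.05, overlap=4, rng=rng, n_decoys=3)
        edges = read_edge_list(info.edge_path)
        comms = read_communities(info.community_path)
        assert len(comms) == 2 + 3
        assert select_community_pair(edges, comms) == tuple(info.planted["pair"])


class TestOverlaps:
    def test_no_overlap_is_identity(self):
        a, b = assign_overlaps(({1, 2}, {3, 4}), "biased")
        assert (a, b) == ({1, 2}, {3, 4})

    def test_biased_balances_sizes(self):
        # |A| = 10, |B| = 6 with 4 shared -> exclusives 6 and 2; the greedy
        # rule sends shared nodes to the currently smaller side: ends (6, 6)
        a = set(range(10))
        b = set(range(6, 16)) - {10, 11, 12, 13}  # {6,7,8,9,14,15}: shares 6..9
        a2, b2 = assign_overlaps((a, b), "biased")
        assert len(a2) == len(b2) == 6
        assert a2 | b2 == a | b and not a2 & b2

    def test_random_mode_reproducible(self):
        pair = (set(range(10)), set(range(5, 15)))
        r1 = assign_overlaps(pair, "random", mt19937(3))
        r2 = assign_overlaps(pair, "random", mt19937(3))
        assert r1 == r2


class TestStats:
    def test_hand_counted_bridged_triangles(self, toy_net):
        st = empirical_stats(toy_net)
        assert st.N == 6
        assert st.mu == pytest.approx(1 / 7)
        assert st.z_a == st.z_b == 2.0

    def test_bipartite_pair(self):
        edges = np.array([[0, 2], [0, 3], [1, 2], [1, 3]])
        net = build_subnetwork(edges, {0, 1}, {2, 3})
        st = empirical_stats(net)
        assert st.mu == 1.0 and st.z_a == st.z_b == 0.0

    def test_fixture_parameters_recovered(self, tmp_path):
        na = nb = 80
        p_intra, p_inter = 0.15, 0.03
        info = make_snap_fixture(tmp_path / "fx", (na, nb), p_intra, p_inter,
                                 overlap=0, rng=mt19937(8))
        edges = read_edge_list(info.edge_path)
        comms = read_communities(info.community_path)
        net = build_subnetwork(edges, comms[0], comms[1])
        st = empirical_stats(net)
        z_intra_exp = p_intra * (na - 1)
        z_inter_exp = p_inter * nb
        assert st.z_a == pytest.approx(z_intra_exp, rel=0.25)
        mu_exp = z_inter_exp / (z_inter_exp + z_intra_exp)
        assert st.mu == pytest.approx(mu_exp, abs=0.05)


class TestFixtureGeneration:
    def test_community_sizes_and_overlap(self, tmp_path, rng):
        info = make_snap_fixture(tmp_path / "fx", (50, 50), 0.1, 0.02, overlap=5, rng=rng)
        comms = read_communities(info.community_path)
        assert len(comms[0]) == len(comms[1]) == 50
        assert len(comms[0] & comms[1]) == 5

    def test_pure_inter_gives_mu_one(self, tmp_path, rng):
        info = make_snap_fixture(tmp_path / "fx", (20, 20), 0.0, 1.0, overlap=0, rng=rng)
        edges = read_edge_list(info.edge_path)
        comms = read_communities(info.community_path)
        net = build_subnetwork(edges, comms[0], comms[1])
        assert mixing_parameter(net) == 1.0

    def test_byte_identical_per_seed(self, tmp_path):
        a = make_snap_fixture(tmp_path / "a", (30, 30), 0.1, 0.05, 3, mt19937(5))
        b = make_snap_fixture(tmp_path / "b", (30, 30), 0.1, 0.05, 3, mt19937(5))
        assert open(a.edge_path).read() == open(b.edge_path).read()
        assert open(a.community_path).read() == open(b.community_path).read()


def test_fixture_pipeline_exhibits_three_regimes(tmp_path):
    """End to end: fixture -> select -> assign -> subnetwork -> cascades.

    Scanning the regulation pair must surface all three diffusion regimes on
    the extracted two-community system.
    """
    info = make_snap_fixture(tmp_path / "fx", (150, 150), p_intra=10 / 149,
                             p_inter=2.5 / 150, overlap=10, rng=mt19937(17),
                             n_decoys=2)
    edges = read_edge_list(info.edge_path)
    comms = read_communities(info.community_path)
    i, j = select_community_pair(edges, comms)
    a, b = assign_overlaps((comms[i], comms[j]), "biased")
    net = build_subnetwork(edges, a, b)
    st = empirical_stats(net)
    assert 0.05 < st.mu < 0.5

    cfg = ContagionConfig(rho0=0.17, theta=0.1, seed=2)
    rho0_comm = np.array([0.17 * net.N / net.module_sizes[0], 0.0])
    seen = set()
    for omega in [(0.05, 0.05), (1.0, 0.0), (1.0, 1.0)]:
        x0 = seed_initial(net, 0.17, 0, mt19937(2))
        traj = run_cascade(net, RegulationMatrix.from_pair(*omega), cfg, x0=x0)
        seen.add(classify_regime(traj.rho_inf_by_module, rho0_comm))
    assert seen == {Regime.NON_DIFFUSION, Regime.LOCALIZED, Regime.GLOBAL_DIFFUSION}
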