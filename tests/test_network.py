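import warnings

import networkx as nx
import numpy as np
import pytest

import oscnet as on
from oscnet.network import _sample_powerlaw_degrees


class TestGilbert:
    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            on.generate_random_gilbert(1, 0.1, seed=0)
        with pytest.raises(ValueError):
            on.generate_random_gilbert(78, -0.5, seed=0)
        # p = (1+eps)ln(n)/n >= 1
        with pytest.raises(ValueError):
            on.generate_random_gilbert(3, 5.0, seed=0)

    def test_two_nodes_forced_edge(self):
        net = on.generate_random_gilbert(2, 1.0, seed=0)
        assert net.adjacency[0, 1] == 1

    def test_connected_symmetric_reproducible(self):
        for seed in range(5):
            net = on.generate_random_gilbert(78, 0.1, seed=seed)
            assert net.is_connected()
            assert np.array_equal(net.adjacency, net.adjacency.T)
            assert np.all(np.diag(net.adjacency) == 0)
        a = on.generate_random_gilbert(78, 0.1, seed=3)
        b = on.generate_random_gilbert(78, 0.1, seed=3)
        assert np.array_equal(a.adjacency, b.adjacency)

    def test_edge_count_matches_binomial(self):
        """Mean edge count over many realizations ≈ C(n,2)·p within 3 SE.

        n and epsilon are chosen so that connectivity conditioning is
        negligible (isolated-node probability ~ 0.5%)."""
        n, eps = 200, 1.0
        p = (1 + eps) * np.log(n) / n
        n_pairs = n * (n - 1) // 2
        reps = 400
        counts = [
            on.generate_random_gilbert(n, eps, seed=s).degrees.sum() / 2 for s in range(reps)
        ]
        expected = n_pairs * p
        se = np.sqrt(n_pairs * p * (1 - p) / reps)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_mean_degree_matches_conditioned_oracle(self):
        """Package ensemble mean degree agrees with an independent
        brute-force implementation of the same conditioned draw."""
        n, eps, reps = 78, 0.1, 150
        p = (1 + eps) * np.log(n) / n
        ours = np.mean(
            [on.generate_random_gilbert(n, eps, seed=s).degrees.mean() for s in range(reps)]
        )
        rng = np.random.default_rng(999)
        oracle = []
        while len(oracle) < reps:
            upper = np.triu(rng.random((n, n)) < p, 1)
            A = upper | upper.T
            G = nx.from_numpy_array(A)
            if nx.is_connected(G):
                oracle.append(2 * G.number_of_edges() / n)
        # generous combined bound: ensemble sds are ~0.25
        assert abs(ours - np.mean(oracle)) < 0.3


class TestCatanzaro:
    def test_structural_properties(self):
        for seed in range(5):
            net = on.generate_scale_free_catanzaro(78, 2.2, seed=seed)
            assert net.is_connected()
            assert net.degrees.max() <= int(np.sqrt(78))
            assert net.degrees.min() >= 1
            assert np.array_equal(net.adjacency, net.adjacency.T)
            assert np.all(np.diag(net.adjacency) == 0)

    def test_substantial_degree_one_fraction(self):
        net = on.generate_scale_free_catanzaro(78, 2.2, seed=1)
        assert (net.degrees == 1).mean() > 0.25

    def test_determinism(self):
        a = on.generate_scale_free_catanzaro(78, 2.2, seed=5)
        b = on.generate_scale_free_catanzaro(78, 2.2, seed=5)
        assert np.array_equal(a.adjacency, b.adjacency)

    def test_large_exponent_collapses_to_minimum_degree(self):
        """Steep exponent: mass collapses to degree 1, with only the
        bridging edges needed for connectivity on top."""
        net = on.generate_scale_free_catanzaro(78, 10.0, seed=0)
        assert net.is_connected()
        assert net.degrees.max() <= 3
        assert (net.degrees == 1).sum() >= 78 // 3

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            on.generate_scale_free_catanzaro(5, 2.2)
        with pytest.raises(ValueError):
            on.generate_scale_free_catanzaro(78, 1.5)

    def test_degree_distribution_slope(self):
        """Pooled degree histogram follows k^(−2.2): weighted log-log fit
        of the empirical pmf recovers the exponent."""
        degrees = np.concatenate(
            [on.generate_scale_free_catanzaro(1000, 2.2, seed=s).degrees for s in range(20)]
        )
        ks = np.arange(1, int(np.sqrt(1000)) + 1)
        counts = np.bincount(degrees, minlength=ks[-1] + 1)[1:]
        mask = counts >= 20
        slope = np.polyfit(np.log(ks[mask]), np.log(counts[mask]), 1)[0]
        assert -2.6 < slope < -1.8


class TestClassifyNodes:
    def test_star(self, star_network):
        hubs, peripherals = on.classify_nodes(star_network)
        assert list(hubs) == [0]
        assert sorted(peripherals) == list(range(1, 11))

    def test_regular_graph_empty_hub_set(self):
        net = on.Network(nx.to_numpy_array(nx.cycle_graph(8), dtype=int))
        with pytest.warns(UserWarning):
            hubs, _ = on.classify_nodes(net)
        assert len(hubs) == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_bruteforce_scan(self, seed):
        net = on.generate_scale_free_catanzaro(78, 2.2, seed=seed)
        hubs, peri = on.classify_nodes(net, peripheral_rule="mean_minus_sd")
        k = net.degrees
        expected_hubs = [j for j in range(78) if k[j] > k.mean() + k.std()]
        expected_peri = [j for j in range(78) if k[j] < k.mean() - k.std()]
        assert list(hubs) == expected_hubs
        assert list(peri) == expected_peri
        assert not set(hubs) & set(peri)


class TestDelayMatrix:
    def test_constant(self, star_network):
        dm = on.build_delay_matrix(star_network, "constant", 0.010)
        assert dm.values[0, 1] == pytest.approx(0.010)
        assert dm.values[1, 2] == 0.0  # non-edge
        assert np.allclose(dm.values, dm.values.T)

    def test_distance_mode(self):
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 60.0, 0.0], [0.0, 120.0, 0.0]])
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        net = on.Network(A, coordinates=coords)
        dm = on.build_delay_matrix(net, "distance", 6.0)
        # 60 mm at 6 m/s = 10 ms
        assert dm.values[0, 1] == pytest.approx(0.010)

    def test_zero_distances_zero_delays(self):
        A = np.array([[0, 1], [1, 0]])
        net = on.Network(A, distances=np.zeros((2, 2)))
        dm = on.build_delay_matrix(net, "distance", 6.0)
        assert np.all(dm.values == 0)

    def test_distance_mode_requires_distances(self, star_network):
        with pytest.raises(ValueError):
            on.build_delay_matrix(star_network, "distance", 6.0)

    def test_quarter_cycle_warning(self, star_network):
        with pytest.warns(UserWarning, match="quarter cycle"):
            on.build_delay_matrix(star_network, "constant", 0.030)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            on.build_delay_matrix(star_network, "constant", 0.010)


class TestIO:
    def test_triangle_edge_list(self, tmp_path):
        p = tmp_path / "tri.txt"
        p.write_text("0 1\n1 2\n0 2\n")
        net = on.load_network(p)
        assert list(net.degrees) == [2, 2, 2]

    def test_roundtrip_adjacency(self, tmp_path):
        net = on.generate_scale_free_catanzaro(78, 2.2, seed=2)
        p = tmp_path / "net.csv"
        on.save_network(net, p)
        back = on.load_network(p)
        assert np.array_equal(net.adjacency, back.adjacency)

    def test_roundtrip_labels_and_coordinates(self, tmp_path):
        net = on.make_brainlike_network(30, seed=0)
        labelled = on.Network(
            net.adjacency, coordinates=net.coordinates, labels=[f"n{i}" for i in range(30)]
        )
        p = tmp_path / "net.csv"
        cp = tmp_path / "coords.csv"
        on.save_network(labelled, p, coords_path=cp)
        back = on.load_network(p, coords_path=cp)
        assert back.labels == labelled.labels
        assert np.allclose(back.coordinates, labelled.coordinates)
        assert np.array_equal(back.adjacency, labelled.adjacency)

    def test_asymmetric_adjacency_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        rows = np.zeros((4, 4), dtype=int)
        rows[1, 2] = 1  # (2,1) left 0
        p.write_text("\n".join(",".join(map(str, r)) for r in rows))
        with pytest.raises(ValueError, match="symmetric"):
            on.load_network(p)

    def test_nonzero_diagonal_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        A = np.eye(5, dtype=int)
        p.write_text("\n".join(",".join(map(str, r)) for r in A))
        with pytest.raises(ValueError, match="diagonal"):
            on.load_network(p)
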