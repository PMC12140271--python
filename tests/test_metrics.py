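import numpy as np
import pytest

from pasom import NetworkState, classify_echo_chamber, run_simulation
from pasom.metrics import (EC_ANTI, EC_NONE, EC_PRO, density_table,
                           label_population, select_quantile_run,
                           summarize_batch)


class TestClassify:
    def test_quorum_below_ninety_percent_fails(self):
        assert classify_echo_chamber(0.35, [0.2, 0.3, 0.45, 0.48, 0.55]) == "none"

    def test_exact_ninety_percent_is_inclusive(self):
        nb = [0.3] * 9 + [0.7]
        assert classify_echo_chamber(0.35, nb) == "anti"

    def test_neutral_opinion_never_in_chamber(self):
        assert classify_echo_chamber(0.5, [0.9] * 10) == "none"

    def test_no_neighbours_means_none(self):
        assert classify_echo_chamber(0.1, []) == "none"

    def test_neighbour_at_half_counts_for_neither(self):
        assert classify_echo_chamber(0.8, [0.5] * 10) == "none"

    def test_pro_side_mirror(self):
        nb = [0.7] * 9 + [0.3]
        assert classify_echo_chamber(0.65, nb) == "pro"


class TestLabelPopulation:
    def _net(self, n, edges):
        return NetworkState(n, edges=edges)

    def test_matches_scalar_rule(self, rng):
        n = 40
        net = self._net(n, [])
        net.adj = np.triu(rng.random((n, n)) < 0.2, 1)
        net.adj |= net.adj.T
        opinions = rng.uniform(0.01, 0.99, n)
        labels = label_population(opinions, net)
        names = {EC_NONE: "none", EC_PRO: "pro", EC_ANTI: "anti"}
        for i in range(n):
            nb = opinions[net.neighbors(i)]
            assert names[labels[i]] == classify_echo_chamber(opinions[i], nb)

    def test_mirror_symmetry(self, rng):
        n = 60
        net = self._net(n, [])
        net.adj = np.triu(rng.random((n, n)) < 0.15, 1)
        net.adj |= net.adj.T
        opinions = rng.uniform(0.01, 0.99, n)
        a = label_population(opinions, net)
        b = label_population(1.0 - opinions, net)
        assert (a == EC_PRO).sum() == (b == EC_ANTI).sum()
        assert (a == EC_ANTI).sum() == (b == EC_PRO).sum()
        np.testing.assert_array_equal(a == EC_NONE, b == EC_NONE)

    def test_labels_mutually_exclusive(self, small_config):
        res = run_simulation(small_config, seed=4)
        pro = (res.ec_label == EC_PRO).mean(axis=0)
        anti = (res.ec_label == EC_ANTI).mean(axis=0)
        assert (pro + anti <= 1.0 + 1e-12).all()


class FakeResult:
    def __init__(self, opinions, labels, net):
        self.opinions = opinions
        self.ec_label = labels
        self.initial_network = net
        self.final_network = net


def _fake(final_ops, labels=None, n_rounds=1, net=None):
    n = len(final_ops)
    ops = np.tile(np.asarray(final_ops, dtype=float)[:, None], (1, n_rounds + 1))
    if labels is None:
        labels = np.zeros_like(ops, dtype=np.int8)
    net = net or NetworkState(n)
    return FakeResult(ops, labels, net)


class TestSummaries:
    def test_all_pro_run(self):
        labels = np.full((4, 2), EC_PRO, dtype=np.int8)
        res = _fake([0.9] * 4, labels=labels)
        s = summarize_batch([res])
        assert s["pct_pro_ec"].iloc[-1] == 100.0
        assert s["pct_total_ec"].iloc[-1] == 100.0
        assert s["pct_anti_ec"].iloc[-1] == 0.0

    def test_batch_mean_is_arithmetic(self):
        a = _fake([0.9] * 50, labels=np.full((50, 2), EC_PRO, dtype=np.int8))
        lab = np.full((50, 2), EC_PRO, dtype=np.int8)
        lab[49, :] = EC_NONE
        b = _fake([0.9] * 50, labels=lab)
        s = summarize_batch([a, b])
        assert s["pct_total_ec"].iloc[-1] == pytest.approx(99.0)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            summarize_batch([])


class TestDensity:
    def test_single_clique_single_cell(self):
        n = 5
        net = NetworkState(n, edges=[(i, j) for i in range(n)
                                     for j in range(i + 1, n)])
        res = _fake([0.9] * n, net=net)
        d = density_table(res, -1, bins=10)
        assert d.grid.sum() == pytest.approx(1.0, abs=1e-9)
        assert d.grid[9, 9] == pytest.approx(1.0)
        assert d.n_isolated == 0

    def test_two_cliques_two_corner_cells(self):
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        edges += [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
        net = NetworkState(8, edges=edges)
        res = _fake([0.05] * 4 + [0.95] * 4, net=net)
        d = density_table(res, -1, bins=10)
        assert d.grid[0, 0] == pytest.approx(0.5)
        assert d.grid[9, 9] == pytest.approx(0.5)

    def test_isolated_agents_counted_separately(self):
        net = NetworkState(3, edges=[(0, 1)])
        res = _fake([0.2, 0.3, 0.8], net=net)
        d = density_table(res, -1)
        assert d.n_isolated == 1
        assert d.grid.sum() == pytest.approx(1.0, abs=1e-9)

    def test_intermediate_round_unavailable(self):
        res = _fake([0.5, 0.5], n_rounds=3)
        with pytest.raises(ValueError):
            density_table(res, 1)


class TestSelectQuantile:
    def test_rank_selects_sorted_position(self):
        runs = [_fake([m] * 3) for m in (0.5, 0.2, 0.9)]
        assert select_quantile_run(runs, rank=2) is runs[0]
        assert select_quantile_run(runs, rank=1) is runs[1]   # most anti
        assert select_quantile_run(runs, rank=3) is runs[2]   # most pro

    def test_rank_out_of_range(self):
        with pytest.raises(ValueError):
            select_quantile_run([_fake([0.5])], rank=2)
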