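"""Co-expression networks: correlation, degree law, threshold, hub comparison."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import diffcoex as dc
from diffcoex import network

from test_expression import make_design, make_matrix


def corr_from_array(arr):
    arr = np.asarray(arr, dtype=float)
    genes = pd.Index([f"g{i}" for i in range(arr.shape[0])])
    return network.CorrelationMatrix(genes, arr)


class TestPairwiseCorrelation:
    def test_known_pair_and_self_and_anticorrelation(self):
        x = np.array([1, 2, 3, 4], dtype=float)
        y = np.array([2, 4, 6, 9], dtype=float)
        m = make_matrix(np.vstack([x, y, -x]), scale="log2ratio")
        design = dc.SampleDesign({f"s{j}": "control" for j in range(4)})
        corr = network.pairwise_correlation(m, "control", design)
        assert corr.values[0, 0] == pytest.approx(1.0)
        assert corr.values[0, 1] == pytest.approx(0.9943767126843688, abs=1e-12)
        assert corr.values[0, 2] == pytest.approx(-1.0)

    def test_zero_variance_gene_gets_zero_and_flag(self):
        m = make_matrix([[1, 2, 3], [5, 5, 5]], scale="log2ratio")
        design = dc.SampleDesign({f"s{j}": "control" for j in range(3)})
        corr = network.pairwise_correlation(m, "control", design)
        assert corr.values[0, 1] == 0.0
        assert corr.zero_variance_genes == {"g1"}

    def test_rejects_fewer_than_three_samples(self):
        m = make_matrix([[1, 2]], scale="log2ratio")
        with pytest.raises(ValueError):
            network.pairwise_correlation(
                m, "control", dc.SampleDesign({"s0": "control", "s1": "control"})
            )


class TestBuildNetwork:
    def test_inclusive_threshold_and_signed_r(self):
        corr = corr_from_array([[1, 0.9, -0.95], [0.9, 1, 0.2], [-0.95, 0.2, 1]])
        net = network.build_network(corr, 0.9)
        assert net.has_edge("g0", "g1")          # r exactly at threshold
        assert not net.has_edge("g0", "g2")      # strong negative r: no edge
        assert network.build_network(corr, 0.9, absolute_r=True).has_edge("g0", "g2")

    def test_raising_threshold_never_adds_edges(self, rng):
        z = rng.standard_normal((30, 8))
        corr = corr_from_array(np.corrcoef(z))
        lo = network.build_network(corr, 0.3)
        hi = network.build_network(corr, 0.6)
        assert set(hi.edges) <= set(lo.edges)

    def test_matches_brute_force_all_pairs(self, rng):
        z = rng.standard_normal((200, 6))
        corr = corr_from_array(np.corrcoef(z))
        net = network.build_network(corr, 0.5)
        expected = {
            frozenset((f"g{i}", f"g{j}"))
            for i in range(200)
            for j in range(i + 1, 200)
            if corr.values[i, j] >= 0.5
        }
        got = {frozenset(e) for e in net.edges}
        assert got == expected


class TestDegreeDistribution:
    @pytest.mark.parametrize(
        "edges,n_nodes,expected",
        [
            ([(0, 1), (1, 2), (0, 2)], 3, {2: 1.0}),              # triangle
            ([], 4, {0: 1.0}),                                    # edgeless
            ([(0, 1), (0, 2), (0, 3)], 4, {1: 0.75, 3: 0.25}),    # star
        ],
    )
    def test_enumerated_graphs(self, edges, n_nodes, expected):
        g = nx.Graph()
        g.add_nodes_from(range(n_nodes))
        g.add_edges_from(edges)
        dist = network.degree_distribution(g)
        got = dict(zip(dist["k"], dist["p_k"]))
        assert got == expected
        assert dist["count"].sum() == n_nodes


class TestScaleFreeFit:
    def test_exact_power_law_r2_one_slope_minus_two(self):
        k = np.arange(1, 11)
        p = k**-2.0
        dist = pd.DataFrame({"k": k, "count": 1, "p_k": p / p.sum()})
        fit = network.scale_free_fit(dist)
        assert fit.valid
        assert fit.fit_r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(-2.0, abs=1e-9)

    def test_uniform_distribution_is_degenerate(self):
        dist = pd.DataFrame({"k": np.arange(1, 11), "count": 1, "p_k": 0.1})
        fit = network.scale_free_fit(dist)
        assert not fit.valid and fit.fit_r2 == 0.0

    def test_matches_independent_correlation_routine(self, rng):
        k = np.arange(1, 20)
        p = k**-1.7 * np.exp(rng.normal(0, 0.2, size=len(k)))
        p = p / p.sum()
        dist = pd.DataFrame({"k": k, "count": 1, "p_k": p})
        fit = network.scale_free_fit(dist)
        r_oracle = stats.pearsonr(np.log10(k), np.log10(p)).statistic
        assert fit.fit_r2 == pytest.approx(r_oracle**2, abs=1e-12)

    def test_fewer_than_three_points_invalid(self):
        dist = pd.DataFrame({"k": [0, 1, 2], "count": 1, "p_k": [0.5, 0.25, 0.25]})
        assert not network.scale_free_fit(dist).valid


class TestSelectThreshold:
    def _patch_fits(self, monkeypatch, fits):
        it = iter(fits)
        monkeypatch.setattr(
            network,
            "scale_free_fit",
            lambda dist: network.ScaleFreeFit(-2.0, 0.0, next(it), 5, True),
        )

    def test_smallest_passing_grid_value_selected(self, monkeypatch, rng):
        corr = corr_from_array(np.corrcoef(rng.standard_normal((20, 6))))
        # fit R² rises along the grid; only 0.90 passes the 0.80 criterion
        self._patch_fits(monkeypatch, [0.60, 0.70, 0.78, 0.85])
        selected, report = network.select_threshold(corr)
        assert selected == 0.90
        assert list(report["fit_r2"]) == [0.60, 0.70, 0.78, 0.85]

    def test_all_pass_takes_smallest(self, monkeypatch, rng):
        corr = corr_from_array(np.corrcoef(rng.standard_normal((20, 6))))
        self._patch_fits(monkeypatch, [0.9, 0.9, 0.9, 0.9])
        assert network.select_threshold(corr)[0] == 0.75

    def test_none_pass_raises_with_report(self, monkeypatch, rng):
        corr = corr_from_array(np.corrcoef(rng.standard_normal((20, 6))))
        self._patch_fits(monkeypatch, [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError, match="scale-free criterion"):
            network.select_threshold(corr)

    def test_unsorted_grid_rejected(self, rng):
        corr = corr_from_array(np.corrcoef(rng.standard_normal((5, 6))))
        with pytest.raises(ValueError):
            network.select_threshold(corr, grid=(0.9, 0.8))


class TestCompareNetworks:
    def test_identical_networks_full_overlap(self):
        g = nx.Graph([(f"g{i}", f"g{i+1}") for i in range(5)])
        table, overlaps = network.compare_networks(g, g, (1, 3, 6))
        assert overlaps == {1: 1, 3: 3, 6: 6}
        assert (table["k_control"] == table["k_knockdown"]).all()
        assert (table["status"] == "retained").all()

    def test_disjoint_stars_have_no_top_hub_overlap(self):
        ctl = nx.star_graph(["h1", "a", "b", "c"])
        kd = nx.star_graph(["h2", "a", "b", "c"])
        table, overlaps = network.compare_networks(ctl, kd, (1,))
        assert overlaps[1] == 0
        assert table.loc["h1", "rank_control"] == 1
        assert table.loc["h2", "rank_knockdown"] == 1
        assert table.loc["h1", "status"] == "lost"    # no edges left in kd
        assert table.loc["h2", "status"] == "gained"
        assert table.loc["a", "status"] == "retained"

    def test_handshake_lemma(self, rng):
        g1 = nx.gnp_random_graph(40, 0.1, seed=1)
        g2 = nx.gnp_random_graph(40, 0.2, seed=2)
        table, _ = network.compare_networks(g1, g2, (10,))
        assert table["k_control"].sum() == 2 * g1.number_of_edges()
        assert table["k_knockdown"].sum() == 2 * g2.number_of_edges()


class TestPlantedStructureRecovery:
    def test_planted_hub_ranks_top_five(self, hub_scenario):
        _, ratios, design, truth = hub_scenario
        corr = network.pairwise_correlation(ratios, "control", design)
        net = network.build_network(corr, 0.9)
        ranking = network.hub_ranking(net)
        hub = truth.hub_genes[0]
        assert ranking.index(hub) < 5

    def test_control_only_module_loses_edges_in_knockdown(self, module_scenario):
        _, ratios, design, truth = module_scenario
        mod = [g for g, m in truth.module_membership.items() if m == "ctl_specific"]
        nets = {}
        for cond in ("control", "knockdown"):
            corr = network.pairwise_correlation(ratios, cond, design)
            nets[cond] = network.build_network(corr, 0.75)
        def within(net):
            return sum(
                1
                for i, a in enumerate(mod)
                for b in mod[i + 1:]
                if net.has_edge(a, b)
            )
        n_ctl, n_kd = within(nets["control"]), within(nets["knockdown"])
        assert n_ctl >= 20  # module is dense in its active condition
        assert n_kd < 0.10 * n_ctl
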