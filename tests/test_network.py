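import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from benthonet.io import CommunityMatrix
from benthonet.network import (
    build_network,
    network_summary,
    spearman_matrix,
    grouped_summaries,
)
from benthonet.synthetic import CommunitySpec, generate


from oracles import brute_force_summary, midranks, pearson


# ---------------------------------------------------------------- spearman

class TestSpearmanMatrix:
    def _corr(self, cols):
        df = pd.DataFrame(cols, dtype=float)
        df.index = [f"s{i}" for i in range(len(df))]
        return spearman_matrix(CommunityMatrix(df))

    def test_monotone_pair_is_plus_one(self):
        c = self._corr({"x": [1, 2, 3], "y": [10, 20, 30]})
        assert c.rho[0, 1] == pytest.approx(1.0)
        assert c.p[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_reversed_pair_is_minus_one(self):
        c = self._corr({"x": [1, 2, 3], "y": [3, 2, 1]})
        assert c.rho[0, 1] == pytest.approx(-1.0)

    def test_tied_vector_matches_rank_pearson_oracle(self):
        c = self._corr({"x": [1, 2, 2, 4], "y": [1, 3, 2, 4]})
        expected = pearson(midranks([1, 2, 2, 4]), midranks([1, 3, 2, 4]))
        assert c.rho[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_oracle_equivalence_on_random_tied_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(4, 12)
            x = rng.integers(0, 5, n).astype(float)  # heavy ties
            y = rng.integers(0, 5, n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            c = self._corr({"x": x, "y": y})
            assert c.rho[0, 1] == pytest.approx(
                pearson(midranks(x), midranks(y)), abs=1e-12
            )

    def test_p_values_match_t_approximation(self):
        rng = np.random.default_rng(7)
        x, y = rng.lognormal(size=10), rng.lognormal(size=10)
        c = self._corr({"x": x, "y": y})
        rho = c.rho[0, 1]
        t = rho * math.sqrt((10 - 2) / (1 - rho**2))
        assert c.p[0, 1] == pytest.approx(2 * stats.t.sf(abs(t), df=8), rel=1e-10)

    def test_zero_variance_taxon_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            c = self._corr({"x": [1, 2, 3], "flat": [5, 5, 5]})
        assert np.isnan(c.rho[0, 1])

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="at least 3"):
            spearman_matrix(CommunityMatrix(df))


# ---------------------------------------------------------------- edges

class TestBuildNetwork:
    def _toy_corr(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "a": [1, 2, 3, 4, 5, 6, 7, 8],
                "b": [2, 3, 4, 5, 6, 7, 8, 9],     # rho=1 with a
                "c": [8, 7, 6, 5, 4, 3, 2, 1],     # rho=-1 with a, b
                "d": rng.permutation(8).astype(float),
            },
            index=[f"s{i}" for i in range(8)],
            dtype=float,
        )
        return spearman_matrix(CommunityMatrix(df))

    def test_all_p_one_gives_edgeless_graph(self):
        from benthonet.network import CorrelationMatrix

        k = 4
        c = CorrelationMatrix(
            taxon_ids=tuple("abcd"),
            rho=np.full((k, k), 0.1) + np.eye(k) * 0.9,
            p=np.ones((k, k)) - np.eye(k),
            n_samples=10,
        )
        net = build_network(c, alpha=0.05)
        assert len(net.nodes) == 4 and len(net.edges) == 0

    def test_alpha_one_gives_complete_graph(self):
        c = self._toy_corr()
        net = build_network(c, alpha=1.0)
        assert len(net.edges) == 6

    def test_rule_selects_exactly_the_significant_pairs(self):
        c = self._toy_corr()
        net = build_network(c, alpha=0.05)
        expected = {
            frozenset((c.taxon_ids[i], c.taxon_ids[j]))
            for i in range(4)
            for j in range(i + 1, 4)
            if c.p[i, j] < 0.05
        }
        assert {frozenset(e) for e in net.edges} == expected
        assert frozenset(("a", "b")) in expected  # perfectly correlated pair

    def test_positive_only_drops_negative_edges(self):
        c = self._toy_corr()
        both = build_network(c, alpha=0.05, signed="both")
        pos = build_network(c, alpha=0.05, signed="positive_only")
        dropped = {frozenset(e) for e in both.edges} - {frozenset(e) for e in pos.edges}
        assert frozenset(("a", "c")) in dropped


# ---------------------------------------------------------------- summary

class TestNetworkSummary:
    def test_path_graph_p3(self):
        g = nx.path_graph(3)
        s = network_summary(g)
        assert s.n_edges == 2
        assert s.avg_degree == pytest.approx(4 / 3)
        assert s.avg_path_length == pytest.approx(4 / 3)
        assert s.transitivity == 0.0
        assert s.edge_density == pytest.approx(2 / 3)

    def test_complete_graph_k4(self):
        s = network_summary(nx.complete_graph(4))
        assert s.avg_path_length == pytest.approx(1.0)
        assert s.transitivity == pytest.approx(1.0)
        assert s.edge_density == pytest.approx(1.0)

    def test_oracle_equivalence_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for trial in range(30):
            n = int(rng.integers(2, 13))
            p = float(rng.uniform(0.1, 0.9))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
            got = network_summary(g).as_dict()
            want = brute_force_summary(g)
            for key, w in want.items():
                v = got[key]
                if isinstance(w, float) and math.isnan(w):
                    assert math.isnan(v), key
                else:
                    assert v == pytest.approx(w, abs=1e-12), (key, trial)

    def test_invariant_to_relabeling(self):
        g = nx.gnp_random_graph(10, 0.4, seed=5)
        h = nx.relabel_nodes(g, {i: f"taxon_{i}" for i in g.nodes})
        assert network_summary(g) == network_summary(h)

    def test_adding_edge_monotonicity(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            g = nx.gnp_random_graph(8, 0.3, seed=int(rng.integers(1 << 30)))
            non_edges = list(nx.non_edges(g))
            if not non_edges:
                continue
            before = network_summary(g)
            connected_before = nx.number_connected_components(g) == 1
            g.add_edge(*non_edges[0])
            after = network_summary(g)
            assert after.edge_density >= before.edge_density
            assert after.n_edges == before.n_edges + 1
            if connected_before:
                # with the pair set unchanged, a shortcut can only help
                assert after.avg_path_length <= before.avg_path_length + 1e-12


def test_expected_edges_increase_with_gradient_strength():
    def mean_edges(gs):
        out = []
        for seed in range(20):
            spec = CommunitySpec(
                seed=seed, sites_per_cluster=(8, 8, 7), n_core_taxa=20,
                n_indicator_taxa_per_cluster=0, n_rare_taxa=0,
                gradient_strength=gs,
            )
            m = generate(spec).matrix
            net = build_network(spearman_matrix(m))
            out.append(len(net.edges))
        return np.mean(out)

    e0, e1, e2 = (mean_edges(g) for g in (0.0, 1.0, 2.0))
    assert e0 < e1 < e2
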