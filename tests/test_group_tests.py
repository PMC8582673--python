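import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from benthonet.group_tests import (
    compare_variables,
    dunn_posthoc,
    kruskal_wallis,
    mrpp,
)


from oracles import mrpp_delta as mrpp_delta_oracle, mrpp_exact_p


class TestMrpp:
    def test_duplicated_points_give_A_equal_one(self):
        X = np.array([[0.0, 0.0]] * 3 + [[5.0, 5.0]] * 3)
        labels = ["a"] * 3 + ["b"] * 3
        res = mrpp(X, labels, n_perm=999, seed=0)
        assert res.delta_obs == pytest.approx(0.0)
        assert res.A == pytest.approx(1.0)
        # 2 * 3! * 3! of the 6! label orderings reproduce the split exactly
        assert res.p == pytest.approx(0.1, abs=0.04)

    def test_null_labels_give_A_near_zero(self):
        rng = np.random.default_rng(0)
        As = []
        for seed in range(50):
            X = rng.normal(size=(40, 5))
            labels = np.repeat([0, 1, 2, 3], 10)
            res = mrpp(X, labels, n_perm=199, seed=seed)
            As.append(res.A)
        assert max(abs(a) for a in As) < 0.1

    def test_monte_carlo_p_matches_exact_enumeration(self):
        rng = np.random.default_rng(5)
        for trial in range(3):
            X = rng.normal(size=(6, 3))
            labels = np.array([0, 0, 0, 1, 1, 1])
            exact = mrpp_exact_p(X, labels)
            res = mrpp(X, labels, n_perm=999, seed=trial)
            se = math.sqrt(exact * (1 - exact) / 999) + 2 / 999
            assert abs(res.p - exact) < 4 * se + 1e-9

    def test_delta_matches_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 4))
        labels = np.repeat([0, 1, 2], 4)
        res = mrpp(X, labels, n_perm=9, seed=0)
        assert res.delta_obs == pytest.approx(mrpp_delta_oracle(X, labels))
        assert res.A == pytest.approx(1 - res.delta_obs / res.expected_delta)

    def test_bray_curtis_distance_supported(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(10, size=(8, 5)).astype(float)
        labels = [0] * 4 + [1] * 4
        res = mrpp(X, labels, distance="bray_curtis", n_perm=99, seed=0)
        D = squareform(pdist(X, "braycurtis"))
        within0 = D[:4, :4][np.triu_indices(4, 1)].mean()
        within1 = D[4:, 4:][np.triu_indices(4, 1)].mean()
        assert res.delta_obs == pytest.approx(0.5 * within0 + 0.5 * within1)

    def test_singleton_group_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError, match="singleton"):
            mrpp(X, ["a", "a", "b"], n_perm=9)

    def test_null_p_approximately_uniform(self):
        rng = np.random.default_rng(1)
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            X = rng.normal(size=(30, 3))
            labels = np.repeat([0, 1, 2], 10)
            res = mrpp(X, labels, n_perm=99, seed=rep)
            rejections += res.p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09


# ---------------------------------------------------------------- KW

class TestKruskalWallis:
    def test_hand_computed_three_group_case(self):
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        H, df, p = kruskal_wallis(values, labels)
        assert H == pytest.approx(7.2)
        assert df == 2

    def test_invariant_to_group_relabeling(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=15)
        lab = np.repeat([0, 1, 2], 5)
        H1, _, _ = kruskal_wallis(v, lab)
        H2, _, _ = kruskal_wallis(v, 2 - lab)
        assert H1 == pytest.approx(H2)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=12)
        lab = np.repeat([0, 1, 2], 4)
        H1, _, _ = kruskal_wallis(v, lab)
        H2, _, _ = kruskal_wallis(np.exp(v), lab)
        assert H1 == pytest.approx(H2)

    def test_all_tied_values_warn(self):
        with pytest.warns(UserWarning, match="identical"):
            H, df, p = kruskal_wallis([2.0] * 6, [0, 0, 0, 1, 1, 1])
        assert H == 0.0 and p == 1.0

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(6)
        alpha = 0.05
        rejections = 0
        n_rep = 1000
        lab = np.repeat([0, 1, 2], 10)
        for _ in range(n_rep):
            v = rng.normal(size=30)
            _, _, p = kruskal_wallis(v, lab)
            rejections += p < alpha
        assert 0.035 <= rejections / n_rep <= 0.065


# ---------------------------------------------------------------- Dunn

class TestDunnPosthoc:
    def test_identical_groups_share_a_letter(self):
        v = [1, 2, 3, 1, 2, 3]
        lab = ["a", "a", "a", "b", "b", "b"]
        res = dunn_posthoc(v, lab)
        assert res.pairwise["z"].iloc[0] == pytest.approx(0.0)
        assert set(res.letters["a"]) & set(res.letters["b"])

    def test_shifted_group_gets_unique_letter(self):
        rng = np.random.default_rng(7)
        v = np.concatenate(
            [rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(100, 1, 10)]
        )
        lab = np.repeat(["a", "b", "c"], 10)
        res = dunn_posthoc(v, lab)
        assert not (set(res.letters["c"]) & set(res.letters["a"]))
        assert not (set(res.letters["c"]) & set(res.letters["b"]))
        assert set(res.letters["a"]) & set(res.letters["b"])

    def test_pairwise_p_symmetric_and_z_antisymmetric(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=15)
        lab = np.repeat(["a", "b", "c"], 5)
        res = dunn_posthoc(v, lab)
        # the table stores each unordered pair once; reversing the group
        # order flips z and keeps p
        res2 = dunn_posthoc(v[::-1], lab[::-1])
        got = dict(zip(zip(res.pairwise.group_i, res.pairwise.group_j),
                       res.pairwise.p))
        got2 = dict(zip(zip(res2.pairwise.group_i, res2.pairwise.group_j),
                        res2.pairwise.p))
        for pair, p in got.items():
            assert got2[pair] == pytest.approx(p)

    @pytest.mark.parametrize("adjust", ["none", "holm", "bonferroni"])
    def test_letters_consistent_with_significance_graph(self, adjust):
        rng = np.random.default_rng(10)
        for _ in range(10):
            v = np.concatenate(
                [rng.normal(rng.uniform(0, 4), 1, 8) for _ in range(4)]
            )
            lab = np.repeat(list("abcd"), 8)
            res = dunn_posthoc(v, lab, alpha=0.05, adjust=adjust)
            padj = dict(zip(zip(res.pairwise.group_i, res.pairwise.group_j),
                            res.pairwise.p_adj))
            for (a, b), p in padj.items():
                share = bool(set(res.letters[a]) & set(res.letters[b]))
                assert share == (p >= 0.05), (a, b, p, res.letters)

    def test_z_statistic_formula_no_ties(self):
        # hand check against the textbook formula on untied data
        v = np.array([1, 2, 3, 4, 5, 6, 7, 8], dtype=float)
        lab = np.array(["a"] * 4 + ["b"] * 4)
        res = dunn_posthoc(v, lab)
        # mean ranks 2.5 and 6.5; se = sqrt((8*9/12)*(1/4+1/4)) = sqrt(3)
        assert res.pairwise["z"].iloc[0] == pytest.approx(-4 / math.sqrt(3))


def test_compare_variables_layout(tiny_matrix):
    from benthonet.metrics import indices_table

    idx = indices_table(tiny_matrix)
    labels = pd.Series([1, 1, 2, 2], index=tiny_matrix.sample_ids)
    out = compare_variables(idx[["richness", "shannon"]], labels)
    assert set(out["variable"]) == {"richness", "shannon"}
    assert set(out.columns) >= {"variable", "cluster", "mean", "sd", "letter",
                                "kw_H", "kw_p"}
    assert len(out) == 4
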