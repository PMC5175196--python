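import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poma.outliers import (
    outlier_pvalue,
    outlier_pvalues,
    select_significant,
    signed_rank_p,
)


def enumeration_p(d):
    """Oracle: exact tail probability over all 2^n sign assignments.

    Ranks the absolute differences (mid-ranks for ties) and enumerates
    every sign assignment explicitly; independent of the DP used by the
    implementation.
    """
    d = np.asarray([x for x in d if x != 0], dtype=float)
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= observed - 1e-12:
            count += 1
    return count / 2**n


class TestSignedRank:
    def test_all_positive_four(self):
        res = signed_rank_p([4, 3, 2, 1])
        assert res.statistic == 10
        assert res.p_value == pytest.approx(0.0625)
        assert res.method == "exact"

    def test_single_positive_difference(self):
        res = signed_rank_p([3])  # 1 of the 2 sign assignments reaches W+ >= 1
        assert res.statistic == 1
        assert res.p_value == pytest.approx(0.5)

    def test_all_zero_degenerate(self):
        res = signed_rank_p([0, 0, 0])
        assert res.p_value == 1.0
        assert res.n_eff == 0
        assert res.method == "exact"

    def test_zeros_dropped_before_ranking(self):
        assert signed_rank_p([4, 3, 2, 1, 0, 0]).p_value == signed_rank_p(
            [4, 3, 2, 1]
        ).p_value

    @pytest.mark.parametrize("n", range(1, 13))
    def test_exact_path_equals_enumeration_tie_free(self, n):
        rng = np.random.default_rng(n)
        for _ in range(3):
            mags = rng.permutation(np.arange(1, n + 1)) + rng.uniform(0, 0.4, n)
            signs = rng.choice([-1.0, 1.0], size=n)
            d = mags * signs
            res = signed_rank_p(d)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(enumeration_p(d), abs=1e-12)

    def test_tied_inputs_use_midrank_normal_approximation(self):
        res = signed_rank_p([2.0, 2.0, -1.0, 3.0])
        assert res.method == "normal_approx"
        ref = stats.wilcoxon(
            [2.0, 2.0, -1.0, 3.0], alternative="greater", correction=True, method="approx"
        )
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_normal_approx_close_to_exact_at_n25(self):
        rng = np.random.default_rng(12345)
        for _ in range(10):
            d = rng.normal(size=25) + 0.3
            exact = signed_rank_p(d)
            assert exact.method == "exact"
            mu = 25 * 26 / 4
            sigma = np.sqrt(25 * 26 * 51 / 24)
            approx = stats.norm.sf((exact.statistic - 0.5 - mu) / sigma)
            assert abs(exact.p_value - approx) <= 0.01

    def test_matches_scipy_exact_on_tie_free_vectors(self):
        rng = np.random.default_rng(99)
        for n in (5, 10, 20):
            d = rng.permutation(np.arange(1, n + 1)) * rng.choice([-1, 1], n)
            ref = stats.wilcoxon(d, alternative="greater", method="exact")
            assert signed_rank_p(d).p_value == pytest.approx(ref.pvalue, abs=1e-12)


class TestOutlierPvalue:
    def test_clear_outlier_vs_background(self):
        scores = pd.Series({"mX": 10.0, "a": 1, "b": 2, "c": 3, "d": 4, "e": 5})
        res = outlier_pvalue(scores, "mX")
        assert res.p_value == pytest.approx(0.03125)  # 1 of 2^5 assignments

    def test_constant_background_gives_p_one(self):
        scores = pd.Series({m: 2.0 for m in "abcde"})
        assert all(outlier_pvalues(scores) == 1.0)

    def test_equal_scores_equal_pvalues(self):
        scores = pd.Series({"a": 1.0, "b": 3.0, "c": 3.0, "d": 0.0, "e": 2.0})
        p = outlier_pvalues(scores)
        assert p["b"] == p["c"]

    def test_monotone_in_score(self):
        rng = np.random.default_rng(4)
        scores = pd.Series(rng.integers(0, 6, size=30).astype(float),
                           index=[f"m{i}" for i in range(30)])
        p = outlier_pvalues(scores)
        df = pd.DataFrame({"s": scores, "p": p}).sort_values("s")
        assert (df["p"].diff().dropna() <= 1e-12).all()

    def test_unknown_focal_is_lookup_error(self):
        with pytest.raises(KeyError):
            outlier_pvalue(pd.Series({"a": 1.0, "b": 2.0}), "zzz")


class TestSelectSignificant:
    def make_table(self):
        return pd.DataFrame(
            {"nod": [5.0, 3.0, 1.0], "nod_p": [0.01, 0.05, 0.2]},
            index=["a", "b", "c"],
        )

    def test_strict_alpha(self):
        assert select_significant(self.make_table(), "nod", 0.05) == ["a"]

    def test_alpha_one_keeps_all_in_score_order(self):
        assert select_significant(self.make_table(), "nod", 1.01) == ["a", "b", "c"]

    def test_empty_survivors_is_not_an_error(self):
        assert select_significant(self.make_table(), "nod", 1e-9) == []

    def test_missing_pvalues_is_state_error(self):
        t = self.make_table().drop(columns="nod_p")
        with pytest.raises(ValueError, match="not computed"):
            select_significant(t, "nod")
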