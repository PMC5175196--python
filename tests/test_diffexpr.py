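import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from poma import diffexpr
from poma.io import ValidationError
from poma.simulate import simulate_expression

from conftest import two_group_matrix


class TestCollapseProbes:
    def test_multi_probe_gene_averages(self):
        m = two_group_matrix({"p1": [2, 2, 2, 2], "p2": [4, 4, 4, 4]}, n_case=2)
        out = diffexpr.collapse_probes(m, {"p1": "G", "p2": "G"})
        assert out.gene_ids == ["G"]
        assert (out.values.loc["G"] == 3.0).all()

    def test_single_probe_identity(self):
        m = two_group_matrix({"p1": [1, 2, 3, 4]}, n_case=2)
        out = diffexpr.collapse_probes(m, {"p1": "G"})
        np.testing.assert_array_equal(out.values.loc["G"], m.values.loc["p1"])

    def test_all_unmapped_is_error(self):
        m = two_group_matrix({"p1": [1, 2, 3, 4]}, n_case=2)
        with pytest.raises(ValidationError):
            diffexpr.collapse_probes(m, {"other": "G"})


class TestGeneTTest:
    def test_identical_groups_give_p_one(self):
        assert diffexpr.gene_t_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_separated_groups_match_t_distribution_tail(self):
        # t = 7.746 on 4 df; expected two-sided tail computed independently
        # from the regularized incomplete beta I_{df/(df+t^2)}(df/2, 1/2)
        p = diffexpr.gene_t_test([10, 12, 14], [1, 2, 3])
        assert p == pytest.approx(0.001496481055900334, rel=1e-9)

    def test_zero_variance_conventions(self):
        assert diffexpr.gene_t_test([5, 5], [5, 5]) == 1.0
        assert diffexpr.gene_t_test([6, 6], [5, 5]) == 0.0


class TestFoldChange:
    @pytest.mark.parametrize(
        "case,control,expected",
        [([8, 8], [2, 2], 4.0), ([1, 1], [4, 4], 0.25), ([3, 3], [3, 3], 1.0)],
    )
    def test_ratio_of_group_means(self, case, control, expected):
        assert diffexpr.fold_change(case, control) == pytest.approx(expected)

    def test_nonpositive_control_mean_is_error(self):
        with pytest.raises(ValidationError):
            diffexpr.fold_change([1, 2], [0, 0])


class TestSelectDEGenes:
    def make_matrix(self):
        rng = np.random.default_rng(0)
        jitter = lambda base, fac, n: list(base * fac * (1 + 0.01 * rng.standard_normal(n)))
        rows = {
            "UP": jitter(10, 3.0, 10) + jitter(10, 1.0, 10),
            "WEAK": jitter(10, 1.5, 10) + jitter(10, 1.0, 10),
            "FLAT": jitter(10, 1.0, 10) + jitter(10, 1.0, 10),
            "DOWN": jitter(10, 0.25, 10) + jitter(10, 1.0, 10),
        }
        return two_group_matrix(rows, n_case=10)

    def test_cutoffs_applied_with_both_arms(self):
        res = {r.gene_id: r for r in diffexpr.select_de_genes(self.make_matrix())}
        assert res["UP"].is_de and res["UP"].fold_change > 2
        assert res["DOWN"].is_de and res["DOWN"].fold_change < 0.5
        assert not res["WEAK"].is_de  # significant but fails the FC arm
        assert res["WEAK"].p_value < 0.05
        assert not res["FLAT"].is_de

    def test_row_order_independent(self):
        m = self.make_matrix()
        shuffled = two_group_matrix(
            {g: list(m.values.loc[g]) for g in reversed(m.gene_ids)}, n_case=10
        )
        a = {r.gene_id: r.is_de for r in diffexpr.select_de_genes(m)}
        b = {r.gene_id: r.is_de for r in diffexpr.select_de_genes(shuffled)}
        assert a == b

    def test_planted_de_recovery_from_simulation(self):
        matrix, manifest = simulate_expression(
            n_genes=1000, n_case=20, n_control=20, n_de=100, fc=4.0, cv=0.2, seed=1
        )
        planted = set(manifest["planted_de"])
        flagged = {r.gene_id for r in diffexpr.select_de_genes(matrix) if r.is_de}
        assert len(flagged & planted) >= 95
        false_pos = flagged - planted
        assert len(false_pos) <= 0.05 * 900


class TestInvariances:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_group_swap_inverts_fc_and_keeps_p(self, seed):
        rng = np.random.default_rng(seed)
        case = rng.lognormal(size=5)
        control = rng.lognormal(size=5)
        fc = diffexpr.fold_change(case, control)
        assert diffexpr.fold_change(control, case) == pytest.approx(1.0 / fc)
        p1 = diffexpr.gene_t_test(case, control)
        p2 = diffexpr.gene_t_test(control, case)
        assert p1 == pytest.approx(p2, rel=1e-12)

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_positive_scaling_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        case = rng.lognormal(size=4) + 0.1
        control = rng.lognormal(size=4) + 0.1
        assert diffexpr.gene_t_test(case * scale, control * scale) == pytest.approx(
            diffexpr.gene_t_test(case, control), rel=1e-9
        )
        assert diffexpr.fold_change(case * scale, control * scale) == pytest.approx(
            diffexpr.fold_change(case, control), rel=1e-9
        )
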