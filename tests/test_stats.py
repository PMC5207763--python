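import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom, rankdata

from genecycle.stats import (
    bootstrap_se_median,
    fisher_exact_2x2,
    fit_local_loss_model,
    fold_enrichment,
    integration_ratio,
    ordering_pvalue,
    wilcoxon_rank_sum,
)
from genecycle.synthetic_data import simulate_logistic


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = hypergeom.pmf(k, n, col1, row1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


class TestFisher:
    def test_balanced_table_is_null(self):
        assert fisher_exact_2x2(1, 1, 1, 1).p_value == pytest.approx(1.0)

    def test_diagonal_table(self):
        assert fisher_exact_2x2(3, 0, 0, 3).p_value == pytest.approx(0.1)

    @given(
        st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(1, 15)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        res = fisher_exact_2x2(a, b, c, d)
        if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
            assert res.p_value == 1.0
        else:
            assert res.p_value == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-8)

    def test_odds_ratio(self):
        assert fisher_exact_2x2(6, 2, 3, 4).effect == pytest.approx(4.0)


class TestFoldEnrichment:
    def test_identity(self):
        assert fold_enrichment(7, 100, 7, 100) == 1.0

    def test_forced_arithmetic(self):
        assert fold_enrichment(10, 100, 5, 100) == pytest.approx(2.0)

    def test_empty_reference_is_infinite(self):
        assert math.isinf(fold_enrichment(3, 10, 0, 10))


def rank_sum_oracle(x, y):
    """Exact two-sided Mann-Whitney p via all C(n, nx) splits (midranks)."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    nx, n = len(x), len(pooled)
    centre = nx * (n - nx) / 2
    offset = nx * (nx + 1) / 2
    u_obs = ranks[:nx].sum() - offset
    hits = total = 0
    for idx in combinations(range(n), nx):
        total += 1
        if abs(ranks[list(idx)].sum() - offset - centre) >= abs(u_obs - centre) - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_extreme_small_sample(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4]).p_value == pytest.approx(1 / 3)

    def test_identical_multisets_null(self):
        assert wilcoxon_rank_sum([1, 2, 2], [1, 2, 2]).p_value == pytest.approx(1.0)

    @given(
        st.lists(st.integers(0, 6), min_size=1, max_size=5),
        st.lists(st.integers(0, 6), min_size=1, max_size=5),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_exact_path_matches_enumeration(self, x, y):
        res = wilcoxon_rank_sum(x, y)
        assert res.method == "wilcoxon_exact"
        assert res.p_value == pytest.approx(rank_sum_oracle(np.array(x, float), np.array(y, float)))

    def test_power_on_shifted_normals(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 200)
        y = rng.normal(1, 1, 200)
        assert wilcoxon_rank_sum(x, y).p_value < 1e-6

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            if wilcoxon_rank_sum(x, y).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBootstrapMedianSE:
    def test_constant_vector_zero(self):
        assert bootstrap_se_median([4.0] * 25, seed=1) == 0.0

    def test_seed_reproducibility(self):
        vals = list(np.random.default_rng(5).normal(size=60))
        assert bootstrap_se_median(vals, seed=9) == bootstrap_se_median(vals, seed=9)
        assert bootstrap_se_median(vals, seed=9) != bootstrap_se_median(vals, seed=10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bootstrap_se_median([], seed=0)
        with pytest.raises(ValueError):
            bootstrap_se_median([1.0, 2.0], n_resamples=1, seed=0)


class TestOrdering:
    def test_exact_match_of_four(self):
        nets = ["regulatory", "kinase", "genetic", "ppi"]
        assert ordering_pvalue(nets, nets) == pytest.approx(1 / 24)

    def test_single_network(self):
        assert ordering_pvalue(["a"], ["a"]) == 1.0

    def test_exact_match_of_three(self):
        assert ordering_pvalue(["a", "b", "c"], ["a", "b", "c"]) == pytest.approx(1 / 6)

    def test_adjacent_swap_tail(self):
        # 2 concordant pairs; permutations of 3 with >= 2 concordant: 3 of 6
        assert ordering_pvalue(["b", "a", "c"], ["a", "b", "c"]) == pytest.approx(0.5)

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            ordering_pvalue(["a", "b"], ["a", "c"])


class TestIntegrationRatio:
    def test_halved(self):
        assert integration_ratio([2, 4], [4, 8]) == pytest.approx(0.5)

    def test_identity(self):
        assert integration_ratio([3, 5], [3, 5]) == 1.0

    def test_zero_old_mean_rejected(self):
        with pytest.raises(ValueError):
            integration_ratio([1.0], [0.0])


class TestLossModel:
    FEATURES = [
        "ppi_degree",
        "genetic_degree",
        "regulatory_in_degree",
        "mrna_expression",
        "expression_spread",
        "essential",
    ]

    def test_null_features_give_near_zero_r2(self):
        coefs = {f: 0.0 for f in self.FEATURES}
        X, y = simulate_logistic(2000, coefs, seed=21)
        fit = fit_local_loss_model(X, y)
        assert fit.r_squared < 0.01
        assert (fit.partial_pvalues > 1e-3).all()

    def test_sign_recovery_single_replicate(self):
        coefs = dict(
            zip(self.FEATURES, [-0.5, -0.4, +0.5, -0.6, +0.4, -0.3])
        )
        X, y = simulate_logistic(5000, coefs, seed=3)
        fit = fit_local_loss_model(X, y)
        assert list(fit.direction()) == ["-", "-", "+", "-", "+", "-"]
        assert fit.r_squared > 0.05

    def test_binary_feature_matches_closed_form_lr(self):
        # 2x2-structured data: outcome rate 0.8 when x=1, 0.2 when x=0
        x = np.repeat([0.0, 1.0], 50)
        y = np.concatenate([np.repeat([0.0, 1.0], [40, 10]), np.repeat([0.0, 1.0], [10, 40])])
        X = pd.DataFrame({"x": x})
        fit = fit_local_loss_model(X, y)

        def llf(p, k, n):
            return k * math.log(p) + (n - k) * math.log(1 - p)

        lr = 2 * ((llf(0.2, 10, 50) + llf(0.8, 40, 50)) - llf(0.5, 50, 100))
        from scipy.stats import chi2

        assert fit.partial_pvalues["x"] == pytest.approx(chi2.sf(lr, 1), rel=1e-4)

    def test_collinear_feature_dropped(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.normal(size=500)})
        X["b"] = 2 * X["a"]
        y = (rng.random(500) < 1 / (1 + np.exp(-X["a"]))).astype(float)
        fit = fit_local_loss_model(X, y)
        assert len(fit.dropped) == 1

    def test_fitted_probabilities_in_unit_interval(self):
        coefs = {"a": 1.0, "b": -1.0}
        X, y = simulate_logistic(500, coefs, seed=8)
        fit = fit_local_loss_model(X, y)
        assert ((fit.fitted > 0) & (fit.fitted < 1)).all()
        assert 0.0 <= fit.r_squared <= 1.0

    def test_f_test_variant_close_to_lr(self):
        # at moderate evidence the deviance F-test tracks the LR chi-square
        coefs = {"a": 0.15, "b": -0.1}
        X, y = simulate_logistic(2000, coefs, seed=10)
        lr = fit_local_loss_model(X, y, partial_test="lr")
        f = fit_local_loss_model(X, y, partial_test="f")
        assert np.allclose(
            np.log10(lr.partial_pvalues), np.log10(f.partial_pvalues), atol=0.3
        )
        assert list(lr.partial_pvalues.sort_values().index) == list(
            f.partial_pvalues.sort_values().index
        )
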