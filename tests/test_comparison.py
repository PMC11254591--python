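"""Strategy aggregation, savings, microsimulation, and the Mann-Whitney test."""
import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from pccost import markov_cohort as mc
from pccost.comparison import (
    compare,
    evaluate_strategy,
    mann_whitney,
    microsimulate_costs,
)
from pccost.parameters import ParameterError


class TestEvaluateStrategy:
    def test_total_decomposes_into_diagnostics_plus_state_spend(self, default_params, components):
        for strat in ("psa_mri", "sthlm3_reflex", "swop"):
            res = evaluate_strategy(default_params, strat, components=components)
            assert res.total_cost_per_1000 == pytest.approx(
                res.diagnostic_spend_per_1000 + sum(res.per_state_spend.values()), abs=1e-6
            )
            assert res.cost_per_man == pytest.approx(res.total_cost_per_1000 / 1000)

    def test_hand_built_toy_total(self, default_params, components):
        # 990 men stop after one PSA test, 10 reach a metastatic diagnosis at
        # zero marginal diagnostic cost: total = 990*29 + 10*(29 + 269 028)
        params = default_params.copy()
        params.diag_probs.p_psa_ge_3 = 0.01
        params.diag_probs.p_pirads_ge_3_given_referred["psa_mri"] = 1.0
        params.diag_probs.biopsy_outcome["psa_mri"] = {
            "benign": 0.0, "isup1": 0.0, "isup2_5": 0.0, "metastatic": 1.0,
        }
        for key in ("mri", "biopsy"):
            params.costs.items[key].unit_cost = 0.0
        res = evaluate_strategy(params, "psa_mri",
                                components={**components, "metastatic": 269028.0})
        assert res.total_cost_per_1000 == pytest.approx(990 * 29 + 10 * (29 + 269028.0))

    def test_zero_cancers_leaves_only_diagnostics(self, default_params, components):
        params = default_params.copy()
        params.diag_probs.biopsy_outcome["psa_mri"] = {
            "benign": 1.0, "isup1": 0.0, "isup2_5": 0.0, "metastatic": 0.0,
        }
        res = evaluate_strategy(params, "psa_mri", components=components)
        assert res.total_cost_per_1000 == pytest.approx(res.diagnostic_spend_per_1000)

    def test_linear_in_state_counts_and_components(self, default_params, components):
        res = evaluate_strategy(default_params, "psa_mri", components=components)
        doubled = {k: 2 * v for k, v in components.items()}
        res2 = evaluate_strategy(default_params, "psa_mri", components=doubled)
        treat = res.total_cost_per_1000 - res.diagnostic_spend_per_1000
        treat2 = res2.total_cost_per_1000 - res2.diagnostic_spend_per_1000
        assert treat2 == pytest.approx(2 * treat, rel=1e-12)

    def test_unknown_strategy_raises(self, default_params):
        with pytest.raises(ParameterError, match="unknown strategy"):
            evaluate_strategy(default_params, "nonesuch")


class TestCompare:
    def test_published_saving_and_percent(self, default_params):
        res = compare(default_params)
        assert res.baseline.cost_per_man == pytest.approx(4676.0, abs=0.01)
        assert res.comparator.cost_per_man == pytest.approx(4317.76, abs=0.01)
        assert res.saving_per_man_reported == 358
        assert res.saving_percent == 7.7
        assert res.net_saving_per_1000 == pytest.approx(358239.0, abs=0.01)

    def test_saving_percent_rounding_rule(self):
        # 100 * 358.239 / 4676 = 7.661 -> one decimal, half-up
        from pccost.util import round_half_up

        assert round_half_up(100 * 358.239 / 4676, 1) == 7.7

    def test_strategy_compared_to_itself_warns_and_returns_zero(self, default_params):
        with pytest.warns(UserWarning, match="itself"):
            res = compare(default_params, "psa_mri", "psa_mri")
        assert res.saving_per_man_reported == 0
        assert res.saving_percent == 0.0


class TestMicrosimulation:
    def test_degenerate_paths_cost_one_psa_test(self, default_params):
        params = default_params.copy()
        params.diag_probs.p_psa_ge_3 = 0.0
        params.diag_probs.p_psa_ge_1_5 = 0.0
        for strat in ("psa_mri", "sthlm3_reflex"):
            draws = microsimulate_costs(params, strat, 500, seed=1)
            assert np.all(draws == 29.0)

    def test_seed_contract(self, default_params):
        a = microsimulate_costs(default_params, "psa_mri", 2000, seed=7)
        b = microsimulate_costs(default_params, "psa_mri", 2000, seed=7)
        c = microsimulate_costs(default_params, "psa_mri", 2000, seed=8)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_zero_sample_size_rejected(self, default_params):
        with pytest.raises(ParameterError, match=">= 1"):
            microsimulate_costs(default_params, "psa_mri", 0, seed=1)

    @pytest.mark.parametrize("strategy", ["psa_mri", "sthlm3_reflex", "swop"])
    def test_sample_mean_converges_to_analytic_cost_per_man(
        self, default_params, components, strategy
    ):
        n = 60_000
        res = evaluate_strategy(default_params, strategy, components=components)
        draws = microsimulate_costs(default_params, strategy, n, seed=20240625)
        se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - res.cost_per_man) < 4 * se


class TestMannWhitney:
    def test_fully_separated_small_samples_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_midrank_u(self):
        u, p = mann_whitney([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert u == pytest.approx(9 / 2)

    def test_all_values_identical_convention(self):
        u, p = mann_whitney([3.0, 3.0], [3.0, 3.0, 3.0])
        assert p == 1.0

    def test_u_statistics_sum_to_product(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a = rng.integers(0, 8, size=rng.integers(2, 30)).astype(float)
            b = rng.integers(0, 8, size=rng.integers(2, 30)).astype(float)
            u_a, _ = mann_whitney(a, b)
            u_b, _ = mann_whitney(b, a)
            assert u_a + u_b == pytest.approx(len(a) * len(b))

    def test_exact_agrees_with_scipy_enumeration(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 12)
        u, p = mann_whitney(a, b)
        ref = mannwhitneyu(a, b, method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_and_normal_branches_agree_at_15x15(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
        _, p_exact = mann_whitney(a, b)
        ref = mannwhitneyu(a, b, method="asymptotic")
        assert abs(p_exact - ref.pvalue) < 0.01

    def test_large_tied_samples_agree_with_scipy_asymptotic(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 5, 300).astype(float)
        b = rng.integers(1, 6, 300).astype(float)
        u, p = mann_whitney(a, b)
        ref = mannwhitneyu(a, b, method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError, match="nonempty"):
            mann_whitney([], [1.0])

    def test_microsimulated_arm_comparison_is_significant(self, default_params):
        res = compare(default_params, microsim_n=1000, seed=20240625)
        assert res.p_value < 0.001
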