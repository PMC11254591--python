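"""Decision-tree evaluation: expected costs, state counts, stage migration."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pccost.decision_tree import (
    MigrationFactors,
    StateDistribution,
    apply_stage_migration,
    build_tree,
    enumerate_paths,
    expected_diagnostic_cost,
    state_distribution,
    swop_distribution,
)
from pccost.parameters import CostTable, ParameterError
from pccost.synthetic_data import random_parameter_set


def _chain_probs(default_params, p3, pirads, outcome=None):
    probs = default_params.copy().diag_probs
    probs.p_psa_ge_3 = p3
    probs.p_pirads_ge_3_given_referred["psa_mri"] = pirads
    if outcome is not None:
        probs.biopsy_outcome["psa_mri"] = outcome
    return probs


class TestExpectedCost:
    def test_toy_chain_hand_expansion(self, default_params):
        # PSA always (29), MRI w.p. 0.5 (406), biopsy w.p. 0.25 (1347)
        probs = _chain_probs(default_params, p3=0.5, pirads=0.5)
        total, breakdown = expected_diagnostic_cost("psa_mri", probs, default_params.costs)
        assert total == pytest.approx(29 + 0.5 * 406 + 0.25 * 1347, abs=1e-9)
        assert breakdown["psa"] == 29
        assert breakdown["mri"] == pytest.approx(203)
        assert breakdown["biopsy"] == pytest.approx(336.75)

    def test_degenerate_tree_costs_one_psa_test(self, default_params):
        probs = _chain_probs(default_params, p3=0.0, pirads=0.0)
        total, _ = expected_diagnostic_cost("psa_mri", probs, default_params.costs)
        assert total == 29

    def test_breakdown_sums_to_total(self, default_params):
        for strat in ("psa_mri", "sthlm3_reflex", "swop"):
            total, breakdown = expected_diagnostic_cost(
                strat, default_params.diag_probs, default_params.costs
            )
            assert sum(breakdown.values()) == pytest.approx(total, abs=1e-9)

    def test_calibrated_tables_reproduce_published_cost_gap(self, default_params):
        psa, _ = expected_diagnostic_cost("psa_mri", default_params.diag_probs, default_params.costs)
        bio, _ = expected_diagnostic_cost("sthlm3_reflex", default_params.diag_probs, default_params.costs)
        assert bio - psa == pytest.approx(151.0, abs=1e-9)

    @given(st.integers(0, 200))
    def test_recursive_evaluator_equals_path_enumeration(self, seed):
        params = random_parameter_set(seed)
        for strat in ("psa_mri", "sthlm3_reflex", "swop"):
            tree = build_tree(strat, params.diag_probs)
            paths = list(enumerate_paths(tree, params.costs))
            assert sum(p for p, _, _ in paths) == pytest.approx(1.0, abs=1e-12)
            brute_cost = sum(p * c for p, c, _ in paths)
            total, _ = expected_diagnostic_cost(strat, params.diag_probs, params.costs)
            assert total == pytest.approx(brute_cost, rel=1e-12)

            brute_counts = {}
            for p, _, state in paths:
                brute_counts[state] = brute_counts.get(state, 0.0) + 1000 * p
            dist = state_distribution(strat, params.diag_probs)
            for state, count in brute_counts.items():
                assert getattr(dist, state) == pytest.approx(count, abs=1e-9)

    def test_raising_downstream_probability_never_decreases_cost(self, default_params):
        base, _ = expected_diagnostic_cost("psa_mri", default_params.diag_probs, default_params.costs)
        for field, bump in (("p_psa_ge_3", 0.1), ("p_pirads_ge_3_given_referred", 0.1)):
            probs = default_params.copy().diag_probs
            if field == "p_psa_ge_3":
                probs.p_psa_ge_3 += bump
            else:
                probs.p_pirads_ge_3_given_referred["psa_mri"] += bump
            up, _ = expected_diagnostic_cost("psa_mri", probs, default_params.costs)
            assert up >= base

    def test_unknown_cost_key_is_named(self, default_params):
        costs = CostTable.defaults()
        del costs.items["mri"]
        with pytest.raises(ParameterError, match="'mri'"):
            expected_diagnostic_cost("psa_mri", default_params.diag_probs, costs)


class TestStateDistribution:
    def test_toy_multiply_through(self, default_params):
        # p(biopsy) = 0.2 * 0.5 = 0.1, outcomes (0.5, 0.2, 0.25, 0.05)
        outcome = {"benign": 0.5, "isup1": 0.2, "isup2_5": 0.25, "metastatic": 0.05}
        probs = _chain_probs(default_params, p3=0.2, pirads=0.5, outcome=outcome)
        dist = state_distribution("psa_mri", probs)
        assert dist.no_workup == pytest.approx(900)
        assert dist.benign == pytest.approx(50)
        assert dist.isup1 == pytest.approx(20)
        assert dist.isup2_5 == pytest.approx(25)
        assert dist.metastatic == pytest.approx(5)

    def test_zero_biopsy_probability(self, default_params):
        probs = _chain_probs(default_params, p3=0.0, pirads=0.0)
        dist = state_distribution("psa_mri", probs)
        assert dist.no_workup == pytest.approx(1000)
        assert dist.total == pytest.approx(1000)

    @given(st.integers(0, 300))
    def test_counts_always_sum_to_cohort(self, seed):
        params = random_parameter_set(seed)
        for strat in ("psa_mri", "sthlm3_reflex", "swop"):
            dist = state_distribution(strat, params.diag_probs)
            assert dist.total == pytest.approx(1000.0, abs=1e-9)


class TestStageMigration:
    def test_published_factors_on_round_numbers(self):
        base = StateDistribution(no_workup=690, benign=100, isup1=100, isup2_5=100, metastatic=10)
        out = apply_stage_migration(base)
        assert out.isup1 == pytest.approx(54)
        assert out.isup2_5 == pytest.approx(124)
        assert out.metastatic == pytest.approx(8.4)
        assert out.total == pytest.approx(1000, abs=1e-12)

    def test_identity_factors(self):
        base = StateDistribution(no_workup=900, benign=50, isup1=20, isup2_5=25, metastatic=5)
        out = apply_stage_migration(base, MigrationFactors(1.0, 1.0, 1.0))
        assert out.as_dict() == pytest.approx(base.as_dict())

    @given(st.integers(0, 300))
    def test_conservation_for_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.dirichlet((20.0, 3.0, 1.0, 1.0, 0.3)) * 1000
        base = StateDistribution(*w)
        out = apply_stage_migration(base)
        assert out.total == pytest.approx(1000.0, abs=1e-9)

    def test_negative_absorber_is_an_error(self):
        base = StateDistribution(no_workup=0, benign=1, isup1=0, isup2_5=990, metastatic=9)
        with pytest.raises(ParameterError, match="negative"):
            apply_stage_migration(base, MigrationFactors(1.0, 2.0, 1.0))


class TestSwop:
    def test_zero_progression_mirrors_psa_metastatic_count(self, default_params):
        psa = state_distribution("psa_mri", default_params.diag_probs)
        dist, _ = swop_distribution(psa, default_params.diag_probs, 0.0)
        assert dist.metastatic == pytest.approx(psa.metastatic, abs=1e-12)

    def test_twenty_false_negatives_add_two_metastatic(self, default_params):
        probs = default_params.copy().diag_probs
        psa = state_distribution("psa_mri", probs)
        swop_base = state_distribution("swop", probs)
        # retune the SWOP biopsy outcomes so exactly 20 ISUP 2-5 cases are missed
        bx = swop_base.total - swop_base.no_workup
        target_cs = psa.isup2_5 - 20.0
        out = probs.biopsy_outcome["swop"]
        shift = target_cs / bx - out["isup2_5"]
        out["isup2_5"] += shift
        out["benign"] -= shift
        dist, _ = swop_distribution(psa, probs, 0.10)
        assert dist.metastatic == pytest.approx(psa.metastatic + 2.0, abs=1e-9)
        assert dist.total == pytest.approx(1000.0, abs=1e-9)

    def test_diagnostic_cost_includes_trus(self, default_params):
        psa = state_distribution("psa_mri", default_params.diag_probs)
        _, cost = swop_distribution(
            psa, default_params.diag_probs, 0.1, costs=default_params.costs
        )
        _, breakdown = expected_diagnostic_cost(
            "swop", default_params.diag_probs, default_params.costs
        )
        assert breakdown["risk_calc"] == pytest.approx(
            default_params.diag_probs.p_psa_ge_3 * 100.0
        )
        assert cost == pytest.approx(sum(breakdown.values()))

    def test_swop_detecting_more_than_psa_is_an_error(self, default_params):
        probs = default_params.copy().diag_probs
        probs.biopsy_outcome["swop"] = {
            "benign": 0.0, "isup1": 0.0, "isup2_5": 1.0, "metastatic": 0.0,
        }
        psa = state_distribution("psa_mri", probs)
        with pytest.raises(ParameterError, match="exceeds available"):
            swop_distribution(psa, probs, 0.1)
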