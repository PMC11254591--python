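"""Per-strategy spending aggregation, savings, and the statistical comparison.

A strategy's total spend per 1000 men tested is the decision-tree diagnostic
spend (all men, including those with no further workup) plus the sum over
disease states of detected count x treatment-only state component. The
published per-state cost anchors embed the fixed diagnostic cascade, so the
treatment-only component of a state is its anchor minus the benign anchor.

The statistical comparison microsimulates per-man six-year discounted costs
(diagnostic path plus an individual treatment realization) for each arm and
applies the Mann-Whitney U test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import norm, rankdata

from . import markov_cohort as mc
from .decision_tree import (
    StateDistribution,
    expected_diagnostic_cost,
    get_strategy,
    rescale_state,
    state_distribution,
    swop_distribution,
)
from .parameters import ParameterError, ParameterSet
from .synthetic_data import sample_state_costs
from .util import discount_factors, round_half_up, truncate_euro

__all__ = [
    "Scenario",
    "StrategyResult",
    "ComparisonResult",
    "evaluate_strategy",
    "compare",
    "microsimulate_costs",
    "mann_whitney",
]

_TREATED = ("benign", "isup1", "isup2_5", "metastatic")


@dataclass
class Scenario:
    """Deterministic perturbations applied on top of a parameter set.

    Used by the sensitivity analysis: override a state's treatment component
    with an absolute value, scale a state's detected count in both arms, or
    scale all diagnostic costs.
    """

    component_overrides: dict[str, float] = field(default_factory=dict)
    count_scale: dict[str, float] = field(default_factory=dict)
    diag_scale: float = 1.0


@dataclass
class StrategyResult:
    strategy: str
    diagnostic_cost_per_man: float
    diagnostic_breakdown: dict[str, float]
    state_distribution: StateDistribution
    components: dict[str, float]
    per_state_spend: dict[str, float]
    diagnostic_spend_per_1000: float
    total_cost_per_1000: float

    @property
    def cost_per_man(self) -> float:
        return self.total_cost_per_1000 / self.state_distribution.cohort


def _apply_scenario_dist(dist: StateDistribution, scenario: Scenario) -> StateDistribution:
    for state, factor in scenario.count_scale.items():
        dist = rescale_state(dist, state, factor)
    return dist


def evaluate_strategy(
    params: ParameterSet,
    strategy: str,
    scenario: Scenario | None = None,
    components: dict[str, float] | None = None,
) -> StrategyResult:
    """Combine the decision tree with the per-state cohort costs.

    ``components`` (treatment-only per-state costs) may be passed to avoid
    recomputation; otherwise they are derived from the calibrated cohort
    model.
    """
    sc = scenario or Scenario()
    sdef = get_strategy(strategy)
    comps = dict(components or mc.state_components(params))
    comps.update(sc.component_overrides)

    diag_per_man, breakdown = expected_diagnostic_cost(sdef, params.diag_probs, params.costs)
    if strategy == "swop" or sdef.name == "swop":
        psa_dist = state_distribution("psa_mri", params.diag_probs)
        psa_dist = _apply_scenario_dist(psa_dist, sc)
        dist, _ = swop_distribution(
            psa_dist, params.diag_probs, params.swop_fn_progress_fraction
        )
        # count_scale already applied through the mirrored PSA distribution;
        # apply residual scaling only for states the mirror does not cover
    else:
        dist = state_distribution(sdef, params.diag_probs)
        dist = _apply_scenario_dist(dist, sc)

    diag_per_man *= sc.diag_scale
    breakdown = {k: v * sc.diag_scale for k, v in breakdown.items()}

    spend = {s: getattr(dist, s) * comps[s] for s in _TREATED}
    diag_spend = diag_per_man * dist.cohort
    total = diag_spend + sum(spend.values())
    return StrategyResult(
        strategy=sdef.name,
        diagnostic_cost_per_man=diag_per_man,
        diagnostic_breakdown=breakdown,
        state_distribution=dist,
        components=comps,
        per_state_spend=spend,
        diagnostic_spend_per_1000=diag_spend,
        total_cost_per_1000=total,
    )


@dataclass
class ComparisonResult:
    baseline: StrategyResult
    comparator: StrategyResult
    u_statistic: float | None = None
    p_value: float | None = None
    microsim_n: int | None = None

    @property
    def net_saving_per_1000(self) -> float:
        return self.baseline.total_cost_per_1000 - self.comparator.total_cost_per_1000

    @property
    def saving_per_man(self) -> float:
        return self.baseline.cost_per_man - self.comparator.cost_per_man

    @property
    def saving_per_man_reported(self) -> float:
        """Saving per man truncated to whole euros (reporting rule)."""
        return truncate_euro(self.saving_per_man)

    @property
    def saving_percent(self) -> float:
        """Saving as a percent of the baseline total, one decimal, half-up."""
        return round_half_up(
            100.0 * self.net_saving_per_1000 / self.baseline.total_cost_per_1000, 1
        )


def compare(
    params: ParameterSet,
    baseline_strategy: str = "psa_mri",
    comparator_strategy: str = "sthlm3_reflex",
    scenario: Scenario | None = None,
    microsim_n: int | None = None,
    seed: int | None = None,
) -> ComparisonResult:
    """Evaluate both strategies and, optionally, the Mann-Whitney comparison."""
    if get_strategy(baseline_strategy).name == get_strategy(comparator_strategy).name:
        warnings.warn("comparing a strategy to itself", stacklevel=2)
    comps = mc.state_components(params)
    base = evaluate_strategy(params, baseline_strategy, scenario, comps)
    comp = evaluate_strategy(params, comparator_strategy, scenario, comps)
    result = ComparisonResult(baseline=base, comparator=comp)
    if microsim_n:
        if seed is None:
            raise ParameterError("a seed is required for the microsimulated comparison")
        a = microsimulate_costs(params, baseline_strategy, microsim_n, seed)
        b = microsimulate_costs(params, comparator_strategy, microsim_n, seed + 1)
        result.u_statistic, result.p_value = mann_whitney(a, b)
        result.microsim_n = microsim_n
    return result


# --------------------------------------------------------------------------
# Microsimulation of per-man costs
# --------------------------------------------------------------------------

def microsimulate_costs(
    params: ParameterSet, strategy: str, n: int, seed: int
) -> np.ndarray:
    """Draw per-man six-year discounted costs (diagnostic path + treatment).

    Each man's path through the diagnostic tree is sampled stage by stage;
    diseased men add an individual treatment realization drawn from the state
    model's schedules. The sample mean converges to the strategy's analytic
    cost per man.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    sdef = get_strategy(strategy)
    rng = np.random.default_rng(seed)
    p = params.diag_probs
    costs = params.costs
    diag = np.full(n, costs.unit("psa_test"))
    state = np.zeros(n, dtype=np.int8)  # 0 = no_workup, 1..4 = disease states
    state_names = {1: "benign", 2: "isup1", 3: "isup2_5", 4: "metastatic"}

    if sdef.name == "psa_mri":
        referred = rng.random(n) < p.p_psa_ge_3
        stages = [(referred, "mri", p.p_pirads_ge_3_given_referred["psa_mri"])]
        outcome = p.biopsy_outcome["psa_mri"]
    elif sdef.name == "sthlm3_reflex":
        reflex = rng.random(n) < p.p_psa_ge_1_5
        diag[reflex] += costs.unit("stockholm3")
        referred = reflex & (rng.random(n) < p.p_sthlm3_ge_11_given_psa_1_5)
        stages = [(referred, "mri", p.p_pirads_ge_3_given_referred["sthlm3_reflex"])]
        outcome = p.biopsy_outcome["sthlm3_reflex"]
    elif sdef.name == "swop":
        elevated = rng.random(n) < p.p_psa_ge_3
        diag[elevated] += costs.unit("trus")
        referred = elevated & (rng.random(n) < p.p_swop_referred_given_psa_ge_3)
        stages = [(referred, "mri", p.p_pirads_ge_3_given_referred["swop"])]
        outcome = p.biopsy_outcome["swop"]
    else:  # pragma: no cover - registry is closed
        raise ParameterError(f"unknown strategy '{strategy}'")

    mask, cost_key, p_next = stages[0]
    diag[mask] += costs.unit(cost_key)
    biopsied = mask & (rng.random(n) < p_next)
    diag[biopsied] += costs.unit("biopsy")
    idx = np.flatnonzero(biopsied)
    if idx.size:
        probs = np.array([outcome.get(s, 0.0) for s in ("benign", "isup1", "isup2_5", "metastatic")])
        draw = rng.choice(4, size=idx.size, p=probs / probs.sum()) + 1
        state[idx] = draw

    if sdef.name == "swop":
        # false-negative clinically significant cases progressing to metastatic
        # disease within the horizon: drawn from the undiagnosed elevated-PSA pool
        psa_dist = state_distribution("psa_mri", p)
        swop_dist, _ = swop_distribution(psa_dist, p, params.swop_fn_progress_fraction)
        base = state_distribution("swop", p)
        extra = swop_dist.metastatic - base.metastatic
        pool = elevated & (state == 0)
        pool_count_per_1000 = (
            base.cohort * p.p_psa_ge_3
            - base.cohort * p.p_psa_ge_3 * p.p_swop_referred_given_psa_ge_3
            * p.p_pirads_ge_3_given_referred["swop"]
        )
        # pool = elevated men not biopsied (includes MRI-negative referrals)
        rate = extra / pool_count_per_1000 if pool_count_per_1000 > 0 else 0.0
        progress = pool & (rng.random(n) < rate)
        state[progress] = 4

    total = diag.astype(float)
    for code, name in state_names.items():
        members = np.flatnonzero(state == code)
        if members.size:
            total[members] += sample_state_costs(name, members.size, params, rng)
    return total


# --------------------------------------------------------------------------
# Mann-Whitney U test
# --------------------------------------------------------------------------

_EXACT_LIMIT = 400


@lru_cache(maxsize=None)
def _u_count(n: int, m: int, u: int) -> int:
    """Number of orderings of n+m distinct values with U statistic u.

    Standard lattice-path recurrence: N(n, m, u) = N(n-1, m, u-m) + N(n, m-1, u).
    """
    if u < 0:
        return 0
    if n == 0 or m == 0:
        return 1 if u == 0 else 0
    return _u_count(n - 1, m, u - m) + _u_count(n, m - 1, u)


def _exact_u_pmf(n: int, m: int) -> np.ndarray:
    counts = np.array([_u_count(n, m, u) for u in range(n * m + 1)], dtype=float)
    return counts / counts.sum()


def mann_whitney(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test by rank summation with midrank ties.

    Returns ``(U_a, p)`` where ``U_a`` is the statistic of the first sample.
    The p-value is exact (enumeration of the null distribution) when
    ``n_a * n_b <= 400`` and the pooled sample has no ties; otherwise a normal
    approximation with tie and continuity corrections is used. If every value
    in both samples is identical the p-value is 1.0 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both samples must be nonempty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate((a, b))
    ranks = rankdata(pooled)
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if np.all(tie_counts == pooled.size):  # all values identical
        return u_a, 1.0

    if not has_ties and n_a * n_b <= _EXACT_LIMIT:
        pmf = _exact_u_pmf(n_a, n_b)
        u_int = int(round(u_a))
        mean = n_a * n_b / 2.0
        if u_a <= mean:
            p = 2.0 * float(pmf[: u_int + 1].sum())
        else:
            p = 2.0 * float(pmf[u_int:].sum())
        return u_a, min(1.0, p)

    n_tot = n_a + n_b
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n_tot * (n_tot - 1)))
    sigma2 = n_a * n_b / 12.0 * ((n_tot + 1) - tie_term)
    if sigma2 <= 0:
        return u_a, 1.0
    mean = n_a * n_b / 2.0
    z = (u_a - mean - 0.5 * np.sign(u_a - mean)) / np.sqrt(sigma2)
    p = 2.0 * float(norm.sf(abs(z)))
    return u_a, min(1.0, p)
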