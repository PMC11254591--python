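"""Six-year discounted per-patient costs for each disease state.

An annual-cycle cohort model (no half-cycle correction): each disease state is
modelled as a deterministic cohort trace over the horizon, with fractions of
the cohort occupying treatment lines each year and costs accrued per occupied
line. Future costs are discounted at the configured annual rate; year-1 costs
are undiscounted.

State components returned here are *treatment-only*: the fixed diagnostic
cascade (``benign_cost``) is added on top to form the published per-state
totals, which include diagnostics.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    ASchedule,
    CostTable,
    LocalizedMix,
    ModelConfig,
    ParameterError,
    ParameterSet,
    TreatmentMix,
)
from .util import discount_factors

__all__ = [
    "CostStream",
    "CohortTrace",
    "discount",
    "benign_cost",
    "as_cost",
    "localized_cost",
    "metastatic_cost",
    "state_component",
    "state_components",
    "state_cost",
    "state_costs",
    "traces_frame",
]


@dataclass
class CostStream:
    """Per-model-year costs (index 0 = year 1)."""

    annual_costs: np.ndarray

    def __post_init__(self):
        self.annual_costs = np.asarray(self.annual_costs, dtype=float)
        if np.any(self.annual_costs < 0):
            raise ParameterError("cost stream entries must be >= 0")


def discount(stream, rate: float, horizon: int | None = None) -> float:
    """Present value of an annual cost stream: sum of cost_t / (1+rate)^(t-1)."""
    costs = stream.annual_costs if isinstance(stream, CostStream) else np.asarray(stream, dtype=float)
    if rate < 0:
        raise ParameterError("discount rate must be >= 0")
    if horizon is not None and len(costs) > horizon:
        raise ParameterError(f"cost stream of length {len(costs)} exceeds horizon {horizon}")
    return float(costs @ discount_factors(len(costs), rate))


@dataclass
class CohortTrace:
    """Annual cohort trace for one disease state.

    ``occupancy`` maps line/compartment names to per-year cohort fractions;
    compartments listed in ``conserved`` partition the cohort (sum to 1 each
    year). Costs are treatment-only per initial state member.
    """

    state: str
    annual_costs: np.ndarray
    discount_rate: float
    occupancy: dict[str, np.ndarray] = field(default_factory=dict)
    conserved: tuple[str, ...] = ()

    @property
    def undiscounted_cost(self) -> float:
        return float(np.sum(self.annual_costs))

    @property
    def discounted_cost(self) -> float:
        return discount(self.annual_costs, self.discount_rate)

    @property
    def discounted_annual(self) -> np.ndarray:
        return self.annual_costs * discount_factors(len(self.annual_costs), self.discount_rate)

    def conservation_error(self) -> float:
        if not self.conserved:
            return 0.0
        total = sum(self.occupancy[k] for k in self.conserved)
        return float(np.max(np.abs(total - 1.0)))


def benign_cost(costs: CostTable) -> float:
    """Cost of the full diagnostic cascade: PSA + Stockholm3 + MRI + biopsy.

    This is the published benign-state cost; it is also the fixed diagnostic
    component embedded in every per-state cost anchor.
    """
    return (
        costs.unit("psa_test")
        + costs.unit("stockholm3")
        + costs.unit("mri")
        + costs.unit("biopsy")
    )


def _course_stream(annual_cost: float, years: float, horizon: int, start_year: int = 1) -> np.ndarray:
    """Spread an annual-cost course of fractional length over model years."""
    if years < 0:
        raise ParameterError("negative course length")
    s = np.zeros(horizon)
    remaining = years
    t = start_year - 1
    while remaining > 1e-12 and t < horizon:
        s[t] = annual_cost * min(1.0, remaining)
        remaining -= 1.0
        t += 1
    return s


def as_cost(
    sched: ASchedule,
    costs: CostTable,
    config: ModelConfig,
    surveillance_multiplier: float = 1.0,
) -> CohortTrace:
    """Active-surveillance cohort trace for low-grade disease.

    Non-progressed occupants accrue the surveillance event schedule (scaled by
    the calibration multiplier); the fraction progressing each year incurs the
    curative-mix cost in that year and leaves surveillance.
    """
    sched.validate()
    h = config.horizon_years
    cum = sched.yearly_cum(h)
    delta = np.diff(np.concatenate(([0.0], cum)))
    on_as = 1.0 - cum

    events = sched.events_per_year(h)
    surv_per_year = sum(n * costs.unit(k) for k, n in events.items())
    surv_per_year = np.asarray(surv_per_year, dtype=float) * surveillance_multiplier

    w_rp = sched.curative_mix.get("rp", 0.0)
    w_rt = sched.curative_mix.get("rt_short_adt", 0.0)
    curative_unit = w_rp * costs.unit("rp") + w_rt * (
        costs.unit("rt") + sched.curative_adt_years * costs.unit("adt")
    )

    annual = on_as * surv_per_year + delta * curative_unit
    return CohortTrace(
        state="isup1",
        annual_costs=annual,
        discount_rate=config.discount_rate,
        occupancy={"surveillance": on_as, "progressed": cum},
        conserved=("surveillance", "progressed"),
    )


def localized_cost(
    mix: LocalizedMix,
    costs: CostTable,
    config: ModelConfig,
    adt_multiplier: float = 1.0,
) -> CohortTrace:
    """Curative treatment trace for intermediate- to high-grade localized disease.

    Year-1 curative costs (RP, or RP + pelvic lymphadenectomy for the
    high-grade surgical arm) plus ADT annual costs over the configured course
    lengths; ADT course lengths are scaled by the calibration multiplier.
    """
    mix.validate()
    if adt_multiplier < 0:
        raise ParameterError("negative ADT duration multiplier")
    h = config.horizon_years
    annual = np.zeros(h)
    w_int = mix.intermediate_fraction
    w_high = 1.0 - w_int

    arms = [
        (w_int * mix.intermediate_weights.get("rp", 0.0), costs.unit("rp"), 0.0),
        (
            w_int * mix.intermediate_weights.get("rt_short_adt", 0.0),
            costs.unit("rt"),
            mix.adt_short_years * adt_multiplier,
        ),
        (
            w_high * mix.high_weights.get("rp_plnd", 0.0),
            costs.unit("rp") + costs.unit("plnd"),
            0.0,
        ),
        (
            w_high * mix.high_weights.get("rt_long_adt", 0.0),
            costs.unit("rt"),
            mix.adt_long_years * adt_multiplier,
        ),
    ]
    for weight, upfront, adt_years in arms:
        if weight == 0.0:
            continue
        annual[0] += weight * upfront
        annual += weight * _course_stream(costs.unit("adt"), adt_years, h)

    return CohortTrace(
        state="isup2_5",
        annual_costs=annual,
        discount_rate=config.discount_rate,
        occupancy={"treated": np.ones(h)},
        conserved=("treated",),
    )


def _discontinuation(mix: TreatmentMix, horizon: int) -> np.ndarray:
    """Cumulative fraction off systemic therapy by end of each model year."""
    t = np.arange(1, horizon + 1)
    cum = mix.discontinuation_year1 + mix.discontinuation_increment * (t - 1)
    if np.any(cum > 1.0):
        warnings.warn("discontinuation schedule exceeds 100%; clamped", stacklevel=2)
    return np.clip(cum, 0.0, 1.0)


def metastatic_cost(
    mix: TreatmentMix,
    costs: CostTable,
    config: ModelConfig,
    intensity_multiplier: float = 1.0,
) -> CohortTrace:
    """Metastatic-disease cohort trace.

    Recurring systemic-therapy costs (ADT backbone, ARPI, PARP, immune,
    radiopharmaceutical, osteoprotective support) accrue only to the active
    occupancy, which is attenuated by the cumulative discontinuation schedule.
    One-time items (upfront chemotherapy course, PSMA-PET staging, palliative
    and end-of-life totals) are charged to their fixed cohort fractions
    regardless of discontinuation. The calibration multiplier scales the
    annual costs of the named therapy lines (treatment intensity), not the
    ADT backbone or supportive/terminal care.
    """
    mix.validate()
    if intensity_multiplier < 0:
        raise ParameterError("negative intensity multiplier")
    h = config.horizon_years
    m = intensity_multiplier
    cum_off = _discontinuation(mix, h)
    active = 1.0 - cum_off

    annual = np.zeros(h)

    # ADT backbone for active occupants
    adt_years = h if mix.adt_years is None else min(mix.adt_years, h)
    adt_mask = _course_stream(1.0, adt_years, h)
    annual += costs.unit("adt") * adt_mask * active

    # systemic lines, active-attenuated, intensity-scaled
    for fraction, key, years in (
        (mix.arpi_fraction, "arpi", mix.arpi_years),
        (mix.parp_fraction, "parp", mix.parp_years),
        (mix.immune_fraction, "immune", mix.immune_years),
    ):
        annual += fraction * m * costs.unit(key) * _course_stream(1.0, years, h) * active

    # upfront chemotherapy: triplet (with ARPI) or taxane-only, one full course
    chemo_fraction = (
        mix.arpi_fraction * mix.triplet_given_arpi_fraction + mix.taxane_only_fraction
    )
    annual[0] += chemo_fraction * m * costs.unit("chemo_cycle")

    # radiopharmaceutical therapy in the final window, Lu-PSMA / Ra-223 split
    blended = (
        mix.radiopharm_lu_split * costs.unit("lu_psma")
        + (1.0 - mix.radiopharm_lu_split) * costs.unit("ra223")
    )
    window = min(mix.radiopharm_window_years, h)
    for t in range(h - window, h):
        annual[t] += mix.radiopharm_fraction * m * blended * active[t]

    # osteoprotective support for active occupants
    annual += mix.osteoprotective_fraction * costs.unit("osteoprotective") * active

    # staging PSMA-PET at diagnosis
    if mix.psma_pet_at_diagnosis:
        annual[0] += costs.unit("psma_pet")

    # palliative and end-of-life one-time totals at the end of the horizon
    if mix.palliative_year <= h:
        annual[mix.palliative_year - 1] += mix.palliative_fraction * costs.unit("palliative")
    if mix.eol_year <= h:
        annual[mix.eol_year - 1] += mix.eol_fraction * costs.unit("end_of_life")

    return CohortTrace(
        state="metastatic",
        annual_costs=annual,
        discount_rate=config.discount_rate,
        occupancy={"active": active, "discontinued": cum_off},
        conserved=("active", "discontinued"),
    )


# --------------------------------------------------------------------------
# Per-state aggregation used by the comparison and calibration layers
# --------------------------------------------------------------------------

def _trace(params: ParameterSet, state: str, multipliers: dict[str, float]) -> CohortTrace:
    if state == "isup1":
        return as_cost(params.as_schedule, params.costs, params.config,
                       surveillance_multiplier=multipliers["as_surveillance"])
    if state == "isup2_5":
        return localized_cost(params.localized_mix, params.costs, params.config,
                              adt_multiplier=multipliers["localized_adt"])
    if state == "metastatic":
        return metastatic_cost(params.mix, params.costs, params.config,
                               intensity_multiplier=multipliers["metastatic_intensity"])
    raise ParameterError(f"unknown treated state '{state}'")


def state_component(params: ParameterSet, state: str, multipliers: dict[str, float] | None = None) -> float:
    """Treatment-only six-year discounted cost for one state (benign = 0)."""
    if state == "benign":
        return 0.0
    mult = multipliers or params.mix.calibration_multipliers
    return _trace(params, state, mult).discounted_cost


def state_components(params: ParameterSet) -> dict[str, float]:
    return {s: state_component(params, s) for s in ("benign", "isup1", "isup2_5", "metastatic")}


def state_cost(params: ParameterSet, state: str, multipliers: dict[str, float] | None = None) -> float:
    """Per-state total cost including the fixed diagnostic cascade."""
    return state_component(params, state, multipliers) + benign_cost(params.costs)


def state_costs(params: ParameterSet) -> dict[str, float]:
    return {s: state_cost(params, s) for s in ("benign", "isup1", "isup2_5", "metastatic")}


def traces_frame(params: ParameterSet) -> pd.DataFrame:
    """Long-format per-state annual traces (state, year, line, occupancy, cost)."""
    rows = []
    mult = params.mix.calibration_multipliers
    for state in ("isup1", "isup2_5", "metastatic"):
        trace = _trace(params, state, mult)
        disc = trace.discounted_annual
        for t in range(params.config.horizon_years):
            for line, occ in trace.occupancy.items():
                rows.append({
                    "state": state,
                    "year": t + 1,
                    "line": line,
                    "occupancy": float(occ[t]),
                    "cost": float(trace.annual_costs[t]),
                    "discounted_cost": float(disc[t]),
                })
    return pd.DataFrame(rows)
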