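"""Generation of every model input from published aggregate targets.

The study's diagnostic probability tables come from registry data that is not
redistributable; what is published is a set of aggregate outcomes (per-man
diagnostic cost gap, Stockholm3's share of diagnostic spend, the metastatic
detection rate, per-state cost anchors, strategy totals). Because the decision
trees are small, each aggregate pins exactly one degree of freedom, and the
calibrated tables can be solved in closed form:

* the PSA-arm per-man diagnostic cost follows from the cost gap and its
  relative size;
* Stockholm3's spend share fixes the fraction of men with PSA >= 1.5 ng/ml;
* the strategy totals and the net saving fix the ISUP 1 and ISUP 2-5 detection
  counts through a 2x2 linear solve against the per-state treatment
  components;
* the biomarker-arm cancer counts are the stage-migrated PSA-arm counts;
* the SWOP variant's referral rate and false-negative count follow from its
  published diagnostic-cost reduction and total spend.

This module also provides seeded random parameter sets for property testing
and individual-level synthetic cohorts for the microsimulation; per-man cost
realizations use the same annual schedules as the cohort model with Bernoulli
line assignment, so the microsimulation mean equals the cohort-model cost by
construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import markov_cohort as mc
from .decision_tree import MigrationFactors, StateDistribution, state_distribution
from .parameters import (
    ASchedule,
    CalibrationError,
    CostTable,
    DiagProbTable,
    LocalizedMix,
    ModelConfig,
    ParameterError,
    ParameterSet,
    TreatmentMix,
    calibrate,
)
from .util import discount_factors

__all__ = [
    "CalibrationTargets",
    "DEFAULT_TARGETS",
    "generate_diag_prob_table",
    "build_default_parameter_set",
    "random_parameter_set",
    "SyntheticCohort",
    "generate_cohort",
    "sample_state_costs",
]


@dataclass
class CalibrationTargets:
    """Published aggregates that pin the synthesized diagnostic tables."""

    diag_cost_gap_per_man: float = 151.0        # EUR, biomarker minus PSA arm
    diag_cost_gap_relative: float = 0.42        # gap as a fraction of the PSA-arm cost
    sthlm3_share_of_diag: float = 0.35          # Stockholm3 share of biomarker-arm diag spend
    psa_arm_mpc_per_1000: float = 13.0          # metastatic detections per 1000 tested
    anchors: tuple[float, float, float, float] = (2182.0, 10023.0, 13073.0, 271210.0)
    psa_total_per_man: float = 4676.0           # EUR, PSA-strategy overall cost per man
    saving_per_1000: float = 358239.0           # EUR, biomarker-strategy net saving
    swop_total_per_1000: float = 4787048.0      # EUR, SWOP-strategy overall cost
    swop_diag_reduction: float = 0.43           # SWOP diag cost reduction vs PSA arm
    fn_progress_fraction: float = 0.10          # SWOP false negatives progressing to mPC
    migration: MigrationFactors = field(default_factory=MigrationFactors)
    # fixed pathway assumptions (not pinned by any printed aggregate)
    p_psa_ge_3: float = 0.35
    p_pirads_sthlm3: float = 0.45               # MRI yield in the biomarker-enriched group
    p_pirads_swop: float = 0.75                 # MRI yield after risk-calculator selection
    swop_isup1_sensitivity: float = 0.75        # SWOP detection of ISUP 1 vs PSA pathway

    def validate(self) -> None:
        positives = (
            "diag_cost_gap_per_man", "diag_cost_gap_relative", "sthlm3_share_of_diag",
            "psa_total_per_man", "swop_total_per_1000", "swop_diag_reduction",
        )
        for name in positives:
            if getattr(self, name) <= 0:
                raise ParameterError(f"targets.{name}: must be positive")
        if self.psa_arm_mpc_per_1000 < 0:
            raise ParameterError("targets.psa_arm_mpc_per_1000: must be >= 0")
        for v in self.anchors:
            if v <= 0:
                raise ParameterError("targets.anchors: must be positive")


DEFAULT_TARGETS = CalibrationTargets()


def _components(anchors) -> tuple[float, float, float]:
    benign, isup1, isup2_5, metastatic = anchors
    return isup1 - benign, isup2_5 - benign, metastatic - benign


def generate_diag_prob_table(
    targets: CalibrationTargets | None = None,
    seed: int | None = None,
) -> DiagProbTable:
    """Solve the diagnostic probability tables hitting all aggregate targets.

    Deterministic (closed form); ``seed`` is accepted for interface symmetry
    with the other generators but does not influence the result.
    """
    t = targets or DEFAULT_TARGETS
    t.validate()
    tab = CostTable.defaults()
    psa, s3 = tab.unit("psa_test"), tab.unit("stockholm3")
    mri, biopsy, trus = tab.unit("mri"), tab.unit("biopsy"), tab.unit("trus")
    c1, c2, cm = _components(t.anchors)
    f = t.migration
    nm = t.psa_arm_mpc_per_1000

    # --- per-man diagnostic costs of the three strategies -------------------
    diag_psa = t.diag_cost_gap_per_man / t.diag_cost_gap_relative
    diag_bio = diag_psa + t.diag_cost_gap_per_man
    diag_swop = (1.0 - t.swop_diag_reduction) * diag_psa

    # --- detection counts per 1000 from the strategy totals -----------------
    # x = c1*n1 (low-grade treatment spend), y = c2*n2: two linear constraints
    b1 = 1000.0 * (t.psa_total_per_man - diag_psa) - nm * cm
    b2 = (t.saving_per_1000 + 1000.0 * t.diag_cost_gap_per_man
          - (1.0 - f.metastatic_factor) * nm * cm)
    d1, d2 = 1.0 - f.isup1_factor, f.isup2_5_factor - 1.0
    x = (b2 + d2 * b1) / (d1 + d2)
    y = b1 - x
    if x < 0 or y < 0:
        raise CalibrationError(
            "infeasible targets: implied treatment spends are negative "
            f"(low-grade {x:.0f}, localized {y:.0f}); feasible saving interval is "
            f"[{-1000 * t.diag_cost_gap_per_man + (1 - f.metastatic_factor) * nm * cm - d2 * b1:.0f}, "
            f"{-1000 * t.diag_cost_gap_per_man + (1 - f.metastatic_factor) * nm * cm + d1 * b1:.0f}] per 1000"
        )
    n1, n2 = x / c1, y / c2

    # --- PSA-arm tree -------------------------------------------------------
    p3 = t.p_psa_ge_3
    pp_psa = ((diag_psa - psa) / p3 - mri) / biopsy
    bx_psa = 1000.0 * p3 * pp_psa
    cancers_psa = n1 + n2 + nm

    # --- biomarker-arm tree -------------------------------------------------
    p15 = t.sthlm3_share_of_diag * diag_bio / s3
    pp_bio = t.p_pirads_sthlm3
    ps3 = (diag_bio - psa - p15 * s3) / (p15 * (mri + pp_bio * biopsy))
    bx_bio = 1000.0 * p15 * ps3 * pp_bio
    n1_b, n2_b, nm_b = n1 * f.isup1_factor, n2 * f.isup2_5_factor, nm * f.metastatic_factor
    cancers_bio = n1_b + n2_b + nm_b

    # --- SWOP tree ----------------------------------------------------------
    pp_swop = t.p_pirads_swop
    q_swop = ((diag_swop - psa) / p3 - trus) / (mri + pp_swop * biopsy)
    bx_swop = 1000.0 * p3 * q_swop * pp_swop
    fn_1 = (1.0 - t.swop_isup1_sensitivity) * n1
    # total spend target pins the false-negative clinically significant count:
    # spend = diag + (n1-fn_1) c1 + (n2-fn_cs) c2 + (nm + fr*fn_cs) cm
    denom = t.fn_progress_fraction * cm - c2
    spend_target = t.swop_total_per_1000 - 1000.0 * diag_swop
    fn_cs = (spend_target - (n1 - fn_1) * c1 - n2 * c2 - nm * cm) / denom
    n1_s, n2_s = n1 - fn_1, n2 - fn_cs
    cancers_swop = n1_s + n2_s + nm  # metastatic detection mirrors the PSA arm

    # --- feasibility and assembly -------------------------------------------
    checks = {
        "p_psa_ge_3": p3,
        "p_pirads_ge_3_given_referred.psa_mri": pp_psa,
        "p_psa_ge_1_5": p15,
        "p_sthlm3_ge_11_given_psa_1_5": ps3,
        "p_swop_referred_given_psa_ge_3": q_swop,
    }
    for path, value in checks.items():
        if not (0.0 <= value <= 1.0):
            raise CalibrationError(f"infeasible targets: implied {path} = {value:.4f} outside [0, 1]")
    for label, bx, cancers in (
        ("psa_mri", bx_psa, cancers_psa),
        ("sthlm3_reflex", bx_bio, cancers_bio),
        ("swop", bx_swop, cancers_swop),
    ):
        if bx < cancers - 1e-9:
            raise CalibrationError(
                f"infeasible targets: {label} biopsy volume {bx:.1f}/1000 below "
                f"implied cancer detections {cancers:.1f}/1000"
            )
    if fn_cs < -1e-9:
        raise CalibrationError("infeasible targets: SWOP false-negative count negative")

    def _outcome(bx: float, counts: tuple[float, float, float]) -> dict[str, float]:
        i1, i25, met = counts
        benign = bx - (i1 + i25 + met)
        out = {"benign": benign / bx, "isup1": i1 / bx, "isup2_5": i25 / bx,
               "metastatic": met / bx}
        # remove float residue so the distribution sums to 1 exactly
        out["benign"] = 1.0 - (out["isup1"] + out["isup2_5"] + out["metastatic"])
        return out

    table = DiagProbTable(
        p_psa_ge_3=p3,
        p_psa_ge_1_5=p15,
        p_sthlm3_ge_11_given_psa_1_5=ps3,
        p_swop_referred_given_psa_ge_3=q_swop,
        p_pirads_ge_3_given_referred={
            "psa_mri": pp_psa, "sthlm3_reflex": pp_bio, "swop": pp_swop,
        },
        biopsy_outcome={
            "psa_mri": _outcome(bx_psa, (n1, n2, nm)),
            "sthlm3_reflex": _outcome(bx_bio, (n1_b, n2_b, nm_b)),
            "swop": _outcome(bx_swop, (n1_s, n2_s, nm)),
        },
    )
    table.validate()
    return table


def build_default_parameter_set(
    targets: CalibrationTargets | None = None,
    seed: int | None = None,
) -> ParameterSet:
    """Assemble and calibrate the full default parameter set from targets."""
    t = targets or DEFAULT_TARGETS
    params = ParameterSet(
        costs=CostTable.defaults(),
        config=ModelConfig(),
        diag_probs=generate_diag_prob_table(t, seed),
        mix=TreatmentMix(),
        as_schedule=ASchedule(),
        localized_mix=LocalizedMix(),
        swop_fn_progress_fraction=t.fn_progress_fraction,
    ).validate()
    return calibrate(params, t.anchors)


# --------------------------------------------------------------------------
# Random parameter sets for property/fuzz testing
# --------------------------------------------------------------------------

def random_parameter_set(seed: int, ranges: dict | None = None) -> ParameterSet:
    """Draw a valid random parameter set (uniform within sensible ranges)."""
    rng = np.random.default_rng(seed)
    ranges = ranges or {}
    cost_lo, cost_hi = ranges.get("cost_scale", (0.5, 1.5))
    mult_lo, mult_hi = ranges.get("multiplier", (0.5, 2.0))

    costs = CostTable.defaults()
    for item in costs.items.values():
        item.unit_cost *= float(rng.uniform(cost_lo, cost_hi))

    p3 = float(rng.uniform(0.05, 0.5))
    p15 = float(rng.uniform(p3, min(1.0, p3 + 0.4)))

    def _dirichlet() -> dict[str, float]:
        w = rng.dirichlet((8.0, 4.0, 6.0, 1.5))
        out = {"benign": float(w[0]), "isup1": float(w[1]),
               "isup2_5": float(w[2]), "metastatic": float(w[3])}
        out["benign"] = 1.0 - (out["isup1"] + out["isup2_5"] + out["metastatic"])
        return out

    diag = DiagProbTable(
        p_psa_ge_3=p3,
        p_psa_ge_1_5=p15,
        p_sthlm3_ge_11_given_psa_1_5=float(rng.uniform(0.2, 0.95)),
        p_swop_referred_given_psa_ge_3=float(rng.uniform(0.2, 0.95)),
        p_pirads_ge_3_given_referred={s: float(rng.uniform(0.2, 0.9))
                                      for s in ("psa_mri", "sthlm3_reflex", "swop")},
        biopsy_outcome={s: _dirichlet() for s in ("psa_mri", "sthlm3_reflex", "swop")},
    )
    arpi = float(rng.uniform(0.5, 0.95))
    mix = TreatmentMix(
        arpi_fraction=arpi,
        taxane_only_fraction=1.0 - arpi,
        triplet_given_arpi_fraction=float(rng.uniform(0.0, 0.5)),
        parp_fraction=float(rng.uniform(0.0, 0.2)),
        immune_fraction=float(rng.uniform(0.0, 0.05)),
        radiopharm_fraction=float(rng.uniform(0.0, 0.5)),
        radiopharm_lu_split=float(rng.uniform(0.0, 1.0)),
        osteoprotective_fraction=float(rng.uniform(0.0, 0.6)),
        palliative_fraction=float(rng.uniform(0.2, 0.8)),
        eol_fraction=float(rng.uniform(0.1, 0.6)),
        discontinuation_year1=float(rng.uniform(0.0, 0.4)),
        discontinuation_increment=float(rng.uniform(0.0, 0.12)),
        calibration_multipliers={
            "as_surveillance": float(rng.uniform(mult_lo, mult_hi)),
            "localized_adt": float(rng.uniform(mult_lo, mult_hi)),
            "metastatic_intensity": float(rng.uniform(mult_lo, mult_hi)),
        },
    )
    w = float(rng.uniform(0.2, 0.8))
    loc = LocalizedMix(
        intermediate_fraction=float(rng.uniform(0.3, 0.8)),
        intermediate_weights={"rp": w, "rt_short_adt": 1.0 - w},
        high_weights={"rp_plnd": 1.0 - w, "rt_long_adt": w},
        adt_short_years=float(rng.uniform(0.25, 1.0)),
        adt_long_years=float(rng.uniform(1.0, 3.0)),
    )
    p_prog3 = float(rng.uniform(0.1, 0.4))
    sched = ASchedule(cum_progression={3: p_prog3, 5: min(1.0, p_prog3 + float(rng.uniform(0.0, 0.2)))})
    return ParameterSet(
        costs=costs, config=ModelConfig(), diag_probs=diag, mix=mix,
        as_schedule=sched, localized_mix=loc,
        swop_fn_progress_fraction=float(rng.uniform(0.0, 0.3)),
    ).validate()


# --------------------------------------------------------------------------
# Individual-level cost realizations (microsimulation building block)
# --------------------------------------------------------------------------

def sample_state_costs(
    state: str, n: int, params: ParameterSet, rng: np.random.Generator
) -> np.ndarray:
    """Sample per-patient six-year discounted *treatment* costs for one state.

    Uses the same annual schedules as the cohort model with Bernoulli line
    assignment, so the expectation equals the cohort-model state component
    exactly.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    cfg = params.config
    h = cfg.horizon_years
    d = discount_factors(h, cfg.discount_rate)
    costs = params.costs
    mult = params.mix.calibration_multipliers

    if state in ("benign", "no_workup"):
        return np.zeros(n)

    if state == "isup1":
        sched = params.as_schedule
        cum = sched.yearly_cum(h)
        delta = np.diff(np.concatenate(([0.0], cum)))
        p_never = 1.0 - cum[-1]
        probs = np.concatenate((delta, [p_never]))
        events = sched.events_per_year(h)
        surv = sum(nv * costs.unit(k) for k, nv in events.items()) * mult["as_surveillance"]
        surv = np.asarray(surv, dtype=float) * d
        # discounted surveillance paid before progression year y (cumulative)
        surv_before = np.concatenate(([0.0], np.cumsum(surv)))
        year = rng.choice(h + 1, size=n, p=probs / probs.sum())  # h == never progresses
        w_rp = sched.curative_mix.get("rp", 0.0)
        take_rp = rng.random(n) < w_rp
        cur_rp = costs.unit("rp")
        cur_rt = costs.unit("rt") + sched.curative_adt_years * costs.unit("adt")
        out = np.empty(n)
        progressed = year < h
        out[~progressed] = surv_before[h]
        y = year[progressed]
        cur = np.where(take_rp[progressed], cur_rp, cur_rt) * d[y]
        out[progressed] = surv_before[y] + cur
        return out

    if state == "isup2_5":
        loc = params.localized_mix
        m = mult["localized_adt"]
        adt = costs.unit("adt")

        def _arm_cost(upfront: float, adt_years: float) -> float:
            return float(upfront * d[0]
                         + mc._course_stream(adt, adt_years * m, h) @ d)

        atoms = np.array([
            _arm_cost(costs.unit("rp"), 0.0),
            _arm_cost(costs.unit("rt"), loc.adt_short_years),
            _arm_cost(costs.unit("rp") + costs.unit("plnd"), 0.0),
            _arm_cost(costs.unit("rt"), loc.adt_long_years),
        ])
        wi = loc.intermediate_fraction
        probs = np.array([
            wi * loc.intermediate_weights.get("rp", 0.0),
            wi * loc.intermediate_weights.get("rt_short_adt", 0.0),
            (1 - wi) * loc.high_weights.get("rp_plnd", 0.0),
            (1 - wi) * loc.high_weights.get("rt_long_adt", 0.0),
        ])
        idx = rng.choice(4, size=n, p=probs / probs.sum())
        return atoms[idx]

    if state == "metastatic":
        mix = params.mix
        m = mult["metastatic_intensity"]
        cum_off = mc._discontinuation(mix, h)
        # discontinuation year D: active in year t iff D > t
        p_d = np.diff(np.concatenate(([0.0], cum_off)))
        p_never = 1.0 - cum_off[-1]
        probs = np.concatenate((p_d, [p_never]))
        dyear = rng.choice(h + 1, size=n, p=probs / probs.sum())
        active = np.arange(h)[None, :] < dyear[:, None]          # (n, h)
        ad = active * d[None, :]

        adt_years = h if mix.adt_years is None else min(mix.adt_years, h)
        adt_mask = mc._course_stream(1.0, adt_years, h)
        out = ad @ (costs.unit("adt") * adt_mask)

        flags = {
            "arpi": rng.random(n) < mix.arpi_fraction,
            "parp": rng.random(n) < mix.parp_fraction,
            "immune": rng.random(n) < mix.immune_fraction,
            "radiopharm": rng.random(n) < mix.radiopharm_fraction,
            "lu": rng.random(n) < mix.radiopharm_lu_split,
            "osteo": rng.random(n) < mix.osteoprotective_fraction,
            "triplet": rng.random(n) < mix.triplet_given_arpi_fraction,
            "palliative": rng.random(n) < mix.palliative_fraction,
            "eol": rng.random(n) < mix.eol_fraction,
        }
        for key, years in (("arpi", mix.arpi_years), ("parp", mix.parp_years),
                           ("immune", mix.immune_years)):
            mask = mc._course_stream(1.0, years, h)
            out += flags[key] * (m * costs.unit(key) * (ad @ mask))

        chemo = flags["triplet"] & flags["arpi"] | ~flags["arpi"]
        out += chemo * (m * costs.unit("chemo_cycle") * d[0])

        window = min(mix.radiopharm_window_years, h)
        win_mask = np.zeros(h)
        win_mask[h - window:] = 1.0
        rp_cost = np.where(flags["lu"], costs.unit("lu_psma"), costs.unit("ra223"))
        out += flags["radiopharm"] * rp_cost * m * (ad @ win_mask)

        out += flags["osteo"] * costs.unit("osteoprotective") * (ad @ np.ones(h))

        if mix.psma_pet_at_diagnosis:
            out += costs.unit("psma_pet") * d[0]
        if mix.palliative_year <= h:
            out += flags["palliative"] * costs.unit("palliative") * d[mix.palliative_year - 1]
        if mix.eol_year <= h:
            out += flags["eol"] * costs.unit("end_of_life") * d[mix.eol_year - 1]
        return np.asarray(out, dtype=float)

    raise ParameterError(f"unknown state '{state}'")


@dataclass
class SyntheticCohort:
    """Individual-level cohort: per-man terminal state and 6-yr cost realization."""

    records: pd.DataFrame     # columns: state, cost
    seed: int

    @property
    def mean_cost(self) -> float:
        return float(self.records["cost"].mean())

    def state_counts(self) -> pd.Series:
        return self.records["state"].value_counts()


def generate_cohort(
    dist: StateDistribution,
    n: int,
    seed: int,
    params: ParameterSet | None = None,
) -> SyntheticCohort:
    """Multinomial draw of disease states plus per-man cost realizations.

    Diagnostic costs follow the per-state averaging convention (diseased and
    benign men carry the full cascade; no-workup men one PSA test), so the
    cohort mean converges to the state-cost-weighted analytic mean.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if params is None:
        from .parameters import load_parameters

        params = load_parameters("defaults")
    rng = np.random.default_rng(seed)
    names = list(dist.as_dict())
    p = np.array([dist.as_dict()[k] for k in names], dtype=float)
    p = p / p.sum()
    counts = rng.multinomial(n, p)
    cascade = mc.benign_cost(params.costs)
    psa_only = params.costs.unit("psa_test")

    states_col = []
    costs_col = []
    for name, k in zip(names, counts):
        if k == 0:
            continue
        treat = sample_state_costs(name, k, params, rng)
        diag = psa_only if name == "no_workup" else cascade
        states_col.append(np.full(k, name))
        costs_col.append(treat + diag)
    records = pd.DataFrame({
        "state": np.concatenate(states_col),
        "cost": np.concatenate(costs_col),
    })
    # fixed permutation so record order is not grouped by state
    perm = rng.permutation(len(records))
    records = records.iloc[perm].reset_index(drop=True)
    return SyntheticCohort(records=records, seed=seed)
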