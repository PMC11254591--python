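"""Model parameters: definitions, packaged defaults, validation, I/O, calibration.

The model is parameterised by

* a unit-cost table (consolidated average European costs for diagnostics,
  curative treatment, systemic therapy and supportive care),
* a diagnostic-probability table describing the decision trees of the three
  testing strategies,
* treatment-mix and schedule parameters for the four disease states, and
* a model configuration (horizon, annual discount rate, cohort size).

`calibrate` adjusts the three free intensity scalars (active-surveillance
intensity, ADT-course duration for localized disease, metastatic treatment
intensity) so that the modelled per-state six-year discounted costs hit the
published per-state cost anchors, by bracketed one-dimensional root finding
(the three states are cost-independent of each other).
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.optimize import brentq

__all__ = [
    "ParameterError",
    "CalibrationError",
    "CostItem",
    "CostTable",
    "ModelConfig",
    "TreatmentMix",
    "ASchedule",
    "LocalizedMix",
    "DiagProbTable",
    "ParameterSet",
    "TABLE1_COSTS",
    "REQUIRED_COST_KEYS",
    "DEFAULT_ANCHORS",
    "load_parameters",
    "save_parameters",
    "calibrate",
]


class ParameterError(ValueError):
    """Invalid or incomplete model parameters."""


class CalibrationError(RuntimeError):
    """A per-state cost anchor is unreachable within the multiplier bounds."""


#: Consolidated average European unit costs (EUR). ``basis`` states whether the
#: value is charged per event, per treatment-year, or once per full course.
TABLE1_COSTS: dict[str, dict] = {
    "psa_test":        {"unit_cost": 29.0,     "sd": 12.0,    "basis": "per_event"},
    "stockholm3":      {"unit_cost": 400.0,    "sd": None,    "basis": "per_event"},
    "mri":             {"unit_cost": 406.0,    "sd": 169.0,   "basis": "per_event"},
    "biopsy":          {"unit_cost": 1347.0,   "sd": 1540.0,  "basis": "per_event"},
    "rp":              {"unit_cost": 10832.0,  "sd": 3464.0,  "basis": "per_event"},
    "rt":              {"unit_cost": 7726.0,   "sd": 3334.0,  "basis": "per_event"},
    "plnd":            {"unit_cost": 1500.0,   "sd": None,    "basis": "per_event"},
    "adt":             {"unit_cost": 2370.0,   "sd": 1413.0,  "basis": "per_year"},
    "arpi":            {"unit_cost": 8905.0,   "sd": 18886.0, "basis": "per_year"},
    "chemo_cycle":     {"unit_cost": 15519.0,  "sd": 9476.0,  "basis": "total_course"},
    "immune":          {"unit_cost": 104264.0, "sd": 28046.0, "basis": "per_year"},
    "parp":            {"unit_cost": 51216.0,  "sd": 15444.0, "basis": "per_year"},
    "lu_psma":         {"unit_cost": 90106.0,  "sd": 36598.0, "basis": "per_year"},
    "ra223":           {"unit_cost": 25692.0,  "sd": 5825.0,  "basis": "per_year"},
    "psma_pet":        {"unit_cost": 1498.0,   "sd": 1209.0,  "basis": "per_event"},
    "osteoprotective": {"unit_cost": 1058.0,   "sd": 1031.0,  "basis": "per_year"},
    "palliative":      {"unit_cost": 27980.0,  "sd": 16067.0, "basis": "total_course"},
    "end_of_life":     {"unit_cost": 13939.0,  "sd": 13179.0, "basis": "total_course"},
    "trus":            {"unit_cost": 100.0,    "sd": None,    "basis": "per_event"},
}

REQUIRED_COST_KEYS = tuple(TABLE1_COSTS)

#: Published six-year per-state cost anchors, EUR per patient, diagnostics included
#: (benign, low grade, intermediate/high localized, metastatic).
DEFAULT_ANCHORS: tuple[float, float, float, float] = (2182.0, 10023.0, 13073.0, 271210.0)

STATES = ("benign", "isup1", "isup2_5", "metastatic")
STRATEGIES = ("psa_mri", "sthlm3_reflex", "swop")

_BASES = ("per_event", "per_year", "total_course")


def _check_fraction(value: float, path: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{path}: probability/fraction {value!r} outside [0, 1]")


@dataclass
class CostItem:
    name: str
    unit_cost: float
    sd: float | None = None
    basis: str = "per_event"

    def validate(self) -> None:
        if self.unit_cost < 0:
            raise ParameterError(f"costs.{self.name}.unit_cost: negative cost {self.unit_cost!r}")
        if self.sd is not None and self.sd < 0:
            raise ParameterError(f"costs.{self.name}.sd: negative sd {self.sd!r}")
        if self.basis not in _BASES:
            raise ParameterError(f"costs.{self.name}.basis: unknown basis {self.basis!r}")


@dataclass
class CostTable:
    items: dict[str, CostItem]

    @classmethod
    def defaults(cls) -> "CostTable":
        return cls({k: CostItem(name=k, **v) for k, v in TABLE1_COSTS.items()})

    def unit(self, name: str) -> float:
        try:
            return self.items[name].unit_cost
        except KeyError:
            raise ParameterError(f"incomplete cost table: missing key '{name}'") from None

    def __getitem__(self, name: str) -> CostItem:
        return self.items[name]

    def scaled(self, factor: float) -> "CostTable":
        out = copy.deepcopy(self)
        for item in out.items.values():
            item.unit_cost *= factor
        return out

    def validate(self) -> None:
        for key in REQUIRED_COST_KEYS:
            if key not in self.items:
                raise ParameterError(f"incomplete cost table: missing key '{key}'")
        for item in self.items.values():
            item.validate()


@dataclass
class ModelConfig:
    horizon_years: int = 6
    discount_rate: float = 0.03
    cycle_length: float = 1.0
    cohort_size: float = 1000.0

    def validate(self) -> None:
        if self.horizon_years < 1:
            raise ParameterError(f"config.horizon_years: must be >= 1, got {self.horizon_years}")
        if self.discount_rate < 0:
            raise ParameterError(f"config.discount_rate: negative rate {self.discount_rate!r}")
        if self.cycle_length != 1.0:
            raise ParameterError("config.cycle_length: only annual cycles are supported")
        if self.cohort_size <= 0:
            raise ParameterError("config.cohort_size: must be positive")


@dataclass
class TreatmentMix:
    """Metastatic treatment mix, schedules and the free calibration scalars."""

    arpi_fraction: float = 0.80
    triplet_given_arpi_fraction: float = 0.25
    taxane_only_fraction: float = 0.20
    parp_fraction: float = 0.09
    immune_fraction: float = 0.01
    radiopharm_fraction: float = 0.30
    radiopharm_lu_split: float = 0.50
    osteoprotective_fraction: float = 0.33
    palliative_fraction: float = 0.50
    eol_fraction: float = 0.35
    discontinuation_year1: float = 0.30
    discontinuation_increment: float = 0.10
    # base systemic line durations, years (before the horizon cap)
    arpi_years: float = 3.0
    parp_years: float = 3.0
    immune_years: float = 3.0
    adt_years: float | None = None          # None -> full horizon backbone
    radiopharm_window_years: int = 2        # final N model years
    palliative_year: int = 5
    eol_year: int = 6
    psma_pet_at_diagnosis: bool = True
    calibration_multipliers: dict[str, float] = field(
        default_factory=lambda: {
            "as_surveillance": 1.0,
            "localized_adt": 1.0,
            "metastatic_intensity": 1.0,
        }
    )

    def validate(self) -> None:
        fractions = {
            "mix.arpi_fraction": self.arpi_fraction,
            "mix.triplet_given_arpi_fraction": self.triplet_given_arpi_fraction,
            "mix.taxane_only_fraction": self.taxane_only_fraction,
            "mix.parp_fraction": self.parp_fraction,
            "mix.immune_fraction": self.immune_fraction,
            "mix.radiopharm_fraction": self.radiopharm_fraction,
            "mix.radiopharm_lu_split": self.radiopharm_lu_split,
            "mix.osteoprotective_fraction": self.osteoprotective_fraction,
            "mix.palliative_fraction": self.palliative_fraction,
            "mix.eol_fraction": self.eol_fraction,
            "mix.discontinuation_year1": self.discontinuation_year1,
            "mix.discontinuation_increment": self.discontinuation_increment,
        }
        for path, value in fractions.items():
            _check_fraction(value, path)
        if abs(self.arpi_fraction + self.taxane_only_fraction - 1.0) > 1e-9:
            raise ParameterError(
                "mix: arpi_fraction + taxane_only_fraction must equal 1 "
                f"(got {self.arpi_fraction} + {self.taxane_only_fraction})"
            )
        for line in ("arpi_years", "parp_years", "immune_years"):
            if getattr(self, line) < 0:
                raise ParameterError(f"mix.{line}: negative duration")
        for key, value in self.calibration_multipliers.items():
            if value <= 0:
                raise ParameterError(f"mix.calibration_multipliers.{key}: must be positive")


@dataclass
class ASchedule:
    """Active-surveillance schedule for low-grade (ISUP 1) disease.

    ``cum_progression`` maps model year to the cumulative fraction that has
    progressed to curative treatment; between anchors the fraction is linearly
    interpolated, before the first anchor it is zero and after the last it is
    flat. Surveillance events are counts per year; the first year is the most
    intensive, matching clinical practice.
    """

    cum_progression: dict[int, float] = field(default_factory=lambda: {3: 0.25, 5: 0.35})
    psa_per_year: tuple[float, ...] = (3, 2, 2, 2, 2, 2)
    mri_per_year: tuple[float, ...] = (1, 0, 1, 0, 1, 0)
    biopsy_per_year: tuple[float, ...] = (1, 0, 1, 0, 0, 0)
    curative_mix: dict[str, float] = field(default_factory=lambda: {"rp": 0.5, "rt_short_adt": 0.5})
    curative_adt_years: float = 0.5

    def yearly_cum(self, horizon: int) -> np.ndarray:
        years = sorted(self.cum_progression)
        vals = [self.cum_progression[y] for y in years]
        prev = 0.0
        for v in vals:
            _check_fraction(v, "as_schedule.cum_progression")
            if v < prev - 1e-12:
                raise ParameterError("as_schedule.cum_progression: must be nondecreasing")
            prev = v
        t = np.arange(1, horizon + 1, dtype=float)
        out = np.interp(t, years, vals, left=0.0, right=vals[-1])
        out[t < years[0]] = 0.0
        return out

    def events_per_year(self, horizon: int) -> dict[str, np.ndarray]:
        def _pad(seq):
            arr = np.zeros(horizon)
            take = min(horizon, len(seq))
            arr[:take] = seq[:take]
            return arr

        return {"psa_test": _pad(self.psa_per_year), "mri": _pad(self.mri_per_year),
                "biopsy": _pad(self.biopsy_per_year)}

    def validate(self) -> None:
        self.yearly_cum(6)
        total = sum(self.curative_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError("as_schedule.curative_mix: weights must sum to 1")
        for k in self.curative_mix:
            if k not in ("rp", "rt_short_adt"):
                raise ParameterError(f"as_schedule.curative_mix: unknown arm '{k}'")
        if self.curative_adt_years < 0:
            raise ParameterError("as_schedule.curative_adt_years: negative course length")


@dataclass
class LocalizedMix:
    """Treatment mix for intermediate- to high-grade localized disease.

    Intermediate-grade disease receives radical prostatectomy (RP) or radiation
    therapy (RT) with an abbreviated ADT course; high-grade disease receives RP
    with pelvic lymph-node dissection or RT with an extended ADT course.
    """

    intermediate_fraction: float = 0.60
    intermediate_weights: dict[str, float] = field(default_factory=lambda: {"rp": 0.5, "rt_short_adt": 0.5})
    high_weights: dict[str, float] = field(default_factory=lambda: {"rp_plnd": 0.5, "rt_long_adt": 0.5})
    adt_short_years: float = 0.5
    adt_long_years: float = 2.0

    def validate(self) -> None:
        _check_fraction(self.intermediate_fraction, "localized_mix.intermediate_fraction")
        for arm, weights, allowed in (
            ("intermediate_weights", self.intermediate_weights, ("rp", "rt_short_adt")),
            ("high_weights", self.high_weights, ("rp_plnd", "rt_long_adt")),
        ):
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ParameterError(f"localized_mix.{arm}: weights must sum to 1")
            for k in weights:
                if k not in allowed:
                    raise ParameterError(f"localized_mix.{arm}: unknown arm '{k}'")
        if self.adt_short_years < 0 or self.adt_long_years < 0:
            raise ParameterError("localized_mix: negative ADT course length")


@dataclass
class DiagProbTable:
    """Branch probabilities of the diagnostic decision trees.

    Threshold-crossing probabilities are shared across strategies (the same
    tested population); the MRI yield and the biopsy outcome distribution over
    {benign, isup1, isup2_5, metastatic} are per strategy.
    """

    p_psa_ge_3: float
    p_psa_ge_1_5: float
    p_sthlm3_ge_11_given_psa_1_5: float
    p_swop_referred_given_psa_ge_3: float
    p_pirads_ge_3_given_referred: dict[str, float]
    biopsy_outcome: dict[str, dict[str, float]]

    def validate(self) -> None:
        _check_fraction(self.p_psa_ge_3, "diag_probs.p_psa_ge_3")
        _check_fraction(self.p_psa_ge_1_5, "diag_probs.p_psa_ge_1_5")
        _check_fraction(self.p_sthlm3_ge_11_given_psa_1_5, "diag_probs.p_sthlm3_ge_11_given_psa_1_5")
        _check_fraction(self.p_swop_referred_given_psa_ge_3, "diag_probs.p_swop_referred_given_psa_ge_3")
        if self.p_psa_ge_1_5 < self.p_psa_ge_3 - 1e-12:
            raise ParameterError(
                "diag_probs: nested thresholds violated, p_psa_ge_1_5 "
                f"({self.p_psa_ge_1_5}) < p_psa_ge_3 ({self.p_psa_ge_3})"
            )
        for strat, p in self.p_pirads_ge_3_given_referred.items():
            _check_fraction(p, f"diag_probs.p_pirads_ge_3_given_referred.{strat}")
        for strat, dist in self.biopsy_outcome.items():
            total = 0.0
            for state, p in dist.items():
                if state not in STATES:
                    raise ParameterError(f"diag_probs.biopsy_outcome.{strat}: unknown state '{state}'")
                _check_fraction(p, f"diag_probs.biopsy_outcome.{strat}.{state}")
                total += p
            if abs(total - 1.0) > 1e-12:
                raise ParameterError(
                    f"diag_probs.biopsy_outcome.{strat}: distribution sums to {total!r}, not 1"
                )


@dataclass
class ParameterSet:
    costs: CostTable
    config: ModelConfig
    diag_probs: DiagProbTable
    mix: TreatmentMix
    as_schedule: ASchedule
    localized_mix: LocalizedMix
    swop_fn_progress_fraction: float = 0.10

    def validate(self) -> "ParameterSet":
        self.costs.validate()
        self.config.validate()
        self.diag_probs.validate()
        self.mix.validate()
        self.as_schedule.validate()
        self.localized_mix.validate()
        _check_fraction(self.swop_fn_progress_fraction, "swop_fn_progress_fraction")
        return self

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "costs": {
                k: {"unit_cost": i.unit_cost, "sd": i.sd, "basis": i.basis}
                for k, i in self.costs.items.items()
            },
            "config": {
                "horizon_years": self.config.horizon_years,
                "discount_rate": self.config.discount_rate,
                "cycle_length": self.config.cycle_length,
                "cohort_size": self.config.cohort_size,
            },
            "strategies": {
                "diag_probs": {
                    "p_psa_ge_3": self.diag_probs.p_psa_ge_3,
                    "p_psa_ge_1_5": self.diag_probs.p_psa_ge_1_5,
                    "p_sthlm3_ge_11_given_psa_1_5": self.diag_probs.p_sthlm3_ge_11_given_psa_1_5,
                    "p_swop_referred_given_psa_ge_3": self.diag_probs.p_swop_referred_given_psa_ge_3,
                    "p_pirads_ge_3_given_referred": dict(self.diag_probs.p_pirads_ge_3_given_referred),
                    "biopsy_outcome": {s: dict(d) for s, d in self.diag_probs.biopsy_outcome.items()},
                },
                "swop_fn_progress_fraction": self.swop_fn_progress_fraction,
            },
            "mix": {
                "arpi_fraction": self.mix.arpi_fraction,
                "triplet_given_arpi_fraction": self.mix.triplet_given_arpi_fraction,
                "taxane_only_fraction": self.mix.taxane_only_fraction,
                "parp_fraction": self.mix.parp_fraction,
                "immune_fraction": self.mix.immune_fraction,
                "radiopharm_fraction": self.mix.radiopharm_fraction,
                "radiopharm_lu_split": self.mix.radiopharm_lu_split,
                "osteoprotective_fraction": self.mix.osteoprotective_fraction,
                "palliative_fraction": self.mix.palliative_fraction,
                "eol_fraction": self.mix.eol_fraction,
                "discontinuation_year1": self.mix.discontinuation_year1,
                "discontinuation_increment": self.mix.discontinuation_increment,
                "arpi_years": self.mix.arpi_years,
                "parp_years": self.mix.parp_years,
                "immune_years": self.mix.immune_years,
                "adt_years": self.mix.adt_years,
                "radiopharm_window_years": self.mix.radiopharm_window_years,
                "palliative_year": self.mix.palliative_year,
                "eol_year": self.mix.eol_year,
                "psma_pet_at_diagnosis": self.mix.psma_pet_at_diagnosis,
                "calibration_multipliers": dict(self.mix.calibration_multipliers),
            },
            "schedules": {
                "active_surveillance": {
                    "cum_progression": {int(k): v for k, v in self.as_schedule.cum_progression.items()},
                    "psa_per_year": list(self.as_schedule.psa_per_year),
                    "mri_per_year": list(self.as_schedule.mri_per_year),
                    "biopsy_per_year": list(self.as_schedule.biopsy_per_year),
                    "curative_mix": dict(self.as_schedule.curative_mix),
                    "curative_adt_years": self.as_schedule.curative_adt_years,
                },
                "localized": {
                    "intermediate_fraction": self.localized_mix.intermediate_fraction,
                    "intermediate_weights": dict(self.localized_mix.intermediate_weights),
                    "high_weights": dict(self.localized_mix.high_weights),
                    "adt_short_years": self.localized_mix.adt_short_years,
                    "adt_long_years": self.localized_mix.adt_long_years,
                },
            },
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ParameterSet":
        try:
            costs = CostTable(
                {k: CostItem(name=k, **v) for k, v in doc["costs"].items()}
            )
            cfg = ModelConfig(**doc["config"])
            strat = doc["strategies"]
            dp = strat["diag_probs"]
            diag = DiagProbTable(
                p_psa_ge_3=dp["p_psa_ge_3"],
                p_psa_ge_1_5=dp["p_psa_ge_1_5"],
                p_sthlm3_ge_11_given_psa_1_5=dp["p_sthlm3_ge_11_given_psa_1_5"],
                p_swop_referred_given_psa_ge_3=dp["p_swop_referred_given_psa_ge_3"],
                p_pirads_ge_3_given_referred=dict(dp["p_pirads_ge_3_given_referred"]),
                biopsy_outcome={s: dict(d) for s, d in dp["biopsy_outcome"].items()},
            )
            mix = TreatmentMix(**doc["mix"])
            sched = doc["schedules"]
            asched = ASchedule(
                cum_progression={int(k): v for k, v in sched["active_surveillance"]["cum_progression"].items()},
                psa_per_year=tuple(sched["active_surveillance"]["psa_per_year"]),
                mri_per_year=tuple(sched["active_surveillance"]["mri_per_year"]),
                biopsy_per_year=tuple(sched["active_surveillance"]["biopsy_per_year"]),
                curative_mix=dict(sched["active_surveillance"]["curative_mix"]),
                curative_adt_years=sched["active_surveillance"]["curative_adt_years"],
            )
            loc = LocalizedMix(**sched["localized"])
        except KeyError as exc:
            raise ParameterError(f"parameter document missing section/field: {exc}") from None
        params = cls(
            costs=costs, config=cfg, diag_probs=diag, mix=mix,
            as_schedule=asched, localized_mix=loc,
            swop_fn_progress_fraction=strat.get("swop_fn_progress_fraction", 0.10),
        )
        return params.validate()

    def save(self, path: str | Path) -> None:
        save_parameters(self, path)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    path = Path(path)
    doc = params.to_dict()
    if path.suffix.lower() == ".json":
        import json

        path.write_text(json.dumps(doc, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=True))


def load_parameters(source: str | Path | Mapping = "defaults") -> ParameterSet:
    """Load and validate a parameter set.

    ``source`` may be the string ``"defaults"`` (the packaged calibrated set),
    a YAML/JSON file path, or an already-parsed mapping.
    """
    if isinstance(source, Mapping):
        return ParameterSet.from_dict(source)
    if str(source) == "defaults":
        text = resources.files("pccost.data").joinpath("defaults.yaml").read_text()
        return ParameterSet.from_dict(yaml.safe_load(text))
    path = Path(source)
    if not path.exists():
        raise ParameterError(f"parameter source not found: {source}")
    if path.suffix.lower() == ".json":
        import json

        return ParameterSet.from_dict(json.loads(path.read_text()))
    return ParameterSet.from_dict(yaml.safe_load(path.read_text()))


# --------------------------------------------------------------------------
# Calibration to the per-state cost anchors
# --------------------------------------------------------------------------

MULTIPLIER_BOUNDS = (0.01, 100.0)

_STATE_TO_MULT = {
    "isup1": "as_surveillance",
    "isup2_5": "localized_adt",
    "metastatic": "metastatic_intensity",
}


def _as_anchor_map(anchors) -> dict[str, float]:
    if isinstance(anchors, Mapping):
        return {s: float(anchors[s]) for s in STATES}
    vals = list(anchors)
    if len(vals) != 4:
        raise ParameterError("anchors must supply four per-state target costs")
    return dict(zip(STATES, (float(v) for v in vals)))


def calibrate(params: ParameterSet, anchors=DEFAULT_ANCHORS) -> ParameterSet:
    """Return a copy of ``params`` whose free scalars reproduce the anchors.

    Each anchor is the total six-year discounted per-patient cost of one
    disease state, diagnostics included. The benign anchor has no free scalar
    (it is the diagnostic cascade itself) and is verified; each remaining state
    is solved independently by Brent root finding on its multiplier within
    ``MULTIPLIER_BOUNDS``.
    """
    from . import markov_cohort as mc

    target = _as_anchor_map(anchors)
    for state, value in target.items():
        if value <= 0:
            raise ParameterError(f"anchors.{state}: must be positive")
    out = params.copy().validate()

    cascade = mc.benign_cost(out.costs)
    if abs(cascade - target["benign"]) > 1.0:
        raise CalibrationError(
            "benign state has no free scalar: diagnostic cascade costs "
            f"{cascade:.2f}, anchor is {target['benign']:.2f}"
        )

    for state, mult_key in _STATE_TO_MULT.items():
        def modelled(m: float, _state=state, _key=mult_key) -> float:
            trial = out.mix.calibration_multipliers.copy()
            trial[_key] = m
            return mc.state_cost(out, _state, multipliers=trial) - target[_state]

        lo, hi = MULTIPLIER_BOUNDS
        f_lo, f_hi = modelled(lo), modelled(hi)
        if f_lo * f_hi > 0:
            reachable = sorted((f_lo + target[state], f_hi + target[state]))
            raise CalibrationError(
                f"calibration out of range for state '{state}': anchor "
                f"{target[state]:.2f} outside achievable interval "
                f"[{reachable[0]:.2f}, {reachable[1]:.2f}]"
            )
        root = brentq(modelled, lo, hi, xtol=1e-10, rtol=8.9e-16)
        out.mix.calibration_multipliers[mult_key] = float(root)

    return out
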