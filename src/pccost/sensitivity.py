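"""One-way deterministic sensitivity analysis (tornado table).

Each parameter is varied one at a time, by default 30% above and below its
baseline value, holding everything else fixed; the outcome is the net saving
per man of the comparator strategy versus the baseline strategy. Rows are
sorted by descending outcome range (stable, so exact ties keep the default
spec order).

Perturbed monetary values are truncated to whole euros before re-evaluation
(the reporting resolution of the cost inputs); perturbed probabilities are
clamped to [0, 1] with a warning.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

from . import markov_cohort as mc
from .comparison import Scenario, compare
from .parameters import ParameterError, ParameterSet
from .util import truncate_euro

__all__ = [
    "PerturbationSpec",
    "TornadoRow",
    "scale_parameter",
    "default_specs",
    "one_way_dsa",
]


def scale_parameter(value: float, delta: float, mode: str = "none") -> float:
    """Scale a value by (1 + delta); optionally truncate to whole euros.

    Probabilities (values in [0, 1] with ``mode='none'``) that leave [0, 1]
    are clamped with a warning.
    """
    out = value * (1.0 + delta)
    if mode == "truncate_euro":
        return truncate_euro(out)
    if mode == "none":
        if 0.0 <= value <= 1.0 and out > 1.0:
            warnings.warn(
                f"perturbed probability {out:.4f} clamped to 1.0", stacklevel=2
            )
            return 1.0
        return out
    raise ParameterError(f"unknown scaling mode '{mode}'")


@dataclass
class PerturbationSpec:
    """One tornado parameter.

    ``kind`` selects how the perturbation enters the model:

    * ``component`` — override the treatment-only cost of ``target`` state
      with explicit low/high values (euro-truncated scaling of the baseline);
    * ``count_scale`` — scale the detected count of ``target`` state in both
      arms (stage migration applies on top);
    * ``diag_scale`` — scale all diagnostic test costs.
    """

    name: str
    kind: str
    target: str | None = None
    rel: float = 0.30
    low: float | None = None
    high: float | None = None
    mode: str = "none"

    def bounds(self, baseline: float | None = None) -> tuple[float, float]:
        if self.low is not None and self.high is not None:
            if not self.low < self.high:
                raise ParameterError(f"spec '{self.name}': low must be < high")
            return self.low, self.high
        if self.kind == "component":
            if baseline is None:
                raise ParameterError(f"spec '{self.name}': baseline required")
            return (
                scale_parameter(baseline, -self.rel, self.mode),
                scale_parameter(baseline, +self.rel, self.mode),
            )
        return 1.0 - self.rel, 1.0 + self.rel


@dataclass
class TornadoRow:
    parameter: str
    low_value: float
    high_value: float
    outcome_low: float
    outcome_high: float

    @property
    def range(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def default_specs() -> list[PerturbationSpec]:
    """Default tornado parameters: treatment costs, detection proportions,
    diagnostic costs, each varied +/-30% around baseline."""
    return [
        PerturbationSpec("metastatic_treatment_cost", "component",
                         target="metastatic", mode="truncate_euro"),
        PerturbationSpec("mpc_proportion", "count_scale", target="metastatic"),
        PerturbationSpec("diagnostic_costs", "diag_scale"),
        PerturbationSpec("localized_treatment_cost", "component",
                         target="isup2_5", mode="truncate_euro"),
        PerturbationSpec("isup2_5_proportion", "count_scale", target="isup2_5"),
        PerturbationSpec("lowgrade_treatment_cost", "component",
                         target="isup1", mode="truncate_euro"),
        PerturbationSpec("isup1_proportion", "count_scale", target="isup1"),
    ]


def _scenario_for(spec: PerturbationSpec, value: float) -> Scenario:
    if spec.kind == "component":
        return Scenario(component_overrides={spec.target: value})
    if spec.kind == "count_scale":
        return Scenario(count_scale={spec.target: value})
    if spec.kind == "diag_scale":
        return Scenario(diag_scale=value)
    raise ParameterError(f"unresolvable perturbation kind '{spec.kind}' in spec '{spec.name}'")


def one_way_dsa(
    params: ParameterSet,
    specs: list[PerturbationSpec] | None = None,
    baseline_strategy: str = "psa_mri",
    comparator_strategy: str = "sthlm3_reflex",
) -> list[TornadoRow]:
    """Re-evaluate the strategy comparison at each spec's low and high values.

    Returns tornado rows (outcome = saving per man, unrounded) sorted by
    descending range.
    """
    specs = default_specs() if specs is None else specs
    components = mc.state_components(params)
    rows = []
    for spec in specs:
        baseline = components.get(spec.target) if spec.kind == "component" else None
        lo, hi = spec.bounds(baseline)
        outcomes = []
        for value in (lo, hi):
            result = compare(
                params, baseline_strategy, comparator_strategy,
                scenario=_scenario_for(spec, value),
            )
            outcomes.append(result.saving_per_man)
        rows.append(TornadoRow(spec.name, lo, hi, outcomes[0], outcomes[1]))
    rows.sort(key=lambda r: -r.range)
    return rows
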