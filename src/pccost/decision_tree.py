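"""Diagnostic decision trees: expected per-man cost and disease-state counts.

Three testing strategies are modelled as small binary trees over threshold
tests, each node charging its unit cost to every man who reaches it:

* ``psa_mri`` — PSA for all; PSA >= 3 ng/ml prompts MRI; PI-RADS >= 3 prompts
  biopsy.
* ``sthlm3_reflex`` — PSA for all; Stockholm3 reflex at PSA >= 1.5 ng/ml;
  Stockholm3 >= 11 prompts MRI; PI-RADS >= 3 prompts biopsy.
* ``swop`` — PSA for all; at PSA >= 3 a risk-calculator work-up (TRUS prostate
  volume measurement) gates MRI referral; PI-RADS >= 3 prompts biopsy.

Biopsy outcomes distribute men over the four disease states; men leaving the
tree earlier fall into the "no further workup" category. The recursive
evaluator is checked in the test suite against exhaustive root-to-leaf path
enumeration (`enumerate_paths`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Union

from .parameters import CostTable, DiagProbTable, ParameterError

__all__ = [
    "Leaf",
    "TestNode",
    "OutcomeNode",
    "StrategyDefinition",
    "STRATEGIES",
    "StateDistribution",
    "MigrationFactors",
    "get_strategy",
    "build_tree",
    "expected_diagnostic_cost",
    "state_distribution",
    "enumerate_paths",
    "apply_stage_migration",
    "rescale_state",
    "swop_distribution",
]

TERMINALS = ("no_workup", "benign", "isup1", "isup2_5", "metastatic")
DISEASE_STATES = ("benign", "isup1", "isup2_5", "metastatic")


@dataclass
class Leaf:
    state: str


@dataclass
class TestNode:
    """A test with a unit cost and a binary branch on its result."""

    name: str
    cost_key: str
    p_positive: float
    positive: "Node"
    negative: "Node"


@dataclass
class OutcomeNode:
    """A terminal test (biopsy) distributing men over disease states."""

    name: str
    cost_key: str
    outcome: dict[str, float]


Node = Union[Leaf, TestNode, OutcomeNode]


@dataclass
class StrategyDefinition:
    """Named diagnostic strategy with a tree builder over a probability table."""

    name: str
    build: Callable[[DiagProbTable], Node] = field(repr=False)


def _psa_tree(p: DiagProbTable) -> Node:
    return TestNode(
        "psa", "psa_test", p.p_psa_ge_3,
        positive=TestNode(
            "mri", "mri", p.p_pirads_ge_3_given_referred["psa_mri"],
            positive=OutcomeNode("biopsy", "biopsy", p.biopsy_outcome["psa_mri"]),
            negative=Leaf("no_workup"),
        ),
        negative=Leaf("no_workup"),
    )


def _sthlm3_tree(p: DiagProbTable) -> Node:
    return TestNode(
        "psa", "psa_test", p.p_psa_ge_1_5,
        positive=TestNode(
            "sthlm3", "stockholm3", p.p_sthlm3_ge_11_given_psa_1_5,
            positive=TestNode(
                "mri", "mri", p.p_pirads_ge_3_given_referred["sthlm3_reflex"],
                positive=OutcomeNode("biopsy", "biopsy", p.biopsy_outcome["sthlm3_reflex"]),
                negative=Leaf("no_workup"),
            ),
            negative=Leaf("no_workup"),
        ),
        negative=Leaf("no_workup"),
    )


def _swop_tree(p: DiagProbTable) -> Node:
    return TestNode(
        "psa", "psa_test", p.p_psa_ge_3,
        positive=TestNode(
            "risk_calc", "trus", p.p_swop_referred_given_psa_ge_3,
            positive=TestNode(
                "mri", "mri", p.p_pirads_ge_3_given_referred["swop"],
                positive=OutcomeNode("biopsy", "biopsy", p.biopsy_outcome["swop"]),
                negative=Leaf("no_workup"),
            ),
            negative=Leaf("no_workup"),
        ),
        negative=Leaf("no_workup"),
    )


STRATEGIES: dict[str, StrategyDefinition] = {
    "psa_mri": StrategyDefinition("psa_mri", _psa_tree),
    "sthlm3_reflex": StrategyDefinition("sthlm3_reflex", _sthlm3_tree),
    "swop": StrategyDefinition("swop", _swop_tree),
}

_ALIASES = {"psa": "psa_mri", "sthlm3": "sthlm3_reflex", "stockholm3": "sthlm3_reflex"}


def get_strategy(name: str | StrategyDefinition) -> StrategyDefinition:
    if isinstance(name, StrategyDefinition):
        return name
    key = _ALIASES.get(name, name)
    try:
        return STRATEGIES[key]
    except KeyError:
        raise ParameterError(
            f"unknown strategy '{name}' (expected one of {sorted(STRATEGIES)})"
        ) from None


def build_tree(strategy: str | StrategyDefinition, probs: DiagProbTable) -> Node:
    return get_strategy(strategy).build(probs)


def _validate_node(node: Node, costs: CostTable) -> None:
    if isinstance(node, Leaf):
        if node.state not in TERMINALS:
            raise ParameterError(f"dangling branch: unknown terminal '{node.state}'")
        return
    if isinstance(node, OutcomeNode):
        costs.unit(node.cost_key)  # raises on unknown key
        total = sum(node.outcome.values())
        if abs(total - 1.0) > 1e-12:
            raise ParameterError(f"{node.name}: outcome distribution sums to {total!r}")
        for state in node.outcome:
            if state not in DISEASE_STATES:
                raise ParameterError(f"{node.name}: unknown outcome state '{state}'")
        return
    if isinstance(node, TestNode):
        costs.unit(node.cost_key)
        if not (0.0 <= node.p_positive <= 1.0):
            raise ParameterError(f"{node.name}: branch probability outside [0, 1]")
        _validate_node(node.positive, costs)
        _validate_node(node.negative, costs)
        return
    raise ParameterError(f"dangling branch: node {node!r} has no terminal")


def enumerate_paths(node: Node, costs: CostTable) -> Iterator[tuple[float, float, str]]:
    """Yield (probability, cost, terminal state) for every root-to-leaf path."""
    if isinstance(node, Leaf):
        yield 1.0, 0.0, node.state
    elif isinstance(node, OutcomeNode):
        c = costs.unit(node.cost_key)
        for state, p in node.outcome.items():
            if p > 0.0 or True:  # keep zero-probability leaves for exhaustiveness
                yield p, c, state
    elif isinstance(node, TestNode):
        c = costs.unit(node.cost_key)
        for p_branch, child in ((node.p_positive, node.positive),
                                (1.0 - node.p_positive, node.negative)):
            for p, cost, state in enumerate_paths(child, costs):
                yield p_branch * p, c + cost, state
    else:
        raise ParameterError(f"dangling branch: node {node!r} has no terminal")


def _evaluate(node: Node, costs: CostTable, breakdown: dict[str, float], reach: float):
    """Recursive evaluation: (expected cost, state probabilities) below ``node``."""
    if isinstance(node, Leaf):
        return 0.0, {node.state: 1.0}
    if isinstance(node, OutcomeNode):
        c = costs.unit(node.cost_key)
        breakdown[node.name] = breakdown.get(node.name, 0.0) + reach * c
        return c, dict(node.outcome)
    c = costs.unit(node.cost_key)
    breakdown[node.name] = breakdown.get(node.name, 0.0) + reach * c
    exp_cost = c
    dist: dict[str, float] = {}
    for p_branch, child in ((node.p_positive, node.positive),
                            (1.0 - node.p_positive, node.negative)):
        sub_cost, sub_dist = _evaluate(child, costs, breakdown, reach * p_branch)
        exp_cost += p_branch * sub_cost
        for state, p in sub_dist.items():
            dist[state] = dist.get(state, 0.0) + p_branch * p
    return exp_cost, dist


def expected_diagnostic_cost(
    strategy: str | StrategyDefinition,
    probs: DiagProbTable,
    costs: CostTable,
) -> tuple[float, dict[str, float]]:
    """Expected diagnostic cost per man tested, with a per-test breakdown.

    The breakdown maps each test name to its expected per-man contribution;
    contributions sum to the total.
    """
    tree = build_tree(strategy, probs)
    _validate_node(tree, costs)
    breakdown: dict[str, float] = {}
    total, _ = _evaluate(tree, costs, breakdown, 1.0)
    return total, breakdown


@dataclass
class StateDistribution:
    """Counts of men per cohort (default 1000 tested) in each terminal category."""

    no_workup: float
    benign: float
    isup1: float
    isup2_5: float
    metastatic: float
    cohort: float = 1000.0

    def as_dict(self) -> dict[str, float]:
        return {
            "no_workup": self.no_workup,
            "benign": self.benign,
            "isup1": self.isup1,
            "isup2_5": self.isup2_5,
            "metastatic": self.metastatic,
        }

    @property
    def total(self) -> float:
        return sum(self.as_dict().values())

    def validate(self) -> "StateDistribution":
        for k, v in self.as_dict().items():
            if v < -1e-9:
                raise ParameterError(f"state distribution: negative count for '{k}'")
        if abs(self.total - self.cohort) > 1e-9:
            raise ParameterError(
                f"state distribution sums to {self.total!r}, expected {self.cohort!r}"
            )
        return self


def state_distribution(
    strategy: str | StrategyDefinition,
    probs: DiagProbTable,
    cohort: float = 1000.0,
) -> StateDistribution:
    """Per-cohort counts in each terminal category, by path enumeration."""
    tree = build_tree(strategy, probs)
    counts = dict.fromkeys(TERMINALS, 0.0)
    # cost table irrelevant for counts; reuse enumeration with a permissive table
    for p, _cost, state in enumerate_paths(tree, _ZERO_COSTS):
        counts[state] += p * cohort
    return StateDistribution(cohort=cohort, **counts).validate()


class _ZeroCosts:
    def unit(self, name: str) -> float:  # pragma: no cover - trivial
        return 0.0


_ZERO_COSTS = _ZeroCosts()


@dataclass
class MigrationFactors:
    """Multiplicative stage-migration factors applied to detected cancer counts.

    Defaults encode the registry-observed stage shift under the
    biomarker-enhanced pathway: 46% fewer ISUP 1 cancers, 24% more ISUP 2-5
    cancers, 16% fewer metastatic cancers.
    """

    isup1_factor: float = 0.54
    isup2_5_factor: float = 1.24
    metastatic_factor: float = 0.84

    def validate(self) -> None:
        for name in ("isup1_factor", "isup2_5_factor", "metastatic_factor"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"migration.{name}: must be positive")


def apply_stage_migration(
    base: StateDistribution,
    factors: MigrationFactors | None = None,
    absorb: str = "benign",
) -> StateDistribution:
    """Scale cancer-state counts by the migration factors, conserving the cohort.

    The net change in cancer counts is absorbed by the ``absorb`` category
    (benign by default: men not diagnosed with cancer return to the
    no-cancer pool).
    """
    f = factors or MigrationFactors()
    f.validate()
    base.validate()
    new = {
        "isup1": base.isup1 * f.isup1_factor,
        "isup2_5": base.isup2_5 * f.isup2_5_factor,
        "metastatic": base.metastatic * f.metastatic_factor,
    }
    net = (base.isup1 + base.isup2_5 + base.metastatic) - sum(new.values())
    counts = base.as_dict() | new
    counts[absorb] = counts[absorb] + net
    if counts[absorb] < -1e-9:
        raise ParameterError(
            f"stage migration drives absorbing category '{absorb}' negative "
            f"({counts[absorb]:.3f})"
        )
    return StateDistribution(cohort=base.cohort, **counts).validate()


def rescale_state(
    dist: StateDistribution, state: str, factor: float, absorb: str = "benign"
) -> StateDistribution:
    """Scale one state's count by ``factor``, absorbing the change elsewhere."""
    if state == absorb:
        raise ParameterError("cannot rescale the absorbing category")
    counts = dist.as_dict()
    delta = counts[state] * (factor - 1.0)
    counts[state] += delta
    counts[absorb] -= delta
    if counts[absorb] < -1e-9:
        raise ParameterError(f"rescaling drives absorbing category '{absorb}' negative")
    return StateDistribution(cohort=dist.cohort, **counts).validate()


def swop_distribution(
    psa_dist: StateDistribution,
    swop_probs: DiagProbTable,
    fn_progress_fraction: float,
    costs: CostTable | None = None,
) -> tuple[StateDistribution, float]:
    """Disease-state distribution and per-man diagnostic cost of the SWOP variant.

    The metastatic count mirrors the PSA strategy's, plus the stated fraction
    of SWOP false-negative clinically significant cases projected to progress
    to metastatic disease within the horizon. False negatives are cases the
    PSA pathway detects but the risk-calculator gating does not; progressors
    move out of the no-workup pool.
    """
    if not (0.0 <= fn_progress_fraction <= 1.0):
        raise ParameterError("fn_progress_fraction must be in [0, 1]")
    base = state_distribution("swop", swop_probs, cohort=psa_dist.cohort)
    fn_cs = psa_dist.isup2_5 - base.isup2_5
    if fn_cs < -1e-9:
        raise ParameterError(
            "SWOP false-negative count exceeds available cases: SWOP detects more "
            f"ISUP 2-5 cancers ({base.isup2_5:.3f}) than the PSA pathway ({psa_dist.isup2_5:.3f})"
        )
    fn_cs = max(fn_cs, 0.0)
    progressed = fn_progress_fraction * fn_cs
    counts = base.as_dict()
    counts["metastatic"] = psa_dist.metastatic + progressed
    # metastatic detection mirrors the PSA arm; adjust the no-workup pool so the
    # cohort is conserved
    counts["no_workup"] -= (counts["metastatic"] - base.metastatic)
    if counts["no_workup"] < -1e-9:
        raise ParameterError("SWOP progression exceeds the undiagnosed pool")
    dist = StateDistribution(cohort=base.cohort, **counts).validate()

    diag_cost = float("nan")
    if costs is not None:
        diag_cost, _ = expected_diagnostic_cost("swop", swop_probs, costs)
    return dist, diag_cost
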