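# Methods

This note documents the model implemented in `pccost`: its structure,
assumptions, parameter defaults, calibration, the synthetic-data
construction, numerical conventions, and known limitations.

## Scope and perspective

The model takes a health-sector perspective on direct costs of prostate-cancer
diagnosis and treatment over a six-year horizon, per 1000 men undergoing
opportunistic testing, in euros (consolidated average European unit costs).
It compares diagnostic strategies only through (a) their diagnostic spend and
(b) the disease-state distribution they induce. Out of scope by design:
QALYs, mortality as an explicit state, age structure, adverse effects,
comorbidities, indirect costs, country-specific cost tables, and
probabilistic sensitivity analysis.

## Diagnostic decision trees

Each strategy is a chain of threshold tests; each node charges its unit cost
to every man reaching it. Expected per-man cost and per-1000 state counts are
computed by recursive evaluation and verified in the test suite against
exhaustive root-to-leaf enumeration (≤ 16 leaves). Men below the first
threshold incur only the PSA test cost; the model assumes a steady-state
system of interval testing captured as a six-year cross-section, so no
repeat-testing costs accrue within the horizon.

Stage migration is applied to *detected cancer counts* per 1000 tested
(ISUP 1 × 0.54, ISUP 2–5 × 1.24, metastatic × 0.84); the net change in cancer
detections is absorbed by the benign (no-cancer) pool, a configurable choice
(`absorb=`). The factors act on counts per 1000 tested, not per 1000
diagnosed — consistent with the 0.84 factor reproducing the published
metastatic-spend reduction (3.50 → 2.94 M€/1000).

## Disease-state cost model

Annual cycles, no half-cycle correction (all quantities are stated
per year); year-1 costs undiscounted, later years discounted at 3%/yr.

Per-state cost anchors (€2 182 benign, €10 023 low grade, €13 073
intermediate/high localized, €271 210 metastatic) are interpreted as
*including* the diagnostic cascade PSA + Stockholm3 + MRI + biopsy
(29 + 400 + 406 + 1347 = 2 182 matches the benign anchor exactly, which
motivates the decomposition). The treatment-only component of a state is
therefore anchor − 2 182; strategy totals add the strategy-specific
decision-tree diagnostic spend instead of the fixed cascade, so the
diagnostic cost difference between arms is fully reflected.

**Low-grade (ISUP 1), active surveillance.** Cumulative progression to
curative treatment: 0 in years 1–2, 25% at year 3, linearly interpolated to
35% at year 5, flat in year 6. Progressing fractions incur the curative mix
(50% RP, 50% RT + 0.5 yr ADT) in the progression year and stop surveillance.
Surveillance events default to 3 PSA + 1 MRI + 1 biopsy in year 1, 2 PSA/yr
with MRI every other year and a year-3 biopsy thereafter, scaled by the
calibrated intensity multiplier (1.316 at the packaged defaults).

**Localized (ISUP 2–5).** 60% intermediate grade (RP, or RT + short 0.5-yr
ADT course, 50/50), 40% high grade (RP + pelvic lymphadenectomy, or RT +
extended 2-yr ADT course, 50/50). The calibration multiplier scales the ADT
course durations (1.018 at the packaged defaults); fractional course years
spill into the following model year pro rata.

**Metastatic.** Cohort fractions: 80% ARPI (25% of whom also receive a
triplet docetaxel course), 20% taxane-only chemotherapy, 9% PARP inhibitor,
1% immune therapy, 30% radiopharmaceutical therapy (50/50 Lu-PSMA/Ra-223)
restricted to model years 5–6, 33% osteoprotective support, 50% palliative
care (year 5), 35% end-of-life care (year 6); PSMA-PET staging at diagnosis.
Chemotherapy's "full cycle cost" (€15 519) is taken as one complete course,
charged once at diagnosis. Discontinuation is interpreted as a *cumulative*
fraction off systemic therapy — 30% by end of year 1, +10 percentage points
per later year (30/40/50/60/70/80%), clamped at 100% with a warning —
attenuating all recurring line costs but not one-time items (upfront
chemotherapy, staging PET, palliative, end-of-life).

**Metastatic calibration scalar.** The published €269 028 treatment
component exceeds by ~4× what the stated mix yields at Table-unit prices
with any line durations inside the horizon, so a duration multiplier cannot
reach the anchor. The calibration scalar is therefore a *treatment-intensity*
multiplier scaling the annual costs of the named therapy lines (ARPI,
chemotherapy, PARP, immune, radiopharmaceutical) — equivalently, cycles or
dispensings per year — leaving the ADT backbone, supportive and terminal care
at list intensity. The component is then linear and strictly increasing in
the multiplier; the packaged calibrated value is 6.731 (e.g. effective ARPI
spend ≈ €60k/yr, in the range of contemporary list prices).

**Calibration.** Each treated state's cost is independent of the others'
multipliers, so calibration is three bracketed one-dimensional Brent solves
on [0.01, 100] (xtol 1e-10); an unreachable anchor raises an error reporting
the achievable interval. The benign anchor has no free scalar and is
verified to within €1. Calibration is idempotent to < 1e-9 relative.

## Synthetic diagnostic tables

The branch probabilities are synthesized so the decision trees reproduce the
published aggregates; each aggregate pins one degree of freedom and the
system solves in closed form (no iteration):

* PSA-arm diagnostic cost per man = gap / relative gap = 151/0.42 = €359.52;
  biomarker arm = €510.52.
* Stockholm3's 35% share of biomarker-arm diagnostic spend fixes
  P(PSA ≥ 1.5) = 0.35 × 510.52 / 400 = 0.447.
* The PSA-arm strategy total (€4 676/man) and the net saving (€358 239/1000)
  are two linear constraints on the ISUP 1 and ISUP 2–5 detection counts
  given the treatment components and migration factors: n₁ = 26.65,
  n₂ = 56.03 per 1000 (metastatic count 13.0 = 3.50 M€/€269 028).
* Biomarker-arm cancer counts are the stage-migrated PSA counts; the benign
  biopsy count is whatever the (cost-pinned) biopsy volume leaves over, so
  the benign/no-workup split differs from a literal migrated distribution.
* SWOP: the 43% diagnostic-cost reduction versus the PSA arm fixes its
  referral rate (and is mutually consistent with the published 60% reduction
  versus the biomarker arm); the published total €4 787 048/1000 then pins
  the number of clinically significant cancers the risk-calculator gating
  misses (19.9/1000, of which 10% progress to metastatic disease within the
  horizon). Missed cases that do not progress accrue no treatment cost.

Three pathway quantities are not pinned by any published aggregate and are
fixed as defaults: P(PSA ≥ 3) = 0.35 (opportunistically tested, largely
older men), MRI yield P(PI-RADS ≥ 3) = 0.45 in the biomarker-enriched group
and 0.75 after risk-calculator selection (each gate enriches the referred
population). Changing them re-allocates probability along the tree without
moving any calibrated aggregate. The resulting implied quantities are
clinically plausible: ~140 biopsies/1000 (PSA arm) with ~68% cancer yield.

The generator raises a calibration error, reporting the violated feasibility
condition, when targets are inconsistent (e.g. implied cancer detections
exceeding the biopsy volume, or probabilities outside [0, 1]).

## Microsimulation and statistical comparison

Per-man six-year costs are simulated by drawing each man's path through the
diagnostic tree stage by stage, then, for diseased men, an individual
treatment realization using the same annual schedules as the cohort model
with Bernoulli line assignment (progression year, discontinuation year,
treatment arm, line flags). Expectations therefore equal the cohort-model
values by construction; at n = 200 000 per state the sampled state means
agree with the cohort components to well within 0.5%. The whole-cohort
per-man mean carries binomial noise from the metastatic count
(SE ≈ 1.4% of the mean at n = 200 000), so tests of that mean use
Monte-Carlo error bounds rather than a fixed percentage.

The published analysis does not state what constitutes the Mann–Whitney
samples; here they are defined as microsimulated per-man six-year discounted
costs, n = 1000 per arm at the packaged seed (20240625). The U statistic is
computed by rank summation with midranks; the two-sided p-value is exact
(lattice-path enumeration of the null distribution) for n_a·n_b ≤ 400
without ties, otherwise a normal approximation with tie and continuity
corrections; all values identical across both samples gives p = 1 by
convention. At the packaged seed the arm comparison gives p ≈ 4×10⁻⁶; across
seeds p fluctuates in roughly the 10⁻⁷–10⁻² range, i.e. the comparison is
significant at α = 0.05 for essentially all seeds and below 0.001 for most.

## Sensitivity analysis

One parameter at a time is varied ±30% around baseline, everything else
held fixed; the outcome is the saving per man of the biomarker strategy
versus the PSA strategy. Perturbed monetary components are truncated to
whole euros (reproducing the published metastatic bounds €188 319/€349 736);
perturbed probabilities are clamped to [0, 1] with a warning. Rows are
sorted by descending range with a stable sort. The default specs perturb the
metastatic treatment component, the metastatic presentation proportion (both
arms proportionally), all diagnostic unit costs, the localized and low-grade
components, and the ISUP 1/ISUP 2–5 detection proportions. The top two rows
— metastatic treatment cost (range €335.75) and metastatic proportion
(€335.75) — are near-exact ties, as expected since both enter the saving
through the same linear term; the published account likewise names them
first and second. An alternative named spec varying the net metastatic
decrease over 11–21% is available via `PerturbationSpec` explicitly.

## Numerical and reporting conventions

Monetary values are carried at full float precision; reported aggregates are
truncated to whole euros (with a 10⁻⁶ epsilon absorbing float representation
error); percentages are reported to one decimal, ties rounded half-up.
Currency is EUR throughout; no exchange-rate handling. All random draws use
`numpy.random.default_rng` with explicit seeds; identical seeds give
bitwise-identical cohorts and byte-identical JSON reports (reports contain
no timestamps).

## What the synthetic defaults do and do not show

The synthesized tables reproduce every published aggregate simultaneously,
so downstream results (savings, tornado, SWOP premium) are exact
consequences of the published figures plus the documented pathway
assumptions — not of registry data. They do not emulate individual PSA value
distributions, PI-RADS category-specific yields, re-testing intervals, or
age stratification; passing tests demonstrate internal consistency and
faithful arithmetic, not external validity of the diagnostic probabilities.
Costs beyond six years (in particular continued metastatic treatment) are
censored; death is implicit in the discontinuation/palliative fractions.
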