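# Methods

This note records the modelling assumptions, parameter defaults and design
choices behind `pedsirs`, and what the synthetic-cohort tests do and do not
demonstrate about real data.

## Time, days and stays

All timestamps live on a single timezone-naive clock (ISO-8601 in files);
no timezone or DST arithmetic is performed, which is appropriate for a
single-site deployment. A *calendar day* is midnight-to-midnight of that
clock; a *patient-day* is one calendar date intersecting the half-open stay
window `[admit, discharge)`, so a discharge exactly at midnight does not
open a new day. Reference episodes still open at discharge are truncated at
discharge for every day- and episode-level computation. Units are fixed per
variable (°C, /min, 10³/µL, fraction); unit conversion is deliberately out
of scope — it belongs to the extract-transform layer feeding the cohort
files, not to the method.

## Threshold table

The four SIRS criteria are evaluated against an age-banded limit table
shipped as an editable YAML file (`data/ipscc_2005.yaml`) transcribing the
2005 pediatric consensus values; the engine treats the table strictly as
data and validates its structure on load (bands must partition 0–18 years).
The printed consensus bands leave gaps in their labels ("1 mo to 1 yr",
then "2–5 yr"); we implement the conventional contiguous half-open partition
[0 d, 7 d), [7 d, 30 d), [30 d, 2 y), [2 y, 6 y), [6 y, 13 y), [13 y, 18 y).
Comparators are **exclusive** by default (a value must be strictly beyond a
limit to fire), making boundary behavior deterministic and testable; an
inclusive mode exists. Bradycardia applies only to bands flagged as such
(infants under one year). The left-shift trigger fires when the immature
neutrophil fraction exceeds 0.10.

## Sample-and-hold and unknowns

Monitoring values are point samples; rules need values over intervals. A
measurement is held from its timestamp until the next measurement or a
validity horizon — **4 h for vitals, 24 h for laboratory values** by
default, reflecting monitoring vs lab cadence; both are configurable.
While a variable is unknown its criterion cannot fire, and unknown never
counts toward the 2-of-4 rule: the conservative reading, treating data
gaps as an error source rather than as evidence. Observations that failed
manual validation are used by default; a strict mode drops them so both
behaviors can be compared.

## Context rules

* Hypothermia does not fire during active-cooling intervals (device-induced
  low temperature is not inflammation); the whole low-temperature sub-rule
  can be disabled for the ablation analysis.
* Heart rate does not fire while a pacemaker is active.
* During mechanical ventilation, measured respiratory rates are never
  compared against limits; the respiratory criterion instead fires on
  ventilated intervals flagged *acute*. This is the corrected form of the
  ventilation/respiratory-rate interaction.

## Episodes and days

Raw SIRS intervals separated by gaps **< 24 h** merge into one episode whose
end is the last instant criteria were fulfilled (not the start of the
closing gap). Episodes spanning less than **60 min** are discarded by
default — this aligns flicker suppression with the day rule and can be set
to 0. "At least one full hour per day" is read as **cumulative ≥ 60 SIRS
minutes within the calendar date** (the weaker, more sensitive reading); a
contiguous-run mode is available behind a flag, and minutes that straddle
midnight are accounted per date under either reading. Day minutes are exact
interval arithmetic rounded to the minute.

## Stay-level scheme and matching

Detected episodes match reference episodes one-to-one when their starts lie
within ±4 h (inclusive). Matching is greedy in reference-start order,
taking the nearest admissible unmatched detected start with ties broken
toward the earlier one. Greedy nearest-start matching can in principle drop
a feasible pair when several detected starts crowd inside one tolerance
window (a frozen example lives in the test suite); with episodes separated
by the 24-h closing rule this cannot occur, and the suite verifies greedy
optimality under realistic separation. A stay with at least one matched
episode never also contributes a false negative — the six-case scheme has
no TP+FN combination, so unmatched extra reference episodes are absorbed;
this TP precedence is intentional and prominent. Cases 5 (FN+FP) and 6
(FP+TP) contribute two assessment units each, so the stay-level table total
exceeds the stay count.

## Estimation

Sensitivity and specificity are marginal proportions of clustered binary
units; **clusters are patients** (not stays) at both levels, because a
quarter of patients have multiple stays. The GEE is intercept-only
logistic with exchangeable working correlation. The estimating equation has
the closed form expit(β) = Σ wᵢȲᵢ / Σ wᵢ with wᵢ = nᵢ/(1 + (nᵢ−1)α), so we
iterate: solve β given α, re-estimate α from Pearson-residual
cross-products (moment estimator with one-parameter degrees-of-freedom
correction), until β is stable to 10⁻¹²; after convergence β is re-solved
exactly at the final α so the reported estimating-equation residual is at
machine precision. The sandwich variance reduces to
Σ wᵢ²(Ȳᵢ−μ)² / (μ(1−μ) Σ wᵢ)², which equals the binomial variance for
singleton clusters and makes the estimate the pooled mean for equal cluster
sizes. CIs are Wald with z = 1.96, symmetric **on the logit scale** and
back-transformed (a linear-scale variant exists for comparison). Strata
with all-identical outcomes return the boundary estimate 0 or 1 with a
flagged degenerate zero-width CI instead of raising — perfect detectors are
a legitimate, testable outcome. Endpoint verdicts compare the GEE CI lower
bound to configurable null values (0.90 sensitivity, 0.80 specificity);
no multiplicity adjustment is applied, as the two endpoints are co-primary,
each against its own null.

Missing routine-assessment days are handled by complete-case analysis plus
deterministic bounds: the best case imputes every missing
reference-positive day as TP and reference-negative day as TN, the worst
case as FN and FP; the crude point estimates therefore bracket the
complete-case value by construction. Per-shift forms collapse to day level
by an any-positive rule (positive if any non-missing shift form is
positive; negative if all are negative; missing if none exists) — the
study's collapsing rule is unstated, so this documented choice is explicit.

Sample sizes use the one-sample normal-approximation (chi-square
equivalent) formula without continuity correction,
n = ⌈(z₁₋α/2 √(p₀q₀) + z_power √(p₁q₁))² / (p₁−p₀)²⌉. For the specificity
design (0.80 vs 0.90, α = 0.05, power 0.90) this gives 137. For the
sensitivity design (0.90 vs 0.98) it gives 93; published plans sometimes
report slightly larger figures from exact-binomial or continuity-corrected
procedures, so the planner exposes its formula explicitly rather than
guessing a software default.

## Synthetic cohorts

The generator's defaults encode the study conditions: 168 patients with the
observed age-band mix (11 %, 6 %, 36 %, 26 %, 15 %, 7 %), mean stay length
12 days, 25 % of patients with a second stay, ≈ 0.9 injected episodes per
stay, hourly vitals and daily labs. Baselines sit midway between the active
threshold table's limits, so generator and engine stay consistent if the
table changes; noise is Gaussian, truncated strictly inside the normal band
in clean mode, with limits taken conservatively across the hold window so a
value never becomes abnormal merely because an age-band boundary passes
while it is held. Episodes are aligned to the sampling grid, separated by
> 26 h, driven by a mandatory criterion (temperature or leukocytes) plus
one other, and realized by abnormal *held* values — including laboratory
draws pinned to episode bounds, as happens clinically at deterioration —
so detection recovers each injected window exactly. Context intervals are
placed clear of episode windows so suppression rules cannot mask injected
episodes. Tests and the acceptance script run desk-scale versions of these
conditions (10–30 patients for cohort work; 200 stays × 10 days ≈ 2,000
patient-days for rater recovery), which the package treats as its standard
worked-example sizes.

What clean-mode perfection shows: the interval algebra, rule logic and
evaluation plumbing are exact. What it does not show: performance on real
monitoring data, whose artifacts (sensor noise, borderline values,
device-induced physiology, validation errors, irregular cadence) are only
partially emulated by the borderline-rate and context machinery, and whose
reference standards are themselves imperfect. The published headline
accuracy figures arise from such data and are not reproducible from
synthetic cohorts; the package instead verifies every analytic and
table-assembly quantity that is reproducible, and validates the stochastic
machinery by parameter recovery (a simulated rater with sensitivity 62 %,
specificity 83 % and 36 % missing days is recovered within Monte-Carlo
error, with GEE CI coverage close to nominal).

## Numerical conventions and degenerate inputs

Intervals are half-open `[start, end)` throughout; outputs are normalized
to sorted disjoint form. Where criterion directions overlap after context
subtraction, labeling priority is high > low > context (the union, which is
all the combination rule uses, is unaffected). Empty strata are reported as
empty rather than raising; zero denominators raise estimation errors at the
crude level but are guarded in report assembly. Seeds are mandatory in the
generator; per-operation substreams are derived from (seed, fixed label)
so adding an operation never perturbs another's draws.

## Known limitations

* Greedy episode matching is not a maximum-cardinality assignment in
  adversarial configurations (see above).
* The exchangeable-correlation moment estimator differs from other GEE
  implementations in small degrees-of-freedom conventions; point estimates
  agree with `statsmodels` to ~10⁻³ on desk-scale data (cross-checked in
  tests), exact agreement is not a goal.
* No organ-dysfunction grading, severity scoring, microbiology, fuzzy
  borderline handling, or real-time/streaming operation.
* The day-level rule applies to calendar dates; cross-midnight qualifying
  hours are split between dates by construction, under either reading of
  the one-hour rule.
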