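# pedsirs

Rule-based detection of **systemic inflammatory response syndrome (SIRS)** in
pediatric intensive-care (PICU) time series, together with the full
diagnostic-accuracy machinery needed to evaluate such a detector — or a human
rater — against an adjudicated reference standard, and a synthetic-cohort
generator so the entire pipeline can be exercised with known ground truth.

It is aimed at clinical-informatics and biostatistics groups building or
validating knowledge-based early-warning rules on routine PICU monitoring
data.

## The method

**Detection.** Pediatric SIRS is defined by the IPSCC consensus as the
presence of at least two of four criteria — abnormal body temperature,
leukocyte count (or neutrophil left shift), heart rate, and respiratory rate,
each against age-specific limits — of which one must be temperature or
leukocytes. `pedsirs` evaluates each criterion as a boolean step function
over continuous time: point measurements are extended by sample-and-hold
(4 h for vitals, 24 h for labs, configurable), compared against an editable
age-banded threshold table, and modified by clinical context (hypothermia is
suppressed during active cooling; heart rate during pacemaker activity;
measured respiratory rates are not interpreted during mechanical
ventilation, where the criterion instead fires on acute ventilation).
Raw SIRS intervals become **episodes** via the study's closing rule — an
episode ends only after ≥ 24 h without criteria — and **SIRS-positive
patient-days** via the one-full-hour-per-day rule.

**Evaluation.** Each PICU stay is classified into one of six cases (FP, TP,
FN, TN, FN+FP, FP+TP) from a one-to-one matching of detected to reference
episode starts within ±4 h; combined cases contribute two assessment units.
Days are classified TP/FP/FN/TN directly. Sensitivity and specificity are
estimated as marginal proportions by an intercept-only logistic GEE with
exchangeable working correlation, clustered on patients,

&nbsp;&nbsp;&nbsp;&nbsp;logit P(Y<sub>ij</sub> = 1) = β,&nbsp;&nbsp;
Corr(Y<sub>ij</sub>, Y<sub>ik</sub>) = α,

with robust (sandwich) standard errors and Wald 95 % CIs on the logit scale.
Secondary analyses: age subgroups (< / ≥ 12 months), a hypothermia-rule
ablation, specificity among patients with no SIRS at all, best/worst-case
bounds for missing routine assessments, and one-proportion sample-size
planning.

## Worked example

```python
from pedsirs import (CohortScenario, detect, evaluate, generate_cohort,
                     load_thresholds)

cohort, reference, truth_days = generate_cohort(CohortScenario(seed=7, n_patients=12))
states = detect(cohort, load_thresholds())
report = evaluate(cohort, states)
print("stay cases", report["stay_level"]["cases"])
print("day table ", report["day_level"]["table"])
```

prints

```
stay cases {1: 0, 2: 8, 3: 0, 4: 7, 5: 0, 6: 0}
day table  {'tp': 18, 'fp': 0, 'fn': 0, 'tn': 227, 'level': 'day', 'detected_positive': 18,
            'detected_negative': 227, 'reference_positive': 18, 'reference_negative': 227, 'total': 245}
```

— on this noise-free cohort all 8 stays with injected SIRS episodes are true
positives (case 2), the other 7 are true negatives (case 4), and all 18
SIRS-positive patient-days are recovered with no false positives, i.e.
sensitivity = specificity = 1 at both levels (reported with degenerate,
flagged CIs).

The same pipeline is available from the shell:

```bash
pedsirs simulate --out-dir cohort/ --seed 7 --n-patients 12
pedsirs detect   --cohort-dir cohort/ --out-dir detected/
pedsirs evaluate --cohort-dir cohort/ --out report.json --with-routine
pedsirs samplesize
```

## Layout

- `src/pedsirs/cohort.py` — cohort schema, CSV readers/writers, patient-day enumeration
- `src/pedsirs/thresholds.py`, `src/pedsirs/data/ipscc_2005.yaml` — age-banded limits (data, not code)
- `src/pedsirs/rules.py` — sample-and-hold, criterion evaluation, 2-of-4 combination
- `src/pedsirs/timeline.py` — episode closing rule, day labeling
- `src/pedsirs/accuracy.py` — matching, six-case scheme, contingency tables, evaluation pipeline
- `src/pedsirs/estimation.py` — crude/GEE estimation, Wald CIs, sample size
- `src/pedsirs/synth.py` — synthetic cohorts, simulated raters, missingness
- `src/pedsirs/cli.py` — `pedsirs` command-line interface
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
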