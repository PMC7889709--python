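"""Diagnostic-accuracy evaluation against the adjudicated reference standard.

Stay level: each PICU stay is assigned one of six cases — (1) false positive,
(2) true positive, (3) false negative, (4) true negative, (5) false negative
and false positive, (6) false positive and true positive — from a one-to-one
matching of detected to reference episodes within a ±4 h window on the
episode start. Cases 5 and 6 contribute two assessment units; a stay with a
matched episode never also contributes a false negative (the six-case scheme
has no TP+FN combination — extra unmatched reference episodes are absorbed).

Day level: each patient-day is classified TP/FP/FN/TN from the (reference,
detected) SIRS-positive booleans.

Sensitivity and specificity are estimated crudely (binomial) and by
intercept-only logistic GEE with exchangeable working correlation, clustered
on patients, with Wald 95% CIs on the logit scale (see ``estimation``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .cohort import Cohort
from .estimation import AccuracyEstimate, crude_estimate, gee_estimate
from .rules import DetectorConfig, SirsState, detect
from .thresholds import ThresholdTable
from .timeline import SirsEpisode, build_episodes, label_days, reference_day_labels

CASE_CELLS = {
    1: ("FP",),
    2: ("TP",),
    3: ("FN",),
    4: ("TN",),
    5: ("FN", "FP"),
    6: ("FP", "TP"),
}
_CELLS_TO_CASE = {frozenset(v): k for k, v in CASE_CELLS.items()}


@dataclass
class Matching:
    pairs: list[tuple[int, int]]
    unmatched_reference: list[int]
    unmatched_detected: list[int]


@dataclass
class StayAssessment:
    stay_id: str
    patient_id: str
    case: int

    @property
    def contributes(self) -> tuple[str, ...]:
        return CASE_CELLS[self.case]


@dataclass
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int
    level: str  # 'stay' | 'day'

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def marginals(self) -> dict:
        return {
            "detected_positive": self.tp + self.fp,
            "detected_negative": self.fn + self.tn,
            "reference_positive": self.tp + self.fn,
            "reference_negative": self.fp + self.tn,
            "total": self.total,
        }

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                "level": self.level, **self.marginals()}


def match_episodes(
    reference_starts: list[pd.Timestamp],
    detected_starts: list[pd.Timestamp],
    tolerance: pd.Timedelta = pd.Timedelta(hours=4),
) -> Matching:
    """Greedy one-to-one matching of episode starts within ±tolerance.

    Reference episodes are processed in start order; each takes the nearest
    admissible unmatched detected start (|Δ| ≤ tolerance, inclusive), ties
    broken toward the earlier detected start.
    """
    if tolerance < pd.Timedelta(0):
        raise ValueError("tolerance must be non-negative")
    ref_order = sorted(range(len(reference_starts)), key=lambda i: reference_starts[i])
    det_order = sorted(range(len(detected_starts)), key=lambda j: detected_starts[j])
    free = set(det_order)
    pairs = []
    for i in ref_order:
        best = None
        for j in det_order:
            if j not in free:
                continue
            delta = abs(detected_starts[j] - reference_starts[i])
            if delta <= tolerance and (best is None or delta < best[0]):
                best = (delta, j)  # det_order scan makes ties favor earlier start
        if best is not None:
            pairs.append((i, best[1]))
            free.discard(best[1])
    matched_ref = {i for i, _ in pairs}
    return Matching(
        pairs=sorted(pairs),
        unmatched_reference=[i for i in range(len(reference_starts)) if i not in matched_ref],
        unmatched_detected=sorted(free),
    )


def classify_stay(
    matching: Matching, n_reference: int, n_detected: int,
    stay_id: str = "", patient_id: str = "",
) -> StayAssessment:
    """Map one stay's episode matching to the six-case scheme."""
    if len(matching.pairs) + len(matching.unmatched_reference) != n_reference:
        raise ValueError("matching inconsistent with reference episode count")
    if len(matching.pairs) + len(matching.unmatched_detected) != n_detected:
        raise ValueError("matching inconsistent with detected episode count")
    cells = set()
    if matching.pairs:
        cells.add("TP")
    elif n_reference:
        cells.add("FN")
    if matching.unmatched_detected:
        cells.add("FP")
    if not cells:
        cells.add("TN")
    case = _CELLS_TO_CASE[frozenset(cells)]
    return StayAssessment(stay_id, patient_id, case)


def stay_contingency(assessments: list[StayAssessment]) -> ContingencyTable:
    """Assemble the stay-level table: tp = #case2+#case6, fn = #case3+#case5,
    fp = #case1+#case5+#case6, tn = #case4. Combined cases contribute two
    assessment units, so total = #stays + #case5 + #case6."""
    c = {k: sum(1 for a in assessments if a.case == k) for k in range(1, 7)}
    return ContingencyTable(
        tp=c[2] + c[6], fn=c[3] + c[5], fp=c[1] + c[5] + c[6], tn=c[4], level="stay"
    )


def day_contingency(reference_days: pd.DataFrame, detected_days: pd.DataFrame) -> ContingencyTable:
    """Classify each patient-day from the (reference, detected) label pair."""
    ref = reference_days.set_index(["stay_id", "date"])["sirs_positive"]
    det = detected_days.set_index(["stay_id", "date"])["sirs_positive"]
    if not ref.index.sort_values().equals(det.index.sort_values()):
        raise ValueError("reference and detected day grids do not align")
    det = det.reindex(ref.index)
    return ContingencyTable(
        tp=int((ref & det).sum()),
        fp=int((~ref & det).sum()),
        fn=int((ref & ~det).sum()),
        tn=int((~ref & ~det).sum()),
        level="day",
    )


@dataclass(frozen=True)
class EvalConfig:
    tolerance: pd.Timedelta = pd.Timedelta(hours=4)
    ci_scale: str = "logit"
    contiguous_day_rule: bool = False
    null_sensitivity: float = 0.90
    null_specificity: float = 0.80
    age_cutoff_months: float = 12.0


def _estimates(units: list[tuple[str, int]], measure: str, ci_scale: str) -> dict:
    """Crude + GEE estimates from (cluster, outcome) units; empty-safe."""
    if not units:
        return {"n_units": 0, "empty": True}
    clusters = [c for c, _ in units]
    y = [v for _, v in units]
    crude = crude_estimate(sum(y), len(y) - sum(y), measure, ci_scale)
    gee = gee_estimate(y, clusters, measure, ci_scale)
    return {"crude": crude.as_dict(), "gee": gee.as_dict(), "empty": False}


def _verdict(est: dict, null: float) -> dict:
    if est.get("empty"):
        return {"null": null, "reject": None}
    g = est["gee"]
    return {"null": null, "ci_low": g["ci_low"], "reject": bool(g["ci_low"] > null)}


def evaluate(
    cohort: Cohort,
    detected_states: dict[str, SirsState],
    config: EvalConfig = EvalConfig(),
) -> dict:
    """Full accuracy report for a detector output against the reference standard.

    Returns a JSON-serializable dict with stay-level and day-level sections;
    clusters are patients at both levels.
    """
    stays = cohort.stays
    patient_of = dict(zip(stays["stay_id"], stays["patient_id"]))
    ref_eps = cohort.reference_episodes

    assessments: list[StayAssessment] = []
    ref_day_frames, det_day_frames = [], []
    for stay in stays.itertuples():
        state = detected_states.get(stay.stay_id, SirsState())
        det_episodes = build_episodes(state)
        sel = ref_eps[ref_eps["stay_id"] == stay.stay_id].sort_values("start")
        ref_starts = list(sel["start"])
        det_starts = [ep.start for ep in det_episodes]
        m = match_episodes(ref_starts, det_starts, config.tolerance)
        assessments.append(
            classify_stay(m, len(ref_starts), len(det_starts), stay.stay_id, stay.patient_id)
        )
        ref_day_frames.append(
            reference_day_labels(ref_eps, stay.stay_id, stay.admit, stay.discharge,
                                 config.contiguous_day_rule)
        )
        det_day_frames.append(
            label_days(state, stay.stay_id, stay.admit, stay.discharge,
                       config.contiguous_day_rule)
        )

    ref_days = pd.concat(ref_day_frames, ignore_index=True) if ref_day_frames else pd.DataFrame(
        columns=["stay_id", "date", "sirs_positive", "minutes_in_sirs"])
    det_days = pd.concat(det_day_frames, ignore_index=True) if det_day_frames else ref_days.copy()

    # stay-level units: one per contributed cell, clustered on patient
    sens_units, spec_units = [], []
    for a in assessments:
        for cell in a.contributes:
            if cell in ("TP", "FN"):
                sens_units.append((a.patient_id, 1 if cell == "TP" else 0))
            else:
                spec_units.append((a.patient_id, 1 if cell == "TN" else 0))
    stay_table = stay_contingency(assessments)

    # specificity among patients with no reference SIRS at all
    pos_patients = set(ref_eps["patient_id"])
    spec_units_nosirs = [
        (a.patient_id, 1 if cell == "TN" else 0)
        for a in assessments
        if a.patient_id not in pos_patients
        for cell in a.contributes
        if cell in ("TN", "FP")
    ]

    day_table = day_contingency(ref_days, det_days)
    merged = ref_days.merge(det_days, on=["stay_id", "date"], suffixes=("_ref", "_det"))
    merged["patient_id"] = merged["stay_id"].map(patient_of)
    day_sens_units = [
        (r.patient_id, int(r.sirs_positive_det))
        for r in merged.itertuples() if r.sirs_positive_ref
    ]
    day_spec_units = [
        (r.patient_id, int(not r.sirs_positive_det))
        for r in merged.itertuples() if not r.sirs_positive_ref
    ]

    stay_sens = _estimates(sens_units, "sensitivity", config.ci_scale)
    stay_spec = _estimates(spec_units, "specificity", config.ci_scale)
    report = {
        "stay_level": {
            "cases": {k: sum(1 for a in assessments if a.case == k) for k in range(1, 7)},
            "n_stays": len(assessments),
            "table": stay_table.as_dict(),
            "sensitivity": stay_sens,
            "specificity": stay_spec,
            "specificity_no_sirs_patients": _estimates(
                spec_units_nosirs, "specificity", config.ci_scale
            ),
            "verdicts": {
                "sensitivity": _verdict(stay_sens, config.null_sensitivity),
                "specificity": _verdict(stay_spec, config.null_specificity),
            },
        },
        "day_level": {
            "table": day_table.as_dict(),
            "sensitivity": _estimates(day_sens_units, "sensitivity", config.ci_scale),
            "specificity": _estimates(day_spec_units, "specificity", config.ci_scale),
        },
        "config": {
            "tolerance_hours": config.tolerance / pd.Timedelta(hours=1),
            "ci_scale": config.ci_scale,
            "contiguous_day_rule": config.contiguous_day_rule,
            "null_sensitivity": config.null_sensitivity,
            "null_specificity": config.null_specificity,
        },
    }
    return report


def subgroup_by_age(
    cohort: Cohort,
    detected_states: dict[str, SirsState],
    config: EvalConfig = EvalConfig(),
) -> dict:
    """Evaluate separately for stays admitted under vs over the age cutoff."""
    cutoff = pd.Timedelta(days=config.age_cutoff_months * 365.25 / 12)
    birth = cohort.patients.set_index("patient_id")["birth_datetime"]
    age_at_admit = cohort.stays["admit"] - cohort.stays["patient_id"].map(birth)
    out = {}
    for label, mask in [("younger", age_at_admit < cutoff), ("older", age_at_admit >= cutoff)]:
        sub = cohort.copy()
        sub.stays = cohort.stays[mask].reset_index(drop=True)
        keep = set(sub.stays["stay_id"])
        sub.reference_episodes = cohort.reference_episodes[
            cohort.reference_episodes["stay_id"].isin(keep)
        ].reset_index(drop=True)
        sub.routine_assessments = cohort.routine_assessments[
            cohort.routine_assessments["stay_id"].isin(keep)
        ].reset_index(drop=True)
        if not len(sub.stays):
            out[label] = {"empty": True, "n_stays": 0}
            continue
        states = {sid: detected_states.get(sid, SirsState()) for sid in keep}
        out[label] = evaluate(sub, states, config)
    return out


def sensitivity_analysis_exclude_hypothermia(
    cohort: Cohort,
    thresholds: ThresholdTable,
    detector_config: DetectorConfig = DetectorConfig(),
    eval_config: EvalConfig = EvalConfig(),
) -> dict:
    """Re-run detection with the hypothermia sub-rule disabled; report both."""
    import dataclasses

    with_h = detect(cohort, thresholds, dataclasses.replace(detector_config, hypothermia_enabled=True))
    without_h = detect(cohort, thresholds, dataclasses.replace(detector_config, hypothermia_enabled=False))
    return {
        "with_hypothermia": evaluate(cohort, with_h, eval_config),
        "without_hypothermia": evaluate(cohort, without_h, eval_config),
    }


def missingness_bounds(
    complete_case: ContingencyTable,
    missing_pos_days: int,
    missing_neg_days: int,
    ci_scale: str = "logit",
) -> dict:
    """Best/worst-case imputation bounds around a complete-case day table.

    Best case adds the missing reference-positive days to TP and the missing
    reference-negative days to TN; worst case adds them to FN and FP.
    """
    if missing_pos_days < 0 or missing_neg_days < 0:
        raise ValueError("missing day counts must be non-negative")
    t = complete_case
    scenarios = {
        "complete_case": t,
        "best_case": ContingencyTable(t.tp + missing_pos_days, t.fp, t.fn,
                                      t.tn + missing_neg_days, t.level),
        "worst_case": ContingencyTable(t.tp, t.fp + missing_neg_days,
                                       t.fn + missing_pos_days, t.tn, t.level),
    }
    def _crude(successes, failures, measure):
        if successes + failures == 0:
            return {"empty": True}
        return crude_estimate(successes, failures, measure, ci_scale).as_dict()

    out = {}
    for name, tab in scenarios.items():
        out[name] = {
            "table": tab.as_dict(),
            "sensitivity": _crude(tab.tp, tab.fn, "sensitivity"),
            "specificity": _crude(tab.tn, tab.fp, "specificity"),
        }
    return out


def aggregate_routine_forms(
    forms: pd.DataFrame,
    stay_id: str,
    admit: pd.Timestamp,
    discharge: pd.Timestamp,
) -> pd.DataFrame:
    """Collapse per-shift routine forms to day-level ratings for one stay.

    A day rates positive if any non-missing shift form is positive, negative
    if all non-missing forms are negative, and missing if no form exists.
    """
    from .cohort import enumerate_patient_days

    sel = forms[(forms["stay_id"] == stay_id) & (forms["rating"] != "missing")]
    by_date = dict(tuple(sel.groupby("date")))
    rows = []
    for day in enumerate_patient_days(admit, discharge):
        key = day.date().isoformat()
        grp = by_date.get(key)
        if grp is None or not len(grp):
            rating = "missing"
        elif (grp["rating"] == "positive").any():
            rating = "positive"
        else:
            rating = "negative"
        rows.append((stay_id, key, rating))
    return pd.DataFrame(rows, columns=["stay_id", "date", "rating"])


def evaluate_routine(
    cohort: Cohort,
    config: EvalConfig = EvalConfig(),
) -> dict:
    """Score the per-shift clinician routine assessment against the reference.

    Complete-case analysis over days with a non-missing day rating, plus
    best/worst-case imputation of the missing days; GEE clustered on patients.
    """
    patient_of = dict(zip(cohort.stays["stay_id"], cohort.stays["patient_id"]))
    frames = []
    for stay in cohort.stays.itertuples():
        ref = reference_day_labels(
            cohort.reference_episodes, stay.stay_id, stay.admit, stay.discharge,
            config.contiguous_day_rule,
        )
        rated = aggregate_routine_forms(
            cohort.routine_assessments, stay.stay_id, stay.admit, stay.discharge
        )
        frames.append(ref.merge(rated, on=["stay_id", "date"]))
    days = pd.concat(frames, ignore_index=True)
    days["patient_id"] = days["stay_id"].map(patient_of)

    cc = days[days["rating"] != "missing"]
    cc_table = ContingencyTable(
        tp=int(((cc["sirs_positive"]) & (cc["rating"] == "positive")).sum()),
        fp=int(((~cc["sirs_positive"]) & (cc["rating"] == "positive")).sum()),
        fn=int(((cc["sirs_positive"]) & (cc["rating"] == "negative")).sum()),
        tn=int(((~cc["sirs_positive"]) & (cc["rating"] == "negative")).sum()),
        level="day",
    )
    missing = days[days["rating"] == "missing"]
    miss_pos = int(missing["sirs_positive"].sum())
    miss_neg = int((~missing["sirs_positive"]).sum())

    sens_units = [
        (r.patient_id, 1 if r.rating == "positive" else 0)
        for r in cc.itertuples() if r.sirs_positive
    ]
    spec_units = [
        (r.patient_id, 1 if r.rating == "negative" else 0)
        for r in cc.itertuples() if not r.sirs_positive
    ]
    report = {
        "complete_case": {
            "table": cc_table.as_dict(),
            "sensitivity": _estimates(sens_units, "sensitivity", config.ci_scale),
            "specificity": _estimates(spec_units, "specificity", config.ci_scale),
        },
        "missing_days": {
            "total": miss_pos + miss_neg,
            "reference_positive": miss_pos,
            "reference_negative": miss_neg,
            "n_days": int(len(days)),
        },
        "bounds": missingness_bounds(cc_table, miss_pos, miss_neg, config.ci_scale),
    }
    return report
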