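"""IPSCC SIRS rule engine.

Evaluates the four pediatric SIRS criteria (abnormal temperature, leukocyte
count / left shift, heart rate, respiratory rate — each against age-specific
limits) as boolean step functions over continuous time, and combines them
under the consensus rule: SIRS holds wherever at least two criteria fire and
at least one of them is temperature or leukocytes.

Point measurements are extended by sample-and-hold: a value is trusted from
its timestamp until the next measurement or a validity horizon, whichever
comes first; while no value is held the criterion cannot fire. Context
intervals modify individual criteria:

* hypothermia is suppressed during active cooling (and can be disabled
  wholesale for the hypothermia-ablation sensitivity analysis);
* the heart-rate criterion is suppressed while a pacemaker is active;
* while mechanically ventilated, measured respiratory rates are not compared
  against limits — instead the respiratory criterion fires on ventilated
  intervals flagged acute.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import intervals as iv
from .cohort import Cohort
from .thresholds import CRITERIA, MANDATORY_CRITERIA, ThresholdTable

Direction = str  # 'high' | 'low' | 'context'


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable behavior of the rule engine.

    vital_horizon / lab_horizon: how long a vital-sign / laboratory value is
    held after measurement (monitoring vs lab cadence).
    hypothermia_enabled: include the low-temperature sub-rule.
    validated_only: drop observations whose manual-validation flag is false.
    """

    vital_horizon: pd.Timedelta = pd.Timedelta(hours=4)
    lab_horizon: pd.Timedelta = pd.Timedelta(hours=24)
    hypothermia_enabled: bool = True
    validated_only: bool = False


@dataclass
class CriterionState:
    """Where one criterion fires, as disjoint sorted (start, end, direction)."""

    criterion: str
    intervals: list[tuple[pd.Timestamp, pd.Timestamp, Direction]] = field(default_factory=list)

    @property
    def fired(self) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
        return iv.normalize([(s, e) for s, e, _ in self.intervals])


@dataclass
class SirsState:
    """Maximal disjoint intervals where the SIRS definition holds."""

    intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = field(default_factory=list)
    provenance: list[frozenset[str]] = field(default_factory=list)


def sample_and_hold(
    series: pd.DataFrame, horizon: pd.Timedelta
) -> list[tuple[pd.Timestamp, pd.Timestamp, float]]:
    """Extend point samples to held segments [t_i, min(t_{i+1}, t_i + horizon)).

    ``series`` needs columns ``timestamp`` and ``value``, sorted by timestamp.
    Between segments the value is unknown (no segment emitted).
    """
    ts = list(series["timestamp"])
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise ValueError("series must be sorted by timestamp")
    vals = list(series["value"])
    out = []
    for i, (t, v) in enumerate(zip(ts, vals)):
        end = t + horizon
        if i + 1 < len(ts):
            end = min(end, ts[i + 1])
        if t < end:
            out.append((t, end, float(v)))
    return out


def _split_by_age_bands(
    segments: list[tuple[pd.Timestamp, pd.Timestamp, float]],
    birth: pd.Timestamp,
    thresholds: ThresholdTable,
) -> list[tuple[pd.Timestamp, pd.Timestamp, float, "AgeBand"]]:
    """Split held segments at age-band boundaries; attach the band in force."""
    boundaries = [birth + pd.Timedelta(days=b.end_days) for b in thresholds.bands[:-1]]
    out = []
    for s, e, v in segments:
        cuts = [s] + [b for b in boundaries if s < b < e] + [e]
        for cs, ce in zip(cuts, cuts[1:]):
            age_days = (cs - birth) / pd.Timedelta(days=1)
            out.append((cs, ce, v, thresholds.band_at(age_days)))
    return out


def _normalize_state(
    pieces: list[tuple[pd.Timestamp, pd.Timestamp, Direction]], criterion: str
) -> CriterionState:
    """Resolve overlaps (direction priority high > low > context) and merge."""
    order = {"high": 0, "low": 1, "context": 2}
    by_dir: dict[str, list] = {}
    for s, e, d in pieces:
        by_dir.setdefault(d, []).append((s, e))
    taken: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    labeled: list[tuple[pd.Timestamp, pd.Timestamp, Direction]] = []
    for d in sorted(by_dir, key=order.__getitem__):
        free = iv.subtract(iv.normalize(by_dir[d]), taken)
        labeled.extend((s, e, d) for s, e in free)
        taken = iv.union(taken, free)
    labeled.sort()
    merged: list[tuple[pd.Timestamp, pd.Timestamp, Direction]] = []
    for s, e, d in labeled:
        if merged and merged[-1][1] == s and merged[-1][2] == d:
            merged[-1] = (merged[-1][0], e, d)
        else:
            merged.append((s, e, d))
    return CriterionState(criterion, merged)


def _context_windows(context: pd.DataFrame, kind: str, acute_only: bool = False) -> list:
    sel = context[context["kind"] == kind]
    if acute_only:
        sel = sel[sel["acute"] == True]  # noqa: E712  (column is object-typed)
    return iv.normalize([(r.start, r.end) for r in sel.itertuples()])


def evaluate_criterion(
    criterion: str,
    observations: pd.DataFrame,
    birth: pd.Timestamp,
    stay_window: tuple[pd.Timestamp, pd.Timestamp],
    thresholds: ThresholdTable,
    context: pd.DataFrame,
    config: DetectorConfig = DetectorConfig(),
) -> CriterionState:
    """Evaluate one SIRS criterion for one stay.

    ``observations`` holds all of the patient's observations (any variables);
    the relevant ones are selected here. The returned state is clipped to the
    stay window.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    admit, discharge = stay_window
    obs = observations
    if config.validated_only:
        obs = obs[obs["validated"] != False]  # noqa: E712

    def held(variable: str, horizon: pd.Timedelta):
        sel = obs[obs["variable"] == variable].sort_values(
            "timestamp", kind="stable"
        )
        # values measured before admission may still be held into the stay
        sel = sel[sel["timestamp"] >= admit - horizon]
        sel = sel[sel["timestamp"] < discharge]
        return sample_and_hold(sel, horizon)

    pieces: list[tuple[pd.Timestamp, pd.Timestamp, Direction]] = []

    if criterion == "temperature":
        for s, e, v in held("temperature", config.vital_horizon):
            if thresholds.exceeds_high(v, thresholds.temperature_high):
                pieces.append((s, e, "high"))
            elif config.hypothermia_enabled and thresholds.below_low(v, thresholds.temperature_low):
                pieces.append((s, e, "low"))
        cooling = _context_windows(context, "active_cooling")
        if cooling:
            lows = iv.subtract([(s, e) for s, e, d in pieces if d == "low"], cooling)
            pieces = [(s, e, d) for s, e, d in pieces if d == "high"]
            pieces += [(s, e, "low") for s, e in lows]

    elif criterion == "heart_rate":
        for s, e, v, band in _split_by_age_bands(held("heart_rate", config.vital_horizon), birth, thresholds):
            if thresholds.exceeds_high(v, band.heart_rate_high):
                pieces.append((s, e, "high"))
            elif (
                band.bradycardia_applicable
                and band.heart_rate_low is not None
                and thresholds.below_low(v, band.heart_rate_low)
            ):
                pieces.append((s, e, "low"))
        paced = _context_windows(context, "pacemaker")
        if paced:
            pieces = [
                (s, e, d)
                for ss, ee, d in pieces
                for s, e in iv.subtract([(ss, ee)], paced)
            ]

    elif criterion == "respiratory_rate":
        vent = _context_windows(context, "mechanical_ventilation")
        for s, e, v, band in _split_by_age_bands(held("respiratory_rate", config.vital_horizon), birth, thresholds):
            if thresholds.exceeds_high(v, band.respiratory_rate_high):
                # measured rates are not interpretable while ventilated
                for fs, fe in iv.subtract([(s, e)], vent):
                    pieces.append((fs, fe, "high"))
        acute_vent = _context_windows(context, "mechanical_ventilation", acute_only=True)
        for s, e in iv.clip(acute_vent, admit, discharge):
            pieces.append((s, e, "context"))

    elif criterion == "leukocytes":
        for s, e, v, band in _split_by_age_bands(held("leukocyte_count", config.lab_horizon), birth, thresholds):
            if thresholds.exceeds_high(v, band.leukocyte_high):
                pieces.append((s, e, "high"))
            elif band.leukocyte_low is not None and thresholds.below_low(v, band.leukocyte_low):
                pieces.append((s, e, "low"))
        for s, e, v in held("immature_neutrophil_fraction", config.lab_horizon):
            if thresholds.exceeds_high(v, thresholds.immature_neutrophil_limit):
                pieces.append((s, e, "high"))  # left shift

    clipped = [
        (cs, ce, d)
        for s, e, d in pieces
        for cs, ce in iv.clip([(s, e)], admit, discharge)
    ]
    return _normalize_state(clipped, criterion)


def leukocyte_criterion(
    observations: pd.DataFrame,
    birth: pd.Timestamp,
    stay_window: tuple[pd.Timestamp, pd.Timestamp],
    thresholds: ThresholdTable,
    config: DetectorConfig = DetectorConfig(),
) -> CriterionState:
    """Leukocyte criterion: abnormal count or neutrophil left shift."""
    return evaluate_criterion(
        "leukocytes", observations, birth, stay_window, thresholds,
        context=pd.DataFrame(columns=["kind", "acute", "start", "end"]),
        config=config,
    )


def combine_criteria(
    states: Sequence[CriterionState],
    mandatory: frozenset[str] = MANDATORY_CRITERIA,
) -> SirsState:
    """Apply the 2-of-4 rule with a mandatory temperature/leukocyte criterion."""
    fired = {st.criterion: st.fired for st in states}
    bounds = sorted({t for ivs in fired.values() for s, e in ivs for t in (s, e)})
    raw: list[tuple[pd.Timestamp, pd.Timestamp, frozenset[str]]] = []
    for s, e in zip(bounds, bounds[1:]):
        active = frozenset(c for c, ivs in fired.items() if iv.covers(ivs, s))
        if len(active) >= 2 and active & mandatory:
            raw.append((s, e, active))
    out = SirsState()
    for s, e, active in raw:
        if out.intervals and out.intervals[-1][1] == s:
            out.intervals[-1] = (out.intervals[-1][0], e)
            out.provenance[-1] = out.provenance[-1] | active
        else:
            out.intervals.append((s, e))
            out.provenance.append(active)
    return out


def detect(
    cohort: Cohort,
    thresholds: ThresholdTable,
    config: DetectorConfig = DetectorConfig(),
) -> dict[str, SirsState]:
    """Run the full rule engine; returns a SirsState per stay_id."""
    birth = cohort.patients.set_index("patient_id")["birth_datetime"]
    obs_by_patient = dict(tuple(cohort.observations.groupby("patient_id")))
    ctx_by_patient = dict(tuple(cohort.context.groupby("patient_id")))
    empty_obs = cohort.observations.iloc[0:0]
    empty_ctx = cohort.context.iloc[0:0]
    out: dict[str, SirsState] = {}
    for stay in cohort.stays.itertuples():
        obs = obs_by_patient.get(stay.patient_id, empty_obs)
        ctx = ctx_by_patient.get(stay.patient_id, empty_ctx)
        states = [
            evaluate_criterion(
                c, obs, birth[stay.patient_id], (stay.admit, stay.discharge),
                thresholds, ctx, config,
            )
            for c in CRITERIA
        ]
        out[stay.stay_id] = combine_criteria(states)
    return out
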