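"""Episodes and SIRS-positive patient-days from a continuous SIRS state.

Two temporal rules from the study protocol govern the discretization:

* an episode ends only once the criteria have been unfulfilled for at least
  24 consecutive hours (the closing gap), so raw intervals separated by
  shorter gaps belong to one episode;
* a patient-day counts as SIRS-positive when the patient was in SIRS for at
  least one full hour that calendar date (read as cumulative minutes by
  default; a contiguous-run reading is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import intervals as iv
from .cohort import enumerate_patient_days
from .rules import SirsState

CLOSING_GAP = pd.Timedelta(hours=24)
MIN_DURATION = pd.Timedelta(minutes=60)
DAY_RULE_MINUTES = 60


@dataclass
class SirsEpisode:
    start: pd.Timestamp
    end: pd.Timestamp  # last instant criteria were fulfilled, not start of gap
    criteria: frozenset[str] = frozenset()


def build_episodes(
    state: SirsState,
    closing_gap: pd.Timedelta = CLOSING_GAP,
    min_duration: pd.Timedelta = MIN_DURATION,
) -> list[SirsEpisode]:
    """Merge raw SIRS intervals separated by gaps < closing_gap into episodes.

    Merged episodes spanning less than ``min_duration`` are discarded
    (flicker suppression; set to 0 to keep every raw interval).
    """
    if closing_gap <= pd.Timedelta(0):
        raise ValueError("closing_gap must be positive")
    ivs = iv.normalize(state.intervals)
    prov = _provenance_map(state)
    episodes: list[SirsEpisode] = []
    for s, e in ivs:
        if episodes and s - episodes[-1].end < closing_gap:
            episodes[-1].end = e
            episodes[-1].criteria = episodes[-1].criteria | prov.get((s, e), frozenset())
        else:
            episodes.append(SirsEpisode(s, e, prov.get((s, e), frozenset())))
    return [ep for ep in episodes if ep.end - ep.start >= min_duration]


def _provenance_map(state: SirsState):
    prov = getattr(state, "provenance", None) or []
    return {ivl: p for ivl, p in zip(state.intervals, prov)}


def label_days(
    state: SirsState,
    stay_id: str,
    admit: pd.Timestamp,
    discharge: pd.Timestamp,
    contiguous: bool = False,
    threshold_minutes: int = DAY_RULE_MINUTES,
) -> pd.DataFrame:
    """Per-calendar-date SIRS minutes and positivity for one stay.

    Returns columns stay_id, date, sirs_positive, minutes_in_sirs covering
    every date intersecting [admit, discharge).
    """
    ivs = iv.clip(iv.normalize(state.intervals), admit, discharge)
    rows = []
    for day in enumerate_patient_days(admit, discharge):
        day_end = day + pd.Timedelta(days=1)
        in_day = iv.clip(ivs, day, day_end)
        minutes = int(round(iv.total_duration(in_day) / pd.Timedelta(minutes=1)))
        if contiguous:
            longest = max(
                ((e - s) / pd.Timedelta(minutes=1) for s, e in in_day), default=0.0
            )
            positive = longest >= threshold_minutes
        else:
            positive = minutes >= threshold_minutes
        rows.append((stay_id, day.date().isoformat(), positive, minutes))
    return pd.DataFrame(rows, columns=["stay_id", "date", "sirs_positive", "minutes_in_sirs"])


def reference_day_labels(
    reference_episodes: pd.DataFrame,
    stay_id: str,
    admit: pd.Timestamp,
    discharge: pd.Timestamp,
    contiguous: bool = False,
) -> pd.DataFrame:
    """Day labels with the adjudicated reference episodes as the SIRS state.

    Open-ended episodes (missing end) are truncated at discharge.
    """
    sel = reference_episodes[reference_episodes["stay_id"] == stay_id]
    ivs = [
        (r.start, r.end if pd.notna(r.end) else discharge)
        for r in sel.itertuples()
    ]
    return label_days(SirsState(iv.normalize(ivs)), stay_id, admit, discharge, contiguous)


def episodes_table(per_stay: dict[str, list[SirsEpisode]]) -> pd.DataFrame:
    """Flatten detected episodes into the delimited-text output schema."""
    rows = [
        (
            stay_id,
            ep.start.isoformat(),
            ep.end.isoformat(),
            "|".join(sorted(ep.criteria)),
        )
        for stay_id, eps in per_stay.items()
        for ep in eps
    ]
    return pd.DataFrame(rows, columns=["stay_id", "start", "end", "criteria_provenance"])
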