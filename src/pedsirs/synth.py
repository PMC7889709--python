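"""Synthetic PICU cohorts with known ground truth.

Emulates a patient-data-management-system export: per-patient vital-sign and
laboratory streams with injected SIRS episodes, device/procedure context
intervals, an imperfect per-shift clinician rater, and day-level missingness.
Defaults mirror the evaluated study's cohort: 168 patients with the observed
age-band mix, mean stay of 12 days, a quarter of patients with a second
stay, and roughly 0.9 injected episodes per stay.

Episode injection pushes the driving variables beyond the active threshold
table's limits for the whole episode window (modifying held values, not
instantaneous spikes) while honoring the mandatory-criterion rule; every
episode is driven by temperature or leukocytes plus one further criterion.
Outside episodes, values stay strictly within the age-appropriate normal
band (clean mode) or cross it at a configurable borderline rate. Episode
windows are aligned to the vital-sign sampling grid and separated by more
than the 24-h closing gap, so in clean mode the rule engine recovers the
injected episodes exactly.

All randomness flows from a single scenario seed through fixed-label
substreams, so adding one draw site never perturbs another's stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, empty_cohort
from .thresholds import ThresholdTable, load_thresholds
from .timeline import reference_day_labels

HOUR = pd.Timedelta(hours=1)


def substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-operation random stream derived from (seed, label)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


@dataclass(frozen=True)
class CohortScenario:
    """Study-condition defaults; see module docstring."""

    seed: int
    n_patients: int = 168
    # Table-1 age-band mix (0d-1wk, 1wk-1mo, 1mo-1yr, 2-5yr, 6-12yr, 13-18yr)
    age_band_counts: tuple[int, ...] = (18, 10, 60, 44, 25, 11)
    multi_stay_prob: float = 0.25
    mean_stay_days: float = 12.0
    episodes_per_stay_mean: float = 0.9
    episode_duration_hours_mean: float = 24.0
    episode_duration_hours_sd: float = 12.0
    vital_cadence: pd.Timedelta = pd.Timedelta(hours=1)
    lab_cadence: pd.Timedelta = pd.Timedelta(hours=24)
    temperature_sd: float = 0.3
    heart_rate_sd: float = 8.0
    respiratory_rate_sd: float = 3.0
    leukocyte_sd: float = 1.5
    borderline_rate: float = 0.0  # per-sample probability of a spurious crossing
    ventilation_rate: float = 0.3  # per-stay probability of a ventilation interval
    acute_ventilation_prob: float = 0.3
    pacemaker_rate: float = 0.05
    cooling_rate: float = 0.05
    study_start: pd.Timestamp = pd.Timestamp("2018-08-01")
    # fix the criteria driving every episode instead of sampling them;
    # must contain temperature or leukocytes (the mandatory-criterion rule)
    episode_drivers: tuple[str, str] | None = None

    def __post_init__(self):
        if self.episode_drivers is not None:
            valid = {"temperature", "leukocytes", "heart_rate", "respiratory_rate"}
            if (len(set(self.episode_drivers)) != 2
                    or not set(self.episode_drivers) <= valid):
                raise ScenarioError(f"episode_drivers must be two distinct criteria, got {self.episode_drivers}")
            if not set(self.episode_drivers) & {"temperature", "leukocytes"}:
                raise ScenarioError(
                    "an episode driven only by heart_rate and respiratory_rate "
                    "cannot be a valid SIRS episode (mandatory-criterion rule)"
                )
        for name in ("multi_stay_prob", "borderline_rate", "ventilation_rate",
                     "acute_ventilation_prob", "pacemaker_rate", "cooling_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")


@dataclass(frozen=True)
class RaterSpec:
    """Imperfect per-day rater: hit/correct-rejection probabilities + missingness."""

    sensitivity: float
    specificity: float
    missing_rate: float
    seed: int

    def __post_init__(self):
        for name in ("sensitivity", "specificity", "missing_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


class ScenarioError(ValueError):
    pass


def _conservative_limits(
    thresholds: ThresholdTable, birth: pd.Timestamp, t: pd.Timestamp, horizon: pd.Timedelta
):
    """Band limits in force anywhere in the hold window [t, t + horizon]."""
    bands = []
    for tt in (t, t + horizon):
        age_days = (tt - birth) / pd.Timedelta(days=1)
        age_days = min(age_days, thresholds.bands[-1].end_days - 0.01)
        bands.append(thresholds.band_at(age_days))
    return bands


def _normal_value(rng, variable, thresholds, bands, sd):
    """Baseline + truncated noise, strictly inside every band in the hold window."""
    if variable == "temperature":
        lo, hi = thresholds.temperature_low, thresholds.temperature_high
    elif variable == "heart_rate":
        hi = min(b.heart_rate_high for b in bands)
        lo = max((b.heart_rate_low or 0.5 * hi) for b in bands)
    elif variable == "respiratory_rate":
        hi = min(b.respiratory_rate_high for b in bands)
        lo = 0.4 * hi
    elif variable == "leukocyte_count":
        hi = min(b.leukocyte_high for b in bands)
        lo = max((b.leukocyte_low or 4.5) for b in bands)
    else:
        raise ValueError(variable)
    margin = 0.02 * (hi - lo)
    base = 0.5 * (lo + hi)
    return float(np.clip(base + rng.normal(0.0, sd), lo + margin, hi - margin))


def _abnormal_value(variable, direction, thresholds, bands):
    """A value beyond the limit throughout the hold window."""
    if variable == "temperature":
        return thresholds.temperature_high + 0.7 if direction == "high" else thresholds.temperature_low - 0.8
    if variable == "heart_rate":
        return max(b.heart_rate_high for b in bands) + 20.0
    if variable == "respiratory_rate":
        return max(b.respiratory_rate_high for b in bands) + 10.0
    if variable == "leukocyte_count":
        if direction == "high":
            return max(b.leukocyte_high for b in bands) + 4.0
        lows = [b.leukocyte_low for b in bands]
        if any(l is None for l in lows):
            return max(b.leukocyte_high for b in bands) + 4.0
        return min(lows) - 1.0
    raise ValueError(variable)


_CRIT_VARS = {
    "temperature": "temperature",
    "heart_rate": "heart_rate",
    "respiratory_rate": "respiratory_rate",
    "leukocytes": "leukocyte_count",
}


def _place_episodes(rng, admit, discharge, scenario, cadence) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Grid-aligned, non-overlapping episode windows separated by > 26 h."""
    stay_hours = int((discharge - admit) / cadence)
    k = int(rng.poisson(scenario.episodes_per_stay_mean))
    episodes = []
    cursor = 2  # start margin, grid units
    for _ in range(k):
        dur_h = float(np.clip(
            rng.normal(scenario.episode_duration_hours_mean, scenario.episode_duration_hours_sd),
            2.0, 96.0,
        ))
        dur = max(2, int(round(dur_h)))
        latest_start = stay_hours - dur - 1
        if cursor > latest_start:
            break
        start_idx = int(rng.integers(cursor, latest_start + 1))
        episodes.append((admit + start_idx * cadence, admit + (start_idx + dur) * cadence))
        cursor = start_idx + dur + 27  # > closing gap of 24 h
    return episodes


def generate_cohort(
    scenario: CohortScenario, thresholds: ThresholdTable | None = None
) -> tuple[Cohort, pd.DataFrame, pd.DataFrame]:
    """Generate (cohort, ground-truth reference episodes, ground-truth day labels)."""
    if thresholds is None:
        thresholds = load_thresholds()
    sc = scenario
    band_probs = np.asarray(sc.age_band_counts, dtype=float)
    band_probs /= band_probs.sum()

    patients, stays, observations, context, ref_eps = [], [], [], [], []
    for i in range(sc.n_patients):
        rng = substream(sc.seed, f"patient/{i}")
        pid = f"P{i:04d}"
        sex = "female" if rng.random() < 0.38 else "male"
        n_stays = 2 if rng.random() < sc.multi_stay_prob else 1
        band = thresholds.bands[int(rng.choice(len(band_probs), p=band_probs))]

        admit0 = sc.study_start + pd.Timedelta(minutes=int(rng.integers(0, 180 * 24 * 60)))
        stay_days = [max(0.75, rng.exponential(sc.mean_stay_days)) for _ in range(n_stays)]
        age_days = float(rng.uniform(band.start_days, band.end_days))
        # keep the whole record inside the threshold table's age coverage
        total_span = sum(stay_days) + 30 * (n_stays - 1) + 2
        age_cap = thresholds.bands[-1].end_days - total_span - 1
        age_days = min(age_days, max(band.start_days, age_cap))
        birth = (admit0 - pd.Timedelta(days=age_days)).floor("min")
        patients.append((pid, birth, sex))

        admit = admit0
        for s in range(n_stays):
            sid = f"{pid}-S{s}"
            discharge = admit + pd.Timedelta(days=stay_days[s])
            discharge = admit + max(1, int((discharge - admit) / sc.vital_cadence)) * sc.vital_cadence
            stays.append((sid, pid, admit, discharge))

            episodes = _place_episodes(rng, admit, discharge, sc, sc.vital_cadence)
            drivers: list[tuple[str, str, str, str]] = []  # (mand, mand_dir, sec, sec_dir)
            for (es, ee) in episodes:
                if sc.episode_drivers is not None:
                    pair = set(sc.episode_drivers)
                    mand = ("temperature" if "temperature" in pair else "leukocytes")
                    sec = next(iter(pair - {mand}))
                else:
                    mand = str(rng.choice(["temperature", "leukocytes"]))
                    sec_pool = [c for c in ("heart_rate", "respiratory_rate", "temperature", "leukocytes")
                                if c != mand]
                    sec = str(rng.choice(sec_pool))
                mand_dir = str(rng.choice(["high", "low"])) if mand == "temperature" else "high"
                sec_dir = "high"
                drivers.append((mand, mand_dir, sec, sec_dir))
                ref_eps.append((pid, sid, es, ee))

            def in_episode(t):
                for idx, (es, ee) in enumerate(episodes):
                    if es <= t < ee:
                        return idx
                return None

            def abnormal_for(variable, idx):
                mand, mand_dir, sec, sec_dir = drivers[idx]
                if _CRIT_VARS.get(mand) == variable:
                    return mand_dir
                if _CRIT_VARS.get(sec) == variable:
                    return sec_dir
                return None

            # vitals on the hourly grid; episode bounds are grid points, and a
            # normal value at the end bound closes the held abnormal segment
            n_vitals = int((discharge - admit) / sc.vital_cadence)
            for j in range(n_vitals):
                t = admit + j * sc.vital_cadence
                bands_t = _conservative_limits(thresholds, birth, t, sc.vital_cadence)
                idx = in_episode(t)
                for variable, sd in (
                    ("temperature", sc.temperature_sd),
                    ("heart_rate", sc.heart_rate_sd),
                    ("respiratory_rate", sc.respiratory_rate_sd),
                ):
                    direction = abnormal_for(variable, idx) if idx is not None else None
                    if direction is not None:
                        v = _abnormal_value(variable, direction, thresholds, bands_t)
                    else:
                        v = _normal_value(rng, variable, thresholds, bands_t, sd)
                        if sc.borderline_rate and rng.random() < sc.borderline_rate:
                            v = _abnormal_value(variable, "high", thresholds, bands_t)
                    observations.append((pid, t, variable, round(v, 2), True))

            # labs daily, plus draws pinned to leukocyte-driven episode bounds
            lab_times = {admit + j * sc.lab_cadence for j in range(int((discharge - admit) / sc.lab_cadence) + 1)}
            for idx, (es, ee) in enumerate(episodes):
                if "leukocytes" in (drivers[idx][0], drivers[idx][2]):
                    lab_times.update({es, ee})
                    t = es
                    while t + sc.lab_cadence < ee:
                        t += sc.lab_cadence
                        lab_times.add(t)
            for t in sorted(lab_times):
                if t >= discharge:
                    continue
                bands_t = _conservative_limits(thresholds, birth, t, sc.lab_cadence)
                idx = in_episode(t)
                direction = abnormal_for("leukocyte_count", idx) if idx is not None else None
                left_shift = False
                if direction is not None and rng.random() < 0.3:
                    left_shift = True  # realize the criterion via immature neutrophils
                if direction is not None and not left_shift:
                    wbc = _abnormal_value("leukocyte_count", direction, thresholds, bands_t)
                else:
                    wbc = _normal_value(rng, "leukocyte_count", thresholds, bands_t, sc.leukocyte_sd)
                frac = 0.25 if left_shift else round(float(rng.uniform(0.0, 0.05)), 3)
                observations.append((pid, t, "leukocyte_count", round(wbc, 2), True))
                observations.append((pid, t, "immature_neutrophil_fraction", frac, True))

            # context intervals, kept clear of episode windows (with hold margin)
            blocked = [(es - pd.Timedelta(hours=5), ee + pd.Timedelta(hours=5)) for es, ee in episodes]
            for kind, rate in (
                ("mechanical_ventilation", sc.ventilation_rate),
                ("pacemaker", sc.pacemaker_rate),
                ("active_cooling", sc.cooling_rate),
            ):
                if rng.random() >= rate or n_vitals < 8:
                    continue
                for _ in range(8):  # rejection-sample a clear window
                    a = int(rng.integers(0, n_vitals - 4))
                    b = a + int(rng.integers(2, min(24, n_vitals - a)))
                    cs, ce = admit + a * sc.vital_cadence, admit + b * sc.vital_cadence
                    if all(ce <= bs or cs >= be for bs, be in blocked):
                        acute = bool(rng.random() < sc.acute_ventilation_prob) if kind == "mechanical_ventilation" else False
                        context.append((pid, kind, acute, cs, ce))
                        break

            admit = discharge + pd.Timedelta(days=30)

    cohort = empty_cohort()
    cohort.patients = pd.DataFrame(patients, columns=["patient_id", "birth_datetime", "sex"])
    cohort.stays = pd.DataFrame(stays, columns=["stay_id", "patient_id", "admit", "discharge"])
    cohort.observations = pd.DataFrame(
        observations, columns=["patient_id", "timestamp", "variable", "value", "validated"]
    ).sort_values(["patient_id", "variable", "timestamp"], kind="stable").reset_index(drop=True)
    cohort.context = pd.DataFrame(context, columns=["patient_id", "kind", "acute", "start", "end"])
    cohort.context["acute"] = cohort.context["acute"].astype(object)
    ref = pd.DataFrame(ref_eps, columns=["patient_id", "stay_id", "start", "end"])
    cohort.reference_episodes = ref
    cohort.validate()

    truth_frames = [
        reference_day_labels(ref, stay.stay_id, stay.admit, stay.discharge)
        for stay in cohort.stays.itertuples()
    ]
    truth_days = pd.concat(truth_frames, ignore_index=True)
    return cohort, ref, truth_days


def simulate_rater(truth_days: pd.DataFrame, spec: RaterSpec) -> pd.DataFrame:
    """Per-day Bernoulli clinician ratings given the ground-truth day labels.

    Returns a routine_assessments table; missing days emit no form at all.
    """
    rng = substream(spec.seed, "rater")
    rows = []
    for r in truth_days.sort_values(["stay_id", "date"], kind="stable").itertuples():
        if rng.random() < spec.missing_rate:
            continue
        p = spec.sensitivity if r.sirs_positive else 1 - spec.specificity
        rating = "positive" if rng.random() < p else "negative"
        rows.append((r.stay_id, r.date, "early", rating))
    return pd.DataFrame(rows, columns=["stay_id", "date", "shift", "rating"])


def inject_missingness(
    truth_days: pd.DataFrame, fraction_pos: float, fraction_neg: float, seed: int
) -> pd.DataFrame:
    """Mask a simple random sample of each SIRS stratum of the day grid.

    Per stratum, exactly round(fraction * stratum size) days are masked.
    Returns a copy with a boolean ``masked`` column.
    """
    for name, f in (("fraction_pos", fraction_pos), ("fraction_neg", fraction_neg)):
        if not 0 <= f <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = substream(seed, "missingness")
    out = truth_days.sort_values(["stay_id", "date"], kind="stable").reset_index(drop=True).copy()
    out["masked"] = False
    for positive, frac in ((True, fraction_pos), (False, fraction_neg)):
        idx = out.index[out["sirs_positive"] == positive].to_numpy()
        k = int(round(frac * len(idx)))
        if k:
            out.loc[rng.choice(idx, size=k, replace=False), "masked"] = True
    return out
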