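"""Independent brute-force oracles used by the test suite.

Everything here re-derives expected results by direct, naive computation
(minute grids, exhaustive scans/enumeration) without reusing the package's
interval algebra, so oracle and implementation can only agree by being right.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

MIN = pd.Timedelta(minutes=1)


def minute_grid(start: pd.Timestamp, end: pd.Timestamp) -> pd.DatetimeIndex:
    return pd.date_range(start, end - MIN, freq="min")


def rasterize(intervals, grid) -> np.ndarray:
    """Boolean membership of each grid instant in the half-open interval union."""
    out = np.zeros(len(grid), dtype=bool)
    for s, e in intervals:
        out |= (grid >= s) & (grid < e)
    return out


def held_values_on_grid(times, values, horizon: pd.Timedelta, grid) -> np.ndarray:
    """Sample-and-hold evaluated pointwise: NaN where the value is unknown."""
    out = np.full(len(grid), np.nan)
    times = list(times)
    values = list(values)
    for k, t in enumerate(grid):
        for i, ti in enumerate(times):
            nxt = times[i + 1] if i + 1 < len(times) else None
            end = ti + horizon if nxt is None else min(nxt, ti + horizon)
            if ti <= t < end:
                out[k] = values[i]
    return out


def criterion_fire_on_grid(
    criterion, observations, birth, grid, thresholds, context, *,
    vital_horizon=pd.Timedelta(hours=4), lab_horizon=pd.Timedelta(hours=24),
    hypothermia_enabled=True,
) -> np.ndarray:
    """Pointwise re-evaluation of one SIRS criterion on a minute grid."""
    def ctx_mask(kind, acute_only=False):
        sel = context[context["kind"] == kind]
        if acute_only:
            sel = sel[sel["acute"] == True]  # noqa: E712
        return rasterize([(r.start, r.end) for r in sel.itertuples()], grid)

    def series(variable):
        s = observations[observations["variable"] == variable].sort_values("timestamp")
        return list(s["timestamp"]), list(s["value"])

    age_days = (grid - birth) / pd.Timedelta(days=1)
    bands = [thresholds.band_at(min(a, thresholds.bands[-1].end_days - 1e-9)) for a in age_days]

    if criterion == "temperature":
        v = held_values_on_grid(*series("temperature"), vital_horizon, grid)
        high = v > thresholds.temperature_high
        low = (v < thresholds.temperature_low) & ~ctx_mask("active_cooling")
        if not hypothermia_enabled:
            low[:] = False
        return np.where(np.isnan(v), False, high | low)
    if criterion == "heart_rate":
        v = held_values_on_grid(*series("heart_rate"), vital_horizon, grid)
        fire = np.zeros(len(grid), dtype=bool)
        for k, b in enumerate(bands):
            if np.isnan(v[k]):
                continue
            if v[k] > b.heart_rate_high:
                fire[k] = True
            elif b.bradycardia_applicable and b.heart_rate_low is not None and v[k] < b.heart_rate_low:
                fire[k] = True
        return fire & ~ctx_mask("pacemaker")
    if criterion == "respiratory_rate":
        v = held_values_on_grid(*series("respiratory_rate"), vital_horizon, grid)
        measured = np.array(
            [(not np.isnan(v[k])) and v[k] > b.respiratory_rate_high for k, b in enumerate(bands)]
        )
        return (measured & ~ctx_mask("mechanical_ventilation")) | ctx_mask(
            "mechanical_ventilation", acute_only=True
        )
    if criterion == "leukocytes":
        c = held_values_on_grid(*series("leukocyte_count"), lab_horizon, grid)
        f = held_values_on_grid(*series("immature_neutrophil_fraction"), lab_horizon, grid)
        fire = np.zeros(len(grid), dtype=bool)
        for k, b in enumerate(bands):
            if not np.isnan(c[k]):
                if c[k] > b.leukocyte_high:
                    fire[k] = True
                elif b.leukocyte_low is not None and c[k] < b.leukocyte_low:
                    fire[k] = True
            if not np.isnan(f[k]) and f[k] > thresholds.immature_neutrophil_limit:
                fire[k] = True
        return fire
    raise ValueError(criterion)


def sirs_on_grid(fire_by_criterion: dict[str, np.ndarray]) -> np.ndarray:
    """2-of-4 with mandatory temperature/leukocytes, pointwise."""
    count = sum(fire_by_criterion.values())
    mand = fire_by_criterion["temperature"] | fire_by_criterion["leukocytes"]
    return (count >= 2) & mand


def episodes_by_scan(intervals, closing_gap: pd.Timedelta, min_duration: pd.Timedelta):
    """Gap-scan episode builder over sorted disjoint raw intervals."""
    ivs = sorted(intervals)
    groups = []
    for s, e in ivs:
        if groups and (s - groups[-1][-1][1]) < closing_gap:
            groups[-1].append((s, e))
        else:
            groups.append([(s, e)])
    eps = [(g[0][0], g[-1][1]) for g in groups]
    return [(s, e) for s, e in eps if e - s >= min_duration]


def day_minutes_by_grid(intervals, admit, discharge) -> dict[str, int]:
    """Per-date SIRS minutes by counting grid minutes inside the stay."""
    grid = minute_grid(admit, discharge)
    mask = rasterize(intervals, grid)
    out: dict[str, int] = {}
    for day in pd.date_range(admit.normalize(), (discharge - pd.Timedelta(nanoseconds=1)).normalize()):
        sel = (grid >= day) & (grid < day + pd.Timedelta(days=1))
        out[day.date().isoformat()] = int(mask[sel].sum())
    return out


def optimal_matching_size(ref_starts, det_starts, tolerance) -> int:
    """Maximum-cardinality one-to-one matching by exhaustive assignment."""
    best = 0
    n, m = len(ref_starts), len(det_starts)
    for k in range(min(n, m), 0, -1):
        for ref_sub in itertools.combinations(range(n), k):
            for det_perm in itertools.permutations(range(m), k):
                if all(
                    abs(det_starts[j] - ref_starts[i]) <= tolerance
                    for i, j in zip(ref_sub, det_perm)
                ):
                    return k
    return best
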