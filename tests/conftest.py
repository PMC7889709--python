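import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from pedsirs import CohortScenario, generate_cohort, load_thresholds

T0 = pd.Timestamp("2019-01-10 00:00")


@pytest.fixture(scope="session")
def thresholds():
    return load_thresholds()


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free synthetic cohort with ground truth (30 patients)."""
    return generate_cohort(CohortScenario(seed=11, n_patients=30))


def obs_frame(rows):
    """rows: (patient_id, timestamp, variable, value) or with validated flag."""
    full = [r if len(r) == 5 else (*r, True) for r in rows]
    return pd.DataFrame(full, columns=["patient_id", "timestamp", "variable", "value", "validated"])


def ctx_frame(rows=()):
    return pd.DataFrame(list(rows), columns=["patient_id", "kind", "acute", "start", "end"])


def random_stay_inputs(rng: np.random.Generator, thresholds, stay_hours=36):
    """Random observations/contexts/birth for one stay, spanning both sides
    of every limit, for dense-grid oracle comparisons."""
    admit = T0
    discharge = T0 + pd.Timedelta(hours=stay_hours)
    # random age, sometimes close below a band boundary so the stay crosses it
    bands = thresholds.bands
    if rng.random() < 0.5:
        b = bands[int(rng.integers(0, len(bands) - 1))]
        age_days = b.end_days - float(rng.uniform(0, 3))
    else:
        age_days = float(rng.uniform(0, bands[-1].end_days - 30))
    birth = (admit - pd.Timedelta(days=age_days)).floor("min")

    rows = []
    ranges = {
        "temperature": (34.0, 40.5),
        "heart_rate": (60.0, 220.0),
        "respiratory_rate": (8.0, 70.0),
        "leukocyte_count": (2.0, 40.0),
        "immature_neutrophil_fraction": (0.0, 0.3),
    }
    for variable, (lo, hi) in ranges.items():
        n = int(rng.integers(3, 15))
        ts = sorted(
            admit + pd.Timedelta(minutes=int(m))
            for m in rng.choice(stay_hours * 60, size=n, replace=False)
        )
        for t in ts:
            rows.append(("P0", t, variable, float(rng.uniform(lo, hi)), True))
    ctx_rows = []
    for kind in ("mechanical_ventilation", "pacemaker", "active_cooling"):
        if rng.random() < 0.5:
            a = int(rng.integers(0, stay_hours * 60 - 60))
            b_ = a + int(rng.integers(30, stay_hours * 60 - a))
            ctx_rows.append(
                ("P0", kind, bool(rng.random() < 0.5),
                 admit + pd.Timedelta(minutes=a), admit + pd.Timedelta(minutes=b_))
            )
    return dict(
        observations=obs_frame(rows), context=ctx_frame(ctx_rows),
        birth=birth, admit=admit, discharge=discharge,
    )


def random_state_intervals(rng: np.random.Generator, start=T0, span_hours=200, n_max=8):
    """Random disjoint minute-aligned intervals (a synthetic SIRS state)."""
    n = int(rng.integers(0, n_max + 1))
    marks = sorted(rng.choice(span_hours * 60, size=2 * n, replace=False))
    return [
        (start + pd.Timedelta(minutes=int(a)), start + pd.Timedelta(minutes=int(b)))
        for a, b in zip(marks[::2], marks[1::2])
    ]
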