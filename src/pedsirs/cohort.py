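"""Cohort schema: in-memory container plus delimited-text readers/writers.

A cohort bundles six tables emulating a patient-data-management-system
export for a pediatric intensive-care unit:

* ``patients`` — patient_id, birth_datetime, sex
* ``stays`` — stay_id, patient_id, admit, discharge
* ``observations`` — patient_id, timestamp, variable, value, validated
* ``context`` — patient_id, kind, acute, start, end (device/procedure intervals)
* ``reference_episodes`` — patient_id, stay_id, start, end (adjudicated SIRS;
  an empty ``end`` means the episode was still open at discharge)
* ``routine_assessments`` — stay_id, date, shift, rating (per-shift clinician forms)

Files are comma-separated UTF-8 with a header row; timestamps are ISO-8601 on
a single timezone-naive clock; the empty string encodes a missing value.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

VARIABLES = (
    "temperature",
    "heart_rate",
    "respiratory_rate",
    "leukocyte_count",
    "immature_neutrophil_fraction",
)
CONTEXT_KINDS = ("mechanical_ventilation", "pacemaker", "active_cooling")
SEXES = ("female", "male", "other")
SHIFTS = ("early", "late", "night", "unspecified")
RATINGS = ("positive", "negative", "missing")

_TABLES = {
    "patients": ["patient_id", "birth_datetime", "sex"],
    "stays": ["stay_id", "patient_id", "admit", "discharge"],
    "observations": ["patient_id", "timestamp", "variable", "value", "validated"],
    "context": ["patient_id", "kind", "acute", "start", "end"],
    "reference_episodes": ["patient_id", "stay_id", "start", "end"],
    "routine_assessments": ["stay_id", "date", "shift", "rating"],
}

_TS_COLS = {
    "patients": ["birth_datetime"],
    "stays": ["admit", "discharge"],
    "observations": ["timestamp"],
    "context": ["start", "end"],
    "reference_episodes": ["start", "end"],
    "routine_assessments": [],
}


class SchemaError(ValueError):
    """A file or table does not conform to the cohort schema."""


class IntegrityError(ValueError):
    """Cross-table referential integrity or an invariant is violated."""


@dataclass
class Cohort:
    patients: pd.DataFrame
    stays: pd.DataFrame
    observations: pd.DataFrame
    context: pd.DataFrame
    reference_episodes: pd.DataFrame
    routine_assessments: pd.DataFrame

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def copy(self) -> "Cohort":
        return replace(self, **{n: self.table(n).copy() for n in _TABLES})

    def validate(self) -> "Cohort":
        _validate(self)
        return self


def empty_cohort() -> Cohort:
    return Cohort(**{n: pd.DataFrame(columns=c) for n, c in _TABLES.items()})


def _parse_timestamps(df: pd.DataFrame, cols: list[str], table: str, allow_na: set[str]) -> None:
    for col in cols:
        try:
            parsed = pd.to_datetime(df[col], format="ISO8601")
        except (ValueError, TypeError):
            # locate the offending row for the error message
            for i, raw in enumerate(df[col]):
                if pd.isna(raw) or raw == "":
                    continue
                try:
                    pd.Timestamp(raw)
                except (ValueError, TypeError):
                    raise SchemaError(
                        f"{table}: unparseable timestamp {raw!r} in column "
                        f"{col!r} at data row {i + 1}"
                    ) from None
            raise SchemaError(f"{table}: unparseable timestamps in column {col!r}")
        if parsed.isna().any() and col not in allow_na:
            row = int(parsed.isna().idxmax()) + 1
            raise SchemaError(f"{table}: missing timestamp in column {col!r} at data row {row}")
        df[col] = parsed


def _validate(cohort: Cohort) -> None:
    pat = cohort.patients
    if pat["patient_id"].duplicated().any():
        dupes = pat.loc[pat["patient_id"].duplicated(), "patient_id"].tolist()
        raise IntegrityError(f"duplicate patient_id(s): {dupes}")
    known_patients = set(pat["patient_id"])
    bad_sex = set(pat["sex"]) - set(SEXES)
    if bad_sex:
        raise SchemaError(f"patients: unknown sex value(s) {sorted(bad_sex)}")

    stays = cohort.stays
    if stays["stay_id"].duplicated().any():
        raise IntegrityError("duplicate stay_id(s)")
    known_stays = set(stays["stay_id"])
    for tname, col, known in [
        ("stays", "patient_id", known_patients),
        ("observations", "patient_id", known_patients),
        ("context", "patient_id", known_patients),
        ("reference_episodes", "patient_id", known_patients),
        ("reference_episodes", "stay_id", known_stays),
        ("routine_assessments", "stay_id", known_stays),
    ]:
        vals = cohort.table(tname)[col]
        dangling = sorted(set(vals) - known)
        if dangling:
            raise IntegrityError(f"{tname}.{col} references unknown id(s): {dangling}")

    if len(stays) and not (stays["admit"] < stays["discharge"]).all():
        raise IntegrityError("stays: admit must precede discharge")
    # per-patient stays must not overlap
    for pid, grp in stays.groupby("patient_id"):
        g = grp.sort_values("admit")
        if (g["admit"].iloc[1:].values < g["discharge"].iloc[:-1].values).any():
            raise IntegrityError(f"overlapping stays for patient {pid}")

    birth = pat.set_index("patient_id")["birth_datetime"]
    if len(stays):
        b = stays["patient_id"].map(birth)
        if not (b <= stays["admit"]).all():
            raise IntegrityError("stay admits before patient birth")
    obs = cohort.observations
    if len(obs):
        bad_var = set(obs["variable"]) - set(VARIABLES)
        if bad_var:
            raise SchemaError(f"observations: unknown variable(s) {sorted(bad_var)}")
        if not obs["value"].map(pd.api.types.is_number).all() or obs["value"].isna().any():
            raise SchemaError("observations: non-numeric or missing value")
        frac = obs.loc[obs["variable"] == "immature_neutrophil_fraction", "value"]
        if len(frac) and not frac.between(0, 1).all():
            raise IntegrityError("immature_neutrophil_fraction outside [0, 1]")
        b = obs["patient_id"].map(birth)
        if not (b <= obs["timestamp"]).all():
            raise IntegrityError("observations timestamped before patient birth")
    ctx = cohort.context
    if len(ctx):
        bad = set(ctx["kind"]) - set(CONTEXT_KINDS)
        if bad:
            raise SchemaError(f"context: unknown kind(s) {sorted(bad)}")
        if not (ctx["start"] < ctx["end"]).all():
            raise IntegrityError("context: start must precede end")
    ref = cohort.reference_episodes
    if len(ref):
        closed = ref["end"].notna()
        if not (ref.loc[closed, "start"] < ref.loc[closed, "end"]).all():
            raise IntegrityError("reference_episodes: start must precede end")
    forms = cohort.routine_assessments
    if len(forms):
        bad = set(forms["rating"]) - set(RATINGS)
        if bad:
            raise SchemaError(f"routine_assessments: unknown rating(s) {sorted(bad)}")
        if forms.duplicated(["stay_id", "date", "shift"]).any():
            raise IntegrityError("routine_assessments: duplicate (stay, date, shift)")


def read_cohort(path: str | Path) -> Cohort:
    """Read and cross-validate a cohort directory of CSV tables."""
    path = Path(path)
    tables: dict[str, pd.DataFrame] = {}
    for name, cols in _TABLES.items():
        fp = path / f"{name}.csv"
        if not fp.exists():
            raise SchemaError(f"missing table file: {fp}")
        df = pd.read_csv(fp, dtype=str, keep_default_na=False)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{name}: missing column(s) {missing}")
        df = df[cols].replace("", pd.NA)
        _parse_timestamps(df, _TS_COLS[name], name, allow_na={"end"} if name == "reference_episodes" else set())
        tables[name] = df
    tables["observations"]["value"] = pd.to_numeric(tables["observations"]["value"], errors="coerce")
    tables["observations"]["validated"] = tables["observations"]["validated"].map(
        {"true": True, "false": False, "True": True, "False": False}
    ).fillna(True).astype(bool)
    ctx = tables["context"]
    ctx["acute"] = ctx["acute"].map(
        {"true": True, "false": False, "True": True, "False": False}
    ).astype(object)
    tables["routine_assessments"]["date"] = tables["routine_assessments"]["date"].astype(str)
    tables["routine_assessments"]["shift"] = (
        tables["routine_assessments"]["shift"].fillna("unspecified")
    )
    cohort = Cohort(**tables)
    _validate(cohort)
    return cohort


def _fmt_ts(x) -> str:
    if pd.isna(x):
        return ""
    return pd.Timestamp(x).isoformat()


def write_cohort(cohort: Cohort, out_dir: str | Path) -> list[Path]:
    """Serialize a cohort to CSV tables readable by :func:`read_cohort`.

    Write → read → write is byte-stable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, cols in _TABLES.items():
        df = cohort.table(name)[cols].copy()
        for col in _TS_COLS[name]:
            df[col] = df[col].map(_fmt_ts)
        if name == "observations" and len(df):
            df["validated"] = df["validated"].map({True: "true", False: "false"})
            df["value"] = df["value"].map(lambda v: format(float(v), ".6g"))
        if name == "context" and len(df):
            df["acute"] = df["acute"].map({True: "true", False: "false"}).fillna("")
        buf = io.StringIO()
        df.to_csv(buf, index=False, lineterminator="\n")
        fp = out_dir / f"{name}.csv"
        fp.write_text(buf.getvalue(), encoding="utf-8")
        written.append(fp)
    return written


def enumerate_patient_days(admit: pd.Timestamp, discharge: pd.Timestamp) -> list[pd.Timestamp]:
    """Calendar dates (midnight-anchored) intersecting the stay [admit, discharge)."""
    if admit >= discharge:
        raise IntegrityError("admit must precede discharge")
    first = admit.normalize()
    # discharge exactly at midnight does not open a new day (half-open stay)
    last = (discharge - pd.Timedelta(nanoseconds=1)).normalize()
    return list(pd.date_range(first, last, freq="D"))
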