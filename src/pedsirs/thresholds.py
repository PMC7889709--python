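"""Age-banded SIRS threshold tables.

The numeric limits live in an editable YAML config (the packaged default
transcribes the IPSCC 2005 consensus table); the engine only interprets the
structure validated here. Limits are exclusive by default: a held value must
be strictly beyond the limit to fire a criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

CRITERIA = ("temperature", "leukocytes", "heart_rate", "respiratory_rate")
MANDATORY_CRITERIA = frozenset({"temperature", "leukocytes"})


class ThresholdConfigError(ValueError):
    """The threshold config is malformed or does not cover a required age."""


@dataclass(frozen=True)
class AgeBand:
    name: str
    start_days: float
    end_days: float
    heart_rate_high: float
    heart_rate_low: float | None
    respiratory_rate_high: float
    leukocyte_high: float
    leukocyte_low: float | None
    bradycardia_applicable: bool


@dataclass(frozen=True)
class ThresholdTable:
    version: str
    comparator: str  # 'exclusive' (strict) or 'inclusive'
    temperature_high: float
    temperature_low: float
    immature_neutrophil_limit: float
    bands: tuple[AgeBand, ...]

    def band_at(self, age_days: float) -> AgeBand:
        for band in self.bands:
            if band.start_days <= age_days < band.end_days:
                return band
        raise ThresholdConfigError(
            f"no age band covers age {age_days:.1f} days "
            f"(coverage [{self.bands[0].start_days}, {self.bands[-1].end_days}) days)"
        )

    def exceeds_high(self, value: float, limit: float) -> bool:
        return value > limit if self.comparator == "exclusive" else value >= limit

    def below_low(self, value: float, limit: float) -> bool:
        return value < limit if self.comparator == "exclusive" else value <= limit


def _band_from_dict(d: dict) -> AgeBand:
    try:
        return AgeBand(
            name=str(d["name"]),
            start_days=float(d["start_days"]),
            end_days=float(d["end_days"]),
            heart_rate_high=float(d["heart_rate"]["high"]),
            heart_rate_low=(float(d["heart_rate"]["low"]) if "low" in d["heart_rate"] else None),
            respiratory_rate_high=float(d["respiratory_rate"]["high"]),
            leukocyte_high=float(d["leukocyte_count"]["high"]),
            leukocyte_low=(float(d["leukocyte_count"]["low"]) if "low" in d["leukocyte_count"] else None),
            bradycardia_applicable=bool(d.get("bradycardia_applicable", False)),
        )
    except KeyError as exc:
        raise ThresholdConfigError(f"age band {d.get('name', '?')!r} missing key {exc}") from None


def load_thresholds(path: str | Path | None = None) -> ThresholdTable:
    """Load and validate a threshold table; default is the packaged IPSCC table."""
    if path is None:
        text = resources.files("pedsirs.data").joinpath("ipscc_2005.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    for key in ("version", "age_bands", "temperature", "immature_neutrophil_limit"):
        if key not in raw:
            raise ThresholdConfigError(f"threshold config missing key {key!r}")
    comparator = raw.get("comparator", "exclusive")
    if comparator not in ("exclusive", "inclusive"):
        raise ThresholdConfigError(f"unknown comparator {comparator!r}")
    mandatory = set(raw.get("mandatory_criteria", sorted(MANDATORY_CRITERIA)))
    if mandatory != set(MANDATORY_CRITERIA):
        raise ThresholdConfigError(
            "mandatory_criteria must be exactly {temperature, leukocytes}"
        )
    bands = tuple(sorted((_band_from_dict(b) for b in raw["age_bands"]), key=lambda b: b.start_days))
    if not bands or bands[0].start_days != 0:
        raise ThresholdConfigError("age bands must start at 0 days")
    for prev, nxt in zip(bands, bands[1:]):
        if prev.end_days != nxt.start_days:
            raise ThresholdConfigError(
                f"age bands {prev.name!r} and {nxt.name!r} leave a gap or overlap "
                f"at {prev.end_days} days"
            )
    table = ThresholdTable(
        version=str(raw["version"]),
        comparator=comparator,
        temperature_high=float(raw["temperature"]["high"]),
        temperature_low=float(raw["temperature"]["low"]),
        immature_neutrophil_limit=float(raw["immature_neutrophil_limit"]),
        bands=bands,
    )
    return table
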