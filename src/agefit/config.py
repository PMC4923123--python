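"""Configuration for the non-exercise fitness (eCRF) regression model.

The eCRF model is a linear regression in gender, age, BMI, resting heart
rate, and a five-level self-reported physical-activity category derived from
weekly PASE minutes.  The packaged default weights are a documented
reconstruction of the cited self-report model family; they live in a YAML
file so a study can drop in calibrated weights without touching code.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class ECRFModel:
    """Weights and activity thresholds for eCRF estimation (units: MET)."""

    intercept: float
    coef_gender: float
    coef_age: float
    coef_bmi: float
    coef_hr: float
    coef_activity: tuple[float, float, float, float, float]
    gender_code: dict[str, int] = field(default_factory=lambda: {"F": 0, "M": 1})
    activity_thresholds: dict[str, float] = field(
        default_factory=lambda: {
            "aerobic_high": 180.0,
            "aerobic_mid": 60.0,
            "low_high": 120.0,
            "low_mid": 30.0,
        }
    )
    met_to_vo2max_factor: float = 3.5

    def __post_init__(self) -> None:
        if len(self.coef_activity) != 5:
            raise ValueError("coef_activity must have exactly 5 entries")
        th = self.activity_thresholds
        if not (0 < th["low_mid"] <= th["low_high"]):
            raise ValueError("low-exertion thresholds must satisfy 0 < mid <= high")
        if not (0 < th["aerobic_mid"] <= th["aerobic_high"]):
            raise ValueError("aerobic thresholds must satisfy 0 < mid <= high")


def load_ecrf_model(path: str | Path | None = None) -> ECRFModel:
    """Load an eCRF model config; the packaged default when *path* is None."""
    if path is None:
        ref = importlib.resources.files("agefit.data") / "ecrf_default.yaml"
        with importlib.resources.as_file(ref) as p:
            raw = yaml.safe_load(Path(p).read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    return ECRFModel(
        intercept=float(raw["intercept"]),
        coef_gender=float(raw["coef_gender"]),
        coef_age=float(raw["coef_age"]),
        coef_bmi=float(raw["coef_bmi"]),
        coef_hr=float(raw["coef_hr"]),
        coef_activity=tuple(float(c) for c in raw["coef_activity"]),
        gender_code={str(k): int(v) for k, v in raw["gender_code"].items()},
        activity_thresholds={
            str(k): float(v) for k, v in raw["activity_thresholds"].items()
        },
        met_to_vo2max_factor=float(raw.get("met_to_vo2max_factor", 3.5)),
    )
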