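"""Cohort screening, physiology, and cardiorespiratory-fitness estimation.

A cohort is a :class:`pandas.DataFrame` with one row per participant and the
columns listed in :data:`COHORT_COLUMNS`.  The functions here add derived
columns (BMI, pulse pressure, activity category, eCRF in METs, estimated
VO2max) and flag participants excluded by the neuropsychological screens:
a Beck Depression Inventory score above 14, or a modified Mini-Mental State
score of 51 or less, or missing screening data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import ECRFModel

COHORT_COLUMNS = [
    "id", "age", "gender", "height", "weight", "resting_hr",
    "low_exertion_min", "aerobic_min", "bdi", "mmms", "systolic", "diastolic",
]

#: Variables summarized in the group comparison table.
SUMMARY_VARIABLES = [
    "age", "ecrf", "vo2max", "weight", "bmi", "bdi", "mmms",
    "resting_hr", "systolic", "diastolic", "pulse_pressure",
]


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    bad_height = cohort["height"].notna() & (cohort["height"] <= 0)
    if bad_height.any():
        raise ValueError(
            f"nonpositive height for ids {list(cohort.loc[bad_height, 'id'])}"
        )
    return cohort


def mean_resting_hr(measurements: np.ndarray | list[float]) -> float:
    """Average repeated resting heart-rate measurements (helper)."""
    arr = np.asarray(measurements, dtype=float)
    if arr.size == 0:
        raise ValueError("at least one heart-rate measurement required")
    return float(arr.mean())


def apply_screening(
    cohort: pd.DataFrame, bdi_max: float = 14, mmms_min: float = 52
) -> pd.DataFrame:
    """Flag participants failing the depression / mental-state screens.

    Retains BDI <= ``bdi_max`` and mMMS >= ``mmms_min`` (both boundaries
    retained).  Missing scores are flagged with reason ``"incomplete"``.
    Retained rows are returned unaltered.
    """
    out = cohort.copy()
    bdi = out["bdi"]
    mmms = out["mmms"]
    reasons = pd.Series([""] * len(out), index=out.index, dtype=object)
    reasons[bdi > bdi_max] = "bdi"
    reasons[mmms < mmms_min] = reasons[mmms < mmms_min].where(
        reasons[mmms < mmms_min] != "", "mmms"
    )
    reasons[(bdi > bdi_max) & (mmms < mmms_min)] = "bdi+mmms"
    reasons[bdi.isna() | mmms.isna()] = "incomplete"
    out["screened_out"] = reasons != ""
    out["screen_reason"] = reasons
    return out


def retained(cohort: pd.DataFrame) -> pd.DataFrame:
    """Rows passing screening (all rows if screening was never applied)."""
    if "screened_out" not in cohort.columns:
        return cohort
    return cohort.loc[~cohort["screened_out"]]


def derive_physiology(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add BMI (kg/m^2) and pulse pressure (mmHg) columns."""
    validate_cohort(cohort)
    out = cohort.copy()
    out["bmi"] = out["weight"] / out["height"] ** 2
    out["pulse_pressure"] = out["systolic"] - out["diastolic"]
    return out


def categorize_activity(
    low_exertion_min: float, aerobic_min: float, model: ECRFModel
) -> int:
    """Map weekly PASE minutes to the five-level activity category.

    The configured thresholds partition the whole non-negative quadrant:
    aerobic minutes dominate (categories 3-5); with no aerobic activity the
    category (1-3) is set by low-exertion minutes.
    """
    if low_exertion_min < 0 or aerobic_min < 0:
        raise ValueError("activity minutes must be non-negative")
    th = model.activity_thresholds
    if aerobic_min >= th["aerobic_high"]:
        return 5
    if aerobic_min >= th["aerobic_mid"]:
        return 4
    if aerobic_min > 0:
        return 3
    if low_exertion_min >= th["low_high"]:
        return 3
    if low_exertion_min >= th["low_mid"]:
        return 2
    return 1


def estimate_ecrf(row: pd.Series, model: ECRFModel) -> float:
    """Linear eCRF (METs) for one participant; NaN if a predictor is missing."""
    needed = ["age", "gender", "bmi", "resting_hr", "low_exertion_min", "aerobic_min"]
    vals = [row.get(k) for k in needed]
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
        return float("nan")
    cat = categorize_activity(row["low_exertion_min"], row["aerobic_min"], model)
    g = model.gender_code[str(row["gender"])]
    return float(
        model.intercept
        + model.coef_gender * g
        + model.coef_age * row["age"]
        + model.coef_bmi * row["bmi"]
        + model.coef_hr * row["resting_hr"]
        + model.coef_activity[cat - 1]
    )


def met_to_vo2max(ecrf: float | np.ndarray, factor: float = 3.5):
    """Convert METs to estimated VO2max in ml/min/kg."""
    return np.multiply(ecrf, factor)


def add_fitness(cohort: pd.DataFrame, model: ECRFModel) -> pd.DataFrame:
    """Add activity_category, ecrf and vo2max columns; flag incomplete rows."""
    out = derive_physiology(cohort)
    cats, ecrfs = [], []
    for _, row in out.iterrows():
        try:
            cats.append(
                categorize_activity(row["low_exertion_min"], row["aerobic_min"], model)
                if not (np.isnan(row["low_exertion_min"]) or np.isnan(row["aerobic_min"]))
                else np.nan
            )
        except (TypeError, ValueError):
            cats.append(np.nan)
        ecrfs.append(estimate_ecrf(row, model))
    out["activity_category"] = cats
    out["ecrf"] = ecrfs
    out["vo2max"] = met_to_vo2max(out["ecrf"], model.met_to_vo2max_factor)
    incomplete = out["ecrf"].isna()
    if "screened_out" not in out.columns:
        out["screened_out"] = False
        out["screen_reason"] = ""
    out["screened_out"] = out["screened_out"].fillna(False).astype(bool)
    out["screen_reason"] = out["screen_reason"].fillna("").astype(object)
    out.loc[incomplete, "screened_out"] = True
    out.loc[incomplete, "screen_reason"] = "incomplete fitness estimate"
    return out


def pooled_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample t statistic and two-tailed p (pooled by default)."""
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def pooled_t_from_summaries(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> float:
    """Pooled two-sample t computed from printed group summaries."""
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    return float((mean_a - mean_b) / np.sqrt(sp2 * (1 / n_a + 1 / n_b)))


def summarize_groups(
    cohort: pd.DataFrame,
    design: pd.DataFrame,
    variables: list[str] | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-variable group means/SDs and two-tailed two-sample t-tests.

    ``design`` must carry ``id`` and ``fitness_score`` (+1 high-fit, -1
    low-fit).  Returns one row per variable with low/high means, SDs, t and
    p; t is NaN when both groups have zero variance.
    """
    variables = variables or [v for v in SUMMARY_VARIABLES if v in cohort.columns]
    merged = retained(cohort).merge(design[["id", "fitness_score"]], on="id")
    lo = merged.loc[merged["fitness_score"] == -1]
    hi = merged.loc[merged["fitness_score"] == +1]
    if len(lo) < 2 or len(hi) < 2:
        raise ValueError("each fitness group needs n >= 2")
    rows = []
    for var in variables:
        a, b = lo[var].to_numpy(float), hi[var].to_numpy(float)
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            # zero variance in both groups: t undefined
            t, p = np.nan, np.nan
        else:
            t, p = pooled_t(b, a, equal_var=equal_var)  # high minus low
        rows.append(
            {
                "variable": var,
                "mean_low": a.mean(), "sd_low": np.std(a, ddof=1), "n_low": len(a),
                "mean_high": b.mean(), "sd_high": np.std(b, ddof=1), "n_high": len(b),
                "t": t, "p": p,
            }
        )
    summary = pd.DataFrame(rows).set_index("variable")
    summary.attrs["gender_counts"] = {
        "low": lo["gender"].value_counts().to_dict(),
        "high": hi["gender"].value_counts().to_dict(),
    }
    return summary
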