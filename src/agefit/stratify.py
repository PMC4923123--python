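"""Orthogonalize age and fitness by nested stratification.

Age and estimated fitness are strongly correlated in older cohorts, so a
raw fitness regressor would largely re-measure age.  The design here breaks
that collinearity by ranking each participant only against same-gender
peers in the same age half:

1. split the cohort at its mean age (ties to the younger half);
2. split each age half by gender, giving four cells;
3. median-split each cell on eCRF; in odd cells the median participant is
   high-fit iff their eCRF exceeds the cell mean;
4. collapse the four cells into overall high-fit (+1) / low-fit (-1) groups.

The resulting regressors are the centered age ("age-score"), the ±1
fitness-score, and their product (the age x fitness interaction).  A flag
switches the interaction to centered-age x centered-eCRF.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import retained


def age_score(age: np.ndarray | float, cohort_mean: float):
    """Deviation of age from the cohort mean age (years)."""
    return np.subtract(age, cohort_mean)


def interaction_term(age_score_v, fitness_score_v):
    """Elementwise product of centered age and the ±1 fitness score."""
    return np.multiply(age_score_v, fitness_score_v)


def _split_cell(cell: pd.DataFrame) -> pd.Series:
    """Assign ±1 fitness scores within one (age-half x gender) cell."""
    cell = cell.sort_values(["ecrf", "id"], kind="mergesort")
    n = len(cell)
    score = pd.Series(0, index=cell.index, dtype=int)
    if n == 0:
        return score
    if n % 2 == 1:
        mid = n // 2
        lower, median_row, upper = cell.iloc[:mid], cell.iloc[mid], cell.iloc[mid + 1:]
        score.loc[lower.index] = -1
        score.loc[upper.index] = +1
        # the median participant joins the high group iff above the cell mean
        score.loc[median_row.name] = +1 if median_row["ecrf"] > cell["ecrf"].mean() else -1
    else:
        half = n // 2
        score.iloc[:half] = -1
        score.iloc[half:] = +1
    return score


def stratify(cohort: pd.DataFrame, interaction: str = "dichotomized") -> pd.DataFrame:
    """Build the stratified design table for the retained cohort.

    Returns a DataFrame with ``id``, ``age_score``, ``age_group``
    (young-half/old-half), ``cell``, ``fitness_score`` (±1) and
    ``interaction``.  ``interaction`` is centered age x ±1 fitness score by
    default; ``interaction="continuous"`` uses centered age x centered eCRF.
    """
    data = retained(cohort)
    for col in ("age", "gender", "ecrf"):
        if data[col].isna().any():
            raise ValueError(f"missing {col} for retained participants")
    data = data.sort_values("id", kind="mergesort").reset_index(drop=True)
    mean_age = data["age"].mean()
    a_score = age_score(data["age"].to_numpy(float), mean_age)
    # age exactly at the mean goes to the younger half
    old = a_score > 0
    design = pd.DataFrame(
        {
            "id": data["id"],
            "age_score": a_score,
            "age_group": np.where(old, "old-half", "young-half"),
            "cell": [
                f"{g}|{h}" for g, h in zip(data["gender"], np.where(old, "O", "Y"))
            ],
        }
    )
    design["ecrf"] = data["ecrf"]
    fitness = pd.Series(0, index=design.index, dtype=int)
    for _, idx in design.groupby("cell").groups.items():
        cell = pd.DataFrame(
            {"id": design.loc[idx, "id"], "ecrf": design.loc[idx, "ecrf"]}
        )
        fitness.loc[idx] = _split_cell(cell)
    design["fitness_score"] = fitness
    if interaction == "dichotomized":
        design["interaction"] = interaction_term(
            design["age_score"], design["fitness_score"]
        )
    elif interaction == "continuous":
        design["interaction"] = design["age_score"] * (
            design["ecrf"] - design["ecrf"].mean()
        )
    else:
        raise ValueError("interaction must be 'dichotomized' or 'continuous'")
    return design.drop(columns="ecrf")
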