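"""Per-region association statistics and effect-size profiles.

Two complementary views of the same design are produced for every region:

* raw Pearson correlations of the adjusted volume with the age-score, the
  ±1 fitness-score and their interaction, and standardized OLS coefficients
  from the joint three-predictor regression (with one-tailed p-values for
  the directional hypotheses that volumes shrink with age and grow with
  fitness);
* Cohen's d effect profiles — for each region the standardized mean
  difference between the age halves and between the fitness groups, signed
  so that a positive age d is an age-related volume *reduction* and a
  positive fitness d is a fitness-related volume *increase*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PREDICTORS = ("age", "fitness", "interaction")


@dataclass
class EffectProfile:
    """Per-region effect sizes for one factor (age or fitness)."""

    factor: str                      # "age" or "fitness"
    effects: pd.Series = field(repr=False)   # index = region names
    df: int = 0
    critical_t: float = float("nan")

    @property
    def regions(self) -> list[str]:
        return list(self.effects.index)

    def n_significant(self, n: int | None = None) -> int:
        """Count regions whose effect crosses the one-tailed threshold.

        Converts each d to a t statistic for a balanced two-group split of
        ``n`` participants (t = d * sqrt(n)/2; ``n`` defaults to df + 1) and
        compares with the stored critical t.
        """
        n = n if n is not None else self.df + 1
        t = self.effects * np.sqrt(n) / 2
        return int((t > self.critical_t).sum())


def _design_matrix(design: pd.DataFrame) -> pd.DataFrame:
    x = pd.DataFrame(
        {
            "age": design["age_score"].to_numpy(float),
            "fitness": design["fitness_score"].to_numpy(float),
            "interaction": design["interaction"].to_numpy(float),
        },
        index=design["id"],
    )
    return x


def _aligned(volumes: pd.DataFrame, design: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    x = _design_matrix(design)
    common = volumes.index.intersection(x.index)
    if len(common) < 4:
        raise ValueError("need at least 4 participants present in both tables")
    return volumes.loc[common], x.loc[common]


def roi_correlations(volumes: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Raw Pearson r of each region with each design predictor.

    Constant regions get NaN r and a ``flagged`` mark rather than a silent
    zero.
    """
    v, x = _aligned(volumes, design)
    for p in PREDICTORS:
        if np.ptp(x[p]) == 0:
            raise ValueError(f"constant predictor {p!r}")
    rows = []
    for region in v.columns:
        y = v[region].to_numpy(float)
        rec = {"region": region, "flagged": bool(np.ptp(y) == 0)}
        for p in PREDICTORS:
            if rec["flagged"]:
                rec[f"r_{p}"] = np.nan
            else:
                rec[f"r_{p}"] = float(stats.pearsonr(x[p], y).statistic)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("region")


def roi_partial_betas(
    volumes: pd.DataFrame,
    design: pd.DataFrame,
    df_convention: str = "n-1",
    semipartial: bool = False,
) -> pd.DataFrame:
    """Standardized OLS coefficients of each region on the three predictors.

    One-tailed p-values follow the directional hypotheses (smaller volumes
    with age, larger with fitness): the p reported for each coefficient is
    the one-tailed p in the direction the coefficient actually took.
    ``df_convention`` is "n-1" (reproducing the n-1 threshold convention) or
    "n-k-1" (residual df).  With ``semipartial=True`` semi-partial
    correlations are reported instead of betas.
    """
    v, x = _aligned(volumes, design)
    n = len(v)
    xs = (x - x.mean()) / x.std(ddof=1)
    xmat = xs.to_numpy(float)
    rank = np.linalg.matrix_rank(xmat)
    if rank < xmat.shape[1]:
        corr = np.corrcoef(xmat, rowvar=False)
        pairs = [
            (PREDICTORS[i], PREDICTORS[j])
            for i in range(3) for j in range(i + 1, 3)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear predictors: {pairs}")
    df = n - 1 if df_convention == "n-1" else n - xmat.shape[1] - 1
    rows = []
    for region in v.columns:
        y = v[region].to_numpy(float)
        if np.ptp(y) == 0:
            rec = {"region": region, "flagged": True}
            for p in PREDICTORS:
                rec[f"beta_{p}"], rec[f"p_{p}"] = np.nan, np.nan
            rows.append(rec)
            continue
        ys = (y - y.mean()) / np.std(y, ddof=1)
        beta, *_ = np.linalg.lstsq(xmat, ys, rcond=None)
        resid = ys - xmat @ beta
        dof_res = n - xmat.shape[1] - 1  # intercept implicit via centering
        s2 = float(resid @ resid) / dof_res
        cov = s2 * np.linalg.inv(xmat.T @ xmat)
        se = np.sqrt(np.diag(cov))
        rec = {"region": region, "flagged": False}
        for j, p in enumerate(PREDICTORS):
            val = float(beta[j])
            if semipartial:
                # semi-partial r: t * sqrt((1-R2)/dof_res)-free identity
                tj = val / se[j]
                r2 = 1 - float(resid @ resid) / float(ys @ ys)
                val = float(tj * np.sqrt((1 - r2) / dof_res))
            tstat = float(beta[j] / se[j])
            rec[f"beta_{p}"] = val
            rec[f"p_{p}"] = float(stats.t.sf(abs(tstat), df))  # one-tailed
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("region")
    for level, mark in ((0.10, "sig10"), (0.05, "sig05"), (0.01, "sig01")):
        for p in PREDICTORS:
            out[f"{mark}_{p}"] = out[f"p_{p}"] < level
    out.attrs["df"] = df
    return out


def cohen_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD Cohen's d for the mean difference a - b."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def significance_threshold(df: int, alpha: float = 0.05, tails: int = 1) -> float:
    """Critical t for the configured df / alpha / number of tails."""
    if df < 1 or not 0 < alpha < 1 or tails not in (1, 2):
        raise ValueError("invalid df/alpha/tails")
    return float(stats.t.ppf(1 - alpha / tails, df))


def cohen_d_profiles(
    volumes: pd.DataFrame,
    design: pd.DataFrame,
    profile_regions: list[str] | None = None,
    df_convention: str = "n-1",
    alpha: float = 0.05,
) -> tuple[EffectProfile, EffectProfile]:
    """Cohen's d effect profiles for age and fitness.

    Age split: participants below vs above the mean age (age_score sign).
    Fitness split: the ±1 fitness groups.  Signs follow the reporting
    convention that positive values are age-related volume reductions and
    fitness-related volume increases.
    """
    v, x = _aligned(volumes, design)
    regions = profile_regions if profile_regions is not None else list(v.columns)
    missing = [r for r in regions if r not in v.columns]
    if missing:
        raise KeyError(f"profile regions absent from volume table: {missing}")
    young = x["age"] <= 0
    high = x["fitness"] > 0
    n = len(v)
    df = n - 1 if df_convention == "n-1" else n - 2
    crit = significance_threshold(df, alpha, tails=1)
    d_age, d_fit = {}, {}
    for region in regions:
        y = v[region].to_numpy(float)
        d_age[region] = cohen_d(y[young.to_numpy()], y[~young.to_numpy()])
        d_fit[region] = cohen_d(y[high.to_numpy()], y[~high.to_numpy()])
    age_profile = EffectProfile(
        factor="age", effects=pd.Series(d_age).reindex(regions), df=df, critical_t=crit
    )
    fit_profile = EffectProfile(
        factor="fitness", effects=pd.Series(d_fit).reindex(regions), df=df, critical_t=crit
    )
    return age_profile, fit_profile
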