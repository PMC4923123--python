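"""Overlap statistics between the age and fitness effect-size profiles.

If fitness simply counteracted aging, the vector of per-region age effects
and the vector of per-region fitness effects (both in their "positive =
age-related loss / fitness-related gain" orientation) should be strongly
correlated across regions.  Three complementary statistics quantify this:

* the Pearson correlation across regions (df = n_regions - 2, two-tailed p);
* a consistency-based two-way mixed intraclass correlation, single
  measures (ICC(C,1)): regions are the targets, the two profiles the fixed
  measurements, and column offsets are ignored;
* a median-split sub-analysis correlating the profiles separately within
  the high-age-effect and low-age-effect halves of the regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regional import EffectProfile


@dataclass
class OverlapResult:
    r: float
    df: int
    p: float
    icc: float
    icc_p: float
    halves: pd.DataFrame | None = field(default=None, repr=False)


def _check_pair(age: EffectProfile, fit: EffectProfile, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    if age.regions != fit.regions:
        raise ValueError("profiles must cover the same regions in the same order")
    a = age.effects.to_numpy(float)
    b = fit.effects.to_numpy(float)
    if len(a) < min_n:
        raise ValueError(f"need at least {min_n} regions")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant profile: correlation undefined")
    return a, b


def profile_correlation(age: EffectProfile, fit: EffectProfile) -> tuple[float, int, float]:
    """Pearson r between the two profiles across regions, df = n - 2."""
    a, b = _check_pair(age, fit)
    res = stats.pearsonr(a, b)
    return float(res.statistic), len(a) - 2, float(res.pvalue)


def icc_consistency(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """ICC(C,1): two-way mixed, consistency, single measures, k = 2 raters.

    From the two-way ANOVA decomposition with targets as rows:
    ICC = (MS_rows - MS_err) / (MS_rows + (k-1) MS_err); p is the one-sided
    F test of MS_rows / MS_err with (n-1, (n-1)(k-1)) df.
    """
    x = np.column_stack([np.asarray(a, float), np.asarray(b, float)])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows + (k - 1) * ms_err == 0:
        raise ValueError("degenerate profiles: zero total variance")
    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    if ms_err == 0:
        p = 0.0
    else:
        f = ms_rows / ms_err
        p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(icc), p


def profile_icc(age: EffectProfile, fit: EffectProfile) -> tuple[float, float]:
    """Consistency ICC between the two effect profiles."""
    a, b = _check_pair(age, fit)
    return icc_consistency(a, b)


def median_split_analysis(age: EffectProfile, fit: EffectProfile) -> pd.DataFrame:
    """Correlate the profiles within high- and low-age-effect region halves.

    Regions are split at the median of the age profile; with an odd region
    count the median region joins the high-effect half.  Ties at the median
    are broken by region-name order.  Returns one row per half with n, r,
    df and two-tailed p, plus the member regions.
    """
    a, b = _check_pair(age, fit, min_n=6)
    regions = np.array(age.regions)
    order = np.lexsort((regions, -a))  # descending age effect, names break ties
    n = len(a)
    n_high = (n + 1) // 2
    idx_high, idx_low = order[:n_high], order[n_high:]
    rows = []
    for half, idx in (("high", idx_high), ("low", idx_low)):
        r, df, p = (np.nan, len(idx) - 2, np.nan)
        if np.ptp(a[idx]) > 0 and np.ptp(b[idx]) > 0:
            res = stats.pearsonr(a[idx], b[idx])
            r, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {"half": half, "n": len(idx), "r": r, "df": df, "p": p,
             "regions": list(regions[idx])}
        )
    return pd.DataFrame(rows).set_index("half")


def profile_overlap(age: EffectProfile, fit: EffectProfile) -> OverlapResult:
    """All three overlap statistics in one result object."""
    r, df, p = profile_correlation(age, fit)
    icc, icc_p = profile_icc(age, fit)
    halves = median_split_analysis(age, fit)
    return OverlapResult(r=r, df=df, p=p, icc=icc, icc_p=icc_p, halves=halves)
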