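"""Figure-level statistical summaries: size-scaling regressions, slope
comparison (ANCOVA homogeneity-of-slopes), distribution comparison, and
spine fraction tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import ks_2samp

__all__ = [
    "ScalingFit",
    "fit_size_scaling",
    "compare_slopes",
    "ks_compare",
    "fraction_tables",
]


@dataclass(frozen=True)
class ScalingFit:
    slope: float
    slope_se: float
    intercept: float
    r_squared: float
    n: int


def _paired(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def fit_size_scaling(x, y) -> ScalingFit:
    """Ordinary least squares of y on x (e.g., nanomodule count vs spine
    volume); returns slope +/- SE, intercept and R^2."""
    x, y = _paired(x, y)
    if len(x) < 3:
        raise ValueError("need at least 3 paired finite observations")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; slope undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return ScalingFit(
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        n=len(x),
    )


def compare_slopes(group_a, group_b) -> dict:
    """Homogeneity-of-slopes test between two (x, y) groups: the p-value of
    the group-by-x interaction term in a pooled linear model (the ANCOVA
    slope-equality test)."""
    xa, ya = _paired(*group_a)
    xb, yb = _paired(*group_b)
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("each group needs at least 3 paired finite observations")
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise ValueError("degenerate x in one group")
    x = np.concatenate([xa, xb])
    g = np.concatenate([np.zeros(len(xa)), np.ones(len(xb))])
    design = sm.add_constant(np.column_stack([x, g, x * g]))
    res = sm.OLS(np.concatenate([ya, yb]), design).fit()
    return {
        "slope_a": fit_size_scaling(xa, ya).slope,
        "slope_b": fit_size_scaling(xb, yb).slope,
        "p": float(res.pvalues[3]),
    }


def ks_compare(sample_a, sample_b) -> dict:
    """Two-sample Kolmogorov-Smirnov test, with the empirical cumulative
    curves included for plotting."""
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if len(a) < 5 or len(b) < 5:
        raise ValueError("each sample needs n >= 5")
    stat = ks_2samp(a, b)
    return {
        "D": float(stat.statistic),
        "p": float(stat.pvalue),
        "ecdf_a": (a, np.arange(1, len(a) + 1) / len(a)),
        "ecdf_b": (b, np.arange(1, len(b) + 1) / len(b)),
    }


def fraction_tables(spines) -> dict[str, pd.DataFrame]:
    """Fraction tables over classified spines with nanomodule counts.

    Returns three tables: percent TC vs CC (of classified spines), percent
    single vs multiple nanomodules per class (spines with zero aligned
    nanomodules are excluded from these denominators and reported
    separately), and the full count distribution (1..4) per class.
    Denominators are included in every table.
    """
    rows = [(s.input_class, s.nanomodule_count) for s in spines]
    df = pd.DataFrame(rows, columns=["input_class", "count"])
    classified = df[df.input_class.isin(["CC", "TC"])]

    n_cls = len(classified)
    cls_tab = pd.DataFrame({
        "n": classified.input_class.value_counts().reindex(["CC", "TC"], fill_value=0),
    })
    cls_tab["percent"] = 100.0 * cls_tab.n / n_cls if n_cls else np.nan

    rows_sm, rows_pmf = [], []
    for cls in ("CC", "TC"):
        sub = classified[classified.input_class == cls]
        with_mod = sub[sub["count"] >= 1]
        denom = len(with_mod)
        single = int((with_mod["count"] == 1).sum())
        rows_sm.append({
            "input_class": cls,
            "n": denom,
            "n_zero_excluded": int((sub["count"] == 0).sum()),
            "percent_single": 100.0 * single / denom if denom else np.nan,
            "percent_multiple": 100.0 * (denom - single) / denom if denom else np.nan,
        })
        for c in (1, 2, 3, 4):
            rows_pmf.append({
                "input_class": cls, "count": c, "n": denom,
                "percent": 100.0 * int((with_mod["count"] == c).sum()) / denom
                if denom else np.nan,
            })
    return {
        "input_class": cls_tab,
        "single_multiple": pd.DataFrame(rows_sm).set_index("input_class"),
        "count_distribution": pd.DataFrame(rows_pmf).set_index(["input_class", "count"]),
    }
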