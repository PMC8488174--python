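"""Statistical surface: normality gating, group comparison, HU-SUV regression.

The analysis records a Shapiro-Wilk normality check for each bone's SUV
sample (without branching on it), compares bones by one-way ANOVA with
Tukey-HSD-adjusted all-pairs comparisons, and quantifies the density-
metabolism relationship per bone by simple linear regression of
equilibrium SUV on mean CT Hounsfield units across animals, reporting r².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA: float = 0.05


@dataclass(frozen=True)
class NormalityResult:
    statistic: float  # Shapiro-Wilk W
    p_value: float


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    mean_diff: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class GroupComparison:
    f_statistic: float
    p_value: float
    comparisons: tuple[PairwiseComparison, ...]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def normality_test(sample: np.ndarray) -> NormalityResult:
    """Shapiro-Wilk test for 3 <= n <= 5000 non-degenerate samples."""
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1:
        raise ValueError("sample must be 1-D")
    if not (3 <= len(x) <= 5000):
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("sample is constant; normality test undefined")
    w, p = sps.shapiro(x)
    return NormalityResult(statistic=float(w), p_value=float(p))


def one_way_anova_with_comparisons(groups: dict[str, np.ndarray]) -> GroupComparison:
    """One-way ANOVA across groups plus Tukey-HSD all-pairs comparisons.

    ``p_raw`` is the unadjusted p of the same pooled-variance pairwise
    statistic; ``p_adjusted`` is the Tukey HSD familywise-adjusted value,
    flagged significant below 0.05.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {name: np.asarray(v, dtype=float) for name, v in groups.items()}
    for name, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} needs at least two values")

    f_stat, p_val = sps.f_oneway(*arrays.values())

    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[name] * len(v) for name, v in arrays.items()])
    tukey = pairwise_tukeyhsd(values, labels, alpha=ALPHA)

    n_total = len(values)
    k = len(arrays)
    df_resid = n_total - k
    group_means = {name: v.mean() for name, v in arrays.items()}
    sse = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    mse = sse / df_resid

    comparisons = []
    pairs = [tuple(row[:2]) for row in tukey._results_table.data[1:]]
    for (a, b), p_adj in zip(pairs, tukey.pvalues):
        na, nb = len(arrays[a]), len(arrays[b])
        diff = group_means[b] - group_means[a]
        se = np.sqrt(mse * (1.0 / na + 1.0 / nb))
        t = diff / se if se > 0 else np.inf * np.sign(diff)
        p_raw = float(2 * sps.t.sf(abs(t), df_resid)) if np.isfinite(t) else 0.0
        comparisons.append(
            PairwiseComparison(
                pair=(str(a), str(b)),
                mean_diff=float(diff),
                p_raw=p_raw,
                p_adjusted=float(p_adj),
                significant=bool(p_adj < ALPHA),
            )
        )
    return GroupComparison(
        f_statistic=float(f_stat), p_value=float(p_val), comparisons=tuple(comparisons)
    )


def simple_linear_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Least-squares fit y = a + b x with r² = squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if len(x) < 2:
        raise ValueError("need at least two points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(x),
    )


def per_bone_regressions(suv: pd.DataFrame, hu: pd.DataFrame) -> pd.DataFrame:
    """Per-bone regression of equilibrium SUV on mean HU across animals.

    Both inputs are tidy frames with columns (animal_id, bone, value
    column ``suv`` resp. ``hu``).  Returns a frame indexed by bone with
    slope, intercept, r2 and n.
    """
    merged = suv.merge(hu, on=["animal_id", "bone"], how="inner")
    rows = {}
    for bone, grp in merged.groupby("bone", sort=False):
        res = simple_linear_regression(grp["hu"].to_numpy(), grp["suv"].to_numpy())
        rows[bone] = {
            "slope": res.slope,
            "intercept": res.intercept,
            "r2": res.r_squared,
            "n": res.n,
        }
    out = pd.DataFrame.from_dict(rows, orient="index").rename_axis("bone")
    out["n"] = out["n"].astype(int)
    return out
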