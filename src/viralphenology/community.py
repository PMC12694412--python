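"""Community-level seasonality from pairwise Bray-Curtis similarity.

All unordered sample pairs are compared with Bray-Curtis similarity and
organized by temporal lag (difference in calendar months).  A seasonal
community shows similarity peaking at 12-month multiples, which is
quantified by an ordinary-least-squares harmonic regression of similarity
on a 12-month cosine/sine pair; a linear trend over lag captures long-term
drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis

from .core_io import AbundanceTable
from .periodicity import HarmonicFit

__all__ = [
    "bray_curtis_similarity",
    "pairwise_lag_table",
    "per_lag_means",
    "lag_linear_fit",
    "seasonality_regression",
]


def bray_curtis_similarity(u, v) -> float:
    """1 - Bray-Curtis dissimilarity = 1 - sum|u-v| / sum(u+v).

    Requires nonnegative vectors of equal length, not both all-zero.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("abundances must be nonnegative")
    if u.sum() + v.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - braycurtis(u, v))


def pairwise_lag_table(table: AbundanceTable, include_lag0: bool = False) -> pd.DataFrame:
    """Bray-Curtis similarity of every unordered sample pair, with its lag.

    Lag is the difference in (year, month) index.  Lag-0 pairs (same
    calendar month, e.g. two size fractions) are excluded by default since
    fractions are analyzed separately.
    """
    n = len(table.samples)
    if n < 3:
        raise ValueError("need at least 3 samples")
    months = table.month_indices
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            lag = int(abs(months[j] - months[i]))
            if lag == 0 and not include_lag0:
                continue
            rows.append(
                dict(
                    sample_a=table.samples[i].sample_id,
                    sample_b=table.samples[j].sample_id,
                    lag_months=lag,
                    bc_similarity=bray_curtis_similarity(
                        table.coverage[:, i], table.coverage[:, j]
                    ),
                )
            )
    return pd.DataFrame(rows)


def per_lag_means(pairs: pd.DataFrame) -> pd.DataFrame:
    """Mean similarity at each temporal lag (the red curve of a lag plot)."""
    out = (
        pairs.groupby("lag_months", as_index=False)["bc_similarity"]
        .agg(mean_similarity="mean", n_pairs="count")
        .sort_values("lag_months", ignore_index=True)
    )
    return out


def lag_linear_fit(pairs: pd.DataFrame) -> tuple[float, float]:
    """OLS slope and intercept of similarity on lag over all pairs."""
    slope, intercept = np.polyfit(pairs["lag_months"], pairs["bc_similarity"], 1)
    return float(slope), float(intercept)


@dataclass
class SeasonalityRegression:
    """12-month harmonic regression of similarity on lag.

    ``all_pairs`` fits every sample pair; ``lag_means`` fits the per-lag
    mean curve.  The all-pairs p-value is nominal: pair similarities
    sharing a sample are not independent.
    """

    all_pairs: HarmonicFit
    lag_means: HarmonicFit
    lags_all: np.ndarray
    lags_means: np.ndarray


def _harmonic_on_lags(lags: np.ndarray, y: np.ndarray) -> HarmonicFit:
    n = len(y)
    if len(np.unique(lags)) < 3:
        raise ValueError("need at least 3 distinct lags")
    w = 2 * np.pi * lags / 12.0
    X = np.column_stack([np.ones(n), np.cos(w), np.sin(w)])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss1 = float(resid @ resid)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if rss0 == 0 else min(max(1 - rss1 / rss0, 0.0), 1.0)
    k = 2
    from scipy import stats

    if r2 >= 1.0:
        f, fp = np.inf, 0.0
    else:
        f = (r2 / k) / ((1 - r2) / (n - k - 1))
        fp = float(stats.f.sf(f, k, n - k - 1))
    lrt = np.inf if rss1 == 0 else n * np.log(rss0 / rss1)
    lrt_p = 0.0 if rss1 == 0 else float(stats.chi2.sf(lrt, k))
    return HarmonicFit(
        coefficients=beta, periods=(12.0,), rss0=rss0, rss1=rss1, r_squared=r2,
        f_statistic=float(f), f_pvalue=fp, lrt_statistic=float(lrt),
        lrt_pvalue=lrt_p, n=n,
    )


def seasonality_regression(pairs: pd.DataFrame) -> SeasonalityRegression:
    """Fit the 12-month harmonic both on all pairs and on per-lag means."""
    lags = pairs["lag_months"].to_numpy(dtype=float)
    y = pairs["bc_similarity"].to_numpy(dtype=float)
    means = per_lag_means(pairs)
    mlags = means["lag_months"].to_numpy(dtype=float)
    my = means["mean_similarity"].to_numpy(dtype=float)
    return SeasonalityRegression(
        all_pairs=_harmonic_on_lags(lags, y),
        lag_means=_harmonic_on_lags(mlags, my),
        lags_all=lags,
        lags_means=mlags,
    )
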