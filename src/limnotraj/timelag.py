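"""Time-lag analysis (TLA) of community dissimilarity.

For one lake, every unordered pair of sampling dates yields a point
(elapsed days, mean Bray-Curtis dissimilarity between the two dates'
replicates).  Ordinary least-squares polynomials of degree 1-5 are fitted to
dissimilarity versus lag and compared by AIC; a seasonal community produces a
periodic lag profile best captured by higher-degree polynomials, while a
significantly positive degree-1 slope indicates progressive divergence
(the community does not return to its earlier state).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from skbio import DistanceMatrix


@dataclass
class LagPairSet:
    """All date-pair (lag, dissimilarity) points for one lake.

    ``pairs`` columns: lag_days (positive int), dissimilarity (mean of all
    replicate-to-replicate Bray-Curtis values between the two dates), and
    rate (dissimilarity / lag_days, a per-day divergence rate).
    """

    lake: str
    pairs: pd.DataFrame


def build_lag_pairs(dm: DistanceMatrix, meta: pd.DataFrame, lake: str) -> LagPairSet:
    """Aggregate replicate-level dissimilarities into date-pair points.

    For every unordered pair of the lake's sampling dates, the dissimilarity
    is the mean over all replicate-to-replicate values between the two dates
    (up to 3 x 3) and the lag is the number of days between the dates.
    """
    sub = meta[meta["lake"] == lake]
    sub = sub.loc[[s for s in sub.index if s in set(dm.ids)]]
    if sub.empty:
        raise ValueError(f"no samples of lake {lake!r} in the distance matrix")
    dates = sorted(pd.to_datetime(sub["date"]).unique())
    if len(dates) < 3:
        raise ValueError(
            f"lake {lake!r}: need at least 3 sampling dates, got {len(dates)}"
        )
    data = dm.data
    index = {sid: i for i, sid in enumerate(dm.ids)}
    by_date = {
        d: [index[s] for s in sub.index[pd.to_datetime(sub["date"]) == d]]
        for d in dates
    }
    rows = []
    for a in range(len(dates)):
        for b in range(a + 1, len(dates)):
            ia, ib = by_date[dates[a]], by_date[dates[b]]
            block = data[np.ix_(ia, ib)]
            lag = int((dates[b] - dates[a]) / np.timedelta64(1, "D"))
            rows.append(
                {
                    "lag_days": lag,
                    "dissimilarity": float(block.mean()),
                    "rate": float(block.mean()) / lag,
                }
            )
    return LagPairSet(lake=lake, pairs=pd.DataFrame(rows))


@dataclass
class LagModelFit:
    """One OLS polynomial fit of dissimilarity on lag (days).

    AIC uses the Gaussian convention counting the residual-variance
    parameter: AIC = n ln(2 pi RSS / n) + n + 2 (p + 1) with p = degree + 1
    coefficients.  ``slope``/``slope_p`` are populated for degree 1 only.
    """

    degree: int
    coefficients: np.ndarray  # ascending powers
    rss: float
    aic: float
    slope: float | None = None
    slope_p: float | None = None
    best: bool = False


def gaussian_aic(rss: float, n: int, n_coefficients: int) -> float:
    """AIC of a Gaussian OLS fit; -inf when the fit is exact (RSS = 0)."""
    if rss <= 0:
        return -math.inf
    return n * math.log(2 * math.pi * rss / n) + n + 2 * (n_coefficients + 1)


def fit_lag_models(pair_set: LagPairSet, max_degree: int = 5) -> list[LagModelFit]:
    """OLS polynomials of degree 1..max_degree, ranked by AIC.

    Degrees requiring more distinct lags than available are skipped with a
    warning.  Exactly one returned fit has ``best=True`` (minimum AIC).
    """
    pairs = pair_set.pairs
    if len(pairs) < 8:
        raise ValueError(f"need at least 8 lag pairs, got {len(pairs)}")
    x = pairs["lag_days"].to_numpy(dtype=float)
    y = pairs["dissimilarity"].to_numpy(dtype=float)
    n = x.size
    n_distinct = np.unique(x).size
    fits: list[LagModelFit] = []
    for degree in range(1, max_degree + 1):
        if n_distinct < degree + 1:
            warnings.warn(
                f"lake {pair_set.lake!r}: only {n_distinct} distinct lags, "
                f"skipping degree {degree}"
            )
            continue
        # scale x for conditioning; refit coefficients on the raw scale
        coeffs_scaled = np.polynomial.polynomial.polyfit(x / x.max(), y, degree)
        scale = x.max() ** np.arange(degree + 1)
        coeffs = coeffs_scaled / scale
        resid = y - np.polynomial.polynomial.polyval(x, coeffs)
        rss = float(resid @ resid)
        if rss < 1e-25:
            rss = 0.0
        fit = LagModelFit(
            degree=degree,
            coefficients=coeffs,
            rss=rss,
            aic=gaussian_aic(rss, n, degree + 1),
        )
        if degree == 1:
            lr = scipy.stats.linregress(x, y)
            fit.slope = float(lr.slope)
            fit.slope_p = float(lr.pvalue)
        fits.append(fit)
    if not fits:
        raise ValueError("no polynomial degree could be fitted")
    best = min(fits, key=lambda f: f.aic)
    best.best = True
    return fits


@dataclass
class DivergenceVerdict:
    """Degree-1 slope test: diverging / converging / stationary at alpha."""

    lake: str
    slope: float
    p_value: float
    verdict: str


def divergence_test(pair_set: LagPairSet, alpha: float = 0.05) -> DivergenceVerdict:
    """Classify a lake's temporal dynamics from the linear lag slope.

    "diverging" iff slope > 0 and p < alpha; "converging" iff slope < 0 and
    p < alpha; otherwise "stationary".  A slope of exactly zero (constant
    dissimilarity) is stationary.
    """
    pairs = pair_set.pairs
    x = pairs["lag_days"].to_numpy(dtype=float)
    y = pairs["dissimilarity"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return DivergenceVerdict(pair_set.lake, 0.0, 1.0, "stationary")
    lr = scipy.stats.linregress(x, y)
    slope, p = float(lr.slope), float(lr.pvalue)
    if slope > 0 and p < alpha:
        verdict = "diverging"
    elif slope < 0 and p < alpha:
        verdict = "converging"
    else:
        verdict = "stationary"
    return DivergenceVerdict(pair_set.lake, slope, p, verdict)


def lag_analysis_table(
    dm: DistanceMatrix,
    meta: pd.DataFrame,
    lakes=None,
    max_degree: int = 5,
) -> pd.DataFrame:
    """Per-lake TLA summary: best polynomial degree, linear slope, p, verdict."""
    if lakes is None:
        lakes = sorted(set(meta["lake"]))
    rows = []
    for lake in lakes:
        pair_set = build_lag_pairs(dm, meta, lake)
        fits = fit_lag_models(pair_set, max_degree=max_degree)
        best = next(f for f in fits if f.best)
        verdict = divergence_test(pair_set)
        rows.append(
            {
                "lake": lake,
                "n_pairs": len(pair_set.pairs),
                "best_degree": best.degree,
                "best_aic": best.aic,
                "slope": verdict.slope,
                "slope_p": verdict.p_value,
                "verdict": verdict.verdict,
            }
        )
    return pd.DataFrame(rows).set_index("lake")
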