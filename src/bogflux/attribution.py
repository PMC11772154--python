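"""Downstream attribution: week bookkeeping, lagged cross-correlation,
piecewise GPP-SWC threshold estimation, and redundancy analysis.

The weekly calendar convention is 52 exact seven-day bins per calendar
year anchored at 1 January, with the trailing one or two days of the year
folded into bin 52. The breakpoint estimator is a continuous two-segment
piecewise-linear fit chosen by exhaustive grid search with an AIC guard
against a plain linear fit and a seeded bootstrap confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import swc_to_wtd

__all__ = [
    "CrossCorrResult",
    "BreakpointResult",
    "RDAResult",
    "weekly_aggregate",
    "cross_correlation",
    "breakpoint",
    "rda",
]


@dataclass
class CrossCorrResult:
    """Lagged Pearson cross-correlation between two aligned series."""

    best_lag: int
    r_at_best: float
    df: int
    ci95: tuple
    r_by_lag: pd.DataFrame


@dataclass
class BreakpointResult:
    """Two-segment piecewise-linear threshold estimate."""

    threshold_est: float
    threshold_wtd: float
    sse_segmented: float
    sse_linear: float
    has_breakpoint: bool
    bootstrap_ci: tuple = (np.nan, np.nan)
    slopes: tuple = (np.nan, np.nan)


@dataclass
class RDAResult:
    """Redundancy analysis (constrained ordination) of Y on X."""

    constrained_axis_scores: np.ndarray  # (n, n_axes)
    variable_arrows: pd.DataFrame  # explanatory variable x axis
    response_loadings: pd.DataFrame  # response variable x axis
    proportion_explained: np.ndarray
    axes: np.ndarray  # orthonormal axis directions in response space
    dropped_columns: list = field(default_factory=list)


def week_bin(timestamps):
    """Assign 1-based seven-day bins (1..52) within each calendar year.

    Day-of-year 1-7 -> bin 1, ..., 358 onwards (including day 365/366)
    folds into bin 52.
    """
    doy = pd.DatetimeIndex(timestamps).dayofyear
    return np.minimum((doy - 1) // 7, 51) + 1


def weekly_aggregate(records, period_start, period_end, omit_weeks=(), sum_columns=("P",)):
    """Aggregate timestamped records into 52 seven-day bins per year.

    Parameters
    ----------
    records : pandas.DataFrame
        Must contain a datetime column ``time`` (or ``week_start``).
        Rows outside [period_start, period_end] are ignored.
    period_start, period_end : date-like
        Inclusive period bounds.
    omit_weeks : iterable of (year, week_bin)
        Bins dropped after aggregation (1-based bins).
    sum_columns : tuple
        Columns aggregated by sum (precipitation-like); all other numeric
        columns are averaged.

    Returns
    -------
    (weekly, retained) : pandas.DataFrame, int
        Weekly table with ``week_start`` (bin anchor date) and the count
        of retained bins.
    """
    time_col = "time" if "time" in records else "week_start"
    df = records.copy()
    df[time_col] = pd.to_datetime(df[time_col])
    start = pd.Timestamp(period_start)
    end = pd.Timestamp(period_end)
    df = df[(df[time_col] >= start) & (df[time_col] <= end)]
    if df.empty:
        raise ValueError("no records in the requested period")
    years = pd.DatetimeIndex(df[time_col]).year
    bins = week_bin(df[time_col])
    df = df.assign(_year=years, _bin=bins)
    omit = {(int(y), int(b)) for y, b in omit_weeks}

    num_cols = [c for c in df.columns if c not in (time_col, "_year", "_bin")
                and pd.api.types.is_numeric_dtype(df[c])]
    agg = {c: ("sum" if c in sum_columns else "mean") for c in num_cols}
    grouped = df.groupby(["_year", "_bin"]).agg(agg).reset_index()
    keep = [(y, b) not in omit for y, b in zip(grouped["_year"], grouped["_bin"])]
    grouped = grouped.loc[keep].reset_index(drop=True)
    week_start = pd.to_datetime(
        {
            "year": grouped["_year"],
            "month": 1,
            "day": 1,
        }
    ) + pd.to_timedelta(7 * (grouped["_bin"] - 1), unit="D")
    out = grouped.drop(columns=["_year", "_bin"])
    out.insert(0, "week_start", week_start)
    return out, len(out)


def cross_correlation(x, y, max_lag, min_lag=None, detrend=False):
    """Pearson correlation of ``x[t]`` with ``y[t + k]`` over a lag range.

    Positive lags mean ``y`` responds after ``x``. The best lag maximizes
    ``|r|``; degrees of freedom are ``N - 2`` for the aligned
    complete-case series, and the 95 % confidence interval at the best
    lag uses the Fisher z-transform.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must be aligned")
    if min_lag is None:
        min_lag = -max_lag
    ok = ~(np.isnan(x) | np.isnan(y))
    n_obs = int(ok.sum())
    if n_obs <= max(abs(min_lag), abs(max_lag)) + 3:
        raise ValueError("series too short for the requested lag range")
    if np.nanstd(x) == 0 or np.nanstd(y) == 0:
        raise ValueError("constant series: correlation undefined")
    if detrend:
        t = np.arange(len(x))
        for arr in (x, y):
            m = ~np.isnan(arr)
            b, a = np.polyfit(t[m], arr[m], 1)
            arr[m] -= a + b * t[m]

    rows = []
    for k in range(min_lag, max_lag + 1):
        if k >= 0:
            xa, ya = x[: len(x) - k or None], y[k:]
        else:
            xa, ya = x[-k:], y[: len(y) + k]
        m = ~(np.isnan(xa) | np.isnan(ya))
        n_pairs = int(m.sum())
        if n_pairs < 3:
            rows.append((k, np.nan, n_pairs))
            continue
        r = float(np.corrcoef(xa[m], ya[m])[0, 1])
        rows.append((k, r, n_pairs))
    table = pd.DataFrame(rows, columns=["lag", "r", "n_pairs"])
    valid = table.dropna(subset=["r"])
    best_row = valid.loc[valid["r"].abs().idxmax()]
    best_lag = int(best_row["lag"])
    r_best = float(best_row["r"])
    n_best = int(best_row["n_pairs"])
    z = np.arctanh(np.clip(r_best, -1 + 1e-12, 1 - 1e-12))
    zse = 1.0 / np.sqrt(max(n_best - 3, 1))
    ci = (float(np.tanh(z - 1.959963984540054 * zse)),
          float(np.tanh(z + 1.959963984540054 * zse)))
    return CrossCorrResult(
        best_lag=best_lag,
        r_at_best=r_best,
        df=n_obs - 2,
        ci95=ci,
        r_by_lag=table,
    )


def _hinge_fit(x, y, c):
    """Continuous two-segment fit: y = a + b*x + g*min(x - c, 0)."""
    design = np.column_stack([np.ones_like(x), x, np.minimum(x - c, 0.0)])
    sol, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    sse = float(np.sum((y - design @ sol) ** 2))
    return sol, sse


def _fit_grid(x, y, grid):
    best_c, best_sol, best_sse = np.nan, None, np.inf
    for c in grid:
        # require support on both sides of the candidate
        if np.sum(x < c) < 3 or np.sum(x >= c) < 3:
            continue
        sol, sse = _hinge_fit(x, y, c)
        if sse < best_sse:
            best_c, best_sol, best_sse = c, sol, sse
    return best_c, best_sol, best_sse


def breakpoint(gpp, swc, candidate_grid=None, n_boot=500, seed=0, grid_step=0.5):
    """Estimate the SWC threshold of GPP limitation by segmented regression.

    A continuous two-segment piecewise-linear model of GPP on SWC is fit
    by exhaustive grid search over candidate thresholds (default grid:
    ``grid_step``-spaced values spanning the interior of the observed SWC
    range), minimizing the sum of squared errors. The segmented model
    must beat the plain linear fit by AIC, otherwise the verdict is "no
    breakpoint". A seeded nonparametric bootstrap gives a percentile
    confidence interval on the threshold.

    Returns
    -------
    BreakpointResult
    """
    x = np.asarray(swc, dtype=float)
    y = np.asarray(gpp, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 paired observations")
    if candidate_grid is None:
        lo = np.floor(np.quantile(x, 0.02) / grid_step) * grid_step
        hi = np.ceil(np.quantile(x, 0.98) / grid_step) * grid_step
        candidate_grid = np.arange(lo, hi + grid_step / 2, grid_step)
    grid = np.asarray(candidate_grid, dtype=float)
    if grid.min() < x.min() - 10 or grid.max() > x.max() + 10:
        raise ValueError("candidate grid far outside the data range")

    c_hat, sol, sse_seg = _fit_grid(x, y, grid)
    lin = np.column_stack([np.ones_like(x), x])
    lin_sol, _, _, _ = np.linalg.lstsq(lin, y, rcond=None)
    sse_lin = float(np.sum((y - lin @ lin_sol) ** 2))
    if not np.isfinite(sse_seg) or sol is None:
        raise ValueError("no admissible breakpoint candidate within the data")
    # AIC with k = parameter count (+1 for sigma); constant terms cancel.
    aic_seg = n * np.log(max(sse_seg, 1e-300) / n) + 2 * 5
    aic_lin = n * np.log(max(sse_lin, 1e-300) / n) + 2 * 3
    has_bp = bool(aic_seg < aic_lin)

    ci = (np.nan, np.nan)
    if has_bp and n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            take = rng.integers(0, n, size=n)
            c_b, _, sse_b = _fit_grid(x[take], y[take], grid)
            if np.isfinite(sse_b):
                boots.append(c_b)
        if boots:
            ci = tuple(np.percentile(boots, [2.5, 97.5]))
    slope_above = float(sol[1])
    slope_below = float(sol[1] + sol[2])
    return BreakpointResult(
        threshold_est=float(c_hat),
        threshold_wtd=float(swc_to_wtd(c_hat)),
        sse_segmented=sse_seg,
        sse_linear=sse_lin,
        has_breakpoint=has_bp,
        bootstrap_ci=ci,
        slopes=(slope_below, slope_above),
    )


def rda(Y, X, response_names=None, explanatory_names=None):
    """Redundancy analysis: constrained ordination of responses on drivers.

    Both matrices are column-standardized; Y is regressed on X by least
    squares and the fitted values are decomposed by SVD. Axis directions
    are orthonormal in response space; per-axis proportion explained is
    relative to the total variance of (standardized) Y, so constrained
    plus residual variance conserves the total. Variable arrows are the
    correlations of each explanatory column with the constrained site
    scores (correlation-scaled biplot).

    Collinear explanatory columns are dropped (recorded on the result).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim == 1:
        X = X[:, None]
    if len(Y) != len(X):
        raise ValueError("Y and X must have the same number of rows")
    ok = ~(np.isnan(Y).any(axis=1) | np.isnan(X).any(axis=1))
    Y, X = Y[ok], X[ok]
    n = len(Y)
    if n < X.shape[1] + 2:
        raise ValueError("too few complete cases for the ordination")
    rnames = list(response_names) if response_names else [f"y{i}" for i in range(Y.shape[1])]
    xnames = list(explanatory_names) if explanatory_names else [f"x{i}" for i in range(X.shape[1])]

    def _std(M):
        mu = M.mean(axis=0)
        sd = M.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        return (M - mu) / sd

    Ys = _std(Y)
    Xs = _std(X)
    # drop collinear columns via rank-revealing QR
    q, r, piv = _qr_pivot(Xs)
    tol = max(Xs.shape) * np.finfo(float).eps * abs(r[0, 0]) if r.size else 0.0
    rank = int(np.sum(np.abs(np.diag(r)) > max(tol, 1e-10)))
    keep_cols = sorted(piv[:rank])
    dropped = [xnames[i] for i in range(Xs.shape[1]) if i not in keep_cols]
    Xk = Xs[:, keep_cols]
    xnames_k = [xnames[i] for i in keep_cols]

    beta, _, _, _ = np.linalg.lstsq(Xk, Ys, rcond=None)
    Yhat = Xk @ beta
    u, svals, vt = np.linalg.svd(Yhat / np.sqrt(n - 1), full_matrices=False)
    n_axes = int(np.sum(svals > 1e-12))
    v = vt.T[:, :n_axes]
    eig = svals[:n_axes] ** 2
    total_var = float(np.sum(Ys.var(axis=0, ddof=1)))
    proportion = eig / total_var
    scores = Yhat @ v
    arrows = np.zeros((Xk.shape[1], n_axes))
    for j in range(Xk.shape[1]):
        for a in range(n_axes):
            sc = scores[:, a]
            if np.std(sc) > 0 and np.std(Xk[:, j]) > 0:
                arrows[j, a] = np.corrcoef(Xk[:, j], sc)[0, 1]
    loadings = v * np.sqrt(eig)
    axis_names = [f"RDA{a + 1}" for a in range(n_axes)]
    return RDAResult(
        constrained_axis_scores=scores,
        variable_arrows=pd.DataFrame(arrows, index=xnames_k, columns=axis_names),
        response_loadings=pd.DataFrame(loadings, index=rnames, columns=axis_names),
        proportion_explained=proportion,
        axes=v,
        dropped_columns=dropped,
    )


def _qr_pivot(M):
    from scipy import linalg

    q, r, piv = linalg.qr(M, mode="economic", pivoting=True)
    return q, r, piv
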