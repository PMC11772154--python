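"""Drought and plant-water-stress indicators for weekly peatland records.

Covers the moisture coefficient (ET/PET ratio with its 0.6 weekly stress
cut-off), a standardized precipitation-evapotranspiration index (SPEI)
computed from rolling climatic water-balance sums via a three-parameter
log-logistic distribution fitted with unbiased probability-weighted
moments, and the fixed-threshold annual high/low classification of
drought-related parameters.

With only a few years of weekly data the log-logistic fit pools all
rolling sums into a single calibration sample rather than fitting one
distribution per calendar week.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "WEEKLY_STRESS_THRESHOLD",
    "ANNUAL_THRESHOLDS",
    "moisture_coefficient",
    "fit_loglogistic_pwm",
    "spei",
    "annual_summary",
    "classify_years",
]

#: Weekly moisture-coefficient value below which plants count as water stressed.
WEEKLY_STRESS_THRESHOLD = 0.6

#: Fixed annual classification thresholds (value, direction).
ANNUAL_THRESHOLDS = {
    "stress_high": ("moisture_coefficient", "<", 0.4),
    "drought_severe": ("spei", "<=", -1.5),
    "gsw_high": ("gsw", ">=", 0.2),
    "et_high": ("et", ">=", 3.0),
    "swc_decline_high": ("swc", "<", 82.5),
    "ef_high": ("ef", ">", 0.5),
}


def moisture_coefficient(et, pet, stress_threshold=WEEKLY_STRESS_THRESHOLD):
    """Moisture coefficient ET/PET and the weekly water-stress flag.

    Parameters
    ----------
    et, pet : array-like
        Actual and potential evapotranspiration, same units (mm day-1).
    stress_threshold : float
        Strict cut-off: a week is stressed iff ratio < threshold.

    Returns
    -------
    (ratio, stressed) : ndarray, ndarray of bool
        ``ratio`` is NaN where ``pet <= 0`` (undefined, flagged);
        ``stressed`` is False there.
    """
    et = np.asarray(et, dtype=float)
    pet = np.asarray(pet, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pet > 0, et / pet, np.nan)
    stressed = np.where(np.isnan(ratio), False, ratio < stress_threshold)
    return ratio, stressed


def _unbiased_pwm(sorted_x, s):
    """Unbiased sample probability-weighted moment ``E[X (1-F)^s]``.

    ``sorted_x`` must be in ascending order.
    """
    n = len(sorted_x)
    i = np.arange(1, n + 1)
    w = special.comb(n - i, s) / special.comb(n - 1, s)
    return float(np.sum(w * sorted_x) / n)


def fit_loglogistic_pwm(x):
    """Fit a three-parameter log-logistic distribution by unbiased PWMs.

    CDF: ``F(x) = (1 + (alpha / (x - loc))**beta)**-1`` for ``x > loc``.

    Returns
    -------
    (alpha, beta, loc) : floats
        Scale, shape, and location parameters.

    Raises
    ------
    ValueError
        If the sample is too small, degenerate (constant), or the PWM
        system has no admissible solution (shape <= 1 breaks the mean).
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 4:
        raise ValueError("need at least 4 values to fit the distribution")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) water-balance series: fit failure")
    # Centre before computing PWMs: the shape estimate is a ratio of
    # small differences of large moments, so a big location offset causes
    # catastrophic cancellation. The location parameter absorbs the shift.
    shift = float(np.mean(x))
    xs = np.sort(x - shift)
    w0 = _unbiased_pwm(xs, 0)
    w1 = _unbiased_pwm(xs, 1)
    w2 = _unbiased_pwm(xs, 2)
    den = 6.0 * w1 - w0 - 6.0 * w2
    if den == 0:
        raise ValueError("probability-weighted moments are degenerate")
    beta = (2.0 * w1 - w0) / den
    if beta <= 1.0:
        raise ValueError(f"inadmissible log-logistic shape {beta:.4f} (<= 1)")
    g1 = special.gamma(1.0 + 1.0 / beta)
    g2 = special.gamma(1.0 - 1.0 / beta)
    alpha = (w0 - 2.0 * w1) * beta / (g1 * g2)
    if alpha <= 0:
        raise ValueError("inadmissible log-logistic scale")
    loc = w0 - alpha * g1 * g2 + shift
    return float(alpha), float(beta), float(loc)


def spei(water_balance, scale=12):
    """Standardized index of the rolling climatic water balance.

    Rolling ``scale``-week sums of the water balance (P - PET, mm) are
    fitted with a three-parameter log-logistic distribution via unbiased
    probability-weighted moments; probabilities are mapped to standard
    normal quantiles. Over the calibration sample the index has mean
    ~0 and standard deviation ~1, and it is invariant to adding a
    constant to the balance series (the location parameter absorbs it).

    Parameters
    ----------
    water_balance : array-like
        Weekly water balance, length >= 2 * scale.
    scale : int
        Accumulation window in weeks (>= 1).

    Returns
    -------
    ndarray
        SPEI aligned with the input; the first ``scale - 1`` entries are
        NaN (incomplete window).
    """
    wb = np.asarray(water_balance, dtype=float)
    if scale < 1:
        raise ValueError("scale must be >= 1")
    if len(wb) < 2 * scale:
        raise ValueError(f"series length {len(wb)} < 2*scale = {2 * scale}")
    sums = pd.Series(wb).rolling(scale).sum().to_numpy()
    valid = ~np.isnan(sums)
    x = sums[valid]
    # Left-skewed balances can push the PWM shape estimate out of the
    # admissible range; fitting the reflected sample is the standard fix.
    try:
        alpha, beta, loc = fit_loglogistic_pwm(x)
        reflected = False
    except ValueError as err:
        if "inadmissible" not in str(err):
            raise
        alpha, beta, loc = fit_loglogistic_pwm(-x)
        reflected = True
    z = (-x if reflected else x) - loc
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        prob = np.where(z > 0, 1.0 / (1.0 + (alpha / np.maximum(z, 1e-300)) ** beta), 0.0)
    if reflected:
        prob = 1.0 - prob
    # Keep quantiles finite for sums below the fitted support.
    prob = np.clip(prob, 1e-12, 1.0 - 1e-12)
    out = np.full(len(wb), np.nan)
    out[valid] = stats.norm.ppf(prob)
    return out


def annual_summary(df, growing_season=(4, 9)):
    """Per-year summaries feeding the high/low classification.

    Growing-season (month range, inclusive) means of the moisture
    coefficient, Gsw, ET, and EF; growing-season minima of SWC and SPEI
    (drought severity reflects the summer minimum).

    Parameters
    ----------
    df : pandas.DataFrame
        Weekly table with ``week_start`` plus columns MOISTURE_COEF,
        SPEI, GSW, ET, SWC, EF (missing columns yield NaN summaries).
    growing_season : (int, int)
        First and last month of the growing season.

    Returns
    -------
    pandas.DataFrame indexed by year.
    """
    months = pd.DatetimeIndex(df["week_start"]).month
    years = pd.DatetimeIndex(df["week_start"]).year
    in_gs = (months >= growing_season[0]) & (months <= growing_season[1])
    gs = df.loc[in_gs].copy()
    gs_years = years[in_gs]

    def _col(name):
        return gs[name] if name in gs else pd.Series(np.nan, index=gs.index)

    agg = pd.DataFrame(
        {
            "moisture_coefficient": _col("MOISTURE_COEF"),
            "spei": _col("SPEI"),
            "gsw": _col("GSW"),
            "et": _col("ET"),
            "swc": _col("SWC"),
            "ef": _col("EF"),
            "year": gs_years,
        }
    )
    grouped = agg.groupby("year")
    out = grouped[["moisture_coefficient", "gsw", "et", "ef"]].mean()
    out["swc"] = grouped["swc"].min()
    out["spei"] = grouped["spei"].min()
    return out


@dataclass(frozen=True)
class YearClassification:
    """Boolean high/low flags for one year's drought-related parameters."""

    year: int
    stress_high: bool
    drought_severe: bool
    gsw_high: bool
    et_high: bool
    swc_decline_high: bool
    ef_high: bool


_OPS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
}


def classify_years(summary):
    """Apply the fixed annual thresholds to per-year summaries.

    Inequality directions are exact: stress is high when the moisture
    coefficient is strictly below 0.4; drought is severe when SPEI <= -1.5;
    Gsw and ET are high at >= 0.2 m s-1 and >= 3 mm day-1; SWC decline is
    high strictly below 82.5 %; EF is high strictly above 0.5.

    Parameters
    ----------
    summary : pandas.DataFrame
        Output of :func:`annual_summary` (indexed by year).

    Returns
    -------
    list of YearClassification
    """
    results = []
    for year, row in summary.iterrows():
        flags = {}
        for flag, (field, op, value) in ANNUAL_THRESHOLDS.items():
            if field not in row or pd.isna(row[field]):
                raise ValueError(f"missing summary field {field!r} for year {year}")
            flags[flag] = bool(_OPS[op](row[field], value))
        results.append(YearClassification(year=int(year), **flags))
    return results
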