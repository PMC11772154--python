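"""Empirical dynamic modelling from first principles.

Time-delay embedding, simplex projection (leave-one-out nearest-neighbour
forecasting, used to select the embedding dimension), S-maps (locally
weighted linear maps whose per-point coefficients quantify time-varying
interaction strengths), and convergent cross mapping (CCM) with the
``sqrt((1 - rho^2) / (N - 3))`` standard error on the cross-map skill.

Conventions: distances are Euclidean on z-scored coordinates; simplex
uses E+1 neighbours with exponential weights ``exp(-d/d_min)`` floored at
1e-6; equidistant neighbours are broken by time index so all routines are
deterministic; CCM library subsets are drawn with replacement from a
seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "EmbeddingConfig",
    "CCMResult",
    "SMapResult",
    "embed",
    "simplex",
    "smap",
    "ccm",
    "cross_map_se",
]

_WEIGHT_FLOOR = 1e-6


@dataclass(frozen=True)
class EmbeddingConfig:
    """Settings for state-space reconstruction and prediction."""

    E: int = 3
    tau: int = 1
    tp: int = 1
    theta: float = 0.0
    exclusion_radius: int = 0

    def __post_init__(self):
        if self.E < 1:
            raise ValueError("embedding dimension E must be >= 1")
        if self.tau < 1:
            raise ValueError("lag step tau must be >= 1")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")


@dataclass
class CCMResult:
    """Cross-map skill versus library size for one directed pair."""

    cause_name: str
    effect_name: str
    lib_sizes: np.ndarray
    rho: np.ndarray
    se: np.ndarray
    converged: bool
    rho_max: float
    E: int = 0
    tp: int = 0


@dataclass
class SMapResult:
    """Per-week locally linear coefficients for one target variable."""

    target_name: str
    theta: float
    coefficients: np.ndarray  # (n_rows, n_drivers)
    intercepts: np.ndarray
    predictions: np.ndarray
    forecast_skill: float
    driver_names: list = field(default_factory=list)
    valid_index: np.ndarray | None = None


def embed(series, E, tau=1):
    """Time-delay embedding.

    Row for time ``t`` is ``(x_t, x_{t-tau}, ..., x_{t-(E-1)tau})``. Rows
    whose lags would fall before the start of the series are dropped;
    rows containing NaN in any lag are dropped too.

    Returns
    -------
    (block, index) : ndarray (n_rows, E), ndarray of int
        ``index[i]`` is the time index of the leading coordinate of row i.
    """
    x = np.asarray(series, dtype=float)
    if E < 1 or tau < 1:
        raise ValueError("E and tau must be >= 1")
    span = (E - 1) * tau
    if len(x) <= span:
        raise ValueError(f"series of length {len(x)} too short for E={E}, tau={tau}")
    t = np.arange(span, len(x))
    block = np.column_stack([x[t - j * tau] for j in range(E)])
    keep = ~np.isnan(block).any(axis=1)
    return block[keep], t[keep]


def _standardize(block):
    mu = np.nanmean(block, axis=0)
    sd = np.nanstd(block, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (block - mu) / sd


def _pearson(a, b):
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        return np.nan
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def _simplex_weights(d_sorted):
    """Exponential simplex weights for an ascending distance vector."""
    d_min = d_sorted[0]
    if d_min > 0:
        w = np.exp(-d_sorted / d_min)
    else:
        # Exact-match neighbours get full weight, the rest the floor.
        w = np.where(d_sorted == 0, 1.0, 0.0)
    w = np.maximum(w, _WEIGHT_FLOOR)
    return w / w.sum()


def _knn_predict(dist_row, candidates, values, k):
    """Simplex prediction from the k nearest candidates (stable ties)."""
    d = dist_row[candidates]
    if len(d) < k:
        return np.nan
    # argsort is stable, so equidistant neighbours resolve by time index.
    order = np.argsort(d, kind="stable")[:k]
    w = _simplex_weights(d[order])
    return float(np.dot(w, values[candidates[order]]))


def simplex(series, E_range=range(1, 11), tau=1, tp=1, exclusion_radius=0):
    """Leave-one-out simplex forecast skill for each embedding dimension.

    For each E the series is embedded, every point is predicted ``tp``
    steps ahead from its E+1 nearest neighbours (itself and any point
    within ``exclusion_radius`` in time excluded), and skill is the
    Pearson correlation between predictions and observations.

    Returns
    -------
    (skills, best_E) : dict {E: rho}, int
    """
    x = np.asarray(series, dtype=float)
    finite = x[~np.isnan(x)]
    if len(finite) and np.ptp(finite) == 0:
        raise ValueError("constant series: forecast skill undefined")
    skills = {}
    for E in E_range:
        block, idx = embed(x, E, tau)
        target_t = idx + tp
        ok = (target_t >= 0) & (target_t < len(x))
        block_v, idx_v = block[ok], idx[ok]
        y = x[target_t[ok]]
        ok2 = ~np.isnan(y)
        block_v, idx_v, y = block_v[ok2], idx_v[ok2], y[ok2]
        if len(y) < E + 2:
            skills[E] = np.nan
            continue
        z = _standardize(block_v)
        dist = np.sqrt(((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2))
        preds = np.full(len(y), np.nan)
        all_idx = np.arange(len(y))
        for i in range(len(y)):
            cand = all_idx[np.abs(idx_v - idx_v[i]) > exclusion_radius]
            preds[i] = _knn_predict(dist[i], cand, y, E + 1)
        skills[E] = _pearson(preds, y)
    finite_skills = {e: s for e, s in skills.items() if not np.isnan(s)}
    if not finite_skills:
        raise ValueError("no embedding dimension produced a defined skill")
    best_E = max(finite_skills, key=finite_skills.get)
    return skills, best_E


def smap(block, target, theta, driver_names=None, target_name="target"):
    """S-map: locally weighted linear fits at every point of a state block.

    For each row ``t`` a weighted least-squares linear map from the block
    columns to the target is solved (SVD-backed), with weights
    ``w_i = exp(-theta * d(x_i, x_t) / d_mean)`` where ``d_mean`` is the
    mean distance from ``x_t`` to all rows. The per-row coefficients are
    the local interaction strengths (e.g. dGPP/dSWC). ``theta = 0`` gives
    uniform weights, so every row's coefficients equal the global
    ordinary-least-squares solution.

    Parameters
    ----------
    block : ndarray (n, p)
        Multivariate state, columns standardized by the caller or not
        (distances are computed on z-scored columns internally; the
        regression itself uses the block as given).
    target : ndarray (n,)
        Response aligned with the block rows.
    theta : float
        Nonlinearity parameter >= 0.

    Returns
    -------
    SMapResult
    """
    block = np.asarray(block, dtype=float)
    y = np.asarray(target, dtype=float)
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if block.ndim != 2 or len(block) != len(y):
        raise ValueError("block and target must be aligned 2-D/1-D arrays")
    ok = ~(np.isnan(block).any(axis=1) | np.isnan(y))
    bv, yv = block[ok], y[ok]
    n, p = bv.shape
    if n < p + 2:
        raise ValueError("too few complete rows for the S-map fit")
    z = _standardize(bv)
    dist = np.sqrt(((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2))
    coef = np.full((n, p), np.nan)
    intercept = np.full(n, np.nan)
    preds = np.full(n, np.nan)
    design = np.column_stack([np.ones(n), bv])
    for t in range(n):
        d_mean = dist[t].mean()
        if d_mean > 0:
            w = np.exp(-theta * dist[t] / d_mean)
        else:
            w = np.ones(n)
        sw = np.sqrt(w)
        try:
            sol, _, rank, _ = np.linalg.lstsq(design * sw[:, None], yv * sw, rcond=None)
        except np.linalg.LinAlgError:
            continue  # singular design: week stays flagged as NaN
        if rank < p + 1:
            continue
        intercept[t] = sol[0]
        coef[t] = sol[1:]
        preds[t] = design[t] @ sol
    skill = _pearson(preds, yv)
    names = list(driver_names) if driver_names is not None else [f"x{i}" for i in range(p)]
    return SMapResult(
        target_name=target_name,
        theta=float(theta),
        coefficients=coef,
        intercepts=intercept,
        predictions=preds,
        forecast_skill=skill,
        driver_names=names,
        valid_index=np.flatnonzero(ok),
    )


def cross_map_se(rho, n):
    """Standard error of a cross-map skill: ``sqrt((1 - rho^2)/(N - 3))``."""
    rho = np.asarray(rho, dtype=float)
    n = np.asarray(n)
    if np.any(n <= 3):
        raise ValueError("library size N must exceed 3")
    if np.any(np.abs(rho) > 1 + 1e-12):
        raise ValueError("|rho| must be <= 1")
    se = np.sqrt((1.0 - np.clip(rho, -1, 1) ** 2) / (n - 3))
    return float(se) if se.ndim == 0 else se


def ccm(
    cause,
    effect,
    E,
    tau=1,
    tp=-1,
    lib_sizes=None,
    n_samples=100,
    seed=0,
    cause_name="cause",
    effect_name="effect",
    convergence_gain=0.1,
    exclusion_radius=0,
):
    """Convergent cross mapping of ``cause`` from the effect's manifold.

    The effect series is delay-embedded (its shadow manifold). For each
    library size, ``n_samples`` random libraries are drawn with
    replacement (seeded); every reconstructed state cross-maps the cause
    at horizon ``tp`` (default -1: the cause one step before the effect's
    state) via simplex weights over the E+1 nearest library neighbours.
    Skill is the Pearson correlation between observed and cross-mapped
    cause values, averaged over samples. A Theiler window
    (``exclusion_radius``, weeks) removes temporally adjacent states from
    the neighbour candidates, which matters for autocorrelated series.

    Convergence verdict: skill gain from the smallest to the largest
    library exceeds ``convergence_gain`` and the final skill exceeds
    1.96 standard errors.

    Returns
    -------
    CCMResult
    """
    cause = np.asarray(cause, dtype=float)
    effect = np.asarray(effect, dtype=float)
    if len(cause) != len(effect):
        raise ValueError("cause and effect series must be aligned")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    block, idx = embed(effect, E, tau)
    target_t = idx + tp
    ok = (target_t >= 0) & (target_t < len(cause))
    block, idx = block[ok], idx[ok]
    y = cause[target_t[ok]]
    ok2 = ~np.isnan(y)
    block, idx, y = block[ok2], idx[ok2], y[ok2]
    n = len(y)
    if lib_sizes is None:
        lib_sizes = np.unique(np.linspace(E + 2, n, 8, dtype=int))
    lib_sizes = np.asarray(sorted(lib_sizes), dtype=int)
    if lib_sizes[-1] > n:
        raise ValueError(f"library size {lib_sizes[-1]} exceeds usable points {n}")
    if np.any(np.diff(lib_sizes) <= 0):
        raise ValueError("lib_sizes must be strictly increasing")

    z = _standardize(block)
    dist = np.sqrt(((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2))
    rng = np.random.default_rng(seed)
    k = E + 1
    all_rows = np.arange(n)
    mean_rho = np.empty(len(lib_sizes))
    for s_i, L in enumerate(lib_sizes):
        rhos = np.empty(n_samples)
        for j in range(n_samples):
            lib = np.unique(rng.integers(0, n, size=L))  # sampled with replacement
            preds = np.full(n, np.nan)
            for i in all_rows:
                cand = lib[np.abs(idx[lib] - idx[i]) > exclusion_radius]
                if len(cand) < k:
                    continue
                preds[i] = _knn_predict(dist[i], cand, y, k)
            rhos[j] = _pearson(preds, y)
        mean_rho[s_i] = np.nanmean(rhos)
    se = cross_map_se(np.clip(mean_rho, -1, 1), lib_sizes)
    rho_max = mean_rho[-1]
    converged = bool(
        (rho_max - mean_rho[0]) > convergence_gain and rho_max > 1.96 * se[-1]
    )
    return CCMResult(
        cause_name=cause_name,
        effect_name=effect_name,
        lib_sizes=lib_sizes,
        rho=mean_rho,
        se=np.atleast_1d(se),
        converged=converged,
        rho_max=float(rho_max),
        E=E,
        tp=tp,
    )
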