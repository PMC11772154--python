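"""Synthetic data generators with known causal structure.

Two generators back the test and validation suites:

* :func:`gen_coupled_logistic` — a pair of coupled logistic maps with
  tunable, possibly asymmetric coupling; the standard fixture for
  validating cross-mapping causality detection.
* :func:`gen_bog_weekly` — five years (by default) of weekly bog records
  with seasonal drivers, drought years, a soil-water store whose response
  to evapotranspiration is delayed by a tunable number of weeks, a GPP
  model with vapour-pressure-deficit down-regulation and a soil-moisture
  limitation that switches on only below a threshold, and seeded additive
  observation noise per channel.

Every implanted mechanism (thresholds, lag, driver sets, the SWC-WTD
affine link) is exposed on the returned :class:`BogTruth` so inference
results can be scored against ground truth.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import micromet

__all__ = [
    "CoupledMapConfig",
    "SimConfig",
    "BogTruth",
    "gen_coupled_logistic",
    "gen_bog_weekly",
    "swc_to_wtd",
    "wtd_to_swc",
]

#: Anchors of the fixed monotone affine SWC (%) <-> WTD (cm) link:
#: 82.5 % corresponds to -8 cm, saturation (100 %) to +2 cm.
_SWC_REF, _WTD_REF = 82.5, -8.0
_SWC_SAT, _WTD_SAT = 100.0, 2.0
_WTD_SLOPE = (_WTD_SAT - _WTD_REF) / (_SWC_SAT - _SWC_REF)

#: Default per-channel observation noise (standard deviations).
DEFAULT_NOISE_SD = {
    "TA": 1.0,
    "SW_IN": 22.0,
    "VPD": 0.2,
    "WS": 0.25,
    "USTAR": 0.02,
    "P": 4.0,
    "LE": 6.0,
    "GPP": 0.15,
    "RECO": 0.1,
    "SWC": 0.15,
    "WTD": 0.3,
    "CO2": 1.0,
}


def swc_to_wtd(swc):
    """Map volumetric soil water content (%) to water table depth (cm)."""
    return _WTD_REF + _WTD_SLOPE * (np.asarray(swc, dtype=float) - _SWC_REF)


def wtd_to_swc(wtd):
    """Inverse of :func:`swc_to_wtd`."""
    return _SWC_REF + (np.asarray(wtd, dtype=float) - _WTD_REF) / _WTD_SLOPE


@dataclass(frozen=True)
class CoupledMapConfig:
    """Parameters of the coupled logistic map pair.

    ``beta_xy`` is the strength with which y forces x; ``beta_yx`` the
    strength with which x forces y.
    """

    r_x: float = 3.8
    r_y: float = 3.5
    beta_xy: float = 0.02
    beta_yx: float = 0.1
    n_steps: int = 1000
    burn_in: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.burn_in < 0 or self.n_steps <= self.burn_in:
            raise ValueError("require n_steps > burn_in >= 0")


def gen_coupled_logistic(config):
    """Simulate the coupled logistic pair; returns (x, y) after burn-in.

    Dynamics::

        x[t+1] = x[t] * (r_x - r_x * x[t] - beta_xy * y[t])
        y[t+1] = y[t] * (r_y - r_y * y[t] - beta_yx * x[t])

    Deterministic given the seed (which sets the initial conditions).

    Raises
    ------
    ValueError
        If a trajectory leaves the open interval (0, 1) — the parameters
        are inadmissible and must be rejected, not silently clipped.
    """
    rng = np.random.default_rng(config.seed)
    x = np.empty(config.n_steps)
    y = np.empty(config.n_steps)
    x[0], y[0] = rng.uniform(0.2, 0.8, size=2)
    for t in range(config.n_steps - 1):
        x[t + 1] = x[t] * (config.r_x - config.r_x * x[t] - config.beta_xy * y[t])
        y[t + 1] = y[t] * (config.r_y - config.r_y * y[t] - config.beta_yx * x[t])
        if not (0.0 < x[t + 1] < 1.0 and 0.0 < y[t + 1] < 1.0):
            raise ValueError(
                f"trajectory left (0,1) at step {t + 1}; inadmissible parameters"
            )
    return x[config.burn_in :], y[config.burn_in :]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the weekly bog generator.

    The headline parameters are the implanted ground truths recovered by
    the downstream analysis: ``swc_threshold`` (% volumetric) below which
    GPP becomes soil-moisture limited, the equivalent ``wtd_threshold``
    (cm, negative below surface), and ``et_swc_lag`` — the travel time,
    in weeks, of the soil-water response to evapotranspiration.

    The soil-water store is an exponential smoother with a plug-flow
    delay: the storage forcing at week ``t`` is ``et_ref - ET[t - lag]``
    and is relaxed at ``drainage_rate`` per week. The default
    ``drainage_rate = 1`` makes the store memoryless apart from the
    delay, so the implanted lag is exactly identifiable from the output.
    SWC amplitude scales inversely with ``bucket_capacity``.

    Remaining fields are documented artifact choices (the source study's
    conceptual diagram fixes mechanisms, not functional forms): VPD
    down-regulation of conductance and GPP is exponential with slope
    ``stomatal_sensitivity``; the sub-threshold SWC limitation of GPP is
    linear with slope ``swc_decline_slope`` per percentage point.
    """

    n_years: int = 5
    seed: int = 0
    swc_threshold: float = 82.5
    wtd_threshold: float = -8.0
    et_swc_lag: int = 14
    drought_years: tuple = (0, 2, 4)
    stomatal_sensitivity: float = 0.4
    bucket_capacity: float = 510.0
    drainage_rate: float = 1.0
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    start_year: int = 2016
    # artifact defaults of the forcing / response model
    gs_max: float = 0.012
    gpp_max: float = 4.2
    gpp_base: float = 0.15
    vpd_comp_point: float = 0.5
    swc_decline_slope: float = 0.2
    et_ref: float = 2.0
    swc_eq: float = 96.0
    vpd_drought_boost: float = 1.2
    drought_phase_advance: int = 8
    interannual_sd: float = 0.12
    weather_persistence: float = 0.65
    stomatal_memory: float = 0.6
    available_energy_frac: float = 0.65
    decouple_gpp: bool = False

    def __post_init__(self):
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if not 0.0 < self.swc_threshold < 100.0:
            raise ValueError("swc_threshold must be in (0, 100)")
        if self.et_swc_lag < 0:
            raise ValueError("et_swc_lag must be >= 0")
        if self.bucket_capacity <= 0:
            raise ValueError("bucket_capacity must be positive")
        if not 0.0 < self.drainage_rate <= 1.0:
            raise ValueError("drainage_rate must be in (0, 1]")
        bad = [k for k, v in self.noise_sd.items() if v < 0]
        if bad:
            raise ValueError(f"negative noise_sd for channels {bad}")


@dataclass(frozen=True)
class BogTruth:
    """Implanted causal structure of one :func:`gen_bog_weekly` run."""

    swc_threshold: float
    wtd_threshold: float
    et_swc_lag: int
    gpp_drivers: tuple
    independent_channels: tuple
    swc_wtd_slope: float
    drought_years: tuple


def _season(woy):
    """Smooth annual cycle in [0, 1], peaking mid-summer (week ~26)."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (np.asarray(woy, dtype=float) + 0.5) / 52.0))


def gen_bog_weekly(config):
    """Generate a weekly bog record table plus its ground truth.

    Returns
    -------
    (df, truth) : pandas.DataFrame, BogTruth
        ``df`` has 52 rows per simulated year with AmeriFlux-style
        columns (TA, SW_IN, VPD, WS, USTAR, H, LE, P, GPP, RECO, NEE,
        SWC, WTD, CO2, ET) and an ISO ``week_start`` column. Identical
        config and seed give bit-identical tables.
    """
    cfg = config
    lag = cfg.et_swc_lag
    burn = lag + 8
    n_keep = cfg.n_years * 52
    n_tot = burn + n_keep
    rng = np.random.default_rng(cfg.seed)

    def noise(channel, size):
        sd = cfg.noise_sd.get(channel, 0.0)
        return rng.normal(0.0, sd, size) if sd > 0 else np.zeros(size)

    def red_noise(channel, size):
        """AR(1) weather anomalies with the channel's stationary sd."""
        phi = cfg.weather_persistence
        sd = cfg.noise_sd.get(channel, 0.0)
        if sd <= 0:
            return np.zeros(size)
        e = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), size)
        out = np.empty(size)
        out[0] = e[0]
        for t in range(1, size):
            out[t] = phi * out[t - 1] + e[t]
        return out

    # Week-of-year indices; burn weeks wrap through the preceding year.
    w = np.arange(n_tot) - burn
    woy = np.mod(w, 52)
    year_idx = np.floor_divide(w, 52)
    s = _season(woy)
    in_drought_year = np.isin(year_idx, np.asarray(cfg.drought_years, dtype=int))
    # Drought stress is phase-advanced so its lagged soil-water imprint
    # lands inside the growing season.
    drought = in_drought_year * _season(woy + cfg.drought_phase_advance)

    # Seeded interannual amplitude variability of the seasonal forcing,
    # so years are not carbon copies of each other (clipped so the
    # no-drought system can never be pushed across the SWC threshold).
    n_amp_years = int(year_idx.max()) - int(year_idx.min()) + 1
    amp = 1.0 + np.clip(
        cfg.interannual_sd * rng.standard_normal((3, n_amp_years)), -0.25, 0.25
    )
    ai = year_idx - int(year_idx.min())
    amp_ta, amp_sw, amp_vpd = amp[0][ai], amp[1][ai], amp[2][ai]

    sw_noise = red_noise("SW_IN", n_tot)
    ta = -1.0 + 19.0 * amp_ta * s + 3.0 * drought + red_noise("TA", n_tot)
    sw_in = np.maximum(15.0 + 235.0 * amp_sw * s + sw_noise, 0.0)
    vpd = np.maximum(
        0.05 + 0.85 * amp_vpd * s + cfg.vpd_drought_boost * drought
        + red_noise("VPD", n_tot),
        1e-3,
    )
    ws = np.maximum(2.3 + 0.4 * np.cos(2.0 * np.pi * woy / 52.0) + noise("WS", n_tot), 0.2)
    ustar = np.maximum(0.05 + 0.09 * ws + noise("USTAR", n_tot), 0.02)
    precip = np.maximum(
        8.0 + 55.0 * (1.0 - s) * (1.0 - 0.35 * in_drought_year) + noise("P", n_tot), 0.0
    )
    co2 = 412.0 + noise("CO2", n_tot)

    # Forward Penman-Monteith with prescribed surface conductance. The
    # available energy uses the climatological radiation (amplitude
    # factor excluded): energy partitioning buffers interannual radiation
    # anomalies, which also bounds interannual ET so that only drought
    # years can draw the soil store below the GPP threshold.
    avail = cfg.available_energy_frac * np.maximum(15.0 + 235.0 * s + sw_noise, 2.0)
    gsw = cfg.gs_max * (0.3 + 0.7 * s) * np.exp(-cfg.stomatal_sensitivity * vpd)
    le = np.empty(n_tot)
    lam = np.empty(n_tot)
    for i in range(n_tot):
        st = micromet.psychro_state(float(ta[i]), rh=75.0)
        lam[i] = st.lam
        le[i] = micromet.pm_latent_heat(gsw[i], _gah(ws[i], ustar[i]), avail[i], vpd[i], st)
    le = np.maximum(le + noise("LE", n_tot), 0.0)
    h = avail - le
    et = micromet.et_from_latent_heat(le, lam)

    # Soil-water store: plug-flow delay of the ET forcing plus an
    # exponential relaxation at drainage_rate per week.
    et_gain = 2800.0 / cfg.bucket_capacity
    forcing = np.zeros(n_tot)
    forcing[lag:] = cfg.et_ref - et[: n_tot - lag] if lag > 0 else cfg.et_ref - et
    forcing[:lag] = forcing[lag] if lag > 0 else forcing[:lag]
    a = np.empty(n_tot)
    a[0] = forcing[0]
    d = cfg.drainage_rate
    for t in range(1, n_tot):
        a[t] = (1.0 - d) * a[t - 1] + d * forcing[t]
    swc_raw = cfg.swc_eq + et_gain * a
    # Smooth saturation keeps SWC strictly monotone in the forcing while
    # approaching (not clipping at) 100 %.
    sharp = 2.0
    swc_true = 100.0 - sharp * np.log1p(np.exp((100.0 - swc_raw) / sharp))
    swc_true = np.maximum(swc_true, 0.0)
    wtd_true = swc_to_wtd(swc_true)

    # GPP: light use x VPD down-regulation x sub-threshold SWC limitation.
    # The light term consumes the actual SW_IN channel (including its
    # noise), so SW_IN is a genuine dynamical driver, not a shared proxy.
    f_light = sw_in / 250.0
    f_vpd = np.exp(-cfg.stomatal_sensitivity * np.maximum(vpd - cfg.vpd_comp_point, 0.0))
    # Stomatal state adjusts towards the VPD-set target with memory, so
    # the VPD influence on GPP is distributed over several weeks.
    g_state = np.empty(n_tot)
    g_state[0] = f_vpd[0]
    mu = cfg.stomatal_memory
    for t in range(1, n_tot):
        g_state[t] = (1.0 - mu) * g_state[t - 1] + mu * f_vpd[t]
    deficit = np.maximum(cfg.swc_threshold - swc_true, 0.0)
    f_swc = np.maximum(1.0 - cfg.swc_decline_slope * deficit, 0.0)
    if cfg.decouple_gpp:
        gpp = np.full(n_tot, cfg.gpp_base + 0.5 * cfg.gpp_max)
    else:
        gpp = cfg.gpp_base + cfg.gpp_max * f_light * g_state * f_swc
    gpp = np.maximum(gpp + noise("GPP", n_tot), 0.0)
    reco = np.maximum(0.5 * np.exp(0.08 * ta) + noise("RECO", n_tot), 0.0)
    nee = reco - gpp

    swc = np.clip(swc_true + noise("SWC", n_tot), 0.0, 100.0)
    wtd = wtd_true + noise("WTD", n_tot)

    keep = slice(burn, n_tot)
    week_start = [
        _dt.date(cfg.start_year + int(y), 1, 1) + _dt.timedelta(days=7 * int(wk))
        for y, wk in zip(year_idx[keep], woy[keep])
    ]
    df = pd.DataFrame(
        {
            "week_start": pd.to_datetime(week_start),
            "TA": ta[keep],
            "SW_IN": sw_in[keep],
            "VPD": vpd[keep],
            "WS": ws[keep],
            "USTAR": ustar[keep],
            "H": h[keep],
            "LE": le[keep],
            "P": precip[keep],
            "GPP": gpp[keep],
            "RECO": reco[keep],
            "NEE": nee[keep],
            "SWC": swc[keep],
            "WTD": wtd[keep],
            "CO2": co2[keep],
            "ET": et[keep],
        }
    )
    truth = BogTruth(
        swc_threshold=cfg.swc_threshold,
        wtd_threshold=cfg.wtd_threshold,
        et_swc_lag=cfg.et_swc_lag,
        gpp_drivers=() if cfg.decouple_gpp else ("SW_IN", "VPD", "SWC"),
        independent_channels=("CO2",),
        swc_wtd_slope=_WTD_SLOPE,
        drought_years=tuple(cfg.drought_years),
    )
    return df, truth


def _gah(u, ustar):
    _, _, gah = micromet.aerodynamic_conductance(u, ustar)
    return gah
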