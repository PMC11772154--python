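"""Micrometeorological derivations from weekly flux-tower records.

Implements the big-leaf water-vapour transfer chain used throughout the
package: psychrometric state of the air, the Penman potential
evapotranspiration (PET) combination equation with its empirical wind
function, bulk aerodynamic conductances from friction velocity and wind
speed, the bulk surface conductance obtained by inverting the
Penman-Monteith (PM) equation with available energy approximated as
``H + LE``, and the evaporative fraction.

Unit conventions
----------------
Temperatures in degC, vapour pressures and VPD in kPa, ``s`` and ``gamma``
in kPa K-1, fluxes (``H``, ``LE``) in W m-2, conductances in m s-1,
radiation for PET in MJ m-2 day-1, PET/ET in mm day-1 (== kg H2O m-2 day-1).
The single W m-2 -> MJ m-2 day-1 conversion factor lives in
:data:`WM2_TO_MJ_DAY`; it is applied nowhere else.

Invalid inputs (non-positive denominators, negative conductances) yield
NaN rather than clipped values, so downstream state-space methods never
see truncated records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WM2_TO_MJ_DAY",
    "CP_AIR",
    "SEA_LEVEL_PRESSURE_KPA",
    "PsychroState",
    "saturation_vapour_pressure",
    "latent_heat_of_vaporisation",
    "psychro_state",
    "wind_function",
    "penman_pet",
    "aerodynamic_conductance",
    "pm_latent_heat",
    "surface_conductance",
    "evaporative_fraction",
    "et_from_latent_heat",
    "derive_weekly",
]

#: W m-2 to MJ m-2 day-1 (86400 s / 1e6). The only place this factor appears.
WM2_TO_MJ_DAY = 0.0864

#: Specific heat of moist air at constant pressure, J kg-1 K-1.
CP_AIR = 1013.0

#: Default site pressure (lowland coastal site), kPa.
SEA_LEVEL_PRESSURE_KPA = 101.325

#: Ratio of molecular weights of water vapour and dry air.
_EPSILON = 0.622

#: Specific gas constant of dry air, J kg-1 K-1.
_R_DRY = 287.058


@dataclass(frozen=True)
class PsychroState:
    """Psychrometric scalars of moist air at a given temperature/pressure.

    Attributes
    ----------
    s : float
        Slope of the saturation vapour pressure curve, kPa K-1.
    gamma : float
        Psychrometric constant, kPa K-1.
    lam : float
        Latent heat of vaporisation, MJ kg-1.
    e_sat, e_act : float
        Saturation and actual vapour pressure, kPa.
    rho_air : float
        Moist air density, kg m-3.
    cp : float
        Specific heat of air, J kg-1 K-1.
    pressure : float
        Air pressure, kPa.
    """

    s: float
    gamma: float
    lam: float
    e_sat: float
    e_act: float
    rho_air: float
    cp: float
    pressure: float

    @property
    def vpd(self) -> float:
        """Vapour pressure deficit e_sat - e_act, kPa."""
        return self.e_sat - self.e_act


def saturation_vapour_pressure(tair):
    """Saturation vapour pressure (kPa) via the Magnus formula.

    ``0.6108 * exp(17.27 T / (T + 237.3))`` with T in degC.
    """
    t = np.asarray(tair, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def latent_heat_of_vaporisation(tair):
    """Latent heat of vaporisation (MJ kg-1), linear in air temperature."""
    return 2.501 - 0.002361 * np.asarray(tair, dtype=float)


def psychro_state(tair, rh=None, e_act=None, pressure=SEA_LEVEL_PRESSURE_KPA):
    """Compute the psychrometric state of the air.

    Parameters
    ----------
    tair : float
        Air temperature, degC (plausible range -50..60).
    rh : float, optional
        Relative humidity in percent (0..100). Exactly one of ``rh`` /
        ``e_act`` must be given.
    e_act : float, optional
        Actual vapour pressure, kPa.
    pressure : float
        Air pressure, kPa (> 0).

    Returns
    -------
    PsychroState
    """
    if pressure <= 0:
        raise ValueError(f"pressure must be positive, got {pressure}")
    if not -50.0 <= tair <= 60.0:
        raise ValueError(f"air temperature {tair} degC outside plausible range")
    if (rh is None) == (e_act is None):
        raise ValueError("provide exactly one of rh or e_act")

    e_sat = float(saturation_vapour_pressure(tair))
    if e_act is None:
        if not 0.0 <= rh <= 100.0:
            raise ValueError(f"relative humidity {rh} outside [0, 100]")
        e_act = e_sat * rh / 100.0
    if e_act > e_sat + 1e-12:
        raise ValueError("actual vapour pressure exceeds saturation")

    lam = float(latent_heat_of_vaporisation(tair))
    # d(e_sat)/dT of the Magnus formula.
    s = 4098.0 * e_sat / (tair + 237.3) ** 2
    # cp expressed in MJ kg-1 K-1 so gamma comes out in kPa K-1.
    gamma = (CP_AIR * 1e-6) * pressure / (_EPSILON * lam)
    t_kelvin = tair + 273.15
    # Moist-air density; 0.378 = 1 - epsilon accounts for vapour buoyancy.
    rho_air = 1000.0 * (pressure - 0.378 * e_act) / (_R_DRY * t_kelvin)
    return PsychroState(
        s=s,
        gamma=gamma,
        lam=lam,
        e_sat=e_sat,
        e_act=float(e_act),
        rho_air=rho_air,
        cp=CP_AIR,
        pressure=pressure,
    )


def wind_function(u):
    """Empirical Penman aerodynamic wind function ``fu = 2.626 + 1.381 u``.

    Parameters
    ----------
    u : float or array
        Wind speed at reference height, m s-1 (>= 0).
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("wind speed must be non-negative")
    out = 2.626 + 1.381 * u
    return float(out) if out.ndim == 0 else out


def penman_pet(rn, d, u, state):
    """Penman potential evapotranspiration, mm day-1.

    ``PET = s/(s+gamma) * Rn/lam + gamma/(s+gamma) * Ea`` with the
    aerodynamic term ``Ea = fu * D`` (mm day-1).

    Parameters
    ----------
    rn : float or array
        Net (shortwave) radiation, MJ m-2 day-1.
    d : float or array
        Vapour pressure deficit, kPa.
    u : float or array
        Wind speed, m s-1.
    state : PsychroState

    Returns
    -------
    float or ndarray
        PET in mm day-1; NaN where ``rn`` or ``d`` is missing.
    """
    rn = np.asarray(rn, dtype=float)
    d = np.asarray(d, dtype=float)
    w = state.s / (state.s + state.gamma)
    ea = wind_function(u) * d
    pet = w * rn / state.lam + (1.0 - w) * ea
    # Missing drivers propagate as NaN (flagged), never silently zeroed.
    pet = np.where(np.isnan(rn) | np.isnan(d), np.nan, pet)
    return float(pet) if pet.ndim == 0 else pet


def aerodynamic_conductance(u, u_star):
    """Aerodynamic conductances from wind speed and friction velocity.

    ``Gam = u*^2 / u`` (momentum), ``Gbh = (6.2 u*^-0.67)^-1`` (quasi-laminar
    boundary layer), ``Gah = (1/Gam + 1/Gbh)^-1`` (bulk, heat; series
    resistances). All in m s-1.

    Returns
    -------
    (gam, gbh, gah) : floats or ndarrays
        NaN where ``u <= 0`` or ``u_star <= 0`` (undefined, flagged).
    """
    u = np.asarray(u, dtype=float)
    u_star = np.asarray(u_star, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        gam = np.where((u > 0) & (u_star > 0), u_star**2 / u, np.nan)
        gbh = np.where(u_star > 0, 1.0 / (6.2 * u_star**-0.67), np.nan)
        gah = 1.0 / (1.0 / gam + 1.0 / gbh)
    if gam.ndim == 0:
        return float(gam), float(gbh), float(gah)
    return gam, gbh, gah


def pm_latent_heat(gsw, gah, available_energy, d, state):
    """Forward Penman-Monteith latent heat flux, W m-2.

    ``LE = (s*A + rho*cp*Gah*D) / (s + gamma*(1 + Gah/Gsw))`` with the
    available energy ``A`` in W m-2. This is the forward model whose
    inversion is :func:`surface_conductance`.
    """
    gsw = np.asarray(gsw, dtype=float)
    gah = np.asarray(gah, dtype=float)
    a = np.asarray(available_energy, dtype=float)
    d = np.asarray(d, dtype=float)
    num = state.s * a + state.rho_air * state.cp * gah * d
    den = state.s + state.gamma * (1.0 + gah / gsw)
    le = num / den
    return float(le) if le.ndim == 0 else le


def surface_conductance(le, h, d, gah, state):
    """Bulk surface conductance by inverting Penman-Monteith, m s-1.

    ``Gsw = gamma*LE*Gah / (s*(H+LE) + rho*cp*Gah*D - LE*(s+gamma))``
    where available energy is approximated as ``H + LE``; the denominator
    simplifies to ``s*H + rho*cp*Gah*D - gamma*LE``.

    Weeks with a non-positive denominator or a negative result are
    physically inconsistent and returned as NaN (flagged, not clipped).
    """
    le = np.asarray(le, dtype=float)
    h = np.asarray(h, dtype=float)
    d = np.asarray(d, dtype=float)
    gah = np.asarray(gah, dtype=float)
    den = state.s * h + state.rho_air * state.cp * gah * d - state.gamma * le
    with np.errstate(divide="ignore", invalid="ignore"):
        gsw = state.gamma * le * gah / den
        gsw = np.where((den > 0) & (gsw >= 0), gsw, np.nan)
    return float(gsw) if gsw.ndim == 0 else gsw


def evaporative_fraction(le, h):
    """Evaporative fraction ``EF = LE / (LE + H)``; NaN where LE + H == 0."""
    le = np.asarray(le, dtype=float)
    h = np.asarray(h, dtype=float)
    tot = le + h
    with np.errstate(divide="ignore", invalid="ignore"):
        ef = np.where(tot != 0, le / tot, np.nan)
    return float(ef) if ef.ndim == 0 else ef


def et_from_latent_heat(le, lam):
    """Convert latent heat flux (W m-2) to ET (mm day-1 == kg m-2 day-1)."""
    return np.asarray(le, dtype=float) * WM2_TO_MJ_DAY / lam


def derive_weekly(df, pressure=SEA_LEVEL_PRESSURE_KPA, albedo=0.1, rh=70.0):
    """Append derived columns (PET, GAM, GBH, GAH, GSW, EF, ET) to a table.

    Parameters
    ----------
    df : pandas.DataFrame
        Weekly records with AmeriFlux-style columns TA, SW_IN, VPD, WS,
        USTAR, H, LE. A NETRAD column (W m-2) is used for the PET
        radiation term when present; otherwise net shortwave is
        approximated as ``(1 - albedo) * SW_IN``.
    pressure : float
        Site air pressure, kPa.
    albedo : float
        Shortwave albedo used only in the NETRAD fallback.
    rh : float
        Relative humidity (%) assumed when deriving actual vapour
        pressure is not needed; only air density depends on it weakly.

    Returns
    -------
    pandas.DataFrame
        Copy of ``df`` with derived columns appended.
    """
    out = df.copy()
    rn_wm2 = out["NETRAD"] if "NETRAD" in out else (1.0 - albedo) * out["SW_IN"]
    rn_mj = np.asarray(rn_wm2, dtype=float) * WM2_TO_MJ_DAY

    n = len(out)
    pet = np.full(n, np.nan)
    gam = np.full(n, np.nan)
    gbh = np.full(n, np.nan)
    gah = np.full(n, np.nan)
    gsw = np.full(n, np.nan)
    ef = np.full(n, np.nan)
    et = np.full(n, np.nan)
    ta = np.asarray(out["TA"], dtype=float)
    d = np.asarray(out["VPD"], dtype=float)
    u = np.asarray(out["WS"], dtype=float)
    ustar = np.asarray(out["USTAR"], dtype=float)
    h = np.asarray(out["H"], dtype=float)
    le = np.asarray(out["LE"], dtype=float)
    for i in range(n):
        if np.isnan(ta[i]):
            continue
        st = psychro_state(ta[i], rh=rh, pressure=pressure)
        pet[i] = penman_pet(rn_mj[i], d[i], max(u[i], 0.0), st)
        gam[i], gbh[i], gah[i] = aerodynamic_conductance(u[i], ustar[i])
        gsw[i] = surface_conductance(le[i], h[i], d[i], gah[i], st)
        ef[i] = evaporative_fraction(le[i], h[i])
        et[i] = et_from_latent_heat(le[i], st.lam)
    out["PET"] = pet
    out["GAM"] = gam
    out["GBH"] = gbh
    out["GAH"] = gah
    out["GSW"] = gsw
    out["EF"] = ef
    if "ET" not in out:
        out["ET"] = et
    return out
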