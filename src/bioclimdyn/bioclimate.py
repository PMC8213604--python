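"""Monthly UTCI bioclimate series under constant wind scenarios.

The chain per month: sunshine -> cloudiness -> mid-month solar altitude ->
absorbed solar radiation -> longwave budget -> mean radiant temperature ->
UTCI.  The UTCI core is the published operational polynomial approximation
(:mod:`bioclimdyn._utci_poly`): it enforces the operational validity ranges
and never clamps silently; wind clamping happens only at the scenario layer.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._utci_poly import utci_polynomial
from .series import MonthlySeries, aligned

__all__ = [
    "MeteoMonth", "RadiationBudget", "UTCIScenario", "UTCISeriesResult",
    "tetens_saturation_vp", "cloudiness_from_sunshine", "sun_altitude_midmonth",
    "absorbed_radiation_solalt", "longwave_terms", "mrt", "utci",
    "utci_series", "compare_series",
]

log = logging.getLogger(__name__)

SIGMA = 5.667e-8          # Stefan-Boltzmann constant, W m^-2 K^-4
HUMAN_EMISSIVITY = 0.95   # s_h
DEFAULT_LATITUDE = 51.1   # degrees N (Wroclaw)
DEFAULT_RH_PROXY = 0.7    # relative-humidity stand-in when e is not supplied
DEFAULT_IRC = 1.0         # clothing heat-transfer reduction coefficient

#: operational validity box for the UTCI polynomial
UTCI_T_RANGE = (-50.0, 50.0)
UTCI_V_RANGE = (0.5, 17.0)
UTCI_DTMRT_RANGE = (-30.0, 70.0)

_DAYS_IN_MONTH = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
_MONTH_START_DOY = tuple(int(np.sum(_DAYS_IN_MONTH[:m])) for m in range(12))


@dataclass(frozen=True)
class MeteoMonth:
    """One month's UTCI inputs after preprocessing."""
    T: float       # air temperature, degC
    e: float       # water vapour pressure, hPa
    s: float       # sunshine duration, h/month
    N: float       # cloudiness, %
    hSl: float     # mid-month solar altitude, degrees
    v: float       # wind speed, m/s

    def __post_init__(self) -> None:
        if not 0.0 <= self.N <= 100.0:
            raise ValueError("cloudiness must lie in [0, 100] %")
        if self.v < 0 or self.e < 0:
            raise ValueError("wind speed and vapour pressure must be >= 0")


@dataclass(frozen=True)
class RadiationBudget:
    R: float                       # absorbed solar radiation, W m^-2
    Lg: float                      # ground radiation, W m^-2
    La: float                      # atmospheric back radiation, W m^-2
    Irc: float = DEFAULT_IRC       # clothing reduction coefficient
    sh: float = HUMAN_EMISSIVITY
    sigma: float = SIGMA

    def __post_init__(self) -> None:
        if min(self.R, self.Lg, self.La) < 0:
            raise ValueError("radiation fluxes must be >= 0")


@dataclass(frozen=True)
class UTCIScenario:
    """Constant-wind scenario; winds below 0.5 m/s are raised to the validity
    floor with a logged warning."""
    wind_speed: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.wind_speed < 0:
            raise ValueError("wind speed must be >= 0")
        if not self.label:
            object.__setattr__(self, "label", f"{self.wind_speed:g}ms")

    @property
    def effective_wind(self) -> float:
        if self.wind_speed < UTCI_V_RANGE[0]:
            log.warning("scenario wind %.2f m/s below validity floor; using %.1f",
                        self.wind_speed, UTCI_V_RANGE[0])
            return UTCI_V_RANGE[0]
        return self.wind_speed


def tetens_saturation_vp(T) -> np.ndarray | float:
    """Saturation vapour pressure over water [hPa], Tetens formula."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= -237.3):
        raise ValueError("temperature at or below the -237.3 degC pole")
    out = 6.1078 * 10.0 ** (7.5 * T / (T + 237.3))
    return float(out) if out.ndim == 0 else out


def _declination_deg(day_of_year: int) -> float:
    """Solar declination from the standard day-angle formula [deg]."""
    return 23.45 * np.sin(2.0 * np.pi * (284 + day_of_year) / 365.0)


def _daylength_hours(day_of_year: int, latitude: float) -> float:
    """Astronomical day length from the sunrise equation [h]."""
    phi = np.radians(latitude)
    delta = np.radians(_declination_deg(day_of_year))
    cos_h0 = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    return float(2.0 * np.degrees(np.arccos(cos_h0)) / 15.0)


def max_monthly_sunshine(month: int, latitude: float = DEFAULT_LATITUDE) -> float:
    """Astronomical monthly sunshine cap: day lengths summed over the month."""
    if not 1 <= month <= 12:
        raise ValueError(f"invalid month {month}")
    start = _MONTH_START_DOY[month - 1]
    return sum(_daylength_hours(start + d + 1, latitude)
               for d in range(_DAYS_IN_MONTH[month - 1]))


def cloudiness_from_sunshine(s: float, month: int,
                             latitude: float = DEFAULT_LATITUDE) -> float:
    """Cloudiness N [%] = 100 (1 - s / S0), clamped to [0, 100].

    S0 is the astronomical maximum monthly sunshine at the site latitude.
    """
    if s < 0:
        raise ValueError("sunshine duration must be >= 0")
    s0 = max_monthly_sunshine(month, latitude)
    return float(np.clip(100.0 * (1.0 - s / s0), 0.0, 100.0))


def sun_altitude_midmonth(month: int, latitude: float = DEFAULT_LATITUDE) -> float:
    """Solar altitude at solar noon on the 15th of the month [deg]."""
    if not 1 <= month <= 12:
        raise ValueError(f"invalid month {month}")
    doy = _MONTH_START_DOY[month - 1] + 15
    return 90.0 - abs(latitude - _declination_deg(doy))


# clear-sky atmospheric transmission and human shortwave absorptivity used by
# the absorbed-radiation parameterization; the cloud attenuation is the
# classical quadratic in cloud fraction
_SOLAR_CONSTANT = 1367.0
_CLEAR_SKY_TRANSMISSION = 0.75
_HUMAN_ABSORPTIVITY = 0.7


def absorbed_radiation_solalt(N: float, hSl: float) -> float:
    """Absorbed solar radiation R [W m^-2] from cloudiness and sun altitude.

    Clear-sky irradiance scales with sin(hSl); cloud attenuation follows the
    quadratic (0.803 - 0.340 n - 0.458 n^2) in cloud fraction n; the body
    absorbs a 0.7 fraction.  Zero below the horizon; monotone decreasing in N.
    """
    if not 0.0 <= N <= 100.0:
        raise ValueError("cloudiness must lie in [0, 100] %")
    if hSl < 0:
        raise ValueError("solar altitude must be >= 0 (use 0 below horizon)")
    if hSl == 0.0:
        return 0.0
    n = N / 100.0
    cloud_factor = max(0.803 - 0.340 * n - 0.458 * n * n, 0.0)
    k_glob = _SOLAR_CONSTANT * _CLEAR_SKY_TRANSMISSION * np.sin(np.radians(hSl))
    return float(_HUMAN_ABSORPTIVITY * k_glob * cloud_factor)


def longwave_terms(T: float, e: float, N: float) -> tuple[float, float]:
    """Ground radiation Lg and atmospheric back radiation La [W m^-2].

    Lg uses emissivity 0.95 with ground temperature approximated by air
    temperature; La uses a Brunt-type clear-sky emissivity
    0.526 + 0.065 sqrt(e) with the quadratic cloud correction
    (1 + 0.22 (N/100)^2).  Both are documented conventions.
    """
    tk4 = (T + 273.15) ** 4
    lg = 0.95 * SIGMA * tk4
    eps0 = 0.526 + 0.065 * np.sqrt(max(e, 0.0))
    eps_a = eps0 * (1.0 + 0.22 * (N / 100.0) ** 2)
    la = eps_a * SIGMA * tk4
    return float(lg), float(la)


def mrt(budget: RadiationBudget) -> float:
    """Mean radiant temperature [degC] from the radiation budget.

    Tmrt = ((R/Irc + 0.5 Lg + 0.5 La) / (sh sigma))^0.25 - 273.
    """
    radicand = (budget.R / budget.Irc + 0.5 * budget.Lg + 0.5 * budget.La) \
        / (budget.sh * budget.sigma)
    if radicand <= 0:
        raise ValueError("non-positive radicand in the mean radiant temperature")
    return float(radicand ** 0.25 - 273.0)


def utci(T: float, v: float, e: float, Tmrt: float) -> float:
    """UTCI [degC] via the operational polynomial, with strict validity checks.

    T in degC, v in m/s (10 m), e in hPa, Tmrt in degC.  Out-of-range input
    raises, naming the violated bound; clamping is the scenario layer's job.
    """
    if not UTCI_T_RANGE[0] <= T <= UTCI_T_RANGE[1]:
        raise ValueError(f"air temperature {T:g} outside {UTCI_T_RANGE} degC")
    if not UTCI_V_RANGE[0] <= v <= UTCI_V_RANGE[1]:
        raise ValueError(f"wind speed {v:g} outside {UTCI_V_RANGE} m/s")
    d_tmrt = Tmrt - T
    if not UTCI_DTMRT_RANGE[0] <= d_tmrt <= UTCI_DTMRT_RANGE[1]:
        raise ValueError(f"Tmrt - T = {d_tmrt:g} outside {UTCI_DTMRT_RANGE} K")
    if e < 0:
        raise ValueError("vapour pressure must be >= 0")
    return float(utci_polynomial(T, v, d_tmrt, e / 10.0))


@dataclass(frozen=True)
class UTCISeriesResult:
    series: MonthlySeries          # NaN where a month violated validity
    valid: np.ndarray              # bool per month
    scenario: UTCIScenario
    tmrt: np.ndarray
    messages: tuple = ()

    @property
    def mean_valid(self) -> float:
        return float(np.nanmean(self.series.values[self.valid]))


def utci_series(dataset, scenario: UTCIScenario,
                vapour_pressure: MonthlySeries | None = None,
                latitude: float = DEFAULT_LATITUDE,
                rh_proxy: float = DEFAULT_RH_PROXY,
                irc: float = DEFAULT_IRC) -> UTCISeriesResult:
    """Monthly UTCI under a constant-wind scenario.

    `dataset` is (sunshine, precipitation, temperature) MonthlySeries; the
    vapour-pressure series is optional (falls back to rh_proxy * e_sat(T)).
    Months violating the UTCI validity box are flagged invalid (NaN), never
    aborting the whole series.
    """
    sun, _pre, tem = dataset
    aligned(sun, tem)
    if vapour_pressure is not None:
        aligned(sun, vapour_pressure)
    months = tem.month_numbers()
    n = len(tem)
    v = scenario.effective_wind
    out = np.full(n, np.nan)
    tmrt_arr = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    messages = []
    for i in range(n):
        T = float(tem.values[i])
        s = max(float(sun.values[i]), 0.0)
        try:
            e = (float(vapour_pressure.values[i]) if vapour_pressure is not None
                 else rh_proxy * tetens_saturation_vp(T))
            m = int(months[i])
            N = cloudiness_from_sunshine(s, m, latitude)
            hsl = max(sun_altitude_midmonth(m, latitude), 0.0)
            r = absorbed_radiation_solalt(N, hsl)
            lg, la = longwave_terms(T, e, N)
            tmrt_val = mrt(RadiationBudget(R=r, Lg=lg, La=la, Irc=irc))
            tmrt_arr[i] = tmrt_val
            out[i] = utci(T, v, e, tmrt_val)
            valid[i] = True
        except ValueError as exc:
            messages.append(f"month index {i}: {exc}")
    series = MonthlySeries(tem.start_year, tem.start_month, out, "utci")
    return UTCISeriesResult(series=series, valid=valid, scenario=scenario,
                            tmrt=tmrt_arr, messages=tuple(messages))


def compare_series(a: MonthlySeries, b: MonthlySeries, bins: int = 50) -> dict:
    """MSE, means and histogram-intersection PDF overlap of two series."""
    if len(a) != len(b):
        raise ValueError("series must have equal length")
    av, bv = a.values, b.values
    ok = np.isfinite(av) & np.isfinite(bv)
    av, bv = av[ok], bv[ok]
    if av.size == 0:
        raise ValueError("no overlapping valid months to compare")
    lo = min(av.min(), bv.min())
    hi = max(av.max(), bv.max())
    if hi == lo:
        overlap = 1.0
    else:
        edges = np.linspace(lo, hi, bins + 1)
        pa, _ = np.histogram(av, bins=edges, density=True)
        pb, _ = np.histogram(bv, bins=edges, density=True)
        overlap = float(np.sum(np.minimum(pa, pb)) * (edges[1] - edges[0]))
    return {
        "mse": float(np.mean((av - bv) ** 2)),
        "mean_a": float(av.mean()),
        "mean_b": float(bv.mean()),
        "pdf_overlap": overlap,
        "n": int(av.size),
    }


def export_comparison(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
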