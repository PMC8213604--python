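"""Slow/fast decomposition of a monthly series.

The slow nonlinear trend is a ten-year symmetric moving average followed by
zero-phase Butterworth low-pass filtering; the remainder is split into a
12-value seasonal profile (per-calendar-month means) and a standardized
correlated residual.  The components reconstruct the input exactly on the
interior where all of them are defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import butter, periodogram, sosfiltfilt

from .series import MonthlySeries

__all__ = [
    "DecompositionResult", "moving_average", "dominant_frequency",
    "butterworth_lowpass", "extract_slow", "deseasonalize", "standardize",
    "decompose",
]

DEFAULT_WINDOW = 120          # months; realized as a centred 121-point window
DEFAULT_CUTOFF = 0.0038       # cycles/month
DEFAULT_ORDER = 4
NYQUIST = 0.5                 # cycles/month for monthly sampling


@dataclass(frozen=True)
class DecompositionResult:
    """Additive decomposition  x = slow + seasonal[m] + mean + sd * residual.

    `residual_standardized` has zero mean and unit (population) standard
    deviation unless `degenerate` is set (zero-variance residual, e.g. for a
    constant input), in which case it is identically zero and sd is 0.
    """

    slow: MonthlySeries
    seasonal: np.ndarray                  # 12 values, January first
    residual_standardized: MonthlySeries
    residual_mean: float
    residual_sd: float
    cutoff_frequency: float
    window_months: int
    degenerate: bool = False

    def reconstruct(self) -> MonthlySeries:
        """Recombine the components (defined on the interior calendar)."""
        months = self.slow.month_numbers()
        values = (self.slow.values + self.seasonal[months - 1] + self.residual_mean
                  + self.residual_sd * self.residual_standardized.values)
        return self.slow.with_values(values)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps({
            "variable": self.slow.variable,
            "start_year": self.slow.start_year,
            "start_month": self.slow.start_month,
            "slow": self.slow.values.tolist(),
            "seasonal": self.seasonal.tolist(),
            "residual_standardized": self.residual_standardized.values.tolist(),
            "residual_mean": self.residual_mean,
            "residual_sd": self.residual_sd,
            "cutoff_frequency": self.cutoff_frequency,
            "window_months": self.window_months,
            "degenerate": self.degenerate,
        }, indent=2)
        if path is not None:
            Path(path).write_text(doc)
        return doc


def moving_average(series: MonthlySeries, window_months: int = DEFAULT_WINDOW
                   ) -> MonthlySeries:
    """Symmetric centred moving average (window_months neighbours + centre).

    The output is restricted to the interior months where the full window
    fits, so it is shorter than the input by `window_months` points.
    """
    if window_months < 2 or window_months % 2:
        raise ValueError("window_months must be a positive even count of neighbours")
    width = window_months + 1
    if len(series) <= width:
        raise ValueError(
            f"series of {len(series)} months is too short for a {width}-point window")
    kernel = np.full(width, 1.0 / width)
    smoothed = np.convolve(series.values, kernel, mode="valid")
    return series.slice(window_months // 2, smoothed.size).with_values(smoothed)


def dominant_frequency(series: MonthlySeries) -> float:
    """Frequency (cycles/month) of the largest non-DC periodogram ordinate.

    Ties are broken toward the lower frequency; a constant series has no
    spectral peak and raises.
    """
    x = series.values
    if np.allclose(x, x[0]):
        raise ValueError("constant series has no dominant frequency")
    freqs, power = periodogram(x, fs=1.0, detrend="constant", window="boxcar")
    power = power[1:]
    freqs = freqs[1:]
    return float(freqs[int(np.argmax(power))])


def butterworth_lowpass(series: MonthlySeries, cutoff: float = DEFAULT_CUTOFF,
                        order: int = DEFAULT_ORDER) -> MonthlySeries:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The double pass squares the magnitude response, so the gain at the cutoff
    is 0.5; no phase delay is introduced.  Edge transients are suppressed by
    even (mirror) reflection padding, trimmed back afterwards.
    """
    if not 0 < cutoff < NYQUIST:
        raise ValueError(f"cutoff must lie in (0, {NYQUIST}) cycles/month")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    # second-order sections keep the filter numerically sound at the very
    # low cutoffs used here
    sos = butter(order, cutoff / NYQUIST, output="sos")
    n = len(series)
    padlen = min(n - 1, int(3.0 / cutoff))
    filtered = sosfiltfilt(sos, series.values, padtype="even", padlen=padlen)
    return series.with_values(filtered)


def extract_slow(series: MonthlySeries, window_months: int = DEFAULT_WINDOW,
                 cutoff: float = DEFAULT_CUTOFF, order: int = DEFAULT_ORDER
                 ) -> MonthlySeries:
    """Slow nonlinear trend: moving average then zero-phase low-pass.

    Alignment is preserved exactly (both stages are symmetric / zero phase);
    the output lives on the moving-average interior.
    """
    if len(series) < 2 * window_months:
        raise ValueError("series must be at least twice the window length")
    return butterworth_lowpass(moving_average(series, window_months), cutoff, order)


def deseasonalize(detrended: MonthlySeries) -> tuple[np.ndarray, MonthlySeries]:
    """Seasonal profile = per-calendar-month means of the detrended series.

    Returns the 12-value profile (January first) and the residual series;
    residual means per calendar month are zero to machine precision.
    """
    if len(detrended) < 24:
        raise ValueError("deseasonalization needs at least two full years")
    months = detrended.month_numbers()
    seasonal = np.empty(12)
    for m in range(1, 13):
        sel = months == m
        if not np.any(sel):
            raise ValueError(f"calendar month {m} is absent from the series")
        seasonal[m - 1] = detrended.values[sel].mean()
    residual = detrended.with_values(detrended.values - seasonal[months - 1])
    return seasonal, residual


def standardize(series: MonthlySeries) -> tuple[MonthlySeries, float, float]:
    """Zero-mean unit-variance rescaling; returns (series, mean, sd)."""
    mean = float(series.values.mean())
    sd = float(series.values.std())
    if sd == 0.0:
        raise ValueError("cannot standardize a zero-variance series")
    return series.with_values((series.values - mean) / sd), mean, sd


def decompose(series: MonthlySeries, window_months: int = DEFAULT_WINDOW,
              cutoff: float = DEFAULT_CUTOFF, order: int = DEFAULT_ORDER
              ) -> DecompositionResult:
    """Full chain: extract_slow -> subtract -> deseasonalize -> standardize.

    A zero-variance residual (e.g. constant input) is flagged `degenerate`
    instead of raising: the standardized residual is then identically zero.
    """
    slow = extract_slow(series, window_months, cutoff, order)
    offset = (slow.start_year * 12 + slow.start_month
              - series.start_year * 12 - series.start_month)
    interior = series.slice(offset, len(slow))
    detrended = interior.with_values(interior.values - slow.values)
    seasonal, residual = deseasonalize(detrended)
    scale = max(1.0, float(np.max(np.abs(interior.values))))
    if residual.values.std() <= 1e-12 * scale:
        return DecompositionResult(
            slow=slow, seasonal=seasonal,
            residual_standardized=residual.with_values(np.zeros(len(residual))),
            residual_mean=float(residual.values.mean()), residual_sd=0.0,
            cutoff_frequency=cutoff, window_months=window_months, degenerate=True)
    standardized, mean, sd = standardize(residual)
    return DecompositionResult(
        slow=slow, seasonal=seasonal, residual_standardized=standardized,
        residual_mean=mean, residual_sd=sd,
        cutoff_frequency=cutoff, window_months=window_months)
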