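"""Monthly time-series container and the canonical CSV dialect.

A :class:`MonthlySeries` holds one variable's uninterrupted monthly record.
Month index 1 is January; each value represents the whole month (monthly sum
or monthly mean), timestamped at month start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: canonical CSV columns, in order; vapour pressure and wind are optional
CSV_COLUMNS = ("year", "month", "sunshine_h", "precip_mm", "temp_c")
CSV_OPTIONAL = ("vapour_hpa", "wind_ms")

#: variable name -> canonical CSV column
VARIABLE_COLUMNS: Mapping[str, str] = {
    "sunshine": "sunshine_h",
    "precipitation": "precip_mm",
    "temperature": "temp_c",
    "vapour_pressure": "vapour_hpa",
    "utci": "utci_c",
}

VARIABLE_UNITS: Mapping[str, str] = {
    "sunshine": "h/month",
    "precipitation": "mm/month",
    "temperature": "degC",
    "vapour_pressure": "hPa",
    "utci": "degC",
}


@dataclass(frozen=True)
class MonthlySeries:
    """One variable's gap-free monthly record.

    Parameters
    ----------
    start_year, start_month : int
        Calendar position of the first value (month 1 = January).
    values : ndarray
        One value per consecutive month, no missing entries.
    variable : str
        One of ``sunshine``, ``precipitation``, ``temperature``,
        ``vapour_pressure``, ``utci``.
    """

    start_year: int
    start_month: int
    values: np.ndarray
    variable: str = "temperature"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not 1 <= self.start_month <= 12:
            raise ValueError(f"start_month must be 1..12, got {self.start_month}")
        if self.variable not in VARIABLE_UNITS:
            raise ValueError(f"unknown variable {self.variable!r}")
        if np.any(~np.isfinite(self.values)):
            # UTCI series may carry NaN for months outside validity
            if self.variable != "utci":
                raise ValueError("values contain non-finite entries")

    def __len__(self) -> int:
        return self.values.size

    @property
    def units(self) -> str:
        return VARIABLE_UNITS[self.variable]

    def month_numbers(self) -> np.ndarray:
        """Calendar month (1..12) of every sample."""
        m0 = (self.start_year * 12 + (self.start_month - 1))
        return (m0 + np.arange(len(self))) % 12 + 1

    def calendar(self) -> tuple[np.ndarray, np.ndarray]:
        """(years, months) arrays for every sample."""
        m0 = self.start_year * 12 + (self.start_month - 1)
        idx = m0 + np.arange(len(self))
        return idx // 12, idx % 12 + 1

    def slice(self, offset: int, length: int) -> "MonthlySeries":
        """Sub-series of `length` months starting `offset` months in."""
        if offset < 0 or offset + length > len(self):
            raise ValueError("slice out of range")
        m0 = self.start_year * 12 + (self.start_month - 1) + offset
        return MonthlySeries(m0 // 12, m0 % 12 + 1, self.values[offset:offset + length],
                             self.variable)

    def with_values(self, values: np.ndarray) -> "MonthlySeries":
        """Same calendar, new values (must keep length)."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("replacement values must keep the length")
        return MonthlySeries(self.start_year, self.start_month, values, self.variable)

    def same_calendar(self, other: "MonthlySeries") -> bool:
        return (self.start_year == other.start_year
                and self.start_month == other.start_month
                and len(self) == len(other))


def aligned(*series: MonthlySeries) -> None:
    """Raise unless all series share one calendar."""
    first = series[0]
    for s in series[1:]:
        if not first.same_calendar(s):
            raise ValueError(
                f"series not aligned: {first.start_year}-{first.start_month} "
                f"x{len(first)} vs {s.start_year}-{s.start_month} x{len(s)}")


def write_csv(path: str | Path, sunshine: MonthlySeries, precipitation: MonthlySeries,
              temperature: MonthlySeries, vapour_pressure: MonthlySeries | None = None,
              wind_ms: float | np.ndarray | None = None) -> None:
    """Write the canonical CSV (header ``year,month,sunshine_h,precip_mm,temp_c[,...]``)."""
    aligned(sunshine, precipitation, temperature)
    years, months = sunshine.calendar()
    frame = pd.DataFrame({
        "year": years, "month": months,
        "sunshine_h": sunshine.values,
        "precip_mm": precipitation.values,
        "temp_c": temperature.values,
    })
    if vapour_pressure is not None:
        aligned(sunshine, vapour_pressure)
        frame["vapour_hpa"] = vapour_pressure.values
    if wind_ms is not None:
        frame["wind_ms"] = np.broadcast_to(np.asarray(wind_ms, dtype=float), (len(frame),))
    frame.to_csv(path, index=False)


def read_csv(path: str | Path) -> dict[str, MonthlySeries | np.ndarray]:
    """Read the canonical CSV into MonthlySeries keyed by variable name.

    Returns a dict with keys ``sunshine``, ``precipitation``, ``temperature``
    and, if present in the file, ``vapour_pressure`` and ``wind_ms`` (the
    latter a plain array).
    """
    frame = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"canonical CSV is missing columns {missing}")
    months_abs = frame["year"].to_numpy() * 12 + frame["month"].to_numpy() - 1
    if len(frame) > 1 and np.any(np.diff(months_abs) != 1):
        raise ValueError("canonical CSV must be gap-free consecutive months")
    y0, m0 = int(frame["year"].iloc[0]), int(frame["month"].iloc[0])
    out: dict[str, MonthlySeries | np.ndarray] = {
        "sunshine": MonthlySeries(y0, m0, frame["sunshine_h"].to_numpy(), "sunshine"),
        "precipitation": MonthlySeries(y0, m0, frame["precip_mm"].to_numpy(), "precipitation"),
        "temperature": MonthlySeries(y0, m0, frame["temp_c"].to_numpy(), "temperature"),
    }
    if "vapour_hpa" in frame.columns:
        out["vapour_pressure"] = MonthlySeries(y0, m0, frame["vapour_hpa"].to_numpy(),
                                               "vapour_pressure")
    if "wind_ms" in frame.columns:
        out["wind_ms"] = frame["wind_ms"].to_numpy(dtype=float)
    return out


def month_span(first_year: int, last_year: int) -> int:
    """Number of months in the inclusive calendar-year span."""
    if last_year < first_year:
        raise ValueError("last year must be >= first year")
    return 12 * (last_year - first_year + 1)
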