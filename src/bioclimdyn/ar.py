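"""Autoregressive modelling of the standardized correlated residual.

AR(p) identification follows the classical route: sample ACF/PACF, order
selection from the initial run of significant partial autocorrelations,
Yule-Walker estimation, and a residual-whiteness check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve_toeplitz
from statsmodels.stats.diagnostic import acorr_ljungbox

__all__ = [
    "ARModel", "CorrelogramResult", "WhitenessReport",
    "correlogram", "select_order", "fit_ar", "residual_whiteness", "simulate",
]


@dataclass(frozen=True)
class ARModel:
    """AR(p) model  x_t = mu + sum_j phi_j (x_{t-j} - mu) + eps_t."""

    phi: np.ndarray
    mu: float = 0.0
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi", np.atleast_1d(np.asarray(self.phi, dtype=float)))
        if self.sigma2 < 0:
            raise ValueError("innovation variance must be >= 0")

    @property
    def p(self) -> int:
        return self.phi.size

    def is_stationary(self) -> bool:
        """All companion-matrix eigenvalues strictly inside the unit circle."""
        if self.p == 0:
            return True
        companion = np.zeros((self.p, self.p))
        companion[0] = self.phi
        if self.p > 1:
            companion[1:, :-1] = np.eye(self.p - 1)
        return bool(np.max(np.abs(np.linalg.eigvals(companion))) < 1.0)

    def theoretical_acf(self, max_lag: int) -> np.ndarray:
        """ACF at lags 0..max_lag from the Yule-Walker recursion."""
        if not self.is_stationary():
            raise ValueError("theoretical ACF requires a stationary model")
        p = self.p
        if p == 0:
            out = np.zeros(max_lag + 1)
            out[0] = 1.0
            return out
        # first p Yule-Walker equations: rho_k = sum_j phi_j rho_{|k-j|}
        A = np.zeros((p, p))
        b = np.zeros(p)
        for k in range(1, p + 1):
            for j in range(1, p + 1):
                lag = abs(k - j)
                if lag == 0:
                    b[k - 1] += self.phi[j - 1]
                else:
                    A[k - 1, lag - 1] -= self.phi[j - 1]
            A[k - 1, k - 1] += 1.0
        rho = np.linalg.solve(A, b)
        out = np.empty(max_lag + 1)
        out[0] = 1.0
        for k in range(1, max_lag + 1):
            if k <= p:
                out[k] = rho[k - 1]
            else:
                out[k] = np.dot(self.phi, out[k - self.p:k][::-1])
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps({"order": self.p, "phi": self.phi.tolist(),
                          "mu": self.mu, "sigma2": self.sigma2}, indent=2)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, doc: str | Path) -> "ARModel":
        text = Path(doc).read_text() if isinstance(doc, Path) else doc
        d = json.loads(text)
        return cls(phi=np.asarray(d["phi"], dtype=float), mu=d["mu"], sigma2=d["sigma2"])


@dataclass(frozen=True)
class CorrelogramResult:
    lags: np.ndarray
    acf: np.ndarray
    pacf: np.ndarray        # pacf[0] = 1 by convention
    n: int
    bound: float            # +-1.96/sqrt(n) pointwise significance band

    def export_csv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame({"lag": self.lags, "acf": self.acf, "pacf": self.pacf}
                     ).to_csv(path, index=False)


def _values(series) -> np.ndarray:
    return np.asarray(getattr(series, "values", series), dtype=float)


def sample_acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased-normalization sample autocorrelation at lags 0..max_lag."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    denom = np.dot(xc, xc)
    if denom == 0:
        raise ValueError("constant series has no autocorrelation")
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    for k in range(1, max_lag + 1):
        out[k] = np.dot(xc[:-k], xc[k:]) / denom
    return out


def pacf_durbin_levinson(acf: np.ndarray) -> np.ndarray:
    """PACF from an ACF via the Durbin-Levinson recursion (pacf[0] = 1)."""
    max_lag = acf.size - 1
    pacf = np.empty(max_lag + 1)
    pacf[0] = 1.0
    if max_lag == 0:
        return pacf
    phi_prev = np.array([acf[1]])
    pacf[1] = acf[1]
    for k in range(2, max_lag + 1):
        num = acf[k] - np.dot(phi_prev, acf[1:k][::-1])
        den = 1.0 - np.dot(phi_prev, acf[1:k])
        a = num / den
        pacf[k] = a
        phi_prev = np.concatenate([phi_prev - a * phi_prev[::-1], [a]])
    return pacf


def correlogram(series, max_lag: int = 24) -> CorrelogramResult:
    """Sample ACF and PACF with the 1.96/sqrt(n) significance band."""
    x = _values(series)
    if max_lag >= x.size / 2:
        raise ValueError("max_lag must be below half the series length")
    acf = sample_acf(x, max_lag)
    pacf = pacf_durbin_levinson(acf)
    return CorrelogramResult(lags=np.arange(max_lag + 1), acf=acf, pacf=pacf,
                             n=x.size, bound=1.96 / np.sqrt(x.size))


def select_order(corr: CorrelogramResult, cap: int = 12) -> int:
    """Initial run of significant PACF lags starting at lag 1 (0 if none)."""
    p = 0
    for k in range(1, min(cap, corr.lags.max()) + 1):
        if abs(corr.pacf[k]) > corr.bound:
            p = k
        else:
            break
    return p


def fit_ar(series, p: int) -> ARModel:
    """Yule-Walker estimation of an AR(p) model.

    mu is the sample mean; sigma2 is the variance of the one-step fitted
    residuals.
    """
    x = _values(series)
    if p < 0:
        raise ValueError("order must be non-negative")
    if p >= x.size:
        raise ValueError("order must be below the series length")
    mu = float(x.mean())
    if p == 0:
        return ARModel(phi=np.empty(0), mu=mu, sigma2=float(x.var()))
    acf = sample_acf(x, p)
    try:
        phi = solve_toeplitz(acf[:p], acf[1:p + 1])
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("Yule-Walker system is singular") from exc
    if not np.all(np.isfinite(phi)):
        raise ValueError("Yule-Walker system is singular")
    model = ARModel(phi=phi, mu=mu, sigma2=1.0)
    if not model.is_stationary():
        raise ValueError("Yule-Walker estimate is non-stationary")
    resid = one_step_residuals(model, x)
    return ARModel(phi=phi, mu=mu, sigma2=float(resid.var()))


def one_step_residuals(model: ARModel, x: np.ndarray) -> np.ndarray:
    """eps_t = (x_t - mu) - sum_j phi_j (x_{t-j} - mu), for t >= p."""
    x = _values(x)
    xc = x - model.mu
    p = model.p
    if p == 0:
        return xc.copy()
    pred = np.zeros(x.size - p)
    for j in range(1, p + 1):
        pred += model.phi[j - 1] * xc[p - j:x.size - j]
    return xc[p:] - pred


@dataclass(frozen=True)
class WhitenessReport:
    passed: bool
    fraction_in_band: float
    ljung_box_stat: float
    ljung_box_pvalue: float
    acf: np.ndarray
    bound: float


def residual_whiteness(model: ARModel, series, max_lag: int = 20) -> WhitenessReport:
    """Check the fitted residuals for leftover autocorrelation.

    Pass criterion: at least 93% of residual ACF lags 1..max_lag fall inside
    the +-1.96/sqrt(n) band.  A Ljung-Box statistic (dof adjusted by the AR
    order) is reported alongside.
    """
    resid = one_step_residuals(model, _values(series))
    acf = sample_acf(resid, max_lag)
    bound = 1.96 / np.sqrt(resid.size)
    frac = float(np.mean(np.abs(acf[1:]) <= bound))
    lb = acorr_ljungbox(resid, lags=[max_lag], model_df=model.p)
    return WhitenessReport(
        passed=frac >= 0.93,
        fraction_in_band=frac,
        ljung_box_stat=float(lb["lb_stat"].iloc[0]),
        ljung_box_pvalue=float(lb["lb_pvalue"].iloc[0]),
        acf=acf, bound=bound)


def simulate(model: ARModel, n: int, seed: int | np.random.Generator,
             burn_in: int | None = None) -> np.ndarray:
    """Seeded realization of a stationary AR(p) model.

    A burn-in of at least 10 x p samples (default max(10 p, 50) for p > 0)
    is generated and discarded so the output is effectively stationary.
    """
    if not model.is_stationary():
        raise ValueError("cannot simulate a non-stationary AR model")
    if n < 1:
        raise ValueError("n must be positive")
    p = model.p
    if burn_in is None:
        burn_in = max(10 * p, 50) if p > 0 else 0
    elif p > 0 and burn_in < 10 * p:
        raise ValueError("burn-in must be at least 10 x order")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.normal(0.0, np.sqrt(model.sigma2), size=n + burn_in)
    if p == 0:
        return model.mu + eps[burn_in:]
    x = np.zeros(n + burn_in)
    for t in range(n + burn_in):
        acc = eps[t]
        for j in range(1, min(p, t) + 1):
            acc += model.phi[j - 1] * x[t - j]
        x[t] = acc
    return model.mu + x[burn_in:]
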