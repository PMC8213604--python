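"""Phase-space reconstruction of a 3-D cubic-polynomial ODE from monthly data.

The model class is the complete third-order polynomial vector field in the
three state variables (sunshine, precipitation, temperature).  Candidate
coefficient matrices are scored by evolving the model from observed states
over doubling horizons and accumulating the deviation from the observed
trajectory (the quality function), then refined by least squares.

State variables are affinely pre-scaled to [-1, 1] before any fitting (the
raw units make the cubic design matrix catastrophically ill-conditioned);
coefficients are mapped back to data units exactly via
:func:`bioclimdyn.polybasis.change_of_variables`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from . import polybasis
from .series import MonthlySeries, aligned

__all__ = [
    "PolyODEModel", "TMConfig", "QualityReport", "Trajectory", "SearchResult",
    "monomial_basis", "evaluate_rhs", "integrate", "quality",
    "init_coefficients", "refine", "is_stable", "search",
]


@dataclass(frozen=True)
class PolyODEModel:
    """Cubic polynomial vector field: row i of `coefficients` gives equation i
    over the canonical 20-monomial basis (see :mod:`bioclimdyn.polybasis`)."""

    coefficients: np.ndarray
    state_units: tuple[str, str, str] = ("h/month", "mm/month", "degC")
    time_unit: str = "month"

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if c.shape != (3, polybasis.N_TERMS):
            raise ValueError(f"coefficients must be 3x{polybasis.N_TERMS}, got {c.shape}")
        object.__setattr__(self, "coefficients", c)

    def rhs(self, state: np.ndarray) -> np.ndarray:
        return evaluate_rhs(self, state)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps({
            "monomials": list(polybasis.MONOMIAL_NAMES),
            "coefficients": self.coefficients.tolist(),
            "state_units": list(self.state_units),
            "time_unit": self.time_unit,
        }, indent=2)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, doc: str | Path) -> "PolyODEModel":
        text = Path(doc).read_text() if isinstance(doc, Path) else doc
        d = json.loads(text)
        return cls(coefficients=np.asarray(d["coefficients"], dtype=float),
                   state_units=tuple(d.get("state_units", ("h/month", "mm/month", "degC"))),
                   time_unit=d.get("time_unit", "month"))


@dataclass(frozen=True)
class TMConfig:
    """Reconstruction parameters.

    Horizons follow t_l = dt * 2**(l-1) for l = 1..l_max; the j_max initial
    conditions are observed samples spaced d apart.
    """

    j_max: int = 48
    d: int = 7
    l_max: int = 4
    dt: float = 1.0
    ridge_weight: float = 1e-10
    optimizer_budget: int = 200          # max residual evaluations in refine
    divergence_penalty: float = 1e6      # per scheduled comparison
    substeps: int = 4                    # RK4 sub-steps per sampling interval
    init_jitter: float = 0.0             # sd of relative jitter on the start model

    def horizons(self) -> np.ndarray:
        """Evolution horizons in months."""
        return self.dt * 2.0 ** np.arange(self.l_max)

    def required_length(self) -> int:
        """Minimum number of samples the scheme needs."""
        return int(self.j_max * self.d + 2 ** (self.l_max - 1)) + 1

    def validate(self, n_samples: int) -> None:
        if self.j_max < 1 or self.d < 1 or self.l_max < 1 or self.dt <= 0:
            raise ValueError("j_max, d, l_max must be positive and dt > 0")
        if self.required_length() > n_samples:
            raise ValueError(
                f"infeasible config: needs {self.required_length()} samples, "
                f"data has {n_samples}")


@dataclass(frozen=True)
class QualityReport:
    q_components: np.ndarray   # (Q^1, Q^2, Q^3)
    total: float
    n_initial_conditions: int
    stable: bool               # False if any model evolution diverged

    def __post_init__(self) -> None:
        object.__setattr__(self, "q_components",
                           np.asarray(self.q_components, dtype=float))


@dataclass(frozen=True)
class Trajectory:
    """Fixed-step integration output; `diverged` marks a blow-up abort."""
    times: np.ndarray
    states: np.ndarray         # (n, 3); truncated at the blow-up point
    diverged: bool = False
    message: str = ""


def monomial_basis(state: np.ndarray) -> np.ndarray:
    """The 20 canonical cubic monomials evaluated at `state`."""
    return polybasis.basis(state)


def evaluate_rhs(model: PolyODEModel, state: np.ndarray) -> np.ndarray:
    """Time derivative(s) at one state (3,) or a batch (n, 3)."""
    b = polybasis.basis(state)
    return b @ model.coefficients.T


_DEFAULT_GUARD = 1e6


def integrate(model: PolyODEModel, initial_state: Sequence[float],
              horizon_months: float, dt: float = 1.0, substeps: int = 4,
              guard: float = _DEFAULT_GUARD) -> Trajectory:
    """Fixed-step RK4 integration sampled at multiples of `dt`.

    The blow-up guard aborts (returning a truncated, flagged trajectory, not
    raising) as soon as any state component leaves [-guard, guard], so that
    candidate searches can discard divergent models cheaply.
    """
    x = np.asarray(initial_state, dtype=float)
    if x.shape != (3,):
        raise ValueError("initial state must have three components")
    if dt <= 0 or substeps < 1:
        raise ValueError("dt must be positive and substeps >= 1")
    n_out = int(round(horizon_months / dt))
    h = dt / substeps
    C = model.coefficients

    def f(s: np.ndarray) -> np.ndarray:
        return polybasis.basis(s) @ C.T

    states = np.empty((n_out + 1, 3))
    states[0] = x
    with np.errstate(over="ignore", invalid="ignore"):
        for i in range(1, n_out + 1):
            for _ in range(substeps):
                k1 = f(x)
                k2 = f(x + 0.5 * h * k1)
                k3 = f(x + 0.5 * h * k2)
                k4 = f(x + h * k3)
                x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                if not np.all(np.isfinite(x)) or np.any(np.abs(x) > guard):
                    return Trajectory(
                        times=np.arange(i) * dt, states=states[:i], diverged=True,
                        message=f"state left the guard box at month {i * dt:g}")
            states[i] = x
    return Trajectory(times=np.arange(n_out + 1) * dt, states=states)


def _as_state_array(slow_data) -> np.ndarray:
    """Accept three MonthlySeries or an (n, 3) array."""
    if isinstance(slow_data, np.ndarray):
        data = np.asarray(slow_data, dtype=float)
        if data.ndim != 2 or data.shape[1] != 3:
            raise ValueError("state data must be (n, 3)")
        return data
    sun, pre, tem = slow_data
    aligned(sun, pre, tem)
    return np.column_stack([sun.values, pre.values, tem.values])


def _comparison_schedule(config: TMConfig) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(config.j_max) * config.d
    offsets = 2 ** np.arange(config.l_max)      # horizon in samples
    return starts, offsets


def _evolve_batch(C: np.ndarray, x0: np.ndarray, offsets: np.ndarray,
                  dt: float, substeps: int, guard: float) -> np.ndarray | None:
    """RK4-evolve a batch of states, sampling at the given step offsets.

    Returns (n_batch, n_offsets, 3) model states, or None on any blow-up.
    Identical stepping to :func:`integrate`, vectorized over the batch.
    """
    x = np.array(x0, dtype=float)
    h = dt / substeps
    out = np.empty((x.shape[0], offsets.size, 3))
    oi = 0
    with np.errstate(over="ignore", invalid="ignore"):
        for step in range(1, int(offsets[-1]) + 1):
            for _ in range(substeps):
                k1 = polybasis.basis(x) @ C.T
                k2 = polybasis.basis(x + 0.5 * h * k1) @ C.T
                k3 = polybasis.basis(x + 0.5 * h * k2) @ C.T
                k4 = polybasis.basis(x + h * k3) @ C.T
                x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > guard:
                    return None
            while oi < offsets.size and offsets[oi] == step:
                out[:, oi] = x
                oi += 1
    return out


def quality(model: PolyODEModel, slow_data, config: TMConfig = TMConfig(),
            guard: float | None = None) -> QualityReport:
    """Trajectory-method quality function.

    From each of `j_max` observed states (spaced `d` samples apart) the model
    is evolved to the doubling horizons and the absolute deviation from the
    observed samples is accumulated per component.  A divergent evolution
    replaces the whole score with the configured penalty.
    """
    data = _as_state_array(slow_data)
    config.validate(data.shape[0])
    starts, offsets = _comparison_schedule(config)
    if guard is None:
        width = np.max(np.abs(data))
        guard = max(100.0 * width, _DEFAULT_GUARD * 1e-3)
    evolved = _evolve_batch(model.coefficients, data[starts], offsets,
                            config.dt, config.substeps, guard)
    if evolved is None:
        n_cmp = config.j_max * config.l_max
        penalty = config.divergence_penalty * n_cmp
        return QualityReport(q_components=np.full(3, penalty),
                             total=3 * penalty,
                             n_initial_conditions=config.j_max, stable=False)
    observed = data[starts[:, None] + offsets[None, :]]
    q = np.sum(np.abs(evolved - observed), axis=(0, 1))
    return QualityReport(q_components=q, total=float(q.sum()),
                         n_initial_conditions=config.j_max, stable=True)


# ---------------------------------------------------------------------------
# scaling helpers

def _scaling(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Affine map x = center + half * u sending the data range to [-1, 1]."""
    lo, hi = data.min(axis=0), data.max(axis=0)
    center = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    half[half == 0] = 1.0
    return center, half


def _to_scaled(coeffs: np.ndarray, center: np.ndarray, half: np.ndarray) -> np.ndarray:
    """Raw-unit coefficients -> dynamics of u = (x - center) / half."""
    return polybasis.change_of_variables(coeffs, -center / half, 1.0 / half)


def _to_raw(coeffs_scaled: np.ndarray, center: np.ndarray, half: np.ndarray) -> np.ndarray:
    """Scaled-unit coefficients -> dynamics of x = center + half * u."""
    return polybasis.change_of_variables(coeffs_scaled, center, half)


def derivative_regression(slow_data, ridge_weight: float = 1e-8,
                          dt: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ridge regression of central-difference derivatives on the basis.

    Operates entirely in [-1, 1]-scaled state variables; returns the scaled
    3x20 coefficient matrix together with the (center, half) scaling.
    """
    data = _as_state_array(slow_data)
    n = data.shape[0]
    if n < 40:
        raise ValueError("need at least 40 samples for derivative regression")
    if ridge_weight < 0:
        raise ValueError("ridge weight must be >= 0")
    center, half = _scaling(data)
    u = (data - center) / half
    du = (u[2:] - u[:-2]) / (2.0 * dt)
    B = polybasis.basis(u[1:-1])
    G = B.T @ B + ridge_weight * np.eye(polybasis.N_TERMS)
    try:
        sol = np.linalg.solve(G, B.T @ du)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular normal equations; use a ridge weight > 0") from exc
    if ridge_weight == 0 and np.linalg.cond(G) > 1e14:
        raise ValueError("normal equations numerically singular; use a ridge weight > 0")
    return sol.T, center, half


def init_coefficients(slow_data, ridge_weight: float = 1e-8,
                      dt: float = 1.0) -> PolyODEModel:
    """Initial model by ridge-regularized derivative regression.

    Central-difference derivative estimates of the (pre-scaled) data are
    regressed on the monomial basis, one equation at a time; the coefficients
    are mapped back to data units exactly.
    """
    coeffs_scaled, center, half = derivative_regression(slow_data, ridge_weight, dt)
    return PolyODEModel(coefficients=_to_raw(coeffs_scaled, center, half))


def _residual_vector(coeffs_scaled: np.ndarray, data: np.ndarray,
                     config: TMConfig, center: np.ndarray, half: np.ndarray,
                     guard: float) -> np.ndarray:
    """Signed scaled deviations over the comparison schedule (for refine)."""
    C = _to_raw(coeffs_scaled.reshape(3, polybasis.N_TERMS), center, half)
    starts, offsets = _comparison_schedule(config)
    evolved = _evolve_batch(C, data[starts], offsets, config.dt,
                            config.substeps, guard)
    if evolved is None:
        return np.full(starts.size * offsets.size * 3, 1e3)
    observed = data[starts[:, None] + offsets[None, :]]
    return ((evolved - observed) / half).ravel()


def refine(model: PolyODEModel, slow_data, config: TMConfig = TMConfig()
           ) -> tuple[PolyODEModel, QualityReport]:
    """Least-squares refinement of the quality function.

    Minimizes the stacked (scaled) horizon deviations over all 60
    coefficients; guaranteed to never return a model whose quality exceeds
    the input's (falls back to the input when the optimizer does not help).
    The report's `stable` flag is False when the optimizer budget ran out.
    """
    data = _as_state_array(slow_data)
    config.validate(data.shape[0])
    center, half = _scaling(data)
    guard = 100.0 * float(np.max(np.abs(data))) + 1.0
    c0 = _to_scaled(model.coefficients, center, half).ravel()
    q_start = quality(model, data, config)
    if q_start.total == 0.0:
        return model, q_start
    res = least_squares(
        _residual_vector, c0, args=(data, config, center, half, guard),
        method="lm", max_nfev=config.optimizer_budget, xtol=1e-12, ftol=1e-12)
    refined = PolyODEModel(coefficients=_to_raw(
        res.x.reshape(3, polybasis.N_TERMS), center, half))
    q_new = quality(refined, data, config)
    if q_new.total > q_start.total:
        return model, q_start
    budget_ok = res.nfev < config.optimizer_budget
    return refined, replace(q_new, stable=q_new.stable and budget_ok)


def is_stable(model: PolyODEModel, reference_data, factor: float = 5.0) -> bool:
    """Long-run boundedness screen.

    Integrates from the first observed state for `factor` times the data span
    and requires the trajectory to stay inside the data's bounding box
    inflated to three times its width (one extra width on each side).
    """
    data = _as_state_array(reference_data)
    lo, hi = data.min(axis=0), data.max(axis=0)
    w = hi - lo
    w[w == 0] = 1.0
    box_lo, box_hi = lo - w, hi + w
    horizon = factor * (data.shape[0] - 1)
    traj = integrate(model, data[0], horizon_months=horizon, dt=1.0, substeps=2,
                     guard=float(np.max(np.abs([box_lo, box_hi]))) + 1.0)
    if traj.diverged:
        return False
    return bool(np.all(traj.states >= box_lo) and np.all(traj.states <= box_hi))


@dataclass(frozen=True)
class SearchResult:
    candidates: list            # (model, QualityReport, config) stable, Q-sorted
    trial_log: list             # one dict per trial

    @property
    def best(self):
        return self.candidates[0] if self.candidates else None

    def log_frame(self):
        import pandas as pd
        return pd.DataFrame(self.trial_log)

    def export_log(self, path: str | Path) -> None:
        self.log_frame().to_csv(path, index=False)


def _parsimony(model: PolyODEModel, center: np.ndarray, half: np.ndarray) -> int:
    """Number of scaled coefficients with magnitude above 1e-3 (tie-break)."""
    return int(np.sum(np.abs(_to_scaled(model.coefficients, center, half)) > 1e-3))


def search(slow_data, config_grid: Sequence[TMConfig], seed: int = 0) -> SearchResult:
    """init -> refine -> stability screen over a grid of configurations.

    Stable candidates are ranked by total quality (ties broken toward fewer
    active coefficients).  Quality refinement very often destabilizes the
    long-term dynamics (most reconstruction trials fail the screen), so when
    a trial's refined model is unstable but its ridge-regularized init model
    is stable, the init model is kept as that trial's candidate (logged as
    `fallback_init`).  Returns an empty candidate list, with the full trial
    log, when no stable model is found at all.
    """
    if len(config_grid) == 0:
        raise ValueError("config grid must be non-empty")
    data = _as_state_array(slow_data)
    center, half = _scaling(data)
    rng = np.random.default_rng(seed)
    candidates = []
    log = []
    for i, cfg in enumerate(config_grid):
        entry = {"trial": i, "j_max": cfg.j_max, "d": cfg.d, "l_max": cfg.l_max,
                 "dt": cfg.dt, "ridge": cfg.ridge_weight}
        try:
            cfg.validate(data.shape[0])
            model0 = init_coefficients(data, ridge_weight=cfg.ridge_weight, dt=cfg.dt)
            if cfg.init_jitter > 0:
                jitter = 1.0 + cfg.init_jitter * rng.standard_normal(
                    model0.coefficients.shape)
                model0 = PolyODEModel(coefficients=model0.coefficients * jitter)
            model, rep = refine(model0, data, cfg)
            stable = is_stable(model, data) and rep.stable
            fallback = False
            if not stable:
                rep0 = quality(model0, data, cfg)
                if rep0.stable and is_stable(model0, data):
                    model, rep = model0, rep0
                    stable, fallback = True, True
            entry.update(q_total=rep.total, stable=stable,
                         fallback_init=fallback, error="")
            if stable:
                candidates.append((model, rep, cfg))
        except ValueError as exc:
            entry.update(q_total=np.inf, stable=False, error=str(exc))
        log.append(entry)
    candidates.sort(key=lambda t: (t[1].total, _parsimony(t[0], center, half)))
    return SearchResult(candidates=candidates, trial_log=log)
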