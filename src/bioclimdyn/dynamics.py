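"""Equilibria, linear stability and limit-cycle period of a cubic ODE model.

Equilibria are located by multi-start Newton iteration on a lattice of
starting points, classified from the analytic Jacobian's eigenvalues, and
long-term integrations provide the oscillation period via mean-crossing
spacing of the temperature component.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import polybasis
from .trajectory import PolyODEModel, integrate

__all__ = [
    "Classification", "EquilibriumPoint", "LongTermRun",
    "find_equilibria", "jacobian", "classify", "long_term", "estimate_period",
    "export_equilibria_csv",
]

HYPERBOLIC_TOL = 1e-6


@dataclass(frozen=True)
class Classification:
    planar: str      # stable_focus | unstable_focus | stable_node | unstable_node | saddle
    axial: str       # stable_node | unstable_node
    hyperbolic: bool

    @property
    def label(self) -> str:
        """Human-readable label in the planar/axial vocabulary."""
        if self.planar.endswith("focus"):
            kind = self.planar.replace("_", " ")
            axis = self.axial.replace("_", " ")
            return f"{kind} in (X,Y), {axis} along Z"
        if self.planar == "saddle":
            return "saddle"
        return self.planar.replace("_", " ")


@dataclass(frozen=True)
class EquilibriumPoint:
    state: np.ndarray
    eigenvalues: np.ndarray
    classification: Classification
    residual_norm: float

    @property
    def hyperbolic(self) -> bool:
        return self.classification.hyperbolic


@dataclass(frozen=True)
class LongTermRun:
    """Sampled long-term integration; `period_months` is filled by
    :func:`estimate_period` (None when no oscillation is detected)."""

    times: np.ndarray
    states: np.ndarray
    steps: int
    dt: float
    transient_cut: int
    diverged: bool = False

    @property
    def simulated_months(self) -> float:
        return self.steps * self.dt

    @property
    def simulated_years(self) -> int:
        """Whole simulated years: floor(steps * dt / 12)."""
        return int(self.steps * self.dt // 12)

    def post_transient(self) -> np.ndarray:
        return self.states[self.transient_cut:]


def jacobian(model: PolyODEModel, state: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the cubic vector field (no finite differences)."""
    b = polybasis.basis(np.asarray(state, dtype=float))
    cols = [J @ b for J in polybasis.jacobian_coefficients(model.coefficients)]
    return np.column_stack(cols)


def classify(eigenvalues) -> Classification:
    """Stability classification from exactly three eigenvalues.

    A complex-conjugate pair gives a planar focus (stable/unstable by the
    sign of its real part) with the lone real eigenvalue an axial node.
    Three real eigenvalues give a node when they share a sign and a saddle
    otherwise (the minority-sign eigenvalue plays the axial role).
    Hyperbolic iff every |Re(lambda)| exceeds 1e-6.
    """
    eig = np.atleast_1d(np.asarray(eigenvalues, dtype=complex))
    if eig.shape != (3,):
        raise ValueError("classification needs exactly three eigenvalues")
    hyperbolic = bool(np.min(np.abs(eig.real)) > HYPERBOLIC_TOL)
    imag_tol = 1e-12 * max(1.0, float(np.max(np.abs(eig))))
    complex_mask = np.abs(eig.imag) > imag_tol
    if np.any(complex_mask):
        if np.sum(complex_mask) != 2:
            raise ValueError("eigenvalues must be one real plus a conjugate pair, "
                             "or all real")
        pair_re = float(eig[complex_mask][0].real)
        lone = float(eig[~complex_mask][0].real)
        planar = "stable_focus" if pair_re < 0 else "unstable_focus"
        axial = "stable_node" if lone < 0 else "unstable_node"
        return Classification(planar=planar, axial=axial, hyperbolic=hyperbolic)
    re = np.sort(eig.real)
    if re[-1] < 0:
        return Classification("stable_node", "stable_node", hyperbolic)
    if re[0] > 0:
        return Classification("unstable_node", "unstable_node", hyperbolic)
    # mixed signs: the minority-sign eigenvalue is the axial direction
    n_neg = int(np.sum(re < 0))
    axial = "unstable_node" if n_neg == 2 else "stable_node"
    return Classification("saddle", axial, hyperbolic)


def find_equilibria(model: PolyODEModel, search_box, grid_n: int = 15,
                    tol: float = 1e-6, residual_tol: float = 1e-8
                    ) -> list[EquilibriumPoint]:
    """Roots of f(x) = 0 by Newton iteration from a grid_n^3 lattice.

    `search_box` is (lo, hi) triples.  Work happens in box-scaled units;
    converged roots are deduplicated within `tol` (scaled), restricted to the
    box, and returned sorted lexicographically by state.
    """
    lo = np.asarray(search_box[0], dtype=float)
    hi = np.asarray(search_box[1], dtype=float)
    if lo.shape != (3,) or hi.shape != (3,) or np.any(hi <= lo):
        raise ValueError("search box must be (lo, hi) triples with hi > lo")
    center, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    C = model.coefficients

    def f_scaled(s: np.ndarray) -> np.ndarray:
        return (polybasis.basis(center + half * s) @ C.T) / half

    roots: list[np.ndarray] = []
    axes = [np.linspace(-1, 1, grid_n)] * 3
    for s0 in np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3):
        s = s0.copy()
        fv = f_scaled(s)
        ok = False
        for _ in range(80):
            if np.linalg.norm(fv) < 1e-13:
                ok = True
                break
            x = center + half * s
            J = jacobian(model, x) * half[None, :] / half[:, None]
            try:
                step = np.linalg.solve(J, fv)
            except np.linalg.LinAlgError:
                break
            # damped Newton: backtrack until the residual actually shrinks
            lam, fnorm = 1.0, np.linalg.norm(fv)
            for _bt in range(25):
                s_new = s - lam * step
                f_new = f_scaled(s_new)
                if np.all(np.isfinite(f_new)) and np.linalg.norm(f_new) < fnorm:
                    break
                lam *= 0.5
            else:
                break
            s, fv = s_new, f_new
            if not np.all(np.isfinite(s)) or np.max(np.abs(s)) > 1e6:
                break
            if lam * np.max(np.abs(step)) < 1e-9:
                ok = True
                break
        if not ok:
            continue
        if np.linalg.norm(f_scaled(s)) > residual_tol:
            continue
        if np.any(s < -1 - 1e-9) or np.any(s > 1 + 1e-9):
            continue
        if any(np.max(np.abs(s - r)) < tol for r in roots):
            continue
        roots.append(s)
    points = []
    for s in sorted(roots, key=lambda r: tuple(r)):
        x = center + half * s
        eig = np.linalg.eigvals(jacobian(model, x))
        points.append(EquilibriumPoint(
            state=x, eigenvalues=eig, classification=classify(eig),
            residual_norm=float(np.linalg.norm(f_scaled(s)))))
    return points


def long_term(model: PolyODEModel, initial_state, steps: int = 7000,
              dt: float = 1.0, transient_fraction: float = 0.3,
              substeps: int = 4, guard: float = 1e6) -> LongTermRun:
    """Long integration with a blow-up guard and a default 30% transient cut.

    A divergent run is returned truncated and flagged, not raised.
    """
    traj = integrate(model, initial_state, horizon_months=steps * dt, dt=dt,
                     substeps=substeps, guard=guard)
    actual_steps = traj.states.shape[0] - 1
    return LongTermRun(times=traj.times, states=traj.states, steps=steps, dt=dt,
                       transient_cut=int(transient_fraction * actual_steps),
                       diverged=traj.diverged)


def estimate_period(run: LongTermRun, component: int = 2) -> float | None:
    """Mean spacing of upward mean-crossings of one component (months).

    Uses the post-transient segment of the mean-removed signal (temperature
    by default) with linear interpolation of the crossing times; returns
    None for fewer than two crossings (no oscillation).
    """
    x = run.post_transient()[:, component]
    if x.size < 3:
        return None
    y = x - x.mean()
    if np.allclose(y, 0.0):
        return None
    up = np.nonzero((y[:-1] < 0) & (y[1:] >= 0))[0]
    if up.size < 2:
        return None
    frac = -y[up] / (y[up + 1] - y[up])
    t_cross = (up + frac) * run.dt
    return float((t_cross[-1] - t_cross[0]) / (up.size - 1))


def export_equilibria_csv(points: list[EquilibriumPoint], path: str | Path) -> None:
    """Table-1-style report: state values, eigenvalues, characteristic label."""
    import pandas as pd
    rows = []
    for i, p in enumerate(points, start=1):
        rows.append({
            "point": f"P{i}",
            "sunshine": p.state[0], "precipitation": p.state[1],
            "temperature": p.state[2],
            "eig1": str(p.eigenvalues[0]), "eig2": str(p.eigenvalues[1]),
            "eig3": str(p.eigenvalues[2]),
            "characteristic": p.classification.label,
            "hyperbolic": p.classification.hyperbolic,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
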