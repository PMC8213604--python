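"""Complete cubic (degree <= 3) monomial basis in three state variables.

The canonical ordering is fixed package-wide::

    1, x, y, z, x^2, xy, xz, y^2, yz, z^2,
    x^3, x^2 y, x^2 z, x y^2, xyz, x z^2, y^3, y^2 z, y z^2, z^3

Everything that manipulates cubic vector fields (evaluation, analytic
Jacobians, affine changes of variables) is derived from the exponent table
below, so the ordering is defined in exactly one place.
"""

from __future__ import annotations

from math import comb

import numpy as np

#: exponent triples (ex, ey, ez) in canonical order
EXPONENTS: tuple[tuple[int, int, int], ...] = (
    (0, 0, 0),
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2),
    (3, 0, 0), (2, 1, 0), (2, 0, 1), (1, 2, 0), (1, 1, 1), (1, 0, 2),
    (0, 3, 0), (0, 2, 1), (0, 1, 2), (0, 0, 3),
)

N_TERMS = len(EXPONENTS)  # 20 = C(6,3)

_INDEX = {e: k for k, e in enumerate(EXPONENTS)}

MONOMIAL_NAMES: tuple[str, ...] = tuple(
    "1" if e == (0, 0, 0) else
    "*".join(f"{v}^{p}" if p > 1 else v
             for v, p in zip(("x", "y", "z"), e) if p > 0)
    for e in EXPONENTS
)

_EXP_ARR = np.array(EXPONENTS)  # (20, 3)


def basis(state: np.ndarray) -> np.ndarray:
    """Evaluate the 20 monomials at one state or a batch of states.

    `state` of shape (3,) gives a (20,) vector; shape (n, 3) gives (n, 20).
    """
    state = np.asarray(state, dtype=float)
    single = state.ndim == 1
    pts = np.atleast_2d(state)
    if pts.shape[1] != 3:
        raise ValueError("state must have three components")
    # pts[:, None, :] ** EXP -> (n, 20, 3); product over the last axis
    out = np.prod(pts[:, None, :] ** _EXP_ARR[None, :, :], axis=2)
    return out[0] if single else out


def gradient_columns() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Matrices D_x, D_y, D_z (20x20) with d(m_k)/dv = sum_j D_v[j, k] m_j.

    Differentiating any degree-<=3 monomial yields a single lower-degree
    monomial, so these matrices have at most one nonzero per column.
    """
    mats = []
    for axis in range(3):
        D = np.zeros((N_TERMS, N_TERMS))
        for k, e in enumerate(EXPONENTS):
            if e[axis] == 0:
                continue
            lower = list(e)
            lower[axis] -= 1
            D[_INDEX[tuple(lower)], k] = e[axis]
        mats.append(D)
    return tuple(mats)


_GRAD = gradient_columns()


def jacobian_coefficients(coeffs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coefficient matrices of the analytic Jacobian of a cubic vector field.

    For coefficient matrix ``coeffs`` (3x20), returns (Jx, Jy, Jz), each 3x20,
    such that d f_i / d v evaluated at a state is ``Jv[i] @ basis(state)``.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (3, N_TERMS):
        raise ValueError(f"coefficient matrix must be 3x{N_TERMS}")
    return tuple(coeffs @ D.T for D in _GRAD)


def affine_substitution_matrix(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Matrix T of the substitution u_i = alpha_i * x_i + beta_i.

    For a polynomial h(u) = sum_k c_k m_k(u), the same function of x is
    sum_j (T @ c)_j m_j(x).  Exact (binomial expansion), no fitting.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if alpha.shape != (3,) or beta.shape != (3,):
        raise ValueError("alpha and beta must be length-3")
    T = np.zeros((N_TERMS, N_TERMS))
    for k, e in enumerate(EXPONENTS):
        # expand prod_i (alpha_i x_i + beta_i)^e_i term by term
        acc: dict[tuple[int, int, int], float] = {(0, 0, 0): 1.0}
        for axis in range(3):
            nxt: dict[tuple[int, int, int], float] = {}
            for j in range(e[axis] + 1):
                w = comb(e[axis], j) * alpha[axis] ** j * beta[axis] ** (e[axis] - j)
                if w == 0.0:
                    continue
                for expo, c in acc.items():
                    ne = list(expo)
                    ne[axis] = j
                    key = tuple(ne)
                    nxt[key] = nxt.get(key, 0.0) + c * w
            acc = nxt
        for expo, c in acc.items():
            T[_INDEX[expo], k] += c
    return T


def change_of_variables(coeffs: np.ndarray, shift: np.ndarray,
                        scale: np.ndarray) -> np.ndarray:
    """Rewrite a cubic vector field under the state map  x = shift + scale * u.

    ``coeffs`` describes du/dt = F(u); the returned 3x20 matrix describes the
    identical dynamics of x:  dx/dt = scale_i * F_i((x - shift) / scale).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    shift = np.asarray(shift, dtype=float)
    scale = np.asarray(scale, dtype=float)
    if np.any(scale == 0):
        raise ValueError("scale components must be nonzero")
    T = affine_substitution_matrix(1.0 / scale, -shift / scale)
    return scale[:, None] * (coeffs @ T.T)
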