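"""Compartmental retention models: mono-exponential, biexponential, and the
two-compartment (blood <-> deep tissue) system with urinary elimination.

The two-compartment model is

    dC_b/dt = -(k_bd + k_e) C_b + k_db C_d        C_b(0) = C0
    dC_d/dt =   k_bd C_b          - k_db C_d      C_d(0) = 0

with first-order transfer rates k_bd (blood -> deep), k_db (deep -> blood)
and elimination k_e from blood, all in day^-1.  Its blood solution is the
biexponential

    C_b(t) = C0 (k_db - beta)/(alpha - beta) e^{-beta t}
           + C0 (k_db - alpha)/(beta - alpha) e^{-alpha t}
           = B e^{-beta t} + A e^{-alpha t}

where alpha >= beta > 0 are the roots of
lambda^2 - (k_bd + k_db + k_e) lambda + k_db k_e = 0 (the negatives of the
rate-matrix eigenvalues).  The module provides the closed forms, an ODE
integrator that serves as their independent numeric oracle, and the exact
micro (k_bd, k_db, k_e) <-> macro (A, B, alpha, beta) conversions.

Amounts and concentrations differ only by the distribution volume, so the
equations are carried in amounts (equivalently percent retention) and no
volume parameter appears.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import (
    DomainError,
    InconsistentMacroSetError,
    RepeatedEigenvalueError,
)

#: relative discriminant below which the eigenvalues are treated as repeated
EIGEN_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class MonoExpParams:
    """Single-phase decay: retention(t) = r0 * exp(-k t)."""

    r0: float
    k: float

    def __post_init__(self):
        if self.r0 <= 0:
            raise DomainError("r0 must be positive")
        if self.k < 0:
            raise DomainError("k must be non-negative")


@dataclass(frozen=True)
class BiCompartmentParams:
    """Micro rate constants of the two-compartment model (day^-1) plus the
    initial blood amount C0 (percent or activity units)."""

    k_bd: float
    k_db: float
    k_e: float
    c0: float = 100.0

    def __post_init__(self):
        if min(self.k_bd, self.k_db, self.k_e) < 0:
            raise DomainError("rate constants must be non-negative")
        if self.c0 <= 0:
            raise DomainError("c0 must be positive")


@dataclass(frozen=True)
class MacroBiexpParams:
    """Observable biexponential form A e^{-alpha t} + B e^{-beta t} with the
    fast/slow convention alpha >= beta."""

    coeff_a: float
    coeff_b: float
    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha < self.beta:
            raise DomainError("require alpha >= beta (alpha is the fast phase)")
        if self.beta <= 0:
            raise DomainError("require beta > 0")


def eigenvalues(params: BiCompartmentParams) -> tuple[float, float]:
    """Exponents (alpha, beta), alpha >= beta, of the two-compartment model.

    Roots of lambda^2 - (k_bd+k_db+k_e) lambda + k_db k_e = 0, computed with
    the numerically stable quadratic formula (product/larger-root for the
    small root, avoiding cancellation).
    """
    s = params.k_bd + params.k_db + params.k_e
    p = params.k_db * params.k_e
    disc = s * s - 4.0 * p
    if disc < 0:  # cannot occur for non-negative rates except via round-off
        disc = 0.0
    root = np.sqrt(disc)
    alpha = 0.5 * (s + root)
    beta = p / alpha if alpha > 0 else 0.0
    return float(alpha), float(beta)


def _is_confluent(params: BiCompartmentParams) -> bool:
    s = params.k_bd + params.k_db + params.k_e
    disc = s * s - 4.0 * params.k_db * params.k_e
    return s > 0 and abs(disc) < EIGEN_TIE_RTOL * s * s


def mono_exp(params: MonoExpParams, t) -> np.ndarray:
    """Evaluate r0 * exp(-k t) for t >= 0 (days)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be non-negative")
    return params.r0 * np.exp(-params.k * t)


def bicompartment_blood(params: BiCompartmentParams, t) -> np.ndarray:
    """Closed-form blood amount C_b(t) of the two-compartment model.

    A numerically repeated eigenvalue (relative discriminant below
    ``EIGEN_TIE_RTOL``) is handled by the confluent limit
    C_b(t) = C0 (1 - (k_bd + k_e - lam) t) e^{-lam t}.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be non-negative")
    if _is_confluent(params):
        lam = 0.5 * (params.k_bd + params.k_db + params.k_e)
        return params.c0 * (1.0 - (params.k_bd + params.k_e - lam) * t) * np.exp(-lam * t)
    alpha, beta = eigenvalues(params)
    if alpha == beta:  # all rates zero
        return np.full_like(t, params.c0, dtype=float)
    cb = params.c0 * (
        (params.k_db - beta) / (alpha - beta) * np.exp(-beta * t)
        + (params.k_db - alpha) / (beta - alpha) * np.exp(-alpha * t)
    )
    return cb


def bicompartment_deep(params: BiCompartmentParams, t) -> np.ndarray:
    """Closed-form deep-compartment amount C_d(t); C_d(0) = 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be non-negative")
    if _is_confluent(params):
        lam = 0.5 * (params.k_bd + params.k_db + params.k_e)
        return params.c0 * params.k_bd * t * np.exp(-lam * t)
    alpha, beta = eigenvalues(params)
    if alpha == beta:
        return np.zeros_like(t, dtype=float)
    return (
        params.c0
        * params.k_bd
        / (alpha - beta)
        * (np.exp(-beta * t) - np.exp(-alpha * t))
    )


def bicompartment_total(params: BiCompartmentParams, t) -> np.ndarray:
    """Whole-body amount C_b(t) + C_d(t) (what a whole-body counter sees)."""
    return bicompartment_blood(params, t) + bicompartment_deep(params, t)


def integrate_ode(params: BiCompartmentParams, t_grid, rtol=1e-11, atol=None):
    """Numerically integrate the two-compartment ODEs on ``t_grid``.

    Returns a dict with keys ``blood``, ``deep`` and ``eliminated`` (the
    latter accumulated as k_e * integral of C_b, so that
    blood + deep + eliminated = C0 at every grid point).  This integrator is
    deliberately independent of the closed forms and serves as their oracle.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise DomainError("t_grid must be increasing with >= 2 points")
    if t_grid[0] < 0:
        raise DomainError("t_grid must start at t >= 0")
    if atol is None:
        atol = 1e-12 * params.c0

    kbd, kdb, ke = params.k_bd, params.k_db, params.k_e

    def rhs(_t, y):
        cb, cd, _el = y
        return [-(kbd + ke) * cb + kdb * cd, kbd * cb - kdb * cd, ke * cb]

    y0 = [params.c0, 0.0, 0.0]
    t0 = min(0.0, t_grid[0])
    sol = solve_ivp(
        rhs, (t0, t_grid[-1]), y0, t_eval=t_grid, method="LSODA",
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise DomainError(f"ODE solver failed: {sol.message}")
    return {"blood": sol.y[0], "deep": sol.y[1], "eliminated": sol.y[2]}


def micro_to_macro(params: BiCompartmentParams) -> MacroBiexpParams:
    """Exact map from micro rates to the macro set (A, B, alpha, beta).

    A = C0 (k_db - alpha)/(beta - alpha) multiplies e^{-alpha t},
    B = C0 (k_db - beta)/(alpha - beta) multiplies e^{-beta t};
    A + B = C0 by construction.
    """
    if _is_confluent(params):
        raise RepeatedEigenvalueError(
            "repeated eigenvalue: the macro biexponential set is undefined; "
            "use the confluent closed form in bicompartment_blood"
        )
    alpha, beta = eigenvalues(params)
    if beta <= 0:
        raise DomainError("macro set requires k_db > 0 and k_e > 0")
    a = params.c0 * (params.k_db - alpha) / (beta - alpha)
    b = params.c0 * (params.k_db - beta) / (alpha - beta)
    return MacroBiexpParams(coeff_a=a, coeff_b=b, alpha=alpha, beta=beta)


def macro_to_micro(params: MacroBiexpParams) -> BiCompartmentParams:
    """Exact inverse map from (A, B, alpha, beta) to the micro rates:

    k_db = (A beta + B alpha)/(A + B),  k_e = alpha beta / k_db,
    k_bd = alpha + beta - k_db - k_e,   C0 = A + B.
    """
    a, b = params.coeff_a, params.coeff_b
    if a <= 0 or b <= 0:
        raise DomainError("require A > 0 and B > 0")
    if params.alpha <= params.beta:
        raise RepeatedEigenvalueError("require alpha > beta (distinct phases)")
    c0 = a + b
    k_db = (a * params.beta + b * params.alpha) / c0
    k_e = params.alpha * params.beta / k_db
    k_bd = params.alpha + params.beta - k_db - k_e
    if min(k_bd, k_db, k_e) < -1e-12:
        raise InconsistentMacroSetError(
            f"macro set maps to negative rates (k_bd={k_bd:.3g}, "
            f"k_db={k_db:.3g}, k_e={k_e:.3g})"
        )
    return BiCompartmentParams(
        k_bd=max(k_bd, 0.0), k_db=k_db, k_e=k_e, c0=c0
    )


def half_life(k: float) -> float:
    """Half-life ln(2)/k in days for a first-order rate k (day^-1)."""
    if k <= 0:
        raise DomainError("half-life requires k > 0")
    return float(np.log(2.0) / k)
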