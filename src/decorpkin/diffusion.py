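"""Diffusion-limited release from an "infinite" tissue reservoir.

Late-phase decorporation is modelled as one-dimensional Fick diffusion of
the chelate complex across the cell membrane from a reservoir held at
constant concentration C_d0 into a semi-infinite medium:

    dC/dt = D d2C/dx2,   C(0, t) = C_d0,  C(x, 0) = 0,  C(inf, t) = 0.

The similarity solution is C(x, t) = C_d0 erfc(x / (2 sqrt(D t))); the flux
across the interface x = 0 is J(t) = C_d0 sqrt(D / (pi t)), and the
cumulative amount transferred through an interface of area A is

    Q(t) = A * integral_0^t J dt = 2 A C_d0 sqrt(D t / pi),

proportional to sqrt(t).  On retention data the law appears in the
empirical form %Retention = a - b sqrt(t); only the lumped slope
2 A C_d0 sqrt(D/pi) is identifiable from retention measurements, never the
mechanistic triple (D, C_d0, A) separately.

A Crank-Nicolson finite-difference solver of the same initial-boundary
problem on a truncated domain is provided as an independent numeric oracle
for the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import erfc

from .exceptions import DomainError


@dataclass(frozen=True)
class DiffusionParams:
    """Mechanistic parameters: diffusion coefficient D (length^2/day),
    reservoir concentration C_d0, and interface area A (length^2)."""

    d_coeff: float
    c_d0: float
    area: float = 1.0

    def __post_init__(self):
        if min(self.d_coeff, self.c_d0, self.area) <= 0:
            raise DomainError("D, C_d0 and area must all be positive")


@dataclass(frozen=True)
class SqrtLawParams:
    """Empirical square-root law %Retention(t) = intercept - slope * sqrt(t).

    The intercept is not constrained to 100 because the law describes the
    late window after the first-day drop, not the full curve.
    """

    intercept: float
    slope: float

    def __post_init__(self):
        if self.slope < 0:
            raise DomainError("slope must be >= 0 (retention non-increasing)")

    @property
    def zero_crossing(self) -> float:
        """Diagnostic time t* = (a/b)^2 at which the line would reach 0%."""
        if self.slope == 0:
            return float("inf")
        return (self.intercept / self.slope) ** 2


def profile(params: DiffusionParams, x, t) -> np.ndarray:
    """Concentration C(x, t) = C_d0 erfc(x / (2 sqrt(D t))) for t > 0."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise DomainError("profile requires t > 0")
    if np.any(x < 0):
        raise DomainError("x must be non-negative")
    return params.c_d0 * erfc(x / (2.0 * np.sqrt(params.d_coeff * t)))


def boundary_flux(params: DiffusionParams, t) -> np.ndarray:
    """Interface flux J(t) = C_d0 sqrt(D / (pi t)) at x = 0, for t > 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise DomainError("boundary_flux requires t > 0")
    return params.c_d0 * np.sqrt(params.d_coeff / (np.pi * t))


def cumulative_transfer(params: DiffusionParams, t) -> np.ndarray:
    """Cumulative amount Q(t) = 2 A C_d0 sqrt(D t / pi) through the interface."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("cumulative_transfer requires t >= 0")
    return 2.0 * params.area * params.c_d0 * np.sqrt(params.d_coeff * t / np.pi)


def sqrt_retention(params: SqrtLawParams, t) -> np.ndarray:
    """Empirical retention a - b sqrt(t).  No clipping at zero: the law's
    validity window ends before the zero crossing (see ``zero_crossing``)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be non-negative")
    return params.intercept - params.slope * np.sqrt(t)


@dataclass
class PdeSolution:
    """Finite-difference solution: grid, profiles at requested times, the
    numerically integrated cumulative transfer, and any warnings raised."""

    x: np.ndarray
    t_grid: np.ndarray
    profiles: np.ndarray  # shape (len(t_grid), nx)
    q_numeric: np.ndarray
    warnings: list = field(default_factory=list)


def pde_oracle(
    params: DiffusionParams,
    domain_length: float,
    nx: int,
    t_grid,
    n_time_steps: int = 800,
) -> PdeSolution:
    """Implicit (Crank-Nicolson) finite-difference oracle for the closed forms.

    Solves dC/dt = D d2C/dx2 on [0, L] with C(0) = C_d0 and C(L) = 0 on a
    uniform spatial grid.  Time stepping is square-root graded (fine near the
    initial boundary-layer singularity) with a few backward-Euler start-up
    steps to damp the Crank-Nicolson oscillation from the discontinuous
    initial/boundary data.  Q(t) is accumulated by trapezoidal integration of
    the second-order one-sided boundary flux over the internal time grid.

    ``domain_length`` should satisfy L >= 6 sqrt(D t_max) so the truncated
    far boundary does not contaminate the solution; a violation is recorded
    as a warning on the result, not raised.
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if np.any(t_grid <= 0) or np.any(np.diff(t_grid) <= 0):
        raise DomainError("t_grid must be positive and strictly increasing")
    if nx < 100:
        raise DomainError("nx must be >= 100 for oracle-quality accuracy")
    warnings = []
    t_max = float(t_grid[-1])
    needed = 6.0 * np.sqrt(params.d_coeff * t_max)
    if domain_length < needed:
        warnings.append(
            f"domain_length {domain_length:.4g} < 6 sqrt(D t_max) = {needed:.4g}; "
            "truncation error may exceed the stated tolerance"
        )

    x = np.linspace(0.0, domain_length, nx)
    dx = x[1] - x[0]
    c = np.zeros(nx)
    c[0] = params.c_d0

    # internal times: sqrt-graded so that steps are fine near t = 0
    n_steps = max(int(n_time_steps), 2 * t_grid.size)
    internal = t_max * (np.arange(n_steps + 1) / n_steps) ** 2
    times = np.unique(np.concatenate((internal, t_grid)))

    def one_sided_flux(cvec):
        # second-order one-sided derivative at x = 0
        dcdx = (-3.0 * cvec[0] + 4.0 * cvec[1] - cvec[2]) / (2.0 * dx)
        return -params.d_coeff * dcdx

    n_int = nx - 2  # interior unknowns
    flux_hist = np.empty(times.size)
    flux_hist[0] = one_sided_flux(c)  # zero-state flux (0 at t=0+ numerically)
    profiles = np.empty((t_grid.size, nx))
    q_cum = np.zeros(times.size)
    out_idx = {round(t, 15): i for i, t in enumerate(t_grid)}

    n_rannacher = 4  # backward-Euler start-up steps
    for step in range(1, times.size):
        dt = times[step] - times[step - 1]
        r = params.d_coeff * dt / dx**2
        theta = 1.0 if step <= n_rannacher else 0.5
        # (I - theta r L) c_new = (I + (1-theta) r L) c_old + boundary terms
        ab = np.zeros((3, n_int))
        ab[0, 1:] = -theta * r
        ab[1, :] = 1.0 + 2.0 * theta * r
        ab[2, :-1] = -theta * r
        interior = c[1:-1]
        rhs = interior + (1.0 - theta) * r * (c[:-2] - 2.0 * interior + c[2:])
        rhs[0] += theta * r * params.c_d0  # left Dirichlet value (constant)
        new = np.empty_like(c)
        new[0], new[-1] = params.c_d0, 0.0
        new[1:-1] = solve_banded((1, 1), ab, rhs)
        c = new
        flux_hist[step] = one_sided_flux(c)
        q_cum[step] = q_cum[step - 1] + 0.5 * dt * (
            flux_hist[step] + flux_hist[step - 1]
        ) * params.area
        key = round(float(times[step]), 15)
        if key in out_idx:
            profiles[out_idx[key]] = c

    q_numeric = np.interp(t_grid, times, q_cum)
    return PdeSolution(
        x=x, t_grid=t_grid, profiles=profiles, q_numeric=q_numeric,
        warnings=warnings,
    )
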