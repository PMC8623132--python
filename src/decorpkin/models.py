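"""Registry of fittable retention models.

Every entry maps a string identifier to a :class:`ModelSpec` bundling the
prediction function (vectorised over time), parameter names, box bounds for
the optimizer, a data-driven initial guess, and the derived quantities
(half-lives, eigenvalues, zero-crossing diagnostics) reported with a fit.

Identifiers
-----------
``monoexp``        r0 exp(-k t)
``biexp_macro``    A exp(-alpha t) + B exp(-beta t)
``bicompartment``  two-compartment model in micro rates (k_bd, k_db, k_e, C0);
                   the observable is either the whole body (blood + deep,
                   default) or the blood compartment alone, selected with
                   ``options={"observable": "blood"}``
``sqrtlaw``        a - b sqrt(t), the empirical square-root law
``diffusion``      mechanistic square-root transfer: r0 - 100 Q(t)/m0 with
                   Q(t) = 2 A C_d0 sqrt(D t / pi).  Only the lumped slope
                   2 A C_d0 sqrt(D/pi) is identifiable from retention data,
                   so the fit parameter is that lumped slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import diffusion, kinetics
from .exceptions import ConfigError, DomainError


@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    param_names: tuple[str, ...]
    predict: Callable  # predict(theta, t, **options) -> ndarray
    initial_guess: Callable  # initial_guess(t, y) -> theta ndarray
    lower: np.ndarray
    upper: np.ndarray
    derived: Callable = field(default=lambda theta, **opts: {})

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def _loglinear(t, y):
    """Slope/intercept of a log-linear fit, ignoring non-positive values."""
    mask = y > 0
    if mask.sum() < 2:
        return np.log(max(y[0], 1e-6)), 0.1
    slope, intercept = np.polyfit(t[mask], np.log(y[mask]), 1)
    return intercept, max(-slope, 1e-6)


# --- monoexp ---------------------------------------------------------------


def _monoexp_predict(theta, t, **_):
    return theta[0] * np.exp(-theta[1] * t)


def _monoexp_init(t, y):
    intercept, k = _loglinear(t, y)
    return np.array([np.exp(intercept), k])


def _monoexp_derived(theta, **_):
    r0, k = theta
    out = {}
    if k > 0:
        out["t_half"] = kinetics.half_life(k)
    return out


# --- biexp_macro -----------------------------------------------------------


def _biexp_predict(theta, t, **_):
    a, b, alpha, beta = theta
    return a * np.exp(-alpha * t) + b * np.exp(-beta * t)


def _biexp_init(t, y):
    from .fitting import strip_initialize_arrays

    macro, _info = strip_initialize_arrays(t, y)
    return np.array([macro.coeff_a, macro.coeff_b, macro.alpha, macro.beta])


def _biexp_derived(theta, **_):
    a, b, alpha, beta = theta
    out = {"t_half_terminal": kinetics.half_life(beta) if beta > 0 else np.inf}
    try:
        micro = kinetics.macro_to_micro(
            kinetics.MacroBiexpParams(a, b, alpha, beta)
        )
        out.update(
            k_bd=micro.k_bd, k_db=micro.k_db, k_e=micro.k_e,
            t_half_e=kinetics.half_life(micro.k_e),
        )
    except DomainError:
        pass
    return out


# --- bicompartment ---------------------------------------------------------


def _bicomp_predict(theta, t, observable="total", **_):
    p = kinetics.BiCompartmentParams(*np.maximum(theta, 0.0))
    if observable == "total":
        return kinetics.bicompartment_total(p, t)
    if observable == "blood":
        return kinetics.bicompartment_blood(p, t)
    raise ConfigError(f"unknown observable {observable!r}")


def _bicomp_init(t, y):
    from .fitting import strip_initialize_arrays

    macro, _info = strip_initialize_arrays(t, y)
    try:
        micro = kinetics.macro_to_micro(macro)
        return np.array([micro.k_bd, micro.k_db, micro.k_e, micro.c0])
    except DomainError:
        # macro set inconsistent with a two-compartment system: fall back to
        # a mild-transfer guess anchored on the terminal slope
        return np.array([macro.beta, macro.beta, 5.0 * macro.beta, max(y[0], 1.0)])


def _bicomp_derived(theta, **_):
    p = kinetics.BiCompartmentParams(*np.maximum(theta, 0.0))
    alpha, beta = kinetics.eigenvalues(p)
    out = {"alpha": alpha, "beta": beta}
    if p.k_e > 0:
        out["t_half_e"] = kinetics.half_life(p.k_e)
    if beta > 0:
        out["t_half_terminal"] = kinetics.half_life(beta)
    return out


# --- square-root laws ------------------------------------------------------


def _sqrtlaw_predict(theta, t, **_):
    return theta[0] - theta[1] * np.sqrt(t)


def _sqrtlaw_init(t, y):
    design = np.vstack([np.ones_like(t), np.sqrt(t)]).T
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return np.array([coef[0], max(-coef[1], 0.0)])


def _sqrtlaw_derived(theta, **_):
    a, b = theta
    return {"zero_crossing": (a / b) ** 2 if b > 0 else np.inf}


def _diffusion_predict(theta, t, **_):
    # r0 - lumped_slope * sqrt(t); the lumped slope is 100 * 2 A C_d0
    # sqrt(D/pi) / m0, realised through cumulative_transfer with unit A, C_d0
    # and D = pi * slope^2 / 4 so the mechanistic route is exercised.
    r0, slope = theta
    if slope <= 0:
        return np.full_like(np.asarray(t, dtype=float), r0)
    params = diffusion.DiffusionParams(
        d_coeff=np.pi * slope**2 / 4.0, c_d0=1.0, area=1.0
    )
    return r0 - diffusion.cumulative_transfer(params, t)


REGISTRY: dict[str, ModelSpec] = {
    "monoexp": ModelSpec(
        "monoexp", ("r0", "k"), _monoexp_predict, _monoexp_init,
        lower=np.array([1e-9, 0.0]), upper=np.array([np.inf, np.inf]),
        derived=_monoexp_derived,
    ),
    "biexp_macro": ModelSpec(
        "biexp_macro", ("coeff_a", "coeff_b", "alpha", "beta"),
        _biexp_predict, _biexp_init,
        lower=np.array([0.0, 0.0, 1e-9, 1e-9]),
        upper=np.array([np.inf] * 4),
        derived=_biexp_derived,
    ),
    "bicompartment": ModelSpec(
        "bicompartment", ("k_bd", "k_db", "k_e", "c0"),
        _bicomp_predict, _bicomp_init,
        lower=np.array([0.0, 0.0, 1e-9, 1e-9]),
        upper=np.array([np.inf] * 4),
        derived=_bicomp_derived,
    ),
    "sqrtlaw": ModelSpec(
        "sqrtlaw", ("intercept", "slope"), _sqrtlaw_predict, _sqrtlaw_init,
        lower=np.array([-np.inf, 0.0]), upper=np.array([np.inf, np.inf]),
        derived=_sqrtlaw_derived,
    ),
    "diffusion": ModelSpec(
        "diffusion", ("r0", "lumped_slope"), _diffusion_predict, _sqrtlaw_init,
        lower=np.array([-np.inf, 0.0]), upper=np.array([np.inf, np.inf]),
        derived=_sqrtlaw_derived,
    ),
}


def get_model(model_id: str) -> ModelSpec:
    try:
        return REGISTRY[model_id]
    except KeyError:
        raise ConfigError(
            f"unknown model id {model_id!r}; registered: {sorted(REGISTRY)}"
        ) from None
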