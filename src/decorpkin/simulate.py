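"""Synthetic whole-body retention data with the design structure of the
three rat decorporation experiments.

Three designs are encoded (seven animals per arm, 0.037 MBq of tracer per
rat, intraperitoneal chelator at 3.32 or 5 mg per 0.25 mL per 100 g body
weight):

* ``exp1`` - control vs a single low pre-contamination dose (30 min before,
  encoded as day -0.021), measured daily on days 0-10;
* ``exp2`` - control vs a single high pre-dose vs high pre-dose repeated
  24 h after contamination, measured daily on days 0-10;
* ``exp3`` - delayed course: five consecutive daily doses on days 12-16,
  whole-body retention measured daily on days 13-23.

The generative truth is a two-compartment kinetic state (blood, deep
tissue) propagated exactly (matrix exponential) through piecewise-constant
rate constants: chelator administrations multiply (k_e, k_db) by fixed
factors for a stated effect duration, with the compartment state carried
continuously across switches.  Measurement noise is multiplicative
log-normal on activity (counting and biological variability are
scale-proportional).  Radioactive decay of the tracer (physical half-life
~244 d) is not modelled separately: over a 23-day study it is dominated by
biology and mostly cancels in the retention ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .data import RatSeries, RetentionSeries, normalize_retention
from .diffusion import SqrtLawParams, sqrt_retention
from .exceptions import ConfigError, DataValidationError
from .kinetics import BiCompartmentParams, bicompartment_total

#: reference treated-arm micro rates (high-dose rapid intervention), day^-1
TREATED_RATES = BiCompartmentParams(k_bd=1.77, k_db=1.21, k_e=0.19, c0=100.0)
#: untreated transfer rates, day^-1 (k_e is calibrated, see control_rates())
CONTROL_KBD = 0.14
CONTROL_KDB = 0.09
#: early whole-body half-life the control elimination rate is calibrated to
CONTROL_EARLY_T_HALF = 2.8

HIGH_DOSE = 5.0
LOW_DOSE = 3.32
PRE_DOSE_DAY = -0.021  # 30 min before contamination


@dataclass(frozen=True)
class ExperimentDesign:
    """One treatment arm: dosing schedule and measurement grid."""

    design_id: str  # exp1 | exp2 | exp3 | custom
    arm: str
    dose_mg: float
    dosing_days: tuple = ()
    measurement_days: tuple = tuple(range(0, 11))
    contamination_day: float = 0.0
    n_rats: int = 7
    initial_activity: float = 0.037  # MBq per rat

    def __post_init__(self):
        if self.n_rats < 1:
            raise DataValidationError("n_rats must be >= 1")
        if self.dose_mg < 0:
            raise DataValidationError("dose must be non-negative")
        days = np.asarray(self.measurement_days, dtype=float)
        if days.size < 2 or np.any(np.diff(days) <= 0):
            raise DataValidationError("measurement days must be increasing, >= 2")
        if days[0] < self.contamination_day:
            raise DataValidationError("measurements precede contamination")

    @property
    def ref_time(self) -> float:
        """Normalization reference: the first sampling day."""
        return float(self.measurement_days[0])


@dataclass(frozen=True)
class TreatmentEffect:
    """Multiplicative kinetic effect of one chelator administration: while
    active, k_e and k_db are multiplied by the stated factors."""

    factor_ke: float = 1.0
    factor_kdb: float = 1.0
    duration_days: float = 1.0

    def __post_init__(self):
        if min(self.factor_ke, self.factor_kdb) <= 0:
            raise DataValidationError("effect factors must be positive")
        if self.duration_days <= 0:
            raise DataValidationError("effect duration must be positive")


@dataclass(frozen=True)
class TruthModel:
    """Generative truth for one arm.

    ``base_params`` is either a kinetic rate set (two-compartment state
    propagated piecewise through the treatment windows) or an empirical
    square-root law evaluated directly at the measurement days.
    ``observable`` selects what fraction of the kinetic state the whole-body
    counter reading represents (see the methods note).
    """

    base_params: object  # BiCompartmentParams | SqrtLawParams
    observable: str = "total"  # total | blood
    treatment_effect: TreatmentEffect = field(default_factory=TreatmentEffect)
    noise_sigma: float = 0.02  # log-normal sigma per measurement
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise DataValidationError("noise_sigma must be >= 0")
        if self.observable not in ("total", "blood"):
            raise ConfigError(f"unknown observable {self.observable!r}")


@lru_cache(maxsize=1)
def control_ke() -> float:
    """Untreated elimination rate, calibrated so that the noiseless control
    whole-body curve crosses 50% at t = 2.8 d (the early half-life)."""

    def crossing(ke):
        p = BiCompartmentParams(CONTROL_KBD, CONTROL_KDB, ke, 100.0)
        return float(bicompartment_total(p, CONTROL_EARLY_T_HALF)) - 50.0

    return float(brentq(crossing, 0.05, 2.0, xtol=1e-12))


def control_rates() -> BiCompartmentParams:
    """Untreated two-compartment rate set."""
    return BiCompartmentParams(CONTROL_KBD, CONTROL_KDB, control_ke(), 100.0)


def _rate_matrix(p: BiCompartmentParams) -> np.ndarray:
    return np.array(
        [[-(p.k_bd + p.k_e), p.k_db], [p.k_bd, -p.k_db]]
    )


def _effect_windows(design: ExperimentDesign, effect: TreatmentEffect):
    """Merged time intervals during which the treatment effect is active,
    clipped to start no earlier than contamination."""
    raw = sorted(
        (max(d, design.contamination_day), d + effect.duration_days)
        for d in design.dosing_days
    )
    merged: list[list[float]] = []
    for lo, hi in raw:
        if merged and lo <= merged[-1][1] + 1e-12:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def retention_fraction(design: ExperimentDesign, truth: TruthModel, times):
    """Noise-free retention fraction (of the initial amount) at ``times``.

    Kinetic truths are propagated exactly segment-by-segment with the matrix
    exponential of the piecewise-constant rate matrix; the compartment state
    is continuous at every switch.  Square-root truths are evaluated
    directly (as percent, converted to fraction).
    """
    times = np.asarray(times, dtype=float)
    if isinstance(truth.base_params, SqrtLawParams):
        return sqrt_retention(truth.base_params, times) / 100.0

    base: BiCompartmentParams = truth.base_params
    eff = truth.treatment_effect
    boosted = replace(
        base, k_db=base.k_db * eff.factor_kdb, k_e=base.k_e * eff.factor_ke
    )
    windows = _effect_windows(design, eff)
    # segment boundaries over [t0, max(times)]
    t0 = design.contamination_day
    edges = sorted({t0, *(b for w in windows for b in w), float(times.max())})
    edges = [e for e in edges if t0 <= e <= float(times.max())]
    if edges[-1] < float(times.max()):
        edges.append(float(times.max()))

    def active(lo):
        return any(w0 - 1e-12 <= lo < w1 - 1e-12 for w0, w1 in windows)

    state = np.array([base.c0, 0.0])
    out = np.empty(times.size)
    done = np.zeros(times.size, dtype=bool)
    for lo, hi in zip(edges[:-1], edges[1:]):
        mat = _rate_matrix(boosted if active(lo) else base)
        inside = ~done & (times >= lo - 1e-12) & (times <= hi + 1e-12)
        for idx in np.flatnonzero(inside):
            y = expm(mat * (times[idx] - lo)) @ state
            out[idx] = y[0] if truth.observable == "blood" else y.sum()
            done[idx] = True
        state = expm(mat * (hi - lo)) @ state
    return out / base.c0


def simulate_rat(design: ExperimentDesign, truth: TruthModel,
                 rat_index: int) -> RatSeries:
    """One animal's activity series: initial activity x retention fraction x
    independent log-normal measurement noise.  The per-rat random stream is
    derived from (truth.seed, rat_index), so a fixed seed reproduces the
    series exactly."""
    times = np.asarray(design.measurement_days, dtype=float)
    frac = retention_fraction(design, truth, times)
    rng = np.random.default_rng([int(truth.seed), int(rat_index)])
    eps = rng.normal(0.0, truth.noise_sigma, times.size)
    activity = design.initial_activity * frac * np.exp(eps)
    return RatSeries(
        rat_id=f"rat{rat_index + 1:02d}", group=design.arm,
        times=times, activity=activity,
    )


def simulate_group(design: ExperimentDesign, truth: TruthModel):
    """Simulate all animals of an arm and pool them.

    Returns ``(rats, series)`` where ``series`` is the group
    :class:`RetentionSeries` normalized at the design's first sampling day.
    """
    rats = [simulate_rat(design, truth, i) for i in range(design.n_rats)]
    series = normalize_retention(rats, ref_time=design.ref_time)
    return rats, series


# ---------------------------------------------------------------------------
# encoded study designs and default truths


def experiment_designs() -> list[ExperimentDesign]:
    """The seven control/treated arms of the three experiments."""
    rapid = tuple(range(0, 11))
    delayed = tuple(range(13, 24))
    return [
        ExperimentDesign("exp1", "exp1_control", 0.0, (), rapid),
        ExperimentDesign("exp1", "exp1_low", LOW_DOSE, (PRE_DOSE_DAY,), rapid),
        ExperimentDesign("exp2", "exp2_control", 0.0, (), rapid),
        ExperimentDesign("exp2", "exp2_high", HIGH_DOSE, (PRE_DOSE_DAY,), rapid),
        ExperimentDesign(
            "exp2", "exp2_high_repeat", HIGH_DOSE, (PRE_DOSE_DAY, 1.0), rapid
        ),
        ExperimentDesign("exp3", "exp3_control", 0.0, (), delayed),
        ExperimentDesign(
            "exp3", "exp3_treated", HIGH_DOSE,
            (12.0, 13.0, 14.0, 15.0, 16.0), delayed,
        ),
    ]


def get_design(arm: str) -> ExperimentDesign:
    for d in experiment_designs():
        if d.arm == arm:
            return d
    raise ConfigError(f"unknown arm {arm!r}")


def _interp_rates(w: float) -> BiCompartmentParams:
    """Geometric interpolation between control and treated rate sets,
    weight w in [0, 1] toward the treated set (used for the low dose)."""
    c, t = control_rates(), TREATED_RATES
    geo = lambda a, b: float(a ** (1 - w) * b**w)  # noqa: E731
    return BiCompartmentParams(
        geo(c.k_bd, t.k_bd), geo(c.k_db, t.k_db), geo(c.k_e, t.k_e), 100.0
    )


def default_truth(arm: str, noise_sigma: float = 0.02, seed: int = 0) -> TruthModel:
    """Plausible generative truth per arm (kinetic rates anchored on the
    fitted rate constants; not experiment-certified ground truth).

    Control arms carry the untreated rate set observed as whole-body
    (blood + deep) retention.  Rapid treated arms carry the treated rate
    set observed as the blood-compartment solution, which is the form under
    which those rates reproduce the reported treated retention levels (see
    the methods note).  The delayed arm starts from untreated kinetics and
    boosts (k_e, k_db) during the five daily administrations (days 12-17).
    """
    controls = {"exp1_control", "exp2_control", "exp3_control"}
    if arm in controls:
        return TruthModel(control_rates(), observable="total",
                          noise_sigma=noise_sigma, seed=seed)
    if arm in ("exp2_high", "exp2_high_repeat"):
        return TruthModel(TREATED_RATES, observable="blood",
                          noise_sigma=noise_sigma, seed=seed)
    if arm == "exp1_low":
        return TruthModel(_interp_rates(LOW_DOSE / HIGH_DOSE), observable="blood",
                          noise_sigma=noise_sigma, seed=seed)
    if arm == "exp3_treated":
        c = control_rates()
        effect = TreatmentEffect(
            factor_ke=8.0,
            factor_kdb=TREATED_RATES.k_db / c.k_db,
            duration_days=1.0,
        )
        return TruthModel(c, observable="total", treatment_effect=effect,
                          noise_sigma=noise_sigma, seed=seed)
    raise ConfigError(f"unknown arm {arm!r}")


#: square-root-law truths: rapid-arm coefficients are the sqrt-law projection
#: of the treated blood curve over days 1-10; delayed coefficients are the
#: reported late-window (16-23 d) regression lines.
SQRT_TRUTHS = {
    "rapid_treated": SqrtLawParams(intercept=45.76, slope=8.86),
    "delayed_treated": SqrtLawParams(intercept=156.0, slope=19.4),
    "delayed_control": SqrtLawParams(intercept=176.0, slope=22.1),
}


def sqrt_truth(kind: str, noise_sigma: float = 0.02, seed: int = 0) -> TruthModel:
    """Square-root-law generative truth (see :data:`SQRT_TRUTHS`)."""
    if kind not in SQRT_TRUTHS:
        raise ConfigError(f"unknown sqrt truth {kind!r}; have {sorted(SQRT_TRUTHS)}")
    return TruthModel(SQRT_TRUTHS[kind], observable="total",
                      noise_sigma=noise_sigma, seed=seed)
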