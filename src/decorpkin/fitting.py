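"""Model fitting: nonlinear least squares over the model registry,
curve-stripping initialization, two-phase segmented log-linear regression,
and R-squared-based model comparison.

The central object is :class:`RetentionModel`, built from a
:class:`~decorpkin.data.RetentionSeries` plus a model identifier and fitting
window; its :meth:`~RetentionModel.fit` runs a bounded trust-region least
squares (optionally multi-started from jittered curve-stripping estimates)
and returns a :class:`FitResult` carrying the estimates, their standard
errors, residual diagnostics, derived half-lives and a ``summary()`` table.
The functional entry point :func:`fit_model` is a thin wrapper.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .data import RetentionSeries
from .exceptions import (
    DataValidationError,
    FitError,
    UndefinedRSquaredError,
)
from .kinetics import MacroBiexpParams
from .models import ModelSpec, get_model

#: multiplicative jitter scale (log-normal sigma) for multi-start points
MULTISTART_JITTER = 0.3


def r_squared(obs, pred) -> float:
    """Coefficient of determination 1 - SSE/SStot about the observed mean.

    May be negative when the model predicts worse than the mean.  Raises
    :class:`UndefinedRSquaredError` when the observations have zero variance.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise DataValidationError("obs and pred must share a length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedRSquaredError("observations have zero total variance")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


# ---------------------------------------------------------------------------
# curve stripping (method of residuals)


def strip_initialize_arrays(t, y, tail_points: int | None = None):
    """Curve-strip a biexponential initial guess from raw (t, y) arrays.

    The terminal phase (slow exponent ``beta`` and coefficient ``B``) comes
    from a log-linear fit of the tail; the fast phase from a log-linear fit
    of the early residuals y - B exp(-beta t).  Returns
    ``(MacroBiexpParams, info)`` where ``info['fallback']`` records whether
    non-positive residuals forced the heuristic alpha = 5 beta,
    A = y[0] - B.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 4:
        raise DataValidationError("curve stripping needs at least 4 points")
    if np.any(y <= 0):
        raise DataValidationError("curve stripping needs positive observations")
    if tail_points is None:
        tail_points = 4 if t.size >= 6 else 3
    tail_points = max(3, min(tail_points, t.size - 1))

    ts, ys = t[-tail_points:], y[-tail_points:]
    slope, intercept = np.polyfit(ts, np.log(ys), 1)
    beta = max(-slope, 1e-9)
    coeff_b = float(np.exp(intercept))

    head = slice(0, t.size - tail_points)
    tail_pred = coeff_b * np.exp(-beta * t[head])
    resid = y[head] - tail_pred
    info = {"fallback": False, "tail_points": tail_points}
    # strip only where the fast phase still carries signal; residuals that
    # are a tiny fraction of the terminal phase are dominated by the error
    # of the tail estimate, not by the fast exponential
    keep = resid > 0.01 * tail_pred
    if keep.sum() < 2:
        info["fallback"] = True
        alpha = 5.0 * beta
        coeff_a = max(y[0] - coeff_b, 0.05 * coeff_b)
    else:
        s2, i2 = np.polyfit(t[head][keep], np.log(resid[keep]), 1)
        alpha = max(-s2, 1e-9)
        coeff_a = float(np.exp(i2))
        if alpha <= beta:  # stripping failed to separate the phases
            info["fallback"] = True
            alpha = 5.0 * beta
            coeff_a = max(y[0] - coeff_b, 0.05 * coeff_b)
    return MacroBiexpParams(coeff_a, coeff_b, alpha, max(beta, 1e-9)), info


def strip_initialize(series: RetentionSeries, window):
    """Curve-stripping initializer on a retention series window."""
    mask = series.window_mask(window)
    return strip_initialize_arrays(series.times[mask], series.mean_retention[mask])


# ---------------------------------------------------------------------------
# results container


@dataclass
class FitResult:
    """Least-squares fit of one registered model on one window.

    ``params`` maps parameter names to estimates, ``stderr`` to asymptotic
    standard errors (NaN where the information matrix is singular),
    ``derived`` to model-specific quantities such as half-lives and
    eigenvalues.  ``sse``/``residuals``/``r2`` are unweighted; the weighted
    objective actually minimized is in ``metadata['weighted_sse']``.
    """

    model_id: str
    params: dict
    window: tuple
    r2: float
    sse: float
    residuals: np.ndarray
    derived: dict
    stderr: dict = field(default_factory=dict)
    n_obs: int = 0
    converged: bool = True
    metadata: dict = field(default_factory=dict)

    @property
    def theta(self) -> np.ndarray:
        return np.array(list(self.params.values()))

    def predict(self, t):
        spec = get_model(self.model_id)
        return spec.predict(self.theta, np.asarray(t, dtype=float),
                            **self.metadata.get("options", {}))

    def summary(self) -> str:
        buf = io.StringIO()
        w = self.window
        buf.write(f"Model: {self.model_id}   window: [{w[0]:g}, {w[1]:g}] d   "
                  f"n = {self.n_obs}\n")
        buf.write(f"R2 = {self.r2:.6f}   SSE = {self.sse:.6g}   "
                  f"converged = {self.converged}\n")
        buf.write(f"{'param':>14} {'estimate':>14} {'std err':>12}\n")
        for name, val in self.params.items():
            se = self.stderr.get(name, float('nan'))
            buf.write(f"{name:>14} {val:>14.6g} {se:>12.4g}\n")
        if self.derived:
            buf.write("derived: " + ", ".join(
                f"{k} = {v:.4g}" for k, v in self.derived.items()) + "\n")
        return buf.getvalue()

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "window": [float(self.window[0]), float(self.window[1])],
            "params": {k: float(v) for k, v in self.params.items()},
            "stderr": {k: float(v) for k, v in self.stderr.items()},
            "r2": float(self.r2),
            "sse": float(self.sse),
            "derived": {k: float(v) for k, v in self.derived.items()},
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "weights": self.metadata.get("weights", "none"),
            "options": self.metadata.get("options", {}),
        }


# ---------------------------------------------------------------------------
# the model object


class RetentionModel:
    """A registered retention model bound to data, ready to fit.

    Parameters
    ----------
    series : RetentionSeries
        Group-level retention data.
    model : str
        Registry identifier (``monoexp``, ``biexp_macro``, ``bicompartment``,
        ``sqrtlaw``, ``diffusion``).
    window : (float, float), optional
        Fitting window in days; defaults to the full observed range.
    weights : {"none", "inverse-sem"}
        ``inverse-sem`` minimizes sum((obs-pred)^2 / sem^2) (zero SEMs are
        floored at the smallest positive SEM); the default unweighted fit
        matches analyses performed directly on group means.
    options : dict, optional
        Model-specific options, e.g. ``{"observable": "blood"}`` for the
        two-compartment model.
    """

    def __init__(self, series: RetentionSeries, model: str, window=None,
                 weights: str = "none", options: dict | None = None):
        self.series = series
        self.spec: ModelSpec = get_model(model)
        if window is None:
            window = (float(series.times[0]), float(series.times[-1]))
        self.window = (float(window[0]), float(window[1]))
        mask = series.window_mask(self.window)
        self.t = series.times[mask]
        self.y = series.mean_retention[mask]
        self.sem = series.sem[mask]
        if weights not in ("none", "inverse-sem"):
            raise DataValidationError(f"unknown weights policy {weights!r}")
        self.weights = weights
        self.options = dict(options or {})
        if self.t.size < self.spec.n_params + 1:
            raise FitError(
                f"{self.spec.model_id}: window holds {self.t.size} points but "
                f"needs at least {self.spec.n_params + 1}"
            )
        if weights == "inverse-sem":
            sem = self.sem.copy()
            positive = sem[sem > 0]
            floor = positive.min() if positive.size else 1.0
            sem[sem <= 0] = floor
            self._sqrt_w = 1.0 / sem
        else:
            self._sqrt_w = np.ones_like(self.t)

    @classmethod
    def from_dataframe(cls, df, model: str, group: str | None = None, **kw):
        """Build from a ``group_level``-schema DataFrame (one group)."""
        from .data import GROUP_LEVEL_COLUMNS, RetentionSeries

        missing = [c for c in GROUP_LEVEL_COLUMNS if c not in df.columns]
        if missing:
            raise DataValidationError(f"dataframe lacks columns {missing}")
        if group is not None:
            df = df[df["group"] == group]
        times = df["time_day"].to_numpy(dtype=float)
        mean = df["mean_retention_pct"].to_numpy(dtype=float)
        iref = int(np.argmin(np.abs(mean - 100.0)))
        series = RetentionSeries(
            group=str(df["group"].iloc[0]), times=times, mean_retention=mean,
            sem=df["sem_pct"].to_numpy(dtype=float),
            n=df["n"].to_numpy(dtype=int), ref_time=float(times[iref]),
        )
        return cls(series, model, **kw)

    # -- fitting ------------------------------------------------------------

    def _residual(self, theta):
        pred = self.spec.predict(theta, self.t, **self.options)
        return self._sqrt_w * (pred - self.y)

    def fit(self, init=None, multistart: int = 5, seed: int = 0,
            max_nfev: int = 2000, xtol: float = 1e-12) -> FitResult:
        """Bounded trust-region least squares with multi-start.

        ``multistart`` jittered initializations (log-normal factors on the
        data-driven initial guess, seed-controlled) guard against local
        minima in the nonlinear models; the best SSE wins.
        """
        spec = self.spec
        if init is None:
            try:
                theta0 = np.asarray(spec.initial_guess(self.t, self.y), dtype=float)
            except Exception:
                theta0 = np.ones(spec.n_params)
        else:
            theta0 = np.asarray(init, dtype=float)
            if theta0.size != spec.n_params:
                raise FitError(
                    f"init has {theta0.size} values, model needs {spec.n_params}"
                )
        lo, hi = spec.lower, spec.upper
        theta0 = np.clip(theta0, np.where(lo == 0, 1e-9, lo), hi)

        rng = np.random.default_rng(seed)
        starts = [theta0]
        for _ in range(max(0, multistart - 1)):
            jitter = np.exp(rng.normal(0.0, MULTISTART_JITTER, theta0.size))
            starts.append(np.clip(theta0 * jitter,
                                  np.where(lo == 0, 1e-9, lo), hi))

        best = None
        n_ok = 0
        for start in starts:
            try:
                res = least_squares(
                    self._residual, start, bounds=(lo, hi), method="trf",
                    xtol=xtol, ftol=1e-12, gtol=1e-12, max_nfev=max_nfev,
                )
            except Exception:
                continue
            if not np.all(np.isfinite(res.x)):
                continue
            n_ok += 1
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise FitError(
                f"{spec.model_id}: no start converged",
                diagnostics={"starts": [list(map(float, s)) for s in starts]},
            )

        theta = best.x
        pred = spec.predict(theta, self.t, **self.options)
        residuals = self.y - pred
        sse = float(np.sum(residuals**2))
        try:
            r2 = r_squared(self.y, pred)
        except UndefinedRSquaredError:
            r2 = float("nan")

        stderr = self._stderr(best, theta)
        params = dict(zip(spec.param_names, map(float, theta)))
        return FitResult(
            model_id=spec.model_id,
            params=params,
            window=self.window,
            r2=r2,
            sse=sse,
            residuals=residuals,
            derived=spec.derived(theta, **self.options),
            stderr=dict(zip(spec.param_names, stderr)),
            n_obs=int(self.t.size),
            converged=bool(best.status > 0),
            metadata={
                "weights": self.weights,
                "options": self.options,
                "weighted_sse": float(2.0 * best.cost),
                "nfev": int(best.nfev),
                "n_starts_converged": n_ok,
                "multistart": multistart,
                "seed": seed,
                "init": list(map(float, theta0)),
                "status": int(best.status),
            },
        )

    def _stderr(self, res, theta):
        n, p = self.t.size, theta.size
        if n <= p:
            return [float("nan")] * p
        dof_var = 2.0 * res.cost / (n - p)
        jtj = res.jac.T @ res.jac
        try:
            cov = dof_var * np.linalg.pinv(jtj)
            return list(np.sqrt(np.clip(np.diag(cov), 0.0, np.inf)))
        except np.linalg.LinAlgError:
            return [float("nan")] * p


def fit_model(model_id: str, series: RetentionSeries, window=None, init=None,
              weights: str = "none", options: dict | None = None,
              multistart: int = 5, seed: int = 0) -> FitResult:
    """Fit one registered model to a retention series (functional wrapper
    around :class:`RetentionModel`)."""
    model = RetentionModel(series, model_id, window=window, weights=weights,
                           options=options)
    return model.fit(init=init, multistart=multistart, seed=seed)


# ---------------------------------------------------------------------------
# two-phase segmented log-linear regression


@dataclass(frozen=True)
class PhaseFit:
    """One log-linear phase: slope/intercept of ln(%retention) vs day."""

    slope: float
    intercept: float
    r2: float

    @property
    def half_life(self) -> float:
        """Apparent half-life -ln2/slope in days (inf for a flat phase)."""
        return float(np.log(2) / -self.slope) if self.slope < 0 else float("inf")


@dataclass
class SegmentedFit:
    """Two-phase segmented regression of log retention with a free breakpoint.

    The breakpoint is the inter-sample midpoint that minimizes the pooled
    SSE of the two independent (unconstrained, possibly discontinuous)
    log-linear segments.
    """

    breakpoint: float
    phase1: PhaseFit
    phase2: PhaseFit
    pooled_sse: float
    window: tuple
    candidates: np.ndarray = None

    def summary(self) -> str:
        lines = [
            f"Two-phase log-linear fit on [{self.window[0]:g}, {self.window[1]:g}] d",
            f"breakpoint = {self.breakpoint:g} d   pooled SSE (log) = "
            f"{self.pooled_sse:.6g}",
        ]
        for name, ph in (("phase 1", self.phase1), ("phase 2", self.phase2)):
            lines.append(
                f"{name}: slope = {ph.slope:+.5g} /d  intercept = "
                f"{ph.intercept:.5g}  R2 = {ph.r2:.5f}  t1/2 = {ph.half_life:.4g} d"
            )
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "breakpoint": float(self.breakpoint),
            "pooled_sse_log": float(self.pooled_sse),
            "window": [float(self.window[0]), float(self.window[1])],
            "phase1": {"slope": self.phase1.slope,
                       "intercept": self.phase1.intercept,
                       "r2": self.phase1.r2,
                       "half_life": self.phase1.half_life},
            "phase2": {"slope": self.phase2.slope,
                       "intercept": self.phase2.intercept,
                       "r2": self.phase2.r2,
                       "half_life": self.phase2.half_life},
        }


def _ols_phase(t, logy) -> tuple[PhaseFit, float]:
    slope, intercept = np.polyfit(t, logy, 1)
    pred = slope * t + intercept
    sse = float(np.sum((logy - pred) ** 2))
    try:
        r2 = r_squared(logy, pred)
    except UndefinedRSquaredError:
        r2 = 1.0 if sse < 1e-20 else float("nan")
    return PhaseFit(float(slope), float(intercept), r2), sse


def fit_two_phase(series: RetentionSeries, window=None,
                  min_points_per_phase: int = 2) -> SegmentedFit:
    """Exhaustive breakpoint search for a two-phase log-linear fit.

    Candidate breakpoints are the midpoints between consecutive sampling
    days that leave at least ``min_points_per_phase`` points on each side;
    each candidate gets two independent OLS fits to ln(mean retention) and
    the candidate with the smallest pooled SSE wins (ties resolved toward
    the earliest breakpoint).
    """
    if min_points_per_phase < 2:
        raise DataValidationError("min_points_per_phase must be >= 2")
    if window is None:
        window = (float(series.times[0]), float(series.times[-1]))
    mask = series.window_mask(window)
    t = series.times[mask]
    y = series.mean_retention[mask]
    if t.size < 2 * min_points_per_phase:
        raise DataValidationError(
            f"window holds {t.size} points; need >= {2 * min_points_per_phase}"
        )
    bad = np.flatnonzero(y <= 0)
    if bad.size:
        raise DataValidationError(
            f"non-positive retention at day {t[bad[0]]:g}; cannot take log"
        )
    logy = np.log(y)

    mids = 0.5 * (t[:-1] + t[1:])
    best = None
    cands = []
    for bp in mids:
        left = t < bp
        n_left = int(left.sum())
        if n_left < min_points_per_phase or t.size - n_left < min_points_per_phase:
            continue
        cands.append(bp)
        ph1, sse1 = _ols_phase(t[left], logy[left])
        ph2, sse2 = _ols_phase(t[~left], logy[~left])
        pooled = sse1 + sse2
        if best is None or pooled < best[0] - 1e-15:
            best = (pooled, bp, ph1, ph2)
    if best is None:
        raise DataValidationError("no admissible breakpoint candidates")
    pooled, bp, ph1, ph2 = best
    return SegmentedFit(
        breakpoint=float(bp), phase1=ph1, phase2=ph2, pooled_sse=pooled,
        window=(float(window[0]), float(window[1])),
        candidates=np.asarray(cands),
    )


# ---------------------------------------------------------------------------
# model comparison


@dataclass
class ModelComparison:
    """R2 contest between registered models on one identical window."""

    entries: list  # dicts: model_id, window, r2, sse, n_params
    ranking: list  # model ids, best first
    failures: dict = field(default_factory=dict)
    fits: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"{'rank':>4} {'model':>14} {'R2':>10} {'SSE':>12} {'k':>3}"]
        by_id = {e["model_id"]: e for e in self.entries}
        for i, mid in enumerate(self.ranking, 1):
            e = by_id[mid]
            lines.append(
                f"{i:>4} {mid:>14} {e['r2']:>10.5f} {e['sse']:>12.5g} "
                f"{e['n_params']:>3}"
            )
        for mid, msg in self.failures.items():
            lines.append(f"   - {mid:>14} FAILED: {msg}")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "entries": [
                {k: (float(v) if isinstance(v, (int, float, np.floating)) and
                     k in ("r2", "sse") else v)
                 for k, v in e.items() if k != "window"}
                for e in self.entries
            ],
            "ranking": list(self.ranking),
            "failures": {k: str(v) for k, v in self.failures.items()},
        }


def compare_models(series: RetentionSeries, model_ids, window=None,
                   weights: str = "none", options: dict | None = None,
                   seed: int = 0) -> ModelComparison:
    """Fit each model on the identical window/weights and rank by R2
    (descending); ties broken in favour of fewer parameters.  Individual fit
    failures yield a partial comparison with the failure recorded."""
    entries, failures, fits = [], {}, {}
    per_model_options = options or {}
    for mid in model_ids:
        spec = get_model(mid)  # unknown ids fail fast, before any fitting
        try:
            res = fit_model(
                mid, series, window=window, weights=weights,
                options=per_model_options.get(mid), seed=seed,
            )
        except Exception as exc:  # noqa: BLE001 - partial comparison by contract
            failures[mid] = str(exc)
            continue
        fits[mid] = res
        entries.append({
            "model_id": mid, "window": res.window, "r2": res.r2,
            "sse": res.sse, "n_params": spec.n_params,
        })
    ranking = [
        e["model_id"]
        for e in sorted(entries, key=lambda e: (-e["r2"], e["n_params"]))
    ]
    return ModelComparison(entries=entries, ranking=ranking,
                           failures=failures, fits=fits)
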