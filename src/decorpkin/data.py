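"""Domain containers and tabular I/O for whole-body retention data.

The unit of analysis throughout the package is the *retention series*: the
whole-body activity of a group of animals expressed as a percentage of the
activity at a reference (normalization) time, carried as mean +/- SEM across
animals at each measurement day.  Raw per-animal counts live in
:class:`RatSeries`; :func:`normalize_retention` turns a group of them into a
:class:`RetentionSeries`.

Two CSV schemas are supported (comma-separated, dot decimal, UTF-8, header
required):

* ``per_rat``:      ``group,rat_id,time_day,activity``
* ``group_level``:  ``group,time_day,mean_retention_pct,sem_pct,n``
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DataValidationError,
    DegenerateDesignError,
    SchemaError,
    TableParseError,
    WindowError,
)

PER_RAT_COLUMNS = ["group", "rat_id", "time_day", "activity"]
GROUP_LEVEL_COLUMNS = ["group", "time_day", "mean_retention_pct", "sem_pct", "n"]

#: times are matched to the reference time after rounding to this many decimals
TIME_DECIMALS = 6


@dataclass(frozen=True)
class RatSeries:
    """Raw whole-body activity of a single animal over time.

    Parameters
    ----------
    rat_id, group : str
        Animal and treatment-arm labels.
    times : array of float
        Measurement days, strictly increasing, non-negative.
    activity : array of float
        Whole-body activity (counts or MBq-equivalent), strictly positive.
    """

    rat_id: str
    group: str
    times: np.ndarray
    activity: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        activity = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "activity", activity)
        if times.ndim != 1 or times.size < 2:
            raise DataValidationError(
                f"rat {self.rat_id!r}: need at least 2 time points, got {times.size}"
            )
        if activity.shape != times.shape:
            raise DataValidationError(
                f"rat {self.rat_id!r}: times and activity lengths differ"
            )
        if np.any(times < 0):
            raise DataValidationError(f"rat {self.rat_id!r}: negative measurement time")
        if np.any(np.diff(times) <= 0):
            raise DataValidationError(
                f"rat {self.rat_id!r}: times must be strictly increasing"
            )
        if np.any(activity <= 0) or not np.all(np.isfinite(activity)):
            raise DataValidationError(
                f"rat {self.rat_id!r}: activity must be positive and finite"
            )


@dataclass(frozen=True)
class RetentionSeries:
    """Group-level percent retention vs time (mean +/- SEM over animals).

    ``mean_retention`` is 100 * activity(t) / activity(ref_time), averaged
    across animals; ``sem`` is the standard error of that mean (sample SD
    with n-1 denominator divided by sqrt(n)); ``n`` is the number of animals
    contributing at each time point.
    """

    group: str
    times: np.ndarray
    mean_retention: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    ref_time: float

    def __post_init__(self):
        for name in ("times", "mean_retention", "sem"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "n", np.asarray(self.n, dtype=int))
        if not (
            self.times.shape
            == self.mean_retention.shape
            == self.sem.shape
            == self.n.shape
        ):
            raise DataValidationError("times/mean/sem/n lengths disagree")
        if np.any(np.diff(self.times) <= 0):
            raise DataValidationError("times must be strictly increasing")
        if np.any(self.sem < 0):
            raise DataValidationError("sem must be non-negative")
        if np.any(self.n < 1):
            raise DataValidationError("n must be a positive integer")
        iref = self._ref_index()
        if not np.isclose(self.mean_retention[iref], 100.0, rtol=0, atol=1e-9):
            raise DataValidationError(
                f"mean retention at ref_time must be 100, got "
                f"{self.mean_retention[iref]!r}"
            )

    def _ref_index(self) -> int:
        match = np.flatnonzero(
            np.round(self.times, TIME_DECIMALS) == round(self.ref_time, TIME_DECIMALS)
        )
        if match.size != 1:
            raise DataValidationError(
                f"ref_time {self.ref_time} not among measurement times"
            )
        return int(match[0])

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask of points inside ``[t_start, t_end]`` (inclusive)."""
        t0, t1 = window
        if t1 <= t0:
            raise WindowError(f"empty window {window}")
        if t0 < self.times[0] - 1e-9 or t1 > self.times[-1] + 1e-9:
            raise WindowError(
                f"window {window} outside observed times "
                f"[{self.times[0]}, {self.times[-1]}]"
            )
        return (self.times >= t0 - 1e-9) & (self.times <= t1 + 1e-9)

    def retention_at(self, t: float) -> float:
        """Mean retention at day ``t`` (linear interpolation on the grid)."""
        if t < self.times[0] or t > self.times[-1]:
            raise WindowError(f"query time {t} outside observed times")
        return float(np.interp(t, self.times, self.mean_retention))


@dataclass(frozen=True)
class SummaryMetrics:
    """Model-free exposure summaries: AURC and retention at query times."""

    aurc: float
    retention_at: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.aurc < 0:
            raise DataValidationError("AURC must be non-negative")


@dataclass(frozen=True)
class DoseResponseFit:
    """Ordinary least-squares line of a summary metric against chelator dose."""

    slope: float
    intercept: float
    r2: float
    doses: np.ndarray

    def predict(self, dose):
        return self.slope * np.asarray(dose, dtype=float) + self.intercept


# ---------------------------------------------------------------------------
# delimited-text I/O


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def _to_float(df: pd.DataFrame, col: str, path) -> np.ndarray:
    try:
        return df[col].astype(float).to_numpy()
    except ValueError:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        # +2: header line plus 1-based numbering
        raise TableParseError(
            f"{path}: non-numeric value {df[col].iloc[bad]!r} in column "
            f"{col!r} at data row {bad + 2}",
            row=int(bad) + 2,
        ) from None


def read_retention_table(path, schema: str):
    """Read a retention table.

    Parameters
    ----------
    path : path-like
        CSV file with the declared header.
    schema : {"per_rat", "group_level"}
        ``per_rat`` returns a list of :class:`RatSeries` (one per
        group/rat_id pair, row order preserved within each animal);
        ``group_level`` returns a list of :class:`RetentionSeries`, taking
        the reference time as the time where the mean equals 100.
    """
    if schema == "per_rat":
        df = _read_csv(path, PER_RAT_COLUMNS)
        times = _to_float(df, "time_day", path)
        act = _to_float(df, "activity", path)
        out = []
        seen = []
        keys = list(zip(df["group"], df["rat_id"]))
        for key in keys:
            if key not in seen:
                seen.append(key)
        for group, rat_id in seen:
            sel = [i for i, k in enumerate(keys) if k == (group, rat_id)]
            out.append(
                RatSeries(
                    rat_id=str(rat_id),
                    group=str(group),
                    times=times[sel],
                    activity=act[sel],
                )
            )
        return out
    if schema == "group_level":
        df = _read_csv(path, GROUP_LEVEL_COLUMNS)
        out = []
        for group, sub in df.groupby("group", sort=False):
            times = _to_float(sub, "time_day", path)
            mean = _to_float(sub, "mean_retention_pct", path)
            sem = _to_float(sub, "sem_pct", path)
            n = _to_float(sub, "n", path).astype(int)
            at100 = np.flatnonzero(np.isclose(mean, 100.0, rtol=0, atol=1e-9))
            if at100.size == 0:
                raise DataValidationError(
                    f"{path}: group {group!r} has no 100% reference point"
                )
            out.append(
                RetentionSeries(
                    group=str(group),
                    times=times,
                    mean_retention=mean,
                    sem=sem,
                    n=n,
                    ref_time=float(times[at100[0]]),
                )
            )
        return out
    raise SchemaError(f"unknown schema {schema!r}")


def write_retention_table(path, records, schema: str) -> None:
    """Write :class:`RatSeries` or :class:`RetentionSeries` records to CSV."""
    rows = []
    if schema == "per_rat":
        for r in records:
            for t, a in zip(r.times, r.activity):
                rows.append((r.group, r.rat_id, repr(float(t)), repr(float(a))))
        df = pd.DataFrame(rows, columns=PER_RAT_COLUMNS)
    elif schema == "group_level":
        for s in records:
            for t, m, e, k in zip(s.times, s.mean_retention, s.sem, s.n):
                rows.append(
                    (s.group, repr(float(t)), repr(float(m)), repr(float(e)), int(k))
                )
        df = pd.DataFrame(rows, columns=GROUP_LEVEL_COLUMNS)
    else:
        raise SchemaError(f"unknown schema {schema!r}")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# normalization and summaries


def normalize_retention(raw, ref_time: float) -> RetentionSeries:
    """Normalize per-animal activities to a reference day and pool the group.

    Each animal's activity is converted to percent of its own activity at
    ``ref_time``; the group mean and SEM (sample SD / sqrt(n)) are then taken
    across animals at every measurement day.  The reference day is a
    parameter because delayed-intervention analyses renormalize mid-course
    (e.g. to day 12 or 13) rather than to the contamination day.
    """
    if not raw:
        raise DataValidationError("no rat series supplied")
    refkey = round(float(ref_time), TIME_DECIMALS)
    percent: dict[float, list[float]] = {}
    group = raw[0].group
    for rat in raw:
        keys = np.round(rat.times, TIME_DECIMALS)
        hit = np.flatnonzero(keys == refkey)
        if hit.size == 0:
            raise DataValidationError(
                f"rat {rat.rat_id!r} has no measurement at ref_time {ref_time}"
            )
        ref_act = rat.activity[hit[0]]
        for t, a in zip(keys, rat.activity):
            percent.setdefault(float(t), []).append(100.0 * a / ref_act)
    times = np.array(sorted(percent))
    mean = np.array([np.mean(percent[t]) for t in times])
    sem = np.array(
        [
            np.std(percent[t], ddof=1) / np.sqrt(len(percent[t]))
            if len(percent[t]) > 1
            else 0.0
            for t in times
        ]
    )
    n = np.array([len(percent[t]) for t in times])
    iref = int(np.flatnonzero(np.round(times, TIME_DECIMALS) == refkey)[0])
    # per-rat percent at the reference day is exactly 100; kill round-off
    mean[iref], sem[iref] = 100.0, 0.0
    return RetentionSeries(
        group=group, times=times, mean_retention=mean, sem=sem, n=n,
        ref_time=float(ref_time),
    )


def aurc(series: RetentionSeries, window: tuple[float, float]) -> float:
    """Area under the mean retention curve over ``window``, in percent*day.

    Uses the trapezoidal rule on the observed mean curve (model-free), with
    linear interpolation at window edges that fall between sampling days.
    """
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise WindowError(f"empty window {window}")
    if t0 < series.times[0] - 1e-9 or t1 > series.times[-1] + 1e-9:
        raise WindowError(f"window {window} outside observed times")
    inner = series.times[(series.times > t0) & (series.times < t1)]
    grid = np.concatenate(([t0], inner, [t1]))
    vals = np.interp(grid, series.times, series.mean_retention)
    if grid.size < 2:
        raise WindowError("need at least 2 points in window")
    return float(np.trapezoid(vals, grid))


def summarize(series: RetentionSeries, window, query_times=()) -> SummaryMetrics:
    """AURC over ``window`` plus retention at each query day."""
    return SummaryMetrics(
        aurc=aurc(series, window),
        retention_at={float(t): series.retention_at(t) for t in query_times},
    )


def dose_response(doses, metrics) -> DoseResponseFit:
    """OLS line of a summary metric (AURC or %retention) against dose.

    ``doses`` are in mg per 0.25 mL per 100 g body weight; the untreated
    control is encoded as dose 0.  Exactly collinear inputs are reproduced
    with r2 = 1; two points always give r2 = 1.
    """
    doses = np.asarray(doses, dtype=float)
    metrics = np.asarray(metrics, dtype=float)
    if doses.shape != metrics.shape or doses.size < 2:
        raise DataValidationError("need >= 2 (dose, metric) pairs of equal length")
    if np.unique(doses).size < 2:
        raise DegenerateDesignError("all doses identical; slope not identifiable")
    res = stats.linregress(doses, metrics)
    ss_tot = float(np.sum((metrics - metrics.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0  # horizontal line through identical metrics: exact fit
    else:
        pred = res.slope * doses + res.intercept
        r2 = 1.0 - float(np.sum((metrics - pred) ** 2)) / ss_tot
    return DoseResponseFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(np.clip(r2, 0.0, 1.0)), doses=doses,
    )
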