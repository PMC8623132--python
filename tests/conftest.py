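import numpy as np
import pytest

from decorpkin import (
    BiCompartmentParams,
    RatSeries,
    RetentionSeries,
    bicompartment_blood,
)

#: fitted high-dose rapid-intervention rate constants (day^-1)
TREATED = BiCompartmentParams(k_bd=1.77, k_db=1.21, k_e=0.19, c0=100.0)


@pytest.fixture
def treated_params():
    return TREATED


@pytest.fixture
def random_rate_sets():
    """Moderate log-uniform rate draws, repeated-eigenvalue cases excluded."""
    rng = np.random.default_rng(20240917)
    out = []
    while len(out) < 200:
        kbd, kdb, ke = np.exp(rng.uniform(np.log(0.02), np.log(3.0), 3))
        s, p = kbd + kdb + ke, kdb * ke
        if s * s - 4 * p > 1e-6 * s * s:
            out.append(BiCompartmentParams(kbd, kdb, ke, 100.0))
    return out


def make_series(times, values, group="g", sem=None, n=7, ref_index=0):
    """Build a RetentionSeries from raw mean values, normalizing so the
    reference point equals 100 exactly."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    values = values / values[ref_index] * 100.0
    if sem is None:
        sem = np.zeros_like(values)
    return RetentionSeries(
        group=group, times=times, mean_retention=values, sem=np.asarray(sem),
        n=np.full(times.size, n), ref_time=float(times[ref_index]),
    )


@pytest.fixture
def noiseless_treated_series(treated_params):
    """Blood-compartment retention of the treated rate set, days 0-10."""
    t = np.arange(0.0, 11.0)
    return make_series(t, bicompartment_blood(treated_params, t), group="treated")


@pytest.fixture
def simple_rats():
    return [
        RatSeries("r1", "g", [0.0, 1.0, 2.0], [500.0, 250.0, 125.0]),
        RatSeries("r2", "g", [0.0, 1.0, 2.0], [400.0, 210.0, 105.0]),
    ]
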