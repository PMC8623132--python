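"""Closed-form compartmental solutions, the ODE oracle, and parameter maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decorpkin import (
    BiCompartmentParams,
    MacroBiexpParams,
    MonoExpParams,
    bicompartment_blood,
    bicompartment_deep,
    bicompartment_total,
    eigenvalues,
    half_life,
    integrate_ode,
    macro_to_micro,
    micro_to_macro,
    mono_exp,
)
from decorpkin.exceptions import DomainError, RepeatedEigenvalueError

rates = st.floats(0.02, 3.0)


def distinct(kbd, kdb, ke):
    s, p = kbd + kdb + ke, kdb * ke
    return s * s - 4 * p > 1e-6 * s * s


class TestMonoExp:
    def test_basics(self):
        assert mono_exp(MonoExpParams(100.0, 0.0), 5.0) == pytest.approx(100.0)
        assert mono_exp(MonoExpParams(100.0, np.log(2)), 1.0) == pytest.approx(50.0)

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            mono_exp(MonoExpParams(100.0, 0.1), -1.0)

    def test_matches_decoupled_bicompartment(self):
        # with k_bd = 0 the blood compartment never feeds the deep pool:
        # C_b is exactly mono-exponential with rate k_e
        p = BiCompartmentParams(0.0, 1.21, 0.19, 100.0)
        t = np.linspace(0, 10, 23)
        np.testing.assert_allclose(
            bicompartment_blood(p, t),
            mono_exp(MonoExpParams(100.0, 0.19), t),
            rtol=1e-12,
        )


class TestClosedForms:
    def test_initial_conditions(self, treated_params):
        assert bicompartment_blood(treated_params, 0.0) == pytest.approx(100.0)
        assert bicompartment_deep(treated_params, 0.0) == pytest.approx(0.0)

    def test_decoupled_blood_value(self):
        p = BiCompartmentParams(0.0, 1.21, 0.19, 100.0)
        assert bicompartment_blood(p, 1.0) == pytest.approx(100 * np.exp(-0.19))
        np.testing.assert_allclose(
            bicompartment_deep(p, np.linspace(0, 5, 7)), 0.0, atol=1e-12
        )

    def test_treated_rates_match_ode_oracle(self, treated_params):
        t = np.array([0.0, 0.5, 1.0, 2.0, 5.0, 10.0])
        tr = integrate_ode(treated_params, t)
        np.testing.assert_allclose(
            bicompartment_blood(treated_params, t), tr["blood"],
            rtol=1e-9, atol=1e-9 * 100,
        )
        np.testing.assert_allclose(
            bicompartment_deep(treated_params, t), tr["deep"],
            rtol=1e-9, atol=1e-9 * 100,
        )

    def test_repeated_eigenvalue_confluent_branch(self):
        # k_bd = 0, k_db = k_e = 1 has a double root at lambda = 1
        p = BiCompartmentParams(0.0, 1.0, 1.0, 100.0)
        t = np.linspace(0, 5, 11)
        np.testing.assert_allclose(
            bicompartment_blood(p, t), 100 * np.exp(-t), rtol=1e-12
        )
        tr = integrate_ode(p, np.linspace(0, 5, 6))
        np.testing.assert_allclose(
            bicompartment_blood(p, np.linspace(0, 5, 6)), tr["blood"], rtol=1e-8
        )

    def test_negative_rates_rejected(self):
        with pytest.raises(DomainError):
            BiCompartmentParams(-0.1, 1.0, 0.2, 100.0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(kbd=rates, kdb=rates, ke=rates)
    def test_closed_forms_equal_ode(self, kbd, kdb, ke):
        if not distinct(kbd, kdb, ke):
            return
        p = BiCompartmentParams(kbd, kdb, ke, 100.0)
        t = np.linspace(0.0, 30.0, 7)
        tr = integrate_ode(p, t)
        np.testing.assert_allclose(
            bicompartment_blood(p, t), tr["blood"], rtol=1e-8, atol=1e-8 * 100
        )
        np.testing.assert_allclose(
            bicompartment_deep(p, t), tr["deep"], rtol=1e-8, atol=1e-8 * 100
        )

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(kbd=rates, kdb=rates, ke=rates)
    def test_mass_conservation(self, kbd, kdb, ke):
        p = BiCompartmentParams(kbd, kdb, ke, 100.0)
        t = np.linspace(0.0, 30.0, 7)
        tr = integrate_ode(p, t)
        total = tr["blood"] + tr["deep"] + tr["eliminated"]
        np.testing.assert_allclose(total, 100.0, rtol=1e-6)

    def test_deep_log_slope_tends_to_minus_beta(self, treated_params):
        # asymptotically log C_d decays with the slow eigenvalue beta
        _, beta = eigenvalues(treated_params)
        t = np.array([40.0, 41.0])
        cd = bicompartment_deep(treated_params, t)
        slope = np.diff(np.log(cd))[0]
        assert slope == pytest.approx(-beta, rel=1e-6)

    def test_degeneration_as_kbd_vanishes(self, treated_params):
        t = np.linspace(0.0, 10.0, 101)
        ref = 100.0 * np.exp(-treated_params.k_e * t)
        dists = []
        for kbd in (0.1, 0.01, 0.001):
            p = BiCompartmentParams(kbd, treated_params.k_db,
                                    treated_params.k_e, 100.0)
            dists.append(np.max(np.abs(bicompartment_blood(p, t) - ref)))
        assert dists[0] > dists[1] > dists[2]
        assert dists[2] < 0.1  # sup-norm in percent units


class TestOde:
    def test_zero_rates_constant(self):
        p = BiCompartmentParams(0.0, 0.0, 0.0, 100.0)
        tr = integrate_ode(p, np.linspace(0, 10, 5))
        np.testing.assert_allclose(tr["blood"], 100.0, rtol=1e-9)
        np.testing.assert_allclose(tr["deep"], 0.0, atol=1e-9)

    def test_bad_grid_rejected(self, treated_params):
        with pytest.raises(DomainError):
            integrate_ode(treated_params, [0.0, 0.0, 1.0])


class TestParameterMaps:
    def test_treated_rates_vieta(self, treated_params):
        alpha, beta = eigenvalues(treated_params)
        assert alpha + beta == pytest.approx(3.17, abs=1e-12)
        assert alpha * beta == pytest.approx(0.2299, abs=1e-12)

    def test_macro_coefficients_sum_to_c0(self, treated_params):
        m = micro_to_macro(treated_params)
        assert m.coeff_a + m.coeff_b == pytest.approx(100.0, rel=1e-12)
        total = m.coeff_a * np.exp(-m.alpha * 2.0) + m.coeff_b * np.exp(-m.beta * 2.0)
        assert total == pytest.approx(bicompartment_blood(treated_params, 2.0))

    def test_decoupled_macro_degeneration(self):
        m = micro_to_macro(BiCompartmentParams(0.0, 1.21, 0.19, 100.0))
        # the k_db eigenvalue carries zero amplitude; everything sits on k_e
        assert m.alpha == pytest.approx(1.21)
        assert m.beta == pytest.approx(0.19)
        assert m.coeff_a == pytest.approx(0.0, abs=1e-12)
        assert m.coeff_b == pytest.approx(100.0)

    def test_roundtrip_on_treated_rates(self, treated_params):
        back = macro_to_micro(micro_to_macro(treated_params))
        assert back.k_bd == pytest.approx(1.77, rel=1e-12)
        assert back.k_db == pytest.approx(1.21, rel=1e-12)
        assert back.k_e == pytest.approx(0.19, rel=1e-12)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(kbd=rates, kdb=rates, ke=rates)
    def test_roundtrip_identity_and_vieta(self, kbd, kdb, ke):
        if not distinct(kbd, kdb, ke):
            return
        p = BiCompartmentParams(kbd, kdb, ke, 100.0)
        m = micro_to_macro(p)
        assert m.alpha + m.beta == pytest.approx(kbd + kdb + ke, rel=1e-12)
        assert m.alpha * m.beta == pytest.approx(kdb * ke, rel=1e-12)
        back = macro_to_micro(m)
        assert back.k_bd == pytest.approx(kbd, rel=1e-9, abs=1e-10)
        assert back.k_db == pytest.approx(kdb, rel=1e-10)
        assert back.k_e == pytest.approx(ke, rel=1e-10)

    def test_macro_roundtrip_from_macro_side(self):
        m = MacroBiexpParams(62.0, 38.0, 3.1, 0.07)
        m2 = micro_to_macro(macro_to_micro(m))
        for attr in ("coeff_a", "coeff_b", "alpha", "beta"):
            assert getattr(m2, attr) == pytest.approx(getattr(m, attr), rel=1e-10)

    def test_repeated_roots_rejected(self):
        with pytest.raises(RepeatedEigenvalueError):
            micro_to_macro(BiCompartmentParams(0.0, 1.0, 1.0, 100.0))
        with pytest.raises((DomainError, RepeatedEigenvalueError)):
            macro_to_micro(MacroBiexpParams(50.0, 50.0, 1.0, 1.0))

    def test_nonpositive_macro_rejected(self):
        with pytest.raises(DomainError):
            macro_to_micro(MacroBiexpParams(-1.0, 50.0, 2.0, 1.0))


class TestHalfLife:
    def test_reference_elimination_half_life(self):
        assert half_life(0.19) == pytest.approx(3.648, abs=5e-4)

    def test_ln2_rate(self):
        assert half_life(np.log(2)) == pytest.approx(1.0)
        assert half_life(0.6931) == pytest.approx(1.0, abs=1e-4)

    def test_domain(self):
        with pytest.raises(DomainError):
            half_life(0.0)
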