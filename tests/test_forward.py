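"""Tests for the TRAST forward model: state evolution, pulse averaging,
volume averaging, and the full spatial-integration reference."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import trast as T
from trast.photophysics import effective_kox


class TestEvolveStates:
    def test_zero_generator_is_identity(self):
        p0 = np.array([0.3, 0.7])
        res = T.evolve_states(np.zeros((2, 2)), p0, [0.0, 1e-3, 1.0])
        np.testing.assert_allclose(res.populations, np.tile(p0, (3, 1)), atol=1e-12)

    def test_two_state_matches_exponential_relaxation(self, two_state):
        K = T.build_rate_matrix(two_state, 6.49e4)
        lam = two_state.kox_eff + two_state.rates.k_red
        s_eq = two_state.rates.k_red / lam
        t = np.geomspace(1e-7, 1e-2, 40)
        res = T.evolve_states(K, [1.0, 0.0], t)
        expected = s_eq + (1 - s_eq) * np.exp(-lam * t)
        np.testing.assert_allclose(res.S, expected, rtol=1e-9)

    @given(
        rates=st.tuples(*[st.floats(min_value=0, max_value=1e7) for _ in range(5)])
    )
    def test_probability_conserved(self, rates):
        k_isc, k_t, k_ox, k_red, k01 = rates
        model = T.StateModel(
            "four_state",
            T.RateConstants(k_isc=k_isc, k_t=k_t, k_ox=k_ox, k_red=k_red),
        )
        K = T.build_rate_matrix(model, k01)
        res = T.evolve_states(K, [0.25, 0.25, 0.25, 0.25], [1e-3])
        assert abs(res.populations[0].sum() - 1.0) < 1e-9

    def test_rejects_non_probability_initial(self):
        with pytest.raises(ValueError):
            T.evolve_states(np.zeros((2, 2)), [0.5, 0.2], [0.0])


class TestTrastPoint:
    def test_no_dark_state_flat(self, tyr_rates):
        model = T.StateModel("two_state", T.RateConstants(), kox_eff=0.0)
        w = np.geomspace(1e-7, 1e-2, 10)
        np.testing.assert_allclose(T.trast_point(model, 6.49e4, w), 1.0, atol=1e-12)

    def test_matches_closed_form_oracle(self, two_state):
        f = T.trast_point(two_state, 6.49e4, 126e-6, method="eig")
        assert f == pytest.approx(
            T.two_state_closed_form(two_state.kox_eff, 3.7e3, 126e-6), rel=1e-6
        )
        assert f == pytest.approx(0.8036, abs=1e-3)

    def test_short_pulse_limit(self, two_state):
        assert T.trast_point(two_state, 6.49e4, 1e-8) == pytest.approx(1.0, abs=1e-4)

    def test_oracle_equivalence_across_grid(self, two_state):
        w = np.geomspace(1e-7, 1e-2, 30)
        f_eig = T.trast_point(two_state, 6.49e4, w, method="eig")
        f_cf = T.two_state_closed_form(two_state.kox_eff, 3.7e3, w)
        np.testing.assert_allclose(f_eig, f_cf, rtol=1e-6)

    def test_four_state_short_pulse_normalization(self):
        # minor intersystem crossing, as appropriate for tyrosine where no
        # significant triplet build-up is observed
        model = T.StateModel(
            "four_state",
            T.RateConstants(k_isc=1e4, k_ox=19.2e6, k_red=3.7e3),
        )
        assert T.trast_point(model, 6.49e4, 1e-8) == pytest.approx(1.0, abs=1e-4)

    def test_zero_k01_rejected(self, two_state):
        with pytest.raises(ValueError):
            T.trast_point(two_state, 0.0, 1e-4)


class TestAverageExcitationRate:
    def test_top_hat_exact(self, tyr_rates, k01_peak):
        beam = T.BeamProfile(geometry="top_hat")
        kbar = T.average_excitation_rate(beam, tyr_rates, 10.3)
        assert kbar == pytest.approx(k01_peak, rel=1e-12)

    def test_low_saturation_two_thirds(self, tyr_rates, beam, k01_peak):
        """Radial Gaussian beam, equal CEF and excitation radii: the
        analytic ratio of Gaussian integrals gives k̄01 = (2/3)σΦ_peak."""
        kbar = T.average_excitation_rate(beam, tyr_rates, 10.3)
        assert kbar / k01_peak == pytest.approx(2.0 / 3.0, abs=1e-3)

    def test_saturation_behaviour(self, beam):
        """k̄01 grows monotonically with irradiance, while its ratio to
        σΦ_peak falls from 2/3 toward 1/2: saturation flattens the S̄1
        weighting so the Gaussian wings (lower flux) count more."""
        rates = T.RateConstants(sigma=4.47e-14)  # strong saturation reachable
        k01p_lo = T.excitation_rate(rates.sigma, T.photon_flux(1.0, 280.0))
        k01p_hi = T.excitation_rate(rates.sigma, T.photon_flux(1000.0, 280.0))
        kbar_lo = T.average_excitation_rate(beam, rates, 1.0)
        kbar_hi = T.average_excitation_rate(beam, rates, 1000.0)
        assert kbar_hi > kbar_lo
        assert 0.5 - 1e-2 < kbar_hi / k01p_hi < kbar_lo / k01p_lo <= 2.0 / 3.0

    def test_gaussian_3d_below_radial(self, tyr_rates, k01_peak):
        """Axial averaging dilutes the excitation further than radial-only."""
        b3 = T.BeamProfile(geometry="gaussian_3d")
        kbar3 = T.average_excitation_rate(b3, tyr_rates, 10.3)
        assert kbar3 < (2.0 / 3.0) * k01_peak


class TestTrastCurve:
    def test_flat_for_no_dark_states(self, beam):
        model = T.StateModel("two_state", T.RateConstants(), kox_eff=0.0)
        curve = T.trast_curve(
            model,
            T.ExcitationConditions(I_exc=10.3),
            beam,
            T.PulseScheme(w=1e-2),
            T.default_w_grid(10),
        )
        np.testing.assert_allclose(curve.f_norm, 1.0, atol=1e-12)

    def test_decay_window(self, tyr_rates, beam):
        """The half-decay pulse width lies in the 50–500 µs window for the
        study-scale rates (overall decay starting around 100 µs)."""
        kbar = T.average_excitation_rate(beam, tyr_rates, 10.3)
        model = T.StateModel(
            "two_state", tyr_rates,
            kox_eff=effective_kox(tyr_rates.k_ox, kbar, tyr_rates.k10),
        )
        w = np.geomspace(1e-6, 1e-3, 200)
        curve = T.trast_curve(
            model, T.ExcitationConditions(I_exc=10.3), beam,
            T.PulseScheme(w=1e-3), w,
        )
        half_depth = (1.0 - curve.f_norm[-1]) / 2.0
        w_half = w[np.argmin(np.abs((1.0 - curve.f_norm) - half_depth))]
        assert 50e-6 < w_half < 500e-6

    def test_doubling_k_red_raises_curve(self, tyr_rates, beam):
        kbar = T.average_excitation_rate(beam, tyr_rates, 10.3)
        kox_eff = effective_kox(tyr_rates.k_ox, kbar, tyr_rates.k10)
        w = np.geomspace(1e-6, 1e-2, 10)
        cond = T.ExcitationConditions(I_exc=10.3)
        scheme = T.PulseScheme(w=1e-2)
        lo = T.trast_curve(
            T.StateModel("two_state", tyr_rates, kox_eff=kox_eff),
            cond, beam, scheme, w,
        )
        hi = T.trast_curve(
            T.StateModel(
                "two_state", tyr_rates.__class__(
                    k_ox=tyr_rates.k_ox, k_red=2 * tyr_rates.k_red,
                    sigma=tyr_rates.sigma, k10=tyr_rates.k10,
                ),
                kox_eff=kox_eff,
            ),
            cond, beam, scheme, w,
        )
        assert np.all(hi.f_norm > lo.f_norm)

    def test_duty_cycle_warning(self, two_state, beam):
        with pytest.warns(UserWarning, match="duty cycle"):
            T.trast_curve(
                two_state, T.ExcitationConditions(I_exc=10.3), beam,
                T.PulseScheme(w=1e-2, eta=0.1), T.default_w_grid(5),
            )

    def test_w_range_enforced(self, two_state, beam):
        with pytest.raises(ValueError):
            T.trast_curve(
                two_state, T.ExcitationConditions(I_exc=10.3), beam,
                T.PulseScheme(w=1.0), np.array([1e-3, 1.0]),
            )


class TestFullVolume:
    def test_top_hat_equals_point(self, two_state, k01_peak):
        beam = T.BeamProfile(geometry="top_hat")
        full = T.full_volume_trast(two_state, beam, 10.3, 126e-6)
        assert full == T.trast_point(two_state, k01_peak, 126e-6)

    def test_no_dark_state_unity(self, beam):
        model = T.StateModel("two_state", T.RateConstants(), kox_eff=0.0)
        assert T.full_volume_trast(model, beam, 10.3, 1e-4) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_grid_refinement_converged(self, two_state, beam):
        f1 = T.full_volume_trast(two_state, beam, 10.3, 126e-6, n_radial=129)
        f2 = T.full_volume_trast(two_state, beam, 10.3, 126e-6, n_radial=257)
        assert abs(f1 / f2 - 1.0) < 1e-4

    def test_volume_average_approximation_error(self, tyr_rates, beam, k01_peak):
        """The single-k̄01 approximation stays within 5% of the curve
        amplitude of the full spatial integral at 10.3 kW/cm²."""
        kbar = T.average_excitation_rate(beam, tyr_rates, 10.3)
        m_bar = T.StateModel(
            "two_state", tyr_rates,
            kox_eff=effective_kox(tyr_rates.k_ox, kbar, tyr_rates.k10),
        )
        m_peak = T.StateModel(
            "two_state", tyr_rates,
            kox_eff=effective_kox(tyr_rates.k_ox, k01_peak, tyr_rates.k10),
        )
        w = np.geomspace(1e-7, 1e-2, 12)
        f_approx = T.trast_point(m_bar, kbar, w)
        f_full = np.array(
            [T.full_volume_trast(m_peak, beam, 10.3, wi) for wi in w]
        )
        amplitude = 1.0 - f_approx.min()
        assert np.max(np.abs(f_full - f_approx)) < 0.05 * amplitude


class TestCurveContainer:
    def test_non_ascending_w_rejected(self):
        with pytest.raises(ValueError):
            T.TrastCurve(
                w_values=[1e-4, 1e-5], f_norm=[0.9, 0.8], sem=[0.01, 0.01]
            )

    def test_gross_overshoot_rejected(self):
        with pytest.raises(ValueError):
            T.TrastCurve(
                w_values=[1e-5, 1e-4], f_norm=[1.5, 0.8], sem=[0.01, 0.01]
            )

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            T.PulseScheme(w=1e-3, eta=0.0)
        with pytest.raises(ValueError):
            T.PulseScheme(w=1e-3, w0=2e-3)
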