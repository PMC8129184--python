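"""Ogden-QLV material engine: closed forms, spectra, fits and histories."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from braincal.constitutive import (
    BRAIN_PRONY,
    MaterialCard,
    OgdenParams,
    PronyFitError,
    PronySeries,
    complex_modulus,
    fit_prony,
    infinitesimal_shear_modulus,
    instantaneous_stress,
    mu_from_infinitesimal,
    qlv_stress_history,
    reduced_relaxation,
    single_element_curves,
    tan_delta,
)


class TestInfinitesimalModulus:
    @pytest.mark.parametrize(
        "mu,alpha,mu0",
        [
            (0.337, 6.67, 1.124),   # calibrated median card, to rounding
            (1.0, 2.0, 1.0),        # Neo-Hookean: mu0 = mu
            (0.179, 6.67, 0.597),   # softest card
        ],
    )
    def test_examples(self, mu, alpha, mu0):
        assert infinitesimal_shear_modulus(OgdenParams(mu, alpha)) == pytest.approx(
            mu0, abs=5e-4
        )

    def test_inverse_round_trip(self):
        for mu0, alpha in [(1.125, 6.67), (0.3, 2.0), (2.0, 4.0)]:
            mu = mu_from_infinitesimal(mu0, alpha)
            assert infinitesimal_shear_modulus(OgdenParams(mu, alpha)) == pytest.approx(
                mu0, rel=1e-12
            )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            OgdenParams(mu=-1.0, alpha=2.0)
        with pytest.raises(ValueError):
            OgdenParams(mu=1.0, alpha=0.0)


class TestInstantaneousStress:
    @pytest.mark.parametrize("mode", ["tension", "compression", "simple_shear"])
    def test_undeformed_state_is_stress_free(self, mode):
        assert instantaneous_stress(mode, 0.0, OgdenParams(1.0, 6.67)) == 0.0

    def test_tension_neo_hookean_closed_form(self):
        # lam = 1.5: T = mu (lam - lam^-2) = 1.5 - 1/2.25
        got = instantaneous_stress("tension", 0.5, OgdenParams(1.0, 2.0))
        assert got == pytest.approx(1.5 - 1.5**-2, abs=1e-12)
        assert got == pytest.approx(1.0556, abs=1e-4)

    def test_neo_hookean_closed_forms_all_modes(self):
        mu = 0.8
        og = OgdenParams(mu, 2.0)
        eps = np.array([0.05, 0.2, 0.45])
        lam = 1 + eps
        np.testing.assert_allclose(
            instantaneous_stress("tension", eps, og), mu * (lam - lam**-2), atol=1e-10
        )
        lam = 1 - eps
        np.testing.assert_allclose(
            instantaneous_stress("compression", eps, og), mu * (lam - lam**-2), atol=1e-10
        )
        # Neo-Hookean simple shear: tau = mu * gamma
        np.testing.assert_allclose(
            instantaneous_stress("simple_shear", eps, og), mu * eps, atol=1e-10
        )

    def test_tension_matches_energy_derivative(self):
        # Central difference of W(lam, lam^-1/2, lam^-1/2) in lam.
        og = OgdenParams(0.337, 6.67)

        def W(lam):
            s = lam**og.alpha + 2.0 * lam ** (-og.alpha / 2.0) - 3.0
            return og.mu / og.alpha * s

        lam = 1.3
        h = 1e-6
        num = (W(lam + h) - W(lam - h)) / (2 * h)
        assert instantaneous_stress("tension", lam - 1.0, og) == pytest.approx(
            num, rel=1e-7
        )

    def test_shear_small_strain_slope_is_mu0(self):
        og = OgdenParams(0.337, 6.67)
        g = 1e-7
        slope = instantaneous_stress("simple_shear", g, og) / g
        assert slope == pytest.approx(infinitesimal_shear_modulus(og), rel=1e-5)

    def test_overcompression_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_stress("tension", -1.0, OgdenParams(1.0, 2.0))
        with pytest.raises(ValueError):
            instantaneous_stress("compression", 1.0, OgdenParams(1.0, 2.0))


class TestPronySeries:
    def test_table_normalization(self):
        # g_inf follows from the sum-to-one constraint on the four g_i.
        assert BRAIN_PRONY.g_inf == pytest.approx(0.0337, abs=1e-12)

    def test_invalid_spectra_rejected(self):
        with pytest.raises(ValueError):
            PronySeries(g=(0.5,), tau=(1.0,), g_inf=0.6)  # sums to 1.1
        with pytest.raises(ValueError):
            PronySeries(g=(-0.1,), tau=(1.0,), g_inf=1.1)
        with pytest.raises(ValueError):
            PronySeries(g=(0.5,), tau=(-1.0,), g_inf=0.5)

    def test_relaxation_normalized_at_zero(self):
        assert reduced_relaxation(0.0, BRAIN_PRONY) == pytest.approx(1.0, abs=1e-12)

    def test_relaxation_long_term_limit(self):
        assert reduced_relaxation(1e9, BRAIN_PRONY) == pytest.approx(0.0337, abs=1e-9)

    def test_relaxation_monotone_non_increasing(self):
        t = np.logspace(-3, 3, 200)
        g = reduced_relaxation(t, BRAIN_PRONY)
        assert np.all(np.diff(g) <= 1e-15)
        assert np.all((g > 0) & (g <= 1))

    def test_relaxation_at_10ms_direct_sum(self):
        expect = 0.0337 + sum(
            g * np.exp(-10.0 / t) for g, t in zip(BRAIN_PRONY.g, BRAIN_PRONY.tau)
        )
        assert reduced_relaxation(10.0, BRAIN_PRONY) == pytest.approx(expect, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            reduced_relaxation(-1.0, BRAIN_PRONY)


class TestComplexModulus:
    def test_static_limit_quasi_static_reference(self):
        og = OgdenParams(0.337, 6.67)
        sp, lo = complex_modulus(1e-9, og, BRAIN_PRONY, "quasi_static")
        assert sp == pytest.approx(infinitesimal_shear_modulus(og), rel=1e-5)
        assert lo == pytest.approx(0.0, abs=1e-6)

    def test_single_term_at_unit_omega_tau(self):
        p = PronySeries.from_g((0.6,), (1.0,))
        f = 1.0 / (2 * np.pi * 1e-3)  # omega*tau = 1
        sp, lo = complex_modulus(f, OgdenParams(2.0, 1.0), p, "instantaneous")
        mu0 = 1.0
        assert sp == pytest.approx(mu0 * (0.4 + 0.3), rel=1e-9)
        assert lo == pytest.approx(mu0 * 0.3, rel=1e-9)

    def test_stiffness_scaling_leaves_tan_delta_unchanged(self):
        rng = np.random.default_rng(0)
        freqs = np.logspace(0, 3, 7)
        for _ in range(10):
            g = rng.dirichlet(np.ones(4)) * rng.uniform(0.5, 0.99)
            p = PronySeries.from_g(g, (10.0, 1.0, 0.1, 0.01))
            base = None
            for c in (0.5, 1.0, 7.3):
                og = OgdenParams(0.337 * c, 6.67)
                sp, lo = complex_modulus(freqs, og, p)
                td = lo / sp
                if base is None:
                    base = td
                np.testing.assert_allclose(td, base, rtol=1e-12)
                np.testing.assert_allclose(td, tan_delta(freqs, p), rtol=1e-12)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            tan_delta(0.0, BRAIN_PRONY)


class TestTanDelta:
    def test_elastic_limits_vanish(self):
        assert tan_delta(1e-9, BRAIN_PRONY) < 1e-6
        assert tan_delta(1e12, BRAIN_PRONY) < 1e-6

    def test_single_term_peak_location(self):
        # d(tan delta)/ds = 0 at s = sqrt(g_inf / (g_inf + g1)).
        g1, g_inf = 0.7, 0.3
        p = PronySeries.from_g((g1,), (1.0,))
        s = np.logspace(-3, 3, 200001)
        f = s / (2 * np.pi * 1e-3)
        td = tan_delta(f, p)
        s_peak = s[np.argmax(td)]
        assert s_peak == pytest.approx(np.sqrt(g_inf / (g_inf + g1)), rel=1e-3)


class TestFitProny:
    def test_round_trip_brain_spectrum(self):
        freqs = np.logspace(0, 5, 30)
        data = np.column_stack([freqs, tan_delta(freqs, BRAIN_PRONY)])
        fit = fit_prony(data)
        np.testing.assert_allclose(fit.g, BRAIN_PRONY.g, atol=1e-3)
        assert fit.g_inf == pytest.approx(BRAIN_PRONY.g_inf, abs=1e-3)

    def test_zero_damping_gives_elastic_material(self):
        freqs = np.logspace(0, 4, 20)
        fit = fit_prony(np.column_stack([freqs, np.zeros(20)]))
        assert fit.g_inf == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(fit.g, 0.0, atol=1e-8)

    def test_single_term_exact_recovery(self):
        p = PronySeries.from_g((0.55,), (1.0,))
        freqs = np.logspace(0, 4, 15)
        fit = fit_prony(
            np.column_stack([freqs, tan_delta(freqs, p)]), n_terms=1, tau_grid=(1.0,)
        )
        assert fit.g[0] == pytest.approx(0.55, abs=1e-6)

    def test_insufficient_data_rejected(self):
        with pytest.raises(PronyFitError):
            fit_prony([(1.0, 0.1), (10.0, 0.2)], n_terms=4)
        with pytest.raises(PronyFitError):
            fit_prony([])


class TestQlvHistory:
    def card(self, prony, reference="instantaneous", alpha=2.0, mu=1.0):
        return MaterialCard(OgdenParams(mu, alpha), prony, reference=reference)

    def test_step_strain_relaxes_like_g(self):
        p = PronySeries.from_g((0.6,), (50.0,))
        card = self.card(p)
        dt = 0.01
        n = 20000
        eps = np.full(n, 0.2)
        eps[0] = 0.0
        sigma = qlv_stress_history(eps, "simple_shear", card, dt)
        te = instantaneous_stress("simple_shear", 0.2, card.ogden)
        t = dt * np.arange(n)
        expect = reduced_relaxation(np.maximum(t - dt / 2, 0), p) * te
        np.testing.assert_allclose(sigma[10:], expect[10:], rtol=2e-3)

    def test_step_relaxation_ratio_is_g_inf(self):
        p = PronySeries.from_g((0.6,), (5.0,))
        card = self.card(p)
        eps = np.full(5000, 0.3)
        eps[0] = 0.0
        sigma = qlv_stress_history(eps, "tension", card, dt=0.05)
        assert sigma[-1] / sigma[1] == pytest.approx(p.g_inf, rel=1e-2)

    def test_quasi_static_reference_relaxes_to_static_curve(self):
        p = PronySeries.from_g((0.6,), (5.0,))
        card = self.card(p, reference="quasi_static")
        eps = np.full(5000, 0.3)
        eps[0] = 0.0
        sigma = qlv_stress_history(eps, "tension", card, dt=0.05)
        assert sigma[-1] == pytest.approx(
            instantaneous_stress("tension", 0.3, card.ogden), rel=1e-2
        )

    def test_elastic_limit_without_prony_terms(self):
        p = PronySeries.from_g((), ())
        card = self.card(p)
        t = np.linspace(0, 10, 300)
        eps = 0.04 * t
        sigma = qlv_stress_history(eps, "simple_shear", card, dt=t[1] - t[0])
        np.testing.assert_allclose(
            sigma, instantaneous_stress("simple_shear", eps, card.ogden), rtol=1e-12
        )

    def test_ramp_matches_convolution_oracle(self):
        # Trapezoid-rule convolution of g(t-s) dT/ds at 10x finer sampling.
        p = PronySeries.from_g((0.5,), (3.0,))
        card = self.card(p, alpha=2.0)
        dt = 0.05
        t = np.arange(0, 20 + dt / 2, dt)
        eps = 0.02 * t
        sigma = qlv_stress_history(eps, "simple_shear", card, dt)

        fine = dt / 10
        tf = np.arange(0, 20 + fine / 2, fine)
        te = instantaneous_stress("simple_shear", 0.02 * tf, card.ogden)
        dte = np.gradient(te, fine)
        oracle = np.empty_like(t)
        for k, tk in enumerate(t):
            m = tf <= tk + 1e-12
            kernel = reduced_relaxation(tk - tf[m], p)
            oracle[k] = np.trapezoid(kernel * dte[m], dx=fine)
        np.testing.assert_allclose(sigma[1:], oracle[1:], rtol=5e-3)

    def test_halving_dt_converges(self):
        card = self.card(BRAIN_PRONY, alpha=6.67, mu=0.337)
        t_end = 50.0
        for dt in (0.05,):
            n1 = int(t_end / dt)
            e1 = 0.01 * dt * np.arange(n1 + 1)
            s1 = qlv_stress_history(e1, "tension", card, dt)
            n2 = 2 * n1
            e2 = 0.01 * (dt / 2) * np.arange(n2 + 1)
            s2 = qlv_stress_history(e2, "tension", card, dt / 2)
            assert abs(s1[-1] - s2[-1]) / abs(s2[-1]) < 5e-3

    def test_nonzero_start_rejected(self):
        card = self.card(BRAIN_PRONY)
        with pytest.raises(ValueError):
            qlv_stress_history(np.array([0.1, 0.2]), "tension", card, 0.1)


class TestSingleElementCurves:
    def card(self, mu0=1.125, alpha=6.67):
        from braincal.constitutive import mu_from_infinitesimal

        return MaterialCard(
            OgdenParams(mu_from_infinitesimal(mu0, alpha), alpha), BRAIN_PRONY
        )

    @pytest.mark.parametrize("mode", ["tension", "compression", "simple_shear"])
    def test_faster_loading_is_stiffer(self, mode):
        card = self.card()
        e_slow, s_slow = single_element_curves(card, mode, rate=0.5)
        e_fast, s_fast = single_element_curves(card, mode, rate=30.0)
        np.testing.assert_allclose(e_slow, e_fast)
        mag_slow, mag_fast = np.abs(s_slow), np.abs(s_fast)
        assert np.all(mag_fast >= mag_slow - 1e-12)

    def test_curves_scale_linearly_with_mu(self):
        c1 = self.card(mu0=1.125)
        c2 = self.card(mu0=1.125 * 1.53)
        _, s1 = single_element_curves(c1, "simple_shear", rate=5.0)
        _, s2 = single_element_curves(c2, "simple_shear", rate=5.0)
        np.testing.assert_allclose(s2, 1.53 * s1, rtol=1e-12)

    def test_slow_limit_recovers_static_ogden(self):
        card = self.card()
        eps, sigma = single_element_curves(card, "tension", rate=1e-4)
        static = instantaneous_stress("tension", eps, card.ogden)
        # skip the start-up transient where the ramp has just begun
        np.testing.assert_allclose(sigma[5:], static[5:], rtol=1e-2)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    g1=st.floats(0.05, 0.9),
    tau=st.floats(0.1, 50.0),
    t=st.floats(0.0, 200.0),
)
def test_relaxation_bounded_and_normalized(g1, tau, t):
    p = PronySeries.from_g((g1,), (tau,))
    g = reduced_relaxation(t, p)
    assert p.g_inf - 1e-12 <= g <= 1.0 + 1e-12
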