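"""Catastrophe-time law, load rescaling, and per-filament update rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from mtpush.mt_dynamics import (
    CatastropheModel,
    MicrotubuleState,
    Phase,
    Side,
    catastrophe_probability,
    gamma_catastrophe_pdf,
    inverse_hazard,
    rescale_catastrophe_time,
    sample_catastrophe_ages_hazard,
    step_microtubule,
    truncated_pdf,
)


def _oracle_gamma_density(t, n, ts):
    """Independent evaluation of the gamma density: Gamma(n) by quadrature."""
    gamma_n, _ = integrate.quad(lambda u: u ** (n - 1) * math.exp(-u), 0, np.inf)
    return t ** (n - 1) * math.exp(-t / ts) / (ts**n * gamma_n)


class TestGammaPdf:
    def test_exponential_limit_at_origin(self):
        model = CatastropheModel(1.0, 35.0, tau0=25.0)
        assert gamma_catastrophe_pdf(0.0, model) == pytest.approx(1.0 / 35.0)

    @pytest.mark.parametrize("n,ts", [(1.0, 35.0), (2.0, 10.0), (3.6, 35.0)])
    def test_normalization(self, n, ts):
        model = CatastropheModel(n, ts, tau0=0.5)
        total, _ = integrate.quad(lambda t: gamma_catastrophe_pdf(t, model), 0, 50 * n * ts)
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("t", [2.0, 10.0, 50.0])
    def test_matches_quadrature_oracle(self, t):
        model = CatastropheModel(2.0, 10.0, tau0=5.0)
        assert gamma_catastrophe_pdf(t, model) == pytest.approx(
            _oracle_gamma_density(t, 2.0, 10.0), rel=1e-9
        )

    def test_rejects_negative_and_nonfinite_times(self, mal3_model):
        with pytest.raises(ValueError):
            gamma_catastrophe_pdf(-1.0, mal3_model)
        with pytest.raises(ValueError):
            gamma_catastrophe_pdf(np.nan, mal3_model)


class TestTruncatedPdf:
    def test_infinite_window_is_identity(self, mal3_model):
        t = np.linspace(0.5, 400, 64)
        np.testing.assert_allclose(
            truncated_pdf(t, mal3_model, 0.0, np.inf),
            gamma_catastrophe_pdf(t, mal3_model),
            rtol=1e-12,
        )

    def test_matches_renormalization_oracle(self, mal3_model):
        lo, hi = 40.0, 300.0
        mass, _ = integrate.quad(lambda t: gamma_catastrophe_pdf(t, mal3_model), lo, hi)
        for t in (50.0, 100.0, 250.0):
            assert truncated_pdf(t, mal3_model, lo, hi) == pytest.approx(
                gamma_catastrophe_pdf(t, mal3_model) / mass, rel=1e-8
            )
        assert truncated_pdf(10.0, mal3_model, lo, hi) == 0.0
        assert truncated_pdf(350.0, mal3_model, lo, hi) == 0.0

    def test_window_mass_is_one(self, mal3_model):
        total, _ = integrate.quad(lambda t: truncated_pdf(t, mal3_model, 40, 300), 40, 300)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_support_raises(self):
        model = CatastropheModel(3.6, 35.0, tau0=25.0)
        with pytest.raises(ValueError, match="degenerate"):
            truncated_pdf(5000.0, model, 4000.0, 5000.0)


class TestInverseHazard:
    def test_exponential_is_memoryless(self):
        model = CatastropheModel(1.0, 35.0, tau0=25.0)
        for age in (0.0, 10.0, 500.0, 5000.0):
            assert inverse_hazard(age, model) == pytest.approx(35.0, rel=1e-9)

    def test_zero_hazard_at_origin_for_shaped_model(self):
        assert inverse_hazard(0.0, CatastropheModel(2.0, 10.0, tau0=5.0)) == math.inf

    def test_matches_quadrature_oracle(self, mal3_model):
        dens = lambda t: _oracle_gamma_density(t, 3.6, 35.0)
        surv, _ = integrate.quad(dens, 100.0, np.inf)
        assert inverse_hazard(100.0, mal3_model) == pytest.approx(surv / dens(100.0), rel=1e-6)

    def test_no_underflow_at_large_age(self, mal3_model):
        val = inverse_hazard(5000.0, mal3_model)
        assert np.isfinite(val) and val > 0


class TestCatastropheProbability:
    def test_vanishes_as_dt_shrinks(self, mal3_model):
        assert catastrophe_probability(50.0, 1e-9, mal3_model) < 1e-9

    def test_exponential_closed_form(self):
        model = CatastropheModel(1.0, 35.0, tau0=25.0)
        assert catastrophe_probability(123.0, 0.1, model) == pytest.approx(
            1.0 - math.exp(-0.1 / 35.0)
        )

    @given(
        dt=st.floats(0.01, 10.0),
        load=st.floats(1.0, 5.0),
        age=st.floats(0.0, 500.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_probability_bounds_and_monotonicity(self, dt, load, age):
        model = CatastropheModel(3.6, 35.0, 25.0)
        p = catastrophe_probability(age, dt, model, load)
        assert 0.0 <= p <= 1.0
        assert catastrophe_probability(age, 2 * dt, model, load) >= p
        assert catastrophe_probability(age, dt, model, load + 1.0) >= p


class TestRescaling:
    def test_free_growth_identity(self, mal3_model):
        assert rescale_catastrophe_time(100.0, mal3_model, 1.0) == 100.0

    def test_printed_arithmetic(self, mal3_model):
        assert rescale_catastrophe_time(125.0, mal3_model, 0.5) == pytest.approx(75.0)

    def test_stall_limit(self, mal3_model):
        assert rescale_catastrophe_time(125.0, mal3_model, 1e-12) == pytest.approx(25.0, abs=1e-6)

    def test_small_draws_clamped_to_tau0(self, mal3_model):
        assert rescale_catastrophe_time(10.0, mal3_model, 0.5) == 25.0

    @given(tau=st.floats(26.0, 1000.0), v_ratio=st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, tau, v_ratio):
        model = CatastropheModel(3.6, 35.0, 25.0)
        out = rescale_catastrophe_time(tau, model, v_ratio)
        assert model.tau0 <= out <= tau


class TestStepMicrotubule:
    def test_free_growth_arithmetic(self, kinetics, rng):
        mt = MicrotubuleState(0.0, 0.0, Side.RIGHT, length=1.0, drawn_tau=500.0)
        out = step_microtubule(mt, 0.1, False, kinetics, rng)
        assert out.length == pytest.approx(1.0 + 0.05 * 0.1)
        assert out.cat_clock == pytest.approx(0.1)

    def test_instantaneous_rescue_at_zero_length(self, kinetics, rng):
        mt = MicrotubuleState(
            0.0, 0.3, Side.RIGHT, length=0.01, phase=Phase.SHRINKING, drawn_tau=50.0, cat_clock=50.0
        )
        out = step_microtubule(mt, 0.1, False, kinetics, rng, axis_angle_sampler=lambda r: 0.7)
        assert out.phase is Phase.GROWING
        assert out.length == 0.0
        assert out.cat_clock == 0.0
        assert out.axis_angle == 0.7
        assert out.buckling_ref_length is None
        assert out.drawn_tau != 50.0  # fresh draw

    def test_contact_lifetime_equals_rescaled_time(self, kinetics, rng):
        # clock scheme contract: permanent contact realizes exactly the
        # load-rescaled catastrophe time
        mt = MicrotubuleState(0.0, 0.0, Side.RIGHT, length=1.0, drawn_tau=125.0)
        dt, t = 0.05, 0.0
        while mt.phase is Phase.GROWING:
            mt = step_microtubule(mt, dt, True, kinetics, rng)
            t += dt
        expected = 25.0 + (125.0 - 25.0) * kinetics.v_ratio
        assert t == pytest.approx(expected, abs=2 * dt)

    def test_contact_ensemble_mean_matches_rescaling_oracle(self, mal3_model, rng):
        # Monte-Carlo oracle: with v_ratio = 0.5, mean wall-clock catastrophe
        # time under permanent contact is tau0 + (N*T - tau0)/2
        from mtpush.mt_dynamics import KineticParams

        kin = KineticParams(0.05, 0.025, 0.15, 5.0, 1.25, mal3_model)
        n, dt = 300, 0.25
        times = np.empty(n)
        for k in range(n):
            mt = MicrotubuleState(0.0, 0.0, Side.RIGHT, drawn_tau=np.nan)
            t = 0.0
            mt = step_microtubule(mt, dt, True, kin, rng)  # draws tau
            while mt.phase is Phase.GROWING:
                mt = step_microtubule(mt, dt, True, kin, rng)
                t += dt
            times[k] = t
        expected = 25.0 + (3.6 * 35.0 - 25.0) * 0.5
        sem = times.std(ddof=1) / math.sqrt(n)
        assert abs(times.mean() - expected) < 2 * sem + dt


class TestHazardScheme:
    def test_memorylessness_of_exponential_hazard(self, rng):
        model = CatastropheModel(1.0, 35.0, tau0=25.0)
        ages = sample_catastrophe_ages_hazard(40_000, 0.2, model, rng)
        # conditional survival beyond 30 s given survival to 30 s matches the
        # unconditional law
        survivors = ages[ages > 30.0] - 30.0
        p_cond = np.mean(survivors > 35.0)
        p_uncond = np.mean(ages > 35.0)
        assert p_cond == pytest.approx(p_uncond, abs=0.02)

    def test_load_factor_accelerates_catastrophe(self, mal3_model, rng):
        free = sample_catastrophe_ages_hazard(20_000, 0.2, mal3_model, rng)
        loaded = sample_catastrophe_ages_hazard(20_000, 0.2, mal3_model, rng, load_factor=2.0)
        assert loaded.mean() < free.mean()
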