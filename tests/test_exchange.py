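"""Forward-model tests: Bloch-McConnell propagation, R1rho and CEST limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import protonex as px
from protonex.exchange import (
    _alignment,
    _loglinear_rate,
    _tilt_angles,
    bloch_mcconnell_matrix,
    propagate,
    propagate_ode,
)

DELAYS = np.array([0.0, 0.015, 0.030, 0.045, 0.060])


def ode_r1rho(model, relax, probe, power, offset):
    """R1rho through dense ODE integration of the magnetization (oracle path)."""
    L = bloch_mcconnell_matrix(model, relax, probe, power, offset)
    align = _alignment(model, probe)
    sin_t, cos_t = _tilt_angles(model, probe, np.asarray(power), np.asarray(offset), align)
    n = model.n_states
    m0 = np.zeros(3 * n)
    for i in range(n):
        m0[3 * i] = model.populations[i] * sin_t
        m0[3 * i + 2] = model.populations[i] * cos_t
    traj = propagate_ode(L, m0, DELAYS)
    proj = sum(
        traj[:, 3 * i] * sin_t + traj[:, 3 * i + 2] * cos_t for i in range(n)
    )
    return _loglinear_rate(DELAYS, proj)


class TestR1rhoLimits:
    def test_no_exchange_on_resonance_returns_r2(self, probe_c13, relax):
        model = px.two_state(0.0, 0.0, 2.5)
        scheme = px.SpinLockScheme(1000.0, 1e-9)
        assert px.simulate_r1rho(model, relax, probe_c13, scheme) == pytest.approx(
            relax.r2, abs=1e-9
        )

    def test_no_exchange_off_resonance_tilt_formula(self, probe_c13, relax):
        # R1 cos^2(theta) + R2 sin^2(theta) is the leading-order rotating-frame
        # rate; deviations scale as ((R2-R1)/w_eff)^2, so agreement is checked
        # at the corresponding tolerance rather than machine precision
        model = px.two_state(0.0, 0.0, 2.5)
        scheme = px.SpinLockScheme(1000.0, 500.0)
        theta = np.arctan2(scheme.power_hz, scheme.offset_hz)
        expected = relax.r1 * np.cos(theta) ** 2 + relax.r2 * np.sin(theta) ** 2
        got = px.simulate_r1rho(model, relax, probe_c13, scheme)
        assert got == pytest.approx(expected, rel=1e-5)

    def test_matches_ode_oracle_at_reported_low_ph_truth(self, probe_c13, relax):
        # minor population 1.7%, k_ex 562/s, dw 2.54 ppm: the low-pH exchange fit
        model = px.two_state(0.017, 562.0, 2.54)
        powers = [150.0, 400.0, 1000.0, 2000.0]
        offsets = [100.0, -500.0, 383.0, 1e-6]
        fast = px.simulate_r1rho_grid(model, relax, probe_c13, powers, offsets)
        for k, (pw, off) in enumerate(zip(powers, offsets)):
            oracle = ode_r1rho(model, relax, probe_c13, pw, off)
            assert fast[k] == pytest.approx(oracle, rel=1e-6)

    def test_fast_exchange_limit_rex(self, probe_c13, relax):
        dw_ppm, kex, p = 1.0, 5e4, 0.05
        dw = probe_c13.ppm_to_rads(dw_ppm)
        model = px.two_state(p, kex, dw_ppm)
        for power in (500.0, 1000.0, 2000.0):
            r = px.simulate_r1rho(model, relax, probe_c13, px.SpinLockScheme(power, 1e-9))
            rex_pred = (1 - p) * p * dw**2 * kex / (kex**2 + (2 * np.pi * power) ** 2)
            assert r - relax.r2 == pytest.approx(rex_pred, rel=0.05)

    def test_state_swap_symmetry(self, probe_c13, relax):
        # relabelling the reference state while negating dw is the same physics
        for p, kex, dw in [(0.017, 562.0, 2.54), (0.1, 5000.0, -1.2), (0.004, 474.0, 3.0)]:
            m1 = px.two_state(p, kex, dw)
            states = (
                px.ExchangeState("ES", p, 0.0),
                px.ExchangeState("GS", 1.0 - p, -dw),
            )
            m2 = px.ExchangeModel(
                states, {("ES", "GS"): (1 - p) * kex, ("GS", "ES"): p * kex}
            )
            powers = np.array([200.0, 800.0])
            offsets = np.array([150.0, -600.0])
            r1v = px.simulate_r1rho_grid(m1, relax, probe_c13, powers, offsets)
            r2v = px.simulate_r1rho_grid(m2, relax, probe_c13, powers, offsets)
            np.testing.assert_allclose(r1v, r2v, rtol=0, atol=1e-9)

    def test_alignment_rule_insensitivity_in_its_regimes(self, probe_c13, relax):
        # where the k_ex/dw rule selects a regime, the other alignment choice
        # changes R1rho by under 1% of the exchange contribution
        powers = np.array([200.0, 500.0, 1000.0])
        offsets = np.array([300.0, -400.0, 150.0])
        for ratio, dw in [(10.0, 1.0), (0.05, 2.0)]:
            kex = ratio * abs(probe_c13.ppm_to_rads(dw))
            model = px.two_state(0.02, kex, dw)
            base = px.simulate_r1rho_grid(
                px.two_state(0.0, 0.0, dw), relax, probe_c13, powers, offsets
            )
            rex = px.simulate_r1rho_grid(model, relax, probe_c13, powers, offsets) - base
            r_avg = px.simulate_r1rho_grid(
                model, relax, probe_c13, powers, offsets, alignment="avg"
            )
            r_gs = px.simulate_r1rho_grid(
                model, relax, probe_c13, powers, offsets, alignment="gs"
            )
            assert np.max(np.abs(r_avg - r_gs) / np.abs(rex)) < 0.01

    def test_invalid_power_and_pathological_rates_raise(self, probe_c13, relax):
        with pytest.raises(px.InvalidSchemeError):
            px.SpinLockScheme(-100.0, 0.0)
        with pytest.raises(px.InvalidSchemeError):
            px.simulate_r1rho_grid(
                px.two_state(0.01, 500.0, 1.0), relax, probe_c13, [0.0], [100.0]
            )
        with pytest.raises(px.NumericRangeError):
            px.simulate_r1rho_grid(
                px.two_state(0.01, 5e9, 1.0), relax, probe_c13, [100.0], [100.0]
            )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    p=st.floats(1e-3, 0.3),
    kex=st.floats(10.0, 1e6),
    dw=st.floats(-5.0, 5.0),
    power=st.floats(50.0, 3000.0),
    offset=st.floats(-3000.0, 3000.0),
)
def test_propagator_matches_ode_integration(p, kex, dw, power, offset):
    """Eigen-propagation equals high-accuracy ODE integration for bounded rates."""
    probe = px.Probe("C", 150.9)
    relax = px.RelaxParams(1.5, 18.0)
    model = px.two_state(p, kex, dw)
    L = bloch_mcconnell_matrix(model, relax, probe, power, offset)
    m0 = np.zeros(6)
    m0[2], m0[5] = 1.0 - p, p
    fast = propagate(L, m0, DELAYS)
    slow = propagate_ode(L, m0, DELAYS)
    assert np.max(np.abs(fast - slow)) <= 1e-8 * max(np.max(np.abs(slow)), 1.0)


class TestCEST:
    def test_on_resonance_saturation(self, probe_h1, relax):
        model = px.two_state(0.004, 470.0, -2.8)
        scheme = px.CESTScheme((500.0,), (0.0,), 0.1)
        prof = px.simulate_cest(model, relax, probe_h1, scheme)
        assert prof[0, 0] < 0.05

    def test_far_off_resonance_decays_at_r1(self, probe_h1, relax):
        model = px.two_state(0.0, 0.0, 0.0)
        scheme = px.CESTScheme((10.0,), (6.0,), 0.1)
        prof = px.simulate_cest(model, relax, probe_h1, scheme)
        assert prof[0, 0] == pytest.approx(np.exp(-relax.r1 * 0.1), abs=0.02)

    def test_minor_dip_lies_at_minor_shift(self, probe_h1, relax):
        model = px.two_state(0.004, 470.0, -2.8)
        scheme = px.CESTScheme.default_grid((25.0,), span_ppm=6.0, step_ppm=0.1)
        prof = px.simulate_cest(model, relax, probe_h1, scheme)
        offs = np.array(scheme.offsets_ppm)
        away = np.abs(offs) > 1.0
        dip = offs[away][np.argmin(prof[0][away])]
        assert abs(dip - (-2.8)) <= 0.1 + 1e-9

    def test_empty_offset_grid_rejected(self):
        with pytest.raises(px.InvalidSchemeError):
            px.CESTScheme((100.0,), ())


class TestMonoExp:
    def test_noiseless_recovery(self):
        t = np.linspace(0.0, 0.12, 5)
        res = px.monoexp_rate(t, np.exp(-10.0 * t), sigma=0.01, n_mc=50, seed=0)
        assert res.rate == pytest.approx(10.0, abs=1e-9)
        assert not res.degenerate

    def test_constant_intensities_give_zero_rate(self):
        t = np.linspace(0.0, 0.12, 5)
        res = px.monoexp_rate(t, np.ones(5), sigma=0.01, n_mc=50, seed=0)
        assert res.rate == pytest.approx(0.0, abs=1e-9)

    def test_rising_data_flagged_not_raised(self):
        t = np.linspace(0.0, 0.12, 5)
        res = px.monoexp_rate(t, np.exp(3.0 * t), sigma=0.01, n_mc=50, seed=0)
        assert res.degenerate and res.rate < 0

    def test_monte_carlo_sd_coverage(self):
        # noisy decays: the 2-SD interval from 500 resamples covers the true
        # rate in at least 95% of repeated experiments
        rng = np.random.default_rng(11)
        t = np.linspace(0.0, 0.12, 5)
        truth = 10.0
        n_rep, covered = 200, 0
        for rep in range(n_rep):
            y = np.exp(-truth * t) + rng.normal(0.0, 0.01, 5)
            res = px.monoexp_rate(t, np.clip(y, 1e-6, None), sigma=0.01,
                                  n_mc=500, seed=rep)
            covered += abs(res.rate - truth) <= 2 * res.sd
        assert covered / n_rep >= 0.95


class TestModelInvariants:
    def test_population_sum_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            px.ExchangeModel(
                (px.ExchangeState("A", 0.6), px.ExchangeState("B", 0.5)),
                {("A", "B"): 1.0, ("B", "A"): 1.2},
            )

    def test_detailed_balance_enforced(self):
        with pytest.raises(ValueError, match="detailed balance"):
            px.ExchangeModel(
                (px.ExchangeState("A", 0.9), px.ExchangeState("B", 0.1)),
                {("A", "B"): 1.0, ("B", "A"): 1.0},
            )

    @given(p=st.floats(1e-4, 0.5), kex=st.floats(1.0, 1e5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_kex_decomposition(self, p, kex):
        m = px.two_state(p, kex, 1.0)
        assert m.kex("GS", "ES") == pytest.approx(kex, rel=1e-12)
        assert m.rate("GS", "ES") == pytest.approx(p * kex, rel=1e-12)

    def test_rate_matrix_columns_sum_to_zero(self):
        m = px.linear_three_state([0.9, 0.06, 0.04], 1e5, 600.0, [0.0, 0.2, 2.5])
        K = m.rate_matrix()
        np.testing.assert_allclose(K.sum(axis=0), 0.0, atol=1e-9)
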