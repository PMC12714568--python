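"""Explicit kinetic simulation and mechanism-discrimination tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import protonex as px
from protonex.kinetics import hplus, simulate_three_state_ode


def rand_params(rng):
    return px.KineticParams(
        kon_es1=float(rng.uniform(1e6, 1e10)),
        koff_es1=float(rng.uniform(100.0, 3e4)),
        kon_es2=float(rng.uniform(1e5, 1e8)),
        koff_es2=float(rng.uniform(10.0, 5e3)),
    )


class TestRateMatrix:
    @given(
        kon1=st.floats(0.0, 1e10),
        koff1=st.floats(0.0, 1e5),
        kon2=st.floats(0.0, 1e9),
        koff2=st.floats(0.0, 1e4),
        ph=st.floats(4.0, 8.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_columns_sum_to_zero(self, kon1, koff1, kon2, koff2, ph):
        params = px.KineticParams(kon_es1=kon1, koff_es1=koff1,
                                  kon_es2=kon2, koff_es2=koff2)
        K = px.rate_matrix_three_state(params, ph)
        np.testing.assert_allclose(K.sum(axis=0), 0.0, atol=1e-6 * max(np.max(np.abs(K)), 1.0))

    def test_population_conserved_and_reaches_equilibrium(self):
        params = px.KineticParams(kon_es1=2e9, koff_es1=21000.0,
                                  kon_es2=8.2e6, koff_es2=490.0)
        trace = px.simulate_three_state(params, 6.4)
        np.testing.assert_allclose(trace.populations.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(
            trace.populations[-1], px.equilibrium_populations(params, 6.4), atol=1e-8
        )

    def test_detailed_balance_at_equilibrium(self):
        params = px.KineticParams(kon_es1=0.0, koff_es1=0.0,
                                  kon_es2=8.2e6, koff_es2=490.0)
        trace = px.simulate_three_state(params, 6.4)
        h = hplus(6.4)
        ratio = trace.populations[-1, 2] / trace.populations[-1, 1]
        assert ratio == pytest.approx(params.kon_es2 * h / params.koff_es2, rel=1e-8)

    def test_eigen_solution_matches_stiff_ode(self):
        rng = np.random.default_rng(17)
        times = np.linspace(0.0, 0.1, 40)
        for _ in range(30):
            params = rand_params(rng)
            ph = float(rng.uniform(5.0, 7.5))
            fast = px.simulate_three_state(params, ph, times_s=times,
                                           extend_to_equilibrium=False)
            slow = simulate_three_state_ode(params, ph, times_s=times)
            err = np.max(np.abs(fast.populations - slow.populations))
            assert err <= 1e-8


class TestApparentExchange:
    def test_pure_two_state_trace_reduces_exactly(self):
        params = px.KineticParams(kon_es1=0.0, koff_es1=0.0,
                                  kon_es2=8.2e6, koff_es2=490.0)
        trace = px.simulate_three_state(params, 6.4)
        app = px.apparent_exchange_from_trace(trace)
        kex_true = params.kon_es2 * hplus(6.4) + params.koff_es2
        assert app["k_ex"] == pytest.approx(kex_true, rel=1e-6)
        p_true = px.equilibrium_populations(params, 6.4)[2]
        assert app["p_minor"] == pytest.approx(p_true, rel=1e-6)
        assert not app["multi_exponential"]

    def test_timescale_separated_branches(self):
        # a ~25000/s competing branch barely perturbs the ~500/s transition
        params = px.KineticParams(kon_es1=1.3e9, koff_es1=21000.0,
                                  kon_es2=8.2e6, koff_es2=490.0)
        trace = px.simulate_three_state(params, 6.4)
        app = px.apparent_exchange_from_trace(trace)
        kex_true = params.kon_es2 * hplus(6.4) + params.koff_es2
        assert app["k_ex"] == pytest.approx(kex_true, rel=0.05)

    def test_rate_independent_of_initial_condition(self):
        params = px.KineticParams(kon_es1=1.3e9, koff_es1=21000.0,
                                  kon_es2=8.2e6, koff_es2=490.0)
        rates = []
        for init in [(0.0, 1.0, 0.0), (0.2, 0.8, 0.0), (0.05, 0.85, 0.1)]:
            trace = px.simulate_three_state(params, 6.4, init=init)
            rates.append(px.apparent_exchange_from_trace(trace)["k_ex"])
        assert max(rates) / min(rates) - 1.0 < 0.01

    def test_unequilibrated_trace_rejected(self):
        params = px.KineticParams(kon_es1=0.0, koff_es1=0.0,
                                  kon_es2=8.2e6, koff_es2=490.0)
        trace = px.simulate_three_state(
            params, 6.4, times_s=np.linspace(0, 1e-4, 20),
            extend_to_equilibrium=False,
        )
        with pytest.raises(ValueError, match="equilibrium"):
            px.apparent_exchange_from_trace(trace)


class TestProtonLinearFit:
    PHS = (5.4, 6.0, 6.4, 7.0, 7.4)

    def test_noiseless_exact_recovery(self):
        kon, koff = 8.2e6, 490.0
        pts = [(ph, kon * hplus(ph), 0.0, koff, 0.0) for ph in self.PHS]
        fit = px.fit_proton_linear(pts)
        assert fit["kon"] == pytest.approx(kon, rel=1e-9)
        assert fit["koff"] == pytest.approx(koff, rel=1e-9)

    def test_ph_flat_forward_rate_gives_zero_slope(self):
        rng = np.random.default_rng(5)
        pts = [(ph, 300.0 + rng.normal(0, 5.0), 5.0, 490.0, 10.0) for ph in self.PHS]
        fit = px.fit_proton_linear(pts)
        # a pH-independent forward rate forces most weight to low [H+]; the
        # slope picks up only the residual scatter
        assert abs(fit["kon"]) * hplus(min(self.PHS)) < 2.0 * 300.0

    def test_weights_follow_inverse_variance(self):
        pts = [(5.4, 40.0, 2.0, 490.0, 10.0), (6.0, 8.0, 1.0, 480.0, 10.0),
               (6.4, 3.2, 0.5, 500.0, 10.0)]
        fit = px.fit_proton_linear(pts)
        h = np.array([hplus(p[0]) for p in pts])
        kf = np.array([p[1] for p in pts])
        w = np.array([1.0 / p[2] ** 2 for p in pts])
        manual = float(np.sum(w * h * kf) / np.sum(w * h * h))
        assert fit["kon"] == pytest.approx(manual, rel=1e-12)
        # inflating one SD by 2x reduces that point's pull by 4x
        pts2 = [pts[0], (6.0, 8.0, 2.0, 480.0, 10.0), pts[2]]
        fit2 = px.fit_proton_linear(pts2)
        w2 = w.copy(); w2[1] /= 4.0
        manual2 = float(np.sum(w2 * h * kf) / np.sum(w2 * h * h))
        assert fit2["kon"] == pytest.approx(manual2, rel=1e-12)


class TestMechanismPredictions:
    def test_csprot_forward_rate_value(self):
        params = px.KineticParams(k_prot=6e11)
        out = px.predict_mechanism_rates("CSprot", params, 0.9e-3, 6.4)
        assert out["k_forward"] == pytest.approx(214.8, rel=0.01)

    def test_csconf_forward_rate_is_ph_flat(self):
        params = px.KineticParams()
        a = px.predict_mechanism_rates("CSconf", params, 0.9e-3, 5.4)
        b = px.predict_mechanism_rates("CSconf", params, 0.9e-3, 7.4)
        assert a["k_forward"] == b["k_forward"]

    def test_ifprot_implies_diffusion_limited_kon(self):
        params = px.KineticParams(k_prot=5e10)
        out = px.predict_mechanism_rates("IFprot", params, 0.9e-3, 6.4)
        kon_implied = out["k_forward"] / hplus(6.4)
        assert 1e10 <= kon_implied <= 1e11

    def test_unknown_mechanism_rejected(self):
        with pytest.raises(ValueError):
            px.predict_mechanism_rates("CSboth", px.KineticParams(), 1.0, 6.4)


class TestKIE:
    def test_ifconf_without_pka_shift_has_no_kie(self):
        out = px.predict_kie("IFconf", delta_pka=0.0)
        assert out["forward"] == (1.0, 1.0)
        assert out["reverse"] == (1.0, 1.0)

    def test_protonation_limited_forward_range(self):
        out = px.predict_kie("CSprot")
        assert out["forward"] == (2.0, 4.0)

    def test_protonation_limited_reverse_range_with_pka_shift(self):
        out = px.predict_kie("CSprot", kprot_ratio_range=(2.0, 4.0), delta_pka=0.1)
        assert out["reverse"][0] == pytest.approx(2.52, abs=0.01)
        assert out["reverse"][1] == pytest.approx(5.04, abs=0.01)


class TestMutantFoldChange:
    def test_identity_mutation_changes_nothing(self):
        out = px.predict_mutant_fold_change("CSprot", 0.9e-3, 0.9e-3)
        assert out["forward_fold"] == pytest.approx(1.0)
        assert out["reverse_fold"] == 1.0

    def test_csprot_predicted_folds_for_stabilizing_mutation(self):
        # 0.9e-3 -> 1.4 conformational equilibrium: ~650-fold forward increase
        out = px.predict_mutant_fold_change("CSprot", 0.9e-3, 1.4)
        assert out["forward_fold"] == pytest.approx(6.5e2, rel=0.01)
        assert out["reverse_fold"] == 1.0

    def test_csprot_reverse_always_unity(self):
        for mut in (1e-4, 0.1, 10.0, 1e4):
            assert px.predict_mutant_fold_change("CSprot", 0.9e-3, mut)["reverse_fold"] == 1.0

    def test_ifconf_folds_unconstrained(self):
        out = px.predict_mutant_fold_change("IFconf", 0.9e-3, 1.4)
        assert out["forward_fold"] is None and out["reverse_fold"] is None


class TestMechanismClassification:
    PHS = (5.4, 6.0, 6.4, 7.0, 7.4)

    def curve(self, mech, params, kconf):
        pts = []
        for ph in self.PHS:
            r = px.predict_mechanism_rates(mech, params, kconf, ph)
            pts.append((ph, r["k_forward"], 0.0, r["k_reverse"], 0.0))
        return pts

    def test_noiseless_round_trip_for_all_mechanisms(self):
        # decision rules recover the generating mechanism for 25 random
        # parameter draws each (100 noiseless cases in total)
        rng = np.random.default_rng(23)
        for _ in range(25):
            # K_conf well below ~1e-2 keeps the CS^prot slope sub-diffusion;
            # at larger K_conf CS^prot and IF^prot are degenerate by slope
            kconf = float(10.0 ** rng.uniform(-4, -2))
            params = px.KineticParams(
                k_prot=float(rng.uniform(1e10, 1e11)) if rng.uniform() < 0.5 else 6e11,
                kf_conf=float(rng.uniform(50, 2000)),
                kr_conf=float(rng.uniform(50, 2000)),
                pka_gs=4.0,
            )
            for mech in px.MECHANISMS:
                p = params
                if mech == "IFprot":
                    p = px.KineticParams(k_prot=float(rng.uniform(1e10, 1e11)),
                                         kf_conf=params.kf_conf,
                                         kr_conf=params.kr_conf)
                kie = px.predict_kie(mech)["forward"]
                got = px.classify_mechanism(
                    self.curve(mech, p, kconf),
                    kie_forward=float(np.mean(kie)),
                )
                assert got == mech, f"{mech} classified as {got}"


class TestInducedFitReduction:
    def test_fast_protonation_collapses_to_linear_forward_rate(self):
        # GS <-> GS+ <-> ES2+ chain with protonation >=1e4 faster than the
        # conformational step: the extracted forward rate is linear in [H+]
        kprot, pka_gs = 6e11, 4.0
        kf_conf, kr_conf = 270.0, 423.0
        phs = np.array([5.4, 6.0, 6.4, 7.0, 7.4])
        kfs = []
        for ph in phs:
            h = hplus(ph)
            kp, kd = kprot * h, kprot * 10.0**-pka_gs
            assert kp + kd >= 1e4 * (kf_conf + kr_conf)
            K = np.array([
                [-kp, kd, 0.0],
                [kp, -(kd + kf_conf), kr_conf],
                [0.0, kf_conf, -kr_conf],
            ])
            trace = px.simulate_rate_system(K, (1.0, 0.0, 0.0),
                                            labels=("GS", "GS+", "ES2+"))
            app = px.apparent_exchange_from_trace(trace, "ES2+")
            kfs.append(app["p_minor"] * app["k_ex"])
        h = 10.0**-phs
        slope = float(np.sum(h * kfs) / np.sum(h * h))
        pred = slope * h
        r2 = 1.0 - np.sum((kfs - pred) ** 2) / np.sum((kfs - np.mean(kfs)) ** 2)
        assert r2 > 0.999

    def test_fast_es1_branch_suppresses_low_ph_forward_rate(self):
        # a competing protonated branch soaks up ground-state population at
        # low pH, pulling the extracted forward rate below the linear trend
        base = dict(kon_es2=8.2e6, koff_es2=490.0)
        ratios = {}
        for ph in (5.4, 6.4):
            t0 = px.simulate_three_state(
                px.KineticParams(kon_es1=0.0, koff_es1=0.0, **base), ph)
            a0 = px.apparent_exchange_from_trace(t0)
            t1 = px.simulate_three_state(
                px.KineticParams(kon_es1=1.3e9, koff_es1=21000.0, **base), ph)
            a1 = px.apparent_exchange_from_trace(t1)
            ratios[ph] = (a1["p_minor"] * a1["k_ex"]) / (a0["p_minor"] * a0["k_ex"])
        assert ratios[5.4] < 1.0
        assert ratios[5.4] < ratios[6.4]
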