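"""Two-pulse estimation, junction tuning and sequential decomposition."""

import numpy as np
import pytest

import fiakit as fk
from fiakit import kinetics as K
from fiakit.routine import (
    DecompositionResult,
    OJIPDecomposition,
    TwoPulseModel,
    decompose_ojip,
    detect_Fm,
    estimate_beta,
    estimate_kL,
    estimate_nFv,
    kab_vs_duration,
    tune_secondary,
    two_pulse_analysis,
)


class TestElementaryEstimators:
    @pytest.mark.parametrize("fm, expected", [(5.0, 2.0), (3.0, 1.0), (1.001, 0.0005)])
    def test_nFv_from_maximum(self, fm, expected):
        assert estimate_nFv(fm) == pytest.approx(expected, rel=1e-12)

    def test_nFv_rejects_baseline_values(self):
        with pytest.raises(ValueError):
            estimate_nFv(1.0)

    def test_kL_from_slope(self):
        assert estimate_kL(1 / 0.35, 2.0) == pytest.approx(1.43, abs=0.01)
        assert estimate_kL(3.7, 1.0) == 3.7
        with pytest.raises(ValueError):
            estimate_kL(0.0, 2.0)

    def test_kL_round_trip_on_simulated_rise(self):
        p = fk.PhotochemParams(k_L=1.5, k_AB=2.8, nF_v=2.0, beta=0.15, phi=0.15)
        proto = fk.PulseProtocol.single_pulse(2.0, 3000.0, resolution=0.01)
        tr = fk.simulate(proto, p, fk.ThermalParams(0.0, 0.0))
        slope, _ = fk.initial_slope(tr)
        assert estimate_kL(slope, p.nF_v) == pytest.approx(1.5, rel=0.01)

    @pytest.mark.parametrize(
        "a_slow, nfv, k_l, t0, expected, tol",
        [(0.08, 2.0, 1.25, 0.25, 0.149, 5e-3), (0.0, 2.0, 1.25, 0.25, 0.0, 1e-12)],
    )
    def test_beta_estimator(self, a_slow, nfv, k_l, t0, expected, tol):
        assert estimate_beta(a_slow, nfv, k_l, t0) == pytest.approx(expected, abs=tol)

    def test_beta_rejects_bad_pulse_length(self):
        with pytest.raises(ValueError):
            estimate_beta(0.08, 2.0, 1.25, 0.0)

    def test_scale_consistency_of_slope_factorization(self):
        # doubling nF_v while halving k_L leaves the initial slope unchanged
        p1 = fk.PhotochemParams(k_L=1.5, k_AB=2.8, nF_v=2.0)
        p2 = fk.PhotochemParams(k_L=0.75, k_AB=2.8, nF_v=4.0)
        h = 1e-6
        assert K.f_pp(h, p1) == pytest.approx(K.f_pp(h, p2), rel=1e-6)
        # and the estimator product is invariant
        assert estimate_kL(3.0, 2.0) * 2.0 == estimate_kL(3.0, 4.0) * 4.0


class TestFmDetection:
    def test_plateau_value(self, two_pulse_noiseless):
        _, sp = two_pulse_noiseless
        assert detect_Fm(sp) == pytest.approx(5.076, abs=0.01)

    def test_unsaturated_pulse_rejected(self):
        t = np.arange(1, 20001) * 0.05
        tr = fk.FluorTrace(t, 1 + 0.004 * t, np.ones_like(t, dtype=int))
        with pytest.raises(ValueError, match="plateau"):
            detect_Fm(tr)


class TestTwoPulseAnalysis:
    def test_noiseless_recovery_within_five_percent(self, kala_p, fitted_noiseless):
        est, _ = fitted_noiseless
        for name in ("k_L", "k_AB", "nF_v", "beta"):
            assert getattr(est, name) == pytest.approx(getattr(kala_p, name), rel=0.05), name

    def test_homogeneous_control_beta_near_zero(self, kala_th):
        p = fk.PhotochemParams(k_L=1.5, k_AB=2.8, nF_v=2.0, beta=0.0, phi=0.15)
        ssp, sp = fk.make_two_pulse_fixture(p, kala_th, resolution=0.01, sp_resolution=0.05)
        est = two_pulse_analysis(ssp, sp)
        assert est.beta < 0.02

    def test_blocked_reoxidation_limit(self):
        # DCMU-like: k_AB = 0, homogeneous, no thermal phase
        p = fk.PhotochemParams(k_L=1.5, k_AB=0.0, nF_v=2.0, beta=0.0)
        th0 = fk.ThermalParams(0.0, 0.0)
        ssp, sp = fk.make_two_pulse_fixture(p, th0, resolution=0.01, sp_resolution=0.05)
        fit = fk.fit_multiexp(ssp.dark_segment(), 3)
        k_dom = fit.rates[int(np.argmax(fit.amplitudes))]
        assert k_dom < 0.05
        f_end = sp.light_on_segment().f_rel[-1]
        assert f_end - 1.0 == pytest.approx(p.nF_v, rel=0.01)

    def test_missing_dark_tail_raises(self, kala_p, kala_th, two_pulse_noiseless):
        _, sp = two_pulse_noiseless
        proto = fk.PulseProtocol.single_pulse(0.25, 3000.0, resolution=0.01)
        pulse_only = fk.simulate(proto, kala_p, kala_th)
        with pytest.raises(ValueError, match="dark tail"):
            two_pulse_analysis(pulse_only, sp)

    def test_model_facade_summary(self, two_pulse_noiseless):
        ssp, sp = two_pulse_noiseless
        res = TwoPulseModel(ssp, sp).fit()
        text = res.summary()
        for key in ("kL", "kAB", "nFv", "beta", "kqbf", "NIP"):
            assert key in text
        d = res.to_dict()
        assert d["kL"] == pytest.approx(1.5, rel=0.05)
        assert res.decomposition is not None


class TestTuneSecondary:
    def test_exact_input_is_fixed_point(self, kala_p):
        proto = fk.PulseProtocol.single_pulse(5.0, 3000.0, resolution=0.01)
        tr = fk.simulate(proto, kala_p, fk.ThermalParams(0.0, 0.0))
        tuned, jerr = tune_secondary(tr, kala_p)
        assert tuned.phi == kala_p.phi
        assert tuned.k_2AB == kala_p.k_2AB
        assert tuned.k_AB == kala_p.k_AB
        assert jerr < 1e-10

    def test_recovers_planted_phi_within_grid_step(self, kala_p):
        p_true = kala_p.replace(phi=0.15)
        proto = fk.PulseProtocol.single_pulse(5.0, 3000.0, resolution=0.01)
        tr = fk.simulate(proto, p_true, fk.ThermalParams(0.0, 0.0))
        start = p_true.replace(phi=0.3, k_2AB=0.275)
        tuned, _ = tune_secondary(tr, start)
        assert tuned.phi == pytest.approx(0.15, abs=0.05)

    def test_planted_phi_at_upper_bound_is_clamped_there(self, kala_p):
        p_true = kala_p.replace(phi=0.5)
        proto = fk.PulseProtocol.single_pulse(5.0, 3000.0, resolution=0.01)
        tr = fk.simulate(proto, p_true, fk.ThermalParams(0.0, 0.0))
        tuned, _ = tune_secondary(tr, p_true.replace(phi=0.3))
        assert tuned.phi == pytest.approx(0.5, abs=0.02)


class TestDecomposition:
    def test_round_trip_thermal_rates_within_ten_percent(self, kala_p, kala_th,
                                                         two_pulse_noiseless):
        _, sp = two_pulse_noiseless
        dec = decompose_ojip(sp, kala_p)
        assert dec.params_thermal.k_qbf == pytest.approx(0.1, rel=0.10)
        assert dec.params_thermal.k_minus_qbf == pytest.approx(0.01, rel=0.10)

    def test_self_consistent_input_decomposes_exactly(self, kala_p, two_pulse_noiseless):
        _, sp = two_pulse_noiseless
        dec = decompose_ojip(sp, kala_p)
        assert dec.residual_rms < 1e-6

    def test_photochemical_only_input_gives_null_thermal(self, kala_p, photochem_only_sp):
        dec = decompose_ojip(photochem_only_sp, kala_p)
        assert dec.component_traces["F_PE"].max() < 1e-4
        assert dec.component_traces["F_CET"].max() < 1e-4
        assert dec.residual_rms < 1e-6

    def test_component_sum_identity(self, kala_p, two_pulse_noiseless):
        _, sp = two_pulse_noiseless
        dec = decompose_ojip(sp, kala_p)
        ct = dec.component_traces
        np.testing.assert_allclose(
            ct["F_FIA"], 1.0 + ct["F_PP"] + ct["F_PE"] + ct["F_CET"], atol=1e-12
        )

    def test_signal_conservation(self, kala_p, two_pulse_noiseless):
        # F_exp = F_FIA + residual pointwise, by construction
        _, sp = two_pulse_noiseless
        dec = decompose_ojip(sp, kala_p)
        np.testing.assert_allclose(
            dec.f_exp, dec.component_traces["F_FIA"] + dec.residual, atol=1e-12
        )

    def test_short_record_rejected(self, kala_p):
        proto = fk.PulseProtocol.single_pulse(100.0, 3000.0, resolution=0.05)
        tr = fk.simulate(proto, kala_p, fk.kalanchoe_thermal())
        with pytest.raises(ValueError, match="500"):
            decompose_ojip(tr, kala_p)

    def test_model_object_and_summary(self, kala_p, two_pulse_noiseless):
        _, sp = two_pulse_noiseless
        dec = OJIPDecomposition(sp, kala_p).fit()
        assert isinstance(dec, DecompositionResult)
        assert "kqbf" in dec.summary()

    def test_component_plot_renders(self, kala_p, two_pulse_noiseless):
        import matplotlib

        matplotlib.use("Agg")
        _, sp = two_pulse_noiseless
        ax = decompose_ojip(sp, kala_p).plot()
        assert len(ax.lines) >= 5
        import matplotlib.pyplot as plt

        plt.close("all")


class TestKabVsDuration:
    def test_planted_trend_recovered(self, kala_th):
        traces = []
        durations = (0.25, 0.5, 1.0)
        planted = (3.2, 2.8, 2.2)  # re-oxidation slows with pulse length
        for t0, kab in zip(durations, planted):
            p = fk.PhotochemParams(k_L=1.5, k_AB=kab, nF_v=2.0, beta=0.15, phi=0.15)
            proto = fk.PulseProtocol.single_pulse(t0, 3000.0, tail=20.0, resolution=0.01)
            traces.append(fk.simulate(proto, p, kala_th))
        table = kab_vs_duration(traces)
        assert list(table["t0_ms"]) == list(durations)
        assert np.all(np.diff(table["k1"]) < 0)
        np.testing.assert_allclose(table["k1"], planted, rtol=0.1)

    def test_identical_traces_identical_rows(self, two_pulse_noiseless):
        ssp, _ = two_pulse_noiseless
        table = kab_vs_duration([ssp, ssp])
        assert table.iloc[0]["k1"] == table.iloc[1]["k1"]

    def test_single_trace_matches_direct_fit(self, two_pulse_noiseless):
        ssp, _ = two_pulse_noiseless
        table = kab_vs_duration([ssp])
        direct = fk.fit_multiexp(ssp.dark_segment(), 3)
        assert table.iloc[0]["k1"] == pytest.approx(direct.rates[0], rel=1e-9)
        assert table.iloc[0]["reciprocal_ms"] == pytest.approx(1 / direct.rates[0])

    def test_fit_failure_recorded_not_fatal(self, two_pulse_noiseless):
        ssp, sp = two_pulse_noiseless
        table = kab_vs_duration([ssp, sp])  # sp has no dark tail
        assert (table["error"] != "").sum() == 1
        assert (table["error"] == "").sum() == 1
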