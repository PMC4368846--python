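"""Closed-form kinetics: worked values, ODE cross-checks, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fiakit as fk
from fiakit import kinetics as K
from fiakit.params import PhotochemParams, ThermalParams, YieldRates


def euler_closure(t_end, k_l, k_ab, step=1e-4, q0=0.0):
    """Brute-force integration of dq/dt = k_L (1 - q) - k_AB q."""
    n = int(round(t_end / step))
    q = q0
    for _ in range(n):
        q += step * (k_l * (1.0 - q) - k_ab * q)
    return q


class TestClosureFractions:
    @pytest.mark.parametrize(
        "t, k_l, k_ab, expected, tol",
        [
            (0.0, 1.5, 2.8, 0.0, 0.0),
            (1e9, 1.5, 2.8, 1.5 / 4.3, 1e-9),     # saturation level
            (1.0, 1.5, 2.8, 0.3441, 5e-4),        # direct evaluation
        ],
    )
    def test_open_pool_values(self, t, k_l, k_ab, expected, tol):
        assert K.q_open_closure(t, k_l, k_ab) == pytest.approx(expected, abs=max(tol, 1e-12))

    def test_open_pool_matches_euler_oracle(self):
        for t_end in (0.25, 1.0, 3.0):
            q_num = euler_closure(t_end, 1.5, 2.8)
            assert abs(K.q_open_closure(t_end, 1.5, 2.8) - q_num) < 1e-4

    @pytest.mark.parametrize(
        "t, k_l, expected",
        [(0.25, 1.25, 0.2684), (0.0, 1.25, 0.0), (1e9, 0.3, 1.0)],
    )
    def test_nonreducing_pool_values(self, t, k_l, expected):
        assert K.q_nonreducing_closure(t, k_l) == pytest.approx(expected, abs=5e-4)

    def test_heterogeneous_limits(self, kala_p):
        t = np.linspace(0, 5, 50)
        p0 = kala_p.replace(beta=0.0)
        p1 = kala_p.replace(beta=1.0)
        np.testing.assert_allclose(K.q_total(t, p0), K.q_open_closure(t, p0.k_L, p0.k_AB))
        np.testing.assert_allclose(K.q_total(t, p1), K.q_nonreducing_closure(t, p1.k_L))
        # worked value: 0.85 * 1.5/4.3 + 0.15
        assert K.q_total(1e9, kala_p) == pytest.approx(0.4465, abs=5e-4)

    @pytest.mark.parametrize(
        "dt, q0, k_ab, expected",
        [(0.0, 0.5, 2.0, 0.5), (np.log(2) / 2.0, 0.5, 2.0, 0.25), (1e9, 0.8, 2.0, 0.0)],
    )
    def test_dark_reopening(self, dt, q0, k_ab, expected):
        assert K.q_dark(dt, q0, k_ab) == pytest.approx(expected, abs=1e-12)

    def test_dark_matches_euler_oracle(self):
        q0 = 0.45
        q_num = q0
        step = 1e-4
        for _ in range(int(2.0 / step)):
            q_num += step * (-2.8 * q_num)
        assert abs(K.q_dark(2.0, q0, 2.8) - q_num) < 1e-4

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            K.q_open_closure(-0.1, 1.0, 1.0)
        with pytest.raises(ValueError):
            K.q_open_closure(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            K.q_dark(1.0, 1.5, 1.0)
        with pytest.raises(ValueError):
            K.q_dark(1.0, 0.5, -1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        t=st.floats(0, 100),
        k_l=st.floats(0.01, 10),
        k_ab=st.floats(0, 10),
        beta=st.floats(0, 1),
    )
    def test_fractions_bounded_unit_interval(self, t, k_l, k_ab, beta):
        p = PhotochemParams(k_L=k_l, k_AB=k_ab, nF_v=2.0, beta=beta)
        for q in (
            K.q_open_closure(t, k_l, k_ab),
            K.q_nonreducing_closure(t, k_l),
            K.q_total(t, p),
        ):
            assert 0.0 <= q <= 1.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(k_l=st.floats(0.05, 5), k_ab=st.floats(0, 5), beta=st.floats(0, 1))
    def test_closure_monotone_in_light(self, k_l, k_ab, beta):
        p = PhotochemParams(k_L=k_l, k_AB=k_ab, nF_v=2.0, beta=beta)
        t = np.linspace(0, 20, 200)
        q = K.q_total(t, p)
        assert np.all(np.diff(q) >= -1e-12)


class TestPhotochemicalFluorescence:
    def test_steady_state_worked_value(self, kala_p):
        assert K.f_pp_steady(kala_p) == pytest.approx(0.893, abs=5e-4)
        # long-time evaluation agrees with the closed-form limit
        assert K.f_pp(5e3, kala_p) == pytest.approx(K.f_pp_steady(kala_p), abs=1e-6)

    def test_steady_state_homogeneous_reduces(self):
        p = PhotochemParams(k_L=1.5, k_AB=2.8, nF_v=2.0, beta=0.0)
        assert K.f_pp_steady(p) == pytest.approx(2.0 * 1.5 / 4.3, rel=1e-12)

    def test_blocked_reoxidation_reaches_nFv(self):
        p = PhotochemParams(k_L=1.0, k_AB=0.0, nF_v=2.0, beta=0.0)
        assert K.f_pp_steady(p) == pytest.approx(2.0, rel=1e-12)
        assert K.f_pp(1e4, p) == pytest.approx(2.0, abs=1e-9)

    def test_second_hit_term_starts_flat(self, kala_p):
        assert K.f_pp2(0.0, kala_p) == 0.0
        h = 1e-7
        assert K.f_pp2(h, kala_p) / h < 1e-4  # derivative ~ 0 at t = 0

    @pytest.mark.parametrize("k_ab", [0.0, 1.0, 5.0])
    def test_initial_slope_is_nFv_kL_regardless_of_kAB(self, k_ab):
        p = PhotochemParams(k_L=1.5, k_AB=k_ab, nF_v=2.0, beta=0.15, phi=0.2)
        h = 1e-4
        slope = K.f_pp(h, p) / h
        assert abs(slope - p.nF_v * p.k_L) / (p.nF_v * p.k_L) < 1e-3
        h = 1e-6
        slope = K.f_pp(h, p) / h
        assert abs(slope - p.nF_v * p.k_L) / (p.nF_v * p.k_L) < 1e-5

    def test_nonnegative_components(self, kala_p, kala_th):
        t = np.geomspace(1e-3, 1e3, 300)
        assert np.all(K.f_pp(t, kala_p) >= 0)
        assert np.all(K.f_pe(t, kala_p, kala_th) >= 0)
        assert np.all(K.f_cet(t, kala_th) >= 0)


class TestThermalComponents:
    def test_pe_zero_at_onset_and_without_drive(self, kala_p):
        th = ThermalParams(k_qbf=0.1, k_minus_qbf=0.01)
        assert K.f_pe(0.0, kala_p, th) == 0.0
        th0 = ThermalParams(k_qbf=0.0, k_minus_qbf=0.05)
        t = np.linspace(0, 100, 50)
        np.testing.assert_allclose(K.f_pe(t, kala_p, th0), 0.0)

    def test_pe_steady_state_term_by_term(self, kala_p):
        # independent hand evaluation of the closed-form limit
        th = ThermalParams(k_qbf=0.1, k_minus_qbf=0.01)
        r = 0.1 / 0.11
        q_ss = 0.85 * 1.5 / 4.3 + 0.15
        expected = 2.0 * r * (1.0 + (1.0 - q_ss) * r)
        assert K.f_pe_steady(kala_p, th) == pytest.approx(expected, rel=1e-12)
        assert K.f_pe(1e5, kala_p, th) == pytest.approx(expected, rel=1e-9)

    def test_pe_rejects_zero_total_rate(self, kala_p):
        with pytest.raises(ValueError):
            K.f_pe(1.0, kala_p, ThermalParams(k_qbf=0.0, k_minus_qbf=0.0))

    def test_cet_single_stage_is_saturating_exponential(self):
        th = ThermalParams(k_qbf=0.1, k_minus_qbf=0.01, IP_amp=0.45, k_IP=0.02, N_IP=1)
        t = np.linspace(0, 400, 100)
        np.testing.assert_allclose(
            K.f_cet(t, th), 0.45 * (1 - np.exp(-0.02 * t)), rtol=1e-12, atol=1e-14
        )

    def test_cet_delay_and_steepness_grow_with_stage_count(self):
        t_half = []
        t = np.linspace(0, 2000, 20001)
        for n in (1, 3, 6, 9):
            th = ThermalParams(0.1, 0.01, IP_amp=1.0, k_IP=0.02, N_IP=n)
            y = K.f_cet(t, th)
            assert y[0] == 0.0
            t_half.append(t[np.searchsorted(y, 0.5)])
        assert all(np.diff(t_half) > 0)  # rising delay with N

    def test_cet_rejects_bad_stage_count(self):
        for bad in (0, 10, 2.5, True):
            with pytest.raises(ValueError):
                ThermalParams(0.1, 0.01, IP_amp=0.4, N_IP=bad)

    def test_fia_baseline_and_limits(self, kala_p, kala_th):
        assert K.f_fia(0.0, kala_p, kala_th) == pytest.approx(1.0, abs=1e-12)
        # photochemical-only limit
        th0 = ThermalParams(k_qbf=0.0, k_minus_qbf=0.05, IP_amp=0.0)
        t = np.geomspace(0.01, 1000.0, 100)
        np.testing.assert_allclose(K.f_fia(t, kala_p, th0), 1.0 + K.f_pp(t, kala_p))

    def test_fia_maximum_near_five_for_worked_example(self, kala_p, kala_th):
        t = np.geomspace(0.01, 1000.0, 2000)
        fm = K.f_fia(t, kala_p, kala_th).max()
        assert 4.5 < fm < 5.5


class TestFluorescenceYield:
    def test_unit_boltzmann_half(self):
        r = YieldRates(kf=1.0, kw=0.0, ke=0.0, ky=0.0, kd=1.0, N=1.0, psi0=0.3)
        assert K.fluor_yield(0.0, 0.0, 0.3, r) == pytest.approx(0.5, rel=1e-12)

    def test_no_rc_quenching_gives_antenna_limit(self):
        r = YieldRates(kf=1.0, kw=0.25)
        for psi in (-2.0, 0.0, 5.0):
            assert K.fluor_yield(0.7, 0.2, psi, r) == pytest.approx(1 / 1.25, rel=1e-12)

    def test_large_field_gives_antenna_limit(self):
        r = YieldRates(kf=1.0, kw=0.25, ke=2.0, ky=1.0, kd=0.5, N=4.0)
        assert K.fluor_yield(1.0, 1.0, 60.0, r) == pytest.approx(1 / 1.25, rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        psi=st.floats(-5, 5),
        dpsi=st.floats(0.01, 3),
        th1=st.floats(0, 1),
        th2=st.floats(0, 1),
    )
    def test_yield_increases_with_potential(self, psi, dpsi, th1, th2):
        r = YieldRates(kf=1.0, kw=0.3, ke=2.0, ky=0.8, kd=0.4, N=4.0, psi0=0.5)
        assert K.fluor_yield(th1, th2, psi + dpsi, r) > K.fluor_yield(th1, th2, psi, r)

    def test_open_center_gains_more_from_potential_rise(self):
        r = YieldRates(kf=1.0, kw=0.3, ke=2.0, ky=0.8, kd=0.1, N=4.0, psi0=0.5)
        for psi, dpsi in [(0.0, 1.0), (0.5, 0.5), (-1.0, 2.0)]:
            gain_open = K.fluor_yield(1, 1, psi + dpsi, r) - K.fluor_yield(1, 1, psi, r)
            gain_closed = K.fluor_yield(0, 0, psi + dpsi, r) - K.fluor_yield(0, 0, psi, r)
            assert gain_open > gain_closed

    def test_validation(self):
        r = YieldRates(kf=1.0)
        with pytest.raises(ValueError):
            K.fluor_yield(1.5, 0.0, 0.0, r)
        with pytest.raises(ValueError):
            YieldRates(kf=0.0)
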