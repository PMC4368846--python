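"""Closed-form forward model of the OJIP fluorescence induction curve.

The variable fluorescence of a dark-adapted leaf or algal sample during a
saturating light pulse is modelled as the sum of three components, each an
increment over the F_o = 1 baseline:

* ``F^PP`` -- photochemical: release of Q_A quenching by reversible
  photoreduction (closure) of reaction centers, with a heterogeneous
  beta-fraction of Q_B-nonreducing centers in which re-oxidation of Q_A^-
  is suppressed and a second excitation can transiently double-reduce the
  acceptor pair.
* ``F^PE`` -- photo-electrochemical: the J-I rise (roughly 2-50 ms) driven
  by lumenal proton-transfer reactions at the Q_A-Q_B site, forward rate
  k_qbf and dark reversal k_-qbf.
* ``F^CET`` -- photo-electric: the sigmoidal I-P rise (roughly 50-500 ms)
  attributed to the proton-motive force built by PSI-driven cyclic electron
  transport, modelled as an N-stage first-order cascade (Erlang CDF).

Every function accepts scalar or array time arguments (ms) and returns a
matching shape.  Connectivity between photosynthetic units and donor-side
quenching are assumed negligible throughout.
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .params import PhotochemParams, ThermalParams, YieldRates

__all__ = [
    "q_open_closure",
    "q_nonreducing_closure",
    "q_total",
    "q_dark",
    "f_pp1",
    "f_pp2",
    "f_pp",
    "f_pp_steady",
    "f_pe",
    "f_pe_steady",
    "f_cet",
    "f_fia",
    "fluor_yield",
]

# Below this total rate (ms^-1) the saturating-exponential closure term is
# evaluated by its first-order series to avoid 0/0.
_RATE_EPS = 1e-12


def _check_time(t: np.ndarray) -> None:
    if np.any(t < 0):
        raise ValueError("time must be >= 0 ms")


def _asarray(t) -> tuple[np.ndarray, bool]:
    arr = np.asarray(t, dtype=float)
    return arr, arr.ndim == 0


def _ret(x: np.ndarray, scalar: bool):
    return float(x) if scalar else x


def q_open_closure(t, k_L: float, k_AB: float):
    """Fraction of Q_B-reducing (open-pool) centers photochemically closed at time t.

    Solves dq/dt = k_L (1 - q) - k_AB q from q(0) = 0::

        q(t) = k_L / (k_L + k_AB) * (1 - exp(-(k_L + k_AB) t))

    The value saturates at k_L / (k_L + k_AB) < 1: in continuous light the
    closed fraction equilibrates below unity because dark re-oxidation of
    Q_A^- competes with its photoreduction.
    """
    if k_L <= 0:
        raise ValueError(f"k_L must be > 0, got {k_L}")
    if k_AB < 0:
        raise ValueError(f"k_AB must be >= 0, got {k_AB}")
    t, scalar = _asarray(t)
    _check_time(t)
    s = k_L + k_AB
    if s < _RATE_EPS:
        return _ret(k_L * t, scalar)
    q = (k_L / s) * (-np.expm1(-s * t))
    return _ret(q, scalar)


def q_nonreducing_closure(t, k_L: float):
    """Closure fraction of the Q_B-nonreducing pool (k_AB ~ 0): 1 - exp(-k_L t)."""
    if k_L <= 0:
        raise ValueError(f"k_L must be > 0, got {k_L}")
    t, scalar = _asarray(t)
    _check_time(t)
    return _ret(-np.expm1(-k_L * t), scalar)


def q_total(t, p: PhotochemParams):
    """Heterogeneous closed fraction: (1-beta) open-pool + beta nonreducing-pool."""
    t, scalar = _asarray(t)
    _check_time(t)
    q = (1.0 - p.beta) * q_open_closure(t, p.k_L, p.k_AB) + p.beta * q_nonreducing_closure(t, p.k_L)
    return _ret(q, scalar)


def q_dark(dt, q_t0: float, k_AB: float):
    """Re-opening of closed centers in the dark: q(t0) * exp(-k_AB dt)."""
    if not 0.0 <= q_t0 <= 1.0:
        raise ValueError(f"q_t0 must be in [0, 1], got {q_t0}")
    if k_AB < 0:
        raise ValueError(f"k_AB must be >= 0, got {k_AB}")
    dt, scalar = _asarray(dt)
    _check_time(dt)
    return _ret(q_t0 * np.exp(-k_AB * dt), scalar)


def f_pp1(t, p: PhotochemParams):
    """Variable fluorescence from first-hit closure: nF_v * q_total(t)."""
    t, scalar = _asarray(t)
    return _ret(p.nF_v * q_total(t, p), scalar)


def f_pp2(t, p: PhotochemParams):
    """Second-hit contribution of the beta-fraction.

    beta * nF_v * q_beta(t) * (1 - exp(-phi k_L t)) * exp(-k_2AB t);
    both the value and the first derivative vanish at t = 0, giving this
    term its S-shaped onset.
    """
    t, scalar = _asarray(t)
    _check_time(t)
    v = (
        p.beta
        * p.nF_v
        * q_nonreducing_closure(t, p.k_L)
        * (-np.expm1(-p.phi * p.k_L * t))
        * np.exp(-p.k_2AB * t)
    )
    return _ret(v, scalar)


def f_pp(t, p: PhotochemParams):
    """Total photochemical variable fluorescence F^PP = F^PP1 + F^PP2.

    Initial slope is nF_v * k_L, independent of k_AB (F^PP2 starts with zero
    slope), so the earliest rise reads the excitation rate alone.
    """
    t, scalar = _asarray(t)
    return _ret(f_pp1(t, p) + f_pp2(t, p), scalar)


def f_pp_steady(p: PhotochemParams) -> float:
    """Asymptotic steady state of F^PP in continuous light.

    nF_v * [(1-beta) k_L/(k_L+k_AB) + beta]: the second-hit term decays away
    (t >> 1/k_2AB) while the beta-fraction closes completely.  With beta = 0
    this reduces to nF_v * k_L/(k_L+k_AB); with k_AB = 0 (e.g. DCMU-blocked
    electron transfer) it reaches the full nF_v.
    """
    s = p.k_L + p.k_AB
    if s <= 0:
        raise ValueError("k_L + k_AB must be > 0")
    return p.nF_v * ((1.0 - p.beta) * p.k_L / s + p.beta)


def _pe_relax(t: np.ndarray, th: ThermalParams) -> np.ndarray:
    s = th.k_qbf + th.k_minus_qbf
    if s <= 0:
        raise ValueError("k_qbf + k_minus_qbf must be > 0")
    return -np.expm1(-s * t)


def f_pe(t, p: PhotochemParams, th: ThermalParams):
    """Photo-electrochemical component of the J-I phase (increment over F_o).

    With E(t) = 1 - exp(-(k_qbf + k_-qbf) t) and R = k_qbf/(k_qbf + k_-qbf)::

        F^PE(t) = nF_v * E(t) * R * (1 + (1 - q(t)) * E(t) * R)

    q(t) is the heterogeneous closed fraction; the bracketed factor expresses
    the extra de-quenching available in still-open centers.  Zero at t = 0
    and identically zero when k_qbf = 0 (no forward drive).
    """
    t, scalar = _asarray(t)
    _check_time(t)
    e = _pe_relax(t, th)
    r = th.k_qbf / (th.k_qbf + th.k_minus_qbf)
    occ = e * r
    v = p.nF_v * occ * (1.0 + (1.0 - q_total(t, p)) * occ)
    return _ret(v, scalar)


def f_pe_steady(p: PhotochemParams, th: ThermalParams) -> float:
    """t -> infinity limit of F^PE with the closed fraction at its steady state."""
    s = th.k_qbf + th.k_minus_qbf
    if s <= 0:
        raise ValueError("k_qbf + k_minus_qbf must be > 0")
    r = th.k_qbf / s
    q_ss = (1.0 - p.beta) * p.k_L / (p.k_L + p.k_AB) + p.beta
    return p.nF_v * r * (1.0 + (1.0 - q_ss) * r)


def f_cet(t, th: ThermalParams):
    """Photo-electric I-P component: IP_amp times an N_IP-stage cascade CDF.

    The sigmoidal delay-then-rise of the I-P phase is modelled as the output
    of N_IP identical first-order stages in series (tanks-in-series), whose
    step response is the Erlang CDF -- the regularized lower incomplete gamma
    function P(N_IP, k_IP t).  N_IP = 1 recovers a plain saturating
    exponential; larger N_IP increases both delay and steepness.  Saturates
    at IP_amp.
    """
    n = th.N_IP
    if not (isinstance(n, int) and not isinstance(n, bool)) or not 0 < n < 10:
        raise ValueError(f"N_IP must be an integer in (0, 10), got {n!r}")
    t, scalar = _asarray(t)
    _check_time(t)
    v = th.IP_amp * special.gammainc(n, th.k_IP * t)
    return _ret(v, scalar)


def f_fia(t, p: PhotochemParams, th: ThermalParams):
    """Full simulated induction curve: F^FIA(t) = 1 + F^PP + F^PE + F^CET.

    The F_o baseline enters exactly once; each component is an increment
    that vanishes at t = 0, so F^FIA(0) = 1.
    """
    t, scalar = _asarray(t)
    v = 1.0 + f_pp(t, p) + f_pe(t, p, th) + f_cet(t, th)
    return _ret(v, scalar)


def fluor_yield(theta1: float, theta2: float, psi, r: YieldRates):
    """Fluorescence quantum yield with antenna, RC and photo-electric quenching.

    phi_f = 1 / (1 + kw/kf + [theta1 (ke+ky) + theta2 ky + kd] / (kf N)
                 * exp(psi0 - psi))

    theta1, theta2 in [0, 1] are the RC fractions with unaffected and with
    acceptor-side-inhibited charge stabilization; (1,1) describes open and
    (0,0) closed centers.  An increase in the membrane potential psi (RT/F
    units) suppresses occupancy of the charge-separated state via the
    Boltzmann factor and so raises the yield; as psi -> infinity the RC term
    vanishes and the yield tends to the antenna-only limit 1/(1 + kw/kf).
    """
    for name, th in (("theta1", theta1), ("theta2", theta2)):
        if not 0.0 <= th <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {th}")
    psi_arr, scalar = _asarray(psi)
    rc = (theta1 * (r.ke + r.ky) + theta2 * r.ky + r.kd) / (r.kf * r.N)
    y = 1.0 / (1.0 + r.kw / r.kf + rc * np.exp(r.psi0 - psi_arr))
    return _ret(y, scalar)
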