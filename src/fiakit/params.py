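"""Parameter records for the fluorescence-induction kinetic model.

Units are milliseconds for time and ms**-1 for all rate constants.
Fluorescence values are normalized to the dark-adapted minimum, F_o = 1,
so every variable-fluorescence amplitude is expressed in F_o units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _replace
from typing import Mapping

__all__ = [
    "PhotochemParams",
    "ThermalParams",
    "YieldRates",
    "intensity_to_kL",
    "KL_PER_INTENSITY",
]

#: Default linear light-intensity -> excitation-rate map: an incident PAR of
#: ~2000 umol photons m^-2 s^-1 at the leaf surface corresponds globally to
#: k_L ~ 1 ms^-1 across a wide range of plant species.
KL_PER_INTENSITY = 1.0 / 2000.0

# Default search ranges for the second-hit tuning parameters.
PHI_RANGE = (0.1, 0.5)
K2AB_RANGE = (0.05, 0.5)


def intensity_to_kL(intensity: float, kl_per_intensity: float = KL_PER_INTENSITY) -> float:
    """Map actinic intensity (umol photons m^-2 s^-1) to excitation rate k_L (ms^-1).

    The default proportionality (1 ms^-1 per 2000 umol photons m^-2 s^-1) is an
    empirical cross-species average; pass ``kl_per_intensity`` to override.
    """
    if intensity < 0:
        raise ValueError(f"intensity must be >= 0, got {intensity}")
    return intensity * kl_per_intensity


@dataclass(frozen=True)
class PhotochemParams:
    """Rate constants and fractions governing the photochemical component F^PP.

    Attributes
    ----------
    k_L : float
        Light excitation rate (photoreduction rate of Q_A), ms^-1.
    k_AB : float
        Dark re-oxidation rate of Q_A^- by Q_B, ms^-1.
    nF_v : float
        Maximal normalized variable fluorescence at 100 % Q_A reduction,
        dimensionless (F_o units).
    beta : float
        Fraction of Q_B-nonreducing reaction centers (k_AB ~ 0 in this pool).
    phi : float
        Second-hit electron-trapping efficiency in the beta-fraction,
        usually in the range 0.1-0.5.
    k_2AB : float
        Re-oxidation rate of the double-reduced acceptor pair, ms^-1,
        usually in the range 0.05-0.5.
    k_slow : float
        Dark relaxation rate of the closed beta-fraction (the slow decay
        component of short-pulse tails, ~0.02 ms^-1).
    """

    k_L: float
    k_AB: float
    nF_v: float
    beta: float = 0.0
    phi: float = 0.3
    k_2AB: float = 0.2
    k_slow: float = 0.02

    def __post_init__(self) -> None:
        if self.k_L <= 0:
            raise ValueError(f"k_L must be > 0, got {self.k_L}")
        if self.k_AB < 0 or self.k_2AB < 0 or self.k_slow < 0:
            raise ValueError("rate constants must be >= 0")
        if self.nF_v <= 0:
            raise ValueError(f"nF_v must be > 0, got {self.nF_v}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi must be in [0, 1], got {self.phi}")

    def replace(self, **changes) -> "PhotochemParams":
        return _replace(self, **changes)

    def to_dict(self) -> dict:
        """Flat report mapping using the field's conventional parameter names."""
        return {
            "kL": self.k_L,
            "kAB": self.k_AB,
            "nFv": self.nF_v,
            "beta": self.beta,
            "phi": self.phi,
            "k2AB": self.k_2AB,
            "k_slow": self.k_slow,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhotochemParams":
        return cls(
            k_L=float(d["kL"]),
            k_AB=float(d["kAB"]),
            nF_v=float(d["nFv"]),
            beta=float(d.get("beta", 0.0)),
            phi=float(d.get("phi", 0.3)),
            k_2AB=float(d.get("k2AB", 0.2)),
            k_slow=float(d.get("k_slow", 0.02)),
        )


@dataclass(frozen=True)
class ThermalParams:
    """Parameters of the thermal-phase components F^PE (J-I) and F^CET (I-P).

    k_qbf / k_minus_qbf are the forward (light) and reversal (dark) rate
    constants of the photo-electrochemical transfer reaction; IP_amp, k_IP,
    k_minus_IP and the sigmoidicity integer N_IP shape the I-P rise attributed
    to PSI-driven cyclic electron transport.
    """

    k_qbf: float
    k_minus_qbf: float
    IP_amp: float = 0.0
    k_IP: float = 0.02
    k_minus_IP: float = 0.001
    N_IP: int = 3

    def __post_init__(self) -> None:
        for name in ("k_qbf", "k_minus_qbf", "k_IP", "k_minus_IP"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.IP_amp < 0:
            raise ValueError(f"IP_amp must be >= 0, got {self.IP_amp}")
        n = self.N_IP
        if not (isinstance(n, (int,)) and not isinstance(n, bool)):
            raise ValueError(f"N_IP must be an integer, got {n!r}")
        if not 0 < n < 10:
            raise ValueError(f"N_IP must satisfy 0 < N_IP < 10, got {n}")

    def replace(self, **changes) -> "ThermalParams":
        return _replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "kqbf": self.k_qbf,
            "k_qbf_rev": self.k_minus_qbf,
            "IP": self.IP_amp,
            "kIP": self.k_IP,
            "kIP_rev": self.k_minus_IP,
            "NIP": self.N_IP,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThermalParams":
        return cls(
            k_qbf=float(d["kqbf"]),
            k_minus_qbf=float(d["k_qbf_rev"]),
            IP_amp=float(d.get("IP", 0.0)),
            k_IP=float(d.get("kIP", 0.02)),
            k_minus_IP=float(d.get("kIP_rev", 0.001)),
            N_IP=int(d.get("NIP", 3)),
        )


@dataclass(frozen=True)
class YieldRates:
    """Rate constants of the fluorescence quantum-yield expression.

    kf, kw are radiative and heat-loss rates in the antenna (N antennas per
    reaction center); ke, ky, kd are photochemical trapping, photo-
    electrochemical trapping and non-radiative dissipation rates in the RC.
    psi0 is the redox potential of the charge-separated state in RT/F units.
    All rates share one arbitrary common unit.
    """

    kf: float
    kw: float = 0.0
    ke: float = 0.0
    ky: float = 0.0
    kd: float = 0.0
    N: float = 1.0
    psi0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kf", "kw", "ke", "ky", "kd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kf == 0:
            raise ValueError("kf must be > 0 (radiative rate cannot vanish)")
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
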