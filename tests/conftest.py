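import numpy as np
import pytest

import fiakit as fk


@pytest.fixture(scope="session")
def kala_p():
    """Worked-example photochemical parameters (Kalanchoe leaf, 3000 umol)."""
    return fk.kalanchoe_photochem()


@pytest.fixture(scope="session")
def kala_th():
    return fk.kalanchoe_thermal()


@pytest.fixture(scope="session")
def two_pulse_noiseless(kala_p, kala_th):
    """Noiseless default two-pulse fixture (sSP at 10 us, SP at 50 us)."""
    return fk.make_two_pulse_fixture(
        kala_p, kala_th, resolution=0.01, sp_resolution=0.05
    )


@pytest.fixture(scope="session")
def fitted_noiseless(two_pulse_noiseless):
    """Full pipeline run on the noiseless fixture (shared: it is the
    expensive step several recovery tests check from different angles)."""
    ssp, sp = two_pulse_noiseless
    est = fk.two_pulse_analysis(ssp, sp)
    dec = fk.decompose_ojip(sp, est)
    return est, dec


@pytest.fixture(scope="session")
def photochem_only_sp(kala_p):
    """A long pulse driven by the photochemical component alone."""
    proto = fk.PulseProtocol.single_pulse(1000.0, 3000.0, resolution=0.05)
    return fk.simulate(proto, kala_p, fk.ThermalParams(0.0, 0.0))


def rel_err(est, true):
    return abs(est - true) / abs(true)
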