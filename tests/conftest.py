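import numpy as np
import pytest

import hemoconn as hc


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def coupled_pair_phases():
    """Phases of a unidirectionally coupled oscillator pair (2→1) with known
    parameters, at the 2 Hz inference rate; session-scoped fixture reused by
    several estimator tests."""
    osc = [hc.OscillatorSpec(0.10, 0.05), hc.OscillatorSpec(0.16, 0.05)]
    coupling = [hc.CouplingSpec(1, 0, 0.3)]
    phi = hc.simulate_coupled_phases(osc, coupling, 600.0, 0.01, seed=11)
    return hc.decimate_phases(phi, 0.01, 2.0)


@pytest.fixture(scope="session")
def two_region_recording():
    """One coupled region pair (LPFC→RPFC, band III) plus an uncoupled
    control pair (LMC, RMC), one channel per region, 600 s at 10 Hz."""
    osc = [
        hc.LatentOscillator(hc.OscillatorSpec(0.080, 0.05, 0.0), "III", ("LPFC",)),
        hc.LatentOscillator(hc.OscillatorSpec(0.100, 0.05, 1.0), "III", ("RPFC",)),
        hc.LatentOscillator(hc.OscillatorSpec(0.085, 0.05, 2.0), "III", ("LMC",)),
        hc.LatentOscillator(hc.OscillatorSpec(0.105, 0.05, 3.0), "III", ("RMC",)),
    ]
    coupling = [hc.CouplingSpec(0, 1, 0.15), hc.CouplingSpec(1, 0, 0.15)]
    phi = hc.simulate_coupled_phases([o.spec for o in osc], coupling,
                                     600.0, 0.01, seed=21)
    phases = hc.decimate_phases(phi, 0.01, 10.0)
    return hc.render_observations(
        phases, osc, {"III": 1.0}, sampling_rate=10.0,
        n_channels_per_region=1, noise_sd=0.3, drift_amplitude=0.3, seed=22)
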