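import numpy as np
import pytest

import ibeat as ib


@pytest.fixture(scope="session")
def stopping():
    return ib.StoppingModel()


@pytest.fixture(scope="session")
def geometry():
    return ib.MediumGeometry(z_d=0.055)


@pytest.fixture(scope="session")
def mono_bragg(stopping):
    """Single-ion 9.4 MeV Bragg curve on a fine grid."""
    r = ib.csda_range(9.4, stopping)
    z = np.arange(0.0, 1.3 * r, 2e-6)
    return ib.bragg_curve(9.4, z, stopping)


@pytest.fixture(scope="session")
def transducer():
    """10 MHz, 60% fractional bandwidth synthetic kernel at 100 MS/s."""
    return ib.make_transducer_ir(10e6, 0.6, 1e-8)


@pytest.fixture(scope="session")
def small_trace(mono_bragg, geometry, stopping):
    """Direct-segment pressure trace of a mono-energetic 9.4 MeV bunch."""
    beam = ib.BeamParams(n_i=1e8, sigma_r=1.5e-3)
    r = ib.csda_range(9.4, stopping)
    t_lo, t_hi = ib.direct_window(geometry, r, beam.sigma_r, pad=1e-6)
    n = int((t_hi - t_lo) / 1e-8)
    return ib.pressure_trace(mono_bragg, beam, geometry, t_lo, 1e-8, n, segments=("direct",))
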