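import numpy as np
import pytest

from glyx.electrokinetics import Electrolyte, GlycocalyxModel
from glyx.zstack import RoiMask, ZStack


@pytest.fixture(scope="session")
def electrolyte() -> Electrolyte:
    """Physiological saline at 25 C."""
    return Electrolyte()


@pytest.fixture(scope="session")
def glycocalyx() -> GlycocalyxModel:
    """Native red-cell glycocalyx with calibrated defaults."""
    return GlycocalyxModel()


def make_manual_stack(n_slices=48, shape=(8, 8), z_step=0.2,
                      membrane_peak=12, probe_slices=(13, 32),
                      probe_value=100.0, nuclei_value=0.0,
                      probe_profile=None) -> ZStack:
    """Hand-built noiseless stack: Gaussian membrane peak, boxcar probe."""
    z = np.arange(n_slices)
    membrane = 50.0 * np.exp(-0.5 * ((z - membrane_peak) / 1.5) ** 2)
    probe = np.zeros(n_slices)
    if probe_profile is not None:
        probe[:len(probe_profile)] = probe_profile
    elif probe_slices is not None:
        lo, hi = probe_slices
        probe[lo:hi + 1] = probe_value
    channels = {
        "membrane": np.broadcast_to(membrane[:, None, None],
                                    (n_slices, *shape)).copy(),
        "probe": np.broadcast_to(probe[:, None, None],
                                 (n_slices, *shape)).copy(),
    }
    if nuclei_value > 0:
        nuc = np.where(z <= membrane_peak, nuclei_value, 0.0)
        channels["nuclei"] = np.broadcast_to(nuc[:, None, None],
                                             (n_slices, *shape)).copy()
    return ZStack(channels=channels, z_step=z_step)


@pytest.fixture
def full_roi() -> RoiMask:
    return RoiMask(np.ones((8, 8), dtype=bool))
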