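import warnings

import numpy as np
import pytest

import hybridose as h


@pytest.fixture(scope="session")
def nuclide():
    return h.load_nuclide()


@pytest.fixture(scope="session")
def electron_only_nuclide():
    from hybridose.nuclide import Emission, NuclideData

    return NuclideData("e-test", 6.0067, (Emission("electron", 100.0, 1.0),))


@pytest.fixture(scope="session")
def kernel49(nuclide):
    """Kernel on a 49^3 grid at the clinical 4.418 mm voxel."""
    return h.build_kernel(nuclide, 4.418, 24)


@pytest.fixture(scope="session")
def calibration_curves():
    """Segmentation threshold curves over the full sphere/SBR training grid.

    Built once per session; the acquisition uses the clinical geometry with
    Poisson noise and a fixed seed.
    """
    acq = h.AcquisitionSpec(rng_seed=999)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return h.build_calibration_curves(
            [12, 20, 50, 100], [2, 4, 8, 16, 32], acq, grid_shape=(48, 48, 48)
        )


@pytest.fixture(scope="session")
def pediatric_phantom():
    spec = h.reference_phantom(age_scale=h.PEDIATRIC_AGE_SCALE, grid_shape=(72, 72, 72))
    labels, mu, mass = h.build_phantom(spec)
    return spec, labels, mu, mass, h.region_masks(labels, mass)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
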