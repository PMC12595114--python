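import numpy as np
import pytest

from lobemap.core import VoxelGrid
from lobemap.phantoms import Metastasis, PhantomSpec, Vessel

ANISO = (2.9, 1.22, 1.22)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def grid():
    """Factory for intensity grids with unit spacing by default."""

    def make(data, spacing=(1.0, 1.0, 1.0), role="intensity"):
        return VoxelGrid(np.asarray(data), spacing, role)

    return make


@pytest.fixture(scope="session")
def small_phantom_spec():
    """One z-cylinder (radius 10 μm) plus one mono sphere and one poly sphere,
    in a volume small enough to run the whole pipeline in well under a second."""
    ext_z = 31 * 2.9
    return PhantomSpec(
        shape=(32, 96, 96),
        spacing=ANISO,
        vessels=[Vessel(p0=(0.0, 30.0, 30.0), p1=(ext_z, 30.0, 30.0), radius_um=10.0)],
        metastases=[
            Metastasis(centre_um=(45.0, 70.0, 35.0), semi_axes_um=(15.0, 15.0, 15.0),
                       code_fractions={5: 1.0}),
            Metastasis(centre_um=(45.0, 35.0, 80.0), semi_axes_um=(14.0, 14.0, 14.0),
                       code_fractions={1: 0.6, 2: 0.4}),
            # below the 9000 μm³ filter
            Metastasis(centre_um=(30.0, 80.0, 80.0), semi_axes_um=(8.0, 8.0, 8.0),
                       code_fractions={4: 1.0}),
        ],
        seed=99,
    )
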