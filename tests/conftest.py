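import numpy as np
import pytest

from panc13c import (
    AcquisitionParams,
    CSIDataset,
    PhantomSpec,
    RegionSpec,
    build_phantom,
)


@pytest.fixture
def small_acq() -> AcquisitionParams:
    """8x8 matrix, 64-point FIDs: large enough for spectra, cheap to DFT."""
    return AcquisitionParams(
        matrix=(8, 8),
        fov=(40.0, 40.0),
        n_fid_points=64,
        tr=0.030,
        spectral_width=6000.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150907)


def make_dataset(acq: AcquisitionParams, fids: np.ndarray) -> CSIDataset:
    return CSIDataset(fids=fids, acq=acq)


@pytest.fixture
def small_phantom():
    spec = PhantomSpec(
        grid=(16, 16),
        regions=(
            RegionSpec(name="pancreas", stage="kc_9mo", center=(0.5, 0.45), radii=(0.18, 0.25)),
        ),
    )
    return build_phantom(spec, seed=1)
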