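import numpy as np
import pytest

import mdtmap as m


@pytest.fixture(scope="session")
def small_phantom() -> m.PhantomVolume:
    """32^3 head phantom with all compartments present."""
    return m.build_phantom((32, 32, 32), 1.0, ribbon_thickness_mm=3.0)


@pytest.fixture(scope="session")
def tissue_csf_mixture() -> m.CompartmentMixture:
    """The canonical 70% tissue (0.7) / 30% CSF (3.0) partial-volume voxel."""
    return m.CompartmentMixture(
        (
            m.DiffusionCompartment(md=0.7, fraction=0.7),
            m.DiffusionCompartment(md=m.FREE_WATER_DIFFUSIVITY, fraction=0.3),
        )
    )


@pytest.fixture(scope="session")
def identity_geometry() -> m.StackGeometry:
    """Degenerate geometry whose forward sampling is (padded) identity."""
    return m.StackGeometry(
        in_plane_mm=(1.0, 1.0),
        slice_thickness_mm=1.0,
        slice_profile="boxcar",
        rotation_angles_deg=(0.0,),
    )


def central_crop(stack: np.ndarray, shape) -> np.ndarray:
    """Crop the central ``shape`` region (identity stacks are slice-padded)."""
    off = [(s2 - s1) // 2 for s1, s2 in zip(shape, stack.shape)]
    sl = tuple(slice(o, o + s) for o, s in zip(off, shape))
    return stack[sl]
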