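import numpy as np
import pytest

from vesselfd import PhantomSpec, make_vascular_phantom

SMALL = dict(
    image_size=256,
    od_center=(128.0, 38.0),
    fovea_center=(128.0, 128.0),
    od_radius=18.0,
    trunk_width_px=4.5,
    trunk_length_px=20.0,
)


def small_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """A 256-px phantom spec for fast unit tests (same geometry, halved)."""
    return PhantomSpec(seed=seed, **{**SMALL, **overrides})


@pytest.fixture(scope="session")
def default_phantom():
    """One full-size phantom shared across tests."""
    return make_vascular_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def small_phantom():
    return make_vascular_phantom(small_spec(seed=1))


@pytest.fixture(scope="session")
def phantom_ensemble():
    """Twenty seeded full-size phantoms (the ensemble the studies use)."""
    return [make_vascular_phantom(PhantomSpec(seed=s)) for s in range(20)]


def fovea_roi(bundle, k):
    from vesselfd.roi import ROISpec, circular_roi_mask

    spec = ROISpec(center=bundle.fovea_center, k=k,
                   od_radius=bundle.od_geometry.od_radius, anchor="fovea")
    return circular_roi_mask(spec, bundle.truth_vessels.shape)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160914)
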