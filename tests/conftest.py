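import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hiikit import (
    make_ellipsoid_phantom,
    make_lobulated_phantom,
    make_sphere_phantom,
    phantom_mask,
    resample_to_slices,
)


@pytest.fixture(scope="session")
def sphere_phantom_r20():
    """r=20 mm sphere at 0.5 mm isotropic spacing, with analytic truth."""
    return make_sphere_phantom(20.0, 0.5)


@pytest.fixture(scope="session")
def sphere_mask_r20(sphere_phantom_r20):
    vol, _ = sphere_phantom_r20
    return phantom_mask(vol)


@pytest.fixture(scope="session")
def phantom_suite():
    """The standard fixture suite as (name, mask, truth) triples, in memory.

    Mirrors what the `hii fixtures` command writes: a fine sphere, three
    prolate ellipsoids, a lobulated blob and a thick-slice sphere.
    """
    suite = []
    vol, truth = make_sphere_phantom(20.0, 0.5)
    suite.append(("sphere_r20", phantom_mask(vol), truth))
    for a in (10.0, 20.0, 40.0):
        vol, truth = make_ellipsoid_phantom(a, 10.0, 10.0, 0.5)
        suite.append((f"ellipsoid_a{a:.0f}", phantom_mask(vol), truth))
    vol, truth = make_lobulated_phantom(
        n_lobes=5, lobe_radius_range_mm=(5.0, 8.0), center_spread_mm=8.0,
        spacing_mm=0.5, seed=7,
    )
    suite.append(("lobulated_n5", phantom_mask(vol), truth))
    iso, truth = make_sphere_phantom(20.0, 1.0)
    sliced = resample_to_slices(iso, 5.0)
    suite.append(("sphere_sliced_5mm", phantom_mask(sliced), truth))
    return suite
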