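import numpy as np
import pytest

from actnet import netsim


@pytest.fixture(scope="session")
def study_pattern() -> netsim.StripePattern:
    """The stripe geometry used for the ABP experiments (2.5/17.5 um)."""
    return netsim.StripePattern(
        stripe_width=2.5,
        gap_width=17.5,
        pixel_size=0.267,
        image_shape=(192, 160),
        orientation="vertical",
    )


@pytest.fixture
def horizontal_segment_scene() -> netsim.SceneGroundTruth:
    """One straight horizontal bundle on a minimal pattern: exact
    noiseless pixel values are predictable on the path."""
    pattern = netsim.StripePattern(2.5, 17.5, 0.267, (64, 160))
    seg = netsim.BundleGroundTruth(
        segment_id=0,
        path=np.array([[32.0, 20.0], [32.0, 120.0]]),
        n=1,
        F_seg=0.0,
        actin_density_per_filament=100.0,
        abp_density_per_filament=30.0,
    )
    return netsim.SceneGroundTruth(
        pattern=pattern, segments=[seg], binding=netsim.BindingParams()
    )


def make_two_bundle_scene(n_a: int = 1, n_b: int = 3) -> netsim.SceneGroundTruth:
    """Two parallel horizontal bundles of different filament counts."""
    pattern = netsim.StripePattern(2.5, 17.5, 0.267, (96, 160))
    binding = netsim.BindingParams()
    F = 6.0
    segs = []
    for i, (row, n) in enumerate(((30.0, n_a), (66.0, n_b))):
        segs.append(
            netsim.BundleGroundTruth(
                segment_id=i,
                path=np.array([[row, 20.0], [row, 140.0]]),
                n=n,
                F_seg=F,
                actin_density_per_filament=120.0,
                abp_density_per_filament=netsim.binding_density(binding, n, F),
            )
        )
    return netsim.SceneGroundTruth(pattern=pattern, segments=segs, binding=binding)
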