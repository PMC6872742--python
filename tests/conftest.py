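"""Shared fixtures: tiny phantoms and networks sized for fast CPU tests."""

import numpy as np
import pytest

from seg2surv.preprocess import clip_intensities, crop_mask, crop_roi, mask_centroid
from seg2surv.synthetic import (
    CohortDistribution,
    PhantomSpec,
    SurvivalGenerator,
    generate_cohort,
    generate_tumor_mask,
    render_ct,
    render_pet,
)
from seg2surv.unet import UNet, UNetConfig


@pytest.fixture(scope="session")
def tiny_spec():
    return PhantomSpec(
        volume_shape=(32, 32, 16),
        tumor_radii=(5.0, 5.0, 3.0),
        lobularity=0.15,
        heterogeneity=0.5,
        vessel_count=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_phantom(tiny_spec):
    mask = generate_tumor_mask(tiny_spec)
    return {
        "spec": tiny_spec,
        "mask": mask,
        "ct": render_ct(mask, tiny_spec),
        "pet": render_pet(mask, tiny_spec),
    }


@pytest.fixture(scope="session")
def tiny_roi_pair(tiny_phantom):
    """Clipped CT ROI + aligned mask at the full 32x32x16 grid."""
    mask = tiny_phantom["mask"]
    roi = clip_intensities(crop_roi(tiny_phantom["ct"], mask, (32, 32, 16)))
    msk = crop_mask(mask, (32, 32, 16), mask_centroid(mask))
    return roi, msk


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 phantoms at 24x24x16 with the default planted survival signal."""
    dist = CohortDistribution(volume_shape=(24, 24, 16))
    return generate_cohort(12, dist, SurvivalGenerator(seed=5), seed=21)


@pytest.fixture(scope="session")
def micro_unet():
    """Smallest legal network (3 levels) in float64 for gradient work."""
    cfg = UNetConfig(in_shape=(16, 16, 8), base_channels=2, n_levels=3, seed=3)
    return UNet(cfg, dtype=np.float64)
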