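import numpy as np
import pytest

import noduleseg as ns


@pytest.fixture(scope="session")
def solid_truth():
    """Default isolated solid phantom (8 mm nodule, 20 HU noise)."""
    return ns.generate_thorax(ns.PhantomSpec())


@pytest.fixture(scope="session")
def solid_segmentation(solid_truth):
    """Default-config segmentation of the solid phantom, seeded at truth centroid."""
    seed = ns.centroid_of_mask(solid_truth.nodule_mask)
    mask, details = ns.segment_nodule(
        solid_truth.volume, [seed], "solid", return_details=True
    )
    return mask, details


def random_mask_quadruple(rng, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0)):
    """Four random masks on one grid (possibly empty), for metric tests."""
    masks = []
    for _ in range(4):
        p = rng.uniform(0.05, 0.6)
        masks.append(ns.BinaryMask(rng.random(shape) < p, spacing, (0, 0, 0)))
    return masks


def cube_mask(shape, lo, hi, spacing=(1.0, 1.0, 1.0)):
    data = np.zeros(shape, dtype=bool)
    data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return ns.BinaryMask(data, spacing, (0, 0, 0))
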