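"""Shared fixtures: one default phantom pair per session plus derived stages."""

from __future__ import annotations

import numpy as np
import pytest

from petct_register import (
    PhantomSpec,
    generate_phantom_pair,
    gfs_segment,
    normalize_intensity,
)
from petct_register.pet_preprocess import bspline_upsample, dtd_segment, median_filter


@pytest.fixture(scope="session")
def phantom0():
    """Default phantom pair (seed 0): (ct, pet, truth)."""
    return generate_phantom_pair(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def ct_normalized(phantom0):
    return normalize_intensity(phantom0[0])


@pytest.fixture(scope="session")
def pet_normalized(phantom0):
    return normalize_intensity(phantom0[1])


@pytest.fixture(scope="session")
def ct_features(ct_normalized):
    """GFS feature images for every CT slice of the default phantom."""
    n = ct_normalized.n_slices
    return [gfs_segment(s, i, n)[1] for i, s in enumerate(ct_normalized.slices)]


@pytest.fixture(scope="session")
def pet_features(phantom0, pet_normalized):
    """Full PET chain (upsample, median, DTD) feature images."""
    spec_factor = phantom0[0].slices[0].shape[0] // phantom0[1].slices[0].shape[0]
    n = pet_normalized.n_slices
    feats = []
    for i, s in enumerate(pet_normalized.slices):
        up = bspline_upsample(
            s, (s.shape[0] * spec_factor, s.shape[1] * spec_factor)
        )
        med = median_filter(up)
        feats.append(dtd_segment(med, i, n)[1])
    return feats


def small_spec(seed, n_slices=6):
    """A quick 64x64 phantom spec with margins scaled to the small frame."""
    return PhantomSpec(
        seed=seed, n_slices=n_slices, ct_shape=(64, 64), pet_shape=(16, 16),
        max_translation_px=4.0, pet_psf_sigma_px=1.0,
    )


def filled_disk(shape, center, radius):
    rr, cc = np.mgrid[0: shape[0], 0: shape[1]]
    return ((rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2).astype(float)
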