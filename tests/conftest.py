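"""Shared fixtures: desk-scale phantoms, atlas libraries, settings."""

from __future__ import annotations

import numpy as np
import pytest

from pallidex.label_fusion import SegmentationSettings
from pallidex.phantom import (
    CohortSpec,
    PhantomSpec,
    make_atlas_library,
    make_template,
)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """32³ phantom at 4 mm spacing: same geometry, 8x fewer voxels."""
    return PhantomSpec(grid_shape=(32, 32, 32), spacing=(4.0, 4.0, 4.0),
                       n_coarse_regions=6)


@pytest.fixture(scope="session")
def small_template(small_spec):
    return make_template(small_spec)


@pytest.fixture(scope="session")
def small_library(small_spec):
    return make_atlas_library(4, small_spec, seed=7)


@pytest.fixture(scope="session")
def clean_spec() -> PhantomSpec:
    """Noiseless, bias-free, texture-free, undeformed: construction oracle."""
    return PhantomSpec(grid_shape=(32, 32, 32), spacing=(4.0, 4.0, 4.0),
                       n_coarse_regions=6, noise_sd=0.0, bias_amplitude=0.0,
                       texture_amplitude=0.0, deform_amplitude_mm=0.0)


@pytest.fixture(scope="session")
def desk_spec() -> PhantomSpec:
    """The 64³ desk-scale configuration with reduced coarse regions."""
    return PhantomSpec(n_coarse_regions=8)


@pytest.fixture(scope="session")
def desk_template(desk_spec):
    return make_template(desk_spec)


@pytest.fixture(scope="session")
def desk_library(desk_spec):
    return make_atlas_library(6, desk_spec, seed=1000)


@pytest.fixture()
def fast_settings(desk_template):
    tvol, _, tcoarse = desk_template
    st = SegmentationSettings.fast()
    st.region_template = (tvol, tcoarse)
    return st


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
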