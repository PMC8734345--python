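"""Shared fixtures: small phantoms and atlases generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from kbplan import (
    PhantomConfig,
    build_atlas,
    generate_phantom,
    reference_dose,
    train_atlas_forests,
)
from kbplan.phantom import atlas_configs

# Small desk-scale grid: 32^3 at 6 mm spacing (192 mm extent holds the head;
# coarser spacing would collapse the 3 mm PTV margin to nothing).
SMALL_SHAPE = (32, 32, 32)
SMALL_SPACING = (6.0, 6.0, 6.0)


def small_config(**overrides) -> PhantomConfig:
    kwargs = dict(grid_shape=SMALL_SHAPE, voxel_spacing=SMALL_SPACING, seed=11)
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_config())


@pytest.fixture(scope="session")
def small_dose(small_phantom):
    image, structures = small_phantom
    return reference_dose(image, structures)


@pytest.fixture(scope="session")
def tiny_library():
    configs = atlas_configs(4, seed=5, grid_shape=SMALL_SHAPE,
                            voxel_spacing=SMALL_SPACING)
    return build_atlas(configs)


@pytest.fixture(scope="session")
def tiny_forests(tiny_library):
    return train_atlas_forests(tiny_library)
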