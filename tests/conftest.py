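"""Shared fixtures: small seeded phantoms reused across the suite.

Rendered volumes are session-scoped because rendering + segmentation of even
a small volume takes seconds; tests must treat them as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from octindent.phantom import PhantomSpec, make_phantom, render_oct
from octindent.segmentation import build_thickness_map, mask_artifacts

#: Reference measurement conditions: 0.92 kPa under a 3-mm punch on a 0.5-mm
#: sheet of 14 kPa modulus (the combined-average tissue stiffness scale).
REF_STRESS = 0.92
REF_MODULUS = 14.0


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Featureless speckled sheet, small lateral extent (fully in-footprint)."""
    return PhantomSpec(
        true_modulus=REF_MODULUS,
        lateral_extent=(1.5, 1.5),
        speckle_contrast=0.3,
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_scene(small_spec):
    return make_phantom(small_spec)


@pytest.fixture(scope="session")
def vol_uncompressed(small_scene):
    return render_oct(small_scene, 0.0, seed=101)


@pytest.fixture(scope="session")
def vol_compressed(small_scene):
    return render_oct(small_scene, REF_STRESS, seed=102)


@pytest.fixture(scope="session")
def map_uncompressed(vol_uncompressed):
    return mask_artifacts(build_thickness_map(vol_uncompressed))


@pytest.fixture(scope="session")
def map_compressed(vol_compressed):
    return mask_artifacts(build_thickness_map(vol_compressed))


@pytest.fixture(scope="session")
def noiseless_spec() -> PhantomSpec:
    return PhantomSpec(
        true_modulus=REF_MODULUS,
        lateral_extent=(1.5, 1.5),
        speckle_contrast=0.0,
        rng_seed=0,
    )


@pytest.fixture(scope="session")
def noiseless_volume(noiseless_spec):
    return render_oct(make_phantom(noiseless_spec), 0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_map(noiseless_spec, noiseless_volume):
    return build_thickness_map(noiseless_volume)


def uniform_map(thickness_mm: float = 0.5, n: int = 40):
    """Hand-built perfectly uniform ThicknessMap for mask/score fixtures."""
    from octindent.segmentation import ThicknessMap

    t = np.full((n, n), thickness_mm)
    return ThicknessMap(
        top_depth=np.full((n, n), 0.1),
        bottom_depth=np.full((n, n), 0.1 + thickness_mm),
        thickness=t,
        mask=np.zeros((n, n), dtype=bool),
        lateral_pitch=(0.011, 0.011),
        axial_pitch=0.008,
    )
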