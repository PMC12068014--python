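"""Shared fixtures: a reference instrument, small scenes for unit tests and
the full-size scene used by the acceptance checks.

The reference instrument (water-dipping objective, NA 0.8, vacuum wavelength
0.804 µm, water at 1.33 everywhere outside the glass) is the package's fixed
choice for tests that need concrete optics; unit tests use a reduced ray
budget and raster so the full suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from tubeao import (
    ObjectiveModel,
    OpticalConfig,
    capillary_scene,
    compute_correction,
    gaussian_amplitude,
)
from tubeao.metrics import DefocusModel

NA = 0.8
WAVELENGTH = 0.804  # µm
N_WATER = 1.33
WAIST = 1.18


@pytest.fixture(scope="session")
def small_scene():
    """Nominal capillary at reduced ray budget for unit tests."""
    return capillary_scene(
        na=NA, wavelength=WAVELENGTH, n_rays=30_000, slm_shape=(128, 128)
    )


@pytest.fixture(scope="session")
def small_amp(small_scene):
    return gaussian_amplitude(small_scene.config.slm_shape, WAIST)


@pytest.fixture(scope="session")
def small_defocus(small_scene):
    return DefocusModel(
        n=small_scene.config.n_focus_medium,
        numerical_aperture=NA,
        k0=small_scene.config.k0,
    )


@pytest.fixture(scope="session")
def bottom_pattern_small(small_scene):
    """Correction pattern for the bottom-of-tube focus, reduced budget."""
    s = small_scene
    return compute_correction(s.tube, s.objective, s.config, s.focus_presets["bottom"])


@pytest.fixture(scope="session")
def study_scene():
    """Full-size study conditions: 250,000 rays on a 512x512 SLM raster."""
    return capillary_scene(na=NA, wavelength=WAVELENGTH)


@pytest.fixture(scope="session")
def study_patterns(study_scene):
    """The four named correction patterns at full size (top/centre/bottom/side)."""
    s = study_scene
    return {
        name: compute_correction(s.tube, s.objective, s.config, focus)
        for name, focus in s.focus_presets.items()
    }


@pytest.fixture(scope="session")
def study_amp(study_scene):
    return gaussian_amplitude(study_scene.config.slm_shape, WAIST)


@pytest.fixture(scope="session")
def study_defocus(study_scene):
    return DefocusModel(
        n=study_scene.config.n_focus_medium,
        numerical_aperture=NA,
        k0=study_scene.config.k0,
    )


def flat_like(pattern):
    """A zero-phase (no-correction) pattern on the same grid and mask."""
    return pattern.with_phase(np.where(pattern.valid_mask, 0.0, np.nan))
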