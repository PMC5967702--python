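"""Shared synthetic-scene fixtures.

Heavy scenes are session-scoped; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

import stereocanopy as sc


@pytest.fixture(scope="session")
def rig_500px() -> sc.CameraRig:
    """The field rig with pixel pitch chosen so ground disparity is 500 px
    (0.04 cm/px ground resolution) — used for metric-conversion tests."""
    return sc.CameraRig(
        focal_length=18.0, baseline=200.0, camera_height=1900.0, pixel_pitch=0.0037895
    )


@pytest.fixture(scope="session")
def rig() -> sc.CameraRig:
    """The scene-scale rig (ground disparity 40 px, 5 mm/px footprint)."""
    return sc.default_rig()


@pytest.fixture(scope="session")
def slab_scene(rig):
    """Full-coverage flat canopy slab at 500 mm, rendered."""
    spec = sc.SceneSpec(
        shape=(160, 224), coverage=1.0, canopy_family="slab", canopy_mode_mm=500.0, seed=1
    )
    truth = sc.generate_scene(spec)
    pair = sc.render_stereo_pair(truth, spec)
    return spec, truth, pair


@pytest.fixture(scope="session")
def mixed_scene(rig):
    """Patchy unimodal canopy over bare ground, rendered."""
    spec = sc.SceneSpec(
        shape=(240, 320), coverage=0.6, canopy_mode_mm=500.0, canopy_spread_mm=80.0, seed=7
    )
    truth = sc.generate_scene(spec)
    pair = sc.render_stereo_pair(truth, spec)
    return spec, truth, pair


@pytest.fixture(scope="session")
def flat_ground_scene(rig):
    """Bare textured ground — the self-calibration capture."""
    spec = sc.SceneSpec(shape=(240, 320), coverage=0.0, texture_strength=0.4, seed=11)
    truth = sc.generate_scene(spec)
    pair = sc.render_stereo_pair(truth, spec)
    return spec, truth, pair


@pytest.fixture(scope="session")
def mixed_disparity(mixed_scene, rig):
    """Computed disparity map for the mixed scene (shared across tests)."""
    _, truth, pair = mixed_scene
    d_range = sc.disparity_search_range(rig, -50, 900)
    return sc.compute_disparity(pair, rig, d_range)


def truth_disparity_map(truth, rig) -> sc.DisparityMap:
    """Exact DisparityMap built from scene truth (no matching noise)."""
    d = truth.disparity_px.astype(np.float32)
    return sc.DisparityMap(
        disparity=d,
        valid=np.ones_like(d, dtype=bool),
        d_min=int(np.floor(d.min())),
        d_max=int(np.ceil(d.max())),
    )
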