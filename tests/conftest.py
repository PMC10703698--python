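"""Shared fixtures: small, seeded synthetic scenes reused across test modules."""

import numpy as np
import pytest

from gemquant.synthetic import (
    ProbMapConfig,
    SceneConfig,
    render_probability_map,
    simulate_scene,
)


@pytest.fixture(scope="session")
def plane_scene():
    """Membrane-plane scene: 15 particles, margins wide enough that detector
    blobs are never clipped by the volume or lamella boundary."""
    cfg = SceneConfig(
        volume_shape=(192, 192, 110),
        voxel_size=1.37,
        lamella_thickness=110.0,
        structure_kind="plane",
        n_bound=10,
        bound_distance_mean=10.0,
        bound_distance_sd=6.0,
        n_background=5,
        min_separation=40.0,
        edge_margin=20.0,
        seed=1,
    )
    return simulate_scene(cfg)


@pytest.fixture(scope="session")
def plane_probmap(plane_scene):
    """Clean probability map with in-range blob sizes (no decoys, no noise)."""
    return render_probability_map(
        plane_scene, ProbMapConfig(blob_radius=16.4, peak_prob_range=(0.8, 1.0), seed=2)
    )


@pytest.fixture(scope="session")
def mito_like_scene():
    """The distance-recovery study condition: 200 bound particles at surface
    distances N(10, 6) nm from a membrane plane, 1.37 nm voxels."""
    cfg = SceneConfig(
        volume_shape=(512, 512, 160),
        voxel_size=1.37,
        lamella_thickness=200.0,
        structure_kind="plane",
        n_bound=200,
        bound_distance_mean=10.0,
        bound_distance_sd=6.0,
        n_background=0,
        seed=42,
    )
    return simulate_scene(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
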