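"""Generator contracts: placement distributions, determinism, rendering."""

import numpy as np
import pandas as pd
import pytest

from gemquant.errors import ConfigError, GeometryError, PlacementError
from gemquant.frap import fit_recovery, normalize_trace
from gemquant.synthetic import (
    ColocTimecourseConfig,
    ContrastParams,
    FrapSimConfig,
    ProbMapConfig,
    SceneConfig,
    missing_wedge_mask,
    render_density_volume,
    render_probability_map,
    simulate_coloc_timecourse,
    simulate_frap_traces,
    simulate_scene,
)


def small_scene_config(**overrides):
    base = dict(
        volume_shape=(128, 128, 96),
        voxel_size=1.37,
        lamella_thickness=100.0,
        structure_kind="plane",
        n_bound=5,
        bound_distance_mean=10.0,
        bound_distance_sd=6.0,
        n_background=3,
        min_separation=40.0,
        edge_margin=18.0,
        seed=7,
    )
    base.update(overrides)
    return SceneConfig(**base)


class TestSimulateScene:
    def test_degenerate_sd_places_all_at_the_mean(self):
        # sd=0 puts all centres on one plane; give the packing enough area
        truth = simulate_scene(small_scene_config(n_bound=20, bound_distance_sd=0.0,
                                                  n_background=0, edge_margin=0.0,
                                                  volume_shape=(256, 256, 96)))
        d = truth.particles.df["surface_distance_nm"]
        assert len(d) == 20
        assert np.allclose(d, 10.0)

    def test_empty_particle_request_gives_empty_set_nonempty_masks(self):
        truth = simulate_scene(small_scene_config(n_bound=0, n_background=0))
        assert len(truth.particles) == 0
        assert truth.structure_mask.n_true > 0
        assert truth.lamella_mask.n_true > 0

    def test_sample_mean_of_recorded_distances_obeys_lln(self, mito_like_scene):
        # n=200 draws from N(10, 6): sample mean within 3 sigma/sqrt(n) of 10
        d = mito_like_scene.particles.df["surface_distance_nm"].to_numpy()
        assert len(d) == 200
        assert abs(d.mean() - 10.0) < 3 * 6.0 / np.sqrt(200)

    def test_particle_count_is_conserved(self, plane_scene):
        cfg = plane_scene.config
        assert len(plane_scene.particles) == cfg.n_bound + cfg.n_background

    def test_every_center_lies_inside_the_lamella_mask(self, plane_scene):
        vox = plane_scene.lamella_mask.voxel_size
        idx = np.round(plane_scene.particles.coords / vox).astype(int)
        assert plane_scene.lamella_mask.data[idx[:, 2], idx[:, 1], idx[:, 0]].all()

    def test_hard_sphere_separation_enforced(self, plane_scene):
        coords = plane_scene.particles.coords
        dists = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        assert dists.min() >= plane_scene.config.separation - 1e-9

    def test_seed_determinism_is_bit_identical(self):
        a = simulate_scene(small_scene_config())
        b = simulate_scene(small_scene_config())
        pd.testing.assert_frame_equal(a.particles.df, b.particles.df)
        assert np.array_equal(a.structure_mask.data, b.structure_mask.data)

    def test_different_seeds_differ(self):
        a = simulate_scene(small_scene_config())
        b = simulate_scene(small_scene_config(seed=8))
        assert not np.allclose(a.particles.coords, b.particles.coords)

    def test_structure_missing_lamella_is_geometry_error(self):
        cfg = small_scene_config(
            structure_kind="sphere",
            structure_params={"radius_nm": 10.0, "center_nm": (80.0, 80.0, 2.0)},
            lamella_thickness=40.0,
        )
        with pytest.raises(GeometryError):
            simulate_scene(cfg)

    def test_impossible_packing_is_placement_error(self):
        with pytest.raises(PlacementError):
            simulate_scene(small_scene_config(n_bound=500, volume_shape=(64, 64, 64),
                                              lamella_thickness=60.0, edge_margin=0.0))

    @pytest.mark.parametrize(
        "bad",
        [
            dict(voxel_size=-1.0),
            dict(lamella_thickness=20.0),  # below particle diameter
            dict(n_bound=-1),
            dict(bound_distance_sd=-0.5),
            dict(structure_kind="cube"),
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigError):
            small_scene_config(**bad)

    @pytest.mark.parametrize("kind,params", [
        ("sphere", {"radius_nm": 40.0}),
        ("tube", {"radius_nm": 30.0}),
    ])
    def test_curved_structures_record_consistent_distances(self, kind, params):
        from gemquant.spatial import SpatialParams, surface_distances

        truth = simulate_scene(small_scene_config(
            structure_kind=kind, structure_params=params,
            volume_shape=(160, 160, 110), lamella_thickness=120.0,
            n_bound=8, n_background=0))
        rec = surface_distances(truth.particles, truth.structure_mask, SpatialParams())
        diff = rec["surface_distance_nm"].to_numpy() - \
            truth.particles.df["surface_distance_nm"].to_numpy()
        assert np.abs(diff).max() <= truth.config.voxel_size * np.sqrt(3)


class TestProbabilityMap:
    def test_values_in_unit_interval_even_with_noise(self, plane_scene):
        pm = render_probability_map(plane_scene, ProbMapConfig(noise_sd=0.3, seed=3))
        assert pm.data.min() >= 0.0 and pm.data.max() <= 1.0

    def test_single_particle_peak_at_center_within_range(self):
        truth = simulate_scene(small_scene_config(n_bound=1, n_background=0))
        cfg = ProbMapConfig(seed=5)
        pm = render_probability_map(truth, cfg)
        # the blob has a uniform peak value, so every maximal voxel must lie
        # inside the blob sphere around the true centre
        peak_idx = np.unravel_index(np.argmax(pm.data), pm.data.shape)
        center_vox = truth.particles.coords[0][::-1] / truth.config.voxel_size
        dist_nm = np.linalg.norm(np.array(peak_idx) - center_vox) * truth.config.voxel_size
        assert dist_nm <= cfg.blob_radius + 1e-9
        assert 0.8 <= pm.data.max() <= 1.0

    def test_noise_free_map_has_one_component_per_particle(self, plane_scene,
                                                           plane_probmap):
        # independent flood-fill oracle over the thresholded map
        n = _flood_fill_count(plane_probmap.data >= 0.5)
        assert n == len(plane_scene.particles)

    def test_bit_identical_for_fixed_seed(self, plane_scene):
        a = render_probability_map(plane_scene, ProbMapConfig(seed=9, noise_sd=0.05))
        b = render_probability_map(plane_scene, ProbMapConfig(seed=9, noise_sd=0.05))
        assert np.array_equal(a.data, b.data)

    def test_small_decoys_are_rejected_by_the_size_filter(self, plane_scene):
        from gemquant.detect import DetectionParams, postprocess_probability_map

        pm = render_probability_map(
            plane_scene,
            ProbMapConfig(blob_radius=16.4, n_false_small=3, seed=4),
        )
        detected = postprocess_probability_map(pm, plane_scene.lamella_mask,
                                               DetectionParams())
        # brute-force check: a 6 nm sphere rasterizes well below 5,000 voxels
        assert _lattice_ball_count(6.0 / 1.37) < 5000
        assert len(detected) == len(plane_scene.particles)


class TestDensityVolume:
    def test_radial_profile_dips_inside_the_shell(self):
        truth = simulate_scene(small_scene_config(n_bound=1, n_background=0))
        vol = render_density_volume(truth, ContrastParams(noise_sd=0.0))
        center = truth.particles.coords[0]
        vox = truth.config.voxel_size
        z, y, x = vol.axis_coords()
        r = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2)
        shell_mean = vol.data[(r >= 9.0) & (r <= 12.5)].mean()
        outside_mean = vol.data[(r > 20) & (r < 30)].mean()
        inside_mean = vol.data[r < 6.0].mean()
        assert shell_mean < outside_mean - 0.5
        assert shell_mean < inside_mean - 0.5

    def test_missing_wedge_region_carries_no_energy(self):
        truth = simulate_scene(small_scene_config(n_bound=2, n_background=0))
        vol = render_density_volume(
            truth, ContrastParams(noise_sd=0.1, missing_wedge=True, seed=6)
        )
        ft = np.fft.fftn(vol.data)
        wedge = missing_wedge_mask(vol.data.shape, 60.0)
        assert np.abs(ft[wedge]).max() < 1e-6 * np.abs(ft).max()


class TestColocTimecourse:
    def test_zero_timepoint_has_no_bound_puncta(self):
        sim = simulate_coloc_timecourse(ColocTimecourseConfig(n_cells=4, seed=1))
        t0 = sim.truth[sim.truth["timepoint_min"] == 0.0]
        assert (t0["n_on_target"] == 0).all()

    def test_saturation_reaches_f_max_within_binomial_interval(self):
        cfg = ColocTimecourseConfig(
            n_cells=5, timepoints=(0.0, 20 * 15.0), f_max=0.8, tau=15.0,
            puncta_per_cell=60, seed=2,
        )
        sim = simulate_coloc_timecourse(cfg)
        late = sim.truth[sim.truth["timepoint_min"] == 300.0]
        n = int(late["n_puncta"].sum())
        k = int(late["n_on_target"].sum())
        # 99% normal-approx binomial interval around f_max
        half = 2.576 * np.sqrt(0.8 * 0.2 / n)
        assert abs(k / n - 0.8) <= half

    def test_one_time_constant_gives_63_percent_of_f_max(self):
        cfg = ColocTimecourseConfig(
            n_cells=40, timepoints=(30.0,), f_max=0.9, tau=30.0,
            puncta_per_cell=50, seed=3,
        )
        sim = simulate_coloc_timecourse(cfg)
        expected = 0.9 * (1 - np.exp(-1.0))
        n = int(sim.truth["n_puncta"].sum())
        k = int(sim.truth["n_on_target"].sum())
        assert abs(k / n - expected) <= 3 * np.sqrt(expected * (1 - expected) / n)

    def test_f_max_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigError):
            ColocTimecourseConfig(f_max=1.2)

    def test_unsorted_timepoints_rejected(self):
        with pytest.raises(ConfigError):
            ColocTimecourseConfig(timepoints=(10.0, 5.0))


class TestFrapSim:
    def test_noise_free_value_at_one_half_life_is_midpoint(self):
        cfg = FrapSimConfig(true_half_life=1.0, bleach_depth=0.4, plateau=1.0,
                            noise_sd=0.0, n_frames=60, background_level=0.0,
                            prebleach_intensity=1.0)
        trace = simulate_frap_traces(cfg)[0]
        # one half-life after the bleach: halfway from 0.4 to 1.0 = 0.7
        i_bleach = cfg.n_prebleach
        idx = i_bleach + int(round(1.0 / cfg.frame_interval))
        assert trace.intensities[idx] == pytest.approx(0.7, abs=1e-12)

    def test_noise_free_fit_recovers_half_life_exactly(self):
        cfg = FrapSimConfig(true_half_life=1.3, noise_sd=0.0)
        fit = fit_recovery(normalize_trace(simulate_frap_traces(cfg)[0]))
        assert fit.half_life == pytest.approx(1.3, abs=1e-6)

    def test_monte_carlo_mean_half_life_within_5_percent(self):
        cfg = FrapSimConfig(true_half_life=1.0, noise_sd=0.05, n_traces=100, seed=11)
        fits = [fit_recovery(normalize_trace(t)) for t in simulate_frap_traces(cfg)]
        mean_hl = np.mean([f.half_life for f in fits])
        assert abs(mean_hl - 1.0) < 0.05

    def test_traces_are_seed_deterministic(self):
        a = simulate_frap_traces(FrapSimConfig(noise_sd=0.05, n_traces=2, seed=5))
        b = simulate_frap_traces(FrapSimConfig(noise_sd=0.05, n_traces=2, seed=5))
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.intensities, tb.intensities)


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def _flood_fill_count(binary: np.ndarray) -> int:
    """BFS connected-component count, 26-connectivity; independent of
    scipy.ndimage.label."""
    from collections import deque

    visited = np.zeros_like(binary, dtype=bool)
    shape = binary.shape
    offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
               for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    count = 0
    for start in zip(*np.nonzero(binary)):
        if visited[start]:
            continue
        count += 1
        queue = deque([start])
        visited[start] = True
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]
                        and binary[nz, ny, nx] and not visited[nz, ny, nx]):
                    visited[nz, ny, nx] = True
                    queue.append((nz, ny, nx))
    return count


def _lattice_ball_count(radius_vox: float) -> int:
    """Brute-force count of lattice points within a sphere."""
    r = int(np.ceil(radius_vox))
    ax = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(ax, ax, ax, indexing="ij")
    return int((dz**2 + dy**2 + dx**2 <= radius_vox**2).sum())
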