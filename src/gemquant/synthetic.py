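"""Synthetic ground-truth scenes for the tomographic and fluorescence pipelines.

Generators cover every input the analysis stages consume:

* :func:`simulate_scene` — a slab-shaped lamella containing a segmented
  target structure (membrane plane, sphere, or tube) with 25 nm shell
  particles bound at controlled surface distances plus uniform background
  particles;
* :func:`render_probability_map` — detector-style probability maps made of
  spherical blobs at the true particle centres, with optional decoys and
  noise;
* :func:`render_density_volume` — negative-contrast hollow-shell density for
  the matched-filter detector, with an optional missing wedge;
* :func:`simulate_coloc_timecourse` — punctate label images recruited onto a
  target mask with first-order saturation kinetics;
* :func:`simulate_frap_traces` — single-exponential fluorescence recovery
  traces with background and noise.

All randomness flows through ``numpy.random.default_rng(seed)``: identical
configs and seeds give bit-identical outputs.

Conventions: surface distance is the gap from the *particle surface* to the
structure surface, i.e. a particle whose centre sits ``d + particle_radius``
from the structure records surface distance ``d``; negative values mean
overlap. Particle centres must lie inside the lamella mask; hard-sphere
non-overlap (centre separation ≥ 2x radius by default) is enforced by
rejection sampling with a bounded retry budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import SlabSpec, build_slab_mask
from .errors import ConfigError, GeometryError, PlacementError, ResolutionError
from .frap import FrapTrace
from .grid import BinaryMask, VoxelGrid
from .particles import PARTICLE_COLUMNS, ParticleSet

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "ProbMapConfig",
    "ContrastParams",
    "ColocTimecourseConfig",
    "ColocFrame",
    "ColocSim",
    "FrapSimConfig",
    "simulate_scene",
    "render_probability_map",
    "render_density_volume",
    "simulate_coloc_timecourse",
    "simulate_frap_traces",
    "missing_wedge_mask",
]

_MAX_RETRIES = 1000  # per-particle rejection-sampling budget


# --------------------------------------------------------------------------
# Scene generation
# --------------------------------------------------------------------------

@dataclass
class SceneConfig:
    """Geometry and placement parameters for one synthetic tomographic scene.

    ``volume_shape`` is (nx, ny, nz) voxels; all physical lengths in nm.
    ``structure_params`` depends on ``structure_kind``:

    * ``plane`` — {"offset_nm": position of the membrane plane along x
      (default: volume centre)}; the plane is normal to x and snapped to the
      nearest voxel plane so rasterized and analytic geometry agree;
    * ``sphere`` — {"radius_nm", "center_nm": (x, y, z), default centre};
    * ``tube`` — {"radius_nm", "center_nm"}; axis along y through the centre.
    """

    volume_shape: tuple[int, int, int]
    voxel_size: float
    lamella_thickness: float
    structure_kind: str
    structure_params: dict = field(default_factory=dict)
    lamella_tilt: float = 0.0
    n_bound: int = 0
    bound_distance_mean: float = 10.0
    bound_distance_sd: float = 6.0
    n_background: int = 0
    particle_radius: float = 12.5
    min_separation: float | None = None  # default: hard-sphere 2 x radius
    edge_margin: float = 0.0  # keep centres this far (nm) from volume and lamella faces
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.volume_shape) != 3 or any(n <= 0 for n in self.volume_shape):
            raise ConfigError(f"volume_shape must be a positive triple, got {self.volume_shape}")
        if self.voxel_size <= 0:
            raise ConfigError("voxel_size must be positive (isotropic nm/voxel)")
        if self.lamella_thickness <= 2 * self.particle_radius:
            raise ConfigError("lamella_thickness must exceed the particle diameter")
        if self.bound_distance_sd < 0 or self.n_bound < 0 or self.n_background < 0:
            raise ConfigError("counts must be >= 0 and bound_distance_sd >= 0")
        if self.structure_kind not in ("plane", "sphere", "tube"):
            raise ConfigError(f"unknown structure_kind {self.structure_kind!r}")

    @property
    def separation(self) -> float:
        return 2 * self.particle_radius if self.min_separation is None else self.min_separation


@dataclass
class SceneTruth:
    """Ground truth for a simulated scene."""

    particles: ParticleSet
    structure_mask: BinaryMask
    lamella_mask: BinaryMask
    config: SceneConfig


class _Structure:
    """Analytic structure geometry + rasterized membrane mask."""

    def __init__(self, cfg: SceneConfig):
        nx, ny, nz = cfg.volume_shape
        vox = cfg.voxel_size
        self.cfg = cfg
        self.extent = ((nx - 1) * vox, (ny - 1) * vox, (nz - 1) * vox)
        center_default = tuple(e / 2 for e in self.extent)
        p = cfg.structure_params
        if cfg.structure_kind == "plane":
            offset = p.get("offset_nm", self.extent[0] / 2)
            self.offset = round(offset / vox) * vox  # snap to a voxel plane
        else:
            self.center = np.asarray(p.get("center_nm", center_default), dtype=float)
            self.radius = float(p["radius_nm"])

    def mask(self, geometry: VoxelGrid) -> BinaryMask:
        vox = self.cfg.voxel_size
        z, y, x = geometry.axis_coords()
        if self.cfg.structure_kind == "plane":
            m = np.abs(x - self.offset) <= vox / 2
            m = np.broadcast_to(m, geometry.data.shape)
        elif self.cfg.structure_kind == "sphere":
            cx, cy, cz = self.center
            dist = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
            m = np.abs(dist - self.radius) <= vox / 2
        else:  # tube along y
            cx, _, cz = self.center
            rad = np.sqrt((x - cx) ** 2 + (z - cz) ** 2)
            m = np.broadcast_to(np.abs(rad - self.radius) <= vox / 2, geometry.data.shape)
        return BinaryMask(m.copy(), vox)

    def surface_point(self, center_dist: float, rng: np.random.Generator) -> np.ndarray:
        """Random point at distance ``center_dist`` outside the structure surface."""
        ex, ey, ez = self.extent
        if self.cfg.structure_kind == "plane":
            return np.array(
                [self.offset + center_dist, rng.uniform(0, ey), rng.uniform(0, ez)]
            )
        if self.cfg.structure_kind == "sphere":
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            return self.center + (self.radius + center_dist) * u
        theta = rng.uniform(0, 2 * math.pi)
        r = self.radius + center_dist
        return np.array(
            [self.center[0] + r * math.cos(theta), rng.uniform(0, ey),
             self.center[2] + r * math.sin(theta)]
        )

    def in_interior(self, pos: np.ndarray) -> bool:
        if self.cfg.structure_kind == "plane":
            return False
        if self.cfg.structure_kind == "sphere":
            return float(np.linalg.norm(pos - self.center)) < self.radius
        return float(np.hypot(pos[0] - self.center[0], pos[2] - self.center[2])) < self.radius


def _lamella_spec(cfg: SceneConfig, extent: tuple[float, float, float]) -> SlabSpec:
    tilt = math.radians(cfg.lamella_tilt)
    normal = (math.sin(tilt), 0.0, math.cos(tilt))
    center = np.array([e / 2 for e in extent])
    point = center - (cfg.lamella_thickness / 2) * np.asarray(normal)
    return SlabSpec(tuple(point), normal, cfg.lamella_thickness)


def simulate_scene(config: SceneConfig) -> SceneTruth:
    """Generate a lamella scene with bound and background particles.

    Bound particles sit at surface distances drawn from
    N(bound_distance_mean, bound_distance_sd), redrawn (up to 1000 tries per
    particle) until the centre lies inside the lamella and respects the
    hard-sphere separation. Background particles are uniform over the lamella
    excluding the structure interior.
    """
    rng = np.random.default_rng(config.seed)
    nx, ny, nz = config.volume_shape
    geometry = VoxelGrid(np.zeros((nz, ny, nx), dtype=np.float32), config.voxel_size)

    structure = _Structure(config)
    structure_mask = structure.mask(geometry)
    slab = _lamella_spec(config, structure.extent)
    lamella_mask = build_slab_mask(geometry, slab)
    if not (structure_mask.data & lamella_mask.data).any():
        raise GeometryError("structure does not intersect the lamella slab")

    extent = np.asarray(structure.extent)
    normal = np.asarray(slab.normal)
    point = np.asarray(slab.point)

    margin = config.edge_margin

    def in_lamella(pos: np.ndarray) -> bool:
        s = float(np.dot(pos - point, normal))
        return (
            margin <= s <= slab.thickness - margin
            and np.all(pos >= margin)
            and np.all(pos <= extent - margin)
        )

    placed: list[np.ndarray] = []
    sep2 = config.separation**2

    def separated(pos: np.ndarray) -> bool:
        if sep2 == 0 or not placed:
            return True
        arr = np.asarray(placed)
        return bool(np.min(((arr - pos) ** 2).sum(axis=1)) >= sep2)

    rows: list[dict] = []
    for i in range(config.n_bound):
        for _ in range(_MAX_RETRIES):
            d = rng.normal(config.bound_distance_mean, config.bound_distance_sd)
            center_dist = d + config.particle_radius
            if center_dist < 0:
                continue
            pos = structure.surface_point(center_dist, rng)
            if in_lamella(pos) and separated(pos):
                placed.append(pos)
                rows.append(
                    {"particle_id": i, "x_nm": pos[0], "y_nm": pos[1], "z_nm": pos[2],
                     "bound": True, "surface_distance_nm": d}
                )
                break
        else:
            raise PlacementError(f"could not place bound particle {i} after {_MAX_RETRIES} tries")

    for i in range(config.n_background):
        for _ in range(_MAX_RETRIES):
            pos = rng.uniform(0, 1, size=3) * extent
            if in_lamella(pos) and not structure.in_interior(pos) and separated(pos):
                placed.append(pos)
                rows.append(
                    {"particle_id": config.n_bound + i, "x_nm": pos[0], "y_nm": pos[1],
                     "z_nm": pos[2], "bound": False, "surface_distance_nm": np.nan}
                )
                break
        else:
            raise PlacementError(
                f"could not place background particle {i} after {_MAX_RETRIES} tries"
            )

    df = pd.DataFrame(rows, columns=["particle_id", "x_nm", "y_nm", "z_nm",
                                     "bound", "surface_distance_nm"])
    df["tomo_id"] = "synthetic"
    df["score"] = 1.0
    df["source"] = "manual"
    df["status"] = "retained"
    particles = ParticleSet(df[PARTICLE_COLUMNS + ["particle_id", "bound",
                                                   "surface_distance_nm"]])
    return SceneTruth(particles, structure_mask, lamella_mask, config)


# --------------------------------------------------------------------------
# Probability maps and density volumes
# --------------------------------------------------------------------------

@dataclass
class ProbMapConfig:
    """Detector-style probability map parameters.

    ``blob_radius`` defaults to 13.7 nm (the 137 Å training-label radius).
    Decoy radii are chosen so that at the 1.37 nm reference voxel size the
    small/large decoys fall below/above the standard 5,000–50,000-voxel size
    band while ``valid`` decoys pass it.
    """

    blob_radius: float = 13.7
    peak_prob_range: tuple[float, float] = (0.8, 1.0)
    n_false_small: int = 0
    n_false_large: int = 0
    n_false_valid: int = 0
    small_radius_nm: float = 6.0
    valid_radius_nm: float = 18.0
    large_radius_nm: float = 34.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.peak_prob_range
        if not (0.5 < lo <= hi <= 1.0):
            raise ConfigError("peak_prob_range must satisfy 0.5 < low <= high <= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def _paint_sphere(data: np.ndarray, center_nm: np.ndarray, radius_nm: float,
                  value: float, vox: float) -> None:
    """Set ``data`` to max(data, value) inside a sphere (coords in nm)."""
    nz, ny, nx = data.shape
    cx, cy, cz = center_nm
    r_vox = radius_nm / vox
    lo = [max(int(math.floor(c / vox - r_vox)) - 1, 0) for c in (cz, cy, cx)]
    hi = [min(int(math.ceil(c / vox + r_vox)) + 2, n) for c, n in ((cz, nz), (cy, ny), (cx, nx))]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    z = np.arange(lo[0], hi[0])[:, None, None] * vox
    y = np.arange(lo[1], hi[1])[None, :, None] * vox
    x = np.arange(lo[2], hi[2])[None, None, :] * vox
    inside = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius_nm**2
    sub = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(sub, np.where(inside, value, 0.0), out=sub)


def render_probability_map(truth: SceneTruth, config: ProbMapConfig) -> VoxelGrid:
    """Render spherical probability blobs at true centres plus decoys and noise."""
    vox = truth.lamella_mask.voxel_size
    if config.blob_radius < vox:
        raise ResolutionError(f"blob radius {config.blob_radius} nm is under one voxel")
    rng = np.random.default_rng(config.seed)
    data = np.zeros(truth.lamella_mask.data.shape, dtype=np.float64)
    lo, hi = config.peak_prob_range

    coords = truth.particles.coords
    for center in coords:
        _paint_sphere(data, center, config.blob_radius, rng.uniform(lo, hi), vox)

    # decoys: placed uniformly in the lamella, kept clear of every existing blob
    extent = np.array(truth.lamella_mask.extent_xyz)
    lam = truth.lamella_mask.data
    existing = [(c, config.blob_radius) for c in coords]
    decoy_plan = (
        [(config.small_radius_nm, "small")] * config.n_false_small
        + [(config.valid_radius_nm, "valid")] * config.n_false_valid
        + [(config.large_radius_nm, "large")] * config.n_false_large
    )
    for radius, kind in decoy_plan:
        for _ in range(_MAX_RETRIES):
            pos = rng.uniform(0, 1, size=3) * extent
            iz, iy, ix = (int(round(c / vox)) for c in pos[::-1])
            if not lam[iz, iy, ix]:
                continue
            clear = all(
                np.linalg.norm(pos - c) >= r + radius + 2 * vox for c, r in existing
            )
            if clear:
                _paint_sphere(data, pos, radius, rng.uniform(lo, hi), vox)
                existing.append((pos, radius))
                break
        else:
            raise PlacementError(f"could not place a {kind} decoy blob")

    if config.noise_sd > 0:
        data += rng.normal(0, config.noise_sd, size=data.shape)
    np.clip(data, 0.0, 1.0, out=data)
    return VoxelGrid(data, vox)


@dataclass
class ContrastParams:
    """Rendering parameters for negative-contrast shell density."""

    shell_amplitude: float = 1.0
    inner_radius: float = 9.0  # nm; outer radius comes from the scene config
    noise_sd: float = 0.0
    missing_wedge: bool = False
    max_tilt_deg: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_radius < 0:
            raise ConfigError("inner_radius must be >= 0")


def missing_wedge_mask(shape: tuple[int, int, int], max_tilt_deg: float) -> np.ndarray:
    """Boolean Fourier-domain mask of the missing wedge (tilt axis = y).

    A tilt series limited to ±max_tilt about y leaves unsampled the wedge of
    directions within (90° − max_tilt) of the z (beam) frequency axis in the
    kx–kz plane; the wedge extends freely along ky. The ky axis line itself
    (kz = kx = 0) is sampled by every projection and is excluded.
    """
    fz = np.fft.fftfreq(shape[0])[:, None, None]
    fx = np.fft.fftfreq(shape[2])[None, None, :]
    semi = math.radians(90.0 - max_tilt_deg)
    angle_from_kz = np.arctan2(np.abs(fx), np.abs(fz))
    wedge = (angle_from_kz < semi) & ((np.abs(fz) + np.abs(fx)) > 0)
    return np.broadcast_to(wedge, shape)


def render_density_volume(truth: SceneTruth, contrast: ContrastParams | None = None) -> VoxelGrid:
    """Render hollow shells (dark, negative contrast) over Gaussian noise.

    The shell outer radius equals the scene's ``particle_radius``; an optional
    missing wedge zeroes the unsampled Fourier region.
    """
    contrast = contrast or ContrastParams()
    cfg = truth.config
    if contrast.inner_radius >= cfg.particle_radius:
        raise GeometryError("inner radius must be smaller than the particle radius")
    vox = truth.lamella_mask.voxel_size
    rng = np.random.default_rng(contrast.seed)
    shape = truth.lamella_mask.data.shape
    data = (
        rng.normal(0, contrast.noise_sd, size=shape)
        if contrast.noise_sd > 0
        else np.zeros(shape, dtype=np.float64)
    )
    # paint shell = outer sphere minus inner sphere, as negative contrast
    for center in truth.particles.coords:
        shell = np.zeros(shape, dtype=np.float64)
        _paint_sphere(shell, center, cfg.particle_radius, 1.0, vox)
        inner = np.zeros(shape, dtype=np.float64)
        _paint_sphere(inner, center, contrast.inner_radius, 1.0, vox)
        data -= contrast.shell_amplitude * np.clip(shell - inner, 0.0, 1.0)

    if contrast.missing_wedge:
        ft = np.fft.fftn(data)
        ft[missing_wedge_mask(shape, contrast.max_tilt_deg)] = 0.0
        data = np.fft.ifftn(ft).real
    return VoxelGrid(data, vox)


# --------------------------------------------------------------------------
# Fluorescence timecourses
# --------------------------------------------------------------------------

@dataclass
class ColocTimecourseConfig:
    """First-order recruitment of punctate labels onto a target region.

    The expected fraction of puncta on target at time ``t`` (minutes) is
    ``f_max * (1 − exp(−t / tau))``; per cell and timepoint the realized
    on-target count is binomial. This saturation model is the generator's own
    stated structure for ligand-induced recruitment, not a fitted mechanism.
    """

    n_cells: int = 10
    timepoints: tuple[float, ...] = (0.0, 5.0, 15.0, 30.0, 60.0)
    f_max: float = 0.8
    tau: float = 15.0
    puncta_per_cell: int = 40
    image_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 100.0  # nm/px
    target_radius_px: float = 28.0
    spot_sigma_px: float = 2.0
    poisson_scale: float = 0.0  # photons per intensity unit; 0 disables shot noise
    gauss_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_max <= 1.0:
            raise ConfigError("f_max must lie in [0, 1]")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size == 0 or np.any(tp < 0) or np.any(np.diff(tp) < 0):
            raise ConfigError("timepoints must be nonnegative and sorted")
        if self.tau <= 0:
            raise ConfigError("tau must be positive")


@dataclass
class ColocFrame:
    """One rendered cell at one timepoint."""

    cell_id: int
    timepoint: float
    image: np.ndarray
    target_mask: np.ndarray
    puncta_xy: np.ndarray  # (n, 2) pixel coordinates (x, y)
    on_target: np.ndarray  # boolean per punctum


@dataclass
class ColocSim:
    frames: list[ColocFrame]
    truth: pd.DataFrame  # cell_id, timepoint_min, n_puncta, n_on_target, frac_on_target
    config: ColocTimecourseConfig


def _render_spots(shape: tuple[int, int], xy: np.ndarray, sigma: float) -> np.ndarray:
    img = np.zeros(shape, dtype=np.float64)
    yy = np.arange(shape[0])[:, None]
    xx = np.arange(shape[1])[None, :]
    for x, y in xy:
        img += np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    return img


def simulate_coloc_timecourse(config: ColocTimecourseConfig) -> ColocSim:
    """Render per-cell label images over a disk target with saturating recruitment."""
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    r_t = config.target_radius_px
    frames: list[ColocFrame] = []
    rows: list[dict] = []
    for cell in range(config.n_cells):
        cx = rng.uniform(r_t + 4, w - r_t - 4)
        cy = rng.uniform(r_t + 4, h - r_t - 4)
        yy = np.arange(h)[:, None]
        xx = np.arange(w)[None, :]
        target = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_t**2
        for t in config.timepoints:
            p = config.f_max * (1.0 - math.exp(-t / config.tau))
            n_on = int(rng.binomial(config.puncta_per_cell, p))
            pts = []
            flags = []
            for _ in range(n_on):  # uniform inside the disk
                while True:
                    u = rng.uniform(-r_t, r_t, size=2)
                    if u[0] ** 2 + u[1] ** 2 <= r_t**2:
                        pts.append((cx + u[0], cy + u[1]))
                        flags.append(True)
                        break
            for _ in range(config.puncta_per_cell - n_on):  # uniform outside
                while True:
                    x, y = rng.uniform(0, w), rng.uniform(0, h)
                    if (x - cx) ** 2 + (y - cy) ** 2 > r_t**2:
                        pts.append((x, y))
                        flags.append(False)
                        break
            xy = np.asarray(pts, dtype=float).reshape(-1, 2)
            img = _render_spots((h, w), xy, config.spot_sigma_px)
            if config.poisson_scale > 0:
                img = rng.poisson(img * config.poisson_scale) / config.poisson_scale
            if config.gauss_sd > 0:
                # detected counts cannot go negative
                img = np.maximum(img + rng.normal(0, config.gauss_sd, size=img.shape), 0.0)
            frames.append(ColocFrame(cell, t, img, target, xy, np.asarray(flags)))
            rows.append(
                {"cell_id": cell, "timepoint_min": t, "n_puncta": config.puncta_per_cell,
                 "n_on_target": n_on,
                 "frac_on_target": n_on / config.puncta_per_cell
                 if config.puncta_per_cell else np.nan}
            )
    return ColocSim(frames, pd.DataFrame(rows), config)


# --------------------------------------------------------------------------
# FRAP traces
# --------------------------------------------------------------------------

@dataclass
class FrapSimConfig:
    """Single-exponential FRAP recovery traces.

    ``noise_sd`` is expressed as a fraction of the prebleach intensity, so the
    normalized trace carries Gaussian noise of exactly that sd. Frame
    ``n_prebleach`` (0-based) is the first frame acquired after the bleach
    pulse; its noise-free value is the bleach depth.
    """

    true_half_life: float = 1.0  # s
    bleach_depth: float = 0.4
    plateau: float = 0.9
    frame_interval: float = 0.05  # s
    n_prebleach: int = 10
    n_frames: int = 200
    noise_sd: float = 0.0
    background_level: float = 10.0
    prebleach_intensity: float = 100.0
    n_traces: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_half_life <= 0:
            raise ConfigError("true_half_life must be positive")
        if self.n_prebleach < 1:
            raise ConfigError("need at least one prebleach frame")
        if self.n_frames <= self.n_prebleach + 3:
            raise ConfigError("need at least 4 post-bleach frames")
        if not 0 <= self.bleach_depth < self.plateau <= 1.0:
            raise ConfigError("require 0 <= bleach_depth < plateau <= 1")


def frap_model(t: np.ndarray, bleach_depth: float, plateau: float, rate: float) -> np.ndarray:
    """Noise-free normalized recovery: I(t) = I_inf − (I_inf − I_0) e^(−k t)."""
    return plateau - (plateau - bleach_depth) * np.exp(-rate * np.asarray(t, dtype=float))


def simulate_frap_traces(config: FrapSimConfig) -> list[FrapTrace]:
    """Generate raw (unnormalized) FRAP traces with constant background."""
    rng = np.random.default_rng(config.seed)
    k = math.log(2) / config.true_half_life
    times = np.arange(config.n_frames) * config.frame_interval
    t_post = times[config.n_prebleach:] - times[config.n_prebleach]
    model = np.ones(config.n_frames)
    model[config.n_prebleach:] = frap_model(t_post, config.bleach_depth, config.plateau, k)
    traces = []
    for i in range(config.n_traces):
        noise = rng.normal(0, config.noise_sd, size=config.n_frames) if config.noise_sd > 0 \
            else np.zeros(config.n_frames)
        intensities = config.prebleach_intensity * (model + noise) + config.background_level
        traces.append(
            FrapTrace(times=times.copy(), intensities=intensities,
                      background=config.background_level,
                      bleach_index=config.n_prebleach, trace_id=str(i))
        )
    return traces
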