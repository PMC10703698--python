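"""Tomogram preprocessing and particle detection postprocessing.

The workflow mirrors standard cellular cryo-ET picking practice: tomograms
are band-pass filtered and intensity-normalized; a per-voxel probability map
(from a CNN detector, or here the shell matched filter) is thresholded,
restricted to the lamella, and size-filtered into particle coordinates; the
resulting peaks are curated with an explicit accounting ledger.

Filter dialect
--------------
Both Fourier filters are Gaussians parameterized in cycles/voxel with
amplitude ``exp(-f^2 / (2 c^2))``: the low-pass uses ``c = lowpass_cutoff_abs``
and the high-pass is its complement with ``c = 1 / highpass_cutoff_pixels``.
The stage order is fixed: low-pass, high-pass, zero-mean/unit-sd
normalization, clamping at ``±clamp_nsigma`` (no re-normalization after the
clamp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import (
    ConfigError,
    GeometryError,
    InputError,
    LedgerError,
    NormalizationError,
    ResolutionError,
)
from .grid import BinaryMask, VoxelGrid, require_same_geometry
from .particles import ParticleSet, SOURCE_MANUAL

__all__ = [
    "PreprocessParams",
    "DetectionParams",
    "SlabSpec",
    "CurationLedger",
    "preprocess_volume",
    "apply_bandpass",
    "build_slab_mask",
    "postprocess_probability_map",
    "detect_shells",
    "apply_curation",
]

# Curation categories observed in practice; free-form strings are accepted.
DEFAULT_DISCARD_CATEGORIES = ("organelle-interior", "surface-damage", "visual-reject")


@dataclass
class PreprocessParams:
    """EMAN2-style filter chain parameters (cycles/voxel units)."""

    lowpass_cutoff_abs: float = 0.25
    highpass_cutoff_pixels: float = 5.0
    clamp_nsigma: float = 3.0

    def __post_init__(self) -> None:
        if self.lowpass_cutoff_abs <= 0 or self.highpass_cutoff_pixels <= 0:
            raise ConfigError("filter cutoffs must be positive")
        if self.clamp_nsigma <= 0:
            raise ConfigError("clamp_nsigma must be positive")


@dataclass
class DetectionParams:
    """Threshold + connected-component size filter for probability maps.

    Size bounds are physical-volume bounds anchored at ``reference_voxel_size``
    (1.37 nm): a component of ``n`` voxels at voxel size ``v`` counts as
    ``n * (v / reference)^3`` reference voxels, so accept/reject decisions are
    invariant to the map's binning.
    """

    prob_threshold: float = 0.5
    min_component_voxels: float = 5000.0
    max_component_voxels: float = 50000.0
    reference_voxel_size: float = 1.37
    connectivity: str = "face+edge+corner"  # 26-neighbourhood; "face" = 6

    def __post_init__(self) -> None:
        if not 0 < self.prob_threshold < 1:
            raise ConfigError("prob_threshold must lie in (0, 1)")
        if not 0 < self.min_component_voxels < self.max_component_voxels:
            raise ConfigError("size filter requires 0 < min < max")
        if self.connectivity not in ("face", "face+edge+corner"):
            raise ConfigError(f"unknown connectivity {self.connectivity!r}")

    @property
    def structure(self) -> np.ndarray:
        rank = 1 if self.connectivity == "face" else 3
        return ndimage.generate_binary_structure(3, rank)


@dataclass
class SlabSpec:
    """Geometric lamella slab: a point on the front plane, unit normal, thickness (nm)."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]
    thickness: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-6):
            raise ConfigError("slab normal must have unit length")
        if self.thickness <= 0:
            raise ConfigError("slab thickness must be positive")


@dataclass
class CurationLedger:
    """Accounting of detector peaks: discards by category plus manual additions."""

    n_peaks: int
    discards: dict[str, int] = field(default_factory=dict)
    n_manual_added: int = 0

    def __post_init__(self) -> None:
        if self.n_peaks < 0 or self.n_manual_added < 0 or any(
            v < 0 for v in self.discards.values()
        ):
            raise LedgerError("ledger counts must be nonnegative")
        if sum(self.discards.values()) > self.n_peaks:
            raise LedgerError(
                f"discards ({sum(self.discards.values())}) exceed peaks ({self.n_peaks})"
            )

    @property
    def n_discarded(self) -> int:
        return sum(self.discards.values())

    @property
    def final_count(self) -> int:
        return self.n_peaks - self.n_discarded + self.n_manual_added


def apply_bandpass(volume: VoxelGrid, params: PreprocessParams) -> VoxelGrid:
    """Fourier Gaussian low-pass x high-pass only (no normalization/clamp)."""
    data = np.asarray(volume.data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise InputError("volume contains non-finite values")
    freqs = [np.fft.fftfreq(n) for n in data.shape]
    fz, fy, fx = np.meshgrid(*freqs, indexing="ij", sparse=True)
    f2 = fz**2 + fy**2 + fx**2
    c_lo = params.lowpass_cutoff_abs
    c_hi = 1.0 / params.highpass_cutoff_pixels
    transfer = np.exp(-f2 / (2 * c_lo**2)) * (1.0 - np.exp(-f2 / (2 * c_hi**2)))
    filtered = np.fft.ifftn(np.fft.fftn(data) * transfer).real
    return VoxelGrid(filtered, volume.voxel_size)


def preprocess_volume(volume: VoxelGrid, params: PreprocessParams | None = None) -> VoxelGrid:
    """Band-pass, normalize to zero mean / unit sd, clamp to ±nsigma."""
    params = params or PreprocessParams()
    if np.ptp(volume.data) == 0:
        raise NormalizationError("constant volume: normalization undefined")
    out = apply_bandpass(volume, params)
    sd = out.data.std()
    if sd == 0:
        raise NormalizationError("zero variance after filtering")
    data = (out.data - out.data.mean()) / sd
    np.clip(data, -params.clamp_nsigma, params.clamp_nsigma, out=data)
    return VoxelGrid(data, volume.voxel_size)


def build_slab_mask(geometry: VoxelGrid, slab: SlabSpec) -> BinaryMask:
    """Mask voxels whose signed distance to the front plane lies in [0, thickness]."""
    z, y, x = geometry.axis_coords()
    px, py, pz = slab.point
    nx_, ny_, nz_ = slab.normal
    s = (x - px) * nx_ + (y - py) * ny_ + (z - pz) * nz_
    mask = (s >= 0) & (s <= slab.thickness)
    if not mask.any():
        raise GeometryError("slab does not intersect the volume")
    return BinaryMask(mask, geometry.voxel_size)


def postprocess_probability_map(
    prob: VoxelGrid,
    lamella: BinaryMask | None,
    params: DetectionParams | None = None,
    tomo_id: str = "tomo",
) -> ParticleSet:
    """Threshold, lamella-mask and size-filter a probability map into particles.

    Retained components yield one particle each with a probability-weighted
    (sub-voxel) centroid in nm and the component's maximum probability as
    score. Masking commutes with thresholding, so applying the lamella mask
    before or after binarization gives identical results.
    """
    params = params or DetectionParams()
    data = np.asarray(prob.data, dtype=np.float64)
    if data.min() < 0 or data.max() > 1:
        raise InputError(
            f"probability map values outside [0, 1]: [{data.min():.3g}, {data.max():.3g}]"
        )
    if lamella is not None:
        require_same_geometry(prob, lamella, "probability map and lamella mask")
        data = np.where(lamella.data, data, 0.0)

    binary = data >= params.prob_threshold
    labels, n_labels = ndimage.label(binary, structure=params.structure)
    if n_labels == 0:
        return ParticleSet.empty()

    scale = (prob.voxel_size / params.reference_voxel_size) ** 3
    counts = np.bincount(labels.ravel())[1:]  # voxels per component
    keep = np.flatnonzero(
        (counts * scale >= params.min_component_voxels)
        & (counts * scale <= params.max_component_voxels)
    ) + 1
    if keep.size == 0:
        return ParticleSet.empty()

    centers = []
    scores = []
    zz, yy, xx = np.nonzero(np.isin(labels, keep))
    lab = labels[zz, yy, xx]
    w = data[zz, yy, xx]
    for lbl in keep:
        sel = lab == lbl
        wsel = w[sel]
        wsum = wsel.sum()
        cz = (zz[sel] * wsel).sum() / wsum
        cy = (yy[sel] * wsel).sum() / wsum
        cx = (xx[sel] * wsel).sum() / wsum
        centers.append((cx * prob.voxel_size, cy * prob.voxel_size, cz * prob.voxel_size))
        scores.append(wsel.max())
    return ParticleSet.from_coords(np.array(centers), np.array(scores), tomo_id=tomo_id)


def _shell_kernel(outer_vox: float, inner_vox: float) -> np.ndarray:
    """Zero-mean, unit-norm hollow-shell template (negative in the shell:
    protein is dark in tomograms)."""
    r = int(np.ceil(outer_vox)) + 1
    ax = np.arange(-r, r + 1, dtype=float)
    dz, dy, dx = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    dist = np.sqrt(dz**2 + dy**2 + dx**2)
    kernel = np.where((dist >= inner_vox) & (dist <= outer_vox), -1.0, 0.0)
    kernel -= kernel.mean()
    norm = np.sqrt((kernel**2).sum())
    return kernel / norm


def detect_shells(
    volume: VoxelGrid,
    shell_radius: float,
    min_separation: float,
    score_cutoff: float = 0.5,
    shell_thickness: float = 4.0,
    tomo_id: str = "tomo",
) -> ParticleSet:
    """Matched-filter detection of hollow spherical shells.

    Normalized cross-correlation against a hollow-shell template of outer
    radius ``shell_radius`` (nm); local maxima above ``score_cutoff`` are kept
    greedily, highest score first (ties broken by lexicographic z, y, x voxel
    order), suppressing any candidate within ``min_separation`` of a kept one.
    """
    vox = volume.voxel_size
    outer = shell_radius / vox
    if outer < 2:
        raise ResolutionError(
            f"shell radius {shell_radius} nm is under 2 voxels at {vox} nm/voxel"
        )
    inner = max(outer - shell_thickness / vox, 0.0)
    kernel = _shell_kernel(outer, inner)
    data = np.asarray(volume.data, dtype=np.float64)

    # Local normalization: correlation coefficient between the template and
    # the patch under it at every position.
    n_k = float(kernel.size)
    ones = np.ones_like(kernel)
    num = signal.fftconvolve(data, kernel[::-1, ::-1, ::-1], mode="same")
    local_sum = signal.fftconvolve(data, ones, mode="same")
    local_sq = signal.fftconvolve(data**2, ones, mode="same")
    local_var = np.maximum(local_sq - local_sum**2 / n_k, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = np.where(local_var > 1e-12, num / np.sqrt(local_var), 0.0)
    ncc = np.clip(ncc, -1.0, 1.0)

    peak_mask = (ncc >= score_cutoff) & (ncc == ndimage.maximum_filter(ncc, size=3))
    coords = np.argwhere(peak_mask)  # (n, 3) z, y, x
    if coords.size == 0:
        return ParticleSet.empty()
    scores = ncc[tuple(coords.T)]
    # highest score first; ties by lexicographic voxel order
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], -scores))
    coords, scores = coords[order], scores[order]

    kept: list[int] = []
    min_sep_vox2 = (min_separation / vox) ** 2
    for i in range(len(coords)):
        if all(((coords[i] - coords[j]) ** 2).sum() >= min_sep_vox2 for j in kept):
            kept.append(i)
    centers_nm = coords[kept][:, ::-1] * vox  # z,y,x → x,y,z
    return ParticleSet.from_coords(centers_nm, scores[kept], tomo_id=tomo_id)


def apply_curation(
    particles: ParticleSet | None = None,
    ledger: CurationLedger | None = None,
    manual_additions: ParticleSet | None = None,
) -> tuple[ParticleSet | None, CurationLedger]:
    """Apply curation decisions and return the retained set plus its ledger.

    Two entry points: a :class:`ParticleSet` whose ``status`` column records
    per-particle decisions (``discarded:<category>``), or a pre-tallied
    :class:`CurationLedger`. The final count is always
    ``n_peaks − Σ discards + n_manual_added``.
    """
    if particles is None and ledger is None:
        raise InputError("provide particles or a ledger")

    if particles is not None:
        status = particles.df["status"].astype(str)
        discarded = status.str.startswith("discarded")
        categories: dict[str, int] = {}
        for s in status[discarded]:
            cat = s.split(":", 1)[1] if ":" in s else "unspecified"
            categories[cat] = categories.get(cat, 0) + 1
        n_manual = len(manual_additions) if manual_additions is not None else 0
        derived = CurationLedger(len(particles), categories, n_manual)
        if ledger is not None and (
            ledger.n_peaks != derived.n_peaks
            or ledger.n_discarded != derived.n_discarded
            or ledger.n_manual_added != derived.n_manual_added
        ):
            raise LedgerError("supplied ledger disagrees with per-particle statuses")
        curated = particles.retained()
        if manual_additions is not None and len(manual_additions):
            add = manual_additions.df.copy()
            add["source"] = SOURCE_MANUAL
            add["status"] = "retained"
            curated = curated.concat(ParticleSet(add))
        assert len(curated) == derived.final_count
        return curated, derived

    if manual_additions is not None and len(manual_additions) != ledger.n_manual_added:
        raise LedgerError("manual additions disagree with ledger count")
    return None, ledger
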