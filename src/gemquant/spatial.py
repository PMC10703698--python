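"""Particle-to-structure distance statistics and volumetric fold-enrichment.

Distances are measured from a particle's *refined centre* to the nearest
annotated structure voxel via the Euclidean distance transform, then the
particle radius (12.5 nm for a 25 nm encapsulin shell) is subtracted to give
the surface distance; negative surface distances mean the shell overlaps the
structure.

The volumetric enrichment (relative labeling index) compares the fraction of
particles within a proximity cutoff of the structure with the share of the
imaged volume occupied by the structure's dilated neighbourhood:

    fold = f_P / f_V,   f_P = n_within / n_total,
    f_V = V(dilate(structure) ∩ lamella) / V(lamella).

A fold of 1 is the uniform-placement expectation; pooling across tomograms
sums counts and voxel volumes before dividing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError, InputError
from .grid import BinaryMask, require_same_geometry
from .particles import ParticleSet

__all__ = [
    "SpatialParams",
    "EnrichmentResult",
    "surface_distances",
    "fraction_within",
    "dilate_mask",
    "volumetric_enrichment",
    "pooled_enrichment",
    "summarize_distances",
]


@dataclass
class SpatialParams:
    """Physical parameters of the proximity analysis (nm)."""

    particle_radius: float = 12.5
    proximity_cutoff: float = 50.0
    dilation_radius: float = 50.0
    interpolate: bool = True  # trilinear EDT sampling; False = nearest voxel

    def __post_init__(self) -> None:
        if self.particle_radius < 0 or self.proximity_cutoff <= 0 or self.dilation_radius <= 0:
            raise ConfigError("spatial parameters must be positive (radius may be 0)")


@dataclass
class EnrichmentResult:
    """Counts and volumes behind one fold-enrichment estimate.

    Volumes may be voxel counts or nm³ — only their ratio enters f_V. The
    identities ``f_P = n_within/n_total``, ``f_V = region/lamella`` and
    ``fold = f_P/f_V`` hold exactly as stored.
    """

    n_within: int
    n_total: int
    region_volume: float
    lamella_volume: float

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise InputError("enrichment needs at least one particle")
        if not 0 <= self.n_within <= self.n_total:
            raise InputError("n_within must lie in [0, n_total]")
        if self.region_volume <= 0:
            raise InputError("dilated region does not intersect the lamella (f_V = 0)")
        if self.lamella_volume <= 0:
            raise InputError("empty lamella mask")

    @classmethod
    def from_counts(cls, n_within: int, n_total: int, volume_fraction: float) -> "EnrichmentResult":
        """Build from published counts plus a printed volume fraction."""
        return cls(n_within, n_total, volume_fraction, 1.0)

    @property
    def particle_fraction(self) -> float:
        return self.n_within / self.n_total

    @property
    def volume_fraction(self) -> float:
        return self.region_volume / self.lamella_volume

    @property
    def fold(self) -> float:
        return self.particle_fraction / self.volume_fraction


def _edt_nm(mask: BinaryMask) -> np.ndarray:
    """Distance (nm) from every voxel centre to the nearest true voxel centre."""
    return ndimage.distance_transform_edt(~mask.data) * mask.voxel_size


def surface_distances(
    particles: ParticleSet,
    structure: BinaryMask,
    params: SpatialParams | None = None,
) -> pd.DataFrame:
    """Centre and surface distances (nm) from each particle to the structure.

    The distance transform of the structure complement is sampled at the
    continuous particle centre by trilinear interpolation (or nearest voxel
    with ``params.interpolate=False``); the surface distance subtracts the
    particle radius and may be negative.
    """
    params = params or SpatialParams()
    if not structure.data.any():
        raise InputError("structure mask is empty")
    coords = particles.coords
    nz, ny, nx = structure.data.shape
    vox = structure.voxel_size
    if coords.size:
        idx = coords / vox  # fractional voxel indices per axis (x, y, z)
        limits = np.array([nx - 1, ny - 1, nz - 1], dtype=float)
        if np.any(idx < -0.5) or np.any(idx > limits + 0.5):
            raise InputError("particle centres fall outside the structure grid")

    edt = _edt_nm(structure)
    if coords.size == 0:
        center = np.empty(0)
    elif params.interpolate:
        center = ndimage.map_coordinates(edt, (coords / vox)[:, ::-1].T, order=1,
                                         mode="nearest")
    else:
        nearest = np.clip(np.round(coords / vox).astype(int), 0,
                          [nx - 1, ny - 1, nz - 1])
        center = edt[nearest[:, 2], nearest[:, 1], nearest[:, 0]]

    df = particles.df
    return pd.DataFrame(
        {
            "particle_id": df["particle_id"].to_numpy()
            if "particle_id" in df.columns else np.arange(len(df)),
            "tomo_id": df["tomo_id"].to_numpy(),
            "center_distance_nm": center,
            "surface_distance_nm": center - params.particle_radius,
        }
    )


def fraction_within(records: pd.DataFrame, cutoff: float) -> tuple[float, int, int]:
    """Fraction of particles with surface distance ≤ cutoff (inclusive).

    Negative surface distances (overlap) always count as within. Returns
    ``(fraction, n_within, n_total)``; an empty collection is an error, never
    a silent zero.
    """
    if len(records) == 0:
        raise InputError("no distance records: fraction undefined")
    d = records["surface_distance_nm"].to_numpy(dtype=float)
    n_within = int((d <= cutoff).sum())
    return n_within / len(d), n_within, len(d)


def dilate_mask(mask: BinaryMask, radius: float) -> BinaryMask:
    """Exact Euclidean dilation: true where the distance transform of the
    complement is ≤ radius (nm). A radius below one voxel cannot change the
    mask on this grid; a warning is emitted and a copy returned."""
    if radius < mask.voxel_size:
        warnings.warn(
            f"dilation radius {radius} nm is below the voxel size "
            f"{mask.voxel_size} nm; returning the mask unchanged",
            stacklevel=2,
        )
        return BinaryMask(mask.data.copy(), mask.voxel_size)
    if not mask.data.any():
        return BinaryMask(mask.data.copy(), mask.voxel_size)
    return BinaryMask(_edt_nm(mask) <= radius, mask.voxel_size)


def volumetric_enrichment(
    particles: ParticleSet,
    region: BinaryMask,
    lamella: BinaryMask,
    params: SpatialParams | None = None,
) -> EnrichmentResult:
    """Fold enrichment of particles around a structure, within a lamella.

    ``region`` is the *pre-dilation* structure (e.g. a segmented contact
    site); it is dilated by ``params.dilation_radius`` and intersected with
    the lamella to form the volume denominator. ``n_within`` counts particles
    whose surface distance to the structure is ≤ ``params.proximity_cutoff``.
    """
    params = params or SpatialParams()
    require_same_geometry(region, lamella, "region and lamella masks")
    if not lamella.data.any():
        raise InputError("empty lamella mask")
    if len(particles) == 0:
        raise InputError("no particles")
    records = surface_distances(particles, region, params)
    _, n_within, n_total = fraction_within(records, params.proximity_cutoff)
    dilated = dilate_mask(region, params.dilation_radius)
    region_vox = int((dilated.data & lamella.data).sum())
    return EnrichmentResult(n_within, n_total, float(region_vox), float(lamella.n_true))


def pooled_enrichment(results: list[EnrichmentResult]) -> EnrichmentResult:
    """Pool across tomograms: sum counts and volumes, then divide."""
    if not results:
        raise InputError("nothing to pool")
    return EnrichmentResult(
        n_within=sum(r.n_within for r in results),
        n_total=sum(r.n_total for r in results),
        region_volume=sum(r.region_volume for r in results),
        lamella_volume=sum(r.lamella_volume for r in results),
    )


def summarize_distances(records: pd.DataFrame, by_tomo: bool = True) -> pd.DataFrame:
    """Mean and sample sd (n−1 denominator) of surface distances.

    Returns one row per tomogram (if ``by_tomo``) plus a pooled row with
    ``tomo_id == "pooled"``. With n = 1 the sd is undefined and reported as
    missing (NaN)."""
    if len(records) == 0:
        raise InputError("no distance records to summarize")

    def _stats(d: np.ndarray) -> dict:
        return {
            "n": len(d),
            "mean_nm": float(np.mean(d)),
            "sd_nm": float(np.std(d, ddof=1)) if len(d) > 1 else np.nan,
        }

    rows = []
    if by_tomo and records["tomo_id"].nunique() > 1:
        for tomo, grp in records.groupby("tomo_id", sort=True):
            rows.append({"tomo_id": tomo,
                         **_stats(grp["surface_distance_nm"].to_numpy(float))})
    rows.append({"tomo_id": "pooled",
                 **_stats(records["surface_distance_nm"].to_numpy(float))})
    return pd.DataFrame(rows)
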