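"""Particle coordinate tables.

A :class:`ParticleSet` wraps a pandas DataFrame with one row per particle in
the physical tomogram frame (nm). The canonical column schema is

    tomo_id, x_nm, y_nm, z_nm, score, source, status

where ``source`` is ``detector`` or ``manual`` and ``status`` is ``retained``
or ``discarded:<category>``. Truth tables from the simulator carry extra
columns (``particle_id``, ``bound``, ``surface_distance_nm``); extra columns
round-trip through CSV untouched.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["ParticleSet", "read_particles", "write_particles", "PARTICLE_COLUMNS"]

PARTICLE_COLUMNS = ["tomo_id", "x_nm", "y_nm", "z_nm", "score", "source", "status"]

SOURCE_DETECTOR = "detector"
SOURCE_MANUAL = "manual"
STATUS_RETAINED = "retained"


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {c: pd.Series(dtype="float64" if "_nm" in c or c == "score" else "object")
         for c in PARTICLE_COLUMNS}
    )


@dataclass
class ParticleSet:
    """Particle records with scores, provenance and curation status."""

    df: pd.DataFrame = field(default_factory=_empty_frame)

    def __post_init__(self) -> None:
        missing = [c for c in PARTICLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"particle table missing columns: {missing}")
        coords = self.df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        if coords.size and not np.all(np.isfinite(coords)):
            raise SchemaError("particle coordinates must be finite")

    @classmethod
    def empty(cls) -> "ParticleSet":
        return cls(_empty_frame())

    @classmethod
    def from_coords(
        cls,
        coords_xyz_nm: np.ndarray,
        scores: np.ndarray | float | None = None,
        source: str = SOURCE_DETECTOR,
        tomo_id: str = "tomo",
        status: str = STATUS_RETAINED,
    ) -> "ParticleSet":
        coords = np.atleast_2d(np.asarray(coords_xyz_nm, dtype=float))
        if coords.size == 0:
            coords = coords.reshape(0, 3)
        n = len(coords)
        if scores is None:
            scores = np.full(n, np.nan)
        scores = np.broadcast_to(np.asarray(scores, dtype=float), (n,))
        df = pd.DataFrame(
            {
                "tomo_id": tomo_id,
                "x_nm": coords[:, 0],
                "y_nm": coords[:, 1],
                "z_nm": coords[:, 2],
                "score": scores,
                "source": source,
                "status": status,
            }
        )
        return cls(df)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of xyz centres in nm."""
        return self.df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)

    def retained(self) -> "ParticleSet":
        return ParticleSet(self.df[self.df["status"] == STATUS_RETAINED].reset_index(drop=True))

    def concat(self, other: "ParticleSet") -> "ParticleSet":
        return ParticleSet(pd.concat([self.df, other.df], ignore_index=True))


def write_particles(path: str | os.PathLike, particles: ParticleSet) -> None:
    particles.df.to_csv(path, index=False, float_format="%.6g")


def read_particles(path: str | os.PathLike, voxel_size_nm: float | None = None) -> ParticleSet:
    """Read a particle CSV.

    If the file stores voxel-index coordinates (columns ``x, y, z``), pass
    ``voxel_size_nm`` to convert them to physical nm on ingest.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # surface the offending row number
        raise SchemaError(f"{path}: malformed CSV ({exc})") from exc
    if voxel_size_nm is not None and {"x", "y", "z"}.issubset(df.columns):
        for axis in "xyz":
            df[f"{axis}_nm"] = df[axis].astype(float) * voxel_size_nm
        df = df.drop(columns=["x", "y", "z"])
    missing = [c for c in PARTICLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    bad = df.index[~np.isfinite(df[["x_nm", "y_nm", "z_nm"]].to_numpy(float)).all(axis=1)]
    if len(bad):
        raise SchemaError(f"{path}: non-finite coordinates at data row(s) {list(bad + 2)}")
    return ParticleSet(df)
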