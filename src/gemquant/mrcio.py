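"""Minimal MRC2014 volume I/O.

Reads and writes single-volume MRC2014 files with the voxel size carried in
the cell-dimension header words. Maps are written as mode 2 (32-bit float),
masks as mode 0 (signed 8-bit); modes 0/1/2/6 are accepted on read. Only the
standard 1024-byte header is handled (no extended headers are written; an
extended header on read is skipped via NSYMBT).

Header sizes are in ångström per the MRC convention; :class:`~gemquant.grid.VoxelGrid`
carries nanometres, so values are converted at this boundary (1 nm = 10 Å).
"""

from __future__ import annotations

import os

import numpy as np

from .errors import InputError
from .grid import BinaryMask, VoxelGrid

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask"]

_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_HEADER_BYTES = 1024


def _build_header(data: np.ndarray, voxel_size_nm: float, mode: int) -> bytes:
    nz, ny, nx = data.shape
    apix = voxel_size_nm * 10.0  # Å per voxel
    hdr_i = np.zeros(256, dtype="<i4")
    hdr_f = hdr_i.view("<f4")
    hdr_i[0:3] = (nx, ny, nz)
    hdr_i[3] = mode
    hdr_i[7:10] = (nx, ny, nz)  # sampling grid mx, my, mz
    hdr_f[10:13] = (nx * apix, ny * apix, nz * apix)  # cell dimensions, Å
    hdr_f[13:16] = 90.0  # cell angles
    hdr_i[16:19] = (1, 2, 3)  # axis order: columns=x, rows=y, sections=z
    hdr_f[19] = float(data.min()) if data.size else 0.0
    hdr_f[20] = float(data.max()) if data.size else 0.0
    hdr_f[21] = float(data.mean()) if data.size else 0.0
    hdr_i[22] = 1  # ISPG=1: volume
    hdr_i[23] = 0  # NSYMBT: no extended header
    hdr_i[52] = int.from_bytes(b"MAP ", "little")
    hdr_i[53] = int.from_bytes(bytes((0x44, 0x44, 0, 0)), "little")  # little-endian stamp
    hdr_f[54] = float(data.std()) if data.size else 0.0
    hdr_i[55] = 0  # NLABL
    return hdr_i.tobytes()


def write_volume(path: str | os.PathLike, grid: VoxelGrid, mode: int = 2) -> None:
    """Write a grid as MRC2014; ``mode`` 2 for maps, 0 for masks."""
    if mode not in _MODE_DTYPES:
        raise InputError(f"unsupported MRC mode {mode}")
    data = np.ascontiguousarray(grid.data, dtype=_MODE_DTYPES[mode])
    with open(path, "wb") as fh:
        fh.write(_build_header(data, grid.voxel_size, mode))
        fh.write(data.tobytes())


def write_mask(path: str | os.PathLike, mask: BinaryMask) -> None:
    write_volume(path, VoxelGrid(mask.data.astype(np.int8), mask.voxel_size), mode=0)


def read_volume(path: str | os.PathLike, voxel_size_nm: float | None = None) -> VoxelGrid:
    """Read an MRC2014 volume.

    ``voxel_size_nm`` overrides the header pixel size; it is *required* when
    the header carries a zero or missing size.
    """
    with open(path, "rb") as fh:
        raw = fh.read(_HEADER_BYTES)
        if len(raw) < _HEADER_BYTES:
            raise InputError(f"{path}: truncated MRC header")
        hdr_i = np.frombuffer(raw, dtype="<i4")
        hdr_f = hdr_i.view("<f4")
        nx, ny, nz = (int(v) for v in hdr_i[0:3])
        mode = int(hdr_i[3])
        if mode not in _MODE_DTYPES:
            raise InputError(f"{path}: unsupported MRC mode {mode}")
        mx = int(hdr_i[7])
        xlen = float(hdr_f[10])
        nsymbt = int(hdr_i[23])
        fh.seek(_HEADER_BYTES + nsymbt)
        dtype = _MODE_DTYPES[mode]
        count = nx * ny * nz
        data = np.frombuffer(fh.read(count * np.dtype(dtype).itemsize), dtype=dtype)
        if data.size != count:
            raise InputError(f"{path}: truncated data block")
        data = data.reshape(nz, ny, nx)

    if voxel_size_nm is None:
        if mx <= 0 or xlen <= 0:
            raise InputError(
                f"{path}: header has no voxel size; pass voxel_size_nm (--voxel-size)"
            )
        voxel_size_nm = (xlen / mx) / 10.0  # Å → nm
    return VoxelGrid(data, float(voxel_size_nm))


def read_mask(path: str | os.PathLike, voxel_size_nm: float | None = None,
              threshold: float = 0.5) -> BinaryMask:
    """Read a mask; non-boolean storage is binarized at ``threshold``."""
    grid = read_volume(path, voxel_size_nm)
    return BinaryMask(grid.data.astype(np.float64) >= threshold, grid.voxel_size)
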