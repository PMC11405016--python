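"""Minimal MRC2014 image reader/writer.

Supports the subset of the format needed for single 2-D micrographs:
modes 0 (int8), 1 (int16), 2 (float32), 6 (uint16) on read; mode 2 on
write. The physical pixel size is carried in the CELLA field (cell
dimensions in angstroms divided by the grid size), which is how EM
software conventionally stores it.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_HEADER_BYTES = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def read_mrc(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Read a 2-D MRC file.

    Returns ``(pixels, pixel_size_angstrom)``; the pixel size is ``None``
    when the header carries a zero cell dimension.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_BYTES)
        if len(header) < _HEADER_BYTES:
            raise ValueError(f"corrupt MRC header (truncated): {path}")
        nx, ny, nz, mode = struct.unpack("<4i", header[0:16])
        if not (0 < nx < 1 << 20 and 0 < ny < 1 << 20 and nz >= 1):
            raise ValueError(f"corrupt MRC header (bad dimensions): {path}")
        if mode not in _MODE_DTYPES:
            raise ValueError(f"unsupported MRC mode {mode}: {path}")
        map_id = header[208:212]
        if map_id not in (b"MAP ", b"\x00\x00\x00\x00"):
            raise ValueError(f"corrupt MRC header (bad MAP stamp): {path}")
        cella_x = struct.unpack("<f", header[40:44])[0]
        nsymbt = struct.unpack("<i", header[92:96])[0]
        fh.seek(_HEADER_BYTES + max(nsymbt, 0))
        dtype = _MODE_DTYPES[mode]
        count = nx * ny
        data = np.fromfile(fh, dtype=dtype, count=count)
        if data.size != count:
            raise ValueError(f"corrupt MRC file (truncated data): {path}")
    pixels = data.reshape(ny, nx)
    pixel_a = cella_x / nx if cella_x > 0 else None
    return pixels, pixel_a


def write_mrc(path: str | Path, pixels: np.ndarray, pixel_size_angstrom: float) -> None:
    """Write a 2-D array as a mode-2 (float32) MRC2014 file."""
    pixels = np.asarray(pixels, dtype=np.float32)
    if pixels.ndim != 2:
        raise ValueError("write_mrc expects a 2-D array")
    if pixel_size_angstrom <= 0:
        raise ValueError("pixel_size_angstrom must be positive")
    ny, nx = pixels.shape
    header = bytearray(_HEADER_BYTES)
    struct.pack_into("<4i", header, 0, nx, ny, 1, 2)  # nx ny nz mode
    struct.pack_into("<3i", header, 28, nx, ny, 1)  # mx my mz
    struct.pack_into(
        "<3f", header, 40, nx * pixel_size_angstrom, ny * pixel_size_angstrom, pixel_size_angstrom
    )  # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # axis order
    struct.pack_into(
        "<3f", header, 76, float(pixels.min()), float(pixels.max()), float(pixels.mean())
    )
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    with open(path, "wb") as fh:
        fh.write(header)
        pixels.tofile(fh)
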