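"""On-disk formats: micrographs (MRC/TIFF), measurement tables (CSV), configs (YAML).

Conventions
-----------
* All physical lengths are nanometers internally. Angstrom values are
  accepted at the boundary (MRC headers, override arguments) and converted
  once on read.
* Image origin is the top-left corner, x increases rightward (columns),
  y increases downward (rows), and pixel centers sit at integer coordinates.
* Tables are CSV, one row per object, with a schema-version comment line so
  that readers can refuse files written by an incompatible version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import mrc

A_PER_NM = 10.0

TABLE_SCHEMA_VERSION = 1
_TABLE_MAGIC = "# evquant-table schema="

MODALITIES = ("cryo", "nstem", "fluor")


@dataclass
class Micrograph:
    """A single 2-D intensity image with its physical pixel size.

    ``pixels`` is a 2-D float array indexed ``[y, x]``; ``pixel_size_nm``
    is the edge length of one pixel in nanometers.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    modality: str = "cryo"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("Micrograph pixels must be a 2-D array")
        if not np.isfinite(self.pixels).all():
            raise ValueError("Micrograph pixels must be finite")
        if not (self.pixel_size_nm > 0):
            raise ValueError("pixel_size_nm must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")

    @property
    def pixel_size_a(self) -> float:
        return self.pixel_size_nm * A_PER_NM

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def read_micrograph(
    path: str | Path,
    pixel_size_override_a: float | None = None,
    modality: str = "cryo",
    source_id: str | None = None,
) -> Micrograph:
    """Read an MRC or TIFF micrograph.

    The pixel size is taken from the MRC header or the TIFF resolution
    metadata unless ``pixel_size_override_a`` (in angstroms) is given.
    A file with no recoverable pixel size and no override is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"micrograph not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".mrc", ".mrcs", ".map"):
        pixels, pixel_a = mrc.read_mrc(path)
    elif suffix in (".tif", ".tiff"):
        pixels, pixel_a = _read_tiff(path)
    else:
        raise ValueError(f"unsupported micrograph format {suffix!r}: {path}")
    if pixel_size_override_a is not None:
        pixel_a = float(pixel_size_override_a)
    if pixel_a is None or pixel_a <= 0:
        raise ValueError(
            f"no pixel size in {path} and no override given; "
            "pass pixel_size_override_a (angstroms)"
        )
    return Micrograph(
        pixels=np.asarray(pixels, dtype=np.float64),
        pixel_size_nm=pixel_a / A_PER_NM,
        modality=modality,
        source_id=source_id if source_id is not None else path.stem,
    )


def _read_tiff(path: Path) -> tuple[np.ndarray, float | None]:
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        pixels = page.asarray()
        pixel_a = None
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                if "pixel_size_nm" in meta:
                    pixel_a = float(meta["pixel_size_nm"]) * A_PER_NM
            except (ValueError, TypeError):
                pass
        if pixel_a is None:
            xres = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is not None and unit is not None:
                num, den = xres.value
                unit_val = getattr(unit.value, "value", unit.value)
                # pixels per unit -> nm per pixel
                unit_nm = {2: 2.54e7, 3: 1e7}.get(int(unit_val))
                if unit_nm and num:
                    pixel_a = (den / num) * unit_nm * A_PER_NM
    return pixels, pixel_a


def write_micrograph(path: str | Path, m: Micrograph) -> Path:
    """Write a micrograph as MRC (float32, pixel size in header) or 16-bit TIFF."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".mrc", ".mrcs", ".map"):
        mrc.write_mrc(path, m.pixels.astype(np.float32), m.pixel_size_a)
    elif suffix in (".tif", ".tiff"):
        lo, hi = float(m.pixels.min()), float(m.pixels.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        data = np.round((m.pixels - lo) * scale).astype(np.uint16)
        meta = {"pixel_size_nm": m.pixel_size_nm, "scale": scale, "offset": lo}
        tifffile.imwrite(str(path), data, description=json.dumps(meta))
    else:
        raise ValueError(f"unsupported output format {suffix!r}")
    return path


def write_multichannel_tiff(path: str | Path, channels: np.ndarray, channel_names: list[str]) -> Path:
    """Write a (C, H, W) float stack as a multi-page 32-bit TIFF with channel names."""
    channels = np.asarray(channels, dtype=np.float32)
    if channels.ndim != 3:
        raise ValueError("expected a (C, H, W) stack")
    if len(channel_names) != channels.shape[0]:
        raise ValueError("channel_names length must match the number of channels")
    meta = {"channel_names": list(channel_names)}
    tifffile.imwrite(str(path), channels, description=json.dumps(meta))
    return Path(path)


def read_multichannel_tiff(path: str | Path) -> tuple[np.ndarray, list[str]]:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray().astype(np.float64)
        names: list[str] = []
        desc = tif.pages[0].tags.get("ImageDescription")
        if desc is not None:
            try:
                names = list(json.loads(desc.value).get("channel_names", []))
            except (ValueError, TypeError):
                names = []
    if data.ndim == 2:
        data = data[None]
    if not names:
        names = [f"ch{i}" for i in range(data.shape[0])]
    return data, names


@dataclass
class MeasurementTable:
    """A per-object (vesicle or bead) measurement table with a schema version.

    Thin wrapper over a pandas DataFrame that enforces required columns on
    write and version agreement on read.
    """

    data: pd.DataFrame
    schema_version: int = TABLE_SCHEMA_VERSION
    required_columns: tuple[str, ...] = field(default=("source_id",))

    def validate(self) -> None:
        for col in self.required_columns:
            if col not in self.data.columns:
                raise ValueError(f"measurement table missing required column {col!r}")
            if len(self.data) and self.data[col].isna().any():
                raise ValueError(f"NaN in required column {col!r}")


def write_table(table: MeasurementTable, path: str | Path) -> Path:
    table.validate()
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{_TABLE_MAGIC}{table.schema_version}\n")
        table.data.to_csv(fh, index=False)
    return path


def read_table(path: str | Path, required_columns: tuple[str, ...] = ("source_id",)) -> MeasurementTable:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(_TABLE_MAGIC):
            raise ValueError(f"not an evquant table (missing schema line): {path}")
        version = int(first[len(_TABLE_MAGIC):].strip())
        if version != TABLE_SCHEMA_VERSION:
            raise ValueError(
                f"table schema version {version} != supported {TABLE_SCHEMA_VERSION}: {path}"
            )
        data = pd.read_csv(fh)
    table = MeasurementTable(data=data, schema_version=version, required_columns=required_columns)
    table.validate()
    return table


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: dict, path: str | Path) -> Path:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return Path(path)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping, stored with every run's outputs."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
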