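"""Readers and writers for on-disk artifacts.

Images travel as MRC2014 (micrographs, particle stacks, templates, class
averages), particle coordinates as tab-separated tables, evaluation curves
(ranked peaks, FRC, SSNR) as two/three-column TSV, and configuration as a
single YAML tree that is echoed into the log.

Conventions used throughout the package:

* pixel coordinates are 0-based, ``(x, y) = (column, row)``, and refer to
  the **center** of a particle box;
* image samples are 32-bit floats in memory and on disk (MRC mode 2);
* a stack is returned with the image index leading, ``(n, ny, nx)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("bofem")

__all__ = [
    "ImageHeaderInfo",
    "CoordinateRecord",
    "FormatError",
    "read_image",
    "write_image",
    "read_coords",
    "write_coords",
    "read_curve",
    "write_curve",
    "load_config",
    "save_config",
]


class FormatError(ValueError):
    """Raised for malformed or unsupported on-disk data."""


@dataclass(frozen=True)
class ImageHeaderInfo:
    """Shape and sampling metadata of an MRC image or stack."""

    nx: int
    ny: int
    nz: int
    pixel_size: float  # Angstrom / pixel
    mode: int  # MRC sample encoding

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1 or self.nz < 1:
            raise FormatError(
                f"image dimensions must be >= 1, got nx={self.nx} ny={self.ny} nz={self.nz}"
            )
        if not self.pixel_size > 0:
            raise FormatError(f"pixel_size must be > 0, got {self.pixel_size}")


@dataclass
class CoordinateRecord:
    """One ranked particle pick: box-center position and its FLC peak."""

    micrograph_id: str
    x_center: float
    y_center: float
    peak: float
    rank: int


# ---------------------------------------------------------------------------
# MRC2014
# ---------------------------------------------------------------------------

# 1024-byte main header; field names follow the MRC2014 specification.
_HEADER_DTYPE = np.dtype(
    [
        ("nx", "<i4"), ("ny", "<i4"), ("nz", "<i4"),
        ("mode", "<i4"),
        ("nxstart", "<i4"), ("nystart", "<i4"), ("nzstart", "<i4"),
        ("mx", "<i4"), ("my", "<i4"), ("mz", "<i4"),
        ("cella", "<f4", 3), ("cellb", "<f4", 3),
        ("mapc", "<i4"), ("mapr", "<i4"), ("maps", "<i4"),
        ("dmin", "<f4"), ("dmax", "<f4"), ("dmean", "<f4"),
        ("ispg", "<i4"), ("nsymbt", "<i4"),
        ("extra", "V100"),
        ("origin", "<f4", 3),
        ("map", "S4"), ("machst", "<u1", 4),
        ("rms", "<f4"), ("nlabl", "<i4"),
        ("label", "S800"),
    ]
)
assert _HEADER_DTYPE.itemsize == 1024

_MODE_DTYPES = {
    0: np.dtype("<i1"),
    1: np.dtype("<i2"),
    2: np.dtype("<f4"),
    6: np.dtype("<u2"),
}


def read_image(path: str | Path) -> tuple[np.ndarray, ImageHeaderInfo]:
    """Read an MRC2014 file.

    Returns ``(pixels, header)``; a single image comes back 2D ``(ny, nx)``,
    a stack 3D ``(nz, ny, nx)``.  Data are converted to float32.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_DTYPE.itemsize:
        raise FormatError(f"{path}: file shorter than the 1024-byte MRC header")
    hdr = np.frombuffer(raw[:1024], dtype=_HEADER_DTYPE)[0]
    nx, ny, nz = int(hdr["nx"]), int(hdr["ny"]), int(hdr["nz"])
    mode = int(hdr["mode"])
    if mode not in _MODE_DTYPES:
        raise FormatError(f"{path}: unsupported MRC mode={mode}")
    if nx < 1 or ny < 1 or nz < 1:
        raise FormatError(f"{path}: invalid header field nx/ny/nz = {nx}/{ny}/{nz}")
    mx = int(hdr["mx"]) or nx
    cella_x = float(hdr["cella"][0])
    pixel_size = cella_x / mx if cella_x > 0 else 1.0
    dtype = _MODE_DTYPES[mode]
    offset = 1024 + int(hdr["nsymbt"])
    count = nx * ny * nz
    if len(raw) < offset + count * dtype.itemsize:
        raise FormatError(f"{path}: data block truncated (nx*ny*nz={count})")
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)
    pixels = data.reshape(nz, ny, nx).astype(np.float32)
    if nz == 1:
        pixels = pixels[0]
    info = ImageHeaderInfo(nx=nx, ny=ny, nz=nz, pixel_size=pixel_size, mode=mode)
    return pixels, info


def write_image(path: str | Path, pixels: np.ndarray, pixel_size: float = 1.0) -> None:
    """Write a 2D image or 3D stack as MRC2014 mode 2 (float32)."""
    pixels = np.asarray(pixels)
    if not np.all(np.isfinite(pixels)):
        raise FormatError("refusing to write non-finite pixel values")
    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.ndim != 3:
        raise FormatError(f"expected 2D or 3D array, got ndim={pixels.ndim}")
    if not pixel_size > 0:
        raise FormatError(f"pixel_size must be > 0, got {pixel_size}")
    nz, ny, nx = pixels.shape
    data = np.ascontiguousarray(pixels, dtype="<f4")
    hdr = np.zeros(1, dtype=_HEADER_DTYPE)[0]
    hdr["nx"], hdr["ny"], hdr["nz"] = nx, ny, nz
    hdr["mode"] = 2
    hdr["mx"], hdr["my"], hdr["mz"] = nx, ny, nz
    hdr["cella"] = (nx * pixel_size, ny * pixel_size, nz * pixel_size)
    hdr["cellb"] = (90.0, 90.0, 90.0)
    hdr["mapc"], hdr["mapr"], hdr["maps"] = 1, 2, 3
    hdr["dmin"], hdr["dmax"], hdr["dmean"] = (
        float(data.min()), float(data.max()), float(data.mean()),
    )
    hdr["ispg"] = 0
    hdr["map"] = b"MAP "
    hdr["machst"] = (0x44, 0x44, 0, 0)  # little-endian
    hdr["rms"] = float(data.std())
    with open(path, "wb") as fh:
        fh.write(hdr.tobytes())
        fh.write(data.tobytes())


# ---------------------------------------------------------------------------
# Coordinate tables
# ---------------------------------------------------------------------------

_COORD_COLUMNS = ["micrograph_id", "x", "y", "peak", "rank"]


def write_coords(path: str | Path, records: Sequence[CoordinateRecord]) -> None:
    """Write ranked picks as TSV with a one-line header."""
    df = pd.DataFrame(
        {
            "micrograph_id": [r.micrograph_id for r in records],
            "x": [r.x_center for r in records],
            "y": [r.y_center for r in records],
            "peak": [r.peak for r in records],
            "rank": [r.rank for r in records],
        },
        columns=_COORD_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_coords(path: str | Path) -> list[CoordinateRecord]:
    """Read a coordinate TSV back into records, validating every row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _COORD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records: list[CoordinateRecord] = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # 1-based, after the header line
        try:
            records.append(
                CoordinateRecord(
                    micrograph_id=str(row["micrograph_id"]),
                    x_center=float(row["x"]),
                    y_center=float(row["y"]),
                    peak=float(row["peak"]),
                    rank=int(row["rank"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed row at line {line_no}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# Curve tables and config
# ---------------------------------------------------------------------------

def write_curve(path: str | Path, columns: dict[str, np.ndarray]) -> None:
    """Write named, equal-length columns (ranked peaks, FRC, SSNR...) as TSV."""
    pd.DataFrame(columns).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_curve(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path: str | Path) -> dict:
    """Load a YAML config tree and echo it into the log."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    logger.info("config %s: %s", path, cfg)
    return cfg


def save_config(path: str | Path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
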