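"""Minimal multi-band raster container with TIFF persistence.

Rasters are stored band-major ``(bands, rows, cols)`` in float32 with an
explicit per-cell validity mask.  On disk, invalid cells carry the nodata
value and acquisition date / band names travel in the TIFF description tag.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

NODATA = -9999.0


@dataclass
class Raster:
    """A dated multi-band raster with a validity mask.

    Parameters
    ----------
    data : ndarray, shape (bands, rows, cols)
        Cell values; contents at invalid cells are unspecified.
    valid : ndarray of bool, same shape as ``data``
        True where the observation is usable.
    band_names : list of str
        One name per band.
    date : datetime.date or None
        Acquisition date, when the raster represents a single scene.
    """

    data: np.ndarray
    valid: np.ndarray
    band_names: list[str] = field(default_factory=list)
    date: datetime.date | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"raster data must be 3-D (bands, rows, cols), got {self.data.shape}")
        if self.valid is None:
            self.valid = np.ones(self.data.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.data.shape:
            raise ValueError("valid mask shape must match data shape")
        if self.band_names and len(self.band_names) != self.data.shape[0]:
            raise ValueError("band_names length must match band count")

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def band(self, name: str) -> np.ndarray:
        """Return the data plane for the named band."""
        try:
            i = self.band_names.index(name)
        except ValueError:
            raise KeyError(f"no band named {name!r}; have {self.band_names}") from None
        return self.data[i]

    def band_valid(self, name: str) -> np.ndarray:
        return self.valid[self.band_names.index(name)]


def write_raster(path: str | Path, raster: Raster, nodata: float = NODATA) -> Path:
    """Write a raster as a multi-band float32 TIFF with a metadata tag."""
    path = Path(path)
    out = np.where(raster.valid, raster.data, nodata).astype(np.float32)
    meta = {
        "band_names": list(raster.band_names),
        "nodata": float(nodata),
        "date": raster.date.isoformat() if raster.date else None,
    }
    tifffile.imwrite(path, out, photometric="minisblack", planarconfig="separate", metadata=meta)
    return path


def read_raster(path: str | Path) -> Raster:
    """Read a raster written by :func:`write_raster`."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None]
    data = data.astype(np.float32)
    nodata = float(meta.get("nodata", NODATA))
    valid = data != nodata
    date_s = meta.get("date")
    date = datetime.date.fromisoformat(date_s) if date_s else None
    names = list(meta.get("band_names", []) or [])
    return Raster(data=data, valid=valid, band_names=names, date=date)


def check_same_grid(rasters: Sequence[Raster], names: Sequence[str] | None = None) -> None:
    """Raise ValueError naming the first raster whose grid differs from the first."""
    if not rasters:
        raise ValueError("no rasters given")
    ref = rasters[0].shape
    for i, r in enumerate(rasters):
        if r.shape != ref:
            label = names[i] if names else f"raster #{i}"
            raise ValueError(f"grid mismatch: {label} has shape {r.shape}, expected {ref}")
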