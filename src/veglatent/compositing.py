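"""Monthly median compositing of per-scene index stacks.

Dated 16-band index stacks are aggregated into a single 192-band annual
composite ordered month-major: band ``m * 16 + j`` holds index ``j`` (registry
order) for calendar month ``m + 1``.  A cell is valid iff at least one
unmasked observation of that index exists in that month; gaps can be filled
afterwards by temporal interpolation within each index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from veglatent.indices import INDEX_NAMES
from veglatent.raster import Raster, check_same_grid

logger = logging.getLogger(__name__)

N_MONTHS = 12
N_FEATURES = N_MONTHS * len(INDEX_NAMES)  # 192


def composite_band_names() -> list[str]:
    """Band names ``m{MM}_{INDEX}`` in month-major order."""
    return [f"m{m + 1:02d}_{name}" for m in range(N_MONTHS) for name in INDEX_NAMES]


@dataclass
class MonthlyComposite:
    """Per-pixel annual feature stack of monthly median index values.

    Attributes
    ----------
    data : ndarray, shape (192, rows, cols)
        Month-major stack; contents of invalid cells are unspecified.
    valid : ndarray of bool, same shape
        True where >= 1 unmasked observation contributed.
    counts : ndarray of int, same shape
        Number of scenes contributing per cell.
    """

    data: np.ndarray
    valid: np.ndarray
    counts: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def to_raster(self) -> Raster:
        return Raster(
            data=self.data.astype(np.float32),
            valid=self.valid,
            band_names=composite_band_names(),
        )

    @classmethod
    def from_raster(cls, raster: Raster) -> "MonthlyComposite":
        if raster.n_bands != N_FEATURES:
            raise ValueError(f"composite raster must have {N_FEATURES} bands, got {raster.n_bands}")
        counts = raster.valid.astype(np.int32)
        return cls(data=raster.data.astype(np.float64), valid=raster.valid.copy(), counts=counts)


def monthly_median(stacks: list[Raster]) -> MonthlyComposite:
    """Composite dated index stacks into per-pixel monthly medians.

    Each cell (pixel, month, index) is the median over the unmasked
    observations of that index among the scenes acquired in that calendar
    month (all years pooled); even counts use the mean of the two central
    order statistics.  Cells with no observation are flagged invalid.
    """
    if not stacks:
        raise ValueError("at least one index stack is required")
    names = [s.date.isoformat() if s.date else f"stack #{i}" for i, s in enumerate(stacks)]
    check_same_grid(stacks, names)
    n_idx = len(INDEX_NAMES)
    for s, label in zip(stacks, names):
        if s.n_bands != n_idx:
            raise ValueError(f"stack {label} has {s.n_bands} bands, expected {n_idx}")
        if s.date is None:
            raise ValueError(f"stack {label} lacks an acquisition date")

    shape = stacks[0].shape
    data = np.zeros((N_FEATURES,) + shape, dtype=np.float64)
    valid = np.zeros((N_FEATURES,) + shape, dtype=bool)
    counts = np.zeros((N_FEATURES,) + shape, dtype=np.int32)

    for m in range(N_MONTHS):
        group = [s for s in stacks if s.date.month == m + 1]
        if not group:
            continue
        # (scenes, 16, H, W) with masked observations as NaN
        obs = np.stack([np.where(s.valid, s.data.astype(np.float64), np.nan) for s in group])
        n_obs = np.sum(~np.isnan(obs), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells handled below
            med = np.nanmedian(obs, axis=0)
        sl = slice(m * n_idx, (m + 1) * n_idx)
        data[sl] = np.where(n_obs > 0, med, 0.0)
        valid[sl] = n_obs > 0
        counts[sl] = n_obs
    return MonthlyComposite(data=data, valid=valid, counts=counts)


def fill_gaps(comp: MonthlyComposite) -> tuple[MonthlyComposite, np.ndarray]:
    """Fill invalid cells by linear interpolation across months per index.

    Interior gaps are linearly interpolated between the nearest valid months
    of the same index; gaps at the ends take the nearest valid value.  Pixels
    where some index has zero valid months cannot be filled and are returned
    in a boolean ``dropped`` map (rows, cols) for downstream exclusion.
    """
    n_idx = len(INDEX_NAMES)
    h, w = comp.shape
    data = comp.data.reshape(N_MONTHS, n_idx, h * w).copy()
    valid = comp.valid.reshape(N_MONTHS, n_idx, h * w)

    n_valid_months = valid.sum(axis=0)  # (16, P)
    dropped_flat = np.any(n_valid_months == 0, axis=0)  # (P,)
    n_filled = 0

    months = np.arange(N_MONTHS, dtype=float)
    fill_targets = np.argwhere(~np.all(valid, axis=0) & (n_valid_months > 0))
    for j, p in fill_targets:
        ok = valid[:, j, p]
        # np.interp clamps to end values, giving nearest-value extrapolation
        data[~ok, j, p] = np.interp(months[~ok], months[ok], data[ok, j, p])
        n_filled += int(np.count_nonzero(~ok))

    if n_filled:
        logger.info("fill_gaps: interpolated %d cell(s)", n_filled)
    n_dropped = int(np.count_nonzero(dropped_flat))
    if n_dropped:
        logger.warning("fill_gaps: %d pixel(s) have an index with zero valid months; flagged for drop", n_dropped)

    out_valid = comp.valid.copy()
    out_valid.reshape(N_MONTHS, n_idx, h * w)[:, :, ~dropped_flat] = True
    filled = MonthlyComposite(
        data=data.reshape(N_FEATURES, h, w),
        valid=out_valid,
        counts=comp.counts.copy(),
    )
    return filled, dropped_flat.reshape(h, w)


def pixel_matrix(comp: MonthlyComposite, exclude: np.ndarray | None = None) -> np.ndarray:
    """Flatten a composite into an (n_pixels, 192) matrix, row-major pixels.

    ``exclude`` is an optional (rows, cols) boolean map of pixels to drop.
    """
    h, w = comp.shape
    X = comp.data.reshape(N_FEATURES, h * w).T
    if exclude is not None:
        X = X[~exclude.ravel()]
    return np.ascontiguousarray(X, dtype=np.float64)
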