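"""Latent-space visualisation: 3-D class scatter plots and RGB composites."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from veglatent.evaluation import LabelledFeatures
from veglatent.raster import Raster


@dataclass
class StretchParams:
    """Per-channel (low, high) cut values for the linear display stretch."""

    cuts: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for lo, hi in self.cuts:
            if lo > hi:
                raise ValueError("stretch low cut must not exceed high cut")


def class_colors(classes: list[str]) -> dict[str, tuple]:
    """Deterministic class -> color mapping (tab20 cycle, sorted names)."""
    cmap = plt.get_cmap("tab20")
    return {c: cmap(i % 20) for i, c in enumerate(sorted(classes))}


def scatter3d(latents: LabelledFeatures, out: str | Path, title: str = "") -> Path:
    """3-D scatter of the first three latent dimensions, one color per class."""
    if latents.n_features < 3:
        raise ValueError(f"need at least 3 latent dimensions, got {latents.n_features}")
    colors = class_colors(list(np.unique(latents.y)))
    fig = plt.figure(figsize=(8, 7))
    ax = fig.add_subplot(projection="3d")
    for cls, color in colors.items():
        mask = latents.y == cls
        ax.scatter(
            latents.X[mask, 0], latents.X[mask, 1], latents.X[mask, 2],
            s=6, color=color, label=cls, depthshade=False,
        )
    ax.set_xlabel("latent 1")
    ax.set_ylabel("latent 2")
    ax.set_zlabel("latent 3")
    if title:
        ax.set_title(title)
    ax.legend(loc="center left", bbox_to_anchor=(1.05, 0.5), fontsize=6)
    out = Path(out)
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out


def percentile_stretch(raster: Raster, low: float = 2.0, high: float = 98.0) -> StretchParams:
    """Per-channel percentile cut values over valid pixels."""
    cuts = []
    for b in range(raster.n_bands):
        vals = raster.data[b][raster.valid[b]]
        if vals.size == 0:
            cuts.append((0.0, 0.0))
        else:
            cuts.append((float(np.percentile(vals, low)), float(np.percentile(vals, high))))
    return StretchParams(cuts=cuts)


def rgb_composite(raster: Raster, stretch: StretchParams | None = None) -> np.ndarray:
    """Render a 3-band raster as (rows, cols, 3) uint8.

    Channel order is band 1, 2, 3 -> R, G, B.  Each band is linearly mapped
    from its (low, high) window to [0, 255] and clipped; a degenerate window
    (low == high) renders mid-gray 127; invalid pixels render 0.
    """
    if raster.n_bands != 3:
        raise ValueError(
            f"rgb_composite needs exactly 3 bands, got {raster.n_bands}; "
            "select 3 channels first"
        )
    if stretch is None:
        stretch = percentile_stretch(raster)
    if len(stretch.cuts) != 3:
        raise ValueError("stretch must provide cuts for exactly 3 channels")

    h, w = raster.shape
    out = np.zeros((h, w, 3), dtype=np.uint8)
    for b, (lo, hi) in enumerate(stretch.cuts):
        plane = raster.data[b].astype(np.float64)
        if hi > lo:
            scaled = (plane - lo) / (hi - lo) * 255.0
            vals = np.clip(np.rint(scaled), 0, 255)
        else:
            vals = np.full((h, w), 127.0)
        vals = np.where(raster.valid[b], vals, 0.0)
        out[:, :, b] = vals.astype(np.uint8)
    return out


def save_rgb(image: np.ndarray, out: str | Path) -> Path:
    out = Path(out)
    plt.imsave(out, image)
    return out
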