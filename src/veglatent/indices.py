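"""Spectral vegetation indices computed from six band roles.

Sixteen indices are registered in a fixed order (ARVI .. VARI).  Each is
computed in double precision from the Blue (B), Green (G), Red (R),
RedEdge1 (RE1), RedEdge3 (RE3) and NIR (N) reflectances.  A near-zero
denominator masks that single index value; the other fifteen survive.

Two registry notes (both deliberate):

* ARVI uses the Kaufman-Tanre form with gamma = 1, i.e. rb = 2R - B, so
  ARVI = (N - (2R - B)) / (N + (2R - B)).
* GCI is N/R - 1 exactly as tabulated in the source material, despite the
  "Green" in its name suggesting N/G - 1.
"""

from __future__ import annotations

import logging

import numpy as np

from veglatent.raster import Raster

logger = logging.getLogger(__name__)

DENOM_EPS = 1e-12

BAND_ROLES = ("B", "G", "R", "RE1", "RE3", "N")


def _ratio(num, den):
    """Elementwise num/den with |den| < DENOM_EPS masked out."""
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    ok = np.abs(den) >= DENOM_EPS
    out = np.divide(num, np.where(ok, den, 1.0))
    return out, ok


def _arvi(B, G, R, RE1, RE3, N):
    rb = 2.0 * R - B
    return _ratio(N - rb, N + rb)


def _evi(B, G, R, RE1, RE3, N):
    return _ratio(2.5 * (N - R), (N + 6.0 * R - 7.5 * B) + 1.0)


def _gari(B, G, R, RE1, RE3, N):
    g = G - 1.7 * (B - R)
    return _ratio(N - g, N + g)


def _gci(B, G, R, RE1, RE3, N):
    val, ok = _ratio(N, R)
    return val - 1.0, ok


def _gli(B, G, R, RE1, RE3, N):
    return _ratio((G - R) + (G - B), 2.0 * G + R + B)


def _gndvi(B, G, R, RE1, RE3, N):
    return _ratio(N - G, N + G)


def _grvi(B, G, R, RE1, RE3, N):
    return _ratio(G - R, G + R)


def _mrendvi(B, G, R, RE1, RE3, N):
    return _ratio(RE3 - RE1, RE3 + RE1 - 2.0 * B)


def _mresr(B, G, R, RE1, RE3, N):
    return _ratio(RE3 - B, RE1 - B)


def _msavi(B, G, R, RE1, RE3, N):
    N = np.asarray(N, dtype=np.float64)
    R = np.asarray(R, dtype=np.float64)
    # discriminant (2N+1)^2 - 8(N-R) = (2N-1)^2 + 8R >= 0 for R >= 0
    disc = (2.0 * N + 1.0) ** 2 - 8.0 * (N - R)
    ok = disc >= 0.0
    val = (2.0 * N + 1.0 - np.sqrt(np.where(ok, disc, 0.0))) / 2.0
    return val, ok


def _ndvi(B, G, R, RE1, RE3, N):
    return _ratio(N - R, N + R)


def _osavi(B, G, R, RE1, RE3, N):
    return _ratio(N - R, N + R + 0.16)


def _rendvi(B, G, R, RE1, RE3, N):
    return _ratio(RE3 - RE1, RE3 + RE1)


def _savi(B, G, R, RE1, RE3, N):
    return _ratio(1.5 * (N - R), N + R + 0.5)


def _sipi(B, G, R, RE1, RE3, N):
    return _ratio(N - B, N - R)


def _vari(B, G, R, RE1, RE3, N):
    return _ratio(G - R, G + R - B)


INDEX_REGISTRY = {
    "ARVI": _arvi,
    "EVI": _evi,
    "GARI": _gari,
    "GCI": _gci,
    "GLI": _gli,
    "GNDVI": _gndvi,
    "GRVI": _grvi,
    "MRENDVI": _mrendvi,
    "MRESR": _mresr,
    "MSAVI": _msavi,
    "NDVI": _ndvi,
    "OSAVI": _osavi,
    "RENDVI": _rendvi,
    "SAVI": _savi,
    "SIPI": _sipi,
    "VARI": _vari,
}

INDEX_NAMES: tuple[str, ...] = tuple(INDEX_REGISTRY)


def compute_index(name: str, bands: dict) -> tuple[np.ndarray, np.ndarray]:
    """Compute one index from a mapping of band role -> value or array.

    Returns ``(value, valid)``; ``valid`` is False where the formula's
    denominator (or square-root argument) is degenerate.  Scalars in,
    0-d arrays out.
    """
    if name not in INDEX_REGISTRY:
        raise KeyError(f"unknown index {name!r}; known: {list(INDEX_NAMES)}")
    missing = [r for r in BAND_ROLES if r not in bands]
    if missing:
        raise ValueError(f"missing band role(s): {missing}")
    fn = INDEX_REGISTRY[name]
    return fn(*(np.asarray(bands[r], dtype=np.float64) for r in BAND_ROLES))


def compute_stack(scene: Raster) -> Raster:
    """Compute all 16 indices for a six-band scene.

    The output raster has 16 bands in registry order; a pixel masked in the
    input is masked in all 16 outputs, and near-zero denominators mask the
    affected index only.  Per-index masked-cell counts are logged.
    """
    missing = [r for r in BAND_ROLES if r not in scene.band_names]
    if missing:
        raise ValueError(f"scene is missing band role(s): {missing}")
    bands = {r: scene.band(r).astype(np.float64) for r in BAND_ROLES}
    in_valid = np.logical_and.reduce([scene.band_valid(r) for r in BAND_ROLES])

    data = np.empty((len(INDEX_NAMES),) + scene.shape, dtype=np.float32)
    valid = np.empty_like(data, dtype=bool)
    for j, name in enumerate(INDEX_NAMES):
        val, ok = INDEX_REGISTRY[name](*(bands[r] for r in BAND_ROLES))
        v = in_valid & ok
        data[j] = val.astype(np.float32)
        valid[j] = v
        n_degenerate = int(np.count_nonzero(in_valid & ~ok))
        if n_degenerate:
            logger.info("index %s: %d cell(s) masked by degenerate denominator", name, n_degenerate)
    return Raster(data=data, valid=valid, band_names=list(INDEX_NAMES), date=scene.date)
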