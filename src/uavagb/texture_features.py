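"""GLCM texture statistics per plot ROI, band, and ridge-relative direction.

A gray level co-occurrence matrix (GLCM) tallies, for one pixel offset, how
often each ordered pair of quantized gray levels co-occurs; symmetrized and
normalized it is a joint probability over level pairs from which the six
texture statistics (VAR, HOM, CON, DIS, ENT, SEC) are computed with the
standard Haralick definitions.

Directions are defined relative to the crop ridges rather than the image
axes: D_par runs along the ridges, D_perp across them, D_45 diagonally.
On ridge-periodic canopies the cross-ridge offset sees the plant/soil
alternation, so CON and DIS are larger in D_perp than in D_par — the
directional structure the band/direction screening exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from uavagb.raster_io import BAND_LABELS, WAVELENGTHS, ReflectanceCube, ROI, _check_roi

DIRECTIONS: tuple[str, ...] = ("D_par", "D_perp", "D_45")

STAT_NAMES: tuple[str, ...] = ("VAR", "HOM", "CON", "DIS", "ENT", "SEC")

#: default gray-level count; community convention, configurable everywhere
DEFAULT_LEVELS = 32


@dataclass
class GLCMatrix:
    """Normalized (and by default symmetrized) co-occurrence matrix."""

    levels: int
    direction: str
    distance: int
    matrix: np.ndarray
    symmetric: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (self.levels, self.levels):
            raise ValueError("matrix shape must be (levels, levels)")
        if self.matrix.min() < 0:
            raise ValueError("GLCM entries must be non-negative")
        if abs(self.matrix.sum() - 1.0) > 1e-12:
            raise ValueError("GLCM must sum to 1")


def direction_offset(direction: str, ridge_axis: str = "row") -> tuple[int, int]:
    """Map a ridge-relative direction to a (drow, dcol) pixel offset.

    ``ridge_axis`` is the image axis the ridges run parallel to.  With
    ridges along rows, "along the ridge" is a column step and "across" a
    row step; with ridges along columns the two swap.  The 45° direction is
    the unit diagonal either way.
    """
    if ridge_axis not in ("row", "col"):
        raise ValueError("ridge_axis must be 'row' or 'col'")
    if direction == "D_par":
        return (0, 1) if ridge_axis == "row" else (1, 0)
    if direction == "D_perp":
        return (1, 0) if ridge_axis == "row" else (0, 1)
    if direction == "D_45":
        return (1, 1)
    raise ValueError(f"unknown direction {direction!r}")


def quantize(values: np.ndarray, levels: int) -> np.ndarray:
    """Linear min–max quantization of an ROI into ``levels`` equal-width bins.

    The maximum maps into the top bin ``levels - 1``; a constant ROI maps
    entirely to bin 0.
    """
    v = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        return np.zeros(v.shape, dtype=np.intp)
    idx = np.floor((v - vmin) / (vmax - vmin) * levels).astype(np.intp)
    return np.minimum(idx, levels - 1)


def compute_glcm(gray: np.ndarray, direction: str, distance: int = 1,
                 levels: int | None = None, symmetric: bool = True,
                 ridge_axis: str = "row") -> GLCMatrix:
    """Co-occurrence matrix of a quantized grid at one ridge-relative offset.

    Counts ordered pixel pairs separated by ``distance`` steps of the
    direction's offset vector, adds the transpose when ``symmetric``, and
    normalizes to probabilities.
    """
    g = np.asarray(gray)
    if not np.issubdtype(g.dtype, np.integer):
        raise ValueError("gray grid must be integer (use quantize first)")
    if levels is None:
        levels = int(g.max()) + 1
    if g.min() < 0 or g.max() >= levels:
        raise ValueError("gray levels outside [0, levels)")
    dr, dc = direction_offset(direction, ridge_axis)
    dr, dc = dr * distance, dc * distance
    h, w = g.shape
    if h <= dr or w <= dc:
        raise ValueError(
            f"ROI {g.shape} too small for offset ({dr}, {dc})")
    a = g[: h - dr, : w - dc].ravel()
    b = g[dr:, dc:].ravel()
    counts = np.bincount(a * levels + b,
                         minlength=levels * levels).astype(np.float64)
    mat = counts.reshape(levels, levels)
    if symmetric:
        mat = mat + mat.T
    mat /= mat.sum()
    return GLCMatrix(levels=levels, direction=direction, distance=distance,
                     matrix=mat, symmetric=symmetric)


def glcm_statistics(glcm: GLCMatrix) -> dict[str, float]:
    """The six texture statistics of one GLCM.

    CON = ΣP(i,j)(i−j)²;  DIS = ΣP|i−j|;  HOM = ΣP/(1+(i−j)²);
    ENT = −ΣP·lnP (0·ln0 = 0);  SEC = ΣP²;  VAR = ΣP(i,j)(i−μ)² with μ the
    marginal mean Σi·P_i.  A constant image therefore gives
    CON = DIS = VAR = ENT = 0 and HOM = SEC = 1.
    """
    p = glcm.matrix
    n = glcm.levels
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    diff = i - j
    mu = float((i * p).sum())
    pos = p > 0
    ent = float(-(p[pos] * np.log(p[pos])).sum())
    return {
        "VAR": float((p * (i - mu) ** 2).sum()),
        "HOM": float((p / (1.0 + diff ** 2)).sum()),
        "CON": float((p * diff ** 2).sum()),
        "DIS": float((p * np.abs(diff)).sum()),
        "ENT": ent,
        "SEC": float((p ** 2).sum()),
    }


def plot_texture_features(cube: ReflectanceCube, roi: ROI,
                          levels: int = DEFAULT_LEVELS, distance: int = 1,
                          ridge_axis: str = "row",
                          symmetric: bool = True) -> dict[str, float]:
    """All 6 bands × 3 directions × 6 statistics for one plot ROI.

    Keys follow the feature-table convention ``TEX_{band}_{dir}_{stat}``
    with ``dir`` ∈ {Dpar, Dperp, D45}, e.g. ``TEX_B_Dperp_ENT``.
    """
    _check_roi(roi, cube.shape)
    r0, r1, c0, c1 = roi
    out: dict[str, float] = {}
    for label, band in zip(BAND_LABELS, cube.values):
        gray = quantize(band[r0:r1, c0:c1], levels)
        for direction in DIRECTIONS:
            glcm = compute_glcm(gray, direction, distance=distance,
                                levels=levels, symmetric=symmetric,
                                ridge_axis=ridge_axis)
            stats = glcm_statistics(glcm)
            dir_tag = direction.replace("D_par", "Dpar").replace(
                "D_perp", "Dperp").replace("D_45", "D45")
            for stat, value in stats.items():
                out[f"TEX_{label}_{dir_tag}_{stat}"] = value
    return out


def texture_columns(band: str, direction: str) -> list[str]:
    """Feature-table column names of one (band, direction) texture set."""
    dir_tag = direction.replace("D_par", "Dpar").replace(
        "D_perp", "Dperp").replace("D_45", "D45")
    return [f"TEX_{band}_{dir_tag}_{s}" for s in STAT_NAMES]


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r with zero-variance features treated as r = 0."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def screen_texture_source(texture_table: Mapping[str, Sequence[float]] | "pandas.DataFrame",
                          agb: Sequence[float]) -> tuple[str, str]:
    """Pick the (band, direction) whose six textures best track AGB.

    Ranks candidates by the mean absolute Pearson correlation of their six
    statistics with AGB; ties break deterministically by band order
    (B, G, R, RE1, RE2, NIR) then direction order (D_par, D_perp, D_45).
    """
    agb = np.asarray(agb, dtype=np.float64)
    if len(agb) < 3:
        raise ValueError("need at least 3 samples to screen textures")
    best: tuple[str, str] | None = None
    best_score = -np.inf
    for band in BAND_LABELS:
        for direction in DIRECTIONS:
            cols = texture_columns(band, direction)
            try:
                scores = [abs(_safe_pearson(np.asarray(texture_table[c]), agb))
                          for c in cols]
            except KeyError as exc:
                raise KeyError(f"texture table missing column {exc}") from exc
            score = float(np.mean(scores))
            if score > best_score:  # strict: earlier candidates win ties
                best_score = score
                best = (band, direction)
    assert best is not None
    return best
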