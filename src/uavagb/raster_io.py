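"""Raster and table I/O plus plot-level reduction of imagery.

Rasters are stored as plain multiband TIFF (float64, band-interleaved) with
the affine transform and band wavelengths carried in the ImageDescription
tag as JSON.  Tables (plot layout, feature tables, evaluation reports) are
CSV with documented headers; reports are additionally written as JSON.

Pixel coordinates are 0-based and ROIs are half-open rectangles
``(row0, row1, col0, col1)`` — ``row1``/``col1`` are exclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

#: Center wavelengths (nm) of the six-band multispectral sensor, ascending:
#: blue, green, red, red-edge 1, red-edge 2, near infrared.
WAVELENGTHS: tuple[int, ...] = (450, 555, 660, 720, 750, 840)

#: Short band labels in the same order as :data:`WAVELENGTHS`.
BAND_LABELS: tuple[str, ...] = ("B", "G", "R", "RE1", "RE2", "NIR")

#: Identity-like placeholder affine (a, b, c, d, e, f) mapping
#: (col, row) -> (x, y) as x = a*col + b*row + c, y = d*col + e*row + f.
DEFAULT_TRANSFORM: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, -1.0, 0.0)

STAGES: tuple[str, ...] = ("SP", "FP", "TP")

ROI = tuple[int, int, int, int]


class FormatError(ValueError):
    """Raised when a raster or table does not match the expected layout."""


class SchemaError(ValueError):
    """Raised when a CSV table is missing required columns."""


@dataclass
class ReflectanceCube:
    """Six-band reflectance raster.

    Parameters
    ----------
    values : ndarray, shape (6, rows, cols)
        Reflectance in [0, 1], ordered by ascending wavelength.
    wavelengths : tuple of int
        Band center wavelengths in nm; must equal :data:`WAVELENGTHS`.
    transform : tuple of float
        Pixel-to-world affine (a, b, c, d, e, f).
    """

    values: np.ndarray
    wavelengths: tuple[int, ...] = WAVELENGTHS
    transform: tuple[float, ...] = DEFAULT_TRANSFORM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[0] != len(WAVELENGTHS):
            raise FormatError(
                f"expected ({len(WAVELENGTHS)}, rows, cols) array, "
                f"got shape {self.values.shape}"
            )
        if tuple(self.wavelengths) != WAVELENGTHS:
            raise FormatError(f"wavelengths must be {WAVELENGTHS}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("reflectance values must be finite")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise FormatError("reflectance values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the raster grid."""
        return self.values.shape[1:]

    def band(self, wavelength: int) -> np.ndarray:
        """Return the 2-D band at the given center wavelength (nm)."""
        return self.values[WAVELENGTHS.index(wavelength)]


@dataclass
class PlotRecord:
    """One experimental plot: ROI, factor labels and field measurements."""

    plot_id: str
    roi: ROI
    variety: str
    fertilizer: str
    rep: int
    stage: str
    measured_agb: float | None = None
    measured_height: float | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        r0, r1, c0, c1 = self.roi
        if r1 <= r0 or c1 <= c0:
            raise ValueError(f"empty ROI {self.roi}")


def _check_roi(roi: ROI, shape: tuple[int, int]) -> None:
    r0, r1, c0, c1 = roi
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"empty ROI {roi}")
    if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
        raise ValueError(f"ROI {roi} outside raster bounds {shape}")


# ---------------------------------------------------------------------------
# rasters


def write_cube(cube: ReflectanceCube, path: str | Path) -> None:
    """Write a reflectance cube as a multiband float64 TIFF."""
    meta = {
        "wavelengths_nm": list(cube.wavelengths),
        "transform": list(cube.transform),
    }
    tifffile.imwrite(
        str(path), cube.values, photometric="minisblack",
        description=json.dumps(meta),
    )


def read_cube(path: str | Path, clip: bool = False) -> ReflectanceCube:
    """Read a six-band reflectance TIFF.

    Parameters
    ----------
    clip : bool
        If true, values outside [0, 1] are clipped; otherwise they cause a
        :class:`FormatError`.
    """
    try:
        with tifffile.TiffFile(str(path)) as tif:
            values = tif.asarray()
            desc = tif.pages[0].description
    except (OSError, tifffile.TiffFileError) as exc:
        raise IOError(f"cannot read raster {path}: {exc}") from exc
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 3 or values.shape[0] != len(WAVELENGTHS):
        raise FormatError(
            f"{path}: expected {len(WAVELENGTHS)} bands, got shape {values.shape}"
        )
    transform = DEFAULT_TRANSFORM
    if desc:
        try:
            meta = json.loads(desc)
            transform = tuple(meta.get("transform", DEFAULT_TRANSFORM))
        except json.JSONDecodeError:
            pass
    if clip:
        values = np.clip(values, 0.0, 1.0)
    return ReflectanceCube(values=values, transform=transform)


def write_raster(values: np.ndarray, path: str | Path,
                 transform: tuple[float, ...] = DEFAULT_TRANSFORM) -> None:
    """Write a single-band float64 raster (DSM, DEM, NDVI, ...)."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise FormatError(f"expected 2-D raster, got shape {values.shape}")
    meta = {"transform": list(transform)}
    tifffile.imwrite(str(path), values, photometric="minisblack",
                     description=json.dumps(meta))


def read_raster(path: str | Path) -> np.ndarray:
    """Read a single-band raster written by :func:`write_raster`."""
    try:
        values = tifffile.imread(str(path))
    except (OSError, tifffile.TiffFileError) as exc:
        raise IOError(f"cannot read raster {path}: {exc}") from exc
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise FormatError(f"{path}: expected single band, got shape {values.shape}")
    return values


def write_abundance_maps(abundances: np.ndarray, names: Sequence[str],
                         path: str | Path) -> None:
    """Write per-endmember abundance maps as one multiband TIFF."""
    abundances = np.asarray(abundances, dtype=np.float64)
    meta = {"endmembers": list(names)}
    tifffile.imwrite(str(path), abundances, photometric="minisblack",
                     description=json.dumps(meta))


# ---------------------------------------------------------------------------
# plot-level reduction


def plot_mean_spectrum(cube: ReflectanceCube, roi: ROI) -> np.ndarray:
    """Arithmetic mean reflectance per band over the ROI pixels.

    The plot-level spectrum of a plot is the mean reflectance within its
    rectangular region of interest; this 6-vector feeds the vegetation
    indices and the harmonic decomposition.
    """
    _check_roi(roi, cube.shape)
    r0, r1, c0, c1 = roi
    return cube.values[:, r0:r1, c0:c1].mean(axis=(1, 2))


# ---------------------------------------------------------------------------
# tables

_PLOT_COLUMNS = ["plot_id", "row0", "row1", "col0", "col1", "variety",
                 "fertilizer", "rep", "stage", "measured_agb",
                 "measured_height"]


def write_plot_table(plots: Sequence[PlotRecord], path: str | Path) -> None:
    """Write plot records to CSV with one row per plot."""
    rows = []
    for p in plots:
        r0, r1, c0, c1 = p.roi
        rows.append({
            "plot_id": p.plot_id, "row0": r0, "row1": r1, "col0": c0,
            "col1": c1, "variety": p.variety, "fertilizer": p.fertilizer,
            "rep": p.rep, "stage": p.stage, "measured_agb": p.measured_agb,
            "measured_height": p.measured_height,
        })
    pd.DataFrame(rows, columns=_PLOT_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def read_plot_table(path: str | Path) -> list[PlotRecord]:
    """Read plot records from CSV; missing required columns raise SchemaError."""
    df = pd.read_csv(path)
    required = set(_PLOT_COLUMNS) - {"measured_agb", "measured_height"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        agb = row.get("measured_agb")
        height = row.get("measured_height")
        records.append(PlotRecord(
            plot_id=str(row["plot_id"]),
            roi=(int(row["row0"]), int(row["row1"]),
                 int(row["col0"]), int(row["col1"])),
            variety=str(row["variety"]),
            fertilizer=str(row["fertilizer"]),
            rep=int(row["rep"]),
            stage=str(row["stage"]),
            measured_agb=None if pd.isna(agb) else float(agb),
            measured_height=None if pd.isna(height) else float(height),
        ))
    return records


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table losslessly (float64 round-trip to 1e-12)."""
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report(reports: pd.DataFrame, path_csv: str | Path,
                 path_json: str | Path | None = None) -> None:
    """Write an evaluation report as CSV and, optionally, JSON."""
    reports.to_csv(path_csv, index=False, float_format="%.17g")
    if path_json is not None:
        Path(path_json).write_text(
            json.dumps(reports.to_dict(orient="records"), indent=2))
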