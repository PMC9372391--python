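"""Spectral variables: vegetation indices, linear unmixing, soil-free indices.

The six vegetation indices (NDVI, NDRE, MTCI, EVI2, VARI, OSAVI) are
computed from plot-level mean reflectance.  Mixed pixels are decomposed with
a fully constrained linear mixing model

    R_mix = sum_i Abd_i * R_i + eps,   0 <= Abd_i <= 1,   sum_i Abd_i = 1,

where R_i are stage-specific endmember spectra (lit/shaded leaf, lit/shaded
soil, flower, yellow leaf).  The summed non-soil abundance multiplied by a
plot-level index gives the soil-free index VI[v], which tracks biomass more
closely than the raw plot index when soil fraction varies between plots.

The FCLS solver enumerates endmember support subsets: for every non-empty
subset it solves the equality-constrained least-squares problem in closed
form (KKT system), then keeps the feasible candidate with minimum residual.
For the at-most-six endmembers used here this is exact for the convex
program — the global optimum restricted to its own support is the
equality-constrained solution on that support — and it vectorizes over all
pixels of a scene at once.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from uavagb.raster_io import WAVELENGTHS, ReflectanceCube, ROI, _check_roi

VI_NAMES: tuple[str, ...] = ("NDVI", "NDRE", "MTCI", "EVI2", "VARI", "OSAVI")

# band positions in the ascending-wavelength order
_B450, _B555, _B660, _B720, _B750, _B840 = range(6)


class LibraryError(ValueError):
    """Raised when an endmember library violates its contract."""


@dataclass
class EndmemberLibrary:
    """Stage-tagged pure spectra used for unmixing.

    Parameters
    ----------
    stage : str
        Growth stage the library belongs to (SP, FP or TP).
    names : list of str
        Endmember names, e.g. ``["LL", "SL", "LS", "SS"]``.
    spectra : ndarray, shape (M, 6)
        Reflectance of each endmember at the six band centers, in [0, 1].
    is_soil : ndarray of bool, shape (M,)
        True for soil endmembers; everything else (leaves, flower, yellow
        leaf) counts as vegetation when summing non-soil abundance.
    """

    stage: str
    names: list[str]
    spectra: np.ndarray
    is_soil: np.ndarray

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=np.float64)
        self.is_soil = np.asarray(self.is_soil, dtype=bool)
        m = len(self.names)
        if m < 2:
            raise LibraryError("library needs at least 2 endmembers")
        if self.spectra.shape != (m, len(WAVELENGTHS)):
            raise LibraryError(
                f"spectra must have shape ({m}, {len(WAVELENGTHS)}), "
                f"got {self.spectra.shape}")
        if self.is_soil.shape != (m,):
            raise LibraryError("is_soil must have one flag per endmember")
        if not self.is_soil.any() or self.is_soil.all():
            raise LibraryError("library needs at least one soil and one "
                               "non-soil endmember")
        if not np.all(np.isfinite(self.spectra)):
            raise LibraryError("endmember spectra must be finite")
        if self.spectra.min() < 0.0 or self.spectra.max() > 1.0:
            raise LibraryError("endmember reflectance outside [0, 1]")

    @property
    def n_endmembers(self) -> int:
        return len(self.names)

    @property
    def matrix(self) -> np.ndarray:
        """Endmember matrix R with shape (6, M), one column per endmember."""
        return self.spectra.T

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.spectra,
                          columns=[f"R{w}" for w in WAVELENGTHS])
        df.insert(0, "name", self.names)
        df.insert(1, "is_soil", self.is_soil)
        df.insert(0, "stage", self.stage)
        return df


def write_endmembers(lib: EndmemberLibrary, path) -> None:
    """Write an endmember library as CSV (stage, name, is_soil, R450..R840)."""
    lib.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_endmembers(path) -> EndmemberLibrary:
    df = pd.read_csv(path)
    required = {"stage", "name", "is_soil"} | {f"R{w}" for w in WAVELENGTHS}
    missing = required - set(df.columns)
    if missing:
        raise LibraryError(f"{path}: missing columns {sorted(missing)}")
    return EndmemberLibrary(
        stage=str(df["stage"].iloc[0]),
        names=[str(n) for n in df["name"]],
        spectra=df[[f"R{w}" for w in WAVELENGTHS]].to_numpy(dtype=np.float64),
        is_soil=df["is_soil"].to_numpy(dtype=bool),
    )


@dataclass
class UnmixResult:
    """Abundances and residual of one fully constrained unmixing solve.

    ``residual`` is the root-mean-square spectral error across the six
    bands.  ``nonunique`` flags solves against a rank-deficient (e.g.
    duplicated-endmember) library, where abundances are not identifiable
    even though the fitted spectrum is.
    """

    abundances: np.ndarray
    residual: float
    nonunique: bool = False


# ---------------------------------------------------------------------------
# vegetation indices


def _vi_from_bands(name: str, b: Sequence[np.ndarray | float]):
    """Evaluate one index from the six band values (arrays or scalars).

    Zero denominators yield NaN (missing), not an exception.
    """
    if name == "NDVI":
        num, den = b[_B840] - b[_B660], b[_B840] + b[_B660]
    elif name == "NDRE":
        num, den = b[_B840] - b[_B720], b[_B840] + b[_B720]
    elif name == "MTCI":
        num, den = b[_B840] - b[_B720], b[_B720] + b[_B660]
    elif name == "EVI2":
        num = 2.5 * (b[_B840] - b[_B660])
        den = b[_B840] + 2.4 * b[_B660] + 1.0
    elif name == "VARI":
        num, den = b[_B555] - b[_B660], b[_B555] + b[_B660]
    elif name == "OSAVI":
        num = (1.0 + 0.16) * (b[_B840] - b[_B660])
        den = b[_B840] + b[_B660] + 0.16
    else:
        raise ValueError(f"unknown vegetation index {name!r}")
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den == 0.0, np.nan, num / np.where(den == 0.0, 1.0, den))
    return out if out.ndim else float(out)


def compute_vi(spectrum: np.ndarray, index_name: str) -> float:
    """Evaluate a named vegetation index on a six-band spectrum.

    Parameters
    ----------
    spectrum : array-like, shape (6,)
        Reflectance ordered by ascending wavelength.
    index_name : str
        One of :data:`VI_NAMES`.

    Returns
    -------
    float
        Index value; NaN if the formula's denominator is zero.
    """
    s = np.asarray(spectrum, dtype=np.float64)
    if s.shape != (len(WAVELENGTHS),):
        raise ValueError(f"spectrum must be a 6-vector, got shape {s.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError("spectrum must be finite")
    return _vi_from_bands(index_name, s)


def vi_image(cube: ReflectanceCube, index_name: str) -> np.ndarray:
    """Per-pixel vegetation index map over a whole reflectance cube."""
    return _vi_from_bands(index_name, list(cube.values))


# ---------------------------------------------------------------------------
# fully constrained least squares unmixing


class FclsSolver:
    """Support-enumeration FCLS solver for one endmember library.

    Precomputes, for every non-empty endmember subset S, the inverse of the
    KKT system of ``min ||R_S a - r||^2  s.t.  1'a = 1``.  A solve then
    evaluates every subset's closed-form candidate, discards infeasible ones
    (negative abundances), and keeps the minimum-residual candidate; ties in
    residual are broken by minimum-norm abundance.
    """

    #: abundances this far below zero are treated as infeasible
    FEAS_TOL = 1e-9
    #: squared residuals within ``TIE_REL * best + TIE_ABS`` are ties,
    #: broken by minimum-norm abundance; kept at rounding level so that a
    #: genuinely smaller support (one endmember dropped) never ties a
    #: strictly better full-support solution
    TIE_REL = 1e-12
    TIE_ABS = 1e-18

    def __init__(self, lib: EndmemberLibrary):
        self.lib = lib
        R = lib.matrix  # (6, M)
        m = lib.n_endmembers
        # non-uniqueness: the augmented matrix [R; 1'] must have full column
        # rank for abundances to be identifiable
        aug = np.vstack([R, np.ones((1, m))])
        self.nonunique = np.linalg.matrix_rank(aug, tol=1e-10) < m
        self._subsets: list[tuple[tuple[int, ...], np.ndarray, np.ndarray]] = []
        for size in range(1, m + 1):
            for subset in itertools.combinations(range(m), size):
                Rs = R[:, subset]
                k = len(subset)
                kkt = np.zeros((k + 1, k + 1))
                kkt[:k, :k] = 2.0 * (Rs.T @ Rs)
                kkt[:k, k] = 1.0
                kkt[k, :k] = 1.0
                try:
                    inv = np.linalg.inv(kkt)
                except np.linalg.LinAlgError:
                    continue  # degenerate subset (duplicate endmembers)
                if not np.all(np.isfinite(inv)) or np.abs(inv).max() > 1e12:
                    continue  # numerically unusable subset
                self._subsets.append((subset, Rs, inv[:k, :]))

    def solve(self, mixed: np.ndarray) -> UnmixResult:
        """Unmix a single six-band spectrum."""
        r = np.asarray(mixed, dtype=np.float64)
        if r.shape != (len(WAVELENGTHS),):
            raise ValueError(f"mixed spectrum must be a 6-vector, got {r.shape}")
        if not np.all(np.isfinite(r)):
            raise ValueError("mixed spectrum must be finite")
        abd, res2 = self._solve_matrix(r[:, None])
        residual = float(np.sqrt(max(res2[0], 0.0) / len(WAVELENGTHS)))
        return UnmixResult(abundances=abd[:, 0], residual=residual,
                           nonunique=self.nonunique)

    def solve_image(self, pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Unmix many spectra at once.

        Parameters
        ----------
        pixels : ndarray, shape (6, ...) or (..., 6) is NOT accepted;
            bands must be the leading axis, trailing axes are spatial.

        Returns
        -------
        abundances : ndarray, shape (M, ...)
        residual : ndarray, shape (...)
            Root-mean-square spectral error per pixel.
        """
        X = np.asarray(pixels, dtype=np.float64)
        if X.shape[0] != len(WAVELENGTHS):
            raise ValueError("bands must be the leading axis")
        spatial = X.shape[1:]
        flat = X.reshape(len(WAVELENGTHS), -1)
        abd, res2 = self._solve_matrix(flat)
        residual = np.sqrt(np.maximum(res2, 0.0) / len(WAVELENGTHS))
        m = self.lib.n_endmembers
        return abd.reshape((m,) + spatial), residual.reshape(spatial)

    def _solve_matrix(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Core batched solve; X has shape (6, N)."""
        m = self.lib.n_endmembers
        n = X.shape[1]
        best_a = np.zeros((m, n))
        best_res = np.full(n, np.inf)
        best_norm = np.full(n, np.inf)
        any_feasible = np.zeros(n, dtype=bool)
        for subset, Rs, solve_rows in self._subsets:
            k = len(subset)
            rhs = np.empty((k + 1, n))
            rhs[:k] = 2.0 * (Rs.T @ X)
            rhs[k] = 1.0
            a = solve_rows @ rhs  # (k, N)
            feasible = np.all(a >= -self.FEAS_TOL, axis=0)
            if not feasible.any():
                continue
            diff = X - Rs @ a
            res2 = np.einsum("ij,ij->j", diff, diff)
            norm2 = np.einsum("ij,ij->j", a, a)
            slack = self.TIE_REL * np.minimum(best_res, res2) + self.TIE_ABS
            better = feasible & (
                (res2 < best_res - slack)
                | ((res2 <= best_res + slack) & (norm2 < best_norm - 1e-15))
            )
            if better.any():
                cols = np.where(better)[0]
                best_res[cols] = res2[cols]
                best_norm[cols] = norm2[cols]
                best_a[:, cols] = 0.0
                best_a[np.ix_(list(subset), cols)] = a[:, cols]
                any_feasible[cols] = True
        if not any_feasible.all():
            # cannot happen for a valid library (singletons are feasible),
            # but guard against fully degenerate numerical input
            raise RuntimeError("FCLS found no feasible support for some pixels")
        # clip tolerance-level negatives and renormalize the sum exactly
        best_a = np.maximum(best_a, 0.0)
        best_a /= best_a.sum(axis=0, keepdims=True)
        return best_a, best_res


def unmix_fcls(mixed: np.ndarray, lib: EndmemberLibrary) -> UnmixResult:
    """Fully constrained least-squares unmixing of one mixed spectrum.

    Minimizes ``||R_mix - sum_i Abd_i R_i||_2`` subject to non-negativity
    and sum-to-one.  Deterministic; ties between equal-residual solutions
    are broken by minimum-norm abundance.
    """
    return FclsSolver(lib).solve(mixed)


def unmix_image(cube: ReflectanceCube,
                lib: EndmemberLibrary) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel FCLS abundance maps for a whole scene.

    Returns ``(abundances, residual)`` with shapes (M, rows, cols) and
    (rows, cols).
    """
    return FclsSolver(lib).solve_image(cube.values)


# ---------------------------------------------------------------------------
# soil-free indices


def vegetation_abundance(result: UnmixResult, lib: EndmemberLibrary) -> float:
    """Summed abundance of all non-soil endmembers (leaves, flower, ...)."""
    return float(result.abundances[~lib.is_soil].sum())


def vegetation_abundance_map(abundances: np.ndarray,
                             lib: EndmemberLibrary) -> np.ndarray:
    """Per-pixel summed non-soil abundance from stacked abundance maps."""
    return np.asarray(abundances)[~lib.is_soil].sum(axis=0)


def plot_vegetation_abundance(abundances: np.ndarray, lib: EndmemberLibrary,
                              roi: ROI) -> float:
    """ROI mean of per-pixel non-soil abundance (default plot reduction)."""
    _check_roi(roi, abundances.shape[1:])
    r0, r1, c0, c1 = roi
    veg = vegetation_abundance_map(abundances, lib)
    return float(veg[r0:r1, c0:c1].mean())


def compute_vi_v(vi_plot: float, veg_abund: float) -> float:
    """Soil-free index: VI[v] = VI[plot] × summed non-soil abundance."""
    if not (np.isnan(veg_abund) or 0.0 <= veg_abund <= 1.0 + 1e-9):
        raise ValueError(f"vegetation abundance {veg_abund} outside [0, 1]")
    return vi_plot * veg_abund
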