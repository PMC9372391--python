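"""Geometric variables: canopy height from DSM−DEM and fractional cover.

Fractional vegetation cover (FVC) is estimated two independent ways and
cross-validated:

* the dimidiate pixel model (DPM), which rescales each pixel's NDVI
  between a bare-soil bound NDVI_NS and a pure-plant bound NDVI_PP,

      FVC = (NDVI_M − NDVI_NS) / (NDVI_PP − NDVI_NS),

  with the bounds taken as scene-wide NDVI quantiles at a 98% confidence
  range (1st/99th percentiles) to resist noisy extremes; and

* supervised pixel classification on the six band values (any fitted
  classifier predicting a truthy vegetation label), where plot FVC is the
  vegetation pixel count divided by the ROI pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from uavagb.raster_io import ReflectanceCube, ROI, _check_roi
from uavagb.spectral_features import vi_image


class DegenerateSceneError(ValueError):
    """Raised when the scene NDVI range collapses (NDVI_PP <= NDVI_NS)."""


@dataclass
class FvcEstimate:
    """One plot's fractional vegetation cover estimate.

    ``ndvi_ns``/``ndvi_pp`` are the bare-soil and pure-plant NDVI bounds
    (DPM only; None for the classification method).
    """

    method: str  # "DPM" or "CLS"
    value: float
    ndvi_ns: float | None = None
    ndvi_pp: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"FVC {self.value} outside [0, 1]")
        if self.method == "DPM" and not (self.ndvi_ns < self.ndvi_pp):
            raise ValueError("DPM requires ndvi_ns < ndvi_pp")


def height_map(dsm: np.ndarray, dem: np.ndarray) -> np.ndarray:
    """Per-pixel canopy height max(DSM − DEM, 0) in metres."""
    dsm = np.asarray(dsm, dtype=np.float64)
    dem = np.asarray(dem, dtype=np.float64)
    if dsm.shape != dem.shape:
        raise ValueError(f"DSM shape {dsm.shape} != DEM shape {dem.shape}")
    return np.maximum(dsm - dem, 0.0)


def canopy_height(dsm: np.ndarray, dem: np.ndarray, roi: ROI) -> float:
    """Plot canopy height: ROI mean of max(DSM − DEM, 0)."""
    hm = height_map(dsm, dem)
    _check_roi(roi, hm.shape)
    r0, r1, c0, c1 = roi
    return float(hm[r0:r1, c0:c1].mean())


def dpm_bounds(ndvi_pixels: np.ndarray,
               confidence: float = 0.98) -> tuple[float, float]:
    """Scene-wide (NDVI_NS, NDVI_PP) bounds at the given confidence range."""
    ndvi = np.asarray(ndvi_pixels, dtype=np.float64)
    ndvi = ndvi[np.isfinite(ndvi)]
    if ndvi.size < 10:
        raise ValueError("need at least 10 finite NDVI pixels for stable "
                         "percentile bounds")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    tail = (1.0 - confidence) / 2.0
    ns, pp = np.quantile(ndvi, [tail, 1.0 - tail])
    if pp <= ns:
        raise DegenerateSceneError(
            f"flat NDVI scene: NDVI_PP={pp:.4f} <= NDVI_NS={ns:.4f}")
    return float(ns), float(pp)


def fvc_dpm(ndvi_pixels: np.ndarray, roi: ROI,
            confidence: float = 0.98) -> FvcEstimate:
    """Dimidiate-pixel-model FVC of one plot.

    Bounds come from the whole scene (per-plot extremes are unstable at
    plot ROI sizes); per-pixel FVC is clipped to [0, 1] before the ROI
    mean, since the linear rescaling can overshoot at noisy extremes.
    """
    ndvi = np.asarray(ndvi_pixels, dtype=np.float64)
    ns, pp = dpm_bounds(ndvi, confidence)
    _check_roi(roi, ndvi.shape)
    r0, r1, c0, c1 = roi
    fvc_px = np.clip((ndvi[r0:r1, c0:c1] - ns) / (pp - ns), 0.0, 1.0)
    value = float(np.nanmean(fvc_px))
    return FvcEstimate(method="DPM", value=value, ndvi_ns=ns, ndvi_pp=pp)


def fvc_classification(cube: ReflectanceCube, roi: ROI,
                       classifier) -> FvcEstimate:
    """Classification FVC: vegetation pixel count over ROI pixel count.

    ``classifier`` is any fitted estimator with ``predict`` taking
    (n_pixels, 6) band vectors and returning truthy labels for vegetation
    (the pipeline trains a support vector machine on seed-labelled pixels).
    """
    if not hasattr(classifier, "predict"):
        raise ValueError("classifier must expose predict()")
    if hasattr(classifier, "fit"):  # sklearn estimator: must be fitted
        from sklearn.exceptions import NotFittedError
        from sklearn.utils.validation import check_is_fitted

        try:
            check_is_fitted(classifier)
        except NotFittedError as exc:
            raise ValueError("classifier is not trained") from exc
    _check_roi(roi, cube.shape)
    r0, r1, c0, c1 = roi
    pixels = cube.values[:, r0:r1, c0:c1].reshape(len(cube.values), -1).T
    labels = np.asarray(classifier.predict(pixels)).astype(bool)
    return FvcEstimate(method="CLS", value=float(labels.mean()))


def train_pixel_classifier(cube: ReflectanceCube, seed_pixels: np.ndarray,
                           seed_labels: np.ndarray, seed: int = 0):
    """Train the default SVM pixel classifier from seed-labelled pixels.

    Parameters
    ----------
    seed_pixels : ndarray, shape (n, 2)
        (row, col) coordinates of labelled pixels.
    seed_labels : ndarray of bool, shape (n,)
        True for vegetation.
    """
    from sklearn.svm import SVC

    coords = np.asarray(seed_pixels, dtype=np.intp)
    X = cube.values[:, coords[:, 0], coords[:, 1]].T
    y = np.asarray(seed_labels, dtype=bool)
    clf = SVC(kernel="rbf", C=10.0, gamma="scale", random_state=seed)
    clf.fit(X, y)
    return clf


def crossvalidate_fvc(dpm: np.ndarray, cls: np.ndarray) -> tuple[float, float]:
    """Agreement (R², RMSE) between the two FVC methods across plots.

    Uses the same metric definitions as the regression evaluation
    (R² = 1 − SS_res/SS_tot with the DPM values as the observations).
    """
    dpm = np.asarray(dpm, dtype=np.float64)
    cls = np.asarray(cls, dtype=np.float64)
    if dpm.shape != cls.shape:
        raise ValueError("FVC vectors must have equal length")
    if len(dpm) < 3:
        raise ValueError("need at least 3 plots to cross-validate FVC")
    from uavagb.regression_eval import evaluate

    metrics = evaluate(dpm, cls)
    return metrics.r2, metrics.rmse
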