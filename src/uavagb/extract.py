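"""Orchestration: reduce scenes to the 39-variable feature table.

For each plot × stage sample the candidate predictors are

* 6 soil-free spectral variables ``NDVI_v`` … ``OSAVI_v`` (plot-level
  index × ROI-mean non-soil abundance from per-pixel FCLS unmixing),
* 6 texture variables ``TEX_{band}_{dir}_{stat}`` of the single
  band/direction whose textures correlate best with AGB (screened over
  the pooled samples),
* 2 geometric variables ``HEIGHT_m`` (DSM − DEM) and ``FVC`` (dimidiate
  pixel model by default, SVM classification behind a flag), and
* 25 frequency-domain variables from the harmonic decomposition of the
  plot-mean spectrum,

39 candidates in all, plus the measured AGB target and sample metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from uavagb.feature_selection import feature_columns
from uavagb.frequency_features import harmonic_decompose, harmonic_feature_names
from uavagb.geometric_features import (
    canopy_height,
    dpm_bounds,
    fvc_classification,
    fvc_dpm,
    train_pixel_classifier,
)
from uavagb.raster_io import PlotRecord, ReflectanceCube, plot_mean_spectrum
from uavagb.spectral_features import (
    EndmemberLibrary,
    FclsSolver,
    VI_NAMES,
    compute_vi,
    compute_vi_v,
    plot_vegetation_abundance,
    unmix_fcls,
    vi_image,
)
from uavagb.texture_features import (
    DEFAULT_LEVELS,
    plot_texture_features,
    screen_texture_source,
    texture_columns,
)

#: number of candidate predictors in the reduced feature table
N_CANDIDATE_FEATURES = 39


@dataclass(frozen=True)
class ExtractionParams:
    """Tunable extraction constants (all configurable from the CLI)."""

    glcm_levels: int = DEFAULT_LEVELS
    glcm_distance: int = 1
    ridge_axis: str = "row"
    dpm_confidence: float = 0.98
    fvc_method: str = "dpm"  # "dpm" or "cls"
    #: unmix every pixel and average non-soil abundance over the ROI
    #: (default); the cheaper alternative unmixes the plot-mean spectrum
    pixelwise_unmixing: bool = True
    seed: int = 0


def extract_scene_features(cube: ReflectanceCube, dsm: np.ndarray,
                           dem: np.ndarray, plots: list[PlotRecord],
                           lib: EndmemberLibrary,
                           params: ExtractionParams = ExtractionParams(),
                           cls_train: tuple[np.ndarray, np.ndarray] | None = None,
                           ) -> pd.DataFrame:
    """Per-plot features of one stage's scene (textures not yet screened).

    Returns one row per plot with metadata, all 108 texture columns, the
    spectral/geometric/frequency variables and the AGB target.  When
    ``params.fvc_method == "cls"``, ``cls_train`` must provide seed pixel
    coordinates and labels for the SVM pixel classifier.
    """
    ndvi = vi_image(cube, "NDVI")
    solver = FclsSolver(lib)
    if params.pixelwise_unmixing:
        abundances, _ = solver.solve_image(cube.values)

    classifier = None
    if params.fvc_method == "cls":
        if cls_train is None:
            raise ValueError("fvc_method='cls' needs seed pixels and labels")
        classifier = train_pixel_classifier(cube, *cls_train,
                                            seed=params.seed)
    elif params.fvc_method != "dpm":
        raise ValueError("fvc_method must be 'dpm' or 'cls'")

    rows = []
    for plot in plots:
        spectrum = plot_mean_spectrum(cube, plot.roi)
        if params.pixelwise_unmixing:
            veg = plot_vegetation_abundance(abundances, lib, plot.roi)
        else:
            res = solver.solve(spectrum)
            veg = float(res.abundances[~lib.is_soil].sum())
        row: dict[str, object] = {
            "sample_id": f"{plot.plot_id}_{plot.stage}",
            "plot_id": plot.plot_id, "stage": plot.stage,
            "variety": plot.variety, "fertilizer": plot.fertilizer,
            "rep": plot.rep,
        }
        for name in VI_NAMES:
            row[f"{name}_v"] = compute_vi_v(compute_vi(spectrum, name), veg)
        row.update(plot_texture_features(
            cube, plot.roi, levels=params.glcm_levels,
            distance=params.glcm_distance, ridge_axis=params.ridge_axis))
        row["HEIGHT_m"] = canopy_height(dsm, dem, plot.roi)
        if params.fvc_method == "dpm":
            row["FVC"] = fvc_dpm(ndvi, plot.roi,
                                 confidence=params.dpm_confidence).value
        else:
            row["FVC"] = fvc_classification(cube, plot.roi, classifier).value
        harm = harmonic_decompose(spectrum)
        row.update(dict(zip(harmonic_feature_names(), harm.to_vector())))
        row["AGB"] = plot.measured_agb
        rows.append(row)
    return pd.DataFrame(rows)


def reduce_textures(table: pd.DataFrame) -> tuple[pd.DataFrame, str, str]:
    """Screen the texture block and keep only the winning band/direction.

    Returns the 39-candidate table plus the selected (band, direction).
    """
    band, direction = screen_texture_source(table, table["AGB"])
    keep_tex = set(texture_columns(band, direction))
    drop = [c for c in table.columns
            if c.startswith("TEX_") and c not in keep_tex]
    return table.drop(columns=drop), band, direction


def build_feature_table(scenes: list[tuple[ReflectanceCube, np.ndarray,
                                           np.ndarray, list[PlotRecord],
                                           EndmemberLibrary]],
                        params: ExtractionParams = ExtractionParams(),
                        ) -> tuple[pd.DataFrame, str, str]:
    """Pool stages, screen textures, return the 39-feature table.

    ``scenes`` holds one (cube, dsm, dem, plots, library) tuple per stage.
    """
    parts = [extract_scene_features(cube, dsm, dem, plots, lib, params)
             for cube, dsm, dem, plots, lib in scenes]
    pooled = pd.concat(parts, ignore_index=True)
    table, band, direction = reduce_textures(pooled)
    n = len(feature_columns(table))
    if n != N_CANDIDATE_FEATURES:
        raise RuntimeError(
            f"expected {N_CANDIDATE_FEATURES} candidate features, got {n}")
    return table, band, direction


def synthetic_feature_table(seed: int,
                            params: ExtractionParams = ExtractionParams(),
                            mixing_noise_sd: float | None = None,
                            ) -> tuple[pd.DataFrame, str, str]:
    """Simulate the default three-stage trial and extract its feature table.

    Convenience wrapper around :func:`uavagb.synthetic_scene.generate_scene`
    and :func:`build_feature_table`; returns the pooled 144-sample table
    (48 plots × 3 stages) plus the screened texture (band, direction).
    """
    from uavagb.raster_io import STAGES
    from uavagb.synthetic_scene import SceneConfig, generate_endmembers, generate_scene

    scenes = []
    for stage in STAGES:
        kwargs = {} if mixing_noise_sd is None else {
            "mixing_noise_sd": mixing_noise_sd}
        cfg = SceneConfig(seed=seed, stage=stage, **kwargs)
        cube, dsm, dem, _truth, plots = generate_scene(cfg)
        scenes.append((cube, dsm, dem, plots,
                       generate_endmembers(stage, seed)))
    return build_feature_table(scenes, params)
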