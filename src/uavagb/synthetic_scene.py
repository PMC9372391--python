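"""Synthetic potato-trial scene generator.

Emulates a replicated fertilization trial imaged by a six-band UAV sensor:
48 plots (4 varieties × 4 N-P-K fertilization gradients × 3 repetitions)
laid out on a rectangular raster, three growth stages (seedling SP,
flowering FP, tuber TP) with stage-specific endmember sets, ridge-periodic
vegetation cover, linear spectral mixing with additive Gaussian noise, a
digital surface model DSM = DEM + canopy height, and per-plot aboveground
biomass (AGB, g/m²) tied to a latent plot vigor v ∈ [0, 1].

Structure the downstream analysis relies on, true by construction:

* per-pixel abundances are non-negative and sum to one, so noise-free
  pixels are exact convex combinations of the library spectra;
* vegetation cover is a ridge-periodic strip pattern whose width grows
  with vigor, so plot-mean NDVI increases with v and ridge-perpendicular
  texture contrast exceeds ridge-parallel contrast;
* AGB is affine in v with additive noise, so every feature dimension
  (spectral, texture, geometric, frequency-domain) carries signal about
  the same latent variable through a different physical pathway.

All randomness flows from ``SceneConfig.seed`` through named
``numpy.random.SeedSequence`` children (see ``_rng``), so regeneration with
the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from uavagb.raster_io import (
    BAND_LABELS,
    DEFAULT_TRANSFORM,
    STAGES,
    WAVELENGTHS,
    PlotRecord,
    ReflectanceCube,
    write_cube,
    write_plot_table,
    write_raster,
)
from uavagb.spectral_features import EndmemberLibrary, write_endmembers

_WL = np.asarray(WAVELENGTHS, dtype=np.float64)

#: Stage-specific generator constants: AGB = agb_a0 + agb_a1 * v (g/m²),
#: maximum canopy height h_max (m), and the canopy cover scale that maps
#: vigor to ridge-strip width (fraction of the half-period).
STAGE_PARAMS: dict[str, dict[str, float]] = {
    "SP": {"agb_a0": 20.0, "agb_a1": 200.0, "h_max": 0.30, "cover": 0.45},
    "FP": {"agb_a0": 60.0, "agb_a1": 450.0, "h_max": 0.55, "cover": 0.80},
    "TP": {"agb_a0": 80.0, "agb_a1": 620.0, "h_max": 0.60, "cover": 0.85},
}

#: How the vegetated fraction of a pixel is split between the non-soil
#: endmembers at each stage (must sum to 1 per stage).
_VEG_SPLIT: dict[str, dict[str, float]] = {
    "SP": {"LL": 0.70, "SL": 0.30},
    "FP": {"LL": 0.62, "SL": 0.28, "flower": 0.10},
    "TP": {"LGL": 0.55, "SGL": 0.25, "YL": 0.12, "flower": 0.08},
}

#: Soil split of the non-vegetated fraction (lit vs shaded soil).
_SOIL_SPLIT: dict[str, float] = {"LS": 0.65, "SS": 0.35}

#: Endmember names per stage, soil flags resolved from this set.
STAGE_ENDMEMBERS: dict[str, list[str]] = {
    "SP": ["LL", "SL", "LS", "SS"],
    "FP": ["LL", "SL", "LS", "SS", "flower"],
    "TP": ["LGL", "SGL", "YL", "LS", "SS", "flower"],
}

_SOIL_NAMES = {"LS", "SS"}

#: Shaded endmembers are their lit counterparts scaled by this
#: wavelength-dependent curve (~0.48 at 450 nm falling to ~0.38 at 840 nm,
#: mean ~0.43).  Shadowed canopy is illuminated mostly by blue-rich
#: skylight, so the attenuation weakens toward short wavelengths; a
#: wavelength-dependent curve also keeps lit/shaded pairs linearly
#: independent, without which mixture abundances would not be identifiable.
SHADE_CURVE = 0.48 - 0.00025 * (_WL - 450.0)

#: Half-width (in crest-distance units, [0, 1]) of the cosine taper between
#: full canopy and bare soil at the edge of a ridge strip.
_TAPER = 0.1

_VARIETIES = ("Dongnong310", "Jishu1", "Chunshu10", "Xuechuan1")


class SceneSizeError(ValueError):
    """Raised when the raster cannot hold the requested plot grid."""


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of one synthetic scene (one stage of the trial).

    Defaults reproduce the trial the pipeline is designed around: a
    4 × 4 × 3 factorial (48 plots) on a 480 × 240 px raster with
    60 × 40 px plot ROIs and ridges running parallel to image rows with a
    12 px period.
    """

    seed: int = 0
    stage: str = "SP"
    n_varieties: int = 4
    n_fertilizer_levels: int = 4
    n_reps: int = 3
    scene_shape_px: tuple[int, int] = (480, 240)
    plot_shape_px: tuple[int, int] = (60, 40)
    ridge_period_px: int = 12
    ridge_axis: str = "row"  # ridges run parallel to this image axis
    mixing_noise_sd: float = 0.005
    agb_noise_sd: float = 10.0
    agb_range: tuple[float, float] = (0.0, 700.0)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if min(self.n_varieties, self.n_fertilizer_levels, self.n_reps) < 1:
            raise ValueError("factor counts must be >= 1")
        if self.mixing_noise_sd < 0 or self.agb_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.ridge_axis not in ("row", "col"):
            raise ValueError("ridge_axis must be 'row' or 'col'")
        if self.ridge_period_px < 2:
            raise ValueError("ridge_period_px must be >= 2")

    @property
    def n_plots(self) -> int:
        return self.n_varieties * self.n_fertilizer_levels * self.n_reps


@dataclass
class SceneTruth:
    """Ground truth of a generated scene.

    ``vigor`` and ``agb`` are per plot (ordered as the plot records);
    ``abundances`` is (M, rows, cols); ``fvc`` is the per-plot ROI mean of
    summed non-soil abundance, i.e. the true fractional vegetation cover.
    """

    vigor: np.ndarray
    abundances: np.ndarray
    endmember_names: list[str]
    height: np.ndarray
    agb: np.ndarray
    veg_mask: np.ndarray
    fvc: np.ndarray


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Documented seed-splitting scheme: one root seed, named children."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# stream ids for the seed-splitting scheme
_STREAM_ENDMEMBERS = 1
_STREAM_VIGOR = 2
_STREAM_MIX_NOISE = 3
_STREAM_AGB_NOISE = 4
_STREAM_RIDGE = 5


# ---------------------------------------------------------------------------
# trial layout


def generate_trial_layout(config: SceneConfig) -> list[PlotRecord]:
    """Lay the variety × fertilizer × rep grid out as non-overlapping ROIs.

    Plots tile the raster row-major; raises :class:`SceneSizeError` when the
    raster is too small to hold all plots.
    """
    rows, cols = config.scene_shape_px
    prow, pcol = config.plot_shape_px
    grid_rows, grid_cols = rows // prow, cols // pcol
    if grid_rows * grid_cols < config.n_plots:
        raise SceneSizeError(
            f"raster {rows}x{cols} holds {grid_rows * grid_cols} plots of "
            f"{prow}x{pcol}, need {config.n_plots}")
    records = []
    idx = 0
    for vi in range(config.n_varieties):
        variety = (_VARIETIES[vi] if vi < len(_VARIETIES)
                   else f"Variety{vi + 1}")
        for fi in range(config.n_fertilizer_levels):
            fert = f"N{fi + 1}P{fi + 1}K{fi + 1}"
            for rep in range(1, config.n_reps + 1):
                gr, gc = divmod(idx, grid_cols)
                roi = (gr * prow, (gr + 1) * prow, gc * pcol, (gc + 1) * pcol)
                records.append(PlotRecord(
                    plot_id=f"P{idx + 1:02d}", roi=roi, variety=variety,
                    fertilizer=fert, rep=rep, stage=config.stage))
                idx += 1
    return records


# ---------------------------------------------------------------------------
# endmember spectra


def _leaf_spectrum(rng: np.random.Generator, green: bool = True) -> np.ndarray:
    """Parametric leaf template: low red, green bump, logistic red edge."""
    scale = rng.uniform(0.9, 1.1)
    nir = rng.uniform(0.45, 0.55)
    red = rng.uniform(0.035, 0.055)
    base = np.array([0.045, 0.10 if green else 0.07, 0.0, 0.0, 0.0, 0.0])
    base[2] = red
    edge = 1.0 / (1.0 + np.exp(-(_WL - 710.0) / 22.0))
    spec = base + (nir - red) * edge
    spec[:3] += 0.004 * rng.standard_normal(3)  # small visible-band jitter
    return np.clip(spec * scale, 0.01, 0.98)


def _yellow_leaf_spectrum(rng: np.random.Generator) -> np.ndarray:
    """Senescent leaf: elevated green/red, moderate NIR."""
    scale = rng.uniform(0.9, 1.1)
    spec = np.array([0.08, 0.25, 0.30, 0.38, 0.41, 0.44])
    spec = spec * scale + 0.005 * rng.standard_normal(6)
    return np.clip(spec, 0.01, 0.98)


def _soil_spectrum(rng: np.random.Generator) -> np.ndarray:
    """Bare-soil template: strictly increasing linear ramp with wavelength.

    Dark, humus-rich chernozem levels (northeast China black-soil belt);
    the dark background also gives mixed-pixel NDVI its characteristic
    saturating response to vegetation cover.
    """
    r450 = rng.uniform(0.03, 0.05)
    r840 = rng.uniform(0.10, 0.14)
    return r450 + (r840 - r450) * (_WL - _WL[0]) / (_WL[-1] - _WL[0])


def _flower_spectrum(rng: np.random.Generator) -> np.ndarray:
    """White potato flower: elevated visible, moderate NIR."""
    scale = rng.uniform(0.9, 1.1)
    spec = np.array([0.45, 0.50, 0.48, 0.47, 0.46, 0.43])
    spec = spec * scale + 0.005 * rng.standard_normal(6)
    return np.clip(spec, 0.01, 0.98)


def generate_endmembers(stage: str, seed: int) -> EndmemberLibrary:
    """Stage-specific endmember library with seeded template jitter.

    SP yields {LL, SL, LS, SS}; FP adds the flower; TP replaces the leaf
    pair by {LGL, SGL, YL} (light/shaded green leaf, yellow leaf).  Shaded
    variants are their lit spectra scaled by :data:`SHADE_CURVE`.
    """
    if stage not in STAGE_ENDMEMBERS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    rng = _rng(seed, _STREAM_ENDMEMBERS, STAGES.index(stage))
    spectra: dict[str, np.ndarray] = {}
    for name in STAGE_ENDMEMBERS[stage]:
        if name in ("LL", "LGL"):
            spectra[name] = _leaf_spectrum(rng, green=True)
        elif name in ("SL", "SGL"):
            lit = "LL" if name == "SL" else "LGL"
            spectra[name] = SHADE_CURVE * spectra[lit]
        elif name == "YL":
            spectra[name] = _yellow_leaf_spectrum(rng)
        elif name == "LS":
            spectra[name] = _soil_spectrum(rng)
        elif name == "SS":
            spectra[name] = SHADE_CURVE * spectra["LS"]
        elif name == "flower":
            spectra[name] = _flower_spectrum(rng)
    names = STAGE_ENDMEMBERS[stage]
    return EndmemberLibrary(
        stage=stage,
        names=list(names),
        spectra=np.vstack([spectra[n] for n in names]),
        is_soil=np.array([n in _SOIL_NAMES for n in names]),
    )


# ---------------------------------------------------------------------------
# scene synthesis


def _plot_vigor(config: SceneConfig,
                plots: Sequence[PlotRecord]) -> np.ndarray:
    """Latent vigor per plot: monotone in fertilizer + variety offset + noise."""
    rng = _rng(config.seed, _STREAM_VIGOR)
    offsets = rng.uniform(-0.06, 0.06, size=config.n_varieties)
    variety_names = sorted({p.variety for p in plots})
    off = {v: offsets[i % len(offsets)] for i, v in enumerate(variety_names)}
    vig = np.empty(len(plots))
    for i, p in enumerate(plots):
        level = int(p.fertilizer[1])  # N<level>P<level>K<level>
        base = 0.15 + 0.18 * level
        vig[i] = base + off[p.variety] + rng.normal(0.0, 0.03)
    return np.clip(vig, 0.02, 0.98)


def _ridge_profile(config: SceneConfig, width: float,
                   shape: tuple[int, int],
                   rng: tuple[float, float]) -> np.ndarray:
    """Per-pixel vegetated fraction of one plot's ridge-strip pattern.

    ``width`` is the vegetated half-width as a fraction of the ridge
    half-period.  The profile is 1 on the strip, 0 in the furrow, with a
    narrow cosine taper (half-width :data:`_TAPER`) at the strip edge.
    ``rng`` carries the scene-wide ridge phase and a smooth sinusoidal
    edge wobble (amplitude period/4, one cycle per plot length) shared by
    every plot — ridges run continuously across a field — which both
    looks like real ragged planting and dithers the discrete row sampling
    so that mean cover and the above-half-cover mask fraction both track
    ``width`` closely.
    """
    period = config.ridge_period_px
    if config.ridge_axis == "row":
        n_across, n_along = shape
    else:
        n_along, n_across = shape
    x = np.arange(n_across) + 0.5
    phase0, psi = rng
    wobble = phase0 + (period / 4.0) * np.sin(
        2.0 * np.pi * (np.arange(n_along) + 0.5) / n_along + psi)
    pos = x[:, None] + wobble[None, :]
    # distance from the nearest ridge crest (at half-period), in [0, 1]
    d = np.abs((pos % period) - period / 2.0) / (period / 2.0)
    lo, hi = width - _TAPER, width + _TAPER
    prof = np.where(d <= lo, 1.0,
                    np.where(d >= hi, 0.0,
                             0.5 * (1.0 + np.cos(np.pi * (d - lo) / (2 * _TAPER)))))
    return prof if config.ridge_axis == "row" else prof.T


def generate_scene(config: SceneConfig) -> tuple[
        ReflectanceCube, np.ndarray, np.ndarray, SceneTruth, list[PlotRecord]]:
    """Generate one stage's scene: cube, DSM, DEM, truth, plot records.

    Per-pixel reflectance is ``sum_i Abd_i R_i`` plus Gaussian noise of sd
    ``mixing_noise_sd``, clipped to [0, 1]; abundances are exact simplex
    points before noise.  Canopy height is ``h_max * v**0.7`` inside the
    vegetation mask, DSM = DEM + height, and AGB is affine in vigor with
    additive noise, clipped to ``agb_range``.
    """
    stage = config.stage
    params = STAGE_PARAMS[stage]
    lib = generate_endmembers(stage, config.seed)
    plots = generate_trial_layout(config)
    vigor = _plot_vigor(config, plots)

    rows, cols = config.scene_shape_px
    m = lib.n_endmembers
    veg_frac = np.zeros((rows, cols))
    height = np.zeros((rows, cols))
    ridge_rng = _rng(config.seed, _STREAM_RIDGE)
    ridge_phase = (float(ridge_rng.uniform(0.0, config.ridge_period_px)),
                   float(ridge_rng.uniform(0.0, 2.0 * np.pi)))
    for p, v in zip(plots, vigor):
        r0, r1, c0, c1 = p.roi
        width = float(np.clip(1.1 * params["cover"] * v, 0.05, 0.98))
        prof = _ridge_profile(config, width, (r1 - r0, c1 - c0), ridge_phase)
        veg_frac[r0:r1, c0:c1] = prof
        height[r0:r1, c0:c1] = np.where(
            prof > 0.5, params["h_max"] * v ** 0.7, 0.0)

    # split vegetated / soil fractions among endmembers
    abundances = np.zeros((m, rows, cols))
    for name, frac in _VEG_SPLIT[stage].items():
        abundances[lib.names.index(name)] = frac * veg_frac
    for name, frac in _SOIL_SPLIT.items():
        abundances[lib.names.index(name)] = frac * (1.0 - veg_frac)

    reflectance = np.einsum("mhw,mb->bhw", abundances, lib.spectra)
    if config.mixing_noise_sd > 0:
        noise_rng = _rng(config.seed, _STREAM_MIX_NOISE)
        reflectance = reflectance + noise_rng.normal(
            0.0, config.mixing_noise_sd, size=reflectance.shape)
    cube = ReflectanceCube(values=np.clip(reflectance, 0.0, 1.0))

    # terrain: gentle planar slope; DSM adds the canopy
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    dem = 200.0 + 5e-4 * rr + 3e-4 * cc
    dsm = dem + height

    agb_rng = _rng(config.seed, _STREAM_AGB_NOISE)
    agb = params["agb_a0"] + params["agb_a1"] * vigor
    if config.agb_noise_sd > 0:
        agb = agb + agb_rng.normal(0.0, config.agb_noise_sd, size=agb.shape)
    agb = np.clip(agb, *config.agb_range)

    veg_mask = veg_frac > 0.5
    fvc = np.empty(len(plots))
    for i, p in enumerate(plots):
        r0, r1, c0, c1 = p.roi
        fvc[i] = veg_frac[r0:r1, c0:c1].mean()
        plots[i] = PlotRecord(
            plot_id=p.plot_id, roi=p.roi, variety=p.variety,
            fertilizer=p.fertilizer, rep=p.rep, stage=p.stage,
            measured_agb=float(agb[i]),
            measured_height=float(height[r0:r1, c0:c1].mean()))

    truth = SceneTruth(vigor=vigor, abundances=abundances,
                       endmember_names=list(lib.names), height=height,
                       agb=agb, veg_mask=veg_mask, fvc=fvc)
    return cube, dsm, dem, truth, plots


# ---------------------------------------------------------------------------
# on-disk bundle


def write_scene_bundle(config: SceneConfig, out_dir: str | Path) -> Path:
    """Generate a scene and write its full bundle to ``out_dir/<stage>/``.

    Files: ``reflectance.tif`` (6-band), ``dsm.tif``, ``dem.tif``,
    ``layout.csv`` (plot records incl. measured AGB/height),
    ``endmembers.csv``, ``truth.csv`` (per-plot vigor/AGB/FVC) and
    ``config.yaml``.
    """
    out = Path(out_dir) / config.stage
    out.mkdir(parents=True, exist_ok=True)
    cube, dsm, dem, truth, plots = generate_scene(config)
    write_cube(cube, out / "reflectance.tif")
    write_raster(dsm, out / "dsm.tif")
    write_raster(dem, out / "dem.tif")
    write_plot_table(plots, out / "layout.csv")
    write_endmembers(generate_endmembers(config.stage, config.seed),
                     out / "endmembers.csv")
    import pandas as pd

    pd.DataFrame({
        "plot_id": [p.plot_id for p in plots],
        "vigor": truth.vigor,
        "agb": truth.agb,
        "fvc": truth.fvc,
    }).to_csv(out / "truth.csv", index=False, float_format="%.17g")
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(config).items()}
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return out
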