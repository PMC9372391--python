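# Methods

This note documents the models and numerical choices behind `uavagb`: what
the synthetic trial generator produces and why, how each feature dimension
is computed, how the selection and regression stages are configured, and
what the package's passing tests do and do not demonstrate about real
field data.

## The synthetic trial

The generator emulates one growth stage of a replicated potato
fertilization trial imaged by a six-band UAV sensor (450, 555, 660, 720,
750, 840 nm). Its purpose is statistical, not radiometric: it reproduces
the *structure* the analysis exploits — mixed pixels, ridge-periodic
texture, canopy geometry, and a latent growth variable that all feature
dimensions reflect — with known ground truth at every pixel and plot.

**Trial layout.** 4 varieties × 4 N-P-K fertilization gradients
(N1P1K1 = none … N4P4K4 = double) × 3 repetitions = 48 plots, tiled
row-major as 60 × 40 px rectangular ROIs on a 480 × 240 px raster. The
raster size is desk-scale but each ROI holds 2 400 pixels, enough for
stable co-occurrence statistics at 32 gray levels.

**Latent vigor.** Each plot carries a vigor v ∈ [0.02, 0.98]:
v = 0.15 + 0.18·(fertilizer level) + (variety offset ~ U(−0.06, 0.06))
+ N(0, 0.03), clipped. Vigor is the single latent variable every feature
dimension sees through a different physical pathway.

**Canopy pattern.** Ridges run parallel to image rows with a 12 px
period. Vegetation cover is a strip of half-width w = 1.1·c_stage·v
(fraction of the half-period; c_stage = 0.45/0.80/0.85 for the seedling,
flowering and tuber stages), with a narrow cosine taper (half-width 0.1)
at the strip edge. The ridge phase is drawn once per scene and given a
smooth sinusoidal wobble (amplitude period/4, one cycle per plot length)
shared by all plots: ridges run continuously across a real field, the
wobble looks like ragged planting, and — the numerical reason — it
dithers the discrete row sampling so that both the mean cover and the
fraction of above-half-cover pixels track w closely instead of being
quantized to multiples of 1/6. Because every plot samples the identical
profile, mean cover is strictly increasing in w, which makes plot-mean
NDVI strictly increasing in vigor on noise-free scenes.

**Spectra.** Endmember libraries are stage-specific: seedling
{LL, SL, LS, SS} (lit/shaded leaf, lit/shaded soil), flowering adds the
flower, tuber replaces the leaf pair with {LGL, SGL, YL} (lit/shaded
green leaf, yellow leaf). Templates are parametric — logistic red edge
for leaves, elevated-visible flower, senescent yellow leaf — with seeded
jitter; only their qualitative shapes matter downstream. Two deliberate
choices:

* *Soil is dark.* The soil ramp runs 0.03–0.05 (450 nm) to 0.10–0.14
  (840 nm), chernozem levels typical of northeast China's black-soil
  belt. Beyond realism, the dark background is what gives mixed-pixel
  NDVI its saturating response to cover, and hence what makes the
  soil-free index VI[v] = VI[plot] × (non-soil abundance) genuinely more
  informative than VI[plot] when samples are pooled across stages
  (measured pooled correlations with AGB: 0.87 vs 0.56). On a bright
  background the mixed NDVI is nearly linear in cover and the product
  adds nothing — a structural fact worth knowing when transferring the
  method across soil types.
* *Shading is wavelength-dependent.* Shaded endmembers are lit spectra ×
  (0.48 at 450 nm falling linearly to ~0.38 at 840 nm, mean ≈ 0.43),
  because shadowed canopy is lit mostly by blue-rich skylight. A flat
  shade factor would also make the augmented endmember matrix [R; 1ᵀ]
  *exactly singular* whenever two lit/shaded pairs are present (the pair
  contributes one spectral direction but two columns), leaving abundances
  unidentifiable; the wavelength dependence restores full column rank
  (smallest singular value ~2×10⁻³).

**Mixing and truth.** Per-pixel reflectance is Σ Abdᵢ·Rᵢ plus Gaussian
noise (sd 0.005 by default, a plausible radiometric calibration residual),
clipped to [0, 1]; abundances are exact simplex points, with the
vegetated fraction split among leaf/flower endmembers in fixed
stage-specific proportions and the remainder split 65:35 between lit and
shaded soil. Canopy height is h_max·v^0.7 inside the vegetation mask
(h_max = 0.30/0.55/0.60 m by stage), DSM = DEM + height over a gently
sloping planar DEM. AGB is affine in vigor with stage-specific
coefficients (20 + 200v, 60 + 450v, 80 + 620v g/m²) plus N(0, 10 g/m²)
noise, clipped to [0, 700]. The 10 g/m² default is a realistic oven-dry
weighing/subsampling error and keeps the AGB–vigor correlation ≥ 0.95
within every stage, including the narrow-span seedling stage.

All randomness flows from one integer seed through named
`numpy.random.SeedSequence` children (endmembers, vigor, mixing noise,
AGB noise, ridge phase), so scenes are bit-reproducible.

## Feature extraction

**Unmixing.** The fully constrained least-squares problem
min ‖R a − r‖² s.t. a ≥ 0, 1ᵀa = 1 is solved by support enumeration:
for each of the ≤ 63 non-empty endmember subsets, the
equality-constrained subproblem has a closed-form KKT solution; feasible
candidates are compared and the minimum-residual one kept, with
rounding-level ties broken by minimum-norm abundance. Because the global
optimum of the convex program restricted to its own support *is* the
equality-constrained solution there, the enumeration is exact — no
iteration, no tolerance tuning — and the KKT inverses are precomputed per
library, so whole scenes (115 200 pixels) unmix in under a second. The
tie tolerance is kept at rounding level (relative 10⁻¹², absolute 10⁻¹⁸)
so that dropping a genuinely tiny abundance never masquerades as a tie.
Rank-deficient libraries (duplicated endmembers) are solved but flagged
non-unique. Plot-level vegetation abundance is the ROI mean of per-pixel
non-soil abundance by default; unmixing the plot-mean spectrum instead is
available behind a flag and agrees closely on synthetic scenes.

**Vegetation indices.** The six index formulas are evaluated exactly as
defined (including MTCI with the R720 + R660 denominator and VARI without
a blue term); zero denominators propagate as missing values rather than
exceptions.

**Textures.** ROIs are min–max quantized into G = 32 equal-width bins
(configurable); co-occurrence counts at 1 px offsets in the three
ridge-relative directions are symmetrized (matrix plus transpose) and
normalized. The six statistics use the standard Haralick forms, with
entropy in natural log and variance about the marginal mean. One GLCM per
plot ROI — no sliding window. Band/direction screening takes the highest
mean |Pearson r| of the six statistics against AGB, with deterministic
ties broken by band then direction order; zero-variance features count as
r = 0.

**Geometry.** Canopy height is the ROI mean of max(DSM − DEM, 0). The
dimidiate pixel model interprets its "98% confidence" bounds as the
1st/99th percentiles of scene-wide NDVI (per-plot extremes are unstable
at 60 × 40 px); per-pixel FVC is clipped to [0, 1] before averaging.
Classification FVC accepts any fitted pixel classifier over the six band
values; the bundled trainer fits an RBF-kernel SVM on seed-labelled
pixels.

**Harmonics.** With n = 6 bands indexed j = 1..6 in ascending wavelength,
A_t and B_t are the discrete cosine/sine projections for t = 1..6,
C_t = √(A_t² + B_t²), and the phase is atan2(A_t, B_t) — the
two-argument form resolves quadrants and the B_t = 0 case, which provably
occurs at t = 6 (where A₆ = 2·mean, B₆ = 0); φ is defined as 0 when
C_t = 0. Orders above Nyquist alias (C₅ = C₁, C₄ = C₂), but all six
orders are emitted because the candidate set and its screening operate on
the full 25-parameter block.

## Selection and regression

**RReliefF** (regression form): features min–max normalized, every
instance visited (m = n), k = 10 nearest neighbours by Manhattan
distance, uniform neighbour weights; constant features are guarded to
weight exactly 0. **RF-Gini**: the continuous target is quantile-binned
into 4 classes and a classification forest's mean decrease in Gini
impurity is reported — faithful to the Gini purity criterion while a
variance-reduction importance on the raw target sits behind a flag.
**RF-OOB**: per tree, the out-of-bag MSE before and after corrupting one
feature among that tree's OOB samples; corruption is OOB permutation by
default (additive Gaussian behind a flag), and IMP_F = Σ(E₂ − E₁)/K.
Forests everywhere use K = 500 trees, ⌈p/3⌉ candidate features per split,
minimum leaf 5, one integer seed. Known behaviour worth noting:
impurity importance does *not* conserve a feature's share under
duplication when max_features < p (availability doubles, so the copies'
combined share roughly doubles); the copies do share it symmetrically,
which is what the tests assert.

**Regression.** Samples are plot × stage rows pooled across the three
stages, split 2:1 into calibration/validation stratified by stage. PLSR
chooses its latent-component count by 10-fold cross-validated RMSE
(capped at 10); predictions are deliberately not clipped at zero so the
method's characteristic negative low-AGB predictions remain observable.
RFR uses the shared forest defaults. R² is 1 − SS_res/SS_tot (negative
values allowed on validation data; squared Pearson r appears only in
correlation screens), and a constant observed vector yields R² = 0 by
convention.

## What the tests show — and what they cannot

Passing tests establish that each operation implements its definition
exactly (brute-force oracles at 10⁻¹² level for GLCM and harmonics, an
exhaustive simplex grid for FCLS), that generator truth is recovered
where the design makes recovery exact (heights to 10⁻⁹ m, noise-free
abundances to 10⁻⁶), and that the analysis-level claims hold on the
synthetic trial: FVC methods within 0.05 of true cover and R² ≈ 0.98
agreement, all three selection methods recovering ≥ 4 of 5 planted
signal features in ≥ 18/20 replicates, the four-dimension combination
outperforming every two-dimension combination on average, and the
selected RFR model reaching validation R² well above 0.85.

They cannot certify field performance. The generator has a single latent
factor, linear mixing, no BRDF or illumination drift, no georeferencing
or co-registration error, and feature noises that are largely
independent across the 39 candidates. One consequence is measured and
documented rather than hidden: selection down to 10 features does *not*
reduce validation RMSE below a no-selection forest fed 20 extra
pure-noise features here, because a forest over 39 noisy views of one
latent variable enjoys variance averaging that a 10-feature model
forfeits, and random forests are largely insensitive to appended noise
columns. The corresponding robustness advantage of selection reported on
field data presumably rests on redundancy structure (shared measurement
error, saturating and collinear indices) that this generator does not
reproduce.

## Problem sizes

Default analyses run 48 plots × 3 stages = 144 samples with 39
candidates; trend properties replicate the full pipeline over 20 seeds;
oracle checks use 200 random mixtures (grid step 10⁻³), 1 000 random
spectra, and 100 random 8 × 8 images. These sizes keep a full
verification run in the minutes range on one CPU while leaving every
statistical assertion comfortably powered.
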