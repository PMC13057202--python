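# Methods

This note documents the models, numerical choices and limitations of
`mangrovecarbon`. It covers what the synthetic data emulate, how each
stage computes its quantities, and where design was genuinely open.

## The synthetic study system

The generator emulates a small tidal mangrove mosaic surveyed by a
multispectral UAV: four species — *Rhizophora stylosa* (tall, sparse),
*Bruguiera gymnorrhiza* (mid-height), *Avicennia marina* (short, dense)
and *Aegiceras corniculatum* (shrubby, very dense) — interleaved with
soil, water and shadow, at 0.53 m pixels.

**Species map.** Each of the seven classes gets an independent Gaussian
random field (white noise smoothed at `patch_scale` pixels, default 8);
the label is the argmax of the biased fields, with biases iterated until
realized class fractions match the requested ones to ~0.5 %. This gives
compact blob-like patches for every class including rare ones, unlike a
single-field quantile cut which forces mid-fraction classes into thin
transitional shells.

**Reflectance.** Per class, band values follow a multivariate normal
(mean vector, 5×5 covariance) with spatial correlation injected by
smoothing unit-variance noise fields at the class's `texture_scale`
before mixing through the covariance square root; values are clipped to
the physical [0, 1]. No per-species reflectance spectra are published
for this system, so the default means are synthetic but encode the
reported ordinal contrasts: every species is brightest in G and darkest
in B within the visible bands, *A. marina* has the highest B
reflectance, *R. stylosa* the lowest R and G, *B. gymnorrhiza* the
highest R and G. Default per-band SD is 0.010, which puts every class
pair at Mahalanobis distance ≥ 5 — deliberately an easy regime, because
the acceptance checks are about correctness of the machinery, not about
the irreducible confusion of real canopies.

**Heights and terrain.** Canopy height is a per-class normal
(*A. marina* 2.44 ± 0.50 m, *A. corniculatum* 1.83 ± 0.46 m,
*R. stylosa* 4.73 ± 0.72 m, *B. gymnorrhiza* 2.51 ± 0.65 m — the
surveyed community structure), spatially smoothed, clipped at 0. The
true terrain is a smooth low-relief field (SD 0.15 m, correlation 40 px)
and DSM = DTM + height. Flat classes have height exactly 0.

**Field plots.** 5 m × 5 m squares, ten per species, placed only where a
window is ≥ 90 % single-species (feasible positions found via an
integral image, sampled without overlap). Tree count is Poisson with
mean density × plot area using the surveyed densities (7 480–133 200
trees·hm⁻²); tree heights follow the plot's local canopy-height mean
(so plot carbon correlates with `H_Mean`, as it does in real stands),
and stem diameters scale with height around the surveyed diameter
distributions.

**What the generator does not emulate:** radiative transfer, shadows
cast by canopies (shadow is just another class), photogrammetric DSM
noise, tidal inundation, spatially varying species mixtures inside a
pixel, or measurement error in field geometry. Passing tests therefore
demonstrate the correctness and internal consistency of the estimation
machinery under known truth — not that the defaults match the radiometry
of any particular sensor or site.

## Allometry

Biomass is `a·xᵇ` per stem (x = DBH, basal diameter or height; a `d²h`
form is available), times a carbon fraction, summed per plot and scaled
kg·plot⁻¹ → t·hm⁻² (×10⁴/area ÷ 10³). Equations are configuration
(JSON), because species-specific published equations vary by site and
should be user-supplied. The shipped example registry is synthetic: it
fixes exponents (2.2 above-ground, 2.0 below-ground) and carbon
fractions (0.45 / 0.39, typical for mangrove tissue), and calibrates
each `a` once by Monte Carlo so that expected plot AGC/BGC match the
surveyed community means (e.g. *R. stylosa* ≈ 96 t·hm⁻² AGC). Multi-stem
individuals are handled by treating each stem as a record.

## Feature extraction

* **Indices** follow the standard literature formulas (NDVI, GNDVI,
  NDRE, OSAVI with the 0.16 soil term, LCI = (NIR−RE)/(NIR+R), and the
  ratio family RVI = NIR/R, MACI = NIR/G, VREI = NIR/RE, SR = NIR/B).
  SR is assigned NIR/B to keep it distinct from RVI. Every formula is
  overridable via the `formulas` argument; division-by-zero pixels
  become nodata.
* **IDW DTM**: ẑ = Σwᵢzᵢ/Σwᵢ, wᵢ = dᵢ⁻ᵖ over the n nearest GCPs, exact
  (d < 1e-9) at data points. Power, neighbour count and evaluation pixel
  size are selected by leave-one-GCP-out RMSE over a candidate grid;
  pixel size enters by snapping the held-out query to its cell centre.
  Ties break toward smaller power, then fewer neighbours, then finer
  pixels. CHM = DSM − DTM with negatives clamped to 0 and counted
  (physical non-negativity; clamping is reported, not silent).
* **GLCM**: the raster is quantized once globally (min–max to `levels`
  grey levels, default 64) so texture is on one scale across the scene;
  per pixel, co-occurrence counts are pooled over the four standard
  offsets (0,1),(1,1),(1,0),(1,−1) and their transposes within an odd
  window (default 3×3, truncated at image edges), normalized, and
  summarized by Con, Cor, Dis, Ent (natural log, 0·ln0 ≡ 0), Hom, Mean,
  Asm and Var; Cor ≡ 0 when a marginal SD is zero. The window kernel is
  numba-compiled with an identical pure-Python fallback. Window size,
  levels and offsets are exposed because the reference workflow does not
  pin them.
* **Plot aggregation** averages pixels whose centres fall inside the
  plot polygon, half-open on the right/top boundary so adjacent plots
  partition pixels; a plot capturing no centre is a named error.
* **Resampling** is block-mean with integer factors only; a coarse pixel
  is nodata when ≥ 50 % of its contributors are nodata.

## Classification

Per class: sample mean, sample covariance (n−1), priors equal by default
(frequency priors by option). A ridge (default 1e-6) is always added to
the covariance diagonal and escalated ×10 until Cholesky succeeds;
exactly/near-exactly singular covariances (relative smallest singular
value ≤ 1e-14) additionally warn — which happens legitimately whenever a
flat class has zero canopy-height variance. Ties in the discriminant
argmax go to the lowest class index. The fifteen combinations follow the
published V1–V15 structure where it is pinned by the narrative (V1–V4
visible/RE/NIR ladders; V8–V11 add height to V1 and the index sets;
V12/V15 the full band+index fusion without/with height); the index-only
memberships V5–V7 and the V13–V14 variants are not published and are
config-overridable placeholders.

Accuracy is scored on a stratified 70/30 pixel split (one split per
evaluation call, shared across combinations so the comparison is
paired). OA = trace/total; PA and UA are column- and row-normalized
diagonals; zero-denominator ratios are NaN and excluded from any
averaging.

## Carbon regression

Small-sample (10 plots per species) linear modelling, deliberately not
machine learning: Pearson screening ranks predictors by |r|; the top
predictor seeds a univariate OLS retained at P < 0.05; multivariate
search enumerates subsets of size 2–3 from the top-8 candidates,
rejecting any subset with max VIF ≥ 3 (VIF ≥ 10 is labelled collinear in
the report) or any slope p ≥ 0.05, and ranks survivors by LOOCV R².
LOOCV uses the PRESS form, R² = 1 − Σ(yᵢ−ŷ₍₋ᵢ₎)²/Σ(yᵢ−ȳ)² with the
global mean, which can legitimately be negative for uninformative
predictors. VIFⱼ = 1/(1−R²ⱼ), infinite under perfect collinearity. The
exhaustive small-subset search replaces an unspecified manual variable
choice: at n = 10 it is exact and reproducible.

Species pooling: all 15 candidate groups (4 singletons + 11 multi-species
subsets) are fit per response; the final registry is the partition of the
species set maximizing mean LOOCV R² (ties → fewer groups, then lower
summed RMSE), per response independently. This formalizes an otherwise
manual "compare R² and RMSE" choice as a reproducible objective.

## Mapping

The routed model is evaluated on each classified mangrove pixel;
negative predictions (unavoidable with negative intercepts at low
predictor values) are clamped to 0 and counted. TGC adds a per-species
soil carbon constant (defaults 177.37 / 281.14 / 236.18 / 257.67 t·hm⁻²
for *A. marina* / *R. stylosa* / *A. corniculatum* / *B. gymnorrhiza*,
from published coring studies); soil, water and shadow are nodata, so
non-mangrove gaps carry no soil constant. Transects sample the nearest
pixel every `step_m` along a polyline (no interpolation, preserving
per-pixel model outputs). Summaries report area = pixel count × pixel
area, means over valid pixels, totals = mean × area, and proportions
normalized over mangrove species.

## Pipeline and problem sizes

The five stages (`simulate`, `features`, `classify`, `model`, `map`)
share one root seed split per stage; every artifact is hashed into a
manifest so reruns are verifiably bit-identical. Default problem sizes —
a 200×200-pixel scene (~1.1 hm²), 600 labelled pixels per class for
training, 40 plots — were chosen so a full run completes in well under a
minute on one CPU while keeping every per-class sample size comfortably
above the feature dimension; all are configuration.

Rasters are written as plain TIFF with a JSON sidecar carrying the
affine transform, nodata value and CRS tag — a deliberately minimal
georeferencing scheme that round-trips exactly without a GIS stack.

## Known limitations

* The published-coefficient registry maps texture predictors (RE_Mean,
  B_Var, …) on the grey-level scale of the original workflow's software;
  applying it to scenes quantized differently shifts those predictors'
  scales, so absolute carbon maps from the shipped published models are
  only meaningful on inputs with matching quantization. The data-driven
  registry (fit on the scene's own plots) is the default mapping route.
* Classification is pixel-based and one-shot (no iterative training
  sample refinement, no object segmentation).
* The species-map fractions are matched to ~0.5 %, not exactly.
* LOOCV at n = 3 is undefined (needs |predictors| + 3 plots); univariate
  fits on 3 plots report NaN cross-validation metrics.
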