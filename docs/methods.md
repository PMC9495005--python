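# Methods

## Study system and scope

The package models a rotationally grazed pasture: seven contiguous 2450 m²
paddocks (17,150 m² total) under *Panicum maximum* cv. Mombaça, each grazed
briefly and rested, sampled for soil pH at 0–0.2, 0.2–0.3, and 0.3–0.4 m
and for forage dry matter (DM) and green matter (GM) on a regular mesh of
28 points per paddock (196 total) in UTM zone 22 S (EPSG:32722). The raw
field measurements were never deposited, so every analysis here runs on
synthetic data whose generating parameters are the published variogram
fits for this system. Out of scope by design: laboratory soil-pH protocol,
forage cutting/drying protocol, Sentinel-2 SAFE-archive handling,
anisotropic variograms, universal/co-/block kriging, and full radiative
transfer atmospheric correction.

## Sampling design

Only the paddock area (2450 m²) is published, not the aspect ratio. The
default layout takes seven 35 m × 70 m rectangles laid side by side along
the easting axis (245 m × 70 m strip), matching the published total area
and strip appearance. Fence margins of 2.5 m are excluded at the 70 m ends
and side margins of 5 m at the 35 m sides. A 10 m grid along the 65 m
interior of the long axis gives 7 rows; the 25 m cross-axis interior cannot
hold 4 columns at exactly 10 m, so the 4 columns required by the 28-point
per-paddock density are spaced evenly at 25/3 ≈ 8.33 m, endpoints on the
margin lines. Both spacings are recorded in the output table's metadata.
The generator is deterministic; infeasible targets (not a multiple of the
row count) raise an error naming the nearest feasible counts.

## Gaussian random field simulation

`simulate_field` draws one realization of a stationary Gaussian field at
the sample coordinates by dense Cholesky factorization of the covariance
C(h) = C1·(1 − γ₀(h)) implied by the prescribed variogram (γ₀ the
unit-sill curve), plus independent nugget noise of variance C0 added
pointwise. A 1e-10 diagonal jitter guards against numerically indefinite
matrices; a genuinely non-PSD covariance raises with the offending
parameters. Dense factorization limits inputs to ≤ 5000 points, ample at
desk scale.

The linear variogram has no finite-variance stationary representation, so
for simulation it is replaced by a spherical surrogate matched to the
linear model inside the sampled extent: slope at the origin equal to C1/a
(range 1.5·D, partial sill (C1/a)·D for extent D), recorded in the model
metadata. Fitting and kriging use the linear form directly (it is a valid
conditionally-negative-definite variogram).

Validation: the expected empirical semivariogram of simulated fields
matches the generating curve within 2% across all lags (400-replicate
check), and the pooled variance across replicates matches the generating
sill (a tested invariant).

All randomness flows from one integer seed; per-stage and per-replicate
sub-seeds are derived by CRC-32 of a stage label XORed with the seed,
reduced mod 2³¹−1.

## Variography

The Matheron estimator assigns each unordered pair to a distance bin
(right-closed, 12 equal-width bins by default) up to a maximum lag of half
the maximum pairwise distance — beyond that, estimates rest on few, highly
overlapping pairs. Reported lag centers are mean pair distances per bin;
empty bins are omitted. Fewer than 10 usable points triggers a warning
(estimates are then unstable), fewer than 2 an error.

Model fitting is weighted least squares with weights N(h) (pair counts);
Cressie reweighting (N/γ²) is available behind a flag. Initialization is
data-driven: nugget from the first bin, sill from the sample variance,
range from the lag where the estimator first reaches 95% of the sample
variance. Parameters are bounded C0, C1 ≥ 0 and a ∈ (0, 2·max_lag]. The
linear family is fitted in closed form (weighted regression of γ̂ on h) and
reports its "sill" at the maximum lag, flagged `sill_at_max_lag`, since no
true sill exists. R² is computed unweighted on the binned values,
RSS as the unweighted residual sum of squares; ranking is lexicographic
(R² descending, RSS ascending), with ties broken by the parsimony order
spherical > exponential > gaussian > linear.

Practical ranges follow the 95%-of-sill convention: a (spherical, exact),
3a (exponential), √3·a (gaussian), and a for linear by convention. DSD uses
the Cambardella ratio 100·C0/(C0+C1) with class bounds closed on the
moderate side (exactly 25% and 75% are moderate). Published tables for this
system contain practical-range and class labels inconsistent with these
rules; the implementation follows the stated rules, not those cells.

## Ordinary kriging

The OK system uses pairwise model semivariances with γ(0) = 0 on the
diagonal, bordered by the unbiasedness row/column. The right-hand side uses
the nugget limit γ(0⁺) = C0 when a target coincides with a sample: the
predictor targets the underlying signal, so with C0 > 0 it smooths rather
than honors the datum (exact interpolation and zero kriging variance hold
when C0 = 0 — both tested). Kriging variance is Σλᵢγᵢ₀ + μ, clipped at
zero with a logged warning if it dips below −1e-10 numerically.

Grid prediction factorizes the left-hand matrix once (LU) and solves all
cell right-hand sides in a batch; the default grid is 1 m pixels over the
paddock bounding box, masked to the paddock polygons (nodata outside).
Duplicate sample coordinates are an error, not averaged — the design has
none, and silent averaging hides data bugs. A `max_points` nearest-neighbour
option exists for inputs beyond desk scale. Leave-one-out cross-validation
re-solves each held-out point and is verified against an independent
per-point dense-solve oracle.

## Scene synthesis and spectral indices

`synthesize_scene` interpolates the DM sample values to pixel centers
(piecewise-linear inside the convex hull, nearest-neighbour outside), maps
DM to a noise-free NDVI through an affine biomass link, optionally adds
Gaussian noise to the NDVI, and then decomposes it into red/NIR bands of
fixed total brightness (0.6) so the scene's pixelwise NDVI reproduces the
link exactly. SWIR1 is derived the same way from a proportional NDWI
(factor 0.5). A zero-reflectance dark-object pixel is planted in the rim
outside the paddocks — the premise DOS relies on — so each band's minimum
after the additive per-band path-radiance offsets equals exactly that
offset. Defaults: 10 m pixels; link slope 0.04 (ton/ha)⁻¹ and intercept
0.35, placing NDVI ≈ 0.47–0.83 over the realistic DM span 3–12 ton/ha;
noise_sd 0.10, the closed-form value putting the pixel-level NDVI–DM R²
near 0.3, the order reported for such pastures. Path radiance defaults
(red 0.03, NIR 0.02, SWIR1 0.01 reflectance units) follow the usual
wavelength-decreasing haze pattern.

What the generator does not emulate: sensor point-spread functions, mixed
pixels at paddock edges, the 20 m native SWIR resolution, view/illumination
geometry, soil-background variation, and any pH→biomass causal link
(variables are simulated independently unless linked through the scene).
Passing tests therefore validate the estimators and the pipeline plumbing,
not field-scale ecological conclusions. Point extraction against the scene
is also attenuated relative to the closed-form R²: samples rarely sit at
pixel centers, so extracted-NDVI regressions run below the pixel-level
value — a misregistration effect real campaigns share.

DOS correction subtracts the per-band minimum of valid pixels (the classic
DOS1 dark-object choice; a quantile up to 5% is available) and clamps at
zero. Index math sets nodata where any input band is nodata or the
denominator is zero; results lie in [−1, 1] by construction and are never
clipped post hoc. Integer-scaled reflectance (×10000) is auto-detected by
band maximum and divided out with a log notice. Extraction is
nearest-pixel-center — indices are ratios, and interpolating ratios mixes
physical meanings.

## Regressions

Simple OLS with intercept for every published pair: three pH depths × DM/GM
and NDVI/NDWI × DM/GM (10 fits). R² = 1 − SSres/SStot is reported together
with the signed Pearson r — "negative R²" values reported in this
literature are read as negative correlations, which simple-OLS R² cannot
express. Deletion of missing rows is listwise per pair, not global. No
p-values: inference under spatial autocorrelation needs corrections outside
this scope.

## Pipeline defaults

The per-variable generating truths are the published fits: pH 0–0.2 m
spherical (C0 0.194, sill 0.404, a 83.90 m), pH 0.2–0.3 m gaussian (0.220,
0.705, 110 m), pH 0.3–0.4 m gaussian (0.149, 0.851, 235.69 m), GM linear
(97.377, 130.288, 47.34 m). The published DM sill (2.624 × 10⁷) is
dimensionally implausible for ton/ha (it would imply a ±5000 ton/ha
spread); the DM default therefore scales nugget and sill by 10⁻⁷ —
spherical C0 0.053, sill 2.624 (ton/ha)², a 13.6 m — preserving the
nugget-to-sill ratio and range while keeping values in realistic units.
Field means (pH 5.0/4.9/4.8, DM 7, GM 22) sit mid-range of the published
maps. Simulated pH is clipped to (0, 14) and masses to ≥ 0; at these
parameters clipping is almost never active.

The pipeline derives per-stage seeds from the global seed, writes all
artifacts (CSV, JSON, GeoTIFF) under one output directory, and records
SHA-256 hashes in a manifest; same config + seed ⇒ identical hashes.

## Problem sizes and numerical choices

The parameter-recovery experiment simulates spherical fields (the pH
0–0.2 m truth) at the 196-point design and refits each replicate
(12 bins, max lag = half max distance, pair-count weights). The range
estimator on this 245 m × 70 m domain is right-skewed — occasional
realizations fit ranges at the 2·max_lag bound — so the replicate mean
carries a modest upward bias (~+15%), well inside the ±25% band the
experiment checks. 200 replicates (tests) / 300 (acceptance script) keep
the Monte Carlo error of the mean a few percent; the whole experiment runs
in seconds. Kriged test grids use 5–10 m pixels; the 1 m default is for
production maps.

## Known limitations

- Isotropy is assumed throughout; the strip-shaped domain makes long-lag
  estimates eastern-axis dominated.
- The GM linear model's simulation surrogate is exact only in its
  near-origin behavior; long-range GM structure is approximate.
- GeoTIFF I/O covers the single-strip, north-up, square-pixel case this
  package writes; it is not a general GeoTIFF reader.
- Kriging with a global neighborhood scales as O(n³) in samples; use
  `max_points` beyond a few thousand.
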