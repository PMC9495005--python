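# pasturegeo

Geostatistics and satellite spectral indices for paddock-scale pasture
management, built around a rotational buffalo-grazing study system: a
17,150 m² pasture split into seven 2450 m² paddocks, sampled on a ~10 m mesh
of 196 georeferenced points for soil pH (three depths) and forage dry/green
matter (DM/GM, ton/ha).

The package is for agronomists and precision-livestock researchers who want
to go from point samples and multispectral imagery to variability maps:

- **Variography** — the Matheron semivariogram estimator
  γ̂(h) = 1/(2N(h)) Σ [Z(xᵢ) − Z(xᵢ+h)]², weighted-least-squares fits of the
  spherical, exponential, Gaussian, and linear model families, model
  selection by R²/RSS, and the Cambardella degree-of-spatial-dependence
  classification DSD = 100·C0/(C0+C1) (strong < 25%, moderate 25–75%,
  weak > 75%).
- **Ordinary kriging** — z*(x₀) = Σ λᵢ z(xᵢ) with weights from the
  variogram-based system under the Σλᵢ = 1 constraint (Lagrange
  multiplier), per-cell kriging variances, paddock masking, GeoTIFF export,
  and leave-one-out cross-validation.
- **Spectral indices** — dark-object subtraction (DOS) haze removal, then
  NDVI = (ρNIR−ρRED)/(ρNIR+ρRED) and Gao's NDWI = (ρNIR−ρSWIR1)/(ρNIR+ρSWIR1),
  with nearest-pixel extraction at the sample points.
- **Association** — pairwise OLS regressions (slope, intercept, R², signed r)
  between pH depths, DM, GM, NDVI, and NDWI.
- **Synthetic data** — because the original field measurements are
  unpublished, a first-class generator reproduces the sampling design
  exactly and simulates stationary Gaussian random fields with prescribed
  variograms, plus co-registered red/NIR/SWIR1 scenes whose NDVI co-varies
  with the biomass field.

## Worked example

```python
import pasturegeo as pg

cfg = pg.PipelineConfig(seed=1)
points = pg.simulate_dataset(cfg)                   # 196-point design + fields
emp = pg.empirical_semivariogram(points, "ph_0_20", n_bins=12)
best = pg.fit_variogram(emp)[0]
print(f"points: {len(points)}")
print(f"best family: {best.family}")
print(f"nugget C0 = {best.nugget:.3f}, sill C0+C1 = {best.sill:.3f}, "
      f"range a = {best.range_m:.1f} m")
print(f"R^2 = {best.r_squared:.3f}, DSD = {best.dsd_percent:.1f}% ({best.dsd_class})")

surface = pg.krige_grid(points, "ph_0_20", best, pixel_size=2.0,
                        mask=pg.PaddockLayout().paddock_polygons())
valid = surface.predictions != surface.nodata
print(f"kriged pH range: {surface.predictions[valid].min():.2f} - "
      f"{surface.predictions[valid].max():.2f}")
```

prints

```
points: 196
best family: spherical
nugget C0 = 0.207, sill C0+C1 = 0.368, range a = 61.1 m
R^2 = 0.907, DSD = 56.2% (moderate)
kriged pH range: 4.26 - 5.87
```

One seeded realization of the topsoil-pH field (generating truth: spherical,
C0 = 0.194, sill 0.404, range 83.9 m) yields a fitted spherical variogram
with a range of ~61 m and a sill of ~0.37 — single-realization fits scatter
around the truth; the recovery experiment below quantifies that scatter. The
kriged surface maps pH at 2 m resolution across the seven paddocks, the
scale at which lime or fertilizer could be applied at a variable rate.

The same flow is available from the shell:

```bash
pasturegeo pipeline --seed 1 --outdir run1   # full simulate→map→regress run
pasturegeo simulate --seed 1 --out points.csv
pasturegeo variogram points.csv --variable dm
```

`pasturegeo pipeline` writes the points CSV, per-variable variogram JSONs,
kriged GeoTIFFs, NDVI/NDWI GeoTIFFs, a regression report, and a manifest of
SHA-256 hashes; reruns with the same seed are bit-identical.

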