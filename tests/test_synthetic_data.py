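"""Sampling design geometry, Gaussian-field simulation, scene synthesis."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from pasturegeo import (
    FieldSpec,
    PaddockLayout,
    SceneSpec,
    VariogramModel,
    build_sampling_design,
    empirical_semivariogram,
    read_points_csv,
    simulate_field,
    synthesize_scene,
    write_points_csv,
)
from pasturegeo.spectral_indices import compute_index, dos_correct


class TestSamplingDesign:
    def test_default_design_has_196_points(self, design):
        assert len(design) == 196
        assert design["paddock"].nunique() == 7
        assert (design.groupby("paddock").size() == 28).all()

    def test_single_paddock_has_28_points(self):
        layout = PaddockLayout(n_paddocks=1)
        assert len(build_sampling_design(layout)) == 28

    def test_layout_areas(self):
        layout = PaddockLayout()
        assert layout.paddock_area_m2 == pytest.approx(2450.0)
        assert layout.total_area_m2 == pytest.approx(17_150.0)

    def test_deterministic_and_idempotent(self, design):
        again = build_sampling_design(PaddockLayout())
        assert design.equals(again)

    def test_no_duplicate_locations(self, design):
        xy = design[["easting", "northing"]].to_numpy()
        assert pdist(xy).min() > 1e-3  # 1 mm

    def test_points_inside_their_paddock(self, design):
        layout = PaddockLayout()
        polys = layout.paddock_polygons()
        from shapely.geometry import Point
        for _, row in design.iterrows():
            p = Point(row.easting, row.northing)
            owners = [k + 1 for k, poly in enumerate(polys) if poly.covers(p)]
            assert owners == [row.paddock]

    def test_long_axis_spacing_is_exact(self, design):
        one = design[design.paddock == 1]
        northings = np.sort(one["northing"].unique())
        assert np.allclose(np.diff(northings), 10.0)
        assert design.attrs["spacing_cross_axis_m"] == pytest.approx(25.0 / 3.0)

    def test_margins_honored(self, design):
        layout = PaddockLayout()
        rel_n = design["northing"] - layout.origin_northing
        assert rel_n.min() >= layout.fence_margin_m
        assert rel_n.max() <= layout.paddock_length_m - layout.fence_margin_m
        rel_e = (design["easting"] - layout.origin_easting) % layout.paddock_width_m
        assert rel_e.min() >= layout.side_margin_m

    def test_oversized_margins_error(self):
        layout = PaddockLayout(side_margin_m=20.0)  # 2*20 > 35 m width
        with pytest.raises(ValueError, match="no paddock interior"):
            build_sampling_design(layout)

    def test_infeasible_target_names_feasible_count(self):
        layout = PaddockLayout(points_per_paddock_target=30)  # not multiple of 7
        with pytest.raises(ValueError, match="feasible"):
            build_sampling_design(layout)

    def test_csv_round_trip(self, tmp_path, design):
        df = design.copy()
        df["ph_0_20"] = 5.0
        df.loc[df.index[:3], "ph_0_20"] = np.nan
        path = tmp_path / "points.csv"
        write_points_csv(df, path)
        header = path.read_text().splitlines()[0]
        assert header == ("point_id,easting,northing,paddock,"
                          "ph_0_20,ph_20_30,ph_30_40,dm,gm")
        back = read_points_csv(path)
        assert len(back) == 196
        assert back["ph_0_20"].isna().sum() == 3


class TestSimulateField:
    def test_zero_variance_gives_constant_mean(self, design):
        model = VariogramModel(family="spherical", nugget=0.0,
                               partial_sill=0.0, range_m=10.0)
        z = simulate_field(design, FieldSpec(model, mean=5.5, seed=1))
        assert np.allclose(z, 5.5)

    def test_seed_determinism_bit_identical(self, design, ph_model):
        spec = FieldSpec(ph_model, mean=5.0, seed=7)
        z1 = simulate_field(design, spec)
        z2 = simulate_field(design, spec)
        assert np.array_equal(z1, z2)
        z3 = simulate_field(design, FieldSpec(ph_model, mean=5.0, seed=8))
        assert not np.array_equal(z1, z3)

    def test_pooled_variance_matches_sill(self, design, ph_model):
        # marginal variance of the field is the sill C0+C1 = 0.404; pooling
        # values across independent replicates estimates it
        pool = [simulate_field(design, FieldSpec(ph_model, 5.0, seed=10_000 + r))
                for r in range(300)]
        pooled_var = np.var(np.concatenate(pool))
        assert pooled_var == pytest.approx(0.404, rel=0.05)

    def test_nugget_only_variogram_is_flat(self, design):
        model = VariogramModel(family="spherical", nugget=0.5,
                               partial_sill=0.0, range_m=10.0)
        acc = []
        for r in range(200):
            df = design.copy()
            df["z"] = simulate_field(df, FieldSpec(model, 0.0, seed=r))
            emp = empirical_semivariogram(df, "z", n_bins=8)
            acc.append(emp.semivariances)
        mean_gamma = np.mean(acc, axis=0)
        assert np.allclose(mean_gamma, 0.5, rtol=0.05)

    def test_semivariance_reaches_sill_beyond_range(self, design):
        # short-range model: most lags exceed the practical range, where the
        # expected semivariance is the full sill
        model = VariogramModel(family="spherical", nugget=0.1,
                               partial_sill=0.4, range_m=15.0)
        acc = None
        n_rep = 200
        for r in range(n_rep):
            df = design.copy()
            df["z"] = simulate_field(df, FieldSpec(model, 0.0, seed=40_000 + r))
            emp = empirical_semivariogram(df, "z", n_bins=8)
            acc = emp.semivariances if acc is None else acc + emp.semivariances
            lags = emp.lag_centers
        mean_gamma = acc / n_rep
        far = lags > 3 * model.range_m
        assert far.any()
        assert np.allclose(mean_gamma[far], 0.5, rtol=0.05)

    def test_linear_model_simulated_via_bounded_surrogate(self, design):
        model = VariogramModel(family="linear", nugget=97.377,
                               partial_sill=32.911, range_m=47.34)
        z = simulate_field(design, FieldSpec(model, 22.0, seed=3))
        assert z.shape == (196,)
        assert np.isfinite(z).all()

    def test_too_many_points_error(self, ph_model, rng):
        import pandas as pd
        n = 5001
        df = pd.DataFrame({"easting": rng.uniform(0, 1000, n),
                           "northing": rng.uniform(0, 1000, n)})
        with pytest.raises(ValueError, match="5000"):
            simulate_field(df, FieldSpec(ph_model, 0.0, seed=0))


class TestSynthesizeScene:
    @pytest.fixture
    def dm_points(self, design, rng):
        df = design.copy()
        df["dm"] = rng.uniform(3.0, 12.0, len(df))
        return df

    def test_noise_free_ndvi_matches_link_at_sample_pixels(self, dm_points):
        spec = SceneSpec(biomass_link={"slope": 0.04, "intercept": 0.35,
                                       "noise_sd": 0.0},
                         path_radiance={"red": 0.0, "nir": 0.0, "swir1": 0.0},
                         seed=0)
        scene = synthesize_scene(dm_points, spec)
        ndvi = compute_index(scene, "NDVI")
        row, col = ndvi.rowcol(dm_points["easting"].to_numpy(),
                               dm_points["northing"].to_numpy())
        got = ndvi.data[0][row, col]
        x, y = ndvi.pixel_centers()
        # the link holds exactly where a sample sits at the pixel center;
        # elsewhere the pixel sees linearly interpolated dry matter, so
        # compare against the link applied to the interpolated field
        from scipy.interpolate import griddata
        xy = dm_points[["easting", "northing"]].to_numpy()
        dm_at_pixels = griddata(xy, dm_points["dm"].to_numpy(),
                                (x[col], y[row]), method="linear")
        expected = 0.04 * dm_at_pixels + 0.35
        ok = np.isfinite(dm_at_pixels)
        assert ok.sum() > 100
        assert np.allclose(got[ok], expected[ok], atol=1e-6)

    def test_band_minimum_equals_path_radiance(self, dm_points):
        spec = SceneSpec(biomass_link={"slope": 0.04, "intercept": 0.35,
                                       "noise_sd": 0.0}, seed=0)
        scene = synthesize_scene(dm_points, spec)
        for name in ("red", "nir", "swir1"):
            assert scene.band(name).min() == pytest.approx(
                spec.path_radiance[name], abs=1e-7)

    def test_dos_round_trip_recovers_clean_bands(self, dm_points):
        link = {"slope": 0.04, "intercept": 0.35, "noise_sd": 0.0}
        clean = synthesize_scene(dm_points, SceneSpec(
            biomass_link=link,
            path_radiance={"red": 0.0, "nir": 0.0, "swir1": 0.0}, seed=0))
        hazy = synthesize_scene(dm_points, SceneSpec(
            biomass_link=link,
            path_radiance={"red": 0.03, "nir": 0.02, "swir1": 0.01}, seed=0))
        corrected, offsets = dos_correct(hazy)
        assert offsets["red"] == pytest.approx(0.03, abs=1e-7)
        assert offsets["nir"] == pytest.approx(0.02, abs=1e-7)
        assert offsets["swir1"] == pytest.approx(0.01, abs=1e-7)
        assert np.allclose(corrected.data, clean.data, atol=1e-6)

    def test_pixelwise_r2_near_construction_target(self, dm_points):
        # closed form: R^2 = var(signal) / (var(signal) + noise_sd^2)
        noise_sd = 0.05
        spec = SceneSpec(biomass_link={"slope": 0.04, "intercept": 0.35,
                                       "noise_sd": noise_sd},
                         path_radiance={"red": 0, "nir": 0, "swir1": 0},
                         seed=11)
        clean_spec = SceneSpec(biomass_link={"slope": 0.04, "intercept": 0.35,
                                             "noise_sd": 0.0},
                               path_radiance={"red": 0, "nir": 0, "swir1": 0},
                               seed=11)
        noisy = compute_index(synthesize_scene(dm_points, spec), "NDVI").data[0]
        clean = compute_index(synthesize_scene(dm_points, clean_spec),
                              "NDVI").data[0]
        ok = (noisy != -9999) & (clean != -9999)
        signal_var = clean[ok].var()
        expected_r2 = signal_var / (signal_var + noise_sd**2)
        from pasturegeo import fit_regression
        fit = fit_regression(clean[ok], noisy[ok])
        assert fit.r_squared == pytest.approx(expected_r2, abs=0.05)

    def test_oversized_pixel_errors(self, dm_points):
        with pytest.raises(ValueError, match="pixel size"):
            synthesize_scene(dm_points, SceneSpec(pixel_size_m=50.0))

    def test_missing_dm_errors(self, design):
        df = design.copy()
        df["dm"] = np.nan
        with pytest.raises(ValueError, match="dm"):
            synthesize_scene(df, SceneSpec())

    def test_scene_determinism(self, dm_points):
        s1 = synthesize_scene(dm_points, SceneSpec(seed=5))
        s2 = synthesize_scene(dm_points, SceneSpec(seed=5))
        assert np.array_equal(s1.data, s2.data)
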