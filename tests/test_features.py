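import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mangrovecarbon import features as ft
from mangrovecarbon import synthetic as syn
from mangrovecarbon.raster import Affine, Raster

from _oracles import glcm_oracle, idw_predict_oracle


def make_raster(values, pixel_size=1.0, north=None):
    values = np.asarray(values, dtype=float)
    north = values.shape[0] * pixel_size if north is None else north
    return Raster(values, Affine.from_origin(0.0, north, pixel_size))


# --------------------------------------------------------------------------
# resampling

class TestResample:
    def test_two_by_two_block_mean(self):
        r = make_raster([[1, 2], [3, 4]])
        out = ft.resample(r, 2.0)
        assert out.values.shape == (1, 1)
        assert out.values[0, 0] == 2.5

    def test_constant_raster_stays_constant(self):
        r = make_raster(np.full((8, 8), 3.7))
        for factor in (2.0, 4.0):
            assert np.all(ft.resample(r, factor).values == 3.7)

    def test_checkerboard_averages_to_half(self):
        board = np.indices((4, 4)).sum(axis=0) % 2
        out = ft.resample(make_raster(board.astype(float)), 2.0)
        np.testing.assert_array_equal(out.values, np.full((2, 2), 0.5))

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="upsampling"):
            ft.resample(make_raster(np.zeros((4, 4))), 0.5)

    def test_majority_nodata_propagates(self):
        v = np.zeros((2, 2))
        v[0, 0] = v[0, 1] = v[1, 0] = -9999.0
        out = ft.resample(make_raster(v), 2.0)
        assert out.values[0, 0] == -9999.0
        # half nodata is tolerated (mean of valid pixels)
        v2 = np.array([[1.0, -9999.0], [3.0, -9999.0]])
        assert ft.resample(make_raster(v2), 2.0).values[0, 0] == 2.0


# --------------------------------------------------------------------------
# vegetation indices

def scene_from_band_values(values: dict) -> syn.Scene:
    shape = np.shape(next(iter(values.values())))
    tr = Affine.from_origin(0, shape[0], 1.0)
    bands = {
        b: Raster(np.asarray(values[b], dtype=float), tr) for b in syn.BANDS
    }
    zero = Raster(np.zeros(shape), tr)
    return syn.Scene(bands=bands, dsm=zero, dtm_true=zero,
                     species_true=zero, pixel_size=1.0)


class TestIndices:
    def test_ndvi_worked_value(self):
        sc = scene_from_band_values(
            {b: [[0.5 if b == "NIR" else 0.1]] for b in syn.BANDS}
        )
        assert ft.compute_index(sc, "NDVI").values[0, 0] == pytest.approx(
            (0.5 - 0.1) / (0.5 + 0.1)
        )

    def test_normalized_difference_zero_when_bands_equal(self):
        sc = scene_from_band_values({b: [[0.3]] for b in syn.BANDS})
        for name in ("NDVI", "GNDVI", "NDRE"):
            assert ft.compute_index(sc, name).values[0, 0] == 0.0

    def test_rvi_ratio(self):
        vals = {b: [[0.2]] for b in syn.BANDS}
        vals["NIR"] = [[0.6]]
        sc = scene_from_band_values(vals)
        assert ft.compute_index(sc, "RVI").values[0, 0] == pytest.approx(3.0)

    def test_zero_denominator_becomes_nodata(self):
        vals = {b: [[0.0]] for b in syn.BANDS}
        sc = scene_from_band_values(vals)
        out = ft.compute_index(sc, "RVI")
        assert not out.mask[0, 0]

    def test_unknown_index_rejected(self, scene):
        with pytest.raises(ValueError, match="unknown index"):
            ft.compute_index(scene, "EVI2")

    @settings(max_examples=50, deadline=None)
    @given(
        nir=st.floats(1e-6, 1.0), r=st.floats(1e-6, 1.0),
        g=st.floats(1e-6, 1.0), re=st.floats(1e-6, 1.0),
    )
    def test_normalized_difference_indices_bounded(self, nir, r, g, re):
        sc = scene_from_band_values(
            {"B": [[0.1]], "G": [[g]], "R": [[r]], "RE": [[re]], "NIR": [[nir]]}
        )
        for name in ("NDVI", "GNDVI", "NDRE"):
            v = ft.compute_index(sc, name).values[0, 0]
            assert -1.0 <= v <= 1.0


# --------------------------------------------------------------------------
# IDW interpolation

def gcp_table(points):
    return ft.GCPTable(pd.DataFrame(points, columns=["x", "y", "z"]))


class TestIDW:
    def test_exact_at_gcp_locations(self):
        gcps = gcp_table([(0, 0, 1.0), (1, 0, 2.0), (0, 1, 3.0), (1, 1, 4.0)])
        z = ft.idw_at_points(gcps, np.array([[1.0, 0.0]]), power=2, n_points=4)
        assert z[0] == 2.0

    def test_midpoint_symmetry_for_any_power(self):
        gcps = gcp_table([(0, 0, 2.0), (2, 0, 4.0), (5, 5, 9.0), (6, 6, 9.0)])
        for power in (0.5, 1, 2, 3):
            z = ft.idw_at_points(gcps, np.array([[1.0, 0.0]]), power, n_points=2)
            assert z[0] == pytest.approx(3.0)

    def test_hand_weight_arithmetic(self):
        # z=0 at distance 1, z=6 at distance 2, power 1 → (0·1 + 6·0.5)/1.5 = 2
        gcps = gcp_table([(1, 0, 0.0), (2, 0, 6.0), (9, 9, 1.0), (9, 8, 1.0)])
        z = ft.idw_at_points(gcps, np.array([[0.0, 0.0]]), power=1, n_points=2)
        assert z[0] == pytest.approx(2.0)

    def test_prediction_bounded_by_neighbors(self, rng):
        pts = rng.uniform(0, 10, size=(20, 2))
        zs = rng.uniform(-5, 5, size=20)
        gcps = gcp_table(np.column_stack([pts, zs]))
        queries = rng.uniform(0, 10, size=(50, 2))
        zhat = ft.idw_at_points(gcps, queries, power=2, n_points=5)
        assert np.all(zhat >= zs.min() - 1e-12)
        assert np.all(zhat <= zs.max() + 1e-12)

    def test_matches_oracle_on_random_configurations(self, rng):
        pts = rng.uniform(0, 10, size=(15, 2))
        zs = rng.normal(size=15)
        gcps = gcp_table(np.column_stack([pts, zs]))
        queries = rng.uniform(0, 10, size=(20, 2))
        for power, npts in ((1, 3), (2, 5), (3, 1)):
            mine = ft.idw_at_points(gcps, queries, power, npts)
            want = [idw_predict_oracle(pts, zs, q, power, npts) for q in queries]
            np.testing.assert_allclose(mine, want, atol=1e-10)

    def test_interpolated_grid_shape_and_exactness(self):
        gcps = gcp_table([(0.5, 0.5, 1.0), (3.5, 0.5, 2.0),
                          (0.5, 3.5, 3.0), (3.5, 3.5, 4.0)])
        dtm = ft.idw_interpolate(
            gcps, ft.GridSpec(0, 4, 4, 4), power=2, n_points=4, pixel_size=1.0
        )
        assert dtm.shape == (4, 4)
        assert dtm.values[3, 0] == 1.0  # pixel centre (0.5, 0.5)

    def test_empty_or_small_gcp_table_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            gcp_table([(0, 0, 1.0)])


class TestSelectIDWParams:
    def test_planar_gcps_tie_break_to_smallest_power_and_points(self, rng):
        xy = rng.uniform(0, 10, size=(12, 2))
        z = 2.0 + 0.0 * xy[:, 0]  # constant plane: every candidate has RMSE 0
        gcps = gcp_table(np.column_stack([xy, z]))
        best, table = ft.select_idw_params(gcps, [1.0], [1, 2, 3], [3, 5])
        assert best["power"] == 1 and best["n_points"] == 3
        assert best["rmse"] == pytest.approx(0.0, abs=1e-12)

    def test_single_candidate_returned(self, rng):
        xy = rng.uniform(0, 10, size=(8, 2))
        gcps = gcp_table(np.column_stack([xy, rng.normal(size=8)]))
        best, table = ft.select_idw_params(gcps, [2.0], [2.5], [4])
        assert (best["power"], best["n_points"]) == (2.5, 4)
        assert len(table) == 1

    def test_selector_agrees_with_exhaustive_oracle_table(self, rng):
        # rough synthetic terrain; the test computes its own LOO RMSE table
        xy = rng.uniform(0, 20, size=(25, 2))
        z = np.sin(xy[:, 0] / 3.0) + np.cos(xy[:, 1] / 4.0) + 0.05 * xy[:, 0]
        gcps = gcp_table(np.column_stack([xy, z]))
        powers, npts_opts = [1, 2, 3], [2, 3, 5]
        ps = 1.0
        best, table = ft.select_idw_params(gcps, [ps], powers, npts_opts)
        snapped = (np.floor(xy / ps) + 0.5) * ps
        oracle_rows = []
        for power in powers:
            for npts in npts_opts:
                errs = []
                for i in range(len(xy)):
                    keep = np.arange(len(xy)) != i
                    zhat = idw_predict_oracle(
                        xy[keep], z[keep], snapped[i], power, npts
                    )
                    errs.append(zhat - z[i])
                oracle_rows.append((power, npts, np.sqrt(np.mean(np.square(errs)))))
        oracle_best = min(oracle_rows, key=lambda t: t[2])
        assert (best["power"], best["n_points"]) == oracle_best[:2]
        for power, npts, rmse in oracle_rows:
            got = table[(table.power == power) & (table.n_points == npts)].rmse
            assert got.iloc[0] == pytest.approx(rmse, abs=1e-10)


# --------------------------------------------------------------------------
# canopy height model

class TestCHM:
    def test_identity_and_offset(self):
        dsm = make_raster(np.full((3, 3), 5.0))
        chm, clamped = ft.compute_chm(dsm, dsm)
        assert np.all(chm.values == 0.0) and clamped == 0
        dtm = make_raster(np.full((3, 3), 3.0))
        chm, clamped = ft.compute_chm(dsm, dtm)
        assert np.all(chm.values == 2.0) and clamped == 0

    def test_negative_difference_clamped_and_counted(self):
        dsm = make_raster([[1.8]])
        dtm = make_raster([[2.0]])
        chm, clamped = ft.compute_chm(dsm, dtm)
        assert chm.values[0, 0] == 0.0
        assert clamped == 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ft.compute_chm(make_raster(np.zeros((2, 2))),
                           make_raster(np.zeros((3, 3))))


# --------------------------------------------------------------------------
# GLCM textures

WORKED_IMAGE = [[0, 0], [0, 1]]
WORKED_EXPECTED = dict(Con=0.5, Dis=0.5, Hom=0.75, Asm=0.375,
                       Ent=1.0397207708399179, Mean=0.25, Var=0.1875,
                       Cor=-1.0 / 3.0)


class TestGLCM:
    def test_worked_two_by_two_example(self):
        got = ft.glcm_summary(WORKED_IMAGE, levels=2, offsets=[(0, 1)])
        for name, want in WORKED_EXPECTED.items():
            assert got[name] == pytest.approx(want, abs=1e-10), name

    def test_constant_image_degenerate_metrics(self):
        got = ft.glcm_summary(np.full((4, 4), 7.0), levels=8)
        assert got["Con"] == 0 and got["Dis"] == 0
        assert got["Hom"] == 1 and got["Asm"] == 1
        assert got["Ent"] == 0 and got["Var"] == 0
        assert got["Cor"] == 0  # σ = 0 rule

    def test_matches_brute_force_oracle_on_random_images(self, rng):
        offsets = [(0, 1), (1, 0), (1, 1), (1, -1)]
        for _ in range(25):
            levels = int(rng.choice([2, 4, 8]))
            img = rng.integers(0, 32, size=(8, 8)).astype(float)
            got = ft.glcm_summary(img, levels=levels, offsets=offsets)
            want = glcm_oracle(img, levels=levels, offsets=offsets)
            for name in ft.GLCM_METRICS:
                assert got[name] == pytest.approx(want[name], abs=1e-10), name

    def test_windowed_metrics_match_whole_image_summary_per_window(self, rng):
        """The moving-window raster at an interior pixel equals the summary
        of that pixel's window (quantization held fixed globally)."""
        img = rng.integers(0, 64, size=(7, 7)).astype(float)
        r = make_raster(img)
        out = ft.glcm_metrics(r, window=3, levels=8)
        q = ft.quantize(img, 8)
        for (pr, pc) in [(1, 1), (3, 4), (5, 2)]:
            window = q[pr - 1 : pr + 2, pc - 1 : pc + 2]
            want = ft.glcm_summary(
                window, levels=8, offsets=ft.DEFAULT_OFFSETS,
                quantize_input=False,
            )
            for name in ft.GLCM_METRICS:
                assert out[name].values[pr, pc] == pytest.approx(
                    want[name], abs=1e-10
                ), name

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_probability_bounds_hold(self, seed):
        img = np.random.default_rng(seed).integers(0, 16, size=(6, 6)).astype(float)
        got = ft.glcm_summary(img, levels=4)
        assert 0 <= got["Hom"] <= 1 and 0 < got["Asm"] <= 1
        assert got["Ent"] >= 0 and abs(got["Cor"]) <= 1 + 1e-12

    def test_parameter_validation(self):
        r = make_raster(np.zeros((5, 5)))
        with pytest.raises(ValueError, match="odd"):
            ft.glcm_metrics(r, window=4)
        with pytest.raises(ValueError, match="levels"):
            ft.glcm_metrics(r, levels=1)
        with pytest.raises(ValueError, match="larger than raster"):
            ft.glcm_metrics(make_raster(np.zeros((3, 3))), window=5)
        with pytest.raises(ValueError, match="offset"):
            ft.glcm_metrics(r, offsets=[])


# --------------------------------------------------------------------------
# plot aggregation

class TestAggregateToPlots:
    @staticmethod
    def _plot(x0, y0, side, plot_id="p1", species="A_marina"):
        from shapely.geometry import Polygon

        return syn.PlotRecord(
            plot_id=plot_id, species_id=species,
            polygon=Polygon([(x0, y0), (x0 + side, y0),
                             (x0 + side, y0 + side), (x0, y0 + side)]),
            trees=[], agc=1.0, bgc=0.5,
        )

    def test_constant_layer_gives_constant_mean(self):
        stack = ft.FeatureStack({"B": make_raster(np.full((10, 10), 7.0))})
        table = ft.aggregate_to_plots(stack, [self._plot(2, 2, 4)])
        assert table.B.iloc[0] == 7.0
        assert table.pixel_count.iloc[0] == 16

    def test_mean_of_known_pixels(self):
        v = np.zeros((4, 4))
        v[2, 0], v[2, 1], v[3, 0], v[3, 1] = 1, 2, 3, 4
        stack = ft.FeatureStack({"B": make_raster(v)})
        table = ft.aggregate_to_plots(stack, [self._plot(0, 0, 2)])
        assert table.B.iloc[0] == 2.5

    def test_pixel_count_matches_brute_force_geometry(self, scene, plots):
        # 5 m plots on 0.53 m pixels capture ~81–100 centres
        stack = ft.FeatureStack({"B": scene.bands["B"]})
        table = ft.aggregate_to_plots(stack, plots)
        assert table.pixel_count.between(81, 100).all()
        xs, ys = scene.bands["B"].pixel_centers()
        p = plots[0]
        minx, miny, maxx, maxy = p.polygon.bounds
        brute = 0
        for x, y in zip(xs.ravel(), ys.ravel()):
            if minx <= x < maxx and miny <= y < maxy:
                brute += 1
        assert table.pixel_count.iloc[0] == brute

    def test_empty_plot_raises_with_name(self):
        stack = ft.FeatureStack({"B": make_raster(np.zeros((10, 10)))})
        tiny = self._plot(2.6, 2.6, 0.2, plot_id="tiny")
        with pytest.raises(ValueError, match="tiny"):
            ft.aggregate_to_plots(stack, [tiny])

    def test_resample_then_aggregate_consistent_for_constant_layers(self):
        v = np.full((8, 8), 3.0)
        stack_fine = ft.FeatureStack({"B": make_raster(v)})
        stack_coarse = ft.FeatureStack({"B": ft.resample(make_raster(v), 2.0)})
        plot = self._plot(0, 0, 8)
        fine = ft.aggregate_to_plots(stack_fine, [plot]).B.iloc[0]
        coarse = ft.aggregate_to_plots(stack_coarse, [plot]).B.iloc[0]
        assert fine == coarse == 3.0
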