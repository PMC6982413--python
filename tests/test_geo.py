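import numpy as np
import pytest

from chorodig.geo import (Affine, DegenerateGCPError, GroundControlPoint,
                          RasterImage, ZoneLayer, fit_polynomial_transform,
                          n_coefficients, read_gcps, read_raster, read_zones,
                          warp_image, write_raster, write_vector)


def gcps_from(fn, cols, rows):
    return [GroundControlPoint(c, r, *fn(c, r)) for c, r in zip(cols, rows)]


class TestPolynomialFit:
    def test_identity_order1(self):
        g = gcps_from(lambda c, r: (c, r), [0, 10, 3], [0, 2, 9])
        t = fit_polynomial_transform(g, order=1)
        # monomials are ordered 1, col, row
        np.testing.assert_allclose(t.coeffs_x, [0, 1, 0], atol=1e-9)
        np.testing.assert_allclose(t.coeffs_y, [0, 0, 1], atol=1e-9)
        assert t.rms_residual == pytest.approx(0, abs=1e-9)

    def test_recovers_known_affine(self):
        rng = np.random.default_rng(0)
        cols = rng.uniform(0, 100, 12)
        rows = rng.uniform(0, 100, 12)
        g = gcps_from(lambda c, r: (2 * c + 10, -3 * r + 5), cols, rows)
        t = fit_polynomial_transform(g, order=1)
        np.testing.assert_allclose(t.coeffs_x, [10, 2, 0], atol=1e-9)
        np.testing.assert_allclose(t.coeffs_y, [5, 0, -3], atol=1e-9)
        assert t.rms_residual < 1e-9

    def test_exact_cubic_recovery(self):
        rng = np.random.default_rng(3)
        cx = rng.uniform(-2, 2, n_coefficients(3))
        cy = rng.uniform(-2, 2, n_coefficients(3))
        from chorodig.geo import _design_matrix

        cols = rng.uniform(0, 50, 10)
        rows = rng.uniform(0, 50, 10)
        A = _design_matrix(cols, rows, 3)
        g = [GroundControlPoint(c, r, x, y)
             for c, r, x, y in zip(cols, rows, A @ cx, A @ cy)]
        t = fit_polynomial_transform(g, order=3)
        assert t.rms_residual < 1e-6
        np.testing.assert_allclose(t.coeffs_x, cx, atol=1e-6)
        np.testing.assert_allclose(t.coeffs_y, cy, atol=1e-6)

    def test_too_few_gcps(self):
        g = gcps_from(lambda c, r: (c, r), [0, 1], [0, 1])
        with pytest.raises(ValueError, match="at least 3"):
            fit_polynomial_transform(g, order=1)

    def test_collinear_is_degenerate(self):
        g = gcps_from(lambda c, r: (c + 1, r + 1), [0, 1, 2, 3], [0, 1, 2, 3])
        with pytest.raises(DegenerateGCPError):
            fit_polynomial_transform(g, order=1)

    def test_exact_fit_when_gcps_match_coefficient_count(self):
        # property: with exactly (p+1)(p+2)/2 non-degenerate points the fit
        # interpolates (rms <= 1e-6)
        rng = np.random.default_rng(9)
        for order in (1, 2, 3):
            k = n_coefficients(order)
            cols = rng.uniform(0, 30, k)
            rows = rng.uniform(0, 30, k)
            g = gcps_from(lambda c, r: (3 * c - r + 2, c + 4 * r - 7), cols, rows)
            t = fit_polynomial_transform(g, order=order)
            assert t.rms_residual <= 1e-6


class TestWarp:
    def _image(self, seed=0, h=40, w=50):
        rng = np.random.default_rng(seed)
        return RasterImage(rng.integers(0, 256, (h, w, 3), dtype=np.uint8),
                           Affine.from_origin(0, h, 1, 1))

    def test_identity_warp(self):
        img = self._image()
        g = gcps_from(lambda c, r: (c, r), [0, 50, 0, 50], [0, 0, 40, 40])
        t = fit_polynomial_transform(g, order=1)
        # output grid mapping pixel centers to (col, row) map coords directly
        grid = Affine(1, 0, 0, 0, 1, 0)
        out = warp_image(img, t, grid, img.shape)
        np.testing.assert_array_equal(out.pixels, img.pixels)
        assert out.mask().all()

    def test_integer_translation(self):
        img = self._image(1)
        g = gcps_from(lambda c, r: (c + 5, r), [0, 50, 0, 50], [0, 0, 40, 40])
        t = fit_polynomial_transform(g, order=1)
        grid = Affine(1, 0, 0, 0, 1, 0)
        out = warp_image(img, t, grid, img.shape)
        np.testing.assert_array_equal(out.pixels[:, 5:], img.pixels[:, :-5])
        assert not out.mask()[:, :5].any()

    def test_round_trip_mild_affine(self):
        img = self._image(2, 60, 60)
        fwd = lambda c, r: (1.005 * c + 0.003 * r + 3.0,
                            0.995 * r - 0.003 * c + 1.0)
        cols = np.array([0, 60, 0, 60, 30, 15, 45, 30.0])
        rows = np.array([0, 0, 60, 60, 30, 45, 15, 10.0])
        t = fit_polynomial_transform(gcps_from(fwd, cols, rows), order=1)
        grid = Affine(1, 0, 0, 0, 1, 0)
        warped = warp_image(img, t, grid, (70, 70))
        inv = fit_polynomial_transform(
            [GroundControlPoint(g.map_x, g.map_y, g.src_col, g.src_row)
             for g in gcps_from(fwd, cols, rows)], order=1)
        back = warp_image(warped, inv, grid, img.shape)
        interior = np.zeros(img.shape, bool)
        interior[5:-5, 5:-5] = True
        same = (back.pixels == img.pixels).all(axis=2)
        assert same[interior & back.mask()].mean() >= 0.99


class TestRasterIO:
    def test_tiff_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(4)
        img = RasterImage(rng.integers(0, 256, (20, 30, 3), dtype=np.uint8),
                          Affine.from_origin(1000.0, 2000.0, 30.0, 30.0),
                          crs="EPSG:5070")
        p = tmp_path / "map.tif"
        write_raster(img, p)
        back = read_raster(p)
        np.testing.assert_array_equal(back.pixels, img.pixels)
        assert back.transform == img.transform
        assert back.crs == img.crs
        assert back.georeferenced

    def test_png_without_world_file_warns(self, tmp_path):
        from PIL import Image

        arr = np.zeros((5, 5, 3), np.uint8)
        p = tmp_path / "plain.png"
        Image.fromarray(arr).save(p)
        with pytest.warns(UserWarning, match="no georeference"):
            img = read_raster(p)
        assert not img.georeferenced
        assert img.transform == Affine.identity()

    def test_png_world_file_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        img = RasterImage(rng.integers(0, 256, (8, 9, 3), dtype=np.uint8),
                          Affine.from_origin(-100.0, 50.0, 2.0, 2.0))
        p = tmp_path / "map.png"
        write_raster(img, p)
        back = read_raster(p)
        np.testing.assert_array_equal(back.pixels, img.pixels)
        np.testing.assert_allclose(back.transform, img.transform)

    def test_gcp_table(self, tmp_path):
        p = tmp_path / "gcps.csv"
        p.write_text("src_col,src_row,map_x,map_y\n1,2,100,200\n3,4,300,400\n")
        g = read_gcps(p)
        assert g == [GroundControlPoint(1, 2, 100, 200),
                     GroundControlPoint(3, 4, 300, 400)]


class TestVectorIO:
    def test_geojson_round_trip(self, tmp_path, clean_scene):
        _, _, zones = clean_scene
        p = tmp_path / "zones.geojson"
        write_vector(zones, p)
        back = read_zones(p)
        assert back.unit_ids == zones.unit_ids
        assert (back.units.official_area_km2 > 0).all()
        for g1, g2 in zip(zones.units.geometry, back.units.geometry):
            assert g1.symmetric_difference(g2).area < 1e-6

    def test_three_unit_layer(self, tmp_path):
        import json

        feats = []
        for i in range(3):
            feats.append({
                "type": "Feature",
                "properties": {"unit_id": f"C{i}", "state_id": "S1"},
                "geometry": {"type": "Polygon", "coordinates": [[
                    [i * 1000.0, 0.0], [(i + 1) * 1000.0, 0.0],
                    [(i + 1) * 1000.0, 1000.0], [i * 1000.0, 1000.0],
                    [i * 1000.0, 0.0]]]},
            })
        p = tmp_path / "units.geojson"
        p.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
        layer = read_zones(p)
        assert len(layer) == 3
        assert layer.unit_ids == ["C0", "C1", "C2"]
        assert (layer.units.official_area_km2 > 0).all()

    def test_duplicate_unit_ids_rejected(self):
        import pandas as pd
        from shapely.geometry import box

        df = pd.DataFrame({
            "unit_id": ["A", "A"], "state_id": ["S", "S"],
            "geometry": [box(0, 0, 1, 1), box(1, 0, 2, 1)],
            "official_area_km2": [1.0, 1.0],
        })
        with pytest.raises(ValueError, match="duplicate"):
            ZoneLayer(df)
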