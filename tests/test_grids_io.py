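"""GeoTIFF round-trips, QA bit masking, nearest resampling, compositing."""

import datetime as dt

import numpy as np
import pytest

from rsei.grids import GeoGrid, QualityMask, ReflectanceScene, ThermalScene
from rsei.grids_io import (
    DEFAULT_QA_BIT_SPEC,
    apply_quality_mask,
    decode_qa_words,
    read_scene,
    resample_nearest,
    seasonal_composite,
    season_window,
    write_raster,
)

DATE = dt.date(2001, 1, 15)


def refl_scene(grid, fill=0.3, date=DATE):
    return ReflectanceScene(grid, date, np.full((7,) + grid.shape, fill))


class TestGeoTiffIO:
    def test_reflectance_roundtrip_preserves_header_and_values(self, tmp_path, small_grid):
        bands = np.random.default_rng(0).uniform(0.0, 0.6, (7,) + small_grid.shape)
        path = write_raster(
            tmp_path / "s.tif", bands, small_grid, nodata=-9999.0, acq_date=DATE
        )
        scene = read_scene(path, "reflectance")
        assert scene.grid.n_rows == small_grid.n_rows
        assert scene.grid.cell_size_deg == pytest.approx(0.005)
        assert scene.grid.origin_lon == pytest.approx(-36.0)
        assert scene.acq_date == DATE
        np.testing.assert_array_equal(scene.bands, bands)

    def test_scaled_integer_reflectance_converted(self, tmp_path, small_grid):
        ints = np.full((7,) + small_grid.shape, 5000, dtype=np.int16)
        path = write_raster(tmp_path / "i.tif", ints, small_grid, acq_date=DATE)
        scene = read_scene(path, "reflectance")
        assert scene.bands[0, 0, 0] == pytest.approx(0.5)

    def test_band_count_mismatch_rejected(self, tmp_path, small_grid):
        six = np.zeros((6,) + small_grid.shape, dtype=np.float32)
        path = write_raster(tmp_path / "b.tif", six, small_grid, acq_date=DATE)
        with pytest.raises(ValueError, match="7 bands"):
            read_scene(path, "reflectance")

    def test_thermal_nodata_becomes_nan(self, tmp_path, small_grid):
        dn = np.full(small_grid.shape, 15000, dtype=np.uint16)
        dn[0, 0] = 0
        path = write_raster(tmp_path / "t.tif", dn, small_grid, nodata=0, acq_date=DATE)
        scene = read_scene(path, "thermal")
        assert np.isnan(scene.dn[0, 0])
        assert scene.dn[1, 1] == 15000

    def test_out_of_range_reflectance_is_nodata(self, small_grid):
        bands = np.full((7,) + small_grid.shape, 0.3)
        bands[0, 0, 0] = 1.7  # beyond the nominal valid range
        scene = ReflectanceScene(small_grid, DATE, bands)
        assert np.isnan(scene.bands[0, 0, 0])


class TestQualityMask:
    def test_cloud_bits_reject_cell(self, small_grid):
        words = np.zeros(small_grid.shape, dtype=np.uint8)
        words[1, 1] = 1  # cloud state bits 0-1 nonzero
        scene = apply_quality_mask(refl_scene(small_grid), words, DEFAULT_QA_BIT_SPEC)
        assert np.isnan(scene.bands[:, 1, 1]).all()
        assert np.isfinite(scene.bands[:, 0, 0]).all()

    def test_clear_words_are_identity(self, small_grid):
        words = np.zeros(small_grid.shape, dtype=np.uint8)
        src = refl_scene(small_grid)
        out = apply_quality_mask(src, words, DEFAULT_QA_BIT_SPEC)
        np.testing.assert_array_equal(out.bands, src.bands)

    def test_shadow_bit_alone_rejects(self, small_grid):
        # bits 0-1 clear but shadow bit 2 set: word 0b100 = 4
        words = np.zeros(small_grid.shape, dtype=np.uint8)
        words[2, 3] = 4
        usable = decode_qa_words(words, DEFAULT_QA_BIT_SPEC)
        assert not usable[2, 3]
        assert usable.sum() == usable.size - 1

    def test_grid_mismatch_rejected(self, small_grid):
        other = GeoGrid(3, 3, 0.005, -36.0, -9.3)
        qa = QualityMask(other, DATE, np.ones(other.shape, dtype=bool))
        with pytest.raises(ValueError, match="grid"):
            apply_quality_mask(refl_scene(small_grid), qa)

    def test_retained_values_bit_exact(self, small_grid):
        rng = np.random.default_rng(3)
        bands = rng.uniform(0, 1, (7,) + small_grid.shape)
        words = (rng.random(small_grid.shape) < 0.4).astype(np.uint8)
        out = apply_quality_mask(
            ReflectanceScene(small_grid, DATE, bands.copy()), words, DEFAULT_QA_BIT_SPEC
        )
        keep = words == 0
        np.testing.assert_array_equal(out.bands[:, keep], bands[:, keep])


class TestResampleNearest:
    def test_aligned_2x_refinement_blocks(self):
        src_grid = GeoGrid(2, 2, 0.01, 0.0, 1.0)
        dst_grid = GeoGrid(4, 4, 0.005, 0.0, 1.0)
        src = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = resample_nearest(src, src_grid, dst_grid)
        expected = np.repeat(np.repeat(src, 2, axis=0), 2, axis=1)
        np.testing.assert_array_equal(out, expected)

    def test_identity_on_same_grid(self, small_grid):
        src = np.arange(20, dtype=float).reshape(small_grid.shape)
        np.testing.assert_array_equal(
            resample_nearest(src, small_grid, small_grid), src
        )

    def test_half_cell_shift_matches_exhaustive_search(self):
        src_grid = GeoGrid(5, 5, 0.01, 0.0, 1.0)
        dst_grid = GeoGrid(5, 5, 0.01, 0.005, 1.0 - 0.005)
        rng = np.random.default_rng(7)
        src = rng.integers(0, 100, src_grid.shape).astype(float)
        out = resample_nearest(src, src_grid, dst_grid)

        # oracle: exhaustive nearest-center search; ties -> north then west
        slat, slon = src_grid.lat_centers(), src_grid.lon_centers()
        for r, dlat in enumerate(dst_grid.lat_centers()):
            for c, dlon in enumerate(dst_grid.lon_centers()):
                best = min(
                    ((i, j) for i in range(5) for j in range(5)),
                    key=lambda ij: (
                        round(abs(slat[ij[0]] - dlat) + abs(slon[ij[1]] - dlon), 9),
                        ij,
                    ),
                )
                assert out[r, c] == src[best]

    def test_no_new_values_created(self):
        src_grid = GeoGrid(3, 4, 0.013, -1.0, 2.0)
        dst_grid = GeoGrid(7, 9, 0.007, -1.001, 2.002)
        src = np.random.default_rng(1).normal(size=src_grid.shape)
        out = resample_nearest(src, src_grid, dst_grid)
        assert set(out.ravel()) <= set(src.ravel())

    def test_disjoint_grids_rejected(self):
        src_grid = GeoGrid(2, 2, 0.01, 0.0, 1.0)
        dst_grid = GeoGrid(2, 2, 0.01, 10.0, 1.0)
        with pytest.raises(ValueError, match="overlap"):
            resample_nearest(np.zeros((2, 2)), src_grid, dst_grid)


class TestSeasonalComposite:
    def make_scenes(self, grid, cell_values, dates=None):
        dates = dates or [dt.date(2000, 10, 1), dt.date(2000, 12, 1), dt.date(2001, 2, 1)]
        scenes = []
        for value, date in zip(cell_values, dates):
            bands = np.full((7,) + grid.shape, value)
            scenes.append(ReflectanceScene(grid, date, bands))
        return scenes

    def thermal(self, grid, date=dt.date(2000, 11, 1), dn=15000.0):
        return [ThermalScene(grid, date, np.full(grid.shape, dn))]

    def test_median_of_three(self, small_grid):
        scenes = self.make_scenes(small_grid, [0.2, 0.4, 0.6])
        comp = seasonal_composite(scenes, self.thermal(small_grid), 2001)
        assert comp.bands[0, 0, 0] == pytest.approx(0.4)
        assert comp.index_year == 2001

    def test_all_masked_cell_is_nodata(self, small_grid):
        scenes = self.make_scenes(small_grid, [0.2, 0.4, 0.6])
        for scene in scenes:
            scene.bands[:, 0, 0] = np.nan
        comp = seasonal_composite(scenes, self.thermal(small_grid), 2001)
        assert not comp.valid_mask[0, 0]
        assert np.isnan(comp.bands[:, 0, 0]).all()
        assert comp.valid_mask[1, 1]

    def test_season_window_and_year_label(self):
        start, end = season_window(2001)
        assert start == dt.date(2000, 9, 1)
        assert end == dt.date(2001, 3, 31)

    def test_out_of_window_scene_rejected(self, small_grid):
        scenes = self.make_scenes(
            small_grid, [0.2], dates=[dt.date(2001, 6, 1)]
        )
        with pytest.raises(ValueError, match="outside season"):
            seasonal_composite(scenes, self.thermal(small_grid), 2001)

    def test_single_scene_is_identity_on_valid_cells(self, small_grid):
        scenes = self.make_scenes(small_grid, [0.37], dates=[dt.date(2000, 9, 5)])
        comp = seasonal_composite(scenes, self.thermal(small_grid), 2001)
        np.testing.assert_allclose(comp.bands, scenes[0].bands)

    def test_thermal_composited_then_converted(self, small_grid):
        scenes = self.make_scenes(small_grid, [0.3], dates=[dt.date(2000, 9, 5)])
        comp = seasonal_composite(scenes, self.thermal(small_grid, dn=15000), 2001)
        assert comp.lst_celsius[0, 0] == pytest.approx(26.85)

    def test_mixed_grids_rejected(self, small_grid):
        other = GeoGrid(3, 3, 0.005, -36.0, -9.3)
        scenes = self.make_scenes(small_grid, [0.2], dates=[dt.date(2000, 10, 1)])
        with pytest.raises(ValueError, match="grid"):
            seasonal_composite(scenes, self.thermal(other), 2001)
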