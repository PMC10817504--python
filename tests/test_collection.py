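"""Filtering, cloud masking, and reducers against hand-computed values
and a brute-force per-pixel oracle."""

import datetime as dt
import statistics

import numpy as np
import pytest
from shapely.geometry import box

from forestmon.collection import (
    SceneCollection,
    filter_bounds,
    filter_cloud_metadata,
    filter_date,
    make_rgb,
    mask_clouds,
    mask_collection,
    reduce,
)
from forestmon.errors import FormatError
from forestmon.grid import GridSpec

from conftest import make_collection_of, make_scene


def _coll(grid, values_by_date):
    scenes = [make_scene(grid, d, v) for d, v in values_by_date.items()]
    return make_collection_of(grid, *scenes)


class TestFilters:
    def test_date_window_is_half_open(self, grid4):
        coll = _coll(
            grid4,
            {
                dt.date(2017, 4, 13): {"B4": 0.1},
                dt.date(2017, 4, 14): {"B4": 0.2},
                dt.date(2017, 10, 15): {"B4": 0.3},
            },
        )
        kept = filter_date(coll, dt.date(2017, 4, 14), dt.date(2017, 10, 15))
        assert kept.dates == [dt.date(2017, 4, 14)]
        # window covering everything is the identity; empty window errors
        assert len(filter_date(coll, dt.date(2017, 1, 1), dt.date(2018, 1, 1))) == 3
        assert len(filter_date(coll, dt.date(2018, 1, 1), dt.date(2019, 1, 1))) == 0
        with pytest.raises(ValueError):
            filter_date(coll, dt.date(2017, 10, 15), dt.date(2017, 4, 14))

    def test_cloud_metadata_threshold_is_inclusive(self, grid4):
        scenes = [
            make_scene(grid4, dt.date(2017, 5, i + 1), {"B4": 0.1}, cloud_pct=p)
            for i, p in enumerate([3.0, 5.0, 7.0])
        ]
        coll = make_collection_of(grid4, *scenes)
        assert [s.cloudy_pixel_percentage for s in filter_cloud_metadata(coll, 5)] == [3.0, 5.0]
        assert len(filter_cloud_metadata(coll, 100)) == 3
        assert len(filter_cloud_metadata(coll, 0)) == 0

    def test_bounds_uses_pixel_centre_containment(self, grid4):
        coll = _coll(grid4, {dt.date(2017, 6, 1): {"B4": 0.1}})
        # full extent: identity
        full = filter_bounds(coll, grid4.extent_polygon())
        assert np.isfinite(full[0].bands["B4"]).all()
        # one 10 m cell keeps exactly one pixel
        one = filter_bounds(coll, grid4.pixel_polygon(2, 1))
        assert np.isfinite(one[0].bands["B4"]).sum() == 1
        assert np.isfinite(one[0].bands["B4"][2, 1])

    def test_disjoint_roi_warns_and_blanks(self, grid4, caplog):
        coll = _coll(grid4, {dt.date(2017, 6, 1): {"B4": 0.1}})
        with caplog.at_level("WARNING"):
            out = filter_bounds(coll, box(1e5, 1e5, 2e5, 2e5))
        assert not np.isfinite(out[0].bands["B4"]).any()
        assert "disjoint" in caplog.text

    def test_filter_composition_is_order_independent(self, grid4):
        rng = np.random.default_rng(0)
        scenes = [
            make_scene(
                grid4,
                dt.date(2017, 5, 1 + 3 * i),
                {"B4": rng.uniform(0, 1, grid4.shape), "B8": rng.uniform(0, 1, grid4.shape)},
                cloud_pct=float(rng.uniform(0, 10)),
            )
            for i in range(6)
        ]
        coll = make_collection_of(grid4, *scenes)
        roi = box(0, -40, 20, 0)
        start, end = dt.date(2017, 5, 2), dt.date(2017, 5, 15)

        a = filter_cloud_metadata(filter_date(filter_bounds(coll, roi), start, end), 5)
        b = filter_bounds(filter_cloud_metadata(filter_date(coll, start, end), 5), roi)
        c = filter_date(filter_bounds(filter_cloud_metadata(coll, 5), roi), start, end)
        for x, y in ((a, b), (a, c)):
            assert x.dates == y.dates
            for sx, sy in zip(x, y):
                for band in sx.bands:
                    assert np.array_equal(sx.bands[band], sy.bands[band], equal_nan=True)


class TestCloudMask:
    @pytest.mark.parametrize(
        "qa_value,masked",
        [(0, False), (1 << 10, True), ((1 << 10) | (1 << 11), True), (1 << 9, False)],
    )
    def test_bit_rules(self, grid4, qa_value, masked):
        qa = np.full(grid4.shape, qa_value, dtype=np.uint16)
        s = make_scene(grid4, dt.date(2017, 6, 1), {"B4": 0.1}, qa=qa)
        out = mask_clouds(s)
        assert np.isfinite(out.bands["B4"]).all() != masked

    def test_missing_qa_band_is_a_format_error(self, grid4):
        s = make_scene(grid4, dt.date(2017, 6, 1), {"B4": 0.1})
        s.qa = None
        with pytest.raises(FormatError):
            mask_clouds(s)

    def test_masking_monotonicity(self, grid4):
        rng = np.random.default_rng(1)
        qa = rng.integers(0, 2**13, grid4.shape).astype(np.uint16)
        s = make_scene(grid4, dt.date(2017, 6, 1), {"B4": 0.1}, qa=qa)
        few = np.isfinite(mask_clouds(s, (10,)).bands["B4"]).sum()
        more = np.isfinite(mask_clouds(s, (10, 11)).bands["B4"]).sum()
        even_more = np.isfinite(mask_clouds(s, (10, 11, 12)).bands["B4"]).sum()
        assert few >= more >= even_more


class TestReducers:
    def test_median_skips_nodata(self, grid4):
        v1, v2, v3 = (np.full(grid4.shape, x) for x in (0.2, 0.4, 0.9))
        v3[:] = np.nan
        coll = _coll(
            grid4,
            {
                dt.date(2017, 5, 1): {"B4": v1},
                dt.date(2017, 6, 1): {"B4": v2},
                dt.date(2017, 7, 1): {"B4": v3},
            },
        )
        comp = reduce(coll, "median")
        assert np.allclose(comp.bands["B4"], 0.3)
        assert (comp.n_scenes_used == 2).all()

    def test_population_std(self, grid4):
        coll = _coll(
            grid4, {dt.date(2017, 5, 1): {"B4": 0.0}, dt.date(2017, 6, 1): {"B4": 2.0}}
        )
        assert np.allclose(reduce(coll, "std").bands["B4"], 1.0)
        const = _coll(
            grid4,
            {dt.date(2017, m, 1): {"B4": 1.0} for m in (5, 6, 7)},
        )
        assert np.allclose(reduce(const, "std").bands["B4"], 0.0)

    def test_single_scene_median_is_identity(self, grid4):
        vals = np.random.default_rng(2).uniform(0, 1, grid4.shape)
        coll = _coll(grid4, {dt.date(2017, 6, 1): {"B4": vals}})
        assert np.array_equal(reduce(coll, "median").bands["B4"], vals)

    def test_empty_collection_reduces_to_all_nodata(self, grid4):
        coll = _coll(grid4, {dt.date(2017, 6, 1): {"B4": 0.5}})
        empty = filter_date(coll, dt.date(2018, 1, 1), dt.date(2019, 1, 1))
        comp = reduce(empty, "median")
        assert not np.isfinite(comp.bands["B4"]).any()
        assert (comp.n_scenes_used == 0).all()

    def test_unknown_reducer_rejected(self, grid4):
        coll = _coll(grid4, {dt.date(2017, 6, 1): {"B4": 0.5}})
        with pytest.raises(ValueError):
            reduce(coll, "mode")

    @pytest.mark.parametrize("reducer", ["median", "mean", "std"])
    def test_reducers_match_bruteforce_loop(self, reducer):
        """Vectorised reducers equal a naive per-pixel loop on small grids."""
        rng = np.random.default_rng(42)
        grid = GridSpec(width=5, height=4)
        scenes = []
        for i in range(6):
            vals = rng.uniform(0, 1, grid.shape)
            vals[rng.uniform(size=grid.shape) < 0.3] = np.nan
            scenes.append(make_scene(grid, dt.date(2017, 4, 1 + i), {"B4": vals}))
        comp = reduce(make_collection_of(grid, *scenes), reducer)
        for r in range(grid.height):
            for c in range(grid.width):
                obs = [s.bands["B4"][r, c] for s in scenes if np.isfinite(s.bands["B4"][r, c])]
                if not obs:
                    assert not np.isfinite(comp.bands["B4"][r, c])
                    continue
                if reducer == "median":
                    expect = statistics.median(obs)
                elif reducer == "mean":
                    expect = statistics.fmean(obs)
                else:
                    expect = statistics.pstdev(obs) if len(obs) > 1 else 0.0
                assert comp.bands["B4"][r, c] == pytest.approx(expect, abs=1e-12)


class TestRgb:
    def test_stretch_endpoints_and_rounding(self, grid4):
        for refl, expect in [(0.3, 255), (0.0, 0), (0.15, 128)]:
            coll = _coll(grid4, {dt.date(2017, 6, 1): {"B2": refl, "B3": refl, "B4": refl}})
            rgb = make_rgb(reduce(coll, "median"))
            assert rgb.shape == (4,) + grid4.shape
            assert (rgb[:3] == expect).all()
            assert (rgb[3] == 255).all()

    def test_nodata_is_transparent_and_missing_band_errors(self, grid4):
        vals = np.full(grid4.shape, 0.2)
        vals[0, 0] = np.nan
        coll = _coll(grid4, {dt.date(2017, 6, 1): {"B2": vals, "B3": vals, "B4": vals}})
        rgb = make_rgb(reduce(coll, "median"))
        assert rgb[3, 0, 0] == 0
        bad = _coll(grid4, {dt.date(2017, 6, 1): {"B2": 0.1, "B3": 0.1}})
        with pytest.raises(FormatError):
            make_rgb(reduce(bad, "median"))
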