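"""Random-forest species classification, zonal majority, and the
compartment-agreement accuracy."""

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from forestmon.collection import mask_collection, reduce
from forestmon.errors import FormatError, TrainingError
from forestmon.grid import GridSpec
from forestmon.simulate import (
    TRAINING_COUNTS,
    make_collection,
    make_compartments,
)
from forestmon.species import (
    SpeciesMap,
    TrainingPoint,
    agreement_accuracy,
    auto_training_points,
    classify_species,
    sample_training,
    species_accuracy,
    train_rf,
    zonal_majority,
)

from conftest import make_collection_of, make_scene


def _composite(grid, band_values, date=dt.date(2020, 7, 1)):
    return reduce(make_collection_of(grid, make_scene(grid, date, band_values)), "median")


@pytest.fixture(scope="module")
def demo_composite():
    """Noise-free demo composite of the species year plus its compartments."""
    from forestmon.simulate import demo_config

    cfg = demo_config(seed=13, noise_sd=0.0, cloud_frac_range=(0.0, 0.0))
    comps = make_compartments(cfg)
    comp = reduce(mask_collection(make_collection(cfg, 2020)), "median")
    return cfg, comps, comp


class TestSampling:
    def test_feature_lookup_and_out_of_grid_drop(self, grid4, caplog):
        comp = _composite(grid4, {"B2": 0.1, "B3": 0.2, "B4": 0.3, "B8": 0.6})
        pts = [
            TrainingPoint(*grid4.pixel_centre(1, 2), 2),
            TrainingPoint(1e6, 1e6, 3),  # outside
        ]
        with caplog.at_level("WARNING"):
            ts = sample_training(pts, comp)
        assert ts.features.tolist() == [[0.1, 0.2, 0.3, 0.6]]
        assert ts.labels.tolist() == [2]
        assert "outside grid" in caplog.text

    def test_nodata_pixel_dropped_with_warning(self, grid4, caplog):
        vals = {b: np.full(grid4.shape, 0.2) for b in ("B2", "B3", "B4", "B8")}
        vals["B8"][1, 1] = np.nan
        comp = _composite(grid4, vals)
        with caplog.at_level("WARNING"):
            ts = sample_training(
                [TrainingPoint(*grid4.pixel_centre(1, 1), 0),
                 TrainingPoint(*grid4.pixel_centre(0, 0), 1)],
                comp,
            )
        assert len(ts.labels) == 1
        assert "nodata" in caplog.text

    def test_field_protocol_point_counts_preserved(self, demo_composite):
        cfg, comps, comp = demo_composite
        pts = auto_training_points(comps, cfg.grid, seed=1)
        assert len(pts) == 123
        ts = sample_training(pts, comp)
        assert ts.class_counts() == TRAINING_COUNTS
        assert sorted(TRAINING_COUNTS.values()) == [15, 19, 22, 27, 40]


class TestTraining:
    def test_single_class_rejected(self, grid4):
        comp = _composite(grid4, {"B4": 0.3, "B8": 0.6})
        ts = sample_training([TrainingPoint(*grid4.pixel_centre(0, 0), 2)] * 3, comp)
        with pytest.raises(TrainingError):
            train_rf(ts)

    def test_vars_per_split_clamped_with_warning(self, demo_composite, caplog):
        cfg, comps, comp = demo_composite
        ts = sample_training(auto_training_points(comps, cfg.grid, seed=1), comp)
        with caplog.at_level("WARNING"):
            model = train_rf(ts, vars_per_split=10, seed=0)
        assert "clamped" in caplog.text
        assert model.forest.max_features == 4

    def test_separable_signatures_give_perfect_oob(self, demo_composite):
        cfg, comps, comp = demo_composite
        ts = sample_training(auto_training_points(comps, cfg.grid, seed=1), comp)
        model = train_rf(ts, seed=0, oob=True)
        assert model.oob_accuracy == 1.0

    def test_same_seed_reproduces_predictions(self, demo_composite):
        cfg, comps, comp = demo_composite
        ts = sample_training(auto_training_points(comps, cfg.grid, seed=1), comp)
        a = classify_species(train_rf(ts, seed=5), comp)
        b = classify_species(train_rf(ts, seed=5), comp)
        assert np.array_equal(a.values, b.values)


class TestClassification:
    def test_uniform_signature_gives_uniform_map_and_nodata_propagates(self, demo_composite):
        cfg, comps, comp = demo_composite
        ts = sample_training(auto_training_points(comps, cfg.grid, seed=1), comp)
        model = train_rf(ts, seed=0)
        sig = {b: np.full((4, 4), ts.features[0][i]) for i, b in enumerate(ts.feature_names)}
        sig["B8"][0, 0] = np.nan
        grid = GridSpec(width=4, height=4)
        uniform = _composite(grid, sig)
        out = classify_species(model, uniform)
        assert out.values[0, 0] == -1
        assert (out.values.ravel()[1:] == ts.labels[0]).all()

    def test_band_mismatch_is_a_format_error(self, demo_composite, grid4):
        cfg, comps, comp = demo_composite
        ts = sample_training(auto_training_points(comps, cfg.grid, seed=1), comp)
        model = train_rf(ts, seed=0)
        with pytest.raises(FormatError):
            classify_species(model, _composite(grid4, {"B4": 0.1, "B8": 0.5}))

    def test_noiseless_per_pixel_agreement(self, demo_composite):
        cfg, comps, comp = demo_composite
        ts = sample_training(auto_training_points(comps, cfg.grid, seed=1), comp)
        sp = classify_species(train_rf(ts, seed=2), comp)
        truth = comps.species_raster(cfg.grid)
        ok = (truth >= 0) & (sp.values >= 0)
        assert (sp.values[ok] == truth[ok]).mean() >= 0.99


class TestZonalMajority:
    def _map(self, grid, values):
        return SpeciesMap(np.asarray(values, dtype=np.int16), {}, grid)

    def test_mode_tie_and_empty_rules(self, tiny_sim_config):
        comps = make_compartments(tiny_sim_config)
        grid = tiny_sim_config.grid
        labels = comps.label_raster(grid)
        vals = np.full(grid.shape, -1, dtype=np.int16)
        # compartment 0: clear mode; compartment 1: 50/50 tie between 1 and 3
        c0 = np.flatnonzero(labels.ravel() == 0)
        vals.ravel()[c0] = 2
        vals.ravel()[c0[:1]] = 1
        c1 = np.flatnonzero(labels.ravel() == 1)
        half = len(c1) // 2
        vals.ravel()[c1[:half]] = 3
        vals.ravel()[c1[half : 2 * half]] = 1
        # compartment 2 stays all nodata
        table = zonal_majority(self._map(grid, vals), comps).set_index("compartment_id")
        assert table.loc["C001", "majority_code"] == 2
        assert table.loc["C002", "majority_code"] == 1  # tie -> lowest code
        assert bool(table.loc["C002", "tie"])
        assert table.loc["C003", "majority_code"] == -1
        assert table.loc["C003", "n_pixels"] == 0

    def test_majority_matches_bruteforce_counter(self, tiny_sim_config):
        from collections import Counter

        comps = make_compartments(tiny_sim_config)
        grid = tiny_sim_config.grid
        labels = comps.label_raster(grid)
        rng = np.random.default_rng(17)
        vals = rng.integers(0, 5, grid.shape).astype(np.int16)
        table = zonal_majority(self._map(grid, vals), comps)
        for i, row in table.iterrows():
            pix = vals[labels == comps.ids.index(row.compartment_id)]
            counts = Counter(int(v) for v in pix)
            best = max(counts.values())
            expect = min(k for k, v in counts.items() if v == best)
            assert row.majority_code == expect

    def test_perfect_pixels_give_perfect_compartments(self, tiny_sim_config):
        comps = make_compartments(tiny_sim_config)
        truth = comps.species_raster(tiny_sim_config.grid)
        table = zonal_majority(self._map(tiny_sim_config.grid, truth), comps)
        assert species_accuracy(table) == 100.0


class TestAccuracy:
    def test_published_count_arithmetic(self):
        assert round(agreement_accuracy(258, 339), 1) == 76.1

    def test_all_or_none_agree_and_ordering_invariance(self):
        table = pd.DataFrame(
            {
                "compartment_id": ["a", "b", "c"],
                "field_code": [0, 1, 4],
                "majority_code": [0, 2, 4],
                "n_pixels": [5, 5, 5],
                "tie": [False] * 3,
                "agreement": [True, False, True],
            }
        )
        acc = species_accuracy(table)
        assert acc == pytest.approx(100 * 2 / 3)
        shuffled = table.sample(frac=1, random_state=4)
        assert species_accuracy(shuffled) == acc
        assert species_accuracy(table, exclude_clearcut=True) == pytest.approx(50.0)
        all_agree = table.assign(majority_code=table.field_code, agreement=True)
        assert species_accuracy(all_agree) == 100.0
        none_agree = table.assign(agreement=False)
        assert species_accuracy(none_agree) == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            species_accuracy(pd.DataFrame())
        with pytest.raises(ValueError):
            agreement_accuracy(1, 0)
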