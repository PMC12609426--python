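import datetime as dt

import numpy as np
import pandas as pd
import pytest

from sifmstws import (
    GridGeometry,
    ModelKey,
    Raster,
    RegistryConfig,
    StratumMap,
    predict_grid,
    resolve_model,
    select_algorithm,
    train_model_cv,
    train_registry,
)
from sifmstws.models import FittedModel, ModelRegistry, circular_doy_distance, predict_rows
from sifmstws.preprocess import FEATURE_COLUMNS
from sifmstws.sampling import UNIVERSAL
from sifmstws.synthetic import simulate_reflectance

from conftest import FAST_GRID


def _toy_table(n=200, seed=0, slope=1.5):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(n, 7))
    y = 0.4 + slope * (X[:, 1] - X[:, 0])
    tbl = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    tbl["sif_smoothed"] = y
    tbl["doy"] = 200
    tbl["stratum"] = 1
    return tbl


class _ConstantModel:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


def _stub(doy, stratum, value=1.0):
    return FittedModel(
        key=ModelKey(doy, stratum), algorithm="stub", params={}, cv_score=0.0,
        n_train=0, estimator=_ConstantModel(value),
    )


class TestTrainModelCv:
    def test_single_configuration_grid_is_selected(self):
        fm = train_model_cv(_toy_table(), "gbt", param_grid=FAST_GRID, folds=2, seed=0)
        assert fm.params == FAST_GRID[0]
        assert np.isfinite(fm.cv_score)

    def test_same_seed_reproduces_selection_and_fit(self):
        grid = [
            {"max_iter": 40, "learning_rate": 0.2, "max_leaf_nodes": 7},
            {"max_iter": 80, "learning_rate": 0.1, "max_leaf_nodes": 15},
        ]
        a = train_model_cv(_toy_table(), "gbt", param_grid=grid, folds=3, seed=9)
        b = train_model_cv(_toy_table(), "gbt", param_grid=grid, folds=3, seed=9)
        assert a.params == b.params
        X = np.full((5, 7), 0.5)
        assert np.array_equal(a.predict(X), b.predict(X))

    def test_degenerate_target_rejected(self):
        tbl = _toy_table(slope=0.0)
        tbl["sif_smoothed"] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            train_model_cv(tbl, "gbt", param_grid=FAST_GRID, folds=2)

    @pytest.mark.parametrize("algorithm", ["gbt", "rf", "nn"])
    def test_all_candidate_families_fit_and_predict_finite(self, algorithm):
        fm = train_model_cv(_toy_table(n=150), algorithm, folds=2, seed=1)
        pred = fm.predict(np.random.default_rng(0).uniform(0, 1, (20, 7)))
        assert np.isfinite(pred).all()

    @pytest.mark.parametrize("algorithm", ["gbt", "rf"])
    def test_tree_models_recover_noiseless_linear_stratum(self, algorithm):
        """On a noiseless linear pool, tree-based candidates validate at
        R^2 >= 0.99."""
        from sifmstws.sampling import split_train_val

        tbl = _toy_table(n=1500, seed=2)
        train, val = split_train_val(tbl, ratio=0.7, seed=2)
        fm = train_model_cv(train, algorithm, folds=2, seed=2)
        from sifmstws.evaluate import regression_metrics

        m = regression_metrics(fm.predict_table(val), val["sif_smoothed"].to_numpy())
        assert m.r2 >= 0.99


class TestSelectAlgorithm:
    def test_single_candidate_returned(self):
        tag, report = select_algorithm([_toy_table()], candidates=("rf",), folds=2, seed=0)
        assert tag == "rf"
        assert report["selected"].all()

    def test_tie_breaks_by_declared_order(self):
        # identical candidates: the first declared wins
        tag, _ = select_algorithm(
            [_toy_table()], candidates=("gbt", "gbt"),
            param_grids={"gbt": FAST_GRID}, folds=2, seed=0,
        )
        assert tag == "gbt"

    def test_selected_candidate_scores_at_least_rejected_ones(self):
        """The winner's mean CV score bounds every rejected candidate's."""
        rng = np.random.default_rng(5)
        tbl = _toy_table(n=600, seed=5)
        tbl["sif_smoothed"] += rng.normal(0, 0.05, len(tbl))
        grids = {"gbt": FAST_GRID, "rf": [{"n_estimators": 50}], "nn": [{"hidden_layer_sizes": (16,)}]}
        tag, report = select_algorithm(
            [tbl], candidates=("gbt", "rf", "nn"), param_grids=grids, folds=2, seed=5
        )
        means = report.groupby("algorithm")["cv_r2"].mean()
        assert means[tag] == means.max()

    def test_requires_candidates_and_pools(self):
        with pytest.raises(ValueError):
            select_algorithm([], candidates=("gbt",))
        with pytest.raises(ValueError):
            select_algorithm([_toy_table()], candidates=())


class TestRegistry:
    def test_fleet_composition(self, mini_registry, mini_table):
        strata = set(int(s) for s in mini_table["stratum"].unique())
        model_strata = {k.stratum for k in mini_registry.models if k.stratum != UNIVERSAL}
        skip_strata = {k.stratum for k in mini_registry.skips}
        assert model_strata | skip_strata == strata
        assert ModelKey(225, UNIVERSAL) in mini_registry.models

    def test_skip_marker_for_underpopulated_stratum(self, mini_table):
        # drain one stratum below the floor
        target = int(mini_table["stratum"].iloc[0])
        reduced = pd.concat(
            [
                mini_table[mini_table["stratum"] != target],
                mini_table[mini_table["stratum"] == target].head(50),
            ]
        )
        rc = RegistryConfig(
            algorithm="gbt", param_grid=FAST_GRID, folds=2, cap=1500, min_n=200,
            seed=7, doys=(225,), strata=(target,),
        )
        reg = train_registry(reduced, rc)
        assert ModelKey(225, target) in reg.skips
        assert ModelKey(225, target) not in reg.models
        assert ModelKey(225, UNIVERSAL) in reg.models

    def test_round_trip_serialization(self, mini_registry, tmp_path):
        mini_registry.save(tmp_path / "reg")
        loaded = ModelRegistry.load(tmp_path / "reg")
        assert set(loaded.models) == set(mini_registry.models)
        assert loaded.skips == mini_registry.skips
        X = np.random.default_rng(0).uniform(0, 0.6, (50, 7))
        for key, fm in mini_registry.models.items():
            assert np.array_equal(fm.predict(X), loaded.models[key].predict(X))
        # a second save emits an identical manifest
        loaded.save(tmp_path / "reg2")
        assert (tmp_path / "reg/manifest.json").read_text() == (
            tmp_path / "reg2/manifest.json"
        ).read_text()

    def test_no_key_is_both_model_and_skip(self, mini_registry):
        assert set(mini_registry.models) & mini_registry.skips == set()


class TestResolveModel:
    def _registry(self, keys, with_universal=()):
        reg = ModelRegistry(algorithm="stub", config=RegistryConfig(doys=(1,)))
        for doy, stratum in keys:
            reg.models[ModelKey(doy, stratum)] = _stub(doy, stratum, value=doy)
        for doy in with_universal:
            reg.models[ModelKey(doy, UNIVERSAL)] = _stub(doy, UNIVERSAL, value=-doy)
        return reg

    def test_exact_hit(self):
        reg = self._registry([(200, 5)])
        assert resolve_model(reg, 200, 5).key == ModelKey(200, 5)

    def test_nearest_circular_distance(self):
        reg = self._registry([(198, 5), (203, 5)])
        assert resolve_model(reg, 200, 5).key.doy == 198  # distance 2 < 3

    def test_wraps_around_year_end(self):
        reg = self._registry([(360, 5), (20, 5)])
        assert resolve_model(reg, 3, 5).key.doy == 360  # distance 8 < 17

    def test_tie_prefers_earlier_doy(self):
        reg = self._registry([(198, 5), (202, 5)])
        assert resolve_model(reg, 200, 5).key.doy == 198

    def test_untrained_stratum_falls_back_to_universal(self):
        reg = self._registry([(200, 5)], with_universal=[200])
        assert resolve_model(reg, 200, 9).key.stratum == UNIVERSAL

    def test_horizon_limits_nearest_date(self):
        reg = self._registry([(100, 5)], with_universal=[200])
        fm = resolve_model(reg, 200, 5, horizon=30)
        assert fm.key.stratum == UNIVERSAL
        assert resolve_model(reg, 200, 5, horizon=182).key == ModelKey(100, 5)

    def test_unresolvable_raises_with_key(self):
        reg = self._registry([(200, 5)])
        with pytest.raises(KeyError, match="stratum=9"):
            resolve_model(reg, 200, 9)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(4)
        doys = sorted(set(rng.integers(1, 366, 25).tolist()))
        reg = self._registry([(d, 3) for d in doys])
        for q in rng.integers(1, 366, 50):
            got = resolve_model(reg, int(q), 3).key.doy
            best = min(circular_doy_distance(d, int(q)) for d in doys)
            assert circular_doy_distance(got, int(q)) == best


class TestPredictGrid:
    def test_empty_stratum_map_gives_all_nodata(self, mini_registry, mini_world):
        d = dt.date(2023, 8, 13)
        refl = simulate_reflectance(mini_world, d)
        empty = StratumMap(
            model_ids=np.zeros_like(mini_world.strata.model_ids), geom=mini_world.geom
        )
        grid = predict_grid(mini_registry, refl, empty, d)
        assert grid.mask().all()

    def test_geometry_and_provenance(self, mini_registry, mini_world):
        d = dt.date(2023, 8, 13)
        refl = simulate_reflectance(mini_world, d)
        grid = predict_grid(mini_registry, refl, mini_world.strata, d)
        assert grid.geom == mini_world.geom
        veg = mini_world.strata.model_ids > 0
        assert np.isfinite(grid.values[veg]).all()
        assert (grid.values[~veg] != grid.values[~veg]).all()  # NaN
        assert (grid.source_doy[veg] > 0).all()

    def test_mismatched_geometry_rejected(self, mini_registry, mini_world):
        d = dt.date(2023, 8, 13)
        other = GridGeometry(lat_max=0.5, lon_min=0.0, nrows=3, ncols=3, cell=0.05)
        refl = Raster(values=np.zeros((7, 3, 3)), geom=other)
        with pytest.raises(ValueError, match="geometry mismatch"):
            predict_grid(mini_registry, refl, mini_world.strata, d)

    def test_removing_models_degrades_but_keeps_coverage(self, mini_registry, mini_world):
        import copy

        reg = copy.copy(mini_registry)
        reg.models = dict(mini_registry.models)
        victims = [k for k in reg.models if k.stratum not in (UNIVERSAL,)][:2]
        for k in victims:
            del reg.models[k]
        d = dt.date(2023, 8, 13)
        grid = predict_grid(reg, simulate_reflectance(mini_world, d), mini_world.strata, d)
        veg = mini_world.strata.model_ids > 0
        assert np.isfinite(grid.values[veg]).all()


class TestPredictRows:
    def test_rows_route_to_their_stratum_model(self):
        reg = ModelRegistry(algorithm="stub", config=RegistryConfig(doys=(100,)))
        reg.models[ModelKey(100, 1)] = _stub(100, 1, value=10.0)
        reg.models[ModelKey(100, 2)] = _stub(100, 2, value=20.0)
        tbl = _toy_table(n=6)
        tbl["stratum"] = [1, 2, 1, 2, 1, 2]
        tbl["doy"] = 100
        pred = predict_rows(reg, tbl)
        assert pred.tolist() == [10.0, 20.0, 10.0, 20.0, 10.0, 20.0]
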