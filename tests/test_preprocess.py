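import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sifmstws import GridGeometry, Raster, StratumMap
from sifmstws.preprocess import (
    FEATURE_COLUMNS,
    _haversine_deg,
    build_training_table,
    combine_bands,
    knn_smooth,
    match_reflectance,
    qc_filter,
)


class TestQcFilter:
    def test_all_flags_allowed_is_identity(self, simple_footprints):
        out = qc_filter(simple_footprints, allowed_flags=(0, 1))
        pd.testing.assert_frame_equal(out, simple_footprints)

    def test_no_matching_flag_gives_empty(self, simple_footprints):
        assert len(qc_filter(simple_footprints, allowed_flags=(7,))) == 0

    def test_counts_and_order(self, simple_footprints):
        out = qc_filter(simple_footprints, allowed_flags=(0,))
        assert len(out) == 17
        assert list(out.index) == sorted(out.index)  # original order kept

    def test_empty_allowed_set_rejected(self, simple_footprints):
        with pytest.raises(ValueError):
            qc_filter(simple_footprints, allowed_flags=())


class TestCombineBands:
    @pytest.mark.parametrize(
        "b757,b771,expected",
        [(0.0, 0.0, 0.0), (1.0, 0.8, 1.1), (0.9, 0.6, 0.9), (2.4, 1.6, 2.4)],
    )
    def test_known_values(self, b757, b771, expected):
        assert combine_bands(b757, b771) == pytest.approx(expected, abs=1e-12)

    @given(s=st.floats(-5, 5), alpha=st.floats(-3, 3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linearity_and_exact_inversion(self, s, alpha):
        # f(ax, ay) = a f(x, y), and f(S, 2S/3) = S
        assert combine_bands(alpha * s, alpha * 0.5) == pytest.approx(
            alpha * combine_bands(s, 0.5), rel=1e-9, abs=1e-9
        )
        assert combine_bands(s, 2.0 * s / 3.0) == pytest.approx(s, rel=1e-9, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            combine_bands(np.nan, 1.0)


def _fp_table(lats, lons, vals, date=dt.date(2023, 6, 1)):
    n = len(lats)
    return pd.DataFrame(
        {
            "id": [f"f{i:04d}" for i in range(n)],
            "date": pd.Timestamp(date),
            "lat": np.asarray(lats, float),
            "lon": np.asarray(lons, float),
            "sif_daily": np.asarray(vals, float),
        }
    )


class TestKnnSmooth:
    def test_collinear_fixture_mean_of_other_five(self):
        # 6 equally spaced collinear footprints: everyone's 5 nearest
        # neighbors are the other 5
        tbl = _fp_table(np.zeros(6), np.arange(6) * 0.01, [1, 2, 3, 4, 5, 6])
        kept, dropped = knn_smooth(tbl, k=5, max_radius=0.1)
        assert len(dropped) == 0
        # middle footprint (value 3): mean of {1,2,4,5,6} = 3.6
        assert kept.loc[2, "sif_smoothed"] == pytest.approx(3.6)
        # neighbor set {1,2,3,4,5} for the last: mean 3.0
        assert kept.loc[5, "sif_smoothed"] == pytest.approx(3.0)

    def test_constant_values_are_fixed_point(self):
        rng = np.random.default_rng(0)
        tbl = _fp_table(rng.uniform(0, 0.05, 30), rng.uniform(0, 0.05, 30), np.full(30, 0.7))
        kept, _ = knn_smooth(tbl, k=5, max_radius=1.0)
        assert np.allclose(kept["sif_smoothed"], 0.7)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        frames = []
        for day, n in ((1, 90), (2, 110)):
            t = _fp_table(
                rng.uniform(-0.2, 0.2, n), rng.uniform(0, 0.4, n), rng.normal(1, 0.3, n),
                date=dt.date(2023, 6, day),
            )
            t["id"] = [f"d{day}-{i:04d}" for i in range(n)]
            frames.append(t)
        tbl = pd.concat(frames, ignore_index=True)
        kept, dropped = knn_smooth(tbl, k=5, max_radius=0.5)

        # brute force: all-pairs same-date distances, pick 5 smallest by
        # (distance, id), unweighted mean
        expected = {}
        for _, grp in tbl.groupby("date"):
            g = grp.reset_index()
            for i in range(len(g)):
                dists = []
                for j in range(len(g)):
                    if i == j:
                        continue
                    dij = _haversine_deg(
                        g.loc[i, "lat"], g.loc[i, "lon"], g.loc[j, "lat"], g.loc[j, "lon"]
                    )
                    if dij <= 0.5:
                        dists.append((float(dij), g.loc[j, "id"], g.loc[j, "sif_daily"]))
                dists.sort()
                if len(dists) >= 5:
                    expected[g.loc[i, "id"]] = np.mean([v for _, _, v in dists[:5]])
        assert len(kept) == len(expected)
        for _, row in kept.iterrows():
            assert row["sif_smoothed"] == pytest.approx(expected[row["id"]], abs=1e-12)
        assert len(dropped) == len(tbl) - len(expected)

    def test_underpopulated_neighborhoods_dropped_or_renormalized(self):
        tbl = _fp_table([0, 0, 10], [0, 0.01, 10], [1.0, 2.0, 9.0])
        kept, dropped = knn_smooth(tbl, k=5, max_radius=0.1)
        assert len(kept) == 0 and len(dropped) == 3
        kept_r, dropped_r = knn_smooth(tbl, k=5, max_radius=0.1, renormalize_partial=True)
        assert len(kept_r) == 2  # isolated point still has zero neighbors
        assert kept_r.loc[0, "sif_smoothed"] == pytest.approx(2.0)

    def test_invalid_k(self, simple_footprints):
        tbl = simple_footprints.assign(sif_daily=1.0)
        with pytest.raises(ValueError):
            knn_smooth(tbl, k=0)


class TestMatchReflectance:
    geom = GridGeometry(lat_max=1.0, lon_min=0.0, nrows=10, ncols=10, cell=0.05)

    def _raster(self, values=None):
        if values is None:
            rng = np.random.default_rng(1)
            values = rng.uniform(0.1, 0.5, size=(7, 10, 10))
        return Raster(values=values, geom=self.geom)

    def test_single_covered_pixel_equals_that_pixel(self):
        rast = self._raster()
        tbl = _fp_table([0.975], [0.025], [1.0])  # dead center of cell (0, 0)
        kept, dropped = match_reflectance(tbl, {dt.date(2023, 6, 1): rast}, radius=0.02)
        assert len(dropped) == 0
        assert np.allclose(kept[FEATURE_COLUMNS].to_numpy()[0], rast.values[:, 0, 0])

    def test_two_pixel_mean(self):
        vals = np.full((7, 10, 10), 0.2)
        vals[:, 0, 1] = 0.4
        rast = self._raster(vals)
        # halfway between centers of cells (0,0) and (0,1): covers exactly both
        tbl = _fp_table([0.975], [0.05], [1.0])
        kept, _ = match_reflectance(tbl, {dt.date(2023, 6, 1): rast}, radius=0.03)
        assert np.allclose(kept[FEATURE_COLUMNS].to_numpy()[0], 0.3)

    def test_three_by_three_block_mean(self):
        rast = self._raster()
        tbl = _fp_table([0.975 - 0.05 * 4], [0.025 + 0.05 * 4], [1.0])  # center cell (4,4)
        kept, _ = match_reflectance(tbl, {dt.date(2023, 6, 1): rast}, radius=0.08)
        expected = rast.values[:, 3:6, 3:6].reshape(7, -1).mean(axis=1)
        assert np.allclose(kept[FEATURE_COLUMNS].to_numpy()[0], expected, atol=1e-9)

    def test_uncovered_footprint_dropped_and_missing_date_errors(self):
        rast = self._raster()
        tbl = _fp_table([50.0], [100.0], [1.0])  # outside the grid
        kept, dropped = match_reflectance(tbl, {dt.date(2023, 6, 1): rast}, radius=0.02)
        assert len(kept) == 0 and len(dropped) == 1
        with pytest.raises(KeyError, match="2023-06-01"):
            match_reflectance(_fp_table([0.975], [0.025], [1.0]), {}, radius=0.02)


class TestBuildTrainingTable:
    geom = GridGeometry(lat_max=1.0, lon_min=0.0, nrows=4, ncols=4, cell=0.5)

    def _processed(self, lats, lons):
        tbl = _fp_table(lats, lons, np.ones(len(lats)))
        tbl["sif_smoothed"] = 1.0
        for c in FEATURE_COLUMNS:
            tbl[c] = 0.3
        return tbl

    def test_stratum_labels_and_water_exclusion(self):
        ids = np.zeros((4, 4), dtype=int)
        ids[0, 0] = 1  # NF/NH cell
        ids[3, 3] = 13  # GRA/SH cell; everything else unmapped (e.g. water)
        smap = StratumMap(model_ids=ids, geom=self.geom)
        tbl = self._processed([0.75, -0.75, 0.75], [0.25, 1.75, 1.25])
        out = build_training_table(tbl, smap)
        assert len(out) == 2  # third row sits on an unmapped cell
        assert out.iloc[0]["stratum"] == 1
        assert out.iloc[1]["stratum"] == 13
        assert (out["doy"] == 152).all()  # 2023-06-01
        assert (out["year"] == 2023).all()

    def test_row_conservation(self):
        ids = np.ones((4, 4), dtype=int)
        smap = StratumMap(model_ids=ids, geom=self.geom)
        tbl = self._processed([0.75] * 5, [0.25, 0.75, 1.25, 1.75, 0.4])
        out = build_training_table(tbl, smap)
        assert len(out) == len(tbl)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            build_training_table(
                _fp_table([0.0], [0.0], [1.0]),
                StratumMap(model_ids=np.ones((4, 4), int), geom=self.geom),
            )
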