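import datetime as dt

import numpy as np
import pandas as pd
import pytest

from sifmstws import GridGeometry, ModelKey, RegistryConfig
from sifmstws.evaluate import (
    aggregate_airborne,
    correct_airborne,
    cross_biome_report,
    cross_sensor_validate,
    regression_metrics,
)
from sifmstws.models import FittedModel, ModelRegistry, SifGrid
from sifmstws.sampling import UNIVERSAL


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.r2, m.rmse, m.slope, m.n) == (1.0, 0.0, 1.0, 3)

    def test_constant_shift(self):
        obs = np.array([0.5, 1.0, 1.5, 2.0])
        m = regression_metrics(obs + 1.0, obs)
        assert m.rmse == pytest.approx(1.0)
        assert m.slope == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self):
        p = np.array([0.2, 0.9, 1.4, 0.7, 1.1])
        o = np.array([0.3, 1.0, 1.2, 0.5, 1.3])
        m = regression_metrics(p, o)
        # independent closed forms
        ss_res = np.sum((p - o) ** 2)
        ss_tot = np.sum((o - o.mean()) ** 2)
        assert m.r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)
        assert m.rmse == pytest.approx(np.sqrt(ss_res / len(p)), abs=1e-12)
        assert m.slope == pytest.approx(
            np.polyfit(o, p, 1)[0], abs=1e-12
        )

    def test_pearson_variant_diverges_under_scaling(self):
        o = np.array([0.0, 1.0, 2.0, 3.0])
        p = 2.0 * o
        assert regression_metrics(p, o, r2_mode="pearson").r2 == pytest.approx(1.0)
        assert regression_metrics(p, o).r2 < 1.0

    def test_zero_observation_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            regression_metrics([1.0, 2.0], [1.0, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics([1.0], [1.0, 2.0])


def _truth_grid(seed=0, n=10):
    rng = np.random.default_rng(seed)
    geom = GridGeometry(lat_max=0.5, lon_min=0.0, nrows=n, ncols=n, cell=0.05)
    values = rng.uniform(0.3, 1.5, size=(n, n))
    return SifGrid(
        values=values, geom=geom, date=dt.date(2023, 7, 1),
        source_doy=np.full((n, n), 182), source_stratum=np.ones((n, n), int),
    )


def _airborne_from(grid, scale=1.12, per_cell=4, noise=0.0, seed=1):
    rng = np.random.default_rng(seed)
    rows, cols = np.meshgrid(range(grid.geom.nrows), range(grid.geom.ncols), indexing="ij")
    rr = np.repeat(rows.ravel(), per_cell)
    cc = np.repeat(cols.ravel(), per_cell)
    jit = rng.uniform(-0.4, 0.4, (rr.size, 2)) * grid.geom.cell
    return pd.DataFrame(
        {
            "date": pd.Timestamp(grid.date),
            "lat": grid.geom.lat_centers[rr] + jit[:, 0],
            "lon": grid.geom.lon_centers[cc] + jit[:, 1],
            "sif_755": scale * grid.values[rr, cc] + rng.normal(0, noise, rr.size),
        }
    )


class TestCrossSensor:
    def test_noiseless_consistency(self):
        grid = _truth_grid()
        air = _airborne_from(grid)
        m, pairs = cross_sensor_validate({grid.date: grid}, air)
        assert m.r2 == pytest.approx(1.0, abs=1e-12)
        assert m.slope == pytest.approx(1.0, abs=1e-12)
        assert len(pairs) == grid.geom.nrows * grid.geom.ncols  # every covered cell

    def test_omitting_correction_biases_slope_by_the_wavelength_factor(self):
        grid = _truth_grid()
        air = _airborne_from(grid)
        m_corr, _ = cross_sensor_validate({grid.date: grid}, air)
        m_raw, _ = cross_sensor_validate({grid.date: grid}, air, apply_correction=False)
        assert m_corr.slope / m_raw.slope == pytest.approx(1.12, abs=1e-9)

    def test_scaling_invariance(self):
        # validating 1.12x samples with correction == validating unscaled
        # samples without it
        grid = _truth_grid()
        scaled = _airborne_from(grid, scale=1.12)
        unscaled = _airborne_from(grid, scale=1.0)
        m1, _ = cross_sensor_validate({grid.date: grid}, scaled, apply_correction=True)
        m2, _ = cross_sensor_validate({grid.date: grid}, unscaled, apply_correction=False)
        assert m1.r2 == pytest.approx(m2.r2, abs=1e-10)
        assert m1.slope == pytest.approx(m2.slope, abs=1e-10)

    def test_min_samples_filter_and_zero_overlap(self):
        grid = _truth_grid()
        air = _airborne_from(grid, per_cell=2)
        # jitter keeps both samples in their cell: min_samples=2 keeps all,
        # min_samples=3 empties the pairing
        _, pairs = cross_sensor_validate({grid.date: grid}, air, min_samples=2)
        assert (pairs["n_samples"] >= 2).all()
        with pytest.raises(ValueError, match="paired cells"):
            cross_sensor_validate({grid.date: grid}, air, min_samples=3)
        far = air.assign(date=pd.Timestamp(dt.date(2001, 1, 1)))
        with pytest.raises(ValueError, match="overlap"):
            cross_sensor_validate({grid.date: grid}, far)

    def test_correct_airborne_is_exact_inverse(self):
        vals = np.array([0.0, 1.12, 2.24])
        assert np.allclose(correct_airborne(vals), [0.0, 1.0, 2.0])


class _ConstantModel:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


class TestCrossBiomeReport:
    def _registry_and_rows(self):
        reg = ModelRegistry(algorithm="stub", config=RegistryConfig(doys=(100,)))
        for s, val in ((1, 0.5), (2, 1.5)):
            reg.models[ModelKey(100, s)] = FittedModel(
                key=ModelKey(100, s), algorithm="stub", params={}, cv_score=0.0,
                n_train=0, estimator=_ConstantModel(val),
            )
        rng = np.random.default_rng(0)
        rows = pd.DataFrame(rng.uniform(0, 1, (40, 7)), columns=[f"b{i}" for i in range(1, 8)])
        rows["doy"] = 100
        rows["stratum"] = [1, 2] * 20
        rows["sif_smoothed"] = np.where(rows["stratum"] == 1, 0.5, 1.5) + rng.normal(
            0, 0.1, 40
        )
        return reg, rows

    def test_absent_strata_marked_absent_not_zero(self):
        reg, rows = self._registry_and_rows()
        rep = cross_biome_report(reg, rows)
        absent = rep[rep["stratum"] == 7]
        assert absent["absent"].all()
        assert absent["r2"].isna().all()

    def test_n_partition(self):
        reg, rows = self._registry_and_rows()
        rep = cross_biome_report(reg, rows)
        assert rep["n"].sum() == len(rows)

    def test_per_stratum_rmse_reflects_stratum_noise(self):
        reg, rows = self._registry_and_rows()
        # stratum 2 noisier than stratum 1
        rows.loc[rows["stratum"] == 2, "sif_smoothed"] += np.random.default_rng(1).normal(
            0, 0.4, 20
        )
        rep = cross_biome_report(reg, rows).set_index("stratum")
        assert rep.loc[2, "rmse"] > rep.loc[1, "rmse"]
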