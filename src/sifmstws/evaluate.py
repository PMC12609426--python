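"""Evaluation surfaces: scatter metrics, cross-biome stratified reports,
stratified-vs-universal strategy comparison, and cross-sensor validation
against airborne-style SIF.

Conventions
-----------
R^2 is the coefficient of determination 1 - SS_res / SS_tot with the
observations as truth (a ``pearson`` variant is available); the slope is the
ordinary-least-squares slope of predictions (y) on observations (x), the
standard validation-scatter convention. Airborne 755 nm values are divided
by 1.12 before comparison to remove the known cross-wavelength magnitude
offset, then averaged per 0.05 deg cell and date.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EvalMetrics",
    "regression_metrics",
    "correct_airborne",
    "aggregate_airborne",
    "cross_sensor_validate",
    "cross_biome_report",
    "compare_strategies",
    "StrategyComparison",
]

AIRBORNE_SCALE = 1.12


@dataclass(frozen=True)
class EvalMetrics:
    """Validation-scatter summary: R^2, RMSE (SIF units), OLS slope, n."""

    r2: float
    rmse: float
    slope: float
    n: int

    def as_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "slope": self.slope, "n": self.n}


def regression_metrics(predicted, observed, r2_mode: str = "ss") -> EvalMetrics:
    """Metrics of predictions against observations.

    ``r2_mode='ss'`` gives 1 - SS_res/SS_tot; ``'pearson'`` gives the squared
    Pearson correlation (the two diverge when the slope is not 1).
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have equal length")
    if p.size < 2:
        raise ValueError("need at least two pairs")
    if not (np.isfinite(p).all() and np.isfinite(o).all()):
        raise ValueError("non-finite values in metric inputs")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observations have zero variance; R^2 undefined")
    resid = p - o
    rmse = float(np.sqrt(np.mean(resid**2)))
    if r2_mode == "ss":
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    elif r2_mode == "pearson":
        r2 = float(np.corrcoef(p, o)[0, 1] ** 2)
    else:
        raise ValueError("r2_mode must be 'ss' or 'pearson'")
    slope = float(np.sum((o - o.mean()) * (p - p.mean())) / ss_tot)
    return EvalMetrics(r2=r2, rmse=rmse, slope=slope, n=int(p.size))


# ---------------------------------------------------------------------------
# cross-sensor validation


def correct_airborne(values, scale: float = AIRBORNE_SCALE):
    """Scale airborne 755 nm SIF onto the satellite 757 nm magnitude (divide
    by 1.12)."""
    return np.asarray(values, dtype=float) / scale


def aggregate_airborne(samples: pd.DataFrame, geom, value_col: str = "sif_755") -> pd.DataFrame:
    """Unweighted per-cell, per-date mean of airborne samples on the target
    grid. Returns rows (date, row, col, value, n_samples)."""
    row, col = geom.cell_of(samples["lat"].to_numpy(float), samples["lon"].to_numpy(float))
    df = samples.assign(row=row, col=col)
    df = df[(df["row"] >= 0) & (df["col"] >= 0)]
    agg = (
        df.groupby(["date", "row", "col"])[value_col]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "value", "size": "n_samples"})
    )
    return agg


def cross_sensor_validate(
    grids,
    airborne: pd.DataFrame,
    scale: float = AIRBORNE_SCALE,
    min_samples: int = 1,
    apply_correction: bool = True,
) -> tuple[EvalMetrics, pd.DataFrame]:
    """Validate predicted SIF grids against independent airborne samples.

    ``grids`` is a dict date -> SifGrid (or any object with ``values``,
    ``geom``, ``date``). Airborne values are 1/1.12-corrected (unless
    disabled), averaged per cell and date, and paired with the predicted
    cell values; nodata cells and cells with fewer than ``min_samples``
    airborne points are excluded.
    """
    if not isinstance(grids, dict):
        grids = {g.date: g for g in grids}
    air = airborne.copy()
    air["value"] = correct_airborne(air["sif_755"], scale) if apply_correction else air["sif_755"]

    pairs = []
    for date, grid in grids.items():
        sub = air[pd.to_datetime(air["date"]).dt.date == pd.Timestamp(date).date()]
        if sub.empty:
            continue
        agg = aggregate_airborne(sub, grid.geom, value_col="value")
        agg = agg[agg["n_samples"] >= min_samples]
        pred = grid.values[agg["row"].to_numpy(int), agg["col"].to_numpy(int)]
        ok = np.isfinite(pred)
        pairs.append(
            pd.DataFrame(
                {
                    "date": pd.Timestamp(date),
                    "row": agg["row"].to_numpy(int)[ok],
                    "col": agg["col"].to_numpy(int)[ok],
                    "observed": agg["value"].to_numpy(float)[ok],
                    "predicted": pred[ok],
                    "n_samples": agg["n_samples"].to_numpy(int)[ok],
                }
            )
        )
    if not pairs:
        raise ValueError("no spatial/temporal overlap between grids and airborne samples")
    paired = pd.concat(pairs, ignore_index=True)
    if len(paired) < 2:
        raise ValueError("fewer than two paired cells after aggregation/filtering")
    metrics = regression_metrics(paired["predicted"], paired["observed"])
    return metrics, paired


# ---------------------------------------------------------------------------
# cross-biome stratified report


def cross_biome_report(registries, validation: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum metrics for each algorithm's registry.

    ``registries`` maps algorithm tag -> ModelRegistry (a single registry is
    accepted too). Strata absent from the validation rows, or whose models
    cannot be resolved, are reported with ``absent=True`` and NaN metrics
    rather than zeros.
    """
    from .models import predict_rows
    from .stratify import ALL_STRATA, STRATUM_NAMES

    if not isinstance(registries, dict):
        registries = {getattr(registries, "algorithm", "model"): registries}

    rows = []
    for tag, registry in registries.items():
        for s in ALL_STRATA:
            sub = validation[validation["stratum"] == s]
            rec = {"algorithm": tag, "stratum": s, "name": STRATUM_NAMES[s], "n": len(sub)}
            if len(sub) < 2:
                rec.update(r2=np.nan, rmse=np.nan, slope=np.nan, absent=True)
            else:
                try:
                    pred = predict_rows(registry, sub)
                    m = regression_metrics(pred, sub["sif_smoothed"].to_numpy(float))
                    rec.update(r2=m.r2, rmse=m.rmse, slope=m.slope, absent=False)
                except (KeyError, ValueError):
                    rec.update(r2=np.nan, rmse=np.nan, slope=np.nan, absent=True)
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stratified vs universal strategy comparison


def _table_hash(table: pd.DataFrame) -> str:
    cols = sorted(c for c in table.columns if c not in ("n_neighbors",))
    raw = pd.util.hash_pandas_object(table[cols].reset_index(drop=True), index=False).to_numpy()
    return hashlib.sha256(raw.tobytes()).hexdigest()


@dataclass
class StrategyComparison:
    """Paired report: the stratified moving-window fleet vs one universal
    model evaluated on a byte-identical holdout."""

    mstws: EvalMetrics
    universal: EvalMetrics
    holdout_hash: str
    n_holdout: int

    @property
    def r2_gain(self) -> float:
        return self.mstws.r2 - self.universal.r2

    @property
    def rmse_gain(self) -> float:
        return self.universal.rmse - self.mstws.rmse

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"strategy": "mstws", **self.mstws.as_dict()},
            {"strategy": "universal", **self.universal.as_dict()},
            {
                "strategy": "difference",
                "r2": self.r2_gain,
                "rmse": -self.rmse_gain,
                "slope": self.mstws.slope - self.universal.slope,
                "n": self.n_holdout,
            },
        ]
        return pd.DataFrame(rows)


def scatter_plot(paired: pd.DataFrame, metrics: EvalMetrics, path, title: str = "") -> None:
    """Optional validation scatter (predicted vs observed) with the metric
    annotation; requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(paired["observed"], paired["predicted"], s=4, alpha=0.4)
    lim = [
        min(paired["observed"].min(), paired["predicted"].min()),
        max(paired["observed"].max(), paired["predicted"].max()),
    ]
    ax.plot(lim, lim, "k--", lw=0.8)
    ax.set_xlabel("observed SIF (W m$^{-2}$ $\\mu$m$^{-1}$ sr$^{-1}$)")
    ax.set_ylabel("predicted SIF")
    ax.set_title(title or f"R$^2$={metrics.r2:.3f}  RMSE={metrics.rmse:.3f}  "
                          f"slope={metrics.slope:.3f}  n={metrics.n}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def compare_strategies(
    table: pd.DataFrame, config, seed: int = 0, holdout_ratio: float = 0.7
) -> StrategyComparison:
    """Train the stratified moving-window fleet and a universal model on the
    same rows and evaluate both on the same held-out 30%.

    ``config`` is a ``RegistryConfig``; its ``doys`` (required here) bound
    the fleet, and holdout rows are restricted to those DOYs so every
    holdout row has an in-fleet model. Both strategies see exactly the fit
    partition (the fleet's per-key internal split is disabled) and use the
    same algorithm, hyperparameter search, folds and seed. The universal
    model pools all fit rows of all dates and strata.
    """
    import dataclasses

    from .models import predict_rows, train_model_cv, train_registry
    from .sampling import doy_window, split_train_val

    if not config.doys:
        raise ValueError("config.doys must list the evaluated DOYs")
    fit, holdout = split_train_val(table, ratio=holdout_ratio, seed=seed)
    # evaluate on the DOY windows the fleet covers; rows between trained
    # DOYs resolve through the nearest-date fallback
    wanted: set[int] = set()
    for d in config.doys:
        wanted.update(doy_window(d))
    holdout = holdout[holdout["doy"].isin(wanted)]
    if len(holdout) < 2:
        raise ValueError("holdout too small on the requested DOY windows")

    registry = train_registry(fit, config=dataclasses.replace(config, split_ratio=None))
    pred_fleet = predict_rows(registry, holdout)

    uni = train_model_cv(
        fit,
        algorithm=registry.algorithm,
        param_grid=config.param_grid,
        folds=config.folds,
        seed=seed,
    )
    pred_uni = uni.predict_table(holdout)

    obs = holdout["sif_smoothed"].to_numpy(float)
    return StrategyComparison(
        mstws=regression_metrics(pred_fleet, obs),
        universal=regression_metrics(pred_uni, obs),
        holdout_hash=_table_hash(holdout),
        n_holdout=len(holdout),
    )
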