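"""Delimited-text formats for footprint tables and processed tables.

Footprint tables are CSV with the column schema
``id, date (ISO-8601), lat, lon, sif_757, sif_771, qc_flag``; processed
tables append ``sif_daily, sif_smoothed, b1..b7, doy, stratum``. Reading is
validating: malformed rows are rejected with their line number and a
reason rather than poisoning the table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FOOTPRINT_COLUMNS",
    "read_footprint_table",
    "write_footprint_table",
]

FOOTPRINT_COLUMNS = ["id", "date", "lat", "lon", "sif_757", "sif_771", "qc_flag"]


def write_footprint_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = table.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    cols = FOOTPRINT_COLUMNS + [c for c in out.columns if c not in FOOTPRINT_COLUMNS]
    out[cols].to_csv(path, index=False, float_format="%.10g")
    return path


def read_footprint_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a footprint table.

    Returns ``(table, rejected)``; ``rejected`` carries ``line`` (1-based
    file line number) and ``reason`` columns. A missing required column
    raises ``ValueError`` naming it; a header-only file gives an empty,
    correctly typed table.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in FOOTPRINT_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"footprint table {path} is missing required columns: {missing}")

    n = len(raw)
    reasons = np.full(n, "", dtype=object)

    def flag(bad: np.ndarray, reason: str) -> None:
        fresh = bad & (reasons == "")
        reasons[fresh] = reason

    date = pd.to_datetime(raw["date"], format="%Y-%m-%d", errors="coerce")
    flag(date.isna().to_numpy(), "unparseable date")
    num = {}
    for col in ("lat", "lon", "sif_757", "sif_771"):
        v = pd.to_numeric(raw[col], errors="coerce")
        flag((v.isna() | ~np.isfinite(v)).to_numpy(), f"non-numeric {col}")
        num[col] = v
    qc = pd.to_numeric(raw["qc_flag"], errors="coerce")
    flag(qc.isna().to_numpy() | (qc % 1 != 0).to_numpy(), "non-integer qc_flag")
    flag(((num["lat"] < -90) | (num["lat"] > 90)).to_numpy(), "lat outside [-90, 90]")
    flag(((num["lon"] < -180) | (num["lon"] >= 180)).to_numpy(), "lon outside [-180, 180)")

    bad = reasons != ""
    rejected = raw[bad].copy()
    rejected["line"] = np.nonzero(bad)[0] + 2  # header is line 1
    rejected["reason"] = reasons[bad]

    good = ~bad
    table = pd.DataFrame(
        {
            "id": raw.loc[good, "id"].to_numpy(),
            "date": date[good].to_numpy(),
            "lat": num["lat"][good].to_numpy(float),
            "lon": num["lon"][good].to_numpy(float),
            "sif_757": num["sif_757"][good].to_numpy(float),
            "sif_771": num["sif_771"][good].to_numpy(float),
            "qc_flag": qc[good].to_numpy(int) if good.any() else np.array([], dtype=int),
        }
    )
    return table, rejected
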