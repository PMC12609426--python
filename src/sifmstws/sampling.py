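"""Moving spatial-temporal window sampling (MSTWS).

One regression model is trained per (DOY, sub-biome stratum). The sample
pool for a target DOY is a 16-day window — the target day, the 7 days
before and the 8 days after, wrapping across the year boundary — pooled
over all available years, then restricted to the stratum. Pools are capped
at 5000 rows (uniform random subset), pools at or below the minimum sample
size (default 1000) are skipped, and each used pool is split 70:30 into
training and validation partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UNIVERSAL",
    "ModelKey",
    "doy_window",
    "collect_window_samples",
    "apply_sampling_rules",
    "split_train_val",
    "SamplerAudit",
]

UNIVERSAL = "universal"


@dataclass(frozen=True, order=True)
class ModelKey:
    """Identity of one model: a DOY plus a stratum ID or the universal marker."""

    doy: int
    stratum: int | str  # 1..19 or UNIVERSAL

    def __post_init__(self) -> None:
        if not 1 <= self.doy <= 365:
            raise ValueError(f"doy must be in [1, 365], got {self.doy}")
        if self.stratum != UNIVERSAL and self.stratum not in range(1, 20):
            raise ValueError(f"stratum must be 1..19 or '{UNIVERSAL}', got {self.stratum}")

    def __str__(self) -> str:
        return f"doy{self.doy:03d}/{self.stratum}"


def doy_window(doy: int) -> list[int]:
    """The 16-day window for a target DOY: {doy-7, ..., doy, ..., doy+8},
    wrapped on the 365-day circle. E.g. DOY 244 (Sep 1) -> 237..252
    (Aug 25 - Sep 9)."""
    if not 1 <= doy <= 365:
        raise ValueError(f"doy must be in [1, 365], got {doy}")
    return [((doy - 1 + off) % 365) + 1 for off in range(-7, 9)]


def collect_window_samples(table: pd.DataFrame, key: ModelKey) -> pd.DataFrame:
    """Rows of ``table`` inside the key's DOY window, pooled over all years,
    restricted to the key's stratum (all vegetated rows if universal)."""
    window = set(doy_window(key.doy))
    sel = table["doy"].isin(window)
    if key.stratum != UNIVERSAL:
        sel &= table["stratum"] == key.stratum
    return table[sel].copy()


def apply_sampling_rules(
    table: pd.DataFrame, cap: int = 5000, min_n: int = 1000, seed: int = 0
) -> pd.DataFrame | None:
    """Cap and minimum-sample rules for one pool.

    Returns ``None`` (a skip marker) if the pool size is at or below
    ``min_n``; the full pool if within the cap; otherwise a uniform random
    subset of exactly ``cap`` rows (seeded, without replacement).
    """
    if not cap > min_n > 0:
        raise ValueError("need cap > min_n > 0")
    n = len(table)
    if n <= min_n:
        return None
    if n <= cap:
        return table
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=cap, replace=False)
    return table.iloc[np.sort(idx)]


def split_train_val(
    table: pd.DataFrame, ratio: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded disjoint, exhaustive split; train gets round(ratio * n) rows."""
    n = len(table)
    if n < 2:
        raise ValueError("need at least two rows to split")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = round(ratio * n)
    return table.iloc[np.sort(perm[:n_train])], table.iloc[np.sort(perm[n_train:])]


class SamplerAudit:
    """Per-key sampling bookkeeping (n found, n used, skipped flag)."""

    def __init__(self) -> None:
        self.records: list[dict] = []

    def add(self, key: ModelKey, n_found: int, n_used: int, skipped: bool) -> None:
        self.records.append(
            {
                "doy": key.doy,
                "stratum": key.stratum,
                "n_found": n_found,
                "n_used": n_used,
                "skipped": skipped,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=["doy", "stratum", "n_found", "n_used", "skipped"]
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
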