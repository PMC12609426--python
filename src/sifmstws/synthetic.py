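"""Synthetic world generator.

Builds a self-contained miniature earth with the statistical structure the
moving-window stratified reconstruction assumes:

* a biome raster of IGBP classes laid out in longitudinal strips crossed
  with a hemisphere split, so that all 19 sub-biome strata are realizable;
* 7-band surface reflectance with stratum-specific seasonal cycles (phase
  peaks in mid-July for NH strata, mid-January for SH strata) plus a static
  per-cell texture and optional observation noise;
* a latent SIF truth that is *linear in a vegetation contrast of the bands*
  with coefficients that differ by sub-biome stratum and by season — the
  heterogeneity that makes stratified modeling strictly better than a single
  universal regressor, which is the property the package is built to test;
* striped two-band footprint sampling emulating a sparse polar orbiter: on
  each date only a longitudinal swath is observed, the swath sweeping the
  grid once per revisit period, with independent Gaussian noise on the
  757 nm and 771 nm bands (771 nm carries 2/3 of the signal, so the standard
  cross-band combination is an exact inverse when noise is zero);
* dense airborne-style validation samples at a 1.12x magnitude scale,
  mimicking a 755 nm instrument flown under the satellite.

All generators are pure functions of (config, seed); per-date randomness is
derived by hashing the date ordinal into the seed stream.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grids import GridGeometry, Raster
from .stratify import (
    ALL_STRATA,
    IGBP,
    REGION_CODES,
    BiomeGrid,
    StratumMap,
    assign_model_ids,
)

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "generate_world",
    "simulate_reflectance",
    "simulate_true_sif",
    "sample_footprints",
    "simulate_airborne",
    "band_contrast",
    "doy_365",
    "season_of_doy",
    "SEASON_EDGES",
]

# fixed season boundaries (DOY): Jan1, Apr2, Jul2, Oct1
SEASON_EDGES = (1, 92, 183, 274)

# 7-band mean reflectance and seasonal amplitude; band 2 is the NIR-like
# band and carries the strongest seasonal and vegetation signal.
_BAND_MEAN = np.array([0.06, 0.30, 0.04, 0.08, 0.26, 0.20, 0.12])
_BAND_SEAS = np.array([0.02, 0.15, 0.01, 0.02, 0.08, 0.04, 0.03])
# loading of the static per-cell texture onto each band
_BAND_TEXTURE = np.array([-0.2, 0.8, 0.0, 0.0, 0.4, 0.1, 0.0])

_NH_STRATA = frozenset({1, 6, 8, 10, 12, 14, 16, 18})
_SH_STRATA = frozenset({2, 7, 9, 11, 13, 15, 17, 19})
_EBF_STRATA = frozenset({3, 4, 5})


def doy_365(date: dt.date) -> int:
    """Day of year on a fixed 365-day calendar.

    February 29 maps to DOY 60; later days of a leap year shift back by one
    so that a calendar date keeps the same DOY in every year.
    """
    yday = date.timetuple().tm_yday
    if date.year % 4 == 0 and (date.year % 100 != 0 or date.year % 400 == 0):
        if yday >= 61:
            return yday - 1
        return min(yday, 60)
    return yday


def season_of_doy(doy: int) -> int:
    """Season index 0-3 for a DOY on the 365-day calendar."""
    if not 1 <= doy <= 365:
        raise ValueError(f"doy must be in [1, 365], got {doy}")
    s = 0
    for i, edge in enumerate(SEASON_EDGES):
        if doy >= edge:
            s = i
    return s


@dataclass(frozen=True)
class WorldConfig:
    """Configuration of the synthetic world.

    Defaults describe a 2 deg x 4 deg equator-straddling domain at 0.05 deg
    (40 x 80 cells) observed for two years — large enough to host all 19
    sub-biome strata while keeping every experiment desk-scale.
    """

    lat_min: float = -1.0
    lat_max: float = 1.0
    lon_min: float = 0.0
    lon_max: float = 4.0
    cell: float = 0.05
    years: tuple[int, ...] = (2022, 2023)
    biome_seed: int = 0

    # latent mapping: true SIF = a0(s, season) + a1(s, season) * (NIR - red)
    a0_range: tuple[float, float] = (0.3, 0.8)
    a1_range: tuple[float, float] = (0.8, 2.0)
    season_amp: float = 0.35  # half-width of the per-season multiplier spread
    uniform_mapping: bool = False  # True -> identical coefficients everywhere

    # observation model
    sigma_band: float | dict[int, float] = 0.1  # SIF band noise, scalar or per-stratum
    sigma_refl: float = 0.005
    texture_sd: float = 0.05
    qc_fail_frac: float = 0.05

    # orbit emulation
    swath_width: int = 12  # cells
    revisit_days: int = 8
    footprints_per_cell: int = 6
    jitter_frac: float = 0.15  # of a cell, keeps same-cell footprints mutually nearest

    # airborne emulation
    airborne_scale: float = 1.12
    airborne_noise: float = 0.02
    airborne_per_cell: int = 16

    def __post_init__(self) -> None:
        GridGeometry.from_bounds(self.lat_min, self.lat_max, self.lon_min, self.lon_max, self.cell)
        sigmas = self.sigma_band.values() if isinstance(self.sigma_band, dict) else [self.sigma_band]
        if any(s < 0 for s in sigmas) or self.sigma_refl < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.swath_width < 1:
            raise ValueError("swath width must be at least one cell")
        if self.revisit_days < 1:
            raise ValueError("revisit period must be at least one day")
        if not 0 <= self.qc_fail_frac <= 1:
            raise ValueError("qc_fail_frac must be a fraction")

    @property
    def geom(self) -> GridGeometry:
        return GridGeometry.from_bounds(
            self.lat_min, self.lat_max, self.lon_min, self.lon_max, self.cell
        )

    def band_sigma(self, stratum: int) -> float:
        if isinstance(self.sigma_band, dict):
            return float(self.sigma_band.get(stratum, 0.0))
        return float(self.sigma_band)

    def date_range(self) -> list[dt.date]:
        days = []
        for y in self.years:
            d = dt.date(y, 1, 1)
            while d.year == y:
                days.append(d)
                d += dt.timedelta(days=1)
        return days


# ---------------------------------------------------------------------------
# world generation


def _strip_layout(geom: GridGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic biome/region layout: 12 longitudinal strips x hemisphere."""
    nr, nc = geom.nrows, geom.ncols
    strip = (np.arange(nc) * 12) // nc  # strip id per column
    nh = geom.lat_centers >= 0.0  # per row

    classes = np.zeros((nr, nc), dtype=int)
    region = np.zeros((nr, nc), dtype=int)

    for j in range(nc):
        s = strip[j]
        for i in range(nr):
            north = nh[i]
            if s == 0:
                classes[i, j] = IGBP.WATER
            elif s == 1:
                classes[i, j] = IGBP.ENF if north else IGBP.DNF
            elif s == 2:
                classes[i, j] = IGBP.DBF
            elif s == 3:
                classes[i, j] = IGBP.CSH if north else IGBP.OSH
            elif s == 4:
                classes[i, j] = IGBP.WSA if north else IGBP.SAV
            elif s == 5:
                classes[i, j] = IGBP.GRA
            elif s == 6:
                classes[i, j] = IGBP.EBF
                band = (i * 3) // nr  # latitudinal thirds: Amazon/Congo/SE Asia
                region[i, j] = (
                    REGION_CODES["amazon"], REGION_CODES["congo"], REGION_CODES["seasia"]
                )[band]
            elif s in (7, 8, 9):
                classes[i, j] = IGBP.CRO
                region[i, j] = {
                    7: (REGION_CODES["north_america"], REGION_CODES["south_america"]),
                    8: (REGION_CODES["europe"], REGION_CODES["africa"]),
                    9: (REGION_CODES["asia"], REGION_CODES["australia"]),
                }[s][0 if north else 1]
            elif s == 10:
                classes[i, j] = IGBP.BAR
            else:
                classes[i, j] = IGBP.WET
    return classes, region


def _expected_strata(geom: GridGeometry) -> set[int]:
    has_nh = bool((geom.lat_centers >= 0).any())
    has_sh = bool((geom.lat_centers < 0).any())
    expected = set(ALL_STRATA)
    if not has_nh:
        expected -= _NH_STRATA
    if not has_sh:
        expected -= _SH_STRATA
    return expected


@dataclass
class SyntheticWorld:
    """Generated world: biome layout plus the latent-truth skeleton.

    The generating coefficients are retrievable (``coefficients``) so tests
    can do exact parameter-recovery checks against fitted models.
    """

    config: WorldConfig
    seed: int
    biome: BiomeGrid
    region: np.ndarray
    strata: StratumMap
    texture: np.ndarray  # static per-cell field, N(0, texture_sd)
    a0: np.ndarray  # (20, 4): a0[stratum, season]; row 0 unused
    a1: np.ndarray
    phase: np.ndarray  # (20,) seasonal phase peak DOY per stratum

    @property
    def geom(self) -> GridGeometry:
        return self.biome.geom

    def coefficients(self, stratum: int, doy: int) -> tuple[float, float]:
        """Generating (a0, a1) for a stratum at a DOY — the recovery oracle."""
        s = season_of_doy(doy)
        return float(self.a0[stratum, s]), float(self.a1[stratum, s])

    def check_date(self, date: dt.date) -> None:
        if date.year not in self.config.years:
            raise ValueError(f"date {date} outside simulated years {self.config.years}")


def generate_world(config: WorldConfig, seed: int = 0) -> SyntheticWorld:
    """Build the deterministic world skeleton for (config, seed)."""
    geom = config.geom
    classes, region = _strip_layout(geom)

    rng = np.random.default_rng([int(config.biome_seed), int(seed), 1])
    biome = BiomeGrid(classes=classes, geom=geom)
    strata = assign_model_ids(biome, regions=region)

    # speckle a little open water into large strata (keeps all strata alive)
    ids = strata.model_ids
    counts = np.bincount(ids.ravel(), minlength=20)
    speckle = (rng.random(ids.shape) < 0.02) & (counts[ids] > 8)
    classes = np.where(speckle, IGBP.WATER, classes)
    biome = BiomeGrid(classes=classes, geom=geom)
    strata = assign_model_ids(biome, regions=region)

    realized = set(np.unique(strata.model_ids)) - {0}
    missing = _expected_strata(geom) - realized
    if missing:
        raise ValueError(
            f"extent too small to host all sub-biome strata; missing model IDs {sorted(missing)}"
        )

    # Static texture field, a function of latitude row only. Sharing the
    # texture pattern across the longitudinal biome strips gives different
    # strata overlapping reflectance distributions, so the stratum signal is
    # contextual (location), not spectral — the regime stratified modeling
    # is designed for.
    i = np.arange(geom.nrows)
    row_pattern = np.sin(2 * np.pi * 1.1 * i / geom.nrows + 0.7) + 0.6 * np.sin(
        2 * np.pi * 3.3 * i / geom.nrows
    )
    texture = np.repeat(
        (config.texture_sd * row_pattern)[:, None], geom.ncols, axis=1
    )

    a0 = np.zeros((20, 4))
    a1 = np.zeros((20, 4))
    phase = np.zeros(20)
    crng = np.random.default_rng([int(config.biome_seed), int(seed), 2])
    base0 = crng.uniform(*config.a0_range, size=20)
    base1 = crng.uniform(*config.a1_range, size=20)
    mult0 = crng.uniform(1 - config.season_amp, 1 + config.season_amp, size=(20, 4))
    mult1 = crng.uniform(1 - config.season_amp, 1 + config.season_amp, size=(20, 4))
    if config.uniform_mapping:
        base0[:] = base0[1]
        base1[:] = base1[1]
        mult0[:] = mult0[1]
        mult1[:] = mult1[1]
    for s in ALL_STRATA:
        a0[s] = base0[s] * mult0[s]
        a1[s] = base1[s] * mult1[s]
        phase[s] = 196.0 if s in _NH_STRATA else (15.0 if s in _SH_STRATA else 280.0)

    # coverage invariant: over one revisit period the swath union must span
    # every column of the grid
    max_gap = math.ceil(geom.ncols / config.revisit_days)
    if config.swath_width < max_gap:
        raise ValueError(
            f"swath width {config.swath_width} too narrow for full coverage within "
            f"{config.revisit_days} days over {geom.ncols} columns (needs >= {max_gap})"
        )

    return SyntheticWorld(
        config=config, seed=int(seed), biome=biome, region=region, strata=strata,
        texture=texture, a0=a0, a1=a1, phase=phase,
    )


# ---------------------------------------------------------------------------
# forward simulation


def simulate_reflectance(world: SyntheticWorld, date: dt.date, noiseless: bool = False) -> Raster:
    """7-band reflectance raster for a date; values clipped to [0, 1].

    Each band follows a stratum-phased annual cosine around its mean, plus
    the static texture field and, unless ``noiseless``, i.i.d. Gaussian
    observation noise of sd ``sigma_refl`` drawn reproducibly per date.
    """
    world.check_date(date)
    cfg = world.config
    doy = doy_365(date)
    cphase = world.phase[world.strata.model_ids]  # (nr, nc), 0 for unmapped
    seas = np.cos(2 * np.pi * (doy - cphase) / 365.0)

    bands = (
        _BAND_MEAN[:, None, None]
        + _BAND_SEAS[:, None, None] * seas[None]
        + _BAND_TEXTURE[:, None, None] * world.texture[None]
    )
    if not noiseless and cfg.sigma_refl > 0:
        rng = np.random.default_rng([world.seed, date.toordinal(), 3])
        bands = bands + rng.normal(0.0, cfg.sigma_refl, size=bands.shape)
    return Raster(values=np.clip(bands, 0.0, 1.0), geom=world.geom)


def band_contrast(bands: np.ndarray) -> np.ndarray:
    """Scalar vegetation contrast g = NIR - red (band 2 minus band 1).

    The latent truth is linear in this contrast, per stratum and season.
    """
    bands = np.asarray(bands)
    return bands[..., 1] - bands[..., 0] if bands.ndim <= 2 else bands[1] - bands[0]


def simulate_true_sif(world: SyntheticWorld, reflectance: Raster, date: dt.date) -> Raster:
    """Latent true SIF: a0(s, season) + a1(s, season) * g(bands), clamped at 0.

    Non-vegetated / unmapped cells carry zero SIF.
    """
    world.check_date(date)
    if reflectance.geom != world.geom:
        raise ValueError("reflectance raster is not aligned to the world grid")
    doy = doy_365(date)
    s = season_of_doy(doy)
    ids = world.strata.model_ids
    a0 = world.a0[ids, s]
    a1 = world.a1[ids, s]
    g = band_contrast(reflectance.values)
    sif = np.where(ids > 0, np.maximum(a0 + a1 * g, 0.0), 0.0)
    return Raster(values=sif, geom=world.geom)


def true_sif_raster(world: SyntheticWorld, date: dt.date) -> Raster:
    """Noise-free latent truth for a date (noiseless reflectance path)."""
    return simulate_true_sif(world, simulate_reflectance(world, date, noiseless=True), date)


def swath_columns(world: SyntheticWorld, date: dt.date) -> np.ndarray:
    """Grid columns observed on a date: a wrapping swath that sweeps the
    full longitude range once per revisit period."""
    cfg = world.config
    k = date.toordinal() % cfg.revisit_days
    start = (k * world.geom.ncols) // cfg.revisit_days
    return (start + np.arange(cfg.swath_width)) % world.geom.ncols


def sample_footprints(world: SyntheticWorld, date: dt.date, seed: int) -> pd.DataFrame:
    """Simulate one day of two-band footprint soundings inside the swath.

    Each swath cell yields ``footprints_per_cell`` jittered footprints with
    sif_757 = S + e1 and sif_771 = (2/3) S + e2, e1, e2 ~ N(0, sigma_band)
    independent, so the standard cross-band combination
    0.5 (sif_757 + 1.5 sif_771) recovers S in expectation. A configured
    fraction receives a failing QC flag (1; 0 = good).
    """
    world.check_date(date)
    cfg = world.config
    geom = world.geom
    truth = true_sif_raster(world, date).values
    cols = swath_columns(world, date)

    rows = np.repeat(np.arange(geom.nrows), len(cols))
    ccols = np.tile(cols, geom.nrows)
    rows = np.repeat(rows, cfg.footprints_per_cell)
    ccols = np.repeat(ccols, cfg.footprints_per_cell)
    n = rows.size

    rng = np.random.default_rng([world.seed, int(seed), date.toordinal(), 4])
    jit = rng.uniform(-cfg.jitter_frac, cfg.jitter_frac, size=(n, 2)) * geom.cell
    lat = geom.lat_centers[rows] + jit[:, 0]
    lon = geom.lon_centers[ccols] + jit[:, 1]

    s = truth[rows, ccols]
    strat = world.strata.model_ids[rows, ccols]
    sigma = np.array([cfg.band_sigma(t) for t in range(20)])[strat]
    e = rng.normal(0.0, 1.0, size=(n, 2)) * sigma[:, None]
    sif_757 = s + e[:, 0]
    sif_771 = (2.0 / 3.0) * s + e[:, 1]
    qc = (rng.random(n) < cfg.qc_fail_frac).astype(int)

    return pd.DataFrame(
        {
            "id": [f"{date.isoformat()}-{i:06d}" for i in range(n)],
            "date": pd.Timestamp(date),
            "lat": lat,
            "lon": lon,
            "sif_757": sif_757,
            "sif_771": sif_771,
            "qc_flag": qc,
        }
    )


def simulate_airborne(
    world: SyntheticWorld,
    region: tuple[float, float, float, float],
    date: dt.date,
    seed: int,
) -> pd.DataFrame:
    """Dense fine-resolution 755 nm samples over ``region``.

    ``region`` is (lat_min, lat_max, lon_min, lon_max) and must lie inside
    the world extent. Values are ``airborne_scale`` (default 1.12) times the
    local truth plus small Gaussian noise — emulating an airborne
    spectrometer whose retrieval wavelength runs ~12% hot relative to the
    satellite's 757 nm product.
    """
    world.check_date(date)
    cfg = world.config
    geom = world.geom
    lat_min, lat_max, lon_min, lon_max = region
    if lat_min < geom.lat_min or lat_max > geom.lat_max or lon_min < geom.lon_min or lon_max > geom.lon_max:
        raise ValueError(f"airborne region {region} outside world extent")

    truth = true_sif_raster(world, date).values
    in_lat = (geom.lat_centers >= lat_min) & (geom.lat_centers <= lat_max)
    in_lon = (geom.lon_centers >= lon_min) & (geom.lon_centers <= lon_max)
    rows = np.where(in_lat)[0]
    cols = np.where(in_lon)[0]
    if rows.size == 0 or cols.size == 0:
        raise ValueError("airborne region covers no grid cell")

    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    rr = np.repeat(rr.ravel(), cfg.airborne_per_cell)
    cc = np.repeat(cc.ravel(), cfg.airborne_per_cell)
    n = rr.size
    rng = np.random.default_rng([world.seed, int(seed), date.toordinal(), 5])
    jit = rng.uniform(-0.5, 0.5, size=(n, 2)) * geom.cell
    lat = geom.lat_centers[rr] + jit[:, 0]
    lon = geom.lon_centers[cc] + jit[:, 1]
    vals = cfg.airborne_scale * truth[rr, cc]
    if cfg.airborne_noise > 0:
        vals = vals + rng.normal(0.0, cfg.airborne_noise, size=n)
    return pd.DataFrame(
        {"date": pd.Timestamp(date), "lat": lat, "lon": lon, "sif_755": vals}
    )
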