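"""Sub-biome stratification of IGBP land cover.

The model fleet is stratified into 19 sub-biome domains: seven biome groups
derived from IGBP classes, split geographically —

=====  ==================  ==========================  =========
group  IGBP classes        split                       model IDs
=====  ==================  ==========================  =========
NF     ENF, DNF            hemisphere (NH / SH)        1, 2
EBF    EBF                 Amazon / Congo / SE Asia    3, 4, 5
DBF    DBF, MF             hemisphere                  6, 7
SHR    closed/open shrub   hemisphere                  8, 9
SAV    woody sav., sav.    hemisphere                  10, 11
GRA    grassland           hemisphere                  12, 13
CRO    cropland, mosaic    six continents              14 .. 19
=====  ==================  ==========================  =========

Mixed forest is folded into the DBF group (closest structural analogue);
wetlands carry no model ID. The equator boundary is closed on the north:
lat >= 0 is NH. Region membership comes either from a synthetic region-code
raster or from user polygons (GeoJSON / shapely).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import GridGeometry, Raster

__all__ = [
    "IGBP",
    "REGION_CODES",
    "BiomeGrid",
    "StratumMap",
    "vegetated_mask",
    "assign_model_ids",
    "STRATUM_NAMES",
]


class IGBP:
    """IGBP class codes (MCD12-style, 0 = water)."""

    WATER = 0
    ENF = 1
    EBF = 2
    DNF = 3
    DBF = 4
    MF = 5
    CSH = 6
    OSH = 7
    WSA = 8
    SAV = 9
    GRA = 10
    WET = 11
    CRO = 12
    URB = 13
    MOS = 14
    SNO = 15
    BAR = 16

    ALL = frozenset(range(17))


# Codes excluded from the vegetated mask: water, urban, snow/ice, barren.
_NONVEGETATED = frozenset({IGBP.WATER, IGBP.URB, IGBP.SNO, IGBP.BAR})

# biome group per IGBP class (classes absent here carry no model ID)
_CLASS_GROUP = {
    IGBP.ENF: "NF",
    IGBP.DNF: "NF",
    IGBP.EBF: "EBF",
    IGBP.DBF: "DBF",
    IGBP.MF: "DBF",
    IGBP.CSH: "SHR",
    IGBP.OSH: "SHR",
    IGBP.WSA: "SAV",
    IGBP.SAV: "SAV",
    IGBP.GRA: "GRA",
    IGBP.CRO: "CRO",
    IGBP.MOS: "CRO",
}

# region-code raster values (synthetic worlds label regions directly)
REGION_CODES = {
    "none": 0,
    "amazon": 1,
    "congo": 2,
    "seasia": 3,
    "north_america": 4,
    "south_america": 5,
    "europe": 6,
    "africa": 7,
    "asia": 8,
    "australia": 9,
}

_EBF_IDS = {"amazon": 3, "congo": 4, "seasia": 5}
_CRO_IDS = {
    "north_america": 14,
    "south_america": 15,
    "europe": 16,
    "africa": 17,
    "asia": 18,
    "australia": 19,
}
_HEMI_IDS = {"NF": (1, 2), "DBF": (6, 7), "SHR": (8, 9), "SAV": (10, 11), "GRA": (12, 13)}

STRATUM_NAMES = {
    1: "NF/NH", 2: "NF/SH",
    3: "EBF/Amazon", 4: "EBF/Congo", 5: "EBF/SE-Asia",
    6: "DBF/NH", 7: "DBF/SH",
    8: "SHR/NH", 9: "SHR/SH",
    10: "SAV/NH", 11: "SAV/SH",
    12: "GRA/NH", 13: "GRA/SH",
    14: "CRO/N-America", 15: "CRO/S-America", 16: "CRO/Europe",
    17: "CRO/Africa", 18: "CRO/Asia", 19: "CRO/Australia",
}

ALL_STRATA = tuple(range(1, 20))


@dataclass
class BiomeGrid:
    """Annual land-cover raster of IGBP class codes on the prediction grid."""

    classes: np.ndarray  # (nrows, ncols) int
    geom: GridGeometry
    year: int | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.classes)
        if c.shape != (self.geom.nrows, self.geom.ncols):
            raise ValueError("class raster shape does not match geometry")
        bad = set(np.unique(c)) - IGBP.ALL
        if bad:
            raise ValueError(f"unknown IGBP class codes: {sorted(bad)}")
        self.classes = c.astype(int)


@dataclass
class StratumMap:
    """Raster of model IDs 1-19; 0 marks cells with no model (non-vegetated
    or unmapped classes)."""

    model_ids: np.ndarray
    geom: GridGeometry
    unresolved: int = 0  # count of EBF/CRO cells that fell outside all regions

    NONE = 0

    def stratum_at(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        row, col = self.geom.cell_of(lat, lon)
        out = np.full(np.shape(row), self.NONE, dtype=int)
        ok = (row >= 0) & (col >= 0)
        out[ok] = self.model_ids[row[ok], col[ok]]
        return out

    def to_raster(self) -> Raster:
        return Raster(values=self.model_ids.astype(float), geom=self.geom, nodata=0.0)


def vegetated_mask(biome: BiomeGrid) -> np.ndarray:
    """True for every cell except water, urban, snow/ice and barren."""
    mask = np.ones(biome.classes.shape, dtype=bool)
    for code in _NONVEGETATED:
        mask &= biome.classes != code
    return mask


def _region_from_polygons(geom: GridGeometry, polygons: dict[str, object]) -> np.ndarray:
    """Rasterize name->shapely-polygon dict to region codes by cell center."""
    from shapely.geometry import Point

    region = np.zeros((geom.nrows, geom.ncols), dtype=int)
    lats, lons = geom.lat_centers, geom.lon_centers
    for name, poly in polygons.items():
        code = REGION_CODES[name]
        for i, la in enumerate(lats):
            for j, lo in enumerate(lons):
                if region[i, j] == 0 and poly.covers(Point(lo, la)):
                    region[i, j] = code
    return region


def assign_model_ids(
    biome: BiomeGrid,
    regions: np.ndarray | dict | None = None,
    unresolved: str = "none",
) -> StratumMap:
    """Assign each vegetated cell one of the 19 sub-biome model IDs.

    Parameters
    ----------
    biome:
        IGBP class raster on the prediction grid.
    regions:
        Region membership for the EBF and CRO splits: either an integer
        raster of :data:`REGION_CODES` (the synthetic world emits one), or a
        dict mapping region name to a shapely polygon in lon/lat.
    unresolved:
        What to do with EBF/CRO cells outside every region: ``"none"`` drops
        them (model ID 0), ``"nearest"`` assigns the nearest cell that did
        resolve within the same biome group.
    """
    if unresolved not in ("none", "nearest"):
        raise ValueError("unresolved must be 'none' or 'nearest'")
    geom = biome.geom
    if regions is None:
        region = np.zeros((geom.nrows, geom.ncols), dtype=int)
    elif isinstance(regions, dict):
        region = _region_from_polygons(geom, regions)
    else:
        region = np.asarray(regions, dtype=int)
        if region.shape != biome.classes.shape:
            raise ValueError("region raster shape does not match biome grid")

    code_to_name = {v: k for k, v in REGION_CODES.items()}
    nh = geom.lat_centers[:, None] >= 0.0  # closed on the north side
    ids = np.zeros(biome.classes.shape, dtype=int)
    veg = vegetated_mask(biome)

    for cls, group in _CLASS_GROUP.items():
        sel = (biome.classes == cls) & veg
        if not sel.any():
            continue
        if group in _HEMI_IDS:
            id_nh, id_sh = _HEMI_IDS[group]
            ids[sel & nh] = id_nh
            ids[sel & ~nh] = id_sh
        else:
            table = _EBF_IDS if group == "EBF" else _CRO_IDS
            for code, name in code_to_name.items():
                if name in table:
                    ids[sel & (region == code)] = table[name]

    # EBF/CRO cells that no region claimed
    split_classes = [c for c, g in _CLASS_GROUP.items() if g in ("EBF", "CRO")]
    pending = veg & np.isin(biome.classes, split_classes) & (ids == 0)
    n_unresolved = int(pending.sum())
    if n_unresolved and unresolved == "nearest":
        from scipy.spatial import cKDTree

        for group_classes, table in ((["EBF"], _EBF_IDS), (["CRO"], _CRO_IDS)):
            grp_cls = [c for c, g in _CLASS_GROUP.items() if g in group_classes]
            grp_pending = pending & np.isin(biome.classes, grp_cls)
            grp_done = np.isin(ids, list(table.values()))
            if grp_pending.any() and grp_done.any():
                src = np.argwhere(grp_done)
                dst = np.argwhere(grp_pending)
                _, nearest = cKDTree(src).query(dst)
                ids[tuple(dst.T)] = ids[tuple(src[nearest].T)]

    return StratumMap(model_ids=ids, geom=geom, unresolved=n_unresolved)
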