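"""Buffer land-use composition, habitat classification, LUR and WEDGE.

Each survey point is characterised by the land-use mosaic inside a 200 m
radius buffer (planar metric coordinates).  From the patch polygons we
derive:

* per-class area percentages (normalized by covered patch area, so small
  rasterization slivers do not break the sum-to-100 invariant);
* the dominant-habitat label, via an ordered threshold ruleset
  (forest-union subdivision first, then single-class dominance at >=60%,
  then the urban >=30% rule, otherwise "mixed");
* land-use richness (LUR) — the number of distinct classes present;
* weighted edge density (WEDGE) — the summed perimeter of all patch
  polygons multiplied by LUR.  Boundaries shared by two patches belong to
  both polygons and are therefore counted once per polygon.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .errors import EmptyInputError, InvalidGeometryError, InvalidInputError

#: The ten base land-use classes a patch may carry.
LAND_USE_CLASSES = (
    "coniferous_forest",
    "deciduous_forest",
    "shrubs",
    "herbaceous",
    "wetlands_water",
    "bare_soil_dunes",
    "orchards_vineyards",
    "forage",
    "croplands",
    "urban",
)

#: Derived label for buffers without a dominant class.
MIXED = "mixed"

#: All 11 possible habitat labels.
HABITAT_LABELS = LAND_USE_CLASSES + (MIXED,)

FOREST_CLASSES = ("coniferous_forest", "deciduous_forest")

DEFAULT_BUFFER_RADIUS = 200.0

# geometric tolerance for treating patch intersections as real overlaps
_OVERLAP_AREA_TOL = 1e-6


@dataclass(frozen=True)
class LandUsePatch:
    """One land-use polygon inside a site's buffer."""

    site_id: str
    landuse: str
    geometry: BaseGeometry

    def __post_init__(self):
        if self.landuse not in LAND_USE_CLASSES:
            raise InvalidInputError(f"unknown land-use class: {self.landuse!r}")
        if self.geometry.is_empty or self.geometry.area <= 0:
            raise InvalidGeometryError(f"patch for {self.site_id} has no area")
        if not self.geometry.is_valid:
            raise InvalidGeometryError(f"invalid patch geometry for {self.site_id}")


@dataclass
class BufferComposition:
    """Land-use summary of one buffer."""

    site_id: str
    pct: dict[str, float]
    perimeter_sum: float
    lur: int = 0
    wedge: float = 0.0
    habitat: str = field(default="")

    def finalize(self) -> "BufferComposition":
        """Fill LUR, WEDGE and the habitat label from pct and perimeter."""
        self.lur = land_use_richness(self)
        self.wedge = weighted_edge_density(self)
        self.habitat = classify_habitat(self)
        return self


def _check_no_overlap(geoms) -> None:
    tree = STRtree(geoms)
    for i, g in enumerate(geoms):
        for j in tree.query(g):
            j = int(j)
            if j <= i:
                continue
            inter = g.intersection(geoms[j])
            if inter.area > _OVERLAP_AREA_TOL:
                raise InvalidGeometryError(
                    f"patches {i} and {j} overlap (area {inter.area:.3g} m^2)"
                )


def buffer_composition(
    patches: list[LandUsePatch],
    buffer_radius: float = DEFAULT_BUFFER_RADIUS,
    finalize: bool = True,
) -> BufferComposition:
    """Per-class area percentages and summed perimeter of one buffer.

    Percentages are normalized by covered patch area.  Patches must belong
    to one site and must be pairwise non-overlapping.
    """
    if not patches:
        raise EmptyInputError("no patches supplied")
    site_ids = {p.site_id for p in patches}
    if len(site_ids) != 1:
        raise InvalidInputError(f"patches span several sites: {sorted(site_ids)}")
    _check_no_overlap([p.geometry for p in patches])
    areas = {c: 0.0 for c in LAND_USE_CLASSES}
    perimeter = 0.0
    for p in patches:
        areas[p.landuse] += p.geometry.area
        perimeter += p.geometry.length
    total = sum(areas.values())
    pct = {c: 100.0 * a / total for c, a in areas.items()}
    comp = BufferComposition(site_id=site_ids.pop(), pct=pct, perimeter_sum=perimeter)
    return comp.finalize() if finalize else comp


def _validate_pct(comp: BufferComposition, tol: float = 1e-6) -> dict[str, float]:
    pct = {c: float(comp.pct.get(c, 0.0)) for c in LAND_USE_CLASSES}
    if any(v < 0 for v in pct.values()):
        raise InvalidInputError("percentages must be nonnegative")
    if abs(sum(pct.values()) - 100.0) > tol:
        raise InvalidInputError(
            f"percentages sum to {sum(pct.values())!r}, expected 100"
        )
    return pct


def classify_habitat(comp: BufferComposition) -> str:
    """Dominant-habitat label of a buffer by the ordered threshold ruleset.

    1. Forest union (coniferous + deciduous) >= 60%: deciduous forest if
       deciduous >= 40% and coniferous <= 20%; coniferous forest if
       coniferous >= 40% and deciduous <= 20%; otherwise mixed.
    2. Any single non-forest class >= 60%: that class.
    3. Urban >= 30% and every other class <= 60%: urban.
    4. Otherwise mixed.
    """
    pct = _validate_pct(comp)
    con, dec = pct["coniferous_forest"], pct["deciduous_forest"]
    if con + dec >= 60.0:
        if dec >= 40.0 and con <= 20.0:
            return "deciduous_forest"
        if con >= 40.0 and dec <= 20.0:
            return "coniferous_forest"
        return MIXED
    for c in LAND_USE_CLASSES:
        if c in FOREST_CLASSES:
            continue
        if pct[c] >= 60.0:
            return c
    if pct["urban"] >= 30.0 and all(
        pct[c] <= 60.0 for c in LAND_USE_CLASSES if c != "urban"
    ):
        return "urban"
    return MIXED


def land_use_richness(comp: BufferComposition, threshold: float = 0.0) -> int:
    """Number of land-use classes covering more than ``threshold`` percent."""
    pct = _validate_pct(comp)
    return sum(1 for v in pct.values() if v > threshold)


def weighted_edge_density(comp: BufferComposition) -> float:
    """WEDGE: summed patch perimeters times land-use richness."""
    if comp.perimeter_sum < 0:
        raise InvalidInputError("perimeter_sum must be nonnegative")
    return comp.perimeter_sum * land_use_richness(comp)


def site_metrics_table(compositions: list[BufferComposition]) -> pd.DataFrame:
    """Assemble per-site buffer metrics into one DataFrame."""
    rows = []
    for comp in compositions:
        row = {
            "site_id": comp.site_id,
            "habitat": comp.habitat,
            "lur": comp.lur,
            "perimeter_sum": comp.perimeter_sum,
            "wedge": comp.wedge,
        }
        for c in LAND_USE_CLASSES:
            row[f"pct_{c}"] = comp.pct.get(c, 0.0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("site_id")


def expected_disc_circumference(buffer_radius: float = DEFAULT_BUFFER_RADIUS) -> float:
    """Perimeter of the ideal (unpolygonized) buffer disc."""
    return 2.0 * math.pi * buffer_radius


# ---------------------------------------------------------------------------
# I/O: GeoJSON FeatureCollection and WKT-in-CSV
# ---------------------------------------------------------------------------

def patches_to_geojson(patches: list[LandUsePatch], path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"site_id": p.site_id, "landuse": p.landuse},
            "geometry": mapping(p.geometry),
        }
        for p in patches
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def patches_from_geojson(path) -> dict[str, list[LandUsePatch]]:
    """Read patches grouped by site id from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        collection = json.load(fh)
    by_site: dict[str, list[LandUsePatch]] = {}
    for feat in collection["features"]:
        props = feat["properties"]
        patch = LandUsePatch(
            site_id=str(props["site_id"]),
            landuse=props["landuse"],
            geometry=shape(feat["geometry"]),
        )
        by_site.setdefault(patch.site_id, []).append(patch)
    return by_site


def patches_from_csv(path) -> dict[str, list[LandUsePatch]]:
    """Read patches from a CSV with site_id, landuse and WKT geometry columns."""
    df = pd.read_csv(path)
    for col in ("site_id", "landuse", "wkt"):
        if col not in df.columns:
            raise InvalidInputError(f"patch CSV lacks a '{col}' column")
    by_site: dict[str, list[LandUsePatch]] = {}
    for _, row in df.iterrows():
        patch = LandUsePatch(
            site_id=str(row["site_id"]),
            landuse=row["landuse"],
            geometry=shapely_wkt.loads(row["wkt"]),
        )
        by_site.setdefault(patch.site_id, []).append(patch)
    return by_site
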