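"""Labelled landscape geometry and plant-composition extraction.

A :class:`PlantPolygonMap` is a set of labelled patches (shrub, forb, bare
soil, ...) inside a rectangular study domain split by a linear ecosystem
boundary.  Ground not covered by any patch is treated as grass and described
by an *average grass composition* — a fixed relative-cover vector over grass
categories — mirroring how unmapped cover is handled when only the larger
plants are digitised from aerial imagery.

:func:`plant_composition_at_radius` returns the relative plant cover inside a
circle of a given radius around a sampling point.  The circle is represented
as a 256-vertex polygon (relative area error below 1e-4), so every
circle-polygon intersection is an exact polygonal area computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from shapely.geometry import Point, Polygon, box, mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "CIRCLE_QUAD_SEGS",
    "GeometryError",
    "CompositionError",
    "SampleLocation",
    "PlantComposition",
    "PlantPolygonMap",
    "plant_composition_at_radius",
]

#: Quarter-circle segment count used when discretising circles; 4 * 64 = 256
#: vertices keep the relative area error of every intersection below 1e-4.
CIRCLE_QUAD_SEGS = 64

_SUM_TOL = 1e-9


class GeometryError(ValueError):
    """Raised for invalid landscape geometry or out-of-domain queries."""


class CompositionError(ValueError):
    """Raised when a plant composition cannot be formed (degenerate cover)."""


@dataclass(frozen=True)
class SampleLocation:
    """A trap location on a transect, with planar coordinates in meters."""

    sample_id: str
    x: float
    y: float
    ecosystem: str = ""
    transect: int = 0
    offset_m: float = 0.0

    @property
    def point(self) -> Point:
        return Point(self.x, self.y)


@dataclass(frozen=True)
class PlantComposition:
    """Relative cover per plant category; fractions are >= 0 and sum to 1."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        fr = dict(self.fractions)
        if not fr:
            raise CompositionError("composition has no categories")
        for cat, f in fr.items():
            if f < -_SUM_TOL:
                raise CompositionError(f"negative fraction for category {cat!r}: {f}")
        total = sum(fr.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise CompositionError(f"fractions sum to {total}, expected 1")
        object.__setattr__(self, "fractions", fr)

    @classmethod
    def from_areas(cls, areas: Mapping[str, float]) -> "PlantComposition":
        """Normalise non-negative areas (or weights) into fractions."""
        total = sum(areas.values())
        if total <= 0:
            raise CompositionError("total area is zero; composition undefined")
        return cls({c: max(a, 0.0) / total for c, a in areas.items()})

    def __getitem__(self, category: str) -> float:
        return self.fractions.get(category, 0.0)

    @property
    def categories(self) -> list[str]:
        return list(self.fractions)

    def as_vector(self, categories: Sequence[str]) -> list[float]:
        """Fractions in a fixed category order (0 for absent categories)."""
        return [self.fractions.get(c, 0.0) for c in categories]

    def items(self):
        return self.fractions.items()


@dataclass
class PlantPolygonMap:
    """Labelled patches plus the study-domain rectangle.

    ``patches`` are (category, geometry) pairs assumed mutually
    non-overlapping (the synthetic generator clips later patches against
    earlier ones).  ``grass_background`` is the average grass composition
    assigned to ground not covered by any patch.
    """

    patches: list[tuple[str, BaseGeometry]]
    domain: Polygon
    boundary_x_m: float | None = None
    grass_background: PlantComposition | None = None

    def __post_init__(self) -> None:
        if self.domain.is_empty or self.domain.area <= 0:
            raise GeometryError("domain polygon is empty")
        for cat, geom in self.patches:
            if not cat:
                raise GeometryError("patch with empty category label")
            if not geom.is_valid:
                raise GeometryError(f"invalid geometry for category {cat!r}")

    @property
    def categories(self) -> list[str]:
        seen: dict[str, None] = {}
        for cat, _ in self.patches:
            seen.setdefault(cat)
        return list(seen)

    @property
    def all_categories(self) -> list[str]:
        """Patch categories followed by grass-background categories."""
        cats = self.categories
        if self.grass_background is not None:
            for c in self.grass_background.categories:
                if c not in cats:
                    cats.append(c)
        return cats

    # -- GeoJSON round trip -------------------------------------------------

    def to_geojson(self) -> dict:
        features = [
            {
                "type": "Feature",
                "properties": {"category": cat, "role": "patch"},
                "geometry": mapping(geom),
            }
            for cat, geom in self.patches
        ]
        features.append(
            {
                "type": "Feature",
                "properties": {"category": None, "role": "domain"},
                "geometry": mapping(self.domain),
            }
        )
        obj: dict = {"type": "FeatureCollection", "features": features}
        if self.boundary_x_m is not None:
            obj["boundary_x_m"] = self.boundary_x_m
        if self.grass_background is not None:
            obj["grass_background"] = dict(self.grass_background.fractions)
        return obj

    def write_geojson(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_geojson(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_geojson(cls, obj_or_path) -> "PlantPolygonMap":
        if isinstance(obj_or_path, (str, bytes)) or hasattr(obj_or_path, "__fspath__"):
            with open(obj_or_path, encoding="utf-8") as fh:
                obj = json.load(fh)
        else:
            obj = obj_or_path
        if obj.get("type") != "FeatureCollection":
            raise GeometryError("expected a GeoJSON FeatureCollection")
        patches: list[tuple[str, BaseGeometry]] = []
        domain: Polygon | None = None
        for feat in obj.get("features", []):
            props = feat.get("properties") or {}
            geom = shape(feat["geometry"])
            if props.get("role") == "domain":
                domain = geom
            else:
                cat = props.get("category")
                if not cat:
                    raise GeometryError("patch feature without a 'category' property")
                patches.append((cat, geom))
        if domain is None:
            raise GeometryError("FeatureCollection lacks a domain feature")
        grass = obj.get("grass_background")
        return cls(
            patches=patches,
            domain=domain,
            boundary_x_m=obj.get("boundary_x_m"),
            grass_background=PlantComposition(grass) if grass else None,
        )


def _circle(x: float, y: float, radius_m: float) -> Polygon:
    return Point(x, y).buffer(radius_m, quad_segs=CIRCLE_QUAD_SEGS)


def plant_composition_at_radius(
    pmap: PlantPolygonMap,
    point,
    radius_m: float,
    avg_grass: PlantComposition | None = None,
) -> PlantComposition:
    """Relative plant cover within ``radius_m`` of ``point``.

    Each mapped category contributes its intersection area with the circle
    (clipped to the domain), divided by the circle-within-domain area.  The
    residual unmapped fraction is split across grass categories in proportion
    to ``avg_grass`` (default: the map's ``grass_background``).

    Parameters
    ----------
    point : SampleLocation, shapely Point, or (x, y) pair.
    radius_m : circle radius in meters, > 0.
    """
    if radius_m <= 0:
        raise GeometryError(f"radius must be positive, got {radius_m}")
    if isinstance(point, SampleLocation):
        x, y = point.x, point.y
    elif isinstance(point, Point):
        x, y = point.x, point.y
    else:
        x, y = point
    if avg_grass is None:
        avg_grass = pmap.grass_background

    cell = _circle(x, y, radius_m).intersection(pmap.domain)
    if cell.is_empty or cell.area <= 0:
        raise GeometryError(
            f"circle of radius {radius_m} m at ({x}, {y}) lies entirely outside the domain"
        )
    cell_area = cell.area

    areas: dict[str, float] = {}
    mapped = 0.0
    for cat, geom in pmap.patches:
        a = geom.intersection(cell).area
        if a > 0:
            areas[cat] = areas.get(cat, 0.0) + a
            mapped += a

    residual = max(cell_area - mapped, 0.0)
    if residual / cell_area > _SUM_TOL:
        if avg_grass is None:
            raise CompositionError(
                "unmapped area present but no average grass composition supplied"
            )
        for cat, f in avg_grass.items():
            areas[cat] = areas.get(cat, 0.0) + residual * f
    elif mapped <= 0:
        raise CompositionError("circle covers neither mapped nor unmapped area")

    return PlantComposition.from_areas(areas)
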