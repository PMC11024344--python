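"""Niche geometry: the SGZ midline polyline and labeled subregion polygons.

The subgranular zone (SGZ) is the narrow band, about two cell bodies wide,
between the granule cell layer and the hilus.  Its centreline (the
"midline") is the reference curve for the systematic random null: sample
points are laid out at fixed arc-length spacing along it.  Subregions of
the dentate gyrus (molecular layer ML, granule cell layer GCL, SGZ, hilus
HL) are simple polygons in µm coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

__all__ = ["MidlinePolyline", "RegionMap", "write_geometry_json", "read_midline_json",
           "read_regions_json"]


@dataclass
class MidlinePolyline:
    """Ordered midline vertices (µm) plus the band half-width.

    ``band_halfwidth_um`` defines the SGZ band: all points within that
    perpendicular distance of the midline.
    """

    vertices: np.ndarray  # (n, 2) array of (x_um, y_um)
    band_halfwidth_um: float

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y) µm")
        if len(self.vertices) < 2:
            raise ValueError("midline needs at least 2 vertices")
        if self.band_halfwidth_um <= 0:
            raise ValueError("band_halfwidth_um must be positive")
        if self.arc_length_um <= 0:
            raise ValueError("midline has zero arc length")

    @property
    def line(self) -> LineString:
        return LineString(self.vertices)

    @property
    def arc_length_um(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))

    def point_at(self, s_um) -> np.ndarray:
        """Point(s) at arc length ``s_um`` from the start, shape (..., 2)."""
        s = np.atleast_1d(np.asarray(s_um, dtype=float))
        pts = [self.line.interpolate(float(v)) for v in s]
        out = np.array([[p.x, p.y] for p in pts])
        return out if np.ndim(s_um) else out[0]

    def distance_to(self, xy: np.ndarray) -> np.ndarray:
        """Perpendicular distance (µm) from points (n, 2) to the midline."""
        pts = shapely.points(np.asarray(xy, dtype=float))
        return shapely.distance(self.line, pts)

    def in_band(self, xy: np.ndarray) -> np.ndarray:
        """Boolean: which points lie inside the SGZ band."""
        return self.distance_to(xy) <= self.band_halfwidth_um


@dataclass
class RegionMap:
    """Labeled simple polygons for DG subregions, in µm coordinates."""

    regions: dict[str, Polygon] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fixed = {}
        for name, poly in self.regions.items():
            if not isinstance(poly, Polygon):
                poly = Polygon(np.asarray(poly, dtype=float))
            if not poly.is_valid:
                raise ValueError(f"region {name!r} polygon is not simple/valid")
            fixed[name] = poly
        self.regions = fixed

    def names(self) -> list[str]:
        return list(self.regions)

    def label_raster(self, shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
        """Assign each pixel centre to a region.

        Returns an int raster: -1 outside all regions, else the index of the
        region in :meth:`names`.  Assignment is pixel-centre-in-polygon with
        boundaries inclusive; where polygons share a boundary the
        first-listed region wins.
        """
        nr, nc = shape
        s = pixel_size_um
        xs = (np.arange(nc) + 0.5) * s
        ys = (np.arange(nr) + 0.5) * s
        xx, yy = np.meshgrid(xs, ys)
        out = np.full(shape, -1, dtype=np.int32)
        for i, name in reversed(list(enumerate(self.names()))):
            poly = self.regions[name]
            # intersects == covers for points: boundary-inclusive
            inside = shapely.intersects_xy(poly, xx.ravel(), yy.ravel())
            out.ravel()[inside] = i
        return out


def write_geometry_json(path, midline: MidlinePolyline | None = None,
                        regions: RegionMap | None = None) -> None:
    """Write midline and/or region polygons as a JSON vertex-list file."""
    doc: dict = {"units": "um", "schema": "nichescape-geometry-1"}
    if midline is not None:
        doc["midline"] = {
            "vertices": midline.vertices.tolist(),
            "band_halfwidth_um": midline.band_halfwidth_um,
        }
    if regions is not None:
        doc["regions"] = {
            name: np.asarray(poly.exterior.coords).tolist()
            for name, poly in regions.regions.items()
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def read_midline_json(path) -> MidlinePolyline:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    m = doc["midline"]
    return MidlinePolyline(np.asarray(m["vertices"]), float(m["band_halfwidth_um"]))


def read_regions_json(path) -> RegionMap:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return RegionMap({name: Polygon(v) for name, v in doc.get("regions", {}).items()})
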