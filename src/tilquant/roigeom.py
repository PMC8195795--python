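"""Regions of interest on a slide: tumor center (TC), invasive margin (IM).

The quantification template measures cell densities inside manually marked
regions. This module represents those annotations as labelled polygons in
pixel coordinates, rasterizes them to binary masks, and measures their area
in physical units (mm**2).

Coordinate convention
---------------------
Pixel indices are 0-based, x to the right, y down; polygon vertices are
expressed at pixel centers, so the pixel at (row=i, col=j) has center
(x=j, y=i). A pixel belongs to a polygon iff its center is inside under the
even-odd fill rule with a half-open boundary (top/left boundary pixels are
included, bottom/right excluded), the standard scanline convention: an
axis-aligned square from (0, 0) to (w, h) covers exactly w*h pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
import shapely.geometry as sgeom

from .errors import GeometryError, SchemaError, ZeroAreaError

VALID_LABELS = ("TC", "IM", "EXCLUDE")

PolygonLike = "sgeom.Polygon | sgeom.MultiPolygon | Sequence[tuple[float, float]]"


def as_polygon(poly) -> sgeom.Polygon | sgeom.MultiPolygon:
    """Coerce a vertex sequence or shapely geometry to a (Multi)Polygon.

    Raises
    ------
    GeometryError
        If the polygon has fewer than 3 vertices or is not simple.
    """
    if isinstance(poly, (sgeom.Polygon, sgeom.MultiPolygon)):
        geom = poly
    else:
        verts = list(poly)
        if len(verts) < 3:
            raise GeometryError(f"polygon needs >= 3 vertices, got {len(verts)}")
        geom = sgeom.Polygon(verts)
    if geom.is_empty or not geom.is_valid:
        raise GeometryError("polygon is degenerate or self-intersecting")
    return geom


@dataclass
class RegionAnnotation:
    """Labelled polygons (TC, IM, EXCLUDE) for one slide.

    Parameters
    ----------
    slide_id : str
        Identifier of the slide the annotation belongs to.
    regions : list of (label, polygon)
        ``label`` in {"TC", "IM", "EXCLUDE"}; polygons in pixel coordinates.
        Multiple parts per label are allowed; EXCLUDE regions may overlap
        TC/IM and always win (they model areas manually removed as
        artifacts or unspecific staining).
    um_per_px : float
        Physical pixel size in micrometers per pixel.
    """

    slide_id: str
    regions: list = field(default_factory=list)
    um_per_px: float = 1.0

    def __post_init__(self):
        if self.um_per_px <= 0:
            raise GeometryError(f"um_per_px must be > 0, got {self.um_per_px}")
        self.regions = [(lab, as_polygon(p)) for lab, p in self.regions]
        for lab, _ in self.regions:
            if lab not in VALID_LABELS:
                raise SchemaError(f"unknown region label {lab!r}; expected one of {VALID_LABELS}")

    def polygons(self, label: str) -> list[sgeom.Polygon]:
        out = []
        for lab, geom in self.regions:
            if lab != label:
                continue
            if isinstance(geom, sgeom.MultiPolygon):
                out.extend(geom.geoms)
            else:
                out.append(geom)
        return out

    def labels(self) -> set[str]:
        return {lab for lab, _ in self.regions}


def _polygon_mask(poly: sgeom.Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd scanline rasterization of one simple polygon (with holes).

    A pixel center (x=j, y=i) is inside if a ray to +x crosses an odd number
    of edges, using the half-open rule ``(y1 <= y) != (y2 <= y)`` so shared
    edges between adjacent polygons are never double-counted and integer
    vertex squares cover exactly their nominal pixel count.
    """
    h, w = shape
    minx, miny, maxx, maxy = poly.bounds
    # restrict to bounding box (plus 1 px guard) for speed
    c0, c1 = max(int(np.floor(minx)) - 1, 0), min(int(np.ceil(maxx)) + 1, w - 1)
    r0, r1 = max(int(np.floor(miny)) - 1, 0), min(int(np.ceil(maxy)) + 1, h - 1)
    mask = np.zeros(shape, dtype=bool)
    if c1 < c0 or r1 < r0:
        return mask
    ys = np.arange(r0, r1 + 1, dtype=float)[:, None]
    xs = np.arange(c0, c1 + 1, dtype=float)[None, :]
    inside = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
    rings = [poly.exterior, *poly.interiors]
    for ring in rings:
        coords = np.asarray(ring.coords)
        for (x1, y1), (x2, y2) in zip(coords[:-1], coords[1:]):
            if y1 == y2:
                continue
            cond = (y1 <= ys) != (y2 <= ys)
            with np.errstate(invalid="ignore"):
                xint = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)
            inside ^= cond & (xs < xint)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    return mask


def rasterize_region(
    annotation: RegionAnnotation, label: str, image_shape: tuple[int, int]
) -> np.ndarray:
    """Binary mask of a labelled region, with EXCLUDE areas removed.

    Parameters
    ----------
    annotation : RegionAnnotation
    label : str
        "TC" or "IM" (rasterizing "EXCLUDE" itself is also allowed).
    image_shape : (height, width)

    Returns
    -------
    ndarray of bool, shape ``image_shape``
        True where the pixel center lies inside any polygon of ``label``
        and not inside any EXCLUDE polygon.

    Raises
    ------
    KeyError
        If ``label`` is absent from the annotation.
    """
    if label not in annotation.labels():
        raise KeyError(f"label {label!r} not present in annotation for slide {annotation.slide_id!r}")
    mask = np.zeros(image_shape, dtype=bool)
    for poly in annotation.polygons(label):
        mask |= _polygon_mask(poly, image_shape)
    if label != "EXCLUDE":
        for poly in annotation.polygons("EXCLUDE"):
            mask &= ~_polygon_mask(poly, image_shape)
    return mask


def region_area_mm2(mask: np.ndarray, um_per_px: float) -> float:
    """Area of a binary mask in mm**2: ``count * um_per_px**2 / 1e6``.

    Raises :class:`ZeroAreaError` on an empty mask — a zero-area region
    cannot serve as a density denominator.
    """
    if um_per_px <= 0:
        raise GeometryError(f"um_per_px must be > 0, got {um_per_px}")
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ZeroAreaError("region mask is empty; cannot compute a density over zero area")
    return n * um_per_px**2 / 1e6


def derive_invasive_margin(
    tumor_boundary, half_width_um: float = 500.0, um_per_px: float = 1.0
) -> sgeom.Polygon | sgeom.MultiPolygon:
    """Symmetric band of +-``half_width_um`` around a tumor boundary.

    Convenience constructor for an invasive-margin annotation when only the
    tumor outline is available: the band is (outline dilated by half_width)
    minus (outline eroded by half_width). A manually drawn IM polygon, when
    present, always takes precedence over this derived band.

    The default half width of 500 um is a package convention (a symmetric
    band around the tumor front), configurable per run.
    """
    if half_width_um <= 0:
        raise GeometryError(f"half_width_um must be > 0, got {half_width_um}")
    poly = as_polygon(tumor_boundary)
    hw_px = half_width_um / um_per_px
    outer = poly.buffer(hw_px)
    inner = poly.buffer(-hw_px)
    if inner.is_empty:
        import warnings

        warnings.warn(
            "erosion by half_width annihilated the tumor polygon; "
            "invasive-margin band equals the full dilated region",
            stacklevel=2,
        )
    return outer.difference(inner)


# ---------------------------------------------------------------------------
# GeoJSON I/O — FeatureCollection with {"label": ...} properties, pixel
# coordinates, and the pixel size carried as a top-level "um_per_px" member.
# ---------------------------------------------------------------------------

def annotation_to_geojson(annotation: RegionAnnotation) -> dict:
    features = []
    for lab, geom in annotation.regions:
        features.append(
            {
                "type": "Feature",
                "properties": {"label": lab},
                "geometry": sgeom.mapping(geom),
            }
        )
    return {
        "type": "FeatureCollection",
        "slide_id": annotation.slide_id,
        "um_per_px": annotation.um_per_px,
        "features": features,
    }


def annotation_from_geojson(obj: dict) -> RegionAnnotation:
    if obj.get("type") != "FeatureCollection":
        raise SchemaError("annotation GeoJSON must be a FeatureCollection")
    if "um_per_px" not in obj:
        raise SchemaError("annotation GeoJSON is missing the 'um_per_px' member")
    regions = []
    for feat in obj.get("features", []):
        props = feat.get("properties") or {}
        label = props.get("label")
        if label not in VALID_LABELS:
            raise SchemaError(f"feature has missing/unknown label {label!r}")
        geom = sgeom.shape(feat["geometry"])
        regions.append((label, geom))
    return RegionAnnotation(
        slide_id=obj.get("slide_id", ""),
        regions=regions,
        um_per_px=float(obj["um_per_px"]),
    )


def write_annotation(path, annotation: RegionAnnotation) -> None:
    with open(path, "w") as fh:
        json.dump(annotation_to_geojson(annotation), fh, indent=1)


def read_annotation(path) -> RegionAnnotation:
    with open(path) as fh:
        return annotation_from_geojson(json.load(fh))


def shoelace_area(vertices: Iterable[tuple[float, float]]) -> float:
    """Signed-area magnitude of a polygon by the shoelace formula (px**2)."""
    v = np.asarray(list(vertices), dtype=float)
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)
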