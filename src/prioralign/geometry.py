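"""Planar polygon primitives: repair, area, clip, dissolve, intersect, centroid.

Every layer-level operation in the assessment pipeline reduces to the handful
of primitives defined here.  All computation is in double precision on planar
coordinates expressed in kilometres, so areas come out in km².  Geometries are
shapely 2.x objects; layers are thin ordered containers that carry a
coordinate-frame tag so that mismatched frames are caught instead of silently
overlaid.

Overlay products are re-repaired and near-zero slivers (area below
``SLIVER_AREA_KM2``) are dropped: they are numerical noise from coordinate
rounding at shared edges, not land.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry.base import BaseGeometry

from .errors import (
    CoordinateFrameError,
    InvalidGeometryError,
    UnsupportedGeometryError,
)

#: Overlay slivers below this area (km²) are treated as numerical noise.
SLIVER_AREA_KM2 = 1e-9

#: Frame tag for synthetic / already-planar data with coordinates in km.
PLANAR_KM = "planar-km"

_POLYGONAL = (shapely.Polygon, shapely.MultiPolygon)


@dataclass(frozen=True)
class Feature:
    """One polygon record: stable id, planar geometry, free-form attributes.

    ``attributes`` may carry ``acquisition_date`` (ISO date string or
    ``datetime.date``), ``tenure`` (``"easement"`` | ``"fee"`` | ``"unknown"``)
    and ``state_name``.  A missing attribute is genuinely absent from the
    mapping; an empty string is never used as a stand-in for "missing".
    """

    id: str
    geometry: BaseGeometry
    attributes: Mapping[str, object] = field(default_factory=dict)

    def with_geometry(self, geometry: BaseGeometry) -> "Feature":
        return replace(self, geometry=geometry)


@dataclass
class VectorLayer:
    """Ordered collection of polygon features sharing one planar frame."""

    features: list[Feature]
    crs_tag: str = PLANAR_KM

    def __post_init__(self) -> None:
        ids = [f.id for f in self.features]
        if len(ids) != len(set(ids)):
            raise ValueError("feature ids must be unique within a layer")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def geometries(self) -> np.ndarray:
        """Geometries as a shapely object array (for vectorized ops)."""
        return np.array([f.geometry for f in self.features], dtype=object)

    def areas(self) -> np.ndarray:
        return shapely.area(self.geometries()) if self.features else np.zeros(0)

    def total_area(self) -> float:
        return float(self.areas().sum())

    def union(self) -> BaseGeometry:
        return shapely.union_all(self.geometries()) if self.features else shapely.Polygon()

    def repaired(self) -> "VectorLayer":
        """Copy of the layer with every geometry made valid."""
        return VectorLayer(
            [f.with_geometry(make_valid(f.geometry)) for f in self.features],
            crs_tag=self.crs_tag,
        )

    @classmethod
    def from_geometries(
        cls,
        geometries: Iterable[BaseGeometry],
        crs_tag: str = PLANAR_KM,
        attributes: Sequence[Mapping[str, object]] | None = None,
        id_prefix: str = "f",
    ) -> "VectorLayer":
        geoms = list(geometries)
        attrs = attributes if attributes is not None else [{}] * len(geoms)
        feats = [
            Feature(id=f"{id_prefix}{i}", geometry=g, attributes=dict(a))
            for i, (g, a) in enumerate(zip(geoms, attrs))
        ]
        return cls(feats, crs_tag=crs_tag)


def _require_same_frame(a: VectorLayer, b: VectorLayer) -> None:
    if a.crs_tag != b.crs_tag:
        raise CoordinateFrameError(
            f"layers are in different frames: {a.crs_tag!r} vs {b.crs_tag!r}"
        )


def _only_polygonal(g: BaseGeometry) -> BaseGeometry:
    """Keep the polygonal content of a geometry (drops lines/points)."""
    if isinstance(g, _POLYGONAL):
        return g
    if isinstance(g, shapely.GeometryCollection):
        parts = [p for p in shapely.get_parts(g) if isinstance(p, _POLYGONAL)]
        if not parts:
            return shapely.Polygon()
        return shapely.union_all(parts)
    return shapely.Polygon()


def make_valid(g: BaseGeometry) -> BaseGeometry:
    """Repair a polygonal geometry (bow-ties, self-touches, duplicate rings).

    The result is valid and covers the input's valid interpretation, so the
    area is preserved; the operation is idempotent.  Non-polygonal input
    raises :class:`UnsupportedGeometryError`.
    """
    if g is None or not isinstance(g, BaseGeometry):
        raise UnsupportedGeometryError("unsupported geometry: not a geometry object")
    if not isinstance(g, (shapely.Polygon, shapely.MultiPolygon, shapely.GeometryCollection)):
        raise UnsupportedGeometryError(
            f"unsupported geometry: expected polygon or multipolygon, got {g.geom_type}"
        )
    if isinstance(g, _POLYGONAL) and g.is_valid:
        return g
    return _only_polygonal(shapely.make_valid(g))


def _clean_overlay_output(g: BaseGeometry) -> BaseGeometry:
    """Valid polygonal content of an overlay product.

    Overlays of touching geometries can emit lines/points alongside (or
    instead of) polygons; only the polygonal content carries area and is
    kept.
    """
    if isinstance(g, _POLYGONAL) and g.is_valid:
        return g
    return _only_polygonal(shapely.make_valid(g))


def planar_area(g: BaseGeometry) -> float:
    """Area (km²) of a valid planar geometry.

    Additive over disjoint parts and invariant under rigid motions; invalid
    input raises :class:`InvalidGeometryError` rather than returning the
    signed-ring area a raw shoelace pass would produce.
    """
    if not g.is_valid:
        raise InvalidGeometryError("geometry is invalid; run make_valid first")
    return float(shapely.area(g))


def _drop_slivers(geoms: np.ndarray) -> np.ndarray:
    if len(geoms) == 0:
        return geoms
    keep = ~shapely.is_empty(geoms) & (shapely.area(geoms) >= SLIVER_AREA_KM2)
    return geoms[keep]


def clip(layer: VectorLayer, boundary: VectorLayer) -> VectorLayer:
    """Restrict ``layer`` to the union of ``boundary``; attributes survive.

    Features falling entirely outside the boundary are dropped, as are
    sub-sliver crumbs produced at boundary edges.
    """
    _require_same_frame(layer, boundary)
    if not layer.features:
        return VectorLayer([], crs_tag=layer.crs_tag)
    bound = boundary.union()
    geoms = layer.geometries()
    clipped = shapely.intersection(geoms, bound)
    out: list[Feature] = []
    for feat, g in zip(layer.features, clipped):
        g = _clean_overlay_output(g)
        if not g.is_empty and shapely.area(g) >= SLIVER_AREA_KM2:
            out.append(feat.with_geometry(g))
    return VectorLayer(out, crs_tag=layer.crs_tag)


def dissolve(layer: VectorLayer) -> VectorLayer:
    """Set-union of all features so overlapping parcels are counted once.

    Implemented as connected components of the "intersects" relation: only
    groups of mutually touching features are unioned, features disjoint from
    all others pass through untouched.  On layers that are mostly disjoint
    this is near-linear while producing exactly the same union as a global
    cascaded union; the output is a minimal set of pairwise-disjoint
    features.  Idempotent and independent of feature order.
    """
    if not layer.features:
        return VectorLayer([], crs_tag=layer.crs_tag)
    geoms = layer.geometries()
    n = len(geoms)
    tree = shapely.STRtree(geoms)
    ii, jj = tree.query(geoms, predicate="intersects")
    adj = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    counts = np.bincount(labels, minlength=n_comp)
    merged: list[BaseGeometry] = []
    singles = counts[labels] == 1
    merged.extend(geoms[singles])
    multi = np.flatnonzero(~singles)
    for lab in np.unique(labels[multi]):
        merged.append(shapely.union_all(geoms[multi[labels[multi] == lab]]))
    kept = _drop_slivers(np.array(merged, dtype=object))
    # stable output order: sort by (minx, miny) so results are order-free
    if len(kept):
        bounds = shapely.bounds(np.asarray(kept, dtype=object))
        order = np.lexsort((bounds[:, 1], bounds[:, 0]))
        kept = np.asarray(kept, dtype=object)[order]
    return VectorLayer.from_geometries(kept, crs_tag=layer.crs_tag, id_prefix="dissolved")


def intersect_area(
    a: VectorLayer,
    b: VectorLayer,
    assume_dissolved: bool = False,
) -> tuple[VectorLayer, float]:
    """Overlap regions of two layers and their total area (km²).

    Each input is dissolved first (skipped when the caller guarantees
    ``assume_dissolved``), after which the total overlap is the sum of
    pairwise intersections found through a spatial index.  Symmetric in its
    arguments and bounded by ``min(area(a), area(b))``.
    """
    _require_same_frame(a, b)
    if not assume_dissolved:
        a, b = dissolve(a), dissolve(b)
    if not a.features or not b.features:
        return VectorLayer([], crs_tag=a.crs_tag), 0.0
    ga, gb = a.geometries(), b.geometries()
    tree = shapely.STRtree(gb)
    ia, ib = tree.query(ga, predicate="intersects")
    if len(ia) == 0:
        return VectorLayer([], crs_tag=a.crs_tag), 0.0
    pieces = shapely.intersection(ga[ia], gb[ib])
    pieces = np.array([_clean_overlay_output(p) for p in pieces], dtype=object)
    pieces = _drop_slivers(pieces)
    layer = VectorLayer.from_geometries(pieces, crs_tag=a.crs_tag, id_prefix="overlap")
    return layer, layer.total_area()


def centroid(g: BaseGeometry) -> shapely.Point:
    """Area-weighted geometric centroid of a polygonal geometry.

    For a multipolygon this is the centroid of the whole record, which may
    fall outside every part; zero-area geometry raises
    :class:`InvalidGeometryError`.
    """
    if not g.is_valid:
        raise InvalidGeometryError("geometry is invalid; run make_valid first")
    if g.is_empty or shapely.area(g) <= 0.0:
        raise InvalidGeometryError("centroid undefined for zero-area geometry")
    return g.centroid


def point_in_layer(p: shapely.Point, layer: VectorLayer) -> bool:
    """True iff ``p`` lies inside or on the boundary of any feature."""
    if not layer.features:
        return False
    geoms = layer.geometries()
    tree = shapely.STRtree(geoms)
    return len(tree.query(p, predicate="intersects")) > 0


def points_in_layer(points: Sequence[shapely.Point], layer: VectorLayer) -> np.ndarray:
    """Vectorized membership test; boundary points count as inside."""
    pts = np.array(points, dtype=object)
    result = np.zeros(len(pts), dtype=bool)
    if not layer.features or len(pts) == 0:
        return result
    tree = shapely.STRtree(layer.geometries())
    idx_pts, _ = tree.query(pts, predicate="intersects")
    result[np.unique(idx_pts)] = True
    return result


def rotate_layer(layer: VectorLayer, angle_deg: float, origin=(0.0, 0.0)) -> VectorLayer:
    """Rigid rotation of every feature (testing aid for affine invariance)."""
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    ox, oy = origin
    feats = [
        f.with_geometry(
            shapely.transform(
                f.geometry,
                lambda xy: np.column_stack(
                    (
                        ox + c * (xy[:, 0] - ox) - s * (xy[:, 1] - oy),
                        oy + s * (xy[:, 0] - ox) + c * (xy[:, 1] - oy),
                    )
                ),
            )
        )
        for f in layer.features
    ]
    return VectorLayer(feats, crs_tag=layer.crs_tag)


def translate_layer(layer: VectorLayer, dx: float, dy: float) -> VectorLayer:
    feats = [
        f.with_geometry(
            shapely.transform(f.geometry, lambda xy: xy + np.array([dx, dy]))
        )
        for f in layer.features
    ]
    return VectorLayer(feats, crs_tag=layer.crs_tag)
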