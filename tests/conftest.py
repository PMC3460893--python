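import numpy as np
import pytest
import shapely

from prioralign import Feature, VectorLayer


def layer_from_boxes(boxes, attrs=None, crs_tag="planar-km", id_prefix="f"):
    """Build a layer from (minx, miny, maxx, maxy) tuples."""
    feats = []
    for i, b in enumerate(boxes):
        a = attrs[i] if attrs else {}
        feats.append(Feature(id=f"{id_prefix}{i}", geometry=shapely.box(*b), attributes=a))
    return VectorLayer(feats, crs_tag=crs_tag)


@pytest.fixture
def unit_square():
    return shapely.box(0, 0, 1, 1)


@pytest.fixture
def rng():
    return np.random.default_rng(20120928)


def random_star_polygon(rng, n_vertices=12, radius=1.0):
    """Simple (non-self-intersecting) polygon: star-shaped about the origin."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(0.3 * radius, radius, n_vertices)
    pts = np.column_stack((radii * np.cos(angles), radii * np.sin(angles)))
    return shapely.Polygon(pts)


def monte_carlo_area(rng, geom, n_samples=1_000_000):
    """Rejection-sampling area estimate and its standard error."""
    minx, miny, maxx, maxy = geom.bounds
    box_area = (maxx - minx) * (maxy - miny)
    xs = rng.uniform(minx, maxx, n_samples)
    ys = rng.uniform(miny, maxy, n_samples)
    inside = shapely.contains_xy(geom, xs, ys)
    p = inside.mean()
    est = p * box_area
    se = box_area * np.sqrt(p * (1 - p) / n_samples)
    return est, se
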