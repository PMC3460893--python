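"""Layer readers/writers, projection, report rendering, run configuration.

Input and output vector layers are GeoJSON (``.geojson`` / ``.json``), the
one standard vector format that is plain text end to end.  Layers arriving
in geographic coordinates (longitude/latitude degrees, the GeoJSON default)
are projected to an Albers Equal Area Conic frame in kilometres before any
area arithmetic; layers tagged ``planar-km`` (e.g. synthetic landscapes)
bypass projection.

Reports are rendered as three CSV tables (by period, by tenure, by state)
plus a JSON block for the centroid test and a manifest.  Percentages are
rounded half-away-from-zero at the configured precision; undefined values
render as ``NA``, never as zero.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import mapping, shape

from . import __version__
from .errors import ConfigError, DataError, UnsupportedFormatError
from .geometry import PLANAR_KM, Feature, VectorLayer, make_valid
from .metrics import AlignmentSummary
from .strata import (
    ALL_STRATUM,
    TENURE_CLASSES,
    UNDATED_STRATUM,
    AssessmentReport,
    PeriodDefinition,
    default_periods,
)

logger = logging.getLogger(__name__)

_SUPPORTED_EXTENSIONS = (".geojson", ".json")

# ---------------------------------------------------------------------------
# Albers Equal Area Conic (spherical form, authalic radius)
# ---------------------------------------------------------------------------

#: Authalic Earth radius in km (sphere with the ellipsoid's surface area).
EARTH_RADIUS_KM = 6371.0072

#: Frame tag for layers projected by :func:`albers_project`.
ALBERS_NA_KM = "albers-conus-km"


@dataclass(frozen=True)
class AlbersParameters:
    """Standard parallels and origin of an Albers Equal Area Conic frame.

    Defaults are the conventional North America parameterization
    (parallels 29.5°N and 45.5°N, origin 23°N 96°W).
    """

    lat_1: float = 29.5
    lat_2: float = 45.5
    lat_0: float = 23.0
    lon_0: float = -96.0


_PROJECTIONS = {"albers-north-america": AlbersParameters()}


def resolve_projection(identifier: str) -> AlbersParameters:
    try:
        return _PROJECTIONS[identifier]
    except KeyError:
        raise ConfigError(
            f"unknown projection identifier {identifier!r}; "
            f"known: {sorted(_PROJECTIONS)}"
        ) from None


def albers_project(
    lon: np.ndarray, lat: np.ndarray, params: AlbersParameters | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Forward Albers Equal Area Conic on the authalic sphere, output in km.

    The spherical form is exactly area-preserving on the sphere, which is
    the property the area arithmetic needs; planar areas of projected
    (edge-densified) polygons equal their spherical areas on the authalic
    globe.
    """
    p = params or AlbersParameters()
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    phi1, phi2 = math.radians(p.lat_1), math.radians(p.lat_2)
    phi0, lam0 = math.radians(p.lat_0), math.radians(p.lon_0)
    n = 0.5 * (math.sin(phi1) + math.sin(phi2))
    c = math.cos(phi1) ** 2 + 2.0 * n * math.sin(phi1)
    rho = EARTH_RADIUS_KM / n * np.sqrt(c - 2.0 * n * np.sin(phi))
    rho0 = EARTH_RADIUS_KM / n * math.sqrt(c - 2.0 * n * math.sin(phi0))
    theta = n * (lam - lam0)
    return rho * np.sin(theta), rho0 - rho * np.cos(theta)


def project_geometry(
    g: shapely.Geometry,
    params: AlbersParameters | None = None,
    densify_deg: float = 0.05,
) -> shapely.Geometry:
    """Project a lon/lat geometry to the Albers plane.

    Edges are densified (default every 0.05°) before projection so that
    straight chords in the plane track the projected images of parallels
    and meridians and areas converge to their spherical values.
    """
    dense = shapely.segmentize(g, densify_deg)
    return shapely.transform(
        dense,
        lambda xy: np.column_stack(albers_project(xy[:, 0], xy[:, 1], params)),
    )


def spherical_cell_area_km2(lon_w: float, lat_s: float, lon_e: float, lat_n: float) -> float:
    """Closed-form area of a lon/lat cell on the authalic sphere (km²)."""
    return (
        EARTH_RADIUS_KM**2
        * math.radians(lon_e - lon_w)
        * (math.sin(math.radians(lat_n)) - math.sin(math.radians(lat_s)))
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class FieldMapping:
    """How holdings attributes are found in the input layer.

    A field set to ``None`` is declared absent; a named field must exist in
    the layer.  ``tenure_values`` maps raw values onto the canonical
    ``easement`` / ``fee`` / ``unknown`` classes.
    """

    date_field: str | None = "acquisition_date"
    tenure_field: str | None = "tenure"
    state_field: str | None = "state_name"
    date_format: str = "%Y-%m-%d"
    tenure_values: dict[str, str] = field(default_factory=dict)

    def map_tenure(self, raw: object) -> str:
        if raw is None or raw == "":
            return "unknown"
        mapped = self.tenure_values.get(str(raw), str(raw))
        return mapped if mapped in (*TENURE_CLASSES, "unknown") else "unknown"


@dataclass
class RunConfig:
    """Configuration of one assessment run (loadable from YAML)."""

    fields: FieldMapping = field(default_factory=FieldMapping)
    periods: list[PeriodDefinition] = field(default_factory=default_periods)
    projection: str = "albers-north-america"
    source_crs: str = PLANAR_KM  # or "geographic"
    rounding_precision: int = 1
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        try:
            fields = FieldMapping(**raw.get("fields", {}))
            periods = [
                PeriodDefinition(
                    label=p["label"],
                    start=dt.date.fromisoformat(p["start"]),
                    end=dt.date.fromisoformat(p["end"]),
                )
                for p in raw["periods"]
            ] if "periods" in raw else default_periods(
                dt.date.fromisoformat(raw["extraction_date"])
                if "extraction_date" in raw
                else dt.date(2011, 7, 20)
            )
            return cls(
                fields=fields,
                periods=periods,
                projection=raw.get("projection", "albers-north-america"),
                source_crs=raw.get("source_crs", PLANAR_KM),
                rounding_precision=int(raw.get("rounding_precision", 1)),
                log_level=raw.get("log_level", "INFO"),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"malformed run configuration {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Layer reading / writing
# ---------------------------------------------------------------------------


def _check_extension(path: Path) -> None:
    if path.suffix.lower() not in _SUPPORTED_EXTENSIONS:
        raise UnsupportedFormatError(
            f"unsupported format {path.suffix!r}: supported formats are "
            + ", ".join(_SUPPORTED_EXTENSIONS)
            + " (GeoJSON)"
        )


def read_layer(
    path: str | Path,
    mapping_cfg: FieldMapping | None = None,
    source_crs: str = PLANAR_KM,
    projection: str = "albers-north-america",
) -> VectorLayer:
    """Load a GeoJSON polygon layer, repairing and (if needed) projecting.

    ``source_crs='geographic'`` treats coordinates as lon/lat degrees and
    projects them to the configured equal-area frame; ``'planar-km'`` takes
    them as already-planar kilometres.  Non-polygonal features are dropped
    with a logged count; invalid polygons are repaired.
    """
    path = Path(path)
    _check_extension(path)
    if not path.exists():
        raise DataError(f"layer file not found: {path}")
    fm = mapping_cfg or FieldMapping()
    doc = json.loads(path.read_text())
    raw_features = doc.get("features", [])
    params = resolve_projection(projection)

    declared = [f for f in (fm.date_field, fm.tenure_field, fm.state_field) if f]
    if raw_features and declared:
        seen = set()
        for rf in raw_features:
            seen.update((rf.get("properties") or {}).keys())
        for name in declared:
            if name not in seen:
                raise ConfigError(
                    f"declared attribute field {name!r} missing from layer {path.name}"
                )

    feats: list[Feature] = []
    n_repaired = 0
    n_dropped = 0
    for i, rf in enumerate(raw_features):
        geom = shape(rf["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            n_dropped += 1
            continue
        if not geom.is_valid:
            n_repaired += 1
            logger.warning("feature %d of %s repaired (invalid geometry)", i, path.name)
        geom = make_valid(geom)
        if geom.is_empty:
            n_dropped += 1
            continue
        if source_crs == "geographic":
            geom = make_valid(project_geometry(geom, params))
        props = rf.get("properties") or {}
        attrs: dict[str, object] = {}
        if fm.date_field and props.get(fm.date_field) not in (None, ""):
            raw_date = str(props[fm.date_field])
            try:
                attrs["acquisition_date"] = (
                    dt.datetime.strptime(raw_date, fm.date_format).date().isoformat()
                )
            except ValueError:
                attrs["acquisition_date"] = raw_date  # kept; stratifier logs it
        if fm.tenure_field:
            attrs["tenure"] = fm.map_tenure(props.get(fm.tenure_field))
        if fm.state_field and props.get(fm.state_field) not in (None, ""):
            attrs["state_name"] = str(props[fm.state_field])
        feats.append(Feature(id=str(rf.get("id", f"record_{i}")), geometry=geom, attributes=attrs))

    logger.info(
        "%s: read %d records (%d repaired, %d non-polygonal/empty dropped)",
        path.name,
        len(feats),
        n_repaired,
        n_dropped,
    )
    tag = ALBERS_NA_KM if source_crs == "geographic" else source_crs
    return VectorLayer(feats, crs_tag=tag)


def write_layer(layer: VectorLayer, path: str | Path) -> None:
    """Write a layer as a GeoJSON FeatureCollection (deterministic bytes)."""
    path = Path(path)
    _check_extension(path)
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "id": f.id,
                "properties": dict(f.attributes),
                "geometry": mapping(f.geometry),
            }
            for f in layer
        ],
    }
    path.write_text(json.dumps(doc, separators=(",", ":"), allow_nan=False))


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (tables use 74.5 → 74.5, 74.45 → 74.5)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def _pct(value: float | None, ndigits: int) -> float | str:
    if value is None:
        return "NA"
    return round_half_away(100.0 * value, ndigits)


def _summary_row(label: str, s: AlignmentSummary, ndigits: int, with_state_pct: bool) -> dict:
    row = {
        "stratum" if not with_state_pct else "state": label,
        "land_acquired_km2": round_half_away(s.a_tnc, ndigits),
        "pct_acquisition_in_priority": _pct(s.p_tnc, ndigits),
    }
    if with_state_pct:
        row["pct_state_in_priority"] = _pct(s.p_s, ndigits)
    row["science_influence_score"] = _pct(s.score, ndigits)
    return row


def write_report(
    report: AssessmentReport,
    out_dir: str | Path,
    precision: int = 1,
    config_echo: dict | None = None,
) -> dict[str, Path]:
    """Render an assessment report as CSV tables + JSON blocks.

    Writes ``by_period.csv``, ``by_tenure.csv``, ``by_state.csv``,
    ``centroid_test.json`` and ``manifest.json`` into ``out_dir`` and
    returns the paths.  Raises :class:`DataError` if the directory cannot
    be created or written.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise DataError(f"output directory not writable: {out}: {exc}") from exc

    paths: dict[str, Path] = {}

    period_labels = [ALL_STRATUM] + [
        lab for lab in report.strata if lab not in (ALL_STRATUM, *TENURE_CLASSES)
    ]
    rows = [
        _summary_row(lab, report.strata[lab], precision, with_state_pct=False)
        for lab in period_labels
        if lab in report.strata
    ]
    paths["by_period"] = out / "by_period.csv"
    pd.DataFrame(rows).to_csv(paths["by_period"], index=False)

    tenure_rows = [
        _summary_row(lab, report.strata[lab], precision, with_state_pct=False)
        for lab in TENURE_CLASSES
        if lab in report.strata
    ]
    paths["by_tenure"] = out / "by_tenure.csv"
    pd.DataFrame(tenure_rows).to_csv(paths["by_tenure"], index=False)

    state_rows = [
        _summary_row(name, s, precision, with_state_pct=True)
        for name, s in sorted(report.by_state.items())
    ]
    paths["by_state"] = out / "by_state.csv"
    pd.DataFrame(state_rows).to_csv(paths["by_state"], index=False)

    paths["centroid_test"] = out / "centroid_test.json"
    test = report.centroid_test
    test_doc = (
        None
        if test is None
        else {
            "n_in": test.n_in,
            "n_out": test.n_out,
            "n_total": test.n_total,
            "p_null": test.p_null,
            "expected_in": test.expected_in,
            "expected_out": test.expected_out,
            "chi2": test.chi2,
            "df": test.df,
            "p_value": test.p_value,
            "small_sample": test.small_sample,
        }
    )
    paths["centroid_test"].write_text(json.dumps(test_doc, indent=2))

    echo = config_echo or {}
    manifest = {
        "software": {"name": "prioralign", "version": __version__},
        "config": echo,
        "config_hash": hashlib.sha256(
            json.dumps(echo, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_records": report.n_records,
        "n_undated": report.n_undated,
        "empty_lands": report.empty_lands,
        "timestamp": dt.datetime.now(dt.timezone.utc).isoformat(),
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return paths


def layer_manifest(manifest: dict, out_dir: str | Path) -> Path:
    """Write a simulation manifest (no timestamp: same seed, same bytes)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
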