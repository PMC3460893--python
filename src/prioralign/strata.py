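"""End-to-end alignment assessment over date/tenure strata and states.

The pipeline mirrors standard gap-analysis practice: project everything to a
planar equal-area frame (upstream, in :mod:`prioralign.io`), clip holdings
and priority areas to the jurisdiction boundaries, split the holdings into
analysis strata (all records, three acquisition periods, easements, fee
simple), dissolve each stratum so overlapping records are not double
counted, intersect with the dissolved priority layer, and summarize areas
nationally, per stratum and per state.  The centroid test runs on the
undissolved records because each record is one acquisition event.

Date strata use half-open ``[start, end)`` intervals so boundary dates are
unambiguous; records without a parseable date stay in the all-records
stratum but join no period.  Records of unknown tenure likewise join neither
tenure stratum.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

from .errors import DataError
from .geometry import VectorLayer, clip, dissolve, intersect_area
from .metrics import (
    AlignmentSummary,
    CentroidTestResult,
    centroid_chi_square,
    count_centroids_in_priorities,
    summarize_alignment,
)

logger = logging.getLogger(__name__)

#: Date on which the motivating land-interest database was extracted; the
#: last acquisition period closes at (and includes) this date by default.
DEFAULT_EXTRACTION_DATE = dt.date(2011, 7, 20)

ALL_STRATUM = "all"
UNDATED_STRATUM = "undated"
TENURE_CLASSES = ("easement", "fee")


@dataclass(frozen=True)
class PeriodDefinition:
    """A labelled half-open date interval ``[start, end)``."""

    label: str
    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"period {self.label!r}: start must precede end")

    def contains(self, day: dt.date) -> bool:
        return self.start <= day < self.end


@dataclass(frozen=True)
class StratumSpec:
    """Identifies one analysis subset of the holdings layer."""

    kind: str  # "all" | "period" | "tenure"
    period: PeriodDefinition | None = None
    tenure: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("all", "period", "tenure"):
            raise ValueError(f"unknown stratum kind {self.kind!r}")
        if (self.kind == "period") != (self.period is not None):
            raise ValueError("period strata require a PeriodDefinition, others must omit it")
        if (self.kind == "tenure") != (self.tenure is not None):
            raise ValueError("tenure strata require a tenure class, others must omit it")

    @property
    def label(self) -> str:
        if self.kind == "all":
            return ALL_STRATUM
        if self.kind == "period":
            return self.period.label
        return self.tenure


def default_periods(extraction_date: dt.date = DEFAULT_EXTRACTION_DATE) -> list[PeriodDefinition]:
    """The three standard acquisition periods, closing at the extraction date."""
    return [
        PeriodDefinition("pre-2000", dt.date(1900, 1, 1), dt.date(2000, 1, 1)),
        PeriodDefinition("2000-2005", dt.date(2000, 1, 1), dt.date(2006, 1, 1)),
        PeriodDefinition(
            "2006-2011", dt.date(2006, 1, 1), extraction_date + dt.timedelta(days=1)
        ),
    ]


def _validate_periods(periods: list[PeriodDefinition]) -> None:
    ordered = sorted(periods, key=lambda p: p.start)
    for a, b in zip(ordered, ordered[1:]):
        if a.end > b.start:
            raise ValueError(f"periods {a.label!r} and {b.label!r} overlap")


def parse_acquisition_date(value: object) -> dt.date | None:
    """Coerce an attribute value to a date; ``None`` if absent or malformed."""
    if value is None or value == "":
        return None
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    if isinstance(value, str):
        try:
            return dt.date.fromisoformat(value)
        except ValueError:
            return None
    return None


def stratify_by_date(
    layer: VectorLayer, periods: list[PeriodDefinition]
) -> dict[str, VectorLayer]:
    """Split records into period layers; undated records join none of them."""
    _validate_periods(periods)
    buckets: dict[str, list] = {p.label: [] for p in periods}
    n_undated = 0
    n_malformed = 0
    for feat in layer:
        raw = feat.attributes.get("acquisition_date")
        day = parse_acquisition_date(raw)
        if day is None:
            if raw not in (None, ""):
                n_malformed += 1
                logger.warning(
                    "record %s: malformed acquisition_date %r treated as undated",
                    feat.id,
                    raw,
                )
            n_undated += 1
            continue
        for p in periods:
            if p.contains(day):
                buckets[p.label].append(feat)
                break
    if n_undated:
        logger.info(
            "%d of %d records undated (%d malformed); kept in all-records stratum only",
            n_undated,
            len(layer),
            n_malformed,
        )
    return {
        label: VectorLayer(feats, crs_tag=layer.crs_tag) for label, feats in buckets.items()
    }


def stratify_by_tenure(layer: VectorLayer) -> dict[str, VectorLayer]:
    """Split records into easement and fee layers; unknown tenure joins neither."""
    buckets: dict[str, list] = {t: [] for t in TENURE_CLASSES}
    for feat in layer:
        tenure = feat.attributes.get("tenure", "unknown")
        if tenure in buckets:
            buckets[tenure].append(feat)
    return {
        label: VectorLayer(feats, crs_tag=layer.crs_tag) for label, feats in buckets.items()
    }


@dataclass
class AssessmentConfig:
    """Knobs of :func:`run_assessment`.

    ``strata`` picks which families of analysis subsets are computed; the
    all-records stratum is always present.  Per-state summaries and the
    centroid test can be switched off for bulk simulation work where only
    the national score is of interest.
    """

    periods: list[PeriodDefinition] = field(default_factory=default_periods)
    strata: tuple[str, ...] = ("period", "tenure")
    per_state: bool = True
    centroid_test: bool = True


@dataclass
class AssessmentReport:
    """Everything the pipeline computes in one run."""

    strata: dict[str, AlignmentSummary]
    by_state: dict[str, AlignmentSummary]
    centroid_test: CentroidTestResult | None
    n_records: int
    n_undated: int
    empty_lands: bool = False

    @property
    def national(self) -> AlignmentSummary:
        return self.strata[ALL_STRATUM]


def _state_layers(states: VectorLayer) -> dict[str, VectorLayer]:
    """Group state features by name (multi-feature states are one region)."""
    groups: dict[str, list] = {}
    for feat in states:
        name = str(feat.attributes.get("state_name", feat.id))
        groups.setdefault(name, []).append(feat)
    return {
        name: VectorLayer(feats, crs_tag=states.crs_tag) for name, feats in groups.items()
    }


def per_state_summary(
    lands_dissolved: VectorLayer,
    priorities_dissolved: VectorLayer,
    states: VectorLayer,
) -> dict[str, AlignmentSummary]:
    """Alignment areas within each state polygon.

    A state with no holdings gets a summary whose ``p_tnc`` and ``score``
    are undefined (``None``) — missing, not zero.
    """
    out: dict[str, AlignmentSummary] = {}
    for name, state_layer in _state_layers(states).items():
        a_s = dissolve(state_layer).total_area()
        lands_in = clip(lands_dissolved, state_layer)
        prio_in = clip(priorities_dissolved, state_layer)
        a_tnc = lands_in.total_area()
        a_p = prio_in.total_area()
        _, a_o = intersect_area(lands_in, prio_in, assume_dissolved=True)
        out[name] = summarize_alignment(a_o, a_tnc, a_p, a_s)
    return out


def run_assessment(
    lands: VectorLayer,
    priorities: VectorLayer,
    states: VectorLayer,
    config: AssessmentConfig | None = None,
) -> AssessmentReport:
    """Clip, stratify, dissolve, intersect, and summarize in one pass.

    Raises :class:`DataError` if the priority layer is empty (every score
    would be undefined).  An empty holdings layer yields a flagged report
    with zero areas and no centroid test.
    """
    cfg = config or AssessmentConfig()
    if not priorities.features:
        raise DataError("priority layer is empty: all scores would be undefined")

    states_dissolved = dissolve(states)
    a_s = states_dissolved.total_area()
    if a_s <= 0.0:
        raise DataError("state boundary layer has zero area")

    lands = clip(lands, states_dissolved)
    priorities_dissolved = dissolve(clip(priorities, states_dissolved))
    a_p = priorities_dissolved.total_area()

    if not lands.features:
        logger.warning("no land records after clipping; report flagged empty")
        empty = summarize_alignment(0.0, 0.0, a_p, a_s)
        return AssessmentReport(
            strata={ALL_STRATUM: empty},
            by_state={},
            centroid_test=None,
            n_records=0,
            n_undated=0,
            empty_lands=True,
        )

    subsets: dict[str, VectorLayer] = {ALL_STRATUM: lands}
    undated_feats = [
        f for f in lands if parse_acquisition_date(f.attributes.get("acquisition_date")) is None
    ]
    n_undated = len(undated_feats)
    if "period" in cfg.strata:
        subsets.update(stratify_by_date(lands, cfg.periods))
        subsets[UNDATED_STRATUM] = VectorLayer(undated_feats, crs_tag=lands.crs_tag)
    if "tenure" in cfg.strata:
        subsets.update(stratify_by_tenure(lands))

    strata: dict[str, AlignmentSummary] = {}
    lands_dissolved_all: VectorLayer | None = None
    for label, subset in subsets.items():
        dissolved = dissolve(subset)
        if label == ALL_STRATUM:
            lands_dissolved_all = dissolved
        a_tnc = dissolved.total_area()
        _, a_o = intersect_area(dissolved, priorities_dissolved, assume_dissolved=True)
        strata[label] = summarize_alignment(a_o, a_tnc, a_p, a_s)

    by_state: dict[str, AlignmentSummary] = {}
    if cfg.per_state:
        by_state = per_state_summary(lands_dissolved_all, priorities_dissolved, states)

    test: CentroidTestResult | None = None
    if cfg.centroid_test:
        n_in, n_out = count_centroids_in_priorities(lands, priorities_dissolved)
        n_total = n_in + n_out
        if n_total > 0 and 0.0 < a_p / a_s < 1.0:
            test = centroid_chi_square(n_in, n_total, a_p / a_s)

    return AssessmentReport(
        strata=strata,
        by_state=by_state,
        centroid_test=test,
        n_records=len(lands),
        n_undated=n_undated,
    )
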