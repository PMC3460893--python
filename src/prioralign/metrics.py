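"""Alignment statistics: the science influence score and the centroid test.

The science influence score asks how much the observed alignment of acquired
land with priority areas exceeds what uniform-random acquisition would give.
With

* ``P_TNC`` — fraction of acquired land area lying inside priority areas, and
* ``P_S``  — fraction of the region's area designated as priority (the
  chance-level expectation of ``P_TNC``),

the score is ``(P_TNC − P_S) / (1 − P_S)``: 0 when alignment is exactly at
chance level, 1 when every acquired hectare is inside a priority area, and
negative when alignment falls below chance.  Under the mixture reading — a
fraction ``s`` of acquisitions target priority areas deliberately, the rest
ignore them — the expected score equals ``s``.

The centroid test turns the same question into a count-based null-hypothesis
test: each record's geometric centroid either falls inside the priority
layer or not, and under the area-proportional null the inside probability is
the priority coverage fraction.  A two-cell Pearson chi-square with one
degree of freedom (no continuity correction) tests that null.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import shapely
from scipy import stats

from .errors import ScoreUndefinedError
from .geometry import VectorLayer, points_in_layer

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentSummary:
    """Area bookkeeping and score for one stratum within one region.

    Areas are km²: ``a_o`` overlap of holdings with priorities, ``a_tnc``
    total holdings, ``a_p`` total priority area, ``a_s`` region area.
    ``p_tnc`` and ``score`` are ``None`` when the stratum holds no land
    (undefined, deliberately distinct from zero).
    """

    a_o: float
    a_tnc: float
    a_p: float
    a_s: float
    p_tnc: float | None
    p_s: float
    score: float | None

    @property
    def defined(self) -> bool:
        return self.score is not None


@dataclass(frozen=True)
class CentroidTestResult:
    """Two-cell goodness-of-fit of centroid placement against coverage."""

    n_in: int
    n_out: int
    n_total: int
    p_null: float
    expected_in: float
    expected_out: float
    chi2: float
    df: int
    p_value: float
    small_sample: bool = False


def science_influence_score(p_tnc: float, p_s: float) -> float:
    """Excess of observed over chance-level alignment, normalized to ≤ 1.

    Parameters are fractions: ``p_tnc`` the observed in-priority proportion
    of acquired area, ``p_s`` the priority coverage of the region.  Raises
    :class:`ScoreUndefinedError` when ``p_s == 1`` (a fully covered region
    leaves no room for the score to discriminate).  ``p_s > p_tnc`` is a
    legitimate below-chance outcome and yields a negative score.
    """
    if not 0.0 <= p_tnc <= 1.0:
        raise ValueError(f"p_tnc must be a fraction in [0, 1], got {p_tnc}")
    if not 0.0 <= p_s <= 1.0:
        raise ValueError(f"p_s must be a fraction in [0, 1], got {p_s}")
    if p_s == 1.0:
        raise ScoreUndefinedError("score undefined: region fully covered by priorities")
    return (p_tnc - p_s) / (1.0 - p_s)


def summarize_alignment(a_o: float, a_tnc: float, a_p: float, a_s: float) -> AlignmentSummary:
    """Build an :class:`AlignmentSummary` from the four raw areas (km²)."""
    if a_s <= 0.0:
        raise ValueError("region area a_s must be positive")
    for name, val in (("a_o", a_o), ("a_tnc", a_tnc), ("a_p", a_p)):
        if val < 0.0:
            raise ValueError(f"{name} must be non-negative, got {val}")
    p_s = a_p / a_s
    if a_tnc <= 0.0:
        return AlignmentSummary(a_o, a_tnc, a_p, a_s, None, p_s, None)
    p_tnc = min(a_o / a_tnc, 1.0)
    return AlignmentSummary(a_o, a_tnc, a_p, a_s, p_tnc, p_s, science_influence_score(p_tnc, p_s))


def centroid_chi_square(n_in: int, n_total: int, p_null: float) -> CentroidTestResult:
    """Pearson chi-square (1 df, no continuity correction) for centroid counts.

    ``n_in`` records had their centroid inside the priority layer out of
    ``n_total``; the null expects a ``p_null`` fraction inside.  The p-value
    is the upper tail of the chi-square distribution with one degree of
    freedom.  An expected cell below 5 flags ``small_sample`` but the test is
    still computed.
    """
    if not 0.0 < p_null < 1.0:
        raise ValueError(f"p_null must lie strictly in (0, 1), got {p_null}")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_in <= n_total:
        raise ValueError("n_in must lie in [0, n_total]")
    n_out = n_total - n_in
    expected_in = p_null * n_total
    expected_out = (1.0 - p_null) * n_total
    chi2 = (n_in - expected_in) ** 2 / expected_in + (n_out - expected_out) ** 2 / expected_out
    p_value = float(stats.chi2.sf(chi2, df=1))
    small = expected_in < 5.0 or expected_out < 5.0
    if small:
        warnings.warn(
            "an expected cell count is below 5; the chi-square approximation is weak",
            stacklevel=2,
        )
    return CentroidTestResult(
        n_in=n_in,
        n_out=n_out,
        n_total=n_total,
        p_null=p_null,
        expected_in=expected_in,
        expected_out=expected_out,
        chi2=float(chi2),
        df=1,
        p_value=p_value,
        small_sample=small,
    )


def count_centroids_in_priorities(
    lands: VectorLayer, priorities: VectorLayer
) -> tuple[int, int]:
    """Count per-record centroids inside vs outside the priority layer.

    Operates on the undissolved layer so each record (acquisition) counts as
    one event; zero-area records cannot carry a centroid and are excluded
    with a logged warning.
    """
    pts: list[shapely.Point] = []
    dropped = 0
    for feat in lands:
        if feat.geometry.is_empty or shapely.area(feat.geometry) <= 0.0:
            dropped += 1
            continue
        pts.append(feat.geometry.centroid)
    if dropped:
        logger.warning("excluded %d zero-area records from the centroid test", dropped)
    inside = points_in_layer(pts, priorities)
    n_in = int(inside.sum())
    return n_in, len(pts) - n_in


def chi_square_p_value_closed_form(chi2: float) -> float:
    """Closed-form 1-df upper tail, ``erfc(sqrt(x/2))`` (cross-check route)."""
    return math.erfc(math.sqrt(chi2 / 2.0))
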