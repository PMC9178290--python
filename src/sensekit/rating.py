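"""Qualitative 0-3 influence rating of the aggregated comparison metrics.

Each of the four outcome metrics is binned onto a seven-level scale
(0, 0.5, 1, 1.5, 2, 2.5, 3 — "none" through "large"), with metric-specific
bin boundaries.  Exactly zero maps to 0; every bin is lower-exclusive /
upper-inclusive.  The varus and valgus directions are binned separately and
their scores averaged, which is why quarter-point combined scores (0.25,
0.75, ...) occur.  Models are always rated separately.

The default boundaries ship as a versioned YAML config
(``sensekit/data/rating_scale.yaml``) and can be overridden by the user.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .outcomes import ParameterAggregate

__all__ = [
    "METRIC_KINDS",
    "SCORES",
    "ZERO_TOLERANCE",
    "RatingError",
    "RatingScale",
    "InfluenceRating",
    "default_scales",
    "load_scales",
    "score_metric",
    "combine_directions",
    "rate_study",
    "rating_table",
]

METRIC_KINDS = ("convergence_pct", "valgus_rmse", "pressure_pct", "location_mm")
SCORES = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

#: Values with magnitude below this count as an exact zero (score 0); absorbs
#: float noise in metrics that are analytically zero.
ZERO_TOLERANCE = 1e-12


class RatingError(ValueError):
    pass


@dataclass(frozen=True)
class RatingScale:
    """Upper-inclusive bin boundaries mapping a metric value to a score.

    ``uppers`` are the finite upper bounds of the 0.5..2.5 bins; values above
    the last bound score 3.  ``x == 0`` scores 0.
    """

    metric_kind: str
    uppers: tuple[float, ...]  # strictly increasing, len == 5

    def __post_init__(self) -> None:
        if len(self.uppers) != len(SCORES) - 2:
            raise RatingError(
                f"scale for {self.metric_kind}: expected {len(SCORES) - 2} "
                f"finite bin bounds, got {len(self.uppers)}"
            )
        if any(b <= a for a, b in zip(self.uppers, self.uppers[1:])) or self.uppers[0] <= 0:
            raise RatingError(f"scale for {self.metric_kind}: bounds must be positive increasing")

    def bins(self) -> list[tuple[float, float, float]]:
        """(score, lower-exclusive, upper-inclusive) triples covering (0, inf)."""
        lowers = (0.0,) + self.uppers
        uppers = self.uppers + (math.inf,)
        return [(s, lo, hi) for s, lo, hi in zip(SCORES[1:], lowers, uppers)]


_DEFAULT_SCALE_FILE = "rating_scale.yaml"


def default_scales() -> dict[str, RatingScale]:
    """The study's rating scale, loaded from the packaged config."""
    with resources.files("sensekit.data").joinpath(_DEFAULT_SCALE_FILE).open() as fh:
        return _parse_scales(yaml.safe_load(fh))


def load_scales(path: str | Path) -> dict[str, RatingScale]:
    """Load a user-supplied rating scale YAML (same layout as the default)."""
    with open(path) as fh:
        return _parse_scales(yaml.safe_load(fh))


def _parse_scales(doc: dict) -> dict[str, RatingScale]:
    try:
        raw = doc["scales"]
    except (TypeError, KeyError):
        raise RatingError("rating scale config must contain a 'scales' mapping")
    scales = {}
    for kind in METRIC_KINDS:
        if kind not in raw:
            raise RatingError(f"rating scale config missing metric kind {kind!r}")
        scales[kind] = RatingScale(kind, tuple(float(v) for v in raw[kind]))
    return scales


def score_metric(
    metric_kind: str,
    value: float,
    scales: Mapping[str, RatingScale] | None = None,
    zero_tolerance: float = ZERO_TOLERANCE,
) -> float:
    """Bin one non-negative metric value onto the 0-3 score scale."""
    if scales is None:
        scales = default_scales()
    if metric_kind not in scales:
        raise RatingError(f"unknown metric kind {metric_kind!r}")
    if not math.isfinite(value) or value < 0:
        raise RatingError(f"metric value must be finite and >= 0, got {value}")
    if value <= zero_tolerance:
        return 0.0
    for score, lower, upper in scales[metric_kind].bins():
        if lower < value <= upper:
            return score
    raise AssertionError("bins must partition (0, inf)")  # pragma: no cover


def combine_directions(varus_score: float | None, valgus_score: float | None) -> tuple[float | None, bool]:
    """Average the per-direction scores; flag single-direction ratings.

    Returns ``(combined, partial)``.  With both directions present the
    combined score is their arithmetic mean (quarter-point values occur);
    with one absent the available score is passed through with
    ``partial=True``; with both absent the rating is unavailable.
    """
    present = [s for s in (varus_score, valgus_score) if s is not None]
    for s in present:
        if s not in SCORES:
            raise RatingError(f"score {s} is not on the rating scale")
    if not present:
        return None, False
    if len(present) == 1:
        return present[0], True
    return (varus_score + valgus_score) / 2.0, False


_METRIC_FIELDS = {
    "convergence_pct": "convergence_pct_diff",
    "valgus_rmse": "valgus_rmse",
    "pressure_pct": "pressure_pct_diff",
    "location_mm": "location_distance",
}


@dataclass(frozen=True)
class InfluenceRating:
    """Final rating of one parameter of interest on one outcome, one model."""

    model_id: str
    parameter_of_interest: str
    metric_kind: str
    varus_score: float | None
    valgus_score: float | None
    combined_score: float | None
    partial: bool
    n_excluded: int


def rate_study(
    aggregates: Mapping[str, Mapping[str, ParameterAggregate]],
    model_id: str,
    scales: Mapping[str, RatingScale] | None = None,
) -> list[InfluenceRating]:
    """Rate every (parameter of interest, metric) of one model.

    ``aggregates`` maps parameter-of-interest -> direction -> aggregate, as
    produced by the outcomes module.  Each direction is binned separately and
    the two scores averaged.
    """
    if scales is None:
        scales = default_scales()
    ratings: list[InfluenceRating] = []
    for parameter, per_direction in aggregates.items():
        n_excluded = sum(a.n_excluded for a in per_direction.values())
        for kind, attr in _METRIC_FIELDS.items():
            per_dir_scores: dict[str, float | None] = {}
            for direction in ("varus", "valgus"):
                agg = per_direction.get(direction)
                value = getattr(agg, attr) if agg is not None else None
                per_dir_scores[direction] = (
                    score_metric(kind, value, scales) if value is not None else None
                )
            combined, partial = combine_directions(
                per_dir_scores["varus"], per_dir_scores["valgus"]
            )
            ratings.append(
                InfluenceRating(
                    model_id=model_id,
                    parameter_of_interest=parameter,
                    metric_kind=kind,
                    varus_score=per_dir_scores["varus"],
                    valgus_score=per_dir_scores["valgus"],
                    combined_score=combined,
                    partial=partial,
                    n_excluded=n_excluded,
                )
            )
    return ratings


def rating_table(ratings: Sequence[InfluenceRating]) -> pd.DataFrame:
    """Flat rating matrix (model x parameter x metric kind)."""
    return pd.DataFrame(
        {
            "model_id": r.model_id,
            "parameter_of_interest": r.parameter_of_interest,
            "metric_kind": r.metric_kind,
            "varus_score": r.varus_score,
            "valgus_score": r.valgus_score,
            "combined_score": r.combined_score,
            "partial": r.partial,
            "n_excluded": r.n_excluded,
        }
        for r in ratings
    )
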