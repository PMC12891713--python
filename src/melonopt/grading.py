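"""Fruit grading and market-grade scoring.

Two graded attributes drive melon market value: soluble solids (Brix) and the
visual quality of the rind netting (panel score, 1 excellent .. 5 bad). Brix
maps to four market tiers (Premium >= 14, Superior 12-14, Medium 10-12,
Inferior < 10 degrees Brix; intervals closed at the lower bound). Sugar is
min-max normalized to 0-100 and the netting score reverse-normalized (lower
panel scores are better); a channel-weighted combination

    market grade = alpha * sugar_score + beta * netting_score

gives the 0-100 composite used as the "quality" objective downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GRADE_TIERS, FruitRecord, MarketWeights, records_to_frame
from .exceptions import DomainError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GradeThresholds:
    """Brix cut points (strictly decreasing) and panel-score tier mapping.

    ``net_tiers`` maps the rounded panel score to a tier; scores >= the largest
    key fall in the lowest mapped tier.
    """

    brix_cuts: tuple[float, float, float] = (14.0, 12.0, 10.0)
    net_tiers: Mapping[int, str] = field(
        default_factory=lambda: {1: "Premium", 2: "Superior", 3: "Medium", 4: "Inferior"}
    )

    def __post_init__(self) -> None:
        if not (self.brix_cuts[0] > self.brix_cuts[1] > self.brix_cuts[2]):
            raise ValidationError(f"brix cuts must be strictly decreasing, got {self.brix_cuts}")
        if set(self.net_tiers.values()) - set(GRADE_TIERS):
            raise ValidationError("net tier mapping uses unknown tiers")


DEFAULT_THRESHOLDS = GradeThresholds()


@dataclass(frozen=True)
class NormalizationBounds:
    """Observed min/max of a response over the comparison set."""

    min_value: float
    max_value: float

    def __post_init__(self) -> None:
        if self.max_value < self.min_value:
            raise ValidationError(
                f"max_value {self.max_value} < min_value {self.min_value}"
            )

    @property
    def span(self) -> float:
        return self.max_value - self.min_value


@dataclass(frozen=True)
class MarketGradeScore:
    sugar_score: float
    net_score_norm: float
    composite: float
    weights: MarketWeights


def brix_grade(brix: float, thresholds: GradeThresholds = DEFAULT_THRESHOLDS) -> str:
    """Market tier for a Brix reading; lower interval bounds are inclusive."""
    if brix <= 0:
        raise DomainError(f"brix must be > 0, got {brix}")
    hi, mid, lo = thresholds.brix_cuts
    if brix >= hi:
        return "Premium"
    if brix >= mid:
        return "Superior"
    if brix >= lo:
        return "Medium"
    return "Inferior"


def net_grade(net_score: float, thresholds: GradeThresholds = DEFAULT_THRESHOLDS) -> str:
    """Market tier for a panel netting score (rounded to the nearest level)."""
    if not 1.0 <= net_score <= 5.0:
        raise DomainError(f"net_score must lie in [1, 5], got {net_score}")
    level = int(round(net_score))
    keys = sorted(thresholds.net_tiers)
    level = min(level, keys[-1])
    return thresholds.net_tiers[level]


def _normalize(observed: float, bounds: NormalizationBounds, reverse: bool) -> float:
    if bounds.span == 0:
        raise DomainError("degenerate bounds: max equals min")
    if observed < bounds.min_value or observed > bounds.max_value:
        logger.warning(
            "observed value %.6g outside bounds [%g, %g]; clamped",
            observed, bounds.min_value, bounds.max_value,
        )
        observed = min(max(observed, bounds.min_value), bounds.max_value)
    if reverse:
        return (bounds.max_value - observed) / bounds.span * 100.0
    return (observed - bounds.min_value) / bounds.span * 100.0


def normalize_sugar(observed: float, bounds: NormalizationBounds) -> float:
    """0-100 min-max score for Brix (higher Brix -> higher score)."""
    return _normalize(observed, bounds, reverse=False)


def reverse_normalize_net(observed: float, bounds: NormalizationBounds) -> float:
    """0-100 reverse min-max score for netting (lower panel score is better)."""
    return _normalize(observed, bounds, reverse=True)


def market_grade_score(
    sugar_score: float, net_score_norm: float, weights: MarketWeights
) -> MarketGradeScore:
    """Channel-weighted composite of normalized sugar and netting scores."""
    for name, v in (("sugar_score", sugar_score), ("net_score_norm", net_score_norm)):
        if not 0.0 <= v <= 100.0:
            raise ValidationError(f"{name} must lie in [0, 100], got {v}")
    composite = weights.alpha * sugar_score + weights.beta * net_score_norm
    return MarketGradeScore(
        sugar_score=sugar_score,
        net_score_norm=net_score_norm,
        composite=composite,
        weights=weights,
    )


def _as_frame(records: Iterable[FruitRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(list(records))


def _treatment_labels(df: pd.DataFrame) -> pd.Series:
    return (
        df["cultivar"].astype(str)
        + "/" + df["substrate_volume"].map("{:g}".format) + "L"
        + "/" + df["plants_per_slab"].astype(int).astype(str) + "p"
    )


def grade_distribution(
    records: Iterable[FruitRecord] | pd.DataFrame,
    by: str = "brix",
    thresholds: GradeThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-treatment tier percentages (rows sum to 100).

    ``by='brix'`` grades on sugar tiers; ``by='net'`` on the panel-score
    mapping. Treatments with no fruit are excluded with a logged warning.
    """
    if by not in ("brix", "net"):
        raise ValidationError(f"by must be 'brix' or 'net', got {by!r}")
    df = _as_frame(records).copy()
    if df.empty:
        raise DomainError("no fruit records supplied")
    grader = brix_grade if by == "brix" else net_grade
    df["tier"] = df[by if by == "brix" else "net_score"].map(
        lambda v: grader(v, thresholds)
    )
    df["treatment"] = _treatment_labels(df)
    counts = (
        df.groupby("treatment", sort=False)["tier"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(GRADE_TIERS), fill_value=0)
    )
    totals = counts.sum(axis=1)
    empty = totals[totals == 0].index.tolist()
    if empty:
        logger.warning("treatments with no fruit excluded: %s", empty)
        counts = counts.drop(index=empty)
        totals = totals.drop(index=empty)
    return counts.div(totals, axis=0) * 100.0


def bounds_from_values(values: Sequence[float]) -> NormalizationBounds:
    arr = np.asarray(list(values), dtype=float)
    return NormalizationBounds(min_value=float(arr.min()), max_value=float(arr.max()))


def quality_scores_from_means(
    means: pd.DataFrame, weights: MarketWeights = None
) -> pd.Series:
    """Composite quality score per treatment from mean Brix and net score.

    ``means`` needs columns ``brix`` and ``net_score`` indexed by treatment.
    Normalization bounds are taken jointly over all rows, so the score ranks
    treatments within the trial. A degenerate column (all means equal) scores
    0 everywhere with a logged warning rather than raising.
    """
    from .core_io import PREMIUM_CHANNEL

    if weights is None:
        weights = PREMIUM_CHANNEL
    for col in ("brix", "net_score"):
        if col not in means.columns:
            raise ValidationError(f"means table missing column {col!r}")

    def _col_scores(col: str, reverse: bool) -> pd.Series:
        b = bounds_from_values(means[col])
        if b.span == 0:
            logger.warning("degenerate bounds for %s (all means equal); scores set to 0", col)
            return pd.Series(0.0, index=means.index)
        return means[col].map(lambda v: _normalize(v, b, reverse=reverse))

    sugar = _col_scores("brix", reverse=False)
    net = _col_scores("net_score", reverse=True)
    return weights.alpha * sugar + weights.beta * net


def treatment_quality_score(
    records: Iterable[FruitRecord] | pd.DataFrame,
    weights: MarketWeights = None,
) -> pd.Series:
    """Per-treatment composite quality from per-fruit data.

    Treatment means of Brix and net score are computed first; normalization
    bounds come from the full set of treatment means (the whole trial), so the
    treatment holding both trial maxima scores 100 and the joint minimum 0.
    """
    df = _as_frame(records).copy()
    if df.empty:
        raise DomainError("no fruit records supplied")
    df["treatment"] = _treatment_labels(df)
    means = df.groupby("treatment", sort=False)[["brix", "net_score"]].mean()
    return quality_scores_from_means(means, weights)
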