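"""Per-criterion scoring: the linear price function and category lookup.

The price scoring function is anchored to the lowest eligible bid p_min and a
voted cut-off excess c: the lowest bid earns the full price score, and the
score falls linearly to zero at p_min * (1 + c); any bid at or beyond the
cut-off earns zero. With c = 2.0 (+200%) a bid at twice the lowest price
earns exactly half of the price points. Keeping the zero point at a fixed
excess — rather than at the most expensive competitor — makes the function
independent of the price distribution of the field.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import PriceError
from .model import Criterion


@dataclass(frozen=True)
class PriceContext:
    """Anchors of the price function: lowest eligible bid and cut-off excess."""

    p_min: float
    cutoff_excess: float

    def __post_init__(self) -> None:
        if self.p_min <= 0:
            raise PriceError(f"p_min must be positive, got {self.p_min}")
        if self.cutoff_excess <= 0:
            raise PriceError(f"cutoff_excess must be positive, got {self.cutoff_excess}")


@dataclass(frozen=True)
class CriterionScore:
    """A product's score on one criterion.

    ``raw_fraction`` is the unweighted score in [0, 1]; ``weighted`` is
    raw_fraction times the criterion weight. For an exclusion category both
    are stored as 0 and ``excluded`` is set.
    """

    criterion_id: str
    raw_fraction: float
    weighted: float
    excluded: bool = False


def price_score(p: float, ctx: PriceContext) -> float:
    """Fraction of the maximum price points for a bid of p.

    s = clamp(1 - ((p - p_min)/p_min) / c, 0, 1): 1 at the lowest bid,
    0 at or beyond the cut-off. Bids below p_min mean the context was built
    without all eligible bids and are an error.
    """
    if p <= 0:
        raise PriceError(f"bid price must be positive, got {p}")
    if p < ctx.p_min:
        raise PriceError(
            f"bid {p} is below p_min {ctx.p_min}; build the context from all eligible bids"
        )
    s = 1.0 - ((p - ctx.p_min) / ctx.p_min) / ctx.cutoff_excess
    return min(1.0, max(0.0, s))


def category_score(criterion: Criterion, label: str) -> CriterionScore:
    """Score one product on one non-price criterion by its selected category.

    Unknown labels raise, listing the valid ones (exact, case-sensitive match).
    A selection in an exclusion category yields an exclusion-flagged score.
    """
    if criterion.is_price:
        raise PriceError(
            f"criterion {criterion.id!r} is the price criterion; use price_score"
        )
    cat = criterion.category(label)
    if cat.is_exclusion:
        return CriterionScore(criterion.id, raw_fraction=0.0, weighted=0.0, excluded=True)
    weight = criterion.weight
    if weight is None:
        raise PriceError(f"criterion {criterion.id!r} has no weight set (draft framework?)")
    return CriterionScore(
        criterion.id,
        raw_fraction=cat.score_fraction,
        weighted=cat.score_fraction * weight,
    )
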