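"""Tender evaluation: composite scoring, ranking, winners, sensitivity sweeps.

A tender is a set of competing products, each described by its bid price and
one selected performance category per non-price criterion (the performance
matrix). Each eligible product receives a composite score

    S = sum_i w_i * s_i,

the weighted sum of its per-criterion score fractions, including the price
criterion scored by the linear price function. Products that hit an exclusion
category are disqualified: they receive no composite and no rank, and by
default they are removed before the lowest bid p_min is determined, so a
disqualified bid cannot distort competitors' price scores (``price_basis="all"``
restores the alternative).

Ranking is by descending composite; exact ties break by lower bid price, then
lexicographic product id, and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import pandas as pd

from .errors import FrameworkInvalidError, McdaError, SelectionError
from .model import Framework, validate_framework
from .scoring import CriterionScore, PriceContext, category_score, price_score

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class ProductProfile:
    """One candidate product: bid price plus its performance selections."""

    product_id: str
    price: float
    selections: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "selections", dict(self.selections))


@dataclass(frozen=True)
class ProductResult:
    product_id: str
    price: float
    scores: tuple[CriterionScore, ...]
    composite: float | None
    excluded: bool
    rank: int | None
    tied: bool = False


@dataclass(frozen=True)
class EvaluationResult:
    """Full outcome of one tender evaluation."""

    products: tuple[ProductResult, ...]
    p_min: float | None
    framework_name: str
    framework_hash: str
    price_weight: float
    price_cutoff_excess: float

    @property
    def ranked(self) -> tuple[ProductResult, ...]:
        return tuple(
            sorted(
                (p for p in self.products if p.rank is not None),
                key=lambda p: p.rank,  # type: ignore[arg-type]
            )
        )

    @property
    def excluded_ids(self) -> tuple[str, ...]:
        return tuple(p.product_id for p in self.products if p.excluded)

    def winners(self, n: int = 1) -> tuple[str, ...]:
        return tuple(p.product_id for p in self.ranked[: max(n, 0)])

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per product, one column per criterion."""
        rows = []
        for p in self.products:
            row: dict = {
                "product": p.product_id,
                "price": p.price,
                "composite": p.composite,
                "rank": p.rank,
                "excluded": p.excluded,
                "tied": p.tied,
            }
            for s in p.scores:
                row[f"score:{s.criterion_id}"] = s.raw_fraction
            rows.append(row)
        return pd.DataFrame(rows).set_index("product")


def evaluate_tender(
    products: Sequence[ProductProfile],
    fw: Framework,
    price_basis: Literal["eligible", "all"] = "eligible",
) -> EvaluationResult:
    """Score and rank every product in a tender under a weighted framework."""
    if not products:
        raise McdaError("a tender needs at least one product")
    violations = validate_framework(fw)
    if violations or not fw.is_weighted:
        if not violations:
            raise McdaError("framework is not weighted; run the elicitation first")
        raise FrameworkInvalidError(violations)
    if fw.price_cutoff_excess is None:
        raise McdaError("framework has no price cut-off; cannot score prices")

    ids = [p.product_id for p in products]
    if len(set(ids)) != len(ids):
        raise McdaError("duplicate product ids in tender")

    nonprice = fw.nonprice_criteria
    wanted = {c.id for c in nonprice}
    for p in products:
        if p.price <= 0:
            raise McdaError(f"product {p.product_id!r}: bid price must be positive")
        missing = wanted - set(p.selections)
        if missing:
            raise SelectionError(
                f"product {p.product_id!r} is missing a selection for "
                f"criteria {sorted(missing)}"
            )
        extra = set(p.selections) - wanted
        if extra:
            raise SelectionError(
                f"product {p.product_id!r} selects unknown criteria {sorted(extra)}"
            )

    # first pass: category scores and exclusion flags
    cat_scores: dict[str, list[CriterionScore]] = {}
    excluded_flags: dict[str, bool] = {}
    for p in products:
        scores = [category_score(fw.criterion(cid), p.selections[cid]) for cid in
                  (c.id for c in nonprice)]
        cat_scores[p.product_id] = scores
        excluded_flags[p.product_id] = any(s.excluded for s in scores)

    basis = [
        p for p in products
        if price_basis == "all" or not excluded_flags[p.product_id]
    ]
    price_crit = fw.price_criterion
    if not basis:
        # every product disqualified: an explicit "no eligible bids" result
        results = tuple(
            ProductResult(
                p.product_id, p.price, tuple(cat_scores[p.product_id]),
                composite=None, excluded=True, rank=None,
            )
            for p in products
        )
        return EvaluationResult(
            products=results, p_min=None,
            framework_name=fw.name, framework_hash=fw.content_hash(),
            price_weight=fw.price_weight,  # type: ignore[arg-type]
            price_cutoff_excess=fw.price_cutoff_excess,
        )

    ctx = PriceContext(
        p_min=min(p.price for p in basis), cutoff_excess=fw.price_cutoff_excess
    )

    scored: list[ProductResult] = []
    for p in products:
        scores = list(cat_scores[p.product_id])
        if excluded_flags[p.product_id]:
            scored.append(
                ProductResult(p.product_id, p.price, tuple(scores),
                              composite=None, excluded=True, rank=None)
            )
            continue
        s_price = price_score(p.price, ctx)
        scores.append(
            CriterionScore(price_crit.id, s_price, s_price * price_crit.weight)  # type: ignore[operator]
        )
        composite = sum(s.weighted for s in scores)
        scored.append(
            ProductResult(p.product_id, p.price, tuple(scores),
                          composite=composite, excluded=False, rank=None)
        )

    eligible = [p for p in scored if not p.excluded]
    eligible.sort(key=lambda p: (-p.composite, p.price, p.product_id))  # type: ignore[operator]
    ranked: dict[str, tuple[int, bool]] = {}
    for i, p in enumerate(eligible):
        tie = any(
            abs(p.composite - q.composite) <= _TIE_TOL  # type: ignore[operator]
            for q in eligible
            if q.product_id != p.product_id
        )
        ranked[p.product_id] = (i + 1, tie)

    final = tuple(
        p if p.excluded else replace(p, rank=ranked[p.product_id][0],
                                     tied=ranked[p.product_id][1])
        for p in scored
    )
    return EvaluationResult(
        products=final,
        p_min=ctx.p_min,
        framework_name=fw.name,
        framework_hash=fw.content_hash(),
        price_weight=fw.price_weight,  # type: ignore[arg-type]
        price_cutoff_excess=fw.price_cutoff_excess,
    )


def select_winners(result: EvaluationResult, n_winners: int) -> tuple[str, ...]:
    """Top-min(n_winners, #eligible) product ids by rank.

    Tenders may nominate multiple winners to keep manufacturers participating;
    n_winners larger than the eligible field simply returns everyone ranked.
    """
    if n_winners < 1:
        raise McdaError(f"n_winners must be >= 1, got {n_winners}")
    return result.winners(n_winners)


def reweighted(fw: Framework, price_weight: float) -> Framework:
    """A copy of ``fw`` with a new price weight.

    Non-price criteria keep their elicited relative proportions; only the
    rescaling against the price weight is redone (mirroring the workshop's
    adjustment step, which re-voted price parameters but not the swing ladder).
    """
    if not 0.0 < price_weight < 1.0:
        raise McdaError(f"price weight {price_weight} must lie in (0, 1)")
    if not fw.is_weighted or fw.price_weight is None:
        raise McdaError("cannot reweight an unweighted framework")
    rest = 1.0 - fw.price_weight
    weights = {}
    for c in fw.criteria:
        if c.is_price:
            weights[c.id] = price_weight
        else:
            weights[c.id] = (c.weight / rest) * (1.0 - price_weight)  # type: ignore[operator]
    return fw.with_weights(weights, price_weight=price_weight)


def sensitivity_sweep(
    products: Sequence[ProductProfile],
    fw: Framework,
    parameter: Literal["price_weight", "price_cutoff"],
    grid: Sequence[float],
) -> pd.DataFrame:
    """Re-evaluate the tender across a grid of price-weight or cut-off values.

    Returns one row per grid value with the full ranking (best first, as
    "a > b > c"), the winner, and whether the ranking/winner changed relative
    to the framework as given.
    """
    if parameter not in ("price_weight", "price_cutoff"):
        raise McdaError(f"unknown sweep parameter {parameter!r}")
    if not grid:
        raise McdaError("sweep grid must be non-empty")
    base = evaluate_tender(products, fw)
    base_ranking = [p.product_id for p in base.ranked]
    rows = []
    for value in grid:
        value = float(value)
        if parameter == "price_weight":
            if not 0.0 < value < 1.0:
                raise McdaError(f"price weight {value} must lie in (0, 1)")
            fw_v = reweighted(fw, value)
        else:
            if value <= 0:
                raise McdaError(f"price cut-off excess {value} must be > 0")
            fw_v = replace(fw, price_cutoff_excess=value)
        res = evaluate_tender(products, fw_v)
        ranking = [p.product_id for p in res.ranked]
        rows.append(
            {
                "parameter": parameter,
                "value": value,
                "ranking": " > ".join(ranking),
                "winner": ranking[0] if ranking else None,
                "ranking_changed": ranking != base_ranking,
                "winner_changed": (ranking[:1] != base_ranking[:1]),
                "n_excluded": len(res.excluded_ids),
            }
        )
    return pd.DataFrame(rows)
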