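"""Weight elicitation from workshop vote records.

The elicitation protocol turns anonymous group votes into a complete weight
vector, in five steps:

1. *Price weight*: participants vote a weight for the price criterion on a
   5%-step grid from 5% to 100%; the median vote is taken to damp outliers.
2. *Price cut-off*: a vote on the excess over the lowest bid at which the
   price score reaches zero (grid 25%..500%), again reduced by the median.
3. *Modified SMART ranking*: starting from a hypothetical worst-case product,
   participants repeatedly vote which criterion should be "swung" from worst
   to best level; round k's plurality winner is the k-th most important
   criterion, and a single unvoted criterion falls to the last rank.
4. *Swing weighting*: the least important criterion is anchored at 10 points;
   for each step up the ranking participants vote a percentage increment
   (0..50% by 5%, then 60..100% by 10%) and points accumulate
   multiplicatively: P_{k+1} = P_k * (1 + delta_{k+1}). A 0% increment
   encodes equal importance.
5. *Two-stage normalization*: ladder points are normalized to relative
   non-price weights, then rescaled by (1 - price weight) so the full weight
   vector sums to one. Optional adjustment rounds override the initial price
   weight and cut-off medians.

Criteria voted out by simple majority (strictly more than half of the cast
votes) are dropped before ranking.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ElicitationError, VoteError
from .model import Framework, Violation, validate_framework
from .errors import FrameworkInvalidError

_GRID_TOL = 1e-9


@dataclass(frozen=True)
class OptionGrid:
    """An ordered set of allowed vote values (fractions)."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if not vals:
            raise VoteError("option grid must be non-empty")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise VoteError("option grid values must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __contains__(self, x: object) -> bool:
        try:
            xf = float(x)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            return False
        return any(abs(xf - v) <= _GRID_TOL for v in self.values)

    def snap(self, x: float) -> float:
        """Nearest grid value; an exact midpoint snaps to the lower value."""
        best = self.values[0]
        best_d = abs(x - best)
        for v in self.values[1:]:
            d = abs(x - v)
            if d < best_d - _GRID_TOL:
                best, best_d = v, d
            # ties keep the earlier (lower) value
        return best


def _steps(start: float, stop: float, step: float) -> list[float]:
    n = round((stop - start) / step)
    return [round(start + i * step, 10) for i in range(n + 1)]


#: price-weight votes: 5% to 100% by 5% increments
PRICE_WEIGHT_GRID = OptionGrid(tuple(_steps(0.05, 1.00, 0.05)))
#: swing increments: 0 to +50% by 5%, then +50% to +100% by 10%
SWING_GRID = OptionGrid(tuple(_steps(0.00, 0.50, 0.05) + _steps(0.60, 1.00, 0.10)))
#: price cut-off excess: +25% to +500% by 25%
CUTOFF_GRID = OptionGrid(tuple(_steps(0.25, 5.00, 0.25)))

#: sentinel option for "exclude nothing" in exclusion rounds
NO_EXCLUSION = "none"


@dataclass(frozen=True)
class VotingRound:
    """One elicitation round: a purpose tag, the allowed grid, and cast votes.

    Numeric rounds (price weight, cut-off, swing steps) carry a grid and
    fractional vote values; categorical rounds (SMART, exclusion) vote over
    criterion ids and carry no grid.
    """

    purpose: str
    votes: tuple
    grid: OptionGrid | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "votes", tuple(self.votes))
        if not self.votes:
            raise VoteError(f"round {self.purpose!r}: no votes cast")
        if self.grid is not None:
            for v in self.votes:
                if v not in self.grid:
                    raise VoteError(
                        f"round {self.purpose!r}: vote {v!r} is not on the option grid"
                    )

    @property
    def n(self) -> int:
        return len(self.votes)

    def tallies(self) -> Counter:
        return Counter(self.votes)


def median_vote(round: VotingRound) -> float:
    """Median of the cast votes, closed on the round's grid.

    Odd n: the middle order statistic (necessarily on the grid). Even n: the
    mean of the two middle votes, snapped to the nearest grid value with exact
    midpoints snapping downward.
    """
    if round.grid is None:
        raise VoteError(f"round {round.purpose!r} is categorical; no numeric median")
    votes = sorted(float(v) for v in round.votes)
    n = len(votes)
    if n % 2 == 1:
        return round.grid.snap(votes[n // 2])
    mid = 0.5 * (votes[n // 2 - 1] + votes[n // 2])
    return round.grid.snap(mid)


@dataclass(frozen=True)
class SmartRanking:
    """Outcome of the modified SMART process: ids ordered most -> least important."""

    order: tuple[str, ...]
    #: ranks (1-based) where the plurality was tied and broken lexicographically
    tied_ranks: tuple[int, ...] = ()


def smart_rank(rounds: Sequence[VotingRound], candidates: Iterable[str]) -> SmartRanking:
    """Rank criteria by sequential plurality votes.

    Round k's winner takes rank k; ties break lexicographically by criterion
    id and are recorded. If exactly one candidate is left unranked after all
    rounds it becomes the last rank; more than one left is an error (the vote
    record is incomplete).
    """
    remaining = sorted(set(candidates))
    order: list[str] = []
    tied: list[int] = []
    for rnd in rounds:
        tally = rnd.tallies()
        for cid in tally:
            if cid not in remaining:
                raise VoteError(
                    f"round {rnd.purpose!r}: criterion {cid!r} is not an unranked candidate"
                )
        top = max(tally.values())
        winners = sorted(cid for cid, k in tally.items() if k == top)
        if len(winners) > 1:
            tied.append(len(order) + 1)
        winner = winners[0]
        order.append(winner)
        remaining.remove(winner)
    if len(remaining) > 1:
        raise ElicitationError(
            f"SMART rounds leave {len(remaining)} criteria unranked: {remaining}"
        )
    order.extend(remaining)
    return SmartRanking(order=tuple(order), tied_ranks=tuple(tied))


@dataclass(frozen=True)
class SwingLadder:
    """Accumulated swing-weighting points.

    ``ranking`` is ordered least -> most important; ``points[k]`` is the
    criterion's accumulated point value, starting from ``base_points`` at the
    bottom rung and growing by the voted increment at each step.
    """

    ranking: tuple[str, ...]
    increments: tuple[float, ...]
    points: tuple[float, ...]
    base_points: float = 10.0


def swing_points(
    ranking: Sequence[str],
    increments: Sequence[float],
    base_points: float = 10.0,
) -> SwingLadder:
    """Accumulate ladder points: P_1 = base; P_{k+1} = P_k * (1 + delta_{k+1}).

    ``ranking`` is least -> most important; ``increments[k]`` is the voted
    step from rung k to rung k+1 (a fraction, >= 0; 0 means equal importance).
    """
    ranking = list(ranking)
    increments = [float(d) for d in increments]
    if len(increments) != max(len(ranking) - 1, 0):
        raise ElicitationError(
            f"need {len(ranking) - 1} increments for {len(ranking)} criteria, "
            f"got {len(increments)}"
        )
    for d in increments:
        if d < 0:
            raise ElicitationError(f"negative swing increment {d}")
    points = [float(base_points)]
    for d in increments:
        points.append(points[-1] * (1.0 + d))
    return SwingLadder(
        ranking=tuple(ranking),
        increments=tuple(increments),
        points=tuple(points[: len(ranking)]),
        base_points=float(base_points),
    )


def normalize_nonprice(ladder: SwingLadder) -> dict[str, float]:
    """Ladder points normalized to relative non-price weights (sum 1)."""
    total = sum(ladder.points)
    if total <= 0:
        raise ElicitationError("swing ladder has zero total points")
    return {cid: p / total for cid, p in zip(ladder.ranking, ladder.points)}


def combine_with_price(
    nonprice_weights: Mapping[str, float],
    price_weight: float,
    price_id: str = "price",
) -> dict[str, float]:
    """Rescale non-price weights by (1 - w_p) and add the price criterion.

    The result is the final weight vector: price gets ``price_weight`` and
    every non-price criterion keeps its relative proportion of the remainder.
    """
    if not 0.0 < price_weight < 1.0:
        raise ElicitationError(f"price weight {price_weight} must lie in (0, 1)")
    total = sum(nonprice_weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ElicitationError(f"non-price weights sum to {total:.6g}, not 1")
    out = {cid: w * (1.0 - price_weight) for cid, w in nonprice_weights.items()}
    if price_id in out:
        raise ElicitationError(f"price id {price_id!r} collides with a non-price criterion")
    out[price_id] = price_weight
    return out


# ---------------------------------------------------------------------------
# Full elicitation pipeline

_SMART_RE = re.compile(r"^smart_round_(\d+)$")
_SWING_RE = re.compile(r"^swing_step_(\d+)$")
_EXCL_RE = re.compile(r"^exclusion_vote(?:_\d+)?$")


@dataclass(frozen=True)
class ElicitationRecord:
    """Everything the elicitation computed, for reporting and auditing."""

    framework: Framework
    price_weight_initial: float
    price_weight: float
    price_cutoff_initial: float
    price_cutoff: float
    excluded: tuple[str, ...]
    smart: SmartRanking
    ladder: SwingLadder
    nonprice_weights: dict[str, float] = field(default_factory=dict)
    final_weights: dict[str, float] = field(default_factory=dict)


def default_grid_for(purpose: str) -> OptionGrid | None:
    """The documented option grid for a round purpose (None for categorical)."""
    if purpose.startswith("price_weight"):
        return PRICE_WEIGHT_GRID
    if purpose.startswith("price_cutoff"):
        return CUTOFF_GRID
    if _SWING_RE.match(purpose):
        return SWING_GRID
    if _SMART_RE.match(purpose) or _EXCL_RE.match(purpose):
        return None
    raise VoteError(f"unknown round purpose {purpose!r}")


def run_elicitation(draft: Framework, rounds: Sequence[VotingRound]) -> ElicitationRecord:
    """Run the whole protocol on a draft framework and return the full record."""
    by_purpose: dict[str, VotingRound] = {}
    for rnd in rounds:
        if rnd.purpose in by_purpose:
            raise VoteError(f"duplicate round purpose {rnd.purpose!r}")
        by_purpose[rnd.purpose] = rnd

    missing = [p for p in ("price_weight", "price_cutoff") if p not in by_purpose]
    if missing:
        raise ElicitationError(f"missing required voting rounds: {missing}")

    w_p_initial = median_vote(by_purpose["price_weight"])
    cutoff_initial = median_vote(by_purpose["price_cutoff"])
    w_p = w_p_initial
    cutoff = cutoff_initial
    if "price_weight_adjustment" in by_purpose:
        w_p = median_vote(by_purpose["price_weight_adjustment"])
    if "price_cutoff_adjustment" in by_purpose:
        cutoff = median_vote(by_purpose["price_cutoff_adjustment"])

    nonprice_ids = [c.id for c in draft.nonprice_criteria]

    # majority-vote exclusions: a criterion named by strictly more than half
    # of a round's votes is dropped before ranking
    excluded: list[str] = []
    for purpose, rnd in by_purpose.items():
        if not _EXCL_RE.match(purpose):
            continue
        tally = rnd.tallies()
        for cid, count in tally.items():
            if cid == NO_EXCLUSION:
                continue
            if cid not in nonprice_ids:
                raise VoteError(
                    f"round {purpose!r}: {cid!r} is not a non-price criterion of the draft"
                )
            if count * 2 > rnd.n and cid not in excluded:
                excluded.append(cid)
    kept_ids = [cid for cid in nonprice_ids if cid not in excluded]
    if not kept_ids:
        raise ElicitationError("every non-price criterion was excluded by majority vote")

    smart_rounds = sorted(
        ((int(m.group(1)), rnd) for p, rnd in by_purpose.items() if (m := _SMART_RE.match(p))),
        key=lambda kv: kv[0],
    )
    smart = smart_rank([rnd for _, rnd in smart_rounds], kept_ids)

    m = len(kept_ids)
    swing_rounds = sorted(
        ((int(g.group(1)), rnd) for p, rnd in by_purpose.items() if (g := _SWING_RE.match(p))),
        key=lambda kv: kv[0],
    )
    if len(swing_rounds) != m - 1 or [k for k, _ in swing_rounds] != list(range(1, m)):
        raise ElicitationError(
            f"need swing_step_1..swing_step_{m - 1} for {m} ranked criteria, "
            f"got {[f'swing_step_{k}' for k, _ in swing_rounds]}"
        )
    increments = [median_vote(rnd) for _, rnd in swing_rounds]

    ladder = swing_points(list(reversed(smart.order)), increments)
    nonprice_weights = normalize_nonprice(ladder)
    price_id = draft.price_criterion.id
    final = combine_with_price(nonprice_weights, w_p, price_id=price_id)

    criteria = tuple(c for c in draft.criteria if c.id not in excluded)
    fw = Framework(
        criteria=criteria,
        name=draft.name,
        version=draft.version,
        notes=draft.notes,
    ).with_weights(final, price_weight=w_p, price_cutoff_excess=cutoff)
    violations: list[Violation] = validate_framework(fw)
    if violations:
        raise FrameworkInvalidError(violations)
    return ElicitationRecord(
        framework=fw,
        price_weight_initial=w_p_initial,
        price_weight=w_p,
        price_cutoff_initial=cutoff_initial,
        price_cutoff=cutoff,
        excluded=tuple(excluded),
        smart=smart,
        ladder=ladder,
        nonprice_weights=nonprice_weights,
        final_weights=final,
    )


def elicit_framework(
    draft: Framework, votes: Sequence[VotingRound] | str | Path
) -> Framework:
    """Turn a draft framework plus a vote record into a weighted framework.

    ``votes`` may be a sequence of :class:`VotingRound` or a path to a vote
    CSV (columns ``round_purpose, option_value, vote_count``).
    """
    if isinstance(votes, (str, Path)):
        from .io import read_votes

        votes = read_votes(votes)
    return run_elicitation(draft, votes).framework
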