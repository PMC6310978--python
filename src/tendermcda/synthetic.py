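"""Synthetic tenders and synthetic vote sessions.

Two generators back the test pyramid:

* :func:`generate_tender` draws hypothetical competing products in the shape
  of the packaged test cases: one bid price (a log-uniform multiplicative
  spread over a reference price, default factors [1.0, 2.5], with one product
  anchored at the low end so the reference is the lowest bid) and one selected
  performance category per non-price criterion (default uniform over the
  non-exclusion levels; exclusion levels get an explicit probability).

* :func:`generate_votes` draws a full elicitation session around a stated
  true preference. Numeric votes are the preferred grid value displaced by a
  discretized symmetric number of grid steps (rounded Normal(0, dispersion));
  ranking and exclusion votes err with probability dispersion/(1+dispersion).
  With dispersion 0 every median and plurality equals the true preference, so
  the elicitation pipeline must recover the generating framework exactly —
  the package's end-to-end consistency check.

Both are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .elicitation import (
    CUTOFF_GRID,
    PRICE_WEIGHT_GRID,
    SWING_GRID,
    NO_EXCLUSION,
    OptionGrid,
    VotingRound,
)
from .errors import McdaError
from .evaluation import ProductProfile
from .model import Framework


@dataclass(frozen=True)
class SyntheticTenderSpec:
    """Recipe for one synthetic tender.

    Parameters
    ----------
    framework :
        Supplies the non-price criteria and their category ladders.
    n_products :
        Number of competing products (>= 1).
    reference_price :
        The lowest bid; every price is this times a spread factor. The
        default (2200) matches the packaged test cases' IDR scale.
    spread_range :
        (lo, hi) multiplicative factor range, log-uniform; product 1 is
        anchored at ``lo`` so the minimum is always drawn.
    category_probs :
        Optional per-criterion probability vector over category levels
        (overrides the default uniform-over-non-exclusion model).
    exclusion_probability :
        Probability assigned to *each* exclusion-flagged category.
    seed :
        RNG seed; identical specs produce identical tenders.
    """

    framework: Framework
    n_products: int
    reference_price: float = 2200.0
    spread_range: tuple[float, float] = (1.0, 2.5)
    category_probs: Mapping[str, Sequence[float]] = field(default_factory=dict)
    exclusion_probability: float = 0.0
    seed: int = 0


def generate_tender(spec: SyntheticTenderSpec) -> list[ProductProfile]:
    """Draw a reproducible synthetic tender from the spec."""
    if spec.n_products < 1:
        raise McdaError(f"n_products must be >= 1, got {spec.n_products}")
    lo, hi = spec.spread_range
    if not (0 < lo <= hi) or spec.reference_price <= 0:
        raise McdaError("spread_range must satisfy 0 < lo <= hi and reference_price > 0")
    if not 0.0 <= spec.exclusion_probability < 1.0:
        raise McdaError("exclusion_probability must lie in [0, 1)")
    rng = np.random.default_rng(spec.seed)
    factors = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_products))
    factors[0] = lo  # guarantee the minimum price is attained
    products = []
    nonprice = spec.framework.nonprice_criteria
    for i in range(spec.n_products):
        selections = {}
        for crit in nonprice:
            cats = sorted(crit.categories, key=lambda c: c.level)
            if crit.id in spec.category_probs:
                probs = np.asarray(spec.category_probs[crit.id], dtype=float)
                if probs.shape != (len(cats),) or probs.min() < 0:
                    raise McdaError(
                        f"category_probs[{crit.id!r}] must be {len(cats)} non-negative values"
                    )
                probs = probs / probs.sum()
            else:
                probs = np.zeros(len(cats))
                excl = [j for j, c in enumerate(cats) if c.is_exclusion]
                keep = [j for j, c in enumerate(cats) if not c.is_exclusion]
                for j in excl:
                    probs[j] = spec.exclusion_probability
                rest = 1.0 - spec.exclusion_probability * len(excl)
                if rest <= 0 or not keep:
                    raise McdaError(
                        f"criterion {crit.id!r}: exclusion probabilities leave no mass"
                    )
                probs[keep] = rest / len(keep)
            choice = rng.choice(len(cats), p=probs)
            selections[crit.id] = cats[choice].label
        products.append(
            ProductProfile(
                product_id=f"product-{i + 1:03d}",
                price=float(spec.reference_price * factors[i]),
                selections=selections,
            )
        )
    return products


@dataclass(frozen=True)
class TruePreference:
    """The group's latent consensus, around which synthetic votes scatter.

    ``ranking`` is most -> least important over the non-excluded non-price
    criteria; ``increments`` are the swing steps least -> most important
    (length ``len(ranking) - 1``). Optional adjustment values add second
    price-weight / cut-off rounds that override the initial medians.
    """

    price_weight: float
    price_cutoff: float
    ranking: tuple[str, ...]
    increments: tuple[float, ...]
    exclusions: tuple[str, ...] = ()
    adjust_price_weight: float | None = None
    adjust_price_cutoff: float | None = None


def indonesia_preference() -> TruePreference:
    """The consensus the packaged Indonesian vote record expresses."""
    return TruePreference(
        price_weight=0.50,
        price_cutoff=0.50,
        ranking=(
            "quality-assurance",
            "equivalence",
            "stability-formulation",
            "supply-reliability",
            "real-world-outcomes",
            "pharmacovigilance",
        ),
        increments=(0.15, 1.00, 0.50, 0.00, 0.50),
        exclusions=("macroeconomic-benefit", "added-value-services"),
        adjust_price_weight=0.40,
        adjust_price_cutoff=1.00,
    )


def _numeric_round(
    purpose: str,
    grid: OptionGrid,
    preferred: float,
    n_voters: int,
    dispersion: float,
    rng: np.random.Generator,
) -> VotingRound:
    values = list(grid.values)
    center = values.index(grid.snap(preferred))
    if dispersion == 0:
        shifts = np.zeros(n_voters, dtype=int)
    else:
        shifts = np.rint(rng.normal(0.0, dispersion, size=n_voters)).astype(int)
    idx = np.clip(center + shifts, 0, len(values) - 1)
    return VotingRound(purpose, tuple(values[i] for i in idx), grid)


def generate_votes(
    n_voters: int,
    preference: TruePreference,
    dispersion: float = 0.0,
    seed: int = 0,
) -> list[VotingRound]:
    """Draw a complete elicitation session around a true preference.

    ``dispersion`` is the standard deviation of the vote displacement in grid
    steps (numeric rounds) and controls the error rate of categorical votes;
    0 means perfect consensus.
    """
    if n_voters < 1:
        raise McdaError(f"n_voters must be >= 1, got {n_voters}")
    if dispersion < 0:
        raise McdaError(f"dispersion must be >= 0, got {dispersion}")
    m = len(preference.ranking)
    if len(preference.increments) != max(m - 1, 0):
        raise McdaError(
            f"preference needs {m - 1} increments for {m} ranked criteria"
        )
    rng = np.random.default_rng(seed)
    err_p = min(dispersion / (1.0 + dispersion), 0.5)
    rounds: list[VotingRound] = [
        _numeric_round("price_weight", PRICE_WEIGHT_GRID, preference.price_weight,
                       n_voters, dispersion, rng),
        _numeric_round("price_cutoff", CUTOFF_GRID, preference.price_cutoff,
                       n_voters, dispersion, rng),
    ]
    for i, cid in enumerate(preference.exclusions, start=1):
        votes = tuple(
            cid if rng.random() >= err_p else NO_EXCLUSION for _ in range(n_voters)
        )
        # a majority for the target must survive noise at dispersion 0
        rounds.append(VotingRound(f"exclusion_vote_{i}", votes))
    remaining = list(preference.ranking)
    for k in range(1, m):
        target = remaining[0]
        votes = []
        for _ in range(n_voters):
            if len(remaining) > 1 and rng.random() < err_p:
                votes.append(str(rng.choice([c for c in remaining if c != target])))
            else:
                votes.append(target)
        rounds.append(VotingRound(f"smart_round_{k}", tuple(votes)))
        remaining.pop(0)
    for k, delta in enumerate(preference.increments, start=1):
        rounds.append(
            _numeric_round(f"swing_step_{k}", SWING_GRID, delta, n_voters, dispersion, rng)
        )
    if preference.adjust_price_weight is not None:
        rounds.append(
            _numeric_round("price_weight_adjustment", PRICE_WEIGHT_GRID,
                           preference.adjust_price_weight, n_voters, dispersion, rng)
        )
    if preference.adjust_price_cutoff is not None:
        rounds.append(
            _numeric_round("price_cutoff_adjustment", CUTOFF_GRID,
                           preference.adjust_price_cutoff, n_voters, dispersion, rng)
        )
    return rounds
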