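"""File readers/writers for vote records, performance matrices and reports.

CSV dialect: UTF-8, comma-separated, header required, locale-independent
decimal points. Percent values may be written as "40%", "40" or "0.40".
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .elicitation import VotingRound, default_grid_for
from .errors import McdaError, VoteError
from .evaluation import EvaluationResult, ProductProfile
from .model import Framework
from .units import format_percent, parse_percent

VOTE_COLUMNS = ("round_purpose", "option_value", "vote_count")


def read_votes(path: str | Path) -> list[VotingRound]:
    """Read a vote CSV into voting rounds, in file order.

    Columns: ``round_purpose`` (price_weight, price_cutoff, their
    ``_adjustment`` variants, smart_round_k, swing_step_k, exclusion_vote_k),
    ``option_value`` (a percent/fraction for numeric rounds, a criterion id —
    or "none" — for categorical ones) and ``vote_count``.
    """
    df = pd.read_csv(path, dtype=str)
    missing = set(VOTE_COLUMNS) - set(df.columns)
    if missing:
        raise VoteError(f"{path}: vote file is missing columns {sorted(missing)}")
    rounds: list[VotingRound] = []
    for purpose, group in df.groupby("round_purpose", sort=False):
        grid = default_grid_for(str(purpose))
        votes: list = []
        for _, row in group.iterrows():
            try:
                count = int(row["vote_count"])
            except (TypeError, ValueError) as exc:
                raise VoteError(
                    f"{path}: round {purpose!r}: bad vote_count {row['vote_count']!r}"
                ) from exc
            if count < 0:
                raise VoteError(f"{path}: round {purpose!r}: negative vote_count")
            value = (
                parse_percent(row["option_value"])
                if grid is not None
                else str(row["option_value"]).strip()
            )
            votes.extend([value] * count)
        rounds.append(VotingRound(purpose=str(purpose), votes=tuple(votes), grid=grid))
    return rounds


def write_votes(rounds: Sequence[VotingRound], path: str | Path) -> None:
    """Write voting rounds as the documented (purpose, value, count) CSV."""
    rows = []
    for rnd in rounds:
        for value, count in sorted(rnd.tallies().items(), key=lambda kv: str(kv[0])):
            out = format_percent(value, 0) if rnd.grid is not None else value
            rows.append(
                {"round_purpose": rnd.purpose, "option_value": out, "vote_count": count}
            )
    pd.DataFrame(rows, columns=list(VOTE_COLUMNS)).to_csv(path, index=False)


def read_performance_matrix(
    path: str | Path, fw: Framework | None = None
) -> list[ProductProfile]:
    """Read a tender performance matrix CSV.

    One row per product: ``product_id``, ``price``, then one column per
    non-price criterion holding the selected category label. When a framework
    is given, only its non-price criteria are kept (extra columns — e.g. for
    criteria later excluded from the framework — are dropped) and a missing
    criterion column is an error.
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("product_id", "price"):
        if col not in df.columns:
            raise McdaError(f"{path}: performance matrix is missing column {col!r}")
    criterion_cols = [c for c in df.columns if c not in ("product_id", "price")]
    if fw is not None:
        wanted = [c.id for c in fw.nonprice_criteria]
        missing = set(wanted) - set(criterion_cols)
        if missing:
            raise McdaError(
                f"{path}: matrix is missing criterion columns {sorted(missing)}"
            )
        criterion_cols = wanted
    products = []
    for _, row in df.iterrows():
        try:
            price = float(row["price"])
        except (TypeError, ValueError) as exc:
            raise McdaError(
                f"{path}: product {row['product_id']!r}: bad price {row['price']!r}"
            ) from exc
        products.append(
            ProductProfile(
                product_id=str(row["product_id"]),
                price=price,
                selections={c: str(row[c]).strip() for c in criterion_cols},
            )
        )
    return products


def write_performance_matrix(products: Sequence[ProductProfile], path: str | Path) -> None:
    rows = []
    for p in products:
        rows.append({"product_id": p.product_id, "price": p.price, **p.selections})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Report rendering


def result_to_dict(result: EvaluationResult, seed: int | None = None) -> dict:
    """Machine-readable report with enough metadata to re-run the evaluation."""
    from . import __version__

    return {
        "tool": {"name": "tendermcda", "version": __version__},
        "framework": {
            "name": result.framework_name,
            "hash": result.framework_hash,
            "price_weight": result.price_weight,
            "price_cutoff_excess": result.price_cutoff_excess,
        },
        "seed": seed,
        "p_min": result.p_min,
        "products": [
            {
                "product_id": p.product_id,
                "price": p.price,
                "composite": p.composite,
                "composite_percent": None if p.composite is None
                else float(format_percent(p.composite).rstrip("%")),
                "rank": p.rank,
                "excluded": p.excluded,
                "tied": p.tied,
                "scores": {
                    s.criterion_id: {
                        "raw_fraction": s.raw_fraction,
                        "weighted": s.weighted,
                        "excluded": s.excluded,
                    }
                    for s in p.scores
                },
            }
            for p in result.products
        ],
    }


def render_result_text(result: EvaluationResult, fw: Framework) -> str:
    """Aligned-text report: weights line, then one line per product."""
    lines = [
        f"Framework: {result.framework_name or '<unnamed>'}  "
        f"[{result.framework_hash}]",
        f"Price weight: {format_percent(result.price_weight)}   "
        f"cut-off: +{format_percent(result.price_cutoff_excess, 0)} over the lowest bid",
        f"Lowest eligible bid: {result.p_min}",
        "",
        "Weights: "
        + ", ".join(
            f"{c.id}={format_percent(c.weight)}" for c in fw.criteria if c.weight is not None
        ),
        "",
        f"{'rank':>4}  {'product':<16}{'price':>10}  {'composite':>9}  flags",
    ]
    order = sorted(
        result.products,
        key=lambda p: (p.rank is None, p.rank if p.rank is not None else 0, p.product_id),
    )
    for p in order:
        flags = []
        if p.excluded:
            flags.append("EXCLUDED")
        if p.tied:
            flags.append("tied")
        comp = "-" if p.composite is None else format_percent(p.composite)
        rank = "-" if p.rank is None else str(p.rank)
        lines.append(
            f"{rank:>4}  {p.product_id:<16}{p.price:>10g}  {comp:>9}  {' '.join(flags)}"
        )
    return "\n".join(lines) + "\n"


def write_result(
    result: EvaluationResult,
    fw: Framework,
    path: str | Path,
    fmt: str = "json",
    seed: int | None = None,
) -> None:
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(result_to_dict(result, seed=seed), indent=2) + "\n")
    elif fmt == "csv":
        result.to_frame().to_csv(path)
    elif fmt == "text":
        path.write_text(render_result_text(result, fw))
    else:
        raise McdaError(f"unknown report format {fmt!r}")
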