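"""Domain model: criteria, performance categories, and the weighted framework.

An MCDA framework for tendering consists of one price criterion plus a set of
non-price criteria. Each non-price criterion carries an ordered ladder of
performance categories; every category maps to a score fraction in [0, 1]
(the criterion's scoring function), and a category may instead be flagged as
an *exclusion* category — a performance level so poor that a product selecting
it is disqualified from the tender rather than scored.

Weights are proportions summing to 1. Before elicitation a framework is a
*draft*: all weights are ``None`` and conservation is not enforced; after
elicitation every criterion holds its final weight and the price criterion's
weight equals ``price_weight``.

Serialization is YAML (or JSON) with an explicit ``schema_version``; the
packaged Indonesian framework is the canonical example of the format.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterator

import yaml

from .errors import FrameworkSchemaError, UnknownCategoryError

SCHEMA_VERSION = 1

#: absolute tolerance for weight conservation
WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class PerformanceCategory:
    """One ordinal performance level of a criterion.

    Parameters
    ----------
    label :
        Short stable identifier, unique within the criterion.
    level :
        Ordinal position, 0 = worst.
    score_fraction :
        Proportion of the criterion's full score awarded at this level,
        in [0, 1]; stored as 0 for exclusion categories.
    description :
        Free-text definition of the level.
    is_exclusion :
        If true, a product at this level is disqualified from the tender.
    """

    label: str
    level: int
    score_fraction: float
    description: str = ""
    is_exclusion: bool = False


@dataclass(frozen=True)
class Criterion:
    """One decision criterion: either the price criterion or a category ladder."""

    id: str
    name: str
    definition: str = ""
    is_price: bool = False
    categories: tuple[PerformanceCategory, ...] = ()
    weight: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", tuple(self.categories))

    def category(self, label: str) -> PerformanceCategory:
        """Look up a category by exact, case-sensitive label."""
        for cat in self.categories:
            if cat.label == label:
                return cat
        valid = ", ".join(repr(c.label) for c in self.categories)
        raise UnknownCategoryError(
            f"criterion {self.id!r} has no category {label!r}; valid labels: {valid}"
        )

    @property
    def best_category(self) -> PerformanceCategory:
        """Highest-level non-exclusion category (full score)."""
        eligible = [c for c in self.categories if not c.is_exclusion]
        if not eligible:
            raise UnknownCategoryError(
                f"criterion {self.id!r} has no non-exclusion categories"
            )
        return max(eligible, key=lambda c: c.level)


@dataclass(frozen=True)
class Framework:
    """A complete criteria framework for one tender decision context.

    ``price_cutoff_excess`` is the excess over the lowest bid, as a fraction,
    at and beyond which a bid earns zero price score (1.0 means "+100%"); it
    sets the slope of the linear price scoring function.
    """

    criteria: tuple[Criterion, ...]
    price_weight: float | None = None
    price_cutoff_excess: float | None = None
    name: str = ""
    version: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "criteria", tuple(self.criteria))

    def __iter__(self) -> Iterator[Criterion]:
        return iter(self.criteria)

    @property
    def price_criterion(self) -> Criterion:
        price = [c for c in self.criteria if c.is_price]
        if len(price) != 1:
            raise FrameworkSchemaError(
                f"framework must have exactly one price criterion, found {len(price)}"
            )
        return price[0]

    @property
    def nonprice_criteria(self) -> tuple[Criterion, ...]:
        return tuple(c for c in self.criteria if not c.is_price)

    @property
    def is_weighted(self) -> bool:
        return all(c.weight is not None for c in self.criteria)

    def criterion(self, cid: str) -> Criterion:
        for c in self.criteria:
            if c.id == cid:
                return c
        raise KeyError(f"no criterion with id {cid!r}")

    def with_weights(
        self,
        weights: dict[str, float],
        price_weight: float | None = None,
        price_cutoff_excess: float | None = None,
    ) -> "Framework":
        """Return a copy with per-criterion weights (and optionally price params) set."""
        missing = {c.id for c in self.criteria} - set(weights)
        if missing:
            raise FrameworkSchemaError(f"weights missing for criteria: {sorted(missing)}")
        new_criteria = tuple(replace(c, weight=weights[c.id]) for c in self.criteria)
        return replace(
            self,
            criteria=new_criteria,
            price_weight=(self.price_weight if price_weight is None else price_weight),
            price_cutoff_excess=(
                self.price_cutoff_excess
                if price_cutoff_excess is None
                else price_cutoff_excess
            ),
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "version": self.version,
            "notes": self.notes,
            "price_weight": self.price_weight,
            "price_cutoff_excess": self.price_cutoff_excess,
            "criteria": [
                {
                    "id": c.id,
                    "name": c.name,
                    "definition": c.definition,
                    "is_price": c.is_price,
                    "weight": c.weight,
                    "categories": [
                        {
                            "label": cat.label,
                            "level": cat.level,
                            "score_fraction": cat.score_fraction,
                            "description": cat.description,
                            "is_exclusion": cat.is_exclusion,
                        }
                        for cat in c.categories
                    ],
                }
                for c in self.criteria
            ],
        }

    def content_hash(self) -> str:
        """Stable sha256 over the canonical serialized form (for report metadata)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class Violation:
    """One broken framework invariant, naming the offending element."""

    rule: str
    subject: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"[{self.rule}] {self.subject}: {self.message}"


def validate_framework(fw: Framework) -> list[Violation]:
    """Check every framework invariant; return violations (empty iff valid).

    Never raises: callers decide what to do with the violation list. Weight
    conservation is enforced only when the framework is fully weighted; an
    all-``None`` weight vector is a legitimate draft.
    """
    out: list[Violation] = []

    price = [c for c in fw.criteria if c.is_price]
    if len(price) != 1:
        names = ", ".join(c.id for c in price) or "<none>"
        out.append(
            Violation("price-uniqueness", names,
                      f"exactly one price criterion required, found {len(price)}")
        )

    seen_ids: set[str] = set()
    for c in fw.criteria:
        if c.id in seen_ids:
            out.append(Violation("criterion-id-unique", c.id, "duplicate criterion id"))
        seen_ids.add(c.id)
        if c.is_price:
            if c.categories:
                out.append(
                    Violation("price-no-categories", c.id,
                              "price criterion must have no performance categories")
                )
            continue
        out.extend(_validate_categories(c))
        if c.weight is not None and not (0.0 <= c.weight <= 1.0):
            out.append(Violation("weight-range", c.id, f"weight {c.weight} outside [0, 1]"))

    weights = [c.weight for c in fw.criteria]
    if all(w is not None for w in weights) and fw.criteria:
        total = sum(weights)  # type: ignore[arg-type]
        if abs(total - 1.0) > WEIGHT_TOL:
            out.append(
                Violation("weights-sum", "framework", f"weights sum to {total:.6g}, not 1")
            )
        if len(price) == 1:
            if fw.price_weight is None:
                out.append(
                    Violation("price-weight-set", price[0].id,
                              "weighted framework must declare price_weight")
                )
            elif abs(price[0].weight - fw.price_weight) > WEIGHT_TOL:  # type: ignore[operator]
                out.append(
                    Violation(
                        "price-weight-match", price[0].id,
                        f"price criterion weight {price[0].weight} != "
                        f"price_weight {fw.price_weight}",
                    )
                )
    elif any(w is not None for w in weights):
        unset = [c.id for c in fw.criteria if c.weight is None]
        out.append(
            Violation("weights-partial", ", ".join(unset),
                      "framework is partially weighted (some weights unset)")
        )

    if fw.price_cutoff_excess is not None and fw.price_cutoff_excess <= 0:
        out.append(
            Violation("price-cutoff-positive", "framework",
                      f"price_cutoff_excess {fw.price_cutoff_excess} must be > 0")
        )
    return out


def _validate_categories(c: Criterion) -> list[Violation]:
    out: list[Violation] = []
    if len(c.categories) < 2:
        out.append(
            Violation("categories-count", c.id,
                      f"non-price criterion needs >= 2 categories, has {len(c.categories)}")
        )
        return out
    labels = [cat.label for cat in c.categories]
    if len(set(labels)) != len(labels):
        out.append(Violation("category-labels-unique", c.id, "duplicate category labels"))
    levels = [cat.level for cat in c.categories]
    if sorted(levels) != list(range(min(levels), min(levels) + len(levels))) or len(
        set(levels)
    ) != len(levels):
        # allow any strictly increasing set, not necessarily contiguous
        if any(b <= a for a, b in zip(sorted(levels), sorted(levels)[1:])):
            out.append(
                Violation("category-levels", c.id, "category levels must be strictly increasing")
            )
    ordered = sorted(c.categories, key=lambda cat: cat.level)
    prev = None
    for cat in ordered:
        subj = f"{c.id}/{cat.label}"
        if cat.is_exclusion:
            if cat.score_fraction != 0.0:
                out.append(
                    Violation("exclusion-zero-fraction", subj,
                              "exclusion category must store score_fraction 0")
                )
            continue
        if not (0.0 <= cat.score_fraction <= 1.0):
            out.append(
                Violation("fraction-range", subj,
                          f"score_fraction {cat.score_fraction} outside [0, 1]")
            )
        if prev is not None and cat.score_fraction < prev - 1e-12:
            out.append(
                Violation("fraction-monotone", subj,
                          "score_fraction must be non-decreasing with level")
            )
        prev = cat.score_fraction
    non_excl = [cat for cat in ordered if not cat.is_exclusion]
    if non_excl and abs(non_excl[-1].score_fraction - 1.0) > 1e-12:
        out.append(
            Violation("best-full-score", f"{c.id}/{non_excl[-1].label}",
                      "best non-exclusion category must have score_fraction 1")
        )
    if not non_excl:
        out.append(Violation("all-exclusion", c.id, "every category is an exclusion category"))
    return out


# ---------------------------------------------------------------------------
# (De)serialization


def framework_from_dict(data: dict[str, Any]) -> Framework:
    if not isinstance(data, dict):
        raise FrameworkSchemaError("framework config must be a mapping")
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise FrameworkSchemaError(
            f"unknown schema_version {version!r} (expected {SCHEMA_VERSION})"
        )
    raw_criteria = data.get("criteria")
    if not isinstance(raw_criteria, list) or not raw_criteria:
        raise FrameworkSchemaError("field 'criteria' must be a non-empty list")
    criteria = []
    for i, rc in enumerate(raw_criteria):
        where = f"criteria[{i}]"
        if not isinstance(rc, dict) or "id" not in rc or "name" not in rc:
            raise FrameworkSchemaError(f"{where}: each criterion needs 'id' and 'name'")
        cats = []
        for j, rcat in enumerate(rc.get("categories") or []):
            cwhere = f"{where}.categories[{j}]"
            try:
                cats.append(
                    PerformanceCategory(
                        label=str(rcat["label"]),
                        level=int(rcat["level"]),
                        score_fraction=float(rcat.get("score_fraction", 0.0)),
                        description=str(rcat.get("description", "")),
                        is_exclusion=bool(rcat.get("is_exclusion", False)),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise FrameworkSchemaError(f"{cwhere}: {exc}") from exc
        weight = rc.get("weight")
        criteria.append(
            Criterion(
                id=str(rc["id"]),
                name=str(rc["name"]),
                definition=str(rc.get("definition", "")),
                is_price=bool(rc.get("is_price", False)),
                categories=tuple(sorted(cats, key=lambda c: c.level)),
                weight=None if weight is None else float(weight),
            )
        )
    pw = data.get("price_weight")
    cutoff = data.get("price_cutoff_excess")
    return Framework(
        criteria=tuple(criteria),
        price_weight=None if pw is None else float(pw),
        price_cutoff_excess=None if cutoff is None else float(cutoff),
        name=str(data.get("name", "")),
        version=str(data.get("version", "")),
        notes=str(data.get("notes", "")),
    )


def load_framework(path: str | Path) -> Framework:
    """Load a framework config (YAML or JSON by extension)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FrameworkSchemaError(f"{path}: file is empty")
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise FrameworkSchemaError(f"{path}: cannot parse: {exc}") from exc
    return framework_from_dict(data)


def save_framework(fw: Framework, path: str | Path) -> None:
    """Write a framework config; load(save(fw)) reproduces an equal framework."""
    path = Path(path)
    data = fw.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False, allow_unicode=True))
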