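"""Packaged fixtures: the Indonesian pilot framework, votes and test cases.

Everything ships inside the package so every stage of the pipeline is testable
without downloads: the draft 8+1 criteria framework, the workshop vote record
(whose round sizes and medians match the pilot's published tallies), the final
elicited 6+1 framework, and the four hypothetical test-case products (bids of
2200, 2900, 3000 and 3800 IDR).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal

from .elicitation import VotingRound
from .evaluation import ProductProfile
from .model import Framework, load_framework

FIXTURE_FILES = (
    "indonesia_draft.yaml",
    "indonesia_final.yaml",
    "indonesia_votes.csv",
    "indonesia_test_cases.csv",
)


def _data_path(name: str) -> Path:
    return Path(resources.files("tendermcda").joinpath("data", name))  # type: ignore[arg-type]


def indonesia_draft_framework() -> Framework:
    """The pre-elicitation draft: 8 non-price criteria + price, unweighted."""
    return load_framework(_data_path("indonesia_draft.yaml"))


def indonesia_final_framework() -> Framework:
    """The elicited framework: 6 non-price criteria + price at 40% weight."""
    return load_framework(_data_path("indonesia_final.yaml"))


def indonesia_votes() -> list[VotingRound]:
    """The workshop vote record (all elicitation rounds, explicit tallies)."""
    from .io import read_votes

    return read_votes(_data_path("indonesia_votes.csv"))


def indonesia_test_cases(
    framework: Literal["draft", "final"] = "final",
) -> list[ProductProfile]:
    """The four hypothetical competing products.

    ``framework="draft"`` keeps selections for all 8 non-price criteria;
    ``"final"`` drops the two criteria removed by majority vote.
    """
    from .io import read_performance_matrix

    fw = indonesia_draft_framework() if framework == "draft" else indonesia_final_framework()
    return read_performance_matrix(_data_path("indonesia_test_cases.csv"), fw)


def load_reference_fixtures() -> tuple[
    Framework, list[VotingRound], Framework, list[ProductProfile]
]:
    """(draft 8+1 framework, vote record, final 6+1 framework, 4 test cases)."""
    return (
        indonesia_draft_framework(),
        indonesia_votes(),
        indonesia_final_framework(),
        indonesia_test_cases("final"),
    )


def emit_fixtures(directory: str | Path) -> list[Path]:
    """Copy every packaged fixture file into ``directory``; return the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for name in FIXTURE_FILES:
        target = directory / name
        target.write_text(_data_path(name).read_text())
        out.append(target)
    return out
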