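"""Weight elicitation: medians, SMART ranking, swing ladder, normalization."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tendermcda.elicitation import (
    PRICE_WEIGHT_GRID,
    SWING_GRID,
    SmartRanking,
    VotingRound,
    combine_with_price,
    median_vote,
    normalize_nonprice,
    run_elicitation,
    smart_rank,
    swing_points,
)
from tendermcda.errors import ElicitationError, VoteError
from tendermcda.units import percent_value

SETTINGS = settings(derandomize=True, max_examples=100, deadline=None)


def weight_round(tallies):
    votes = [v for value, count in tallies for v in [value] * count]
    return VotingRound("price_weight", tuple(votes), PRICE_WEIGHT_GRID)


class TestMedianVote:
    @pytest.mark.parametrize(
        "tallies, expected",
        [
            # even n: mean of the 8th and 9th of 16 sorted votes
            ([(0.40, 1), (0.45, 5), (0.50, 8), (0.55, 1), (0.60, 1)], 0.50),
            # odd n: the 8th order statistic of 15
            ([(0.35, 1), (0.40, 7), (0.45, 7)], 0.40),
            ([(0.50, 1)], 0.50),
        ],
    )
    def test_median_of_group_votes(self, tallies, expected):
        assert median_vote(weight_round(tallies)) == pytest.approx(expected)

    def test_even_n_midpoint_snaps_to_lower_grid_value(self):
        # middle votes 45% and 50% average to 47.5%, equidistant -> snap down
        assert median_vote(weight_round([(0.45, 1), (0.50, 1)])) == pytest.approx(0.45)

    def test_empty_round_rejected(self):
        with pytest.raises(VoteError, match="no votes"):
            VotingRound("price_weight", (), PRICE_WEIGHT_GRID)

    def test_off_grid_vote_named_in_error(self):
        with pytest.raises(VoteError, match="0.42"):
            VotingRound("price_weight", (0.42,), PRICE_WEIGHT_GRID)

    @SETTINGS
    @given(st.lists(st.sampled_from(PRICE_WEIGHT_GRID.values), min_size=1, max_size=40))
    def test_median_always_lands_on_the_grid(self, votes):
        result = median_vote(weight_round([(v, 1) for v in votes]))
        assert result in PRICE_WEIGHT_GRID


class TestSmartRank:
    def test_sequential_winners_and_unvoted_last_rank(self):
        candidates = ["quality", "equivalence", "stability", "reliability",
                      "real-world", "pharmacovigilance"]
        winners = ["quality", "equivalence", "stability", "reliability", "real-world"]
        rounds = [
            VotingRound(f"smart_round_{k}", (w,) * 3 + tuple(
                c for c in candidates[k:] if c != w)[:1])
            for k, w in enumerate(winners, start=1)
        ]
        ranking = smart_rank(rounds, candidates)
        assert ranking.order[:5] == tuple(winners)
        assert ranking.order[-1] == "pharmacovigilance"  # never voted on
        assert ranking.tied_ranks == ()

    def test_single_criterion_needs_no_rounds(self):
        assert smart_rank([], ["only"]) == SmartRanking(order=("only",))

    def test_tie_breaks_lexicographically_and_is_recorded(self):
        rounds = [VotingRound("smart_round_1", ("b", "a", "a", "b"))]
        ranking = smart_rank(rounds, ["a", "b"])
        assert ranking.order == ("a", "b")
        assert ranking.tied_ranks == (1,)

    def test_incomplete_rounds_leave_criteria_unrankable(self):
        with pytest.raises(ElicitationError, match="unranked"):
            smart_rank([VotingRound("smart_round_1", ("a",))], ["a", "b", "c"])

    def test_already_ranked_criterion_rejected(self):
        rounds = [
            VotingRound("smart_round_1", ("a", "a")),
            VotingRound("smart_round_2", ("a", "b")),
        ]
        with pytest.raises(VoteError, match="'a'"):
            smart_rank(rounds, ["a", "b", "c"])


class TestSwingLadder:
    def test_worked_example_one_step(self):
        ladder = swing_points(["least", "next"], [0.50])
        assert ladder.points == (10.0, 15.0)

    def test_pilot_ladder(self):
        ladder = swing_points(
            ["pv", "rw", "supply", "stability", "equivalence", "quality"],
            [0.15, 1.00, 0.50, 0.00, 0.50],
        )
        assert ladder.points == (10.0, 11.5, 23.0, 34.5, 34.5, 51.75)

    def test_all_zero_increments_keep_base_points(self):
        ladder = swing_points(["a", "b", "c"], [0.0, 0.0])
        assert ladder.points == (10.0, 10.0, 10.0)

    def test_negative_increment_rejected(self):
        with pytest.raises(ElicitationError, match="negative"):
            swing_points(["a", "b"], [-0.1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ElicitationError, match="increments"):
            swing_points(["a", "b", "c"], [0.1])

    @SETTINGS
    @given(
        st.lists(st.sampled_from(SWING_GRID.values), min_size=1, max_size=7),
        st.floats(min_value=1.0, max_value=100.0),
    )
    def test_points_match_a_brute_force_accumulation(self, increments, base):
        names = [f"c{i}" for i in range(len(increments) + 1)]
        ladder = swing_points(names, increments, base_points=base)
        expected = [base]
        for d in increments:  # independent loop oracle
            expected.append(expected[-1] + expected[-1] * d)
        assert list(ladder.points) == pytest.approx(expected, abs=0, rel=1e-15)
        # increments >= 0 => points never decrease up the ranking
        assert all(b >= a for a, b in zip(ladder.points, ladder.points[1:]))


class TestNormalization:
    def test_relative_weight_of_the_top_criterion(self):
        ladder = swing_points(
            ["pv", "rw", "supply", "stability", "equivalence", "quality"],
            [0.15, 1.00, 0.50, 0.00, 0.50],
        )
        weights = normalize_nonprice(ladder)
        assert weights["quality"] == pytest.approx(51.75 / 165.25, abs=1e-15)
        assert math.isclose(sum(weights.values()), 1.0, abs_tol=1e-12)

    def test_single_criterion_gets_weight_one(self):
        assert normalize_nonprice(swing_points(["only"], [])) == {"only": 1.0}

    def test_equal_points_give_equal_weights(self):
        weights = normalize_nonprice(swing_points(["a", "b", "c"], [0.0, 0.0]))
        assert list(weights.values()) == pytest.approx([1 / 3] * 3)

    def test_combine_with_price_rescales_and_conserves(self):
        nonprice = {"quality": 51.75 / 165.25, "rest": 1 - 51.75 / 165.25}
        final = combine_with_price(nonprice, 0.40)
        assert final["quality"] == pytest.approx(0.1878971255673222, abs=1e-15)
        assert percent_value(final["quality"]) == 18.8
        assert math.isclose(sum(final.values()), 1.0, abs_tol=1e-12)
        # at the draft-stage price weight of 50% the same criterion shows 15.7%
        assert percent_value(combine_with_price(nonprice, 0.50)["quality"]) == 15.7

    def test_two_equal_nonprice_criteria_at_half_price_weight(self):
        final = combine_with_price({"a": 0.5, "b": 0.5}, 0.5)
        assert final == {"a": 0.25, "b": 0.25, "price": 0.5}

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.4])
    def test_price_weight_outside_unit_interval_rejected(self, bad):
        with pytest.raises(ElicitationError):
            combine_with_price({"a": 1.0}, bad)


class TestFullElicitation:
    def test_pilot_votes_reproduce_published_weights(self, draft_framework, vote_rounds):
        record = run_elicitation(draft_framework, vote_rounds)
        shown = {cid: percent_value(w) for cid, w in record.final_weights.items()}
        assert shown == {
            "price": 40.0,
            "quality-assurance": 18.8,
            "equivalence": 12.5,
            "stability-formulation": 12.5,
            "supply-reliability": 8.4,
            "real-world-outcomes": 4.2,
            "pharmacovigilance": 3.6,
        }
        assert record.price_weight_initial == pytest.approx(0.50)
        assert record.price_cutoff_initial == pytest.approx(0.50)
        assert record.framework.price_cutoff_excess == pytest.approx(1.00)

    def test_majority_exclusions_drop_two_criteria(self, draft_framework, vote_rounds):
        record = run_elicitation(draft_framework, vote_rounds)
        assert set(record.excluded) == {"macroeconomic-benefit", "added-value-services"}
        assert len(record.framework.nonprice_criteria) == 6

    def test_elicited_framework_matches_packaged_final(
        self, draft_framework, vote_rounds, final_framework
    ):
        fw = run_elicitation(draft_framework, vote_rounds).framework
        for c in fw.criteria:
            assert c.weight == pytest.approx(
                final_framework.criterion(c.id).weight, abs=1e-12
            )

    def test_missing_required_round_listed(self, draft_framework, vote_rounds):
        partial = [r for r in vote_rounds if r.purpose != "price_cutoff"]
        with pytest.raises(ElicitationError, match="price_cutoff"):
            run_elicitation(draft_framework, partial)

    def test_missing_swing_step_listed(self, draft_framework, vote_rounds):
        partial = [r for r in vote_rounds if r.purpose != "swing_step_3"]
        with pytest.raises(ElicitationError, match="swing_step"):
            run_elicitation(draft_framework, partial)


class TestWeightProperties:
    @SETTINGS
    @given(
        st.lists(st.sampled_from(SWING_GRID.values), min_size=1, max_size=6),
        st.sampled_from([0.3, 0.4, 0.5, 0.7]),
    )
    def test_conservation_of_weight(self, increments, w_p):
        names = [f"c{i}" for i in range(len(increments) + 1)]
        final = combine_with_price(
            normalize_nonprice(swing_points(names, increments)), w_p
        )
        assert math.isclose(sum(final.values()), 1.0, abs_tol=1e-12)

    @SETTINGS
    @given(
        st.lists(st.sampled_from(SWING_GRID.values), min_size=2, max_size=6),
        st.data(),
    )
    def test_raising_one_increment_never_hurts_criteria_above_it(self, increments, data):
        k = data.draw(st.integers(0, len(increments) - 1))
        names = [f"c{i}" for i in range(len(increments) + 1)]
        before = normalize_nonprice(swing_points(names, increments))
        bumped = list(increments)
        bumped[k] += 0.05
        after = normalize_nonprice(swing_points(names, bumped))
        for i, name in enumerate(names):
            if i > k:  # rungs above the raised step
                assert after[name] >= before[name] - 1e-12
            else:  # rungs at or below it lose relative weight
                assert after[name] <= before[name] + 1e-12

    @SETTINGS
    @given(st.lists(st.sampled_from(SWING_GRID.values), min_size=1, max_size=6))
    def test_final_weights_non_increasing_along_the_ranking(self, increments):
        names = [f"c{i}" for i in range(len(increments) + 1)]
        final = combine_with_price(normalize_nonprice(swing_points(names, increments)), 0.4)
        ordered = [final[n] for n in reversed(names)]  # most -> least important
        assert all(a >= b - 1e-12 for a, b in zip(ordered, ordered[1:]))
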