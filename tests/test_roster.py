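"""Ratification voting and expert-judgment aggregation."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ismkit.errors import ElicitationError, TieError, ValidationError
from ismkit.roster import (
    DeterminantRoster,
    ExpertJudgmentSet,
    RosterEntry,
    VoteSheet,
    aggregate_judgments,
    ratify_determinants,
    validate_roster,
)
from ismkit.ssim import SYMBOLS, upper_triangle_pairs

EXPERTS = tuple(f"E{i}" for i in range(1, 25))


def sheet(code: int, yes: int, no: int) -> VoteSheet:
    return VoteSheet(code, EXPERTS[: yes + no], (True,) * yes + (False,) * no)


class TestRatification:
    def test_unanimous_yes_included(self):
        res = ratify_determinants([sheet(5, 10, 0)])
        assert 5 in res.included_codes
        assert res.tallies[5] == (10, 0)
        assert not res.tie_flags

    def test_tie_included_and_flagged_under_include_policy(self):
        res = ratify_determinants([sheet(4, 5, 5)], tie_policy="include")
        assert 4 in res.included_codes
        assert 4 in res.tie_flags

    def test_tie_policies_exclude_and_error(self):
        res = ratify_determinants([sheet(4, 5, 5)], tie_policy="exclude")
        assert 4 not in res.included_codes and 4 in res.tie_flags
        with pytest.raises(TieError, match="factor 4"):
            ratify_determinants([sheet(4, 5, 5)], tie_policy="error")

    def test_unanimous_no_excluded(self):
        res = ratify_determinants([sheet(9, 0, 10)])
        assert 9 not in res.included_codes

    def test_empty_panel_and_inconsistent_experts_rejected(self):
        with pytest.raises(ElicitationError):
            ratify_determinants([])
        other = VoteSheet(2, ("A", "B"), (True, False))
        with pytest.raises(ValidationError):
            ratify_determinants([sheet(1, 6, 4), other])

    def test_case_study_votes_ratify_all_eleven(self, study):
        res = ratify_determinants(list(study.votes), tie_policy="include")
        assert res.included_codes == frozenset(range(1, 12))
        assert res.tie_flags == frozenset({4})
        assert res.tallies[1] == (8, 2)
        assert res.tallies[5] == (10, 0)

    @given(yes=st.integers(0, 9), no=st.integers(1, 9))
    @settings(max_examples=60, derandomize=True)
    def test_adding_a_yes_vote_is_monotone(self, yes, no):
        base = ratify_determinants([sheet(1, yes, no)]).included_codes
        more = ratify_determinants([sheet(1, yes + 1, no)]).included_codes
        assert base <= more


def judgment_set(eid: str, codes: tuple[int, ...], symbol: str) -> ExpertJudgmentSet:
    return ExpertJudgmentSet(eid, {p: symbol for p in upper_triangle_pairs(codes)})


class TestAggregation:
    CODES = (1, 2, 3)

    def test_unanimous_panel_is_absolute_majority(self):
        panel = [judgment_set(f"E{i}", self.CODES, "V") for i in range(10)]
        ssim, tallies = aggregate_judgments(panel, self.CODES)
        assert ssim[(1, 2)] == "V"
        assert all(t.majority_kind == "absolute" for t in tallies)

    def test_plurality_winner_matches_direct_count(self):
        # counts V:4 A:3 X:2 O:1 over 10 experts on every pair
        votes = ["V"] * 4 + ["A"] * 3 + ["X"] * 2 + ["O"]
        panel = [judgment_set(f"E{i}", self.CODES, s) for i, s in enumerate(votes)]
        ssim, tallies = aggregate_judgments(panel, self.CODES)
        assert ssim[(1, 2)] == "V"
        for t in tallies:
            assert t.majority_kind == "plurality"
            assert t.counts == {"V": 4, "A": 3, "X": 2, "O": 1}
            # winner maximal by brute-force count
            assert t.counts[t.winner] == max(t.counts.values())

    def test_tie_resolved_by_priority_order_and_flagged(self):
        votes = ["V"] * 5 + ["A"] * 5
        panel = [judgment_set(f"E{i}", self.CODES, s) for i, s in enumerate(votes)]
        ssim, tallies = aggregate_judgments(panel, self.CODES, tie_policy="priority_order")
        assert ssim[(1, 2)] == "V"  # X > V > A > O
        assert all(t.majority_kind == "tie" and t.tied_symbols == ("V", "A") for t in tallies)
        with pytest.raises(TieError, match=r"\(1, 2\)"):
            aggregate_judgments(panel, self.CODES, tie_policy="error")

    def test_single_expert_panel_returns_that_expert(self):
        ex = judgment_set("only", self.CODES, "X")
        ssim, _ = aggregate_judgments([ex], self.CODES)
        assert dict(ssim.symbols) == ex.judgments

    def test_incomplete_triangle_rejected_with_missing_pairs(self):
        ex = ExpertJudgmentSet("E1", {(1, 2): "V"})
        with pytest.raises(ValidationError, match=r"\(1, 3\)"):
            aggregate_judgments([ex], self.CODES)

    @given(
        data=st.lists(
            st.tuples(*[st.sampled_from(SYMBOLS)] * 3), min_size=1, max_size=9
        )
    )
    @settings(max_examples=60, derandomize=True)
    def test_tally_counts_sum_to_panel_size_and_winner_is_maximal(self, data):
        panel = [
            ExpertJudgmentSet(
                f"E{i}", dict(zip(upper_triangle_pairs(self.CODES), syms))
            )
            for i, syms in enumerate(data)
        ]
        ssim, tallies = aggregate_judgments(panel, self.CODES)
        for t in tallies:
            assert sum(t.counts.values()) == len(panel)
            brute = Counter(ex.judgments[t.pair] for ex in panel)
            assert t.counts[t.winner] == max(brute.values())
            assert ssim[t.pair] == t.winner

    def test_identical_panels_reproduce_the_shared_judgments(self, study):
        truth = study.ssim
        panel = [
            ExpertJudgmentSet(f"E{i}", dict(truth.symbols)) for i in range(1, 6)
        ]
        ssim, _ = aggregate_judgments(panel, truth.codes)
        assert ssim == truth


class TestRosterValidation:
    def test_case_study_roster_is_valid(self, study):
        rep = validate_roster(study.roster)
        assert rep.valid and rep.n == 11

    def test_gap_and_duplicate_and_empty_reported(self):
        r = DeterminantRoster(
            (RosterEntry(1, "a"), RosterEntry(3, "b"), RosterEntry(3, ""))
        )
        rep = validate_roster(r)
        assert not rep.valid
        text = " ".join(rep.problems)
        assert "duplicate" in text and "contiguous" in text and "empty labels" in text

    def test_too_small_roster_invalid(self):
        rep = validate_roster(DeterminantRoster((RosterEntry(1, "only"),)))
        assert not rep.valid and rep.n == 1
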