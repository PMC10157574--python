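"""Pair assignment balancing, PHE slots, QC rules, test-retest diagnostics."""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest

import dwkit
from dwkit.survey import (
    PHE_MULTIPLIERS,
    SurveyConfig,
    SurveyError,
    assign_pc_pairs,
    assign_phe_questions,
    qc_filter,
)
from dwkit.survey import test_retest_consistency as retest_consistency


def _pair_counts(assignments, config):
    """Selection counts of unordered pairs over fresh draws only."""
    reps = config.repeated_positions
    counts = Counter()
    for resp in assignments:
        for pos, (a, b) in enumerate(resp, start=1):
            if pos in reps[1:]:
                continue
            counts[frozenset((a, b))] += 1
    return counts


class TestAssignPcPairs:
    def test_repeated_positions_hold_identical_ordered_pair(self):
        cat = dwkit.make_catalog(20, seed=0)
        cfg = SurveyConfig(seed=3)
        out = assign_pc_pairs(cat, 50, cfg)
        for resp in out:
            assert len(resp) == 16
            assert resp[2] == resp[9] == resp[15]  # positions 3, 10, 16
            assert all(a != b for a, b in resp)

    def test_min_selection_spread_at_most_one(self):
        cat = dwkit.make_catalog(8, seed=0)
        cfg = SurveyConfig(seed=5)
        counts = _pair_counts(assign_pc_pairs(cat, 40, cfg), cfg)
        n_pairs = 8 * 7 // 2
        assert len(counts) == n_pairs
        assert max(counts.values()) - min(counts.values()) <= 1

    def test_three_states_three_questions_pigeonhole(self):
        cat = dwkit.make_catalog(3, seed=0)
        cfg = SurveyConfig(n_pc_questions=3, repeated_positions=(1, 2), seed=1)
        # 2 fresh draws per respondent; over 3 respondents all 3 pairs twice
        out = assign_pc_pairs(cat, 3, cfg)
        counts = _pair_counts(out, cfg)
        assert set(counts.values()) == {2}

    def test_full_coverage_of_pair_universe(self):
        # enough respondents that every unordered pair is drawn at least once
        cat = dwkit.make_catalog(15, seed=0)
        cfg = SurveyConfig(seed=2)
        n_pairs = 15 * 14 // 2  # 105; 8 respondents x 14 fresh draws = 112
        counts = _pair_counts(assign_pc_pairs(cat, 8, cfg), cfg)
        assert len(counts) == n_pairs
        assert min(counts.values()) >= 1

    def test_same_seed_reproduces_assignment(self):
        cat = dwkit.make_catalog(12, seed=0)
        cfg = SurveyConfig(seed=9)
        assert assign_pc_pairs(cat, 10, cfg) == assign_pc_pairs(cat, 10, cfg)

    def test_too_few_states_errors(self):
        cat = dwkit.make_catalog(1, seed=0)
        with pytest.raises(SurveyError):
            assign_pc_pairs(cat, 5, SurveyConfig())


class TestAssignPheQuestions:
    def test_balancing_and_household_exclusion(self):
        cat = dwkit.make_catalog(30, n_anchors=4, seed=0)
        resp = pd.DataFrame(
            {
                "respondent_id": [f"r{i}" for i in range(30)],
                "mode": ["web"] * 20 + ["household"] * 10,
                "completion_seconds": 300.0,
            }
        )
        cfg = SurveyConfig(seed=4)
        slots = assign_phe_questions(cat, resp, cfg)
        # 20 web x 3 questions over 4 anchors -> 15 each
        assert len(slots) == 60
        assert set(slots["respondent_id"]) == set(f"r{i}" for i in range(20))
        counts = slots["state"].value_counts()
        assert set(counts) == {15}

    def test_uneven_totals_spread_within_one(self):
        cat = dwkit.make_catalog(30, n_anchors=7, seed=0)
        resp = pd.DataFrame(
            {
                "respondent_id": [f"w{i}" for i in range(11)],
                "mode": "web",
                "completion_seconds": 300.0,
            }
        )
        slots = assign_phe_questions(cat, resp, SurveyConfig(seed=8))
        counts = slots["state"].value_counts()  # 33 slots over 7 anchors
        assert counts.max() - counts.min() <= 1

    def test_multiplier_frequencies_uniform_within_3se(self):
        cat = dwkit.make_catalog(30, n_anchors=5, seed=0)
        n_web = 3140
        resp = pd.DataFrame(
            {
                "respondent_id": [f"w{i}" for i in range(n_web)],
                "mode": "web",
                "completion_seconds": 300.0,
            }
        )
        slots = assign_phe_questions(cat, resp, SurveyConfig(seed=6))
        n = len(slots)
        assert n == 9420
        se = np.sqrt(0.2 * 0.8 / n)
        for m in PHE_MULTIPLIERS:
            freq = (slots["multiplier"] == m).mean()
            assert abs(freq - 0.2) < 3 * se

    def test_no_anchors_errors(self):
        cat = dwkit.make_catalog(5, n_anchors=0, seed=0)
        resp = pd.DataFrame(
            {"respondent_id": ["a"], "mode": "web", "completion_seconds": 300.0}
        )
        with pytest.raises(SurveyError, match="anchor"):
            assign_phe_questions(cat, resp, SurveyConfig())


def _mk_respondent(rid, mode="web", secs=300.0):
    return {"respondent_id": rid, "mode": mode, "completion_seconds": secs}


def _mk_pc(rid, choices):
    return pd.DataFrame(
        {
            "respondent_id": rid,
            "question_index": range(1, len(choices) + 1),
            "first_state": [1] * len(choices),
            "second_state": [2] * len(choices),
            "choice": choices,
        }
    )


class TestQcFilter:
    @pytest.mark.parametrize(
        "choices,rule",
        [
            (["first"] * 16, "all-A"),
            (["second"] * 16, "all-B"),
            (["first", "second"] * 8, "alternation"),
            (["second", "first"] * 8, "alternation"),
        ],
    )
    def test_straightline_patterns_excluded(self, choices, rule):
        resp = pd.DataFrame([_mk_respondent("r1")])
        retained, report = qc_filter(resp, _mk_pc("r1", choices))
        assert len(retained) == 0
        assert report.iloc[0]["rule"] == rule

    def test_single_break_in_alternation_is_retained(self):
        choices = ["first", "second"] * 8
        choices[14], choices[15] = "second", "first"  # one break at the end
        resp = pd.DataFrame([_mk_respondent("r1")])
        retained, report = qc_filter(resp, _mk_pc("r1", choices))
        assert len(retained) == 1 and report.empty

    def test_min_time_applies_to_web_only(self):
        resp = pd.DataFrame(
            [
                _mk_respondent("web1", "web", 150.0),
                _mk_respondent("hh1", "household", 150.0),
            ]
        )
        pc = pd.concat(
            [
                _mk_pc("web1", ["first", "second", "second"] * 5 + ["first"]),
                _mk_pc("hh1", ["first", "second", "second"] * 5 + ["first"]),
            ]
        )
        retained, report = qc_filter(resp, pc)
        assert list(retained["respondent_id"]) == ["hh1"]
        assert report.iloc[0].tolist() == ["web1", "min-time"]

    def test_duplicate_and_incomplete_rules(self):
        resp = pd.DataFrame(
            [
                _mk_respondent("a"),
                _mk_respondent("a"),
                _mk_respondent("b"),
            ]
        )
        pc = pd.concat(
            [
                _mk_pc("a", ["first", "second", "second"] * 5 + ["first"]),
                _mk_pc("b", ["first", "second"]),  # only 2 responses
            ]
        )
        retained, report = qc_filter(resp, pc)
        rules = dict(zip(report["respondent_id"], report["rule"]))
        assert rules == {"a": "duplicate", "b": "incomplete"}
        assert list(retained["respondent_id"]) == ["a"]

    def test_idempotent(self, small_cohort):
        resp, pc = small_cohort["respondents"], small_cohort["pc"]
        retained, _ = qc_filter(resp, pc, small_cohort["config"])
        again, report = qc_filter(
            retained, pc[pc["respondent_id"].isin(retained["respondent_id"])],
            small_cohort["config"],
        )
        assert report.empty
        assert len(again) == len(retained)


class TestRetestConsistency:
    def _pc_with_repeats(self, rid, c3, c10, c16):
        rows = []
        for q in range(1, 17):
            if q in (3, 10, 16):
                first, second = 1, 2
                choice = {3: c3, 10: c10, 16: c16}[q]
            else:
                first, second = 3, 4
                choice = "first"
            rows.append(
                {
                    "respondent_id": rid,
                    "question_index": q,
                    "first_state": first,
                    "second_state": second,
                    "choice": choice,
                }
            )
        return pd.DataFrame(rows)

    def test_full_agreement_scores_one(self):
        per, agg = retest_consistency(
            self._pc_with_repeats("r", "first", "first", "first")
        )
        assert per["r"] == 1.0 and agg == 1.0

    def test_partial_agreement_scores_half(self):
        per, _ = retest_consistency(
            self._pc_with_repeats("r", "first", "second", "second")
        )
        assert per["r"] == 0.5

    def test_different_pairs_at_repeats_is_integrity_error(self):
        pc = self._pc_with_repeats("r", "first", "first", "first")
        pc.loc[pc["question_index"] == 10, "first_state"] = 9
        with pytest.raises(SurveyError, match="different pairs"):
            retest_consistency(pc)

    def test_aggregate_matches_binomial_expectation(self):
        # choice probability p at every showing of the repeated pair:
        # expected agreement with the first answer = p^2 + (1-p)^2
        p = 0.8
        rng = np.random.default_rng(123)
        n = 4000
        frames = []
        for i in range(n):
            draws = rng.random(3) < p
            frames.append(
                self._pc_with_repeats(
                    f"r{i}", *("first" if d else "second" for d in draws)
                )
            )
        _, agg = retest_consistency(pd.concat(frames, ignore_index=True))
        expected = p**2 + (1 - p) ** 2  # 0.68
        se = np.sqrt(expected * (1 - expected) / (2 * n))
        assert abs(agg - expected) < 3 * se
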