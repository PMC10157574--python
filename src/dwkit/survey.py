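"""Survey mechanics: pair assignment, PHE slot assignment, quality control.

This module reproduces the survey's assignment machinery and the data
cleaning applied before estimation:

* paired-comparison (PC) pairs are assigned by *minimum-selection
  balancing*: each new pair is drawn uniformly from the unordered pairs
  that currently have the fewest selections, which keeps the global
  selection counts within a spread of one and guarantees full coverage
  of the pair universe once enough draws have been made;
* one pair per respondent is repeated at fixed questionnaire positions
  (3, 10 and 16 by default) to support test-retest diagnostics; the
  repeated pair is shown in the same presentation order each time;
* web respondents additionally answer PHE questions over the anchor
  subset, with the nonfatal-program size drawn uniformly from
  {1500, 2000, 3000, 5000, 10000};
* quality-control filtering drops duplicate respondents, incomplete PC
  sets, web respondents faster than the minimum completion time, and
  straightlined answer patterns (all-A, all-B, strict alternation).

Respondent and response tables are plain pandas DataFrames with the
column schemas given by ``RESPONDENT_COLUMNS``, ``PC_COLUMNS`` and
``PHE_COLUMNS``; the CSV files the command-line tools read and write use
the same headers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PHE_MULTIPLIERS",
    "RESPONDENT_COLUMNS",
    "PC_COLUMNS",
    "PHE_COLUMNS",
    "SurveyConfig",
    "SurveyError",
    "assign_pc_pairs",
    "assign_phe_questions",
    "qc_filter",
    "test_retest_consistency",
]

#: Allowed sizes of the nonfatal prevention program in a PHE question
#: (the fatal program always prevents 1000 rapid deaths).
PHE_MULTIPLIERS: tuple[int, ...] = (1500, 2000, 3000, 5000, 10000)

RESPONDENT_COLUMNS = (
    "respondent_id", "mode", "completion_seconds",
    "age", "sex", "education", "occupation",
)
PC_COLUMNS = ("respondent_id", "question_index", "first_state", "second_state", "choice")
PHE_COLUMNS = ("respondent_id", "state", "multiplier", "choice")

MODES = ("household", "web")
PC_CHOICES = ("first", "second")
PHE_CHOICES = ("fatal_program", "nonfatal_program")


class SurveyError(ValueError):
    """Raised for invalid survey configuration or malformed response data."""


@dataclass(frozen=True)
class SurveyConfig:
    """Questionnaire design and QC thresholds.

    Defaults are the study design this package models: 16 PC questions
    per respondent with the same pair repeated at positions 3, 10 and 16,
    3 PHE questions per web respondent, and a 3-minute minimum completion
    time for the web survey.
    """

    n_pc_questions: int = 16
    repeated_positions: tuple[int, ...] = (3, 10, 16)
    n_phe_questions: int = 3
    min_completion_seconds: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        reps = tuple(sorted(self.repeated_positions))
        object.__setattr__(self, "repeated_positions", reps)
        if len(reps) < 2:
            raise SurveyError("repeated_positions needs at least 2 positions")
        if not all(1 <= p <= self.n_pc_questions for p in reps):
            raise SurveyError(
                f"repeated_positions {reps} outside 1..{self.n_pc_questions}"
            )
        if len(set(reps)) != len(reps):
            raise SurveyError("repeated_positions must be distinct")
        if self.n_pc_questions < 1 or self.n_phe_questions < 0:
            raise SurveyError("question counts must be positive")
        if self.min_completion_seconds < 0:
            raise SurveyError("min_completion_seconds must be >= 0")

    @property
    def n_fresh_pairs(self) -> int:
        """Distinct pair draws per respondent (repeats reuse one draw)."""
        return self.n_pc_questions - (len(self.repeated_positions) - 1)


def _balanced_stream(items: list, n_draws: int, rng: np.random.Generator) -> list:
    """Draw ``n_draws`` items under minimum-selection balancing.

    Equivalent to repeatedly drawing uniformly from the items with the
    current minimum selection count: concatenate independent uniform
    permutations of the full item list and take draws in order.  The
    max-min spread of selection counts never exceeds one.
    """
    out: list = []
    while len(out) < n_draws:
        perm = rng.permutation(len(items))
        out.extend(items[i] for i in perm)
    return out[:n_draws]


def assign_pc_pairs(
    catalog,
    n_respondents: int,
    config: SurveyConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[list[tuple[int, int]]]:
    """Assign ordered PC pairs to every respondent.

    Returns one list of ``n_pc_questions`` ordered ``(first, second)``
    pairs per respondent.  Pairs at the repeated positions are identical
    within a respondent (same pair, same presentation order).  Each fresh
    pair is drawn by minimum-selection balancing over the unordered pair
    universe and then given a random presentation order.
    """
    config = config or SurveyConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ids = [s.state_id for s in catalog]
    if len(ids) < 2:
        raise SurveyError("catalog needs at least 2 states for paired comparison")
    if n_respondents < 1:
        raise SurveyError("n_respondents must be >= 1")
    pairs = list(itertools.combinations(ids, 2))

    n_fresh = config.n_fresh_pairs
    stream = _balanced_stream(pairs, n_respondents * n_fresh, rng)
    flips = rng.random(n_respondents * n_fresh) < 0.5

    reps = config.repeated_positions
    fresh_positions = [
        p for p in range(1, config.n_pc_questions + 1) if p not in reps[1:]
    ]
    out: list[list[tuple[int, int]]] = []
    for r in range(n_respondents):
        base = r * n_fresh
        by_pos: dict[int, tuple[int, int]] = {}
        for k, pos in enumerate(fresh_positions):
            a, b = stream[base + k]
            by_pos[pos] = (b, a) if flips[base + k] else (a, b)
        for pos in reps[1:]:
            by_pos[pos] = by_pos[reps[0]]
        out.append([by_pos[p] for p in range(1, config.n_pc_questions + 1)])
    return out


def assign_phe_questions(
    catalog,
    respondents: pd.DataFrame,
    config: SurveyConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign PHE question slots to web respondents.

    Each web respondent receives ``n_phe_questions`` slots; anchor states
    are drawn by minimum-selection balancing over the anchor subset and
    multipliers uniformly from :data:`PHE_MULTIPLIERS`.  Household
    respondents receive none.  Returns a DataFrame with columns
    ``respondent_id, state, multiplier``.
    """
    config = config or SurveyConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    anchors = [s.state_id for s in catalog if s.is_phe_anchor]
    if not anchors:
        raise SurveyError("catalog has no PHE anchor states")
    web_ids = respondents.loc[respondents["mode"] == "web", "respondent_id"]
    n_slots = len(web_ids) * config.n_phe_questions
    states = _balanced_stream(anchors, n_slots, rng)
    mults = rng.choice(PHE_MULTIPLIERS, size=n_slots)
    return pd.DataFrame(
        {
            "respondent_id": np.repeat(web_ids.to_numpy(), config.n_phe_questions),
            "state": states,
            "multiplier": mults,
        }
    )


def _is_strict_alternation(choices: np.ndarray) -> bool:
    if len(choices) < 2:
        return False
    return all(choices[i] != choices[i + 1] for i in range(len(choices) - 1))


def qc_filter(
    respondents: pd.DataFrame,
    pc_responses: pd.DataFrame,
    config: SurveyConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the survey's quality-control rules.

    Exclusion rules, applied in order (a respondent is reported under the
    first rule it trips):

    - ``duplicate``: repeated respondent_id rows beyond the first;
    - ``incomplete``: PC set with a number of responses different from
      ``n_pc_questions`` or with repeated question indices;
    - ``min-time``: web respondent faster than the minimum completion
      time (household interviews are interviewer-administered and
      exempt);
    - ``all-A`` / ``all-B``: every choice "first" / every choice
      "second";
    - ``alternation``: strictly alternating choices over the whole
      questionnaire, starting with either option.

    Returns ``(retained_respondents, exclusions)`` where ``exclusions``
    has columns ``respondent_id, rule``.  Filtering is idempotent.
    """
    config = config or SurveyConfig()
    exclusions: list[tuple[str, str]] = []

    dup_mask = respondents["respondent_id"].duplicated()
    for rid in respondents.loc[dup_mask, "respondent_id"]:
        exclusions.append((rid, "duplicate"))
    resp = respondents.loc[~dup_mask]

    grouped = pc_responses.groupby("respondent_id")
    keep: list[bool] = []
    for row in resp.itertuples(index=False):
        rid = row.respondent_id
        try:
            grp = grouped.get_group(rid)
        except KeyError:
            exclusions.append((rid, "incomplete"))
            keep.append(False)
            continue
        if (
            len(grp) != config.n_pc_questions
            or grp["question_index"].duplicated().any()
        ):
            exclusions.append((rid, "incomplete"))
            keep.append(False)
            continue
        if row.mode == "web" and row.completion_seconds < config.min_completion_seconds:
            exclusions.append((rid, "min-time"))
            keep.append(False)
            continue
        choices = grp.sort_values("question_index")["choice"].to_numpy()
        if (choices == "first").all():
            exclusions.append((rid, "all-A"))
            keep.append(False)
        elif (choices == "second").all():
            exclusions.append((rid, "all-B"))
            keep.append(False)
        elif _is_strict_alternation(choices):
            exclusions.append((rid, "alternation"))
            keep.append(False)
        else:
            keep.append(True)

    retained = resp.loc[np.asarray(keep, dtype=bool)].reset_index(drop=True)
    report = pd.DataFrame(exclusions, columns=["respondent_id", "rule"])
    return retained, report


def test_retest_consistency(
    pc_responses: pd.DataFrame,
    config: SurveyConfig | None = None,
) -> tuple[pd.Series, float]:
    """Per-respondent and aggregate agreement on the repeated pair.

    For each respondent, the fraction of successive repeated-position
    pairs (e.g. Q3 vs Q10, then Q10 vs Q16) picking the same *state*
    (presentation order is accounted for by comparing chosen state IDs,
    not answer letters), so one changed answer among three showings
    scores 0.5.  A diagnostic, not a filter.

    Returns ``(per_respondent, aggregate_mean)``.
    """
    config = config or SurveyConfig()
    reps = config.repeated_positions
    sub = pc_responses[pc_responses["question_index"].isin(reps)]
    per: dict[str, float] = {}
    for rid, grp in sub.groupby("respondent_id"):
        grp = grp.set_index("question_index")
        missing = [p for p in reps if p not in grp.index]
        if missing:
            raise SurveyError(
                f"respondent {rid!r}: missing repeated position(s) {missing}"
            )
        pairs = {
            frozenset((grp.loc[p, "first_state"], grp.loc[p, "second_state"]))
            for p in reps
        }
        if len(pairs) != 1:
            raise SurveyError(
                f"respondent {rid!r}: repeated positions hold different pairs"
            )

        def chosen(p):
            row = grp.loc[p]
            return row["first_state"] if row["choice"] == "first" else row["second_state"]

        picks = [chosen(p) for p in reps]
        agree = [a == b for a, b in zip(picks, picks[1:])]
        per[rid] = float(np.mean(agree))
    series = pd.Series(per, name="retest_consistency")
    return series, float(series.mean()) if len(series) else float("nan")
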