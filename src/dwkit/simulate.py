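"""Synthetic survey cohorts with the statistical structure the estimators assume.

The generator draws a ground-truth disability weight (DW) per state from
a right-skewed law on (0, 1) — by default Beta(1.2, 6), calibrated so
most of the mass lies below 0.4 as observed in practice — and converts it
to a latent "healthiness" index through the inverse of the anchoring
model used downstream::

    h(state) = (logit(dw) - a*) / b*,    b* < 0

so that healthier states (lower DW) have a higher index.  Paired-
comparison choices follow a Thurstonian probit rule: the first state is
chosen healthier with probability ``Phi(h_first - h_second)``.  PHE
choices follow a noisy threshold rule: a respondent perceives the
nonfatal program's per-case severity as ``dw * exp(eps)`` with
``eps ~ Normal(0, phe_noise_sd^2)`` and prefers it when the perceived
total benefit ``M * dw * exp(eps)`` exceeds the 1000 prevented deaths,
i.e. ``P(nonfatal) = Phi((ln dw - ln(1000/M)) / phe_noise_sd)``.  Exact
indifference under zero noise resolves to the fatal program.

Default anchor parameters (a* = -2.0, b* = -1.7) center the index near
zero and give a median paired-comparison choice accuracy of about 0.75,
a realistic discrimination level for lay respondents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit, ndtr

from .catalog import HealthState, available_states
from .survey import (
    PHE_MULTIPLIERS,
    RESPONDENT_COLUMNS,
    SurveyConfig,
    assign_pc_pairs,
    assign_phe_questions,
)

__all__ = [
    "TruthSet",
    "DEFAULT_ANCHOR_INTERCEPT",
    "DEFAULT_ANCHOR_SLOPE",
    "DEFAULT_PHE_NOISE_SD",
    "sample_true_dws",
    "latent_health_index",
    "simulate_pc_choice",
    "simulate_phe_choice",
    "generate_cohort",
    "make_catalog",
    "select_anchors",
    "recovery_study",
]

DEFAULT_ANCHOR_INTERCEPT = -2.0   # a*: location of logit(DW) at index 0
DEFAULT_ANCHOR_SLOPE = -1.7       # b*: logit(DW) change per index unit (negative)
DEFAULT_PHE_NOISE_SD = 0.5        # log-scale perception noise in PHE choices
DEFAULT_TRUTH_DISTRIBUTION = stats.beta(1.2, 6.0)


@dataclass(frozen=True)
class TruthSet:
    """Ground truth for a simulated cohort.

    ``true_dw`` maps every DW-available state to a value strictly inside
    (0, 1); ``anchor_intercept``/``anchor_slope`` define the latent-index
    mapping; ``phe_noise_sd`` is the log-scale perception noise of the
    PHE choice rule.
    """

    true_dw: dict[int, float]
    anchor_intercept: float = DEFAULT_ANCHOR_INTERCEPT
    anchor_slope: float = DEFAULT_ANCHOR_SLOPE
    phe_noise_sd: float = DEFAULT_PHE_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.anchor_slope == 0:
            raise ValueError("anchor_slope must be nonzero")
        if self.phe_noise_sd < 0:
            raise ValueError("phe_noise_sd must be >= 0")
        bad = {s: v for s, v in self.true_dw.items() if not (0.0 < v < 1.0)}
        if bad:
            raise ValueError(f"true DWs must lie strictly inside (0, 1): {bad}")


def sample_true_dws(
    catalog: list[HealthState],
    distribution=None,
    seed: int = 0,
    anchor_intercept: float = DEFAULT_ANCHOR_INTERCEPT,
    anchor_slope: float = DEFAULT_ANCHOR_SLOPE,
    phe_noise_sd: float = DEFAULT_PHE_NOISE_SD,
) -> TruthSet:
    """Draw one true DW per DW-available state.

    ``distribution`` may be a frozen scipy distribution on (0, 1)
    (default Beta(1.2, 6)) or a float for a degenerate point mass.
    Reproducible from ``seed``.
    """
    ids = available_states(catalog)
    rng = np.random.default_rng(seed)
    if distribution is None:
        distribution = DEFAULT_TRUTH_DISTRIBUTION
    if isinstance(distribution, (int, float)):
        vals = np.full(len(ids), float(distribution))
    else:
        vals = np.asarray(distribution.rvs(size=len(ids), random_state=rng), dtype=float)
    # keep strictly inside (0,1) against floating-point underflow
    vals = np.clip(vals, 1e-9, 1.0 - 1e-9)
    return TruthSet(
        true_dw=dict(zip(ids, vals.tolist())),
        anchor_intercept=anchor_intercept,
        anchor_slope=anchor_slope,
        phe_noise_sd=phe_noise_sd,
        seed=seed,
    )


def latent_health_index(truth: TruthSet, state_id: int) -> float:
    """Latent healthiness index of a state: ``(logit(dw) - a*) / b*``.

    Strictly decreasing in the true DW (with the default negative slope);
    the exact inverse of the anchoring prediction under zero noise.
    """
    dw = truth.true_dw[state_id]
    return float((logit(dw) - truth.anchor_intercept) / truth.anchor_slope)


def _health_indices(truth: TruthSet, states: np.ndarray) -> np.ndarray:
    dws = np.array([truth.true_dw[s] for s in states])
    return (logit(dws) - truth.anchor_intercept) / truth.anchor_slope


def simulate_pc_choice(h_first: float, h_second: float, rng: np.random.Generator) -> str:
    """One paired-comparison choice: "first" with probability Phi(h1 - h2)."""
    p = ndtr(h_first - h_second)
    return "first" if rng.random() < p else "second"


def simulate_phe_choice(
    true_dw: float,
    multiplier: int,
    phe_noise_sd: float,
    rng: np.random.Generator,
) -> str:
    """One PHE choice under the noisy threshold rule.

    Chooses "nonfatal_program" iff the perceived benefit
    ``M * dw * exp(eps)`` exceeds 1000, i.e. with probability
    ``Phi((ln dw - ln(1000/M)) / sd)``; with ``sd = 0`` the rule is the
    deterministic threshold ``dw > 1000/M``, ties going to the fatal
    program.
    """
    threshold = 1000.0 / multiplier
    if phe_noise_sd == 0:
        return "nonfatal_program" if true_dw > threshold else "fatal_program"
    z = (np.log(true_dw) - np.log(threshold)) / phe_noise_sd
    return "nonfatal_program" if rng.random() < ndtr(z) else "fatal_program"


_EDUCATION = ("elementary_or_below", "middle_school", "high_school", "college_or_above")
_OCCUPATION = ("non_manual", "manual", "other")


def _sample_demographics(n: int, mode: str, rng: np.random.Generator) -> dict:
    high = 70 if mode == "web" else 90
    return {
        "age": rng.integers(18, high, size=n),
        "sex": rng.choice(["male", "female"], size=n),
        "education": rng.choice(_EDUCATION, size=n, p=[0.08, 0.14, 0.21, 0.57]),
        "occupation": rng.choice(_OCCUPATION, size=n, p=[0.45, 0.20, 0.35]),
    }


def generate_cohort(
    catalog: list[HealthState],
    truth: TruthSet,
    n_household: int = 2610,
    n_web: int = 3140,
    config: SurveyConfig | None = None,
    invalid_fraction: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic survey dataset.

    Returns ``(respondents, pc_responses, phe_responses)`` DataFrames.
    Pair assignment runs over DW-available states only (states with no
    estimable DW have no latent index to compare).  Completion times are
    sampled above the QC threshold so a clean cohort passes filtering by
    construction; ``invalid_fraction`` injects deliberately invalid
    respondents, each tagged with its rule in the ``injected_rule``
    column of the respondent table (empty string for valid rows).
    """
    config = config or SurveyConfig()
    rng = np.random.default_rng(config.seed)
    avail = [s for s in catalog if s.dw_available]

    frames = []
    for mode, n in (("household", n_household), ("web", n_web)):
        if n == 0:
            continue
        prefix = "H" if mode == "household" else "W"
        base = 180.0 if mode == "web" else 0.0
        frames.append(
            pd.DataFrame(
                {
                    "respondent_id": [f"{prefix}{i:05d}" for i in range(1, n + 1)],
                    "mode": mode,
                    "completion_seconds": np.round(
                        base + rng.lognormal(mean=np.log(300.0), sigma=0.5, size=n), 1
                    ),
                    **_sample_demographics(n, mode, rng),
                }
            )
        )
    respondents = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(RESPONDENT_COLUMNS))
    )
    respondents["injected_rule"] = ""
    n_total = len(respondents)

    # --- PC responses -----------------------------------------------------
    assignments = assign_pc_pairs(avail, n_total, config, rng) if n_total else []
    rows = {
        "respondent_id": np.repeat(
            respondents["respondent_id"].to_numpy(), config.n_pc_questions
        ),
        "question_index": np.tile(
            np.arange(1, config.n_pc_questions + 1), n_total
        ),
        "first_state": np.array(
            [p[0] for resp in assignments for p in resp], dtype=int
        ),
        "second_state": np.array(
            [p[1] for resp in assignments for p in resp], dtype=int
        ),
    }
    h1 = _health_indices(truth, rows["first_state"]) if n_total else np.array([])
    h2 = _health_indices(truth, rows["second_state"]) if n_total else np.array([])
    p_first = ndtr(h1 - h2)
    rows["choice"] = np.where(
        rng.random(len(p_first)) < p_first, "first", "second"
    )
    pc_responses = pd.DataFrame(rows)

    # --- PHE responses ----------------------------------------------------
    slots = assign_phe_questions(catalog, respondents, config, rng)
    if len(slots):
        dws = np.array([truth.true_dw[s] for s in slots["state"]])
        thresholds = 1000.0 / slots["multiplier"].to_numpy()
        if truth.phe_noise_sd == 0:
            nonfatal = dws > thresholds
        else:
            z = (np.log(dws) - np.log(thresholds)) / truth.phe_noise_sd
            nonfatal = rng.random(len(dws)) < ndtr(z)
        slots = slots.assign(
            choice=np.where(nonfatal, "nonfatal_program", "fatal_program")
        )
    else:
        slots = slots.assign(choice=pd.Series(dtype=str))
    phe_responses = slots

    # --- injected invalid respondents ------------------------------------
    if invalid_fraction > 0 and n_total:
        n_bad = int(round(invalid_fraction * n_total))
        bad_idx = rng.choice(n_total, size=n_bad, replace=False)
        pc_by_rid = pc_responses.groupby("respondent_id", sort=False).indices
        for i in bad_idx:
            rid = respondents.at[i, "respondent_id"]
            web = respondents.at[i, "mode"] == "web"
            rules = ["all-A", "all-B", "alternation"] + (["min-time"] if web else [])
            rule = rules[rng.integers(len(rules))]
            respondents.at[i, "injected_rule"] = rule
            if rule == "min-time":
                respondents.at[i, "completion_seconds"] = float(
                    np.round(rng.uniform(10, config.min_completion_seconds - 1), 1)
                )
                continue
            idx = pc_by_rid[rid]
            if rule == "all-A":
                pattern = ["first"] * config.n_pc_questions
            elif rule == "all-B":
                pattern = ["second"] * config.n_pc_questions
            else:
                start = int(rng.integers(2))
                pattern = [
                    ("first", "second")[(start + k) % 2]
                    for k in range(config.n_pc_questions)
                ]
            pc_responses.loc[idx, "choice"] = pattern

    return respondents, pc_responses, phe_responses


def make_catalog(
    n_states: int,
    n_anchors: int = 0,
    seed: int = 0,
    flag_probability: float = 0.2,
) -> list[HealthState]:
    """A small synthetic catalog for simulation studies and tests.

    Flags are independent Bernoulli draws; anchors, if requested, are
    spread evenly over the state IDs (use :func:`select_anchors` to place
    them by true severity instead).
    """
    rng = np.random.default_rng(seed)
    anchor_ids = set()
    if n_anchors:
        anchor_ids = set(
            np.linspace(1, n_states, n_anchors).round().astype(int).tolist()
        )
    return [
        HealthState(
            state_id=i,
            label=f"State {i}",
            lay_description=f"Synthetic lay description of state {i}",
            symptom_flags=tuple(rng.random(11) < flag_probability),
            is_phe_anchor=i in anchor_ids,
        )
        for i in range(1, n_states + 1)
    ]


def select_anchors(
    catalog: list[HealthState],
    dws: dict[int, float],
    n_anchors: int,
    min_dw: float = 0.05,
    max_dw: float = 0.95,
) -> list[HealthState]:
    """Mark an anchor subset spanning mild to severe states.

    Picks ``n_anchors`` DW-available states at evenly spaced ranks of
    ``dws`` (mirroring the survey design, whose PHE subset ranged from
    mild to severe) and returns a catalog with ``is_phe_anchor`` set on
    exactly those states.  Candidates are restricted to ``[min_dw,
    max_dw]``: the PHE thresholds 1000/M span DWs 0.1 to 2/3, so states
    far outside that band are essentially unmeasurable by the PHE
    instrument (nearly every respondent gives the same answer at every
    multiplier) and make uninformative, high-leverage anchors.
    """
    ranked = sorted(
        (
            s.state_id
            for s in catalog
            if s.dw_available and s.state_id in dws and min_dw <= dws[s.state_id] <= max_dw
        ),
        key=lambda sid: dws[sid],
    )
    if n_anchors > len(ranked):
        raise ValueError("more anchors requested than DW-available states")
    idx = np.linspace(0, len(ranked) - 1, n_anchors).round().astype(int)
    chosen = {ranked[i] for i in idx}
    return [s.with_anchor(s.state_id in chosen) for s in catalog]


def recovery_study(
    seed: int = 0,
    n_datasets: int = 3,
    n_states: int = 30,
    n_anchors: int = 10,
    n_household: int = 1000,
    n_web: int = 1000,
    n_bootstrap: int = 200,
    n_mc: int = 500,
) -> dict:
    """Parameter-recovery simulation on a reduced universe.

    For each of ``n_datasets`` independent replicates: draw a truth set,
    generate a cohort, QC-filter it, run the full estimation pipeline,
    and score the recovered DWs against truth.  Metrics are pooled over
    all states of all replicates:

    - ``pearson_r`` / ``spearman_rho`` between estimated and true DWs;
    - ``median_abs_error`` of the point estimates;
    - ``ui_coverage``: fraction of states whose true DW falls inside
      the bootstrap 95% uncertainty interval.

    Reduced defaults (30 states, 2000 respondents, 10 anchors, 200
    bootstrap replicates) keep a full study under a couple of minutes.
    """
    import warnings

    from scipy import stats as _stats

    from .pipeline import RunConfig, estimate_dws
    from .survey import qc_filter

    true_all: list[float] = []
    est_all: list[float] = []
    cover_all: list[bool] = []
    per_dataset = []
    base = np.random.SeedSequence(seed)
    for rep, child in enumerate(base.spawn(n_datasets)):
        s1, s2, s3, s4 = (int(x) for x in child.generate_state(4) >> 1)
        catalog = make_catalog(n_states, seed=s1)
        truth = sample_true_dws(catalog, seed=s2)
        catalog = select_anchors(catalog, truth.true_dw, n_anchors)
        cfg = SurveyConfig(seed=s3)
        respondents, pc, phe = generate_cohort(
            catalog, truth, n_household, n_web, cfg
        )
        retained, _ = qc_filter(respondents, pc, cfg)
        kept = set(retained["respondent_id"])
        pc = pc[pc["respondent_id"].isin(kept)].reset_index(drop=True)
        phe = phe[phe["respondent_id"].isin(kept)].reset_index(drop=True)
        run_cfg = RunConfig(seed=s4, n_bootstrap=n_bootstrap, n_mc=n_mc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bundle = estimate_dws(pc, phe, retained, catalog, run_cfg)
        res = bundle["results"]
        true = np.array([truth.true_dw[s] for s in res["state_id"]])
        est = res["dw_mean"].to_numpy()
        lo = res["ui_low"].to_numpy()
        hi = res["ui_high"].to_numpy()
        covered = (true >= lo) & (true <= hi)
        true_all.extend(true)
        est_all.extend(est)
        cover_all.extend(covered)
        per_dataset.append(
            {
                "replicate": rep,
                "pearson_r": float(_stats.pearsonr(true, est)[0]),
                "median_abs_error": float(np.median(np.abs(true - est))),
                "ui_coverage": float(covered.mean()),
            }
        )
    true_arr, est_arr = np.asarray(true_all), np.asarray(est_all)
    return {
        "pearson_r": float(_stats.pearsonr(true_arr, est_arr)[0]),
        "spearman_rho": float(_stats.spearmanr(true_arr, est_arr)[0]),
        "median_abs_error": float(np.median(np.abs(true_arr - est_arr))),
        "ui_coverage": float(np.mean(cover_all)),
        "n_states_scored": len(true_arr),
        "per_dataset": per_dataset,
    }
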