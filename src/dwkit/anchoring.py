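"""Anchoring the probit index to the 0-1 DW scale, with uncertainty.

The paired-comparison probit yields a unitless healthiness index per
state; the PHE interval regression yields disability weights for the
anchor subset only.  The anchoring step links the two with an ordinary
least-squares regression over the anchor states,

    T(DW_PHE)  ~  a + b * r(state)

where the regressor ``r`` is the probit predicted probability
``Phi(beta)`` by default (the latent index ``beta`` itself as an
option), and the dependent scale ``T`` is the logit by default (so
predictions stay inside (0, 1) without clamping) or the identity.  All
states then receive ``DW = T^{-1}(a + b * r)``.

Uncertainty is attached two ways, mirroring standard practice for this
estimator family:

* *Monte Carlo means*: beta vectors are drawn from the multivariate
  normal defined by the probit estimate and covariance, pushed through
  the anchoring prediction, and averaged per state;
* *bootstrap 95% uncertainty intervals*: respondents (the exchangeable
  unit) are resampled with replacement, stratified by survey mode so the
  web-only PHE structure is preserved; the whole probit -> interval ->
  anchor -> predict chain is re-run per replicate and the 2.5th/97.5th
  percentiles of the replicate DWs taken per state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .catalog import HealthState
from .interval import IntervalError, _fit_arrays, _transform, phe_dw_estimates
from .probit import PCDesign, ProbitFit, fit_probit

__all__ = [
    "AnchorModel",
    "AnchoringError",
    "fit_anchor",
    "predict_dws",
    "monte_carlo_mean",
    "bootstrap_ui",
    "assemble_estimates",
]


class AnchoringError(ValueError):
    """Raised when the anchoring regression cannot be fitted."""


@dataclass(frozen=True)
class AnchorModel:
    """Fitted anchoring line mapping the probit index onto the DW scale."""

    intercept: float
    slope: float
    dependent_scale: str = "logit"   # T applied to the PHE DWs
    regressor: str = "probability"   # Phi(beta) or the raw index
    r_squared: float = float("nan")
    n_anchors: int = 0


def _regressor_values(fit: ProbitFit, regressor: str) -> dict[int, float]:
    if regressor == "probability":
        return {s: float(ndtr(b)) for s, b in fit.beta.items()}
    if regressor == "index":
        return dict(fit.beta)
    raise AnchoringError(f"unknown regressor {regressor!r}")


def fit_anchor(
    phe_dws: dict[int, float],
    probit_fit: ProbitFit,
    anchor_states=None,
    dependent_scale: str = "logit",
    regressor: str = "probability",
) -> AnchorModel:
    """OLS of transformed PHE DWs on the probit regressor over anchors.

    Needs at least two anchor states carrying both a PHE DW and a probit
    beta, with non-degenerate regressor values.
    """
    if anchor_states is None:
        anchor_states = sorted(phe_dws)
    rvals = _regressor_values(probit_fit, regressor)
    usable = [s for s in anchor_states if s in phe_dws and s in rvals]
    if len(usable) < 2:
        raise AnchoringError(
            f"need >= 2 anchor states with both PHE DW and probit beta; "
            f"got {len(usable)}"
        )
    fwd, _ = _transform(dependent_scale) if dependent_scale == "logit" else (
        (lambda v: v), None
    )
    x = np.array([rvals[s] for s in usable])
    y = np.array([fwd(phe_dws[s]) for s in usable], dtype=float)
    if np.ptp(x) == 0:
        raise AnchoringError("zero variance in the anchoring regressor")
    xc = x - x.mean()
    slope = float((xc @ (y - y.mean())) / (xc @ xc))
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
    return AnchorModel(
        intercept=intercept,
        slope=slope,
        dependent_scale=dependent_scale,
        regressor=regressor,
        r_squared=r2,
        n_anchors=len(usable),
    )


def predict_dws(
    anchor: AnchorModel,
    probit_fit: ProbitFit,
    catalog: list[HealthState] | None = None,
) -> dict[int, float]:
    """Anchored DW point estimates for every fitted state.

    With the logit dependent scale predictions lie in (0, 1) by
    construction; with the identity scale they are clamped to [0, 1]
    (a warning reports the clamp count).
    """
    rvals = _regressor_values(probit_fit, anchor.regressor)
    states = (
        [s.state_id for s in catalog if s.state_id in rvals]
        if catalog is not None
        else sorted(rvals)
    )
    lin = np.array([anchor.intercept + anchor.slope * rvals[s] for s in states])
    if anchor.dependent_scale == "logit":
        dws = expit(lin)
    else:
        clamped = int(((lin < 0) | (lin > 1)).sum())
        if clamped:
            warnings.warn(
                f"{clamped} identity-scale DW prediction(s) clamped to [0, 1]",
                stacklevel=2,
            )
        dws = np.clip(lin, 0.0, 1.0)
    return {s: float(d) for s, d in zip(states, dws)}


def _mvn_draws(
    mean: np.ndarray, cov: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Draws from N(mean, cov) tolerating the (singular) constrained vcov."""
    w, V = np.linalg.eigh((cov + cov.T) / 2.0)
    if w.min() < -1e-8 * max(1.0, w.max()):
        warnings.warn(
            "probit covariance not PSD; repaired by clipping negative "
            f"eigenvalues (min eigenvalue {w.min():.3g})",
            stacklevel=3,
        )
    L = V * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n_draws, len(mean)))
    return mean + z @ L.T


def monte_carlo_mean(
    anchor: AnchorModel,
    probit_fit: ProbitFit,
    n_draws: int = 1000,
    seed: int = 0,
) -> dict[int, float]:
    """Monte Carlo integration of the anchored DW over probit uncertainty.

    Draws beta vectors from the normal approximation of the probit fit,
    pushes each through the anchoring prediction, and averages per
    state.  Reproducible from ``seed``; a zero covariance returns the
    point prediction exactly.
    """
    rng = np.random.default_rng(seed)
    beta = probit_fit.beta_vector()
    draws = _mvn_draws(beta, probit_fit.vcov, n_draws, rng)
    r = ndtr(draws) if anchor.regressor == "probability" else draws
    lin = anchor.intercept + anchor.slope * r
    if anchor.dependent_scale == "logit":
        dws = expit(lin)
    else:
        dws = np.clip(lin, 0.0, 1.0)
    means = dws.mean(axis=0)
    return {s: float(m) for s, m in zip(probit_fit.states, means)}


def _replicate_dws(
    first: np.ndarray,
    second: np.ndarray,
    outcome: np.ndarray,
    phe_state: np.ndarray,
    phe_bound: np.ndarray,
    phe_right: np.ndarray,
    *,
    penalty: float,
    scale: str,
    regressor: str,
    dependent_scale: str,
    constraint: str,
) -> dict[int, float]:
    """Run probit -> interval -> anchor -> predict on one data realization."""
    present = np.unique(np.concatenate([first, second]))
    if len(present) < 2:
        raise AnchoringError("fewer than 2 states present in replicate")
    fidx = np.searchsorted(present, first)
    sidx = np.searchsorted(present, second)
    design = PCDesign(
        states=tuple(int(s) for s in present),
        first_idx=fidx,
        second_idx=sidx,
        outcome=outcome,
    )
    pfit = fit_probit(design, penalty=penalty, constraint=constraint)
    ifit = _fit_arrays(phe_state, phe_bound, phe_right, scale)
    phe_dws = phe_dw_estimates(ifit)
    # boundary-pinned locations carry no PHE information; keep them out
    # of the anchoring line
    usable = [s for s in phe_dws if s not in ifit.boundary_states]
    anchor = fit_anchor(
        phe_dws,
        pfit,
        anchor_states=usable,
        dependent_scale=dependent_scale,
        regressor=regressor,
    )
    return predict_dws(anchor, pfit)


def bootstrap_ui(
    pc_responses: pd.DataFrame,
    phe_responses: pd.DataFrame,
    respondents: pd.DataFrame,
    n_reps: int = 1000,
    seed: int = 0,
    penalty: float = 1e-6,
    scale: str = "logit",
    regressor: str = "probability",
    dependent_scale: str = "logit",
    constraint: str = "sum_zero",
) -> tuple[dict[int, tuple[float, float]], dict]:
    """Respondent-level bootstrap 95% uncertainty intervals.

    Respondents are resampled with replacement, stratified by survey
    mode (household/web counts preserved); the full estimation chain is
    re-run per replicate.  Per state, the UI is the 2.5th/97.5th
    percentile of its replicate DWs; replicates where a state drops out
    are excluded for that state.  States absent from more than 10% of
    replicates are flagged unreliable in the report.

    Expects QC-filtered data.  Returns ``(ui, report)`` with ``report``
    carrying per-state replicate coverage and failed-replicate counts.
    """
    rng = np.random.default_rng(seed)

    pc_first = pc_responses["first_state"].to_numpy()
    pc_second = pc_responses["second_state"].to_numpy()
    pc_outcome = (pc_responses["choice"].to_numpy() == "first").astype(np.int8)
    pc_rows = pc_responses.groupby("respondent_id", sort=False).indices

    fwd, _ = _transform(scale)
    phe_state_all = phe_responses["state"].to_numpy()
    phe_bound_all = np.asarray(
        fwd(1000.0 / phe_responses["multiplier"].to_numpy())
    )
    phe_right_all = phe_responses["choice"].to_numpy() == "nonfatal_program"
    phe_rows = phe_responses.groupby("respondent_id", sort=False).indices

    by_mode = {
        mode: grp["respondent_id"].to_numpy()
        for mode, grp in respondents.groupby("mode", sort=False)
    }
    all_states = np.unique(np.concatenate([pc_first, pc_second]))
    state_pos = {int(s): i for i, s in enumerate(all_states)}
    reps = np.full((n_reps, len(all_states)), np.nan)
    n_failed = 0

    empty = np.array([], dtype=np.int64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_reps):
            pc_idx_parts, phe_idx_parts = [], []
            for mode, ids in by_mode.items():
                draw = rng.choice(ids, size=len(ids), replace=True)
                for rid in draw:
                    pc_idx_parts.append(pc_rows.get(rid, empty))
                    if mode == "web":
                        phe_idx_parts.append(phe_rows.get(rid, empty))
            pc_idx = np.concatenate(pc_idx_parts) if pc_idx_parts else empty
            phe_idx = np.concatenate(phe_idx_parts) if phe_idx_parts else empty
            try:
                dws = _replicate_dws(
                    pc_first[pc_idx],
                    pc_second[pc_idx],
                    pc_outcome[pc_idx],
                    phe_state_all[phe_idx],
                    phe_bound_all[phe_idx],
                    phe_right_all[phe_idx],
                    penalty=penalty,
                    scale=scale,
                    regressor=regressor,
                    dependent_scale=dependent_scale,
                    constraint=constraint,
                )
            except (AnchoringError, IntervalError):
                n_failed += 1
                continue
            for s, d in dws.items():
                reps[r, state_pos[s]] = d

    coverage = np.isfinite(reps).sum(axis=0)
    ui: dict[int, tuple[float, float]] = {}
    unreliable: list[int] = []
    for s, j in state_pos.items():
        if coverage[j] == 0:
            unreliable.append(s)
            ui[s] = (float("nan"), float("nan"))
            continue
        col = reps[np.isfinite(reps[:, j]), j]
        lo, hi = np.percentile(col, [2.5, 97.5])
        ui[s] = (float(lo), float(hi))
        if coverage[j] < 0.9 * (n_reps - n_failed):
            unreliable.append(s)
    report = {
        "n_reps": n_reps,
        "n_failed": n_failed,
        "state_coverage": {s: int(coverage[j]) for s, j in state_pos.items()},
        "unreliable_states": sorted(unreliable),
    }
    return ui, report


def assemble_estimates(
    dw_mean: dict[int, float],
    ui: dict[int, tuple[float, float]],
    catalog: list[HealthState] | None = None,
    n_bootstrap: int = 0,
) -> pd.DataFrame:
    """Combine means and bootstrap UIs into the results table.

    Enforces ``ui_low <= dw_mean <= ui_high`` by widening an interval to
    include the mean when percentile noise violates it (with a warning).
    Values are kept at full precision; exports round to 3 decimals.
    """
    labels = (
        {s.state_id: s.label for s in catalog} if catalog is not None else {}
    )
    rows, widened = [], 0
    for s in sorted(dw_mean):
        m = dw_mean[s]
        lo, hi = ui.get(s, (float("nan"), float("nan")))
        flags = []
        if np.isfinite(lo) and lo > m:
            lo, widened = m, widened + 1
            flags.append("ui_widened")
        if np.isfinite(hi) and hi < m:
            hi, widened = m, widened + 1
            flags.append("ui_widened")
        rows.append(
            {
                "state_id": s,
                "label": labels.get(s, ""),
                "dw_mean": m,
                "ui_low": lo,
                "ui_high": hi,
                "n_bootstrap": n_bootstrap,
                "flags": ";".join(dict.fromkeys(flags)),
            }
        )
    if widened:
        warnings.warn(
            f"widened {widened} uncertainty bound(s) to include the mean",
            stacklevel=2,
        )
    return pd.DataFrame(rows)
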