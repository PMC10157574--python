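"""Interval regression of population-health-equivalence (PHE) choices.

A PHE question opposes a program preventing 1000 rapid deaths to one
preventing ``M`` lifelong nonfatal cases of a given health state, with
``M`` in {1500, 2000, 3000, 5000, 10000}.  A respondent preferring the
nonfatal program reveals ``DW > 1000/M``; preferring the fatal program
reveals ``DW < 1000/M``.  Each response is therefore a one-sided
censored observation of the state's disability weight on a transformed
scale ``T`` (logit by default, natural log as an option):

    nonfatal choice  ->  (T(1000/M), +inf)
    fatal choice     ->  (-inf, T(1000/M))

The censored-normal (interval regression) model places a location
``gamma_state`` per anchor state and a common residual standard
deviation ``sigma``; maximum likelihood maximizes

    sum_i log[ Phi((upper_i - gamma_s(i)) / sigma)
               - Phi((lower_i - gamma_s(i)) / sigma) ]

with the infinite bounds handled as CDF limits.  Locations are bounded
to ``T((1e-4, 1 - 1e-4))`` so states with all responses on one side pin
to the boundary (with a warning) instead of diverging.  The inverse
transform of ``gamma`` is the state's PHE disability weight, the
dependent variable of the anchoring step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, log_ndtr, logit

from .catalog import HealthState
from .survey import PHE_MULTIPLIERS

__all__ = [
    "CensoredObservation",
    "IntervalFit",
    "IntervalError",
    "phe_to_interval",
    "build_observations",
    "fit_interval_regression",
    "phe_dw_estimates",
]

_DW_FLOOR = 1e-4  # location box: gamma in T([1e-4, 1 - 1e-4])


class IntervalError(ValueError):
    """Raised for invalid PHE data or unidentifiable interval models."""


@dataclass(frozen=True)
class CensoredObservation:
    """One PHE response as a transformed-scale interval (one finite bound)."""

    state: int
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise IntervalError(f"empty interval: ({self.lower}, {self.upper})")


def _transform(scale: str):
    if scale == "logit":
        return logit, expit
    if scale == "log":
        return np.log, np.exp
    raise IntervalError(f"unknown scale {scale!r} (use 'logit' or 'log')")


def phe_to_interval(
    state: int, multiplier: int, choice: str, scale: str = "logit"
) -> CensoredObservation:
    """Map one PHE response to its censored observation.

    The threshold is ``t = 1000 / multiplier`` on the DW scale;
    a nonfatal-program choice gives ``(T(t), +inf)``, a fatal-program
    choice ``(-inf, T(t))``.
    """
    if multiplier not in PHE_MULTIPLIERS:
        raise IntervalError(
            f"invalid multiplier {multiplier}; expected one of {PHE_MULTIPLIERS}"
        )
    fwd, _ = _transform(scale)
    bound = float(fwd(1000.0 / multiplier))
    if choice == "nonfatal_program":
        return CensoredObservation(state=state, lower=bound, upper=np.inf)
    if choice == "fatal_program":
        return CensoredObservation(state=state, lower=-np.inf, upper=bound)
    raise IntervalError(f"invalid PHE choice {choice!r}")


def build_observations(
    phe_responses: pd.DataFrame, scale: str = "logit"
) -> list[CensoredObservation]:
    """Vector version of :func:`phe_to_interval` over a response table."""
    return [
        phe_to_interval(int(r.state), int(r.multiplier), r.choice, scale)
        for r in phe_responses.itertuples(index=False)
    ]


@dataclass(frozen=True)
class IntervalFit:
    """Fitted censored-normal model: per-state locations, common sigma."""

    gamma: dict[int, float]
    sigma: float
    loglik: float
    scale_name: str = "logit"
    n_observations: int = 0
    boundary_states: tuple[int, ...] = ()


def fit_interval_regression(
    observations,
    catalog: list[HealthState] | None = None,
    scale: str = "logit",
) -> IntervalFit:
    """Maximum-likelihood interval regression over PHE observations.

    ``observations`` is a list of :class:`CensoredObservation` or a PHE
    response DataFrame (converted with the given scale).  Requires at
    least one state with responses in both directions, otherwise the
    common ``sigma`` is unidentifiable.  Optimization is deterministic:
    per-state locations start at the mean of the state's finite bounds,
    ``sigma`` at 1, and L-BFGS-B with analytic gradients runs to
    convergence within the location box.
    """
    if isinstance(observations, pd.DataFrame):
        observations = build_observations(observations, scale)
    if not observations:
        raise IntervalError("no PHE observations to fit")
    if catalog is not None:
        anchors = {s.state_id for s in catalog if s.is_phe_anchor}
        bad = sorted({o.state for o in observations} - anchors)
        if bad:
            raise IntervalError(f"PHE observations for non-anchor state(s): {bad}")

    state_ids = np.array([o.state for o in observations])
    upper = np.array([o.upper for o in observations])
    right = np.isinf(upper)   # (bound, +inf): choice said DW above threshold
    bound = np.where(
        right, np.array([o.lower for o in observations]), upper
    )
    return _fit_arrays(state_ids, bound, right, scale)


def _fit_arrays(
    state_ids: np.ndarray, bound: np.ndarray, right: np.ndarray, scale: str
) -> IntervalFit:
    """Core censored-normal MLE on flat arrays (one finite bound per row)."""
    if len(state_ids) == 0:
        raise IntervalError("no PHE observations to fit")
    states, sidx = np.unique(state_ids, return_inverse=True)
    states = [int(s) for s in states]
    if not right.any() or right.all():
        raise IntervalError(
            "all observations censored in the same direction; "
            "sigma is unidentifiable"
        )
    has_r = np.zeros(len(states), dtype=bool)
    has_l = np.zeros(len(states), dtype=bool)
    np.logical_or.at(has_r, sidx, right)
    np.logical_or.at(has_l, sidx, ~right)
    if not (has_r & has_l).any():
        raise IntervalError(
            "no state has observations in both directions; "
            "sigma is unidentifiable"
        )

    fwd, _ = _transform(scale)
    lo_box, hi_box = float(fwd(_DW_FLOOR)), float(fwd(1.0 - _DW_FLOOR))

    gamma0 = np.zeros(len(states))
    for k in range(len(states)):
        gamma0[k] = np.clip(bound[sidx == k].mean(), lo_box, hi_box)

    def unpack(params):
        return params[:-1], np.exp(params[-1])

    def neg_loglik_and_grad(params):
        gamma, sigma = unpack(params)
        g = gamma[sidx]
        # signed standardized distance u with log P(obs) = log Phi(u):
        #   right-censored: u = (gamma - L)/sigma; left: u = (U - gamma)/sigma
        sgn = np.where(right, 1.0, -1.0)
        u = sgn * (g - bound) / sigma
        ll = log_ndtr(u).sum()
        lam = np.exp(-0.5 * u * u - 0.5 * np.log(2 * np.pi) - log_ndtr(u))
        d_u = lam  # dloglik/du per row
        dg_rows = d_u * sgn / sigma
        grad_gamma = np.zeros(len(states))
        np.add.at(grad_gamma, sidx, dg_rows)
        # du/dlog_sigma = -u
        grad_logsigma = float((d_u * (-u)).sum())
        return -ll, np.concatenate([-grad_gamma, [-grad_logsigma]])

    x0 = np.concatenate([gamma0, [0.0]])
    bounds = [(lo_box, hi_box)] * len(states) + [(np.log(1e-6), np.log(1e3))]
    res = optimize.minimize(
        neg_loglik_and_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    if not res.success and "CONVERGENCE" not in str(res.message).upper():
        raise IntervalError(f"interval regression failed to converge: {res.message}")
    gamma_hat, sigma_hat = unpack(res.x)
    at_boundary = tuple(
        states[k]
        for k in range(len(states))
        if gamma_hat[k] <= lo_box + 1e-8 or gamma_hat[k] >= hi_box - 1e-8
    )
    if at_boundary:
        warnings.warn(
            f"interval-regression location(s) pinned at the DW boundary for "
            f"state(s) {list(at_boundary)} (one-sided data)",
            stacklevel=2,
        )
    return IntervalFit(
        gamma={s: float(g) for s, g in zip(states, gamma_hat)},
        sigma=float(sigma_hat),
        loglik=float(-res.fun),
        scale_name=scale,
        n_observations=len(state_ids),
        boundary_states=at_boundary,
    )


def phe_dw_estimates(fit: IntervalFit) -> dict[int, float]:
    """Per-anchor-state disability weights: the inverse transform of gamma."""
    _, inv = _transform(fit.scale_name)
    return {s: float(inv(g)) for s, g in fit.gamma.items()}
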