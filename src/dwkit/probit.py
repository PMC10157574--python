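"""Thurstonian probit scaling of paired-comparison choices.

Each paired-comparison response contributes one row of a design matrix
with a ``+1`` in the column of the state shown first, a ``-1`` in the
column of the state shown second, and zeros elsewhere; the outcome is 1
when the first state is chosen as the healthier one.  The probit model

    P(Y = 1 | X) = Phi(X' beta)

is fitted by penalized maximum likelihood, giving a latent "healthiness"
index ``beta`` per state.  Because the design only identifies pairwise
differences, the location of ``beta`` is pinned by a constraint —
sum-to-zero over the included states by default, or a reference state
fixed at zero.  A small ridge penalty (1e-6 by default) keeps estimates
finite under quasi-complete separation, where a state wins or loses
every one of its comparisons.

The optimizer is a damped Newton iteration on the free parameters with
analytic gradient and observed-information Hessian; the log-likelihood
is concave, the start is ``beta = 0``, and convergence is declared when
the free-parameter gradient max-norm drops below 1e-8, so the fit is
deterministic given the design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

from .catalog import HealthState

__all__ = [
    "PCDesign",
    "ProbitFit",
    "ProbitError",
    "ProbitConvergenceError",
    "build_design",
    "probit_loglik",
    "fit_probit",
    "predicted_probability",
    "predicted_probabilities",
]


class ProbitError(ValueError):
    """Raised for malformed paired-comparison designs."""


class ProbitConvergenceError(RuntimeError):
    """Raised when the Newton iteration fails to converge."""


@dataclass(frozen=True)
class PCDesign:
    """Sparse encoding of the +1/-1/0 paired-comparison design.

    ``states`` lists the included state IDs (the matrix columns, in
    order); ``first_idx``/``second_idx`` give, per response row, the
    column index of the state coded +1 / -1; ``outcome`` is 1 when the
    first state was chosen healthier.
    """

    states: tuple[int, ...]
    first_idx: np.ndarray
    second_idx: np.ndarray
    outcome: np.ndarray
    n_dropped: int = 0

    @property
    def n_responses(self) -> int:
        return len(self.outcome)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def matrix(self) -> np.ndarray:
        """Materialize the dense design matrix (small problems only)."""
        X = np.zeros((self.n_responses, self.n_states))
        X[np.arange(self.n_responses), self.first_idx] = 1.0
        X[np.arange(self.n_responses), self.second_idx] = -1.0
        return X


def build_design(
    pc_responses: pd.DataFrame, catalog: list[HealthState]
) -> PCDesign:
    """Convert PC responses into the probit design.

    Responses referencing states with no estimable DW are excluded with
    a warning (and counted in ``n_dropped``); a response comparing a
    state with itself is a data error.
    """
    available = {s.state_id for s in catalog if s.dw_available}
    first = pc_responses["first_state"].to_numpy()
    second = pc_responses["second_state"].to_numpy()
    if (first == second).any():
        bad = first[first == second]
        raise ProbitError(f"response compares a state with itself: {bad[:5].tolist()}")
    ok = np.isin(first, list(available)) & np.isin(second, list(available))
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(
            f"excluded {n_dropped} response(s) referencing states with no "
            "estimable DW",
            stacklevel=2,
        )
    first, second = first[ok], second[ok]
    seen = sorted(set(first.tolist()) | set(second.tolist()))
    index = {sid: i for i, sid in enumerate(seen)}
    outcome = (pc_responses.loc[ok, "choice"].to_numpy() == "first").astype(np.int8)
    return PCDesign(
        states=tuple(seen),
        first_idx=np.array([index[s] for s in first], dtype=np.int64),
        second_idx=np.array([index[s] for s in second], dtype=np.int64),
        outcome=outcome,
        n_dropped=n_dropped,
    )


@dataclass(frozen=True)
class ProbitFit:
    """Fitted probit scaling model.

    ``beta`` maps state_id to its healthiness index under the chosen
    identifiability constraint; ``vcov`` is the covariance of the full
    beta vector (singular by construction: the constraint removes one
    degree of freedom), ordered like ``states``.
    """

    states: tuple[int, ...]
    beta: dict[int, float]
    vcov: np.ndarray
    loglik: float
    penalty: float
    n_responses: int
    constraint: str = "sum_zero"
    n_iter: int = 0
    separated_states: tuple[int, ...] = ()

    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta[s] for s in self.states])


def _signed_z(beta_vec: np.ndarray, design: PCDesign) -> np.ndarray:
    """q_i * x_i' beta where q_i = +-1 encodes the outcome."""
    z = beta_vec[design.first_idx] - beta_vec[design.second_idx]
    q = np.where(design.outcome == 1, 1.0, -1.0)
    return q * z


def probit_loglik(
    beta, design: PCDesign, penalty: float = 0.0
) -> float:
    """Penalized probit log-likelihood of a beta vector (or state map).

    ``sum_i log Phi(q_i x_i' beta) - penalty * ||beta||^2``, computed
    with the numerically safe log-CDF.
    """
    if isinstance(beta, dict):
        beta = np.array([beta[s] for s in design.states])
    beta = np.asarray(beta, dtype=float)
    u = _signed_z(beta, design)
    return float(log_ndtr(u).sum() - penalty * (beta @ beta))


def _constraint_basis(n: int, constraint: str, ref_idx: int = 0) -> np.ndarray:
    """Map free parameters theta (n-1) to the full beta vector (n)."""
    C = np.zeros((n, n - 1))
    if constraint == "sum_zero":
        C[: n - 1, :] = np.eye(n - 1)
        C[n - 1, :] = -1.0
    elif constraint == "reference":
        free = [i for i in range(n) if i != ref_idx]
        for j, i in enumerate(free):
            C[i, j] = 1.0
    else:
        raise ValueError(f"unknown constraint {constraint!r}")
    return C


def fit_probit(
    design: PCDesign,
    penalty: float = 1e-6,
    constraint: str = "sum_zero",
    reference_state: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ProbitFit:
    """Maximize the penalized probit likelihood under a location constraint.

    ``constraint`` is ``"sum_zero"`` (default: the betas of all included
    states sum to zero) or ``"reference"`` (the ``reference_state`` beta
    is fixed at zero).  States winning or losing every comparison are
    reported as separated (the ridge penalty keeps them finite).  The
    covariance is the inverse observed information on the free
    parameters, mapped back to the full beta vector.
    """
    if design.n_responses == 0:
        raise ProbitError("empty design: no responses to fit")
    n = design.n_states
    if n < 2:
        raise ProbitError("need at least 2 states in the design")

    # separation diagnostics: per-state win fraction
    wins = np.zeros(n)
    shows = np.zeros(n)
    q = design.outcome.astype(float)
    np.add.at(wins, design.first_idx, q)
    np.add.at(wins, design.second_idx, 1.0 - q)
    np.add.at(shows, design.first_idx, 1.0)
    np.add.at(shows, design.second_idx, 1.0)
    sep = [i for i in range(n) if wins[i] in (0.0, shows[i])]
    if sep:
        names = [design.states[i] for i in sep]
        warnings.warn(
            f"quasi-complete separation: state(s) {names} win or lose every "
            "comparison; estimates regularized by the ridge penalty",
            stacklevel=2,
        )

    ref_idx = 0
    if constraint == "reference":
        if reference_state is None:
            reference_state = design.states[0]
        ref_idx = design.states.index(reference_state)
    C = _constraint_basis(n, constraint, ref_idx)

    def grad_hess(beta_vec):
        u = _signed_z(beta_vec, design)
        qsign = np.where(design.outcome == 1, 1.0, -1.0)
        lam = np.exp(norm.logpdf(u) - log_ndtr(u))  # phi/Phi, stable
        g_z = qsign * lam                            # dloglik/dz per row
        w = lam * (lam + u)                          # -d2loglik/dz2, > 0
        g = np.zeros(n)
        np.add.at(g, design.first_idx, g_z)
        np.add.at(g, design.second_idx, -g_z)
        g -= 2.0 * penalty * beta_vec
        H = np.zeros((n, n))
        np.add.at(H, (design.first_idx, design.first_idx), w)
        np.add.at(H, (design.second_idx, design.second_idx), w)
        np.add.at(H, (design.first_idx, design.second_idx), -w)
        np.add.at(H, (design.second_idx, design.first_idx), -w)
        H += 2.0 * penalty * np.eye(n)               # H = observed information
        return g, H

    theta = np.zeros(n - 1)
    ll = probit_loglik(C @ theta, design, penalty)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        beta_vec = C @ theta
        g, H = grad_hess(beta_vec)
        g_free = C.T @ g
        if np.max(np.abs(g_free)) < tol:
            break
        H_free = C.T @ H @ C
        step = np.linalg.solve(H_free, g_free)
        # cap the step: under separation the penalized ridge direction is
        # nearly flat and the raw Newton step can be enormous
        biggest = np.max(np.abs(step))
        if biggest > 2.0:
            step *= 2.0 / biggest
        # damped Newton: halve until the objective improves.  The
        # acceptance slack is relative to |loglik| so float-level noise
        # near the optimum cannot reject the final tightening steps.
        slack = 1e-12 * (1.0 + abs(ll))
        scale = 1.0
        for _ in range(50):
            cand = theta + scale * step
            ll_new = probit_loglik(C @ cand, design, penalty)
            if ll_new >= ll - slack:
                theta, ll = cand, ll_new
                break
            scale *= 0.5
        else:  # pragma: no cover - concave objective, should not happen
            raise ProbitConvergenceError("line search failed to improve")
    else:
        raise ProbitConvergenceError(
            f"no convergence after {max_iter} iterations "
            f"(gradient max-norm {np.max(np.abs(g_free)):.3g})"
        )

    beta_vec = C @ theta
    _, H = grad_hess(beta_vec)
    H_free = C.T @ H @ C
    vcov_free = np.linalg.inv(H_free)
    vcov = C @ vcov_free @ C.T
    return ProbitFit(
        states=design.states,
        beta={s: float(b) for s, b in zip(design.states, beta_vec)},
        vcov=vcov,
        loglik=float(probit_loglik(beta_vec, design, penalty=0.0)),
        penalty=penalty,
        n_responses=design.n_responses,
        constraint=constraint,
        n_iter=n_iter,
        separated_states=tuple(design.states[i] for i in sep),
    )


def predicted_probability(fit: ProbitFit, state_id: int) -> float:
    """Model probability ``Phi(beta_state)`` that the state is judged
    healthier than a hypothetical average state (index zero)."""
    if state_id not in fit.beta:
        raise KeyError(f"state {state_id} not in fit")
    return float(ndtr(fit.beta[state_id]))


def predicted_probabilities(fit: ProbitFit) -> dict[int, float]:
    """``Phi(beta)`` for every included state."""
    return {s: float(ndtr(b)) for s, b in fit.beta.items()}
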