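"""Anchoring regression, Monte Carlo means, bootstrap uncertainty."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit, ndtr

import dwkit
from dwkit.anchoring import (
    AnchoringError,
    assemble_estimates,
    bootstrap_ui,
    fit_anchor,
    monte_carlo_mean,
    predict_dws,
)
from dwkit.probit import ProbitFit


def make_fit(betas: dict, vcov=None, constraint="sum_zero"):
    """A ProbitFit stub with prescribed betas and covariance."""
    states = tuple(sorted(betas))
    if vcov is None:
        vcov = np.zeros((len(states), len(states)))
    return ProbitFit(
        states=states,
        beta={s: float(betas[s]) for s in states},
        vcov=np.asarray(vcov, dtype=float),
        loglik=0.0,
        penalty=0.0,
        n_responses=0,
        constraint=constraint,
    )


class TestFitAnchor:
    def test_exact_line_recovered(self):
        a, b = 0.7, -3.1
        betas = {s: x for s, x in zip(range(1, 7), np.linspace(-1, 1, 6))}
        fit = make_fit(betas)
        phe = {s: float(expit(a + b * ndtr(v))) for s, v in betas.items()}
        model = fit_anchor(phe, fit, regressor="probability")
        assert model.intercept == pytest.approx(a, abs=1e-10)
        assert model.slope == pytest.approx(b, abs=1e-10)
        assert model.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(77)
        betas = {s: v for s, v in zip(range(1, 29), rng.normal(0, 0.8, 28))}
        fit = make_fit(betas)
        phe = {
            s: float(expit(-2.0 - 2.5 * ndtr(v) + rng.normal(0, 0.2)))
            for s, v in betas.items()
        }
        model = fit_anchor(phe, fit, regressor="probability")
        X = np.column_stack(
            [np.ones(28), [ndtr(betas[s]) for s in sorted(betas)]]
        )
        y = np.array([logit(phe[s]) for s in sorted(betas)])
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        assert model.intercept == pytest.approx(coef[0], abs=1e-9)
        assert model.slope == pytest.approx(coef[1], abs=1e-9)

    def test_healthier_anchors_with_lower_dw_give_negative_slope(self):
        betas = {1: -1.0, 2: 0.0, 3: 1.0}
        phe = {1: 0.5, 2: 0.2, 3: 0.05}  # healthier -> lower DW
        model = fit_anchor(phe, make_fit(betas))
        assert model.slope < 0

    def test_too_few_anchors_or_degenerate_regressor_error(self):
        with pytest.raises(AnchoringError, match=">= 2"):
            fit_anchor({1: 0.3}, make_fit({1: 0.0, 2: 0.1}))
        with pytest.raises(AnchoringError, match="variance"):
            fit_anchor({1: 0.3, 2: 0.4}, make_fit({1: 0.5, 2: 0.5}))


class TestPredictDws:
    def test_interpolates_anchors_on_perfect_line(self):
        betas = {s: x for s, x in zip(range(1, 5), [-0.9, -0.2, 0.4, 1.1])}
        fit = make_fit(betas)
        phe = {s: float(expit(-1.5 - 2.0 * ndtr(v))) for s, v in betas.items()}
        model = fit_anchor(phe, fit)
        pred = predict_dws(model, fit)
        for s in betas:
            assert pred[s] == pytest.approx(phe[s], abs=1e-12)

    def test_monotone_decreasing_in_beta_for_negative_slope(self):
        betas = {s: x for s, x in zip(range(1, 11), np.linspace(-1.2, 1.2, 10))}
        fit = make_fit(betas)
        phe = {1: 0.55, 5: 0.2, 10: 0.04}
        model = fit_anchor(phe, fit)
        pred = predict_dws(model, fit)
        ordered = [pred[s] for s in range(1, 11)]
        assert all(a > b for a, b in zip(ordered, ordered[1:]))
        assert all(0 < v < 1 for v in ordered)

    def test_identity_scale_clamps_with_warning(self):
        betas = {1: -2.0, 2: 0.0, 3: 2.0}
        fit = make_fit(betas)
        phe = {1: 0.9, 2: 0.4, 3: 0.05}
        model = fit_anchor(phe, fit, dependent_scale="identity", regressor="index")
        assert model.dependent_scale == "identity"
        wide = make_fit({1: -4.0, 2: 0.0, 3: 4.0})
        with pytest.warns(UserWarning, match="clamped"):
            pred = predict_dws(model, wide)
        assert 0.0 <= min(pred.values()) and max(pred.values()) <= 1.0


class TestMonteCarloMean:
    def test_zero_vcov_returns_point_prediction(self):
        betas = {1: -0.5, 2: 0.0, 3: 0.5}
        fit = make_fit(betas)
        model = fit_anchor({1: 0.4, 2: 0.2, 3: 0.1}, fit)
        point = predict_dws(model, fit)
        mc = monte_carlo_mean(model, fit, n_draws=500, seed=4)
        for s in betas:
            assert mc[s] == pytest.approx(point[s], abs=1e-12)

    def test_matches_gauss_hermite_quadrature(self):
        # diagonal vcov: each state's mean is a 1-D normal integral
        betas = {1: -0.4, 2: 0.6}
        var = {1: 0.05, 2: 0.12}
        fit = make_fit(betas, vcov=np.diag([var[1], var[2]]))
        model = fit_anchor(
            {1: 0.35, 2: 0.08}, make_fit(betas), regressor="probability"
        )
        n = 40_000
        mc = monte_carlo_mean(model, fit, n_draws=n, seed=11)
        nodes, weights = np.polynomial.hermite_e.hermegauss(80)
        for s in betas:
            vals = expit(
                model.intercept
                + model.slope * ndtr(betas[s] + np.sqrt(var[s]) * nodes)
            )
            quad = float(weights @ vals / np.sqrt(2 * np.pi))
            # MC standard error of the mean for this integrand
            draws = expit(
                model.intercept
                + model.slope
                * ndtr(betas[s] + np.sqrt(var[s]) * np.random.default_rng(1).standard_normal(n))
            )
            se = draws.std() / np.sqrt(n)
            assert abs(mc[s] - quad) < 3 * se

    def test_same_seed_same_means(self):
        betas = {1: -0.3, 2: 0.3}
        fit = make_fit(betas, vcov=np.eye(2) * 0.04)
        model = fit_anchor({1: 0.3, 2: 0.1}, make_fit(betas))
        assert monte_carlo_mean(model, fit, seed=9) == monte_carlo_mean(
            model, fit, seed=9
        )


def _degenerate_cohort(n=12):
    """n identical web respondents with identical answers."""
    respondents = pd.DataFrame(
        {
            "respondent_id": [f"w{i}" for i in range(n)],
            "mode": "web",
            "completion_seconds": 400.0,
        }
    )
    pc_rows, phe_rows = [], []
    pattern = [
        (1, 2, "first"), (2, 3, "first"), (3, 4, "first"), (1, 3, "first"),
        (2, 4, "first"), (1, 4, "first"), (2, 1, "first"), (3, 2, "first"),
        (4, 3, "second"), (3, 1, "second"), (4, 2, "second"), (4, 1, "second"),
    ]
    for i in range(n):
        for q, (f, s, c) in enumerate(pattern, start=1):
            pc_rows.append(
                {
                    "respondent_id": f"w{i}",
                    "question_index": q,
                    "first_state": f,
                    "second_state": s,
                    "choice": c,
                }
            )
        phe_rows += [
            {"respondent_id": f"w{i}", "state": 2, "multiplier": 2000,
             "choice": "nonfatal_program"},
            {"respondent_id": f"w{i}", "state": 2, "multiplier": 1500,
             "choice": "fatal_program"},
            {"respondent_id": f"w{i}", "state": 3, "multiplier": 5000,
             "choice": "fatal_program"},
            {"respondent_id": f"w{i}", "state": 3, "multiplier": 10000,
             "choice": "nonfatal_program"},
        ]
    return respondents, pd.DataFrame(pc_rows), pd.DataFrame(phe_rows)


class TestBootstrapUi:
    def test_degenerate_cohort_gives_zero_width_intervals(self):
        respondents, pc, phe = _degenerate_cohort()
        ui, report = bootstrap_ui(pc, phe, respondents, n_reps=25, seed=3)
        assert report["n_failed"] == 0
        for lo, hi in ui.values():
            assert lo == pytest.approx(hi, abs=1e-12)

    def test_reproducible_from_seed(self, small_cohort, small_catalog):
        args = (
            small_cohort["pc"],
            small_cohort["phe"],
            small_cohort["respondents"],
        )
        ui1, _ = bootstrap_ui(*args, n_reps=10, seed=21)
        ui2, _ = bootstrap_ui(*args, n_reps=10, seed=21)
        assert ui1 == ui2


class TestAssembleEstimates:
    def test_mean_outside_percentiles_widens_with_warning(self):
        dw_mean = {1: 0.30, 2: 0.10}
        ui = {1: (0.32, 0.40), 2: (0.05, 0.08)}
        with pytest.warns(UserWarning, match="widened"):
            table = assemble_estimates(dw_mean, ui, n_bootstrap=100)
        assert (table["ui_low"] <= table["dw_mean"]).all()
        assert (table["dw_mean"] <= table["ui_high"]).all()
        assert set(table.loc[table["flags"] != "", "state_id"]) == {1, 2}

    def test_well_ordered_input_unchanged(self):
        table = assemble_estimates({1: 0.2}, {1: (0.1, 0.3)}, n_bootstrap=5)
        row = table.iloc[0]
        assert (row["ui_low"], row["dw_mean"], row["ui_high"]) == (0.1, 0.2, 0.3)
        assert row["flags"] == ""
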