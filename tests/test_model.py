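"""Conditional Poisson likelihood, Newton fit, Wald intervals and contrasts.

The independent oracles here are deliberately naive: plain-Python multinomial
log-likelihoods and coarse-to-fine grid searches over the coefficient space.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from mphsccs.model import EstimationError, SCCSModel, SCCSResults
from mphsccs.scenarios import ScenarioConfig, collect_intervals, runs_to_table
from mphsccs.simulate import toy_fixture


def _table(rows):
    """rows: (patient_id, category, age_band, season, length, events)"""
    return pd.DataFrame(
        rows,
        columns=["patient_id", "category", "age_band", "season", "length_days", "events"],
    )


def brute_force_loglik(table: pd.DataFrame, coef: dict) -> float:
    """Per-patient multinomial probability, computed with plain Python loops."""
    total = 0.0
    for _, group in table.groupby("patient_id"):
        weights = []
        for _, row in group.iterrows():
            eta = 0.0
            if row.category == "pre_exposure":
                eta += coef.get("pre_exposure", 0.0)
            elif row.category == "exposed":
                eta += coef.get("exposed", 0.0)
            eta += coef.get(f"age[{row.age_band}]", 0.0)
            eta += coef.get(f"season[{row.season}]", 0.0)
            weights.append(row.length_days * math.exp(eta))
        denom = sum(weights)
        for w, n in zip(weights, group.events):
            if n:
                total += n * math.log(w / denom)
    return total


def grid_search_mle(model: SCCSModel, span=6.0, refine_to=1e-5):
    """Coarse-to-fine grid search over 1 or 2 free coefficients."""
    k = model._X.shape[1]
    assert k in (1, 2), "oracle supports 1-2 parameters"
    centre = np.zeros(k)
    width = span
    while width > refine_to:
        axes = [np.linspace(c - width, c + width, 21) for c in centre]
        best, best_ll = None, -np.inf
        if k == 1:
            for a in axes[0]:
                ll = model.loglik_grad_hess(np.array([a]))[0]
                if ll > best_ll:
                    best, best_ll = np.array([a]), ll
        else:
            for a in axes[0]:
                for b in axes[1]:
                    ll = model.loglik_grad_hess(np.array([a, b]))[0]
                    if ll > best_ll:
                        best, best_ll = np.array([a, b]), ll
        centre = best
        width /= 5.0
    return centre


class TestLikelihood:
    def test_closed_form_at_zero(self):
        table = _table([("A", "exposed", 0, 1, 100, 1), ("A", "baseline", 0, 1, 300, 0)])
        model = SCCSModel(table, adjust_age=False, adjust_season=False)
        ll, grad, hess = model.loglik_grad_hess(np.zeros(1))
        assert ll == pytest.approx(math.log(100 / 400), abs=1e-12)

    def test_matches_brute_force_on_random_small_datasets(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            rows = []
            for pid in range(rng.integers(2, 5)):
                n_iv = int(rng.integers(2, 6))
                cats = rng.choice(["baseline", "pre_exposure", "exposed"], n_iv)
                cats[0] = "baseline"
                event_at = int(rng.integers(0, n_iv))
                for j in range(n_iv):
                    rows.append(
                        (
                            f"P{pid}",
                            cats[j],
                            int(rng.integers(6, 9)),
                            int(rng.integers(1, 5)),
                            int(rng.integers(5, 400)),
                            int(j == event_at),
                        )
                    )
            table = _table(rows)
            model = SCCSModel(table)
            coef = rng.normal(0, 0.7, len(model.term_names))
            ll = model.loglik_grad_hess(coef)[0]
            oracle = brute_force_loglik(table, dict(zip(model.term_names, coef)))
            assert ll == pytest.approx(oracle, abs=1e-10)

    def test_gradient_vanishes_at_optimum(self, data500, pre90_scenario):
        kept, _ = collect_intervals(data500, pre90_scenario)
        model = SCCSModel(runs_to_table(kept))
        results = model.fit()
        grad = model.loglik_grad_hess(results.params.to_numpy())[1]
        assert np.max(np.abs(grad)) < 1e-6
        assert results.converged

    def test_numeric_gradient_and_hessian(self):
        table = _table(
            [
                ("A", "exposed", 6, 1, 120, 1),
                ("A", "baseline", 6, 2, 250, 0),
                ("B", "exposed", 7, 1, 60, 0),
                ("B", "baseline", 7, 1, 400, 1),
            ]
        )
        model = SCCSModel(table)
        coef = np.array([0.3, -0.2, 0.1])[: len(model.term_names)]
        ll, grad, hess = model.loglik_grad_hess(coef)
        eps = 1e-6
        for i in range(len(coef)):
            up, down = coef.copy(), coef.copy()
            up[i] += eps
            down[i] -= eps
            num = (model.loglik_grad_hess(up)[0] - model.loglik_grad_hess(down)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(num, abs=1e-5)
            gnum = (model.loglik_grad_hess(up)[1] - model.loglik_grad_hess(down)[1]) / (2 * eps)
            np.testing.assert_allclose(hess[:, i], gnum, atol=1e-5)


class TestFit:
    def test_two_patient_closed_form_irr3(self):
        table = _table(
            [
                ("A", "exposed", 0, 1, 100, 1),
                ("A", "baseline", 0, 1, 300, 0),
                ("B", "exposed", 0, 1, 100, 0),
                ("B", "baseline", 0, 1, 300, 1),
            ]
        )
        results = SCCSModel(table, adjust_age=False, adjust_season=False).fit()
        assert math.exp(results.params["exposed"]) == pytest.approx(3.0, abs=1e-8)

    def test_irr3_fixture_through_pipeline(self):
        data = toy_fixture("irr3_pair").to_data()
        scenario = ScenarioConfig(name="primary", pre_exposure_days=0)
        kept, _ = collect_intervals(data, scenario)
        results = SCCSModel(
            runs_to_table(kept), adjust_age=False, adjust_season=False
        ).fit()
        assert math.exp(results.params["exposed"]) == pytest.approx(3.0, abs=1e-8)

    def test_no_information_raises(self):
        data = toy_fixture("no_information").to_data()
        scenario = ScenarioConfig(name="primary", pre_exposure_days=0)
        kept, _ = collect_intervals(data, scenario)
        with pytest.raises(EstimationError):
            SCCSModel(runs_to_table(kept), adjust_age=False, adjust_season=False).fit()

    def test_one_parameter_score_equation(self):
        """MLE solves sum(n_exp) = sum(t_e*rho / (t_e*rho + t_b)) (root-finding oracle)."""
        from scipy.optimize import brentq

        rows, rng = [], np.random.default_rng(8)
        for pid in range(6):
            te, tb = int(rng.integers(20, 200)), int(rng.integers(100, 600))
            in_exposed = int(rng.random() < 0.5)
            rows.append((f"P{pid}", "exposed", 0, 1, te, in_exposed))
            rows.append((f"P{pid}", "baseline", 0, 1, tb, 1 - in_exposed))
        table = _table(rows)
        results = SCCSModel(table, adjust_age=False, adjust_season=False).fit()
        te = table[table.category == "exposed"].set_index("patient_id").length_days
        tb = table[table.category == "baseline"].set_index("patient_id").length_days
        n_exp = table[table.category == "exposed"].events.sum()

        def score(rho):
            return sum(
                te[p] * rho / (te[p] * rho + tb[p]) for p in te.index
            ) - n_exp

        rho_oracle = brentq(score, 1e-6, 1e6, xtol=1e-12)
        assert math.exp(results.params["exposed"]) == pytest.approx(rho_oracle, rel=1e-7)

    def test_grid_search_oracle_two_params(self):
        table = _table(
            [
                ("A", "pre_exposure", 0, 1, 90, 1),
                ("A", "exposed", 0, 1, 140, 0),
                ("A", "baseline", 0, 1, 700, 0),
                ("B", "pre_exposure", 0, 1, 60, 0),
                ("B", "exposed", 0, 1, 300, 1),
                ("B", "baseline", 0, 1, 900, 0),
                ("C", "pre_exposure", 0, 1, 90, 0),
                ("C", "exposed", 0, 1, 180, 0),
                ("C", "baseline", 0, 1, 1100, 1),
                ("D", "exposed", 0, 1, 90, 1),
                ("D", "baseline", 0, 1, 500, 0),
            ]
        )
        model = SCCSModel(table, adjust_age=False, adjust_season=False)
        fitted = model.fit().params.to_numpy()
        oracle = grid_search_mle(model)
        np.testing.assert_allclose(fitted, oracle, atol=1e-4)

    def test_refinement_invariance(self, data500, pre90_scenario):
        """Splitting every interval in half leaves the estimates unchanged."""
        kept, _ = collect_intervals(data500, pre90_scenario)
        table = runs_to_table(kept)
        base = SCCSModel(table).fit()
        halves = []
        for _, row in table.iterrows():
            L = int(row.length_days)
            a = dict(row)
            if L == 1:
                halves.append(a)
                continue
            b = dict(row)
            a["length_days"], b["length_days"] = L // 2, L - L // 2
            b["events"] = 0  # keep the event in the first half
            halves.append(a)
            halves.append(b)
        refined = SCCSModel(pd.DataFrame(halves)).fit()
        np.testing.assert_allclose(
            base.params.to_numpy(), refined.params.to_numpy(), atol=1e-10
        )

    def test_time_scale_invariance(self):
        table = _table(
            [
                ("A", "exposed", 0, 1, 100, 1),
                ("A", "baseline", 0, 1, 300, 0),
                ("B", "exposed", 0, 1, 40, 0),
                ("B", "baseline", 0, 1, 360, 1),
            ]
        )
        base = SCCSModel(table, adjust_age=False, adjust_season=False).fit()
        scaled = table.assign(length_days=table.length_days * 7)
        refit = SCCSModel(scaled, adjust_age=False, adjust_season=False).fit()
        np.testing.assert_allclose(
            base.params.to_numpy(), refit.params.to_numpy(), atol=1e-9
        )

    def test_noninformative_patients_do_not_move_estimates(self):
        informative = [
            ("A", "exposed", 0, 1, 100, 1),
            ("A", "baseline", 0, 1, 300, 0),
            ("B", "exposed", 0, 1, 100, 0),
            ("B", "baseline", 0, 1, 300, 1),
        ]
        extra = [("Z", "baseline", 0, 1, 500, 1)]  # single covariate pattern
        base = SCCSModel(_table(informative), adjust_age=False, adjust_season=False).fit()
        padded = SCCSModel(
            _table(informative + extra), adjust_age=False, adjust_season=False
        ).fit()
        assert padded.n_dropped_noninformative == 1
        assert padded.n_cases_used == 2
        np.testing.assert_allclose(
            base.params.to_numpy(), padded.params.to_numpy(), atol=1e-12
        )


class TestWaldAndContrast:
    def _fake_results(self, coefs, cov):
        terms = list(coefs)
        return SCCSResults(
            model=None,
            params=pd.Series(coefs),
            cov=pd.DataFrame(cov, index=terms, columns=terms),
            loglik=0.0,
            converged=True,
            iterations=1,
            n_cases_used=1,
            n_dropped_noninformative=0,
        )

    def test_wald_closed_form(self):
        res = self._fake_results({"exposed": 0.0}, [[0.0625]])  # se 0.25
        est = res.wald("exposed")
        assert est.irr == pytest.approx(1.0)
        assert est.ci_low == pytest.approx(math.exp(-1.959964 * 0.25), abs=1e-4)
        assert est.ci_high == pytest.approx(math.exp(1.959964 * 0.25), abs=1e-4)
        assert est.p_value == pytest.approx(1.0)

    def test_wald_ci_brackets_point(self):
        res = self._fake_results({"pre_exposure": math.log(4.64)}, [[0.15]])
        est = res.wald("pre_exposure")
        assert est.ci_low < 4.64 < est.ci_high
        assert est.irr == pytest.approx(4.64, abs=1e-9)

    def test_missing_term_raises(self):
        res = self._fake_results({"exposed": 0.0}, [[1.0]])
        with pytest.raises(KeyError):
            res.wald("pre_exposure")

    def test_contrast_identity_and_arithmetic(self):
        cov = [[0.04, 0.0], [0.0, 0.09]]
        res = self._fake_results(
            {"exposed": math.log(2.0), "pre_exposure": math.log(4.0)}, cov
        )
        same = res.contrast("exposed", "exposed")
        assert same.irr == pytest.approx(1.0) and same.ci_low == pytest.approx(1.0)
        diff = res.contrast("exposed", "pre_exposure")
        assert diff.irr == pytest.approx(0.5)

    def test_contrast_matches_reparameterised_fit(self, data500, pre90_scenario):
        """Swapping the reference category reproduces the contrast (oracle)."""
        kept, _ = collect_intervals(data500, pre90_scenario)
        table = runs_to_table(kept)
        results = SCCSModel(table).fit()
        contrast = results.contrast("exposed", "pre_exposure")
        # recode so pre-exposure becomes the reference level
        swapped = table.copy()
        swapped["category"] = swapped["category"].map({0: 1, 1: 0, 2: 2})
        reparam = SCCSModel(swapped).fit()
        assert math.log(contrast.irr) == pytest.approx(
            float(reparam.params["exposed"]), abs=1e-8
        )

    def test_summary_mentions_terms_and_diagnostics(self, data500, pre90_scenario):
        kept, _ = collect_intervals(data500, pre90_scenario)
        res = SCCSModel(runs_to_table(kept)).fit()
        text = res.summary()
        assert "exposed" in text and "pre_exposure" in text
        assert "cases used: 500" in text
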