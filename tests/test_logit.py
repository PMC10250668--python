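"""In-house logistic regression: ML fit, Wald inference, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from nptpredict.logit import (
    SeparationError,
    accuracy_at_half,
    add_intercept,
    box_tidwell,
    fit_logistic,
    model_chi2,
    nagelkerke_r2,
    predict_probability,
    wald_or_ci,
)


def _sim(rng, n, beta):
    """Bernoulli data from a known logistic model (intercept + slopes)."""
    k = len(beta) - 1
    x = rng.normal(size=(n, k))
    eta = beta[0] + x @ np.asarray(beta[1:])
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    design = add_intercept(pd.DataFrame(x, columns=[f"x{i}" for i in range(k)]))
    return design, y


class TestFit:
    def test_null_data_gives_near_zero_slope(self, rng):
        design, y = _sim(rng, 2000, [0.0, 0.0])
        fit = fit_logistic(design, y)
        assert abs(fit.params["x0"]) < 0.15
        assert abs(fit.params["const"]) < 0.15

    def test_saturated_2x2_closed_form(self):
        """Binary predictor: the slope is the log odds ratio ln(351/44)."""
        x = np.concatenate([np.ones(61), np.zeros(11)])
        y = np.concatenate([np.ones(39), np.zeros(22), np.ones(2), np.zeros(9)])
        design = add_intercept(pd.DataFrame({"x": x}))
        fit = fit_logistic(design, y)
        assert fit.params["x"] == pytest.approx(math.log(351 / 44), abs=1e-8)
        assert fit.params["const"] == pytest.approx(math.log(2 / 9), abs=1e-8)
        assert fit.exp_b["x"] == pytest.approx(351 / 44, rel=1e-8)

    def test_odds_ratio_ci_arithmetic(self):
        """B=0.886, SE=0.334 -> OR 2.425 with 95% CI (1.260, 4.667)."""
        or_, (lo, hi) = wald_or_ci(0.886, 0.334)
        # agreement to the printed precision (the source table rounds B and
        # SE themselves, so the last CI digit can move by half a unit)
        assert or_ == pytest.approx(2.425, abs=1e-3)
        assert lo == pytest.approx(1.260, abs=1e-3)
        assert hi == pytest.approx(4.667, abs=1e-3)

    def test_score_equations_vanish_at_convergence(self, rng):
        design, y = _sim(rng, 500, [-0.5, 0.8, -0.4])
        fit = fit_logistic(design, y)
        x = design.to_numpy()
        p = 1 / (1 + np.exp(-(x @ fit.params.to_numpy())))
        score = x.T @ (y - p)
        assert np.max(np.abs(score)) < 1e-6

    def test_separation_raises(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = (x > 2.5).astype(float)
        with pytest.raises(SeparationError):
            fit_logistic(add_intercept(pd.DataFrame({"x": x})), y)

    def test_singular_design_rejected(self, rng):
        x = rng.normal(size=50)
        y = (rng.random(50) < 0.5).astype(float)
        y[:2] = [0, 1]
        design = add_intercept(pd.DataFrame({"x": x, "x2": 2 * x}))
        with pytest.raises((ValueError, SeparationError)):
            fit_logistic(design, y)

    def test_agreement_with_reference_optimizer(self, rng):
        """Coefficients match statsmodels to 1e-6 on random fixtures."""
        for _ in range(20):
            n = int(rng.integers(60, 200))
            k = int(rng.integers(1, 4))
            beta = rng.normal(scale=0.7, size=k + 1)
            design, y = _sim(rng, n, beta)
            if y.sum() in (0, n):
                continue
            try:
                fit = fit_logistic(design, y)
            except SeparationError:
                continue
            ref = sm.Logit(y, design.to_numpy()).fit(disp=0)
            assert np.allclose(fit.params.to_numpy(), ref.params, atol=1e-6)
            assert np.allclose(fit.se.to_numpy(), ref.bse, atol=1e-6)
            assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-6)


class TestFitStatistics:
    def test_intercept_only_model_is_null(self, rng):
        y = (rng.random(200) < 0.7).astype(float)
        design = pd.DataFrame({"const": np.ones(200)})
        fit = fit_logistic(design, y)
        assert nagelkerke_r2(fit) == pytest.approx(0.0, abs=1e-10)
        chi2, df, _ = model_chi2(fit)
        assert chi2 == pytest.approx(0.0, abs=1e-8)

    def test_nagelkerke_approaches_one_for_near_perfect_fit(self, rng):
        design, y = _sim(rng, 800, [0.0, 8.0])
        try:
            fit = fit_logistic(design, y)
        except SeparationError:
            pytest.skip("sampled dataset fully separated")
        assert nagelkerke_r2(fit) > 0.8

    def test_r2_and_chi2_match_hand_computed_likelihoods(self):
        """Six-row fixture checked against directly evaluated likelihoods."""
        design = add_intercept(pd.DataFrame({"x": [0.0, 1.0, 2.0, 0.5, 1.5, 2.5]}))
        y = np.array([0.0, 1.0, 0.0, 0.0, 1.0, 1.0])  # overlapping classes
        fit = fit_logistic(design, y)
        b = fit.params.to_numpy()
        eta = design.to_numpy() @ b
        p = 1 / (1 + np.exp(-eta))
        ll1 = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        pbar = y.mean()
        ll0 = len(y) * (pbar * math.log(pbar) + (1 - pbar) * math.log(1 - pbar))
        n = len(y)
        r2_cs = 1 - math.exp(2 * (ll0 - ll1) / n)
        expected = r2_cs / (1 - math.exp(2 * ll0 / n))
        assert nagelkerke_r2(fit) == pytest.approx(expected, abs=1e-10)
        assert model_chi2(fit)[0] == pytest.approx(-2 * (ll0 - ll1), abs=1e-8)

    def test_chi2_monotone_in_informative_predictors(self, rng):
        design, y = _sim(rng, 400, [0.2, 0.9, 0.6])
        small = fit_logistic(design[["const", "x0"]], y)
        full = fit_logistic(design, y)
        assert full.model_chi2 >= small.model_chi2 - 1e-8


class TestPredictionAndAccuracy:
    def test_probability_examples(self):
        assert predict_probability([0.0, 0.0], [1.0, 5.0]) == pytest.approx(0.5)
        # published coefficient set at VAS=7, activity=7.25
        p = predict_probability([-5.300, 0.886, 0.209], [1.0, 7.0, 7.25])
        assert p == pytest.approx(0.9181, abs=1e-4)

    def test_probability_monotone_in_positive_coefficient(self):
        b = [-1.0, 0.5]
        ps = [predict_probability(b, [1.0, v]) for v in (0.0, 1.0, 2.0, 5.0)]
        assert all(p2 > p1 for p1, p2 in zip(ps, ps[1:]))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            predict_probability([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_accuracy_for_majority_prediction(self, rng):
        """Intercept-only model on 61/72 positives predicts everyone positive."""
        y = np.concatenate([np.ones(61), np.zeros(11)])
        design = pd.DataFrame({"const": np.ones(72)})
        fit = fit_logistic(design, y)
        assert accuracy_at_half(fit, design, y) == 84.7  # 100 * 61/72

    def test_accuracy_matches_brute_force(self, rng):
        design, y = _sim(rng, 300, [0.3, 1.0])
        fit = fit_logistic(design, y)
        p = 1 / (1 + np.exp(-(design.to_numpy() @ fit.params.to_numpy())))
        brute = 100.0 * np.mean((p >= 0.5).astype(float) == y)
        assert accuracy_at_half(fit, design, y) == pytest.approx(brute, abs=0.051)


class TestBoxTidwell:
    def test_single_predictor_equals_direct_augmented_fit(self, rng):
        x = rng.uniform(0.5, 10.0, size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-(-1 + 0.4 * x)))).astype(float)
        design = add_intercept(pd.DataFrame({"x": x}))
        p_bt = box_tidwell(design, y, ["x"])
        aug = design.copy()
        aug["x:xlnx"] = x * np.log(x)
        direct = fit_logistic(aug, y)
        assert p_bt["x"] == pytest.approx(direct.p["x:xlnx"], abs=1e-12)

    def test_nonpositive_after_shift_rejected(self, rng):
        design = add_intercept(pd.DataFrame({"x": [-1.0, 2.0, 3.0, 4.0]}))
        with pytest.raises(ValueError):
            box_tidwell(design, np.array([0.0, 1.0, 0.0, 1.0]), ["x"])

    def test_null_linear_logit_keeps_size(self):
        """Under a truly linear logit the augmentation term is rarely significant."""
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            x = r.uniform(0.5, 10.0, size=2000)
            y = (r.random(2000) < 1 / (1 + np.exp(-(-2 + 0.35 * x)))).astype(float)
            p = box_tidwell(add_intercept(pd.DataFrame({"x": x})), y, ["x"])["x"]
            hits += p < 0.05
        # ~5% expected; 3*sqrt(0.05*0.95/60) ~ 8.4% slack
        assert hits / n_seeds < 0.15

    def test_quadratic_logit_detected(self):
        """A logit quadratic in x is flagged with high power at n=2000."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(1000 + seed)
            x = r.uniform(0.5, 10.0, size=2000)
            eta = -2 + 0.1 * x + 0.08 * x**2
            y = (r.random(2000) < 1 / (1 + np.exp(-eta))).astype(float)
            p = box_tidwell(add_intercept(pd.DataFrame({"x": x})), y, ["x"])["x"]
            hits += p < 0.05
        assert hits / n_seeds > 0.8
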