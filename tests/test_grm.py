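import numpy as np
import pytest

from catgrm.core import Item, ItemBank, ResponseMatrix
from catgrm.grm import (
    _pattern_logp,
    category_probabilities,
    eap_scores,
    estimate_theta,
    fit_grm_mml,
    information_curve,
    item_information,
    mean_theta_by_response,
)
from catgrm.grm import test_information as total_information
from catgrm.synth import CohortSpec, generate_cohort, simulate_responses


class TestCategoryProbabilities:
    def test_low_theta_floor_category_near_one(self, item7):
        p = category_probabilities(item7, -2.0)
        assert round(float(p[0]), 2) == 1.00

    def test_probabilities_sum_to_one(self, bank):
        rng = np.random.default_rng(0)
        for item in bank:
            thetas = rng.uniform(-6, 6, 50)
            p = category_probabilities(item, thetas)
            assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-15)
            assert np.all(p >= 0)

    def test_boundary_curve_half_at_beta1(self, bank):
        from scipy.special import expit

        for item in bank:
            p = category_probabilities(item, item.betas[0])
            # P*_1 = 1 - P_0 = 0.5 exactly at theta = beta_1
            assert 1.0 - p[0] == pytest.approx(0.5, abs=1e-12)
            assert expit(item.alpha * 0.0) == 0.5

    def test_item7_at_theta_1_5_matches_high_precision_oracle(self, item7):
        """Closed form evaluated with 50-digit arithmetic via sympy."""
        import sympy as sp

        theta = sp.Rational(3, 2)
        a = sp.Rational(4117, 1000)
        b1, b2 = sp.Rational(171, 1000), sp.Rational(1243, 1000)
        p1s = 1 / (1 + sp.exp(-a * (theta - b1)))
        p2s = 1 / (1 + sp.exp(-a * (theta - b2)))
        oracle = [float(sp.N(1 - p1s, 50)), float(sp.N(p1s - p2s, 50)),
                  float(sp.N(p2s, 50))]
        p = category_probabilities(item7, 1.5)
        assert np.allclose(p, oracle, atol=1e-12)

    def test_saturation_at_infinite_theta(self, item7):
        p_lo = category_probabilities(item7, -np.inf)
        p_hi = category_probabilities(item7, np.inf)
        assert p_lo[0] == pytest.approx(1.0)
        assert p_hi[2] == pytest.approx(1.0)

    def test_boundary_curves_decreasing_in_k_increasing_in_theta(self, bank):
        grid = np.linspace(-4, 4, 41)
        for item in bank:
            p = category_probabilities(item, grid)
            pstar1 = 1 - p[:, 0]
            pstar2 = p[:, 2]
            assert np.all(pstar1 > pstar2)
            assert np.all(np.diff(pstar1) > 0)
            assert np.all(np.diff(pstar2) > 0)

    def test_expected_score_strictly_increasing(self, bank):
        grid = np.linspace(-5, 5, 101)
        for item in bank:
            p = category_probabilities(item, grid)
            escore = p @ np.arange(item.n_categories)
            assert np.all(np.diff(escore) > 0)


class TestItemInformation:
    def test_argmax_at_zero_is_item4(self, bank):
        info = [item_information(it, 0.0) for it in bank]
        assert int(np.argmax(info)) + 1 == 4

    def test_nonnegative_everywhere(self, bank):
        grid = np.linspace(-8, 8, 81)
        for item in bank:
            assert np.all(item_information(item, grid) >= 0)

    def test_matches_finite_difference_curvature_oracle(self, bank):
        """I(theta) = -E[d2 log P_X / dtheta2], expectation over categories."""
        item = bank[4]
        theta, h = 0.0, 1e-4
        p0 = category_probabilities(item, theta)
        curvature = 0.0
        for k in range(item.n_categories):
            lp = [float(np.log(category_probabilities(item, theta + d)[k]))
                  for d in (-h, 0.0, h)]
            curvature += p0[k] * (lp[0] - 2 * lp[1] + lp[2]) / h**2
        assert item_information(item, theta) == pytest.approx(-curvature, abs=1e-4)

    def test_vanishes_in_the_tails(self, bank):
        for item in bank:
            assert item_information(item, -30.0) < 1e-6
            assert item_information(item, 30.0) < 1e-6

    def test_integrates_to_finite_value(self, item7):
        grid = np.linspace(-50, 50, 20001)
        total = np.trapezoid(item_information(item7, grid), grid)
        assert np.isfinite(total)
        # integral of GRM information equals alpha * (sum over boundaries of 1)
        # heuristically bounded by alpha * m
        assert total < item7.alpha * 2 + 1


class TestTestInformation:
    def test_singleton_equals_item_information(self, bank):
        assert total_information(bank, 0.3, subset=[7]) == pytest.approx(
            float(item_information(bank[7], 0.3))
        )

    def test_additivity(self, bank):
        full = total_information(bank, -0.5)
        parts = sum(float(item_information(it, -0.5)) for it in bank)
        assert full == pytest.approx(parts)

    def test_curve_peak_above_zero(self, bank):
        curve = information_curve(bank, np.linspace(-3, 3, 241))
        peak = curve.loc[curve["information"].idxmax(), "theta"]
        assert peak > 0

    def test_empty_subset_warns_and_returns_zero(self, bank):
        with pytest.warns(UserWarning, match="empty"):
            assert total_information(bank, 0.0, subset=[]) == 0.0

    def test_unknown_subset_id_raises(self, bank):
        with pytest.raises(KeyError):
            total_information(bank, 0.0, subset=[42])


class TestFitGRM:
    def test_parameter_recovery_single_cohort(self, bank, normal_cohort):
        fit = fit_grm_mml(normal_cohort.matrix)
        assert fit.converged
        assert np.abs(fit.bank.alphas - bank.alphas).mean() < 0.35
        assert np.abs(fit.bank.beta_matrix - bank.beta_matrix).mean() < 0.15

    def test_random_responses_give_near_zero_alpha(self):
        rng = np.random.default_rng(9)
        X = rng.integers(0, 3, (3000, 8))
        fit = fit_grm_mml(ResponseMatrix(np.arange(3000), X))
        # far below the weakest real discrimination in the shipped bank (1.098)
        assert np.all(fit.bank.alphas < 0.3)

    def test_self_consistency_of_loglik(self, bank):
        """Refitting data simulated from a fit's own parameters yields a
        log-likelihood within sampling noise of the generating model's."""
        rng = np.random.default_rng(14)
        thetas = rng.normal(0, 1, 1500)
        m = simulate_responses(bank, thetas, rng)
        fit = fit_grm_mml(m)
        m2 = simulate_responses(fit.bank, rng.normal(0, 1, 1500), rng)
        refit = fit_grm_mml(m2)
        # per-person average log-likelihood comparable across the two fits
        # (independent theta draws, so allow a few sd of the mean loglik)
        assert abs(fit.log_likelihood - refit.log_likelihood) / 1500 < 0.5

    def test_estimated_betas_ordered(self, normal_cohort):
        fit = fit_grm_mml(normal_cohort.matrix)
        assert np.all(np.diff(fit.bank.beta_matrix, axis=1) > 0)

    def test_standard_errors_positive_and_finite(self, normal_cohort):
        fit = fit_grm_mml(normal_cohort.matrix)
        ses = fit.standard_errors.to_numpy()
        assert np.all(np.isfinite(ses))
        assert np.all(ses > 0)

    def test_single_category_item_rejected(self):
        X = np.column_stack([np.zeros(100, dtype=int), np.resize([0, 1, 2], 100)])
        with pytest.raises(ValueError, match="single category"):
            fit_grm_mml(ResponseMatrix(np.arange(100), X))

    def test_bias_shrinks_with_n(self, bank):
        maes = []
        for n in (500, 8000):
            rng = np.random.default_rng(100 + n)
            m = simulate_responses(bank, rng.normal(0, 1, n), rng)
            fit = fit_grm_mml(m)
            maes.append(np.abs(fit.bank.alphas - bank.alphas).mean())
        assert maes[1] < maes[0]


class TestEstimateTheta:
    def test_symmetric_pattern_gives_zero_eap(self, tiny_bank):
        # bank betas mirror around 0 and the response pattern is
        # complementary, so the posterior is symmetric
        est_lo = estimate_theta(tiny_bank, {1: 0, 2: 0, 3: 0}, "EAP")
        est_hi = estimate_theta(tiny_bank, {1: 2, 2: 2, 3: 2}, "EAP")
        assert est_lo.theta_hat == pytest.approx(-est_hi.theta_hat, abs=1e-10)
        est_mid = estimate_theta(tiny_bank, {2: 1}, "EAP")
        assert est_mid.theta_hat == pytest.approx(0.0, abs=1e-10)

    def test_eap_matches_dense_grid_oracle(self, bank):
        rng = np.random.default_rng(7)
        dense = np.linspace(-4.5, 4.5, 100_001)
        for _ in range(25):
            k = rng.integers(1, 20)
            ids = rng.choice(19, size=k, replace=False) + 1
            resp = {int(i): int(rng.integers(0, 3)) for i in ids}
            est = estimate_theta(bank, resp, "EAP")
            lp = _pattern_logp(bank, resp, dense) - 0.5 * dense**2
            w = np.exp(lp - lp.max())
            w /= w.sum()
            assert abs(est.theta_hat - float(w @ dense)) < 1e-3

    def test_single_high_response_on_item4_pushes_theta_up(self, bank):
        est = estimate_theta(bank, {4: 2}, "EAP")
        assert est.theta_hat > 0

    def test_eap_se_positive(self, bank):
        est = estimate_theta(bank, {1: 1}, "EAP")
        assert est.se > 0

    def test_mle_matches_eap_for_long_informative_pattern(self, bank):
        resp = {i: (1 if i % 2 else 0) for i in range(1, 20)}
        eap = estimate_theta(bank, resp, "EAP")
        mle = estimate_theta(bank, resp, "MLE")
        assert abs(eap.theta_hat - mle.theta_hat) < 0.2
        assert mle.se > 0

    def test_mle_boundary_flag(self, bank):
        est = estimate_theta(bank, {1: 0, 2: 0}, "MLE")
        assert est.boundary
        est = estimate_theta(bank, {1: 2, 2: 2}, "MLE")
        assert est.boundary

    def test_empty_pattern_rejected(self, bank):
        with pytest.raises(ValueError, match="at least one"):
            estimate_theta(bank, {}, "EAP")

    def test_eap_se_shrinks_with_more_items(self, bank):
        se_short = estimate_theta(bank, {4: 1}, "EAP").se
        se_long = estimate_theta(bank, {4: 1, 7: 1, 2: 1, 14: 1}, "EAP").se
        assert se_long < se_short

    def test_vectorised_scores_match_scalar_path(self, bank, clinical_cohort):
        scores = eap_scores(bank, clinical_cohort.matrix)
        for i in (0, 100, 400):
            resp = {j + 1: int(clinical_cohort.matrix.responses[i, j]) for j in range(19)}
            est = estimate_theta(bank, resp, "EAP")
            assert scores.loc[i, "theta_hat"] == pytest.approx(est.theta_hat, abs=1e-12)
            assert scores.loc[i, "se"] == pytest.approx(est.se, abs=1e-12)


class TestMeanThetaByResponse:
    def test_well_separated_item_monotone_no_flag(self, bank):
        cohort = generate_cohort(
            CohortSpec(n_persons=5000, bank=bank, seed=15, theta_mixture=((1.0, 0, 1),))
        )
        table = mean_theta_by_response(cohort.matrix, bank)
        item7 = table[table["item"] == 7].sort_values("category")
        means = item7["mean_theta"].to_numpy()
        assert np.all(np.diff(means) > 0)
        assert not item7["overlap_flag"].any()

    def test_overlapping_categories_flagged(self, bank):
        """An item whose top categories carry no trait separation gets
        flagged via overlapping CIs, the printed diagnostic logic."""
        rng = np.random.default_rng(16)
        cohort = generate_cohort(
            CohortSpec(n_persons=3000, bank=bank, seed=16, theta_mixture=((1.0, 0, 1),))
        )
        responses = cohort.matrix.responses.copy()
        col = responses[:, 12]
        swap = col > 0
        responses[swap, 12] = rng.integers(1, 3, int(swap.sum()))
        m = ResponseMatrix(cohort.matrix.person_ids, responses)
        table = mean_theta_by_response(m, bank)
        assert table[table["item"] == 13]["overlap_flag"].all()

    def test_empty_category_reported_missing(self, bank):
        rng = np.random.default_rng(18)
        cohort = generate_cohort(
            CohortSpec(n_persons=500, bank=bank, seed=18, theta_mixture=((1.0, 0, 1),))
        )
        responses = cohort.matrix.responses.copy()
        responses[:, 0] = 0
        m = ResponseMatrix(cohort.matrix.person_ids, responses)
        table = mean_theta_by_response(m, bank)
        rows = table[(table["item"] == 1) & (table["category"] > 0)]
        assert (rows["n"] == 0).all()
        assert rows["mean_theta"].isna().all()
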