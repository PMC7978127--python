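import numpy as np
import pandas as pd
import pytest

from maintainage.lcga import (
    GrowthSpec,
    LCGA,
    blrt,
    enumerate_classes,
    fit_indices,
    fit_lcga,
    select_model,
    transform_time,
)


def _simulate(coefs, weights, n, sd, seed, missing_rate=0.0, time=None):
    """Draw subjects x phases data from the growth-mixture generative model."""
    tm = time or transform_time([53, 56, 64, 68, 70])
    X = np.vander(tm.scores, coefs.shape[1], increasing=True)
    rng = np.random.default_rng(seed)
    cls = rng.choice(len(weights), size=n, p=weights)
    Y = (X @ coefs[cls].T).T + rng.normal(0, sd, (n, len(tm.scores)))
    if missing_rate > 0:
        miss = rng.random(n) < missing_rate
        drop = rng.integers(0, len(tm.scores) - 1, size=n)
        Y[np.arange(n)[miss], drop[miss]] = np.nan
    return Y, cls, tm


class TestTimeMetric:
    @pytest.mark.parametrize("age,score", [(53.0, 0.0), (63.0, 1.0)])
    def test_single_ages(self, age, score):
        assert transform_time([age]).scores[0] == pytest.approx(score)

    def test_printed_score_vector(self):
        tm = transform_time([53, 56, 64, 68, 70])
        np.testing.assert_allclose(tm.scores, [0, 0.3, 1.1, 1.5, 1.7], atol=1e-12)

    def test_non_increasing_ages_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            transform_time([53, 52, 64])


class TestFit:
    def test_single_class_noiseless_recovers_coefficients(self):
        coefs = np.array([[0.4, -0.9, 0.3]])
        Y, _, tm = _simulate(coefs, [1.0], 50, sd=0.0, seed=0)
        res = fit_lcga(Y, tm, GrowthSpec(n_classes=1, order=2), seed=0)
        np.testing.assert_allclose(res.coefficients[0], coefs[0], atol=1e-8)

    def test_single_class_equals_polynomial_least_squares(self):
        Y, _, tm = _simulate(np.array([[0.2, 0.5, -0.3]]), [1.0], 80, sd=0.4, seed=2,
                             missing_rate=0.3)
        res = fit_lcga(Y, tm, GrowthSpec(n_classes=1, order=2), seed=0)
        # closed-form OLS over the stacked observed rows
        X = np.vander(tm.scores, 3, increasing=True)
        rows, cols = np.where(~np.isnan(Y))
        A, y = X[cols], Y[rows, cols]
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(res.coefficients[0], beta, atol=1e-8)
        resid = y - A @ beta
        np.testing.assert_allclose(res.sigma2, np.mean(resid**2), atol=1e-8)

    def test_em_loglik_monotone(self):
        Y, _, tm = _simulate(
            np.array([[1.0, 0.2, -0.1], [-1.0, 0.0, 0.2]]), [0.5, 0.5], 150, 0.5, 3
        )
        res = fit_lcga(Y, tm, GrowthSpec(n_classes=2, order=2, n_starts=10, n_final=2),
                       seed=4)
        assert np.all(np.diff(res.ll_path) >= -1e-8)

    def test_planted_three_classes_recovered(self):
        coefs = np.array([[1.5, 0.1, -0.2], [0.0, 0.0, 0.0], [-1.5, 0.6, -0.1]])
        w = np.array([0.3, 0.35, 0.35])
        Y, cls, tm = _simulate(coefs, w, 500, sd=0.5, seed=5, missing_rate=0.3)
        res = fit_lcga(Y, tm, GrowthSpec(n_classes=3, order=2, n_starts=15, n_final=3),
                       seed=6)
        # classes are ordered by descending baseline, truth class 0 is highest
        modal = res.modal_assignment.to_numpy()
        acc = np.mean(modal == cls)
        assert acc >= 0.9
        np.testing.assert_allclose(np.sort(res.weights), np.sort(w), atol=0.05)
        assert np.all(res.posterior.sum(axis=1) - 1 < 1e-9)
        assert res.weights.sum() == pytest.approx(1.0)

    def test_fiml_robust_to_missing_phases(self):
        coefs = np.array([[1.5, 0.1, -0.2], [0.0, 0.0, 0.0], [-1.5, 0.6, -0.1]])
        w = np.array([0.3, 0.35, 0.35])
        Y_full, _, tm = _simulate(coefs, w, 500, sd=0.5, seed=7)
        res_full = fit_lcga(Y_full, tm,
                            GrowthSpec(n_classes=3, order=2, n_starts=15, n_final=3),
                            seed=8)
        Y_miss = Y_full.copy()
        rng = np.random.default_rng(9)
        miss = rng.random(500) < 0.2
        Y_miss[np.arange(500)[miss], rng.integers(0, 4, 500)[miss]] = np.nan
        res_miss = fit_lcga(Y_miss, tm,
                            GrowthSpec(n_classes=3, order=2, n_starts=15, n_final=3),
                            seed=8)
        assert np.max(np.abs(res_full.coefficients - res_miss.coefficients)) < 0.05

    def test_label_switching_invariance(self):
        Y, _, tm = _simulate(
            np.array([[1.2, 0.0, 0.0], [-1.2, 0.0, 0.0]]), [0.5, 0.5], 200, 0.4, 10
        )
        a = fit_lcga(Y, tm, GrowthSpec(n_classes=2, order=2, n_starts=10, n_final=2),
                     seed=11)
        b = fit_lcga(Y, tm, GrowthSpec(n_classes=2, order=2, n_starts=10, n_final=2),
                     seed=99)
        # different seeds, same canonical labelling and likelihood
        assert a.loglike == pytest.approx(b.loglike, abs=1e-4)
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-3)
        fa, fb = fit_indices(a), fit_indices(b)
        assert fa.bic == pytest.approx(fb.bic, abs=1e-3)
        assert fa.entropy == pytest.approx(fb.entropy, abs=1e-3)

    def test_too_many_parameters_rejected(self):
        with pytest.raises(ValueError, match="parameters"):
            LCGA(np.zeros((5, 5)), transform_time([53, 56, 64, 68, 70]), n_classes=3)


class TestFitIndices:
    def _results_stub(self, ll, K, order, posterior):
        model = LCGA(np.zeros((len(posterior), 5)),
                     transform_time([53, 56, 64, 68, 70]), n_classes=K, order=order)
        from maintainage.lcga import LCGAResults

        return LCGAResults(model, np.full(K, 1 / K), np.zeros((K, order + 1)), 1.0,
                           posterior, ll, [ll], GrowthSpec(n_classes=K, order=order),
                           True)

    def test_plugin_formulas(self):
        # LL=-100, K=1 quadratic: p = 3 coefs + 1 sigma = 4, n=100
        post = np.ones((100, 1))
        res = self._results_stub(-100.0, 1, 2, post)
        assert res.n_params == 4
        fi = fit_indices(res)
        assert fi.aic == pytest.approx(208.0)
        assert fi.bic == pytest.approx(200 + 4 * np.log(100), abs=1e-9)
        assert fi.abic == pytest.approx(200 + 4 * np.log(102 / 24), abs=1e-9)
        assert fi.entropy == 1.0  # K=1 special case

    def test_entropy_bounds(self):
        sharp = np.zeros((50, 2))
        sharp[:25, 0] = 1.0
        sharp[25:, 1] = 1.0
        assert fit_indices(self._results_stub(-10, 2, 2, sharp)).entropy == pytest.approx(1.0)
        uniform = np.full((50, 2), 0.5)
        assert fit_indices(self._results_stub(-10, 2, 2, uniform)).entropy == pytest.approx(0.0)


class TestBLRT:
    def test_strong_separation_minimal_p(self):
        coefs = np.array([[1.5, 0.0, 0.0], [-1.5, 0.0, 0.0]])
        Y, _, tm = _simulate(coefs, [0.5, 0.5], 200, sd=0.4, seed=12)
        out = blrt(
            Y, tm,
            GrowthSpec(n_classes=2, order=2, n_starts=5, n_final=1),
            GrowthSpec(n_classes=1, order=2),
            n_bootstrap=9, seed=13,
        )
        assert out.p == pytest.approx(1 / 10)  # zero exceedances of 9 bootstraps
        assert out.observed_stat > max(out.bootstrap_stats)

    def test_null_data_rarely_significant(self):
        # data truly one class: p should usually be large
        small = 0
        for seed in range(8):
            Y, _, tm = _simulate(np.array([[0.0, 0.3, 0.0]]), [1.0], 120, 0.5,
                                 seed=20 + seed)
            out = blrt(
                Y, tm,
                GrowthSpec(n_classes=2, order=2, n_starts=4, n_final=1,
                           max_iter_final=100),
                GrowthSpec(n_classes=1, order=2),
                n_bootstrap=19, seed=seed,
            )
            small += out.p <= 0.1
        assert small <= 2

    def test_class_count_contract(self):
        Y, _, tm = _simulate(np.array([[0.0, 0.0, 0.0]]), [1.0], 60, 0.5, 30)
        with pytest.raises(ValueError, match="K-1"):
            blrt(Y, tm, GrowthSpec(n_classes=3), GrowthSpec(n_classes=1))


class TestSelection:
    def _candidate(self, k, bic, entropy, share, p, ll=-100.0):
        from maintainage.lcga import FitIndices, LCGAResults

        model = LCGA(np.zeros((100, 5)), transform_time([53, 56, 64, 68, 70]),
                     n_classes=k, order=1)
        post = np.zeros((100, k))
        counts = np.round(np.r_[np.full(k - 1, share), 1 - share * (k - 1)] * 100
                          ).astype(int) if k > 1 else np.array([100])
        i = 0
        for kk, c in enumerate(counts):
            post[i:i + c, kk] = 1.0
            i += c
        res = LCGAResults(model, counts / 100, np.zeros((k, 2)), 1.0, post, ll, [ll],
                          GrowthSpec(n_classes=k, order=1), True)
        return (res, FitIndices(bic - 1, bic, bic - 2, entropy, counts.min() / 100), p)

    def test_single_valid_candidate_selected(self):
        report = select_model([self._candidate(2, 500.0, 0.9, 0.4, 0.001)])
        assert report.selected_k == 2 and report.met_criteria

    def test_small_class_excluded_with_reason(self):
        report = select_model(
            [self._candidate(2, 400.0, 0.9, 0.04, 0.001),
             self._candidate(3, 500.0, 0.9, 0.2, 0.001)]
        )
        assert report.selected_k == 3
        reasons = [a["reasons"] for a in report.audit if a["k"] == 2][0]
        assert any("share" in r for r in reasons)

    def test_no_survivor_falls_back_to_best_bic(self):
        report = select_model(
            [self._candidate(2, 400.0, 0.5, 0.4, 0.9),
             self._candidate(3, 500.0, 0.5, 0.2, 0.9)]
        )
        assert report.selected_k == 2 and not report.met_criteria

    def test_enumeration_recovers_planted_k(self):
        coefs = np.array([[1.5, 0.1, -0.2], [0.0, 0.0, 0.0], [-1.5, 0.6, -0.1]])
        Y, _, tm = _simulate(coefs, [0.3, 0.35, 0.35], 400, sd=0.5, seed=31,
                             missing_rate=0.3)
        report, candidates = enumerate_classes(
            Y, tm, k_max=3, order=2, n_starts=8, n_final=2, n_bootstrap=24, seed=31,
            blrt_spec_overrides={"n_starts": 3, "n_final": 1, "max_iter_final": 120,
                                 "tol": 1e-4},
        )
        assert report.selected_k == 3 and report.met_criteria
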