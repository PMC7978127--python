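import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from maintainage.gaps import (
    associate,
    bias_correct_gap,
    compute_gap,
    correlate_gaps,
    exclude_outliers,
    fdr_correct,
    se_from_ci,
    z_correlated,
)


class TestComputeGap:
    def test_zero_when_prediction_exact(self):
        g = compute_gap([70.0, 65.0], [70.0, 65.0])
        np.testing.assert_allclose(g.raw, 0.0)

    def test_sign_convention_older_positive(self):
        g = compute_gap([72.0], [70.0])
        assert g.raw[0] == pytest.approx(2.0)

    def test_mean_linearity(self):
        rng = np.random.default_rng(0)
        pred, chron = rng.normal(70, 5, 50), rng.normal(70, 5, 50)
        g = compute_gap(pred, chron)
        assert g.raw.mean() == pytest.approx(pred.mean() - chron.mean())
        np.testing.assert_allclose(g.raw + g.chronological, g.predicted)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            compute_gap([70.0], [70.0, 71.0])


class TestBiasCorrection:
    def test_hand_computed_residuals(self):
        # gaps [1,3,2] on ages [60,70,80]: slope .05 -> residuals [-0.5, 1, -0.5]
        g = compute_gap(np.array([61.0, 73.0, 82.0]), np.array([60.0, 70.0, 80.0]))
        out = bias_correct_gap(g)
        np.testing.assert_allclose(out.corrected, [-0.5, 1.0, -0.5], atol=1e-12)

    def test_linear_gap_fully_removed(self):
        age = np.linspace(60, 80, 30)
        g = compute_gap(age + 0.2 * age - 10, age)
        out = bias_correct_gap(g)
        np.testing.assert_allclose(out.corrected, 0.0, atol=1e-10)

    def test_uncorrelated_gap_only_centered(self):
        rng = np.random.default_rng(1)
        age = rng.uniform(60, 80, 200)
        raw = rng.normal(2.0, 1.0, 200)
        raw = raw - np.polyval(np.polyfit(age, raw, 1), age) + 2.0  # de-correlate
        out = bias_correct_gap(compute_gap(age + raw, age))
        np.testing.assert_allclose(out.corrected, raw - raw.mean(), atol=1e-8)

    def test_corrected_orthogonal_to_age(self):
        rng = np.random.default_rng(2)
        age = rng.uniform(60, 80, 300)
        g = bias_correct_gap(compute_gap(age + rng.normal(0, 4, 300), age))
        assert abs(np.corrcoef(g.corrected, age)[0, 1]) < 1e-10

    def test_linear_age_terms_do_not_move_corrected_gap(self):
        # adding any linear-in-age term to predictions leaves corrected gaps unchanged
        rng = np.random.default_rng(3)
        age = rng.uniform(60, 80, 100)
        pred = age + rng.normal(0, 3, 100)
        base = bias_correct_gap(compute_gap(pred, age))
        shifted = bias_correct_gap(compute_gap(pred + 0.7 * age - 12.0, age))
        np.testing.assert_allclose(shifted.corrected, base.corrected, atol=1e-9)

    def test_zero_age_variance_rejected(self):
        g = compute_gap([70.0, 71.0, 69.0], [70.0, 70.0, 70.0])
        with pytest.raises(ValueError, match="variance"):
            bias_correct_gap(g)


class TestGapCorrelation:
    def _gap(self, corrected, ids):
        age = np.linspace(60, 80, len(corrected))
        g = bias_correct_gap(compute_gap(age + corrected, age, ids))
        return g

    def test_identical_gaps_r_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        ids = pd.Index(range(50))
        a, b = self._gap(x, ids), self._gap(x, ids)
        assert correlate_gaps(a, b).r == pytest.approx(1.0)
        assert correlate_gaps(a, self._gap(-x, ids)).r == pytest.approx(-1.0)

    def test_independent_gaps_null_distribution(self):
        # n=537 independent gaps: |r| < 0.12 in >= 95% of simulations
        rng = np.random.default_rng(5)
        n, hits, sims = 537, 0, 1000
        for _ in range(sims):
            x, y = rng.normal(size=n), rng.normal(size=n)
            xc, yc = x - x.mean(), y - y.mean()
            r = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            hits += abs(r) < 0.12
        assert hits / sims >= 0.95

    def test_small_sample_rejected(self):
        ids = pd.Index(range(3))
        a = self._gap(np.array([1.0, -1.0, 0.5]), ids)
        with pytest.raises(ValueError, match="n >= 4"):
            correlate_gaps(a, a)


class TestAssociate:
    def _data(self, n, rng):
        return pd.DataFrame(
            {
                "age": rng.uniform(60, 80, n),
                "sex": rng.binomial(1, 0.2, n),
                "education": rng.normal(16, 4, n),
                "ethnicity": rng.binomial(1, 0.1, n),
                "bmi": rng.normal(26, 4, n),
                "premorbid_iq": rng.normal(100, 15, n),
            },
            index=pd.RangeIndex(n),
        )

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(6)
        n = 10
        data = self._data(n, rng)
        gap_raw = rng.normal(0, 3, n)
        gap = compute_gap(data["age"].to_numpy() + gap_raw, data["age"].to_numpy(),
                          data.index)
        res = associate(gap, "premorbid_iq", data, tier=1)
        # brute-force normal equations on the standardized design
        z = lambda v: (v - v.mean()) / v.std(ddof=1)
        y = z(gap_raw)
        X = np.column_stack([np.ones(n), z(data["premorbid_iq"]), z(data["age"])])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.beta == pytest.approx(beta[1], abs=1e-10)

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(7)
        betas = []
        for _ in range(200):
            n = 537
            iq = rng.normal(size=n)
            age = rng.uniform(60, 80, n)
            gap_raw = -0.3 * iq + np.sqrt(1 - 0.09) * rng.normal(size=n)
            data = self._data(n, rng)
            data["premorbid_iq"] = iq
            g = compute_gap(age + gap_raw, age, data.index)
            betas.append(associate(g, "premorbid_iq", data, tier=1).beta)
        assert abs(np.mean(betas) - (-0.3)) < 0.05

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(8)
        rejections = 0
        sims = 1000
        for _ in range(sims):
            n = 200
            age = rng.uniform(60, 80, n)
            gap_raw = rng.normal(size=n)
            data = self._data(n, rng)
            g = compute_gap(age + gap_raw, age, data.index)
            rejections += associate(g, "premorbid_iq", data, tier=1).p < 0.05
        assert abs(rejections / sims - 0.05) <= 0.02

    def test_tier2_reserve_proxy_rule(self):
        rng = np.random.default_rng(9)
        n = 60
        data = self._data(n, rng)
        data["other_gap"] = rng.normal(size=n)
        g = compute_gap(data["age"].to_numpy() + rng.normal(size=n),
                        data["age"].to_numpy(), data.index)
        from maintainage.gaps import GapAssociation

        m_iq = GapAssociation(g, data, "premorbid_iq", tier=2)
        cols = m_iq.covariate_columns()
        assert "bmi" not in cols and "education" in cols and "other_gap" in cols
        m_cum = GapAssociation(g, pd.concat([data], axis=1).assign(cum=rng.normal(size=n)),
                               "cum", tier=2)
        cols = m_cum.covariate_columns()
        assert "bmi" in cols and "education" in cols

    def test_unknown_tier_rejected(self):
        rng = np.random.default_rng(10)
        data = self._data(10, rng)
        g = compute_gap(data["age"].to_numpy(), data["age"].to_numpy(), data.index)
        with pytest.raises(ValueError, match="tier"):
            associate(g, "premorbid_iq", data, tier=3)


class TestZCorrelated:
    def test_equal_betas_z_zero(self):
        out = z_correlated(0.5, 0.1, 0.5, 0.2, 0.3)
        assert out.z == 0.0 and out.p == pytest.approx(1.0)

    def test_analytic_value(self):
        out = z_correlated(1.0, 1.0, 0.0, 1.0, 0.0)
        assert out.z == pytest.approx(1 / np.sqrt(2))

    def test_reduces_to_independent_samples_when_uncorrelated(self):
        b1, s1, b2, s2 = 0.4, 0.12, 0.1, 0.2
        out = z_correlated(b1, s1, b2, s2, 0.0)
        assert out.z == pytest.approx((b1 - b2) / np.hypot(s1, s2))

    def test_printed_comparison_reproduced(self):
        # beta_CAG=-.07 CI [-.12,-.02]; beta_BAG=.08 CI [.00,.16]; rho=.06
        se_c = se_from_ci(-0.12, -0.02)
        se_b = se_from_ci(0.00, 0.16)
        out = z_correlated(-0.07, se_c, 0.08, se_b, 0.06)
        assert out.z == pytest.approx(-3.24, abs=0.15)
        assert out.p < 0.005

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            z_correlated(0.1, 0.1, 0.2, 0.1, 1.0)
        with pytest.raises(ValueError, match="positive"):
            z_correlated(0.1, 0.0, 0.2, 0.1, 0.0)


def bh_stepup_decision_oracle(p):
    """Adjusted p via the step-up *decision rule* searched over candidate levels."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    candidates = sorted(set(np.minimum(p[order] * n / (np.arange(n) + 1), 1.0)))

    def rejected_at(alpha):
        sorted_p = p[order]
        # 1e-12 absorbs round-trip error of alpha = p*n/j followed by j*alpha/n
        ks = np.where(sorted_p <= (np.arange(1, n + 1) / n) * alpha + 1e-12)[0]
        if len(ks) == 0:
            return np.zeros(n, dtype=bool)
        cut = sorted_p[ks.max()]
        return p <= cut

    adj = np.ones(n)
    for alpha in candidates:
        rej = rejected_at(alpha)
        adj = np.where(rej & (alpha < adj), alpha, adj)
    return adj


class TestFDR:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_correct([0.07]), [0.07])

    def test_hand_worked_examples(self):
        np.testing.assert_allclose(fdr_correct([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)
        np.testing.assert_allclose(fdr_correct([0.005, 0.5]), [0.01, 0.5], atol=1e-12)

    def test_matches_stepup_decision_oracle_random_lists(self):
        rng = np.random.default_rng(11)
        for length in range(1, 7):
            for _ in range(200):
                p = np.round(rng.uniform(0, 1, length), 3)
                np.testing.assert_allclose(
                    fdr_correct(p), bh_stepup_decision_oracle(p), atol=1e-12
                )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.2])


class TestOutlierExclusion:
    def test_benign_values_all_kept(self):
        assert exclude_outliers([1, 2, 3, 4, 5]).all()

    def test_extreme_value_excluded(self):
        mask = exclude_outliers([1, 2, 3, 4, 100])
        assert list(mask) == [True, True, True, True, False]

    def test_constant_vector_all_kept(self):
        assert exclude_outliers([5.0] * 6).all()

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="4"):
            exclude_outliers([1.0, 2.0, 3.0])
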