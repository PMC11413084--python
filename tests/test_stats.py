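"""Statistical layer: correlations, cutpoints, exact CIs, model comparison,
gamma GLM, PART rule, and subgroup queries — each against an independent
oracle or a worked hand example."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from tauconcord.stats import (
    EmptySubsetError,
    assign_sextiles,
    classify_part,
    clopper_pearson,
    concordance_accuracy,
    fit_gamma_glm,
    linear_vs_polynomial,
    spearman_corr,
    subgroup_spearman,
    youden_detection_threshold,
)


class TestSpearman:
    def test_perfect_monotone_agreement(self):
        r = spearman_corr([1, 2, 3, 5, 8, 13, 21, 30, 44, 60, 81, 100],
                          [2, 4, 9, 11, 20, 40, 41, 60, 61, 80, 90, 95])
        assert r.rho == pytest.approx(1.0)
        assert r.p_value < 1e-6

    def test_perfect_reversal(self):
        x = np.arange(12.0)
        assert spearman_corr(x, -x).rho == pytest.approx(-1.0)

    def test_tied_data_matches_hand_midrank_computation(self):
        # x = [1, 2, 2, 3] -> ranks [1, 2.5, 2.5, 4]
        # y = [10, 10, 20, 30] -> ranks [1.5, 1.5, 3, 4]
        x = [1.0, 2.0, 2.0, 3.0]
        y = [10.0, 10.0, 20.0, 30.0]
        rx = np.array([1.0, 2.5, 2.5, 4.0])
        ry = np.array([1.5, 1.5, 3.0, 4.0])
        hand_rho = np.corrcoef(rx, ry)[0, 1]
        assert spearman_corr(x, y).rho == pytest.approx(hand_rho)

    def test_matches_scipy_rho_with_ties(self, rng):
        x = rng.integers(0, 6, 50).astype(float)
        y = x + rng.normal(0, 1.5, 50)
        ours = spearman_corr(x, y)
        ref = sps.spearmanr(x, y)
        assert ours.rho == pytest.approx(ref.statistic, abs=1e-12)

    def test_exact_permutation_p_matches_direct_enumeration(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 0.5])
        ours = spearman_corr(x, y)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            rho = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
            count += rho >= obs - 1e-9
            total += 1
        assert ours.p_value == pytest.approx(count / total)

    @given(
        seed=st.integers(0, 2**16),
        a=st.floats(0.1, 5.0),
        b=st.floats(-10.0, 10.0),
    )
    def test_invariance_under_strictly_increasing_transforms(self, seed, a, b):
        r = np.random.default_rng(seed)
        x = r.normal(size=20)
        y = r.normal(size=20)
        base = spearman_corr(x, y)
        transformed = spearman_corr(a * x + b, np.exp(y))
        assert transformed.rho == pytest.approx(base.rho, abs=1e-12)
        assert transformed.p_value == pytest.approx(base.p_value, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestYoudenThreshold:
    def test_perfectly_separated_example(self):
        # pathology 0.1..0.5 PET-negative, 0.7..1.1 PET-positive
        path = [0.1, 0.2, 0.3, 0.4, 0.5, 0.7, 0.8, 0.9, 1.0, 1.1]
        pos = [False] * 5 + [True] * 5
        res = youden_detection_threshold(path, pos)
        assert res.youden_j == pytest.approx(1.0)
        assert res.pathology_threshold_pct == pytest.approx(0.6)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_tie_broken_toward_smallest_threshold(self):
        # two cutpoints achieve the same J; the smaller one must be returned
        path = [1.0, 2.0, 3.0, 4.0]
        pos = [False, False, True, True]
        res = youden_detection_threshold(path, pos)
        assert res.pathology_threshold_pct == pytest.approx(2.5)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle_on_small_samples(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(6, 13))
        path = np.round(r.uniform(0, 3, n), 2)
        pos = r.random(n) < 0.5
        if pos.all() or not pos.any() or np.unique(path).size < 2:
            pos[0] = ~pos[0]
        res = youden_detection_threshold(path, pos)
        # oracle: evaluate J at every midpoint directly
        u = np.unique(path)
        best_j, best_t = -np.inf, None
        for t in (u[:-1] + u[1:]) / 2:
            pred = path >= t
            sens = (pred & pos).sum() / pos.sum()
            spec = (~pred & ~pos).sum() / (~pos).sum()
            j = sens + spec - 1
            if j > best_j + 1e-12:
                best_j, best_t = j, t
        assert res.youden_j == pytest.approx(best_j)
        assert res.pathology_threshold_pct == pytest.approx(best_t)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_detection_threshold([1.0, 2.0, 3.0], [True, True, True])


class TestClopperPearson:
    def test_boundary_counts(self):
        low, high = clopper_pearson(0, 20)
        assert low == 0.0 and 0 < high < 1
        low, high = clopper_pearson(20, 20)
        assert 0 < low < 1 and high == 1.0

    def test_matches_tail_probability_inversion(self):
        # the exact interval satisfies P(X >= k | p = low) = alpha/2 and
        # P(X <= k | p = high) = alpha/2; invert both tails by bisection
        k, n, alpha = 53, 63, 0.05

        def upper_tail(p):
            return sps.binom.sf(k - 1, n, p)

        def lower_tail(p):
            return sps.binom.cdf(k, n, p)

        from scipy.optimize import brentq

        low = brentq(lambda p: upper_tail(p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-12)
        high = brentq(lambda p: lower_tail(p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-12)
        ours = clopper_pearson(k, n)
        assert ours[0] == pytest.approx(low, abs=1e-6)
        assert ours[1] == pytest.approx(high, abs=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 0)
        with pytest.raises(ValueError):
            clopper_pearson(7, 5)
        with pytest.raises(ValueError):
            clopper_pearson(3, 10, level=1.0)

    @given(k=st.integers(0, 40), seed=st.integers(0, 1000))
    def test_interval_contains_point_estimate(self, k, seed):
        n = 40
        low, high = clopper_pearson(k, n)
        assert low <= k / n <= high


class TestConcordance:
    def test_counts_and_accuracy(self):
        path = [True, True, False, False, True]
        pet = [True, False, False, True, True]
        res = concordance_accuracy(path, pet)
        assert (res.tp, res.tn, res.fp, res.fn) == (2, 1, 1, 1)
        assert res.accuracy == pytest.approx(3 / 5)
        assert res.n == 5

    def test_ci_matches_clopper_pearson_of_agreements(self):
        rng = np.random.default_rng(7)
        path = rng.random(63) < 0.8
        pet = rng.random(63) < 0.8
        res = concordance_accuracy(path, pet)
        agree = int((np.asarray(path) == np.asarray(pet)).sum())
        assert (res.ci_low, res.ci_high) == clopper_pearson(agree, 63)


class TestLinearVsPolynomial:
    # 8-point worked example (also reproduced in docs/methods.md):
    # x = 1..8, y = x + 0.5 x^2 with small fixed perturbations
    X8 = np.arange(1.0, 9.0)
    Y8 = np.array([1.61, 4.12, 7.42, 11.87, 17.55, 24.10, 31.45, 40.02])

    @staticmethod
    def normal_equations_rss(x, y, degree):
        X = np.vander(x, degree + 1, increasing=True)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    def test_worked_example_matches_normal_equations_oracle(self):
        res = linear_vs_polynomial(self.X8, self.Y8, degree=2)
        rss1 = self.normal_equations_rss(self.X8, self.Y8, 1)
        rss2 = self.normal_equations_rss(self.X8, self.Y8, 2)
        assert res.rss_linear == pytest.approx(rss1, abs=1e-6)
        assert res.rss_poly == pytest.approx(rss2, abs=1e-6)
        f = ((rss1 - rss2) / 1) / (rss2 / (8 - 2 - 1))
        assert res.f_stat == pytest.approx(f, abs=1e-6)
        assert res.p_value == pytest.approx(float(sps.f.sf(f, 1, 5)), abs=1e-9)
        n = 8
        aic1 = n * np.log(2 * np.pi) + n * np.log(rss1 / n) + n + 2 * 3
        aic2 = n * np.log(2 * np.pi) + n * np.log(rss2 / n) + n + 2 * 4
        assert res.delta_aic == pytest.approx(aic2 - aic1, abs=1e-9)

    def test_strong_curvature_detected(self, rng):
        x = np.repeat(np.arange(1.0, 7.0), 20)
        y = 0.3 * x**2 + rng.normal(0, 0.3, x.size)
        res = linear_vs_polynomial(x, y)
        assert res.p_value < 1e-6
        # delta_aic = AIC(poly) - AIC(linear): negative favors the polynomial
        assert res.delta_aic < 0

    def test_linear_truth_usually_not_rejected(self):
        rejections = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            x = np.repeat(np.arange(1.0, 7.0), 10)
            y = 1.0 + 0.5 * x + r.normal(0, 0.5, x.size)
            if linear_vs_polynomial(x, y).p_value < 0.05:
                rejections += 1
        assert rejections <= 8  # ~5% nominal rate, generous margin

    def test_statsmodels_agreement(self, rng):
        import statsmodels.api as sm

        x = np.repeat(np.arange(1.0, 7.0), 8)
        y = 0.2 * x**2 + rng.normal(0, 1.0, x.size)
        res = linear_vs_polynomial(x, y, degree=2)
        m1 = sm.OLS(y, sm.add_constant(x)).fit()
        m2 = sm.OLS(y, sm.add_constant(np.column_stack([x, x**2]))).fit()
        cmp = m2.compare_f_test(m1)
        assert res.f_stat == pytest.approx(cmp[0], rel=1e-9)
        assert res.p_value == pytest.approx(cmp[1], rel=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            linear_vs_polynomial([1, 2, 3], [1, 2, 3], degree=1)
        with pytest.raises(ValueError):
            linear_vs_polynomial([1, 2, 3], [1, 2, 3], degree=2)  # n too small
        with pytest.raises(ValueError):
            linear_vs_polynomial(self.X8, self.X8**2)  # zero residuals


class TestAssignSextiles:
    def test_balanced_sizes_when_divisible(self):
        labels = assign_sextiles(np.arange(60.0))
        counts = np.bincount(labels)[1:]
        assert (counts == 10).all()

    def test_remainder_goes_to_lowest_groups(self):
        labels = assign_sextiles(np.arange(63.0))
        counts = np.bincount(labels)[1:]
        assert list(counts) == [11, 11, 11, 10, 10, 10]

    def test_order_respects_values(self):
        v = np.array([5.0, 1.0, 9.0, 3.0, 7.0, 2.0, 8.0, 0.0, 6.0, 4.0, 10.0, 11.0])
        labels = assign_sextiles(v)
        # group means must be increasing in the group label
        means = [v[labels == g].mean() for g in range(1, 7)]
        assert (np.diff(means) > 0).all()

    def test_ties_keep_stable_input_order(self):
        v = np.zeros(12)
        labels = assign_sextiles(v)
        assert list(labels) == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6]

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            assign_sextiles([1.0, 2.0, 3.0])


def irls_gamma_log(y, X, tol=1e-12, max_iter=200):
    """Hand-rolled IRLS for a log-link gamma GLM (unit working weights)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(y.mean())
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        new, *_ = np.linalg.lstsq(X, z, rcond=None)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    mu = np.exp(X @ beta)
    n, k = X.shape
    pearson = ((y - mu) / mu) ** 2
    dispersion = pearson.sum() / (n - k)
    cov = dispersion * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return beta, se, dispersion


class TestGammaGlm:
    def _toy(self):
        x = np.array([0.1, 0.4, 0.8, 1.1, 1.6, 2.0, 2.5, 3.1])
        y = np.array([1.05, 1.12, 1.30, 1.38, 1.62, 1.80, 2.05, 2.45])
        return pd.DataFrame({"pathology": x}), y

    def test_matches_hand_irls_oracle(self):
        preds, y = self._toy()
        res = fit_gamma_glm(y, preds, link="log")
        X = np.column_stack([np.ones(len(y)), preds["pathology"].to_numpy()])
        beta, se, dispersion = irls_gamma_log(y, X)
        assert res.table["estimate"].to_numpy() == pytest.approx(beta, abs=1e-6)
        assert res.table["t_value"].to_numpy() == pytest.approx(beta / se, abs=1e-4)
        assert res.dispersion == pytest.approx(dispersion, rel=1e-4)

    def test_recovers_planted_coefficients(self, rng):
        n = 400
        path = rng.uniform(0, 3, n)
        age = rng.uniform(60, 95, n)
        eta = 0.05 + 0.30 * path - 0.002 * age
        shape = 100.0
        y = rng.gamma(shape, np.exp(eta) / shape)
        preds = pd.DataFrame({"pathology": path, "age": age})
        res = fit_gamma_glm(y, preds)
        assert res.table.loc["pathology", "estimate"] == pytest.approx(0.30, abs=0.03)
        assert res.table.loc["age", "estimate"] == pytest.approx(-0.002, abs=0.002)
        assert res.table.loc["pathology", "p_value"] < 1e-10

    def test_pure_noise_covariate_not_significant(self):
        r = np.random.default_rng(21)
        n = 300
        path = r.uniform(0, 3, n)
        noise = r.normal(size=n)
        y = r.gamma(50.0, np.exp(0.3 * path) / 50.0)
        res = fit_gamma_glm(y, pd.DataFrame({"pathology": path, "noise": noise}))
        assert res.table.loc["noise", "p_value"] > 0.05

    def test_identity_link_supported(self):
        preds, y = self._toy()
        res = fit_gamma_glm(y, preds, link="identity")
        assert res.link == "identity"
        assert res.table.loc["pathology", "estimate"] > 0

    def test_invalid_inputs(self):
        preds, y = self._toy()
        with pytest.raises(ValueError):
            fit_gamma_glm(np.append(y[:-1], 0.0), preds)
        dup = preds.copy()
        dup["copy"] = dup["pathology"]
        with pytest.raises(ValueError):
            fit_gamma_glm(y, dup)


class TestClassifyPart:
    @pytest.mark.parametrize(
        "thal,braak,expected",
        [
            (0, 1, "definite"),
            (0, 4, "definite"),
            (1, 2, "possible"),
            (2, 4, "possible"),
            (3, 2, "none"),  # Thal too high for PART
            (0, 0, "none"),  # no tau pathology
            (0, 5, "none"),  # Braak above IV
            (1, 6, "none"),
        ],
    )
    def test_rule(self, thal, braak, expected):
        assert classify_part(thal, braak).category == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_part(6, 2)
        with pytest.raises(ValueError):
            classify_part(1, 7)


class TestSubgroupSpearman:
    def _table(self):
        rng = np.random.default_rng(3)
        n = 40
        return pd.DataFrame(
            {
                "pct_at8": rng.uniform(0, 5, n),
                "suvr": rng.uniform(1, 2, n),
                "braak_stage": rng.integers(0, 7, n),
                "region": rng.choice(["entorhinal", "midbrain"], n),
            }
        )

    def test_ungrouped_matches_direct_call(self):
        t = self._table()
        res = subgroup_spearman(t, "pct_at8", "suvr")
        direct = spearman_corr(t["pct_at8"], t["suvr"])
        assert res["all"].rho == direct.rho

    def test_query_and_grouping(self):
        t = self._table()
        res = subgroup_spearman(
            t, "pct_at8", "suvr", query="braak_stage <= 4", by="region"
        )
        assert set(res) == {"entorhinal", "midbrain"}

    def test_empty_subset_raises(self):
        with pytest.raises(EmptySubsetError):
            subgroup_spearman(self._table(), "pct_at8", "suvr", query="braak_stage > 10")
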