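"""Latent profile analysis: EM, fit indices, enumeration tests."""

import numpy as np
import pytest
from scipy import stats

from profilenet.lpa import (
    LatentProfileModel,
    LatentProfileResults,
    assign_classes,
    blrt,
    enumerate_classes,
    fit_indices,
    fit_lpa,
    lmr_lrt,
)
from profilenet.simulate import THREE_CLASS_MEANS


def _dummy_results(K, loglik, n_params, posteriors):
    post = np.asarray(posteriors, dtype=float)
    P = 3
    return LatentProfileResults(
        K=K,
        weights=np.full(K, 1.0 / K),
        means=np.zeros((K, P)),
        variances=np.ones((K, P)),
        loglik=loglik,
        n_params=n_params,
        posteriors=post,
        converged=True,
        n_starts_used=1,
        equal_variances=True,
        n_iter=1,
    )


class TestEMFit:
    def test_single_class_closed_form(self):
        """K=1 must reproduce the analytic Gaussian MLE and likelihood."""
        rng = np.random.default_rng(0)
        X = rng.normal(2.0, 1.5, size=(200, 6))
        res = fit_lpa(X, 1)
        assert np.allclose(res.means[0], X.mean(axis=0))
        assert np.allclose(res.variances[0], X.var(axis=0))
        oracle = sum(
            stats.norm.logpdf(X[:, j], X[:, j].mean(), X[:, j].std()).sum()
            for j in range(6)
        )
        assert res.loglik == pytest.approx(oracle, abs=1e-6)
        assert res.n_params == 12

    def test_duplicated_rows_double_loglik(self, three_class_data):
        data, _ = three_class_data
        X = data.item_matrix()[:150]
        res = fit_lpa(X, 2, n_starts=5, seed=3)
        res2 = fit_lpa(np.vstack([X, X]), 2, n_starts=5, seed=3)
        assert res2.loglik == pytest.approx(2 * res.loglik, rel=1e-4)
        assert np.allclose(res.means, res2.means, atol=1e-3)

    def test_three_class_recovery(self, three_class_data):
        data, truth = three_class_data
        res = fit_lpa(data, 3, n_starts=10, seed=2)
        labels, _, _ = assign_classes(res)
        # classes are sorted low -> high at fit time; truth uses 0/1/2 too
        acc = (labels == truth).mean()
        assert acc > 0.95
        # conditional item means recover the generating profiles
        gen = np.vstack(
            [THREE_CLASS_MEANS[k] for k in ("low", "moderate", "high")]
        )
        assert np.max(np.abs(res.means - gen)) < 0.15

    def test_parameter_recovery_large_n(self):
        from profilenet.simulate import default_three_class_config, generate_likert

        data, _ = generate_likert(default_three_class_config(2000, seed=11))
        res = fit_lpa(data, 3, n_starts=10, seed=4)
        gen = np.vstack(
            [THREE_CLASS_MEANS[k] for k in ("low", "moderate", "high")]
        )
        assert np.max(np.abs(res.means - gen)) < 0.1

    def test_class_varying_variances_match_sklearn(self):
        """Dual route: our class-varying EM vs sklearn's diagonal mixture."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(5)
        X = np.vstack(
            [rng.normal(0, 1, (150, 3)), rng.normal(4, 0.5, (150, 3))]
        )
        ours = fit_lpa(X, 2, n_starts=10, seed=1, equal_variances=False)
        gm = GaussianMixture(
            2, covariance_type="diag", n_init=10, random_state=0, reg_covar=1e-10,
            tol=1e-8, max_iter=1000,
        ).fit(X)
        sk_ll = gm.score(X) * len(X)
        assert ours.loglik == pytest.approx(sk_ll, abs=0.05)
        sk_means = gm.means_[np.argsort(gm.means_.sum(axis=1))]
        assert np.allclose(ours.means, sk_means, atol=0.02)

    def test_too_many_classes_rejected(self):
        with pytest.raises(ValueError):
            LatentProfileModel(np.zeros((3, 2)), 3)


class TestFitIndices:
    def test_information_criteria_arithmetic(self):
        res = _dummy_results(1, -100.0, 5, np.ones((100, 1)))
        fi = fit_indices(res, 100)
        assert fi.aic == pytest.approx(210.0)
        assert fi.bic == pytest.approx(200 + 5 * np.log(100))
        assert fi.abic == pytest.approx(200 + 5 * np.log(102 / 24))
        assert fi.entropy is None  # undefined marker for K=1

    def test_entropy_extremes(self):
        hard = np.zeros((40, 2))
        hard[:20, 0] = 1.0
        hard[20:, 1] = 1.0
        assert fit_indices(_dummy_results(2, -1.0, 3, hard)).entropy == pytest.approx(1.0)
        uniform = np.full((40, 2), 0.5)
        assert fit_indices(_dummy_results(2, -1.0, 3, uniform)).entropy == pytest.approx(
            0.0, abs=1e-12
        )

    def test_component_permutation_invariance(self, three_class_data):
        data, _ = three_class_data
        res = fit_lpa(data, 3, n_starts=5, seed=9)
        fi = fit_indices(res)
        perm = [2, 0, 1]
        permuted = LatentProfileResults(
            K=3,
            weights=res.weights[perm],
            means=res.means[perm],
            variances=res.variances[perm],
            loglik=res.loglik,
            n_params=res.n_params,
            posteriors=res.posteriors[:, perm],
            converged=True,
            n_starts_used=1,
            equal_variances=True,
            n_iter=1,
        )
        fi2 = fit_indices(permuted)
        assert fi2.aic == fi.aic and fi2.entropy == pytest.approx(fi.entropy)


class TestEnumerationTests:
    def test_lmr_no_improvement(self):
        a = _dummy_results(1, -500.0, 8, np.ones((100, 1)))
        b = _dummy_results(2, -500.0, 12, np.full((100, 2), 0.5))
        stat, p = lmr_lrt(b, a, 100)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_lmr_negative_lr_signals_refit(self):
        a = _dummy_results(1, -500.0, 8, np.ones((100, 1)))
        b = _dummy_results(2, -501.0, 12, np.full((100, 2), 0.5))
        with pytest.raises(ValueError, match="more starts"):
            lmr_lrt(b, a, 100)

    def test_lmr_size_is_not_liberal(self):
        """Null rejection rate at alpha=.05 stays below the tolerance band
        ceiling; the chi-square(2d) reference is deliberately conservative."""
        n, P, reps = 100, 4, 200
        rej = 0
        for rep in range(reps):
            rng = np.random.default_rng(50_000 + rep)
            X = rng.standard_normal((n, P))
            r1 = LatentProfileModel(X, 1).fit()
            r2 = LatentProfileModel(X, 2).fit(n_starts=4, seed=rep)
            _, p = lmr_lrt(r2, r1, n)
            rej += p < 0.05
        assert rej / reps <= 0.12

    def test_lmr_power_at_strong_separation(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(90_000 + rep)
            comp = rng.random(500) < 0.5
            X = rng.standard_normal((500, 4)) * 0.8 + np.where(
                comp[:, None], 2.0, 0.0
            )
            r1 = LatentProfileModel(X, 1).fit()
            r2 = LatentProfileModel(X, 2).fit(n_starts=5, seed=rep)
            _, p = lmr_lrt(r2, r1, 500)
            hits += p < 0.001
        assert hits >= 19

    def test_blrt_separated_data_minimal_p(self):
        rng = np.random.default_rng(1)
        comp = rng.random(300) < 0.5
        X = rng.standard_normal((300, 3)) * 0.5 + np.where(comp[:, None], 3.0, 0.0)
        r1 = LatentProfileModel(X, 1).fit()
        r2 = LatentProfileModel(X, 2).fit(n_starts=5, seed=2)
        obs, p, failed = blrt(r2, r1, X, B=19, seed=3)
        assert p == pytest.approx(1 / 20)  # observed above every bootstrap LR
        assert failed == 0

    def test_blrt_requires_adjacent_models(self):
        a = _dummy_results(1, -500.0, 8, np.ones((100, 1)))
        with pytest.raises(ValueError):
            blrt(a, a, np.zeros((100, 3)))


class TestEnumeration:
    def test_recommends_three_classes(self, three_class_data):
        data, _ = three_class_data
        enum = enumerate_classes(
            data, K_max=4, n_starts=6, seed=7, run_blrt=False
        )
        assert enum.recommended_K == 3
        tab = enum.table
        assert np.isnan(tab.loc[tab["K"] == 1, "entropy"].iloc[0])
        assert np.isnan(tab.loc[tab["K"] == 1, "p_LMR"].iloc[0])
        assert (tab["K"] == np.arange(1, 5)).all()

    def test_one_class_truth_not_split(self):
        rng = np.random.default_rng(3)
        X = rng.normal(3.0, 1.0, size=(300, 5))
        enum = enumerate_classes(X, K_max=3, n_starts=6, blrt_reps=39, seed=5)
        assert enum.recommended_K == 1

    def test_kmax_validation(self):
        with pytest.raises(ValueError):
            enumerate_classes(np.zeros((50, 3)), K_max=1)


class TestAssignment:
    def test_modal_and_ties(self):
        res = _dummy_results(
            2, -1.0, 3, np.array([[0.9, 0.1], [0.5, 0.5], [0.2, 0.8]])
        )
        labels, post, ties = assign_classes(res)
        assert labels.tolist() == [0, 0, 1]  # tie broken toward lower index
        assert ties.tolist() == [False, True, False]

    def test_classes_ordered_low_to_high(self, three_class_data):
        data, _ = three_class_data
        res = fit_lpa(data, 3, n_starts=6, seed=13)
        totals = res.means.sum(axis=1)
        assert (np.diff(totals) > 0).all()
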