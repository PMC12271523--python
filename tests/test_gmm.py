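import numpy as np
import pytest
from scipy.stats import multivariate_normal

from longax.gmm import (
    GMMModel,
    bic,
    fit_em,
    gaussian_density,
    gaussian_log_density,
    posterior,
    sample_virtual_axons,
    select_model,
)


def blobs(rng, mus, sigma=1.0, ns=(70, 70, 60)):
    return np.vstack([rng.normal(mu, sigma, size=(n, len(mus[0])))
                      for mu, n in zip(mus, ns)])


def two_cluster_model(sep=4.0):
    return GMMModel("s", ["a", "b"], 2, [0.5, 0.5],
                    [[0.0, 0.0], [sep, 0.0]], [1.0, 1.0])


class TestDensity:
    def test_at_mean_closed_form(self):
        for d in (1, 3, 6):
            mu = np.zeros(d)
            assert gaussian_density(mu, mu, 1.0) == pytest.approx(
                (2 * np.pi) ** (-d / 2)
            )

    def test_one_sigma_offset_1d_scales_standard_normal(self):
        sigma = 2.5
        val = gaussian_density([sigma], [0.0], sigma**2)
        std_at_1 = np.exp(-0.5) / np.sqrt(2 * np.pi)
        assert val == pytest.approx(std_at_1 / sigma)

    @pytest.mark.parametrize("cov_type", ["spherical", "diag", "full"])
    def test_matches_scipy_reference(self, cov_type):
        rng = np.random.default_rng(0)
        d = 4
        mu = rng.normal(size=d)
        if cov_type == "spherical":
            cov = 1.7
            full = np.eye(d) * cov
        elif cov_type == "diag":
            cov = rng.uniform(0.5, 2.0, d)
            full = np.diag(cov)
        else:
            a = rng.normal(size=(d, d))
            cov = a @ a.T + d * np.eye(d)
            full = cov
        for _ in range(20):
            x = rng.normal(size=d, scale=3)
            expect = multivariate_normal(mu, full).logpdf(x)
            assert gaussian_log_density(x, mu, cov, cov_type) == pytest.approx(
                expect, abs=1e-12
            )


class TestPosterior:
    def test_single_cluster_is_certain(self):
        m = GMMModel("s", ["a"], 1, [1.0], [[0.0]], [1.0])
        assert posterior(m, [3.0]) == pytest.approx([1.0])

    def test_midpoint_of_mirror_clusters_is_half_half(self):
        m = two_cluster_model(sep=6.0)
        assert posterior(m, [3.0, 0.0]) == pytest.approx([0.5, 0.5])

    def test_matches_naive_unstabilized_at_moderate_scale(self):
        rng = np.random.default_rng(1)
        m = GMMModel("s", list("abc"), 3, [0.2, 0.5, 0.3],
                     rng.normal(size=(3, 3)), [1.0, 2.0, 0.5])
        for _ in range(20):
            x = rng.normal(size=3, scale=2)
            dens = np.array([
                w * gaussian_density(x, mu, c)
                for w, mu, c in zip(m.weights, m.means, m.covariances)
            ])
            naive = dens / dens.sum()
            assert np.max(np.abs(posterior(m, x) - naive)) < 1e-10

    def test_rows_sum_to_one_on_fitted_model(self):
        rng = np.random.default_rng(2)
        X = blobs(rng, [[0, 0], [8, 0]], ns=(40, 40))
        m = fit_em(X, 2, rng=rng)
        rows = m.posterior(X).sum(axis=1)
        assert np.allclose(rows, 1.0, atol=1e-9)


class TestFitEM:
    def test_single_cluster_closed_form(self):
        rng = np.random.default_rng(3)
        X = rng.normal(2.0, 3.0, size=(200, 1))
        m = fit_em(X, 1, rng=rng)
        assert m.means[0, 0] == pytest.approx(X.mean(), abs=1e-9)
        assert m.covariances[0] == pytest.approx(X.var(), rel=1e-6)  # MLE (biased)
        assert m.weights == pytest.approx([1.0])

    def test_log_likelihood_monotone_nondecreasing(self):
        rng = np.random.default_rng(4)
        X = blobs(rng, [[0, 0], [6, 0], [0, 6]])
        for c in (1, 2, 3, 4):
            m = fit_em(X, c, rng=rng)
            diffs = np.diff(m.ll_trace)
            assert np.all(diffs >= -1e-6 * np.abs(m.ll_trace[-1]))

    def test_weights_sum_to_one_after_fit(self):
        rng = np.random.default_rng(5)
        X = blobs(rng, [[0, 0], [7, 0]], ns=(50, 50))
        for c in (1, 2, 3):
            m = fit_em(X, c, rng=rng)
            assert m.weights.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(m.weights >= 0)

    def test_parameter_recovery_on_separated_blobs(self):
        mus = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        ns = (80, 60, 60)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = blobs(rng, mus, sigma=1.0, ns=ns)
            m = fit_em(X, 3, rng=rng)
            # match fitted to true means greedily
            order = [int(np.argmin(((m.means - mu) ** 2).sum(axis=1)))
                     for mu in mus]
            mean_ok = all(
                np.linalg.norm(m.means[o] - mu) <= 3.0 / np.sqrt(n)
                for o, mu, n in zip(order, mus, ns)
            )
            w_ok = all(
                abs(m.weights[o] - n / sum(ns)) < 0.1
                for o, n in zip(order, ns)
            )
            hits += mean_ok and w_ok
        assert hits >= 9

    def test_c_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            fit_em(np.zeros((3, 2)), 4)


class TestBIC:
    def test_free_parameter_count_spherical(self):
        m = GMMModel("s", list("abc"), 2, [0.5, 0.5],
                     np.zeros((2, 3)), [1.0, 1.0])
        assert m.n_free_parameters() == 1 + 6 + 2

    def test_single_cluster_matches_hand_computation(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(100, 1))
        m = fit_em(X, 1, rng=rng)
        var = X.var()
        ll = np.sum(-0.5 * (np.log(2 * np.pi * var) + (X[:, 0] - X.mean()) ** 2 / var))
        kappa = 0 + 1 + 1
        assert bic(m, X) == pytest.approx(kappa * np.log(100) - 2 * ll, rel=1e-9)

    def test_duplicate_cluster_never_improves_bic(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(80, 2))
        m1 = fit_em(X, 1, rng=rng)
        dup = GMMModel("s", [], 2, [0.5, 0.5],
                       np.vstack([m1.means, m1.means]),
                       np.concatenate([m1.covariances, m1.covariances]))
        assert bic(dup, X) > bic(m1, X)

    def test_matches_sklearn_bic_on_identical_parameters(self):
        """Independent cross-check: my EM on well-separated blobs lands on
        the same optimum as sklearn's spherical GMM, with equal BIC."""
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(8)
        X = blobs(rng, [[0, 0], [10, 0], [0, 10]])
        mine = fit_em(X, 3, rng=rng)
        ref = sklearn.GaussianMixture(
            3, covariance_type="spherical", n_init=10, random_state=0
        ).fit(X)
        assert mine.bic == pytest.approx(ref.bic(X), rel=1e-6)


class TestSelectModel:
    def test_imposed_five_clusters_on_demo_population(self, atlas, demo_population):
        from longax.projections import compute_projection_features, stack_population

        morphs, _, _ = demo_population
        mat = stack_population(
            [compute_projection_features(m, atlas) for m in morphs]
        )
        m = select_model(mat.feature("lengths"), imposed_c=5, rng=0)
        assert m.C == 5

    def test_single_axon_degenerates_to_one_floored_cluster(self):
        m = select_model(np.array([[3.0, 1.0]]), rng=0)
        assert m.C == 1
        assert m.covariances[0] > 0

    def test_default_range_is_half_to_n(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(6, 2))
        m = select_model(X, rng=rng)
        assert set(m.bic_trace) == {3, 4, 5, 6}

    def test_recovers_three_patterns_with_widened_range(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = blobs(rng, [[0, 0], [12, 0], [0, 12]], ns=(40, 30, 30))
            m = select_model(X, c_range=(1, 6), rng=rng)
            hits += m.C == 3
        assert hits >= 4


class TestSampling:
    def test_floored_variance_returns_clipped_mean(self):
        m = GMMModel("s", ["a", "b"], 1, [1.0], [[5.0, -2.0]], [1e-18],
                     observed_masks=np.array([[True, True]]))
        samples, _ = sample_virtual_axons(m, 5, rng=0)
        assert np.allclose(samples, [[5.0, 0.0]], atol=1e-6)

    def test_cluster_frequencies_match_weights(self):
        m = GMMModel("s", ["a"], 3, [0.2, 0.5, 0.3], np.zeros((3, 1)),
                     [1.0, 1.0, 1.0])
        _, labels = sample_virtual_axons(m, 10_000, rng=1)
        for k, p in enumerate(m.weights):
            sigma = np.sqrt(10_000 * p * (1 - p))
            assert abs((labels == k).sum() - 10_000 * p) <= 3 * sigma

    def test_unobserved_regions_zeroed(self):
        m = GMMModel("s", ["a", "b"], 1, [1.0], [[5.0, 5.0]], [0.1],
                     observed_masks=np.array([[True, False]]))
        samples, _ = sample_virtual_axons(m, 20, rng=2)
        assert np.all(samples[:, 1] == 0.0)
        assert np.all(samples[:, 0] > 0)

    def test_virtual_axons_reproduce_cluster_top_regions(self, atlas,
                                                         demo_population):
        """Resampled virtual axons keep each cluster's main projections."""
        from longax.projections import compute_projection_features, stack_population

        morphs, _, _ = demo_population
        mat = stack_population(
            [compute_projection_features(m, atlas) for m in morphs]
        )
        X = mat.feature("lengths")
        model = select_model(X, imposed_c=5, rng=0, region_vocab=mat.region_vocab)
        labels = model.predict(X)
        samples, slabels = sample_virtual_axons(model, 59, rng=3)
        for c in range(5):
            train = X[labels == c]
            virt = samples[slabels == c]
            if len(train) == 0 or len(virt) == 0:
                continue
            k = min(3, (train.mean(0) > 0).sum())
            top_train = set(np.argsort(-train.mean(0))[:k])
            top_virt = set(np.argsort(-virt.mean(0))[:k])
            assert top_train == top_virt
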