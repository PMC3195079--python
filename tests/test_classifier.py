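"""Fitting, the Bayes discriminant score, Fisher axis and predictions."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import gcda
from gcda import ShrinkageSpec, empty_graph, erdos_renyi, fit
from gcda.classifier import _assemble, discriminant_score, fisher_axis, predict, scores


def make_model(mu1, mu2, sigma1, sigma2=None, pi1=0.5, flavor="linear"):
    sigma2 = sigma1 if sigma2 is None else sigma2
    return _assemble(flavor, (1, 2), mu1, mu2, pi1, 1 - pi1, sigma1, sigma2,
                     lam=0.5, eps=1.0, graph_ids=("manual",))


class TestFit:
    def test_balanced_priors(self, small_dataset):
        X, y = small_dataset
        m = fit(X, y, empty_graph(5), ShrinkageSpec(lam=0.2))
        assert m.pi1 == m.pi2 == 0.5

    def test_uniform_priors_flag(self, small_dataset):
        X, y = small_dataset
        m = fit(X[:45], y[:45], empty_graph(5), uniform_priors=True)
        assert m.pi1 == m.pi2 == 0.5

    def test_lam_zero_ignores_data_covariance(self, sim_dataset):
        X, y, g, _ = sim_dataset
        spec = ShrinkageSpec(lam=0.0, eps=1.0)
        m1 = fit(X, y, g, spec)
        m2 = fit(X + np.sin(X), y, g, spec)  # different data, same target
        T = gcda.shrinkage_target(gcda.laplacian(g), 1.0).matrix
        assert np.allclose(m1.sigma1, T)
        assert np.allclose(m2.sigma1, T)

    def test_parameter_recovery_at_large_n(self):
        rng = np.random.default_rng(4)
        p, n = 5, 4000
        Sigma = np.diag([1.0, 2.0, 0.5, 1.5, 1.0])
        mu1, mu2 = np.zeros(p), np.full(p, 1.0)
        X = np.vstack([
            rng.multivariate_normal(mu1, Sigma, n // 2),
            rng.multivariate_normal(mu2, Sigma, n // 2),
        ])
        y = np.array([1] * (n // 2) + [2] * (n // 2))
        m = fit(X, y, empty_graph(p), ShrinkageSpec(lam=1.0))
        assert np.linalg.norm(m.mu1 - mu1) < 0.1
        assert np.linalg.norm(m.mu2 - mu2) < 0.1
        assert np.linalg.norm(m.sigma1 - Sigma, "fro") < 0.2

    def test_flavor_graph_count_contract(self, sim_dataset):
        X, y, g, _ = sim_dataset
        with pytest.raises(ValueError, match="two graphs"):
            fit(X, y, g, flavor="quadratic")
        with pytest.raises(ValueError, match="one graph"):
            fit(X, y, (g, g), flavor="linear")

    def test_singular_empirical_estimate_advises_shrinkage(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 20))  # n <= p
        y = np.array([1, 2] * 5)
        with pytest.raises(Exception, match="lam < 1"):
            fit(X, y, empty_graph(20), ShrinkageSpec(lam=1.0))


class TestDiscriminantScore:
    def test_midpoint_symmetry_and_sign(self):
        m = make_model(np.array([-1.0, 0.0]), np.array([1.0, 0.0]), np.eye(2))
        assert discriminant_score(m, [0.0, 0.0]) == pytest.approx(0.0, abs=1e-12)
        assert discriminant_score(m, [-2.0, 0.0]) > 0
        assert discriminant_score(m, [2.0, 0.0]) < 0

    @pytest.mark.parametrize("flavor", ["linear", "quadratic"])
    def test_matches_log_density_oracle(self, flavor, rng):
        # Brute-force oracle: two Gaussian log-densities plus log-priors.
        for _ in range(10):
            p = int(rng.integers(2, 10))
            A1 = rng.standard_normal((p, p))
            sigma1 = A1 @ A1.T / p + 0.5 * np.eye(p)
            if flavor == "linear":
                sigma2 = sigma1
            else:
                A2 = rng.standard_normal((p, p))
                sigma2 = A2 @ A2.T / p + 0.5 * np.eye(p)
            mu1, mu2 = rng.standard_normal(p), rng.standard_normal(p)
            pi1 = float(rng.uniform(0.2, 0.8))
            m = make_model(mu1, mu2, sigma1, sigma2, pi1, flavor)
            x = rng.standard_normal(p)
            oracle = (
                np.log(pi1) + multivariate_normal.logpdf(x, mu1, sigma1)
                - np.log(1 - pi1) - multivariate_normal.logpdf(x, mu2, sigma2)
            )
            assert abs(discriminant_score(m, x) - oracle) < 1e-8

    def test_quadratic_with_equal_covariances_is_linear(self, rng):
        p = 6
        A = rng.standard_normal((p, p))
        sigma = A @ A.T / p + np.eye(p)
        mu1, mu2 = rng.standard_normal(p), rng.standard_normal(p)
        lin = make_model(mu1, mu2, sigma, flavor="linear")
        quad = make_model(mu1, mu2, sigma, sigma.copy(), flavor="quadratic")
        X = rng.standard_normal((20, p))
        assert np.allclose(scores(lin, X), scores(quad, X), atol=1e-10)


class TestClassicalReductions:
    def test_lam_one_matches_textbook_lda(self, small_dataset):
        # Textbook oracle written from the definition with explicit inverses.
        X, y = small_dataset
        m = fit(X, y, empty_graph(5), ShrinkageSpec(lam=1.0))
        mu1, mu2 = X[y == 1].mean(0), X[y == 2].mean(0)
        Xc = np.vstack([X[y == 1] - mu1, X[y == 2] - mu2])
        Sw = Xc.T @ Xc / (len(y) - 2)
        Swi = np.linalg.inv(Sw)
        def oracle(x):
            return (
                np.log(0.5) - 0.5 * (x - mu1) @ Swi @ (x - mu1)
                - np.log(0.5) + 0.5 * (x - mu2) @ Swi @ (x - mu2)
            )
        for x in X[:10]:
            assert discriminant_score(m, x) == pytest.approx(oracle(x), abs=1e-8)

    def test_lam_one_matches_textbook_qda(self, small_dataset):
        X, y = small_dataset
        m = fit(X, y, (empty_graph(5), empty_graph(5)),
                ShrinkageSpec(lam=1.0), flavor="quadratic")
        parts = {}
        for k in (1, 2):
            mu = X[y == k].mean(0)
            S = np.cov(X[y == k], rowvar=False, ddof=1)
            parts[k] = (mu, np.linalg.inv(S), np.linalg.slogdet(S)[1])
        def oracle(x):
            out = 0.0
            for k, sign in ((1, 1.0), (2, -1.0)):
                mu, Si, ld = parts[k]
                out += sign * (np.log(0.5) - 0.5 * ld - 0.5 * (x - mu) @ Si @ (x - mu))
            return out
        for x in X[:10]:
            assert discriminant_score(m, x) == pytest.approx(oracle(x), abs=1e-8)

    def test_empty_graph_is_identity_target_rda(self, sim_dataset):
        # Independently coded ridge-like discriminant with Sigma-hat =
        # lam*S_W + (1-lam)*(1/eps)*I.
        X, y, _, _ = sim_dataset
        lam, eps = 0.3, 2.0
        m = fit(X, y, empty_graph(X.shape[1]), ShrinkageSpec(lam=lam, eps=eps))
        mu1, mu2 = X[y == 1].mean(0), X[y == 2].mean(0)
        Xc = np.vstack([X[y == 1] - mu1, X[y == 2] - mu2])
        Sw = Xc.T @ Xc / (len(y) - 2)
        Shat = lam * Sw + (1 - lam) * np.eye(X.shape[1]) / eps
        Si = np.linalg.inv(Shat)
        n1, n2 = (y == 1).sum(), (y == 2).sum()
        def rda_score(x):
            return (
                np.log(n1 / len(y)) - 0.5 * (x - mu1) @ Si @ (x - mu1)
                - np.log(n2 / len(y)) + 0.5 * (x - mu2) @ Si @ (x - mu2)
            )
        for x in X[:8]:
            assert discriminant_score(m, x) == pytest.approx(rda_score(x), abs=1e-8)


class TestFisherAxis:
    def test_identity_covariance_gives_mean_difference(self):
        mu1, mu2 = np.array([1.0, 2.0]), np.array([-1.0, 0.0])
        m = make_model(mu1, mu2, np.eye(2))
        d = (mu1 - mu2) / np.linalg.norm(mu1 - mu2)
        assert np.allclose(fisher_axis(m), d)

    def test_diagonal_covariance_by_hand(self):
        m = make_model(np.array([1.0, 1.0]), np.zeros(2), np.diag([2.0, 0.5]))
        expected = np.array([0.5, 2.0]) / np.linalg.norm([0.5, 2.0])
        assert np.allclose(fisher_axis(m), expected)

    def test_maximizes_rayleigh_quotient(self, rng):
        p = 5
        A = rng.standard_normal((p, p))
        sigma = A @ A.T / p + np.eye(p)
        mu1, mu2 = rng.standard_normal(p), rng.standard_normal(p)
        m = make_model(mu1, mu2, sigma)
        d = mu1 - mu2
        def rayleigh(w):
            return (w @ d) ** 2 / (w @ sigma @ w)
        best = rayleigh(fisher_axis(m))
        for _ in range(1000):
            w = rng.standard_normal(p)
            assert rayleigh(w / np.linalg.norm(w)) <= best + 1e-9

    def test_rejected_for_quadratic(self, rng):
        m = make_model(np.zeros(2), np.ones(2), np.eye(2), 2 * np.eye(2),
                       flavor="quadratic")
        with pytest.raises(ValueError, match="linear"):
            fisher_axis(m)


class TestPredict:
    def test_separable_training_accuracy(self, small_dataset):
        X, y = small_dataset
        m = fit(X, y, empty_graph(5), ShrinkageSpec(lam=0.2))
        assert np.array_equal(predict(m, X), y)

    def test_tie_goes_to_class_two(self):
        m = make_model(np.array([-1.0, 0.0]), np.array([1.0, 0.0]), np.eye(2))
        assert predict(m, np.zeros((1, 2)))[0] == 2

    def test_permutation_equivariance(self, small_dataset, rng):
        X, y = small_dataset
        m = fit(X, y, empty_graph(5))
        perm = rng.permutation(len(y))
        assert np.array_equal(predict(m, X)[perm], predict(m, X[perm]))

    def test_affine_shift_invariance(self, small_dataset):
        X, y = small_dataset
        shift = np.array([3.0, -1.0, 0.5, 2.0, -4.0])
        m1 = fit(X, y, empty_graph(5), ShrinkageSpec(lam=0.4))
        m2 = fit(X + shift, y, empty_graph(5), ShrinkageSpec(lam=0.4))
        assert np.array_equal(predict(m1, X), predict(m2, X + shift))

    def test_label_encoding_preserved(self, small_dataset):
        X, y = small_dataset
        y_str = np.where(y == 1, "tumor", "control")
        m = fit(X, y_str, empty_graph(5))
        preds = predict(m, X)
        assert set(preds) <= {"tumor", "control"}
        # sorted order maps "control" -> class 1
        assert m.classes == ("control", "tumor")


class TestSerialization:
    def test_round_trip_scores(self, sim_dataset, tmp_path):
        X, y, g, _ = sim_dataset
        m = fit(X, y, g, ShrinkageSpec(lam=0.15, eps=0.5))
        path = tmp_path / "model.yaml"
        m.save(path)
        m2 = gcda.GcdaModel.load(path)
        assert np.allclose(scores(m, X), scores(m2, X), atol=1e-10)
        assert m2.flavor == m.flavor and m2.classes == m.classes
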