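import numpy as np
import pytest

from aquaopes import (CVModel, DeepTICACV, LDACV, cubic_transform,
                      lda_direction, tica, train_deep_lda)
from aquaopes.mlcv import fisher_ratio, scatter_matrices


def make_clouds(rng, d=6, n=3000, shift=None):
    shift = np.r_[1.2, -0.8, np.zeros(d - 2)] if shift is None else shift
    X_B = rng.normal(0, 1, (n, d))
    X_U = rng.normal(0, 1, (n, d)) + shift
    return X_B, X_U


def simulate_ou(rng, T, n, dt=1.0):
    a = np.exp(-dt / T)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    noise = rng.standard_normal(n) * np.sqrt(1 - a * a)
    for i in range(1, n):
        x[i] = a * x[i - 1] + noise[i]
    return x


class TestLDA:
    def test_identity_within_scatter_gives_mean_difference(self, rng):
        # isotropic classes: w must align with mu_B - mu_U
        X_B, X_U = make_clouds(rng, n=50_000)
        w = lda_direction(X_B, X_U)
        target = np.r_[1.2, -0.8, np.zeros(4)]
        target = -target / np.linalg.norm(target)  # mu_B - mu_U = -shift
        assert abs(w @ target) > 0.99

    def test_degenerate_equal_means_rejected(self, rng):
        X = rng.normal(0, 1, (100, 3))
        with pytest.raises(ValueError, match="degenerate"):
            lda_direction(X, X)

    def test_beats_random_directions(self, rng):
        X_B, X_U = make_clouds(rng, d=5)
        w = lda_direction(X_B, X_U, reg_lambda=1e-9)
        ratio = fisher_ratio(X_B, X_U, w)
        vs = rng.normal(0, 1, (10_000, 5))
        vs /= np.linalg.norm(vs, axis=1, keepdims=True)
        ratios = [fisher_ratio(X_B, X_U, v) for v in vs]
        assert ratio >= max(ratios)

    def test_scale_invariance(self, rng):
        X_B, X_U = make_clouds(rng)
        w1 = lda_direction(X_B, X_U)
        w2 = lda_direction(7.3 * X_B, 7.3 * X_U)
        assert abs(w1 @ w2) == pytest.approx(1.0, abs=1e-9)

    def test_scatter_shapes_and_rank(self, rng):
        X_B, X_U = make_clouds(rng, d=4)
        sp = scatter_matrices(X_B, X_U)
        assert np.linalg.matrix_rank(sp.S_b) == 1
        assert np.all(np.linalg.eigvalsh(sp.S_w) > 0)

    def test_estimator_protocol(self, rng):
        X_B, X_U = make_clouds(rng, n=500)
        X = np.vstack([X_U, X_B])
        y = np.r_[np.zeros(500), np.ones(500)]
        est = LDACV().fit(X, y)
        s = est.transform(X)
        assert s.shape == (1000, 1)
        # class "1" (B) maps to positive side by convention
        assert s[500:].mean() > 0 > s[:500].mean()
        assert est.get_params()["reg_lambda"] == 0.0


class TestCubicTransform:
    @pytest.mark.parametrize("s,expected", [(0.0, 0.0), (1.0, 2.0), (-2.0, -10.0)])
    def test_closed_form(self, s, expected):
        assert cubic_transform(s) == expected

    def test_strictly_monotone(self):
        s = np.linspace(-3, 3, 1001)
        assert np.all(np.diff(cubic_transform(s)) > 0)


class TestDeepLDA:
    def test_linear_activation_collapses_to_lda(self, rng):
        """With linear activations the learned CV direction matches the
        closed-form discriminant (cosine >= 0.99)."""
        X_B, X_U = make_clouds(rng, d=6, n=4000)
        model = train_deep_lda(X_B, X_U, hidden_sizes=(8, 4),
                               activation="linear", epochs=200, lr=5e-3,
                               seed=1, output_transform="identity")
        w_ref = lda_direction(X_B, X_U, 1e-9)
        # effective linear direction via finite differences at the origin
        e = np.eye(6) * 1e-4
        g = np.array([(model.evaluate(r[None]) - model.evaluate(-r[None]))[0]
                      for r in e])
        cos = abs(g @ w_ref) / np.linalg.norm(g)
        assert cos >= 0.99

    def test_separable_clouds_give_separated_cv(self, rng):
        X_B = rng.normal(0, 0.3, (2000, 5))
        X_U = rng.normal(0, 0.3, (2000, 5))
        X_U[:, 0] += 4.0
        model = train_deep_lda(X_B, X_U, epochs=150, seed=2)
        hold_B = rng.normal(0, 0.3, (500, 5))
        hold_U = rng.normal(0, 0.3, (500, 5))
        hold_U[:, 0] += 4.0
        s_B, s_U = model.evaluate(hold_B), model.evaluate(hold_U)
        pooled = np.sqrt(0.5 * (s_B.var() + s_U.var()))
        assert abs(s_B.mean() - s_U.mean()) >= 5 * pooled

    def test_seed_determinism(self, rng):
        X_B, X_U = make_clouds(rng, n=400)
        m1 = train_deep_lda(X_B, X_U, epochs=30, seed=5)
        m2 = train_deep_lda(X_B, X_U, epochs=30, seed=5)
        assert m1.to_json() == m2.to_json()

    def test_cubic_output_by_default(self, rng):
        X_B, X_U = make_clouds(rng, n=300)
        model = train_deep_lda(X_B, X_U, epochs=20, seed=0)
        assert model.output_transform == "cubic"


class TestTICA:
    def test_ou_eigenvalue_and_timescale(self):
        rng = np.random.default_rng(0)
        T, lag = 20.0, 5.0
        x = simulate_ou(rng, T, 400_000)
        sol = tica(x[:, None], lag_time=lag)
        assert sol.eigenvalues[0] == pytest.approx(np.exp(-lag / T), abs=0.01)
        assert sol.implied_timescales[0] == pytest.approx(T, rel=0.1)

    def test_white_noise_has_no_slow_mode(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100_000, 3))
        sol = tica(X, lag_time=5.0)
        assert np.all(sol.implied_timescales <= 5.0)

    def test_two_ou_planted_axis_recovery(self):
        rng = np.random.default_rng(2)
        slow = simulate_ou(rng, 50.0, 200_000)
        fast = simulate_ou(rng, 2.0, 200_000)
        # mix the components into observed descriptors
        M = np.array([[1.0, 0.8], [0.5, -1.0]])
        X = np.c_[slow, fast] @ M.T
        sol = tica(X, lag_time=10.0)
        # leading eigenvector must isolate the slow component:
        # its projection of X should match `slow` up to scale
        proj = (X - sol.mean) @ sol.eigenvectors[:, 0]
        corr = abs(np.corrcoef(proj, slow)[0, 1])
        assert corr >= 0.99

    def test_variational_bound(self):
        rng = np.random.default_rng(3)
        x = simulate_ou(rng, 10.0, 50_000)
        X = np.c_[x, rng.standard_normal(50_000)]
        sol = tica(X, lag_time=3.0)
        assert sol.eigenvalues[0] <= 1.0 + 1e-8

    def test_eigenvectors_c0_orthonormal(self):
        rng = np.random.default_rng(4)
        X = np.c_[simulate_ou(rng, 10.0, 50_000),
                  simulate_ou(rng, 3.0, 50_000)]
        sol = tica(X, lag_time=2.0)
        from aquaopes.mlcv import _tica_covariances
        C0, _, _ = _tica_covariances(X, 2, np.ones(len(X)))
        G = sol.eigenvectors.T @ C0 @ sol.eigenvectors
        np.testing.assert_allclose(G, np.eye(2), atol=1e-6)

    def test_lag_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            tica(np.random.default_rng(0).standard_normal((10, 2)),
                 lag_time=20.0)


class TestDeepTICA:
    def test_linear_collapse_to_tica(self):
        rng = np.random.default_rng(5)
        slow = simulate_ou(rng, 40.0, 60_000)
        fast = simulate_ou(rng, 2.0, 60_000)
        X = np.c_[slow + 0.3 * fast, fast]
        est = DeepTICACV(hidden_sizes=(6,), activation="linear", n_out=2,
                         lag_time=8.0, epochs=120, lr=5e-3, seed=0)
        est.fit(X)
        s = est.transform(X)[:, 0]
        ref = tica(X, lag_time=8.0)
        proj = (X - ref.mean) @ ref.eigenvectors[:, 0]
        corr = abs(np.corrcoef(s, proj)[0, 1])
        assert corr >= 0.98

    def test_unit_weights_match_unweighted(self):
        rng = np.random.default_rng(6)
        X = np.c_[simulate_ou(rng, 20.0, 20_000),
                  simulate_ou(rng, 2.0, 20_000)]
        a = DeepTICACV(lag_time=5.0, epochs=40, seed=1).fit(X)
        b = DeepTICACV(lag_time=5.0, epochs=40, seed=1).fit(
            X, frame_weights=np.ones(len(X)))
        assert a.model_.to_json() == b.model_.to_json()

    def test_recovers_planted_nonlinear_slow_mode(self):
        """The slow coordinate is hidden under monotone nonlinearities of
        the descriptors; the learned CV must still track it in rank
        correlation."""
        from scipy.stats import spearmanr
        rng = np.random.default_rng(7)
        slow = simulate_ou(rng, 50.0, 80_000)
        fast1 = simulate_ou(rng, 2.0, 80_000)
        fast2 = simulate_ou(rng, 1.0, 80_000)
        X = np.c_[np.tanh(slow) + 0.1 * fast1,
                  slow**3 / 5 + 0.2 * fast2,
                  fast1, fast2]
        est = DeepTICACV(hidden_sizes=(16, 8), lag_time=10.0, epochs=200,
                         lr=3e-3, seed=2)
        est.fit(X)
        s = est.transform(X)[:, 0]
        rho = abs(spearmanr(s[::10], slow[::10]).statistic)
        assert rho >= 0.9


class TestCVModelSerialization:
    def test_roundtrip_is_exact(self, rng):
        X_B, X_U = make_clouds(rng, n=300)
        model = train_deep_lda(X_B, X_U, epochs=25, seed=3)
        back = CVModel.from_json(model.to_json())
        X = rng.normal(0, 1, (200, 6))
        np.testing.assert_allclose(back.evaluate(X), model.evaluate(X),
                                   rtol=0, atol=1e-12)

    def test_save_load(self, tmp_path, rng):
        X_B, X_U = make_clouds(rng, n=200)
        model = train_deep_lda(X_B, X_U, epochs=10, seed=4)
        path = tmp_path / "model.json"
        model.save(path)
        back = CVModel.load(path)
        X = rng.normal(0, 1, (50, 6))
        np.testing.assert_array_equal(back.evaluate(X), model.evaluate(X))
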