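import numpy as np
import pytest

from aquaopes import (BiasState, LangevinSpec, OPESConfig, count_well_transitions,
                      epsilon_from_barrier, make_potential, reweighted_fes,
                      run_langevin, run_opes)
from aquaopes.colvar import ColvarSeries


def make_state(sigma=0.2, gamma=10.0, beta=1.0, barrier=5.0, **kw):
    eps = epsilon_from_barrier(barrier, gamma, beta)
    return BiasState(sigma, gamma, beta, eps, **kw)


def kernel_sum_oracle(centers, weights, sigma, s):
    """Independent dense re-summation of the normalized Gaussian mixture."""
    norm = 1.0 / (sigma * np.sqrt(2 * np.pi))
    g = norm * np.exp(-0.5 * ((s[:, None] - centers[None, :]) / sigma) ** 2)
    return g @ weights / weights.sum()


class TestEpsilon:
    def test_closed_form(self):
        assert epsilon_from_barrier(5.0, np.inf, 1.0) == pytest.approx(np.exp(-5.0))

    def test_limit_large_barrier(self):
        assert epsilon_from_barrier(500.0, 10.0, 1.0) < 1e-200

    def test_gamma_le_one_rejected(self):
        with pytest.raises(ValueError):
            epsilon_from_barrier(5.0, 1.0, 1.0)

    def test_floor_equals_minus_barrier(self):
        state = make_state(barrier=4.0, gamma=8.0)
        state.deposit([0.0])
        assert state.bias_floor == pytest.approx(-4.0)


class TestDeposit:
    def test_first_weight_is_one(self):
        state = make_state()
        state.deposit([0.3])
        assert state.weights[0] == pytest.approx(1.0)

    def test_excluded_region_is_a_noop(self):
        state = make_state(excluded_region=lambda s: s[0] > 0.5)
        state.deposit([0.2])
        state.deposit([0.8])
        assert state.n_kernels == 1
        assert state.centers[0, 0] == 0.2

    def test_repeated_deposits_at_one_point_gamma_inf(self):
        """With gamma=inf and epsilon ~ 0, the bias at the only visited
        point stays ~0, so every weight is 1 and P_n is a single
        Gaussian peak (hand-computed kernel sum)."""
        sigma = 0.25
        state = BiasState(sigma, np.inf, 1.0, 1e-300)
        for _ in range(7):
            state.deposit([1.0])
        np.testing.assert_allclose(state.weights, 1.0, rtol=1e-12)
        peak = 1.0 / (sigma * np.sqrt(2 * np.pi))
        assert state.prob([[1.0]])[0] == pytest.approx(peak, rel=1e-12)

    def test_nonfinite_rejected(self):
        state = make_state()
        with pytest.raises(ValueError):
            state.deposit([np.nan])


class TestEvaluateBias:
    def test_empty_state_is_zero(self):
        state = make_state()
        assert state.evaluate([[0.0]])[0] == 0.0

    def test_gamma_one_gives_zero_bias(self):
        state = BiasState(0.2, 1.0, 1.0, 1.0)
        for s in (-0.5, 0.0, 0.7):
            state.deposit([s])
        v = state.evaluate(np.linspace(-2, 2, 50)[:, None])
        np.testing.assert_allclose(v, 0.0, atol=1e-14)

    def test_far_from_kernels_hits_floor(self):
        state = make_state(barrier=3.0)
        state.deposit([0.0])
        v = state.evaluate([[50.0]])[0]
        assert v == pytest.approx(state.bias_floor)

    def test_matches_independent_kernel_sum(self):
        rng = np.random.default_rng(3)
        state = make_state(sigma=0.3, gamma=6.0, barrier=4.0)
        for s in rng.normal(0, 0.5, 40):
            state.deposit([s])
        grid = np.linspace(-2, 2, 101)
        p_oracle = kernel_sum_oracle(state.centers[:, 0], state.weights,
                                     0.3, grid)
        v = state.evaluate(grid[:, None])
        expected = state.prefactor * np.log(p_oracle / state.Z + state.epsilon)
        np.testing.assert_allclose(v, expected, rtol=1e-10)

    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(5)
        state = make_state(sigma=0.3, gamma=6.0, barrier=4.0)
        for s in rng.normal(0, 0.5, 30):
            state.deposit([s])
        pts = rng.uniform(-1.5, 1.5, 20)
        _, dv = state.evaluate(pts[:, None], with_gradient=True)
        h = 1e-6
        fd = (state.evaluate((pts + h)[:, None])
              - state.evaluate((pts - h)[:, None])) / (2 * h)
        np.testing.assert_allclose(dv[:, 0], fd, rtol=1e-6, atol=1e-12)

    def test_monotone_in_gamma_prefactor(self):
        """For a fixed kernel history the bias scales exactly as (1-1/gamma)
        (same epsilon argument) — checked by ratio of prefactors."""
        state = make_state(sigma=0.2, gamma=5.0, barrier=4.0)
        for s in (-0.2, 0.1, 0.4):
            state.deposit([s])
        grid = np.linspace(-1, 1, 21)[:, None]
        v5 = state.evaluate(grid)
        state.gamma = 10.0
        v10 = state.evaluate(grid)
        np.testing.assert_allclose(v10 / v5, (1 - 1 / 10.0) / (1 - 1 / 5.0),
                                   rtol=1e-12)

    def test_bias_cap_on_dense_grid(self, double_well_opes):
        """After a long run, Eq.-style bias stays within [-dE, dE]."""
        _, config, _, state = double_well_opes
        grid = np.linspace(-2.5, 2.5, 4001)[:, None]
        v = state.evaluate(grid)
        assert v.max() <= config.barrier
        assert v.min() >= -config.barrier - 1e-9
        # the total bias range (what can be poured into a basin) ~ dE
        assert v.max() - v.min() <= config.barrier + 1.0


class TestRunOpes:
    def test_gamma_one_identical_to_unbiased(self):
        pot = make_potential("double_well_1d", {"h": 4.0})
        spec = LangevinSpec(potential=pot, n_steps=100_000, seed=8,
                            initial_position=(-1.0,))
        config = OPESConfig(barrier=5.0, gamma=1.0, sigma=0.2,
                            grid=(-2.5, 2.5, 301))
        biased, state = run_opes(spec, config, record_stride=10)
        unbiased = run_langevin(spec, record_stride=10)
        np.testing.assert_array_equal(biased["cv"], unbiased["cv"])
        np.testing.assert_allclose(biased["opes.bias"], 0.0, atol=1e-14)

    def test_deposit_period_beyond_run_gives_zero_bias(self):
        pot = make_potential("double_well_1d", {"h": 4.0})
        spec = LangevinSpec(potential=pot, n_steps=20_000, seed=8,
                            initial_position=(-1.0,))
        config = OPESConfig(barrier=5.0, gamma=10.0, sigma=0.2,
                            deposit_period=50_000, grid=(-2.5, 2.5, 301))
        series, state = run_opes(spec, config, record_stride=10)
        assert state.n_kernels == 0
        np.testing.assert_array_equal(series["opes.bias"], 0.0)

    def test_biasing_multiplies_transitions(self, double_well_opes):
        spec, _, series, _ = double_well_opes
        biased = count_well_transitions(series["cv"])
        unbiased = count_well_transitions(run_langevin(spec)["cv"])
        assert biased >= 20
        assert biased > 10 * max(unbiased, 1)

    def test_no_kernel_in_excluded_region_after_run(self):
        pot = make_potential("double_well_1d", {"h": 5.0})
        spec = LangevinSpec(potential=pot, n_steps=300_000, seed=4,
                            initial_position=(-1.0,))
        config = OPESConfig(barrier=4.0, gamma=10.0, sigma=0.15,
                            grid=(-2.0, 1.5, 301),
                            excluded_region=lambda s: s[0] > -0.3)
        _, state = run_opes(spec, config)
        assert state.n_kernels > 0
        assert np.all(state.centers[:, 0] <= -0.3)


class TestReweightedFES:
    def test_zero_bias_reduces_to_histogram(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.5, 4000)
        series = ColvarSeries.from_columns(np.arange(1, 4001) * 0.1,
                                           cv=x, **{"opes.bias": np.zeros(4000)})
        edges = np.linspace(-1.5, 1.5, 31)
        fes = reweighted_fes(series, edges, 2)
        hist, _ = np.histogram(x, bins=edges)
        with np.errstate(divide="ignore"):
            f = -np.log(hist / hist.sum())
        f -= f[np.isfinite(f)].min()
        np.testing.assert_allclose(fes.free_energy, f, atol=1e-12)

    def test_identical_halves_have_zero_error(self):
        x = np.tile(np.linspace(-1, 1, 500), 2)
        series = ColvarSeries.from_columns(np.arange(1, 1001) * 0.1, cv=x,
                                           **{"opes.bias": np.zeros(1000)})
        fes = reweighted_fes(series, np.linspace(-1, 1, 11), 2)
        np.testing.assert_allclose(fes.error, 0.0, atol=1e-12)

    def test_missing_bias_column_and_bad_blocks(self):
        series = ColvarSeries.from_columns([1.0, 2.0], cv=[0.0, 1.0])
        with pytest.raises(ValueError, match="bias"):
            reweighted_fes(series, np.linspace(-1, 1, 5), 2)
        series2 = ColvarSeries.from_columns([1.0, 2.0], cv=[0.0, 1.0],
                                            **{"opes.bias": [0.0, 0.0]})
        with pytest.raises(ValueError, match="n_blocks"):
            reweighted_fes(series2, np.linspace(-1, 1, 5), 1)

    def test_converged_run_recovers_analytic_potential(self, double_well_opes):
        spec, _, series, _ = double_well_opes
        edges = np.linspace(-1.5, 1.5, 61)
        fes = reweighted_fes(series, edges, 4)
        mask = np.isfinite(fes.free_energy)
        u = spec.potential.energy(fes.grid[mask])
        u -= u.min()
        rmse = np.sqrt(np.mean((fes.free_energy[mask] - u) ** 2))
        assert rmse <= 0.5

    def test_symmetric_wells_equal_free_energy(self, double_well_opes):
        """Free-energy difference between the two symmetric wells vanishes
        within the block error."""
        _, _, series, _ = double_well_opes
        edges = np.linspace(-1.5, 1.5, 31)
        fes = reweighted_fes(series, edges, 4)
        left = fes.grid < -0.5
        right = fes.grid > 0.5
        f_left = fes.free_energy[left].min()
        f_right = fes.free_energy[right].min()
        err = np.hypot(fes.error[left][np.argmin(fes.free_energy[left])],
                       fes.error[right][np.argmin(fes.free_energy[right])])
        assert abs(f_left - f_right) <= max(3 * err, 0.2)


def test_fes_grid_write_read_roundtrip(tmp_path, double_well_opes):
    _, _, series, _ = double_well_opes
    from aquaopes import FESGrid
    fes = reweighted_fes(series, np.linspace(-1.5, 1.5, 31), 2)
    path = tmp_path / "fes.dat"
    fes.write(path)
    back = FESGrid.read(path)
    np.testing.assert_allclose(back.grid, fes.grid, rtol=1e-8)
    m = np.isfinite(fes.free_energy)
    np.testing.assert_allclose(back.free_energy[m], fes.free_energy[m], rtol=1e-7)
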