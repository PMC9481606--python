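"""On-the-fly Probability Enhanced Sampling (OPES).

The probability density of the biased collective variable s is estimated
on the fly from weighted Gaussian kernels deposited along the run,

    P_n(s) = sum_k w_k G(s, s_k) / sum_k w_k,    w_k = exp(beta * V_{k-1}(s_k)),

and converted into the well-tempered bias

    V_n(s) = (1 - 1/gamma) * (1/beta) * log(P_n(s)/Z_n + epsilon),

where gamma > 1 is the bias factor, Z_n tracks the explored configuration
space (here: the mean of P_n over the deposited centers) and epsilon sets
the maximum bias that can ever be deposited: with

    epsilon = exp(-beta * dE / (1 - 1/gamma))

the bias far from all kernels sits at the floor -dE and the total bias
range never exceeds ~dE.  In the long run the sampled CV marginal tends to
the well-tempered target P(s)^(1/gamma).

The integrator applies the floor-shifted bias V - V_floor (identical
forces; zero far from all kernels), which is also the quantity that enters
hyperdynamics acceleration factors downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .colvar import ColvarSeries
from .dynamics import BiasGrid, LangevinSpec, _simulate, _to_series

__all__ = [
    "BiasState", "OPESConfig", "FESGrid", "epsilon_from_barrier",
    "deposit", "evaluate_bias", "run_opes", "reweighted_fes",
]


def epsilon_from_barrier(delta_E: float, gamma: float, beta: float) -> float:
    """Regularizer epsilon that caps the deposited bias at ``delta_E``.

    epsilon = exp(-beta*dE/(1-1/gamma)); the far-field bias floor is then
    exactly -dE, so no more than ~dE of bias can ever be poured into a
    basin.
    """
    if delta_E <= 0:
        raise ValueError("delta_E must be > 0")
    if not gamma > 1:
        raise ValueError("gamma must be > 1")
    return float(np.exp(-beta * delta_E / (1.0 - 1.0 / gamma)))


class BiasState:
    """The running kernel estimate of P(s) and the bias built from it.

    Kernels are normalized (multivariate diagonal) Gaussians with fixed
    per-dimension bandwidth ``sigma``.  Deposits inside ``excluded_region``
    are silently skipped — nothing about the state changes — which is what
    makes the flooding variant rate-safe.
    """

    def __init__(self, sigma, gamma: float, beta: float, epsilon: float,
                 excluded_region: Callable[[np.ndarray], bool] | None = None,
                 deposit_period: int = 500):
        sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
        if np.any(sigma <= 0):
            raise ValueError("bandwidths must be positive")
        if not gamma >= 1:
            raise ValueError("gamma must be >= 1")
        if epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        self.sigma = sigma
        self.gamma = float(gamma)
        self.beta = float(beta)
        self.epsilon = float(epsilon)
        self.excluded_region = excluded_region
        self.deposit_period = int(deposit_period)
        self.dim = len(sigma)
        self.centers = np.empty((0, self.dim))
        self.weights = np.empty(0)
        self.weight_sum = 0.0
        # running unnormalized kernel sums evaluated at each center,
        # S_k = sum_j w_j G(s_k, s_j); Z_n = mean_k S_k / weight_sum
        self._center_sums = np.empty(0)
        self.Z = 1.0
        self._norm = float(np.prod(1.0 / (self.sigma * np.sqrt(2 * np.pi))))

    # -- kernel algebra -------------------------------------------------
    @property
    def n_kernels(self) -> int:
        return len(self.weights)

    @property
    def prefactor(self) -> float:
        return (1.0 - 1.0 / self.gamma) / self.beta

    @property
    def bias_floor(self) -> float:
        """Bias value infinitely far from every kernel."""
        if self.n_kernels == 0:
            return 0.0
        return self.prefactor * np.log(self.epsilon)

    def _kernel_values(self, s: np.ndarray) -> np.ndarray:
        """G(s, s_k) for all centers; s shape (m, dim) -> (m, n)."""
        d = (s[:, None, :] - self.centers[None, :, :]) / self.sigma
        return self._norm * np.exp(-0.5 * np.sum(d * d, axis=-1))

    def prob(self, s) -> np.ndarray:
        """P_n(s); zero-kernel state returns 0."""
        s = np.atleast_2d(np.asarray(s, dtype=float))
        if self.n_kernels == 0:
            return np.zeros(len(s))
        return self._kernel_values(s) @ self.weights / self.weight_sum

    def evaluate(self, s, with_gradient: bool = False):
        """The well-tempered bias V_n(s) (and optionally dV/ds).

        Before any deposit the bias is identically zero (the V_0 = 0
        convention that the weight definition forces at k = 1).
        """
        s = np.atleast_2d(np.asarray(s, dtype=float))
        if not np.all(np.isfinite(s)):
            raise ValueError("non-finite CV value")
        if self.n_kernels == 0:
            v = np.zeros(len(s))
            return (v, np.zeros_like(s)) if with_gradient else v
        g = self._kernel_values(s)
        p = g @ self.weights / self.weight_sum
        arg = p / self.Z + self.epsilon
        v = self.prefactor * np.log(arg)
        if not with_gradient:
            return v
        # dP/ds_i = sum_k w_k G * (-(s_i - c_ki)/sigma_i^2) / wsum
        diff = -(s[:, None, :] - self.centers[None, :, :]) / self.sigma**2
        dp = np.einsum("mk,mki->mi", g * self.weights, diff) / self.weight_sum
        dv = self.prefactor * dp / (self.Z * arg[:, None])
        return v, dv

    def deposit(self, s_k) -> "BiasState":
        """Deposit one kernel at ``s_k`` (no-op inside the excluded region).

        The kernel weight is exp(beta * V_{k-1}(s_k)) with the bias as
        defined above, evaluated before the deposit.
        """
        s_k = np.atleast_1d(np.asarray(s_k, dtype=float))
        if not np.all(np.isfinite(s_k)):
            raise ValueError("non-finite deposit point")
        if self.excluded_region is not None and self.excluded_region(s_k):
            return self
        v = float(self.evaluate(s_k[None, :])[0])
        w = float(np.exp(self.beta * v))
        if self.n_kernels:
            g_new_at_old = self._kernel_values(s_k[None, :])[0]  # G(s_k, s_j)
            self._center_sums = self._center_sums + w * g_new_at_old
            s_new_sum = float(g_new_at_old @ self.weights) + w * self._norm
        else:
            s_new_sum = w * self._norm
        self.centers = np.vstack([self.centers, s_k[None, :]])
        self.weights = np.append(self.weights, w)
        self.weight_sum += w
        self._center_sums = np.append(self._center_sums, s_new_sum)
        self.Z = float(np.mean(self._center_sums)) / self.weight_sum
        return self

    # -- serialization ---------------------------------------------------
    def to_kernel_table(self) -> list[dict]:
        """JSON-lines-able kernel table (center, sigma, weight per row)."""
        return [
            {"center": list(map(float, c)), "sigma": list(map(float, self.sigma)),
             "weight": float(w)}
            for c, w in zip(self.centers, self.weights)
        ]

    def bias_grid(self, lo: float, hi: float, n: int, cv_index: int = 0) -> BiasGrid:
        """Floor-shifted bias + force cached on a uniform 1D grid."""
        grid = np.linspace(lo, hi, n)
        if self.n_kernels == 0:
            return BiasGrid(lo, grid[1] - grid[0], np.zeros(n), np.zeros(n), cv_index)
        v, dv = self.evaluate(grid[:, None], with_gradient=True)
        return BiasGrid(lo, grid[1] - grid[0], v - self.bias_floor,
                        -dv[:, 0], cv_index)


def deposit(state: BiasState, s_k) -> BiasState:
    return state.deposit(s_k)


def evaluate_bias(state: BiasState, s, with_gradient: bool = False):
    return state.evaluate(s, with_gradient=with_gradient)


@dataclass
class OPESConfig:
    """Run-time OPES settings.

    barrier is the bias cap dE (same units as kT); barrier <= 0 disables
    biasing entirely.  sigma=None estimates the kernel bandwidth from a
    short unbiased segment (std of the CV), falling back to 2% of the grid
    range if that segment never moves.
    """

    barrier: float
    gamma: float = 10.0
    sigma: float | None = None
    deposit_period: int = 500
    grid: tuple = (-3.0, 3.0, 801)
    excluded_region: Callable[[np.ndarray], bool] | None = None
    sigma_estimation_steps: int = 5000


class _GridCache:
    """Incremental numerator/derivative of the kernel sum on the 1D grid.

    Adding a kernel is O(grid); the full bias curve is then recomputed
    from the cached sums in O(grid) as weight_sum and Z evolve.
    """

    def __init__(self, lo, hi, n):
        self.grid = np.linspace(lo, hi, n)
        self.num = np.zeros(n)     # sum_k w_k G(grid, s_k)  (unnormalized)
        self.dnum = np.zeros(n)    # its derivative
        self.excluded_mask = None  # set in rate-safe (flooding) mode

    def add_kernel(self, center, weight, sigma, norm):
        d = (self.grid - center) / sigma
        g = norm * np.exp(-0.5 * d * d)
        self.num += weight * g
        self.dnum += weight * g * (-(self.grid - center) / sigma**2)

    def bias_grid(self, state: BiasState, cv_index: int) -> BiasGrid:
        if state.n_kernels == 0:
            n = len(self.grid)
            return BiasGrid(self.grid[0], self.grid[1] - self.grid[0],
                            np.zeros(n), np.zeros(n), cv_index)
        p = self.num / state.weight_sum
        arg = p / state.Z + state.epsilon
        v = state.prefactor * np.log(arg)
        dx = self.grid[1] - self.grid[0]
        if self.excluded_mask is not None:
            v_shift = np.where(self.excluded_mask, 0.0, v - state.bias_floor)
            force = -np.gradient(v_shift, dx)
            return BiasGrid(self.grid[0], dx, v_shift, force, cv_index)
        dv = state.prefactor * (self.dnum / state.weight_sum) / (state.Z * arg)
        return BiasGrid(self.grid[0], dx, v - state.bias_floor, -dv, cv_index)


def _estimate_sigma(spec: LangevinSpec, cv_index: int, config: OPESConfig) -> float:
    probe = spec.with_(n_steps=min(config.sigma_estimation_steps, spec.n_steps),
                       seed=spec.seed + 1)
    out = _simulate(probe, None, record_stride=max(1, probe.n_steps // 2000))
    sig = float(np.std(out["positions"][:, cv_index]))
    if sig <= 0:
        sig = 0.02 * (config.grid[1] - config.grid[0])
    return sig


def run_opes(spec: LangevinSpec, config: OPESConfig, cv_index: int = 0,
             record_stride: int | None = None,
             _accumulate_accel: bool = False,
             stop=None, static_bias: BiasGrid | None = None):
    """Couple the Langevin propagator to on-the-fly bias construction.

    Returns (ColvarSeries, BiasState).  The recorded ``opes.bias`` column
    is the floor-shifted instantaneous bias (constant shifts cancel in
    reweighting).  ``stop``/``_accumulate_accel``/``static_bias`` are the
    hooks the flooding module builds on; with ``_accumulate_accel`` a third
    element with raw run counters is returned.
    """
    from . import _kernels
    from .dynamics import DivergenceError, _pack

    if record_stride is None:
        record_stride = max(1, spec.n_steps // 100_000)
    beta = 1.0 / spec.kT
    lo, hi, n_grid = config.grid
    use_opes = config.barrier > 0 and static_bias is None
    if use_opes:
        sigma = config.sigma if config.sigma is not None else _estimate_sigma(
            spec, cv_index, config)
        if config.gamma > 1:
            eps = epsilon_from_barrier(config.barrier, config.gamma, beta)
        else:
            eps = 1.0  # gamma = 1: prefactor 0, bias identically zero
        state = BiasState(sigma, config.gamma, beta, eps,
                          excluded_region=config.excluded_region,
                          deposit_period=config.deposit_period)
        cache = _GridCache(lo, hi, n_grid)
        if config.excluded_region is not None:
            # rate-safe mode: the applied bias is exactly zero inside the
            # excluded region (kernel tails would otherwise leak bias onto
            # the transition state and corrupt the time rescaling)
            cache.excluded_mask = np.array(
                [bool(config.excluded_region(np.array([g]))) for g in cache.grid])
        bias = cache.bias_grid(state, cv_index)
    else:
        state = BiasState(config.sigma or 1.0, max(config.gamma, 1.0),
                          beta, 1.0, excluded_region=config.excluded_region,
                          deposit_period=config.deposit_period)
        cache = None
        bias = static_bias  # may be None (-> unbiased)

    pid, pp = _pack(spec.potential)
    dim = spec.potential.dimension
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    x = np.array(spec.initial_position, dtype=float)
    stop_enabled = stop is not None
    s_sign = stop.sign if stop_enabled else 1.0
    s_val = stop.threshold if stop_enabled else 0.0
    s_dwell = stop.dwell if stop_enabled else 1

    max_rec = (spec.n_steps // record_stride + 2) if record_stride > 0 else 1
    rec_pos = np.empty((max_rec, dim))
    rec_bias = np.empty(max_rec)
    n_rec_tot = 0
    steps_done = 0
    accel_sum = 0.0
    dwell_state = 0
    stopped = False
    zero = BiasGrid.zero(cv_index)
    while steps_done < spec.n_steps and not stopped:
        n = min(config.deposit_period, spec.n_steps - steps_done)
        noise = rng.standard_normal((n, dim))
        b = bias if bias is not None else zero
        status, nstp, n_rec, a_sum, dwell_state = _kernels.propagate_segment(
            x, pid, pp, spec.kT, spec.friction, spec.dt, noise,
            b.cv_index, bias is not None, b.lo, b.dx, b.values, b.forces,
            beta, _accumulate_accel,
            stop_enabled, s_sign, s_val, s_dwell, dwell_state,
            spec.domain_bound, record_stride,
            rec_pos[n_rec_tot:], rec_bias[n_rec_tot:], steps_done,
        )
        steps_done += nstp
        n_rec_tot += n_rec
        accel_sum += a_sum
        if status == _kernels.STATUS_DIVERGED:
            raise DivergenceError(
                f"trajectory diverged (|x| > {spec.domain_bound}) "
                f"at step {steps_done}")
        stopped = status == _kernels.STATUS_STOPPED
        if use_opes and not stopped and steps_done < spec.n_steps:
            n_before = state.n_kernels
            state.deposit(np.array([x[cv_index]]))
            if state.n_kernels > n_before:
                cache.add_kernel(float(state.centers[-1, 0]),
                                 float(state.weights[-1]),
                                 float(state.sigma[0]), state._norm)
            bias = cache.bias_grid(state, cv_index)
    result = {
        "positions": rec_pos[:n_rec_tot], "bias": rec_bias[:n_rec_tot],
        "record_stride": record_stride, "steps": steps_done,
        "accel_sum": accel_sum, "stopped": stopped, "x": x,
    }
    series = _to_series(spec, result, cv_index)
    series.metadata.update({"gamma": repr(config.gamma),
                            "barrier": repr(config.barrier)})
    if _accumulate_accel:
        return series, state, result
    return series, state


def reweighted_fes(series: ColvarSeries, grid_edges, n_blocks: int,
                   beta: float = 1.0, cv_col: str = "cv",
                   bias_col: str = "opes.bias") -> "FESGrid":
    """Reweighted free-energy surface with block-averaged errors.

    Frames carry weights proportional to exp(beta*V); the weighted CV
    histogram gives F = -(1/beta) log P, min-zeroed.  The error per node
    is the standard error over ``n_blocks`` contiguous-block estimates
    (each block min-zeroed before comparison).
    """
    if bias_col not in series:
        raise ValueError(f"series has no bias column {bias_col!r}")
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    edges = np.asarray(grid_edges, dtype=float)
    cv = series[cv_col]
    v = series[bias_col]
    w = np.exp(beta * (v - v.max()))  # stabilized; constants cancel

    def fes_of(cv_part, w_part):
        hist, _ = np.histogram(cv_part, bins=edges, weights=w_part)
        with np.errstate(divide="ignore"):
            f = -np.log(hist / hist.sum()) / beta
        return f - np.nanmin(f[np.isfinite(f)])

    f_total = fes_of(cv, w)
    blocks_cv = np.array_split(cv, n_blocks)
    blocks_w = np.array_split(w, n_blocks)
    if any(len(b) == 0 for b in blocks_cv):
        raise ValueError("empty block: fewer frames than n_blocks")
    f_blocks = np.vstack([fes_of(c, wb) for c, wb in zip(blocks_cv, blocks_w)])
    finite = np.isfinite(f_blocks)
    n_ok = finite.sum(axis=0)
    masked = np.where(finite, f_blocks, np.nan)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var = np.nanvar(masked, axis=0, ddof=1)
    err = np.where(n_ok > 1, np.sqrt(var / np.maximum(n_ok, 1)), np.inf)
    nodes = 0.5 * (edges[:-1] + edges[1:])
    return FESGrid(grid=nodes, free_energy=f_total, error=err)


@dataclass
class FESGrid:
    """A 1D free-energy curve on a grid, min-zeroed, with per-node errors."""

    grid: np.ndarray
    free_energy: np.ndarray
    error: np.ndarray
    reference: str = "min-zeroed"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        self.error = np.asarray(self.error, dtype=float)
        if len(self.grid) > 1 and not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        finite = np.isfinite(self.free_energy)
        if finite.any():
            self.free_energy = self.free_energy - self.free_energy[finite].min()

    def write(self, path, cv_name: str = "cv") -> None:
        with open(path, "w") as fh:
            fh.write(f"#! FIELDS {cv_name} file.free error\n")
            for g, f, e in zip(self.grid, self.free_energy, self.error):
                fh.write(f"{g:.8e} {f:.8e} {e:.8e}\n")

    @classmethod
    def read(cls, path) -> "FESGrid":
        data = np.loadtxt(path)
        data = np.atleast_2d(data)
        return cls(grid=data[:, 0], free_energy=data[:, 1],
                   error=data[:, 2] if data.shape[1] > 2 else np.zeros(len(data)))
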