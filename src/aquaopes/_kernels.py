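"""Numba inner loops for the overdamped Langevin propagator.

The bias potential changes only when a kernel is deposited, so between
deposits the integrator sees a static bias cached on a 1D grid (value +
force, linear interpolation).  Segments of ``deposit_period`` steps run
inside numba; bookkeeping happens in numpy between segments.

Potential ids: 0 flat, 1 double_well_1d, 2 double_well_2d,
3 binding_funnel_2d.  Parameters are packed into a flat float array.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_DIVERGED = 1
STATUS_STOPPED = 2


@njit(cache=True, inline="always")
def _grad_into(pid, pp, x, g):
    if pid == 0:
        for i in range(x.shape[0]):
            g[i] = 0.0
    elif pid == 1:
        g[0] = 4.0 * pp[0] * x[0] * (x[0] * x[0] - 1.0)
    elif pid == 2:
        g[0] = 4.0 * pp[0] * x[0] * (x[0] * x[0] - 1.0)
        g[1] = pp[1] * x[1]
    elif pid == 3:
        D, a, z_ts, b, B0, c, kq = pp[0], pp[1], pp[2], pp[3], pp[4], pp[5], pp[6]
        z = x[0]
        q = x[1]
        ez = np.exp(-((z / a) ** 2))
        er = np.exp(-(((z - z_ts) / b) ** 2))
        hq = B0 / (1.0 + c * q * q)
        g[0] = 2.0 * D * z / (a * a) * ez - 2.0 * (z - z_ts) / (b * b) * hq * er
        g[1] = kq * q - 2.0 * B0 * c * q / ((1.0 + c * q * q) ** 2) * er


@njit(cache=True, inline="always")
def _interp(grid_lo, grid_dx, values, s):
    n = values.shape[0]
    u = (s - grid_lo) / grid_dx
    if u <= 0.0:
        return values[0]
    if u >= n - 1:
        return values[n - 1]
    i = int(u)
    f = u - i
    return values[i] * (1.0 - f) + values[i + 1] * f


@njit(cache=True)
def propagate_segment(
    x,                 # (dim,) in/out current position
    pid, pp,           # potential id + packed params
    kT, friction, dt,
    noise,             # (n_steps, dim) standard normals
    cv_index,          # coordinate the bias acts on
    use_bias,          # bool
    grid_lo, grid_dx,
    vgrid,             # bias value on grid (shifted: 0 far away, >=0 in basins)
    fgrid,             # bias force (-dV/ds) on grid
    beta,
    accumulate_accel,  # bool: accumulate sum of exp(beta * V_shifted)
    stop_enabled, stop_sign, stop_value, dwell_needed, dwell_state,
    domain_bound,
    record_stride,
    rec_pos,           # (max_rec, dim) output positions
    rec_bias,          # (max_rec,) output instantaneous shifted bias
    step_offset,       # global step index of first step in this segment
):
    """Advance n_steps (len(noise)); returns (status, steps_done, n_rec, accel_sum, dwell)."""
    n_steps = noise.shape[0]
    dim = x.shape[0]
    g = np.empty(dim)
    amp = np.sqrt(2.0 * kT * dt / friction)
    inv_friction_dt = dt / friction
    accel_sum = 0.0
    n_rec = 0
    dwell = dwell_state
    for step in range(n_steps):
        _grad_into(pid, pp, x, g)
        if use_bias:
            s = x[cv_index]
            fb = _interp(grid_lo, grid_dx, fgrid, s)
            g[cv_index] -= fb
        for i in range(dim):
            x[i] += -g[i] * inv_friction_dt + amp * noise[step, i]
        if accumulate_accel:
            v = _interp(grid_lo, grid_dx, vgrid, x[cv_index]) if use_bias else 0.0
            accel_sum += np.exp(beta * v)
        gstep = step_offset + step + 1
        if record_stride > 0 and gstep % record_stride == 0:
            for i in range(dim):
                rec_pos[n_rec, i] = x[i]
            rec_bias[n_rec] = (
                _interp(grid_lo, grid_dx, vgrid, x[cv_index]) if use_bias else 0.0
            )
            n_rec += 1
        for i in range(dim):
            if np.abs(x[i]) > domain_bound:
                return STATUS_DIVERGED, step + 1, n_rec, accel_sum, dwell
        if stop_enabled:
            if stop_sign * x[cv_index] >= stop_sign * stop_value:
                dwell += 1
                if dwell >= dwell_needed:
                    return STATUS_STOPPED, step + 1, n_rec, accel_sum, dwell
            else:
                dwell = 0
    return STATUS_OK, n_steps, n_rec, accel_sum, dwell


@njit(cache=True)
def gaussian_sum(centers, weights, sig, s_eval):
    """Sum_k w_k G(s, s_k) with normalized 1D Gaussians, vector of s."""
    out = np.zeros(s_eval.shape[0])
    norm = 1.0 / (sig * np.sqrt(2.0 * np.pi))
    inv2 = 1.0 / (2.0 * sig * sig)
    for j in range(s_eval.shape[0]):
        acc = 0.0
        for k in range(centers.shape[0]):
            d = s_eval[j] - centers[k]
            acc += weights[k] * np.exp(-d * d * inv2)
        out[j] = acc * norm
    return out
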