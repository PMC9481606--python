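"""Overdamped Langevin dynamics on the model potentials.

Euler–Maruyama update in reduced units:

    x <- x - (dt/friction) * dU/dx + sqrt(2 kT dt / friction) * eta

so the free diffusion constant is D = kT/friction.  Trajectories are
bitwise reproducible for a fixed spec + seed (noise comes from a PCG64
generator in fixed-size chunks, independent of recording options).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .colvar import ColvarSeries
from .potentials import Potential

__all__ = [
    "LangevinSpec", "StopSpec", "BiasGrid", "run_langevin",
    "brute_force_escape_times", "count_well_transitions",
]

_PIDS = {"flat": 0, "double_well_1d": 1, "double_well_2d": 2, "binding_funnel_2d": 3}

_CHUNK = 1 << 18


def _pack(potential: Potential):
    if potential.name not in _PIDS:
        raise ValueError(
            f"integrator supports {sorted(_PIDS)}; got {potential.name!r}")
    pid = _PIDS[potential.name]
    p = potential.params
    if potential.name == "flat":
        pp = np.zeros(1)
    elif potential.name == "double_well_1d":
        pp = np.array([p["h"]])
    elif potential.name == "double_well_2d":
        pp = np.array([p["h"], p["k"]])
    else:
        pp = np.array([p["depth"], p["a"], p["z_ts"], p["b"],
                       p["ridge"], p["coupling"], p["k_q"]])
    return pid, pp


@dataclass(frozen=True)
class LangevinSpec:
    """Everything needed to reproduce one overdamped trajectory."""

    potential: Potential
    kT: float = 1.0
    friction: float = 1.0
    dt: float = 1e-3
    n_steps: int = 100_000
    seed: int = 0
    initial_position: tuple = (0.0,)
    domain_bound: float = 1e3

    def __post_init__(self):
        if self.dt <= 0 or self.kT <= 0 or self.friction <= 0:
            raise ValueError("dt, kT and friction must be positive")
        if len(self.initial_position) != self.potential.dimension:
            raise ValueError("initial_position dimension mismatch")

    def with_(self, **kw) -> "LangevinSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class StopSpec:
    """First-passage criterion on one CV with a commitment dwell.

    The event fires once ``cv (op) threshold`` has held for ``dwell``
    consecutive steps (dwell > 1 suppresses recrossing artifacts).
    """

    threshold: float
    op: str = ">="       # ">=" or "<="
    cv_index: int = 0
    dwell: int = 1

    @property
    def sign(self) -> float:
        if self.op == ">=":
            return 1.0
        if self.op == "<=":
            return -1.0
        raise ValueError("op must be '>=' or '<='")


@dataclass
class BiasGrid:
    """Static 1D bias cache: value and force (-dV/ds) on a uniform grid.

    Values are the *shifted* bias (zero far from all kernels) so that
    exp(beta*V) averages are hyperdynamics acceleration factors.
    """

    lo: float
    dx: float
    values: np.ndarray
    forces: np.ndarray
    cv_index: int = 0

    @classmethod
    def zero(cls, cv_index: int = 0) -> "BiasGrid":
        return cls(0.0, 1.0, np.zeros(2), np.zeros(2), cv_index)


class DivergenceError(RuntimeError):
    pass


def _simulate(spec: LangevinSpec, bias: BiasGrid | None, record_stride: int,
              stop: StopSpec | None = None, beta_accel: float = 0.0,
              accumulate_accel: bool = False):
    """Shared driver; returns dict with trajectory records and counters."""
    pid, pp = _pack(spec.potential)
    dim = spec.potential.dimension
    x = np.array(spec.initial_position, dtype=float)
    rng = np.random.Generator(np.random.PCG64(spec.seed))

    use_bias = bias is not None
    if bias is None:
        bias = BiasGrid.zero()
    stop_enabled = stop is not None
    s_sign = stop.sign if stop_enabled else 1.0
    s_val = stop.threshold if stop_enabled else 0.0
    s_dwell = stop.dwell if stop_enabled else 1

    max_rec = (spec.n_steps // record_stride + 2) if record_stride > 0 else 1
    rec_pos = np.empty((max_rec, dim))
    rec_bias = np.empty(max_rec)
    n_rec_tot = 0
    accel_sum = 0.0
    dwell_state = 0
    steps_done = 0
    status = _kernels.STATUS_OK
    while steps_done < spec.n_steps:
        n = min(_CHUNK, spec.n_steps - steps_done)
        noise = rng.standard_normal((n, dim))
        status, nstp, n_rec, a_sum, dwell_state = _kernels.propagate_segment(
            x, pid, pp, spec.kT, spec.friction, spec.dt, noise,
            bias.cv_index, use_bias, bias.lo, bias.dx, bias.values, bias.forces,
            beta_accel, accumulate_accel,
            stop_enabled, s_sign, s_val, s_dwell, dwell_state,
            spec.domain_bound, record_stride,
            rec_pos[n_rec_tot:], rec_bias[n_rec_tot:], steps_done,
        )
        steps_done += nstp
        n_rec_tot += n_rec
        accel_sum += a_sum
        if status == _kernels.STATUS_DIVERGED:
            raise DivergenceError(
                f"trajectory diverged (|x| > {spec.domain_bound}) at step {steps_done}")
        if status == _kernels.STATUS_STOPPED:
            break
    return {
        "x": x, "steps": steps_done, "stopped": status == _kernels.STATUS_STOPPED,
        "positions": rec_pos[:n_rec_tot], "bias": rec_bias[:n_rec_tot],
        "record_stride": record_stride, "accel_sum": accel_sum,
    }


def _to_series(spec: LangevinSpec, out: dict, cv_index: int) -> ColvarSeries:
    stride = out["record_stride"]
    n = len(out["positions"])
    time = (np.arange(1, n + 1) * stride) * spec.dt
    cols = {}
    for i in range(spec.potential.dimension):
        cols[f"x{i + 1}"] = out["positions"][:, i]
    cols["cv"] = out["positions"][:, cv_index]
    cols["opes.bias"] = out["bias"]
    meta = {"seed": str(spec.seed), "dt": repr(spec.dt), "kT": repr(spec.kT),
            "potential": spec.potential.name}
    return ColvarSeries.from_columns(time, metadata=meta, **cols)


def run_langevin(spec: LangevinSpec, bias: BiasGrid | None = None,
                 cv_index: int = 0, record_stride: int | None = None) -> ColvarSeries:
    """Propagate and record a (possibly statically biased) trajectory.

    Parameters
    ----------
    bias : BiasGrid, optional
        Static external bias acting on coordinate ``bias.cv_index``.
    cv_index : int
        Which coordinate is reported in the ``cv`` column.
    record_stride : int, optional
        Record every this many steps (default keeps ~1e5 frames).
    """
    if record_stride is None:
        record_stride = max(1, spec.n_steps // 100_000)
    out = _simulate(spec, bias, record_stride)
    return _to_series(spec, out, cv_index)


def brute_force_escape_times(spec: LangevinSpec, stop: StopSpec, n_events: int,
                             seed: int, max_steps_per_event: int | None = None
                             ) -> np.ndarray:
    """Independent unbiased first-passage times from the initial basin.

    Each event restarts at ``spec.initial_position`` with a child seed
    derived from ``seed``.  Raises if the per-event step budget is
    exhausted before the event completes.
    """
    if max_steps_per_event is None:
        max_steps_per_event = spec.n_steps
    times = np.empty(n_events)
    children = np.random.SeedSequence(seed).spawn(n_events)
    for i, child in enumerate(children):
        ev_seed = int(child.generate_state(1)[0] % (2**31))
        ev_spec = spec.with_(seed=ev_seed, n_steps=max_steps_per_event)
        out = _simulate(ev_spec, None, record_stride=0, stop=stop)
        if not out["stopped"]:
            raise RuntimeError(
                f"event {i}: step budget {max_steps_per_event} exhausted "
                "before first passage")
        times[i] = out["steps"] * spec.dt
    return times


def count_well_transitions(x: np.ndarray, lower: float = -0.5,
                           upper: float = 0.5) -> int:
    """Count committed well-to-well transitions of a 1D series.

    Uses hysteresis: a transition is counted each time the series reaches
    the opposite threshold after having been beyond the near one.
    """
    x = np.asarray(x)
    state = 0
    count = 0
    for v in x:
        if v <= lower:
            if state == 1:
                count += 1
            state = -1
        elif v >= upper:
            if state == -1:
                count += 1
            state = 1
    return count
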