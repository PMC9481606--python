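"""Analytic model potentials for exercising the sampling machinery.

These are reduced-unit toy landscapes (energies in kT by default) with
closed-form energies and gradients.  They stand in for the molecular
interaction potential when testing bias construction, rate estimation and
free-energy reconstruction at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize

__all__ = ["Potential", "make_potential", "barrier_height"]


@dataclass(frozen=True)
class Potential:
    """A named analytic potential with closed-form energy and gradient.

    Attributes
    ----------
    name : str
        Identifier of the functional form.
    params : dict
        Named real parameters of the form.
    dimension : int
        Number of coordinates.
    """

    name: str
    params: dict
    dimension: int
    _energy: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    _gradient: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def energy(self, x) -> np.ndarray:
        """Potential energy at ``x`` (last axis = coordinates for dim > 1)."""
        return self._energy(np.asarray(x, dtype=float))

    def gradient(self, x) -> np.ndarray:
        """Analytic gradient dU/dx at ``x``."""
        return self._gradient(np.asarray(x, dtype=float))


def _double_well_1d(params):
    h = float(params.get("h", 5.0))
    if not np.isfinite(h) or h <= 0:
        raise ValueError(f"double_well_1d requires finite h > 0, got {h}")

    def energy(x):
        return h * (x * x - 1.0) ** 2

    def grad(x):
        return 4.0 * h * x * (x * x - 1.0)

    return energy, grad, 1, {"h": h}


def _double_well_2d(params):
    h = float(params.get("h", 5.0))
    k = float(params.get("k", 2.0))
    if not (np.isfinite(h) and np.isfinite(k)) or h <= 0 or k <= 0:
        raise ValueError("double_well_2d requires finite h > 0 and k > 0")

    def energy(x):
        x = np.atleast_1d(x)
        return h * (x[..., 0] ** 2 - 1.0) ** 2 + 0.5 * k * x[..., 1] ** 2

    def grad(x):
        x = np.atleast_1d(x)
        g = np.empty_like(x)
        g[..., 0] = 4.0 * h * x[..., 0] * (x[..., 0] ** 2 - 1.0)
        g[..., 1] = k * x[..., 1]
        return g

    return energy, grad, 2, {"h": h, "k": k}


def _binding_funnel_2d(params):
    # Bound well at z=0 (depth D); exit barrier ridge at z=z_ts whose height is
    # lowered by displacing the gating coordinate q (a solvation-like mode with
    # harmonic stiffness k_q).  Escape requires both crossing the ridge in z and
    # paying part of the gating cost — the saddle sits at q != 0.
    p = {
        "depth": float(params.get("depth", 6.0)),
        "a": float(params.get("a", 1.5)),
        "z_ts": float(params.get("z_ts", 3.0)),
        "b": float(params.get("b", 0.8)),
        "ridge": float(params.get("ridge", 4.0)),
        "coupling": float(params.get("coupling", 2.0)),
        "k_q": float(params.get("k_q", 1.0)),
    }
    for key, v in p.items():
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"binding_funnel_2d parameter {key} must be finite and > 0")
    D, a, z_ts, b, B0, c, kq = (
        p["depth"], p["a"], p["z_ts"], p["b"], p["ridge"], p["coupling"], p["k_q"],
    )

    def ridge_height(q):
        return B0 / (1.0 + c * q * q)

    def energy(x):
        x = np.atleast_1d(x)
        z, q = x[..., 0], x[..., 1]
        well = -D * np.exp(-((z / a) ** 2))
        ridge = ridge_height(q) * np.exp(-(((z - z_ts) / b) ** 2))
        gate = 0.5 * kq * q * q
        return well + ridge + gate

    def grad(x):
        x = np.atleast_1d(x)
        z, q = x[..., 0], x[..., 1]
        g = np.empty_like(x)
        ez = np.exp(-((z / a) ** 2))
        er = np.exp(-(((z - z_ts) / b) ** 2))
        hq = B0 / (1.0 + c * q * q)
        g[..., 0] = 2.0 * D * z / a**2 * ez - 2.0 * (z - z_ts) / b**2 * hq * er
        g[..., 1] = kq * q - 2.0 * B0 * c * q / (1.0 + c * q * q) ** 2 * er
        return g

    return energy, grad, 2, p


def _flat(params):
    dim = int(params.get("dimension", 1))
    if dim < 1:
        raise ValueError("flat potential needs dimension >= 1")

    def energy(x):
        x = np.atleast_1d(x)
        return np.zeros(x.shape[:-1]) if x.ndim > 1 else np.zeros(()) + 0.0

    def grad(x):
        return np.zeros_like(np.atleast_1d(x))

    return energy, grad, dim, {"dimension": dim}


_FORMS = {
    "flat": _flat,
    "double_well_1d": _double_well_1d,
    "double_well_2d": _double_well_2d,
    "binding_funnel_2d": _binding_funnel_2d,
}


def make_potential(name: str, params: dict | None = None) -> Potential:
    """Build one of the shipped analytic potentials.

    Parameters
    ----------
    name : {"double_well_1d", "double_well_2d", "binding_funnel_2d"}
    params : dict, optional
        Form parameters; missing entries take documented defaults.
        ``double_well_1d``: U(x) = h (x^2 - 1)^2.
        ``double_well_2d``: the 1d form plus a harmonic transverse mode.
        ``binding_funnel_2d``: an exit coordinate z coupled to a gating
        coordinate q such that escape requires both.
    """
    if name not in _FORMS:
        raise ValueError(f"unknown potential {name!r}; choose from {sorted(_FORMS)}")
    energy, grad, dim, resolved = _FORMS[name](params or {})
    return Potential(name=name, params=resolved, dimension=dim,
                     _energy=energy, _gradient=grad)


def barrier_height(potential: Potential, x_min, x_saddle_guess) -> float:
    """Barrier height from a local minimum to the saddle nearest a guess.

    The saddle is located by a root search on the gradient (Newton–Krylov via
    ``scipy.optimize.root``) started from ``x_saddle_guess``; the barrier is
    U(saddle) - U(minimum).  For 1d potentials pass scalars.
    """
    x_min = np.atleast_1d(np.asarray(x_min, dtype=float))
    guess = np.atleast_1d(np.asarray(x_saddle_guess, dtype=float))
    if potential.dimension == 1:
        sol = optimize.root_scalar(
            lambda x: float(potential.gradient(np.array([x]))[0]),
            x0=float(guess[0]), x1=float(guess[0]) + 1e-3, method="secant",
        )
        if not sol.converged:
            raise RuntimeError("saddle search did not converge")
        saddle = np.array([sol.root])
    else:
        sol = optimize.root(lambda x: potential.gradient(x), guess, method="hybr")
        if not sol.success:
            raise RuntimeError(f"saddle search did not converge: {sol.message}")
        saddle = sol.x
    return float(potential.energy(saddle) - potential.energy(x_min))
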