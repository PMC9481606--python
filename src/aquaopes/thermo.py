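"""Funnel restraint geometry and binding thermodynamics.

A funnel restraint confines the unbound ligand to a cone that narrows
into a cylinder of radius R_cyl along the exit axis, making the unbound
volume finite.  The absolute binding free energy then needs the
standard-state correction

    dF = -(1/beta) * log( C0 * pi * R_cyl^2 *
                          int_B dz exp(-beta (W(z) - W_U)) )

with C0 = 1/1660 A^-3 the standard concentration, W(z) the free energy
along the funnel axis and W_U its unbound-plateau reference.  Enthalpy
and entropy follow from free energies converged at several temperatures
through dF(T) = dU - T dS (weighted linear fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .opes import FESGrid

__all__ = [
    "C0_STANDARD", "FunnelGeometry", "ThermoResult",
    "funnel_wall_energy", "funnel_correction", "thermo_decomposition",
]

C0_STANDARD = 1.0 / 1660.0   # standard concentration, A^-3


@dataclass
class FunnelGeometry:
    """Cone-into-cylinder restraint around the exit axis.

    The allowed radius is r_max(z) = R_cyl + cone_slope * (z_switch - z)
    for z < z_switch (the widening cone toward the binding site) and
    R_cyl beyond; continuous at z_switch by construction.
    """

    axis: tuple = (0.0, 0.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    z_switch: float = 10.0
    R_cyl: float = 1.0
    cone_slope: float = 0.8
    wall_k: float = 10.0

    def __post_init__(self):
        if self.R_cyl <= 0 or self.wall_k < 0 or self.cone_slope < 0:
            raise ValueError("R_cyl must be > 0; slopes/stiffness non-negative")
        a = np.asarray(self.axis, dtype=float)
        self.axis = tuple(a / np.linalg.norm(a))

    def r_max(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return self.R_cyl + self.cone_slope * np.clip(self.z_switch - z, 0.0, None)


def funnel_wall_energy(position, geom: FunnelGeometry,
                       with_gradient: bool = False):
    """Half-harmonic wall: 0 inside the funnel, (k/2)(r - r_max)^2 outside.

    Continuous and once-differentiable across the funnel surface.
    """
    p = np.atleast_2d(np.asarray(position, dtype=float))
    axis = np.asarray(geom.axis)
    rel = p - np.asarray(geom.origin, dtype=float)
    z = rel @ axis
    radial = rel - z[:, None] * axis
    r = np.linalg.norm(radial, axis=1)
    over = r - geom.r_max(z)
    outside = over > 0
    e = np.where(outside, 0.5 * geom.wall_k * over**2, 0.0)
    e_out = e if p.shape[0] > 1 else float(e[0])
    if not with_gradient:
        return e_out
    g = np.zeros_like(p)
    if np.any(outside):
        with np.errstate(invalid="ignore", divide="ignore"):
            rhat = np.where(r[:, None] > 0, radial / np.maximum(r, 1e-300)[:, None], 0.0)
        in_cone = z < geom.z_switch
        # d r_max/dz = -cone_slope in the cone, 0 in the cylinder
        drmax = np.where(in_cone, -geom.cone_slope, 0.0)
        coeff = geom.wall_k * over
        g_rad = coeff[:, None] * rhat
        g_z = coeff * (-drmax)
        g = np.where(outside[:, None], g_rad + g_z[:, None] * axis, 0.0)
    return e_out, (g if p.shape[0] > 1 else g[0])


def funnel_correction(fes_1d: FESGrid, R_cyl: float, beta: float,
                      bound_region: tuple, unbound_reference: tuple) -> float:
    """Standard-state binding free energy from the funnel-axis profile.

    Integrates exp(-beta (W(z) - W_U)) over the bound interval by the
    trapezoid rule, multiplies by the cylinder cross-section and the
    standard concentration, and returns dF with the convention that a
    stable binder has dF > 0 (an unbinding cost).  W_U is the mean of
    W(z) over the unbound reference interval.
    """
    if R_cyl <= 0 or beta <= 0:
        raise ValueError("R_cyl and beta must be positive")
    z = fes_1d.grid
    W = fes_1d.free_energy
    for name, (lo, hi) in (("bound_region", bound_region),
                           ("unbound_reference", unbound_reference)):
        if lo >= hi:
            raise ValueError(f"{name} must be an increasing interval")
        if lo < z[0] - 1e-9 or hi > z[-1] + 1e-9:
            raise ValueError(f"{name} {lo, hi} outside the FES grid")
    u_mask = (z >= unbound_reference[0]) & (z <= unbound_reference[1])
    if not u_mask.any() or not np.all(np.isfinite(W[u_mask])):
        raise ValueError("unbound reference interval has no finite W values")
    W_U = float(W[u_mask].mean())
    b_mask = (z >= bound_region[0]) & (z <= bound_region[1])
    if b_mask.sum() < 2:
        raise ValueError("bound region covers fewer than 2 grid nodes")
    if not np.all(np.isfinite(W[b_mask])):
        raise ValueError("non-finite W inside the bound region")
    integrand = np.exp(-beta * (W[b_mask] - W_U))
    integral = np.trapezoid(integrand, z[b_mask])
    dF_unbind = (1.0 / beta) * np.log(C0_STANDARD * np.pi * R_cyl**2 * integral)
    return float(dF_unbind)


@dataclass
class ThermoResult:
    """dF = dU - T dS decomposition at a reference temperature."""

    dF: float
    dU: float
    minus_TdS: float
    dF_err: float
    dU_err: float
    minus_TdS_err: float
    reference_T: float
    temperatures: np.ndarray


def thermo_decomposition(dF_by_T, reference_T: float | None = None
                         ) -> ThermoResult:
    """Weighted linear fit dF(T) = dU - T*dS over >= 2 temperatures.

    ``dF_by_T`` is a list of (T, dF, sigma) triples; sigma may be 0 for
    an exact (unweighted) two-point fit but must not be negative.
    Uncertainties come from the fit covariance (unscaled, i.e. taken at
    face value from the supplied sigmas).
    """
    arr = np.asarray(dF_by_T, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected (T, dF, sigma) triples")
    T, dF, sig = arr.T
    if len(np.unique(T)) < 2:
        raise ValueError("need at least two distinct temperatures")
    if np.any(sig < 0):
        raise ValueError("sigmas must be non-negative")
    if reference_T is None:
        reference_T = float(np.mean(T))
    A = np.c_[np.ones_like(T), -T]          # dF = dU - T dS
    if np.all(sig > 0):
        Aw = A / sig[:, None]
        yw = dF / sig
        coef, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
        cov = np.linalg.inv(Aw.T @ Aw)
    else:
        coef, *_ = np.linalg.lstsq(A, dF, rcond=None)
        cov = np.zeros((2, 2))
    dU, dS = coef
    var_dU = cov[0, 0]
    var_dS = cov[1, 1]
    cov_US = cov[0, 1]
    minus_TdS = -reference_T * dS
    dF_ref = dU + minus_TdS
    var_dF = (var_dU + reference_T**2 * var_dS - 2 * reference_T * cov_US)
    return ThermoResult(
        dF=float(dF_ref), dU=float(dU), minus_TdS=float(minus_TdS),
        dF_err=float(np.sqrt(max(var_dF, 0.0))),
        dU_err=float(np.sqrt(max(var_dU, 0.0))),
        minus_TdS_err=float(reference_T * np.sqrt(max(var_dS, 0.0))),
        reference_T=reference_T, temperatures=T.copy())
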