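"""Seeded synthetic data: two-state descriptor clouds and water scenes.

These generators define the study conditions for desk-scale validation:

* ``synth_two_state_descriptors`` emulates unbiased bound/unbound
  simulations feeding discriminant-CV training — two labelled Gaussian
  clouds, 18 descriptor components by default;

* ``synth_water_scene`` emulates a protein-enclosed hydration analysis:
  a convex protein-like envelope of anchor atoms, a handful of planted
  long-lived "reservoir" waters jittering around fixed interior spots,
  and bulk waters random-walking outside with only brief incursions.
  Water exchange is modelled by identity swaps (a planted occupant trades
  places with an outside bulk walker at the end of its lifetime) — only
  the residence bookkeeping matters downstream, not diffusion pathways.

All outputs are bitwise reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hydration import build_hull

__all__ = [
    "SyntheticWaterScene", "default_anchor_shell", "default_planted_spots",
    "synth_two_state_descriptors", "synth_water_scene",
]


def synth_two_state_descriptors(n_per_state: int = 5000, mean_B=None,
                                mean_U=None, cov_B=None, cov_U=None,
                                seed: int = 0, dimension: int = 18
                                ) -> pd.DataFrame:
    """Two labelled Gaussian descriptor clouds (states ``B`` and ``U``).

    Defaults: 18 components; the states differ by a unit shift on the
    first three components (solvation-like contrast) with identity
    covariances.  Covariances must be symmetric positive-definite.
    Returns a DataFrame with columns d1..dN and ``state``.
    """
    if mean_B is None:
        mean_B = np.zeros(dimension)
    if mean_U is None:
        mean_U = np.zeros(dimension)
        mean_U[:3] = 1.0
    mean_B = np.asarray(mean_B, dtype=float)
    mean_U = np.asarray(mean_U, dtype=float)
    if mean_B.shape != mean_U.shape:
        raise ValueError("state means must have equal dimension")
    d = len(mean_B)
    cov_B = np.eye(d) if cov_B is None else np.asarray(cov_B, dtype=float)
    cov_U = np.eye(d) if cov_U is None else np.asarray(cov_U, dtype=float)
    for name, cov in (("cov_B", cov_B), ("cov_U", cov_U)):
        if cov.shape != (d, d) or not np.allclose(cov, cov.T):
            raise ValueError(f"{name} must be symmetric ({d},{d})")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise ValueError(f"{name} is not positive-definite")
    rng = np.random.Generator(np.random.PCG64(seed))
    X_B = rng.multivariate_normal(mean_B, cov_B, size=n_per_state,
                                  method="cholesky")
    X_U = rng.multivariate_normal(mean_U, cov_U, size=n_per_state,
                                  method="cholesky")
    cols = [f"d{i + 1}" for i in range(d)]
    frame = pd.DataFrame(np.vstack([X_B, X_U]), columns=cols)
    frame["state"] = ["B"] * n_per_state + ["U"] * n_per_state
    return frame


# --------------------------------------------------------------------------
# water scenes
# --------------------------------------------------------------------------

def default_anchor_shell(n_points: int = 40, radius: float = 12.0,
                         center=(15.0, 15.0, 15.0)) -> np.ndarray:
    """Anchor atoms on a Fibonacci sphere: a convex protein-like envelope."""
    i = np.arange(n_points)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(1.0 - z * z)
    pts = np.c_[r * np.cos(phi), r * np.sin(phi), z] * radius
    return pts + np.asarray(center, dtype=float)


def default_planted_spots(center=(15.0, 15.0, 15.0), spacing: float = 4.5
                          ) -> np.ndarray:
    """Five interior spots with mutual distances >= ``spacing``."""
    c = np.asarray(center, dtype=float)
    offsets = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0],
                        [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]) * spacing
    return c + offsets


@dataclass
class SyntheticWaterScene:
    """Planted-truth hydration scene.

    With the defaults (5 spots, 500 ps lifetimes, 2 ps frames, 580 ps of
    trajectory, bulk incursions capped at 40 ps) exactly the five planted
    occupants survive a 100 ps residence filter: each spot's first
    occupant stays 500 ps, its post-swap successor only 80 ps, and no
    bulk walker can accumulate more than 40 ps inside.
    """

    anchor_points: np.ndarray = field(default_factory=default_anchor_shell)
    planted_spots: np.ndarray = field(default_factory=default_planted_spots)
    spot_lifetimes: np.ndarray | float = 500.0          # ps
    n_bulk_waters: int = 40
    box: tuple = (30.0, 30.0, 30.0)                     # Angstrom
    frame_interval: float = 2.0                         # ps
    n_frames: int = 291
    seed: int = 0
    jitter_sigma: float = 0.5                           # Angstrom
    bulk_step_sigma: float = 1.0                        # Angstrom / frame
    max_bulk_incursion: float = 40.0                    # ps
    lifetime_threshold: float = 100.0                   # ps, filter to beat

    def __post_init__(self):
        self.anchor_points = np.asarray(self.anchor_points, dtype=float)
        self.planted_spots = np.atleast_2d(np.asarray(self.planted_spots,
                                                      dtype=float))
        if np.isscalar(self.spot_lifetimes):
            self.spot_lifetimes = np.full(len(self.planted_spots),
                                          float(self.spot_lifetimes))
        else:
            self.spot_lifetimes = np.asarray(self.spot_lifetimes, dtype=float)
        if len(self.spot_lifetimes) != len(self.planted_spots):
            raise ValueError("one lifetime per planted spot required")
        hull = build_hull(self.anchor_points)
        # spots must sit inside with enough margin that jitter stays inside
        margin = 5.0 * self.jitter_sigma
        a, b = hull.facets[:, :3], hull.facets[:, 3]
        depth = -(self.planted_spots @ a.T + b)     # distance inward per facet
        if np.any(depth.min(axis=1) < margin):
            raise ValueError("planted spot outside hull (or too close to it)")
        if np.any(self.spot_lifetimes <= self.lifetime_threshold):
            raise ValueError("planted lifetimes must exceed the filter threshold")
        self.hull = hull

    @property
    def n_waters(self) -> int:
        return len(self.planted_spots) + self.n_bulk_waters


def _random_outside(rng, hull, box, n=1):
    """Rejection-sample points in the box but outside the hull."""
    out = np.empty((n, 3))
    box = np.asarray(box, dtype=float)
    filled = 0
    while filled < n:
        cand = rng.uniform(0.0, 1.0, size=(4 * (n - filled), 3)) * box
        keep = cand[~hull.contains(cand)]
        take = min(len(keep), n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def synth_water_scene(scene: SyntheticWaterScene
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Generate (water_traj, anchor_points).

    ``water_traj`` has shape (n_frames, n_waters, 3); water identities
    are the second-axis indices and persist across frames.  The first
    ``len(planted_spots)`` identities start as the spot occupants.
    """
    rng = np.random.Generator(np.random.PCG64(scene.seed))
    n_spots = len(scene.planted_spots)
    n_w = scene.n_waters
    hull = scene.hull
    box = np.asarray(scene.box, dtype=float)

    # which water identity currently occupies each spot
    occupant = np.arange(n_spots)
    swap_frame = np.rint(scene.spot_lifetimes / scene.frame_interval).astype(int)
    next_swap = swap_frame.copy()

    pos = np.empty((n_w, 3))
    pos[n_spots:] = _random_outside(rng, hull, box, scene.n_bulk_waters)
    inside_run = np.zeros(n_w, dtype=int)   # consecutive inside frames (bulk)
    cap_frames = int(scene.max_bulk_incursion / scene.frame_interval)

    traj = np.empty((scene.n_frames, n_w, 3))
    is_occupant = np.zeros(n_w, dtype=bool)
    is_occupant[occupant] = True
    for f in range(scene.n_frames):
        # spot occupants jitter around their centers (clipped: never exit)
        for s in range(n_spots):
            if f == next_swap[s]:
                # swap identity with a bulk walker currently outside
                outside = np.flatnonzero(~is_occupant & ~hull.contains(pos))
                j = rng.choice(outside)
                i = occupant[s]
                pos[[i, j]] = pos[[j, i]]
                is_occupant[i] = False
                is_occupant[j] = True
                occupant[s] = j
                inside_run[i] = 0
                next_swap[s] += swap_frame[s]
            jit = rng.normal(0.0, scene.jitter_sigma, 3)
            nrm = np.linalg.norm(jit)
            lim = 4.0 * scene.jitter_sigma
            if nrm > lim:
                jit *= lim / nrm
            pos[occupant[s]] = scene.planted_spots[s] + jit
        # bulk walkers
        bulk = np.flatnonzero(~is_occupant)
        steps = rng.normal(0.0, scene.bulk_step_sigma, (len(bulk), 3))
        cand = pos[bulk] + steps
        cand = np.clip(cand, 0.0, box)       # reflective-ish wall
        pos[bulk] = cand
        inside_now = hull.contains(pos[bulk])
        inside_run[bulk] = np.where(inside_now, inside_run[bulk] + 1, 0)
        # enforce the incursion cap: long-dwelling bulk waters are expelled
        too_long = bulk[inside_run[bulk] >= cap_frames]
        if len(too_long):
            pos[too_long] = _random_outside(rng, hull, box, len(too_long))
            inside_run[too_long] = 0
        traj[f] = pos
    return traj, scene.anchor_points.copy()
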