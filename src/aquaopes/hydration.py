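"""Trapped-water analysis: hull containment, residence filtering,
hydration-spot clustering and coordination-number descriptors.

The four-step procedure for locating long-lived water density inside a
protein-enclosed region:

1. select anchor atoms (typically alpha-carbons) that enclose the region;
2. build their convex hull;
3. keep the positions of waters that stay inside the hull for longer than
   a lifetime threshold (default 100 ps), interval by interval;
4. K-means-cluster the pooled positions into hydration spots, choosing k
   so that neighbouring centers sit 2-3 Angstrom apart.

Around each spot (and around ligand/site anchor atoms) water coordination
numbers are evaluated with a rational switching function, giving the
descriptor vector d = [G, H, V_1..V_k] used to train water CVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull
from sklearn.cluster import KMeans

__all__ = [
    "HullRegion", "ResidenceRecord", "HydrationSpotSet", "DescriptorSpec",
    "build_hull", "track_residences", "cluster_spots", "coordination",
    "descriptor_vector", "HydrationSpotFinder",
]


@dataclass
class HullRegion:
    """Convex hull over anchor points with a closed containment test."""

    anchor_points: np.ndarray
    hull: ConvexHull = field(repr=False)

    @property
    def volume(self) -> float:
        return float(self.hull.volume)

    @property
    def facets(self) -> np.ndarray:
        """Facet half-space rows [a, b, c, d]: inside iff a*x+b*y+c*z+d <= 0."""
        return self.hull.equations

    def contains(self, points, tol: float = 1e-9) -> np.ndarray:
        """Closed containment (boundary counts as inside); vectorized."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        a = self.hull.equations[:, :3]
        b = self.hull.equations[:, 3]
        return np.all(pts @ a.T + b <= tol, axis=1)


def build_hull(anchor_points) -> HullRegion:
    """Convex hull of the anchor atoms (>= 4 points, not coplanar)."""
    pts = np.asarray(anchor_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("need >= 4 three-dimensional anchor points")
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # qhull reports degenerate input
        raise ValueError(f"degenerate anchor set (coplanar/collinear?): {exc}")
    return HullRegion(anchor_points=pts, hull=hull)


@dataclass
class ResidenceRecord:
    """One contiguous inside-the-hull interval of one water molecule."""

    water_id: int
    entry_frame: int
    exit_frame: int            # first frame outside (half-open interval)
    duration: float            # ps, = (exit - entry) * frame_interval
    positions: np.ndarray      # (n_frames_inside, 3), the inside positions


def track_residences(water_positions: np.ndarray, hull: HullRegion,
                     lifetime_threshold: float, frame_interval: float
                     ) -> tuple[list[ResidenceRecord], np.ndarray]:
    """Residence intervals inside the hull, filtered by lifetime.

    Parameters
    ----------
    water_positions : (n_frames, n_waters, 3) array
        Water (oxygen) positions with persistent identities across frames.
    lifetime_threshold : float
        Keep intervals strictly longer than this many ps.
    frame_interval : float
        Time between frames, ps.

    Returns (records, pooled_positions): the retained intervals and the
    union of their stored positions.  A single-frame exit splits an
    interval in two; each piece is tested separately.
    """
    traj = np.asarray(water_positions, dtype=float)
    if traj.ndim != 3 or traj.shape[0] == 0:
        raise ValueError("need a (n_frames, n_waters, 3) trajectory with >= 1 frame")
    if frame_interval <= 0:
        raise ValueError("frame interval must be positive (and known)")
    n_frames, n_waters, _ = traj.shape
    inside = np.empty((n_frames, n_waters), dtype=bool)
    for f in range(n_frames):
        inside[f] = hull.contains(traj[f])
    records: list[ResidenceRecord] = []
    for w in range(n_waters):
        col = inside[:, w]
        # contiguous True runs as half-open [entry, exit)
        padded = np.concatenate([[False], col, [False]])
        d = np.diff(padded.astype(np.int8))
        entries = np.flatnonzero(d == 1)
        exits = np.flatnonzero(d == -1)
        for e, x in zip(entries, exits):
            duration = (x - e) * frame_interval
            if duration > lifetime_threshold:
                records.append(ResidenceRecord(
                    water_id=w, entry_frame=int(e), exit_frame=int(x),
                    duration=float(duration), positions=traj[e:x, w]))
    pooled = (np.vstack([r.positions for r in records])
              if records else np.empty((0, 3)))
    return records, pooled


@dataclass
class HydrationSpotSet:
    """Cluster centers of long-lived water density with spacing metadata."""

    centers: np.ndarray
    member_counts: np.ndarray
    min_pair_distance: float
    max_nearest_neighbor_distance: float

    @property
    def k(self) -> int:
        return len(self.centers)

    def to_dict(self) -> dict:
        return {"k": self.k, "centers": self.centers.tolist(),
                "member_counts": self.member_counts.tolist(),
                "min_pair_distance": self.min_pair_distance,
                "max_nearest_neighbor_distance": self.max_nearest_neighbor_distance}


def _spacing_stats(centers: np.ndarray) -> tuple[float, float]:
    if len(centers) < 2:
        return float("inf"), float("inf")
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(d.min()), float(d.min(axis=1).max())


def _kmeans(points, k, seed, n_restarts):
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(points)
    counts = np.bincount(labels, minlength=k)
    return km.cluster_centers_, counts


def cluster_spots(pooled_positions, k="auto", spacing_band=(2.0, 3.0),
                  seed: int = 0, n_restarts: int = 10,
                  max_k: int = 40) -> HydrationSpotSet:
    """K-means hydration spots from pooled long-lived water positions.

    With ``k="auto"`` the center count is swept upward from 1 and the
    largest k whose minimum inter-center distance stays >= the lower
    spacing bound is kept (the achieved spacing statistics are reported;
    the upper bound is a goal, not a guarantee).
    """
    pts = np.asarray(pooled_positions, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise ValueError("pooled_positions must be a non-empty (n, 3) array")
    if k == "auto":
        lo = spacing_band[0]
        best = None
        for kk in range(1, min(max_k, len(pts)) + 1):
            centers, counts = _kmeans(pts, kk, seed, n_restarts)
            min_pair, _ = _spacing_stats(centers)
            if min_pair >= lo:
                best = (centers, counts)
            else:
                break
        if best is None:
            raise ValueError("no clustering satisfies the spacing band")
        centers, counts = best
    else:
        k = int(k)
        if k < 1 or len(pts) < k:
            raise ValueError(f"need at least k={k} points, got {len(pts)}")
        centers, counts = _kmeans(pts, k, seed, n_restarts)
    order = np.lexsort(centers.T)  # deterministic center ordering
    centers, counts = centers[order], counts[order]
    min_pair, max_nn = _spacing_stats(centers)
    return HydrationSpotSet(centers=centers, member_counts=counts,
                            min_pair_distance=min_pair,
                            max_nearest_neighbor_distance=max_nn)


class HydrationSpotFinder:
    """Estimator-style wrapper: fit on a water trajectory, expose spots.

    Parameters mirror :func:`track_residences` and :func:`cluster_spots`.
    Fitted attributes carry trailing underscores (``spots_``,
    ``records_``, ``pooled_positions_``).
    """

    def __init__(self, lifetime_threshold: float = 100.0,
                 frame_interval: float = 1.0, k="auto",
                 spacing_band=(2.0, 3.0), seed: int = 0, n_restarts: int = 10):
        self.lifetime_threshold = lifetime_threshold
        self.frame_interval = frame_interval
        self.k = k
        self.spacing_band = spacing_band
        self.seed = seed
        self.n_restarts = n_restarts

    def get_params(self, deep: bool = True) -> dict:
        return {"lifetime_threshold": self.lifetime_threshold,
                "frame_interval": self.frame_interval, "k": self.k,
                "spacing_band": self.spacing_band, "seed": self.seed,
                "n_restarts": self.n_restarts}

    def set_params(self, **params) -> "HydrationSpotFinder":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, water_positions, anchor_points) -> "HydrationSpotFinder":
        self.hull_ = build_hull(anchor_points)
        self.records_, self.pooled_positions_ = track_residences(
            water_positions, self.hull_, self.lifetime_threshold,
            self.frame_interval)
        self.spots_ = cluster_spots(self.pooled_positions_, k=self.k,
                                    spacing_band=self.spacing_band,
                                    seed=self.seed, n_restarts=self.n_restarts)
        return self

    def transform(self, water_positions, r0: float = 3.5, n: int = 6,
                  m: int = 12) -> np.ndarray:
        """Per-frame spot coordination numbers (n_frames, k)."""
        traj = np.asarray(water_positions, dtype=float)
        out = np.empty((traj.shape[0], self.spots_.k))
        for f in range(traj.shape[0]):
            for j, c in enumerate(self.spots_.centers):
                out[f, j] = coordination(c, traj[f], r0, n, m)
        return out


def coordination(center, oxygen_positions, r0: float = 3.5,
                 n: int = 6, m: int = 12) -> float:
    """Smooth water coordination with the rational switching function.

    sum_j (1 - (r_j/r0)^n) / (1 - (r_j/r0)^m); the removable singularity
    at r_j = r0 takes its limit n/m.  An empty oxygen list gives 0.
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    if n >= m:
        raise ValueError("switching exponents require n < m")
    pos = np.atleast_2d(np.asarray(oxygen_positions, dtype=float))
    if pos.size == 0:
        return 0.0
    r = np.linalg.norm(pos - np.asarray(center, dtype=float), axis=1)
    x = r / r0
    xn, xm = x**n, x**m
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (1.0 - xn) / (1.0 - xm)
    s = np.where(np.abs(1.0 - xm) < 1e-12, n / m, s)
    return float(np.sum(s))


@dataclass
class DescriptorSpec:
    """What goes into the water descriptor vector d = [G, H, V_1..V_k].

    ``ligand_atom`` / ``site_atom`` are selectors resolving to exactly one
    atom each (the amidine-carbon and site-carboxylate-carbon analogues);
    the spots supply the V centers.
    """

    ligand_atom: str
    site_atom: str
    spots: HydrationSpotSet
    r0: float = 3.5
    n: int = 6
    m: int = 12

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.n >= self.m:
            raise ValueError("switching exponents require n < m")

    @property
    def length(self) -> int:
        return 2 + self.spots.k


def descriptor_vector(frame_waters, spec: DescriptorSpec,
                      atom_lookup) -> np.ndarray:
    """Evaluate d = [G, H, V_1..V_k] on one frame.

    ``atom_lookup`` maps a selector string to a single (3,) position
    (e.g. built from a structure file); ambiguous or missing selectors
    must raise there.  ``frame_waters`` are the water oxygen positions of
    the frame; the vector is invariant under their permutation.
    """
    lig = np.asarray(atom_lookup(spec.ligand_atom), dtype=float)
    site = np.asarray(atom_lookup(spec.site_atom), dtype=float)
    if lig.shape != (3,) or site.shape != (3,):
        raise ValueError("selectors must resolve to exactly one atom each")
    d = np.empty(spec.length)
    d[0] = coordination(lig, frame_waters, spec.r0, spec.n, spec.m)
    d[1] = coordination(site, frame_waters, spec.r0, spec.n, spec.m)
    for j, c in enumerate(spec.spots.centers):
        d[2 + j] = coordination(c, frame_waters, spec.r0, spec.n, spec.m)
    return d
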