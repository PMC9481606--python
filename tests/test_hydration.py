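import numpy as np
import pytest

from aquaopes import (HydrationSpotFinder, build_hull, cluster_spots,
                      coordination, descriptor_vector, track_residences)
from aquaopes.hydration import DescriptorSpec


def halfspace_oracle(anchor_points, points):
    """Brute-force containment: a point is inside the convex hull iff it
    cannot be separated from the anchors — checked via scipy linprog-free
    half-space construction from all facet triplets is overkill; instead
    use the definition through convex combinations (linear program)."""
    from scipy.optimize import linprog
    out = []
    A_eq = np.vstack([anchor_points.T, np.ones(len(anchor_points))])
    for p in points:
        b_eq = np.r_[p, 1.0]
        res = linprog(np.zeros(len(anchor_points)), A_eq=A_eq, b_eq=b_eq,
                      bounds=(0, None), method="highs")
        out.append(res.success)
    return np.array(out)


class TestHull:
    def test_unit_tetrahedron_volume(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        hull = build_hull(pts)
        assert hull.volume == pytest.approx(1 / 6)

    def test_centroid_inside_and_boundary_closed(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 3, (20, 3))
        hull = build_hull(pts)
        assert hull.contains(pts.mean(axis=0))[0]
        # anchor points themselves lie on the boundary -> inside (closed)
        assert hull.contains(pts, tol=1e-7).all()

    def test_containment_agrees_with_convex_combination_oracle(self):
        rng = np.random.default_rng(1)
        anchors = rng.normal(0, 3, (15, 3))
        hull = build_hull(anchors)
        pts = rng.uniform(-5, 5, (1000, 3))
        mine = hull.contains(pts)
        oracle = halfspace_oracle(anchors, pts)
        assert np.array_equal(mine, oracle)

    def test_degenerate_input_rejected(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="degenerate"):
            build_hull(flat)
        with pytest.raises(ValueError, match=">= 4"):
            build_hull(flat[:3])


class TestTrackResidences:
    def test_planted_scene_counts(self, planted_scene):
        scene, traj, anchors = planted_scene
        hull = build_hull(anchors)
        recs, pooled = track_residences(traj, hull, 100.0, scene.frame_interval)
        assert len({r.water_id for r in recs}) == 5
        assert all(r.duration == pytest.approx(500.0) for r in recs)
        recs600, _ = track_residences(traj, hull, 600.0, scene.frame_interval)
        assert recs600 == []

    def test_single_frame_exit_splits_interval(self):
        """A water leaving for one frame mid-residence yields two
        intervals, each tested separately (hand-built toy trajectory)."""
        anchors = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10],
                            [10, 10, 10]], dtype=float)
        hull = build_hull(anchors)
        inside = [2.0, 2.0, 2.0]
        outside = [50.0, 50.0, 50.0]
        traj = np.array([[inside], [inside], [outside], [inside], [inside],
                         [inside]], dtype=float)
        recs, pooled = track_residences(traj, hull, lifetime_threshold=2.5,
                                        frame_interval=1.5)
        # intervals: frames [0,2) -> 3.0 ps (passes), [3,6) -> 4.5 ps (passes)
        assert [(r.entry_frame, r.exit_frame) for r in recs] == [(0, 2), (3, 6)]
        recs2, _ = track_residences(traj, hull, lifetime_threshold=3.5,
                                    frame_interval=1.5)
        assert [(r.entry_frame, r.exit_frame) for r in recs2] == [(3, 6)]
        assert len(pooled) == 5

    def test_bad_inputs(self, planted_scene):
        scene, traj, _ = planted_scene
        hull = build_hull(scene.anchor_points)
        with pytest.raises(ValueError, match="frame"):
            track_residences(traj, hull, 100.0, frame_interval=0.0)
        with pytest.raises(ValueError, match="trajectory"):
            track_residences(traj[:0], hull, 100.0, 1.0)


class TestClusterSpots:
    def test_k1_is_centroid(self, rng):
        pts = rng.normal(0, 1, (200, 3))
        spots = cluster_spots(pts, k=1, seed=0)
        np.testing.assert_allclose(spots.centers[0], pts.mean(axis=0),
                                   atol=1e-8)

    def test_planted_centers_recovered(self, planted_scene):
        scene, traj, anchors = planted_scene
        hull = build_hull(anchors)
        _, pooled = track_residences(traj, hull, 100.0, scene.frame_interval)
        spots = cluster_spots(pooled, k=5, seed=0)
        d = np.linalg.norm(scene.planted_spots[:, None] - spots.centers[None],
                           axis=-1)
        assert d.min(axis=1).max() <= 0.5
        # nearest-center assignment of pooled points is unambiguous:
        # every stored position of spot occupant i is closest to spot i
        recs, _ = track_residences(traj, hull, 100.0, scene.frame_interval)
        for r in recs:
            dp = np.linalg.norm(r.positions[:, None]
                                - scene.planted_spots[None], axis=-1)
            assert (dp.argmin(axis=1) == r.water_id).all()

    def test_auto_k_respects_spacing_band(self, planted_scene):
        """Exhaustive sweep oracle: auto-k must be the largest k whose
        minimum inter-center spacing stays above the band floor."""
        scene, traj, anchors = planted_scene
        hull = build_hull(anchors)
        _, pooled = track_residences(traj, hull, 100.0, scene.frame_interval)
        auto = cluster_spots(pooled, k="auto", spacing_band=(2.0, 3.0), seed=0)
        assert auto.min_pair_distance >= 2.0
        bigger = cluster_spots(pooled, k=auto.k + 1, seed=0)
        assert bigger.min_pair_distance < 2.0
        assert auto.k == 5

    def test_contract_errors(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            cluster_spots(np.empty((0, 3)))
        with pytest.raises(ValueError, match="at least"):
            cluster_spots(rng.normal(0, 1, (3, 3)), k=10)

    def test_determinism(self, planted_scene):
        scene, traj, anchors = planted_scene
        hull = build_hull(anchors)
        _, pooled = track_residences(traj, hull, 100.0, scene.frame_interval)
        a = cluster_spots(pooled, k="auto", seed=3)
        b = cluster_spots(pooled, k="auto", seed=3)
        np.testing.assert_array_equal(a.centers, b.centers)


class TestCoordination:
    def test_empty_and_limit_values(self):
        assert coordination([0, 0, 0], np.empty((0, 3))) == 0.0
        # one water exactly at r0: removable singularity -> n/m = 0.5
        assert coordination([0, 0, 0], [[3.5, 0, 0]]) == pytest.approx(0.5)

    def test_close_waters_count_fully(self):
        waters = np.array([[0.1, 0, 0], [0, 0.15, 0], [0, 0, 0.05]])
        assert coordination([0, 0, 0], waters) == pytest.approx(3.0, abs=1e-6)

    def test_smooth_across_r0(self):
        rs = np.linspace(3.3, 3.7, 401)
        vals = np.array([coordination([0, 0, 0], [[r, 0, 0]]) for r in rs])
        # finite-difference continuity: no jumps at the switching radius
        assert np.abs(np.diff(vals)).max() < 5e-3

    def test_bad_parameters(self):
        with pytest.raises(ValueError):
            coordination([0, 0, 0], [[1, 0, 0]], r0=-1)
        with pytest.raises(ValueError):
            coordination([0, 0, 0], [[1, 0, 0]], n=12, m=6)


class TestDescriptorVector:
    @staticmethod
    def _spec(planted_scene):
        scene, traj, anchors = planted_scene
        finder = HydrationSpotFinder(frame_interval=scene.frame_interval,
                                     k=5, seed=0)
        finder.fit(traj, anchors)
        return DescriptorSpec(ligand_atom="lig", site_atom="site",
                              spots=finder.spots_)

    def test_length_is_two_plus_k(self, planted_scene):
        spec = self._spec(planted_scene)
        lookup = {"lig": [15.0, 15, 15], "site": [14, 15, 15]}.__getitem__
        d = descriptor_vector(planted_scene[1][0], spec, lookup)
        assert len(d) == 2 + spec.spots.k == 7

    def test_zero_waters_gives_zero_vector(self, planted_scene):
        spec = self._spec(planted_scene)
        lookup = {"lig": [15.0, 15, 15], "site": [14, 15, 15]}.__getitem__
        d = descriptor_vector(np.empty((0, 3)), spec, lookup)
        np.testing.assert_array_equal(d, 0.0)

    def test_permutation_invariance(self, planted_scene, rng):
        spec = self._spec(planted_scene)
        lookup = {"lig": [15.0, 15, 15], "site": [14, 15, 15]}.__getitem__
        frame = planted_scene[1][3]
        d1 = descriptor_vector(frame, spec, lookup)
        d2 = descriptor_vector(frame[rng.permutation(len(frame))], spec, lookup)
        np.testing.assert_allclose(d1, d2, rtol=1e-12)


def test_spot_finder_estimator_protocol(planted_scene):
    scene, traj, anchors = planted_scene
    finder = HydrationSpotFinder(frame_interval=scene.frame_interval, seed=1)
    assert finder.get_params()["k"] == "auto"
    finder.set_params(k=5).fit(traj, anchors)
    assert finder.spots_.k == 5
    coords = finder.transform(traj[:3])
    assert coords.shape == (3, 5)
    # each planted spot hosts at least its occupant; neighbours add tails
    assert 0.5 < coords.mean() < 2.5
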