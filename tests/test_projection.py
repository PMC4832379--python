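"""Projection, density-map binning and quadrant counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from physis import (
    Bridge,
    BridgeSet,
    ProjectedPoint,
    density_map,
    mean_areal_density,
    project_bridges,
    quadrant_counts,
)


def _point(u, v, pid=1):
    return ProjectedPoint(pid, u, v)


def _points(coords):
    return [_point(u, v, i + 1) for i, (u, v) in enumerate(coords)]


class TestProject:
    def test_orthogonal_projection_of_centroids(self):
        b = Bridge(1, np.zeros((1, 3), int), 1.0, (500.0, 100.0, 200.0),
                   True, True, 1.0)
        pts = project_bridges(BridgeSet([b], spacing=1.0))
        assert pts == [ProjectedPoint(1, 100.0, 200.0)]
        assert project_bridges(BridgeSet([])) == []

    def test_phantom_centroids_project_to_planted_positions(self, default_phantom):
        from physis import binarize_bone, detect_bridges, extract_plate_region, \
            split_epiphysis_metaphysis

        vol, gt = default_phantom
        bone = binarize_bone(vol)
        joint = split_epiphysis_metaphysis(bone, extract_plate_region(bone, 60.0))
        pts = project_bridges(detect_bridges(joint, bone))
        got = np.array([[p.u, p.v] for p in pts])
        want = np.array([[u, v] for u, v, _ in gt.bridge_centers_um])
        from scipy.spatial.distance import cdist

        assert (cdist(want, got).min(axis=1) <= vol.spacing).all()


class TestDensityMap:
    def test_single_point_single_tile(self):
        dm = density_map(_points([(100.0, 100.0)]), window=256.0)
        assert dm.total == 1
        assert dm.counts.sum() == 1
        assert (dm.counts == 1).sum() == 1

    def test_boundary_point_goes_to_higher_tile(self):
        # a point exactly at u = window lands in tile index 1, not 0
        dm = density_map(_points([(256.0, 10.0), (10.0, 10.0)]), window=256.0)
        assert dm.counts.shape[0] == 2
        assert dm.counts[0, 0] == 1 and dm.counts[1, 0] == 1

    def test_grid_autoexpands_instead_of_dropping(self):
        fp = np.ones((4, 4), bool)
        dm = density_map(
            _points([(-500.0, 2000.0)]),
            window=256.0,
            plate_footprint=fp,
            footprint_spacing=64.0,
        )
        assert dm.total == 1  # conservation even far outside the footprint

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_binning(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 2000, size=(100, 2))
        w = 256.0
        dm = density_map(_points(coords), window=w)
        # brute-force double loop over tiles
        i0 = int(np.floor(coords[:, 0].min() / w))
        j0 = int(np.floor(coords[:, 1].min() / w))
        for i in range(dm.counts.shape[0]):
            for j in range(dm.counts.shape[1]):
                left_u = dm.origin_uv[0] + i * w
                left_v = dm.origin_uv[1] + j * w
                expected = sum(
                    1
                    for (u, v) in coords
                    if left_u <= u < left_u + w and left_v <= v < left_v + w
                )
                assert dm.counts[i, j] == expected
        assert dm.total == 100

    @given(
        st.lists(
            st.tuples(st.integers(-10000, 10000), st.integers(-10000, 10000)),
            max_size=30,
        ),
        st.integers(0, 7),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_conservation_and_tiling_shift_invariance(self, grid_coords, shift):
        # quarter-voxel offsets keep points off tile boundaries, where the
        # physical assignment is well defined independent of the anchor
        coords = [(u * 0.5 + 0.25, v * 0.5 + 0.25) for u, v in grid_coords]
        pts = _points(coords)
        dm = density_map(pts, window=128.0)
        assert dm.total == len(coords)
        # shifting the anchor by whole windows permutes tiles only
        dm2 = density_map(pts, window=128.0, origin_uv=(shift * 128.0, -shift * 128.0))
        assert sorted(dm2.counts.ravel()) == sorted(dm.counts.ravel())


class TestMeanDensity:
    def test_bridges_per_footprint_tile(self):
        fp = np.zeros((40, 40), bool)
        fp[:10, :16] = True  # 10×16 px at 64 μm/px = 640×1024 μm ⇒ 3×4 tiles
        pts = _points([(i * 100.0 + 5, 50.0) for i in range(5)])
        dm = density_map(pts, 256.0, fp, footprint_spacing=64.0)
        assert int(dm.footprint.sum()) == 12
        assert mean_areal_density(dm) == pytest.approx(5 / 12)

    def test_zero_bridges_zero_density(self):
        fp = np.ones((8, 8), bool)
        dm = density_map([], 256.0, fp, footprint_spacing=64.0)
        assert mean_areal_density(dm) == 0.0

    def test_empty_footprint_is_an_error(self):
        dm = density_map(_points([(1.0, 1.0)]), 256.0)
        with pytest.raises(ValueError):
            mean_areal_density(dm)

    def test_poisson_placement_recovers_planted_rate(self):
        rng = np.random.default_rng(99)
        lam, n_tiles = 0.7, 400
        w = 256.0
        counts = rng.poisson(lam, n_tiles)
        coords = []
        for t, c in enumerate(counts):
            i, j = divmod(t, 20)
            for _ in range(c):
                coords.append(
                    (i * w + rng.uniform(0, w), j * w + rng.uniform(0, w))
                )
        fp = np.ones((20 * 4, 20 * 4), bool)  # 4 px of 64 μm per tile edge
        dm = density_map(_points(coords), w, fp, footprint_spacing=64.0)
        est = mean_areal_density(dm)
        se = np.sqrt(lam / n_tiles)
        assert abs(est - lam) <= 3 * se

    def test_density_invariant_to_quarter_turn(self, default_phantom):
        from physis import (
            binarize_bone,
            detect_bridges,
            extract_plate_region,
            plate_footprint,
            split_epiphysis_metaphysis,
        )
        from physis import BinaryMask

        vol, _ = default_phantom
        bone = binarize_bone(vol)
        joint = split_epiphysis_metaphysis(bone, extract_plate_region(bone, 60.0))

        def measure(j, b):
            pts = project_bridges(detect_bridges(j, b))
            fp, sp, orig = plate_footprint(j)
            dm = density_map(pts, 256.0, fp, footprint_spacing=sp,
                             footprint_origin=orig)
            return mean_areal_density(dm)

        d0 = measure(joint, bone)
        rb = BinaryMask(np.rot90(bone.data, axes=(1, 2)).copy(), vol.spacing)
        from physis import extract_plate_region as epr

        rj = split_epiphysis_metaphysis(rb, epr(rb, 60.0))
        assert measure(rj, rb) == pytest.approx(d0)


class TestQuadrants:
    def test_one_point_per_open_quadrant(self):
        pts = _points([(10, 10), (10, -10), (-10, 10), (-10, -10)])
        qc = quadrant_counts(pts, (0.0, 0.0), "+u")
        assert qc.to_dict() == {
            "anterior_lateral": 1,
            "anterior_medial": 1,
            "posterior_lateral": 1,
            "posterior_medial": 1,
        }

    def test_center_points_go_anterior_medial(self):
        pts = _points([(0.0, 0.0)] * 5)
        qc = quadrant_counts(pts, (0.0, 0.0), "+u")
        assert qc.anterior_medial == 5 and qc.total == 5

    @pytest.mark.parametrize("medial", ["+u", "-u", "+v", "-v"])
    def test_matches_brute_force_sign_tests(self, medial):
        rng = np.random.default_rng(3)
        coords = rng.uniform(-300, 300, (200, 2))
        center = (12.0, -7.0)
        qc = quadrant_counts(_points(coords), center, medial)
        assert qc.total == 200

        axes = {"+u": (1, 0), "-u": (-1, 0), "+v": (0, 1), "-v": (0, -1)}
        rot = {"+u": "+v", "+v": "-u", "-u": "-v", "-v": "+u"}
        mu, mv = axes[medial]
        au, av = axes[rot[medial]]
        expected = {"anterior_medial": 0, "anterior_lateral": 0,
                    "posterior_medial": 0, "posterior_lateral": 0}
        for (u, v) in coords:
            du, dv = u - center[0], v - center[1]
            med = mu * du + mv * dv >= 0
            ant = au * du + av * dv >= 0
            key = ("anterior" if ant else "posterior") + "_" + \
                  ("medial" if med else "lateral")
            expected[key] += 1
        assert qc.to_dict() == expected
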