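"""Bridge detection against ground truth and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from physis import (
    BinaryMask,
    LabelledJoint,
    PhantomSpec,
    binarize_bone,
    detect_bridges,
    extract_plate_region,
    make_plate_phantom,
    merge_touching_bridges,
    split_epiphysis_metaphysis,
)


def _segment(vol, closing_um=60.0):
    bone = binarize_bone(vol)
    plate = extract_plate_region(bone, closing_um)
    return bone, split_epiphysis_metaphysis(bone, plate)


def _slab_scene(pegs=(), spurs=(), shape=(30, 32, 32), gap=(12, 18), radius=3):
    """Two slabs + cylindrical pegs (crossing) and spurs (one-sided)."""
    nz, ny, nx = shape
    bone = np.zeros(shape, bool)
    bone[4:gap[0]] = True
    bone[gap[1]:nz - 4] = True
    yy, xx = np.mgrid[:ny, :nx]
    for (py, px) in pegs:
        disk = (yy - py) ** 2 + (xx - px) ** 2 <= radius**2
        bone[gap[0] - 1:gap[1] + 1, disk] = True
    for (py, px) in spurs:
        disk = (yy - py) ** 2 + (xx - px) ** 2 <= radius**2
        bone[gap[0]:gap[0] + 3, disk] = True  # attached to epiphysis only
    return bone


def _joint_from_scene(bone, gap=(12, 18)):
    """Labelled joint for a two-slab scene: the gap rows are the plate band."""
    lo, hi = gap
    labels = np.zeros(bone.shape, np.uint8)
    labels[:lo][bone[:lo]] = 1
    labels[hi:][bone[hi:]] = 2
    labels[lo:hi] = 3
    return LabelledJoint(labels, 1.0)


class TestDetect:
    def test_pegs_counted_with_analytic_volume(self):
        pegs = [(6, 6), (6, 26), (16, 16), (26, 6), (26, 26)]
        bone = _slab_scene(pegs=pegs)
        mask = BinaryMask(bone, 1.0)
        joint = _joint_from_scene(bone)
        bs = detect_bridges(joint, mask)
        assert bs.n_bridges == 5
        r, h = 3, 6  # the component is the in-band part of the peg
        analytic = np.pi * r**2 * h
        shell = 2 * np.pi * r * h + 2 * np.pi * r**2  # one-voxel surface shell
        for b in bs.bridges:
            assert b.touches_epiphysis and b.touches_metaphysis
            assert abs(b.volume_um3 - analytic) <= shell
            assert b.min_cross_section_um2 >= np.pi * (r - 1) ** 2

    def test_spurs_are_discarded(self):
        bone = _slab_scene(pegs=[(8, 8), (24, 24)], spurs=[(8, 24), (24, 8), (16, 8)])
        bs = detect_bridges(_joint_from_scene(bone), BinaryMask(bone, 1.0))
        assert bs.n_bridges == 2

    def test_no_plate_bone_gives_empty_set(self):
        bone = _slab_scene()
        bs = detect_bridges(_joint_from_scene(bone), BinaryMask(bone, 1.0))
        assert bs.n_bridges == 0 and bs.bridges == []

    def test_shape_mismatch_rejected(self):
        bone = _slab_scene()
        joint = _joint_from_scene(bone)
        with pytest.raises(ValueError):
            detect_bridges(joint, BinaryMask(bone[:-2], 1.0))

    def test_count_invariant_to_rotation_and_translation(self):
        vol, gt = make_plate_phantom(PhantomSpec(seed=9, n_bridges=7))
        _, joint = _segment(vol)
        bone = binarize_bone(vol)
        n0 = detect_bridges(joint, bone).n_bridges
        assert n0 == 7

        rot = np.rot90(vol.data, axes=(1, 2)).copy()
        from physis import VoxelVolume

        bone_r, joint_r = _segment(VoxelVolume(rot, vol.spacing))
        assert detect_bridges(joint_r, bone_r).n_bridges == n0

        shifted = np.roll(vol.data, (2, 3), axis=(1, 2))
        bone_s, joint_s = _segment(VoxelVolume(shifted, vol.spacing))
        assert detect_bridges(joint_s, bone_s).n_bridges == n0

    def test_adding_a_disjoint_peg_increments_count(self):
        base = [(6, 6), (26, 26)]
        for extra in [(6, 26), (16, 16)]:
            b0 = _slab_scene(pegs=base)
            b1 = _slab_scene(pegs=base + [extra])
            n0 = detect_bridges(_joint_from_scene(b0), BinaryMask(b0, 1.0)).n_bridges
            n1 = detect_bridges(_joint_from_scene(b1), BinaryMask(b1, 1.0)).n_bridges
            assert n1 == n0 + 1

    def test_fully_bridged_counts_components(self):
        bone = np.ones((20, 20, 20), bool)
        labels = np.zeros(bone.shape, np.uint8)
        labels[8:12] = 3
        labels[:8] = 1
        labels[12:] = 2
        joint = LabelledJoint(labels, 1.0, fully_bridged=True)
        bs = detect_bridges(joint, BinaryMask(bone, 1.0))
        assert bs.fully_bridged
        assert bs.n_bridges == 1  # the fused slab is one component


from oracles import oracle_bridge_count


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_flood_fill_oracle_on_random_scenes(self, seed):
        rng = np.random.default_rng(seed)
        shape = (24, 24, 24)
        bone = np.zeros(shape, bool)
        bone[3:9] = True
        bone[15:21] = True
        # random clutter in and around the gap
        clutter = rng.random(shape) > 0.82
        clutter[:8] = clutter[16:] = False
        bone |= clutter
        labels = np.zeros(shape, np.uint8)
        labels[bone & (np.arange(24) < 9)[:, None, None]] = 1
        labels[bone & (np.arange(24) >= 15)[:, None, None]] = 2
        band = (np.arange(24)[:, None, None] >= 8) & (np.arange(24)[:, None, None] < 16)
        labels[np.broadcast_to(band, shape)] = 3
        joint = LabelledJoint(labels, 1.0)
        mask = BinaryMask(bone, 1.0)

        got = detect_bridges(joint, mask).n_bridges
        cand = bone & (labels == 3)
        expected = oracle_bridge_count(cand, labels == 1, labels == 2)
        assert got == expected


class TestMerge:
    def test_forced_merge_and_identity(self):
        # radius-3 pegs 9 apart leave a 2-voxel gap (nearest centres 3 μm)
        bone = _slab_scene(pegs=[(10, 10), (10, 19)])
        bs = detect_bridges(_joint_from_scene(bone), BinaryMask(bone, 1.0))
        assert bs.n_bridges == 2
        assert merge_touching_bridges(bs, 0.0).n_bridges == 2
        assert merge_touching_bridges(bs, 2.0).n_bridges == 2
        merged = merge_touching_bridges(bs, 3.0)
        assert merged.n_bridges == 1
        assert merged.bridges[0].volume_um3 == pytest.approx(
            sum(b.volume_um3 for b in bs.bridges)
        )

    @pytest.mark.parametrize("separation", [0.0, 1.5, 3.0, 6.0, 50.0])
    def test_matches_single_linkage_oracle(self, separation):
        vol, _ = make_plate_phantom(PhantomSpec(seed=13, n_bridges=8))
        bone, joint = _segment(vol)
        bs = detect_bridges(joint, bone)
        merged = merge_touching_bridges(bs, separation)

        # brute-force single linkage on pairwise voxel distances
        n = bs.n_bridges
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i] = parent[parent[i]]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                d = cdist(
                    bs.bridges[i].voxels * bs.spacing,
                    bs.bridges[j].voxels * bs.spacing,
                ).min()
                if d <= separation and separation > 0:
                    parent[find(j)] = find(i)
        expected = len({find(i) for i in range(n)})
        assert merged.n_bridges == expected


class TestPhantomRecovery:
    @pytest.mark.parametrize("seed,n", [(1, 0), (2, 3), (3, 8), (4, 14), (5, 20)])
    def test_planted_bridges_recovered_exactly(self, seed, n):
        spec = PhantomSpec(seed=seed, n_bridges=n)
        vol, gt = make_plate_phantom(spec)
        bone, joint = _segment(vol)
        bs = detect_bridges(joint, bone)
        assert bs.n_bridges == n
        if n:
            got = np.array([[b.centroid_um[1], b.centroid_um[2]] for b in bs.bridges])
            want = np.array([[u, v] for u, v, _ in gt.bridge_centers_um])
            d = cdist(want, got)
            assert (d.min(axis=1) <= vol.spacing).all()

    def test_serialization_round_trip(self, tmp_path, default_phantom):
        vol, _ = default_phantom
        bone, joint = _segment(vol)
        bs = detect_bridges(joint, bone)
        bs.to_csv(tmp_path / "b.csv")
        bs.to_json(tmp_path / "b.json")
        import json

        import pandas as pd

        df = pd.read_csv(tmp_path / "b.csv")
        assert list(df["id"]) == list(range(1, bs.n_bridges + 1))
        payload = json.loads((tmp_path / "b.json").read_text())
        assert payload["n_bridges"] == bs.n_bridges
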