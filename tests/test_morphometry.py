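"""SA detection chain: DoG filter, tracking, cistern classification, census."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage
from scipy.signal import convolve

from spinetools import morphometry as mm
from spinetools.errors import CensusError, RefinementError, SeedError, ValidationError

VOX = (10.0, 10.0, 10.0)


def _vol(arr):
    return mm.EMVolume(np.asarray(arr, dtype=float), VOX)


def _dog_oracle(data, s1, s2):
    """Direct-convolution DoG with edge replication, matching gaussian_filter."""

    def kern(sigma):
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / sigma) ** 2)
        return k / k.sum(), radius

    def blur(d, sigma):
        k, radius = kern(sigma)
        out = np.pad(d, radius, mode="edge")
        for ax in range(3):
            shape = [1, 1, 1]
            shape[ax] = len(k)
            out = convolve(out, k.reshape(shape), mode="same")
        return out[radius:-radius, radius:-radius, radius:-radius]

    return blur(data, s1) - blur(data, s2)


class TestDogFilter:
    def test_annihilates_constant_volume(self):
        out = mm.dog_filter(_vol(np.full((8, 8, 8), 42.0)), 1.0, 2.0)
        np.testing.assert_allclose(out.voxels, 0.0, atol=1e-10)

    def test_point_source_gives_mexican_hat(self):
        data = np.zeros((15, 15, 15))
        data[7, 7, 7] = 1.0
        out = mm.dog_filter(_vol(data), 1.0, 3.0).voxels
        assert np.unravel_index(np.argmax(out), out.shape) == (7, 7, 7)
        assert out[7, 7, 2] < 0  # negative annulus away from the centre

    def test_matches_direct_convolution_on_planted_sheet(self):
        data = np.full((20, 20, 20), 100.0)
        data[9:12] = 20.0  # dark sheet 3 voxels thick
        out = mm.dog_filter(_vol(data), 1.0, 3.0, invert=True).voxels
        oracle = _dog_oracle(-data, 1.0, 3.0)
        np.testing.assert_allclose(out, oracle, atol=1e-8)
        assert np.unravel_index(np.argmax(out), out.shape)[0] == 10  # sheet mid-plane

    def test_sigma_order_enforced(self):
        with pytest.raises(ValidationError):
            mm.dog_filter(_vol(np.zeros((8, 8, 8))), 3.0, 1.0)

    @given(offset=st.floats(-1e3, 1e3, allow_nan=False))
    def test_invariant_to_intensity_offset(self, offset):
        rng = np.random.default_rng(0)
        data = rng.random((6, 6, 6)) * 10
        a = mm.dog_filter(_vol(data), 1.0, 2.0).voxels
        b = mm.dog_filter(_vol(data + offset), 1.0, 2.0).voxels
        np.testing.assert_allclose(a, b, atol=1e-8)


class TestThresholdMask:
    @pytest.mark.parametrize(
        "threshold,expected",
        [(6.0, {10.0}), (10.0, {10.0}), (0.0, {0.0, 5.0, 10.0}), (11.0, set())],
    )
    def test_inclusive_convention(self, threshold, expected):
        data = np.array([[[0.0, 5.0, 10.0]]])
        mask = mm.threshold_mask(mm.EMVolume(data), threshold)
        assert set(data[mask.data].tolist()) == expected
        if threshold > 10:
            assert not mask.data.any()


def _seed_at(shape, plane, r, c):
    region = np.zeros(shape[1:], dtype=bool)
    region[r, c] = True
    return mm.SeedSelection(plane=plane, region=region)


class TestTracking:
    def test_pillar_equals_connected_component_oracle(self):
        mask = np.zeros((3, 6, 6), dtype=bool)
        mask[:, 2:4, 2:4] = True
        obj = mm.track_structure(mask, _seed_at(mask.shape, 0, 2, 2))
        labels, _ = ndimage.label(mask, structure=mm.STRUCT_26)
        np.testing.assert_array_equal(obj.mask(), labels == labels[0, 2, 2])
        assert obj.planes == (0, 2)

    def test_no_overlap_stops_propagation(self):
        mask = np.zeros((3, 8, 8), dtype=bool)
        mask[0, 0:2, 0:2] = True  # far corner, no 26-adjacency to plane 1
        mask[1, 5:7, 5:7] = True
        obj = mm.track_structure(mask, _seed_at(mask.shape, 0, 0, 0))
        assert sorted(obj.plane_masks) == [0]

    def test_parallel_pillars_stay_separate(self):
        mask = np.zeros((4, 10, 10), dtype=bool)
        mask[:, 1:3, 1:3] = True  # pillar A
        mask[:, 6:8, 6:8] = True  # pillar B
        obj = mm.track_structure(mask, _seed_at(mask.shape, 1, 1, 1))
        assert not obj.mask()[:, 6:8, 6:8].any()
        labels, _ = ndimage.label(mask, structure=mm.STRUCT_26)
        np.testing.assert_array_equal(obj.mask(), labels == labels[1, 1, 1])

    def test_min_overlap_gate_blocks_thin_bridges(self):
        mask = np.zeros((2, 6, 6), dtype=bool)
        mask[0, 2, 2] = True  # single-voxel footprint
        mask[1, 2:5, 2:5] = True
        assert sorted(mm.track_structure(mask, _seed_at(mask.shape, 0, 2, 2), 1).plane_masks) == [0, 1]
        # the 3x3 component overlaps the dilated single voxel by 4 voxels only
        assert sorted(mm.track_structure(mask, _seed_at(mask.shape, 0, 2, 2), 5).plane_masks) == [0]

    def test_empty_seed_intersection_raises(self):
        mask = np.zeros((2, 4, 4), dtype=bool)
        mask[0, 0, 0] = True
        with pytest.raises(SeedError):
            mm.track_structure(mask, _seed_at(mask.shape, 0, 3, 3))

    def test_tracked_voxels_subset_of_mask(self):
        rng = np.random.default_rng(3)
        mask = rng.random((6, 12, 12)) < 0.3
        mask[2, 5, 5] = True
        obj = mm.track_structure(mask, _seed_at(mask.shape, 2, 5, 5))
        assert not (obj.mask() & ~mask).any()


class TestRefineObject:
    def _obj(self):
        mask = np.zeros((2, 4, 4), dtype=bool)
        mask[0, 1:3, 1:3] = True
        mask[1, 1:3, 1:3] = True
        return mm.track_structure(mask, _seed_at(mask.shape, 0, 1, 1))

    def test_identity_with_empty_edits(self):
        obj = self._obj()
        np.testing.assert_array_equal(mm.refine_object(obj).mask(), obj.mask())

    def test_removals_win_over_additions(self):
        obj = self._obj()
        both = np.zeros(obj.shape, dtype=bool)
        both[0, 1, 1] = True
        out = mm.refine_object(obj, additions=both, removals=both)
        assert not out.mask()[0, 1, 1]

    def test_full_removal_raises(self):
        obj = self._obj()
        with pytest.raises(RefinementError):
            mm.refine_object(obj, removals=np.ones(obj.shape, dtype=bool))

    def test_idempotent_for_fixed_edits(self):
        obj = self._obj()
        add = np.zeros(obj.shape, dtype=bool)
        add[1, 0, 0] = True
        once = mm.refine_object(obj, additions=add)
        twice = mm.refine_object(once, additions=add)
        np.testing.assert_array_equal(once.mask(), twice.mask())


def _slab(shape, z0, thickness, extent=10, offset=(8, 8)):
    out = np.zeros(shape, dtype=bool)
    out[z0 : z0 + thickness, offset[0] : offset[0] + extent, offset[1] : offset[1] + extent] = True
    return out


class TestCisternsAndClassification:
    def test_planar_slab_is_flat_with_perpendicular_normal(self):
        mask = _slab((24, 26, 26), 10, 2)
        (c,) = mm.segment_cisterns(mask, VOX)
        assert c.flatness < 0.33
        assert abs(c.normal[0]) > 0.99  # normal along the stacking (z) axis

    def test_ball_is_not_flat(self):
        zz, yy, xx = np.ogrid[:13, :13, :13]
        ball = (zz - 6) ** 2 + (yy - 6) ** 2 + (xx - 6) ** 2 <= 25
        (c,) = mm.segment_cisterns(ball, VOX)
        # eigenvalues of a discretized ball are equal by symmetry -> flatness ~ 1
        coords = np.argwhere(ball) * np.array(VOX)
        eig = np.linalg.eigvalsh(np.cov(coords.T))
        assert c.flatness == pytest.approx(eig[0] / eig[1], rel=1e-9)
        assert c.flatness > 0.9

    def test_three_parallel_slabs_classified_as_sa(self):
        mask = _slab((24, 26, 26), 4, 2) | _slab((24, 26, 26), 8, 2) | _slab((24, 26, 26), 12, 2)
        cisterns = mm.segment_cisterns(mask, VOX)
        assert len(cisterns) == 3
        angles = [
            abs(np.dot(a.normal, b.normal))
            for i, a in enumerate(cisterns)
            for b in cisterns[i + 1 :]
        ]
        assert min(angles) > np.cos(np.deg2rad(5))
        is_sa, count, _ = mm.classify_sa(cisterns)
        assert (is_sa, count) == (True, 3)

    def test_single_flat_cistern_is_not_sa(self):
        cisterns = mm.segment_cisterns(_slab((24, 26, 26), 10, 2), VOX)
        is_sa, count, _ = mm.classify_sa(cisterns)
        assert (is_sa, count) == (False, 1)

    def test_orthogonal_slabs_fail_parallelism(self):
        mask = _slab((26, 26, 26), 8, 2)
        mask[6:16, 20:22, 8:18] = True  # disjoint slab rotated 90 deg (normal along y)
        cisterns = mm.segment_cisterns(mask, VOX)
        assert len(cisterns) == 2
        is_sa, _, _ = mm.classify_sa(cisterns)
        assert not is_sa

    def test_wide_gap_fails_apposition(self):
        mask = _slab((40, 26, 26), 4, 2) | _slab((40, 26, 26), 24, 2)  # 170 nm gap
        is_sa, count, _ = mm.classify_sa(mm.segment_cisterns(mask, VOX), gap_max_nm=80.0)
        assert not is_sa and count == 1


class TestContacts:
    def test_distant_mask_yields_no_contacts(self):
        sa = np.zeros((10, 10, 10), dtype=bool)
        sa[5, 5, 5] = True
        other = np.zeros_like(sa)
        other[5, 5, 9] = True  # 40 nm away
        assert mm.detect_contacts(sa, other, VOX, 30.0) == []

    def test_face_adjacent_voxel_detected(self):
        sa = np.zeros((4, 4, 4), dtype=bool)
        sa[1, 1, 1] = True
        other = np.zeros_like(sa)
        other[1, 1, 2] = True
        assert mm.detect_contacts(sa, other, VOX, contact_dist_nm=10.0) == [(1, 1, 2)]

    def test_shrinking_distance_never_adds_contacts(self):
        rng = np.random.default_rng(5)
        sa = rng.random((8, 8, 8)) < 0.1
        other = rng.random((8, 8, 8)) < 0.1
        sa[4, 4, 4] = True
        prev = None
        for dist in (60.0, 40.0, 20.0, 10.0):
            hits = set(mm.detect_contacts(sa, other, VOX, dist))
            if prev is not None:
                assert hits <= prev
            prev = hits

    def test_anisotropic_voxels_use_physical_distance(self):
        sa = np.zeros((4, 4, 4), dtype=bool)
        sa[1, 1, 1] = True
        other = np.zeros_like(sa)
        other[2, 1, 1] = True  # one step along z
        assert mm.detect_contacts(sa, other, (50.0, 10.0, 10.0), 30.0) == []
        assert mm.detect_contacts(sa, other, (20.0, 10.0, 10.0), 30.0) == [(2, 1, 1)]


class TestCensus:
    def test_er_negative_spines_have_no_sa(self):
        records = [mm.SpineRecord(i, True, False, False) for i in range(5)]
        census = mm.spine_census(records)
        assert census.frac_sa == 0.0 and census.frac_er == 0.0

    def test_single_positive_spine(self):
        census = mm.spine_census([mm.SpineRecord(0, True, True, True)])
        assert (census.frac_er, census.frac_sa, census.frac_sa_given_er) == (1.0, 1.0, 1.0)

    def test_psd_negative_spines_excluded_from_denominator(self):
        records = [
            mm.SpineRecord(0, True, True, True),
            mm.SpineRecord(1, True, False, False),
            mm.SpineRecord(2, False, True, True),
        ]
        census = mm.spine_census(records)
        assert census.n_psd_spines == 2 and census.frac_sa == 0.5

    def test_no_psd_spines_raises(self):
        with pytest.raises(CensusError):
            mm.spine_census([mm.SpineRecord(0, False, False, False)])

    def test_sa_implies_er_invariant(self):
        with pytest.raises(ValidationError):
            mm.SpineRecord(0, True, False, True)
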