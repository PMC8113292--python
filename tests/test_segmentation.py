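"""Delineation methods against brute-force oracles and analytic shapes."""

import numpy as np
import pytest

from helpers import brute_max_in_sphere, flood_fill, sphere_labels
from petmtv.phantom import PhantomSpec, make_phantom
from petmtv.segmentation import (
    AdjustmentGrade,
    Ellipsoid,
    Grade,
    GradientError,
    MisSeedingError,
    SegmentationError,
    apply_bladder_mask,
    bladder_masking_required,
    compute_suvmax,
    ellipsoid_constrained_segment,
    fixed_suv_segment,
    grade_and_adjust,
    gradient_segment,
    threshold_segment,
)
from petmtv.volumes import BinaryMask, LabelVolume, ScalarVolume, mtv_ml


def _random_volume(seed, shape=(8, 8, 8), spacing=(3.0, 3.0, 3.0)):
    r = np.random.default_rng(seed)
    vol = ScalarVolume(r.random(shape) * 10.0, spacing)
    seed_vox = np.unravel_index(int(np.argmax(vol.values)), shape)
    return vol, seed_vox


class TestSuvmax:
    def test_constant_volume(self):
        vol = ScalarVolume(np.full((5, 5, 5), 7.0), (1.0, 1.0, 1.0))
        assert compute_suvmax(vol, np.ones((5, 5, 5), bool)) == 7.0

    def test_matches_exhaustive_scan(self, rng):
        vals = rng.random((10, 10, 10))
        sel = rng.random((10, 10, 10)) > 0.5
        vol = ScalarVolume(vals, (1.0, 1.0, 1.0))
        assert compute_suvmax(vol, sel) == max(
            vals[i, j, k] for (i, j, k) in np.argwhere(sel)
        )

    def test_empty_region_rejected(self):
        vol = ScalarVolume(np.ones((3, 3, 3)), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="empty"):
            compute_suvmax(vol, np.zeros((3, 3, 3), bool))

    def test_cohort_peaks_center_near_published_suvmax(self):
        from petmtv.phantom import CohortSpec, make_cohort

        peaks = [
            compute_suvmax(pet, labels.tumour)
            for _, pet, labels in make_cohort(CohortSpec(n_cases=25, master_seed=31))
        ]
        assert np.mean(peaks) == pytest.approx(15.1, rel=0.15)


class TestThresholdSegment:
    def test_unblurred_cube_recovered_exactly(self):
        vals = np.zeros((20, 20, 20))
        vals[5:12, 5:12, 5:12] = 10.0
        pet = ScalarVolume(vals, (3.0, 3.0, 3.0))
        mask = threshold_segment(pet, (8, 8, 8), 0.4)
        np.testing.assert_array_equal(mask.voxels, vals == 10.0)

    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("fraction", [0.2, 0.4, 0.7, 1.0])
    def test_matches_flood_fill_oracle(self, seed, fraction):
        pet, seed_vox = _random_volume(seed)
        mask = threshold_segment(pet, seed_vox, fraction, search_radius_mm=60.0)
        suvmax = brute_max_in_sphere(pet.values, pet.spacing, seed_vox, 60.0)
        expected = flood_fill(pet.values, seed_vox, fraction * suvmax)
        np.testing.assert_array_equal(mask.voxels, expected)

    def test_volume_non_increasing_in_fraction(self, clean_phantom):
        _, pet, labels = clean_phantom
        anchor = np.unravel_index(int(np.argmax(pet.values)), pet.values.shape)
        vols = [
            mtv_ml(threshold_segment(pet, anchor, f))
            for f in (0.25, 0.30, 0.35, 0.40, 0.50, 0.60)
        ]
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_mis_seeding_detected(self):
        vals = np.ones((10, 10, 10))
        vals[5, 5, 5] = 10.0
        pet = ScalarVolume(vals, (3.0, 3.0, 3.0))
        with pytest.raises(MisSeedingError):
            threshold_segment(pet, (0, 0, 0), 0.5)

    def test_fraction_out_of_range(self):
        pet = ScalarVolume(np.ones((4, 4, 4)), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="fraction"):
            threshold_segment(pet, (0, 0, 0), 1.5)

    def test_excluded_voxels_never_selected(self, rng):
        pet, seed_vox = _random_volume(3, shape=(10, 10, 10))
        excl = BinaryMask(rng.random((10, 10, 10)) > 0.7, pet.spacing)
        if excl.voxels[seed_vox]:
            excl.voxels[seed_vox] = False
        mask = threshold_segment(pet, seed_vox, 0.3, exclusion=excl)
        assert not (mask.voxels & excl.voxels).any()

    def test_pure_cut_variant_is_plain_threshold_in_sphere(self):
        pet, seed_vox = _random_volume(8)
        mask = threshold_segment(pet, seed_vox, 0.5, connected=False, search_radius_mm=1e3)
        suvmax = pet.values.max()
        np.testing.assert_array_equal(mask.voxels, pet.values >= 0.5 * suvmax)


class TestFixedSuvSegment:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_flood_fill_oracle(self, seed):
        pet, seed_vox = _random_volume(seed)
        mask = fixed_suv_segment(pet, seed_vox, suv_cut=4.0)
        expected = flood_fill(pet.values, seed_vox, 4.0, strict=True)
        np.testing.assert_array_equal(mask.voxels, expected)

    def test_clean_tumour_recovered(self):
        vals = np.zeros((16, 16, 16))
        vals[4:9, 4:9, 4:9] = 10.0
        pet = ScalarVolume(vals, (3.0, 3.0, 3.0))
        mask = fixed_suv_segment(pet, (6, 6, 6), 2.5)
        np.testing.assert_array_equal(mask.voxels, vals == 10.0)

    def test_connected_warm_background_grossly_overestimates(self):
        # background 3.0 > cut and touching the tumour: the component
        # spans the whole field, the classic fixed-threshold failure
        vals = np.full((16, 16, 16), 3.0)
        vals[4:9, 4:9, 4:9] = 10.0
        pet = ScalarVolume(vals, (3.0, 3.0, 3.0))
        mask = fixed_suv_segment(pet, (6, 6, 6), 2.5)
        assert mask.count == 16**3

    def test_seed_below_cut_rejected(self):
        pet = ScalarVolume(np.full((4, 4, 4), 2.0), (1.0, 1.0, 1.0))
        with pytest.raises(MisSeedingError):
            fixed_suv_segment(pet, (0, 0, 0), 2.5)


class TestBladderMasking:
    def _masks(self, cand, blad):
        sp = (3.0, 3.0, 3.0)
        return BinaryMask(cand, sp), BinaryMask(blad, sp)

    def test_empty_intersection_false(self):
        cand = np.zeros((10, 10, 10), bool)
        cand[2:5, 2:5, 2:5] = True
        blad = np.zeros((10, 10, 10), bool)
        blad[7:9, 7:9, 7:9] = True
        assert bladder_masking_required(*self._masks(cand, blad)) is False

    def test_six_overlap_slices_triggers(self):
        cand = np.zeros((10, 10, 10), bool)
        cand[0:8, 0:8, 0:8] = True
        blad = np.zeros((10, 10, 10), bool)
        blad[0:2, 0:2, 0:6] = True  # overlap on exactly 6 axial slices
        assert bladder_masking_required(*self._masks(cand, blad)) is True

    def test_five_slices_and_minor_overlap_does_not_trigger(self):
        cand = np.zeros((10, 10, 10), bool)
        cand[0:10, 0:10, 0:5] = True  # 500 voxels
        blad = np.zeros((10, 10, 10), bool)
        blad[0:2, 0:2, 0:5] = True  # 20 voxels on 5 slices -> 4% of candidate
        assert bladder_masking_required(*self._masks(cand, blad)) is False

    def test_bladder_outlined_instead_of_tumour_triggers(self):
        cand = np.zeros((10, 10, 10), bool)
        cand[0:3, 0:3, 0:3] = True
        blad = np.zeros((10, 10, 10), bool)
        blad[0:3, 0:3, 0:2] = True  # 18 of 27 candidate voxels, only 2 slices
        assert bladder_masking_required(*self._masks(cand, blad)) is True

    def test_apply_mask_zeroes_bladder_only(self, default_phantom):
        _, pet, labels = default_phantom
        masked = apply_bladder_mask(pet, labels.bladder)
        assert (masked.values[labels.bladder.voxels] == 0).all()
        keep = ~labels.bladder.voxels
        np.testing.assert_array_equal(masked.values[keep], pet.values[keep])

    def test_threshold_on_masked_pet_never_reaches_bladder(self, default_phantom):
        _, pet, labels = default_phantom
        masked = apply_bladder_mask(pet, labels.bladder)
        anchor = np.unravel_index(int(np.argmax(masked.values)), pet.values.shape)
        for f in (0.2, 0.3, 0.5):
            mask = threshold_segment(masked, anchor, f)
            assert not (mask.voxels & labels.bladder.voxels).any()


class TestGradeAndAdjust:
    def _labels(self, bladder_slices):
        labels = np.zeros((30, 30, 30), dtype=np.int64)
        labels[5:15, 5:15, 2:28] = 1
        labels[20:25, 20:25, 2 : 2 + bladder_slices] = 2
        return LabelVolume(labels, (3.0, 3.0, 3.0))

    def test_mask_within_tumour_untouched(self):
        labels = self._labels(0)
        mask = BinaryMask(labels.labels == 1, labels.spacing)
        adjusted, grade = grade_and_adjust(mask, labels)
        assert grade == AdjustmentGrade(Grade.NONE, 0)
        np.testing.assert_array_equal(adjusted.voxels, mask.voxels)

    @pytest.mark.parametrize(
        "n_slices,expected",
        [(3, Grade.MINOR), (12, Grade.MAJOR), (20, Grade.MAJOR)],
    )
    def test_overlap_removed_and_graded(self, n_slices, expected):
        labels = self._labels(n_slices)
        mask = BinaryMask((labels.labels == 1) | (labels.labels == 2), labels.spacing)
        adjusted, grade = grade_and_adjust(mask, labels)
        assert grade.grade is expected
        assert grade.affected_slices == n_slices
        assert not (adjusted.voxels & (labels.labels == 2)).any()

    def test_too_difficult_yields_no_mask(self):
        labels = self._labels(21)
        mask = BinaryMask((labels.labels == 1) | (labels.labels == 2), labels.spacing)
        adjusted, grade = grade_and_adjust(mask, labels)
        assert adjusted is None
        assert grade.grade is Grade.TOO_DIFFICULT

    def test_grade_band_consistency_enforced(self):
        with pytest.raises(ValueError, match="grade"):
            AdjustmentGrade(Grade.MINOR, 10)

    def test_unmeasured_result_carries_no_mtv(self):
        from petmtv.segmentation import SegmentationResult

        with pytest.raises(ValueError, match="unmeasured"):
            SegmentationResult(mask=None, mtv_ml=12.0, method="gradient", measured=False)
        res = SegmentationResult(mask=None, mtv_ml=None, method="gradient", measured=False)
        assert res.mtv_ml is None


class TestEllipsoidConstrained:
    def test_constraint_inactive_when_containing_tumour(self):
        vals = np.zeros((20, 20, 20))
        vals[6:12, 6:12, 6:12] = 8.0
        pet = ScalarVolume(vals, (3.0, 3.0, 3.0))
        ell = Ellipsoid((25.5, 25.5, 25.5), (25.0, 25.0, 25.0))
        m_ell = ellipsoid_constrained_segment(pet, ell, fraction=0.4)
        m_thr = threshold_segment(pet, (8, 8, 8), 0.4)
        np.testing.assert_array_equal(m_ell.voxels, m_thr.voxels)

    def test_suvmax_taken_inside_ellipsoid_only(self):
        vals = np.full((30, 30, 30), 1.0)
        vals[8:14, 8:14, 8:14] = 10.0  # tumour
        vals[22:28, 22:28, 22:28] = 30.0  # hotter bladder, outside the VOI
        pet = ScalarVolume(vals, (3.0, 3.0, 3.0))
        ell = Ellipsoid((33.0, 33.0, 33.0), (18.0, 18.0, 18.0))
        mask, info = ellipsoid_constrained_segment(pet, ell, fraction=0.5, with_info=True)
        brute = max(
            vals[i, j, k]
            for (i, j, k) in np.argwhere(ell.contains_grid(pet))
        )
        assert info["suvmax"] == brute == 10.0
        assert not (mask.voxels & (vals == 30.0)).any()

    def test_abutting_bladder_inside_ellipsoid_is_included(self):
        vals = np.full((30, 30, 30), 1.0)
        vals[8:14, 8:14, 8:14] = 10.0
        vals[14:20, 8:14, 8:14] = 12.0  # bladder abutting, partially in VOI
        pet = ScalarVolume(vals, (3.0, 3.0, 3.0))
        ell = Ellipsoid((36.0, 33.0, 33.0), (20.0, 15.0, 15.0))
        mask = ellipsoid_constrained_segment(pet, ell, fraction=0.5)
        assert (mask.voxels & (vals == 12.0)).any()

    def test_fixed_cut_variant(self):
        vals = np.zeros((16, 16, 16))
        vals[4:9, 4:9, 4:9] = 10.0
        pet = ScalarVolume(vals, (3.0, 3.0, 3.0))
        ell = Ellipsoid((18.0, 18.0, 18.0), (12.0, 12.0, 12.0))
        mask = ellipsoid_constrained_segment(pet, ell, suv_cut=2.5)
        inside = ell.contains_grid(pet)
        np.testing.assert_array_equal(mask.voxels, (vals == 10.0) & inside)

    def test_empty_ellipsoid_rejected(self):
        pet = ScalarVolume(np.ones((10, 10, 10)), (3.0, 3.0, 3.0))
        with pytest.raises(SegmentationError, match="ellipsoid"):
            ellipsoid_constrained_segment(pet, Ellipsoid((200.0, 200.0, 200.0), (1.0, 1.0, 1.0)), fraction=0.5)

    def test_exactly_one_threshold_kind(self):
        pet = ScalarVolume(np.ones((4, 4, 4)), (1.0, 1.0, 1.0))
        ell = Ellipsoid((2.0, 2.0, 2.0), (2.0, 2.0, 2.0))
        with pytest.raises(ValueError, match="exactly one"):
            ellipsoid_constrained_segment(pet, ell, fraction=0.5, suv_cut=2.5)


def _blurred_sphere(radius_mm, suv=10.0, background=1.0, fwhm=5.0, spacing=3.0, n=65):
    from scipy.ndimage import gaussian_filter

    ax = np.arange(n) * spacing
    c = ax[n // 2]
    x, y, z = ax[:, None, None], ax[None, :, None], ax[None, None, :]
    inside = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius_mm**2
    vals = np.where(inside, suv, background).astype(float)
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / spacing
    vals = gaussian_filter(vals, sigma, mode="nearest")
    return ScalarVolume(vals, (spacing,) * 3), (n // 2,) * 3


class TestGradientSegment:
    def test_uniform_image_rejected(self):
        pet = ScalarVolume(np.full((20, 20, 20), 4.0), (3.0, 3.0, 3.0))
        with pytest.raises(GradientError, match="gradient"):
            gradient_segment(pet, (10, 10, 10))

    def test_blurred_sphere_volume_recovered(self):
        pet, center = _blurred_sphere(20.0)
        mask = gradient_segment(pet, center)
        analytic = 4.0 / 3.0 * np.pi * 2.0**3
        assert mtv_ml(mask) == pytest.approx(analytic, rel=0.10)

    def test_mean_boundary_radius_error_below_one_voxel(self):
        for radius in (15.0, 24.0, 30.0):
            pet, center = _blurred_sphere(radius)
            mask = gradient_segment(pet, center)
            vol = mtv_ml(mask) * 1000.0
            r_eff = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
            assert abs(r_eff - radius) <= 3.0  # one voxel

    def test_off_peak_seed_climbs_to_peak(self):
        pet, center = _blurred_sphere(20.0)
        off = (center[0] - 3, center[1] + 2, center[2])
        m1 = gradient_segment(pet, center)
        m2 = gradient_segment(pet, off)
        np.testing.assert_array_equal(m1.voxels, m2.voxels)

    def test_requires_minimum_directions(self):
        pet, center = _blurred_sphere(20.0)
        with pytest.raises(ValueError, match="n_directions"):
            gradient_segment(pet, center, n_directions=10)

    def test_deterministic(self):
        pet, center = _blurred_sphere(18.0)
        m1 = gradient_segment(pet, center)
        m2 = gradient_segment(pet, center)
        np.testing.assert_array_equal(m1.voxels, m2.voxels)
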