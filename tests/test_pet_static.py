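"""SUV arithmetic, static windows, blood-pool correction, TBR, threshold
masks and overlap scores."""

import numpy as np
import pytest

from fpia_quant.core_io import (
    DynamicImage,
    PatientMeta,
    ValidationError,
    VOIMask,
    parse_frame_schedule,
    CLINICAL_FRAME_SPEC,
)
from fpia_quant.pet_static import (
    SUVImage,
    blood_correct,
    compute_suv,
    dice,
    static_window,
    tbr,
    threshold_mask,
    volume_variation,
)

EYE = np.eye(4)


def _mask(vox):
    return VOIMask(np.asarray(vox, bool), EYE)


class TestComputeSuv:
    def test_definition(self):
        meta = PatientMeta("p", 350.0, 70.0)
        suv = compute_suv(np.array([[[5.0]]]), meta)
        assert suv.voxels[0, 0, 0] == pytest.approx(1.0)

    def test_zero_activity_zero_suv(self):
        meta = PatientMeta("p", 350.0, 70.0)
        assert compute_suv(np.zeros((2, 2, 2)), meta).voxels.max() == 0.0

    def test_hand_arithmetic(self):
        meta = PatientMeta("p", 420.0, 84.0)
        suv = compute_suv(np.array([[[2.5]]]), meta)
        assert suv.voxels[0, 0, 0] == pytest.approx(2.5 / (420.0 / 84.0), abs=1e-12)


class TestStaticWindow:
    @pytest.fixture()
    def clinical_image(self):
        schedule = parse_frame_schedule(CLINICAL_FRAME_SPEC)
        vox = np.ones((3, 3, 3, 28))
        return DynamicImage(vox, EYE, schedule)

    def test_constant_image_same_under_both_modes(self, clinical_image):
        a = static_window(clinical_image, "last5_mean")
        b = static_window(clinical_image, "frame_nearest_60")
        assert np.allclose(a, 1.0) and np.allclose(b, 1.0)

    def test_last5_window_is_26_minutes(self, clinical_image):
        s = clinical_image.schedule
        assert s.frame_duration_s[-5:].sum() / 60.0 == pytest.approx(26.0)

    def test_frame_nearest_60_selects_mid_time_58(self, clinical_image):
        """No clinical frame has mid-time exactly 60 min; the 55.5-60.5 min
        frame (mid 58) is the closest and must be selected."""
        s = clinical_image.schedule
        idx = int(np.argmin(np.abs(s.mid_times_min - 60.0)))
        assert s.frame_start_s[idx] == pytest.approx(55.5 * 60.0)
        assert s.mid_times_min[idx] == pytest.approx(58.0)
        vox = np.zeros((2, 2, 2, 28))
        vox[..., idx] = 7.0
        img = DynamicImage(vox, EYE, s)
        assert np.allclose(static_window(img, "frame_nearest_60"), 7.0)

    def test_last5_requires_five_frames(self):
        img = DynamicImage(np.ones((2, 2, 2, 3)), EYE, parse_frame_schedule([(3, 60)]))
        with pytest.raises(ValidationError):
            static_window(img, "last5_mean")

    def test_last5_is_duration_weighted(self):
        sched = parse_frame_schedule([(4, 300), (1, 360)])
        vox = np.zeros((1, 1, 1, 5))
        vox[..., -1] = 1.0  # only the 360-s frame is hot
        img = DynamicImage(vox, EYE, sched)
        assert static_window(img, "last5_mean")[0, 0, 0] == pytest.approx(360.0 / 1560.0)


class TestBloodCorrect:
    def _suv(self, arr):
        return SUVImage(np.asarray(arr, float), EYE)

    def test_zero_sinus_mean_is_identity(self):
        suv = self._suv(np.ones((3, 3, 3)))
        sinus_vox = np.zeros((3, 3, 3), bool)
        sinus_vox[0, 0, 0] = True
        suv.voxels[0, 0, 0] = 0.0
        out = blood_correct(suv, _mask(sinus_vox), blood_fraction=0.05)
        assert np.allclose(out.voxels, suv.voxels)

    def test_zero_blood_fraction_is_identity(self):
        rng = np.random.default_rng(1)
        suv = self._suv(rng.uniform(size=(3, 3, 3)))
        out = blood_correct(suv, _mask(np.ones((3, 3, 3), bool)), blood_fraction=0.0)
        assert np.allclose(out.voxels, suv.voxels)
        assert out.corrected

    def test_full_fraction_uniform_image_zeroes(self):
        suv = self._suv(np.full((3, 3, 3), 2.0))
        out = blood_correct(suv, _mask(np.ones((3, 3, 3), bool)), blood_fraction=1.0)
        assert np.allclose(out.voxels, 0.0)

    def test_empty_sinus_raises(self):
        with pytest.raises(ValidationError, match="sinus"):
            blood_correct(self._suv(np.ones((3, 3, 3))), _mask(np.zeros((3, 3, 3))))

    def test_phantom_correction_approaches_blood_free_uptake(self, clean_study):
        """Forward-model oracle: subtracting the vb-scaled sinus signal from
        the lesion SUV approximates the blood-free tissue curve."""
        from fpia_quant.pet_static import compute_suv, static_window

        study = clean_study
        vb = study.truth["kinetic_presets"]["4"]["vb"]
        static = static_window(study.pet, "frame_nearest_60")
        suv = compute_suv(static, study.meta)
        suvc = blood_correct(suv, study.masks["sinus"], blood_fraction=vb)
        lesion = study.masks["lesion_flair"].voxels
        corrected_mean = suvc.voxels[lesion].mean()
        # blood-free forward model: (1-vb) * convolution term only
        idx = int(np.argmin(np.abs(study.pet.schedule.mid_times_min - 60.0)))
        tissue_only = (
            np.asarray(study.truth["region_frame_means"]["lesion"])[idx]
            - vb * np.asarray(study.truth["region_frame_means"]["sinus"])[idx]
        )
        norm = study.meta.injected_activity_MBq / study.meta.body_weight_kg
        assert corrected_mean == pytest.approx(tissue_only / norm, rel=0.05)


class TestTbr:
    def _suv(self, arr):
        return SUVImage(np.asarray(arr, float), EYE)

    def test_worked_example(self):
        vox = np.ones((4, 4, 4))
        vox[0, 0, 0] = 2.0
        tum = np.zeros((4, 4, 4), bool)
        tum[0, 0, :2] = True
        contra = np.zeros((4, 4, 4), bool)
        contra[3, 3, :] = True
        r = tbr(self._suv(vox), _mask(tum), _mask(contra))
        assert r["tbr_max"] == pytest.approx(2.0)

    def test_identical_regions_give_unity(self):
        vox = np.full((3, 3, 3), 1.7)
        m = np.zeros((3, 3, 3), bool)
        m[1] = True
        r = tbr(self._suv(vox), _mask(m), _mask(m))
        assert r["tbr_max"] == pytest.approx(1.0)
        assert r["tbr_mean"] == pytest.approx(1.0)

    def test_invariant_under_global_rescaling(self):
        rng = np.random.default_rng(5)
        vox = rng.uniform(0.5, 3.0, size=(4, 4, 4))
        tum = np.zeros((4, 4, 4), bool)
        tum[:2] = True
        contra = ~tum
        r1 = tbr(self._suv(vox), _mask(tum), _mask(contra))
        r2 = tbr(self._suv(10.0 * vox), _mask(tum), _mask(contra))
        assert r1["tbr_max"] == pytest.approx(r2["tbr_max"])
        assert r1["tbr_mean"] == pytest.approx(r2["tbr_mean"])

    def test_grade_iv_phantom_tbr_at_least_2(self, noisy_study):
        from fpia_quant.pet_static import compute_suv, static_window

        static = static_window(noisy_study.pet, "frame_nearest_60")
        suv = compute_suv(static, noisy_study.meta)
        r = tbr(suv, noisy_study.masks["lesion_flair"], noisy_study.masks["contralateral"])
        assert r["tbr_max"] >= 2.0


class TestThresholdMask:
    def _suv(self, arr):
        return SUVImage(np.asarray(arr, float), EYE)

    def test_uniform_image_selects_whole_search_region(self):
        search = np.zeros((4, 4, 4), bool)
        search[1:3, 1:3, 1:3] = True
        out = threshold_mask(self._suv(np.ones((4, 4, 4))), 0.4, _mask(search))
        assert np.array_equal(out.voxels, search)

    def test_single_hot_voxel(self):
        vox = np.ones((4, 4, 4))
        vox[2, 2, 2] = 10.0
        out = threshold_mask(self._suv(vox), 0.4, _mask(np.ones((4, 4, 4), bool)))
        assert out.n_voxels == 1
        assert out.voxels[2, 2, 2]

    def test_volume_nonincreasing_with_fraction_on_blurred_sphere(self, noisy_study):
        from fpia_quant.pet_static import compute_suv, static_window

        static = static_window(noisy_study.pet, "last5_mean")
        suv = compute_suv(static, noisy_study.meta)
        search = noisy_study.masks.get("brain", noisy_study.masks["lesion_flair"])
        vols = [
            threshold_mask(suv, f, search).n_voxels
            for f in (0.3, 0.35, 0.4, 0.5, 0.6)
        ]
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_lower_fraction_mask_contains_higher(self, noisy_study):
        from fpia_quant.pet_static import compute_suv, static_window

        static = static_window(noisy_study.pet, "last5_mean")
        suv = compute_suv(static, noisy_study.meta)
        search = noisy_study.masks["lesion_flair"]
        m30 = threshold_mask(suv, 0.3, search)
        m40 = threshold_mask(suv, 0.4, search)
        assert np.all(m30.voxels | ~m40.voxels)  # m40 subset of m30

    def test_all_zero_image_raises(self):
        with pytest.raises(ValidationError):
            threshold_mask(self._suv(np.zeros((3, 3, 3))), 0.4, _mask(np.ones((3, 3, 3))))


class TestOverlapScores:
    def test_dice_identities(self):
        a = np.zeros((4, 4, 4), bool)
        a[:2] = True
        assert dice(_mask(a), _mask(a)) == 1.0
        assert dice(_mask(a), _mask(~a)) == 0.0

    def test_dice_worked_example(self):
        """|A| = 2, |B| = 4, |A n B| = 2 -> 2*2/(2+4) = 0.6667."""
        a = np.zeros((4, 4, 4), bool)
        a[0, 0, :2] = True
        b = np.zeros((4, 4, 4), bool)
        b[0, 0, :4] = True
        assert dice(_mask(a), _mask(b)) == pytest.approx(2 * 2 / (2 + 4))

    def test_dice_symmetric(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(size=(5, 5, 5)) > 0.5
        b = rng.uniform(size=(5, 5, 5)) > 0.5
        assert dice(_mask(a), _mask(b)) == dice(_mask(b), _mask(a))

    def test_both_empty_raises(self):
        z = np.zeros((3, 3, 3), bool)
        with pytest.raises(ValidationError):
            dice(_mask(z), _mask(z))

    @pytest.mark.parametrize(
        "n_mri,n_suv,expected", [(4, 4, 0.0), (8, 4, 100.0), (1, 4, -75.0)]
    )
    def test_volume_variation_formula(self, n_mri, n_suv, expected):
        mri = np.zeros((4, 4, 4), bool)
        mri.ravel()[:n_mri] = True
        suv = np.zeros((4, 4, 4), bool)
        suv.ravel()[:n_suv] = True
        assert volume_variation(_mask(mri), _mask(suv)) == pytest.approx(expected)

    def test_volume_variation_not_symmetric(self):
        mri = np.zeros((4, 4, 4), bool)
        mri.ravel()[:8] = True
        suv = np.zeros((4, 4, 4), bool)
        suv.ravel()[:4] = True
        assert volume_variation(_mask(mri), _mask(suv)) != volume_variation(
            _mask(suv), _mask(mri)
        )

    def test_empty_suv_mask_raises(self):
        m = np.zeros((3, 3, 3), bool)
        m[0, 0, 0] = True
        with pytest.raises(ValidationError):
            volume_variation(_mask(m), _mask(np.zeros((3, 3, 3), bool)))
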