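"""Affine alignment, diffeomorphic registration, warping, similarity."""

import numpy as np
import pytest
from dataclasses import replace

from pallidex.errors import AlignmentError, ContractError, SimilarityError
from pallidex.phantom import make_template, random_deformation
from pallidex.registration import (
    DeformationField,
    RegistrationSettings,
    affine_align,
    build_group_template,
    diffeomorphic_register,
    invert_disp,
    pearson_similarity,
    resample_affine,
    warp,
    warp_array,
)
from pallidex.volume_io import Volume


def _vol(data, spacing=(1.0, 1.0, 1.0)):
    return Volume(np.asarray(data, float), spacing, np.diag(list(spacing) + [1.0]))


class TestPearson:
    def test_self_correlation(self, small_template):
        vol = small_template[0]
        assert pearson_similarity(vol, vol) == pytest.approx(1.0)

    def test_sign_symmetry(self, rng):
        a = rng.standard_normal((8, 8, 8))
        a -= a.mean()
        shift = a.max() * 2
        va, vb = _vol(a + shift), _vol(-a + shift)   # keep data finite/pos
        assert pearson_similarity(va, vb) == pytest.approx(-1.0)

    def test_three_voxel_example(self):
        a = np.zeros((3, 1, 1)); a[:, 0, 0] = [1, 2, 3]
        b = np.zeros((3, 1, 1)); b[:, 0, 0] = [1, 2, 4]
        r = pearson_similarity(_vol(a), _vol(b))
        # oracle: direct product-moment formula
        x, y = np.array([1, 2, 3.0]), np.array([1, 2, 4.0])
        expected = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert r == pytest.approx(expected, abs=1e-12)
        assert r == pytest.approx(0.9819805, abs=1e-6)

    def test_zero_variance_raises(self):
        with pytest.raises(SimilarityError):
            pearson_similarity(_vol(np.ones((4, 4, 4))),
                               _vol(np.random.default_rng(0).random((4, 4, 4))))

    def test_symmetry_and_rescale_invariance(self, rng):
        a = _vol(rng.random((6, 6, 6)))
        b = _vol(rng.random((6, 6, 6)))
        r1 = pearson_similarity(a, b)
        assert pearson_similarity(b, a) == pytest.approx(r1, abs=1e-12)
        assert pearson_similarity(a.with_data(a.data * 7.3 + 0.0), b) == \
            pytest.approx(r1, abs=1e-10)


class TestAffine:
    def test_self_alignment_identity(self, small_template):
        vol = small_template[0]
        T = affine_align(vol, vol)
        assert np.allclose(T, np.eye(4), atol=1e-3)

    def test_translation_recovery(self, small_template):
        vol = small_template[0]
        moved = vol.with_data(np.roll(vol.data, 3, axis=0))
        T = affine_align(vol, moved)
        # fixed->moving: sampling the original 3 voxels (12 mm) back
        assert abs(T[0, 3] - (-3 * vol.spacing[0])) < 0.5 * vol.spacing[0]
        assert abs(T[1, 3]) < 0.5 * vol.spacing[1]

    def test_constant_image_rejected(self, small_template):
        vol = small_template[0]
        with pytest.raises(AlignmentError):
            affine_align(_vol(np.ones((8, 8, 8))), vol)

    def test_resample_identity(self, small_template):
        vol = small_template[0]
        out = resample_affine(vol, np.eye(4), vol)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-10)


class TestWarp:
    def test_zero_field_identity(self, small_template):
        vol, fine, _ = small_template
        field = DeformationField.zero(vol)
        np.testing.assert_allclose(warp(vol, field).data, vol.data, atol=1e-12)
        np.testing.assert_array_equal(warp(fine, field).labels, fine.labels)

    def test_label_warp_preserves_id_set(self, small_spec, small_template, rng):
        _, fine, _ = small_template
        field = random_deformation(small_spec, rng)
        out = warp(fine, field)
        assert set(np.unique(out.labels)) <= set(np.unique(fine.labels))

    def test_linear_interpolation_for_labels_rejected(self, small_template):
        _, fine, _ = small_template
        field = DeformationField.zero(small_template[0])
        with pytest.raises(ContractError):
            warp(fine, field, interpolation="linear")

    def test_warp_then_inverse_recovers_volume(self, desk_spec, desk_template, rng):
        vol, _, _ = desk_template
        field = random_deformation(desk_spec, rng)
        dv = field.disp_vox()
        warped = warp_array(vol.data, dv)
        back = warp_array(warped, invert_disp(dv))
        wm = desk_spec.tissue_means[2]
        interior = np.s_[2:-2, 2:-2, 2:-2]
        mad = np.abs(back[interior] - vol.data[interior]).mean()
        assert mad < 0.02 * wm

    def test_warp_matches_simpleitk(self, small_spec, small_template, rng):
        """Independent oracle: SimpleITK resampling through the same field."""
        sitk = pytest.importorskip("SimpleITK")
        vol = small_template[0]
        field = random_deformation(small_spec, rng)
        mine = warp(vol, field).data

        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T))
        img.SetSpacing(vol.spacing)
        disp = np.stack([field.disp[k].T for k in range(3)], axis=-1)
        disp_img = sitk.GetImageFromArray(np.ascontiguousarray(disp), isVector=True)
        disp_img.SetSpacing(vol.spacing)
        tx = sitk.DisplacementFieldTransform(
            sitk.Cast(disp_img, sitk.sitkVectorFloat64))
        res = sitk.Resample(img, img, tx, sitk.sitkLinear, 0.0)
        theirs = sitk.GetArrayFromImage(res).T
        interior = np.s_[2:-2, 2:-2, 2:-2]
        np.testing.assert_allclose(mine[interior], theirs[interior],
                                   atol=1e-3 * vol.data.max())


class TestDiffeomorphic:
    def test_identity_registration_small_displacement(self, small_template):
        vol = small_template[0]
        field = diffeomorphic_register(vol, vol, RegistrationSettings.fast())
        assert field.magnitude_vox().mean() < 0.1

    def test_known_field_recovery_64cubed(self, desk_spec, desk_template):
        vol, fine, _ = desk_template
        rng = np.random.default_rng(7)
        truth = random_deformation(desk_spec, rng)
        dv = truth.disp_vox()
        subject = vol.with_data(warp_array(vol.data, dv))
        rec = diffeomorphic_register(vol, subject)
        brain = warp_array((fine.labels > 0).astype(float), dv, order=0) > 0.5
        epe = np.sqrt(((rec.disp_vox() - dv) ** 2).sum(axis=0))
        assert epe[brain].mean() < 1.0

    def test_positive_jacobian(self, small_spec, small_template, rng):
        vol = small_template[0]
        truth = random_deformation(small_spec, rng)
        subject = vol.with_data(warp_array(vol.data, truth.disp_vox()))
        rec = diffeomorphic_register(vol, subject, RegistrationSettings.fast())
        assert rec.min_jacobian() > 0

    def test_residual_never_worse_than_start(self, small_template, rng):
        vol = small_template[0]
        other = vol.with_data(vol.data + rng.normal(0, 0.3, vol.shape))

        def residual(m, f):
            return 1 - np.corrcoef(m.ravel(), f.ravel())[0, 1]

        field = diffeomorphic_register(other, vol, RegistrationSettings.fast())
        assert residual(warp(other, field).data, vol.data) <= \
            residual(other.data, vol.data) + 1e-9

    def test_field_nifti_round_trip(self, small_spec, tmp_path, rng):
        field = random_deformation(small_spec, rng)
        p = tmp_path / "field.nii.gz"
        field.save(p)
        loaded = DeformationField.load(p)
        np.testing.assert_allclose(loaded.disp, field.disp, atol=1e-6)


class TestGroupTemplate:
    def test_fixed_point_of_identical_images(self, small_template):
        vol = small_template[0]
        st = RegistrationSettings.fast()
        template, fields = build_group_template([vol, vol, vol], st, rounds=1)
        np.testing.assert_allclose(template.data, vol.data, atol=1e-8)
        for f in fields:
            assert f.magnitude_vox().mean() < 0.1

    def test_permutation_invariance(self, small_spec, small_library):
        imgs = [a.volume for a in small_library[:3]]
        st = RegistrationSettings.fast()
        t1, _ = build_group_template(imgs, st, rounds=1)
        t2, _ = build_group_template(imgs[::-1], st, rounds=1)
        assert np.abs(t1.data - t2.data).max() < 1e-6

    def test_template_closer_to_truth_than_single_images(self, small_spec):
        truth, _, _ = make_template(small_spec)
        lib_spec = replace(small_spec, noise_sd=0.05)
        from pallidex.phantom import make_atlas_library
        lib = make_atlas_library(6, lib_spec, seed=31)
        imgs = [a.volume for a in lib]
        template, _ = build_group_template(imgs, RegistrationSettings(),
                                           rounds=3)

        def corr(a, b):
            return np.corrcoef(a.ravel(), b.ravel())[0, 1]

        r_template = corr(template.data, truth.data)
        r_singles = [corr(im.data, truth.data) for im in imgs]
        assert r_template > max(r_singles)

    def test_too_few_images(self, small_template):
        with pytest.raises(ContractError):
            build_group_template([small_template[0]])
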