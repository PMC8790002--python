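import numpy as np
import pytest
from scipy import ndimage

from livreg.grid import LabelMap3D
from livreg.phantom import (
    AffineMagnitude,
    PhantomConfig,
    generate_phantom,
    simulate_modality,
    simulate_spect,
)
from livreg.transform import warp

SMALL = dict(grid_shape=(32, 32, 32), n_landmarks=2, landmark_radius_mm=6.0)


class TestConfigValidation:
    def test_amplitude_must_stay_below_smoothness(self):
        with pytest.raises(ValueError, match="smoothness"):
            PhantomConfig(warp_amplitude_mm=30.0, warp_smoothness_mm=20.0)

    def test_unknown_modality_rejected(self):
        with pytest.raises(ValueError, match="modality"):
            PhantomConfig(modality="pet")

    def test_negative_landmark_count_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(n_landmarks=-1)


class TestGeneratorDeterminismAndGeometry:
    def test_same_config_bit_identical(self):
        cfg = PhantomConfig(seed=5, **SMALL)
        a, b = generate_phantom(cfg), generate_phantom(cfg)
        np.testing.assert_array_equal(a.reference_image.values, b.reference_image.values)
        np.testing.assert_array_equal(a.floating_image.values, b.floating_image.values)
        np.testing.assert_array_equal(a.spect_counts.values, b.spect_counts.values)
        np.testing.assert_array_equal(a.truth_field.vectors, b.truth_field.vectors)

    def test_identity_deformation_gives_equal_masks(self):
        cfg = PhantomConfig(seed=3, warp_amplitude_mm=0.0,
                            affine_magnitude=AffineMagnitude(0.0, 0.0, 0.0), **SMALL)
        s = generate_phantom(cfg)
        np.testing.assert_array_equal(s.reference_liver.labels, s.floating_liver.labels)
        for r, f in zip(s.reference_landmarks, s.floating_landmarks):
            np.testing.assert_array_equal(r.labels, f.labels)
        np.testing.assert_allclose(s.truth_affine.matrix, np.eye(3))
        assert np.abs(s.truth_field.vectors).max() == 0.0

    def test_landmarks_disjoint_and_inside_liver(self):
        s = generate_phantom(PhantomConfig(seed=7, grid_shape=(40, 40, 40), n_landmarks=3))
        assert len(s.reference_landmarks) == 3
        combined = np.zeros(s.reference_liver.grid.shape, dtype=int)
        for space_liver, landmarks in [
            (s.reference_liver, s.reference_landmarks),
            (s.floating_liver, s.floating_landmarks),
        ]:
            for lm in landmarks:
                assert np.all((lm.labels > 0) <= (space_liver.labels > 0))
        for lm in s.reference_landmarks:
            combined += lm.labels > 0
        assert combined.max() == 1  # pairwise disjoint, voxel-wise check

    def test_liver_single_connected_component_and_plausible_volume(self, small_study):
        fg = small_study.reference_liver.labels > 0
        _, n = ndimage.label(fg, structure=ndimage.generate_binary_structure(3, 1))
        assert n == 1
        assert 0.05 < fg.mean() < 0.45

    def test_too_many_landmarks_fail_loudly(self):
        with pytest.raises(ValueError, match="landmark"):
            generate_phantom(PhantomConfig(seed=1, grid_shape=(24, 24, 24),
                                           n_landmarks=40, landmark_radius_mm=8.0))

    def test_truth_field_pulls_floating_masks_onto_reference(self, small_study):
        s = small_study
        from livreg.evaluation import dsc

        back = warp(s.floating_liver, s.truth_field, "nearest")
        assert dsc(back, s.reference_liver) > 0.95

    def test_truth_maps_landmark_centroids(self, small_study):
        # floating centroid must equal the ground-truth image of the
        # reference centroid to within half a voxel
        s = small_study
        from livreg.phantom import _interp_field

        spacing = max(s.reference_liver.grid.spacing_mm)
        for r, f in zip(s.reference_landmarks, s.floating_landmarks):
            c_r = r.grid.index_to_world(np.argwhere(r.labels > 0).mean(axis=0))
            c_f = f.grid.index_to_world(np.argwhere(f.labels > 0).mean(axis=0))
            d = _interp_field(s.truth_field.vectors, s.truth_field.grid, c_r[None])[0]
            assert np.linalg.norm(c_r + d - c_f) < 0.5 * spacing


class TestModalitySimulation:
    @pytest.fixture
    def labels(self, small_study):
        return small_study.reference_labelmap()

    def test_noise_free_pseudo_ct_piecewise_constant(self, labels):
        img = simulate_modality(labels, "pseudo_ct", noise_sd=0.0, seed=0)
        for lab in np.unique(labels.labels):
            vals = img.values[labels.labels == lab]
            assert vals.max() == vals.min()

    def test_seed_determinism(self, labels):
        a = simulate_modality(labels, "pseudo_mr", noise_sd=3.0, seed=9)
        b = simulate_modality(labels, "pseudo_mr", noise_sd=3.0, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_cross_modality_relation_is_nonlinear(self, labels):
        # no straight line maps pseudo-CT to pseudo-MR intensities: the
        # least-squares line must leave substantial residual
        ct = simulate_modality(labels, "pseudo_ct", noise_sd=0.0, seed=1)
        mr = simulate_modality(labels, "pseudo_mr", noise_sd=0.0, seed=1)
        x = ct.values.ravel()
        y = mr.values.ravel()
        slope, intercept = np.polyfit(x, y, 1)
        residual = np.sqrt(np.mean((y - slope * x - intercept) ** 2))
        assert residual > 1.0

    def test_unknown_modality_rejected(self, labels):
        with pytest.raises(ValueError, match="modality"):
            simulate_modality(labels, "spect", noise_sd=0.0, seed=0)


class TestSpectSimulation:
    def test_noise_free_ratio_exact(self, small_study):
        s = small_study
        counts = simulate_spect(s.reference_landmarks, s.reference_liver,
                                lesion_to_liver_ratio=5.0, psf_fwhm_mm=0.0,
                                poisson=False, background_counts=10.0)
        lesion = np.zeros(s.reference_liver.grid.shape, dtype=bool)
        for lm in s.reference_landmarks:
            lesion |= lm.labels > 0
        liver_bg = (s.reference_liver.labels > 0) & ~lesion
        assert np.all(counts.values[lesion] == 50.0)
        assert np.all(counts.values[liver_bg] == 10.0)
        assert np.all(counts.values[s.reference_liver.labels == 0] == 0.0)

    def test_no_landmarks_uniform_inside_liver(self, small_study):
        s = small_study
        counts = simulate_spect([], s.reference_liver, psf_fwhm_mm=0.0, poisson=False)
        inside = counts.values[s.reference_liver.labels > 0]
        assert inside.max() == inside.min()

    def test_counts_nonnegative_with_blur_and_noise(self, small_study):
        s = small_study
        counts = simulate_spect(s.reference_landmarks, s.reference_liver,
                                psf_fwhm_mm=12.0, seed=4)
        assert counts.values.min() >= 0.0

    def test_poisson_mean_converges_to_noise_free_map(self, small_study):
        # Monte-Carlo mean over many seeds within 3 standard errors
        s = small_study
        clean = simulate_spect(s.reference_landmarks, s.reference_liver,
                               psf_fwhm_mm=10.0, poisson=False)
        n = 120
        acc = np.zeros(clean.values.shape)
        for seed in range(n):
            acc += simulate_spect(s.reference_landmarks, s.reference_liver,
                                  psf_fwhm_mm=10.0, seed=seed).values
        mean = acc / n
        sel = clean.values > 1.0
        se = np.sqrt(clean.values[sel] / n)
        frac_inside = np.mean(np.abs(mean[sel] - clean.values[sel]) <= 3 * se)
        assert frac_inside > 0.99

    def test_empty_liver_rejected(self, small_study):
        empty = LabelMap3D(small_study.reference_liver.grid,
                           np.zeros(small_study.reference_liver.grid.shape, dtype=np.uint8))
        with pytest.raises(ValueError, match="empty"):
            simulate_spect([], empty)
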