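import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from livreg.grid import Image3D, LabelMap3D, VolumeGrid
from livreg.registration import (
    LiverRegistration,
    LossWeights,
    RegistrationConfig,
    _spring_gradient_arr,
    register_nonrigid,
    spring_energy,
    total_loss,
)
from livreg.transform import AffineTransform, DisplacementField, affine_to_field

FAST = RegistrationConfig(levels=2, max_iter=10)


class TestSpringEnergy:
    def test_zero_field_has_zero_energy(self, unit_grid):
        assert spring_energy(DisplacementField.zero(unit_grid), 1.0) == 0.0

    def test_uniform_translation_is_an_isometry(self, unit_grid):
        vec = np.broadcast_to([3.0, -1.0, 2.0], unit_grid.shape + (3,)).copy()
        assert spring_energy(DisplacementField(unit_grid, vec), 2.0) == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("spacing", [1.0, 2.5])
    def test_single_stretched_pair(self, spacing):
        grid = VolumeGrid((2, 1, 1), (spacing, 1.0, 1.0))
        vec = np.zeros((2, 1, 1, 3))
        vec[1, 0, 0, 0] = spacing  # second voxel pushed one rest length away
        k = 0.7
        assert spring_energy(DisplacementField(grid, vec), k) == pytest.approx(k * spacing**2)

    @pytest.mark.parametrize("seed", range(3))
    def test_invariance_under_global_rigid_motion(self, seed):
        # applying any rotation+translation to the deformed points p + d
        # preserves all pairwise distances, hence the energy
        grid = VolumeGrid((6, 6, 6), (2.0, 1.5, 1.0))
        rng = np.random.default_rng(seed)
        vec = rng.normal(scale=0.4, size=grid.shape + (3,))
        fld = DisplacementField(grid, vec)
        e0 = spring_energy(fld, 1.0)
        rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        shift = rng.normal(size=3) * 10
        pts = grid.world_points()
        moved = (pts + vec).reshape(-1, 3) @ rot.T + shift
        vec_rigid = moved.reshape(grid.shape + (3,)) - pts
        e1 = spring_energy(DisplacementField(grid, vec_rigid), 1.0)
        assert e1 == pytest.approx(e0, rel=1e-8, abs=1e-10)

    @pytest.mark.parametrize("seed", range(2))
    def test_gradient_matches_finite_differences(self, seed):
        grid = VolumeGrid((4, 3, 3), (1.5, 1.0, 2.0))
        rng = np.random.default_rng(seed)
        vec = rng.normal(scale=0.3, size=grid.shape + (3,))
        k = 0.8
        grad = _spring_gradient_arr(vec, grid.spacing_mm, k)
        eps = 1e-6
        for _ in range(10):
            ijk = tuple(rng.integers(0, s) for s in grid.shape) + (rng.integers(0, 3),)
            plus = vec.copy()
            plus[ijk] += eps
            minus = vec.copy()
            minus[ijk] -= eps
            fd = (spring_energy(DisplacementField(grid, plus), k)
                  - spring_energy(DisplacementField(grid, minus), k)) / (2 * eps)
            assert grad[ijk] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestTotalLoss:
    def test_pure_regularizer_when_weights_vanish(self, small_study):
        s = small_study
        rng = np.random.default_rng(0)
        vec = rng.normal(scale=0.5, size=s.reference_image.grid.shape + (3,))
        fld = DisplacementField(s.reference_image.grid, vec)
        w = LossWeights(w_I=0.0, w_S=0.0, rigidity_k=0.3)
        tot, _, _, l_r = total_loss(s.reference_image, s.floating_image,
                                    s.reference_liver, s.floating_liver, fld, w, "seg")
        assert tot == pytest.approx(l_r)
        assert l_r == pytest.approx(spring_energy(fld, 0.3))

    def test_zero_field_identical_inputs(self, small_study):
        s = small_study
        fld = DisplacementField.zero(s.reference_image.grid)
        w = LossWeights(w_I=2.0, w_S=1.0, rigidity_k=0.1)
        tot, l_i, l_s, l_r = total_loss(s.reference_image, s.reference_image,
                                        s.reference_liver, s.reference_liver, fld, w, "seg")
        assert l_s == 0.0 and l_r == 0.0
        assert tot == pytest.approx(2.0 * l_i)

    def test_components_sum_to_total(self, small_study):
        s = small_study
        rng = np.random.default_rng(1)
        fld = DisplacementField(s.reference_image.grid,
                                rng.normal(scale=1.0, size=s.reference_image.grid.shape + (3,)))
        w = LossWeights(w_I=0.6, w_S=1.7, rigidity_k=0.2)
        tot, l_i, l_s, l_r = total_loss(s.reference_image, s.floating_image,
                                        s.reference_liver, s.floating_liver, fld, w, "seg")
        assert tot == pytest.approx(w.w_I * l_i + w.w_S * l_s + l_r, abs=1e-12)

    def test_image_mode_has_no_segmentation_term(self, small_study):
        s = small_study
        fld = DisplacementField.zero(s.reference_image.grid)
        _, _, l_s, _ = total_loss(s.reference_image, s.floating_image,
                                  None, None, fld, LossWeights(), "image")
        assert l_s == 0.0

    def test_guided_mode_requires_labels(self, small_study):
        s = small_study
        fld = DisplacementField.zero(s.reference_image.grid)
        with pytest.raises(ValueError, match="label"):
            total_loss(s.reference_image, s.floating_image, None, None, fld,
                       LossWeights(), "seg")


class TestLossWeights:
    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(w_I=-1.0)
        with pytest.raises(ValueError):
            LossWeights(rigidity_k=0.0)


class TestNonRigid:
    def test_pure_spring_keeps_zero_field(self, small_study):
        s = small_study
        init = DisplacementField.zero(s.reference_image.grid)
        res = register_nonrigid(s.reference_image, s.floating_image, init,
                                LossWeights(w_I=0.0, w_S=0.0, rigidity_k=0.5),
                                mode="image", config=FAST)
        assert np.abs(res.field.vectors).max() == pytest.approx(0.0, abs=1e-12)

    def test_descent_contract_trace_monotone(self, small_study):
        s = small_study
        init = DisplacementField.zero(s.reference_image.grid)
        res = register_nonrigid(
            s.reference_image, s.floating_image, init, LossWeights(1.0, 1.0, 0.05),
            mode="seg", config=FAST,
            ref_labels=s.reference_liver, flo_labels=s.floating_liver,
        )
        for _, level_trace in res.loss_trace.groupby("level"):
            totals = level_trace["total"].to_numpy()
            assert np.all(np.diff(totals) <= 1e-9)

    def test_trace_total_is_recorded_weighted_sum(self, small_study):
        s = small_study
        init = DisplacementField.zero(s.reference_image.grid)
        w = LossWeights(0.8, 1.2, 0.05)
        res = register_nonrigid(
            s.reference_image, s.floating_image, init, w, mode="seg", config=FAST,
            ref_labels=s.reference_liver, flo_labels=s.floating_liver,
        )
        tr = res.loss_trace
        np.testing.assert_allclose(
            tr["total"], w.w_I * tr["L_I"] + w.w_S * tr["L_S"] + tr["L_R"], atol=1e-9)

    def test_identical_pair_total_does_not_increase(self, small_study):
        s = small_study
        init = DisplacementField.zero(s.reference_image.grid)
        res = register_nonrigid(s.reference_image, s.reference_image, init,
                                LossWeights(1.0, 0.0, 0.1), mode="image", config=FAST)
        tr = res.loss_trace
        assert tr.iloc[-1]["total"] <= tr.iloc[0]["total"] + 1e-12

    def test_init_field_must_live_on_reference_grid(self, small_study):
        s = small_study
        wrong = DisplacementField.zero(VolumeGrid((8, 8, 8), (3.0, 3.0, 3.0)))
        with pytest.raises(ValueError, match="reference grid"):
            register_nonrigid(s.reference_image, s.floating_image, wrong,
                              LossWeights(), mode="image", config=FAST)


class TestModelSurface:
    def test_skip_nonrigid_returns_exact_affine_field(self, small_study):
        s = small_study
        config = RegistrationConfig(skip_nonrigid=True)
        model = LiverRegistration.from_study(s, mode="seg", config=config)
        res = model.fit()
        expected = affine_to_field(res.affine, s.reference_image.grid)
        np.testing.assert_array_equal(res.field.vectors, expected.vectors)

    def test_guided_model_requires_labels(self, small_study):
        s = small_study
        with pytest.raises(ValueError, match="guidance"):
            LiverRegistration(s.reference_image, s.floating_image, mode="seg")

    def test_summary_reports_mode_and_weights(self, small_study):
        s = small_study
        config = RegistrationConfig(skip_nonrigid=True)
        res = LiverRegistration.from_study(s, mode="seg_lm", config=config).fit(
            LossWeights(0.5, 2.0, 0.07))
        text = res.summary()
        assert "seg_lm" in text and "w_S=2" in text and "translation" in text

    def test_warped_labels_are_hard(self, small_study):
        s = small_study
        config = RegistrationConfig(skip_nonrigid=True)
        res = LiverRegistration.from_study(s, mode="seg", config=config).fit()
        assert set(np.unique(res.warped_labels.labels)) <= {0, 1, 2}
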