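"""Registration: focus box geometry, rigid recovery, hybrid DIR recovery,
and mask/image warping contracts."""

import numpy as np
import pytest

from doseaccum.core import DisplacementField, GridDescriptor, ImageVolume, sample_volume
from doseaccum.metrics import geometric_indices
from doseaccum.phantom import DeformationSpec, generate_daily_case
from doseaccum.registration import (
    RegistrationConfig,
    RigidTransform,
    make_focus_box,
    register_hybrid_deformable,
    register_rigid,
    warp_image,
    warp_mask,
)


class TestFocusBox:
    grid = GridDescriptor((120, 120, 120), (1.0, 1.0, 1.0))

    def _slab(self, half_extents, center=(60, 60, 60)):
        mask = np.zeros(self.grid.shape, dtype=bool)
        sl = tuple(slice(c - h, c + h + 1) for c, h in zip(center, half_extents))
        mask[sl] = True
        return mask

    def test_margins_expand_each_side(self):
        """A 40 mm-wide PTV grows to 100 mm in RL under the 30 mm margin."""
        mask = self._slab((20, 10, 10))  # 41 voxels ~ 40 mm span RL
        box = make_focus_box(mask, self.grid)
        width_rl = box.upper[0] - box.lower[0]
        assert width_rl == pytest.approx(40.0 + 2 * 30.0)
        width_si = box.upper[2] - box.lower[2]
        assert width_si == pytest.approx(20.0 + 2 * 20.0)

    def test_zero_margins_equal_bounding_box(self):
        mask = self._slab((5, 6, 7))
        box = make_focus_box(mask, self.grid, margins_mm=(0.0, 0.0, 0.0))
        idx = np.argwhere(mask)
        assert np.allclose(box.lower, idx.min(axis=0))
        assert np.allclose(box.upper, idx.max(axis=0))

    def test_clipped_to_grid_extent(self):
        mask = self._slab((10, 10, 10), center=(10, 60, 60))  # touches RL edge
        box = make_focus_box(mask, self.grid)
        assert box.lower[0] == 0.0  # clipped at grid edge

    def test_empty_mask_raises(self):
        from doseaccum.core import GeometryError

        with pytest.raises(GeometryError):
            make_focus_box(np.zeros(self.grid.shape, dtype=bool), self.grid)


class TestRigid:
    def test_self_registration_is_identity(self, med_case, recovery):
        tf = register_rigid(med_case.image, med_case.image, recovery["box"])
        assert np.abs(tf.translation_mm).max() < 0.1
        assert np.abs(tf.rotation_rad).max() < 1e-3

    def test_translation_recovery_within_half_voxel(self, med_case, recovery):
        grid = med_case.grid
        t = np.array([4.0, -3.0, 2.0])
        u = DisplacementField(
            np.broadcast_to(t[:, None, None, None], (3, *grid.shape)).copy(), grid
        )
        moving = warp_image(u, med_case.image)  # moving(p) = fixed(p + t)
        tf = register_rigid(med_case.image, moving, recovery["box"])
        # fixed(p) ~ moving(p + t_rec) = fixed(p + t_rec + t)  =>  t_rec = -t
        assert np.abs(np.asarray(tf.translation_mm) + t).max() < 0.5 * grid.spacing.max()

    def test_rotation_recovery_within_half_degree(self, med_case, recovery):
        grid = med_case.grid
        box = recovery["box"]
        rot = RigidTransform((0.0, 0.0, np.deg2rad(3.0)), center_mm=tuple(box.center_mm))
        pts = np.stack(np.meshgrid(*[grid.axis_coords(a) for a in range(3)], indexing="ij"))
        idx = (rot.apply(pts) - grid.origin[:, None, None, None]) / grid.spacing[:, None, None, None]
        moving = ImageVolume(sample_volume(med_case.image, idx, edge="nearest"), grid)
        tf = register_rigid(med_case.image, moving, box)
        assert abs(abs(np.rad2deg(tf.rotation_rad[2])) - 3.0) < 0.5

    def test_inverse_composes_to_identity(self):
        tf = RigidTransform((0.1, -0.2, 0.3), (5.0, -2.0, 1.0), (10.0, 10.0, 10.0))
        pts = np.random.default_rng(0).uniform(0, 50, size=(3, 20))
        assert np.abs(tf.inverse().apply(tf.apply(pts)) - pts).max() < 1e-9


class TestHybridDeformable:
    def test_self_registration_field_near_zero(self, med_case, recovery):
        res = register_hybrid_deformable(
            med_case.image,
            med_case.image,
            med_case.structures,
            med_case.structures,
            box=recovery["box"],
        )
        assert res.field.max_magnitude_mm < 0.2

    def test_truth_field_recovery_ptv_dice(self, med_case, deformed_daily, recovery):
        """Warping the daily PTV through the recovered field agrees with the
        truth-field warp at DICE >= 0.95 and MSD <= 1 voxel."""
        grid = med_case.grid
        w = warp_mask(recovery["result"].field, deformed_daily.structures["PTV_eval"], grid)
        wt = warp_mask(deformed_daily.truth_field, deformed_daily.structures["PTV_eval"], grid)
        gi = geometric_indices(w, wt, grid.spacing)
        assert gi.dice >= 0.95
        assert gi.hd_mean_mm <= grid.spacing.max()

    def test_cost_trace_monotone_within_levels(self, recovery):
        for trace in recovery["result"].cost_trace:
            assert len(trace) >= 2
            assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_contour_only_mode_aligns_rectum(self, med_case, recovery):
        deform = DeformationSpec(seed=3, random_field_amp_mm=5.0)
        daily = generate_daily_case(med_case, deform, 1)
        cfg = RegistrationConfig(intensity_weight=0.0)
        res = register_hybrid_deformable(
            med_case.image,
            daily.image,
            med_case.structures,
            daily.structures,
            cfg=cfg,
            box=recovery["box"],
        )
        grid = med_case.grid
        w = warp_mask(res.field, daily.structures["rectum"], grid)
        gi = geometric_indices(w, med_case.structures["rectum"], grid.spacing)
        assert gi.hd_mean_mm <= grid.spacing.max()

    def test_missing_structure_skipped_with_warning(self, med_case, deformed_daily, recovery):
        partial = deformed_daily.structures.copy()
        del partial.masks["penile_bulb"]
        cfg = RegistrationConfig(pyramid_factors=(4,), max_iterations=2)
        with pytest.warns(UserWarning, match="penile_bulb"):
            register_hybrid_deformable(
                med_case.image,
                deformed_daily.image,
                med_case.structures,
                partial,
                cfg=cfg,
                box=recovery["box"],
            )


class TestWarping:
    grid = GridDescriptor((20, 20, 20), (1.0, 1.0, 1.0))

    def _shift_field(self, t):
        vec = np.broadcast_to(np.asarray(t, float)[:, None, None, None], (3, *self.grid.shape))
        return DisplacementField(vec.copy(), self.grid)

    def test_identity_leaves_mask_and_image_unchanged(self, rng):
        mask = rng.uniform(size=self.grid.shape) > 0.7
        img = ImageVolume(rng.normal(size=self.grid.shape), self.grid)
        ident = DisplacementField.identity(self.grid)
        assert np.array_equal(warp_mask(ident, mask, self.grid), mask)
        assert np.array_equal(warp_image(ident, img).data, img.data)

    def test_integer_translation_shifts_exactly(self, rng):
        mask = np.zeros(self.grid.shape, dtype=bool)
        mask[8:12, 8:12, 8:12] = True
        out = warp_mask(self._shift_field((3.0, 0.0, 0.0)), mask, self.grid)
        assert np.array_equal(out[5:9, 8:12, 8:12], mask[8:12, 8:12, 8:12])
        assert out.sum() == mask.sum()

    def test_truth_field_roundtrip_large_organ_dice(self, med_case, deformed_daily):
        grid = med_case.grid
        w = warp_mask(deformed_daily.truth_field, deformed_daily.structures["bladder"], grid)
        gi = geometric_indices(w, med_case.structures["bladder"], grid.spacing)
        assert gi.dice >= 0.98
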