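"""ROI definition/transfer, the relative-enhancement statistic, and the call."""

import numpy as np
import pytest

from cthaem.emap import EnhancementMap
from cthaem.phantom import VesselSpec, generate_case
from cthaem.register import RigidTransform
from cthaem.response import (NormalizationError, PlanarROI, classify_response,
                             define_normal_roi, define_tumor_roi, rasterize_roi,
                             relative_enhancement, transfer_roi)
from cthaem.volgeom import Mask

from _phantoms import TINY_ROI_AREA, identity_maps, tiny_spec


def _em(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return EnhancementMap(np.asarray(values, float), spacing, origin)


def _mask(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), label="tumor"):
    return Mask(np.asarray(values, bool), label=label, spacing=spacing, origin=origin)


def _ellipsoid_mask(shape, semi, spacing=1.0):
    c = (np.asarray(shape) - 1) / 2.0 * spacing
    ax = [np.arange(n) * spacing for n in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    vals = ((gx - c[0]) / semi[0]) ** 2 + ((gy - c[1]) / semi[1]) ** 2 \
        + ((gz - c[2]) / semi[2]) ** 2 <= 1.0
    return _mask(vals, spacing=(spacing,) * 3)


class TestTumorRoi:
    def test_sphere_selects_equatorial_axial_slice(self, clean_case_f05):
        case = clean_case_f05
        em_pre, _ = identity_maps(case)
        roi = define_tumor_roi(em_pre, case.truth.tumor_mask)
        r = case.spec.tumor_radius_mm
        assert roi.plane == "axial"  # tie between axial/coronal goes to axial
        assert abs(roi.slice_world_mm - case.spec.tumor_center_mm[2]) <= case.spec.spacing_mm
        assert roi.area_mm2 == pytest.approx(np.pi * r**2, rel=0.05)

    def test_tall_ellipsoid_selects_coronal(self):
        # semi-axes (10, 6, 14): axial max area 60*pi < coronal 140*pi
        mask = _ellipsoid_mask((40, 40, 40), (10.0, 6.0, 14.0))
        em = _em(np.zeros((40, 40, 40)))
        roi = define_tumor_roi(em, mask)
        assert roi.plane == "coronal"
        assert roi.area_mm2 == pytest.approx(np.pi * 10 * 14, rel=0.06)

    def test_single_voxel_tumor(self):
        vals = np.zeros((8, 8, 8), bool)
        vals[3, 4, 5] = True
        em = _em(np.zeros((8, 8, 8)))
        roi = define_tumor_roi(em, _mask(vals))
        inside, k = rasterize_roi(roi, em)
        assert k == 5
        assert inside.sum() == 1 and inside[3, 4]

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            define_tumor_roi(_em(np.zeros((4, 4, 4))), _mask(np.zeros((4, 4, 4))))


class TestNormalRoi:
    def test_avoids_vessels_in_contralateral_lobe(self):
        # vessel tube running through the contralateral (right, -x) lobe
        spec = tiny_spec(noise_sigma_hu=0.0, deformation_amplitude_mm=0.0)
        cx, cy, cz = spec.liver_center_mm
        contralateral_vessel = VesselSpec(
            points=np.array([[cx - 8.0, cy - 8.0, cz], [cx - 8.0, cy + 8.0, cz]]),
            presence="both",
        )
        spec.vessel_tree = spec.vessel_tree + [contralateral_vessel]
        case = generate_case(spec)
        em_pre, _ = identity_maps(case)
        t = case.truth
        roi = define_normal_roi(em_pre, t.liver_mask, "left", t.vessel_mask_pre,
                                area_mm2=TINY_ROI_AREA, lobe_split_x_mm=t.lobe_split_x_mm)
        inside, k = rasterize_roi(roi, em_pre)
        assert not np.any(inside & t.vessel_mask_pre.values[:, :, k])
        assert np.all(inside <= t.liver_mask.values[:, :, k])
        xs = em_pre.axis_coords(0)
        assert xs[np.where(inside.any(axis=1))[0]].max() < t.lobe_split_x_mm

    def test_no_vessel_mask_reduces_to_inscribed_disk(self, clean_case_f05):
        case = clean_case_f05
        em_pre, _ = identity_maps(case)
        roi = define_normal_roi(em_pre, case.truth.liver_mask, "left", None,
                                lobe_split_x_mm=case.truth.lobe_split_x_mm)
        assert roi.area_mm2 == pytest.approx(300.0, rel=1e-6)

    def test_no_room_raises_with_advice(self, clean_case_f05):
        case = clean_case_f05
        em_pre, _ = identity_maps(case)
        # a split plane beyond the liver leaves no contralateral parenchyma
        with pytest.raises(ValueError):
            define_normal_roi(em_pre, case.truth.liver_mask, "left", None,
                              lobe_split_x_mm=-1000.0)
        # a huge requested area cannot fit: the error advises a smaller one
        with pytest.raises(ValueError, match="smaller"):
            define_normal_roi(em_pre, case.truth.liver_mask, "left", None,
                              area_mm2=5000.0,
                              lobe_split_x_mm=case.truth.lobe_split_x_mm)


class TestTransferRoi:
    def _roi(self):
        verts = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 6.0], [0.0, 6.0]])
        return PlanarROI(plane="axial", slice_world_mm=5.0, vertices=verts)

    def test_identity_transform_is_identity(self):
        roi = self._roi()
        out = transfer_roi(roi, RigidTransform.identity())
        assert np.allclose(out.vertices, roi.vertices)
        assert out.slice_world_mm == roi.slice_world_mm

    def test_translation_moves_vertices_exactly(self):
        roi = self._roi()
        tf = RigidTransform(np.eye(3), np.array([4.0, -2.0, 1.5]))
        out = transfer_roi(roi, tf)
        assert np.allclose(out.vertices, roi.vertices + [4.0, -2.0])
        assert out.slice_world_mm == pytest.approx(6.5)

    @pytest.mark.parametrize("angle_deg", [7.0, 45.0, 160.0])
    def test_area_preserved_under_inplane_rotation(self, angle_deg):
        roi = self._roi()
        a = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(a), -np.sin(a), 0.0],
                        [np.sin(a), np.cos(a), 0.0],
                        [0.0, 0.0, 1.0]])
        out = transfer_roi(roi, RigidTransform(rot, np.zeros(3)))
        assert out.area_mm2 == pytest.approx(roi.area_mm2, rel=1e-6)


class TestRelativeEnhancement:
    def _setup(self, tumor_vals):
        """One slice: a 2x3 tumor rectangle with given values, normal block at 20."""
        vals = np.zeros((12, 12, 3))
        vals[1:3, 1:4, 1] = np.asarray(tumor_vals).reshape(2, 3)
        vals[6:10, 6:10, 1] = 20.0
        em = _em(vals)
        tumor = PlanarROI("axial", 1.0, np.array(
            [[0.5, 0.5], [2.5, 0.5], [2.5, 3.5], [0.5, 3.5]]), role="tumor")
        normal = PlanarROI("axial", 1.0, np.array(
            [[5.5, 5.5], [9.5, 5.5], [9.5, 9.5], [5.5, 9.5]]), role="normal")
        return em, tumor, normal

    def test_simple_ratio(self):
        em, tumor, normal = self._setup([60.0] * 6)
        out = relative_enhancement(em, tumor, normal)
        assert out.T == pytest.approx(3.0)
        assert out.mean_normal == pytest.approx(20.0)

    def test_high_attenuation_subset_vs_whole(self):
        em, tumor, normal = self._setup([0, 0, 0, 0, 40, 40])
        whole = relative_enhancement(em, tumor, normal, high_attenuation_mode=False)
        subset = relative_enhancement(em, tumor, normal, high_attenuation_mode=True)
        assert whole.T == pytest.approx((80 / 6) / 20.0)  # ~0.667
        assert subset.T == pytest.approx(2.0)
        assert subset.n_voxels_tumor_used == 2
        assert subset.high_attenuation_applicable

    def test_subset_inapplicable_falls_back_to_whole(self):
        em, tumor, normal = self._setup([-5.0, -1.0, 0.0, 0.0, -2.0, -3.0])
        out = relative_enhancement(em, tumor, normal, high_attenuation_mode=True)
        assert not out.high_attenuation_applicable
        assert out.n_voxels_tumor_used == 6

    def test_nonpositive_normal_mean_raises(self):
        em, tumor, normal = self._setup([60.0] * 6)
        em.values[6:10, 6:10, 1] = -5.0
        with pytest.raises(NormalizationError):
            relative_enhancement(em, tumor, normal)

    def test_scale_invariance(self, clean_case_f05):
        case = clean_case_f05
        em_pre, em_post = identity_maps(case)
        t = case.truth
        roi_t = define_tumor_roi(em_pre, t.tumor_mask)
        roi_n = define_normal_roi(em_pre, t.liver_mask, "left", t.vessel_mask_pre,
                                  lobe_split_x_mm=t.lobe_split_x_mm)
        base = relative_enhancement(em_post, roi_t, roi_n, high_attenuation_mode=True)
        scaled_map = EnhancementMap(em_post.values * 3.7, em_post.spacing,
                                    em_post.origin, phase_pair="post")
        scaled = relative_enhancement(scaled_map, roi_t, roi_n, high_attenuation_mode=True)
        assert scaled.T == pytest.approx(base.T, abs=1e-12)
        assert classify_response(scaled.T).call == classify_response(base.T).call

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_clean_extremes_classify_correctly(self, seed):
        for f, expected in ((0.0, "non_residual"), (1.0, "residual")):
            spec = tiny_spec(residual_fraction=f, noise_sigma_hu=0.0,
                             deformation_amplitude_mm=0.0, seed=seed)
            case = generate_case(spec)
            em_pre, em_post = identity_maps(case)
            t = case.truth
            roi_t = define_tumor_roi(em_pre, t.tumor_mask)
            roi_n = define_normal_roi(em_pre, t.liver_mask, "left", t.vessel_mask_pre,
                                      area_mm2=TINY_ROI_AREA,
                                      lobe_split_x_mm=t.lobe_split_x_mm)
            out = relative_enhancement(em_post, roi_t, roi_n, high_attenuation_mode=True)
            assert classify_response(out.T).call == expected


class TestClassifyResponse:
    def test_group_mean_values_from_reference_cohort(self):
        # 3.05 is the residual group's mean, 0.48 the non-residual group's
        assert classify_response(3.05).call == "residual"
        assert classify_response(0.48).call == "non_residual"

    def test_boundary_value_is_non_residual(self):
        assert classify_response(1.0).call == "non_residual"
        assert classify_response(1.0 + 1e-9).call == "residual"

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            classify_response(float("nan"))
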