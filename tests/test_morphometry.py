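import numpy as np
import pytest

from mandmorph import imagecore, phantom
from mandmorph.imagecore import Volume
from mandmorph.morphometry import (
    CheekToothHeight,
    Plane,
    SagittalProfile,
    cheek_tooth_height,
    extract_sagittal_profile,
    fit_occlusal_plane,
    measure_incisor,
    molar_cusp_points,
    occlusal_angle,
    path_length,
    reorient_to_occlusal,
)
from mandmorph.transforms import RigidTransform


# -- occlusal plane ----------------------------------------------------------

def test_plane_normal_is_normalized():
    p = Plane((0, 0, 0), (0, 0, 10))
    np.testing.assert_allclose(np.linalg.norm(p.normal), 1.0, atol=1e-9)


def test_fit_flat_points():
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.uniform(-5, 5, 30), rng.uniform(-5, 5, 30), np.zeros(30)])
    plane = fit_occlusal_plane(pts)
    np.testing.assert_allclose(plane.normal, (0, 0, 1), atol=1e-12)
    np.testing.assert_allclose(plane.signed_distance(pts), 0, atol=1e-12)


def test_fit_tilted_plane_svd_oracle():
    # z = 0.1 x  ->  normal parallel to (-0.0995, 0, 0.995)
    rng = np.random.default_rng(1)
    x = rng.uniform(-10, 10, 50)
    y = rng.uniform(-10, 10, 50)
    pts = np.column_stack([x, y, 0.1 * x])
    plane = fit_occlusal_plane(pts)
    expected = np.array([-0.1, 0.0, 1.0])
    expected /= np.linalg.norm(expected)
    np.testing.assert_allclose(plane.normal, expected, atol=1e-9)


def test_fit_rotation_equivariance():
    rng = np.random.default_rng(2)
    pts = np.column_stack([rng.uniform(-5, 5, 40), rng.uniform(-5, 5, 40),
                           rng.normal(0, 0.01, 40)])
    rot = RigidTransform((8.0, -4.0, 13.0)).matrix
    n0 = fit_occlusal_plane(pts).normal
    n1 = fit_occlusal_plane(pts @ rot.T).normal
    expected = rot @ np.asarray(n0)
    if expected[2] < 0:
        expected = -expected
    np.testing.assert_allclose(n1, expected, atol=1e-6)


def test_fit_rejects_collinear():
    pts = np.column_stack([np.arange(10.0), np.arange(10.0), np.arange(10.0)])
    with pytest.raises(ValueError, match="collinear"):
        fit_occlusal_plane(pts)


def test_molar_cusp_points_coplanar(rat01):
    vol, gt = rat01
    _, tooth = imagecore.split_bone_teeth(vol)
    cusps = molar_cusp_points(tooth)
    assert len(cusps) == 6  # 3 molars per side
    z_occ = gt.alveolus_z_mm + 2.5
    np.testing.assert_allclose(cusps[:, 2], z_occ, atol=vol.spacing[2])


def test_reorient_horizontal_plane_is_identity(rat02):
    vol, _ = rat02
    out, t = reorient_to_occlusal(vol, Plane((0, 0, 5), (0, 0, 1)))
    assert t.is_identity
    np.testing.assert_array_equal(out.data, vol.data)


def test_reorient_recovers_tilt(rat02):
    vol, _ = rat02
    center = tuple(o + s * (n - 1) / 2
                   for o, s, n in zip(vol.origin, vol.spacing, vol.shape))
    tilt = RigidTransform((0.0, 15.0, 0.0), (0, 0, 0), center)
    from mandmorph.register import apply_transform
    tilted = apply_transform(vol, tilt, vol)
    _, tooth = imagecore.split_bone_teeth(tilted)
    plane = fit_occlusal_plane(molar_cusp_points(tooth))
    reoriented, t = reorient_to_occlusal(tilted, plane)
    _, tooth2 = imagecore.split_bone_teeth(reoriented)
    plane2 = fit_occlusal_plane(molar_cusp_points(tooth2))
    angle = np.degrees(np.arccos(np.clip(np.dot(plane2.normal, (0, 0, 1)), -1, 1)))
    assert angle < 0.5


def test_reorient_idempotent(rat02):
    vol, _ = rat02
    plane = Plane((0, 0, 10), (0.15, 0.05, 0.98))
    once, t1 = reorient_to_occlusal(vol, plane)
    rotated_normal = t1.matrix @ np.asarray(plane.normal)
    again, t2 = reorient_to_occlusal(once, Plane(plane.point, tuple(rotated_normal)))
    assert t2.is_identity


# -- sagittal profile --------------------------------------------------------

def test_profile_landmarks_ordered(rat01, masks):
    vol, _ = rat01
    bone, tooth = masks(vol)
    prof = extract_sagittal_profile(tooth, "left", bone)
    lm = prof.landmarks
    assert lm["alveolus_edge"] == 0
    assert lm["alveolus_edge"] < lm["tip"] < lm["gnaw_ridge"] < lm["lingual_alveolus_edge"]
    assert lm["lingual_alveolus_edge"] == len(prof.points) - 1


def test_profile_arc_length_near_ground_truth(rat01, masks):
    vol, gt = rat01
    bone, tooth = masks(vol)
    prof = extract_sagittal_profile(tooth, "left", bone)
    two_vox = 2 * vol.spacing[0]
    assert path_length(prof, surface="labial") == pytest.approx(gt.labial_mm["left"], abs=two_vox)
    assert path_length(prof, surface="lingual") == pytest.approx(gt.lingual_mm["left"], abs=two_vox)
    assert path_length(prof, surface="occlusal") == pytest.approx(gt.occlusal_mm["left"], abs=two_vox)


def test_profiles_mirror_between_sides(rat01, masks):
    vol, _ = rat01
    bone, tooth = masks(vol)
    left = extract_sagittal_profile(tooth, "left", bone)
    right = extract_sagittal_profile(tooth, "right", bone)
    one_vox = vol.spacing[0]
    for surface in ("labial", "lingual", "occlusal"):
        assert path_length(left, surface=surface) == pytest.approx(
            path_length(right, surface=surface), abs=one_vox
        )
    # angle sign is preserved under left-right mirroring
    assert occlusal_angle(left) == pytest.approx(occlusal_angle(right), abs=0.5)


def test_profile_missing_side_errors(rat01, masks):
    vol, _ = rat01
    bone, tooth = masks(vol)
    xs = tooth.axis_coords(0)
    half = Volume(np.where(xs[:, None, None] > 0, tooth.data, 0), tooth.spacing, tooth.origin)
    with pytest.raises(ValueError, match="left"):
        extract_sagittal_profile(half, "left", bone)


# -- path_length / occlusal_angle on synthetic profiles ----------------------

def _straight_profile():
    pts = np.array([[0.0, 0.0], [3.0, 4.0]])
    return SagittalProfile("left", pts, {"alveolus_edge": 0, "tip": 1})


def test_two_point_path_length():
    assert path_length(_straight_profile(), "alveolus_edge", "tip", "labial") == pytest.approx(5.0)


def test_quarter_circle_path_length():
    theta = np.deg2rad(np.arange(0, 90.001, 0.5))
    pts = 10.0 * np.column_stack([np.cos(theta), np.sin(theta)])
    prof = SagittalProfile("left", pts, {"alveolus_edge": 0, "tip": len(pts) - 1})
    assert path_length(prof, "alveolus_edge", "tip", "labial") == pytest.approx(15.708, abs=0.01)


def test_path_length_requires_landmarks():
    with pytest.raises(ValueError, match="landmark"):
        path_length(_straight_profile(), surface="lingual")


def test_occlusal_angle_flat_facet_is_zero():
    pts = np.column_stack([np.linspace(0, 5, 20), np.zeros(20)])
    prof = SagittalProfile("left", pts, {"alveolus_edge": 0, "tip": 2, "gnaw_ridge": 17,
                                         "lingual_alveolus_edge": 19})
    assert occlusal_angle(prof) == pytest.approx(0.0, abs=1e-9)


def test_occlusal_angle_requires_three_facet_points():
    pts = np.array([[0, 0], [1, 0], [2, 0.1], [3, 1]])
    prof = SagittalProfile("left", pts, {"alveolus_edge": 0, "tip": 1, "gnaw_ridge": 2,
                                         "lingual_alveolus_edge": 3})
    with pytest.raises(ValueError, match="3 points"):
        occlusal_angle(prof)


def test_constructed_bevel_angle_recovered(rat01, masks):
    vol, gt = rat01
    bone, tooth = masks(vol)
    prof = extract_sagittal_profile(tooth, "left", bone)
    assert occlusal_angle(prof) == pytest.approx(gt.occlusal_angle_deg["left"], abs=1.0)


def test_measure_incisor_species_contract(rat01, masks):
    vol, _ = rat01
    bone, tooth = masks(vol)
    rat = measure_incisor(tooth, bone, "left", species="rat")
    assert rat.lingual_mm is not None and rat.occlusal_mm is not None
    rabbit_like = measure_incisor(tooth, bone, "left", species="rabbit")
    assert rabbit_like.lingual_mm is None and rabbit_like.occlusal_mm is None
    assert rabbit_like.labial_mm == pytest.approx(rat.labial_mm)


# -- cheek teeth -------------------------------------------------------------

def test_cheek_tooth_height_constructed(rabbit01, masks):
    vol, gt = rabbit01
    bone, tooth = masks(vol)
    two_vox = 2 * vol.spacing[2]
    for i, label in enumerate(("#2", "#3", "#4", "#5")):
        h = cheek_tooth_height(tooth, bone, label, "left")
        assert h.height_mm == pytest.approx(gt.cheek_heights_mm["left"][i], abs=two_vox), label


def test_rabbit_table_one_tooth2_height():
    # published baseline: tooth #2 left erupted height 5.3 mm
    spec = phantom.rabbit_spec(voxel_mm=0.09)
    vol, gt = phantom.make_phantom(spec)
    bone, tooth = imagecore.split_bone_teeth(vol)
    h = cheek_tooth_height(tooth, bone, 2, "left")
    assert gt.cheek_heights_mm["left"][0] == 5.3
    assert h.height_mm == pytest.approx(5.3, abs=2 * 0.09)


def test_cheek_tooth_flush_crown_is_zero():
    # a crown whose top is level with the surrounding alveolar bone
    nx, ny, nz = 40, 40, 40
    bone = np.zeros((nx, ny, nz), dtype=np.uint8)
    tooth = np.zeros_like(bone)
    bone[:, :, :20] = 1
    bone[10:20, 10:20, :] = 0
    tooth[11:19, 11:19, 5:20] = 1
    sp = (0.1, 0.1, 0.1)
    origin = (0.5, 0, 0)  # single tooth on the right side
    big = tooth.copy()
    big[2:8, 25:39, 2:30] = 1  # dummy incisor (largest component)
    h = cheek_tooth_height(
        Volume(big, sp, origin), Volume(bone, sp, origin), "#2", "right"
    )
    assert h.height_mm == pytest.approx(0.0, abs=2 * sp[2])


def test_cheek_tooth_missing_errors(rabbit01, masks):
    vol, _ = rabbit01
    bone, tooth = masks(vol)
    with pytest.raises(ValueError, match="#9"):
        cheek_tooth_height(tooth, bone, "#9", "left")


def test_rectangular_crown_height_oracle():
    # 3 mm crown above a flat alveolus edge at 0.09 mm voxels
    sp = (0.09, 0.09, 0.09)
    n = 80
    bone = np.zeros((n, n, n), dtype=np.uint8)
    tooth = np.zeros_like(bone)
    bone[:, :, :30] = 1
    tooth[30:40, 30:40, 25:64] = 1  # crown top at z index 63
    big = tooth.copy()
    big[5:15, 5:70, 5:40] = 1  # dummy incisor
    origin = (0.5, 0.0, 0.0)
    h = cheek_tooth_height(Volume(big, sp, origin), Volume(bone, sp, origin), "#2", "right")
    # top of crown: (63 + 0.5) * 0.09 ; alveolus edge: (29 + 0.5) * 0.09
    assert h.height_mm == pytest.approx((63 - 29) * 0.09, abs=2 * 0.09)
    assert h.height_mm == pytest.approx(3.0, abs=2 * 0.09)
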