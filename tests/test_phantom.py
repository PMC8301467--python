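import numpy as np
import pytest

from mandmorph import imagecore, phantom
from mandmorph.phantom import (
    CohortParams,
    DefectSpec,
    IncisorSpec,
    MetricParams,
    PhantomSpec,
    apply_defect,
    make_phantom,
    perturb_pose,
    simulate_cohort,
    solve_arc,
)
from mandmorph.transforms import RigidTransform


# -- arc geometry ------------------------------------------------------------

def _numeric_arc_length(radius, phi_a, phi_b, n=200_000):
    """Independent oracle: numeric arc-length integration of r*(cos, sin)."""
    phi = np.linspace(phi_a, phi_b, n)
    pts = radius * np.column_stack([np.cos(phi), np.sin(phi)])
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def test_arc_solution_matches_numeric_integration():
    spec = IncisorSpec(14.0, 1.0, 12.66, 1.67, 5.85)
    sol = solve_arc(spec)
    labial = _numeric_arc_length(sol.outer, sol.phi_alv_outer, sol.phi_tip)
    lingual = _numeric_arc_length(sol.inner, sol.phi_alv_inner, sol.phi_ridge)
    occlusal = float(np.linalg.norm(sol.tip - sol.ridge))
    assert labial == pytest.approx(12.66, abs=1e-6)
    assert lingual == pytest.approx(1.67, abs=1e-6)
    assert occlusal == pytest.approx(5.85, abs=1e-9)


def test_quarter_circle_arc_length_oracle():
    # quarter circle of radius 10: numeric integration vs analytic pi*r/2
    numeric = _numeric_arc_length(10.0, 0.0, np.pi / 2)
    assert numeric == pytest.approx(np.pi * 10 / 2, abs=1e-6)
    assert numeric == pytest.approx(15.708, abs=1e-3)


def test_arc_rejects_unrealizable_targets():
    with pytest.raises(ValueError):
        solve_arc(IncisorSpec(14.0, 1.0, 12.66, 1.67, 50.0))
    with pytest.raises(ValueError):
        IncisorSpec(1.0, 1.5, 5, 1, 2)  # tube radius >= centerline radius


# -- make_phantom ------------------------------------------------------------

def test_ground_truth_mirrored_exactly(rat02):
    _, gt = rat02
    for metric in ("labial_mm", "lingual_mm", "occlusal_mm", "occlusal_angle_deg"):
        assert gt.metric(metric, "left") == gt.metric(metric, "right")


def test_crown_overgrowth_shifts_labial_exactly():
    spec = phantom.rat_spec(voxel_mm=0.2, crown_extra_mm={"left": 2.3})
    _, gt = make_phantom(spec)
    assert gt.labial_mm["left"] - gt.labial_mm["right"] == pytest.approx(2.3, abs=1e-12)


def test_ground_truth_independent_of_voxel_size():
    gts = [make_phantom(phantom.rat_spec(voxel_mm=v))[1] for v in (0.3, 0.2)]
    assert gts[0].labial_mm == gts[1].labial_mm
    assert gts[0].occlusal_angle_deg == gts[1].occlusal_angle_deg


def test_voxel_larger_than_tube_radius_rejected():
    with pytest.raises(ValueError, match="unresolvable"):
        phantom.rat_spec(voxel_mm=1.5)


def test_phantom_intensities_and_noise():
    vol, _ = make_phantom(phantom.rat_spec(voxel_mm=0.25))
    vals = np.unique(vol.data)
    assert set(vals) == {phantom.BACKGROUND, phantom.BONE_INTENSITY, phantom.TOOTH_INTENSITY}
    noisy, _ = make_phantom(phantom.rat_spec(voxel_mm=0.25, noise_sd=0.05, seed=3))
    assert np.std(noisy.data[vol.data == 0]) == pytest.approx(50.0, rel=0.05)


def test_phantom_noise_deterministic_under_seed():
    a, _ = make_phantom(phantom.rat_spec(voxel_mm=0.25, noise_sd=0.05, seed=9))
    b, _ = make_phantom(phantom.rat_spec(voxel_mm=0.25, noise_sd=0.05, seed=9))
    np.testing.assert_array_equal(a.data, b.data)


def test_symphysis_separates_sides(rat02):
    vol, _ = rat02
    mask = imagecore.binarize(vol, phantom.BONE_THRESHOLD)
    _, n = imagecore.connected_components(mask)
    assert n >= 2  # left and right hemi-mandibles never touch
    xs = mask.axis_coords(0)
    gap = np.abs(xs) < 0.4
    assert mask.data[gap].sum() == 0


# -- defects -----------------------------------------------------------------

def test_csd_sphere_removed_volume_oracle(bone_block):
    vol, mask = bone_block
    defect = DefectSpec("CSD", "right")
    geometry = ("sphere", ((1.0, 0.5, -0.5), 2.5))
    out, removed, _ = apply_defect(vol, mask, defect, geometry=geometry)
    analytic = 4.0 / 3.0 * np.pi * 2.5**3
    assert removed == pytest.approx(analytic, rel=0.02)
    region = out.data == phantom.BACKGROUND
    # voxels removed only inside the stated geometry
    xs, ys, zs = (vol.axis_coords(i) for i in range(3))
    d2 = ((xs - 1.0)[:, None, None] ** 2 + (ys - 0.5)[None, :, None] ** 2
          + (zs + 0.5)[None, None, :] ** 2)
    assert not np.any(region & (d2 > 2.6**2))


def test_defect_none_is_noop(rat02):
    vol, _ = rat02
    bone, _ = imagecore.split_bone_teeth(vol)
    out, removed, n = apply_defect(vol, bone, DefectSpec("none"))
    assert removed == 0.0
    np.testing.assert_array_equal(out.data, vol.data)
    assert n == 1


@pytest.mark.parametrize("dtype,expected_components", [
    ("CSD", 1), ("ID", 1), ("CRO_narrow", 2), ("CRO_wide", 2),
])
def test_rat_defect_component_counts(dtype, expected_components):
    spec = phantom.rat_spec(voxel_mm=0.2)
    vol, bone, _ = phantom.rasterize(spec)
    _, removed, n = apply_defect(vol, bone, DefectSpec(dtype, "left"), spec)
    assert n == expected_components
    assert removed > 0


def test_rat_defect_removed_volume_matches_analytic():
    spec = phantom.rat_spec(voxel_mm=0.1)
    for dtype in ("CSD", "ID", "CRO_wide"):
        vol, bone, _ = phantom.rasterize(spec)
        _, removed, _ = apply_defect(vol, bone, DefectSpec(dtype, "left"), spec)
        _, _, analytic = phantom.default_defect_geometry(spec, DefectSpec(dtype, "left"))
        # box faces quantize to the voxel grid: allow half a voxel per face
        assert removed == pytest.approx(analytic, rel=0.04), dtype


def test_rabbit_defect_modes():
    spec = phantom.rabbit_spec(voxel_mm=0.25)
    for dtype, expected in (("CSD", 1), ("ID", 1), ("BODY", 1), ("CRO_wide", 2)):
        vol, bone, _ = phantom.rasterize(spec)
        _, removed, n = apply_defect(vol, bone, DefectSpec(dtype, "left"), spec)
        assert n == expected, dtype
        _, _, analytic = phantom.default_defect_geometry(spec, DefectSpec(dtype, "left"))
        assert removed == pytest.approx(analytic, rel=0.08), dtype


def test_defect_contralateral_side_untouched():
    spec = phantom.rat_spec(voxel_mm=0.2)
    vol, bone, _ = phantom.rasterize(spec)
    before = vol.data.copy()
    out, _, _ = apply_defect(vol, bone, DefectSpec("CRO_wide", "left"), spec)
    xs = vol.axis_coords(0)
    right = xs > 0
    np.testing.assert_array_equal(out.data[right], before[right])


def test_ground_truth_records_defect_volume():
    spec = phantom.rat_spec(voxel_mm=0.2)
    _, gt = make_phantom(spec, DefectSpec("CSD", "left"))
    assert gt.defect_removed_mm3 == pytest.approx(4 / 3 * np.pi * 2.5**3, rel=1e-9)
    assert gt.defect_side == "left"


# -- pose perturbation -------------------------------------------------------

def test_perturb_identity_is_noop(rat02):
    vol, _ = rat02
    out = perturb_pose(vol, RigidTransform())
    np.testing.assert_array_equal(out.data, vol.data)


def test_perturb_whole_voxel_shift_nearest(rat02):
    vol, _ = rat02
    k = 3
    t = RigidTransform(translation_mm=(0.0, k * vol.spacing[1], 0.0))
    out = perturb_pose(vol, t, interpolation="nearest")
    np.testing.assert_array_equal(out.data[:, k:, :], vol.data[:, :-k, :])
    assert np.all(out.data[:, :k, :] == phantom.BACKGROUND)


def test_perturb_rotation_round_trip(rat02):
    vol, _ = rat02
    center = tuple(o + s * (n - 1) / 2
                   for o, s, n in zip(vol.origin, vol.spacing, vol.shape))
    t = RigidTransform((0, 0, 4.0), (0, 0, 0), center)
    back = perturb_pose(perturb_pose(vol, t), t.invert())
    interior = vol.data > 0
    mad = np.mean(np.abs(back.data[interior] - vol.data[interior]))
    assert mad < 0.15 * phantom.DYNAMIC_RANGE  # documented interpolation tolerance


def test_perturb_pose_capped():
    vol = imagecore.Volume(np.zeros((4, 4, 4)), (1, 1, 1))
    with pytest.raises(ValueError, match="capped"):
        perturb_pose(vol, RigidTransform((20, 0, 0)))
    with pytest.raises(ValueError, match="capped"):
        phantom.random_pose(seed=0, max_mm=9.0)


def test_random_pose_seeded():
    a = phantom.random_pose(3)
    b = phantom.random_pose(3)
    assert a == b
    assert np.all(np.abs(a.angles_deg) <= 4.0)
    assert np.all(np.abs(a.translation_mm) <= 2.5)


# -- cohort simulator --------------------------------------------------------

def _params(n=8, seed=0, **over):
    metrics = {"labial": MetricParams(12.66, 0.59, over.pop("diff_sd", 0.6),
                                      over.pop("effect", 0.0))}
    return CohortParams(metrics, n_animals=n, seed=seed, **over)


def test_zero_diff_sd_gives_equal_sides():
    table = simulate_cohort(_params(n=50, diff_sd=0.0))
    wide = table.pivot_table(index="animal_id", columns="side", values="value")
    np.testing.assert_allclose(wide["left"], wide["right"])


def test_cohort_mean_matches_configured():
    table = simulate_cohort(_params(n=20_000, seed=11))
    left = table[table.side == "left"].value
    se = np.sqrt(0.59**2 + 0.3**2) / np.sqrt(20_000)
    assert abs(left.mean() - 12.66) < 3 * se


def test_cohort_deterministic_under_seed():
    a = simulate_cohort(_params(seed=21))
    b = simulate_cohort(_params(seed=21))
    assert a.equals(b)


def test_cohort_difference_sd_converges():
    table = simulate_cohort(_params(n=100_000, seed=5))
    wide = table.pivot_table(index="animal_id", columns="side", values="value")
    d = wide["left"] - wide["right"]
    assert abs(d.std(ddof=1) - 0.6) / 0.6 < 0.05


def test_cohort_defect_effect_applied_post_baseline():
    params = CohortParams(
        {"labial": MetricParams(12.66, 0.59, 0.0, defect_effect=2.3)},
        n_animals=10, timepoints=("baseline", "wk1"), defect_side="left", seed=2,
    )
    table = simulate_cohort(params)
    wide = table.pivot_table(index=["animal_id", "timepoint"], columns="side", values="value")
    d = (wide["left"] - wide["right"]).reset_index()
    base = d[d.timepoint == "baseline"][0]
    post = d[d.timepoint == "wk1"][0]
    np.testing.assert_allclose(base, 0.0, atol=1e-12)
    np.testing.assert_allclose(post, 2.3, atol=1e-12)


def test_cohort_rejects_bad_params():
    with pytest.raises(ValueError):
        MetricParams(1.0, -0.1, 0.1)
    with pytest.raises(ValueError):
        CohortParams({"m": MetricParams(1, 0.1, 0.1)}, n_animals=1)
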