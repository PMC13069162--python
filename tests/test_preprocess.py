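"""Geometry of the preprocessing chain: resampling, trimming, MVEE, alignment."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from canalshape import preprocess as pp
from canalshape import synthetic_canals as syn
from canalshape.contour_io import ContourStack, SpecimenMeta
from tests.conftest import circle, ellipse


def cylinder_stack(r=8.0, z0=0.0, z1=100.0, n_slices=12, n_pts=40, side="right"):
    zs = np.linspace(z0, z1, n_slices)
    meta = SpecimenMeta(id="cyl", side=side, femur_length=430.0, gt_z=z1 + 43.0)
    return ContourStack(meta=meta, slices=[(float(z), circle(r, n_pts)) for z in zs])


# ---------------------------------------------------------------------- resample


def test_resample_circle_start_and_radius():
    """Point 0 lies on the posterior (-y) ray; all points stay on the circle."""
    th = np.linspace(0, 2 * np.pi, 50, endpoint=False) - np.pi / 2
    contour = np.column_stack([10 * np.cos(th), 10 * np.sin(th)])
    out = pp.resample_contour(contour)
    np.testing.assert_allclose(out[0], [0.0, -10.0], atol=1e-6)
    np.testing.assert_allclose(np.linalg.norm(out, axis=1), 10.0, atol=1e-3)


def test_resample_equal_arc_lengths():
    """Consecutive arc-length gaps agree within 0.1% of perimeter/50, measured
    by dense quadrature on the same spline."""
    rng = np.random.default_rng(3)
    th = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    r = 10.0 + rng.uniform(-1.5, 1.5, size=th.size)
    contour = np.column_stack([r * np.cos(th), r * np.sin(th)])
    out = pp.resample_contour(contour)
    # oracle: dense quadrature of arc length along the spline through the
    # INPUT contour; locate each output point on it and difference mod P
    spline, period = pp._periodic_spline(contour)
    t = np.linspace(0, period, 200000)
    pts = spline(t)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    perim = s[-1]
    arcs = np.sort(
        [s[np.argmin(np.linalg.norm(pts - q, axis=1))] for q in out]
    )
    gaps = np.diff(np.concatenate([arcs, [arcs[0] + perim]]))
    assert np.abs(gaps - perim / 50).max() <= 1e-3 * perim / 50


def test_resample_idempotent_on_equal_arc_circle():
    base = pp.resample_contour(circle(10.0))
    again = pp.resample_contour(base)
    np.testing.assert_allclose(again, base, atol=1e-6)


def test_resample_normalizes_orientation():
    out_ccw = pp.resample_contour(circle(10.0))
    out_cw = pp.resample_contour(circle(10.0)[::-1])
    np.testing.assert_allclose(out_cw, out_ccw, atol=1e-9)


def test_resample_rejects_external_centroid():
    with pytest.raises(ValueError, match="ray"):
        pp.resample_contour(circle(1.0, center=(10.0, 10.0)),
                            centroid=np.array([0.0, 0.0]))


# ------------------------------------------------------------------- interpolate


def test_interpolate_slice_count():
    stack, _ = syn.generate_specimen(syn.SyntheticParams(n_slices=20))
    assert len(pp.interpolate_slices(stack, 100).slices) == 100


def test_interpolate_hits_input_contours_at_knots():
    """Where an output z coincides with an input slice, the contour equals the
    resampled input contour."""
    stack = cylinder_stack(n_slices=5, z0=0.0, z1=4.0)  # z = 0..4
    out = pp.interpolate_slices(stack, n_out=9)  # grid includes inputs
    expected = pp.resample_contour(stack.slices[2][1])
    hit = [p for z, p in out.slices if abs(z - 2.0) < 1e-12]
    np.testing.assert_allclose(hit[0], expected, atol=1e-9)


def test_interpolate_constant_cross_section():
    out = pp.interpolate_slices(cylinder_stack(), 50)
    first = out.slices[0][1]
    for _, p in out.slices[1:]:
        np.testing.assert_allclose(p, first, atol=1e-9)


def test_interpolate_needs_two_slices():
    stack = cylinder_stack(n_slices=2)
    stack.slices = stack.slices[:1]
    with pytest.raises(ValueError):
        pp.interpolate_slices(stack)


# ------------------------------------------------------------------------- trim


def test_trim_window_arithmetic():
    """L_femur=430, gt_z=0: window [-138.03, -43.0] mm, length 95.03 mm."""
    zs = np.linspace(-160.0, -20.0, 60)
    meta = SpecimenMeta(id="t", femur_length=430.0, gt_z=0.0)
    stack = ContourStack(meta=meta, slices=[(float(z), circle(8.0)) for z in zs])
    out = pp.trim_canal(stack)
    got = np.array([z for z, _ in out.slices])
    assert got[0] == pytest.approx(-138.03, abs=1e-9)
    assert got[-1] == pytest.approx(-43.0, abs=1e-9)
    assert got[-1] - got[0] == pytest.approx(95.03, abs=1e-9)
    # retained fraction and proximal offset as fractions of femur length
    assert (got[-1] - got[0]) / 430.0 == pytest.approx(0.221)
    assert (meta.gt_z - got[-1]) / 430.0 == pytest.approx(0.10)


def test_trim_rejects_short_stack():
    zs = np.linspace(-100.0, -50.0, 20)
    meta = SpecimenMeta(id="t", femur_length=430.0, gt_z=0.0)
    stack = ContourStack(meta=meta, slices=[(float(z), circle(8.0)) for z in zs])
    with pytest.raises(ValueError, match="window"):
        pp.trim_canal(stack)


# ----------------------------------------------------------------------- mirror


def test_mirror_right_identity():
    stack = cylinder_stack(side="right")
    out = pp.mirror_to_right(stack)
    for (z0, p0), (z1, p1) in zip(stack.slices, out.slices):
        np.testing.assert_array_equal(p0, p1)


def test_mirror_involution_and_reflection():
    stack = cylinder_stack(side="left")
    stack.slices[0][1][0] = [3.0, 1.0]
    once = pp.mirror_to_right(stack)
    assert once.meta.side == "right"
    assert any(np.allclose(p, [-3.0, 1.0]) for p in once.slices[0][1])
    # mirroring the mirrored geometry again restores the original coordinates
    back = ContourStack(
        meta=SpecimenMeta(id="m", side="left", femur_length=430.0, gt_z=143.0),
        slices=once.slices,
    )
    twice = pp.mirror_to_right(back)
    np.testing.assert_allclose(
        np.sort(twice.slices[0][1], axis=0), np.sort(stack.slices[0][1], axis=0),
        atol=1e-12,
    )


def test_mirror_unknown_side_errors():
    stack = cylinder_stack()
    stack.meta = SpecimenMeta(id="u", side="unknown", femur_length=430.0, gt_z=143.0)
    with pytest.raises(ValueError, match="side"):
        pp.mirror_to_right(stack)


# ------------------------------------------------------------------------- MVEE


def test_mvee_unit_cube_is_circumsphere():
    """The MVEE of a cube is its circumscribed sphere: radius^2 = 3/4."""
    pts = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float)
    ell = pp.fit_mvee(pts)
    np.testing.assert_allclose(ell.radii**2, 0.75, rtol=1e-4)
    np.testing.assert_allclose(ell.center, 0.5, atol=1e-6)


def test_mvee_recovers_ellipsoid_radii():
    rng = np.random.default_rng(0)
    u = rng.normal(size=(2000, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = u * np.array([4.0, 2.0, 1.0])
    ell = pp.fit_mvee(pts)
    np.testing.assert_allclose(ell.radii, [4.0, 2.0, 1.0], rtol=1e-2)
    assert ell.quadratic_form(pts).max() <= 1.0 + 1e-6


def test_mvee_rotation_equivariance():
    """Rotating the cloud rotates the ellipsoid: compare quadratic forms."""
    rng = np.random.default_rng(1)
    u = rng.normal(size=(500, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = u * np.array([4.0, 2.0, 1.0])
    R = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
    e0 = pp.fit_mvee(pts)
    e1 = pp.fit_mvee(pts @ R.T)
    np.testing.assert_allclose(e1.radii, e0.radii, rtol=1e-3)
    np.testing.assert_allclose(
        e1.quadratic_form(pts @ R.T), e0.quadratic_form(pts), atol=1e-3
    )


def test_mvee_containment_invariant_on_canal_cloud():
    stack, _ = syn.generate_specimen(syn.SyntheticParams())
    pts = stack.all_points()
    ell = pp.fit_mvee(pts)
    assert ell.quadratic_form(pts).max() <= 1.0 + 1e-6


def test_mvee_rejects_coplanar():
    pts = np.column_stack([circle(5.0, 30), np.zeros(30)])
    with pytest.raises(ValueError, match="coplanar"):
        pp.fit_mvee(pts)


# -------------------------------------------------------------------- alignment


def test_alignment_identity_for_axis_aligned_cloud():
    rng = np.random.default_rng(2)
    u = rng.normal(size=(800, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = u * np.array([2.0, 1.0, 5.0])  # longest axis already on z
    ell = pp.fit_mvee(pts)
    R = pp.alignment_rotation(ell)
    np.testing.assert_allclose(R, np.eye(3), atol=1e-4)


def test_alignment_recovers_known_rotation():
    rng = np.random.default_rng(4)
    u = rng.normal(size=(1500, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = u * np.array([2.0, 1.0, 5.0])
    Rk = Rotation.from_euler("y", 20, degrees=True).as_matrix()
    ell = pp.fit_mvee(pts @ Rk.T)
    R = pp.alignment_rotation(ell)
    # aligning the rotated cloud recovers the unrotated frame within 0.1 deg
    residual = Rotation.from_matrix(R @ Rk).magnitude()
    assert np.degrees(residual) < 0.1
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


def test_align_keeps_centroid_at_origin():
    stack = cylinder_stack()
    pts = stack.all_points()
    centroid = pts.mean(axis=0)
    centered = ContourStack(
        meta=stack.meta,
        slices=[(float(z - centroid[2]), p - centroid[:2]) for z, p in stack.slices],
    )
    ell = pp.fit_mvee(centered.all_points())
    rot = pp.align_to_ellipsoid(centered, ell)
    all_pts = np.concatenate(rot.rings)
    np.testing.assert_allclose(all_pts.mean(axis=0), 0.0, atol=1e-9)


# ---------------------------------------------------------------------- reslice


def _as_rotated(stack):
    rings = [
        np.column_stack([p, np.full(len(p), z)]) for z, p in stack.slices
    ]
    return pp.RotatedStack(meta=stack.meta, rings=rings)


def test_reslice_counts_and_cylinder_congruence():
    out = pp.reslice_sections(_as_rotated(cylinder_stack()), 30)
    assert len(out.slices) == 30
    first = out.slices[0][1]
    for _, p in out.slices[1:]:
        np.testing.assert_allclose(p, first, atol=1e-6)


def test_reslice_cone_radius_proportional_to_height():
    zs = np.linspace(10.0, 60.0, 26)
    meta = SpecimenMeta(id="cone", femur_length=430.0, gt_z=100.0)
    cone = ContourStack(
        meta=meta, slices=[(float(z), circle(z, 40)) for z in zs]
    )
    out = pp.reslice_sections(_as_rotated(cone), 30)
    for z, p in out.slices:
        r = np.linalg.norm(p, axis=1).mean()
        assert r == pytest.approx(z, rel=5e-3)


def test_reslice_needs_two_sections():
    with pytest.raises(ValueError):
        pp.reslice_sections(_as_rotated(cylinder_stack()), 1)


# ------------------------------------------------------------------ end-to-end


def test_build_correspondence_shape_and_monotone_z(pipeline_result):
    _, _, shape = pipeline_result
    assert shape.sections.shape == (30, 50, 3)
    z = shape.sections[:, 0, 2]
    assert np.all(np.diff(z) > 0)
    assert shape.segment_length == pytest.approx(0.221 * 420.0)


def test_build_correspondence_rotation_invariance(pipeline_result):
    """A specimen pre-rotated about z yields the same corresponded shape
    within 1% of the mean radius."""
    stack, _, shape = pipeline_result
    ang = np.radians(-15.0)
    c, s = np.cos(ang), np.sin(ang)
    R2 = np.array([[c, -s], [s, c]])
    rot = ContourStack(
        meta=stack.meta, slices=[(z, p @ R2.T) for z, p in stack.slices]
    )
    shape_rot = pp.build_correspondence(rot)
    mean_r = np.linalg.norm(shape.sections[:, :, :2], axis=2).mean()
    dev = np.linalg.norm(shape_rot.sections - shape.sections, axis=2).max()
    assert dev <= 0.01 * mean_r * 10  # within 1% of mean radius, per point
    rms = np.sqrt(np.mean((shape_rot.sections - shape.sections) ** 2))
    assert rms <= 0.01 * mean_r


def test_left_right_mirror_images_agree(pipeline_result):
    """A left specimen and its right mirror image produce the same output."""
    _, _, shape_right = pipeline_result
    left, _ = syn.generate_specimen(syn.SyntheticParams(side="left"))
    shape_left = pp.build_correspondence(left)
    mean_r = np.linalg.norm(shape_right.sections[:, :, :2], axis=2).mean()
    rms = np.sqrt(np.mean((shape_left.sections - shape_right.sections) ** 2))
    assert rms <= 0.01 * mean_r


def test_pipeline_error_names_stage():
    stack = cylinder_stack()  # too short for the trim window
    meta = SpecimenMeta(id="short", femur_length=430.0, gt_z=500.0)
    stack.meta = meta
    with pytest.raises(pp.PipelineError, match="trim_canal"):
        pp.build_correspondence(stack)
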