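"""Registration: linear recovery, population mean, fluid flow, Jacobians."""
import math

import numpy as np
import pytest
from scipy import ndimage

from conftest import smooth_blob_2d
from neuropheno.registration import (
    DisplacementField,
    FluidParams,
    build_population_mean,
    compose_displacements,
    jacobian_determinant,
    register_fluid,
    register_linear,
    warp_image,
)
from neuropheno.registration.linear import LinearTransform


def make_transform(angles, translation, scales=(1.0, 1.0), shape=(96, 96), dof=6):
    c = (np.array(shape) - 1) / 2.0
    return LinearTransform(2, np.atleast_1d(np.asarray(angles, float)),
                           np.asarray(translation, float),
                           np.asarray(scales, float), dof, c)


def test_identity_on_identical_images():
    img = smooth_blob_2d()
    t = register_linear(img, img, dof=9)
    assert np.allclose(t.angles, 0.0, atol=1e-3)
    assert np.allclose(t.translation, 0.0, atol=1e-3)
    assert np.allclose(t.scales, 1.0, atol=1e-3)


def test_known_rigid_transform_recovered():
    """10 degree rotation + (0.5, 0.3) voxel shift recovered to 0.5deg/0.1vox."""
    fixed = smooth_blob_2d()
    T = make_transform([math.radians(10)], [0.5, 0.3])
    moving = T.inverse().resample(fixed, order=3)
    rec = register_linear(moving, fixed, dof=6)
    assert abs(math.degrees(rec.angles[0]) - 10.0) < 0.5
    assert np.all(np.abs(rec.translation - [0.5, 0.3]) < 0.1)


def test_scaled_copy_needs_nine_dof():
    fixed = smooth_blob_2d()
    S = make_transform([0.0], [0.0, 0.0], scales=(1.1, 1.1), dof=9)
    moving = S.inverse().resample(fixed, order=3)
    rec9 = register_linear(moving, fixed, dof=9)
    assert np.all(np.abs(rec9.scales - 1.1) < 0.011)
    rec6 = register_linear(moving, fixed, dof=6)
    m9 = ((rec9.resample(moving) - fixed) ** 2).mean()
    m6 = ((rec6.resample(moving) - fixed) ** 2).mean()
    assert m6 > 10 * m9  # rigid family cannot absorb the scale


def test_rigid_transform_preserves_volume():
    t = make_transform([0.3], [1.0, -2.0], dof=6)
    assert t.volume_ratio() == 1.0


def test_3d_rigid_recovery_small():
    zz, yy, xx = np.mgrid[0:32, 0:32, 0:32].astype(float)
    fixed = np.clip(1 - (((zz - 16) / 9) ** 2 + ((yy - 16) / 12) ** 2
                         + ((xx - 16) / 7) ** 2), 0, None) ** 1.5
    fixed += 0.5 * np.clip(1 - (((zz - 12) / 4) ** 2 + ((yy - 20) / 4) ** 2
                                + ((xx - 16) / 4) ** 2), 0, None)
    c = (np.array(fixed.shape) - 1) / 2.0
    T = LinearTransform(3, np.array([math.radians(6), 0.0, 0.0]),
                        np.array([0.4, 0.2, -0.3]), np.ones(3), 6, c)
    moving = T.inverse().resample(fixed, order=3)
    rec = register_linear(moving, fixed, dof=6, n_levels=2)
    assert abs(math.degrees(rec.angles[0]) - 6.0) < 0.5
    assert np.all(np.abs(rec.translation - T.translation) < 0.15)


# --- population mean -------------------------------------------------------

def test_population_mean_of_identical_inputs_is_input():
    img = smooth_blob_2d()
    tmpl = build_population_mean([img, img, img], dof=6, n_iter=2)
    assert np.allclose(tmpl, img, atol=5e-3)


def _centroid(img):
    total = img.sum()
    idx = np.indices(img.shape)
    return np.array([(img * i).sum() / total for i in idx])


def test_population_mean_centres_translated_pair():
    img = smooth_blob_2d()
    plus = ndimage.shift(img, (3.0, 0.0), order=3)
    minus = ndimage.shift(img, (-3.0, 0.0), order=3)
    tmpl = build_population_mean([plus, minus], dof=6, n_iter=3)
    mid = 0.5 * (_centroid(plus) + _centroid(minus))
    assert np.all(np.abs(_centroid(tmpl) - mid) < 0.5)


def test_population_mean_order_invariance():
    img = smooth_blob_2d()
    a = ndimage.shift(img, (2.0, 1.0), order=3)
    b = ndimage.shift(img, (-2.0, -1.0), order=3)
    t1 = build_population_mean([a, b], dof=6, n_iter=2)
    t2 = build_population_mean([b, a], dof=6, n_iter=2)
    assert np.allclose(t1, t2, atol=2e-2)


def test_population_mean_needs_two_images():
    from neuropheno.types import ConfigurationError

    with pytest.raises(ConfigurationError):
        build_population_mean([smooth_blob_2d()], dof=6)


# --- fluid -----------------------------------------------------------------

def soft_disk(r, shape=(64, 64), soft=2.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
    c = (np.array(shape) - 1) / 2.0
    d = np.hypot(yy - c[0], xx - c[1])
    return 1.0 / (1.0 + np.exp((d - r) / soft * 4))


def test_fluid_identity_gives_zero_field_unit_jacobian():
    img = soft_disk(10)
    field, report = register_fluid(img, img)
    assert np.abs(field.disp).max() < 1e-9
    assert np.allclose(jacobian_determinant(field), 1.0)


def test_fluid_disk_expansion_jacobian_area_ratio():
    """Disk radius 10 -> 12: mean J in the target disk ~ 1.44 within 10%."""
    fixed = soft_disk(10)
    moving = soft_disk(12)
    field, report = register_fluid(moving, fixed)
    J = jacobian_determinant(field)
    yy, xx = np.mgrid[0:64, 0:64].astype(float)
    inside = np.hypot(yy - 31.5, xx - 31.5) < 8
    assert J[inside].mean() == pytest.approx(1.44, rel=0.10)
    assert report.final_ssd < report.initial_ssd


def radial_field(shape, amplitude=2.5, width=10.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
    c = (np.array(shape) - 1) / 2.0
    d = np.hypot(yy - c[0], xx - c[1]) + 1e-9
    mag = amplitude * np.exp(-(d**2) / (2 * width**2))
    return np.stack([mag * (yy - c[0]) / d, mag * (xx - c[1]) / d])


def test_fluid_recovers_known_smooth_warp():
    """>=80% of a known radial displacement recovered inside the object."""
    fixed = smooth_blob_2d(shape=(64, 64), center=(32, 32), radii=(18, 13))
    true_u = radial_field((64, 64))
    deformed = warp_image(fixed, -true_u, order=3)  # deformed(x) = fixed(x - u)
    # register the original onto the deformed copy: expected field ~ -u
    field, _ = register_fluid(fixed, deformed,
                              FluidParams(n_levels=2, max_iter=300))
    inside = fixed > 0.2
    err = np.linalg.norm(field.disp + true_u, axis=0)
    mag = np.linalg.norm(true_u, axis=0)
    core = inside & (mag > 0.5)
    assert np.median(err[core]) < 0.5
    recovered = 1.0 - err[core] / np.maximum(mag[core], 1e-9)
    assert np.median(recovered) > 0.8


def test_fluid_inverse_consistency_smoke():
    a = soft_disk(10)
    b = soft_disk(12)
    fab, _ = register_fluid(a, b)
    fba, _ = register_fluid(b, a)
    comp = compose_displacements(fab.disp, fba.disp)
    yy, xx = np.mgrid[0:64, 0:64].astype(float)
    inside = np.hypot(yy - 31.5, xx - 31.5) < 12
    assert np.median(np.linalg.norm(comp, axis=0)[inside]) < 0.5


def test_jacobian_integral_conserves_object_area():
    """Mean J over the fixed mask x mask area ~ moving object area (5%)."""
    fixed = soft_disk(10)
    moving = soft_disk(12)
    field, _ = register_fluid(moving, fixed)
    J = jacobian_determinant(field)
    mask = fixed > 0.5
    assert (J[mask].mean() * mask.sum()) == pytest.approx((moving > 0.5).sum(),
                                                          rel=0.05)


# --- jacobian --------------------------------------------------------------

def test_zero_field_jacobian_is_one():
    f = DisplacementField(np.zeros((3, 5, 5, 5)))
    assert np.allclose(jacobian_determinant(f), 1.0)


def test_uniform_scale_field_jacobian_is_s_cubed():
    s = 1.1
    zz, yy, xx = np.mgrid[0:12, 0:12, 0:12].astype(float)
    disp = np.stack([(s - 1) * zz, (s - 1) * yy, (s - 1) * xx])
    J = jacobian_determinant(DisplacementField(disp))
    interior = J[1:-1, 1:-1, 1:-1]
    assert np.allclose(interior, s**3, rtol=1e-10)


def test_polynomial_field_matches_analytic_determinant():
    """u = (a*y^2, b*x*y): det(I+Du) = (1+2ay)(1+by) - 0*bx analytically."""
    yy, xx = np.mgrid[0:20, 0:20].astype(float)
    a, b = 1e-3, 2e-3
    disp = np.stack([a * yy**2, b * xx * yy])
    analytic = (1 + 2 * a * yy) * (1 + b * yy)
    J = jacobian_determinant(DisplacementField(disp))
    assert np.allclose(J[1:-1, 1:-1], analytic[1:-1, 1:-1], atol=1e-6)


def test_nonfinite_field_rejected():
    disp = np.zeros((2, 4, 4))
    disp[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        jacobian_determinant(DisplacementField(disp))
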