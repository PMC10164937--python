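import numpy as np
import pytest

from wingmorph.efa import (
    AliasingError,
    efa_decompose,
    nef_feature_vector,
    outline_size_measures,
    reconstruct_contour,
    resample_contour,
    shoelace_area,
)
from wingmorph.simulate import ellipse_contour


def blob_contour(m=256, seed=0):
    """A smooth, elongated, non-symmetric closed test contour."""
    phi = np.linspace(0, 2 * np.pi, m, endpoint=False)
    r = 1.0 + 0.25 * np.cos(phi + 0.7) + 0.12 * np.cos(2 * phi) + 0.06 * np.sin(3 * phi)
    pts = np.column_stack([2.0 * r * np.cos(phi), r * np.sin(phi)])
    return pts


def test_resample_unit_square_equal_arcs():
    square = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
    rs = resample_contour(square, 8)
    closed = np.vstack([rs, rs[:1]])
    gaps = np.sqrt((np.diff(closed, axis=0) ** 2).sum(axis=1))
    np.testing.assert_allclose(gaps, 0.5, atol=1e-12)
    np.testing.assert_allclose(rs[0], square[0])


def test_resample_preserves_perimeter():
    blob = blob_contour(512)
    rs = resample_contour(blob, 51200)
    from wingmorph.efa import perimeter
    assert perimeter(rs) == pytest.approx(perimeter(blob), rel=1e-6)
    # exact when resampled points hit every vertex (square, spacing 0.25)
    square = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
    assert perimeter(resample_contour(square, 16)) == pytest.approx(4.0, abs=1e-12)


def test_resample_reverses_clockwise_input():
    square_cw = np.array([[0.0, 0], [0, 1], [1, 1], [1, 0]])
    rs = resample_contour(square_cw, 16)
    assert shoelace_area(rs) > 0
    np.testing.assert_allclose(rs[0], square_cw[0])


def test_circle_single_harmonic():
    circle = ellipse_contour(3.0, 3.0, m=512, center=(5.0, -2.0))
    coeffs = efa_decompose(circle, H=6, normalize=False)
    major, minor = coeffs.first_ellipse_axes
    assert major == pytest.approx(3.0, rel=1e-4)
    assert minor == pytest.approx(3.0, rel=1e-4)
    assert np.abs(coeffs.harmonics[1:]).max() < 1e-6 * 3.0
    np.testing.assert_allclose(coeffs.dc, [5.0, -2.0], atol=1e-3)


def test_ellipse_harmonic_axes():
    """First-harmonic semi-axes of a 2:1 ellipse under the arc-length
    parameterization.

    Expected values frozen from an independent dense numerical integration
    of the first Fourier harmonic of x(s), y(s): the arc-length convention
    yields (1.82841, 1.07302), not the geometric semi-axes (2, 1) of the
    angle parameterization (equality holds only for circles).
    """
    ell = ellipse_contour(2.0, 1.0, m=2048)
    raw = efa_decompose(ell, H=4, normalize=False)
    major, minor = raw.first_ellipse_axes
    assert major == pytest.approx(1.828412, rel=1e-4)
    assert minor == pytest.approx(1.073017, rel=1e-4)
    coeffs = efa_decompose(resample_contour(ell, 1024), H=4, normalize=True)
    assert coeffs.scale == pytest.approx(major, rel=1e-3)
    # normalized first harmonic: a1=1, b1=c1=0, |d1| = minor/major
    a1, b1, c1, d1 = coeffs.harmonics[0]
    assert a1 == pytest.approx(1.0)
    assert abs(b1) < 1e-9 and abs(c1) < 1e-9
    assert abs(d1) == pytest.approx(minor / major, rel=1e-3)


def test_nef_invariance_under_similarity_and_start_shift(rng):
    blob = blob_contour(360)
    ref = efa_decompose(resample_contour(blob, 512), H=6)
    theta = np.deg2rad(37.0)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = np.roll(blob, 101, axis=0) @ rot.T * 3.0 + np.array([4.0, -7.0])
    other = efa_decompose(resample_contour(moved, 512), H=6)
    np.testing.assert_allclose(ref.harmonics, other.harmonics, atol=1e-6)
    np.testing.assert_allclose(nef_feature_vector(ref), nef_feature_vector(other), atol=1e-6)


def test_outline_sizes_unit_square_and_circle():
    square = resample_contour(np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]]), 400)
    s = outline_size_measures(square)
    assert s.sqrt_area == pytest.approx(1.0, rel=1e-6)
    assert s.perimeter == pytest.approx(4.0, rel=1e-6)
    circle = ellipse_contour(1.0, 1.0, m=512)
    c = outline_size_measures(circle)
    assert c.sqrt_area == pytest.approx(np.sqrt(np.pi), rel=1e-3)
    assert c.perimeter == pytest.approx(2 * np.pi, rel=1e-3)
    assert c.semi_major_1 == pytest.approx(1.0, rel=1e-3)


def test_outline_sizes_scale_homogeneously():
    blob = blob_contour(256)
    s1 = outline_size_measures(blob)
    s3 = outline_size_measures(blob * 3.0)
    assert s3.sqrt_area == pytest.approx(3 * s1.sqrt_area, rel=1e-9)
    assert s3.perimeter == pytest.approx(3 * s1.perimeter, rel=1e-9)
    assert s3.semi_major_1 == pytest.approx(3 * s1.semi_major_1, rel=1e-9)


def test_isoperimetric_inequality_on_generated_contours(rng):
    from wingmorph.simulate import SyntheticConfig, simulate_outline_dataset
    ds = simulate_outline_dataset(SyntheticConfig(n_per_group=(3, 3, 3), seed=9))
    for c in ds.configurations:
        s = outline_size_measures(c.points)
        assert s.perimeter**2 >= 4 * np.pi * s.sqrt_area**2 - 1e-9


def test_reconstruction_round_trip_and_monotone_refinement():
    """Reconstruction error shrinks with H and is tiny at the Nyquist count.

    The coefficients are the exact Fourier series of the piecewise-linear
    contour, whose spectrum decays as 1/n^2, so truncation at H = m/2 leaves
    a small (not machine-zero) residual.
    """
    blob = resample_contour(blob_contour(256), 256)

    def rmse(h):
        co = efa_decompose(blob, H=h, normalize=False)
        r = reconstruct_contour(co, 256)
        return np.sqrt(((r - blob) ** 2).sum(axis=1)).mean()

    scale = np.abs(blob).max()
    assert rmse(128) < 1e-4 * scale
    assert rmse(2) >= rmse(8) - 1e-12
    assert rmse(8) >= rmse(32) - 1e-12
    assert rmse(32) >= rmse(128) - 1e-12


def test_circle_reconstruction_exact_at_h1():
    circle = ellipse_contour(1.0, 1.0, m=256)
    co = efa_decompose(circle, H=1, normalize=False)
    rec = reconstruct_contour(co, 256)
    r = np.sqrt((rec**2).sum(axis=1))
    np.testing.assert_allclose(r, 1.0, atol=1e-4)


def test_aliasing_guard():
    blob = blob_contour(32)
    with pytest.raises(AliasingError):
        efa_decompose(blob, H=17)
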