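"""Monogenic filters and decomposition: identities and invariances."""

import numpy as np
import pytest

from cinescar import build_filters, monogenic, monogenic_diff
from cinescar.io import myocardium_mask


@pytest.fixture(scope="module")
def filters128():
    return build_filters((128, 128), wavelength=16.0, sigma_on_f=0.5)


def test_log_gabor_peaks_at_centre_frequency():
    filt = build_filters((64, 64), wavelength=16.0)
    freqs = np.hypot(
        np.fft.fftfreq(64)[:, None], np.fft.fftfreq(64)[None, :]
    )
    at_f0 = np.isclose(freqs, 1.0 / 16.0, atol=1e-12)
    assert at_f0.any()
    assert np.allclose(filt.h_even[at_f0], 1.0)
    assert filt.h_even[0, 0] == 0.0  # DC killed
    assert (filt.h_even >= 0).all()


def test_riesz_multipliers_directional_and_unit_magnitude():
    filt = build_filters((64, 64), wavelength=8.0)
    # along the pure-horizontal-frequency axis (v = 0, u > 0): |r1| = 1, r2 = 0
    assert np.allclose(np.abs(filt.r1[0, 1:32]), 1.0)
    assert np.allclose(filt.r2[0, 1:32], 0.0)
    # along the pure-vertical axis: r1 = 0
    assert np.allclose(filt.r1[1:32, 0], 0.0)
    # off-DC unit-magnitude identity
    mag = filt.r1**2 + filt.r2**2
    mag[0, 0] = 1.0
    assert np.allclose(mag, 1.0, atol=1e-12)
    # odd symmetry r(-u, -v) = -r(u, v); on the fft grid the negated
    # frequency of index i sits at (n - i) % n (Nyquist rows excluded,
    # where +0.5 and -0.5 cycles/pixel coincide)
    n = 64
    rng = np.random.default_rng(0)
    for r in (filt.r1, filt.r2):
        for _ in range(200):
            i, j = rng.integers(0, n, size=2)
            if i == n // 2 or j == n // 2 or (i == 0 and j == 0):
                continue
            assert r[(n - i) % n, (n - j) % n] == pytest.approx(-r[i, j], abs=1e-12)


def test_invalid_filter_parameters_rejected():
    with pytest.raises(ValueError):
        build_filters((32, 32), wavelength=1.0)
    with pytest.raises(ValueError):
        build_filters((32, 32), sigma_on_f=1.5)


def test_constant_image_yields_zero_components(filters128):
    comp = monogenic(np.full((128, 128), 37.0), filters128)
    for arr in (comp.w, comp.q1, comp.q2, comp.amplitude, comp.phase):
        np.testing.assert_allclose(arr, 0.0, atol=1e-9)


def test_dc_offset_invariance(filters128):
    rng = np.random.default_rng(0)
    image = rng.normal(100, 20, size=(128, 128))
    a = monogenic(image, filters128)
    b = monogenic(image + 50.0, filters128)
    np.testing.assert_allclose(a.amplitude, b.amplitude, atol=1e-8)
    np.testing.assert_allclose(a.phase, b.phase, atol=1e-8)


def test_amplitude_identity_and_positivity(filters128):
    rng = np.random.default_rng(1)
    image = rng.normal(0, 1, size=(128, 128))
    comp = monogenic(image, filters128)
    np.testing.assert_allclose(
        comp.amplitude**2, comp.w**2 + comp.q1**2 + comp.q2**2, rtol=1e-6
    )
    assert (comp.amplitude >= 0).all()
    assert (comp.phase >= 0).all() and (comp.phase <= np.pi).all()


def test_horizontal_sinusoid_constant_amplitude(filters128):
    cols = np.arange(128)
    image = np.cos(2 * np.pi * cols / 16.0)[None, :].repeat(128, axis=0)
    comp = monogenic(image, filters128)
    interior = comp.amplitude[10:-10, 10:-10]
    cv = interior.std() / interior.mean()
    assert cv < 0.05
    # no vertical structure: q2 vanishes
    np.testing.assert_allclose(comp.q2, 0.0, atol=1e-9)


def test_homogeneity_amplitude_degree_one_phase_degree_zero(filters128):
    rng = np.random.default_rng(2)
    image = rng.normal(0, 1, size=(128, 128))
    a = monogenic(image, filters128)
    b = monogenic(image * 4.0, filters128)
    np.testing.assert_allclose(b.amplitude, 4.0 * a.amplitude, rtol=1e-8)
    np.testing.assert_allclose(b.phase, a.phase, atol=1e-8)


def test_rotation_equivariance_of_amplitude():
    filt = build_filters((96, 96), wavelength=12.0)
    rng = np.random.default_rng(3)
    image = rng.normal(0, 1, size=(96, 96))
    a = monogenic(image, filt).amplitude
    a_rot = monogenic(np.rot90(image), filt).amplitude
    np.testing.assert_allclose(a_rot, np.rot90(a), atol=1e-8)


def test_parseval_energy_bound(filters128):
    rng = np.random.default_rng(4)
    image = rng.normal(0, 1, size=(128, 128))
    comp = monogenic(image, filters128)
    assert np.sum(comp.w**2) <= np.sum(image**2) * filters128.h_even.max() ** 2 + 1e-9


def test_literal_arctan_convention_range(filters128):
    rng = np.random.default_rng(5)
    image = rng.normal(0, 1, size=(128, 128))
    comp = monogenic(image, filters128, phase_convention="literal-arctan")
    assert (comp.phase <= np.pi / 2 + 1e-12).all()
    assert (comp.phase >= -np.pi / 2).all()


def test_diff_of_equal_frames_is_zero(filters128):
    rng = np.random.default_rng(6)
    frame = rng.normal(100, 15, size=(128, 128))
    diff = monogenic_diff(frame, frame, filters128)
    np.testing.assert_array_equal(diff.ma.data, 0.0)
    np.testing.assert_array_equal(diff.mp.data, 0.0)


def test_diff_of_scaled_frame(filters128):
    rng = np.random.default_rng(7)
    ed = rng.normal(0, 1, size=(128, 128))
    diff = monogenic_diff(ed, 2.0 * ed, filters128)
    a_ed = monogenic(ed, filters128).amplitude
    np.testing.assert_allclose(diff.ma.data, -a_ed, rtol=1e-7, atol=1e-10)
    np.testing.assert_allclose(diff.mp.data, 0.0, atol=1e-8)


def test_scar_sector_ma_change_below_remote(scar_phantom):
    """Less deformation between ED and ES inside the scar sector means a
    smaller structural (amplitude) change there than on the remote wall."""
    loop, contours, _ = scar_phantom
    filt = build_filters(loop.shape, wavelength=8.0)
    T = loop.n_frames
    diff = monogenic_diff(loop.frames[0], loop.frames[T // 2], filt)
    myo = myocardium_mask(contours, 0, loop.shape)
    rows, cols = np.mgrid[0:64, 0:64]
    theta = np.mod(np.arctan2(rows - 32.0, cols - 32.0), 2 * np.pi)
    in_sector = theta < np.pi / 2
    scar_mean = np.abs(diff.ma.data)[myo & in_sector].mean()
    remote_mean = np.abs(diff.ma.data)[myo & ~in_sector].mean()
    assert scar_mean < remote_mean


def test_shape_mismatch_rejected(filters128):
    with pytest.raises(ValueError):
        monogenic(np.zeros((64, 64)), filters128)
    with pytest.raises(ValueError):
        monogenic_diff(np.zeros((128, 128)), np.zeros((64, 64)), filters128)
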