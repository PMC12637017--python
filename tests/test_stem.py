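import math

import numpy as np
import pytest

import cryocontrast as cc
from cryocontrast.multislice import SliceStack, exit_wave, vacuum_stack
from cryocontrast.optics import OpticsParameters
from cryocontrast.physics import PhysicsError
from cryocontrast.stem import (DetectorGeometry, parallax_shift,
                               default_mc_detector, probe_wave, record_4d,
                               shift_image, tilt_corrected_bf)
from cryocontrast.tem import image_from_exit_wave

from conftest import ncc


@pytest.fixture(scope="module")
def thin_stack(beam200):
    N, L = 128, 32.0
    x = (np.arange(N) + 0.5) * L / N
    X, Y = np.meshgrid(x, x)
    phi = (0.3 * np.exp(-((X - 13) ** 2 + (Y - 15) ** 2) / (2 * 2.0**2))
           + 0.4 * np.exp(-((X - 20) ** 2 + (Y - 18) ** 2) / (2 * 3.0**2)))
    return SliceStack(np.exp(1j * phi)[None].repeat(3, axis=0), 2.0, L,
                      beam200)


def test_detector_geometry_validation():
    with pytest.raises(PhysicsError):
        DetectorGeometry(ring_edges_mrad=[3.0, 2.0])
    with pytest.raises(PhysicsError):
        DetectorGeometry(ring_edges_mrad=[-1.0, 2.0])
    with pytest.raises(PhysicsError):
        DetectorGeometry(ring_edges_mrad=[0.0, 1.0], segments=0)
    det = DetectorGeometry(ring_edges_mrad=[0.0, 2.0, 4.0], segments=[4, 8])
    assert det.n_rings == 2
    assert len(det.bin_centers()) == 12


def test_default_detectors():
    d200 = default_mc_detector(200.0)
    assert d200.ring_edges_mrad == [0.0, 7.0, 10.0, 20.0, 30.0, 44.0]
    d1m = default_mc_detector(1000.0)
    assert d1m.ring_edges_mrad[1] == pytest.approx(2.43)
    with pytest.raises(PhysicsError):
        default_mc_detector(300.0)


def test_probe_unit_intensity_and_centering(beam200):
    opt = OpticsParameters(cs_mm=0.0, defocus_nm=0.0)
    w = probe_wave((16.0, 12.0), 3e-3, opt, beam200, 256, 64.0)
    assert w.intensity == pytest.approx(1.0, rel=1e-9)
    inten = np.abs(w.array) ** 2
    iy, ix = np.unravel_index(np.argmax(inten), inten.shape)
    x = (np.arange(256) + 0.5) * 64.0 / 256
    assert x[ix] == pytest.approx(16.0, abs=0.3)
    assert x[iy] == pytest.approx(12.0, abs=0.3)


def test_probe_airy_first_zero(beam200):
    # aberration-free probe is an Airy pattern with first zero at
    # 0.61 * lambda / alpha
    opt = OpticsParameters(cs_mm=0.0, defocus_nm=0.0)
    N, L = 512, 64.0
    alpha = 4e-3
    pos = 32.0625  # a pixel center, so the pattern is grid-symmetric
    w = probe_wave((pos, pos), alpha, opt, beam200, N, L)
    inten = np.abs(w.array) ** 2
    x = (np.arange(N) + 0.5) * L / N - pos
    X, Y = np.meshgrid(x, x)
    r = np.hypot(X, Y)
    r_zero = 0.61 * beam200.wavelength_nm / alpha
    # Airy-pattern oracle: 83.8% of the energy lies within the first zero
    enc = inten[r <= r_zero].sum() / inten.sum()
    assert enc == pytest.approx(0.838, abs=0.02)


def test_probe_convergence_beyond_sampling_rejected(beam200):
    opt = OpticsParameters()
    with pytest.raises(PhysicsError):
        probe_wave((0.0, 0.0), 10e-3, opt, beam200, 128, 64.0)


def test_record_vacuum_all_in_bf_disc(beam200):
    stack = vacuum_stack(3, 128, 32.0, 2.0, beam200)
    det = DetectorGeometry(ring_edges_mrad=[0.0, 1.0, 2.0, 3.0, 4.0],
                           segments=4)
    opt = OpticsParameters(cs_mm=2.0, defocus_nm=500.0)
    rec = record_4d(stack, opt, det, (4, 4), 4.0, 3e-3)
    total = rec.data.sum(axis=(2, 3))
    np.testing.assert_allclose(total + rec.beyond, 1.0, atol=1e-5)
    # all intensity within the convergence disc (<= 3 mrad rings)
    outside = rec.data[:, :, 3, :].sum()
    assert outside < 1e-6
    np.testing.assert_allclose(rec.absorbed, 0.0, atol=1e-5)


def test_record_ice_absorption_matches_attenuation(materials, beam200):
    # pure-ice stack: per-position deficit equals the exp(-mu t) oracle
    from cryocontrast.geometry import SpecimenModel, rasterize
    from cryocontrast.multislice import phase_gratings
    model = SpecimenModel(bodies=[], background="vitreous_ice",
                          materials=materials, bounds=(32.0, 32.0, 60.0))
    maps = rasterize(model, 128, 32.0, 2.0)
    stack = phase_gratings(maps, materials, beam200)
    det = DetectorGeometry(ring_edges_mrad=[0.0, 4.0], segments=1)
    opt = OpticsParameters(cs_mm=2.0, defocus_nm=500.0)
    rec = record_4d(stack, opt, det, (3, 3), 4.0, 3e-3)
    survived = 1.0 - rec.absorbed
    expect = math.exp(-1.82e-4 * 600.0)
    np.testing.assert_allclose(survived, expect, rtol=1e-4)


def test_parallax_shift_closed_form():
    opt = OpticsParameters(cs_mm=2.0, defocus_nm=2000.0)
    assert np.allclose(parallax_shift(np.zeros(2), opt), 0.0)
    # shift vanishes at df = Cs * omega^2
    om = 1e-3
    opt2 = OpticsParameters(cs_mm=2.0, defocus_nm=2e6 * om**2)
    assert np.allclose(parallax_shift(np.array([om, 0.0]), opt2), 0.0,
                       atol=1e-12)
    # scalar oracle: (Cs w^2 - df) w at w = 2 mrad, df = 2 um, Cs = 2 mm
    w = 2e-3
    expect = (2e6 * w**2 - 2000.0) * w
    got = parallax_shift(np.array([w, 0.0]), opt)
    assert got[0] == pytest.approx(expect, rel=1e-12)
    assert got[1] == 0.0


def test_parallax_identity_when_unaberrated():
    opt = OpticsParameters(cs_mm=0.0, defocus_nm=0.0)
    for om in (np.array([1e-3, 2e-3]), np.array([-3e-3, 0.5e-3])):
        assert np.allclose(parallax_shift(om, opt), 0.0)


def test_shift_image_round_trip():
    rng = np.random.default_rng(0)
    img = rng.normal(size=(64, 64))
    # band-limit to make Fourier shifting exact
    F = np.fft.fft2(img)
    F[10:-10, :] = 0
    F[:, 10:-10] = 0
    img = np.real(np.fft.ifft2(F))
    back = shift_image(shift_image(img, (1.3, -2.7)), (-1.3, 2.7))
    np.testing.assert_allclose(back, img, atol=1e-10)


def test_tcbf_single_axial_bin_is_plain_bf(thin_stack, beam200):
    det = DetectorGeometry(ring_edges_mrad=[0.0, 0.5], segments=1)
    opt = OpticsParameters(cs_mm=2.0, defocus_nm=500.0)
    rec = record_4d(thin_stack, opt, det, (16, 16), 2.0, 3e-3)
    # shift-correction self-consistency: with Cs = 0 and df = 0 the parallax
    # correction is the identity, so the single-bin tcBF is the raw BF image
    flat = OpticsParameters(cs_mm=0.0, defocus_nm=0.0)
    img = tilt_corrected_bf(rec, flat, 3e-3)
    raw = rec.data[:, :, 0, 0]
    np.testing.assert_allclose(img.counts, raw, rtol=1e-10, atol=1e-14)


def test_tcbf_excludes_bins_outside_bf_disc(thin_stack, beam200):
    det = DetectorGeometry(ring_edges_mrad=[0.0, 1.5, 3.0, 4.5], segments=4)
    opt = OpticsParameters(cs_mm=2.0, defocus_nm=500.0)
    rec = record_4d(thin_stack, opt, det, (8, 8), 4.0, 3e-3)
    with pytest.warns(UserWarning, match="outside the bright-field"):
        img = tilt_corrected_bf(rec, opt, 3e-3)
    assert img.provenance["bins_skipped"] == 4


def test_reciprocity_tcbf_matches_tem(beam200):
    # noiseless reciprocity regression: matched aperture, scan positions
    # aligned with image pixel centers
    N, L = 128, 32.0
    x = (np.arange(N) + 0.5) * L / N
    X, Y = np.meshgrid(x, x)
    phi = (0.3 * np.exp(-((X - 13) ** 2 + (Y - 15) ** 2) / (2 * 2.0**2))
           + 0.4 * np.exp(-((X - 20) ** 2 + (Y - 18) ** 2) / (2 * 3.0**2))
           + 0.25 * np.exp(-((X - 16) ** 2 + (Y - 22) ** 2) / (2 * 1.5**2)))
    stack = SliceStack(np.exp(1j * phi * 0.3)[None].repeat(4, axis=0),
                       2.0, L, beam200)
    conv = 3e-3
    opt = OpticsParameters(cs_mm=2.0, defocus_nm=500.0, aperture_mrad=3.0)
    tem = image_from_exit_wave(exit_wave(stack), opt, beam200,
                               envelopes=False)
    det = DetectorGeometry(ring_edges_mrad=list(np.linspace(0.0, 3.0, 7)),
                           segments=12)
    # scan 32x32, step 1 nm, origin chosen so probes sit on pixel centers
    origin = 0.375
    rec = record_4d(stack, opt, det, (32, 32), 1.0, conv,
                    scan_origin=(origin, origin))
    img = tilt_corrected_bf(rec, opt, conv).counts
    tem_pts = tem[1::4, 1::4]
    assert ncc(img, tem_pts) > 0.98


def test_tcbf_sum_improves_snr(thin_stack, beam200):
    # the aligned sum has more signal than any single bin at equal noise:
    # total intensity grows ~n_bins while structure stays coherent
    det = DetectorGeometry(ring_edges_mrad=[0.0, 1.0, 2.0, 3.0], segments=8)
    opt = OpticsParameters(cs_mm=0.0, defocus_nm=500.0)
    rec = record_4d(thin_stack, opt, det, (16, 16), 2.0, 3e-3)
    img = tilt_corrected_bf(rec, opt, 3e-3)
    single = rec.data[:, :, 0, 0]
    assert img.counts.mean() > 5 * single.mean()


def test_tcbf_ring_averaged_option(thin_stack, beam200):
    det = DetectorGeometry(ring_edges_mrad=[0.0, 1.0, 2.0, 3.0], segments=6)
    opt = OpticsParameters(cs_mm=2.0, defocus_nm=500.0)
    rec = record_4d(thin_stack, opt, det, (16, 16), 2.0, 3e-3)
    per_seg = tilt_corrected_bf(rec, opt, 3e-3)
    per_ring = tilt_corrected_bf(rec, opt, 3e-3, ring_averaged=True)
    # same structure, different weighting
    assert ncc(per_seg.counts, per_ring.counts) > 0.95


def test_record_scan_beyond_field_rejected(thin_stack):
    det = DetectorGeometry(ring_edges_mrad=[0.0, 4.0])
    opt = OpticsParameters()
    with pytest.raises(PhysicsError):
        record_4d(thin_stack, opt, det, (16, 16), 4.0, 3e-3)
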