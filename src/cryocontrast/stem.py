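"""Phase-contrast STEM by reciprocity: probe scan, segmented-detector 4D
recording, parallax correction and tilt-corrected bright-field summation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .multislice import (SliceStack, WaveField, bandlimit_mask, exit_wave,
                         k_grids, max_sampled_angle)
from .optics import OpticsParameters, chi
from .physics import BeamParameters, PhysicsError
from .tem import SimImage


@dataclass
class DetectorGeometry:
    """Annular rings split into azimuthal segments.

    ``ring_edges_mrad`` has n_rings + 1 strictly increasing entries starting
    at the inner cutoff of the first ring; ``segments`` is the azimuthal
    division per ring (a single int applies to every ring).
    """

    ring_edges_mrad: list[float]
    segments: int | list[int] = 1

    def __post_init__(self) -> None:
        e = np.asarray(self.ring_edges_mrad, dtype=float)
        if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0) or e[0] < 0:
            raise PhysicsError("ring edges must be >= 0 and strictly increasing")
        segs = self.segments
        if isinstance(segs, int):
            segs = [segs] * self.n_rings
        if len(segs) != self.n_rings or any(s < 1 for s in segs):
            raise PhysicsError("need >= 1 azimuthal segment per ring")
        self._segs = list(segs)

    @property
    def n_rings(self) -> int:
        return len(self.ring_edges_mrad) - 1

    @property
    def segments_per_ring(self) -> list[int]:
        return self._segs

    @property
    def max_segments(self) -> int:
        return max(self._segs)

    @property
    def outer_mrad(self) -> float:
        return float(self.ring_edges_mrad[-1])

    def bin_centers(self) -> list[tuple[int, int, np.ndarray]]:
        """(ring, segment, omega vector in rad) for every bin."""
        out = []
        e = self.ring_edges_mrad
        for r in range(self.n_rings):
            theta_c = 0.5 * (e[r] + e[r + 1]) * 1e-3
            ns = self._segs[r]
            for s in range(ns):
                phi = (s + 0.5) * 2.0 * math.pi / ns
                out.append((r, s, theta_c * np.array([math.cos(phi),
                                                      math.sin(phi)])))
        return out


def default_mc_detector(energy_keV: float = 200.0) -> DetectorGeometry:
    """The four-bin segmented-detector ranges used for the incoherent images.

    200 keV: 0-7 (BF), 10-20, 20-30, 30-44 mrad.  1 MeV: the same wavevector
    ranges, scaled by the wavelength ratio: 0-2.43, 3.5-7.0, 7.0-10.4,
    10.4-15.3 mrad.
    """
    if energy_keV == 200.0:
        edges = [0.0, 7.0, 10.0, 20.0, 30.0, 44.0]
    elif energy_keV == 1000.0:
        edges = [0.0, 2.43, 3.5, 7.0, 10.4, 15.3]
    else:
        raise PhysicsError("tabulated detectors exist for 200 keV and 1 MeV only")
    # ring index 1 (between BF and the first DF ring) is a physical gap; it
    # is kept as a ring so conservation bookkeeping stays simple
    return DetectorGeometry(ring_edges_mrad=edges, segments=1)


MC_BIN_LABELS = ["BF", "gap", "DF1", "DF2", "DF3"]


@dataclass
class FourDRecord:
    """Scan grid x detector bins intensity record.

    ``data`` is (ny, nx, n_rings, max_segments); unused segment slots of
    coarser rings stay zero.  ``beyond`` and ``absorbed`` close the per-
    position electron budget: sum(bins) + beyond + absorbed = 1.
    """

    data: np.ndarray
    detector: DetectorGeometry
    scan_step: float            # nm
    scan_origin: tuple[float, float]
    beyond: np.ndarray          # (ny, nx) intensity beyond the detector
    absorbed: np.ndarray        # (ny, nx) deficit vs unit probe
    meta: dict = field(default_factory=dict)

    @property
    def scan_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


def probe_wave(position: tuple[float, float], convergence_rad: float,
               optics: OpticsParameters, beam: BeamParameters,
               N: int, L: float) -> WaveField:
    """Aberrated, aperture-limited probe centered at ``position`` (nm).

    Normalized to unit total intensity.
    """
    theta_max = max_sampled_angle(N, L, beam)
    if convergence_rad > theta_max:
        raise PhysicsError(
            f"convergence {convergence_rad * 1e3:.2f} mrad exceeds the sampled "
            f"angle {theta_max * 1e3:.2f} mrad")
    kx, ky, k2 = k_grids(N, L)
    theta = np.sqrt(k2) * beam.wavelength_nm
    pupil = (theta <= convergence_rad).astype(np.complex128)
    pupil *= np.exp(-1j * chi(theta, optics, beam))
    x0, y0 = position
    pupil *= np.exp(-2j * math.pi * (kx * x0 + ky * y0))
    psi = np.fft.ifft2(pupil)
    norm = math.sqrt(float(np.sum(np.abs(psi) ** 2)))
    return WaveField(psi / norm, L)


def _bin_index_maps(detector: DetectorGeometry, N: int, L: float,
                    beam: BeamParameters):
    """Flattened detector-bin index per k-space sample (-1 outside)."""
    kx, ky, k2 = k_grids(N, L)
    theta = np.sqrt(k2) * beam.wavelength_nm
    phi = np.mod(np.arctan2(ky, kx), 2.0 * math.pi)
    edges = np.asarray(detector.ring_edges_mrad) * 1e-3
    ring = np.searchsorted(edges, theta, side="right") - 1
    valid = (ring >= 0) & (ring < detector.n_rings) & (theta >= edges[0])
    ms = detector.max_segments
    flat = np.full(theta.shape, -1, dtype=np.int64)
    for r in range(detector.n_rings):
        ns = detector.segments_per_ring[r]
        sel = valid & (ring == r)
        seg = np.minimum((phi[sel] / (2.0 * math.pi) * ns).astype(np.int64),
                         ns - 1)
        flat[sel] = r * ms + seg
    return flat, theta


def record_4d(stack: SliceStack, optics: OpticsParameters,
              detector: DetectorGeometry, scan_shape: tuple[int, int],
              scan_step: float, convergence_rad: float,
              scan_origin: tuple[float, float] = (0.0, 0.0),
              batch: int = 16, single_precision: bool = True,
              ) -> FourDRecord:
    """Scan an aberrated probe and bin each far-field pattern on the detector.

    Probe positions are processed in FFT batches; ``single_precision``
    (default) runs the per-probe multislice in complex64, ample for binned
    intensities.
    """
    import scipy.fft as _fft

    beam = stack.beam
    N, L = stack.N, stack.L
    ny, nx = scan_shape
    if scan_origin[0] + (nx - 1) * scan_step > L or \
            scan_origin[1] + (ny - 1) * scan_step > L:
        raise PhysicsError("scan grid extends beyond the simulated field")
    theta_max = max_sampled_angle(N, L, beam)
    if convergence_rad > theta_max:
        raise PhysicsError(
            f"convergence {convergence_rad * 1e3:.2f} mrad exceeds the sampled "
            f"angle {theta_max * 1e3:.2f} mrad")
    cdtype = np.complex64 if single_precision else np.complex128
    flat, _ = _bin_index_maps(detector, N, L, beam)
    inside = flat >= 0
    flat_in = flat[inside]
    ms = detector.max_segments
    nbins = detector.n_rings * ms
    data = np.zeros((ny, nx, detector.n_rings, ms))
    beyond = np.zeros((ny, nx))
    absorbed = np.zeros((ny, nx))

    kx, ky, k2 = k_grids(N, L)
    theta = np.sqrt(k2) * beam.wavelength_nm
    pupil0 = ((theta <= convergence_rad)
              * np.exp(-1j * chi(theta, optics, beam))).astype(cdtype)
    kernel = (np.exp(-1j * math.pi * beam.wavelength_nm * stack.delta_t * k2)
              * bandlimit_mask(N, L)).astype(cdtype)
    grids = stack.grids.astype(cdtype)

    coords = [(iy, ix) for iy in range(ny) for ix in range(nx)]
    for lo in range(0, len(coords), batch):
        chunk = coords[lo:lo + batch]
        xs = np.array([scan_origin[0] + ix * scan_step for _, ix in chunk])
        ys = np.array([scan_origin[1] + iy * scan_step for iy, _ in chunk])
        ramp = np.exp(-2j * math.pi * (kx[None] * xs[:, None, None]
                                       + ky[None] * ys[:, None, None]))
        psi = _fft.ifft2(pupil0[None] * ramp.astype(cdtype), axes=(-2, -1))
        norm = np.sqrt(np.sum(np.abs(psi) ** 2, axis=(-2, -1)))
        psi /= norm[:, None, None]
        for i in range(stack.n_slices):
            psi *= grids[i][None]
            psi = _fft.ifft2(_fft.fft2(psi, axes=(-2, -1)) * kernel[None],
                             axes=(-2, -1))
        I_k = np.abs(_fft.fft2(psi, axes=(-2, -1))) ** 2 / (N * N)
        for j, (iy, ix) in enumerate(chunk):
            total = float(I_k[j].sum())
            binned = np.bincount(flat_in, weights=I_k[j][inside].astype(float),
                                 minlength=nbins)
            data[iy, ix] = binned.reshape(detector.n_rings, ms)
            beyond[iy, ix] = total - binned.sum()
            absorbed[iy, ix] = 1.0 - total
    return FourDRecord(data=data, detector=detector, scan_step=scan_step,
                       scan_origin=scan_origin, beyond=beyond,
                       absorbed=absorbed,
                       meta={"convergence_rad": convergence_rad,
                             "energy_keV": beam.energy_keV,
                             "defocus_nm": optics.defocus_nm,
                             "cs_mm": optics.cs_mm})


def parallax_shift(omega: np.ndarray, optics: OpticsParameters) -> np.ndarray:
    """Image displacement (Cs*|omega|^2 - df) * omega in nm for tilt omega (rad)."""
    om = np.asarray(omega, dtype=float)
    om2 = np.sum(om**2, axis=-1, keepdims=True)
    return (optics.cs_nm * om2 - optics.defocus_nm) * om


def shift_image(img: np.ndarray, shift_px: tuple[float, float]) -> np.ndarray:
    """Subpixel translation by (dx, dy) pixels via a Fourier phase ramp."""
    ny, nx = img.shape
    fx = np.fft.fftfreq(nx)
    fy = np.fft.fftfreq(ny)
    KX, KY = np.meshgrid(fx, fy)
    ramp = np.exp(-2j * math.pi * (KX * shift_px[0] + KY * shift_px[1]))
    return np.real(np.fft.ifft2(np.fft.fft2(img) * ramp))


def tilt_corrected_bf(record: FourDRecord, optics: OpticsParameters,
                      convergence_rad: float | None = None,
                      fluence: float | None = None,
                      seed: int | None = None,
                      ring_averaged: bool = False) -> SimImage:
    """Sum parallax-corrected scan images of all bright-field detector bins.

    Bins whose center lies beyond the bright-field disc (the probe
    convergence) are excluded with a warning.  With ``fluence`` (e-/A^2) the
    summed intensity is converted to Poisson counts at the *full* incident
    fluence -- there is no energy-selection loss in this mode.
    """
    if convergence_rad is None:
        convergence_rad = record.meta.get("convergence_rad")
    if convergence_rad is None:
        raise PhysicsError("bright-field disc (convergence) not specified")
    step = record.scan_step
    total = np.zeros(record.scan_shape)
    n_used = 0
    n_skipped = 0
    ring_sums: dict[int, tuple[np.ndarray, int]] = {}
    for ring, seg, omega in record.detector.bin_centers():
        if np.linalg.norm(omega) > convergence_rad + 1e-12:
            n_skipped += 1
            continue
        img = record.data[:, :, ring, seg]
        # undo the (Cs w^2 - df) w displacement of this tilt's scan image;
        # with this package's FFT conventions the correction is +d
        d = parallax_shift(omega, optics)  # nm
        shifted = shift_image(img, (d[0] / step, d[1] / step))
        if ring_averaged:
            acc, cnt = ring_sums.get(ring, (np.zeros(record.scan_shape), 0))
            ring_sums[ring] = (acc + shifted, cnt + 1)
        else:
            total += shifted
        n_used += 1
    if ring_averaged:
        # equal weight per ring instead of per segment
        for acc, cnt in ring_sums.values():
            total += acc / cnt
        total *= n_used / max(len(ring_sums), 1)
    if n_skipped:
        warnings.warn(f"{n_skipped} detector bins outside the bright-field "
                      "disc were excluded from the tcBF sum", stacklevel=2)
    if n_used == 0:
        raise PhysicsError("no detector bins inside the bright-field disc")
    prov = dict(record.meta, mode="tcbf", bins_used=n_used,
                bins_skipped=n_skipped)
    from .tem import add_shot_noise
    if fluence is None:
        return SimImage(counts=total, pixel_size=step, fluence=float("nan"),
                        seed=None, provenance=prov)
    return add_shot_noise(total, fluence, step, seed, prov)
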