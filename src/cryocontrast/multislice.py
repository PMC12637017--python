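"""Multislice propagation of the electron wave through a voxelized specimen.

Complex per-slice transmission functions exp(i*phi - mu*dt/2) alternate with
Fourier-space Fresnel propagation exp(-i*pi*lambda*dt*k^2) (spatial frequency
k in cycles/nm; this sign convention is fixed here and used consistently by
the optics and image pipelines).  A circular 2/3-band mask is applied after
every slice as anti-aliasing hygiene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import MaterialMap
from .physics import (A_PER_NM, BeamParameters, Material, PhysicsError,
                      optical_constants, phase_per_thickness)


@dataclass
class WaveField:
    """Complex wave amplitudes on an L x L field sampled N x N."""

    array: np.ndarray  # (N, N) complex
    L: float           # nm

    @property
    def N(self) -> int:
        return self.array.shape[0]

    @property
    def intensity(self) -> float:
        return float(np.sum(np.abs(self.array) ** 2))

    def copy(self) -> "WaveField":
        return WaveField(self.array.copy(), self.L)


def plane_wave(N: int, L: float, amplitude: float = 1.0) -> WaveField:
    return WaveField(np.full((N, N), amplitude, dtype=np.complex128), L)


def k_grids(N: int, L: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(kx, ky, k^2) spatial-frequency grids in cycles/nm, fftfreq layout."""
    f = np.fft.fftfreq(N, d=L / N)
    kx, ky = np.meshgrid(f, f)
    return kx, ky, kx**2 + ky**2


def bandlimit_mask(N: int, L: float, fraction: float = 2.0 / 3.0) -> np.ndarray:
    _, _, k2 = k_grids(N, L)
    k_nyq = N / (2.0 * L)
    return k2 <= (fraction * k_nyq) ** 2


@dataclass
class SliceStack:
    """Per-slice complex transmission grids plus sampling metadata."""

    grids: np.ndarray          # (n_slices, N, N) complex
    delta_t: float             # nm
    L: float                   # nm
    beam: BeamParameters

    @property
    def n_slices(self) -> int:
        return self.grids.shape[0]

    @property
    def N(self) -> int:
        return self.grids.shape[1]

    @property
    def thickness(self) -> float:
        return self.n_slices * self.delta_t


def phase_gratings(maps: list[MaterialMap], materials: dict[str, Material],
                   beam: BeamParameters, absorb_beyond: float = 6e-3,
                   ) -> SliceStack:
    """Build exp(i*phi - mu*dt/2) transmission grids from material maps.

    ``absorb_beyond`` (rad) is the aperture beyond which scattering is treated
    as absorption: mu is taken over the window (absorb_beyond, pi).
    """
    if not 0.0 < absorb_beyond < math.pi:
        raise PhysicsError("absorb_beyond must lie in (0, pi)")
    if not maps:
        raise PhysicsError("empty material map sequence")
    names = maps[0].materials
    dt_A = maps[0].delta_t * A_PER_NM
    values = np.empty(len(names), dtype=np.complex128)
    for idx, name in enumerate(names):
        if name not in materials:
            raise PhysicsError(f"material map references unknown material {name!r}")
        oc = optical_constants(materials[name], beam, absorb_beyond, math.pi)
        values[idx] = np.exp(1j * oc.phase_per_A * dt_A - oc.mu * dt_A / 2.0)
    grids = values[np.stack([m.grid for m in maps])]
    N = maps[0].grid.shape[0]
    return SliceStack(grids=grids, delta_t=maps[0].delta_t,
                      L=N * maps[0].pixel_size, beam=beam)


def vacuum_stack(n_slices: int, N: int, L: float, delta_t: float,
                 beam: BeamParameters) -> SliceStack:
    return SliceStack(np.ones((n_slices, N, N), dtype=np.complex128),
                      delta_t, L, beam)


def propagate(wave: WaveField, distance: float, beam: BeamParameters,
              ) -> WaveField:
    """Free-space Fresnel propagation by ``distance`` nm (unitary)."""
    if distance < 0:
        raise PhysicsError("propagation distance must be >= 0")
    if distance == 0:
        return wave.copy()
    _, _, k2 = k_grids(wave.N, wave.L)
    kernel = np.exp(-1j * math.pi * beam.wavelength_nm * distance * k2)
    return WaveField(np.fft.ifft2(np.fft.fft2(wave.array) * kernel), wave.L)


def exit_wave(stack: SliceStack, incident: WaveField | None = None,
              bandlimit: float = 2.0 / 3.0) -> WaveField:
    """Propagate ``incident`` (default: unit plane wave) through the stack."""
    if stack.n_slices == 0:
        raise PhysicsError("empty slice stack")
    if incident is None:
        incident = plane_wave(stack.N, stack.L)
    if incident.N != stack.N or abs(incident.L - stack.L) > 1e-9:
        raise PhysicsError("incident wave sampling does not match the stack")
    _, _, k2 = k_grids(stack.N, stack.L)
    kernel = np.exp(-1j * math.pi * stack.beam.wavelength_nm
                    * stack.delta_t * k2)
    if bandlimit is not None:
        kernel = kernel * bandlimit_mask(stack.N, stack.L, bandlimit)
    psi = incident.array.copy()
    for i in range(stack.n_slices):
        psi *= stack.grids[i]
        psi = np.fft.ifft2(np.fft.fft2(psi) * kernel)
    return WaveField(psi, stack.L)


def max_sampled_angle(N: int, L: float, beam: BeamParameters) -> float:
    """Largest scattering angle sampled along the cell side: lambda*N/(2L), rad."""
    if N <= 0 or L <= 0:
        raise PhysicsError("N and L must be positive")
    return beam.wavelength_nm * N / (2.0 * L)


def slice_error(material: Material, beam: BeamParameters, delta_t: float,
                theta_M: float, total_thickness: float | None = None) -> float:
    """Fractional multislice error from finite slice thickness.

    Per slice the error is half the product of the slice phase shift
    (evaluated with the scattering factor at ``theta_M``) and the propagator
    phase at ``theta_M`` across one slice, each proportional to ``delta_t``.
    With ``total_thickness`` the per-slice error is multiplied by the number
    of slices, so the overall error scales linearly in ``delta_t``.
    """
    if delta_t <= 0:
        raise PhysicsError("delta_t must be positive")
    phi_per_A = phase_per_thickness(material, beam)
    f0 = material.f0(beam)
    f_at = float(material.f_average(theta_M, beam))
    phi_slice = phi_per_A * (f_at / f0) * delta_t * A_PER_NM
    prop_phase = theta_M**2 * (delta_t * A_PER_NM) / (2.0 * beam.wavelength_A)
    per_slice = 0.5 * phi_slice * prop_phase
    if total_thickness is None:
        return per_slice
    n = total_thickness / delta_t
    if abs(round(n) - n) > 1e-9:
        raise PhysicsError("delta_t must divide total_thickness")
    return per_slice * round(n)
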