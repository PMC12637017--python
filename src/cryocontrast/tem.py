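"""End-to-end TEM phase-contrast image simulation.

Exit wave -> aberrated image intensity -> zero-loss fluence budget ->
Poisson-noised electron counts.  Intensity 1 is the incident plane-wave
flux; electron counts appear only at the output stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import SpecimenModel, rasterize
from .multislice import SliceStack, WaveField, exit_wave, k_grids, phase_gratings
from .optics import OpticsParameters, transfer_function
from .physics import A_PER_NM, BeamParameters, PhysicsError


@dataclass
class SimImage:
    """Electron-count image with fluence and seed provenance."""

    counts: np.ndarray        # (N, N), electrons per pixel (float for noiseless)
    pixel_size: float         # nm
    fluence: float            # incident e-/A^2 at the specimen
    seed: int | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return self.counts.shape[0]


def image_from_exit_wave(wave: WaveField, optics: OpticsParameters,
                         beam: BeamParameters, envelopes: bool = True,
                         loss_ev: float | None = None) -> np.ndarray:
    """Aberrated image intensity |F^-1[ psi(k) exp(i chi) E(k) A(k) ]|^2."""
    _, _, k2 = k_grids(wave.N, wave.L)
    tf = transfer_function(k2, optics, beam, envelopes=envelopes,
                           loss_ev=loss_ev)
    img = np.fft.ifft2(np.fft.fft2(wave.array) * tf)
    return np.abs(img) ** 2


def zero_loss_fluence(fluence_in: float, ice_thickness_nm: float,
                      inelastic_mfp_nm: float) -> float:
    """Fluence left in the zero-loss peak: f * exp(-t/lambda_imfp)."""
    if fluence_in < 0 or ice_thickness_nm < 0 or inelastic_mfp_nm <= 0:
        raise PhysicsError("fluence/thickness must be >= 0 and mfp > 0")
    return fluence_in * math.exp(-ice_thickness_nm / inelastic_mfp_nm)


def add_shot_noise(intensity: np.ndarray, fluence: float, pixel_size_nm: float,
                   seed: int | None, provenance: dict | None = None) -> SimImage:
    """Poisson counts with mean = intensity * fluence * pixel area.

    ``fluence`` is in e-/A^2; ``seed=None`` returns the noiseless expectation.
    """
    if fluence < 0:
        raise PhysicsError("fluence must be >= 0")
    mean = np.asarray(intensity, dtype=float) * fluence \
        * (pixel_size_nm * A_PER_NM) ** 2
    if np.any(mean < 0):
        raise PhysicsError("negative expected counts")
    if seed is None:
        counts = mean
    else:
        counts = np.random.default_rng(seed).poisson(mean).astype(float)
    return SimImage(counts=counts, pixel_size=pixel_size_nm, fluence=fluence,
                    seed=seed, provenance=provenance or {})


def simulate_tem(model: SpecimenModel, beam: BeamParameters,
                 optics: OpticsParameters, fluence: float = 4.0,
                 seed: int | None = 0, N: int = 512, L: float | None = None,
                 delta_t: float = 2.0, absorb_beyond: float = 6e-3,
                 inelastic_mfp_nm: float | None = None,
                 stack: SliceStack | None = None) -> SimImage:
    """Zero-loss energy-filtered TEM image of the model.

    Composes rasterize -> phase gratings -> multislice -> aberrated image ->
    zero-loss fluence budget -> shot noise.  A prebuilt ``stack`` bypasses
    rasterization (for reuse across defocus series).
    """
    if L is None:
        L = model.bounds[0]
    if stack is None:
        maps = rasterize(model, N=N, L=L, delta_t=delta_t)
        stack = phase_gratings(maps, model.materials, beam,
                               absorb_beyond=absorb_beyond)
    wave = exit_wave(stack)
    intensity = image_from_exit_wave(wave, optics, beam)
    if inelastic_mfp_nm is None:
        bg = model.materials[model.background]
        inelastic_mfp_nm = bg.inelastic_mfp_nm or math.inf
    t = model.bounds[2]
    filtered = zero_loss_fluence(fluence, t, inelastic_mfp_nm)
    prov = {
        "mode": "tem",
        "energy_keV": beam.energy_keV,
        "defocus_nm": optics.defocus_nm,
        "cs_mm": optics.cs_mm,
        "N": stack.N,
        "L_nm": stack.L,
        "delta_t_nm": stack.delta_t,
        "thickness_nm": t,
        "fluence_incident": fluence,
        "fluence_zero_loss": filtered,
    }
    return add_shot_noise(intensity, filtered, stack.L / stack.N, seed, prov)
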