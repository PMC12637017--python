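"""Aberration function, contrast transfer and coherence envelopes.

Angles are radians, lengths nm.  Defocus is positive for underfocus, so
chi(theta) = pi/lambda * (Cs*theta^4/2 - df*theta^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import constants as _const

from .physics import BeamParameters, PhysicsError

NM_PER_MM = 1e6


@dataclass
class OpticsParameters:
    """Objective-lens and illumination settings."""

    cs_mm: float = 2.0
    defocus_nm: float = 500.0        # underfocus positive
    aperture_mrad: float | None = None   # objective semi-angle
    convergence_mrad: float = 0.0        # illumination semi-angle (Gaussian source)
    focal_spread_nm: float = 0.0
    source: str = "gaussian"             # 'gaussian' | 'lorentzian'
    source_width_mrad: float | None = None  # overrides convergence if set

    def __post_init__(self) -> None:
        if self.cs_mm < 0 or self.focal_spread_nm < 0:
            raise PhysicsError("Cs and focal spread must be >= 0")
        if self.source not in ("gaussian", "lorentzian"):
            raise PhysicsError(f"unknown source distribution {self.source!r}")

    @property
    def cs_nm(self) -> float:
        return self.cs_mm * NM_PER_MM

    @property
    def aperture_rad(self) -> float | None:
        return None if self.aperture_mrad is None else self.aperture_mrad * 1e-3


def chi(theta, optics: OpticsParameters, beam: BeamParameters):
    """Wavefront aberration phase (rad) at scattering angle theta (rad)."""
    th = np.asarray(theta, dtype=float)
    lam = beam.wavelength_nm
    return (math.pi / lam) * (0.5 * optics.cs_nm * th**4
                              - optics.defocus_nm * th**2)


def dchi_dtheta(theta, optics: OpticsParameters, beam: BeamParameters):
    """d(chi)/d(theta), rad per rad."""
    th = np.asarray(theta, dtype=float)
    lam = beam.wavelength_nm
    return (math.pi / lam) * (2.0 * optics.cs_nm * th**3
                              - 2.0 * optics.defocus_nm * th)


def scherzer_defocus(cs_mm: float, beam: BeamParameters) -> float:
    """Extended Scherzer defocus sqrt(4 Cs lambda / 3) in nm."""
    if cs_mm <= 0:
        raise PhysicsError("Cs must be positive")
    return math.sqrt(4.0 * cs_mm * NM_PER_MM * beam.wavelength_nm / 3.0)


def temporal_envelope(k, focal_spread_nm: float, beam: BeamParameters):
    """Gaussian focal-spread damping at spatial frequency k (1/nm)."""
    if focal_spread_nm < 0:
        raise PhysicsError("focal spread must be >= 0")
    kk = np.asarray(k, dtype=float)
    lam = beam.wavelength_nm
    return np.exp(-0.5 * (math.pi * lam * focal_spread_nm * kk**2) ** 2)


def focal_spread_from_energy(delta_e_ev: float, cc_mm: float,
                             beam: BeamParameters) -> float:
    """Chromatic focal spread Cc * dE/E* (nm), E* the relativistic voltage.

    E* = E (1 + E/2mc^2) / (1 + E/mc^2); for dE << E this is the standard
    defocus change per unit energy loss.
    """
    E = beam.energy_keV * 1e3
    mc2 = _const.electron_mass * _const.c**2 / _const.electron_volt
    estar = E * (1.0 + E / (2.0 * mc2)) / (1.0 + E / mc2)
    return cc_mm * NM_PER_MM * delta_e_ev / estar


def characteristic_angle(energy_loss_ev: float, beam: BeamParameters) -> float:
    """Relativistic dipole characteristic angle theta_E = dE / (gamma m v^2), rad."""
    mc2_ev = _const.electron_mass * _const.c**2 / _const.electron_volt
    gamma = beam.gamma
    # gamma m v^2 = gamma m c^2 beta^2
    return energy_loss_ev / (gamma * mc2_ev * beam.beta2)


def spatial_envelope(k, optics: OpticsParameters, beam: BeamParameters,
                     source: str | None = None,
                     width_rad: float | None = None):
    """Source-size damping driven by the aberration gradient d(chi)/d(theta).

    A tilt omega of the illumination (or, by reciprocity, of a detector
    pixel) advances the aberration phase by omega * dchi/dtheta; averaging
    over the source distribution gives its characteristic function evaluated
    there: Gaussian sources damp as exp(-(w*dchi/dtheta)^2/2), Lorentzian
    sources (inelastic dipole scattering) as exp(-w*|dchi/dtheta|).
    """
    source = source or optics.source
    if width_rad is None:
        if optics.source_width_mrad is not None:
            width_rad = optics.source_width_mrad * 1e-3
        else:
            width_rad = optics.convergence_mrad * 1e-3
    if width_rad < 0:
        raise PhysicsError("source width must be >= 0")
    kk = np.asarray(k, dtype=float)
    theta = kk * beam.wavelength_nm
    grad = dchi_dtheta(theta, optics, beam)
    if source == "gaussian":
        return np.exp(-0.5 * (width_rad * grad) ** 2)
    return np.exp(-width_rad * np.abs(grad))


def aperture_mask(k, aperture_rad: float | None, beam: BeamParameters):
    kk = np.asarray(k, dtype=float)
    if aperture_rad is None:
        return np.ones_like(kk)
    return (kk * beam.wavelength_nm <= aperture_rad).astype(float)


def ctf(k, optics: OpticsParameters, beam: BeamParameters,
        loss_ev: float | None = None):
    """Phase-contrast transfer sin(chi) with envelopes and aperture.

    ``loss_ev`` switches the spatial envelope to the Lorentzian inelastic
    form with the characteristic angle of that energy loss.
    """
    kk = np.asarray(k, dtype=float)
    theta = kk * beam.wavelength_nm
    t = np.sin(chi(theta, optics, beam))
    t = t * temporal_envelope(kk, optics.focal_spread_nm, beam)
    if loss_ev is not None:
        t = t * spatial_envelope(kk, optics, beam, source="lorentzian",
                                 width_rad=characteristic_angle(loss_ev, beam))
    elif (optics.convergence_mrad > 0 or optics.source_width_mrad):
        t = t * spatial_envelope(kk, optics, beam)
    return t * aperture_mask(kk, optics.aperture_rad, beam)


def transfer_function(k2, optics: OpticsParameters, beam: BeamParameters,
                      envelopes: bool = True, loss_ev: float | None = None):
    """Complex pupil exp(-i*chi)*envelopes*aperture on a k^2 grid (1/nm^2).

    The -i*chi sign pairs with the propagator convention exp(-i*pi*lam*dt*k^2)
    of the multislice module; with it a weak phase object images as
    I = 1 + 2*F^-1[Phi(k) sin(chi)] and underfocus gives the familiar
    positive-defocus contrast.
    """
    kk = np.sqrt(np.asarray(k2, dtype=float))
    theta = kk * beam.wavelength_nm
    tf = np.exp(-1j * chi(theta, optics, beam)).astype(np.complex128)
    if envelopes:
        tf *= temporal_envelope(kk, optics.focal_spread_nm, beam)
        if loss_ev is not None:
            tf *= spatial_envelope(kk, optics, beam, source="lorentzian",
                                   width_rad=characteristic_angle(loss_ev, beam))
        elif optics.convergence_mrad > 0 or optics.source_width_mrad:
            tf *= spatial_envelope(kk, optics, beam)
    tf *= aperture_mask(kk, optics.aperture_rad, beam)
    return tf


def depth_of_field(convergence_rad: float, beam: BeamParameters) -> float:
    """lambda / alpha^2 in nm."""
    if convergence_rad <= 0:
        raise PhysicsError("convergence must be positive")
    return beam.wavelength_nm / convergence_rad**2


def angle_to_resolution(theta_rad: float, beam: BeamParameters) -> float:
    """d = lambda / theta (nm); the convention behind the printed figures."""
    if theta_rad <= 0:
        raise PhysicsError("angle must be positive")
    return beam.wavelength_nm / theta_rad


def resolution_to_angle(d_nm: float, beam: BeamParameters) -> float:
    if d_nm <= 0:
        raise PhysicsError("resolution must be positive")
    return beam.wavelength_nm / d_nm


def convergence_for_resolution(d_nm: float, beam: BeamParameters) -> float:
    """Illumination semi-angle needed to include vectors up to d: lambda/(2d)."""
    return beam.wavelength_nm / (2.0 * d_nm)
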