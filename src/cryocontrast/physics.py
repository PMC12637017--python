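"""Relativistic beam quantities and low-angle electron scattering of amorphous materials.

External lengths are nm, energies keV.  Internally the phase/absorption
formulas use Angstrom (the natural unit of elastic scattering factors);
conversions are centralized in :data:`A_PER_NM`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy import constants as _const
from scipy.integrate import quad

A_PER_NM = 10.0  # Angstrom per nanometre

#: electron rest energy in keV
MC2_KEV = _const.electron_mass * _const.c**2 / _const.electron_volt / 1e3

# Peng, Ren, Dudarev & Whelan (1996) 5-Gaussian elastic scattering factor
# fits for neutral atoms: f(s) = sum_i a_i exp(-b_i s^2), s = sin(theta/2)/lambda
# in 1/A, f in A.  Only the light elements needed for ice/protein/nucleic acid.
PENG_COEFFS: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "H": ((0.0349, 0.1201, 0.1970, 0.0573, 0.1195),
          (0.5347, 3.5867, 12.3471, 18.9525, 38.6269)),
    "C": ((0.0893, 0.2563, 0.7570, 1.0487, 0.3575),
          (0.2465, 1.7100, 6.4094, 18.6113, 50.2523)),
    "N": ((0.1022, 0.3219, 0.7982, 0.8197, 0.1715),
          (0.2451, 1.7481, 6.1925, 17.3894, 48.1431)),
    "O": ((0.0974, 0.2921, 0.6910, 0.6990, 0.2039),
          (0.2067, 1.3815, 4.6943, 12.7105, 32.4726)),
    "P": ((0.2548, 0.6106, 1.4541, 2.3204, 0.8477),
          (0.2908, 1.8740, 8.5176, 24.3434, 63.2996)),
    "S": ((0.2497, 0.5628, 1.3899, 2.1865, 0.7715),
          (0.2681, 1.6711, 7.0267, 19.5377, 50.3888)),
}

ATOMIC_MASS: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06,
}

ATOMIC_NUMBER: dict[str, int] = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}


class PhysicsError(ValueError):
    """Domain error in a physics-level computation."""


@dataclass(frozen=True)
class BeamParameters:
    """Derived relativistic quantities for a given accelerating voltage.

    Attributes
    ----------
    energy_keV : accelerating voltage in kV (kinetic energy in keV)
    gamma : Lorentz factor
    wavelength_pm : relativistic de Broglie wavelength in pm
    wavevector : 2*pi/wavelength in 1/pm
    sigma : interaction constant in rad / (V * A)
    """

    energy_keV: float
    gamma: float
    wavelength_pm: float
    wavevector: float
    sigma: float

    @property
    def wavelength_nm(self) -> float:
        return self.wavelength_pm * 1e-3

    @property
    def wavelength_A(self) -> float:
        return self.wavelength_pm * 1e-2

    @property
    def beta2(self) -> float:
        """(v/c)^2."""
        return 1.0 - 1.0 / self.gamma**2


def beam_parameters(energy_keV: float) -> BeamParameters:
    """Relativistic wavelength, Lorentz factor and interaction constant.

    lambda = h c / sqrt(E (E + 2 m c^2)),  gamma = 1 + E / m c^2,
    sigma = 2 pi gamma m e lambda / h^2 (rad per volt-Angstrom).
    """
    if energy_keV <= 0:
        raise PhysicsError(f"accelerating voltage must be positive, got {energy_keV}")
    E = energy_keV * 1e3 * _const.electron_volt  # J
    mc2 = _const.electron_mass * _const.c**2
    gamma = 1.0 + E / mc2
    wavelength_m = _const.h * _const.c / math.sqrt(E * (E + 2.0 * mc2))
    wavelength_pm = wavelength_m * 1e12
    wavelength_A = wavelength_m * 1e10
    # interaction constant in rad/(V A)
    sigma = (2.0 * math.pi * gamma * _const.electron_mass * _const.e
             * (wavelength_m) / _const.h**2) * 1e-10
    return BeamParameters(
        energy_keV=float(energy_keV),
        gamma=gamma,
        wavelength_pm=wavelength_pm,
        wavevector=2.0 * math.pi / wavelength_pm,
        sigma=sigma,
    )


def lambda_gamma_product(energy_keV: float) -> float:
    """wavelength * gamma in pm: the voltage scaling of the scattering potential."""
    b = beam_parameters(energy_keV)
    return b.wavelength_pm * b.gamma


def lambda_gamma_squared(energy_keV: float) -> float:
    """(wavelength * gamma)^2 in pm^2: mean-free-path voltage scaling."""
    return lambda_gamma_product(energy_keV) ** 2


def scale_mfp(mfp_ref_nm: float, energy_ref_keV: float, energy_keV: float) -> float:
    """Scale a mean free path measured at one voltage to another.

    Incoherent mean free paths vary as 1/(lambda*gamma)^2.
    """
    return mfp_ref_nm * (lambda_gamma_squared(energy_ref_keV)
                         / lambda_gamma_squared(energy_keV))


@dataclass
class Material:
    """An amorphous material given by elemental number fractions and density.

    Optional overrides allow injecting tabulated per-material constants
    (average f(0), absorption coefficient for a stated angular window, and
    measured mean free paths) in place of values derived from the built-in
    scattering-factor parameterization.
    """

    name: str
    fractions: dict[str, float]
    density: float  # g/cc
    avg_f0: float | None = None          # override: composition-average f(0), A
    mu: float | None = None              # override: absorption coeff, 1/A, for mu_window
    mu_window_mrad: tuple[float, float] | None = None
    elastic_mfp_nm: float | None = None  # override (tabulated)
    inelastic_mfp_nm: float | None = None
    inelastic_mfp_ref_keV: float = 200.0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.density < 0:
            raise PhysicsError(f"density must be >= 0, got {self.density}")
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise PhysicsError(
                f"element fractions of {self.name!r} sum to {total}, expected 1")
        for el in self.fractions:
            if el not in PENG_COEFFS:
                raise PhysicsError(f"unknown element {el!r} in material {self.name!r}")

    @property
    def mean_atomic_mass(self) -> float:
        """sum_j n_j A_j in amu."""
        return sum(n * ATOMIC_MASS[el] for el, n in self.fractions.items())

    def f_element(self, element: str, theta: np.ndarray | float,
                  beam: BeamParameters) -> np.ndarray | float:
        """Elastic scattering factor (A) of one element at scattering angle theta (rad)."""
        a, b = PENG_COEFFS[element]
        s = np.sin(np.asarray(theta, dtype=float) / 2.0) / beam.wavelength_A
        s2 = s * s
        out = np.zeros_like(s2)
        for ai, bi in zip(a, b):
            out = out + ai * np.exp(-bi * s2)
        return out

    def f_average(self, theta: np.ndarray | float,
                  beam: BeamParameters) -> np.ndarray | float:
        """Composition-weighted average elastic scattering factor at theta (rad).

        If ``avg_f0`` is overridden the angular shape from the built-in
        parameterization is kept and rescaled so f_average(0) == avg_f0.
        """
        val = sum(n * self.f_element(el, theta, beam)
                  for el, n in self.fractions.items())
        if self.avg_f0 is not None:
            f0_param = sum(n * self.f_element(el, 0.0, beam)
                           for el, n in self.fractions.items())
            val = val * (self.avg_f0 / f0_param)
        return val

    def f0(self, beam: BeamParameters) -> float:
        if self.avg_f0 is not None:
            return self.avg_f0
        return float(sum(n * self.f_element(el, 0.0, beam)
                         for el, n in self.fractions.items()))

    @property
    def number_density_A3(self) -> float:
        """Atoms per cubic Angstrom (all species combined)."""
        if not self.fractions or self.density == 0:
            return 0.0
        return self.density / (1.66 * self.mean_atomic_mass)


@dataclass(frozen=True)
class OpticalConstants:
    """Per-material optical constants at a given beam and angular window."""

    phase_per_A: float      # rad/A
    mu: float               # 1/A over [theta_min, theta_max]
    window: tuple[float, float]  # rad
    elastic_mfp_nm: float
    inelastic_mfp_nm: float

    def __post_init__(self) -> None:
        if self.phase_per_A < 0 or self.mu < 0:
            raise PhysicsError("optical constants must be non-negative")


def phase_per_thickness(material: Material, beam: BeamParameters) -> float:
    """Phase shift per unit thickness (rad/A) from the mean inner potential.

    phi/t = lambda * rho * gamma * avg_f(0) / (1.66 * sum_j n_j A_j)
    with lambda in A and rho in g/cc.
    """
    if material.density == 0 or not material.fractions:
        return 0.0
    return (beam.wavelength_A * material.density * beam.gamma * material.f0(beam)
            / (1.66 * material.mean_atomic_mass))


def one_radian_thickness(mat_a: Material, mat_b: Material,
                         beam: BeamParameters) -> float:
    """Thickness (nm) of ``mat_a`` embedded in ``mat_b`` giving 1 rad phase difference."""
    dphi = phase_per_thickness(mat_a, beam) - phase_per_thickness(mat_b, beam)
    if dphi == 0.0:
        raise PhysicsError(
            f"materials {mat_a.name!r} and {mat_b.name!r} have identical phase "
            "shifts; the 1-radian thickness is undefined")
    return 1.0 / abs(dphi) / A_PER_NM


def absorption_coefficient(material: Material, beam: BeamParameters,
                           theta_min: float, theta_max: float) -> float:
    """Absorption coefficient mu (1/A) for scattering into [theta_min, theta_max].

    mu = gamma^2 rho / (1.66 sum n_j A_j) * integral over the solid-angle
    window of sum_j n_j f_j(theta)^2.
    """
    if not (0.0 <= theta_min <= theta_max <= math.pi):
        raise PhysicsError(
            f"angular window must satisfy 0 <= min <= max <= pi, got "
            f"({theta_min}, {theta_max})")
    if theta_min == theta_max or material.density == 0 or not material.fractions:
        return 0.0

    def integrand(theta: float) -> float:
        total = sum(n * material.f_element(el, theta, beam) ** 2
                    for el, n in material.fractions.items())
        return float(total) * 2.0 * math.pi * math.sin(theta)

    integral, _ = quad(integrand, theta_min, theta_max, limit=200)
    return (beam.gamma**2 * material.density
            / (1.66 * material.mean_atomic_mass)) * integral


def elastic_mfp(material: Material, beam: BeamParameters,
                prefer_override: bool = True) -> float:
    """Elastic mean free path in nm (tabulated override or 1/mu over the full sphere)."""
    if prefer_override and material.elastic_mfp_nm is not None:
        return material.elastic_mfp_nm
    mu = absorption_coefficient(material, beam, 0.0, math.pi)
    if mu == 0.0:
        return math.inf
    return 1.0 / mu / A_PER_NM


def attenuation(thickness_nm: float, mu_per_A: float | None = None,
                mfp_nm: float | None = None) -> float:
    """Transmitted fraction exp(-mu t) for thickness t.

    Exactly one of ``mu_per_A`` (1/A) or ``mfp_nm`` may be given.
    """
    if thickness_nm < 0:
        raise PhysicsError(f"thickness must be >= 0, got {thickness_nm}")
    if (mu_per_A is None) == (mfp_nm is None):
        raise PhysicsError("give exactly one of mu_per_A or mfp_nm")
    if mu_per_A is not None:
        return math.exp(-mu_per_A * thickness_nm * A_PER_NM)
    return math.exp(-thickness_nm / mfp_nm)


def optical_constants(material: Material, beam: BeamParameters,
                      theta_min: float, theta_max: float = math.pi,
                      ) -> OpticalConstants:
    """Bundle phase/absorption constants for one material and angular window.

    A tabulated ``material.mu`` override is honoured when its declared window
    matches the requested one (to 0.01 mrad).
    """
    mu = None
    if material.mu is not None and material.mu_window_mrad is not None:
        w = material.mu_window_mrad
        if (abs(w[0] * 1e-3 - theta_min) < 1e-5
                and (w[1] >= 3000.0 or abs(w[1] * 1e-3 - theta_max) < 1e-5)):
            mu = material.mu
    if mu is None:
        mu = absorption_coefficient(material, beam, theta_min, theta_max)
    imfp = material.inelastic_mfp_nm
    if imfp is not None and material.inelastic_mfp_ref_keV != beam.energy_keV:
        imfp = scale_mfp(imfp, material.inelastic_mfp_ref_keV, beam.energy_keV)
    return OpticalConstants(
        phase_per_A=phase_per_thickness(material, beam),
        mu=mu,
        window=(theta_min, theta_max),
        elastic_mfp_nm=elastic_mfp(material, beam),
        inelastic_mfp_nm=imfp if imfp is not None else math.inf,
    )


def load_materials(path: str | None = None) -> dict[str, Material]:
    """Load material definitions from YAML (the packaged defaults if no path)."""
    if path is None:
        text = resources.files("cryocontrast.data").joinpath(
            "materials.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out: dict[str, Material] = {}
    for name, entry in raw["materials"].items():
        out[name] = Material(
            name=name,
            fractions={k: float(v) for k, v in entry["fractions"].items()},
            density=float(entry["density"]),
            avg_f0=entry.get("avg_f0"),
            mu=entry.get("mu"),
            mu_window_mrad=(tuple(entry["mu_window_mrad"])
                            if "mu_window_mrad" in entry else None),
            elastic_mfp_nm=entry.get("elastic_mfp_nm"),
            inelastic_mfp_nm=entry.get("inelastic_mfp_nm"),
            inelastic_mfp_ref_keV=float(entry.get("inelastic_mfp_ref_keV", 200.0)),
        )
    return out


def default_materials() -> dict[str, Material]:
    return load_materials(None)
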