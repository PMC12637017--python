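"""Low-loss EELS modelling: log-ratio thickness, energy-window statistics and
synthetic thick-specimen spectra from Poisson multiple plasmon scattering.

The synthetic spectrum sums scattering orders explicitly: the n-fold
scattered component is the n-fold linear self-convolution of a unit-area
single-scattering profile, weighted Poisson(t/lambda).  The inelastic part
is renormalized on the recorded axis to its exact Poisson complement
1 - exp(-t/lambda), so the zero-loss fraction and the log-ratio thickness
are exact in the noiseless model regardless of axis truncation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .physics import PhysicsError


class DataError(ValueError):
    """Unusable spectral data."""


@dataclass
class EELSSpectrum:
    energy: np.ndarray   # eV, uniform, strictly increasing
    counts: np.ndarray   # per channel, >= 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.energy.ndim != 1 or self.energy.shape != self.counts.shape:
            raise DataError("energy and counts must be matching 1-D arrays")
        d = np.diff(self.energy)
        if len(d) and (np.any(d <= 0) or np.ptp(d) > 1e-6 * d[0]):
            raise DataError("energy axis must be uniform and increasing")
        if np.any(self.counts < 0):
            raise DataError("counts must be non-negative")

    @property
    def dispersion(self) -> float:
        return float(self.energy[1] - self.energy[0])

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def synthesize_spectrum(t_over_lambda: float, plasmon_energy: float = 20.0,
                        plasmon_width: float = 10.0, n_channels: int = 1024,
                        dispersion: float = 0.5, e_min: float = -12.0,
                        zero_loss_width: float = 1.0,
                        low_cutoff: float = 8.0,
                        total_counts: float = 1e6,
                        seed: int | None = None) -> EELSSpectrum:
    """Synthetic low-loss spectrum for a specimen of ``t_over_lambda`` mfp.

    The single-scattering profile is a Drude-like skewed Lorentzian peaked at
    ``plasmon_energy`` with FWHM ``plasmon_width``; the zero-loss peak is a
    Gaussian of FWHM ``zero_loss_width``.  Without a seed the noiseless
    expectation is returned, in which the zero-loss fraction is exactly
    exp(-t/lambda).
    """
    if t_over_lambda < 0:
        raise PhysicsError("t/lambda must be >= 0")
    from scipy.signal import fftconvolve
    from scipy.stats import poisson

    n_pad = 4 * n_channels
    energy = e_min + dispersion * np.arange(n_channels)
    e_pad = e_min + dispersion * np.arange(n_pad)
    i0 = int(round(-e_min / dispersion))  # channel of E = 0

    # single-scattering profile: E * Lorentzian (Drude-like shape), forced to
    # zero below ``low_cutoff`` so the zero-loss peak stays strictly separable
    # and its weight is exactly the Poisson zero-order term
    gam = plasmon_width / 2.0
    prof = np.where(e_pad > low_cutoff,
                    e_pad / ((e_pad**2 - plasmon_energy**2) ** 2
                             + (2.0 * gam * e_pad) ** 2), 0.0)
    s = prof.sum()
    if s == 0:
        raise PhysicsError("plasmon profile vanished on this axis")
    prof = prof / s

    # zero-loss peak, unit area, centered on E = 0
    sig = zero_loss_width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    zl = np.exp(-0.5 * (e_pad / sig) ** 2)
    zl /= zl.sum()

    # explicit order-by-order sum: linear convolutions so no energy wraps
    # back onto the zero-loss region; out-of-range mass is simply dropped
    t = t_over_lambda
    p0 = math.exp(-t)
    inel = np.zeros(n_pad)
    if t > 0:
        n_max = int(t + 10.0 * math.sqrt(t) + 15.0)
        order = prof.copy()
        for n in range(1, n_max + 1):
            inel += poisson.pmf(n, t) * order
            if n < n_max:
                # grid origin is channel i0; realign after full convolution
                order = fftconvolve(order, prof)[i0:i0 + n_pad]
        inel = np.clip(fftconvolve(inel, zl)[i0:i0 + n_pad], 0.0, None)

    spec = p0 * zl[:n_channels] + inel[:n_channels]
    inel_mass = inel[:n_channels].sum()
    if inel_mass > 0:
        # pin the inelastic weight on the recorded axis to 1 - exp(-t)
        spec = p0 * zl[:n_channels] \
            + (1.0 - p0) * inel[:n_channels] / inel_mass
    counts = spec * total_counts
    if seed is not None:
        counts = np.random.default_rng(seed).poisson(counts).astype(float)
    return EELSSpectrum(energy=energy, counts=counts, metadata={
        "t_over_lambda": t_over_lambda, "plasmon_energy_ev": plasmon_energy,
        "plasmon_width_ev": plasmon_width, "seed": seed})


def thickness_from_spectrum(spec: EELSSpectrum,
                            zero_loss_window: tuple[float, float] = (-4.0, 4.0),
                            ) -> float:
    """t/lambda = ln(I_total / I_zero-loss) by the log-ratio method."""
    lo, hi = zero_loss_window
    mask = (spec.energy >= lo) & (spec.energy <= hi)
    i0 = float(spec.counts[mask].sum())
    it = spec.total
    if i0 <= 0 or it <= 0:
        raise DataError("zero-loss or total integral is not positive")
    return math.log(it / i0)


def window_fraction(spec: EELSSpectrum, window: tuple[float, float]) -> float:
    """Fraction of all counts falling inside the energy window [lo, hi]."""
    lo, hi = window
    mask = (spec.energy >= lo) & (spec.energy <= hi)
    if not mask.any():
        warnings.warn("energy window contains no channels", stacklevel=2)
        return 0.0
    if spec.total == 0:
        raise DataError("empty spectrum")
    return float(spec.counts[mask].sum()) / spec.total


def optimal_window(spec: EELSSpectrum, width: float) -> tuple[float, float]:
    """Window of given width (eV) maximizing the captured fraction."""
    if width <= 0:
        raise PhysicsError("window width must be positive")
    n_win = max(int(round(width / spec.dispersion)), 1)
    c = np.convolve(spec.counts, np.ones(n_win), mode="valid")
    i = int(np.argmax(c))
    return (float(spec.energy[i]),
            float(spec.energy[i] + (n_win - 1) * spec.dispersion))


# ---------------------------------------------------------------------------
# I/O: two-column text and MSA

def write_text(spec: EELSSpectrum, path: str) -> None:
    np.savetxt(path, np.column_stack([spec.energy, spec.counts]),
               fmt="%.6g", header="energy_eV counts")


def read_text(path: str) -> EELSSpectrum:
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise DataError(f"{path}: expected two columns")
    return EELSSpectrum(energy=arr[:, 0], counts=arr[:, 1])


def write_msa(spec: EELSSpectrum, path: str, title: str = "spectrum") -> None:
    with open(path, "w") as fh:
        fh.write("#FORMAT      : EMSA/MAS Spectral Data File\n")
        fh.write("#VERSION     : 1.0\n")
        fh.write(f"#TITLE       : {title}\n")
        fh.write(f"#NPOINTS     : {len(spec.energy)}\n")
        fh.write("#NCOLUMNS    : 1\n")
        fh.write("#XUNITS      : eV\n")
        fh.write("#YUNITS      : counts\n")
        fh.write(f"#XPERCHAN    : {spec.dispersion:.6g}\n")
        fh.write(f"#OFFSET      : {spec.energy[0]:.6g}\n")
        fh.write("#DATATYPE    : XY\n")
        fh.write("#SPECTRUM    :\n")
        for e, c in zip(spec.energy, spec.counts):
            fh.write(f"{e:.6g}, {c:.6g}\n")
        fh.write("#ENDOFDATA   :\n")


def read_msa(path: str) -> EELSSpectrum:
    energy, counts, meta = [], [], {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) >= 2:
                energy.append(float(parts[0]))
                counts.append(float(parts[1]))
    if not energy:
        raise DataError(f"{path}: no spectral data found")
    return EELSSpectrum(energy=np.array(energy), counts=np.array(counts),
                        metadata=meta)
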