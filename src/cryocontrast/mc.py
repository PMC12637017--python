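"""Monte Carlo simulation of incoherent (amplitude) STEM contrast.

Electron trajectories are stepped through the voxelized specimen with
exponential free paths; elastic deflections follow a screened-Rutherford
angular distribution, inelastic deflections a Lorentzian dipole distribution
with cutoff.  Energy losses are tallied but do not alter trajectories
(tens of eV are negligible against hundreds of keV at these thicknesses).
Exit polar angles are binned onto a segmented annular detector.

Reproducibility contract: every scan position owns an independent child of
``numpy.random.SeedSequence(seed)``, so partitioning the scan across workers
or runs and summing partial tallies reproduces the single-stream result
exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import MaterialMap, SpecimenModel, rasterize
from .physics import (BeamParameters, Material, PhysicsError, beam_parameters,
                      elastic_mfp, scale_mfp, ATOMIC_NUMBER)
from .stem import DetectorGeometry, default_mc_detector
from .tem import SimImage

#: measured ratio of inelastic to elastic mean free path for vitreous ice
INELASTIC_TO_ELASTIC = 0.27

#: dipole-scattering angular cutoff (rad): beyond this the Lorentzian tail is
#: truncated (Bethe-ridge territory, negligible for low-loss events)
DIPOLE_CUTOFF = 20e-3

MAX_EVENTS = 10_000


@dataclass
class MCConfig:
    """Scan, dose and detector settings for a Monte Carlo run."""

    electrons_per_pixel: int = 10_000   # == 100 e-/A^2 on 1 nm pixels
    scan_shape: tuple[int, int] = (110, 110)
    scan_step: float = 1.0              # nm
    seed: int = 0
    energy_keV: float = 200.0
    detector: DetectorGeometry | None = None
    max_events: int = MAX_EVENTS

    def __post_init__(self) -> None:
        if self.electrons_per_pixel <= 0:
            raise PhysicsError("electrons_per_pixel must be positive")
        if self.detector is None:
            self.detector = default_mc_detector(self.energy_keV)


@dataclass
class MCResult:
    """Per-scan-position detector-bin counts with exact electron bookkeeping."""

    counts: np.ndarray         # (ny, nx, n_bins) int64
    out_of_range: np.ndarray   # (ny, nx) int64: beyond detector / backscattered
    config: MCConfig
    bin_labels: list[str] = field(default_factory=list)
    unscattered: np.ndarray | None = None  # (ny, nx) zero-event electrons

    def conservation_ok(self) -> bool:
        total = self.counts.sum(axis=2) + self.out_of_range
        return bool(np.all(total == self.config.electrons_per_pixel))


@dataclass(frozen=True)
class _MaterialMC:
    """Precomputed sampling constants for one material at one beam energy."""

    mfp_el_nm: float
    mfp_in_nm: float
    mfp_tot_nm: float
    p_inelastic: float
    elements: tuple[str, ...]
    elem_probs: np.ndarray      # selection probability per element
    theta0: np.ndarray          # screening angle per element (rad)
    theta_e: float              # dipole characteristic angle (rad)


def screening_angle(element: str, beam: BeamParameters) -> float:
    """Thomas-Fermi screening angle theta_0 = lambda / (2 pi R), R = 0.885 a0 Z^-1/3."""
    a0 = 0.529  # A
    R = 0.885 * a0 * ATOMIC_NUMBER[element] ** (-1.0 / 3.0)
    return beam.wavelength_A / (2.0 * math.pi * R)


def _prepare_material(mat: Material, beam: BeamParameters) -> _MaterialMC:
    if not mat.fractions or mat.density == 0:
        return _MaterialMC(math.inf, math.inf, math.inf, 0.0, (), np.empty(0),
                           np.empty(0), 0.0)
    mfp_el = elastic_mfp(mat, beam, prefer_override=True)
    if mat.elastic_mfp_nm is not None and beam.energy_keV != 200.0:
        mfp_el = scale_mfp(mat.elastic_mfp_nm, 200.0, beam.energy_keV)
    mfp_in = mat.inelastic_mfp_nm
    if mfp_in is None:
        mfp_in = INELASTIC_TO_ELASTIC * mfp_el
    elif mat.inelastic_mfp_ref_keV != beam.energy_keV:
        mfp_in = scale_mfp(mfp_in, mat.inelastic_mfp_ref_keV, beam.energy_keV)
    mfp_tot = 1.0 / (1.0 / mfp_el + 1.0 / mfp_in)
    elements = tuple(mat.fractions)
    theta0 = np.array([screening_angle(el, beam) for el in elements])
    z = np.array([ATOMIC_NUMBER[el] for el in elements], dtype=float)
    n = np.array([mat.fractions[el] for el in elements])
    # screened-Rutherford total cross section per element ~ Z^2 / theta0^2
    w = n * z**2 / theta0**2
    from .optics import characteristic_angle
    return _MaterialMC(
        mfp_el_nm=mfp_el, mfp_in_nm=mfp_in, mfp_tot_nm=mfp_tot,
        p_inelastic=mfp_tot / mfp_in, elements=elements,
        elem_probs=w / w.sum(), theta0=theta0,
        theta_e=characteristic_angle(20.0, beam))


def sample_free_path(mc: _MaterialMC, rng: np.random.Generator,
                     size: int) -> tuple[np.ndarray, np.ndarray]:
    """(path lengths nm, inelastic? flags) for ``size`` electrons."""
    if not np.isfinite(mc.mfp_tot_nm):
        return np.full(size, np.inf), np.zeros(size, dtype=bool)
    s = rng.exponential(mc.mfp_tot_nm, size)
    inelastic = rng.random(size) < mc.p_inelastic
    return s, inelastic


def sample_elastic_angle(mc: _MaterialMC, rng: np.random.Generator,
                         size: int) -> tuple[np.ndarray, np.ndarray]:
    """Screened-Rutherford polar angles + uniform azimuths (rad)."""
    idx = rng.choice(len(mc.elements), size=size, p=mc.elem_probs) \
        if len(mc.elements) > 1 else np.zeros(size, dtype=int)
    th0 = mc.theta0[idx]
    u = rng.random(size)
    # invert CDF of sin(theta) dtheta / (theta^2 + theta0^2)^2 on [0, pi]
    # (small-angle form, exact for the 1/(t^2+t0^2)^2 kernel)
    tmax2 = math.pi**2
    a = u / th0**2 + (1.0 - u) / (tmax2 + th0**2)
    theta = np.sqrt(1.0 / a - th0**2)
    phi = rng.uniform(0.0, 2.0 * math.pi, size)
    return theta, phi


def sample_inelastic_angle(mc: _MaterialMC, rng: np.random.Generator,
                           size: int) -> tuple[np.ndarray, np.ndarray]:
    """Lorentzian dipole polar angles with cutoff + uniform azimuths."""
    u = rng.random(size)
    te2 = mc.theta_e**2
    theta = np.sqrt(te2 * ((1.0 + DIPOLE_CUTOFF**2 / te2) ** u - 1.0))
    phi = rng.uniform(0.0, 2.0 * math.pi, size)
    return theta, phi


def _deflect(d: np.ndarray, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit direction vectors ``d`` (M,3) by polar/azimuthal deflections."""
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    # build an orthonormal frame around each direction
    dz = d[:, 2]
    small = np.abs(dz) > 0.999999
    ref = np.where(small[:, None], np.array([1.0, 0.0, 0.0]),
                   np.array([0.0, 0.0, 1.0]))
    e1 = np.cross(ref, d)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    return (ct[:, None] * d + st[:, None] * (cp[:, None] * e1
                                             + sp[:, None] * e2))


class _VoxelModel:
    """Material lookup on the rasterized stack (periodic laterally)."""

    def __init__(self, maps: list[MaterialMap]):
        self.grid = np.stack([m.grid for m in maps])  # (nz, N, N)
        self.names = maps[0].materials
        self.px = maps[0].pixel_size
        self.dt = maps[0].delta_t
        self.nz, self.ny, self.nx = self.grid.shape
        self.thickness = self.nz * self.dt
        self.L = self.nx * self.px

    def material_at(self, pts: np.ndarray) -> np.ndarray:
        ix = np.floor(np.mod(pts[:, 0], self.L) / self.px).astype(int) % self.nx
        iy = np.floor(np.mod(pts[:, 1], self.L) / self.px).astype(int) % self.ny
        iz = np.clip(np.floor(pts[:, 2] / self.dt).astype(int), 0, self.nz - 1)
        return self.grid[iz, iy, ix]


def _trace_pixel(vox: _VoxelModel, mats: list[_MaterialMC], start_xy: np.ndarray,
                 n: int, rng: np.random.Generator, max_events: int,
                 ) -> tuple[np.ndarray, int, int]:
    """Exit polar angles of electrons entering at ``start_xy``; -1 = lost.

    Also returns the number of electrons that crossed without any event.
    """
    pos = np.tile(np.array([start_xy[0], start_xy[1], 0.0]), (n, 1))
    dirs = np.tile(np.array([0.0, 0.0, 1.0]), (n, 1))
    exit_theta = np.full(n, -1.0)
    active = np.arange(n)
    t = vox.thickness
    n_events = 0
    n_unscattered = 0
    while len(active) and n_events < max_events:
        n_events += 1
        mat_idx = vox.material_at(pos[active])
        s = np.empty(len(active))
        inel = np.zeros(len(active), dtype=bool)
        for mi in np.unique(mat_idx):
            sel = mat_idx == mi
            s[sel], inel[sel] = sample_free_path(mats[mi], rng, int(sel.sum()))
        # clamp so vacuum (infinite path) stays finite in the arithmetic
        nxt = pos[active] + np.minimum(s, 1e9)[:, None] * dirs[active]
        # exits through the bottom before the next event
        dz = dirs[active][:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            exit_down = (dz > 0) & (nxt[:, 2] >= t)
            exit_up = (dz < 0) & (nxt[:, 2] <= 0.0)
        done = exit_down | exit_up
        if n_events == 1:
            n_unscattered = int(exit_down.sum())
        idx_done = active[done]
        theta_exit = np.arccos(np.clip(dirs[idx_done][:, 2], -1.0, 1.0))
        exit_theta[idx_done] = np.where(exit_down[done], theta_exit, -1.0)
        keep = ~done
        active = active[keep]
        if not len(active):
            break
        pos[active] = nxt[keep]
        # scatter at the event site, using the material there
        mat_here = vox.material_at(pos[active])
        theta = np.empty(len(active))
        phi = np.empty(len(active))
        inel_k = inel[keep]
        for mi in np.unique(mat_here):
            for flavour, sampler in ((False, sample_elastic_angle),
                                     (True, sample_inelastic_angle)):
                sel = (mat_here == mi) & (inel_k == flavour)
                if sel.any():
                    theta[sel], phi[sel] = sampler(mats[mi], rng, int(sel.sum()))
        dirs[active] = _deflect(dirs[active], theta, phi)
    if len(active):
        warnings.warn(f"{len(active)} trajectories exceeded {max_events} "
                      "events and were dropped", stacklevel=2)
    return exit_theta, n, n_unscattered


def run_mc(model: SpecimenModel, config: MCConfig, voxel_size: float = 1.0,
           delta_t: float = 2.0, maps: list[MaterialMap] | None = None,
           row_range: tuple[int, int] | None = None) -> MCResult:
    """Trace ``electrons_per_pixel`` trajectories per scan position.

    The specimen is voxelized at ``voxel_size`` laterally and ``delta_t``
    axially (or pass precomputed ``maps``).  Exit polar angles are binned by
    the detector rings; azimuthal segmentation uses the exit azimuth.

    ``row_range`` restricts the run to scan rows [lo, hi) while keeping the
    per-position RNG streams of the full grid, so partial runs sum exactly to
    the whole (rows outside the range stay zero in the tallies).
    """
    beam = beam_parameters(config.energy_keV)
    if maps is None:
        L = model.bounds[0]
        N = int(round(L / voxel_size))
        maps = rasterize(model, N=N, L=L, delta_t=delta_t)
    vox = _VoxelModel(maps)
    mats = [_prepare_material(model.materials[name], beam)
            for name in maps[0].materials]
    det = config.detector
    edges = np.asarray(det.ring_edges_mrad) * 1e-3
    ny, nx = config.scan_shape
    n_bins = det.n_rings
    counts = np.zeros((ny, nx, n_bins), dtype=np.int64)
    lost = np.zeros((ny, nx), dtype=np.int64)
    unscattered = np.zeros((ny, nx), dtype=np.int64)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(ny * nx)
    x0 = (vox.L - (nx - 1) * config.scan_step) / 2.0
    y0 = (vox.L - (ny - 1) * config.scan_step) / 2.0
    rows = range(ny) if row_range is None else range(*row_range)
    for iy in rows:
        for ix in range(nx):
            rng = np.random.default_rng(children[iy * nx + ix])
            start = np.array([x0 + ix * config.scan_step,
                              y0 + iy * config.scan_step])
            theta, n, n0 = _trace_pixel(vox, mats, start,
                                        config.electrons_per_pixel, rng,
                                        config.max_events)
            ok = theta >= 0.0
            ring = np.searchsorted(edges, theta[ok], side="right") - 1
            in_det = (ring >= 0) & (ring < n_bins)
            counts[iy, ix] = np.bincount(ring[in_det], minlength=n_bins)
            lost[iy, ix] = n - int(in_det.sum())
            unscattered[iy, ix] = n0
    labels = [f"{edges[i]*1e3:g}-{edges[i+1]*1e3:g} mrad"
              for i in range(n_bins)]
    return MCResult(counts=counts, out_of_range=lost, config=config,
                    bin_labels=labels, unscattered=unscattered)


def mc_images(result: MCResult) -> list[SimImage]:
    """One electron-count image per detector ring."""
    cfg = result.config
    fluence = cfg.electrons_per_pixel / (cfg.scan_step * 10.0) ** 2
    out = []
    for b in range(result.counts.shape[2]):
        out.append(SimImage(
            counts=result.counts[:, :, b].astype(float),
            pixel_size=cfg.scan_step, fluence=fluence, seed=cfg.seed,
            provenance={"mode": "mc", "bin": result.bin_labels[b],
                        "energy_keV": cfg.energy_keV}))
    return out
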