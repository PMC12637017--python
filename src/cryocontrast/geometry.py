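"""Constructive-solid-geometry specimen model of a tailless phage in vitreous ice.

The capsid is an elongated icosahedron (a regular icosahedron with a 5-fold
axis along its long axis, stretched anisotropically; an affine map keeps the
20 faces planar).  The genome is modelled as concentric cylindrical shells
of nucleic acid separated by a fixed gap, clipped to the capsid interior.

Coordinates: z is the beam axis, slices are half-open [z, z + dt); the image
origin is at the field corner with x fastest.  Rasterization samples voxel
centers (no antialiasing) -- pixels are much smaller than any feature here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .physics import Material, default_materials


class ModelError(ValueError):
    """Inconsistent specimen-model construction."""


# ---------------------------------------------------------------------------
# shapes

class Shape:
    def contains(self, pts: np.ndarray) -> np.ndarray:  # (M,3) -> (M,) bool
        raise NotImplementedError


@dataclass
class HalfSpaceSet(Shape):
    """Convex polyhedron: the set of points with normals . x <= offsets."""

    normals: np.ndarray  # (F,3), unit rows
    offsets: np.ndarray  # (F,)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return np.all(pts @ self.normals.T <= self.offsets[None, :] + 1e-12, axis=1)

    def shrunk(self, margin: float) -> "HalfSpaceSet":
        """Polyhedron with every face moved inward by ``margin`` (nm)."""
        return HalfSpaceSet(self.normals, self.offsets - margin)


@dataclass
class CylinderShell(Shape):
    """r_in <= rho <= r_out around the local z axis, |z| <= half_length."""

    r_in: float
    r_out: float
    half_length: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        rho2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
        return ((rho2 >= self.r_in**2) & (rho2 <= self.r_out**2)
                & (np.abs(pts[:, 2]) <= self.half_length))


@dataclass
class Slab(Shape):
    """z_min <= z <= z_max, unbounded laterally."""

    z_min: float
    z_max: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return (pts[:, 2] >= self.z_min) & (pts[:, 2] <= self.z_max)


@dataclass
class Intersection(Shape):
    parts: list

    def contains(self, pts: np.ndarray) -> np.ndarray:
        mask = np.ones(len(pts), dtype=bool)
        for p in self.parts:
            mask &= p.contains(pts)
        return mask


@dataclass
class Body:
    """A shape filled with one material, placed by a rigid transform.

    ``rotation`` and ``translation`` map local coordinates to model
    coordinates; containment tests apply the inverse transform to the query
    points.  Higher ``priority`` wins where bodies overlap.
    """

    shape: Shape
    material: str
    priority: int
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def contains(self, pts: np.ndarray) -> np.ndarray:
        local = (pts - self.translation[None, :]) @ self.rotation
        return self.shape.contains(local)


# ---------------------------------------------------------------------------
# model

@dataclass
class MaterialMap:
    """Material indices of one slice, sampled at voxel centers."""

    grid: np.ndarray          # (N, N) uint8, [iy, ix]
    pixel_size: float         # nm
    z: float                  # slice start, nm
    delta_t: float            # nm
    materials: list[str]      # index -> material name


@dataclass
class SpecimenModel:
    bodies: list[Body]
    background: str
    materials: dict[str, Material]
    bounds: tuple[float, float, float]  # L_x, L_y, thickness t (nm)
    phage_half_extent: np.ndarray | None = None  # (3,) nm, about phage center
    phage_center: np.ndarray | None = None

    @property
    def material_names(self) -> list[str]:
        names = [self.background]
        for b in self.bodies:
            if b.material not in names:
                names.append(b.material)
        return names

    def classify(self, pts: np.ndarray) -> np.ndarray:
        """Material index (into :attr:`material_names`) of each point (M,3)."""
        names = self.material_names
        out = np.zeros(len(pts), dtype=np.uint8)
        unassigned = np.ones(len(pts), dtype=bool)
        for body in sorted(self.bodies, key=lambda b: -b.priority):
            if not unassigned.any():
                break
            idx = np.where(unassigned)[0]
            hit = body.contains(pts[idx])
            out[idx[hit]] = names.index(body.material)
            unassigned[idx[hit]] = False
        return out


def _icosahedron_planes(length: float, width: float) -> HalfSpaceSet:
    """Face planes of an icosahedron with a 5-fold axis along z, stretched to
    ``length`` tip-to-tip along z and ``width`` across the equatorial rings."""
    phi = np.arange(5) * 2.0 * math.pi / 5.0
    ring = 2.0 / math.sqrt(5.0)
    zr = 1.0 / math.sqrt(5.0)
    verts = [[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]
    verts += [[ring * math.cos(p), ring * math.sin(p), zr] for p in phi]
    verts += [[ring * math.cos(p + math.pi / 5.0),
               ring * math.sin(p + math.pi / 5.0), -zr] for p in phi]
    v = np.asarray(verts)
    v[:, :2] *= (width / 2.0) / ring
    v[:, 2] *= length / 2.0
    hull = ConvexHull(v)
    eq = hull.equations  # rows: (a, b, c, d) with a.x + d <= 0 inside
    normals = eq[:, :3]
    norms = np.linalg.norm(normals, axis=1)
    return HalfSpaceSet(normals / norms[:, None], -eq[:, 3] / norms)


def _interior_inradius_xy(poly: HalfSpaceSet) -> float:
    """Largest cylinder radius (axis = z) fitting inside at the equator z=0."""
    lateral = np.abs(poly.normals[:, 2]) < 0.999
    n_xy = np.linalg.norm(poly.normals[lateral, :2], axis=1)
    return float(np.min(poly.offsets[lateral] / n_xy))


def _poly_volume_grid(poly: HalfSpaceSet, extent: float, half_len: float,
                      step: float = 0.5) -> float:
    """Deterministic grid estimate of the polyhedron volume (nm^3)."""
    ax = np.arange(-extent, extent, step) + step / 2.0
    az = np.arange(-half_len, half_len, step) + step / 2.0
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    vol = 0.0
    cell = step**3
    xy = np.column_stack([X.ravel(), Y.ravel()])
    for z in az:
        pts = np.column_stack([xy, np.full(len(xy), z)])
        vol += poly.contains(pts).sum() * cell
    return vol


def build_phage(capsid_length: float = 110.0, capsid_width: float = 80.0,
                shell_thickness: float = 3.0, dna_gap: float = 1.0,
                dna_shell_thickness: float = 2.0,
                dna_volume_fraction: float = 0.45,
                materials: dict[str, Material] | None = None) -> SpecimenModel:
    """Parametric phage: protein capsid shell with concentric DNA cylinders.

    ``dna_volume_fraction`` is the target ratio of DNA volume to capsid
    *interior* volume; cylinder shells of ``dna_shell_thickness`` separated by
    ``dna_gap`` are added from the outside in, the innermost one thinned to
    approach the target.  The long (5-fold) axis starts along z (top view).
    """
    if min(capsid_length, capsid_width, shell_thickness,
           dna_shell_thickness) <= 0 or dna_gap < 0:
        raise ModelError("phage dimensions must be positive")
    if not 0.0 <= dna_volume_fraction <= 0.95:
        raise ModelError("dna_volume_fraction must be in [0, 0.95]")
    materials = materials or default_materials()
    for req in ("protein", "dna", "vitreous_ice"):
        if req not in materials:
            raise ModelError(f"material set lacks {req!r}")

    outer = _icosahedron_planes(capsid_length, capsid_width)
    inner = outer.shrunk(shell_thickness)
    if np.any(inner.offsets <= 0):
        raise ModelError("shell thickness leaves no capsid interior")

    bodies = [Body(outer, "protein", priority=1),
              Body(inner, "vitreous_ice", priority=2)]

    r_max = _interior_inradius_xy(inner) - 0.25
    if dna_volume_fraction > 0:
        if r_max <= dna_shell_thickness:
            raise ModelError("DNA shells do not fit inside the capsid")
        v_int = _poly_volume_grid(inner, capsid_width / 2.0 + 1.0,
                                  capsid_length / 2.0 + 1.0)
        target = dna_volume_fraction * v_int
        half_len = capsid_length / 2.0  # clipped by the interior polyhedron
        pitch = dna_shell_thickness + dna_gap
        acc = 0.0
        prio = 3
        r_out = r_max
        thinned = False
        while r_out > 0.1 and acc < target and not thinned:
            r_in = max(r_out - dna_shell_thickness, 0.0)
            shell = Intersection([CylinderShell(r_in, r_out, half_len), inner])
            v_shell = _shell_volume_grid(shell)
            if acc + v_shell > target and v_shell > 0:
                thinned = True
                # thin the innermost shell (raise r_in) to land on the target
                want = target - acc
                lo, hi = r_in, r_out  # volume decreases as r_in rises
                for _ in range(30):
                    mid = 0.5 * (lo + hi)
                    v_mid = _shell_volume_grid(
                        Intersection([CylinderShell(mid, r_out, half_len), inner]))
                    if v_mid > want:
                        lo = mid
                    else:
                        hi = mid
                shell = Intersection(
                    [CylinderShell(0.5 * (lo + hi), r_out, half_len), inner])
                v_shell = _shell_volume_grid(shell)
            bodies.append(Body(shell, "dna", priority=prio))
            acc += v_shell
            prio += 1
            r_out -= pitch

    half = np.array([capsid_width / 2.0, capsid_width / 2.0, capsid_length / 2.0])
    return SpecimenModel(
        bodies=bodies, background="vitreous_ice", materials=materials,
        bounds=(capsid_width + 10.0, capsid_width + 10.0, capsid_length + 10.0),
        phage_half_extent=half, phage_center=np.zeros(3))


def _shell_volume_grid(shape: Shape, step: float = 0.5) -> float:
    """Grid-sampled volume of a clipped cylinder shell (nm^3)."""
    # bounding box from the cylinder part
    cyl = shape.parts[0] if isinstance(shape, Intersection) else shape
    r = cyl.r_out
    h = cyl.half_length
    ax = np.arange(-r, r, step) + step / 2.0
    az = np.arange(-h, h, step) + step / 2.0
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    xy = np.column_stack([X.ravel(), Y.ravel()])
    keep = xy[:, 0] ** 2 + xy[:, 1] ** 2 <= (r + step) ** 2
    xy = xy[keep]
    vol = 0.0
    for z in az:
        pts = np.column_stack([xy, np.full(len(xy), z)])
        vol += shape.contains(pts).sum()
    return vol * step**3


_ORIENTATIONS = {
    # long axis along the beam: top view, DNA renders as concentric rings
    "top": np.eye(3),
    # long axis along x: side view, DNA renders as parallel stripes
    "side": np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]]),
    # long axis along y
    "side2": np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, -1.0, 0.0]]),
}


def orient(model: SpecimenModel, orientation: str | np.ndarray) -> SpecimenModel:
    """Rigidly rotate all bodies about the phage center."""
    R = _ORIENTATIONS[orientation] if isinstance(orientation, str) \
        else np.asarray(orientation, dtype=float)
    center = model.phage_center if model.phage_center is not None else np.zeros(3)
    bodies = []
    for b in model.bodies:
        bodies.append(Body(shape=b.shape, material=b.material, priority=b.priority,
                           rotation=R @ b.rotation,
                           translation=center + R @ (b.translation - center)))
    half = model.phage_half_extent
    if half is not None:
        half = np.abs(R) @ half
    return SpecimenModel(bodies=bodies, background=model.background,
                         materials=model.materials, bounds=model.bounds,
                         phage_half_extent=half, phage_center=center)


def embed_in_ice(model: SpecimenModel, ice_thickness: float,
                 depth_of_center: float | None = None,
                 field_width: float | None = None) -> SpecimenModel:
    """Place the phage in an ice slab [0, ice_thickness] along z.

    ``depth_of_center`` defaults to the slab midplane.  Raises if the phage
    would protrude from the slab.
    """
    if depth_of_center is None:
        depth_of_center = ice_thickness / 2.0
    half = model.phage_half_extent
    if half is None:
        raise ModelError("model has no phage extent metadata")
    if depth_of_center - half[2] < -1e-9 or \
            depth_of_center + half[2] > ice_thickness + 1e-9:
        raise ModelError(
            f"phage (z half-extent {half[2]:.1f} nm) protrudes from "
            f"{ice_thickness} nm slab at depth {depth_of_center} nm")
    L = field_width if field_width is not None else model.bounds[0]
    center_old = model.phage_center if model.phage_center is not None else np.zeros(3)
    center_new = np.array([L / 2.0, L / 2.0, depth_of_center])
    shift = center_new - center_old
    bodies = [Body(shape=b.shape, material=b.material, priority=b.priority,
                   rotation=b.rotation, translation=b.translation + shift)
              for b in model.bodies]
    return SpecimenModel(bodies=bodies, background=model.background,
                         materials=model.materials,
                         bounds=(L, L, ice_thickness),
                         phage_half_extent=half, phage_center=center_new)


def rasterize(model: SpecimenModel, N: int, L: float,
              delta_t: float) -> list[MaterialMap]:
    """Sample the model on N x N voxel centers for each slice of ``delta_t``.

    The slab thickness must be an integer number of slices.
    """
    t = model.bounds[2]
    n_slices = round(t / delta_t)
    if abs(n_slices * delta_t - t) > 1e-6:
        raise ModelError(f"slice thickness {delta_t} does not divide {t}")
    px = L / N
    ax = (np.arange(N) + 0.5) * px
    X, Y = np.meshgrid(ax, ax)  # [iy, ix], x fastest
    xy = np.column_stack([X.ravel(), Y.ravel()])
    names = model.material_names
    maps = []
    for i in range(n_slices):
        zc = (i + 0.5) * delta_t
        pts = np.column_stack([xy, np.full(len(xy), zc)])
        grid = model.classify(pts).reshape(N, N)
        maps.append(MaterialMap(grid=grid, pixel_size=px, z=i * delta_t,
                                delta_t=delta_t, materials=names))
    return maps
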