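"""Voxel phantoms, the three benchmark heterogeneity cases, cone direction
sets and transport-line lattices.

The benchmark geometry is a cubic water phantom with a point Ir-192 source
at its center and a box-shaped heterogeneity (cortical bone or air) of
2.1 x 2.1 x 3.1 cm^3 offset along +x, its long axis along z:

========  ============  ==================
case      box medium    box center [cm]
========  ============  ==================
A         cortical bone (6, 0, 0)
B         cortical bone (3, 0, 0)
C         air           (3, 0, 0)
========  ============  ==================

Box faces must land exactly on voxel boundaries (no voxel may straddle a
media interface).  That is only possible for 0.1 cm-compatible voxel
sizes; ``snap_to_grid=True`` instead snaps each face to the nearest
boundary for coarser desk-scale grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _geometry
from .physics_data import Medium, standard_media

__all__ = [
    "VoxelPhantom",
    "HeterogeneityBox",
    "TransportLineLattice",
    "build_case",
    "build_water_phantom",
    "radiological_path",
    "cone_directions",
    "build_line_lattice",
    "CASE_SPECS",
]

#: (box medium, box-center offset a along +x [cm]) per benchmark case
CASE_SPECS = {
    "A": ("cortical_bone", 6.0),
    "B": ("cortical_bone", 3.0),
    "C": ("air", 3.0),
}

#: paper box half extents (x, y, z) [cm]
BOX_HALF_EXTENTS = (1.05, 1.05, 1.55)


@dataclass(frozen=True)
class HeterogeneityBox:
    """Axis-aligned heterogeneity box, long axis along z."""

    medium: str
    center: tuple[float, float, float]
    half_extents: tuple[float, float, float]

    def contains(self, x, y, z) -> np.ndarray:
        cx, cy, cz = self.center
        ex, ey, ez = self.half_extents
        return ((np.abs(x - cx) < ex) & (np.abs(y - cy) < ey)
                & (np.abs(z - cz) < ez))


@dataclass
class VoxelPhantom:
    """Uniform cubic-voxel phantom: media map plus densities.

    ``medium_index`` indexes into ``media``; ``density`` is per voxel
    [g/cm^3].  The source sits at the world origin, which coincides with
    the center of the central voxel for the benchmark builders.
    """

    shape: tuple[int, int, int]
    voxel_size: float
    origin: np.ndarray
    medium_index: np.ndarray
    density: np.ndarray
    media: list[Medium]
    source_position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    case_id: str | None = None
    box: HeterogeneityBox | None = None

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.medium_index.max() >= len(self.media):
            raise ValueError("medium index out of range")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size

    def voxel_centers(self):
        """Broadcastable (sparse) center-coordinate grids (x, y, z)."""
        return np.meshgrid(*(self.axis_centers(k) for k in range(3)),
                           indexing="ij", sparse=True)

    def voxel_volume(self) -> float:
        return self.voxel_size**3

    def box_mask(self) -> np.ndarray:
        """Boolean mask of voxels strictly inside the heterogeneity box."""
        if self.box is None:
            raise ValueError("phantom has no heterogeneity box")
        x, y, z = self.voxel_centers()
        return np.broadcast_to(self.box.contains(x, y, z), self.shape).copy()

    def mu_linear_per_medium(self, energy_mev) -> np.ndarray:
        """(n_media,) linear attenuation coefficients at one energy."""
        return np.array([m.mu_linear_at(energy_mev) for m in self.media])


def _aligned(value: float, origin: float, h: float, tol: float = 1e-9) -> bool:
    r = (value - origin) / h
    return abs(r - round(r)) < tol


def build_water_phantom(voxel_size: float = 0.1, side: float = 30.1) -> VoxelPhantom:
    """Homogeneous cubic water phantom with the source at its center."""
    n = int(round(side / voxel_size))
    if n % 2 == 0:
        n += 1  # keep the source on the central voxel center
    media = list(standard_media().values())
    origin = np.full(3, -0.5 * n * voxel_size)
    mi = np.zeros((n, n, n), dtype=np.uint8)
    rho = np.full((n, n, n), media[0].density)
    return VoxelPhantom((n, n, n), voxel_size, origin, mi, rho, media)


def build_case(case_id: str, voxel_size: float = 0.1, side: float = 30.1,
               snap_to_grid: bool = False,
               box_medium: str | None = None) -> VoxelPhantom:
    """Build benchmark case A, B or C.

    Defaults give the full-resolution geometry: a 30.1 cm water cube at
    0.1 cm voxels (301^3) with the box faces exactly on voxel boundaries.
    A voxel size that would make any box face cut through voxel interiors
    raises unless ``snap_to_grid`` is set, in which case faces snap to the
    nearest boundary (the engine and the MC reference then share the
    snapped geometry).
    """
    case_id = case_id.upper()
    if case_id not in CASE_SPECS:
        raise ValueError(f"unknown case {case_id!r}; expected one of A, B, C")
    medium_name, a = CASE_SPECS[case_id]
    if box_medium is not None:
        medium_name = box_medium
    ph = build_water_phantom(voxel_size, side)
    media_by_name = {m.name: i for i, m in enumerate(ph.media)}
    if medium_name not in media_by_name:
        raise ValueError(f"unknown box medium {medium_name!r}")

    h = ph.voxel_size
    # box center must sit on a voxel center (voxel centers at multiples of h)
    if abs(a / h - round(a / h)) > 1e-9:
        if not snap_to_grid:
            raise ValueError(
                f"box center x={a} cm is not a voxel center for voxel_size="
                f"{h}; no voxel may straddle a media boundary")
        a = round(a / h) * h

    half = []
    for e in BOX_HALF_EXTENTS:
        k = e / h - 0.5
        if abs(k - round(k)) > 1e-9:
            if not snap_to_grid:
                raise ValueError(
                    f"box half-extent {e} cm does not land on a voxel "
                    f"boundary for voxel_size={h}; no voxel may straddle a "
                    f"media boundary (use snap_to_grid=True to snap faces)")
            k = max(round(k), 0.0)
        half.append((round(k) + 0.5) * h)
    box = HeterogeneityBox(medium_name, (a, 0.0, 0.0), tuple(half))

    x, y, z = ph.voxel_centers()
    inside = np.broadcast_to(box.contains(x, y, z), ph.shape)
    mi = ph.medium_index
    target = media_by_name[medium_name]
    mi[inside] = target
    ph.density[inside] = ph.media[target].density
    ph.case_id = case_id
    ph.box = box
    return ph


def radiological_path(phantom: VoxelPhantom, p0, p1,
                      mu_linear: np.ndarray) -> float:
    """Optical depth between two points: sum over traversed voxels of
    geometric length times the linear attenuation of the voxel's medium.

    ``mu_linear`` is one linear coefficient [1/cm] per phantom medium.
    """
    mu_linear = np.asarray(mu_linear, dtype=float)
    if mu_linear.shape[0] != len(phantom.media):
        raise ValueError("need one coefficient per phantom medium")
    buf = np.zeros(len(phantom.media))
    nx, ny, nz = phantom.shape
    _geometry.walk_segments(np.asarray(p0, dtype=float),
                            np.asarray(p1, dtype=float),
                            phantom.origin, phantom.voxel_size,
                            nx, ny, nz, phantom.medium_index, buf)
    return float(np.dot(buf, mu_linear))


def cone_directions(n_directions: int, axis_seed: int = 0):
    """Deterministic zenith-uniform partition of the sphere into cones.

    Rings of equal-width cos(theta) bands are populated proportionally to
    band solid angle; returns unit vectors (M, 3) and per-cone solid
    angles (M,) summing to exactly 4 pi.
    """
    m = int(n_directions)
    if m < 1:
        raise ValueError("need at least one direction")
    n_rings = max(1, int(round(np.sqrt(m / 2.0))))
    edges = np.linspace(1.0, -1.0, n_rings + 1)  # cos(theta) band edges
    band_solid = 2.0 * np.pi * (edges[:-1] - edges[1:])
    raw = band_solid / (4.0 * np.pi) * m
    counts = np.maximum(1, np.floor(raw).astype(int))
    # largest-remainder top-up to exactly m
    while counts.sum() < m:
        counts[np.argmax(raw - counts)] += 1
    while counts.sum() > m:
        k = np.argmax(counts - raw)
        if counts[k] <= 1:
            break
        counts[k] -= 1
    dirs = np.empty((counts.sum(), 3))
    dom = np.empty(counts.sum())
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = 0
    for r in range(n_rings):
        ct = 0.5 * (edges[r] + edges[r + 1])
        st = np.sqrt(max(0.0, 1.0 - ct * ct))
        for j in range(counts[r]):
            phi = (j + 0.5) * 2.0 * np.pi / counts[r] + (r + axis_seed) * golden
            dirs[i] = (st * np.cos(phi), st * np.sin(phi), ct)
            dom[i] = band_solid[r] / counts[r]
            i += 1
    return dirs, dom


@dataclass
class TransportLineLattice:
    """Parallel transport lines for one direction.

    ``line_starts[l]:line_starts[l+1]`` delimits line ``l``'s ordered steps
    in ``voxel_flat`` (flat voxel index) / ``step_length`` [cm].
    ``dlmax`` is the per-voxel summed crossing length for this direction
    (the per-voxel total step length), flattened; ``line_area`` is the
    cross-sectional area one line represents.
    """

    direction: np.ndarray
    line_starts: np.ndarray
    voxel_flat: np.ndarray
    step_length: np.ndarray
    dlmax: np.ndarray
    line_area: float

    @property
    def n_lines(self) -> int:
        return len(self.line_starts) - 1


def build_line_lattice(phantom: VoxelPhantom, directions: np.ndarray,
                       spacing: float | None = None) -> list[TransportLineLattice]:
    """Build the transport-line lattice for each direction.

    Default lattice spacing is voxel_size/sqrt(2), which guarantees every
    voxel is crossed by at least one line in every direction (the voxel's
    projected shadow always contains a disc of diameter voxel_size).
    """
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    nx, ny, nz = phantom.shape
    h = phantom.voxel_size
    s = h / np.sqrt(2.0) if spacing is None else float(spacing)
    diag = np.sqrt(3.0) * max(nx, ny, nz) * h
    max_lines = int((diag / s + 2) ** 2)
    max_steps = int(3.5 * nx * ny * nz * (h / s) ** 2) + 10 * max_lines
    vox_buf = np.empty(max_steps, dtype=np.int64)
    dl_buf = np.empty(max_steps)
    start_buf = np.empty(max_lines + 1, dtype=np.int64)

    out = []
    for d in directions:
        d = d / np.linalg.norm(d)
        # canonicalize antiparallel directions: build along the direction
        # whose dominant component is positive, then reverse step order,
        # so d and -d yield identical lattices with reversed steps
        dom_ax = int(np.argmax(np.abs(d)))
        flip = d[dom_ax] < 0
        d_build = -d if flip else d
        n_lines, n_steps = _geometry.build_direction_lines(
            np.ascontiguousarray(d_build), phantom.origin, h, nx, ny, nz, s,
            vox_buf, dl_buf, start_buf)
        vox = vox_buf[:n_steps].copy()
        dl = dl_buf[:n_steps].copy()
        starts = start_buf[:n_lines + 1].copy()
        if flip:
            for li in range(n_lines):
                sl = slice(starts[li], starts[li + 1])
                vox[sl] = vox[sl][::-1]
                dl[sl] = dl[sl][::-1]
        dlmax = np.zeros(nx * ny * nz)
        np.add.at(dlmax, vox, dl)
        out.append(TransportLineLattice(d.copy(), starts, vox, dl, dlmax,
                                        s * s))
    return out
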