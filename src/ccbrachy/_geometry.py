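"""Numba geometry kernels: voxel-grid ray walks and transport-line lattices.

All walks use the incremental grid-crossing (Amanatides-Woo) traversal.
Grids are cubic-voxel, axis-aligned, with ``origin`` the world coordinate
of the low corner and half-open voxel intervals [low, high).
"""

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True)
def clip_ray_aabb(p, d, lo, hi):
    """Clip ray p + t*d against the box [lo, hi]; return (t0, t1), t0>t1 if miss."""
    t0 = -1.0e300
    t1 = 1.0e300
    for k in range(3):
        if abs(d[k]) < _EPS:
            if p[k] < lo[k] or p[k] > hi[k]:
                return 1.0, 0.0
        else:
            ta = (lo[k] - p[k]) / d[k]
            tb = (hi[k] - p[k]) / d[k]
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    return t0, t1


@njit(cache=True)
def walk_segments(p0, p1, origin, h, nx, ny, nz, medium_idx, path_per_medium):
    """Accumulate geometric path length per medium along segment p0 -> p1.

    ``path_per_medium`` is zeroed and filled; the segment is clipped to the
    grid first.  Returns the clipped segment length.
    """
    for m in range(path_per_medium.shape[0]):
        path_per_medium[m] = 0.0
    d = np.empty(3)
    seg = 0.0
    for k in range(3):
        d[k] = p1[k] - p0[k]
        seg += d[k] * d[k]
    seg = np.sqrt(seg)
    if seg < _EPS:
        return 0.0
    for k in range(3):
        d[k] /= seg
    lo = origin
    hi = np.empty(3)
    hi[0] = origin[0] + nx * h
    hi[1] = origin[1] + ny * h
    hi[2] = origin[2] + nz * h
    t0, t1 = clip_ray_aabb(p0, d, lo, hi)
    if t0 > t1:
        return 0.0
    if t0 < 0.0:
        t0 = 0.0
    if t1 > seg:
        t1 = seg
    if t1 <= t0:
        return 0.0

    # voxel of entry point (nudged inside)
    t = t0 + 1e-9 * (t1 - t0)
    ix = int((p0[0] + t * d[0] - origin[0]) / h)
    iy = int((p0[1] + t * d[1] - origin[1]) / h)
    iz = int((p0[2] + t * d[2] - origin[2]) / h)
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix >= nx:
        ix = nx - 1
    if iy >= ny:
        iy = ny - 1
    if iz >= nz:
        iz = nz - 1

    step = np.empty(3, dtype=np.int64)
    t_max = np.empty(3)
    t_delta = np.empty(3)
    idx = np.empty(3, dtype=np.int64)
    idx[0], idx[1], idx[2] = ix, iy, iz
    for k in range(3):
        if d[k] > _EPS:
            step[k] = 1
            t_max[k] = ((idx[k] + 1) * h + origin[k] - p0[k]) / d[k]
            t_delta[k] = h / d[k]
        elif d[k] < -_EPS:
            step[k] = -1
            t_max[k] = (idx[k] * h + origin[k] - p0[k]) / d[k]
            t_delta[k] = -h / d[k]
        else:
            step[k] = 0
            t_max[k] = 1.0e300
            t_delta[k] = 1.0e300

    t_cur = t0
    while t_cur < t1 - _EPS:
        k_min = 0
        if t_max[1] < t_max[k_min]:
            k_min = 1
        if t_max[2] < t_max[k_min]:
            k_min = 2
        t_next = t_max[k_min]
        if t_next > t1:
            t_next = t1
        m = medium_idx[idx[0], idx[1], idx[2]]
        path_per_medium[m] += t_next - t_cur
        t_cur = t_next
        if t_cur >= t1 - _EPS:
            break
        idx[k_min] += step[k_min]
        if idx[k_min] < 0 or idx[k_min] >= (nx if k_min == 0 else (ny if k_min == 1 else nz)):
            break
        t_max[k_min] += t_delta[k_min]
    return t1 - t0


@njit(cache=True)
def paths_to_all_voxels(source, origin, h, nx, ny, nz, medium_idx, n_media,
                        density):
    """Per-voxel mass thickness [g/cm^2] in each medium from the source to
    every voxel center (geometric length times the local voxel density).
    Returns (nx, ny, nz, n_media) float64."""
    out = np.zeros((nx, ny, nz, n_media))
    buf = np.zeros(n_media)
    p1 = np.empty(3)
    for i in range(nx):
        p1[0] = origin[0] + (i + 0.5) * h
        for j in range(ny):
            p1[1] = origin[1] + (j + 0.5) * h
            for k in range(nz):
                p1[2] = origin[2] + (k + 0.5) * h
                walk_segments_weighted(source, p1, origin, h, nx, ny, nz,
                                       medium_idx, density, buf)
                for m in range(n_media):
                    out[i, j, k, m] = buf[m]
    return out


@njit(cache=True)
def walk_segments_weighted(p0, p1, origin, h, nx, ny, nz, medium_idx,
                           density, mass_per_medium):
    """Like walk_segments but accumulates density-weighted length (mass
    thickness) per medium."""
    for m in range(mass_per_medium.shape[0]):
        mass_per_medium[m] = 0.0
    d = np.empty(3)
    seg = 0.0
    for k in range(3):
        d[k] = p1[k] - p0[k]
        seg += d[k] * d[k]
    seg = np.sqrt(seg)
    if seg < _EPS:
        return 0.0
    for k in range(3):
        d[k] /= seg
    lo = origin
    hi = np.empty(3)
    hi[0] = origin[0] + nx * h
    hi[1] = origin[1] + ny * h
    hi[2] = origin[2] + nz * h
    t0, t1 = clip_ray_aabb(p0, d, lo, hi)
    if t0 > t1:
        return 0.0
    if t0 < 0.0:
        t0 = 0.0
    if t1 > seg:
        t1 = seg
    if t1 <= t0:
        return 0.0

    t = t0 + 1e-9 * (t1 - t0)
    idx = np.empty(3, dtype=np.int64)
    for k in range(3):
        ii = int((p0[k] + t * d[k] - origin[k]) / h)
        lim = nx if k == 0 else (ny if k == 1 else nz)
        if ii < 0:
            ii = 0
        if ii >= lim:
            ii = lim - 1
        idx[k] = ii
    step = np.empty(3, dtype=np.int64)
    t_max = np.empty(3)
    t_delta = np.empty(3)
    for k in range(3):
        if d[k] > _EPS:
            step[k] = 1
            t_max[k] = ((idx[k] + 1) * h + origin[k] - p0[k]) / d[k]
            t_delta[k] = h / d[k]
        elif d[k] < -_EPS:
            step[k] = -1
            t_max[k] = (idx[k] * h + origin[k] - p0[k]) / d[k]
            t_delta[k] = -h / d[k]
        else:
            step[k] = 0
            t_max[k] = 1.0e300
            t_delta[k] = 1.0e300

    t_cur = t0
    while t_cur < t1 - _EPS:
        k_min = 0
        if t_max[1] < t_max[k_min]:
            k_min = 1
        if t_max[2] < t_max[k_min]:
            k_min = 2
        t_next = t_max[k_min]
        if t_next > t1:
            t_next = t1
        m = medium_idx[idx[0], idx[1], idx[2]]
        mass_per_medium[m] += (t_next - t_cur) * density[idx[0], idx[1], idx[2]]
        t_cur = t_next
        if t_cur >= t1 - _EPS:
            break
        idx[k_min] += step[k_min]
        if idx[k_min] < 0 or idx[k_min] >= (nx if k_min == 0 else (ny if k_min == 1 else nz)):
            break
        t_max[k_min] += t_delta[k_min]
    return t1 - t0


@njit(cache=True)
def build_direction_lines(d, origin, h, nx, ny, nz, spacing,
                          vox_buf, dl_buf, line_start_buf):
    """Build the transport-line set for one direction.

    Lines are seeded on a square lattice (cell ``spacing``) in the plane
    through the grid center perpendicular to ``d`` and clipped to the grid;
    each line's voxel crossings (flat voxel index, step length) are appended
    to ``vox_buf``/``dl_buf``.  ``line_start_buf[l]`` is the offset of line
    l's first step; the function returns (n_lines, n_steps).
    """
    # orthonormal basis perpendicular to d
    e1 = np.empty(3)
    if abs(d[0]) <= abs(d[1]) and abs(d[0]) <= abs(d[2]):
        ax = 0
    elif abs(d[1]) <= abs(d[2]):
        ax = 1
    else:
        ax = 2
    for k in range(3):
        e1[k] = 0.0
    e1[ax] = 1.0
    # e1 = normalize(e1 - (e1.d) d); e2 = d x e1
    dot = e1[0] * d[0] + e1[1] * d[1] + e1[2] * d[2]
    for k in range(3):
        e1[k] -= dot * d[k]
    norm = np.sqrt(e1[0] ** 2 + e1[1] ** 2 + e1[2] ** 2)
    for k in range(3):
        e1[k] /= norm
    e2 = np.empty(3)
    e2[0] = d[1] * e1[2] - d[2] * e1[1]
    e2[1] = d[2] * e1[0] - d[0] * e1[2]
    e2[2] = d[0] * e1[1] - d[1] * e1[0]

    center = np.empty(3)
    center[0] = origin[0] + 0.5 * nx * h
    center[1] = origin[1] + 0.5 * ny * h
    center[2] = origin[2] + 0.5 * nz * h

    # projected extent of the 8 corners on (e1, e2)
    u0 = 1.0e300
    u1 = -1.0e300
    v0 = 1.0e300
    v1 = -1.0e300
    corner = np.empty(3)
    for ci in range(2):
        for cj in range(2):
            for ck in range(2):
                corner[0] = origin[0] + ci * nx * h - center[0]
                corner[1] = origin[1] + cj * ny * h - center[1]
                corner[2] = origin[2] + ck * nz * h - center[2]
                u = corner[0] * e1[0] + corner[1] * e1[1] + corner[2] * e1[2]
                v = corner[0] * e2[0] + corner[1] * e2[1] + corner[2] * e2[2]
                if u < u0:
                    u0 = u
                if u > u1:
                    u1 = u
                if v < v0:
                    v0 = v
                if v > v1:
                    v1 = v

    nu = int((u1 - u0) / spacing) + 1
    nv = int((v1 - v0) / spacing) + 1

    lo = origin
    hi = np.empty(3)
    hi[0] = origin[0] + nx * h
    hi[1] = origin[1] + ny * h
    hi[2] = origin[2] + nz * h

    n_lines = 0
    n_steps = 0
    p = np.empty(3)
    idx = np.empty(3, dtype=np.int64)
    step = np.empty(3, dtype=np.int64)
    t_max = np.empty(3)
    t_delta = np.empty(3)
    for iu in range(nu):
        u = u0 + (iu + 0.5) * spacing
        for iv in range(nv):
            v = v0 + (iv + 0.5) * spacing
            for k in range(3):
                p[k] = center[k] + u * e1[k] + v * e2[k]
            t0, t1 = clip_ray_aabb(p, d, lo, hi)
            if t0 >= t1 - 1e-9:
                continue
            line_start_buf[n_lines] = n_steps
            n_lines += 1

            t = t0 + 1e-9 * (t1 - t0)
            for k in range(3):
                q = p[k] + t * d[k]
                ii = int((q - origin[k]) / h)
                if ii < 0:
                    ii = 0
                lim = nx if k == 0 else (ny if k == 1 else nz)
                if ii >= lim:
                    ii = lim - 1
                idx[k] = ii
                if d[k] > _EPS:
                    step[k] = 1
                    t_max[k] = ((idx[k] + 1) * h + origin[k] - p[k]) / d[k]
                    t_delta[k] = h / d[k]
                elif d[k] < -_EPS:
                    step[k] = -1
                    t_max[k] = (idx[k] * h + origin[k] - p[k]) / d[k]
                    t_delta[k] = -h / d[k]
                else:
                    step[k] = 0
                    t_max[k] = 1.0e300
                    t_delta[k] = 1.0e300

            t_cur = t0
            while t_cur < t1 - _EPS:
                k_min = 0
                if t_max[1] < t_max[k_min]:
                    k_min = 1
                if t_max[2] < t_max[k_min]:
                    k_min = 2
                t_next = t_max[k_min]
                if t_next > t1:
                    t_next = t1
                dl = t_next - t_cur
                if dl > _EPS:
                    vox_buf[n_steps] = (idx[0] * ny + idx[1]) * nz + idx[2]
                    dl_buf[n_steps] = dl
                    n_steps += 1
                t_cur = t_next
                if t_cur >= t1 - _EPS:
                    break
                idx[k_min] += step[k_min]
                if idx[k_min] < 0 or idx[k_min] >= (nx if k_min == 0 else (ny if k_min == 1 else nz)):
                    break
                t_max[k_min] += t_delta[k_min]
    line_start_buf[n_lines] = n_steps
    return n_lines, n_steps
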