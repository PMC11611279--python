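"""Compiled inner loops shared by the ray-tracing back-ends.

All kernels work in the array frame (z, y, x) = axes (0, 1, 2), with voxel
centers at integer coordinates and the volume occupying [0, dim-1] per axis.
Faces of the bounding cuboid are enumerated x-min, x-max, y-min, y-max,
z-min, z-max (indices 0..5); ties in the exit-distance search are broken by
the lowest face index, which makes X the preferred driving axis when a ray
leaves exactly through an edge or corner.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# face indices: last array axis first, min before max
FACE_XMIN, FACE_XMAX, FACE_YMIN, FACE_YMAX, FACE_ZMIN, FACE_ZMAX = range(6)

#: array axis driven by each face
FACE_AXIS = (2, 2, 1, 1, 0, 0)

#: tolerance (voxel units) for on-face / tie tests
TOL = 1e-9


@njit(cache=True, nogil=True, inline="always")
def _rnd(v):
    # round half away from zero; np.round's half-to-even would break the
    # one-voxel-per-interval pattern of the traversal worked example
    if v >= 0.0:
        return int(math.floor(v + 0.5))
    return int(math.ceil(v - 0.5))


@njit(cache=True, nogil=True)
def _exit_face(pz, py, px, dz, dy, dx, nz, ny, nx):
    """First exit of ray p + t*d from the cuboid [0,n-1]^3.

    Returns (t, face). face == -1 only for a zero direction. A t of zero is
    accepted only when the ray points outward through the face plane the
    start point already lies on.
    """
    best_t = 1.0e300
    best_face = -1
    for face in range(6):
        if face < 2:
            comp = dx
            p = px
            dim = nx
        elif face < 4:
            comp = dy
            p = py
            dim = ny
        else:
            comp = dz
            p = pz
            dim = nz
        if comp == 0.0:
            continue  # ray parallel to this plane: no candidate
        if face % 2 == 0:
            bound = 0.0
            outward = comp < 0.0
        else:
            bound = dim - 1.0
            outward = comp > 0.0
        t = (bound - p) / comp
        if t < TOL:
            if t < -TOL or not outward:
                continue
            t = 0.0
        if t < best_t - TOL:
            best_t = t
            best_face = face
    return best_t, best_face


@njit(cache=True, nogil=True)
def _ray_steps(nz, ny, nx, sz, sy, sx, dz, dy, dx):
    """Initialization of the incremental traversal.

    Chooses the driving axis from the exit face and rescales the direction
    so the driving component advances one voxel per step. Returns
    (n, step_z, step_y, step_x, face) with n the maximum interval index:
    positions are start + s*step for s = 0..n.
    """
    t, face = _exit_face(float(sz), float(sy), float(sx), dz, dy, dx, nz, ny, nx)
    if face < 2:
        comp = dx
        s0 = sx
        dim = nx
    elif face < 4:
        comp = dy
        s0 = sy
        dim = ny
    else:
        comp = dz
        s0 = sz
        dim = nz
    bound = 0 if face % 2 == 0 else dim - 1
    n = bound - s0
    if n < 0:
        n = -n
    inv = 1.0 / abs(comp)
    return n, dz * inv, dy * inv, dx * inv, face


@njit(cache=True, nogil=True)
def _label_at(labels, sz, sy, sx, ddz, ddy, ddx, s):
    """Label of the voxel recorded at step s of a stepped ray."""
    nz, ny, nx = labels.shape
    rz = _rnd(sz + s * ddz)
    ry = _rnd(sy + s * ddy)
    rx = _rnd(sx + s * ddx)
    if rz < 0:
        rz = 0
    elif rz > nz - 1:
        rz = nz - 1
    if ry < 0:
        ry = 0
    elif ry > ny - 1:
        ry = ny - 1
    if rx < 0:
        rx = 0
    elif rx > nx - 1:
        rx = nx - 1
    return labels[rz, ry, rx]


@njit(cache=True, nogil=True)
def _traverse_counts(labels, sz, sy, sx, dz, dy, dx, counts):
    """Accumulate per-code voxel counts along a ray; one voxel per interval.

    Returns (n, end_z, end_y, end_x). counts must be zeroed by the caller
    and long enough to index every label code.
    """
    nz, ny, nx = labels.shape
    n, ddz, ddy, ddx, _face = _ray_steps(nz, ny, nx, sz, sy, sx, dz, dy, dx)
    rz = sz
    ry = sy
    rx = sx
    for s in range(n + 1):
        rz = _rnd(sz + s * ddz)
        ry = _rnd(sy + s * ddy)
        rx = _rnd(sx + s * ddx)
        if rz < 0:
            rz = 0
        elif rz > nz - 1:
            rz = nz - 1
        if ry < 0:
            ry = 0
        elif ry > ny - 1:
            ry = ny - 1
        if rx < 0:
            rx = 0
        elif rx > nx - 1:
            rx = nx - 1
        counts[labels[rz, ry, rx]] += 1
    return n, rz, ry, rx


@njit(cache=True, nogil=True)
def _one_way_exponent(labels, sz, sy, sx, dz, dy, dx, mu_code, voxel_size, counts):
    """Sum_m mu_m * L_m for one ray, L_m the zigzag-corrected length in um.

    L_m = (counts_m / total) * euclidean_length_voxels * voxel_size; the
    accumulation order here is the single source of truth so that gridding
    lookups on exact nodes reproduce the standard back-end bit for bit.
    """
    counts[:] = 0
    n, ez, ey, ex = _traverse_counts(labels, sz, sy, sx, dz, dy, dx, counts)
    eu = math.sqrt(float((ez - sz) ** 2 + (ey - sy) ** 2 + (ex - sx) ** 2))
    acc = 0.0
    for c in range(mu_code.shape[0]):
        acc += mu_code[c] * counts[c]
    return acc / (n + 1.0) * eu * voxel_size


@njit(cache=True, nogil=True)
def _exponents_batch(labels, voxels, r1z, r1y, r1x, r2z, r2y, r2x,
                     mu_code, voxel_size, out):
    """Two-way exponents mu.(L1+L2) for a batch of start voxels.

    (r1z, r1y, r1x) is the reversed incident direction, (r2z, r2y, r2x)
    the diffracted one. out must have len(voxels) slots.
    """
    counts = np.zeros(mu_code.shape[0], np.int64)
    for k in range(voxels.shape[0]):
        sz = voxels[k, 0]
        sy = voxels[k, 1]
        sx = voxels[k, 2]
        e1 = _one_way_exponent(labels, sz, sy, sx, r1z, r1y, r1x,
                               mu_code, voxel_size, counts)
        e2 = _one_way_exponent(labels, sz, sy, sx, r2z, r2y, r2x,
                               mu_code, voxel_size, counts)
        out[k] = e1 + e2


@njit(cache=True, nogil=True)
def _build_grid(labels, sz, sy, sx, mu_code, voxel_size, values):
    """Fill a (360, 180) array of one-way exponents at 1-degree spacing.

    Node (i, j) holds the exponent for the unit direction with azimuth
    theta = i deg (from +x toward +y, about z) and polar angle phi = j deg
    (from +z), i.e. (z, y, x) = (cos phi, sin phi sin theta, sin phi cos theta).
    """
    counts = np.zeros(mu_code.shape[0], np.int64)
    for i in range(360):
        th = i * math.pi / 180.0
        ct = math.cos(th)
        st = math.sin(th)
        for j in range(180):
            ph = j * math.pi / 180.0
            sp = math.sin(ph)
            cp = math.cos(ph)
            values[i, j] = _one_way_exponent(
                labels, sz, sy, sx, cp, sp * st, sp * ct,
                mu_code, voxel_size, counts)
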