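"""Ray-cuboid intersection: where does a ray leave the voxel cube?

The segmented volume is a cuboid bounded by six axis-aligned planes through
the outermost voxel centers (offsets 0 and dim-1 per axis). For a ray
P0 + t*d starting inside, the exit is the smallest non-negative t over the
plane intersections t_i = (x_i - P0).n_i / d.n_i; the face reached at that
t fixes the driving axis of the voxel traversal. Faces are enumerated
x-min, x-max, y-min, y-max, z-min, z-max and an exit exactly through an
edge or corner resolves to the lowest face index.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from ._kernels import FACE_AXIS, TOL, _exit_face

__all__ = ["Face", "RayExit", "exit_point"]


class Face(IntEnum):
    """Cuboid faces, named by outward normal in the (z, y, x) frame."""

    XMIN = 0
    XMAX = 1
    YMIN = 2
    YMAX = 3
    ZMIN = 4
    ZMAX = 5

    @property
    def axis(self) -> int:
        """Array axis (0=z, 1=y, 2=x) whose bound this face lies on."""
        return FACE_AXIS[self.value]

    @property
    def outward_normal(self) -> np.ndarray:
        n = np.zeros(3)
        n[self.axis] = -1.0 if self.value % 2 == 0 else 1.0
        return n


@dataclass(frozen=True)
class RayExit:
    """Exit of a ray from the voxel cube.

    ``t`` is the distance in voxel units (for a unit direction),
    ``exit_point`` lies on the plane of ``face``.
    """

    t: float
    exit_point: np.ndarray
    face: Face


def exit_point(P0, d, dims) -> RayExit:
    """First exit of the ray P0 + t*d from the cuboid [0, dim-1]^3.

    Parameters
    ----------
    P0
        Real (z, y, x) point inside the cuboid (bounds inclusive, within
        tolerance).
    d
        Nonzero (z, y, x) direction; normalized internally so ``t`` is a
        Euclidean distance in voxel units.
    dims
        Volume shape (nz, ny, nx).

    Raises
    ------
    ValueError
        For a zero direction or a start point outside the cuboid.
    """
    P0 = np.asarray(P0, dtype=float)
    d = np.asarray(d, dtype=float)
    dims = tuple(int(v) for v in dims)
    if P0.shape != (3,) or d.shape != (3,):
        raise ValueError("P0 and d must be 3-vectors")
    norm = float(np.linalg.norm(d))
    if norm == 0.0:
        raise ValueError("direction vector must be nonzero")
    d = d / norm
    upper = np.asarray(dims, float) - 1.0
    if np.any(P0 < -TOL) or np.any(P0 > upper + TOL):
        raise ValueError(f"P0 {P0.tolist()} lies outside the cuboid {dims}")

    t, face = _exit_face(P0[0], P0[1], P0[2], d[0], d[1], d[2], *dims)
    face = Face(face)
    point = P0 + t * d
    # pin the driven coordinate to its plane exactly
    point[face.axis] = 0.0 if face.value % 2 == 0 else dims[face.axis] - 1.0
    return RayExit(t=float(t), exit_point=point, face=face)
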