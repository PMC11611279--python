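"""Gridding back-end: precomputed angular attenuation maps per crystal voxel.

When many reflections (or several datasets on the same sample) are
processed, nearby beam directions repeat near-identical path-length
computations. This back-end trades memory for time: for each sampled
crystal voxel it precomputes a (360, 180) spherical grid of *one-way*
attenuation exponents sum_m mu_m L_m at 1 deg spacing, then answers each
reflection by two nearest-neighbour lookups (reversed incident + diffracted
direction) and sums them. Build cost is independent of the reflection
count; query cost is linear in reflections x sampled voxels.

To avoid edge artefacts in the lookup, each grid is padded to (420, 210):
30 deg of azimuthal wrap-around on either side and 15 deg of polar
continuation across each pole (a polar reflection lands on the meridian
180 deg away). Grids are double precision; one grid costs about 1.2 MB,
which is why gridding is only practical together with voxel sampling.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._kernels import _build_grid
from .tracing import AbsorptionResult, Reflection, _check_start, _run_backend
from .volume import MaterialCoefficients, SegmentedVolume, volume_checksum

__all__ = [
    "GRID_SHAPE",
    "PADDED_SHAPE",
    "AngularGrid",
    "node_direction",
    "build_voxel_grid",
    "pad_grid",
    "interpolate_exponent",
    "grid_memory_bytes",
    "run_gridding",
]

GRID_SHAPE = (360, 180)
PADDED_SHAPE = (420, 210)
_PAD_THETA = 30  # deg per side, azimuth
_PAD_PHI = 15  # deg per side, polar


def node_direction(i: int, j: int) -> np.ndarray:
    """Unit (z, y, x) direction of grid node (i, j).

    theta = i deg is the azimuth about z measured from +x toward +y,
    phi = j deg the polar angle from +z. This is exactly the arithmetic the
    grid builder uses, so traversing along ``node_direction(i, j)`` with the
    standard back-end reproduces node (i, j) bit for bit.
    """
    th = i * math.pi / 180.0
    ph = j * math.pi / 180.0
    sp = math.sin(ph)
    return np.array([math.cos(ph), sp * math.sin(th), sp * math.cos(th)])


@dataclass
class AngularGrid:
    """Per-voxel map of one-way exponents over the direction sphere."""

    voxel: np.ndarray
    values: np.ndarray
    padded_values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != GRID_SHAPE:
            raise ValueError(f"values must have shape {GRID_SHAPE}")
        if self.padded_values.shape != PADDED_SHAPE:
            raise ValueError(f"padded_values must have shape {PADDED_SHAPE}")


def pad_grid(values: np.ndarray) -> np.ndarray:
    """Pad a (360, 180) grid to (420, 210) with continuity at its edges.

    Azimuth wraps modulo 360 deg; polar padding reflects across the poles,
    which maps (theta, phi) outside [0, 180) to (theta + 180, phi') on the
    opposite meridian.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape != GRID_SHAPE:
        raise ValueError(f"expected shape {GRID_SHAPE}, got {values.shape}")
    ti = (np.arange(PADDED_SHAPE[0]) - _PAD_THETA) % 360
    jj = np.arange(PADDED_SHAPE[1]) - _PAD_PHI
    j_ref = np.where(jj < 0, -1 - jj, np.where(jj >= 180, 359 - jj, jj))
    flip = (jj < 0) | (jj >= 180)
    TI = (ti[:, None] + np.where(flip, 180, 0)[None, :]) % 360
    JJ = np.broadcast_to(j_ref, PADDED_SHAPE)
    return values[TI, JJ]


def build_voxel_grid(volume: SegmentedVolume, coeffs: MaterialCoefficients,
                     n) -> AngularGrid:
    """Compute the (360, 180) one-way exponent grid for crystal voxel ``n``.

    Every node runs the standard traversal + proportional length
    conversion for its direction; the result is deterministic.
    """
    start = _check_start(volume, n)
    if volume.labels[tuple(start)] != volume.code("crystal"):
        raise ValueError(f"voxel {start.tolist()} is not crystal-labelled")
    mu_code = coeffs.code_array(volume.label_map)
    values = np.empty(GRID_SHAPE, dtype=np.float64)
    _build_grid(volume.labels, int(start[0]), int(start[1]), int(start[2]),
                mu_code, volume.voxel_size_um, values)
    return AngularGrid(voxel=start, values=values, padded_values=pad_grid(values))


def _node_indices(direction: np.ndarray) -> tuple[int, int]:
    """Padded-grid indices of the node nearest to a unit direction."""
    z, y, x = float(direction[0]), float(direction[1]), float(direction[2])
    phi = math.degrees(math.acos(max(-1.0, min(1.0, z))))
    theta = math.degrees(math.atan2(y, x)) % 360.0
    ip = int(math.floor(theta + 0.5)) + _PAD_THETA
    jp = int(math.floor(phi + 0.5)) + _PAD_PHI
    return ip, jp


def interpolate_exponent(grid: AngularGrid, direction) -> float:
    """Nearest-neighbour lookup of the one-way exponent for a direction.

    A query exactly on a node returns that node's value unchanged.
    """
    d = np.asarray(direction, dtype=np.float64)
    nrm = float(np.linalg.norm(d))
    if nrm == 0.0:
        raise ValueError("direction vector must be nonzero")
    ip, jp = _node_indices(d / nrm)
    return float(grid.padded_values[ip, jp])


def grid_memory_bytes(n_grids: int) -> int:
    """Double-precision memory footprint of ``n_grids`` angular grids
    (values + padded lookup copy)."""
    per = 8 * (GRID_SHAPE[0] * GRID_SHAPE[1] + PADDED_SHAPE[0] * PADDED_SHAPE[1])
    return n_grids * per


def _coeff_hash(coeffs: MaterialCoefficients) -> str:
    return hashlib.sha256(repr(sorted(coeffs.mu.items())).encode()).hexdigest()[:16]


def _build_all_grids(volume, coeffs, selected) -> np.ndarray:
    mu_code = coeffs.code_array(volume.label_map)
    values = np.empty((selected.shape[0],) + GRID_SHAPE, dtype=np.float64)
    for k in range(selected.shape[0]):
        _build_grid(volume.labels, int(selected[k, 0]), int(selected[k, 1]),
                    int(selected[k, 2]), mu_code, volume.voxel_size_um,
                    values[k])
    return values


def run_gridding(volume: SegmentedVolume, coeffs: MaterialCoefficients,
                 reflections, plan, workers: int = 1,
                 precision: str = "double", cache_dir=None,
                 max_grid_bytes: int = 2 ** 31) -> AbsorptionResult:
    """Absorption factors via per-voxel angular grids.

    Grids are built once for the plan's voxels and reused for every
    reflection; with ``cache_dir`` set they are also reused across runs
    (keyed by volume checksum, coefficient hash and voxel set; a cache file
    whose key does not match raises). The builder refuses plans whose total
    grid memory exceeds ``max_grid_bytes``.
    """
    selected = np.ascontiguousarray(
        np.asarray(plan.selected if hasattr(plan, "selected") else plan),
        dtype=np.int64)
    if selected.size == 0:
        raise ValueError("sampling plan selects no crystal voxels")
    need = grid_memory_bytes(selected.shape[0])
    if need > max_grid_bytes:
        raise MemoryError(
            f"plan needs {need / 1e6:.0f} MB of angular grids, over the "
            f"{max_grid_bytes / 1e6:.0f} MB budget; lower the sampling ratio "
            "or raise max_grid_bytes")

    vol_hash = volume_checksum(volume)[:16]
    values = None
    cache_file = None
    if cache_dir is not None:
        vox_hash = hashlib.sha256(selected.tobytes()).hexdigest()[:16]
        cache_file = (Path(cache_dir) /
                      f"grids_{vol_hash}_{_coeff_hash(coeffs)}_{vox_hash}.npz")
        if cache_file.exists():
            with np.load(cache_file, allow_pickle=False) as fh:
                if (str(fh["volume_checksum"]) != vol_hash
                        or not np.array_equal(fh["voxels"], selected)):
                    raise ValueError(
                        f"grid cache {cache_file} does not match the volume/plan")
                values = fh["values"]
    if values is None:
        values = _build_all_grids(volume, coeffs, selected)
        if cache_file is not None:
            cache_file.parent.mkdir(parents=True, exist_ok=True)
            np.savez(cache_file, values=values, voxels=selected,
                     volume_checksum=np.asarray(vol_hash))

    padded = np.stack([pad_grid(v) for v in values])

    def one(reflection: Reflection, sel) -> np.ndarray:
        i1, j1 = _node_indices(-reflection.incident)
        i2, j2 = _node_indices(reflection.diffracted)
        return padded[:, i1, j1] + padded[:, i2, j2]

    result = _run_backend(volume, coeffs, reflections, plan, workers,
                          precision, method="gridding", one=one)
    result.metadata["n_grids"] = int(selected.shape[0])
    result.metadata["grid_bytes"] = int(need)
    return result
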