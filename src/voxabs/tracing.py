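"""Standard ray-tracing back-end.

For every reflection h, each (sampled) crystal voxel n sends two rays
through the segmented model: one back along the incident beam (the incoming
direction is reversed because the traversal starts at the diffracting voxel,
not at the source) and one along the diffracted beam. The traversal steps
one voxel per interval of the driving axis -- the axis of the face through
which the ray exits -- and records the material label of one voxel per
interval, rounding the other coordinates to the nearest pixel. Rays are
followed all the way to the model boundary, never stopped early inside
vacuum, so liquor or loop beyond an internal gap still attenuates.

The staircase ("zigzag") overcount of the voxelized path is corrected by
converting per-material voxel counts to lengths via their *proportion* of
the Euclidean start-to-end distance:

    L_m = counts_m / total * ||end - start|| * voxel_size

The absorption factor of the reflection is then the mean transmission over
the selected crystal voxels,

    A_h = (1/N) * sum_n exp(-sum_m mu_m (L1_nm + L2_nm)).
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from ._kernels import _exponents_batch, _one_way_exponent, _ray_steps
from .volume import MaterialCoefficients, SegmentedVolume

__all__ = [
    "Reflection",
    "PathSegmentRecord",
    "AbsorptionResult",
    "NonCrystalStartWarning",
    "step_coordinates",
    "traverse",
    "path_lengths",
    "voxel_exponent",
    "absorption_factor",
    "run_standard",
]


class NonCrystalStartWarning(UserWarning):
    """A path-length query started from a voxel not labelled crystal."""


@dataclass(frozen=True)
class Reflection:
    """One Bragg reflection, characterized by its beam directions.

    ``incident`` is the propagation direction of the incoming beam and
    ``diffracted`` that of the outgoing beam, both unit (z, y, x) vectors
    (within 1e-6) in the frame of the voxel model. ``index`` is the row in
    the input reflection table.
    """

    incident: np.ndarray
    diffracted: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        for name in ("incident", "diffracted"):
            v = np.ascontiguousarray(getattr(self, name), dtype=np.float64)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            if abs(float(np.linalg.norm(v)) - 1.0) > 1e-6:
                raise ValueError(
                    f"{name} must be a unit vector within 1e-6 "
                    f"(norm {np.linalg.norm(v):.8f})")
            object.__setattr__(self, name, v)


@dataclass
class PathSegmentRecord:
    """What one traversal recorded: voxel counts per material and endpoints."""

    counts: dict[str, int]
    total_count: int
    start_voxel: np.ndarray
    end_voxel: np.ndarray
    euclidean_length_voxels: float


@dataclass
class AbsorptionResult:
    """Absorption factors A_h in (0, 1], in input reflection order."""

    factors: np.ndarray
    method: str
    sampling: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.factors)


def _check_start(volume: SegmentedVolume, start) -> np.ndarray:
    start = np.asarray(start)
    if start.shape != (3,) or not np.issubdtype(start.dtype, np.integer):
        start = np.asarray(np.rint(start), dtype=np.int64)
    start = start.astype(np.int64)
    dims = np.asarray(volume.shape)
    if np.any(start < 0) or np.any(start >= dims):
        raise ValueError(f"start voxel {start.tolist()} outside volume {volume.shape}")
    return start


def _unit(d) -> np.ndarray:
    d = np.asarray(d, dtype=np.float64)
    n = float(np.linalg.norm(d))
    if n == 0.0:
        raise ValueError("direction vector must be nonzero")
    return d / n


def step_coordinates(volume: SegmentedVolume, start, d) -> np.ndarray:
    """Rounded (z, y, x) voxel coordinates recorded at steps s = 0..n.

    One voxel per interval of the driving axis; coordinates are clipped to
    the volume. This is the explicit form of what :func:`traverse` counts.
    """
    start = _check_start(volume, start)
    d = _unit(d)
    nz, ny, nx = volume.shape
    n, ddz, ddy, ddx = _ray_steps(nz, ny, nx, int(start[0]), int(start[1]),
                                  int(start[2]), d[0], d[1], d[2])[:4]
    s = np.arange(n + 1, dtype=np.float64)
    coords = start[None, :] + s[:, None] * np.array([ddz, ddy, ddx])
    rounded = np.where(coords >= 0, np.floor(coords + 0.5),
                       np.ceil(coords - 0.5)).astype(np.int64)
    np.clip(rounded, 0, np.asarray(volume.shape) - 1, out=rounded)
    return rounded


def traverse(volume: SegmentedVolume, start, d) -> PathSegmentRecord:
    """Traverse the volume from ``start`` along ``d`` to the boundary.

    Records exactly one voxel per driving-axis interval (including the
    start voxel) and never stops early inside vacuum. The Euclidean length
    is taken between the start voxel and the recorded end voxel.
    """
    path = step_coordinates(volume, start, d)
    labs = volume.labels[path[:, 0], path[:, 1], path[:, 2]]
    binc = np.bincount(labs, minlength=256)
    counts = {name: int(binc[code]) for name, code in volume.label_map.items()}
    start = path[0]
    end = path[-1]
    return PathSegmentRecord(
        counts=counts,
        total_count=int(path.shape[0]),
        start_voxel=start,
        end_voxel=end,
        euclidean_length_voxels=float(np.linalg.norm((end - start).astype(float))),
    )


def path_lengths(record: PathSegmentRecord, voxel_size_um: float) -> dict[str, float]:
    """Zigzag-corrected per-material path lengths in micrometres.

    Each material gets its proportion of the recorded voxels times the
    Euclidean ray length, so the per-material lengths sum exactly to the
    total Euclidean length.
    """
    scale = record.euclidean_length_voxels * float(voxel_size_um) / record.total_count
    return {m: c * scale for m, c in record.counts.items()}


def voxel_exponent(volume: SegmentedVolume, coeffs: MaterialCoefficients,
                   n, incident, diffracted,
                   on_noncrystal: str = "raise") -> float:
    """Two-way attenuation exponent sum_m mu_m (L1_m + L2_m) for voxel ``n``.

    L1 is measured back along the reversed incident direction, L2 along the
    diffracted direction. ``on_noncrystal`` is "raise", "warn" or "ignore"
    for a start voxel that is not crystal-labelled.
    """
    start = _check_start(volume, n)
    if volume.labels[tuple(start)] != volume.code("crystal"):
        msg = f"voxel {start.tolist()} is not crystal-labelled"
        if on_noncrystal == "raise":
            raise ValueError(msg)
        if on_noncrystal == "warn":
            warnings.warn(msg, NonCrystalStartWarning, stacklevel=2)
    rev = -_unit(incident)
    dif = _unit(diffracted)
    mu_code = coeffs.code_array(volume.label_map)
    counts = np.zeros(mu_code.shape[0], dtype=np.int64)
    e1 = _one_way_exponent(volume.labels, int(start[0]), int(start[1]), int(start[2]),
                           rev[0], rev[1], rev[2], mu_code,
                           volume.voxel_size_um, counts)
    e2 = _one_way_exponent(volume.labels, int(start[0]), int(start[1]), int(start[2]),
                           dif[0], dif[1], dif[2], mu_code,
                           volume.voxel_size_um, counts)
    return float(e1 + e2)


def reflection_exponents(volume: SegmentedVolume, coeffs: MaterialCoefficients,
                         reflection: Reflection, voxels: np.ndarray) -> np.ndarray:
    """Two-way exponents for one reflection over a batch of crystal voxels."""
    voxels = np.ascontiguousarray(voxels, dtype=np.int64)
    if voxels.ndim != 2 or voxels.shape[1] != 3 or voxels.shape[0] == 0:
        raise ValueError("voxels must be a non-empty (k, 3) index array")
    rev = -reflection.incident
    dif = reflection.diffracted
    mu_code = coeffs.code_array(volume.label_map)
    out = np.empty(voxels.shape[0], dtype=np.float64)
    _exponents_batch(volume.labels, voxels, rev[0], rev[1], rev[2],
                     dif[0], dif[1], dif[2], mu_code,
                     volume.voxel_size_um, out)
    return out


def absorption_factor(volume: SegmentedVolume, coeffs: MaterialCoefficients,
                      reflection: Reflection, plan) -> float:
    """Mean transmission exp(-exponent) over the plan's crystal voxels."""
    selected = np.asarray(plan.selected if hasattr(plan, "selected") else plan)
    if selected.size == 0:
        raise ValueError("sampling plan selects no crystal voxels")
    exponents = reflection_exponents(volume, coeffs, reflection, selected)
    return float(np.exp(-exponents).mean())


def run_standard(volume: SegmentedVolume, coeffs: MaterialCoefficients,
                 reflections, plan, workers: int = 1,
                 precision: str = "double") -> AbsorptionResult:
    """Absorption factors for a reflection table with the standard back-end.

    The result is identical for any ``workers`` count (each reflection is
    independent and written to its input slot). ``precision="single"``
    evaluates the exponent and transmission in float32, mirroring
    reduced-precision accelerator arithmetic; the default is full double
    precision.
    """
    return _run_backend(volume, coeffs, reflections, plan, workers,
                        precision, method="standard",
                        one=lambda refl, sel: reflection_exponents(
                            volume, coeffs, refl, sel))


def _run_backend(volume, coeffs, reflections, plan, workers, precision,
                 method, one) -> AbsorptionResult:
    reflections = list(reflections)
    if precision not in ("double", "single"):
        raise ValueError("precision must be 'double' or 'single'")
    selected = np.asarray(plan.selected if hasattr(plan, "selected") else plan)
    factors = np.empty(len(reflections), dtype=np.float64)

    def compute(i: int) -> None:
        try:
            exponents = one(reflections[i], selected)
            if precision == "single":
                exponents = exponents.astype(np.float32)
                factors[i] = float(np.exp(-exponents).mean())
            else:
                factors[i] = float(np.exp(-exponents).mean())
        except Exception as exc:  # re-raise with the reflection index
            raise RuntimeError(f"reflection {i} failed: {exc}") from exc

    if reflections:
        if workers > 1:
            with ThreadPoolExecutor(max_workers=workers) as pool:
                list(pool.map(compute, range(len(reflections))))
        else:
            for i in range(len(reflections)):
                compute(i)

    sampling_meta = {}
    if hasattr(plan, "method"):
        sampling_meta = {"method": plan.method, "ratio": plan.ratio,
                         "seed": plan.seed, "n_selected": int(len(selected))}
    return AbsorptionResult(factors=factors, method=method,
                            sampling=sampling_meta,
                            metadata={"precision": precision})
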