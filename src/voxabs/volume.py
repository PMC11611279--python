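"""Segmented voxel models: containers, file I/O and synthetic phantoms.

A sample sitting in the X-ray beam is represented by a 3D array of integer
material labels (crystal, mother liquor, loop, background/vacuum) on an
isotropic voxel grid, the standard product of segmenting a tomographic
reconstruction. This module holds the in-memory container, readers/writers
for the common on-disk forms (NPY, multi-page TIFF, HDF5), and a phantom
generator that emulates mounted protein crystals — a crystal core, a liquor
shell and a partially open loop shell in vacuum — for testing and validation
at desk scale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "DEFAULT_LABEL_MAP",
    "PRESET_COEFFICIENTS",
    "MATERIALS",
    "SegmentedVolume",
    "MaterialCoefficients",
    "load_volume",
    "save_volume",
    "make_phantom",
    "crystal_voxels",
    "volume_checksum",
]

#: canonical material names
MATERIALS = ("background", "liquor", "loop", "crystal")

#: default integer codes; overridable through any label_map argument
DEFAULT_LABEL_MAP = {"background": 0, "liquor": 1, "loop": 2, "crystal": 3}

#: representative linear absorption coefficients (um^-1) for protein
#: crystals measured at long wavelengths: insulin at 3.10 A, thermolysin at
#: 3.53 A, thaumatin at 4.13 A (crystal / liquor / loop; background 0)
PRESET_COEFFICIENTS = {
    "insulin": {"crystal": 0.00745, "liquor": 0.00720, "loop": 0.00690},
    "thermolysin": {"crystal": 0.01312, "liquor": 0.01583, "loop": 0.01172},
    "thaumatin": {"crystal": 0.01926, "liquor": 0.02019, "loop": 0.01864},
}

_MAX_CODE = 255  # labels are stored compactly and index count arrays


@dataclass
class SegmentedVolume:
    """A segmented voxel cube.

    Parameters
    ----------
    labels
        3D integer array in (z, y, x) axis order; every value must be a
        code listed in ``label_map``.
    voxel_size_um
        Isotropic voxel edge length in micrometres (> 0).
    label_map
        Mapping material-name -> integer code. Codes must be distinct and
        in [0, 255].
    """

    labels: np.ndarray
    voxel_size_um: float
    label_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"labels must be a 3D array, got {labels.ndim}D")
        if min(labels.shape) < 1:
            raise ValueError("every dimension must be >= 1")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError(f"labels must be integer, got dtype {labels.dtype}")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        codes = list(self.label_map.values())
        if len(set(codes)) != len(codes):
            raise ValueError("label codes must be distinct")
        if any(c < 0 or c > _MAX_CODE for c in codes):
            raise ValueError(f"label codes must lie in [0, {_MAX_CODE}]")
        present = np.unique(labels)
        unknown = sorted(set(present.tolist()) - set(codes))
        if unknown:
            raise ValueError(
                f"labels contain codes absent from label_map: {unknown}")
        self.labels = np.ascontiguousarray(labels.astype(np.uint8, copy=False))
        self.voxel_size_um = float(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def code(self, material: str) -> int:
        return self.label_map[material]

    def material_of(self, code: int) -> str:
        for name, c in self.label_map.items():
            if c == code:
                return name
        raise KeyError(code)

    def counts(self) -> dict[str, int]:
        """Voxel count per material name."""
        binc = np.bincount(self.labels.ravel(), minlength=_MAX_CODE + 1)
        return {name: int(binc[code]) for name, code in self.label_map.items()}


@dataclass
class MaterialCoefficients:
    """Per-material linear absorption coefficients mu in um^-1.

    ``background`` is fixed at exactly 0 (vacuum does not attenuate); it is
    inserted if missing and rejected if nonzero.
    """

    mu: dict[str, float]

    def __post_init__(self) -> None:
        mu = {k: float(v) for k, v in self.mu.items()}
        mu.setdefault("background", 0.0)
        if mu["background"] != 0.0:
            raise ValueError("background coefficient must be exactly 0")
        if any(v < 0 for v in mu.values()):
            raise ValueError("absorption coefficients must be >= 0")
        self.mu = mu

    def code_array(self, label_map: dict[str, int]) -> np.ndarray:
        """mu indexed by label code (um^-1), for the compiled kernels."""
        out = np.zeros(max(label_map.values()) + 1, dtype=np.float64)
        for name, code in label_map.items():
            out[code] = self.mu.get(name, 0.0)
        return out

    def scaled(self, factor: float) -> "MaterialCoefficients":
        return MaterialCoefficients({k: v * factor for k, v in self.mu.items()})


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".npy":
        return "npy"
    if suffix in (".tif", ".tiff"):
        return "tiff-stack"
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    raise ValueError(f"cannot infer volume format from suffix {suffix!r}")


def load_volume(path, format: str | None = None,
                label_map: dict[str, int] | None = None,
                voxel_size_um: float = 1.0,
                dataset: str = "labels") -> SegmentedVolume:
    """Load a segmented volume from NPY, multi-page TIFF or HDF5.

    Parameters
    ----------
    path
        File to read. ``format`` is inferred from the suffix when omitted.
    dataset
        HDF5 dataset path (hdf5 format only).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "npy":
        labels = np.load(path)
    elif fmt == "tiff-stack":
        import tifffile

        labels = tifffile.imread(path)
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as fh:
            labels = fh[dataset][()]
    else:
        raise ValueError(f"unknown volume format {fmt!r}")
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError(
            f"{path} decodes to a {labels.ndim}D array; a 3D label volume is required")
    return SegmentedVolume(labels=labels, voxel_size_um=voxel_size_um,
                           label_map=dict(label_map or DEFAULT_LABEL_MAP))


def save_volume(volume: SegmentedVolume, path, format: str | None = None,
                dataset: str = "labels") -> Path:
    """Write the label array to NPY, multi-page TIFF or HDF5 (round-trips
    with :func:`load_volume`)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "npy":
        np.save(path, volume.labels)
    elif fmt == "tiff-stack":
        import tifffile

        tifffile.imwrite(path, volume.labels)
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset(dataset, data=volume.labels)
    else:
        raise ValueError(f"unknown volume format {fmt!r}")
    return path


def volume_checksum(volume: SegmentedVolume) -> str:
    """SHA-256 of the label array, its shape and the voxel size."""
    h = hashlib.sha256()
    h.update(str(volume.shape).encode())
    h.update(repr(volume.voxel_size_um).encode())
    h.update(json.dumps(sorted(volume.label_map.items())).encode())
    h.update(volume.labels.tobytes())
    return h.hexdigest()


def _core_mask(kind: str, extent, dims) -> np.ndarray:
    center = (np.asarray(dims, float) - 1.0) / 2.0
    zz, yy, xx = np.indices(dims).astype(float)
    dz, dy, dx = zz - center[0], yy - center[1], xx - center[2]
    if kind == "sphere":
        r = float(np.atleast_1d(extent)[0])
        return dz * dz + dy * dy + dx * dx <= r * r
    if kind == "rod":
        half_len, radius = (float(v) for v in np.atleast_1d(extent)[:2])
        ax = np.maximum(np.abs(dz) - half_len, 0.0)  # capsule along z
        return ax * ax + dy * dy + dx * dx <= radius * radius
    if kind == "bipyramid":
        half_h, half_w = (float(v) for v in np.atleast_1d(extent)[:2])
        return np.abs(dz) / half_h + (np.abs(dy) + np.abs(dx)) / half_w <= 1.0
    raise ValueError(f"unknown phantom kind {kind!r}")


def make_phantom(kind: str, crystal_extent_voxels, shells=(3, 2),
                 volume_dims=(32, 32, 32), voxel_size_um: float = 0.3,
                 seed: int = 0, noise_rate: float = 0.0,
                 label_map: dict[str, int] | None = None) -> SegmentedVolume:
    """Synthesize a mounted-crystal phantom.

    Concentric bodies on a vacuum background: a crystal core of the given
    ``kind`` (sphere: radius; rod: (half-length, radius) capsule along z;
    bipyramid: (half-height, half-width) octahedron), a uniform liquor shell
    of ``shells[0]`` voxels and a loop shell of ``shells[1]`` voxels opened
    over the +z half of the volume, the way a real mounting loop cradles the
    sample from one side and leaves it exposed on the other. Along any ray from a crystal voxel the materials
    appear in the order crystal, liquor, loop, background with no vacuum
    between crystal and loop, which is the geometry the bisection back-end
    assumes.

    ``noise_rate`` > 0 flips that fraction of voxels to a uniformly random
    other label (segmentation-noise emulation, off by default). The result
    is a pure function of the arguments: a fixed seed gives an identical
    volume.
    """
    dims = tuple(int(v) for v in volume_dims)
    t_liquor, t_loop = (float(s) for s in shells)
    if t_liquor < 0 or t_loop < 0:
        raise ValueError("shell thicknesses must be >= 0")
    lm = dict(label_map or DEFAULT_LABEL_MAP)

    core = _core_mask(kind, crystal_extent_voxels, dims)
    if not core.any():
        raise ValueError("crystal body is empty for the given extent")
    # uniform-thickness shells for any core shape via the Euclidean
    # distance transform of the complement
    dist_out = ndimage.distance_transform_edt(~core)
    liquor = (dist_out > 0) & (dist_out <= t_liquor)
    loop = (dist_out > t_liquor) & (dist_out <= t_liquor + t_loop)

    if t_loop > 0:
        # open the loop above the equatorial plane: a half-space cut keeps
        # the crystal->liquor->loop->background ordering intact along every
        # straight ray (a line crosses the plane at most once), which the
        # bisection back-end relies on
        center_z = (dims[0] - 1.0) / 2.0
        zz = np.indices(dims)[0].astype(float)
        loop &= zz - center_z <= 0

    labels = np.full(dims, lm["background"], dtype=np.uint8)
    labels[loop] = lm["loop"]
    labels[liquor] = lm["liquor"]
    labels[core] = lm["crystal"]

    if noise_rate > 0:
        rng = np.random.default_rng(seed)
        flip = rng.random(dims) < noise_rate
        codes = np.array(sorted(lm.values()), dtype=np.uint8)
        shift = rng.integers(1, len(codes), size=dims)
        pos = np.searchsorted(codes, labels)
        labels = np.where(flip, codes[(pos + shift) % len(codes)], labels)
        labels = labels.astype(np.uint8)

    volume = SegmentedVolume(labels=labels, voxel_size_um=voxel_size_um,
                             label_map=lm)
    border = np.concatenate([
        volume.labels[0].ravel(), volume.labels[-1].ravel(),
        volume.labels[:, 0].ravel(), volume.labels[:, -1].ravel(),
        volume.labels[:, :, 0].ravel(), volume.labels[:, :, -1].ravel(),
    ])
    if noise_rate == 0 and np.any(border != lm["background"]):
        raise ValueError(
            "bodies do not fit: crystal + shells reach the volume boundary; "
            "enlarge volume_dims or shrink the bodies")
    return volume


def crystal_voxels(volume: SegmentedVolume) -> np.ndarray:
    """Indices (z, y, x) of all crystal voxels, sorted row-major.

    The length of the returned (N, 3) array is the N of the absorption-factor
    average; downstream back-ends reject an empty selection.
    """
    idx = np.argwhere(volume.labels == volume.code("crystal"))
    return np.ascontiguousarray(idx.astype(np.int64))
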