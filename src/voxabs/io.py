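"""Reflection tables, run configuration and JSON factor output."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sampling import DEFAULT_RATIO
from .tracing import AbsorptionResult, Reflection
from .volume import SegmentedVolume, volume_checksum

__all__ = [
    "RunConfig",
    "load_reflections",
    "save_reflections",
    "write_factors",
    "read_factors",
]

_CSV_COLUMNS = ["ix", "iy", "iz", "dx", "dy", "dz"]

METHODS = ("standard", "bisection", "gridding")
SAMPLING_METHODS = ("systematic", "randomized_systematic", "random", "stratified")


def _make_reflection(row_xyz: np.ndarray, index: int) -> Reflection:
    """Build a Reflection from (ix, iy, iz, dx, dy, dz) laboratory-order
    components; vectors are stored internally in (z, y, x) order."""
    vecs = []
    for name, sl in (("incident", slice(0, 3)), ("diffracted", slice(3, 6))):
        x, y, z = (float(v) for v in row_xyz[sl])
        v = np.array([z, y, x])
        norm = float(np.linalg.norm(v))
        if norm == 0.0:
            raise ValueError(f"row {index}: {name} vector is zero")
        if not 0.99 <= norm <= 1.01:
            raise ValueError(
                f"row {index}: {name} vector norm {norm:.4f} outside [0.99, 1.01]")
        vecs.append(v / norm)
    return Reflection(incident=vecs[0], diffracted=vecs[1], index=index)


def load_reflections(path) -> list[Reflection]:
    """Read a reflection table of incident/diffracted direction vectors.

    Two dialects: CSV with header columns ``ix,iy,iz,dx,dy,dz`` (components
    of the incident and diffracted directions in x, y, z order, expressed
    in the voxel-model frame) or JSON -- either a list of 6-element rows in
    the same order or a list of ``{"incident": [x,y,z], "diffracted":
    [x,y,z]}`` objects. Vectors with norm in [0.99, 1.01] are renormalized;
    anything else is rejected with the offending row named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        rows = []
        for entry in json.loads(path.read_text()):
            if isinstance(entry, dict):
                rows.append(list(entry["incident"]) + list(entry["diffracted"]))
            else:
                rows.append(list(entry))
        table = np.asarray(rows, dtype=float) if rows else np.empty((0, 6))
    else:
        import pandas as pd

        frame = pd.read_csv(path)
        missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing reflection columns {missing}")
        try:
            table = frame[_CSV_COLUMNS].to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric entries in table: {exc}") from exc
    if table.size and table.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 numeric columns, got {table.shape[1]}")
    if table.size and not np.all(np.isfinite(table)):
        bad = int(np.argwhere(~np.isfinite(table))[0, 0])
        raise ValueError(f"{path}: non-numeric entry in row {bad}")
    return [_make_reflection(row, i) for i, row in enumerate(table)]


def save_reflections(reflections, path) -> Path:
    """Write reflections back to the CSV dialect (x, y, z column order)."""
    import pandas as pd

    rows = []
    for r in reflections:
        iz, iy, ix = r.incident
        dz, dy, dx = r.diffracted
        rows.append([ix, iy, iz, dx, dy, dz])
    path = Path(path)
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
    return path


def write_factors(result: AbsorptionResult, path,
                  volume: SegmentedVolume | None = None) -> Path:
    """Write absorption factors as JSON, in input-reflection order.

    The payload is ``{"factors": [...], "metadata": {...}}``; the metadata
    block (method, sampling, volume checksum) makes the run reproducible.
    """
    meta = {"method": result.method, "sampling": result.sampling,
            "n_reflections": int(len(result.factors))}
    meta.update(result.metadata)
    if volume is not None:
        meta["volume_checksum"] = volume_checksum(volume)
    path = Path(path)
    path.write_text(json.dumps(
        {"factors": [float(f) for f in np.asarray(result.factors)],
         "metadata": meta}, indent=1))
    return path


def read_factors(path) -> AbsorptionResult:
    data = json.loads(Path(path).read_text())
    meta = dict(data.get("metadata", {}))
    return AbsorptionResult(factors=np.asarray(data["factors"], dtype=float),
                            method=meta.pop("method", "unknown"),
                            sampling=meta.pop("sampling", {}), metadata=meta)


@dataclass
class RunConfig:
    """Validated configuration of one correction run."""

    model_path: str
    reflections_path: str
    output_path: str
    coefficients: dict[str, float]
    model_format: str | None = None
    label_map: dict[str, int] | None = None
    voxel_size_um: float = 1.0
    method: str = "standard"
    sampling_method: str = "systematic"
    ratio: float = DEFAULT_RATIO
    seed: int = 0
    workers: int = 1
    precision: str = "double"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.sampling_method not in SAMPLING_METHODS:
            raise ValueError(f"sampling method must be one of {SAMPLING_METHODS}")
        if not 0.0 < self.ratio <= 1.0:
            raise ValueError("sampling ratio must lie in (0, 1]")
        if self.precision not in ("double", "single"):
            raise ValueError("precision must be 'double' or 'single'")
        if any(v < 0 for v in self.coefficients.values()):
            raise ValueError("absorption coefficients must be >= 0")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load YAML or JSON config; keyword overrides win over the file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        data = dict(data or {})
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
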