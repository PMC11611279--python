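import numpy as np
import pytest

import voxabs as vx


@pytest.fixture(scope="session")
def sphere_phantom() -> vx.SegmentedVolume:
    """32^3 four-material phantom: sphere crystal r=8, liquor 3, loop 2."""
    return vx.make_phantom("sphere", 8, shells=(3, 2), volume_dims=(32, 32, 32),
                           voxel_size_um=0.3, seed=0)


@pytest.fixture(scope="session")
def thermolysin_like_coeffs() -> vx.MaterialCoefficients:
    return vx.MaterialCoefficients(vx.PRESET_COEFFICIENTS["thermolysin"])


@pytest.fixture(scope="session")
def crystal_list(sphere_phantom) -> np.ndarray:
    return vx.crystal_voxels(sphere_phantom)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_unit(rng: np.random.Generator, size=None) -> np.ndarray:
    v = rng.normal(size=(size or 1, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v if size else v[0]


def random_reflections(rng: np.random.Generator, k: int) -> list:
    return [vx.Reflection(incident=random_unit(rng), diffracted=random_unit(rng),
                          index=i) for i in range(k)]


def marching_lengths(volume: vx.SegmentedVolume, start, d,
                     step: float = 1e-3) -> dict[str, float]:
    """Dense-marching oracle: per-material lengths in voxel units, sampling
    the label at the nearest voxel every `step` voxels until the exit."""
    d = np.asarray(d, float)
    d = d / np.linalg.norm(d)
    ex = vx.exit_point(np.asarray(start, float), d, volume.shape)
    t = np.arange(0.0, ex.t + step, step)
    pos = np.asarray(start, float)[None, :] + t[:, None] * d
    r = np.where(pos >= 0, np.floor(pos + 0.5), np.ceil(pos - 0.5)).astype(int)
    np.clip(r, 0, np.asarray(volume.shape) - 1, out=r)
    labs = volume.labels[r[:, 0], r[:, 1], r[:, 2]]
    binc = np.bincount(labs, minlength=256)
    return {m: float(binc[c]) * step for m, c in volume.label_map.items()}
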