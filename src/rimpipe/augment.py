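"""Offline and online 3D patch augmentation.

Offline (computed once, before training):

* axis-aligned rotations of every rim+ patch by 90, 180 and 270 degrees
  about each of the three array axes — the original plus nine rotated
  copies, a tenfold increase of the minority class with no interpolation;
* three elastically deformed versions of every patch (both classes),
  quadrupling the training set while preserving the class ratio.

Online (sampled fresh every time a patch is fed to the network):

* a flip along one of {none, X, Y, Z} followed by a translation of
  -2 / 0 / +2 voxels along each axis — a space of 4 x 27 = 108 transforms.

All augmentations preserve patch shape and the [-1, 1] intensity range.
Transform tags are recorded on each patch so repeated variants can be
detected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .patches import Patch

AXES = ("X", "Y", "Z")
#: array-axis index pairs defining the rotation plane about each axis
_ROT_PLANES = {"X": (1, 2), "Y": (0, 2), "Z": (0, 1)}

ONLINE_FLIPS: tuple[str | None, ...] = (None, "X", "Y", "Z")
ONLINE_SHIFTS: tuple[int, ...] = (-2, 0, 2)


@dataclass
class AugmentConfig:
    rotation_angles: tuple[int, ...] = (90, 180, 270)
    rotation_axes: tuple[str, ...] = AXES
    n_elastic: int = 3
    elastic_amplitude_vox: float = 2.0
    elastic_grid_points: int = 4
    online_translation_vox: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a % 90 != 0 for a in self.rotation_angles):
            raise ValueError("rotation angles must be multiples of 90°")
        if self.elastic_amplitude_vox < 0:
            raise ValueError("elastic amplitude must be >= 0")


def offline_rotations(patch: Patch,
                      config: AugmentConfig | None = None) -> list[Patch]:
    """The original patch plus its nine 90°-multiple rotations.

    Rotations are pure axis permutations/reversals (``np.rot90``), so no
    interpolation occurs.  Right-handed rotations about array axes 0, 1, 2.
    """
    config = config or AugmentConfig()
    size = {v.shape for v in patch.data.values()}
    if size != {(patch.size,) * 3}:
        raise ValueError("offline rotations require a cubic patch")
    out = [patch.with_data(dict(patch.data), "rot:identity")]
    for axis in config.rotation_axes:
        plane = _ROT_PLANES[axis]
        for angle in config.rotation_angles:
            k = angle // 90
            data = {m: np.ascontiguousarray(np.rot90(v, k=k, axes=plane))
                    for m, v in patch.data.items()}
            out.append(patch.with_data(data, f"rot:{axis}{angle}"))
    return out


def _displacement_field(shape: tuple[int, ...], amplitude: float,
                        grid_points: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Smooth random field (3, *shape); vector norm bounded by amplitude.

    A coarse grid of uniform displacements is clipped to norm <= amplitude
    and upsampled with trilinear interpolation; linear interpolation is a
    convex combination, so the bound survives upsampling.
    """
    g = grid_points
    coarse = rng.uniform(-amplitude, amplitude, size=(3, g, g, g))
    norms = np.linalg.norm(coarse, axis=0)
    over = norms > amplitude
    if amplitude > 0 and over.any():
        coarse[:, over] *= amplitude / norms[over]
    # sample coarse field at fractional grid coordinates of each voxel
    coords = np.meshgrid(*[np.linspace(0, g - 1, s) for s in shape],
                         indexing="ij")
    coords = np.stack(coords)
    field = np.stack([
        ndimage.map_coordinates(coarse[a], coords, order=1, mode="nearest")
        for a in range(3)])
    return field


def elastic_deform(patch: Patch, config: AugmentConfig, seed: int) -> Patch:
    """Apply one smooth random displacement field to all modalities.

    Deterministic given ``seed``; maximum voxel displacement is bounded by
    ``config.elastic_amplitude_vox``.  Values are re-clamped to [-1, 1]
    after interpolation.
    """
    rng = np.random.default_rng(seed)
    shape = next(iter(patch.data.values())).shape
    field = _displacement_field(shape, config.elastic_amplitude_vox,
                                config.elastic_grid_points, rng)
    base = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                indexing="ij")).astype(np.float64)
    coords = base + field
    data = {}
    for m, v in patch.data.items():
        warped = ndimage.map_coordinates(v.astype(np.float64), coords,
                                         order=1, mode="constant", cval=0.0)
        data[m] = np.clip(warped, -1.0, 1.0).astype(np.float32)
    return patch.with_data(data, f"elastic:{seed}")


def enumerate_online_transforms() -> list[tuple[str | None,
                                                tuple[int, int, int]]]:
    """All 4 x 27 = 108 (flip, shift) pairs of the online scheme."""
    shifts = list(itertools.product(ONLINE_SHIFTS, repeat=3))
    return [(f, s) for f in ONLINE_FLIPS for s in shifts]


def apply_flip_shift(data: dict[str, np.ndarray], flip: str | None,
                     shift: tuple[int, int, int]) -> dict[str, np.ndarray]:
    out = {}
    for m, v in data.items():
        w = v
        if flip is not None:
            w = np.flip(w, axis=AXES.index(flip))
        if any(shift):
            moved = np.zeros_like(w)
            src = [slice(max(0, -d), w.shape[i] - max(0, d))
                   for i, d in enumerate(shift)]
            dst = [slice(max(0, d), w.shape[i] - max(0, -d))
                   for i, d in enumerate(shift)]
            moved[tuple(dst)] = w[tuple(src)]
            w = moved
        out[m] = np.ascontiguousarray(w)
    return out


def online_augment(patch: Patch, rng: np.random.Generator | int) -> Patch:
    """Sample one of the 108 online transforms uniformly and apply it.

    Translation zero-fills vacated voxels.  The sampled transform is
    recorded in the patch's transform history.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    size = {v.shape for v in patch.data.values()}
    if size != {(patch.size,) * 3}:
        raise ValueError("online augmentation requires a cubic patch")
    flip = ONLINE_FLIPS[rng.integers(len(ONLINE_FLIPS))]
    shift = tuple(ONLINE_SHIFTS[i]
                  for i in rng.integers(len(ONLINE_SHIFTS), size=3))
    data = apply_flip_shift(patch.data, flip, shift)
    tag = f"online:flip={flip or 'none'},shift={shift}"
    return patch.with_data(data, tag)


def offline_augment(patches: Sequence[Patch], config: AugmentConfig,
                    minority_label: str = "rim+") -> list[Patch]:
    """Full offline scheme: rotations of the minority class, then three
    elastic versions of every patch (quadrupling the set).

    Elastic seeds derive deterministically from ``config.seed`` and the
    patch index, so the augmented set is reproducible.
    """
    rotated: list[Patch] = []
    for p in patches:
        if p.label == minority_label:
            rotated.extend(offline_rotations(p, config))
        else:
            rotated.append(p)
    ss = np.random.SeedSequence([config.seed, len(rotated)])
    seeds = ss.generate_state(max(1, config.n_elastic * len(rotated)))
    out = list(rotated)
    k = 0
    for p in rotated:
        for _ in range(config.n_elastic):
            out.append(elastic_deform(p, config, int(seeds[k] % (2 ** 31))))
            k += 1
    return out
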