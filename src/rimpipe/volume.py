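"""Co-registered multimodal volume container and NIfTI I/O.

A :class:`VolumeSet` holds several 3D intensity grids (e.g. a FLAIR-like,
a T2*-magnitude-like and a phase-like contrast) that live on one common
voxel grid with isotropic spacing.  Registration between native spaces is
deliberately out of scope: the pipeline consumes volumes that are already
co-registered.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import nibabel as nib
import numpy as np

log = logging.getLogger("rimpipe")

#: tolerance used when comparing affines of supposedly co-registered files
AFFINE_TOL = 1e-3


@dataclass
class VolumeSet:
    """Multimodal 3D intensity grids on a shared voxel grid.

    Parameters
    ----------
    modalities:
        Mapping from modality name (``"flair"``, ``"t2star"``, ``"phase"``)
        to a 3D float array.  All arrays must share one shape.
    spacing_mm:
        Isotropic voxel edge length in millimetres.
    affine:
        Optional 4x4 voxel-to-world matrix; a diagonal scaling by
        ``spacing_mm`` is used when omitted.
    """

    modalities: dict[str, np.ndarray]
    spacing_mm: float
    affine: np.ndarray | None = None
    patient_id: str = "patient0"
    site_id: str = "site0"

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ValueError("VolumeSet needs at least one modality")
        shapes = {m: v.shape for m, v in self.modalities.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"modalities live on different grids: {shapes}")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if self.affine is None:
            self.affine = np.diag([self.spacing_mm] * 3 + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.modalities.values())).shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.spacing_mm) ** 3

    def __getitem__(self, modality: str) -> np.ndarray:
        return self.modalities[modality]


def save_volume_set(vs: VolumeSet, out_dir: str | os.PathLike,
                    prefix: str = "") -> dict[str, str]:
    """Write one ``.nii.gz`` per modality; returns modality -> path."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, vol in vs.modalities.items():
        img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), vs.affine)
        img.header.set_zooms((vs.spacing_mm,) * 3)
        p = os.path.join(out_dir, f"{prefix}{name}.nii.gz")
        nib.save(img, p)
        paths[name] = p
    return paths


def save_mask(mask: np.ndarray, spacing_mm: float, path: str,
              affine: np.ndarray | None = None) -> str:
    if affine is None:
        affine = np.diag([spacing_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.int16), affine)
    img.header.set_zooms((spacing_mm,) * 3)
    nib.save(img, path)
    return path


def load_mask(path: str) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj)


def load_volume_set(paths: Mapping[str, str],
                    expected_spacing: float | None = None,
                    patient_id: str = "patient0",
                    site_id: str = "site0") -> VolumeSet:
    """Load co-registered NIfTI volumes into a :class:`VolumeSet`.

    All files must share grid shape and affine (within :data:`AFFINE_TOL`).
    Anisotropic spacing is accepted with a warning — the classification
    pipeline itself is agnostic, but the geometry defaults assume isotropy —
    and the mean zoom is used as the nominal spacing.
    """
    if not paths:
        raise ValueError("no volume paths given")
    missing = [p for p in paths.values() if not os.path.exists(p)]
    if missing:
        raise FileNotFoundError(f"missing volume files: {missing}")
    imgs = {m: nib.load(p) for m, p in paths.items()}
    shapes = {m: im.shape for m, im in imgs.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"volume grids differ: {shapes}")
    affines = list(imgs.values())
    ref = affines[0].affine
    bad = [m for m, im in imgs.items()
           if not np.allclose(im.affine, ref, atol=AFFINE_TOL)]
    if bad:
        raise ValueError(f"affines differ beyond tolerance for: {bad}")
    zooms = np.asarray(affines[0].header.get_zooms()[:3], dtype=float)
    if not np.allclose(zooms, zooms[0], atol=1e-3):
        log.warning("anisotropic voxel spacing %s; using mean", zooms)
    spacing = float(zooms.mean())
    if expected_spacing is not None and abs(spacing - expected_spacing) > 1e-3:
        log.warning("spacing %.4f mm differs from expected %.4f mm",
                    spacing, expected_spacing)
    data = {m: np.asarray(im.dataobj, dtype=np.float32)
            for m, im in imgs.items()}
    return VolumeSet(modalities=data, spacing_mm=spacing, affine=ref.copy(),
                     patient_id=patient_id, site_id=site_id)
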