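"""Fixed-size multimodal patch extraction and intensity normalisation.

Patches are cubes (default 28 voxels per edge) centred on the rounded
centre of mass of a lesion candidate.  Voxels falling outside the volume
are zero-filled before normalisation.  Each modality is normalised
independently by a linear min-max map onto [-1, 1]; a constant window maps
to all zeros (the midpoint of the output range).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .candidates import LesionCandidate, window_bounds
from .volume import VolumeSet

DEFAULT_PATCH_SIZE = 28


@dataclass
class Patch:
    """A multimodal intensity cube with provenance."""
    data: dict[str, np.ndarray]
    label: str | None
    candidate_id: int
    patient_id: str = "patient0"
    site_id: str = "site0"
    transforms: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def modalities(self) -> list[str]:
        return list(self.data)

    def with_data(self, data: dict[str, np.ndarray],
                  transform: str) -> "Patch":
        return replace(self, data=data,
                       transforms=self.transforms + (transform,))


def normalize_patch(block: np.ndarray) -> np.ndarray:
    """Linear map of one modality block onto [-1, 1] (constant -> 0)."""
    block = np.asarray(block, dtype=np.float32)
    lo, hi = float(block.min()), float(block.max())
    if hi == lo:
        return np.zeros_like(block)
    return (2.0 * (block - lo) / (hi - lo) - 1.0).astype(np.float32)


def extract_patch(volume_set: VolumeSet, candidate: LesionCandidate,
                  patch_size: int = DEFAULT_PATCH_SIZE,
                  normalize: bool = True) -> Patch:
    """Extract the multimodal patch centred on a candidate.

    The window is ``[c - patch_size//2, c - patch_size//2 + patch_size)``
    per axis with ``c`` the half-up-rounded centre of mass; overhang beyond
    the volume is zero-filled before normalisation.
    """
    shape = np.array(volume_set.shape)
    if patch_size > shape.min():
        raise ValueError(
            f"patch_size {patch_size} exceeds volume extent {tuple(shape)}")
    start, stop = window_bounds(candidate.center_of_mass, patch_size)
    lo = np.maximum(start, 0)
    hi = np.minimum(stop, shape)
    ins_lo = lo - start
    ins_hi = ins_lo + (hi - lo)
    data = {}
    for name, vol in volume_set.modalities.items():
        block = np.zeros((patch_size,) * 3, dtype=np.float32)
        if np.all(hi > lo):
            block[ins_lo[0]:ins_hi[0], ins_lo[1]:ins_hi[1],
                  ins_lo[2]:ins_hi[2]] = vol[lo[0]:hi[0], lo[1]:hi[1],
                                             lo[2]:hi[2]]
        data[name] = normalize_patch(block) if normalize else block
    return Patch(data=data, label=candidate.label, candidate_id=candidate.id,
                 patient_id=candidate.patient_id, site_id=candidate.site_id)


def save_patches(patches: list[Patch], out_dir: str) -> str:
    """Persist patches as compressed arrays plus a CSV manifest."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, p in enumerate(patches):
        fname = f"patch_{i:06d}.npz"
        np.savez_compressed(os.path.join(out_dir, fname), **p.data)
        rows.append({"index": i, "file": fname, "label": p.label,
                     "candidate_id": p.candidate_id,
                     "patient_id": p.patient_id, "site_id": p.site_id,
                     "transforms": "|".join(p.transforms)})
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_patches(manifest_path: str) -> list[Patch]:
    df = pd.read_csv(manifest_path)
    base = os.path.dirname(manifest_path)
    out = []
    for _, row in df.iterrows():
        with np.load(os.path.join(base, row["file"])) as z:
            data = {k: z[k] for k in z.files}
        tf = row.get("transforms")
        transforms = tuple(str(tf).split("|")) if isinstance(tf, str) and tf \
            else ()
        out.append(Patch(data=data, label=row["label"],
                         candidate_id=int(row["candidate_id"]),
                         patient_id=str(row["patient_id"]),
                         site_id=str(row["site_id"]),
                         transforms=transforms))
    return out
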