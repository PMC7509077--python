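"""Lesion-candidate extraction, labelling and exclusion rules.

Candidates are the 6-connected components of a binary lesion segmentation.
A candidate is labelled rim+ when it overlaps the rim+ annotation mask by at
least one voxel, rim- otherwise.  Exclusion rules are then applied in a
fixed order so that reports are reproducible:

1. ``too_small``          — volume below ``min_volume_mm3`` (default 12.3),
2. ``too_big``            — more than ``max_voxels`` voxels (default 10,000),
3. ``artefact``           — the candidate's patch window intersects the
                            artefact mask,
4. ``rim_contaminated``   — a rim- candidate whose patch window contains
                            more than ``rim_contamination_voxels`` voxels of
                            rim+ lesions other than its own (default 900).

Confluent rim+ lesions are an input contract: the caller supplies masks in
which they are already separated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

SIX_CONN = ndimage.generate_binary_structure(3, 1)

RIM_POS = "rim+"
RIM_NEG = "rim-"


@dataclass
class LesionCandidate:
    """One 6-connected component of the lesion segmentation."""
    id: int
    voxels: np.ndarray                # (n, 3) int voxel indices
    voxel_count: int
    volume_mm3: float
    center_of_mass: np.ndarray        # continuous voxel coordinates
    label: str | None = None          # RIM_POS / RIM_NEG
    exclusion_reason: str | None = None
    patient_id: str = "patient0"
    site_id: str = "site0"

    @property
    def excluded(self) -> bool:
        return self.exclusion_reason is not None


@dataclass
class ExclusionConfig:
    min_volume_mm3: float = 12.3
    max_voxels: int = 10_000
    rim_contamination_voxels: int = 900
    use_artefact_mask: bool = True

    def __post_init__(self) -> None:
        if self.min_volume_mm3 <= 0:
            raise ValueError("min_volume_mm3 must be positive")
        if self.max_voxels <= self.rim_contamination_voxels:
            raise ValueError("max_voxels must exceed rim_contamination_voxels")


def window_bounds(center_of_mass: np.ndarray, patch_size: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Patch window [start, stop) centred at the rounded centre of mass.

    Rounding is half-up per axis; the window may extend beyond the volume
    (patch extraction zero-fills the overhang).
    """
    center = np.floor(np.asarray(center_of_mass, dtype=float) + 0.5
                      ).astype(int)
    start = center - patch_size // 2
    return start, start + patch_size


def _clipped_window(mask: np.ndarray, start: np.ndarray, stop: np.ndarray
                    ) -> np.ndarray:
    lo = np.maximum(start, 0)
    hi = np.minimum(stop, mask.shape)
    if np.any(hi <= lo):
        return mask[0:0, 0:0, 0:0]
    return mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]


def extract_components(mask: np.ndarray, spacing_mm: float,
                       patient_id: str = "patient0",
                       site_id: str = "site0") -> list[LesionCandidate]:
    """Partition a binary mask into maximal 6-connected components.

    Components are ordered by their first voxel in a lexicographic raster
    scan, so extraction is deterministic.
    """
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask must be binary, found values {vals}")
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be positive")
    labeled, n = ndimage.label(mask, structure=SIX_CONN)
    if n == 0:
        return []
    # order labels by first occurrence in the flat raster scan
    flat = labeled.ravel()
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier indices overwrite later ones
    first_idx[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first_idx[1:], kind="stable")
    vox_vol = spacing_mm ** 3
    out = []
    objects = ndimage.find_objects(labeled)
    for new_id, lab0 in enumerate(order, start=1):
        lab = lab0 + 1
        sl = objects[lab - 1]
        local = np.argwhere(labeled[sl] == lab)
        offset = np.array([s.start for s in sl])
        vox = local + offset
        out.append(LesionCandidate(
            id=new_id, voxels=vox, voxel_count=len(vox),
            volume_mm3=len(vox) * vox_vol,
            center_of_mass=vox.mean(axis=0),
            patient_id=patient_id, site_id=site_id))
    return out


def label_candidates(candidates: Sequence[LesionCandidate],
                     rim_plus_mask: np.ndarray,
                     grid_shape: tuple[int, ...] | None = None
                     ) -> list[LesionCandidate]:
    """Label each candidate rim+ iff it overlaps the annotation mask."""
    rim_plus_mask = np.asarray(rim_plus_mask).astype(bool)
    if grid_shape is not None and rim_plus_mask.shape != tuple(grid_shape):
        raise ValueError("rim+ mask grid does not match the lesion grid")
    out = []
    for c in candidates:
        if c.voxels.size and np.any(c.voxels.max(axis=0)
                                    >= rim_plus_mask.shape):
            raise ValueError(f"candidate {c.id} outside the rim+ mask grid")
        overlap = rim_plus_mask[tuple(c.voxels.T)].any()
        out.append(replace(c, label=RIM_POS if overlap else RIM_NEG))
    return out


@dataclass
class ExclusionReport:
    """Per-reason, per-class bookkeeping of the exclusion pass."""
    counts: pd.DataFrame     # index: reason incl. 'kept'; columns: classes

    def kept(self, label: str) -> int:
        return int(self.counts.loc["kept", label])

    def removed(self, reason: str, label: str) -> int:
        if reason not in self.counts.index:
            return 0
        return int(self.counts.loc[reason, label])


_REASONS = ("too_small", "too_big", "artefact", "rim_contaminated")


def apply_exclusions(candidates: Sequence[LesionCandidate],
                     rim_plus_mask: np.ndarray,
                     artefact_mask: np.ndarray | None,
                     config: ExclusionConfig,
                     patch_size: int = 28
                     ) -> tuple[list[LesionCandidate],
                                list[LesionCandidate], ExclusionReport]:
    """Apply the exclusion rules in their fixed order.

    Returns (kept, excluded, report); every input candidate appears in
    exactly one of the two lists.
    """
    rim_plus_mask = np.asarray(rim_plus_mask).astype(bool)
    if artefact_mask is not None:
        artefact_mask = np.asarray(artefact_mask).astype(bool)
    kept: list[LesionCandidate] = []
    excluded: list[LesionCandidate] = []
    for c in candidates:
        if c.label not in (RIM_POS, RIM_NEG):
            raise ValueError(f"candidate {c.id} is unlabeled")
        reason = None
        start, stop = window_bounds(c.center_of_mass, patch_size)
        if c.volume_mm3 < config.min_volume_mm3:
            reason = "too_small"
        elif c.voxel_count > config.max_voxels:
            reason = "too_big"
        elif (config.use_artefact_mask and artefact_mask is not None
              and _clipped_window(artefact_mask, start, stop).any()):
            reason = "artefact"
        elif c.label == RIM_NEG:
            in_window = int(_clipped_window(rim_plus_mask, start, stop).sum())
            own = int(rim_plus_mask[tuple(c.voxels.T)].sum())
            if in_window - own > config.rim_contamination_voxels:
                reason = "rim_contaminated"
        if reason is None:
            kept.append(c)
        else:
            excluded.append(replace(c, exclusion_reason=reason))

    idx = list(_REASONS) + ["kept"]
    counts = pd.DataFrame(0, index=idx, columns=[RIM_NEG, RIM_POS])
    for c in kept:
        counts.loc["kept", c.label] += 1
    for c in excluded:
        counts.loc[c.exclusion_reason, c.label] += 1
    return kept, excluded, ExclusionReport(counts=counts)


def candidates_to_frame(candidates: Sequence[LesionCandidate]) -> pd.DataFrame:
    """Tabular view written to the candidate CSV manifest."""
    rows = []
    for c in candidates:
        rows.append({
            "id": c.id, "patient_id": c.patient_id, "site_id": c.site_id,
            "label": c.label, "voxel_count": c.voxel_count,
            "volume_mm3": c.volume_mm3,
            "center_x": c.center_of_mass[0],
            "center_y": c.center_of_mass[1],
            "center_z": c.center_of_mass[2],
            "exclusion_reason": c.exclusion_reason,
        })
    return pd.DataFrame(rows, columns=[
        "id", "patient_id", "site_id", "label", "voxel_count", "volume_mm3",
        "center_x", "center_y", "center_z", "exclusion_reason"])
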