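"""Reference study configurations built entirely from synthetic data.

Two ready-made set-ups:

* :func:`reference_phantom_experiment` — the package's standard recovery
  experiment: a ~300-lesion multi-site phantom cohort (25% rim+, strong
  rim contrast, mild noise and bias field) classified with a reduced
  network (filters 8/16/32) under patient-grouped stratified 4-fold
  cross-validation.  Patch size 16 and a short fixed epoch budget keep
  the experiment desktop-sized; the rim signal is strong enough that the
  bimodal phase+FLAIR model should approach perfect separation while the
  FLAIR-only baseline has no rim information to exploit.
* :func:`exclusion_bookkeeping_scenario` — a synthetic candidate cohort
  whose per-rule exclusion counts reproduce the standard dataset
  bookkeeping of a 124-patient MS cohort (4857 rim- / 462 rim+ before
  filtering; 32+25+113 rim- and 4+1 rim+ removals), used to exercise the
  exclusion report arithmetic end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .candidates import LesionCandidate, RIM_NEG, RIM_POS
from .model import ArchConfig
from .phantom import PhantomConfig, generate_cohort
from .pipeline import CVResult, run_cv_experiment
from .train import TrainConfig

#: study conditions of the reference phantom cohort
REFERENCE_PHANTOM = dict(
    n_patients=24,                 # ~312 lesions, 25% rim+
    n_rim_pos=3, n_rim_neg=10,
    grid_shape=(96, 96, 96),
    noise_sd=2.0,
    bias_field_amplitude=0.1,
)
REFERENCE_PATCH_SIZE = 16
REFERENCE_FILTERS = (8, 16, 32)
REFERENCE_FC = (64, 16)
REFERENCE_EPOCHS = 4


def reference_phantom_cohort(seed: int):
    base = PhantomConfig(
        grid_shape=REFERENCE_PHANTOM["grid_shape"],
        n_rim_pos=REFERENCE_PHANTOM["n_rim_pos"],
        n_rim_neg=REFERENCE_PHANTOM["n_rim_neg"],
        n_artefacts=1,
        noise_sd=REFERENCE_PHANTOM["noise_sd"],
        bias_field_amplitude=REFERENCE_PHANTOM["bias_field_amplitude"])
    return generate_cohort(base, REFERENCE_PHANTOM["n_patients"],
                           sites=("siteA", "siteB"), seed=seed)


def reference_phantom_experiment(seed: int,
                                 modalities: tuple[str, ...] =
                                 ("phase", "flair"),
                                 cohort=None) -> CVResult:
    """Run the reference 4-fold CV experiment for one seed.

    ``modalities`` selects the bimodal network (two entries, main first)
    or the unimodal baseline (one entry).  Passing a prebuilt ``cohort``
    lets several network configurations share one cohort.
    """
    if cohort is None:
        cohort = reference_phantom_cohort(seed)
    arch = ArchConfig(modalities=modalities,
                      early_fusion=len(modalities) == 2,
                      filters=REFERENCE_FILTERS, fc_widths=REFERENCE_FC)
    train_cfg = TrainConfig(max_epochs=REFERENCE_EPOCHS, batch_size=32,
                            online_augmentation=True)
    return run_cv_experiment(
        cohort, arch=arch, train_cfg=train_cfg,
        patch_size=REFERENCE_PATCH_SIZE, n_folds=4, seed=seed,
        epoch_budget=[REFERENCE_EPOCHS, 0, 0, 0])


# ---------------------------------------------------------------------------
# exclusion bookkeeping scenario
# ---------------------------------------------------------------------------

@dataclass
class BookkeepingScenario:
    candidates: list[LesionCandidate]
    rim_plus_mask: np.ndarray
    artefact_mask: np.ndarray
    spacing_mm: float
    patch_size: int


def exclusion_bookkeeping_scenario(
        n_rim_neg: int = 4857, n_rim_pos: int = 462,
        n_too_big_neg: int = 32, n_too_big_pos: int = 4,
        n_artefact_neg: int = 25, n_artefact_pos: int = 1,
        n_contaminated_neg: int = 113,
        patch_size: int = 28) -> BookkeepingScenario:
    """Construct a synthetic candidate cohort with prescribed rule hits.

    Candidates sit on a lattice whose pitch exceeds the patch window, so
    rules never interact across cells.  Ordinary candidates are single
    voxels at 3 mm spacing (27 mm^3, clear of the 12.3 mm^3 size filter);
    "too big" candidates have 10,001 voxels; "artefact" candidates have an
    artefact voxel inside their patch window; "contaminated" rim-
    candidates see a 1000-voxel rim+ blob (one of the rim+ candidates)
    inside their window.
    """
    if n_contaminated_neg > n_rim_pos - n_too_big_pos - n_artefact_pos:
        raise ValueError("not enough ordinary rim+ lesions to act as "
                         "contamination sources")
    pitch = patch_size + 4
    n_cells_needed = n_rim_neg + n_rim_pos - n_contaminated_neg
    per_axis = int(np.ceil(n_cells_needed ** (1 / 3))) + 1
    shape = (per_axis * pitch,) * 3
    rim_mask = np.zeros(shape, dtype=bool)
    art_mask = np.zeros(shape, dtype=bool)
    spacing = 3.0

    centers = iter(
        (pitch // 2 + i * pitch, pitch // 2 + j * pitch,
         pitch // 2 + k * pitch)
        for i in range(per_axis) for j in range(per_axis)
        for k in range(per_axis))
    cands: list[LesionCandidate] = []
    cid = 0

    def add(voxels: np.ndarray, label: str) -> LesionCandidate:
        nonlocal cid
        cid += 1
        c = LesionCandidate(id=cid, voxels=voxels, voxel_count=len(voxels),
                            volume_mm3=len(voxels) * spacing ** 3,
                            center_of_mass=voxels.mean(axis=0), label=label)
        cands.append(c)
        return c

    def big_blob(center: tuple[int, int, int]) -> np.ndarray:
        # 22 x 22 x 21 = 10,164 voxels > 10,000
        cz, cy, cx = center
        zz, yy, xx = np.meshgrid(np.arange(cz - 11, cz + 11),
                                 np.arange(cy - 11, cy + 11),
                                 np.arange(cx - 10, cx + 11), indexing="ij")
        return np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)

    def small_blob(center: tuple[int, int, int]) -> np.ndarray:
        cz, cy, cx = center
        zz, yy, xx = np.meshgrid(np.arange(cz - 5, cz + 5),
                                 np.arange(cy - 5, cy + 5),
                                 np.arange(cx - 5, cx + 5), indexing="ij")
        return np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)

    # rim+ candidates ------------------------------------------------------
    for _ in range(n_too_big_pos):
        add(big_blob(next(centers)), RIM_POS)
    for _ in range(n_artefact_pos):
        c = np.array(next(centers))
        cand = add(c[None, :], RIM_POS)
        art_mask[tuple(c + np.array([0, 0, 5]))] = True
    n_pos_sources = n_contaminated_neg
    for _ in range(n_pos_sources):
        # a 1000-voxel rim+ blob sharing a cell with one rim- candidate
        center = np.array(next(centers))
        blob = small_blob(tuple(center + np.array([0, 0, 7])))
        add(blob, RIM_POS)
        rim_mask[tuple(blob.T)] = True
        add(center[None, :], RIM_NEG)          # the contaminated rim-
    n_pos_rest = n_rim_pos - n_too_big_pos - n_artefact_pos - n_pos_sources
    for _ in range(n_pos_rest):
        c = np.array(next(centers))
        cand = add(c[None, :], RIM_POS)
        rim_mask[tuple(c)] = True

    # rim- candidates ------------------------------------------------------
    for _ in range(n_too_big_neg):
        add(big_blob(next(centers)), RIM_NEG)
    for _ in range(n_artefact_neg):
        c = np.array(next(centers))
        add(c[None, :], RIM_NEG)
        art_mask[tuple(c + np.array([0, 0, 5]))] = True
    n_neg_rest = (n_rim_neg - n_too_big_neg - n_artefact_neg
                  - n_contaminated_neg)
    for _ in range(n_neg_rest):
        add(np.array(next(centers))[None, :], RIM_NEG)

    # mark rim+ voxels of the big/plain rim+ candidates too
    for c in cands:
        if c.label == RIM_POS and c.voxel_count > 1 \
                and not rim_mask[tuple(c.voxels[0])]:
            rim_mask[tuple(c.voxels.T)] = True
    return BookkeepingScenario(candidates=cands, rim_plus_mask=rim_mask,
                               artefact_mask=art_mask, spacing_mm=spacing,
                               patch_size=patch_size)
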