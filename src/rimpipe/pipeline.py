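"""End-to-end orchestration with reproducible configuration and manifests.

``run_cv_experiment`` is the library-level workhorse: cohort -> candidate
extraction -> patch extraction -> patient-grouped stratified folds ->
per-fold training -> held-out scores -> fold-averaged evaluation.
``run_pipeline`` wraps it with file I/O: every stage writes a manifest
into an append-only run directory, together with a config snapshot, so a
rerun with the same config and seed reproduces the manifests bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .augment import AugmentConfig, offline_augment
from .candidates import (ExclusionConfig, apply_exclusions,
                         candidates_to_frame, extract_components,
                         label_candidates)
from .evaluate import EvalReport, evaluate_folds
from .model import ArchConfig
from .patches import DEFAULT_PATCH_SIZE, Patch, extract_patch
from .phantom import GroundTruth, PhantomConfig, generate_cohort
from .train import (FoldSplit, PatientInfo, TrainConfig, inner_cv_epochs,
                    make_folds, predict_rim_probability, train_model)
from .volume import VolumeSet, load_volume_set, load_mask

log = logging.getLogger("rimpipe")


def derive_seed(seed: int, *stages: str) -> int:
    """Deterministic per-stage seed fan-out from one global seed."""
    ss = np.random.SeedSequence([seed] + [abs(hash_stable(s)) for s in stages])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def hash_stable(s: str) -> int:
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) % (2 ** 32)
    return h


def cohort_to_candidates(cohort: Sequence[tuple[VolumeSet, GroundTruth]],
                         exclusion: ExclusionConfig,
                         patch_size: int = DEFAULT_PATCH_SIZE):
    """Candidate extraction + labelling + exclusions for every patient."""
    kept_all, excluded_all = [], []
    for vs, gt in cohort:
        cands = extract_components(gt.lesion_mask.astype(np.uint8),
                                   vs.spacing_mm, patient_id=vs.patient_id,
                                   site_id=vs.site_id)
        cands = label_candidates(cands, gt.rim_plus_mask)
        kept, excluded, _ = apply_exclusions(
            cands, gt.rim_plus_mask, gt.artefact_mask, exclusion, patch_size)
        kept_all.append((vs, kept))
        excluded_all.extend(excluded)
    return kept_all, excluded_all


def extract_cohort_patches(kept_all, patch_size: int) -> list[Patch]:
    patches = []
    for vs, kept in kept_all:
        for c in kept:
            patches.append(extract_patch(vs, c, patch_size))
    return patches


@dataclass
class CVResult:
    fold_split: FoldSplit
    per_fold_scores: list[np.ndarray]
    per_fold_labels: list[np.ndarray]
    lesion_table: pd.DataFrame
    report: EvalReport
    histories: list


def run_cv_experiment(cohort: Sequence[tuple[VolumeSet, GroundTruth]],
                      arch: ArchConfig,
                      train_cfg: TrainConfig,
                      exclusion: ExclusionConfig | None = None,
                      patch_size: int = DEFAULT_PATCH_SIZE,
                      n_folds: int = 4,
                      seed: int = 0,
                      epoch_budget: Sequence[int] | None = None,
                      nested: bool = False,
                      augment_cfg: AugmentConfig | None = None) -> CVResult:
    """Patient-grouped, per-site stratified k-fold cross-validation.

    Per outer fold the model is trained on the remaining folds and scored
    on the held-out fold.  The epoch schedule comes from, in order of
    precedence: ``epoch_budget`` (fixed per-rate counts), ``nested=True``
    (3-fold inner CV determines the budget), or a patient-grouped
    validation split carved out of the training folds.  Offline
    augmentation, when configured, is applied to training patches only.
    """
    exclusion = exclusion or ExclusionConfig()
    kept_all, _ = cohort_to_candidates(cohort, exclusion, patch_size)
    patches = extract_cohort_patches(kept_all, patch_size)
    infos = _patient_infos(patches)
    split = make_folds(infos, n_folds=n_folds,
                       seed=derive_seed(seed, "folds"))

    per_scores, per_labels, histories = [], [], []
    rows = []
    for fold in range(n_folds):
        test_p = set(split.patients_in_fold(fold))
        train_patches = [p for p in patches if p.patient_id not in test_p]
        test_patches = [p for p in patches if p.patient_id in test_p]
        if augment_cfg is not None:
            train_patches = offline_augment(train_patches, augment_cfg)
        fold_seed = derive_seed(seed, "train", str(fold))
        if epoch_budget is not None:
            net, hist = train_model(train_patches, None, arch, train_cfg,
                                    seed=fold_seed,
                                    epoch_budget=epoch_budget)
        elif nested:
            budget = inner_cv_epochs(train_patches, arch, train_cfg,
                                     seed=fold_seed)
            net, hist = train_model(train_patches, None, arch, train_cfg,
                                    seed=fold_seed, epoch_budget=budget)
        else:
            tr, va = _carve_validation(train_patches, fold_seed)
            net, hist = train_model(tr, va, arch, train_cfg, seed=fold_seed)
        scores = predict_rim_probability(net, test_patches)
        labels = np.array([1 if p.label == "rim+" else 0
                           for p in test_patches])
        per_scores.append(scores)
        per_labels.append(labels)
        histories.append(hist)
        for p, s, y in zip(test_patches, scores, labels):
            rows.append({"fold": fold, "patient_id": p.patient_id,
                         "site_id": p.site_id,
                         "candidate_id": p.candidate_id,
                         "score": float(s), "label": int(y)})
    lesion_table = pd.DataFrame(rows)
    report = evaluate_folds(per_scores, per_labels, lesion_table)
    return CVResult(fold_split=split, per_fold_scores=per_scores,
                    per_fold_labels=per_labels, lesion_table=lesion_table,
                    report=report, histories=histories)


def _patient_infos(patches: Sequence[Patch]) -> list[PatientInfo]:
    stats: dict[str, dict] = {}
    for p in patches:
        s = stats.setdefault(p.patient_id,
                             {"site": p.site_id, "pos": 0, "neg": 0})
        s["pos" if p.label == "rim+" else "neg"] += 1
    return [PatientInfo(pid, s["site"], s["pos"], s["neg"])
            for pid, s in sorted(stats.items())]


def _carve_validation(train_patches: list[Patch], seed: int,
                      frac: float = 0.25) -> tuple[list[Patch], list[Patch]]:
    """Patient-grouped validation split from the training patches."""
    rng = np.random.default_rng(seed)
    pids = sorted({p.patient_id for p in train_patches})
    rng.shuffle(pids)
    n_val = max(1, int(round(frac * len(pids))))
    # ensure both classes in both sides: move patients until satisfied
    for shift in range(len(pids)):
        val_p = set(pids[:n_val])
        tr = [p for p in train_patches if p.patient_id not in val_p]
        va = [p for p in train_patches if p.patient_id in val_p]
        if (_has_both(tr) and _has_both(va)):
            return tr, va
        pids = pids[1:] + pids[:1]
    raise ValueError("cannot build a two-class validation split")


def _has_both(patches: Sequence[Patch]) -> bool:
    labels = {p.label for p in patches}
    return {"rim+", "rim-"}.issubset(labels)


# ---------------------------------------------------------------------------
# file-level pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Reproducible end-to-end run configuration (YAML-serialisable)."""
    seed: int = 0
    patch_size: int = DEFAULT_PATCH_SIZE
    n_folds: int = 4
    phantom: PhantomConfig | None = None
    n_patients: int = 8
    volumes: list[dict] | None = None     # [{patient_id, site_id, paths...}]
    lesion_mask_key: str = "lesion_mask"
    rim_plus_mask_key: str = "rim_plus_mask"
    artefact_mask_key: str = "artefact_mask"
    modalities: tuple[str, ...] = ("phase", "flair")
    exclusion: ExclusionConfig = field(default_factory=ExclusionConfig)
    arch: ArchConfig | None = None
    train: TrainConfig = field(default_factory=TrainConfig)
    augment: AugmentConfig | None = None
    epoch_budget: tuple[int, ...] | None = None
    nested: bool = False
    target_specificity: float = 0.95

    def __post_init__(self) -> None:
        if self.arch is None:
            self.arch = ArchConfig(modalities=tuple(self.modalities))
        if self.phantom is None and self.volumes is None:
            self.phantom = PhantomConfig()
        if self.volumes is not None:
            missing = []
            for entry in self.volumes:
                for key, path in entry.items():
                    if key.endswith(("_mask", "path")) or key in \
                            self.modalities:
                        if isinstance(path, str) and not os.path.exists(path):
                            missing.append(path)
            if missing:
                raise FileNotFoundError(
                    f"pipeline config references missing files: {missing}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "phantom" in d and d["phantom"] is not None:
            from .phantom import ModalityContrast
            ph = d["phantom"]
            if "contrast" in ph:
                ph["contrast"] = {k: ModalityContrast(**v)
                                  for k, v in ph["contrast"].items()}
            for key in ("grid_shape", "lesion_radius_range_mm"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            d["phantom"] = PhantomConfig(**ph)
        if "exclusion" in d:
            d["exclusion"] = ExclusionConfig(**d["exclusion"])
        if "arch" in d and d["arch"] is not None:
            a = d["arch"]
            for key in ("modalities", "filters", "fc_widths"):
                if key in a:
                    a[key] = tuple(a[key])
            d["arch"] = ArchConfig(**a)
        if "train" in d:
            t = d["train"]
            if "learning_rates" in t:
                t["learning_rates"] = tuple(t["learning_rates"])
            d["train"] = TrainConfig(**t)
        if "augment" in d and d["augment"] is not None:
            d["augment"] = AugmentConfig(**d["augment"])
        if "modalities" in d:
            d["modalities"] = tuple(d["modalities"])
        if "epoch_budget" in d and d["epoch_budget"] is not None:
            d["epoch_budget"] = tuple(d["epoch_budget"])
        return cls(**d)

    def snapshot(self, path: str) -> None:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v
                        in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj
        with open(path, "w") as fh:
            yaml.safe_dump(enc(self), fh, sort_keys=False)


def _load_cohort_from_config(cfg: PipelineConfig
                             ) -> list[tuple[VolumeSet, GroundTruth]]:
    if cfg.volumes is None:
        return generate_cohort(cfg.phantom, cfg.n_patients,
                               seed=derive_seed(cfg.seed, "phantom"))
    cohort = []
    for entry in cfg.volumes:
        paths = {m: entry[m] for m in cfg.modalities}
        vs = load_volume_set(paths,
                             patient_id=str(entry.get("patient_id", "p?")),
                             site_id=str(entry.get("site_id", "site0")))
        lesion = load_mask(entry[cfg.lesion_mask_key]) > 0
        rim = (load_mask(entry[cfg.rim_plus_mask_key]) > 0
               if cfg.rim_plus_mask_key in entry
               else np.zeros_like(lesion))
        art = (load_mask(entry[cfg.artefact_mask_key]) > 0
               if cfg.artefact_mask_key in entry
               else np.zeros_like(lesion))
        gt = GroundTruth(lesion_labels=lesion.astype(np.int32),
                         rim_plus_mask=rim, artefact_mask=art,
                         region_masks={}, table=pd.DataFrame())
        cohort.append((vs, gt))
    return cohort


def run_pipeline(config: PipelineConfig, out_dir: str) -> str:
    """Execute all stages and write an append-only run directory."""
    os.makedirs(out_dir, exist_ok=True)
    config.snapshot(os.path.join(out_dir, "config.yaml"))
    logging.basicConfig(level=logging.INFO)
    log.info("pipeline seed=%d out=%s", config.seed, out_dir)

    cohort = _load_cohort_from_config(config)
    kept_all, excluded = cohort_to_candidates(cohort, config.exclusion,
                                              config.patch_size)
    all_c = [c for _, kept in kept_all for c in kept] + excluded
    candidates_to_frame(all_c).to_csv(
        os.path.join(out_dir, "candidates.csv"), index=False)

    result = run_cv_experiment(
        cohort, arch=config.arch, train_cfg=config.train,
        exclusion=config.exclusion, patch_size=config.patch_size,
        n_folds=config.n_folds, seed=config.seed,
        epoch_budget=config.epoch_budget, nested=config.nested,
        augment_cfg=config.augment)

    folds = pd.DataFrame(sorted(result.fold_split.assignment.items()),
                         columns=["patient_id", "fold"])
    folds.to_csv(os.path.join(out_dir, "folds.csv"), index=False)
    result.fold_split.table.to_csv(
        os.path.join(out_dir, "fold_stats.csv"), index=False)
    result.lesion_table.to_csv(
        os.path.join(out_dir, "lesion_scores.csv"), index=False)
    for k, hist in enumerate(result.histories):
        hist.to_frame().to_csv(
            os.path.join(out_dir, f"history_fold{k}.csv"), index=False)
    with open(os.path.join(out_dir, "eval_report.json"), "w") as fh:
        json.dump(result.report.to_dict(), fh, indent=2)
    curves = pd.DataFrame({
        "fpr": result.report.curves.fpr_grid,
        "mean_tpr": result.report.curves.mean_tpr,
        "recall": result.report.curves.recall_grid,
        "mean_precision": result.report.curves.mean_precision})
    curves.to_csv(os.path.join(out_dir, "curves.csv"), index=False)
    return out_dir
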