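"""Statistical evaluation: fold-averaged curves, paired tests, operating
points, patient-level categorisation and anatomical-location analysis.

Conventions
-----------
* ROC and PR curves of the testing folds are interpolated onto a fixed
  1001-point abscissa grid with piecewise-constant (step) interpolation
  and averaged pointwise; the reported AUC is the *mean of the per-fold
  AUCs*, not the AUC of the mean curve (the pooled AUC is also returned
  for diagnostics).
* Correlated ROC AUCs are compared with the DeLong test (midrank-based
  covariance, two-sided normal reference); paired classifier decisions
  with the McNemar test with continuity correction.
* The operating point is the smallest score threshold whose empirical
  specificity reaches a target (95% by default); a lesion is called rim+
  iff its score is >= the threshold.
* A patient is "chronic active" iff its rim+ lesion count reaches a
  threshold (headline value: >= 4 lesions).
* Anatomical regions: the cortex and ventricle masks are dilated by 2 mm
  and 3 mm respectively (spherical structuring element); a lesion is
  periventricular on any overlap with the dilated ventricles, otherwise
  assigned to the first region covering at least half of its volume
  (juxtacortical, then deep gray/brainstem/cerebellum), and falls back to
  deep white matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn import metrics as skm

from .candidates import LesionCandidate

CURVE_GRID_POINTS = 1001


# ---------------------------------------------------------------------------
# fold-averaged curves
# ---------------------------------------------------------------------------

@dataclass
class AveragedCurves:
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    recall_grid: np.ndarray
    mean_precision: np.ndarray
    roc_aucs: list[float]
    pr_aucs: list[float]
    mean_roc_auc: float
    mean_pr_auc: float
    pooled_roc_auc: float


def _step_interp(x_grid: np.ndarray, x: np.ndarray, y: np.ndarray
                 ) -> np.ndarray:
    """Piecewise-constant interpolation: y of the last x <= grid point."""
    idx = np.searchsorted(x, x_grid, side="right") - 1
    idx = np.clip(idx, 0, len(y) - 1)
    return y[idx]


def averaged_curves(per_fold_scores: Sequence[np.ndarray],
                    per_fold_labels: Sequence[np.ndarray]
                    ) -> AveragedCurves:
    """Step-interpolated, pointwise-averaged ROC and PR curves over folds."""
    if len(per_fold_scores) != len(per_fold_labels):
        raise ValueError("need one label set per score set")
    grid = np.linspace(0.0, 1.0, CURVE_GRID_POINTS)
    tprs, precs, roc_aucs, pr_aucs = [], [], [], []
    for k, (s, y) in enumerate(zip(per_fold_scores, per_fold_labels)):
        s = np.asarray(s, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError(f"fold {k} contains a single class")
        fpr, tpr, _ = skm.roc_curve(y, s)
        tprs.append(_step_interp(grid, fpr, tpr))
        roc_aucs.append(float(skm.roc_auc_score(y, s)))
        prec, rec, _ = skm.precision_recall_curve(y, s)
        order = np.argsort(rec, kind="stable")
        precs.append(_step_interp(grid, rec[order], prec[order]))
        pr_aucs.append(float(skm.average_precision_score(y, s)))
    all_s = np.concatenate([np.asarray(s) for s in per_fold_scores])
    all_y = np.concatenate([np.asarray(y) for y in per_fold_labels])
    return AveragedCurves(
        fpr_grid=grid, mean_tpr=np.mean(tprs, axis=0),
        recall_grid=grid, mean_precision=np.mean(precs, axis=0),
        roc_aucs=roc_aucs, pr_aucs=pr_aucs,
        mean_roc_auc=float(np.mean(roc_aucs)),
        mean_pr_auc=float(np.mean(pr_aucs)),
        pooled_roc_auc=float(skm.roc_auc_score(all_y, all_s)))


# ---------------------------------------------------------------------------
# DeLong test for paired ROC AUCs
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the V10 (per-positive) and V01 (per-negative) structural
    components of the DeLong decomposition."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return float(auc), v10, v01


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> tuple[float, float, float]:
    """Two-sided DeLong test on the AUC difference of paired scores.

    Returns ``(auc_a, auc_b, p_value)``.  When the variance of the
    difference is zero, p is 1.0 for equal AUCs (identical behaviour) and
    0.0 otherwise.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores and labels must be paired (equal length)")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var <= 0:
        return auc_a, auc_b, 1.0 if np.isclose(auc_a, auc_b) else 0.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return auc_a, auc_b, p


# ---------------------------------------------------------------------------
# McNemar test with continuity correction
# ---------------------------------------------------------------------------

def mcnemar_test(b: int, c: int) -> tuple[float, float]:
    """Continuity-corrected McNemar statistic and p-value.

    ``b`` and ``c`` are the two discordant-pair counts.  The statistic
    (|b - c| - 1)^2 / (b + c) is referred to chi-square with 1 df;
    p = 1 when there is no discordance at all.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        return 0.0, 1.0
    statistic = (abs(b - c) - 1.0) ** 2 / (b + c)
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


# ---------------------------------------------------------------------------
# operating point and confusion-matrix metrics
# ---------------------------------------------------------------------------

def operating_point(scores: np.ndarray, labels: np.ndarray,
                    target_specificity: float = 0.95
                    ) -> tuple[float, float]:
    """Smallest threshold whose empirical specificity meets the target.

    A case is called positive iff ``score >= threshold``; specificity is
    the fraction of negatives below the threshold.  Returns
    ``(threshold, achieved_specificity)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    neg = scores[labels == 0]
    candidates = np.concatenate([np.unique(scores), [np.inf]])
    for t in candidates:
        spec = float(np.mean(neg < t))
        if spec >= target_specificity:
            return float(t), spec
    return float(np.inf), 1.0           # unreachable; kept for safety


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray
                               ) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))))


def lesion_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Accuracy, F1, sensitivity, specificity, PPV, NPV as fractions.

    Ratios with a zero denominator are reported as ``None`` (absent), not
    as zero.  An all-zero matrix is an error.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    sens = ratio(cm.tp, cm.tp + cm.fn)
    spec = ratio(cm.tn, cm.tn + cm.fp)
    ppv = ratio(cm.tp, cm.tp + cm.fp)
    npv = ratio(cm.tn, cm.tn + cm.fn)
    acc = (cm.tp + cm.tn) / cm.total
    f1 = (2 * ppv * sens / (ppv + sens)
          if ppv is not None and sens is not None and (ppv + sens) > 0
          else None)
    return {"accuracy": acc, "f1": f1, "sensitivity": sens,
            "specificity": spec, "ppv": ppv, "npv": npv}


# ---------------------------------------------------------------------------
# patient-level categorisation
# ---------------------------------------------------------------------------

def patient_categorize(lesions: pd.DataFrame, score_threshold: float,
                       n_lesion_threshold: int = 4
                       ) -> tuple[pd.DataFrame, ConfusionMatrix]:
    """Chronic-active categorisation from per-lesion predictions.

    ``lesions`` needs columns ``patient_id``, ``score`` (rim+ probability)
    and ``label`` (1 for true rim+).  A patient is chronic active iff its
    rim+ lesion count (predicted resp. true) is >= ``n_lesion_threshold``.
    """
    required = {"patient_id", "score", "label"}
    if not required.issubset(lesions.columns):
        raise ValueError(f"lesion table needs columns {sorted(required)}")
    df = lesions.copy()
    df["pred"] = (df["score"] >= score_threshold).astype(int)
    per_patient = (df.groupby("patient_id")
                   .agg(pred_rim_pos=("pred", "sum"),
                        true_rim_pos=("label", "sum"))
                   .reset_index())
    per_patient["pred_active"] = (per_patient["pred_rim_pos"]
                                  >= n_lesion_threshold).astype(int)
    per_patient["true_active"] = (per_patient["true_rim_pos"]
                                  >= n_lesion_threshold).astype(int)
    cm = confusion_from_predictions(per_patient["true_active"],
                                    per_patient["pred_active"])
    return per_patient, cm


def patient_threshold_sweep(lesions: pd.DataFrame, score_threshold: float,
                            thresholds: Sequence[int] = range(1, 7)
                            ) -> dict[int, ConfusionMatrix]:
    """Patient-level confusion matrices for lesion-count thresholds 1..6."""
    return {t: patient_categorize(lesions, score_threshold, t)[1]
            for t in thresholds}


# ---------------------------------------------------------------------------
# anatomical-location analysis
# ---------------------------------------------------------------------------

def _ball(radius_vox: int) -> np.ndarray:
    if radius_vox <= 0:
        return np.ones((1, 1, 1), dtype=bool)
    r = radius_vox
    zz, yy, xx = np.ogrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return zz ** 2 + yy ** 2 + xx ** 2 <= r ** 2


REGION_DILATION_MM = {"cortex": 2.0, "ventricles": 3.0}
#: precedence after the any-overlap periventricular rule
_HALF_OVERLAP_ORDER = ("cortex", "deep_gray", "brainstem", "cerebellum")
_REGION_NAMES = {"ventricles": "periventricular", "cortex": "juxtacortical",
                 "deep_gray": "deep_gray", "brainstem": "brainstem",
                 "cerebellum": "cerebellum"}
DEEP_WM = "deep_white_matter"


def prepare_region_masks(region_masks: Mapping[str, np.ndarray],
                         spacing_mm: float) -> dict[str, np.ndarray]:
    """Dilate cortex (2 mm) and ventricles (3 mm) with a spherical element
    of radius ``round(mm / spacing)`` voxels."""
    out = {}
    for name, mask in region_masks.items():
        mask = np.asarray(mask).astype(bool)
        if name in REGION_DILATION_MM:
            r = round(REGION_DILATION_MM[name] / spacing_mm)
            mask = ndimage.binary_dilation(mask, structure=_ball(r))
        out[name] = mask
    return out


def assign_region(candidate: LesionCandidate,
                  prepared_masks: Mapping[str, np.ndarray]) -> str:
    """Assign one lesion to an exclusive anatomical region.

    Precedence: periventricular on any overlap with the (dilated)
    ventricles; then the first region of cortex / deep gray / brainstem /
    cerebellum covering >= 50% of the lesion's voxels; else deep WM.
    """
    vox = tuple(candidate.voxels.T)
    shape = next(iter(prepared_masks.values())).shape
    if np.any(candidate.voxels.max(axis=0) >= shape):
        raise ValueError(f"candidate {candidate.id} outside the region grid")
    if "ventricles" in prepared_masks and \
            prepared_masks["ventricles"][vox].any():
        return _REGION_NAMES["ventricles"]
    n = candidate.voxel_count
    for name in _HALF_OVERLAP_ORDER:
        if name in prepared_masks and \
                prepared_masks[name][vox].sum() >= 0.5 * n:
            return _REGION_NAMES[name]
    return DEEP_WM


def location_report(assignments: Sequence[str],
                    labels: Sequence[str]) -> pd.DataFrame:
    """Counts and within-class percentages per region per class."""
    if len(assignments) != len(labels):
        raise ValueError("one label per assignment required")
    df = pd.DataFrame({"region": assignments, "label": labels})
    counts = (df.groupby(["label", "region"]).size()
              .rename("count").reset_index())
    totals = counts.groupby("label")["count"].transform("sum")
    counts["percent"] = 100.0 * counts["count"] / totals
    return counts


# ---------------------------------------------------------------------------
# aggregate report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    curves: AveragedCurves
    operating_threshold: float
    achieved_specificity: float
    lesion_confusion: ConfusionMatrix
    lesion_metrics: dict[str, float | None]
    patient_confusions: dict[int, ConfusionMatrix]
    tests: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean_roc_auc": self.curves.mean_roc_auc,
            "mean_pr_auc": self.curves.mean_pr_auc,
            "pooled_roc_auc": self.curves.pooled_roc_auc,
            "per_fold_roc_auc": self.curves.roc_aucs,
            "per_fold_pr_auc": self.curves.pr_aucs,
            "operating_threshold": self.operating_threshold,
            "achieved_specificity": self.achieved_specificity,
            "lesion_confusion": vars(self.lesion_confusion),
            "lesion_metrics": self.lesion_metrics,
            "patient_confusions": {t: vars(c) for t, c
                                   in self.patient_confusions.items()},
            "tests": self.tests,
        }


def evaluate_folds(per_fold_scores: Sequence[np.ndarray],
                   per_fold_labels: Sequence[np.ndarray],
                   lesion_table: pd.DataFrame | None = None,
                   target_specificity: float = 0.95,
                   patient_thresholds: Sequence[int] = range(1, 7)
                   ) -> EvalReport:
    """Build the full lesion-level (and optionally patient-level) report."""
    curves = averaged_curves(per_fold_scores, per_fold_labels)
    scores = np.concatenate([np.asarray(s) for s in per_fold_scores])
    labels = np.concatenate([np.asarray(y) for y in per_fold_labels])
    thr, spec = operating_point(scores, labels, target_specificity)
    preds = (scores >= thr).astype(int)
    cm = confusion_from_predictions(labels, preds)
    pm = {}
    if lesion_table is not None:
        pm = patient_threshold_sweep(lesion_table, thr, patient_thresholds)
    return EvalReport(curves=curves, operating_threshold=thr,
                      achieved_specificity=spec, lesion_confusion=cm,
                      lesion_metrics=lesion_metrics(cm),
                      patient_confusions=pm)
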