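"""Fold construction, the training loop and ensemble inference.

Folds are patient-grouped (all lesions of a patient share its fold) and
per-site stratified: within each site, patients are assigned greedily —
sorted by rim+ lesion count descending (longest-processing-time order) and
placed into the currently least-loaded fold, ties broken by rim- load and
then fold index.  The training loop uses Adam with a four-step learning-
rate ladder (1e-4, 5e-5, 2.5e-5, 1e-5): after ``patience`` consecutive
epochs without a new validation-loss minimum the next rate is engaged, and
a decay triggered past the last rate stops training.  A three-fold inner
cross-validation can convert that adaptive schedule into fixed per-rate
epoch budgets for retraining on a full outer-training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .augment import online_augment
from .model import ArchConfig, _Network, build_network, stack_patches
from .patches import Patch
from . import nn

RIM_POS = "rim+"


@dataclass
class PatientInfo:
    patient_id: str
    site_id: str
    n_rim_pos: int
    n_rim_neg: int


@dataclass
class FoldSplit:
    n_folds: int
    assignment: dict[str, int]          # patient_id -> fold index
    table: pd.DataFrame                 # per fold/site/class lesion counts

    def patients_in_fold(self, fold: int) -> list[str]:
        return [p for p, f in self.assignment.items() if f == fold]


@dataclass
class TrainConfig:
    learning_rates: tuple[float, ...] = (1.0e-4, 5.0e-5, 2.5e-5, 1.0e-5)
    patience: int = 3
    batch_size: int = 32
    max_epochs: int = 100
    inner_folds: int = 3
    online_augmentation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        rates = tuple(self.learning_rates)
        if any(rates[i + 1] >= rates[i] for i in range(len(rates) - 1)):
            raise ValueError("learning_rates must be strictly decreasing")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def make_folds(patients: Sequence[PatientInfo], n_folds: int = 4,
               seed: int = 0) -> FoldSplit:
    """Greedy balanced patient-to-fold assignment, stratified per site."""
    by_site: dict[str, list[PatientInfo]] = {}
    for p in patients:
        by_site.setdefault(p.site_id, []).append(p)
    for site, plist in by_site.items():
        if len(plist) < n_folds:
            raise ValueError(
                f"site {site} has {len(plist)} patients; "
                f"need at least {n_folds}")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for site in sorted(by_site):
        plist = list(by_site[site])
        rng.shuffle(plist)                      # seed-ordered tie-breaking
        plist.sort(key=lambda p: (-p.n_rim_pos, -p.n_rim_neg))
        load_pos = [0] * n_folds
        load_neg = [0] * n_folds
        load_n = [0] * n_folds
        for p in plist:
            fold = min(range(n_folds),
                       key=lambda f: (load_pos[f], load_neg[f],
                                      load_n[f], f))
            assignment[p.patient_id] = fold
            load_pos[fold] += p.n_rim_pos
            load_neg[fold] += p.n_rim_neg
            load_n[fold] += 1
    rows = []
    for p in patients:
        rows.append({"fold": assignment[p.patient_id], "site": p.site_id,
                     "patient_id": p.patient_id,
                     "n_rim_pos": p.n_rim_pos, "n_rim_neg": p.n_rim_neg})
    table = (pd.DataFrame(rows)
             .groupby(["fold", "site"])
             .agg(n_patients=("patient_id", "count"),
                  rim_pos=("n_rim_pos", "sum"),
                  rim_neg=("n_rim_neg", "sum"))
             .reset_index())
    return FoldSplit(n_folds=n_folds, assignment=assignment, table=table)


class LRScheduler:
    """Learning-rate ladder with patience-based decay and early stop.

    An epoch counts as an improvement only when its validation loss is
    strictly below the best loss seen so far; the very first epoch
    establishes the baseline and is not an improvement.  After ``patience``
    consecutive non-improving epochs the next rate is engaged; a decay
    triggered while already on the last rate stops training.  With a
    never-improving loss sequence training therefore stops after exactly
    ``len(rates) * patience`` epochs.
    """

    def __init__(self, rates: Sequence[float], patience: int):
        self.rates = list(rates)
        self.patience = patience
        self.rate_idx = 0
        self.best: float | None = None
        self.bad_epochs = 0
        self.stopped = False
        self.epochs_per_rate = [0] * len(self.rates)

    @property
    def lr(self) -> float:
        return self.rates[self.rate_idx]

    def step(self, val_loss: float) -> bool:
        """Register one epoch's validation loss; returns True to continue."""
        if self.stopped:
            raise RuntimeError("scheduler already stopped")
        self.epochs_per_rate[self.rate_idx] += 1
        if self.best is not None and val_loss < self.best:
            self.best = val_loss
            self.bad_epochs = 0
        else:
            if self.best is None:
                self.best = val_loss
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.bad_epochs = 0
                if self.rate_idx + 1 < len(self.rates):
                    self.rate_idx += 1
                else:
                    self.stopped = True
        return not self.stopped


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    epochs_per_rate: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(1, len(self.train_loss) + 1),
                             "train_loss": self.train_loss,
                             "val_loss": self.val_loss, "lr": self.lr})


def _labels(patches: Sequence[Patch]) -> np.ndarray:
    return np.array([1 if p.label == RIM_POS else 0 for p in patches])


def _check_two_classes(y: np.ndarray, what: str) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError(f"{what} data contains a single class")


def train_model(train_patches: Sequence[Patch],
                val_patches: Sequence[Patch] | None,
                arch: ArchConfig, config: TrainConfig,
                seed: int = 0,
                epoch_budget: Sequence[int] | None = None
                ) -> tuple[_Network, History]:
    """Train one network.

    With ``val_patches`` the learning-rate ladder is driven by the
    validation loss; with ``epoch_budget`` (per-rate epoch counts, e.g.
    from :func:`inner_cv_epochs`) the schedule is fixed and no validation
    set is needed.  Deterministic given ``seed`` and fixed BLAS settings,
    up to floating-point reduction order.
    """
    y_train = _labels(train_patches)
    _check_two_classes(y_train, "training")
    if val_patches is None and epoch_budget is None:
        raise ValueError("need either a validation set or an epoch budget")

    rng = np.random.default_rng(seed)
    net = build_network(arch, seed=int(rng.integers(2 ** 31)))
    xs_train = stack_patches(list(train_patches), arch.modalities)
    # materialise the lazily built head before the optimiser snapshots params
    net.forward([x[:1] for x in xs_train], training=False)
    opt = nn.Adam(net.parameters(), lr=config.learning_rates[0])
    sched = LRScheduler(config.learning_rates, config.patience)
    history = History()

    if val_patches is not None:
        y_val = _labels(val_patches)
        _check_two_classes(y_val, "validation")
        xs_val = stack_patches(list(val_patches), arch.modalities)

    if epoch_budget is not None:
        schedule = [(config.learning_rates[i], int(n))
                    for i, n in enumerate(epoch_budget) if n > 0]
        plan = [lr for lr, n in schedule for _ in range(n)]
    else:
        plan = None

    n = len(train_patches)
    epoch = 0
    while True:
        if plan is not None:
            if epoch >= len(plan):
                break
            lr = plan[epoch]
        else:
            lr = sched.lr
        if epoch >= config.max_epochs:
            break
        opt.lr = lr
        order = rng.permutation(n)
        losses = []
        for i0 in range(0, n, config.batch_size):
            idx = order[i0:i0 + config.batch_size]
            batch = [train_patches[i] for i in idx]
            if config.online_augmentation:
                batch = [online_augment(p, rng) for p in batch]
            xb = stack_patches(batch, arch.modalities)
            yb = y_train[idx]
            logits = net.forward(xb, training=True)
            loss, dlogits, _ = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch "
                    f"{epoch + 1}")
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)))
        history.lr.append(lr)
        epoch += 1
        if plan is not None:
            history.val_loss.append(np.nan)
            continue
        val_probs = net.predict_proba(xs_val)
        vloss = float(-np.mean(np.log(
            val_probs[np.arange(len(y_val)), y_val] + 1e-12)))
        history.val_loss.append(vloss)
        if not sched.step(vloss):
            break
    history.epochs_per_rate = (list(sched.epochs_per_rate)
                               if plan is None else
                               [int(n) for n in (epoch_budget or [])])
    return net, history


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def inner_cv_epochs(train_patches: Sequence[Patch], arch: ArchConfig,
                    config: TrainConfig, seed: int = 0) -> list[int]:
    """Per-rate epoch budgets from a 3-fold inner cross-validation.

    Patients of the outer-training set are split into ``config.inner_folds``
    patient-grouped folds; each inner split trains with the adaptive ladder
    and the per-rate epoch counts are averaged (rounded half-up, minimum 1)
    across the inner folds.
    """
    stats: dict[str, dict] = {}
    for p in train_patches:
        s = stats.setdefault(p.patient_id, {"site": p.site_id,
                                            "pos": 0, "neg": 0})
        s["pos" if p.label == RIM_POS else "neg"] += 1
    infos = [PatientInfo(pid, s["site"], s["pos"], s["neg"])
             for pid, s in stats.items()]
    split = make_folds(infos, n_folds=config.inner_folds, seed=seed)
    budgets = []
    for k in range(config.inner_folds):
        val_p = {p for p in split.assignment if split.assignment[p] == k}
        tr = [p for p in train_patches if p.patient_id not in val_p]
        va = [p for p in train_patches if p.patient_id in val_p]
        _, hist = train_model(tr, va, arch, config, seed=seed + k)
        budgets.append(hist.epochs_per_rate)
    arr = np.array(budgets, dtype=float)
    return [max(1, _round_half_up(v)) for v in arr.mean(axis=0)]


def predict_rim_probability(net: _Network, patches: Sequence[Patch]
                            ) -> np.ndarray:
    xs = stack_patches(list(patches), net.config.modalities)
    return net.predict_proba(xs)[:, 1]


def ensemble_predict(models: Sequence[_Network],
                     patches: Sequence[Patch]) -> np.ndarray:
    """Arithmetic mean of per-model rim+ probabilities."""
    if not models:
        raise ValueError("ensemble needs at least one model")
    fps = {m.config.fingerprint() for m in models}
    if len(fps) != 1:
        raise ValueError("ensemble members have mismatched architectures")
    probs = [predict_rim_probability(m, patches) for m in models]
    return np.mean(probs, axis=0)
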