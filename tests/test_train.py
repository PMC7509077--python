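"""Fold construction, LR-ladder scheduler, training loop, ensembling."""

import itertools

import numpy as np
import pytest

import rimpipe as rp
from rimpipe.patches import Patch
from rimpipe.train import LRScheduler, PatientInfo


def _patients(spec):
    """spec: list of (pid, site, n_pos, n_neg)."""
    return [PatientInfo(p, s, a, b) for p, s, a, b in spec]


class TestMakeFolds:
    def test_one_patient_per_fold(self):
        pats = _patients([(f"p{i}", "s", 1, 5) for i in range(4)])
        split = rp.make_folds(pats, n_folds=4, seed=0)
        assert sorted(split.assignment.values()) == [0, 1, 2, 3]

    def test_perfect_balance_attainable(self):
        pats = _patients([(f"p{i}", "s", 1, 0) for i in range(8)])
        split = rp.make_folds(pats, n_folds=4, seed=1)
        loads = [0] * 4
        for p in pats:
            loads[split.assignment[p.patient_id]] += p.n_rim_pos
        assert loads == [2, 2, 2, 2]

    def test_every_patient_in_exactly_one_fold(self):
        rng = np.random.default_rng(3)
        pats = _patients([(f"p{i}", "AB"[i % 2], int(rng.integers(0, 9)),
                           int(rng.integers(0, 40))) for i in range(30)])
        split = rp.make_folds(pats, n_folds=4, seed=2)
        assert set(split.assignment) == {p.patient_id for p in pats}
        assert set(split.assignment.values()) <= {0, 1, 2, 3}

    def test_greedy_close_to_enumerated_optimum(self):
        """On instances small enough to enumerate, the greedy spread of
        rim+ counts is within the largest single-patient load of the
        exhaustive optimum."""
        rng = np.random.default_rng(7)
        for trial in range(3):
            loads_p = [int(rng.integers(0, 8)) for _ in range(8)]
            pats = _patients([(f"p{i}", "s", lp, 0)
                              for i, lp in enumerate(loads_p)])
            split = rp.make_folds(pats, n_folds=4, seed=trial)
            fold_loads = [0] * 4
            for p in pats:
                fold_loads[split.assignment[p.patient_id]] += p.n_rim_pos
            greedy_spread = max(fold_loads) - min(fold_loads)
            best = None
            for assign in itertools.product(range(4), repeat=8):
                fl = [0] * 4
                for a, lp in zip(assign, loads_p):
                    fl[a] += lp
                spread = max(fl) - min(fl)
                best = spread if best is None else min(best, spread)
            assert greedy_spread <= best + max(loads_p)

    def test_too_few_patients_raises(self):
        pats = _patients([("p0", "s", 1, 1), ("p1", "s", 1, 1)])
        with pytest.raises(ValueError, match="patients"):
            rp.make_folds(pats, n_folds=4)

    def test_deterministic_given_seed(self):
        pats = _patients([(f"p{i}", "s", 2, 2) for i in range(12)])
        a = rp.make_folds(pats, n_folds=4, seed=5).assignment
        b = rp.make_folds(pats, n_folds=4, seed=5).assignment
        assert a == b


class TestScheduler:
    def test_first_decay_after_patience_non_improving_epochs(self):
        """Losses [1.0, .9, .9, .9, .9]: the epoch-2 minimum resets the
        counter, so the first decay fires at epoch 5."""
        s = LRScheduler([1e-4, 5e-5, 2.5e-5, 1e-5], patience=3)
        decay_epoch = None
        for epoch, loss in enumerate([1.0, 0.9, 0.9, 0.9, 0.9, 0.9],
                                     start=1):
            before = s.rate_idx
            s.step(loss)
            if s.rate_idx != before and decay_epoch is None:
                decay_epoch = epoch
        assert decay_epoch == 5

    def test_never_improving_stops_after_rates_times_patience(self):
        s = LRScheduler([1, 2, 3, 4][::-1], patience=3)
        epochs = 0
        while True:
            epochs += 1
            if not s.step(1.0):
                break
        assert epochs == 4 * 3
        assert s.epochs_per_rate == [3, 3, 3, 3]

    def test_improvement_resets_counter(self):
        s = LRScheduler([1e-4, 5e-5], patience=2)
        for loss in [1.0, 0.9, 0.95, 0.8, 0.85, 0.9]:
            assert s.step(loss)
        # epochs 5,6 are the only consecutive non-improvements -> decayed once
        assert s.rate_idx == 1
        assert not s.stopped

    def test_config_validation(self):
        with pytest.raises(ValueError):
            rp.TrainConfig(learning_rates=(1e-4, 1e-4))
        with pytest.raises(ValueError):
            rp.TrainConfig(patience=0)


def _toy_patches(n_pos=12, n_neg=12, size=8, sep=2.0, seed=0,
                 n_patients=6):
    """Linearly separable two-modality toy patches: positives carry a
    bright blob on the phase channel."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_pos + n_neg):
        pos = i < n_pos
        phase = rng.normal(0, 0.1, (size,) * 3)
        flair = rng.normal(0, 0.1, (size,) * 3)
        if pos:
            phase[2:6, 2:6, 2:6] -= sep
        data = {"phase": np.clip(phase, -1, 1).astype(np.float32),
                "flair": np.clip(flair, -1, 1).astype(np.float32)}
        out.append(Patch(data=data, label="rim+" if pos else "rim-",
                         candidate_id=i,
                         patient_id=f"p{i % n_patients}", site_id="s"))
    return out


SMALL_ARCH = rp.ArchConfig(modalities=("phase", "flair"), filters=(2, 3, 4),
                           fc_widths=(8,))


class TestTrainModel:
    def test_learns_separable_task(self):
        patches = _toy_patches()
        # a faster ladder than the production default: the toy task is
        # tiny, so convergence within the test budget needs a larger step
        cfg = rp.TrainConfig(learning_rates=(1e-2, 5e-3, 2.5e-3, 1e-3),
                             max_epochs=10, batch_size=8,
                             online_augmentation=False)
        net, hist = rp.train_model(patches, None, SMALL_ARCH, cfg, seed=0,
                                   epoch_budget=[10, 0, 0, 0])
        assert hist.train_loss[-1] < hist.train_loss[0]
        probs = rp.predict_rim_probability(net, patches)
        labels = np.array([p.label == "rim+" for p in patches])
        acc = np.mean((probs >= 0.5) == labels)
        assert acc >= 0.95

    def test_single_class_rejected(self):
        patches = _toy_patches(n_pos=0, n_neg=8)
        with pytest.raises(ValueError, match="single class"):
            rp.train_model(patches, None, SMALL_ARCH, rp.TrainConfig(),
                           epoch_budget=[1])

    def test_validation_driven_ladder_records_history(self):
        patches = _toy_patches(n_pos=10, n_neg=10)
        cfg = rp.TrainConfig(max_epochs=3, batch_size=8,
                             online_augmentation=False)
        train = patches[:8] + patches[12:]      # both classes on each side
        val = patches[8:12]
        net, hist = rp.train_model(train, val, SMALL_ARCH, cfg, seed=1)
        assert len(hist.train_loss) == len(hist.val_loss) == len(hist.lr)
        assert all(lr in cfg.learning_rates for lr in hist.lr)

    def test_deterministic_given_seed(self):
        patches = _toy_patches(n_pos=6, n_neg=6)
        cfg = rp.TrainConfig(max_epochs=2, batch_size=8,
                             online_augmentation=True)
        n1, h1 = rp.train_model(patches, None, SMALL_ARCH, cfg, seed=3,
                                epoch_budget=[2])
        n2, h2 = rp.train_model(patches, None, SMALL_ARCH, cfg, seed=3,
                                epoch_budget=[2])
        assert h1.train_loss == h2.train_loss
        p1 = rp.predict_rim_probability(n1, patches)
        p2 = rp.predict_rim_probability(n2, patches)
        assert np.array_equal(p1, p2)


class TestInnerCV:
    def test_budgets_positive_and_deterministic(self):
        patches = _toy_patches(n_pos=12, n_neg=12, n_patients=6)
        cfg = rp.TrainConfig(max_epochs=3, batch_size=8, inner_folds=3,
                             online_augmentation=False)
        b1 = rp.inner_cv_epochs(patches, SMALL_ARCH, cfg, seed=2)
        b2 = rp.inner_cv_epochs(patches, SMALL_ARCH, cfg, seed=2)
        assert b1 == b2
        assert all(isinstance(x, int) and x >= 1 for x in b1)
        assert len(b1) == len(cfg.learning_rates)


class TestEnsemble:
    def _trained(self, seed):
        patches = _toy_patches(n_pos=6, n_neg=6)
        cfg = rp.TrainConfig(max_epochs=1, batch_size=8,
                             online_augmentation=False)
        net, _ = rp.train_model(patches, None, SMALL_ARCH, cfg, seed=seed,
                                epoch_budget=[1])
        return net, patches

    def test_single_model_identity(self):
        net, patches = self._trained(0)
        solo = rp.predict_rim_probability(net, patches)
        ens = rp.ensemble_predict([net], patches)
        assert np.allclose(ens, solo)

    def test_mean_of_two_models(self):
        n1, patches = self._trained(0)
        n2, _ = self._trained(1)
        p1 = rp.predict_rim_probability(n1, patches)
        p2 = rp.predict_rim_probability(n2, patches)
        ens = rp.ensemble_predict([n1, n2], patches)
        assert np.allclose(ens, (p1 + p2) / 2)

    def test_identical_members_idempotent(self):
        net, patches = self._trained(0)
        solo = rp.predict_rim_probability(net, patches)
        ens = rp.ensemble_predict([net, net, net], patches)
        assert np.allclose(ens, solo)

    def test_architecture_mismatch_rejected(self):
        net, patches = self._trained(0)
        other_arch = rp.ArchConfig(modalities=("phase", "flair"),
                                   filters=(2, 3, 5), fc_widths=(8,))
        other = rp.build_rimnet(other_arch, seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            rp.ensemble_predict([net, other], patches)
        with pytest.raises(ValueError, match="at least one"):
            rp.ensemble_predict([], patches)
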