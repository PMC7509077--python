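"""Curves, DeLong, McNemar, operating points, patient- and region-level."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rimpipe as rp
from rimpipe.candidates import LesionCandidate
from conftest import brute_force_auc


class TestAveragedCurves:
    def test_perfect_separation_every_fold(self, rng):
        scores, labels = [], []
        for _ in range(4):
            y = np.array([0] * 10 + [1] * 5)
            s = np.concatenate([rng.uniform(0, 0.4, 10),
                                rng.uniform(0.6, 1.0, 5)])
            scores.append(s)
            labels.append(y)
        c = rp.averaged_curves(scores, labels)
        assert c.mean_roc_auc == 1.0
        assert np.all(c.mean_tpr[1:] == 1.0)

    def test_random_scores_near_half(self, rng):
        scores = [rng.random(400) for _ in range(4)]
        labels = [(rng.random(400) < 0.3).astype(int) for _ in range(4)]
        c = rp.averaged_curves(scores, labels)
        # SE of one fold's AUC is ~0.03; the 4-fold mean is tighter
        assert abs(c.mean_roc_auc - 0.5) < 0.05

    def test_mean_of_fold_aucs_not_auc_of_mean(self):
        """Folds constructed to have pairwise AUCs 0.8 and 0.9 (verified
        against the Mann-Whitney oracle) must report exactly 0.85."""
        # fold 1: 0.8 -> 16/20 concordant pairs (one negative outscores
        # all four positives)
        s1 = np.array([1, 2, 3, 4, 8.5, 5, 6, 7, 8])
        y1 = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1])
        # fold 2: 0.9 -> 18/20 concordant
        s2 = np.array([1, 2, 3, 4, 6.5, 5, 6, 7, 8])
        y2 = y1
        assert brute_force_auc(s1, y1) == pytest.approx(0.8)
        assert brute_force_auc(s2, y2) == pytest.approx(0.9)
        c = rp.averaged_curves([s1, s2], [y1, y2])
        assert c.mean_roc_auc == pytest.approx(0.85)

    def test_per_fold_auc_equals_brute_force(self, rng):
        scores = [rng.random(60) for _ in range(3)]
        labels = [(rng.random(60) < 0.4).astype(int) for _ in range(3)]
        c = rp.averaged_curves(scores, labels)
        for auc, s, y in zip(c.roc_aucs, scores, labels):
            assert auc == pytest.approx(brute_force_auc(s, y))

    def test_single_class_fold_names_the_fold(self):
        with pytest.raises(ValueError, match="fold 1"):
            rp.averaged_curves(
                [np.array([0.1, 0.9]), np.array([0.2, 0.3])],
                [np.array([0, 1]), np.array([0, 0])])


class TestDeLong:
    def test_identical_scores_give_p_one(self, rng):
        s = rng.random(40)
        y = (rng.random(40) < 0.5).astype(int)
        a1, a2, p = rp.delong_test(s, s, y)
        assert a1 == a2
        assert p == 1.0

    def test_auc_equals_mann_whitney(self, rng):
        s = rng.random(50)
        y = (rng.random(50) < 0.4).astype(int)
        a1, _, _ = rp.delong_test(s, rng.random(50), y)
        assert a1 == pytest.approx(brute_force_auc(s, y))

    def test_symmetry(self, rng):
        sa, sb = rng.random(60), rng.random(60)
        y = (rng.random(60) < 0.5).astype(int)
        a1, b1, p1 = rp.delong_test(sa, sb, y)
        b2, a2, p2 = rp.delong_test(sb, sa, y)
        assert (a1, b1) == (a2, b2)
        assert p1 == pytest.approx(p2)

    def test_matches_stratified_bootstrap(self):
        """DeLong p-value within Monte-Carlo tolerance of a 10,000-resample
        stratified bootstrap on a seeded 60-case instance."""
        rng = np.random.default_rng(60)
        n = 60
        y = np.array([0] * 40 + [1] * 20)
        base = rng.normal(size=n)
        sa = base + y * 1.0 + rng.normal(0, 0.8, n)
        sb = base + y * 0.5 + rng.normal(0, 0.8, n)
        auc_a, auc_b, p = rp.delong_test(sa, sb, y)
        obs = auc_a - auc_b
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        B = 10_000
        diffs = np.empty(B)
        for i in range(B):
            idx = np.concatenate([rng.choice(pos, len(pos)),
                                  rng.choice(neg, len(neg))])
            yy = y[idx]
            diffs[i] = (brute_auc_fast(sa[idx], yy)
                        - brute_auc_fast(sb[idx], yy))
        # normal-approximation bootstrap test of H0: diff = 0
        se = diffs.std(ddof=1)
        p_boot = 2 * stats.norm.sf(abs(obs) / se)
        assert p == pytest.approx(p_boot, abs=0.1)

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            rp.delong_test(np.zeros(5), np.zeros(6),
                           np.array([0, 1, 0, 1, 0, 1]))


def brute_auc_fast(s, y):
    pos = s[y == 1]
    neg = s[y == 0]
    diff = pos[:, None] - neg[None, :]
    return ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size


class TestMcNemar:
    def test_no_discordance_gives_p_one(self):
        stat, p = rp.mcnemar_test(0, 0)
        assert p == 1.0

    def test_equal_discordance_statistic(self):
        stat, p = rp.mcnemar_test(5, 5)
        assert stat == pytest.approx(0.1)
        assert p == pytest.approx(stats.chi2.sf(0.1, 1))

    def test_closed_form_example(self):
        stat, p = rp.mcnemar_test(15, 3)
        assert stat == pytest.approx(121 / 18)
        assert p == pytest.approx(stats.chi2.sf(121 / 18, 1))

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mc
        for b, c in [(5, 5), (15, 3), (2, 9), (1, 0)]:
            stat, p = rp.mcnemar_test(b, c)
            res = sm_mc([[0, b], [c, 0]], exact=False, correction=True)
            assert stat == pytest.approx(res.statistic)
            assert p == pytest.approx(res.pvalue)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            rp.mcnemar_test(-1, 2)


class TestOperatingPoint:
    def test_separable_scores(self):
        s = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        y = np.array([0, 0, 0, 1, 1])
        t, spec = rp.operating_point(s, y, 0.95)
        assert 0.3 < t <= 0.8
        assert spec == 1.0

    def test_order_statistic_count(self):
        """20 negatives scored 1..20: threshold 20 leaves exactly 19 below
        it, specificity 0.95."""
        s = np.concatenate([np.arange(1, 21), [25.0]])
        y = np.array([0] * 20 + [1])
        t, spec = rp.operating_point(s, y, 0.95)
        assert t == 20.0
        assert spec == 0.95

    def test_monotone_in_target(self, rng):
        s = rng.random(100)
        y = (rng.random(100) < 0.3).astype(int)
        prev = -np.inf
        for target in (0.5, 0.8, 0.9, 0.95, 0.99):
            t, _ = rp.operating_point(s, y, target)
            assert t >= prev
            prev = t


class TestLesionMetrics:
    def test_perfect_matrix(self):
        m = rp.lesion_metrics(rp.ConfusionMatrix(tp=5, fp=0, fn=0, tn=20))
        for k in ("accuracy", "f1", "sensitivity", "specificity",
                  "ppv", "npv"):
            assert m[k] == 1.0

    def test_direct_arithmetic(self):
        m = rp.lesion_metrics(rp.ConfusionMatrix(tp=7, fp=3, fn=3, tn=87))
        assert m["sensitivity"] == pytest.approx(0.70)
        assert m["specificity"] == pytest.approx(0.9667, abs=1e-4)
        assert m["ppv"] == pytest.approx(0.70)
        assert m["npv"] == pytest.approx(0.9667, abs=1e-4)

    def test_undefined_ratio_is_absent_not_zero(self):
        m = rp.lesion_metrics(rp.ConfusionMatrix(tp=0, fp=0, fn=4, tn=10))
        assert m["sensitivity"] == 0.0
        assert m["ppv"] is None

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            rp.lesion_metrics(rp.ConfusionMatrix(0, 0, 0, 0))


class TestPatientCategorize:
    def _table(self, counts_pred, counts_true):
        rows = []
        for pid, (np_, nt) in enumerate(zip(counts_pred, counts_true)):
            n = max(np_, nt, 1) + 2
            for i in range(n):
                rows.append({"patient_id": f"p{pid}",
                             "score": 1.0 if i < np_ else 0.0,
                             "label": 1 if i < nt else 0})
        return pd.DataFrame(rows)

    def test_zero_predictions_never_active(self):
        df = self._table([0], [0])
        for t in range(1, 7):
            per, cm = rp.patient_categorize(df, 0.5, t)
            assert per["pred_active"].iloc[0] == 0

    def test_boundary_inclusive_at_threshold(self):
        df = self._table([3, 4, 5], [3, 4, 5])
        per, cm = rp.patient_categorize(df, 0.5, 4)
        got = dict(zip(per["patient_id"], per["pred_active"]))
        assert got == {"p0": 0, "p1": 1, "p2": 1}

    def test_confusion_matches_recount(self, rng):
        pred = rng.integers(0, 8, 12)
        true = rng.integers(0, 8, 12)
        df = self._table(pred, true)
        _, cm = rp.patient_categorize(df, 0.5, 4)
        tp = int(np.sum((pred >= 4) & (true >= 4)))
        fp = int(np.sum((pred >= 4) & (true < 4)))
        fn = int(np.sum((pred < 4) & (true >= 4)))
        tn = int(np.sum((pred < 4) & (true < 4)))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)

    def test_monotone_in_threshold(self, rng):
        pred = rng.integers(0, 10, 15)
        df = self._table(pred, pred)
        prev = None
        for t in range(1, 7):
            per, _ = rp.patient_categorize(df, 0.5, t)
            n_active = int(per["pred_active"].sum())
            if prev is not None:
                assert n_active <= prev
            prev = n_active


class TestRegions:
    def _cand(self, voxels, cid=1):
        vox = np.asarray(voxels)
        return LesionCandidate(id=cid, voxels=vox, voxel_count=len(vox),
                               volume_mm3=float(len(vox)),
                               center_of_mass=vox.mean(axis=0))

    def _masks(self):
        shape = (40, 40, 40)
        vent = np.zeros(shape, bool)
        vent[18:22, 18:22, 18:22] = True
        cortex = np.zeros(shape, bool)
        cortex[0:3, :, :] = True
        return {"ventricles": vent, "cortex": cortex}

    def test_any_ventricle_overlap_is_periventricular(self):
        prepared = rp.prepare_region_masks(self._masks(), spacing_mm=1.0)
        # voxel 3 mm away from the ventricle box: inside the dilation
        c = self._cand([(15, 20, 20), (14, 20, 20), (13, 20, 20)])
        assert rp.assign_region(c, prepared) == "periventricular"

    def test_forty_percent_cortex_overlap_is_deep_wm(self):
        prepared = rp.prepare_region_masks(self._masks(), spacing_mm=1.0)
        # 2 of 5 voxels inside the dilated cortex (rows 0-4), no ventricle
        c = self._cand([(4, 30, 30), (5, 30, 30), (8, 30, 30),
                        (9, 30, 30), (10, 30, 30)])
        assert rp.assign_region(c, prepared) == "deep_white_matter"

    def test_half_overlap_is_juxtacortical(self):
        prepared = rp.prepare_region_masks(self._masks(), spacing_mm=1.0)
        c = self._cand([(4, 30, 30), (3, 30, 30), (8, 30, 30),
                        (9, 30, 30)])
        assert rp.assign_region(c, prepared) == "juxtacortical"

    def test_assignments_match_overlap_oracle(self, rng):
        prepared = rp.prepare_region_masks(self._masks(), spacing_mm=1.0)
        for _ in range(20):
            base = rng.integers(3, 36, 3)
            vox = np.clip(base + rng.integers(-2, 3, (6, 3)), 0, 39)
            c = self._cand(np.unique(vox, axis=0))
            got = rp.assign_region(c, prepared)
            idx = tuple(c.voxels.T)
            if prepared["ventricles"][idx].any():
                expect = "periventricular"
            elif prepared["cortex"][idx].sum() >= 0.5 * c.voxel_count:
                expect = "juxtacortical"
            else:
                expect = "deep_white_matter"
            assert got == expect

    def test_dilation_radii(self):
        masks = {"ventricles": np.zeros((20, 20, 20), bool),
                 "cortex": np.zeros((20, 20, 20), bool)}
        masks["ventricles"][10, 10, 10] = True
        masks["cortex"][10, 10, 10] = True
        prep = rp.prepare_region_masks(masks, spacing_mm=1.0)
        assert prep["ventricles"][13, 10, 10]          # 3 mm
        assert not prep["ventricles"][14, 10, 10]
        assert prep["cortex"][12, 10, 10]              # 2 mm
        assert not prep["cortex"][13, 10, 10]


class TestLocationReport:
    def test_published_style_percentages(self):
        """225 periventricular rim+ of 389 -> 57.8%."""
        assignments = (["periventricular"] * 225 + ["juxtacortical"] * 65
                       + ["deep_white_matter"] * 99)
        labels = ["rim+"] * 389
        rep = rp.location_report(assignments, labels)
        peri = rep[(rep["label"] == "rim+")
                   & (rep["region"] == "periventricular")]
        assert peri["percent"].iloc[0] == pytest.approx(57.8, abs=0.05)

    def test_single_region_is_hundred_percent(self):
        rep = rp.location_report(["deep_white_matter"] * 5, ["rim-"] * 5)
        assert rep["percent"].iloc[0] == 100.0

    def test_percentages_sum_to_hundred_per_class(self, rng):
        regions = ["periventricular", "juxtacortical", "deep_white_matter"]
        assignments = [regions[i] for i in rng.integers(0, 3, 200)]
        labels = ["rim+" if x < 0.3 else "rim-" for x in rng.random(200)]
        rep = rp.location_report(assignments, labels)
        sums = rep.groupby("label")["percent"].sum()
        assert np.allclose(sums, 100.0, atol=0.1)
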