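"""ROC/AUC machinery against brute-force oracles, folds, and threshold metrics."""

import numpy as np
import pytest

import connectocam as cc
from connectocam.errors import ConfigurationError, DataError
from connectocam.evaluation import TrialRecord, select_best_trial


# ---------------------------------------------------------------------------
# Independent oracles, coded from the definitions
# ---------------------------------------------------------------------------

def auc_by_pair_counting(scores, labels):
    """P(random positive > random negative), ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def delong_brute_force(a, b, labels):
    """Placement-value variance of the paired AUC difference, by definition."""
    a, b, labels = map(np.asarray, (a, b, labels))
    pos, neg = labels == 1, labels == 0
    out = {}
    for name, s in (("a", a), ("b", b)):
        v10 = np.array([np.mean([1.0 if p > n else 0.5 if p == n else 0.0
                                 for n in s[neg]]) for p in s[pos]])
        v01 = np.array([np.mean([1.0 if p > n else 0.5 if p == n else 0.0
                                 for p in s[pos]]) for n in s[neg]])
        out[name] = (v10, v01)
    (a10, a01), (b10, b01) = out["a"], out["b"]
    m, n = a10.size, a01.size
    var = (np.var(a10 - b10, ddof=1) / m) + (np.var(a01 - b01, ddof=1) / n)
    diff = a10.mean() - b10.mean()
    return diff, var


class TestAUC:
    def test_worked_example(self):
        auc, _ = cc.compute_auc([0.9, 0.8, 0.4, 0.3, 0.7], [1, 1, 1, 0, 0])
        assert auc == pytest.approx(5 / 6)

    def test_perfect_and_degenerate(self):
        assert cc.compute_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])[0] == 1.0
        assert cc.compute_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])[0] == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(4, 21)
            labels = np.zeros(n, dtype=int)
            labels[:max(1, int(n // 2))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid to force ties
            auc, _ = cc.compute_auc(scores, labels)
            assert auc == pytest.approx(auc_by_pair_counting(scores, labels))

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = rng.random(30)
            labels = (rng.random(30) < 0.5).astype(int)
            if labels.sum() in (0, 30):
                continue
            auc, (lo, hi) = cc.compute_auc(scores, labels)
            assert 0.0 <= lo <= auc <= hi <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            cc.compute_auc([0.1, 0.2], [1, 1])


class TestDeLong:
    def test_identical_scores(self):
        labels = [1, 1, 0, 0, 1]
        s = [0.9, 0.7, 0.2, 0.4, 0.6]
        res = cc.delong_paired_test(s, s, labels)
        assert res.difference == 0.0
        assert res.p_value == 1.0

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        labels = np.array([1] * 10 + [0] * 10)
        a, b = rng.random(20), rng.random(20)
        r1 = cc.delong_paired_test(a, b, labels)
        r2 = cc.delong_paired_test(b, a, labels)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_placement_brute_force(self):
        """Variance/covariance identical to the definition on n=8 toys."""
        rng = np.random.default_rng(11)
        from scipy import stats
        for _ in range(30):
            labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
            rng.shuffle(labels)
            a = np.round(rng.random(8), 1)
            b = np.round(rng.random(8), 1)
            diff, var = delong_brute_force(a, b, labels)
            res = cc.delong_paired_test(a, b, labels)
            assert res.difference == pytest.approx(diff, abs=1e-12)
            if var > 0:
                expect_z = diff / np.sqrt(var)
                assert res.z == pytest.approx(expect_z, abs=1e-12)
                assert res.p_value == pytest.approx(2 * stats.norm.sf(abs(expect_z)),
                                                    abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            cc.delong_paired_test([0.1], [0.2, 0.3], [1, 0])

    def test_type_one_error_rate(self):
        """Null rejection rate ~5% for correlated score pairs with equal AUC."""
        rng = np.random.default_rng(2024)
        n_rep, n = 2000, 60
        labels = np.array([1] * (n // 2) + [0] * (n // 2))
        rejections = 0
        for _ in range(n_rep):
            latent = rng.normal(size=n) + 0.8 * labels  # same signal for both
            a = latent + 0.6 * rng.normal(size=n)
            b = latent + 0.6 * rng.normal(size=n)
            if cc.delong_paired_test(a, b, labels).p_value < 0.05:
                rejections += 1
        rate = rejections / n_rep
        # binomial sd at p=0.05, n=2000 is ~0.49%; allow ~3 sd
        assert abs(rate - 0.05) < 0.015


class TestBonferroniAndConfusion:
    def test_bonferroni(self):
        assert cc.bonferroni_threshold(0.05, 10) == pytest.approx(0.005)
        assert cc.bonferroni_threshold(0.05, 1) == 0.05
        with pytest.raises(ConfigurationError):
            cc.bonferroni_threshold(0.05, 0)

    def test_five_categories_make_ten_pairs(self):
        from math import comb
        assert comb(5, 2) == 10

    def test_perfect_classifier(self):
        m = cc.confusion_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert (m.sensitivity, m.specificity, m.accuracy) == (1.0, 1.0, 1.0)
        assert m.percents() == {"sensitivity": 100, "specificity": 100,
                                "accuracy": 100}

    def test_all_below_cutoff(self):
        m = cc.confusion_metrics([0.4] * 6, [1, 1, 1, 0, 0, 0])
        assert m.sensitivity == 0.0 and m.specificity == 1.0

    def test_integer_percent_rendering(self):
        """89 of 115 patients above cutoff renders as sensitivity 77%."""
        scores = [0.9] * 89 + [0.1] * 26 + [0.2] * 115
        labels = [1] * 115 + [0] * 115
        m = cc.confusion_metrics(scores, labels)
        assert m.tp == 89 and m.tp + m.fn == 115
        assert m.percents()["sensitivity"] == 77


class TestFoldsAndSelection:
    def test_fold_partition(self, small_cohort):
        cfg = cc.CVConfig(n_folds=3, seed=4)
        folds = cc.make_folds(small_cohort, cfg)
        all_idx = np.sort(np.concatenate(folds))
        assert np.array_equal(all_idx, np.arange(12))
        labels = small_cohort.labels()
        for f in folds:
            assert 0 < labels[f].mean() < 1  # stratified: both classes present

    def test_fold_sizes_near_equal(self, small_cohort):
        folds = cc.make_folds(small_cohort, cc.CVConfig(n_folds=5, seed=1))
        sizes = sorted(len(f) for f in folds)
        assert sizes[-1] - sizes[0] <= 1

    def test_same_seed_same_partition(self, small_cohort):
        cfg = cc.CVConfig(n_folds=4, seed=9)
        a = cc.make_folds(small_cohort, cfg)
        b = cc.make_folds(small_cohort, cfg)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa, fb)

    def test_too_few_subjects_rejected(self, small_cohort):
        with pytest.raises(DataError):
            cc.make_folds(small_cohort, cc.CVConfig(n_folds=13))

    def test_trial_selection_rules(self):
        trials = [
            TrialRecord(0, None, np.zeros(1), 0.7, 0.30),
            TrialRecord(1, None, np.zeros(1), 0.9, 0.50),
            TrialRecord(2, None, np.zeros(1), 0.9, 0.10),
        ]
        assert select_best_trial(trials, "val_auc").trial == 1  # tie -> earliest
        assert select_best_trial(trials, "train_loss").trial == 2


class TestCrossValidation:
    def test_every_subject_scored_once_and_auc_high(self, small_cohort):
        arch = cc.ArchitectureSpec(conv_channels=(4, 8), fc_units=(32, 2))
        cfg = cc.TrainConfig(learning_rate=0.02, epochs=40, noise_sds=(), seed=0)
        cv = cc.CVConfig(n_folds=3, n_trials=2, seed=5)
        res = cc.run_cross_validation(small_cohort, "NOS", arch, cfg, cv)
        ids = [sid for sid, _, _ in res.per_subject]
        assert sorted(ids) == sorted(small_cohort.subject_ids)
        assert len(res.per_fold_auc) == 3
        assert 0.0 <= res.pooled_auc <= 1.0
        assert res.pooled_ci[0] <= res.pooled_auc <= res.pooled_ci[1]
        # strong planted effect, tiny cohort: must beat chance comfortably
        assert res.pooled_auc > 0.7

    def test_missing_metric_rejected(self, small_cohort):
        with pytest.raises(DataError):
            cc.run_cross_validation(small_cohort, "RK", cc.REDUCED_ARCHITECTURE,
                                    cc.TrainConfig(), cc.CVConfig())
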