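"""Agreement, calibration, discrimination statistics and threshold search."""

import itertools
import math

import numpy as np
import pytest

from bonescreen.evaluation import (
    ConfusionCounts,
    PairedSample,
    agreement_stats,
    bland_altman,
    calibration,
    confusion_metrics,
    find_threshold,
    osteoporosis_scores,
    roc_pr_curves,
    wilson_interval,
)


def longhand_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def brute_force_auroc(scores, labels):
    """O(n^2) concordance fraction with 0.5 credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_threshold(values, labels, target, kind):
    """Exhaustive scan over every candidate threshold."""
    candidates = sorted(set(values)) + [np.inf]
    best = None
    for t in candidates:
        called_pos = [l for v, l in zip(values, labels) if v < t]
        called_neg = [l for v, l in zip(values, labels) if v >= t]
        if kind == "ppv" and called_pos:
            ppv = sum(called_pos) / len(called_pos)
            if ppv >= target:
                best = t  # ascending scan: keeps the largest satisfying t
        elif kind == "npv" and called_neg and t != np.inf:
            npv = sum(1 for l in called_neg if not l) / len(called_neg)
            if npv >= target and best is None:
                best = t  # smallest satisfying t
    return best


class TestAgreement:
    def test_perfect_agreement(self):
        x = np.linspace(0.4, 1.2, 10)
        s = agreement_stats(PairedSample(x, x))
        assert s.pearson_r == pytest.approx(1.0)
        assert s.r2 == pytest.approx(1.0)
        assert s.rmse == pytest.approx(0.0, abs=1e-12)

    def test_perfect_anticorrelation(self):
        x = np.linspace(0.4, 1.2, 10)
        s = agreement_stats(PairedSample(x, -x))
        assert s.pearson_r == pytest.approx(-1.0)

    def test_matches_longhand_sums(self):
        rng = np.random.default_rng(3)
        pred = rng.normal(0.8, 0.15, 50)
        meas = pred + rng.normal(0, 0.05, 50)
        s = agreement_stats(PairedSample(pred, meas))
        assert s.pearson_r == pytest.approx(longhand_pearson(pred, meas), abs=1e-12)
        # longhand OLS of measured on predicted
        mx, my = pred.mean(), meas.mean()
        slope = ((pred - mx) * (meas - my)).sum() / ((pred - mx) ** 2).sum()
        intercept = my - slope * mx
        resid = meas - (intercept + slope * pred)
        assert s.rmse == pytest.approx(math.sqrt((resid**2).mean()), abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            agreement_stats(PairedSample([1.0, 2.0], [1.0, 2.0]))
        with pytest.raises(ValueError):
            agreement_stats(PairedSample([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestCalibration:
    def test_identical_samples(self):
        x = np.linspace(0.4, 1.2, 20)
        c = calibration(PairedSample(x, x))
        assert c.slope == pytest.approx(1.0)
        assert c.calibration_in_the_large == pytest.approx(0.0, abs=1e-15)

    def test_cohort_level_means_give_printed_style_citl(self):
        # mean predicted 0.692, mean measured 0.689 -> CITL -0.003
        rng = np.random.default_rng(5)
        pred = rng.normal(0.0, 0.14, 400)
        pred = pred - pred.mean() + 0.692
        meas = pred + rng.normal(0, 0.05, 400)
        meas = meas - meas.mean() + 0.689
        c = calibration(PairedSample(pred, meas))
        assert c.calibration_in_the_large == pytest.approx(-0.003, abs=1e-12)

    def test_constant_shift(self):
        x = np.linspace(0.4, 1.2, 20)
        c = calibration(PairedSample(x + 0.05, x))
        assert c.slope == pytest.approx(1.0)
        assert c.calibration_in_the_large == pytest.approx(-0.05)


class TestBlandAltman:
    def test_identity_and_constant_offset(self):
        x = np.linspace(0.4, 1.2, 20)
        assert bland_altman(PairedSample(x, x)).bias == 0.0
        ba = bland_altman(PairedSample(x + 0.003, x))
        assert ba.bias == pytest.approx(-0.003)
        assert ba.sd == pytest.approx(0.0, abs=1e-15)

    def test_matches_longhand_and_equals_citl(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            pred = rng.normal(0.8, 0.15, 30)
            meas = pred + rng.normal(0, 0.06, 30)
            s = PairedSample(pred, meas)
            ba = bland_altman(s)
            diffs = meas - pred
            assert ba.bias == pytest.approx(float(diffs.mean()), abs=1e-12)
            assert ba.sd == pytest.approx(float(diffs.std(ddof=1)), abs=1e-12)
            # calibration-in-the-large is the same quantity
            assert calibration(s).calibration_in_the_large == pytest.approx(
                ba.bias, abs=1e-12
            )


class TestConfusionMetrics:
    def test_rates_from_counts(self):
        m = confusion_metrics(ConfusionCounts(tp=524, fp=25, tn=3812, fn=196))
        assert m.ppv == pytest.approx(524 / 549)
        assert m.npv == pytest.approx(3812 / 4008)
        assert m.sensitivity == pytest.approx(524 / 720)
        assert m.accuracy == pytest.approx((524 + 3812) / 4557)

    def test_accuracy_consistency_with_sens_spec(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 200, 4)
            c = ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
            m = confusion_metrics(c)
            p, n = tp + fn, tn + fp
            assert m.sensitivity * p + m.specificity * n == pytest.approx(
                m.accuracy * c.total
            )

    def test_perfect_table_uses_continuity_correction(self):
        m = confusion_metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        assert m.accuracy == 1.0
        # Haldane-Anscombe: (10.5 * 10.5) / (0.5 * 0.5)
        assert m.odds_ratio == pytest.approx(441.0)
        assert m.or_ci[0] < m.odds_ratio < m.or_ci[1]

    def test_woolf_interval_brackets_estimate(self):
        m = confusion_metrics(ConfusionCounts(tp=50, fp=10, tn=80, fn=20))
        assert m.or_ci[0] < m.odds_ratio < m.or_ci[1]

    def test_wilson_interval_contains_proportion(self):
        lo, hi = wilson_interval(524, 549)
        assert lo < 524 / 549 < hi


class TestROCPR:
    def test_perfect_separation(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        auroc, auprc = roc_pr_curves(scores, labels)
        assert auroc == 1.0 and auprc == 1.0

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(17)
        scores = rng.random(4000)
        labels = rng.random(4000) < 0.4
        auroc, _ = roc_pr_curves(scores, labels)
        assert auroc == pytest.approx(0.5, abs=0.05)

    def test_matches_concordance_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            n = int(rng.integers(8, 30))
            scores = rng.integers(0, 6, n).astype(float)  # ties likely
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            auroc, _ = roc_pr_curves(scores, labels)
            assert auroc == pytest.approx(brute_force_auroc(scores, labels), abs=1e-12)

    def test_orientation_helper_ranks_low_bmd_positive(self):
        bmd = np.array([0.5, 0.9])
        s = osteoporosis_scores(bmd)
        assert s[0] > s[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_curves([0.1, 0.2], [1, 1])


class TestFindThreshold:
    def test_perfect_separation_captures_all_positives(self):
        values = np.array([0.4, 0.45, 0.5, 0.9, 1.0, 1.1])
        labels = np.array([1, 1, 1, 0, 0, 0])
        res = find_threshold(values, labels, 1.0, "ppv")
        assert res.found and res.attained == 1.0 and res.n_captured == 3
        assert res.threshold == pytest.approx(0.9)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(23)
        for kind in ("ppv", "npv"):
            for _ in range(40):
                n = 20
                values = np.round(rng.normal(0.8, 0.2, n), 2)
                labels = (values + rng.normal(0, 0.15, n)) < 0.7
                if labels.all() or not labels.any():
                    continue
                res = find_threshold(values, labels, 0.8, kind)
                oracle = brute_force_threshold(values, labels, 0.8, kind)
                if oracle is None:
                    assert not res.found
                else:
                    assert res.found
                    assert res.threshold == pytest.approx(oracle)

    def test_unattainable_target_returns_no_solution(self):
        # one mislabelled positive at the benign extreme poisons NPV 1.0
        values = np.array([0.4, 0.5, 0.9, 1.0, 1.2])
        labels = np.array([1, 1, 0, 0, 1])
        res = find_threshold(values, labels, 1.0, "npv")
        assert not res.found and res.threshold is None

    def test_attained_value_satisfies_constraint(self):
        rng = np.random.default_rng(29)
        values = rng.normal(0.8, 0.2, 200)
        labels = values + rng.normal(0, 0.1, 200) < 0.65
        for kind in ("ppv", "npv"):
            res = find_threshold(values, labels, 0.9, kind)
            if res.found:
                assert res.attained >= 0.9
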