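import numpy as np
import pytest

from sfdcm.forward import BurstTrain, simulate
from sfdcm.inversion import InversionResult
from sfdcm.preproc import ConductanceSeries, Epoch, baseline_subtract
from sfdcm.stats import (
    between_subject_scores,
    count_bursts,
    count_sf_conventional,
    nested_f_test,
    pearson_r,
    roc_curve,
    threshold_sweep,
)


def make_result(onsets, amps):
    """Minimal InversionResult wrapping a burst train (for counting tests)."""
    train = (BurstTrain(np.asarray(onsets, float), np.asarray(amps, float))
             if len(onsets) else BurstTrain.empty())
    return InversionResult(
        bursts=train,
        amp_sd=np.zeros(len(onsets)),
        onset_sd=np.zeros(len(onsets)),
        noise_precision=1.0,
        free_energy=0.0,
        fitted=ConductanceSeries(np.zeros(2), rate=10),
        residual_sd=0.0,
        n_iter=1,
        converged=True,
    )


class TestCountBursts:
    def test_direct_count(self):
        res = make_result([1, 2, 3], [0.05, 0.12, 0.30])
        assert count_bursts(res, 0.1) == 2

    def test_empty_train(self):
        assert count_bursts(make_result([], []), 0.1) == 0

    def test_zero_threshold_counts_all(self):
        res = make_result([1, 2, 3], [0.05, 0.12, 0.30])
        assert count_bursts(res, 0.0) == 3

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            count_bursts(make_result([1], [0.5]), -0.1)

    def test_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(0)
        res = make_result(np.sort(rng.uniform(0, 60, 12)), rng.uniform(0, 1, 12))
        counts = [count_bursts(res, t) for t in np.linspace(0, 1.2, 25)]
        assert np.all(np.diff(counts) <= 0)


class TestCountSfConventional:
    def test_flat_epoch(self):
        ep = Epoch(series=ConductanceSeries(np.zeros(600), rate=10))
        assert count_sf_conventional(ep) == 0

    def test_two_separated_fluctuations(self, kernel):
        train = BurstTrain(np.array([10.0, 40.0]), np.array([0.5, 0.5]))
        ep = Epoch(series=baseline_subtract(simulate(kernel, train, 60, 10)))
        assert count_sf_conventional(ep, threshold=0.25) == 2

    def test_subthreshold_fluctuation_not_counted(self, kernel):
        train = BurstTrain(np.array([30.0]), np.array([0.2]))
        ep = Epoch(series=baseline_subtract(simulate(kernel, train, 60, 10)))
        assert count_sf_conventional(ep, threshold=0.25) == 0


class TestPearsonR:
    def test_identity(self):
        x = np.array([1.0, 2, 3, 5])
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_negation(self):
        x = np.array([1.0, 2, 3, 5])
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_sums(self):
        # closed form from raw sums for x=[0,1,2,3], y=[1,1,2,4]
        x = np.array([0.0, 1, 2, 3])
        y = np.array([1.0, 1, 2, 4])
        n = 4
        num = n * (x @ y) - x.sum() * y.sum()
        den = np.sqrt(n * (x @ x) - x.sum() ** 2) * np.sqrt(n * (y @ y) - y.sum() ** 2)
        assert pearson_r(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_r(np.ones(5), np.arange(5.0))


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(1.0)

    def test_endpoints_present(self):
        roc = roc_curve([3, 1, 2, 5], [0, 1, 0, 1])
        assert [0.0, 0.0] in roc.points.tolist()
        assert [1.0, 1.0] in roc.points.tolist()

    def test_auc_equals_mann_whitney_construction(self):
        # brute-force pairwise oracle: P(count+ > count-) + 0.5 P(tie)
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(6, 30))
            counts = rng.integers(0, 8, n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            roc = roc_curve(counts, labels)
            pos = counts[labels == 1]
            neg = counts[labels == 0]
            gt = (pos[:, None] > neg[None, :]).sum()
            tie = (pos[:, None] == neg[None, :]).sum()
            u = (gt + 0.5 * tie) / (pos.size * neg.size)
            assert roc.auc == pytest.approx(u, abs=1e-12)

    def test_random_labels_auc_near_half(self):
        rng = np.random.default_rng(23)
        aucs = []
        for _ in range(2000):
            counts = rng.integers(0, 10, 20)
            labels = rng.integers(0, 2, 20)
            if labels.min() == labels.max() or np.unique(counts).size == 1:
                continue
            aucs.append(roc_curve(counts, labels).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            roc_curve([1, 2, 3], [1, 1, 1])


class TestNestedFTest:
    def test_identical_predictor_gives_zero_f(self):
        state = np.array([0.0, 1, 0, 1, 1, 0])
        base = np.array([1.0, 2, 1, 3, 2, 1])
        with pytest.warns(UserWarning, match="collinear"):
            f, df1, df2, p = nested_f_test(state, base, base)
        assert f == 0.0
        assert (df1, df2) == (1, 3)

    def test_perfect_added_predictor(self):
        rng = np.random.default_rng(31)
        state = rng.integers(0, 2, 12).astype(float)
        base = rng.standard_normal(12)
        f, df1, df2, p = nested_f_test(state, base, state)
        # full model fits exactly: F explodes, p collapses
        assert f > 1e6
        assert p < 1e-10

    def test_matches_extra_sum_of_squares_oracle(self):
        rng = np.random.default_rng(8)
        state = rng.standard_normal(8)
        base = rng.standard_normal(8)
        add = rng.standard_normal(8)
        f, df1, df2, p = nested_f_test(state, base, add)
        # independent matrix-algebra oracle via explicit projections
        X0 = np.column_stack([np.ones(8), base])
        X1 = np.column_stack([np.ones(8), base, add])
        H0 = X0 @ np.linalg.inv(X0.T @ X0) @ X0.T
        H1 = X1 @ np.linalg.inv(X1.T @ X1) @ X1.T
        rss0 = state @ (np.eye(8) - H0) @ state
        rss1 = state @ (np.eye(8) - H1) @ state
        f_oracle = (rss0 - rss1) / (rss1 / (8 - 3))
        assert f == pytest.approx(f_oracle, abs=1e-6)
        from scipy import stats as sstats

        assert p == pytest.approx(float(sstats.f.sf(f_oracle, 1, 5)), abs=1e-9)


class TestThresholdSweep:
    def test_identical_counts_give_unit_method_correlation(self):
        results = [make_result([10, 20], [0.5, 0.3]),
                   make_result([15], [0.4]),
                   make_result([5, 25, 45], [0.6, 0.2, 0.15])]
        thresholds = [0.1, 0.25, 0.5]
        conv = np.array([
            [count_bursts(r, t) for r in results] for t in thresholds
        ])
        rows = threshold_sweep(results, conv, [0, 1, 1], thresholds)
        assert all(row["r_methods"] == 1.0 for row in rows)

    def test_permuted_labels_have_small_validity(self):
        rng = np.random.default_rng(41)
        counts = rng.integers(0, 8, 24)
        results = [make_result(np.arange(c) * 2.0, np.full(c, 0.5))
                   for c in counts]
        labels = np.array([0] * 12 + [1] * 12)
        rs = []
        for _ in range(100):
            perm = rng.permutation(labels)
            rows = threshold_sweep(results, counts, perm, [0.1])
            rs.append(rows[0]["r_validity_dcm"])
        assert abs(np.mean(rs)) < 0.1

    def test_condition_effect_yields_positive_validity(self):
        # doubled burst rate in the labelled condition
        rng = np.random.default_rng(43)
        labels = np.array([0] * 10 + [1] * 10)
        results = []
        for lab in labels:
            c = rng.poisson(6 if lab == 0 else 12)
            results.append(make_result(np.arange(c) * 1.5, np.full(c, 0.5)))
        counts = np.array([count_bursts(r, 0.1) for r in results])
        rows = threshold_sweep(results, counts, labels, [0.1])
        assert rows[0]["r_validity_dcm"] > 0

    def test_single_class_rejected(self):
        results = [make_result([1], [0.5])] * 4
        with pytest.raises(ValueError, match="label classes"):
            threshold_sweep(results, [1, 1, 1, 1], [1, 1, 1, 1], [0.1])


class TestBetweenSubjectScores:
    def test_anticipation_minus_baseline(self):
        counts = [2, 5, 7, 1, 2, 3]
        labels = ["baseline", "anticipation", "anticipation"] * 2
        subjects = ["a", "a", "a", "b", "b", "b"]
        ids, scores = between_subject_scores(counts, labels, subjects)
        assert ids == ["a", "b"]
        assert scores == pytest.approx([4.0, 1.5])
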