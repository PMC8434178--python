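import math

import numpy as np
import pytest
from scipy.special import expit

from cgbvs import (
    ApplicabilityParams,
    DataError,
    applicability_index,
    classification_report,
    fit_weight_params,
    generate_applicability_benchmark,
    select_threshold,
    spearman,
    weight,
)


def dense_grid_oracle(aurocs, neighbors, n_grid=120):
    """Vectorized dense-grid argmax of Spearman(auroc, logA)."""
    from scipy import stats

    KP = np.array([[v[1] for v in row] for row in neighbors])
    N = np.array([[v[2] for v in row] for row in neighbors])
    best = -2.0
    for a in np.geomspace(0.1, 200, n_grid):
        for r in np.linspace(0, 1, n_grid):
            A = (expit(a * (KP - r)) * N).sum(axis=1)
            if (A <= 0).any():
                continue
            rho = stats.spearmanr(aurocs, np.log(A)).statistic
            if rho > best:
                best = rho
    return best


class TestWeight:
    def test_midpoint(self):
        assert weight(0.4, ApplicabilityParams(5.0, 0.4)) == pytest.approx(0.5)

    def test_fitted_msa_parameters_midpoint(self):
        # steep sigmoid fitted for the dense-compound/MSA combination
        p = ApplicabilityParams(alpha=12.77, r=0.4365)
        assert weight(0.4365, p) == pytest.approx(0.5)

    def test_saturation(self):
        p = ApplicabilityParams(alpha=100.0, r=0.2)
        assert weight(1.0, p) == pytest.approx(1.0)
        assert weight(0.95, p) > 0.999

    def test_strictly_increasing(self, rng):
        p = ApplicabilityParams(alpha=7.0, r=0.5)
        x = np.sort(rng.uniform(0, 1, 50))
        w = weight(x, p)
        assert np.all(np.diff(w) > 0)

    def test_overflow_safe(self):
        p = ApplicabilityParams(alpha=200.0, r=0.0)
        assert 0.0 <= float(weight(-1e6, p)) <= 1.0

    def test_alpha_must_be_positive(self):
        with pytest.raises(DataError):
            ApplicabilityParams(alpha=0.0, r=0.5)


class TestApplicabilityIndex:
    def test_weight_ceiling_gives_plain_sum(self):
        p = ApplicabilityParams(alpha=0.1, r=-1000.0)
        res = applicability_index("t", [("a", 0.5, 100), ("b", 0.2, 50)], p)
        assert res.A == pytest.approx(150.0, rel=1e-6)

    def test_two_neighbor_sigmoid_oracle(self):
        p = ApplicabilityParams(alpha=10.0, r=0.5)
        res = applicability_index("t", [("a", 0.9, 100), ("b", 0.1, 1000)], p)
        expected = float(expit(4.0)) * 100 + float(expit(-4.0)) * 1000
        assert res.A == pytest.approx(expected, abs=1e-6)
        assert res.A == pytest.approx(116.2, abs=0.1)
        assert res.logA == pytest.approx(math.log(expected))

    def test_no_neighbors_sentinel(self):
        with pytest.warns(UserWarning, match="logA undefined"):
            res = applicability_index("t", [], ApplicabilityParams(1.0, 0.5))
        assert res.A == 0.0 and res.logA == float("-inf")

    def test_self_neighbor_rejected(self):
        with pytest.raises(DataError, match="excluded"):
            applicability_index("t", [("t", 1.0, 10)], ApplicabilityParams(1.0, 0.5))

    def test_monotone_in_counts_and_similarity(self, rng):
        p = ApplicabilityParams(alpha=8.0, r=0.5)
        base = [("a", 0.4, 100.0), ("b", 0.7, 10.0)]
        A0 = applicability_index("t", base, p).A
        assert applicability_index("t", [("a", 0.4, 150.0), base[1]], p).A > A0
        assert applicability_index("t", [("a", 0.5, 100.0), base[1]], p).A > A0

    def test_count_scaling_shifts_logA(self):
        p = ApplicabilityParams(alpha=5.0, r=0.3)
        base = [("a", 0.4, 100.0), ("b", 0.7, 10.0)]
        scaled = [(n, k, 7.0 * c) for n, k, c in base]
        r0 = applicability_index("t", base, p)
        r1 = applicability_index("t", scaled, p)
        assert r1.logA - r0.logA == pytest.approx(math.log(7.0), abs=1e-12)


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1.0, 2, 3, 4, 5]
        assert spearman(x, [2.0, 4, 5, 7, 9]) == pytest.approx(1.0)
        assert spearman(x, [9.0, 7, 5, 4, 2]) == pytest.approx(-1.0)

    def test_rank_difference_formula(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (0, 1, -1, 0) -> 1 - 12/60
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_error(self):
        with pytest.raises(DataError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_scaling_counts_leaves_spearman_unchanged(self):
        bench = generate_applicability_benchmark(n_targets=12, noise_sd=0.05, seed=5)
        p = ApplicabilityParams(5.0, 0.4)
        logA = [applicability_index(t, row, p).logA
                for t, row in zip(bench.target_ids, bench.neighbors)]
        scaled = [[(n, k, 3.0 * c) for n, k, c in row] for row in bench.neighbors]
        logA2 = [applicability_index(t, row, p).logA
                 for t, row in zip(bench.target_ids, scaled)]
        assert spearman(bench.aurocs, logA) == pytest.approx(
            spearman(bench.aurocs, logA2), abs=1e-12
        )


class TestFitWeightParams:
    def test_noise_free_recovery(self):
        bench = generate_applicability_benchmark(n_targets=30, noise_sd=0.0, seed=1)
        params, rho = fit_weight_params(bench.aurocs, bench.neighbors, seed=1)
        assert rho == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_matches_grid_oracle(self):
        bench = generate_applicability_benchmark(n_targets=50, noise_sd=0.05, seed=2)
        params, rho = fit_weight_params(bench.aurocs, bench.neighbors, seed=2)
        assert rho >= 0.9
        assert rho >= dense_grid_oracle(bench.aurocs, bench.neighbors) - 0.02

    def test_fitted_at_least_coarse_grid(self):
        from scipy import stats

        bench = generate_applicability_benchmark(n_targets=20, noise_sd=0.1, seed=3)
        params, rho = fit_weight_params(bench.aurocs, bench.neighbors, seed=3)
        KP = np.array([[v[1] for v in row] for row in bench.neighbors])
        N = np.array([[v[2] for v in row] for row in bench.neighbors])
        for a in np.geomspace(0.1, 200, 25):
            for r in np.linspace(0, 1, 25):
                A = (expit(a * (KP - r)) * N).sum(axis=1)
                assert rho >= stats.spearmanr(bench.aurocs, np.log(A)).statistic - 1e-12

    def test_deterministic(self):
        bench = generate_applicability_benchmark(n_targets=15, noise_sd=0.05, seed=4)
        p1, r1 = fit_weight_params(bench.aurocs, bench.neighbors, seed=4)
        p2, r2 = fit_weight_params(bench.aurocs, bench.neighbors, seed=4)
        assert (p1.alpha, p1.r, r1) == (p2.alpha, p2.r, r2)

    def test_too_few_targets(self):
        with pytest.raises(DataError, match="at least 5"):
            fit_weight_params([0.8, 0.9], [[("a", 0.5, 1)], [("a", 0.5, 1)]])


class TestSelectThreshold:
    def test_perfect_separation(self):
        results = [(1.0, 0.9), (2.0, 0.95), (-1.0, 0.6), (-2.0, 0.5)]
        clf = select_threshold(results)
        assert clf.fit_accuracy_ == 1.0
        assert -1.0 < clf.threshold_logA < 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        logA = rng.normal(size=40)
        au = np.clip(0.8 + 0.1 * logA + rng.normal(0, 0.08, 40), 0.4, 1.0)
        results = list(zip(logA, au))
        clf = select_threshold(results)
        truth = au > 0.8
        # exhaustive scan over a fine threshold sweep can do no better
        best = max(
            float(np.mean((logA >= t) == truth))
            for t in np.linspace(logA.min() - 1, logA.max() + 1, 5000)
        )
        assert clf.fit_accuracy_ == pytest.approx(best, abs=1e-12)

    def test_value_at_threshold_predicted_positive(self):
        clf = select_threshold([(10.0, 0.9), (9.5, 0.85), (8.0, 0.7), (7.0, 0.6)])
        clf.threshold_logA = 8.999
        assert clf.predict([9.0])[0]
        assert not clf.predict([8.9])[0]

    def test_single_class_error(self):
        with pytest.raises(DataError, match="both classes"):
            select_threshold([(1.0, 0.9), (2.0, 0.95)])


def fisher_hypergeometric_oracle(tp, fp, fn, tn):
    """Two-sided Fisher p by hypergeometric enumeration."""
    from math import comb

    n = tp + fp + fn + tn
    row1, col1 = tp + fp, tp + fn

    def prob(a):
        b = row1 - a
        c = col1 - a
        d = n - row1 - c
        if min(b, c, d) < 0:
            return None
        return comb(col1, a) * comb(n - col1, b) / comb(n, row1)

    p_obs = prob(tp)
    total = 0.0
    for a in range(0, min(row1, col1) + 1):
        p = prob(a)
        if p is not None and p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestClassificationReport:
    def test_accuracy_46_of_52(self):
        pred = np.zeros(52, bool)
        truth = np.zeros(52, bool)
        pred[:29] = True
        truth[:26] = True
        truth[29:32] = True  # 26 tp, 3 fp, 3 fn, 20 tn -> 46 correct
        rep = classification_report(pred, truth)
        assert rep.tp + rep.tn == 46
        assert rep.accuracy == pytest.approx(0.8846, abs=5e-5)

    def test_fisher_balanced_table(self):
        pred = np.array([True] * 5 + [False] * 5)
        rep = classification_report(pred, pred)
        from math import comb

        assert rep.fisher_p == pytest.approx(2 / comb(10, 5), rel=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_fisher_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.random(30) < 0.5
        truth = rng.random(30) < 0.5
        if not pred.any():
            pred[0] = True
        rep = classification_report(pred, truth)
        oracle = fisher_hypergeometric_oracle(rep.tp, rep.fp, rep.fn, rep.tn)
        assert rep.fisher_p == pytest.approx(oracle, rel=1e-6)

    def test_all_correct(self):
        truth = np.array([True, True, False, False, True])
        rep = classification_report(truth, truth)
        assert rep.ppv == 1.0 and rep.accuracy == 1.0

    def test_counts_reconcile(self, rng):
        pred = rng.random(40) < 0.4
        truth = rng.random(40) < 0.6
        pred[0] = True
        rep = classification_report(pred, truth)
        assert rep.tp + rep.fp + rep.tn + rep.fn == 40
        assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / 40)
        assert rep.ppv == pytest.approx(rep.tp / (rep.tp + rep.fp))

    def test_no_predicted_positives_flagged(self):
        with pytest.warns(UserWarning, match="PPV undefined"):
            rep = classification_report([False, False], [True, False])
        assert not rep.ppv_defined and math.isnan(rep.ppv)
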