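"""Metric and statistics oracles: hand computation, enumeration, properties."""

import itertools
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

from radsections.metrics import (
    ComparisonResult,
    ConfusionMatrix,
    accuracy,
    ablate_training_fraction,
    bonferroni,
    general_f1,
    mann_whitney_u,
    mcnemar_from_counts,
    mcnemar_test,
    per_report_metrics,
    stratified_kfold,
)


def cm(*rows):
    """rows of (tp, fp, fn, tn)."""
    tp, fp, fn, tn = zip(*rows)
    return ConfusionMatrix(tp, fp, fn, tn)


class TestAccuracy:
    def test_all_correct_is_one(self):
        assert accuracy(cm((5, 0, 0, 7), (7, 0, 0, 5))) == 1.0

    def test_all_wrong_is_zero(self):
        assert accuracy(cm((0, 6, 6, 0), (0, 6, 6, 0))) == 0.0

    def test_hand_counted_two_class(self):
        # 12 items: class A 9 right / 1 missed, class B 1 right / 1 missed
        m = ConfusionMatrix.from_labels(
            ["a"] * 10 + ["b"] * 2,
            ["a"] * 9 + ["b"] + ["b", "a"],
            ["a", "b"],
        )
        assert accuracy(m) == pytest.approx(10 / 12)

    def test_zero_predictions_raises(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionMatrix([], [], [], []))


class TestGeneralF1:
    def test_perfect_predictions(self):
        assert general_f1(cm((5, 0, 0, 7), (7, 0, 0, 5))) == 1.0

    def test_zero_tp_with_errors(self):
        assert general_f1(cm((0, 2, 3, 7), (0, 3, 2, 7))) == 0.0

    def test_hand_evaluated_weighted_case(self):
        # class A: P=10, TP=9, FP=1, FN=1; class B: P=2, TP=1, FP=1, FN=1
        # w = (1/100, 1/4); G.F1 = 2*(0.09+0.25) / (0.19 + 0.25*4) = 0.68/1.19
        m = cm((9, 1, 1, 1), (1, 1, 1, 9))
        w_a, w_b = 1 / 100, 1 / 4
        expected = (2 * (w_a * 9 + w_b * 1)) / (
            w_a * (2 * 9 + 1 + 1) + w_b * (2 * 1 + 1 + 1)
        )
        assert general_f1(m) == pytest.approx(expected)
        assert general_f1(m) == pytest.approx(0.5667, abs=5e-5)

    def test_equal_support_reduces_to_macro_dice(self):
        m = cm((6, 2, 4, 8), (7, 4, 3, 6))
        dice = np.mean(
            [2 * 6 / (2 * 6 + 2 + 4), 2 * 7 / (2 * 7 + 4 + 3)]
        )
        assert general_f1(m) == pytest.approx(dice)

    def test_minority_error_costs_more_than_majority_error(self):
        # start perfect: majority P=50, minority P=2
        base = cm((50, 0, 0, 2), (2, 0, 0, 50))
        perfect = general_f1(base)
        lose_major = cm((49, 0, 1, 2), (2, 1, 0, 49))
        lose_minor = cm((50, 1, 0, 1), (1, 0, 1, 50))
        drop_major = perfect - general_f1(lose_major)
        drop_minor = perfect - general_f1(lose_minor)
        assert drop_minor > drop_major > 0

    def test_zero_support_classes_excluded(self):
        with_empty = cm((9, 1, 1, 1), (1, 1, 1, 9), (0, 0, 0, 12))
        without = cm((9, 1, 1, 1), (1, 1, 1, 9))
        assert general_f1(with_empty) == pytest.approx(general_f1(without))

    def test_all_empty_raises(self):
        with pytest.raises(ValueError):
            general_f1(cm((0, 0, 0, 5), (0, 0, 0, 5)))


class TestPerReport:
    def test_identical_predictions(self):
        res = per_report_metrics([["a", "b"]], [["a", "b"]], ["a", "b"])
        assert res.acc_mean == 1.0 and res.acc_std == 0.0
        assert res.gf1_mean == 1.0

    def test_mean_of_two_reports(self):
        res = per_report_metrics(
            [["a", "a"], ["a", "b"]],
            [["a", "a"], ["a", "a"]],
            ["a", "b"],
        )
        assert res.acc_mean == pytest.approx(0.75)
        assert res.acc_std == pytest.approx(0.25)  # population std

    def test_matches_bruteforce_loop(self, small_corpus, rng):
        classes = ["x", "y", "z"]
        gold, pred = [], []
        for _ in range(50):
            n = int(rng.integers(3, 12))
            gold.append([classes[i] for i in rng.integers(0, 3, n)])
            pred.append([classes[i] for i in rng.integers(0, 3, n)])
        res = per_report_metrics(gold, pred, classes)
        accs = []
        for g, p in zip(gold, pred):
            accs.append(np.mean([a == b for a, b in zip(g, p)]))
        assert res.acc_mean == pytest.approx(np.mean(accs))
        assert res.acc_std == pytest.approx(np.std(accs))

    def test_length_mismatch_names_report(self):
        with pytest.raises(ValueError, match="R7"):
            per_report_metrics([["a"]], [["a", "b"]], ["a", "b"], ["R7"])


class TestFolds:
    def test_balanced_two_strata(self):
        ids = [f"r{i}" for i in range(100)]
        strata = ["MG"] * 50 + ["MRI"] * 50
        plan = stratified_kfold(ids, strata, k=5, seed=0)
        for fold in plan.folds:
            kinds = [plan.strata[r] for r in fold]
            assert kinds.count("MG") == 10 and kinds.count("MRI") == 10

    def test_folds_partition_ids(self):
        ids = [f"r{i}" for i in range(83)]
        strata = ["a" if i % 3 else "b" for i in range(83)]
        plan = stratified_kfold(ids, strata, k=5, seed=3)
        flat = [r for f in plan.folds for r in f]
        assert sorted(flat) == sorted(ids)
        assert len(set(flat)) == len(flat)

    def test_stratification_not_significantly_skewed(self):
        # chi-square of stratum x fold should not reject at 0.05 (per seed);
        # a handful of seeds guards against systematic skew
        fails = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            strata = [["MG", "MRI", "US"][i] for i in rng.integers(0, 3, 200)]
            ids = [f"r{i}" for i in range(200)]
            plan = stratified_kfold(ids, strata, k=5, seed=seed)
            table = np.array(
                [
                    [sum(plan.strata[r] == s for r in fold) for s in ("MG", "MRI", "US")]
                    for fold in plan.folds
                ]
            )
            _, p, _, _ = sps.chi2_contingency(table)
            fails += p < 0.05
        assert fails == 0

    def test_k_too_small_raises(self):
        with pytest.raises(ValueError):
            stratified_kfold(["a", "b"], ["x", "x"], k=1)


class TestAblation:
    @staticmethod
    def _signatures(rng, n):
        sections = ["T", "H", "F", "I"]
        return {
            f"r{i}": ["T"] + [s for s in sections[1:] if rng.random() > 0.3]
            for i in range(n)
        }

    def test_identity_at_full_fraction(self, rng):
        sig = self._signatures(rng, 40)
        ids = list(sig)
        assert ablate_training_fraction(ids, sig, 1.0, seed=0) == ids

    def test_tenth_of_720_is_72(self, rng):
        sig = self._signatures(rng, 720)
        out = ablate_training_fraction(list(sig), sig, 0.10, seed=0)
        assert abs(len(out) - 72) <= 1  # +1 possible when a section is rescued

    def test_section_proportions_preserved(self, rng):
        sig = self._signatures(rng, 500)
        ids = list(sig)
        out = ablate_training_fraction(ids, sig, 0.2, seed=1)

        def props(subset):
            counts = {}
            for r in subset:
                for s in sig[r]:
                    counts[s] = counts.get(s, 0) + 1
            total = sum(counts.values())
            return {s: c / total for s, c in counts.items()}

        full, sub = props(ids), props(out)
        for s in full:
            assert abs(full[s] - sub[s]) < 0.05


class TestMcNemar:
    def test_symmetric_counts_near_one(self):
        for n in range(1, 6):
            assert mcnemar_from_counts(n, n).p_raw >= 0.99

    def test_corrected_chi_square_hand_value(self):
        # the continuity-corrected statistic for (b=20, c=40):
        # (|20-40|-1)^2/60
        res = mcnemar_from_counts(20, 40)
        assert res.statistic == pytest.approx((abs(20 - 40) - 1) ** 2 / 60)
        # and for the b=2, c=8 pattern the corrected statistic is 25/10
        assert (abs(2 - 8) - 1) ** 2 / (2 + 8) == pytest.approx(2.5)

    def test_exact_branch_equals_tail_enumeration(self):
        # brute-force two-sided binomial tail at p=1/2
        for n in range(1, 13):
            for b in range(n + 1):
                c = n - b
                expected = sum(
                    comb(n, k) * 0.5**n
                    for k in range(n + 1)
                    if comb(n, k) <= comb(n, b) + 1e-12
                )
                got = mcnemar_from_counts(b, c).p_raw
                assert got == pytest.approx(min(1.0, expected), abs=1e-9), (b, c)

    def test_zero_discordant_pairs(self):
        assert mcnemar_from_counts(0, 0).p_raw == 1.0

    def test_from_predictions(self):
        gold = [0, 0, 0, 0, 1, 1]
        a = [0, 0, 0, 1, 1, 1]  # one error
        b = [0, 1, 1, 1, 1, 1]  # three errors
        res = mcnemar_test(gold, a, b)
        # b_count = A right, B wrong = 2; c_count = 0
        assert res == mcnemar_from_counts(2, 0)


class TestMannWhitney:
    def test_identical_multisets(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(4.5)
        assert res.p_raw == pytest.approx(1.0)

    def test_full_separation_u_zero(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_raw == pytest.approx(0.1, abs=0.01)  # 2/C(6,3)

    def test_constant_samples(self):
        assert mann_whitney_u([2, 2], [2, 2]).p_raw == 1.0

    @pytest.mark.parametrize(
        "a,b",
        [
            ((0.1, 0.9, 0.4), (0.5, 0.2, 0.8, 0.6)),
            ((1, 1, 2, 3), (2, 4, 4)),  # ties across and within samples
            ((5, 6, 7, 8, 9, 10), (1, 2, 3, 4, 11, 12)),
        ],
    )
    def test_exact_branch_equals_bruteforce_enumeration(self, a, b):
        res = mann_whitney_u(list(a), list(b))
        pooled = list(a) + list(b)
        n = len(a)
        ranks = sps.rankdata(pooled)
        center = n * len(b) / 2.0

        def u_of(idx):
            w = sum(ranks[i] for i in idx)
            return w - n * (n + 1) / 2.0

        u_obs = u_of(range(n))
        hits = total = 0
        for idx in itertools.combinations(range(len(pooled)), n):
            total += 1
            if abs(u_of(idx) - center) >= abs(u_obs - center) - 1e-9:
                hits += 1
        assert res.p_raw == pytest.approx(hits / total)
        assert res.statistic == pytest.approx(u_obs)

    def test_exact_matches_scipy_on_tie_free_samples(self, rng):
        for _ in range(10):
            a = rng.permutation(40)[:6].astype(float)
            b = rng.permutation(40)[:5].astype(float) + 0.5
            res = mann_whitney_u(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert res.p_raw == pytest.approx(float(ref.pvalue))

    def test_large_samples_use_normal_approximation(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 25)
        res = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_raw == pytest.approx(float(ref.pvalue))

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestBonferroni:
    def test_basic_scaling_and_cap(self):
        assert bonferroni([0.01], m=3) == [pytest.approx(0.03)]
        assert bonferroni([0.5], m=3) == [1.0]

    def test_never_lowers_and_monotone(self, rng):
        ps = np.sort(rng.random(20))
        adj = bonferroni(list(ps), m=7)
        assert all(a >= p for a, p in zip(adj, ps))
        assert all(a1 <= a2 for a1, a2 in zip(adj, adj[1:]))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], m=2)

    def test_comparison_result_invariant(self):
        res = mcnemar_from_counts(2, 9, m=4)
        assert isinstance(res, ComparisonResult)
        assert res.p_adjusted == pytest.approx(min(1.0, 4 * res.p_raw))
        assert res.p_adjusted >= res.p_raw
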