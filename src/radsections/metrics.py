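"""Imbalance-aware evaluation metrics, cross-validation and model comparison.

Two headline metrics: pooled (micro) multi-class accuracy, and the
generalized F1 (G.F1) derived from the generalized Dice coefficient with
per-class weights w_i = 1/P_i^2, where P_i is the class's positive count in
the test set. Squared-inverse-support weighting makes a single error on a
rare class cost far more than one on the dominant class — the property that
matters when most reports carry the majority label.

Model comparison: exact/corrected McNemar for paired classifiers,
exact/asymptotic Mann-Whitney U for per-report metric distributions, and
Bonferroni adjustment for families of comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Hashable, Optional, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold, train_test_split

# ---------------------------------------------------------------------------
# Confusion matrix and metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """Per-class one-vs-rest counts for a multi-class problem.

    P_i (positives per class) always equals TP_i + FN_i; the total number of
    predictions is identical across classes.
    """

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    def __post_init__(self) -> None:
        self.tp, self.fp, self.fn, self.tn = (
            np.asarray(a, dtype=np.int64) for a in (self.tp, self.fp, self.fn, self.tn)
        )
        totals = self.tp + self.fp + self.fn + self.tn
        if len(set(totals.tolist())) > 1:
            raise ValueError("per-class counts must sum to the same total")
        if np.any(self.tp < 0) or np.any(self.fp < 0) or np.any(self.fn < 0) or np.any(self.tn < 0):
            raise ValueError("counts must be non-negative")

    @property
    def positives(self) -> np.ndarray:
        """P_i: positive cases in the test set per class."""
        return self.tp + self.fn

    @property
    def n_predictions(self) -> int:
        return int((self.tp + self.fp + self.fn + self.tn)[0]) if len(self.tp) else 0

    @classmethod
    def from_labels(
        cls,
        gold: Sequence[Hashable],
        predicted: Sequence[Hashable],
        classes: Sequence[Hashable],
    ) -> "ConfusionMatrix":
        if len(gold) != len(predicted):
            raise ValueError("gold and predicted must have equal length")
        index = {c: i for i, c in enumerate(classes)}
        n = len(classes)
        tp = np.zeros(n, np.int64)
        fp = np.zeros(n, np.int64)
        fn = np.zeros(n, np.int64)
        total = len(gold)
        for g, p in zip(gold, predicted):
            gi, pi = index[g], index[p]
            if gi == pi:
                tp[gi] += 1
            else:
                fn[gi] += 1
                fp[pi] += 1
        tn = total - tp - fp - fn
        return cls(tp, fp, fn, tn)


def accuracy(cm: ConfusionMatrix) -> float:
    """Pooled multi-class accuracy: correct predictions over all predictions."""
    total = cm.n_predictions
    if total == 0:
        raise ValueError("confusion matrix holds zero predictions")
    return float(cm.tp.sum() / total)


def general_f1(cm: ConfusionMatrix) -> float:
    """Generalized F1: Dice with class weights w_i = 1/P_i^2.

    Classes with zero positives in the test set are excluded (their weight
    is undefined). Raises if every class has zero positives.
    """
    P = cm.positives
    live = P > 0
    if not live.any():
        raise ValueError("every class has zero positives")
    w = 1.0 / P[live].astype(float) ** 2
    num = 2.0 * np.sum(w * cm.tp[live])
    den = np.sum(w * (2.0 * cm.tp[live] + cm.fp[live] + cm.fn[live]))
    return float(num / den) if den > 0 else 0.0


@dataclass
class ReportMetrics:
    acc_mean: float
    acc_std: float
    gf1_mean: float
    gf1_std: float
    per_report_acc: list[float]
    per_report_gf1: list[float]


def per_report_metrics(
    gold_by_report: Sequence[Sequence[Hashable]],
    pred_by_report: Sequence[Sequence[Hashable]],
    classes: Sequence[Hashable],
    report_ids: Optional[Sequence[str]] = None,
) -> ReportMetrics:
    """Per-report accuracy and G.F1, averaged over reports.

    Std is the population (ddof=0) standard deviation over reports.
    """
    if len(gold_by_report) != len(pred_by_report):
        raise ValueError("gold and predicted report lists differ in length")
    accs, gf1s = [], []
    for i, (g, p) in enumerate(zip(gold_by_report, pred_by_report)):
        if len(g) != len(p):
            rid = report_ids[i] if report_ids else f"#{i}"
            raise ValueError(f"label length mismatch in report {rid}")
        cm = ConfusionMatrix.from_labels(g, p, classes)
        accs.append(accuracy(cm))
        gf1s.append(general_f1(cm))
    return ReportMetrics(
        acc_mean=float(np.mean(accs)),
        acc_std=float(np.std(accs)),
        gf1_mean=float(np.mean(gf1s)),
        gf1_std=float(np.std(gf1s)),
        per_report_acc=accs,
        per_report_gf1=gf1s,
    )


# ---------------------------------------------------------------------------
# Cross-validation plans
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    """k disjoint folds of report ids, stratified by modality/procedure."""

    folds: list[list[str]]
    strata: dict[str, str] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.folds)

    def split(self, fold: int) -> tuple[list[str], list[str]]:
        """(train ids, test ids) with the given fold held out."""
        test = list(self.folds[fold])
        train = [rid for j, f in enumerate(self.folds) if j != fold for rid in f]
        return train, test


def stratified_kfold(
    report_ids: Sequence[str],
    strata: Sequence[str],
    k: int = 5,
    seed: int = 0,
    min_stratum: Optional[int] = None,
) -> FoldPlan:
    """Deterministic stratified k-fold plan over reports.

    Strata (modality/procedure labels) smaller than `min_stratum` (default k)
    are merged into an "other" stratum so every retained stratum can spread
    across all folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(report_ids) != len(strata):
        raise ValueError("report_ids and strata must align")
    min_stratum = k if min_stratum is None else min_stratum
    counts: dict[str, int] = {}
    for s in strata:
        counts[s] = counts.get(s, 0) + 1
    merged = [s if counts[s] >= min_stratum else "other" for s in strata]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[list[str]] = []
    ids = np.asarray(report_ids, dtype=object)
    for _, test_idx in skf.split(np.zeros(len(ids)), merged):
        folds.append([str(r) for r in ids[test_idx]])
    return FoldPlan(folds=folds, strata=dict(zip(map(str, report_ids), merged)))


def split_sentences_stratified(
    sentence_ids: Sequence[int],
    section_labels: Sequence[Hashable],
    val_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[list[int], list[int]]:
    """Sentence-level train/validation split stratified by section label."""
    train, val = train_test_split(
        list(sentence_ids),
        test_size=val_fraction,
        random_state=seed,
        stratify=list(section_labels),
    )
    return list(train), list(val)


def ablate_training_fraction(
    train_ids: Sequence[str],
    section_signature: dict[str, Sequence[Hashable]],
    fraction: float = 0.10,
    seed: int = 0,
) -> list[str]:
    """Stratified subsample of one fold's training reports.

    Reports are grouped by the set of sections they contain and sampled
    proportionally within each group, which preserves the corpus's section
    composition. If the subsample would lose a section entirely, a report
    containing it is added back (with a warning).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(train_ids)
    rng = np.random.default_rng(seed)
    groups: dict[tuple, list[str]] = {}
    for rid in train_ids:
        key = tuple(sorted(set(section_signature[rid])))
        groups.setdefault(key, []).append(rid)
    n_target = max(1, round(fraction * len(train_ids)))
    chosen: list[str] = []
    # largest-remainder apportionment across signature groups
    quotas = {key: fraction * len(members) for key, members in groups.items()}
    base = {key: int(q) for key, q in quotas.items()}
    remainders = sorted(
        groups, key=lambda key: (quotas[key] - base[key]), reverse=True
    )
    short = n_target - sum(base.values())
    for key in remainders[:max(0, short)]:
        base[key] += 1
    for key, members in groups.items():
        take = min(len(members), base[key])
        if take:
            picked = rng.choice(len(members), size=take, replace=False)
            chosen.extend(members[i] for i in sorted(picked))
    # guarantee every section present in the full training set survives
    covered = {s for rid in chosen for s in section_signature[rid]}
    wanted = {s for rid in train_ids for s in section_signature[rid]}
    for missing in sorted(wanted - covered, key=str):
        candidates = [r for r in train_ids if missing in section_signature[r]]
        extra = candidates[int(rng.integers(len(candidates)))]
        if extra not in chosen:
            warnings.warn(
                f"ablation fraction {fraction} lost section {missing}; "
                f"keeping one report containing it"
            )
            chosen.append(extra)
    return chosen


# ---------------------------------------------------------------------------
# Paired model comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    statistic: float
    p_raw: float
    p_adjusted: float
    m: int


EXACT_MCNEMAR_MAX = 25  # discordant-pair count below which the test is exact


def mcnemar_from_counts(b: int, c: int, m: int = 1) -> ComparisonResult:
    """McNemar test from discordant counts.

    b: items model A got right and B wrong; c: the reverse. Exact two-sided
    binomial when b + c < 25, else chi-square with continuity correction
    (|b-c|-1)^2/(b+c). b + c = 0 gives p = 1 by convention.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return ComparisonResult(0.0, 1.0, 1.0, m)
    if n < EXACT_MCNEMAR_MAX:
        p = float(sps.binomtest(b, n, 0.5).pvalue)
        stat = float(min(b, c))
    else:
        stat = (abs(b - c) - 1) ** 2 / n
        p = float(sps.chi2.sf(stat, df=1))
    return ComparisonResult(stat, p, min(1.0, m * p), m)


def mcnemar_test(
    gold: Sequence[Hashable],
    pred_a: Sequence[Hashable],
    pred_b: Sequence[Hashable],
    m: int = 1,
) -> ComparisonResult:
    """Paired comparison of two classifiers on the same test items."""
    if not (len(gold) == len(pred_a) == len(pred_b)):
        raise ValueError("paired predictions must cover the same test items")
    b = sum(1 for g, a, bb in zip(gold, pred_a, pred_b) if a == g and bb != g)
    c = sum(1 for g, a, bb in zip(gold, pred_a, pred_b) if a != g and bb == g)
    return mcnemar_from_counts(b, c, m)


EXACT_MWU_MAX = 20  # per-sample size above which the normal approximation is used


def _mwu_exact_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact permutation two-sided p for the Mann-Whitney U statistic.

    Conditional on the observed (possibly tied) pooled values: counts, by
    dynamic programming over doubled midranks, how many of the C(n+m, n)
    assignments give a U at least as far from n*m/2 as the observed one.
    """
    n, m_ = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    dr = np.rint(2 * ranks).astype(int)  # doubled midranks are integers
    w_obs = float(ranks[:n].sum())
    u_obs = w_obs - n * (n + 1) / 2.0

    max_sum = int(dr.sum())
    # dp[k][s]: number of size-k subsets of the pooled ranks with doubled sum s
    dp = np.zeros((n + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in dr:
        for k in range(n - 1, -1, -1):
            row = dp[k]
            nz = np.nonzero(row)[0]
            if len(nz):
                dp[k + 1, nz + r] += row[nz]
    total = comb(n + m_, n)
    center = n * m_ / 2.0
    dev = abs(u_obs - center)
    count = 0.0
    for s2 in np.nonzero(dp[n])[0]:
        w = s2 / 2.0
        u = w - n * (n + 1) / 2.0
        if abs(u - center) >= dev - 1e-9:
            count += dp[n, s2]
    return u_obs, min(1.0, count / total)


def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float], m: int = 1
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test between two metric samples.

    Exact permutation enumeration when both samples have at most 20
    observations; tie-corrected normal approximation (scipy) otherwise.
    Identical constant samples give p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return ComparisonResult(len(a) * len(b) / 2.0, 1.0, 1.0, m)
    if max(len(a), len(b)) <= EXACT_MWU_MAX:
        u, p = _mwu_exact_p(a, b)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(float(u), float(p), min(1.0, m * p), m)


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> list[float]:
    """Bonferroni adjustment: min(1, m * p) per value."""
    ps = list(p_values)
    m = len(ps) if m is None else m
    if m < 1:
        raise ValueError("m must be >= 1")
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in ps]
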