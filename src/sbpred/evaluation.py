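"""Performance assessment: confusion metrics, ROC/AUC, cross-validation,
label-permutation significance, and positive-rate comparison.

Sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(FP+TN), accuracy
Acc = (TP+TN)/total and the Matthews correlation coefficient
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)) summarize a 2x2
confusion table.  Model quality is estimated by stratified fivefold
cross-validation; significance by shuffling labels and repeating the full
cross-validation; and independent-set positive rates are compared with a
Pearson chi-square test on the 2x2 count table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2_contingency
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from ._svm import SVMConfig, check_binary, grid_search, make_svc
from .feature_selection import select_features
from .features import FeatureMatrix, base_descriptors, encode_pair
from .peptide_io import PeptideSet

# ---------------------------------------------------------------------------
# Confusion counts and scalar metrics


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(true_labels: Sequence[int], calls: Sequence[int]) -> ConfusionCounts:
    """Cross-tabulate binary truth against binary calls (1 = binder)."""
    t = np.asarray(true_labels)
    c = np.asarray(calls)
    if t.shape != c.shape:
        raise ValueError("true_labels and calls have different lengths")
    return ConfusionCounts(
        TP=int(np.sum((t == 1) & (c == 1))),
        FP=int(np.sum((t == 0) & (c == 1))),
        TN=int(np.sum((t == 0) & (c == 0))),
        FN=int(np.sum((t == 1) & (c == 0))),
    )


@dataclass
class MetricsReport:
    """Sn/Sp/Acc/MCC (and AUC / per-fold accuracies when available)."""

    sn: float
    sp: float
    acc: float
    mcc: float
    auc: Optional[float] = None
    counts: Optional[ConfusionCounts] = None
    fold_accuracies: list[float] = field(default_factory=list)

    @property
    def acc_mean(self) -> float:
        return float(np.mean(self.fold_accuracies)) if self.fold_accuracies else self.acc

    @property
    def acc_std(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0

    def summary(self) -> str:
        parts = [
            f"Sn={100 * self.sn:.2f}%",
            f"Sp={100 * self.sp:.2f}%",
            f"Acc={100 * self.acc:.2f}%",
            f"MCC={self.mcc:.2f}",
        ]
        if self.auc is not None:
            parts.append(f"AUC={self.auc:.2f}")
        if self.fold_accuracies:
            parts.append(
                f"fold Acc {100 * self.acc_mean:.2f}% +/- {100 * self.acc_std:.2f}%"
            )
        return "  ".join(parts)


def metrics(cc: ConfusionCounts) -> MetricsReport:
    """Sn, Sp, Acc and MCC from a confusion table.

    A zero denominator factor makes MCC 0 (the random-prediction value);
    Sn/Sp are 0 when their class is absent.
    """
    if cc.total == 0:
        raise ValueError("empty confusion table")
    tp, fp, tn, fn = cc.TP, cc.FP, cc.TN, cc.FN
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (fp + tn) if fp + tn else 0.0
    acc = (tp + tn) / cc.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(sn=sn, sp=sp, acc=acc, mcc=mcc, counts=cc)


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class ROCCurve:
    """Threshold-swept ROC points from (0,0) to (1,1) with trapezoidal AUC."""

    points: list[tuple[float, float]]
    auc: float

    def to_tsv(self, path) -> None:
        from pathlib import Path

        lines = ["fpr\ttpr"] + [f"{x:.6f}\t{y:.6f}" for x, y in self.points]
        Path(path).write_text("\n".join(lines) + "\n")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """ROC curve over all distinct score thresholds (ties grouped) + AUC."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    check_binary(y)
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(points=list(zip(fpr.tolist(), tpr.tolist())), auc=auc)


# ---------------------------------------------------------------------------
# Cross-validation


def _cv_on_matrix(
    X: np.ndarray,
    y: np.ndarray,
    svm_config: SVMConfig,
    k: int,
    seed: int,
) -> MetricsReport:
    """Stratified k-fold CV: pooled confusion + ROC, per-fold accuracies."""
    check_binary(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    calls = np.empty(len(y), dtype=int)
    scores = np.empty(len(y), dtype=float)
    fold_accs = []
    for train, test in skf.split(X, y):
        c, g, _ = grid_search(X[train], y[train], svm_config, seed)
        clf = make_svc(c, g, seed=seed).fit(X[train], y[train])
        calls[test] = clf.predict(X[test])
        scores[test] = clf.decision_function(X[test])
        fold_accs.append(float(np.mean(calls[test] == y[test])))
    rep = metrics(confusion(y, calls))
    rep.auc = roc_auc(scores, y).auc
    rep.fold_accuracies = fold_accs
    return rep


def cross_validate(
    positives: PeptideSet,
    negative_subset: PeptideSet,
    feature_kind: str = "ODPC",
    svm_config: Optional[SVMConfig] = None,
    k: int = 5,
    seed: int = 0,
    selection_scope: str = "full",
    selection_max_prefix: Optional[int] = None,
) -> MetricsReport:
    """Stratified k-fold cross-validation of one balanced pair.

    For the optimized kinds, ``selection_scope="full"`` (default) runs
    feature selection once on the whole pair before splitting — replicating
    the original protocol — while ``"nested"`` re-selects inside each
    training fold, avoiding selection leakage at extra cost.
    """
    if svm_config is None:
        svm_config = SVMConfig()
    if selection_scope not in ("full", "nested"):
        raise ValueError("selection_scope must be 'full' or 'nested'")
    feature_kind = feature_kind.upper()
    matrix = encode_pair(positives, negative_subset, base_descriptors(feature_kind))
    y = matrix.labels
    optimized = feature_kind in ("OAAC", "ODPC")

    if optimized and selection_scope == "full":
        trace = select_features(
            matrix, svm_config, cv_folds=k, seed=seed, max_prefix=selection_max_prefix
        )
        matrix = matrix.select(trace.selected)

    if optimized and selection_scope == "nested":
        check_binary(y)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        calls = np.empty(len(y), dtype=int)
        scores = np.empty(len(y), dtype=float)
        fold_accs = []
        for train, test in skf.split(matrix.X, y):
            sub = FeatureMatrix(matrix.descriptors, matrix.X[train], [], y[train])
            trace = select_features(
                sub, svm_config, cv_folds=k, seed=seed, max_prefix=selection_max_prefix
            )
            cols = [matrix.descriptors.index(d) for d in trace.selected]
            c, g, _ = grid_search(matrix.X[np.ix_(train, cols)], y[train], svm_config, seed)
            clf = make_svc(c, g, seed=seed).fit(matrix.X[np.ix_(train, cols)], y[train])
            calls[test] = clf.predict(matrix.X[np.ix_(test, cols)])
            scores[test] = clf.decision_function(matrix.X[np.ix_(test, cols)])
            fold_accs.append(float(np.mean(calls[test] == y[test])))
        rep = metrics(confusion(y, calls))
        rep.auc = roc_auc(scores, y).auc
        rep.fold_accuracies = fold_accs
        return rep

    return _cv_on_matrix(matrix.X, y, svm_config, k, seed)


@dataclass
class EnsembleEvaluation:
    """Per-pair CV reports and their across-pair aggregate (Table-style)."""

    per_pair: list[MetricsReport]

    def _agg(self, attr: str) -> tuple[float, float]:
        vals = [getattr(r, attr) for r in self.per_pair]
        return float(np.mean(vals)), (
            float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        )

    @property
    def acc(self) -> float:
        return self._agg("acc")[0]

    def summary(self) -> str:
        rows = []
        for name in ("sn", "sp", "acc"):
            m, s = self._agg(name)
            rows.append(f"{name.capitalize()}={100 * m:.2f}% +/- {100 * s:.2f}%")
        m, s = self._agg("mcc")
        rows.append(f"MCC={m:.2f} +/- {s:.2f}")
        m, s = self._agg("auc")
        rows.append(f"AUC={m:.2f} +/- {s:.2f}")
        return "  ".join(rows)


def evaluate_ensemble(
    positives: PeptideSet,
    negatives: PeptideSet,
    feature_kind: str = "ODPC",
    svm_config: Optional[SVMConfig] = None,
    n_subsets: int = 10,
    k: int = 5,
    seed: int = 0,
    subset_size: Optional[int] = None,
    selection_max_prefix: Optional[int] = None,
) -> EnsembleEvaluation:
    """Cross-validate every downsampled pair and aggregate across pairs.

    The headline accuracy of the ensemble is the mean of the per-pair CV
    accuracies (reported with their standard deviation).
    """
    from .ensemble import downsample_negatives

    if subset_size is None:
        subset_size = len(positives)
    subsets = downsample_negatives(negatives, n_subsets, subset_size, seed)
    rng = np.random.default_rng(seed)
    pair_seeds = rng.integers(0, 2**31 - 1, size=n_subsets)
    reports = [
        cross_validate(
            positives,
            subset,
            feature_kind,
            svm_config,
            k=k,
            seed=int(s),
            selection_max_prefix=selection_max_prefix,
        )
        for subset, s in zip(subsets, pair_seeds)
    ]
    return EnsembleEvaluation(per_pair=reports)


# ---------------------------------------------------------------------------
# Permutation test


@dataclass
class PermutationResult:
    """Label-permutation significance of an observed CV accuracy.

    ``p_value`` is the fraction of permutations whose CV accuracy strictly
    exceeded the observed one; when none did, the true p is below
    1/n_permutations and ``p_is_upper_bound`` is set.
    """

    observed_acc: float
    n_permutations: int
    n_exceeding: int
    p_value: float
    p_is_upper_bound: bool

    @property
    def p_display(self) -> str:
        if self.p_is_upper_bound:
            return f"< {1.0 / self.n_permutations:g}"
        return f"{self.p_value:g}"


def permutation_test(
    positives: PeptideSet,
    negative_subset: PeptideSet,
    feature_kind: str = "DPC",
    svm_config: Optional[SVMConfig] = None,
    n_permutations: int = 1000,
    k: int = 5,
    seed: int = 0,
) -> PermutationResult:
    """Shuffle labels and repeat the full cross-validation each time.

    The optimized kinds re-run feature selection per permutation, so a
    fixed-feature kind (AAC/DPC) with a single-cell grid is the practical
    fast mode for large permutation counts.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if svm_config is None:
        svm_config = SVMConfig.fast()
    feature_kind = feature_kind.upper()
    matrix = encode_pair(positives, negative_subset, base_descriptors(feature_kind))
    y = np.asarray(matrix.labels)

    if feature_kind in ("OAAC", "ODPC"):
        trace = select_features(matrix, svm_config, cv_folds=k, seed=seed)
        matrix = matrix.select(trace.selected)

    observed = _cv_on_matrix(matrix.X, y, svm_config, k, seed).acc
    rng = np.random.default_rng(seed)
    n_exceeding = 0
    for i in range(n_permutations):
        yp = rng.permutation(y)
        if len(np.unique(yp)) < 2:  # pragma: no cover - both classes present
            continue
        acc_perm = _cv_on_matrix(matrix.X, yp, svm_config, k, seed=seed + i + 1).acc
        if acc_perm > observed:
            n_exceeding += 1
    return PermutationResult(
        observed_acc=observed,
        n_permutations=n_permutations,
        n_exceeding=n_exceeding,
        p_value=n_exceeding / n_permutations,
        p_is_upper_bound=(n_exceeding == 0),
    )


# ---------------------------------------------------------------------------
# Independent-set positive rates


def positive_rate(records: Sequence) -> float:
    """Percentage of records called SBP (errors excluded from neither count)."""
    records = list(records)
    if not records:
        raise ValueError("no prediction records")
    n_sbp = sum(1 for r in records if getattr(r, "call", r) == "SBP")
    return 100.0 * n_sbp / len(records)


@dataclass
class RateComparison:
    """Chi-square comparison of two positive rates from 2x2 counts."""

    counts_a: tuple[int, int]
    counts_b: tuple[int, int]
    rate_a: float
    rate_b: float
    chi_square_statistic: float
    p_value: float


def compare_rates(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> RateComparison:
    """Pearson chi-square (1 df, no continuity correction) on positive counts.

    ``counts_* = (positives, total)``.  A degenerate table (all peptides
    positive or all negative overall) yields statistic 0 and p = 1 with a
    warning.
    """
    (pa, na), (pb, nb) = counts_a, counts_b
    if na <= 0 or nb <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= pa <= na and 0 <= pb <= nb):
        raise ValueError("positive counts must lie within the totals")
    table = np.array([[pa, na - pa], [pb, nb - pb]])
    if np.any(table.sum(axis=0) == 0):
        warnings.warn("degenerate 2x2 table (a zero column); reporting p = 1")
        stat, p = 0.0, 1.0
    else:
        res = chi2_contingency(table, correction=False)
        stat, p = float(res.statistic), float(res.pvalue)
    return RateComparison(
        counts_a=counts_a,
        counts_b=counts_b,
        rate_a=100.0 * pa / na,
        rate_b=100.0 * pb / nb,
        chi_square_statistic=stat,
        p_value=p,
    )
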