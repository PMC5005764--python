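"""The undersampling voting ensemble of RBF-SVM submodels.

Class imbalance (few hundred binders vs. >10k non-binders) is handled by
drawing several random negative subsets of the positive-set size, training
one RBF-SVM per balanced pair, and aggregating: each submodel emits a
calibrated probability that a peptide binds streptavidin, the ensemble
reports the arithmetic mean, the number of submodels voting >= 0.5, and a
binary call at a user threshold ``tp`` (default 0.5) on the mean.

Submodels are calibrated by a Platt sigmoid fitted on stratified
cross-validated decision values, then serialized (support vectors, dual
coefficients, intercept, sigmoid A/B) into a versioned JSON text file;
prediction always runs through the package's own RBF + sigmoid arithmetic
on that state, so save -> load round-trips are bit-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._svm import SVMConfig, check_binary, grid_search, make_svc
from .feature_selection import SelectionTrace, select_features
from .features import (
    FeatureDescriptor,
    FeatureMatrix,
    base_descriptors,
    encode,
    encode_pair,
)
from .peptide_io import Peptide, PeptideSet

MODEL_FORMAT = "sbpred-ensemble"
MODEL_VERSION = 1

OPTIMIZED_KINDS = {"OAAC", "ODPC"}
FEATURE_KINDS = {"AAC", "OAAC", "DPC", "ODPC"}


# ---------------------------------------------------------------------------
# Platt sigmoid calibration (libsvm-style, on cross-validated decision values)


def platt_fit(decision_values: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit sigmoid P(y=1 | f) = 1 / (1 + exp(A f + B)) by Newton's method.

    Uses the regularized targets (N+ + 1)/(N+ + 2) and 1/(N- + 2) so the
    fit is well-behaved even when the decision values separate the classes
    perfectly.
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(y)
    prior1 = int(np.sum(y == 1))
    prior0 = len(y) - prior1
    hi = (prior1 + 1.0) / (prior1 + 2.0)
    lo = 1.0 / (prior0 + 2.0)
    t = np.where(y == 1, hi, lo)

    A, B = 0.0, math.log((prior0 + 1.0) / (prior1 + 1.0))
    max_iter, min_step, sigma, eps = 100, 1e-10, 1e-12, 1e-5

    def objective(a: float, b: float) -> float:
        fab = a * f + b
        # stable log(1 + exp(.)) split by sign
        return float(
            np.sum(
                np.where(
                    fab >= 0,
                    t * fab + np.log1p(np.exp(-fab)),
                    (t - 1.0) * fab + np.log1p(np.exp(fab)),
                )
            )
        )

    fval = objective(A, B)
    for _ in range(max_iter):
        fab = A * f + B
        p = np.where(
            fab >= 0,
            np.exp(-fab) / (1.0 + np.exp(-fab)),
            1.0 / (1.0 + np.exp(fab)),
        )
        q = 1.0 - p
        d1 = t - p
        d2 = p * q
        g1 = float(np.sum(f * d1))
        g2 = float(np.sum(d1))
        if abs(g1) < eps and abs(g2) < eps:
            break
        h11 = float(np.sum(f * f * d2)) + sigma
        h22 = float(np.sum(d2)) + sigma
        h21 = float(np.sum(f * d2))
        det = h11 * h22 - h21 * h21
        dA = -(h22 * g1 - h21 * g2) / det
        dB = -(-h21 * g1 + h11 * g2) / det
        gd = g1 * dA + g2 * dB
        step = 1.0
        while step >= min_step:
            newA, newB = A + step * dA, B + step * dB
            newf = objective(newA, newB)
            if newf < fval + 1e-4 * step * gd:
                A, B, fval = newA, newB, newf
                break
            step /= 2.0
        else:
            break
    return A, B


def _sigmoid_prob(decision_values: np.ndarray, a: float, b: float) -> np.ndarray:
    fab = a * np.asarray(decision_values, dtype=float) + b
    return np.where(
        fab >= 0,
        np.exp(-fab) / (1.0 + np.exp(-fab)),
        1.0 / (1.0 + np.exp(fab)),
    )


# ---------------------------------------------------------------------------
# Submodel


@dataclass
class Submodel:
    """One trained, calibrated RBF-SVM on a balanced positive/negative pair."""

    index: int
    feature_kind: str
    selected_features: list[FeatureDescriptor]
    chosen_c: float
    chosen_g: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    platt_a: float
    platt_b: float
    negative_subset_ids: list[str]
    grid_cv_accuracy: float = float("nan")
    selection_trace: Optional[SelectionTrace] = None

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """RBF decision values; positive values favor the binder class."""
        d2 = (
            np.sum(X**2, axis=1)[:, None]
            + np.sum(self.support_vectors**2, axis=1)[None, :]
            - 2.0 * X @ self.support_vectors.T
        )
        K = np.exp(-self.chosen_g * np.maximum(d2, 0.0))
        return K @ self.dual_coef + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Calibrated probability of being a binder, one value per row."""
        return _sigmoid_prob(self.decision_function(X), self.platt_a, self.platt_b)


def _cv_decision_values(
    X: np.ndarray, y: np.ndarray, c: float, g: float, folds: int, seed: int
) -> np.ndarray:
    """Held-out decision values from a seeded stratified k-fold split."""
    dec = np.empty(len(y), dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y):
        clf = make_svc(c, g, seed=seed)
        clf.fit(X[train], y[train])
        dec[test] = clf.decision_function(X[test])
    return dec


def train_submodel(
    positives: PeptideSet,
    negative_subset: PeptideSet,
    feature_kind: str = "ODPC",
    svm_config: Optional[SVMConfig] = None,
    selection_enabled: Optional[bool] = None,
    seed: int = 0,
    index: int = 1,
    selection_cv_folds: int = 5,
    selection_max_prefix: Optional[int] = None,
    calibration_folds: int = 5,
) -> Submodel:
    """Train one submodel on a (typically balanced) positive/negative pair.

    For the optimized kinds (OAAC/ODPC) accuracy-ranked forward selection is
    run on this pair first; then (c, g) are grid-searched by CV accuracy,
    the final SVM is fitted on the whole pair, and a Platt sigmoid is
    calibrated on stratified cross-validated decision values.
    """
    feature_kind = feature_kind.upper()
    if feature_kind not in FEATURE_KINDS:
        raise ValueError(f"unknown feature kind {feature_kind!r}")
    if svm_config is None:
        svm_config = SVMConfig()
    if selection_enabled is None:
        selection_enabled = feature_kind in OPTIMIZED_KINDS

    overlap = set(positives.sequences()) & set(negative_subset.sequences())
    if overlap:
        raise ValueError(
            f"positive and negative sets share {len(overlap)} sequence(s); "
            "remove the overlap before training"
        )

    matrix = encode_pair(positives, negative_subset, base_descriptors(feature_kind))
    y = matrix.labels
    check_binary(y)

    trace: Optional[SelectionTrace] = None
    if selection_enabled:
        trace = select_features(
            matrix,
            svm_config,
            cv_folds=selection_cv_folds,
            seed=seed,
            max_prefix=selection_max_prefix,
        )
        matrix = matrix.select(trace.selected)

    c, g, grid_acc = grid_search(matrix.X, y, svm_config, seed)

    dec = _cv_decision_values(matrix.X, y, c, g, calibration_folds, seed)
    a, b = platt_fit(dec, y)

    clf = make_svc(c, g, seed=seed).fit(matrix.X, y)
    # sklearn binary convention: decision > 0 favors classes_[1] == 1
    return Submodel(
        index=index,
        feature_kind=feature_kind,
        selected_features=list(matrix.descriptors),
        chosen_c=c,
        chosen_g=g,
        support_vectors=np.array(clf.support_vectors_, dtype=float),
        dual_coef=np.array(clf.dual_coef_[0], dtype=float),
        intercept=float(clf.intercept_[0]),
        platt_a=a,
        platt_b=b,
        negative_subset_ids=negative_subset.ids(),
        grid_cv_accuracy=grid_acc,
        selection_trace=trace,
    )


# ---------------------------------------------------------------------------
# Downsampling and the ensemble


def downsample_negatives(
    negatives: PeptideSet,
    n_subsets: int = 10,
    subset_size: Optional[int] = None,
    seed: int = 0,
) -> list[PeptideSet]:
    """Draw ``n_subsets`` independent random negative subsets.

    Each subset samples ``subset_size`` peptides uniformly without
    replacement; different subsets are drawn independently, so a negative
    peptide may appear in several of them.
    """
    if subset_size is None:
        raise ValueError("subset_size is required (defaults to the positive-set size)")
    if subset_size > len(negatives):
        raise ValueError(
            f"subset_size {subset_size} exceeds the negative set size {len(negatives)}"
        )
    rng = np.random.default_rng(seed)
    subsets = []
    for _ in range(n_subsets):
        idx = rng.choice(len(negatives), size=subset_size, replace=False)
        subsets.append(
            PeptideSet([negatives[int(i)] for i in idx], label=negatives.label)
        )
    return subsets


@dataclass
class EnsembleModel:
    """A voting ensemble of submodels sharing one feature kind."""

    submodels: list[Submodel]
    feature_kind: str
    default_tp: float = 0.5
    version: int = MODEL_VERSION
    seed: Optional[int] = None
    n_positives: Optional[int] = None
    n_negatives: Optional[int] = None

    @property
    def n_subsets(self) -> int:
        return len(self.submodels)

    def consensus_features(self, min_votes: Optional[int] = None) -> list[FeatureDescriptor]:
        """Descriptors selected by at least ``min_votes`` submodels.

        Default threshold: half the submodels, rounded up.  This collapses
        the per-pair selections into one reported feature set.
        """
        if min_votes is None:
            min_votes = (len(self.submodels) + 1) // 2
        counts: dict[FeatureDescriptor, int] = {}
        for sm in self.submodels:
            for d in sm.selected_features:
                counts[d] = counts.get(d, 0) + 1
        return sorted(d for d, n in counts.items() if n >= min_votes)


def train_ensemble(
    positives: PeptideSet,
    negatives: PeptideSet,
    feature_kind: str = "ODPC",
    svm_config: Optional[SVMConfig] = None,
    n_subsets: int = 10,
    seed: int = 0,
    subset_size: Optional[int] = None,
    selection_cv_folds: int = 5,
    selection_max_prefix: Optional[int] = None,
) -> EnsembleModel:
    """Downsample the negatives and train one submodel per balanced pair."""
    if subset_size is None:
        subset_size = len(positives)
    subsets = downsample_negatives(negatives, n_subsets, subset_size, seed)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_subsets)
    submodels = [
        train_submodel(
            positives,
            subset,
            feature_kind,
            svm_config,
            seed=int(s),
            index=i + 1,
            selection_cv_folds=selection_cv_folds,
            selection_max_prefix=selection_max_prefix,
        )
        for i, (subset, s) in enumerate(zip(subsets, sub_seeds))
    ]
    return EnsembleModel(
        submodels=submodels,
        feature_kind=feature_kind.upper(),
        seed=seed,
        n_positives=len(positives),
        n_negatives=len(negatives),
    )


# ---------------------------------------------------------------------------
# Prediction


@dataclass
class PredictionRecord:
    """Per-peptide ensemble output."""

    id: str
    sequence: str
    submodel_probabilities: list[float] = field(default_factory=list)
    mean_probability: float = float("nan")
    votes: int = 0
    call: str = "non-SBP"
    error: Optional[str] = None


#: Submodel vote threshold, fixed independently of the user's tp.
VOTE_THRESHOLD = 0.5


def predict(
    model: EnsembleModel, peptides: PeptideSet, tp: float = 0.5
) -> list[PredictionRecord]:
    """Score peptides: per-submodel probabilities, mean, votes, call.

    ``call`` is "SBP" iff the mean probability is >= ``tp``; votes count
    submodels whose probability is >= 0.5 regardless of ``tp``.  Peptides
    too short to encode yield an error record instead of raising.
    """
    if not 0.0 <= tp <= 1.0:
        raise ValueError("tp must be in [0, 1]")
    base = base_descriptors(model.feature_kind)
    min_len = 2 if base[0].kind == "DPC" else 1

    records = []
    encodable = []
    for p in peptides:
        if len(p.sequence) < min_len:
            records.append(
                PredictionRecord(
                    p.id,
                    p.sequence,
                    error=f"sequence too short for {model.feature_kind} encoding",
                )
            )
        else:
            records.append(PredictionRecord(p.id, p.sequence))
            encodable.append(p)

    if encodable:
        full = encode(PeptideSet(encodable), base)
        probs = np.column_stack(
            [
                sm.predict_proba(full.select(sm.selected_features).X)
                for sm in model.submodels
            ]
        )
        it = iter(range(len(encodable)))
        for rec in records:
            if rec.error is not None:
                continue
            row = probs[next(it)]
            rec.submodel_probabilities = [float(v) for v in row]
            rec.mean_probability = float(np.mean(row))
            rec.votes = int(np.sum(row >= VOTE_THRESHOLD))
            rec.call = "SBP" if rec.mean_probability >= tp else "non-SBP"
    return records


# ---------------------------------------------------------------------------
# Persistence


def save_model(model: EnsembleModel, path: str | Path) -> None:
    """Write the ensemble as a versioned, self-contained JSON text file."""
    doc = {
        "format": MODEL_FORMAT,
        "version": model.version,
        "feature_kind": model.feature_kind,
        "default_tp": model.default_tp,
        "seed": model.seed,
        "n_positives": model.n_positives,
        "n_negatives": model.n_negatives,
        "submodels": [
            {
                "index": sm.index,
                "feature_kind": sm.feature_kind,
                "selected_tokens": [d.token for d in sm.selected_features],
                "chosen_c": sm.chosen_c,
                "chosen_g": sm.chosen_g,
                "support_vectors": sm.support_vectors.tolist(),
                "dual_coef": sm.dual_coef.tolist(),
                "intercept": sm.intercept,
                "platt_a": sm.platt_a,
                "platt_b": sm.platt_b,
                "negative_subset_ids": sm.negative_subset_ids,
                "grid_cv_accuracy": sm.grid_cv_accuracy,
            }
            for sm in model.submodels
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> EnsembleModel:
    """Load a model file written by :func:`save_model`.

    Raises ``ValueError`` on a truncated/corrupt file or a version mismatch.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: corrupt or truncated model file: {e}") from e
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise ValueError(f"{path}: not a {MODEL_FORMAT} model file")
    if doc.get("version") != MODEL_VERSION:
        raise ValueError(
            f"{path}: model version {doc.get('version')} not supported "
            f"(expected {MODEL_VERSION})"
        )
    kind_token = {"AAC": "AAC", "OAAC": "AAC", "DPC": "DPC", "ODPC": "DPC"}
    submodels = []
    for sd in doc["submodels"]:
        base_kind = kind_token[sd["feature_kind"]]
        submodels.append(
            Submodel(
                index=sd["index"],
                feature_kind=sd["feature_kind"],
                selected_features=[
                    FeatureDescriptor(base_kind, t) for t in sd["selected_tokens"]
                ],
                chosen_c=sd["chosen_c"],
                chosen_g=sd["chosen_g"],
                support_vectors=np.array(sd["support_vectors"], dtype=float),
                dual_coef=np.array(sd["dual_coef"], dtype=float),
                intercept=sd["intercept"],
                platt_a=sd["platt_a"],
                platt_b=sd["platt_b"],
                negative_subset_ids=list(sd["negative_subset_ids"]),
                grid_cv_accuracy=sd.get("grid_cv_accuracy", float("nan")),
            )
        )
    return EnsembleModel(
        submodels=submodels,
        feature_kind=doc["feature_kind"],
        default_tp=doc["default_tp"],
        version=doc["version"],
        seed=doc.get("seed"),
        n_positives=doc.get("n_positives"),
        n_negatives=doc.get("n_negatives"),
    )
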