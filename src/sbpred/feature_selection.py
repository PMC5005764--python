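"""Accuracy-ranked forward feature selection producing OAAC/ODPC subsets.

Three steps: (i) score every descriptor alone by cross-validated classifier
accuracy; (ii) rank descriptors by that accuracy (descending, ties broken
lexicographically by token); (iii) grow prefixes of the ranking one feature
at a time, evaluating each prefix by the same CV accuracy, and keep the
smallest prefix attaining the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._svm import SVMConfig, check_binary, subset_cv_accuracy
from .features import FeatureDescriptor, FeatureMatrix


@dataclass(frozen=True)
class RankedFeature:
    """A descriptor with its single-feature CV accuracy."""

    descriptor: FeatureDescriptor
    solo_accuracy: float


@dataclass
class SelectionTrace:
    """Full audit of one forward-selection run.

    ``selected`` is always a prefix of ``ranked``; ``selected_accuracy``
    equals ``max(prefix_accuracies)`` exactly.
    """

    ranked: list[RankedFeature]
    prefix_accuracies: list[float]
    selected: list[FeatureDescriptor]
    selected_accuracy: float

    def to_tsv(self, path: str | Path) -> None:
        lines = ["rank\ttoken\tsolo_accuracy\tprefix_accuracy"]
        for i, rf in enumerate(self.ranked):
            pa = (
                f"{self.prefix_accuracies[i]:.6f}"
                if i < len(self.prefix_accuracies)
                else "NA"
            )
            lines.append(
                f"{i + 1}\t{rf.descriptor.token}\t{rf.solo_accuracy:.6f}\t{pa}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def score_single_features(
    matrix: FeatureMatrix,
    classifier_config: SVMConfig,
    cv_folds: int = 5,
    seed: int = 0,
) -> list[RankedFeature]:
    """CV accuracy of each descriptor alone, sorted descending.

    Ties are ordered lexicographically by token so the ranking is
    deterministic.
    """
    if matrix.labels is None:
        raise ValueError("matrix has no labels")
    y = np.asarray(matrix.labels)
    check_binary(y)
    scored = []
    for j, d in enumerate(matrix.descriptors):
        acc = subset_cv_accuracy(
            matrix.X[:, j : j + 1], y, classifier_config, cv_folds, seed
        )
        scored.append(RankedFeature(d, acc))
    scored.sort(key=lambda rf: (-rf.solo_accuracy, rf.descriptor.token))
    return scored


def forward_select(
    ranked: Sequence[RankedFeature],
    matrix: FeatureMatrix,
    classifier_config: SVMConfig,
    cv_folds: int = 5,
    seed: int = 0,
    max_prefix: Optional[int] = None,
) -> SelectionTrace:
    """Evaluate prefixes {top-1}, {top-2}, ... and keep the best one.

    ``selected`` is the smallest prefix attaining the maximum CV accuracy
    (ties favor fewer features).  ``max_prefix`` optionally caps the search
    at the top-ranked features for large descriptor spaces; the default
    evaluates every prefix.
    """
    if not ranked:
        raise ValueError("ranked feature list is empty")
    if matrix.labels is None:
        raise ValueError("matrix has no labels")
    y = np.asarray(matrix.labels)
    check_binary(y)

    pos = {d: i for i, d in enumerate(matrix.descriptors)}
    order = [pos[rf.descriptor] for rf in ranked]
    limit = len(order) if max_prefix is None else min(max_prefix, len(order))

    prefix_accuracies: list[float] = []
    for k in range(1, limit + 1):
        acc = subset_cv_accuracy(
            matrix.X[:, order[:k]], y, classifier_config, cv_folds, seed
        )
        prefix_accuracies.append(acc)

    best_k = int(np.argmax(prefix_accuracies)) + 1  # argmax -> smallest prefix
    return SelectionTrace(
        ranked=list(ranked),
        prefix_accuracies=prefix_accuracies,
        selected=[rf.descriptor for rf in ranked[:best_k]],
        selected_accuracy=prefix_accuracies[best_k - 1],
    )


def select_features(
    matrix: FeatureMatrix,
    classifier_config: SVMConfig,
    cv_folds: int = 5,
    seed: int = 0,
    max_prefix: Optional[int] = None,
) -> SelectionTrace:
    """Convenience wrapper: rank all descriptors, then forward-select."""
    ranked = score_single_features(matrix, classifier_config, cv_folds, seed)
    return forward_select(
        ranked, matrix, classifier_config, cv_folds, seed, max_prefix
    )
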