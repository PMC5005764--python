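"""Shared low-level RBF-SVM machinery: configuration, CV accuracy, grid search.

Kept private so both feature selection and the ensemble can use one seeded,
tie-break-deterministic implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

# The canonical libsvm practical-guide grid.
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**k for k in range(-5, 16, 2))
DEFAULT_G_GRID: tuple[float, ...] = tuple(2.0**k for k in range(-15, 4, 2))


@dataclass
class SVMConfig:
    """RBF-SVM hyperparameter search configuration.

    ``c_grid`` and ``g_grid`` are the regularization and kernel-width
    candidates for grid search (ties broken toward the smallest c, then the
    smallest g).  ``search_grid_in_selection`` controls whether the grid is
    re-run for every feature-selection evaluation (the default) or the first
    grid cell is used as a fixed fast setting.
    """

    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    g_grid: tuple[float, ...] = DEFAULT_G_GRID
    cv_folds_for_grid: int = 5
    search_grid_in_selection: bool = True
    kernel: str = "rbf"  # fixed; recorded for model files
    probability_calibration: str = "sigmoid-on-decision-values"

    def __post_init__(self) -> None:
        self.c_grid = tuple(sorted(float(c) for c in self.c_grid))
        self.g_grid = tuple(sorted(float(g) for g in self.g_grid))
        if not self.c_grid or not self.g_grid:
            raise ValueError("c_grid and g_grid must be nonempty")
        if min(self.c_grid) <= 0 or min(self.g_grid) <= 0:
            raise ValueError("all c and g values must be positive")

    @classmethod
    def fast(cls, c: float = 8.0, g: float = 8.0) -> "SVMConfig":
        """Single-cell grid: a fixed (c, g) with no search."""
        return cls(c_grid=(c,), g_grid=(g,), search_grid_in_selection=False)

    @classmethod
    def reduced(cls) -> "SVMConfig":
        """A coarse 3x3 grid for benchmark-scale runs on one CPU."""
        return cls(
            c_grid=(2.0**-1, 2.0**3, 2.0**7),
            g_grid=(2.0**-3, 2.0**1, 2.0**3),
            search_grid_in_selection=False,
        )


def make_svc(c: float, g: float, seed: int = 0) -> SVC:
    return SVC(kernel="rbf", C=c, gamma=g, random_state=seed)


def check_binary(y: np.ndarray) -> None:
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; need both 0 and 1")


def cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    c: float,
    g: float,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean stratified k-fold CV accuracy of an RBF-SVM at fixed (c, g).

    The fold partition depends only on (y, folds, seed), so evaluations of
    different feature subsets see identical folds.
    """
    check_binary(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, y):
        clf = make_svc(c, g, seed=seed)
        clf.fit(X[train], y[train])
        accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
    return float(np.mean(accs))


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    config: SVMConfig,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Pick (c, g) maximizing CV accuracy; ties -> smallest c, then smallest g.

    Returns ``(c, g, accuracy)``.
    """
    best: tuple[float, float, float] | None = None
    for c in config.c_grid:
        for g in config.g_grid:
            acc = cv_accuracy(X, y, c, g, config.cv_folds_for_grid, seed)
            if best is None or acc > best[2]:
                best = (c, g, acc)
    assert best is not None
    return best


def subset_cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    config: SVMConfig,
    cv_folds: int,
    seed: int,
) -> float:
    """CV accuracy of a feature subset, with or without grid re-search.

    Used by feature selection: when ``search_grid_in_selection`` is off the
    middle grid cell serves as the fixed (c, g), so a coarse grid still
    evaluates subsets at a sane operating point.
    """
    if config.search_grid_in_selection and (
        len(config.c_grid) > 1 or len(config.g_grid) > 1
    ):
        cfg = SVMConfig(
            c_grid=config.c_grid,
            g_grid=config.g_grid,
            cv_folds_for_grid=cv_folds,
        )
        return grid_search(X, y, cfg, seed)[2]
    c = config.c_grid[len(config.c_grid) // 2]
    g = config.g_grid[len(config.g_grid) // 2]
    return cv_accuracy(X, y, c, g, cv_folds, seed)
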