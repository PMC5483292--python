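"""Cross-validated two-group SVM classification on PCA-reduced features.

Four kernel presets are swept over retained-component counts 8–12:
linear, quadratic (polynomial degree 2), cubic (polynomial degree 3) and
"medium Gaussian" (RBF with length-scale sqrt(k), i.e. gamma = 1/k for k
features).  All use a unit box constraint and features standardized with
training-fold statistics only.  Accuracy is the percentage of correctly
classified held-out subjects over a stratified k-fold split, so every
reported value is a multiple of 100/N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import FeatureMatrix, ThermofaceError
from .stats import pca_reduce

KERNEL_NAMES = ("linear", "quadratic", "cubic", "medium_gaussian")


class ClassifyError(ThermofaceError):
    pass


def make_svm(kernel: str, n_features: int, C: float = 1.0) -> SVC:
    """SVC preset for one of the four named kernels."""
    gamma = 1.0 / n_features  # length-scale sqrt(k)
    if kernel == "linear":
        return SVC(kernel="linear", C=C)
    if kernel == "quadratic":
        return SVC(kernel="poly", degree=2, gamma=gamma, coef0=1.0, C=C)
    if kernel == "cubic":
        return SVC(kernel="poly", degree=3, gamma=gamma, coef0=1.0, C=C)
    if kernel == "medium_gaussian":
        return SVC(kernel="rbf", gamma=gamma, C=C)
    raise ClassifyError(f"unknown kernel {kernel!r}; expected one of {KERNEL_NAMES}")


@dataclass
class CvReport:
    """Stratified cross-validation outcome for one kernel and one k."""

    kernel: str
    k_features: int
    fold_assignments: np.ndarray  # fold index per subject
    fold_accuracies: list[float]  # per-fold, %
    accuracy: float  # overall, % of correctly classified subjects


def _check_folds(y: np.ndarray, folds: int) -> None:
    _, counts = np.unique(y, return_counts=True)
    if len(counts) < 2:
        raise ClassifyError("both groups must be present")
    if folds > counts.min():
        raise ClassifyError(
            f"{folds} folds exceed the smaller group size {counts.min()}: use fewer folds"
        )


def cv_accuracy(
    reduced: FeatureMatrix,
    kernel: str = "medium_gaussian",
    folds: int = 5,
    seed: int = 0,
    pca_k: int | None = None,
) -> CvReport:
    """Stratified k-fold accuracy of one SVM kernel on a reduced block.

    With ``pca_k`` set, the block is treated as raw features and PCA to
    ``pca_k`` components is re-fit inside each training fold (leakage-safe
    mode); otherwise the block is used as-is.  Deterministic given ``seed``.
    """
    X, y = reduced.values, reduced.labels
    _check_folds(y, folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignments = np.full(len(y), -1)
    fold_acc: list[float] = []
    n_correct = 0
    k_eff = pca_k if pca_k is not None else X.shape[1]
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        assignments[te] = fold
        if len(set(y[tr].tolist())) < 2:
            raise ClassifyError("degenerate fold with a single class: use fewer folds")
        Xtr, Xte = X[tr], X[te]
        if pca_k is not None:
            model, red_tr = pca_reduce(
                FeatureMatrix(Xtr, y[tr], reduced.roi, reduced.emotion), k=pca_k
            )
            Xtr, Xte = red_tr.values, model.transform(Xte)
        clf = make_pipeline(StandardScaler(), make_svm(kernel, k_eff))
        clf.fit(Xtr, y[tr])
        correct = int((clf.predict(Xte) == y[te]).sum())
        n_correct += correct
        fold_acc.append(100.0 * correct / len(te))
    return CvReport(
        kernel=kernel,
        k_features=k_eff,
        fold_assignments=assignments,
        fold_accuracies=fold_acc,
        accuracy=100.0 * n_correct / len(y),
    )


def permutation_null_accuracy(
    reduced: FeatureMatrix,
    kernel: str = "medium_gaussian",
    folds: int = 5,
    n_permutations: int = 50,
    seed: int = 0,
) -> float:
    """Mean CV accuracy over label permutations (chance level, %)."""
    rng = np.random.default_rng(seed)
    accs = []
    for i in range(n_permutations):
        perm = rng.permutation(len(reduced.labels))
        fm = FeatureMatrix(
            reduced.values, reduced.labels[perm], reduced.roi, reduced.emotion
        )
        accs.append(cv_accuracy(fm, kernel, folds, seed=int(rng.integers(2**31 - 1))).accuracy)
    return float(np.mean(accs))


def sweep_feature_counts(
    block: FeatureMatrix,
    k_values: Sequence[int] = (8, 9, 10, 11, 12),
    kernels: Sequence[str] = KERNEL_NAMES,
    folds: int = 5,
    seed: int = 0,
    leakage_safe: bool = False,
) -> pd.DataFrame:
    """Kernel x component-count accuracy grid for one raw feature block.

    By default PCA is fit on the full block before cross-validation,
    mirroring the sequential reduce-then-classify protocol; pass
    ``leakage_safe=True`` to re-fit PCA inside each training fold (the
    methodologically preferred option).  Returns a DataFrame with kernels
    as rows and k values as columns, accuracies in %.
    """
    n, p = block.values.shape
    if max(k_values) > min(n - 1, p):
        raise ClassifyError(f"max k {max(k_values)} exceeds min(n-1, p) = {min(n - 1, p)}")
    grid = pd.DataFrame(index=list(kernels), columns=list(k_values), dtype=float)
    for k in k_values:
        if leakage_safe:
            use, pk = block, k
        else:
            _, use = pca_reduce(block, k=k)
            pk = None
        for kernel in kernels:
            grid.loc[kernel, k] = cv_accuracy(use, kernel, folds, seed, pca_k=pk).accuracy
    grid.index.name = "kernel"
    grid.columns.name = "k"
    return grid
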