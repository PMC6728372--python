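"""Condition-ordered run averaging and nested cross-validated direction decoding.

Per participant and factor, the 96 trial betas of each run are grouped by the
to-be-decoded direction label, the within-direction order is permuted
independently per run (a seeded random pairing, chosen to weaken signal tied
to any other condition), and the three runs are averaged position-wise. The
result is 96 samples, 24 per direction, each the mean of one trial per run.

Decoding is a 4-way linear support vector classifier with L2 regularisation.
Accuracy is estimated with three outer stratified shuffle-splits holding out
20% of the samples; within each outer training set, a 3-fold stratified grid
search over C in {1, 10, 100, 1000} selects the regularisation strength (ties
broken toward the smallest C), and the classifier is refit on the full outer
training set before scoring the held-out samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import LinearSVC

from .design import DIRECTIONS
from .glm import TrialBetas

__all__ = ["SampleSet", "DecodingScore", "order_and_average", "nested_cv_accuracy", "C_GRID"]

#: regularisation grid, 1 to 10^3 in powers of ten
C_GRID = (1.0, 10.0, 100.0, 1000.0)

CHANCE_LEVEL = 1.0 / len(DIRECTIONS)


@dataclass
class SampleSet:
    """Run-averaged multivoxel samples with direction labels for one factor."""

    factor: str
    samples: np.ndarray  # (96, n_voxels)
    labels: np.ndarray  # (96,) strings from DIRECTIONS
    averaging_seed: int

    def validate(self) -> None:
        if self.samples.shape[0] != len(self.labels):
            raise ValueError("samples/labels length mismatch")
        _, counts = np.unique(self.labels, return_counts=True)
        if len(set(counts)) != 1:
            raise ValueError("direction labels must be balanced")


@dataclass
class DecodingScore:
    """Nested-CV accuracy for one participant, ROI and factor."""

    participant: int
    roi: str
    factor: str
    fold_accuracies: list[float]
    mean_accuracy: float
    chosen_C: list[float]
    cv_seed: int
    details: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "participant": self.participant,
            "roi": self.roi,
            "factor": self.factor,
            "fold_accuracies": self.fold_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "chosen_C": self.chosen_C,
            "cv_seed": self.cv_seed,
        }


def order_and_average(
    betas_by_run: Mapping[int, TrialBetas],
    labels_by_run: Mapping[int, Sequence[str]],
    factor: str,
    seed: int = 0,
) -> SampleSet:
    """Average trial betas across runs after ordering by condition.

    Within each run, the trials of each direction are randomly permuted
    (independently per run, seeded) and the runs are then averaged
    position-wise, so each of the 96 output samples is the mean of exactly one
    same-direction trial per run.
    """
    runs = sorted(betas_by_run)
    rng = np.random.default_rng(seed)
    per_label_counts = None
    ordered = []
    for run in runs:
        labels = np.asarray(labels_by_run[run])
        betas = betas_by_run[run].betas
        if len(labels) != betas.shape[0]:
            raise ValueError(f"run {run}: labels do not match beta rows")
        counts = {d: int(np.sum(labels == d)) for d in DIRECTIONS}
        if per_label_counts is None:
            per_label_counts = counts
        elif counts != per_label_counts:
            raise ValueError("label marginals differ across runs")
        idx = np.concatenate(
            [rng.permutation(np.where(labels == d)[0]) for d in DIRECTIONS]
        )
        ordered.append(betas[idx])
    samples = np.mean(ordered, axis=0)
    out_labels = np.concatenate(
        [np.repeat(d, per_label_counts[d]) for d in DIRECTIONS]
    )
    ss = SampleSet(factor=factor, samples=samples, labels=out_labels, averaging_seed=seed)
    ss.validate()
    return ss


def _make_svc(C: float) -> LinearSVC:
    return LinearSVC(C=C, max_iter=20000, random_state=0)


def nested_cv_accuracy(
    samples: SampleSet,
    cv_seed: int = 0,
    participant: int = 0,
    roi: str = "roi",
    n_outer: int = 3,
    test_size: float = 0.2,
    inner_folds: int = 3,
    c_grid: Sequence[float] = C_GRID,
    standardize: bool = False,
) -> DecodingScore:
    """Nested cross-validated 4-way decoding accuracy.

    Outer loop: ``n_outer`` stratified shuffle-splits with ``test_size`` held
    out. Inner loop (outer-training data only): stratified ``inner_folds``-fold
    grid search over ``c_grid``; the smallest C attaining the best inner mean
    accuracy is refit on the outer-training set and scored on the held-out
    samples. Set ``standardize`` to z-score features using outer-training
    statistics (off by default; betas come from filtered, residualized data).
    """
    X = np.asarray(samples.samples, dtype=float)
    y = np.asarray(samples.labels)
    outer = StratifiedShuffleSplit(n_splits=n_outer, test_size=test_size, random_state=cv_seed)
    fold_acc: list[float] = []
    chosen: list[float] = []
    details = {"folds": []}
    for train_idx, test_idx in outer.split(X, y):
        Xtr, ytr = X[train_idx], y[train_idx]
        if standardize:
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (X[test_idx] - mu) / sd
        else:
            Xte = X[test_idx]
        inner = StratifiedKFold(n_splits=inner_folds)
        inner_splits = list(inner.split(Xtr, ytr))
        inner_scores = []
        for C in c_grid:
            accs = []
            for itr, ite in inner_splits:
                clf = _make_svc(C).fit(Xtr[itr], ytr[itr])
                accs.append(clf.score(Xtr[ite], ytr[ite]))
            inner_scores.append(np.mean(accs))
        best_C = float(c_grid[int(np.argmax(inner_scores))])  # first max = smallest C
        clf = _make_svc(best_C).fit(Xtr, ytr)
        acc = float(clf.score(Xte, y[test_idx]))
        fold_acc.append(acc)
        chosen.append(best_C)
        details["folds"].append(
            {
                "train_idx": train_idx.tolist(),
                "test_idx": test_idx.tolist(),
                "inner_splits": [(tr.tolist(), te.tolist()) for tr, te in inner_splits],
                "inner_scores": [float(s) for s in inner_scores],
            }
        )
    return DecodingScore(
        participant=participant,
        roi=roi,
        factor=samples.factor,
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        chosen_C=chosen,
        cv_seed=cv_seed,
        details=details,
    )
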