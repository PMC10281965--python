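"""The seven shape-combination SVM screening models.

Each model trains a soft-margin SVM on the per-shape feature triples
(drawing time, average pressure, SPARC) of one non-empty subset of the
three guide shapes — 3 singletons, 3 pairs, and the full set make seven
models. Evaluation is leave-one-out cross-validation: for each held-out
participant the remaining rows are standardized and fitted, and the
held-out signed decision value is recorded; pooling the out-of-fold
values over participants gives one ROC curve per model, its AUC, and an
operating point at the ROC vertex closest to the upper-left corner
(perfect sensitivity and specificity).

Standardization is leakage-free by default: fold ``i`` is scaled by the
mean/SD of the other ``n - 1`` rows only. A ``global`` normalization
mode (scale once on the full matrix) is available because published
pipelines often do the simpler thing without saying so.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _metrics
from sklearn.svm import SVC

from .features import FEATURE_NAMES
from .recordings import SHAPES

logger = logging.getLogger(__name__)

__all__ = ["ModelSpec", "EvalResult", "enumerate_models", "assemble_matrix",
           "loocv_scores", "roc_curve", "auc", "best_threshold",
           "tune_hyperparameters", "evaluate_models", "DEFAULT_C_GRID"]

#: Regularization grid searched when tuning; ascending so ties resolve
#: toward the larger margin.
DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)

POSITIVE_LABEL = "CM"


@dataclass(frozen=True)
class ModelSpec:
    """One screening model: a non-empty subset of guide shapes."""

    shapes: tuple[str, ...]

    def __post_init__(self):
        if not 1 <= len(self.shapes) <= 3:
            raise ValueError("a model uses 1-3 shapes")
        if len(set(self.shapes)) != len(self.shapes):
            raise ValueError("duplicate shapes in model")

    @property
    def name(self) -> str:
        return "+".join(self.shapes)

    @property
    def n_features(self) -> int:
        return 3 * len(self.shapes)


@dataclass
class EvalResult:
    """LOOCV evaluation of one model: pooled decision scores, the ROC
    they trace, its area, and the upper-left operating point."""

    model: ModelSpec
    scores: np.ndarray            # out-of-fold decision values
    labels: np.ndarray            # 1 = CM, 0 = non-CM
    participant_ids: list[str]
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    hyperparams: dict = field(default_factory=dict)
    mode: str = "paper_faithful"
    normalization: str = "per_fold"

    def to_dict(self) -> dict:
        return {
            "model": self.model.name,
            "shapes": list(self.model.shapes),
            "mode": self.mode,
            "normalization": self.normalization,
            "hyperparams": self.hyperparams,
            "auc": float(self.auc),
            "operating_point": {
                "threshold": float(self.threshold),
                "sensitivity": float(self.sensitivity),
                "specificity": float(self.specificity),
            },
            "roc": [{"fpr": float(f), "tpr": float(t), "threshold": float(h)}
                    for f, t, h in zip(self.fpr, self.tpr, self.thresholds)],
            "scores": {pid: float(s) for pid, s in
                       zip(self.participant_ids, self.scores)},
            "labels": {pid: int(y) for pid, y in
                       zip(self.participant_ids, self.labels)},
        }


def enumerate_models(shapes: Iterable[str] = SHAPES) -> list[ModelSpec]:
    """All non-empty shape subsets: singletons first, then pairs, then
    the full set, lexicographic within each size."""
    shapes = sorted(set(shapes))
    if not shapes:
        raise ValueError("need at least one shape")
    out = []
    for size in range(1, len(shapes) + 1):
        for combo in itertools.combinations(shapes, size):
            out.append(ModelSpec(shapes=combo))
    return out


def assemble_matrix(features: pd.DataFrame, model: ModelSpec
                    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Build the participants x (3 per shape) matrix for one model.

    Columns are ordered shape-major: for each shape in the model, its
    DT, AP, SP. Participants missing any required shape are dropped with
    a logged count. Returns ``(X, y, participant_ids)`` with ``y = 1``
    for the CM group.
    """
    wide = features.pivot_table(index="participant_id", columns="shape",
                                values=list(FEATURE_NAMES), aggfunc="first")
    groups = features.drop_duplicates("participant_id").set_index(
        "participant_id")["group"]
    cols = [(feat, shape) for shape in model.shapes
            for feat in FEATURE_NAMES]
    missing_shape = [s for s in model.shapes
                     if s not in wide.columns.get_level_values(1)]
    if missing_shape:
        raise ValueError(f"no recordings at all for shape(s) "
                         f"{missing_shape}")
    sub = wide[cols]
    keep = sub.notna().all(axis=1) & groups.reindex(sub.index).notna()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("model %s: dropped %d participant(s) with "
                       "incomplete shapes or missing labels",
                       model.name, n_drop)
    sub = sub[keep]
    if sub.empty:
        raise ValueError(f"no complete participants for model {model.name}")
    ids = list(sub.index)
    y = (groups.loc[ids] == POSITIVE_LABEL).to_numpy(dtype=int)
    return sub.to_numpy(dtype=float), y, ids


def _fold_standardize(train: np.ndarray, test: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        logger.warning("zero-variance column(s) %s in training fold; "
                       "scale set to 1", np.nonzero(zero)[0].tolist())
        sd = np.where(zero, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _median_heuristic_gamma(x: np.ndarray) -> float:
    """RBF bandwidth from the median pairwise distance of the
    (standardized) training rows: gamma = 1 / (2 * median_dist**2)."""
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    iu = np.triu_indices_from(d2, k=1)
    med2 = float(np.median(d2[iu]))
    if med2 <= 0:
        return 1.0 / x.shape[1]
    return 1.0 / (2.0 * med2)


def loocv_scores(matrix: np.ndarray, labels: np.ndarray,
                 hyperparams: dict | None = None,
                 normalization: str = "per_fold") -> np.ndarray:
    """Out-of-fold SVM decision values under leave-one-out CV.

    For each participant ``i`` the remaining rows are standardized
    (column mean/SD of those rows only, unless
    ``normalization='global'``), an SVM is fitted on them, and the
    signed decision value of row ``i`` is recorded. Positive values lean
    toward the CM class. Deterministic given its inputs.
    """
    hp = {"kernel": "rbf", "C": 1.0, "gamma": "median"}
    hp.update(hyperparams or {})
    x = np.asarray(matrix, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("matrix/labels shape mismatch")
    if np.isnan(x).any():
        raise ValueError("missing values in feature matrix")
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    n = x.shape[0]
    if normalization == "global":
        mu, sd = x.mean(axis=0), x.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        x_global = (x - mu) / sd
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ValueError(f"training fold {i} contains one class only")
        if normalization == "global":
            xtr, xte = x_global[mask], x_global[[i]]
        elif normalization == "per_fold":
            xtr, xte = _fold_standardize(x[mask], x[[i]])
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        gamma = hp["gamma"]
        if gamma == "median":
            gamma = _median_heuristic_gamma(xtr)
        clf = SVC(kernel=hp["kernel"], C=hp["C"], gamma=gamma)
        clf.fit(xtr, y[mask])
        scores[i] = float(clf.decision_function(xte)[0])
    return scores


def roc_curve(scores: Sequence[float], labels: Sequence[int]
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC vertices from pooled decision scores.

    Thresholds sweep the unique score values in descending order with
    ties grouped (one vertex per unique score); the first vertex is
    (0, 0) and the last is (1, 1). Positives are the CM class
    (label 1).
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes")
    fpr, tpr, thr = _metrics.roc_curve(y, np.asarray(scores, dtype=float),
                                       drop_intermediate=False)
    return fpr, tpr, thr


def auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Trapezoidal area under an ROC polyline."""
    return float(np.trapezoid(tpr, fpr))


def best_threshold(fpr: np.ndarray, tpr: np.ndarray,
                   thresholds: np.ndarray) -> tuple[float, float, float]:
    """Operating point: the ROC vertex minimizing the Euclidean distance
    to the upper-left corner (0, 1).

    Ties break toward higher sensitivity, then higher specificity.
    Returns ``(threshold, sensitivity, specificity)``.
    """
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    d = np.hypot(fpr, 1.0 - tpr)
    best = np.flatnonzero(np.isclose(d, d.min(), rtol=0, atol=1e-12))
    order = sorted(best, key=lambda i: (-tpr[i], fpr[i]))
    i = order[0]
    return float(thresholds[i]), float(tpr[i]), float(1.0 - fpr[i])


def _evaluate_at(matrix, labels, ids, model, hp, normalization,
                 mode) -> EvalResult:
    scores = loocv_scores(matrix, labels, hp, normalization)
    fpr, tpr, thr = roc_curve(scores, labels)
    a = auc(fpr, tpr)
    t, sens, spec = best_threshold(fpr, tpr, thr)
    return EvalResult(model=model, scores=scores,
                      labels=np.asarray(labels, dtype=int),
                      participant_ids=list(ids), fpr=fpr, tpr=tpr,
                      thresholds=thr, auc=a, threshold=t, sensitivity=sens,
                      specificity=spec, hyperparams=dict(hp), mode=mode,
                      normalization=normalization)


def tune_hyperparameters(matrix: np.ndarray, labels: np.ndarray,
                         ids: Sequence[str] | None = None,
                         model: ModelSpec | None = None,
                         c_grid: Sequence[float] = DEFAULT_C_GRID,
                         kernel: str = "rbf",
                         mode: str = "paper_faithful",
                         normalization: str = "per_fold") -> EvalResult:
    """Choose the SVM regularization strength over a grid.

    ``paper_faithful`` runs the full LOOCV at every grid point, takes
    each run's upper-left operating point, and keeps the grid point
    maximizing sensitivity + specificity (ties toward smaller C, the
    larger margin). This mirrors tuning on the same cross-validation
    that is reported, so its accuracy estimate is optimistic.
    ``nested`` selects C inside each training fold by an inner LOOCV
    (same objective), so the outer estimate is honest. Both modes label
    their output.
    """
    if not len(c_grid):
        raise ValueError("empty hyperparameter grid")
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if ids is None:
        ids = [str(i) for i in range(matrix.shape[0])]
    if model is None:
        model = ModelSpec(shapes=("spiral",))

    def objective(x, y, c) -> float:
        s = loocv_scores(x, y, {"kernel": kernel, "C": c}, normalization)
        fpr, tpr, thr = roc_curve(s, y)
        _, sens, spec = best_threshold(fpr, tpr, thr)
        return sens + spec

    if mode == "paper_faithful":
        results = [
            _evaluate_at(matrix, labels, ids, model,
                         {"kernel": kernel, "C": c}, normalization, mode)
            for c in c_grid]
        objs = [r.sensitivity + r.specificity for r in results]
        best = int(np.lexsort((c_grid, [-o for o in objs]))[0])
        return results[best]
    if mode == "nested":
        n = matrix.shape[0]
        scores = np.empty(n)
        chosen = []
        if normalization == "global":
            mu, sd = matrix.mean(axis=0), matrix.std(axis=0, ddof=0)
            sd = np.where(sd == 0, 1.0, sd)
            x_global = (matrix - mu) / sd
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            inner_objs = [objective(matrix[mask], labels[mask], c)
                          for c in c_grid]
            c = c_grid[int(np.lexsort((c_grid,
                                       [-o for o in inner_objs]))[0])]
            chosen.append(c)
            xtr, xte = _fold_standardize(matrix[mask], matrix[[i]]) \
                if normalization == "per_fold" else (x_global[mask],
                                                     x_global[[i]])
            gamma = _median_heuristic_gamma(xtr) if kernel == "rbf" else \
                "scale"
            clf = SVC(kernel=kernel, C=c, gamma=gamma)
            clf.fit(xtr, labels[mask])
            scores[i] = float(clf.decision_function(xte)[0])
        fpr, tpr, thr = roc_curve(scores, labels)
        t, sens, spec = best_threshold(fpr, tpr, thr)
        return EvalResult(model=model, scores=scores, labels=labels,
                          participant_ids=list(ids), fpr=fpr, tpr=tpr,
                          thresholds=thr, auc=auc(fpr, tpr), threshold=t,
                          sensitivity=sens, specificity=spec,
                          hyperparams={"kernel": kernel,
                                       "C_per_fold": chosen},
                          mode=mode, normalization=normalization)
    raise ValueError(f"unknown mode {mode!r}")


def evaluate_models(features: pd.DataFrame,
                    shapes: Iterable[str] = SHAPES,
                    c_grid: Sequence[float] = DEFAULT_C_GRID,
                    kernel: str = "rbf",
                    mode: str = "paper_faithful",
                    normalization: str = "per_fold") -> list[EvalResult]:
    """Run the full screening evaluation: every shape-combination model,
    tuned and scored by LOOCV."""
    out = []
    for model in enumerate_models(shapes):
        x, y, ids = assemble_matrix(features, model)
        out.append(tune_hyperparameters(
            x, y, ids=ids, model=model, c_grid=c_grid, kernel=kernel,
            mode=mode, normalization=normalization))
    return out
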