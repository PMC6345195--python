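"""Classifier evaluation: LDA, k-NN and SVM-RBF under leave-one-out or
stratified 10-fold cross-validation, with per-feature unit-norm scaling and
the hyperparameter grids used throughout the study.

Conventions that matter for reproducing the grids:

* The RBF kernel is K(u, v) = exp(-||u - v||^2 / scale^2) — MATLAB
  ``KernelScale`` semantics.  Other parameterizations (e.g. gamma =
  1/(2 scale^2)) shift the scale grid and will not land on the same cells.
* k-NN breaks voting ties (even k, or equidistant neighbors) with the label
  of the single nearest neighbor, deterministically.
* Feature normalization scales every column to unit Euclidean norm.  GLOBAL
  mode fits the scale on the whole cohort; TRAINFOLD fits it on the training
  fold only and applies it to the held-out samples (leakage-safe).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.svm import SVC

from .ingest import ParameterError
from .metrics import ConfusionMatrix, accuracy as cm_accuracy, confusion_from_predictions
from .selection import FeatureMatrix, relieff_rank, select_top

#: DCT coefficient counts explored for the residue method.
L_GRID = (10, 15, 16, 17, 18, 20, 21, 22, 23, 25, 30, 50)
#: Odd neighbor counts explored for k-NN.
KNN_K_GRID = tuple(range(1, 34, 2))
#: SVM box-constraint (cost) grid, 10^-5 .. 10^4.
SVM_COST_GRID = tuple(float(10.0**e) for e in range(-5, 5))
#: SVM kernel-scale grid, 0.1 .. 1.1.
SVM_SCALE_GRID = tuple(round(0.1 * i, 1) for i in range(1, 12))


class Method(str, enum.Enum):
    RESIDUE = "RESIDUE"
    RADIUS = "RADIUS"
    COMBINED = "COMBINED"


class ClassifierKind(str, enum.Enum):
    LDA = "LDA"
    KNN = "KNN"
    SVM_RBF = "SVM_RBF"


class CVMode(str, enum.Enum):
    LOO = "LOO"
    KFOLD10 = "KFOLD10"


class SelectionMode(str, enum.Enum):
    NAMED_SUBSET = "NAMED_SUBSET"  # caller already restricted the columns
    RELIEFF_GLOBAL = "RELIEFF_GLOBAL"  # rank once on the full cohort
    RELIEFF_NESTED = "RELIEFF_NESTED"  # re-rank inside every training fold


class NormMode(str, enum.Enum):
    UNIT_NORM_GLOBAL = "UNIT_NORM_GLOBAL"
    UNIT_NORM_TRAINFOLD = "UNIT_NORM_TRAINFOLD"


@dataclass
class EvalConfig:
    method: Method = Method.RESIDUE
    L: int = 17
    classifier: ClassifierKind = ClassifierKind.SVM_RBF
    knn_k: int = 3
    svm_cost: float = 1e3
    svm_scale: float = 0.2
    cv: CVMode = CVMode.LOO
    selection_mode: SelectionMode = SelectionMode.NAMED_SUBSET
    n_features: int = 5
    normalization: NormMode = NormMode.UNIT_NORM_GLOBAL
    relieff_neighbors: int = 10
    seed: int = 0

    def validate_grids(self) -> None:
        """Warn when hyperparameters lie off the study grids (still allowed)."""
        if self.method is Method.RESIDUE and self.L not in L_GRID:
            warnings.warn(f"L={self.L} is outside the study grid {L_GRID}")
        if self.classifier is ClassifierKind.KNN and self.knn_k not in KNN_K_GRID:
            warnings.warn(f"knn_k={self.knn_k} is outside the study grid")
        if self.classifier is ClassifierKind.SVM_RBF:
            if not np.any(np.isclose(self.svm_cost, SVM_COST_GRID)):
                warnings.warn(f"svm_cost={self.svm_cost} is outside the study grid")
            if not np.any(np.isclose(self.svm_scale, SVM_SCALE_GRID)):
                warnings.warn(f"svm_scale={self.svm_scale} is outside the study grid")

    def to_dict(self) -> dict:
        return {
            k: (v.value if isinstance(v, enum.Enum) else v)
            for k, v in self.__dict__.items()
        }


@dataclass
class CVResult:
    y_true: np.ndarray
    y_pred: np.ndarray
    confusion: ConfusionMatrix
    config: EvalConfig

    @property
    def accuracy(self) -> float:
        return cm_accuracy(self.confusion)


def normalize_features(
    fm: FeatureMatrix, mode: NormMode = NormMode.UNIT_NORM_GLOBAL
) -> tuple[FeatureMatrix, np.ndarray]:
    """Scale each feature column to unit Euclidean norm.

    Returns the scaled matrix and the per-column norms (the transform record);
    zero-norm columns are left as all zeros with a warning.
    """
    norms = np.linalg.norm(fm.values, axis=0)
    if np.any(norms == 0):
        warnings.warn("zero-norm feature column(s) scaled to all zeros")
    safe = np.where(norms == 0, 1.0, norms)
    out = replace(fm, values=fm.values / safe)
    return out, norms


def _knn_predict(
    x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray, k: int
) -> np.ndarray:
    """Euclidean k-NN, majority vote, ties decided by the nearest neighbor."""
    d = cdist(x_test, x_train)
    order = np.argsort(d, axis=1, kind="stable")[:, : min(k, x_train.shape[0])]
    preds = []
    for row in order:
        votes = y_train[row]
        labs, counts = np.unique(votes, return_counts=True)
        top = labs[counts == counts.max()]
        preds.append(top[0] if len(top) == 1 else votes[0])
    return np.asarray(preds)


def _fit_predict(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    cfg: EvalConfig,
) -> np.ndarray:
    if len(np.unique(y_train)) < 2:
        raise ParameterError("a class is absent from the training fold")
    if cfg.classifier is ClassifierKind.LDA:
        clf = LinearDiscriminantAnalysis()  # pooled covariance, empirical priors
        clf.fit(x_train, y_train)
        return clf.predict(x_test)
    if cfg.classifier is ClassifierKind.KNN:
        return _knn_predict(x_train, y_train, x_test, cfg.knn_k)
    if cfg.classifier is ClassifierKind.SVM_RBF:
        clf = SVC(C=cfg.svm_cost, kernel="rbf", gamma=1.0 / cfg.svm_scale**2)
        clf.fit(x_train, y_train)
        return clf.predict(x_test)
    raise ParameterError(f"unknown classifier {cfg.classifier}")


def _run_cv(fm: FeatureMatrix, cfg: EvalConfig, splits) -> CVResult:
    x_all = fm.values
    y = fm.labels
    if cfg.normalization is NormMode.UNIT_NORM_GLOBAL:
        fm_g, _ = normalize_features(fm)
        x_all = fm_g.values
    if cfg.selection_mode is SelectionMode.RELIEFF_GLOBAL:
        rank = relieff_rank(fm, cfg.relieff_neighbors, cfg.seed)
        cols_global = select_top(rank, cfg.n_features)
    else:
        cols_global = list(range(fm.n_features))

    y_pred = np.empty(fm.n_samples, dtype=y.dtype)
    seen = np.zeros(fm.n_samples, dtype=bool)
    for train, test in splits:
        if cfg.selection_mode is SelectionMode.RELIEFF_NESTED:
            sub = FeatureMatrix(
                fm.values[train], fm.feature_names, y[train],
                [fm.subject_ids[i] for i in train],
            )
            cols = select_top(
                relieff_rank(sub, cfg.relieff_neighbors, cfg.seed), cfg.n_features
            )
        else:
            cols = cols_global
        xtr, xte = x_all[np.ix_(train, cols)], x_all[np.ix_(test, cols)]
        if cfg.normalization is NormMode.UNIT_NORM_TRAINFOLD:
            norms = np.linalg.norm(xtr, axis=0)
            norms = np.where(norms == 0, 1.0, norms)
            xtr, xte = xtr / norms, xte / norms
        y_pred[test] = _fit_predict(xtr, y[train], xte, cfg)
        seen[test] = True
    assert seen.all(), "every sample must be predicted exactly once"
    cm = confusion_from_predictions(y, y_pred)
    return CVResult(y_true=y, y_pred=y_pred, confusion=cm, config=cfg)


def loocv(fm: FeatureMatrix, cfg: EvalConfig) -> CVResult:
    """Leave-one-out CV: each sample predicted by a model trained on the rest."""
    for c in np.unique(fm.labels):
        if np.sum(fm.labels == c) < 2:
            raise ParameterError(f"class {c!r} needs at least 2 samples for LOO")
    return _run_cv(fm, cfg, LeaveOneOut().split(fm.values))


def kfold_cv(fm: FeatureMatrix, cfg: EvalConfig, k: int = 10, seed: int | None = None) -> CVResult:
    """Stratified k-fold CV, seed-deterministic fold assignment."""
    seed = cfg.seed if seed is None else seed
    _, counts = np.unique(fm.labels, return_counts=True)
    n_splits = min(k, int(counts.min()))
    if n_splits < k:
        warnings.warn(
            f"smallest class has {counts.min()} samples; using {n_splits} folds"
        )
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return _run_cv(fm, cfg, skf.split(fm.values, fm.labels))


def evaluate(fm: FeatureMatrix, cfg: EvalConfig) -> CVResult:
    """Dispatch on ``cfg.cv``."""
    if cfg.cv is CVMode.LOO:
        return loocv(fm, cfg)
    return kfold_cv(fm, cfg)


@dataclass
class GridSearchResult:
    table: pd.DataFrame  # accuracy (%) per grid cell
    results: dict  # grid key -> CVResult
    best_accuracy: float
    best_keys: list = field(default_factory=list)  # all argmax cells, ties listed


def grid_search(
    fm_by_L: dict[int, FeatureMatrix],
    cfg_template: EvalConfig,
    knn_grid=KNN_K_GRID,
    cost_grid=SVM_COST_GRID,
    scale_grid=SVM_SCALE_GRID,
) -> GridSearchResult:
    """Cartesian accuracy tables over the study grids.

    LDA: one row, columns = L.  k-NN: rows = k, columns = L.  SVM-RBF: rows =
    cost, columns = scale, one block per L (stacked with a MultiIndex when
    several L are given).
    """
    results: dict = {}

    def run(L, **over):
        cfg = replace(cfg_template, L=L, **over)
        res = evaluate(fm_by_L[L], cfg)
        return res

    Ls = sorted(fm_by_L)
    if cfg_template.classifier is ClassifierKind.LDA:
        row = {}
        for L in Ls:
            res = run(L)
            results[(L,)] = res
            row[L] = res.accuracy
        table = pd.DataFrame([row], index=["LDA"])
    elif cfg_template.classifier is ClassifierKind.KNN:
        table = pd.DataFrame(index=list(knn_grid), columns=Ls, dtype=float)
        for L in Ls:
            for k in knn_grid:
                res = run(L, knn_k=k)
                results[(L, k)] = res
                table.loc[k, L] = res.accuracy
        table.index.name = "k"
    elif cfg_template.classifier is ClassifierKind.SVM_RBF:
        blocks = []
        for L in Ls:
            block = pd.DataFrame(
                index=list(cost_grid), columns=list(scale_grid), dtype=float
            )
            for cost in cost_grid:
                for scale in scale_grid:
                    res = run(L, svm_cost=cost, svm_scale=scale)
                    results[(L, cost, scale)] = res
                    block.loc[cost, scale] = res.accuracy
            block.index.name = "cost"
            blocks.append(block)
        table = (
            blocks[0]
            if len(blocks) == 1
            else pd.concat(blocks, keys=Ls, names=["L", "cost"])
        )
    else:
        raise ParameterError(f"unknown classifier {cfg_template.classifier}")

    best = max(res.accuracy for res in results.values())
    best_keys = [k for k, res in results.items() if res.accuracy == best]
    return GridSearchResult(
        table=table, results=results, best_accuracy=best, best_keys=best_keys
    )


def combine_feature_sets(
    residue_fm: FeatureMatrix,
    radius_fm: FeatureMatrix,
    residue_features=("MNF", "WAMP", "MAV", "MFL", "FD"),
    radius_features=("MFL", "FD"),
) -> FeatureMatrix:
    """Column-concatenate named residue and radius features ("_residue"/"_radius").

    Both matrices must describe the same samples in the same order.
    """
    if list(residue_fm.subject_ids) != list(radius_fm.subject_ids) or not np.array_equal(
        residue_fm.labels, radius_fm.labels
    ):
        raise ValueError("residue and radius matrices describe different samples")
    a = residue_fm.subset(list(residue_features))
    b = radius_fm.subset(list(radius_features))
    return FeatureMatrix(
        values=np.hstack([a.values, b.values]),
        feature_names=[f"{n}_residue" for n in a.feature_names]
        + [f"{n}_radius" for n in b.feature_names],
        labels=residue_fm.labels.copy(),
        subject_ids=list(residue_fm.subject_ids),
    )
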