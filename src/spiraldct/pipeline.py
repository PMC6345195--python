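"""End-to-end orchestration helpers shared by the CLI and scripts.

These functions wire the stages together — drawing -> resample -> scalar
sequence -> feature vector -> cohort matrix -> ranking/classification — with
the study defaults (4096 points, centering before the radius method only).
"""

from __future__ import annotations

import numpy as np

from .classify import (
    ClassifierKind,
    EvalConfig,
    Method,
    SelectionMode,
    SVM_COST_GRID,
    SVM_SCALE_GRID,
    grid_search,
)
from .dct_core import ScalarSequence, radius_sequence, residue_distance_sequence
from .feature_bank import FeatureParams, extract_all
from .ingest import DrawingSample, center_coordinates, resample_to_n
from .selection import FeatureMatrix
from .synthetic_spirals import CohortSpec, generate_cohort

N_POINTS_DEFAULT = 4096


def sequence_for(
    sample: DrawingSample,
    method: Method,
    L: int = 17,
    n_points: int = N_POINTS_DEFAULT,
    center_radius: bool = True,
) -> ScalarSequence:
    """Resample a drawing and build its radius or residue-distance sequence.

    Coordinates are centered before the radius method (the polar radius is
    origin-dependent) but not before the residue method (the residue discards
    the DC term for L >= 1 anyway).
    """
    seq = resample_to_n(sample, n_points)
    if method is Method.RADIUS:
        if center_radius:
            seq = center_coordinates(seq)
        return radius_sequence(seq)
    if method is Method.RESIDUE:
        return residue_distance_sequence(seq, L)
    raise ValueError(f"no single sequence for method {method}")


def feature_matrix_from_samples(
    samples: list[DrawingSample],
    method: Method,
    L: int = 17,
    n_points: int = N_POINTS_DEFAULT,
    params: FeatureParams | None = None,
) -> FeatureMatrix:
    """Stack the 35-feature vectors of a cohort into a labelled matrix."""
    params = params or FeatureParams()
    rows, labels, ids = [], [], []
    for s in samples:
        seq = sequence_for(s, method, L, n_points)
        feats = extract_all(seq, params)
        rows.append(list(feats.values()))
        names = list(feats.keys())
        labels.append(s.label.value)
        ids.append(s.subject_id)
    return FeatureMatrix(
        values=np.asarray(rows), feature_names=names, labels=np.asarray(labels),
        subject_ids=ids,
    )


def best_svm_loo_accuracy(
    fm: FeatureMatrix,
    n_features: int = 5,
    seed: int = 0,
    cost_grid=SVM_COST_GRID,
    scale_grid=SVM_SCALE_GRID,
) -> float:
    """Best LOO accuracy of an SVM-RBF over the cost x scale grid, after
    global unit-norm scaling and global ReliefF top-``n_features`` selection."""
    cfg = EvalConfig(
        classifier=ClassifierKind.SVM_RBF,
        selection_mode=SelectionMode.RELIEFF_GLOBAL,
        n_features=n_features,
        seed=seed,
    )
    res = grid_search({cfg.L: fm}, cfg, cost_grid=cost_grid, scale_grid=scale_grid)
    return res.best_accuracy


def residue_surrogate_accuracies(
    base_seed: int,
    n_seeds: int = 20,
    n_et: int = 24,
    n_control: int = 27,
    L: int = 17,
    n_features: int = 5,
) -> list[float]:
    """Per-seed best LOO accuracy of the full residue pipeline on synthetic
    cohorts (generate -> residue features at L -> ReliefF top-5 -> SVM grid).

    Seeds are ``base_seed + i`` for i in 0..n_seeds-1 (kept below 2^31).
    """
    accs = []
    for i in range(n_seeds):
        seed = int((base_seed + i) % (2**31 - 1))
        samples, _ = generate_cohort(CohortSpec(n_et=n_et, n_control=n_control, seed=seed))
        fm = feature_matrix_from_samples(samples, Method.RESIDUE, L)
        accs.append(best_svm_loo_accuracy(fm, n_features=n_features, seed=seed))
    return accs
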