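"""Feature-matrix container, ReliefF relevance ranking and top-k selection.

ReliefF scores each feature by how well it separates nearest neighbors of
opposite classes relative to neighbors of the same class: for every sample
the k nearest hits and k nearest misses (Manhattan distance on
range-normalized features) are found, and the weight of feature f is
incremented by the mean miss difference and decremented by the mean hit
difference.  Features that are constant (zero range) get weight exactly 0.

The cohort's published 5-feature subsets are shipped as named constants so
classifiers can be evaluated on exactly those features without re-ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import ParameterError

#: Top-5 ReliefF features for the residue-distance sequence (best first).
RESIDUE_TOP5 = ("MNF", "WAMP", "MAV", "MFL", "FD")
#: Top-5 ReliefF features for the radius sequence (best first).
RADIUS_TOP5 = ("MFL", "FD", "MYO", "MAV", "STD")


@dataclass
class FeatureMatrix:
    """samples x features matrix with names, binary labels and subject ids."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray  # strings, e.g. "ET" / "CONTROL"
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.feature_names = list(self.feature_names)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match columns")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must match rows")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix must be finite")
        if not self.subject_ids:
            self.subject_ids = [f"s{i}" for i in range(self.values.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, columns) -> "FeatureMatrix":
        """New matrix restricted to the given column indices or names, in order."""
        idx = [
            self.feature_names.index(c) if isinstance(c, str) else int(c)
            for c in columns
        ]
        return FeatureMatrix(
            values=self.values[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            labels=self.labels.copy(),
            subject_ids=list(self.subject_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "label", self.labels)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("subject_id", "label")]
        return cls(
            values=df[names].to_numpy(float),
            feature_names=names,
            labels=df["label"].to_numpy(),
            subject_ids=df["subject_id"].astype(str).tolist(),
        )


@dataclass
class FeatureRanking:
    """Feature indices sorted by ReliefF weight (best first) plus the weights."""

    order: np.ndarray
    weights: np.ndarray
    feature_names: list[str]

    def ranked_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.order]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "feature_name": self.ranked_names(),
                "weight": self.weights[self.order],
            }
        ).to_csv(path, index=False)


def relieff_rank(
    fm: FeatureMatrix, n_neighbors: int = 10, seed: int = 0
) -> FeatureRanking:
    """Deterministic binary ReliefF over all samples (no subsampling).

    Distances and per-feature differences use range normalization, so weights
    are invariant to affine rescaling of any single feature.  Ties in
    neighbor distance are broken by sample index (stable sort), so the result
    does not depend on ``seed``; the argument is kept for interface parity.
    """
    classes = np.unique(fm.labels)
    if len(classes) != 2:
        raise ParameterError("ReliefF requires exactly two classes")
    counts = {c: int(np.sum(fm.labels == c)) for c in classes}
    if min(counts.values()) < n_neighbors + 1:
        raise ParameterError(
            f"each class needs at least n_neighbors+1={n_neighbors + 1} samples "
            f"(have {counts}); use a smaller n_neighbors"
        )

    rng_range = fm.values.max(axis=0) - fm.values.min(axis=0)
    live = rng_range > 0
    z = np.zeros_like(fm.values)
    z[:, live] = fm.values[:, live] / rng_range[live]  # diffs now in [0, 1]

    m = fm.n_samples
    k = n_neighbors
    weights = np.zeros(fm.n_features)
    for i in range(m):
        diff = np.abs(z - z[i])  # (m, n_features)
        dist = diff.sum(axis=1)  # Manhattan
        same = fm.labels == fm.labels[i]
        hits = np.where(same)[0]
        hits = hits[hits != i]
        misses = np.where(~same)[0]
        hit_sel = hits[np.argsort(dist[hits], kind="stable")[:k]]
        miss_sel = misses[np.argsort(dist[misses], kind="stable")[:k]]
        weights += diff[miss_sel].sum(axis=0) / (m * k)
        weights -= diff[hit_sel].sum(axis=0) / (m * k)

    order = np.lexsort((np.arange(fm.n_features), -weights))
    return FeatureRanking(
        order=order, weights=weights, feature_names=list(fm.feature_names)
    )


def select_top(rank: FeatureRanking, n: int = 5) -> list[int]:
    """First ``n`` feature indices of the ranking, best first."""
    if not 1 <= n <= len(rank.order):
        raise ParameterError(f"n must be in [1, {len(rank.order)}], got {n}")
    return [int(i) for i in rank.order[:n]]
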