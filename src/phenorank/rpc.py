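"""Ranking by pairwise comparison (RPC) baseline.

The q-label ranking problem is decomposed into C(q,2) = q(q−1)/2 one-vs-one
binary tasks.  The training subset for label pair (a, b) contains exactly
those proteins annotated with one and only one of the two labels — proteins
carrying both (or neither) are excluded.  At query time every trained
pairwise classifier casts one vote for the label it predicts; labels are
ranked by descending vote count (0..q−1 votes each).  Pairs whose training
subset is empty abstain.

The binary learner is pluggable (any object with ``fit``/``predict``); the
default is a deterministic nearest-centroid classifier on cosine
similarity, which needs no external learning machinery and no RNG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np

from .io import FeatureMatrix, LabelMatrix, LabelRanking, check_paired
from .evaluation import OrderAccuracyProfile, order_accuracy
from .knna import rank_labels, LabelScoreVector

logger = logging.getLogger("phenorank")

__all__ = [
    "PairwiseSubset",
    "BinaryClassifier",
    "NearestCentroidCosine",
    "count_pairs",
    "build_pairwise_subsets",
    "train_pairwise_classifiers",
    "rpc_rank",
    "rpc_jackknife",
]


def count_pairs(q: int) -> int:
    """Number of unordered label pairs, C(q, 2) = q(q−1)/2."""
    if q < 2:
        raise ValueError("need at least 2 labels for pairwise comparison")
    return q * (q - 1) // 2


@dataclass
class PairwiseSubset:
    """Training rows for one label pair (a < b): annotated by exactly one
    of the two labels."""

    label_pair: tuple[int, int]
    row_indices: np.ndarray

    def __post_init__(self) -> None:
        a, b = self.label_pair
        if not a < b:
            raise ValueError("label pair must satisfy a < b")
        self.row_indices = np.asarray(self.row_indices, dtype=int)

    @property
    def is_empty(self) -> bool:
        return self.row_indices.size == 0


@runtime_checkable
class BinaryClassifier(Protocol):
    """Contract for pluggable pairwise learners.

    ``fit`` receives the subset's feature rows and binary targets
    (0 = first label a, 1 = second label b); ``predict`` must return 0 or 1
    for any finite feature vector and be deterministic.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BinaryClassifier": ...

    def predict(self, x: np.ndarray) -> int: ...


class NearestCentroidCosine:
    """Nearest class centroid under cosine similarity; ties and one-class
    subsets resolve to the lower label (class 0)."""

    def __init__(self) -> None:
        self._centroids: dict[int, np.ndarray] = {}

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NearestCentroidCosine":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.shape[0] != y.shape[0] or X.shape[0] == 0:
            raise ValueError("fit needs matching, non-empty X and y")
        self._centroids = {
            cls: X[y == cls].mean(axis=0) for cls in np.unique(y)
        }
        return self

    def predict(self, x: np.ndarray) -> int:
        if not self._centroids:
            raise RuntimeError("classifier not fitted")
        if len(self._centroids) == 1:
            return int(next(iter(self._centroids)))
        x = np.asarray(x, dtype=float).ravel()
        best_cls, best_sim = 0, -np.inf
        for cls in sorted(self._centroids):  # ties -> lower class
            c = self._centroids[cls]
            nx, nc = np.linalg.norm(x), np.linalg.norm(c)
            sim = 0.0 if nx == 0.0 or nc == 0.0 else float(x @ c / (nx * nc))
            if sim > best_sim:
                best_cls, best_sim = cls, sim
        return best_cls


def build_pairwise_subsets(Y: LabelMatrix) -> list[PairwiseSubset]:
    """One subset per unordered label pair; a row belongs to subset (a, b)
    iff it carries exactly one of the two labels."""
    subsets = []
    inc = Y.incidence
    for a in range(Y.q):
        for b in range(a + 1, Y.q):
            mask = inc[:, a] != inc[:, b]  # exactly one of the two
            sub = PairwiseSubset((a, b), np.flatnonzero(mask))
            if sub.is_empty:
                logger.warning(
                    "empty pairwise subset for labels (%s, %s) — classifier "
                    "will abstain", Y.tags[a], Y.tags[b],
                )
            subsets.append(sub)
    assert len(subsets) == count_pairs(Y.q)
    return subsets


def train_pairwise_classifiers(
    X: FeatureMatrix | np.ndarray,
    Y: LabelMatrix,
    factory: Callable[[], BinaryClassifier] = NearestCentroidCosine,
    feature_subset: Sequence[int] | None = None,
) -> dict[tuple[int, int], BinaryClassifier | None]:
    """Fit one binary classifier per non-empty pairwise subset.

    Returns ``None`` for empty subsets (they abstain at voting time).
    """
    mat = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    if feature_subset is not None:
        mat = mat[:, np.asarray(feature_subset, dtype=int)]
    trained: dict[tuple[int, int], BinaryClassifier | None] = {}
    for sub in build_pairwise_subsets(Y):
        a, b = sub.label_pair
        if sub.is_empty:
            trained[(a, b)] = None
            continue
        rows = sub.row_indices
        targets = Y.incidence[rows, b].astype(int)  # 1 iff annotated with b
        trained[(a, b)] = factory().fit(mat[rows], targets)
    return trained


def rpc_rank(
    query: np.ndarray,
    classifiers: dict[tuple[int, int], BinaryClassifier | None],
    tags: Sequence[str],
    query_id: str = "",
) -> LabelRanking:
    """Each non-abstaining pairwise classifier casts one vote; labels are
    ranked by descending vote count (ties: ascending tag index)."""
    q = len(tags)
    votes = np.zeros(q)
    query = np.asarray(query, dtype=float).ravel()
    for (a, b), clf in classifiers.items():
        if clf is None:
            continue
        winner = b if clf.predict(query) == 1 else a
        votes[winner] += 1
    ranking = rank_labels(LabelScoreVector(votes), tags)
    ranking.query_id = query_id
    return ranking


def rpc_jackknife(
    X: FeatureMatrix,
    Y: LabelMatrix,
    factory: Callable[[], BinaryClassifier] = NearestCentroidCosine,
    feature_subset: Sequence[int] | None = None,
) -> OrderAccuracyProfile:
    """Leave-one-out RPC: for every held-out protein all pairwise
    classifiers are retrained without it, the query is ranked by votes and
    the rankings are scored with the order-i accuracy metric."""
    check_paired(X, Y)
    if X.n < 2:
        raise ValueError("jackknife needs at least 2 proteins")
    rankings: list[LabelRanking] = []
    for z in range(X.n):
        keep = [i for i in range(X.n) if i != z]
        Y_tr = LabelMatrix(
            [Y.protein_ids[i] for i in keep], list(Y.tags), Y.incidence[keep]
        )
        mat = X.values[keep]
        clfs = train_pairwise_classifiers(mat, Y_tr, factory, feature_subset)
        qvec = X.values[z]
        if feature_subset is not None:
            qvec = qvec[np.asarray(feature_subset, dtype=int)]
        rankings.append(rpc_rank(qvec, clfs, Y.tags, query_id=X.protein_ids[z]))
    return order_accuracy(rankings, Y)
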