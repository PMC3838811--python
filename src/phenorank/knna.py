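"""Cosine-weighted k-nearest-neighbor multi-label ranking (kNNA).

For a query protein the k training proteins with the largest cosine
similarity are retrieved (cosines w_1 >= ... >= w_k).  Each phenotype j is
scored by the weighted vote

    S(P => j) = sum_i  w_i * t_{p_i, j},

where t_{p_i, j} is 1 iff neighbor p_i carries label j.  The q scores are
sorted descending into a complete label ranking.  Scores are used raw
(no normalization, negative cosines are not clipped); zero-norm vectors
get cosine 0 with a warning so that aggressive feature subsetting cannot
abort a jackknife run.  All ties break by ascending index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import FeatureMatrix, LabelMatrix, LabelRanking

logger = logging.getLogger("phenorank")

__all__ = [
    "NeighborSet",
    "LabelScoreVector",
    "cosine_similarity",
    "find_neighbors",
    "score_labels",
    "rank_labels",
    "predict",
]


@dataclass
class NeighborSet:
    """Indices of the k nearest training rows and their cosine weights,
    sorted by non-increasing weight."""

    indices: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.indices.shape != self.weights.shape or self.indices.ndim != 1:
            raise ValueError("indices and weights must be 1-D and equally long")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("neighbor indices must be distinct")
        if np.any(np.diff(self.weights) > 1e-12):
            raise ValueError("weights must be non-increasing")


@dataclass
class LabelScoreVector:
    """Per-label weighted vote totals for one query."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("label scores must be finite")


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """cos(x, y) = x·y / (‖x‖ ‖y‖); 0 (with a warning) if either norm is 0."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        logger.warning("cosine of a zero-norm vector defined as 0")
        return 0.0
    return float(x @ y / (nx * ny))


def _cosines_to_rows(query: np.ndarray, mat: np.ndarray) -> np.ndarray:
    """Cosine of the query against every row of ``mat`` (zero norms -> 0)."""
    qn = np.linalg.norm(query)
    norms = np.linalg.norm(mat, axis=1)
    if qn == 0.0 or np.any(norms == 0.0):
        logger.warning("zero-norm vector(s) in cosine computation treated as 0")
    cos = np.zeros(mat.shape[0])
    ok = norms > 0
    if qn > 0 and ok.any():
        cos[ok] = mat[ok] @ query / (norms[ok] * qn)
    return cos


def find_neighbors(
    query: np.ndarray,
    train: FeatureMatrix | np.ndarray,
    k: int,
    exclude: int | None = None,
) -> NeighborSet:
    """The k training rows with the largest cosine to the query (all rows if
    fewer than k remain).  ``exclude`` removes one row — the jackknife
    self-match.  Cosine ties break by ascending row index.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mat = train.values if isinstance(train, FeatureMatrix) else np.asarray(train, float)
    query = np.asarray(query, dtype=float).ravel()
    if query.shape[0] != mat.shape[1]:
        raise ValueError(
            f"query dimension {query.shape[0]} != training dimension {mat.shape[1]}"
        )
    cos = _cosines_to_rows(query, mat)
    order = np.argsort(-cos, kind="stable")
    if exclude is not None:
        order = order[order != exclude]
    if order.size == 0:
        raise ValueError("no usable training rows after exclusion")
    top = order[:k]
    return NeighborSet(top, cos[top])


def score_labels(nbrs: NeighborSet, Y: LabelMatrix) -> LabelScoreVector:
    """score_j = sum_i w_i * incidence[p_i, j] (exact weighted vote)."""
    if nbrs.indices.size and nbrs.indices.max() >= Y.n:
        raise ValueError("neighbor index out of range of the label matrix")
    scores = nbrs.weights @ Y.incidence[nbrs.indices].astype(float)
    return LabelScoreVector(scores)


def rank_labels(s: LabelScoreVector, tags: Sequence[str]) -> LabelRanking:
    """Descending sort of the q label scores; equal scores keep ascending
    tag-index order (stable)."""
    scores = s.scores
    if len(scores) != len(tags):
        raise ValueError(f"{len(scores)} scores for {len(tags)} tags")
    order = np.argsort(-scores, kind="stable")
    return LabelRanking(
        query_id="",
        ranked_tags=[tags[j] for j in order],
        scores=scores[order],
    )


def predict(
    query: np.ndarray,
    train: FeatureMatrix,
    Y: LabelMatrix,
    k: int,
    feature_subset: Sequence[int] | None = None,
    exclude: int | None = None,
    query_id: str = "",
) -> LabelRanking:
    """Full kNNA prediction: restrict to the feature subset, retrieve
    neighbors, score labels, rank.  ``exclude`` implements leave-one-out."""
    if train.n != Y.n:
        raise ValueError("training features and labels have different n")
    query = np.asarray(query, dtype=float).ravel()
    mat = train.values
    if feature_subset is not None:
        idx = np.asarray(feature_subset, dtype=int)
        mat = mat[:, idx]
        query = query[idx]
    nbrs = find_neighbors(query, mat, k, exclude=exclude)
    ranking = rank_labels(score_labels(nbrs, Y), Y.tags)
    ranking.query_id = query_id
    return ranking
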