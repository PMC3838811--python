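"""Minimum-Redundancy-Maximum-Relevance (mRMR) feature ranking.

Continuous standardized features are coarsened into three states
(below mean − σ, within, above mean + σ) and ranked by plug-in mutual
information (log base 2, i.e. bits) against the binary phenotype columns.
Two orders are produced:

* MaxRel — descending relevance I(f; class), where the multi-label class is
  aggregated as the max (default) or mean over the binary label columns;
* mRMR   — the greedy MID (difference) order: after seeding with the MaxRel
  top feature, repeatedly pick ``argmax_f [relevance(f) − mean_{s in S} I(f; s)]``
  over unselected features f given the selected set S.

Both orders are deterministic; ties break by ascending feature index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import FeatureMatrix, LabelMatrix, RankedFeatureList

__all__ = [
    "DiscreteMatrix",
    "discretize",
    "mutual_information",
    "maxrel_ranking",
    "mrmr_ranking",
]


@dataclass
class DiscreteMatrix:
    """Three-state (−1/0/+1) coding of a feature matrix with the per-feature
    (low, high) bin edges used."""

    codes: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if not np.isin(self.codes, (-1, 0, 1)).all():
            raise ValueError("codes must be in {-1, 0, +1}")
        self.codes = self.codes.astype(np.int8)
        if self.bin_edges.shape != (self.codes.shape[1], 2):
            raise ValueError("bin_edges must be (d, 2)")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def d(self) -> int:
        return self.codes.shape[1]


def discretize(X: FeatureMatrix, sigma_mult: float = 1.0) -> DiscreteMatrix:
    """Code each column as −1/0/+1 around mean ± ``sigma_mult``·std
    (population std, computed per column)."""
    mean = X.values.mean(axis=0)
    std = X.values.std(axis=0, ddof=0)
    lo = mean - sigma_mult * std
    hi = mean + sigma_mult * std
    codes = np.zeros(X.values.shape, dtype=np.int8)
    codes[X.values < lo] = -1
    codes[X.values > hi] = 1
    return DiscreteMatrix(codes, np.column_stack([lo, hi]))


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information I(a; b) in bits over the observed cells.

    Non-negative up to floating error; I(a; a) equals the plug-in entropy.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty vectors")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    joint = np.bincount(ai * kb + bi, minlength=ka * kb).reshape(ka, kb) / n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    ratio = joint[nz] / np.outer(pa, pb)[nz]
    return float(np.sum(joint[nz] * np.log2(ratio)))


def _relevance(D: DiscreteMatrix, Y: LabelMatrix, agg: str) -> np.ndarray:
    if D.n != Y.n:
        raise ValueError("discretized features and labels have different n")
    if agg not in ("max", "mean"):
        raise ValueError(f"unknown aggregation {agg!r}")
    mi = np.empty((D.d, Y.q))
    for j in range(D.d):
        for c in range(Y.q):
            mi[j, c] = mutual_information(D.codes[:, j], Y.incidence[:, c])
    return mi.max(axis=1) if agg == "max" else mi.mean(axis=1)


def maxrel_ranking(
    D: DiscreteMatrix, Y: LabelMatrix, agg: str = "max"
) -> RankedFeatureList:
    """Sort all features by descending relevance to the phenotype labels."""
    rel = _relevance(D, Y, agg)
    order = np.argsort(-rel, kind="stable")  # ties: ascending feature index
    return RankedFeatureList(order, rel[order], "maxrel")


def mrmr_ranking(
    D: DiscreteMatrix,
    Y: LabelMatrix,
    m: int | None = None,
    agg: str = "max",
) -> RankedFeatureList:
    """Greedy MID (relevance minus mean redundancy) feature order.

    ``m`` is the number of features to rank (default: all).  The first
    selected feature is always the MaxRel top feature.
    """
    d = D.d
    if m is None:
        m = d
    if not 1 <= m <= d:
        raise ValueError(f"m={m} out of range 1..{d}")
    rel = _relevance(D, Y, agg)

    selected: list[int] = []
    scores: list[float] = []
    remaining = np.ones(d, dtype=bool)
    red_sum = np.zeros(d)  # sum of I(f; s) over selected s

    first = int(np.argmax(rel))  # argmax takes the lowest index on ties
    selected.append(first)
    scores.append(float(rel[first]))
    remaining[first] = False

    while len(selected) < m:
        last = selected[-1]
        for f in np.flatnonzero(remaining):
            red_sum[f] += mutual_information(D.codes[:, f], D.codes[:, last])
        crit = rel - red_sum / len(selected)
        crit[~remaining] = -np.inf
        best = int(np.argmax(crit))
        selected.append(best)
        scores.append(float(crit[best]))
        remaining[best] = False

    return RankedFeatureList(np.array(selected), np.array(scores), "mrmr")
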