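"""Feature standardization and correlation-based pre-filtering.

Features are z-scored (population std, ddof=0) so that every retained
column has mean 0 and std 1; constant columns are dropped and recorded.
A feature then survives the pre-filter iff its strongest absolute Pearson
correlation with any binary phenotype column reaches the threshold
(default 0.1) — weakly label-related features are discarded before the
mutual-information ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import FeatureMatrix, LabelMatrix, check_paired

logger = logging.getLogger("phenorank")

__all__ = [
    "StandardizationParams",
    "FilterResult",
    "standardize",
    "apply_standardization",
    "correlation_filter",
]


@dataclass
class StandardizationParams:
    """Per-feature mean/std of the training data, plus the indices of
    constant features dropped because their std is zero.

    ``means``/``stds`` are indexed by the ORIGINAL feature positions.
    """

    means: np.ndarray
    stds: np.ndarray
    dropped_constant: list[int]

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.stds = np.asarray(self.stds, dtype=float)
        kept = np.setdiff1d(np.arange(len(self.stds)), self.dropped_constant)
        if np.any(self.stds[kept] <= 0):
            raise ValueError("retained features must have positive std")

    @property
    def kept_indices(self) -> np.ndarray:
        return np.setdiff1d(
            np.arange(len(self.stds)), np.asarray(self.dropped_constant, dtype=int)
        )


def standardize(X: FeatureMatrix) -> tuple[FeatureMatrix, StandardizationParams]:
    """Z-score every feature column; drop zero-variance columns.

    Uses the population std (divide by n).  Requires n >= 2 rows.
    """
    if X.n < 2:
        raise ValueError("standardization needs at least 2 proteins (std undefined)")
    means = X.values.mean(axis=0)
    stds = X.values.std(axis=0, ddof=0)
    dropped = [int(j) for j in np.flatnonzero(stds == 0.0)]
    if dropped:
        logger.warning(
            "dropping %d constant feature(s): %s",
            len(dropped),
            ", ".join(X.feature_names[j] for j in dropped[:5])
            + ("..." if len(dropped) > 5 else ""),
        )
    params = StandardizationParams(means, stds, dropped)
    kept = params.kept_indices
    Z = (X.values[:, kept] - means[kept]) / stds[kept]
    out = FeatureMatrix(
        protein_ids=list(X.protein_ids),
        feature_names=[X.feature_names[j] for j in kept],
        values=Z,
    )
    return out, params


def apply_standardization(
    values: np.ndarray, params: StandardizationParams
) -> np.ndarray:
    """Transform new rows (original feature space) with training parameters,
    returning only the retained columns."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    kept = params.kept_indices
    return (values[:, kept] - params.means[kept]) / params.stds[kept]


@dataclass
class FilterResult:
    """Outcome of the correlation pre-filter."""

    kept_indices: np.ndarray
    correlations: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.kept_indices = np.asarray(self.kept_indices, dtype=int)
        self.correlations = np.asarray(self.correlations, dtype=float)
        expected = np.flatnonzero(self.correlations >= self.threshold)
        if not np.array_equal(self.kept_indices, expected):
            raise ValueError("kept_indices inconsistent with correlations/threshold")


def correlation_filter(
    X: FeatureMatrix,
    Y: LabelMatrix,
    threshold: float = 0.1,
    agg: str = "max",
) -> FilterResult:
    """Keep feature j iff the aggregated |Pearson r(X_j, Y_c)| over label
    columns c reaches ``threshold``.

    ``agg`` is ``"max"`` (default: a feature survives if it tracks at least
    one phenotype) or ``"mean"``.  Label columns with zero variance are
    skipped with a warning and contribute correlation 0.
    """
    check_paired(X, Y)
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if agg not in ("max", "mean"):
        raise ValueError(f"unknown aggregation {agg!r}")
    n = X.n
    Xc = X.values - X.values.mean(axis=0)
    x_sd = X.values.std(axis=0, ddof=0)
    L = Y.incidence.astype(float)
    Lc = L - L.mean(axis=0)
    l_sd = L.std(axis=0, ddof=0)
    usable = l_sd > 0
    if not usable.all():
        skipped = [Y.tags[c] for c in np.flatnonzero(~usable)]
        logger.warning(
            "label column(s) with zero variance skipped in correlation "
            "filter: %s", ", ".join(skipped)
        )
    R = np.zeros((X.d, Y.q))
    x_ok = x_sd > 0
    if usable.any() and x_ok.any():
        # r = cov(x, y) / (sd_x sd_y); constant features get r = 0
        cov = Xc[:, x_ok].T @ Lc[:, usable] / n
        R[np.ix_(x_ok, usable)] = cov / np.outer(x_sd[x_ok], l_sd[usable])
    absR = np.abs(R[:, usable]) if usable.any() else np.zeros((X.d, 0))
    if absR.shape[1] == 0:
        corr = np.zeros(X.d)
    elif agg == "max":
        corr = absR.max(axis=1)
    else:
        corr = absR.mean(axis=1)
    # |r| is bounded by 1; snap float round-off at the boundary so a feature
    # identical to a label survives threshold 1.0
    corr[corr > 1.0 - 1e-12] = 1.0
    kept = np.flatnonzero(corr >= threshold)
    logger.info(
        "correlation filter (threshold %.3g, agg=%s): %d of %d features kept",
        threshold, agg, len(kept), X.d,
    )
    return FilterResult(kept, corr, threshold)
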