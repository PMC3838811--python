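"""Jackknife evaluation, the order-i accuracy profile, and incremental
feature selection (IFS).

The jackknife (leave-one-out) test knocks each protein out in turn as the
query and predicts its label ranking from the remaining n − 1 proteins.
The i-th order accuracy is

    A^i = (1/m) * sum_z  t_{z, mu_i(z)},

the fraction of the m evaluated proteins whose rank-i predicted label is
among their true labels.  Because every ranking is a complete permutation
of the q tags, each true label is hit at exactly one rank, so

    sum_i A^i = (total true-label assignments) / m

holds exactly for ANY complete-ranking predictor — a conservation law used
throughout the test suite.

IFS evaluates nested prefixes S_n = {f_1..f_n} of a ranked feature list for
every k in a grid and picks the (k, n) cell with the highest first-order
accuracy (ties: smaller n, then smaller k).  By default standardization,
the correlation filter and the mRMR ranking are computed once on the full
dataset before the jackknife (the protocol the accuracy profile describes);
``nested_ifs_search`` instead recomputes the whole selection inside each
leave-one-out fold, avoiding selection bias at much higher cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    FeatureMatrix,
    LabelMatrix,
    LabelRanking,
    RankedFeatureList,
    check_paired,
)
from .knna import predict
from .mrmr import discretize, maxrel_ranking, mrmr_ranking
from .preprocessing import apply_standardization, correlation_filter, standardize

logger = logging.getLogger("phenorank")

__all__ = [
    "OrderAccuracyProfile",
    "IFSResult",
    "jackknife",
    "order_accuracy",
    "ifs_search",
    "nested_ifs_search",
    "plot_ifs_curves",
]


@dataclass
class OrderAccuracyProfile:
    """A^1..A^q over m evaluated proteins."""

    accuracies: np.ndarray
    m: int

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if self.m < 1:
            raise ValueError("profile needs at least one evaluated protein")
        if np.any(self.accuracies < -1e-12) or np.any(self.accuracies > 1 + 1e-12):
            raise ValueError("order accuracies must lie in [0, 1]")

    @property
    def first_order(self) -> float:
        return float(self.accuracies[0])


@dataclass
class IFSResult:
    """IFS grid of first-order accuracies plus the optimal cell.

    ``grid`` has one row per (k, n) with columns ``k, n, A1..Aq``.
    """

    grid: pd.DataFrame
    best_k: int
    best_n: int
    best_profile: OrderAccuracyProfile

    def __post_init__(self) -> None:
        if self.grid.empty:
            raise ValueError("empty IFS grid")
        best = self.grid["A1"].max()
        cell = self.grid[(self.grid["k"] == self.best_k) & (self.grid["n"] == self.best_n)]
        if cell.empty or abs(float(cell["A1"].iloc[0]) - best) > 1e-12:
            raise ValueError("best cell does not attain the grid maximum of A1")


def jackknife(
    X: FeatureMatrix,
    Y: LabelMatrix,
    k: int,
    feature_subset: Sequence[int] | None = None,
) -> list[LabelRanking]:
    """Leave-one-out kNNA over all n proteins: ranking z is predicted with
    row z excluded from the training set."""
    check_paired(X, Y)
    if X.n < 2:
        raise ValueError("jackknife needs at least 2 proteins")
    return [
        predict(
            X.values[z],
            X,
            Y,
            k,
            feature_subset=feature_subset,
            exclude=z,
            query_id=X.protein_ids[z],
        )
        for z in range(X.n)
    ]


def order_accuracy(
    rankings: Sequence[LabelRanking], Y: LabelMatrix
) -> OrderAccuracyProfile:
    """A^i = fraction of proteins whose rank-i predicted label is true.

    Rankings are aligned to Y by query ID; every evaluated protein must be
    present in Y and every ranking must cover all q tags.
    """
    if not rankings:
        raise ValueError("no rankings to evaluate")
    row_of = {pid: i for i, pid in enumerate(Y.protein_ids)}
    col_of = {t: j for j, t in enumerate(Y.tags)}
    m = len(rankings)
    hits = np.zeros(Y.q)
    for r in rankings:
        if r.query_id not in row_of:
            raise ValueError(f"ranking for unknown protein {r.query_id!r}")
        if sorted(r.ranked_tags) != sorted(Y.tags):
            raise ValueError(
                f"ranking for {r.query_id!r} does not cover the label tag set"
            )
        row = Y.incidence[row_of[r.query_id]]
        for i, tag in enumerate(r.ranked_tags):
            hits[i] += row[col_of[tag]]
    return OrderAccuracyProfile(hits / m, m)


def _best_cell(grid: pd.DataFrame) -> tuple[int, int]:
    """Max A1; ties broken by smaller n, then smaller k."""
    best = grid["A1"].max()
    tied = grid[grid["A1"] == best].sort_values(["n", "k"])
    return int(tied["k"].iloc[0]), int(tied["n"].iloc[0])


def ifs_search(
    X: FeatureMatrix,
    Y: LabelMatrix,
    ranked: RankedFeatureList,
    k_grid: Sequence[int],
    max_n: int | None = None,
) -> IFSResult:
    """Jackknife first-order accuracy for every (k, prefix length) cell.

    ``ranked`` indexes columns of X; prefixes run from 1 to
    ``min(len(ranked), max_n)`` in ranked order.
    """
    if len(k_grid) == 0:
        raise ValueError("k_grid must be non-empty")
    if len(ranked) == 0:
        raise ValueError("ranked feature list must be non-empty")
    N = len(ranked) if max_n is None else min(len(ranked), max_n)
    rows = []
    profiles: dict[tuple[int, int], OrderAccuracyProfile] = {}
    for k in k_grid:
        for n in range(1, N + 1):
            prof = order_accuracy(jackknife(X, Y, k, ranked.top(n)), Y)
            profiles[(int(k), n)] = prof
            rows.append(
                {"k": int(k), "n": n}
                | {f"A{i + 1}": prof.accuracies[i] for i in range(Y.q)}
            )
    grid = pd.DataFrame(rows)
    best_k, best_n = _best_cell(grid)
    logger.info(
        "IFS: best A1=%.4f at k=%d, n=%d (grid %d cells)",
        profiles[(best_k, best_n)].first_order, best_k, best_n, len(grid),
    )
    return IFSResult(grid, best_k, best_n, profiles[(best_k, best_n)])


def nested_ifs_search(
    X_raw: FeatureMatrix,
    Y: LabelMatrix,
    k_grid: Sequence[int],
    max_n: int,
    threshold: float = 0.1,
    scheme: str = "mrmr",
    sigma_mult: float = 1.0,
    agg: str = "max",
) -> IFSResult:
    """IFS with feature selection recomputed inside every leave-one-out fold.

    For each held-out protein: standardize on the n − 1 training rows, apply
    the correlation filter, rank the surviving features (MaxRel or mRMR) and
    predict the held-out query — so the query never influences its own
    feature selection.  Far more expensive than ``ifs_search``; intended for
    small studies of selection bias.
    """
    check_paired(X_raw, Y)
    if scheme not in ("maxrel", "mrmr"):
        raise ValueError(f"unknown ranking scheme {scheme!r}")
    if len(k_grid) == 0:
        raise ValueError("k_grid must be non-empty")
    n_prot = X_raw.n
    fold_rankings: dict[tuple[int, int], list[LabelRanking]] = {
        (int(k), n): [] for k in k_grid for n in range(1, max_n + 1)
    }
    for z in range(n_prot):
        keep_rows = [i for i in range(n_prot) if i != z]
        X_tr = FeatureMatrix(
            [X_raw.protein_ids[i] for i in keep_rows],
            list(X_raw.feature_names),
            X_raw.values[keep_rows],
        )
        Y_tr = LabelMatrix(
            X_tr.protein_ids, list(Y.tags), Y.incidence[keep_rows]
        )
        Z_tr, params = standardize(X_tr)
        filt = correlation_filter(Z_tr, Y_tr, threshold=threshold, agg=agg)
        if len(filt.kept_indices) == 0:
            raise ValueError(
                f"fold {z}: correlation filter removed every feature"
            )
        Z_sel = Z_tr.subset_features(filt.kept_indices)
        D = discretize(Z_sel, sigma_mult=sigma_mult)
        fold_max = min(max_n, Z_sel.d)
        if scheme == "mrmr":
            ranked = mrmr_ranking(D, Y_tr, m=fold_max, agg=agg)
        else:
            ranked = maxrel_ranking(D, Y_tr, agg=agg)
        q_std = apply_standardization(X_raw.values[z], params).ravel()
        q_sel = q_std[filt.kept_indices]
        for k in k_grid:
            for n in range(1, max_n + 1):
                r = predict(
                    q_sel,
                    Z_sel,
                    Y_tr,
                    int(k),
                    feature_subset=ranked.top(min(n, fold_max)),
                    query_id=X_raw.protein_ids[z],
                )
                fold_rankings[(int(k), n)].append(r)
    rows = []
    profiles: dict[tuple[int, int], OrderAccuracyProfile] = {}
    for (k, n), rks in fold_rankings.items():
        prof = order_accuracy(rks, Y)
        profiles[(k, n)] = prof
        rows.append(
            {"k": k, "n": n}
            | {f"A{i + 1}": prof.accuracies[i] for i in range(Y.q)}
        )
    grid = pd.DataFrame(rows).sort_values(["k", "n"], ignore_index=True)
    best_k, best_n = _best_cell(grid)
    return IFSResult(grid, best_k, best_n, profiles[(best_k, best_n)])


def plot_ifs_curves(
    result: IFSResult,
    path: str,
    series_path: str | None = None,
) -> None:
    """One accuracy-vs-prefix-length curve per k, peak annotated.

    The plotted series is also written as TSV (``series_path`` or
    ``path + ".tsv"``) so the underlying numbers are reproducible
    byte-for-byte.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = result.grid
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for k, sub in grid.groupby("k"):
        sub = sub.sort_values("n")
        ax.plot(sub["n"], sub["A1"], lw=1, label=f"k={k}")
    best_a1 = float(
        grid[(grid["k"] == result.best_k) & (grid["n"] == result.best_n)]["A1"].iloc[0]
    )
    ax.plot([result.best_n], [best_a1], "r*", ms=12)
    ax.annotate(
        f"peak A1={best_a1:.4f}\n(k={result.best_k}, n={result.best_n})",
        xy=(result.best_n, best_a1),
        xytext=(5, -15),
        textcoords="offset points",
        fontsize=8,
    )
    ax.set_xlabel("number of top-ranked features (n)")
    ax.set_ylabel("first-order accuracy $A^1$")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)

    if series_path is None:
        series_path = str(path) + ".tsv"
    cols = ["k", "n"] + [c for c in grid.columns if c.startswith("A")]
    with open(series_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for _, row in grid.sort_values(["k", "n"]).iterrows():
            cells = [str(int(row["k"])), str(int(row["n"]))] + [
                f"{row[c]:.17g}" for c in cols[2:]
            ]
            fh.write("\t".join(cells) + "\n")
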