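"""Domain containers and TSV readers/writers.

All files are UTF-8 tab-separated with a mandatory header row and ``.`` as
the decimal separator.  Four artifacts are exchanged on disk:

* feature tables   — ``id`` column + one numeric column per feature,
* label annotations — long format ``id<TAB>tag`` (or a directory of per-tag
  ID lists, one protein ID per line, file name = tag),
* ranked-feature tables — ``rank, feature_name, score, scheme``,
* prediction tables — one row per query: ``id`` then ``tag:score`` pairs in
  rank order.

Missing values are a hard error everywhere; no imputation is performed.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("phenorank")

__all__ = [
    "FeatureMatrix",
    "LabelMatrix",
    "RankedFeatureList",
    "LabelRanking",
    "read_feature_table",
    "write_feature_table",
    "read_labels",
    "write_labels",
    "read_ranked_features",
    "write_ranked_features",
    "read_predictions",
    "write_predictions",
    "check_paired",
]


def _find_duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass
class FeatureMatrix:
    """An ``n x d`` real-valued table of per-protein features.

    ``values[i, j]`` is the (unitless) enrichment score of protein
    ``protein_ids[i]`` for feature ``feature_names[j]``.
    """

    protein_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.values = np.asarray(self.values, dtype=float)
        n, d = len(self.protein_ids), len(self.feature_names)
        if n < 1 or d < 1:
            raise ValueError("feature matrix needs at least one row and one column")
        if self.values.shape != (n, d):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} proteins x {d} features"
            )
        dup = _find_duplicates(self.protein_ids)
        if dup:
            raise ValueError(f"duplicate protein ID(s): {', '.join(dup)}")
        dup = _find_duplicates(self.feature_names)
        if dup:
            raise ValueError(f"duplicate feature name(s): {', '.join(dup)}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at protein {self.protein_ids[i]!r}, "
                f"feature {self.feature_names[j]!r}"
            )

    @property
    def n(self) -> int:
        return len(self.protein_ids)

    @property
    def d(self) -> int:
        return len(self.feature_names)

    def subset_features(self, indices: Sequence[int]) -> "FeatureMatrix":
        """Column subset (copy), preserving the given order."""
        idx = list(indices)
        return FeatureMatrix(
            protein_ids=list(self.protein_ids),
            feature_names=[self.feature_names[j] for j in idx],
            values=self.values[:, idx].copy(),
        )


@dataclass
class LabelMatrix:
    """Binary ``n x q`` incidence of phenotype tags; every protein carries
    at least one tag (multi-label)."""

    protein_ids: list[str]
    tags: list[str]
    incidence: np.ndarray

    def __post_init__(self) -> None:
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.tags = [str(t) for t in self.tags]
        self.incidence = np.asarray(self.incidence)
        n, q = len(self.protein_ids), len(self.tags)
        if q < 2:
            raise ValueError("need at least two label tags")
        if self.incidence.shape != (n, q):
            raise ValueError(
                f"incidence shape {self.incidence.shape} does not match "
                f"{n} proteins x {q} tags"
            )
        if not np.isin(self.incidence, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")
        self.incidence = self.incidence.astype(np.int8)
        dup = _find_duplicates(self.protein_ids)
        if dup:
            raise ValueError(f"duplicate protein ID(s): {', '.join(dup)}")
        dup = _find_duplicates(self.tags)
        if dup:
            raise ValueError(f"duplicate tag(s): {', '.join(dup)}")
        zero = np.flatnonzero(self.incidence.sum(axis=1) == 0)
        if zero.size:
            raise ValueError(
                f"protein {self.protein_ids[zero[0]]!r} carries no tag"
            )

    @property
    def n(self) -> int:
        return len(self.protein_ids)

    @property
    def q(self) -> int:
        return len(self.tags)

    @property
    def label_mass(self) -> int:
        """Total number of (protein, tag) assignments."""
        return int(self.incidence.sum())


@dataclass
class RankedFeatureList:
    """Feature indices ordered best-first with their ranking scores."""

    order: np.ndarray
    scores: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scheme not in ("maxrel", "mrmr"):
            raise ValueError(f"unknown ranking scheme {self.scheme!r}")
        if self.order.ndim != 1 or self.scores.shape != self.order.shape:
            raise ValueError("order and scores must be 1-D and equally long")
        if len(np.unique(self.order)) != len(self.order):
            raise ValueError("ranked feature order contains repeats")

    def __len__(self) -> int:
        return len(self.order)

    def top(self, n: int) -> np.ndarray:
        return self.order[:n]


@dataclass
class LabelRanking:
    """A complete descending ranking of the q tags for one query protein."""

    query_id: str
    ranked_tags: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.ranked_tags = [str(t) for t in self.ranked_tags]
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.ranked_tags) != len(self.scores):
            raise ValueError("ranked_tags and scores length mismatch")
        dup = _find_duplicates(self.ranked_tags)
        if dup:
            raise ValueError(f"ranking repeats tag(s): {', '.join(dup)}")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("ranking scores must be non-increasing")


def check_paired(X: FeatureMatrix, Y: LabelMatrix) -> None:
    """Fail loudly unless X and Y describe the same proteins in the same order."""
    if X.protein_ids != Y.protein_ids:
        raise ValueError(
            "feature matrix and label matrix protein IDs differ "
            f"(n={X.n} vs n={Y.n})"
        )


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def read_feature_table(path: str | os.PathLike) -> FeatureMatrix:
    """Read a TSV feature table (header ``id<TAB>feat1<TAB>...``).

    Row and column order are preserved.  Duplicate IDs, non-numeric cells and
    missing values are hard errors.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an id column plus >=1 feature column")
    ids = df.iloc[:, 0].tolist()
    dup = _find_duplicates(ids)
    if dup:
        raise ValueError(f"{path}: duplicate protein ID(s): {', '.join(dup)}")
    feat = df.iloc[:, 1:]
    try:
        values = feat.astype(float).to_numpy()
    except (TypeError, ValueError):
        for col in feat.columns:
            coerced = pd.to_numeric(feat[col], errors="coerce")
            bad = coerced.isna() & feat[col].notna()
            if bad.any():
                row = bad.idxmax()
                raise ValueError(
                    f"{path}: non-numeric value {feat.at[row, col]!r} at "
                    f"protein {ids[row]!r}, feature {col!r}"
                ) from None
        raise
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path}: missing value at protein {ids[i]!r}, "
            f"feature {feat.columns[j]!r} (no imputation is performed)"
        )
    return FeatureMatrix(ids, list(feat.columns), values)


def write_feature_table(X: FeatureMatrix, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(X.feature_names) + "\n")
        for pid, row in zip(X.protein_ids, X.values):
            fh.write(pid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# label annotations
# ---------------------------------------------------------------------------

def read_labels(
    path: str | os.PathLike, tags: Sequence[str] | None = None
) -> LabelMatrix:
    """Read multi-label annotations.

    ``path`` may be a long-format TSV (header ``id<TAB>tag``, one row per
    assignment, repeated IDs allowed) or a directory of per-tag ID lists
    (file name = tag, one protein ID per line).  Tags are ordered
    lexicographically unless an explicit ``tags`` list is supplied.
    """
    pairs: list[tuple[str, str]] = []
    p = Path(path)
    if p.is_dir():
        for f in sorted(p.iterdir()):
            if f.is_file():
                tag = f.name
                for line in f.read_text(encoding="utf-8").splitlines():
                    pid = line.strip()
                    if pid:
                        pairs.append((pid, tag))
    else:
        with open(p, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.strip():
                raise ValueError(f"{path}: no annotations")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2 or not parts[0] or not parts[1]:
                    raise ValueError(f"{path}:{lineno}: expected 'id<TAB>tag'")
                pairs.append((parts[0], parts[1]))
    if not pairs:
        raise ValueError(f"{path}: no annotations")

    observed = sorted({t for _, t in pairs})
    if tags is None:
        tag_list = observed
    else:
        tag_list = [str(t) for t in tags]
        unknown = sorted(set(observed) - set(tag_list))
        if unknown:
            raise ValueError(f"{path}: unknown tag(s): {', '.join(unknown)}")
    tag_idx = {t: j for j, t in enumerate(tag_list)}

    ids: list[str] = []
    id_idx: dict[str, int] = {}
    for pid, _ in pairs:
        if pid not in id_idx:
            id_idx[pid] = len(ids)
            ids.append(pid)
    inc = np.zeros((len(ids), len(tag_list)), dtype=np.int8)
    for pid, tag in pairs:
        inc[id_idx[pid], tag_idx[tag]] = 1
    return LabelMatrix(ids, tag_list, inc)


def write_labels(Y: LabelMatrix, path: str | os.PathLike) -> None:
    """Write annotations in long format (``id<TAB>tag``)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\ttag\n")
        for i, pid in enumerate(Y.protein_ids):
            for j in np.flatnonzero(Y.incidence[i]):
                fh.write(f"{pid}\t{Y.tags[j]}\n")


# ---------------------------------------------------------------------------
# ranked-feature tables
# ---------------------------------------------------------------------------

def write_ranked_features(
    ranked: RankedFeatureList,
    feature_names: Sequence[str],
    path: str | os.PathLike,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tfeature_name\tscore\tscheme\n")
        for r, (j, s) in enumerate(zip(ranked.order, ranked.scores), start=1):
            fh.write(f"{r}\t{feature_names[j]}\t{s:.17g}\t{ranked.scheme}\n")


def read_ranked_features(
    path: str | os.PathLike, feature_names: Sequence[str]
) -> RankedFeatureList:
    """Read a ranked-feature table, mapping names back to column indices of
    the given feature universe."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={"feature_name": str})
    name_idx = {n: j for j, n in enumerate(feature_names)}
    try:
        order = np.array([name_idx[n] for n in df["feature_name"]], dtype=int)
    except KeyError as exc:
        raise ValueError(f"{path}: feature {exc.args[0]!r} not in table") from None
    schemes = set(df["scheme"])
    if len(schemes) != 1:
        raise ValueError(f"{path}: mixed ranking schemes {sorted(schemes)}")
    return RankedFeatureList(order, df["score"].to_numpy(float), schemes.pop())


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

def write_predictions(
    rankings: Sequence[LabelRanking], path: str | os.PathLike
) -> None:
    """One row per query: id, then ``tag:score`` pairs in rank order.

    Scores are printed with six decimal places.  All rankings must be over
    the same tag set.
    """
    tag_sets = {frozenset(r.ranked_tags) for r in rankings}
    if len(tag_sets) > 1:
        raise ValueError("rankings are over inconsistent tag sets")
    with open(path, "w", encoding="utf-8") as fh:
        if not rankings:
            fh.write("id\n")
            return
        q = len(rankings[0].ranked_tags)
        fh.write("id\t" + "\t".join(f"rank{i + 1}" for i in range(q)) + "\n")
        for r in rankings:
            cells = [f"{t}:{s:.6f}" for t, s in zip(r.ranked_tags, r.scores)]
            fh.write(r.query_id + "\t" + "\t".join(cells) + "\n")


def read_predictions(path: str | os.PathLike) -> list[LabelRanking]:
    rankings: list[LabelRanking] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty predictions file")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            tags, scores = [], []
            for cell in parts[1:]:
                tag, _, score = cell.rpartition(":")
                tags.append(tag)
                scores.append(float(score))
            rankings.append(LabelRanking(parts[0], tags, np.array(scores)))
    return rankings
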