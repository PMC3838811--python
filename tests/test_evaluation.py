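"""Jackknife, order-i accuracy and incremental feature selection."""

import numpy as np
import pytest

from phenorank import (
    FeatureMatrix,
    LabelMatrix,
    LabelRanking,
    RankedFeatureList,
    ifs_search,
    jackknife,
    nested_ifs_search,
    order_accuracy,
    plot_ifs_curves,
    predict,
)

from conftest import make_dataset


class TestJackknife:
    def test_each_ranking_excludes_its_own_row(self):
        X, Y = make_dataset(40, 6, 3, seed=21)
        rankings = jackknife(X, Y, k=3)
        assert len(rankings) == X.n
        for z, r in enumerate(rankings):
            manual = predict(X.values[z], X, Y, k=3, exclude=z,
                             query_id=X.protein_ids[z])
            assert r.ranked_tags == manual.ranked_tags
            np.testing.assert_allclose(r.scores, manual.scores, atol=1e-12)

    def test_two_proteins_predict_each_other(self):
        X = FeatureMatrix(["a", "b"], ["f1", "f2"], [[1.0, 0.1], [0.2, 1.0]])
        Y = LabelMatrix(["a", "b"], ["T1", "T2"], [[1, 0], [0, 1]])
        r = jackknife(X, Y, k=1)
        assert r[0].ranked_tags[0] == "T2"  # a's only neighbor is b
        assert r[1].ranked_tags[0] == "T1"

    def test_identical_rows_and_labels_score_perfectly(self):
        n = 8
        X = FeatureMatrix(
            [f"p{i}" for i in range(n)], ["f1", "f2"],
            np.tile([1.0, 2.0], (n, 1)),
        )
        Y = LabelMatrix(
            X.protein_ids, ["T1", "T2"], np.tile([1, 0], (n, 1))
        )
        prof = order_accuracy(jackknife(X, Y, k=3), Y)
        assert prof.first_order == 1.0

    def test_single_protein_is_an_error(self):
        X = FeatureMatrix(["a"], ["f1", "f2"], [[1.0, 2.0]])
        Y = LabelMatrix(["a"], ["T1", "T2"], [[1, 0]])
        with pytest.raises(ValueError, match="at least 2"):
            jackknife(X, Y, k=1)


class TestOrderAccuracy:
    def test_perfect_first_rank_single_label(self):
        Y = LabelMatrix(["a", "b"], ["T1", "T2"], [[1, 0], [0, 1]])
        rankings = [
            LabelRanking("a", ["T1", "T2"], [1.0, 0.0]),
            LabelRanking("b", ["T2", "T1"], [1.0, 0.0]),
        ]
        prof = order_accuracy(rankings, Y)
        np.testing.assert_allclose(prof.accuracies, [1.0, 0.0])

    def test_conservation_is_exact_for_any_complete_ranking(self):
        X, Y = make_dataset(50, 5, 4, seed=22)
        prof = order_accuracy(jackknife(X, Y, k=4), Y)
        assert prof.accuracies.sum() * prof.m == pytest.approx(
            Y.label_mass, abs=1e-9
        )

    def test_random_rankings_hit_mean_labels_over_q_at_every_rank(self):
        # a uniformly random complete ranking puts a given true label at any
        # rank with equal probability, so E[A^i] = (mean labels) / q
        rng = np.random.default_rng(23)
        n, q = 200, 5
        _, Y = make_dataset(n, 3, q, seed=24)
        rankings = []
        for i, pid in enumerate(Y.protein_ids):
            order = rng.permutation(q)
            rankings.append(
                LabelRanking(pid, [Y.tags[j] for j in order], np.zeros(q))
            )
        prof = order_accuracy(rankings, Y)
        p = Y.label_mass / n / q
        sigma = np.sqrt(p * (1 - p) / n)
        for i in range(q):
            assert abs(prof.accuracies[i] - p) <= 3 * sigma

    def test_unknown_query_id_is_an_error(self):
        _, Y = make_dataset(5, 3, 3, seed=25)
        r = LabelRanking("nope", Y.tags, [0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="unknown protein"):
            order_accuracy([r], Y)


def _planted_dataset(seed, n=30, noise_features=10):
    """Labels are a deterministic function of feature 0; the rest is noise."""
    rng = np.random.default_rng(seed)
    f0 = rng.normal(size=n)
    inc = np.zeros((n, 2), dtype=int)
    inc[f0 > 0, 0] = 1
    inc[f0 <= 0, 1] = 1
    values = np.column_stack([f0 * 5, rng.normal(size=(n, noise_features))])
    ids = [f"p{i}" for i in range(n)]
    X = FeatureMatrix(ids, [f"f{j}" for j in range(noise_features + 1)], values)
    return X, LabelMatrix(ids, ["T1", "T2"], inc)


class TestIFS:
    def test_informative_prefix_beats_full_noise_set(self):
        X, Y = _planted_dataset(seed=26, n=40, noise_features=20)
        ranked = RankedFeatureList(np.arange(21), np.zeros(21), "maxrel")
        res = ifs_search(X, Y, ranked, k_grid=[3])
        grid = res.grid
        a1_first = float(grid[grid["n"] == 1]["A1"].iloc[0])
        a1_full = float(grid[grid["n"] == 21]["A1"].iloc[0])
        assert a1_first >= a1_full

    def test_single_cell_grid(self, small_dataset):
        X, Y = small_dataset
        ranked = RankedFeatureList([0], [0.0], "mrmr")
        res = ifs_search(X, Y, ranked, k_grid=[1])
        assert len(res.grid) == 1
        assert (res.best_k, res.best_n) == (1, 1)

    def test_grid_is_deterministic_across_reruns(self, small_dataset):
        X, Y = small_dataset
        ranked = RankedFeatureList(np.arange(X.d), np.zeros(X.d), "mrmr")
        r1 = ifs_search(X, Y, ranked, k_grid=[1, 3], max_n=4)
        r2 = ifs_search(X, Y, ranked, k_grid=[1, 3], max_n=4)
        assert r1.grid.equals(r2.grid)
        assert (r1.best_k, r1.best_n) == (r2.best_k, r2.best_n)

    def test_grid_matches_nested_loop_reference(self):
        # naive reference: independent loops over k, prefix length and
        # held-out row, recomputing each prediction from scratch
        X, Y = make_dataset(30, 8, 3, seed=27)
        ranked = RankedFeatureList(
            [5, 2, 7, 0, 1, 3, 4, 6], np.zeros(8), "mrmr"
        )
        res = ifs_search(X, Y, ranked, k_grid=[1, 3])
        for k in (1, 3):
            for n in range(1, 9):
                sub = ranked.order[:n]
                hits = np.zeros(Y.q)
                for z in range(X.n):
                    r = predict(X.values[z], X, Y, k, feature_subset=sub,
                                exclude=z, query_id=X.protein_ids[z])
                    row = Y.incidence[z]
                    tag_col = {t: j for j, t in enumerate(Y.tags)}
                    for i, tag in enumerate(r.ranked_tags):
                        hits[i] += row[tag_col[tag]]
                cell = res.grid[(res.grid["k"] == k) & (res.grid["n"] == n)]
                np.testing.assert_allclose(
                    cell.iloc[0][[f"A{i+1}" for i in range(Y.q)]].astype(float),
                    hits / X.n, atol=1e-12,
                )

    def test_best_cell_tie_breaks_prefer_small_n_then_small_k(self):
        X, Y = _planted_dataset(seed=28, n=20, noise_features=2)
        ranked = RankedFeatureList([0, 1, 2], np.zeros(3), "maxrel")
        res = ifs_search(X, Y, ranked, k_grid=[1, 3])
        grid = res.grid
        best = grid["A1"].max()
        tied = grid[grid["A1"] == best].sort_values(["n", "k"])
        assert res.best_n == int(tied["n"].iloc[0])
        assert res.best_k == int(tied["k"].iloc[0])

    def test_planted_signal_prefers_short_prefix_on_average(self):
        # over many draws the informative-only prefix is at least as accurate
        # as informative + noise, in expectation
        diffs = []
        for seed in range(20):
            X, Y = _planted_dataset(seed=100 + seed, n=24, noise_features=5)
            ranked = RankedFeatureList(np.arange(6), np.zeros(6), "maxrel")
            res = ifs_search(X, Y, ranked, k_grid=[3])
            g = res.grid
            diffs.append(
                float(g[g["n"] == 1]["A1"].iloc[0])
                - float(g[g["n"] == 6]["A1"].iloc[0])
            )
        assert np.mean(diffs) >= 0


class TestNestedIFS:
    def test_nested_mode_runs_and_conserves_label_mass(self):
        X, Y = make_dataset(16, 6, 3, seed=29)
        res = nested_ifs_search(X, Y, k_grid=[1, 3], max_n=3, threshold=0.0)
        assert len(res.grid) == 6
        for _, row in res.grid.iterrows():
            total = sum(row[f"A{i+1}"] for i in range(Y.q))
            assert total * X.n == pytest.approx(Y.label_mass, abs=1e-9)


class TestPlot:
    def test_plot_writes_image_and_reproducible_series(self, tmp_path):
        X, Y = make_dataset(20, 5, 3, seed=30)
        ranked = RankedFeatureList(np.arange(3), np.zeros(3), "mrmr")
        res = ifs_search(X, Y, ranked, k_grid=[1, 3])
        p1 = tmp_path / "curves1.png"
        p2 = tmp_path / "curves2.png"
        plot_ifs_curves(res, str(p1))
        plot_ifs_curves(res, str(p2))
        assert p1.exists() and p1.stat().st_size > 0
        s1 = (tmp_path / "curves1.png.tsv").read_bytes()
        s2 = (tmp_path / "curves2.png.tsv").read_bytes()
        assert s1 == s2
        header = s1.decode().splitlines()[0].split("\t")
        assert header[:2] == ["k", "n"]
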