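import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from cacaopheno import (
    WardClusterer,
    au_support,
    choose_k,
    cluster_distances,
    pca,
    pearson_matrix,
    ward_linkage,
)
from cacaopheno.multivariate import (
    cut_tree,
    gap_choose_k,
    gap_statistic,
    mean_inter_distances,
    _node_leafsets,
)


# -- independent brute-force Ward.D2 agglomerator (oracle) ------------------


def brute_force_ward(X):
    """O(n^3) Ward.D2: recompute every pairwise merge cost from scratch at
    each step; cost(A, B) = sqrt(2|A||B|/(|A|+|B|)) * ||mean_A - mean_B||."""
    X = np.asarray(X, dtype=float)
    clusters = {i: [i] for i in range(len(X))}
    next_id = len(X)
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                ma = X[clusters[a]].mean(axis=0)
                mb = X[clusters[b]].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                cost = np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(ma - mb)
                if best is None or cost < best[0]:
                    best = (cost, a, b)
        cost, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        merges.append((sorted((a, b)), cost, frozenset(clusters[next_id])))
        next_id += 1
    return merges


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(20)
        res = pearson_matrix(pd.DataFrame({"a": x, "b": x.copy()}))
        assert res.r.loc["a", "b"] == pytest.approx(1.0)
        assert res.p.loc["a", "b"] == 0.0

    def test_perfect_negative(self):
        res = pearson_matrix(pd.DataFrame({"x": [1, 2, 3], "y": [6, 4, 2]}))
        assert res.r.loc["x", "y"] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        res = pearson_matrix(pd.DataFrame({"x": [1, 2, 3, 4], "y": [2, 1, 4, 3]}))
        assert res.r.loc["x", "y"] == pytest.approx(0.6)
        assert res.band.loc["x", "y"] == "moderate"

    def test_zero_variance_column_flagged_not_fabricated(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(10), "c": np.ones(10)})
        res = pearson_matrix(df)
        assert res.constant_columns == ["c"]
        assert np.isnan(res.r.loc["x", "c"])

    def test_p_value_matches_scipy(self, rng):
        from scipy import stats

        x, y = rng.standard_normal((2, 15))
        res = pearson_matrix(pd.DataFrame({"x": x, "y": y}))
        r_ref, p_ref = stats.pearsonr(x, y)
        assert res.r.loc["x", "y"] == pytest.approx(r_ref)
        assert res.p.loc["x", "y"] == pytest.approx(p_ref, rel=1e-6)


class TestPCA:
    def test_two_variable_closed_form(self, rng):
        # construct two variables with exact sample correlation r
        r = 0.6
        z = rng.standard_normal((200, 2))
        # orthogonalize then mix to hit r exactly
        q, _ = np.linalg.qr(z - z.mean(axis=0))
        a = q[:, 0]
        b = r * q[:, 0] + np.sqrt(1 - r**2) * q[:, 1]
        model = pca(pd.DataFrame({"a": a, "b": b}))
        assert model.eigenvalues_.to_numpy() == pytest.approx([1.6, 0.4], abs=1e-9)
        assert model.contributions_["Dim1"].to_numpy() == pytest.approx(
            [50.0, 50.0], abs=1e-9
        )

    def test_contributions_sum_to_hundred(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 6)))
        model = pca(X)
        assert model.contributions_.sum(axis=0).to_numpy() == pytest.approx(
            np.full(6, 100.0)
        )

    def test_eigenvalues_sum_to_variable_count(self, rng):
        X = pd.DataFrame(rng.standard_normal((25, 7)))
        model = pca(X)
        assert model.eigenvalues_.sum() == pytest.approx(7.0)

    def test_correlation_reconstruction(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 5)))
        model = pca(X)
        V = model.components_.to_numpy().T
        w = model.eigenvalues_.to_numpy()
        R = (V * w) @ V.T
        assert np.allclose(R, model.correlation_.to_numpy(), atol=1e-8)

    def test_scores_centered(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 4)) + 7.0)
        model = pca(X)
        assert np.allclose(model.scores_.mean(axis=0), 0.0, atol=1e-10)

    def test_retention_rule(self, rng):
        # strongly collinear block: one dominant eigenvalue, retention must
        # still reach 75% cumulative variance
        base = rng.standard_normal(50)
        X = pd.DataFrame(
            {f"v{i}": base + 0.05 * rng.standard_normal(50) for i in range(4)}
        )
        model = pca(X)
        kaiser = int((model.eigenvalues_ > 1).sum())
        cum = model.pct_var_.cumsum()
        assert model.n_retained_ >= kaiser
        assert cum.iloc[model.n_retained_ - 1] >= 75.0

    def test_mean_imputation_of_missing_cells(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        X.loc[3, "a"] = np.nan
        model = pca(X)  # should not raise
        assert model.eigenvalues_.sum() == pytest.approx(3.0)


class TestWardLinkage:
    def test_two_points_merge_at_their_distance(self):
        Z = ward_linkage(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert Z[0, 2] == pytest.approx(5.0)

    def test_duplicate_points_merge_first_at_zero(self):
        X = np.array([[1.0, 1.0], [5.0, 5.0], [1.0, 1.0]])
        Z = ward_linkage(X)
        assert Z[0, 2] == pytest.approx(0.0)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 2}

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            ward_linkage(np.array([[1.0, np.nan], [0.0, 1.0]]))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        X = rng.standard_normal((n, 3))
        Z = ward_linkage(X)
        oracle = brute_force_ward(X)
        assert np.allclose(Z[:, 2], [m[1] for m in oracle], rtol=1e-9)
        ours = {frozenset(s) for s in _node_leafsets(Z, n)}
        theirs = {m[2] for m in oracle}
        assert ours == theirs

    def test_heights_monotone(self, rng):
        X = rng.standard_normal((30, 4))
        Z = ward_linkage(X)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)


class TestChooseK:
    def test_two_tight_blobs(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.05, (20, 2)), rng.normal(10, 0.05, (20, 2))]
        )
        Z = ward_linkage(X)
        sil, gap, K = choose_k(X, Z, range(2, 6), B_gap=10, seed=0)
        assert K == 2
        assert sil[2] > 0.9
        assert gap_choose_k(gap) <= 2

    def test_silhouette_bounded(self, rng):
        X = rng.standard_normal((25, 3))
        Z = ward_linkage(X)
        sil, _, _ = choose_k(X, Z, range(2, 8), B_gap=5, seed=0)
        assert ((sil >= -1) & (sil <= 1)).all()

    def test_gap_null_prefers_one_cluster(self):
        # single Gaussian blob: the gap rule should pick K = 1..2 in >= 90%
        # of seeds
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((50, 2))
            gap = gap_statistic(X, k_max=6, B=20, seed=seed + 1000)
            hits += gap_choose_k(gap) <= 2
        assert hits >= 0.9 * n_seeds

    def test_k_range_validated(self, rng):
        X = rng.standard_normal((10, 2))
        Z = ward_linkage(X)
        with pytest.raises(ValueError):
            choose_k(X, Z, range(2, 11), B_gap=5)


class TestAUSupport:
    def test_single_scale_collapses_to_bp(self, rng):
        X = rng.standard_normal((12, 6))
        Z = ward_linkage(X)
        res = au_support(X, Z, scales=[1.0], B=100, seed=0)
        assert np.allclose(res["AU"], res["BP"])

    def test_bounds(self, rng):
        X = rng.standard_normal((10, 8))
        Z = ward_linkage(X)
        res = au_support(X, Z, B=200, seed=0)
        assert ((res["AU"] >= 0) & (res["AU"] <= 1)).all()
        assert ((res["BP"] >= 0) & (res["BP"] <= 1)).all()

    def test_clear_bipartition_gets_high_support(self, rng):
        X = np.vstack(
            [rng.normal(0, 1, (10, 10)), rng.normal(100, 1, (10, 10))]
        )
        Z = ward_linkage(X)
        res = au_support(X, Z, B=200, seed=0)
        top = res[res["size"] == 10]
        assert (top["AU"] >= 0.95).all()

    def test_small_b_rejected(self, rng):
        X = rng.standard_normal((8, 4))
        Z = ward_linkage(X)
        with pytest.raises(ValueError):
            au_support(X, Z, B=50)


class TestClusterDistances:
    def test_identical_points_all_zero(self):
        X = np.ones((6, 2))
        D = squareform(pdist(X))
        res = cluster_distances(D, [1, 1, 1, 2, 2, 2])
        assert np.allclose(res.matrix.to_numpy(), 0.0)

    def test_hand_computed_two_cluster_example(self):
        pts = np.array([[0, 0], [0, 2], [10, 0], [10, 2]], dtype=float)
        D = squareform(pdist(pts))
        res = cluster_distances(D, ["A", "A", "B", "B"])
        assert res.matrix.loc["A", "A"] == pytest.approx(2.0)
        assert res.matrix.loc["B", "B"] == pytest.approx(2.0)
        expected = np.mean([10, np.sqrt(104), np.sqrt(104), 10])
        assert res.matrix.loc["A", "B"] == pytest.approx(expected, abs=1e-4)
        assert res.matrix.loc["A", "B"] == pytest.approx(10.0990, abs=1e-4)

    def test_matches_pair_enumeration(self, rng):
        X = rng.standard_normal((15, 3))
        labels = rng.integers(0, 3, 15)
        D = squareform(pdist(X))
        res = cluster_distances(D, labels)
        for a in range(3):
            for b in range(3):
                pairs = [
                    D[i, j]
                    for i in range(15)
                    for j in range(15)
                    if labels[i] == a and labels[j] == b and (i < j if a == b else True)
                ]
                if a == b and len(pairs) == 0:
                    continue
                assert res.matrix.loc[a, b] == pytest.approx(np.mean(pairs))

    def test_mean_distance_is_row_mean_of_inter_entries(self, rng):
        X = rng.standard_normal((20, 4))
        labels = rng.integers(0, 4, 20)
        D = squareform(pdist(X))
        res = cluster_distances(D, labels)
        M = res.matrix.to_numpy().copy()
        np.fill_diagonal(M, np.nan)
        assert np.allclose(res.mean_distance.to_numpy(), np.nanmean(M, axis=1))

    def test_singleton_cluster_flagged(self, rng):
        X = rng.standard_normal((5, 2))
        D = squareform(pdist(X))
        res = cluster_distances(D, [1, 1, 1, 1, 2])
        assert res.singleton_clusters == [2]
        assert res.matrix.loc[2, 2] == 0.0

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cluster_distances(np.zeros((3, 3)), [1, 2])


class TestWardClusterer:
    def test_recovers_planted_clusters(self, small_trial):
        from sklearn.metrics import adjusted_rand_score

        trial, truth = small_trial
        model = WardClusterer(n_clusters=4, B_gap=5).fit(trial.trait_matrix())
        ari = adjusted_rand_score(
            truth["labels"].reindex(model.index_), model.labels_
        )
        assert ari >= 0.9

    def test_sklearn_params_round_trip(self):
        model = WardClusterer(n_clusters=8, B_gap=7)
        params = model.get_params()
        assert params["n_clusters"] == 8
        clone = WardClusterer(**params)
        assert clone.get_params() == params

    def test_cut_labels_partition(self, small_trial):
        trial, _ = small_trial
        model = WardClusterer(n_clusters=4, B_gap=5).fit(trial.trait_matrix())
        labels = model.labels_series()
        assert sorted(labels.unique()) == [1, 2, 3, 4]
        assert len(labels) == 20


def test_mean_inter_distances_helper():
    mat = pd.DataFrame(
        [[1.0, 2.0, 4.0], [2.0, 1.5, 6.0], [4.0, 6.0, 0.5]],
        index=list("abc"), columns=list("abc"),
    )
    md = mean_inter_distances(mat)
    assert md["a"] == pytest.approx(3.0)
    assert md["b"] == pytest.approx(4.0)
    assert md["c"] == pytest.approx(5.0)
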