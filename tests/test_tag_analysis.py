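import numpy as np
import pandas as pd
import pytest

from topotag.tag_analysis import (
    BlockSimilarity,
    ClusterSolution,
    CorrelationResult,
    GeneFilterConfig,
    block_similarity,
    cluster_axis,
    correlation_matrix,
    filter_genes,
    log_transform,
    tag_report,
)


def _counts(columns: dict[str, list]) -> pd.DataFrame:
    df = pd.DataFrame(columns)
    df.index = [f"S{i}" for i in range(len(df))]
    return df


class TestFilterGenes:
    def test_zero_fraction_threshold_is_strict(self):
        n = 100
        over = [0] * 26 + [5] * 74   # 26% zeros: excluded
        at = [0] * 25 + [5] * 75     # exactly 25%: kept
        counts = _counts({"OVER": over, "AT": at})
        assert filter_genes(counts, GeneFilterConfig(0.25, 150)) == ["AT"]

    def test_truncation_noop_when_fewer_qualify(self, rng):
        counts = pd.DataFrame(rng.integers(1, 50, (40, 140)),
                              columns=[f"G{i:03d}" for i in range(140)])
        assert len(filter_genes(counts, GeneFilterConfig(0.25, 150))) == 140

    def test_ranked_by_log1p_variance_ties_by_gene_id(self):
        counts = _counts({
            "B": [1, 9, 1, 9], "A": [1, 9, 1, 9],   # tied variance
            "C": [4, 5, 4, 5],                       # smaller variance
        })
        assert filter_genes(counts, GeneFilterConfig(1.0, 2)) == ["A", "B"]

    def test_no_qualifying_gene_is_an_error(self):
        counts = _counts({"G": [0, 0, 0, 1]})
        with pytest.raises(ValueError, match="zero-read"):
            filter_genes(counts, GeneFilterConfig(0.25, 150))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            filter_genes(_counts({"G": [1, -2]}), GeneFilterConfig())


def test_log_transform_values_and_monotonicity():
    np.testing.assert_allclose(log_transform(np.array([0.0])), [0.0])
    np.testing.assert_allclose(log_transform(np.array([np.e - 1])), [1.0])
    x = np.linspace(0, 10, 50)
    assert (np.diff(log_transform(x)) > 0).all()
    with pytest.raises(ValueError):
        log_transform(np.array([-0.1]))


class TestCorrelationMatrix:
    def test_perfect_and_anti_correlation(self, rng):
        base = rng.normal(size=30)
        genes = pd.DataFrame({"G+": base, "G-": -base + 7.0},
                             index=[f"S{i}" for i in range(30)])
        itfs = pd.DataFrame({"F": base}, index=genes.index)
        res = correlation_matrix(genes, itfs)
        assert res.matrix.loc["G+", "F"] == pytest.approx(1.0)
        assert res.matrix.loc["G-", "F"] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self, rng):
        n = 1000
        genes = pd.DataFrame(rng.normal(size=(n, 5)),
                             columns=[f"G{i}" for i in range(5)])
        itfs = pd.DataFrame(rng.normal(size=(n, 5)),
                            columns=[f"F{i}" for i in range(5)])
        genes.index = itfs.index = [f"S{i}" for i in range(n)]
        res = correlation_matrix(genes, itfs)
        assert res.matrix.abs().to_numpy().max() < 0.1

    def test_zero_variance_columns_dropped_and_recorded(self, rng):
        idx = [f"S{i}" for i in range(20)]
        genes = pd.DataFrame({"G": rng.normal(size=20), "CONST": 3.0}, index=idx)
        itfs = pd.DataFrame({"F": rng.normal(size=20), "ZERO": 0.0}, index=idx)
        res = correlation_matrix(genes, itfs)
        assert res.dropped_genes == ["CONST"]
        assert res.dropped_itfs == ["ZERO"]
        assert not res.matrix.isna().any().any()

    def test_too_few_spots_rejected(self):
        df = pd.DataFrame({"A": [1.0, 2.0]}, index=["S0", "S1"])
        with pytest.raises(ValueError, match="3 spots"):
            correlation_matrix(df, df)

    def test_mismatched_index_rejected(self, rng):
        a = pd.DataFrame({"A": rng.normal(size=5)}, index=list("abcde"))
        b = pd.DataFrame({"B": rng.normal(size=5)}, index=list("abcdf"))
        with pytest.raises(ValueError, match="spot index"):
            correlation_matrix(a, b)

    def test_itf_rescaling_leaves_pcc_unchanged(self, rng):
        """Positive rescaling of ITFs cannot change the correlation matrix,
        so the persistence scale convention cannot affect TAG calls."""
        idx = [f"S{i}" for i in range(50)]
        genes = pd.DataFrame(rng.normal(size=(50, 4)), index=idx,
                             columns=list("ABCD"))
        itfs = pd.DataFrame(rng.uniform(1, 2, size=(50, 6)), index=idx,
                            columns=[f"F{i}" for i in range(6)])
        scales = rng.uniform(0.01, 100, size=6)
        res1 = correlation_matrix(genes, itfs)
        res2 = correlation_matrix(genes, itfs * scales)
        np.testing.assert_allclose(res1.matrix, res2.matrix, atol=1e-12)


def _blob_corr(rng, n_per=8, k=3, n_itfs=12):
    """Correlation-profile matrix with k well-separated gene blobs."""
    centers = rng.uniform(-0.9, 0.9, size=(k, n_itfs))
    while np.min(
        np.linalg.norm(centers[:, None] - centers[None], axis=-1)
        + np.eye(k) * 99
    ) < 1.5:
        centers = rng.uniform(-0.9, 0.9, size=(k, n_itfs))
    rows, ids, truth = [], [], []
    for c in range(k):
        for i in range(n_per):
            rows.append(centers[c] + rng.normal(0, 0.02, n_itfs))
            ids.append(f"G{c}_{i}")
            truth.append(c)
    mat = pd.DataFrame(np.clip(rows, -1, 1), index=ids,
                       columns=[f"F{j:02d}" for j in range(n_itfs)])
    return CorrelationResult(mat), np.asarray(truth)


class TestClusterAxis:
    def test_recovers_three_blobs_with_elbow(self, rng):
        corr, truth = _blob_corr(rng)
        sol = cluster_axis(corr, "genes", k_range=(2, 8), seed=0)
        assert sol.k_chosen == 3
        # assignments recover the blobs exactly (up to label permutation)
        df = pd.DataFrame({"found": sol.assignments.to_numpy(), "truth": truth})
        assert (df.groupby("truth")["found"].nunique() == 1).all()
        assert df["found"].nunique() == 3
        # WCSS at the chosen k matches a direct recomputation from labels
        X = corr.matrix.to_numpy()
        labels = sol.assignments.to_numpy()
        wcss = sum(
            ((X[labels == c] - X[labels == c].mean(axis=0)) ** 2).sum()
            for c in np.unique(labels)
        )
        assert wcss == pytest.approx(sol.wcss_by_k[3], rel=1e-9)

    def test_identical_rows_choose_smallest_interior_k(self):
        mat = pd.DataFrame(np.ones((10, 4)) * 0.5,
                           index=[f"G{i}" for i in range(10)],
                           columns=list("WXYZ"))
        sol = cluster_axis(CorrelationResult(mat), "genes", k_range=(2, 6), seed=0)
        assert sol.wcss_by_k[2] == pytest.approx(0.0, abs=1e-12)
        assert sol.k_chosen == 3  # flat curve: tie broken toward min interior k

    def test_deterministic_under_seed(self, rng):
        corr, _ = _blob_corr(rng)
        a = cluster_axis(corr, "genes", (2, 6), seed=5)
        b = cluster_axis(corr, "genes", (2, 6), seed=5)
        pd.testing.assert_series_equal(a.assignments, b.assignments)
        assert a.k_chosen == b.k_chosen

    def test_cluster_ids_contiguous_from_one(self, rng):
        corr, _ = _blob_corr(rng)
        sol = cluster_axis(corr, "genes", (2, 6), seed=1)
        labels = sorted(set(sol.assignments))
        assert labels == list(range(1, sol.k_chosen + 1))

    def test_invalid_k_range_rejected(self, rng):
        corr, _ = _blob_corr(rng)
        with pytest.raises(ValueError, match="k_range"):
            cluster_axis(corr, "genes", (1, 5))
        with pytest.raises(ValueError, match="k_range"):
            cluster_axis(corr, "genes", (2, 500))

    def test_itf_axis_clusters_columns(self, rng):
        corr, _ = _blob_corr(rng)
        sol = cluster_axis(corr, "itfs", (2, 6), seed=0)
        assert set(sol.assignments.index) == set(corr.itf_names)


def _solution(axis, mapping):
    s = pd.Series(mapping, name="cluster")
    return ClusterSolution(axis=axis, k_chosen=len(set(mapping.values())),
                           assignments=s, wcss_by_k={}, seed=0)


class TestBlockSimilarity:
    def test_block_diagonal_identity_pairing(self):
        mat = pd.DataFrame(np.kron(np.eye(3) * 0.9, np.ones((2, 2))),
                           index=[f"G{i}" for i in range(6)],
                           columns=[f"F{i}" for i in range(6)])
        g = _solution("genes", {f"G{i}": i // 2 + 1 for i in range(6)})
        f = _solution("itfs", {f"F{i}": i // 2 + 1 for i in range(6)})
        sim = block_similarity(CorrelationResult(mat), g, f)
        assert sim.most_similar == {1: 1, 2: 2, 3: 3}

    def test_uniform_matrix_ties_select_cluster_one(self):
        mat = pd.DataFrame(np.full((4, 4), 0.3),
                           index=[f"G{i}" for i in range(4)],
                           columns=[f"F{i}" for i in range(4)])
        g = _solution("genes", {f"G{i}": i % 2 + 1 for i in range(4)})
        f = _solution("itfs", {f"F{i}": i % 2 + 1 for i in range(4)})
        sim = block_similarity(CorrelationResult(mat), g, f)
        assert sim.most_similar == {1: 1, 2: 1}

    def test_block_mean_matches_direct_summation(self, rng):
        mat = pd.DataFrame(rng.uniform(-1, 1, (7, 5)),
                           index=[f"G{i}" for i in range(7)],
                           columns=[f"F{i}" for i in range(5)])
        g_map = {f"G{i}": rng.integers(1, 4) for i in range(7)}
        f_map = {f"F{i}": rng.integers(1, 3) for i in range(5)}
        g, f = _solution("genes", g_map), _solution("itfs", f_map)
        sim = block_similarity(CorrelationResult(mat), g, f)
        for fc in sim.block_means.index:
            for gc in sim.block_means.columns:
                cells = [
                    mat.loc[gi, fi]
                    for gi in mat.index if g_map[gi] == gc
                    for fi in mat.columns if f_map[fi] == fc
                ]
                if cells:
                    assert sim.block_means.loc[fc, gc] == pytest.approx(
                        np.mean(cells))


class TestTagReport:
    def test_per_gene_max_abs_pcc_matches_row_max(self, rng):
        corr, _ = _blob_corr(rng)
        g = cluster_axis(corr, "genes", (2, 6), seed=0)
        f = cluster_axis(corr, "itfs", (2, 6), seed=0)
        sim = block_similarity(corr, g, f)
        report = tag_report(corr, g, f, sim)
        genes = report["genes"].set_index("gene_id")
        assert len(genes) == len(corr.gene_ids)
        for gid in corr.gene_ids:
            row = corr.matrix.loc[gid]
            assert genes.loc[gid, "max_abs_pcc"] == pytest.approx(row.abs().max())
            assert genes.loc[gid, "best_itf"] == row.abs().idxmax()
            assert genes.loc[gid, "best_pcc"] == pytest.approx(
                row[row.abs().idxmax()])

    def test_tables_cover_all_items(self, rng):
        corr, _ = _blob_corr(rng)
        g = cluster_axis(corr, "genes", (2, 6), seed=0)
        f = cluster_axis(corr, "itfs", (2, 6), seed=0)
        report = tag_report(corr, g, f, block_similarity(corr, g, f))
        assert set(report["tag_clusters"]["gene_id"]) == set(corr.gene_ids)
        order = report["heatmap_order"]
        assert set(order.loc[order["axis"] == "itfs", "item"]) == set(corr.itf_names)
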