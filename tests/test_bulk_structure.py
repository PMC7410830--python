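"""Bulk transcriptome structuring: partition, PCA, clustering, CCA, sex."""

import numpy as np
import pandas as pd
import pytest

from devdecomp import bulk_structure as bs


def make_matrix(values, tissues=None, **meta_cols):
    """Small ExpressionMatrix helper; values is genes x samples."""
    df = pd.DataFrame(values)
    df.index = [f"g{i}" for i in range(len(df))] if df.index.dtype != object else df.index
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    meta = pd.DataFrame(
        {
            "tissue": tissues or ["T1"] * df.shape[1],
            "stage": [f"S{i}" for i in range(df.shape[1])],
            **meta_cols,
        },
        index=df.columns,
    )
    return bs.ExpressionMatrix(values=df, sample_meta=meta)


class TestLogTransform:
    def test_closed_form_values(self):
        df = pd.DataFrame({"s": [0.0, 0.9]})
        out = bs.log_transform(df)
        assert out.iloc[0, 0] == pytest.approx(np.log2(0.1))
        assert out.iloc[1, 0] == pytest.approx(0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bs.log_transform(pd.DataFrame({"s": [-1.0]}))

    def test_matrix_matches_scalar_loop(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.uniform(0, 50, (20, 5)))
        out = bs.log_transform(df)
        for i in range(20):
            for j in range(5):
                assert out.iloc[i, j] == pytest.approx(np.log2(df.iloc[i, j] + 0.1))


class TestPrefilter:
    def _matrix(self, counts, biotype=None):
        m = make_matrix(np.ones((len(counts), len(counts[0]))))
        m.read_counts = pd.DataFrame(counts, index=m.genes, columns=m.samples)
        if biotype:
            m.gene_biotype = pd.Series(biotype, index=m.genes)
        return m

    def test_below_threshold_everywhere_removed(self):
        m = self._matrix([[9, 9, 9], [9, 10, 0], [100, 0, 0]])
        filt, removed = bs.prefilter_genes(m)
        assert removed == ["g0"]
        assert list(filt.genes) == ["g1", "g2"]

    def test_trna_removed(self):
        m = self._matrix([[50, 50]] * 2, biotype=["tRNA", "protein_coding"])
        _, removed = bs.prefilter_genes(m)
        assert removed == ["g0"]

    def test_requires_count_table(self):
        m = make_matrix(np.ones((2, 3)))
        with pytest.raises(ValueError, match="read-count"):
            bs.prefilter_genes(m)

    def test_random_fixture_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 20, (50, 6))
        m = self._matrix(counts)
        filt, removed = bs.prefilter_genes(m)
        expected_removed = [f"g{i}" for i in range(50) if max(counts[i]) < 10]
        assert removed == expected_removed


class TestPartition:
    def test_boundary_inclusive(self):
        m = make_matrix([[1.0, 10.0, 3.0], [2.0, 19.9, 2.0]])
        part = bs.partition_dynamic_genes(m)
        assert part.labels["g0"] == "dynamic"  # ratio exactly 10
        assert part.labels["g1"] == "ubiquitous"

    def test_zero_minimum_uses_pseudocount_floor(self):
        m = make_matrix([[0.0, 0.5]])
        part = bs.partition_dynamic_genes(m)
        assert part.fold_ratio["g0"] == pytest.approx(5.0)  # 0.5 / 0.1

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            bs.partition_dynamic_genes(make_matrix([[1.0]]))

    def test_recovers_planted_truth(self, bulk_data):
        matrix, truth = bulk_data
        filt, removed = bs.prefilter_genes(matrix)
        assert set(removed) == truth.planted_removed
        part = bs.partition_dynamic_genes(filt, removed=removed)
        for g, dyn in truth.planted_dynamic.items():
            assert part.labels[g] == ("dynamic" if dyn else "ubiquitous"), g

    def test_matches_bruteforce_scan(self, bulk_data):
        matrix, _ = bulk_data
        filt, _ = bs.prefilter_genes(matrix)
        part = bs.partition_dynamic_genes(filt)
        v = filt.values
        for g in list(filt.genes)[::37]:
            row = v.loc[g].values
            expected = "dynamic" if row.max() / max(row.min(), 0.1) >= 10 else "ubiquitous"
            assert part.labels[g] == expected


@pytest.fixture(scope="module")
def logm(bulk_data):
    matrix, _ = bulk_data
    filt, _ = bs.prefilter_genes(matrix)
    return bs.log_transform(filt.values)


@pytest.fixture(scope="module")
def fitted(bulk_data):
    matrix, truth = bulk_data
    filt, _ = bs.prefilter_genes(matrix)
    pca = bs.run_pca(bs.log_transform(filt.values))
    design = bs.encode_metadata(filt.sample_meta)
    return filt, truth, pca, design


class TestPCA:
    def test_duplicated_samples_share_scores(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(30, 1))
        X = pd.DataFrame(
            np.hstack([base, base, rng.normal(size=(30, 4))]),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(6)],
        )
        pca = bs.run_pca(X, n_pcs=3)
        np.testing.assert_allclose(
            pca.scores.loc["s0"], pca.scores.loc["s1"], atol=1e-8
        )

    def test_rank_one_matrix_concentrates_variance(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(40, 1))
        v = rng.normal(size=(1, 8))
        X = pd.DataFrame(u @ v + 1e-4 * rng.normal(size=(40, 8)))
        X.index = [f"g{i}" for i in range(40)]
        pca = bs.run_pca(X, n_pcs=3)
        assert pca.var_explained.iloc[0] >= 0.99

    def test_loadings_orthonormal(self, logm):
        pca = bs.run_pca(logm, n_pcs=10)
        G = pca.loadings.values.T @ pca.loadings.values
        np.testing.assert_allclose(G, np.eye(10), atol=1e-8)

    def test_scores_standardized(self, logm):
        pca = bs.run_pca(logm, n_pcs=10)
        np.testing.assert_allclose(pca.scores.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(pca.scores.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_full_reconstruction(self, logm):
        k = min(logm.shape)
        pca = bs.run_pca(logm, n_pcs=k)
        Xc = logm.T.values - logm.T.values.mean(axis=0)
        rec = pca.raw_scores.values @ pca.loadings.values.T
        assert np.linalg.norm(rec - Xc) / np.linalg.norm(Xc) < 1e-8

    def test_too_many_pcs_rejected(self, logm):
        with pytest.raises(ValueError):
            bs.run_pca(logm, n_pcs=logm.shape[1] + 1)


class TestTopLoadingGenes:
    def _pca(self):
        load = pd.DataFrame(
            {"PC1": [0.9, -0.9, 0.1, 0.1, -0.1]},
            index=["gB", "gA", "gC", "gD", "gE"],
        )
        return bs.PCAResult(load, None, None, None)

    def test_extremes_selected(self):
        pos, neg = bs.top_loading_genes(self._pca(), "PC1", k=1)
        assert pos == ["gB"] and neg == ["gA"]

    def test_ties_lexicographic(self):
        load = pd.DataFrame({"PC1": [0.5, 0.5, -0.5, -0.5]}, index=["gB", "gA", "gD", "gC"])
        pca = bs.PCAResult(load, None, None, None)
        pos, neg = bs.top_loading_genes(pca, "PC1", k=1)
        assert pos == ["gA"] and neg == ["gC"]

    def test_disjoint_when_k_small(self):
        pos, neg = bs.top_loading_genes(self._pca(), "PC1", k=2)
        assert not set(pos) & set(neg)

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            bs.top_loading_genes(self._pca(), "PC1", k=10)


class TestClusterGenes:
    def _two_blocks(self, n_a=40, n_b=40, seed=0):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, 12)
        rows, ids = [], []
        for i in range(n_a):
            rows.append(t * 5 + rng.normal(0, 0.05, len(t)))
            ids.append(f"A{i:02d}")
        for i in range(n_b):
            rows.append(-t * 5 + rng.normal(0, 0.05, len(t)))
            ids.append(f"B{i:02d}")
        return pd.DataFrame(rows, index=ids, columns=[f"s{j}" for j in range(len(t))])

    def test_two_anticorrelated_blocks_found(self):
        cs = bs.cluster_genes(self._two_blocks(), min_clade=30)
        assert len(cs.major_clusters) == 2
        members = [set(m) for _, m in cs.major_clusters]
        assert {frozenset(m) for m in members} == {
            frozenset(f"A{i:02d}" for i in range(40)),
            frozenset(f"B{i:02d}" for i in range(40)),
        }

    def test_small_block_not_major(self):
        X = self._two_blocks(n_a=40, n_b=25)
        cs = bs.cluster_genes(X, min_clade=30)
        b_block = {f"B{i:02d}" for i in range(25)}
        assert all(set(m) != b_block for _, m in cs.major_clusters)

    def test_leaf_count_conserved(self):
        X = self._two_blocks()
        cs = bs.cluster_genes(X, min_clade=30)
        total = sum(len(m) for _, m in cs.major_clusters)
        assert total <= len(X)
        assigned = set().union(*(m for _, m in cs.major_clusters))
        assert len(assigned) == total  # clusters are disjoint

    def test_input_order_invariant(self):
        X = self._two_blocks()
        shuffled = X.sample(frac=1, random_state=3)
        a = bs.cluster_genes(X, min_clade=30)
        b = bs.cluster_genes(shuffled, min_clade=30)
        assert [m for _, m in a.major_clusters] == [m for _, m in b.major_clusters]

    def test_constant_gene_warns(self):
        X = self._two_blocks(n_a=5, n_b=5)
        X.loc["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            bs.cluster_genes(X, min_clade=3)


class TestCCA:
    def test_metadata_copy_of_pc_gives_unit_correlation(self, fitted):
        _, _, pca, _ = fitted
        design = pd.DataFrame({"pc1_copy": pca.scores["PC1"].values}, index=pca.scores.index)
        cca = bs.run_cca(pca, design)
        assert cca.correlations[0] == pytest.approx(1.0, abs=1e-8)

    def test_correlations_in_range_and_sorted(self, fitted):
        _, _, pca, design = fitted
        cca = bs.run_cca(pca, design)
        assert np.all(cca.correlations >= 0) and np.all(cca.correlations <= 1)
        assert np.all(np.diff(cca.correlations) <= 1e-9)

    def test_gene_loadings_equal_explicit_product(self, fitted):
        _, _, pca, design = fitted
        cca = bs.run_cca(pca, design)
        explicit = pca.loadings.values @ cca.x_coef.values
        assert np.abs(explicit - cca.gene_loadings.values).max() < 1e-10

    def test_sex_axis_recovers_planted_genes(self, fitted):
        filt, truth, pca, design = fitted
        cca = bs.run_cca(pca, design)
        sex = (filt.sample_meta["sex"] == "female").astype(float).values
        corrs = {
            c: abs(np.corrcoef(cca.y_variates[c], sex)[0, 1])
            for c in cca.y_variates.columns
        }
        cc_sex = max(corrs, key=corrs.get)
        top10 = set(cca.gene_loadings[cc_sex].abs().sort_values(ascending=False).index[:10])
        assert "Xist" in top10 and "Ddx3y" in top10

    def test_invariant_to_invertible_recoding(self, fitted):
        _, _, pca, design = fitted
        design = bs._drop_collinear(design)
        rng = np.random.default_rng(0)
        while True:
            A = rng.normal(size=(design.shape[1], design.shape[1]))
            if abs(np.linalg.det(A)) > 1e-3:
                break
        recoded = pd.DataFrame(design.values @ A, index=design.index)
        recoded.columns = [f"m{i}" for i in range(recoded.shape[1])]
        a = bs.run_cca(pca, design)
        b = bs.run_cca(pca, recoded)
        np.testing.assert_allclose(a.correlations, b.correlations, atol=1e-8)

    def test_matches_statsmodels(self, fitted):
        from statsmodels.multivariate.cancorr import CanCorr

        _, _, pca, design = fitted
        design = bs._drop_collinear(design)
        ours = bs.run_cca(pca, design)
        sm = CanCorr(design.values, pca.scores.values)
        np.testing.assert_allclose(
            ours.correlations, np.asarray(sm.cancorr)[: len(ours.correlations)], atol=1e-8
        )

    def test_too_few_samples_rejected(self, fitted):
        _, _, pca, design = fitted
        small_scores = pca.scores.iloc[:5]
        small_pca = bs.PCAResult(pca.loadings, small_scores, pca.raw_scores.iloc[:5], pca.var_explained)
        with pytest.raises(ValueError):
            bs.run_cca(small_pca, design.iloc[:5])


class TestInferSex:
    def _matrix(self, xist, ddx3y):
        v = pd.DataFrame({"s0": [xist, ddx3y]}, index=["Xist", "Ddx3y"])
        meta = pd.DataFrame({"tissue": ["T"], "stage": ["S"]}, index=["s0"])
        return bs.ExpressionMatrix(values=v, sample_meta=meta)

    @pytest.mark.parametrize(
        "xist,ddx3y,expected",
        [(5, 0, "female"), (0, 5, "male"), (4, 2, "mixed"), (0.5, 0.2, "unknown")],
    )
    def test_rules(self, xist, ddx3y, expected):
        assert bs.infer_sex(self._matrix(xist, ddx3y))["s0"] == expected

    def test_missing_marker_rejected(self):
        m = self._matrix(1, 1)
        with pytest.raises(ValueError, match="absent"):
            bs.infer_sex(m, xist_id="NotAGene")

    def test_full_agreement_with_planted_sex(self, bulk_data):
        matrix, truth = bulk_data
        calls = bs.infer_sex(matrix)
        assert all(calls[s] == truth.planted_sex[s] for s in calls.index)


class TestStratifyUbiquitous:
    def test_three_genes_one_per_group(self):
        logm = pd.DataFrame(
            {"s0": [3.0, 4.0, 5.0], "s1": [3.0, 4.0, 5.0]},
            index=["lo", "mid", "hi"],
        )
        out = bs.stratify_ubiquitous(logm, ["lo", "mid", "hi"], n=3)
        assert out == {"high": ["hi"], "medium": ["mid"], "low": ["lo"]}

    def test_boundary_value_two_removed(self):
        logm = pd.DataFrame({"s0": [2.0, 2.1], "s1": [2.0, 2.1]}, index=["at", "above"])
        with pytest.warns(UserWarning):
            out = bs.stratify_ubiquitous(logm, ["at", "above"], n=2)
        assert "at" not in sum(out.values(), [])

    def test_groups_match_sort_oracle(self, bulk_data):
        matrix, _ = bulk_data
        filt, _ = bs.prefilter_genes(matrix)
        part = bs.partition_dynamic_genes(filt)
        logm = bs.log_transform(filt.values)
        ubi = part.genes_with("ubiquitous")
        n = 300
        out = bs.stratify_ubiquitous(logm, ubi, n=n)
        assert len(out["high"]) == len(out["medium"]) == len(out["low"]) == n // 3
        # oracle: high group means all >= medium group means >= low
        mean_fpkm = (np.power(2.0, logm) - 0.1).mean(axis=1)
        assert mean_fpkm[out["high"]].min() >= mean_fpkm[out["medium"]].max() - 1e-12
        assert mean_fpkm[out["medium"]].min() >= mean_fpkm[out["low"]].max() - 1e-12
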