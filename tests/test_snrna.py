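"""snRNA-seq QC, normalization, typing, receptor classes, DE and dendrograms."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

import songkit.snrna as sn
from songkit.snrna import (
    MARKER_TABLE,
    PathwayGrouping,
    QCConfig,
    assign_cell_types,
    bootstrap_dendrogram,
    coexpression_summary,
    flag_mito,
    log_normalize,
    marker_summary,
    mito_fraction,
    pathway_de,
    qc_filter,
    receptor_class,
    receptor_classes,
    receptor_shift_test,
)


def toy_adata(counts, genes, cells=None, mito=("MT-G1",)):
    cells = cells or [f"c{i}" for i in range(len(counts))]
    adata = AnnData(
        X=sp.csr_matrix(np.asarray(counts, dtype=np.float64)),
        obs=pd.DataFrame(index=cells),
        var=pd.DataFrame(index=genes),
    )
    return flag_mito(adata, mito_genes=[g for g in mito if g in genes] or None)


class TestQC:
    def test_doublet_and_damage_rules(self):
        counts = [
            [12000, 0, 100],  # high UMI -> removed
            [2940, 0, 60],  # 2% mito -> kept
            [900, 0, 100],  # 10% mito -> removed
            [9500, 0, 500],  # exactly 10,000 UMI and 5% mito -> kept (strict >)
        ]
        adata = toy_adata(counts, ["GeneA", "GeneB", "MT-G1"])
        kept, report = qc_filter(adata)
        assert list(kept.obs_names) == ["c1", "c3"]
        reasons = dict(zip(report["barcode"], report["reason"]))
        assert reasons == {"c0": "high_umi", "c2": "high_mito"}

    def test_predicate_oracle_equivalence(self):
        rng = np.random.default_rng(0)
        cfg = QCConfig()
        counts = rng.integers(0, 4000, size=(50, 4))
        adata = toy_adata(counts, ["G1", "G2", "G3", "MT-G1"])
        kept, _ = qc_filter(adata, cfg)
        expected = [
            f"c{i}"
            for i, row in enumerate(counts)
            if row.sum() <= cfg.umi_max
            and 100 * row[3] / max(row.sum(), 1) <= cfg.mito_pct_max
        ]
        assert list(kept.obs_names) == expected

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        counts = np.column_stack(
            [
                rng.integers(500, 8000, size=40),
                rng.integers(500, 8000, size=40),
                rng.integers(0, 400, size=40),  # mito: some cells exceed 5%
            ]
        )
        adata = toy_adata(counts, ["G1", "G2", "MT-G1"])
        once, _ = qc_filter(adata)
        twice, report = qc_filter(once)
        assert list(once.obs_names) == list(twice.obs_names)
        assert report.empty

    def test_all_removed_is_error(self):
        adata = toy_adata([[20000, 0]], ["G1", "G2"], mito=())
        with pytest.raises(ValueError):
            qc_filter(adata)

    def test_mito_fraction(self):
        adata = toy_adata([[950, 50]], ["G1", "MT-G1"])
        assert mito_fraction(adata, "c0") == pytest.approx(5.0)
        adata0 = toy_adata([[1000, 0]], ["G1", "MT-G1"])
        assert mito_fraction(adata0, "c0") == 0.0


class TestNormalization:
    def test_ln101_closed_form(self):
        adata = toy_adata([[10, 990]], ["G1", "G2"], mito=())
        log_normalize(adata)
        # count 10 of 1000 total, scaled by 1e4: ln(1 + 100) = ln(101)
        assert adata.X[0, 0] == pytest.approx(math.log(101), abs=1e-9)
        assert math.log(101) == pytest.approx(4.6151, abs=1e-4)

    def test_zero_count_maps_to_zero(self):
        adata = toy_adata([[0, 100]], ["G1", "G2"], mito=())
        log_normalize(adata)
        assert adata.X[0, 0] == 0.0

    def test_zero_total_cell_is_error(self):
        adata = toy_adata([[0, 0], [1, 1]], ["G1", "G2"], mito=())
        with pytest.raises(ValueError):
            log_normalize(adata)

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 50, size=(10, 6)) + 1
        genes = [f"G{i}" for i in range(6)]
        perm = rng.permutation(6)
        a = toy_adata(counts, genes, mito=())
        b = toy_adata(counts[:, perm], [genes[j] for j in perm], mito=())
        log_normalize(a)
        log_normalize(b)
        assert np.allclose(a[:, [genes[j] for j in perm]].X.toarray(), b.X.toarray())


class TestClustering:
    def test_two_programs_recovered(self, clustered_sim):
        adata, truth, types, _ = clustered_sim
        from sklearn.metrics import adjusted_rand_score

        singlets = ~truth["doublet"]
        ari = adjusted_rand_score(
            truth.loc[singlets, "program"], adata.obs["cluster"][singlets.to_numpy()]
        )
        assert ari > 0.95

    def test_clusters_numbered_by_decreasing_size(self, clustered_sim):
        adata, *_ = clustered_sim
        sizes = adata.obs["cluster"].value_counts().sort_index()
        assert list(sizes.index) == list(range(1, len(sizes) + 1))
        assert list(sizes) == sorted(sizes, reverse=True)

    def test_identical_cells_single_cluster(self):
        counts = np.tile([[5, 3, 2, 1]], (30, 1))
        adata = toy_adata(counts, ["G1", "G2", "G3", "G4"], mito=())
        log_normalize(adata)
        with pytest.raises(ValueError):
            sn.cluster_cells(adata, seed=0)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        counts = np.vstack(
            [rng.poisson(5, size=(40, 20)), rng.poisson([20] * 10 + [1] * 10, size=(40, 20))]
        )
        adata = toy_adata(counts + 1, [f"G{i}" for i in range(20)], mito=())
        log_normalize(adata)
        a = sn.cluster_cells(adata.copy(), seed=11).obs["cluster"]
        b = sn.cluster_cells(adata.copy(), seed=11).obs["cluster"]
        assert (a.to_numpy() == b.to_numpy()).all()

    def test_elbow_selector(self):
        ratio = np.array([0.4, 0.2, 0.1, 0.02, 0.015, 0.012, 0.01])
        k = sn.elbow_n_pcs(ratio)
        assert 2 <= k <= 4


class TestMarkerSummary:
    def test_hand_tally(self):
        counts = [[0, 4], [2, 4], [0, 4], [3, 4]]
        adata = toy_adata(counts, ["G1", "G2"], mito=())
        log_normalize(adata)
        adata.obs["cluster"] = [1, 1, 2, 2]
        ms = marker_summary(adata, "G1")
        assert ms.loc[1, "pct_expressing"] == 50.0
        assert ms.loc[2, "pct_expressing"] == 50.0
        v = adata[:, "G1"].X.toarray().ravel()
        assert ms.loc[1, "mean_expression"] == pytest.approx(v[:2].mean())

    def test_all_zero_gene(self):
        adata = toy_adata([[0, 5], [0, 5]], ["G1", "G2"], mito=())
        log_normalize(adata)
        adata.obs["cluster"] = [1, 1]
        ms = marker_summary(adata, "G1")
        assert ms.loc[1, "pct_expressing"] == 0.0
        assert ms.loc[1, "mean_expression"] == 0.0

    def test_unknown_gene_error(self, clustered_sim):
        adata, *_ = clustered_sim
        with pytest.raises(KeyError):
            marker_summary(adata, "NotAGene")


class TestCellTypes:
    def test_simulated_programs_typed(self, clustered_sim):
        adata, truth, types, _ = clustered_sim
        singlets = ~truth["doublet"].to_numpy()
        clusters = adata.obs["cluster"].to_numpy()
        for cid, called in types.items():
            inside = (clusters == cid) & singlets
            if not inside.any():
                continue
            majority = truth.loc[inside, "program"].mode()[0]
            expected = {
                "PN": "PN",
                "Glut": "Glutamatergic",
                "Astrocyte": "Astrocyte",
                "Oligodendrocyte": "Oligodendrocyte",
                "OPC": "Oligodendrocyte Precursor",
                "Microglia": "Microglia",
                "Endothelial": "Endothelial",
            }.get(majority, "MSN" if majority.startswith("MSN") else "Interneuron")
            assert called == expected, (cid, majority, called)

    def test_mbp_only_cluster_is_oligodendrocyte(self):
        rng = np.random.default_rng(4)
        base = rng.poisson(2, size=(30, 5)) + 1
        counts = np.vstack([base, base])
        counts[30:, 4] += 40  # Mbp high in the second block
        genes = ["G1", "G2", "G3", "G4", "Mbp"]
        adata = toy_adata(counts, genes, mito=())
        log_normalize(adata)
        adata.obs["cluster"] = [1] * 30 + [2] * 30
        types = assign_cell_types(adata)
        assert types[2] == "Oligodendrocyte"

    def test_no_marker_above_threshold_unassigned(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(3, size=(20, 4)) + 1
        adata = toy_adata(counts, ["G1", "G2", "G3", "G4"], mito=())
        log_normalize(adata)
        adata.obs["cluster"] = [1] * 20
        assert assign_cell_types(adata) == {1: "unassigned"}

    def test_empty_marker_table_error(self, clustered_sim):
        adata, *_ = clustered_sim
        with pytest.raises(ValueError):
            assign_cell_types(adata, markers={})


class TestReceptorClasses:
    def make(self, rows):
        genes = ["Drd1", "Drd5", "Drd2", "FoxP2", "Other"]
        adata = toy_adata(rows, genes, mito=())
        log_normalize(adata)
        return adata

    @pytest.mark.parametrize(
        "row, expected",
        [
            ([2, 0, 0, 0, 5], "D1/5-only"),
            ([0, 1, 0, 0, 5], "D1/5-only"),
            ([0, 0, 3, 0, 5], "D2-only"),
            ([1, 0, 1, 0, 5], "both"),
            ([0, 0, 0, 0, 5], "none"),
        ],
    )
    def test_rules(self, row, expected):
        adata = self.make([row])
        cls, fox = receptor_class(adata, "c0")
        assert cls == expected and fox is False

    def test_foxp2_flag(self):
        adata = self.make([[1, 0, 0, 2, 5]])
        assert receptor_class(adata, "c0") == ("D1/5-only", True)

    def test_partition_sums(self):
        rng = np.random.default_rng(6)
        rows = rng.integers(0, 2, size=(40, 5)) * rng.integers(1, 4, size=(40, 5))
        rows[:, 4] += 1  # keep totals positive
        adata = self.make(rows)
        classes = receptor_classes(adata)
        assert classes["receptor_class"].value_counts().sum() == 40

    def test_missing_receptor_gene_error(self):
        adata = toy_adata([[1, 2]], ["Drd1", "FoxP2"], mito=())
        log_normalize(adata)
        with pytest.raises(KeyError):
            receptor_classes(adata)


class TestCoexpression:
    def test_single_class_all_foxp2(self):
        genes = ["Drd1", "Drd5", "Drd2", "FoxP2", "Other"]
        adata = toy_adata([[2, 0, 0, 1, 5]] * 10, genes, mito=())
        log_normalize(adata)
        adata.obs["cluster"] = 1
        summ = coexpression_summary(adata, [1])
        assert summ.loc["D1/5-only", "pct_of_msns"] == 100.0
        assert summ.loc["D1/5-only", "pct_foxp2_positive"] == 100.0

    def test_percentages_partition(self, clustered_sim):
        adata, truth, types, _ = clustered_sim
        msn = sorted(c for c, t in types.items() if t == "MSN")
        summ = coexpression_summary(adata, msn)
        assert summ["pct_of_msns"].sum() == pytest.approx(100.0)

    def test_no_msns_error(self, clustered_sim):
        adata, *_ = clustered_sim
        with pytest.raises(ValueError):
            coexpression_summary(adata, [999])


class TestPathwayDE:
    def test_identical_groups_nothing_passes(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(5, size=(60, 20)) + 1
        adata = toy_adata(counts, [f"G{i}" for i in range(20)], mito=())
        log_normalize(adata)
        adata.obs["cluster"] = [1] * 30 + [2] * 30
        de = pathway_de(adata, PathwayGrouping(frozenset({1}), frozenset({2})))
        assert (de["direction"] != "ns").sum() == 0

    def test_constructed_marker_detected(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(5, size=(80, 10)) + 1
        counts[:40, 0] += 30  # gene G0 expressed high only in group A
        adata = toy_adata(counts, [f"G{i}" for i in range(10)], mito=())
        log_normalize(adata)
        adata.obs["cluster"] = [1] * 40 + [2] * 40
        de = pathway_de(adata, PathwayGrouping(frozenset({1}), frozenset({2})))
        top = de.iloc[0]
        assert top["gene"] == "G0" and top["direction"] == "direct-like"

    def test_pvalues_match_reference_ranksum(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(9)
        counts = rng.poisson(4, size=(30, 10)) + 1
        counts[:15, :5] += rng.poisson(6, size=(15, 5))
        adata = toy_adata(counts, [f"G{i}" for i in range(10)], mito=())
        log_normalize(adata)
        adata.obs["cluster"] = [1] * 15 + [2] * 15
        de = pathway_de(
            adata,
            PathwayGrouping(frozenset({1}), frozenset({2})),
            logfc_threshold=0.0,
            min_pct=0.0,
        )
        X = adata.X.toarray()
        for _, row in de.iterrows():
            j = list(adata.var_names).index(row["gene"])
            ref = mannwhitneyu(X[:15, j], X[15:, j], alternative="two-sided").pvalue
            assert row["p_value"] == pytest.approx(ref, rel=1e-9)

    def test_empty_group_error(self, clustered_sim):
        adata, *_ = clustered_sim
        with pytest.raises(ValueError):
            pathway_de(adata, PathwayGrouping(frozenset({998}), frozenset({999})))

    def test_bonferroni_cap(self):
        rng = np.random.default_rng(10)
        counts = rng.poisson(5, size=(20, 30)) + 1
        adata = toy_adata(counts, [f"G{i}" for i in range(30)], mito=())
        log_normalize(adata)
        adata.obs["cluster"] = [1] * 10 + [2] * 10
        de = pathway_de(
            adata,
            PathwayGrouping(frozenset({1}), frozenset({2})),
            logfc_threshold=0.0,
            min_pct=0.0,
        )
        assert (de["p_adjusted"] <= 1.0).all()
        n = len(de)
        expected = np.minimum(1.0, de["p_value"] * n)
        assert np.allclose(de["p_adjusted"], expected)


class TestWelchShift:
    def make_condition(self, mean, n, seed):
        rng = np.random.default_rng(seed)
        drd1 = rng.poisson(mean, size=n)
        drd1 = np.maximum(drd1, 1)
        counts = np.column_stack(
            [
                drd1,
                np.zeros(n, dtype=int),
                np.zeros(n, dtype=int),
                np.ones(n, dtype=int),
                rng.poisson(50, size=n) + 50,
            ]
        )
        adata = toy_adata(counts, ["Drd1", "Drd5", "Drd2", "FoxP2", "Other"], mito=())
        log_normalize(adata)
        return adata

    def test_identical_conditions_t_near_zero(self):
        a = self.make_condition(5, 400, seed=1)
        res = receptor_shift_test(a, a, gene="Drd1")
        assert res.loc["D1+", "t"] == pytest.approx(0.0, abs=1e-9)

    def test_reduction_detected_with_power(self):
        hits = 0
        for s in range(20):
            a = self.make_condition(6, 500, seed=100 + s)
            b = self.make_condition(4.2, 500, seed=200 + s)  # 30% lower
            res = receptor_shift_test(a, b, gene="Drd1")
            hits += res.loc["D1+", "p_value"] < 0.001 and res.loc["D1+", "t"] > 0
        assert hits / 20 > 0.95

    def test_matches_closed_form_welch(self):
        # two tiny printed samples, Welch statistic recomputed by hand
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0])
        se = math.sqrt(a.var(ddof=1) / 4 + b.var(ddof=1) / 3)
        t_hand = (a.mean() - b.mean()) / se
        from scipy.stats import ttest_ind

        t_lib = ttest_ind(a, b, equal_var=False).statistic
        assert t_lib == pytest.approx(t_hand, rel=1e-12)

    def test_too_few_cells_error(self):
        a = self.make_condition(5, 1, seed=3)
        b = self.make_condition(5, 50, seed=4)
        with pytest.raises(ValueError):
            receptor_shift_test(a, b, gene="Drd1")


class TestDendrogram:
    def test_duplicated_profiles_distance_zero(self):
        rng = np.random.default_rng(11)
        block = rng.poisson(5, size=(20, 30)) + 1
        counts = np.vstack([block, block, rng.poisson(30, size=(20, 30)) + 1])
        adata = toy_adata(counts, [f"G{i}" for i in range(30)], mito=())
        log_normalize(adata)
        adata.obs["cluster"] = [1] * 20 + [2] * 20 + [3] * 20
        dend = bootstrap_dendrogram(adata, n_boot=20, seed=0)
        # clusters 1 and 2 duplicate the same program: they join first at ~0
        first_join = dend.linkage[0]
        assert set(first_join[:2].astype(int)) == {0, 1}
        assert first_join[2] < 0.05

    def test_linkage_order_matches_hand_computation(self):
        # three profiles with known correlations: (p1,p2) most similar
        p1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        p2 = np.array([1.1, 2.1, 2.9, 4.2, 5.0])
        p3 = np.array([5.0, 1.0, 4.0, 2.0, 3.0])
        from songkit.snrna import _correlation_linkage

        Z = _correlation_linkage(np.vstack([p1, p2, p3]))
        assert set(Z[0, :2].astype(int)) == {0, 1}
        d12 = 1 - np.corrcoef(p1, p2)[0, 1]
        assert Z[0, 2] == pytest.approx(d12, abs=1e-12)
        # average linkage: distance of cluster {1,2} to 3
        d13 = 1 - np.corrcoef(p1, p3)[0, 1]
        d23 = 1 - np.corrcoef(p2, p3)[0, 1]
        assert Z[1, 2] == pytest.approx((d13 + d23) / 2, abs=1e-12)

    def test_supports_are_proportions(self, clustered_sim):
        adata, *_ = clustered_sim
        dend = bootstrap_dendrogram(adata, n_boot=25, seed=1)
        assert all(0.0 <= s <= 1.0 for s in dend.supports.values())
        assert dend.newick().endswith(";")

    def test_single_cluster_error(self):
        adata = toy_adata([[5, 3], [4, 2]], ["G1", "G2"], mito=())
        log_normalize(adata)
        adata.obs["cluster"] = [1, 1]
        with pytest.raises(ValueError):
            bootstrap_dendrogram(adata)
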