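"""QC filter rules, boundary conventions and annotation summaries."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from neuroquant.sc_qc import (
    CountMatrix,
    QCThresholds,
    apply_qc,
    cluster_phase_summary,
    composition_ratio,
    compute_cell_metrics,
)
from neuroquant.synthetic import MatrixSimParams, simulate_count_matrix


def brute_force_filter(dense, gene_ids, thresholds=QCThresholds()):
    """Independent filter written directly from the rules: genes in >= 3
    cells and cells with >= 300 genes on the raw matrix, then cells with
    < 15,000 UMIs and < 10% mitochondrial counts (raw metrics)."""
    mito = np.array([g.upper().startswith("MT-") for g in gene_ids])
    gene_keep, cell_keep = [], []
    for i in range(dense.shape[0]):
        gene_keep.append(sum(dense[i, j] > 0 for j in range(dense.shape[1]))
                         >= thresholds.min_cells_per_gene)
    for j in range(dense.shape[1]):
        col = dense[:, j]
        n_feat = sum(v > 0 for v in col)
        n_umi = sum(col)
        pct = 100.0 * sum(col[mito]) / n_umi if n_umi > 0 else 0.0
        cell_keep.append(
            n_feat >= thresholds.min_features_per_cell
            and n_umi < thresholds.max_umi_per_cell
            and pct < thresholds.max_mito_percent
        )
    return np.array(gene_keep), np.array(cell_keep)


def tiny_matrix(dense, mito_first=True):
    G = dense.shape[0]
    genes = [("MT-G0" if (i == 0 and mito_first) else f"G{i}") for i in range(G)]
    cells = [f"c{j}" for j in range(dense.shape[1])]
    return CountMatrix(sp.csr_matrix(dense), genes, cells)


class TestCellMetrics:
    def test_arithmetic_on_a_known_cell(self):
        # one cell: geneA=5, MT-CO1=5 -> 2 features, 10 UMIs, 50% mito
        cm = CountMatrix(
            sp.csr_matrix(np.array([[5], [5]])), ["geneA", "MT-CO1"], ["c0"]
        )
        m = compute_cell_metrics(cm).iloc[0]
        assert m["n_features"] == 2 and m["n_umi"] == 10
        assert m["percent_mito"] == pytest.approx(50.0)

    def test_all_zero_cell_uses_zero_conventions(self):
        cm = tiny_matrix(np.array([[1, 0], [2, 0]]))
        m = compute_cell_metrics(cm)
        assert m.loc[1, "n_features"] == 0
        assert m.loc[1, "n_umi"] == 0
        assert m.loc[1, "percent_mito"] == 0.0

    def test_matches_dense_brute_force(self):
        rng = np.random.default_rng(8)
        dense = rng.integers(0, 5, size=(40, 15)) * (rng.random((40, 15)) < 0.3)
        cm = tiny_matrix(dense)
        m = compute_cell_metrics(cm)
        mito = np.array([g.upper().startswith("MT-") for g in cm.gene_ids])
        for j in range(15):
            col = dense[:, j]
            assert m.loc[j, "n_features"] == (col > 0).sum()
            assert m.loc[j, "n_umi"] == col.sum()
            expected = 100.0 * col[mito].sum() / col.sum() if col.sum() else 0.0
            assert m.loc[j, "percent_mito"] == pytest.approx(expected)


class TestApplyQC:
    def boundary_matrix(self):
        """Cells sitting exactly on each threshold, 320 genes x 5 cells."""
        G = 320
        dense = np.zeros((G, 5), dtype=np.int64)
        dense[:300, 0] = 1                      # exactly 300 features -> kept
        dense[:299, 1] = 1                      # 299 features -> removed
        dense[:300, 2] = 50                     # 15,000 UMIs exactly -> removed
        dense[0, 3] = 40                        # MT gene: 40 of 400 = 10% -> removed
        dense[1:301, 3] = 1                     # 301 features, 360 non-mito UMIs
        dense[1:61, 3] = 2
        dense[:310, 4] = 2                      # clean cell
        return dense

    def test_boundary_conventions(self):
        dense = self.boundary_matrix()
        cm = tiny_matrix(dense)
        filtered, report = apply_qc(cm)
        kept = set(filtered.barcodes)
        assert "c0" in kept     # at least 300 features
        assert "c1" not in kept
        assert "c2" not in kept  # fewer than 15,000 means 15,000 fails
        assert "c3" not in kept  # less than 10% means 10% fails
        assert "c4" in kept
        assert report.cells_removed_min_features == 1
        assert report.cells_removed_max_umi == 1
        assert report.cells_removed_max_mito == 1

    def test_gene_in_exactly_two_cells_removed(self):
        rng = np.random.default_rng(0)
        dense = np.zeros((310, 6), dtype=np.int64)
        dense[:305, :] = 1  # every gene in 6 cells, every cell 305 features
        dense[305, :2] = 4  # detected in exactly 2 cells
        dense[306, :3] = 4  # detected in exactly 3 cells
        filtered, report = apply_qc(tiny_matrix(dense))
        assert "G305" not in filtered.gene_ids
        assert "G306" in filtered.gene_ids

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for trial in range(25):
            G, C = 40, 12
            dense = (rng.integers(1, 6, size=(G, C))
                     * (rng.random((G, C)) < rng.uniform(0.2, 0.9))).astype(np.int64)
            th = QCThresholds(min_cells_per_gene=3, min_features_per_cell=10,
                              max_umi_per_cell=60, max_mito_percent=10.0)
            cm = tiny_matrix(dense)
            filtered, report = apply_qc(cm, th)
            gk, ck = brute_force_filter(dense, cm.gene_ids, th)
            assert filtered.gene_ids == [g for g, k in zip(cm.gene_ids, gk) if k]
            assert filtered.barcodes == [b for b, k in zip(cm.barcodes, ck) if k]
            assert report.n_cells_after == ck.sum()

    def test_planted_violations_filtered_exactly(self):
        p = MatrixSimParams(
            n_cells=100, planted_low_feature_cells=2, planted_high_mito_cells=1,
            planted_rare_genes=3, seed=2,
        )
        m, genes, barcodes, truth = simulate_count_matrix(p)
        filtered, report = apply_qc(CountMatrix(m, genes, barcodes))
        assert filtered.n_cells == 97
        assert set(filtered.barcodes) == {
            b for b, ok in zip(barcodes, truth["cell_passes"]) if ok
        }
        assert report.genes_removed_min_cells == 3

    def test_permutation_invariance_of_survivors(self):
        rng = np.random.default_rng(9)
        dense = (rng.integers(1, 5, size=(30, 10))
                 * (rng.random((30, 10)) < 0.5)).astype(np.int64)
        th = QCThresholds(min_cells_per_gene=2, min_features_per_cell=5,
                          max_umi_per_cell=40, max_mito_percent=50.0)
        cm = tiny_matrix(dense)
        f1, _ = apply_qc(cm, th)
        gp, cp = rng.permutation(30), rng.permutation(10)
        cm2 = CountMatrix(
            sp.csr_matrix(dense[np.ix_(gp, cp)]),
            [cm.gene_ids[i] for i in gp], [cm.barcodes[j] for j in cp],
        )
        f2, _ = apply_qc(cm2, th)
        assert set(f1.gene_ids) == set(f2.gene_ids)
        assert set(f1.barcodes) == set(f2.barcodes)

    def test_empty_result_warns_not_raises(self):
        dense = np.ones((5, 3), dtype=np.int64)
        with pytest.warns(UserWarning, match="removed every"):
            filtered, _ = apply_qc(tiny_matrix(dense))  # nobody has 300 features
        assert filtered.n_cells == 0


class TestAnnotationSummaries:
    def test_phase_fractions_and_dominance(self):
        ann = pd.DataFrame(
            {"cluster": [0] * 10, "phase": ["G1"] * 9 + ["S"]}
        )
        out = cluster_phase_summary(ann)
        assert out.loc[0, "frac_G1"] == pytest.approx(0.9)
        assert bool(out.loc[0, "g1_dominant"])

    def test_exactly_80_percent_is_not_dominant(self):
        ann = pd.DataFrame({"cluster": [1] * 10, "phase": ["G1"] * 8 + ["S", "G2M"]})
        out = cluster_phase_summary(ann)
        assert out.loc[0, "frac_G1"] == pytest.approx(0.8)
        assert not bool(out.loc[0, "g1_dominant"])

    def test_fractions_match_brute_tally_and_sum_to_one(self):
        rng = np.random.default_rng(3)
        ann = pd.DataFrame(
            {
                "cluster": rng.integers(0, 5, 200),
                "phase": rng.choice(["G1", "S", "G2M"], 200),
            }
        )
        out = cluster_phase_summary(ann).set_index("cluster")
        for cl, sub in ann.groupby("cluster"):
            for ph in ("G1", "S", "G2M"):
                assert out.loc[cl, f"frac_{ph}"] == pytest.approx(
                    (sub["phase"] == ph).mean()
                )
        assert np.allclose(
            out[["frac_G1", "frac_S", "frac_G2M"]].sum(axis=1), 1.0
        )

    def test_unknown_phase_label_rejected(self):
        ann = pd.DataFrame({"cluster": [0], "phase": ["G0"]})
        with pytest.raises(ValueError, match="unknown"):
            cluster_phase_summary(ann)

    def test_balanced_composition_is_unity(self):
        ann = pd.DataFrame({"lineage": ["glial"] * 50 + ["neuronal"] * 50})
        assert composition_ratio(ann, "glial", "neuronal") == pytest.approx(1.0)

    def test_55_to_50_gives_one_point_one(self):
        ann = pd.DataFrame({"lineage": ["neuronal"] * 55 + ["glial"] * 50})
        assert composition_ratio(ann, "neuronal", "glial") == pytest.approx(1.1)

    def test_unmapped_cluster_counts_as_other_with_warning(self):
        ann = pd.DataFrame({"cluster": [0, 0, 1, 2]})
        with pytest.warns(UserWarning, match="absent from lineage"):
            ratio = composition_ratio(
                ann, "glial", "neuronal",
                cluster_lineage_map={0: "glial", 1: "neuronal"},
            )
        assert ratio == pytest.approx(2.0)

    def test_empty_denominator_is_undefined(self):
        ann = pd.DataFrame({"lineage": ["glial"] * 3})
        with pytest.raises(ZeroDivisionError):
            composition_ratio(ann, "glial", "neuronal")
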