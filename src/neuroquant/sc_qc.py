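"""Single-cell QC filtering and cluster-level summaries.

Filters a genes x cells UMI count matrix with the four-rule scheme used
when loading droplet scRNA-seq data from long-term neural cultures:

* stage 1, evaluated jointly on the raw matrix: keep genes detected in
  at least 3 cells and cells with at least 300 detected genes;
* stage 2, on the surviving cells, with metrics computed on the raw
  matrix: keep cells with fewer than 15,000 total UMIs and less than
  10% mitochondrial counts.

Both stages are a single pass — gene removal is not allowed to re-drop
cells below the feature threshold, mirroring the creation-time semantics
of the ``min.cells`` / ``min.features`` loading parameters followed by a
one-shot cell selection.  Boundary conventions are explicit: exactly 300
features is kept ("at least 300"), exactly 15,000 UMIs and exactly 10%
mitochondrial are removed (strict "fewer than" / "less than").

Downstream summaries operate on externally produced per-cell annotations
(cluster id, cell-cycle phase, lineage class): per-cluster phase
occupancy with a strict >80% G1-dominance flag, and lineage composition
ratios such as glia : neurons.
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "QCThresholds",
    "QCReport",
    "compute_cell_metrics",
    "apply_qc",
    "cluster_phase_summary",
    "composition_ratio",
    "read_10x_dir",
]

MITO_PREFIX = re.compile(r"^MT-", re.IGNORECASE)
PHASES = ("G1", "S", "G2M")


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI matrix with identifiers.

    ``mito_genes`` may be given explicitly; otherwise genes whose name
    matches the ``MT-`` prefix (case-insensitive) are treated as
    mitochondrial.
    """

    matrix: sp.spmatrix
    gene_ids: list[str]
    barcodes: list[str]
    mito_genes: list[str] | None = None

    def __post_init__(self):
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} cells"
            )
        if self.matrix.nnz and (
            self.matrix.data.min() < 0
            or np.any(self.matrix.data != np.rint(self.matrix.data))
        ):
            raise ValueError("counts must be non-negative integers")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def mito_mask(self) -> np.ndarray:
        if self.mito_genes is not None:
            mset = set(self.mito_genes)
            return np.array([g in mset for g in self.gene_ids])
        return np.array([bool(MITO_PREFIX.match(g)) for g in self.gene_ids])


@dataclass(frozen=True)
class QCThresholds:
    """The four filter parameters.

    ``min_cells_per_gene`` and ``min_features_per_cell`` are inclusive
    minima; ``max_umi_per_cell`` and ``max_mito_percent`` are exclusive
    maxima.
    """

    min_cells_per_gene: int = 3
    min_features_per_cell: int = 300
    max_umi_per_cell: int = 15_000
    max_mito_percent: float = 10.0

    def __post_init__(self):
        if min(
            self.min_cells_per_gene, self.min_features_per_cell,
            self.max_umi_per_cell, self.max_mito_percent,
        ) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass(frozen=True)
class QCReport:
    n_genes_before: int
    n_genes_after: int
    n_cells_before: int
    n_cells_after: int
    genes_removed_min_cells: int
    cells_removed_min_features: int
    cells_removed_max_umi: int
    cells_removed_max_mito: int

    def __post_init__(self):
        removed = (
            self.cells_removed_min_features
            + self.cells_removed_max_umi
            + self.cells_removed_max_mito
        )
        assert self.n_cells_before - removed == self.n_cells_after
        assert self.n_genes_before - self.genes_removed_min_cells == self.n_genes_after

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compute_cell_metrics(cm: CountMatrix) -> pd.DataFrame:
    """Per-cell QC metrics on the raw matrix.

    ``n_features`` counts genes with count > 0, ``n_umi`` is the column
    sum and ``percent_mito`` is 100 x mito counts / total counts with the
    0/0 case defined as 0 (an empty cell fails the feature rule anyway).
    """
    csc = sp.csc_matrix(cm.matrix, copy=True)
    csc.eliminate_zeros()  # stored explicit zeros are not detections
    n_features = np.diff(csc.indptr)
    n_umi = np.asarray(csc.sum(axis=0)).ravel()
    mito = np.asarray(csc[cm.mito_mask(), :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_umi > 0, 100.0 * mito / np.where(n_umi > 0, n_umi, 1), 0.0)
    return pd.DataFrame(
        {
            "barcode": cm.barcodes,
            "n_features": n_features.astype(int),
            "n_umi": n_umi.astype(int),
            "percent_mito": pct,
        }
    )


def apply_qc(
    cm: CountMatrix, thresholds: QCThresholds = QCThresholds()
) -> tuple[CountMatrix, QCReport]:
    """Apply the two-stage QC filter; returns the filtered matrix and a
    report whose per-rule removal counts attribute each removed cell to
    the first rule (features, then UMI, then mito) that rejects it."""
    metrics = compute_cell_metrics(cm)
    gene_detected_in = np.asarray((cm.matrix > 0).sum(axis=1)).ravel()

    gene_keep = gene_detected_in >= thresholds.min_cells_per_gene
    feat_ok = metrics["n_features"].to_numpy() >= thresholds.min_features_per_cell
    umi_ok = metrics["n_umi"].to_numpy() < thresholds.max_umi_per_cell
    mito_ok = metrics["percent_mito"].to_numpy() < thresholds.max_mito_percent
    cell_keep = feat_ok & umi_ok & mito_ok

    removed_feat = int((~feat_ok).sum())
    removed_umi = int((feat_ok & ~umi_ok).sum())
    removed_mito = int((feat_ok & umi_ok & ~mito_ok).sum())

    filtered = CountMatrix(
        matrix=cm.matrix[gene_keep][:, cell_keep],
        gene_ids=[g for g, k in zip(cm.gene_ids, gene_keep) if k],
        barcodes=[b for b, k in zip(cm.barcodes, cell_keep) if k],
        mito_genes=cm.mito_genes,
    )
    report = QCReport(
        n_genes_before=cm.n_genes,
        n_genes_after=filtered.n_genes,
        n_cells_before=cm.n_cells,
        n_cells_after=filtered.n_cells,
        genes_removed_min_cells=int((~gene_keep).sum()),
        cells_removed_min_features=removed_feat,
        cells_removed_max_umi=removed_umi,
        cells_removed_max_mito=removed_mito,
    )
    if filtered.n_cells == 0 or filtered.n_genes == 0:
        warnings.warn("QC filtering removed every cell or gene", stacklevel=2)
    return filtered, report


# ---------------------------------------------------------------------------
# Annotation summaries

def cluster_phase_summary(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster cell-cycle phase occupancy with G1-dominance flags.

    ``annotations`` needs columns (cluster, phase) with phases from
    {G1, S, G2M}.  A cluster is flagged ``g1_dominant`` when strictly
    more than 80% of its cells are in G1; exactly 80% is not dominant.
    G1-dominant clusters are read as terminally differentiating
    populations, the remainder as cycling stem/progenitor pools.
    """
    for col in ("cluster", "phase"):
        if col not in annotations.columns:
            raise ValueError(f"annotation table missing column {col!r}")
    unknown = set(annotations["phase"]) - set(PHASES)
    if unknown:
        raise ValueError(f"unknown cell-cycle phase label(s): {sorted(unknown)}")

    rows = []
    for cluster, sub in annotations.groupby("cluster", sort=True):
        n = len(sub)
        fracs = {ph: float((sub["phase"] == ph).sum()) / n for ph in PHASES}
        rows.append(
            {
                "cluster": cluster,
                "n_cells": n,
                **{f"frac_{ph}": fracs[ph] for ph in PHASES},
                "g1_dominant": fracs["G1"] > 0.80,
            }
        )
    return pd.DataFrame(rows)


def composition_ratio(
    annotations: pd.DataFrame,
    numerator: str,
    denominator: str,
    cluster_lineage_map: dict | None = None,
) -> float:
    """Cell-count ratio of two lineage classes (e.g. glial : neuronal).

    Lineage comes from a ``lineage`` column or, if a cluster->lineage map
    is supplied, from mapping each cell's cluster; clusters absent from
    the map count as "other" (with a warning) and are excluded from both
    sides of the ratio.
    """
    ann = annotations.copy()
    if cluster_lineage_map is not None:
        if "cluster" not in ann.columns:
            raise ValueError("cluster_lineage_map given but no 'cluster' column")
        unmapped = set(ann["cluster"]) - set(cluster_lineage_map)
        if unmapped:
            warnings.warn(
                f"cluster(s) {sorted(map(str, unmapped))} absent from lineage "
                "map; their cells are counted as 'other'",
                stacklevel=2,
            )
        ann["lineage"] = ann["cluster"].map(cluster_lineage_map).fillna("other")
    elif "lineage" not in ann.columns:
        raise ValueError("need a 'lineage' column or a cluster_lineage_map")

    n_num = int((ann["lineage"] == numerator).sum())
    n_den = int((ann["lineage"] == denominator).sum())
    if n_den == 0:
        raise ZeroDivisionError(
            f"no cells in denominator class {denominator!r}; ratio undefined"
        )
    return n_num / n_den


# ---------------------------------------------------------------------------
# I/O

def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.strip().split("\t")[0] for line in fh if line.strip()]


def _find(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {dir_path}")


def read_10x_dir(dir_path: str | Path, mito_genes: list[str] | None = None) -> CountMatrix:
    """Read a 10x-style MatrixMarket triplet directory.

    Accepts ``features.tsv`` or ``genes.tsv`` (plain or gzip).  The
    matrix orientation is auto-detected from the id-file lengths and
    transposed to genes x cells if needed.
    """
    dir_path = Path(dir_path)
    mat = sp.csr_matrix(scipy.io.mmread(str(_find(dir_path, "matrix.mtx"))))
    try:
        genes = _read_lines(_find(dir_path, "features.tsv"))
    except FileNotFoundError:
        genes = _read_lines(_find(dir_path, "genes.tsv"))
    barcodes = _read_lines(_find(dir_path, "barcodes.tsv"))

    if mat.shape == (len(genes), len(barcodes)):
        pass
    elif mat.shape == (len(barcodes), len(genes)):
        mat = sp.csr_matrix(mat.T)
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither orientation of "
            f"{len(genes)} genes x {len(barcodes)} barcodes"
        )
    return CountMatrix(matrix=mat, gene_ids=genes, barcodes=barcodes, mito_genes=mito_genes)
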