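"""Synthetic data generators with recorded ground truth.

Every input class the pipeline consumes can be generated here at desk
scale: two-channel fluorescence fields, qPCR Ct tables, sparse UMI count
matrices, and serial-passage cell counts.  Each generator is a pure
function of its parameter object plus a seed, and attaches the labels
needed to compute the expected downstream answer by brute force.

Image model
-----------
Nuclei are isotropic Gaussian blobs at centres rejection-sampled to be at
least ``2 * nucleus_sigma`` apart (approximately non-overlapping nuclei).
A fixed fraction of cells is marker-positive; positive cells re-use their
nucleus centre with a larger footprint, approximating cytoplasmic
staining.  The camera model is: optional Poisson shot noise on the
noiseless signal, additive Gaussian read noise, then clip and quantise to
the requested bit depth.  A secondary-only negative control is the same
field with the marker amplitude forced to zero (background + noise only).

Ct model
--------
One PCR cycle corresponds to one doubling of template (perfect
efficiency), so a planted log2 fold change of ``L`` in a group lowers
that group's Ct by ``L`` cycles.  Per-sample global shifts emulate
loading/pipetting effects; per-gene per-sample jitter plants
reference-gene instability for the stability ranking to detect.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import tifffile

from ._rng import child_rng
from .image_quant import FluorescenceImage, ImagePair

__all__ = [
    "ImageSimParams",
    "CtSimParams",
    "MatrixSimParams",
    "GrowthSimParams",
    "simulate_image_pair",
    "simulate_ct_table",
    "simulate_count_matrix",
    "simulate_growth_series",
    "write_image_dataset",
    "write_count_matrix",
]


# ---------------------------------------------------------------------------
# Fluorescence image fields

@dataclass(frozen=True)
class ImageSimParams:
    """Parameters of one simulated stained field.

    Defaults describe a moderately dense 16-bit field: 40 nuclei of
    ~4 px sigma on a 256x256 grid, dim uniform background and mild read
    noise.  ``positive_fraction`` of the cells carry marker signal of
    ``marker_amplitude`` peak intensity.
    """

    width: int = 256
    height: int = 256
    bit_depth: int = 16
    n_cells: int = 40
    nucleus_sigma: float = 4.0
    nucleus_amplitude: float = 8000.0
    positive_fraction: float = 0.3
    marker_amplitude: float = 6000.0
    background_level: float = 200.0
    read_noise_sd: float = 30.0
    shot_noise: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if min(self.nucleus_amplitude, self.marker_amplitude,
               self.background_level, self.read_noise_sd) < 0:
            raise ValueError("amplitudes, background and noise must be >= 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


def _sample_centres(rng, n, width, height, min_dist):
    """Rejection-sample blob centres at pairwise distance >= min_dist."""
    centres: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = max(2000, 200 * n)
    while len(centres) < n and attempts < max_attempts:
        attempts += 1
        x = rng.uniform(0, width)
        y = rng.uniform(0, height)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_dist**2 for cx, cy in centres):
            centres.append((x, y))
    if len(centres) < n:
        raise ValueError(
            f"could not place {n} non-overlapping nuclei on a "
            f"{width}x{height} field (placed {len(centres)})"
        )
    return np.array(centres, dtype=float).reshape(-1, 2)


def _render_blobs(shape, centres, sigma, amplitude):
    """Sum of isotropic Gaussian blobs, evaluated on a local window only."""
    img = np.zeros(shape, dtype=float)
    if amplitude == 0 or len(centres) == 0:
        return img
    h, w = shape
    r = int(math.ceil(4 * sigma))
    for cx, cy in centres:
        x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
        y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)[:, None]
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma**2)
        )
    return img


def simulate_image_pair(params: ImageSimParams, control: bool = False) -> ImagePair:
    """Render one marker/DAPI field; ``control=True`` gives the matched
    secondary-only negative control (marker amplitude forced to zero).

    Ground-truth cell centres and positivity labels travel in
    ``pair.truth``.  Deterministic given ``params.seed``; the control
    shares the stained field's geometry but has independent noise.
    """
    max_val = 2**params.bit_depth - 1
    if params.nucleus_amplitude + params.background_level > max_val or (
        params.marker_amplitude + params.background_level > max_val
    ):
        saturation_expected = True
    else:
        saturation_expected = False

    geom_rng = child_rng(params.seed, 0)
    noise_rng = child_rng(params.seed, 2 if control else 1)

    shape = (params.height, params.width)
    centres = _sample_centres(
        geom_rng, params.n_cells, params.width, params.height,
        2 * params.nucleus_sigma,
    )
    n_positive = round(params.positive_fraction * params.n_cells)
    positive = np.zeros(params.n_cells, dtype=bool)
    if n_positive:
        positive[geom_rng.choice(params.n_cells, size=n_positive, replace=False)] = True

    nuclei_signal = _render_blobs(
        shape, centres, params.nucleus_sigma, params.nucleus_amplitude
    )
    marker_amp = 0.0 if control else params.marker_amplitude
    marker_signal = _render_blobs(
        shape, centres[positive], 1.8 * params.nucleus_sigma, marker_amp
    )

    def camera(signal):
        out = signal + params.background_level
        if params.shot_noise:
            out = noise_rng.poisson(np.clip(out, 0, None)).astype(float)
        if params.read_noise_sd > 0:
            out = out + noise_rng.normal(0.0, params.read_noise_sd, size=shape)
        return np.clip(np.rint(out), 0, max_val).astype(
            np.uint8 if params.bit_depth == 8 else np.uint16
        )

    marker_px = camera(marker_signal)
    nuclei_px = camera(nuclei_signal)

    return ImagePair(
        marker=FluorescenceImage(marker_px, params.bit_depth, "marker"),
        nuclei=FluorescenceImage(nuclei_px, params.bit_depth, "nuclei"),
        is_negative_control=control,
        truth={
            "centres": centres,
            "positive": positive,
            "n_positive": int(positive.sum()),
            "saturation_expected": saturation_expected,
        },
    )


# ---------------------------------------------------------------------------
# qPCR Ct tables

@dataclass(frozen=True)
class CtSimParams:
    """Parameters of a simulated long-format Ct table.

    ``true_log2fc[gene][group]`` is the planted log2 fold change of a
    target gene in a group relative to the first (calibrator) group; one
    extra cycle equals half the expression, so a planted +L lowers Ct by
    L cycles.  ``gene_instability_sd[gene]`` adds per-sample jitter to a
    gene on top of measurement noise, making it a poor normaliser.
    ``sample_shift_sd`` draws one global Ct offset per biological sample
    applied to every gene (loading effect); the ddCt pipeline must be
    invariant to it.
    """

    genes: tuple[str, ...] = ("NES", "PAX6", "GFAP", "TUBB3")
    reference_genes: tuple[str, ...] = ("EMC7", "PSMB4")
    groups: tuple[str, ...] = ("p5", "p25")
    true_log2fc: dict = dc_field(default_factory=dict)
    base_ct: float = 24.0
    ct_noise_sd: float = 0.2
    sample_shift_sd: float = 0.0
    gene_instability_sd: dict = dc_field(default_factory=dict)
    n_bio_reps: int = 5
    n_tech_reps: int = 3
    seed: int = 0

    def __post_init__(self):
        if len(self.reference_genes) < 1:
            raise ValueError("need at least one reference gene")
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        if self.n_bio_reps < 1 or self.n_tech_reps < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.ct_noise_sd < 0 or self.sample_shift_sd < 0:
            raise ValueError("noise parameters must be >= 0")


def simulate_ct_table(params: CtSimParams) -> pd.DataFrame:
    """Simulate a long-format Ct table with planted effects.

    Returns columns (gene, sample, group, bio_rep, tech_rep, ct) plus a
    ``true_log2fc`` attribute-style ground-truth table in
    ``df.attrs["truth"]`` and the reference set in
    ``df.attrs["reference_genes"]``.
    """
    rng = child_rng(params.seed, 0)
    all_genes = tuple(params.genes) + tuple(
        g for g in params.reference_genes if g not in params.genes
    )
    rows = []
    for group in params.groups:
        for bio in range(1, params.n_bio_reps + 1):
            sample = f"{group}_b{bio}"
            shift = rng.normal(0.0, params.sample_shift_sd) if params.sample_shift_sd else 0.0
            for gene in all_genes:
                l2fc = float(params.true_log2fc.get(gene, {}).get(group, 0.0))
                instab = params.gene_instability_sd.get(gene, 0.0)
                gene_jitter = rng.normal(0.0, instab) if instab else 0.0
                true_ct = params.base_ct - l2fc + shift + gene_jitter
                for tech in range(1, params.n_tech_reps + 1):
                    noise = rng.normal(0.0, params.ct_noise_sd) if params.ct_noise_sd else 0.0
                    rows.append(
                        (gene, sample, group, bio, tech, true_ct + noise)
                    )
    df = pd.DataFrame(
        rows, columns=["gene", "sample", "group", "bio_rep", "tech_rep", "ct"]
    )
    if df["ct"].min() < 5 or df["ct"].max() > 40:
        raise ValueError("generated Ct values left the plausible 5-40 cycle range")
    df.attrs["reference_genes"] = list(params.reference_genes)
    df.attrs["truth"] = {
        gene: dict(per_group) for gene, per_group in params.true_log2fc.items()
    }
    return df


# ---------------------------------------------------------------------------
# Sparse UMI count matrices

@dataclass(frozen=True)
class MatrixSimParams:
    """Parameters of a simulated genes x cells UMI matrix.

    ``planted_*`` counts choose how many cells violate exactly one QC
    rule each (fewer than 300 detected genes; at least 15,000 UMIs; at
    least 10% mitochondrial counts) and how many genes are detected in
    fewer than 3 cells.  All remaining cells and genes are constructed to
    satisfy every rule, and the per-cell / per-gene pass labels are
    recorded as ground truth.
    """

    n_genes: int = 800
    n_cells: int = 100
    mito_gene_fraction: float = 0.02
    planted_low_feature_cells: int = 0
    planted_high_umi_cells: int = 0
    planted_high_mito_cells: int = 0
    planted_rare_genes: int = 0
    seed: int = 0

    def __post_init__(self):
        bad_cells = (
            self.planted_low_feature_cells
            + self.planted_high_umi_cells
            + self.planted_high_mito_cells
        )
        if bad_cells > self.n_cells:
            raise ValueError("planted bad cells exceed n_cells")
        if self.planted_rare_genes > self.n_genes:
            raise ValueError("planted rare genes exceed n_genes")
        if self.n_cells - bad_cells < 3:
            raise ValueError("need at least 3 rule-passing cells to anchor genes")
        n_mito = max(1, round(self.mito_gene_fraction * self.n_genes))
        usable = self.n_genes - self.planted_rare_genes
        if usable < 300 + n_mito:
            raise ValueError(
                "infeasible plant: passing cells need >= 300 detectable genes "
                f"but only {usable} non-rare genes are available"
            )


def simulate_count_matrix(params: MatrixSimParams):
    """Simulate a sparse UMI matrix with planted QC violations.

    Returns ``(matrix, gene_ids, barcodes, truth)`` where ``matrix`` is a
    CSR genes x cells integer matrix and ``truth`` holds boolean
    ``cell_passes`` / ``gene_passes`` arrays plus the planted index sets.
    """
    rng = child_rng(params.seed, 0)
    G, C = params.n_genes, params.n_cells
    n_mito = max(1, round(params.mito_gene_fraction * G))

    gene_ids = [f"MT-G{i}" if i < n_mito else f"GENE{i}" for i in range(G)]
    barcodes = [f"CELL{j:05d}" for j in range(C)]

    rare = np.arange(G - params.planted_rare_genes, G)
    common = np.setdiff1d(np.arange(G), rare)
    common_mito = common[common < n_mito]
    common_nonmito = common[common >= n_mito]

    cells = rng.permutation(C)
    k1 = params.planted_low_feature_cells
    k2 = params.planted_high_umi_cells
    k3 = params.planted_high_mito_cells
    low_feat = cells[:k1]
    high_umi = cells[k1 : k1 + k2]
    high_mito = cells[k1 + k2 : k1 + k2 + k3]
    normal = cells[k1 + k2 + k3 :]

    dense = np.zeros((G, C), dtype=np.int64)

    def fill_cell(j, n_feat, total_target, mito_frac):
        """Give cell j ~n_feat features and ~total_target UMIs with the
        requested mitochondrial share, drawn from common genes only."""
        n_mito_feat = max(1, round(mito_frac * n_feat)) if mito_frac > 0 else 0
        n_mito_feat = min(n_mito_feat, common_mito.size)
        n_plain = n_feat - n_mito_feat
        chosen_plain = rng.choice(common_nonmito, size=n_plain, replace=False)
        mito_total = int(round(total_target * mito_frac))
        plain_total = total_target - mito_total
        # multinomial split keeps every chosen gene detected (>=1 count)
        extra = rng.multinomial(max(plain_total - n_plain, 0), np.full(n_plain, 1 / n_plain))
        dense[chosen_plain, j] = 1 + extra
        if n_mito_feat:
            chosen_mito = rng.choice(common_mito, size=n_mito_feat, replace=False)
            extra_m = rng.multinomial(
                max(mito_total - n_mito_feat, 0), np.full(n_mito_feat, 1 / n_mito_feat)
            )
            dense[chosen_mito, j] = 1 + extra_m

    max_normal_feat = min(int(0.8 * common_nonmito.size), 900)
    for j in normal:
        n_feat = int(rng.integers(400, max(401, max_normal_feat)))
        total = int(rng.integers(1500, 6000))
        fill_cell(j, n_feat, total, mito_frac=0.03)
    for j in low_feat:
        n_feat = int(rng.integers(50, 300))  # < 300 detected genes
        total = int(rng.integers(200, 2000))
        fill_cell(j, n_feat, total, mito_frac=0.03)
    for j in high_umi:
        n_feat = int(rng.integers(400, max(401, max_normal_feat)))
        total = int(rng.integers(15_000, 25_000))  # >= 15,000 UMIs
        fill_cell(j, n_feat, total, mito_frac=0.03)
    for j in high_mito:
        n_feat = int(rng.integers(400, max(401, max_normal_feat)))
        total = int(rng.integers(1500, 6000))
        fill_cell(j, n_feat, total, mito_frac=0.25)  # >= 10% mitochondrial

    # Anchor every common gene in >= 3 rule-passing cells so only planted
    # rare genes violate the gene rule.
    detected = (dense[:, normal] > 0).sum(axis=1)
    for g in common:
        need = 3 - int(detected[g])
        if need > 0:
            anchor = rng.choice(normal, size=need, replace=False)
            dense[g, anchor] += 1
    # Plant each rare gene in exactly 0-2 cells.
    for g in rare:
        n_det = int(rng.integers(0, 3))
        if n_det:
            anchor = rng.choice(normal, size=n_det, replace=False)
            dense[g, anchor] += 1

    cell_passes = np.ones(C, dtype=bool)
    cell_passes[low_feat] = False
    cell_passes[high_umi] = False
    cell_passes[high_mito] = False
    gene_passes = np.ones(G, dtype=bool)
    gene_passes[rare] = False

    truth = {
        "cell_passes": cell_passes,
        "gene_passes": gene_passes,
        "low_feature_cells": np.sort(low_feat),
        "high_umi_cells": np.sort(high_umi),
        "high_mito_cells": np.sort(high_mito),
        "rare_genes": rare,
    }
    return sp.csr_matrix(dense), gene_ids, barcodes, truth


# ---------------------------------------------------------------------------
# Serial-passage growth

@dataclass(frozen=True)
class GrowthSimParams:
    """Exponential-growth passage series.

    Every passage seeds the same ``n_seeded`` cells (the culture protocol
    fixes 800,000 per dish) and harvests
    ``n_seeded * 2**(doublings_per_passage + noise)`` cells.
    """

    n_passages: int = 25
    n_seeded: int = 800_000
    doublings_per_passage: float = 2.0
    doubling_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_passages < 0 or self.n_seeded <= 0:
            raise ValueError("invalid growth parameters")


def simulate_growth_series(params: GrowthSimParams) -> pd.DataFrame:
    """Simulate per-passage seeded/harvested counts with known true rate."""
    rng = child_rng(params.seed, 0)
    rows = []
    for p in range(1, params.n_passages + 1):
        m = params.doublings_per_passage + (
            rng.normal(0.0, params.doubling_noise_sd)
            if params.doubling_noise_sd
            else 0.0
        )
        rows.append((p, params.n_seeded, int(round(params.n_seeded * 2**m))))
    df = pd.DataFrame(rows, columns=["passage", "n_seeded", "n_grown"])
    df.attrs["true_doublings_per_passage"] = params.doublings_per_passage
    return df


# ---------------------------------------------------------------------------
# On-disk dataset writers

def write_image_dataset(
    out_dir: str | Path,
    params: ImageSimParams,
    n_fields: int,
    line: str = "KYOU",
    passage: int = 5,
    marker: str = "GFAP",
    with_controls: bool = True,
) -> Path:
    """Write ``n_fields`` stained fields (and matched controls) as TIFF
    pairs plus a manifest CSV; returns the manifest path.

    Fields are assigned round-robin to two biological x two technical
    replicates, the replicate structure of the study design this package
    serves.  Field ``i`` uses child seed ``params.seed + i`` so any single
    field can be regenerated alone.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i in range(n_fields):
        bio = (i // 2) % 2 + 1
        tech = i % 2 + 1
        p_i = ImageSimParams(**{**params.__dict__, "seed": params.seed + i})
        variants = [("stained", False)] + ([("control", True)] if with_controls else [])
        for tag, is_ctrl in variants:
            pair = simulate_image_pair(p_i, control=is_ctrl)
            stem = f"{line}_p{passage}_{marker}_b{bio}_t{tech}_f{i}_{tag}"
            marker_path = f"{stem}_marker.tif"
            dapi_path = f"{stem}_dapi.tif"
            tifffile.imwrite(out_dir / marker_path, pair.marker.pixels)
            tifffile.imwrite(out_dir / dapi_path, pair.nuclei.pixels)
            records.append(
                dict(
                    marker_path=marker_path, dapi_path=dapi_path, line=line,
                    passage=passage, marker=marker, bio_rep=bio, tech_rep=tech,
                    is_control=is_ctrl,
                )
            )
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(records[0].keys()))
        writer.writeheader()
        writer.writerows(records)
    return manifest


def write_count_matrix(out_dir: str | Path, matrix, gene_ids, barcodes) -> Path:
    """Write a 10x-style MatrixMarket triplet (matrix.mtx, features.tsv,
    barcodes.tsv) and return the directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), sp.coo_matrix(matrix))
    (out_dir / "features.tsv").write_text("\n".join(gene_ids) + "\n")
    (out_dir / "barcodes.tsv").write_text("\n".join(barcodes) + "\n")
    return out_dir
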