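"""Relative expression by the -ddCt method with reference-gene stability.

Workflow
--------
1. :func:`reference_stability` ranks candidate housekeeping genes by the
   classic geNorm M measure: for candidate j, M_j is the mean over the
   other candidates k of the standard deviation across samples of the
   per-sample log2 expression ratio of j versus k.  On the Ct scale
   (expression ~ 2**(-Ct)) that log-ratio is simply Ct_k - Ct_j, so M
   is computed directly from technical-replicate-averaged Ct values.
   Lower M means more stable.

2. :func:`delta_delta_ct` computes relative expression.  Technical
   replicates are averaged first to one Ct per (gene, biological
   sample); the normaliser is the arithmetic mean of the reference-gene
   Ct values (equivalent to the geometric mean of their linear
   quantities); dCt = Ct_target - Ct_ref per sample; ddCt is the group
   mean dCt minus the calibrator mean dCt.  Reported on both scales:
   -ddCt (log2 fold change) and 2**(-ddCt) (fold change).  Perfect
   amplification efficiency (2.00 per cycle) is assumed throughout; no
   standard-curve correction is applied.

3. :func:`welch_compare` contrasts two groups on their per-biological-
   replicate -ddCt values with a two-sided Welch t-test.  No
   multiple-testing correction is applied across genes; stars are
   per-gene, which is a documented limitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import GroupComparison, welch_compare_values

__all__ = [
    "RelativeExpression",
    "StabilityRanking",
    "reference_stability",
    "delta_delta_ct",
    "welch_compare",
    "read_ct_table",
]

CT_COLUMNS = ["gene", "sample", "group", "bio_rep", "tech_rep", "ct"]


def _validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    ct = table["ct"]
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise ValueError("Ct values must be finite and > 0")
    return table


def _tech_mean(table: pd.DataFrame) -> pd.DataFrame:
    """One Ct per (gene, sample): mean and sd over technical replicates."""
    return (
        table.groupby(["gene", "sample", "group", "bio_rep"], sort=True)["ct"]
        .agg(ct="mean", ct_tech_sd="std", n_tech="size")
        .reset_index()
    )


@dataclass(frozen=True)
class StabilityRanking:
    """geNorm-style stability of candidate reference genes (lower M =
    more stable); ``ranking`` is ascending in M."""

    m_values: dict[str, float]

    @property
    def ranking(self) -> list[str]:
        return sorted(self.m_values, key=lambda g: (self.m_values[g], g))

    def best(self, n: int = 2) -> list[str]:
        return self.ranking[:n]


def reference_stability(
    table: pd.DataFrame, candidates: Sequence[str]
) -> StabilityRanking:
    """Rank candidate reference genes by the pairwise-variation M value.

    Each candidate must be measured in every sample; the M value is
    computed on technical-replicate-averaged Ct values with the sample
    standard deviation (ddof=1).
    """
    _validate_ct_table(table)
    candidates = list(dict.fromkeys(candidates))
    if len(candidates) < 2:
        raise ValueError("stability ranking needs at least two candidates")

    tech = _tech_mean(table[table["gene"].isin(candidates)])
    wide = tech.pivot(index="sample", columns="gene", values="ct")
    for gene in candidates:
        if gene not in wide.columns or wide[gene].isna().any():
            missing_in = (
                wide.index[wide[gene].isna()].tolist()
                if gene in wide.columns
                else list(wide.index)
            )
            raise ValueError(
                f"candidate {gene!r} missing in sample(s) {missing_in}"
            )
    wide = wide[candidates]

    m_values = {}
    for j in candidates:
        sds = []
        # canonical partner order keeps M bitwise permutation-invariant
        for k in sorted(candidates):
            if k == j:
                continue
            # log2 ratio of j vs k on 2**(-Ct) quantities = Ct_k - Ct_j
            sds.append(float((wide[k] - wide[j]).std(ddof=1)))
        m_values[j] = float(np.mean(sds))
    return StabilityRanking(m_values=m_values)


@dataclass(frozen=True)
class RelativeExpression:
    """Per gene x group relative expression.

    ``summary`` has one row per (gene, group) with the mean -ddCt, the
    fold change 2**(-ddCt), biological-replicate sd of -ddCt, pooled
    technical-replicate sd (the error bars of a per-replicate plot), and
    n.  ``per_sample`` keeps the per-biological-replicate -ddCt values
    that group tests consume.
    """

    summary: pd.DataFrame
    per_sample: pd.DataFrame
    references: tuple[str, ...]
    calibrator: str

    def values(self, gene: str, group: str) -> np.ndarray:
        sel = self.per_sample[
            (self.per_sample["gene"] == gene) & (self.per_sample["group"] == group)
        ]
        return sel["minus_ddct"].to_numpy()


def _pooled_sd(s) -> float:
    """Root-mean-square of per-sample technical sds; NaN with one tech rep."""
    vals = np.asarray(s, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(np.sqrt(np.mean(np.square(vals))))


def delta_delta_ct(
    table: pd.DataFrame,
    references: Sequence[str],
    calibrator: str,
) -> RelativeExpression:
    """Relative expression of every non-reference gene vs a calibrator group."""
    _validate_ct_table(table)
    references = list(dict.fromkeys(references))
    if not references:
        raise ValueError("at least one reference gene is required")
    if len(references) == 1:
        warnings.warn(
            "single reference gene: normalisation cannot average out "
            "gene-specific variation",
            stacklevel=2,
        )
    if calibrator not in set(table["group"]):
        raise ValueError(f"calibrator group {calibrator!r} not present")

    tech = _tech_mean(table)
    ref_rows = tech[tech["gene"].isin(references)]
    got_refs = set(ref_rows["gene"])
    if got_refs != set(references):
        raise ValueError(f"reference gene(s) missing: {sorted(set(references) - got_refs)}")
    per_ref_count = ref_rows.groupby("sample")["gene"].nunique()
    if (per_ref_count < len(references)).any():
        bad = per_ref_count[per_ref_count < len(references)].index.tolist()
        raise ValueError(f"reference genes incomplete in sample(s) {bad}")

    ref_ct = ref_rows.groupby("sample")["ct"].mean().rename("ref_ct")
    targets = tech[~tech["gene"].isin(references)].merge(ref_ct, on="sample")
    targets["dct"] = targets["ct"] - targets["ref_ct"]

    cal = targets[targets["group"] == calibrator]
    cal_mean = cal.groupby("gene")["dct"].mean().rename("cal_dct")
    missing_cal = set(targets["gene"]) - set(cal_mean.index)
    if missing_cal:
        raise ValueError(
            f"target gene(s) absent in calibrator group: {sorted(missing_cal)}"
        )

    targets = targets.merge(cal_mean, on="gene")
    targets["minus_ddct"] = -(targets["dct"] - targets["cal_dct"])
    per_sample = targets[
        ["gene", "sample", "group", "bio_rep", "minus_ddct", "ct_tech_sd", "n_tech"]
    ].copy()

    summary = (
        targets.groupby(["gene", "group"], sort=True)
        .agg(
            minus_ddct=("minus_ddct", "mean"),
            sd_bio=("minus_ddct", "std"),
            sd_tech=("ct_tech_sd", _pooled_sd),
            n=("minus_ddct", "size"),
        )
        .reset_index()
    )
    summary["fold_change"] = 2.0 ** summary["minus_ddct"]
    summary = summary[
        ["gene", "group", "minus_ddct", "fold_change", "sd_bio", "sd_tech", "n"]
    ]
    return RelativeExpression(
        summary=summary,
        per_sample=per_sample,
        references=tuple(references),
        calibrator=calibrator,
    )


def welch_compare(
    expr: RelativeExpression, gene: str, groups: tuple[str, str]
) -> GroupComparison:
    """Two-sided Welch t-test on per-replicate -ddCt values of one gene."""
    a = expr.values(gene, groups[0])
    b = expr.values(gene, groups[1])
    return welch_compare_values(a, b, labels=groups, alternative="two-sided")


def read_ct_table(path) -> pd.DataFrame:
    """Read a long-format Ct CSV (gene, sample, group, bio_rep, tech_rep, ct)."""
    return _validate_ct_table(pd.read_csv(path))
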