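"""Abundance quantification, two-group comparison, and diversity indices.

Feature abundance (contigs, or KO/Pfam functional categories) is expressed
as transcripts per kilobase per million (TPM): counts are first length
normalized to per-kilobase rates, then scaled so each sample sums to 10^6.
Functional-category abundance is the sum of TPM over genes annotated to the
category, computed at gene level.

Two-group differences use the two-sided Wilcoxon rank-sum (Mann-Whitney U)
test per feature — exact when group sizes allow and no ties are present,
otherwise the tie-corrected normal approximation with midranks.  Raw
p-values carry the conventional p < 0.05 significance flag;
Benjamini-Hochberg FDR values are reported alongside.

Diversity over phage taxa: richness ``S`` (taxa with positive abundance),
Shannon ``H = -sum(p_i ln p_i)``, Simpson in Gini form ``D = 1 - sum(p_i^2)``
(inverse Simpson available), and Pielou evenness ``J = H / ln(S)``,
undefined-flagged at S <= 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

TPM_SCALE = 1e6


def tpm(counts: Sequence[float], lengths_bp: Sequence[int]) -> np.ndarray:
    """TPM for one sample: per-kilobase rates rescaled to sum to 1e6.

    An all-zero count vector returns all zeros (flagged by the caller via
    the column sum).  Doubling every count leaves the result unchanged.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths_bp, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("feature lengths must be positive")
    if np.any(counts < 0):
        raise ValueError("negative read counts")
    rates = counts / (lengths / 1000.0)
    total = rates.sum()
    if total == 0:
        return np.zeros_like(rates)
    return TPM_SCALE * rates / total


def tpm_table(
    counts: pd.DataFrame, lengths_bp: Mapping[str, int]
) -> pd.DataFrame:
    """TPM table from a features x samples count table."""
    lengths = [lengths_bp[f] for f in counts.index]
    return counts.apply(lambda col: pd.Series(tpm(col.to_numpy(), lengths),
                                              index=counts.index))


@dataclass(frozen=True)
class ComparisonResult:
    feature_id: str
    median_a: float
    median_b: float
    p_value: float
    bh_fdr: float
    significant_raw: bool


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when both groups are small and tie-free;
    otherwise the normal approximation with midranks and tie correction.
    Two identical constant groups give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        return 1.0
    method = "exact" if (not has_ties and len(a) + len(b) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def compare_groups(
    table: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Per-feature two-group comparison of an abundance table
    (features x samples)."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    missing = [s for s in list(group_a) + list(group_b) if s not in table.columns]
    if missing:
        raise KeyError(f"samples absent from the table: {missing}")
    pvals = []
    medians = []
    for _, row in table.iterrows():
        a = row[list(group_a)].to_numpy(dtype=float)
        b = row[list(group_b)].to_numpy(dtype=float)
        pvals.append(rank_sum_test(a, b))
        medians.append((float(np.median(a)), float(np.median(b))))
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return [
        ComparisonResult(
            feature_id=str(fid),
            median_a=med[0],
            median_b=med[1],
            p_value=p,
            bh_fdr=float(q),
            significant_raw=p < alpha,
        )
        for fid, p, q, med in zip(table.index, pvals, fdr, medians)
    ]


@dataclass(frozen=True)
class DiversityReport:
    sample_id: str
    rank: str
    richness: int
    shannon: float
    simpson: float
    pielou: float  # NaN-flagged when richness <= 1
    pielou_defined: bool


def diversity(
    abundances: Mapping[str, float] | Sequence[float],
    sample_id: str = "",
    rank: str = "genus",
    inverse_simpson: bool = False,
) -> DiversityReport:
    """Diversity indices for one sample's taxon abundance vector."""
    values = np.asarray(
        list(abundances.values()) if isinstance(abundances, Mapping) else abundances,
        dtype=float,
    )
    if np.any(values < 0):
        raise ValueError("negative abundances")
    positive = values[values > 0]
    if positive.size == 0:
        raise ValueError("all-zero abundance vector")
    p = positive / positive.sum()
    shannon = float(-(p * np.log(p)).sum())
    sum_sq = float((p**2).sum())
    simpson = 1.0 / sum_sq if inverse_simpson else 1.0 - sum_sq
    s = int(positive.size)
    if s > 1:
        pielou, defined = shannon / math.log(s), True
    else:
        pielou, defined = float("nan"), False
    return DiversityReport(
        sample_id=sample_id,
        rank=rank,
        richness=s,
        shannon=shannon,
        simpson=simpson,
        pielou=pielou,
        pielou_defined=defined,
    )


def compare_diversity(
    reports_a: Sequence[DiversityReport],
    reports_b: Sequence[DiversityReport],
) -> dict[str, float]:
    """Two-sided rank-sum p per diversity index between two sample groups."""
    out = {}
    for index in ("richness", "shannon", "simpson", "pielou"):
        a = [getattr(r, index) for r in reports_a if not math.isnan(getattr(r, index))]
        b = [getattr(r, index) for r in reports_b if not math.isnan(getattr(r, index))]
        if len(a) >= 2 and len(b) >= 2:
            out[index] = rank_sum_test(a, b)
        else:
            out[index] = float("nan")
    return out


def category_abundance(
    gene_tpm: pd.DataFrame,
    gene_to_categories: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Sum gene-level TPM into functional-category rows (KO/Pfam terms)."""
    rows: dict[str, np.ndarray] = {}
    for gene, cats in gene_to_categories.items():
        if gene not in gene_tpm.index:
            continue
        vec = gene_tpm.loc[gene].to_numpy(dtype=float)
        for cat in cats:
            rows[cat] = rows.get(cat, np.zeros(len(gene_tpm.columns))) + vec
    return pd.DataFrame.from_dict(rows, orient="index", columns=gene_tpm.columns).sort_index()
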