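"""Mode-stratified gene- and variant-level contrasts.

Covers the comparisons used to characterize dominant vs recessive disease
genes: relative brain/body expression (median TPM ratio), developmental-
period brain expression, tissue-specific protein-interaction degree and
breadth, pLI constraint binning, and two-group score comparisons (Wilcoxon
rank-sum for functional/constraint scores, two-sample t-test for expression
levels) with the significance-star convention * p<0.1, ** p<0.01,
*** p<0.001, **** p<0.00001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import GeneAnnotation
from .synthetic_cohort import PPI_TISSUES
from .trio_inheritance import round1

#: pseudocount (TPM) added to both medians when the body denominator is
#: silent, so log-scale ratios stay finite
RATIO_PSEUDOCOUNT = 0.01


class GeneLookupError(KeyError):
    pass


def brain_body_ratio(
    tpm: pd.DataFrame,
    samples: pd.DataFrame,
    gene: str,
    pseudocount: float = RATIO_PSEUDOCOUNT,
) -> float:
    """Median brain TPM over median non-brain TPM for one gene."""
    if gene not in tpm.index:
        raise GeneLookupError(gene)
    is_brain = samples.set_index("sample_id").loc[tpm.columns, "is_brain"].to_numpy()
    if is_brain.sum() == 0 or (~is_brain).sum() == 0:
        raise ValueError("need at least one brain and one non-brain sample")
    row = tpm.loc[gene].to_numpy(dtype=float)
    num = float(np.median(row[is_brain]))
    den = float(np.median(row[~is_brain]))
    if den == 0.0:
        num += pseudocount
        den += pseudocount
    return num / den


def period_median_expression(
    tpm: pd.DataFrame, samples: pd.DataFrame, gene: str, period: str
) -> float:
    """Median TPM of one gene over samples of a developmental period."""
    if gene not in tpm.index:
        raise GeneLookupError(gene)
    meta = samples.set_index("sample_id").loc[tpm.columns]
    mask = (meta["period"] == period).to_numpy()
    if mask.sum() == 0:
        raise ValueError(f"no samples labelled period={period!r}")
    return float(np.median(tpm.loc[gene].to_numpy(dtype=float)[mask]))


def ppi_degree(edges: pd.DataFrame, gene: str, tissue: str) -> int:
    """Number of distinct interaction partners of a gene in one tissue."""
    sub = edges[(edges.gene_a == gene) & (edges.tissue == tissue)]
    partners = set(sub.gene_b)
    sub = edges[(edges.gene_b == gene) & (edges.tissue == tissue)]
    partners |= set(sub.gene_a)
    return len(partners)


def ppi_breadth(edges: pd.DataFrame, gene: str) -> int:
    """Number of tissues (0-7) in which a gene has at least one interaction."""
    tissues = set(edges.loc[(edges.gene_a == gene) | (edges.gene_b == gene), "tissue"])
    return len(tissues & set(PPI_TISSUES))


def ppi_positive_fraction(
    edges: pd.DataFrame, genes: Sequence[str], tissue: str = "brain"
) -> float:
    """Fraction of the gene list with >= 1 interaction in the tissue."""
    if not genes:
        raise ValueError("empty gene list")
    touched = set(edges.loc[edges.tissue == tissue, "gene_a"]) | set(
        edges.loc[edges.tissue == tissue, "gene_b"]
    )
    return sum(g in touched for g in genes) / len(genes)


def mean_ppi_degree(
    edges: pd.DataFrame, genes: Sequence[str], tissue: str = "brain",
    positive_only: bool = True,
) -> float:
    """Mean interaction count in a tissue, by default over PPI-positive genes."""
    degrees = [ppi_degree(edges, g, tissue) for g in genes]
    if positive_only:
        degrees = [d for d in degrees if d > 0]
    if not degrees:
        return float("nan")
    return float(np.mean(degrees))


def constraint_bins(
    genes: Iterable[GeneAnnotation], lo: float = 0.1, hi: float = 0.9
) -> pd.DataFrame:
    """Per-mode percentages of genes with pLI near 0 (<= lo) and near 1 (>= hi).

    Returns a table indexed by disease mode with ``pct_near_0`` and
    ``pct_near_1`` columns (one decimal); empty mode groups are absent.
    """
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("need 0 <= lo < hi <= 1")
    df = pd.DataFrame(
        [{"mode": g.disease_mode, "pli": g.pli} for g in genes]
    )
    if df.empty:
        return pd.DataFrame(columns=["pct_near_0", "pct_near_1"])
    out = {}
    for mode, sub in df.groupby("mode"):
        out[mode] = {
            "pct_near_0": round1(100.0 * float((sub.pli <= lo).mean())),
            "pct_near_1": round1(100.0 * float((sub.pli >= hi).mean())),
        }
    return pd.DataFrame(out).T


@dataclass(frozen=True)
class StatResult:
    """Outcome of a two-group comparison with its significance star label."""

    test: str  # wilcoxon_rank_sum | two_sample_t
    statistic: float
    p_value: float
    n1: int
    n2: int
    stars: str


def star_label(p: float) -> str:
    """Significance stars with half-open boundaries: * p<0.1 ... **** p<1e-5."""
    if p < 1e-5:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.1:
        return "*"
    return ""


#: sample size above which the rank-sum test switches from the exact null
#: distribution to the continuity-corrected normal approximation
EXACT_RANKSUM_MAX_N = 50


def compare_score_groups(
    group1: Sequence[float],
    group2: Sequence[float],
    which_test: str = "wilcoxon_rank_sum",
) -> StatResult:
    """Two-sided two-group comparison.

    ``wilcoxon_rank_sum`` (Mann-Whitney U) is used for functional and
    constraint scores: exact null distribution up to n=50 per group
    (mid-ranked ties force the normal path), continuity-corrected normal
    approximation above. ``two_sample_t`` is Welch's unequal-variance
    t-test, used for expression levels.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    if which_test == "wilcoxon_rank_sum":
        if max(len(x), len(y)) <= EXACT_RANKSUM_MAX_N and not _has_ties(x, y):
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        else:
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            )
        stat, p = float(res.statistic), float(res.pvalue)
    elif which_test == "two_sample_t":
        res = stats.ttest_ind(x, y, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {which_test!r}")
    return StatResult(which_test, stat, min(p, 1.0), len(x), len(y), star_label(p))


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) != len(pooled)
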