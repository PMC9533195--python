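"""End-to-end analysis steps over a simulated study.

Each function here is one stage of the cohort analysis: trio diagnosis and
yield summary, re-analysis comparison, CNV detection validation against the
embedded events, mode-stratified gene-property contrasts, and carrier-
frequency estimation with nested-cohort comparison. The numbered scripts
under ``analysis/`` and the acceptance script are thin drivers over these.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .carrier_estimation import (
    aggregate_q,
    compare_panels,
    panel_report,
    panel_sensitivity,
    population_carrier_rate,
)
from .cnv_depth_caller import CnvThresholds, call_cohort_cnvs
from .gene_property_stats import (
    brain_body_ratio,
    compare_score_groups,
    constraint_bins,
    mean_ppi_degree,
    period_median_expression,
    ppi_breadth,
    ppi_positive_fraction,
)
from .records import CohortSummary, DiagnosisCall
from .synthetic_cohort import SimulatedStudy, SimulationConfig, simulate_study
from .trio_inheritance import (
    ClassifyPolicy,
    classify_cohort,
    reanalysis_diff,
    round1,
    summarize_cohort,
)


def diagnose_cohort(study: SimulatedStudy) -> tuple[list[DiagnosisCall], CohortSummary]:
    """Classify every trio and summarize the cohort's diagnostic yield.

    CNV diagnoses are counted from the ground-truth CNV carrier list (the
    depth-based caller is validated separately in :func:`cnv_validation`).
    """
    genes = {g.symbol: g for g in study.panel}
    tr = study.truth.trios
    routes = dict(zip(tr.trio_id, tr.diagnosis_route))
    calls = classify_cohort(study.cohort.records, genes, routes=routes)
    summary = summarize_cohort(
        calls, len(tr), n_cnv_diagnosed=int((tr.diagnosis_route == "cnv").sum())
    )
    return calls, summary


def reanalysis_comparison(study: SimulatedStudy) -> dict:
    """Re-run classification as the 'initial' pipeline pass and diff.

    The initial pass consults the old gene-database snapshot, drops sites
    under the depth floor, excludes synonymous variants, and misses the
    cases flagged for phenotype re-interpretation; the diff attributes every
    rescued case to a reason.
    """
    genes = {g.symbol: g for g in study.panel}
    tr = study.truth.trios
    old_db = frozenset(study.truth.genes.loc[study.truth.genes.in_old_db, "symbol"])
    set_aside = frozenset(
        tr.loc[tr.missed_reason.isin(["phenotype_reevaluation", "other"]), "trio_id"]
    )
    old_policy = ClassifyPolicy(
        gene_db=old_db, include_synonymous=False, drop_low_depth=True,
        excluded_trios=set_aside,
    )
    old_calls = classify_cohort(study.cohort.records, genes, old_policy)
    new_calls = classify_cohort(study.cohort.records, genes)
    pheno = frozenset(tr.loc[tr.missed_reason == "phenotype_reevaluation", "trio_id"])
    diff = reanalysis_diff(
        old_calls, new_calls, old_db, depth_floor=10, phenotype_reevaluated=pheno
    )
    n = len(tr)
    n_cnv = int((tr.diagnosis_route == "cnv").sum())
    return {
        "n_trios": n,
        "old_yield_pct": round1(100.0 * (len(old_calls) + n_cnv) / n),
        "new_yield_pct": round1(100.0 * (len(new_calls) + n_cnv) / n),
        "gain_pct": round1(100.0 * len(diff) / n),
        "n_rescued": len(diff),
        "reasons": dict(Counter(d.reason for d in diff)),
        "diff": diff,
    }


def cnv_validation(
    config: SimulationConfig, thresholds: CnvThresholds = CnvThresholds()
) -> dict:
    """Run the depth-ratio caller on a simulated cohort and score it against
    the embedded events (state-aware overlap matching)."""
    study = simulate_study(config)
    calls = call_cohort_cnvs(study.intervals, study.coverage,
                             study.cohort.sample_sheet, thresholds)
    true = study.truth.cnvs
    matched = sum(
        any(
            c.trio_id == t.trio_id and c.chrom == t.chrom and c.state == t.state
            and c.first_interval <= t.last_interval
            and c.last_interval >= t.first_interval
            for c in calls
        )
        for _, t in true.iterrows()
    )
    return {
        "n_trios": config.n_trios,
        "n_events": int(len(true)),
        "n_calls": len(calls),
        "recall": matched / len(true) if len(true) else float("nan"),
        "false_calls_per_trio": (len(calls) - matched) / config.n_trios,
        "calls": calls,
    }


def gene_property_contrasts(study: SimulatedStudy) -> dict:
    """Dominant-vs-recessive contrasts: expression, PPI, constraint, scores."""
    genes = study.truth.genes
    by_mode = {m: list(genes.loc[genes.disease_mode == m, "symbol"]) for m in ("AD", "AR", "XL")}
    expr, edges = study.expression, study.ppi_edges

    ratios = {
        m: [brain_body_ratio(expr.tpm, expr.samples, g) for g in syms]
        for m, syms in by_mode.items()
    }
    expr_test = compare_score_groups(
        list(np.log(ratios["AD"])), list(np.log(ratios["AR"])), "two_sample_t"
    )
    period_medians = {
        period: {
            m: float(np.median([
                period_median_expression(expr.tpm, expr.samples, g, period) for g in syms
            ]))
            for m, syms in by_mode.items()
        }
        for period in ("prenatal", "postnatal")
    }

    ppi = {}
    for m in ("AD", "AR"):
        syms = by_mode[m]
        positive = ppi_positive_fraction(edges, syms, "brain")
        ppi[m] = {
            "positive_pct": round1(100 * positive),
            "mean_brain_degree": mean_ppi_degree(edges, syms, "brain", positive_only=True),
        }
    ar_positive = [g for g in by_mode["AR"] if ppi_breadth(edges, g) > 0
                   and any((edges.tissue == "brain") & ((edges.gene_a == g) | (edges.gene_b == g)))]
    all7 = [g for g in ar_positive if ppi_breadth(edges, g) == 7]
    ppi["AR"]["all_seven_tissue_pct"] = (
        round1(100 * len(all7) / len(ar_positive)) if ar_positive else float("nan")
    )

    bins = constraint_bins(
        [row for row in study.panel], lo=0.1, hi=0.9
    )

    modes = dict(zip(genes.symbol, genes.disease_mode))
    scores: dict[str, dict] = {}
    for score in ("cadd", "sift", "phylop", "aa_conservation"):
        groups = {"AD": [], "AR": []}
        for v in study.variants:
            if v.known_pathogenic and modes.get(v.gene) in groups:
                groups[modes[v.gene]].append(getattr(v, score))
        res = compare_score_groups(groups["AD"], groups["AR"], "wilcoxon_rank_sum")
        scores[score] = {
            "median_AD": float(np.median(groups["AD"])),
            "median_AR": float(np.median(groups["AR"])),
            "p_value": res.p_value,
            "stars": res.stars,
        }
    return {
        "brain_body_median_ratio": {m: float(np.median(r)) for m, r in ratios.items()},
        "expression_t_test": expr_test,
        "period_medians": period_medians,
        "ppi": ppi,
        "constraint_bins": bins,
        "score_tests": scores,
    }


def carrier_analysis(study: SimulatedStudy, subset_n_trios: int | None = None) -> dict:
    """Per-gene carrier estimates, population rate, panel sensitivity, and
    the nested smaller-cohort comparison.

    The screening panel is built from the pathogenic alleles observed in
    diagnosed recessive patients of the (sub)cohort that also segregate in
    the population references; sensitivity is evaluated against all
    recessive patient allele observations of the full cohort.
    """
    genes = study.truth.genes
    tr = study.truth.trios
    variants_by_id = {v.variant_id: v for v in study.variants}
    ar_symbols = list(genes.loc[genes.disease_mode == "AR", "symbol"])

    estimates = [aggregate_q(g, study.variants) for g in ar_symbols]
    nonzero = [e for e in estimates if e.carrier_freq > 0]
    report = panel_report(estimates)

    def observed_alleles(trios: pd.DataFrame) -> list[str]:
        out = []
        rec = trios[trios.causal_mode.isin(["comp_het", "homozygous"])]
        for ids in rec.causal_variant_ids:
            for vid in ids.split(";"):
                if vid:
                    out.append(vid)
                    if not ids.count(";"):  # homozygous: two copies of one allele
                        out.append(vid)
        return out

    patient_alleles = observed_alleles(tr)
    if subset_n_trios is None:
        subset_n_trios = len(tr)
    sub = tr.iloc[:subset_n_trios]
    panel = {
        vid for vid in observed_alleles(sub)
        if vid in variants_by_id
        and any(a.het_af > 0 for a in variants_by_id[vid].source_afs.values())
    }
    sens = panel_sensitivity(panel, patient_alleles)

    # nested-cohort estimates use only each cohort's observed alleles
    def cohort_estimates(trios: pd.DataFrame):
        seen = set(observed_alleles(trios))
        ests = []
        for g in ar_symbols:
            vs = [v for v in study.variants if v.gene == g and v.variant_id in seen]
            ests.append(aggregate_q(g, vs))
        return ests

    small = cohort_estimates(sub)
    large = cohort_estimates(tr)
    small_nonzero = {e.gene for e in small if e.carrier_freq > 0}
    large_nonzero = [e for e in large if e.carrier_freq > 0]
    if small_nonzero:
        folds = compare_panels(
            [e for e in small if e.gene in small_nonzero],
            [e for e in large if e.gene in small_nonzero],
        )
    else:
        folds = pd.DataFrame(columns=["gene", "fold"])
        folds.attrs["mean_fold"] = float("nan")
    rate = population_carrier_rate(estimates)
    return {
        "estimates": estimates,
        "report": report,
        "population_carrier_rate": rate,
        "one_in_n": 1.0 / rate if rate > 0 else float("inf"),
        "max_gene_carrier_pct": 100.0 * max((e.carrier_freq for e in estimates), default=0.0),
        "n_genes_with_carriers": len(nonzero),
        "panel_size": len(panel),
        "sensitivity": sens,
        "n_patient_alleles": len(patient_alleles),
        "subset_n_trios": subset_n_trios,
        "n_overlap_genes": int(len(folds)),
        "mean_fold": folds.attrs["mean_fold"],
        "fold_table": folds,
        "n_genes_small_cohort": len(small_nonzero),
        "n_genes_large_cohort": len(large_nonzero),
    }
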