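"""Trio-based inheritance-mode classification and cohort summaries.

Given proband/father/mother genotypes at candidate sites, each site is
labelled by allele origin (de novo, paternal, maternal, both, hemizygous
splits), compound heterozygotes are phased by parental origin, each trio is
assigned one diagnosis-mode category, and cohort-level yield / mode-breakdown
percentages are computed. A re-analysis diff compares two pipeline passes and
attributes each newly diagnosed case to a reason (new database entry,
low-coverage rescue, synonymous re-inclusion, phenotype re-evaluation).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .records import (
    HET,
    HEMI_ALT,
    HOM_ALT,
    MISSING,
    CohortSummary,
    DiagnosisCall,
    GeneAnnotation,
    TrioGenotypeRecord,
    carries_alt,
    is_x,
)

SITE_LABELS = (
    "de_novo",
    "inherited_paternal",
    "inherited_maternal",
    "inherited_both",
    "hemizygous_maternal",
    "hemizygous_de_novo",
    "uninformative",
)


@dataclass(frozen=True)
class SiteCall:
    label: str
    mendelian_error: bool = False


def round1(x: float) -> float:
    """Report-time rounding: half-up to one decimal."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def classify_site(record: TrioGenotypeRecord) -> SiteCall:
    """Label one genotyped site by allele origin.

    De novo means the proband carries an alt allele absent from both
    parents. On chrX a male proband's hemizygous alt splits by maternal
    carrier status. Mendelian-impossible combinations (e.g. a hom-alt
    proband with a hom-ref parent) are flagged and left uninformative.
    """
    p, f, m = record.proband_gt, record.father_gt, record.mother_gt
    on_x = is_x(record.variant.chrom)
    male = record.proband_sex == "male"

    if p == MISSING or not carries_alt(p):
        return SiteCall("uninformative")

    if on_x and male:
        # father's X is irrelevant to a son (he transmits Y)
        if m == MISSING:
            return SiteCall("uninformative")
        if carries_alt(m):
            return SiteCall("hemizygous_maternal")
        return SiteCall("hemizygous_de_novo")

    if f == MISSING or m == MISSING:
        return SiteCall("uninformative")

    father_alt = carries_alt(f)
    mother_alt = carries_alt(m)
    # a parent can only transmit ref if they have one: hemizygous-alt fathers
    # on chrX always transmit alt to daughters, hom-alt parents always alt
    father_must_alt = f == HOM_ALT or (on_x and f == HEMI_ALT)
    mother_must_alt = m == HOM_ALT

    if p == HET:
        if father_must_alt and mother_must_alt:
            return SiteCall("uninformative", mendelian_error=True)
        if father_alt and mother_alt:
            return SiteCall("inherited_both")
        if father_alt:
            return SiteCall("inherited_paternal")
        if mother_alt:
            return SiteCall("inherited_maternal")
        return SiteCall("de_novo")

    # proband hom_alt: one alt allele required from each parent
    if father_alt and mother_alt:
        return SiteCall("inherited_both")
    return SiteCall("uninformative", mendelian_error=True)


def detect_compound_het(
    gene_records: Sequence[TrioGenotypeRecord],
    allow_de_novo_partner: bool = False,
) -> list[tuple[TrioGenotypeRecord, TrioGenotypeRecord]]:
    """Variant pairs in trans within one gene of one trio.

    A pair is in trans when one heterozygous allele is paternally and the
    other maternally inherited. Two alleles from the same parent are in cis
    and never paired. A de novo allele may partner an inherited one only
    when ``allow_de_novo_partner`` is set (its phase is unproven).
    """
    paternal, maternal, de_novo = [], [], []
    for rec in gene_records:
        if rec.proband_gt != HET:
            continue
        label = classify_site(rec).label
        if label == "inherited_paternal":
            paternal.append(rec)
        elif label == "inherited_maternal":
            maternal.append(rec)
        elif label == "de_novo":
            de_novo.append(rec)
    pairs = [(p, m) for p in paternal for m in maternal]
    if allow_de_novo_partner:
        for d in de_novo:
            for other in paternal + maternal:
                pairs.append((d, other))
    return pairs


@dataclass(frozen=True)
class ClassifyPolicy:
    """Settings of one classification pass.

    ``gene_db=None`` consults the full gene panel; a frozenset restricts to
    a database snapshot (for re-analysis comparisons). ``drop_low_depth``
    reproduces a pipeline pass that discards sites with any sample below the
    depth floor; the default keeps them, marking the call non-callable.
    ``excluded_trios`` emulates cases set aside on initial phenotype
    interpretation.
    """

    depth_floor: int = 10
    require_known_pathogenic: bool = True
    allow_de_novo_comp_het: bool = False
    include_synonymous: bool = True
    drop_low_depth: bool = False
    gene_db: frozenset[str] | None = None
    excluded_trios: frozenset[str] = frozenset()


_CATEGORY_RANK = {
    "comp_het": 0,
    "homozygous": 1,
    "de_novo_het": 2,
    "hemizygous": 3,
    "possible_de_novo": 4,
    "unresolved": 5,
}


def assign_mode(
    trio_records: Sequence[TrioGenotypeRecord],
    genes: Mapping[str, GeneAnnotation],
    policy: ClassifyPolicy = ClassifyPolicy(),
) -> DiagnosisCall | None:
    """Assign one trio's diagnosis call from its candidate variants.

    Per gene: an AR gene with a hom-alt proband and two carrier parents is
    homozygous (taking precedence over a coincident trans pair); an AR gene
    with a trans pair is compound het; an AD gene with a de novo site is de
    novo het; an XL gene with a hemizygous-alt male is hemizygous; a
    heterozygous known-pathogenic site with missing parental genotypes is a
    possible de novo; an inherited known-pathogenic dominant site is
    unresolved (inherited dominant). Among genes, definitive categories win
    over unresolved, ties broken by gene symbol.
    """
    if not trio_records:
        return None
    trio_id = trio_records[0].trio_id
    if trio_id in policy.excluded_trios:
        return None

    by_gene: dict[str, list[TrioGenotypeRecord]] = {}
    for rec in trio_records:
        v = rec.variant
        if policy.require_known_pathogenic and not v.known_pathogenic:
            continue
        if policy.gene_db is not None and v.gene not in policy.gene_db:
            continue
        if not policy.include_synonymous and v.consequence == "synonymous":
            continue
        if policy.drop_low_depth and rec.min_depth < policy.depth_floor:
            continue
        by_gene.setdefault(v.gene, []).append(rec)

    candidates: list[DiagnosisCall] = []
    for gene_symbol, recs in by_gene.items():
        ann = genes.get(gene_symbol)
        if ann is None:
            continue
        mode = ann.disease_mode
        calls_here: list[DiagnosisCall] = []
        labelled = [(rec, classify_site(rec)) for rec in recs]
        if mode == "AR":
            hom = [
                rec
                for rec, site in labelled
                if rec.proband_gt == HOM_ALT and site.label == "inherited_both"
            ]
            if hom:
                calls_here.append(_call(trio_id, gene_symbol, (hom[0],), "homozygous", policy))
            else:
                pairs = detect_compound_het(recs, policy.allow_de_novo_comp_het)
                if pairs:
                    calls_here.append(
                        _call(trio_id, gene_symbol, tuple(pairs[0]), "comp_het", policy)
                    )
        elif mode == "AD":
            dn = [rec for rec, site in labelled if site.label == "de_novo"]
            if dn:
                calls_here.append(_call(trio_id, gene_symbol, (dn[0],), "de_novo_het", policy))
            else:
                calls_here.extend(_non_de_novo_dominant(trio_id, gene_symbol, labelled, policy))
        elif mode == "XL":
            hemi = [
                rec
                for rec, site in labelled
                if site.label in ("hemizygous_maternal", "hemizygous_de_novo")
            ]
            dn = [rec for rec, site in labelled if site.label == "de_novo"]
            if hemi:
                calls_here.append(_call(trio_id, gene_symbol, (hemi[0],), "hemizygous", policy))
            elif dn:
                # female X-linked de novo het patients are categorized de novo
                calls_here.append(_call(trio_id, gene_symbol, (dn[0],), "de_novo_het", policy))
            else:
                calls_here.extend(_non_de_novo_dominant(trio_id, gene_symbol, labelled, policy))
        candidates.extend(calls_here)

    if not candidates:
        return None
    candidates.sort(key=lambda c: (_CATEGORY_RANK[c.mode_category], c.gene))
    return candidates[0]


def _non_de_novo_dominant(
    trio_id: str,
    gene_symbol: str,
    labelled: list[tuple[TrioGenotypeRecord, SiteCall]],
    policy: ClassifyPolicy,
) -> list[DiagnosisCall]:
    out = []
    for rec, site in labelled:
        if site.label == "uninformative" and MISSING in (rec.father_gt, rec.mother_gt):
            if carries_alt(rec.proband_gt) and rec.variant.known_pathogenic:
                out.append(
                    _call(
                        trio_id, gene_symbol, (rec,), "possible_de_novo", policy,
                        reason="parental samples unavailable",
                    )
                )
        elif site.label in ("inherited_paternal", "inherited_maternal") and rec.variant.known_pathogenic:
            out.append(
                _call(
                    trio_id, gene_symbol, (rec,), "unresolved", policy,
                    reason="inherited dominant",
                )
            )
    return out


def _call(
    trio_id: str,
    gene: str,
    variants: tuple[TrioGenotypeRecord, ...],
    category: str,
    policy: ClassifyPolicy,
    reason: str = "",
) -> DiagnosisCall:
    callable_ = all(r.min_depth >= policy.depth_floor for r in variants)
    return DiagnosisCall(trio_id, gene, variants, category, callable_, reason)


def classify_cohort(
    records: Iterable[TrioGenotypeRecord],
    genes: Mapping[str, GeneAnnotation],
    policy: ClassifyPolicy = ClassifyPolicy(),
    routes: Mapping[str, str] | None = None,
) -> list[DiagnosisCall]:
    """Classify every trio; returns at most one call per trio.

    ``routes`` optionally stamps each call's diagnosis route
    (known_variant / phenotype_expansion) from clinical chart labels.
    """
    by_trio: dict[str, list[TrioGenotypeRecord]] = {}
    for rec in records:
        by_trio.setdefault(rec.trio_id, []).append(rec)
    calls = []
    for trio_id in sorted(by_trio):
        call = assign_mode(by_trio[trio_id], genes, policy)
        if call is not None:
            if routes is not None and trio_id in routes and routes[trio_id]:
                call.diagnosis_route = routes[trio_id]
            calls.append(call)
    return calls


def summarize_cohort(
    calls: Sequence[DiagnosisCall],
    n_patients: int,
    n_cnv_diagnosed: int = 0,
    possible_de_novo_as_de_novo: bool = True,
) -> CohortSummary:
    """Cohort yield and inheritance-mode breakdown.

    Route percentages (known variant / phenotype expansion / CNV) are of the
    whole cohort and sum to the total diagnostic yield. The mode breakdown
    is a percentage of patients diagnosed with sequence variants; the
    inherited fraction is the recessive (comp het + homozygous) plus
    hemizygous share. Percentages are rounded half-up to one decimal at
    report time only.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    seen = {c.trio_id for c in calls}
    if len(seen) != len(calls):
        raise ValueError("calls must be deduplicated per trio")

    n_known = sum(1 for c in calls if c.diagnosis_route == "known_variant")
    n_pheno = sum(1 for c in calls if c.diagnosis_route == "phenotype_expansion")
    n_diag_snv = len(calls)
    n_diag = n_diag_snv + n_cnv_diagnosed

    def pct(x: float, denom: float) -> float:
        return round1(100.0 * x / denom) if denom else 0.0

    counts: dict[str, int] = {}
    for c in calls:
        cat = c.mode_category
        if possible_de_novo_as_de_novo and cat == "possible_de_novo":
            cat = "de_novo_het"
        counts[cat] = counts.get(cat, 0) + 1
    breakdown = {cat: pct(n, n_diag_snv) for cat, n in sorted(counts.items())}
    inherited = (
        counts.get("comp_het", 0) + counts.get("homozygous", 0) + counts.get("hemizygous", 0)
    )
    return CohortSummary(
        n_patients=n_patients,
        pct_known_variants=pct(n_known, n_patients),
        pct_phenotype_expansion=pct(n_pheno, n_patients),
        pct_cnv=pct(n_cnv_diagnosed, n_patients),
        pct_total_diagnosed=pct(n_diag, n_patients),
        mode_breakdown=breakdown,
        pct_inherited=pct(inherited, n_diag_snv),
    )


REANALYSIS_REASONS = (
    "new_omim_entry",
    "low_coverage_rescue",
    "synonymous_reinclusion",
    "phenotype_reevaluation",
    "other",
)


def reanalysis_diff(
    old_calls: Sequence[DiagnosisCall],
    new_calls: Sequence[DiagnosisCall],
    old_gene_db: frozenset[str] | set[str],
    new_gene_db: frozenset[str] | set[str] | None = None,
    depth_floor: int = 10,
    phenotype_reevaluated: frozenset[str] | set[str] = frozenset(),
) -> list[DiagnosisCall]:
    """Newly diagnosed cases of the second pass, with an attributed reason.

    A case present in ``new_calls`` but absent from ``old_calls`` is
    attributed, in order: to a new gene-database entry if its gene is
    missing from the old snapshot; to a low-coverage rescue if any causal
    site fell below the depth floor; to a synonymous re-inclusion if a
    causal variant is synonymous; to phenotype re-evaluation if the trio is
    on the re-evaluated list; else to 'other'.
    """
    if new_gene_db is not None and not set(old_gene_db) <= set(new_gene_db):
        raise ValueError("old gene database is not a subset of the new one")
    old_trios = {c.trio_id for c in old_calls}
    out = []
    for call in new_calls:
        if call.trio_id in old_trios:
            continue
        if call.gene not in old_gene_db:
            reason = "new_omim_entry"
        elif call.min_depth < depth_floor:
            reason = "low_coverage_rescue"
        elif any(r.variant.consequence == "synonymous" for r in call.variants):
            reason = "synonymous_reinclusion"
        elif call.trio_id in phenotype_reevaluated:
            reason = "phenotype_reevaluation"
        else:
            reason = "other"
        out.append(replace_reason(call, reason))
    return out


def replace_reason(call: DiagnosisCall, reason: str) -> DiagnosisCall:
    new = DiagnosisCall(
        call.trio_id, call.gene, call.variants, call.mode_category, call.callable,
        reason, call.diagnosis_route,
    )
    return new
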