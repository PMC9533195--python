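"""Site classification, compound-het phasing, mode assignment, summaries,
and the re-analysis diff."""

import itertools

import numpy as np
import pytest

from triomode.records import (
    HET,
    HEMI_ALT,
    HEMI_REF,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GeneAnnotation,
    SourceAF,
    TrioGenotypeRecord,
    VariantRecord,
)
from triomode.trio_inheritance import (
    assign_mode,
    classify_cohort,
    classify_site,
    detect_compound_het,
    reanalysis_diff,
    round1,
    summarize_cohort,
)

from oracles import AUTOSOMAL_TABLE, X_FEMALE_TABLE, X_MALE_TABLE


def make_record(
    pgt, fgt, mgt, chrom="chr5", sex="female", gene="G0001", vid="v1",
    pathogenic=True, depth=60, consequence="missense", pos=1000,
):
    v = VariantRecord(
        variant_id=vid, chrom=chrom, pos=pos, ref="A", alt="G", gene=gene,
        consequence=consequence,
        source_afs={"gnomad_eas": SourceAF(0.0, 0, 0)}, known_pathogenic=pathogenic,
    )
    return TrioGenotypeRecord(
        v, "T0001", pgt, fgt, mgt,
        {"proband": depth, "father": depth, "mother": depth}, sex,
    )


def test_autosomal_truth_table_exhaustive():
    for (p, f, m), expected in AUTOSOMAL_TABLE.items():
        got = classify_site(make_record(p, f, m))
        assert got.label == expected, (p, f, m)


def test_chrx_truth_tables_exhaustive():
    for (p, f, m), expected in X_MALE_TABLE.items():
        got = classify_site(make_record(p, f, m, chrom="chrX", sex="male"))
        assert got.label == expected, (p, f, m)
    for (p, f, m), expected in X_FEMALE_TABLE.items():
        got = classify_site(make_record(p, f, m, chrom="chrX", sex="female"))
        assert got.label == expected, (p, f, m)


def test_mendelian_impossible_flagged():
    assert classify_site(make_record(HOM_ALT, HOM_REF, HOM_REF)).mendelian_error
    assert classify_site(make_record(HET, HOM_ALT, HOM_ALT)).mendelian_error
    assert not classify_site(make_record(HET, HOM_REF, HOM_REF)).mendelian_error


def test_missing_genotypes_uninformative():
    assert classify_site(make_record(HET, MISSING, HOM_REF)).label == "uninformative"
    assert classify_site(make_record(MISSING, HET, HET)).label == "uninformative"


def _ch_records(sides):
    recs = []
    for i, side in enumerate(sides):
        f, m = {"P": (HET, HOM_REF), "M": (HOM_REF, HET), "D": (HOM_REF, HOM_REF)}[side]
        recs.append(make_record(HET, f, m, vid=f"v{i}", pos=1000 + i))
    return recs


def test_compound_het_pairing():
    assert len(detect_compound_het(_ch_records("PM"))) == 1
    assert detect_compound_het(_ch_records("PP")) == []  # cis
    pairs = detect_compound_het(_ch_records("PPMMD"))
    assert len(pairs) == 4
    # brute-force oracle over all C(5,2) pairs: in trans iff one paternal,
    # one maternal
    recs = _ch_records("PPMMD")
    sides = "PPMMD"
    expected = {
        frozenset((recs[i].variant.variant_id, recs[j].variant.variant_id))
        for i, j in itertools.combinations(range(5), 2)
        if {sides[i], sides[j]} == {"P", "M"}
    }
    got = {
        frozenset((a.variant.variant_id, b.variant.variant_id)) for a, b in pairs
    }
    assert got == expected
    with_dn = detect_compound_het(_ch_records("PPMMD"), allow_de_novo_partner=True)
    assert len(with_dn) == 8  # de novo pairs with each of the 4 inherited


AR_GENE = {"G0001": GeneAnnotation("G0001", "chr5", "AR", 0.05, 1.0)}
AD_GENE = {"G0001": GeneAnnotation("G0001", "chr5", "AD", 0.99, 0.1)}
XL_GENE = {"G0001": GeneAnnotation("G0001", "chrX", "XL", 0.8, 0.3)}


def test_assign_mode_categories():
    assert assign_mode(_ch_records("PM"), AR_GENE).mode_category == "comp_het"
    assert assign_mode(
        [make_record(HET, HOM_REF, HOM_REF)], AD_GENE
    ).mode_category == "de_novo_het"
    assert assign_mode(
        [make_record(HOM_ALT, HET, HET)], AR_GENE
    ).mode_category == "homozygous"
    assert assign_mode(
        [make_record(HEMI_ALT, HEMI_REF, HET, chrom="chrX", sex="male")], XL_GENE
    ).mode_category == "hemizygous"
    # female X-linked de novo het is categorized de novo, not hemizygous
    assert assign_mode(
        [make_record(HET, HEMI_REF, HOM_REF, chrom="chrX", sex="female")], XL_GENE
    ).mode_category == "de_novo_het"
    # pathogenic alt with parental samples unavailable
    assert assign_mode(
        [make_record(HET, MISSING, MISSING)], AD_GENE
    ).mode_category == "possible_de_novo"
    # inherited dominant stays unresolved
    call = assign_mode([make_record(HET, HET, HOM_REF)], AD_GENE)
    assert call.mode_category == "unresolved" and "inherited" in call.reason


def test_homozygous_takes_precedence_over_comp_het():
    recs = _ch_records("PM") + [make_record(HOM_ALT, HET, HET, vid="v9", pos=1009)]
    assert assign_mode(recs, AR_GENE).mode_category == "homozygous"


def test_non_pathogenic_candidates_yield_no_call():
    rec = make_record(HET, HOM_REF, HOM_REF, pathogenic=False)
    assert assign_mode([rec], AD_GENE) is None


def _dummy_call(i, category, route="known_variant"):
    gt = {"comp_het": (HET, HET, HOM_REF)}.get(category, (HET, HOM_REF, HOM_REF))
    recs = (make_record(*gt, vid=f"c{i}"),)
    if category == "comp_het":
        recs = (make_record(HET, HET, HOM_REF, vid=f"c{i}a"),
                make_record(HET, HOM_REF, HET, vid=f"c{i}b"))
    from triomode.records import DiagnosisCall

    call = DiagnosisCall(f"T{i:04d}", "G0001", recs, category, True, "", route)
    return call


def test_summary_reproduces_cohort_percentages():
    # 1000 patients: 419 known + 47 phenotype-expansion + 42 CNV = 50.8% total
    calls = [
        _dummy_call(i, "de_novo_het", "known_variant") for i in range(419)
    ] + [
        _dummy_call(400 + i, "de_novo_het", "phenotype_expansion") for i in range(19, 66)
    ]
    s = summarize_cohort(calls, 1000, n_cnv_diagnosed=42)
    assert s.pct_known_variants == 41.9
    assert s.pct_phenotype_expansion == 4.7
    assert s.pct_cnv == 4.2
    assert s.pct_total_diagnosed == 50.8
    assert s.pct_total_diagnosed == pytest.approx(
        s.pct_known_variants + s.pct_phenotype_expansion + s.pct_cnv, abs=0.1
    )


def test_summary_mode_breakdown_and_inherited():
    # 629 de novo + 148 comp het + 99 homozygous + 87 hemizygous + 37 other
    calls = (
        [_dummy_call(i, "de_novo_het") for i in range(629)]
        + [_dummy_call(700 + i, "comp_het") for i in range(148)]
        + [_dummy_call(900 + i, "homozygous") for i in range(99)]
        + [_dummy_call(1100 + i, "hemizygous") for i in range(87)]
        + [_dummy_call(1300 + i, "unresolved") for i in range(37)]
    )
    s = summarize_cohort(calls, 2000)
    assert s.mode_breakdown["de_novo_het"] == 62.9
    assert round1(s.mode_breakdown["comp_het"] + s.mode_breakdown["homozygous"]) == 24.7
    assert s.mode_breakdown["hemizygous"] == 8.7
    assert s.pct_inherited == 33.4
    assert sum(s.mode_breakdown.values()) == pytest.approx(100.0, abs=0.2)


def test_summary_single_trio_and_errors():
    s = summarize_cohort([_dummy_call(0, "de_novo_het")], 1)
    assert s.mode_breakdown == {"de_novo_het": 100.0}
    with pytest.raises(ValueError):
        summarize_cohort([], 0)
    with pytest.raises(ValueError):
        summarize_cohort([_dummy_call(0, "de_novo_het")] * 2, 5)


def test_possible_de_novo_counted_in_de_novo_slice():
    calls = [_dummy_call(0, "de_novo_het"), _dummy_call(1, "possible_de_novo")]
    s = summarize_cohort(calls, 10)
    assert s.mode_breakdown == {"de_novo_het": 100.0}
    s2 = summarize_cohort(calls, 10, possible_de_novo_as_de_novo=False)
    assert s2.mode_breakdown == {"de_novo_het": 50.0, "possible_de_novo": 50.0}


def test_reanalysis_diff_reasons():
    old = [_dummy_call(0, "de_novo_het")]
    assert reanalysis_diff(old, old, frozenset({"G0001"})) == []
    new_gene_call = _dummy_call(1, "de_novo_het")
    diff = reanalysis_diff(old, old + [new_gene_call], frozenset({"OTHER"}))
    assert [d.reason for d in diff] == ["new_omim_entry"]
    low = _dummy_call(2, "de_novo_het")
    low.variants = (make_record(HET, HOM_REF, HOM_REF, depth=8, vid="lo"),)
    diff = reanalysis_diff(old, old + [low], frozenset({"G0001"}), depth_floor=10)
    assert [d.reason for d in diff] == ["low_coverage_rescue"]
    syn = _dummy_call(3, "de_novo_het")
    syn.variants = (make_record(HET, HOM_REF, HOM_REF, consequence="synonymous", vid="sy"),)
    diff = reanalysis_diff(old, old + [syn], frozenset({"G0001"}))
    assert [d.reason for d in diff] == ["synonymous_reinclusion"]
    pheno = _dummy_call(4, "de_novo_het")
    diff = reanalysis_diff(
        old, old + [pheno], frozenset({"G0001"}), phenotype_reevaluated={"T0004"}
    )
    assert [d.reason for d in diff] == ["phenotype_reevaluation"]


def test_cohort_classification_recovers_ground_truth(small_study, gene_map):
    tr = small_study.truth.trios
    routes = dict(zip(tr.trio_id, tr.diagnosis_route))
    calls = classify_cohort(small_study.cohort.records, gene_map, routes=routes)
    truth_snv = tr[tr.diagnosed & (tr.diagnosis_route != "cnv")]
    assert {c.trio_id for c in calls} == set(truth_snv.trio_id)
    expected_cat = {
        "de_novo": "de_novo_het",
        "comp_het": "comp_het",
        "homozygous": "homozygous",
        "hemizygous": "hemizygous",
        "inherited_dominant": "unresolved",
    }
    by_trio = {c.trio_id: c for c in calls}
    for _, row in truth_snv.iterrows():
        call = by_trio[row.trio_id]
        assert call.mode_category == expected_cat[row.causal_mode]
        assert call.gene == row.causal_gene


def test_mode_recovery_robust_to_genotype_noise():
    from triomode.synthetic_cohort import SimulationConfig, simulate_study

    cfg = SimulationConfig(
        n_trios=300, n_genes=100, background_variants_per_trio=10,
        genotype_error_rate=0.02, seed=21,
    )
    study = simulate_study(cfg, coverage=False)
    genes = {g.symbol: g for g in study.panel}
    calls = classify_cohort(study.cohort.records, genes)
    tr = study.truth.trios
    truth_dn = (tr.causal_mode == "de_novo").sum()
    called_dn = sum(c.mode_category == "de_novo_het" for c in calls)
    n = int(tr.diagnosed.sum())
    p = truth_dn / n
    se = np.sqrt(n * p * (1 - p))
    assert abs(called_dn - truth_dn) <= 3 * se + 0.05 * n  # noise may drop some calls
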