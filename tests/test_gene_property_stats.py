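"""Expression ratios, PPI counting, constraint binning, two-group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triomode.gene_property_stats import (
    GeneLookupError,
    brain_body_ratio,
    compare_score_groups,
    constraint_bins,
    mean_ppi_degree,
    period_median_expression,
    ppi_breadth,
    ppi_degree,
    ppi_positive_fraction,
    star_label,
)
from triomode.records import GeneAnnotation
from triomode.trio_inheritance import round1

from oracles import exact_ranksum_p


def make_expr(values_by_sample, brain_samples, periods=None):
    tpm = pd.DataFrame({s: [v] for s, v in values_by_sample.items()}, index=["G1"])
    samples = pd.DataFrame(
        {
            "sample_id": list(values_by_sample),
            "tissue": ["brain" if s in brain_samples else "liver" for s in values_by_sample],
            "is_brain": [s in brain_samples for s in values_by_sample],
            "period": [(periods or {}).get(s, "") for s in values_by_sample],
        }
    )
    return tpm, samples


def test_brain_body_ratio_examples():
    tpm, samples = make_expr({"b1": 5.0, "b2": 5.0, "o1": 5.0, "o2": 5.0}, {"b1", "b2"})
    assert brain_body_ratio(tpm, samples, "G1") == 1.0
    tpm, samples = make_expr({"b1": 4.0, "b2": 6.0, "o1": 1.0, "o2": 3.0}, {"b1", "b2"})
    assert brain_body_ratio(tpm, samples, "G1") == pytest.approx(2.5)


def test_brain_body_ratio_zero_denominator_finite():
    tpm, samples = make_expr({"b1": 4.0, "o1": 0.0}, {"b1"})
    r = brain_body_ratio(tpm, samples, "G1")
    assert np.isfinite(r) and r > 1


def test_brain_body_ratio_errors():
    tpm, samples = make_expr({"b1": 4.0, "o1": 1.0}, {"b1"})
    with pytest.raises(GeneLookupError):
        brain_body_ratio(tpm, samples, "NOPE")
    tpm, samples = make_expr({"b1": 4.0, "b2": 1.0}, {"b1", "b2"})
    with pytest.raises(ValueError):
        brain_body_ratio(tpm, samples, "G1")


@settings(derandomize=True, max_examples=50)
@given(st.floats(0.01, 1e4))
def test_brain_body_ratio_scale_invariant(c):
    tpm, samples = make_expr({"b1": 4.0, "b2": 6.0, "o1": 1.0, "o2": 3.0}, {"b1", "b2"})
    assert brain_body_ratio(tpm * c, samples, "G1") == pytest.approx(
        brain_body_ratio(tpm, samples, "G1"), rel=1e-9
    )


def test_period_median_expression():
    tpm, samples = make_expr(
        {"a": 7.0}, {"a"}, periods={"a": "prenatal"}
    )
    assert period_median_expression(tpm, samples, "G1", "prenatal") == 7.0
    tpm, samples = make_expr(
        {"a": 2.0, "b": 4.0, "c": 9.0}, {"a", "b", "c"},
        periods={"a": "prenatal", "b": "prenatal", "c": "prenatal"},
    )
    assert period_median_expression(tpm, samples, "G1", "prenatal") == 4.0
    with pytest.raises(ValueError):
        period_median_expression(tpm, samples, "G1", "postnatal")


EDGES = pd.DataFrame(
    [
        {"gene_a": "g", "gene_b": "x", "tissue": "brain"},
        {"gene_a": "g", "gene_b": "y", "tissue": "brain"},
        {"gene_a": "x", "gene_b": "g", "tissue": "liver"},
    ]
)


def test_ppi_degree_and_breadth_hand_counts():
    assert ppi_degree(EDGES, "g", "brain") == 2
    assert ppi_degree(EDGES, "g", "liver") == 1
    assert ppi_breadth(EDGES, "g") == 2
    assert ppi_degree(EDGES, "nobody", "brain") == 0
    assert ppi_breadth(EDGES, "nobody") == 0


def test_ppi_breadth_bounded_and_degree_sum_dominates(small_study):
    edges = small_study.ppi_edges
    for g in small_study.truth.genes.symbol.head(40):
        b = ppi_breadth(edges, g)
        assert 0 <= b <= 7
        total = sum(
            ppi_degree(edges, g, t)
            for t in ("brain", "heart", "kidney", "liver", "lung", "muscle", "thymus")
        )
        assert total >= b


def test_ppi_positive_fraction_printed_value():
    # 59 of 163 genes with >= 1 brain interaction -> 36.2%
    genes = [f"g{i}" for i in range(163)]
    edges = pd.DataFrame(
        [{"gene_a": f"g{i}", "gene_b": f"p{i}", "tissue": "brain"} for i in range(59)]
    )
    frac = ppi_positive_fraction(edges, genes, "brain")
    assert round1(100 * frac) == 36.2


def test_constraint_bins_hand_counts():
    genes = [GeneAnnotation(f"g{i}", "chr1", "AD", p, 0.5) for i, p in enumerate([1.0, 1.0])]
    bins = constraint_bins(genes)
    assert bins.loc["AD", "pct_near_1"] == 100.0
    plis = [0.05, 0.95, 0.99, 0.5]
    genes = [GeneAnnotation(f"g{i}", "chr1", "AR", p, 0.5) for i, p in enumerate(plis)]
    bins = constraint_bins(genes, lo=0.1, hi=0.9)
    assert bins.loc["AR", "pct_near_0"] == 25.0
    assert bins.loc["AR", "pct_near_1"] == 50.0
    with pytest.raises(ValueError):
        constraint_bins(genes, lo=0.9, hi=0.1)


def test_synthetic_panel_constraint_contrast(small_study):
    bins = constraint_bins(small_study.panel)
    assert bins.loc["AD", "pct_near_1"] > bins.loc["AR", "pct_near_1"]
    assert bins.loc["AR", "pct_near_0"] > bins.loc["AD", "pct_near_0"]


def test_identical_groups_not_significant():
    res = compare_score_groups([1.0, 2, 3, 4], [1.0, 2, 3, 4])
    assert res.p_value > 0.9 and res.stars == ""
    res_t = compare_score_groups([1.0, 2, 3, 4], [1.0, 2, 3, 4], "two_sample_t")
    assert res_t.p_value > 0.9


def test_minimum_exact_p_at_n3():
    res = compare_score_groups([1.0, 2, 3], [4.0, 5, 6])
    assert res.p_value == pytest.approx(0.1)
    assert res.stars == ""  # the star boundary is strict: p < 0.1


def test_ranksum_matches_enumeration_oracle():
    rng = np.random.default_rng(3)
    for _ in range(12):
        n1 = int(rng.integers(2, 7))
        n2 = int(rng.integers(2, 7))
        pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # distinct: no ties
        x, y = list(pooled[:n1]), list(pooled[n1:])
        res = compare_score_groups(x, y)
        assert res.p_value == pytest.approx(exact_ranksum_p(x, y), abs=1e-12)


@settings(derandomize=True, max_examples=30)
@given(st.sampled_from([np.exp, np.cbrt, lambda v: 5 * v + 2]))
def test_ranksum_invariant_under_monotone_transform(f):
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 12)
    y = rng.normal(0.8, 1, 9)
    p1 = compare_score_groups(list(x), list(y)).p_value
    p2 = compare_score_groups(list(f(x)), list(f(y))).p_value
    assert p1 == pytest.approx(p2, rel=1e-9)


def test_star_boundaries_half_open():
    assert star_label(0.1) == ""
    assert star_label(0.0999) == "*"
    assert star_label(0.01) == "*"
    assert star_label(0.0099) == "**"
    assert star_label(0.001) == "**"
    assert star_label(0.0009) == "***"
    assert star_label(1e-5) == "***"
    assert star_label(9e-6) == "****"


def test_unknown_test_rejected():
    with pytest.raises(ValueError):
        compare_score_groups([1.0, 2], [3.0, 4], "anova")
    with pytest.raises(ValueError):
        compare_score_groups([1.0], [2.0, 3])


def test_generator_score_contrast_detected(small_study):
    # recessive variants carry weaker deleteriousness scores by construction
    ad, ar = [], []
    modes = dict(zip(small_study.truth.genes.symbol, small_study.truth.genes.disease_mode))
    for v in small_study.variants:
        if not v.known_pathogenic:
            continue
        (ad if modes[v.gene] == "AD" else ar).append(v)
    res = compare_score_groups(
        [v.aa_conservation for v in ad], [v.aa_conservation for v in ar]
    )
    med_ad = np.median([v.aa_conservation for v in ad])
    med_ar = np.median([v.aa_conservation for v in ar])
    assert med_ad < med_ar  # dominant variants more conserved (fewer divergent species)
    assert res.p_value < 0.01


def test_mean_degree_positive_only(small_study):
    edges = small_study.ppi_edges
    genes = list(small_study.truth.genes.symbol)
    m_all = mean_ppi_degree(edges, genes, positive_only=False)
    m_pos = mean_ppi_degree(edges, genes, positive_only=True)
    assert m_pos >= m_all
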