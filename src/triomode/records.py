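"""Core domain types shared across the pipeline.

Genotypes are plain strings so they survive TSV/VCF round trips unchanged.
Male genotypes on chrX are hemizygous (``hemi_ref``/``hemi_alt``); diploid
codes never appear on chrX for a male proband and hemizygous codes never
appear on autosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

# genotype codes
HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
HEMI_REF = "hemi_ref"
HEMI_ALT = "hemi_alt"
MISSING = "missing"

DIPLOID_GTS = (HOM_REF, HET, HOM_ALT)
HAPLOID_GTS = (HEMI_REF, HEMI_ALT)
ALL_GTS = DIPLOID_GTS + HAPLOID_GTS + (MISSING,)

MODES = ("AD", "AR", "XL")
CONSEQUENCES = ("LoF", "missense", "splice", "synonymous", "other")

X_CHROM = "chrX"


def is_x(chrom: str) -> bool:
    return chrom in ("chrX", "X")


def carries_alt(gt: str) -> bool:
    return gt in (HET, HOM_ALT, HEMI_ALT)


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is inconsistent."""


@dataclass(frozen=True)
class SourceAF:
    """Population-frequency summary of one variant in one reference source."""

    het_af: float = 0.0
    hom_count: int = 0
    hemi_count: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.het_af <= 1.0:
            raise ValueError(f"het_af out of [0,1]: {self.het_af}")
        if self.hom_count < 0 or self.hemi_count < 0:
            raise ValueError("negative genotype count")


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant site.

    ``aa_conservation`` counts the number of species carrying a *different*
    amino acid at the site among 99 ortholog proteins, so lower values mean
    stronger conservation.  ``known_pathogenic`` emulates a curated
    ClinVar/HGMD-style pathogenicity assertion.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    cadd: float = 0.0
    sift: float = 1.0
    phylop: float = 0.0
    aa_conservation: int = 0
    source_afs: Mapping[str, SourceAF] = field(default_factory=dict)
    known_pathogenic: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.sift <= 1.0:
            raise ValueError(f"SIFT out of [0,1]: {self.sift}")
        if not 0 <= self.aa_conservation <= 99:
            raise ValueError(f"aa_conservation out of [0,99]: {self.aa_conservation}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")


@dataclass(frozen=True)
class GeneAnnotation:
    """Disease gene with inheritance mode and gnomAD-style constraint scores."""

    symbol: str
    chrom: str
    disease_mode: str
    pli: float
    oe: float

    def __post_init__(self) -> None:
        if self.disease_mode not in MODES:
            raise ValueError(f"unknown disease mode {self.disease_mode!r}")
        if not 0.0 <= self.pli <= 1.0:
            raise ValueError(f"pLI out of [0,1]: {self.pli}")
        if self.oe < 0.0:
            raise ValueError(f"O/E must be >= 0, got {self.oe}")
        if self.disease_mode == "XL" and not is_x(self.chrom):
            raise ValueError(f"XL gene {self.symbol} not on chrX")


@dataclass(frozen=True)
class TrioGenotypeRecord:
    """One variant site genotyped in a proband-father-mother trio."""

    variant: VariantRecord
    trio_id: str
    proband_gt: str
    father_gt: str
    mother_gt: str
    depths: Mapping[str, int] = field(default_factory=dict)  # proband/father/mother
    proband_sex: str = "female"

    def __post_init__(self) -> None:
        for gt in (self.proband_gt, self.father_gt, self.mother_gt):
            if gt not in ALL_GTS:
                raise ValueError(f"unknown genotype {gt!r}")
        on_x = is_x(self.variant.chrom)
        if on_x and self.proband_sex == "male" and self.proband_gt in DIPLOID_GTS:
            raise ValueError("male proband on chrX must have hemizygous genotype")
        if not on_x:
            for gt in (self.proband_gt, self.father_gt, self.mother_gt):
                if gt in HAPLOID_GTS:
                    raise ValueError("hemizygous genotype on an autosome")

    @property
    def min_depth(self) -> int:
        return min(self.depths.values()) if self.depths else 0


MODE_CATEGORIES = (
    "de_novo_het",
    "comp_het",
    "homozygous",
    "hemizygous",
    "possible_de_novo",
    "unresolved",
)


@dataclass
class DiagnosisCall:
    """A patient's causal gene/variant(s) with its inheritance-mode category.

    ``diagnosis_route`` records how the diagnosis was reached: a known SNV
    ('known_variant'), a known variant with an expanded phenotype
    ('phenotype_expansion'), or a CNV ('cnv').
    """

    trio_id: str
    gene: str
    variants: tuple[TrioGenotypeRecord, ...]
    mode_category: str
    callable: bool = True
    reason: str = ""
    diagnosis_route: str = "known_variant"

    def __post_init__(self) -> None:
        if self.mode_category not in MODE_CATEGORIES:
            raise ValueError(f"unknown mode category {self.mode_category!r}")
        n = len(self.variants)
        if self.mode_category == "comp_het" and n != 2:
            raise ValueError("comp_het call requires exactly 2 variants")
        if self.mode_category != "comp_het" and n != 1:
            raise ValueError(f"{self.mode_category} call requires exactly 1 variant")

    @property
    def min_depth(self) -> int:
        return min(r.min_depth for r in self.variants)


@dataclass
class CohortSummary:
    """Cohort-level diagnostic yield and inheritance-mode breakdown.

    All percentages are of the whole cohort except ``mode_breakdown`` and
    ``pct_inherited``, which are percentages of diagnosed patients.
    """

    n_patients: int
    pct_known_variants: float
    pct_phenotype_expansion: float
    pct_cnv: float
    pct_total_diagnosed: float
    mode_breakdown: dict[str, float]
    pct_inherited: float


@dataclass
class CarrierEstimate:
    """Aggregated pathogenic allele frequency and carrier probability for one gene."""

    gene: str
    q: float
    carrier_freq: float
    n_contributing_variants: int
    per_source: dict[str, float] = field(default_factory=dict)


def variants_to_frame(variants: Iterable[VariantRecord]) -> pd.DataFrame:
    """Flatten variant records into a tidy table (one row per variant)."""
    rows = []
    for v in variants:
        row = {
            "variant_id": v.variant_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "consequence": v.consequence,
            "cadd": v.cadd,
            "sift": v.sift,
            "phylop": v.phylop,
            "aa_conservation": v.aa_conservation,
            "known_pathogenic": v.known_pathogenic,
        }
        for src, af in v.source_afs.items():
            row[f"het_af_{src}"] = af.het_af
            row[f"hom_count_{src}"] = af.hom_count
            row[f"hemi_count_{src}"] = af.hemi_count
        rows.append(row)
    return pd.DataFrame(rows)


def genes_to_frame(genes: Iterable[GeneAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "symbol": g.symbol,
                "chrom": g.chrom,
                "disease_mode": g.disease_mode,
                "pli": g.pli,
                "oe": g.oe,
            }
            for g in genes
        ]
    )


__all__ = [
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "HEMI_REF",
    "HEMI_ALT",
    "MISSING",
    "DIPLOID_GTS",
    "HAPLOID_GTS",
    "ALL_GTS",
    "MODES",
    "MODE_CATEGORIES",
    "CONSEQUENCES",
    "X_CHROM",
    "is_x",
    "carries_alt",
    "ConfigurationError",
    "SourceAF",
    "VariantRecord",
    "GeneAnnotation",
    "TrioGenotypeRecord",
    "DiagnosisCall",
    "CohortSummary",
    "CarrierEstimate",
    "variants_to_frame",
    "genes_to_frame",
    "replace",
]
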