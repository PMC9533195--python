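"""Synthetic trio-exome cohort generator with ground truth.

Emulates the statistical structure of a large neurodevelopmental-disorder
(NDD) trio-WES study: a cohort of proband-father-mother trios with a
configurable diagnostic yield split into de novo, recessive (compound
heterozygous + homozygous), X-linked hemizygous and inherited-dominant causal
variants; benign background variation drawn from a shared population pool
under Hardy-Weinberg; mode-conditional constraint (pLI, O/E), expression and
protein-interaction contrasts between dominant and recessive disease genes;
rare-allele population frequency spectra in two reference sources; and
capture-interval coverage with embedded multi-interval CNVs.

Every generator operation is a pure function of the configuration: the seed
fully determines all outputs, and each operation draws from its own seed
stream so results do not depend on call order.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .records import (
    HET,
    HEMI_ALT,
    HEMI_REF,
    HOM_ALT,
    HOM_REF,
    ConfigurationError,
    GeneAnnotation,
    SourceAF,
    TrioGenotypeRecord,
    VariantRecord,
    is_x,
)

PPI_TISSUES = ("brain", "heart", "kidney", "liver", "lung", "muscle", "thymus")

# seed-stream offsets, one per generator operation
_STREAM_PANEL = 1
_STREAM_AFS = 2
_STREAM_COHORT = 3
_STREAM_COVERAGE = 4
_STREAM_EXPR_PPI = 5

_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


def _check_simplex(name: str, mapping: dict[str, float]) -> None:
    total = sum(mapping.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} must sum to 1, got {total}")
    for key, val in mapping.items():
        if not 0.0 <= val <= 1.0:
            raise ConfigurationError(f"{name}[{key}] out of [0,1]: {val}")


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic NDD trio cohort.

    Defaults reproduce the headline structure of a 1,180-trio cohort with a
    50.8% diagnostic yield (41.9% known variants + 4.7% phenotype expansion
    + 4.2% CNV) whose diagnosed patients split 62.9% de novo, 24.7%
    recessive, 8.7% hemizygous and 3.7% other/inherited-dominant.
    """

    n_genes: int = 284
    mode_proportions: dict[str, float] = field(
        default_factory=lambda: {"AD": 0.57, "AR": 0.33, "XL": 0.10}
    )
    # Beta(a, b) parameters for pLI per mode: dominant genes pile up near 1,
    # recessive genes near 0, X-linked genes closer to the dominant pattern.
    pli_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"AD": (9.0, 1.0), "AR": (1.0, 9.0), "XL": (6.0, 2.0)}
    )
    # O/E constraint ratio ~ oe_scale * Beta(a, b); constrained genes are low.
    oe_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"AD": (2.0, 8.0), "AR": (5.0, 3.0), "XL": (2.5, 6.0)}
    )
    oe_scale: float = 1.5
    new_gene_fraction: float = 0.03  # genes absent from the "old" OMIM snapshot

    n_trios: int = 1180
    diagnostic_yield: float = 0.508
    diagnosis_route_mix: dict[str, float] = field(
        default_factory=lambda: {
            "known_variant": 41.9 / 50.8,
            "phenotype_expansion": 4.7 / 50.8,
            "cnv": 4.2 / 50.8,
        }
    )
    causal_mode_mix: dict[str, float] = field(
        default_factory=lambda: {
            "de_novo": 0.629,
            "comp_het": 0.148,
            "homozygous": 0.099,
            "hemizygous": 0.087,
            "inherited_dominant": 0.037,
        }
    )
    # fraction of SNV-diagnosed trios the "initial" pipeline pass misses,
    # and why (re-analysis taxonomy)
    initially_missed_fraction: float = 0.112
    missed_reason_mix: dict[str, float] = field(
        default_factory=lambda: {
            "new_omim": 8 / 33,
            "low_coverage": 5 / 33,
            "synonymous": 1 / 33,
            "phenotype_reevaluation": 8 / 33,
            "other": 11 / 33,
        }
    )

    background_variants_per_trio: int = 50
    background_pool_size: int = 3000
    de_novo_background_per_trio: int = 1
    # population AF spectrum of benign background alleles: mixture of common
    # (Uniform) and rare (log-uniform) sites
    background_common_fraction: float = 0.8
    background_common_af: tuple[float, float] = (0.01, 0.5)
    background_rare_af: tuple[float, float] = (1e-5, 1e-3)

    pathogenic_af_distribution: tuple[str, dict[str, float]] = field(
        default_factory=lambda: ("log_uniform", {"low": 1e-5, "high": 5e-4})
    )
    alleles_per_recessive_gene: tuple[int, int] = (1, 3)
    af_sources: tuple[str, ...] = ("gnomad_eas", "kova")
    af_aggregation: str = "max"
    novel_recessive_allele_fraction: float = 0.3
    causal_consequence_mix: dict[str, float] = field(
        default_factory=lambda: {"LoF": 0.50, "missense": 0.42, "splice": 0.08}
    )
    # mode-conditional functional-score laws for pathogenic variants
    cadd_normal: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"AD": (26.5, 6.0), "AR": (25.0, 6.0), "XL": (26.0, 6.0)}
    )
    sift_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"AD": (0.4, 6.0), "AR": (0.8, 5.0), "XL": (0.5, 6.0)}
    )
    phylop_normal: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"AD": (7.0, 2.0), "AR": (5.5, 2.0), "XL": (6.5, 2.0)}
    )
    aa_conservation_p: dict[str, float] = field(
        default_factory=lambda: {"AD": 0.05, "AR": 0.15, "XL": 0.08}
    )

    # coverage model
    n_intervals: int = 2000
    interval_length: int = 150
    mean_depth: float = 100.0
    depth_dispersion: float | None = 400.0  # negative-binomial size r; None = noiseless
    sample_scale_jitter: float = 0.15  # per-sample library-size factor U(1-j, 1+j)
    interval_log_sd: float = 0.3  # capture-efficiency spread across intervals
    cnv_n_intervals: int = 5
    cnv_state_mix: dict[str, float] = field(
        default_factory=lambda: {"het_del": 0.6, "dup": 0.3, "hom_del": 0.1}
    )

    # expression model: per-gene baseline TPM ~ LogNormal, brain samples of a
    # mode multiplied by its contrast factor
    n_brain_samples: int = 10
    n_body_samples: int = 20
    tpm_log_mean: float = float(np.log(10.0))
    tpm_log_sd: float = 1.2
    tpm_sample_log_sd: float = 0.4
    expression_contrast: dict[str, float] = field(
        default_factory=lambda: {"AD": 3.0, "AR": 1.0, "XL": 2.5}
    )

    # PPI model per mode: probability of >=1 brain interaction, mean brain
    # degree given positive, probability a brain-positive gene interacts in
    # all seven tissues, and the fallback per-tissue probability / mean degree
    ppi_degree_params: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "AD": {
                "p_positive": 0.362,
                "mean_degree": 7.2,
                "p_all_tissues": 0.10,
                "p_other_tissue": 0.15,
                "other_mean_degree": 2.0,
            },
            "AR": {
                "p_positive": 0.222,
                "mean_degree": 4.5,
                "p_all_tissues": 0.538,
                "p_other_tissue": 0.40,
                "other_mean_degree": 3.0,
            },
            "XL": {
                "p_positive": 0.30,
                "mean_degree": 6.5,
                "p_all_tissues": 0.20,
                "p_other_tissue": 0.20,
                "other_mean_degree": 2.0,
            },
        }
    )
    ppi_partner_pool: int = 2000

    genotype_error_rate: float = 0.0
    male_x_diploid_vcf: bool = False  # emit male chrX alt as 1/1 instead of haploid 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_trios < 0:
            raise ConfigurationError("n_genes must be >= 1 and n_trios >= 0")
        _check_simplex("mode_proportions", self.mode_proportions)
        _check_simplex("causal_mode_mix", self.causal_mode_mix)
        _check_simplex("diagnosis_route_mix", self.diagnosis_route_mix)
        _check_simplex("missed_reason_mix", self.missed_reason_mix)
        _check_simplex("causal_consequence_mix", self.causal_consequence_mix)
        _check_simplex("cnv_state_mix", self.cnv_state_mix)
        for name, val in [
            ("diagnostic_yield", self.diagnostic_yield),
            ("initially_missed_fraction", self.initially_missed_fraction),
            ("novel_recessive_allele_fraction", self.novel_recessive_allele_fraction),
            ("genotype_error_rate", self.genotype_error_rate),
        ]:
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name} out of [0,1]: {val}")
        lo, hi = self.alleles_per_recessive_gene
        if not (1 <= lo <= hi):
            raise ConfigurationError("alleles_per_recessive_gene must satisfy 1 <= lo <= hi")
        # mode mix must be realizable by the gene panel mixture
        need_ar = self.causal_mode_mix.get("comp_het", 0) + self.causal_mode_mix.get("homozygous", 0)
        need_xl = self.causal_mode_mix.get("hemizygous", 0)
        need_ad = self.causal_mode_mix.get("de_novo", 0) + self.causal_mode_mix.get(
            "inherited_dominant", 0
        )
        snv_any = self.diagnostic_yield * (1 - self.diagnosis_route_mix.get("cnv", 0)) > 0
        if snv_any and self.n_trios > 0:
            if need_ar > 0 and self.mode_proportions.get("AR", 0) == 0:
                raise ConfigurationError("recessive causal fraction > 0 but no AR genes")
            if need_xl > 0 and self.mode_proportions.get("XL", 0) == 0:
                raise ConfigurationError("hemizygous causal fraction > 0 but no XL genes")
            if need_ad > 0 and self.mode_proportions.get("AD", 0) == 0:
                raise ConfigurationError("dominant causal fraction > 0 but no AD genes")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Bookkeeping of everything the generator embedded.

    ``genes``: symbol, chrom, disease_mode, pli, oe, in_old_db, true_q.
    ``trios``: trio_id, proband_sex, diagnosed, diagnosis_route, causal_gene,
    causal_mode, causal_variant_ids (';'-joined), initially_missed,
    missed_reason.
    ``cnvs``: trio_id, chrom, start, end, first_interval, last_interval, state.
    """

    genes: pd.DataFrame
    trios: pd.DataFrame = field(default_factory=pd.DataFrame)
    cnvs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": self.genes.to_dict(orient="records"),
            "trios": self.trios.to_dict(orient="records"),
            "cnvs": self.cnvs.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            genes=pd.DataFrame(payload["genes"]),
            trios=pd.DataFrame(payload["trios"]),
            cnvs=pd.DataFrame(payload["cnvs"]),
        )


@dataclass
class ExpressionData:
    """TPM matrix (genes x samples) with per-sample tissue metadata."""

    tpm: pd.DataFrame
    samples: pd.DataFrame  # sample_id, tissue, is_brain, period


@dataclass
class CohortData:
    """Everything one simulated cohort comprises."""

    records: list[TrioGenotypeRecord]
    sample_sheet: pd.DataFrame
    truth: GroundTruth


def _choice(rng: np.random.Generator, mapping: dict[str, float]) -> str:
    keys = list(mapping)
    probs = np.asarray([mapping[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


# ---------------------------------------------------------------------------
# gene panel


def generate_gene_panel(config: SimulationConfig) -> tuple[list[GeneAnnotation], GroundTruth]:
    """Draw a disease-gene panel with mode-conditional constraint scores.

    Dominant genes receive pLI from a Beta law concentrated near 1 and O/E
    near 0; recessive genes the opposite; X-linked genes sit between, closer
    to the dominant pattern. Gene order and all scores are a deterministic
    function of the seed.
    """
    config.validate()
    rng = config.rng(_STREAM_PANEL)
    modes = list(config.mode_proportions)
    probs = np.asarray([config.mode_proportions[m] for m in modes], dtype=float)
    assignments = rng.choice(len(modes), size=config.n_genes, p=probs / probs.sum())

    panel: list[GeneAnnotation] = []
    rows = []
    autosome_cycle = 0
    for i, mi in enumerate(assignments):
        mode = modes[mi]
        symbol = f"G{i:04d}"
        if mode == "XL":
            chrom = "chrX"
        else:
            chrom = _AUTOSOMES[autosome_cycle % len(_AUTOSOMES)]
            autosome_cycle += 1
        a, b = config.pli_beta[mode]
        pli = float(rng.beta(a, b))
        a, b = config.oe_beta[mode]
        oe = float(config.oe_scale * rng.beta(a, b))
        panel.append(GeneAnnotation(symbol, chrom, mode, pli, oe))
        rows.append(
            {"symbol": symbol, "chrom": chrom, "disease_mode": mode, "pli": pli, "oe": oe}
        )
    genes = pd.DataFrame(rows)

    # flag "new" genes (absent from the old database snapshot), a few per mode
    genes["in_old_db"] = True
    for mode in modes:
        idx = genes.index[genes.disease_mode == mode]
        if len(idx) == 0:
            continue
        n_new = max(1, int(round(config.new_gene_fraction * len(idx))))
        chosen = rng.choice(idx, size=min(n_new, len(idx)), replace=False)
        genes.loc[chosen, "in_old_db"] = False
    genes["true_q"] = 0.0
    return panel, GroundTruth(genes=genes)


# ---------------------------------------------------------------------------
# population allele frequencies


def _gene_start(symbol: str) -> int:
    return (int(symbol[1:]) + 1) * 1_000_000


def _draw_af(rng: np.random.Generator, law: tuple[str, dict[str, float]], size: int) -> np.ndarray:
    name, params = law
    if name == "log_uniform":
        lo, hi = params["low"], params["high"]
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))
    if name == "point_mass":
        return np.full(size, params["value"], dtype=float)
    if name == "uniform":
        return rng.uniform(params["low"], params["high"], size=size)
    raise ConfigurationError(f"unknown AF distribution {name!r}")


def aggregate_sources(afs: dict[str, float], rule: str = "max") -> float:
    """Combine one variant's per-source allele frequencies into a single AF."""
    vals = list(afs.values())
    if not vals:
        return 0.0
    if rule == "max":
        return float(max(vals))
    if rule == "mean":
        return float(np.mean(vals))
    if rule == "sum":
        return float(min(1.0, sum(vals)))
    raise ConfigurationError(f"unknown aggregation rule {rule!r}")


def _draw_scores(config: SimulationConfig, mode: str, rng: np.random.Generator) -> dict:
    mu, sd = config.cadd_normal[mode]
    cadd = float(np.clip(rng.normal(mu, sd), 0.1, 99.0))
    a, b = config.sift_beta[mode]
    sift = float(rng.beta(a, b))
    mu, sd = config.phylop_normal[mode]
    phylop = float(rng.normal(mu, sd))
    aa = int(rng.binomial(99, config.aa_conservation_p[mode]))
    return {"cadd": cadd, "sift": sift, "phylop": phylop, "aa_conservation": aa}


def generate_population_afs(
    panel: list[GeneAnnotation],
    truth: GroundTruth,
    config: SimulationConfig,
) -> list[VariantRecord]:
    """Create each gene's pathogenic allelic series with population AFs.

    Recessive (AR) and X-linked genes receive 1-k pathogenic alleles whose
    per-source heterozygous frequencies follow the configured rare-allele
    law and whose homozygous/hemizygous counts are zero in every source.
    Dominant pathogenic alleles have frequency 0 everywhere (never observed
    heterozygous in healthy references). The aggregated per-gene frequency
    ``true_q`` (combine-over-sources, sum-over-alleles) is recorded in the
    ground truth.
    """
    if not panel:
        raise ConfigurationError("empty gene panel")
    rng = config.rng(_STREAM_AFS)
    lo, hi = config.alleles_per_recessive_gene
    variants: list[VariantRecord] = []
    q_by_gene: dict[str, float] = {}
    for gene in panel:
        start = _gene_start(gene.symbol)
        if gene.disease_mode == "AD":
            n_alleles = 2
        else:
            n_alleles = int(rng.integers(lo, hi + 1))
        q = 0.0
        for k in range(n_alleles):
            if gene.disease_mode == "AD":
                source_afs = {s: SourceAF(0.0, 0, 0) for s in config.af_sources}
            else:
                draws = {
                    s: float(_draw_af(rng, config.pathogenic_af_distribution, 1)[0])
                    for s in config.af_sources
                }
                source_afs = {s: SourceAF(af, 0, 0) for s, af in draws.items()}
                q += aggregate_sources(draws, config.af_aggregation)
            cons = _choice(rng, config.causal_consequence_mix)
            scores = _draw_scores(config, gene.disease_mode, rng)
            variants.append(
                VariantRecord(
                    variant_id=f"{gene.symbol}_p{k}",
                    chrom=gene.chrom,
                    pos=start + 100 * (k + 1),
                    ref="A",
                    alt="G",
                    gene=gene.symbol,
                    consequence=cons,
                    source_afs=source_afs,
                    known_pathogenic=True,
                    **scores,
                )
            )
        q_by_gene[gene.symbol] = q
    truth.genes["true_q"] = truth.genes["symbol"].map(q_by_gene).fillna(0.0)
    return variants


# ---------------------------------------------------------------------------
# capture intervals (shared by the trio cohort, which places CNVs on them,
# and by the coverage generator)


def generate_capture_intervals(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic exome-like capture intervals (BED convention, 0-based)."""
    base, rem = divmod(config.n_intervals, len(_AUTOSOMES))
    rows = []
    idx = 0
    for ci, chrom in enumerate(_AUTOSOMES):
        n_here = base + (1 if ci < rem else 0)
        for k in range(n_here):
            start = 10_000 + k * 2_000
            rows.append(
                {
                    "interval_id": idx,
                    "chrom": chrom,
                    "start": start,
                    "end": start + config.interval_length,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trio cohort


class _PositionAllocator:
    """Unique positions within each gene's 1 Mb territory."""

    def __init__(self) -> None:
        self._next: dict[str, int] = defaultdict(lambda: 500)

    def take(self, gene_symbol: str) -> int:
        off = self._next[gene_symbol]
        self._next[gene_symbol] += 1
        return _gene_start(gene_symbol) + 1000 + off


def _nb_depth(rng: np.random.Generator, mean: float, r: float | None, size: int) -> np.ndarray:
    if r is None:
        return np.full(size, mean)
    lam = rng.gamma(r, mean / r, size=size)
    return rng.poisson(lam).astype(float)


def _depths(rng: np.random.Generator, config: SimulationConfig) -> dict[str, int]:
    d = _nb_depth(rng, config.mean_depth, config.depth_dispersion, 3)
    d = np.maximum(d, 1).astype(int)
    return {"proband": int(d[0]), "father": int(d[1]), "mother": int(d[2])}


def _background_pool(
    panel: list[GeneAnnotation], config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[VariantRecord], np.ndarray]:
    """Shared pool of benign autosomal sites with population AFs."""
    autosomal = [g for g in panel if not is_x(g.chrom)]
    alloc = _PositionAllocator()
    n = config.background_pool_size
    common = rng.random(n) < config.background_common_fraction
    afs = np.where(
        common,
        rng.uniform(*config.background_common_af, size=n),
        np.exp(rng.uniform(*np.log(config.background_rare_af), size=n)),
    )
    pool: list[VariantRecord] = []
    for i in range(n):
        gene = autosomal[int(rng.integers(len(autosomal)))]
        # per-source AFs jitter around the true population frequency
        src = {
            s: SourceAF(float(np.clip(afs[i] * rng.uniform(0.7, 1.3), 0.0, 1.0)),
                        int(afs[i] > 0.05), 0)
            for s in config.af_sources
        }
        pool.append(
            VariantRecord(
                variant_id=f"B{i:05d}",
                chrom=gene.chrom,
                pos=alloc.take(gene.symbol),
                ref="C",
                alt="T",
                gene=gene.symbol,
                consequence="other",
                cadd=float(np.clip(rng.normal(8, 5), 0.1, 60)),
                sift=float(rng.beta(3, 1.5)),
                phylop=float(rng.normal(0.5, 1.5)),
                aa_conservation=int(rng.binomial(99, 0.5)),
                source_afs=src,
                known_pathogenic=False,
            )
        )
    return pool, afs


def _transmit(rng: np.random.Generator, parent_gt: str) -> int:
    """Number of alt alleles (0/1) transmitted by a diploid parent."""
    if parent_gt == HOM_ALT:
        return 1
    if parent_gt == HET:
        return int(rng.integers(2))
    return 0


_GT_FROM_COUNT = {0: HOM_REF, 1: HET, 2: HOM_ALT}


def generate_trio_cohort(
    panel: list[GeneAnnotation],
    variants: list[VariantRecord],
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> CohortData:
    """Simulate the trio cohort: causal genotypes, background, ground truth.

    Each trio is independently diagnosed with probability
    ``diagnostic_yield``; diagnosed trios are routed to a known SNV, a
    phenotype-expansion SNV or a CNV, and SNV trios draw a causal mode from
    ``causal_mode_mix``. The constructed genotypes realize each mode:

    * de novo - proband het, both parents hom-ref;
    * comp het - two alleles of one AR gene, one inherited from each parent;
    * homozygous - both parents het carriers, proband hom-alt;
    * hemizygous - male proband alt on chrX, mother het carrier;
    * inherited dominant - proband het, one parent het.

    A configurable fraction of recessive/X-linked patient alleles are novel
    (absent from the population references). Background benign variants are
    drawn per trio from a shared Hardy-Weinberg pool, plus a small number of
    de novo benign sites.
    """
    config.validate()
    if truth is None:
        panel2, truth = generate_gene_panel(config)
    rng = config.rng(_STREAM_COHORT)
    genes_by_mode: dict[str, list[GeneAnnotation]] = defaultdict(list)
    for g in panel:
        genes_by_mode[g.disease_mode].append(g)
    new_genes = set(truth.genes.loc[~truth.genes.in_old_db, "symbol"])
    alleles_by_gene: dict[str, list[VariantRecord]] = defaultdict(list)
    for v in variants:
        if v.known_pathogenic:
            alleles_by_gene[v.gene].append(v)

    pool, pool_afs = _background_pool(panel, config, rng)
    alloc = _PositionAllocator()
    novel_counter = [0]
    intervals = generate_capture_intervals(config)
    iv_by_chrom = {c: sub.reset_index(drop=True) for c, sub in intervals.groupby("chrom")}

    def novel_allele(gene: GeneAnnotation, consequence: str | None = None) -> VariantRecord:
        novel_counter[0] += 1
        cons = consequence or _choice(rng, config.causal_consequence_mix)
        scores = _draw_scores(config, gene.disease_mode, rng)
        return VariantRecord(
            variant_id=f"{gene.symbol}_nov{novel_counter[0]}",
            chrom=gene.chrom,
            pos=alloc.take(gene.symbol),
            ref="G",
            alt="A",
            gene=gene.symbol,
            consequence=cons,
            source_afs={s: SourceAF(0.0, 0, 0) for s in config.af_sources},
            known_pathogenic=True,
            **scores,
        )

    def pick_gene(mode: str, prefer_new: bool) -> GeneAnnotation:
        # new-database-entry cases draw from genes absent from the old
        # snapshot; everyone else from genes already known to it, so the
        # re-analysis taxonomy stays faithful to the embedded labels
        cands = genes_by_mode[mode]
        subset = [g for g in cands if (g.symbol in new_genes) == prefer_new]
        if subset:
            cands = subset
        return cands[int(rng.integers(len(cands)))]

    def maybe_novel(gene: GeneAnnotation, force_syn: bool) -> VariantRecord:
        if force_syn or rng.random() < config.novel_recessive_allele_fraction:
            return novel_allele(gene, "synonymous" if force_syn else None)
        series = alleles_by_gene[gene.symbol]
        return series[int(rng.integers(len(series)))]

    records: list[TrioGenotypeRecord] = []
    trio_rows = []
    cnv_rows = []
    for t in range(config.n_trios):
        trio_id = f"T{t:04d}"
        diagnosed = bool(rng.random() < config.diagnostic_yield)
        route = _choice(rng, config.diagnosis_route_mix) if diagnosed else ""
        mode = ""
        missed = False
        reason = ""
        if diagnosed and route != "cnv":
            mode = _choice(rng, config.causal_mode_mix)
            if rng.random() < config.initially_missed_fraction:
                missed = True
                reason = _choice(rng, config.missed_reason_mix)
        sex = "male" if mode == "hemizygous" else ("male" if rng.random() < 0.5 else "female")

        causal_gene = ""
        causal_ids: list[str] = []
        trio_records: list[TrioGenotypeRecord] = []

        if diagnosed and route == "cnv":
            state = _choice(rng, config.cnv_state_mix)
            chrom = _AUTOSOMES[int(rng.integers(len(_AUTOSOMES)))]
            sub = iv_by_chrom[chrom]
            span = min(config.cnv_n_intervals, len(sub))
            first = int(rng.integers(0, len(sub) - span + 1))
            cnv_rows.append(
                {
                    "trio_id": trio_id,
                    "chrom": chrom,
                    "start": int(sub.start.iloc[first]),
                    "end": int(sub.end.iloc[first + span - 1]),
                    "first_interval": int(sub.interval_id.iloc[first]),
                    "last_interval": int(sub.interval_id.iloc[first + span - 1]),
                    "state": state,
                }
            )
            mode = "cnv"
        elif diagnosed:
            force_syn = reason == "synonymous"
            if mode == "de_novo":
                gene = pick_gene("AD", reason == "new_omim")
                var = maybe_novel(gene, force_syn) if force_syn else (
                    alleles_by_gene[gene.symbol][int(rng.integers(len(alleles_by_gene[gene.symbol])))]
                )
                trio_records.append(
                    TrioGenotypeRecord(var, trio_id, HET, HOM_REF, HOM_REF,
                                       _depths(rng, config), sex)
                )
            elif mode == "inherited_dominant":
                gene = pick_gene("AD", reason == "new_omim")
                series = alleles_by_gene[gene.symbol]
                var = novel_allele(gene, "synonymous") if force_syn else series[
                    int(rng.integers(len(series)))
                ]
                paternal = rng.random() < 0.5
                trio_records.append(
                    TrioGenotypeRecord(
                        var, trio_id, HET,
                        HET if paternal else HOM_REF,
                        HOM_REF if paternal else HET,
                        _depths(rng, config), sex,
                    )
                )
            elif mode == "comp_het":
                gene = pick_gene("AR", reason == "new_omim")
                v1 = maybe_novel(gene, force_syn)
                v2 = maybe_novel(gene, False)
                while v2.variant_id == v1.variant_id:
                    v2 = novel_allele(gene)
                trio_records.append(
                    TrioGenotypeRecord(v1, trio_id, HET, HET, HOM_REF, _depths(rng, config), sex)
                )
                trio_records.append(
                    TrioGenotypeRecord(v2, trio_id, HET, HOM_REF, HET, _depths(rng, config), sex)
                )
            elif mode == "homozygous":
                gene = pick_gene("AR", reason == "new_omim")
                series = alleles_by_gene[gene.symbol]
                var = novel_allele(gene, "synonymous") if force_syn else series[
                    int(rng.integers(len(series)))
                ]
                trio_records.append(
                    TrioGenotypeRecord(var, trio_id, HOM_ALT, HET, HET, _depths(rng, config), sex)
                )
            elif mode == "hemizygous":
                gene = pick_gene("XL", reason == "new_omim")
                var = maybe_novel(gene, force_syn)
                trio_records.append(
                    TrioGenotypeRecord(var, trio_id, HEMI_ALT, HEMI_REF, HET,
                                       _depths(rng, config), "male")
                )
            else:  # pragma: no cover - guarded by validate()
                raise ConfigurationError(f"unknown causal mode {mode!r}")
            causal_gene = gene.symbol
            causal_ids = [r.variant.variant_id for r in trio_records]
            if missed and reason == "low_coverage":
                # first causal site under-covered in the proband
                r0 = trio_records[0]
                depths = dict(r0.depths)
                depths["proband"] = int(rng.integers(4, 10))
                trio_records[0] = TrioGenotypeRecord(
                    r0.variant, r0.trio_id, r0.proband_gt, r0.father_gt, r0.mother_gt,
                    depths, r0.proband_sex,
                )

        # background: HWE draws from the shared pool
        nb = min(config.background_variants_per_trio, len(pool))
        if nb > 0:
            idx = rng.choice(len(pool), size=nb, replace=False)
            f_counts = rng.binomial(2, pool_afs[idx])
            m_counts = rng.binomial(2, pool_afs[idx])
            for j, vi in enumerate(idx):
                fgt = _GT_FROM_COUNT[int(f_counts[j])]
                mgt = _GT_FROM_COUNT[int(m_counts[j])]
                pcount = _transmit(rng, fgt) + _transmit(rng, mgt)
                pgt = _GT_FROM_COUNT[pcount]
                if fgt == HOM_REF and mgt == HOM_REF:
                    continue  # site not variant in this family
                trio_records.append(
                    TrioGenotypeRecord(pool[int(vi)], trio_id, pgt, fgt, mgt,
                                       _depths(rng, config), sex)
                )
        for _ in range(config.de_novo_background_per_trio):
            gene = panel[int(rng.integers(len(panel)))]
            while is_x(gene.chrom):
                gene = panel[int(rng.integers(len(panel)))]
            novel_counter[0] += 1
            bvar = VariantRecord(
                variant_id=f"D{trio_id}_{novel_counter[0]}",
                chrom=gene.chrom,
                pos=alloc.take(gene.symbol),
                ref="T",
                alt="C",
                gene=gene.symbol,
                consequence="other",
                cadd=float(np.clip(rng.normal(10, 6), 0.1, 60)),
                sift=float(rng.beta(2, 2)),
                phylop=float(rng.normal(1.0, 1.5)),
                aa_conservation=int(rng.binomial(99, 0.4)),
                source_afs={s: SourceAF(0.0, 0, 0) for s in config.af_sources},
                known_pathogenic=False,
            )
            trio_records.append(
                TrioGenotypeRecord(bvar, trio_id, HET, HOM_REF, HOM_REF,
                                   _depths(rng, config), sex)
            )

        if config.genotype_error_rate > 0:
            trio_records = [
                _maybe_flip(rng, r, config.genotype_error_rate) for r in trio_records
            ]

        records.extend(trio_records)
        trio_rows.append(
            {
                "trio_id": trio_id,
                "proband_sex": sex,
                "diagnosed": diagnosed,
                "diagnosis_route": route,
                "causal_gene": causal_gene,
                "causal_mode": mode,
                "causal_variant_ids": ";".join(causal_ids),
                "initially_missed": missed,
                "missed_reason": reason,
            }
        )

    truth.trios = pd.DataFrame(trio_rows)
    truth.cnvs = pd.DataFrame(
        cnv_rows,
        columns=["trio_id", "chrom", "start", "end", "first_interval", "last_interval", "state"],
    )
    sheet = pd.DataFrame(
        {
            "trio_id": truth.trios.trio_id,
            "proband_id": truth.trios.trio_id + "_P",
            "father_id": truth.trios.trio_id + "_F",
            "mother_id": truth.trios.trio_id + "_M",
            "proband_sex": truth.trios.proband_sex,
        }
    )
    return CohortData(records=records, sample_sheet=sheet, truth=truth)


def _maybe_flip(
    rng: np.random.Generator, rec: TrioGenotypeRecord, rate: float
) -> TrioGenotypeRecord:
    if rng.random() >= rate:
        return rec
    on_x_male = is_x(rec.variant.chrom) and rec.proband_sex == "male"
    options = [g for g in ((HEMI_REF, HEMI_ALT) if on_x_male else (HOM_REF, HET, HOM_ALT))
               if g != rec.proband_gt]
    new_gt = options[int(rng.integers(len(options)))]
    return TrioGenotypeRecord(
        rec.variant, rec.trio_id, new_gt, rec.father_gt, rec.mother_gt, rec.depths,
        rec.proband_sex,
    )


# ---------------------------------------------------------------------------
# coverage


_COPY_FACTOR = {"het_del": 0.5, "hom_del": 0.0, "dup": 1.5}


def generate_coverage(
    intervals: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    cnvs: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Per-interval per-sample mean coverage depth.

    Depth for interval *j* in sample *s* is negative-binomial (Gamma-Poisson)
    around ``mean_depth * sample_scale[s] * interval_efficiency[j]``, with
    the proband's mean multiplied by 0.5 / 0 / 1.5 on intervals inside an
    embedded het-deletion / hom-deletion / duplication. With
    ``depth_dispersion=None`` the exact mean is returned (noiseless mode).

    Returns a DataFrame indexed like ``intervals`` with one column per sample.
    """
    rng = config.rng(_STREAM_COVERAGE)
    samples: list[str] = []
    for _, row in sample_sheet.iterrows():
        samples.extend([row.proband_id, row.father_id, row.mother_id])
    n_iv, n_s = len(intervals), len(samples)
    if config.sample_scale_jitter > 0:
        scale = rng.uniform(1 - config.sample_scale_jitter, 1 + config.sample_scale_jitter, n_s)
    else:
        scale = np.ones(n_s)
    if config.interval_log_sd > 0:
        eff = np.exp(rng.normal(0.0, config.interval_log_sd, n_iv))
    else:
        eff = np.ones(n_iv)
    mean = config.mean_depth * np.outer(eff, scale)

    col = {s: i for i, s in enumerate(samples)}
    proband_of = dict(zip(sample_sheet.trio_id, sample_sheet.proband_id))
    for _, cnv in cnvs.iterrows():
        pid = proband_of.get(cnv.trio_id)
        if pid is None or pid not in col:
            continue
        mask = (intervals.interval_id >= cnv.first_interval) & (
            intervals.interval_id <= cnv.last_interval
        )
        mean[mask.to_numpy(), col[pid]] *= _COPY_FACTOR[str(cnv.state)]

    if config.depth_dispersion is None:
        depth = mean
    else:
        r = float(config.depth_dispersion)
        lam = np.where(mean > 0, rng.gamma(r, np.maximum(mean, 1e-12) / r), 0.0)
        depth = rng.poisson(lam).astype(float)
    return pd.DataFrame(depth, index=intervals.index, columns=samples)


# ---------------------------------------------------------------------------
# expression + PPI


def generate_expression_ppi(
    panel: list[GeneAnnotation],
    config: SimulationConfig,
) -> tuple[ExpressionData, pd.DataFrame]:
    """Mode-contrasted TPM matrix and tissue-tagged PPI edge list.

    Brain samples of a gene are multiplied by its mode's
    ``expression_contrast`` factor (dominant genes brain-enriched). Each gene
    draws a brain interaction degree and a tissue breadth from its mode's
    ``ppi_degree_params``: dominant genes concentrate interactions in brain
    while recessive genes spread interactions across all seven tissues.
    """
    if not panel:
        raise ConfigurationError("empty gene panel")
    rng = config.rng(_STREAM_EXPR_PPI)

    body_tissues = ("heart", "kidney", "liver", "lung", "muscle", "thymus", "skin", "blood")
    sample_rows = []
    for i in range(config.n_brain_samples):
        sample_rows.append(
            {
                "sample_id": f"BR{i:02d}",
                "tissue": "brain",
                "is_brain": True,
                "period": "prenatal" if i < config.n_brain_samples // 2 else "postnatal",
            }
        )
    for i in range(config.n_body_samples):
        sample_rows.append(
            {
                "sample_id": f"BD{i:02d}",
                "tissue": body_tissues[i % len(body_tissues)],
                "is_brain": False,
                "period": "",
            }
        )
    samples = pd.DataFrame(sample_rows)

    n_g, n_s = len(panel), len(samples)
    base = np.exp(rng.normal(config.tpm_log_mean, config.tpm_log_sd, n_g))
    noise = np.exp(rng.normal(0.0, config.tpm_sample_log_sd, (n_g, n_s)))
    tpm = base[:, None] * noise
    brain_mask = samples.is_brain.to_numpy()
    mult = np.asarray([config.expression_contrast[g.disease_mode] for g in panel])
    tpm[:, brain_mask] *= mult[:, None]
    expr = pd.DataFrame(tpm, index=[g.symbol for g in panel], columns=samples.sample_id)

    partners = [f"P{i:04d}" for i in range(config.ppi_partner_pool)]
    edge_rows = []
    for gi, gene in enumerate(panel):
        p = config.ppi_degree_params[gene.disease_mode]
        if rng.random() >= p["p_positive"]:
            continue
        deg = 1 + int(rng.poisson(max(p["mean_degree"] - 1.0, 0.0)))
        chosen = rng.choice(config.ppi_partner_pool, size=min(deg, config.ppi_partner_pool),
                            replace=False)
        for c in chosen:
            edge_rows.append({"gene_a": gene.symbol, "gene_b": partners[int(c)], "tissue": "brain"})
        other = [t for t in PPI_TISSUES if t != "brain"]
        if rng.random() < p["p_all_tissues"]:
            active = other
        else:
            active = [t for t in other if rng.random() < p["p_other_tissue"]]
        for t in active:
            deg_t = 1 + int(rng.poisson(max(p["other_mean_degree"] - 1.0, 0.0)))
            chosen = rng.choice(config.ppi_partner_pool, size=min(deg_t, config.ppi_partner_pool),
                                replace=False)
            for c in chosen:
                edge_rows.append({"gene_a": gene.symbol, "gene_b": partners[int(c)], "tissue": t})
    edges = pd.DataFrame(edge_rows, columns=["gene_a", "gene_b", "tissue"]).drop_duplicates()
    return ExpressionData(tpm=expr, samples=samples), edges


# ---------------------------------------------------------------------------
# one-call convenience


@dataclass
class SimulatedStudy:
    """A full simulated study: all inputs the analysis pipeline consumes."""

    config: SimulationConfig
    panel: list[GeneAnnotation]
    variants: list[VariantRecord]
    cohort: CohortData
    intervals: pd.DataFrame
    coverage: pd.DataFrame
    expression: ExpressionData
    ppi_edges: pd.DataFrame

    @property
    def truth(self) -> GroundTruth:
        return self.cohort.truth


def simulate_study(config: SimulationConfig, coverage: bool = True) -> SimulatedStudy:
    """Run every generator operation under one configuration."""
    panel, truth = generate_gene_panel(config)
    variants = generate_population_afs(panel, truth, config)
    cohort = generate_trio_cohort(panel, variants, config, truth)
    intervals = generate_capture_intervals(config)
    cov = (
        generate_coverage(intervals, cohort.sample_sheet, truth.cnvs, config)
        if coverage
        else pd.DataFrame()
    )
    expression, edges = generate_expression_ppi(panel, config)
    return SimulatedStudy(config, panel, variants, cohort, intervals, cov, expression, edges)


def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    import yaml

    Path(path).write_text(yaml.safe_dump(asdict(config)))


def config_from_yaml(path: str | Path) -> SimulationConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    for key in ("alleles_per_recessive_gene", "af_sources", "background_common_af",
                "background_rare_af"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    if "pathogenic_af_distribution" in raw and isinstance(raw["pathogenic_af_distribution"], list):
        name, params = raw["pathogenic_af_distribution"]
        raw["pathogenic_af_distribution"] = (name, params)
    for key in ("pli_beta", "oe_beta", "cadd_normal", "sift_beta", "phylop_normal"):
        if key in raw:
            raw[key] = {m: tuple(v) for m, v in raw[key].items()}
    return SimulationConfig(**raw)
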