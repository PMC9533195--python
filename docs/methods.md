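# Methods

## Scope and model

`triomode` treats a rare-disease trio-exome study as five coupled
computations over genotype, coverage, annotation, expression and
interaction tables:

1. population-frequency filtering of candidate pathogenic variants,
2. inheritance-mode classification from trio genotypes,
3. copy-number detection from capture-interval depth ratios,
4. mode-stratified gene/variant property contrasts, and
5. Hardy-Weinberg carrier-frequency estimation for recessive genes.

All five run against cohorts produced by the synthetic generator, which
embeds known truth for every quantity downstream code estimates. The
pipeline starts at genotype tables: read alignment, variant calling and
annotation are out of scope, as are ontology-enrichment analyses that
require external annotation services.

## Inheritance classification

A site label is a pure function of the three genotypes, the chromosome and
the proband's sex. A proband alt allele absent from both parents is de
novo; otherwise the carrying parent(s) determine the inheritance side. On
chrX a male proband is hemizygous and the father's X is ignored (sons
receive the paternal Y); a hemizygous alt splits into maternal-carrier vs
de novo by the mother's genotype. Combinations that violate Mendelian
transmission (e.g. hom-alt proband with a hom-ref parent, het proband when
both parents must transmit alt) are flagged and left uninformative rather
than guessed. The test suite proves exhaustive agreement with hand-written
truth tables over all genotype combinations for autosomes and chrX, both
sexes.

Compound heterozygotes are phased by parental origin: a pair is in trans
iff one het allele is paternally and the other maternally inherited. Two
same-parent alleles are in cis and never paired. A de novo allele has no
proven phase; pairing it with an inherited allele is off by default and
available behind a flag.

Per-trio mode assignment requires a curated pathogenicity assertion
(a boolean emulating ClinVar/HGMD/OMIM lookup) and an annotated disease
gene. Within an AR gene a homozygous pattern takes precedence over a
coincident trans pair. A pathogenic heterozygote with missing parents is a
"possible de novo" and counts toward the de novo slice of summaries by
default (configurable). A female de novo het on chrX is categorized de novo
het, not hemizygous. An inherited pathogenic heterozygote in a dominant
gene is retained as "unresolved" (inherited dominant) and populates the
residual "other" slice of the mode breakdown. Percentages are computed
unrounded and rounded half-up to one decimal only at report time.

The re-analysis comparison runs the classifier twice: an "initial" pass
restricted to an old gene-database snapshot, with synonymous consequences
excluded, sites below the 10x depth floor dropped, and
phenotype-set-aside trios excluded; and a full pass. Newly diagnosed cases
are attributed in fixed rule order: gene absent from the old snapshot →
new database entry; any causal site under the depth floor → low-coverage
rescue; synonymous consequence → synonymous re-inclusion; trio on the
re-evaluated list → phenotype re-evaluation; otherwise "other".

## Frequency filtering

A candidate passes when its combined heterozygous frequency is strictly
below the threshold (default 0.001) and the mode-specific absence condition
holds: dominant (and X-linked dominant) candidates must have het AF exactly
0 in every source; recessive and X-linked candidates must have zero
homozygous and hemizygous observations. Per-source frequencies are combined
as the maximum over sources — the most conservative choice for retention —
and a variant absent from a source counts as AF 0 there; both choices are
policy fields. Strict `<` was chosen because the filter is described as a
cut *at* 0.001; the comparison is also a policy field.

## CNV detection

Each sample's interval depths are divided by that sample's median depth,
then the proband ratio is the normalized proband depth over the mean of the
two normalized parental depths; intervals with zero parental depth are
masked, and calls are invariant to uniform rescaling of any one sample.
Runs of at least `min_consecutive` (default 3) same-state intervals are
merged into calls: ratio ≤ 0.15 hom-deletion, ≤ 0.7 het-deletion, ≥ 1.25
duplication. The deletion and duplication cutoffs sit near the geometric
midpoints between the neutral ratio 1 and the single-copy ratios 0.5
(√0.5 ≈ 0.71) and 1.5 (√1.5 ≈ 1.22), leaving a symmetric noise margin on
the log scale. No GC correction, breakpoint refinement or allele-balance
evidence is used. Under the default dispersion the caller is sensitive but
not specific (duplications have the smallest log-margin); the low-noise
validation condition (150x mean, negative-binomial size 2000,
capture-efficiency log-sd 0.05) shows recall ≥0.95 with ≲0.005 false calls
per trio on embedded 5-interval events.

## Gene-property statistics

The brain/body ratio is median TPM over brain samples divided by median
over all other samples; it is scale-invariant, and a 0.01-TPM pseudocount
is added to both medians only when the body median is zero so log-scale
plots stay finite. Developmental-period expression is the median over
samples carrying the period label (prenatal/postnatal is an input label on
samples, not computed from age). PPI degree counts distinct partners of a
gene in one tissue over the fixed seven-tissue set {brain, heart, kidney,
liver, lung, muscle, thymus}; breadth counts tissues with at least one
edge (0-7). pLI binning reports per-mode percentages at or below `lo`
("near 0") and at or above `hi` ("near 1"); the boundaries default to
0.1/0.9 as a design choice.

Score comparisons use the two-sided Wilcoxon rank-sum (Mann-Whitney U):
exact null distribution when both groups have ≤50 observations and no
ties, continuity-corrected normal approximation otherwise, ties
mid-ranked. Expression comparisons use Welch's unequal-variance t-test.
Stars follow strict boundaries: `*` p<0.1, `**` p<0.01, `***` p<0.001,
`****` p<0.00001. The exact path is proven against exhaustive permutation
enumeration at small n.

## Carrier estimation

Per recessive gene, known-pathogenic LoF/missense alleles that survive the
recessive population filter contribute their combined (max-over-sources)
frequency; the per-gene aggregate q is their sum, capped at 0.5 (rare-allele
regime; the cap only guards degenerate inputs). The carrier probability is
the Hardy-Weinberg heterozygote term 2q(1−q); the 2q approximation is
available as an option and its relative error is below q/(1−q). The
population-wide rate across genes assumes independent carrier status:
1 − Π(1 − 2q(1−q)), which never exceeds the union bound Σ 2q(1−q). The
at-risk couple rate Σ (2q(1−q))² is provided as a convenience. Panel
sensitivity is reported in two denominations — fraction of patient allele
observations on the panel (primary) and fraction of patients with all
causal alleles on the panel — because the single-number definition used in
cohort reports is ambiguous. Nested-cohort comparison computes per-gene
large/small carrier-frequency folds on overlapping genes, excluding (and
flagging) genes with a zero small-cohort estimate, and summarizes with the
mean fold.

## The synthetic generator

The generator emulates the statistical structure of a 1,180-trio NDD
cohort; every operation draws from a seed-stream of its own, so outputs
are bit-identical under a fixed config+seed and independent of call order.

**Gene panel.** 284 genes split AD/AR/XL as 0.57/0.33/0.10 (approximating a
cohort in which dominant diagnoses dominate and ~10% are X-linked). pLI is
Beta(9,1) for AD, Beta(1,9) for AR and Beta(6,2) for XL (X-linked genes
behave more like dominant ones); O/E is 1.5×Beta with means ≈0.3 (AD) and
≈0.94 (AR). About 3% of genes per mode are flagged as absent from the old
database snapshot to support the re-analysis pathway.

**Allele catalogue.** AR/XL genes carry 1-3 pathogenic alleles with
per-source het frequencies log-uniform on [1e-5, 5e-4] — below the 0.001
filter with headroom — and zero hom/hemi counts; dominant pathogenic
alleles have frequency 0 in all sources. The recorded per-gene truth q is
the max-over-sources, sum-over-alleles aggregate. Functional scores are
mode-conditional: dominant variants draw higher CADD/phyloP, lower SIFT
and fewer divergent species among 99 orthologs, with the CADD shift kept
small so its contrast is the weakest of the four, matching the expected
ordering of evidence strength.

**Cohort.** Each trio is diagnosed with probability 0.508 and routed to
known variant / phenotype expansion / CNV in proportion 41.9 : 4.7 : 4.2.
Sequence-diagnosed trios draw a causal mode from {de novo 0.629, comp-het
0.148, homozygous 0.099, hemizygous 0.087, inherited dominant 0.037} (the
comp-het/homozygous split of the 24.7% recessive share reflects an outbred
population where compound heterozygotes predominate) and genotypes are
constructed to realize the mode. 30% of recessive/X-linked patient alleles
are novel (absent from the references), emulating previously unreported
variants; 11.2% of sequence diagnoses are flagged "initially missed" with
reasons in proportion 8:5:1:8:11 (new entry : low coverage : synonymous :
phenotype re-evaluation : unclear), and the flags are realized physically
(gene drawn from the new-gene subset, proband depth 4-9, synonymous
consequence) so the re-analysis diff can rediscover them. Background
variation per trio is drawn from a shared pool of 3,000 benign autosomal
sites (80% common, AF uniform on [0.01, 0.5]; 20% rare, log-uniform on
[1e-5, 1e-3]) under Hardy-Weinberg with Mendelian transmission, plus one
benign de novo site; undiagnosed trios carry background only. Proband sex
is Bernoulli(0.5) except hemizygous trios (male), recorded in the sample
sheet.

**Coverage.** 2,000 capture intervals across the 22 autosomes; depth is
Gamma-Poisson (negative binomial) around mean 100x × per-sample scale
U(0.85, 1.15) × per-interval efficiency LogNormal(0, 0.3), with dispersion
size r=400 (~5% CV beyond Poisson, a realistic modern library; `None`
yields noiseless depth). Embedded CNVs multiply the proband mean by 0.5 /
0 / 1.5 over 5 consecutive intervals.

**Expression and PPI.** Per-gene baseline TPM is log-normal (median 10,
log-sd 1.2) with per-sample log-noise 0.4; brain samples (10, half
prenatal/half postnatal) are multiplied by the mode contrast {AD 3.0,
AR 1.0, XL 2.5}; 20 body samples span eight tissues. PPI edges are drawn
per gene: brain-positive with probability {AD 0.362, AR 0.222, XL 0.30},
brain degree 1+Poisson(mean−1) with means {7.2, 4.5, 6.5}, and
brain-positive AR genes interact in all seven tissues with probability
0.538 versus 0.10 for AD, so recessive genes are broad and dominant genes
brain-centred.

**VCF dialect.** Male chrX genotypes are written haploid (`1`); a flag
writes diploid-style `1/1` instead, since real callers differ, and the
reader accepts both.

### What the generator does not emulate

No read-level data, genotype likelihoods or strand artifacts; no linkage
disequilibrium between background variants; no GC-content or batch
structure in coverage; background variation is autosomal only; gene length
and recurrence hotspots are uniform; population sources differ only by
independent draws, not by systematic ascertainment. Passing tests
demonstrate the *logic* of filtering, phasing, classification and carrier
arithmetic, and calibrated behaviour under the stated noise models — not
robustness to every artifact of real exomes.

## Problem sizes and numerics

The default study is 1,180 trios × 284 genes with 50 background sites per
trio; the full pipeline runs in a few seconds. Validation runs use 1,000
trios for mode-mix recovery (3-binomial-SE bands), 500 trios × 600
intervals for CNV scoring, a 1,000,000-individual Monte-Carlo for the
carrier rate, and exhaustive enumeration for truth tables and small-n
rank-sum. Mixture draws are per-trio Bernoulli/categorical, so realized
proportions fluctuate binomially around the configured values; ground-truth
labels are recorded at draw time and never re-estimated. Seeds derive from
`numpy.random.default_rng([seed, stream])` with one stream per generator
operation.

## Known limitations

* The caller assigns at most one diagnosis per trio (precedence-ordered);
  dual molecular diagnoses are out of scope.
* Carrier-rate independence across genes ignores any shared haplotypes;
  with many genes the union-vs-sum difference is the dominant correction.
* The depth-ratio CNV caller has no reference-panel normalization, so its
  specificity degrades quickly with overdispersion; it is intended as the
  trio-internal comparison method, not a production CNV pipeline.
* Phenotype re-evaluation and "unclear" re-analysis reasons are input
  labels by construction — the pipeline attributes but cannot derive them.
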