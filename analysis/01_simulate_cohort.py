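"""Simulate the study cohort and write every pipeline input to disk.

Generates the default 1,180-trio neurodevelopmental-disorder cohort (50.8%
diagnostic yield split across de novo / recessive / hemizygous / CNV causes)
together with its gene panel, population allele frequencies, coverage,
expression matrix and PPI edge list, and saves the ground truth for the
downstream validation steps. Example per-trio VCFs are written for the first
30 trios; the full genotype table is saved as TSV.

Run from the repository root:  python analysis/01_simulate_cohort.py
"""

from pathlib import Path

import pandas as pd

from triomode import io
from triomode.records import genes_to_frame, variants_to_frame
from triomode.synthetic_cohort import SimulationConfig, config_to_yaml, simulate_study

OUT = Path("results/sim")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)
    study = simulate_study(cfg)

    config_to_yaml(cfg, OUT / "config.yaml")
    io.write_tsv(genes_to_frame(study.panel), OUT / "genes.tsv")
    io.write_tsv(variants_to_frame(study.variants), OUT / "variants.tsv")
    io.write_tsv(study.cohort.sample_sheet, OUT / "sample_sheet.tsv")
    io.write_bed(study.intervals, OUT / "capture.bed")
    io.write_tsv(study.expression.tpm.reset_index(names="gene"), OUT / "expression.tsv")
    io.write_tsv(study.expression.samples, OUT / "expression_samples.tsv")
    io.write_tsv(study.ppi_edges, OUT / "ppi_edges.tsv")
    study.truth.to_json(OUT / "ground_truth.json")

    genotypes = pd.DataFrame(
        {
            "trio_id": [r.trio_id for r in study.cohort.records],
            "variant_id": [r.variant.variant_id for r in study.cohort.records],
            "gene": [r.variant.gene for r in study.cohort.records],
            "proband_gt": [r.proband_gt for r in study.cohort.records],
            "father_gt": [r.father_gt for r in study.cohort.records],
            "mother_gt": [r.mother_gt for r in study.cohort.records],
        }
    )
    io.write_tsv(genotypes, OUT / "trio_genotypes.tsv")
    sheet_head = study.cohort.sample_sheet.head(30)
    example_trios = set(sheet_head.trio_id)
    io.write_cohort_vcfs(
        [r for r in study.cohort.records if r.trio_id in example_trios],
        sheet_head,
        OUT / "vcf_examples",
    )

    tr = study.truth.trios
    print(f"cohort: {cfg.n_trios} trios, {cfg.n_genes} disease genes, seed {SEED}")
    print(f"diagnosed (ground truth): {tr.diagnosed.sum()} "
          f"({100 * tr.diagnosed.mean():.1f}%)")
    print(tr.loc[tr.diagnosed, "causal_mode"].value_counts().to_string())
    print(f"inputs written to {OUT}/")


if __name__ == "__main__":
    main()
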