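"""Estimate recessive carrier frequencies and carrier-panel performance.

Aggregates each recessive gene's pathogenic allele frequencies across the
two population sources into q, converts to the Hardy-Weinberg carrier
probability 2q(1-q), reports the population-wide probability of carrying at
least one pathogenic allele, builds a pre-screening variant panel from the
alleles observed in the first 553 trios, measures its sensitivity on the
full cohort's recessive patient alleles, and compares per-gene estimates
between the nested 553-trio and full 1,180-trio cohorts.

Run from the repository root:  python analysis/05_carrier_frequencies.py
"""

import json
from pathlib import Path

from triomode import io
from triomode.carrier_estimation import estimates_to_frame
from triomode.synthetic_cohort import SimulationConfig, simulate_study
from triomode.workflows import carrier_analysis

OUT = Path("results/carriers")
SEED = 1
SUBSET = 553


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    study = simulate_study(SimulationConfig(seed=SEED), coverage=False)
    ca = carrier_analysis(study, subset_n_trios=SUBSET)

    io.write_tsv(estimates_to_frame(ca["estimates"]), OUT / "carrier_estimates.tsv")
    io.write_tsv(ca["fold_table"], OUT / "nested_cohort_folds.tsv")
    report = dict(ca["report"])
    report.update(
        one_in_n=ca["one_in_n"],
        panel_size=ca["panel_size"],
        sensitivity=ca["sensitivity"],
        mean_fold_nested=ca["mean_fold"],
        n_overlap_genes=ca["n_overlap_genes"],
    )
    (OUT / "panel_report.json").write_text(json.dumps(report, indent=1))

    r = ca["report"]
    print(f"recessive genes: {r['n_genes']} "
          f"({r['genes_with_predicted_carriers']} with predicted carriers, "
          f"{r['genes_without_predicted_carriers']} without)")
    print(f"population carrier rate: {ca['population_carrier_rate']:.4f} "
          f"= one in {ca['one_in_n']:.1f} individuals")
    print(f"largest per-gene carrier frequency: {ca['max_gene_carrier_pct']:.2f}%")
    print(f"panel from first {SUBSET} trios: {ca['panel_size']} variants, "
          f"sensitivity {100 * ca['sensitivity']['by_allele']:.1f}% of "
          f"{ca['n_patient_alleles']} patient allele observations")
    print(f"nested-cohort comparison on {ca['n_overlap_genes']} overlapping genes: "
          f"mean fold {ca['mean_fold']:.2f} "
          f"({ca['n_genes_small_cohort']} genes with carriers at n={SUBSET}, "
          f"{ca['n_genes_large_cohort']} at n={len(study.truth.trios)})")
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
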