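"""Hardy-Weinberg carrier-frequency estimation for recessive disease genes.

Per gene, the population frequencies of its pathogenic LoF/missense alleles
are combined across reference sources (max by default), summed into an
aggregated pathogenic allele frequency q, and converted to the heterozygous
carrier probability 2q(1-q). Panel-level outputs include the probability of
carrying at least one pathogenic allele across genes (assuming independence),
the sensitivity of a pre-screening variant panel against observed patient
alleles, and per-gene fold changes between cohorts of different size.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import CarrierEstimate, VariantRecord
from .synthetic_cohort import aggregate_sources
from .variant_filtering import FilterPolicy, passes_filter

CARRIER_CONSEQUENCES = ("LoF", "missense")


def aggregate_q(
    gene: str,
    pathogenic_variants: Iterable[VariantRecord],
    combine_rule: str = "max",
    filter_policy: FilterPolicy | None = FilterPolicy(),
) -> CarrierEstimate:
    """Aggregated pathogenic allele frequency of one gene.

    Only known-pathogenic LoF/missense alleles that survive the recessive
    population filter contribute. Per variant, sources are combined with
    ``combine_rule``; per gene, variant frequencies are summed (rare-allele
    regime) and capped at 0.5.
    """
    q = 0.0
    n = 0
    per_source: dict[str, float] = {}
    for v in pathogenic_variants:
        if v.gene != gene or not v.known_pathogenic:
            continue
        if v.consequence not in CARRIER_CONSEQUENCES:
            continue
        if filter_policy is not None and not passes_filter(v, filter_policy, "AR"):
            continue
        afs = {s: a.het_af for s, a in v.source_afs.items()}
        av = aggregate_sources(afs, combine_rule)
        if av <= 0.0:
            continue
        q += av
        n += 1
        for s, a in afs.items():
            per_source[s] = per_source.get(s, 0.0) + a
    q = min(q, 0.5)
    return CarrierEstimate(gene, q, carrier_frequency(q), n, per_source)


def carrier_frequency(q: float, approximate: bool = False) -> float:
    """Hardy-Weinberg heterozygote probability 2q(1-q) (or 2q if approximate)."""
    if not 0.0 <= q <= 0.5:
        raise ValueError(f"q must be in [0, 0.5], got {q}")
    if approximate:
        return 2.0 * q
    return 2.0 * q * (1.0 - q)


def population_carrier_rate(estimates: Sequence[CarrierEstimate]) -> float:
    """Probability of carrying >= 1 pathogenic allele across distinct genes.

    Assumes carrier status independent across genes:
    1 - prod_g (1 - carrier_freq_g).
    """
    genes = [e.gene for e in estimates]
    if len(set(genes)) != len(genes):
        raise ValueError("genes must be distinct")
    rate = 1.0
    for e in estimates:
        rate *= 1.0 - e.carrier_freq
    return 1.0 - rate


def at_risk_couple_rate(estimates: Sequence[CarrierEstimate]) -> float:
    """Probability both members of a random couple carry the same gene."""
    return float(sum(e.carrier_freq**2 for e in estimates))


def panel_sensitivity(
    panel_variants: Iterable[str],
    patient_alleles: Sequence[str],
    per_patient: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, float]:
    """Fraction of patient pathogenic alleles a screening panel captures.

    ``by_allele`` counts allele observations whose variant is on the panel;
    ``by_patient`` (when per-patient allele lists are given) counts patients
    with *all* causal alleles on the panel.
    """
    panel = set(panel_variants)
    if len(patient_alleles) == 0:
        raise ValueError("empty patient allele set")
    by_allele = sum(a in panel for a in patient_alleles) / len(patient_alleles)
    out = {"by_allele": by_allele}
    if per_patient is not None:
        if len(per_patient) == 0:
            raise ValueError("empty patient set")
        hits = sum(all(a in panel for a in alleles) for alleles in per_patient.values())
        out["by_patient"] = hits / len(per_patient)
    return out


def compare_panels(
    estimates_small: Sequence[CarrierEstimate],
    estimates_large: Sequence[CarrierEstimate],
) -> pd.DataFrame:
    """Per-gene large/small carrier-frequency fold change on overlapping genes.

    Genes with a zero small-cohort estimate are flagged (``fold`` NaN) and
    excluded from the mean; the summary mean of per-gene folds is stored in
    ``DataFrame.attrs['mean_fold']``.
    """
    small = {e.gene: e for e in estimates_small}
    large = {e.gene: e for e in estimates_large}
    overlap = sorted(set(small) & set(large))
    if not overlap:
        raise ValueError("disjoint gene sets")
    rows = []
    for g in overlap:
        cf_s, cf_l = small[g].carrier_freq, large[g].carrier_freq
        fold = cf_l / cf_s if cf_s > 0 else float("nan")
        rows.append(
            {
                "gene": g,
                "carrier_freq_small": cf_s,
                "carrier_freq_large": cf_l,
                "fold": fold,
                "zero_small_estimate": cf_s == 0.0,
            }
        )
    df = pd.DataFrame(rows)
    valid = df.fold.dropna()
    df.attrs["mean_fold"] = float(valid.mean()) if len(valid) else float("nan")
    return df


def panel_report(estimates: Sequence[CarrierEstimate]) -> dict:
    """Counts of genes with and without predicted carriers, plus the
    population-wide carrier rate across the panel."""
    with_carriers = sum(1 for e in estimates if e.carrier_freq > 0)
    return {
        "n_genes": len(estimates),
        "genes_with_predicted_carriers": with_carriers,
        "genes_without_predicted_carriers": len(estimates) - with_carriers,
        "population_carrier_rate": population_carrier_rate(list(estimates)),
        "at_risk_couple_rate": at_risk_couple_rate(list(estimates)),
    }


def estimates_to_frame(estimates: Sequence[CarrierEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        row = {
            "gene": e.gene,
            "q": e.q,
            "carrier_freq": e.carrier_freq,
            "n_contributing_variants": e.n_contributing_variants,
        }
        for s, v in e.per_source.items():
            row[f"q_{s}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def estimates_from_frame(df: pd.DataFrame) -> list[CarrierEstimate]:
    src_cols = [c for c in df.columns if c.startswith("q_")]
    out = []
    for _, row in df.iterrows():
        out.append(
            CarrierEstimate(
                gene=row.gene,
                q=float(row.q),
                carrier_freq=float(row.carrier_freq),
                n_contributing_variants=int(row.n_contributing_variants),
                per_source={c[2:]: float(row[c]) for c in src_cols if pd.notna(row[c])},
            )
        )
    return out
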