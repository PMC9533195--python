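"""Population-frequency filtering of candidate pathogenic variants.

Implements the rare-disease convention of retaining, per inheritance mode,
only variants compatible with pathogenicity in healthy population references:
dominant candidates must never have been observed heterozygous, recessive and
X-linked candidates must never have been observed homozygous or hemizygous,
and every candidate must be rare (maximum heterozygous allele frequency over
the consulted sources below the threshold, 0.001 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import SourceAF, VariantRecord

VALID_MODES = ("AD", "AR", "XL")


@dataclass(frozen=True)
class FilterPolicy:
    """Frequency-filter settings.

    ``strict_threshold`` keeps the comparison strictly below the threshold.
    A variant absent from a consulted source is treated as AF 0 there
    (``missing_source_af``), the common clinical-pipeline convention.
    The per-source frequencies are combined with ``combine`` (default: the
    maximum over sources, the most conservative choice for retention).
    """

    het_af_threshold: float = 0.001
    dominant_requires_absent_het: bool = True
    recessive_requires_absent_homhemi: bool = True
    sources: tuple[str, ...] | None = None  # None = all sources on the record
    missing_source_af: float = 0.0
    combine: str = "max"
    strict_threshold: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.het_af_threshold < 1.0:
            raise ValueError(f"het_af_threshold must be in (0,1): {self.het_af_threshold}")


def _consulted(variant: VariantRecord, policy: FilterPolicy) -> list[SourceAF]:
    if policy.sources is None:
        return list(variant.source_afs.values()) or [SourceAF(policy.missing_source_af)]
    return [
        variant.source_afs.get(s, SourceAF(policy.missing_source_af)) for s in policy.sources
    ]


def _combined_het_af(variant: VariantRecord, policy: FilterPolicy) -> float:
    afs = [s.het_af for s in _consulted(variant, policy)]
    if policy.combine == "max":
        return max(afs)
    if policy.combine == "mean":
        return sum(afs) / len(afs)
    raise ValueError(f"unknown combine rule {policy.combine!r}")


def passes_filter(variant: VariantRecord, policy: FilterPolicy, mode: str) -> bool:
    """Whether one variant survives the mode-specific frequency filter."""
    reason = removal_reason(variant, policy, mode)
    return reason is None


def removal_reason(variant: VariantRecord, policy: FilterPolicy, mode: str) -> str | None:
    """None if retained, otherwise a short audit tag explaining removal."""
    if mode not in VALID_MODES:
        raise ValueError(f"unknown inheritance mode {mode!r}")
    het = _combined_het_af(variant, policy)
    if policy.strict_threshold:
        if het >= policy.het_af_threshold:
            return "het_af_above_threshold"
    elif het > policy.het_af_threshold:
        return "het_af_above_threshold"
    if mode == "AD" and policy.dominant_requires_absent_het and het > 0.0:
        return "seen_heterozygous"
    if mode in ("AR", "XL") and policy.recessive_requires_absent_homhemi:
        for src in _consulted(variant, policy):
            if src.hom_count > 0:
                return "seen_homozygous"
            if src.hemi_count > 0:
                return "seen_hemizygous"
    return None


def filter_candidates(
    variants: list[VariantRecord], policy: FilterPolicy, mode: str
) -> list[VariantRecord]:
    """Retain, in input order, the variants surviving the mode's filter."""
    return [v for v in variants if passes_filter(v, policy, mode)]


def count_surviving(variants: list[VariantRecord], policy: FilterPolicy, mode: str) -> int:
    return len(filter_candidates(variants, policy, mode))


def audit_filter(
    variants: list[VariantRecord], policy: FilterPolicy, mode: str
) -> list[tuple[str, str]]:
    """(variant_id, reason) for every removed variant, in input order."""
    out = []
    for v in variants:
        reason = removal_reason(v, policy, mode)
        if reason is not None:
            out.append((v.variant_id, reason))
    return out
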