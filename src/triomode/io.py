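"""Readers and writers for the pipeline's on-disk formats.

VCF 4.2 (GT + DP, one file per trio, variant annotations in INFO) via pysam,
BED for capture intervals (0-based half-open), TSV for gene/variant/
expression/PPI/depth/sample-sheet tables, JSON for ground truth and cohort
summaries. Male chrX genotypes are emitted haploid by default; a dialect
flag writes diploid-style hom-alt calls instead, since real callers differ.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .records import (
    HET,
    HEMI_ALT,
    HEMI_REF,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CohortSummary,
    DiagnosisCall,
    GeneAnnotation,
    SourceAF,
    TrioGenotypeRecord,
    VariantRecord,
    is_x,
)

_CONTIGS = [f"chr{i}" for i in range(1, 23)] + ["chrX"]
_CONTIG_RANK = {c: i for i, c in enumerate(_CONTIGS)}

_GT_TO_TUPLE = {
    HOM_REF: (0, 0),
    HET: (0, 1),
    HOM_ALT: (1, 1),
    HEMI_REF: (0,),
    HEMI_ALT: (1,),
    MISSING: (None, None),
}


def _vcf_header(sources: Sequence[str], samples: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in _CONTIGS:
        header.contigs.add(contig, length=250_000_000)
    header.add_meta(
        "INFO", items=[("ID", "GENE"), ("Number", "1"), ("Type", "String"),
                       ("Description", "Gene symbol")]
    )
    header.add_meta(
        "INFO", items=[("ID", "CSQ"), ("Number", "1"), ("Type", "String"),
                       ("Description", "Consequence class")]
    )
    for key, typ, desc in [
        ("CADD", "Float", "CADD phred score"),
        ("SIFT", "Float", "SIFT score"),
        ("PHYLOP", "Float", "phyloP conservation"),
        ("AACON", "Integer", "Species with different amino acid among 99 orthologs"),
    ]:
        header.add_meta(
            "INFO", items=[("ID", key), ("Number", "1"), ("Type", typ),
                           ("Description", desc)]
        )
    header.add_meta(
        "INFO", items=[("ID", "KNOWNPATH"), ("Number", "0"), ("Type", "Flag"),
                       ("Description", "Curated pathogenic assertion")]
    )
    for src in sources:
        up = src.upper()
        header.add_meta(
            "INFO", items=[("ID", f"AF_{up}"), ("Number", "1"), ("Type", "Float"),
                           ("Description", f"Het AF in {src}")]
        )
        header.add_meta(
            "INFO", items=[("ID", f"HOM_{up}"), ("Number", "1"), ("Type", "Integer"),
                           ("Description", f"Hom count in {src}")]
        )
        header.add_meta(
            "INFO", items=[("ID", f"HEMI_{up}"), ("Number", "1"), ("Type", "Integer"),
                           ("Description", f"Hemi count in {src}")]
        )
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for s in samples:
        header.add_sample(s)
    return header


def write_trio_vcf(
    records: Sequence[TrioGenotypeRecord],
    proband_id: str,
    father_id: str,
    mother_id: str,
    path: str | Path,
    male_x_diploid: bool = False,
) -> None:
    """Write one trio's genotyped sites as a VCF 4.2 file."""
    sources: list[str] = []
    for rec in records:
        for s in rec.variant.source_afs:
            if s not in sources:
                sources.append(s)
    samples = [proband_id, father_id, mother_id]
    header = _vcf_header(sources, samples)
    ordered = sorted(
        records, key=lambda r: (_CONTIG_RANK.get(r.variant.chrom, 99), r.variant.pos)
    )
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rec in ordered:
            v = rec.variant
            row = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt), id=v.variant_id,
            )
            row.info["GENE"] = v.gene
            row.info["CSQ"] = v.consequence
            row.info["CADD"] = v.cadd
            row.info["SIFT"] = v.sift
            row.info["PHYLOP"] = v.phylop
            row.info["AACON"] = v.aa_conservation
            if v.known_pathogenic:
                row.info["KNOWNPATH"] = True
            for src, af in v.source_afs.items():
                up = src.upper()
                row.info[f"AF_{up}"] = af.het_af
                row.info[f"HOM_{up}"] = af.hom_count
                row.info[f"HEMI_{up}"] = af.hemi_count
            gts = {
                proband_id: rec.proband_gt,
                father_id: rec.father_gt,
                mother_id: rec.mother_gt,
            }
            dps = {
                proband_id: rec.depths.get("proband"),
                father_id: rec.depths.get("father"),
                mother_id: rec.depths.get("mother"),
            }
            for sample in samples:
                gt = gts[sample]
                tup = _GT_TO_TUPLE[gt]
                if male_x_diploid and gt in (HEMI_REF, HEMI_ALT):
                    tup = (tup[0], tup[0])
                row.samples[sample]["GT"] = tup
                if dps[sample] is not None:
                    row.samples[sample]["DP"] = int(dps[sample])
            vcf.write(row)


def _decode_gt(alleles: tuple, on_x: bool, sample_is_male: bool) -> str:
    vals = tuple(a for a in alleles if a is not None)
    if not vals:
        return MISSING
    if on_x and sample_is_male:
        # haploid call, or diploid-dialect hom call collapsed to hemizygous
        return HEMI_ALT if any(v == 1 for v in vals) else HEMI_REF
    if len(vals) == 1:
        return HET if vals[0] == 1 else HOM_REF
    n_alt = sum(1 for v in vals if v == 1)
    return {0: HOM_REF, 1: HET, 2: HOM_ALT}[n_alt]


def read_trio_vcf(
    path: str | Path,
    trio_id: str,
    proband_sex: str,
) -> list[TrioGenotypeRecord]:
    """Read a trio VCF written by :func:`write_trio_vcf` back into records.

    Sample order in the file is proband, father, mother. The father is male
    by construction; the proband's sex decides chrX genotype decoding.
    """
    out: list[TrioGenotypeRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        proband, father, mother = samples
        sources = [k[3:].lower() for k in vcf.header.info if k.startswith("AF_")]
        for row in vcf:
            info = row.info
            source_afs = {}
            for src in sources:
                up = src.upper()
                source_afs[src] = SourceAF(
                    het_af=float(info.get(f"AF_{up}", 0.0) or 0.0),
                    hom_count=int(info.get(f"HOM_{up}", 0) or 0),
                    hemi_count=int(info.get(f"HEMI_{up}", 0) or 0),
                )
            variant = VariantRecord(
                variant_id=row.id or f"{row.contig}:{row.pos}",
                chrom=row.contig,
                pos=row.pos,
                ref=row.ref,
                alt=row.alts[0] if row.alts else ".",
                gene=str(info.get("GENE", "")),
                consequence=str(info.get("CSQ", "other")),
                cadd=float(info.get("CADD", 0.0) or 0.0),
                sift=float(info.get("SIFT", 1.0)),
                phylop=float(info.get("PHYLOP", 0.0) or 0.0),
                aa_conservation=int(info.get("AACON", 0) or 0),
                source_afs=source_afs,
                known_pathogenic=bool(info.get("KNOWNPATH", False)),
            )
            on_x = is_x(row.contig)
            depths = {}
            gts = {}
            for role, sample, male in [
                ("proband", proband, proband_sex == "male"),
                ("father", father, True),
                ("mother", mother, False),
            ]:
                fmt = row.samples[sample]
                gts[role] = _decode_gt(fmt["GT"], on_x, male)
                dp = fmt.get("DP")
                if dp is not None:
                    depths[role] = int(dp)
            out.append(
                TrioGenotypeRecord(
                    variant, trio_id, gts["proband"], gts["father"], gts["mother"],
                    depths, proband_sex,
                )
            )
    return out


def write_cohort_vcfs(
    records: Sequence[TrioGenotypeRecord],
    sample_sheet: pd.DataFrame,
    outdir: str | Path,
    male_x_diploid: bool = False,
) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_trio: dict[str, list[TrioGenotypeRecord]] = {}
    for rec in records:
        by_trio.setdefault(rec.trio_id, []).append(rec)
    paths = []
    for _, row in sample_sheet.iterrows():
        recs = by_trio.get(row.trio_id, [])
        path = outdir / f"{row.trio_id}.vcf"
        write_trio_vcf(recs, row.proband_id, row.father_id, row.mother_id, path,
                       male_x_diploid)
        paths.append(path)
    return paths


def read_cohort_vcfs(
    outdir: str | Path, sample_sheet: pd.DataFrame
) -> list[TrioGenotypeRecord]:
    records: list[TrioGenotypeRecord] = []
    for _, row in sample_sheet.iterrows():
        path = Path(outdir) / f"{row.trio_id}.vcf"
        if path.exists():
            records.extend(read_trio_vcf(path, row.trio_id, row.proband_sex))
    return records


# ---------------------------------------------------------------------------
# tabular formats


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"])
    df.insert(0, "interval_id", range(len(df)))
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    kwargs.setdefault("float_precision", "round_trip")
    return pd.read_csv(path, sep="\t", **kwargs)


def genes_from_frame(df: pd.DataFrame) -> list[GeneAnnotation]:
    return [
        GeneAnnotation(r.symbol, r.chrom, r.disease_mode, float(r.pli), float(r.oe))
        for r in df.itertuples()
    ]


def variants_from_frame(df: pd.DataFrame) -> list[VariantRecord]:
    src_names = sorted({c[len("het_af_"):] for c in df.columns if c.startswith("het_af_")})
    out = []
    for r in df.itertuples():
        source_afs = {}
        for s in src_names:
            source_afs[s] = SourceAF(
                het_af=float(getattr(r, f"het_af_{s}", 0.0)),
                hom_count=int(getattr(r, f"hom_count_{s}", 0)),
                hemi_count=int(getattr(r, f"hemi_count_{s}", 0)),
            )
        out.append(
            VariantRecord(
                variant_id=r.variant_id, chrom=r.chrom, pos=int(r.pos), ref=r.ref,
                alt=r.alt, gene=r.gene, consequence=r.consequence, cadd=float(r.cadd),
                sift=float(r.sift), phylop=float(r.phylop),
                aa_conservation=int(r.aa_conservation), source_afs=source_afs,
                known_pathogenic=bool(r.known_pathogenic),
            )
        )
    return out


def calls_to_frame(calls: Iterable[DiagnosisCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "trio_id": c.trio_id,
                "gene": c.gene,
                "variant_ids": ";".join(r.variant.variant_id for r in c.variants),
                "mode_category": c.mode_category,
                "callable": c.callable,
                "reason": c.reason,
                "diagnosis_route": c.diagnosis_route,
                "min_depth": c.min_depth,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["trio_id", "gene", "variant_ids", "mode_category", "callable",
                 "reason", "diagnosis_route", "min_depth"],
    )


def summary_to_json(summary: CohortSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(summary), indent=1))
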