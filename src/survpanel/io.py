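"""Readers and writers for the tabular dialects the pipeline consumes.

* MAF-like variant TSV (one row per somatic call, MAF column names);
* clinical TSV (``sample_id``, ``os_time``, ``os_event`` + covariate
  columns);
* gene panels as one-symbol-per-line text;
* COSMIC-style reference signature matrices (96 channel rows x K signature
  columns);
* optional VCF ingestion (via cyvcf2) with per-sample AD/DP and
  gene/effect INFO annotations; multi-allelic records are split into one
  record per alt allele.

All writers emit plain TSV with ``#``-prefixed provenance header comments
ignored on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .immuno import TRINUCLEOTIDE_CHANNELS
from .survival import SurvivalRecord
from .variants import MAF_CLASSIFICATION_MAP, EffectClass, VariantRecord

__all__ = [
    "read_maf",
    "write_maf",
    "read_clinical",
    "write_clinical",
    "read_gene_list",
    "write_gene_list",
    "read_signature_matrix",
    "write_signature_matrix",
    "read_vcf",
]

MAF_COLUMNS = [
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "t_depth",
    "t_alt_count",
]

# canonical MAF string for each internal effect class (for writing)
_EFFECT_TO_MAF = {
    EffectClass.MISSENSE: "Missense_Mutation",
    EffectClass.NONSENSE: "Nonsense_Mutation",
    EffectClass.FRAMESHIFT_INDEL: "Frame_Shift_Del",
    EffectClass.INFRAME_INDEL: "In_Frame_Del",
    EffectClass.SPLICE: "Splice_Site",
    EffectClass.SYNONYMOUS: "Silent",
    EffectClass.NONCODING: "Intron",
}


def read_maf(path: str | Path) -> list[VariantRecord]:
    """Read a MAF-like TSV into variant records.

    Requires the columns in :data:`MAF_COLUMNS`; unknown
    ``Variant_Classification`` strings raise rather than being dropped.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF file {path} lacks required columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        cls = getattr(row, "Variant_Classification")
        if cls not in MAF_CLASSIFICATION_MAP:
            raise ValueError(
                f"unknown Variant_Classification {cls!r} in {path}; "
                f"known: {sorted(MAF_CLASSIFICATION_MAP)}"
            )
        records.append(
            VariantRecord(
                sample_id=str(row.Tumor_Sample_Barcode),
                gene=str(row.Hugo_Symbol),
                chrom=str(row.Chromosome),
                pos=int(row.Start_Position),
                ref=str(row.Reference_Allele),
                alt=str(row.Tumor_Seq_Allele2),
                effect_class=MAF_CLASSIFICATION_MAP[cls],
                total_depth=int(row.t_depth),
                alt_depth=int(row.t_alt_count),
            )
        )
    return records


def write_maf(
    variants: Iterable[VariantRecord],
    path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    rows = [
        {
            "Tumor_Sample_Barcode": v.sample_id,
            "Hugo_Symbol": v.gene,
            "Chromosome": v.chrom,
            "Start_Position": v.pos,
            "Reference_Allele": v.ref,
            "Tumor_Seq_Allele2": v.alt,
            "Variant_Classification": _EFFECT_TO_MAF[v.effect_class],
            "t_depth": v.total_depth,
            "t_alt_count": v.alt_depth,
        }
        for v in variants
    ]
    df = pd.DataFrame(rows, columns=MAF_COLUMNS)
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"#{line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_clinical(path: str | Path) -> list[SurvivalRecord]:
    """Clinical TSV -> survival records; extra columns become covariates."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("sample_id", "os_time", "os_event"):
        if col not in df.columns:
            raise ValueError(f"clinical file {path} lacks required column {col!r}")
    extra = [c for c in df.columns if c not in ("sample_id", "os_time", "os_event")]
    records = []
    for row in df.itertuples(index=False):
        cov = {c: getattr(row, c) for c in extra}
        records.append(
            SurvivalRecord(
                sample_id=str(row.sample_id),
                time=float(row.os_time),
                event=int(row.os_event),
                covariates=cov,
            )
        )
    return records


def write_clinical(
    records: Iterable[SurvivalRecord],
    path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    records = list(records)
    cov_names: list[str] = []
    for r in records:
        for c in r.covariates:
            if c not in cov_names:
                cov_names.append(c)
    rows = [
        {
            "sample_id": r.sample_id,
            "os_time": r.time,
            "os_event": r.event,
            **{c: r.covariates.get(c) for c in cov_names},
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "os_time", "os_event", *cov_names])
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"#{line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    if not genes:
        raise ValueError(f"gene list {path} is empty")
    return genes


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    """96 x K reference signature TSV (channel names in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if set(df.index) != set(TRINUCLEOTIDE_CHANNELS):
        raise ValueError(
            f"signature matrix {path} must index exactly the 96 "
            "pyrimidine-centered trinucleotide channels"
        )
    df = df.loc[list(TRINUCLEOTIDE_CHANNELS)]
    df.columns = [str(c) for c in df.columns]
    return df.astype(float)


def write_signature_matrix(reference: pd.DataFrame, path: str | Path) -> None:
    reference.to_csv(path, sep="\t")


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Ingest a VCF with per-sample depths into variant records.

    Expects ``GENE`` and ``EFFECT`` INFO annotations (EFFECT in the internal
    effect vocabulary) and per-sample FORMAT ``AD``. Multi-allelic sites are
    split into one record per alt allele; a record is emitted for every
    sample carrying at least one alt read.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for var in vcf:
        gene = var.INFO.get("GENE")
        effect = var.INFO.get("EFFECT")
        if gene is None or effect is None:
            raise ValueError(
                f"VCF record {var.CHROM}:{var.POS} lacks GENE/EFFECT INFO"
            )
        ad = var.format("AD")
        if ad is None:
            raise ValueError(
                f"VCF record {var.CHROM}:{var.POS} lacks per-sample AD"
            )
        for alt_i, alt in enumerate(var.ALT):
            for s_i, sample in enumerate(samples):
                depths = np.asarray(ad[s_i], dtype=np.int64)
                depths = depths[depths >= 0]
                alt_depth = int(depths[alt_i + 1]) if len(depths) > alt_i + 1 else 0
                if alt_depth <= 0:
                    continue
                records.append(
                    VariantRecord(
                        sample_id=sample,
                        gene=str(gene),
                        chrom=str(var.CHROM),
                        pos=int(var.POS),
                        ref=str(var.REF),
                        alt=str(alt),
                        effect_class=EffectClass(str(effect)),
                        total_depth=int(depths.sum()),
                        alt_depth=alt_depth,
                    )
                )
    return records
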