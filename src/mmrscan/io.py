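"""Readers and writers for the tabular dialects the pipeline consumes.

Mutations travel as MAF-like TSV (Hugo_Symbol / Start_Position /
Variant_Classification ... headers); internally everything is a pandas
DataFrame with canonical lower-case columns. Copy number is a gene x sample
matrix of discrete GISTIC-style scores; transcripts come either from a
simplified exon TSV or from GFF3 (via gffutils).
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .signatures import SignatureMatrix
from .types import (
    CopyNumberCall,
    OncogenicityRecord,
    ProteinDomain,
    SomaticMutation,
    StructuralVariantCall,
    TranscriptModel,
    TumorSample,
)

#: canonical column -> MAF header
_MAF_HEADERS = {
    "gene": "Hugo_Symbol",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "consequence": "Variant_Classification",
    "t_ref_count": "t_ref_count",
    "t_alt_count": "t_alt_count",
    "transcript_id": "Transcript_ID",
    "sample_id": "Tumor_Sample_Barcode",
    "context": "Context",
    "protein_change": "HGVSp_Short",
}

#: MAF Variant_Classification -> canonical consequence
_MAF_CONSEQUENCE = {
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Del": "frameshift",
    "Frame_Shift_Ins": "frameshift",
    "Missense_Mutation": "missense",
    "Splice_Site": "essential_splice",
    "Silent": "synonymous",
}
_CONSEQUENCE_MAF = {
    "nonsense": "Nonsense_Mutation",
    "frameshift": "Frame_Shift_Del",
    "missense": "Missense_Mutation",
    "essential_splice": "Splice_Site",
    "synonymous": "Silent",
    "other": "Other",
}

MAF_COLUMNS = [
    "sample_id", "gene", "transcript_id", "chrom", "pos", "ref", "alt",
    "consequence", "protein_change", "t_ref_count", "t_alt_count", "context",
]


def write_maf(maf: pd.DataFrame, path: str | Path) -> None:
    out = maf.copy()
    out["consequence"] = out["consequence"].map(
        lambda c: _CONSEQUENCE_MAF.get(c, "Other")
    )
    out = out.rename(columns=_MAF_HEADERS)
    out.to_csv(path, sep="\t", index=False)


def read_maf(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype={"Chromosome": str}, comment="#")
    required = [
        "Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
        "Tumor_Seq_Allele2", "Variant_Classification", "t_ref_count",
        "t_alt_count", "Tumor_Sample_Barcode",
    ]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValidationError(f"MAF missing required headers: {missing}")
    inv = {v: k for k, v in _MAF_HEADERS.items()}
    df = raw.rename(columns=inv)
    for col in MAF_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df["consequence"] = df["consequence"].map(
        lambda c: _MAF_CONSEQUENCE.get(c, "other")
    )
    df["context"] = df["context"].fillna("")
    df["protein_change"] = df["protein_change"].fillna("")
    df["transcript_id"] = df["transcript_id"].fillna("")
    return df[MAF_COLUMNS]


def mutations_from_frame(maf: pd.DataFrame) -> list[SomaticMutation]:
    return [
        SomaticMutation(
            sample_id=str(r.sample_id),
            gene=str(r.gene),
            transcript_id=str(r.transcript_id),
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            consequence=str(r.consequence),
            protein_change=str(r.protein_change),
            t_ref_count=int(r.t_ref_count),
            t_alt_count=int(r.t_alt_count),
            trinucleotide_context=str(r.context),
        )
        for r in maf.itertuples()
    ]


def read_cna(path: str | Path) -> pd.DataFrame:
    """Gene x sample matrix of discrete copy-number scores."""
    return pd.read_csv(path, sep="\t", index_col=0)


def cna_calls_from_frame(cna: pd.DataFrame) -> list[CopyNumberCall]:
    calls = []
    for gene, row in cna.iterrows():
        for sid, value in row.items():
            if pd.notna(value) and value != 0:
                calls.append(CopyNumberCall(str(sid), str(gene), float(value)))
    return calls


def read_sv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def sv_calls_from_frame(sv: pd.DataFrame) -> list[StructuralVariantCall]:
    return [
        StructuralVariantCall(
            str(r.sample_id), str(r.gene_a), str(r.gene_b), str(r.sv_class)
        )
        for r in sv.itertuples()
    ]


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def samples_from_frame(clinical: pd.DataFrame) -> dict[str, TumorSample]:
    out = {}
    for r in clinical.itertuples():
        purity = getattr(r, "purity", None)
        out[str(r.sample_id)] = TumorSample(
            sample_id=str(r.sample_id),
            purity=float(purity) if purity is not None and pd.notna(purity) else None,
            subtype=str(getattr(r, "subtype", "unknown")),
            msi_status=str(getattr(r, "msi_status", "unknown")),
            age=float(r.age) if pd.notna(getattr(r, "age", np.nan)) else None,
            stage=str(getattr(r, "stage", "unknown")),
            os_months=float(getattr(r, "os_months", np.nan)),
            os_event=int(getattr(r, "os_event", 0)),
            pfs_months=float(getattr(r, "pfs_months", np.nan)),
            pfs_event=int(getattr(r, "pfs_event", 0)),
        )
    return out


def read_transcripts_tsv(path: str | Path) -> dict[str, TranscriptModel]:
    """Simplified exon table: transcript_id, gene, strand, exon_rank,
    start, end (1-based inclusive; exon_rank in transcript order)."""
    df = pd.read_csv(path, sep="\t")
    models: dict[str, TranscriptModel] = {}
    for tid, grp in df.groupby("transcript_id"):
        grp = grp.sort_values("exon_rank")
        models[str(tid)] = TranscriptModel(
            transcript_id=str(tid),
            gene=str(grp["gene"].iloc[0]),
            strand=str(grp["strand"].iloc[0]),
            exons=tuple(
                (int(s), int(e)) for s, e in zip(grp["start"], grp["end"])
            ),
        )
    return models


def read_transcripts_gff3(path: str | Path) -> dict[str, TranscriptModel]:
    """Transcript models from GFF3 exon features (requires gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: dict[str, TranscriptModel] = {}
    for tr in db.features_of_type(("mRNA", "transcript")):
        exons = [
            (f.start, f.end) for f in db.children(tr, featuretype="exon", order_by="start")
        ]
        if tr.strand == "-":
            exons = exons[::-1]
        gene = tr.attributes.get("gene_name", tr.attributes.get("Parent", [""]))[0]
        models[tr.id] = TranscriptModel(
            transcript_id=tr.id,
            gene=gene,
            strand=tr.strand,
            exons=tuple(exons),
        )
    return models


def read_oncogenicity(path: str | Path) -> dict[tuple[str, str], str]:
    """(gene, protein_change) -> verdict lookup."""
    df = pd.read_csv(path, sep="\t")
    dupes = df.duplicated(["gene", "protein_change"])
    if dupes.any():
        raise ValidationError("duplicate (gene, protein_change) in oncogenicity table")
    return {
        (str(r.gene), str(r.protein_change)): str(r.verdict)
        for r in df.itertuples()
    }


def onco_records_from_frame(df: pd.DataFrame) -> list[OncogenicityRecord]:
    return [
        OncogenicityRecord(
            str(r.gene), str(r.protein_change), str(r.verdict),
            str(getattr(r, "source", "")),
        )
        for r in df.itertuples()
    ]


def read_domains(path: str | Path) -> list[ProteinDomain]:
    df = pd.read_csv(path, sep="\t")
    return [
        ProteinDomain(str(r.gene), int(r.start_aa), int(r.end_aa),
                      str(getattr(r, "name", "")))
        for r in df.itertuples()
    ]


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    """96-row x K-column signature TSV, first column = channel labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureMatrix.from_frame(df)
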