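"""End-to-end orchestration: mutation/CNA/SV tables -> MMR alteration calls
-> zygosity -> signature exposures -> burden -> one analysis-ready cohort
table, plus the standard cohort report built from it."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .burden import DEFAULT_CALLABLE_MB, TMB_HIGH_CUTOFF, burden_table
from .caller import CallerConfig, call_cohort, is_multi_gene
from .errors import DegenerateInputError
from .signatures import (
    CHANNELS,
    MIN_SNVS,
    MutationCatalog,
    SignatureMatrix,
    channel_of,
    fit_cohort_exposures,
)
from .stats import (
    clinical_characteristics_table,
    km_logrank,
    prevalence_by_subtype,
)
from .types import MMR_GENES, TranscriptModel
from .zygosity import classify_zygosity

_DNA = set("ACGT")


def catalogs_from_frame(
    maf: pd.DataFrame, sample_ids: Sequence[str]
) -> list[MutationCatalog]:
    """Vectorised 96-channel catalog construction from a mutation table.

    Only SNV rows carrying a 3-mer context contribute; indels and
    context-free rows are skipped.
    """
    ref = maf["ref"].astype(str)
    alt = maf["alt"].astype(str)
    ctx = maf["context"].astype(str)
    is_snv = (
        ref.str.len().eq(1)
        & alt.str.len().eq(1)
        & ref.isin(list(_DNA))
        & alt.isin(list(_DNA))
        & ctx.str.len().eq(3)
    )
    sub = maf[is_snv]
    ch_index = {c: i for i, c in enumerate(CHANNELS)}
    ch = [
        ch_index[channel_of(r, a, c)]
        for r, a, c in zip(sub["ref"], sub["alt"], sub["context"])
    ]
    codes = pd.Categorical(sub["sample_id"], categories=list(sample_ids)).codes
    mat = np.zeros((len(sample_ids), 96))
    keep = np.asarray(codes) >= 0
    np.add.at(mat, (np.asarray(codes)[keep], np.asarray(ch)[keep]), 1.0)
    return [
        MutationCatalog(sample_id=str(sid), counts=mat[i])
        for i, sid in enumerate(sample_ids)
    ]


@dataclass
class PipelineConfig:
    caller: CallerConfig = field(default_factory=CallerConfig)
    loh_cutoff: float = 0.9
    callable_mb: float = DEFAULT_CALLABLE_MB
    tmb_high_cutoff: float = TMB_HIGH_CUTOFF
    min_snvs: int = MIN_SNVS


def build_cohort_table(
    maf: pd.DataFrame,
    cna: pd.DataFrame,
    sv: pd.DataFrame,
    clinical: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    onco: Mapping[tuple[str, str], str],
    signature_matrix: Optional[SignatureMatrix] = None,
    config: PipelineConfig = PipelineConfig(),
) -> dict[str, pd.DataFrame]:
    """Run every stage and join the results on sample_id.

    Returns a dict with keys ``cohort`` (analysis-ready table), ``calls``,
    ``zygosity`` and ``exposures``.
    """
    sample_ids = [str(s) for s in clinical["sample_id"]]
    samples = mio.samples_from_frame(clinical)

    # restrict object conversion to the MMR genes the caller looks at
    mmr_maf = maf[maf["gene"].isin(config.caller.genes)]
    mutations = mio.mutations_from_frame(mmr_maf)
    cna_calls = mio.cna_calls_from_frame(cna.loc[cna.index.isin(MMR_GENES)])
    sv_calls = mio.sv_calls_from_frame(sv) if len(sv) else []

    calls_by_sample = call_cohort(
        sample_ids, mutations, cna_calls, sv_calls, transcripts, onco,
        config=config.caller,
    )
    call_rows = []
    zyg_rows = []
    for sid, calls in calls_by_sample.items():
        for c in calls:
            call_rows.append(
                {
                    "sample_id": sid,
                    "gene": c.gene,
                    "alteration_class": c.alteration_class,
                    "vaf": c.vaf,
                }
            )
        if calls:
            for z in classify_zygosity(
                calls, samples[sid], loh_cutoff=config.loh_cutoff
            ):
                zyg_rows.append(
                    {
                        "sample_id": sid,
                        "gene": z.gene,
                        "zygosity": z.zygosity,
                        "mechanism": z.mechanism,
                        "corrected_vaf": z.corrected_vaf,
                    }
                )
    calls_df = pd.DataFrame(
        call_rows, columns=["sample_id", "gene", "alteration_class", "vaf"]
    )
    zyg_df = pd.DataFrame(
        zyg_rows,
        columns=["sample_id", "gene", "zygosity", "mechanism", "corrected_vaf"],
    )

    # burden
    pmhc = None
    if "pmhc_count" in clinical.columns:
        pmhc = clinical.set_index("sample_id")["pmhc_count"]
    burden = burden_table(
        maf, sample_ids, config.callable_mb, pmhc, config.tmb_high_cutoff
    )

    # signatures
    exposures = pd.DataFrame({"sample_id": sample_ids})
    if signature_matrix is not None:
        catalogs = catalogs_from_frame(maf, sample_ids)
        exposures = fit_cohort_exposures(
            catalogs, signature_matrix, config.min_snvs
        )

    cohort = clinical.copy()
    cohort["sample_id"] = cohort["sample_id"].astype(str)
    altered_ids = set(calls_df["sample_id"])
    cohort["mmr_altered"] = cohort["sample_id"].isin(altered_ids)
    gene_sets = calls_df.groupby("sample_id")["gene"].agg(
        lambda g: ",".join(sorted(set(g)))
    )
    class_sets = calls_df.groupby("sample_id")["alteration_class"].agg(
        lambda g: ",".join(sorted(g))
    )
    cohort["mmr_genes"] = cohort["sample_id"].map(gene_sets).fillna("")
    cohort["alteration_classes"] = cohort["sample_id"].map(class_sets).fillna("")
    cohort["multi_gene"] = cohort["sample_id"].map(
        {sid: is_multi_gene(calls) for sid, calls in calls_by_sample.items()}
    ).fillna(False)
    # sample-level zygosity: biallelic if any altered gene is biallelic
    if len(zyg_df):
        rank = {"biallelic": 2, "monoallelic": 1, "unknown": 0}
        best = (
            zyg_df.assign(r=zyg_df["zygosity"].map(rank))
            .sort_values("r")
            .groupby("sample_id")
            .last()["zygosity"]
        )
        cohort["zygosity"] = cohort["sample_id"].map(best).fillna("")
    else:
        cohort["zygosity"] = ""
    cohort = cohort.merge(
        burden.drop(columns=["pmhc_count"]), on="sample_id", how="left"
    )
    if signature_matrix is not None:
        cohort = cohort.merge(exposures, on="sample_id", how="left")

    return {
        "cohort": cohort,
        "calls": calls_df,
        "zygosity": zyg_df,
        "exposures": exposures,
    }


def cohort_report(cohort: pd.DataFrame) -> dict[str, object]:
    """The standard cohort summaries: overall prevalence, Table-2-style
    subtype prevalence, Table-1-style characteristics comparison, and the
    two survival comparisons when survival columns are present."""
    out: dict[str, object] = {}
    n = len(cohort)
    n_alt = int(cohort["mmr_altered"].sum())
    out["overall"] = pd.Series(
        {
            "n_patients": n,
            "mmr_altered": n_alt,
            "prevalence_pct": round(100 * n_alt / n, 1) if n else float("nan"),
        }
    )
    try:
        out["subtype_prevalence"] = prevalence_by_subtype(cohort)
    except (KeyError, DegenerateInputError):
        pass
    long, ps = clinical_characteristics_table(cohort)
    out["characteristics"] = long
    out["characteristics_tests"] = ps
    for prefix in ("os", "pfs"):
        tcol, ecol = f"{prefix}_months", f"{prefix}_event"
        if tcol in cohort.columns and cohort[tcol].notna().any():
            try:
                comp, curves = km_logrank(
                    cohort[tcol], cohort[ecol], cohort["mmr_altered"],
                    variable=prefix,
                )
                out[f"{prefix}_logrank"] = comp
                out[f"{prefix}_curves"] = curves
            except DegenerateInputError:
                pass
    return out


def run_bundle(bundle, config: PipelineConfig = PipelineConfig()) -> dict:
    """Convenience: run the full pipeline on a synthetic CohortBundle."""
    transcripts = {}
    for tid, grp in bundle.transcripts.groupby("transcript_id"):
        grp = grp.sort_values("exon_rank")
        transcripts[str(tid)] = TranscriptModel(
            transcript_id=str(tid),
            gene=str(grp["gene"].iloc[0]),
            strand=str(grp["strand"].iloc[0]),
            exons=tuple((int(s), int(e)) for s, e in zip(grp["start"], grp["end"])),
        )
    onco = {
        (str(r.gene), str(r.protein_change)): str(r.verdict)
        for r in bundle.onco.itertuples()
    }
    tables = build_cohort_table(
        bundle.maf,
        bundle.cna,
        bundle.sv,
        bundle.clinical,
        transcripts,
        onco,
        bundle.signature_matrix,
        config,
    )
    tables["report"] = cohort_report(tables["cohort"])
    return tables
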