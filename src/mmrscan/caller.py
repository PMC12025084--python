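"""Oncogenic somatic MMR alteration calling.

A sample is labelled "MMR-altered" when it carries at least one of:

* an oncogenic small somatic mutation in MLH1/MSH2/MSH6/PMS2 that survives
  the quality gate (depth > 20x, VAF > 10%) and the inclusion rules —
  truncating variants (nonsense/frameshift) unless they would escape
  nonsense-mediated decay (NMD) without hitting a known functional domain;
  essential-splice or missense variants only when a curated lookup calls
  them (likely) oncogenic;
* a homozygous deletion (GISTIC-style copy-number score < -1);
* a structural variant fusing an MMR gene.

The NMD-escape rule: a premature stop introduced in the final exon, or in
the 3'-most 55 bp of the penultimate exon, lies downstream of the last
exon-junction complex and typically escapes NMD, so a truncated (possibly
partly functional) protein may still be made; such variants are not counted
as loss-of-function unless they disrupt an annotated functional domain.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .errors import (
    ConfigurationError,
    MappingError,
    UndefinedVAFError,
    ValidationError,
)
from .types import (
    MMR_GENES,
    MMRAlterationCall,
    CopyNumberCall,
    OncogenicityRecord,
    ProteinDomain,
    SomaticMutation,
    StructuralVariantCall,
    TranscriptModel,
)

#: classification outcomes of :func:`classify_mutation`
INCLUDE_TRUNCATING = "include_truncating"
INCLUDE_ANNOTATED = "include_annotated"
EXCLUDE_NMD_ESCAPE = "exclude_nmd_escape"
EXCLUDE_QUALITY = "exclude_quality"
EXCLUDE_NOT_ONCOGENIC = "exclude_not_oncogenic"

_TRUNCATING = ("nonsense", "frameshift")
_ANNOTATABLE = ("essential_splice", "missense")
_ONCOGENIC_VERDICTS = ("oncogenic", "likely_oncogenic")

#: map input consequence -> alteration class of the emitted call
_CLASS_OF_CONSEQUENCE = {
    "nonsense": "nonsense",
    "frameshift": "frameshift",
    "missense": "deleterious_missense",
    "essential_splice": "splice",
}


@dataclass(frozen=True)
class CallerConfig:
    """Filter thresholds. Defaults follow the published criteria: strict
    depth > 20x, VAF > 0.10, and a 55-bp NMD window in the penultimate exon."""

    min_depth: int = 20
    min_vaf: float = 0.10
    nmd_window: int = 55
    genes: tuple[str, ...] = MMR_GENES


def compute_vaf(m: SomaticMutation) -> float:
    """Variant allele frequency: t_alt / (t_ref + t_alt).

    Raises
    ------
    UndefinedVAFError
        if total tumor coverage is zero.
    """
    total = m.t_ref_count + m.t_alt_count
    if total <= 0:
        raise UndefinedVAFError(
            f"{m.sample_id}:{m.gene}:{m.pos} has zero tumor coverage"
        )
    return m.t_alt_count / total


def passes_quality(m: SomaticMutation, config: CallerConfig = CallerConfig()) -> bool:
    """True iff depth strictly exceeds ``min_depth`` AND VAF strictly exceeds
    ``min_vaf`` (both thresholds are exclusive)."""
    return m.depth > config.min_depth and compute_vaf(m) > config.min_vaf


def _exon_index_of(t: TranscriptModel, pos: int) -> int:
    for i, (s, e) in enumerate(t.exons):
        if s <= pos <= e:
            return i
    raise MappingError(
        f"position {pos} outside exons of transcript {t.transcript_id}"
    )


def nmd_escape(
    m: SomaticMutation, t: TranscriptModel, window: int = 55
) -> bool:
    """Would a truncating variant at this position escape NMD?

    True iff the position lies anywhere in the final exon, or within the
    3'-most ``window`` bp of the penultimate exon, measured in transcript
    (5'->3') orientation — on the '-' strand the 3' end of an exon is its
    smallest genomic coordinate.
    """
    idx = _exon_index_of(t, m.pos)
    last = t.n_exons - 1
    if idx == last:
        return True
    if idx == last - 1:
        s, e = t.exons[idx]
        if t.strand == "+":
            return m.pos >= e - window + 1
        return m.pos <= s + window - 1
    return False


_AA_POS = re.compile(r"[A-Za-z*]+(\d+)")


def _protein_position(protein_change: str) -> Optional[int]:
    """First amino-acid position in an HGVS-p string ('p.E102*' -> 102)."""
    mobj = _AA_POS.search(protein_change.removeprefix("p."))
    return int(mobj.group(1)) if mobj else None


def _hits_domain(
    m: SomaticMutation, domains: Optional[Sequence[ProteinDomain]]
) -> bool:
    if not domains or not m.protein_change:
        return False
    aa = _protein_position(m.protein_change)
    if aa is None:
        return False
    return any(
        d.gene == m.gene and d.start_aa <= aa <= d.end_aa for d in domains
    )


def _onco_verdict(
    onco: Iterable[OncogenicityRecord] | Mapping[tuple[str, str], str],
    gene: str,
    protein_change: str,
) -> str:
    if isinstance(onco, Mapping):
        return onco.get((gene, protein_change), "unknown")
    for rec in onco:
        if rec.gene == gene and rec.protein_change == protein_change:
            return rec.verdict
    return "unknown"


def classify_mutation(
    m: SomaticMutation,
    t: Optional[TranscriptModel],
    onco: Iterable[OncogenicityRecord] | Mapping[tuple[str, str], str] = (),
    domains: Optional[Sequence[ProteinDomain]] = None,
    config: CallerConfig = CallerConfig(),
) -> str:
    """Apply the inclusion/exclusion rules to one mutation.

    Order: quality gate first; then truncating variants are included unless
    they escape NMD and miss every supplied functional domain; splice and
    missense variants require an oncogenic/likely-oncogenic lookup verdict.
    """
    if not passes_quality(m, config):
        return EXCLUDE_QUALITY
    if m.consequence in _TRUNCATING:
        if t is None:
            raise ConfigurationError(
                f"no transcript model for truncating variant {m.gene}:{m.pos}"
            )
        if nmd_escape(m, t, config.nmd_window) and not _hits_domain(m, domains):
            return EXCLUDE_NMD_ESCAPE
        return INCLUDE_TRUNCATING
    if m.consequence in _ANNOTATABLE:
        if _onco_verdict(onco, m.gene, m.protein_change) in _ONCOGENIC_VERDICTS:
            return INCLUDE_ANNOTATED
        return EXCLUDE_NOT_ONCOGENIC
    return EXCLUDE_NOT_ONCOGENIC


def call_sample_alterations(
    sample_id: str,
    mutations: Sequence[SomaticMutation] = (),
    cnas: Sequence[CopyNumberCall] = (),
    svs: Sequence[StructuralVariantCall] = (),
    transcripts: Mapping[str, TranscriptModel] | None = None,
    onco: Iterable[OncogenicityRecord] | Mapping[tuple[str, str], str] = (),
    domains: Optional[Sequence[ProteinDomain]] = None,
    config: CallerConfig = CallerConfig(),
) -> list[MMRAlterationCall]:
    """Union of oncogenic mutation calls, deep deletions (score < -1) and
    MMR-gene fusions for one sample; one call per qualifying event."""
    for g in config.genes:
        if g not in MMR_GENES:
            raise ValidationError(f"{g!r} is not a recognised MMR gene symbol")
    transcripts = transcripts or {}
    calls: list[MMRAlterationCall] = []
    for m in mutations:
        if m.sample_id != sample_id or m.gene not in config.genes:
            continue
        t = transcripts.get(m.transcript_id)
        verdict = classify_mutation(m, t, onco, domains, config)
        if verdict in (INCLUDE_TRUNCATING, INCLUDE_ANNOTATED):
            calls.append(
                MMRAlterationCall(
                    sample_id=sample_id,
                    gene=m.gene,
                    alteration_class=_CLASS_OF_CONSEQUENCE[m.consequence],
                    evidence=m,
                    vaf=compute_vaf(m),
                )
            )
    for c in cnas:
        if c.sample_id != sample_id or c.gene not in config.genes:
            continue
        if c.cna_value < -1:
            calls.append(
                MMRAlterationCall(
                    sample_id=sample_id,
                    gene=c.gene,
                    alteration_class="homozygous_deletion",
                    evidence=c,
                )
            )
    for sv in svs:
        if sv.sample_id != sample_id or sv.sv_class != "fusion":
            continue
        gene = next(
            (g for g in (sv.gene_a, sv.gene_b) if g in config.genes), None
        )
        if gene is not None:
            calls.append(
                MMRAlterationCall(
                    sample_id=sample_id,
                    gene=gene,
                    alteration_class="sv_fusion",
                    evidence=sv,
                )
            )
    return calls


def call_cohort(
    sample_ids: Sequence[str],
    mutations: Sequence[SomaticMutation] = (),
    cnas: Sequence[CopyNumberCall] = (),
    svs: Sequence[StructuralVariantCall] = (),
    transcripts: Mapping[str, TranscriptModel] | None = None,
    onco: Iterable[OncogenicityRecord] | Mapping[tuple[str, str], str] = (),
    domains: Optional[Sequence[ProteinDomain]] = None,
    config: CallerConfig = CallerConfig(),
) -> dict[str, list[MMRAlterationCall]]:
    """Run the caller per sample; returns sample_id -> list of calls.

    Samples with an empty list are MMR-wildtype. A sample whose calls span
    two or more genes is a multi-gene case (counted once in patient-level
    prevalence, once per gene in gene-level tallies).
    """
    by_sample: dict[str, dict[str, list]] = {
        s: {"mut": [], "cna": [], "sv": []} for s in sample_ids
    }
    for m in mutations:
        if m.sample_id in by_sample:
            by_sample[m.sample_id]["mut"].append(m)
    for c in cnas:
        if c.sample_id in by_sample:
            by_sample[c.sample_id]["cna"].append(c)
    for sv in svs:
        if sv.sample_id in by_sample:
            by_sample[sv.sample_id]["sv"].append(sv)
    return {
        s: call_sample_alterations(
            s, rec["mut"], rec["cna"], rec["sv"], transcripts, onco, domains, config
        )
        for s, rec in by_sample.items()
    }


def is_multi_gene(calls: Sequence[MMRAlterationCall]) -> bool:
    """True when one sample's calls hit two or more distinct MMR genes."""
    return len({c.gene for c in calls}) >= 2
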