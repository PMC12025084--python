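"""Domain types for somatic mismatch-repair (MMR) alteration analysis.

The four core MMR genes analysed throughout the package are MLH1, MSH2,
MSH6 and PMS2; their loss of function underlies dMMR / MSI-H tumor states.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ValidationError

MMR_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")

#: consequence classes recognised on input mutation records
CONSEQUENCES = (
    "nonsense",
    "frameshift",
    "missense",
    "essential_splice",
    "synonymous",
    "other",
)

#: alteration classes an oncogenic MMR event can take
ALTERATION_CLASSES = (
    "frameshift",
    "nonsense",
    "deleterious_missense",
    "splice",
    "sv_fusion",
    "homozygous_deletion",
)

#: alteration classes backed by a small somatic mutation (carry a VAF)
MUTATION_CLASSES = ("frameshift", "nonsense", "deleterious_missense", "splice")

_DNA = set("ACGT")


@dataclass(frozen=True)
class SomaticMutation:
    """One called small somatic variant with tumor allele counts.

    ``t_alt_count / (t_ref_count + t_alt_count)`` is the variant allele
    frequency (VAF). ``trinucleotide_context`` is the reference 3-mer centred
    on the variant position (SNVs only); empty when unavailable.
    """

    sample_id: str
    gene: str
    transcript_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    protein_change: str = ""
    t_ref_count: int = 0
    t_alt_count: int = 0
    trinucleotide_context: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.t_ref_count < 0 or self.t_alt_count < 0:
            raise ValidationError("allele counts must be non-negative")
        if self.ref == self.alt:
            raise ValidationError("ref and alt alleles are identical")
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(f"unknown consequence {self.consequence!r}")
        ctx = self.trinucleotide_context
        if ctx:
            if len(ctx) != 3:
                raise ValidationError(f"context must be a 3-mer, got {ctx!r}")
            if self.is_snv and ctx[1] != self.ref:
                raise ValidationError(
                    f"context middle base {ctx[1]!r} != ref allele {self.ref!r}"
                )

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in _DNA
            and self.alt in _DNA
        )

    @property
    def depth(self) -> int:
        return self.t_ref_count + self.t_alt_count


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of one transcript.

    ``exons`` are 1-based inclusive genomic ``(start, end)`` intervals in
    transcript (5'->3') order: ascending genomic coordinates on '+', and
    descending on '-'. Each interval always satisfies start <= end.
    """

    transcript_id: str
    gene: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exons) < 1:
            raise ValidationError("transcript needs at least one exon")
        for s, e in self.exons:
            if s > e:
                raise ValidationError(f"exon interval ({s},{e}) reversed")
        ordered = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValidationError("exons overlap")
        # transcript order must be monotone in the strand direction
        starts = [s for s, _ in self.exons]
        if self.strand == "+" and starts != sorted(starts):
            raise ValidationError("'+' transcript exons not in ascending order")
        if self.strand == "-" and starts != sorted(starts, reverse=True):
            raise ValidationError("'-' transcript exons not in descending order")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)


@dataclass(frozen=True)
class OncogenicityRecord:
    """One (gene, protein change) oncogenicity verdict from a curated lookup
    table (OncoKB-style annotations)."""

    gene: str
    protein_change: str
    verdict: str  # oncogenic | likely_oncogenic | benign | unknown
    source: str = ""


@dataclass(frozen=True)
class CopyNumberCall:
    """Gene-level discrete copy-number score (GISTIC-style; -2 = deep deletion)."""

    sample_id: str
    gene: str
    cna_value: float


@dataclass(frozen=True)
class StructuralVariantCall:
    """One structural variant joining two genes."""

    sample_id: str
    gene_a: str
    gene_b: str
    sv_class: str = "fusion"  # fusion | other


@dataclass(frozen=True)
class MMRAlterationCall:
    """One oncogenic somatic MMR alteration attached to a sample.

    A sample with at least one call is labelled "MMR-altered".
    """

    sample_id: str
    gene: str
    alteration_class: str
    evidence: object = None
    vaf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gene not in MMR_GENES:
            raise ValidationError(f"{self.gene} is not an MMR gene")
        if self.alteration_class not in ALTERATION_CLASSES:
            raise ValidationError(f"unknown alteration class {self.alteration_class!r}")
        if self.alteration_class in MUTATION_CLASSES and self.vaf is None:
            raise ValidationError("mutation-backed call must carry a VAF")


@dataclass(frozen=True)
class TumorSample:
    """Clinical/sample-level attributes used by zygosity calling and cohort
    statistics. ``purity`` is the tumor-cell fraction (TP) of the specimen."""

    sample_id: str
    purity: Optional[float] = None
    subtype: str = "unknown"  # HR+HER2- | HER2+ | TNBC | unknown
    msi_status: str = "unknown"  # MSI-H | MSS | unknown
    age: Optional[float] = None
    stage: str = "unknown"
    os_months: Optional[float] = None
    os_event: Optional[int] = None
    pfs_months: Optional[float] = None
    pfs_event: Optional[int] = None

    def __post_init__(self) -> None:
        if self.purity is not None and not (0.0 < self.purity <= 1.0):
            raise ValidationError(f"purity must be in (0, 1], got {self.purity}")


@dataclass(frozen=True)
class ZygosityCall:
    """Biallelic vs monoallelic inactivation status of one altered gene."""

    sample_id: str
    gene: str
    zygosity: str  # biallelic | monoallelic | unknown
    mechanism: str  # homozygous_deletion | mutation_plus_LOH | single_hit | unknown
    corrected_vaf: Optional[float] = None


@dataclass(frozen=True)
class ProteinDomain:
    """A known functional domain as a 1-based inclusive amino-acid interval."""

    gene: str
    start_aa: int
    end_aa: int
    name: str = ""
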