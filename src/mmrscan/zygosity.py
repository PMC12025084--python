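"""Biallelic vs monoallelic inactivation calling.

A mutation's raw VAF understates the cancer-cell allele fraction when the
specimen contains admixed normal cells, so the VAF is divided by tumor
purity (TP). A purity-corrected VAF >= 0.9 indicates loss of heterozygosity
(LOH) of the wild-type allele — together with the mutation this inactivates
both copies. A deep copy-number deletion (score < -1) removes both copies
outright. Everything else is a single hit, i.e. monoallelic.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import PurityError
from .types import (
    MUTATION_CLASSES,
    CopyNumberCall,
    MMRAlterationCall,
    TumorSample,
    ZygosityCall,
)

LOH_CUTOFF = 0.9


def corrected_vaf(vaf: float, purity: float) -> float:
    """Purity-corrected VAF: min(vaf / purity, 1.0).

    Values above 1 are impossible under the heterozygous/LOH model and are
    clamped. Raises :class:`PurityError` for missing or non-positive purity
    (such samples are excluded from zygosity calling, never silently called
    monoallelic).
    """
    if purity is None or purity <= 0:
        raise PurityError(f"purity must be positive, got {purity!r}")
    return min(vaf / purity, 1.0)


def is_loh(corrected: float) -> bool:
    """LOH iff corrected VAF >= 0.9 (inclusive cutoff)."""
    return corrected >= LOH_CUTOFF


def classify_zygosity(
    calls: Sequence[MMRAlterationCall],
    sample: TumorSample,
    cnas: Sequence[CopyNumberCall] = (),
    loh_cutoff: float = LOH_CUTOFF,
) -> list[ZygosityCall]:
    """One zygosity label per altered gene of an MMR-altered sample.

    Rules, in order per gene:

    * any homozygous-deletion call -> biallelic (homozygous_deletion);
    * any mutation call whose purity-corrected VAF passes ``loh_cutoff``
      -> biallelic (mutation_plus_LOH);
    * otherwise monoallelic (single_hit).

    A mutation call lacking usable allele counts, or a sample without a
    positive purity, yields zygosity "unknown" rather than a guess.
    """
    out: list[ZygosityCall] = []
    for gene in sorted({c.gene for c in calls}):
        gene_calls = [c for c in calls if c.gene == gene]
        if any(c.alteration_class == "homozygous_deletion" for c in gene_calls):
            out.append(
                ZygosityCall(sample.sample_id, gene, "biallelic", "homozygous_deletion")
            )
            continue
        mut_calls = [
            c for c in gene_calls if c.alteration_class in MUTATION_CLASSES
        ]
        best: Optional[float] = None
        unknown = False
        for c in mut_calls:
            if c.vaf is None:
                unknown = True
                continue
            try:
                cv = corrected_vaf(c.vaf, sample.purity)
            except PurityError:
                unknown = True
                continue
            best = cv if best is None else max(best, cv)
        if best is not None and best >= loh_cutoff:
            out.append(
                ZygosityCall(
                    sample.sample_id, gene, "biallelic", "mutation_plus_LOH", best
                )
            )
        elif best is not None:
            out.append(
                ZygosityCall(sample.sample_id, gene, "monoallelic", "single_hit", best)
            )
        elif unknown or not mut_calls:
            # mutation without counts/purity, or an SV-only gene: SVs carry
            # no allele fraction, so a lone fusion is a single hit
            if mut_calls or not gene_calls:
                out.append(
                    ZygosityCall(sample.sample_id, gene, "unknown", "unknown")
                )
            else:
                out.append(
                    ZygosityCall(sample.sample_id, gene, "monoallelic", "single_hit")
                )
    return out
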