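import numpy as np
import pytest

from mmrscan import SyntheticCohortParams, generate_cohort, run_bundle
from mmrscan.simulate import default_signature_matrix
from mmrscan.types import SomaticMutation, TranscriptModel


@pytest.fixture(scope="session")
def sigmat():
    return default_signature_matrix()


@pytest.fixture(scope="session")
def small_bundle():
    """A modest synthetic cohort shared across tests (fixed seed)."""
    return generate_cohort(SyntheticCohortParams(n_patients=800, seed=11))


@pytest.fixture(scope="session")
def small_run(small_bundle):
    return run_bundle(small_bundle)


def make_snv(
    sample_id="S1",
    gene="MLH1",
    transcript_id="TX",
    pos=100,
    ref="C",
    alt="T",
    consequence="nonsense",
    protein_change="p.E102*",
    t_ref_count=60,
    t_alt_count=40,
    context="",
):
    return SomaticMutation(
        sample_id=sample_id,
        gene=gene,
        transcript_id=transcript_id,
        chrom="1",
        pos=pos,
        ref=ref,
        alt=alt,
        consequence=consequence,
        protein_change=protein_change,
        t_ref_count=t_ref_count,
        t_alt_count=t_alt_count,
        trinucleotide_context=context,
    )


def make_transcript(exon_lengths, strand="+", start=1000, gap=500, gene="MLH1",
                    transcript_id="TX"):
    """Build a TranscriptModel from exon lengths in transcript order."""
    genomic = []
    cursor = start
    for L in exon_lengths:
        genomic.append((cursor, cursor + L - 1))
        cursor += L + gap
    if strand == "-":
        genomic = genomic[::-1]
    return TranscriptModel(
        transcript_id=transcript_id, gene=gene, strand=strand,
        exons=tuple(genomic),
    )


def exon_positions_in_transcript_order(t: TranscriptModel):
    """All genomic positions of the transcript, 5'->3'. Oracle helper."""
    out = []
    for s, e in t.exons:
        rng = range(s, e + 1) if t.strand == "+" else range(e, s - 1, -1)
        out.extend(rng)
    return out
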