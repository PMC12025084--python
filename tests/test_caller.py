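"""Alteration caller: VAF, quality gate, NMD-escape rule, classification
and per-sample call assembly."""
import numpy as np
import pytest

from mmrscan import (
    CallerConfig,
    call_sample_alterations,
    classify_mutation,
    compute_vaf,
    nmd_escape,
    passes_quality,
)
from mmrscan.caller import (
    EXCLUDE_NMD_ESCAPE,
    EXCLUDE_NOT_ONCOGENIC,
    EXCLUDE_QUALITY,
    INCLUDE_ANNOTATED,
    INCLUDE_TRUNCATING,
    is_multi_gene,
)
from mmrscan.errors import (
    ConfigurationError,
    MappingError,
    UndefinedVAFError,
    ValidationError,
)
from mmrscan.types import CopyNumberCall, StructuralVariantCall

from conftest import (
    exon_positions_in_transcript_order,
    make_snv,
    make_transcript,
)


@pytest.mark.parametrize(
    "alt,ref,expected",
    [(10, 90, 0.10), (0, 50, 0.0), (45, 55, 0.45)],
)
def test_compute_vaf(alt, ref, expected):
    m = make_snv(t_alt_count=alt, t_ref_count=ref)
    assert compute_vaf(m) == pytest.approx(expected)


def test_vaf_undefined_at_zero_coverage():
    with pytest.raises(UndefinedVAFError):
        compute_vaf(make_snv(t_alt_count=0, t_ref_count=0))


@pytest.mark.parametrize(
    "t_alt,t_ref,ok",
    [
        (3, 18, True),     # depth 21, VAF 14% — just past both strict gates
        (11, 89, True),    # VAF exactly 11%
        (10, 10, False),   # depth exactly 20 — not strictly greater
        (10, 90, False),   # VAF exactly 10% — not strictly greater
    ],
)
def test_quality_gate_strict_boundaries(t_alt, t_ref, ok):
    m = make_snv(t_alt_count=t_alt, t_ref_count=t_ref)
    assert passes_quality(m) is ok


class TestNMDEscape:
    def test_far_upstream_exon_never_escapes(self):
        t = make_transcript([150] * 19)
        pos = t.exons[2][0] + 10  # exon 3 of 19
        assert nmd_escape(make_snv(pos=pos), t) is False

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_whole_final_exon_escapes(self, strand):
        t = make_transcript([120, 90, 200], strand=strand)
        s, e = t.exons[-1]
        for pos in range(s, e + 1):
            assert nmd_escape(make_snv(pos=pos), t) is True

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_penultimate_exon_55bp_boundary(self, strand):
        t = make_transcript([120, 200, 90], strand=strand)
        s, e = t.exons[1]
        if strand == "+":
            at_55, at_56 = e - 54, e - 55
        else:
            at_55, at_56 = s + 54, s + 55
        assert nmd_escape(make_snv(pos=at_55), t) is True
        assert nmd_escape(make_snv(pos=at_56), t) is False

    def test_position_outside_exons_raises(self):
        t = make_transcript([100, 100])
        with pytest.raises(MappingError):
            nmd_escape(make_snv(pos=t.exons[0][1] + 5), t)

    def test_matches_bruteforce_oracle_on_random_transcripts(self):
        """The strand-aware implementation must agree position-by-position
        with an independent oracle that walks every exonic base in
        transcript order and applies the rule from the 3' end."""
        rng = np.random.default_rng(42)
        window = 55
        checked = 0
        while checked < 1000:
            n_exons = int(rng.integers(1, 7))
            lengths = [int(rng.integers(10, 120)) for _ in range(n_exons)]
            strand = "+" if rng.random() < 0.5 else "-"
            t = make_transcript(lengths, strand=strand)
            ordered = exon_positions_in_transcript_order(t)
            # oracle: per-position truth from transcript-order enumeration
            escape_positions = set()
            final_s, final_e = t.exons[-1]
            escape_positions.update(range(final_s, final_e + 1))
            if n_exons >= 2:
                pen_s, pen_e = t.exons[-2]
                pen_order = [
                    p for p in ordered if pen_s <= p <= pen_e
                ]
                escape_positions.update(pen_order[-window:])
            for _ in range(min(25, len(ordered))):
                pos = int(ordered[int(rng.integers(len(ordered)))])
                expected = pos in escape_positions
                assert nmd_escape(make_snv(pos=pos), t, window) is expected
                checked += 1


class TestClassifyMutation:
    ONCO = {
        ("MLH1", "p.G67R"): "oncogenic",
        ("MSH6", "p.X12_splice"): "likely_oncogenic",
    }

    def test_midgene_nonsense_included(self):
        t = make_transcript([150] * 10)
        m = make_snv(pos=t.exons[3][0] + 5, protein_change="p.E102*")
        assert classify_mutation(m, t) == INCLUDE_TRUNCATING

    def test_quality_gate_applies_first(self):
        t = make_transcript([150] * 10)
        m = make_snv(pos=t.exons[3][0] + 5, t_ref_count=10, t_alt_count=5)
        assert classify_mutation(m, t) == EXCLUDE_QUALITY

    def test_unknown_missense_excluded(self):
        m = make_snv(consequence="missense", protein_change="p.A9T")
        assert classify_mutation(m, None, self.ONCO) == EXCLUDE_NOT_ONCOGENIC

    def test_oncogenic_missense_and_splice_included(self):
        m = make_snv(consequence="missense", protein_change="p.G67R")
        assert classify_mutation(m, None, self.ONCO) == INCLUDE_ANNOTATED
        sp = make_snv(gene="MSH6", consequence="essential_splice",
                      protein_change="p.X12_splice")
        assert classify_mutation(sp, None, self.ONCO) == INCLUDE_ANNOTATED

    def test_synonymous_excluded(self):
        m = make_snv(consequence="synonymous", ref="C", alt="T")
        assert classify_mutation(m, None) == EXCLUDE_NOT_ONCOGENIC

    def test_nmd_escape_vs_domain_conjunction(self):
        """Final-exon nonsense is excluded, unless it overlaps a supplied
        functional domain — the full truth table of the conjunction."""
        from mmrscan.types import ProteinDomain

        t = make_transcript([150, 150, 150])
        final = make_snv(pos=t.exons[-1][0] + 10, protein_change="p.E400*")
        mid = make_snv(pos=t.exons[0][0] + 10, protein_change="p.E30*")
        dom_hit = [ProteinDomain("MLH1", 350, 450)]
        dom_miss = [ProteinDomain("MLH1", 1, 100)]
        assert classify_mutation(final, t) == EXCLUDE_NMD_ESCAPE
        assert classify_mutation(final, t, domains=dom_miss) == EXCLUDE_NMD_ESCAPE
        assert classify_mutation(final, t, domains=dom_hit) == INCLUDE_TRUNCATING
        assert classify_mutation(mid, t, domains=dom_miss) == INCLUDE_TRUNCATING

    def test_truncating_without_transcript_is_config_error(self):
        with pytest.raises(ConfigurationError):
            classify_mutation(make_snv(), None)


class TestCallSample:
    def test_deep_deletion_called(self):
        calls = call_sample_alterations(
            "S1", cnas=[CopyNumberCall("S1", "MSH2", -2)]
        )
        assert len(calls) == 1
        assert calls[0].alteration_class == "homozygous_deletion"
        assert calls[0].gene == "MSH2"

    def test_shallow_deletion_not_called(self):
        assert call_sample_alterations(
            "S1", cnas=[CopyNumberCall("S1", "MSH2", -1)]
        ) == []

    def test_no_events_is_wildtype(self):
        assert call_sample_alterations("S1") == []

    def test_fusion_called_on_either_partner(self):
        for a, b in [("MSH2", "XYZ"), ("XYZ", "MSH2")]:
            calls = call_sample_alterations(
                "S1", svs=[StructuralVariantCall("S1", a, b, "fusion")]
            )
            assert [c.gene for c in calls] == ["MSH2"]
        assert call_sample_alterations(
            "S1", svs=[StructuralVariantCall("S1", "MSH2", "XYZ", "other")]
        ) == []

    def test_two_gene_sample_yields_two_calls_and_multigene_flag(self):
        t = make_transcript([150] * 10)
        tx = {"TX": t}
        muts = [
            make_snv(gene="MLH1", pos=t.exons[2][0] + 3),
            make_snv(gene="MSH6", pos=t.exons[2][0] + 7),
        ]
        calls = call_sample_alterations("S1", muts, transcripts=tx)
        assert len(calls) == 2
        assert is_multi_gene(calls)

    def test_unknown_gene_in_filter_set_rejected(self):
        with pytest.raises(ValidationError):
            call_sample_alterations(
                "S1", config=CallerConfig(genes=("MLH1", "BRCA1"))
            )

    def test_idempotent_on_own_evidence(self):
        t = make_transcript([150] * 10)
        muts = [make_snv(pos=t.exons[2][0] + 3)]
        cnas = [CopyNumberCall("S1", "PMS2", -2)]
        first = call_sample_alterations("S1", muts, cnas, transcripts={"TX": t})
        ev_muts = [c.evidence for c in first if c.alteration_class == "nonsense"]
        ev_cnas = [c.evidence for c in first if c.alteration_class == "homozygous_deletion"]
        second = call_sample_alterations(
            "S1", ev_muts, ev_cnas, transcripts={"TX": t}
        )
        assert [(c.gene, c.alteration_class) for c in first] == [
            (c.gene, c.alteration_class) for c in second
        ]

    def test_call_count_monotone_in_thresholds(self):
        """Relaxing the depth or VAF threshold never loses calls."""
        rng = np.random.default_rng(3)
        t = make_transcript([150] * 10)
        muts = []
        for i in range(120):
            depth = int(rng.integers(5, 80))
            alt = int(rng.integers(0, depth + 1))
            muts.append(
                make_snv(
                    sample_id="S1",
                    pos=int(t.exons[int(rng.integers(8))][0]) + 3,
                    t_alt_count=alt,
                    t_ref_count=depth - alt,
                    protein_change=f"p.E{i+10}*",
                )
            )
        counts = []
        for min_depth, min_vaf in [(40, 0.25), (20, 0.10), (10, 0.05), (0, 0.0)]:
            cfg = CallerConfig(min_depth=min_depth, min_vaf=min_vaf)
            counts.append(
                len(call_sample_alterations("S1", muts, transcripts={"TX": t},
                                            config=cfg))
            )
        assert counts == sorted(counts)
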