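"""Synthetic breast-cancer cohort generator.

Emits a complete input bundle (clinical + mutation + copy-number + SV +
transcript + oncogenicity tables) together with a per-sample truth table,
with the statistical structure of the published cohorts baked in as
defaults: subtype-dependent alteration prevalence (0.8% / 1.3% / 3.1%),
the 6:16:1:6:3:12 alteration-class mixture, conditional MSI-H rates
(27% among altered vs 0.9% among wildtype), group-dependent lognormal TMB
(medians 3.7 vs 0.5 mut/Mb), and elevated MMR-deficiency signature
exposure under biallelic inactivation (mean 0.17 vs 0.04).

Allele counts follow a binomial read-sampling model at Poisson depth with
expected alternate fraction purity/2 for heterozygous events and ~purity
under copy-neutral LOH — the simplest model consistent with the
purity-corrected VAF rule used downstream. Everything is driven by one
seeded generator, so a fixed seed reproduces the bundle byte for byte.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .signatures import CHANNELS, SignatureMatrix
from .types import MMR_GENES, SomaticMutation, TranscriptModel

SUBTYPES = ("HR+HER2-", "HER2+", "TNBC")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _norm(d: dict) -> dict:
    total = sum(d.values())
    return {k: v / total for k, v in d.items()}


@dataclass
class SyntheticCohortParams:
    """Every generator knob. Defaults encode the published cohort structure;
    see docs/methods.md for the provenance of each value."""

    n_patients: int = 3667
    seed: int = 0
    subtype_mix: dict = field(
        default_factory=lambda: _norm({"HR+HER2-": 2049, "HER2+": 399, "TNBC": 392})
    )
    subtype_na_rate: float = 827 / 3667
    alteration_rate_by_subtype: dict = field(
        default_factory=lambda: {"HR+HER2-": 0.008, "HER2+": 0.013, "TNBC": 0.031}
    )
    alteration_class_mix: dict = field(
        default_factory=lambda: _norm(
            {
                "frameshift": 6,
                "nonsense": 16,
                "deleterious_missense": 1,
                "splice": 6,
                "sv_fusion": 3,
                "homozygous_deletion": 12,
            }
        )
    )
    gene_mix: dict = field(
        default_factory=lambda: _norm({"MLH1": 11, "MSH2": 8, "MSH6": 10, "PMS2": 12})
    )
    biallelic_fraction: float = 21 / 44
    msi_h_given_altered: float = 0.27
    msi_h_given_wt: float = 0.009
    msi_coverage: float = 1448 / 3667
    mmrdetect_pos_given_altered: float = 0.294
    mmrdetect_pos_given_wt: float = 0.003
    mmrdetect_coverage: float = 693 / 3667
    # lognormal TMB: (median mut/Mb, sigma of log)
    tmb_median_altered: float = 3.7
    tmb_sigma_altered: float = 1.7
    tmb_median_wt: float = 0.5
    tmb_sigma_wt: float = 1.46
    # neoantigen load ~ ratio x nonsynonymous TMB with lognormal noise
    neo_ratio_altered: float = 2.32
    neo_ratio_wt: float = 3.6
    neo_sigma: float = 0.4
    # Beta(a, b) parameters of the true MMR-signature exposure
    sig6_beta_biallelic: tuple = (0.25, 1.22)
    sig6_beta_monoallelic: tuple = (0.05, 1.2)
    sig6_beta_wt: tuple = (0.05, 1.2)
    background_signature_weights: dict = field(
        default_factory=lambda: {"Signature.1": 0.60, "Signature.3": 0.25, "Signature.5": 0.15}
    )
    purity_beta: tuple = (6.0, 3.0)
    depth_mean: float = 100.0
    callable_mb: float = 30.0
    silent_ratio: float = 0.35
    include_drivers: bool = True
    driver_mutation_rates: dict = field(
        default_factory=lambda: {
            "TP53": (0.610, 0.345),
            "KMT2C": (0.268, 0.060),
            "PTEN": (0.244, 0.060),
            "NF1": (0.220, 0.041),
        }
    )
    driver_cna_rates: dict = field(
        default_factory=lambda: {
            # gene: (rate_altered, rate_wt, score)
            "MYC": (0.385, 0.203, 2),
            "RAD21": (0.359, 0.169, 2),
            "RECQL4": (0.282, 0.152, 2),
            "FAT1": (0.128, 0.013, -2),
            "RAC1": (0.128, 0.0004, -2),
        }
    )
    os_scale_months: float = 60.0
    pfs_scale_months: float = 40.0
    censor_max_months: float = 120.0
    age_altered: tuple = (60.3, 14.5)
    age_wt: tuple = (54.6, 13.0)
    stage_mix: dict = field(
        default_factory=lambda: _norm(
            {"Stage I": 712, "Stage II": 1202, "Stage III": 611, "Stage IV": 411}
        )
    )
    stage_na_rate: float = 730 / 3667

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        for name, vec in (
            ("subtype_mix", self.subtype_mix),
            ("alteration_class_mix", self.alteration_class_mix),
            ("gene_mix", self.gene_mix),
        ):
            if abs(sum(vec.values()) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 1")
            if any(v < 0 for v in vec.values()):
                raise ValidationError(f"{name} has negative entries")
        rates = list(self.alteration_rate_by_subtype.values())
        if any(not (0 <= r <= 1) for r in rates):
            raise ValidationError("alteration rates must be fractions")
        if sum(self.alteration_class_mix.values()) == 0 and any(r > 0 for r in rates):
            raise ValidationError("positive alteration rate with empty class mix")
        for frac in (
            self.biallelic_fraction,
            self.msi_h_given_altered,
            self.msi_h_given_wt,
            self.subtype_na_rate,
        ):
            if not (0 <= frac <= 1):
                raise ValidationError("fractions must lie in [0, 1]")


def default_signature_matrix(k: int = 10) -> SignatureMatrix:
    """A deterministic synthetic stand-in for a COSMIC-style reference:
    k sparse, well-separated 96-channel profiles named Signature.1..k.
    Signature.6 plays the MMR-deficiency role in the generator."""
    rng = np.random.default_rng(961)
    profiles = np.zeros((k, 96))
    for i in range(k):
        # concentrate each signature on a distinct random subset of channels
        support = rng.choice(96, size=12, replace=False)
        weights = rng.dirichlet(np.full(12, 0.5))
        profiles[i, support] = weights
        profiles[i] += 1e-4  # small floor so catalogs never have -inf support
        profiles[i] /= profiles[i].sum()
    names = [f"Signature.{i + 1}" for i in range(k)]
    return SignatureMatrix(names=names, profiles=profiles)


@dataclass
class CohortBundle:
    """All generator outputs as DataFrames, in the dialects the pipeline
    reads, plus the truth table used by recovery tests."""

    clinical: pd.DataFrame
    maf: pd.DataFrame
    cna: pd.DataFrame
    sv: pd.DataFrame
    transcripts: pd.DataFrame
    onco: pd.DataFrame
    truth: pd.DataFrame
    signature_matrix: SignatureMatrix
    params: SyntheticCohortParams

    def write(self, outdir: str | Path) -> None:
        from . import io as mio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_maf(self.maf, outdir / "mutations.maf.tsv")
        self.cna.to_csv(outdir / "cna.tsv", sep="\t")
        self.sv.to_csv(outdir / "sv.tsv", sep="\t", index=False)
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
        self.transcripts.to_csv(outdir / "transcripts.tsv", sep="\t", index=False)
        self.onco.to_csv(outdir / "oncogenicity.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.signature_matrix.to_frame().to_csv(
            outdir / "signatures.tsv", sep="\t", index_label="channel"
        )


# ---------------------------------------------------------------------------
# transcript toys


def generate_toy_transcript(
    gene: str,
    transcript_id: str,
    rng: np.random.Generator,
    n_exons: Optional[int] = None,
    chrom_offset: int = 1_000_000,
) -> TranscriptModel:
    """A random toy transcript: 3-19 exons of 80-300 bp, either strand."""
    n = int(n_exons if n_exons is not None else rng.integers(3, 20))
    lengths = rng.integers(80, 301, size=n)
    gaps = rng.integers(200, 2001, size=n)
    strand = "+" if rng.random() < 0.5 else "-"
    genomic = []
    cursor = chrom_offset
    for L, g in zip(lengths, gaps):
        genomic.append((cursor, cursor + int(L) - 1))
        cursor += int(L) + int(g)
    if strand == "-":
        genomic = genomic[::-1]  # transcript order = descending genomic
    return TranscriptModel(
        transcript_id=transcript_id,
        gene=gene,
        strand=strand,
        exons=tuple(genomic),
    )


def _transcript_frame(models: list[TranscriptModel]) -> pd.DataFrame:
    rows = []
    for t in models:
        for rank, (s, e) in enumerate(t.exons, start=1):
            rows.append(
                {
                    "transcript_id": t.transcript_id,
                    "gene": t.gene,
                    "strand": t.strand,
                    "exon_rank": rank,
                    "start": s,
                    "end": e,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# catalog rendering

_CH_REF = np.array([c[2] for c in CHANNELS])
_CH_ALT = np.array([c[4] for c in CHANNELS])
_CH_CTX = np.array([c[0] + c[2] + c[6] for c in CHANNELS])


def generate_catalog_from_exposures(
    weights,
    n_snvs: int,
    S: SignatureMatrix,
    seed: int | np.random.Generator = 0,
    sample_id: str = "SIM",
) -> list[SomaticMutation]:
    """Draw ``n_snvs`` SNVs whose channel distribution is the signature
    mixture ``weights @ S.profiles``; each rendered with a consistent 3-mer
    context (about half on the purine strand, exercising the fold-back)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValidationError("exposure weights must sum to 1")
    if n_snvs == 0:
        return []
    p = w @ S.profiles
    p = p / p.sum()
    counts = rng.multinomial(n_snvs, p)
    out: list[SomaticMutation] = []
    pos = 1
    for ch_idx in np.repeat(np.arange(96), counts):
        ref, alt, ctx = _CH_REF[ch_idx], _CH_ALT[ch_idx], _CH_CTX[ch_idx]
        if rng.random() < 0.5:  # render on the purine strand
            ref = ref.translate(_COMPLEMENT)
            alt = alt.translate(_COMPLEMENT)
            ctx = ctx.translate(_COMPLEMENT)[::-1]
        out.append(
            SomaticMutation(
                sample_id=sample_id,
                gene="PASSENGER",
                transcript_id="",
                chrom="1",
                pos=pos,
                ref=ref,
                alt=alt,
                consequence="missense",
                t_ref_count=50,
                t_alt_count=10,
                trinucleotide_context=ctx,
            )
        )
        pos += 1
    return out


def generate_class_mixture_cohort(
    counts: Optional[dict] = None, seed: int = 0
) -> dict:
    """A minimal deterministic cohort carrying exactly one oncogenic MMR
    event per sample with a prescribed alteration-class histogram (default:
    the published 6 frameshift / 16 nonsense / 1 missense / 6 splice /
    3 fusion / 12 deep-deletion mixture). Returns the keyword inputs for
    :func:`mmrscan.caller.call_cohort`."""
    from .types import CopyNumberCall, StructuralVariantCall

    counts = counts or {
        "frameshift": 6,
        "nonsense": 16,
        "deleterious_missense": 1,
        "splice": 6,
        "sv_fusion": 3,
        "homozygous_deletion": 12,
    }
    rng = np.random.default_rng(seed)
    tx = {
        g: generate_toy_transcript(g, f"TX_{g}", rng, n_exons=6,
                                   chrom_offset=1_000_000 * (i + 1))
        for i, g in enumerate(MMR_GENES)
    }
    sample_ids, mutations, cnas, svs, onco = [], [], [], [], {}
    i = 0
    for cls, k in counts.items():
        for _ in range(int(k)):
            sid = f"F{i:03d}"
            sample_ids.append(sid)
            gene = MMR_GENES[i % 4]
            t = tx[gene]
            if cls == "homozygous_deletion":
                cnas.append(CopyNumberCall(sid, gene, -2))
            elif cls == "sv_fusion":
                svs.append(StructuralVariantCall(sid, gene, "FUSX1", "fusion"))
            else:
                s, e = t.exons[1]  # well upstream of the NMD-escape zone
                pos = (s + e) // 2
                consequence = {
                    "frameshift": "frameshift",
                    "nonsense": "nonsense",
                    "deleterious_missense": "missense",
                    "splice": "essential_splice",
                }[cls]
                pchg = f"p.E{100 + i}*" if cls == "nonsense" else f"p.G{100 + i}R"
                ref, alt = ("AC", "A") if cls == "frameshift" else ("C", "T")
                mutations.append(
                    SomaticMutation(
                        sample_id=sid, gene=gene, transcript_id=t.transcript_id,
                        chrom="1", pos=pos, ref=ref, alt=alt,
                        consequence=consequence, protein_change=pchg,
                        t_ref_count=60, t_alt_count=40,
                    )
                )
                if cls in ("deleterious_missense", "splice"):
                    onco[(gene, pchg)] = "oncogenic"
            i += 1
    return {
        "sample_ids": sample_ids,
        "mutations": mutations,
        "cnas": cnas,
        "svs": svs,
        "transcripts": {t.transcript_id: t for t in tx.values()},
        "onco": onco,
    }


# ---------------------------------------------------------------------------
# the cohort generator


def _draw_event_counts(
    rng: np.random.Generator, depth_mean: float, exp_vaf: float, enforce_gates: bool
) -> tuple[int, int]:
    """Poisson depth + binomial alt count; optionally redrawn until the
    event passes the depth>20 / VAF>0.10 quality gates (oncogenic events
    are generated as confidently called)."""
    for _ in range(200):
        depth = max(int(rng.poisson(depth_mean)), 1)
        alt = int(rng.binomial(depth, min(max(exp_vaf, 0.02), 0.98)))
        if not enforce_gates or (depth > 20 and alt / depth > 0.10):
            return depth - alt, alt
    return depth - alt, alt  # pragma: no cover - practically unreachable


def generate_cohort(params: SyntheticCohortParams) -> CohortBundle:
    """Generate the full synthetic input bundle plus truth."""
    p = params
    p.validate()
    rng = np.random.default_rng(p.seed)
    n = p.n_patients
    sample_ids = np.array([f"S{i:05d}" for i in range(n)])

    subtype_names = list(p.subtype_mix)
    subtype_true = rng.choice(
        subtype_names, size=n, p=[p.subtype_mix[s] for s in subtype_names]
    )
    subtype_obs = subtype_true.copy()
    subtype_obs[rng.random(n) < p.subtype_na_rate] = "unknown"

    rate = np.array([p.alteration_rate_by_subtype[s] for s in subtype_true])
    altered = rng.random(n) < rate

    purity = np.clip(rng.beta(*p.purity_beta, size=n), 0.05, 1.0)

    # --- event class / gene / zygosity truth ------------------------------
    class_names = list(p.alteration_class_mix)
    class_p = np.array([p.alteration_class_mix[c] for c in class_names])
    gene_names = list(p.gene_mix)
    gene_p = np.array([p.gene_mix[g] for g in gene_names])
    p_homdel = p.alteration_class_mix.get("homozygous_deletion", 0.0)
    p_sv = p.alteration_class_mix.get("sv_fusion", 0.0)
    p_mut = 1.0 - p_homdel - p_sv
    p_loh_mut = 0.0
    if p_mut > 0:
        p_loh_mut = min(max((p.biallelic_fraction - p_homdel) / p_mut, 0.0), 1.0)

    event_class = np.full(n, "", dtype=object)
    event_gene = np.full(n, "", dtype=object)
    zygosity = np.full(n, "", dtype=object)
    idx_altered = np.flatnonzero(altered)
    for i in idx_altered:
        event_class[i] = rng.choice(class_names, p=class_p)
        event_gene[i] = rng.choice(gene_names, p=gene_p)
        if event_class[i] == "homozygous_deletion":
            zygosity[i] = "biallelic"
        elif event_class[i] == "sv_fusion":
            zygosity[i] = "monoallelic"
        else:
            zygosity[i] = "biallelic" if rng.random() < p_loh_mut else "monoallelic"

    # --- MSI / MMRDetect labels ------------------------------------------
    msi_rate = np.where(altered, p.msi_h_given_altered, p.msi_h_given_wt)
    msi_true = np.where(rng.random(n) < msi_rate, "MSI-H", "MSS")
    msi_obs = np.where(rng.random(n) < p.msi_coverage, msi_true, "unknown")
    det_rate = np.where(
        altered, p.mmrdetect_pos_given_altered, p.mmrdetect_pos_given_wt
    )
    det_true = np.where(rng.random(n) < det_rate, "Pos", "Neg")
    det_obs = np.where(rng.random(n) < p.mmrdetect_coverage, det_true, "unknown")

    # --- TMB / mutation budgets ------------------------------------------
    log_med = np.where(
        altered, np.log(p.tmb_median_altered), np.log(p.tmb_median_wt)
    )
    sigma = np.where(altered, p.tmb_sigma_altered, p.tmb_sigma_wt)
    tmb_true = np.exp(rng.normal(log_med, sigma))
    n_nonsyn = rng.poisson(tmb_true * p.callable_mb)
    n_silent = rng.poisson(p.silent_ratio * np.maximum(n_nonsyn, 1))

    neo_ratio = np.where(altered, p.neo_ratio_altered, p.neo_ratio_wt)
    pmhc = np.round(
        n_nonsyn * neo_ratio * np.exp(rng.normal(0.0, p.neo_sigma, size=n))
    ).astype(int)

    # --- true signature exposures ----------------------------------------
    sig = default_signature_matrix()
    sig_names = list(sig.names)
    sig6_a = np.empty(n)
    for i in range(n):
        if zygosity[i] == "biallelic":
            a, b = p.sig6_beta_biallelic
        elif zygosity[i] == "monoallelic":
            a, b = p.sig6_beta_monoallelic
        else:
            a, b = p.sig6_beta_wt
        sig6_a[i] = rng.beta(a, b)
    bg = _norm(p.background_signature_weights)
    true_weights = np.zeros((n, sig.k))
    for j, name in enumerate(sig_names):
        if name == "Signature.6":
            true_weights[:, j] = sig6_a
        elif name in bg:
            true_weights[:, j] = (1.0 - sig6_a) * bg[name]

    # --- transcripts + oncogenicity lookup -------------------------------
    tx_models = [
        generate_toy_transcript(
            g, f"TX_{g}", rng, n_exons=int(rng.integers(8, 20)),
            chrom_offset=1_000_000 * (gi + 1),
        )
        for gi, g in enumerate(MMR_GENES)
    ]
    tx_by_gene = {t.gene: t for t in tx_models}

    onco_rows = [
        # decoys exercising the lookup: a benign and an unknown variant
        {"gene": "MLH1", "protein_change": "p.V384D", "verdict": "benign", "source": "synthetic"},
        {"gene": "MSH6", "protein_change": "p.A36T", "verdict": "unknown", "source": "synthetic"},
    ]

    # --- per-sample MAF rows ---------------------------------------------
    maf_cols = {
        "sample_id": [], "gene": [], "transcript_id": [], "chrom": [],
        "pos": [], "ref": [], "alt": [], "consequence": [],
        "protein_change": [], "t_ref_count": [], "t_alt_count": [],
        "context": [],
    }

    def add_row(sid, gene, tid, chrom, pos, ref, alt, csq, pchg, tr, ta, ctx):
        maf_cols["sample_id"].append(sid)
        maf_cols["gene"].append(gene)
        maf_cols["transcript_id"].append(tid)
        maf_cols["chrom"].append(chrom)
        maf_cols["pos"].append(int(pos))
        maf_cols["ref"].append(ref)
        maf_cols["alt"].append(alt)
        maf_cols["consequence"].append(csq)
        maf_cols["protein_change"].append(pchg)
        maf_cols["t_ref_count"].append(int(tr))
        maf_cols["t_alt_count"].append(int(ta))
        maf_cols["context"].append(ctx)

    cna_genes = list(MMR_GENES) + (
        list(p.driver_cna_rates) if p.include_drivers else []
    )
    cna = pd.DataFrame(0, index=cna_genes, columns=sample_ids, dtype=int)
    sv_rows = []

    event_vaf_expected = np.zeros(n)
    for i in idx_altered:
        sid = sample_ids[i]
        gene = event_gene[i]
        cls = event_class[i]
        if cls == "homozygous_deletion":
            cna.loc[gene, sid] = -2
            continue
        if cls == "sv_fusion":
            sv_rows.append(
                {"sample_id": sid, "gene_a": gene, "gene_b": "FUSX1", "sv_class": "fusion"}
            )
            continue
        t = tx_by_gene[gene]
        # place the variant in an exon upstream of the NMD-escape zone
        exon_idx = int(rng.integers(0, max(t.n_exons - 2, 1)))
        s, e = t.exons[exon_idx]
        pos = (s + e) // 2
        exp_vaf = purity[i] if zygosity[i] == "biallelic" else purity[i] / 2.0
        event_vaf_expected[i] = exp_vaf
        tr, ta = _draw_event_counts(rng, p.depth_mean, exp_vaf, enforce_gates=True)
        chrom = t.exons[0][0] // 1_000_000
        aa = int(rng.integers(20, 400))
        if cls == "nonsense":
            ch = int(rng.integers(96))
            add_row(sid, gene, t.transcript_id, str(chrom), pos,
                    _CH_REF[ch], _CH_ALT[ch], "nonsense", f"p.E{aa}*",
                    tr, ta, _CH_CTX[ch])
        elif cls == "frameshift":
            add_row(sid, gene, t.transcript_id, str(chrom), pos,
                    "AC", "A", "frameshift", f"p.K{aa}Rfs*12", tr, ta, "")
        elif cls == "deleterious_missense":
            pchg = f"p.G{aa}R"
            ch = int(rng.integers(96))
            add_row(sid, gene, t.transcript_id, str(chrom), pos,
                    _CH_REF[ch], _CH_ALT[ch], "missense", pchg, tr, ta, _CH_CTX[ch])
            onco_rows.append(
                {"gene": gene, "protein_change": pchg, "verdict": "oncogenic",
                 "source": "synthetic"}
            )
        elif cls == "splice":
            pchg = f"p.X{aa}_splice"
            ch = int(rng.integers(96))
            add_row(sid, gene, t.transcript_id, str(chrom), pos,
                    _CH_REF[ch], _CH_ALT[ch], "essential_splice", pchg,
                    tr, ta, _CH_CTX[ch])
            onco_rows.append(
                {"gene": gene, "protein_change": pchg, "verdict": "likely_oncogenic",
                 "source": "synthetic"}
            )

    # driver mutations / CNAs (group-dependent Bernoulli rates)
    n_driver_mut = np.zeros(n, dtype=int)
    if p.include_drivers:
        for gene, (ra, rw) in p.driver_mutation_rates.items():
            hit = rng.random(n) < np.where(altered, ra, rw)
            n_driver_mut += hit
            for i in np.flatnonzero(hit):
                ch = int(rng.integers(96))
                depth = max(int(rng.poisson(p.depth_mean)), 1)
                ta = int(rng.binomial(depth, min(max(purity[i] / 2, 0.02), 0.98)))
                add_row(sample_ids[i], gene, "", "9", 5_000_000 + i,
                        _CH_REF[ch], _CH_ALT[ch], "missense", "",
                        depth - ta, ta, _CH_CTX[ch])
        for gene, (ra, rw, score) in p.driver_cna_rates.items():
            hit = rng.random(n) < np.where(altered, ra, rw)
            cna.loc[gene, sample_ids[hit]] = score

    # passenger + silent SNVs with signature-mixture contexts, vectorised
    event_is_mut = np.isin(
        event_class, ["nonsense", "frameshift", "deleterious_missense", "splice"]
    )
    n_pass = np.maximum(n_nonsyn - n_driver_mut - event_is_mut.astype(int), 0)
    channel_p = true_weights @ sig.profiles
    channel_p /= channel_p.sum(axis=1, keepdims=True)
    for i in range(n):
        total = int(n_pass[i] + n_silent[i])
        if total == 0:
            continue
        counts = rng.multinomial(total, channel_p[i])
        ch_idx = np.repeat(np.arange(96), counts)
        rng.shuffle(ch_idx)
        depths = np.maximum(rng.poisson(p.depth_mean, size=total), 1)
        alts = rng.binomial(depths, min(max(purity[i] / 2, 0.02), 0.98))
        flip = rng.random(total) < 0.5
        for j, ch in enumerate(ch_idx):
            ref, alt, ctx = _CH_REF[ch], _CH_ALT[ch], _CH_CTX[ch]
            if flip[j]:
                ref = ref.translate(_COMPLEMENT)
                alt = alt.translate(_COMPLEMENT)
                ctx = ctx.translate(_COMPLEMENT)[::-1]
            csq = "missense" if j < n_pass[i] else "synonymous"
            add_row(sample_ids[i], f"G{ch:03d}", "", "10", 10_000_000 + j,
                    ref, alt, csq, "", depths[j] - alts[j], alts[j], ctx)

    maf = pd.DataFrame(maf_cols)

    # --- clinical ---------------------------------------------------------
    age_mean = np.where(altered, p.age_altered[0], p.age_wt[0])
    age_sd = np.where(altered, p.age_altered[1], p.age_wt[1])
    age = np.clip(np.round(rng.normal(age_mean, age_sd)), 23, 95).astype(int)
    stages = list(p.stage_mix)
    stage = rng.choice(stages, size=n, p=[p.stage_mix[s] for s in stages])
    stage = np.where(rng.random(n) < p.stage_na_rate, "unknown", stage)
    os_t = rng.exponential(p.os_scale_months, size=n)
    os_c = rng.uniform(0, p.censor_max_months, size=n)
    pfs_t = rng.exponential(p.pfs_scale_months, size=n)
    pfs_c = rng.uniform(0, p.censor_max_months, size=n)
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subtype": subtype_obs,
            "age": age,
            "stage": stage,
            "purity": np.round(purity, 4),
            "msi_status": msi_obs,
            "mmrdetect": det_obs,
            "pmhc_count": pmhc,
            "os_months": np.round(np.minimum(os_t, os_c), 2),
            "os_event": (os_t <= os_c).astype(int),
            "pfs_months": np.round(np.minimum(pfs_t, pfs_c), 2),
            "pfs_event": (pfs_t <= pfs_c).astype(int),
        }
    )

    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subtype_true": subtype_true,
            "altered": altered,
            "gene": event_gene,
            "alteration_class": event_class,
            "zygosity": zygosity,
            "expected_vaf": np.round(event_vaf_expected, 4),
            "msi_true": msi_true,
            "tmb_true": np.round(tmb_true, 4),
            "n_nonsynonymous": n_nonsyn,
            "sig6_exposure": np.round(sig6_a, 4),
            "purity": np.round(purity, 4),
        }
    )

    return CohortBundle(
        clinical=clinical,
        maf=maf,
        cna=cna,
        sv=pd.DataFrame(sv_rows, columns=["sample_id", "gene_a", "gene_b", "sv_class"]),
        transcripts=_transcript_frame(tx_models),
        onco=pd.DataFrame(onco_rows).drop_duplicates(["gene", "protein_change"]),
        truth=truth,
        signature_matrix=sig,
        params=p,
    )
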