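"""96-channel mutational catalogs and signature exposure refitting.

Single-base substitutions are folded onto the pyrimidine strand and binned
by (5' base, substitution, 3' base) into the standard 96-channel order:
substitutions C>A, C>G, C>T, T>A, T>C, T>G, each crossed with the 16 flank
combinations in A/C/G/T order — ``A[C>A]A, A[C>A]C, ... T[T>G]T``.

Exposure refitting follows the greedy forward-selection scheme used for
per-sample signature deconvolution against a fixed reference matrix
(e.g. the 30 COSMIC v2 signatures): starting from zero weights, each
iteration re-optimises the single signature weight (golden-section line
search on [0, 1]) that most reduces the sum-of-squares reconstruction
error against the sample's normalised 96-channel spectrum, until the
improvement drops below a tolerance; weights below a small cutoff (default
0.06) are then zeroed and the remainder renormalised to sum to one.

Only samples with at least 50 SNVs are eligible — below that the spectrum
is too sparse for a meaningful fit — and a sample's *dominant* signatures
are those contributing strictly more than 10% of its total exposure.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import SomaticMutation

PYRIMIDINE_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

MIN_SNVS = 50
WEIGHT_CUTOFF = 0.06
DOMINANCE_CUTOFF = 0.10


def channels() -> list[str]:
    """The 96 channel labels in canonical COSMIC order."""
    out = []
    for sub in PYRIMIDINE_SUBS:
        for five in _BASES:
            for three in _BASES:
                out.append(f"{five}[{sub}]{three}")
    return out


CHANNELS = tuple(channels())
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def channel_of(ref: str, alt: str, context: str) -> str:
    """Map one SNV (ref, alt, 3-mer reference context) to its channel,
    reverse-complementing purine-reference variants onto the pyrimidine
    strand."""
    if context[1] != ref:
        raise ValidationError(
            f"context middle base {context[1]!r} inconsistent with ref {ref!r}"
        )
    if ref in ("G", "A"):
        ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
        context = _revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class MutationCatalog:
    """Per-sample 96-channel trinucleotide substitution counts."""

    sample_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValidationError("catalog must have exactly 96 channels")
        if (self.counts < 0).any():
            raise ValidationError("catalog counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS), name=self.sample_id)


def build_catalog(
    snvs: Iterable[SomaticMutation], sample_id: str = ""
) -> MutationCatalog:
    """Accumulate SNVs with trinucleotide contexts into a catalog.

    Non-SNV records (indels, MNVs) are ignored; an SNV whose context middle
    base contradicts its ref allele raises :class:`ValidationError`.
    """
    counts = np.zeros(96)
    sid = sample_id
    for m in snvs:
        if not m.is_snv:
            continue
        if not m.trinucleotide_context:
            raise ValidationError(
                f"SNV {m.gene}:{m.pos} lacks a trinucleotide context"
            )
        counts[_CHANNEL_INDEX[channel_of(m.ref, m.alt, m.trinucleotide_context)]] += 1
        sid = sid or m.sample_id
    return MutationCatalog(sample_id=sid, counts=counts)


def catalog_from_channel_counts(
    sample_id: str, counts: np.ndarray
) -> MutationCatalog:
    return MutationCatalog(sample_id=sample_id, counts=np.asarray(counts, float))


def eligible(c: MutationCatalog, min_snvs: int = MIN_SNVS) -> bool:
    """Signature analysis requires at least ``min_snvs`` SNVs (inclusive)."""
    return c.total >= min_snvs


@dataclass
class SignatureMatrix:
    """K reference signatures as a K x 96 row-stochastic matrix."""

    names: list[str]
    profiles: np.ndarray

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (len(self.names), 96):
            raise ValidationError("profiles must be K x 96")
        if (self.profiles < 0).any():
            raise ValidationError("signature probabilities must be non-negative")
        sums = self.profiles.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValidationError("each signature row must sum to 1 (1e-6)")

    @property
    def k(self) -> int:
        return len(self.names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureMatrix":
        """96-row (channel-indexed) x K-column frame, COSMIC-style layout."""
        df = df.reindex(list(CHANNELS))
        if df.isna().any().any():
            raise ValidationError("signature table missing channels")
        return cls(names=list(df.columns), profiles=df.to_numpy().T)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.profiles.T, index=list(CHANNELS), columns=self.names
        )


@dataclass
class ExposureVector:
    """Fitted per-sample signature weights (sum to 1, or all zero when the
    sample was ineligible) plus the residual reconstruction error."""

    sample_id: str
    names: list[str]
    weights: np.ndarray
    residual_error: float
    eligible: bool = True

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.names, name=self.sample_id)

    def weight(self, name: str) -> float:
        return float(self.weights[self.names.index(name)])


def dominant_signatures(e: ExposureVector, cutoff: float = DOMINANCE_CUTOFF) -> set[str]:
    """Signatures contributing strictly more than ``cutoff`` of the total."""
    return {n for n, w in zip(e.names, e.weights) if w > cutoff}


def _golden_section(f, lo: float, hi: float, tol: float = 1e-6) -> float:
    """Minimise a unimodal f on [lo, hi] by golden-section search."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


class SignatureRefit:
    """Model object: refit one catalog against a reference signature matrix.

    Parameters
    ----------
    catalog : MutationCatalog
        Observed 96-channel counts for one sample.
    signatures : SignatureMatrix
        Reference signatures to decompose against.
    min_snvs : int
        Eligibility floor on the catalog total (default 50).
    weight_cutoff : float
        Post-fit small-weight cutoff (default 0.06).
    tol : float
        Stop when an iteration improves the squared error by less than this
        (default 1e-3, on the L2 reconstruction error).
    """

    def __init__(
        self,
        catalog: MutationCatalog,
        signatures: SignatureMatrix,
        min_snvs: int = MIN_SNVS,
        weight_cutoff: float = WEIGHT_CUTOFF,
        tol: float = 1e-3,
    ) -> None:
        self.catalog = catalog
        self.signatures = signatures
        self.min_snvs = min_snvs
        self.weight_cutoff = weight_cutoff
        self.tol = tol

    def fit(self, max_iter: int = 200) -> "SignatureRefitResults":
        c = self.catalog
        S = self.signatures.profiles  # K x 96
        if not eligible(c, self.min_snvs):
            return SignatureRefitResults(
                model=self,
                raw_weights=np.zeros(self.signatures.k),
                weights=np.zeros(self.signatures.k),
                residual_error=float("nan"),
                n_iter=0,
                eligible=False,
            )
        m = c.counts / c.counts.sum()  # observed spectrum, sums to 1
        K = self.signatures.k
        w = np.zeros(K)
        sq_norms = np.einsum("kj,kj->k", S, S)  # ||S_k||^2, fixed

        r = m - w @ S
        err = float(r @ r)
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            # moving w_k to a changes the error by a scalar quadratic in a:
            # err - 2*(a - w_k)*(S_k . r) + (a - w_k)^2 * ||S_k||^2
            grads = S @ r
            best_k, best_a, best_err = -1, 0.0, err
            for k in range(K):
                g, h, wk = grads[k], sq_norms[k], w[k]

                def f(a, g=g, h=h, wk=wk):
                    d = a - wk
                    return err - 2.0 * d * g + d * d * h

                a = _golden_section(f, 0.0, 1.0)
                e = f(a)
                if e < best_err:
                    best_k, best_a, best_err = k, a, e
            # convergence is judged on the L2 reconstruction error, where
            # the classic 1e-3 threshold lives
            if best_k < 0 or np.sqrt(err) - np.sqrt(best_err) < self.tol:
                break
            r = r - (best_a - w[best_k]) * S[best_k]
            w[best_k] = best_a
            err = float(r @ r)
        raw = w.copy()
        total = w.sum()
        if total > 0:
            norm = w / total
            norm[norm < self.weight_cutoff] = 0.0
            if norm.sum() > 0:
                norm = norm / norm.sum()
        else:
            norm = w
        return SignatureRefitResults(
            model=self,
            raw_weights=raw,
            weights=norm,
            residual_error=err,
            n_iter=n_iter,
            eligible=True,
        )


@dataclass
class SignatureRefitResults:
    """Fit output: normalised exposure weights, the pre-normalisation raw
    weights, and the residual sum-of-squares against the observed spectrum."""

    model: SignatureRefit
    raw_weights: np.ndarray
    weights: np.ndarray
    residual_error: float
    n_iter: int
    eligible: bool

    @property
    def exposures(self) -> ExposureVector:
        return ExposureVector(
            sample_id=self.model.catalog.sample_id,
            names=list(self.model.signatures.names),
            weights=self.weights,
            residual_error=self.residual_error,
            eligible=self.eligible,
        )

    def dominant(self, cutoff: float = DOMINANCE_CUTOFF) -> set[str]:
        if not self.eligible:
            return set()
        return dominant_signatures(self.exposures, cutoff)

    def reconstruction(self) -> np.ndarray:
        """Fitted spectrum w @ S (raw weights, pre-normalisation scale)."""
        return self.raw_weights @ self.model.signatures.profiles

    def summary(self) -> pd.DataFrame:
        dom = self.dominant()
        df = pd.DataFrame(
            {
                "signature": self.model.signatures.names,
                "weight": self.weights,
                "dominant": [n in dom for n in self.model.signatures.names],
            }
        )
        df.attrs["sample_id"] = self.model.catalog.sample_id
        df.attrs["residual_error"] = self.residual_error
        df.attrs["eligible"] = self.eligible
        return df.sort_values("weight", ascending=False).reset_index(drop=True)


def fit_exposures(
    c: MutationCatalog,
    S: SignatureMatrix,
    min_snvs: int = MIN_SNVS,
    weight_cutoff: float = WEIGHT_CUTOFF,
    tol: float = 1e-3,
) -> ExposureVector:
    """Functional wrapper around :class:`SignatureRefit`."""
    return SignatureRefit(c, S, min_snvs, weight_cutoff, tol).fit().exposures


def fit_cohort_exposures(
    catalogs: Sequence[MutationCatalog],
    S: SignatureMatrix,
    min_snvs: int = MIN_SNVS,
    weight_cutoff: float = WEIGHT_CUTOFF,
) -> pd.DataFrame:
    """Fit each catalog; returns a sample x (K weights + total_snvs +
    residual + eligible + dominant) frame."""
    rows = []
    for c in catalogs:
        res = SignatureRefit(c, S, min_snvs, weight_cutoff).fit()
        row = dict(zip(S.names, res.weights))
        row["sample_id"] = c.sample_id
        row["total_snvs"] = c.total
        row["residual_error"] = res.residual_error
        row["eligible"] = res.eligible
        row["dominant"] = ",".join(sorted(res.dominant()))
        rows.append(row)
    cols = ["sample_id", "total_snvs", "eligible", "residual_error"] + list(
        S.names
    ) + ["dominant"]
    return pd.DataFrame(rows, columns=cols)
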