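"""Tumor mutational burden (TMB) and neoantigen load.

TMB is the count of nonsynonymous somatic mutations (SNVs and small indels)
per megabase of coding sequence covered by the assay; tumors at >= 10
mutations/Mb are TMB-high. Neoantigen load is analogously the number of
predicted MHC-binding mutant peptides (pMHCs) per megabase — the prediction
itself is upstream, only the normalisation happens here. MSI status and
MMR-deficiency classifier labels are externally supplied annotations, never
computed in this package.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .errors import ValidationError

TMB_HIGH_CUTOFF = 10.0
DEFAULT_CALLABLE_MB = 30.0

#: consequence classes counted as nonsynonymous for TMB
NONSYNONYMOUS = (
    "missense",
    "nonsense",
    "frameshift",
    "essential_splice",
    "inframe_indel",
)


def compute_tmb(n_nonsynonymous: int, callable_mb: float) -> float:
    """Mutations per megabase: n_nonsynonymous / callable_mb."""
    if callable_mb <= 0:
        raise ValidationError(f"callable_mb must be > 0, got {callable_mb}")
    if n_nonsynonymous < 0:
        raise ValidationError("mutation count must be non-negative")
    return n_nonsynonymous / callable_mb


def tmb_class(tmb: float, cutoff: float = TMB_HIGH_CUTOFF) -> str:
    """'TMB-H' iff tmb >= cutoff (inclusive), else 'TMB-L'."""
    return "TMB-H" if tmb >= cutoff else "TMB-L"


def neoantigen_per_mb(
    pmhc_count: Optional[int], callable_mb: float
) -> Optional[float]:
    """pMHCs per megabase; a missing count propagates as missing."""
    if pmhc_count is None or pd.isna(pmhc_count):
        return None
    if callable_mb <= 0:
        raise ValidationError(f"callable_mb must be > 0, got {callable_mb}")
    return pmhc_count / callable_mb


@dataclass(frozen=True)
class BurdenRecord:
    sample_id: str
    n_nonsynonymous: int
    callable_mb: float
    tmb: float
    tmb_class: str
    pmhc_count: Optional[int] = None
    neoantigen_per_mb: Optional[float] = None


def burden_record(
    sample_id: str,
    n_nonsynonymous: int,
    callable_mb: float = DEFAULT_CALLABLE_MB,
    pmhc_count: Optional[int] = None,
    tmb_high_cutoff: float = TMB_HIGH_CUTOFF,
) -> BurdenRecord:
    tmb = compute_tmb(n_nonsynonymous, callable_mb)
    return BurdenRecord(
        sample_id=sample_id,
        n_nonsynonymous=n_nonsynonymous,
        callable_mb=callable_mb,
        tmb=tmb,
        tmb_class=tmb_class(tmb, tmb_high_cutoff),
        pmhc_count=pmhc_count,
        neoantigen_per_mb=neoantigen_per_mb(pmhc_count, callable_mb),
    )


def burden_table(
    maf: pd.DataFrame,
    sample_ids: Iterable[str],
    callable_mb: float = DEFAULT_CALLABLE_MB,
    pmhc_counts: Optional[pd.Series] = None,
    tmb_high_cutoff: float = TMB_HIGH_CUTOFF,
) -> pd.DataFrame:
    """Per-sample burden metrics from a mutation table.

    ``maf`` needs ``sample_id`` and ``consequence`` columns; samples absent
    from the table get zero mutations.
    """
    nonsyn = maf[maf["consequence"].isin(NONSYNONYMOUS)]
    counts = nonsyn.groupby("sample_id").size()
    rows = []
    for sid in sample_ids:
        pm = None
        if pmhc_counts is not None and sid in pmhc_counts.index:
            pm = pmhc_counts.loc[sid]
        rows.append(
            burden_record(
                sid,
                int(counts.get(sid, 0)),
                callable_mb,
                pm,
                tmb_high_cutoff,
            )
        )
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "n_nonsynonymous": [r.n_nonsynonymous for r in rows],
            "callable_mb": [r.callable_mb for r in rows],
            "tmb": [r.tmb for r in rows],
            "tmb_class": [r.tmb_class for r in rows],
            "pmhc_count": [r.pmhc_count for r in rows],
            "neoantigen_per_mb": [r.neoantigen_per_mb for r in rows],
        }
    )
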