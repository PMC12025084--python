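"""Cohort-level comparison statistics.

Categorical variables are compared with Pearson's chi-square test (no
continuity correction), falling back to Fisher's exact test on 2x2 tables
whenever any expected cell count is below 5. Continuous variables use the
two-sided Mann-Whitney U test (exact null when both samples are small and
tie-free, tie-corrected normal approximation otherwise). Survival is
summarised by Kaplan-Meier product-limit curves and compared with the
two-group log-rank test. Stratified gene-enrichment comparisons use the
Cochran-Mantel-Haenszel test across subtype strata.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero, matching how clinical
    tables print percentages (0.25 -> 0.3 at one decimal)."""
    x = float(x)
    if not np.isfinite(x):
        return x
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numer: float, denom: float, decimals: int = 1) -> float:
    """Percentage rounded half-up, e.g. 44/3667 -> 1.2."""
    if denom == 0:
        raise DegenerateInputError("percentage with zero denominator")
    return round_half_up(100.0 * numer / denom, decimals)


@dataclass
class GroupComparison:
    """One two-group (or r x c) comparison: test used, statistic, p-value
    and per-group summaries."""

    variable: str
    test: str  # chi_square | fisher | mann_whitney | log_rank
    statistic: float
    p_value: float
    group_summaries: dict = field(default_factory=dict)

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "variable": self.variable,
                "test": self.test,
                "statistic": self.statistic,
                "p_value": self.p_value,
                **{f"group:{k}": v for k, v in self.group_summaries.items()},
            }
        )


def contingency_test(
    counts, variable: str = "", force: Optional[str] = None
) -> GroupComparison:
    """Chi-square by default; Fisher's exact on a 2x2 when any expected
    count < 5 (or when forced). Two-sided p throughout."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise DegenerateInputError("contingency table must be at least 2 x 2")
    if (table < 0).any() or table.sum() == 0:
        raise DegenerateInputError("table needs non-negative counts, total > 0")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateInputError("contingency table has a zero margin")
    expected = sps.contingency.expected_freq(table)
    use_fisher = force == "fisher" or (
        force is None and table.shape == (2, 2) and (expected < 5).any()
    )
    if use_fisher:
        if table.shape != (2, 2):
            raise DegenerateInputError("Fisher's exact test requires a 2x2 table")
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        return GroupComparison(variable, "fisher", float(odds), float(p))
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return GroupComparison(variable, "chi_square", float(chi2), float(p))


def ranksum_test(
    x: Sequence[float],
    y: Sequence[float],
    variable: str = "",
    exact_max_product: int = 400,
) -> GroupComparison:
    """Two-sided Mann-Whitney U test. Exact U distribution when
    n1*n2 <= ``exact_max_product`` and the pooled data are tie-free;
    tie-corrected normal approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise DegenerateInputError("Mann-Whitney requires two non-empty samples")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) * len(y) <= exact_max_product and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparison(
        variable,
        "mann_whitney",
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        group_summaries={
            "x": {"n": len(x), "median": float(np.median(x))},
            "y": {"n": len(y), "median": float(np.median(y))},
        },
    )


def km_logrank(
    times: Sequence[float],
    events: Sequence[int],
    group_labels: Sequence,
    variable: str = "survival",
):
    """Kaplan-Meier curves per group plus the two-group log-rank test.

    Returns ``(GroupComparison, curves)`` where ``curves`` maps each group
    label to a DataFrame with columns ``time`` and ``survival``.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(group_labels)
    if (times < 0).any():
        raise DegenerateInputError("survival times must be non-negative")
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise DegenerateInputError("log-rank comparison needs exactly two groups")
    if events.sum() == 0:
        raise DegenerateInputError("no events observed; log-rank undefined")
    curves = {}
    for g in groups:
        mask = labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    m0, m1 = labels == groups[0], labels == groups[1]
    res = logrank_test(times[m0], times[m1], events[m0], events[m1])
    comp = GroupComparison(
        variable,
        "log_rank",
        float(res.test_statistic),
        float(res.p_value),
        group_summaries={
            str(g): {"n": int((labels == g).sum()), "events": int(events[labels == g].sum())}
            for g in groups
        },
    )
    return comp, curves


# ---------------------------------------------------------------------------
# cohort tables


def prevalence_by_subtype(
    cohort: pd.DataFrame,
    reference: str = "TNBC",
    subtype_col: str = "subtype",
    altered_col: str = "mmr_altered",
) -> pd.DataFrame:
    """Per-subtype MMR-alteration prevalence with pairwise tests against a
    reference subtype (samples with unknown subtype are excluded)."""
    known = cohort[cohort[subtype_col].notna() & (cohort[subtype_col] != "unknown")]
    rows = []
    ref = known[known[subtype_col] == reference]
    ref_alt = int(ref[altered_col].sum())
    for subtype, grp in known.groupby(subtype_col, sort=True):
        n = len(grp)
        altered = int(grp[altered_col].sum())
        row = {
            "subtype": subtype,
            "n_patients": n,
            "mmr_altered": altered,
            "rate_pct": pct(altered, n),
        }
        if subtype == reference:
            row["p_value"] = np.nan
            row["vs_reference"] = "ref"
        else:
            table = [
                [altered, n - altered],
                [ref_alt, len(ref) - ref_alt],
            ]
            try:
                comp = contingency_test(table, variable=f"{subtype} vs {reference}")
                row["p_value"] = comp.p_value
                row["vs_reference"] = comp.test
            except DegenerateInputError:
                row["p_value"] = np.nan
                row["vs_reference"] = "degenerate"
        rows.append(row)
    return pd.DataFrame(rows)


def _categorical_block(
    cohort: pd.DataFrame, col: str, altered_col: str
) -> tuple[pd.DataFrame, float]:
    """Counts and within-group percentages over non-missing values, plus a
    chi-square/Fisher p across the category x group table."""
    obs = cohort[[col, altered_col]].copy()
    missing = obs[col].isna() | (obs[col] == "unknown")
    known = obs[~missing]
    levels = sorted(known[col].unique())
    rows = []
    counts = []
    for level in levels:
        in_level = known[col] == level
        a = int((in_level & known[altered_col]).sum())
        w = int((in_level & ~known[altered_col]).sum())
        counts.append([a, w])
        rows.append({"level": level, "altered_n": a, "wt_n": w})
    n_alt = max(int(known[altered_col].sum()), 1)
    n_wt = max(int((~known[altered_col]).sum()), 1)
    for row, (a, w) in zip(rows, counts):
        row["altered_pct"] = pct(a, n_alt)
        row["wt_pct"] = pct(w, n_wt)
    na_a = int((missing & obs[altered_col]).sum())
    na_w = int((missing & ~obs[altered_col]).sum())
    rows.append(
        {"level": "NA", "altered_n": na_a, "wt_n": na_w,
         "altered_pct": np.nan, "wt_pct": np.nan}
    )
    table = np.asarray(counts)
    p = np.nan
    if table.shape[0] >= 2 and (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
        p = contingency_test(table, variable=col).p_value
    block = pd.DataFrame(rows)
    block.insert(0, "variable", col)
    return block, p


def _continuous_block(
    cohort: pd.DataFrame, col: str, altered_col: str
) -> tuple[pd.DataFrame, float]:
    a = cohort.loc[cohort[altered_col], col].dropna()
    w = cohort.loc[~cohort[altered_col], col].dropna()
    p = ranksum_test(a, w, variable=col).p_value if len(a) and len(w) else np.nan

    def fmt(v: pd.Series) -> dict:
        if len(v) == 0:
            return {k: float("nan") for k in ("median", "min", "max", "mean", "sd")}
        return {
            "median": round_half_up(float(v.median()), 1),
            "min": round_half_up(float(v.min()), 1),
            "max": round_half_up(float(v.max()), 1),
            "mean": round_half_up(float(v.mean()), 1),
            "sd": round_half_up(float(v.std()), 1),
        }

    block = pd.DataFrame(
        [
            {"variable": col, "level": "altered", "n": len(a), **fmt(a)},
            {"variable": col, "level": "wt", "n": len(w), **fmt(w)},
        ]
    )
    return block, p


def clinical_characteristics_table(
    cohort: pd.DataFrame,
    categorical: Sequence[str] = ("subtype", "stage", "tmb_class", "msi_status", "mmrdetect"),
    continuous: Sequence[str] = ("age", "tmb", "neoantigen_per_mb"),
    altered_col: str = "mmr_altered",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Baseline-characteristics comparison between MMR-altered and MMR-wt
    samples: per-variable level counts/percentages over non-missing values
    with an explicit NA row, and one test p-value per variable.

    Returns ``(long_table, p_table)``.
    """
    blocks, ps = [], []
    for col in categorical:
        if col not in cohort.columns:
            continue
        block, p = _categorical_block(cohort, col, altered_col)
        blocks.append(block)
        ps.append({"variable": col, "kind": "categorical", "p_value": p})
    for col in continuous:
        if col not in cohort.columns:
            continue
        block, p = _continuous_block(cohort, col, altered_col)
        blocks.append(block)
        ps.append({"variable": col, "kind": "continuous", "p_value": p})
    long = pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame()
    return long, pd.DataFrame(ps)


def gene_enrichment(
    altered_labels: pd.Series,
    event_matrix: pd.DataFrame,
    stratify_by: Optional[pd.Series] = None,
    min_total_events: int = 1,
) -> pd.DataFrame:
    """Per-gene enrichment of binary events in MMR-altered vs wildtype.

    Parameters
    ----------
    altered_labels : boolean Series indexed by sample.
    event_matrix : sample x gene 0/1 DataFrame (mutation or CNV events).
    stratify_by : optional categorical Series (e.g. molecular subtype);
        when given, a Cochran-Mantel-Haenszel test across strata is added
        as ``p_adjusted_strata``.

    Output is sorted by raw p and carries a Benjamini-Hochberg column.
    Genes with no events in either group are skipped.
    """
    common = event_matrix.index.intersection(altered_labels.index)
    ev = event_matrix.loc[common].astype(bool)
    alt = altered_labels.loc[common].astype(bool)
    strat = stratify_by.loc[common] if stratify_by is not None else None
    rows = []
    for gene in ev.columns:
        e = ev[gene]
        total = int(e.sum())
        if total < min_total_events:
            continue
        a_e = int((e & alt).sum())
        w_e = int((e & ~alt).sum())
        n_a = int(alt.sum())
        n_w = int((~alt).sum())
        table = [[a_e, n_a - a_e], [w_e, n_w - w_e]]
        try:
            comp = contingency_test(table, variable=gene)
        except DegenerateInputError:
            continue
        row = {
            "gene": gene,
            "altered_events": a_e,
            "altered_pct": pct(a_e, n_a),
            "wt_events": w_e,
            "wt_pct": pct(w_e, n_w),
            "test": comp.test,
            "p_value": comp.p_value,
        }
        if strat is not None:
            tables = []
            for _, idx in strat.groupby(strat).groups.items():
                sa = alt.loc[idx]
                se = e.loc[idx]
                t = np.array(
                    [
                        [int((se & sa).sum()), int((~se & sa).sum())],
                        [int((se & ~sa).sum()), int((~se & ~sa).sum())],
                    ]
                )
                if t.sum() > 0:
                    tables.append(t)
            try:
                cmh = StratifiedTable(tables).test_null_odds(correction=False)
                row["p_adjusted_strata"] = float(cmh.pvalue)
            except (ValueError, ZeroDivisionError):
                row["p_adjusted_strata"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
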