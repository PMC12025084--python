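"""Contingency / rank-sum / survival statistics and the cohort tables."""
import math

import numpy as np
import pandas as pd
import pytest

from mmrscan import (
    contingency_test,
    gene_enrichment,
    km_logrank,
    pct,
    prevalence_by_subtype,
    ranksum_test,
    round_half_up,
)
from mmrscan.errors import DegenerateInputError
from mmrscan.stats import clinical_characteristics_table


class TestContingency:
    def test_msi_table_highly_significant(self):
        comp = contingency_test([[7, 19], [13, 1409]], force="chi_square")
        assert comp.test == "chi_square"
        assert comp.p_value < 0.001

    def test_identical_proportions_give_p_one(self):
        comp = contingency_test([[10, 10], [10, 10]])
        assert comp.statistic == pytest.approx(0.0)
        assert comp.p_value == pytest.approx(1.0)

    def test_small_table_routed_to_fisher_and_matches_enumeration(self):
        """Oracle: exhaustive hypergeometric enumeration over all tables
        with the observed margins; two-sided p sums probabilities of tables
        at most as likely as the observed one."""
        table = [[2, 3], [1, 4]]
        comp = contingency_test(table)
        assert comp.test == "fisher"
        r1, r2 = 5, 5
        c1 = 3
        n = 10

        def hyper(a):
            return (
                math.comb(r1, a) * math.comb(n - r1, c1 - a) / math.comb(n, c1)
            )

        p_obs = hyper(2)
        p_two = sum(
            hyper(a)
            for a in range(max(0, c1 - r2), min(r1, c1) + 1)
            if hyper(a) <= p_obs * (1 + 1e-9)
        )
        assert comp.p_value == pytest.approx(p_two, rel=1e-9)

    def test_large_expected_counts_use_chi_square(self):
        comp = contingency_test([[30, 70], [50, 50]])
        assert comp.test == "chi_square"

    def test_chi_square_matches_permutation_null(self):
        """On a well-populated 2x2 the asymptotic chi-square p agrees with a
        10,000-shuffle permutation null within Monte-Carlo error."""
        rng = np.random.default_rng(12)
        table = np.array([[45, 55], [70, 30]])
        comp = contingency_test(table)
        labels = np.repeat([0, 0, 1, 1], [45, 55, 70, 30])
        group = np.repeat([0, 1], [100, 100])
        obs = comp.statistic
        hits = 0
        n_perm = 10000
        for _ in range(n_perm):
            rng.shuffle(labels)
            a = int(labels[:100].sum())
            b = int(labels[100:].sum())
            t = np.array([[100 - a, a], [100 - b, b]])
            exp = np.outer(t.sum(1), t.sum(0)) / t.sum()
            stat = ((t - exp) ** 2 / exp).sum()
            if stat >= obs - 1e-9:
                hits += 1
        p_perm = hits / n_perm
        se = math.sqrt(max(p_perm * (1 - p_perm), 1e-6) / n_perm)
        assert comp.p_value == pytest.approx(p_perm, abs=max(4 * se, 0.01))

    @pytest.mark.parametrize(
        "bad", [[[0, 0], [5, 5]], [[1, 0], [3, 0]]]
    )
    def test_zero_margin_rejected(self, bad):
        with pytest.raises(DegenerateInputError):
            contingency_test(bad)


class TestRankSum:
    def test_identical_samples_not_significant(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        comp = ranksum_test(x, list(x))
        assert comp.p_value > 0.9

    def test_fully_separated_samples(self):
        comp = ranksum_test(np.arange(20), np.arange(100, 120))
        assert comp.test == "mann_whitney"
        assert comp.p_value < 0.001

    def test_exact_path_on_small_tiefree_samples(self):
        # n1*n2 = 9 <= 400, tie-free: exact two-sided p for total separation
        comp = ranksum_test([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert comp.p_value == pytest.approx(2 / math.comb(6, 3), rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(DegenerateInputError):
            ranksum_test([], [1.0])


class TestSurvival:
    def test_identical_groups_null(self):
        times = [5, 10, 15, 20] * 2
        events = [1, 1, 0, 1] * 2
        groups = ["A"] * 4 + ["B"] * 4
        comp, curves = km_logrank(times, events, groups)
        assert comp.statistic == pytest.approx(0.0, abs=1e-9)
        assert comp.p_value == pytest.approx(1.0, abs=1e-6)
        assert set(curves) == {"A", "B"}

    def test_early_events_vs_all_censored(self):
        times = [1.0] * 20 + [10.0] * 20
        events = [1] * 20 + [0] * 20
        groups = ["A"] * 20 + ["B"] * 20
        comp, _ = km_logrank(times, events, groups)
        assert comp.p_value < 0.01

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(13)
        t = rng.exponential(10, size=50).round(3)
        comp, curves = km_logrank(
            np.concatenate([t, t]), np.ones(100, int),
            ["A"] * 50 + ["B"] * 50,
        )
        curve = curves["A"].set_index("time")["survival"]
        for time_pt in [2.0, 5.0, 10.0]:
            emp = (t > time_pt).mean()
            km = curve[curve.index <= time_pt].iloc[-1]
            assert km == pytest.approx(emp, abs=1e-9)

    def test_no_events_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            km_logrank([1, 2, 3, 4], [0, 0, 0, 0], ["A", "A", "B", "B"])

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            km_logrank([1, 2, 3], [1, 1, 0], ["A", "A", "A"])


class TestRounding:
    @pytest.mark.parametrize(
        "numer,denom,expected",
        [(44, 3667, 1.2), (16, 2049, 0.8), (5, 399, 1.3), (12, 392, 3.1),
         (12, 33, 36.4), (7, 26, 26.9)],
    )
    def test_pct_half_up(self, numer, denom, expected):
        assert pct(numer, denom) == expected

    def test_ties_round_away_from_zero(self):
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(0.35, 1) == 0.4
        assert pct(1, 8) == 12.5


@pytest.fixture(scope="module")
def cohort():
    rng = np.random.default_rng(21)
    n = 2000
    subtype = rng.choice(["HR+HER2-", "HER2+", "TNBC"], size=n,
                         p=[0.72, 0.14, 0.14])
    rate = np.select(
        [subtype == "TNBC", subtype == "HER2+"], [0.10, 0.04], 0.02
    )
    altered = rng.random(n) < rate
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "subtype": subtype,
            "mmr_altered": altered,
            "age": rng.normal(55, 12, size=n).round(),
            "tmb": rng.lognormal(0, 1, size=n),
        }
    )


class TestCohortTables:
    def test_rates_equal_groupby_count_oracle(self, cohort):
        tbl = prevalence_by_subtype(cohort).set_index("subtype")
        oracle = cohort.groupby("subtype")["mmr_altered"].agg(["sum", "size"])
        for subtype, row in oracle.iterrows():
            expected = round(100 * row["sum"] / row["size"], 1)
            assert tbl.loc[subtype, "rate_pct"] == pytest.approx(expected)
        assert tbl.loc["TNBC", "vs_reference"] == "ref"
        assert tbl.loc["HR+HER2-", "p_value"] < 0.001

    def test_all_wildtype_cohort_rates_are_zero(self, cohort):
        quiet = cohort.assign(mmr_altered=False)
        tbl = prevalence_by_subtype(quiet)
        assert (tbl["rate_pct"] == 0.0).all()

    def test_characteristics_table_na_accounting(self, cohort):
        df = cohort.copy()
        df.loc[df.index[:200], "subtype"] = "unknown"
        long, ps = clinical_characteristics_table(
            df, categorical=["subtype"], continuous=["age", "tmb"]
        )
        block = long[long["variable"] == "subtype"]
        na_row = block[block["level"] == "NA"]
        assert int(na_row["altered_n"].iloc[0] + na_row["wt_n"].iloc[0]) == 200
        known = block[block["level"] != "NA"]
        assert int(known["altered_n"].sum() + known["wt_n"].sum()) == len(df) - 200
        assert set(ps["variable"]) == {"subtype", "age", "tmb"}


class TestGeneEnrichment:
    def test_powered_difference_flagged_and_null_not(self):
        rng = np.random.default_rng(31)
        n_alt, n_wt = 40, 3000
        idx = [f"S{i}" for i in range(n_alt + n_wt)]
        altered = pd.Series([True] * n_alt + [False] * n_wt, index=idx)
        events = pd.DataFrame(
            {
                "HOT": np.concatenate(
                    [rng.random(n_alt) < 0.6, rng.random(n_wt) < 0.3]
                ),
                "FLAT": rng.random(n_alt + n_wt) < 0.3,
            },
            index=idx,
        ).astype(int)
        out = gene_enrichment(altered, events).set_index("gene")
        assert out.loc["HOT", "p_value"] < 0.001
        assert out.loc["FLAT", "p_value"] > 0.05

    def test_subtype_confounding_resolved_by_stratified_test(self):
        """Simpson-style fixture: the event rate depends only on subtype,
        but alteration is concentrated in one subtype — the unadjusted test
        fires, the stratum-combined (CMH) test must not."""
        rng = np.random.default_rng(32)
        rows = []
        # stratum A: high event rate, most altered samples live here
        for i in range(400):
            rows.append(("A", i < 60, rng.random() < 0.5))
        # stratum B: low event rate, almost no altered samples
        for i in range(2000):
            rows.append(("B", i < 5, rng.random() < 0.05))
        df = pd.DataFrame(rows, columns=["stratum", "altered", "event"])
        df.index = [f"S{i}" for i in range(len(df))]
        out = gene_enrichment(
            df["altered"],
            df[["event"]].astype(int).rename(columns={"event": "CONF"}),
            stratify_by=df["stratum"],
        ).set_index("gene")
        assert out.loc["CONF", "p_value"] < 0.01
        assert out.loc["CONF", "p_adjusted_strata"] > 0.05

    def test_zero_event_gene_skipped(self):
        idx = ["S1", "S2", "S3", "S4"]
        altered = pd.Series([True, True, False, False], index=idx)
        events = pd.DataFrame({"NONE": [0, 0, 0, 0], "SOME": [1, 0, 1, 0]},
                              index=idx)
        out = gene_enrichment(altered, events)
        assert list(out["gene"]) == ["SOME"]
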