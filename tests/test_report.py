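"""Cohort summaries: frequencies, concordance, completeness, G6PD tables.

The worked examples pin the published Tanzanian-cohort numbers, computed
here from the shipped genotype-count inputs."""

import numpy as np
import pandas as pd
import pytest

from amplitype.datasets import (CONCORDANCE_TOTALS, cohort_genotype_counts,
                                concordance_tables, g6pd_phenotype_table)
from amplitype.report import (allele_count_frequency, carrier_frequency,
                              completeness, concordance, g6pd_distribution,
                              homozygote_frequency, round_half_up,
                              site_summary, summarize_sites)


def _counts(df, rsid):
    row = df[df["rsid"] == rsid].iloc[0]
    return int(row["hom_ref"]), int(row["het"]), int(row["hom_alt"])


class TestFrequencies:
    @pytest.mark.parametrize("rsid, expected", [
        ("rs334", 9.1),          # 9/99 carriers of HbS
        ("rs1050828", 18.4),     # 16/87
        ("rs1050829", 44.8),     # 39/87
        ("rs2814778", 100.0),    # 95/95, Duffy negative fixed
        ("rs186873296", 3.1),    # 3/98 Dantu
        ("rs2230036", 12.1),     # 12/99
        ("rs5986875", 1.0),      # 1/99
        ("rs713040", 95.8),      # 92/96
    ])
    def test_published_carrier_percentages(self, rsid, expected):
        df = cohort_genotype_counts()
        assert carrier_frequency(_counts(df, rsid)) == expected

    @pytest.mark.parametrize("rsid, expected", [
        ("rs713040", 67.7),      # 65/96 homozygous
        ("rs1050829", 26.4),     # 23/87
    ])
    def test_published_homozygote_percentages(self, rsid, expected):
        df = cohort_genotype_counts()
        assert homozygote_frequency(_counts(df, rsid)) == expected

    def test_trivial_cases(self):
        assert carrier_frequency((10, 0, 0)) == 0.0
        assert homozygote_frequency((5, 5, 0)) == 0.0
        assert carrier_frequency((0, 0, 95)) == 100.0

    def test_allele_count_frequency_distinct_from_carrier(self):
        # 8 het + 8 hom among 87: carriers 18.4%, allele count 13.8%
        assert allele_count_frequency((71, 8, 8)) == round_half_up(
            100 * 24 / 174, 1)
        assert carrier_frequency((71, 8, 8)) == 18.4

    def test_empty_counts_signal(self):
        with pytest.raises(ValueError):
            carrier_frequency((0, 0, 0))

    def test_table_variant_differs_only_at_rs334_split(self):
        text = cohort_genotype_counts("text")
        table = cohort_genotype_counts("table")
        assert _counts(text, "rs334") == (90, 5, 4)
        assert _counts(table, "rs334") == (90, 4, 5)
        assert carrier_frequency(_counts(table, "rs334")) == 9.1


class TestSiteSummary:
    def _table_from_counts(self, rsid="rs334"):
        df = cohort_genotype_counts()
        hom_ref, het, hom_alt = _counts(df, rsid)
        row = df[df["rsid"] == rsid].iloc[0]
        rows = []
        i = 0
        for cls, n in (("hom_ref", hom_ref), ("het", het),
                       ("hom_alt", hom_alt), ("no_call", 1)):
            for _ in range(n):
                rows.append({"sample_id": f"s{i}", "site_key": row.site_key,
                             "rsid": rsid, "folded": cls,
                             "depth": 100 if cls != "no_call" else 3})
                i += 1
        return pd.DataFrame(rows)

    def test_no_call_excluded_from_denominator_and_depth(self):
        table = self._table_from_counts()
        summ = site_summary(table, "11:5227002")
        assert summ.n_genotyped == 99
        assert summ.carrier_pct == 9.1
        assert summ.mean_depth == 100.0

    def test_all_no_call_undefined(self):
        table = pd.DataFrame([
            {"sample_id": "a", "site_key": "k", "rsid": "r",
             "folded": "no_call", "depth": 0},
        ])
        summ = site_summary(table, "k")
        assert summ.n_genotyped == 0
        assert summ.carrier_pct is None


class TestConcordance:
    def test_published_totals_reproduce_discordance(self):
        called, ref = concordance_tables(*CONCORDANCE_TOTALS, seed=1)
        rep = concordance(called, ref)
        assert rep.n_compared == 962
        assert rep.n_discordant == 4
        assert rep.discordance_pct == 0.42
        assert rep.discordance_per_1000 == 4.2

    def test_identical_tables_fully_concordant(self):
        called, _ = concordance_tables(200, 0, seed=2)
        rep = concordance(called, called.copy())
        assert rep.n_discordant == 0
        assert rep.concordance_pct == 100.0

    def test_matches_brute_force_pairwise_count(self):
        """Planted-mismatch tables: the report equals an explicit
        pair-by-pair comparison."""
        rng = np.random.default_rng(3)
        for k in (0, 1, 7, 23):
            called, ref = concordance_tables(200, k, seed=int(rng.integers(1e6)))
            rep = concordance(called, ref)
            # brute force
            ref_map = {(r.sample_id, r.site_key): r.genotype
                       for r in ref.itertuples()}
            n = d = 0
            for r in called.itertuples():
                other = ref_map.get((r.sample_id, r.site_key))
                if other is None:
                    continue
                n += 1
                d += (other != r.genotype)
            assert (rep.n_compared, rep.n_discordant) == (n, d)
            assert rep.discordance_pct == round_half_up(100 * d / n, 2)

    def test_symmetric_in_arguments(self):
        called, ref = concordance_tables(150, 5, seed=9)
        a = concordance(called, ref)
        b = concordance(ref, called)
        assert (a.n_compared, a.n_discordant) == (b.n_compared, b.n_discordant)

    def test_no_call_and_missing_rows_excluded(self):
        called, ref = concordance_tables(50, 2, seed=4)
        called.loc[0, "genotype"] = "no_call"   # drops the pair
        ref = ref.drop(index=1)                  # drops a different pair
        rep = concordance(called, ref)
        assert rep.n_compared == 48

    def test_hemizygous_compared_on_folded_class(self):
        called = pd.DataFrame([
            {"sample_id": "m1", "site_key": "X:1", "genotype": "hemi_alt"},
        ])
        ref = pd.DataFrame([
            {"sample_id": "m1", "site_key": "X:1", "genotype": "hom_alt"},
        ])
        assert concordance(called, ref).n_discordant == 0

    def test_zero_comparable_pairs_signal(self):
        a = pd.DataFrame([{"sample_id": "x", "site_key": "k",
                           "genotype": "no_call"}])
        with pytest.raises(ValueError):
            concordance(a, a.copy())


class TestCompleteness:
    def _calls(self, panel, fail_amplicons=(), sample="s0"):
        rows = []
        for amp in panel.amplicons:
            for s in amp.sites:
                failed = amp.amplicon_id in fail_amplicons
                rows.append({
                    "sample_id": sample, "site_key": s.key, "rsid": s.rsid,
                    "folded": "no_call" if failed else "hom_ref",
                    "depth": 0 if failed else 100,
                })
        return pd.DataFrame(rows)

    def test_buckets(self, panel):
        table = pd.concat([
            self._calls(panel, (), "full"),
            self._calls(panel, ("DANTU_1",), "one_fail"),
            self._calls(panel, ("DANTU_1", "HBB_1"), "two_fail"),
            self._calls(panel, tuple(a.amplicon_id for a in panel.amplicons),
                        "all_fail"),
        ])
        comp = completeness(table, panel)
        assert comp["n_samples"] == 4
        assert comp["histogram"] == {0: 1, 1: 1, 2: 1, 7: 1}
        assert comp["n_fully_profiled"] == 1
        assert comp["failed_per_sample"]["one_fail"] == 1


class TestG6PDDistribution:
    def test_published_class_table(self):
        """43 classified males (25 B / 13 A+ / 5 A-), 40 females; 8 of 83
        severely deficient."""
        dist = g6pd_distribution(g6pd_phenotype_table())
        male = dist["by_sex"]["male"]
        assert male["n"] == 43
        assert male["pct"] == {"B": 58.1, "A+": 30.2, "A-": 11.6}
        female = dist["by_sex"]["female"]
        assert female["n"] == 40
        assert female["pct"]["BB"] == 52.5
        assert dist["n_classified"] == 83
        assert dist["severe_pct"] == 9.6

    def test_per_sex_percentages_sum_to_hundred(self):
        dist = g6pd_distribution(g6pd_phenotype_table())
        for sex, d in dist["by_sex"].items():
            assert sum(d["pct"].values()) == pytest.approx(
                100.0, abs=0.1 * len(d["pct"]))

    def test_empty_input_signal(self):
        empty = pd.DataFrame(columns=["sample_id", "sex", "g6pd_class",
                                      "g6pd_severe"])
        with pytest.raises(ValueError):
            g6pd_distribution(empty)


class TestEndToEndConservation:
    def test_site_counts_match_truth_on_error_free_run(self, panel):
        """Error-free simulated cohort: summary counts from calls equal
        counts computed directly from truth."""
        from amplitype.pipeline import (run_simulated_pipeline,
                                        truth_calls_table)
        from amplitype.simulate import SimConfig

        cfg = SimConfig(n_samples=12, mean_depth=60.0, error_rate=0.0,
                        depth_multipliers={}, seed=31)
        res = run_simulated_pipeline(panel, cfg)
        truth = truth_calls_table(res.truth, panel)
        from amplitype.caller import FOLDED

        truth["folded"] = truth["genotype"].map(FOLDED)
        summ = summarize_sites(res.calls, panel)
        for s in panel.sites:
            t = truth[truth["site_key"] == s.key]["folded"].value_counts()
            row = summ[summ["site_key"] == s.key].iloc[0]
            assert row["hom_ref"] == t.get("hom_ref", 0)
            assert row["het"] == t.get("het", 0)
            assert row["hom_alt"] == t.get("hom_alt", 0)


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(0.15, 1) == 0.2
    assert round_half_up(0.25, 1) == 0.3
    assert round_half_up(2.345, 2) == 2.35
    assert round_half_up(-0.15, 1) == -0.2
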