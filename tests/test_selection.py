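"""rDI, Fisher exact, AFS rank tests, enrichment and FST."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from indelstrata import (
    ContingencyTable,
    afs_compare,
    category_contrast,
    fisher_exact_2x2,
    fst_hudson,
    mk_table,
    rdi,
    region_class_contrast,
    score_filter,
    simulate_mk_counts,
)
from indelstrata.selection import assign_region_class


def indel_frame(counts):
    """counts: dict (stratum_value, event) -> n; builds a minimal indel table."""
    rows = []
    for (stratum, event), n in counts.items():
        for _ in range(n):
            rows.append(stratum + (event,))
    cols = ["fixation", "sharing", "length", "event"]
    return pd.DataFrame(rows, columns=cols[: len(rows[0]) - 1] + ["event"])


class TestMkTable:
    def test_fixation_split_counts(self):
        df = pd.DataFrame(
            dict(
                fixation=["fixed"] * 5 + ["polymorphic"] * 7,
                event=["deletion"] * 3 + ["insertion"] * 2
                + ["deletion"] * 4 + ["insertion"] * 3,
                length=[1] * 12,
            )
        )
        t = mk_table(df, split_by="fixation")
        assert (t.a, t.b, t.c, t.d) == (3, 2, 4, 3)
        assert t.row_labels == ("fixed", "polymorphic")

    def test_by_length_stratification_sums_to_pooled(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            dict(
                fixation=rng.choice(["fixed", "polymorphic"], 300),
                event=rng.choice(["deletion", "insertion"], 300),
                length=rng.integers(1, 6, 300),
            )
        )
        tables = mk_table(df, split_by="fixation", by_length=True)
        pooled = tables["pooled"]
        assert sum(tables[L].a for L in range(1, 6)) == pooled.a
        assert sum(tables[L].total for L in range(1, 6)) == pooled.total

    def test_sharing_split_excludes_uncovered(self):
        df = pd.DataFrame(
            dict(
                sharing=["archaic_shared", "modern_specific", "uncovered"],
                event=["deletion"] * 3,
                length=[1] * 3,
            )
        )
        t = mk_table(df, split_by="sharing")
        assert t.total == 2

    def test_empty_input_gives_zero_table(self):
        df = pd.DataFrame(columns=["fixation", "event", "length"])
        t = mk_table(df)
        assert t.total == 0


class TestRdi:
    def test_ratio_and_errors(self):
        assert rdi(10, 5) == 2.0
        assert rdi(7, 7) == 1.0
        with pytest.raises(ValueError):
            rdi(3, 0)


def fisher_oracle(a, b, c, d):
    """Exact two-sided p by full enumeration with rational arithmetic."""
    n1, n2, k = a + b, c + d, a + c
    denom = math.comb(n1 + n2, k)
    probs = {}
    for x in range(max(0, k - n2), min(n1, k) + 1):
        probs[x] = Fraction(math.comb(n1, x) * math.comb(n2, k - x), denom)
    obs = probs[a]
    return float(sum(p for p in probs.values() if p <= obs * Fraction(10**7 + 1, 10**7)))


class TestFisherExact:
    def test_symmetric_table(self):
        r = fisher_exact_2x2(ContingencyTable(10, 10, 10, 10))
        assert r.odds_ratio_sample == 1.0
        assert r.p_two_sided == pytest.approx(1.0)

    def test_against_enumeration_oracle(self):
        r = fisher_exact_2x2(ContingencyTable(5, 1, 2, 8))
        assert r.p_two_sided == pytest.approx(fisher_oracle(5, 1, 2, 8), abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                     st.integers(0, 12), st.integers(0, 12)))
    def test_all_small_tables_match_enumeration(self, t):
        a, b, c, d = t
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        r = fisher_exact_2x2(ContingencyTable(a, b, c, d), compute_cmle=False)
        assert r.p_two_sided == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)
        # independent library cross-check
        assert r.p_two_sided == pytest.approx(
            stats.fisher_exact([[a, b], [c, d]])[1], abs=1e-9
        )

    def test_log_p_is_finite_below_double_underflow(self):
        r = fisher_exact_2x2(ContingencyTable(205_075, 155_818, 604_423, 266_969))
        assert r.p_two_sided == 0.0  # underflows as a plain float
        assert np.isfinite(r.log10_p) and r.log10_p < -1000

    def test_conditional_mle_close_to_sample_or_for_large_tables(self):
        r = fisher_exact_2x2(ContingencyTable(205_075, 155_818, 604_423, 266_969))
        assert r.odds_ratio_cmle == pytest.approx(r.odds_ratio_sample, rel=1e-4)

    def test_zero_margin_convention(self):
        with pytest.warns(UserWarning):
            r = fisher_exact_2x2(ContingencyTable(0, 0, 5, 5))
        assert r.p_two_sided == 1.0


def rank_sum_oracle(x, y):
    """Two-sided permutation p for the rank-sum statistic, mid-ranks for ties."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    mu = n1 * (len(pooled) + 1) / 2
    obs = abs(ranks[:n1].sum() - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestAfsCompare:
    def test_identical_samples_not_significant(self):
        w, p, _ = afs_compare([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert p == 1.0

    def test_complete_separation_is_significant(self):
        rng = np.random.default_rng(1)
        a = np.full(20, 0.01) + rng.normal(0, 1e-4, 20)
        b = np.full(20, 0.5) + rng.normal(0, 1e-4, 20)
        _, p, _ = afs_compare(a, b, method="asymptotic")
        assert p < 0.01

    def test_exact_p_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(2)
        x, y = rng.random(8), rng.random(9)
        _, p, _ = afs_compare(x, y, method="exact")
        assert p == pytest.approx(
            stats.mannwhitneyu(x, y, method="exact").pvalue, abs=1e-9
        )

    def test_exact_p_matches_enumeration_with_ties(self):
        x = np.array([0.1, 0.1, 0.2, 0.5, 0.5, 0.9])
        y = np.array([0.1, 0.2, 0.2, 0.5, 0.8])
        _, p, _ = afs_compare(x, y, method="exact")
        assert p == pytest.approx(rank_sum_oracle(x, y), abs=1e-9)

    def test_binned_spectra_sum_to_sample_sizes(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(100), rng.random(80)
        _, _, spec = afs_compare(a, b, method="asymptotic")
        assert spec["counts_a"].sum() == 100
        assert spec["counts_b"].sum() == 80

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            afs_compare([], [0.1])


class TestRegionClassContrast:
    def planted(self):
        rows = (
            [("intergenic", "deletion")] * 400 + [("intergenic", "insertion")] * 200
            + [("intronic", "deletion")] * 400 + [("intronic", "insertion")] * 400
        )
        return pd.DataFrame(rows, columns=["region", "event"])

    def test_planted_deletion_enrichment_detected(self):
        res = region_class_contrast(self.planted(), contrasts=[("insertion", "deletion")])
        row = res[res["region"] == "intergenic"].iloc[0]
        assert row["odds_ratio"] < 1
        assert row["ci_high"] < 1
        assert row["significant"]

    def test_null_proportions_give_no_discovery(self):
        rows = (
            [("intergenic", "deletion")] * 300 + [("intergenic", "insertion")] * 150
            + [("intronic", "deletion")] * 300 + [("intronic", "insertion")] * 150
        )
        df = pd.DataFrame(rows, columns=["region", "event"])
        res = region_class_contrast(df, contrasts=[("insertion", "deletion")])
        assert not res["significant"].any()

    def test_single_indel_degenerate_table_flagged(self):
        df = pd.DataFrame([("intergenic", "deletion")], columns=["region", "event"])
        res = region_class_contrast(df, contrasts=[("insertion", "deletion")])
        assert res["degenerate"].all()

    def test_bh_adjustment_is_monotone(self):
        rng = np.random.default_rng(4)
        rows = [
            (r, e)
            for r in ["a", "b", "c", "d"]
            for e in rng.choice(["deletion", "insertion"], 120, p=[0.5 + 0.02 * ord(r[0]) % 3 / 10, 0.5 - 0.02 * ord(r[0]) % 3 / 10])
        ]
        df = pd.DataFrame(rows, columns=["region", "event"])
        res = region_class_contrast(df, contrasts=[("insertion", "deletion")]).dropna(
            subset=["p"]
        )
        assert (res["p_fdr"] >= res["p"] - 1e-12).all()
        srt = res.sort_values("p")
        assert srt["p_fdr"].is_monotonic_increasing

    def test_assign_region_class_uses_covering_interval(self):
        ann = pd.DataFrame(
            [("chr1", 0, 100, "coding"), ("chr1", 100, 200, "intronic")],
            columns=["chrom", "start", "end", "region"],
        )
        df = pd.DataFrame(
            [("chr1", 50), ("chr1", 150), ("chr1", 500)], columns=["chrom", "pos"]
        )
        out = assign_region_class(df, ann)
        assert list(out["region"]) == ["coding", "intronic", "intergenic"]


class TestCategoryContrast:
    def test_doubled_share_is_flagged(self):
        cats = pd.DataFrame(
            [
                dict(category="GO:1", countA=100, countB=100, totalA=1000, totalB=3000),
                dict(category="GO:2", countA=50, countB=150, totalA=1000, totalB=3000),
            ]
        )
        res = category_contrast(cats)
        assert res.set_index("category").loc["GO:1", "enriched"]
        assert not res.set_index("category").loc["GO:2", "enriched"]

    def test_global_share_categories_not_flagged(self):
        cats = pd.DataFrame(
            [dict(category=f"GO:{i}", countA=25, countB=75, totalA=1000, totalB=3000)
             for i in range(5)]
        )
        assert not category_contrast(cats)["enriched"].any()

    def test_single_category_bonferroni_m_equals_one(self):
        cats = pd.DataFrame(
            [dict(category="GO:1", countA=61, countB=39, totalA=500, totalB=500)]
        )
        res = category_contrast(cats)
        assert res.iloc[0]["p"] == res.iloc[0]["p_fwer"]
        assert res.iloc[0]["enriched"]

    def test_empty_categories_excluded(self):
        cats = pd.DataFrame(
            [dict(category="GO:1", countA=0, countB=0, totalA=10, totalB=10)]
        )
        assert category_contrast(cats).empty


class TestScoreFilter:
    def base(self):
        return pd.DataFrame(
            [
                dict(chrom="chr1", pos=10, ancestral="T", derived=""),
                dict(chrom="chr1", pos=20, ancestral="", derived="AC"),
                dict(chrom="chr1", pos=30, ancestral="G", derived=""),
                dict(chrom="chr1", pos=40, ancestral="G", derived=""),
            ]
        )

    def test_threshold_is_inclusive(self):
        scores = pd.DataFrame(
            [
                dict(chrom="chr1", pos=10, ancestral="T", derived="", score=19.9),
                dict(chrom="chr1", pos=20, ancestral="", derived="AC", score=20.0),
                dict(chrom="chr1", pos=30, ancestral="G", derived="", score=31.2),
            ]
        )
        kept, n_unjoined = score_filter(self.base(), scores)
        assert list(kept["score"]) == [31.2, 20.0]
        assert n_unjoined == 1

    def test_empty_score_table(self):
        scores = pd.DataFrame(columns=["chrom", "pos", "ancestral", "derived", "score"])
        kept, n_unjoined = score_filter(self.base(), scores)
        assert kept.empty and n_unjoined == 4

    def test_duplicate_scores_keep_highest(self):
        scores = pd.DataFrame(
            [
                dict(chrom="chr1", pos=10, ancestral="T", derived="", score=25.0),
                dict(chrom="chr1", pos=10, ancestral="T", derived="", score=22.0),
            ]
        )
        kept, _ = score_filter(self.base(), scores)
        assert len(kept) == 1 and kept.iloc[0]["score"] == 25.0


class TestFstHudson:
    def test_equal_frequencies_give_zero(self):
        assert fst_hudson(0.3, 100, 0.3, 100) == 0.0

    def test_fixed_difference_gives_one(self):
        assert fst_hudson(0.0, 100, 1.0, 100) == 1.0

    def test_formula_value(self):
        # (0.09 - 0.1*0.9/99 - 0.4*0.6/99) / (0.1*0.6 + 0.4*0.9)
        assert fst_hudson(0.1, 100, 0.4, 100) == pytest.approx(0.2063492, abs=1e-6)

    def test_monomorphic_both_raises(self):
        with pytest.raises(ValueError):
            fst_hudson(0.0, 100, 0.0, 100)


class TestNeutralCalibration:
    def test_rdi_converges_to_rate_ratio_under_neutrality(self):
        t = simulate_mk_counts(2.0, 1.0, 100_000, 100_000, seed=11)
        fixed_rdi, poly_rdi = t.row_rdi
        assert fixed_rdi == pytest.approx(2.0, rel=0.02)
        assert poly_rdi == pytest.approx(2.0, rel=0.02)

    def test_zero_draws_give_zero_table(self):
        t = simulate_mk_counts(2.0, 1.0, 0, 0, seed=1)
        assert t.total == 0
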