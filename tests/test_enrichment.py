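"""Fisher enrichment vs the reference database and its classification rules."""

import math

import numpy as np
import pytest
from scipy import stats

from rava.enrichment import (
    ReferenceCounts,
    absent_variant_chisq,
    aggregate_selected_frequency,
    allele_frequency,
    classify_two_stage,
    fisher_vs_reference,
    haplotype_pool_test,
    reconstruct_ref_an,
)
from rava.fixtures import CTRL_N, MS_COMBINED_N, load_selected_fixture
from rava.types import Consequence, VariantRecord


def exhaustive_fisher_two_sided(table) -> float:
    """Oracle: enumerate the full hypergeometric support and sum the
    probabilities of tables no more likely than the observed one."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {x: stats.hypergeom.pmf(x, n, col1, row1) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


class TestReconstructRefAn:
    @pytest.mark.parametrize(
        "ref_af,ref_ac,expected_an",
        [(8.14e-6, 2, 245700), (4.06e-6, 1, 246305)],
    )
    def test_an_recovered_from_printed_af_ac_pairs(self, ref_af, ref_ac, expected_an):
        ref = reconstruct_ref_an(ref_af, ref_ac)
        assert ref.ref_an == expected_an and ref.ref_ac == ref_ac

    def test_database_absent_uses_default_an(self):
        ref = reconstruct_ref_an(None, 0)
        assert ref == ReferenceCounts(0, 246000)
        assert reconstruct_ref_an(None, None) == ReferenceCounts(0, 246000)

    def test_zero_af_with_positive_ac_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_ref_an(0.0, 2)


class TestFisherVsReference:
    def test_equal_proportions_give_p_one(self):
        assert fisher_vs_reference(1, 100, ReferenceCounts(10, 1000)).p_value == pytest.approx(1.0)

    def test_rare_case_excess_is_significant(self):
        # 2 alleles in 350 vs 2 in ~246k: the printed starred-variant pattern
        ref = reconstruct_ref_an(8.14e-6, 2)
        out = fisher_vs_reference(2, 350, ref)
        assert out.p_value < 0.01

    def test_matches_exhaustive_enumeration_on_small_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            a, b, c, d = rng.integers(0, 13, size=4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            table = [[int(a), int(b)], [int(c), int(d)]]
            p_pkg = fisher_vs_reference(int(a), int(a + b), ReferenceCounts(int(c), int(c + d))).p_value
            assert p_pkg == pytest.approx(exhaustive_fisher_two_sided(table), abs=1e-12)

    def test_p_monotone_decreasing_in_cohort_ac(self):
        ref = ReferenceCounts(5, 246000)
        ps = [fisher_vs_reference(ac, 350, ref).p_value for ac in range(0, 6)]
        assert all(ps[i + 1] <= ps[i] + 1e-12 for i in range(1, 5))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_vs_reference(10, 5, ReferenceCounts(1, 100))


def _variant():
    return VariantRecord("8", 90782096, "C", "T", gene="RIPK2",
                         consequence=Consequence.missense, cadd_phred=32.0)


class TestTwoStageClassification:
    def test_db_absent_multiproband_variant_is_ms_enriched(self):
        ref = reconstruct_ref_an(None, 0)
        res = classify_two_stage(_variant(), 2, 350, 0, 288, ref)
        assert res.classification == "ms_enriched"
        assert res.p_case_vs_ref < 0.01 <= res.p_ctrl_vs_ref

    def test_singleton_is_not_multiproband(self):
        res = classify_two_stage(_variant(), 1, 350, 0, 288, reconstruct_ref_an(None, 0))
        assert res.classification == "not_multiproband"
        assert res.p_case_vs_ref is None

    def test_control_significant_is_population_specific(self):
        ref = ReferenceCounts(10, 246000)
        res = classify_two_stage(_variant(), 8, 350, 9, 288, ref)
        assert res.p_ctrl_vs_ref < 0.01
        assert res.classification == "population_specific"

    def test_ms_enriched_excludes_control_significant(self):
        # mutual exclusion scanned over a grid of count configurations
        ref = ReferenceCounts(4, 246000)
        for ms_ac in range(2, 12):
            for ctrl_ac in range(0, 12):
                res = classify_two_stage(_variant(), ms_ac, 350, ctrl_ac, 288, ref)
                if res.classification == "ms_enriched":
                    assert res.p_ctrl_vs_ref >= 0.01

    def test_homozygote_carrier_threshold(self):
        # 2 alleles carried by a single homozygous proband: not multiproband
        res = classify_two_stage(_variant(), 2, 350, 0, 288,
                                 reconstruct_ref_an(None, 0), ms_carriers=1)
        assert res.classification == "not_multiproband"


class TestAbsentVariantChisq:
    def test_identical_proportions_give_p_one(self):
        assert absent_variant_chisq(10, 100, 10, 100) == pytest.approx(1.0)

    def test_matches_hand_computed_yates_formula(self):
        table = np.array([[25, 175], [5, 195]])
        n = table.sum()
        row = table.sum(axis=1)
        col = table.sum(axis=0)
        expected_cells = np.outer(row, col) / n
        stat = ((np.abs(table - expected_cells) - 0.5) ** 2 / expected_cells).sum()
        p_hand = float(stats.chi2.sf(stat, df=1))
        assert absent_variant_chisq(25, 200, 5, 200) == pytest.approx(p_hand, abs=1e-12)

    def test_calibrated_under_equal_proportions(self):
        rng = np.random.default_rng(19)
        n_rep, alpha = 800, 0.05
        rej = 0
        for _ in range(n_rep):
            a = rng.binomial(200, 0.12)
            c = rng.binomial(200, 0.12)
            if a + c == 0 or (200 - a) + (200 - c) == 0:
                continue
            rej += absent_variant_chisq(a, 200, c, 200) < alpha
        se = math.sqrt(alpha * (1 - alpha) / n_rep)
        assert rej / n_rep <= alpha + 2 * se  # Yates correction is conservative

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            absent_variant_chisq(0, 100, 0, 100)


class TestHaplotypePool:
    def test_co_occurring_pair_pooled_significant(self):
        # two perfectly co-occurring singletons seen in 2 probands across the
        # combined replication cohorts, vs a haplotype frequency ~4e-6
        ref = reconstruct_ref_an(4.06e-6, 1)
        out = haplotype_pool_test([("17", 1, "A", "G"), ("17", 2, "C", "T")],
                                  ms_ac_pooled=2, ms_an=700, ref_pooled=ref,
                                  per_variant_ms_ac=[2, 2])
        assert out.p_value < 0.01

    def test_single_variant_pool_reduces_to_plain_fisher(self):
        ref = ReferenceCounts(3, 246000)
        pooled = haplotype_pool_test([("1", 1, "A", "C")], 2, 350, ref)
        plain = fisher_vs_reference(2, 350, ref)
        assert pooled == plain

    def test_inconsistent_counts_refused(self):
        with pytest.raises(ValueError, match="do not co-occur"):
            haplotype_pool_test([("1", 1, "A", "C"), ("1", 2, "A", "C")],
                                2, 350, ReferenceCounts(1, 246000),
                                per_variant_ms_ac=[2, 3])


class TestAggregateFrequency:
    def test_printed_totals_round_to_table_values(self):
        sel = load_selected_fixture()
        ms = allele_frequency(sel["ms_ac"].sum(), MS_COMBINED_N)
        ctrl = allele_frequency(sel["ctrl_ac"].sum(), CTRL_N)
        assert ms.exact == pytest.approx(29 / 350)
        assert ms.reported == 0.08
        assert ctrl.reported == 0.01

    def test_matrix_based_aggregation(self, tiny_records, tiny_gm, tiny_design):
        selected = [r for r in tiny_records if r.consequence is not Consequence.synonymous
                    and (r.ref_af or 0) < 1e-4]
        out = aggregate_selected_frequency(selected, "MS_combined", tiny_design, tiny_gm)
        # cases S0..S3 carry 3 alleles over 2 selected variants, 2 x 4 alleles
        assert out.exact == pytest.approx(3 / 8)

    def test_empty_selection_and_empty_cohort(self, tiny_gm, tiny_design):
        out = aggregate_selected_frequency([], "CTRL", tiny_design, tiny_gm)
        assert out.exact == 0.0
        with pytest.raises(ValueError):
            allele_frequency(1, 0)
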