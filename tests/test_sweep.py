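"""Cutoff sweeps, the joint grid and the selected-variant classifier."""

import numpy as np
import pytest

from rava.fixtures import selected_fixture_records
from rava.simulate import SimulationConfig, simulate_dataset
from rava.sweep import (
    SelectionCriteria,
    classify_selected,
    default_cadd_grid,
    default_maf_grid,
    joint_grid,
    relative_burden,
    sweep,
)
from rava.types import Consequence, VariantRecord


@pytest.fixture(scope="module")
def sim():
    cfg = SimulationConfig(n_genes=30, panel_size=15, n_variants_per_gene=60.0,
                           prop_ultra_rare=0.7, seed=17)
    refdb, gm, design = simulate_dataset(cfg)
    records = refdb.records_for(gm.variant_keys)
    return records, gm, design


class TestGrids:
    def test_default_lengths_are_300(self):
        assert len(default_maf_grid()) == 300
        assert len(default_cadd_grid()) == 300

    def test_maf_grid_log_spaced_lax_to_stringent(self):
        g = default_maf_grid()
        assert g[0] > g[-1]
        steps = np.diff(np.log10(g))
        np.testing.assert_allclose(steps, steps[0])

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            default_maf_grid(lo=0.1, hi=0.01)
        with pytest.raises(ValueError):
            default_cadd_grid(lo=40, hi=0)


class TestRelativeBurden:
    def test_symmetric_cohorts_give_ratio_near_one(self):
        cfg = SimulationConfig(n_fam_cases=0, n_sporadic_cases=150, n_controls=150,
                               n_genes=20, panel_size=20, n_variants_per_gene=60.0,
                               prop_ultra_rare=0.3, seed=23)
        refdb, gm, design = simulate_dataset(cfg)
        records = refdb.records_for(gm.variant_keys)
        r = relative_burden(records, gm, design, maf_cut=None, cadd_cut=None)
        assert 0.8 < r < 1.25

    def test_fixture_count_arithmetic(self, tiny_records, tiny_gm, tiny_design):
        # pseudocount ratio on hand-countable totals:
        # cases carry 4 qualifying alleles, controls 1 (excluding synonymous
        # and common variants via the cuts)
        r = relative_burden(tiny_records, tiny_gm, tiny_design,
                            maf_cut=1e-4, cadd_cut=None, case_set="MS_combined")
        # qualifying: variants 1 (maf 8e-6) and 2 (absent -> 1e-6);
        # case alleles = 1+0+1+0 + 0+1+0+0 = 3, ctrl alleles = 0
        assert r == pytest.approx(((3 + 0.5) / 4) / ((0 + 0.5) / 2))

    def test_published_scale_counts(self):
        # the printed selected-variant totals pushed through the ratio formula
        ratio = ((29 + 0.5) / 175) / ((3 + 0.5) / 144)
        assert ratio == pytest.approx(6.94, abs=0.01)


class TestSweep:
    def test_lax_end_matches_unfiltered_relative_burden(self, sim):
        records, gm, design = sim
        curve = sweep(records, gm, design, axis="maf")
        unfiltered = relative_burden(records, gm, design, maf_cut=None, cadd_cut=None)
        assert curve.relative_burden[0] == pytest.approx(unfiltered)
        curve_c = sweep(records, gm, design, axis="cadd",
                        grid=default_cadd_grid(lo=-0.01))
        assert curve_c.relative_burden[0] == pytest.approx(unfiltered)

    def test_counts_monotone_as_cutoffs_tighten(self, sim):
        records, gm, design = sim
        for axis in ("maf", "cadd"):
            curve = sweep(records, gm, design, axis=axis)
            assert (np.diff(curve.case_alleles) <= 0).all()
            assert (np.diff(curve.ctrl_alleles) <= 0).all()

    def test_degenerate_identical_annotation_is_step_function(self, tiny_gm, tiny_design):
        recs = [
            VariantRecord("1", 100, "A", "G", gene="G", consequence=Consequence.missense,
                          cadd_phred=15.0, ref_af=1e-3, ref_ac=246),
            VariantRecord("1", 200, "C", "T", gene="G", consequence=Consequence.missense,
                          cadd_phred=15.0, ref_af=1e-3, ref_ac=246),
        ]
        gm = tiny_gm.subset_variants([r.key for r in recs])
        curve = sweep(recs, gm, tiny_design, axis="maf")
        values = set(np.round(curve.relative_burden, 12))
        assert len(values) == 2  # one level on each side of maf 1e-3
        switches = (np.diff(curve.relative_burden) != 0).sum()
        assert switches == 1

    def test_planted_enrichment_raises_stringent_end(self):
        cfg = SimulationConfig(seed=29, enrichment=20.0)
        refdb, gm, design = simulate_dataset(cfg)
        records = refdb.records_for(gm.variant_keys)
        panel_recs = [r for r in records if r.gene in refdb.panel]
        curve = sweep(panel_recs, gm, design, axis="maf", grid=default_maf_grid(60))
        assert curve.relative_burden[-5:].mean() > 2 * curve.relative_burden[:5].mean()


class TestJointGrid:
    def test_lax_corner_equals_unfiltered(self, sim):
        records, gm, design = sim
        maf_g = default_maf_grid(12)
        cadd_g = default_cadd_grid(10, lo=-0.01)
        mat = joint_grid(records, gm, design, maf_g, cadd_g)
        assert mat.shape == (12, 10)
        unfiltered = relative_burden(records, gm, design, None, None)
        assert mat[0, 0] == pytest.approx(unfiltered)

    def test_cells_match_bruteforce_recount(self, sim):
        records, gm, design = sim
        maf_g = default_maf_grid(12)
        cadd_g = default_cadd_grid(10)
        mat = joint_grid(records, gm, design, maf_g, cadd_g)
        case_mask = design.case_mask(gm.sample_ids, "MS_combined")
        ctrl_mask = design.mask(gm.sample_ids, "CTRL")
        rng = np.random.default_rng(2)
        from rava.burden import effective_ref_maf

        for i, j in zip(rng.integers(0, 12, 5), rng.integers(0, 10, 5)):
            a_case = a_ctrl = 0.0
            for k, rec in enumerate(records):
                maf_ok = effective_ref_maf(rec) < maf_g[i]
                if rec.consequence is Consequence.frameshift and rec.cadd_phred is None:
                    cadd_ok = True
                else:
                    cadd_ok = rec.cadd_phred is not None and rec.cadd_phred > cadd_g[j]
                if maf_ok and cadd_ok:
                    col = gm.dosages[:, gm.variant_keys.index(rec.key)]
                    a_case += np.nansum(col[case_mask])
                    a_ctrl += np.nansum(col[ctrl_mask])
            expected = ((a_case + 0.5) / case_mask.sum()) / ((a_ctrl + 0.5) / ctrl_mask.sum())
            assert mat[i, j] == pytest.approx(expected)


class TestClassifySelected:
    def test_rare_high_cadd_missense_selected(self):
        rec = VariantRecord("8", 90782096, "C", "T", gene="RIPK2",
                            consequence=Consequence.missense, cadd_phred=32.0,
                            ref_af=None, ref_ac=0)
        assert classify_selected(rec)

    def test_common_variant_not_selected(self):
        rec = VariantRecord("5", 172197790, "C", "T", gene="DUSP1",
                            consequence=Consequence.missense, cadd_phred=22.7,
                            ref_af=0.022276, ref_ac=2192)
        assert not classify_selected(rec)

    def test_frameshift_qualifies_on_maf_alone(self):
        rec = VariantRecord("11", 104901069, "A", "-", gene="CASP1",
                            consequence=Consequence.frameshift, cadd_phred=None,
                            ref_af=4.10e-6, ref_ac=1)
        assert classify_selected(rec)

    def test_low_cadd_rare_missense_not_selected(self):
        rec = VariantRecord("1", 10, "A", "C", consequence=Consequence.missense,
                            cadd_phred=18.0, ref_af=5e-6, ref_ac=1)
        assert not classify_selected(rec)

    def test_missing_cadd_on_missense_is_contract_violation(self):
        rec = VariantRecord("1", 10, "A", "C", consequence=Consequence.missense,
                            cadd_phred=None)
        with pytest.raises(ValueError, match="lacks a CADD score"):
            classify_selected(rec)

    def test_classifier_coheres_with_joint_grid_cell(self, sim):
        # selection <=> the variant qualifies at the (1e-5, 20) joint cell
        records, gm, design = sim
        from rava.burden import effective_ref_maf

        crit = SelectionCriteria()
        for rec in records:
            maf_ok = effective_ref_maf(rec) < crit.maf_cut
            if rec.consequence is Consequence.frameshift and rec.cadd_phred is None:
                cell_ok = maf_ok
            else:
                cell_ok = maf_ok and rec.cadd_phred is not None and rec.cadd_phred > crit.cadd_cut
            assert classify_selected(rec, crit) == cell_ok

    def test_all_29_fixture_rows_selected_three_by_frameshift_rule(self):
        recs = selected_fixture_records()
        assert len(recs) == 29
        assert all(classify_selected(r) for r in recs)
        by_fs = [r for r in recs if r.consequence is Consequence.frameshift]
        assert len(by_fs) == 3
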