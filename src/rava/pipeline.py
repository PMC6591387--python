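"""End-to-end orchestration: filters -> burden tests -> sweeps -> panel null
-> per-variant enrichment, with a reproducibility manifest.

``run_pipeline`` consumes a :class:`RunConfig` naming the input files (VCF,
annotation TSV, cohort TSV, panel TSV, capture BEDs) and every threshold,
and writes TSV/JSON reports plus a manifest (config hash, seed, package
version) sufficient to reproduce the run.  A filter ledger records the
in/out variant counts of every pre-analysis filter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burden import bonferroni_threshold, burden_test
from .enrichment import (
    DEFAULT_REFERENCE_AN,
    classify_two_stage,
    aggregate_selected_frequency,
    reconstruct_ref_an,
)
from .io import (
    align_matrix_to_records,
    filter_call_rate,
    intersect_captured,
    join_annotations,
    prefilter_rare_protein_altering,
    read_cohorts,
    read_genotypes,
    read_panel,
)
from .panel_null import empirical_p, panel_slope_null
from .sweep import SelectionCriteria, classify_selected, sweep

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

CASE_SETS = ("MSFAM", "MSS", "MS_combined")


@dataclass
class RunConfig:
    """All inputs and thresholds of one reproducible pipeline run."""

    vcf: str
    annotations: str
    cohorts: str
    panel: str
    beds: list[str] = field(default_factory=list)
    out_dir: str = "results/run"
    call_rate_threshold: float = 0.95
    maf_filter: float = 0.05
    selection: SelectionCriteria = field(default_factory=SelectionCriteria)
    n_random_panels: int = 100_000
    n_permutations: int = 10_000
    burden_method: str = "score"
    burden_family_alpha: float = 0.01
    variant_alpha: float = 0.01
    default_an: int = DEFAULT_REFERENCE_AN
    seed: int = 0

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _manifest(config: RunConfig) -> dict:
    blob = json.dumps(config.to_jsonable(), sort_keys=True)
    return {
        "config": config.to_jsonable(),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.seed,
        "package_version": __version__,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write reports under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ledger: dict[str, int] = {}

    gm, records = read_genotypes(config.vcf)
    records = join_annotations(records, config.annotations)
    design = read_cohorts(config.cohorts)
    panel = read_panel(config.panel)
    ledger["variants_in"] = len(records)

    if config.beds:
        records = intersect_captured(records, config.beds)
    ledger["after_capture_intersection"] = len(records)
    records = filter_call_rate(records, config.call_rate_threshold)
    ledger["after_call_rate"] = len(records)
    af = dict(zip(gm.variant_keys, gm.dataset_af()))
    records = prefilter_rare_protein_altering(records, af, config.maf_filter)
    ledger["variants_retained"] = len(records)
    gm = align_matrix_to_records(gm, records)
    logger.info("filter ledger: %s", ledger)

    # --- weighted burden tests, three case contrasts vs CTRL ---
    panel_records = [r for r in records if r.gene in panel]
    threshold = bonferroni_threshold(config.burden_family_alpha, len(CASE_SETS))
    burden_rows = []
    for case_set in CASE_SETS:
        mask = design.case_mask(gm.sample_ids, case_set) | design.mask(
            gm.sample_ids, "CTRL"
        )
        ids = [s for s, m in zip(gm.sample_ids, mask) if m]
        sub = gm.subset_samples(ids)
        y = design.case_mask(ids, case_set).astype(int)
        res = burden_test(
            sub,
            panel_records,
            y,
            method=config.burden_method,
            n_perm=config.n_permutations,
            seed=config.seed,
        )
        burden_rows.append(
            {
                "case_set": case_set,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n_variants": res.n_variants,
                "method": res.method,
                "significant": res.p_value < threshold.exact,
            }
        )
    burden_df = pd.DataFrame(burden_rows)

    # --- cutoff sweeps and panel Monte Carlo (combined cohort) ---
    curves = {
        axis: sweep(panel_records, gm, design, axis=axis, case_set="MS_combined")
        for axis in ("maf", "cadd")
    }
    sweep_frames = []
    for axis, curve in curves.items():
        sweep_frames.append(
            pd.DataFrame(
                {
                    "axis": axis,
                    "cutoff": curve.cutoffs,
                    "case_alleles": curve.case_alleles,
                    "ctrl_alleles": curve.ctrl_alleles,
                    "relative_burden": curve.relative_burden,
                }
            )
        )
    sweep_df = pd.concat(sweep_frames, ignore_index=True)

    panel_null_rows = []
    for axis in ("maf", "cadd"):
        observed, null = panel_slope_null(
            records,
            gm,
            design,
            panel,
            axis=axis,
            n_panels=config.n_random_panels,
            seed=config.seed,
        )
        panel_null_rows.append(
            {
                "axis": axis,
                "observed_slope": observed,
                "n_panels": null.n_panels,
                "p_value": empirical_p(observed, null),
            }
        )
    panel_null_df = pd.DataFrame(panel_null_rows)

    # --- per-variant enrichment and selected classification ---
    ms_mask = design.case_mask(gm.sample_ids, "MS_combined")
    ctrl_mask = design.mask(gm.sample_ids, "CTRL")
    ms_an = 2 * int(ms_mask.sum())
    ctrl_an = 2 * int(ctrl_mask.sum())
    enrich_rows = []
    ms_ac_all = gm.allele_counts(ms_mask)
    ctrl_ac_all = gm.allele_counts(ctrl_mask)
    carriers_all = np.nansum(gm.dosages[ms_mask] > 0, axis=0)
    idx_of = {k: j for j, k in enumerate(gm.variant_keys)}
    for rec in panel_records:
        j = idx_of[rec.key]
        ref = reconstruct_ref_an(rec.ref_af, rec.ref_ac, config.default_an)
        res = classify_two_stage(
            rec,
            int(ms_ac_all[j]),
            ms_an,
            int(ctrl_ac_all[j]),
            ctrl_an,
            ref,
            ms_carriers=int(carriers_all[j]),
            alpha=config.variant_alpha,
        )
        enrich_rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "gene": rec.gene,
                "protein_change": rec.protein_change,
                "consequence": rec.consequence.value if rec.consequence else None,
                "cadd_phred": rec.cadd_phred,
                "ref_af": rec.ref_af,
                "ref_ac": rec.ref_ac,
                "ref_an": ref.ref_an,
                "ms_ac": int(ms_ac_all[j]),
                "ctrl_ac": int(ctrl_ac_all[j]),
                "p_case": res.p_case_vs_ref,
                "p_ctrl": res.p_ctrl_vs_ref,
                "odds_ratio": res.odds_ratio_case,
                "selected": classify_selected(rec, config.selection),
                "classification": res.classification,
            }
        )
    enrich_df = pd.DataFrame(enrich_rows)

    selected_records = [r for r in panel_records if classify_selected(r, config.selection)]
    freqs = {}
    if selected_records:
        for label in ("MS_combined", "CTRL"):
            freqs[label] = aggregate_selected_frequency(
                selected_records, label, design, gm
            ).exact

    results = {
        "manifest": _manifest(config),
        "filter_ledger": ledger,
        "bonferroni_threshold": {"exact": threshold.exact, "reported": threshold.reported},
        "burden": burden_df,
        "sweeps": sweep_df,
        "panel_null": panel_null_df,
        "enrichment": enrich_df,
        "selected_allele_frequency": freqs,
        "n_selected": len(selected_records),
    }

    burden_df.to_csv(out / "burden.tsv", sep="\t", index=False)
    sweep_df.to_csv(out / "sweeps.tsv", sep="\t", index=False)
    panel_null_df.to_csv(out / "panel_null.tsv", sep="\t", index=False)
    enrich_df.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    summary = {
        k: results[k]
        for k in (
            "manifest",
            "filter_ledger",
            "bonferroni_threshold",
            "selected_allele_frequency",
            "n_selected",
        )
    }
    summary["burden"] = burden_rows
    summary["panel_null"] = panel_null_rows
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float) + "\n")
    return results
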