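"""Readers, writers and pre-analysis variant filters.

Standard formats: multi-sample VCF v4.2 (GT field; parsed with cyvcf2), a
flat annotation TSV keyed by (chrom, pos, ref, alt), BED3 capture-region
files (0-based half-open), and a two-column cohort TSV.

The three pre-analysis filters mirror common exome QC practice for a
multi-capture-kit case-control design: restriction to universally captured
loci, a per-variant genotyping (call-rate) threshold, and removal of
synonymous / non-coding and common (MAF > 0.05) variants.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import (
    CohortDesign,
    Consequence,
    GenePanel,
    GenotypeMatrix,
    VariantKey,
    VariantRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VCFParseError",
    "read_genotypes",
    "write_vcf",
    "join_annotations",
    "read_cohorts",
    "read_panel",
    "intersect_captured",
    "filter_call_rate",
    "prefilter_rare_protein_altering",
    "align_matrix_to_records",
]

ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "protein_change",
    "cadd_phred",
    "ref_af",
    "ref_ac",
]


class VCFParseError(ValueError):
    pass


def _prescan_vcf(path: str | Path) -> None:
    # cheap structural check so malformed lines are reported with their number
    n_fixed = 9
    with open(path) as fh:
        saw_header = False
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if not saw_header:
                raise VCFParseError(f"{path}: data before #CHROM header at line {lineno}")
            if line.strip() and len(line.rstrip("\n").split("\t")) < n_fixed + 1:
                raise VCFParseError(f"{path}: malformed VCF line {lineno}")
    if not saw_header:
        raise VCFParseError(f"{path}: missing #CHROM header line")


def read_genotypes(
    vcf_path: str | Path, sample_subset: Sequence[str] | None = None
) -> tuple[GenotypeMatrix, list[VariantRecord]]:
    """Read a multi-sample VCF into a dosage matrix plus bare variant records.

    Only the GT field is used; a missing call (``./.``) becomes ``nan``.
    Multiallelic records and duplicate (chrom, pos, ref, alt) keys are
    rejected.  Annotation fields of the returned records are left absent
    until :func:`join_annotations`.
    """
    from cyvcf2 import VCF

    _prescan_vcf(vcf_path)
    vcf = VCF(str(vcf_path))
    if sample_subset is not None:
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)

    keys: list[VariantKey] = []
    records: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    seen: set[VariantKey] = set()
    for v in vcf:
        if len(v.ALT) != 1:
            raise VCFParseError(
                f"multiallelic record at {v.CHROM}:{v.POS}; split or remove upstream"
            )
        key = (str(v.CHROM), int(v.POS), v.REF, v.ALT[0])
        if key in seen:
            raise VCFParseError(f"duplicate variant key {key}")
        seen.add(key)
        dos = np.empty(len(samples), dtype=float)
        for i, g in enumerate(v.genotypes):
            a = [x for x in g[:-1] if isinstance(x, int)]
            if not a or any(x < 0 for x in a):
                dos[i] = np.nan
            else:
                dos[i] = float(sum(1 for x in a if x > 0))
        keys.append(key)
        records.append(VariantRecord(*key))
        rows.append(dos)
    vcf.close()
    dosages = (
        np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    )
    gm = GenotypeMatrix(samples, keys, dosages)
    call_rates = gm.call_rates() if keys else np.empty(0)
    for rec, cr in zip(records, call_rates):
        rec.call_rate = float(cr)
    return gm, records


def write_vcf(path: str | Path, gm: GenotypeMatrix) -> None:
    """Write a minimal VCF v4.2 (GT only) for a dosage matrix."""
    lines = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for chrom in dict.fromkeys(k[0] for k in gm.variant_keys):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.sample_ids)
    )
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    order = sorted(range(gm.n_variants), key=lambda j: (gm.variant_keys[j][0], gm.variant_keys[j][1]))
    for j in order:
        chrom, pos, ref, alt = gm.variant_keys[j]
        gts = [
            "./." if np.isnan(d) else gt_of[d] for d in gm.dosages[:, j]
        ]
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_optional_float(val, context: str) -> float | None:
    if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
        return None
    try:
        return float(val)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric value {val!r} for {context}") from exc


def join_annotations(
    records: Iterable[VariantRecord], annotation_tsv: str | Path
) -> list[VariantRecord]:
    """Attach gene / consequence / CADD / reference-frequency annotations.

    The TSV is keyed by (chrom, pos, ref, alt); an empty cell means absent.
    Records without a matching row are retained unannotated with a warning.
    """
    df = pd.read_csv(annotation_tsv, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"annotation TSV missing columns: {sorted(missing_cols)}")
    table: dict[VariantKey, dict] = {}
    for row in df.to_dict("records"):
        key = (str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"])
        if key in table:
            raise ValueError(f"annotation key collision for {key}")
        table[key] = row

    out: list[VariantRecord] = []
    for rec in records:
        row = table.get(rec.key)
        if row is None:
            logger.warning("no annotation for variant %s", rec.key)
            out.append(rec)
            continue
        cadd = _parse_optional_float(row["cadd_phred"], f"cadd_phred at {rec.key}")
        ref_af = _parse_optional_float(row["ref_af"], f"ref_af at {rec.key}")
        ref_ac = row["ref_ac"]
        ref_ac = int(ref_ac) if ref_ac != "" else None
        out.append(
            rec.with_annotations(
                gene=row["gene"] or None,
                consequence=Consequence(row["consequence"]) if row["consequence"] else None,
                protein_change=row["protein_change"] or None,
                cadd_phred=cadd,
                ref_af=ref_af if (ref_ac or 0) > 0 else None,
                ref_ac=ref_ac,
            )
        )
    return out


def read_cohorts(tsv_path: str | Path) -> CohortDesign:
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    if not {"sample_id", "cohort"} <= set(df.columns):
        raise ValueError("cohort TSV must have columns: sample_id, cohort")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in cohort TSV")
    return CohortDesign(dict(zip(df["sample_id"], df["cohort"])))


def read_panel(tsv_path: str | Path, name: str | None = None) -> GenePanel:
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    col = "gene" if "gene" in df.columns else df.columns[0]
    genes = list(df[col])
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene symbols in panel TSV")
    return GenePanel(name or Path(tsv_path).stem, frozenset(genes))


def _read_bed_trees(bed_path: str | Path) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
    return trees


def intersect_captured(
    records: Iterable[VariantRecord], bed_paths: Sequence[str | Path]
) -> list[VariantRecord]:
    """Keep variants inside the intersection of all capture BED files.

    VCF positions are 1-based; BED intervals 0-based half-open, so position
    ``pos`` is captured by an interval [start, end) iff start <= pos-1 < end.
    """
    if not bed_paths:
        raise ValueError("at least one BED file required")
    records = list(records)
    all_trees = [_read_bed_trees(p) for p in bed_paths]
    out = []
    for rec in records:
        p0 = rec.pos - 1  # 1-based -> 0-based point
        if all(trees.get(rec.chrom) and trees[rec.chrom].overlaps(p0) for trees in all_trees):
            out.append(rec)
    if records and not out:
        logger.warning("capture intersection removed all %d variants", len(records))
    return out


def filter_call_rate(
    records: Iterable[VariantRecord], threshold: float = 0.95
) -> list[VariantRecord]:
    """Keep variants genotyped in strictly more than ``threshold`` of probands."""
    if not 0 < threshold <= 1:
        raise ValueError(f"call-rate threshold must lie in (0, 1], got {threshold}")
    out = []
    for rec in records:
        if rec.call_rate is None:
            raise ValueError(f"record {rec.key} has no call_rate")
        if rec.call_rate > threshold:
            out.append(rec)
    return out


def prefilter_rare_protein_altering(
    records: Iterable[VariantRecord],
    dataset_af: dict[VariantKey, float],
    maf_cut: float = 0.05,
) -> list[VariantRecord]:
    """Remove synonymous / non-coding variants and common alleles.

    A variant is kept when its consequence is protein-altering, its
    reference-database AF is <= ``maf_cut`` (absent passes: the database-free
    variants are the analysis's main interest), and its within-dataset AF is
    <= ``maf_cut``.
    """
    dropped_csq = {Consequence.synonymous, Consequence.non_coding}
    out = []
    for rec in records:
        if rec.consequence in dropped_csq or rec.consequence is None:
            continue
        if rec.ref_af is not None and rec.ref_af > maf_cut:
            continue
        if dataset_af[rec.key] > maf_cut:
            continue
        out.append(rec)
    return out


def align_matrix_to_records(
    gm: GenotypeMatrix, records: Sequence[VariantRecord]
) -> GenotypeMatrix:
    """Subset the genotype matrix columns to the retained records, in order."""
    return gm.subset_variants([r.key for r in records])
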