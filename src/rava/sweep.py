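"""Relative case/control variant burden across MAF and CADD cutoff grids.

The burden of qualifying variants (those rarer than a MAF cutoff and/or more
deleterious than a CADD cutoff) is summed as alternate alleles per cohort,
normalised to cohort size, and expressed as a case/control ratio.  Scanning
the cutoff over a 300-point grid traces how enrichment concentrates at the
rare / damaging end; the joint 2-D grid combines both criteria.  The
"selected" classifier is the fixed corner of that joint grid: effective
reference MAF < 1e-5 and CADD-phred > 20, with frameshifts (unscorable by
CADD) qualifying on the MAF criterion alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .burden import effective_ref_maf
from .types import CohortDesign, Consequence, GenotypeMatrix, VariantRecord

__all__ = [
    "SelectionCriteria",
    "SweepCurve",
    "default_maf_grid",
    "default_cadd_grid",
    "relative_burden",
    "sweep",
    "joint_grid",
    "classify_selected",
]

PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class SelectionCriteria:
    """Fixed rarity/deleteriousness cuts defining the selected variants."""

    maf_cut: float = 1e-5
    cadd_cut: float = 20.0
    frameshift_by_maf_only: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.maf_cut <= 0.05:
            raise ValueError("maf_cut must lie in (0, 0.05]")
        if self.cadd_cut < 0:
            raise ValueError("cadd_cut must be >= 0")


@dataclass
class SweepCurve:
    """Relative burden along one cutoff axis, ordered lax -> stringent."""

    axis: str  # "maf" or "cadd"
    cutoffs: np.ndarray
    relative_burden: np.ndarray
    case_alleles: np.ndarray
    ctrl_alleles: np.ndarray
    case_set: str = "MS_combined"

    def __post_init__(self) -> None:
        n = len(self.cutoffs)
        if not (len(self.relative_burden) == len(self.case_alleles) == len(self.ctrl_alleles) == n):
            raise ValueError("curve arrays must have equal length")


def default_maf_grid(n: int = 300, lo: float = 2e-6, hi: float = 0.05) -> np.ndarray:
    """MAF cutoffs equally spaced in log10, ordered lax (high) -> stringent (low).

    The lower bound sits just above the 1e-6 effective MAF imputed to
    database-absent variants, so the most stringent cutoff still admits that
    rarest class (variants qualify strictly below a cutoff; a bound of
    exactly 1e-6 would make the terminal cell empty by construction).
    """
    if not 0 < lo < hi:
        raise ValueError("require 0 < lo < hi")
    return np.logspace(np.log10(hi), np.log10(lo), n)


def default_cadd_grid(n: int = 300, lo: float = 0.0, hi: float = 40.0) -> np.ndarray:
    """CADD cutoffs equally spaced linearly, ordered lax (low) -> stringent (high)."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    return np.linspace(lo, hi, n)


def _annotation_arrays(records: Sequence[VariantRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(effective MAF, CADD with nan for unscored, is-frameshift) arrays."""
    maf = np.array([effective_ref_maf(r) for r in records])
    cadd = np.array(
        [r.cadd_phred if r.cadd_phred is not None else np.nan for r in records]
    )
    fs = np.array([r.consequence is Consequence.frameshift for r in records])
    return maf, cadd, fs


def _qualify_mask(
    maf: np.ndarray,
    cadd: np.ndarray,
    frameshift: np.ndarray,
    maf_cut: float | None,
    cadd_cut: float | None,
    frameshift_by_maf_only: bool = True,
) -> np.ndarray:
    """Variants qualifying at strict cuts; ``None`` disables a criterion."""
    mask = np.ones(len(maf), dtype=bool)
    if maf_cut is not None:
        mask &= maf < maf_cut
    if cadd_cut is not None:
        with np.errstate(invalid="ignore"):
            cadd_ok = cadd > cadd_cut
        if frameshift_by_maf_only:
            cadd_ok |= frameshift & np.isnan(cadd)
        mask &= cadd_ok
    return mask


def _cohort_counts(
    gm: GenotypeMatrix, cohorts: CohortDesign, case_set: str
) -> tuple[np.ndarray, np.ndarray, int, int]:
    case_mask = cohorts.case_mask(gm.sample_ids, case_set)
    ctrl_mask = cohorts.mask(gm.sample_ids, "CTRL")
    a_case = gm.allele_counts(case_mask)
    a_ctrl = gm.allele_counts(ctrl_mask)
    return a_case, a_ctrl, int(case_mask.sum()), int(ctrl_mask.sum())


def _ratio(sum_case: float, sum_ctrl: float, n_case: int, n_ctrl: int) -> float:
    return ((sum_case + PSEUDOCOUNT) / n_case) / ((sum_ctrl + PSEUDOCOUNT) / n_ctrl)


def relative_burden(
    records: Sequence[VariantRecord],
    gm: GenotypeMatrix,
    cohorts: CohortDesign,
    maf_cut: float | None,
    cadd_cut: float | None,
    case_set: str = "MS_combined",
) -> float:
    """Size-normalised case/control ratio of qualifying allele counts.

    A 0.5 pseudocount in both cohorts keeps the ratio finite when no
    qualifying alleles are observed on one side.
    """
    maf, cadd, fs = _annotation_arrays(records)
    mask = _qualify_mask(maf, cadd, fs, maf_cut, cadd_cut)
    a_case, a_ctrl, n_case, n_ctrl = _cohort_counts(
        gm.subset_variants([r.key for r in records]), cohorts, case_set
    )
    return _ratio(a_case[mask].sum(), a_ctrl[mask].sum(), n_case, n_ctrl)


def sweep(
    records: Sequence[VariantRecord],
    gm: GenotypeMatrix,
    cohorts: CohortDesign,
    axis: str,
    case_set: str = "MS_combined",
    grid: np.ndarray | None = None,
) -> SweepCurve:
    """Relative burden across a one-dimensional cutoff grid.

    ``axis="maf"`` keeps variants strictly below each MAF cutoff (CADD
    criterion disabled); ``axis="cadd"`` keeps variants strictly above each
    CADD cutoff (MAF criterion disabled).  The returned curve is ordered lax
    -> stringent.
    """
    if axis not in ("maf", "cadd"):
        raise ValueError("axis must be 'maf' or 'cadd'")
    if grid is None:
        grid = default_maf_grid() if axis == "maf" else default_cadd_grid()
    grid = np.asarray(grid, dtype=float)
    maf, cadd, fs = _annotation_arrays(records)
    a_case, a_ctrl, n_case, n_ctrl = _cohort_counts(
        gm.subset_variants([r.key for r in records]), cohorts, case_set
    )
    case_sums = np.empty(len(grid))
    ctrl_sums = np.empty(len(grid))
    for i, cut in enumerate(grid):
        if axis == "maf":
            mask = _qualify_mask(maf, cadd, fs, cut, None)
        else:
            mask = _qualify_mask(maf, cadd, fs, None, cut)
        case_sums[i] = a_case[mask].sum()
        ctrl_sums[i] = a_ctrl[mask].sum()
    ratios = ((case_sums + PSEUDOCOUNT) / n_case) / ((ctrl_sums + PSEUDOCOUNT) / n_ctrl)
    return SweepCurve(axis, grid, ratios, case_sums, ctrl_sums, case_set)


def joint_grid(
    records: Sequence[VariantRecord],
    gm: GenotypeMatrix,
    cohorts: CohortDesign,
    maf_grid: np.ndarray | None = None,
    cadd_grid: np.ndarray | None = None,
    case_set: str = "MS_combined",
) -> np.ndarray:
    """2-D relative-burden matrix over the MAF x CADD cutoff cross-product.

    Entry [i, j] applies MAF cutoff ``maf_grid[i]`` and CADD cutoff
    ``cadd_grid[j]``; frameshift variants qualify by the MAF coordinate
    alone.
    """
    maf_grid = default_maf_grid() if maf_grid is None else np.asarray(maf_grid, float)
    cadd_grid = default_cadd_grid() if cadd_grid is None else np.asarray(cadd_grid, float)
    maf, cadd, fs = _annotation_arrays(records)
    a_case, a_ctrl, n_case, n_ctrl = _cohort_counts(
        gm.subset_variants([r.key for r in records]), cohorts, case_set
    )
    out = np.empty((len(maf_grid), len(cadd_grid)))
    # factor the qualification test: maf mask per row, cadd mask per column
    with np.errstate(invalid="ignore"):
        cadd_masks = [
            (cadd > c) | (fs & np.isnan(cadd)) for c in cadd_grid
        ]
    for i, m in enumerate(maf_grid):
        maf_mask = maf < m
        for j, cadd_mask in enumerate(cadd_masks):
            mask = maf_mask & cadd_mask
            out[i, j] = _ratio(a_case[mask].sum(), a_ctrl[mask].sum(), n_case, n_ctrl)
    return out


def classify_selected(
    record: VariantRecord, criteria: SelectionCriteria = SelectionCriteria()
) -> bool:
    """Whether a variant falls in the selected rare/deleterious corner.

    Frameshift variants qualify on effective reference MAF alone (strictly
    below the cut); every other protein-altering consequence must also have
    CADD-phred strictly above the cut.  Synonymous / non-coding variants are
    never selected.  A missing CADD score on a non-frameshift variant is an
    annotation-contract violation.
    """
    if record.consequence in (Consequence.synonymous, Consequence.non_coding):
        return False
    maf_ok = effective_ref_maf(record) < criteria.maf_cut
    if record.consequence is Consequence.frameshift and criteria.frameshift_by_maf_only:
        return maf_ok
    if record.cadd_phred is None:
        raise ValueError(
            f"variant {record.key} ({record.consequence}) lacks a CADD score; "
            "only frameshift variants may be unscored here"
        )
    return maf_ok and record.cadd_phred > criteria.cadd_cut
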