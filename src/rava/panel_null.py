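"""Monte Carlo null for the sweep trend: random same-size gene panels.

The sweep curve's tendency to rise toward stringent cutoffs is summarised by
the OLS slope of relative burden against the rank position of the cutoff
(rescaled to [0, 1], lax -> stringent).  The observed panel's slope is
compared with slopes of many random gene panels of the same size drawn from
the universe of genes carrying at least one retained variant; the one-sided
empirical p-value uses the add-one permutation convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .burden import effective_ref_maf
from .sweep import PSEUDOCOUNT, SweepCurve, default_cadd_grid, default_maf_grid
from .types import CohortDesign, Consequence, GenePanel, GenotypeMatrix, VariantRecord

__all__ = [
    "NullDistribution",
    "trend_slope",
    "sample_random_panels",
    "panel_slope_null",
    "empirical_p",
]


@dataclass
class NullDistribution:
    """Random-panel slope distribution for one sweep axis."""

    slopes: np.ndarray
    n_panels: int
    seed: int
    axis: str

    def __post_init__(self) -> None:
        if len(self.slopes) != self.n_panels:
            raise ValueError("slopes length inconsistent with n_panels")


def trend_slope(curve: SweepCurve | np.ndarray) -> float:
    """OLS slope of relative burden against [0, 1]-rescaled rank position."""
    y = curve.relative_burden if isinstance(curve, SweepCurve) else np.asarray(curve, float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 curve points for a slope")
    x = np.linspace(0.0, 1.0, n)
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def sample_random_panels(
    gene_universe: Sequence[str], size: int, n_panels: int, seed: int
) -> list[GenePanel]:
    """Uniform same-size gene panels, without replacement within a panel."""
    universe = list(gene_universe)
    if size > len(universe):
        raise ValueError(f"panel size {size} exceeds universe of {len(universe)} genes")
    rng = np.random.default_rng(seed)
    panels = []
    for i in range(n_panels):
        idx = rng.choice(len(universe), size=size, replace=False)
        panels.append(GenePanel(f"random_{i}", frozenset(universe[j] for j in idx)))
    return panels


def _per_gene_cutoff_counts(
    records: Sequence[VariantRecord],
    gm: GenotypeMatrix,
    cohorts: CohortDesign,
    axis: str,
    case_set: str,
    grid: np.ndarray,
) -> tuple[list[str], np.ndarray, np.ndarray, int, int]:
    """Per-gene qualifying allele counts at every cutoff (genes x cutoffs).

    Random-panel curves are then row sums over panel members, which turns
    the 100k-panel Monte Carlo into matrix arithmetic.
    """
    genes = sorted({r.gene for r in records if r.gene is not None})
    gene_idx = {g: i for i, g in enumerate(genes)}
    sub = gm.subset_variants([r.key for r in records])
    case_mask = cohorts.case_mask(sub.sample_ids, case_set)
    ctrl_mask = cohorts.mask(sub.sample_ids, "CTRL")
    a_case = sub.allele_counts(case_mask)
    a_ctrl = sub.allele_counts(ctrl_mask)

    maf = np.array([effective_ref_maf(r) for r in records])
    cadd = np.array([r.cadd_phred if r.cadd_phred is not None else np.nan for r in records])
    fs = np.array([r.consequence is Consequence.frameshift for r in records])
    g = np.array([gene_idx[r.gene] for r in records])

    case_mat = np.zeros((len(genes), len(grid)))
    ctrl_mat = np.zeros((len(genes), len(grid)))
    for k, cut in enumerate(grid):
        if axis == "maf":
            q = maf < cut
        else:
            with np.errstate(invalid="ignore"):
                q = (cadd > cut) | (fs & np.isnan(cadd))
        np.add.at(case_mat[:, k], g[q], a_case[q])
        np.add.at(ctrl_mat[:, k], g[q], a_ctrl[q])
    return genes, case_mat, ctrl_mat, int(case_mask.sum()), int(ctrl_mask.sum())


def panel_slope_null(
    records: Sequence[VariantRecord],
    gm: GenotypeMatrix,
    cohorts: CohortDesign,
    panel: GenePanel,
    axis: str,
    case_set: str = "MS_combined",
    n_panels: int = 100_000,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> tuple[float, NullDistribution]:
    """Observed panel slope and the random-panel null slope distribution.

    The gene universe is every gene with >= 1 retained variant; the observed
    panel contributes the genes it shares with that universe, and random
    panels match that effective size.
    """
    if axis not in ("maf", "cadd"):
        raise ValueError("axis must be 'maf' or 'cadd'")
    if grid is None:
        grid = default_maf_grid() if axis == "maf" else default_cadd_grid()
    genes, case_mat, ctrl_mat, n_case, n_ctrl = _per_gene_cutoff_counts(
        records, gm, cohorts, axis, case_set, grid
    )
    in_panel = np.array([g in panel for g in genes])
    size = int(in_panel.sum())
    if size == 0:
        raise ValueError("panel shares no genes with the retained-variant universe")
    if size > len(genes):
        raise ValueError("panel larger than gene universe")

    x = np.linspace(0.0, 1.0, len(grid))
    xc = x - x.mean()
    sxx = xc @ xc

    def slopes_of(case_rows: np.ndarray, ctrl_rows: np.ndarray) -> np.ndarray:
        ratios = ((case_rows + PSEUDOCOUNT) / n_case) / ((ctrl_rows + PSEUDOCOUNT) / n_ctrl)
        yc = ratios - ratios.mean(axis=-1, keepdims=True)
        return (yc @ xc) / sxx

    observed = float(slopes_of(case_mat[in_panel].sum(0), ctrl_mat[in_panel].sum(0)))

    rng = np.random.default_rng(seed)
    null_slopes = np.empty(n_panels)
    block = 2_000
    done = 0
    while done < n_panels:
        b = min(block, n_panels - done)
        # b independent uniform without-replacement draws via random-key argsort
        pick = np.argsort(rng.random((b, len(genes))), axis=1)[:, :size]
        null_slopes[done : done + b] = slopes_of(
            case_mat[pick].sum(axis=1), ctrl_mat[pick].sum(axis=1)
        )
        done += b
    return observed, NullDistribution(null_slopes, n_panels, seed, axis)


def empirical_p(observed_slope: float, null: NullDistribution) -> float:
    """One-sided add-one empirical p: larger slope = stronger rare-end enrichment."""
    if null.n_panels == 0:
        raise ValueError("empty null distribution")
    return (1 + int((null.slopes >= observed_slope).sum())) / (null.n_panels + 1)
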