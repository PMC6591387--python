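"""Per-variant enrichment against reference-database allele counts.

Each variant seen in two or more case probands is tested with a two-sided
Fisher exact test of cohort alternate/reference allele counts against the
reference database's AC/AN, twice: cases vs reference and controls vs
reference.  Nominal significance (p < 0.01) in the case test but not the
control test marks the variant "MS enriched"; significance in the control
test marks it "population specific".  A Yates-corrected chi-square compares
the share of database-absent variants between cohorts, and a pooled Fisher
test handles perfectly co-occurring variants treated as one haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .types import CohortDesign, GenotypeMatrix, VariantRecord

__all__ = [
    "DEFAULT_REFERENCE_AN",
    "ReferenceCounts",
    "EnrichmentResult",
    "reconstruct_ref_an",
    "fisher_vs_reference",
    "classify_two_stage",
    "absent_variant_chisq",
    "haplotype_pool_test",
    "aggregate_selected_frequency",
]

#: Default reference-database allele number; matches the AC/AF pairing of a
#: ~123,000-individual exome aggregation database (AC=2 at AF ~ 8.1e-6).
DEFAULT_REFERENCE_AN = 246_000


@dataclass(frozen=True)
class ReferenceCounts:
    ref_ac: int
    ref_an: int

    def __post_init__(self) -> None:
        if self.ref_an <= 0:
            raise ValueError("ref_an must be positive")
        if not 0 <= self.ref_ac <= self.ref_an:
            raise ValueError("require 0 <= ref_ac <= ref_an")


class FisherOutcome(NamedTuple):
    p_value: float
    odds_ratio: float  # sample (unconditional) odds ratio


@dataclass
class EnrichmentResult:
    """Two-stage enrichment classification for one variant."""

    key: tuple
    p_case_vs_ref: float | None
    p_ctrl_vs_ref: float | None
    odds_ratio_case: float | None
    classification: str  # ms_enriched | population_specific | neither | not_multiproband


def reconstruct_ref_an(
    ref_af: float | None, ref_ac: int | None, default_an: int = DEFAULT_REFERENCE_AN
) -> ReferenceCounts:
    """Recover the reference allele number from a printed AF/AC pair.

    AN = round(AC / AF) when the variant is present in the database; a
    database-absent variant gets AC = 0 at the configured default AN.
    """
    if ref_ac is not None and ref_ac >= 1:
        if not ref_af or ref_af <= 0:
            raise ValueError("ref_ac >= 1 requires a positive ref_af")
        return ReferenceCounts(ref_ac=int(ref_ac), ref_an=int(round(ref_ac / ref_af)))
    return ReferenceCounts(ref_ac=0, ref_an=default_an)


def fisher_vs_reference(cohort_ac: int, cohort_an: int, ref: ReferenceCounts) -> FisherOutcome:
    """Two-sided Fisher exact test of cohort vs reference allele proportions."""
    if cohort_ac < 0 or cohort_an <= 0 or cohort_ac > cohort_an:
        raise ValueError("require 0 <= cohort_ac <= cohort_an with cohort_an > 0")
    table = np.array(
        [
            [cohort_ac, cohort_an - cohort_ac],
            [ref.ref_ac, ref.ref_an - ref.ref_ac],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return FisherOutcome(p_value=float(p), odds_ratio=float(odds))


def classify_two_stage(
    variant: VariantRecord,
    ms_ac: int,
    ms_an: int,
    ctrl_ac: int,
    ctrl_an: int,
    ref: ReferenceCounts,
    ms_carriers: int | None = None,
    alpha: float = 0.01,
) -> EnrichmentResult:
    """Two-stage rule: case-vs-reference, then control-vs-reference screen.

    Requires >= 2 case carriers (``ms_carriers`` defaults to ``ms_ac``, i.e.
    all-heterozygous).  Case p < alpha with control p >= alpha gives
    ``ms_enriched``; control p < alpha gives ``population_specific``.
    """
    carriers = ms_carriers if ms_carriers is not None else ms_ac
    if carriers < 2:
        return EnrichmentResult(variant.key, None, None, None, "not_multiproband")
    p_case, or_case = fisher_vs_reference(ms_ac, ms_an, ref)
    p_ctrl, _ = fisher_vs_reference(ctrl_ac, ctrl_an, ref)
    if p_ctrl < alpha:
        cls = "population_specific"
    elif p_case < alpha:
        cls = "ms_enriched"
    else:
        cls = "neither"
    return EnrichmentResult(variant.key, p_case, p_ctrl, or_case, cls)


def absent_variant_chisq(
    n_absent_case: int, n_total_case: int, n_absent_ctrl: int, n_total_ctrl: int
) -> float:
    """Yates-corrected chi-square p for database-absent variant proportions.

    Counts are numbers of distinct variants (not alleles), with each cohort's
    total discovered variant count as the background.
    """
    table = np.array(
        [
            [n_absent_case, n_total_case - n_absent_case],
            [n_absent_ctrl, n_total_ctrl - n_absent_ctrl],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(
            "chi-square table has a zero margin; both cohorts need discovered "
            "variants and both absent/present classes must occur"
        )
    if table.min() < 0:
        raise ValueError("negative cell count")
    _, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(p)


def haplotype_pool_test(
    variant_keys: Sequence[tuple],
    ms_ac_pooled: int,
    ms_an: int,
    ref_pooled: ReferenceCounts,
    per_variant_ms_ac: Sequence[int] | None = None,
) -> FisherOutcome:
    """Fisher test for perfectly co-occurring variants pooled as one haplotype.

    The pooled counts are a single representative count, not the per-variant
    sum.  If per-variant counts are supplied and disagree, the variants do
    not co-occur perfectly and pooling is refused.
    """
    if per_variant_ms_ac is not None and len(set(per_variant_ms_ac)) > 1:
        raise ValueError(
            "per-variant allele counts differ; variants do not co-occur as one "
            "haplotype — pass an explicit representative count only if pooling "
            "is really intended"
        )
    return fisher_vs_reference(ms_ac_pooled, ms_an, ref_pooled)


class AggregateFrequency(NamedTuple):
    exact: float
    reported: float  # rounded to 2 decimals for tabulation


def aggregate_selected_frequency(
    selected_records: Sequence[VariantRecord],
    cohort_label: str,
    cohorts: CohortDesign,
    gm: GenotypeMatrix,
) -> AggregateFrequency:
    """Overall selected-variant allele frequency in one cohort.

    Sum of alternate alleles over the selected variants in the cohort's
    probands, divided by 2 x cohort size; ``cohort_label`` may be MSFAM, MSS,
    CTRL or MS_combined.
    """
    if cohort_label == "MS_combined":
        mask = cohorts.case_mask(gm.sample_ids, "MS_combined")
    else:
        mask = cohorts.mask(gm.sample_ids, cohort_label)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no samples in cohort {cohort_label}")
    if not selected_records:
        return AggregateFrequency(0.0, 0.0)
    sub = gm.subset_variants([r.key for r in selected_records])
    total_ac = float(sub.allele_counts(mask).sum())
    return allele_frequency(total_ac, n)


def allele_frequency(total_ac: float, n_individuals: int) -> AggregateFrequency:
    """Allele frequency total_ac / (2 n), with a 2-decimal reported value."""
    if n_individuals <= 0:
        raise ValueError("cohort size must be positive")
    exact = total_ac / (2 * n_individuals)
    return AggregateFrequency(exact=exact, reported=round(exact, 2))
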