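"""Core domain types for rare-variant aggregate analysis.

A study dataset is described by three containers: a list of
:class:`VariantRecord` (one annotated site each), a :class:`GenotypeMatrix`
of alternate-allele dosages (individuals x variants, with missingness), and a
:class:`CohortDesign` assigning each proband to the familial-case (MSFAM),
sporadic-case (MSS) or control (CTRL) cohort.  A :class:`GenePanel` names the
gene set whose aggregate variant burden is under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Consequence",
    "VariantRecord",
    "GenotypeMatrix",
    "CohortDesign",
    "GenePanel",
    "PROTEIN_ALTERING",
    "MSFAM",
    "MSS",
    "CTRL",
]

MSFAM = "MSFAM"
MSS = "MSS"
CTRL = "CTRL"
COHORT_LABELS = (MSFAM, MSS, CTRL)


class Consequence(str, Enum):
    """Functional consequence class of a coding variant."""

    missense = "missense"
    stop_gained = "stop_gained"
    stop_lost = "stop_lost"
    start_lost = "start_lost"
    splice_site = "splice_site"
    frameshift = "frameshift"
    inframe_indel = "inframe_indel"
    synonymous = "synonymous"
    non_coding = "non_coding"


#: Consequence classes kept by the rare protein-altering prefilter.
PROTEIN_ALTERING = frozenset(
    c for c in Consequence if c not in (Consequence.synonymous, Consequence.non_coding)
)

#: Consequence classes for which an absent CADD score is tolerated (indels
#: cannot be scored by the substitution-based CADD model).
CADD_UNSCORED_OK = frozenset({Consequence.frameshift, Consequence.inframe_indel})

VariantKey = tuple[str, int, str, str]


@dataclass
class VariantRecord:
    """One annotated variant site.

    ``ref_af``/``ref_ac`` are the allele frequency and count reported by the
    reference population database (gnomAD-like); both ``None`` means the
    variant is absent from the database.  ``call_rate`` is the fraction of
    cohort probands successfully genotyped at this site.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    consequence: Consequence | None = None
    protein_change: str | None = None
    cadd_phred: float | None = None
    ref_af: float | None = None
    ref_ac: int | None = None
    call_rate: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.consequence is not None:
            self.consequence = Consequence(self.consequence)
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("cadd_phred must be non-negative")
        if self.ref_af is not None:
            if not 0.0 <= self.ref_af <= 1.0:
                raise ValueError("ref_af must lie in [0, 1]")
            if self.ref_ac is None:
                raise ValueError("ref_af present requires ref_ac")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def in_reference_db(self) -> bool:
        return self.ref_ac is not None and self.ref_ac > 0

    def with_annotations(self, **kwargs) -> "VariantRecord":
        return replace(self, **kwargs)


class GenotypeMatrix:
    """Individuals x variants alternate-allele dosages with missingness.

    Dosages are stored as a float array with entries in {0, 1, 2} and ``nan``
    for a missing genotype call.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        variant_keys: Sequence[VariantKey],
        dosages: np.ndarray,
    ):
        sample_ids = list(sample_ids)
        variant_keys = [tuple(k) for k in variant_keys]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(variant_keys)) != len(variant_keys):
            raise ValueError("duplicate variant keys")
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(sample_ids), len(variant_keys)):
            raise ValueError(
                f"dosage shape {dosages.shape} inconsistent with "
                f"{len(sample_ids)} samples x {len(variant_keys)} variants"
            )
        valid = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (nan)")
        self.sample_ids = sample_ids
        self.variant_keys = variant_keys
        self.dosages = dosages
        self._key_index = {k: j for j, k in enumerate(variant_keys)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def call_rates(self) -> np.ndarray:
        """Per-variant fraction of non-missing genotypes."""
        if self.n_samples == 0:
            raise ValueError("no samples")
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def dataset_af(self) -> np.ndarray:
        """Alternate-allele frequency per variant over genotyped individuals."""
        called = ~np.isnan(self.dosages)
        an = 2 * called.sum(axis=0)
        ac = np.nansum(self.dosages, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
        return af

    def allele_counts(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        """Summed alternate-allele dosages per variant (missing ignored)."""
        d = self.dosages if sample_mask is None else self.dosages[sample_mask]
        return np.nansum(d, axis=0)

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries set to the variant mean dosage."""
        d = self.dosages.copy()
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(d, axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
        idx = np.where(np.isnan(d))
        d[idx] = col_mean[idx[1]]
        return d

    def subset_variants(self, keys: Iterable[VariantKey]) -> "GenotypeMatrix":
        keys = [tuple(k) for k in keys]
        cols = [self._key_index[k] for k in keys]
        return GenotypeMatrix(self.sample_ids, keys, self.dosages[:, cols])

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.variant_keys, self.dosages[rows])

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.variant_keys == other.variant_keys
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )


@dataclass
class CohortDesign:
    """Assignment of probands to the MSFAM / MSS / CTRL cohorts."""

    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {lab for lab in self.assignments.values() if lab not in COHORT_LABELS}
        if bad:
            raise ValueError(f"unknown cohort labels: {sorted(bad)}")

    def samples(self, *labels: str) -> list[str]:
        want = set(labels) if labels else set(COHORT_LABELS)
        return [s for s, lab in self.assignments.items() if lab in want]

    def mask(self, sample_ids: Sequence[str], *labels: str) -> np.ndarray:
        want = set(labels)
        return np.array(
            [self.assignments.get(s) in want for s in sample_ids], dtype=bool
        )

    def case_mask(self, sample_ids: Sequence[str], case_set: str = "MS_combined") -> np.ndarray:
        """Boolean case mask for one of the three case contrasts."""
        labels = {
            MSFAM: (MSFAM,),
            MSS: (MSS,),
            "MS_combined": (MSFAM, MSS),
        }[case_set]
        return self.mask(sample_ids, *labels)

    @property
    def n_msfam(self) -> int:
        return sum(1 for v in self.assignments.values() if v == MSFAM)

    @property
    def n_mss(self) -> int:
        return sum(1 for v in self.assignments.values() if v == MSS)

    @property
    def n_ctrl(self) -> int:
        return sum(1 for v in self.assignments.values() if v == CTRL)

    @property
    def n_ms_combined(self) -> int:
        return self.n_msfam + self.n_mss

    def n_cases(self, case_set: str) -> int:
        return {
            MSFAM: self.n_msfam,
            MSS: self.n_mss,
            "MS_combined": self.n_ms_combined,
        }[case_set]


@dataclass(frozen=True)
class GenePanel:
    """A named set of gene symbols whose aggregate burden is tested."""

    name: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes
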