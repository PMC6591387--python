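"""Synthetic reference database and case-control exome cohorts.

The generator emulates the statistical structure the downstream analysis
assumes.  A universe of potential protein-altering sites is drawn per gene;
each site has a true population MAF from a rare-dominated mixture (a point
mass of exceedingly rare sites at MAF ~ 1e-6 plus a log-uniform component up
to 0.05), a consequence class, and a CADD-phred score (frameshifts
unscored).  The reference database reports a binomial AC at ~246,000
alleles, so the rarest sites are stochastically absent from it.  Cohort
genotypes are binomial allele draws at the site's MAF — with a configurable
multiplicative case enrichment on designated-panel sites at the rare /
high-CADD end — and, as in real joint-called exome data, the returned
genotype matrix is ascertained: it contains only sites with at least one
observed alternate allele in the cohort.

Default mixture weights reproduce the scale of the emulated study: about
3 alleles per proband and about 2.5 discovered variants per gene over a
319-proband cohort.  All randomness flows from the single seed in
:class:`SimulationConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .types import (
    CTRL,
    MSFAM,
    MSS,
    CohortDesign,
    Consequence,
    GenePanel,
    GenotypeMatrix,
    VariantRecord,
)

__all__ = [
    "SimulationConfig",
    "SimulatedReference",
    "simulate_reference_db",
    "simulate_cohorts",
    "simulate_dataset",
    "write_dataset",
]

# per-consequence sampling probabilities and CADD-phred normal(mean, sd),
# loosely matching an exome's protein-altering consequence mix
CONSEQUENCE_MIX = (
    (Consequence.missense, 0.82, (15.0, 8.0)),
    (Consequence.stop_gained, 0.05, (35.0, 4.0)),
    (Consequence.splice_site, 0.04, (25.0, 6.0)),
    (Consequence.frameshift, 0.05, None),
    (Consequence.inframe_indel, 0.02, (18.0, 6.0)),
    (Consequence.start_lost, 0.01, (22.0, 5.0)),
    (Consequence.stop_lost, 0.01, (30.0, 5.0)),
)

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the emulated study's cohort sizes (86 + 89 cases, 144
    controls), a 62-gene designated panel inside a 1500-gene universe (a
    scaled-down stand-in for the exome-wide gene set random panels are drawn
    from), and a reference allele number of 246,000.  The potential-site
    density and mixture weights are chosen so a null cohort carries ~3.4
    panel alleles per proband and ~2.7 ascertained variants per gene, the
    scale of the emulated study.  ``enrichment`` is the multiplicative
    case-MAF factor applied to panel sites with true MAF below
    ``maf_enrich_cut`` (the rare range over which the emulated burden trend
    rises) and CADD-phred above ``cadd_enrich_cut`` (or unscored
    frameshifts); 1.0 is the null.
    """

    n_fam_cases: int = 86
    n_sporadic_cases: int = 89
    n_controls: int = 144
    n_genes: int = 1500
    panel_size: int = 62
    n_variants_per_gene: float = 400.0  # mean potential-site count per gene
    prop_ultra_rare: float = 0.985
    ultra_rare_maf: float = 1e-6
    maf_range: tuple[float, float] = (1e-6, 0.05)
    reference_an: int = 246_000
    missingness: float = 0.003
    enrichment: float = 1.0
    maf_enrich_cut: float = 1e-3
    cadd_enrich_cut: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.panel_size > self.n_genes:
            raise ValueError("panel_size must be <= n_genes")
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        for name in ("n_fam_cases", "n_sporadic_cases", "n_controls"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must lie in [0, 1)")

    @property
    def n_cases(self) -> int:
        return self.n_fam_cases + self.n_sporadic_cases

    def to_yaml(self, path: str | Path) -> None:
        import dataclasses

        import yaml

        d = dataclasses.asdict(self)
        d["maf_range"] = list(d["maf_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


@dataclass
class SimulatedReference:
    """Potential-site universe plus the hidden truth behind the database."""

    records: list[VariantRecord]
    true_maf: np.ndarray
    panel: GenePanel

    @property
    def genes(self) -> list[str]:
        return sorted({r.gene for r in self.records})

    def records_for(self, variant_keys) -> list[VariantRecord]:
        """Universe records matching the given keys, in the given order."""
        by_key = {r.key: r for r in self.records}
        return [by_key[tuple(k)] for k in variant_keys]


def _draw_true_maf(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    lo, hi = cfg.maf_range
    maf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    ultra = rng.random(n) < cfg.prop_ultra_rare
    maf[ultra] = cfg.ultra_rare_maf
    return maf


def simulate_reference_db(config: SimulationConfig) -> SimulatedReference:
    """Draw the potential-site universe and its reference-database state.

    Each site's database AC ~ Binomial(reference_an, true MAF); AC = 0
    leaves both AF and AC absent, mimicking a variant never observed by the
    database.  CADD-phred is drawn per consequence class and clipped to
    [0, 40]; frameshifts are unscored.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    panel = GenePanel("designated_panel", frozenset(genes[: config.panel_size]))

    n_per_gene = np.maximum(rng.poisson(config.n_variants_per_gene, size=config.n_genes), 1)
    n = int(n_per_gene.sum())

    gene_of = np.repeat(np.arange(config.n_genes), n_per_gene)
    true_maf = _draw_true_maf(rng, config, n)
    ref_ac = rng.binomial(config.reference_an, true_maf)

    csq_probs = np.array([w for _, w, _ in CONSEQUENCE_MIX])
    csq_idx = rng.choice(len(CONSEQUENCE_MIX), size=n, p=csq_probs / csq_probs.sum())
    ref_base = rng.integers(0, 4, size=n)
    alt_base = (ref_base + rng.integers(1, 4, size=n)) % 4  # always != ref
    cadd_mu = np.array([spec[0] if spec else np.nan for _, _, spec in CONSEQUENCE_MIX])
    cadd_sd = np.array([spec[1] if spec else np.nan for _, _, spec in CONSEQUENCE_MIX])
    with np.errstate(invalid="ignore"):
        cadd = np.clip(
            cadd_mu[csq_idx] + cadd_sd[csq_idx] * rng.normal(size=n), 0.0, 40.0
        )
    csq_of = [c for c, _, _ in CONSEQUENCE_MIX]
    chroms = [str(1 + g % 22) for g in range(config.n_genes)]
    an = config.reference_an

    records: list[VariantRecord] = []
    for i in range(n):
        g = int(gene_of[i])
        ac = int(ref_ac[i])
        records.append(
            VariantRecord(
                chrom=chroms[g],
                pos=1_000_000 + 100_000 * g + 10 * i + 1,
                ref=str(_BASES[ref_base[i]]),
                alt=str(_BASES[alt_base[i]]),
                gene=genes[g],
                consequence=csq_of[csq_idx[i]],
                protein_change=f"p.Sim{i}",
                cadd_phred=None if np.isnan(cadd[i]) else float(cadd[i]),
                ref_af=(ac / an) if ac > 0 else None,
                ref_ac=ac if ac > 0 else None,
            )
        )
    return SimulatedReference(records, true_maf, panel)


def _enriched_mask(refdb: SimulatedReference, config: SimulationConfig) -> np.ndarray:
    """Panel sites at the rare / high-CADD end that receive case enrichment."""
    in_panel = np.array([r.gene in refdb.panel for r in refdb.records])
    rare = refdb.true_maf < config.maf_enrich_cut
    cadd_hi = np.array(
        [
            (r.cadd_phred is not None and r.cadd_phred > config.cadd_enrich_cut)
            or (r.cadd_phred is None and r.consequence is Consequence.frameshift)
            for r in refdb.records
        ]
    )
    return in_panel & rare & cadd_hi


def _group_dosages(
    rng: np.random.Generator, n_group: int, acs: np.ndarray
) -> np.ndarray:
    # distribute each site's alternate alleles uniformly over the group's
    # 2 n chromosome slots (the exact conditional law of iid binomial draws
    # given their total)
    out = np.zeros((n_group, len(acs)))
    for j, ac in enumerate(acs):
        if ac == 0:
            continue
        slots = rng.choice(2 * n_group, size=int(ac), replace=False)
        out[:, j] = np.bincount(slots // 2, minlength=n_group).astype(float)
    return out


def simulate_cohorts(
    config: SimulationConfig, refdb: SimulatedReference
) -> tuple[GenotypeMatrix, CohortDesign]:
    """Genotype the three cohorts and ascertain the observed sites.

    Per individual and site, dosage ~ Binomial(2, MAF), with case MAF =
    min(0.5, enrichment x true MAF) at the designated enriched sites
    (sampled as group allele totals distributed over chromosome slots, which
    is equivalent).  Missing calls are planted completely at random at the
    configured rate.  The returned matrix keeps only sites with at least one
    observed alternate allele — the sites a joint-called cohort VCF would
    contain.
    """
    rng = np.random.default_rng(config.seed + 1)  # decoupled from refdb stream
    n_case, n_ctrl = config.n_cases, config.n_controls
    n_sites = len(refdb.records)

    case_maf = refdb.true_maf.copy()
    boost = _enriched_mask(refdb, config)
    case_maf[boost] = np.minimum(0.5, config.enrichment * case_maf[boost])

    case_ac = rng.binomial(2 * n_case, case_maf)
    ctrl_ac = rng.binomial(2 * n_ctrl, refdb.true_maf)

    # materialize genotype columns only for sites carrying alleles; the
    # all-reference columns are dropped by ascertainment anyway
    candidate = np.flatnonzero(case_ac + ctrl_ac > 0)
    dosages = np.vstack(
        [
            _group_dosages(rng, n_case, case_ac[candidate]),
            _group_dosages(rng, n_ctrl, ctrl_ac[candidate]),
        ]
    )
    if config.missingness > 0:
        dosages[rng.random(dosages.shape) < config.missingness] = np.nan

    observed_cols = np.flatnonzero(np.nansum(dosages, axis=0) > 0)
    observed = candidate[observed_cols]
    dosages = dosages[:, observed_cols]
    keys = [refdb.records[j].key for j in observed]

    fam_ids = [f"FAM{i:04d}" for i in range(config.n_fam_cases)]
    spo_ids = [f"SPO{i:04d}" for i in range(config.n_sporadic_cases)]
    ctl_ids = [f"CTL{i:04d}" for i in range(n_ctrl)]
    sample_ids = fam_ids + spo_ids + ctl_ids
    gm = GenotypeMatrix(sample_ids, keys, dosages)
    design = CohortDesign(
        {**{s: MSFAM for s in fam_ids}, **{s: MSS for s in spo_ids}, **{s: CTRL for s in ctl_ids}}
    )
    for rec, cr in zip(refdb.records_for(keys), gm.call_rates()):
        rec.call_rate = float(cr)
    return gm, design


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[SimulatedReference, GenotypeMatrix, CohortDesign]:
    """Reference universe plus an ascertained cohort dataset, one seed."""
    refdb = simulate_reference_db(config)
    gm, design = simulate_cohorts(config, refdb)
    return refdb, gm, design


def write_dataset(
    out_dir: str | Path,
    refdb: SimulatedReference,
    gm: GenotypeMatrix,
    design: CohortDesign,
) -> dict[str, Path]:
    """Write VCF + annotation TSV + cohort TSV + panel TSV + capture BED.

    Only the ascertained sites in ``gm`` are written, as in a real cohort
    callset; the annotation TSV covers exactly those sites.
    """
    import pandas as pd

    from .io import write_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "annotations": out / "annotations.tsv",
        "cohorts": out / "cohorts.tsv",
        "panel": out / "panel.tsv",
        "bed": out / "capture.bed",
    }
    write_vcf(paths["vcf"], gm)
    records = refdb.records_for(gm.variant_keys)
    pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "ref": [r.ref for r in records],
            "alt": [r.alt for r in records],
            "gene": [r.gene for r in records],
            "consequence": [r.consequence.value for r in records],
            "protein_change": [r.protein_change for r in records],
            "cadd_phred": [r.cadd_phred for r in records],
            "ref_af": [r.ref_af for r in records],
            "ref_ac": ["" if r.ref_ac is None else str(r.ref_ac) for r in records],
        }
    ).to_csv(paths["annotations"], sep="\t", index=False)
    pd.DataFrame(
        {"sample_id": gm.sample_ids, "cohort": [design.assignments[s] for s in gm.sample_ids]}
    ).to_csv(paths["cohorts"], sep="\t", index=False)
    pd.DataFrame({"gene": sorted(refdb.panel.genes)}).to_csv(
        paths["panel"], sep="\t", index=False
    )
    # one whole-span capture interval per chromosome (0-based half-open)
    with open(paths["bed"], "w") as fh:
        by_chrom: dict[str, list[int]] = {}
        for r in records:
            by_chrom.setdefault(r.chrom, []).append(r.pos)
        for chrom, positions in sorted(by_chrom.items()):
            fh.write(f"{chrom}\t{min(positions) - 1}\t{max(positions)}\n")
    return paths
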