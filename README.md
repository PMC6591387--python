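# rava — rare-variant aggregate burden analysis for case-control gene panels

`rava` implements the statistical core of a gene-panel rare-variant
case-control study: given exome genotypes for familial-case, sporadic-case
and control cohorts, per-variant annotations (gene, consequence, CADD-phred,
reference-database allele frequency/count) and a designated gene panel, it
asks whether cases carry an excess burden of rare, predicted-deleterious
variants in that panel — the design used to study inflammasome-pathway genes
in multiple sclerosis.

## What it computes

**Weighted burden test.** Each proband's burden is the weighted allele count
s_i = Σ_j w_j G_ij over panel variants, with Madsen–Browning frequency
weights w_j = 1/√(MAF_j(1−MAF_j)) taken from the reference database
(variants absent from the database are assigned MAF = 1e-6 by extrapolation
of the AC=1/AC=2 grid). Association with case status uses the score test of
the intercept-only logistic model, U = Σ s_i(y_i − ȳ),
Var U = ȳ(1−ȳ)Σ(s_i − s̄)², or its exact label-permutation version
(recommended at cohort sizes of a few hundred). Three contrasts (familial,
sporadic, combined cases vs controls) are held to a Bonferroni family-wise
threshold 0.01/3 ≈ 0.003.

**Cutoff sweeps.** The case/control ratio of qualifying allele counts
(normalized to cohort sizes, 0.5 pseudocount) is traced across 300 MAF
cutoffs (log-spaced, variants qualify strictly below) and 300 CADD cutoffs
(linear, qualify strictly above), plus the joint 2-D grid. "Selected"
variants are the fixed corner: effective reference MAF < 1e-5 and CADD > 20,
with frameshifts (unscorable by CADD) qualifying on MAF alone.

**Random-panel Monte Carlo.** The sweep trend is summarized by the OLS slope
of relative burden against rank position; the designated panel's slope is
compared with slopes of (by default) 100,000 random same-size gene panels
drawn from all genes with a retained variant, giving a one-sided add-one
empirical p-value.

**Per-variant enrichment.** Every variant seen in ≥2 case probands gets
two-sided Fisher exact tests of cohort allele counts against the reference
database's AC/AN (AN reconstructed as round(AC/AF), default 246,000 when
absent): case-significant but not control-significant (p < 0.01) ⇒
"MS enriched"; control-significant ⇒ "population specific". A
Yates-corrected chi-square compares the cohorts' shares of database-absent
variants, and perfectly co-occurring variants can be pooled as one
haplotype.

**Synthetic data.** `rava.simulate` generates seeded reference databases and
ascertained case-control cohorts with a rare-dominated site-frequency
spectrum and a configurable multiplicative case enrichment planted on the
panel's rare high-CADD sites, so every stage is testable without access to
the original exomes. `rava.fixtures` ships the study's printed tables (the
62-gene panel, 29 selected variants, 15 additional enriched variants) as
TSVs.

## Worked example

```sh
python analysis/01_build_fixtures.py
python analysis/02_simulate_cohort.py 1
python analysis/03_run_pipeline.py
```

The first driver exports the printed-table fixtures and checks them:

```
gene panel: 62 genes -> results/fixtures/panel_62_genes.tsv
classifier marks 29/29 selected (3 via the frameshift MAF-only rule)
aggregate selected allele frequency: MS 0.0829 (reported 0.08), CTRL 0.0104 (reported 0.01)
```

i.e. all 29 transcribed selected variants fall in the rare/deleterious
corner, and their aggregate allele frequencies round to the printed 0.08
(combined MS, n=175) and 0.01 (controls, n=144).

The second simulates a 319-proband cohort with a factor-20 enrichment
planted on the panel's rare high-CADD sites; the third runs the whole
pipeline on it:

```
burden MSFAM: p = 1.02e-09 (significant, 252 variants)
burden MSS: p = 1.42e-06 (significant, 252 variants)
burden MS_combined: p = 4.48e-09 (significant, 252 variants)
panel Monte Carlo (maf axis): slope 3.739, p = 0.01185 over 100000 random panels
panel Monte Carlo (cadd axis): slope 0.619, p = 0.02565 over 100000 random panels
```

All three burden contrasts beat the family-wise threshold 0.003, and the
panel's rising burden trend toward rarer (and more damaging) variants is
unexplainable by random gene sets — the qualitative signature of the
emulated study. `analysis/04_fixture_enrichment.py` re-runs the two-stage
Fisher rule on the printed counts and recovers exactly the two starred
variants (RIPK2 p.Pro194Ser, IFIH1 p.Met619Val) as both selected and MS
enriched; `05_calibration.py` and `06_power.py` measure null calibration
and planted-enrichment power over replicate cohorts.

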