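# Methods

## Study design being modeled

The package analyzes a three-cohort exome design: probands from multiplex
families (MSFAM, n=86), sporadic patients (MSS, n=89) and controls (CTRL,
n=144), genotyped at protein-altering variants in a designated 62-gene
panel (inflammasome regulation: NLRP1/NLRP3 sensors, PYCARD/CASP1 core,
priming via interferon and RNA-polymerase-III/RIG-like-receptor signaling,
sequestration, autophagy/mitophagy, and protein tyrosine phosphatases).
Variant rarity comes from a reference aggregation database of roughly
246,000 alleles; deleteriousness from CADD-phred. The central question is
whether cases carry an excess aggregate burden of rare, predicted-damaging
alleles in the panel.

## Pre-analysis filters

Variants are restricted to the intersection of all capture-kit BED files
(VCF positions are 1-based, BED intervals 0-based half-open; the conversion
lives in one place), to sites genotyped in strictly more than 95% of
probands, and to protein-altering consequences with both reference-database
AF and within-dataset AF ≤ 0.05. "Over 95%" is read as a strict
inequality; the threshold is a parameter. A variant absent from the
reference database passes the AF filter — the exceedingly rare end is the
object of study. Dataset AF is alternate-allele count over 2 × genotyped
individuals, missing calls excluded from the denominator. Multiallelic VCF
records are rejected rather than silently split. X-chromosome genotypes are
counted as coded (0/1/2) with no hemizygosity correction; how hemizygous
male genotypes contribute to allele totals is left to the upstream caller,
and X-linked variants are ordinary records here.

## Burden statistic and test

The collapsing score is s_i = Σ_j w_j G_ij with the Madsen–Browning weight
w = 1/√(MAF(1−MAF)) evaluated at the *reference-database* MAF, not the
cohort MAF; database-absent variants get MAF 1e-6, consistent with the
observed mapping of database AC 1 and 2 to ~4e-6 and ~8e-6 at AN ~246,000.
Missing dosages are imputed to the variant's mean observed dosage. The
association test is the score test of the intercept-only logistic null
(no covariates): U = Σ s_i(y_i − ȳ), Var U = ȳ(1−ȳ)Σ(s_i − s̄)², two-sided
normal reference. The exact permutation version permutes case labels and
uses the add-one estimator p = (1 + #{|U*| ≥ |U|})/(B + 1).

With a few hundred probands and weights spanning three orders of magnitude,
the normal reference is accurate in the rejection region but can be off by
a few hundredths at interior p-values; the permutation method is therefore
recommended for cohorts below ~2000 samples and is what the calibration
studies use. This is a known limitation of the asymptotic variant, not of
the statistic. Three contrasts (MSFAM, MSS, combined vs CTRL) are run with
a Bonferroni family-wise threshold α/3 at α = 0.01, reported at the
conventional 3-decimal precision (0.003) alongside the exact value.

## Cutoff sweeps and the selected corner

Relative burden at a cutoff pair is
((A_case + 0.5)/n_case) / ((A_ctrl + 0.5)/n_ctrl), where A sums alternate
alleles (not carriers) over qualifying variants. The 0.5 pseudocount keeps
ratios finite when one cohort has no qualifying alleles; it is applied
identically to both cohorts and noted in outputs. Qualification is strict:
effective reference MAF *below* the MAF cutoff, CADD-phred *above* the CADD
cutoff; frameshift variants, unscorable by CADD, qualify through the MAF
coordinate alone wherever a CADD criterion is active.

MAF cutoffs are equally spaced in log10 — the rare end spans several orders
of magnitude and linear spacing would collapse all structure into a few
grid points — over [2e-6, 0.05] with 300 points by default. The lower bound
sits just above the 1e-6 imputed to database-absent variants: with strict
"below" qualification, a bound of exactly 1e-6 would make the terminal grid
cell empty for every panel, a degenerate cell by construction. CADD cutoffs
are linear over [0, 40]. Both grids are parameters.

The selected-variant classifier is the fixed joint-grid corner: effective
reference MAF < 1e-5 and CADD-phred > 20 (frameshifts by MAF alone). A
missing CADD score on any other protein-altering consequence is treated as
an annotation-contract violation rather than silently passed.

## Random-panel Monte Carlo

The sweep trend is the OLS slope of relative burden against rank position
rescaled to [0,1] (lax → stringent); rank abscissa makes MAF- and CADD-axis
slopes comparable and insensitive to grid parameterization. Random panels
are drawn uniformly without replacement from the universe of genes with at
least one retained variant, the same genotype data being reused across
panels. The empirical p is one-sided — the alternative is excess burden
concentrating at the rare/damaging end, i.e. a larger slope — with the
add-one convention, so p is never exactly 0 and is reproducible given
(dataset, seed, panel count).

## Per-variant enrichment

For each variant carried by ≥2 case probands (carriers, not alleles, so a
single homozygote does not qualify; configurable), two two-sided Fisher
exact tests compare cohort alternate/reference allele counts with the
reference database: cases vs reference and controls vs reference. Nominal
p < 0.01 in the first but not the second ⇒ "MS enriched"; p < 0.01 in the
second ⇒ "population specific" (screened out regardless of the case test).
No multiplicity correction is applied at this stage — the rule is a
nominal-significance screen, and the ≥2-proband requirement is an
independent filter. The reference AN is reconstructed per variant as
round(AC/AF) from the printed pair; database-absent variants use the
default AN 246,000, the value implied by printed AC=2/AF=8.1e-6 pairs.
Fisher tests use the combined MS cohort. The odds ratio reported is the
sample (unconditional) odds ratio.

Database-absent variant counts (distinct variants, each cohort's total
discovered variants as background) are compared with a Yates-corrected
chi-square. Variants that co-occur perfectly in the same probands can be
pooled as a single haplotype: the pooled Fisher test takes one
representative count, and refuses to pool if per-variant counts disagree.

## Synthetic data generator

The generator emulates the *structure* of a joint-called exome study, not
any particular cohort:

- **Site universe.** Each gene carries a Poisson number of potential
  protein-altering sites (mean 400). A real gene offers thousands of
  possible substitutions, almost all of them exceedingly rare in any
  population sample; 400 is a conservative stand-in.
- **Frequency spectrum.** 98.5% of potential sites are a point mass at
  true MAF 1e-6 ("exceedingly rare"); the rest are log-uniform on
  [1e-6, 0.05]. These weights reproduce the scale of the emulated study:
  ~3.4 panel alleles per proband and ~2.5 ascertained variants per gene
  (the study reported 1031 alleles over 319 probands and 300 variants in
  62 genes).
- **Reference database.** Site AC ~ Binomial(246,000, true MAF); AC = 0
  records the variant as database-absent (for true MAF 1e-6 that happens
  with probability (1−1e-6)^246000 ≈ 0.78). Reported AF is AC/AN.
- **Consequences and CADD.** Consequence classes follow a typical
  protein-altering mix (82% missense); CADD-phred is normal per class,
  clipped to [0, 40]; frameshifts are unscored.
- **Cohorts and ascertainment.** Group allele totals are binomial at 2n
  trials and distributed uniformly over chromosome slots (the exact
  conditional law of per-individual Binomial(2, MAF) draws given their
  total). Missing calls are planted completely at random (default rate
  0.003, the study's 99.7% genotyping rate). Only sites with ≥1 observed
  alternate allele are returned — a joint-called VCF contains nothing
  else. This ascertainment step is what makes the rare end of the sweep
  informative: under case enrichment, more rare case variants are
  *discovered*.
- **Planted effect.** Case MAF = min(0.5, enrichment × true MAF) at panel
  sites with true MAF < 1e-3 and CADD > 20 (or unscored frameshifts).
  The MAF boundary mirrors where the emulated study's burden-ratio curve
  begins to rise; the CADD boundary is its deleteriousness threshold.
  enrichment = 1 is the exact null.
- **Universe size.** 1500 genes stand in for the exome-wide gene set that
  random panels are drawn from; at 62-gene panels the expected overlap
  between the designated and a random panel is ~2.6 genes. A larger
  universe would shrink this contamination further at proportional cost.

All randomness flows from the single config seed; equal configs give
byte-identical datasets.

What the generator does *not* model: linkage disequilibrium and haplotype
structure, relatedness and pedigrees (the emulated design kept one proband
per family), sex chromosomes and hemizygosity, population stratification
between cohorts and the reference, sequencing/calling artifacts correlated
with capture kit, and ascertainment of the *reference database* itself.
Passing tests therefore demonstrate the statistics behave correctly under
idealized sampling — calibrated nulls, expected power against a planted
multiplicative effect — not that any particular real-data p-value is
reproducible.

## Replicated studies and their sizes

- Burden type-I error: 1000 null cohorts at the design's 319 probands,
  exact permutation test (B = 2000), α = 0.05. Only the 62 panel genes are
  simulated here — the burden statistic involves no other site, so the
  reduction is exact.
- Panel Monte Carlo calibration: 200 null cohorts, 500 random panels each,
  on a 400-gene × 150-site universe. Under the null the designated panel
  is exchangeable with any random panel for *any* universe size, so the
  uniformity property is scale-free and the smaller universe only bounds
  runtime.
- Power: 50 cohorts at full default conditions with enrichment 20;
  detection = burden p < 0.003 (family-wise threshold) and MAF-axis panel
  p < 0.05 (500 panels, 100-point grid).
- The acceptance script runs the same studies at 400/100/30 replicates.

## Numerical and degenerate-input conventions

Constant phenotype is an error; constant burden scores give p = 1 with a
warning. Empty variant sets, inverted grid bounds, oversized random panels,
zero chi-square margins, and cohort AC > AN all raise with context. The
score-test p is floored at the smallest positive float. Fisher exact and
chi-square computations delegate to scipy.stats; exhaustive hypergeometric
enumeration and the hand-written Yates formula serve as independent oracles
in the test suite. Frequencies are exact internally and rounded (2 decimals
for aggregate frequencies, 3 for the family-wise threshold) only in
reported values.

## Known limitations

- The asymptotic score test drifts from the exact permutation p at interior
  values (a few hundredths at n ≈ 100–300); use the permutation method for
  inference at these sizes.
- Monte Carlo p-values have resolution 1/(n_panels+1); the default 100,000
  panels resolves to 1e-5.
- The two-stage enrichment rule compares cohorts of a few hundred alleles
  with a database of ~246,000; tiny cohort counts (2–3 alleles) sit at the
  edge of Fisher-test resolution, and common variants with large printed
  homozygote brackets are better handled upstream (the bracket counts are
  carried through but not separately modeled).
- The generator's multiplicative enrichment is a transparent, single-knob
  effect model; real architectures mix effect sizes and directions.
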