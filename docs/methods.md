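# Methods

`merinosim` simulates a closed herdbook sheep breeding nucleus — sized
after the German Merino population (469 breeding rams, 7185 breeding
ewes) — and compares genotyping strategies for single-step genomic
selection against the pedigree-BLUP status quo. This note documents the
model, the main numerical choices, and what the desk-scale defaults do
and do not establish.

## Population and genome model

The genome is a set of autosomes (default 26 × 1.0 Morgan) carrying
biallelic markers (default 50 000, evenly spaced). Meiosis follows the
Haldane model: crossovers are a Poisson process along each chromosome
with no interference and a sex-averaged map; there is no mutation during
the breeding programme and no sex chromosome.

Real 50K genotypes of 785 herdbook animals are not available, so
founder haplotypes are emulated:

1. **Ancestral panel** — per-marker allele frequencies from a symmetric
   Beta(0.5, 0.5) (U-shaped) spectrum, haplotypes drawn independently per
   marker, monomorphic markers resampled. Default 100 haplotypes.
2. **Mosaic copying** — 1570 haplotypes (two per emulated genotype
   donor) are built by copying one ancestral template at a time and
   switching templates at Poisson(1.0/Morgan) points. This produces
   block LD whose decay length is set by the switch rate. The real
   panel's LD decay and MAF spectrum are unpublished, so these defaults
   cannot be calibrated against it; they were fixed once as plausible
   for a diverse sheep breed and never revisited.
3. **Random mating** — five discrete generations with recombination
   build initial relatedness and pedigree; the final generation is
   assembled into the configured ram/ewe cohorts. Starting ages are
   sampled from the stationary distribution of the culling model so the
   age pyramid is stable from cycle 0.

## Traits

Two traits — health (h² = 0.1) and production (h² = 0.3) — share one set
of 1000 QTL drawn uniformly from the markers. Per-QTL effect pairs are
bivariate normal; the effect-level correlation is solved (closed form +
root bracketing) so the *realized* founder TBV correlation equals the
target −0.1 exactly for every draw. An alternative construction with
disjoint QTL sets would hit the target only in expectation; the shared
set was chosen as the simplest exact one. Affine scaling anchors founder
TBV mean/variance to exactly 100/10 per trait (population variance,
ddof = 0). Residuals are independent across traits and individuals,
variance 10·(1 − h²)/h² (health 90, production 23.33). Phenotypes are
own performances recorded once, when an animal enters a new-breeder
cohort; no sex effect.

## Breeding cycle

Per cycle: every ewe is mated to one uniformly drawn ram (reuse
allowed, no AI); litter sizes {1,2,3} with probabilities (0.3, 0.6, 0.1)
(mean 1.8); lambs survive with probability 0.9; sexes 50/50. The
surviving litters are then truncated/padded by resampling ewe–ram pairs
to exactly 6450 male and 6465 female lambs, because the selected-cohort
counts (2% → 129 rams, 20% → 1293 ewes) are the primary published
quantities and the demographic rates are mutually inconsistent with
them at the margin.

Selection is truncation on a total merit index (equal-weight sum of the
two trait EBVs — both traits have genetic variance 10, so the raw sum is
the equal-weight index). Scenarios genotyping only a fraction of a lamb
cohort first rank lambs on parental-information EBVs (a preselection
evaluation), genotype the top fraction, then re-evaluate with those
genotypes before final selection. Scenarios genotyping nobody (Ped) or
everybody (GS100, GS100+100) need a single evaluation per cycle.
Selected animals are phenotyped and, if genotyped, join the reference
population, which therefore grows by 129 (plus 1293 with female
genotyping) per cycle from the 469 rams genotyped at cycle 0. Old
breeders are culled with probability proportional to age² — a stable,
right-skewed age pyramid; exact culled counts equal the replacement
numbers so breeding cohorts stay at constant size. Survival among old
breeders is age-random only; an EBV-based retention of old breeders
would be a plausible alternative reading of the programme description
but is not implemented.

## Genetic evaluation

Two-trait animal model MME with trait means as the only fixed effects
and *true* variance components (no REML — isolates strategy effects).
The data window covers animals born in the last 10 cycles; pedigrees
are truncated 7 cycles further back; the genomic reference population
is retained in the window regardless of age (no sliding base). Culled
lambs without phenotype, retained genotype or descendants are dropped
from later windows — they contribute no information.

Relationship machinery: tabular A; inbreeding by Meuwissen–Luo (exact,
maintained incrementally at birth); Henderson's sparse A⁻¹ with
inbreeding; A sub-blocks via the T D T′ decomposition with sparse
triangular solves. G is VanRaden method 1 with centering frequencies
observed in the currently genotyped set (a practitioner has no base-
population frequencies; founder-frequency centering is a one-line
switch), blended Ĝ = 0.95 G + 0.05 A22. H⁻¹ = A⁻¹ +
blockdiag(0, Ĝ⁻¹ − A22⁻¹), with the genomic correction applied through
Cholesky solves. No τ/ω weighting and no mean/variance compatibility
scaling of G to A22 — the literature defaults in the absence of stated
constants.

Solver: purely sparse systems (PBLUP) by sparse LU, exact; ssGBLUP
systems by conjugate gradients preconditioned with the factorized
pedigree-only coefficient matrix, relative residual < 1e-8 (raising an
error otherwise). With zero genotyped animals the ssGBLUP path is
identical to PBLUP.

## Experiment design

Each replicate simulates founders + ten burn-in cycles under Ped
selection; every scenario then continues from an identical copy of that
cycle-0 state. Demographic random streams are keyed by (replicate,
cycle, purpose) only — not by scenario — giving common random numbers,
so the paired t-tests between scenarios are valid and variance-reduced.
Burn-in is re-simulated independently per replicate. Gain is reported in
genetic standard deviations (√10), zeroed at the cycle-0 cohort mean.
Accuracy is cor(TBV, EBV) within a cohort at the cycle's final
evaluation. Diversity metrics on the breeding ram cohort: mean pairwise
pedigree kinship A_ij/2 (self-pairs excluded; including them would add
(1+F)/2 terms and shift the level, not the scenario contrast) and
observed marker heterozygosity. Significance letters label maximal
cliques of the non-significance graph (paired t, p < 0.05, no
multiple-testing correction), so scenarios share a letter iff not
significantly different.

## Desk scaling

The full design (50K markers, 100 runs, ~13 000 lambs/cycle) is far
beyond a single-CPU desk budget. `RunConfig.desk(scale, n_markers)`
shrinks every cohort by `scale` with selection proportions fixed —
*and shrinks the genome*, to `max(2, round(26·scale))` chromosomes.
Rationale: genomic prediction accuracy is governed by the ratio of
reference-population size to the number of independently segregating
genome segments (Me). Scaling cohorts alone would cut the reference
population ~10–20-fold against a fixed Me and make ssGBLUP nearly
uninformative, misrepresenting the scenario contrasts; scaling the
chromosome count alongside keeps N_ref·h²/Me approximately invariant.
QTL count is capped at half the marker panel on small genomes.

What a green desk-scale run establishes: the direction and approximate
relative size of the scenario contrasts and the accuracy ordering.
Known desk-scale artifacts, measured with this package's own runs:

- Between-run SD of cycle-10 gain inflates roughly √(1/scale)-fold
  (drift), so means over a handful of replicates are noisy.
- PBLUP accuracies run ~10% below their full-scale levels at reduced
  cohort sizes. For the low-h² health trait this is amplified into a
  ~20% gain deficit, because the (fixed) negative-correlation drag from
  the strongly selected production trait subtracts from a smaller
  own-information signal. Ratios that divide by the pedigree-scenario
  health gain are therefore biased upward at desk scale.
- On a 2–3 chromosome desk genome, selection-driven allele-frequency
  change is concentrated instead of being diluted over 26 Morgan:
  hitchhiking makes the *genomic* scenarios lose marker heterozygosity
  faster than pedigree selection, inverting the full-scale expectation,
  while pedigree kinship still accumulates fastest under pedigree
  selection (family co-selection), as at full scale.

The synthetic founders also omit features of the real genotypes
(ascertainment bias of the chip, chromosome-length variation,
population substructure — though the source data showed no
stratification).

## Degenerate inputs and tie rules

Selection ties are broken by id (birth order) — deterministic. A trait
with zero founder variance, an all-monomorphic genotyped set, an empty
cohort/scenario list, cyclic or unsorted pedigrees, double phenotyping
and a window without phenotype records all raise errors rather than
propagate NaNs. Accuracy is reported missing for zero-variance EBVs and
cohorts smaller than three.
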