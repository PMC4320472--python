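# Methods

`xpopacc` studies the accuracy of genomic prediction when the reference
population (phenotyped and genotyped) and the selection candidates
(genotyped only) come from different populations — the situation of
numerically small cattle breeds borrowing information from a large one.
It implements two deterministic accuracy predictors, an empirical
GREML/GBLUP pipeline to validate them, and a gene-dropping simulator that
provides multi-breed genotype panels with a known truth.

## Deterministic accuracy

**Selection-index predictor.** The best linear prediction of the breeding
value of candidate *i* from population A given phenotypes of reference
population B is `b'y` with `b = Var(y)^-1 Cov(a_i, y)`.  With additive
gene action, genomic relationships `g` standing in for the covariances of
breeding values, and a genetic correlation `r_G` between the allele
substitution effects of the two populations, the accuracy reduces to

    r_i = r_G * sqrt( g_i' [G_B + R_B * (sigma_e^2/sigma_a^2)]^-1 g_i ),

where `g_i` holds the genomic relationships of the candidate with the
reference individuals and `G_B` those among the reference individuals.
With two reference populations B and C the bracket becomes the 2x2 block
matrix whose cross block is `r_G_BC * G_BC` (in variance-ratio form) and
the numerator stacks `r_G_AB g_B` and `r_G_AC g_C`.  Key requirement: the
GRM must be built with **population-specific allele frequencies**
(`x = (g - 2p_own)/sqrt(2 p_own (1-p_own))`), so that cross-population
relationships have expectation 0; each cross-population block then centers
to exactly zero on complete data, which the tests assert at 1e-12.

The environmental correlation structure `R` defaults to the identity:
simulated environments are independent, and nothing in the validation
pipeline parameterizes correlated environments.  The implementation solves
the bracketed system by Cholesky (one factorization shared by all
candidates of a scenario) and never forms an explicit inverse; a matrix
whose smallest eigenvalue is below `-1e-8 * trace/n` is rejected,
otherwise a single ridge of 1e-8 is applied (genomic covariance matrices
with duplicated relatives are near-singular).

**Population-parameter predictor.** Treating the genome as `Me`
independently segregating segments each explaining `sigma_a^2/Me`, the
accuracy for all candidates of a population is

    r_P = r_G * sqrt( N h^2 / (N h^2 + Me) ),

with `Me = 1 / Var(G_ij - A_ij)`; the variance is taken over reference
pairs (within-population mode) or over all reference x candidate pairs
(across-population mode), again with the own-frequency GRM.  Sample
variance (N-1 denominator) is used everywhere a variance over pairs is
taken; the sources are silent on the denominator and consistency was
preferred.

A small helper converts progeny counts to the reliability of a sire's
deregressed proof, `r^2` with `r = sqrt(n h^2/(n h^2 + 4 - h^2))`; 285
daughters at trait heritability 0.25 give reliability 0.95, which is why
the validation trait uses h^2 = 0.95.

## Empirical pipeline

Phenotypes are simulated on the panel (below), GREML is fitted on the
reference individuals, candidates are predicted through their genomic
relationships, and the empirical accuracy is the Pearson correlation of
EBV with true breeding values within each candidate population.

The GRM used for GREML follows the validation protocol: allele
frequencies pooled over breeds with equal weight per breed (so the largest
breed does not dominate), then two adjustments: (1) within-breed blocks
rescaled to the pedigree inbreeding level, `G* = (1-F_b) G + 2 F_b`, with
`F_b` the breed's mean pedigree inbreeding from a pedigree truncated at 7
generations; (2) regression towards the pedigree matrix,
`Ghat = A + b (G* - A)` with `b = (Var(G*-A) - 1/n)/Var(G*-A)` estimated
separately per breed pair and per bin of pedigree relationships
((-inf,0.10], (0.10,0.25], (0.25,0.50], (0.50,inf); cross-breed pairs have
A ~ 0 and land in the first bin), excluding self and direct
parent-offspring pairs (nearly free of sampling error), with `b` clipped
to [0,1] and defaulting to 1 in bins with at most one eligible pair.  The
deterministic formulas use the raw own-frequency GRM without these
adjustments, per their derivation; both pipelines accept any
RelationshipMatrix, so the pairing is a default, not a constraint.

**REML.** For the single-trait model `y = Xb + a + e` with
`Var(a) = G sa2`, `Var(e) = I se2` and breed as the only fixed effect, the
restricted likelihood is evaluated in the eigenbasis of the reference
block of G; the scale profiles out analytically (`sa2 = quad/(n-p)`),
leaving a bounded 1-D minimization over the log variance ratio
(`xatol` 1e-10, 200 evaluation cap).  The lower bound of the ratio keeps
`D + lambda I` positive definite (the adjusted GRM can carry tiny negative
eigenvalues).  This route is exact, derivative-free and cheap enough to
refit per replicate and per cross-validation fold; one eigendecomposition
is shared across replicates of a fixed panel.  A 2-D quasi-Newton
formulation was tried first and discarded: its line search stalls when it
crosses the infeasible region.

The two-population genetic-correlation model treats the same trait in two
breeds as two traits: `Var = [[sa2_A G_AA, r sa_A sa_B G_AB], [., sa2_B
G_BB]] + diag environmental variances`, environmental cross-covariance 0,
one fixed mean per breed.  The focal breed's variances and `r` are free
(parameterized `log sa2, log se2, atanh r`, so `|r| < 1` by construction);
the other breed's components are fixed at supplied values — small breeds
do not support reliable variance estimation.  Optimization is bounded
L-BFGS-B with a finite penalty outside the feasible region and a
Nelder-Mead polish.  Candidates' EBV carry no fixed-effect term for their
(unphenotyped) breed; this is harmless because accuracy is a
within-population correlation, which the tests assert is invariant to
adding a population-wide constant.

## Synthetic multi-breed panels

The generator emulates breeds that split from one ancestral gene pool:

1. **Ancestral pool.** 200 haplotypes with locus-wise frequencies drawn
   Uniform(0.1, 0.9) — mimicking the intermediate-frequency ascertainment
   of SNP chips — followed by 50 generations of random-mating burn-in in
   100 diploids to build short-range LD shared by all descendants.
2. **Divergence.** Each population draws founders from the pool (default
   50) and mates randomly at constant size for 20 generations.
3. **Breeding phase.** Two recorded generations per population with 10
   sires each, producing paternal half-sib families like dairy cattle; sex
   alternates at birth, which guarantees mating feasibility.  The returned
   panel is the final cohort (default 400/100/100); the pedigree covers
   the breeding phase, founders carrying unknown parents.

Recombination is Haldane (crossovers Poisson with mean = map length in
Morgans, breakpoints uniform, no interference) on three 1-Morgan
chromosomes with evenly spaced loci (2000/chromosome by default).  The
drift expectation of the full design — founder draw plus divergence at
Ne ~ 50 plus two breeding generations at Ne = 4 Ns Nd/(Ns+Nd) — puts
pairwise FST near 0.22; the simulator's Hudson-type estimator (ratio of
averages, nearly unbiased at small samples) reproduces it within 0.05.
Across-breed allele-frequency correlations come out around 0.55-0.65
after QC, a little below the 0.65-0.75 typical of real neighboring cattle
breeds; within-breed LD decays with map distance as required.

Marker QC removes, in order: loci with pooled MAF <= 0.5% (boundary
inclusive), loci with fewer than three observed genotype classes, and loci
in complete LD (r^2 = 1 within 1e-12) with the nearest retained locus to
their left on the same chromosome (the leftmost of a duplicated run is
kept, which makes the scan order-independent).  Missing genotypes are
rejected at input: the validation data are complete and all downstream
algebra assumes it.

**Traits.** A fixed pool of candidate-QTL loci (default 1000) is split
from the markers once per panel; each replicate draws its QTL from the
pool without replacement, so the marker set is constant across
replicates.  Allele substitution effects per population are standard
normal coupled through the Cholesky factor of the between-population
correlation matrix (a semidefinite matrix, e.g. all correlations 1, goes
through the eigendecomposition).  TBV = dosage-weighted effect sums,
linearly rescaled to mean 0 and variance 1 across populations — so the
genetic variance is identical for every QTL count — while between-breed
TBV means (from frequency divergence) remain.  Environmental noise has
variance `(1/h^2 - 1)` times the pooled variance of TBV corrected for the
within-breed means (one pooled variance, since a single heritability is
assumed for all breeds); the means are subtracted only for this variance
computation, never from the phenotype.  Default h^2 = 0.95, the
deregressed-proof level discussed above.  Replicate seeds are
`base_seed + 1000 * (replicate+1)`, so runs at different genetic
correlations share QTL draws and noise ("matched seeds") and ratios of
mean accuracies isolate the correlation effect.

## Problem sizes

Experiments run at desk scale, chosen once: the two-population protocol
uses 400 reference / 100 candidate individuals with 2600 loci per
chromosome (~6000 loci after QC, ~5000 markers); the single-population
protocol uses 400 individuals and ~2500 post-QC loci; proportionality
runs use 20 replicates of 300 QTL; recovery studies in the test suite use
a 250+100 panel with ~2300 loci and 15-20 replicates.  The full test
suite and the acceptance script each complete in minutes on one core.

## What the synthetic validation does and does not show

- The **proportionality** results are robust: deterministic accuracies
  scale exactly with `r_G` (a property of the formula), and empirical
  GREML accuracies scale with the simulated `r_G` within sampling error.
  The ratio-of-means estimator at 20 replicates is unbiased but has a
  seed-level standard deviation of several percentage points; the
  acceptance checks compare within ~2 combined standard errors.
- **Within-population** prediction is quantitatively consistent: mean
  leave-one-out selection-index accuracy ~0.96 versus cross-validated
  GREML accuracy ~0.93 under strong half-sib structure at h^2 = 0.95.
- **Across populations** the selection-index predictor comes out
  systematically optimistic relative to the empirical GREML accuracy on
  these synthetic panels (empirical/deterministic ~0.75-0.85).  This was
  traced to the generative model, not the machinery: when TBV are drawn
  from a multivariate normal with covariance equal to the very GRM used in
  the formula, the empirical accuracy reproduces the deterministic value
  to within Monte-Carlo error.  Locus-based traits with equal per-locus
  effect variance do not have the Yang own-frequency GRM as their exact
  cross-population covariance — the own-frequency standardization weights
  each locus by its within-breed heterozygosities, which no single shared
  effect-variance scheme can produce when frequencies diverge.  The gap is
  insensitive to QTL count, marker density and divergence age.  On real
  high-density cattle data the two agreed; the synthetic panels are a
  sharper test of that assumption than the data that motivated it.  The
  test suite tracks the ratio inside the band [0.65, 1.10] rather than
  asserting equality.
- The generator does not model mutation, selection during breeding,
  coalescent-exact ancestry, sequence-level realism, or low-MAF QTL
  enrichment; QTL frequency spectra match the chip-like marker spectrum.

## Numerical conventions

- Variances over relationship deviations and TBV use the N-1 denominator.
- The regression coefficient b is clipped to [0, 1]; small panels can
  produce out-of-range raw estimates.
- A zero variance of `G - A` deviations makes Me infinite and is an
  explicit error, as are non-positive-definite selection-index systems
  (reported with their smallest eigenvalue).
- Monomorphic or fixed loci under the chosen frequency scheme are
  excluded from the GRM entirely (count reported); excluding them per
  block would give blocks inconsistent denominators and destroy positive
  semidefiniteness.
- GREML fits are deterministic given inputs; all stochastic stages take
  explicit seeds and the whole pipeline is reproducible from
  `(config, base_seed)`.
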