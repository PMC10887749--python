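# Methods

This note records the models implemented, the numerical choices behind
them, what the simulator does and does not emulate, and the study sizes
used in the test and acceptance runs.

## Genotype simulator

Forward-in-time Wright–Fisher random mating. Loci start in linkage
equilibrium at uniform(0.05, 0.95) frequencies; `base_generations` of
finite-size random mating build LD, after which markers with MAF < 0.01
are dropped so the base panel is clean (downstream QC is exercised only
on deliberately injected violations). Recombination follows the Haldane
(no-interference) model: a gamete is built as a Markov chain along each
chromosome with switch probability ½(1 − e^(−2d)) per marker interval
(d in morgans); the first marker of each chromosome gets probability ½,
which doubles as the random template start. Markers are evenly spaced at
roughly 1 cM/Mb. Breeds draw founder haplotypes from the base pool
(without replacement within a breed; breeds may share founders, which is
what creates cross-breed relatedness) and then random-mate independently
at their census sizes. When `target_fst` is set, the number of drift
generations t solves 1 − λ^t = F with λ = 1 − 1/(2Ñ), Ñ the harmonic
mean breed size — adequate for F ≤ ~0.2 (verified to ±0.03 at F = 0.1).

Phenotypes: QTL positions drawn uniformly; each QTL's class comes from
the four-component mixture (relative variances 0, 10⁻⁴, 10⁻³, 10⁻²);
per-breed effect vectors at a QTL are multivariate normal with the
configured cross-breed correlation matrix (eigen factor, so rg = 1 gives
bitwise-identical effects). Residual variances are set per breed from the
realized TBV variance to hit the target h², so the phenotypic scale is
arbitrary but heritability is controlled. Fixed effects: gender, farm and
birth-year level effects drawn with SD 0.3 of the phenotypic SD, plus a
linear slaughter-age covariate over a configurable range (default
540–960 days). All randomness flows from one root seed through named
substreams (haplotypes, split, qtl, effects, fixed, residuals).

What the simulator does **not** emulate: mutation, selection, pedigree/
half-sib family structure, sex chromosomes, genotyping error and
missingness (missingness paths are tested with injected NaNs only), and
sequence-level realities (imputation error, rare-variant site frequency
spectra). Passing tests therefore demonstrate correctness of the
estimators under drift-generated LD and a clean mixture architecture,
not robustness to those nuisances.

## Two architecture regimes

Experiments that measure *variance-component recovery* (h², rg) use a
polygenic mixture (0.2, 0.4, 0.3, 0.1 over the four classes, ~½ of
markers as QTL). Under the sparse default the trait is driven by a
handful of large QTL and the *realized* effect correlation between
breeds has enormous seed-to-seed spread, which would measure
architecture sampling noise rather than estimator error. Experiments
that exercise *BayesR* use sparse mixtures, which is the regime the
model exists for.

## QC

Filter order is fixed — autosome, call rate (≥ 0.90), MAF (≥ 0.01),
Hardy–Weinberg exact test (p ≥ 10⁻⁶) — and each marker is accounted at
its first failing filter, so reports are deterministic and always
balance. With several breeds, call rate/MAF/HWE are evaluated per breed
and a marker must pass in every breed: per-breed HWE avoids Wahlund-
effect false failures on pooled data, and the intersection keeps one
marker set for all GRM blocks. The HWE test sums the probabilities of
all heterozygote counts no more probable than the observed one,
conditional on allele counts (verified against full enumeration for all
tables with ≤ 30 alleles). Missing dosages are imputed with the breed
mean 2p before matrix construction.

## LD statistics

Phased panels use exact haplotype frequencies (the signed r equals the
Pearson correlation of haplotype indicator columns); unphased panels
fall back to the composite-LD dosage correlation with a logged notice.
Phase persistence correlates the adjacent-pair LD statistic across two
populations per autosome and averages over autosomes. The scheme is a
parameter: `signed_r` (default — keeps phase information, ranges over
[−1, 1], standard practice for phase-persistence work) or `r_squared`.
Pairs with a monomorphic member in either population are skipped;
chromosomes need ≥ 3 usable pairs.

GLD weights: for each marker, the r² vector against its ten nearest
same-chromosome neighbours (by base-pair distance, ties toward the lower
index, truncated at chromosome ends) is correlated across the two
breeds. Markers with ≤ 1 shared usable pair, or a zero-variance profile,
receive the mean of the defined raw weights; raw weights are then
floored at 0, because a negative weight would make a marker's
cross-breed contribution meaning-inverting — under the floor the
weighted between block is a damped version of the unweighted one.
Residual indefiniteness of the assembled joint matrix is repaired by
eigenvalue bending (negative eigenvalues raised to 10⁻⁸), recorded in
the result; bending is applied only when the minimum eigenvalue is below
−10⁻⁸, so clean constructions are untouched bit for bit.

## GRMs

Raw-dosage cross products do not form a relationship matrix (nonzero
mean under no relatedness), so all blocks center dosages by twice the
own-breed allele frequency of the counted allele; the between-block
denominator is the geometric mean of the two breeds' Σ2pq sums. The
unit-weight LD-weighted matrix reproduces the unweighted matrix bit for
bit (the central reduction test). Three-breed matrices are assembled
pairwise, with one weight vector per breed pair under GLD.

## Mixed models

Single-trait REML is computed exactly on the GRM eigenbasis: with
G = USU′, the rotated model has diagonal covariance h²s_i + (1 − h²)
after profiling out the total variance, leaving a smooth 1-D restricted
likelihood in h² that a bounded scalar optimizer maximizes to machine
precision. This was chosen over an iterative AI-REML for the univariate
case because it cannot diverge, has no convergence tolerance coupling,
and is directly comparable to a grid-evaluation oracle. Boundary
estimates (h² pinned near 0 or 1) are flagged, not fatal.

The multi-trait (trait-per-breed) model uses AI-REML: parameters are the
genetic covariance matrix across breed-traits plus one residual variance
per trait (cross-breed residual covariance fixed at zero — no animal has
records in two breeds). Safeguards: starting values from per-breed
univariate fits; the Newton step capped so no component moves more than
one phenotypic variance per iteration; step halving (up to 40) when the
restricted likelihood would decrease; the genetic covariance iterate
projected back to the PSD cone (eigenvalue floor 10⁻⁶·max var);
convergence on an unhalved small step, or on three consecutive
negligible improvements when the iterate is pinned against a boundary.
Estimates at the rg = ±1 boundary are legitimate REML boundary solutions
under weak identification and are returned as such.

BLUP solutions use the covariance form ĝ = C V⁻¹(y − Xb̂) with b̂ by
GLS, algebraically identical to Henderson's equations but requiring no
G inverse, and extending naturally to unphenotyped individuals (their
rows of C carry the prediction). Reliabilities come from the
prediction-error variance of the same equations. Fixed-effect designs
one-hot factors against a first-level reference with slaughter age as a
linear covariate; rank deficiency raises an error naming the aliased
columns; validation rows with factor levels unseen in training are
dropped with a warning (the level effect is inestimable).

## BayesR

Model: y = Xb + Mα + e, α_j from the four-component mixture with
variances γ_c σ_g², γ = (0, 10⁻⁴, 10⁻³, 10⁻²), P ~ Dirichlet(1,1,1,1),
flat priors on fixed effects. A deterministic EM pass initializes the
chain: coordinate updates with soft responsibilities for the effects,
but a classification-style (hard-assignment, ties toward the
smaller-variance class) update for P. The hard update matters: for
markers whose per-class Bayes factors are uninformative the BF is an
exact martingale (E[BF] = 1), so a soft count update stalls at an
ambiguous fixed point, while hard assignment lets the null class absorb
them — on pure-noise phenotypes the EM then correctly concentrates all
responsibility on the zero class. The residual-variance update includes
the posterior effect variances (not just the plug-in residual), which
prevents the σ_e² → 0 collapse when markers outnumber records.

The Gibbs sampler sweeps markers in randomized order (per-sweep
permutation from a named substream), sampling each indicator from its
collapsed conditional with the marker's contribution removed from the
residual, then the effect from the conjugate normal (exactly 0 in
class 1); then P | z ~ Dirichlet(1 + counts); fixed effects from their
conditional normal; σ_e² from its flat-prior conditional; and σ_g² from
a scaled-inverse-chi-square conditional with ν = 4 and prior scale set
from the EM estimate. Implementation choices: effects are kept on their
natural scale and σ_g² sampled conditionally (equivalent to the
rescaled-effects parameterization, without the rescaling bookkeeping);
in addition a parameter-expansion move rescales (α, σ_g²) jointly along
the scale ridge each iteration, with the common factor drawn from its
data conditional — this anchors σ_g² to the realized genetic variance.
All per-iteration random numbers are pre-drawn in numpy so the numba
kernel is pure and chains are bit-reproducible under a fixed seed.
Burn-in defaults to 2,000 of 10,000 iterations with thinning 10
(conventional for chains of this scale); both are configurable.

A known identifiability limit, visible in the self-consistency
experiments: the zero class and the 10⁻⁴σ_g² class are individually
indistinguishable unless n·γ₂·σ_g²·2p̄q̄/σ_e² is well above 1, and below
that threshold the posterior spreads mass along a (P₁, P₂, σ_g²) ridge
("dense" solutions with many tiny effects). The mixture-recovery
experiment therefore uses records-per-marker n/m = 2 (n = 4000,
m = 2000), where all four components are resolvable; the two large-
variance classes are recovered tightly at any tested size.

## Cross-validation

Folds partition the target breed's phenotyped individuals; the training
set holds the target's remaining individuals (when the target is in the
reference) plus all phenotyped individuals of the other reference
breeds. Variance components, fixed effects and marker effects are
re-estimated per fold — masked phenotypes influence nothing. GRMs use
all genotypes by default (genotypes of selection candidates are always
available in practice); `ld_from_training_only=True` recomputes GLD
weights from training genotypes per fold for sensitivity analysis.
Accuracy is Pearson r between fold GEBV and y − Xb̂ within the target
breed; the summary is the mean of replicate means with its SE over
replicates (fold-level SE is used when only one replicate is run). A
fixed-size holdout mode (`holdout_size`) is provided as the alternative
protocol. Marker-density comparisons use nested marker sets from one
simulation, so they are paired.

## Study sizes used in tests and acceptance runs

Chosen as the package's desk-scale replication sizes:

* h² recovery: target 0.40, n = 1200, m = 2000, polygenic mixture,
  10 seeds (tolerance ±0.05 on the seed mean).
* rg recovery: target 0.8, n = 800/breed, m = 3000, breeds split 2
  generations ago from a shared base (recent-split demography is what
  identifies the cross-breed genetic covariance), 10 seeds (±0.1).
* BayesR mixture recovery: P = (0.95, 0.03, 0.015, 0.005), h² = 0.5,
  n = 4000, m = 2000, 5000 iterations, 4 seeds (±0.03 per component on
  the seed average); h² coverage: 20 seeds at n = 800, m = 400, 1500
  iterations (≥ 80% of nominal 90% intervals).
* Directional comparisons: 10 seeds each; BayesR vs GBLUP within breed
  at n = 800, m = 1500 with 20 large-effect QTL; multi-breed benefit
  with a 700-animal helper breed and a 250-animal target at rg = 0.8;
  density comparison with a 4× nested marker thinning.

## Known limitations

* The multi-trait AI-REML returns boundary-pinned rg when the data are
  uninformative about the cross-breed covariance; single-seed rg
  estimates are noisy even at n = 800/breed.
* The P₁/P₂ ridge above means BayesR mixture proportions should not be
  interpreted componentwise at low records-per-marker; genetic values
  and h² remain well calibrated there.
* The Fst-targeting formula ignores founder sampling and is inaccurate
  for targets beyond ~0.2.
* VCF input requires biallelic SNPs with integer chromosome names.
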