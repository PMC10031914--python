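# Methods

## The model

`crossblup` evaluates a three-way crossbred population, A x (B x C), with a
single-step SNPBLUP animal model.  The phenotypic model for the crossbred
records is

    y = X b + Z J mu_g + Z u_s + W c + e

where `b` is one combined categorical fixed factor (hatch batch x pen x
sex, cell-means coding), `u_s` is the additive genetic effect of every
pedigree animal, `c` is a non-genetic maternal permanent-environment effect
per dam (i.i.d.), and `e` is the residual.  Variance components
`(var_a, var_c, var_e)` are inputs, not estimated; the defaults are the
early-body-weight set 69.01 / 43.73 / 151.07 g^2, whose additive share
rounds to h^2 = 0.26.

For genotyped animals the breeding value decomposes as
`u_s,g = Z_g g + a_g`: explicit SNP effects `g` plus a residual polygenic
part carrying a proportion `w` (default 5%) of the additive variance.
Genotype dosages are centred at the observed allele frequencies of the
genotyped group, giving

    B = I (1 - w) / (2 sum_o p_o (1 - p_o)),     G = Z_c B Z_c' + w A_gg,

and the joint (ungenotyped, genotyped) covariance is the single-step `H`
built from the pedigree relationship matrix `A` (recursive tabular method,
inbreeding included, one base population, no genetic groups) and `G`.

## J-factor covariates

Centring at observed rather than base-generation frequencies forces the
mean genetic value of the genotyped group into the fixed part of the
model.  The J covariate carries that mean: `-1` for every genotyped animal
and `J_n = -A_ng A_gg^{-1} Q_g` for ungenotyped animals, where `Q_g` is a
column of ones (single factor, ONE) or the genotyped animals' breed
fractions (one factor per breed: pedigree-expected EXP, or observed OBS
from breed-of-origin analysis).  Reported breeding values are
`GEBV = J mu_hat + u_hat`.

Two computational routes are implemented and verified against each other:
the dense formula, and an ancestor-restricted solve followed by
parent-average propagation (oldest to youngest, unknown parents
contributing zero).  The routes agree to 1e-8 because, for an animal with
no genotyped descendants, the conditional expectation of its breeding
value given the genotyped animals is exactly the average of its parents'.

Useful algebraic facts, all enforced by tests: the single J covariate lies
in [-2, 0] on any pedigree; the breed-specific covariates sum per animal
to the single covariate (because breed fractions sum to 1), and that sum
obeys the same range; individual breed-specific entries can overshoot 0
slightly on arbitrarily admixed pedigrees, but stay in range on the
three-way-cross structure the package targets.

## Observed breed fractions

Observed crossbred fractions (e.g. from breed-of-origin-of-alleles calls)
are rescaled before use: the sire-breed contribution is fixed at 0.5
(exact for a three-way cross), and the two dam-breed columns are balanced
by iterative proportional scaling alternating (a) a multiplicative
column-mean correction to 0.25 with (b) a per-animal rescale of the two
dam entries to a combined 0.5, run to the joint fixed point (typically
< 10 sweeps to 1e-12).  A single (a)-(b) sweep — available via
`max_iter=1` — matches the narrated field procedure but is not idempotent:
step (b) perturbs the column means by ~1e-4 under realistic noise, so a
second pass would move entries again.  Running to the fixed point makes
the operation exactly idempotent while changing entries by only ~2e-4
relative to the single sweep; the package treats both constraints as
design knowledge of equal standing.  Purebred parents keep unit rows and
F1 dams keep (0, 0.5, 0.5): both are exact consequences of the mating
design, not estimates.

## Solving

The mixed-model equations are assembled densely and solved by Cholesky
factorization; the solver contract is a relative residual of at most 1e-8,
checked on every solve.  Because the coefficient matrix of `(b, u, c)`
does not depend on the J covariates, it is factorized once per genotyping
scenario and each J method is solved by bordering (a k x k Schur
complement), which makes the scenario grid over {NONE, ONE, EXP, OBS}
essentially free beyond the first solve.

J columns that are linearly dependent on the fixed design — notably a
single J-factor when every phenotyped animal is genotyped, which is
constant `-1` across records — are detected by a greedy least-squares test
(relative residual < 1e-8), constrained to zero, flagged non-estimable and
warned about.  This constrained solution makes the ONE evaluation at a
100% genotyping rate identical to fitting no J-factor, which is the
statistically correct degeneracy of that design cell.

An alternative parameterization with SNP effects explicit in the unknowns
(`solve_snp_level`) builds the joint prior covariance of
`(u_n, u_g, g)` from the conditional decomposition
`u_n = A_ng A_gg^{-1} u_g + eps` and solves the extended system; it is
mathematically equivalent to the H-matrix route and serves as its
cross-check (agreement to 1e-6 on randomized instances).  The
`(u_g, g)` prior covariance block is `Z_g B` — the direct consequence of
`u_g = Z_g g + a_g` with `cov(a_g, g) = 0`.

## Validation statistics

Sire GEBV are scored against progeny means: offspring records corrected
for the fixed factor with a sire model (random sire at the variance ratio
implied by a sire variance of h^2/4 of phenotypic), averaged per sire
(>= 2 offspring), weighted by the reliability
`(n h^2 / 4) / (1 + (n - 1) h^2 / 4)`.  Accuracy is the weighted Pearson
correlation (weighted central moments); dispersion is twice the weighted
regression of progeny mean on GEBV, with expectation 1 for unbiased GEBV
on the individual scale.  Report tables round half-away-from-zero to two
decimals.

Cross-validation partitions sires into five folds of near-equal size
(161 sires give 32/32/32/32/33); each fold's offspring form the validation
set.  Genotyping-rate scenarios (100/75/50/25%, random RND or phenotypic
TOP selection, ties broken by a seeded shuffle) select which reference
crossbreds keep their genotypes, stratified within each reference fold;
validation-fold animals keep neither phenotypes nor genotypes.  All
statistics are computed within fold.

## The synthetic population

The generator emulates a broiler three-way cross: three breeds diverged to
a pairwise F_ST of 0.24 under a Balding-Nichols allele-frequency model
(the drift parameter equals the Hudson-style pairwise F_ST between two
independently drifted populations), Hardy-Weinberg founders, Mendelian
gene dropping with per-allele breed-of-origin tracking, and phenotypes
built from SNP effects (variance calibrated at ancestral frequencies),
a pedigree-correlated residual polygenic part, maternal and residual
noise, and batch x pen x sex level effects (SD 8 g, a moderate barn
effect; the paper-silent choice).  Most of a sire's offspring share the
sire's home pen (probability 0.8), reproducing the pen-family confounding
of real broiler housing.  Observed breed fractions are the true
gene-dropped maternal contributions plus Normal(0, 0.02) noise, rescaled
as above.

Default census: 100 sires (born to 10 grandsires x 50 granddams, giving
half/full-sib ties between cross-validation folds), 5 F1 dams per sire, 4
offspring per mating — 2000 crossbreds, 2000 independent SNPs.  The census
scales the sire count down rather than the family size, because selective
genotyping acts within families and a realistic share of each sire's
offspring must be selectable.

What the generator does not emulate, and what that implies for the tests:
no linkage disequilibrium or genome map (claims about LD-dependent
accuracy levels are out of reach); no selection history in the founders
(divergence enters only through F_ST); a two-generation purebred pedigree
rather than a deep nucleus line.  The last point matters quantitatively:
in a deep real pedigree every sire is near-uniformly related to the
thousands of genotyped crossbreds, so the sire-level spread of the J
covariate is tiny, whereas the synthetic two-generation A line leaves a
spread of ~0.07.  Under TOP genotyping the fitted J coefficient is large
(|mu_hat| ~ 200-350 g — consistent with published magnitudes for this
model class, because it is identified only through the small contrast
between genotyped and ungenotyped records), so the `J mu_hat` term then
dominates the sire-EBV spread and the dispersion slope of the J-fitted
model degrades rather than improves at this scale.  The components of the
mechanism that are desk-verifiable do verify: fitting J improves the
correlation of `u_hat` with the true breeding values under selective
genotyping, the three J methods agree with each other essentially exactly,
and the 100% degeneracy is exact.

A related, intentional property: true SNP-effect variance is calibrated at
ancestral frequencies while the evaluation centres at observed
frequencies.  At F_ST 0.24 the two heterozygosity metrics differ, so the
truth-on-GEBV regression at full genotyping is attenuated to ~0.83; at
negligible divergence it is 1 within sampling noise (both are tested).

## Numerical choices

* Identity tolerances: 1e-8 for J-route equality and MME residuals, 1e-6
  for the H dual-construction and parameterization equivalences (two extra
  matrix inversions of accumulated error), 1e-10 for `A_gg` solves.
* Dense algebra throughout; intended for pedigrees up to ~20k animals.
* Ties and degeneracies: TOP ties broken by seeded shuffle; monomorphic
  SNPs retained with a warning (they centre to zero); `w = 1` handled as
  exact pedigree BLUP (no SNP block); `w = 0` refused where `G` must be
  inverted.
* Seeding: a single root seed spawns per-replicate seeds through
  `numpy.random.SeedSequence`; all outputs are byte-reproducible.

## Known limitations

Single-trait models only; no REML (components are inputs); no genetic
groups or metafounders; no random-regression variant of the genotype-mean
correction; the scenario grid holds variance components fixed across
genotyping scenarios, as the evaluation design assumes.
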