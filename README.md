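# crossblup

Single-step SNPBLUP for three-way crossbred populations with J-factor
genotype-mean covariates.

## The problem

Genomic evaluations centre SNP genotypes at the allele frequencies of the
animals that happen to be genotyped.  When genotyping is selective —
concentrated in recent generations, or restricted to the best phenotypes —
those frequencies are not the base-population frequencies, and the mean
breeding value of the genotyped group leaks into the estimates, inflating
the dispersion of genomic breeding values (GEBV).  The standard repair is
a fixed covariate, the *J-factor*: `-1` for every genotyped animal and the
pedigree regression `J_n = -A_ng A_gg^{-1} 1` for ungenotyped animals.  In
a crossbred population the genotyped group mixes breeds with different
means, so the single covariate generalizes to one per breed,
`J_n = -A_ng A_gg^{-1} Q`, with `Q` the genotyped animals' breed
fractions — pedigree-expected, or observed from breed-of-origin analysis.

`crossblup` implements this machinery end to end for an A x (B x C)
broiler-style cross, for quantitative geneticists who want to study
selective-genotyping bias and its J-factor correction in a controlled,
fully synthetic loop:

* pedigree algebra (tabular `A` with inbreeding, genotype-partitioned
  blocks),
* single and breed-specific J covariates by two verified routes,
* observed breed-fraction rescaling (sire breed fixed at 0.5, dam breeds
  balanced to mean 0.25 and pairwise sum 0.5),
* pedigree BLUP and single-step SNPBLUP (`y = Xb + ZJmu + Zu + Wc + e`,
  `G = ZBZ' + wA_gg`, GEBV `= J mu_hat + u_hat`), with an equivalent
  SNP-level parameterization as a cross-check,
* cross-validation of sire GEBV against progeny means with
  reliability-weighted accuracy and dispersion statistics
  (Cameron reliability `(nh^2/4)/(1+(n-1)h^2/4)`),
* a scenario grid over J methods {NONE, ONE, EXP, OBS} x genotyping rates
  {100, 75, 50, 25%} x selection schemes {RND, TOP},
* a synthetic three-way-cross generator (Balding-Nichols breed divergence,
  Mendelian gene dropping with breed-of-origin tracking).

The model classes follow the scikit-learn estimator protocol
(`get_params`/`set_params`/`clone`, `fit`, fitted attributes with trailing
underscores, `predict(animal_labels)`).

## Worked example

```python
import crossblup as cb

cfg = cb.SimulationConfig(n_sires=20, n_a_grandsires=4, n_a_granddams=10,
                          n_founders_b=10, n_founders_c=40, dams_per_sire=3,
                          offspring_per_mating=3, n_snps=500, seed=42)
ds = cb.simulate_population(cfg)

# selective genotyping: the top 50% of crossbreds by phenotype keep genotypes
genotyped = cb.apply_genotyping_scheme(ds.crossbred_labels, 0.5, "TOP",
                                       ds.phenotypes["y"].to_numpy(), seed=1)
sub = cb.partition(ds.ped, genotyped)
J = cb.compute_J_direct(sub, None, ped=ds.ped)   # single J-factor (ONE)

model = cb.SingleStepSNPBLUP(var_a=69.01, var_c=43.73, var_e=151.07, w=0.05)
model.fit(ds.phenotypes[["animal", "y", "fixed", "dam"]], ds.ped,
          (genotyped, ds.dosages_for(genotyped)), J=J)

h2 = 69.01 / (69.01 + 43.73 + 151.07)
rec = cb.sire_progeny_means(ds.phenotypes[["y", "fixed", "sire"]], h2)
gebv = model.predict(rec["sire"].to_numpy())
print(cb.weighted_accuracy(gebv, rec["progeny_mean"], rec["reliability"]),
      cb.dispersion_slope(gebv, rec["progeny_mean"], rec["reliability"]))
```

This prints (alongside the intermediate values shown here):

```
324 animals, 180 crossbred records
J of a genotyped crossbred:   -1.0
J of an ungenotyped sire:     -1.085
fitted J coefficient (g):     -113.6
weighted accuracy 0.12, dispersion slope 0.10
```

Reading the numbers: every genotyped animal carries the covariate value
`-1` by definition; the ungenotyped sire's value (`-1.085`) is his
pedigree regression on the genotyped group.  Because the genotyped half
was phenotypically selected, the fitted J coefficient is large and
negative (about five phenotypic SDs) — it absorbs the selected group's
elevated mean.  The weighted accuracy and the doubled regression slope of
progeny means on sire GEBV are the two validation statistics; a slope of 1
would mean correctly dispersed GEBV.  At a 100% genotyping rate the single
J column is constant across records, so it is confounded with the general
mean: the package constrains it to zero with a warning, and the ONE and
NONE evaluations coincide exactly.

The same loop at scale, over the full scenario grid, is one call:

```sh
crossblup run --seed 1 --out results/grid          # full default grid
crossblup simulate --seed 1 --out simdata          # just write a dataset
crossblup jfactor --pedigree simdata/pedigree.csv --genotypes geno.tsv --out J.tsv
```

`run` writes per-scenario detail and summary TSVs plus report-shaped
accuracy and dispersion pivot tables, a J-covariate summary and a
J-coefficient summary, and a `run.log` with the seed and per-stage
timings.  Identical seeds give byte-identical outputs.

## Layout

| module | contents |
| --- | --- |
| `crossblup.pedigree` | pedigree validation, `A`, partitions, `A_gg` solves |
| `crossblup.jfactor` | direct and propagated J covariates, row-sum identity |
| `crossblup.breed_fractions` | expected and rescaled observed `Q` |
| `crossblup.model` | centring, `B`, `G`, `H`, the MME solver, SNP-level route |
| `crossblup.estimators` | scikit-learn style model classes |
| `crossblup.validation` | edits, folds, genotyping schemes, weighted statistics |
| `crossblup.grid` | the scenario grid (also exposed via `crossblup.validation`) |
| `crossblup.simulate` | the synthetic three-way cross |
| `crossblup.pipeline` / `crossblup.cli` | orchestration and the `crossblup` command |

See `docs/methods.md` for the model details, the generator's assumptions,
and known limitations.
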