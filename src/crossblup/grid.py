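"""The scenario grid: J-method x genotyping-rate x selection-scheme runs.

For every cross-validation fold, the validation sires' offspring are
removed from the reference population, a genotyped subset of the remaining
crossbreds is drawn at the scenario's rate (randomly or from the top
phenotypes), J covariates are built for the scenario's method, the
single-step model is solved, and the validation sires' GEBV are scored
against their corrected progeny means with reliability-weighted statistics.

All statistics are computed within fold.  Two degeneracies of the design
are handled explicitly: at a 100% genotyping rate the RND and TOP schemes
coincide, and a single J-factor (ONE) is confounded with the general mean,
making it equivalent to fitting no J-factor (NONE); duplicated cells are
computed once and cross-referenced in the ``note`` column.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breed_fractions import BreedFractionMatrix, expected_fractions
from .jfactor import compute_J_direct
from .model import MMEFactor, ModelSpec, build_B, build_G, center_genotypes, h_inverse
from .pedigree import a_matrix, partition
from .simulate import SimulatedDataset
from .validation import (
    apply_genotyping_scheme,
    dispersion_slope,
    make_folds,
    sire_progeny_means,
    weighted_accuracy,
)

J_METHODS = ("NONE", "ONE", "EXP", "OBS")


@dataclass
class GridConfig:
    """Grid selections and bookkeeping for one trait evaluation."""

    j_methods: tuple = J_METHODS
    rates: tuple = (1.0, 0.75, 0.5, 0.25)
    schemes: tuple = ("RND", "TOP")
    n_folds: int = 5
    replicates: int = 1
    max_folds_per_replicate: int | None = None
    w: float = 0.05
    seed: int = 0

    def __post_init__(self):
        bad = [m for m in self.j_methods if m not in J_METHODS]
        if bad:
            raise ValueError(f"unknown J method(s) {bad}; menu is {J_METHODS}")
        for r in self.rates:
            if not any(math.isclose(r, x) for x in (1.0, 0.75, 0.5, 0.25)):
                raise ValueError(f"rate {r} outside the design menu")
        for s in self.schemes:
            if s not in ("RND", "TOP"):
                raise ValueError(f"unknown scheme {s!r}")


def _j_for_method(method, ped, sub, exp_Q, obs_Q):
    if method == "NONE":
        return None
    if method == "ONE":
        return compute_J_direct(sub, None, ped=ped, method_tag="ONE")
    if method == "EXP":
        Qg = exp_Q.subset(sub.genotyped_labels)
        return compute_J_direct(sub, Qg, ped=ped, method_tag="EXP",
                                breed_labels=exp_Q.breed_labels)
    Qg = obs_Q.subset(sub.genotyped_labels)
    return compute_J_direct(sub, Qg, ped=ped, method_tag="OBS",
                            breed_labels=obs_Q.breed_labels)


def scenario_grid(dataset: SimulatedDataset, config: GridConfig | None = None,
                  progress: bool = False) -> pd.DataFrame:
    """Run the grid on one dataset (one trait).

    Returns a per-(replicate, fold, rate, scheme, j_method) table with the
    weighted validation correlation (``accuracy``), the doubled weighted
    dispersion regression (``slope2``), the fitted J coefficients
    (``mu_A``/``mu_B``/``mu_C``, or ``mu_A`` alone for ONE), the mean fitted
    J covariate of the phenotyped reference animals per breed column, and a
    ``note`` marking degenerate duplicated cells.
    """
    cfg = config or GridConfig()
    ped = dataset.ped
    simc = dataset.config
    A = a_matrix(ped)
    var_a, var_c, var_e = simc.var_a, simc.var_c, simc.var_e
    h2 = var_a / (var_a + var_c + var_e)

    phen = dataset.phenotypes
    progeny = sire_progeny_means(phen[["y", "fixed", "sire"]], h2)
    progeny = progeny.set_index("sire")

    exp_Q = expected_fractions(ped, dataset.founder_breed)
    # OBS = breed-of-origin fractions for crossbreds; parents and purebred
    # ancestors have exactly known composition and keep their expected rows
    obs_vals = exp_Q.values.copy()
    obs_vals[ped.index_of(dataset.crossbred_labels)] = \
        dataset.observed_fractions.subset(dataset.crossbred_labels)
    obs_Q = BreedFractionMatrix(obs_vals, ped.labels.copy(), exp_Q.breed_labels, "OBS")


    root = np.random.SeedSequence(cfg.seed)
    rep_seqs = root.spawn(cfg.replicates)
    rows = []
    for rep, rep_seq in enumerate(rep_seqs):
        rng = np.random.default_rng(rep_seq)
        folds = make_folds(dataset.sire_labels, cfg.n_folds, rng)
        fold_phen = [phen[phen["sire"].isin(set(f.tolist()))] for f in folds]
        n_eval = len(folds) if cfg.max_folds_per_replicate is None \
            else min(len(folds), cfg.max_folds_per_replicate)
        for fold_i, val_sires in enumerate(folds[:n_eval]):
            val_set = set(val_sires.tolist())
            is_val = phen["sire"].isin(val_set).to_numpy()
            ref = phen.loc[~is_val].reset_index(drop=True)
            ref_animals = ref["animal"].to_numpy()
            val_tab = progeny.loc[progeny.index.isin(val_set)]

            for scheme in cfg.schemes:
                for rate in cfg.rates:
                    if math.isclose(rate, 1.0) and scheme != cfg.schemes[0]:
                        # with everyone genotyped the schemes coincide
                        for r in [r for r in rows
                                  if r["replicate"] == rep and r["fold"] == fold_i
                                  and math.isclose(r["rate"], 1.0)]:
                            dup = dict(r)
                            dup["scheme"] = scheme
                            dup["note"] = (dup["note"] + "; " if dup["note"] else "") + \
                                f"duplicate of {cfg.schemes[0]} at rate 1.0"
                            rows.append(dup)
                        continue
                    # only crossbreds carry (usable) genotypes; the scenario
                    # selects which reference crossbreds keep theirs,
                    # stratified within each reference fold
                    genotyped = np.sort(np.concatenate([
                        apply_genotyping_scheme(
                            fp["animal"].to_numpy(), rate, scheme,
                            fp["y"].to_numpy(), rng)
                        for j, fp in enumerate(fold_phen) if j != fold_i
                    ]))
                    sub = partition(ped, genotyped, A=A)
                    Zc, p = center_genotypes(dataset.dosages_for(sub.genotyped_labels))
                    G = build_G(Zc, build_B(p, cfg.w), cfg.w, sub.A_gg)
                    H_inv = h_inverse(ped, sub, G, A=A)
                    spec = ModelSpec(
                        y=ref["y"].to_numpy(dtype=float),
                        fixed_levels=ref["fixed"].to_numpy(),
                        record_animals=ref_animals,
                        dams=ref["dam"].to_numpy(),
                        ped=ped,
                        var_a=var_a, var_c=var_c, var_e=var_e,
                        genotypes=(sub.genotyped_labels,
                                   dataset.dosages_for(sub.genotyped_labels)),
                        w=cfg.w,
                    )
                    factor = MMEFactor(spec, K_inv=H_inv)

                    cache = {}
                    for method in cfg.j_methods:
                        note = ""
                        if method == "NONE" and math.isclose(rate, 1.0) \
                                and "ONE" in cfg.j_methods:
                            note = "identical to ONE at rate 1.0 (J confounded with mean)"
                        key = "NONE" if (math.isclose(rate, 1.0)
                                         and method in ("NONE", "ONE")) else method
                        if key in cache:
                            J, sol = cache[key]
                        else:
                            J = _j_for_method(key, ped, sub, exp_Q, obs_Q)
                            with warnings.catch_warnings():
                                warnings.simplefilter("ignore")
                                sol = factor.solve(J)
                            cache[key] = (J, sol)
                        gebv = pd.Series(sol.gebv, index=sol.animal_labels)
                        g_val = gebv.loc[val_tab.index.to_numpy()].to_numpy()
                        wts = val_tab["reliability"].to_numpy()
                        pm = val_tab["progeny_mean"].to_numpy()
                        row = {
                            "rate": rate, "scheme": scheme, "j_method": method,
                            "replicate": rep, "fold": fold_i,
                            "accuracy": weighted_accuracy(g_val, pm, wts),
                            "slope2": dispersion_slope(g_val, pm, wts),
                            "n_val_sires": len(val_tab),
                            "n_genotyped": len(genotyped),
                            "note": note,
                        }
                        for name in ("mu_A", "mu_B", "mu_C", "jbar_A", "jbar_B", "jbar_C"):
                            row[name] = np.nan
                        if J is not None:
                            mu = sol.j_coefficients
                            for j in range(len(mu)):
                                name = f"mu_{'ABC'[j]}"
                                row[name] = np.nan if sol.j_nonestimable[j] else mu[j]
                            # mean fitted J covariate of the phenotyped animals
                            Jph = J.subset(ref_animals)
                            for j in range(Jph.shape[1]):
                                row[f"jbar_{'ABC'[j]}"] = float(Jph[:, j].mean())
                        rows.append(row)
            if progress:
                print(f"replicate {rep} fold {fold_i} done")
    out = pd.DataFrame(rows)
    cols = ["rate", "scheme", "j_method", "replicate", "fold", "accuracy", "slope2",
            "mu_A", "mu_B", "mu_C", "jbar_A", "jbar_B", "jbar_C",
            "n_val_sires", "n_genotyped", "note"]
    return out[cols]


def summarize_grid(detail: pd.DataFrame) -> pd.DataFrame:
    """Per-cell means and SDs over replicates (fold statistics averaged
    within replicate first, mirroring a replicate-level summary)."""
    per_rep = (detail.groupby(["rate", "scheme", "j_method", "replicate"], sort=False)
               [["accuracy", "slope2"]].mean().reset_index())
    g = per_rep.groupby(["rate", "scheme", "j_method"], sort=False)
    out = g.agg(accuracy_mean=("accuracy", "mean"), accuracy_sd=("accuracy", "std"),
                slope2_mean=("slope2", "mean"), slope2_sd=("slope2", "std"),
                n_replicates=("accuracy", "size")).reset_index()
    return out
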