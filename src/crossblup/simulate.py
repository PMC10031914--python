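"""Synthetic three-way crossbred populations.

Emulates the data structure the analysis modules assume: three divergent
purebred founder lines (A, B, C), F1 B x C dams mated to purebred A sires
producing A(BC) crossbreds, a combined batch x pen x sex fixed factor,
and phenotypes with additive genetic, non-genetic maternal permanent
environment and residual components.  Breed divergence is generated with a
Balding-Nichols allele-frequency model calibrated to a target pairwise
F_ST; genotypes descend through the pedigree by Mendelian gene dropping
with per-allele breed-of-origin tracking, which yields true (and, with
noise, "observed") breed fractions for every crossbred.

Independent SNPs are simulated (no linkage map): the quantities under
study — genotype-group means, selective-genotyping bias, J-factor
corrections — do not depend on LD structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breed_fractions import BreedFractionMatrix, scale_observed_fractions
from .pedigree import Pedigree, validate_and_sort

BREEDS = ("A", "B", "C")


@dataclass
class SimulationConfig:
    """Study-design knobs of the simulated three-way cross.

    Defaults follow the structure of a broiler crossbreeding experiment at
    a reduced census: A-line sires born to a grandparent generation, F1
    (B x C) dams, 20 offspring per sire across five hatch batches and 20
    pens, and the body-weight-at-7-days variance components (trait units
    are grams).  Sire count, rather than family size, is scaled down so
    that within-family selective genotyping behaves realistically.
    """

    n_snps: int = 2000
    n_sires: int = 100               # breed A sires of the crossbreds
    n_a_grandsires: int = 10         # breed A founders fathering the sires
    n_a_granddams: int = 50          # breed A founders mothering the sires
    n_founders_b: int = 60           # breed B founders (sires of F1 dams)
    n_founders_c: int = 240          # breed C founders (dams of F1 dams)
    dams_per_sire: int = 5           # F1 dams mated to each A sire
    offspring_per_mating: int = 4
    n_batches: int = 5
    n_pens: int = 20
    target_fst: float = 0.24
    var_a: float = 69.01
    var_c: float = 43.73
    var_e: float = 151.07
    w_true: float = 0.05             # residual polygenic share of var_a
    fixed_sd: float = 8.0            # SD of batch x pen x sex level effects
    home_pen_prob: float = 0.8       # chance an offspring joins its sire's home pen
    frac_noise_sd: float = 0.02      # noise on observed breed fractions
    seed: int = 0

    def __post_init__(self):
        for name in ("n_snps", "n_sires", "n_founders_b", "n_founders_c",
                     "dams_per_sire", "offspring_per_mating", "n_batches", "n_pens"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.target_fst < 0.5:
            raise ValueError("target_fst must be in [0, 0.5)")

    @property
    def n_f1_dams(self) -> int:
        return self.n_sires * self.dams_per_sire


@dataclass
class SimulatedDataset:
    """A population ready for the full evaluation pipeline."""

    config: SimulationConfig
    ped: Pedigree
    phenotypes: pd.DataFrame            # animal, y, fixed, dam, sire, batch, pen, sex
    dosages: np.ndarray                 # all animals x SNPs, pedigree order
    founder_breed: dict                 # founder label -> breed
    breed_freqs: np.ndarray             # 3 x SNPs
    ancestral_freqs: np.ndarray
    true_bv: np.ndarray                 # pedigree order
    true_snp_effects: np.ndarray
    true_maternal: pd.Series
    true_fractions: BreedFractionMatrix     # crossbreds only
    observed_fractions: BreedFractionMatrix  # scaled OBS Q for crossbreds
    crossbred_labels: np.ndarray
    sire_labels: np.ndarray

    def dosages_for(self, labels) -> np.ndarray:
        return self.dosages[self.ped.index_of(labels)]


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def simulate_founder_breeds(config: SimulationConfig, rng: np.random.Generator):
    """Breed allele frequencies (Balding-Nichols) and founder genotypes.

    Ancestral frequencies are Uniform(0.05, 0.95); each breed's frequency
    at a SNP is Beta-distributed around the ancestral value with drift
    parameter ``F`` equal to the target pairwise F_ST: two independently
    drifted breeds satisfy ``E[(p1-p2)^2] / E[p1(1-p2) + p2(1-p1)] = F``
    (Hudson-style estimator).
    """
    m = config.n_snps
    anc = rng.uniform(0.05, 0.95, size=m)
    F = config.target_fst
    freqs = np.empty((3, m))
    if F == 0.0:
        freqs[:] = anc
    else:
        shape = (1.0 - F) / F
        for b in range(3):
            freqs[b] = rng.beta(anc * shape, (1.0 - anc) * shape)
    freqs = np.clip(freqs, 1e-6, 1 - 1e-6)
    counts = {"A": config.n_a_grandsires + config.n_a_granddams,
              "B": config.n_founders_b, "C": config.n_founders_c}
    haplos = {}
    for b, breed in enumerate(BREEDS):
        n = counts[breed]
        haplos[breed] = (rng.random((n, 2, m)) < freqs[b]).astype(np.int8)
    return anc, freqs, haplos


def pairwise_fst(p1: np.ndarray, p2: np.ndarray) -> float:
    """Hudson-style F_ST between two populations from allele frequencies."""
    num = np.mean((p1 - p2) ** 2)
    den = np.mean(p1 * (1 - p2) + p2 * (1 - p1))
    return float(num / den)


# ---------------------------------------------------------------------------
# pedigree and gene dropping
# ---------------------------------------------------------------------------

def build_cross_pedigree(config: SimulationConfig, rng: np.random.Generator):
    """Pedigree of the A x (B x C) design plus housing/sex assignments.

    Returns ``(ped, founder_breed, meta)`` where ``meta`` is a per-crossbred
    DataFrame with sire, dam, batch, pen, sex and the combined fixed level.
    Most of a sire's offspring share that sire's home pen; sexes are drawn
    balanced within batch.
    """
    rows = []
    label = 0

    def new(sire=0, dam=0):
        nonlocal label
        label += 1
        rows.append((label, sire, dam))
        return label

    # the A line has pedigree depth: sires are born to grandsire x granddam
    # matings so that half/full-sib ties connect the cross-validation folds
    a_gsires = [new() for _ in range(config.n_a_grandsires)]
    a_gdams = [new() for _ in range(config.n_a_granddams)]
    b_sires = [new() for _ in range(config.n_founders_b)]
    c_dams = [new() for _ in range(config.n_founders_c)]
    founder_breed = {**{a: "A" for a in a_gsires + a_gdams},
                     **{b: "B" for b in b_sires},
                     **{c: "C" for c in c_dams}}

    a_sires = [new(sire=int(rng.choice(a_gsires)), dam=int(rng.choice(a_gdams)))
               for _ in range(config.n_sires)]
    f1_dams = [new(sire=int(rng.choice(b_sires)), dam=int(rng.choice(c_dams)))
               for _ in range(config.n_f1_dams)]

    # pens are nested in hatch batches; a sire's offspring mostly share a pen
    pens_per_batch = max(1, config.n_pens // config.n_batches)
    home_pen = {s: int(rng.integers(config.n_pens)) for s in a_sires}
    meta = []
    dam_iter = iter(f1_dams)
    for s in a_sires:
        for _ in range(config.dams_per_sire):
            d = next(dam_iter)
            for _ in range(config.offspring_per_mating):
                o = new(sire=s, dam=d)
                if rng.random() < config.home_pen_prob:
                    pen = home_pen[s]
                else:
                    pen = int(rng.integers(config.n_pens))
                batch = pen // pens_per_batch
                sex = int(rng.integers(2))
                meta.append((o, s, d, batch, pen, sex))
    ped = validate_and_sort(rows)
    meta = pd.DataFrame(meta, columns=["animal", "sire", "dam", "batch", "pen", "sex"])
    meta["fixed"] = meta["pen"] * 10 + meta["sex"]
    return ped, founder_breed, meta


def gene_drop(ped: Pedigree, founder_haplos: dict, founder_breed: dict,
              rng: np.random.Generator):
    """Drop founder haplotypes through the pedigree, tracking breed of origin.

    Returns ``(dosages, maternal_origin_fractions)`` where the origin
    fractions (crossbred rows only are meaningful) give, per animal, the
    proportion of the *maternal* gamete originating from each breed.
    """
    n, m = ped.n, next(iter(founder_haplos.values())).shape[2]
    hap = np.zeros((n, 2, m), dtype=np.int8)       # allele values
    org = np.zeros((n, 2, m), dtype=np.int8)       # breed of origin (0/1/2)
    counters = {b: 0 for b in BREEDS}
    breed_code = {b: i for i, b in enumerate(BREEDS)}
    founder_mask = ped.is_founder()
    for i in range(n):
        if founder_mask[i]:
            breed = founder_breed[int(ped.labels[i])]
            hap[i] = founder_haplos[breed][counters[breed]]
            org[i] = breed_code[breed]
            counters[breed] += 1
        else:
            s, d = ped.sire[i], ped.dam[i]
            pick_s = rng.integers(0, 2, size=m)
            pick_d = rng.integers(0, 2, size=m)
            cols = np.arange(m)
            hap[i, 0] = hap[s, pick_s, cols]
            org[i, 0] = org[s, pick_s, cols]
            hap[i, 1] = hap[d, pick_d, cols]
            org[i, 1] = org[d, pick_d, cols]
    dosages = hap.sum(axis=1).astype(np.int8)
    maternal = np.stack([(org[:, 1, :] == b).mean(axis=1) for b in range(3)], axis=1)
    return dosages, maternal


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(ped: Pedigree, dosages: np.ndarray, meta: pd.DataFrame,
                        config: SimulationConfig, rng: np.random.Generator,
                        ancestral_freqs: np.ndarray, A: np.ndarray | None = None):
    """Phenotypes for the crossbreds plus the simulated truth.

    True breeding values are ``u = Z_c beta + a``: SNP effects are normal
    with total variance ``(1 - w_true) var_a`` at base-generation allele
    frequencies, and the residual polygenic part ``a`` follows the pedigree
    (founders N(0, w var_a); descendants parent average plus Mendelian
    sampling).  Records are ``y = fixed(level) + u + c_dam + e``.
    """
    het = 2.0 * np.sum(ancestral_freqs * (1.0 - ancestral_freqs))
    beta = rng.normal(0.0, np.sqrt((1.0 - config.w_true) * config.var_a / het),
                      size=config.n_snps)
    Zc = dosages.astype(float) - 2.0 * ancestral_freqs
    u_snp = Zc @ beta

    sd_a = np.sqrt(config.w_true * config.var_a)
    a = np.zeros(ped.n)
    founder = ped.is_founder()
    from .pedigree import UNKNOWN
    for i in range(ped.n):
        if founder[i]:
            a[i] = rng.normal(0.0, sd_a)
        else:
            s, d = ped.sire[i], ped.dam[i]
            pa = 0.5 * ((a[s] if s != UNKNOWN else 0.0) + (a[d] if d != UNKNOWN else 0.0))
            # no inbreeding in this mating design: Mendelian variance is var/2
            a[i] = pa + rng.normal(0.0, sd_a * np.sqrt(0.5))
    u = u_snp + a

    levels = np.unique(meta["fixed"])
    level_eff = pd.Series(rng.normal(0.0, config.fixed_sd, size=len(levels)), index=levels)
    dams = np.unique(meta["dam"])
    mat_eff = pd.Series(rng.normal(0.0, np.sqrt(config.var_c), size=len(dams)), index=dams)

    idx = ped.index_of(meta["animal"].to_numpy())
    e = rng.normal(0.0, np.sqrt(config.var_e), size=len(meta))
    y = (level_eff.loc[meta["fixed"]].to_numpy()
         + u[idx] + mat_eff.loc[meta["dam"]].to_numpy() + e)
    phen = meta.copy()
    phen.insert(1, "y", y)
    return phen, u, beta, mat_eff


def simulate_population(config: SimulationConfig) -> SimulatedDataset:
    """Run the whole generator: founders, pedigree, gene drop, phenotypes."""
    rng = np.random.default_rng(config.seed)
    anc, freqs, haplos = simulate_founder_breeds(config, rng)
    ped, founder_breed, meta = build_cross_pedigree(config, rng)
    dosages, maternal = gene_drop(ped, haplos, founder_breed, rng)
    phen, u, beta, mat_eff = simulate_phenotypes(ped, dosages, meta, config, rng, anc)

    cross_labels = meta["animal"].to_numpy()
    cross_idx = ped.index_of(cross_labels)
    true_frac = np.column_stack([
        np.full(len(cross_idx), 0.5),                 # paternal gamete is pure A
        0.5 * maternal[cross_idx, 1],
        0.5 * maternal[cross_idx, 2],
    ])
    # paternal half plus maternal B/C shares: rows sum to 1 after adding the
    # maternal-A share (zero by design here)
    true_frac[:, 0] += 0.5 * maternal[cross_idx, 0]
    true = BreedFractionMatrix(true_frac / true_frac.sum(axis=1, keepdims=True),
                               cross_labels, BREEDS, "TRUE")
    noisy = np.clip(true.values + rng.normal(0.0, config.frac_noise_sd, true.values.shape),
                    1e-4, None)
    observed = scale_observed_fractions(noisy, cross_labels, BREEDS)

    return SimulatedDataset(
        config=config,
        ped=ped,
        phenotypes=phen,
        dosages=dosages,
        founder_breed=founder_breed,
        breed_freqs=freqs,
        ancestral_freqs=anc,
        true_bv=u,
        true_snp_effects=beta,
        true_maternal=mat_eff,
        true_fractions=true,
        observed_fractions=observed,
        crossbred_labels=cross_labels,
        sire_labels=np.asarray(sorted({int(s) for s in meta["sire"]})),
    )
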