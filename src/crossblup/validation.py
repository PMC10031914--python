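"""Data edits, cross-validation design and weighted validation statistics.

Sire GEBV are validated against progeny means: offspring phenotypes are
corrected for systematic environmental effects with a sire model, averaged
per sire, and compared with the sire GEBV through a weighted correlation
(accuracy) and a weighted regression slope multiplied by 2 (dispersion;
expectation 1 for unbiased GEBV on the individual scale).  The weights are
the reliabilities of the progeny means, from Cameron's formula

    rel(n, h2) = (n h2 / 4) / (1 + (n - 1) h2 / 4).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .model import _one_hot

GENOTYPING_RATES = (1.0, 0.75, 0.5, 0.25)


# ---------------------------------------------------------------------------
# data edits
# ---------------------------------------------------------------------------

def outlier_filter(df: pd.DataFrame, value_col: str = "y", group_col: str = "group",
                   n_sd: float = 3.5) -> pd.DataFrame:
    """Drop records deviating strictly more than ``n_sd`` group SDs from the
    group mean (single pass; groups of size 1 are kept with a warning)."""
    keep = np.ones(len(df), dtype=bool)
    singles = 0
    for _, idx in df.groupby(group_col, sort=False).indices.items():
        v = df[value_col].to_numpy()[idx]
        if len(v) < 2:
            singles += 1
            continue
        sd = v.std(ddof=1)
        if sd == 0:
            continue
        keep[idx] = np.abs(v - v.mean()) <= n_sd * sd
    if singles:
        warnings.warn(f"{singles} group(s) of size 1 kept unfiltered")
    return df.loc[keep].reset_index(drop=True)


def snp_qc(dosages: np.ndarray, pairs: np.ndarray | None = None, *,
           maf_min: float = 0.005, mendel_max: float = 0.01,
           call_rate_min: float = 0.95) -> np.ndarray:
    """Boolean mask of retained SNPs.

    Drops SNPs with minor allele frequency below ``maf_min`` and SNPs whose
    opposing-homozygote rate across genotyped parent-offspring ``pairs``
    (row indices into ``dosages``) exceeds ``mendel_max``.  A call-rate
    filter applies only when missing values (NaN) are present.
    """
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    keep = np.ones(m, dtype=bool)
    has_missing = np.isnan(dosages).any()
    if has_missing:
        call_rate = 1.0 - np.isnan(dosages).mean(axis=0)
        keep &= call_rate >= call_rate_min
    p = np.nanmean(dosages, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep &= maf >= maf_min
    if pairs is None or len(pairs) == 0:
        warnings.warn("no genotyped parent-offspring pairs; Mendelian filter skipped")
        return keep
    pairs = np.asarray(pairs)
    a = dosages[pairs[:, 0]]
    b = dosages[pairs[:, 1]]
    opposing = ((a == 0) & (b == 2)) | ((a == 2) & (b == 0))
    valid = ~(np.isnan(a) | np.isnan(b))
    with np.errstate(invalid="ignore"):
        rate = opposing.sum(axis=0) / np.maximum(valid.sum(axis=0), 1)
    keep &= rate <= mendel_max
    return keep


# ---------------------------------------------------------------------------
# cross-validation design
# ---------------------------------------------------------------------------

def make_folds(sires, k: int = 5, seed: int | np.random.Generator = 0) -> list[np.ndarray]:
    """Random partition of sires into ``k`` folds with sizes differing by <= 1."""
    sires = np.asarray(list(sires))
    if k > len(sires):
        raise ValueError(f"cannot make {k} folds from {len(sires)} sires")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(sires)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def apply_genotyping_scheme(reference_animals, rate: float, scheme: str,
                            phenotypes=None, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Select the genotyped subset of the reference population.

    ``rate`` must come from the design menu (100/75/50/25%).  ``RND`` draws
    uniformly without replacement; ``TOP`` takes the highest-phenotype
    animals (ties broken by a seeded shuffle).  Returns selected labels.
    """
    if not any(math.isclose(rate, r) for r in GENOTYPING_RATES):
        raise ValueError(f"genotyping rate {rate} not in design menu {GENOTYPING_RATES}")
    animals = np.asarray(list(reference_animals))
    n_sel = math.ceil(rate * len(animals))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if scheme == "RND":
        return np.sort(rng.choice(animals, size=n_sel, replace=False))
    if scheme == "TOP":
        if phenotypes is None:
            raise ValueError("TOP selection requires phenotypes")
        y = np.asarray(phenotypes, dtype=float)
        if len(y) != len(animals):
            raise ValueError("phenotypes must align with reference animals")
        shuffle = rng.permutation(len(animals))
        order = shuffle[np.argsort(-y[shuffle], kind="stable")]
        return np.sort(animals[order[:n_sel]])
    raise ValueError(f"unknown genotyping scheme {scheme!r}")


# ---------------------------------------------------------------------------
# sire progeny means and weighted statistics
# ---------------------------------------------------------------------------

def cameron_reliability(n, h2):
    """Reliability of a sire progeny mean with ``n`` offspring records."""
    n = np.asarray(n, dtype=float)
    if (n < 1).any():
        raise ValueError("offspring count must be >= 1")
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0, 1)")
    out = (0.25 * n * h2) / (1.0 + 0.25 * (n - 1.0) * h2)
    return float(out) if out.ndim == 0 else out


def sire_progeny_means(data: pd.DataFrame, h2: float, sires=None) -> pd.DataFrame:
    """Phenotypes corrected with a sire model, averaged per sire.

    Fits ``y = fixed + sire + e`` with random sires at the variance ratio
    implied by a sire variance of ``h2/4`` of phenotypic variance, subtracts
    the fixed-effect estimates, and averages the corrected records per sire.
    Sires with fewer than 2 offspring records are excluded with a warning.
    Columns: ``sire, n_offspring, progeny_mean, reliability``.
    """
    for c in ("y", "fixed", "sire"):
        if c not in data.columns:
            raise ValueError(f"sire-model table needs column {c!r}")
    y = data["y"].to_numpy(dtype=float)
    levels, codes = np.unique(data["fixed"].to_numpy(), return_inverse=True)
    s_levels, s_codes = np.unique(data["sire"].to_numpy(), return_inverse=True)
    f, S = len(levels), len(s_levels)
    lam = (4.0 - h2) / h2  # var_e / var_sire with var_s = h2/4 of phenotypic
    X = _one_hot(codes, f)
    T = f + S
    LHS = np.zeros((T, T))
    LHS[:f, :f] = X.T @ X
    XZ = np.zeros((f, S))
    np.add.at(XZ.T, s_codes, X)
    LHS[:f, f:] = XZ
    LHS[f:, :f] = XZ.T
    LHS[f:, f:] = np.diag(np.bincount(s_codes, minlength=S).astype(float)) + lam * np.eye(S)
    RHS = np.zeros(T)
    RHS[:f] = X.T @ y
    np.add.at(RHS[f:], s_codes, y)
    theta = cho_solve(cho_factor(LHS), RHS)
    corrected = y - theta[codes]

    tab = pd.DataFrame({"sire": data["sire"].to_numpy(), "corrected": corrected})
    agg = tab.groupby("sire").agg(n_offspring=("corrected", "size"),
                                  progeny_mean=("corrected", "mean")).reset_index()
    if sires is not None:
        agg = agg[agg["sire"].isin(np.asarray(list(sires)))].reset_index(drop=True)
    small = agg["n_offspring"] < 2
    if small.any():
        warnings.warn(f"excluded {int(small.sum())} sire(s) with < 2 offspring records")
        agg = agg[~small].reset_index(drop=True)
    agg["reliability"] = cameron_reliability(agg["n_offspring"].to_numpy(), h2)
    return agg


def _weighted_moments(x, y, w):
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sw = w.sum()
    mx, my = (w * x).sum() / sw, (w * y).sum() / sw
    cxy = (w * (x - mx) * (y - my)).sum() / sw
    vx = (w * (x - mx) ** 2).sum() / sw
    vy = (w * (y - my) ** 2).sum() / sw
    return cxy, vx, vy


def weighted_accuracy(gebv, progeny_mean, weights) -> float:
    """Weighted Pearson correlation (weighted central moments).

    Returns NaN when either weighted variance vanishes.
    """
    if len(np.asarray(gebv)) < 3:
        raise ValueError("need at least 3 sires for a validation correlation")
    cxy, vx, vy = _weighted_moments(gebv, progeny_mean, weights)
    if vx <= 0 or vy <= 0:
        return float("nan")
    return float(cxy / np.sqrt(vx * vy))


def dispersion_slope(gebv, progeny_mean, weights) -> float:
    """Twice the weighted regression slope of progeny mean on GEBV.

    The doubling moves the sire-level expectation to the individual scale,
    so 1 indicates unbiased GEBV dispersion and values below 1 indicate
    inflated GEBV variance.
    """
    if len(np.asarray(gebv)) < 3:
        raise ValueError("need at least 3 sires for a dispersion regression")
    cxy, vx, _ = _weighted_moments(gebv, progeny_mean, weights)
    if vx <= 0:
        return float("nan")
    return float(2.0 * cxy / vx)


def round_half_away(x, ndigits: int = 2):
    """Round half away from zero (report-table convention)."""
    factor = 10.0 ** ndigits
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


def __getattr__(name):
    # the scenario grid lives in .grid to keep this module import-light;
    # expose it here as part of the validation surface
    if name in ("scenario_grid", "summarize_grid", "GridConfig"):
        from . import grid

        return getattr(grid, name)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
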