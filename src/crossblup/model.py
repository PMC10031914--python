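"""Mixed-model equations for pedigree BLUP and single-step SNPBLUP.

The phenotypic model is

    y = X b + Z J mu + Z u + W c + e

with a combined categorical fixed factor ``b`` (cell-means coding), optional
J-factor covariates ``J mu`` modelling the mean of the genotyped group, an
additive genetic effect ``u`` for every pedigree animal, a non-genetic
maternal permanent-environment effect ``c`` per dam, and i.i.d. residuals.
``var(u)`` is ``A * var_a`` for pedigree BLUP or ``H * var_a`` for the
single-step model, where ``H`` combines the pedigree relationship matrix
with the genomic relationship matrix among genotyped animals,

    G = Z_c B Z_c' + w A_gg,      B = I (1 - w) / (2 sum p(1-p)),

``Z_c`` the genotype dosages centred at observed allele frequencies and
``w`` the residual-polygenic proportion of the additive variance.

Genomic breeding values are reported as ``GEBV = J mu_hat + u_hat``.

Two solve routes are provided and are mathematically equivalent: the
H-matrix animal-model MME (:func:`solve_mme`) and an explicit SNP-effect
parameterization (:func:`solve_snp_level`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .jfactor import JCovariateMatrix
from .pedigree import Pedigree, RelationshipSubmatrices, a_matrix, partition

MME_TOL = 1e-8


# ---------------------------------------------------------------------------
# genomic relationship building blocks
# ---------------------------------------------------------------------------

def center_genotypes(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centre a 0/1/2 dosage matrix at observed allele frequencies.

    Returns ``(centred, p)`` with ``p = column mean / 2``.  Monomorphic
    columns (p of 0 or 1) are retained — they centre to zero — with a
    warning.
    """
    dosages = np.asarray(dosages, dtype=float)
    p = dosages.mean(axis=0) / 2.0
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic SNP(s) retained; they contribute zero")
    return dosages - 2.0 * p, p


def build_B(p: np.ndarray, w: float) -> float:
    """Diagonal value of ``B = I (1-w) / (2 sum p(1-p))`` for SNP effects."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must be in [0, 1]")
    het = 2.0 * np.sum(p * (1.0 - p))
    if het == 0.0:
        raise ValueError("all SNPs are monomorphic; genomic variance undefined")
    return (1.0 - w) / het


def build_G(Z_centred: np.ndarray, b_diag: float, w: float, A_gg: np.ndarray) -> np.ndarray:
    """Genomic relationship matrix ``G = Z B Z' + w A_gg`` (symmetric)."""
    G = b_diag * (Z_centred @ Z_centred.T) + w * A_gg
    return 0.5 * (G + G.T)


def assemble_H(sub: RelationshipSubmatrices, G: np.ndarray, route: str = "blocks") -> np.ndarray:
    """Single-step relationship matrix in (ungenotyped, genotyped) order.

    ``route="blocks"`` uses the explicit conditional-covariance blocks;
    ``route="inverse"`` inverts ``A^{-1} + blockdiag(0, G^{-1} - A_gg^{-1})``.
    The two agree within 1e-6 whenever G is well conditioned (w > 0).
    """
    n = sub.A_nn.shape[0]
    if route == "blocks":
        P = np.linalg.solve(sub.A_gg, sub.A_ng.T).T  # A_ng A_gg^{-1}
        H_ng = P @ G
        H_nn = sub.A_nn - P @ sub.A_ng.T + H_ng @ P.T
        H = np.block([[H_nn, H_ng], [H_ng.T, G]])
    elif route == "inverse":
        A = sub.assemble()
        Hinv = np.linalg.inv(A)
        try:
            G_inv = cho_solve(cho_factor(G), np.eye(G.shape[0]))
        except np.linalg.LinAlgError:
            raise ValueError("G is singular; use a residual polygenic proportion w > 0") from None
        Hinv[n:, n:] += G_inv - np.linalg.inv(sub.A_gg)
        H = np.linalg.inv(Hinv)
    else:
        raise ValueError(f"unknown route {route!r}")
    return 0.5 * (H + H.T)


def h_inverse(ped: Pedigree, sub: RelationshipSubmatrices, G: np.ndarray,
              A_inv: np.ndarray | None = None, A: np.ndarray | None = None) -> np.ndarray:
    """``H^{-1}`` in pedigree order: ``A^{-1}`` plus the genotyped-block update."""
    if A_inv is None:
        if A is None:
            A = a_matrix(ped)
        A_inv = np.linalg.inv(A)
    K = A_inv.copy()
    try:
        G_inv = cho_solve(cho_factor(G), np.eye(G.shape[0]))
        Agg_inv = cho_solve(cho_factor(sub.A_gg), np.eye(sub.A_gg.shape[0]))
    except np.linalg.LinAlgError:
        raise ValueError("G (or A_gg) is singular; use w > 0 and distinct genotyped animals") from None
    gi = sub.genotyped_idx
    K[np.ix_(gi, gi)] += G_inv - Agg_inv
    return 0.5 * (K + K.T)


# ---------------------------------------------------------------------------
# model specification and solutions
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Inputs of one mixed-model evaluation.

    ``y``, ``fixed_levels``, ``record_animals`` and ``dams`` are per-record
    arrays; ``genotypes`` is ``(labels, dosage_matrix)`` for the genotyped
    animals.  Variance components are in squared trait units.
    """

    y: np.ndarray
    fixed_levels: np.ndarray
    record_animals: np.ndarray
    dams: np.ndarray
    ped: Pedigree
    var_a: float
    var_c: float
    var_e: float
    J: JCovariateMatrix | None = None
    genotypes: tuple | None = None
    w: float = 0.05

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        m = len(self.y)
        if not (len(self.fixed_levels) == len(self.record_animals) == len(self.dams) == m):
            raise ValueError("per-record arrays must have equal length")
        for v, name in ((self.var_a, "var_a"), (self.var_c, "var_c"), (self.var_e, "var_e")):
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must be in [0, 1]")
        self.ped.index_of(self.record_animals)  # phenotyped animals must be in pedigree


@dataclass
class Solutions:
    """Solved effects of one evaluation; ``gebv = J mu_hat + u_hat``."""

    fixed_effects: pd.Series
    j_coefficients: np.ndarray
    j_nonestimable: np.ndarray
    u: np.ndarray
    gebv: np.ndarray
    maternal_pe: pd.Series
    animal_labels: np.ndarray
    snp_effects: np.ndarray | None = None
    mme_relative_residual: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"animal": self.animal_labels, "gebv": self.gebv, "u_hat": self.u})


def _one_hot(codes: np.ndarray, n_levels: int) -> np.ndarray:
    X = np.zeros((len(codes), n_levels))
    X[np.arange(len(codes)), codes] = 1.0
    return X


def _detect_dependent_j_columns(X: np.ndarray, Jrec: np.ndarray,
                                rtol: float = 1e-8) -> np.ndarray:
    """Indices of J columns linearly dependent on [X, preceding J columns].

    Greedy: each J column is regressed on the fixed design plus the J
    columns already kept; a relative residual below ``rtol`` marks it
    confounded.  The fixed design itself is never dropped.
    """
    drop = []
    base = X
    for j in range(Jrec.shape[1]):
        col = Jrec[:, j]
        coef, *_ = np.linalg.lstsq(base, col, rcond=None)
        resid = np.linalg.norm(col - base @ coef)
        if resid <= rtol * max(np.linalg.norm(col), 1.0):
            drop.append(j)
        else:
            base = np.hstack([base, col[:, None]])
    return np.asarray(drop, dtype=int)


class MMEFactor:
    """Factorized MME core, reusable across J-covariate choices.

    The coefficient matrix of the unknowns ``(b, u, c)`` does not depend on
    the J covariates; it is assembled and Cholesky-factorized once, and each
    J-method's solution is obtained by bordering the factorization with the
    few J columns (a k x k Schur complement).  This is what makes a scenario
    grid over {NONE, ONE, EXP, OBS} cheap: one factorization per genotyping
    scenario, four bordered solves.
    """

    def __init__(self, spec: ModelSpec, K_inv: np.ndarray | None = None):
        ped = spec.ped
        if K_inv is None:
            A = a_matrix(ped)
            if spec.genotypes is not None:
                g_labels, dosages = spec.genotypes
                sub = partition(ped, g_labels, A=A)
                order = {int(l): r for r, l in enumerate(np.asarray(g_labels))}
                dos = np.asarray(dosages, dtype=float)[
                    [order[int(l)] for l in sub.genotyped_labels]]
                Zc, p = center_genotypes(dos)
                if spec.w >= 1.0:
                    G = sub.A_gg.copy()
                else:
                    G = build_G(Zc, build_B(p, spec.w), spec.w, sub.A_gg)
                K_inv = h_inverse(ped, sub, G, A=A)
            else:
                K_inv = np.linalg.inv(A)

        self.spec = spec
        self.ped = ped
        N = ped.n
        levels, codes = np.unique(np.asarray(spec.fixed_levels), return_inverse=True)
        f = len(levels)
        X = _one_hot(codes, f)
        rec_idx = ped.index_of(spec.record_animals)
        dam_levels, dam_codes = np.unique(np.asarray(spec.dams), return_inverse=True)
        D = len(dam_levels)
        lam_a = spec.var_e / spec.var_a
        lam_c = spec.var_e / spec.var_c

        T = f + N + D
        LHS = np.zeros((T, T))
        LHS[:f, :f] = X.T @ X
        XZ = np.zeros((f, N))
        np.add.at(XZ.T, rec_idx, X)
        LHS[:f, f:f + N] = XZ
        LHS[f:f + N, :f] = XZ.T
        XW = np.zeros((f, D))
        np.add.at(XW.T, dam_codes, X)
        LHS[:f, f + N:] = XW
        LHS[f + N:, :f] = XW.T
        counts_u = np.bincount(rec_idx, minlength=N).astype(float)
        LHS[f:f + N, f:f + N] = lam_a * K_inv
        LHS[np.arange(f, f + N), np.arange(f, f + N)] += counts_u
        ZW = np.zeros((N, D))
        np.add.at(ZW, (rec_idx, dam_codes), 1.0)
        LHS[f:f + N, f + N:] = ZW
        LHS[f + N:, f:f + N] = ZW.T
        counts_c = np.bincount(dam_codes, minlength=D).astype(float)
        LHS[f + N:, f + N:] = np.diag(counts_c) + lam_c * np.eye(D)

        RHS = np.zeros(T)
        RHS[:f] = X.T @ spec.y
        np.add.at(RHS[f:f + N], rec_idx, spec.y)
        np.add.at(RHS[f + N:], dam_codes, spec.y)

        self._cf = cho_factor(LHS)
        self._LHS = LHS
        self._RHS = RHS
        self._theta0 = cho_solve(self._cf, RHS)
        self._X, self._levels, self._rec_idx = X, levels, rec_idx
        self._dam_levels, self._dam_codes = dam_levels, dam_codes
        self._f, self._N, self._D = f, N, D

    def _border(self, Jrec: np.ndarray) -> np.ndarray:
        f, N, D = self._f, self._N, self._D
        k = Jrec.shape[1]
        B = np.zeros((f + N + D, k))
        B[:f] = self._X.T @ Jrec
        np.add.at(B[f:f + N], self._rec_idx, Jrec)
        np.add.at(B[f + N:], self._dam_codes, Jrec)
        return B

    def solve(self, J: JCovariateMatrix | None = None) -> Solutions:
        """Solve for one J choice (None = no J covariates).

        J columns confounded with the fixed factor (e.g. a single J-factor
        when every phenotyped animal is genotyped) are constrained to zero,
        flagged in ``j_nonestimable`` and warned about; the remaining system
        is solved exactly (relative MME residual <= 1e-8).
        """
        spec = self.spec
        f, N = self._f, self._N
        if J is not None:
            J_all = J.subset(self.ped.labels)  # N x k, pedigree order
            k = J_all.shape[1]
            Jrec = J_all[self._rec_idx]
            drop = _detect_dependent_j_columns(self._X, Jrec)
            if drop.size:
                names = [J.column_names[int(c)] for c in drop]
                warnings.warn(
                    "J covariate column(s) " + ", ".join(names)
                    + " are confounded with the fixed effects; constrained to zero")
            keep_j = np.setdiff1d(np.arange(k), drop)
        else:
            J_all, k = None, 0
            drop = np.array([], dtype=int)
            keep_j = np.array([], dtype=int)

        mu = np.zeros(k)
        if k and keep_j.size:
            Jfit = J_all[self._rec_idx][:, keep_j]
            B = self._border(Jfit)
            S1 = cho_solve(self._cf, B)
            C = Jfit.T @ Jfit - B.T @ S1
            rhs_j = Jfit.T @ spec.y - B.T @ self._theta0
            mu_fit = np.linalg.solve(C, rhs_j)
            theta = self._theta0 - S1 @ mu_fit
            mu[keep_j] = mu_fit
            resid_vec = np.concatenate([
                self._LHS @ theta + B @ mu_fit - self._RHS,
                B.T @ theta + (Jfit.T @ Jfit) @ mu_fit - Jfit.T @ spec.y,
            ])
            denom = np.linalg.norm(np.concatenate([self._RHS, Jfit.T @ spec.y]))
        else:
            theta = self._theta0
            resid_vec = self._LHS @ theta - self._RHS
            denom = np.linalg.norm(self._RHS)
        resid = np.linalg.norm(resid_vec) / max(denom, 1e-300)
        if resid > MME_TOL:
            raise ArithmeticError(
                f"MME solve did not reach tolerance (relative residual {resid:.2e})")

        u_hat = theta[f:f + N]
        gebv = u_hat + (J_all @ mu if J_all is not None else 0.0)
        nonest = np.zeros(k, dtype=bool)
        nonest[drop] = True
        return Solutions(
            fixed_effects=pd.Series(theta[:f], index=self._levels, name="fixed_effect"),
            j_coefficients=mu,
            j_nonestimable=nonest,
            u=u_hat,
            gebv=gebv,
            maternal_pe=pd.Series(theta[f + N:], index=self._dam_levels, name="maternal_pe"),
            animal_labels=self.ped.labels.copy(),
            mme_relative_residual=float(resid),
        )


def solve_mme(spec: ModelSpec, K_inv: np.ndarray | None = None) -> Solutions:
    """Solve Henderson's MME for the model above.

    ``K_inv`` is the inverse relationship matrix of ``u`` in pedigree order
    (``A^{-1}`` for pedigree BLUP, ``H^{-1}`` for single-step); by default it
    is built from ``spec``: the single-step ``H^{-1}`` when genotypes are
    present, otherwise ``A^{-1}``.
    """
    return MMEFactor(spec, K_inv).solve(spec.J)


def solve_snp_level(spec: ModelSpec) -> Solutions:
    """Single-step solve with SNP effects explicit in the unknowns.

    Parameterizes ``u_g = Z_g g + a_g`` and solves for ``(b, mu, u_n, u_g,
    g, c)`` jointly, with the prior covariance of ``(u_n, u_g, g)`` built
    from the conditional decomposition ``u_n = A_ng A_gg^{-1} u_g + eps``.
    Mathematically equivalent to :func:`solve_mme` with the H matrix; used
    as its cross-check.  At ``w = 1`` the SNP block vanishes and the model
    reduces to pedigree BLUP.
    """
    if spec.genotypes is None:
        raise ValueError("solve_snp_level requires genotypes")
    ped = spec.ped
    A = a_matrix(ped)
    g_labels, dosages = spec.genotypes
    sub = partition(ped, g_labels, A=A)
    order = {int(l): r for r, l in enumerate(np.asarray(g_labels))}
    dos = np.asarray(dosages, dtype=float)[[order[int(l)] for l in sub.genotyped_labels]]
    Zc, p = center_genotypes(dos)
    n = len(sub.nongenotyped_idx)
    g = sub.n_genotyped
    msnp = Zc.shape[1] if spec.w < 1.0 else 0

    P = np.linalg.solve(sub.A_gg, sub.A_ng.T).T  # A_ng A_gg^{-1}
    if msnp:
        b_diag = build_B(p, spec.w)
        G = build_G(Zc, b_diag, spec.w, sub.A_gg)
        Bm = b_diag * np.eye(msnp)
        ZB = Zc * b_diag
        Schur = sub.A_nn - P @ sub.A_ng.T
        Sigma = np.block([
            [Schur + P @ G @ P.T, P @ G, P @ ZB],
            [G @ P.T, G, ZB],
            [ZB.T @ P.T, ZB.T, Bm],
        ])
    else:
        Sigma = sub.assemble()
    Sigma = 0.5 * (Sigma + Sigma.T)
    Sigma_inv = np.linalg.inv(Sigma)
    Sigma_inv = 0.5 * (Sigma_inv + Sigma_inv.T)

    # records load on (u_n, u_g); zero incidence on g
    pos_in_block = np.empty(ped.n, dtype=int)
    pos_in_block[sub.nongenotyped_idx] = np.arange(n)
    pos_in_block[sub.genotyped_idx] = n + np.arange(g)

    levels, codes = np.unique(np.asarray(spec.fixed_levels), return_inverse=True)
    f = len(levels)
    X = _one_hot(codes, f)
    m = len(spec.y)
    rec_idx = ped.index_of(spec.record_animals)
    rec_u = pos_in_block[rec_idx]

    if spec.J is not None:
        J_all = spec.J.subset(ped.labels)
        k = J_all.shape[1]
        Jrec = J_all[rec_idx]
        drop = _detect_dependent_j_columns(X, Jrec)
        keep_j = np.setdiff1d(np.arange(k), drop)
        Jfit = Jrec[:, keep_j]
    else:
        J_all, k = None, 0
        keep_j = np.array([], dtype=int)
        drop = np.array([], dtype=int)
        Jfit = np.zeros((m, 0))

    dam_levels, dam_codes = np.unique(np.asarray(spec.dams), return_inverse=True)
    D = len(dam_levels)
    lam_a = spec.var_e / spec.var_a
    lam_c = spec.var_e / spec.var_c

    F = np.hstack([X, Jfit])
    nf = F.shape[1]
    U = n + g + msnp
    T = nf + U + D
    LHS = np.zeros((T, T))
    RHS = np.zeros(T)
    LHS[:nf, :nf] = F.T @ F
    FZ = np.zeros((nf, U))
    np.add.at(FZ.T, rec_u, F)
    LHS[:nf, nf:nf + U] = FZ
    LHS[nf:nf + U, :nf] = FZ.T
    FW = np.zeros((nf, D))
    np.add.at(FW.T, dam_codes, F)
    LHS[:nf, nf + U:] = FW
    LHS[nf + U:, :nf] = FW.T
    counts_u = np.bincount(rec_u, minlength=U).astype(float)
    LHS[nf:nf + U, nf:nf + U] = np.diag(counts_u) + lam_a * Sigma_inv
    ZW = np.zeros((U, D))
    np.add.at(ZW, (rec_u, dam_codes), 1.0)
    LHS[nf:nf + U, nf + U:] = ZW
    LHS[nf + U:, nf:nf + U] = ZW.T
    counts_c = np.bincount(dam_codes, minlength=D).astype(float)
    LHS[nf + U:, nf + U:] = np.diag(counts_c) + lam_c * np.eye(D)
    RHS[:nf] = F.T @ spec.y
    np.add.at(RHS[nf:nf + U], rec_u, spec.y)
    np.add.at(RHS[nf + U:], dam_codes, spec.y)

    try:
        theta = cho_solve(cho_factor(LHS), RHS)
    except np.linalg.LinAlgError:
        theta, *_ = np.linalg.lstsq(LHS, RHS, rcond=None)
    resid = np.linalg.norm(LHS @ theta - RHS) / max(np.linalg.norm(RHS), 1e-300)
    if resid > MME_TOL:
        raise ArithmeticError(f"SNP-level MME residual {resid:.2e} exceeds tolerance")

    mu = np.zeros(k)
    mu[keep_j] = theta[f:nf]
    u_block = theta[nf:nf + n + g]
    snp = theta[nf + n + g:nf + U] if msnp else np.zeros(0)
    u_hat = np.empty(ped.n)
    u_hat[sub.nongenotyped_idx] = u_block[:n]
    u_hat[sub.genotyped_idx] = u_block[n:]
    c_hat = pd.Series(theta[nf + U:], index=dam_levels, name="maternal_pe")
    gebv = u_hat + (J_all @ mu if J_all is not None else 0.0)
    nonest = np.zeros(k, dtype=bool)
    nonest[drop] = True
    return Solutions(
        fixed_effects=pd.Series(theta[:f], index=levels, name="fixed_effect"),
        j_coefficients=mu,
        j_nonestimable=nonest,
        u=u_hat,
        gebv=gebv,
        maternal_pe=c_hat,
        animal_labels=ped.labels.copy(),
        snp_effects=snp,
        mme_relative_residual=float(resid),
    )
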