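"""J-factor covariates: fixed regressions on the genotype-mean of a population.

When SNP genotypes are centred with observed rather than base-generation
allele frequencies, the mean breeding value of the genotyped group is
absorbed into a fixed covariate, the "J-factor".  Genotyped animals carry
the value -1 (single-breed case) or minus their breed-fraction row
(multi-breed case); ungenotyped animals carry the pedigree regression of
those values, ``J_n = -A_ng A_gg^{-1} Q_g``, which lies in [-2, 0] and is 0
for animals unrelated to any genotyped animal.

Two computation routes are provided: the direct dense formula, and an
efficient route that restricts the solve to genotyped animals and their
ancestors and fills in everyone else by parent averaging in pedigree order.
They agree to within 1e-8 by construction of the pedigree recursion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import (
    UNKNOWN,
    Pedigree,
    RelationshipSubmatrices,
    partition,
    solve_against_Agg,
)

TOL = 1e-8


@dataclass(frozen=True)
class JCovariateMatrix:
    """Animals x k covariate matrix (k = 1 for ONE, k = b for EXP/OBS)."""

    values: np.ndarray
    animal_labels: np.ndarray
    method_tag: str  # ONE | EXP | OBS
    genotyped_labels: np.ndarray
    column_names: tuple

    def subset(self, labels) -> np.ndarray:
        pos = {int(a): i for i, a in enumerate(self.animal_labels)}
        return self.values[[pos[int(l)] for l in labels]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.column_names))
        df.insert(0, "animal", self.animal_labels)
        return df


def _check_Qg(Qg: np.ndarray, n_g: int) -> np.ndarray:
    Qg = np.atleast_2d(np.asarray(Qg, dtype=float))
    if Qg.shape[0] != n_g:
        raise ValueError(f"Qg has {Qg.shape[0]} rows for {n_g} genotyped animals")
    if np.abs(Qg.sum(axis=1) - 1.0).max() > TOL:
        raise ValueError("rows of Qg must sum to 1")
    return Qg


def _tag_and_names(Qg: np.ndarray, method_tag, breed_labels):
    k = Qg.shape[1]
    if method_tag is None:
        method_tag = "ONE" if k == 1 else "EXP"
    if breed_labels is None:
        names = ("J",) if k == 1 else tuple(f"J_{chr(65 + j)}" for j in range(k))
    else:
        names = tuple(f"J_{b}" for b in breed_labels)
    return method_tag, names


def compute_J_direct(sub: RelationshipSubmatrices, Qg: np.ndarray | None = None,
                     *, ped: Pedigree | None = None, method_tag: str | None = None,
                     breed_labels=None) -> JCovariateMatrix:
    """J covariates by the dense formula ``J_n = -A_ng A_gg^{-1} Q_g``.

    ``Qg`` defaults to a column of ones (the single-J, "ONE" case); its rows
    follow ``sub.genotyped_labels`` order.  Genotyped rows of the result are
    exactly ``-Qg``.  Row order follows ``ped`` if given (``sub`` must have
    been partitioned from it), else (ungenotyped, genotyped) block order.
    """
    g = sub.n_genotyped
    if Qg is None:
        Qg = np.ones((g, 1))
    Qg = _check_Qg(Qg, g)
    method_tag, names = _tag_and_names(Qg, method_tag, breed_labels)
    J_n = -sub.A_ng @ solve_against_Agg(sub, Qg)
    if ped is not None:
        J = np.zeros((ped.n, Qg.shape[1]))
        J[sub.nongenotyped_idx] = J_n
        J[sub.genotyped_idx] = -Qg
        labels = ped.labels.copy()
    else:
        J = np.vstack([J_n, -Qg])
        labels = np.concatenate([sub.nongenotyped_labels, sub.genotyped_labels])
    return JCovariateMatrix(J, np.asarray(labels), method_tag,
                            np.asarray(sub.genotyped_labels), names)


def compute_J_efficient(ped: Pedigree, genotyped_labels, Qg: np.ndarray | None = None,
                        *, A_full: np.ndarray | None = None,
                        method_tag: str | None = None, breed_labels=None) -> JCovariateMatrix:
    """J covariates via the ancestor-restricted solve plus parent averaging.

    The dense formula is evaluated on the sub-pedigree of genotyped animals
    and their ancestors only; every remaining animal receives the average of
    its parents' covariate rows, processed oldest to youngest, an unknown
    parent contributing a zero row.
    """
    from .pedigree import a_matrix

    g_labels = np.unique(np.asarray(list(genotyped_labels), dtype=np.int64))
    g_idx = ped.index_of(g_labels)
    if Qg is None:
        Qg = np.ones((len(g_idx), 1))
    Qg = _check_Qg(Qg, len(g_idx))
    method_tag, names = _tag_and_names(Qg, method_tag, breed_labels)

    # closure of genotyped animals under "parent of"
    keep = np.zeros(ped.n, dtype=bool)
    keep[g_idx] = True
    for i in range(ped.n - 1, -1, -1):
        if keep[i]:
            for p in (ped.sire[i], ped.dam[i]):
                if p != UNKNOWN:
                    keep[p] = True
    core = np.nonzero(keep)[0]

    old2new = {int(o): i for i, o in enumerate(core)}
    sub_ped_sire = np.array([old2new.get(int(ped.sire[o]), UNKNOWN) if ped.sire[o] != UNKNOWN else UNKNOWN for o in core])
    sub_ped_dam = np.array([old2new.get(int(ped.dam[o]), UNKNOWN) if ped.dam[o] != UNKNOWN else UNKNOWN for o in core])
    # parents of core animals are themselves in core, so the sub-pedigree is closed
    sub_ped = Pedigree(labels=ped.labels[core], sire=sub_ped_sire, dam=sub_ped_dam,
                       _index={int(l): i for i, l in enumerate(ped.labels[core])})
    A_core = a_matrix(sub_ped) if A_full is None else A_full[np.ix_(core, core)]
    sub = partition(sub_ped, g_labels, A=A_core)
    # Qg rows follow the sorted g_labels order; re-align to partition's order
    lab_order = {int(l): r for r, l in enumerate(g_labels)}
    Qg_block = np.vstack([Qg[lab_order[int(l)]] for l in sub.genotyped_labels])

    J = np.zeros((ped.n, Qg.shape[1]))
    J_core_n = -sub.A_ng @ solve_against_Agg(sub, Qg_block)
    J[core[sub.nongenotyped_idx]] = J_core_n
    J[core[sub.genotyped_idx]] = -Qg_block

    done = keep.copy()
    for i in range(ped.n):
        if done[i]:
            continue
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(Qg.shape[1])
        if s != UNKNOWN:
            row += J[s]
        if d != UNKNOWN:
            row += J[d]
        J[i] = 0.5 * row
        done[i] = True
    return JCovariateMatrix(J, ped.labels.copy(), method_tag, g_labels, names)


def rowsum_check(J_multi: JCovariateMatrix, J_one: JCovariateMatrix, tol: float = TOL):
    """Verify the multi-J row-sum identity against the single-J vector.

    Because breed fractions sum to 1 per animal, summing the multi-breed J
    columns must reproduce the single J covariate animal by animal.  Returns
    ``(ok, report)`` where the report names the worst offender.
    """
    if J_multi.values.shape[0] != J_one.values.shape[0]:
        raise ValueError("J matrices cover different numbers of animals")
    if J_one.values.shape[1] != 1:
        raise ValueError("J_one must have a single column")
    diff = np.abs(J_multi.values.sum(axis=1) - J_one.values[:, 0])
    worst = int(np.argmax(diff))
    ok = bool(diff[worst] <= tol)
    report = {
        "ok": ok,
        "max_abs_diff": float(diff[worst]),
        "worst_animal": int(np.asarray(J_multi.animal_labels)[worst]),
        "tol": tol,
    }
    return ok, report


def write_j_tsv(J: JCovariateMatrix, path) -> None:
    J.to_frame().to_csv(path, sep="\t", index=False)
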