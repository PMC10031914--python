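"""Pedigree representation and numerator-relationship-matrix algebra.

The numerator relationship matrix ``A`` holds expected additive genetic
relationships between all animals in a pedigree.  Everything downstream —
J-factor covariates, the single-step ``H`` matrix, pedigree BLUP — is
expressed in terms of ``A`` or its blocks partitioned by genotyped status.

Conventions
-----------
* Unknown parents are coded ``0`` in input tables and ``-1`` internally.
* A single base population is assumed: unknown parents are unrelated,
  non-inbred founders (no genetic groups, no metafounders).
* Inbreeding is accounted for via the recursive tabular method:
  ``a(i,i) = 1 + a(sire_i, dam_i)/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = -1


@dataclass(frozen=True)
class Pedigree:
    """A validated, topologically sorted pedigree.

    Attributes
    ----------
    labels : ndarray of int
        External animal labels in internal (topological) order; parents
        always precede offspring.
    sire, dam : ndarray of int
        Internal parent indices (``UNKNOWN`` = -1 for missing parents).
    """

    labels: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    _index: dict = field(repr=False, default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, labels) -> np.ndarray:
        """Map external labels to internal indices."""
        try:
            return np.asarray([self._index[int(l)] for l in np.atleast_1d(labels)])
        except KeyError as e:
            raise KeyError(f"animal label {e.args[0]} not in pedigree") from None

    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def to_frame(self) -> pd.DataFrame:
        """External-label view: columns ``animal, sire, dam`` (0 = unknown)."""
        sire_lab = np.where(self.sire == UNKNOWN, 0, self.labels[self.sire])
        dam_lab = np.where(self.dam == UNKNOWN, 0, self.labels[self.dam])
        return pd.DataFrame({"animal": self.labels, "sire": sire_lab, "dam": dam_lab})


def validate_and_sort(rows) -> Pedigree:
    """Validate raw pedigree rows and return a topologically sorted Pedigree.

    Parameters
    ----------
    rows : DataFrame or iterable of (animal, sire, dam)
        Integer labels; 0 codes an unknown parent.  Rows may be in any order.

    Raises
    ------
    ValueError
        If an animal appears twice, a parent label is never defined as an
        animal, or the parent graph contains a cycle (e.g. an animal that is
        its own ancestor).
    """
    if isinstance(rows, pd.DataFrame):
        arr = rows[["animal", "sire", "dam"]].to_numpy(dtype=np.int64)
    else:
        arr = np.asarray(list(rows), dtype=np.int64).reshape(-1, 3)
    animals = arr[:, 0]
    uniq, counts = np.unique(animals, return_counts=True)
    if (counts > 1).any():
        raise ValueError(f"duplicate animal labels: {uniq[counts > 1][:10].tolist()}")
    if (animals == 0).any():
        raise ValueError("0 is reserved for unknown parents, not an animal label")
    known = set(animals.tolist())
    parents = arr[:, 1:].ravel()
    dangling = sorted({int(p) for p in parents if p != 0 and int(p) not in known})
    if dangling:
        raise ValueError(f"parents referenced but never defined: {dangling[:10]}")

    # Kahn topological sort over the parent -> offspring DAG.
    pos = {int(a): i for i, a in enumerate(animals)}
    n = len(animals)
    indeg = np.zeros(n, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for p in (arr[i, 1], arr[i, 2]):
            if p != 0:
                children[pos[int(p)]].append(i)
                indeg[i] += 1
    order: list[int] = []
    stack = [i for i in range(n) if indeg[i] == 0]
    while stack:
        i = stack.pop()
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    if len(order) < n:
        on_cycle = int(animals[np.nonzero(indeg > 0)[0][0]])
        raise ValueError(f"pedigree contains a cycle involving animal {on_cycle}")

    labels = animals[order]
    newpos = {int(l): i for i, l in enumerate(labels)}
    sire = np.array([UNKNOWN if arr[i, 1] == 0 else newpos[int(arr[i, 1])] for i in order])
    dam = np.array([UNKNOWN if arr[i, 2] == 0 else newpos[int(arr[i, 2])] for i in order])
    return Pedigree(labels=labels, sire=sire, dam=dam, _index=newpos)


def read_pedigree_csv(path) -> Pedigree:
    """Read a pedigree from CSV with header ``animal,sire,dam`` (0 = unknown)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    return validate_and_sort(df)


def a_matrix(ped: Pedigree) -> np.ndarray:
    """Full numerator relationship matrix by the recursive tabular method.

    ``a(i,j) = (a(j, sire_i) + a(j, dam_i)) / 2`` for ``j`` older than ``i``,
    and ``a(i,i) = 1 + a(sire_i, dam_i)/2`` (inbreeding included).  Unknown
    parents contribute zero relationship.
    """
    n = ped.n
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s != UNKNOWN:
            A[i, :i] = 0.5 * A[s, :i]
            A[i, i] = 1.0
        elif d != UNKNOWN:
            A[i, :i] = 0.5 * A[d, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return A


@dataclass(frozen=True)
class RelationshipSubmatrices:
    """Blocks of A partitioned by genotyped status, with the ordering used.

    ``A_nn`` (ungenotyped x ungenotyped), ``A_ng`` (ungenotyped x genotyped)
    and ``A_gg`` (genotyped x genotyped), where rows/columns follow
    ``nongenotyped_idx`` and ``genotyped_idx`` (internal pedigree indices).
    """

    A_nn: np.ndarray
    A_ng: np.ndarray
    A_gg: np.ndarray
    genotyped_idx: np.ndarray
    nongenotyped_idx: np.ndarray
    genotyped_labels: np.ndarray
    nongenotyped_labels: np.ndarray

    @property
    def n_genotyped(self) -> int:
        return len(self.genotyped_idx)

    def assemble(self) -> np.ndarray:
        """Reassemble the full A in (n, g) block order."""
        return np.block([[self.A_nn, self.A_ng], [self.A_ng.T, self.A_gg]])


def partition(ped: Pedigree, genotyped_labels, A: np.ndarray | None = None) -> RelationshipSubmatrices:
    """Partition A into (ungenotyped, genotyped) blocks.

    Parameters
    ----------
    genotyped_labels : iterable of external animal labels
    A : optional precomputed full relationship matrix (avoids recomputation).
    """
    g_labels = np.unique(np.asarray(list(genotyped_labels), dtype=np.int64))
    if g_labels.size == 0:
        raise ValueError("genotyped set is empty; J-factors are undefined")
    g_idx = ped.index_of(g_labels)
    mask = np.zeros(ped.n, dtype=bool)
    mask[g_idx] = True
    n_idx = np.nonzero(~mask)[0]
    g_idx = np.sort(g_idx)
    if A is None:
        A = a_matrix(ped)
    return RelationshipSubmatrices(
        A_nn=A[np.ix_(n_idx, n_idx)],
        A_ng=A[np.ix_(n_idx, g_idx)],
        A_gg=A[np.ix_(g_idx, g_idx)],
        genotyped_idx=g_idx,
        nongenotyped_idx=n_idx,
        genotyped_labels=ped.labels[g_idx],
        nongenotyped_labels=ped.labels[n_idx],
    )


def solve_against_Agg(sub: RelationshipSubmatrices, M: np.ndarray) -> np.ndarray:
    """Return ``X`` with ``A_gg X = M`` (relative residual <= 1e-10).

    Raises a ValueError naming a candidate duplicated pair if A_gg is
    numerically singular (A_gg is SPD for distinct genotyped individuals).
    """
    from scipy.linalg import cho_factor, cho_solve

    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.shape[0] != sub.A_gg.shape[0]:
        M = M.T
    try:
        c = cho_factor(sub.A_gg)
    except np.linalg.LinAlgError:
        pair = _most_similar_rows(sub.A_gg)
        raise ValueError(
            "A_gg is numerically singular; genotyped animals "
            f"{sub.genotyped_labels[pair[0]]} and {sub.genotyped_labels[pair[1]]} "
            "may be duplicates"
        ) from None
    X = cho_solve(c, M)
    denom = max(np.linalg.norm(M), 1e-300)
    resid = np.linalg.norm(sub.A_gg @ X - M) / denom
    if resid > 1e-10 and np.linalg.norm(M) > 0:
        raise ValueError(f"A_gg solve did not converge (relative residual {resid:.2e})")
    return X


def _most_similar_rows(S: np.ndarray) -> tuple[int, int]:
    n = S.shape[0]
    best, pair = -np.inf, (0, min(1, n - 1))
    for i in range(n):
        for j in range(i + 1, n):
            # duplicated individuals make off-diagonal approach both diagonals
            score = S[i, j] - 0.5 * (S[i, i] + S[j, j])
            if score > best:
                best, pair = score, (i, j)
    return pair
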