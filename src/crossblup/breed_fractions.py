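"""Breed-fraction (Q) matrices for genotyped animals.

Two sources are supported for a three-way cross A x (B x C):

* EXP — pedigree-expected fractions: founders carry a unit indicator for
  their breed and every descendant's row is the average of its parents'
  rows, so an A(BC) crossbred gets (0.5, 0.25, 0.25).
* OBS — observed fractions from a breed-of-origin-of-alleles analysis,
  rescaled so that (1) the sire-breed contribution is exactly 0.5 (exact by
  the mating design), (2) each dam-breed column averages 0.25 across all
  crossbreds, and (3) each animal's two dam contributions sum to 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree


@dataclass(frozen=True)
class BreedFractionMatrix:
    """Per-animal breed proportions (rows sum to 1).

    ``breed_labels`` are ordered with the sire breed first;
    ``source_tag`` is ``"EXP"`` or ``"OBS"``.
    """

    values: np.ndarray
    animal_labels: np.ndarray
    breed_labels: tuple
    source_tag: str

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != len(self.animal_labels):
            raise ValueError("values must be animals x breeds")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("breed fractions must lie in [0, 1]")
        bad = np.abs(v.sum(axis=1) - 1.0) > 1e-8
        if bad.any():
            raise ValueError(
                f"breed-fraction rows must sum to 1; offenders: "
                f"{np.asarray(self.animal_labels)[bad][:5].tolist()}"
            )

    def subset(self, labels) -> np.ndarray:
        """Rows for the given animal labels, in that order."""
        pos = {int(a): i for i, a in enumerate(self.animal_labels)}
        return self.values[[pos[int(l)] for l in labels]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"frac_{b}" for b in self.breed_labels])
        df.insert(0, "animal", self.animal_labels)
        return df


def expected_fractions(ped: Pedigree, founder_breed: dict, breed_labels=("A", "B", "C")) -> BreedFractionMatrix:
    """Pedigree-expected breed fractions for every animal.

    ``founder_breed`` maps each founder's external label to a breed label.
    Founders receive a unit row; every non-founder receives the average of
    its parents' rows (an unknown parent is treated as an error — expected
    fractions require full founder assignment).
    """
    col = {b: j for j, b in enumerate(breed_labels)}
    Q = np.zeros((ped.n, len(breed_labels)))
    founder = ped.is_founder()
    for i in range(ped.n):
        if founder[i]:
            lab = int(ped.labels[i])
            if lab not in founder_breed:
                raise ValueError(f"founder {lab} has no breed assignment")
            Q[i, col[founder_breed[lab]]] = 1.0
        else:
            s, d = ped.sire[i], ped.dam[i]
            if s == UNKNOWN or d == UNKNOWN:
                raise ValueError(
                    f"animal {int(ped.labels[i])} has one unknown parent; "
                    "expected fractions need both parents or founder status"
                )
            Q[i] = 0.5 * (Q[s] + Q[d])
    return BreedFractionMatrix(Q, ped.labels.copy(), tuple(breed_labels), "EXP")


def _mean_correct_dams(V: np.ndarray, breed_labels) -> np.ndarray:
    """Multiply each dam column so its mean over all crossbreds is 0.25."""
    out = V.copy()
    for j in (1, 2):
        m = out[:, j].mean()
        if m <= 0:
            raise ValueError(f"dam-breed column {breed_labels[j]} has zero mean")
        out[:, j] *= 0.25 / m
    return out


def _pair_rescale_dams(V: np.ndarray) -> np.ndarray:
    """Rescale each animal's two dam entries so they sum to 0.5."""
    out = V.copy()
    dam_sum = out[:, 1] + out[:, 2]
    if (dam_sum <= 0).any():
        raise ValueError("an animal has zero total dam-breed contribution")
    out[:, 1:] *= (0.5 / dam_sum)[:, None]
    return out


def _dam_sweep(V: np.ndarray, breed_labels) -> np.ndarray:
    return _pair_rescale_dams(_mean_correct_dams(V, breed_labels))


def scale_observed_fractions(raw, animal_labels=None, breed_labels=("A", "B", "C"),
                             *, tol: float = 1e-12, max_iter: int = 200) -> BreedFractionMatrix:
    """Rescale raw observed crossbred fractions onto the 3-way-cross design.

    The sire-breed column is fixed at 0.5 (exact by the mating design); the
    two dam-breed columns are then balanced by iterative proportional
    scaling, alternating (a) a multiplicative column correction bringing
    each dam-breed mean across all crossbreds to 0.25 and (b) a per-animal
    rescale bringing the two dam contributions to a combined 0.5, until the
    joint fixed point is reached.  The operation is exactly idempotent and
    leaves the pedigree-expected matrix (0.5, 0.25, 0.25) untouched.

    ``max_iter=1`` performs the single (a)-(b) sweep only, whose output
    carries dam-column means slightly off 0.25.

    ``raw`` may be a :class:`BreedFractionMatrix` or a plain array of
    approximate fractions (rows need not sum to exactly 1) with
    ``animal_labels`` supplied alongside.
    """
    if isinstance(raw, BreedFractionMatrix):
        animal_labels = raw.animal_labels
        breed_labels = raw.breed_labels
        raw = raw.values
    elif animal_labels is None:
        raise ValueError("animal_labels required when raw is a plain array")
    V = np.asarray(raw, dtype=float)
    if V.shape[1] != 3:
        raise ValueError("observed-fraction scaling is defined for 3 breeds (sire, damB, damC)")
    if (V < 0).any():
        raise ValueError("negative raw breed fractions")
    out = V.copy()
    out[:, 0] = 0.5
    for _ in range(max_iter):
        new = _dam_sweep(out, breed_labels)
        done = np.abs(new - out).max() < tol
        out = new
        if done:
            break
    return BreedFractionMatrix(out, np.asarray(animal_labels).copy(), tuple(breed_labels), "OBS")


def read_fractions_tsv(path, source_tag="OBS") -> BreedFractionMatrix:
    """Read ``animal, frac_A, frac_B, frac_C`` (TSV)."""
    df = pd.read_csv(path, sep="\t")
    frac_cols = [c for c in df.columns if c.startswith("frac_")]
    return BreedFractionMatrix(
        df[frac_cols].to_numpy(dtype=float),
        df["animal"].to_numpy(dtype=np.int64),
        tuple(c[5:] for c in frac_cols),
        source_tag,
    )
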