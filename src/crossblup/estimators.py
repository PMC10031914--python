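"""Estimator-style front ends to the BLUP solvers.

:class:`PedigreeBLUP`, :class:`SingleStepSNPBLUP` and
:class:`SNPLevelSingleStep` follow the scikit-learn estimator protocol:
variance components and model settings are constructor parameters
(``get_params``/``set_params``/``clone`` all work), data enter through
``fit``, and solved quantities are exposed as trailing-underscore
attributes (``gebv_``, ``u_``, ``fixed_effects_``, ...).

``fit`` takes a per-record phenotype table plus the pedigree (and, for the
single-step models, genotypes and an optional J-covariate matrix) rather
than an ``(n_samples, n_features)`` X/y pair: records are linked to the
relationship structure by animal identifiers, which is the natural sample
axis for these models.  ``predict(animal_labels)`` returns GEBV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .jfactor import JCovariateMatrix
from .model import ModelSpec, Solutions, solve_mme, solve_snp_level
from .pedigree import Pedigree

_COLS = ("animal", "y", "fixed", "dam")


def _spec_from_frame(data: pd.DataFrame, ped: Pedigree, *, var_a, var_c, var_e,
                     J=None, genotypes=None, w=0.05) -> ModelSpec:
    missing = [c for c in _COLS if c not in data.columns]
    if missing:
        raise ValueError(f"phenotype table lacks column(s) {missing}; expected {list(_COLS)}")
    if data["y"].isna().any():
        raise ValueError("phenotype table contains missing trait values")
    return ModelSpec(
        y=data["y"].to_numpy(dtype=float),
        fixed_levels=data["fixed"].to_numpy(),
        record_animals=data["animal"].to_numpy(),
        dams=data["dam"].to_numpy(),
        ped=ped,
        var_a=var_a, var_c=var_c, var_e=var_e,
        J=J, genotypes=genotypes, w=w,
    )


class _BLUPBase(BaseEstimator):
    def _store(self, sol: Solutions) -> None:
        self.solutions_ = sol
        self.fixed_effects_ = sol.fixed_effects
        self.j_coefficients_ = sol.j_coefficients
        self.j_nonestimable_ = sol.j_nonestimable
        self.u_ = sol.u
        self.gebv_ = sol.gebv
        self.maternal_pe_ = sol.maternal_pe
        self.animal_labels_ = sol.animal_labels
        self._gebv_by_label = pd.Series(sol.gebv, index=sol.animal_labels)

    def predict(self, animal_labels) -> np.ndarray:
        """GEBV of the given animals (fitted model required)."""
        if not hasattr(self, "gebv_"):
            raise AttributeError("estimator is not fitted; call fit first")
        return self._gebv_by_label.loc[np.asarray(animal_labels)].to_numpy()


class PedigreeBLUP(_BLUPBase):
    """Pedigree-based animal model (no genomic information).

    Parameters are the additive, maternal permanent-environment and
    residual variances in squared trait units.
    """

    def __init__(self, var_a: float = 69.01, var_c: float = 43.73, var_e: float = 151.07):
        self.var_a = var_a
        self.var_c = var_c
        self.var_e = var_e

    def fit(self, data: pd.DataFrame, ped: Pedigree, A_inv: np.ndarray | None = None):
        spec = _spec_from_frame(data, ped, var_a=self.var_a, var_c=self.var_c,
                                var_e=self.var_e)
        self._store(solve_mme(spec, K_inv=A_inv))
        return self


class SingleStepSNPBLUP(_BLUPBase):
    """Single-step SNPBLUP via the H-matrix mixed-model equations.

    ``w`` is the residual-polygenic proportion of the additive variance
    (default 5%).  ``fit`` accepts an optional :class:`JCovariateMatrix`;
    without one the model is the plain single-step evaluation (NONE).
    """

    def __init__(self, var_a: float = 69.01, var_c: float = 43.73,
                 var_e: float = 151.07, w: float = 0.05):
        self.var_a = var_a
        self.var_c = var_c
        self.var_e = var_e
        self.w = w

    def fit(self, data: pd.DataFrame, ped: Pedigree, genotypes: tuple,
            J: JCovariateMatrix | None = None, H_inv: np.ndarray | None = None):
        spec = _spec_from_frame(data, ped, var_a=self.var_a, var_c=self.var_c,
                                var_e=self.var_e, J=J, genotypes=genotypes, w=self.w)
        self._store(solve_mme(spec, K_inv=H_inv))
        return self


class SNPLevelSingleStep(_BLUPBase):
    """Single-step evaluation with SNP effects explicit in the unknowns.

    Mathematically equivalent to :class:`SingleStepSNPBLUP`; exposes the
    fitted SNP effects as ``snp_effects_``.
    """

    def __init__(self, var_a: float = 69.01, var_c: float = 43.73,
                 var_e: float = 151.07, w: float = 0.05):
        self.var_a = var_a
        self.var_c = var_c
        self.var_e = var_e
        self.w = w

    def fit(self, data: pd.DataFrame, ped: Pedigree, genotypes: tuple,
            J: JCovariateMatrix | None = None):
        spec = _spec_from_frame(data, ped, var_a=self.var_a, var_c=self.var_c,
                                var_e=self.var_e, J=J, genotypes=genotypes, w=self.w)
        sol = solve_snp_level(spec)
        self._store(sol)
        self.snp_effects_ = sol.snp_effects
        return self
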