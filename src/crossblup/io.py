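"""Tabular readers and writers for the pipeline's plain-text formats.

Pedigrees travel as CSV (``animal,sire,dam``, 0 = unknown parent);
genotypes as TSV dosage matrices (animals x SNPs, values 0/1/2) or the
PLINK ``.raw`` dialect; breed fractions and J covariates as TSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def read_dosage_tsv(path):
    """Read an ``animal`` + SNP-columns dosage TSV -> (labels, dosages, snp_names)."""
    df = pd.read_csv(path, sep="\t")
    snp_cols = [c for c in df.columns if c != "animal"]
    return (df["animal"].to_numpy(dtype=np.int64),
            df[snp_cols].to_numpy(dtype=float),
            snp_cols)


def write_dosage_tsv(path, labels, dosages, snp_names=None):
    dosages = np.asarray(dosages)
    if snp_names is None:
        snp_names = [f"snp{j + 1}" for j in range(dosages.shape[1])]
    df = pd.DataFrame(dosages, columns=snp_names)
    df.insert(0, "animal", np.asarray(labels))
    df.to_csv(path, sep="\t", index=False)


def read_plink_raw(path):
    """Read a PLINK ``.raw`` additive-dosage file.

    Expects the standard header ``FID IID PAT MAT SEX PHENOTYPE SNP_A ...``
    (whitespace separated); IID is used as the animal label.
    """
    df = pd.read_csv(path, sep=r"\s+")
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f".raw file lacks header column(s) {missing}")
    snp_cols = [c for c in df.columns if c not in meta_cols]
    return (df["IID"].to_numpy(dtype=np.int64),
            df[snp_cols].to_numpy(dtype=float),
            snp_cols)


def write_solutions_tsv(solutions, path, j_path=None):
    """Write ``animal, gebv, u_hat`` plus, optionally, the J coefficients."""
    solutions.to_frame().to_csv(path, sep="\t", index=False)
    if j_path is not None:
        k = len(solutions.j_coefficients)
        pd.DataFrame({
            "coefficient": [f"mu_{i + 1}" for i in range(k)],
            "estimate": solutions.j_coefficients,
            "estimable": ~solutions.j_nonestimable,
        }).to_csv(j_path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    """Read the per-record phenotype table (columns animal, y, fixed, dam, sire...)."""
    df = pd.read_csv(path, sep="\t")
    need = {"animal", "y", "fixed", "dam"}
    if not need.issubset(df.columns):
        raise ValueError(f"phenotype TSV needs columns {sorted(need)}")
    return df
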