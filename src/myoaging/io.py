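"""Plain-text readers and writers for the pipeline's tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "write_spectra_tsv", "read_spectra_tsv",
    "write_covariates_csv", "read_covariates_csv",
    "write_matrix_tsv", "read_matrix_tsv",
    "write_tpm_tsv", "read_tpm_tsv",
]

_FLAGS = ["decoy", "contaminant", "shared"]


def write_spectra_tsv(spectra: pd.DataFrame, path: str | Path) -> None:
    spectra.to_csv(path, sep="\t", index=False)


def read_spectra_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for f in _FLAGS:
        df[f] = df[f].astype(bool)
    return df


def write_covariates_csv(donors: pd.DataFrame, path: str | Path) -> None:
    donors.to_csv(path)


def read_covariates_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="donor_id")


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values="NA")


def write_tpm_tsv(tpm: pd.DataFrame, path: str | Path) -> None:
    tpm.to_csv(path, sep="\t")


def read_tpm_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
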