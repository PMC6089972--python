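"""Readers and writers for beta matrices, phenotype tables and signature matrices.

Beta matrices are tab- or comma-delimited text with probe IDs in the first
column and sample IDs in the header; the delimiter is sniffed from the header
line. Signature matrices are written tab-delimited with a leading ``NAME``
column — the layout the CIBERSORT web interface accepts for custom bases.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .matrices import BetaMatrix, SignatureMatrix, ValidationError

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_signature",
    "write_signature",
    "read_phenotype",
    "write_phenotype",
]


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_table(path, missing_token: str) -> pd.DataFrame:
    sep = _sniff_delimiter(path)
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=[missing_token],
        keep_default_na=False, dtype=str,
    )
    # str round-trip keeps non-numeric garbage visible as a parse error
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric value in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_beta_matrix(path, missing_token: str = "NA") -> BetaMatrix:
    """Read a probe-by-sample beta matrix (TSV or CSV, auto-detected)."""
    return BetaMatrix(_read_table(path, missing_token))


def write_beta_matrix(betas: BetaMatrix, path, overwrite: bool = False) -> None:
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    betas.data.to_csv(path, sep="\t", index_label="probe", na_rep="NA")


def write_signature(sig: SignatureMatrix, path, overwrite: bool = False) -> None:
    """Write a signature matrix in the CIBERSORT upload layout.

    Tab-delimited; first column header is ``NAME``, remaining columns the
    cell-type labels, one row per probe, values on the 0-100 scale.
    """
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    sig.data.to_csv(path, sep="\t", index_label="NAME")


def read_signature(path) -> SignatureMatrix:
    """Read a signature matrix written by :func:`write_signature`."""
    df = _read_table(path, missing_token="NA")
    return SignatureMatrix(df)


def read_phenotype(path) -> pd.DataFrame:
    """Read a sample-id-indexed phenotype table (TSV/CSV)."""
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample identifier(s): {dup[:5]}")
    return df


def write_phenotype(pheno: pd.DataFrame, path, overwrite: bool = False) -> None:
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    pheno.to_csv(path, sep="\t", index_label="sample")
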