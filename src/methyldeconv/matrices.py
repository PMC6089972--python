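"""Core containers for methylation data.

Beta values are methylation fractions in [0, 1] (per probe and sample);
signature (basis) matrices hold type-wise mean methylation on the 0-100
percent scale, the layout consumed by SVR-based deconvolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BetaMatrix",
    "ReferenceSet",
    "SignatureMatrix",
    "ValidationError",
]


class ValidationError(ValueError):
    """An input matrix violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} identifier(s): {dup[:5]}")


def _check_range(df: pd.DataFrame, lo: float, hi: float, what: str) -> None:
    vals = df.to_numpy(dtype=float)
    bad = (vals < lo) | (vals > hi)  # NaN compares False: missing is allowed
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{what} value {vals[i, j]!r} outside [{lo}, {hi}] at "
            f"probe {df.index[i]!r}, column {df.columns[j]!r}"
        )


@dataclass
class BetaMatrix:
    """Probe-by-sample methylation beta values in [0, 1].

    Missing entries are stored as NaN and flagged via :attr:`has_missing`;
    computations drop probes with missing data rather than imputing.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "probe")
        _check_unique(self.data.columns, "sample")
        _check_range(self.data, 0.0, 1.0, "beta")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def has_missing(self) -> bool:
        return bool(self.data.isna().to_numpy().any())

    def complete_probes(self) -> "BetaMatrix":
        """Drop probes with any missing value; log how many were dropped."""
        complete = self.data.dropna(axis=0)
        n_dropped = self.data.shape[0] - complete.shape[0]
        if n_dropped:
            logger.info("dropped %d probe(s) with missing values", n_dropped)
        return BetaMatrix(complete)


@dataclass
class ReferenceSet:
    """Reference cell-type methylomes: betas plus a cell-type label per sample."""

    betas: BetaMatrix
    cell_type_of: dict[str, str]

    def __post_init__(self) -> None:
        samples = set(self.betas.sample_ids)
        labelled = set(self.cell_type_of)
        if samples != labelled:
            missing = sorted(samples - labelled) or sorted(labelled - samples)
            raise ValidationError(
                f"sample/label mismatch, e.g. {missing[:3]}"
            )
        counts = pd.Series(list(self.cell_type_of.values())).value_counts()
        if len(counts) < 2:
            raise ValidationError("need at least 2 cell types")
        small = counts[counts < 2]
        if not small.empty:
            raise ValidationError(
                f"cell type(s) with <2 samples (variance needs replicates): "
                f"{small.index.tolist()}"
            )

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(self.cell_type_of.values()))

    def samples_of(self, cell_type: str) -> list[str]:
        return [s for s in self.betas.sample_ids if self.cell_type_of[s] == cell_type]


@dataclass
class SignatureMatrix:
    """Probe-by-cell-type basis matrix of mean methylation, percent scale (0-100)."""

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if self.data.shape[0] == 0:
            raise ValidationError("signature matrix has no probes")
        if self.data.shape[1] < 2:
            raise ValidationError("signature matrix needs >= 2 cell types")
        _check_unique(self.data.index, "probe")
        _check_unique(self.data.columns, "cell type")
        if self.data.isna().to_numpy().any():
            raise ValidationError("signature matrix may not contain missing values")
        _check_range(self.data, 0.0, 100.0, "signature")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)
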