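"""Synthetic reference methylomes, mixtures and immunoediting cohorts.

The generator emulates the structure of a sorted-cell reference panel: a
probe-by-sample beta matrix over a handful of cell types (including a
cancer-cell class), with pair-specific differentially methylated probes
planted at a known separation. Bulk mixtures are composition-weighted
averages of the true type means with additive Gaussian noise, so every
downstream module can be tested against stored ground truth.

A probe planted for the pair (A, B) is shifted +delta/2 in A and -delta/2 in
B, leaving all other types at its baseline: the pair itself separates by
delta while every other contrast involving A or B separates by only delta/2,
so each planted probe is informative for exactly one pairwise comparison.
Noise is additive Gaussian on the beta scale with clipping to [0, 1] — a
deliberate simplification of array noise structure (no probe-type or batch
effects), adequate for recovery testing.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .editing import DEFAULT_CONTEXTS
from .matrices import BetaMatrix, ReferenceSet, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CELL_TYPES",
    "SyntheticDesign",
    "SyntheticReference",
    "generate_reference",
    "generate_mixtures",
    "dirichlet_compositions",
    "compositions_with_purity",
    "default_context_rates",
    "generate_editing_cohort",
]

DEFAULT_CELL_TYPES: tuple[str, ...] = (
    "Cancer", "CD8", "CD4eff", "Treg", "B", "NK", "Monocyte", "Neutrophil",
    "Fibroblast",
)


@dataclass
class SyntheticDesign:
    """Parameters of the synthetic reference panel.

    Defaults mirror the scale of a tumour deconvolution panel: nine cell
    types (seven immune lineages, fibroblasts and a cancer class), 5000
    probes with 100 informative probes per type pair at a planted median
    beta separation of 0.4, four reference replicates per type with
    within-type noise sd 0.02 on the beta scale.
    """

    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    n_probes: int = 5000
    n_informative_per_pair: int = 100
    delta: float = 0.4
    noise_sd: float = 0.02
    n_reference_samples: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        n_pairs = len(self.cell_types) * (len(self.cell_types) - 1) // 2
        needed = n_pairs * self.n_informative_per_pair
        if needed > self.n_probes:
            raise ValidationError(
                f"{self.n_probes} probes cannot host {needed} planted probes "
                f"({n_pairs} pairs x {self.n_informative_per_pair})"
            )
        if not 0 <= self.delta <= 1:
            raise ValidationError("delta must be in [0, 1]")


@dataclass
class SyntheticReference:
    """A generated reference plus the ground truth used to build it."""

    reference: ReferenceSet
    true_means: pd.DataFrame  # probe x cell type, beta scale
    planted: dict[tuple[str, str], list[str]]
    design: SyntheticDesign
    n_clipped: int = 0

    @property
    def planted_union(self) -> set[str]:
        return set(itertools.chain.from_iterable(self.planted.values()))


def generate_reference(design: SyntheticDesign) -> SyntheticReference:
    """Draw a reference panel with pair-specific planted probes.

    Baseline probe means are Uniform(0.1, 0.9); planted probes redraw their
    baseline from Uniform(0.2, 0.8) so the +/- delta/2 shift stays inside
    the unit interval without clip distortion of the planted medians.
    """
    rng = np.random.default_rng(design.seed)
    types = list(design.cell_types)
    n_types = len(types)
    probes = [f"cg{i:06d}" for i in range(design.n_probes)]

    baseline = rng.uniform(0.1, 0.9, size=design.n_probes)
    means = np.tile(baseline[:, None], (1, n_types))

    planted: dict[tuple[str, str], list[str]] = {}
    cursor = 0
    for a, b in itertools.combinations(types, 2):
        idx = np.arange(cursor, cursor + design.n_informative_per_pair)
        cursor += design.n_informative_per_pair
        mid = rng.uniform(0.2, 0.8, size=len(idx))
        means[idx, :] = mid[:, None]
        ia, ib = types.index(a), types.index(b)
        means[idx, ia] = mid + design.delta / 2.0
        means[idx, ib] = mid - design.delta / 2.0
        planted[(a, b)] = [probes[i] for i in idx]

    true_means = pd.DataFrame(means, index=probes, columns=types)

    columns = {}
    cell_type_of = {}
    n_clipped = 0
    for ct in types:
        for rep in range(design.n_reference_samples):
            sample_id = f"{ct}_{rep + 1}"
            vals = true_means[ct].to_numpy() + \
                rng.normal(0.0, design.noise_sd, size=design.n_probes)
            clipped = np.clip(vals, 0.0, 1.0)
            n_clipped += int((clipped != vals).sum())
            columns[sample_id] = clipped
            cell_type_of[sample_id] = ct
    if n_clipped:
        logger.info("clipped %d beta value(s) to [0, 1]", n_clipped)

    betas = BetaMatrix(pd.DataFrame(columns, index=probes))
    return SyntheticReference(
        reference=ReferenceSet(betas=betas, cell_type_of=cell_type_of),
        true_means=true_means,
        planted=planted,
        design=design,
        n_clipped=n_clipped,
    )


def generate_mixtures(
    true_means: pd.DataFrame,
    compositions: pd.DataFrame,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Bulk mixtures: composition-weighted type means plus Gaussian noise.

    ``compositions`` is samples x cell types; each row must be a probability
    vector over the columns of ``true_means``. Returns the mixture
    BetaMatrix and the truth table (a copy of ``compositions``).
    """
    comp = compositions[true_means.columns].astype(float)
    sums = comp.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-8) or (comp.to_numpy() < 0).any():
        raise ValidationError("each composition row must be a probability vector")
    rng = np.random.default_rng(seed)
    clean = true_means.to_numpy() @ comp.to_numpy().T
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean
    clipped = np.clip(noisy, 0.0, 1.0)
    n_clipped = int((clipped != noisy).sum())
    if n_clipped:
        logger.info("clipped %d mixture beta value(s) to [0, 1]", n_clipped)
    mixtures = BetaMatrix(
        pd.DataFrame(clipped, index=true_means.index, columns=comp.index)
    )
    return mixtures, comp.copy()


def dirichlet_compositions(
    n_samples: int, cell_types, alpha: float = 1.0, seed: int = 0
) -> pd.DataFrame:
    """Symmetric-Dirichlet composition truths, one row per sample."""
    rng = np.random.default_rng(seed)
    cell_types = list(cell_types)
    comp = rng.dirichlet(np.full(len(cell_types), alpha), size=n_samples)
    return pd.DataFrame(
        comp, columns=cell_types,
        index=[f"mix_{i + 1}" for i in range(n_samples)],
    )


def compositions_with_purity(
    purities,
    cell_types,
    cancer_label: str = "Cancer",
    alpha: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Compositions with a fixed cancer fraction per sample.

    The non-cancer remainder (1 - purity) is split among the other cell
    types by a symmetric Dirichlet draw.
    """
    purities = np.asarray(purities, dtype=float)
    if ((purities < 0) | (purities > 1)).any():
        raise ValidationError("purities must be in [0, 1]")
    cell_types = list(cell_types)
    if cancer_label not in cell_types:
        raise ValidationError(f"{cancer_label!r} not among cell types")
    others = [c for c in cell_types if c != cancer_label]
    rng = np.random.default_rng(seed)
    rest = rng.dirichlet(np.full(len(others), alpha), size=len(purities))
    comp = pd.DataFrame(
        rest * (1.0 - purities)[:, None], columns=others,
        index=[f"mix_{i + 1}" for i in range(len(purities))],
    )
    comp[cancer_label] = purities
    return comp[cell_types]


def default_context_rates() -> pd.DataFrame:
    """Plausible per-context mutation rates for an editing cohort.

    ``silent_mean`` is the Poisson mean of silent mutations per tumour in
    each base-change context (C>T dominant, as in most solid tumours);
    ``c_neo``/``c_nonneo`` are the expected neoantigenic/non-neoantigenic
    nonsilent mutations per silent mutation.
    """
    return pd.DataFrame(
        {
            "silent_mean": [20.0, 10.0, 40.0, 8.0, 12.0, 10.0],
            "c_neo": [0.25, 0.30, 0.20, 0.35, 0.30, 0.25],
            "c_nonneo": [2.2, 2.5, 2.0, 2.6, 2.4, 2.3],
        },
        index=list(DEFAULT_CONTEXTS),
    )


def generate_editing_cohort(
    n_tumours: int,
    context_rates: pd.DataFrame | None = None,
    depletion_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-form counts table for immunoediting tests.

    Per tumour and context: silent ~ Poisson(silent_mean); neoantigenic
    nonsilent ~ Poisson(silent * c_neo * (1 - depletion)); non-neoantigenic
    nonsilent ~ Poisson(silent * c_nonneo).
    """
    if context_rates is None:
        context_rates = default_context_rates()
    if not 0.0 <= depletion_fraction <= 1.0:
        raise ValidationError("depletion_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_tumours):
        tumour = f"T{i + 1:04d}"
        for ctx, rates in context_rates.iterrows():
            silent = rng.poisson(rates["silent_mean"])
            neo = rng.poisson(silent * rates["c_neo"] * (1.0 - depletion_fraction))
            nonneo = rng.poisson(silent * rates["c_nonneo"])
            rows.append(
                {
                    "tumour": tumour,
                    "context": ctx,
                    "silent": int(silent),
                    "nonsilent_neo": int(neo),
                    "nonsilent_nonneo": int(nonneo),
                }
            )
    return pd.DataFrame(rows)
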