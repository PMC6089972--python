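"""Signature (basis) matrix construction from reference cell-type methylomes.

The feature-selection heuristic: for every unordered pair of cell types, fit a
two-group linear model per probe with empirical-Bayes variance moderation
(the limma model), keep probes with |median beta difference| >= 0.25 at
Benjamini-Hochberg FDR <= 0.01, cap each contrast at 100 probes, take the
union, and export type-wise mean methylation scaled to percent (0-100).

Variance moderation follows the scaled-F empirical Bayes model: per-probe
residual variances s_g^2 are assumed to follow s0^2 * F(d_g, d0); the prior
degrees of freedom d0 and prior variance s0^2 are estimated by moment
matching on the log scale, and posterior variances

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

replace s_g^2 in the t statistic, which then has d_g + d0 degrees of freedom.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .matrices import BetaMatrix, ReferenceSet, SignatureMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialResult",
    "FeatureSelection",
    "moderated_pairwise_test",
    "all_pairwise_tests",
    "select_signature_features",
    "build_signature",
    "derive_signature",
]


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration on 1/y."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good start: trigamma(y) ~ 1/y + 1/(2 y^2)
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) / np.maximum(y, 1e-12) < 1e-10):
            break
    return y


def fit_scaled_f_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior to observed variances on the log scale.

    Returns ``(prior_df, prior_s2)``; ``prior_df`` is ``inf`` when the
    observed spread of log variances is no larger than expected from the
    residual degrees of freedom alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return np.nan, np.nan
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        half_d0 = float(_trigamma_inverse(np.array([evar]))[0])
        prior_df = 2.0 * half_d0
        prior_s2 = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    else:
        prior_df = np.inf
        prior_s2 = float(np.exp(emean))
    return prior_df, prior_s2


@dataclass
class DifferentialResult:
    """Per-probe differential methylation between two cell types."""

    contrast: tuple[str, str]
    table: pd.DataFrame  # columns: delta_median_beta, moderated_t, p_value, fdr_q
    prior_df: float
    prior_s2: float
    n_per_group: tuple[int, int]

    def passing(self, delta_threshold: float, fdr_threshold: float) -> pd.DataFrame:
        t = self.table
        return t[(t["delta_median_beta"].abs() >= delta_threshold)
                 & (t["fdr_q"] <= fdr_threshold)]


def moderated_pairwise_test(
    ref: ReferenceSet,
    contrast: tuple[str, str],
    prior_df: float | None = None,
) -> DifferentialResult:
    """Two-group moderated-t test for every probe with complete data.

    Parameters
    ----------
    ref
        Reference methylomes with cell-type labels.
    contrast
        Ordered pair of cell-type labels (A, B); effects are A minus B.
    prior_df
        Override the estimated empirical-Bayes prior degrees of freedom.
        ``0`` gives the classical pooled two-sample t; ``inf`` pools a single
        common variance across all probes (z-like statistic); ``None``
        (default) estimates the prior by moment matching.
    """
    a, b = contrast
    samples_a = ref.samples_of(a)
    samples_b = ref.samples_of(b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError(
            f"contrast {contrast}: both groups need >= 2 samples "
            f"(got {len(samples_a)}, {len(samples_b)})"
        )
    sub = ref.betas.data[samples_a + samples_b].dropna(axis=0)
    if sub.shape[0] == 0:
        raise ValidationError(f"contrast {contrast}: no probes with complete data")

    xa = sub[samples_a].to_numpy()
    xb = sub[samples_b].to_numpy()
    na, nb = xa.shape[1], xb.shape[1]
    df_resid = na + nb - 2

    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    diff = mean_a - mean_b
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + \
         ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if prior_df is None:
        d0, s20 = fit_scaled_f_prior(s2, df_resid)
        if np.isnan(d0):
            logger.warning(
                "contrast %s: empirical-Bayes prior degenerate, "
                "falling back to classical t", contrast,
            )
            d0, s20 = 0.0, 0.0
    else:
        d0 = float(prior_df)
        s20 = float(np.mean(s2)) if d0 > 0 else 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s20)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = df_resid
    else:
        s2_post = (d0 * s20 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0),
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (diff == 0), 1.0, p)

    fdr = multipletests(p, method="fdr_bh")[1]
    delta_median = np.median(xa, axis=1) - np.median(xb, axis=1)

    table = pd.DataFrame(
        {
            "delta_median_beta": delta_median,
            "moderated_t": t,
            "p_value": p,
            "fdr_q": fdr,
        },
        index=sub.index,
    )
    return DifferentialResult(
        contrast=(a, b), table=table, prior_df=float(d0), prior_s2=float(s20),
        n_per_group=(na, nb),
    )


def all_pairwise_tests(
    ref: ReferenceSet, prior_df: float | None = None
) -> list[DifferentialResult]:
    """Moderated tests for every unordered pair of cell types."""
    return [
        moderated_pairwise_test(ref, (a, b), prior_df=prior_df)
        for a, b in itertools.combinations(ref.cell_types, 2)
    ]


@dataclass
class FeatureSelection:
    """Probes selected per contrast plus their deduplicated union."""

    per_contrast: dict[tuple[str, str], list[str]]
    union: list[str]
    provenance: dict[str, list[tuple[str, str]]]
    delta_threshold: float = 0.25
    fdr_threshold: float = 0.01
    cap: int = 100
    params: dict = field(default_factory=dict)


def select_signature_features(
    results: list[DifferentialResult],
    delta_threshold: float = 0.25,
    fdr_threshold: float = 0.01,
    cap: int = 100,
) -> FeatureSelection:
    """Apply the delta/FDR/cap heuristic to each contrast and pool the union.

    Within a contrast, passing probes are ranked by ascending moderated p,
    ties broken by descending |delta median beta|, then lexical probe ID, and
    truncated at ``cap``. A contrast with no passing probes logs a warning;
    an empty union is an error.
    """
    per_contrast: dict[tuple[str, str], list[str]] = {}
    provenance: dict[str, list[tuple[str, str]]] = {}
    for res in results:
        passing = res.passing(delta_threshold, fdr_threshold)
        if passing.empty:
            logger.warning("contrast %s: no probes pass thresholds", res.contrast)
            per_contrast[res.contrast] = []
            continue
        ranked = (
            passing.assign(
                _abs_delta=passing["delta_median_beta"].abs(),
                _probe=passing.index,
            )
            .sort_values(
                by=["p_value", "_abs_delta", "_probe"],
                ascending=[True, False, True],
                kind="mergesort",
            )
        )
        selected = list(ranked.index[:cap])
        per_contrast[res.contrast] = selected
        for probe in selected:
            provenance.setdefault(probe, []).append(res.contrast)

    union = sorted(provenance)
    if not union:
        raise ValidationError(
            "no probes selected in any contrast; thresholds too strict "
            "or reference has no differential signal"
        )
    return FeatureSelection(
        per_contrast=per_contrast,
        union=union,
        provenance=provenance,
        delta_threshold=delta_threshold,
        fdr_threshold=fdr_threshold,
        cap=cap,
    )


def build_signature(ref: ReferenceSet, features: FeatureSelection) -> SignatureMatrix:
    """Type-wise mean methylation for the selected probes, scaled to 0-100.

    Column order is the sorted cell-type labels.
    """
    missing = [p for p in features.union if p not in ref.betas.data.index]
    if missing:
        raise ValidationError(f"feature probe(s) absent from reference: {missing[:5]}")
    sub = ref.betas.data.loc[features.union]
    cols = {}
    for ct in ref.cell_types:
        cols[ct] = sub[ref.samples_of(ct)].mean(axis=1, skipna=True)
    sig = pd.DataFrame(cols)[ref.cell_types] * 100.0
    return SignatureMatrix(sig, provenance={"selection": features})


def derive_signature(
    ref: ReferenceSet,
    delta_threshold: float = 0.25,
    fdr_threshold: float = 0.01,
    cap: int = 100,
    prior_df: float | None = None,
) -> tuple[SignatureMatrix, FeatureSelection, list[DifferentialResult]]:
    """End-to-end: pairwise tests -> feature selection -> basis matrix."""
    results = all_pairwise_tests(ref, prior_df=prior_df)
    features = select_signature_features(
        results, delta_threshold=delta_threshold,
        fdr_threshold=fdr_threshold, cap=cap,
    )
    sig = build_signature(ref, features)
    return sig, features, results
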