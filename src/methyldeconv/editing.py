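"""Immunoediting: observed versus expected neoantigen burden per tumour.

The expected neoantigen count for a tumour is derived from its silent
mutation spectrum: for each of six base-change contexts k, a cohort-level
coefficient c_neo[k] gives the expected number of neoantigenic nonsilent
mutations per silent mutation in that context (c_nonneo[k] analogously for
non-neoantigenic nonsilent mutations). Coefficients are pooled cohort-wide
(ratio of summed counts), and per tumour

    expected_neo    = sum_k s_k * c_neo[k]
    percent_depleted = 100 * (1 - observed / expected)
    edited_count     = max(expected - observed, 0)

Association of editing with immune cluster is tested by a negative-binomial
regression of edited counts on cluster membership.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .matrices import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CONTEXTS",
    "EditingCoefficients",
    "estimate_editing_coefficients",
    "immunoediting_estimate",
    "ImmunoeditingModel",
    "ImmunoeditingResults",
    "editing_cluster_test",
]

DEFAULT_CONTEXTS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COUNT_COLS = ("silent", "nonsilent_neo", "nonsilent_nonneo")


@dataclass
class EditingCoefficients:
    """Per-context expected nonsilent mutations per silent mutation."""

    c_neo: pd.Series
    c_nonneo: pd.Series

    @property
    def contexts(self) -> list[str]:
        return list(self.c_neo.index)


def _check_counts(counts: pd.DataFrame, cols=_COUNT_COLS) -> None:
    for col in ("tumour", "context"):
        if col not in counts.columns:
            raise ValidationError(f"counts table missing column {col!r}")
    for col in cols:
        if col not in counts.columns:
            raise ValidationError(f"counts table missing column {col!r}")
        if (counts[col] < 0).any():
            raise ValidationError(f"negative values in column {col!r}")


def estimate_editing_coefficients(counts: pd.DataFrame) -> EditingCoefficients:
    """Cohort-pooled per-context coefficients from an (assumed unedited) cohort.

    ``counts`` is long-form with columns tumour, context, silent,
    nonsilent_neo, nonsilent_nonneo. Coefficients are ratios of cohort
    totals, so doubling every tumour's counts leaves them unchanged.
    """
    _check_counts(counts)
    totals = counts.groupby("context")[list(_COUNT_COLS)].sum()
    zero = totals.index[totals["silent"] == 0].tolist()
    if zero:
        raise ValidationError(
            f"zero silent mutations cohort-wide in context(s) {zero}"
        )
    return EditingCoefficients(
        c_neo=(totals["nonsilent_neo"] / totals["silent"]).rename("c_neo"),
        c_nonneo=(totals["nonsilent_nonneo"] / totals["silent"]).rename("c_nonneo"),
    )


def immunoediting_estimate(
    silent_by_context: pd.Series,
    observed_neo: float,
    coefficients: EditingCoefficients,
) -> dict:
    """Observed-versus-expected neoantigen estimate for one tumour.

    ``silent_by_context`` maps context label to the tumour's silent count.
    Returns observed, expected, percent_depleted, edited_count and an
    ``undefined`` flag (expected 0 with observed > 0).
    """
    missing = [c for c in silent_by_context.index if c not in coefficients.c_neo.index]
    if missing:
        raise ValidationError(f"no coefficient for context(s) {missing}")
    if (silent_by_context < 0).any() or observed_neo < 0:
        raise ValidationError("counts must be non-negative")
    expected = float(
        (silent_by_context * coefficients.c_neo[silent_by_context.index]).sum()
    )
    if expected == 0:
        undefined = observed_neo > 0
        return {
            "observed_neo": float(observed_neo),
            "expected_neo": 0.0,
            "percent_depleted": np.nan if undefined else 0.0,
            "edited_count": 0.0,
            "undefined": bool(undefined),
        }
    return {
        "observed_neo": float(observed_neo),
        "expected_neo": expected,
        "percent_depleted": 100.0 * (1.0 - observed_neo / expected),
        "edited_count": float(max(expected - observed_neo, 0.0)),
        "undefined": False,
    }


class ImmunoeditingModel:
    """Per-tumour immunoediting estimates from a long-form counts table.

    When no coefficients are supplied, they are estimated from the cohort
    itself (pooled ratios), which centres mean percent-depleted near zero by
    construction; supplying coefficients from an external unedited
    calibration cohort measures depletion against that baseline.
    """

    def __init__(self, counts: pd.DataFrame):
        _check_counts(counts)
        self.counts = counts.copy()

    def fit(self, coefficients: EditingCoefficients | None = None) -> "ImmunoeditingResults":
        if coefficients is None:
            coefficients = estimate_editing_coefficients(self.counts)
        rows = {}
        for tumour, grp in self.counts.groupby("tumour"):
            silent = grp.set_index("context")["silent"]
            observed = float(grp["nonsilent_neo"].sum())
            rows[tumour] = immunoediting_estimate(silent, observed, coefficients)
        table = pd.DataFrame.from_dict(rows, orient="index")
        return ImmunoeditingResults(coefficients=coefficients, per_tumour=table)


@dataclass
class ImmunoeditingResults:
    """Coefficients plus per-tumour observed/expected/depletion table."""

    coefficients: EditingCoefficients
    per_tumour: pd.DataFrame

    def summary(self) -> str:
        t = self.per_tumour
        lines = [
            "Immunoediting estimates",
            "=======================",
            f"tumours              : {len(t)}",
            f"mean observed neo    : {t['observed_neo'].mean():.2f}",
            f"mean expected neo    : {t['expected_neo'].mean():.2f}",
            f"mean percent depleted: {t['percent_depleted'].mean():.2f}",
            f"mean edited count    : {t['edited_count'].mean():.2f}",
            "per-context c_neo    : "
            + ", ".join(f"{k}={v:.3f}" for k, v in self.coefficients.c_neo.items()),
        ]
        return "\n".join(lines)


def editing_cluster_test(
    edited_counts: pd.Series,
    cluster_labels: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Negative-binomial regression of edited counts on immune cluster.

    Returns the rate ratio (hot vs cold, i.e. second class vs first in
    sorted label order), its p-value and confidence interval. Non-integer
    counts are rounded with a warning. Falls back to Poisson regression when
    the negative-binomial dispersion estimate collapses to zero.
    """
    common = edited_counts.index.intersection(cluster_labels.index)
    y = edited_counts.loc[common].astype(float)
    labels = cluster_labels.loc[common]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValidationError(f"need >= 2 clusters, got {classes}")
    if not np.allclose(y, np.round(y)):
        logger.warning("non-integer edited counts rounded for count regression")
    y = np.round(y).astype(int)
    if (y < 0).any():
        raise ValidationError("edited counts must be non-negative")

    X = pd.get_dummies(labels, drop_first=True, dtype=float)
    term = X.columns[0]
    if covariates is not None:
        X = X.join(covariates.loc[common])
    X = sm.add_constant(X, has_constant="add")

    family_used = "negative_binomial"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", False) or \
                    fit.params.get("alpha", 0.0) < 1e-8:
                raise RuntimeError("NB dispersion degenerate")
        except Exception:
            family_used = "poisson"
            fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    coef = float(fit.params[term])
    ci_lo, ci_hi = fit.conf_int().loc[term]
    return {
        "rate_ratio": float(np.exp(coef)),
        "p_value": float(fit.pvalues[term]),
        "conf_int": (float(np.exp(ci_lo)), float(np.exp(ci_hi))),
        "term": term,
        "family": family_used,
        "fit": fit,
    }
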