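"""Agreement metrics between estimated and ground-truth compositions.

Three views of accuracy: correlation per cell type across samples,
correlation per sample across cell types, and elementwise absolute error,
plus residual analysis of purity estimates against a reference method.
Degenerate (zero-variance) correlations are reported as explicit undefined
flags instead of propagating NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .matrices import ValidationError

__all__ = [
    "celltype_correlations",
    "sample_correlations",
    "absolute_error",
    "compare_error_distributions",
    "purity_residuals",
]


def _align(est: pd.DataFrame, truth: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    samples = est.index.intersection(truth.index)
    types = est.columns.intersection(truth.columns)
    if len(samples) == 0 or len(types) == 0:
        raise ValidationError("estimate and truth tables share no samples/cell types")
    return est.loc[samples, types], truth.loc[samples, types]


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, bool]:
    # exact constancy check: np.std of a constant vector can be ~1e-17
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, False
    if method == "pearson":
        return float(stats.pearsonr(x, y)[0]), True
    if method == "spearman":
        return float(stats.spearmanr(x, y)[0]), True
    raise ValueError(f"unknown correlation method {method!r}")


def celltype_correlations(
    est: pd.DataFrame, truth: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """One correlation per cell type, computed across samples.

    Returns a DataFrame indexed by cell type with columns ``correlation``
    and ``defined`` (False where either column is constant).
    """
    est, truth = _align(est, truth)
    if est.shape[0] < 3:
        raise ValidationError(f"need >= 3 samples, got {est.shape[0]}")
    rows = {}
    for ct in est.columns:
        r, ok = _corr(est[ct].to_numpy(), truth[ct].to_numpy(), method)
        rows[ct] = {"correlation": r, "defined": ok}
    return pd.DataFrame.from_dict(rows, orient="index")


def sample_correlations(
    est: pd.DataFrame, truth: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """One correlation per sample, computed across cell types."""
    est, truth = _align(est, truth)
    if est.shape[1] < 2:
        raise ValidationError(f"need >= 2 cell types, got {est.shape[1]}")
    rows = {}
    for s in est.index:
        r, ok = _corr(est.loc[s].to_numpy(), truth.loc[s].to_numpy(), method)
        rows[s] = {"correlation": r, "defined": ok}
    return pd.DataFrame.from_dict(rows, orient="index")


def absolute_error(
    est: pd.DataFrame, truth: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Elementwise |estimate - truth| plus per-type and overall means."""
    est, truth = _align(est, truth)
    errors = (est - truth).abs()
    summary = {
        "per_type_mean": errors.mean(axis=0),
        "per_sample_mean": errors.mean(axis=1),
        "overall_mean": float(errors.to_numpy().mean()),
    }
    return errors, summary


def compare_error_distributions(
    errors_a, errors_b, method: str = "exact"
) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of two methods' absolute errors.

    Returns ``(U statistic, two-sided p)``; ``method`` is passed through to
    the Mann-Whitney U computation (``"exact"``, ``"asymptotic"``, ``"auto"``).
    """
    a = np.asarray(errors_a, dtype=float).ravel()
    b = np.asarray(errors_b, dtype=float).ravel()
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def purity_residuals(
    est_purity: pd.Series,
    reference_purity: pd.Series,
    n_bins: int = 5,
) -> dict:
    """Residuals of purity estimates against a reference method.

    Residual = method estimate - reference estimate per sample. Returns the
    residual series, the Pearson correlation between the two estimates, and a
    summary binned by reference-purity stratum (equal-width bins on [0, 1]).
    """
    samples = est_purity.index.intersection(reference_purity.index)
    if len(samples) == 0:
        raise ValidationError("no overlapping samples between estimates")
    est = est_purity.loc[samples].astype(float)
    ref = reference_purity.loc[samples].astype(float)
    residuals = (est - ref).rename("residual")
    r, ok = _corr(est.to_numpy(), ref.to_numpy(), "pearson")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bins = pd.cut(ref, edges, include_lowest=True)
    binned = residuals.groupby(bins, observed=False).agg(["mean", "std", "count"])
    return {
        "residuals": residuals,
        "correlation": r,
        "correlation_defined": ok,
        "binned": binned,
    }
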