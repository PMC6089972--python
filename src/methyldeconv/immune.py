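"""Downstream immune analyses on deconvolved cell fractions.

Covers consensus clustering of infiltrate profiles into immune-hot and
immune-cold groups, a transferable elastic-net cluster classifier tuned by
Cohen's kappa, cytolytic activity (CYT, the geometric mean of GZMA and PRF1
expression) and its linear model on cell fractions, the CD8:Treg ratio, and
TCR repertoire diversity.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr
from scipy.spatial.distance import squareform, pdist
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import cohen_kappa_score
from sklearn.model_selection import RepeatedStratifiedKFold

from ._pam import pam
from .matrices import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusCluster",
    "ConsensusClusterResults",
    "consensus_cluster",
    "label_clusters_hot_cold",
    "ClusterClassifier",
    "ClusterClassifierResults",
    "fit_cluster_classifier",
    "cytolytic_activity",
    "cyt_linear_model",
    "cd8_treg_ratio",
    "tcr_diversity",
]

DEFAULT_ALPHA_GRID: tuple[float, ...] = (0.1, 0.325, 0.55, 0.775, 1.0)
DEFAULT_LAMBDA_GRID: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)


# ---------------------------------------------------------------------------
# consensus clustering

class ConsensusCluster:
    """Consensus PAM clustering of sample-by-cell-type fraction profiles.

    Repeated PAM runs on random subsamples (Manhattan distance) yield a
    consensus matrix of co-assignment frequencies; the cluster count k is
    chosen to maximise mean within-cluster consensus.
    """

    def __init__(self, fractions: pd.DataFrame):
        self.fractions = fractions.astype(float)

    def fit(
        self,
        k_range=range(2, 7),
        iterations: int = 100,
        subsample_fraction: float = 0.8,
        seed: int = 0,
    ) -> "ConsensusClusterResults":
        n = self.fractions.shape[0]
        k_range = list(k_range)
        if min(k_range) < 2 or max(k_range) > n // 2:
            raise ValidationError(
                f"k_range {k_range} outside [2, n/2] for n={n} samples"
            )
        D = squareform(pdist(self.fractions.to_numpy(), metric="cityblock"))
        rng = np.random.default_rng(seed)
        n_sub = max(2 * max(k_range), int(round(subsample_fraction * n)))

        consensus_by_k: dict[int, np.ndarray] = {}
        labels_by_k: dict[int, np.ndarray] = {}
        robustness: dict[int, float] = {}
        for k in k_range:
            together = np.zeros((n, n))
            sampled = np.zeros((n, n))
            for _ in range(iterations):
                idx = np.sort(rng.choice(n, size=n_sub, replace=False))
                sub_labels, _ = pam(D[np.ix_(idx, idx)], k)
                sampled[np.ix_(idx, idx)] += 1.0
                for c in range(k):
                    members = idx[sub_labels == c]
                    together[np.ix_(members, members)] += 1.0
            with np.errstate(invalid="ignore"):
                consensus = np.where(sampled > 0, together / np.where(sampled > 0, sampled, 1), 0.0)
            np.fill_diagonal(consensus, 1.0)
            consensus = (consensus + consensus.T) / 2.0
            consensus_by_k[k] = consensus

            final_labels, _ = pam(1.0 - consensus, k)
            labels_by_k[k] = final_labels
            robustness[k] = _mean_within_cluster_consensus(consensus, final_labels)

        best_k = max(robustness, key=lambda k: (robustness[k], -k))
        return ConsensusClusterResults(
            model=self,
            k=best_k,
            labels=pd.Series(labels_by_k[best_k], index=self.fractions.index,
                             name="cluster"),
            consensus_matrix=pd.DataFrame(
                consensus_by_k[best_k],
                index=self.fractions.index, columns=self.fractions.index,
            ),
            robustness=robustness,
            labels_by_k={k: pd.Series(v, index=self.fractions.index)
                         for k, v in labels_by_k.items()},
            seed=seed,
            iterations=iterations,
            subsample_fraction=subsample_fraction,
        )


def _mean_within_cluster_consensus(consensus: np.ndarray, labels: np.ndarray) -> float:
    vals = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if len(members) < 2:
            continue
        block = consensus[np.ix_(members, members)]
        iu = np.triu_indices(len(members), k=1)
        vals.append(block[iu])
    if not vals:
        return 0.0
    return float(np.concatenate(vals).mean())


@dataclass
class ConsensusClusterResults:
    """Chosen k, labels, consensus matrix and per-k robustness."""

    model: ConsensusCluster
    k: int
    labels: pd.Series
    consensus_matrix: pd.DataFrame
    robustness: dict[int, float]
    labels_by_k: dict[int, pd.Series]
    seed: int
    iterations: int
    subsample_fraction: float
    hot_cold: pd.Series | None = None

    def label_hot_cold(self, ctl_label: str, treg_label: str | None = None) -> pd.Series:
        """Name the k=2 clusters: higher mean CTL fraction -> ``hot``.

        Exact CTL ties (possible on degenerate fixtures) break on the higher
        mean Treg fraction, which is logged.
        """
        if self.k != 2:
            raise ValidationError(f"hot/cold labelling requires k=2, got k={self.k}")
        fr = self.model.fractions
        if ctl_label not in fr.columns:
            raise ValidationError(f"CTL column {ctl_label!r} not in fractions")
        means = fr.groupby(self.labels)[ctl_label].mean()
        if means.iloc[0] == means.iloc[1]:
            if treg_label is None or treg_label not in fr.columns:
                raise ValidationError(
                    "CTL means tied and no Treg column given for tie-break"
                )
            logger.warning("CTL means tied; breaking tie on mean %s", treg_label)
            means = fr.groupby(self.labels)[treg_label].mean()
        hot_cluster = means.idxmax()
        named = self.labels.map(lambda c: "hot" if c == hot_cluster else "cold")
        self.hot_cold = named.rename("immune_cluster")
        return self.hot_cold

    def summary(self) -> str:
        lines = [
            "Consensus clustering",
            "====================",
            f"samples     : {len(self.labels)}",
            f"chosen k    : {self.k}",
            "per-k mean within-cluster consensus:",
        ]
        lines += [f"  k={k}: {v:.3f}" for k, v in sorted(self.robustness.items())]
        counts = self.labels.value_counts().sort_index()
        lines.append("cluster sizes: " + ", ".join(f"{c}:{n}" for c, n in counts.items()))
        return "\n".join(lines)


def consensus_cluster(
    fractions: pd.DataFrame,
    k_range=range(2, 7),
    iterations: int = 100,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusClusterResults:
    """Functional wrapper around :class:`ConsensusCluster`."""
    return ConsensusCluster(fractions).fit(
        k_range=k_range, iterations=iterations,
        subsample_fraction=subsample_fraction, seed=seed,
    )


def label_clusters_hot_cold(
    results: ConsensusClusterResults,
    ctl_label: str,
    treg_label: str | None = None,
) -> pd.Series:
    return results.label_hot_cold(ctl_label, treg_label=treg_label)


# ---------------------------------------------------------------------------
# elastic-net cluster classifier

class ClusterClassifier:
    """Elastic-net logistic classifier of immune cluster from cell fractions.

    The penalty mixing alpha (L1 fraction) and strength lambda are tuned by
    mean Cohen's kappa over repeated stratified cross-validation (3 x 5-fold
    by default), then the model is refit on all samples.
    """

    def __init__(self, fractions: pd.DataFrame, labels: pd.Series):
        common = fractions.index.intersection(labels.index)
        self.fractions = fractions.loc[common].astype(float)
        self.labels = labels.loc[common]
        classes = sorted(self.labels.unique())
        if len(classes) != 2:
            raise ValidationError(f"need exactly 2 classes, got {classes}")
        self.classes = classes

    def fit(
        self,
        alpha_grid=DEFAULT_ALPHA_GRID,
        lambda_grid=DEFAULT_LAMBDA_GRID,
        folds: int = 5,
        repeats: int = 3,
        seed: int = 0,
    ) -> "ClusterClassifierResults":
        y = (self.labels == self.classes[1]).to_numpy(dtype=int)
        X = self.fractions.to_numpy()
        counts = np.bincount(y)
        if counts.min() < folds:
            raise ValidationError(
                f"each class needs >= {folds} members for {folds}-fold CV"
            )
        cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                     random_state=seed)
        splits = list(cv.split(X, y))
        records = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for alpha, lam in itertools.product(alpha_grid, lambda_grid):
                kappas = []
                for train, test in splits:
                    clf = _elastic_net_logistic(alpha, lam)
                    clf.fit(X[train], y[train])
                    kappas.append(cohen_kappa_score(y[test], clf.predict(X[test])))
                records.append(
                    {"alpha": alpha, "lambda": lam, "mean_kappa": float(np.mean(kappas))}
                )
        tuning = pd.DataFrame(records)
        # prefer stronger regularisation among kappa ties
        best = tuning.sort_values(
            by=["mean_kappa", "lambda", "alpha"], ascending=[False, False, True],
            kind="mergesort",
        ).iloc[0]
        final = _elastic_net_logistic(best["alpha"], best["lambda"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            final.fit(X, y)
        coefficients = pd.Series(final.coef_.ravel(), index=self.fractions.columns)
        return ClusterClassifierResults(
            model=self,
            estimator=final,
            coefficients=coefficients,
            intercept=float(final.intercept_[0]),
            alpha=float(best["alpha"]),
            lambda_=float(best["lambda"]),
            cv_kappa=float(best["mean_kappa"]),
            tuning=tuning,
            folds=folds,
            repeats=repeats,
            seed=seed,
        )


def _elastic_net_logistic(alpha: float, lam: float) -> LogisticRegression:
    # C is the inverse of the total penalty strength lambda
    return LogisticRegression(
        solver="saga", l1_ratio=float(alpha),
        C=1.0 / float(lam), max_iter=5000, tol=1e-4,
    )


@dataclass
class ClusterClassifierResults:
    """Tuned elastic-net classifier with its cross-validation record."""

    model: ClusterClassifier
    estimator: LogisticRegression
    coefficients: pd.Series
    intercept: float
    alpha: float
    lambda_: float
    cv_kappa: float
    tuning: pd.DataFrame
    folds: int
    repeats: int
    seed: int

    def predict(self, fractions: pd.DataFrame) -> pd.DataFrame:
        """Predicted class labels and probabilities for new samples."""
        missing = [c for c in self.model.fractions.columns if c not in fractions.columns]
        if missing:
            raise ValidationError(f"fractions missing cell-type column(s): {missing}")
        extra = [c for c in fractions.columns if c not in self.model.fractions.columns]
        if extra:
            raise ValidationError(f"unseen cell-type column(s): {extra}")
        X = fractions[self.model.fractions.columns].to_numpy()
        proba = self.estimator.predict_proba(X)[:, 1]
        labels = np.where(proba >= 0.5, self.model.classes[1], self.model.classes[0])
        return pd.DataFrame(
            {"label": labels, f"p_{self.model.classes[1]}": proba},
            index=fractions.index,
        )

    def resubstitution_kappa(self) -> float:
        pred = self.predict(self.model.fractions)["label"]
        return float(cohen_kappa_score(self.model.labels, pred))

    def summary(self) -> str:
        lines = [
            "Cluster classifier (elastic-net logistic)",
            "=========================================",
            f"classes        : {self.model.classes}",
            f"alpha (L1 mix) : {self.alpha}",
            f"lambda         : {self.lambda_}",
            f"CV kappa       : {self.cv_kappa:.3f} "
            f"({self.repeats}x{self.folds}-fold)",
            "coefficients:",
        ]
        lines += [f"  {ct:<15s} {v:+.4f}" for ct, v in self.coefficients.items()]
        lines.append(f"  {'(intercept)':<15s} {self.intercept:+.4f}")
        return "\n".join(lines)


def fit_cluster_classifier(
    fractions: pd.DataFrame,
    labels: pd.Series,
    alpha_grid=DEFAULT_ALPHA_GRID,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    folds: int = 5,
    repeats: int = 3,
    seed: int = 0,
) -> ClusterClassifierResults:
    """Functional wrapper around :class:`ClusterClassifier`."""
    return ClusterClassifier(fractions, labels).fit(
        alpha_grid=alpha_grid, lambda_grid=lambda_grid,
        folds=folds, repeats=repeats, seed=seed,
    )


# ---------------------------------------------------------------------------
# cytolytic activity and simple per-sample statistics

def cytolytic_activity(gzma, prf1):
    """CYT: geometric mean of GZMA and PRF1 expression (vectorised)."""
    g = np.asarray(gzma, dtype=float)
    p = np.asarray(prf1, dtype=float)
    if (g < 0).any() or (p < 0).any():
        raise ValidationError("expression values must be non-negative")
    out = np.sqrt(g * p)
    if np.isscalar(gzma) and np.isscalar(prf1):
        return float(out)
    return out


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return []
    _, _, pivots = qr(X, pivoting=True)
    return sorted(names[j] for j in pivots[rank:])


def cyt_linear_model(
    fractions: pd.DataFrame, cyt: pd.Series, offset: float | None = None
) -> pd.DataFrame:
    """OLS of log2(CYT) on cell-fraction predictors.

    Returns a table of coefficient, standard error, t and p per predictor
    (plus the intercept). ``offset`` is added to CYT before log2 when any
    value is zero; by default it is 0 when all CYT > 0, else 1 (logged).
    Passing the full composition (all columns summing to one) is collinear
    with the intercept and raises an error naming the collinear set.
    """
    common = fractions.index.intersection(cyt.index)
    fr = fractions.loc[common].astype(float)
    c = cyt.loc[common].astype(float)
    if (c < 0).any():
        raise ValidationError("CYT must be non-negative")
    if fr.shape[0] <= fr.shape[1] + 1:
        raise ValidationError(
            f"need n > number of cell types + 1 (n={fr.shape[0]}, "
            f"types={fr.shape[1]})"
        )
    if offset is None:
        offset = 0.0 if (c > 0).all() else 1.0
        if offset:
            logger.info("zero CYT values present; applying +%g offset before log2",
                        offset)
    if ((c + offset) <= 0).any():
        raise ValidationError("CYT + offset must be positive for log2")

    X = sm.add_constant(fr, has_constant="add")
    collinear = _collinear_columns(X.to_numpy(), list(X.columns))
    if collinear:
        raise ValidationError(
            f"collinear predictor set (full compositions are collinear with "
            f"the intercept; drop a column): {collinear}"
        )
    fit = sm.OLS(np.log2(c + offset), X).fit()
    return pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p_value": fit.pvalues,
        }
    )


def cd8_treg_ratio(
    fractions: pd.DataFrame,
    ctl_label: str,
    treg_label: str,
    pseudocount: float = 1e-4,
) -> pd.Series:
    """(CD8 + pseudocount) / (Treg + pseudocount) per sample."""
    for label in (ctl_label, treg_label):
        if label not in fractions.columns:
            raise ValidationError(f"cell type {label!r} not in fractions")
    ratio = (fractions[ctl_label] + pseudocount) / (fractions[treg_label] + pseudocount)
    return ratio.rename("cd8_treg_ratio")


def tcr_diversity(n_clones, n_reads):
    """TCR diversity: number of clones / total reads (vectorised)."""
    clones = np.asarray(n_clones, dtype=float)
    reads = np.asarray(n_reads, dtype=float)
    if (reads <= 0).any():
        raise ValidationError("n_reads must be positive")
    if (clones < 0).any() or (clones > reads).any():
        raise ValidationError("need 0 <= n_clones <= n_reads")
    out = clones / reads
    if np.isscalar(n_clones) and np.isscalar(n_reads):
        return float(out)
    return out
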