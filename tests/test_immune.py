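"""Consensus clustering, cluster classifier, CYT and per-sample statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import methyldeconv as md
from methyldeconv._pam import pam
from methyldeconv.matrices import ValidationError


def blob_fractions(n_per_blob=15, sep=0.25, noise=0.03, seed=0, types=("CD8", "Treg", "B", "Fibroblast")):
    """Two well-separated blobs in fraction space; first blob is CD8-high."""
    rng = np.random.default_rng(seed)
    hot_center = np.array([0.30 + sep, 0.15, 0.20, 0.10])
    cold_center = np.array([0.30 - sep, 0.10, 0.05, 0.30])
    rows, truth = [], []
    for i in range(n_per_blob):
        rows.append(hot_center + rng.normal(0, noise, 4))
        truth.append(1)
    for i in range(n_per_blob):
        rows.append(cold_center + rng.normal(0, noise, 4))
        truth.append(0)
    fr = pd.DataFrame(
        np.clip(rows, 0, 1), columns=list(types),
        index=[f"s{i}" for i in range(2 * n_per_blob)],
    )
    return fr, np.array(truth)


def agreement(labels_a, labels_b) -> float:
    """Best label-matching agreement for 2-cluster labelings."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    direct = (a == b).mean()
    return max(direct, 1 - direct)


class TestPAM:
    def test_matches_exhaustive_medoid_search_small(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            pts = rng.normal(size=(8, 2))
            D = squareform(pdist(pts, metric="cityblock"))
            labels, medoids = pam(D, 2)
            best_cost = min(
                D[:, list(m)].min(axis=1).sum()
                for m in itertools.combinations(range(8), 2)
            )
            assert D[:, medoids].min(axis=1).sum() == pytest.approx(best_cost)

    def test_separated_blobs_recovered(self):
        fr, truth = blob_fractions(seed=4)
        D = squareform(pdist(fr.to_numpy(), metric="cityblock"))
        labels, _ = pam(D, 2)
        assert agreement(labels, truth) == 1.0


class TestConsensusClustering:
    @pytest.fixture(scope="class")
    def blob_results(self):
        fr, truth = blob_fractions(n_per_blob=30, seed=1)
        results = md.consensus_cluster(fr, k_range=range(2, 7), iterations=100,
                                       seed=1)
        return fr, truth, results

    def test_two_blobs_select_k2_with_high_agreement(self, blob_results):
        _, truth, results = blob_results
        assert results.k == 2
        assert agreement(results.labels, truth) >= 0.95

    def test_consensus_matrix_is_valid(self, blob_results):
        _, _, results = blob_results
        C = results.consensus_matrix.to_numpy()
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 1.0)
        assert C.min() >= 0 and C.max() <= 1

    def test_duplicating_samples_leaves_partition_invariant(self):
        fr, truth = blob_fractions(n_per_blob=10, seed=2)
        doubled = pd.concat([fr, fr.set_index(fr.index + "_dup")])
        res = md.consensus_cluster(doubled, k_range=[2], iterations=50, seed=3)
        original = res.labels.loc[fr.index]
        dups = res.labels.loc[fr.index + "_dup"]
        assert np.array_equal(original.to_numpy(), dups.to_numpy())
        assert agreement(original, truth) >= 0.95

    def test_single_blob_less_robust_than_planted_blobs(self):
        rng = np.random.default_rng(5)
        n = 30
        single = pd.DataFrame(
            np.clip(rng.normal(0.25, 0.03, size=(n, 4)), 0, 1),
            columns=["CD8", "Treg", "B", "Fibroblast"],
            index=[f"s{i}" for i in range(n)],
        )
        res_single = md.consensus_cluster(single, k_range=[2], iterations=50, seed=6)
        fr, _ = blob_fractions(n_per_blob=15, seed=6)
        res_blobs = md.consensus_cluster(fr, k_range=[2], iterations=50, seed=6)
        assert res_single.robustness[2] < res_blobs.robustness[2]

    def test_k_range_out_of_bounds_is_error(self):
        fr, _ = blob_fractions(n_per_blob=5, seed=7)
        with pytest.raises(ValidationError, match="k_range"):
            md.consensus_cluster(fr, k_range=range(2, 9))


class TestHotColdLabels:
    def test_high_cd8_blob_is_hot(self):
        fr, truth = blob_fractions(n_per_blob=12, seed=8)
        res = md.consensus_cluster(fr, k_range=[2], iterations=50, seed=8)
        named = res.label_hot_cold("CD8", treg_label="Treg")
        hot_mean = fr.loc[named == "hot", "CD8"].mean()
        cold_mean = fr.loc[named == "cold", "CD8"].mean()
        assert hot_mean > cold_mean

    def test_tie_broken_by_treg_mean(self, caplog):
        # two clusters with identical CD8 means but different Treg means
        fr = pd.DataFrame(
            {
                "CD8": [0.2, 0.2, 0.21, 0.6, 0.6, 0.59],
                "Treg": [0.01, 0.01, 0.01, 0.30, 0.30, 0.30],
            },
            index=[f"s{i}" for i in range(6)],
        )
        fr["CD8"] = 0.3  # force exact CD8 tie
        res = md.consensus_cluster(fr, k_range=[2], iterations=30, seed=9)
        named = res.label_hot_cold("CD8", treg_label="Treg")
        hot_treg = fr.loc[named == "hot", "Treg"].mean()
        cold_treg = fr.loc[named == "cold", "Treg"].mean()
        assert hot_treg > cold_treg

    def test_missing_ctl_label_is_error(self):
        fr, _ = blob_fractions(n_per_blob=10, seed=10)
        res = md.consensus_cluster(fr, k_range=[2], iterations=30, seed=10)
        with pytest.raises(ValidationError):
            res.label_hot_cold("NotACellType")

    def test_k_not_2_is_error(self):
        fr, _ = blob_fractions(n_per_blob=10, seed=11)
        res = md.consensus_cluster(fr, k_range=[3], iterations=30, seed=11)
        with pytest.raises(ValidationError, match="k=2"):
            res.label_hot_cold("CD8")


class TestClusterClassifier:
    @pytest.fixture(scope="class")
    def separable(self):
        fr, truth = blob_fractions(n_per_blob=20, seed=12)
        labels = pd.Series(np.where(truth == 1, "hot", "cold"), index=fr.index)
        return fr, labels

    def test_separable_data_resubstitution_kappa(self, separable):
        fr, labels = separable
        res = md.fit_cluster_classifier(fr, labels, seed=0)
        assert res.resubstitution_kappa() >= 0.9
        assert -1 <= res.cv_kappa <= 1

    def test_shuffled_labels_kappa_near_zero(self, separable):
        fr, labels = separable
        kappas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            shuffled = pd.Series(
                rng.permutation(labels.to_numpy()), index=labels.index
            )
            res = md.fit_cluster_classifier(
                fr, shuffled, alpha_grid=(0.5,), lambda_grid=(0.1, 1.0), seed=seed
            )
            kappas.append(res.cv_kappa)
        assert abs(np.mean(kappas)) <= 0.15

    def test_infinite_penalty_zeroes_coefficients(self, separable):
        fr, labels = separable
        res = md.fit_cluster_classifier(
            fr, labels, alpha_grid=(0.5,), lambda_grid=(1e8,), seed=0
        )
        assert np.allclose(res.coefficients, 0.0, atol=1e-6)
        pred = res.predict(fr)
        assert pred["label"].nunique() == 1  # majority class everywhere

    def test_single_class_is_error(self, separable):
        fr, labels = separable
        constant = pd.Series("hot", index=fr.index)
        with pytest.raises(ValidationError, match="2 classes"):
            md.fit_cluster_classifier(fr, constant)

    def test_predict_on_training_data_consistent(self, separable):
        fr, labels = separable
        res = md.fit_cluster_classifier(fr, labels, seed=0)
        pred = res.predict(fr)
        assert (pred["label"] == labels).mean() >= 0.95

    def test_all_zero_row_gets_intercept_class(self, separable):
        fr, labels = separable
        res = md.fit_cluster_classifier(fr, labels, seed=0)
        zero = pd.DataFrame(0.0, index=["z"], columns=fr.columns)
        pred = res.predict(zero)
        expected = res.model.classes[1] if res.intercept >= 0 else res.model.classes[0]
        assert pred.loc["z", "label"] == expected

    def test_unseen_columns_are_error(self, separable):
        fr, labels = separable
        res = md.fit_cluster_classifier(fr, labels, seed=0)
        with pytest.raises(ValidationError, match="unseen|missing"):
            res.predict(fr.rename(columns={"CD8": "weird"}))


class TestCytolyticActivity:
    def test_geometric_mean_examples(self):
        assert md.cytolytic_activity(4, 9) == pytest.approx(6.0)
        assert md.cytolytic_activity(0, 5) == 0.0
        assert md.cytolytic_activity(3.7, 3.7) == pytest.approx(3.7)

    def test_negative_input_is_error(self):
        with pytest.raises(ValidationError):
            md.cytolytic_activity(-1, 4)

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_scale_equivariance(self, c):
        base = md.cytolytic_activity(3.0, 7.0)
        assert md.cytolytic_activity(c * 3.0, c * 7.0) == pytest.approx(c * base)

    def test_vectorised(self):
        out = md.cytolytic_activity([4, 0], [9, 5])
        assert np.allclose(out, [6.0, 0.0])


class TestCytLinearModel:
    def test_noise_free_single_predictor_exact(self):
        rng = np.random.default_rng(13)
        cd8 = pd.Series(rng.uniform(0, 0.5, 50), index=[f"s{i}" for i in range(50)])
        cyt = pd.Series(2.0 ** (1.0 + 0.13 * cd8), index=cd8.index)
        table = md.cyt_linear_model(cd8.to_frame("CD8"), cyt)
        assert table.loc["CD8", "coef"] == pytest.approx(0.13, abs=1e-10)
        assert table.loc["const", "coef"] == pytest.approx(1.0, abs=1e-10)

    def test_full_composition_collinearity_detected(self):
        rng = np.random.default_rng(14)
        fr = pd.DataFrame(
            rng.dirichlet(np.ones(4), size=30),
            columns=["CD8", "Treg", "B", "Fibroblast"],
            index=[f"s{i}" for i in range(30)],
        )
        cyt = pd.Series(rng.uniform(1, 10, 30), index=fr.index)
        with pytest.raises(ValidationError, match="collinear"):
            md.cyt_linear_model(fr, cyt)

    def test_permuted_cyt_pvalues_uniform(self):
        """Coefficient p under the null is Uniform(0,1) (KS alpha=0.01)."""
        rng = np.random.default_rng(15)
        n = 40
        cd8 = pd.Series(rng.uniform(0, 0.5, n), index=[f"s{i}" for i in range(n)])
        pvals = []
        for rep in range(200):
            cyt = pd.Series(2.0 ** rng.normal(2, 0.5, n), index=cd8.index)
            table = md.cyt_linear_model(cd8.to_frame("CD8"), cyt)
            pvals.append(table.loc["CD8", "p_value"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_too_few_samples_is_error(self):
        fr = pd.DataFrame({"CD8": [0.1, 0.2, 0.3]}, index=["a", "b", "c"])
        cyt = pd.Series([1.0, 2.0, 3.0], index=fr.index)
        with pytest.raises(ValidationError, match="n >"):
            md.cyt_linear_model(fr.iloc[:2], cyt.iloc[:2])

    def test_zero_cyt_offset_applied(self, caplog):
        rng = np.random.default_rng(16)
        cd8 = pd.Series(rng.uniform(0, 0.5, 30), index=[f"s{i}" for i in range(30)])
        cyt = pd.Series(rng.uniform(0, 5, 30), index=cd8.index)
        cyt.iloc[0] = 0.0
        table = md.cyt_linear_model(cd8.to_frame("CD8"), cyt)  # offset 1 kicks in
        assert np.isfinite(table["coef"]).all()


class TestRatiosAndDiversity:
    def test_cd8_treg_ratio(self):
        fr = pd.DataFrame({"CD8": [0.2, 0.0], "Treg": [0.1, 0.0]}, index=["a", "b"])
        ratio = md.cd8_treg_ratio(fr, "CD8", "Treg")
        assert ratio["a"] == pytest.approx(0.2001 / 0.1001)
        assert ratio["b"] == pytest.approx(1.0)  # pseudocount symmetry

    def test_ratio_monotone_in_cd8(self):
        cd8 = np.linspace(0, 0.5, 10)
        fr = pd.DataFrame({"CD8": cd8, "Treg": 0.1},
                          index=[f"s{i}" for i in range(10)])
        ratio = md.cd8_treg_ratio(fr, "CD8", "Treg")
        assert (np.diff(ratio) > 0).all()

    def test_missing_label_is_error(self):
        fr = pd.DataFrame({"CD8": [0.2]}, index=["a"])
        with pytest.raises(ValidationError):
            md.cd8_treg_ratio(fr, "CD8", "Treg")

    def test_tcr_diversity(self):
        assert md.tcr_diversity(10, 100) == pytest.approx(0.1)
        assert md.tcr_diversity(42, 42) == pytest.approx(1.0)
        with pytest.raises(ValidationError):
            md.tcr_diversity(10, 0)
        with pytest.raises(ValidationError):
            md.tcr_diversity(101, 100)
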