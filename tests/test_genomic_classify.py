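import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score, matthews_corrcoef, roc_auc_score

from exemplarscore.data_model import GenotypeDataset
from exemplarscore.errors import ValidationError
from exemplarscore.genomic_classify import (
    coefficient_matrix,
    compare_conditions,
    compute_metrics,
    fit_l2_logistic,
    fold_metric,
    shuffle_split_eval,
    stratified_kfold_eval,
)


def make_genotypes(dosages: np.ndarray) -> GenotypeDataset:
    n, m = dosages.shape
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "chrom": "1", "pos": np.arange(m) + 1, "ref": "A", "alt": "G",
    })
    return GenotypeDataset(
        variants,
        pd.DataFrame(dosages.astype(float),
                     index=pd.Index([f"i{i}" for i in range(n)], name="subject_id"),
                     columns=variants["variant_id"]),
    )


def signal_genotypes(n=120, m=40, n_causal=8, beta=1.5, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    maf = rng.uniform(0.2, 0.5, m)
    dos = rng.binomial(2, maf, size=(n, m)).astype(float)
    tilt = 1 / (1 + np.exp(-(np.log(maf[:n_causal] / (1 - maf[:n_causal]))
                             + beta * (2 * y[:, None] - 1) / 2)))
    dos[:, :n_causal] = rng.binomial(2, tilt)
    labels = pd.Series(y, index=[f"i{i}" for i in range(n)])
    return make_genotypes(dos), labels


class TestLogisticFit:
    def test_null_coefficients_shrink(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2000, 500))
        y = rng.integers(0, 2, 2000)
        coef, _ = fit_l2_logistic(X, y)
        # null coefficients stay an order of magnitude below a real signal's
        assert np.abs(coef).max() < 0.3
        assert np.abs(coef).mean() < 0.08

    def test_duplicated_rows_same_decision_function(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 5))
        y = rng.integers(0, 2, 60)
        c1, b1 = fit_l2_logistic(X, y)
        # doubling every row scales the loss but the L2 prior breaks exact
        # equality; with C rescaled to keep loss/prior balance the optimum matches
        c2, b2 = fit_l2_logistic(np.vstack([X, X]), np.concatenate([y, y]), C=0.5)
        np.testing.assert_allclose(c1, c2, atol=1e-4)
        assert abs(b1 - b2) < 1e-4

    def test_separating_variant_dominates(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * 40)
        X = rng.normal(size=(80, 10))
        X[:, 4] = (2 * y - 1) + rng.normal(scale=0.1, size=80)
        coef, _ = fit_l2_logistic(X, y)
        assert np.abs(coef).argmax() == 4

    def test_missing_entries_rejected(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            fit_l2_logistic(X, np.array([0, 1] * 5))


class TestMetrics:
    def test_perfect_prediction_identity(self):
        m = compute_metrics([1, 0, 1, 0], [0.9, 0.1, 0.8, 0.2])
        assert (m["mcc"], m["auc"], m["kappa"], m["accuracy"]) == (1, 1, 1, 1)

    def test_hand_confusion_matrix_oracle(self):
        # TP=50, TN=45, FP=5, FN=0 -> MCC = 2250/sqrt(55*50*50*45)
        y = [1] * 50 + [0] * 50
        p = [0.9] * 50 + [0.8] * 5 + [0.1] * 45
        m = compute_metrics(y, p)
        assert (m["tp"], m["fp"], m["tn"], m["fn"]) == (50, 5, 45, 0)
        assert m["mcc"] == pytest.approx(2250 / math.sqrt(55 * 50 * 50 * 45))
        assert m["mcc"] == pytest.approx(0.9045, abs=5e-4)

    def test_auc_pair_count_oracle(self):
        m = compute_metrics([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.1])
        assert m["auc"] == pytest.approx(3 / 4)

    def test_against_sklearn_on_random_cases(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(6, 40))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            p = rng.random(n).round(2)  # rounding forces ties
            m = compute_metrics(y, p)
            pred = (p >= 0.5).astype(int)
            assert m["mcc"] == pytest.approx(matthews_corrcoef(y, pred), abs=1e-12)
            assert m["auc"] == pytest.approx(roc_auc_score(y, p), abs=1e-12)
            assert m["kappa"] == pytest.approx(cohen_kappa_score(y, pred), abs=1e-12)

    def test_degenerate_denominators(self):
        m = compute_metrics([1, 1, 0, 0], [0.1, 0.2, 0.3, 0.4])  # nothing predicted 1
        assert m["mcc"] == 0.0
        assert np.isnan(m["ppv"])
        single = compute_metrics([1, 1, 1], [0.9, 0.8, 0.7])
        assert np.isnan(single["auc"])


class TestCrossValidation:
    def test_fold_arithmetic(self):
        geno, labels = signal_genotypes(n=40, m=10, n_causal=0)
        results = stratified_kfold_eval(geno, labels, "ALL", k=10, seed=0)
        assert len(results) == 10
        assert all(len(r.test_ids) == 4 for r in results)
        covered = sorted(sid for r in results for sid in r.test_ids)
        assert covered == sorted(labels.index)

    def test_strong_signal_recovered(self):
        geno, labels = signal_genotypes(n=160, m=40, n_causal=10, beta=2.5, seed=1)
        results = stratified_kfold_eval(geno, labels, "ALL", k=10, seed=0)
        assert np.median(fold_metric(results, "auc")) > 0.85

    def test_no_leakage_between_folds(self):
        geno, labels = signal_genotypes(n=40, m=10)
        for r in stratified_kfold_eval(geno, labels, "ALL", k=5, seed=0):
            assert set(r.train_ids).isdisjoint(r.test_ids)

    def test_missing_dosages_are_handled_by_training_mean(self):
        geno, labels = signal_genotypes(n=60, m=8, n_causal=2, seed=2)
        dos = geno.dosages.copy()
        dos.iloc[::7, 0] = np.nan
        geno2 = make_genotypes(dos.to_numpy())
        results = stratified_kfold_eval(geno2, labels, "ALL", k=5, seed=0)
        assert len(results) == 5

    def test_k_reduced_with_tiny_class(self):
        geno, labels = signal_genotypes(n=16, m=6, n_causal=0)
        results = stratified_kfold_eval(geno, labels, "ALL", k=10, seed=0)
        assert len(results) == 8  # min class count

    def test_determinism_under_seed(self):
        geno, labels = signal_genotypes(n=60, m=12)
        a = stratified_kfold_eval(geno, labels, "ALL", k=5, seed=9)
        b = stratified_kfold_eval(geno, labels, "ALL", k=5, seed=9)
        for ra, rb in zip(a, b):
            assert ra.test_ids == rb.test_ids
            np.testing.assert_array_equal(ra.coefficients, rb.coefficients)

    def test_shuffle_split_protocol(self):
        geno, labels = signal_genotypes(n=80, m=20, n_causal=6, beta=2.5, seed=3)
        one = shuffle_split_eval(geno, labels, "ALL", n_splits=1, test_size=0.2, seed=0)
        assert len(one) == 1
        sweep = {
            ts: np.median(fold_metric(
                shuffle_split_eval(geno, labels, "ALL", n_splits=8,
                                   test_size=ts, seed=0), "auc"))
            for ts in (0.1, 0.2, 0.3)
        }
        assert max(sweep.values()) - min(sweep.values()) < 0.2


class TestCompareConditions:
    def fake_results(self, mccs, condition):
        return [
            type("R", (), {"metrics": dict.fromkeys(
                ("mcc", "accuracy", "auc", "kappa", "sensitivity",
                 "specificity", "ppv", "npv"), v)})()
            for v in mccs
        ]

    def test_identical_distributions_gate_pairwise_off(self):
        folds = [0.1, 0.2, 0.15, 0.12, 0.18]
        res = compare_conditions({
            "ALL": self.fake_results(folds, "ALL"),
            "POOR": self.fake_results(folds, "POOR"),
            "BEST": self.fake_results(folds, "BEST"),
        })
        assert res.omnibus_p > 0.05
        assert res.pairwise == {}
        assert res.corrected_alpha == pytest.approx(0.05 / 3)

    def test_dominant_condition_detected_pairwise(self):
        rng = np.random.default_rng(0)
        low = list(rng.normal(0.1, 0.02, 10))
        high = list(rng.normal(0.7, 0.02, 10))
        res = compare_conditions({
            "ALL": self.fake_results(low, "ALL"),
            "POOR": self.fake_results(low, "POOR"),
            "BEST": self.fake_results(high, "BEST"),
        })
        assert res.omnibus_p < 0.05
        assert res.pairwise[("ALL", "BEST")][1] < 0.017
        assert res.pairwise[("POOR", "BEST")][1] < 0.017

    def test_two_conditions_reduce_to_single_pair(self):
        rng = np.random.default_rng(1)
        res = compare_conditions({
            "A": self.fake_results(list(rng.normal(0.1, 0.05, 8)), "A"),
            "B": self.fake_results(list(rng.normal(0.8, 0.05, 8)), "B"),
        })
        assert len(res.pairwise) == 1

    def test_single_condition_rejected(self):
        with pytest.raises(ValidationError):
            compare_conditions({"A": self.fake_results([0.1, 0.2], "A")})


def test_coefficient_matrix_layout():
    geno, labels = signal_genotypes(n=40, m=6)
    results = stratified_kfold_eval(geno, labels, "ALL", k=4, seed=0)
    cm = coefficient_matrix(results)
    assert cm.shape == (4, 6)
    assert list(cm.columns) == [f"v{j}" for j in range(6)]
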