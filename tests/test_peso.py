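import numpy as np
import pandas as pd
import pytest

from exemplarscore.data_model import ClinicalDataset, DataDictionary, Variable
from exemplarscore.errors import ValidationError
from exemplarscore.peso import (
    PesoConfig,
    cross_site_predict,
    fit_site_model,
    loo_within_site,
    run_peso,
    site_eligible,
)

FAST = PesoConfig(n_trees=20, m_draws=1, seed=0)


def separable_dataset(n_per_site=16, n_sites=2, noise=0.3, seed=0, flip_sites=()):
    """Sites sharing one separable boundary on two continuous features.

    Sites in ``flip_sites`` invert the feature–response relationship, which
    makes their models disagree with everyone else.
    """
    rng = np.random.default_rng(seed)
    dictionary = DataDictionary([
        Variable("f1", "continuous", None),
        Variable("f2", "continuous", None),
    ])
    frames = []
    for s in range(n_sites):
        y = np.array([0, 1] * (n_per_site // 2))
        direction = -1.0 if f"s{s + 1}" in flip_sites else 1.0
        base = direction * (2 * y - 1)[:, None] * 1.5
        features = base + rng.normal(scale=noise, size=(n_per_site, 2))
        frames.append(pd.DataFrame({
            "site": f"s{s + 1}",
            "alda_total": np.where(y == 1, 8.0, 2.0),
            "response": y,
            "f1": features[:, 0],
            "f2": features[:, 1],
        }, index=pd.Index([f"s{s + 1}x{i:02d}" for i in range(n_per_site)],
                          name="subject_id")))
    return ClinicalDataset(pd.concat(frames), dictionary)


class TestFitSiteModel:
    def test_separable_classes_learned(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2, 1, (100, 2)), rng.normal(2, 1, (100, 2))])
        y = np.array([0] * 100 + [1] * 100)
        model = fit_site_model(X, y, n_trees=50, seed=1)
        assert (model.predict(X) == y).mean() > 0.95

    def test_constant_features_predict_prior(self):
        X = np.ones((60, 3))
        y = np.array([0] * 45 + [1] * 15)
        model = fit_site_model(X, y, n_trees=50, seed=1)
        prob = model.predict_proba(X[:1])[0, 1]
        assert abs(prob - 0.25) < 0.15

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            fit_site_model(np.ones((5, 2)), np.zeros(5))

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(3)
        X, y = rng.normal(size=(50, 4)), rng.integers(0, 2, 50)
        p1 = fit_site_model(X, y, seed=7).predict_proba(X)
        p2 = fit_site_model(X, y, seed=7).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)


class TestLooWithinSite:
    def test_separable_site_held_out_on_correct_side(self):
        data = separable_dataset(n_per_site=20, n_sites=1)
        probs = loo_within_site(data, "s1", FAST)
        y = data.response.loc[probs.index]
        assert ((probs > 0.5) == (y == 1)).mean() >= 0.95

    def test_minimal_two_per_class_runs(self):
        data = separable_dataset(n_per_site=4, n_sites=1)
        probs = loo_within_site(data, "s1", FAST)
        assert len(probs) == 4 and probs.between(0, 1).all()

    def test_label_shuffle_destroys_accuracy(self):
        data = separable_dataset(n_per_site=20, n_sites=1, seed=5)
        rng = np.random.default_rng(0)
        shuffled = data.subjects.copy()
        shuffled["response"] = rng.permutation(shuffled["response"].to_numpy())
        data_null = ClinicalDataset(shuffled, data.dictionary)
        probs = loo_within_site(data_null, "s1", FAST)
        acc = ((probs > 0.5) == (data_null.response.loc[probs.index] == 1)).mean()
        assert 0.1 <= acc <= 0.75  # near chance, never near-perfect

    def test_single_class_site_rejected(self):
        data = separable_dataset(n_per_site=6, n_sites=1)
        df = data.subjects.copy()
        df["response"] = 0
        with pytest.raises(ValidationError):
            loo_within_site(ClinicalDataset(df, data.dictionary), "s1", FAST)


class TestCrossSitePredict:
    def test_identical_distributions_transfer(self):
        data = separable_dataset(n_per_site=20, n_sites=2)
        targets = data.subjects.index[data.site == "s2"]
        probs = cross_site_predict(data, "s1", targets, FAST)
        y = data.response.loc[targets]
        assert ((probs > 0.5) == (y == 1)).mean() >= 0.9

    def test_single_target_shape(self):
        data = separable_dataset(n_per_site=8, n_sites=2)
        target = data.subjects.index[data.site == "s2"][:1]
        probs = cross_site_predict(data, "s1", target, FAST)
        assert len(probs) == 1

    def test_own_site_targets_rejected(self):
        data = separable_dataset(n_per_site=8, n_sites=2)
        own = data.subjects.index[data.site == "s1"][:2]
        with pytest.raises(ValidationError):
            cross_site_predict(data, "s1", own, FAST)


class TestRunPeso:
    def test_shared_boundary_matrix_tracks_labels(self):
        data = separable_dataset(n_per_site=14, n_sites=3)
        pm = run_peso(data, FAST)
        assert pm.probabilities.shape == (42, 3)
        close = (pm.probabilities.sub(pm.y, axis=0).abs() < 0.5).to_numpy().mean()
        assert close > 0.9

    def test_no_leakage_recorded(self):
        data = separable_dataset(n_per_site=10, n_sites=2)
        pm = run_peso(data, FAST)
        assert pm.audit.leakage_violations == 0
        assert pm.audit.n_fits > 0

    def test_same_seed_reproduces_matrix(self):
        data = separable_dataset(n_per_site=8, n_sites=2)
        pm1 = run_peso(data, FAST)
        pm2 = run_peso(data, FAST)
        pd.testing.assert_frame_equal(pm1.probabilities, pm2.probabilities)

    def test_site_column_independent_of_other_sites(self):
        # column s depends only on site s's training data and the global seed
        data3 = separable_dataset(n_per_site=8, n_sites=3, seed=2)
        subjects12 = data3.subjects.index[data3.site.isin(["s1", "s2"])]
        pm3 = run_peso(data3, FAST)
        data2 = ClinicalDataset(data3.subjects.loc[subjects12].copy(),
                                data3.dictionary)
        pm2 = run_peso(data2, FAST, subjects=subjects12)
        pd.testing.assert_series_equal(
            pm3.probabilities.loc[subjects12, "s1"], pm2.probabilities["s1"]
        )

    def test_single_class_site_skipped_but_subjects_predicted(self):
        data = separable_dataset(n_per_site=10, n_sites=3)
        df = data.subjects.copy()
        df.loc[df["site"] == "s3", "response"] = 0
        data = ClinicalDataset(df, data.dictionary)
        pm = run_peso(data, FAST)
        assert list(pm.probabilities.columns) == ["s1", "s2"]
        assert pm.audit.skipped_sites == ["s3"]
        assert len(pm.probabilities) == 30  # s3's subjects still scored

    def test_subject_subset_restricts_rows_only(self):
        data = separable_dataset(n_per_site=8, n_sites=2)
        subset = data.subjects.index[::3]
        pm = run_peso(data, FAST, subjects=subset)
        assert list(pm.probabilities.index) == list(subset)
        assert pm.probabilities.shape[1] == 2

    def test_flipped_site_produces_disagreement(self):
        data = separable_dataset(n_per_site=14, n_sites=3, flip_sites=("s3",))
        pm = run_peso(data, FAST)
        agree12 = (pm.probabilities["s1"] - pm.probabilities["s2"]).abs().mean()
        agree13 = (pm.probabilities["s1"] - pm.probabilities["s3"]).abs().mean()
        assert agree13 > agree12 + 0.2

    def test_round_trip_write_read(self, tmp_path):
        data = separable_dataset(n_per_site=6, n_sites=2)
        pm = run_peso(data, FAST)
        pm.write(tmp_path / "pm.tsv")
        from exemplarscore.peso import PredictionMatrix
        again = PredictionMatrix.read(tmp_path / "pm.tsv")
        pd.testing.assert_frame_equal(again.probabilities, pm.probabilities)
        assert (again.y == pm.y).all()


def test_site_eligibility_rule():
    assert site_eligible(pd.Series([0, 0, 1, 1]))
    assert not site_eligible(pd.Series([0, 0, 0, 1]))
    assert not site_eligible(pd.Series([1, 1, 1, 1]))
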