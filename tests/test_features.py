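"""LDA feature analogues: closed-form oracle, normalization, aggregation."""

import numpy as np
import pytest

from pdeeg.decomposition import BAFMatrix
from pdeeg.features import (FeatureSeries, LDAFeatureModel, condition_means,
                            load_means, project_feature, train_lda_feature)
from pdeeg.protocol import load_level


def _toy_model(weights=(1.0,), lo=0.0, hi=10.0, atoms=None):
    atoms = atoms or [f"a{i}" for i in range(len(weights))]
    return LDAFeatureModel(weights=np.array(weights, float), bias=0.0,
                           norm_lo=lo, norm_hi=hi, atom_ids=atoms)


class TestTrainLdaFeature:
    def test_identity_covariance_recovers_mean_difference_direction(self):
        """Closed-form oracle: with (near-)identity pooled covariance and
        means (0,0) vs (1,0), the discriminant direction is (1,0)."""
        rng = np.random.default_rng(0)
        X0 = rng.normal(0.0, 1.0, size=(4000, 2))
        X1 = rng.normal(0.0, 1.0, size=(4000, 2)) + np.array([1.0, 0.0])
        model = train_lda_feature(np.vstack([X0, X1]),
                                  np.r_[np.zeros(4000), np.ones(4000)])
        direction = model.weights / np.linalg.norm(model.weights)
        assert abs(direction[0]) > 0.99
        assert abs(direction[1]) < 0.12

    def test_separable_classes_project_without_overlap(self):
        rng = np.random.default_rng(1)
        X0 = rng.normal(0, 0.1, size=(50, 3))
        X1 = rng.normal(5, 0.1, size=(50, 3))
        m = train_lda_feature(np.vstack([X0, X1]),
                              np.r_[np.zeros(50), np.ones(50)])
        p0, p1 = X0 @ m.weights, X1 @ m.weights
        assert p0.max() < p1.min()

    def test_duplicating_samples_keeps_direction(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 4))
        y = (rng.uniform(size=60) > 0.5).astype(int)
        y[:2] = [0, 1]
        m1 = train_lda_feature(X, y)
        m2 = train_lda_feature(np.vstack([X, X]), np.r_[y, y])
        c = np.dot(m1.weights, m2.weights) / (
            np.linalg.norm(m1.weights) * np.linalg.norm(m2.weights))
        assert abs(c) > 0.999

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_lda_feature(np.zeros((10, 2)), np.zeros(10))


class TestProjectFeature:
    def test_anchor_rows_map_to_0_50_100(self):
        model = _toy_model(weights=(1.0,), lo=2.0, hi=4.0)
        baf = BAFMatrix(values=np.array([[2.0], [3.0], [4.0]]),
                        atom_ids=["a0"])
        series = project_feature(model, baf)
        np.testing.assert_allclose(series.values, [0.0, 50.0, 100.0])

    def test_out_of_range_rows_are_clipped(self):
        model = _toy_model(weights=(1.0,), lo=0.0, hi=1.0)
        baf = BAFMatrix(values=np.array([[-5.0], [5.0]]), atom_ids=["a0"])
        series = project_feature(model, baf)
        np.testing.assert_allclose(series.values, [0.0, 100.0])

    def test_constant_rows_give_constant_series(self):
        model = _toy_model(weights=(1.0, 2.0), lo=0.0, hi=10.0,
                           atoms=["a0", "a1"])
        baf = BAFMatrix(values=np.tile([[1.0, 2.0]], (5, 1)),
                        atom_ids=["a0", "a1"])
        series = project_feature(model, baf)
        assert np.ptp(series.values) == 0.0

    def test_missing_atoms_listed_in_error(self):
        model = _toy_model(weights=(1.0, 1.0), atoms=["a0", "zz"])
        baf = BAFMatrix(values=np.zeros((3, 1)), atom_ids=["a0"])
        with pytest.raises(ValueError, match="zz"):
            project_feature(model, baf)


class TestConditionMeans:
    def test_constant_series_means_equal_constant(self):
        series = FeatureSeries(values=np.full(20, 7.0), feature_name="f")
        labels = ["rest"] * 10 + ["nback1"] * 10
        table = condition_means(series, labels)
        assert (table["mean"] == 7.0).all()

    def test_constructed_rest_mean(self):
        labels = ["rest"] * 5 + ["nback0"] * 5
        series = FeatureSeries(values=np.r_[np.full(5, 10.0),
                                            np.full(5, 90.0)],
                               feature_name="f")
        table = condition_means(series, labels).set_index("condition")
        assert table.loc["rest", "mean"] == 10.0
        assert table.loc["nback0", "mean"] == 90.0

    def test_agrees_with_naive_per_label_loop(self):
        rng = np.random.default_rng(3)
        labels = list(rng.choice(["rest", "nback0", "nback1"], size=50))
        series = FeatureSeries(values=rng.uniform(0, 100, 50),
                               feature_name="f")
        table = condition_means(series, labels).set_index("condition")
        for cond in set(labels):
            manual = np.mean([v for v, c in zip(series.values, labels)
                              if c == cond])
            assert table.loc[cond, "mean"] == pytest.approx(manual)

    def test_load_means_pool_conditions_by_level(self):
        labels = ["rest"] * 4 + ["detection1"] * 2 + ["nback0"] * 2
        series = FeatureSeries(values=np.r_[np.zeros(4), np.full(2, 10.0),
                                            np.full(2, 30.0)],
                               feature_name="f")
        lm = load_means(series, labels).set_index("load")
        assert lm.loc[0, "mean"] == 0.0
        assert lm.loc[1, "mean"] == 20.0

    def test_length_mismatch_beyond_window_trim_rejected(self):
        series = FeatureSeries(values=np.zeros(10), feature_name="f")
        with pytest.raises(ValueError):
            condition_means(series, ["rest"] * 30)


class TestFeatureAnaloguesOnSyntheticCohort:
    def test_l1_analogue_rises_with_load_in_healthy_only(self, small_cohort,
                                                         small_bafs,
                                                         feature_models):
        """Healthy subjects: mean L1 at high load exceeds rest; PD subjects
        carry no load-locked component, so no such ordering is required."""
        recs, _ = small_cohort
        diffs = {"healthy": [], "PD": []}
        for rec, baf in zip(recs, small_bafs):
            series = project_feature(feature_models["L1"], baf)
            labels = rec.labels[:baf.n_windows]
            loads = np.array([load_level(c) for c in labels])
            vals = series.values[:len(loads)]
            diffs[rec.group].append(vals[loads == 2].mean()
                                    - vals[loads == 0].mean())
        assert np.mean(diffs["healthy"]) > 0
        # healthy load response clearly exceeds whatever PD shows
        assert np.mean(diffs["healthy"]) > np.mean(diffs["PD"]) + 1.0

    def test_a0_analogue_group_mean_higher_in_healthy(self, small_cohort,
                                                      small_bafs,
                                                      feature_models):
        recs, _ = small_cohort
        means = {"healthy": [], "PD": []}
        for rec, baf in zip(recs, small_bafs):
            series = project_feature(feature_models["A0"], baf)
            means[rec.group].append(series.values.mean())
        assert np.mean(means["healthy"]) > np.mean(means["PD"])
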