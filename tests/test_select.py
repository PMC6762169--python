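import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import pooled_t
from conftest import make_matrix
from lvsig.select import (
    SelectionParams,
    detection_filter,
    mean_diff_filter,
    select_signature,
    two_sample_t,
)
from lvsig.simulate import SimulationConfig, generate_expression


def paper_labels():
    return pd.Series([True] * 26 + [False] * 62,
                     index=[f"s{j}" for j in range(88)])


def matrix_with_missing(n_missing_pos, n_missing_neg):
    """One fully detected gene and one gene with the given per-class
    below-detection counts, at the study's 26/62 class sizes."""
    vals = np.zeros((2, 88))
    mask = np.zeros((2, 88), dtype=bool)
    mask[1, :n_missing_pos] = True
    mask[1, 26:26 + n_missing_neg] = True
    return make_matrix(vals, mask, samples=[f"s{j}" for j in range(88)])


class TestDetectionFilter:
    @pytest.mark.parametrize("miss_pos,miss_neg,kept", [
        (7, 0, False),    # >= 7 of 26 positives missing -> excluded
        (0, 16, False),   # >= 16 of 62 negatives missing -> excluded
        (6, 15, True),    # just under both boundaries -> retained
        (0, 0, True),     # fully detected -> retained
        (7, 16, False),
    ])
    def test_study_size_boundaries(self, miss_pos, miss_neg, kept):
        m = matrix_with_missing(miss_pos, miss_neg)
        passed = detection_filter(m, paper_labels(), SelectionParams())
        assert bool(passed.iloc[1]) is kept
        assert bool(passed.iloc[0])  # fully detected control gene

    def test_single_class_rejected(self):
        m = matrix_with_missing(0, 0)
        labels = pd.Series(True, index=m.sample_ids)
        with pytest.raises(ValueError, match="both classes"):
            detection_filter(m, labels, SelectionParams())


class TestMeanDiffFilter:
    @pytest.mark.parametrize("mean_pos,mean_neg,passed", [
        (1.0, 0.0, True),    # boundary: >= is inclusive
        (0.99, 0.0, False),
        (0.0, 1.5, False),   # down in positives fails the signed rule
    ])
    def test_signed_rule(self, mean_pos, mean_neg, passed):
        vals = np.r_[np.full(26, mean_pos), np.full(62, mean_neg)][None, :]
        m = make_matrix(vals, samples=[f"s{j}" for j in range(88)])
        out = mean_diff_filter(m, paper_labels(), SelectionParams())
        assert bool(out["passed_diff"].iloc[0]) is passed
        assert out["mean_diff"].iloc[0] == pytest.approx(mean_pos - mean_neg)

    def test_unsigned_option_uses_absolute_difference(self):
        vals = np.r_[np.zeros(26), np.full(62, 1.5)][None, :]
        m = make_matrix(vals, samples=[f"s{j}" for j in range(88)])
        out = mean_diff_filter(m, paper_labels(),
                               SelectionParams(signed=False))
        assert bool(out["passed_diff"].iloc[0])

    def test_means_use_detected_values_only(self):
        vals = np.array([[5.0, 1.0, 1.0, 0.0, 0.0, 0.0]])
        mask = np.array([[True, False, False, False, False, False]])
        m = make_matrix(vals, mask)
        labels = pd.Series([True] * 3 + [False] * 3, index=m.sample_ids)
        out = mean_diff_filter(m, labels, SelectionParams())
        assert out["mean_pos"].iloc[0] == 1.0
        assert out["n_detected_pos"].iloc[0] == 2


class TestTwoSampleT:
    def test_matches_textbook_oracle_to_1e10(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(60, 30))
        mask = rng.random((60, 30)) < 0.2
        m = make_matrix(vals, mask)
        labels = pd.Series([True] * 12 + [False] * 18, index=m.sample_ids)
        out = two_sample_t(m, labels, SelectionParams())
        for i in range(60):
            det = ~mask[i]
            x = vals[i, det & labels.to_numpy()]
            y = vals[i, det & ~labels.to_numpy()]
            if len(x) < 2 or len(y) < 2:
                assert np.isnan(out["t_stat"].iloc[i])
                continue
            t, p = pooled_t(x, y)
            assert out["t_stat"].iloc[i] == pytest.approx(t, rel=1e-10)
            assert out["p_value"].iloc[i] == pytest.approx(p, rel=1e-10)

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(20, 24))
        m = make_matrix(vals)
        labels = pd.Series([True] * 10 + [False] * 14, index=m.sample_ids)
        out = two_sample_t(m, labels, SelectionParams(equal_var=False))
        ref = stats.ttest_ind(vals[:, :10], vals[:, 10:], axis=1,
                              equal_var=False)
        assert np.allclose(out["t_stat"], ref.statistic, rtol=1e-10)
        assert np.allclose(out["p_value"], ref.pvalue, rtol=1e-10)

    def test_identical_classes_give_t0_p1(self):
        vals = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        m = make_matrix(vals)
        labels = pd.Series([True] * 3 + [False] * 3, index=m.sample_ids)
        out = two_sample_t(m, labels, SelectionParams())
        assert out["t_stat"].iloc[0] == 0.0
        assert out["p_value"].iloc[0] == 1.0

    def test_zero_variance_unequal_means_is_infinite_t(self):
        vals = np.array([[0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0]])
        m = make_matrix(vals)
        labels = pd.Series([True] * 4 + [False] * 4, index=m.sample_ids)
        out = two_sample_t(m, labels, SelectionParams())
        assert np.isinf(out["t_stat"].iloc[0])
        assert out["p_value"].iloc[0] == 0.0
        assert bool(out["passed_test"].iloc[0])

    def test_under_two_detected_per_class_is_untestable(self):
        vals = np.zeros((1, 6))
        mask = np.array([[True, True, False, False, False, False]])
        m = make_matrix(vals, mask)
        labels = pd.Series([True] * 3 + [False] * 3, index=m.sample_ids)
        out = two_sample_t(m, labels, SelectionParams())
        assert np.isnan(out["p_value"].iloc[0])
        assert not bool(out["passed_test"].iloc[0])

    def test_null_type_one_error_calibrated(self):
        # fraction of null genes with p < alpha is close to alpha
        ds = generate_expression(SimulationConfig(n_genes=20000,
                                                  n_signature=0, seed=13))
        out = two_sample_t(ds.expression, ds.labels, SelectionParams())
        frac = float((out["p_value"] < 0.005).mean())
        sd = np.sqrt(0.005 * 0.995 / 20000)
        assert abs(frac - 0.005) < 4 * sd


class TestSelectSignature:
    def test_selected_is_conjunction_and_ordered(self, paper_size_dataset):
        ds = paper_size_dataset
        res = select_signature(ds.expression, ds.labels)
        t = res.table
        assert (t["selected"] == (t["passed_detection"] & t["passed_diff"]
                                  & t["passed_test"])).all()
        ps = t.loc[res.signature, "p_value"]
        pairs = list(zip(ps.to_numpy(), res.signature))
        assert pairs == sorted(pairs)
        assert (t["mean_diff"] == t["mean_pos"] - t["mean_neg"]).all()

    def test_recovers_planted_signature(self, paper_size_dataset):
        ds = paper_size_dataset
        res = select_signature(ds.expression, ds.labels)
        truth = set(ds.truth)
        recall = len(set(res.signature) & truth) / len(truth)
        assert recall >= 0.9
        assert len(set(res.signature) - truth) <= 2

    def test_infinite_mean_diff_threshold_empties_selection(self,
                                                            paper_size_dataset):
        ds = paper_size_dataset
        res = select_signature(ds.expression, ds.labels,
                               SelectionParams(min_mean_diff=np.inf))
        assert res.signature == []

    def test_huge_effect_selects_everything(self):
        ds = generate_expression(SimulationConfig(
            n_genes=50, n_signature=50, effect_size=20.0, dropout_rate=0.0,
            seed=6))
        res = select_signature(ds.expression, ds.labels)
        assert len(res.signature) == 50

    @pytest.mark.parametrize("seed", range(3))
    def test_monotonicity_in_thresholds(self, seed):
        # raising alpha or lowering min_mean_diff never shrinks the selection
        ds = generate_expression(SimulationConfig(
            n_genes=300, n_signature=30, effect_size=1.0, seed=seed))
        base = set(select_signature(
            ds.expression, ds.labels,
            SelectionParams(min_mean_diff=1.0, alpha=0.005)).signature)
        looser_alpha = set(select_signature(
            ds.expression, ds.labels,
            SelectionParams(min_mean_diff=1.0, alpha=0.05)).signature)
        looser_diff = set(select_signature(
            ds.expression, ds.labels,
            SelectionParams(min_mean_diff=0.5, alpha=0.005)).signature)
        assert base <= looser_alpha
        assert base <= looser_diff
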