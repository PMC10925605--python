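"""Marker normalisation, dominance analysis, permutation test, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eigenmarkers import (
    classification_dominance,
    dichotomize_arousal,
    dominance_analysis,
    fdr_adjust,
    normalize_markers,
    permutation_test_r2,
)
from eigenmarkers.errors import DegenerateInputError, ParameterError


def _table(values_by_dataset):
    rows = []
    for dataset, values in values_by_dataset.items():
        for v in values:
            rows.append(
                {
                    "dataset": dataset,
                    "gradient_range": v,
                    "hierarchical_integration": 2 * v,
                    "harmonic_energy": -v,
                }
            )
    return pd.DataFrame(rows)


class TestNormalizeMarkers:
    def test_simple_minmax(self):
        out = normalize_markers(_table({"a": [2, 4, 6]}))
        np.testing.assert_allclose(out["gradient_range"], [0, 0.5, 1])

    def test_datasets_normalised_independently(self):
        out = normalize_markers(_table({"a": [2, 4, 6], "b": [100, 200]}))
        for dataset in ("a", "b"):
            col = out.loc[out.dataset == dataset, "gradient_range"]
            assert col.min() == 0.0 and col.max() == 1.0

    def test_matches_two_pass_oracle(self, rng):
        values = {"a": rng.normal(size=10).tolist(), "b": rng.normal(size=7).tolist()}
        out = normalize_markers(_table(values))
        for dataset, vals in values.items():
            x = np.array(vals)
            expected = (x - x.min()) / (x - x.min()).max()
            got = out.loc[out.dataset == dataset, "gradient_range"].to_numpy()
            np.testing.assert_array_equal(got, expected)

    def test_constant_marker_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_markers(_table({"a": [3, 3, 3]}))


class TestDominanceAnalysis:
    def test_single_predictor_has_full_importance(self, rng):
        x = rng.normal(size=(30, 1))
        y = x[:, 0] + 0.1 * rng.normal(size=30)
        res = dominance_analysis(x, y)
        assert res.relative_importance["x1"] == pytest.approx(100.0)
        assert res.n_models == 1

    def test_three_predictors_fit_seven_submodels(self, rng):
        x = rng.normal(size=(40, 3))
        y = x @ [1.0, 0.5, 0.2] + rng.normal(size=40)
        res = dominance_analysis(x, y)
        assert res.n_models == 7
        assert sum(res.relative_importance.values()) == pytest.approx(100.0, abs=1e-6)

    def test_dominances_sum_to_full_r2(self, rng):
        x = rng.normal(size=(50, 4))
        y = x @ [2.0, -1.0, 0.5, 0.0] + rng.normal(size=50)
        res = dominance_analysis(x, y)
        assert sum(res.total_dominance.values()) == pytest.approx(res.r2, abs=1e-8)

    def test_orthogonal_predictors_dominance_equals_marginal_r2(self, rng):
        # with centred orthogonal predictors the incremental R^2 of each
        # predictor is the same in every submodel: its marginal R^2
        raw = rng.normal(size=(60, 3))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        x = q
        y = x @ [1.0, 0.6, 0.3] + 0.5 * rng.normal(size=60)
        res = dominance_analysis(x, y)
        for j, name in enumerate(res.predictors):
            marginal = dominance_analysis(x[:, [j]], y).r2
            assert res.total_dominance[name] == pytest.approx(marginal, abs=1e-10)

    def test_importance_invariant_to_predictor_rescaling(self, rng):
        x = rng.normal(size=(40, 3))
        y = x @ [1.0, 0.5, 0.2] + rng.normal(size=40)
        a = dominance_analysis(x, y)
        x2 = x.copy()
        x2[:, 1] *= 1000
        b = dominance_analysis(x2, y)
        for name in a.predictors:
            assert a.relative_importance[name] == pytest.approx(
                b.relative_importance[name], abs=1e-8
            )

    def test_parameter_recovery_largest_weight_wins(self):
        # orthogonalised design with known weights: the predictor with
        # the largest generating weight should dominate in >= 95 of 100 seeds
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            raw = rng.normal(size=(40, 3))
            q, _ = np.linalg.qr(raw - raw.mean(axis=0))
            y = q @ [2.0, 0.8, 0.4] + 0.5 * rng.normal(size=40)
            res = dominance_analysis(q, y)
            best = max(res.relative_importance, key=res.relative_importance.get)
            wins += best == "x1"
        assert wins >= 95

    def test_adjusted_r2_metric_supported(self, rng):
        x = rng.normal(size=(30, 3))
        y = x @ [1.0, 0.5, 0.2] + rng.normal(size=30)
        res = dominance_analysis(x, y, fit_metric="adjusted_r2")
        assert res.n_models == 7
        assert sum(res.relative_importance.values()) == pytest.approx(100.0, abs=1e-6)

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.normal(size=(20, 2))
        x = np.column_stack([x, x[:, 0]])
        with pytest.raises(DegenerateInputError):
            dominance_analysis(x, rng.normal(size=20))


class TestClassificationDominance:
    def test_importance_order_matches_regression_variant(self):
        agreements = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            raw = rng.normal(size=(60, 3))
            q, _ = np.linalg.qr(raw - raw.mean(axis=0))
            score = q @ [3.0, 1.5, 0.5] + 0.3 * rng.normal(size=60)
            reg = dominance_analysis(q, score)
            cls = classification_dominance(q, (score > np.median(score)).astype(int))
            reg_order = sorted(reg.predictors, key=reg.relative_importance.get)
            cls_order = sorted(cls.predictors, key=cls.relative_importance.get)
            agreements += reg_order == cls_order
        assert agreements >= 8

    def test_non_binary_labels_rejected(self, rng):
        with pytest.raises(ParameterError):
            classification_dominance(rng.normal(size=(20, 2)), np.arange(20))


class TestPermutationTest:
    def test_counting_formula_lower_bound(self, rng):
        # a perfectly linear response beats every permutation
        x = rng.normal(size=(30, 2))
        y = x @ [1.0, 2.0]
        p, null = permutation_test_r2(x, y, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)
        assert null.shape == (999,)

    def test_deterministic_under_seed(self, rng):
        x = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        p1, null1 = permutation_test_r2(x, y, n_perm=200, seed=42)
        p2, null2 = permutation_test_r2(x, y, n_perm=200, seed=42)
        assert p1 == p2
        np.testing.assert_array_equal(null1, null2)

    def test_p_never_zero(self, rng):
        x = rng.normal(size=(20, 2))
        p, _ = permutation_test_r2(x, x @ [1, 1], n_perm=50, seed=1)
        assert 0 < p <= 1


class TestDichotomize:
    @pytest.mark.parametrize(
        "cutoff, expected",
        [(9, [1, 1, 0, 0]), (3, [1, 1, 1, 0])],
    )
    def test_study_cutoffs(self, cutoff, expected):
        labels = dichotomize_arousal([11, 9, 3, 0], cutoff)
        np.testing.assert_array_equal(labels, expected)

    def test_all_zero_scores(self):
        np.testing.assert_array_equal(dichotomize_arousal([0, 0, 0], 9), [0, 0, 0])

    def test_invalid_cutoff_and_scores_rejected(self):
        with pytest.raises(ParameterError):
            dichotomize_arousal([1, 2], 5)
        with pytest.raises(ParameterError):
            dichotomize_arousal([12], 9)


def _bh_oracle(pvals):
    """Step-up Benjamini-Hochberg, straight from the definition."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        prev = min(prev, p[idx] * m / rank)
        adjusted[idx] = prev
    return adjusted


class TestFDR:
    def test_all_rejected_at_threshold(self):
        adjusted, reject = fdr_adjust([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_single_p_unchanged(self):
        adjusted, _ = fdr_adjust([0.2])
        assert adjusted[0] == pytest.approx(0.2)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_matches_step_up_oracle(self, pvals):
        adjusted, _ = fdr_adjust(pvals)
        np.testing.assert_allclose(adjusted, _bh_oracle(pvals), atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ParameterError):
            fdr_adjust([0.5, 1.2])
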