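"""Softmax fusion, weight grid search, and the paired t-test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from glandseg.ensemble import (
    EnsembleWeights,
    ensemble_probs,
    grid_search_weights,
    paired_ttest,
    predict_class,
    weighted_ensemble_probs,
)
from glandseg.metrics import mean_iou


def _field(vec):
    """1-pixel probability field from a 2-vector."""
    return np.array(vec).reshape(1, 1, 2)


class TestEnsembleProbs:
    def test_single_model_is_identity(self):
        f = _field([0.3, 0.7])
        np.testing.assert_array_equal(ensemble_probs([f]), f)

    def test_arithmetic_mean_of_three(self):
        fields = [_field(v) for v in ([0.6, 0.4], [0.4, 0.6], [0.1, 0.9])]
        out = ensemble_probs(fields)
        np.testing.assert_allclose(out[0, 0], [0.36667, 0.63333], atol=1e-5)

    def test_identical_fields_are_fixed_point(self):
        f = _field([0.2, 0.8])
        np.testing.assert_allclose(ensemble_probs([f, f, f]), f)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ensemble_probs([_field([0.5, 0.5]), np.zeros((2, 2, 2))])


class TestWeightedEnsemble:
    def test_reported_weight_tuple(self):
        # weights (0.0, 0.2, 0.4): ([0.12, 0.48] / 0.6) = [0.2, 0.8] -> class 1
        fields = [_field(v) for v in ([0.6, 0.4], [0.4, 0.6], [0.1, 0.9])]
        out = weighted_ensemble_probs(fields, (0.0, 0.2, 0.4))
        np.testing.assert_allclose(out[0, 0], [0.2, 0.8], atol=1e-12)
        assert predict_class(out)[0, 0] == 1

    def test_one_hot_weights_reproduce_that_model(self):
        rng = np.random.default_rng(0)
        fields = [rng.dirichlet((1, 1), size=(4, 4)) for _ in range(3)]
        out = weighted_ensemble_probs(fields, (1.0, 0.0, 0.0))
        np.testing.assert_array_equal(out, fields[0])

    def test_uniform_weights_reduce_to_mean_ensemble(self):
        rng = np.random.default_rng(1)
        fields = [rng.dirichlet((1, 1), size=(4, 4)) for _ in range(3)]
        np.testing.assert_allclose(
            weighted_ensemble_probs(fields, (1, 1, 1)),
            ensemble_probs(fields), atol=1e-12,
        )

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_ensemble_probs([_field([0.5, 0.5])], (0.0,))

    def test_argmax_invariant_to_weight_rescaling(self):
        rng = np.random.default_rng(2)
        fields = [rng.dirichlet((1, 1), size=(1000,)) for _ in range(3)]
        w = (0.1, 0.3, 0.6)
        base = predict_class(weighted_ensemble_probs(fields, w))
        for scale in (0.5, 2.0, 17.0):
            scaled = predict_class(
                weighted_ensemble_probs(fields, tuple(scale * x for x in w))
            )
            np.testing.assert_array_equal(base, scaled)


class TestPredictClass:
    def test_majority_class(self):
        assert predict_class(_field([0.2, 0.8]))[0, 0] == 1

    def test_tie_breaks_to_class_zero(self):
        assert predict_class(_field([0.5, 0.5]))[0, 0] == 0

    def test_argmax_commutes_with_softmax(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(50, 2))
        p = np.exp(z) / np.exp(z).sum(-1, keepdims=True)
        np.testing.assert_array_equal(
            predict_class(p), (z[..., 1] > z[..., 0]).astype(np.uint8)
        )


class TestGridSearch:
    def _setup(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, (6, 8, 8)).astype(np.uint8)
        perfect = np.stack([1.0 - y, y], axis=-1).astype(float)
        noise = rng.dirichlet((1, 1), size=y.shape)
        return y, perfect, noise

    def test_single_model_returns_full_weight(self):
        y, perfect, _ = self._setup()
        best, table = grid_search_weights([perfect], y, step=0.2)
        assert best.w == (0.2,)  # all one-model tuples tie; smallest wins
        assert len(table) == 5

    def test_perfect_model_dominates(self):
        """With one perfect and one random model the exhaustive enumeration
        of all 35 step-0.2 tuples puts the maximal weight on the perfect one."""
        y, perfect, noise = self._setup()
        fields = [perfect, noise]
        best, table = grid_search_weights(fields, y, step=0.2)
        assert len(table) == 35

        # oracle: brute-force every lattice tuple independently
        vals = [round(0.2 * i, 10) for i in range(6)]
        oracle_best, oracle_score = None, -1
        for tup in itertools.product(vals, repeat=2):
            if sum(tup) == 0:
                continue
            w = np.array(tup) / sum(tup)
            probs = sum(wi * f for wi, f in zip(w, fields))
            pred = (probs[..., 1] > probs[..., 0]).astype(np.uint8)
            score, _ = mean_iou(y, pred)
            if score > oracle_score:
                oracle_score, oracle_best = score, tup
        assert best.w == oracle_best
        assert best.w[0] > best.w[1]  # maximal weight on the perfect model

    def test_returned_score_is_table_max(self):
        y, perfect, noise = self._setup()
        best, table = grid_search_weights([perfect, noise], y, step=0.2)
        row = table[
            (table["w1"] == best.w[0]) & (table["w2"] == best.w[1])
        ]
        assert row["mean_iou"].iloc[0] == table["mean_iou"].max()

    def test_optimal_beats_every_single_model(self):
        y, perfect, noise = self._setup()
        mediocre = 0.5 * perfect + 0.5 * noise
        fields = [noise, mediocre, perfect]
        best, table = grid_search_weights(fields, y, step=0.2)
        best_score = table["mean_iou"].max()
        for i in range(3):
            pred = predict_class(fields[i])
            single, _ = mean_iou(y, pred)
            assert best_score >= single - 1e-12

    def test_empty_validation_set_raises(self):
        with pytest.raises(ValueError):
            grid_search_weights([np.zeros((0, 4, 4, 2))], np.zeros((0, 4, 4)))

    def test_bad_step_raises(self):
        y, perfect, _ = self._setup()
        with pytest.raises(ValueError):
            grid_search_weights([perfect], y, step=0.3)


class TestPairedTTest:
    def test_hand_computed_example(self):
        res = paired_ttest((1, 2, 3), (2, 4, 6))
        assert res.t_value == pytest.approx(-3.4641, abs=1e-4)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.0742, abs=1e-3)

    def test_zero_variance_differences_raise(self):
        with pytest.raises(ValueError):
            paired_ttest((1.0, 2.0, 3.0), (2.0, 3.0, 4.0))

    def test_swapping_negates_t_keeps_p(self):
        a, b = (0.3, 0.5, 0.9, 0.2), (0.4, 0.1, 0.8, 0.6)
        fwd, rev = paired_ttest(a, b), paired_ttest(b, a)
        assert fwd.t_value == pytest.approx(-rev.t_value)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(3, 20))
            a = rng.normal(size=n)
            b = a + rng.normal(size=n)
            res = paired_ttest(a, b)
            ref = stats.ttest_rel(a, b)
            assert res.t_value == pytest.approx(ref.statistic, abs=1e-9)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)
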