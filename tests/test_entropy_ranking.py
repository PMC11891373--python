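"""Entropy-weight method: normalization, weights, composite scores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fnstab.entropy_ranking import (
    DEFAULT_ORIENTATION,
    OrientationSpec,
    composite_scores,
    entropy_weights,
    orient_normalize,
    rank_models,
    weights_from_utilities,
)
from fnstab.stability_metrics import METRIC_COLUMNS, MetricRecord, MetricTable
from fnstab.synth_femur import SyntheticDecisionSpec, generate_metric_table


def _table(X, labels=None):
    labels = labels or [f"m{i}" for i in range(len(X))]
    return MetricTable(
        [MetricRecord(l, *row) for l, row in zip(labels, np.asarray(X, float))]
    )


class TestOrientNormalize:
    def test_benefit_and_cost_orientations(self):
        t = _table([[1.0, 1.0, 1.0, 1.0], [3.0, 3.0, 3.0, 3.0]])
        Z = orient_normalize(t)
        # stiffness is a benefit: (1,3) -> (0,1); costs flip: (1,3) -> (1,0)
        assert Z[:, 0].tolist() == [0.0, 1.0]
        assert Z[:, 1].tolist() == [1.0, 0.0]

    def test_constant_column_becomes_zeros(self):
        t = _table([[1.0, 5.0, 1.0, 2.0], [2.0, 5.0, 3.0, 1.0]])
        Z = orient_normalize(t)
        assert np.all(Z[:, 1] == 0.0)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            orient_normalize(_table([[1.0, 1, 1, 1]]))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.floats(min_value=0.1, max_value=50.0),
        st.floats(min_value=0.0, max_value=100.0),
    )
    def test_affine_rescaling_invariance(self, a, b):
        X = np.array(
            [[10.0, 4, 2, 0.5], [20.0, 8, 1, 0.9], [15.0, 2, 5, 0.1], [12.0, 6, 3, 0.7]]
        )
        Y = X.copy()
        Y[:, 0] = a * Y[:, 0] + b
        assert np.allclose(orient_normalize(_table(X)), orient_normalize(_table(Y)))


class TestEntropyWeights:
    def test_published_utility_column_reproduces_weights(self):
        # utility values d = 1 - e for the four stability metrics; the
        # weight of the gap metric then lands at 60.0 %
        wv = weights_from_utilities([0.037, 0.029, 0.054, 0.18])
        w_pct = 100 * wv.weight_w
        assert w_pct[3] == pytest.approx(60.04, abs=0.5)
        assert w_pct[0] == pytest.approx(12.24, abs=0.5)
        assert w_pct[1] == pytest.approx(9.78, abs=0.5)
        assert w_pct[2] == pytest.approx(17.94, abs=0.5)

    def test_identical_column_gets_zero_weight(self):
        Z = np.array([[0.5, 0.0], [0.5, 1.0]])
        wv = entropy_weights(Z, metrics=("a", "b"))
        assert wv.entropy_e[0] == pytest.approx(1.0)
        assert wv.weight_w[0] == 0.0 and wv.weight_w[1] == 1.0

    def test_two_by_two_identity_hand_computation(self):
        # p = ((1,0),(0,1)) column-wise; e_j = 0; d_j = 1; w = (1/2, 1/2)
        wv = entropy_weights(np.eye(2), metrics=("a", "b"))
        assert np.allclose(wv.entropy_e, 0.0)
        assert np.allclose(wv.weight_w, [0.5, 0.5])

    def test_all_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            entropy_weights(np.zeros((3, 4)))

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        Z = rng.uniform(size=(17, 4))
        wv = entropy_weights(Z)
        assert abs(wv.weight_w.sum() - 1.0) < 1e-12
        assert np.all((wv.entropy_e >= 0) & (wv.entropy_e <= 1))
        assert np.allclose(wv.utility_d, 1 - wv.entropy_e)


class TestCompositeScores:
    def test_degenerate_weights_select_single_column(self):
        Z = np.array([[0.2, 0.9], [0.7, 0.1], [0.5, 0.5]])
        wv = weights_from_utilities([1.0, 0.0], metrics=("a", "b"))
        res = composite_scores(Z, wv)
        assert np.allclose(res.scores, Z[:, 0])

    def test_all_equal_rows_full_tie(self):
        Z = np.tile([0.3, 0.6, 0.1, 0.2], (4, 1))
        wv = weights_from_utilities([0.2, 0.3, 0.4, 0.1])
        res = composite_scores(Z, wv)
        assert len(set(np.round(res.scores, 12))) == 1
        assert "tie" in res.ties_note

    def test_random_instance_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        Z = rng.uniform(size=(5, 4))
        wv = entropy_weights(Z)
        res = composite_scores(Z, wv)
        for i in range(5):
            s = sum(wv.weight_w[j] * Z[i, j] for j in range(4))
            assert res.scores[i] == pytest.approx(s, rel=1e-12)
        assert sorted(res.order.tolist()) == list(range(5))

    def test_scores_bounded(self):
        rng = np.random.default_rng(3)
        Z = rng.uniform(size=(9, 4))
        res = composite_scores(Z, entropy_weights(Z))
        assert np.all((res.scores >= 0) & (res.scores <= 1))


class TestRankModels:
    def test_planted_dominant_column_wins(self):
        spec = SyntheticDecisionSpec(planted_weights=(0.1, 0.1, 0.2, 0.6), noise_sd=0.0, seed=2)
        wv, res, audit = rank_models(generate_metric_table(spec))
        assert np.argmax(wv.weight_w) == 3
        assert audit["normalized"].shape == (17, 4)

    def test_row_permutation_invariance(self):
        spec = SyntheticDecisionSpec(planted_weights=(0.4, 0.3, 0.2, 0.1), noise_sd=0.01, seed=9)
        table = generate_metric_table(spec)
        wv1, res1, _ = rank_models(table)
        perm = np.random.default_rng(0).permutation(len(table.records))
        table2 = MetricTable([table.records[i] for i in perm])
        wv2, res2, _ = rank_models(table2)
        assert np.allclose(wv1.weight_w, wv2.weight_w)
        s1 = dict(zip(res1.labels, res1.scores))
        s2 = dict(zip(res2.labels, res2.scores))
        assert all(s1[k] == pytest.approx(s2[k], rel=1e-12) for k in s1)

    def test_default_study_size_returns_17_scores(self):
        wv, res, _ = rank_models(generate_metric_table(SyntheticDecisionSpec(seed=1, noise_sd=0.02)))
        assert len(res.scores) == 17
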