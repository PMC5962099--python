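"""Supervised SOM mechanics: distances, winners, updates, training, scoring."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xyfsom import (
    CodebookSet,
    GridSpec,
    TrainingParams,
    bootstrap_prediction_ci,
    combined_distance,
    confusion_matrix,
    find_winner,
    fit,
    init_codebooks,
    predict,
    tanimoto_distance,
    train_som,
    true_labels,
    update_codebooks,
)
from xyfsom.engine import TrainedMap, quantization_error
from xyfsom.logbook import encode_classes, standardize_columns


class TestTanimoto:
    def test_matches_enumerated_disagreement_on_all_3bit_pairs(self):
        for a in itertools.product([0.0, 1.0], repeat=3):
            for b in itertools.product([0.0, 1.0], repeat=3):
                expected = sum(x != y for x, y in zip(a, b)) / 3.0
                assert tanimoto_distance(np.array(a), np.array(b)) == pytest.approx(expected)

    def test_binarizes_at_half(self):
        assert tanimoto_distance(np.array([1, 0, 0.0]), np.array([0.6, 0.4, 0.0])) == 0.0
        assert tanimoto_distance(np.array([1, 0, 0.0]), np.array([0, 1, 0.0])) == pytest.approx(2 / 3)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            tanimoto_distance(np.zeros(3), np.zeros(4))

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=8),
        st.data(),
    )
    def test_symmetric_and_bounded(self, a, data):
        b = data.draw(st.lists(st.floats(0, 1), min_size=len(a), max_size=len(a)))
        a, b = np.array(a), np.array(b)
        d = tanimoto_distance(a, b)
        assert d == tanimoto_distance(b, a)
        assert 0.0 <= d <= 1.0


class TestCombinedDistance:
    def test_weighted_sum(self):
        assert combined_distance(0.4, 0.2, 0.5) == pytest.approx(0.3)
        assert combined_distance(0.7, 0.9, 1.0) == 0.7
        assert combined_distance(0.0, 0.0, 0.3) == 0.0

    def test_alpha_out_of_range_raises(self):
        with pytest.raises(ValueError):
            combined_distance(0.1, 0.1, 1.5)


class TestInitCodebooks:
    def test_codebooks_are_training_rows(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(1000, 4))
        Y = np.eye(5)[rng.integers(0, 5, 1000)]
        cb = init_codebooks(X, Y, GridSpec(5, 5), seed=7)
        rows = {tuple(r) for r in np.hstack([X, Y])}
        for xw, yw in zip(cb.x_weights, cb.y_weights):
            assert tuple(np.concatenate([xw, yw])) in rows

    def test_deterministic_for_fixed_seed(self):
        X = np.random.default_rng(1).normal(size=(30, 3))
        Y = np.eye(3)[np.arange(30) % 3]
        a = init_codebooks(X, Y, GridSpec(4, 4), seed=42)
        b = init_codebooks(X, Y, GridSpec(4, 4), seed=42)
        np.testing.assert_array_equal(a.x_weights, b.x_weights)
        np.testing.assert_array_equal(a.y_weights, b.y_weights)

    def test_single_node_grid(self):
        X = np.arange(6.0).reshape(3, 2)
        Y = np.eye(3)
        cb = init_codebooks(X, Y, GridSpec(1, 1), seed=0)
        assert any(np.array_equal(cb.x_weights[0], x) for x in X)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            init_codebooks(np.empty((0, 2)), np.empty((0, 1)), GridSpec(2, 2), seed=0)


def _brute_force_winner(cb: CodebookSet, x, y, alpha):
    """Independent argmin oracle using scalar distance calls."""
    best, best_d = 0, np.inf
    dx = np.array([float(np.sum((xw - x) ** 2)) for xw in cb.x_weights])
    if dx.max() > 0:
        dx = dx / dx.max()
    if y is None:
        d = dx
    else:
        dy = np.array([tanimoto_distance(yw, y) for yw in cb.y_weights])
        if dy.max() > 0:
            dy = dy / dy.max()
        d = alpha * dx + (1 - alpha) * dy
    for i, di in enumerate(d):
        if di < best_d:
            best, best_d = i, di
    return best


class TestFindWinner:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            cb = CodebookSet(rng.normal(size=(25, 6)), rng.random((25, 4)))
            x = rng.normal(size=6)
            y = np.eye(4)[rng.integers(0, 4)]
            alpha = rng.random()
            assert find_winner(x, y, cb, alpha) == _brute_force_winner(cb, x, y, alpha)
            assert find_winner(x, None, cb, alpha) == _brute_force_winner(cb, x, None, alpha)

    def test_exact_codebook_match_wins(self):
        cb = CodebookSet(np.array([[0.0, 0], [5, 5], [9, 9]]), np.ones((3, 1)))
        assert find_winner(np.array([5.0, 5]), None, cb, 1.0) == 1

    def test_single_node(self):
        cb = CodebookSet(np.zeros((1, 2)), np.ones((1, 1)))
        assert find_winner(np.array([3.0, 4]), None, cb, 0.5) == 0

    def test_dimension_mismatch_raises(self):
        cb = CodebookSet(np.zeros((2, 3)), np.ones((2, 2)))
        with pytest.raises(ValueError):
            find_winner(np.zeros(4), None, cb, 0.5)


class TestUpdate:
    def test_full_rate_zero_radius_moves_winner_onto_object(self):
        grid = GridSpec(2, 2)
        cb = CodebookSet(np.zeros((4, 2)), np.zeros((4, 2)))
        x, y = np.array([1.0, 2.0]), np.array([0.0, 1.0])
        update_codebooks(cb, 1, x, y, lr=1.0, radius=0.0, node_distances=grid.node_distances())
        np.testing.assert_array_equal(cb.x_weights[1], x)
        np.testing.assert_array_equal(cb.y_weights[1], y)
        assert np.all(cb.x_weights[[0, 2, 3]] == 0.0)

    def test_half_rate_reaches_midpoint(self):
        grid = GridSpec(1, 1)
        cb = CodebookSet(np.array([[0.0, 0.0]]), np.array([[0.0]]))
        update_codebooks(cb, 0, np.array([2.0, 4.0]), np.array([1.0]), 0.5, 0.0, grid.node_distances())
        np.testing.assert_array_equal(cb.x_weights[0], [1.0, 2.0])

    def test_update_contracts_distance_to_object(self):
        rng = np.random.default_rng(2)
        grid = GridSpec(3, 3)
        nd = grid.node_distances()
        for lr in (0.05, 0.5, 1.0):
            cb = CodebookSet(rng.normal(size=(9, 4)), rng.random((9, 2)))
            x, y = rng.normal(size=4), rng.random(2)
            before = np.linalg.norm(cb.x_weights[4] - x)
            update_codebooks(cb, 4, x, y, lr, 1.0, nd)
            after = np.linalg.norm(cb.x_weights[4] - x)
            assert after < before


class TestTrain:
    def test_one_object_one_node_full_rate_converges_immediately(self):
        X = np.array([[2.0, -1.0]])
        Y = np.array([[1.0]])
        cb, qe = train_som(X, Y, GridSpec(1, 1), TrainingParams(rlen=1, lr_start=1.0, lr_end=1.0, seed=0))
        np.testing.assert_allclose(cb.x_weights[0], X[0])
        assert qe == pytest.approx(0.0)

    def test_bit_identical_across_runs_with_same_seed(self, toy_table):
        Z, _, _ = standardize_columns(toy_table)
        enc = encode_classes(toy_table, ("gear",))
        p = TrainingParams(rlen=10, seed=9)
        cb1, qe1 = train_som(Z, enc.indicator, GridSpec(3, 4), p)
        cb2, qe2 = train_som(Z, enc.indicator, GridSpec(3, 4), p)
        np.testing.assert_array_equal(cb1.x_weights, cb2.x_weights)
        np.testing.assert_array_equal(cb1.y_weights, cb2.y_weights)
        assert qe1 == qe2

    def test_y_weights_stay_in_unit_interval(self, toy_table):
        Z, _, _ = standardize_columns(toy_table)
        enc = encode_classes(toy_table)
        cb, _ = train_som(Z, enc.indicator, GridSpec(4, 4), TrainingParams(rlen=30, seed=1))
        assert np.all(cb.y_weights >= 0.0)
        assert np.all(cb.y_weights <= 1.0)

    def test_training_reduces_quantization_error_on_average(self):
        """Trained maps fit clustered data better than their random init."""
        rng = np.random.default_rng(0)
        wins = []
        for seed in range(20):
            centers = rng.normal(scale=4, size=(3, 5))
            X = np.vstack([c + rng.normal(scale=0.5, size=(30, 5)) for c in centers])
            Y = np.repeat(np.eye(3), 30, axis=0)
            grid = GridSpec(4, 4)
            init = init_codebooks(X, Y, grid, np.random.default_rng(seed))
            qe0 = quantization_error(init, X, Y, 0.5)
            _, qe1 = train_som(X, Y, grid, TrainingParams(rlen=100, seed=seed))
            wins.append(qe1 - qe0)
        assert np.mean(wins) < 0

    def test_nan_input_rejected(self):
        X = np.array([[1.0, np.nan]])
        with pytest.raises(ValueError):
            train_som(X, np.array([[1.0]]), GridSpec(1, 1), TrainingParams(rlen=1, seed=0))

    def test_rlen_zero_disallowed(self):
        with pytest.raises(ValueError):
            TrainingParams(rlen=0)


class TestPredict:
    def test_separable_classes_recovered_perfectly(self, toy_map, toy_table):
        pred = predict(toy_map, toy_table)
        truth = true_labels(toy_map, toy_table)
        assert np.mean(pred == truth) == 1.0

    def test_single_class_map_predicts_it_everywhere(self, toy_table):
        sub = toy_table.subset(toy_table.gear == "BL")
        m = fit(sub, GridSpec(2, 2), TrainingParams(rlen=20, seed=0), factors=("gear",))
        assert set(predict(m, toy_table)) == {"BL"}

    def test_species_mismatch_lists_columns(self, toy_map, toy_table):
        bad = toy_table.subset(np.arange(toy_table.n_trips))
        bad.species_names = ("catfish", "snapper", "ray")
        with pytest.raises(ValueError, match="ray"):
            predict(toy_map, bad)

    def test_species_reordering_is_tolerated(self, toy_map, toy_table):
        reordered = TripTable_reorder(toy_table, [2, 0, 1])
        np.testing.assert_array_equal(predict(toy_map, reordered), predict(toy_map, toy_table))


def TripTable_reorder(table, order):
    from xyfsom import TripTable

    return TripTable(
        trip_id=table.trip_id,
        year=table.year,
        season=table.season,
        gear=table.gear,
        catch=table.catch[:, order],
        species_names=tuple(table.species_names[i] for i in order),
    )


class TestConfusionMatrix:
    def test_hand_counted_example(self):
        cm = confusion_matrix(["A", "A", "B", "B"], ["A", "B", "B", "B"])
        assert cm.loc["A", "A"] == pytest.approx(50.0)
        assert cm.loc["A", "B"] == pytest.approx(50.0)
        assert cm.loc["B", "A"] == pytest.approx(0.0)
        assert cm.loc["B", "B"] == pytest.approx(100.0)

    def test_perfect_prediction_is_identity(self):
        cm = confusion_matrix(["x", "y", "z"], ["x", "y", "z"])
        np.testing.assert_allclose(np.diag(cm.to_numpy()), 100.0)

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(3)
        labs = list("abcd")
        t = rng.choice(labs, 200)
        p = rng.choice(labs, 200)
        cm = confusion_matrix(t, p)
        np.testing.assert_allclose(cm.sum(axis=1), 100.0, atol=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            confusion_matrix([], [])


class TestBootstrap:
    def test_perfect_test_set_gives_degenerate_ci(self, toy_map, toy_table):
        ci = bootstrap_prediction_ci(toy_map, toy_table, n_boot=200, seed=0)
        row = ci.table.loc["overall"]
        assert row["mean"] == pytest.approx(100.0)
        assert row["lower"] == pytest.approx(100.0)
        assert row["upper"] == pytest.approx(100.0)

    def test_absent_class_reported_missing(self, toy_map, toy_table):
        sub = toy_table.subset(toy_table.gear != "VL")
        ci = bootstrap_prediction_ci(toy_map, sub, n_boot=50, seed=0)
        assert bool(ci.table.loc["VL", "missing"]) is True
        assert np.isnan(ci.table.loc["VL", "mean"])

    def test_ci_contains_point_estimate(self, small_fleet):
        m = fit(
            small_fleet,
            GridSpec(6, 6),
            TrainingParams(rlen=20, seed=4),
            factors=("gear",),
        )
        truth = true_labels(m, small_fleet)
        pred = predict(m, small_fleet)
        point = 100.0 * float(np.mean(truth == pred))
        ci = bootstrap_prediction_ci(m, small_fleet, n_boot=400, seed=7)
        row = ci.table.loc["overall"]
        assert row["lower"] <= point <= row["upper"]
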