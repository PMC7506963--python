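"""LSTM and BPNN: cell equations against scalar oracles, gate ranges,
training contracts, and hidden-unit selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgknee import (BPNNConfig, LSTMConfig, LSTMWeights, bpnn_forward,
                     hidden_unit_candidates, lstm_cell_step, predict_lstm,
                     select_hidden_units, train_bpnn, train_lstm)
from emgknee.models import BPNNModel, predict_bpnn
from oracles import bpnn_forward_oracle, lstm_cell_oracle


def _random_lstm_weights(D, H, rng):
    def r(*shape):
        return rng.standard_normal(shape)
    kw = {}
    for g in "fico":
        kw[f"U_{g}"] = r(H, D)
        kw[f"W_{g}"] = r(H, H)
        kw[f"b_{g}"] = r(H)
    kw["w_out"] = r(H)
    kw["b_out"] = float(rng.standard_normal())
    return LSTMWeights(**kw)


class TestLstmCell:
    def test_zero_weights(self):
        w = LSTMWeights(**{f"U_{g}": np.zeros((3, 2)) for g in "fico"},
                        **{f"W_{g}": np.zeros((3, 3)) for g in "fico"},
                        **{f"b_{g}": np.zeros(3) for g in "fico"},
                        w_out=np.zeros(3), b_out=0.0)
        c_prev = np.array([1.0, -2.0, 0.5])
        st_ = lstm_cell_step(np.ones(2), np.zeros(3), c_prev, w)
        assert np.allclose(st_.f, 0.5) and np.allclose(st_.i, 0.5)
        assert np.allclose(st_.o, 0.5) and np.allclose(st_.c_candidate, 0.0)
        assert np.allclose(st_.c, 0.5 * c_prev)
        assert np.allclose(st_.h, 0.5 * np.tanh(0.5 * c_prev))

    def test_matches_scalar_oracle_many_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            D = int(rng.integers(1, 4))
            H = int(rng.integers(1, 4))
            w = _random_lstm_weights(D, H, rng)
            x = rng.standard_normal(D)
            h_prev = rng.standard_normal(H)
            c_prev = rng.standard_normal(H)
            ours = lstm_cell_step(x, h_prev, c_prev, w)
            wd = {k: v.tolist() for k, v in w.arrays().items()
                  if not k.startswith(("w_out", "b_out"))}
            ref = lstm_cell_oracle(x.tolist(), h_prev.tolist(), c_prev.tolist(), wd)
            for field in ("f", "i", "o", "c_candidate", "c", "h"):
                assert np.allclose(getattr(ours, field), ref[field], atol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_gate_ranges(self, seed):
        """Sigmoid gates stay in (0,1) and the candidate in (-1,1); extreme
        pre-activations may saturate to the closed bounds in float64, which
        is the best the arithmetic can represent."""
        rng = np.random.default_rng(seed)
        D, H = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        w = _random_lstm_weights(D, H, rng)
        st_ = lstm_cell_step(rng.standard_normal(D),
                             rng.standard_normal(H),
                             rng.standard_normal(H), w)
        for g in (st_.f, st_.i, st_.o):
            assert np.all(g >= 0.0) and np.all(g <= 1.0)
            assert np.all((g > 0.0) & (g < 1.0) | (np.abs(g - 0.5) == 0.5))
        assert np.all(st_.c_candidate >= -1.0) and np.all(st_.c_candidate <= 1.0)
        # at unit-scale pre-activations the strict bounds hold
        mild = lstm_cell_step(0.1 * rng.standard_normal(D), np.zeros(H),
                              np.zeros(H), w)
        for g in (mild.f, mild.i, mild.o):
            assert np.all((g > 0.0) & (g < 1.0))
        assert np.all((mild.c_candidate > -1.0) & (mild.c_candidate < 1.0))

    def test_input_gate_saturation_empties_cell(self):
        """i -> 0 (bias -> -inf) with empty previous cell leaves c at 0."""
        w = _random_lstm_weights(2, 3, np.random.default_rng(1))
        w.b_i = np.full(3, -50.0)
        st_ = lstm_cell_step(np.ones(2), np.zeros(3), np.zeros(3), w)
        assert np.allclose(st_.c, 0.0, atol=1e-12)

    def test_shape_mismatch(self):
        w = _random_lstm_weights(2, 3, np.random.default_rng(0))
        with pytest.raises(ValueError):
            lstm_cell_step(np.ones(5), np.zeros(3), np.zeros(3), w)


class TestLstmTraining:
    def _toy_stream(self, T=400, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-1, 1, size=(T, 4))
        return X

    def test_zero_epochs_returns_initialization(self):
        X = self._toy_stream()
        y = np.zeros(len(X))
        cfg = LSTMConfig(input_size=4, hidden_size=8, seq_len=50, epochs=0, seed=5)
        model = train_lstm(X, y, cfg)
        fresh = LSTMWeights.init(4, 8, np.random.default_rng(5))
        for k, v in model.weights.arrays().items():
            assert np.array_equal(v, fresh.arrays()[k])

    def test_same_seed_identical_loss_trajectories(self):
        X = self._toy_stream()
        y = 0.5 * X[:, 0]
        cfg = LSTMConfig(input_size=4, hidden_size=8, seq_len=50, epochs=5,
                         batch_size=4, seed=3)
        m1 = train_lstm(X, y, cfg)
        m2 = train_lstm(X, y, cfg)
        assert m1.loss_history == m2.loss_history
        assert np.array_equal(m1.weights.w_out, m2.weights.w_out)

    def test_constant_target_learned(self):
        """Constant normalized target 0.3: the smoothed loss decreases and
        the final prediction error is small."""
        X = self._toy_stream(T=500, seed=2)
        y = np.full(len(X), 0.3)
        cfg = LSTMConfig(input_size=4, hidden_size=16, seq_len=50, epochs=30,
                         batch_size=5, learning_rate=5e-3, dropout_p=0.0, seed=0)
        model = train_lstm(X, y, cfg)
        loss = np.array(model.loss_history)
        smooth = np.convolve(loss, np.ones(5) / 5, mode="valid")
        # monotone decrease up to plateau-level jitter, and a large net drop
        assert np.all(np.diff(smooth) <= 1e-4)
        assert smooth[-1] < 0.1 * smooth[0]
        pred = predict_lstm(model, X)
        post_transient = pred[25:] - 0.3
        assert np.sqrt(np.mean(post_transient ** 2)) < 0.05

    def test_stream_shorter_than_window_rejected(self):
        X = self._toy_stream(T=30)
        with pytest.raises(ValueError):
            train_lstm(X, np.zeros(30),
                       LSTMConfig(input_size=4, hidden_size=4, seq_len=50, epochs=1))


class TestLstmPredict:
    def test_constant_input_converges_to_fixed_point(self):
        rng = np.random.default_rng(4)
        w = _random_lstm_weights(3, 6, rng)
        # scale recurrent weights down so iteration is contractive
        for g in "fico":
            setattr(w, f"W_{g}", 0.1 * getattr(w, f"W_{g}"))
        from emgknee.models import LSTMModel
        model = LSTMModel(weights=w, config=LSTMConfig(input_size=3, hidden_size=6))
        X = np.tile(np.array([0.2, -0.4, 0.1]), (300, 1))
        out = predict_lstm(model, X)
        assert abs(out[-1] - out[-2]) < 1e-8

    def test_column_mismatch_raises(self):
        X = np.random.default_rng(0).uniform(-1, 1, (120, 4))
        cfg = LSTMConfig(input_size=4, hidden_size=4, seq_len=30, epochs=1,
                         batch_size=2, seed=0)
        model = train_lstm(X, np.zeros(120), cfg,
                           feature_names=("a", "b", "c", "d"))
        with pytest.raises(ValueError):
            predict_lstm(model, X, feature_names=("b", "a", "c", "d"))

    def test_empty_sequence(self):
        cfg = LSTMConfig(input_size=4, hidden_size=4, seq_len=30, epochs=0)
        model = train_lstm(np.zeros((40, 4)), np.zeros(40), cfg)
        assert predict_lstm(model, np.zeros((0, 4))).size == 0


class TestBpnn:
    def test_zero_weights_printed_formula(self):
        cfg = BPNNConfig(n_input=2, n_hidden=3)
        model = BPNNModel(W_in=np.zeros((3, 2)), b_in=np.zeros(3),
                          W_out=np.zeros(3), b_out=0.25, config=cfg)
        # hidden output 0; sigmoid(0) + b_out = 0.75
        assert bpnn_forward(np.array([5.0, -7.0]), model) == pytest.approx(0.75)

    def test_matches_scalar_oracle_many_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            D, H = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            model = BPNNModel(W_in=rng.standard_normal((H, D)),
                              b_in=rng.standard_normal(H),
                              W_out=rng.standard_normal(H),
                              b_out=float(rng.standard_normal()),
                              config=BPNNConfig(n_input=D, n_hidden=H))
            x = rng.standard_normal(D)
            ref = bpnn_forward_oracle(x.tolist(), model.W_in.tolist(),
                                      model.b_in.tolist(), model.W_out.tolist(),
                                      model.b_out)
            assert bpnn_forward(x, model) == pytest.approx(ref, abs=1e-12)

    def test_saturates_outside_unit_box(self):
        rng = np.random.default_rng(2)
        model = BPNNModel.init(BPNNConfig(n_input=3, n_hidden=4), rng)
        out = bpnn_forward(np.array([100.0, -300.0, 50.0]), model)
        assert np.isfinite(out)

    def test_momentum_training_reaches_goal_on_toy_mapping(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 1, size=(200, 2))
        y = 0.4 + 0.25 * X[:, 0] - 0.15 * X[:, 1]  # inside the sigmoid range
        cfg = BPNNConfig(n_input=2, n_hidden=6, goal_mse=0.01,
                         max_epochs=5000, seed=0)
        model = train_bpnn(X, y, cfg)
        assert model.loss_history[-1] <= cfg.goal_mse
        assert len(model.loss_history) < cfg.max_epochs

    def test_linear_output_mode(self):
        cfg = BPNNConfig(n_input=2, n_hidden=3, output_activation="linear")
        model = BPNNModel(W_in=np.zeros((3, 2)), b_in=np.zeros(3),
                          W_out=np.zeros(3), b_out=0.25, config=cfg)
        assert bpnn_forward(np.array([1.0, 1.0]), model) == pytest.approx(0.25)


class TestHiddenUnitSelection:
    def test_empirical_rule_candidates(self):
        cands = hidden_unit_candidates(n_input=16, n_output=1)
        # floor(sqrt(17)) + a for a in 1..10 gives 5..14; log2(16) adds 4
        assert set(range(5, 15)).issubset(cands)
        assert 4 in cands
        assert max(cands) == 14

    def test_default_scan_covers_reported_optimum(self):
        from emgknee.models import DEFAULT_HIDDEN_CANDIDATES
        assert 18 in DEFAULT_HIDDEN_CANDIDATES

    def test_single_candidate_returned_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (50, 2))
        y = 0.5 * X[:, 0]
        cfg = BPNNConfig(n_input=2, n_hidden=1, max_epochs=50)
        best, scores = select_hidden_units(X, y, X, y, candidates=[7],
                                           base_config=cfg)
        assert best == 7 and list(scores) == [7]

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_hidden_units(np.zeros((4, 2)), np.zeros(4),
                                np.zeros((4, 2)), np.zeros(4), candidates=[])

    def test_picks_minimum_validation_mse(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(-1, 1, (150, 2))
        y = 0.4 + 0.2 * np.tanh(2 * X[:, 0]) * X[:, 1]
        cfg = BPNNConfig(n_input=2, max_epochs=400, seed=1)
        best, scores = select_hidden_units(X[:100], y[:100], X[100:], y[100:],
                                           candidates=(2, 6, 10),
                                           base_config=cfg)
        assert best in scores
        assert scores[best] == min(scores.values())


def test_bpnn_predict_column_mismatch():
    rng = np.random.default_rng(0)
    X = rng.uniform(-1, 1, (30, 2))
    model = train_bpnn(X, 0.3 * X[:, 0],
                       BPNNConfig(n_input=2, n_hidden=3, max_epochs=10),
                       feature_names=("a", "b"))
    with pytest.raises(ValueError):
        predict_bpnn(model, X, feature_names=("b", "a"))
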