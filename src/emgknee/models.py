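"""Angle regressors: an LSTM sequence model and a one-hidden-layer BPNN.

Both networks are implemented directly in NumPy so the gate equations, the
back-propagation-through-time pass and the training recipes are explicit
and auditable.

LSTM cell (elementwise product denoted o):

    f_t = sigmoid(W_f h_{t-1} + U_f x_t + b_f)        forget gate
    i_t = sigmoid(W_i h_{t-1} + U_i x_t + b_i)        input gate
    c'_t = tanh(W_c h_{t-1} + U_c x_t + b_c)          candidate state
    c_t = f_t o c_{t-1} + i_t o c'_t                  cell state
    o_t = sigmoid(W_o h_{t-1} + U_o x_t + b_o)        output gate
    h_t = o_t o tanh(c_t)

A linear readout maps h_t to the scalar (normalized) angle; the loss is the
mean squared error.  Training uses Adam on mini-batches of non-overlapping
sequence windows cut in temporal order and shuffled at the window level
each epoch, with the hidden state reset per window and dropout applied to
h_t before the readout.  The default recipe: 200 hidden units, unroll
length 100, learning rate 5e-4, 200 epochs, mini-batch 50, drop
probability 0.5.  The unroll length of 100 time steps runs over a single
recurrent layer; a ``stacked_layers`` option exists for sensitivity checks
but 100 *stacked* recurrent layers is not a trainable reading of the
recipe.

BPNN: hidden layer tansig (2 / (1 + exp(-2 z)) - 1), output

    y = 1 / (1 + exp(-W_out tansig(W_in x + b_in))) + b_out

exactly as the reference formula prints it (a logistic squash plus output
bias); ``output_activation="linear"`` gives the conventional purelin
reading instead.  Training is full-batch gradient descent with momentum
(default coefficient 0.9), learning rate 0.1, stopping at a goal MSE of
0.01 (normalized units) or 50 000 epochs, whichever comes first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _tansig(z):
    # MATLAB-style fast tanh: 2/(1+exp(-2z)) - 1
    return 2.0 / (1.0 + np.exp(-2.0 * z)) - 1.0


# ===========================================================================
# LSTM
# ===========================================================================

@dataclass
class LSTMConfig:
    input_size: int = 16
    hidden_size: int = 200
    seq_len: int = 100
    learning_rate: float = 5e-4
    epochs: int = 200
    batch_size: int = 50
    dropout_p: float = 0.5
    stacked_layers: int = 1
    seed: int = 0

    def validate(self) -> None:
        for name in ("input_size", "hidden_size", "seq_len", "epochs",
                     "batch_size", "stacked_layers"):
            if getattr(self, name) < (0 if name == "epochs" else 1):
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class LSTMWeights:
    """All parameters of one LSTM layer plus the scalar readout."""

    U_f: np.ndarray
    U_i: np.ndarray
    U_c: np.ndarray
    U_o: np.ndarray
    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray
    w_out: np.ndarray
    b_out: float

    GATES = ("f", "i", "c", "o")

    def arrays(self) -> dict:
        d = {}
        for g in self.GATES:
            d[f"U_{g}"] = getattr(self, f"U_{g}")
            d[f"W_{g}"] = getattr(self, f"W_{g}")
            d[f"b_{g}"] = getattr(self, f"b_{g}")
        d["w_out"] = self.w_out
        d["b_out"] = np.asarray(self.b_out, dtype=float)
        return d

    def copy(self) -> "LSTMWeights":
        d = {k: np.array(v) for k, v in self.arrays().items()}
        d["b_out"] = float(d["b_out"])
        return LSTMWeights(**d)

    @staticmethod
    def init(input_size: int, hidden_size: int,
             rng: np.random.Generator) -> "LSTMWeights":
        """Uniform +-1/sqrt(fan-in) initialization, drawn in a fixed order."""
        def u(shape, fan_in):
            bound = 1.0 / math.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape)

        d = {}
        for g in LSTMWeights.GATES:
            d[f"U_{g}"] = u((hidden_size, input_size), input_size)
            d[f"W_{g}"] = u((hidden_size, hidden_size), hidden_size)
            d[f"b_{g}"] = np.zeros(hidden_size)
        d["w_out"] = u(hidden_size, hidden_size)
        d["b_out"] = 0.0
        return LSTMWeights(**d)


@dataclass
class LSTMState:
    """One step's activations: gates are in (0,1), candidate in (-1,1)."""

    h: np.ndarray
    c: np.ndarray
    f: np.ndarray
    i: np.ndarray
    o: np.ndarray
    c_candidate: np.ndarray


def lstm_cell_step(x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray,
                   w: LSTMWeights) -> LSTMState:
    """One LSTM cell update; supports a leading batch axis on all inputs."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    if x_t.shape[-1] != w.U_f.shape[1]:
        raise ValueError(
            f"input size {x_t.shape[-1]} does not match weights "
            f"({w.U_f.shape[1]})")
    if h_prev.shape[-1] != w.W_f.shape[1] or c_prev.shape != h_prev.shape:
        raise ValueError("hidden/cell state shape mismatch")
    f = _sigmoid(h_prev @ w.W_f.T + x_t @ w.U_f.T + w.b_f)
    i = _sigmoid(h_prev @ w.W_i.T + x_t @ w.U_i.T + w.b_i)
    cc = np.tanh(h_prev @ w.W_c.T + x_t @ w.U_c.T + w.b_c)
    c = f * c_prev + i * cc
    o = _sigmoid(h_prev @ w.W_o.T + x_t @ w.U_o.T + w.b_o)
    h = o * np.tanh(c)
    return LSTMState(h=h, c=c, f=f, i=i, o=o, c_candidate=cc)


@dataclass
class LSTMModel:
    """Trained LSTM: weights, the recipe that produced them, the column
    layout it expects, and the per-epoch training loss."""

    weights: LSTMWeights
    config: LSTMConfig
    feature_names: tuple | None = None
    loss_history: list = field(default_factory=list)


def _forward_seq(X: np.ndarray, w: LSTMWeights):
    """Unroll over a [B, T, D] batch; returns per-step caches for BPTT."""
    B, T, _ = X.shape
    H = w.b_f.size
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    states = []
    for t in range(T):
        st = lstm_cell_step(X[:, t, :], h, c, w)
        states.append((h, c, st))
        h, c = st.h, st.c
    return states


def _bptt(X, y, w: LSTMWeights, drop_mask, keep_p):
    """Forward + backward over a [B, T, D] batch.

    Returns (loss, grads dict keyed like LSTMWeights.arrays()).
    """
    B, T, _ = X.shape
    states = _forward_seq(X, w)
    H = w.b_f.size

    h_stack = np.stack([st.h for (_, _, st) in states], axis=1)  # [B,T,H]
    h_drop = h_stack * drop_mask / keep_p
    y_hat = h_drop @ w.w_out + w.b_out  # [B,T]
    err = y_hat - y
    n_total = err.size
    loss = float(np.mean(err ** 2))

    g = {k: np.zeros_like(v) for k, v in w.arrays().items()}
    dY = 2.0 * err / n_total  # [B,T]
    g["w_out"] = np.einsum("bt,bth->h", dY, h_drop)
    g["b_out"] = np.asarray(dY.sum())

    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        h_prev, c_prev, st = states[t]
        dh = dY[:, t][:, None] * w.w_out[None, :] * drop_mask[:, t, :] / keep_p
        dh = dh + dh_next
        do = dh * np.tanh(st.c)
        da_o = do * st.o * (1.0 - st.o)
        dc = dh * st.o * (1.0 - np.tanh(st.c) ** 2) + dc_next
        df = dc * c_prev
        da_f = df * st.f * (1.0 - st.f)
        di = dc * st.c_candidate
        da_i = di * st.i * (1.0 - st.i)
        dcc = dc * st.i
        da_c = dcc * (1.0 - st.c_candidate ** 2)
        dc_next = dc * st.f
        dh_next = (da_f @ w.W_f + da_i @ w.W_i + da_c @ w.W_c + da_o @ w.W_o)
        x_t = X[:, t, :]
        for gate, da in (("f", da_f), ("i", da_i), ("c", da_c), ("o", da_o)):
            g[f"U_{gate}"] += da.T @ x_t
            g[f"W_{gate}"] += da.T @ h_prev
            g[f"b_{gate}"] += da.sum(axis=0)
    return loss, g


class _Adam:
    def __init__(self, shapes: dict, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in shapes.items()}
        self.v = {k: np.zeros_like(v) for k, v in shapes.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> dict:
        self.t += 1
        out = {}
        for k, p in params.items():
            gk = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            out[k] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out


def _cut_windows(X: np.ndarray, y: np.ndarray, seq_len: int):
    """Non-overlapping windows of seq_len in temporal order."""
    T = X.shape[0]
    n_win = T // seq_len
    if n_win == 0:
        raise ValueError(
            f"training stream ({T} steps) shorter than one unroll window "
            f"({seq_len})")
    Xw = X[: n_win * seq_len].reshape(n_win, seq_len, X.shape[1])
    yw = y[: n_win * seq_len].reshape(n_win, seq_len)
    return Xw, yw


def train_lstm(X: np.ndarray, y: np.ndarray, cfg: LSTMConfig = LSTMConfig(),
               feature_names: tuple | None = None) -> LSTMModel:
    """Train the LSTM on a normalized feature stream.

    X is [T, input_size], y is [T] in normalized units.  Reproducible given
    cfg.seed: a single generator drives initialization, window shuffling
    and dropout masks in that order.
    """
    cfg.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != cfg.input_size:
        raise ValueError(f"X must be [T, {cfg.input_size}]")
    if X.shape[0] != y.size:
        raise ValueError("X and y lengths differ")

    rng = np.random.default_rng(cfg.seed)
    w = LSTMWeights.init(cfg.input_size, cfg.hidden_size, rng)
    model = LSTMModel(weights=w, config=cfg, feature_names=feature_names)
    if cfg.epochs == 0:
        return model

    Xw, yw = _cut_windows(X, y, cfg.seq_len)
    n_win = Xw.shape[0]
    keep_p = 1.0 - cfg.dropout_p
    opt = _Adam(w.arrays(), cfg.learning_rate)

    for _epoch in range(cfg.epochs):
        order = rng.permutation(n_win)
        epoch_losses = []
        for start in range(0, n_win, cfg.batch_size):
            idx = order[start: start + cfg.batch_size]
            Xb, yb = Xw[idx], yw[idx]
            if cfg.dropout_p > 0:
                mask = (rng.random(Xb.shape[:2] + (cfg.hidden_size,))
                        >= cfg.dropout_p).astype(float)
            else:
                mask = np.ones(Xb.shape[:2] + (cfg.hidden_size,))
            loss, grads = _bptt(Xb, yb, w, mask, keep_p)
            params = opt.step(w.arrays(), grads)
            for k, v in params.items():
                if k == "b_out":
                    w.b_out = float(v)
                else:
                    setattr(w, k, v)
            epoch_losses.append(loss)
        model.loss_history.append(float(np.mean(epoch_losses)))
    model.weights = w
    return model


def predict_lstm(model: LSTMModel, X: np.ndarray,
                 feature_names: tuple | None = None) -> np.ndarray:
    """Stateful unroll over the whole sequence; one normalized angle per step.

    If both the model and the call carry feature names, they must match the
    training layout exactly.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.zeros(0)
    if X.ndim != 2 or X.shape[1] != model.config.input_size:
        raise ValueError(f"X must be [T, {model.config.input_size}]")
    if (feature_names is not None and model.feature_names is not None
            and tuple(feature_names) != tuple(model.feature_names)):
        raise ValueError(
            "feature column layout differs from the one the model was "
            f"trained on: {tuple(feature_names)} != {tuple(model.feature_names)}")
    w = model.weights
    h = np.zeros(w.b_f.size)
    c = np.zeros(w.b_f.size)
    out = np.empty(X.shape[0])
    for t in range(X.shape[0]):
        st = lstm_cell_step(X[t], h, c, w)
        h, c = st.h, st.c
        out[t] = float(h @ w.w_out + w.b_out)
    return out


# ===========================================================================
# BPNN
# ===========================================================================

@dataclass
class BPNNConfig:
    n_input: int = 16
    n_hidden: int = 18
    n_output: int = 1
    learning_rate: float = 0.1
    goal_mse: float = 0.01
    max_epochs: int = 50_000
    momentum: float = 0.9
    output_activation: str = "sigmoid"  # printed formula; "linear" = purelin
    seed: int = 0

    def validate(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.output_activation not in ("sigmoid", "linear"):
            raise ValueError("output_activation must be 'sigmoid' or 'linear'")


@dataclass
class BPNNModel:
    W_in: np.ndarray   # [n_hidden, n_input]
    b_in: np.ndarray   # [n_hidden]
    W_out: np.ndarray  # [n_hidden]
    b_out: float
    config: BPNNConfig
    feature_names: tuple | None = None
    loss_history: list = field(default_factory=list)

    @staticmethod
    def init(cfg: BPNNConfig, rng: np.random.Generator) -> "BPNNModel":
        def u(shape, fan_in):
            bound = 1.0 / math.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape)
        return BPNNModel(W_in=u((cfg.n_hidden, cfg.n_input), cfg.n_input),
                         b_in=np.zeros(cfg.n_hidden),
                         W_out=u(cfg.n_hidden, cfg.n_hidden),
                         b_out=0.0, config=cfg)


def bpnn_forward(x: np.ndarray, model: BPNNModel) -> np.ndarray:
    """Network output for a single feature vector or an [n, n_input] batch."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != model.W_in.shape[1]:
        raise ValueError(
            f"input size {x.shape[1]} != {model.W_in.shape[1]}")
    z = _tansig(x @ model.W_in.T + model.b_in)
    u = z @ model.W_out
    if model.config.output_activation == "sigmoid":
        out = _sigmoid(u) + model.b_out
    else:
        out = u + model.b_out
    return float(out[0]) if single else out


def train_bpnn(X: np.ndarray, y: np.ndarray,
               cfg: BPNNConfig = BPNNConfig(),
               feature_names: tuple | None = None) -> BPNNModel:
    """Full-batch gradient descent with momentum; stops at goal_mse or
    max_epochs, whichever comes first."""
    cfg.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != cfg.n_input:
        raise ValueError(f"X must be [T, {cfg.n_input}]")
    if X.shape[0] != y.size:
        raise ValueError("X and y lengths differ")

    rng = np.random.default_rng(cfg.seed)
    model = BPNNModel.init(cfg, rng)
    model.feature_names = feature_names
    n = X.shape[0]
    vel = {"W_in": np.zeros_like(model.W_in), "b_in": np.zeros_like(model.b_in),
           "W_out": np.zeros_like(model.W_out), "b_out": 0.0}

    for _epoch in range(cfg.max_epochs):
        z = _tansig(X @ model.W_in.T + model.b_in)          # [n, H]
        u = z @ model.W_out                                  # [n]
        if cfg.output_activation == "sigmoid":
            s = _sigmoid(u)
            y_hat = s + model.b_out
            du_factor = s * (1.0 - s)
        else:
            y_hat = u + model.b_out
            du_factor = np.ones_like(u)
        err = y_hat - y
        mse = float(np.mean(err ** 2))
        model.loss_history.append(mse)
        if mse <= cfg.goal_mse:
            break
        dY = 2.0 * err / n
        du = dY * du_factor
        g_Wout = du @ z
        g_bout = float(dY.sum())
        dz = du[:, None] * model.W_out[None, :]
        da = dz * (1.0 - z ** 2)  # tansig' = 1 - tansig^2
        g_Win = da.T @ X
        g_bin = da.sum(axis=0)

        for key, grad in (("W_in", g_Win), ("b_in", g_bin),
                          ("W_out", g_Wout), ("b_out", g_bout)):
            vel[key] = cfg.momentum * vel[key] - cfg.learning_rate * grad
            if key == "b_out":
                model.b_out += vel[key]
            else:
                setattr(model, key, getattr(model, key) + vel[key])
    return model


def predict_bpnn(model: BPNNModel, X: np.ndarray,
                 feature_names: tuple | None = None) -> np.ndarray:
    if (feature_names is not None and model.feature_names is not None
            and tuple(feature_names) != tuple(model.feature_names)):
        raise ValueError("feature column layout differs from training")
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.zeros(0)
    return bpnn_forward(X, model)


# ---------------------------------------------------------------------------
# Hidden-unit selection for the BPNN
# ---------------------------------------------------------------------------

#: Default scan range: the union of the empirical-rule candidates below,
#: widened to cover larger hidden layers (up to 26) that the rules miss.
DEFAULT_HIDDEN_CANDIDATES = tuple(range(4, 27))


def hidden_unit_candidates(n_input: int = 16, n_output: int = 1,
                           a_range: tuple = (1, 10)) -> tuple:
    """Candidate hidden-layer sizes from the classical empirical rules.

    Rule 1: n1 = sqrt(n + m) + a for an integer constant a in ``a_range``
    (the square root is taken to its floor).  Rule 2: n1 = log2(n).  The
    returned tuple is the sorted union.
    """
    root = math.floor(math.sqrt(n_input + n_output))
    cands = {root + a for a in range(a_range[0], a_range[1] + 1)}
    if n_input > 1:
        cands.add(round(math.log2(n_input)))
    return tuple(sorted(cands))


def select_hidden_units(X_train, y_train, X_val, y_val,
                        candidates=DEFAULT_HIDDEN_CANDIDATES,
                        base_config: BPNNConfig = BPNNConfig()) -> tuple:
    """Scan candidate hidden sizes; return (best_n_hidden, {n: val_mse}).

    The winner minimizes validation MSE; ties break toward fewer units.
    """
    candidates = tuple(candidates)
    if not candidates:
        raise ValueError("empty candidate set")
    scores = {}
    for n_h in sorted(candidates):
        cfg = replace(base_config, n_hidden=int(n_h))
        model = train_bpnn(X_train, y_train, cfg)
        pred = predict_bpnn(model, X_val)
        scores[int(n_h)] = float(np.mean((pred - np.asarray(y_val).ravel()) ** 2))
    best = min(sorted(scores), key=lambda n: scores[n])
    return best, scores
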