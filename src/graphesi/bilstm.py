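"""Bidirectional LSTM sequence regressor, implemented on NumPy.

The inverse mapping learned here goes from multichannel EEG sequences
(n channels x T samples) to low-band graph Fourier coefficient sequences
(k x T).  A forward-time and a backward-time LSTM scan the sequence; their
hidden states at each time step are concatenated and passed through a dense
output layer.  Training minimizes mean squared error with the Nadam
optimizer (Adam with Nesterov momentum), full backpropagation through time,
mini-batches, and early stopping on validation loss.

Gate equations for one LSTM step, with ``[h, x]`` the concatenation of the
previous hidden state and the current input::

    f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)        forget gate
    i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)        input gate
    g_t = tanh   (W_c [h_{t-1}, x_t] + b_c)        candidate state
    c_t = f_t * c_{t-1} + i_t * g_t                memory cell
    o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)        output gate
    h_t = o_t * tanh(c_t)

and the bidirectional output ``y_t = act(W_s [h_t (+) h'_t] + b_s)`` where
``h'_t`` is the backward-scan state aligned to time ``t``.  The output
activation is identity by default: graph Fourier coefficients are signed
and unbounded, so a squashing nonlinearity cannot represent them (a sigmoid
variant is retained as an option).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "LSTMCellParams",
    "BiLSTMModel",
    "Standardizer",
    "lstm_cell_step",
    "bilstm_forward",
    "mse_loss",
    "BiLSTMRegressor",
    "count_parameters",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class LSTMCellParams:
    """Weights of one LSTM direction.

    Each ``W_*`` is (hidden, hidden + input), acting on the concatenation
    ``[h_{t-1}, x_t]`` (hidden part first); each ``b_*`` has length hidden.
    """

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        h = self.W_f.shape[0]
        cols = self.W_f.shape[1]
        for name in ("W_i", "W_c", "W_o"):
            if getattr(self, name).shape != (h, cols):
                raise ValueError(f"{name} shape mismatch")
        for name in ("b_f", "b_i", "b_c", "b_o"):
            if getattr(self, name).shape != (h,):
                raise ValueError(f"{name} shape mismatch")
        for name in ("W_f", "W_i", "W_c", "W_o", "b_f", "b_i", "b_c", "b_o"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} has non-finite entries")

    @property
    def hidden(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_f.shape[1] - self.W_f.shape[0]

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """(hidden+input, 4*hidden) weight and (4*hidden,) bias, gate order
        f, i, c, o — the layout used by the vectorized scan."""
        w = np.concatenate([self.W_f, self.W_i, self.W_c, self.W_o], axis=0).T
        b = np.concatenate([self.b_f, self.b_i, self.b_c, self.b_o])
        return np.ascontiguousarray(w), b

    @classmethod
    def from_stacked(cls, w: np.ndarray, b: np.ndarray) -> "LSTMCellParams":
        h = w.shape[1] // 4
        wt = w.T
        return cls(
            W_f=wt[0 * h : 1 * h], W_i=wt[1 * h : 2 * h],
            W_c=wt[2 * h : 3 * h], W_o=wt[3 * h : 4 * h],
            b_f=b[0 * h : 1 * h], b_i=b[1 * h : 2 * h],
            b_c=b[2 * h : 3 * h], b_o=b[3 * h : 4 * h],
        )


def lstm_cell_step(
    cell: LSTMCellParams,
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM step on vectors (reference implementation used by tests and
    by the vectorized scan's contract)."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    if x_t.shape[-1] != cell.input_dim or h_prev.shape[-1] != cell.hidden:
        raise ValueError(
            f"expected input {cell.input_dim} and hidden {cell.hidden}, got "
            f"{x_t.shape[-1]} and {h_prev.shape[-1]}"
        )
    hx = np.concatenate([h_prev, x_t], axis=-1)
    f = _sigmoid(hx @ cell.W_f.T + cell.b_f)
    i = _sigmoid(hx @ cell.W_i.T + cell.b_i)
    g = np.tanh(hx @ cell.W_c.T + cell.b_c)
    c_t = f * c_prev + i * g
    o = _sigmoid(hx @ cell.W_o.T + cell.b_o)
    h_t = o * np.tanh(c_t)
    return h_t, c_t


@dataclass
class BiLSTMModel:
    """Weights of the bidirectional regressor."""

    forward_cell: LSTMCellParams
    backward_cell: LSTMCellParams
    W_s: np.ndarray  # (k_out, 2*hidden)
    b_s: np.ndarray  # (k_out,)
    output_activation: str = "identity"  # or "sigmoid"

    def __post_init__(self) -> None:
        if self.output_activation not in ("identity", "sigmoid"):
            raise ValueError("output_activation must be 'identity' or 'sigmoid'")
        if self.forward_cell.hidden != self.backward_cell.hidden:
            raise ValueError("forward/backward hidden sizes differ")
        if self.W_s.shape[1] != 2 * self.forward_cell.hidden:
            raise ValueError("W_s must act on the 2*hidden concatenation")
        if self.b_s.shape != (self.W_s.shape[0],):
            raise ValueError("b_s length mismatch")

    @property
    def input_dim(self) -> int:
        return self.forward_cell.input_dim

    @property
    def hidden(self) -> int:
        return self.forward_cell.hidden

    @property
    def k_out(self) -> int:
        return self.W_s.shape[0]


def count_parameters(model: BiLSTMModel) -> dict[str, int]:
    """Parameter counts; the output layer shrinks by m/k when regressing
    low-band coefficients instead of full source maps."""
    cell = sum(
        getattr(model.forward_cell, name).size
        for name in ("W_f", "W_i", "W_c", "W_o", "b_f", "b_i", "b_c", "b_o")
    )
    out = model.W_s.size + model.b_s.size
    return {"per_cell": cell, "recurrent": 2 * cell, "output": out,
            "total": 2 * cell + out}


def _scan(
    w: np.ndarray, b: np.ndarray, x: np.ndarray, reverse: bool
) -> dict[str, np.ndarray]:
    """Vectorized LSTM scan over a batch.

    ``x`` is (B, T, n); returns cached gate activations and states, each
    (B, T, H), in the original time order.
    """
    B, T, n = x.shape
    H = w.shape[1] // 4
    wh = w[:H]  # (H, 4H)
    wx = w[H:]  # (n, 4H)
    xp = x @ wx + b  # (B, T, 4H), input projection for every step at once
    f = np.empty((B, T, H), dtype=x.dtype)
    i = np.empty_like(f)
    g = np.empty_like(f)
    o = np.empty_like(f)
    c = np.empty_like(f)
    tanh_c = np.empty_like(f)
    h = np.empty_like(f)
    h_t = np.zeros((B, H), dtype=x.dtype)
    c_t = np.zeros((B, H), dtype=x.dtype)
    steps = range(T - 1, -1, -1) if reverse else range(T)
    for t in steps:
        z = xp[:, t] + h_t @ wh
        f_t = _sigmoid(z[:, :H])
        i_t = _sigmoid(z[:, H : 2 * H])
        g_t = np.tanh(z[:, 2 * H : 3 * H])
        o_t = _sigmoid(z[:, 3 * H :])
        c_t = f_t * c_t + i_t * g_t
        th = np.tanh(c_t)
        h_t = o_t * th
        f[:, t], i[:, t], g[:, t], o[:, t] = f_t, i_t, g_t, o_t
        c[:, t], tanh_c[:, t], h[:, t] = c_t, th, h_t
    return {"f": f, "i": i, "g": g, "o": o, "c": c, "tanh_c": tanh_c, "h": h}


def _scan_backprop(
    w: np.ndarray,
    x: np.ndarray,
    cache: dict[str, np.ndarray],
    dh_out: np.ndarray,
    reverse: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """BPTT through one direction; returns (dW stacked, db)."""
    B, T, n = x.shape
    H = w.shape[1] // 4
    wh = w[:H]
    f, i, g, o = cache["f"], cache["i"], cache["g"], cache["o"]
    c, tanh_c, h = cache["c"], cache["tanh_c"], cache["h"]
    dz_all = np.empty((B, T, 4 * H), dtype=x.dtype)
    dh_next = np.zeros((B, H), dtype=x.dtype)
    dc_next = np.zeros((B, H), dtype=x.dtype)
    # walk time in the opposite order of the forward scan
    steps = range(T) if reverse else range(T - 1, -1, -1)
    first = T - 1 if reverse else 0
    for t in steps:
        dh = dh_out[:, t] + dh_next
        do = dh * tanh_c[:, t]
        dc = dc_next + dh * o[:, t] * (1.0 - tanh_c[:, t] ** 2)
        if t == first:
            c_prev = np.zeros((B, H), dtype=x.dtype)
        else:
            c_prev = c[:, t + 1] if reverse else c[:, t - 1]
        df = dc * c_prev
        di = dc * g[:, t]
        dg = dc * i[:, t]
        dz = np.concatenate(
            [
                df * f[:, t] * (1.0 - f[:, t]),
                di * i[:, t] * (1.0 - i[:, t]),
                dg * (1.0 - g[:, t] ** 2),
                do * o[:, t] * (1.0 - o[:, t]),
            ],
            axis=1,
        )
        dz_all[:, t] = dz
        dh_next = dz @ wh.T
        dc_next = dc * f[:, t]
    # h_prev sequence aligned with each step's input
    h_prev = np.zeros_like(h)
    if reverse:
        h_prev[:, :-1] = h[:, 1:]
    else:
        h_prev[:, 1:] = h[:, :-1]
    dz_flat = dz_all.reshape(B * T, 4 * H)
    dwh = h_prev.reshape(B * T, H).T @ dz_flat
    dwx = x.reshape(B * T, n).T @ dz_flat
    dw = np.concatenate([dwh, dwx], axis=0)
    db = dz_flat.sum(axis=0)
    return dw, db


def bilstm_forward(model: BiLSTMModel, x: np.ndarray) -> np.ndarray:
    """Run the bidirectional regressor on one sequence (n, T) or a batch
    (B, n, T); returns (k, T) or (B, k, T)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.shape[2] == 0:
        raise ValueError("empty sequence")
    if x.shape[1] != model.input_dim:
        raise ValueError(
            f"input has {x.shape[1]} channels, model expects {model.input_dim}"
        )
    xt = np.ascontiguousarray(x.transpose(0, 2, 1))  # (B, T, n)
    wf, bf = model.forward_cell.stacked()
    wb, bb = model.backward_cell.stacked()
    h_fwd = _scan(wf, bf, xt, reverse=False)["h"]
    h_bwd = _scan(wb, bb, xt, reverse=True)["h"]
    h_cat = np.concatenate([h_fwd, h_bwd], axis=2)  # (B, T, 2H)
    y = h_cat @ model.W_s.T + model.b_s  # (B, T, k)
    if model.output_activation == "sigmoid":
        y = _sigmoid(y)
    y = y.transpose(0, 2, 1)
    return y[0] if single else y


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean of squared elementwise differences over all entries."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    return float(np.mean((pred - target) ** 2))


@dataclass
class Standardizer:
    """Channel-wise centering with per-channel or global scaling.

    ``scaling="per_channel"`` divides each channel by its own standard
    deviation; ``"global"`` divides all channels by one pooled standard
    deviation, preserving the relative magnitudes between channels (the
    right choice for graph Fourier coefficient targets, whose relative
    weighting carries the spatial pattern).  Channels with zero variance
    keep scale 1 and are flagged in ``zero_variance``.
    """

    mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    std: np.ndarray = field(default_factory=lambda: np.ones(0))
    zero_variance: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    scaling: str = "per_channel"

    def fit(self, x: np.ndarray) -> "Standardizer":
        """``x``: (trials, channels, T)."""
        flat = np.asarray(x, dtype=float).transpose(1, 0, 2).reshape(x.shape[1], -1)
        self.mean = flat.mean(axis=1)
        if self.scaling == "global":
            pooled = float((flat - self.mean[:, None]).std())
            std = np.full(x.shape[1], pooled if pooled > 0 else 1.0)
        elif self.scaling == "per_channel":
            std = flat.std(axis=1)
        else:
            raise ValueError("scaling must be 'per_channel' or 'global'")
        self.zero_variance = std == 0
        std = np.where(self.zero_variance, 1.0, std)
        self.std = std
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean[:, None]) / self.std[:, None]

    def inverse_transform(self, x: np.ndarray) -> np.ndarray:
        return x * self.std[:, None] + self.mean[:, None]


class _Nadam:
    """Nadam: Adam with Nesterov momentum (incorporates the lookahead
    momentum term into the parameter update)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1 = beta1
        self.b2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads) -> None:
        self.t += 1
        b1, b2, t = self.b1, self.b2, self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = b1 * m / (1 - b1 ** (t + 1)) + (1 - b1) * g / (1 - b1**t)
            v_hat = v / (1 - b2**t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class BiLSTMRegressor(RegressorMixin, BaseEstimator):
    """Sequence-to-sequence BiLSTM regressor (scikit-learn style).

    Maps EEG trials ``X`` of shape (n_trials, n_channels, T) to coefficient
    trials ``Y`` of shape (n_trials, k, T).  Inputs and targets are
    standardized per channel on the training data by default.

    Parameters
    ----------
    hidden_size : int, default 256
        Concatenated bidirectional state size; each direction uses
        ``hidden_size // 2`` units.  Set ``hidden_per_direction=True`` to
        interpret it per direction instead.
    epochs : int, default 200
        Maximum training epochs.
    batch_size : int, default 32
    learning_rate : float, default 1e-3
    patience : int, default 20
        Early-stopping patience on validation MSE; the returned weights are
        those of the best validation epoch.
    lr_decay : float, default 0.5
        Multiplier applied to the learning rate after ``lr_patience`` epochs
        without validation improvement (set to 1.0 to disable).
    lr_patience : int, default 6
    output_activation : {"identity", "sigmoid"}, default "identity"
    standardize : bool, default True
        Standardize inputs per channel and center/scale targets.
    target_scaling : {"global", "per_feature"}, default "global"
        How targets are scaled when ``standardize`` is on: one pooled scale
        for all coefficients (preserves their relative weighting, matching
        a raw-units MSE objective) or one scale per coefficient.
    random_state : int, default 0
        Seeds weight initialization and batch shuffling.
    """

    def __init__(
        self,
        hidden_size: int = 256,
        epochs: int = 200,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        patience: int = 20,
        lr_decay: float = 0.5,
        lr_patience: int = 6,
        output_activation: str = "identity",
        standardize: bool = True,
        target_scaling: str = "global",
        hidden_per_direction: bool = False,
        random_state: int = 0,
    ):
        self.hidden_size = hidden_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.lr_decay = lr_decay
        self.lr_patience = lr_patience
        self.output_activation = output_activation
        self.standardize = standardize
        self.target_scaling = target_scaling
        self.hidden_per_direction = hidden_per_direction
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _hidden_each(self) -> int:
        if self.hidden_per_direction:
            return int(self.hidden_size)
        if self.hidden_size % 2:
            raise ValueError("hidden_size must be even (concatenated size)")
        return int(self.hidden_size) // 2

    def _init_params(self, n: int, k: int, rng: np.random.Generator):
        H = self._hidden_each()
        def glorot(rows, cols):
            lim = np.sqrt(6.0 / (rows + cols))
            return rng.uniform(-lim, lim, size=(rows, cols)).astype(np.float32)

        params = []
        for _ in range(2):  # forward, backward
            w = np.concatenate(
                [glorot(H + n, H) for _ in range(4)], axis=1
            )  # (H+n, 4H), gates f,i,c,o
            b = np.zeros(4 * H, dtype=np.float32)
            b[:H] = 1.0  # forget-gate bias: remember by default
            params.extend([w, b])
        params.append(glorot(k, 2 * H))  # W_s
        params.append(np.zeros(k, dtype=np.float32))  # b_s
        return params

    def _forward_batch(self, params, xt):
        """xt: (B, T, n) standardized. Returns (pred (B,T,k), caches)."""
        wf, bf, wb, bb, ws, bs = params
        cf = _scan(wf, bf, xt, reverse=False)
        cb = _scan(wb, bb, xt, reverse=True)
        h_cat = np.concatenate([cf["h"], cb["h"]], axis=2)
        y = h_cat @ ws.T + bs
        if self.output_activation == "sigmoid":
            y = _sigmoid(y)
        return y, (cf, cb, h_cat)

    def _backward_batch(self, params, xt, caches, dy):
        """dy: (B, T, k) gradient of loss wrt pre/post-activation output."""
        wf, bf, wb, bb, ws, bs = params
        cf, cb, h_cat = caches
        B, T, _ = xt.shape
        H = ws.shape[1] // 2
        flat_h = h_cat.reshape(B * T, 2 * H)
        flat_dy = dy.reshape(B * T, -1)
        dws = flat_dy.T @ flat_h
        dbs = flat_dy.sum(axis=0)
        dh_cat = (flat_dy @ ws).reshape(B, T, 2 * H)
        dwf, dbf = _scan_backprop(wf, xt, cf, dh_cat[:, :, :H], reverse=False)
        dwb, dbb = _scan_backprop(wb, xt, cb, dh_cat[:, :, H:], reverse=True)
        return [dwf, dbf, dwb, dbb, dws, dbs]

    # -- estimator API -----------------------------------------------------

    def fit(self, X, Y, validation_data=None):
        """Train on trials ``X`` (n_trials, n, T) against targets ``Y``
        (n_trials, k, T); ``validation_data=(X_val, Y_val)`` drives early
        stopping (without it, the training loss is monitored instead)."""
        X = np.asarray(X, dtype=np.float32)
        Y = np.asarray(Y, dtype=np.float32)
        if X.ndim != 3 or Y.ndim != 3 or X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must be (n_trials, channels, T) with equal "
                             "trial counts")
        if X.shape[2] != Y.shape[2]:
            raise ValueError("X and Y must share the time dimension")
        n, k = X.shape[1], Y.shape[1]
        rng = np.random.default_rng(self.random_state)

        if self.standardize:
            self.input_scaler_ = Standardizer().fit(X)
            tscale = "global" if self.target_scaling == "global" else "per_channel"
            self.target_scaler_ = Standardizer(scaling=tscale).fit(Y)
        else:
            self.input_scaler_ = None
            self.target_scaler_ = None
        Xs = self._std_in(X)
        Ys = self._std_out(Y)
        if validation_data is not None:
            Xv = self._std_in(np.asarray(validation_data[0], dtype=np.float32))
            Yv = self._std_out(np.asarray(validation_data[1], dtype=np.float32))
        else:
            Xv = Yv = None

        params = self._init_params(n, k, rng)
        opt = _Nadam(params, lr=self.learning_rate)
        n_trials = X.shape[0]
        best_val = np.inf
        best_params = [p.copy() for p in params]
        since_best = 0
        history = []
        xt_all = np.ascontiguousarray(Xs.transpose(0, 2, 1))
        yt_all = np.ascontiguousarray(Ys.transpose(0, 2, 1))
        xv_t = None if Xv is None else np.ascontiguousarray(Xv.transpose(0, 2, 1))
        yv_t = None if Yv is None else np.ascontiguousarray(Yv.transpose(0, 2, 1))

        for epoch in range(self.epochs):
            order = rng.permutation(n_trials)
            train_losses = []
            for start in range(0, n_trials, self.batch_size):
                idx = order[start : start + self.batch_size]
                xt = xt_all[idx]
                yt = yt_all[idx]
                pred, caches = self._forward_batch(params, xt)
                diff = pred - yt
                loss = float(np.mean(diff**2))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) at epoch {epoch}"
                    )
                train_losses.append(loss)
                dy = (2.0 / diff.size) * diff
                if self.output_activation == "sigmoid":
                    dy = dy * pred * (1.0 - pred)
                grads = self._backward_batch(params, xt, caches, dy)
                opt.step(grads)
            train_mse = float(np.mean(train_losses))
            if xv_t is not None:
                val_mse = self._eval_loss(params, xv_t, yv_t)
            else:
                val_mse = train_mse
            history.append({"epoch": epoch, "train_mse": train_mse,
                            "val_mse": val_mse, "lr": opt.lr})
            if val_mse < best_val:
                best_val = val_mse
                best_params = [p.copy() for p in params]
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
                if (
                    self.lr_decay < 1.0
                    and since_best > 0
                    and since_best % self.lr_patience == 0
                ):
                    opt.lr *= self.lr_decay

        self.history_ = history
        self.best_val_mse_ = best_val
        self._params_ = best_params
        wf, bf, wb, bb, ws, bs = best_params
        self.model_ = BiLSTMModel(
            forward_cell=LSTMCellParams.from_stacked(
                np.asarray(wf, float), np.asarray(bf, float)
            ),
            backward_cell=LSTMCellParams.from_stacked(
                np.asarray(wb, float), np.asarray(bb, float)
            ),
            W_s=np.asarray(ws, float),
            b_s=np.asarray(bs, float),
            output_activation=self.output_activation,
        )
        return self

    def _eval_loss(self, params, xt, yt, chunk: int = 64) -> float:
        total = 0.0
        count = 0
        for start in range(0, xt.shape[0], chunk):
            pred, _ = self._forward_batch(params, xt[start : start + chunk])
            d = pred - yt[start : start + chunk]
            total += float(np.sum(d**2))
            count += d.size
        return total / count

    def _std_in(self, X):
        return X if self.input_scaler_ is None else np.stack(
            [self.input_scaler_.transform(x) for x in X]
        ).astype(np.float32)

    def _std_out(self, Y):
        return Y if self.target_scaler_ is None else np.stack(
            [self.target_scaler_.transform(y) for y in Y]
        ).astype(np.float32)

    def predict(self, X):
        """Predict coefficient sequences (n_trials, k, T) in original target
        units."""
        X = np.asarray(X, dtype=np.float32)
        single = X.ndim == 2
        if single:
            X = X[None]
        Xs = self._std_in(X)
        xt = np.ascontiguousarray(Xs.transpose(0, 2, 1))
        preds = []
        for start in range(0, xt.shape[0], 64):
            p, _ = self._forward_batch(self._params_, xt[start : start + 64])
            preds.append(p)
        pred = np.concatenate(preds, axis=0).transpose(0, 2, 1).astype(float)
        if self.target_scaler_ is not None:
            pred = np.stack([self.target_scaler_.inverse_transform(p) for p in pred])
        return pred[0] if single else pred
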