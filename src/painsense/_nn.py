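"""Compact numpy implementations of the 1-D CNN and stacked-LSTM classifiers.

Layers implement ``forward``/``backward`` with explicit caches; training uses
minibatch Adam on a softmax cross-entropy loss.  Everything is seeded through
one ``numpy.random.Generator`` per classifier (weight init, shuffling,
dropout masks), so runs are reproducible on a fixed platform.
"""

from __future__ import annotations

import numpy as np

from .exceptions import TrainingError


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer; ``params()`` yields (value, grad) array pairs."""

    def params(self):
        return []

    def forward(self, x, train, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = _glorot(rng, (d_in, d_out), d_in, d_out)
        self.b = np.zeros(d_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise TrainingError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Conv1D(Layer):
    """Valid-padding 1-D convolution over (batch, channels, length)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in, fan_out = c_in * kernel, c_out * kernel
        self.W = _glorot(rng, (c_in * kernel, c_out), fan_in, fan_out)
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train, rng):
        b, c, length = x.shape
        l_out = length - self.k + 1
        if l_out < 1:
            raise TrainingError(
                f"input length {length} shorter than kernel {self.k}"
            )
        windows = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=2)
        # (b, c, l_out, k) -> (b, l_out, c*k)
        cols = windows.transpose(0, 2, 1, 3).reshape(b, l_out, c * self.k)
        self._cols, self._in_shape = cols, x.shape
        out = cols @ self.W + self.b  # (b, l_out, c_out)
        return out.transpose(0, 2, 1)

    def backward(self, grad):
        b, _, l_out = grad.shape
        g = grad.transpose(0, 2, 1)  # (b, l_out, c_out)
        flat_g = g.reshape(-1, self.c_out)
        self.dW[...] = self._cols.reshape(-1, self.c_in * self.k).T @ flat_g
        self.db[...] = flat_g.sum(axis=0)
        dcols = g @ self.W.T  # (b, l_out, c_in*k)
        dcols = dcols.reshape(b, l_out, self.c_in, self.k).transpose(0, 2, 1, 3)
        dx = np.zeros(self._in_shape)
        for kk in range(self.k):
            dx[:, :, kk : kk + l_out] += dcols[:, :, :, kk]
        return dx


class MaxPool1D(Layer):
    def __init__(self, pool: int):
        self.p = pool

    def forward(self, x, train, rng):
        b, c, length = x.shape
        l_out = length // self.p
        self._in_shape = x.shape
        xt = x[:, :, : l_out * self.p].reshape(b, c, l_out, self.p)
        self._arg = xt.argmax(axis=3)
        return xt.max(axis=3)

    def backward(self, grad):
        b, c, l_out = grad.shape
        dxt = np.zeros((b, c, l_out, self.p))
        bi, ci, li = np.ogrid[:b, :c, :l_out]
        dxt[bi, ci, li, self._arg] = grad
        dx = np.zeros(self._in_shape)
        dx[:, :, : l_out * self.p] = dxt.reshape(b, c, l_out * self.p)
        return dx


class LSTM(Layer):
    """Single LSTM layer (tanh cell), returning the last hidden state or the
    full sequence; input is (batch, time, features)."""

    def __init__(self, d_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        h = units
        self.h = h
        self.return_sequences = return_sequences
        self.Wx = _glorot(rng, (d_in, 4 * h), d_in + h, 4 * h)
        self.Wh = _glorot(rng, (h, 4 * h), d_in + h, 4 * h)
        self.b = np.zeros(4 * h)
        self.b[h : 2 * h] = 1.0  # forget-gate bias
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.Wx, self.dWx), (self.Wh, self.dWh), (self.b, self.db)]

    def forward(self, x, train, rng):
        b, t_steps, _ = x.shape
        h = self.h
        hs = np.zeros((b, h))
        cs = np.zeros((b, h))
        self._x = x
        self._cache = []
        seq = np.empty((b, t_steps, h))
        for t in range(t_steps):
            z = x[:, t] @ self.Wx + hs @ self.Wh + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c_prev = cs
            cs = f * c_prev + i * g
            tc = np.tanh(cs)
            h_prev = hs
            hs = o * tc
            self._cache.append((i, f, g, o, c_prev, tc, h_prev))
            seq[:, t] = hs
        self._seq = seq
        return seq if self.return_sequences else hs

    def backward(self, grad):
        x = self._x
        b, t_steps, d_in = x.shape
        h = self.h
        self.dWx[...] = 0
        self.dWh[...] = 0
        self.db[...] = 0
        dx = np.zeros_like(x)
        dh_next = np.zeros((b, h))
        dc_next = np.zeros((b, h))
        for t in range(t_steps - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = self._cache[t]
            dh = dh_next + (grad[:, t] if self.return_sequences else 0)
            if not self.return_sequences and t == t_steps - 1:
                dh = dh + grad
            dc = dc_next + dh * o * (1 - tc * tc)
            di = dc * g * i * (1 - i)
            df = dc * c_prev * f * (1 - f)
            dg = dc * i * (1 - g * g)
            do = dh * tc * o * (1 - o)
            dz = np.concatenate([di, df, dg, do], axis=1)
            self.dWx += x[:, t].T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dx


class Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self, params):
        self.t += 1
        for value, grad in params:
            key = id(value)
            if key not in self._state:
                self._state[key] = (np.zeros_like(value), np.zeros_like(value))
            m, v = self._state[key]
            m += (1 - self.b1) * (grad - m)
            v += (1 - self.b2) * (grad * grad - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SequentialClassifier:
    """Minibatch-Adam training of a layer stack on softmax cross-entropy."""

    def __init__(self, lr: float = 1e-3, epochs: int = 10, batch_size: int = 32,
                 seed: int = 0):
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.layers: list[Layer] = []
        self.history: list[dict] = []

    # subclasses build the stack once the input shape is known
    def _build(self, input_shape: tuple[int, ...], n_classes: int,
               rng: np.random.Generator) -> list[Layer]:  # pragma: no cover
        raise NotImplementedError

    def _shape_input(self, X: np.ndarray) -> np.ndarray:
        return X

    def _forward(self, x, train, rng):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def fit(self, X: np.ndarray, y: np.ndarray, n_classes: int):
        rng = np.random.default_rng(self.seed)
        Xs = self._shape_input(np.asarray(X, dtype=np.float64))
        y = np.asarray(y, dtype=np.int64)
        if len(np.unique(y)) < 2:
            raise TrainingError("training labels contain a single class")
        self.n_classes = n_classes
        self.layers = self._build(Xs.shape[1:], n_classes, rng)
        opt = Adam(self.lr)
        n = Xs.shape[0]
        params = [p for layer in self.layers for p in layer.params()]
        self.history = []
        for ep in range(self.epochs):
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xs[idx], y[idx]
                logits = self._forward(xb, True, rng)
                probs = softmax(logits)
                eps = 1e-12
                losses.append(float(-np.log(probs[np.arange(len(yb)), yb] + eps).mean())
                              * len(yb))
                correct += int((probs.argmax(axis=1) == yb).sum())
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                grad = dlogits
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                opt.step(params)
            self.history.append(
                {"epoch": ep, "loss": sum(losses) / n, "accuracy": correct / n}
            )
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xs = self._shape_input(np.asarray(X, dtype=np.float64))
        out = []
        for start in range(0, Xs.shape[0], 512):
            logits = self._forward(Xs[start : start + 512], False, None)
            out.append(softmax(logits))
        return np.vstack(out)


class CNN1DClassifier(SequentialClassifier):
    """1-D CNN over the ordered feature vector.

    Convolution blocks (ReLU) each followed by max-pooling and dropout,
    then a flatten and two fully connected ReLU layers with their own
    dropout, ending in a softmax output.
    """

    def __init__(self, conv_filters=(32, 64), kernel_size=3, pool_size=2,
                 conv_dropout=0.25, dense_units=(128, 64),
                 dense_dropout=(0.5, 0.3), lr=9e-5, epochs=100,
                 batch_size=32, seed=0):
        super().__init__(lr=lr, epochs=epochs, batch_size=batch_size, seed=seed)
        self.conv_filters = tuple(conv_filters)
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.conv_dropout = conv_dropout
        self.dense_units = tuple(dense_units)
        self.dense_dropout = tuple(dense_dropout)

    def _shape_input(self, X):
        return X[:, None, :] if X.ndim == 2 else X  # (n, 1, d)

    def _build(self, input_shape, n_classes, rng):
        c, length = input_shape
        layers: list[Layer] = []
        for filters in self.conv_filters:
            layers += [Conv1D(c, filters, self.kernel_size, rng), ReLU()]
            length = length - self.kernel_size + 1
            layers.append(MaxPool1D(self.pool_size))
            length //= self.pool_size
            layers.append(Dropout(self.conv_dropout))
            c = filters
            if length < 1:
                raise TrainingError("input too short for the convolution stack")
        layers.append(Flatten())
        d = c * length
        for units, rate in zip(self.dense_units, self.dense_dropout):
            layers += [Dense(d, units, rng), ReLU(), Dropout(rate)]
            d = units
        layers.append(Dense(d, n_classes, rng))
        return layers


class LSTMClassifier(SequentialClassifier):
    """Stacked-LSTM classifier over a (time, features) view of each sample."""

    def __init__(self, lstm_units=(128, 64), lstm_dropout=0.3,
                 dense_units=(64,), seq_shape=None, n_channels=None,
                 lr=1e-3, epochs=100, batch_size=32, seed=0):
        super().__init__(lr=lr, epochs=epochs, batch_size=batch_size, seed=seed)
        self.lstm_units = tuple(lstm_units)
        self.lstm_dropout = lstm_dropout
        self.dense_units = tuple(dense_units)
        self.seq_shape = seq_shape
        self.n_channels = n_channels

    def _shape_input(self, X):
        if X.ndim == 3:
            return X
        n, d = X.shape
        if self.n_channels is not None:
            # channel-major feature rows folded into (band x statistic) steps
            # with one feature per channel at each step
            if d % self.n_channels:
                raise TrainingError(
                    f"{d} features not divisible by {self.n_channels} channels"
                )
            return X.reshape(n, self.n_channels, -1).transpose(0, 2, 1)
        if self.seq_shape is not None:
            t_steps, d_in = self.seq_shape
            if t_steps * d_in != d:
                raise TrainingError(
                    f"seq_shape {self.seq_shape} incompatible with {d} features"
                )
            return X.reshape(n, t_steps, d_in)
        return X.reshape(n, d, 1)  # fall back to one feature per step

    def _build(self, input_shape, n_classes, rng):
        _, d_in = input_shape
        layers: list[Layer] = []
        for j, units in enumerate(self.lstm_units):
            last = j == len(self.lstm_units) - 1
            layers.append(LSTM(d_in, units, rng, return_sequences=not last))
            layers.append(Dropout(self.lstm_dropout))
            d_in = units
        d = self.lstm_units[-1]
        for units in self.dense_units:
            layers += [Dense(d, units, rng), ReLU()]
            d = units
        layers.append(Dense(d, n_classes, rng))
        return layers
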