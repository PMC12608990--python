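"""A compact numpy Q-network: LSTM state encoder + dense head, trained with Adam.

The network scores a (state, action) pair: the state — a short window of
one-hot encoded daily selections — is folded through a single LSTM layer;
the final hidden vector is concatenated with the one-hot action encoding
and passed through one ReLU hidden layer to a scalar Q value. Gradients are
computed by standard backpropagation through time over the (short) window.
"""

from __future__ import annotations

import numpy as np


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTMQNetwork:
    """Q(s, a) with an LSTM over the state window and a dense head.

    Shapes: states ``(B, T, n_in)``, actions ``(B, n_action)``, output ``(B,)``.
    """

    def __init__(self, n_in: int, n_action: int, lstm_units: int = 32, hidden_units: int = 16,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng()
        self.n_in, self.n_action = n_in, n_action
        self.H, self.D = lstm_units, hidden_units
        H = lstm_units
        self.params: dict[str, np.ndarray] = {
            "Wx": _glorot(rng, n_in, 4 * H),
            "Wh": _glorot(rng, H, 4 * H),
            "b": np.zeros(4 * H),
            "W1": _glorot(rng, H + n_action, hidden_units),
            "b1": np.zeros(hidden_units),
            "W2": _glorot(rng, hidden_units, 1),
            "b2": np.zeros(1),
        }
        # forget-gate bias at 1 helps retain the short history from the start
        self.params["b"][H : 2 * H] = 1.0

    def copy(self) -> "LSTMQNetwork":
        clone = LSTMQNetwork.__new__(LSTMQNetwork)
        clone.n_in, clone.n_action = self.n_in, self.n_action
        clone.H, clone.D = self.H, self.D
        clone.params = {k: v.copy() for k, v in self.params.items()}
        return clone

    def sync_from(self, other: "LSTMQNetwork") -> None:
        for k in self.params:
            self.params[k][...] = other.params[k]

    # -- forward --------------------------------------------------------

    def forward(self, states: np.ndarray, actions: np.ndarray, cache: bool = False):
        """Q values for a batch; optionally return the cache for backward."""
        p = self.params
        B, T, _ = states.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(T):
            x = states[:, t, :]
            z = x @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tanh_c = np.tanh(c)
            h_prev = h
            h = o * tanh_c
            if cache:
                steps.append((x, h_prev, c_prev, i, f, g, o, tanh_c))
        u = np.concatenate([h, actions], axis=1)
        pre1 = u @ p["W1"] + p["b1"]
        l1 = np.maximum(pre1, 0.0)
        q = (l1 @ p["W2"] + p["b2"]).ravel()
        if not cache:
            return q
        return q, (steps, u, l1)

    # -- backward -------------------------------------------------------

    def mse_gradients(self, states: np.ndarray, actions: np.ndarray, targets: np.ndarray,
                      dropout_rate: float = 0.0, rng: np.random.Generator | None = None):
        """Loss ``mean((q - y)^2) / 2`` and its gradients w.r.t. all parameters.

        ``dropout_rate`` applies inverted dropout to the hidden dense layer
        during this training pass only (inference is always deterministic).
        """
        p = self.params
        H = self.H
        B = states.shape[0]
        q, (steps, u, l1) = self.forward(states, actions, cache=True)
        mask = None
        if dropout_rate > 0.0:
            if rng is None:
                raise ValueError("dropout requires an rng")
            mask = (rng.random(l1.shape) >= dropout_rate) / (1.0 - dropout_rate)
            l1 = l1 * mask
            q = (l1 @ p["W2"] + p["b2"]).ravel()
        err = q - targets
        loss = 0.5 * float(np.mean(err**2))
        dq = (err / B)[:, None]  # (B, 1)

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["W2"] = l1.T @ dq
        grads["b2"] = dq.sum(axis=0)
        dl1 = dq @ p["W2"].T
        if mask is not None:
            dl1 = dl1 * mask
        dl1[l1 <= 0] = 0.0
        grads["W1"] = u.T @ dl1
        grads["b1"] = dl1.sum(axis=0)
        du = dl1 @ p["W1"].T
        dh = du[:, :H]
        dc = np.zeros_like(dh)
        for x, h_prev, c_prev, i, f, g, o, tanh_c in reversed(steps):
            do = dh * tanh_c
            dct = dh * o * (1.0 - tanh_c**2) + dc
            di = dct * g
            df = dct * c_prev
            dg = dct * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            grads["Wx"] += x.T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dh = dz @ p["Wh"].T
            dc = dct * f
        return loss, grads


class Adam:
    """Adam optimizer over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
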