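"""Long short-term memory network implemented from its gate equations.

The cell follows the standard formulation

    f_t = σ(W_f x_t + U_f h_{t−1} + b_f)        forget gate
    i_t = σ(W_i x_t + U_i h_{t−1} + b_i)        input gate
    o_t = σ(W_o x_t + U_o h_{t−1} + b_o)        output gate
    c̄_t = φ(W_c x_t + U_c h_{t−1} + b_c)        candidate (modulation) state
    c_t = i_t ⊙ c̄_t + f_t ⊙ c_{t−1}
    h_t = o_t ⊙ tanh(c_t)

with φ = tanh by default (``candidate_activation="sigmoid"`` switches to a
logistic candidate for fidelity experiments).  The terminal hidden state
feeds a dense softmax readout; training minimizes categorical
cross-entropy E_t = −y_t log ȳ_t with the Adam optimizer, gradients by
backpropagation through time.  Everything is plain NumPy in float64 and
deterministic given a seed; gradients are validated against central
finite differences in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_EPS = 1e-12  # probability clip in the cross-entropy

# packed gate order along the last weight axis
_GATES = ("f", "i", "o", "c")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LSTMParams:
    """Gate weights packed as (features, 4H) / (H, 4H) in f,i,o,c order."""

    wx: np.ndarray      # input weights, (F, 4H)
    wh: np.ndarray      # recurrent weights, (H, 4H)
    b: np.ndarray       # gate biases, (4H,)
    v: np.ndarray       # readout weights, (H, C)
    b_y: np.ndarray     # readout bias, (C,)
    classes: np.ndarray  # class labels in readout order
    candidate_activation: str = "tanh"

    def __post_init__(self) -> None:
        h = self.hidden_size
        if self.wx.shape[1] != 4 * h or self.b.shape != (4 * h,):
            raise ValueError("inconsistent packed gate shapes")
        if self.v.shape[0] != h or self.v.shape[1] != len(self.classes):
            raise ValueError("inconsistent readout shapes")
        if self.candidate_activation not in ("tanh", "sigmoid"):
            raise ValueError("candidate_activation must be 'tanh' or 'sigmoid'")

    @property
    def hidden_size(self) -> int:
        return self.wh.shape[0]

    @property
    def n_features(self) -> int:
        return self.wx.shape[0]

    def _gate(self, which: str, mat: str) -> np.ndarray:
        h = self.hidden_size
        k = _GATES.index(which)
        return getattr(self, mat)[..., k * h : (k + 1) * h]

    # unpacked views named after the classic equations
    @property
    def w_f(self): return self._gate("f", "wx")
    @property
    def w_i(self): return self._gate("i", "wx")
    @property
    def w_o(self): return self._gate("o", "wx")
    @property
    def w_c(self): return self._gate("c", "wx")
    @property
    def u_f(self): return self._gate("f", "wh")
    @property
    def u_i(self): return self._gate("i", "wh")
    @property
    def u_o(self): return self._gate("o", "wh")
    @property
    def u_c(self): return self._gate("c", "wh")
    @property
    def b_f(self): return self._gate("f", "b")
    @property
    def b_i(self): return self._gate("i", "b")
    @property
    def b_o(self): return self._gate("o", "b")
    @property
    def b_c(self): return self._gate("c", "b")

    def flat(self) -> list[np.ndarray]:
        return [self.wx, self.wh, self.b, self.v, self.b_y]


def init_params(
    n_features: int,
    hidden_size: int,
    classes: np.ndarray,
    seed: int = 0,
    scale: float = 0.1,
    candidate_activation: str = "tanh",
) -> LSTMParams:
    """Small-Gaussian initialization with a +1 forget-gate bias."""
    rng = np.random.default_rng(seed)
    h = hidden_size
    p = LSTMParams(
        wx=rng.normal(0, scale, (n_features, 4 * h)),
        wh=rng.normal(0, scale, (h, 4 * h)),
        b=np.zeros(4 * h),
        v=rng.normal(0, scale, (h, len(classes))),
        b_y=np.zeros(len(classes)),
        classes=np.asarray(classes),
        candidate_activation=candidate_activation,
    )
    p.b[: h] = 1.0  # forget-gate bias: remember by default
    return p


def zero_params(
    n_features: int, hidden_size: int, classes: np.ndarray
) -> LSTMParams:
    """All-zero parameters (used by the degeneracy oracle)."""
    h = hidden_size
    return LSTMParams(
        wx=np.zeros((n_features, 4 * h)),
        wh=np.zeros((h, 4 * h)),
        b=np.zeros(4 * h),
        v=np.zeros((h, len(classes))),
        b_y=np.zeros(len(classes)),
        classes=np.asarray(classes),
    )


def lstm_forward(
    x_seq: np.ndarray,
    params: LSTMParams,
    h0: np.ndarray | None = None,
    c0: np.ndarray | None = None,
    *,
    return_cache: bool = False,
):
    """Run the cell over a batch of sequences.

    Parameters
    ----------
    x_seq
        (batch, T, features) — a single (T, features) sequence is promoted.

    Returns
    -------
    h_seq, c_seq, probs
        Hidden and cell state sequences, (batch, T, H) each, and the
        softmax class probabilities (batch, C) from the terminal hidden
        state.  With ``return_cache`` a dict of per-step intermediates is
        appended for backpropagation.
    """
    x = np.asarray(x_seq, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    nb, t_steps, nf = x.shape
    if nf != params.n_features:
        raise ValueError(f"expected {params.n_features} features, got {nf}")
    hsz = params.hidden_size
    h = np.zeros((nb, hsz)) if h0 is None else np.array(h0, float)
    c = np.zeros((nb, hsz)) if c0 is None else np.array(c0, float)
    cand_tanh = params.candidate_activation == "tanh"

    h_seq = np.empty((nb, t_steps, hsz))
    c_seq = np.empty((nb, t_steps, hsz))
    cache = {"f": [], "i": [], "o": [], "g": [], "c_prev": [], "tanh_c": [], "h_prev": []}
    for t in range(t_steps):
        z = x[:, t] @ params.wx + h @ params.wh + params.b
        f = _sigmoid(z[:, :hsz])
        i = _sigmoid(z[:, hsz : 2 * hsz])
        o = _sigmoid(z[:, 2 * hsz : 3 * hsz])
        g_pre = z[:, 3 * hsz :]
        g = np.tanh(g_pre) if cand_tanh else _sigmoid(g_pre)
        if return_cache:
            cache["c_prev"].append(c)
            cache["h_prev"].append(h)
        c = i * g + f * c
        tc = np.tanh(c)
        h = o * tc
        if not np.all(np.isfinite(h)):
            raise FloatingPointError(f"non-finite activations at step {t}")
        h_seq[:, t] = h
        c_seq[:, t] = c
        if return_cache:
            for k, val in zip(("f", "i", "o", "g", "tanh_c"), (f, i, o, g, tc)):
                cache[k].append(val)

    logits = h @ params.v + params.b_y
    logits -= logits.max(axis=1, keepdims=True)
    ez = np.exp(logits)
    probs = ez / ez.sum(axis=1, keepdims=True)
    if single and not return_cache:
        return h_seq[0], c_seq[0], probs[0]
    if return_cache:
        cache["x"] = x
        return h_seq, c_seq, probs, cache
    return h_seq, c_seq, probs


def lstm_loss(probs: np.ndarray, y_idx: np.ndarray) -> float:
    """Mean categorical cross-entropy −log p(true class) over a batch."""
    p = np.atleast_2d(probs)
    idx = np.atleast_1d(y_idx)
    picked = p[np.arange(len(idx)), idx]
    n_clipped = int((picked < _EPS).sum())
    if n_clipped:
        logger.info("lstm_loss: clipped %d zero probabilities at eps=%g", n_clipped, _EPS)
    return float(-np.mean(np.log(np.clip(picked, _EPS, None))))


def lstm_backward(
    params: LSTMParams,
    cache: dict,
    probs: np.ndarray,
    y_idx: np.ndarray,
    sample_weight: np.ndarray | None = None,
):
    """Backpropagation through time; returns gradients in ``flat()`` order."""
    x = cache["x"]
    nb, t_steps, _ = x.shape
    hsz = params.hidden_size
    cand_tanh = params.candidate_activation == "tanh"

    dlogits = probs.copy()
    dlogits[np.arange(nb), y_idx] -= 1.0
    dlogits /= nb
    if sample_weight is not None:
        dlogits *= np.asarray(sample_weight, float)[:, None]
    h_last = cache["o"][-1] * cache["tanh_c"][-1]
    dv = h_last.T @ dlogits
    db_y = dlogits.sum(axis=0)
    dh = dlogits @ params.v.T
    dc = np.zeros((nb, hsz))
    dwx = np.zeros_like(params.wx)
    dwh = np.zeros_like(params.wh)
    db = np.zeros_like(params.b)

    for t in range(t_steps - 1, -1, -1):
        f, i, o, g = (cache[k][t] for k in ("f", "i", "o", "g"))
        tc, c_prev, h_prev = cache["tanh_c"][t], cache["c_prev"][t], cache["h_prev"][t]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc**2)
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        dzf = df * f * (1.0 - f)
        dzi = di * i * (1.0 - i)
        dzo = do * o * (1.0 - o)
        dzg = dg * (1.0 - g**2) if cand_tanh else dg * g * (1.0 - g)
        dz = np.concatenate([dzf, dzi, dzo, dzg], axis=1)
        dwx += x[:, t].T @ dz
        dwh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh = dz @ params.wh.T
        dc = dc * f
    return [dwx, dwh, db, dv, db_y]


@dataclass
class TrainConfig:
    """Training conditions for the sequence model."""

    hidden_size: int = 16
    epochs: int = 50
    batch_size: int = 128
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    candidate_activation: str = "tanh"
    class_weighting: bool = False
    divergence_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be ≥ 1")


@dataclass
class FittedLSTM:
    """A trained network plus its per-epoch loss history."""

    params: LSTMParams
    loss_history: list[float]
    config: TrainConfig

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        _, _, probs = lstm_forward(X, self.params)
        return np.atleast_2d(probs)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.params.classes[np.argmax(self.predict_proba(X), axis=1)]


def train_lstm(X: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> FittedLSTM:
    """Fit the LSTM with Adam on (n, T, F) sequences and stage labels.

    Deterministic given ``cfg.seed`` (initialization and batch shuffling
    share one generator).  Aborts if the epoch loss exceeds
    ``divergence_factor`` times the initial loss.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) == 0:
        raise ValueError("empty training set")
    classes, y_idx = np.unique(y, return_inverse=True)
    rng = np.random.default_rng(cfg.seed)
    params = init_params(
        X.shape[2], cfg.hidden_size, classes,
        seed=int(rng.integers(2**31)), candidate_activation=cfg.candidate_activation,
    )
    weights = None
    if cfg.class_weighting:
        counts = np.bincount(y_idx, minlength=len(classes))
        weights = len(y) / (len(classes) * counts.astype(float))

    m = [np.zeros_like(p) for p in params.flat()]
    v = [np.zeros_like(p) for p in params.flat()]
    step = 0
    history: list[float] = []
    n = len(X)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            _, _, probs, cache = lstm_forward(X[sel], params, return_cache=True)
            losses.append(lstm_loss(probs, y_idx[sel]))
            sw = weights[y_idx[sel]] if weights is not None else None
            grads = lstm_backward(params, cache, probs, y_idx[sel], sample_weight=sw)
            step += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - cfg.beta2**step) / (1 - cfg.beta1**step)
            for k, (p, g) in enumerate(zip(params.flat(), grads)):
                m[k] = cfg.beta1 * m[k] + (1 - cfg.beta1) * g
                v[k] = cfg.beta2 * v[k] + (1 - cfg.beta2) * g**2
                p -= lr_t * m[k] / (np.sqrt(v[k]) + cfg.adam_eps)
        history.append(float(np.mean(losses)))
        if history[-1] > cfg.divergence_factor * history[0]:
            raise RuntimeError(
                f"training diverged at epoch {epoch}: loss {history[-1]:.4f} "
                f"vs initial {history[0]:.4f}"
            )
    return FittedLSTM(params=params, loss_history=history, config=cfg)
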