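"""Capsule network with dynamic routing and a margin loss.

Architecture: a ReLU convolutional stem, a capsule convolution producing
8-dimensional primary capsules, and one 16-dimensional class capsule per
class whose outputs are coupled to the primary layer by agreement routing.
A capsule output's Euclidean length (always in [0, 1) through the squash
nonlinearity) encodes the possibility that the input belongs to that class.

The loss is the two-sided margin objective
``L_p = T_p max(0, m+ - |v_p|)^2 + lambda (1 - T_p) max(0, |v_p| - m-)^2``
summed over class capsules, with ``m+ = 0.9``, ``m- = 0.1`` and
``lambda = 0.5``; there is no reconstruction regularizer.

The default stem (32 channels, kernel 5; primary capsules kernel 5, stride
2) is sized for the 12x12 mid-slices of the synthetic cohorts; the classic
large-image variant (256 channels, kernel 9, kernel-9 stride-2 primary
capsules) is reachable through the config.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .autodiff import Adam, Tensor, conv2d, softmax

__all__ = [
    "CapsNetConfig",
    "Prediction",
    "CapsNetClassifier",
    "squash",
    "route",
    "margin_loss",
]

_EPS = 1e-12


@dataclasses.dataclass
class CapsNetConfig:
    n_classes: int = 2
    conv1_channels: int = 32
    conv1_kernel: int = 5
    conv1_stride: int = 1
    primary_channels: int = 8  # capsule channels
    primary_dim: int = 8
    primary_kernel: int = 5
    primary_stride: int = 2
    class_dim: int = 16
    routing_iters: int = 3
    m_plus: float = 0.9
    m_minus: float = 0.1
    lambda_: float = 0.5
    epochs: int = 60
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    zscore: bool = True  # z-score each feature map within subject
    slices: str = "axial"  # {"axial", "triplanar"} mid-slice extraction

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.routing_iters < 1:
            raise ValueError("routing_iters must be >= 1")
        if not 0.0 < self.m_minus < self.m_plus < 1.0:
            raise ValueError("need 0 < m_minus < m_plus < 1")
        if self.slices not in ("axial", "triplanar"):
            raise ValueError("slices must be 'axial' or 'triplanar'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class Prediction:
    """Class-capsule lengths and the argmax class (ties -> lower index)."""

    class_scores: np.ndarray
    predicted_class: int


def squash(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """Capsule nonlinearity: keep direction, map norm to ``n^2 / (1 + n^2)``.

    The zero vector maps to itself; output norms lie in [0, 1).
    """
    s = np.asarray(s, dtype=np.float64)
    n2 = (s * s).sum(axis=axis, keepdims=True)
    scale = n2 / (1.0 + n2) / np.sqrt(n2 + _EPS)
    return s * scale


def _squash_t(s: Tensor, axis: int = -1) -> Tensor:
    n2 = (s * s).sum(axis=axis, keepdims=True)
    return s * (n2 / (n2 + 1.0)) * ((n2 + _EPS) ** -0.5)


def route(votes: np.ndarray, iters: int = 3, return_couplings: bool = False):
    """Dynamic agreement routing (forward only, numpy).

    ``votes``: (P, C, D) vote vectors from P input capsules toward C class
    capsules. Logits start at zero; each iteration the coupling coefficients
    are the per-input-capsule softmax of the logits, the class outputs are
    squashed coupling-weighted vote sums, and the logits grow by the
    vote-output agreement. Returns the (C, D) class outputs, plus the list of
    per-iteration coupling matrices when ``return_couplings`` is set.
    """
    votes = np.asarray(votes, dtype=np.float64)
    if votes.ndim != 3:
        raise ValueError("votes must be (n_input_capsules, n_classes, dim)")
    if iters < 1:
        raise ValueError("iters must be >= 1")
    P, C, D = votes.shape
    logits = np.zeros((P, C))
    couplings = []
    v = None
    for _ in range(iters):
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        c = e / e.sum(axis=1, keepdims=True)
        couplings.append(c.copy())
        s = (c[:, :, None] * votes).sum(axis=0)
        v = squash(s, axis=-1)
        logits = logits + (votes * v[None]).sum(axis=-1)
    if return_couplings:
        return v, couplings
    return v


def margin_loss(scores: np.ndarray, true_class: int, cfg: CapsNetConfig | None = None) -> float:
    """Margin loss of one score vector against the true class."""
    cfg = cfg or CapsNetConfig()
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 1:
        raise ValueError("scores must be a vector")
    if not 0 <= true_class < scores.size:
        raise ValueError(f"true_class {true_class} out of range")
    if scores.min() < 0.0 or scores.max() > 1.0:
        raise ValueError("scores must lie in [0, 1]")
    T = np.zeros(scores.size)
    T[true_class] = 1.0
    pos = np.maximum(0.0, cfg.m_plus - scores) ** 2
    neg = np.maximum(0.0, scores - cfg.m_minus) ** 2
    return float((T * pos + cfg.lambda_ * (1.0 - T) * neg).sum())


def _margin_loss_t(scores: Tensor, onehot: np.ndarray, cfg: CapsNetConfig) -> Tensor:
    """Mean margin loss over a batch (Tensor version used in training)."""
    T = Tensor(onehot)
    pos = (Tensor(cfg.m_plus) - scores).relu() ** 2
    neg = (scores - Tensor(cfg.m_minus)).relu() ** 2
    per_class = T * pos + cfg.lambda_ * (Tensor(1.0) - T) * neg
    return per_class.sum(axis=1).mean()


class CapsNetClassifier:
    """Fit/predict estimator around the capsule network.

    ``fit`` consumes an array ``X`` of shape (n, channels, H, W) and integer
    labels ``y``; training history (per-epoch mean loss and training
    accuracy) is kept on the instance and serialized with the parameters.
    """

    def __init__(self, config: CapsNetConfig | None = None):
        self.config = config or CapsNetConfig()
        self.params: dict[str, Tensor] | None = None
        self.history: list[dict] = []
        self.input_shape: tuple[int, int, int] | None = None
        self._n_primary: int | None = None

    # -- construction ------------------------------------------------------

    def _build(self, input_shape: tuple[int, int, int]) -> None:
        cfg = self.config
        C, H, W = input_shape
        h1 = (H - cfg.conv1_kernel) // cfg.conv1_stride + 1
        w1 = (W - cfg.conv1_kernel) // cfg.conv1_stride + 1
        if h1 < 1 or w1 < 1:
            raise ValueError(
                f"conv1 kernel {cfg.conv1_kernel} does not fit input {H}x{W}"
            )
        h2 = (h1 - cfg.primary_kernel) // cfg.primary_stride + 1
        w2 = (w1 - cfg.primary_kernel) // cfg.primary_stride + 1
        if h2 < 1 or w2 < 1:
            raise ValueError(
                f"primary-capsule kernel {cfg.primary_kernel} does not fit "
                f"the {h1}x{w1} stem output"
            )
        P = cfg.primary_channels * h2 * w2
        rng = np.random.default_rng(cfg.seed)

        def normal(shape, std):
            return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)

        k1, k2 = cfg.conv1_kernel, cfg.primary_kernel
        self.params = {
            "conv1_w": normal((cfg.conv1_channels, C, k1, k1), np.sqrt(2.0 / (C * k1 * k1))),
            "conv1_b": Tensor(np.zeros(cfg.conv1_channels), requires_grad=True),
            "primary_w": normal(
                (cfg.primary_channels * cfg.primary_dim, cfg.conv1_channels, k2, k2),
                np.sqrt(2.0 / (cfg.conv1_channels * k2 * k2)),
            ),
            "primary_b": Tensor(
                np.zeros(cfg.primary_channels * cfg.primary_dim), requires_grad=True
            ),
            "caps_w": normal((P, cfg.n_classes, cfg.class_dim, cfg.primary_dim), 0.1),
        }
        self.input_shape = (C, H, W)
        self._n_primary = P
        self._grid2 = (h2, w2)

    # -- forward -----------------------------------------------------------

    def _forward(self, x: np.ndarray) -> Tensor:
        cfg = self.config
        p = self.params
        B = x.shape[0]
        h = conv2d(Tensor(x), p["conv1_w"], p["conv1_b"], stride=cfg.conv1_stride).relu()
        pc = conv2d(h, p["primary_w"], p["primary_b"], stride=cfg.primary_stride)
        h2, w2 = self._grid2
        u = pc.reshape(B, cfg.primary_channels, cfg.primary_dim, h2, w2)
        u = u.transpose(0, 1, 3, 4, 2).reshape(B, self._n_primary, cfg.primary_dim)
        u = _squash_t(u)
        # votes: u_hat[b,p,c,i] = sum_j caps_w[p,c,i,j] u[b,p,j]
        u_exp = u.reshape(B, self._n_primary, 1, 1, cfg.primary_dim)
        u_hat = (p["caps_w"] * u_exp).sum(axis=-1)  # (B, P, C, class_dim)
        # dynamic routing
        b = Tensor(np.zeros((B, self._n_primary, cfg.n_classes, 1)))
        v = None
        for _ in range(cfg.routing_iters):
            c = softmax(b, axis=2)
            s = (c * u_hat).sum(axis=1)  # (B, C, class_dim)
            v = _squash_t(s)
            agreement = (u_hat * v.reshape(B, 1, cfg.n_classes, cfg.class_dim)).sum(
                axis=-1, keepdims=True
            )
            b = b + agreement
        n2 = (v * v).sum(axis=-1)
        return (n2 + 1e-16) ** 0.5  # (B, n_classes) capsule lengths

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CapsNetClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 4:
            raise ValueError("X must be (n, channels, H, W)")
        if set(np.unique(y)) - set(range(self.config.n_classes)):
            raise ValueError("labels outside configured class range")
        if np.unique(y).size < 2:
            raise ValueError("training requires at least two classes")
        cfg = self.config
        if self.params is None:
            self._build(X.shape[1:])
        elif X.shape[1:] != self.input_shape:
            raise ValueError(f"input shape {X.shape[1:]} != model {self.input_shape}")
        opt = Adam(self.params.values(), lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)
        n = X.shape[0]
        onehot = np.eye(cfg.n_classes)[y]
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                scores = self._forward(X[idx])
                loss = _margin_loss_t(scores, onehot[idx], cfg)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            train_acc = float((self.predict(X) == y).mean())
            self.history.append(
                {"epoch": epoch, "loss": float(np.mean(losses)), "train_acc": train_acc}
            )
            if not np.isfinite(self.history[-1]["loss"]):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        return self

    # -- inference ---------------------------------------------------------

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3:
            X = X[None]
        if X.shape[1:] != self.input_shape:
            raise ValueError(f"input shape {X.shape[1:]} != model {self.input_shape}")
        out = []
        for start in range(0, X.shape[0], 64):
            out.append(self._forward(X[start : start + 64]).data)
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_scores(X).argmax(axis=1)

    def predict_one(self, x: np.ndarray) -> Prediction:
        scores = self.predict_scores(x[None] if x.ndim == 3 else x)[0]
        return Prediction(class_scores=scores, predicted_class=int(scores.argmax()))

    # -- serialization -----------------------------------------------------

    def save(self, path) -> None:
        if self.params is None:
            raise RuntimeError("nothing to save: model is not fitted")
        arrays = {k: t.data for k, t in self.params.items()}
        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
            ),
            __history__=np.frombuffer(
                json.dumps(self.history).encode(), dtype=np.uint8
            ),
            __input_shape__=np.array(self.input_shape),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "CapsNetClassifier":
        with np.load(path) as data:
            cfg = CapsNetConfig(**json.loads(bytes(data["__config__"]).decode()))
            model = cls(cfg)
            model._build(tuple(int(v) for v in data["__input_shape__"]))
            model.history = json.loads(bytes(data["__history__"]).decode())
            for k in model.params:
                model.params[k].data = data[k].astype(np.float64)
        return model
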