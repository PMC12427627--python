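"""Hypernetwork-personalized classifier on the fused latent space.

Instead of one shared classifier, a secondary network H maps each subject's
fused latent z (32-d) to the full parameter set of that subject's own
two-layer softmax MLP:

    theta = H(z) = (W1 in R^{16x32}, b1 in R^16, W2 in R^{2x16}, b2 in R^2)
    y_hat = softmax(W2 . ReLU(W1 . z + b1) + b2)

so decision boundaries vary across subjects while all learning is shared
through H (562 generated scalars per subject).  H itself is one hidden
ReLU layer of width 64 with a linear 562-unit output head initialized at a
small scale, so training starts from near-uniform predictions.  Training
minimizes mean cross-entropy, by default over the entire dataset as a
single batch.

A configuration-matched fixed-weight MLP with identical target shapes is
provided as the non-personalized reference classifier for ablations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn

__all__ = [
    "HyperNetConfig",
    "GeneratedParams",
    "HyperNetworkModel",
    "FixedMLPModel",
    "generate_params",
    "personalized_forward",
    "train_hypernet",
    "predict",
    "train_fixed_mlp",
    "predict_fixed",
]


@dataclass
class HyperNetConfig:
    latent_dim: int = 32
    target_hidden: int = 16
    n_classes: int = 2
    hyper_hidden: int = 64
    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int | None = None  # None = full-batch training
    head_init_scale: float = 1e-2
    seed: int = 0

    @property
    def n_generated(self) -> int:
        h, z, k = self.target_hidden, self.latent_dim, self.n_classes
        return h * z + h + k * h + k  # 562 for the default 16/32/2


@dataclass
class GeneratedParams:
    """Per-subject classifier parameters emitted by the hypernetwork.

    Arrays may carry a leading batch axis when generated for several
    subjects at once.
    """

    W1: np.ndarray  # (16, 32) or (n, 16, 32)
    b1: np.ndarray  # (16,) or (n, 16)
    W2: np.ndarray  # (2, 16) or (n, 2, 16)
    b2: np.ndarray  # (2,) or (n, 2)

    @property
    def n_scalars(self) -> int:
        batched = self.W1.ndim == 3
        div = self.W1.shape[0] if batched else 1
        return sum(a.size for a in (self.W1, self.b1, self.W2, self.b2)) // div


@dataclass
class HyperNetworkModel:
    """Trained hypernetwork H (shared across subjects)."""

    config: HyperNetConfig
    weights: dict  # Wh, bh, Whead, bhead
    history: list = field(default_factory=list)
    trained: bool = False

    def _emit(self, Z: np.ndarray) -> np.ndarray:
        w = self.weights
        h = np.maximum(Z @ w["Wh"] + w["bh"], 0.0)
        return h @ w["Whead"] + w["bhead"]  # (n, n_generated)

    def save(self, path) -> None:
        """Serialize to a single .npz archive (H weights + config)."""
        import json

        np.savez(path, meta=json.dumps({"config": self.config.__dict__,
                                        "trained": self.trained}),
                 **self.weights)

    @classmethod
    def load(cls, path) -> "HyperNetworkModel":
        import json

        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            weights = {k: data[k] for k in data.files if k != "meta"}
            return cls(config=HyperNetConfig(**meta["config"]), weights=weights,
                       trained=bool(meta["trained"]))


def _split_theta(flat: np.ndarray, cfg: HyperNetConfig) -> GeneratedParams:
    h, z, k = cfg.target_hidden, cfg.latent_dim, cfg.n_classes
    n = flat.shape[0]
    o = 0
    W1 = flat[:, o:o + h * z].reshape(n, h, z); o += h * z
    b1 = flat[:, o:o + h]; o += h
    W2 = flat[:, o:o + k * h].reshape(n, k, h); o += k * h
    b2 = flat[:, o:o + k]
    return GeneratedParams(W1=W1, b1=b1, W2=W2, b2=b2)


def generate_params(model: HyperNetworkModel, z: np.ndarray) -> GeneratedParams:
    """Map latent(s) z to subject-specific classifier parameters."""
    z = np.asarray(z, dtype=np.float64)
    single = z.ndim == 1
    Z = z[None] if single else z
    if Z.shape[1] != model.config.latent_dim:
        raise ValueError(
            f"expected latent dim {model.config.latent_dim}, got {Z.shape[1]}"
        )
    theta = _split_theta(model._emit(Z), model.config)
    if single:
        theta = GeneratedParams(W1=theta.W1[0], b1=theta.b1[0],
                                W2=theta.W2[0], b2=theta.b2[0])
    return theta


def personalized_forward(z: np.ndarray, theta: GeneratedParams) -> np.ndarray:
    """softmax(W2 . ReLU(W1 . z + b1) + b2) for one subject or a batch."""
    z = np.asarray(z, dtype=np.float64)
    for a in (theta.W1, theta.b1, theta.W2, theta.b2):
        if not np.all(np.isfinite(a)):
            raise ValueError("generated parameters contain non-finite values")
    single = z.ndim == 1
    if single:
        hidden = np.maximum(theta.W1 @ z + theta.b1, 0.0)
        logits = theta.W2 @ hidden + theta.b2
        return _nn.softmax(logits)
    hidden = np.maximum(
        (theta.W1 @ z[:, :, None])[..., 0] + theta.b1, 0.0
    )
    logits = (theta.W2 @ hidden[:, :, None])[..., 0] + theta.b2
    return _nn.softmax(logits)


def train_hypernet(Z, y, config: HyperNetConfig | None = None
                   ) -> HyperNetworkModel:
    """Train H end to end with cross-entropy through the generated weights."""
    from .preprocess import LabelVector

    config = config or HyperNetConfig()
    Z = np.asarray(Z, dtype=np.float64)
    y = y.y if isinstance(y, LabelVector) else np.asarray(y).astype(np.int64)
    if len(Z) != len(y):
        raise ValueError("Z and y lengths differ")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if Z.shape[1] != config.latent_dim:
        config = HyperNetConfig(**{**config.__dict__, "latent_dim": Z.shape[1]})

    rng = np.random.default_rng(config.seed)
    Wh = _nn.glorot(rng, (config.latent_dim, config.hyper_hidden),
                    config.latent_dim, config.hyper_hidden)
    bh = _nn.parameter(np.zeros(config.hyper_hidden))
    Whead = _nn.parameter(
        rng.normal(0.0, config.head_init_scale,
                   (config.hyper_hidden, config.n_generated))
    )
    bhead = _nn.parameter(np.zeros(config.n_generated))
    params = [Wh, bh, Whead, bhead]
    opt = _nn.Adam(params, lr=config.learning_rate)

    n = len(Z)
    bs = config.batch_size or n
    h, zd, k = config.target_hidden, config.latent_dim, config.n_classes
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(n) if bs < n else np.arange(n)
        total, seen = 0.0, 0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            zb = _nn.constant(Z[idx])
            hid = _nn.relu(_nn.add(_nn.matmul(zb, Wh), bh))
            flat = _nn.add(_nn.matmul(hid, Whead), bhead)  # (b, 562)
            m = len(idx)
            o = 0
            W1 = _nn.reshape(_nn.getitem(flat, (slice(None), slice(o, o + h * zd))),
                             (m, h, zd)); o += h * zd
            b1 = _nn.reshape(_nn.getitem(flat, (slice(None), slice(o, o + h))),
                             (m, h, 1)); o += h
            W2 = _nn.reshape(_nn.getitem(flat, (slice(None), slice(o, o + k * h))),
                             (m, k, h)); o += k * h
            b2 = _nn.reshape(_nn.getitem(flat, (slice(None), slice(o, o + k))),
                             (m, k, 1))
            zc = _nn.constant(Z[idx][:, :, None])
            a = _nn.relu(_nn.add(_nn.matmul(W1, zc), b1))  # (b, 16, 1)
            logits = _nn.reshape(_nn.add(_nn.matmul(W2, a), b2), (m, k))
            loss = _nn.softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * m
            seen += m
        history.append(total / seen)

    weights = {"Wh": Wh.data, "bh": bh.data, "Whead": Whead.data,
               "bhead": bhead.data}
    return HyperNetworkModel(config=config, weights=weights, history=history,
                             trained=True)


def predict(model: HyperNetworkModel, Z) -> tuple[np.ndarray, np.ndarray]:
    """Argmax labels and class probabilities; an exact tie goes to Control."""
    if not model.trained:
        raise ValueError("hypernetwork model is not trained")
    Z = np.asarray(Z, dtype=np.float64)
    theta = generate_params(model, Z)
    probs = personalized_forward(Z, theta)
    labels = (probs[:, 1] > probs[:, 0]).astype(np.int64)
    return labels, probs


# Fixed-weight reference classifier (the non-personalized ablation arm) ----


@dataclass
class FixedMLPModel:
    """One shared two-layer softmax MLP with the same target shapes."""

    config: HyperNetConfig
    theta: GeneratedParams
    history: list = field(default_factory=list)
    trained: bool = False


def train_fixed_mlp(Z, y, config: HyperNetConfig | None = None) -> FixedMLPModel:
    """Train a single shared MLP (latent -> 16 -> 2) with cross-entropy."""
    from .preprocess import LabelVector

    config = config or HyperNetConfig()
    Z = np.asarray(Z, dtype=np.float64)
    y = y.y if isinstance(y, LabelVector) else np.asarray(y).astype(np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if Z.shape[1] != config.latent_dim:
        config = HyperNetConfig(**{**config.__dict__, "latent_dim": Z.shape[1]})
    rng = np.random.default_rng(config.seed)
    l1 = _nn.Linear(config.latent_dim, config.target_hidden, rng)
    l2 = _nn.Linear(config.target_hidden, config.n_classes, rng)
    opt = _nn.Adam(l1.parameters() + l2.parameters(), lr=config.learning_rate)
    n = len(Z)
    bs = config.batch_size or n
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(n) if bs < n else np.arange(n)
        total, seen = 0.0, 0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            logits = l2(_nn.relu(l1(_nn.constant(Z[idx]))))
            loss = _nn.softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
            seen += len(idx)
        history.append(total / seen)
    theta = GeneratedParams(W1=l1.W.data.T, b1=l1.b.data,
                            W2=l2.W.data.T, b2=l2.b.data)
    return FixedMLPModel(config=config, theta=theta, history=history,
                         trained=True)


def predict_fixed(model: FixedMLPModel, Z) -> tuple[np.ndarray, np.ndarray]:
    """Predictions of the shared-weight MLP (same tie-break as ``predict``)."""
    if not model.trained:
        raise ValueError("fixed MLP model is not trained")
    Z = np.asarray(Z, dtype=np.float64)
    probs = personalized_forward(Z, model.theta)
    labels = (probs[:, 1] > probs[:, 0]).astype(np.int64)
    return labels, probs
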