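"""Autoencoder fusion of the behavioral and MRI embeddings.

The behavioral branch contributes a single scalar (the additive model's ASD
probability) and the MRI branch a 128-d embedding; their concatenation is
compressed by a 2-layer autoencoder (input -> 64 -> 32 bottleneck, mirrored
decoder) trained to minimize mean squared reconstruction error.  The 32-d
bottleneck code is the fused latent passed to the hypernetwork classifier.

Inputs are standardized with training-split z-scores before entering the
autoencoder, so the lone behavioral scalar is not drowned by the
high-dimensional MRI block; reconstructions are mapped back to the original
scale, and reconstruction error is reported on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .gami import BehavioralEmbedding

__all__ = [
    "FusionConfig",
    "AutoencoderModel",
    "concat_embeddings",
    "fit_autoencoder",
    "encode",
    "decode",
    "reconstruction_error",
]


@dataclass
class FusionConfig:
    hidden_dim: int = 64
    latent_dim: int = 32
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0


def concat_embeddings(behavioral, mri: np.ndarray) -> np.ndarray:
    """Per-subject fusion input ``[prob, mri_1 ... mri_d]``.

    ``behavioral`` is a :class:`BehavioralEmbedding` or a probability array;
    the two modalities must be index-aligned and equally long.
    """
    prob = behavioral.prob if isinstance(behavioral, BehavioralEmbedding) else behavioral
    prob = np.asarray(prob, dtype=np.float64).reshape(-1)
    mri = np.asarray(mri, dtype=np.float64)
    if mri.ndim != 2 or mri.shape[1] == 0:
        raise ValueError("MRI embedding must be a non-empty (n, d) array")
    if len(prob) != len(mri):
        raise ValueError(
            f"misaligned modalities: {len(prob)} behavioral vs {len(mri)} MRI rows"
        )
    return np.concatenate([prob[:, None], mri], axis=1)


@dataclass
class AutoencoderModel:
    """Fitted fusion autoencoder (all weights plain numpy)."""

    input_dim: int
    config: FusionConfig
    mu: np.ndarray  # training-split feature means
    sd: np.ndarray  # training-split feature SDs (floored)
    weights: dict  # We1, be1, We2, be2, Wd1, bd1, Wd2, bd2
    history: list = field(default_factory=list)

    def _encode_np(self, xs: np.ndarray) -> np.ndarray:
        w = self.weights
        h = np.maximum(xs @ w["We1"] + w["be1"], 0.0)
        return h @ w["We2"] + w["be2"]

    def _decode_np(self, z: np.ndarray) -> np.ndarray:
        w = self.weights
        h = np.maximum(z @ w["Wd1"] + w["bd1"], 0.0)
        return h @ w["Wd2"] + w["bd2"]

    def save(self, path) -> None:
        """Serialize to a single .npz archive."""
        import json

        np.savez(path, meta=json.dumps({"input_dim": self.input_dim,
                                        "config": self.config.__dict__}),
                 mu=self.mu, sd=self.sd, **self.weights)

    @classmethod
    def load(cls, path) -> "AutoencoderModel":
        import json

        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            weights = {k: data[k] for k in data.files
                       if k not in ("meta", "mu", "sd")}
            return cls(input_dim=int(meta["input_dim"]),
                       config=FusionConfig(**meta["config"]),
                       mu=data["mu"], sd=data["sd"], weights=weights)


def fit_autoencoder(X: np.ndarray, config: FusionConfig | None = None
                    ) -> AutoencoderModel:
    """Train the fusion autoencoder with MSE on standardized inputs."""
    config = config or FusionConfig()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need a (n >= 2, d) input matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("fusion inputs must be finite")
    d = X.shape[1]
    mu = X.mean(axis=0)
    sd = np.maximum(X.std(axis=0), 1e-8)
    Xs = (X - mu) / sd

    rng = np.random.default_rng(config.seed)
    h, z = config.hidden_dim, config.latent_dim
    enc1 = _nn.Linear(d, h, rng)
    enc2 = _nn.Linear(h, z, rng)
    dec1 = _nn.Linear(z, h, rng)
    dec2 = _nn.Linear(h, d, rng)
    params = enc1.parameters() + enc2.parameters() + dec1.parameters() + dec2.parameters()
    opt = _nn.Adam(params, lr=config.learning_rate)

    n = len(Xs)
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = _nn.constant(Xs[idx])
            code = enc2(_nn.relu(enc1(xb)))
            recon = dec2(_nn.relu(dec1(code)))
            loss = _nn.mean_(_nn.square(_nn.sub(recon, xb)))
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
            seen += len(idx)
        history.append(total / seen)

    weights = {
        "We1": enc1.W.data, "be1": enc1.b.data,
        "We2": enc2.W.data, "be2": enc2.b.data,
        "Wd1": dec1.W.data, "bd1": dec1.b.data,
        "Wd2": dec2.W.data, "bd2": dec2.b.data,
    }
    return AutoencoderModel(input_dim=d, config=config, mu=mu, sd=sd,
                            weights=weights, history=history)


def encode(model: AutoencoderModel, x: np.ndarray) -> np.ndarray:
    """Fused latent code(s); (d,) -> (latent,) or (n, d) -> (n, latent)."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    xs = ((x[None] if single else x) - model.mu) / model.sd
    if xs.shape[1] != model.input_dim:
        raise ValueError(f"expected input of length {model.input_dim}")
    z = model._encode_np(xs)
    return z[0] if single else z


def decode(model: AutoencoderModel, z: np.ndarray) -> np.ndarray:
    """Reconstruction on the original input scale."""
    z = np.asarray(z, dtype=np.float64)
    single = z.ndim == 1
    xr = model._decode_np(z[None] if single else z)
    xr = xr * model.sd + model.mu
    return xr[0] if single else xr


def reconstruction_error(model: AutoencoderModel, X: np.ndarray) -> float:
    """Mean squared reconstruction error over subjects and dimensions."""
    X = np.asarray(X, dtype=np.float64)
    recon = decode(model, encode(model, X))
    return float(np.mean((X - recon) ** 2))
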