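"""Hybrid CNN-GNN encoder for structural brain volumes.

Each subject's 3-D volume is passed through a stack of shape-preserving
3x3x3 convolutions; the resulting feature maps are pooled into one node per
atlas region (masked mean), the nodes are connected by anatomical adjacency
(regions whose voxels share a face in the label volume), and two
symmetric-normalized graph-convolution layers propagate features across the
region graph.  The node embeddings are flattened in ascending-label order
and linearly mapped to a fixed-length embedding vector, which is the MRI
branch's contribution to the fusion stage.

The encoder is trained end-to-end with a temporary linear classification
head (binary cross-entropy on the diagnosis); the head is discarded after
training and only the embedding map is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from ._nn import Tensor

__all__ = [
    "EncoderConfig",
    "ROIGraph",
    "MRIEncoder",
    "atlas_adjacency",
    "normalized_adjacency",
    "cnn_features",
    "roi_pool",
    "gnn_embed",
    "fit_mri_encoder",
]


@dataclass
class EncoderConfig:
    conv_channels: tuple = (8, 16)
    gnn_layers: int = 2
    gnn_hidden: int = 32
    embed_dim: int = 128  # admissible 128-256; low end chosen for speed
    dropout: float = 0.2
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    pool_raw_intensity: bool = False  # fallback: pool the raw volume, skip CNN
    seed: int = 0

    def __post_init__(self):
        if not (8 <= self.embed_dim <= 1024):
            raise ValueError("embed_dim must lie in [8, 1024]")
        if any(c <= 0 for c in self.conv_channels) or self.gnn_hidden <= 0:
            raise ValueError("channel/hidden sizes must be positive")


@dataclass
class ROIGraph:
    """Per-subject node features over atlas regions plus shared adjacency."""

    node_features: np.ndarray  # (R, C)
    adjacency: np.ndarray  # (R, R) symmetric 0/1, zero diagonal
    roi_labels: np.ndarray  # ascending atlas labels, one per node

    def __post_init__(self):
        A = np.asarray(self.adjacency)
        if A.shape[0] < 2:
            raise ValueError("a region graph needs at least 2 nodes")
        if not np.array_equal(A, A.T) or np.any(np.diag(A) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")


def atlas_adjacency(atlas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Anatomical adjacency: regions whose voxels share a face (6-connectivity).

    Returns ``(A, labels)`` with nodes ordered by ascending nonzero label.
    """
    atlas = np.asarray(atlas)
    labels = np.unique(atlas)
    labels = labels[labels != 0]
    if len(labels) < 2:
        raise ValueError("atlas must contain at least 2 nonzero labels")
    index = {int(l): i for i, l in enumerate(labels)}
    R = len(labels)
    A = np.zeros((R, R), dtype=np.int64)
    for ax in range(3):
        a = np.moveaxis(atlas, ax, 0)
        lo, hi = a[:-1], a[1:]
        touch = (lo != hi) & (lo != 0) & (hi != 0)
        for u, v in zip(lo[touch].ravel(), hi[touch].ravel()):
            A[index[int(u)], index[int(v)]] = 1
            A[index[int(v)], index[int(u)]] = 1
    return A, labels.astype(np.int64)


def normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """Propagation operator D^{-1/2} (A + I) D^{-1/2} with self-loops."""
    A = np.asarray(A, dtype=np.float64)
    Ahat = A + np.eye(A.shape[0])
    dinv = 1.0 / np.sqrt(Ahat.sum(axis=1))
    return Ahat * dinv[:, None] * dinv[None, :]


def _pool_matrix(atlas: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(R, V) row-normalized masks: P @ flat_features = per-region means."""
    flat = atlas.ravel()
    P = np.zeros((len(labels), flat.size))
    for i, lab in enumerate(labels):
        mask = flat == lab
        cnt = mask.sum()
        if cnt == 0:
            raise ValueError(f"atlas region {lab} has no voxels")
        P[i, mask] = 1.0 / cnt
    return P


class MRIEncoder:
    """CNN -> ROI pooling -> GNN -> linear readout, trained end to end."""

    def __init__(self, atlas: np.ndarray, config: EncoderConfig):
        self.config = config
        self.spatial_shape = tuple(atlas.shape)
        A, labels = atlas_adjacency(atlas)
        self.adjacency = A
        self.roi_labels = labels
        self.Ahat = normalized_adjacency(A)
        self.P = _pool_matrix(atlas, labels)
        self.R = len(labels)
        self.trained = False
        self.history: list = []

        rng = np.random.default_rng(config.seed)
        self._rng = rng
        self.convs = []
        if not config.pool_raw_intensity:
            cin = 1
            for cout in config.conv_channels:
                self.convs.append(_nn.Conv3d(cin, cout, self.spatial_shape, rng))
                cin = cout
            self.node_channels = config.conv_channels[-1]
        else:
            self.node_channels = 1
        h = config.gnn_hidden
        self.gnn_weights = []
        cin = self.node_channels
        for _ in range(config.gnn_layers):
            self.gnn_weights.append(_nn.glorot(rng, (cin, h), cin, h))
            cin = h
        self.readout = _nn.Linear(self.R * h, config.embed_dim, rng)
        self.head = _nn.Linear(config.embed_dim, 1, rng)

    # -- forward pieces --------------------------------------------------
    def parameters(self):
        params = []
        for c in self.convs:
            params += c.parameters()
        params += self.gnn_weights
        params += self.readout.parameters()
        if self.head is not None:
            params += self.head.parameters()
        return params

    def _cnn(self, vols: np.ndarray) -> Tensor:
        """(B, D, H, W) -> (B, V, C) feature maps (identity when pooling raw)."""
        B = vols.shape[0]
        x = _nn.constant(vols.reshape(B, -1, 1))
        for conv in self.convs:
            x = _nn.relu(conv(x))
        return x

    def _gnn_readout(self, nodes: Tensor, training: bool) -> Tensor:
        """(B, R, C) node features -> (B, embed_dim)."""
        Ahat = _nn.constant(self.Ahat)
        h = nodes
        for W in self.gnn_weights:
            h = _nn.relu(_nn.matmul(_nn.matmul(Ahat, h), W))
            h = _nn.dropout(h, self.config.dropout, self._rng, training)
        B = h.data.shape[0]
        flat = _nn.reshape(h, (B, self.R * self.config.gnn_hidden))
        return self.readout(flat)

    def _forward(self, vols: np.ndarray, training: bool) -> Tensor:
        feats = self._cnn(vols)
        nodes = _nn.matmul(_nn.constant(self.P), feats)  # (B, R, C)
        return self._gnn_readout(nodes, training)

    def embed(self, volumes: np.ndarray) -> np.ndarray:
        """Deterministic (eval-mode) embeddings, (n, embed_dim)."""
        volumes = np.asarray(volumes, dtype=np.float64)
        if volumes.ndim == 3:
            volumes = volumes[None]
        if volumes.shape[1:] != self.spatial_shape:
            raise ValueError(
                f"volume shape {volumes.shape[1:]} != atlas shape {self.spatial_shape}"
            )
        out = []
        bs = self.config.batch_size
        for start in range(0, len(volumes), bs):
            out.append(self._forward(volumes[start:start + bs], training=False).data)
        return np.concatenate(out, axis=0)


def cnn_features(volume: np.ndarray, encoder: MRIEncoder) -> np.ndarray:
    """Feature volume of the convolutional stack, shape (D, H, W, C).

    Spatial dimensions are preserved (stride 1, zero padding) so atlas masks
    still apply voxel-for-voxel.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.shape != encoder.spatial_shape:
        raise ValueError(
            f"volume shape {volume.shape} != encoder shape {encoder.spatial_shape}"
        )
    feats = encoder._cnn(volume[None]).data[0]  # (V, C)
    return feats.reshape(encoder.spatial_shape + (feats.shape[-1],))


def roi_pool(features: np.ndarray, atlas: np.ndarray) -> np.ndarray:
    """Mean of each feature channel over each atlas region.

    ``features`` is (D, H, W, C) or (D, H, W); rows of the result are
    ordered by ascending atlas label.
    """
    features = np.asarray(features, dtype=np.float64)
    atlas = np.asarray(atlas)
    if features.ndim == 3:
        features = features[..., None]
    if features.shape[:3] != atlas.shape:
        raise ValueError("features and atlas have different spatial shapes")
    labels = np.unique(atlas)
    labels = labels[labels != 0]
    flat_a = atlas.ravel()
    flat_f = features.reshape(-1, features.shape[-1])
    out = np.empty((len(labels), flat_f.shape[1]))
    for i, lab in enumerate(labels):
        mask = flat_a == lab
        if not mask.any():
            raise ValueError(f"atlas region {lab} has no voxels")
        out[i] = flat_f[mask].mean(axis=0)
    return out


def gnn_embed(graph: ROIGraph, encoder: MRIEncoder) -> np.ndarray:
    """Embed one region graph with the encoder's GNN + readout (eval mode)."""
    nodes = np.asarray(graph.node_features, dtype=np.float64)
    if nodes.shape != (encoder.R, encoder.node_channels):
        raise ValueError(
            f"node features {nodes.shape} incompatible with fitted encoder "
            f"({encoder.R}, {encoder.node_channels})"
        )
    return encoder._gnn_readout(_nn.constant(nodes[None]), training=False).data[0]


def fit_mri_encoder(volumes, atlas, labels, config: EncoderConfig | None = None
                    ) -> MRIEncoder:
    """Train the CNN-GNN encoder end to end with a temporary linear head.

    The head maps the embedding to a diagnosis logit and is dropped after
    training; ``encoder.history`` records the mean training BCE per epoch.
    """
    from .preprocess import LabelVector

    config = config or EncoderConfig()
    volumes = np.asarray(volumes, dtype=np.float64)
    y = labels.y if isinstance(labels, LabelVector) else np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if volumes.shape[1:] != tuple(np.asarray(atlas).shape):
        raise ValueError("volumes and atlas have different spatial shapes")

    enc = MRIEncoder(np.asarray(atlas), config)
    opt = _nn.Adam(enc.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng((config.seed * 7919 + 1) % 2**31)
    n = len(volumes)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            emb = enc._forward(volumes[idx], training=True)
            logit = enc.head(emb)
            loss = _nn.bce_with_logits(logit, y[idx][:, None])
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
            seen += len(idx)
        enc.history.append(total / seen)
    enc.head = None  # embedding map only; the training head is discarded
    enc.trained = True
    return enc
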