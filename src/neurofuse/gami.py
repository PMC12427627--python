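"""Interpretable additive behavioral embedding (neural GAM with interactions).

The behavioral branch models the ASD logit as an identifiable additive
decomposition

    logit(p) = sum_i f_i(x_i) + sum_{(i,j) in L} f_ij(x_i, x_j) + b,

where every main effect ``f_i`` and pairwise interaction ``f_ij`` is a small
dedicated MLP subnetwork, ``L`` is a screened set of feature pairs, and the
sigmoid of the sum is the scalar ASD probability used downstream as the
behavioral embedding.  Interpretability comes for free from the structure:
per-subject effect contributions, variance-based importance scores, and
partial-dependence curves are exact model components, not approximations.

Fitting is three-stage: (1) main effects trained with binary cross-entropy
plus an L1 penalty on per-effect output scales, (2) interaction screening on
the main-effect residuals with shallow regression-tree surrogates, (3)
interaction subnetworks trained on the residual signal with the main
effects frozen.  Effects whose training-set output variance is negligible
are pruned to exactly zero, and every surviving effect is mean-centered
over the training set (the means are absorbed into the intercept), which
makes the decomposition identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from . import _nn
from ._nn import Tensor
from .preprocess import FeatureMatrix, LabelVector

__all__ = [
    "GAMIConfig",
    "GAMIModel",
    "BehavioralEmbedding",
    "fit_gami",
    "select_interactions",
    "gami_predict",
    "gami_effects",
    "gami_importance",
    "gami_partial_dependence",
]


@dataclass
class GAMIConfig:
    subnet_hidden: tuple = (16, 16)
    max_interactions: int = 10
    l1_penalty: float = 1e-4
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    prune_threshold: float = 1e-4  # fraction of total effect-output variance
    prune_floor: float = 1e-10  # absolute variance floor
    seed: int = 0

    def __post_init__(self):
        if len(self.subnet_hidden) != 2 or any(w <= 0 for w in self.subnet_hidden):
            raise ValueError("subnet_hidden must be two positive widths")


@dataclass
class BehavioralEmbedding:
    """Per-subject scalar ASD probability (the behavioral branch output)."""

    prob: np.ndarray
    subject_ids: list = field(default_factory=list)


def _init_group(m: int, in_dim: int, hidden: tuple, rng: np.random.Generator):
    """Initialize a stacked bank of ``m`` subnetworks (in_dim -> h1 -> h2 -> 1)."""
    h1, h2 = hidden

    def glorot(shape, fi, fo):
        lim = np.sqrt(6.0 / (fi + fo))
        return rng.uniform(-lim, lim, size=shape)

    return {
        "W0": glorot((m, in_dim, h1), in_dim, h1),
        "b0": np.zeros((m, 1, h1)),
        "W1": glorot((m, h1, h2), h1, h2),
        "b1": np.zeros((m, 1, h2)),
        "W2": glorot((m, h2, 1), h2, 1),
        "b2": np.zeros((m, 1, 1)),
        "gamma": np.ones((m, 1, 1)),
    }


def _group_forward_np(params: dict, Xg: np.ndarray) -> np.ndarray:
    """Numpy forward of a stacked subnetwork bank: (m, n, d) -> (m, n)."""
    h = np.maximum(Xg @ params["W0"] + params["b0"], 0.0)
    h = np.maximum(h @ params["W1"] + params["b1"], 0.0)
    out = (h @ params["W2"] + params["b2"]) * params["gamma"]
    return out[..., 0]


def _group_forward_t(tp: dict, Xg: np.ndarray) -> Tensor:
    """Autodiff forward of a stacked subnetwork bank: returns (m, n, 1)."""
    x = _nn.constant(Xg)
    h = _nn.relu(_nn.add(_nn.matmul(x, tp["W0"]), tp["b0"]))
    h = _nn.relu(_nn.add(_nn.matmul(h, tp["W1"]), tp["b1"]))
    return _nn.mul(_nn.add(_nn.matmul(h, tp["W2"]), tp["b2"]), tp["gamma"])


@dataclass
class GAMIModel:
    """Fitted additive model; all arrays are plain numpy."""

    feature_names: list
    config: GAMIConfig
    main: dict  # stacked main-effect subnetwork weights, m = n_features
    pairs: list  # [(i, j), ...] with i < j
    inter: dict | None  # stacked interaction subnetwork weights
    bias: float  # intercept after absorbing effect centers
    main_active: np.ndarray  # (p,) bool
    inter_active: np.ndarray  # (len(pairs),) bool
    main_centers: np.ndarray  # (p,) training-set means of raw main outputs
    inter_centers: np.ndarray
    history: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def effect_names(self) -> list:
        """Names of active effects: feature names, then 'a*b' pair names."""
        names = [self.feature_names[i] for i in np.flatnonzero(self.main_active)]
        for k in np.flatnonzero(self.inter_active):
            i, j = self.pairs[k]
            names.append(f"{self.feature_names[i]}*{self.feature_names[j]}")
        return names

    def _main_raw(self, X: np.ndarray) -> np.ndarray:
        """Raw (uncentered) main-effect outputs, (p, n)."""
        Xg = X.T[:, :, None]
        return _group_forward_np(self.main, Xg)

    def _inter_raw(self, X: np.ndarray) -> np.ndarray:
        if not self.pairs:
            return np.zeros((0, X.shape[0]))
        Xg = np.stack([X[:, [i, j]] for i, j in self.pairs])
        return _group_forward_np(self.inter, Xg)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Additive logit: sum of centered active effects plus intercept."""
        contrib = self.contributions(X)
        return contrib.sum(axis=1) + self.bias

    def contributions(self, X: np.ndarray) -> np.ndarray:
        """(n, n_active_effects) centered contribution matrix."""
        X = np.asarray(X, dtype=np.float64)
        cols = []
        main_raw = self._main_raw(X)
        for i in np.flatnonzero(self.main_active):
            cols.append(main_raw[i] - self.main_centers[i])
        if self.pairs:
            inter_raw = self._inter_raw(X)
            for k in np.flatnonzero(self.inter_active):
                cols.append(inter_raw[k] - self.inter_centers[k])
        if not cols:
            return np.zeros((X.shape[0], 0))
        return np.stack(cols, axis=1)

    def save(self, path) -> None:
        """Serialize to a single .npz archive (weights, pairs, config, centers)."""
        import json

        arrays = {f"main_{k}": v for k, v in self.main.items()}
        if self.inter is not None:
            arrays.update({f"inter_{k}": v for k, v in self.inter.items()})
        np.savez(
            path,
            meta=json.dumps({
                "feature_names": self.feature_names,
                "config": self.config.__dict__ | {
                    "subnet_hidden": list(self.config.subnet_hidden)
                },
                "pairs": [list(p) for p in self.pairs],
                "bias": self.bias,
            }),
            main_active=self.main_active,
            inter_active=self.inter_active,
            main_centers=self.main_centers,
            inter_centers=self.inter_centers,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "GAMIModel":
        import json

        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            cfg = dict(meta["config"])
            cfg["subnet_hidden"] = tuple(cfg["subnet_hidden"])
            main = {k[5:]: data[k] for k in data.files if k.startswith("main_")
                    and k not in ("main_active", "main_centers")}
            inter = {k[6:]: data[k] for k in data.files if k.startswith("inter_")
                     and k not in ("inter_active", "inter_centers")}
            return cls(
                feature_names=meta["feature_names"],
                config=GAMIConfig(**cfg),
                main=main,
                pairs=[tuple(p) for p in meta["pairs"]],
                inter=inter or None,
                bias=float(meta["bias"]),
                main_active=data["main_active"],
                inter_active=data["inter_active"],
                main_centers=data["main_centers"],
                inter_centers=data["inter_centers"],
            )

    @classmethod
    def random(cls, n_features: int, pairs=(), config: GAMIConfig | None = None,
               seed: int = 0) -> "GAMIModel":
        """An untrained model with random weights (for oracles/simulations)."""
        config = config or GAMIConfig(seed=seed)
        rng = np.random.default_rng(seed)
        pairs = [tuple(p) for p in pairs]
        main = _init_group(n_features, 1, config.subnet_hidden, rng)
        # non-degenerate random scales so effects differ
        main["gamma"] = rng.normal(1.0, 0.3, (n_features, 1, 1))
        inter = None
        if pairs:
            inter = _init_group(len(pairs), 2, config.subnet_hidden, rng)
            inter["gamma"] = rng.normal(1.0, 0.3, (len(pairs), 1, 1))
        return cls(
            feature_names=[f"x{i}" for i in range(n_features)],
            config=config,
            main=main,
            pairs=pairs,
            inter=inter,
            bias=float(rng.normal(0.0, 0.5)),
            main_active=np.ones(n_features, dtype=bool),
            inter_active=np.ones(len(pairs), dtype=bool),
            main_centers=np.zeros(n_features),
            inter_centers=np.zeros(len(pairs)),
        )


def _coerce_X(X) -> tuple[np.ndarray, list, list]:
    if isinstance(X, FeatureMatrix):
        return np.asarray(X.values, float), list(X.feature_names), list(X.subject_ids)
    X = np.asarray(X, dtype=np.float64)
    return X, [f"x{i}" for i in range(X.shape[1])], []


def _coerce_y(y) -> np.ndarray:
    if isinstance(y, LabelVector):
        return y.y
    return np.asarray(y).astype(np.int64)


def select_interactions(X, y, main_model: GAMIModel, k: int) -> list:
    """Screen feature pairs by how much of the main-effect residual they explain.

    For each candidate pair (i, j) a shallow regression tree is fitted to the
    working residual ``y - sigmoid(main logit)`` on the two raw features; the
    screening score is the tree's training R^2 (residual variance explained).
    Pairs are ranked by descending score with lexicographic (i, j) tie-break;
    at most ``k`` pairs are returned.
    """
    if k <= 0:
        return []
    Xv, _, _ = _coerce_X(X)
    yv = _coerce_y(y)
    main_raw = main_model._main_raw(Xv)
    logit = (
        main_raw[main_model.main_active].sum(axis=0)
        - main_model.main_centers[main_model.main_active].sum()
        + main_model.bias
    )
    resid = yv - _nn._sigmoid_np(logit)
    if np.var(resid) < 1e-12:
        return []
    scored = []
    for i, j in combinations(range(Xv.shape[1]), 2):
        tree = DecisionTreeRegressor(max_depth=3, random_state=0)
        tree.fit(Xv[:, [i, j]], resid)
        scored.append((-tree.score(Xv[:, [i, j]], resid), i, j))
    scored.sort()
    return [(i, j) for _, i, j in scored[:k]]


def fit_gami(X, y, config: GAMIConfig | None = None) -> GAMIModel:
    """Three-stage fit of the additive behavioral model.

    Requires features scaled to [0, 1] (the model relies on bounded inputs)
    and both classes present.  Training history (mean BCE per epoch) is kept
    in ``model.history``.
    """
    config = config or GAMIConfig()
    Xv, names, _ = _coerce_X(X)
    yv = _coerce_y(y)
    if Xv.min() < -1e-9 or Xv.max() > 1.0 + 1e-9:
        raise ValueError("features must be scaled to [0, 1] before fitting")
    if len(np.unique(yv)) < 2:
        raise ValueError("both classes must be present in y")
    n, p = Xv.shape
    k = min(config.max_interactions, p * (p - 1) // 2)
    rng = np.random.default_rng(config.seed)
    history: dict = {}

    # Stage 1: main effects ------------------------------------------------
    main_np = _init_group(p, 1, config.subnet_hidden, rng)
    main_t = {kk: _nn.parameter(v) for kk, v in main_np.items()}
    bias_t = _nn.parameter(np.zeros(()))
    params = list(main_t.values()) + [bias_t]
    Xg_full = Xv.T[:, :, None]  # (p, n, 1)
    history["stage1_bce"] = _train_additive(
        main_t, None, bias_t, params, Xg_full, None, None, yv, config, rng
    )
    main_np = {kk: t.data.copy() for kk, t in main_t.items()}

    model = GAMIModel(
        feature_names=names,
        config=config,
        main=main_np,
        pairs=[],
        inter=None,
        bias=float(bias_t.data),
        main_active=np.ones(p, dtype=bool),
        inter_active=np.zeros(0, dtype=bool),
        main_centers=np.zeros(p),
        inter_centers=np.zeros(0),
        history=history,
    )
    main_raw = model._main_raw(Xv)
    model.main_active = _prune_mask(np.var(main_raw, axis=1), config)

    # Stage 2: interaction screening --------------------------------------
    pairs = select_interactions(Xv, yv, model, k)
    model.pairs = pairs

    # Stage 3: interaction effects on the residual signal ------------------
    if pairs:
        inter_np = _init_group(len(pairs), 2, config.subnet_hidden, rng)
        inter_t = {kk: _nn.parameter(v) for kk, v in inter_np.items()}
        params3 = list(inter_t.values()) + [bias_t]
        frozen = main_raw[model.main_active].sum(axis=0)  # fixed main logit part
        Xg_int = np.stack([Xv[:, [i, j]] for i, j in pairs])  # (m, n, 2)
        history["stage3_bce"] = _train_additive(
            None, inter_t, bias_t, params3, None, Xg_int, frozen, yv, config, rng
        )
        model.inter = {kk: t.data.copy() for kk, t in inter_t.items()}
        model.bias = float(bias_t.data)
        inter_raw = model._inter_raw(Xv)
        all_vars = np.concatenate(
            [np.var(main_raw, axis=1)[model.main_active],
             np.var(inter_raw, axis=1)]
        )
        total = all_vars.sum()
        ivar = np.var(inter_raw, axis=1)
        model.inter_active = (ivar >= config.prune_threshold * total) & (
            ivar >= config.prune_floor
        )
    else:
        model.inter_active = np.zeros(0, dtype=bool)
        model.bias = float(bias_t.data)

    # Center active effects over the training set; absorb means into bias.
    model.main_centers = np.where(
        model.main_active, main_raw.mean(axis=1), 0.0
    )
    if pairs:
        inter_raw = model._inter_raw(Xv)
        model.inter_centers = np.where(
            model.inter_active, inter_raw.mean(axis=1), 0.0
        )
    model.bias = model.bias + model.main_centers.sum() + model.inter_centers.sum()
    return model


def _prune_mask(variances: np.ndarray, config: GAMIConfig) -> np.ndarray:
    total = variances.sum()
    if total <= 0:
        return np.zeros(len(variances), dtype=bool)
    return (variances >= config.prune_threshold * total) & (
        variances >= config.prune_floor
    )


def _train_additive(main_t, inter_t, bias_t, params, Xg_main, Xg_int, frozen,
                    y, config: GAMIConfig, rng: np.random.Generator) -> list:
    """Minibatch Adam/BCE loop shared by stages 1 and 3.

    Exactly one of ``main_t`` / ``inter_t`` is trained; ``frozen`` is the
    fixed part of the logit (stage 3 keeps the main effects frozen).
    Returns the per-epoch mean training BCE.
    """
    n = len(y)
    opt = _nn.Adam(params, lr=config.learning_rate)
    group_t = main_t if main_t is not None else inter_t
    Xg = Xg_main if main_t is not None else Xg_int
    epoch_bce = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            out = _group_forward_t(group_t, Xg[:, idx, :])  # (m, b, 1)
            logit = _nn.add(_nn.sum_(out, axis=0), bias_t)  # (b, 1)
            if frozen is not None:
                logit = _nn.add(logit, _nn.constant(frozen[idx][:, None]))
            bce = _nn.bce_with_logits(logit, y[idx][:, None])
            loss = _nn.add(
                bce,
                _nn.mul(_nn.sum_(_nn.abs_(group_t["gamma"])), config.l1_penalty),
            )
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(bce.data) * len(idx)
            seen += len(idx)
        epoch_bce.append(total / seen)
    return epoch_bce


# Inference and explainability ------------------------------------------


def gami_predict(model: GAMIModel, X) -> BehavioralEmbedding:
    """Scalar ASD probability: sigmoid of the additive logit."""
    Xv, _, ids = _coerce_X(X)
    if Xv.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {Xv.shape[1]}"
        )
    prob = _nn._sigmoid_np(model.decision_function(Xv))
    return BehavioralEmbedding(prob=prob, subject_ids=ids)


def gami_effects(model: GAMIModel, X):
    """Per-subject contribution table, one column per active effect.

    Row sums plus the intercept pass through the sigmoid to exactly the
    predicted probability; pruned effects have no column.
    """
    import pandas as pd

    Xv, _, ids = _coerce_X(X)
    if Xv.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {Xv.shape[1]}"
        )
    table = pd.DataFrame(model.contributions(Xv), columns=model.effect_names())
    if ids:
        table.index = ids
    return table


def gami_importance(model: GAMIModel, X) -> list:
    """Active effects ranked by normalized contribution variance over X."""
    contrib = gami_effects(model, X)
    if contrib.shape[1] == 0:
        return []
    var = contrib.var(axis=0, ddof=0)
    total = float(var.sum())
    if total <= 0:
        scores = {name: 0.0 for name in contrib.columns}
    else:
        scores = {name: float(v) / total for name, v in var.items()}
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


def gami_partial_dependence(model: GAMIModel, feature, grid):
    """Evaluate a main-effect subnetwork on a grid of values in [0, 1].

    By construction the curve *is* the model's additive component for the
    feature (no marginalization is needed).  Requesting a pruned feature is
    an error.
    """
    if isinstance(feature, str):
        feature = model.feature_names.index(feature)
    if not (0 <= feature < model.n_features):
        raise ValueError(f"feature index {feature} out of range")
    if not model.main_active[feature]:
        raise ValueError(
            f"feature {model.feature_names[feature]!r} was pruned from the model"
        )
    grid = np.asarray(grid, dtype=np.float64)
    sub = {kk: v[feature:feature + 1] for kk, v in model.main.items()}
    vals = _group_forward_np(sub, grid[None, :, None])[0]
    return grid, vals - model.main_centers[feature]
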