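"""Model zoo and training loops.

Four deep formulations share one residual 1-D convolutional backbone and
differ only in the head and loss:

* **direct** — one output, MSE on z-scored targets;
* **gaussian** — two heads (mean μ and a raw variance passed through a
  softplus with a small positivity floor), heteroscedastic Gaussian NLL;
* **classification** — k logits, cross-entropy over discretized classes;
* **ordinal** — k−1 threshold logits, elementwise binary cross-entropy
  against the cumulative encoding.

Training: Adam, fixed epoch budget (default 30), seeded shuffling, and the
returned model is the epoch checkpoint with minimal validation loss.
Everything is deterministic given the seed.

Two families of non-deep baselines are provided for comparison: PCA
reduction of the vectorized traces to 256 components followed by linear
regression / gradient boosting / random forest, and batch-wise training of a
linear model and a 3-layer MLP on the raw flattened input under the same
protocol as the deep models.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .discretization import (
    IntervalScheme,
    assign_class,
    class_to_value,
    ordinal_decode,
    ordinal_encode,
)
from .preprocessing import ArrayDataset, NormalizationParams, fit_normalizer

__all__ = [
    "BackboneConfig",
    "TrainConfig",
    "ModelState",
    "TINY_BACKBONE",
    "DEFAULT_BACKBONE",
    "build_network",
    "train_direct",
    "train_gaussian",
    "train_classifier",
    "train_ordinal",
    "predict",
    "predict_gaussian",
    "predict_proba",
    "predict_class",
    "gaussian_nll",
    "fit_pca_baselines",
    "fit_batchwise_baselines",
]


@dataclass(frozen=True)
class BackboneConfig:
    """Feature-extractor architecture.

    ``kind="resnet"``: stem convolution (``channels_per_stage[0]``,
    ``downsample_factors[0]``) followed by ``n_residual_blocks`` residual
    blocks and global average pooling. ``kind="flatten"``: the identity
    feature map on the vectorized trace (used by the batch-wise linear
    baseline and as an analytically tractable backbone). ``kind="mlp"``:
    flatten followed by ReLU hidden layers ``mlp_hidden``.
    """

    kind: str = "resnet"
    n_residual_blocks: int = 4
    channels_per_stage: tuple = (64, 64, 128, 196, 256)
    kernel_size: int = 17
    downsample_factors: tuple = (4, 4, 4, 2, 2)
    dropout_rate: float = 0.0
    input_shape: tuple = (8, 4096)
    mlp_hidden: tuple = (64, 32)

    def __post_init__(self) -> None:
        if self.kind == "resnet":
            if len(self.channels_per_stage) != self.n_residual_blocks + 1:
                raise ValueError("need one channel count per stage (stem + blocks)")
            if len(self.downsample_factors) != self.n_residual_blocks + 1:
                raise ValueError("need one downsample factor per stage")
            if self.input_shape[1] % int(np.prod(self.downsample_factors)):
                raise ValueError("product of downsample factors must divide samples")

    @property
    def feature_dim(self) -> int:
        if self.kind == "resnet":
            return self.channels_per_stage[-1]
        if self.kind == "flatten":
            return int(np.prod(self.input_shape))
        if self.kind == "mlp":
            return self.mlp_hidden[-1]
        raise ValueError(f"unknown backbone kind {self.kind!r}")


#: Desk-scale profile: 128 Hz x 8 s traces, 2 residual blocks, 32-dim feature.
TINY_BACKBONE = BackboneConfig(
    kind="resnet",
    n_residual_blocks=2,
    channels_per_stage=(16, 24, 32),
    kernel_size=9,
    downsample_factors=(4, 4, 4),
    input_shape=(8, 1024),
)
#: Full-scale profile for 400 Hz x 4096-sample traces.
DEFAULT_BACKBONE = BackboneConfig()


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 64
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def build_network(cfg: BackboneConfig, head_dims: list[int], seed: int) -> nn.Network:
    """Construct backbone + linear heads with seeded He initialization."""
    rng = np.random.default_rng(seed)
    if cfg.kind == "resnet":
        layers: list[nn.Layer] = [
            nn.Conv1d(cfg.input_shape[0], cfg.channels_per_stage[0],
                      cfg.kernel_size, cfg.downsample_factors[0], rng),
            nn.ReLU(),
        ]
        for i in range(cfg.n_residual_blocks):
            layers.append(
                nn.ResidualBlock(
                    cfg.channels_per_stage[i],
                    cfg.channels_per_stage[i + 1],
                    cfg.kernel_size,
                    cfg.downsample_factors[i + 1],
                    rng,
                    dropout=cfg.dropout_rate,
                )
            )
        layers.append(nn.GlobalAvgPool())
        backbone = nn.Sequential(layers)
    elif cfg.kind == "flatten":
        backbone = nn.Sequential([nn.Flatten()])
    elif cfg.kind == "mlp":
        layers = [nn.Flatten()]
        d = int(np.prod(cfg.input_shape))
        for h in cfg.mlp_hidden:
            layers += [nn.Linear(d, h, rng), nn.ReLU()]
            d = h
        backbone = nn.Sequential(layers)
    else:
        raise ValueError(f"unknown backbone kind {cfg.kind!r}")
    heads = [nn.Linear(cfg.feature_dim, d, rng) for d in head_dims]
    return nn.Network(backbone, heads)


@dataclass
class ModelState:
    """A trained model: architecture + parameters + fitted preprocessing.

    Serializable with bit-identical predictions via :meth:`save` /
    :meth:`load` (an ``.npz`` parameter archive plus a JSON sidecar).
    """

    task: str  # direct | gaussian | classification | ordinal
    backbone: BackboneConfig
    head_dims: list
    params: list
    normalization: NormalizationParams
    scheme: IntervalScheme | None = None
    train_config: TrainConfig = field(default_factory=TrainConfig)
    val_losses: list = field(default_factory=list)
    best_epoch: int = -1

    def network(self) -> nn.Network:
        net = build_network(self.backbone, list(self.head_dims), self.train_config.seed)
        net.set_state(self.params)
        return net

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), *self.params)
        sidecar = {
            "task": self.task,
            "backbone": asdict(self.backbone),
            "head_dims": list(self.head_dims),
            "normalization": {"mean": self.normalization.mean, "sd": self.normalization.sd},
            "scheme": self.scheme.to_json_dict() if self.scheme else None,
            "train_config": asdict(self.train_config),
            "val_losses": [float(v) for v in self.val_losses],
            "best_epoch": self.best_epoch,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ModelState":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        bcfg = meta["backbone"]
        for key in ("channels_per_stage", "downsample_factors", "input_shape", "mlp_hidden"):
            bcfg[key] = tuple(bcfg[key])
        with np.load(path.with_suffix(".npz")) as f:
            params = [f[k] for k in sorted(f.files, key=lambda s: int(s.split("_")[1]))]
        return cls(
            task=meta["task"],
            backbone=BackboneConfig(**bcfg),
            head_dims=meta["head_dims"],
            params=params,
            normalization=NormalizationParams(**meta["normalization"]),
            scheme=IntervalScheme.from_json_dict(meta["scheme"]) if meta["scheme"] else None,
            train_config=TrainConfig(**meta["train_config"]),
            val_losses=meta["val_losses"],
            best_epoch=meta["best_epoch"],
        )


# ----------------------------------------------------------------------------
# Training
# ----------------------------------------------------------------------------

def _batched_eval_loss(net: nn.Network, X, targets, loss_fn, batch: int = 256) -> float:
    total, n = 0.0, len(X)
    for i in range(0, n, batch):
        _, outs = net.forward(X[i : i + batch])
        loss, _ = loss_fn(outs, targets[i : i + batch])
        total += loss * len(X[i : i + batch])
    return total / n


def _fit(
    net: nn.Network,
    train_X,
    train_t,
    val_X,
    val_t,
    loss_fn,
    cfg: TrainConfig,
):
    """Seeded minibatch training with best-validation-epoch selection."""
    if len(train_X) == 0:
        raise ValueError("empty training set")
    if len(val_X) == 0:
        raise ValueError("empty validation set")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(net.params(), lr=cfg.lr)
    best_loss, best_state, best_epoch = np.inf, net.get_state(), -1
    val_losses = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(train_X))
        for i in range(0, len(perm), cfg.batch_size):
            idx = perm[i : i + cfg.batch_size]
            net.zero_grad()
            _, outs = net.forward(train_X[idx], train=True)
            _, gouts = loss_fn(outs, train_t[idx])
            net.backward(gouts)
            opt.step(net.grads())
        vl = _batched_eval_loss(net, val_X, val_t, loss_fn)
        val_losses.append(vl)
        if vl < best_loss:
            best_loss, best_state, best_epoch = vl, net.get_state(), epoch
    net.set_state(best_state)
    return val_losses, best_epoch


def _train_regression(
    train: ArrayDataset,
    val: ArrayDataset,
    backbone: BackboneConfig,
    cfg: TrainConfig,
    task: str,
) -> ModelState:
    norm = fit_normalizer(train.y)
    zt, zv = norm.apply(train.y), norm.apply(val.y)
    if task == "direct":
        head_dims = [1]

        def loss_fn(outs, t):
            return nn.mse_loss(outs[0], t)

    elif task == "gaussian":
        head_dims = [1, 1]

        def loss_fn(outs, t):
            return nn.gaussian_nll_loss(outs[0], outs[1], t)

    else:  # pragma: no cover
        raise ValueError(task)
    net = build_network(backbone, head_dims, cfg.seed)
    val_losses, best_epoch = _fit(net, train.X, zt, val.X, zv, loss_fn, cfg)
    return ModelState(
        task=task,
        backbone=backbone,
        head_dims=head_dims,
        params=net.get_state(),
        normalization=norm,
        train_config=cfg,
        val_losses=val_losses,
        best_epoch=best_epoch,
    )


def train_direct(train, val, backbone: BackboneConfig, cfg: TrainConfig) -> ModelState:
    """Deep direct regression: MSE on z-scored targets."""
    return _train_regression(train, val, backbone, cfg, "direct")


def train_gaussian(train, val, backbone: BackboneConfig, cfg: TrainConfig) -> ModelState:
    """Heteroscedastic Gaussian regression trained by NLL."""
    return _train_regression(train, val, backbone, cfg, "gaussian")


def train_classifier(
    train, val, scheme: IntervalScheme, backbone: BackboneConfig, cfg: TrainConfig
) -> ModelState:
    """k-class cross-entropy model over the discretized targets."""
    norm = fit_normalizer(train.y)
    ct = assign_class(train.y, scheme) - 1
    cv = assign_class(val.y, scheme) - 1

    def loss_fn(outs, t):
        return nn.cross_entropy_loss(outs[0], t.astype(int))

    net = build_network(backbone, [scheme.k], cfg.seed)
    val_losses, best_epoch = _fit(net, train.X, ct, val.X, cv, loss_fn, cfg)
    return ModelState(
        task="classification",
        backbone=backbone,
        head_dims=[scheme.k],
        params=net.get_state(),
        normalization=norm,
        scheme=scheme,
        train_config=cfg,
        val_losses=val_losses,
        best_epoch=best_epoch,
    )


def train_ordinal(
    train, val, scheme: IntervalScheme, backbone: BackboneConfig, cfg: TrainConfig
) -> ModelState:
    """Rank-consistent ordinal model: k−1 cumulative thresholds, binary CE."""
    norm = fit_normalizer(train.y)
    et = ordinal_encode(assign_class(train.y, scheme), scheme.k)
    ev = ordinal_encode(assign_class(val.y, scheme), scheme.k)

    def loss_fn(outs, t):
        return nn.binary_cross_entropy_loss(outs[0], t)

    net = build_network(backbone, [scheme.k - 1], cfg.seed)
    val_losses, best_epoch = _fit(net, train.X, et, val.X, ev, loss_fn, cfg)
    return ModelState(
        task="ordinal",
        backbone=backbone,
        head_dims=[scheme.k - 1],
        params=net.get_state(),
        normalization=norm,
        scheme=scheme,
        train_config=cfg,
        val_losses=val_losses,
        best_epoch=best_epoch,
    )


# ----------------------------------------------------------------------------
# Prediction
# ----------------------------------------------------------------------------

def _batched_outputs(model: ModelState, X, batch: int = 256) -> list[np.ndarray]:
    net = model.network()
    outs: list[list[np.ndarray]] = None
    for i in range(0, len(X), batch):
        _, o = net.forward(X[i : i + batch])
        if outs is None:
            outs = [[oo] for oo in o]
        else:
            for acc, oo in zip(outs, o):
                acc.append(oo)
    if outs is None:
        return [np.zeros((0, d)) for d in model.head_dims]
    return [np.concatenate(acc) for acc in outs]


def predict(model: ModelState, X) -> np.ndarray:
    """Predicted concentration per trace, on the de-normalized scale.

    Discretized models predict the representative value of their predicted
    class.
    """
    if model.task in ("direct", "gaussian"):
        mu = _batched_outputs(model, X)[0].ravel()
        return model.normalization.invert(mu)
    return class_to_value(predict_class(model, X), model.scheme)


def predict_gaussian(model: ModelState, X) -> tuple[np.ndarray, np.ndarray]:
    """(mean, variance) on the concentration scale for a Gaussian model."""
    if model.task != "gaussian":
        raise ValueError("predict_gaussian requires a gaussian-head model")
    mu, raw = _batched_outputs(model, X)
    var = nn.softplus(raw.ravel().astype(float)) + nn.VAR_FLOOR
    return (
        model.normalization.invert(mu.ravel()),
        var * model.normalization.sd**2,
    )


def predict_proba(model: ModelState, X) -> np.ndarray:
    """Class probabilities (classification, (n,k)) or threshold probabilities
    (ordinal, (n,k−1))."""
    out = _batched_outputs(model, X)[0].astype(float)
    if model.task == "classification":
        z = out - out.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)
    if model.task == "ordinal":
        return nn.sigmoid(out)
    raise ValueError("predict_proba requires a discretized model")


def predict_class(model: ModelState, X) -> np.ndarray:
    """Predicted class in 1..k."""
    p = predict_proba(model, X)
    if model.task == "classification":
        return p.argmax(axis=1) + 1
    return ordinal_decode(p)


def gaussian_nll(mean, variance, targets) -> float:
    """Summed Gaussian negative log-likelihood.

    ``sum_i [ 0.5 log(2π σ²_i) + (y_i − μ_i)² / (2σ²_i) ]``; variances must
    be strictly positive.
    """
    mu = np.asarray(mean, dtype=float)
    var = np.asarray(variance, dtype=float)
    y = np.asarray(targets, dtype=float)
    if np.any(var <= 0):
        raise ValueError("variances must be strictly positive")
    return float(np.sum(0.5 * np.log(2 * np.pi * var) + (y - mu) ** 2 / (2 * var)))


# ----------------------------------------------------------------------------
# Non-deep baselines
# ----------------------------------------------------------------------------

def _report(pred: np.ndarray, y: np.ndarray) -> dict:
    err = pred - y
    return {"mse": float(np.mean(err**2)), "mae": float(np.mean(np.abs(err)))}


def fit_pca_baselines(
    train: ArrayDataset,
    test: ArrayDataset,
    n_components: int = 256,
    seed: int = 0,
    n_estimators: int = 60,
) -> dict:
    """PCA-reduced traditional regressors: linear, gradient boosting, random forest.

    PCA (randomized SVD) is fitted on the vectorized *training* traces only;
    the three regressors are fitted on the reduced training features and
    scored on the reduced test features. Returns per-model test MSE/MAE.
    """
    from sklearn.decomposition import PCA
    from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
    from sklearn.linear_model import LinearRegression

    xtr = train.X.reshape(len(train.X), -1)
    xte = test.X.reshape(len(test.X), -1)
    n_components = min(n_components, xtr.shape[0], xtr.shape[1])
    pca = PCA(n_components=n_components, svd_solver="randomized", random_state=seed)
    ztr = pca.fit_transform(xtr)
    zte = pca.transform(xte)

    models = {
        "linear": LinearRegression(),
        "gradient_boosting": GradientBoostingRegressor(
            n_estimators=n_estimators, random_state=seed
        ),
        "random_forest": RandomForestRegressor(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        ),
    }
    report = {"n_components": n_components}
    for name, est in models.items():
        est.fit(ztr, train.y)
        report[name] = _report(est.predict(zte), test.y)
    return report


def fit_batchwise_baselines(
    train: ArrayDataset,
    val: ArrayDataset,
    test: ArrayDataset,
    cfg: TrainConfig,
) -> dict:
    """Batch-wise linear model and 3-layer MLP on the raw flattened input.

    Trained with the same minibatch protocol, loss (MSE on z-scored targets)
    and best-validation selection as the deep models.
    """
    input_shape = tuple(train.X.shape[1:])
    report = {}
    for name, kind in (("batch_linear", "flatten"), ("mlp3", "mlp")):
        backbone = BackboneConfig(kind=kind, input_shape=input_shape)
        model = train_direct(train, val, backbone, cfg)
        report[name] = _report(predict(model, test.X), test.y)
    return report
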