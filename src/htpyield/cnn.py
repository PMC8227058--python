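"""Convolutional regressors for plot images and out-of-fold HTP traits.

The CNN regresses a per-plot yield trait (kg/ha) directly on the RGB plot
patch. Training uses Adam on a mean-squared-error loss with flip augmentation
(horizontal, vertical, both) of the training images, and k-fold
cross-validation: each plot's prediction comes from the model trained with
that plot held out, and the concatenated out-of-fold predictions form the
"HTP trait" fed to the genetic analysis.

Three architecture families are provided: a 4-conv batch-norm/average-pool
network with a dropout dense head ("macnn"), a small multi-stream late-fusion
network ("lfcnn"), and a deeper 5-conv/3-dense stack ("alexnet"). Widths are
configurable; parameter counts are reported by the builder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold

from . import nn
from .extraction import PlotImage
from .metrics import MetricSet, regression_metrics


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchSpec:
    """Architecture description: conv blocks as (filters, kernel, pool, batch_norm)."""

    name: str = "macnn"
    conv_blocks: tuple[tuple[int, int, int, bool], ...] = (
        (8, 3, 2, True),
        (16, 3, 2, True),
        (16, 3, 2, True),
        (32, 3, 1, True),
    )
    fc_sizes: tuple[int, ...] = (32,)
    dropout_rate: float = 0.2
    global_pool: bool = False
    pool_kind: str = "avg"  # "avg" | "max"
    n_streams: int = 1  # > 1 only for the late-fusion network

    def validate(self) -> None:
        if len(self.conv_blocks) < 1:
            raise ValueError("at least one conv block is required")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.pool_kind not in ("avg", "max"):
            raise ValueError(f"pool_kind must be 'avg' or 'max', got {self.pool_kind!r}")
        if self.n_streams < 1:
            raise ValueError("n_streams must be >= 1")


def macnn_spec(**overrides) -> ArchSpec:
    """4 conv layers with batch norm and average pooling, dropout dense head."""
    return replace(ArchSpec(name="macnn"), **overrides)


def macnn_table_spec() -> ArchSpec:
    """Wide variant (~1M parameters) of the 4-conv network."""
    return ArchSpec(
        name="macnn",
        conv_blocks=((64, 3, 2, True), (128, 3, 2, True), (256, 3, 2, True), (256, 3, 1, True)),
        fc_sizes=(256,),
        dropout_rate=0.2,
        global_pool=True,
    )


def lfcnn_spec(n_streams: int = 5) -> ArchSpec:
    """Multi-stream late fusion: 8 3x3 filters and a 16-unit dense per stream."""
    return ArchSpec(
        name="lfcnn",
        conv_blocks=((8, 3, 8, False),),
        fc_sizes=(16,),
        dropout_rate=0.0,
        pool_kind="max",
        n_streams=n_streams,
    )


def alexnet_spec() -> ArchSpec:
    """Deeper 5-conv / 3-dense stack with max pooling (no pretrained weights)."""
    return ArchSpec(
        name="alexnet",
        conv_blocks=((32, 3, 2, False), (64, 3, 2, False), (96, 3, 1, False),
                     (96, 3, 1, False), (64, 3, 2, False)),
        fc_sizes=(256, 128),
        dropout_rate=0.5,
        pool_kind="max",
    )


_PRESETS = {"macnn": macnn_spec, "lfcnn": lfcnn_spec, "alexnet": alexnet_spec}


def resolve_arch(arch: str | ArchSpec) -> ArchSpec:
    if isinstance(arch, ArchSpec):
        return arch
    if arch in _PRESETS:
        return _PRESETS[arch]()
    raise ValueError(f"unknown architecture {arch!r}; known: {sorted(_PRESETS)}")


def _build_stream(spec: ArchSpec, input_px: int, rng: np.random.Generator,
                  head: bool, head_sizes: tuple[int, ...]) -> tuple[nn.Sequential, int]:
    layers: list[nn.Layer] = []
    ch, side = 3, input_px
    for filters, kernel, pool, bnorm in spec.conv_blocks:
        layers.append(nn.Conv2d(ch, filters, kernel, pad=kernel // 2, rng=rng))
        if bnorm:
            layers.append(nn.BatchNorm2d(filters))
        layers.append(nn.ReLU())
        if pool > 1:
            if side % pool:
                raise ValueError(f"feature side {side} not divisible by pool {pool}")
            layers.append(nn.AvgPool2d(pool) if spec.pool_kind == "avg" else nn.MaxPool2d(pool))
            side //= pool
        ch = filters
    if spec.global_pool:
        layers.append(nn.GlobalAvgPool())
        feat = ch
    else:
        layers.append(nn.Flatten())
        feat = ch * side * side
    for size in head_sizes:
        layers.append(nn.Dense(feat, size, rng))
        layers.append(nn.ReLU())
        if spec.dropout_rate > 0:
            layers.append(nn.Dropout(spec.dropout_rate, rng))
        feat = size
    if head:
        layers.append(nn.Dense(feat, 1, rng))
    model = nn.Sequential(layers)
    return model, feat


class MultiStreamNet:
    """Late-fusion network: parallel conv streams over the input, fused by a dense head."""

    def __init__(self, spec: ArchSpec, input_px: int, rng: np.random.Generator):
        self.streams = []
        for _ in range(spec.n_streams):
            s, _ = _build_stream(spec, input_px, rng, head=True, head_sizes=spec.fc_sizes)
            self.streams.append(s)
        self.head = nn.Sequential([
            nn.Dense(spec.n_streams, 8, rng), nn.ReLU(), nn.Dense(8, 1, rng)
        ])

    def forward(self, x, train=False):
        outs = [s.forward(x, train) for s in self.streams]
        self._fused = np.concatenate(outs, axis=1)
        return self.head.forward(self._fused, train)

    def backward(self, dout):
        dfused = self.head.backward(dout)
        for i, s in enumerate(self.streams):
            s.backward(dfused[:, i : i + 1])
        return None

    def parameters(self):
        for s in self.streams:
            yield from s.parameters()
        yield from self.head.parameters()

    def n_params(self):
        return sum(s.n_params() for s in self.streams) + self.head.n_params()

    def state(self):
        return [s.state() for s in self.streams] + [self.head.state()]

    def load_state(self, state):
        for s, st in zip(self.streams, state[:-1]):
            s.load_state(st)
        self.head.load_state(state[-1])


def build_regressor(spec: str | ArchSpec, input_size: int = 64, seed: int = 0):
    """Instantiate a network with a single scalar output; init is seed-deterministic.

    Returns ``(model, n_params)``.
    """
    spec = resolve_arch(spec)
    spec.validate()
    rng = np.random.default_rng(seed)
    if spec.n_streams > 1:
        model = MultiStreamNet(spec, input_size, rng)
    else:
        model, _ = _build_stream(spec, input_size, rng, head=True, head_sizes=spec.fc_sizes)
    return model, model.n_params()


# ---------------------------------------------------------------------------
# training configuration / augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Adam + early-stopping settings (reference protocol: lr 0.001,
    beta1 0.9, beta2 0.999, eps 1e-8, MSE loss, validation checks every
    ``early_stop_interval`` epochs)."""

    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    epochs: int = 500
    batch_size: int = 256
    early_stop_interval: int = 100
    val_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size >= 1 and epochs >= 0 required")


def _as_pixel_array(images) -> np.ndarray:
    if isinstance(images, np.ndarray):
        arr = images
    else:
        arr = np.stack([im.pixels if isinstance(im, PlotImage) else np.asarray(im) for im in images])
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"expected (N, H, W, 3) images, got {arr.shape}")
    return arr


def augment_flips(img: PlotImage | np.ndarray):
    """[original, horizontal flip, vertical flip, both]. Labels are unchanged."""
    if isinstance(img, PlotImage):
        px = img.pixels
        return [
            img,
            PlotImage(img.plot_id, px[:, ::-1].copy()),
            PlotImage(img.plot_id, px[::-1, :].copy()),
            PlotImage(img.plot_id, px[::-1, ::-1].copy()),
        ]
    px = np.asarray(img)
    return [px, px[:, ::-1].copy(), px[::-1, :].copy(), px[::-1, ::-1].copy()]


def _augment_batch(x: np.ndarray) -> np.ndarray:
    # x is (N, C, H, W); flips act on the spatial axes
    return np.concatenate([x, x[:, :, :, ::-1], x[:, :, ::-1, :], x[:, :, ::-1, ::-1]])


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class CNNRegressor(BaseEstimator, RegressorMixin):
    """Image regressor: fit(images, y) / predict(images) over (N, H, W, 3) uint8 arrays.

    Internally standardizes the target on the training split (restored at
    prediction), holds out ``val_fraction`` of the training data for early
    stopping evaluated every ``early_stop_interval`` epochs, and augments the
    remaining training images with the three axis flips. Deterministic for a
    fixed ``random_state``.
    """

    def __init__(self, arch: str | ArchSpec = "macnn", input_px: int = 64,
                 learning_rate: float = 0.001, beta1: float = 0.9, beta2: float = 0.999,
                 adam_eps: float = 1e-8, epochs: int = 100, batch_size: int = 64,
                 early_stop_interval: int = 100, val_fraction: float = 0.1,
                 augment: bool = True, random_state: int = 0):
        self.arch = arch
        self.input_px = input_px
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.adam_eps = adam_eps
        self.epochs = epochs
        self.batch_size = batch_size
        self.early_stop_interval = early_stop_interval
        self.val_fraction = val_fraction
        self.augment = augment
        self.random_state = random_state

    def _prep(self, images) -> np.ndarray:
        arr = _as_pixel_array(images)
        if arr.shape[1] != self.input_px or arr.shape[2] != self.input_px:
            from PIL import Image

            arr = np.stack([
                np.asarray(Image.fromarray(a).resize((self.input_px, self.input_px)))
                for a in arr
            ])
        x = arr.astype(np.float32) / 255.0
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def fit(self, X, y):
        y = np.asarray(y, dtype=np.float64)
        if not np.isfinite(y).all():
            raise ValueError("targets must be finite")
        x = self._prep(X)
        n = len(x)
        if n != len(y):
            raise ValueError("images and targets must align")
        rng = np.random.default_rng(self.random_state)

        self.network_, self.n_params_ = build_regressor(self.arch, self.input_px,
                                                        seed=self.random_state)
        opt = nn.Adam(self.network_, lr=self.learning_rate, beta1=self.beta1,
                      beta2=self.beta2, eps=self.adam_eps)

        # validation slice of the training data for early stopping
        perm = rng.permutation(n)
        n_val = int(round(self.val_fraction * n)) if n > 10 else 0
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        x_tr, y_tr = x[tr_idx], y[tr_idx]
        x_val, y_val = x[val_idx], y[val_idx]

        self.y_mean_ = float(y_tr.mean())
        # a zero-variance target stays exactly at its mean on prediction
        self.y_std_ = float(y_tr.std())
        t_tr = ((y_tr - self.y_mean_) / (self.y_std_ or 1.0)).astype(np.float32)

        if self.augment:
            x_tr = _augment_batch(x_tr)
            t_tr = np.tile(t_tr, 4)

        n_tr = len(x_tr)
        bs = min(self.batch_size, n_tr)
        self.loss_trace_ = []
        best_val = np.inf
        best_state = None
        for epoch in range(1, self.epochs + 1):
            order = rng.permutation(n_tr)
            losses = []
            for start in range(0, n_tr, bs):
                idx = order[start : start + bs]
                pred = self.network_.forward(x_tr[idx], train=True)
                loss, dloss = nn.mse_loss(pred[:, 0], t_tr[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(f"training diverged (NaN loss) at epoch {epoch}")
                self.network_.backward(dloss[:, None].astype(np.float32))
                opt.step()
                losses.append(loss)
            self.loss_trace_.append(float(np.mean(losses)))

            if n_val and self.early_stop_interval and epoch % self.early_stop_interval == 0:
                val_pred = self._forward_eval(x_val)
                val_mse = float(np.mean(
                    (val_pred - (y_val - self.y_mean_) / (self.y_std_ or 1.0)) ** 2))
                if val_mse < best_val:
                    best_val = val_mse
                    best_state = self.network_.state()
                else:
                    if best_state is not None:
                        self.network_.load_state(best_state)
                    self.stopped_epoch_ = epoch
                    break
        return self

    def _forward_eval(self, x: np.ndarray) -> np.ndarray:
        out = []
        for start in range(0, len(x), 256):
            out.append(self.network_.forward(x[start : start + 256], train=False)[:, 0])
        return np.concatenate(out) if out else np.empty(0)

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted")
        x = self._prep(X)
        z = self._forward_eval(x)
        return z * self.y_std_ + self.y_mean_


def train_fold(model: CNNRegressor, images, targets, cfg: TrainConfig | None = None):
    """Fit one fold's regressor; returns (fitted model, loss trace)."""
    if cfg is not None:
        cfg.validate()
        model.set_params(
            learning_rate=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2,
            adam_eps=cfg.adam_eps, epochs=cfg.epochs, batch_size=cfg.batch_size,
            early_stop_interval=cfg.early_stop_interval, val_fraction=cfg.val_fraction,
            random_state=cfg.seed,
        )
    model.fit(images, targets)
    return model, model.loss_trace_


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class HTPTrait:
    """Out-of-fold CNN predictions, one per plot — the image-derived trait."""

    plot_ids: np.ndarray
    values: np.ndarray
    folds: np.ndarray
    trait_name: str
    arch_name: str
    fold_metrics: list[MetricSet] = field(default_factory=list)


def crossval_predict(images, targets, arch: str | ArchSpec = "macnn", k: int = 10,
                     seed: int = 0, trait_name: str = "TDMY",
                     **estimator_params) -> HTPTrait:
    """k-fold out-of-fold prediction with a fresh regressor per fold.

    The data are randomly partitioned into k near-equal folds; augmentation is
    applied inside ``fit`` to training images only, so no augmented copy of a
    plot ever reaches the fold where that plot is tested.
    """
    arr = _as_pixel_array(images)
    y = np.asarray(targets, dtype=float)
    n = len(arr)
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} plots")
    if k < 2:
        raise ValueError("k must be >= 2")
    plot_ids = np.array([
        im.plot_id if isinstance(im, PlotImage) else i + 1
        for i, im in enumerate(images if not isinstance(images, np.ndarray) else range(n))
    ])

    spec = resolve_arch(arch)
    yhat = np.full(n, np.nan)
    folds = np.full(n, -1, dtype=int)
    metrics: list[MetricSet] = []
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(kf.split(arr)):
        est = CNNRegressor(arch=spec, random_state=seed + 1000 * (fold + 1), **estimator_params)
        est.fit(arr[tr], y[tr])
        yhat[te] = est.predict(arr[te])
        folds[te] = fold
        metrics.append(regression_metrics(y[te], yhat[te]))

    return HTPTrait(
        plot_ids=plot_ids,
        values=yhat,
        folds=folds,
        trait_name=trait_name,
        arch_name=spec.name,
        fold_metrics=metrics,
    )
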