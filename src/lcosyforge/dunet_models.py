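"""Densely connected U-Net models for NUS reconstruction and quantitation.

The network is an encoder-decoder over the 512 x 32 spectral window.  Each
encoder level applies a dense block (every 3x3 convolution sees the
concatenation of the block input and all previous block outputs, ReLU
activations) followed by 2x2 max pooling; the decoder mirrors it with 2x
nearest upsampling, skip concatenation from the encoder and a dense block,
after a 1x1 channel compression.  A final 1x1 projection maps to the output
channels: (real, imaginary, magnitude) for reconstruction, 17 per-metabolite
magnitude windows for quantitation.  Magnitude and quantitation channels get
a non-negative (ReLU) output activation; real/imaginary channels stay
linear.

Two operating profiles are declared: ``full`` mirrors the published training
scale and is supported by configuration; ``desk`` is the package's reduced
reference profile sized for single-CPU training, used by the test suite and
the acceptance experiments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import nn
from .synthesizer import ChannelStack, SpectrumDataset

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainedModel",
    "DUNet",
    "build_dunet",
    "train_model",
    "reconstruct_spectrum",
    "quantify_spectrum",
    "DUNetRegressor",
    "save_checkpoint",
    "load_checkpoint",
    "DESK_PROFILE",
    "FULL_PROFILE",
]

#: Reduced single-CPU reference profile (declared once; see docs/methods.md).
DESK_PROFILE = dict(depth=5, base_filters=4, growth=4, epochs=16,
                    n_train=600)
#: Published-scale profile; supported by configuration, not exercised by the
#: test suite.
FULL_PROFILE = dict(depth=4, base_filters=32, growth=16, epochs=100,
                    n_train=40000)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (kernel 3x3 and stride 1 are fixed)."""

    in_channels: int = 3
    out_channels: int = 3
    depth: int = 5                  # number of pooling levels
    base_filters: int = 4           # dense-block growth at the first level
    growth: int = 4                 # per-level increment of the growth
    convs_per_block: int = 2        # encoder dense-block convolutions
    coord_channels: bool = True     # concatenate ppm-position maps inside
    io_gain: float = 1.0            # input scale / output scale divisor
    head_hidden: int = 24           # hidden width of the 1x1 output head
    nonneg_channels: tuple = (2,)   # output channels forced non-negative
    out_activation: str = "abs"     # "abs" | "relu" on nonneg channels

    def __post_init__(self):
        if not 1 <= self.depth <= 5:
            raise ValueError("depth must be in 1..5 (32-bin axis halves)")
        if self.base_filters < 1 or self.growth < 0:
            raise ValueError("invalid filter configuration")

    def level_growth(self, level: int) -> int:
        return self.base_filters + self.growth * level


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    batch: int = 10
    epochs: int = 16
    val_fraction: float = 0.1
    seed: int = 0
    profile: str = "desk"

    def __post_init__(self):
        if self.lr < 0:
            raise ValueError("lr must be >= 0")
        if self.batch < 1:
            raise ValueError("batch must be >= 1")


class DUNet:
    """The dense U-Net graph; built by :func:`build_dunet`."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        c = config
        self.enc_blocks = []
        ch = c.in_channels + (2 if c.coord_channels else 0)
        for level in range(c.depth):
            block, ch_out = self._make_block(ch, c.level_growth(level),
                                             c.convs_per_block, rng)
            self.enc_blocks.append(block)
            ch = ch_out
        self.bottleneck, ch = self._make_block(
            ch, c.level_growth(c.depth), c.convs_per_block, rng)
        self.dec_compress = []
        self.dec_blocks = []
        for level in reversed(range(c.depth)):
            g = c.level_growth(level)
            self.dec_compress.append(nn.Conv2d(ch, g, kernel=1, rng=rng))
            skip_ch = c.convs_per_block * g
            block, ch = self._make_block(skip_ch + g, g, 1, rng)
            self.dec_blocks.append(block)
        head_in = ch + c.convs_per_block * c.level_growth(0) \
            + c.in_channels + (2 if c.coord_channels else 0)
        if c.head_hidden > 0:
            self.head_pre = nn.Conv2d(head_in, c.head_hidden, kernel=1,
                                      rng=rng)
            head_in = c.head_hidden
        else:
            self.head_pre = None
        self.head = nn.Conv2d(head_in, c.out_channels, kernel=1, rng=rng)
        # start the output head near zero so optimization begins at the
        # zero-prediction baseline instead of random high-amplitude output
        self.head.weight.data *= 0.1

    @staticmethod
    def _make_block(in_ch, growth, n_convs, rng):
        convs = []
        ch = in_ch
        for _ in range(n_convs):
            convs.append(nn.Conv2d(ch, growth, kernel=3, rng=rng))
            ch += growth
        return convs, n_convs * growth

    @staticmethod
    def _run_block(convs, x):
        feats = [x]
        outs = []
        for conv in convs:
            y = nn.relu(conv(nn.concat(feats) if len(feats) > 1 else feats[0]))
            feats.append(y)
            outs.append(y)
        return nn.concat(outs) if len(outs) > 1 else outs[0]

    def params(self):
        ps = []
        for block in (*self.enc_blocks, self.bottleneck, *self.dec_blocks):
            for conv in block:
                ps.extend(conv.params())
        for conv in self.dec_compress:
            ps.extend(conv.params())
        if self.head_pre is not None:
            ps.extend(self.head_pre.params())
        ps.extend(self.head.params())
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def forward(self, x: np.ndarray) -> nn.Tensor:
        c = self.config
        if x.ndim != 4 or x.shape[1] != c.in_channels:
            raise ValueError(
                f"expected (n, {c.in_channels}, H, W) input, got {x.shape}")
        if x.shape[2] % 2 ** c.depth or x.shape[3] % 2 ** c.depth:
            raise ValueError(
                f"spatial dims {x.shape[2:]} not divisible by 2^{c.depth}")
        xs = np.asarray(x, dtype=np.float32)
        if c.io_gain != 1.0:
            # normalize the working scale internally (0-100 inputs train
            # poorly with fixed-step Adam); the head un-scales outputs
            xs = xs / np.float32(c.io_gain)
        t = nn.Tensor(np.ascontiguousarray(xs.transpose(0, 2, 3, 1)))
        if c.coord_channels:
            # fixed position maps: a CNN is translation-equivariant, but
            # metabolite identity depends on absolute ppm coordinates
            n, h, w, _ = t.data.shape
            hh = np.linspace(-1, 1, h, dtype=np.float32)
            ww = np.linspace(-1, 1, w, dtype=np.float32)
            coords = np.empty((n, h, w, 2), dtype=np.float32)
            coords[..., 0] = hh[:, None]
            coords[..., 1] = ww[None, :]
            t = nn.concat([t, nn.Tensor(coords)])
        x_in = t
        skips = []
        for block in self.enc_blocks:
            t = self._run_block(block, t)
            skips.append(t)
            t = nn.maxpool2(t)
        t = self._run_block(self.bottleneck, t)
        for compress, block, skip in zip(self.dec_compress, self.dec_blocks,
                                         reversed(skips)):
            t = nn.upsample2(compress(t))
            t = self._run_block(block, nn.concat([skip, t]))
        t = nn.concat([x_in, skips[0], t])
        if self.head_pre is not None:
            t = nn.relu(self.head_pre(t))
        t = self.head(t)
        act = nn.abs_channels if c.out_activation == "abs" \
            else nn.relu_channels
        t = act(t, list(self.config.nonneg_channels))
        if c.io_gain != 1.0:
            t = nn.scale(t, float(c.io_gain))
        return t

    def predict(self, x: np.ndarray, batch: int = 20) -> np.ndarray:
        """Inference forward pass; returns (n, out_channels, H, W)."""
        outs = [self.forward(x[i:i + batch]).data.transpose(0, 3, 1, 2)
                for i in range(0, len(x), batch)]
        return np.concatenate(outs, axis=0)

    def get_weights(self):
        return [p.data.copy() for p in self.params()]

    def set_weights(self, weights):
        for p, w in zip(self.params(), weights):
            p.data[...] = w


def build_dunet(config: ModelConfig, seed: int = 0) -> DUNet:
    """Construct a dense U-Net with seeded He initialization."""
    return DUNet(config, np.random.default_rng(seed))


@dataclass
class TrainedModel:
    """Weights plus the configuration and loss history that produced them."""

    model: DUNet
    model_config: ModelConfig
    train_config: TrainConfig
    loss_history: list = field(default_factory=list)
    val_loss_history: list = field(default_factory=list)
    dataset_hash: str = ""
    task: str = "recon"


def _dataset_hash(X: np.ndarray, y: np.ndarray) -> str:
    import hashlib
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X[:2]).tobytes())
    h.update(str(X.shape).encode() + str(y.shape).encode())
    return h.hexdigest()[:16]


def _nhwc(a: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(a.transpose(0, 2, 3, 1))


def train_model(model: DUNet, dataset, tc: TrainConfig) -> TrainedModel:
    """Train with Adam on the mean-squared-error loss, tracking per-epoch
    training and validation losses and returning the best-validation
    weights."""
    if isinstance(dataset, SpectrumDataset):
        X, y, task = dataset.inputs, dataset.targets, dataset.task
    else:
        X, y = dataset
        task = "recon" if y.shape[1] == model.config.out_channels == 3 \
            else "quant"
    if len(X) == 0:
        raise ValueError("empty dataset")
    if y.shape[1] != model.config.out_channels:
        raise ValueError(
            f"dataset targets have {y.shape[1]} channels, model expects "
            f"{model.config.out_channels}")

    rng = np.random.default_rng(tc.seed)
    n_val = max(1, int(round(tc.val_fraction * len(X)))) \
        if len(X) > 1 else 0
    perm = rng.permutation(len(X))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[train_idx], _nhwc(y[train_idx])
    Xva, yva = X[val_idx], y[val_idx]

    opt = nn.Adam(model.params(), lr=tc.lr)
    history, val_history = [], []
    best_val, best_weights = np.inf, model.get_weights()
    for _ in range(tc.epochs):
        order = rng.permutation(len(Xtr))
        total = 0.0
        for i in range(0, len(order), tc.batch):
            idx = order[i:i + tc.batch]
            opt.zero_grad()
            loss = nn.mse_loss(model.forward(Xtr[idx]), ytr[idx])
            loss.backward()
            if tc.lr > 0:
                opt.step()
            total += float(loss.data) * len(idx)   # sample-weighted mean
        history.append(total / len(order))
        if n_val:
            pv = model.predict(Xva)
            val = float(np.mean((pv - yva) ** 2))
        else:
            val = history[-1]
        val_history.append(val)
        if val <= best_val:
            best_val = val
            best_weights = model.get_weights()
    model.set_weights(best_weights)
    return TrainedModel(model, model.config, tc, history, val_history,
                        _dataset_hash(X, y), task)


# ---------------------------------------------------------------------------
# inference wrappers
# ---------------------------------------------------------------------------

def _check_stack(stack: ChannelStack, scale: float, what: str):
    if stack.data.shape[0] != 3:
        raise ValueError(f"{what} expects a 3-channel stack")
    if stack.target_scale != scale:
        raise ValueError(
            f"{what} expects inputs at scale 0-{scale:g}, got "
            f"0-{stack.target_scale:g}")


def reconstruct_spectrum(trained: TrainedModel,
                         stack: ChannelStack) -> ChannelStack:
    """Reconstruct a NUS spectrum stack (scale 0-1) with a recon model."""
    if trained.task != "recon":
        raise ValueError("model was not trained for reconstruction")
    _check_stack(stack, 1.0, "reconstruct_spectrum")
    out = trained.model.predict(stack.data[None])[0]
    return ChannelStack(out, stack.scale_max, 1.0)


def quantify_spectrum(trained: TrainedModel,
                      stack: ChannelStack) -> ChannelStack:
    """Predict 17 per-metabolite magnitude windows (canonical order) from a
    fully sampled spectrum stack at scale 0-100."""
    if trained.task != "quant":
        raise ValueError("model was not trained for quantitation")
    _check_stack(stack, 100.0, "quantify_spectrum")
    out = trained.model.predict(stack.data[None])[0]
    return ChannelStack(out, stack.scale_max, 100.0)


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class DUNetRegressor(BaseEstimator, RegressorMixin):
    """Dense U-Net image-to-image regressor with the scikit-learn API.

    ``fit(X, y)`` expects X of shape (n, 3, H, W) and y of shape
    (n, out_channels, H, W) with H, W divisible by 2**depth; the number of
    output channels is taken from y.  Predictions preserve the target
    layout.  All randomness (init, shuffling, validation split) derives
    from ``seed``.
    """

    def __init__(self, depth=5, base_filters=4, growth=4, convs_per_block=2,
                 epochs=16, lr=1e-3, batch_size=10, val_fraction=0.1,
                 nonneg_channels="auto", io_gain="auto", seed=0):
        self.depth = depth
        self.base_filters = base_filters
        self.growth = growth
        self.convs_per_block = convs_per_block
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.nonneg_channels = nonneg_channels
        self.io_gain = io_gain
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if X.ndim != 4 or y.ndim != 4 or len(X) != len(y):
            raise ValueError("X and y must be (n, channels, H, W) with "
                             "matching n")
        out_ch = y.shape[1]
        if self.nonneg_channels == "auto":
            nonneg = (2,) if out_ch == 3 else tuple(range(out_ch))
        else:
            nonneg = tuple(self.nonneg_channels)
        if self.io_gain == "auto":
            # 0-100-scaled data trains poorly at unit working scale
            gain = 100.0 if float(np.abs(y).max()) > 2.0 else 1.0
        else:
            gain = float(self.io_gain)
        config = ModelConfig(in_channels=X.shape[1], out_channels=out_ch,
                             depth=self.depth, base_filters=self.base_filters,
                             growth=self.growth,
                             convs_per_block=self.convs_per_block,
                             io_gain=gain,
                             nonneg_channels=nonneg)
        tc = TrainConfig(lr=self.lr, batch=self.batch_size,
                         epochs=self.epochs, val_fraction=self.val_fraction,
                         seed=self.seed)
        model = build_dunet(config, seed=self.seed)
        task = "recon" if out_ch == 3 else "quant"
        trained = train_model(model, (X, y), tc)
        trained.task = task
        self.model_ = model
        self.trained_ = trained
        self.config_ = config
        self.loss_history_ = trained.loss_history
        self.val_loss_history_ = trained.val_loss_history
        self.n_parameters_ = model.n_parameters()
        return self

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise AttributeError("DUNetRegressor is not fitted")
        X = np.asarray(X, dtype=np.float32)
        return self.model_.predict(X)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(trained: TrainedModel, path) -> None:
    weights = trained.model.get_weights()
    meta = {
        "model_config": asdict(trained.model_config),
        "train_config": asdict(trained.train_config),
        "loss_history": trained.loss_history,
        "val_loss_history": trained.val_loss_history,
        "dataset_hash": trained.dataset_hash,
        "task": trained.task,
        "version": 1,
    }
    np.savez(path, meta=json.dumps(meta),
             **{f"w{i}": w for i, w in enumerate(weights)})


def load_checkpoint(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        if meta.get("version") != 1:
            raise ValueError("unsupported checkpoint version")
        weights = [f[f"w{i}"] for i in range(len(f.files) - 1)]
    mc = dict(meta["model_config"])
    mc["nonneg_channels"] = tuple(mc["nonneg_channels"])
    config = ModelConfig(**mc)
    model = build_dunet(config, seed=0)
    model.set_weights(weights)
    tc = TrainConfig(**meta["train_config"])
    return TrainedModel(model, config, tc, meta["loss_history"],
                        meta["val_loss_history"], meta["dataset_hash"],
                        meta["task"])
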