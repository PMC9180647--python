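"""1-D CNN and ResNet classifiers for residue-level spectra.

The CNN is a three-stage convolutional funnel (output channels 128, 64, 32;
kernels 3, 3, 5; stride 1; padding 1; BN+ReLU after each convolution),
followed by average pooling (kernel 2), flattening, two fully connected
blocks of 256 and 128 neurons (linear -> BN -> ReLU -> dropout 0.5), and a
linear output over the 4 residue levels. Convolution lengths follow
L_out = L_in + 2*padding - kernel + 1; the pool halves the length.

The ResNet uses a 64-channel stem convolution (kernel 3, padding 1, BN+ReLU)
and three basic residual blocks with channels 64, 128, 256 (two kernel-3
convolutions each, projected skips on channel changes), global average
pooling over the band axis, and a 256 -> 4 linear head — so the pooled
feature length is 256 regardless of the band count.

Training is mini-batch Adam on softmax cross-entropy with Xavier-initialized
weights; all randomness (init, shuffling, dropout) derives from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classical import ModelResult
from .dataset import SpectralDataset
from .evaluation import SplitIndices, accuracy
from .nn import (
    Adam,
    AvgPool1d,
    BatchNorm,
    Conv1d,
    DivergenceError,
    Dropout,
    Flatten,
    GlobalAvgPool1d,
    Linear,
    ReLU,
    ResidualBlock,
    Sequential,
    softmax_cross_entropy,
)
from .nn.layers import DTYPE, ArchitectureError


@dataclass
class CnnSpec:
    conv_out_channels: tuple[int, int, int] = (128, 64, 32)
    kernel_sizes: tuple[int, int, int] = (3, 3, 5)
    stride: int = 1
    padding: int = 1
    avgpool_kernel: int = 2
    fc_sizes: tuple[int, int] = (256, 128)
    dropout: float = 0.5
    n_classes: int = 4

    def __post_init__(self) -> None:
        if len(self.conv_out_channels) != 3 or len(self.kernel_sizes) != 3:
            raise ValueError("expected three convolutional stages")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class ResNetSpec:
    stem_out_channels: int = 64
    stem_kernel: int = 3
    padding: int = 1
    block_channels: tuple[int, int, int] = (64, 128, 256)
    block_kernel: int = 3
    n_classes: int = 4

    def __post_init__(self) -> None:
        if list(self.block_channels) != sorted(self.block_channels):
            raise ValueError("block channels must be nondecreasing")


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


#: full-scale training budgets (epochs, batch, learning rate) for the two
#: architectures; desk-scale runs use fewer epochs with a matched step size
CNN_FULL_BUDGET = TrainConfig(epochs=500, batch_size=32, learning_rate=1e-3)
RESNET_FULL_BUDGET = TrainConfig(epochs=1000, batch_size=32, learning_rate=5e-3)


class SpectralNet:
    """A built network plus its layer table; implements the scorer protocol."""

    def __init__(self, net: Sequential, n_bands: int, arch: str) -> None:
        self.net = net
        self.n_bands = n_bands
        self.arch = arch
        self.summary = self._summarize()

    def _summarize(self) -> list[tuple[str, tuple[int, ...], int]]:
        rows = []
        shape: tuple[int, ...] = (1, self.n_bands)
        for layer in self.net.layers:
            shape = layer.out_shape(shape)
            rows.append((type(layer).__name__, shape, layer.param_count()))
        return rows

    def describe(self) -> str:
        lines = [f"{self.arch} ({self.n_bands} bands)",
                 f"{'layer':<16}{'output shape':<18}{'params':>10}"]
        for name, shape, count in self.summary:
            lines.append(f"{name:<16}{str(shape):<18}{count:>10d}")
        lines.append(f"{'total':<34}{self.param_count():>10d}")
        return "\n".join(lines)

    def param_count(self) -> int:
        return self.net.param_count()

    def _as_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.dtype not in (np.float32, np.float64):
            X = X.astype(DTYPE)
        return X[:, None, :]

    def forward(self, X: np.ndarray, training: bool,
                rng: np.random.Generator | None = None) -> np.ndarray:
        rng = rng or np.random.default_rng(0)
        return self.net.forward(self._as_batch(X), training, rng)

    def class_scores(self, X: np.ndarray) -> np.ndarray:
        """Pre-softmax logits in evaluation mode (deterministic)."""
        return self.forward(X, training=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.class_scores(X), axis=1)

    def score_input_gradient(self, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
        """d(score of the given class)/d(input spectrum), one row per sample.

        Evaluation mode: dropout off, batch-norm frozen at running
        statistics, so the gradient is deterministic. One backward pass
        serves the whole batch because each row's output gradient selects
        only that row's class.
        """
        scores = self.forward(X, training=False)
        grad_out = np.zeros_like(scores)
        grad_out[np.arange(len(X)), np.asarray(classes, dtype=int)] = 1.0
        grad_in = self.net.backward(grad_out)
        return grad_in[:, 0, :].astype(float)


def build_cnn(n_bands: int, spec: CnnSpec | None = None, seed: int = 0) -> SpectralNet:
    """Assemble the spectral CNN; raises ArchitectureError on length underflow."""
    spec = spec or CnnSpec()
    rng = np.random.default_rng(seed)
    chans = spec.conv_out_channels
    layers: list = []
    in_ch = 1
    for out_ch, k in zip(chans, spec.kernel_sizes):
        layers += [Conv1d(in_ch, out_ch, k, spec.padding, rng),
                   BatchNorm(out_ch), ReLU()]
        in_ch = out_ch
    layers += [AvgPool1d(spec.avgpool_kernel), Flatten()]

    # shape arithmetic for the flattened feature length
    shape: tuple[int, ...] = (1, n_bands)
    for layer in layers:
        shape = layer.out_shape(shape)
    n_features = shape[0]

    in_f = n_features
    for fc in spec.fc_sizes:
        layers += [Linear(in_f, fc, rng), BatchNorm(fc), ReLU(), Dropout(spec.dropout)]
        in_f = fc
    layers += [Linear(in_f, spec.n_classes, rng)]
    return SpectralNet(Sequential(layers), n_bands, "cnn")


def build_resnet(n_bands: int, spec: ResNetSpec | None = None, seed: int = 0) -> SpectralNet:
    """Assemble the spectral ResNet; pooled features are 256 for any band count."""
    spec = spec or ResNetSpec()
    if n_bands < 4:
        raise ArchitectureError("resnet requires at least 4 bands")
    rng = np.random.default_rng(seed)
    layers: list = [Conv1d(1, spec.stem_out_channels, spec.stem_kernel, spec.padding, rng),
                    BatchNorm(spec.stem_out_channels), ReLU()]
    in_ch = spec.stem_out_channels
    for out_ch in spec.block_channels:
        layers.append(ResidualBlock(in_ch, out_ch, spec.block_kernel, spec.padding, rng))
        in_ch = out_ch
    layers += [GlobalAvgPool1d(), Linear(in_ch, spec.n_classes, rng)]
    return SpectralNet(Sequential(layers), n_bands, "resnet")


def _recalibrate_batchnorm(net: Sequential, X: np.ndarray, batch_size: int = 256) -> None:
    """Recompute BN running statistics as the average of batch statistics.

    Mini-batch training leaves running estimates lagging the final weights
    (and biased by small trailing batches), which opens a train/eval gap.
    One sweep over the training set with cumulative-average momentum and
    dropout disabled resets them to population estimates under the final
    weights.
    """
    bns = [m for m in net.modules() if isinstance(m, BatchNorm)]
    drops = [m for m in net.modules() if isinstance(m, Dropout)]
    saved_momentum = [bn.momentum for bn in bns]
    saved_p = [d.p for d in drops]
    try:
        for d in drops:
            d.p = 0.0
        rng = np.random.default_rng(0)
        for i, start in enumerate(range(0, len(X), batch_size)):
            for bn in bns:
                bn.momentum = 1.0 / (i + 1)
            net.forward(X[start:start + batch_size][:, None, :], True, rng)
    finally:
        for bn, m in zip(bns, saved_momentum):
            bn.momentum = m
        for d, p in zip(drops, saved_p):
            d.p = p


def train_model(model: SpectralNet, ds: SpectralDataset, split: SplitIndices,
                cfg: TrainConfig | None = None) -> ModelResult:
    """Mini-batch Adam training; returns split accuracies and the loss history.

    The per-epoch entry of the loss history is the mean mini-batch loss of
    that epoch. After the last epoch the batch-norm running statistics are
    recalibrated over the training split so evaluation reflects the final
    weights. A non-finite loss aborts with the offending epoch.
    """
    cfg = cfg or TrainConfig()
    if ds.y.min() < 0 or ds.y.max() >= model.summary[-1][1][0]:
        raise ValueError("labels outside the model's class range")
    rng = np.random.default_rng(cfg.seed)
    X_tr = ds.X[split.train].astype(DTYPE)
    y_tr = ds.y[split.train]
    optimizer = Adam(model.net, lr=cfg.learning_rate)
    history = []
    n = len(y_tr)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            scores = model.net.forward(X_tr[idx][:, None, :], True, rng)
            loss, grad = softmax_cross_entropy(scores, y_tr[idx])
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            model.net.backward(grad)
            optimizer.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))

    _recalibrate_batchnorm(model.net, X_tr)
    preds = {name: model.predict(ds.X[getattr(split, name)])
             for name in ("train", "val", "test")}
    accs = {name: accuracy(preds[name], ds.y[getattr(split, name)])
            for name in ("train", "val", "test")}
    return ModelResult(
        model_kind=model.arch, accuracies=accs, predictions=preds, seed=cfg.seed,
        best_params={"epochs": cfg.epochs, "batch_size": cfg.batch_size,
                     "learning_rate": cfg.learning_rate},
        model=model, loss_history=np.array(history),
    )
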