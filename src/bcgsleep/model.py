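"""LSTM-TCN sleep-stage sequence classifier.

The published architecture: a sequence input feeds two bidirectional LSTM
layers (125 then 100 hidden units, dropout 0.2 after each), whose 200-wide
output enters a temporal convolutional network of four residual blocks.
Each block holds two causal dilated 1-D convolutions (64 filters, kernel 5,
dilation doubling per block), each followed by per-channel layer
normalization, ReLU and spatial dropout (0.005); the first block lifts its
skip path with a 1x1 convolution because the channel counts differ.  A
fully-connected layer and softmax give per-epoch probabilities over the
five stages (W, N1, N2, N3, REM).

With 62 input features the three variants carry 690,885 (combined),
469,805 (LSTM-only) and 169,093 (TCN-only) trainable parameters; the
parameter count is a pure function of the config and is asserted against
closed-form sums in the tests.

Training keeps each session's sleep cycle intact as one sequence (no
shuffling of epochs across sessions), uses class-weighted cross-entropy,
Adam, and a single integer seed for initialization and dropout.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from bcgsleep import nn
from bcgsleep.signal_io import STAGES, STAGES_3CLASS


@dataclasses.dataclass
class ModelConfig:
    input_dim: int = 62
    bilstm_units: tuple[int, int] = (125, 100)
    bilstm_dropout: float = 0.2
    n_blocks: int = 4
    conv_filters: int = 64
    kernel_size: int = 5
    spatial_dropout: float = 0.005
    n_classes: int = 5
    variant: str = "lstm-tcn"   # lstm-tcn | lstm | tcn

    def __post_init__(self) -> None:
        if self.variant not in ("lstm-tcn", "lstm", "tcn"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not (0 <= self.bilstm_dropout < 1 and 0 <= self.spatial_dropout < 1):
            raise ValueError("dropout rates must be in [0, 1)")
        if min(self.input_dim, self.n_blocks, self.conv_filters,
               self.kernel_size, self.n_classes) < 1:
            raise ValueError("all size parameters must be positive")


@dataclasses.dataclass
class TrainingConfig:
    lr: float = 1e-3
    max_passes: int = 40
    seed: int = 0
    patience: Optional[int] = None   # stop after this many passes without improvement
    min_delta: float = 1e-4


@dataclasses.dataclass
class TrainedModel:
    config: ModelConfig
    net: nn.Sequential
    classes: tuple[str, ...]
    loss_log: list[float]
    seed: int


def receptive_field(f: int, K: int) -> int:
    """TCN receptive field R = (f-1)(2^K - 1) + 1.

    ``K`` here counts stacked dilated convolutional layers with dilation
    doubling per layer (the per-block convention, where both convolutions
    of a block share the block's dilation, gives a smaller field; reporting
    in this package uses this per-layer formula).
    """
    if f < 1 or K < 1:
        raise ValueError("kernel size and layer count must be >= 1")
    return (f - 1) * (2 ** K - 1) + 1


def _tcn_layers(cfg: ModelConfig, c_in: int, rng: np.random.Generator
                ) -> list[nn.Layer]:
    layers: list[nn.Layer] = []
    for b in range(cfg.n_blocks):
        dilation = 2 ** b
        layers.append(nn.ResidualBlock(
            c_in if b == 0 else cfg.conv_filters, cfg.conv_filters,
            cfg.kernel_size, dilation, cfg.spatial_dropout, rng))
    return layers


def build_model(cfg: ModelConfig, seed: int = 0) -> nn.Sequential:
    """Instantiate the requested variant; parameter count is determined by
    the config alone."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    if cfg.variant in ("lstm-tcn", "lstm"):
        d = cfg.input_dim
        for units in cfg.bilstm_units:
            layers.append(nn.BiLSTM(d, units, rng))
            layers.append(nn.Dropout(cfg.bilstm_dropout))
            d = 2 * units
        head_in = d
    else:
        head_in = cfg.input_dim
    if cfg.variant in ("lstm-tcn", "tcn"):
        layers.extend(_tcn_layers(cfg, head_in, rng))
        head_in = cfg.conv_filters
    layers.append(nn.Dense(head_in, cfg.n_classes, rng))
    return nn.Sequential(layers, rng)


def count_parameters(cfg: ModelConfig) -> int:
    return build_model(cfg, seed=0).n_params()


def _class_weights(sequences, classes) -> np.ndarray:
    counts = np.zeros(len(classes))
    for _, y in sequences:
        counts += np.bincount(y, minlength=len(classes))
    present = counts > 0
    weights = np.zeros(len(classes))
    # inverse-frequency weights, renormalized over present classes
    weights[present] = counts[present].sum() / (present.sum() * counts[present])
    if not present.all():
        import warnings
        absent = [classes[i] for i in np.flatnonzero(~present)]
        warnings.warn(f"classes absent from training data: {absent}",
                      stacklevel=2)
    return weights


def encode_labels(stages: Sequence[str], classes: Sequence[str]) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([lookup[s] for s in stages], dtype=int)
    except KeyError as exc:
        raise ValueError(f"label outside class set: {exc}") from exc


def train(cfg: ModelConfig,
          sequences: Sequence[tuple[np.ndarray, np.ndarray]],
          training: TrainingConfig = TrainingConfig(),
          classes: Optional[tuple[str, ...]] = None) -> TrainedModel:
    """Fit the model on whole-session sequences.

    ``sequences`` is a list of (X of shape (T, F), integer labels of shape
    (T,)); each session stays one intact sequence.  The loss log records
    the mean weighted cross-entropy per pass; a fixed seed reproduces it
    exactly.
    """
    if classes is None:
        classes = STAGES if cfg.n_classes == 5 else STAGES_3CLASS
    if len(classes) != cfg.n_classes:
        raise ValueError("class list does not match n_classes")
    for X, y in sequences:
        if X.shape[0] != y.shape[0]:
            raise ValueError("labels misaligned with feature rows")
        if X.shape[1] != cfg.input_dim:
            raise ValueError("feature dimension does not match config")

    net = build_model(cfg, seed=training.seed)
    order_rng = np.random.default_rng(training.seed + 1)
    weights = _class_weights(sequences, classes)
    opt = nn.Adam(net, lr=training.lr)
    loss_log: list[float] = []
    best = np.inf
    stale = 0
    for _ in range(training.max_passes):
        order = order_rng.permutation(len(sequences))
        total = 0.0
        for idx in order:
            X, y = sequences[idx]
            net.zero_grad()
            logits = net.forward(X, train=True)
            loss, dlogits = nn.weighted_cross_entropy(logits, y, weights)
            net.backward(dlogits)
            opt.step()
            total += loss
        mean_loss = total / len(sequences)
        loss_log.append(mean_loss)
        if training.patience is not None:
            if mean_loss < best - training.min_delta:
                best, stale = mean_loss, 0
            else:
                stale += 1
                if stale >= training.patience:
                    break
    return TrainedModel(cfg, net, tuple(classes), loss_log, training.seed)


def predict(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Per-epoch class probabilities and argmax labels (dropout inactive)."""
    if X.shape[1] != model.config.input_dim:
        raise ValueError("feature dimension does not match the trained model")
    logits = model.net.forward(X, train=False)
    probs = nn.softmax(logits)
    labels = [model.classes[i] for i in probs.argmax(axis=1)]
    return probs, labels
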