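"""The binary sway-spectrogram CNN and its training regime.

Architecture: a feature extractor of three convolutional and three
max-pooling layers feeding a classifier of three dense layers ending in
two class scores.  Training is full-batch (the entire training tensor in
one Adam step per epoch) with cross-entropy loss, learning rate 1e-4 and
weight decay 1e-3 over 1000 epochs by default.  Kernel sizes, channel
counts, activations and pooling type are free design parameters (the
protocol fixes only the 3/3/3 structure); the defaults below are the
smallest plausible net for 250 x 250 inputs, and
:meth:`ModelConfig.reduced_benchmark` is a desk-scale preset profiled
for single-CPU replicate studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .nn import Adam, CNNCore, cross_entropy, softmax

__all__ = ["ModelConfig", "SwayCNN", "TrainedModel", "build_model", "train"]


def _tuple3(v):
    t = (v,) * 3 if np.isscalar(v) else tuple(v)
    if len(t) != 3:
        raise ValueError(f"expected 3 stages, got {len(t)}")
    return t


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    The structural invariant — exactly three conv, three pool and three
    dense stages with a binary head — is enforced at construction.
    """

    conv_channels: tuple = (8, 16, 32)
    kernel_size: tuple = (3, 3, 3)
    conv_strides: tuple = (1, 1, 1)
    pool_sizes: tuple = (2, 2, 2)
    dense_widths: tuple = (128, 32, 2)
    learning_rate: float = 1e-4
    weight_decay: float = 1e-3
    epochs: int = 1000
    seed: int = 0
    input_shape: tuple = (250, 250)

    def __post_init__(self):
        for name in ("conv_channels", "kernel_size", "conv_strides",
                     "pool_sizes", "dense_widths"):
            object.__setattr__(self, name, _tuple3(getattr(self, name)))
        if self.dense_widths[-1] != 2:
            raise ValueError("final dense width must be 2 (binary classifier)")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs must be >= 1 and learning_rate > 0")

    @classmethod
    def reduced_benchmark(cls, seed=0) -> "ModelConfig":
        """Desk-scale preset for replicate studies on one CPU: a 10 x 10
        patch-embedding first convolution, two 3 x 3 convolutions,
        time-axis-only max pooling (the frequency axis keeps its 26-band
        resolution through the feature extractor, which the Grad-CAM
        attribution inherits), and a learning rate scaled for a 200-epoch
        run."""
        return cls(
            conv_channels=(4, 8, 16), kernel_size=(10, 3, 3),
            conv_strides=(10, 1, 1), pool_sizes=((1, 4), (1, 2), (1, 2)),
            dense_widths=(64, 32, 2), learning_rate=5e-4,
            weight_decay=1e-3, epochs=200, seed=seed,
        )

    def to_dict(self):
        return asdict(self)

    def with_seed(self, seed) -> "ModelConfig":
        return replace(self, seed=int(seed))


class SwayCNN:
    """An (untrained or trained) instance of the classifier."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.core = CNNCore(
            input_hw=config.input_shape,
            conv_channels=config.conv_channels,
            kernel_size=config.kernel_size,
            conv_strides=config.conv_strides,
            pool_sizes=config.pool_sizes,
            dense_widths=config.dense_widths,
            seed=config.seed,
        )

    @property
    def n_params(self) -> int:
        return self.core.n_params()

    def predict_logits(self, x) -> np.ndarray:
        return self.core.predict_logits(x)

    def predict_proba(self, x) -> np.ndarray:
        """Softmax class probabilities, shape (n, 2); column 1 is PD."""
        return softmax(self.predict_logits(x).astype(np.float64))

    def predict(self, x) -> np.ndarray:
        return self.predict_logits(x).argmax(axis=1)


def build_model(config: ModelConfig) -> SwayCNN:
    """Construct the classifier with seed-deterministic initialization."""
    return SwayCNN(config)


@dataclass
class TrainedModel:
    """A trained classifier plus its config and per-epoch learning curve.

    The curve records, per epoch, the training loss/accuracy of the
    full-batch forward pass that produced that epoch's gradient step and
    the validation loss/accuracy evaluated after the step; its final row
    therefore scores the returned parameters.
    """

    model: SwayCNN
    config: ModelConfig
    curve: pd.DataFrame

    @property
    def final_val_accuracy(self) -> float:
        return float(self.curve["val_acc"].iloc[-1])


def train(model: SwayCNN, x_train, y_train, x_val, y_val,
          config: ModelConfig = None) -> TrainedModel:
    """Full-batch Adam training with cross-entropy loss.

    One optimizer step per epoch over the entire (normalized) training
    tensor.  The im2col expansion of the first convolution is computed
    once per dataset and reused every epoch — the arithmetic is identical,
    the inputs being constant.  Aborts on non-finite loss.
    """
    config = config or model.config
    core = model.core
    y_train = np.asarray(y_train, dtype=np.int64)
    y_val = np.asarray(y_val, dtype=np.int64)
    cols_train = core.conv0_cols(x_train)
    cols_val = core.conv0_cols(x_val) if len(x_val) else None
    opt = Adam(core.params, lr=config.learning_rate,
               weight_decay=config.weight_decay)
    records = []
    for epoch in range(config.epochs):
        logits, caches = core.forward(cols0=cols_train, want_caches=True)
        loss, dlogits = cross_entropy(logits, y_train)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss at epoch {epoch}: {loss!r}; "
                f"logit range [{logits.min()}, {logits.max()}]"
            )
        train_acc = float((logits.argmax(axis=1) == y_train).mean())
        grads = core.backward(caches, dlogits)
        opt.step(core.params, grads)
        if cols_val is not None:
            vlogits = core.forward(cols0=cols_val)
            vloss, _ = cross_entropy(vlogits, y_val)
            val_acc = float((vlogits.argmax(axis=1) == y_val).mean())
        else:
            vloss, val_acc = np.nan, np.nan
        records.append((epoch, loss, train_acc, vloss, val_acc))
    curve = pd.DataFrame(
        records, columns=["epoch", "train_loss", "train_acc",
                          "val_loss", "val_acc"]
    )
    return TrainedModel(model=model, config=config, curve=curve)
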