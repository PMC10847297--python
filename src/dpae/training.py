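"""Supervised denoising training (mixture → clean) and inference wrappers."""

from __future__ import annotations

import dataclasses

import numpy as np

from .contamination import PairDataset
from .model import Model
from .nn import Adam
from .nn import tensor as T
from .signals import SegmentSet, SignalSegment


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite training loss at epoch {epoch}")
        self.epoch = epoch


@dataclasses.dataclass
class TrainingConfig:
    """Optimizer settings for supervised denoising.

    Defaults follow the reference protocol: Adam, MSE loss, batch size 128,
    learning rate 1e-3, 200 epochs.
    """

    batch_size: int = 128
    learning_rate: float = 1e-3
    epochs: int = 200
    optimizer: str = "adam"
    loss: str = "mse"
    seed: int = 0
    rms_scale_inputs: bool = False  # optional per-segment RMS scaling (off: raw units)

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size, epochs and learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss != "mse":
            raise ValueError("only the mse loss is supported")


@dataclasses.dataclass
class TrainingHistory:
    train_loss: list[float]
    val_loss: list[float] | None = None

    @property
    def epochs_run(self) -> int:
        return len(self.train_loss)


def _dataset_arrays(dataset: PairDataset, input_len: int, rms_scale: bool):
    clean, mixed, _ = dataset.to_arrays()
    if mixed.shape[1] != input_len:
        raise ValueError(f"pair length {mixed.shape[1]} != model input length {input_len}")
    if rms_scale:
        scale = np.sqrt(np.mean(mixed**2, axis=1, keepdims=True))
        mixed = mixed / scale
        clean = clean / scale
    return clean, mixed


def train(
    model: Model,
    dataset: PairDataset,
    config: TrainingConfig | None = None,
    validation: PairDataset | None = None,
) -> tuple[Model, TrainingHistory]:
    """Minimize MSE(model(mixed), clean) with Adam.

    Data order is reshuffled every epoch from the config seed; the epoch
    loss reported is the sample-weighted mean of the batch losses.  No early
    stopping: validation loss, when a validation set is given, is recorded
    but never used for control.
    """
    config = config or TrainingConfig()
    clean, mixed, = _dataset_arrays(dataset, model.input_len, config.rms_scale_inputs)
    val_arrays = (
        _dataset_arrays(validation, model.input_len, config.rms_scale_inputs)
        if validation is not None
        else None
    )
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    n = mixed.shape[0]
    history = TrainingHistory(train_loss=[], val_loss=[] if validation is not None else None)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb = mixed[idx]
            yb = T.Tensor(clean[idx].astype(model.dtype))
            optimizer.zero_grad()
            out = model.forward(xb, training=True)
            loss = T.mse(out, yb)
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(idx)
        epoch_loss /= n
        if not np.isfinite(epoch_loss):
            raise DivergenceError(epoch)
        history.train_loss.append(epoch_loss)
        if val_arrays is not None:
            v_clean, v_mixed = val_arrays
            v_out = model.predict(v_mixed)
            history.val_loss.append(float(np.mean((v_out - v_clean) ** 2)))
    return model, history


def denoise(model: Model, segments: SegmentSet) -> SegmentSet:
    """Apply a trained model to each segment; outputs are labelled 'denoised'."""
    if segments.length != model.input_len:
        raise ValueError(f"segment length {segments.length} != model input length {model.input_len}")
    out = model.predict(segments.to_matrix())
    return SegmentSet(
        [SignalSegment(row, fs=segments.fs, source="denoised") for row in out],
        seed=segments.seed,
    )


def denoise_multichannel(model: Model, trial: np.ndarray) -> np.ndarray:
    """Channel-by-channel denoising of a (channels, samples) trial matrix.

    Each channel is fed through the single-channel model independently;
    channel order and matrix shape are preserved.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2:
        raise ValueError("trial must be a 2-D channels×samples matrix")
    if trial.shape[1] != model.input_len:
        raise ValueError(
            f"trial has {trial.shape[1]} samples per channel; model expects {model.input_len}"
        )
    # one channel at a time: channel results are bit-identical to
    # single-segment inference regardless of batching kernels
    return np.stack([model.predict(channel) for channel in trial])
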