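"""Desk-scale experiment orchestration: ablation, backbone benchmark,
multichannel evaluation, and model-scale reporting.

Every experiment is reproducible from its config and seed; when an output
directory is configured, the config, per-epoch histories, metric curves and
the estimator parameters are written there as YAML/CSV.
"""

from __future__ import annotations

import dataclasses
import importlib.metadata
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import metrics as M
from .contamination import DEFAULT_SNR_GRID_DB, PairDataset, build_pair_dataset
from .model import (
    ArchitectureSpec,
    LayerSpec,
    Model,
    build_backbone_variant,
    canonical_mlp_table1,
    count_flops,
    count_params,
)
from .signals import GENERATORS, SegmentSet, gen_clean_eeg, split_train_test
from .training import TrainingConfig, TrainingHistory, denoise_multichannel, train

ABLATIONS = ("full", "no_fusion", "no_residual")


@dataclasses.dataclass
class ExperimentConfig:
    artifact: str = "emg"
    backbones: tuple[str, ...] = ("mlp",)
    include_fcnn_baseline: bool = False
    snr_levels: tuple[float, ...] = DEFAULT_SNR_GRID_DB
    train_pairs_per_level: int = 200
    test_pairs_per_level: int = 50
    segment_length: int = 512
    fs: float = 256.0
    epochs: int = 50
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0
    outdir: str | None = None
    canonical_mlp: bool = True  # use the published 512-input widths for the MLP

    def __post_init__(self) -> None:
        if self.artifact not in ("eog", "emg"):
            raise ValueError("artifact must be 'eog' or 'emg'")
        for b in self.backbones:
            if b not in ("mlp", "cnn", "rnn"):
                raise ValueError(f"unknown backbone {b!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def fcnn_spec(input_len: int = 512, width: int = 1024, depth: int = 4) -> ArchitectureSpec:
    """Plain fully connected baseline: ``depth`` equal-width SeLU hidden layers.

    Included for relative comparison only; it is deliberately a heavier,
    structureless stack against which the dual-pathway model's economy shows.
    """
    layers = [LayerSpec("input", "input", input_len)]
    prev = "input"
    for i in range(1, depth + 1):
        layers.append(LayerSpec(f"dense_{i}", "dense", width, (prev,)))
        prev = f"dense_{i}"
    layers.append(LayerSpec("output", "output", input_len, (prev,)))
    return ArchitectureSpec(input_len=input_len, layers=layers, backbone="mlp",
                            use_fusion=False, use_residual=False)


def _pool_size(per_level_train: int, per_level_test: int, n_levels: int) -> int:
    # sized so that (a) per-level sampling without replacement works after the
    # 80/20 split and (b) segments are barely reused across pairs — surrogate
    # sources are free, and source diversity is what keeps training honest
    return int(np.ceil(max(per_level_train * n_levels / 0.8,
                           per_level_test * n_levels / 0.2))) + 2


def make_datasets(config: ExperimentConfig) -> tuple[PairDataset, PairDataset]:
    """Generate surrogate sources and build disjoint train/test pair sets.

    Clean and artifact pools are split 80/20 first, so test mixtures use
    segments the model never saw during training.
    """
    n_pool = _pool_size(config.train_pairs_per_level, config.test_pairs_per_level,
                        len(config.snr_levels))
    seed = config.seed
    cleans = gen_clean_eeg(n_pool, config.segment_length, config.fs, seed=seed * 7 + 1)
    artifacts = GENERATORS[config.artifact](
        n_pool, config.segment_length, config.fs, seed=seed * 7 + 2
    )
    clean_tr, clean_te = split_train_test(cleans, 0.8, seed=seed * 7 + 3)
    art_tr, art_te = split_train_test(artifacts, 0.8, seed=seed * 7 + 4)
    train_set = build_pair_dataset(
        clean_tr, art_tr, config.snr_levels, config.train_pairs_per_level, seed=seed * 7 + 5
    )
    test_set = build_pair_dataset(
        clean_te, art_te, config.snr_levels, config.test_pairs_per_level, seed=seed * 7 + 6
    )
    return train_set, test_set


def _training_config(config: ExperimentConfig) -> TrainingConfig:
    return TrainingConfig(
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        seed=config.seed,
    )


def _build(config: ExperimentConfig, backbone: str, use_fusion: bool = True,
           use_residual: bool = True) -> Model:
    if backbone == "fcnn":
        spec = fcnn_spec(config.segment_length)
    elif backbone == "mlp" and config.canonical_mlp and config.segment_length == 512:
        spec = canonical_mlp_table1(use_fusion=use_fusion, use_residual=use_residual)
    else:
        spec = build_backbone_variant(config.segment_length, backbone,
                                      use_fusion=use_fusion, use_residual=use_residual)
    return Model(spec, seed=config.seed)


def _write_outputs(config: ExperimentConfig, name: str, tables: dict[str, pd.DataFrame]) -> None:
    if config.outdir is None:
        return
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "experiment": name,
        "package_version": importlib.metadata.version("dpae"),
        "psd_params": dict(M.PSD_PARAMS),
        "config": config.to_dict(),
    }
    (outdir / f"{name}_config.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    for key, frame in tables.items():
        frame.to_csv(outdir / f"{name}_{key}.csv", index=False)


@dataclasses.dataclass
class AblationResult:
    histories: dict[str, TrainingHistory]
    table: pd.DataFrame


def run_ablation(config: ExperimentConfig, loss_threshold: float = 0.5) -> AblationResult:
    """Train the full model and its two ablations under one seed and dataset.

    Variants: ``full`` (fusion block + residual additions), ``no_fusion``
    (concatenated features project directly to the decoder branches) and
    ``no_residual`` (the two elementwise additions removed).  All three see
    identical data order and hyperparameters; the comparison table reports
    final training loss and the first epoch at which the loss drops below
    ``loss_threshold``.
    """
    if config.backbones != ("mlp",):
        raise ValueError("the ablation protocol runs on the mlp backbone")
    train_set, _ = make_datasets(config)
    tc = _training_config(config)
    flags = {"full": (True, True), "no_fusion": (False, True), "no_residual": (True, False)}
    histories: dict[str, TrainingHistory] = {}
    rows = []
    for variant in ABLATIONS:
        use_fusion, use_residual = flags[variant]
        model = _build(config, "mlp", use_fusion=use_fusion, use_residual=use_residual)
        _, hist = train(model, train_set, tc)
        histories[variant] = hist
        below = [i + 1 for i, l in enumerate(hist.train_loss) if l < loss_threshold]
        rows.append({
            "variant": variant,
            "final_loss": hist.train_loss[-1],
            "epochs_to_threshold": below[0] if below else None,
            "epochs": hist.epochs_run,
        })
    table = pd.DataFrame(rows)
    losses = pd.DataFrame({v: h.train_loss for v, h in histories.items()})
    losses.insert(0, "epoch", np.arange(1, len(losses) + 1))
    _write_outputs(config, "ablation", {"summary": table, "losses": losses})
    return AblationResult(histories=histories, table=table)


@dataclasses.dataclass
class BenchmarkResult:
    curves: dict[str, dict[str, M.MetricCurve]]
    reference: dict[str, M.MetricCurve]
    report: pd.DataFrame
    histories: dict[str, TrainingHistory]


def run_benchmark(config: ExperimentConfig) -> BenchmarkResult:
    """Train each configured model on one dataset and evaluate per-SNR curves.

    Returns metric curves per model, the raw-mixture reference curves, and a
    table of trainable parameters and forward FLOPs per model.
    """
    names = list(config.backbones) + (["fcnn"] if config.include_fcnn_baseline else [])
    if not names:
        raise ValueError("no models configured")
    train_set, test_set = make_datasets(config)
    tc = _training_config(config)
    curves: dict[str, dict[str, M.MetricCurve]] = {}
    histories: dict[str, TrainingHistory] = {}
    reference: dict[str, M.MetricCurve] = {}
    rows = []
    for name in names:
        model = _build(config, name)
        _, hist = train(model, train_set, tc)
        histories[name] = hist
        model_curves, ref = M.evaluate_per_snr(model.predict, test_set, fs=config.fs)
        curves[name] = model_curves
        reference = ref
        rows.append({
            "model": name,
            "params": count_params(model.spec),
            "flops": count_flops(model.spec),
            "final_train_loss": hist.train_loss[-1],
        })
    report = pd.DataFrame(rows)
    tables = {"report": report}
    for name, model_curves in curves.items():
        tables[f"curves_{name}"] = M.curves_to_frame(model_curves)
    tables["curves_reference"] = M.curves_to_frame(reference)
    _write_outputs(config, "benchmark", tables)
    return BenchmarkResult(curves=curves, reference=reference, report=report, histories=histories)


def run_multichannel_eval(
    config: ExperimentConfig,
    model: Model,
    trials: np.ndarray | Sequence[np.ndarray],
) -> tuple[dict[str, M.MetricCurve], dict[str, M.MetricCurve]]:
    """Contaminate multichannel trials with EMG per SNR level and denoise.

    ``trials`` is one (channels, samples) matrix or a stack of them; each
    channel is treated as a clean reference, contaminated at every SNR level
    of the grid, denoised channel by channel, and scored with the metrics
    pooled over channels and trials.  Returns (denoised curves, raw-mixture
    reference curves).
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim == 2:
        trials = trials[None, ...]
    if trials.ndim != 3 or trials.shape[2] != model.input_len:
        raise ValueError(
            f"trials must be (n, channels, {model.input_len}); got {trials.shape}"
        )
    from .contamination import mix  # local import to avoid cycle at module load
    from .signals import SignalSegment, gen_emg

    n_trials, n_channels, _ = trials.shape
    n_channel_segs = n_trials * n_channels
    emg = gen_emg(n_channel_segs, config.segment_length, config.fs, seed=config.seed * 7 + 11)
    pairs = []
    k = 0
    for trial in trials:
        for channel in trial:
            clean = SignalSegment(channel, fs=config.fs, source="eeg")
            for level in config.snr_levels:
                pairs.append(mix(clean, emg[k], float(level)))
            k += 1
    dataset = PairDataset(pairs=pairs, snr_levels=tuple(config.snr_levels),
                          count_per_level=n_channel_segs, seed=config.seed)

    def denoise_fn(mixed_matrix: np.ndarray) -> np.ndarray:
        return denoise_multichannel(model, mixed_matrix)

    denoised_curves, ref = M.evaluate_per_snr(denoise_fn, dataset, fs=config.fs)
    _write_outputs(config, "multichannel", {
        "curves": M.curves_to_frame(denoised_curves),
        "curves_reference": M.curves_to_frame(ref),
    })
    return denoised_curves, ref
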