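"""Denoising quality metrics: temporal/spectral RRMSE, Pearson CC, band powers.

RRMSE_temporal(y, x) = RMS(y − x) / RMS(x)
RRMSE_spectral(y, x) = RMS(PSD(y) − PSD(x)) / RMS(PSD(x))
CC(y, x)             = cov(y, x) / (std(y)·std(x))

with x the paired clean ground truth.  PSDs are Welch estimates (Hann taper,
256-sample windows, 50% overlap by default); the estimator parameters are
carried into every result so spectral values are comparable across runs.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .contamination import PairDataset, rms


@dataclasses.dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float


#: Conventional EEG rhythm bands (Hz).
EEG_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 80.0),
)

#: Default Welch estimator parameters, recorded alongside every result.
PSD_PARAMS = {"nperseg": 256, "noverlap": 128, "window": "hann"}


def rrmse_temporal(denoised, clean) -> float:
    """Relative root-mean-square error in the time domain."""
    d = np.asarray(getattr(denoised, "samples", denoised), dtype=float)
    c = np.asarray(getattr(clean, "samples", clean), dtype=float)
    if d.shape != c.shape:
        raise ValueError(f"shape mismatch: {d.shape} vs {c.shape}")
    denom = rms(c)
    if denom == 0:
        raise ValueError("clean reference has zero power")
    return rms(d - c) / denom


def psd(
    segment,
    fs: float,
    nperseg: int = PSD_PARAMS["nperseg"],
    noverlap: int | None = None,
    window: str = PSD_PARAMS["window"],
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power-spectral-density estimate of one segment.

    Returns (frequencies in Hz spanning 0…fs/2, density in amplitude²/Hz).
    """
    x = np.asarray(getattr(segment, "samples", segment), dtype=float)
    if x.size < nperseg:
        raise ValueError(f"segment of {x.size} samples is shorter than the {nperseg}-sample window")
    if noverlap is None:
        noverlap = nperseg // 2
    return sps.welch(x, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap)


def rrmse_spectral(denoised, clean, fs: float, **psd_kwargs) -> float:
    """Relative RMS error between Welch PSDs (same estimator for both)."""
    _, p_d = psd(denoised, fs, **psd_kwargs)
    _, p_c = psd(clean, fs, **psd_kwargs)
    denom = rms(p_c)
    if denom == 0:
        raise ValueError("clean reference has zero spectral power")
    return rms(p_d - p_c) / denom


def cc(denoised, clean) -> float:
    """Pearson correlation coefficient between two segments."""
    d = np.asarray(getattr(denoised, "samples", denoised), dtype=float)
    c = np.asarray(getattr(clean, "samples", clean), dtype=float)
    if d.shape != c.shape:
        raise ValueError(f"shape mismatch: {d.shape} vs {c.shape}")
    if np.std(d) == 0 or np.std(c) == 0:
        raise ValueError("zero-variance input")
    return float(np.corrcoef(d, c)[0, 1])


def band_power(frequencies: np.ndarray, power: np.ndarray, band: BandDefinition) -> float:
    """Trapezoidal integral of a power density over one band."""
    if band.lo < frequencies[0] or band.hi > frequencies[-1]:
        raise ValueError(
            f"band {band.name} [{band.lo}, {band.hi}] Hz outside frequency support "
            f"[{frequencies[0]}, {frequencies[-1]}] Hz"
        )
    mask = (frequencies >= band.lo) & (frequencies <= band.hi)
    return float(np.trapezoid(power[mask], frequencies[mask]))


def band_power_fraction(frequencies: np.ndarray, power: np.ndarray, lo: float, hi: float) -> float:
    """Fraction of total integrated power lying inside [lo, hi] Hz."""
    total = np.trapezoid(power, frequencies)
    if total == 0:
        return 0.0
    mask = (frequencies >= lo) & (frequencies <= hi)
    return float(np.trapezoid(power[mask], frequencies[mask]) / total)


METRICS: dict[str, Callable] = {
    "rrmse_temporal": rrmse_temporal,
    "rrmse_spectral": rrmse_spectral,
    "cc": cc,
}


@dataclasses.dataclass
class MetricCurve:
    """Per-SNR-level mean and dispersion of one metric over a test set."""

    metric: str
    snr_levels: tuple[float, ...]
    values: np.ndarray          # mean per level
    dispersion: np.ndarray      # standard deviation across pairs per level
    n_per_level: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.snr_levels) == len(self.values) == len(self.dispersion)):
            raise ValueError("snr_levels, values and dispersion must have equal lengths")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": self.metric,
                "snr_db": self.snr_levels,
                "mean": self.values,
                "sd": self.dispersion,
                "n": self.n_per_level,
            }
        )


def curves_to_frame(curves: dict[str, MetricCurve]) -> pd.DataFrame:
    return pd.concat([c.to_frame() for c in curves.values()], ignore_index=True)


def evaluate_per_snr(
    denoise_fn: Callable[[np.ndarray], np.ndarray] | None,
    test: PairDataset,
    fs: float | None = None,
    metrics: Sequence[str] = ("rrmse_temporal", "rrmse_spectral", "cc"),
) -> tuple[dict[str, MetricCurve], dict[str, MetricCurve]]:
    """Per-SNR metric curves for a denoiser, plus the raw-mixture reference.

    ``denoise_fn`` maps an (n, length) matrix of mixtures to an (n, length)
    matrix of denoised segments; ``None`` evaluates only the reference (the
    untouched mixture).  Returns ``(denoised_curves, reference_curves)``,
    each keyed by metric name.  Per-segment metrics are averaged within each
    SNR level; dispersion is the across-segment standard deviation.
    """
    if fs is None:
        fs = test.pairs[0].clean.fs
    clean_mat, mixed_mat, snr_vec = test.to_arrays()
    out_mat = denoise_fn(mixed_mat) if denoise_fn is not None else mixed_mat

    def _curves(estimates: np.ndarray) -> dict[str, MetricCurve]:
        curves: dict[str, MetricCurve] = {}
        for name in metrics:
            fn = METRICS[name]
            means, sds, ns, levels = [], [], [], []
            for level in test.snr_levels:
                sel = np.flatnonzero(snr_vec == level)
                if sel.size == 0:
                    continue  # empty level: omitted
                if name == "rrmse_spectral":
                    vals = [fn(estimates[i], clean_mat[i], fs) for i in sel]
                else:
                    vals = [fn(estimates[i], clean_mat[i]) for i in sel]
                levels.append(level)
                means.append(np.mean(vals))
                sds.append(np.std(vals))
                ns.append(sel.size)
            curves[name] = MetricCurve(
                metric=name,
                snr_levels=tuple(levels),
                values=np.array(means),
                dispersion=np.array(sds),
                n_per_level=np.array(ns),
            )
        return curves

    denoised_curves = _curves(out_mat)
    reference_curves = denoised_curves if denoise_fn is None else _curves(mixed_mat)
    return denoised_curves, reference_curves
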