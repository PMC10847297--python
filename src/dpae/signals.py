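"""Fixed-length EEG/EOG/EMG segments and band-limited surrogate generators.

Everything downstream works on 2 s windows sampled at 256 Hz (512 samples),
the segment geometry of the EEGdenoiseNet benchmark.  The generators here do
not attempt physiological realism; they reproduce the band structure of the
benchmark sources — clean EEG band-limited to 1–80 Hz (with a visible alpha
rhythm), ocular artifacts to 0.3–10 Hz (slow drifts plus blink transients),
and muscular artifacts to 1–120 Hz (broadband activity in bursts) — and
normalize every segment to unit RMS so that artifact scaling coefficients are
determined by the requested SNR alone.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import signal as sps

DEFAULT_FS = 256.0
DEFAULT_LENGTH = 512

SOURCES = ("eeg", "eog", "emg", "mixed", "denoised")


@dataclasses.dataclass(frozen=True)
class SignalSegment:
    """A single fixed-length, single-channel signal window.

    Parameters
    ----------
    samples
        1-D array of real amplitudes (arbitrary units).
    fs
        Sampling rate in Hz.
    source
        One of ``{"eeg", "eog", "emg", "mixed", "denoised"}``.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    source: str = "eeg"

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {SOURCES}")
        object.__setattr__(self, "samples", arr)

    @property
    def length(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Window duration in seconds."""
        return self.length / self.fs


@dataclasses.dataclass
class SegmentSet:
    """An ordered, homogeneous collection of segments of one source."""

    segments: list[SignalSegment]
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("SegmentSet requires at least one segment")
        first = self.segments[0]
        for seg in self.segments:
            if seg.fs != first.fs or seg.length != first.length or seg.source != first.source:
                raise ValueError("all segments must share fs, length and source")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[SignalSegment]:
        return iter(self.segments)

    def __getitem__(self, idx: int) -> SignalSegment:
        return self.segments[idx]

    @property
    def fs(self) -> float:
        return self.segments[0].fs

    @property
    def length(self) -> int:
        return self.segments[0].length

    @property
    def source(self) -> str:
        return self.segments[0].source

    def to_matrix(self) -> np.ndarray:
        """Stack segments into an (n_segments, length) matrix."""
        return np.stack([seg.samples for seg in self.segments])

    @classmethod
    def from_matrix(
        cls, matrix: np.ndarray, fs: float, source: str, seed: int | None = None
    ) -> "SegmentSet":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2:
            raise ValueError(f"expected a 2-D segment matrix, got ndim={matrix.ndim}")
        segs = [SignalSegment(row, fs=fs, source=source) for row in matrix]
        return cls(segs, seed=seed)


def _check_gen_args(n: int, length: int, fs: float, min_fs: float) -> None:
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < 64:
        raise ValueError("length must be >= 64 samples")
    if fs <= min_fs:
        raise ValueError(f"fs must exceed {min_fs} Hz so the band edge stays below Nyquist")


def _bandpass(x: np.ndarray, lo: float, hi: float, fs: float, order: int = 4) -> np.ndarray:
    # zero-phase forward-backward IIR; edge transients are tolerated because
    # segments are isolated windows, not stream excerpts
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _unit_rms(x: np.ndarray) -> np.ndarray:
    r = np.sqrt(np.mean(x**2))
    if r == 0:
        raise ValueError("degenerate all-zero segment")
    return x / r


def _pink_noise(rng: np.random.Generator, length: int, fs: float) -> np.ndarray:
    """1/f-power-weighted Gaussian noise (amplitude ∝ f^-1/2)."""
    white = rng.standard_normal(length)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(length, d=1.0 / fs)
    weight = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    weight[0] = 0.0
    return np.fft.irfft(spec * weight, n=length)


def gen_clean_eeg(
    n: int, length: int = DEFAULT_LENGTH, fs: float = DEFAULT_FS, seed: int = 0
) -> SegmentSet:
    """Surrogate clean-EEG segments, band-limited to 1–80 Hz.

    Each segment is 1/f-weighted noise plus an alpha-band (8–13 Hz)
    oscillation of random frequency/phase/amplitude, band-pass filtered to
    1–80 Hz and normalized to unit RMS.  Deterministic given ``seed``.
    """
    _check_gen_args(n, length, fs, min_fs=160.0)
    rng = np.random.default_rng(seed)
    t = np.arange(length) / fs
    segs = []
    for _ in range(n):
        x = _pink_noise(rng, length, fs)
        f_alpha = rng.uniform(8.0, 13.0)
        amp = rng.uniform(0.5, 2.0) * np.std(x)
        x = x + amp * np.sin(2 * np.pi * f_alpha * t + rng.uniform(0, 2 * np.pi))
        x = _bandpass(x, 1.0, 80.0, fs)
        segs.append(SignalSegment(_unit_rms(x), fs=fs, source="eeg"))
    return SegmentSet(segs, seed=seed)


def gen_eog(
    n: int, length: int = DEFAULT_LENGTH, fs: float = DEFAULT_FS, seed: int = 0
) -> SegmentSet:
    """Surrogate ocular-artifact segments, band-limited to 0.3–10 Hz.

    Slow smoothed noise plus randomly placed blink-like transient bumps.
    """
    _check_gen_args(n, length, fs, min_fs=160.0)
    rng = np.random.default_rng(seed)
    t = np.arange(length) / fs
    segs = []
    for _ in range(n):
        x = _pink_noise(rng, length, fs)
        n_blinks = rng.integers(0, 4)
        for _ in range(n_blinks):
            center = rng.uniform(0.1, t[-1] - 0.1)
            width = rng.uniform(0.05, 0.2)  # seconds; blink-scale transient
            amp = rng.uniform(2.0, 6.0) * np.std(x)
            sign = 1.0 if rng.random() < 0.8 else -1.0
            x = x + sign * amp * np.exp(-0.5 * ((t - center) / width) ** 2)
        x = _bandpass(x, 0.3, 10.0, fs, order=2)
        segs.append(SignalSegment(_unit_rms(x), fs=fs, source="eog"))
    return SegmentSet(segs, seed=seed)


def gen_emg(
    n: int, length: int = DEFAULT_LENGTH, fs: float = DEFAULT_FS, seed: int = 0
) -> SegmentSet:
    """Surrogate muscular-artifact segments, band-limited to 1–120 Hz.

    Broadband Gaussian noise amplitude-modulated by a random burst envelope.
    Requires fs > 240 Hz so the 120 Hz band edge is below Nyquist.
    """
    _check_gen_args(n, length, fs, min_fs=240.0)
    rng = np.random.default_rng(seed)
    t = np.arange(length) / fs
    segs = []
    for _ in range(n):
        x = rng.standard_normal(length)
        envelope = np.full(length, 0.3)
        n_bursts = rng.integers(1, 4)
        for _ in range(n_bursts):
            center = rng.uniform(0.0, t[-1])
            width = rng.uniform(0.1, 0.5)
            envelope = envelope + rng.uniform(0.5, 2.0) * np.exp(
                -0.5 * ((t - center) / width) ** 2
            )
        x = _bandpass(x * envelope, 1.0, 120.0, fs)
        segs.append(SignalSegment(_unit_rms(x), fs=fs, source="emg"))
    return SegmentSet(segs, seed=seed)


GENERATORS = {"eeg": gen_clean_eeg, "eog": gen_eog, "emg": gen_emg}


def load_segment_matrix(path: str | Path, fs: float, source: str) -> SegmentSet:
    """Load a segment matrix (rows = segments) from an array file.

    Accepts ``.npy`` files or plain-text matrices (``.csv`` comma-separated,
    anything else whitespace-separated) — the row/column layout used by the
    public EEGdenoiseNet distribution.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npy":
        matrix = np.load(path)
    else:
        delimiter = "," if path.suffix == ".csv" else None
        try:
            matrix = np.loadtxt(path, delimiter=delimiter)
        except ValueError as exc:
            raise ValueError(f"non-numeric content in {path}: {exc}") from exc
    matrix = np.asarray(matrix)
    if matrix.ndim != 2:
        raise ValueError(f"expected a 2-D segment matrix in {path}, got ndim={matrix.ndim}")
    return SegmentSet.from_matrix(matrix, fs=fs, source=source)


def save_segment_matrix(path: str | Path, segments: SegmentSet) -> None:
    """Write a SegmentSet as an array file (inverse of :func:`load_segment_matrix`)."""
    path = Path(path)
    matrix = segments.to_matrix()
    if path.suffix == ".npy":
        np.save(path, matrix)
    else:
        np.savetxt(path, matrix, delimiter="," if path.suffix == ".csv" else " ")


def split_train_test(
    segments: SegmentSet, train_fraction: float, seed: int = 0
) -> tuple[SegmentSet, SegmentSet]:
    """Random disjoint train/test partition; train size = round(n·fraction)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(segments)
    n_train = round(n * train_fraction)
    if n_train == 0 or n_train == n:
        raise ValueError(f"split of {n} segments at fraction {train_fraction} leaves an empty side")
    perm = np.random.default_rng(seed).permutation(n)
    train = [segments[int(i)] for i in perm[:n_train]]
    test = [segments[int(i)] for i in perm[n_train:]]
    return SegmentSet(train, seed=seed), SegmentSet(test, seed=seed)
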