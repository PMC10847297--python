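"""SNR-controlled linear contamination of clean EEG with artifact segments.

The contaminated signal is built as

    contaminated = clean + lambda * artifact

where the artifact coefficient ``lambda`` is solved from the requested SNR,

    SNR = 10 * lg( RMS(clean) / RMS(lambda * artifact) )    [dB]

with ``lg`` the base-10 logarithm and RMS the root mean square of the
window.  Note the ratio inside the logarithm is the RMS (amplitude) ratio,
not a power ratio — the convention of the EEGdenoiseNet benchmark — so the
mixture deviates from the clean signal by a factor 10^(−SNR/10) in RMS.
Smaller lambda means larger SNR.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .signals import SegmentSet, SignalSegment

DEFAULT_SNR_GRID_DB = tuple(range(-7, 3))  # −7 … 2 dB in 1 dB steps


class CapacityError(ValueError):
    """Not enough artifact segments to sample without replacement."""


def _samples(x) -> np.ndarray:
    arr = x.samples if isinstance(x, SignalSegment) else np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError("empty segment")
    return arr


def rms(segment) -> float:
    """Root mean square, sqrt(mean(x_i^2)), of a segment or array."""
    return float(np.sqrt(np.mean(_samples(segment) ** 2)))


def measure_snr(clean, scaled_artifact) -> float:
    """SNR in dB of a clean segment against an already-scaled artifact."""
    r_art = rms(scaled_artifact)
    if r_art == 0:
        raise ValueError("artifact has zero power")
    return 10.0 * np.log10(rms(clean) / r_art)


def lambda_for_snr(clean, artifact, snr_db: float) -> float:
    """Artifact coefficient achieving ``snr_db`` for the given pair.

    Inverts the SNR definition: lambda = (RMS(clean)/RMS(artifact)) * 10^(−snr/10).
    """
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    r_art = rms(artifact)
    if r_art == 0:
        raise ValueError("artifact has zero power")
    return float(rms(clean) / r_art * 10.0 ** (-snr_db / 10.0))


@dataclasses.dataclass(frozen=True)
class MixSpec:
    """Target SNR and the solved artifact coefficient for one mixture."""

    snr_db: float
    lam: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


@dataclasses.dataclass(frozen=True)
class ContaminatedPair:
    """A clean segment, the artifact used, the mix spec, and the mixture."""

    clean: SignalSegment
    artifact: SignalSegment
    spec: MixSpec
    mixed: SignalSegment


def mix(clean: SignalSegment, artifact: SignalSegment, snr_db: float) -> ContaminatedPair:
    """Linearly contaminate ``clean`` with ``artifact`` at the requested SNR."""
    if clean.length != artifact.length:
        raise ValueError(f"length mismatch: clean {clean.length} vs artifact {artifact.length}")
    if clean.fs != artifact.fs:
        raise ValueError(f"sampling-rate mismatch: {clean.fs} vs {artifact.fs}")
    lam = lambda_for_snr(clean, artifact, snr_db)
    mixed = SignalSegment(clean.samples + lam * artifact.samples, fs=clean.fs, source="mixed")
    return ContaminatedPair(clean=clean, artifact=artifact, spec=MixSpec(snr_db, lam), mixed=mixed)


@dataclasses.dataclass
class PairDataset:
    """SNR-stratified collection of contaminated pairs."""

    pairs: list[ContaminatedPair]
    snr_levels: tuple[float, ...]
    count_per_level: int
    seed: int

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def at_level(self, snr_db: float) -> list[ContaminatedPair]:
        return [p for p in self.pairs if p.spec.snr_db == snr_db]

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(clean matrix, mixed matrix, per-row SNR vector)."""
        clean = np.stack([p.clean.samples for p in self.pairs])
        mixed = np.stack([p.mixed.samples for p in self.pairs])
        snr = np.array([p.spec.snr_db for p in self.pairs])
        return clean, mixed, snr


def build_pair_dataset(
    cleans: SegmentSet,
    artifacts: SegmentSet,
    snr_levels: Sequence[float] = DEFAULT_SNR_GRID_DB,
    count_per_level: int = 100,
    seed: int = 0,
) -> PairDataset:
    """Build ``count_per_level`` contaminated pairs at each SNR level.

    Artifact segments are drawn without replacement within each level (they
    may recur across levels); clean segments cycle through a seeded
    permutation, so they are reused only once the pool is exhausted.
    """
    if count_per_level < 1:
        raise ValueError("count_per_level must be >= 1")
    if count_per_level > len(artifacts):
        raise CapacityError(
            f"level {snr_levels[0]} dB needs {count_per_level} artifact draws without "
            f"replacement but only {len(artifacts)} artifact segments are available"
        )
    rng = np.random.default_rng(seed)
    clean_perm = rng.permutation(len(cleans))
    clean_idx = np.resize(clean_perm, count_per_level * len(snr_levels))
    pairs: list[ContaminatedPair] = []
    pos = 0
    for level in snr_levels:
        art_idx = rng.choice(len(artifacts), size=count_per_level, replace=False)
        for j in art_idx:
            pairs.append(mix(cleans[int(clean_idx[pos])], artifacts[int(j)], float(level)))
            pos += 1
    return PairDataset(
        pairs=pairs,
        snr_levels=tuple(float(s) for s in snr_levels),
        count_per_level=count_per_level,
        seed=seed,
    )


def normalize_segment(segment: SignalSegment, method: str = "zscore_max") -> SignalSegment:
    """Normalize a segment for display/reporting.

    ``zscore_max`` subtracts the mean and divides by the maximum absolute
    value (conventional).  ``paper`` subtracts the standard deviation (a
    constant shift) before dividing — kept as a literal variant of the
    benchmark's stated two-step rule.  Either way max|output| == 1.
    """
    x = segment.samples
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all samples equal")
    if method == "paper":
        shifted = x - np.std(x)
    elif method == "zscore_max":
        shifted = x - np.mean(x)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    peak = np.max(np.abs(shifted))
    if peak == 0:
        raise ValueError("degenerate input after shift")
    return SignalSegment(shifted / peak, fs=segment.fs, source=segment.source)
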