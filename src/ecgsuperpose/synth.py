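"""Synthetic multi-channel ECG generation.

The generator builds one cycle of ECG morphology as a sum of Gaussian bumps
(one per P, Q, R, S, T wave), tiles it into a recording with optional
beat-to-beat (RR) jitter, and fans the clean signal out to K channels, each
with its own gain, integer-sample propagation delay, and independent
zero-mean Gaussian noise.  This emulates a proximity electrode array in
which every channel sees (to a good approximation) the same cardiac signal
but unrelated instrumentation noise:

    g_i(t) = a_i * f(t - d_i) + eta_i(t),   eta_i ~ N(0, sigma_i^2) iid.

All stochastic operations require an explicit seed so that every experiment
is replayable bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "WaveShape",
    "DEFAULT_MORPHOLOGY",
    "LOCATION_AMPLITUDES_UV",
    "ECGTemplate",
    "ChannelSpec",
    "CleanRecording",
    "MultiChannelRecording",
    "generate_template",
    "generate_clean_recording",
    "make_multichannel",
    "degrees_per_sample",
]


@dataclass(frozen=True)
class WaveShape:
    """One Gaussian bump of the cycle morphology.

    amplitude is relative to the R peak (R = 1); center and sigma are
    fractions of the cycle length, so a morphology scales to any
    samples-per-cycle setting.
    """

    amplitude: float
    center_frac: float
    sigma_frac: float


# Defaults are expressed for a 180-sample cycle (720 ms at 250 Hz):
# P at sample 58 (sigma 5 -> ~80 ms duration), narrow Q/R/S spikes around
# sample 90 spanning ~80-100 ms in total, T at sample 130 (sigma 10 ->
# ~160 ms).  Relative amplitudes P=0.15, Q=-0.1, S=-0.2, T=0.3.
DEFAULT_MORPHOLOGY: Mapping[str, WaveShape] = {
    "P": WaveShape(0.15, 58 / 180, 5 / 180),
    "Q": WaveShape(-0.10, 84 / 180, 2 / 180),
    "R": WaveShape(1.00, 90 / 180, 1.5 / 180),
    "S": WaveShape(-0.20, 96 / 180, 2 / 180),
    "T": WaveShape(0.30, 130 / 180, 10 / 180),
}

# Typical ECG amplitude by electrode location, in microvolts (midpoints of
# the published 30-50 uV mastoid and 50-70 uV upper-arm ranges).
LOCATION_AMPLITUDES_UV: Mapping[str, float] = {
    "chest": 1000.0,
    "mastoid": 40.0,
    "upper_arm": 60.0,
}

_WAVE_ORDER = ("P", "Q", "R", "S", "T")


@dataclass(frozen=True)
class ECGTemplate:
    """One cycle of clean ECG morphology.

    Attributes
    ----------
    samples_per_cycle : int
        Number of samples in one cardiac cycle.
    values : ndarray
        Amplitude sequence in microvolts, length ``samples_per_cycle``.
    landmarks : dict
        Per-wave ``(center_index, half_width_samples)``; waves whose
        amplitude is zero are absent from the dict.
    """

    samples_per_cycle: int
    values: np.ndarray
    landmarks: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.values) != self.samples_per_cycle:
            raise ValueError("values length must equal samples_per_cycle")
        if "R" not in self.landmarks:
            raise ValueError("template must contain an R wave")
        present = [w for w in _WAVE_ORDER if w in self.landmarks]
        centers = [self.landmarks[w][0] for w in present]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("wave landmarks must be strictly increasing P<Q<R<S<T")

    @property
    def r_index(self) -> int:
        return self.landmarks["R"][0]

    @property
    def t_end_offset(self) -> int | None:
        """Offset (samples, relative to R) of the end of the T wave."""
        if "T" not in self.landmarks:
            return None
        c, hw = self.landmarks["T"]
        return c + hw - self.r_index

    @property
    def p_onset_offset(self) -> int | None:
        """Offset (samples, relative to the same beat's R) of the P-wave onset."""
        if "P" not in self.landmarks:
            return None
        c, hw = self.landmarks["P"]
        return c - hw - self.r_index


@dataclass(frozen=True)
class ChannelSpec:
    """Per-channel corruption model: noise level, delay, gain."""

    noise_sigma: float = 0.0  # uV
    phase_offset: int = 0  # samples; positive = delayed
    gain_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.gain_scale <= 0:
            raise ValueError("gain_scale must be > 0")
        if int(self.phase_offset) != self.phase_offset:
            raise ValueError("phase_offset must be an integer number of samples")


@dataclass(frozen=True)
class CleanRecording:
    """Single-channel noise-free signal with ground-truth beat locations."""

    values: np.ndarray
    r_indices: np.ndarray
    fs: float
    samples_per_cycle: int


@dataclass(frozen=True)
class MultiChannelRecording:
    """K x N sample matrix in microvolts plus per-channel metadata."""

    fs: float
    data: np.ndarray
    channel_specs: Sequence[ChannelSpec] = field(default_factory=tuple)
    seed: int | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("data must be a K x N matrix with K,N >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.channel_specs and len(self.channel_specs) != data.shape[0]:
            raise ValueError("one ChannelSpec per channel required")
        object.__setattr__(self, "data", data)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def degrees_per_sample(samples_per_cycle: int) -> float:
    """Cycle phase, in degrees, represented by a one-sample offset.

    A 180-sample cycle gives 2 degrees per sample, so a one-sample
    misalignment between electrodes shifts the channel by 2 degrees of
    cardiac phase.
    """
    if samples_per_cycle <= 0:
        raise ValueError("samples_per_cycle must be positive")
    return 360.0 / samples_per_cycle


def generate_template(
    samples_per_cycle: int = 180,
    r_amplitude: float = 1000.0,
    morphology: Mapping[str, WaveShape] | None = None,
) -> ECGTemplate:
    """Build one cycle of ECG morphology as a sum of Gaussian bumps.

    Parameters
    ----------
    samples_per_cycle : int
        Samples in one cycle (>= 30).
    r_amplitude : float
        Desired peak amplitude in microvolts; the template is rescaled so
        its global maximum equals exactly this value at the R landmark.
    morphology : mapping, optional
        Per-wave :class:`WaveShape`; defaults to a canonical P-QRS-T shape.
        Waves with zero amplitude are dropped from the landmark table.
    """
    if samples_per_cycle < 30:
        raise ValueError("samples_per_cycle must be >= 30")
    if r_amplitude <= 0:
        raise ValueError("r_amplitude must be > 0")
    morph = dict(DEFAULT_MORPHOLOGY if morphology is None else morphology)
    if "R" not in morph or morph["R"].amplitude == 0:
        raise ValueError("morphology must include an R wave with nonzero amplitude")

    n = samples_per_cycle
    x = np.arange(n, dtype=float)
    values = np.zeros(n)
    landmarks: dict[str, tuple[int, int]] = {}
    for wave in _WAVE_ORDER:
        shape = morph.get(wave)
        if shape is None or shape.amplitude == 0.0:
            continue  # absent wave (e.g. isolated-R limit)
        center = shape.center_frac * n
        sigma = max(shape.sigma_frac * n, 1e-9)
        values += shape.amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)
        landmarks[wave] = (int(round(center)), int(round(2.0 * sigma)))

    r_idx = landmarks["R"][0]
    if int(np.argmax(values)) != r_idx:
        raise ValueError("morphology does not place the global maximum at R")
    values *= r_amplitude / values[r_idx]
    return ECGTemplate(n, values, landmarks)


def _resample_cycle(values: np.ndarray, new_len: int, anchor: int) -> tuple[np.ndarray, int]:
    """Linearly resample one cycle to new_len samples, keeping the anchor
    sample (the R apex) exactly on the output grid.

    The segments before and after the anchor are stretched independently;
    this avoids placing the apex between two output samples, which would
    make the returned ground-truth R index ambiguous at the sample level.
    Returns the resampled cycle and the anchor's new index.
    """
    n = len(values)
    padded = np.concatenate([values, values[:1]])
    grid = np.arange(n + 1)
    l1 = int(round(anchor * new_len / n))
    l1 = min(max(l1, 1), new_len - 1)
    l2 = new_len - l1
    xs = np.concatenate(
        [anchor * np.arange(l1) / l1, anchor + (n - anchor) * np.arange(l2) / l2]
    )
    return np.interp(xs, grid, padded), l1


def generate_clean_recording(
    template: ECGTemplate,
    n_cycles: int,
    fs: float = 250.0,
    rr_jitter: float = 0.0,
    seed: int | None = None,
) -> CleanRecording:
    """Tile a template into an n_cycles recording, optionally RR-jittered.

    With ``rr_jitter > 0`` each cycle is linearly resampled to a length
    drawn uniformly in ``samples_per_cycle * (1 +/- rr_jitter)`` (seeded),
    mimicking beat-to-beat heart-rate variability.  Ground-truth R-peak
    indices are returned with the signal.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if rr_jitter < 0:
        raise ValueError("rr_jitter must be >= 0")
    if rr_jitter > 0 and seed is None:
        raise ValueError("a seed is required when rr_jitter > 0")

    n = template.samples_per_cycle
    if rr_jitter == 0:
        values = np.tile(template.values, n_cycles)
        r_indices = template.r_index + n * np.arange(n_cycles)
        return CleanRecording(values, r_indices.astype(int), fs, n)

    rng = np.random.default_rng(seed)
    pieces = []
    r_indices = []
    offset = 0
    for _ in range(n_cycles):
        length = int(round(n * (1.0 + rng.uniform(-rr_jitter, rr_jitter))))
        length = max(length, 2)
        cycle, r_in_cycle = _resample_cycle(template.values, length, template.r_index)
        pieces.append(cycle)
        r_indices.append(offset + r_in_cycle)
        offset += length
    return CleanRecording(
        np.concatenate(pieces), np.asarray(r_indices, dtype=int), fs, n
    )


def _shift_replicate(x: np.ndarray, offset: int) -> np.ndarray:
    """Integer-sample delay with edge replication (non-circular)."""
    if offset == 0:
        return x.copy()
    out = np.empty_like(x)
    if offset > 0:
        out[:offset] = x[0]
        out[offset:] = x[:-offset]
    else:
        out[offset:] = x[-1]
        out[:offset] = x[-offset:]
    return out


def make_multichannel(
    clean: CleanRecording | np.ndarray,
    channel_specs: Sequence[ChannelSpec],
    seed: int | None = None,
    fs: float | None = None,
) -> MultiChannelRecording:
    """Fan a clean signal out to K corrupted channels.

    Row i is ``gain_i * shift(clean, offset_i) + N(0, sigma_i^2)`` with the
    noise drawn independently per channel from one seeded generator.  The
    shift is an integer-sample delay with edge replication: a physical
    propagation delay does not wrap within a recording.
    """
    if isinstance(clean, CleanRecording):
        signal = np.asarray(clean.values, dtype=float)
        fs = clean.fs if fs is None else fs
    else:
        signal = np.asarray(clean, dtype=float)
        fs = 250.0 if fs is None else fs
    if len(channel_specs) < 1:
        raise ValueError("at least one channel spec required")
    n = signal.size
    for spec in channel_specs:
        if abs(spec.phase_offset) >= n:
            raise ValueError("phase_offset magnitude must be < signal length")
    if seed is None and any(s.noise_sigma > 0 for s in channel_specs):
        raise ValueError("a seed is required when any channel has noise")

    rng = np.random.default_rng(seed)
    rows = []
    for spec in channel_specs:
        row = spec.gain_scale * _shift_replicate(signal, int(spec.phase_offset))
        if spec.noise_sigma > 0:
            row = row + rng.normal(0.0, spec.noise_sigma, size=n)
        rows.append(row)
    return MultiChannelRecording(fs, np.vstack(rows), tuple(channel_specs), seed)
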