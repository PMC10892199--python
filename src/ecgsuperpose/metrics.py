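"""Quantitative evaluation of ECG signal quality.

Covers the peak-to-peak SNR used to grade wave visibility, R-peak
detection and heart-rate series, heart-rate correlation between two
simultaneously recorded signals, common-mode rejection ratio, shorted-input
(input-referred) noise, and amplitude-frequency-response characterisation.

SNR definition: 20*log10(QRS_pp / noise_pp), where QRS_pp is the
peak-to-peak amplitude inside a 120 ms window centered on the R apex and
noise_pp is the peak-to-peak amplitude inside a 40 ms window placed on the
isoelectric T-P segment (midway between the end of the T wave and the next
beat's P onset).  Measuring "noise" between T end and the next P is the
only placement that excludes all wave activity, so that is the convention
used here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats

from .synth import MultiChannelRecording

__all__ = [
    "SNRReport",
    "BeatAnnotations",
    "HRCorrelationResult",
    "FrequencyResponse",
    "snr_eq_pp",
    "snr_multibeat",
    "detect_r_peaks",
    "heart_rate_series",
    "hr_correlation",
    "cmrr_db",
    "input_referred_noise_vpp",
    "frequency_response",
]

QRS_WINDOW_S = 0.120  # span of the R-wave measurement window
NOISE_WINDOW_S = 0.040  # span of the isoelectric noise window
REFRACTORY_S = 0.250  # minimum physiologically plausible R-R gap


@dataclass(frozen=True)
class SNRReport:
    snr_db: float
    qrs_vpp: float
    noise_vpp: float
    qrs_window: tuple[int, int]
    noise_window: tuple[int, int]

    @property
    def is_infinite(self) -> bool:
        return np.isinf(self.snr_db)


@dataclass(frozen=True)
class BeatAnnotations:
    """Detected R-peak sample indices for one signal."""

    r_indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.r_indices, dtype=int)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("r_indices must be strictly increasing")
        if idx.size and np.any(np.diff(idx) < REFRACTORY_S * self.fs):
            raise ValueError("r_indices violate the 250 ms refractory period")
        object.__setattr__(self, "r_indices", idx)

    @property
    def n_beats(self) -> int:
        return int(self.r_indices.size)

    @property
    def times_s(self) -> np.ndarray:
        return self.r_indices / self.fs


def snr_eq_pp(
    signal: np.ndarray,
    fs: float,
    r_index: int,
    t_end_index: int,
    next_p_index: int,
) -> SNRReport:
    """Peak-to-peak SNR of one beat.

    ``t_end_index`` / ``next_p_index`` delimit the isoelectric T-P segment;
    the 40 ms noise window is centered midway between them.  A zero noise
    peak-to-peak yields an infinite-SNR report rather than an error.
    """
    x = np.asarray(signal, dtype=float)
    if t_end_index >= next_p_index:
        raise ValueError("t_end_index must precede next_p_index")
    half_q = int(round(QRS_WINDOW_S * fs / 2))
    half_n = int(round(NOISE_WINDOW_S * fs / 2))
    q0, q1 = r_index - half_q, r_index + half_q + 1
    mid = (t_end_index + next_p_index) // 2
    n0, n1 = mid - half_n, mid + half_n + 1
    for a, b in ((q0, q1), (n0, n1)):
        if a < 0 or b > x.size:
            raise ValueError("measurement window out of signal range")
    qrs_vpp = float(np.ptp(x[q0:q1]))
    noise_vpp = float(np.ptp(x[n0:n1]))
    # a noise Vpp at floating-point dust level (clean synthetic signals)
    # is reported as the zero-noise, infinite-SNR case, not a huge number
    if noise_vpp <= 1e-9 * max(qrs_vpp, 1.0):
        snr = np.inf
    else:
        snr = 20.0 * np.log10(qrs_vpp / noise_vpp)
    return SNRReport(float(snr), qrs_vpp, noise_vpp, (q0, q1), (n0, n1))


def snr_multibeat(
    signal: np.ndarray,
    fs: float,
    r_indices: Sequence[int],
    t_end_offset: int,
    p_onset_offset: int,
) -> tuple[float, list[SNRReport]]:
    """Median per-beat SNR over a multi-beat recording.

    ``t_end_offset`` is the T-wave end relative to each beat's R;
    ``p_onset_offset`` is the P onset relative to the *next* beat's R
    (negative).  Beats whose windows do not fit are skipped; the median of
    the per-beat values is reported for robustness to a single bad beat.
    """
    r = np.asarray(r_indices, dtype=int)
    if r.size < 2:
        raise ValueError("need at least two beats to locate a T-P segment")
    reports = []
    for i in range(r.size - 1):
        t_end = r[i] + t_end_offset
        next_p = r[i + 1] + p_onset_offset
        try:
            reports.append(snr_eq_pp(signal, fs, r[i], t_end, next_p))
        except ValueError:
            continue
    if not reports:
        raise ValueError("no beat had in-range measurement windows")
    return float(np.median([rep.snr_db for rep in reports])), reports


def detect_r_peaks(signal: np.ndarray, fs: float) -> BeatAnnotations:
    """Locate R apexes with an envelope detector and adaptive threshold.

    Pipeline: 5-30 Hz zero-phase band-pass, derivative, squaring, 120 ms
    moving-window integration; candidate peaks (250 ms refractory) are
    accepted against a running signal/noise threshold and refined to the
    apex of the raw signal within +/-100 ms.
    """
    x = np.asarray(signal, dtype=float)
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if x.size < 2 * fs:
        raise ValueError("signal must be at least 2 s long")
    if not np.any(x):
        warnings.warn("all-zero signal: no beats found")
        return BeatAnnotations(np.array([], dtype=int), fs)

    sos = sps.butter(2, [5.0, 30.0], "bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    energy = np.gradient(bp) ** 2
    win = max(int(round(0.120 * fs)), 1)
    env = np.convolve(energy, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_S * fs))
    candidates, _ = sps.find_peaks(env, distance=refractory)
    if candidates.size == 0:
        warnings.warn("no beats found")
        return BeatAnnotations(np.array([], dtype=int), fs)

    head = env[: int(2 * fs)]
    spk, npk = float(head.max()), float(head.mean())
    threshold = npk + 0.25 * (spk - npk)
    accepted = []
    for p in candidates:
        if env[p] >= threshold:
            spk = 0.125 * env[p] + 0.875 * spk
            accepted.append(p)
        else:
            npk = 0.125 * env[p] + 0.875 * npk
        threshold = npk + 0.25 * (spk - npk)
    if not accepted:
        warnings.warn("no beats found")
        return BeatAnnotations(np.array([], dtype=int), fs)

    # refine each envelope peak to the apex of the raw waveform
    half = int(round(0.100 * fs))
    apexes = []
    for p in accepted:
        a, b = max(p - half, 0), min(p + half + 1, x.size)
        apexes.append(a + int(np.argmax(x[a:b])))
    # dedupe and enforce the refractory period on the refined indices
    apexes = sorted(set(apexes))
    kept: list[int] = []
    for idx in apexes:
        if not kept or idx - kept[-1] >= refractory:
            kept.append(idx)
        elif x[idx] > x[kept[-1]]:
            kept[-1] = idx
    return BeatAnnotations(np.asarray(kept, dtype=int), fs)


def heart_rate_series(ann: BeatAnnotations) -> np.ndarray:
    """Beat-wise instantaneous heart rate, bpm_i = 60*fs/(r_{i+1}-r_i)."""
    if ann.n_beats < 2:
        raise ValueError("need at least two beats for a heart-rate series")
    return 60.0 * ann.fs / np.diff(ann.r_indices)


@dataclass(frozen=True)
class HRCorrelationResult:
    r: float
    n_pairs: int
    n_dropped_a: int
    n_dropped_b: int


def _match_beats(
    ta: np.ndarray, tb: np.ndarray, tolerance_s: float
) -> list[tuple[int, int]]:
    """Greedy nearest-neighbour matching of beat times within tolerance."""
    pairs = []
    j = 0
    for i, t in enumerate(ta):
        while j < tb.size - 1 and abs(tb[j + 1] - t) <= abs(tb[j] - t):
            j += 1
        if j < tb.size and abs(tb[j] - t) <= tolerance_s:
            if pairs and pairs[-1][1] == j:
                # keep whichever of the two a-beats is closer to tb[j]
                if abs(tb[j] - t) < abs(tb[j] - ta[pairs[-1][0]]):
                    pairs[-1] = (i, j)
            else:
                pairs.append((i, j))
    return pairs


def hr_correlation(
    ann_a: BeatAnnotations,
    ann_b: BeatAnnotations,
    match_tolerance_ms: float = 150.0,
) -> HRCorrelationResult:
    """Pearson correlation of two beat-matched heart-rate series.

    Beats are paired by nearest R time within the tolerance; heart rate is
    computed between successive matched beats in each annotation and the
    paired bpm series are correlated.  Unmatched beats are dropped and
    counted in the result.
    """
    if ann_a.n_beats < 3 or ann_b.n_beats < 3:
        raise ValueError("need at least three beats in each annotation")
    pairs = _match_beats(ann_a.times_s, ann_b.times_s, match_tolerance_ms / 1000.0)
    if len(pairs) < 3:
        raise ValueError("fewer than three matched beat pairs")
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    bpm_a = 60.0 * ann_a.fs / np.diff(ann_a.r_indices[ia])
    bpm_b = 60.0 * ann_b.fs / np.diff(ann_b.r_indices[ib])
    r = float(stats.pearsonr(bpm_a, bpm_b).statistic)
    return HRCorrelationResult(
        r, len(pairs), ann_a.n_beats - len(pairs), ann_b.n_beats - len(pairs)
    )


def cmrr_db(
    diff_in_vpp: float,
    diff_out_vpp: float,
    cm_in_vpp: float,
    cm_out_vpp: float,
) -> float:
    """Common-mode rejection ratio from bench amplitudes.

    CMRR = 20*log10(Ad / Acm) with Ad = diff_out/diff_in and
    Acm = cm_out/cm_in; all four amplitudes must share units.
    """
    vals = (diff_in_vpp, diff_out_vpp, cm_in_vpp, cm_out_vpp)
    if any(v <= 0 for v in vals):
        raise ValueError("all amplitudes must be > 0")
    ad = diff_out_vpp / diff_in_vpp
    acm = cm_out_vpp / cm_in_vpp
    return 20.0 * np.log10(ad / acm)


def input_referred_noise_vpp(
    shorted_recording: MultiChannelRecording | np.ndarray,
    system_gain: float,
) -> np.ndarray:
    """Per-channel peak-to-peak noise referred to the input.

    With the inputs shorted to ground the output is pure system noise;
    dividing its Vpp by the system gain refers it to the input.
    """
    if system_gain <= 0:
        raise ValueError("system_gain must be > 0")
    data = (
        shorted_recording.data
        if isinstance(shorted_recording, MultiChannelRecording)
        else np.atleast_2d(np.asarray(shorted_recording, dtype=float))
    )
    if data.size == 0:
        raise ValueError("empty recording")
    return np.ptp(data, axis=1) / system_gain


@dataclass(frozen=True)
class FrequencyResponse:
    gain_db: float
    f_low_3db: float | None
    f_high_3db: float | None

    @property
    def low_side_open(self) -> bool:
        return self.f_low_3db is None

    @property
    def high_side_open(self) -> bool:
        return self.f_high_3db is None


def frequency_response(
    sweep_results: Sequence[tuple[float, float, float]],
) -> FrequencyResponse:
    """Plateau gain and -3 dB band edges from a sine-sweep table.

    ``sweep_results`` rows are (frequency_hz, vin_vpp, vout_vpp) with f
    strictly increasing.  Band edges are interpolated linearly in dB over
    log-frequency where the gain crosses plateau - 3 dB; a side with no
    crossing is flagged open-ended (None).
    """
    rows = list(sweep_results)
    if len(rows) < 5:
        raise ValueError("need at least 5 sweep points")
    f = np.array([r[0] for r in rows], dtype=float)
    if np.any(np.diff(f) <= 0):
        raise ValueError("frequencies must be strictly increasing")
    vin = np.array([r[1] for r in rows], dtype=float)
    vout = np.array([r[2] for r in rows], dtype=float)
    if np.any(vin <= 0) or np.any(vout <= 0):
        raise ValueError("amplitudes must be > 0")
    gain = 20.0 * np.log10(vout / vin)
    peak = int(np.argmax(gain))
    plateau = float(gain[peak])
    target = plateau - 3.0
    logf = np.log10(f)

    def cross(intervals) -> float | None:
        for i in intervals:
            g0, g1 = gain[i], gain[i + 1]
            if (g0 - target) * (g1 - target) <= 0 and g0 != g1:
                t = (target - g0) / (g1 - g0)
                return float(10 ** (logf[i] + t * (logf[i + 1] - logf[i])))
        return None

    # nearest crossing on each side of the plateau point
    f_low = cross(range(peak - 1, -1, -1)) if peak > 0 else None
    f_high = cross(range(peak, f.size - 1)) if peak < f.size - 1 else None
    return FrequencyResponse(plateau, f_low, f_high)
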