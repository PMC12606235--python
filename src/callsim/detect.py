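"""Call detection and selection filters for ultrasonic recordings.

Detection combines an amplitude criterion (smoothed RMS envelope above a
robust noise floor) with a spectral-density criterion (most short-time
energy above 10 kHz), mirroring the two-cue segmentation used for contact
calls.  Selection filters remove candidates shorter than 3 ms, longer than
50 ms, with peak frequency below 10 kHz, or clipped (relative amplitude
above 0.99 after full-scale normalization of the source recording).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

TARGET_RATE = 250_000


@dataclass
class Waveform:
    samples: np.ndarray
    rate: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


@dataclass
class CallSegment:
    """A detected syllable: a waveform slice with provenance."""

    source: str
    onset_s: float
    offset_s: float
    samples: np.ndarray
    rate: int
    source_peak: float = np.nan  # max |amplitude| of the whole source recording

    def __post_init__(self):
        if self.offset_s <= self.onset_s:
            raise ValueError("offset must follow onset")

    @property
    def duration_ms(self) -> float:
        return (self.offset_s - self.onset_s) * 1e3


@dataclass
class DetectionConfig:
    """Tunables for the two-criterion detector (times in seconds)."""

    envelope_window_s: float = 0.5e-3
    noise_k: float = 5.0  # noise floor = median + k * MAD of envelope
    spectral_window: int = 256
    spectral_min_fraction: float = 0.7  # of band energy above band_split_hz
    band_split_hz: float = 10_000.0
    merge_gap_s: float = 2e-3
    min_duration_s: float = 1e-3  # pre-filter; the 3 ms rule is applied later


def resample_to_250k(w: Waveform) -> Waveform:
    """Downsample to exactly 250 kHz with a steep anti-alias FIR.

    Energy above the 125 kHz output Nyquist is attenuated by >= 60 dB.
    Upsampling is out of contract: input rates below 250 kHz are rejected.
    """
    if w.rate < TARGET_RATE:
        raise ValueError("input rate below 250 kHz; upsampling not supported")
    if w.rate == TARGET_RATE:
        return Waveform(w.samples.copy(), TARGET_RATE)
    frac = Fraction(TARGET_RATE, int(w.rate))
    up, down = frac.numerator, frac.denominator
    # Kaiser FIR with cutoff safely inside the output Nyquist
    cutoff = 0.92 / down  # relative to the (upsampled) Nyquist
    ntaps = 64 * down + 1
    h = signal.firwin(ntaps, cutoff, window=("kaiser", 9.0))
    y = signal.resample_poly(w.samples, up, down, window=h)
    return Waveform(y, TARGET_RATE)


def _rms_envelope(x: np.ndarray, rate: int, window_s: float) -> np.ndarray:
    win = max(3, int(round(window_s * rate)))
    return np.sqrt(uniform_filter1d(x**2, size=win, mode="nearest"))


def _spectral_fraction(x, rate, nwin, split_hz):
    """Per-sample fraction of short-time spectral energy above ``split_hz``."""
    hop = nwin // 4
    f, t, S = signal.stft(
        x, fs=rate, window="hann", nperseg=nwin, noverlap=nwin - hop, padded=True
    )
    power = np.abs(S) ** 2
    hi = power[f >= split_hz].sum(axis=0)
    tot = power.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, hi / np.maximum(tot, 1e-300), 0.0)
    # map every sample to its nearest analysis frame
    idx = np.clip(
        np.round(np.arange(x.size) / rate / (t[1] - t[0])).astype(int), 0, len(t) - 1
    )
    return frac[idx]


def detect_calls(w: Waveform, params: DetectionConfig | None = None,
                 source: str = "recording") -> list[CallSegment]:
    """Detect call segments using amplitude and spectral-density criteria.

    A sample belongs to a candidate call when (a) the smoothed RMS envelope
    exceeds ``median + k * MAD`` of the whole-recording envelope and (b) at
    least ``spectral_min_fraction`` of the local short-time spectral energy
    lies above ``band_split_hz``.  Runs separated by less than the merge gap
    are joined; output segments are sorted and non-overlapping.
    """
    if params is None:
        params = DetectionConfig()
    if w.rate != TARGET_RATE:
        raise ValueError("detect_calls expects a 250 kHz waveform")
    x = w.samples
    if x.size == 0:
        return []

    env = _rms_envelope(x, w.rate, params.envelope_window_s)
    med = np.median(env)
    mad = np.median(np.abs(env - med))
    floor = med + params.noise_k * max(mad, 1e-12)
    amp_ok = env > floor

    spec_ok = (
        _spectral_fraction(x, w.rate, params.spectral_window, params.band_split_hz)
        >= params.spectral_min_fraction
    )
    active = amp_ok & spec_ok
    if not active.any():
        return []

    padded = np.concatenate([[False], active, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive

    merge = int(round(params.merge_gap_s * w.rate))
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < merge:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_len = int(round(params.min_duration_s * w.rate))
    peak = float(np.max(np.abs(x))) if x.size else np.nan
    segs = []
    for s, e in merged:
        if e - s < min_len:
            continue
        segs.append(
            CallSegment(
                source=source,
                onset_s=s / w.rate,
                offset_s=e / w.rate,
                samples=x[s:e].copy(),
                rate=w.rate,
                source_peak=peak,
            )
        )
    return segs


def peak_frequency_hz(seg: CallSegment) -> float:
    """Peak frequency of a segment from its Welch power spectrum."""
    nper = min(len(seg.samples), 512)
    f, p = signal.welch(seg.samples, fs=seg.rate, nperseg=nper)
    return float(f[np.argmax(p)])


def filter_calls(
    segments: list[CallSegment],
    peak_freqs_hz: np.ndarray | list | None = None,
    *,
    min_duration_ms: float = 3.0,
    max_duration_ms: float = 50.0,
    min_peak_hz: float = 10_000.0,
) -> list[CallSegment]:
    """Keep segments with 3 ms <= duration <= 50 ms and peak >= 10 kHz.

    Duration bounds are inclusive; the peak-frequency cut removes peaks
    strictly below 10 kHz.  If ``peak_freqs_hz`` is omitted it is measured
    from each segment's spectrum.
    """
    if peak_freqs_hz is None:
        peak_freqs_hz = [peak_frequency_hz(s) for s in segments]
    out = []
    for seg, pf in zip(segments, peak_freqs_hz):
        if min_duration_ms <= seg.duration_ms <= max_duration_ms and pf >= min_peak_hz:
            out.append(seg)
    return out


def remove_clipped(
    segments: list[CallSegment], threshold: float = 0.99
) -> list[CallSegment]:
    """Drop segments whose relative amplitude exceeds the clip threshold.

    Relative amplitude is the segment's max |sample| after normalizing the
    source recording to full scale; the cut is strict ("more than 0.99"),
    so a relative amplitude of exactly 0.99 is kept.
    """
    out = []
    for seg in segments:
        ref = seg.source_peak
        if not np.isfinite(ref) or ref <= 0:
            ref = max((float(np.max(np.abs(s.samples))) for s in segments), default=1.0)
        rel = float(np.max(np.abs(seg.samples))) / ref if ref > 0 else 0.0
        if rel <= threshold:
            out.append(seg)
    return out
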