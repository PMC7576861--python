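"""Breath segmentation and per-breath tidal images.

The global impedance curve (pixel sum per frame) rises with inspiration
and falls with expiration. Breaths are segmented on a 2 Hz low-passed
copy of that curve — the low-pass suppresses the cardiac band (~1.5-2.5
Hz in pigs) — by finding end-inspiratory maxima and interleaved
end-expiratory minima, gated by amplitude so noise wiggles do not count
as breaths. The tidal image of a breath is the pixel-wise difference
between its end-inspiratory and end-expiratory frames.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .core import BreathCycle, FrameSequence, TidalImage, ValidationError


def global_signal(seq: FrameSequence) -> np.ndarray:
    """Per-frame sum of all pixel values (the global impedance curve)."""
    return seq.frames.reshape(seq.n_frames, -1).sum(axis=1)


def lowpass(signal: np.ndarray, frame_rate: float, cutoff_hz: float = 2.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass; passthrough if the
    cutoff is at or above Nyquist or the signal is too short to filter."""
    signal = np.asarray(signal, dtype=float)
    if cutoff_hz >= frame_rate / 2 or signal.size < 15:
        return signal
    b, a = butter(4, cutoff_hz, fs=frame_rate)
    return filtfilt(b, a, signal)


def detect_breaths(
    signal: np.ndarray,
    frame_rate: float,
    min_breath_s: float = 1.0,
    prominence_fraction: float = 0.25,
    lowpass_hz: float = 2.0,
) -> list[BreathCycle]:
    """Segment complete breath cycles from a global impedance curve.

    Returns min-max-min triplets (end-expiration, end-inspiration, next
    end-expiration) whose peak-to-trough amplitude is at least
    ``prominence_fraction`` of the median tidal amplitude and whose
    extrema are spaced at least ``min_breath_s`` apart. Incomplete
    boundary cycles are dropped. An apneic or flat signal yields an empty
    list with a warning rather than an exception.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size < 2 * min_breath_s * frame_rate:
        raise ValidationError(
            f"signal too short: need at least {2 * min_breath_s * frame_rate:.0f} frames"
        )
    smooth = lowpass(signal, frame_rate, lowpass_hz)
    if np.ptp(smooth) <= 1e-9 * max(1.0, np.abs(smooth).max()):
        warnings.warn("no breaths detected", stacklevel=2)
        return []
    distance = max(int(min_breath_s * frame_rate / 2), 1)
    peaks, _ = find_peaks(smooth, distance=distance)
    troughs, _ = find_peaks(-smooth, distance=distance)
    if peaks.size == 0 or troughs.size < 2:
        warnings.warn("no breaths detected", stacklevel=2)
        return []

    # amplitude gate against the median peak-to-adjacent-trough excursion
    all_amp = []
    for p in peaks:
        prev = troughs[troughs < p]
        nxt = troughs[troughs > p]
        lo = []
        if prev.size:
            lo.append(smooth[prev[-1]])
        if nxt.size:
            lo.append(smooth[nxt[0]])
        if lo:
            all_amp.append(smooth[p] - min(lo))
    median_amp = float(np.median(all_amp)) if all_amp else 0.0
    if median_amp <= 0:
        warnings.warn("no breaths detected", stacklevel=2)
        return []
    amp_floor = prominence_fraction * median_amp

    # smoothing skews extremum positions on asymmetric waveforms (slow
    # inspiratory ramp, sharp release), so refine each index on the raw
    # signal within a small neighborhood of the filtered extremum
    refine = max(int(0.25 * frame_rate), 1)

    def _refined(idx: int, lo: int, hi: int, maximum: bool) -> int:
        a = max(lo, idx - refine)
        b = min(hi, idx + refine + 1)
        seg = signal[a:b]
        return a + int(np.argmax(seg) if maximum else np.argmin(seg))

    cycles: list[BreathCycle] = []
    for i in range(troughs.size - 1):
        t0, t1 = troughs[i], troughs[i + 1]
        between = peaks[(peaks > t0) & (peaks < t1)]
        if between.size == 0:
            continue
        p = between[np.argmax(smooth[between])]
        amplitude = smooth[p] - max(smooth[t0], smooth[t1])
        if amplitude < amp_floor:
            continue
        if (p - t0) + (t1 - p) < min_breath_s * frame_rate:
            continue
        pr = _refined(int(p), int(t0) + 1, int(t1), True)
        t0r = _refined(int(t0), max(int(t0) - refine, 0), pr, False)
        t1r = _refined(int(t1), pr + 1, signal.size, False)
        if t0r < pr < t1r:
            cycles.append(BreathCycle(t0r, pr, t1r))
    if not cycles:
        warnings.warn("no breaths detected", stacklevel=2)
    return cycles


def tidal_image(seq: FrameSequence, breath: BreathCycle) -> TidalImage:
    """End-inspiratory minus end-expiratory frame, pixel-wise (DI_xy)."""
    n = seq.n_frames
    for idx in (breath.end_expiration_index, breath.end_inspiration_index):
        if not 0 <= idx < n:
            raise ValidationError(f"breath index {idx} outside sequence of {n} frames")
    di = seq.frames[breath.end_inspiration_index] - seq.frames[breath.end_expiration_index]
    return TidalImage(di=di, breath=breath)


def mean_tidal_image(seq: FrameSequence, breaths: list[BreathCycle]) -> np.ndarray:
    """Mean per-pixel tidal amplitude across breaths."""
    if not breaths:
        raise ValidationError("no breaths to average")
    return np.mean([tidal_image(seq, b).di for b in breaths], axis=0)


def lung_mask(mean_tidal: np.ndarray, threshold_fraction: float = 0.10) -> np.ndarray:
    """Functional lung region: pixels with mean tidal amplitude at least
    ``threshold_fraction`` of the maximum pixel amplitude.

    Computed once per recording from the mean tidal image and reused for
    every breath of that recording, so the GI of different breaths is
    computed over the same pixel set.
    """
    mean_tidal = np.asarray(mean_tidal, dtype=float)
    peak = mean_tidal.max()
    if not peak > 0:
        raise ValidationError("mean tidal image has no positive pixels; cannot build mask")
    return mean_tidal >= threshold_fraction * peak
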