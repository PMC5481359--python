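"""Spectro-temporal feature extraction from ECoG-like multichannel recordings.

The pipeline turns raw cortical surface potentials into 24 features per
electrode per trial:

1. common-average reference within each grid/strip;
2. low-pass filter at 128 Hz and resample to 256 Hz;
3. time-gate each trial to 0-750 ms post stimulus onset (192 samples);
4. short-time FFT with 500 ms (128-sample) windows at 50% overlap, giving
   exactly two frames centered at 250 and 500 ms, with magnitudes
   normalized per frequency by the mean baseline spectrum of the 1,000 ms
   pre-onset window;
5. average the normalized magnitudes over 24 subregions: the 2 time frames
   crossed with 12 log-spaced, 50%-overlapping frequency bands spanning
   roughly 1.4-128 Hz.

Baseline normalization makes the features invariant to per-channel gain;
the 750 ms gate keeps the analysis window clear of the participant's spoken
response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pandas as pd
import scipy.signal

from .regression import TrialTable

logger = logging.getLogger(__name__)

__all__ = [
    "EcogRecording",
    "FrequencyBand",
    "common_average_reference",
    "antialias_and_resample",
    "gate_trials",
    "spectrogram",
    "subregion_features",
    "default_frequency_bands",
    "screen_channels",
    "extract_features",
]

TARGET_RATE = 256.0
LOWPASS_CUTOFF = 128.0
POST_WINDOW_S = 0.750
BASELINE_S = 1.000
STFT_WINDOW = 128  # samples at 256 Hz = 500 ms
STFT_HOP = 64      # 50% overlap


@dataclass
class EcogRecording:
    """Multichannel recording with electrode grouping and a trial event table.

    ``signals`` is channels x samples (microvolts); ``channel_groups`` names
    the grid or strip each electrode belongs to; ``events`` has columns
    ``onset_sample``, ``class_id``, ``block_id`` with strictly increasing
    onsets.
    """

    signals: np.ndarray
    sample_rate: float
    channel_ids: list
    channel_groups: list
    events: pd.DataFrame
    t_stim: float = 1.0
    t_fix: tuple = (3.5, 4.5)

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be channels x samples")
        n = self.signals.shape[0]
        if len(self.channel_ids) != n or len(self.channel_groups) != n:
            raise ValueError("channel metadata length does not match channel count")
        onsets = np.asarray(self.events["onset_sample"])
        if len(onsets) and not np.all(np.diff(onsets) > 0):
            raise ValueError("event onsets must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


def common_average_reference(rec: EcogRecording) -> EcogRecording:
    """Subtract, per grid/strip, the instantaneous mean of its channels."""
    groups = list(rec.channel_groups)
    for i, g in enumerate(groups):
        if g is None or (isinstance(g, float) and np.isnan(g)) or g == "":
            raise ValueError(f"channel {rec.channel_ids[i]!r} not assigned to a grid/strip")
    out = rec.signals.copy()
    for g in sorted(set(groups)):
        members = [i for i, gg in enumerate(groups) if gg == g]
        out[members] -= rec.signals[members].mean(axis=0, keepdims=True)
    return replace(rec, signals=out)


def antialias_and_resample(rec: EcogRecording, target_rate: float = TARGET_RATE,
                           cutoff: float = LOWPASS_CUTOFF) -> EcogRecording:
    """Low-pass at ``cutoff`` (zero-phase) and resample to ``target_rate``.

    Event onsets are rescaled to the new rate.  Uses an 8th-order
    Butterworth (applied forward-backward) followed by polyphase
    resampling.
    """
    fs = rec.sample_rate
    if fs < target_rate:
        raise ValueError(f"native rate {fs} Hz below target {target_rate} Hz")
    if fs == target_rate:
        return replace(rec, signals=rec.signals.copy())
    sos = scipy.signal.butter(8, cutoff, fs=fs, output="sos")
    filt = scipy.signal.sosfiltfilt(sos, rec.signals, axis=1)
    frac = Fraction(target_rate / fs).limit_denominator(1000)
    out = scipy.signal.resample_poly(filt, frac.numerator, frac.denominator, axis=1)
    events = rec.events.copy()
    events["onset_sample"] = np.round(
        events["onset_sample"].to_numpy() * target_rate / fs).astype(int)
    return replace(rec, signals=out, sample_rate=target_rate, events=events)


def gate_trials(rec: EcogRecording, post_s: float = POST_WINDOW_S,
                baseline_s: float = BASELINE_S):
    """Cut per-trial analysis segments and pre-stimulus baseline segments.

    Returns ``(segments, baselines, events_kept)`` where segments is
    (n_trials, channels, round(post_s * fs)) and baselines covers the
    ``baseline_s`` window immediately before onset.  Trials without room for
    both windows are dropped with a warning.
    """
    fs = rec.sample_rate
    n_post = int(round(post_s * fs))
    n_base = int(round(baseline_s * fs))
    keep, segs, bases = [], [], []
    for i, onset in enumerate(rec.events["onset_sample"].to_numpy()):
        if onset - n_base < 0 or onset + n_post > rec.n_samples:
            logger.warning("gate_trials: dropping trial %d (onset %d too close to edge)",
                           i, onset)
            continue
        keep.append(i)
        segs.append(rec.signals[:, onset:onset + n_post])
        bases.append(rec.signals[:, onset - n_base:onset])
    if not keep:
        raise ValueError("no trial left room for both the baseline and analysis window")
    return (np.stack(segs), np.stack(bases),
            rec.events.iloc[keep].reset_index(drop=True))


def _stft_magnitude(x: np.ndarray, fs: float, window: str, zero_pad: int):
    """Magnitude STFT frames (freqs, times, |S| of shape (F, n_frames))."""
    n = x.shape[-1]
    if n < STFT_WINDOW:
        raise ValueError(f"segment shorter than one {STFT_WINDOW}-sample STFT window")
    win = scipy.signal.get_window(window, STFT_WINDOW)
    nfft = STFT_WINDOW * int(zero_pad)
    n_frames = (n - STFT_WINDOW) // STFT_HOP + 1
    frames = np.stack([x[..., k * STFT_HOP:k * STFT_HOP + STFT_WINDOW]
                       for k in range(n_frames)], axis=-1)
    mag = np.abs(np.fft.rfft(frames * win[:, None], n=nfft, axis=-2))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    times = (np.arange(n_frames) * STFT_HOP + STFT_WINDOW / 2) / fs
    return freqs, times, mag


def spectrogram(segment: np.ndarray, baseline_segment: np.ndarray,
                fs: float = TARGET_RATE, window: str = "hann",
                zero_pad: int = 4, eps: float = 1e-12):
    """Baseline-normalized magnitude spectrogram of one trial segment.

    The 192-sample (750 ms) segment yields exactly 2 frames centered at 250
    and 500 ms; the 256-sample (1,000 ms) baseline yields 3 frames whose
    mean magnitude per frequency divides the trial magnitudes.  ``zero_pad``
    refines the FFT frequency grid (4 -> 0.5 Hz bins at 256 Hz).
    """
    freqs, times, mag = _stft_magnitude(np.asarray(segment, dtype=float), fs,
                                        window, zero_pad)
    _, _, bmag = _stft_magnitude(np.asarray(baseline_segment, dtype=float), fs,
                                 window, zero_pad)
    base = bmag.mean(axis=-1)
    n_floor = int((base <= eps).sum())
    if n_floor:
        logger.warning("spectrogram: %d baseline magnitude(s) at zero floored to eps",
                       n_floor)
    base = np.maximum(base, eps)
    return freqs, times, mag / base[..., None]


@dataclass(frozen=True)
class FrequencyBand:
    lo: float
    center: float
    hi: float


def default_frequency_bands(n_bands: int = 12, lo_center: float = 2.0,
                            hi_center: float = 128.0,
                            nyquist: float = TARGET_RATE / 2) -> list:
    """12 log-spaced frequency bands with 50% overlap in log frequency.

    Centers run geometrically from 2 to 128 Hz; each band spans one
    center-to-center step on either side, so adjacent bands overlap by half
    their log width and the lowest edge lands near 1.4 Hz.  The top edge is
    clipped at the Nyquist frequency.
    """
    centers = np.geomspace(lo_center, hi_center, n_bands)
    step = (np.log(hi_center) - np.log(lo_center)) / (n_bands - 1)
    bands = []
    for c in centers:
        lo = c * np.exp(-step)
        hi = min(c * np.exp(step), nyquist)
        bands.append(FrequencyBand(lo=float(lo), center=float(c), hi=float(hi)))
    return bands


def subregion_features(norm_spec: np.ndarray, freqs: np.ndarray, times: np.ndarray,
                       bands=None, nyquist: float = TARGET_RATE / 2) -> np.ndarray:
    """Average a normalized spectrogram over the 2 x 12 time/frequency cells.

    Returns the 24 features in time-major order (all bands at 250 ms, then
    all bands at 500 ms).
    """
    if bands is None:
        bands = default_frequency_bands(nyquist=nyquist)
    if norm_spec.shape[-1] != len(times):
        raise ValueError("spectrogram frame count does not match times")
    out = np.empty(len(times) * len(bands))
    k = 0
    for t in range(len(times)):
        for band in bands:
            if band.lo >= nyquist:
                raise ValueError(f"band {band} outside the Nyquist range")
            mask = (freqs >= band.lo) & (freqs <= band.hi)
            if not mask.any():
                raise ValueError(f"no FFT bin inside band {band}; increase zero_pad")
            out[k] = norm_spec[mask, t].mean()
            k += 1
    return out


def screen_channels(rec: EcogRecording, max_abs: float | None = None,
                    var_z: float | None = 5.0) -> EcogRecording:
    """Automated noisy-channel rejection.

    Drops channels whose peak amplitude exceeds ``max_abs`` or whose log
    variance is more than ``var_z`` robust standard deviations from the
    median across channels.  A reproducible stand-in for by-eye screening.
    """
    keep = np.ones(rec.n_channels, dtype=bool)
    if max_abs is not None:
        keep &= np.abs(rec.signals).max(axis=1) <= max_abs
    if var_z is not None and rec.n_channels > 2:
        lv = np.log(rec.signals.var(axis=1) + 1e-30)
        med = np.median(lv)
        mad = np.median(np.abs(lv - med)) * 1.4826 + 1e-30
        keep &= np.abs(lv - med) <= var_z * mad
    if not keep.all():
        dropped = [rec.channel_ids[i] for i in np.flatnonzero(~keep)]
        logger.warning("screen_channels: dropping %d channel(s): %s", len(dropped), dropped)
    idx = np.flatnonzero(keep)
    return replace(rec, signals=rec.signals[idx],
                   channel_ids=[rec.channel_ids[i] for i in idx],
                   channel_groups=[rec.channel_groups[i] for i in idx])


def extract_features(rec: EcogRecording, bands=None, window: str = "hann",
                     zero_pad: int = 4) -> TrialTable:
    """Full pipeline: CAR -> low-pass/resample -> gate -> 24 features/electrode.

    Returns a :class:`TrialTable` whose columns are electrode-major blocks
    of 24 spectro-temporal magnitudes, with feature metadata (electrode id,
    time-window center in ms, band center/edges in Hz).
    """
    rec = common_average_reference(rec)
    rec = antialias_and_resample(rec)
    segments, baselines, events = gate_trials(rec)
    nyq = rec.sample_rate / 2
    if bands is None:
        bands = default_frequency_bands(nyquist=nyq)
    n_trials, n_chan = segments.shape[0], segments.shape[1]
    feats = np.empty((n_trials, n_chan * len(bands) * 2))
    times_ms = None
    for ti in range(n_trials):
        for ci in range(n_chan):
            freqs, times, spec = spectrogram(segments[ti, ci], baselines[ti, ci],
                                             fs=rec.sample_rate, window=window,
                                             zero_pad=zero_pad)
            vals = subregion_features(spec, freqs, times, bands, nyquist=nyq)
            feats[ti, ci * len(vals):(ci + 1) * len(vals)] = vals
            times_ms = times * 1000.0
    meta_rows = []
    for ci in range(n_chan):
        for t_ms in times_ms:
            for band in bands:
                meta_rows.append({"feature_id": len(meta_rows),
                                  "electrode": rec.channel_ids[ci],
                                  "time_center_ms": float(t_ms),
                                  "freq_center_hz": band.center,
                                  "freq_lo_hz": band.lo, "freq_hi_hz": band.hi})
    meta = pd.DataFrame(meta_rows)
    return TrialTable(feats, events["class_id"].to_numpy(),
                      events["block_id"].to_numpy(), meta)
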