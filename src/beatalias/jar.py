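"""Jamming-avoidance-response (JAR) analysis on synthetic EOD recordings.

When a wave-type electric fish is stimulated with a frequency a few Hz below
(a multiple of) its own EOD frequency, it shifts its EOD frequency away from
the interference over roughly ten seconds.  This module provides the analysis
chain for such experiments -- spectrogram-based EOD frequency tracking from
the second harmonic, baseline vs. steady-state shift computation, and the
stimulus-protocol frequencies -- together with a generator of synthetic
frequency-shifting EOD recordings for closed-loop round-trip testing (the
behavioral recordings themselves are not part of this package).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import spectrogram

from .signals import DEFAULT_RATE, EODTemplate, Waveform

__all__ = [
    "FrequencyTrace",
    "track_eod_frequency",
    "jar_shift",
    "jar_protocol_frequencies",
    "synth_jar_recording",
]


@dataclass
class FrequencyTrace:
    """Time course of the instantaneous EOD frequency of one fish."""

    time: np.ndarray  # s, segment centers
    frequency: np.ndarray  # Hz
    onset: float  # stimulus onset time, s

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.frequency = np.asarray(self.frequency, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time axis must be increasing")
        if np.any(self.frequency <= 0):
            raise ValueError("frequencies must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "f_eod_hz": self.frequency})


def _parabolic_peak(freqs: np.ndarray, power: np.ndarray, i: int) -> float:
    """Sub-bin peak position by parabolic interpolation of log power across three bins."""
    if i <= 0 or i >= len(power) - 1:
        return float(freqs[i])
    with np.errstate(divide="ignore"):
        y0, y1, y2 = np.log(power[i - 1 : i + 2])
    denom = y0 - 2 * y1 + y2
    if not np.isfinite(denom) or denom == 0:
        return float(freqs[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(freqs[i] + delta * (freqs[1] - freqs[0]))


def track_eod_frequency(
    recording: Waveform,
    nfft: int = 131072,
    overlap: float = 0.5,
    onset: float = 0.0,
    band_halfwidth: float = 50.0,
    f_eod_hint: float | None = None,
) -> FrequencyTrace:
    """Track the EOD frequency over time from the second harmonic of a recording.

    A spectrogram (default segment length 131072 samples, 50 % overlap, about
    0.3 Hz bins at 40 kHz) is computed; in each segment the peak frequency
    within ``band_halfwidth`` Hz around twice the fundamental is located,
    refined by parabolic interpolation, and divided by two.  Tracking the
    second harmonic avoids contamination by a stimulus placed a few Hz from
    the fundamental.

    Raises if the recording carries no energy at the second harmonic.
    """
    if len(recording) < nfft:
        raise ValueError("recording shorter than one spectrogram segment")
    freqs, times, sxx = spectrogram(
        recording.samples,
        fs=recording.rate,
        window="hann",
        nperseg=nfft,
        noverlap=int(round(overlap * nfft)),
        detrend=False,
    )
    if f_eod_hint is None:
        # fundamental of the first segment = strongest peak above 10 Hz
        lo = np.searchsorted(freqs, 10.0)
        f_eod_hint = float(freqs[lo + np.argmax(sxx[lo:, 0])])
    band = (freqs >= 2 * f_eod_hint - band_halfwidth) & (
        freqs <= 2 * f_eod_hint + band_halfwidth
    )
    if not np.any(band):
        raise ValueError("tracking band empty; check f_eod_hint and band_halfwidth")
    idx = np.where(band)[0]
    # second-harmonic energy must stand clearly above window-leakage level
    if np.max(sxx[idx, 0]) < 1e-6 * np.max(sxx[:, 0]):
        raise ValueError("no second-harmonic energy in the tracking band")
    trace = np.empty(len(times))
    for j in range(len(times)):
        band_power = sxx[idx, j]
        i = idx[int(np.argmax(band_power))]
        trace[j] = _parabolic_peak(freqs, sxx[:, j], i) / 2.0
    return FrequencyTrace(time=times, frequency=trace, onset=onset)


def jar_shift(trace: FrequencyTrace) -> float:
    """Steady-state EOD frequency shift of one JAR trial, in Hz.

    Mean EOD frequency 15-25 s after stimulus onset minus the baseline mean
    over the 10 s right before onset.
    """
    t = trace.time - trace.onset
    pre = (t >= -10.0) & (t < 0.0)
    post = (t >= 15.0) & (t <= 25.0)
    if not np.any(pre) or not np.any(post):
        raise ValueError("trace must cover [onset-10 s, onset+25 s]")
    return float(np.mean(trace.frequency[post]) - np.mean(trace.frequency[pre]))


def jar_protocol_frequencies(f_eod: float, k: int) -> float:
    """Stimulus frequency of the JAR protocol for multiple ``k`` of the EOD frequency.

    ``k*f_eod - 5`` Hz for ``1 <= k <= 5`` and ``+5`` Hz for ``k = 0``.
    """
    if not 0 <= k <= 5:
        raise ValueError("k must be in 0..5")
    return 5.0 if k == 0 else k * f_eod - 5.0


def synth_jar_recording(
    f_eod: float,
    shift: float,
    onset: float = 10.0,
    time_constant: float = 3.0,
    harmonics: EODTemplate | None = None,
    rate: float = DEFAULT_RATE,
    duration: float = 40.0,
    phase: float = 0.0,
) -> Waveform:
    """Synthetic multi-harmonic EOD recording with an exponential frequency shift.

    The instantaneous fundamental frequency follows
    ``f_eod + shift*(1 - exp(-(t - onset)/time_constant))`` after stimulus
    onset; the waveform is built by integrating this frequency to a phase, so
    it is continuous at onset.  Default harmonics: fundamental plus a second
    harmonic at half amplitude, enough for second-harmonic tracking.
    """
    if time_constant <= 0:
        raise ValueError("time constant must be positive")
    if harmonics is None:
        harmonics = EODTemplate(amplitudes=(1.0, 0.5))
    n = int(round(rate * duration))
    t = np.arange(n) / rate
    finst = np.full(n, float(f_eod))
    after = t >= onset
    finst[after] += shift * (1.0 - np.exp(-(t[after] - onset) / time_constant))
    phi = 2 * np.pi * np.cumsum(finst) / rate + phase
    x = np.zeros(n)
    a1 = harmonics.amplitudes[0]
    for k, (a, ph) in enumerate(zip(harmonics.amplitudes, harmonics.phases), start=1):
        x += (a / a1) * np.cos(k * phi + ph)
    return Waveform(x, rate, f_carrier=f_eod)
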