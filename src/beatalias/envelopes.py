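"""Static nonlinearities and the pulse-train theory of envelope extraction.

The superposition of a carrier cosine (frequency ``f1``, amplitude 1) and a
stimulus cosine (frequency ``f2``, amplitude ``alpha``) shows slow "beat-like"
envelopes whenever ``f2`` comes close to an integer multiple of ``f1`` -- yet
its power spectrum contains only the two original frequencies.  A static
nonlinearity is required to create a spectral peak at the envelope frequency,
and which nonlinearity is applied decides near which multiples of the carrier
such a peak appears:

* half-wave rectification (:func:`threshold`) creates low-frequency peaks for
  stimulus frequencies near odd multiples of the carrier only;
* rectification followed by a cubic power (:func:`power_threshold` with
  ``p=3``) additionally fills in the even multiples, covering the alias
  ``|f2 - round(f2/f1)*f1|`` up to ``f2 = 3.5*f1``;
* the Hilbert-transform envelope (:func:`analytic_envelope`) and
  :func:`square` instead track the raw difference frequency ``|f2 - f1|`` and
  therefore fail beyond ``f1/2``.

The spectral consequences of rectification are made analytically tractable by
the pulse-train approximation: for ``alpha -> 0`` the rectified signal equals
the raw signal multiplied by a binary square wave locked to the carrier
(:func:`pulse_train`), so the output spectrum is the convolution of the signal
spectrum with the square-wave spectrum (DC 1/2 plus odd harmonics with
coefficients ``2/(pi*k)`` of alternating sign).  :func:`predict_peaks`
evaluates that convolution in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert

from .signals import Waveform

__all__ = [
    "PeakPrediction",
    "threshold",
    "power_threshold",
    "square",
    "analytic_envelope",
    "running_average",
    "pulse_train",
    "pulse_train_approximation",
    "predict_peaks",
]


@dataclass(frozen=True)
class PeakPrediction:
    """A predicted spectral peak of a rectified-and-exponentiated two-tone signal.

    ``amplitude`` is the cosine amplitude of the spectral component measured
    relative to the stimulus contrast ``alpha``; ``provenance`` names the
    convolution branches (pulse-train harmonic x signal component) that
    contributed to it.
    """

    frequency: float
    amplitude: float
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.frequency < 0 or self.amplitude < 0:
            raise ValueError("frequency and amplitude must be non-negative")


def threshold(w: Waveform) -> Waveform:
    """Half-wave rectification: set all negative values to zero (ReLU)."""
    return w.with_samples(np.maximum(w.samples, 0.0))


def power_threshold(w: Waveform, p: float) -> Waveform:
    """Half-wave rectification followed by exponentiation, ``max(x, 0)**p``.

    ``p = 1`` reduces to plain rectification; ``p = 3`` is the smooth "cubed
    threshold" that models the transfer function of the receptor synapse.
    """
    if p <= 0:
        raise ValueError("exponent p must be positive")
    return w.with_samples(np.maximum(w.samples, 0.0) ** p)


def square(w: Waveform) -> Waveform:
    """Elementwise squaring, a classic (and here insufficient) envelope detector."""
    return w.with_samples(w.samples**2)


def analytic_envelope(w: Waveform) -> np.ndarray:
    """Magnitude of the analytic signal (Hilbert-transform envelope)."""
    return np.abs(hilbert(w.samples))


def running_average(w: Waveform, window: float | None = None) -> np.ndarray:
    """Centered moving average, by default over one carrier period.

    Averaging over a single carrier cycle keeps only frequency components
    slower than the carrier, acting as the low-pass filter that isolates the
    envelope after a nonlinearity.
    """
    if window is None:
        if w.f_carrier is None:
            raise ValueError("window required when waveform has no carrier frequency")
        window = 1.0 / w.f_carrier
    n = int(round(window * w.rate))
    if n < 2:
        raise ValueError("window must span at least 2 samples")
    if n > len(w.samples):
        raise ValueError("window longer than signal")
    return uniform_filter1d(w.samples, size=n, mode="nearest")


def pulse_train(carrier: Waveform) -> Waveform:
    """Binary square wave: one where the carrier is non-negative, zero elsewhere.

    For a pure cosine carrier this has a 50 % duty cycle and spectral peaks at
    zero and the odd multiples of the carrier frequency.  Skewed multi-harmonic
    carriers produce duty cycles different from 50 % and additional peaks at
    even multiples.
    """
    return carrier.with_samples((carrier.samples >= 0.0).astype(float))


def pulse_train_approximation(w: Waveform, carrier: Waveform) -> Waveform:
    """Approximate rectification of ``w`` by multiplying with the carrier's pulse train.

    Exact in the limit of vanishing stimulus contrast, where the zero
    crossings of the superposition coincide with those of the carrier.
    """
    if len(w) != len(carrier) or w.rate != carrier.rate:
        raise ValueError("signal and carrier must share the same sample grid")
    return w.with_samples(w.samples * (carrier.samples >= 0.0))


# ---------------------------------------------------------------------------
# Closed-form peak prediction


def _convolve(a: dict[int, float], b: dict[int, float]) -> dict[int, float]:
    """Convolution of two line spectra keyed by an integer frequency index."""
    out: dict[int, float] = {}
    for fa, xa in a.items():
        for fb, xb in b.items():
            f = fa + fb
            out[f] = out.get(f, 0.0) + xa * xb
    return out


def predict_peaks(
    f1: float,
    f2: float,
    alpha: float,
    p: int = 3,
    n_harmonics: int = 9,
    max_freq: float | None = None,
    amp_floor: float = 1e-9,
) -> list[PeakPrediction]:
    """Predicted spectral peaks of ``max(x, 0)**p`` for the two-cosine signal.

    The rectified-and-exponentiated signal is approximated as ``x(t)**p``
    multiplied by the carrier-locked square wave, valid for ``alpha << 1``.
    In the Fourier domain this is the convolution of the exact line spectrum
    of ``x**p`` (obtained by expanding the p-fold product of cosines) with the
    square-wave spectrum ``1/2 + sum_k_odd 2*(-1)^((k-1)/2)/(pi*k) cos(k w1 t)``
    truncated at harmonic ``n_harmonics``.  Components landing on the same
    frequency add coherently (signed), which reproduces the elevated
    amplitudes where spectral-peak branches cross (e.g. at ``f1/2`` for
    ``f2 = 1.5*f1``).

    Parameters
    ----------
    p:
        Threshold exponent; 1 and 3 are supported analytically.
    max_freq:
        Upper edge of the reported band; defaults to ``f1/2`` (inclusive),
        the envelope band below half the carrier.  DC is never reported.

    Returns
    -------
    list of :class:`PeakPrediction`, sorted by frequency, amplitudes relative
    to ``alpha``.
    """
    if f1 <= 0:
        raise ValueError("carrier frequency must be positive")
    if not 0 < alpha:
        raise ValueError("contrast alpha must be positive")
    if p not in (1, 3):
        raise ValueError("analytic prediction supports p in {1, 3} only")
    if max_freq is None:
        max_freq = f1 / 2

    # Represent line spectra on a fine integer grid in units of `quantum` so
    # that components within 1e-6*f1 of each other merge deterministically.
    quantum = 1e-6 * f1
    i1 = int(round(f1 / quantum))
    i2 = int(round(f2 / quantum))

    base = {+i1: 0.5, -i1: 0.5, +i2: alpha / 2, -i2: alpha / 2}
    signal = dict(base)
    for _ in range(p - 1):
        signal = _convolve(signal, base)

    # Square-wave (pulse-train) spectrum: DC plus odd harmonics.
    pulse_components: list[tuple[str, dict[int, float]]] = [("dc", {0: 0.5})]
    for k in range(1, n_harmonics + 1, 2):
        c = (-1.0) ** ((k - 1) // 2) / (np.pi * k)
        pulse_components.append((f"k={k}", {+k * i1: c, -k * i1: c}))

    amps: dict[int, float] = {}
    branches: dict[int, set[str]] = {}
    for label, comp in pulse_components:
        for f, x in _convolve(signal, comp).items():
            amps[f] = amps.get(f, 0.0) + x
            branches.setdefault(f, set()).add(label)

    peaks = []
    imax = int(round(max_freq / quantum)) + 1  # +1: inclusive band edge
    for fi, x in amps.items():
        if fi <= 0 or fi > imax:
            continue
        amp = abs(2 * x) / alpha  # cosine amplitude, relative to alpha
        if amp < amp_floor:
            continue
        peaks.append(
            PeakPrediction(
                frequency=fi * quantum,
                amplitude=amp,
                provenance=tuple(sorted(branches[fi])),
            )
        )
    return sorted(peaks, key=lambda pk: pk.frequency)


def peaks_to_frame(peaks: list[PeakPrediction]):
    """Peak predictions as a pandas DataFrame (frequency_hz, amplitude_rel, branch)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "frequency_hz": [pk.frequency for pk in peaks],
            "amplitude_rel": [pk.amplitude for pk in peaks],
            "branch": ["+".join(pk.provenance) for pk in peaks],
        }
    )
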