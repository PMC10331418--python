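"""Synthetic electric-field signals: two-cosine superpositions, EOD-like carriers, SAMs.

A wave-type electric fish produces a quasi-sinusoidal electric organ discharge
(EOD).  A second fish, or an experimental stimulus electrode, superimposes a
second periodic signal on top of it.  All stimuli in this package are built
from these primitives:

* :func:`synth_superposition` -- carrier cosine plus stimulus cosine,
  ``x(t) = cos(2*pi*f1*t) + alpha*cos(2*pi*f2*t)``, with the carrier amplitude
  normalized to one and the stimulus contrast ``alpha`` expressed relative to it.
* :func:`synth_eod` -- multi-harmonic EOD-like carrier built from a
  :class:`EODTemplate` of relative harmonic amplitudes and phases.
* :func:`synth_sam` -- sinusoidal amplitude modulation (SAM) control stimulus,
  ``(1 + alpha*cos(2*pi*f_am*t)) * cos(2*pi*f1*t)``, which has three spectral
  peaks instead of the superposition's two.
* :func:`cycle_envelope` -- per-carrier-cycle upper/lower envelopes for
  visualization and qualitative checks.

The default sampling rate is 40 kHz throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "DEFAULT_RATE",
    "AliasingError",
    "Waveform",
    "EODTemplate",
    "skewed_eod_template",
    "synth_superposition",
    "synth_eod",
    "synth_sam",
    "cycle_envelope",
]

#: Default sampling rate in Hz (digitization rate of the electrophysiology setup).
DEFAULT_RATE = 40_000.0


class AliasingError(ValueError):
    """A requested frequency is at or above the Nyquist frequency."""


@dataclass
class Waveform:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples:
        Dimensionless amplitude samples; for superpositions the carrier is
        normalized to amplitude one.
    rate:
        Sampling rate in Hz.
    f_carrier, f_stim, contrast:
        Optional metadata: carrier frequency (Hz), stimulus frequency (Hz) and
        stimulus contrast (fraction of the carrier amplitude).
    """

    samples: np.ndarray
    rate: float
    f_carrier: float | None = None
    f_stim: float | None = None
    contrast: float | None = None

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return len(self.samples) / self.rate

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds."""
        return np.arange(len(self.samples)) / self.rate

    def with_samples(self, samples: np.ndarray) -> "Waveform":
        """Copy of this waveform with new samples but identical metadata."""
        return replace(self, samples=np.asarray(samples, dtype=float))

    def to_csv(self, path: str | Path) -> None:
        """Write as two-column CSV (time_s, amplitude)."""
        data = np.column_stack([self.times, self.samples])
        np.savetxt(path, data, delimiter=",", header="time_s,amplitude", comments="")

    @classmethod
    def from_csv(cls, path: str | Path, **metadata) -> "Waveform":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        t, x = data[:, 0], data[:, 1]
        rate = 1.0 / np.median(np.diff(t))
        return cls(samples=x, rate=float(rate), **metadata)


@dataclass(frozen=True)
class EODTemplate:
    """Harmonic structure of an EOD waveform.

    ``amplitudes[k-1]`` and ``phases[k-1]`` are the amplitude (relative to the
    fundamental, which is one by convention) and phase in radians of the k-th
    harmonic of the EOD frequency.
    """

    amplitudes: tuple[float, ...]
    phases: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.amplitudes) < 1:
            raise ValueError("template needs at least the fundamental")
        phases = self.phases or tuple(0.0 for _ in self.amplitudes)
        if len(phases) != len(self.amplitudes):
            raise ValueError("amplitudes and phases must have equal length")
        object.__setattr__(self, "phases", tuple(float(p) for p in phases))
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))

    @property
    def n_harmonics(self) -> int:
        return len(self.amplitudes)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "harmonic": list(range(1, self.n_harmonics + 1)),
                    "amplitude": list(self.amplitudes),
                    "phase_rad": list(self.phases),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "EODTemplate":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["amplitude"]), tuple(d["phase_rad"]))


def skewed_eod_template(a2: float = 0.5) -> EODTemplate:
    """Synthetic two-harmonic stand-in for a real EOD harmonic template.

    The harmonic amplitudes/phases of real *A. leptorhynchus* EODs are not
    shipped with this package, so tests that need an asymmetric (skewed)
    carrier use this synthetic template: a second harmonic of relative
    amplitude ``a2`` in antiphase, which makes the waveform spend more than
    half of each period above zero.  ``a2 = 0.5`` gives a duty cycle of about
    61 %; ``a2 = 1.0`` places the zero crossings at exactly +-120 degrees
    (duty cycle 2/3), for which the third harmonic of the associated pulse
    train vanishes -- the configuration in which plain rectification loses
    the alias response around the third carrier multiple.
    """
    return EODTemplate(amplitudes=(1.0, float(a2)), phases=(0.0, np.pi))


def _check_nyquist(f: float, rate: float, what: str) -> None:
    if f >= rate / 2:
        raise AliasingError(f"{what} frequency {f} Hz is not below Nyquist ({rate / 2} Hz)")


def _time_axis(rate: float, duration: float) -> np.ndarray:
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(rate * duration))
    return np.arange(n) / rate


def synth_superposition(
    f1: float,
    f2: float,
    alpha: float,
    rate: float = DEFAULT_RATE,
    duration: float = 1.0,
    phase1: float = 0.0,
    phase2: float = 0.0,
) -> Waveform:
    """Superposition of a unit-amplitude carrier cosine and a stimulus cosine.

    ``x(t) = cos(2*pi*f1*t + phase1) + alpha*cos(2*pi*f2*t + phase2)``

    This is the signal a fish experiences when a second periodic electric
    field of relative amplitude ``alpha`` (the contrast) adds to its own EOD.
    """
    _check_nyquist(f1, rate, "carrier")
    _check_nyquist(f2, rate, "stimulus")
    t = _time_axis(rate, duration)
    x = np.cos(2 * np.pi * f1 * t + phase1) + alpha * np.cos(2 * np.pi * f2 * t + phase2)
    return Waveform(x, rate, f_carrier=f1, f_stim=f2, contrast=alpha)


def synth_eod(
    template: EODTemplate,
    f_eod: float,
    rate: float = DEFAULT_RATE,
    duration: float = 1.0,
) -> Waveform:
    """Periodic multi-harmonic EOD-like carrier.

    Sums ``a_k * cos(2*pi*k*f_eod*t + phi_k)`` over the template harmonics and
    rescales the amplitudes so the fundamental has amplitude one, matching the
    convention of a receiving fish's EOD normalized to amplitude one.
    """
    if template.n_harmonics * f_eod >= rate / 2:
        raise AliasingError(
            f"harmonic {template.n_harmonics} of {f_eod} Hz is not below Nyquist"
        )
    t = _time_axis(rate, duration)
    a1 = template.amplitudes[0]
    x = np.zeros_like(t)
    for k, (a, phi) in enumerate(zip(template.amplitudes, template.phases), start=1):
        x += (a / a1) * np.cos(2 * np.pi * k * f_eod * t + phi)
    return Waveform(x, rate, f_carrier=f_eod)


def synth_sam(
    f1: float,
    f_am: float,
    alpha: float,
    rate: float = DEFAULT_RATE,
    duration: float = 1.0,
) -> Waveform:
    """Sinusoidal amplitude modulation (SAM) stimulus.

    ``(1 + alpha*cos(2*pi*f_am*t)) * cos(2*pi*f1*t)`` -- a carrier multiplied
    by a periodic modulation.  Unlike the two-cosine superposition its
    spectrum has three peaks: ``f1`` and the side bands ``f1 +- f_am``.
    """
    if f_am >= f1:
        raise ValueError("modulation frequency must be below the carrier frequency")
    _check_nyquist(f1 + f_am, rate, "upper side band")
    t = _time_axis(rate, duration)
    x = (1 + alpha * np.cos(2 * np.pi * f_am * t)) * np.cos(2 * np.pi * f1 * t)
    return Waveform(x, rate, f_carrier=f1, f_stim=f_am, contrast=alpha)


def cycle_envelope(
    w: Waveform, f_carrier: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Upper and lower envelopes through per-carrier-cycle extrema.

    For each full carrier cycle the maximum and minimum sample are located;
    the envelopes are piecewise-linear interpolations through these extrema,
    resampled on the waveform's own time grid.  Intended for visualization and
    qualitative checks, not for quantitative spectral statements.

    Returns ``(upper, lower)`` arrays of the same length as ``w.samples``.
    """
    f_carrier = f_carrier if f_carrier is not None else w.f_carrier
    if f_carrier is None or f_carrier <= 0:
        raise ValueError("carrier frequency required for cycle segmentation")
    n_cycles = int(np.floor(w.duration * f_carrier))
    if n_cycles < 3:
        raise ValueError("waveform must contain at least 3 carrier cycles")
    t = w.times
    x = w.samples
    t_up, v_up, t_lo, v_lo = [], [], [], []
    for c in range(n_cycles):
        i0 = int(round(c * w.rate / f_carrier))
        i1 = int(round((c + 1) * w.rate / f_carrier))
        i1 = min(i1, len(x))
        if i1 - i0 < 2:
            continue
        seg = x[i0:i1]
        imax = i0 + int(np.argmax(seg))
        imin = i0 + int(np.argmin(seg))
        t_up.append(t[imax])
        v_up.append(x[imax])
        t_lo.append(t[imin])
        v_lo.append(x[imin])
    upper = np.interp(t, t_up, v_up)
    lower = np.interp(t, t_lo, v_lo)
    return upper, lower
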