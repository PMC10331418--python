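"""Stimulus-frequency sweeps, population tuning curves and the exponent scan.

A sweep drives either a static nonlinearity cascade (e.g. the cubed
threshold) or a stochastic P-unit model with two-cosine superpositions whose
stimulus frequency steps across multiples of the carrier (EOD) frequency, and
collects for every stimulus frequency the response frequency ``fresp``, the
response amplitude ``Aresp`` and the expected alias ``fexp``.

The exponent scan re-simulates a population of P-unit models with different
threshold exponents ``p`` (re-tuning the bias current so the baseline rate is
preserved) and scores each against reference tuning curves by the root mean
squared error of the frequency and amplitude tuning separately.  Reference
curves are themselves simulated (a parameter-recovery design); recorded
tuning curves are not available in numerical form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import punit, spectral
from .signals import DEFAULT_RATE, EODTemplate, Waveform, synth_eod, synth_superposition
from .spectral import TuningCurve

__all__ = [
    "SweepConfig",
    "cascade",
    "run_sweep",
    "population_summary",
    "rmse_exponent_scan",
]


def default_grid() -> np.ndarray:
    """Relative stimulus frequencies 0.05 to 4.0 in steps of 0.05."""
    return np.round(np.arange(1, 81) * 0.05, 10)


@dataclass
class SweepConfig:
    """Study conditions of one stimulus-frequency sweep.

    Defaults mirror the experimental protocol: contrast 20 %, 1 s trials,
    a 0.5 ms Gaussian rate kernel, and a 0.05-step grid of stimulus
    frequencies in multiples of the EOD frequency.
    """

    f_eod: float = 750.0
    rel_freqs: np.ndarray = field(default_factory=default_grid)
    alpha: float = 0.2
    n_trials: int = 1
    duration: float = 1.0
    kernel_sigma: float = 0.0005
    seed: int = 0
    rate: float = DEFAULT_RATE
    carrier_template: EODTemplate | None = None

    def __post_init__(self) -> None:
        self.rel_freqs = np.asarray(self.rel_freqs, dtype=float)
        if np.any(self.rel_freqs < 0):
            raise ValueError("relative stimulus frequencies must be non-negative")
        if self.alpha <= 0:
            raise ValueError("contrast alpha must be positive")
        if self.duration < 0.5:
            raise ValueError("trial duration must be at least 0.5 s")

    def carrier(self) -> Waveform:
        if self.carrier_template is None:
            return synth_superposition(
                self.f_eod, self.f_eod, 0.0, self.rate, self.duration
            )
        return synth_eod(self.carrier_template, self.f_eod, self.rate, self.duration)

    def stimulus(self, fstim: float) -> Waveform:
        base = self.carrier()
        t = base.times
        x = base.samples + self.alpha * np.cos(2 * np.pi * fstim * t)
        return Waveform(x, self.rate, f_carrier=self.f_eod, f_stim=fstim, contrast=self.alpha)


def cascade(p: float) -> Callable[[Waveform], np.ndarray]:
    """A spikeless envelope-extraction cascade: rectify and raise to power ``p``."""

    def apply(w: Waveform) -> np.ndarray:
        return np.maximum(w.samples, 0.0) ** p

    apply.p = p  # type: ignore[attr-defined]
    return apply


def _trial_seed(master: int, freq_idx: int, trial: int) -> int:
    """Deterministic per-trial seed derived from (master seed, frequency, trial)."""
    ss = np.random.SeedSequence([int(master), int(freq_idx), int(trial)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_sweep(model_or_cascade, cfg: SweepConfig) -> TuningCurve:
    """Tuning curve of a P-unit model or a nonlinearity cascade.

    For a :class:`~beatalias.punit.PUnitParams` model, each stimulus frequency
    is presented for ``cfg.n_trials`` trials; spike trains are convolved with
    the Gaussian rate kernel, their power spectra averaged, and ``fresp`` /
    ``Aresp`` read off the averaged spectrum.  A cascade (any callable mapping
    a waveform to a response series) is analyzed the same way without spiking.
    """
    is_model = isinstance(model_or_cascade, punit.PUnitParams)
    fresp = np.empty(len(cfg.rel_freqs))
    aresp = np.empty(len(cfg.rel_freqs))
    fstim_hz = cfg.rel_freqs * cfg.f_eod
    for i, fstim in enumerate(fstim_hz):
        stim = cfg.stimulus(fstim)
        densities = []
        freqs = None
        n_trials = cfg.n_trials if is_model else 1
        for trial in range(n_trials):
            if is_model:
                st = punit.simulate(
                    model_or_cascade, stim, seed=_trial_seed(cfg.seed, i, trial)
                )
                binary = spectral.spikes_to_binary(st, cfg.rate)
                response = spectral.kernel_rate(binary, cfg.kernel_sigma, cfg.rate)
            else:
                response = np.asarray(model_or_cascade(stim), dtype=float)
            ps = spectral.psd(response, cfg.rate)
            densities.append(ps.density)
            freqs = ps.frequencies
        mean_ps = spectral.PowerSpectrum(freqs, np.mean(densities, axis=0))
        fresp[i] = spectral.response_frequency(mean_ps, cfg.f_eod)
        aresp[i] = spectral.response_amplitude(mean_ps, fresp[i])
    return TuningCurve(f_eod=cfg.f_eod, fstim=fstim_hz, fresp=fresp, aresp=aresp)


def population_summary(curves: Sequence[TuningCurve]) -> pd.DataFrame:
    """Pointwise median and interquartile range of frequency and amplitude tuning."""
    if not curves:
        raise ValueError("need at least one tuning curve")
    grid = curves[0].fstim
    for tc in curves[1:]:
        if len(tc.fstim) != len(grid) or not np.allclose(tc.fstim, grid):
            raise ValueError("tuning curves must share the stimulus-frequency grid")
    fresp = np.vstack([tc.fresp for tc in curves])
    aresp = np.vstack([tc.aresp for tc in curves])
    out = {"fstim_hz": grid, "fstim_rel": grid / curves[0].f_eod}
    for name, data in (("fresp", fresp), ("aresp", aresp)):
        out[f"{name}_median"] = np.median(data, axis=0)
        out[f"{name}_q25"] = np.percentile(data, 25, axis=0)
        out[f"{name}_q75"] = np.percentile(data, 75, axis=0)
    return pd.DataFrame(out)


def tuning_rmse(a: TuningCurve, b: TuningCurve) -> tuple[float, float]:
    """Frequency- and amplitude-tuning RMSE between two curves on a shared grid."""
    if len(a) != len(b) or not np.allclose(a.fstim, b.fstim):
        raise ValueError("tuning curves must share the stimulus-frequency grid")
    rmse_f = float(np.sqrt(np.mean((a.fresp - b.fresp) ** 2)))
    rmse_a = float(np.sqrt(np.mean((a.aresp - b.aresp) ** 2)))
    return rmse_f, rmse_a


def rmse_exponent_scan(
    models: Sequence[punit.PUnitParams],
    reference: Sequence[TuningCurve],
    p_grid: Sequence[float],
    cfg: SweepConfig,
    rebalance: bool = True,
) -> pd.DataFrame:
    """RMSE between model tuning curves at each exponent and reference curves.

    For each model and each exponent ``p`` the bias current is re-tuned to
    preserve the model's baseline rate (unless ``rebalance=False``), a sweep
    is simulated, and frequency-/amplitude-tuning RMSEs against every
    reference curve are recorded.  Returns a tidy DataFrame with columns
    ``cell, p, ref, rmse_freq, rmse_amp``.
    """
    rows = []
    carrier = cfg.carrier()
    for model in models:
        target = None
        if rebalance:
            target = punit._baseline_rate(model, carrier, seed=cfg.seed)
        for p in p_grid:
            m = model.with_exponent(float(p))
            if rebalance and p != model.p:
                m = punit.rebalance_bias(
                    model, float(p), carrier, target_rate=target, seed=cfg.seed
                )
            tc = run_sweep(m, cfg)
            for j, ref in enumerate(reference):
                rmse_f, rmse_a = tuning_rmse(tc, ref)
                rows.append(
                    {
                        "cell": model.cell,
                        "p": float(p),
                        "ref": j,
                        "rmse_freq": rmse_f,
                        "rmse_amp": rmse_a,
                    }
                )
    return pd.DataFrame(rows)
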