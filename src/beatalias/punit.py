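"""Adapting leaky integrate-and-fire model of P-unit electroreceptor afferents.

The model is a cascade of three stages driven by the electrosensory stimulus
``x(t)`` (carrier EOD plus stimulus, carrier amplitude one):

1. a static nonlinearity, half-wave rectification raised to a power ``p``
   (``max(x, 0)**p``), standing for the transfer function of the receptor
   ribbon synapses;
2. a dendritic low-pass filter, ``tau_d * dV_d/dt = -V_d + max(x, 0)**p``,
   which isolates slow envelope components while keeping enough carrier to
   produce the partial phase locking of P-unit spikes to the EOD;
3. an adapting, noisy leaky integrate-and-fire (LIF) spike generator,

   ``tau_m * dV_m/dt = -V_m + f(V_m) + mu + beta*V_d - A + sqrt(2*D)*xi``,

   with unit spike threshold, reset to zero, absolute refractoriness
   ``t_ref``, and a spike-triggered adaptation current ``A`` that decays with
   ``tau_A`` and is incremented at each spike (``tau_A * dA/dt = -A``).
   ``f(V_m)`` is zero for the LIF and the exponential spike-initiation term
   ``Delta_V * exp((V_m - 1)/Delta_V)`` for the EIF variant.

``xi`` is unit-intensity Gaussian white noise; the Euler-Maruyama increment is
``sqrt(2*D*dt)*N(0,1)`` added to the numerator of the voltage update, with
``D`` in ms and all voltages dimensionless.  All time constants are in ms as
printed in the packaged nine-cell parameter table; spike times are returned
in seconds.

Convention note: the per-spike adaptation increment is implemented as
``Delta_A / tau_A``.  With the packaged parameter values this convention
yields baseline rates of a few hundred Hz, consistent with the physiological
P-unit range the parameters were fitted to; a raw ``Delta_A`` jump would
silence the models almost completely.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import brentq

from .signals import Waveform
from .spectral import SpikeTrain

__all__ = [
    "PUnitParams",
    "BaselineStats",
    "eif_term",
    "simulate",
    "baseline_stats",
    "rebalance_bias",
    "load_param_table",
]


@dataclass(frozen=True)
class PUnitParams:
    """Parameters of one P-unit model (time constants in ms, voltages dimensionless)."""

    beta: float  # input gain of the dendritic voltage
    tau_m: float  # membrane time constant, ms
    mu: float  # bias current
    D: float  # noise strength, ms
    tau_A: float  # adaptation time constant, ms
    delta_A: float  # adaptation strength (per-spike increment is delta_A/tau_A)
    tau_d: float  # dendritic low-pass time constant, ms
    t_ref: float  # absolute refractory period, ms
    p: float = 1.0  # threshold exponent of the input nonlinearity
    delta_V: float | None = None  # EIF softness; None -> plain LIF
    cell: str = ""

    #: spike threshold and reset are fixed by the model definition
    threshold: float = 1.0
    reset: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_A", "tau_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t_ref < 0 or self.D < 0 or self.p <= 0:
            raise ValueError("t_ref and D must be non-negative, p positive")

    def with_exponent(self, p: float) -> "PUnitParams":
        return replace(self, p=p)


@dataclass(frozen=True)
class BaselineStats:
    """Baseline firing statistics of a spike train relative to its carrier."""

    rate: float  # Hz
    cv: float  # coefficient of variation of the ISIs
    rho1: float  # serial ISI correlation at lag one
    vector_strength: float  # phase locking to the carrier, 0..1


def eif_term(v_m: float, delta_V: float) -> float:
    """Exponential spike-initiation current ``Delta_V * exp((V_m - 1)/Delta_V)``.

    Strictly increasing in ``v_m``; equals ``Delta_V`` at the threshold
    voltage 1 and is numerically zero well below it.  The plain LIF is the
    ``Delta_V -> 0`` limit.
    """
    return float(delta_V * np.exp(min((v_m - 1.0) / delta_V, 60.0)))


@njit(cache=True)
def _integrate(
    drive, dt, tau_m, mu, beta, tau_a, a_incr, tau_d, t_ref, D, delta_v, noise, warm_steps
):  # pragma: no cover - exercised through simulate()
    n = drive.shape[0]
    cap = int(n * dt / max(t_ref, dt)) + 8
    spikes = np.empty(cap)
    count = 0
    v_d = 0.0
    v_m = 0.0
    a = 0.0
    last = -1.0e30
    vth = 1.0 + 10.0 * delta_v if delta_v > 0.0 else 1.0
    for i in range(n):
        t = i * dt
        v_d += (drive[i] - v_d) * dt / tau_d
        fv = 0.0
        if delta_v > 0.0:
            arg = (v_m - 1.0) / delta_v
            if arg > 60.0:
                arg = 60.0
            fv = delta_v * np.exp(arg)
        v_m += ((-v_m + fv + mu + beta * v_d - a) * dt + noise[i]) / tau_m
        a -= a * dt / tau_a
        if t - last < t_ref:
            v_m = 0.0  # hard refractory clamp at reset
        elif v_m >= vth:
            v_m = 0.0
            a += a_incr
            last = t
            if i >= warm_steps:
                spikes[count] = t
                count += 1
        if not (np.isfinite(v_m) and np.isfinite(a) and np.isfinite(v_d)):
            return spikes[:count], False
    return spikes[:count], True


def simulate(
    params: PUnitParams,
    stimulus: Waveform,
    seed: int = 0,
    warmup: float = 0.5,
) -> SpikeTrain:
    """Euler-Maruyama simulation of the P-unit model driven by a stimulus.

    The stimulus is half-wave rectified and raised to ``params.p`` before it
    enters the dendritic filter.  A warm-up period (default 0.5 s), fed with
    the beginning of the stimulus itself, is simulated first and discarded so
    that adaptation has settled; spike times are reported in seconds relative
    to stimulus onset.
    """
    dt = 1000.0 / stimulus.rate  # ms
    drive = np.maximum(stimulus.samples, 0.0) ** params.p
    warm_steps = int(round(warmup * stimulus.rate))
    if warm_steps > 0:
        pad = drive[:warm_steps] if warm_steps <= len(drive) else np.resize(drive, warm_steps)
        drive = np.concatenate([pad, drive])
    rng = np.random.default_rng(seed)
    if params.D > 0:
        noise = rng.standard_normal(len(drive)) * np.sqrt(2.0 * params.D * dt)
    else:
        noise = np.zeros(len(drive))
    spikes_ms, ok = _integrate(
        drive,
        dt,
        params.tau_m,
        params.mu,
        params.beta,
        params.tau_A,
        params.delta_A / params.tau_A,
        params.tau_d,
        params.t_ref,
        params.D,
        params.delta_V if params.delta_V is not None else 0.0,
        noise,
        warm_steps,
    )
    if not ok:
        raise FloatingPointError("membrane state became non-finite; unstable dt or parameters")
    times = np.asarray(spikes_ms) / 1000.0 - warmup
    times = times[times < stimulus.duration]
    return SpikeTrain(times=times, duration=stimulus.duration)


def baseline_stats(st: SpikeTrain, carrier: Waveform) -> BaselineStats:
    """Firing rate, ISI variability and EOD phase locking of a spike train.

    The vector strength is ``|<exp(i*phi)>|`` with ``phi`` the carrier phase
    ``2*pi*f_carrier*t`` at each spike time.
    """
    if carrier.f_carrier is None:
        raise ValueError("carrier waveform must define f_carrier")
    rate = len(st) / st.duration
    if len(st) < 3:
        raise ValueError("need at least 3 spikes for ISI statistics")
    isi = np.diff(st.times)
    cv = float(np.std(isi) / np.mean(isi))
    if len(isi) > 1:
        rho1 = float(np.corrcoef(isi[:-1], isi[1:])[0, 1])
    else:
        rho1 = 0.0
    phases = 2 * np.pi * carrier.f_carrier * st.times
    vs = float(np.abs(np.mean(np.exp(1j * phases))))
    return BaselineStats(rate=rate, cv=cv, rho1=rho1, vector_strength=vs)


def _baseline_rate(params: PUnitParams, carrier: Waveform, seed: int) -> float:
    st = simulate(params, carrier, seed=seed)
    return len(st) / st.duration


def rebalance_bias(
    params: PUnitParams,
    new_p: float,
    carrier: Waveform,
    target_rate: float | None = None,
    seed: int = 0,
    rel_tol: float = 0.02,
) -> PUnitParams:
    """Adjust the bias current ``mu`` so a modified exponent keeps the baseline rate.

    When the threshold exponent of a fitted model is changed, its mean input
    changes too; the bias current is re-tuned by a scalar root find (baseline
    rate is monotonically increasing in ``mu``) until the simulated baseline
    rate on the plain carrier is within ``rel_tol`` of the original one.
    """
    if target_rate is None:
        target_rate = _baseline_rate(params, carrier, seed)
    if new_p == params.p:
        return params
    new = params.with_exponent(new_p)
    if target_rate <= 0:
        raise ValueError("target baseline rate must be positive")

    def objective(mu: float) -> float:
        return _baseline_rate(replace(new, mu=mu), carrier, seed) - target_rate

    # bracket the root by expanding around the original bias
    lo = hi = params.mu
    step = max(10.0, abs(params.mu) * 0.5)
    f_lo = f_hi = objective(params.mu)
    for _ in range(40):
        if f_lo > 0:
            lo -= step
            f_lo = objective(lo)
        elif f_hi < 0:
            hi += step
            f_hi = objective(hi)
        else:
            break
        step *= 1.6
    if f_lo > 0 or f_hi < 0:
        raise RuntimeError("could not bracket the bias current for the target rate")
    mu_star = brentq(objective, lo, hi, xtol=1e-3, rtol=1e-6, maxiter=200)
    result = replace(new, mu=float(mu_star))
    achieved = _baseline_rate(result, carrier, seed)
    if abs(achieved - target_rate) > rel_tol * target_rate:
        raise RuntimeError(
            f"rebalancing missed the target rate: {achieved:.1f} vs {target_rate:.1f} Hz"
        )
    return result


def load_param_table() -> list[PUnitParams]:
    """The nine fitted P-unit parameter sets shipped with the package."""
    with resources.files("beatalias.data").joinpath("punit_params.csv").open() as fh:
        table = pd.read_csv(fh)
    return [
        PUnitParams(
            beta=row.beta,
            tau_m=row.tau_m_ms,
            mu=row.mu,
            D=row.D_ms,
            tau_A=row.tau_A_ms,
            delta_A=row.delta_A,
            tau_d=row.tau_d_ms,
            t_ref=row.t_ref_ms,
            cell=row.cell,
        )
        for row in table.itertuples()
    ]


def param_table_frame() -> pd.DataFrame:
    """The packaged parameter table as a DataFrame (columns as printed)."""
    with resources.files("beatalias.data").joinpath("punit_params.csv").open() as fh:
        return pd.read_csv(fh)
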