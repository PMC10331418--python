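# Methods

This note documents the models, conventions and numerical choices behind
`beatalias`, in the package's own words.

## Signals

All stimuli are superpositions of a carrier (the receiving fish's EOD,
normalized to amplitude one) and a stimulus cosine of contrast α, sampled at
40 kHz by default.  Multi-harmonic EOD-like carriers are built from a
template of relative harmonic amplitudes and phases and rescaled so the
fundamental has amplitude one.  The harmonic content of real
*A. leptorhynchus* EODs is not shipped; `skewed_eod_template()` is a
synthetic two-harmonic stand-in whose only job is to give the carrier an
asymmetric duty cycle.  With a second harmonic of relative amplitude 1 in
antiphase the zero crossings sit at exactly ±120°, the associated pulse
train has a duty cycle of 2/3 and its third harmonic vanishes — the
configuration in which plain rectification loses the alias response around
the third carrier multiple while the cubed threshold keeps it.

Upper/lower cycle envelopes are piecewise-linear interpolations through
per-carrier-cycle extrema.  They are a visualization aid; all quantitative
statements go through spectra.  Because the extrema are sampled once per
carrier cycle, the interpolated envelope of a beat reaches its analytic
extremes (1 ± α) only to within about half a carrier cycle of envelope
phase; tests allow for that.

## Spectral-peak prediction (pulse-train approximation)

For α → 0 the rectified signal equals the raw signal times a binary square
wave locked to the carrier, so the output spectrum is the convolution of the
signal spectrum with the square-wave spectrum (DC ½; odd harmonics with
cosine amplitudes 2/(πk), alternating sign).  For the cubed threshold the
same multiplication is applied to x(t)³, whose exact line spectrum (eight
positive-frequency components for a two-tone input) is obtained by expanding
the triple product of cosines.  `predict_peaks` evaluates this convolution
symbolically on a frequency grid quantized at 10⁻⁶·f₁: components landing
within that tolerance merge, and their *signed* real amplitudes add, which
reproduces coherent summation where branches cross (e.g. both branches at
f₁/2 for f_stim = 1.5 f₁ are positive and add).  The square-wave series is
truncated at harmonic 9 by default; higher terms scale as 1/k and contribute
nothing above the reporting floor below f₁/2.  Reported amplitudes are
relative to α.  The approximation neglects the stimulus-induced shift of the
carrier's zero crossings, an O(α) effect; against a numerical FFT of the
actually rectified signal the predicted amplitudes agree to well within 10 %
at α ≤ 0.05 (the tests pin this).

Predictions are only offered for exponents p ∈ {1, 3}; other exponents are
handled numerically through the sweep machinery.

## Response analysis

Spike trains are binned at the acquisition rate (0.025 ms bins carrying the
value 40 kHz at spike bins, zero elsewhere, so the series integrates to the
spike count) and optionally convolved with a Gaussian kernel (σ = 0.5 ms or
2 ms) mimicking the postsynaptic potential.  In the frequency domain these
kernels are Gaussians of width (2πσ)⁻¹ — 318 Hz and 80 Hz; the package
computes this width numerically from the kernel's FFT (heavily zero-padded:
the spectral moment converges slowly in the frequency step).

Power spectra use Welch's method with 4096-sample segments, 50 % overlap and
a Hann window, discarding the first and last 5 ms of each trial.  Each
segment is mean-subtracted before windowing; without this, the large DC
component of rectified signals leaks into the lowest bins and masks slow
envelope peaks.  The window function is a package choice — the headline
quantities are window-insensitive, and bin-exact checks (the 69 Hz worked
example, the coverage scan) instead use a single full-length rectangular FFT
on integer-cycle signals, where no leakage exists at all.

The response frequency f_resp is the argmax of the spectral density over
(0, f_EOD/2]; the DC bin is excluded (rectification shifts the mean, which
is not a firing-rate modulation), and the upper edge is inclusive because
the alias of half-integer stimulus multiples lands exactly on it.  No
sub-bin interpolation is applied; finer resolution is obtained with longer
segments.  The response amplitude A_resp is the square root of the power
integrated over the five bins nearest f_resp; for a rate modulation A·cos at
a bin-centered frequency this recovers A/√2.  The expected alias uses
round-half-away-from-zero; by the alias symmetry the tie-break is
immaterial.  The f_max statistic accumulates stimulus-frequency bin widths
(f_{i+1} − f_{i−1})/2 where the squared relative deviation of f_resp from
the alias is below 5·10⁻⁴, with one-sided half-widths at the grid ends
(the interior-only formula leaves endpoints undefined).

## P-unit model

The model cascade is: static nonlinearity ⌊x⌋₀ᵖ → dendritic low-pass
(time constant τ_d) → adapting leaky integrate-and-fire neuron with
Gaussian white noise, unit threshold, zero reset, absolute refractoriness
t_ref, and a spike-triggered adaptation current A with decay constant τ_A.
All time constants are in ms as printed in the packaged nine-cell table;
voltages are dimensionless.  Integration is Euler–Maruyama at dt = 1/rate
(0.025 ms), with noise increment √(2 D dt)·N(0,1) added to the numerator of
the membrane-voltage update (D in ms).  The zero-noise firing rate matches
the closed-form LIF interspike interval to within 1 % at this dt, and
halving dt changes it by less than 1 %.

Conventions that the printed equations leave open, and how they were fixed:

* **Adaptation increment.** At each spike A increases by ΔA/τ_A.  With the
  printed parameter values (ΔA between 19.3 and 142.7, τ_A between 48 and
  295 ms) this convention produces baseline rates of a few hundred Hz,
  consistent with the physiological range the parameters were fitted to; a
  raw jump of ΔA would nearly silence every cell.  This matches the
  δ-input convention dA/dt = −A/τ_A + (ΔA/τ_A)·Σδ(t−t_i).
* **Refractoriness** is a hard clamp of the membrane voltage at reset for
  t_ref after each spike.
* **EIF variant.** The optional exponential spike-initiation term
  ΔV·exp((V−1)/ΔV) (ΔV between 0.001 and 0.1) uses a numerical spike
  criterion of V ≥ 1 + 10·ΔV; the result is insensitive to the exact
  cutoff, and ΔV → 0 recovers the LIF.
* **Initial conditions** are zero for all state variables with a 500 ms
  warm-up (fed with the beginning of the stimulus itself) discarded, long
  enough for adaptation to settle in every packaged cell.

The packaged parameters were fitted elsewhere at p = 1 against recorded
baseline and step-response statistics; absolute simulated rates therefore
depend on the unit conventions above and are validated *qualitatively*
(beat peak at the difference frequency near the carrier; envelope peak at
2.1 carrier multiples present for p = 3 and absent for p = 1; partial phase
locking with vector strength strictly between 0 and 1), not against the
recordings, which this package does not ingest.  When the threshold
exponent of a model is changed, `rebalance_bias` re-tunes the bias current
by a bracketed scalar root find (baseline rate is monotone in the bias)
until the baseline rate on the plain carrier is restored to within 2 %.
Baseline simulations use a 750 Hz cosine carrier by default — a value in the
middle of the species' EOD range; the per-cell fitting frequencies are not
published.

## Sweeps and the exponent scan

A sweep presents stimulus frequencies on a grid in multiples of f_EOD
(default 0.05–4.0 in 0.05 steps, 20 % contrast, 1 s trials) and records
f_resp, A_resp and the alias per frequency, averaging power spectra over
trials.  Per-trial seeds derive deterministically from (master seed,
frequency index, trial index).  Exact integer multiples of the carrier are
excluded from alias-following assertions since their alias is DC.

The exponent scan re-simulates models at exponents p, rebalancing the bias
per p, and scores frequency- and amplitude-tuning RMSEs against reference
curves.  Recorded tuning curves are not available numerically, so the
reference curves are themselves simulated at p = 3 — a parameter-recovery
design: the scan must identify the exponent that generated the references.
With four trials per frequency and a 0.1–3.3 grid this recovery is sharp
(RMSE at p = 3 an order of magnitude below neighboring exponents).  The
test-scale scan uses two cells and four exponents to stay fast; the CLI
exposes the full nine-cell scan.

## JAR analysis

The EOD frequency of a fish is tracked from a spectrogram (131072-sample
segments, 50 % overlap, Hann window — about 0.3 Hz bins and 3.3 s segments
at 40 kHz) as the peak frequency near the *second* harmonic divided by two;
the second harmonic is used because the stimulus sits within a few Hz of
the fundamental.  The search band is ±50 Hz around twice the estimated
fundamental (JAR shifts are a few Hz), and peaks are refined by parabolic
interpolation of log power across three bins, which brings sub-bin accuracy
to the sub-0.1 Hz level needed for 1 Hz shifts.  The steady-state shift is
the mean tracked frequency 15–25 s after stimulus onset minus the mean over
the 10 s before onset.  Protocol frequencies are k·f_EOD − 5 Hz for
k = 1…5 and +5 Hz for k = 0.

Behavioral recordings are not part of the package; `synth_jar_recording`
generates frequency-modulated multi-harmonic waveforms (exponential
approach to the programmed shift, phase-continuous by construction) for
closed-loop testing.  The round trip synth → track → shift recovers
programmed shifts of 1–6 Hz to within 2 %.

## What the synthetic data does and does not show

The generators emulate the study conditions: two-tone superpositions at
10–20 % contrast, EOD-like multi-harmonic carriers, SAM controls, and
JAR-style frequency-shifting recordings.  They do not emulate recording
noise, electrode drift, per-cell EOD frequencies, cell-to-cell sensitivity
differences, or the irregular stimulus grids of real experiments.  Passing
tests therefore establish the internal consistency of the theory and its
implementation — which nonlinearity creates which alias peaks, how kernels
attenuate fast envelopes, that the exponent is identifiable from tuning
curves — not quantitative agreement with any recorded cell.  Statistics
tied to the recorded population (baseline-rate correlations, sensitivity
splits, measured per-fish JAR shifts) are out of scope.

## Known limitations

* Analytic peak predictions cover p ∈ {1, 3} only; other exponents are
  simulated.
* The pulse-train approximation degrades with contrast (O(α) zero-crossing
  shifts); at α = 0.2 side peaks appear that the closed forms omit.
* The LIF unit conventions (noise scaling, adaptation increment) are fixed
  as described above; alternative conventions would require refitting the
  packaged parameters, which is out of scope.
* Tracking assumes a detectable second harmonic; recordings with a pure
  sinusoidal EOD are rejected rather than tracked at the fundamental.
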