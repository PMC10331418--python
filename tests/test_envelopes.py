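"""Static nonlinearities and the pulse-train peak prediction against FFT oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import beatalias as ba

from conftest import RATE, fft_cosine_amplitudes

F1 = 500.0


def beat(rel, alpha=0.2, rate=RATE, duration=1.0):
    return ba.synth_superposition(F1, rel * F1, alpha, rate, duration)


class TestThreshold:
    def test_elementwise_definition(self):
        w = ba.Waveform(np.array([-1.0, 0.0, 0.5]), RATE)
        assert np.allclose(ba.threshold(w).samples, [0.0, 0.0, 0.5])

    def test_idempotent(self):
        w = beat(1.3)
        once = ba.threshold(w).samples
        twice = ba.threshold(ba.threshold(w)).samples
        assert np.array_equal(once, twice)

    def test_mean_of_rectified_cosine(self):
        w = beat(1.0, alpha=0.0)
        # discrete sampling of the rectification kink limits agreement to ~1e-3
        assert np.mean(ba.threshold(w).samples) == pytest.approx(1 / np.pi, rel=1e-3)


class TestPowerThreshold:
    def test_p1_equals_threshold(self):
        w = beat(2.3)
        assert np.array_equal(ba.power_threshold(w, 1).samples, ba.threshold(w).samples)

    def test_mean_of_cubed_rectified_cosine(self):
        w = beat(1.0, alpha=0.0)
        assert np.mean(ba.power_threshold(w, 3).samples) == pytest.approx(
            2 / (3 * np.pi), rel=1e-6
        )

    def test_cubing_adds_envelope_peak_at_second_multiple(self):
        w = beat(2.1)
        fenv = 0.1 * F1
        for p, present in ((1, False), (3, True)):
            y = ba.power_threshold(w, p).samples
            freqs, amp = fft_cosine_amplitudes(y - np.mean(y), RATE)
            a = amp[freqs == fenv][0]
            if present:
                assert a > 0.01
            else:
                assert a < 0.002

    def test_rejects_nonpositive_exponent(self):
        with pytest.raises(ValueError):
            ba.power_threshold(beat(1.1), 0)


class TestSquare:
    def test_double_angle_identity(self):
        w = beat(1.0, alpha=0.0)
        y = ba.square(w).samples
        freqs, amp = fft_cosine_amplitudes(y, RATE)
        assert amp[freqs == 0][0] / 2 == pytest.approx(0.5, rel=1e-6)  # rfft DC
        peaks = freqs[(amp > 1e-6 * amp.max()) & (freqs > 0)]
        assert list(peaks) == [2 * F1]

    def test_tracks_difference_frequency_not_envelope(self):
        w = beat(3.05)
        y = ba.square(w).samples - np.mean(ba.square(w).samples)
        freqs, amp = fft_cosine_amplitudes(y, RATE)
        assert amp[freqs == 2.05 * F1][0] > 10 * amp[freqs == 0.05 * F1][0]

    def test_nonnegative(self):
        assert np.all(ba.square(beat(1.7)).samples >= 0)


class TestAnalyticEnvelope:
    def test_constant_for_pure_cosine(self):
        w = beat(1.0, alpha=0.0)
        env = ba.analytic_envelope(w)[1000:-1000]
        assert np.allclose(env, 1.0, atol=1e-3)

    def test_dominates_signal(self):
        w = beat(1.35)
        env = ba.analytic_envelope(w)
        assert np.all(env >= np.abs(w.samples) - 1e-9)

    def test_envelope_frequency_grows_past_octave(self):
        # near the carrier the Hilbert envelope shows the slow beat; near
        # twice the carrier it tracks a fast frequency instead of the slow alias
        for rel, expected in ((1.1, 0.1 * F1), (2.1, 1.1 * F1)):
            env = ba.analytic_envelope(beat(rel))[2000:-2000]
            env = env - np.mean(env)
            spec = np.abs(np.fft.rfft(env))
            freqs = np.fft.rfftfreq(len(env), 1 / RATE)
            assert freqs[np.argmax(spec)] == pytest.approx(expected, abs=2.0)


class TestRunningAverage:
    def test_zero_for_pure_cosine(self):
        w = beat(1.0, alpha=0.0)
        ra = ba.running_average(w)[200:-200]
        assert np.max(np.abs(ra)) < 1e-3

    def test_follows_envelope_near_carrier(self):
        y = ba.running_average(ba.threshold(beat(1.1)))
        y = y - np.mean(y)
        freqs, amp = fft_cosine_amplitudes(y, RATE)
        assert amp[freqs == 0.1 * F1][0] > 0.05

    def test_rectified_octave_beat_stays_flat(self):
        # at 2.05 multiples plain rectification leaves almost no envelope
        # modulation; the cubed threshold does
        fenv = 0.05 * F1

        def amp_at_env(p):
            y = ba.running_average(ba.power_threshold(beat(2.05), p))
            y = y - np.mean(y)
            freqs, amp = fft_cosine_amplitudes(y, RATE)
            return amp[freqs == fenv][0]

        assert amp_at_env(1) < 0.05 * amp_at_env(3)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            ba.running_average(beat(1.1), window=2.0)


class TestPulseTrain:
    def test_cosine_carrier_duty_cycle(self):
        carrier = beat(1.0, alpha=0.0)
        pt = ba.pulse_train(carrier)
        assert np.mean(pt.samples) == pytest.approx(0.5, abs=1e-3)

    def test_cosine_carrier_odd_harmonics_only(self):
        # half-sample phase offset keeps the zero crossings off the sample
        # grid, so the sampled pulse train is an exactly symmetric square wave
        carrier = ba.synth_superposition(
            F1, F1, 0.0, RATE, 1.0, phase1=np.pi * F1 / RATE
        )
        pt = ba.pulse_train(carrier)
        freqs, amp = fft_cosine_amplitudes(pt.samples, RATE)
        peaks = freqs[amp > 1e-3 * amp.max()]
        multiples = np.round(peaks / F1).astype(int)
        assert 0 in multiples
        assert all(m == 0 or m % 2 == 1 for m in multiples)
        # square-wave Fourier amplitude 2/(pi k)
        assert amp[freqs == F1][0] == pytest.approx(2 / np.pi, abs=1e-3)
        assert amp[freqs == 3 * F1][0] == pytest.approx(2 / (3 * np.pi), abs=1e-3)

    def test_skewed_carrier_gains_even_harmonic(self):
        eod = ba.synth_eod(ba.skewed_eod_template(), F1, RATE, 1.0)
        pt = ba.pulse_train(eod)
        assert np.mean(pt.samples) > 0.55  # duty cycle above 50 %
        freqs, amp = fft_cosine_amplitudes(pt.samples, RATE)
        assert amp[freqs == 2 * F1][0] > 0.1


class TestPulseTrainApproximation:
    def test_exact_at_zero_contrast(self):
        carrier = beat(1.0, alpha=0.0)
        approx = ba.pulse_train_approximation(carrier, carrier)
        assert np.array_equal(approx.samples, ba.threshold(carrier).samples)

    def test_accurate_at_small_contrast(self):
        w = beat(1.15, alpha=0.01)
        carrier = beat(1.0, alpha=0.0)
        approx = ba.pulse_train_approximation(w, carrier).samples
        true = ba.threshold(w).samples
        rel = np.linalg.norm(approx - true) / np.linalg.norm(true)
        assert rel < 0.02

    def test_visible_error_at_large_contrast(self):
        w = beat(1.15, alpha=0.2)
        carrier = beat(1.0, alpha=0.0)
        approx = ba.pulse_train_approximation(w, carrier).samples
        true = ba.threshold(w).samples
        rel = np.linalg.norm(approx - true) / np.linalg.norm(true)
        assert rel > 0.02

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ba.pulse_train_approximation(beat(1.1), beat(1.0, alpha=0.0, duration=0.5))


class TestPredictPeaks:
    def test_p1_beat_gives_single_difference_peak(self):
        peaks = ba.predict_peaks(F1, 1.15 * F1, 0.2, p=1)
        assert len(peaks) == 1
        assert peaks[0].frequency == pytest.approx(0.15 * F1)
        # amplitude of the first odd-harmonic branch: 1/pi relative to alpha
        assert peaks[0].amplitude == pytest.approx(1 / np.pi, rel=1e-6)

    def test_p1_octave_prediction_empty(self):
        assert ba.predict_peaks(F1, 2.05 * F1, 0.2, p=1) == []

    def test_p3_fills_octave(self):
        peaks = ba.predict_peaks(F1, 2.1 * F1, 0.2, p=3)
        freqs = [pk.frequency for pk in peaks]
        assert pytest.approx(0.1 * F1) in freqs

    def test_crossing_peaks_add_up(self):
        # at 1.5 multiples the DC branch of |2 f1 - f2| and the k=1 branch of
        # f2 coincide at f1/2 and add coherently
        peaks = ba.predict_peaks(F1, 1.5 * F1, 0.2, p=3)
        at_half = [pk for pk in peaks if pk.frequency == pytest.approx(F1 / 2)]
        assert len(at_half) == 1
        pk = at_half[0]
        assert {"dc", "k=1"} <= set(pk.provenance)
        assert pk.amplitude > 3 / 8 + 3 / (2 * np.pi) - 0.05  # coherent sum of branches

    def test_unsupported_exponent_rejected(self):
        with pytest.raises(ValueError):
            ba.predict_peaks(F1, 600.0, 0.1, p=2)

    @pytest.mark.parametrize("p", [1, 3])
    @pytest.mark.parametrize("rel", [0.35, 1.15, 1.5, 2.1, 2.45, 3.3])
    def test_oracle_equivalence(self, p, rel):
        """Predicted peaks match the FFT of the actually rectified signal.

        At small contrast the pulse-train approximation is accurate:
        positions agree to within one frequency bin and amplitudes to 10 %.
        """
        alpha, duration = 0.05, 2.0
        w = beat(rel, alpha=alpha, duration=duration)
        y = ba.power_threshold(w, p).samples
        freqs, amp = fft_cosine_amplitudes(y, RATE)
        for pk in ba.predict_peaks(F1, rel * F1, alpha, p=p):
            if pk.amplitude < 1e-3:
                continue  # below the numerical floor of the oracle
            i = int(round(pk.frequency * duration))
            assert freqs[i] == pytest.approx(pk.frequency, abs=1 / duration)
            assert amp[i] == pytest.approx(pk.amplitude * alpha, rel=0.10)

    def test_monotone_amplitude_decay_across_multiples(self):
        """The alias-peak amplitude shrinks with each carrier multiple."""
        for p in (1, 3):
            amps = []
            for rel in (1.1, 3.1, 5.1) if p == 1 else (1.1, 2.1, 3.1):
                peaks = ba.predict_peaks(F1, rel * F1, 0.05, p=p)
                match = [pk for pk in peaks if pk.frequency == pytest.approx(0.1 * F1)]
                assert match, f"no alias peak at rel={rel} for p={p}"
                amps.append(match[0].amplitude)
            assert all(a > b for a, b in zip(amps, amps[1:]))

    def test_p3_coverage_bound(self):
        """The cubed threshold predicts the alias peak up to 3.5 multiples only."""
        grid = np.round(np.arange(1, 91) * 0.05, 10)
        grid = grid[np.abs(grid - np.round(grid)) > 1e-9]
        for rel in grid:
            fexp = ba.expected_alias(rel * F1, F1)
            peaks = ba.predict_peaks(F1, rel * F1, 0.05, p=3)
            found = any(abs(pk.frequency - fexp) < 1e-6 * F1 for pk in peaks)
            if rel <= 3.5:
                assert found, f"missing alias peak at {rel}"
            elif rel < 4.5:
                assert not found, f"unexpected alias peak at {rel}"


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    rel=st.floats(0.05, 4.4).filter(lambda r: abs(r - round(r)) > 0.02),
    alpha=st.floats(0.01, 0.1),
)
def test_predicted_peaks_stay_in_band_and_positive(rel, alpha):
    peaks = ba.predict_peaks(F1, rel * F1, alpha, p=3)
    for pk in peaks:
        assert 0 < pk.frequency <= F1 / 2 + 1e-3
        assert pk.amplitude >= 0
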