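import numpy as np
import pytest

import beatalias as ba

RATE = 40_000.0


@pytest.fixture(scope="session")
def param_table():
    return ba.load_param_table()


@pytest.fixture(scope="session")
def cells(param_table):
    return {c.cell: c for c in param_table}


@pytest.fixture(scope="session")
def carrier_750():
    """Plain 750 Hz cosine carrier, 5 s, used for baseline simulations."""
    return ba.synth_superposition(750.0, 750.0, 0.0, RATE, 5.0)


def fft_cosine_amplitudes(x, rate):
    """Frequencies and cosine amplitudes of a full-length rectangular FFT."""
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), 1.0 / rate)
    return freqs, 2.0 * np.abs(spec) / len(x)


def count_spectral_peaks(x, rate, floor=1e-6, positive_only=True):
    """Number of distinct FFT components above ``floor`` times the maximum."""
    freqs, amp = fft_cosine_amplitudes(x, rate)
    mask = amp > floor * amp.max()
    if positive_only:
        mask &= freqs > 0
    return int(np.sum(mask)), freqs[mask]
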