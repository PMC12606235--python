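import numpy as np
import pandas as pd
import pytest

from callsim import synth
from callsim.detect import CallSegment

RATE = 250_000


def gaussian_feature_table(
    n_bats, n_calls, n_features=6, separation=0.0, seed=0, bat_prefix="b"
):
    """Feature table with per-bat Gaussian feature distributions.

    ``separation`` scales the SD of between-bat mean offsets (0 = zero
    signal).  Fast substitute for full waveform synthesis in tests of the
    statistical machinery.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_bats):
        mu = rng.normal(0.0, separation, n_features)
        X = rng.normal(mu, 1.0, size=(n_calls, n_features))
        for x in X:
            rows.append(
                {"bat_id": f"{bat_prefix}{k}", **{f"f{i}": v for i, v in enumerate(x)}}
            )
    return pd.DataFrame(rows)


def tone_segment(freq_hz=40_000.0, duration_s=0.010, rate=RATE, amplitude=1.0):
    t = np.arange(int(duration_s * rate)) / rate
    return CallSegment(
        "tone", 0.0, duration_s, amplitude * np.sin(2 * np.pi * freq_hz * t), rate
    )


def chirp_segment(f0_hz=80_000.0, f1_hz=20_000.0, duration_s=0.010, rate=RATE):
    t = np.arange(int(duration_s * rate)) / rate
    k = (f1_hz - f0_hz) / duration_s
    phase = 2 * np.pi * (f0_hz * t + 0.5 * k * t**2)
    return CallSegment("chirp", 0.0, duration_s, np.sin(phase), rate)


@pytest.fixture(scope="session")
def small_population():
    return synth.make_population(12, 2, seed=1)


@pytest.fixture(scope="session")
def synthetic_calls():
    """50 calls from one bat, as ready segments."""
    profiles, _ = synth.make_population(2, 1, seed=3)
    return synth.simulate_call_segments(profiles[0], 50, seed=4)
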