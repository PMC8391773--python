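import numpy as np
import pytest

from afpredict import RRSeries, SynthConfig, generate_nsr_rr


def make_constant_rr(n: int = 100, value_ms: float = 800.0) -> RRSeries:
    times = np.arange(n + 1) * value_ms / 1000.0
    return RRSeries(times, np.full(n, value_ms))


def make_rr(intervals_ms) -> RRSeries:
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    times = np.concatenate([[0.0], np.cumsum(intervals_ms) / 1000.0])
    return RRSeries(times, intervals_ms)


@pytest.fixture(scope="session")
def nsr_rr():
    """A clean 5-min normal-sinus-rhythm tachogram."""
    return generate_nsr_rr(SynthConfig(seed=101)).rr


@pytest.fixture(scope="session")
def pac_rr():
    """A 5-min tachogram with 6 premature atrial beats per minute."""
    return generate_nsr_rr(SynthConfig(seed=101, pac_rate_per_min=6.0)).rr
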