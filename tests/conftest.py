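import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import hnslab as H


@pytest.fixture(scope="session")
def quiet_beats():
    """Constant-HR, noise-free beat series (degenerate baseline)."""
    params = H.WaveformSimParams(duration_s=420.0, mean_hr=300.0, seed=11)
    series, truth = H.simulate_beat_series(params)
    return series, truth


@pytest.fixture(scope="session")
def vlf_tone_beats():
    """Beat series with a single planted VLF tone (0.1 Hz, 2 mmHg)."""
    params = H.WaveformSimParams(
        duration_s=420.0, mean_hr=300.0, band_oscillations=((0.1, 2.0),), seed=12)
    series, truth = H.simulate_beat_series(params)
    return series, truth


@pytest.fixture(scope="session")
def brs_beats():
    """~600-beat series with gain 0.8 ms/mmHg at lag 4, low noise."""
    params = H.WaveformSimParams(
        duration_s=125.0, mean_hr=300.0, band_oscillations=((0.3, 4.0),),
        brs_gain=0.8, brs_lag_beats=4,
        noise_sd_mmhg=0.3, pi_noise_sd_ms=0.3, seed=13)
    series, truth = H.simulate_beat_series(params)
    return series, truth


def brute_force_sequences(sbp, pi, lags=(3, 4, 5), min_len=4):
    """Exhaustive enumerator of baroreflex sequences (independent oracle).

    Emits every maximal strictly monotone SBP run of length >= min_len whose
    lagged PI values are strictly monotone in the same direction over the
    whole run.
    """
    sbp = np.asarray(sbp, float)
    pi = np.asarray(pi, float)
    found = set()
    for direction in ("up", "down"):
        def later_greater(a, b):
            return b > a if direction == "up" else b < a
        for i in range(len(sbp)):
            for j in range(i + min_len - 1, len(sbp)):
                if not all(later_greater(sbp[k], sbp[k + 1]) for k in range(i, j)):
                    continue
                if i > 0 and later_greater(sbp[i - 1], sbp[i]):
                    continue  # not maximal on the left
                if j < len(sbp) - 1 and later_greater(sbp[j], sbp[j + 1]):
                    continue  # not maximal on the right
                for lag in lags:
                    if j + lag >= len(pi):
                        continue
                    pv = pi[np.arange(i, j + 1) + lag]
                    if all(later_greater(pv[k], pv[k + 1]) for k in range(len(pv) - 1)):
                        found.add((tuple(range(i, j + 1)), lag, direction))
    return found
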