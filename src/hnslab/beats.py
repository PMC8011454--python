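"""Per-beat hemodynamic value extraction from arterial pressure waveforms.

A continuous arterial pressure trace (telemetry, typically digitised at
1000 Hz) is reduced to a beat-by-beat series of systolic pressure (SBP),
diastolic pressure (DBP), pulse interval (PI) and heart rate (HR = 60/PI).
The beat anchor is the instant of maximal pressure upstroke velocity
(dP/dt_max); PI is the anchor-to-anchor distance, SBP the cycle maximum and
DBP the diastolic minimum preceding the upstroke.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "PressureWaveform",
    "BeatSeries",
    "detect_beats",
    "heart_rate",
]


class BeatDetectionError(RuntimeError):
    """Raised when no beats can be extracted from a waveform."""


@dataclass(frozen=True)
class PressureWaveform:
    """Uniformly sampled arterial pressure trace.

    Parameters
    ----------
    samples : ndarray
        Pressure in mmHg.
    fs_hz : float
        Sampling rate in samples/s.
    t0 : float
        Time of the first sample, seconds.
    """

    samples: np.ndarray
    fs_hz: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not np.isfinite(self.fs_hz) or self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive and finite")
        if samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")
        if samples.size < 2 * self.fs_hz:
            raise ValueError("waveform shorter than ~2 s cannot hold beats")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    @property
    def time_s(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs_hz


@dataclass(frozen=True)
class BeatSeries:
    """Beat-to-beat SBP/DBP/PI/HR values anchored at dP/dt_max instants.

    ``pi_ms[i]`` is the interval between anchors ``i`` and ``i+1``, so the
    PI/HR vectors are one element shorter than the per-beat vectors.
    """

    beat_time_s: np.ndarray
    sbp_mmhg: np.ndarray
    dbp_mmhg: np.ndarray
    pi_ms: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_time_s, dtype=float)
        sbp = np.asarray(self.sbp_mmhg, dtype=float)
        dbp = np.asarray(self.dbp_mmhg, dtype=float)
        if self.pi_ms is None:
            pi = np.diff(t) * 1000.0
        else:
            pi = np.asarray(self.pi_ms, dtype=float)
        for name, arr in (("beat_time_s", t), ("sbp_mmhg", sbp), ("dbp_mmhg", dbp), ("pi_ms", pi)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if not (t.size == sbp.size == dbp.size):
            raise ValueError("beat_time_s, sbp_mmhg and dbp_mmhg must have equal length")
        if pi.size != t.size - 1:
            raise ValueError("pi_ms must have one element fewer than beat_time_s")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("beat_time_s must be strictly increasing")
        if np.any(sbp <= dbp):
            raise ValueError("SBP must exceed DBP on every beat")
        if np.any(pi <= 0):
            raise ValueError("pulse intervals must be positive")
        object.__setattr__(self, "beat_time_s", t)
        object.__setattr__(self, "sbp_mmhg", sbp)
        object.__setattr__(self, "dbp_mmhg", dbp)
        object.__setattr__(self, "pi_ms", pi)

    @property
    def n_beats(self) -> int:
        return self.beat_time_s.size

    @property
    def hr_bpm(self) -> np.ndarray:
        return heart_rate(self.pi_ms)

    @property
    def duration_s(self) -> float:
        return float(self.beat_time_s[-1] - self.beat_time_s[0])


def heart_rate(pi_ms):
    """Convert pulse interval (ms) to heart rate in beats/min: HR = 60000/PI."""
    pi = np.asarray(pi_ms, dtype=float)
    if np.any(pi <= 0):
        raise ValueError("pulse interval must be positive")
    return 60000.0 / pi


def detect_beats(
    waveform: PressureWaveform,
    min_pi_ms: float = 80.0,
    min_prominence_mmhg: float = 10.0,
    smooth_dpdt_samples: int = 1,
) -> BeatSeries:
    """Extract one beat per cardiac cycle from a pressure waveform.

    Systolic peaks are located first (refractory distance ``min_pi_ms``,
    prominence ``min_prominence_mmhg``); for each cycle the diastolic minimum
    preceding the upstroke supplies DBP and the beat anchor is placed at the
    maximum forward difference (dP/dt_max) of the upstroke, earliest sample on
    ties.

    Defaults (80 ms refractory ≈ 750 bpm ceiling, 10 mmHg prominence) suit rat
    telemetry pulse amplitudes and are exposed on the CLI. On noisy
    acquisitions ``smooth_dpdt_samples`` (odd, > 1) applies a short Hann
    smoothing to the derivative before the anchor search.
    """
    if min_pi_ms <= 0:
        raise ValueError("min_pi_ms must be positive")
    p = waveform.samples
    fs = waveform.fs_hz
    distance = max(1, int(round(min_pi_ms / 1000.0 * fs)))
    peaks, _ = find_peaks(p, distance=distance, prominence=min_prominence_mmhg)
    if peaks.size < 2:
        raise BeatDetectionError("no beats found in waveform")

    dp = np.diff(p) * fs  # forward difference, units mmHg/s
    if smooth_dpdt_samples > 1:
        w = np.hanning(smooth_dpdt_samples + 2)[1:-1]
        dp = np.convolve(dp, w / w.sum(), mode="same")

    anchors = np.empty(peaks.size, dtype=int)
    sbp = p[peaks].astype(float)
    dbp = np.empty(peaks.size, dtype=float)
    prev = 0
    for i, pk in enumerate(peaks):
        lo = prev if i == 0 else peaks[i - 1]
        trough = lo + int(np.argmin(p[lo : pk + 1]))
        dbp[i] = p[trough]
        hi = max(trough + 1, pk)  # diff window [trough, pk)
        seg = dp[trough:hi]
        anchors[i] = trough + int(np.argmax(seg)) if seg.size else trough
    # argmax returns the earliest index on ties, matching the tie-break rule

    times = waveform.t0 + anchors / fs
    # greedy refractory pass: anchors may sit closer than the systolic peaks
    keep = np.zeros(times.size, dtype=bool)
    last = -np.inf
    for i, t in enumerate(times):
        if (t - last) * 1000.0 >= min_pi_ms:
            keep[i] = True
            last = t
    return BeatSeries(times[keep], sbp[keep], dbp[keep])
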