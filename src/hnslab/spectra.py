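"""Blood-pressure and heart-rate variability spectral analysis.

The pipeline mirrors classic rodent-telemetry BPV processing: the beat
series is resampled to an even 20 Hz grid, smoothed with a 9-point Hanning
filter, linearly detrended, split into 30 overlapping 2048-point segments
(a 410-s registration period), and averaged into a one-sided FFT power
spectrum. Band powers are integrated over the rat cardiovascular bands
VLF 0.0195–0.195 Hz, LF 0.195–0.8 Hz, HF 0.8–3 Hz (half-open, so the three
bands tile the total 0.0195–3 Hz range exactly).

Power normalisation follows the A²/2 sinusoid convention: a planted
sinusoid of amplitude A mmHg integrates to A²/2 mmHg² in its band, and
white noise of variance σ² integrates to σ² over the full spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d
from scipy.signal import detrend as _scipy_detrend

from .beats import BeatSeries

__all__ = [
    "BANDS",
    "EvenSeries",
    "PowerSpectrum",
    "BandPowerResult",
    "resample_even",
    "hanning_filter9",
    "detrend_linear",
    "segment_series",
    "averaged_spectrum",
    "band_power",
    "bpv_pipeline",
]

#: Rat cardiovascular variability bands, Hz (half-open [low, high)).
BANDS = {
    "total": (0.0195, 3.0),
    "vlf": (0.0195, 0.195),
    "lf": (0.195, 0.8),
    "hf": (0.8, 3.0),
}


@dataclass(frozen=True)
class EvenSeries:
    """Evenly resampled beat-variable series (default 20 samples/s)."""

    values: np.ndarray
    fs_hz: float = 20.0
    source: str = "SBP"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("series contains non-finite values")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        object.__setattr__(self, "values", v)

    def replace(self, values: np.ndarray) -> "EvenSeries":
        return EvenSeries(values, self.fs_hz, self.source)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided averaged spectrum; ``power`` is integrated power per bin."""

    freq_hz: np.ndarray
    power: np.ndarray
    n_segments: int
    seg_len: int

    def __post_init__(self) -> None:
        f = np.asarray(self.freq_hz, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.size != p.size:
            raise ValueError("freq_hz and power must have equal length")
        if f.size and (np.any(np.diff(f) <= 0) or f[0] < 0):
            raise ValueError("freq_hz must increase monotonically from 0")
        if np.any(p < -1e-12):
            raise ValueError("power must be non-negative")
        object.__setattr__(self, "freq_hz", f)
        object.__setattr__(self, "power", np.maximum(p, 0.0))


@dataclass(frozen=True)
class BandPowerResult:
    """Integrated Total/VLF/LF/HF band powers (mmHg² or bpm²)."""

    total: float
    vlf: float
    lf: float
    hf: float
    units: str = "mmHg^2"

    def as_dict(self) -> dict:
        return {"total": self.total, "vlf": self.vlf, "lf": self.lf,
                "hf": self.hf, "units": self.units}


def resample_even(beats: BeatSeries, variable: str = "SBP", fs_hz: float = 20.0) -> EvenSeries:
    """Linearly interpolate a per-beat variable onto a uniform grid.

    The grid starts at the first defining beat time and holds
    ``floor(span × fs)`` samples, so a 410-s recording at 20 Hz yields 8200
    samples. HR (bpm) is defined per interval and anchored at the closing
    beat of each interval.
    """
    variable = variable.upper()
    if variable in ("SBP", "DBP"):
        t = beats.beat_time_s
        v = beats.sbp_mmhg if variable == "SBP" else beats.dbp_mmhg
    elif variable == "HR":
        t = beats.beat_time_s[1:]
        v = beats.hr_bpm
    else:
        raise ValueError("variable must be one of SBP, DBP, HR")
    if t.size < 2:
        raise ValueError("need at least 2 beats to resample")
    span = t[-1] - t[0]
    if span < 1.0:
        raise ValueError("recording shorter than 1 s")
    n = int(np.floor(span * fs_hz))
    grid = t[0] + np.arange(n) / fs_hz
    return EvenSeries(np.interp(grid, t, v), fs_hz, variable)


def hanning_filter9(series: EvenSeries) -> EvenSeries:
    """Smooth with a 9-point Hann kernel normalised to unit DC gain.

    Edges are handled by reflection padding, so a constant series is
    unchanged exactly.
    """
    if len(series) < 9:
        raise ValueError("series must hold at least 9 samples")
    w = np.hanning(9)
    w /= w.sum()
    return series.replace(convolve1d(series.values, w, mode="reflect"))


def detrend_linear(series: EvenSeries) -> EvenSeries:
    """Subtract the least-squares best-fit line."""
    if len(series) < 2:
        raise ValueError("series must hold at least 2 samples")
    return series.replace(_scipy_detrend(series.values, type="linear"))


def segment_series(series: EvenSeries, n_segments: int = 30, seg_len: int = 2048) -> list[np.ndarray]:
    """Split into ``n_segments`` equally spaced overlapping segments.

    Start step is ``floor((N − seg_len)/(n_segments − 1))`` when the series
    is long enough for distinct starts; otherwise overlap is maximal (step 1)
    and the feasible number of segments is returned.
    """
    v = series.values
    N = v.size
    if N < seg_len:
        raise ValueError(f"series of {N} samples shorter than one {seg_len}-sample segment")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_segments == 1 or N == seg_len:
        return [v[:seg_len].copy()]
    step = (N - seg_len) // (n_segments - 1)
    if step >= 1:
        starts = [i * step for i in range(n_segments)]
    else:
        starts = list(range(N - seg_len + 1))
    return [v[s : s + seg_len].copy() for s in starts]


def averaged_spectrum(segments, fs_hz: float = 20.0, taper: bool = True) -> PowerSpectrum:
    """Average per-segment one-sided FFT power with Hann taper correction.

    Each segment is Hann-tapered (power-corrected by the mean squared taper)
    so that a sinusoid of amplitude A integrates to A²/2 across its leakage
    bins and white noise of variance σ² integrates to σ² over [0, fs/2].
    ``taper=False`` reproduces raw rectangular-window periodograms.
    """
    segments = [np.asarray(s, dtype=float) for s in segments]
    if not segments:
        raise ValueError("need at least one segment")
    n = segments[0].size
    if any(s.size != n for s in segments):
        raise ValueError("segments must share one length")
    w = np.hanning(n) if taper else np.ones(n)
    denom = n * np.sum(w**2)
    scale = np.full(n // 2 + 1, 2.0 / denom)
    scale[0] = 1.0 / denom
    if n % 2 == 0:
        scale[-1] = 1.0 / denom
    acc = np.zeros(n // 2 + 1)
    for s in segments:
        X = np.fft.rfft(s * w)
        acc += scale * np.abs(X) ** 2
    acc /= len(segments)
    freq = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    return PowerSpectrum(freq, acc, len(segments), n)


def band_power(spectrum: PowerSpectrum, band: tuple[float, float]) -> float:
    """Sum bin powers with centre frequency in the half-open band [low, high)."""
    low, high = band
    if high <= low:
        raise ValueError("band must satisfy low < high")
    sel = (spectrum.freq_hz >= low) & (spectrum.freq_hz < high)
    return float(spectrum.power[sel].sum())


def bpv_pipeline(
    beats: BeatSeries,
    variable: str = "SBP",
    fs_hz: float = 20.0,
    n_segments: int = 30,
    seg_len: int = 2048,
    taper: bool = True,
) -> BandPowerResult:
    """Full band-power pipeline for one beat variable.

    resample → 9-point Hanning filter → linear detrend → overlapping
    segmentation → averaged FFT spectrum → Total/VLF/LF/HF integration.
    """
    if beats.duration_s < 410.0:
        warnings.warn(
            f"recording of {beats.duration_s:.0f} s is shorter than the "
            "preferred 410 s registration period", stacklevel=2,
        )
    series = resample_even(beats, variable, fs_hz)
    series = detrend_linear(hanning_filter9(series))
    spec = averaged_spectrum(segment_series(series, n_segments, seg_len), fs_hz, taper)
    units = "bpm^2" if variable.upper() == "HR" else "mmHg^2"
    return BandPowerResult(
        total=band_power(spec, BANDS["total"]),
        vlf=band_power(spec, BANDS["vlf"]),
        lf=band_power(spec, BANDS["lf"]),
        hf=band_power(spec, BANDS["hf"]),
        units=units,
    )
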