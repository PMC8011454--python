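"""Spontaneous baroreceptor reflex sensitivity by the sequence method.

A baroreflex sequence is a run of at least four consecutively increasing
(or decreasing) systolic pressures matched by a same-direction run of pulse
intervals delayed by 3, 4 or 5 beats. BRS (ms/mmHg) is the least-squares
slope of PI on SBP averaged over all sequences, and the sequence coverage
area (SCA) is the operating-range rectangle spanned by pooled sequence
points in the SBP–PI plane after symmetric percentile trimming of outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .beats import BeatSeries

__all__ = [
    "BaroSequence",
    "BRSResult",
    "find_ramps",
    "match_sequences",
    "estimate_brs",
    "sequence_coverage_area",
    "analyze_brs",
]


class NoSequencesError(RuntimeError):
    """Raised when BRS is requested but no baroreflex sequences were found."""


@dataclass(frozen=True)
class BaroSequence:
    """One matched SBP→PI ramp with its per-sequence regression slope."""

    sbp_indices: tuple[int, ...]
    lag_beats: int
    direction: str  # "up" | "down"
    sbp_values: np.ndarray
    pi_values: np.ndarray
    slope_ms_per_mmhg: float
    r2: float

    @property
    def pi_indices(self) -> tuple[int, ...]:
        return tuple(i + self.lag_beats for i in self.sbp_indices)

    def __len__(self) -> int:
        return len(self.sbp_indices)


@dataclass(frozen=True)
class BRSResult:
    """Mean baroreflex slope and operating-range summary."""

    brs_ms_per_mmhg: float
    n_sequences: int
    per_lag_counts: dict
    sbp_range: tuple[float, float]
    pi_range: tuple[float, float]
    sca_mmhg_ms: float | None = None


def find_ramps(values, min_len: int = 4, direction: str = "up", min_delta: float = 0.0):
    """Maximal strictly monotone runs of consecutive values, length >= min_len.

    A run is maximal with respect to the per-step criterion (difference
    strictly greater than ``min_delta`` for "up", strictly smaller than
    ``-min_delta`` for "down"); sub-runs of a maximal run are not emitted.
    Returns a list of ``range``-like index tuples.
    """
    v = np.asarray(values, dtype=float)
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    if v.size < min_len:
        return []
    d = np.diff(v)
    ok = d > min_delta if direction == "up" else d < -min_delta
    ramps = []
    i = 0
    while i < ok.size:
        if ok[i]:
            j = i
            while j < ok.size and ok[j]:
                j += 1
            if j - i + 1 >= min_len:
                ramps.append(tuple(range(i, j + 1)))
            i = j
        else:
            i += 1
    return ramps


def _monotone(values: np.ndarray, direction: str, min_delta: float) -> bool:
    d = np.diff(values)
    return bool(np.all(d > min_delta)) if direction == "up" else bool(np.all(d < -min_delta))


def match_sequences(
    beats: BeatSeries,
    lags=(3, 4, 5),
    min_len: int = 4,
    min_dsbp_mmhg: float = 0.0,
    min_dpi_ms: float = 0.0,
):
    """Detect baroreflex sequences: concordant SBP and lagged-PI ramps.

    For each maximal SBP ramp and each lag, the PI values at the lagged
    indices must be strictly monotone in the same direction over the full
    ramp (no sliding sub-windows). Sequences found at different lags are all
    retained. The per-sequence slope regresses PI (ms) on SBP (mmHg).
    """
    sbp = beats.sbp_mmhg
    pi = beats.pi_ms
    sequences = []
    for direction in ("up", "down"):
        for ramp in find_ramps(sbp, min_len, direction, min_dsbp_mmhg):
            for lag in lags:
                pidx = np.asarray(ramp) + int(lag)
                if pidx[-1] >= pi.size:
                    continue
                pvals = pi[pidx]
                if not _monotone(pvals, direction, min_dpi_ms):
                    continue
                svals = sbp[np.asarray(ramp)]
                fit = stats.linregress(svals, pvals)
                sequences.append(BaroSequence(
                    sbp_indices=tuple(ramp),
                    lag_beats=int(lag),
                    direction=direction,
                    sbp_values=svals,
                    pi_values=pvals,
                    slope_ms_per_mmhg=float(fit.slope),
                    r2=float(fit.rvalue**2),
                ))
    sequences.sort(key=lambda s: (s.sbp_indices[0], s.lag_beats))
    return sequences


def estimate_brs(sequences) -> BRSResult:
    """Unweighted mean of per-sequence slopes, with per-lag counts and ranges."""
    if not sequences:
        raise NoSequencesError("no baroreflex sequences detected; BRS undefined")
    slopes = np.array([s.slope_ms_per_mmhg for s in sequences])
    counts: dict[int, int] = {}
    for s in sequences:
        counts[s.lag_beats] = counts.get(s.lag_beats, 0) + 1
    sbp_all = np.concatenate([s.sbp_values for s in sequences])
    pi_all = np.concatenate([s.pi_values for s in sequences])
    return BRSResult(
        brs_ms_per_mmhg=float(slopes.mean()),
        n_sequences=len(sequences),
        per_lag_counts=counts,
        sbp_range=(float(sbp_all.min()), float(sbp_all.max())),
        pi_range=(float(pi_all.min()), float(pi_all.max())),
    )


def sequence_coverage_area(sequences, trim_fraction: float = 0.05) -> float:
    """Operating-range rectangle of pooled sequence points, mmHg·ms.

    All (SBP, PI) points belonging to sequences are pooled; per dimension,
    ``trim_fraction/2`` is dropped from each tail via linear-interpolated
    percentiles, and the SCA is the product of the trimmed ranges.
    """
    if not 0 <= trim_fraction < 1:
        raise ValueError("trim_fraction must lie in [0, 1)")
    if not sequences:
        raise ValueError("no sequences supplied")
    sbp = np.concatenate([np.asarray(s.sbp_values, float) for s in sequences])
    pi = np.concatenate([np.asarray(s.pi_values, float) for s in sequences])
    if sbp.size < 4:
        raise ValueError("need at least 4 pooled points for a coverage area")
    lo = 100.0 * trim_fraction / 2.0
    hi = 100.0 - lo
    sbp_lo, sbp_hi = np.percentile(sbp, [lo, hi])
    pi_lo, pi_hi = np.percentile(pi, [lo, hi])
    return float((sbp_hi - sbp_lo) * (pi_hi - pi_lo))


def analyze_brs(
    beats: BeatSeries,
    lags=(3, 4, 5),
    min_len: int = 4,
    min_dsbp_mmhg: float = 0.0,
    min_dpi_ms: float = 0.0,
    trim_fraction: float = 0.05,
) -> tuple[BRSResult, list]:
    """Full sequence analysis: detection, mean BRS and coverage area."""
    sequences = match_sequences(beats, lags, min_len, min_dsbp_mmhg, min_dpi_ms)
    result = estimate_brs(sequences)
    sca = sequence_coverage_area(sequences, trim_fraction)
    result = BRSResult(
        brs_ms_per_mmhg=result.brs_ms_per_mmhg,
        n_sequences=result.n_sequences,
        per_lag_counts=result.per_lag_counts,
        sbp_range=result.sbp_range,
        pi_range=result.pi_range,
        sca_mmhg_ms=sca,
    )
    return result, sequences
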