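"""Seeded synthetic-data generators with ground-truth records.

Each generator emulates the statistical structure one analysis stage assumes
— beat-to-beat pressure series with oscillatory power planted in named
frequency bands and linear baroreflex coupling of known gain and lag,
rendered pulse waveforms, expression matrices with planted fold changes,
efficiency-consistent qPCR Ct tables, and two-channel puncta stacks with a
controlled co-localised fraction — and returns the planted parameters
alongside the data so parameter recovery can be scored without any external
file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .beats import BeatSeries, PressureWaveform

__all__ = [
    "WaveformSimParams",
    "ExpressionSimParams",
    "ColocSimParams",
    "simulate_beat_series",
    "simulate_pressure_waveform",
    "simulate_expression",
    "simulate_coloc_stack",
    "simulate_qpcr",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveformSimParams:
    """Settings for beat-series / pulse-waveform simulation.

    Defaults describe an adult spontaneously hypertensive rat on
    radiotelemetry: systolic ~160 mmHg, diastolic ~110 mmHg, resting heart
    rate ~300 bpm, 410-s registration periods. ``band_oscillations`` plants
    sinusoidal SBP modulation as (frequency Hz, amplitude mmHg) pairs;
    ``brs_gain``/``brs_lag_beats`` couple the pulse interval to systolic
    pressure ``lag`` beats earlier with slope ``gain`` ms/mmHg.
    """

    duration_s: float = 410.0
    fs_hz: float = 1000.0
    mean_sbp: float = 160.0
    mean_dbp: float = 110.0
    mean_hr: float = 300.0
    band_oscillations: tuple[tuple[float, float], ...] = ()
    brs_gain: float = 0.0
    brs_lag_beats: int = 4
    noise_sd_mmhg: float = 0.0
    pi_noise_sd_ms: float = 0.0
    waveform_noise_sd_mmhg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "band_oscillations",
            tuple((float(f), float(a)) for f, a in self.band_oscillations),
        )
        scalars = [self.duration_s, self.fs_hz, self.mean_sbp, self.mean_dbp,
                   self.mean_hr, self.brs_gain, self.noise_sd_mmhg,
                   self.pi_noise_sd_ms, self.waveform_noise_sd_mmhg]
        scalars += [v for pair in self.band_oscillations for v in pair]
        if not all(math.isfinite(v) for v in scalars):
            raise ValueError("simulation parameters must be finite")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs_hz < 50:
            raise ValueError("fs_hz must be >= 50 so each pulse is resolvable")
        if self.mean_sbp <= self.mean_dbp:
            raise ValueError("mean_sbp must exceed mean_dbp")
        if self.mean_hr <= 0:
            raise ValueError("mean_hr must be positive")
        if not (0 <= int(self.brs_lag_beats) <= 10):
            raise ValueError("brs_lag_beats must lie in 0..10")
        if min(self.noise_sd_mmhg, self.pi_noise_sd_ms,
               self.waveform_noise_sd_mmhg) < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if any(f <= 0 for f, _ in self.band_oscillations):
            raise ValueError("oscillation frequencies must be positive")

    @property
    def mean_pi_ms(self) -> float:
        return 60000.0 / self.mean_hr


@dataclass(frozen=True)
class ExpressionSimParams:
    """Settings for two-group expression-matrix simulation.

    Defaults mirror a 5-vs-5 chip design: log2 intensities are normal around
    a per-probe baseline with ``within_group_sd`` (log2 units); ``n_de``
    probes carry a planted linear fold change ``planted_fc`` in group B and
    are forced to all-Present detection calls.
    """

    n_probes: int = 2000
    n_per_group: int = 5
    n_de: int = 50
    planted_fc: float = 2.5
    within_group_sd: float = 0.25
    call_present_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_probes:
            raise ValueError("n_de cannot exceed n_probes")
        if self.planted_fc <= 0:
            raise ValueError("planted_fc must be positive")
        if not 0 <= self.call_present_prob <= 1:
            raise ValueError("call_present_prob must lie in [0, 1]")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 chips per group")
        if self.within_group_sd < 0:
            raise ValueError("within_group_sd must be non-negative")


@dataclass(frozen=True)
class ColocSimParams:
    """Settings for two-channel puncta-stack simulation.

    Defaults describe sparse, well-separated bright puncta (~25 per channel
    in an 8 × 128 × 128 stack, PSF ~1.5 px, peak ~1000 grey-scale units)
    over a dim noisy background, so puncta dominate the integrated channel
    intensity, chance overlap between channels stays small, and the planted
    co-localised fraction is recoverable from the Manders coefficients.
    """

    shape: tuple[int, int, int] = (8, 128, 128)
    n_puncta: int = 25
    overlap_fraction: float = 0.5
    psf_sd_px: float = 1.5
    amplitude: float = 1000.0
    background_level: float = 2.0
    noise_sd: float = 1.0
    min_separation_px: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(d) for d in self.shape))
        if len(self.shape) != 3 or any(d < 8 for d in self.shape):
            raise ValueError("shape must be (z, y, x) with every dim >= 8")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.n_puncta < 1:
            raise ValueError("n_puncta must be positive")
        if self.psf_sd_px <= 0 or self.amplitude <= 0:
            raise ValueError("psf_sd_px and amplitude must be positive")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("background and noise must be non-negative")


# --------------------------------------------------------------------------
# beat series & waveform
# --------------------------------------------------------------------------

def _sbp_deviation(t: float, oscillations) -> float:
    return sum(a * math.sin(2 * math.pi * f * t) for f, a in oscillations)


def simulate_beat_series(params: WaveformSimParams):
    """Generate a beat series with planted oscillations and baroreflex coupling.

    SBP_i = mean_sbp + Σ_k A_k sin(2π f_k t_i) + ε_i, and the pulse interval
    started at beat i follows PI_i = mean_PI + gain·(SBP_{i−lag} − mean_sbp)
    + η_i; beat times are cumulative sums of PI. Returns ``(BeatSeries,
    truth)`` where ``truth`` records the planted gain, lag, band amplitudes
    and means.
    """
    rng = np.random.default_rng(params.seed)
    lag = int(params.brs_lag_beats)
    mean_pi = params.mean_pi_ms
    pulse = params.mean_sbp - params.mean_dbp

    times: list[float] = []
    sbp: list[float] = []
    t = 0.0
    while t <= params.duration_s:
        times.append(t)
        s = params.mean_sbp + _sbp_deviation(t, params.band_oscillations)
        if params.noise_sd_mmhg > 0:
            s += rng.normal(0.0, params.noise_sd_mmhg)
        sbp.append(s)
        i = len(sbp) - 1
        src = sbp[i - lag] if i >= lag else params.mean_sbp
        pi = mean_pi + params.brs_gain * (src - params.mean_sbp)
        if params.pi_noise_sd_ms > 0:
            pi += rng.normal(0.0, params.pi_noise_sd_ms)
        pi = max(pi, 0.25 * mean_pi)  # guard against non-physical intervals
        t += pi / 1000.0

    t_arr = np.asarray(times)
    sbp_arr = np.asarray(sbp)
    dbp_arr = sbp_arr - pulse
    series = BeatSeries(t_arr, sbp_arr, dbp_arr)
    truth = {
        "brs_gain_ms_per_mmhg": params.brs_gain,
        "brs_lag_beats": lag,
        "mean_pi_ms": mean_pi,
        "mean_sbp_mmhg": params.mean_sbp,
        "mean_dbp_mmhg": params.mean_dbp,
        "band_oscillations": list(params.band_oscillations),
        "seed": params.seed,
    }
    return series, truth


def simulate_pressure_waveform(params: WaveformSimParams):
    """Render a beat series as a continuous arterial pulse waveform.

    Each beat is a two-phase template: a raised-cosine systolic upstroke
    over 15% of the pulse interval from the diastolic minimum to SBP_i
    (so the upstroke velocity dP/dt peaks uniquely at mid-rise), then an
    exponential diastolic decay (3 time constants) reaching the next beat's
    DBP exactly at the next onset. Returns ``(waveform, true_beats,
    truth)``; ``truth["anchor_time_s"]`` holds the exact dP/dt_max instants
    a beat detector should recover.
    """
    series, truth = simulate_beat_series(params)
    t_on = series.beat_time_s
    sbp = series.sbp_mmhg
    dbp = series.dbp_mmhg
    fs = params.fs_hz

    n_samp = int(math.floor(t_on[-1] * fs))
    if n_samp < 2 * fs:
        raise ValueError("simulated waveform too short; increase duration_s")
    t = np.arange(n_samp) / fs
    p = np.empty(n_samp)

    decay_end = math.exp(-3.0)
    idx = np.searchsorted(t_on, t, side="right") - 1
    idx = np.clip(idx, 0, len(t_on) - 2)
    onset = t_on[idx]
    pi_s = t_on[idx + 1] - onset
    rise = 0.15 * pi_s
    frac = t - onset
    up = frac < rise
    phase = frac[up] / rise[up]
    p[up] = dbp[idx[up]] + (sbp[idx[up]] - dbp[idx[up]]) * 0.5 * (1.0 - np.cos(math.pi * phase))
    dn = ~up
    tau = (pi_s[dn] - rise[dn]) / 3.0
    raw = np.exp(-(frac[dn] - rise[dn]) / tau)
    target = dbp[idx[dn] + 1]
    p[dn] = target + (sbp[idx[dn]] - target) * (raw - decay_end) / (1.0 - decay_end)

    if params.waveform_noise_sd_mmhg > 0:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
        p += rng.normal(0.0, params.waveform_noise_sd_mmhg, size=p.shape)

    waveform = PressureWaveform(p, fs)
    truth = dict(truth)
    rise_all = 0.15 * np.diff(t_on)
    truth["peak_time_s"] = t_on[:-1] + rise_all
    truth["anchor_time_s"] = t_on[:-1] + 0.5 * rise_all  # dP/dt_max at mid-rise
    return waveform, series, truth


# --------------------------------------------------------------------------
# expression matrix
# --------------------------------------------------------------------------

def simulate_expression(params: ExpressionSimParams):
    """Two-group expression matrix with planted fold changes and P/A calls.

    Returns ``(values, calls, truth)``: linear-scale intensity DataFrame
    (probes × samples), a matching Present/Absent call table, and a truth
    record listing the planted probe ids. Sample ids carry the group label
    (``A1..An, B1..Bn``).
    """
    rng = np.random.default_rng(params.seed)
    n, m = params.n_probes, params.n_per_group
    probe_ids = [f"probe_{i:05d}" for i in range(n)]
    samples = [f"A{j+1}" for j in range(m)] + [f"B{j+1}" for j in range(m)]

    base = rng.uniform(6.0, 12.0, size=n)
    log2 = rng.normal(0.0, params.within_group_sd, size=(n, 2 * m)) + base[:, None]
    de_idx = rng.choice(n, size=params.n_de, replace=False)
    log2[de_idx, m:] += math.log2(params.planted_fc)

    calls = np.where(rng.random(size=(n, 2 * m)) < params.call_present_prob, "P", "A")
    calls[de_idx, :] = "P"

    values = pd.DataFrame(np.exp2(log2), index=probe_ids, columns=samples)
    call_df = pd.DataFrame(calls, index=probe_ids, columns=samples)
    truth = {
        "de_probes": sorted(probe_ids[i] for i in de_idx),
        "planted_fc": params.planted_fc,
        "groups": {s: ("A" if s.startswith("A") else "B") for s in samples},
        "seed": params.seed,
    }
    return values, call_df, truth


# --------------------------------------------------------------------------
# colocalisation stack
# --------------------------------------------------------------------------

def simulate_coloc_stack(params: ColocSimParams):
    """Two-channel z-stack of Gaussian puncta with a known co-localised fraction.

    ``overlap_fraction`` of channel-1 puncta are duplicated at the same
    coordinates in channel 2; the remaining channel-2 puncta are placed
    independently. Setting ``min_separation_px`` rejection-samples the
    non-shared channel-2 puncta to keep at least that in-plane distance
    from every channel-1 punctum, so a planted fraction of 0 yields truly
    disjoint support. Returns ``(stack, truth)`` with ``stack`` shaped
    (2, z, y, x).
    """
    rng = np.random.default_rng(params.seed)
    z, y, x = params.shape
    n = params.n_puncta
    n_shared = int(round(params.overlap_fraction * n))

    def _draw(k):
        return np.column_stack([
            rng.uniform(1, z - 1, size=k),
            rng.uniform(2, y - 2, size=k),
            rng.uniform(2, x - 2, size=k),
        ])

    coords1 = _draw(n)
    extra = []
    sep = params.min_separation_px
    while len(extra) < n - n_shared:
        cand = _draw(1)[0]
        if sep is not None:
            d_xy = np.hypot(coords1[:, 1] - cand[1], coords1[:, 2] - cand[2])
            if d_xy.min() < sep:
                continue
        extra.append(cand)
    coords2 = np.vstack([coords1[:n_shared]] + [np.asarray(extra)]) if extra else coords1[:n_shared]

    def _render(coords):
        img = np.zeros(params.shape)
        ij = np.round(coords).astype(int)
        ij[:, 0] = np.clip(ij[:, 0], 0, z - 1)
        ij[:, 1] = np.clip(ij[:, 1], 0, y - 1)
        ij[:, 2] = np.clip(ij[:, 2], 0, x - 1)
        np.add.at(img, tuple(ij.T), 1.0)
        img = gaussian_filter(img, sigma=params.psf_sd_px)
        peak = 1.0 / (2 * math.pi * params.psf_sd_px**2) ** 1.5
        return img * (params.amplitude / peak)

    stack = np.stack([_render(coords1), _render(coords2)])
    stack += params.background_level
    if params.noise_sd > 0:
        stack += rng.normal(0.0, params.noise_sd, size=stack.shape)
        stack = np.clip(stack, 0.0, None)

    truth = {
        "coords_ch1": coords1,
        "coords_ch2": coords2,
        "n_shared": n_shared,
        "overlap_fraction": n_shared / n,
        "seed": params.seed,
    }
    return stack, truth


# --------------------------------------------------------------------------
# qPCR Ct table
# --------------------------------------------------------------------------

def simulate_qpcr(
    n_samples: int,
    efficiencies: Mapping[str, float],
    true_ratios: Mapping[str, float],
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    reference_gene: str = "Rpl19",
    base_ct: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Ct table consistent with efficiency-corrected relative quantification.

    For each target gene the test-group Ct is shifted by −log_E(ratio)
    relative to the control group, so the Pfaffl ratio recovers
    ``true_ratios`` exactly at zero noise. The reference gene is simulated
    with ratio 1. Returns a long-format table (sample, group, gene, role,
    efficiency, ct) plus the truth record.
    """
    for gene, e in efficiencies.items():
        if not 1.6 <= e <= 2.1:
            raise ValueError(f"efficiency for {gene} outside plausible range [1.6, 2.1]")
    if reference_gene not in efficiencies:
        raise ValueError("efficiencies must include the reference gene")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    base_ct = dict(base_ct or {})
    rows = []
    genes = [reference_gene] + [g for g in true_ratios if g != reference_gene]
    for gene in genes:
        e = efficiencies[gene]
        ratio = 1.0 if gene == reference_gene else float(true_ratios[gene])
        ct0 = base_ct.get(gene, 20.0 if gene == reference_gene else 25.0)
        shift = math.log(ratio, e)
        for grp, delta in (("control", 0.0), ("test", -shift)):
            for j in range(n_samples):
                ct = ct0 + delta
                if ct_noise_sd > 0:
                    ct += rng.normal(0.0, ct_noise_sd)
                rows.append({
                    "sample": f"{grp[0]}{j+1}",
                    "group": grp,
                    "gene": gene,
                    "role": "reference" if gene == reference_gene else "target",
                    "efficiency": e,
                    "ct": ct,
                })
    table = pd.DataFrame(rows)
    truth = {"true_ratios": dict(true_ratios), "reference_gene": reference_gene,
             "efficiencies": dict(efficiencies), "seed": seed}
    return table, truth
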