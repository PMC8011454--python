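# Methods

This note documents the models and procedures implemented in `hnslab`, the
assumptions behind them, the defaults that matter, and what the synthetic
generators do and do not emulate.

## Beat extraction

An arterial pulse waveform (uniformly sampled, typically 1000 Hz telemetry)
is reduced to one beat per cardiac cycle. Systolic peaks are located by a
prominence- and refractory-constrained peak search; within each cycle the
diastolic minimum preceding the upstroke supplies DBP and the beat anchor
is placed at the maximal forward-difference upstroke velocity (dP/dt_max),
earliest sample on ties. The pulse interval is the anchor-to-anchor
distance in ms and HR = 60000/PI bpm. PI is stored in milliseconds
throughout so that baroreflex slopes carry ms/mmHg units.

Defaults: `min_pi_ms = 80` (a ~750 bpm ceiling, safely above any rat heart
rate) and `min_prominence_mmhg = 10` (well below rat telemetry pulse
pressures of 40–60 mmHg). Both are exposed on the CLI. On acquisitions with
appreciable sample-level measurement noise the raw forward difference is an
unreliable anchor locator; `smooth_dpdt_samples` applies a short Hann
smoothing to the derivative first (off by default, because it slightly
biases the anchor on asymmetric upstrokes). No artifact or ectopic-beat
classification is attempted beyond the refractory rule.

## Blood-pressure variability spectra

The per-beat series (SBP, DBP or HR) is processed as:

1. linear interpolation onto a uniform 20 Hz grid (`floor(span × fs)`
   samples, so a 410-s recording yields 8200 samples). HR, defined per
   interval, is anchored at the closing beat of each interval.
2. 9-point Hanning filter, kernel normalised to unit DC gain, reflect
   padding (a constant series is unchanged exactly);
3. least-squares linear detrend;
4. segmentation into 30 overlapping 2048-point segments with equally
   spaced starts, step `floor((N − 2048)/29)` (212 for N = 8200); when the
   series is too short for distinct starts, overlap is maximal and the
   feasible number of segments is used;
5. per-segment Hann-tapered one-sided FFT power, corrected by the mean
   squared taper and averaged across segments;
6. band integration over half-open bands VLF [0.0195, 0.195), LF
   [0.195, 0.8), HF [0.8, 3) Hz, so the three bands tile the total band
   [0.0195, 3) exactly and Total = VLF + LF + HF holds identically.

Normalisation follows the A²/2 sinusoid convention: a planted sinusoid of
amplitude A mmHg integrates to A²/2 mmHg² across its leakage bins, and
white noise of variance σ² integrates to σ² over [0, 10] Hz. Design
choices that were genuinely open: linear interpolation for resampling
(cubic or Berger-style resampling rejected for simplicity; the interpolant
attenuates < 2% at VLF/LF frequencies for rat heart rates), a per-segment
Hann taper (without it, spectral leakage from the large DC offset corrupts
the VLF band; disable with `taper=False`/`--no-taper`), and equally spaced
segment starts (the exact overlap convention of legacy acquisition
software is not recoverable). HR spectra are reported in bpm².

The 9-point Hanning pre-filter attenuates ~5% of power at 0.3 Hz and ~25%
at 0.8 Hz (on a 20 Hz grid); band powers near the upper LF/HF edges are
therefore systematically low relative to the unfiltered signal. This is a
property of the prescribed processing chain, not a defect.

## Spontaneous baroreflex sequence analysis

A baroreflex sequence is a maximal run of ≥ 4 strictly monotone systolic
pressures whose pulse intervals, delayed by 3, 4 or 5 beats, are strictly
monotone in the same direction over the full run. Per-beat change
thresholds default to 0 mmHg / 0 ms (strict monotonicity only); the
conventional 1 mmHg / 1 ms thresholds of the wider sequence-method
literature are available (`min_dsbp_mmhg`, `min_dpi_ms`). Sequences found
at different lags are all retained and pooled; BRS is the unweighted mean
of per-sequence least-squares slopes of PI (ms) on SBP (mmHg). When a ramp
exceeds the minimum length, the full maximal ramp forms one sequence — no
sliding sub-windows are emitted, and the test suite checks the detector
against an exhaustive brute-force enumerator under the same definition.

The sequence coverage area (SCA, operating range) pools all (SBP, PI)
points belonging to sequences, drops `trim_fraction/2` (default 2.5%) from
each tail of each dimension via linear-interpolated percentiles, and
reports the product of the trimmed ranges in mmHg·ms. The 5% omission is
interpreted per dimension and symmetric; a global-outlier interpretation
would require a bivariate depth notion the procedure does not define.

## Expression screening

The two-group screen runs in a fixed order: (1) present-call consensus —
a probe survives only if called Present on every chip of at least one
group (Marginal never counts); (2) twofold cut-off on the linear fold
change of group means, boundary inclusive both directions; (3) Welch
unequal-variance t-test with Benjamini–Hochberg step-up control at
q ≤ 0.05, where the multiple-testing universe is the fold-passing list.
Reordering the filters changes the universe m and hence the q-values; a
test documents this. Fold change is computed on group means of linear
intensities (means of logs would give the geometric-mean ratio; the choice
matters little at the simulated noise levels but is fixed and documented).
Chip normalisation and the detection-call algorithm are upstream of this
package: it consumes normalised linear intensities plus P/M/A call tables.

qPCR quantification is efficiency-corrected:
ratio = E_target^ΔCt_target / E_ref^ΔCt_ref, with ΔCt oriented
calibrator-minus-test so a ratio above 1 means higher expression in the
test group; at E = 2 for both genes this reduces to 2^ΔΔCt. Reported
"signed fold" values use the ratio − 1 mapping (2.12× → +1.12-fold,
0.39× → −0.61-fold); this reporting convention is inferred from common
usage and flagged as such on the result. ELISA concentrations come from a
least-squares line of log10(OD) on log10(concentration) with inverse
prediction; out-of-range ODs warn rather than fail.

## Image quantification and colocalisation

Z-stacks are combined by pixelwise summation in float64 (no clipping), and
a strict lower-limit threshold (value > t retained) masks background;
masked-out pixels are excluded from every statistic, mirroring the
NaN-designation convention of interactive tools. Equality at the threshold
is excluded — the workflow's "below threshold" phrasing leaves the
boundary ambiguous, and the strict reading of "intensity > t" is used.
The fixed per-structure presets (SON 400, PVN 128, pituitary 10) ship as
named config presets. Images are summarised by unit-width integer-aligned
histograms and by the area/mean metric (masked pixel count divided by
masked mean intensity), which normalises for differences in analysed area:
doubling all intensities halves the metric exactly. Group comparison uses
a Student's t-test, one-tailed by default; unpaired by default because
group images come from distinct animals, with a paired mode for genuinely
paired designs.

Colocalisation reports Pearson's r_p over ROI pixels with no threshold,
and thresholded Manders coefficients: tM1 is the fraction of channel-1
intensity on pixels where channel 2 exceeds its threshold, tM2
symmetrically. Automatic thresholds follow the Costes construction:
candidate channel-1 thresholds walk down the orthogonal (major-axis)
inter-channel regression line — quantile-spaced so the grid is dense where
the pixel mass lives — and the largest pair whose sub-threshold pixel
correlation is negligible (≤ 0.02) is taken. The small positive stop
tolerance absorbs the shallow residual correlation contributed by a noise
floor; a strict zero crossing overshoots into the background on synthetic
and low-noise images. If the correlation never reaches the stop level the
threshold minimising it is used (smallest on near-ties, so fully
co-localised channels get a floor threshold and tM ≈ 1). When the
inter-channel covariance is non-positive the Costes construction is
undefined and per-channel Otsu thresholds are used instead. Rolling-ball
background correction (greyscale opening by a ball, output clamped at 0)
is available and should precede colocalisation on images with structured
background.

## Synthetic data

Each generator is seeded (`numpy.random.default_rng`; identical seed and
parameters give bit-identical output) and returns the planted parameters,
so every analysis stage can be scored against ground truth without
external files.

- **Beat series**: SBP_i = mean + Σ A_k sin(2π f_k t_i) + ε_i; the pulse
  interval started at beat i is PI_i = mean_PI + gain·(SBP_{i−lag} −
  mean_SBP) + η_i; beat times are cumulative PI sums. Defaults describe an
  adult SHR on telemetry (160/110 mmHg, 300 bpm, 410-s registrations).
  Coupling acts on PI, not HR, with a pure beat lag — matching the lag
  parameter of the sequence method. The PI noise scale `pi_noise_sd_ms`
  defaults to 0 so degenerate cases are exact. Not emulated: circadian or
  respiratory structure, ectopic beats, and closed-loop feedback from PI
  back to pressure — so recovery tests show estimator correctness under
  the model's own assumptions, not robustness to physiological artifact.
- **Pulse waveform**: each beat renders as a raised-cosine upstroke over
  15% of PI (dP/dt_max uniquely at mid-rise; the truth record stores these
  anchor instants) followed by an exponential decay (3 time constants)
  reaching the next diastolic minimum exactly at the next onset. The
  template's shape parameters are conventions — only the peak, trough and
  dP/dt_max locations matter downstream.
- **Expression**: log2 intensities ~ Normal(per-probe baseline,
  `within_group_sd`) with `planted_fc` applied to `n_de` probes in group
  B; calls are Present with probability 0.9 per chip, forced all-Present
  for planted probes. Defaults mirror a 5-vs-5 chip design with 2000
  probes, 50 planted at 2.5-fold, sd 0.25 log2 units.
- **qPCR**: test-group Ct shifted by −log_E(ratio) against the control
  group, so the efficiency-corrected ratio recovers the truth exactly at
  zero noise.
- **Coloc stacks**: Gaussian puncta (σ 1.5 px, peak 1000) placed uniformly
  in an 8 × 128 × 128 volume, ~25 per channel over a dim noisy background
  (level 2, σ 1); `overlap_fraction` of channel-1 puncta are duplicated in
  channel 2. Sparse bright puncta keep signal dominant over integrated
  background intensity — the regime in which Manders coefficients are
  meaningful. `min_separation_px` rejection-samples non-shared puncta for
  truly disjoint support; without it, chance overlap adds a few percent to
  the measured coefficients, as it would in real images.

## Numerical choices and degenerate inputs

- Zero baroreflex sequences raise an explicit error rather than reporting
  a silent zero; empty threshold masks warn at masking time and fail only
  when a statistic is requested.
- Welch's t is undefined when both groups have zero variance (error); a
  paired image comparison of identical groups reports t = 0, p = 0.5.
- BH q-values use the step-up minimum construction, capped at 1; ties are
  handled by stable sorting.
- Band edges are half-open so the shared 0.195 and 0.8 Hz edges count once.
- Sequence-detection ties (zero per-beat change) break the run under the
  default strict-monotonicity rule.

## Problem sizes

Tests and the acceptance script use 410–420 s beat series (~2100 beats at
300 bpm), 30-s rendered waveforms per heart rate, 200 Monte-Carlo screens
of 2000 × 10 expression matrices, and 8 × 128 × 128 two-channel stacks —
sizes at which every oracle comparison is exact or tightly bounded while
the full suite runs in seconds.

## Known limitations

- The spectral pipeline's overlap convention and taper were chosen here;
  legacy acquisition software may differ in leakage detail, though band
  totals agree for band-interior tones.
- The sequence method's lag handling pools all qualifying lags; software
  that selects a single best lag per ramp will count fewer sequences
  (a per-ramp best-lag mode is available via `lags=(k,)`).
- Costes auto-thresholds are estimated per image pair; comparisons across
  images should standardise thresholds (manual mode) when absolute tM
  values are compared.
- The screen consumes pre-normalised intensities; normalisation choices
  upstream dominate fold-change accuracy on real chips.
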