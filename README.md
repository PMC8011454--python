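# hnslab

Analysis toolkit for rodent hypertension studies that combine
radiotelemetry hemodynamics with transcriptomics and confocal imaging —
the kind of workflow used to characterise the hypothalamo-neurohypophysial
system (supraoptic and paraventricular nuclei, posterior pituitary) of the
spontaneously hypertensive rat (SHR) against its Wistar Kyoto control.

It provides, as a tested reusable library with a CLI:

- **Beat extraction** (`hnslab.beats`) — SBP, DBP, pulse interval (PI) and
  heart rate (HR = 60/PI) from an arterial pulse waveform, with the beat
  anchored at the maximal upstroke velocity dP/dt_max.
- **Blood-pressure variability spectra** (`hnslab.spectra`) — resampling to
  20 Hz, 9-point Hanning filter, linear detrend, 30 overlapping 2048-point
  FFT segments over a 410-s registration period, and band integration over
  the rat cardiovascular bands VLF 0.0195–0.195 Hz, LF 0.195–0.8 Hz,
  HF 0.8–3 Hz. A sinusoid of amplitude *A* mmHg integrates to *A*²/2 mmHg².
- **Spontaneous baroreflex sequence analysis** (`hnslab.baroreflex`) —
  ≥4-beat monotone SBP ramps matched by same-direction PI ramps delayed by
  3, 4 or 5 beats; BRS (ms/mmHg) as the mean least-squares slope of
  PI = BRS·SBP + c over all sequences; sequence coverage area (SCA) as the
  trimmed operating-range rectangle in the SBP–PI plane.
- **Expression screening** (`hnslab.expression`) — Present-call consensus
  (Present on every chip of at least one group), twofold linear fold-change
  cut-off, Welch *t*-test with Benjamini–Hochberg FDR control at 5%;
  efficiency-corrected qPCR quantification
  (ratio = E_t^ΔCt_t / E_ref^ΔCt_ref); log-log ELISA standard curves.
- **Image quantification** (`hnslab.imquant`) — sum-slices z-projection,
  strict lower-limit threshold masking (presets SON = 400, PVN = 128,
  pituitary = 10 grey-scale units), unit-width intensity histograms,
  the area/mean normalisation metric, rolling-ball background correction,
  Pearson r_p and Costes-thresholded Manders tM1/tM2 colocalisation.
- **Synthetic data** (`hnslab.synth`) — seeded generators for each stage
  with ground-truth records: beat series with planted band oscillations and
  baroreflex coupling of known gain and lag, rendered pulse waveforms,
  expression matrices with planted fold changes, Ct tables, and two-channel
  puncta stacks with a controlled co-localised fraction.

## Worked example

Plant a 0.1 Hz (VLF) tone of 2 mmHg and a 0.3 Hz (LF) tone of 4 mmHg on
systolic pressure, couple the pulse interval to SBP with a baroreflex gain
of 0.8 ms/mmHg at a 4-beat lag, then recover all of it:

```python
import hnslab as H

params = H.WaveformSimParams(
    duration_s=420, mean_hr=300,
    band_oscillations=((0.1, 2.0), (0.3, 4.0)),
    brs_gain=0.8, brs_lag_beats=4,
    noise_sd_mmhg=0.3, pi_noise_sd_ms=0.3, seed=13)
series, truth = H.simulate_beat_series(params)

bp = H.bpv_pipeline(series, "SBP")
print(f"VLF {bp.vlf:.3f} LF {bp.lf:.3f} {bp.units}")
# VLF 2.023 LF 7.624 mmHg^2   (theoretical A^2/2: 2.0 and 8.0)

res, seqs = H.analyze_brs(series)
print(f"BRS {res.brs_ms_per_mmhg:.3f} ms/mmHg over {res.n_sequences} sequences")
# BRS 0.788 ms/mmHg over 158 sequences   (planted gain 0.8)
print(res.per_lag_counts)
# {3: 28, 4: 106, 5: 24}
```

Each band captures its planted tone near the theoretical power (the LF
tone loses ~5% to the 9-point Hanning pre-filter), the mean sequence slope
recovers the planted gain within a few percent, and the planted 4-beat lag
dominates the per-lag sequence counts.

The same stages run from the shell, e.g.:

```sh
hnslab synth beats --duration-s 420 --mean-hr 300 --brs-gain 0.8 \
    --brs-lag 4 --oscillation 0.3 4.0 --seed 13 --out beats.csv
hnslab brs run beats.csv --out brs.json
hnslab spectra run beats.csv --variable sbp --out bands.json
```

or from a single YAML config via `hnslab run config.yaml`.

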