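# formantmod

Analysis toolkit for quantifying **learnt formant modulation** in
longitudinal vocal-learning experiments — the situation where an animal
(the motivating case is a harbor seal trained by operant conditioning) is
taught to produce a new vocal type by cyclically reconfiguring its upper
vocal tract, and the question is whether, and how fast, its formant
contours diverge from a baseline vocalization over training days.

The package covers the full chain from audio to inference:

1. **Synthetic data** (`synth`) — a generator of ground-truth formant
   contours for two vocal types: BL (baseline, flat tracks) and CD
   (conditioned, cyclic ~4 Hz modulation whose amplitude follows a logistic
   learning ramp across days, strongest in F1 and F3), including the
   tracking artifacts real formant trackers produce (onset/offset spikes,
   within-time-point formant misassignment), plus a source-filter audio
   renderer. Formant centers default to the quarter-wavelength tube model
   F_i = (2i−1)c/4L, which for a 0.17 m tract puts F1/F2/F3 near
   500/1500/2500 Hz.
2. **I/O** (`io`) — Praat TextGrid annotations (long and short dialects),
   WAV segmentation by labeled interval, and a long-format contour CSV.
3. **Formant tracking** (`tracking`) — Hann stop-band filtering below a
   3 kHz ceiling, resampling, pre-emphasis, Gaussian-windowed Burg LPC,
   root-solving to (frequency, bandwidth) candidates, F1–F3 assignment.
4. **Outlier QC** (`qc`) — the two-stage removal procedure: per-formant
   pooled 2.5% tail trimming, then exclusion of the second point of any
   adjacent-point frequency jump in the top 5% of transitions; plus a
   robustness simulation that corrupts contours with 2–10% formant
   misassignment and verifies that post-QC means stay within 1% of truth.
5. **Modulation metrics** (`metrics`) — coefficient of variation (σ/µ),
   modulation depth |f_{k+1} − f_k|, windowed spectral entropy
   H = −Σ p_i log₂ p_i of the contour periodogram (40-point / 0.5 s windows,
   50% overlap), and Morlet-wavelet dominant-period estimation.
6. **Longitudinal models** (`stats`) — ordered-quantile (rank-based inverse
   normal) response transform, Gaussian linear mixed models of
   formant/vocal-type/day with random intercepts, likelihood-ratio tests
   against the random-intercept null, and per-vocal-type day slopes with a
   Wald contrast (the estimated-marginal-trends construction).
7. **Classification** (`classify`) — per-vocalization 18-feature summaries
   ({F1, F3} × {CV, MD quartiles, SE quartiles}), UMAP embedding per epoch,
   random-forest classification (800 trees, 70/30 split, OOB error),
   ROC/AUC, an unpaired DeLong AUC comparison of start-vs-end epochs, and
   balanced accuracy / sensitivity / specificity.
8. **Pipeline** (`pipeline.run_all`) — seeded end-to-end orchestration with
   a hash manifest for reproducibility.

## Worked example

`examples/modulation_metrics.py` compares the three modulation statistics
between the two vocal types late in training:

```
BL: F1 CV 0.067 | mean MD  26.0 Hz/step | mean SE 3.29 bits | dominant period 0.167 s
CD: F1 CV 0.207 | mean MD  35.0 Hz/step | mean SE 0.59 bits | dominant period 0.263 s
```

The conditioned vocalization has three times the within-contour
variability (CV), steeper point-to-point frequency shifts (MD), a much
more predictable — hence lower-entropy — contour spectrum, and a dominant
period at the trained mouth-cycle rate (0.25 s ≈ 4 Hz). The baseline's
"dominant period" is noise: flat contours have no real periodicity.

`examples/classify_epochs.py` runs the start-vs-end separability analysis
on a full simulated experiment:

```
start: OOB error 0.43 | AUC 0.49 | balanced acc 0.46 (sens 0.42, spec 0.50)
  end: OOB error 0.00 | AUC 1.00 | balanced acc 1.00 (sens 1.00, spec 1.00)
DeLong start vs end: D = -4.11, df = 23.0, p = 0.000429
```

At the start of training the two vocal types are indistinguishable
(chance-level AUC); by the end they separate completely, and the DeLong
test confirms the AUC difference is significant. The other examples cover
QC (`simulate_and_qc.py`), the audio round trip (`track_from_audio.py`)
and the mixed-model slope contrast (`longitudinal_models.py`).

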