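# Methods

## Pipeline

For each subject the pipeline runs: zero-phase Butterworth bandpass
(1–47.5 Hz, 4th order per pass, forward–backward) → anti-aliased polyphase
downsampling to the modality's target rate (250 Hz EEG, 600 Hz MEG) →
selection of one contiguous analysis epoch (60 s EEG, 70 s MEG) → Welch
power spectral density per region (2-s Hann windows, 1-s overlap, 0.5 Hz
resolution, no per-segment detrending — the bandpass owns drift removal) →
per-region normalisation to sum to one over 1–47.5 Hz → band powers by
summing bins whose centres fall inclusively inside the band → the log ratio
ln(slow/fast) with slow = 6–9 Hz and fast = 10–11 Hz.

At 0.5 Hz resolution the inclusive edge rule means slow covers the seven
bins 6.0–9.0 and fast the three bins 10.0–11.0; the 9.5 Hz bin belongs to
neither, preserving the deliberate gap between the bands. Band powers are
floored at 1e-12 before division so degenerate inputs yield large finite
ratios rather than infinities; floored cells are flagged. The log is
natural; sign and every rank-based result are base-invariant.

Pipeline order is fixed as bandpass → resample → epoch. The normalisation
band (1, 47.5) Hz matches the analysis bandpass, making band powers
proportions of in-band power.

### Sign-flip averaging

Where a region aggregates several source series, source polarity is
arbitrary (opposite sulcal walls yield opposite orientations). Each source
is multiplied by the sign of its correlation with the region's first
principal direction (SVD of the centred source block; zero correlation
keeps +1), sources are averaged, and the average is finally sign-fixed to
correlate non-negatively with the region's unflipped first source. This
makes the output invariant, up to that final convention, to sign flips of
any subset of inputs.

### Epoch selection

`mode="first"` is the default. `mode="min_variance"` scans 1-s steps and
keeps the window minimising the across-region mean of per-region variance
(earliest window on ties) — an automated, deterministic stand-in for the
manual selection of artefact-free segments that a human reviewer performs
on clinical data; it is not a claim to replicate that judgement.

## Synthetic cohorts

Each region's signal is the sum of three independent components:

* **aperiodic background** — white Gaussian noise spectrally shaped to
  1/f^χ power (χ = 1 by default), unit variance by deterministic filter
  normalisation, DC removed;
* **alpha oscillator** — white noise shaped by a Gaussian amplitude
  response centred on the subject's drawn peak frequency with half-power
  width 2 Hz (sd = width/2.355), unit variance, scaled by the region's
  topography weight;
* **measurement noise** — white Gaussian, sd 0.1.

Alpha peaks are drawn per subject from a truncated normal on [4, 14] Hz:
controls 10.5 ± 0.5 Hz, patients 8 ± 0.5 Hz. These generative values are
synthetic choices, picked so the two distributions straddle the 6–9 /
10–11 Hz band structure; they are not estimates from clinical data. The
amplitude topography tapers linearly from 1.0 at the posterior end of each
hemisphere's anterior→posterior region ordering to 0.4 anteriorly,
emulating the occipital/parietal dominance of the resting alpha rhythm.
The 68 region labels are the standard 34-per-hemisphere cortical
parcellation names.

Per-subject generators are spawned from the cohort seed via
`numpy.random.SeedSequence`, so cohorts are bit-reproducible and
independent of generation order. Patient laterality: left count =
round(fraction × n_patients), remainder right.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes — 1/f
background, a narrowband group-dependent alpha peak, posterior dominance,
hemispheric symmetry — and therefore exercises every pipeline stage with
known ground truth. It does **not** emulate: volume conduction or sensor
mixing (series are generated at ROI level), artefacts (ocular, cardiac,
interictal spikes), non-stationarity, inter-regional correlation beyond
chance, asymmetry between the ipsilateral and contralateral hemispheres,
or clinically realistic effect sizes. With the default 2.5 Hz peak
separation the cohorts are nearly perfectly separable (AUC ≈ 1.0,
|t| ≈ 30), far beyond the AUC ≈ 0.83–0.90 reported for clinical cohorts;
passing tests demonstrate correctness of the computation, not clinical
effect sizes. A further known divergence: the synthetic subject-level
ratio summaries are strongly non-normal (the log ratio responds sharply to
where the drawn peak falls relative to the band edges, see
`analysis/03_normality_checks.py`), whereas normality was confirmed in the
clinical setting. The t-test battery is still applied as specified, and
the null-calibration sweep verifies its empirical type-I control under
these conditions (family-wise rejection ≈ 2% at nominal 5% over 100 null
cohorts).

## Statistics

* **Unpaired t** — Student's equal-variance by default (Welch optional),
  two-sided, statistic positive when the first group's mean is larger;
  Cohen's d with pooled SD.
* **Paired t** — on positionwise differences, df = n − 1; used per
  hemisphere over the 34 (patient-mean, control-mean) region pairs.
* **Chi-square** — Pearson on 2×2 tables without continuity correction
  (this convention reproduces the cohort sex-table statistics 2.17 and
  1.52 exactly), df = 1.
* **Bonferroni** — adjusted p = min(1, m·p); family sizes are explicit in
  every result: m = 2 for the two-hemisphere families, m = 34 per
  hemisphere for region-wise unpaired families.
* **Normality** — Lilliefors (KS distance to the fitted normal, p from a
  seeded Monte-Carlo null, default 10 000 replicates, cached per sample
  size) and Anderson–Darling (A² with the standard small-sample-adjusted
  p approximation).
* Degenerate zero-variance inputs return boundary p-values (1 for zero
  difference, 0 otherwise) with a `zero_variance` warning flag instead of
  raising, so parameter sweeps never abort.

## ROC

Classification rule: score ≥ threshold ⇒ patient. The orientation is
fixed by the directional hypothesis (more slow alpha ⇒ more patient-like)
rather than auto-flipped, since auto-flipping inflates null AUC.
Thresholds descend from a +∞ sentinel through the unique scores, tied
scores share one operating point, and the trapezoidal AUC equals the
Mann–Whitney U/(n₁n₂) with ties counted half — an identity the tests
verify against an independent rank-statistic oracle.

## Numerical and design choices

* Welch taper: Hann. Frequency-bin membership uses a 1e-12 Hz tolerance
  on bin centres.
* Spectral synthesis normalisation is deterministic (computed from the
  filter, not the realisation), so generated variances are exact in
  expectation and seeds fully determine output.
* 1/f exponent estimation: ordinary least squares of log10 power on
  log10 frequency over 2–40 Hz. Peak detection: argmax of the log-residual
  above the fitted aperiodic trend within 6–13 Hz, requiring an excess of
  0.2 log10 units (~1.6×) to call a peak — below that, Welch estimation
  noise alone regularly produces spurious maxima.
* Monte-Carlo study sizes: the validation sweeps use 100 seeded cohorts of
  n = 20/20 at 20-s epochs; at 0.5 Hz resolution a 20-s epoch already
  gives 19 Welch segments and stable band powers, so the shorter epoch
  changes none of the qualitative conclusions while keeping a full sweep
  to a few minutes.
* Exchange format: TSV + JSON sidecar rather than a binary container, so
  fixtures are diffable and language-neutral; EDF ingestion is optional
  (requires `mne`).

## Known limitations

No source reconstruction, head modelling, or artefact removal — the
pipeline starts at ROI-level series. No peak-alpha-frequency estimator is
offered as an outcome statistic (the ratio is the statistic; the internal
peak detector exists only for generator validation). No cross-validation
or confidence bands on the AUC. Age and medication effects are out of
scope.
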