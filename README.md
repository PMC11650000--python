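# alphaslow

Resting-state EEG/MEG alpha-rhythm slowing analysis: from region-of-interest
(ROI) time series to relative band power, the slow/fast alpha power log
ratio, cohort statistics, and ROC evaluation of the ratio as a
patient-vs-control biomarker.

## The problem

The dominant posterior alpha rhythm (8–13 Hz) of relaxed, eyes-closed
wakefulness slows in several neurological conditions, including temporal
lobe epilepsy (TLE): patients' alpha power concentrates at lower
frequencies than healthy controls'. `alphaslow` implements the spectral
pipeline that quantifies this: per cortical region, the power spectral
density is estimated with Welch's method (2-s Hann windows, 1-s overlap,
0.5 Hz resolution) and normalised to sum to one over the 1–47.5 Hz analysis
band, giving *relative* power. The central statistic is the **alpha power
log ratio**

```
r = ln( P_slow / P_fast ),   P_slow = Σ relative power in 6–9 Hz,
                             P_fast = Σ relative power in 10–11 Hz
```

computed per region and subject. Positive `r` means relatively more slow
alpha — greater deviation from health. Ratios are averaged per hemisphere
(left / right / ipsilateral / contralateral to the seizure focus) or over
all 68 regions, compared between cohorts with t-tests under Bonferroni
correction, and the subject-level mean ratio is evaluated as a classifier
via the ROC curve (AUC = trapezoidal area = Mann–Whitney U/(n₁n₂)).

Because clinical recordings cannot be redistributed, the package ships a
synthetic cohort generator: each subject is 1/f^χ background noise plus a
Gaussian-bandpass alpha oscillator with a posterior-dominant amplitude
topography over 68 regions (34 per hemisphere), with the oscillator's
centre frequency drawn from a group-dependent distribution (controls
10.5 ± 0.5 Hz, patients 8 ± 0.5 Hz by default). Every downstream stage is
therefore testable end to end with known ground truth.

## Worked example

```python
import alphaslow as al

spec = al.CohortSpec(n_controls=17, n_patients=22, fs=250.0,
                     duration=60.0, modality="EEG", seed=101)
config = al.RunConfig.for_modality("EEG", output_dir="results/eeg")
res = al.run_pipeline(config, sim_spec=spec)

ev = res["biomarker"]
print(f"patients {ev.mean_patient:+.3f}, controls {ev.mean_control:+.3f}")
for r in res["stats"]:
    print(f"{r.comparison}: t = {r.statistic:.2f}, p_adj = {r.p_adjusted:.2e}")
print(f"AUC = {ev.roc.auc:.4f}")
```

prints

```
patients +3.243, controls -1.361
patient_vs_control_left_hemisphere: t = 29.18, p_adj = 7.68e-27
patient_vs_control_right_hemisphere: t = 29.69, p_adj = 4.16e-27
AUC = 1.0000
```

Patients' mean log ratio is positive (slow alpha dominates their 6–11 Hz
power) while controls' is negative; with the default 2.5 Hz separation of
the generating peak distributions the cohorts separate far more cleanly
than clinical data would — see `docs/methods.md` for what the synthetic
conditions do and do not emulate.

The same pipeline is scripted as a narrative sequence under `analysis/`:

| script | what it does |
|---|---|
| `01_run_cohort_analysis.py` | EEG- and MEG-convention cohorts end to end |
| `02_band_sensitivity.py`    | robustness to slow/fast band-edge choices |
| `03_normality_checks.py`    | Anderson–Darling / Lilliefors on ratio summaries |
| `04_monte_carlo_validation.py` | 100-seed effect, null and recovery sweeps |

Each writes its tables under `results/`. A `alphaslow` console command
exposes the pipeline stages (`simulate`, `preprocess`, `psd`, `ratio`,
`stats`, `roc`, `run`) for shell use; recordings travel as TSV + JSON
sidecar files.

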