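"""Synthetic resting-state cohorts: 1/f background plus a narrowband alpha rhythm.

Each simulated subject is a region-of-interest (ROI) level recording built
from three additive components per region:

* an aperiodic background — white Gaussian noise spectrally shaped to a
  ``1/f**chi`` power law, emulating the broadband falloff of cortical
  activity;
* a narrowband alpha oscillator — Gaussian-bandpass-filtered noise centred
  at the subject's alpha peak frequency, scaled by a posterior-dominant
  per-region amplitude topography.  Patients draw their peak from a slower
  distribution than controls, which is the effect the downstream slow/fast
  alpha log-ratio statistic is designed to detect;
* additive white measurement noise.

All randomness flows through per-subject substreams spawned deterministically
from the cohort seed, so cohorts are bit-reproducible and independent of the
order in which subjects are generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .parcellation import (
    default_hemispheres,
    default_region_labels,
    default_topography,
)

GROUPS = ("control", "left_TLE", "right_TLE")
PATIENT_GROUPS = ("left_TLE", "right_TLE")

#: Hard truncation bounds (Hz) for drawn alpha peak frequencies; keeps every
#: drawn peak inside the band structure the slow/fast ratio assumes.
PEAK_BOUNDS = (4.0, 14.0)

# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sd ≈ 2.355 * sd
_FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class Recording:
    """One subject's ROI x sample time-series matrix with metadata."""

    subject_id: str
    group: str
    modality: str
    fs: float
    data: np.ndarray
    region_labels: Sequence[str]
    hemisphere: Sequence[str]
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if data.ndim != 2:
            raise ValueError("data must be a 2-D region x sample matrix")
        if data.shape[0] != len(self.region_labels):
            raise ValueError(
                f"data has {data.shape[0]} rows but {len(self.region_labels)} "
                "region labels"
            )
        if len(self.hemisphere) != len(self.region_labels):
            raise ValueError("hemisphere map length must equal region count")
        if not np.all(np.isfinite(data)):
            raise ValueError("data contains non-finite samples")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def laterality(self) -> str | None:
        """Seizure-focus side for patients; None for controls."""
        if self.group == "left_TLE":
            return "left"
        if self.group == "right_TLE":
            return "right"
        return None

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "Recording":
        """Copy with new sample matrix (and optionally new sampling rate)."""
        return replace(self, data=data, fs=self.fs if fs is None else fs)


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic control/patient cohort.

    Defaults define the reference study conditions: controls with a
    10.5 Hz alpha peak, patients with an 8 Hz peak (sd 0.5 Hz), a 1/f
    background with exponent 1, and a posterior-dominant amplitude
    topography over 68 regions.
    """

    n_controls: int = 20
    n_patients: int = 20
    patient_laterality_fractions: tuple[float, float] = (0.5, 0.5)
    fs: float = 250.0
    duration: float = 60.0
    n_regions: int = 68
    aperiodic_exponent: float = 1.0
    alpha_peak_mean_control: float = 10.5
    alpha_peak_mean_patient: float = 8.0
    alpha_peak_sd: float = 0.5
    alpha_bandwidth: float = 2.0
    alpha_amplitude_topography: np.ndarray | None = None
    noise_sd: float = 0.1
    seed: int = 0
    modality: str = "EEG"

    def topography(self) -> np.ndarray:
        if self.alpha_amplitude_topography is None:
            return default_topography(self.n_regions)
        topo = np.asarray(self.alpha_amplitude_topography, dtype=float)
        return topo

    def validate(self, require_subjects: bool = True) -> None:
        if self.n_controls < 0:
            raise ValueError(f"n_controls must be >= 0, got {self.n_controls}")
        if self.n_patients < 0:
            raise ValueError(f"n_patients must be >= 0, got {self.n_patients}")
        if require_subjects and self.n_controls + self.n_patients < 1:
            raise ValueError("n_controls + n_patients must be >= 1")
        fr = self.patient_laterality_fractions
        if len(fr) != 2 or min(fr) < 0:
            raise ValueError(
                "patient_laterality_fractions must be two non-negative numbers"
            )
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(
                f"patient_laterality_fractions must sum to 1, got {sum(fr)}"
            )
        if self.fs <= 2 * 47.5:
            raise ValueError(
                f"fs must exceed 95 Hz so the 1-47.5 Hz analysis band is below "
                f"Nyquist, got fs={self.fs}"
            )
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.n_regions < 1:
            raise ValueError(f"n_regions must be >= 1, got {self.n_regions}")
        if self.alpha_peak_sd < 0:
            raise ValueError(f"alpha_peak_sd must be >= 0, got {self.alpha_peak_sd}")
        if self.alpha_bandwidth <= 0:
            raise ValueError(
                f"alpha_bandwidth must be positive, got {self.alpha_bandwidth}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for mean_name in ("alpha_peak_mean_control", "alpha_peak_mean_patient"):
            mean = getattr(self, mean_name)
            if not (1.0 < mean < self.fs / 2):
                raise ValueError(
                    f"{mean_name} must lie in (1, fs/2) Hz, got {mean}"
                )
        topo = self.topography()
        if topo.shape != (self.n_regions,):
            raise ValueError(
                "alpha_amplitude_topography must have one weight per region "
                f"({self.n_regions}), got shape {topo.shape}"
            )
        if np.any(topo < 0):
            raise ValueError("alpha_amplitude_topography weights must be >= 0")

    def region_labels(self) -> list[str]:
        if self.n_regions == 68:
            return default_region_labels()
        return [f"region_{i:03d}" for i in range(self.n_regions)]

    def hemispheres(self) -> list[str]:
        if self.n_regions == 68:
            return default_hemispheres()
        half = self.n_regions // 2
        return ["left"] * half + ["right"] * (self.n_regions - half)


def _unit_variance_filtered_noise(
    rng: np.random.Generator, n_rows: int, n_samples: int, gain: np.ndarray
) -> np.ndarray:
    """White Gaussian noise spectrally shaped by ``gain``, unit variance.

    ``gain`` is a non-negative amplitude response on the rfft grid.  The
    normalisation is deterministic (computed from the filter, not the
    realisation), so the output is an exactly seeded linear function of the
    white input and its expected variance is 1.
    """
    gain = np.asarray(gain, dtype=float)
    # Expected output variance for unit-variance white input (Parseval).
    weights = np.full(gain.shape, 2.0)
    weights[0] = 1.0
    if n_samples % 2 == 0:
        weights[-1] = 1.0
    expected_var = float(np.sum(weights * gain**2)) / n_samples
    if expected_var <= 0:
        return np.zeros((n_rows, n_samples))
    white = rng.standard_normal((n_rows, n_samples))
    spectrum = np.fft.rfft(white, axis=1) * gain
    shaped = np.fft.irfft(spectrum, n=n_samples, axis=1)
    return shaped / np.sqrt(expected_var)


def _draw_peak(spec: CohortSpec, group: str, rng: np.random.Generator) -> float:
    mean = (
        spec.alpha_peak_mean_control
        if group == "control"
        else spec.alpha_peak_mean_patient
    )
    if spec.alpha_peak_sd == 0:
        return float(np.clip(mean, *PEAK_BOUNDS))
    lo, hi = PEAK_BOUNDS
    for _ in range(1000):  # rejection sampling from the truncated normal
        peak = mean + spec.alpha_peak_sd * rng.standard_normal()
        if lo <= peak <= hi:
            return float(peak)
    return float(np.clip(mean, lo, hi))


def simulate_subject(
    spec: CohortSpec,
    group: str,
    rng_stream: np.random.Generator | int,
    subject_id: str = "sub-000",
) -> Recording:
    """Simulate one subject's ROI-level recording.

    The drawn alpha peak frequency is stored in ``Recording.info`` under
    ``"drawn_peak_hz"`` so recovery tests can compare the spectral estimate
    with the injected ground truth.
    """
    spec.validate(require_subjects=False)
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    rng = (
        rng_stream
        if isinstance(rng_stream, np.random.Generator)
        else np.random.default_rng(rng_stream)
    )

    n = int(round(spec.duration * spec.fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    topo = spec.topography()

    # Aperiodic 1/f**chi background (amplitude response f**(-chi/2), no DC).
    aperiodic_gain = np.zeros_like(freqs)
    pos = freqs > 0
    aperiodic_gain[pos] = freqs[pos] ** (-spec.aperiodic_exponent / 2.0)

    peak = _draw_peak(spec, group, rng)
    sd_hz = spec.alpha_bandwidth / _FWHM_TO_SD
    alpha_gain = np.exp(-0.5 * ((freqs - peak) / sd_hz) ** 2)
    alpha_gain[0] = 0.0

    background = _unit_variance_filtered_noise(rng, spec.n_regions, n, aperiodic_gain)
    oscillation = _unit_variance_filtered_noise(rng, spec.n_regions, n, alpha_gain)
    data = background + topo[:, None] * oscillation
    if spec.noise_sd > 0:
        data = data + spec.noise_sd * rng.standard_normal((spec.n_regions, n))

    return Recording(
        subject_id=subject_id,
        group=group,
        modality=spec.modality,
        fs=spec.fs,
        data=data,
        region_labels=spec.region_labels(),
        hemisphere=spec.hemispheres(),
        info={"drawn_peak_hz": peak, "aperiodic_exponent": spec.aperiodic_exponent},
    )


def _laterality_counts(spec: CohortSpec) -> tuple[int, int]:
    # left count = round(fraction * n), remainder right (half-up rounding)
    n_left = int(np.floor(spec.patient_laterality_fractions[0] * spec.n_patients + 0.5))
    return n_left, spec.n_patients - n_left


def simulate_cohort(spec: CohortSpec) -> tuple[list[Recording], pd.DataFrame]:
    """Simulate a full control + patient cohort.

    Returns the recordings and a provenance table (subject_id, group,
    laterality, drawn_peak_hz, seed) recording each subject's injected
    alpha peak.  Per-subject generators are spawned from ``spec.seed`` so
    the cohort is reproducible regardless of generation order.
    """
    spec.validate()
    n_left, n_right = _laterality_counts(spec)
    groups = (
        ["control"] * spec.n_controls
        + ["left_TLE"] * n_left
        + ["right_TLE"] * n_right
    )
    child_seeds = np.random.SeedSequence(spec.seed).spawn(len(groups))
    recordings: list[Recording] = []
    rows = []
    for i, (group, child) in enumerate(zip(groups, child_seeds)):
        rec = simulate_subject(
            spec, group, np.random.default_rng(child), subject_id=f"sub-{i:03d}"
        )
        recordings.append(rec)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": group,
                "laterality": rec.laterality or "",
                "drawn_peak_hz": rec.info["drawn_peak_hz"],
                "seed": spec.seed,
            }
        )
    return recordings, pd.DataFrame(rows)
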