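"""Welch power spectra, sum-to-one relative power, and band power extraction.

The study convention is Welch's method with a 2-second Hann window and
1-second overlap (0.5 Hz frequency resolution), followed by per-region
normalisation of the power spectral density to sum to one over the analysis
band, so band powers are interpretable as proportions of total power.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .cohort import Recording

#: Default normalisation band (Hz), matching the 1-47.5 Hz analysis bandpass.
DEFAULT_NORM_BAND = (1.0, 47.5)


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band; bin centres at both edges are included."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo <= self.f_hi):
            raise ValueError(
                f"band {self.name!r} needs 0 < f_lo <= f_hi, got "
                f"({self.f_lo}, {self.f_hi})"
            )


#: Slow and fast alpha bands.  At 0.5 Hz resolution SLOW covers the seven
#: bins 6.0-9.0 Hz and FAST the three bins 10.0-11.0 Hz; 9.5 Hz belongs to
#: neither, by design.
SLOW_ALPHA = BandDefinition("slow_alpha", 6.0, 9.0)
FAST_ALPHA = BandDefinition("fast_alpha", 10.0, 11.0)


@dataclass(frozen=True)
class PowerSpectrum:
    """Per-region power on a uniform frequency grid.

    ``normalized`` distinguishes absolute Welch power from relative
    (sum-to-one over ``norm_band``) power.
    """

    freqs: np.ndarray
    power: np.ndarray
    normalized: bool = False
    norm_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)
        if power.ndim != 2 or power.shape[1] != freqs.shape[0]:
            raise ValueError("power must be region x frequency, matching freqs")
        if np.any(power < 0):
            raise ValueError("power must be non-negative")
        df = np.diff(freqs)
        if freqs.size > 1 and (np.any(df <= 0) or not np.allclose(df, df[0])):
            raise ValueError("freqs must be strictly increasing and uniform")

    @property
    def n_regions(self) -> int:
        return self.power.shape[0]

    def band_mask(self, f_lo: float, f_hi: float) -> np.ndarray:
        return (self.freqs >= f_lo - 1e-12) & (self.freqs <= f_hi + 1e-12)


def welch_psd(
    rec: Recording, window_s: float = 2.0, overlap_s: float = 1.0
) -> PowerSpectrum:
    """Welch power spectral density per region (Hann taper).

    Frequency resolution is ``1/window_s`` (0.5 Hz at the 2-s default).
    """
    if not (0 <= overlap_s < window_s):
        raise ValueError(
            f"need 0 <= overlap_s < window_s, got overlap={overlap_s}, "
            f"window={window_s}"
        )
    nperseg = int(round(window_s * rec.fs))
    noverlap = int(round(overlap_s * rec.fs))
    if rec.n_samples < 2 * nperseg:
        raise ValueError(
            f"recording has {rec.n_samples} samples; Welch with a "
            f"{window_s}-s window needs at least {2 * nperseg}"
        )
    # detrend=False keeps the DC bin meaningful; the analysis bandpass is
    # responsible for removing drift before spectral estimation.
    freqs, power = sps.welch(
        rec.data, fs=rec.fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend=False, axis=1,
    )
    return PowerSpectrum(freqs=freqs, power=power, normalized=False)


def relative_power(
    ps: PowerSpectrum, norm_band: tuple[float, float] = DEFAULT_NORM_BAND
) -> PowerSpectrum:
    """Normalise each region's power to sum to one over ``norm_band``.

    Bins outside the band are zeroed, so downstream band powers are
    proportions of in-band power.
    """
    if ps.normalized:
        raise ValueError("spectrum is already normalized")
    mask = ps.band_mask(*norm_band)
    if not mask.any():
        raise ValueError(f"no frequency bins inside norm_band {norm_band}")
    totals = ps.power[:, mask].sum(axis=1)
    dead = np.flatnonzero(totals <= 0)
    if dead.size:
        raise ValueError(
            f"region(s) {dead.tolist()} have zero total power inside "
            f"norm_band {norm_band}"
        )
    power = np.zeros_like(ps.power)
    power[:, mask] = ps.power[:, mask] / totals[:, None]
    return replace(ps, power=power, normalized=True, norm_band=tuple(norm_band))


def band_power(ps: PowerSpectrum, band: BandDefinition) -> np.ndarray:
    """Per-region sum of relative power over the band (edges inclusive)."""
    if not ps.normalized:
        raise ValueError("band_power requires a normalized (relative) spectrum")
    lo, hi = ps.norm_band
    if band.f_lo < lo - 1e-12 or band.f_hi > hi + 1e-12:
        raise ValueError(
            f"band {band.name!r} ({band.f_lo}-{band.f_hi} Hz) extends outside "
            f"norm_band ({lo}-{hi} Hz)"
        )
    mask = ps.band_mask(band.f_lo, band.f_hi)
    return ps.power[:, mask].sum(axis=1)


def fit_aperiodic_exponent(
    ps: PowerSpectrum,
    f_range: tuple[float, float] = (2.0, 40.0),
    exclude: tuple[float, float] | None = None,
) -> np.ndarray:
    """Estimate the 1/f exponent chi per region by log-log regression.

    Fits ``log10 P = a - chi * log10 f`` over ``f_range`` (optionally
    excluding a band, e.g. the alpha range) and returns chi per region.
    """
    mask = ps.band_mask(*f_range) & (ps.freqs > 0)
    if exclude is not None:
        mask &= ~ps.band_mask(*exclude)
    if mask.sum() < 3:
        raise ValueError("too few bins for an aperiodic fit")
    logf = np.log10(ps.freqs[mask])
    power = np.maximum(ps.power[:, mask], 1e-30)
    slopes = np.polynomial.polynomial.polyfit(logf, np.log10(power).T, 1)[1]
    return -np.atleast_1d(slopes)


def detrended_peak_frequency(
    ps: PowerSpectrum,
    search_band: tuple[float, float] = (6.0, 13.0),
    fit_range: tuple[float, float] = (2.0, 40.0),
    min_excess: float = 0.2,
) -> np.ndarray:
    """Per-region frequency of the largest spectral peak above the 1/f trend.

    The aperiodic trend is fitted over ``fit_range`` excluding the search
    band, then subtracted in log space; the argmax of the residual inside
    ``search_band`` is returned.  NaN marks regions whose largest residual
    stays below ``min_excess`` log10 units (~1.6x the trend by default) —
    i.e. no oscillatory peak distinguishable from Welch estimation noise.
    """
    mask = ps.band_mask(*fit_range) & (ps.freqs > 0) & ~ps.band_mask(*search_band)
    logf = np.log10(ps.freqs[mask])
    logp = np.log10(np.maximum(ps.power[:, mask], 1e-30))
    coef = np.polynomial.polynomial.polyfit(logf, logp.T, 1)  # (2, n_regions)
    smask = ps.band_mask(*search_band) & (ps.freqs > 0)
    logf_s = np.log10(ps.freqs[smask])
    trend = coef[0][:, None] + coef[1][:, None] * logf_s[None, :]
    residual = np.log10(np.maximum(ps.power[:, smask], 1e-30)) - trend
    peaks = ps.freqs[smask][np.argmax(residual, axis=1)].astype(float)
    peaks[residual.max(axis=1) < min_excess] = np.nan
    return peaks


def global_band_power(
    cohort_spectra: list[PowerSpectrum], f_range: tuple[float, float] = (1.0, 20.0)
) -> dict[str, np.ndarray]:
    """Cohort-mean relative power per bin with a 95% CI across subjects.

    Each subject is first averaged across regions; the curve is the mean of
    those subject curves and the CI is mean +/- 1.96 * SEM over subjects
    (width 0 for a single subject, by convention).
    """
    if not cohort_spectra:
        raise ValueError("cohort_spectra is empty")
    ref = cohort_spectra[0].freqs
    for ps in cohort_spectra[1:]:
        if ps.freqs.shape != ref.shape or not np.allclose(ps.freqs, ref):
            raise ValueError("all spectra must share the same frequency grid")
    mask = cohort_spectra[0].band_mask(*f_range)
    freqs = ref[mask]
    subject_curves = np.stack([ps.power[:, mask].mean(axis=0) for ps in cohort_spectra])
    mean = subject_curves.mean(axis=0)
    n = subject_curves.shape[0]
    sem = subject_curves.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return {
        "freqs": freqs,
        "mean": mean,
        "ci_lo": mean - 1.96 * sem,
        "ci_hi": mean + 1.96 * sem,
        "n_subjects": n,
    }
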