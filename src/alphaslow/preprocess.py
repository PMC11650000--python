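"""Signal conditioning: bandpass, resampling, epoch selection, sign-flip averaging.

All operations are pure: they return new :class:`~alphaslow.cohort.Recording`
objects (or arrays) and never modify their inputs.  The canonical pipeline
order is ``bandpass -> resample -> select_epoch``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .cohort import Recording


@dataclass(frozen=True)
class EpochSelectionPolicy:
    """How to pick the analysis epoch from a longer recording.

    ``first`` takes the initial segment.  ``min_variance`` scans candidate
    windows in 1-s steps and keeps the one minimising the mean across
    regions of the per-region variance — an automated stand-in for manual
    selection of the most artefact-free segment (ties break to the earliest
    window).
    """

    mode: str = "first"
    duration: float = 60.0

    def __post_init__(self) -> None:
        if self.mode not in ("first", "min_variance"):
            raise ValueError(f"mode must be 'first' or 'min_variance', got {self.mode!r}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")


def bandpass(rec: Recording, f_lo: float, f_hi: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth bandpass (forward-backward, order per pass)."""
    if not (0 < f_lo < f_hi < rec.fs / 2):
        raise ValueError(
            f"band ({f_lo}, {f_hi}) Hz must satisfy 0 < f_lo < f_hi < fs/2 "
            f"(fs={rec.fs})"
        )
    sos = signal.butter(order, [f_lo, f_hi], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.with_data(filtered)


def resample(rec: Recording, fs_target: float) -> Recording:
    """Anti-aliased polyphase downsampling to ``fs_target``.

    Upsampling is not supported; the caller must bandpass below the new
    Nyquist first.  Rational ratios are handled via up/down factors from
    the float ratio (tolerance 1e-9).
    """
    if fs_target > rec.fs:
        raise ValueError(
            f"upsampling not supported: fs_target={fs_target} > fs={rec.fs}"
        )
    if fs_target == rec.fs:
        return rec.with_data(rec.data.copy())
    from fractions import Fraction

    frac = Fraction(fs_target / rec.fs).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(rec.data, up, down, axis=1)
    return rec.with_data(out, fs=fs_target)


def select_epoch(rec: Recording, policy: EpochSelectionPolicy) -> Recording:
    """Extract one contiguous epoch of ``policy.duration`` seconds."""
    n_epoch = int(round(policy.duration * rec.fs))
    if n_epoch > rec.n_samples:
        raise ValueError(
            f"recording ({rec.duration:.1f} s) shorter than requested epoch "
            f"({policy.duration} s)"
        )
    if policy.mode == "first" or n_epoch == rec.n_samples:
        start = 0
    else:
        step = max(1, int(round(rec.fs)))  # 1-s candidate stride
        starts = np.arange(0, rec.n_samples - n_epoch + 1, step)
        scores = np.array(
            [rec.data[:, s : s + n_epoch].var(axis=1).mean() for s in starts]
        )
        start = int(starts[np.argmin(scores)])  # argmin takes earliest tie
    return rec.with_data(rec.data[:, start : start + n_epoch].copy())


def signflip_average(
    sources: np.ndarray, region_assignment: np.ndarray | list
) -> np.ndarray:
    """Sign-flip sources within each region, then average to one series per region.

    Source orientations on opposite sulcal walls carry arbitrary, mutually
    cancelling polarity; within each region every source is multiplied by the
    sign of its correlation with the region's first principal direction
    (zero correlation keeps +1) before averaging.  The result is then
    globally sign-fixed so it correlates non-negatively with the region's
    unflipped lowest-index source — making the output invariant, up to that
    convention, to sign flips of any subset of inputs.

    Regions are returned in order of first appearance in ``region_assignment``.
    """
    sources = np.asarray(sources, dtype=float)
    if sources.ndim != 2:
        raise ValueError("sources must be a 2-D source x sample matrix")
    assignment = np.asarray(region_assignment)
    if assignment.shape[0] != sources.shape[0]:
        raise ValueError("region_assignment must have one entry per source row")

    region_ids = list(dict.fromkeys(assignment.tolist()))
    out = np.empty((len(region_ids), sources.shape[1]))
    for r, rid in enumerate(region_ids):
        idx = np.flatnonzero(assignment == rid)
        if idx.size == 0:
            raise ValueError(f"region {rid!r} has no sources")
        block = sources[idx]
        centred = block - block.mean(axis=1, keepdims=True)
        # First principal direction of the source covariance via SVD.
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        pc1 = vt[0]
        corr = centred @ pc1
        signs = np.where(corr < 0, -1.0, 1.0)
        avg = (signs[:, None] * block).mean(axis=0)
        ref = block[0] - block[0].mean()
        if float((avg - avg.mean()) @ ref) < 0:
            avg = -avg
        out[r] = avg
    return out
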