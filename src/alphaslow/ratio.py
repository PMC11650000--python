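"""The central statistic: the slow/fast alpha power log ratio.

Per region, the ratio is ``log(slow_band_power / fast_band_power)`` with
slow alpha at 6-9 Hz and fast alpha at 10-11 Hz (natural log).  A positive
value means relatively more slow alpha — the alpha-slowing signature that
distinguishes temporal lobe epilepsy patients from controls.  Ratios are
aggregated per subject over hemispheres (left / right / ipsilateral /
contralateral to the seizure focus) or over all 68 regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Recording
from .spectral import (
    FAST_ALPHA,
    SLOW_ALPHA,
    BandDefinition,
    PowerSpectrum,
    band_power,
)

#: Relative powers below this floor are clamped before division so the log
#: ratio stays finite on degenerate inputs; floored cells are flagged.
POWER_FLOOR = 1e-12


@dataclass(frozen=True)
class AlphaRatioTable:
    """Subject x region log-ratio values with subject and region metadata.

    ``subjects`` has columns subject_id, group, modality, laterality;
    ``regions`` has columns label, hemisphere.  ``floored`` flags cells
    where the zero-power guard engaged.
    """

    values: np.ndarray
    subjects: pd.DataFrame
    regions: pd.DataFrame
    log_base: str = "natural"
    floored: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("values must be subject x region")
        if values.shape[0] != len(self.subjects):
            raise ValueError("row count must match subjects table")
        if values.shape[1] != len(self.regions):
            raise ValueError("column count must match regions table")
        if not np.all(np.isfinite(values)):
            raise ValueError("log-ratio values must be finite")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def group_mask(self, *groups: str) -> np.ndarray:
        return self.subjects["group"].isin(groups).to_numpy()

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per (subject, region)."""
        rows = []
        for i, sub in self.subjects.iterrows():
            for j, reg in self.regions.iterrows():
                rows.append(
                    {
                        "subject_id": sub["subject_id"],
                        "group": sub["group"],
                        "laterality": sub.get("laterality", "") or "",
                        "region": reg["label"],
                        "hemisphere": reg["hemisphere"],
                        "log_ratio": self.values[i, j],
                    }
                )
        return pd.DataFrame(rows)


def alpha_log_ratio(slow: np.ndarray, fast: np.ndarray) -> np.ndarray:
    """Per-region ``log(slow / fast)`` with epsilon flooring (natural log)."""
    slow = np.asarray(slow, dtype=float)
    fast = np.asarray(fast, dtype=float)
    if slow.shape != fast.shape:
        raise ValueError("slow and fast band-power vectors must match in length")
    if np.any(slow < 0) or np.any(fast < 0):
        raise ValueError("band powers must be non-negative")
    return np.log(np.maximum(slow, POWER_FLOOR) / np.maximum(fast, POWER_FLOOR))


def ratio_table(
    spectra: list[PowerSpectrum],
    recordings: list[Recording],
    slow: BandDefinition = SLOW_ALPHA,
    fast: BandDefinition = FAST_ALPHA,
) -> AlphaRatioTable:
    """Build the subject x region log-ratio table from relative spectra."""
    if len(spectra) != len(recordings):
        raise ValueError("need one spectrum per recording")
    if not spectra:
        raise ValueError("empty cohort")
    ref = recordings[0]
    values = np.empty((len(spectra), ref.n_regions))
    floored = np.zeros_like(values, dtype=bool)
    for i, ps in enumerate(spectra):
        s = band_power(ps, slow)
        f = band_power(ps, fast)
        floored[i] = (s < POWER_FLOOR) | (f < POWER_FLOOR)
        values[i] = alpha_log_ratio(s, f)
    subjects = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in recordings],
            "group": [r.group for r in recordings],
            "modality": [r.modality for r in recordings],
            "laterality": [r.laterality for r in recordings],
        }
    )
    regions = pd.DataFrame(
        {"label": list(ref.region_labels), "hemisphere": list(ref.hemisphere)}
    )
    return AlphaRatioTable(values=values, subjects=subjects, regions=regions, floored=floored)


def hemisphere_mean(table: AlphaRatioTable, side: str) -> np.ndarray:
    """Per-subject mean log ratio over one hemisphere's regions.

    ``side`` is ``left``, ``right``, ``ipsilateral`` or ``contralateral``;
    the latter two resolve per patient to the seizure-focus side (or its
    opposite) and are undefined for controls.
    """
    hemi = table.regions["hemisphere"].to_numpy()
    if side in ("left", "right"):
        mask = hemi == side
        if not mask.any():
            raise ValueError(f"no regions in hemisphere {side!r}")
        return table.values[:, mask].mean(axis=1)
    if side not in ("ipsilateral", "contralateral"):
        raise ValueError(f"unknown side {side!r}")
    lat = table.subjects["laterality"]
    missing = table.subjects.loc[lat.isna() | (lat == ""), "subject_id"].tolist()
    if missing:
        raise ValueError(
            f"{side} mean requires laterality for every subject; missing for "
            f"{missing}"
        )
    out = np.empty(table.n_subjects)
    left_mask = hemi == "left"
    right_mask = hemi == "right"
    for i, focus in enumerate(lat):
        same = left_mask if focus == "left" else right_mask
        mask = same if side == "ipsilateral" else ~same
        out[i] = table.values[i, mask].mean()
    return out


def global_mean_ratio(table: AlphaRatioTable) -> np.ndarray:
    """Per-subject unweighted mean over all regions."""
    if table.n_regions == 0:
        raise ValueError("table has no regions")
    return table.values.mean(axis=1)


def band_sensitivity(
    spectra: list[PowerSpectrum],
    recordings: list[Recording],
    slow_grid: list[BandDefinition],
    fast_grid: list[BandDefinition],
) -> pd.DataFrame:
    """Sweep slow/fast band-edge choices; one control-vs-patient t per cell.

    For each (slow, fast) pair the subject-level global mean ratio is
    recomputed and compared between patients and controls with an unpaired
    t-test (patients first, so positive t means more slow alpha in
    patients).  Overlapping band pairs are computed anyway but flagged with
    a recorded warning.
    """
    from .stats import unpaired_t

    groups = np.array([r.group for r in recordings])
    is_patient = np.isin(groups, ("left_TLE", "right_TLE"))
    if not is_patient.any() or is_patient.all():
        raise ValueError("band_sensitivity needs both controls and patients")
    rows = []
    for slow in slow_grid:
        for fast in fast_grid:
            overlap = slow.f_hi >= fast.f_lo and fast.f_hi >= slow.f_lo
            if overlap:
                warnings.warn(
                    f"slow band {slow.f_lo}-{slow.f_hi} Hz overlaps fast band "
                    f"{fast.f_lo}-{fast.f_hi} Hz",
                    stacklevel=2,
                )
            tbl = ratio_table(spectra, recordings, slow=slow, fast=fast)
            means = global_mean_ratio(tbl)
            res = unpaired_t(means[is_patient], means[~is_patient])
            rows.append(
                {
                    "slow_lo": slow.f_lo,
                    "slow_hi": slow.f_hi,
                    "fast_lo": fast.f_lo,
                    "fast_hi": fast.f_hi,
                    "t_stat": res.statistic,
                    "p": res.p_value,
                    "bands_overlap": overlap,
                }
            )
    return pd.DataFrame(rows)
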