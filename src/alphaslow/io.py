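"""File formats and run configuration.

The canonical recording exchange format is a TSV (first column ``time_s``,
one column per region, header row of region labels) plus a JSON sidecar
(``<stem>.json``) carrying sampling rate, modality, group, laterality and
the region -> hemisphere map.  Optional EDF ingestion is available when an
EDF reader (mne) is importable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Recording
from .ratio import AlphaRatioTable

_MODALITY_DEFAULTS = {
    "EEG": {"fs_target": 250.0, "epoch_duration": 60.0},
    "MEG": {"fs_target": 600.0, "epoch_duration": 70.0},
}


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline parameters; defaults follow the EEG convention."""

    modality: str = "EEG"
    fs_target: float = 250.0
    bandpass: tuple[float, float] = (1.0, 47.5)
    epoch_mode: str = "first"
    epoch_duration: float = 60.0
    welch_window_s: float = 2.0
    welch_overlap_s: float = 1.0
    norm_band: tuple[float, float] = (1.0, 47.5)
    slow_band: tuple[float, float] = (6.0, 9.0)
    fast_band: tuple[float, float] = (10.0, 11.0)
    t_variant: str = "student"
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.modality not in _MODALITY_DEFAULTS:
            raise ValueError(f"modality must be EEG or MEG, got {self.modality!r}")
        if not (0 < self.bandpass[0] < self.bandpass[1]):
            raise ValueError(f"invalid bandpass {self.bandpass}")
        if self.t_variant not in ("student", "welch"):
            raise ValueError(f"invalid t_variant {self.t_variant!r}")
        if self.epoch_mode not in ("first", "min_variance"):
            raise ValueError(f"invalid epoch_mode {self.epoch_mode!r}")

    @classmethod
    def for_modality(cls, modality: str, **overrides) -> "RunConfig":
        base = dict(_MODALITY_DEFAULTS[modality], modality=modality)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("bandpass", "norm_band", "slow_band", "fast_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("bandpass", "norm_band", "slow_band", "fast_band"):
            d[key] = list(d[key])
        return d


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write one recording as TSV + JSON sidecar; returns the TSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame(rec.data.T, columns=list(rec.region_labels))
    df.insert(0, "time_s", t)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    sidecar = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "modality": rec.modality,
        "fs": rec.fs,
        "laterality": rec.laterality,
        "hemisphere": dict(zip(rec.region_labels, rec.hemisphere)),
        "info": {k: v for k, v in rec.info.items() if isinstance(v, (int, float, str))},
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return path


def read_recording(path: str | Path, format: str = "tabular") -> Recording:
    """Read a recording from TSV + sidecar (or EDF with an mne install)."""
    path = Path(path)
    if format == "edf":
        return _read_edf(path)
    if format != "tabular":
        raise ValueError(f"unknown format {format!r}")
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing JSON sidecar for {path}: expected {sidecar_path}"
        )
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] not in ("time_s", "sample"):
        raise ValueError(
            f"{path}: first column must be 'time_s' or 'sample', "
            f"got {df.columns[0]!r}"
        )
    region_labels = list(df.columns[1:])
    data = df.iloc[:, 1:].to_numpy(dtype=float).T
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-numeric or non-finite cells in data")
    fs = float(meta["fs"])
    if df.columns[0] == "time_s" and len(df) > 1:
        dt = float(np.median(np.diff(df["time_s"].to_numpy())))
        if abs(dt - 1.0 / fs) > 1e-3 / fs:
            raise ValueError(
                f"{path}: sample spacing {dt:.6g}s disagrees with sidecar "
                f"fs={fs} Hz by more than 0.1%"
            )
    hemi_map = meta["hemisphere"]
    missing = [lab for lab in region_labels if lab not in hemi_map]
    if missing:
        raise ValueError(f"{path}: sidecar hemisphere map missing regions {missing}")
    return Recording(
        subject_id=meta["subject_id"],
        group=meta["group"],
        modality=meta.get("modality", "EEG"),
        fs=fs,
        data=data,
        region_labels=region_labels,
        hemisphere=[hemi_map[lab] for lab in region_labels],
        info=meta.get("info", {}),
    )


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF ingestion requires the optional 'mne' package") from exc
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing JSON sidecar for {path}: expected {sidecar_path}"
        )
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    hemi_map = meta["hemisphere"]
    labels = [ch for ch in raw.ch_names if ch in hemi_map]
    if not labels:
        raise ValueError(f"{path}: no EDF channels match the sidecar region map")
    data = raw.get_data(picks=labels)
    return Recording(
        subject_id=meta["subject_id"],
        group=meta["group"],
        modality=meta.get("modality", "EEG"),
        fs=float(raw.info["sfreq"]),
        data=data,
        region_labels=labels,
        hemisphere=[hemi_map[lab] for lab in labels],
        info=meta.get("info", {}),
    )


def write_cohort(recordings, provenance: pd.DataFrame, out_dir: str | Path) -> Path:
    """Write every recording plus the provenance TSV to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(rec, out_dir / f"{rec.subject_id}.tsv")
    provenance.to_csv(out_dir / "provenance.tsv", sep="\t", index=False)
    return out_dir


def read_cohort(in_dir: str | Path) -> list[Recording]:
    in_dir = Path(in_dir)
    paths = sorted(p for p in in_dir.glob("*.tsv") if p.name != "provenance.tsv")
    if not paths:
        raise FileNotFoundError(f"no recording TSVs found in {in_dir}")
    return [read_recording(p) for p in paths]


def write_ratio_table(table: AlphaRatioTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    return path


def read_ratio_table(path: str | Path) -> AlphaRatioTable:
    df = pd.read_csv(Path(path), sep="\t", keep_default_na=False)
    subjects = (
        df[["subject_id", "group", "laterality"]]
        .drop_duplicates("subject_id")
        .reset_index(drop=True)
    )
    subjects["modality"] = ""
    subjects["laterality"] = subjects["laterality"].replace("", None)
    regions = (
        df[["region", "hemisphere"]]
        .drop_duplicates("region")
        .rename(columns={"region": "label"})
        .reset_index(drop=True)
    )
    values = (
        df.pivot(index="subject_id", columns="region", values="log_ratio")
        .loc[subjects["subject_id"], regions["label"]]
        .to_numpy()
    )
    return AlphaRatioTable(values=values, subjects=subjects, regions=regions)
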