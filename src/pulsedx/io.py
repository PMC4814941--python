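"""Plain-text I/O for pulse waveforms, cohort manifests and feature matrices.

All formats are UTF-8 CSV with '.' as the decimal separator:

* waveform file — header row of channel names (subset of the six radial
  palpation sites), one row per sample, amplitude in instrument units;
* manifest — columns ``subject_id,group,file`` (optional ``fs``);
* feature matrix — ``subject_id,group`` plus the 193 named parameters.

The sampling rate is carried out-of-band (manifest column or function
argument); the default is 200 Hz.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError

#: The six radial-artery palpation sites: zuo/you = left/right wrist,
#: cun/guan/chi = distal→proximal positions.
CHANNELS: tuple[str, ...] = (
    "zuocun", "zuoguan", "zuochi", "youcun", "youguan", "youchi",
)

GROUPS: tuple[str, ...] = ("healthy", "fld", "cirrhosis", "unknown")

DEFAULT_FS: float = 200.0

#: Per-channel time-domain parameter names (amplitudes relative to the cycle
#: onset; ratios are dimensionless; times in seconds).
TIME_PARAMS: tuple[str, ...] = (
    "h1", "t1", "h3_h1", "h4_h1", "h5_h1", "w", "t4", "t5",
)

N_HARMONICS = 12
N_FEATURES = 193  # 32 per channel x 6 channels + 1 global mean period


def feature_names() -> list[str]:
    """The fixed, ordered vocabulary of the 193 feature names.

    Per channel: C1..C12 (harmonic amplitudes), F1..F12 (harmonic phases,
    rad), then the eight time-domain parameters; one trailing global mean
    cycle period ``t``.
    """
    names: list[str] = []
    for ch in CHANNELS:
        names.extend(f"C{k}_{ch}" for k in range(1, N_HARMONICS + 1))
        names.extend(f"F{k}_{ch}" for k in range(1, N_HARMONICS + 1))
        names.extend(f"{p}_{ch}" for p in TIME_PARAMS)
    names.append("t")
    assert len(names) == N_FEATURES
    return names


@dataclasses.dataclass
class PulseRecording:
    """Multi-channel radial pulse recording for one subject."""

    subject_id: str
    group: str
    fs: float
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise FormatError(f"unknown group label {self.group!r}; expected one of {GROUPS}")
        if self.fs <= 2 * 48.0:
            raise FormatError(
                f"sampling rate {self.fs} Hz cannot represent the 0.5-48 Hz band (need fs > 96)"
            )
        for name, x in self.channels.items():
            if name not in CHANNELS:
                raise FormatError(f"unknown channel name {name!r}; expected one of {CHANNELS}")
            x = np.asarray(x, dtype=float)
            if x.ndim != 1 or x.size == 0:
                raise FormatError(f"channel {name!r} must be a non-empty 1-D array")
            self.channels[name] = x

    @property
    def duration_s(self) -> float:
        n = max(len(x) for x in self.channels.values())
        return n / self.fs

    @property
    def missing_channels(self) -> tuple[str, ...]:
        return tuple(c for c in CHANNELS if c not in self.channels)


@dataclasses.dataclass
class CohortManifest:
    """Subject roster: id, group label and waveform file per row."""

    table: pd.DataFrame  # columns: subject_id, group, file[, fs]

    def __post_init__(self) -> None:
        t = self.table
        for col in ("subject_id", "group", "file"):
            if col not in t.columns:
                raise FormatError(f"manifest missing required column {col!r}")
        if t["subject_id"].duplicated().any():
            dups = t.loc[t["subject_id"].duplicated(), "subject_id"].tolist()
            raise FormatError(f"duplicate subject_id(s) in manifest: {dups}")
        bad = sorted(set(t["group"]) - set(GROUPS))
        if bad:
            raise FormatError(f"unknown group label(s) in manifest: {bad}")

    def count(self, group: str) -> int:
        return int((self.table["group"] == group).sum())

    @property
    def counts(self) -> dict[str, int]:
        return {g: self.count(g) for g in ("healthy", "fld", "cirrhosis")}


def read_recording(path, fs: float = DEFAULT_FS, subject_id: str = "",
                   group: str = "unknown") -> PulseRecording:
    """Read a waveform CSV (header = channel names) into a PulseRecording.

    Channels absent from the file are permitted and reported via
    :attr:`PulseRecording.missing_channels`.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    bad = [c for c in df.columns if c not in CHANNELS]
    if bad:
        raise FormatError(f"{path.name}: unknown channel column(s) {bad}; expected {CHANNELS}")
    channels: dict[str, np.ndarray] = {}
    for col in df.columns:
        try:
            channels[col] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            bad_rows = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                                & df[col].notna()].tolist()
            raise ParseError(
                f"{path.name}: non-numeric value in column {col!r}, row(s) {bad_rows[:5]}"
            ) from exc
    if not channels:
        raise FormatError(f"{path.name}: no channel columns found")
    return PulseRecording(subject_id=subject_id or path.stem, group=group,
                          fs=fs, channels=channels)


def write_recording(rec: PulseRecording, path) -> None:
    """Write a PulseRecording as a CSV with channel-name header."""
    for name, x in rec.channels.items():
        if len(x) == 0:
            raise FormatError(f"refusing to write zero-length channel {name!r}")
    # preserve canonical channel order for channels present
    cols = [c for c in CHANNELS if c in rec.channels]
    pd.DataFrame({c: rec.channels[c] for c in cols}).to_csv(
        path, index=False, float_format="%.17g")


def read_manifest(path) -> CohortManifest:
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str, "file": str})
    return CohortManifest(table=df)


def write_manifest(manifest: CohortManifest, path) -> None:
    manifest.table.to_csv(path, index=False)


def write_feature_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a per-subject feature matrix (193 named columns + subject_id, group)."""
    names = feature_names()
    missing = [n for n in names if n not in matrix.columns]
    if missing:
        raise FormatError(
            f"feature matrix has {len(names) - len(missing)} of {N_FEATURES} "
            f"expected feature columns; missing e.g. {missing[:3]}"
        )
    cols = ["subject_id", "group"] + names
    out = matrix.reset_index() if "subject_id" not in matrix.columns else matrix
    out[cols].to_csv(path, index=False, float_format="%.17g")


def read_feature_matrix(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str},
                     float_precision="round_trip")
    feat_cols = [c for c in df.columns if c not in ("subject_id", "group")]
    if len(feat_cols) != N_FEATURES:
        raise FormatError(
            f"{path.name}: expected {N_FEATURES} feature columns, found {len(feat_cols)}"
        )
    names = feature_names()
    if set(feat_cols) != set(names):
        unexpected = sorted(set(feat_cols) - set(names))[:3]
        raise FormatError(f"{path.name}: unexpected feature column(s) e.g. {unexpected}")
    return df[["subject_id", "group"] + names]
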