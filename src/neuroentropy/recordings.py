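"""Containers and I/O for multichannel resting-state EEG recordings.

Recordings are plain channels × samples matrices (µV) with 10–20 system
channel labels.  Two on-disk formats are supported: EDF (read via :mod:`mne`,
when installed) and a CSV matrix with one column per channel and a header row
of labels — the format the synthetic cohort writer produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecording",
    "LobeSignal",
    "DEFAULT_MONTAGE",
    "MONTAGE_CHANNELS",
    "validate_montage",
    "read_recording",
    "write_recording_csv",
]

#: Electrode → lobe grouping used throughout the analysis.  T3/T4 are accepted
#: as synonyms of T7/T8 on read and canonicalised.
DEFAULT_MONTAGE: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2"),
    "parietal": ("Pz", "P3", "P4", "P7", "P8"),
    "occipital": ("Oz", "O1", "O2"),
    "temporal": ("T7", "T8"),
}

MONTAGE_CHANNELS: tuple[str, ...] = tuple(
    ch for chans in DEFAULT_MONTAGE.values() for ch in chans
)

# Older 10–20 labels mapped onto their modern equivalents.
_LABEL_SYNONYMS = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

# Canonical capitalisation for 10–20 labels, keyed by upper-case form.
_CANONICAL = {c.upper(): c for c in (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz", "C3", "C4", "Cz",
    "P3", "P4", "P7", "P8", "Pz", "O1", "O2", "Oz", "T7", "T8",
)}


def canonical_label(label: str) -> str:
    """Normalise an electrode label to canonical 10–20 case, mapping
    deprecated temporal names (T3→T7 etc.)."""
    up = label.strip().upper()
    up = _LABEL_SYNONYMS.get(up, up)
    up = _CANONICAL.get(up, up)
    return _LABEL_SYNONYMS.get(up, up) if up in _LABEL_SYNONYMS else up


@dataclass
class EEGRecording:
    """A labelled multichannel time series.

    Parameters
    ----------
    channel_labels : sequence of str
        10–20 electrode names, unique, one per row of ``data``.
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    subject_id : str
        Identifier used to join recordings with metadata.
    """

    channel_labels: list[str]
    data: np.ndarray
    fs: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = [canonical_label(c) for c in self.channel_labels]
        if self.data.ndim != 2:
            raise ValueError("data must be a channels × samples matrix")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        idx = self.channel_labels.index(canonical_label(label))
        return self.data[idx]


@dataclass
class LobeSignal:
    """One lobe-averaged time series for one subject."""

    subject_id: str
    lobe: str
    series: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float).ravel()
        if not np.all(np.isfinite(self.series)):
            raise ValueError("lobe signal contains non-finite values")


def validate_montage(montage: Mapping[str, Sequence[str]]) -> None:
    """Check that no electrode is assigned to two lobes."""
    seen: dict[str, str] = {}
    for lobe, chans in montage.items():
        for ch in chans:
            ch = canonical_label(ch)
            if ch in seen:
                raise ValueError(f"electrode {ch} mapped to both {seen[ch]} and {lobe}")
            seen[ch] = lobe


def _require_channels(labels: Sequence[str], required: Sequence[str]) -> None:
    have = {canonical_label(c) for c in labels}
    missing = [c for c in required if canonical_label(c) not in have]
    if missing:
        raise ValueError(f"recording is missing montage channels: {', '.join(missing)}")


def read_recording(
    path: str | Path,
    format: str | None = None,
    subject_id: str | None = None,
    required_channels: Sequence[str] | None = MONTAGE_CHANNELS,
) -> EEGRecording:
    """Read an EEG recording from disk.

    Parameters
    ----------
    path : path
        EDF file or CSV matrix (header row of channel labels, one column per
        channel; sampling rate in a ``# fs=<Hz>`` comment on the first line).
    format : {"edf", "csv"}, optional
        Inferred from the file suffix when omitted.
    required_channels : sequence of str or None
        Channels that must be present (default: the 12 lobe-mapped
        electrodes); pass ``None`` to skip the check.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        rec = _read_edf(path)
    elif format == "csv":
        rec = _read_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if subject_id is not None:
        rec.subject_id = subject_id
    elif not rec.subject_id:
        rec.subject_id = path.stem
    if required_channels is not None:
        _require_channels(rec.channel_labels, required_channels)
    return rec


def _read_edf(path: Path) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne present in target env
        raise ImportError("reading EDF requires the mne package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne uses volts internally
    return EEGRecording(list(raw.ch_names), data, float(raw.info["sfreq"]))


def _read_csv(path: Path) -> EEGRecording:
    with open(path) as fh:
        first = fh.readline().strip()
    fs = None
    skip = 0
    if first.startswith("#"):
        skip = 1
        for tok in first.lstrip("#").replace(",", " ").split():
            if tok.startswith("fs="):
                fs = float(tok[3:])
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=<Hz>' header line")
    df = pd.read_csv(path, skiprows=skip)
    return EEGRecording(list(df.columns), df.to_numpy().T, fs)


def write_recording_csv(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as a CSV matrix (columns = channels) with the
    sampling rate in a leading ``# fs=`` comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        pd.DataFrame(rec.data.T, columns=rec.channel_labels).to_csv(fh, index=False)
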