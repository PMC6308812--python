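"""Domain types and file I/O for single-channel EEG recordings.

A recording is one continuous voltage trace from a prefrontal (Fp1-A1)
single-channel EEG, typically 60 s at 512 Hz, paired with the subject's
Karolinska Sleepiness Scale (KSS) response for that session.  Signals
travel as plain delimited text (one sample per row); recording metadata
and KSS scores live in a separate tab-separated manifest; metric reports
round-trip through JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import ConfusionCounts, MetricsReport

SESSIONS = ("morning", "daytime", "night", "task")

MANIFEST_COLUMNS = ["recording_id", "subject_id", "session", "kss"]


class RecordingParseError(ValueError):
    """Raised when a signal file contains a row that is not numeric."""


@dataclass
class EEGRecording:
    """One single-channel EEG voltage trace with its metadata.

    Parameters
    ----------
    samples : array-like of float
        Voltage samples in the device's (arbitrary linear) microvolt units.
    fs : float
        Sampling rate in Hz.  The portable device records at 512 Hz.
    subject_id, recording_id : str
        Provenance identifiers.
    session : str
        One of ``morning``, ``daytime``, ``night``, ``task``.
    kss : int or None
        Karolinska Sleepiness Scale response (1 = very alert, 9 = very
        sleepy) collected immediately after the recording; None when the
        recording is unlabeled (e.g. task-mode inference).
    """

    samples: np.ndarray
    fs: float = 512.0
    subject_id: str = ""
    recording_id: str = ""
    session: str = "daytime"
    kss: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}, got {self.session!r}")
        if self.kss is not None:
            kss = int(self.kss)
            if not 1 <= kss <= 9:
                raise ValueError(f"KSS must be an integer in 1..9, got {self.kss}")
            self.kss = kss
        if self.samples.size == 0:
            raise ValueError("recording must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def duration(self) -> float:
        """Length of the trace in seconds (= n_samples / fs, exactly)."""
        return self.samples.size / self.fs

    @property
    def n_samples(self) -> int:
        return self.samples.size


def read_recording(
    path: str | Path,
    fs: float = 512.0,
    channel: str | None = None,
    **metadata,
) -> EEGRecording:
    """Read a recording from delimited text (one sample per row) or EDF.

    Text files may have an optional single header line and use comma or
    whitespace delimiters.  EDF files (suffix ``.edf``) must be single
    channel unless ``channel`` names the one to extract.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path, channel=channel, **metadata)

    samples: list[float] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines and not _is_numeric_row(lines[0]):
        start = 1  # header line
    for i, line in enumerate(lines[start:], start=start + 1):
        line = line.strip()
        if not line:
            continue
        fields = line.replace(",", " ").split()
        try:
            samples.append(float(fields[0]))
        except ValueError as exc:
            raise RecordingParseError(
                f"{path}: row {i} is not numeric: {line!r}"
            ) from exc
    if not samples:
        raise RecordingParseError(f"{path}: file contains no samples")
    metadata.setdefault("recording_id", path.stem)
    return EEGRecording(np.asarray(samples), fs=fs, **metadata)


def _is_numeric_row(line: str) -> bool:
    fields = line.strip().replace(",", " ").split()
    if not fields:
        return False
    try:
        float(fields[0])
    except ValueError:
        return False
    return True


def _read_edf(path: Path, channel: str | None, **metadata) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - env without the extra
        raise ImportError(
            "EDF support requires the 'mne' package (pip install drowsyeeg[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = raw.ch_names
    if channel is None:
        if len(names) != 1:
            raise ValueError(
                f"{path}: EDF has {len(names)} channels {names}; "
                "pass channel=<name> to select one"
            )
        channel = names[0]
    data = raw.get_data(picks=[channel])[0] * 1e6  # volts -> microvolts
    metadata.setdefault("recording_id", path.stem)
    return EEGRecording(data, fs=float(raw.info["sfreq"]), **metadata)


def write_recording(rec: EEGRecording, path: str | Path) -> None:
    """Write samples one per line with full float precision (lossless)."""
    np.savetxt(path, rec.samples, fmt="%.17g")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the recording manifest (TSV: recording_id, subject_id, session, kss)."""
    df = pd.read_csv(path, sep="\t", dtype={"recording_id": str, "subject_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    return df


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def write_metrics(report: MetricsReport, path: str | Path) -> None:
    """Serialize a metrics report (counts + the five derived metrics) to JSON.

    Undefined metrics (zero denominators) are written as JSON null, never 0.
    """
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_metrics(path: str | Path) -> MetricsReport:
    with open(path) as fh:
        payload = json.load(fh)
    return MetricsReport.from_dict(payload)
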