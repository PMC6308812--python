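"""Windowing of recordings, KSS-threshold labeling, and feature-table assembly.

Recordings are cut into fixed-length windows (10 s with a 10 s shift by
default, so a 60 s recording yields six windows) and each window inherits
the recording's KSS rating and metadata.  KSS ratings map to binary
alert/drowsy labels through one strict threshold (alert < A < drowsy,
KSS = A excluded) or two (alert < A, drowsy > B, A <= KSS <= B excluded).

A *feature table* is a pandas DataFrame with the metadata columns
``recording_id, subject_id, session, window_index, kss, label`` followed
by one column per feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EEGRecording

ALERT, DROWSY, EXCLUDED = "alert", "drowsy", "excluded"

META_COLUMNS = ["recording_id", "subject_id", "session", "window_index", "kss", "label"]


@dataclass(frozen=True)
class LabelingScheme:
    """Strict-inequality KSS thresholding into alert/drowsy/excluded.

    ``single`` mode uses one threshold A (KSS = A excluded); ``dual`` uses
    A < B with the whole closed middle band excluded.  The development
    study's primary scheme is dual thresholds (3, 7): alert = KSS 1-2,
    drowsy = KSS 8-9.
    """

    mode: str
    thresholds: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.mode not in ("single", "dual"):
            raise ValueError("mode must be 'single' or 'dual'")
        t = tuple(int(v) for v in self.thresholds)
        object.__setattr__(self, "thresholds", t)
        expected = 1 if self.mode == "single" else 2
        if len(t) != expected:
            raise ValueError(f"{self.mode} mode needs {expected} threshold(s), got {t}")
        if any(not 1 <= v <= 9 for v in t):
            raise ValueError(f"thresholds must be KSS values 1..9, got {t}")
        if self.mode == "dual" and not t[0] < t[1]:
            raise ValueError(f"dual thresholds require A < B, got {t}")

    @classmethod
    def single(cls, a: int) -> "LabelingScheme":
        return cls("single", (a,))

    @classmethod
    def dual(cls, a: int, b: int) -> "LabelingScheme":
        return cls("dual", (a, b))


def label_from_kss(kss: int, scheme: LabelingScheme) -> str:
    """Map one KSS rating to 'alert' / 'drowsy' / 'excluded'."""
    kss = int(kss)
    if not 1 <= kss <= 9:
        raise ValueError(f"KSS must be in 1..9, got {kss}")
    if scheme.mode == "single":
        a = scheme.thresholds[0]
        if kss < a:
            return ALERT
        if kss > a:
            return DROWSY
        return EXCLUDED
    a, b = scheme.thresholds
    if kss < a:
        return ALERT
    if kss > b:
        return DROWSY
    return EXCLUDED


def window_count(duration: float, window_s: float, shift_s: float) -> int:
    return int((duration - window_s) // shift_s) + 1


def window_segment(
    rec: EEGRecording, window_s: float = 10.0, shift_s: float = 10.0
) -> list[EEGRecording]:
    """Cut a recording into windows; each inherits KSS and metadata.

    The number of windows is floor((duration - window) / shift) + 1; with
    shift = window the windows tile the recording without overlap.
    """
    if shift_s <= 0:
        raise ValueError("shift must be positive")
    if window_s > rec.duration:
        raise ValueError(
            f"window of {window_s}s exceeds recording duration {rec.duration}s"
        )
    w = int(round(window_s * rec.fs))
    s = int(round(shift_s * rec.fs))
    segments = []
    for k in range(window_count(rec.duration, window_s, shift_s)):
        start = k * s
        segments.append(
            EEGRecording(
                rec.samples[start : start + w],
                fs=rec.fs,
                subject_id=rec.subject_id,
                recording_id=rec.recording_id,
                session=rec.session,
                kss=rec.kss,
            )
        )
    return segments


def build_feature_table(
    recordings: list[EEGRecording],
    extractor,
    scheme: LabelingScheme | None = None,
    window_s: float = 10.0,
    shift_s: float = 10.0,
) -> pd.DataFrame:
    """Window recordings, extract features, and attach labels.

    ``extractor`` is any fitted-or-stateless transformer with
    ``transform`` over (n_windows, n_samples) and
    ``get_feature_names_out``.  Windows from recordings without a KSS
    rating get label ``excluded`` unless no scheme is given, in which
    case the label column is left empty.
    """
    rows = []
    matrices = []
    for rec in recordings:
        segments = window_segment(rec, window_s, shift_s)
        matrices.append(np.vstack([s.samples for s in segments]))
        for k, seg in enumerate(segments):
            if scheme is None or rec.kss is None:
                label = ""
            else:
                label = label_from_kss(rec.kss, scheme)
            rows.append(
                {
                    "recording_id": rec.recording_id,
                    "subject_id": rec.subject_id,
                    "session": rec.session,
                    "window_index": k,
                    "kss": rec.kss,
                    "label": label,
                }
            )
    X = extractor.fit_transform(np.vstack(matrices))
    names = list(extractor.get_feature_names_out())
    meta = pd.DataFrame(rows)
    feats = pd.DataFrame(X, columns=names)
    table = pd.concat([meta.reset_index(drop=True), feats.reset_index(drop=True)], axis=1)
    if table[names].isna().any().any():
        bad = table[names].columns[table[names].isna().any()].tolist()
        raise ValueError(f"feature extraction produced missing values in {bad}")
    return table


def feature_names(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    return table[feature_names(table)].to_numpy(dtype=float)


def binary_labels(table: pd.DataFrame) -> np.ndarray:
    """0/1 labels (1 = drowsy) for the non-excluded rows; raises if any
    row is excluded — filter with :func:`labeled_subset` first."""
    labels = table["label"].to_numpy()
    if not np.all(np.isin(labels, [ALERT, DROWSY])):
        raise ValueError("table contains excluded/unlabeled rows; use labeled_subset")
    return (labels == DROWSY).astype(int)


def labeled_subset(table: pd.DataFrame) -> pd.DataFrame:
    """Rows labeled alert or drowsy (exclusions dropped)."""
    return table[table["label"].isin([ALERT, DROWSY])].reset_index(drop=True)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"recording_id": str, "subject_id": str})
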