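"""Session data model, CSV readers/writers and epoch segmentation.

A recording session is a single bipolar EEG channel (µV) plus three
gyroscope axes sampled synchronously at 128 Hz, with one drowsiness label
per minute from video-based scoring.  Labels use the integer codes

* ``-1`` — alert,
* ``+1`` — slightly drowsy,
* ``0``  — excluded (mid/late-stage drowsiness; kept for bookkeeping but
  dropped from binary analysis).

On disk a session is two CSV files: a sample table with header
``time_s,eeg_uv,gyro_x,gyro_y,gyro_z`` and a label table with header
``minute_index,label`` whose label tokens are ``alert``, ``slight`` and
``mid_late``.  The time column is advisory; sample index / sample-rate is
authoritative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALERT = -1
DROWSY = 1
EXCLUDED = 0

#: CSV label tokens <-> integer codes
LABEL_CODES = {"alert": ALERT, "slight": DROWSY, "mid_late": EXCLUDED}
LABEL_TOKENS = {v: k for k, v in LABEL_CODES.items()}

SESSION_COLUMNS = ["time_s", "eeg_uv", "gyro_x", "gyro_y", "gyro_z"]
FEATURE_COLUMNS = [
    "subject",
    "window_index",
    "rbp_theta",
    "rbp_alpha",
    "rbp_beta",
    "mp",
    "label",
]


class FormatError(ValueError):
    """Raised when an input file or in-memory session violates the format contract."""


@dataclass
class RawSession:
    """One subject's synchronized EEG + gyroscope recording with minute labels.

    Invariants (checked on construction): the EEG series and all three gyro
    axes have equal length, the length is an integer multiple of the sample
    rate, and there is exactly one label per whole minute of signal.
    """

    subject_id: str
    eeg: np.ndarray
    gyro: np.ndarray  # shape (3, n_samples): x, y, z
    minute_labels: np.ndarray  # int codes in {-1, +1, 0}
    sample_rate: float = 128.0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.minute_labels = np.asarray(self.minute_labels, dtype=int)
        if self.gyro.ndim != 2 or self.gyro.shape[0] != 3:
            raise FormatError(f"gyro must have shape (3, n), got {self.gyro.shape}")
        n = self.eeg.shape[0]
        if self.gyro.shape[1] != n:
            raise FormatError(
                f"channel length mismatch: eeg has {n} samples, "
                f"gyro has {self.gyro.shape[1]}"
            )
        if n % int(self.sample_rate) != 0:
            raise FormatError(
                f"signal length {n} is not a multiple of the sample rate "
                f"{self.sample_rate}"
            )
        n_minutes = int(self.duration_s // 60)
        if self.minute_labels.shape[0] != n_minutes:
            raise FormatError(
                f"expected {n_minutes} minute labels for a {self.duration_s:.0f}-s "
                f"session, got {self.minute_labels.shape[0]}"
            )
        bad = set(np.unique(self.minute_labels)) - {ALERT, DROWSY, EXCLUDED}
        if bad:
            raise FormatError(f"unknown label codes {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return int(self.eeg.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class Epoch:
    """A contiguous 2-s analysis segment: 256 EEG samples + 3x256 gyro samples."""

    index: int
    eeg: np.ndarray
    gyro: np.ndarray  # (3, 256)

    def __post_init__(self) -> None:
        if self.gyro.shape[0] != 3 or self.gyro.shape[1] != self.eeg.shape[0]:
            raise FormatError("epoch channels must share one length across 3 gyro axes")


def epoch_length(sample_rate: float = 128.0, epoch_s: float = 2.0) -> int:
    return int(round(sample_rate * epoch_s))


def segment_epochs(session: RawSession, eeg: np.ndarray | None = None) -> list[Epoch]:
    """Cut a session into contiguous, non-overlapping 2-s epochs.

    Epochs are aligned to sample 0; a trailing remainder shorter than one
    epoch is dropped (and logged).  ``eeg`` substitutes a processed (e.g.
    band-pass filtered) EEG series of the same length for the raw one.

    A session shorter than one epoch yields an empty list, not an error.
    """
    x = session.eeg if eeg is None else np.asarray(eeg, dtype=float)
    if x.shape[0] != session.n_samples:
        raise FormatError("substitute eeg series must match session length")
    m = epoch_length(session.sample_rate)
    n_epochs = x.shape[0] // m
    dropped = x.shape[0] - n_epochs * m
    if dropped:
        logger.info("dropping trailing %d samples (< one epoch)", dropped)
    return [
        Epoch(index=i, eeg=x[i * m : (i + 1) * m], gyro=session.gyro[:, i * m : (i + 1) * m])
        for i in range(n_epochs)
    ]


def read_session(
    session_path: str | Path,
    label_path: str | Path,
    subject_id: str | None = None,
    sample_rate: float = 128.0,
) -> RawSession:
    """Read a session sample CSV and its companion minute-label CSV."""
    session_path = Path(session_path)
    df = pd.read_csv(session_path)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{session_path}: missing columns {missing}")
    labels_df = pd.read_csv(label_path)
    if not {"minute_index", "label"}.issubset(labels_df.columns):
        raise FormatError(f"{label_path}: expected header minute_index,label")
    labels_df = labels_df.sort_values("minute_index")
    tokens = labels_df["label"].astype(str).str.strip()
    unknown = sorted(set(tokens) - set(LABEL_CODES))
    if unknown:
        raise FormatError(f"{label_path}: unknown label tokens {unknown}")
    codes = tokens.map(LABEL_CODES).to_numpy()
    if subject_id is None:
        subject_id = session_path.stem
    return RawSession(
        subject_id=subject_id,
        eeg=df["eeg_uv"].to_numpy(dtype=float),
        gyro=df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(dtype=float).T,
        minute_labels=codes,
        sample_rate=sample_rate,
    )


def write_session(
    session: RawSession, session_path: str | Path, label_path: str | Path
) -> None:
    """Write a session back to the two-CSV on-disk form (inverse of read_session)."""
    t = np.arange(session.n_samples) / session.sample_rate
    df = pd.DataFrame(
        {
            "time_s": t,
            "eeg_uv": session.eeg,
            "gyro_x": session.gyro[0],
            "gyro_y": session.gyro[1],
            "gyro_z": session.gyro[2],
        }
    )
    df.to_csv(session_path, index=False, float_format="%.10g")
    labels = pd.DataFrame(
        {
            "minute_index": np.arange(session.minute_labels.shape[0]),
            "label": [LABEL_TOKENS[c] for c in session.minute_labels],
        }
    )
    labels.to_csv(label_path, index=False)


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    """Write a per-window feature table (schema FEATURE_COLUMNS) to CSV."""
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise FormatError(f"feature table missing columns {missing}")
    features[FEATURE_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: feature table missing columns {missing}")
    return df
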