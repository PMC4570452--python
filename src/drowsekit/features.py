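"""Per-epoch EEG/gyro feature extraction and 1-minute window averaging.

Per 2-s epoch (256 samples at 128 Hz):

* band power — sum of squared one-sided DFT magnitudes over the bins of a
  frequency band (rectangular window, 0.5 Hz bin width, no energy
  correction: the relative measure below is invariant to the scaling);
* RBP — relative band power, one band's power over the summed power of
  theta + alpha + beta, as a percentage (so the three components sum to
  100 by construction);
* MP — movement power, the population standard deviation within the epoch
  of the per-sample mean of the three gyroscope axes.

Thirty consecutive epoch feature sets are averaged into one 1-minute
window to align with the per-minute video-scored ground truth.

The bands partition 4-30 Hz over the 0.5 Hz bin grid as theta [4, 8),
alpha [8, 13), beta [13, 30]: half-open on the left two so no bin is
double-counted and no bin in 4-30 Hz is skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EXCLUDED, FEATURE_COLUMNS, RawSession, epoch_length

RBP_COLUMNS = ["rbp_theta", "rbp_alpha", "rbp_beta"]

#: total power below this is a degenerate (effectively all-zero) epoch
DEGENERATE_POWER = 1e-12


class DegenerateEpochError(ValueError):
    """Raised when RBP is requested for an epoch with no in-band power."""


class AlignmentError(ValueError):
    """Raised when epoch features cannot be aligned with the minute labels."""


@dataclass(frozen=True)
class BandDefinition:
    """Half-open theta/alpha plus closed beta partition of 4-30 Hz (Hz)."""

    theta: tuple[float, float] = (4.0, 8.0)
    alpha: tuple[float, float] = (8.0, 13.0)
    beta: tuple[float, float] = (13.0, 30.0)

    @property
    def names(self) -> tuple[str, str, str]:
        return ("theta", "alpha", "beta")

    def intervals(self) -> list[tuple[float, float, bool]]:
        """(low, high, include_upper) per band; only beta includes its upper edge."""
        return [(*self.theta, False), (*self.alpha, False), (*self.beta, True)]

    def masks(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean (3, n_bins) mask of one-sided FFT bins per band."""
        out = np.empty((3, freqs.shape[0]), dtype=bool)
        for i, (lo, hi, inc) in enumerate(self.intervals()):
            out[i] = (freqs >= lo) & ((freqs <= hi) if inc else (freqs < hi))
        return out


def band_power(
    eeg_epoch: np.ndarray,
    band: tuple[float, float],
    fs: float = 128.0,
    include_upper: bool = False,
) -> float:
    """Sum of squared one-sided DFT magnitudes over the bins inside ``band``.

    The epoch must be exactly 2 s (fs * 2 samples) so bins fall on a 0.5 Hz
    grid.  The band interval is half-open [low, high) unless
    ``include_upper``.
    """
    x = np.asarray(eeg_epoch, dtype=float)
    m = epoch_length(fs)
    if x.shape[-1] != m:
        raise ValueError(f"epoch must have {m} samples, got {x.shape[-1]}")
    lo, hi = band
    if not (0.0 <= lo < hi <= fs / 2.0):
        raise ValueError(f"band {band} outside [0, {fs / 2}] Hz")
    freqs = np.fft.rfftfreq(m, d=1.0 / fs)
    mask = (freqs >= lo) & ((freqs <= hi) if include_upper else (freqs < hi))
    spectrum = np.fft.rfft(x)
    return float(np.sum(np.abs(spectrum[..., mask]) ** 2))


def band_powers(
    eeg_epochs: np.ndarray, bands: BandDefinition | None = None, fs: float = 128.0
) -> np.ndarray:
    """Vectorized three-band powers for a stack of epochs, shape (n, 3)."""
    bands = bands or BandDefinition()
    x = np.atleast_2d(np.asarray(eeg_epochs, dtype=float))
    m = epoch_length(fs)
    if x.shape[1] != m:
        raise ValueError(f"epochs must have {m} samples, got {x.shape[1]}")
    freqs = np.fft.rfftfreq(m, d=1.0 / fs)
    power = np.abs(np.fft.rfft(x, axis=1)) ** 2
    masks = bands.masks(freqs)
    return np.stack([power[:, mk].sum(axis=1) for mk in masks], axis=1)


def relative_band_power(
    eeg_epoch: np.ndarray, bands: BandDefinition | None = None, fs: float = 128.0
) -> np.ndarray:
    """RBP triple (theta%, alpha%, beta%) for one epoch; sums to 100.

    Raises DegenerateEpochError when the three-band total power is zero
    (the caller should flag the epoch and leave it out of its window mean).
    """
    p = band_powers(np.asarray(eeg_epoch)[None, :], bands, fs)[0]
    total = p.sum()
    if total <= DEGENERATE_POWER:
        raise DegenerateEpochError("epoch has no power in the 4-30 Hz bands")
    return 100.0 * p / total


def movement_power(gyro_epoch: np.ndarray) -> float:
    """MP: population std, within the epoch, of the three-axis mean signal."""
    g = np.asarray(gyro_epoch, dtype=float)
    if g.ndim != 2 or g.shape[0] != 3:
        raise ValueError(f"gyro epoch must have shape (3, n), got {g.shape}")
    return float(np.std(g.mean(axis=0)))


def extract_epoch_features(
    eeg: np.ndarray,
    gyro: np.ndarray,
    bands: BandDefinition | None = None,
    fs: float = 128.0,
) -> pd.DataFrame:
    """Per-epoch feature table for pre-filtered EEG + raw gyro of equal length.

    Columns: epoch_index, rbp_theta/alpha/beta, mp, degenerate.  Degenerate
    epochs (no in-band EEG power) carry NaN RBPs and a True flag.  The
    trailing remainder shorter than one epoch is dropped.
    """
    bands = bands or BandDefinition()
    eeg = np.asarray(eeg, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    m = epoch_length(fs)
    n_epochs = eeg.shape[0] // m
    ee = eeg[: n_epochs * m].reshape(n_epochs, m)
    gg = gyro[:, : n_epochs * m].reshape(3, n_epochs, m)

    p = band_powers(ee, bands, fs)
    total = p.sum(axis=1)
    degenerate = total <= DEGENERATE_POWER
    rbp = np.full((n_epochs, 3), np.nan)
    ok = ~degenerate
    rbp[ok] = 100.0 * p[ok] / total[ok, None]
    mp = np.std(gg.mean(axis=0), axis=1)

    return pd.DataFrame(
        {
            "epoch_index": np.arange(n_epochs),
            "rbp_theta": rbp[:, 0],
            "rbp_alpha": rbp[:, 1],
            "rbp_beta": rbp[:, 2],
            "mp": mp,
            "degenerate": degenerate,
        }
    )


def average_windows(
    epoch_features: pd.DataFrame,
    minute_labels: np.ndarray,
    subject_id: str,
    epochs_per_window: int = 30,
) -> pd.DataFrame:
    """Average consecutive disjoint blocks of epoch features into labeled windows.

    Window ``i`` receives ``minute_labels[i]``.  Degenerate epochs are left
    out of their window's mean; a window with more than half of its epochs
    degenerate is marked excluded (label 0, degenerate flag set).  Windows
    labeled excluded are emitted, flagged, and expected to be filtered out
    by downstream classification.
    """
    if len(epoch_features) < epochs_per_window:
        raise AlignmentError(
            f"need at least {epochs_per_window} epoch features, got {len(epoch_features)}"
        )
    n_windows = len(epoch_features) // epochs_per_window
    minute_labels = np.asarray(minute_labels, dtype=int)
    if minute_labels.shape[0] < n_windows:
        raise AlignmentError(
            f"{n_windows} windows but only {minute_labels.shape[0]} minute labels"
        )
    rows = []
    feat = epoch_features[RBP_COLUMNS + ["mp"]].to_numpy(dtype=float)
    degen = epoch_features["degenerate"].to_numpy(dtype=bool)
    for i in range(n_windows):
        sl = slice(i * epochs_per_window, (i + 1) * epochs_per_window)
        block, bad = feat[sl], degen[sl]
        n_bad = int(bad.sum())
        window_degenerate = n_bad * 2 > epochs_per_window
        if n_bad == epochs_per_window:
            mean = np.full(4, np.nan)
        else:
            mean = block[~bad].mean(axis=0)
        rows.append(
            {
                "subject": subject_id,
                "window_index": i,
                "rbp_theta": mean[0],
                "rbp_alpha": mean[1],
                "rbp_beta": mean[2],
                "mp": mean[3],
                "label": EXCLUDED if window_degenerate else int(minute_labels[i]),
                "degenerate": window_degenerate,
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS + ["degenerate"])


def session_features(
    session: RawSession,
    filtered_eeg: np.ndarray,
    bands: BandDefinition | None = None,
    epochs_per_window: int = 30,
) -> pd.DataFrame:
    """Window feature table for one session given its conditioned EEG."""
    ef = extract_epoch_features(filtered_eeg, session.gyro, bands, session.sample_rate)
    return average_windows(ef, session.minute_labels, session.subject_id, epochs_per_window)
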