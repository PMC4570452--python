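"""Causal digital filtering of the EEG channel.

The analysis chain mirrors the analog front end it emulates: a 2nd-order
Butterworth high-pass at 4 Hz cascaded with a 4th-order Butterworth
low-pass at 30 Hz, digitized and applied causally (forward-only), as a
streaming on-chip implementation would run.  A 60 Hz notch is available for
indoor recordings where power-line interference is present; it is off by
default because a car has no mains supply.

Gyroscope channels are never filtered here — the movement sensor
conditions its own output internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


class ConfigurationError(ValueError):
    """Raised when a filter specification is inconsistent with the sample rate."""


@dataclass
class FilterSpec:
    """Band-pass + optional notch design parameters.

    low_cut/high_cut bound the 4-30 Hz pass band that carries the theta,
    alpha and beta rhythms; hp_order/lp_order are the Butterworth section
    orders of the high-pass and low-pass stages.
    """

    low_cut: float = 4.0
    high_cut: float = 30.0
    hp_order: int = 2
    lp_order: int = 4
    notch_freq: float = 60.0
    notch_q: float = 30.0
    notch_enabled: bool = False

    def validate(self, fs: float) -> None:
        if not (0.0 < self.low_cut < self.high_cut < fs / 2.0):
            raise ConfigurationError(
                f"need 0 < low_cut < high_cut < fs/2, got "
                f"({self.low_cut}, {self.high_cut}) at fs={fs}"
            )
        if self.hp_order < 1 or self.lp_order < 1:
            raise ConfigurationError("filter orders must be >= 1")
        if self.notch_enabled and not (0.0 < self.notch_freq < fs / 2.0):
            raise ConfigurationError(f"notch frequency {self.notch_freq} outside (0, fs/2)")


def _bandpass_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    spec.validate(fs)
    hp = signal.butter(spec.hp_order, spec.low_cut, btype="highpass", fs=fs, output="sos")
    lp = signal.butter(spec.lp_order, spec.high_cut, btype="lowpass", fs=fs, output="sos")
    return np.vstack([hp, lp])


def bandpass(x: np.ndarray, spec: FilterSpec | None = None, fs: float = 128.0) -> np.ndarray:
    """Apply the causal 4-30 Hz band-pass chain (zero initial state)."""
    spec = spec or FilterSpec()
    x = np.asarray(x, dtype=float)
    return signal.sosfilt(_bandpass_sos(spec, fs), x)


def notch60(x: np.ndarray, spec: FilterSpec | None = None, fs: float = 128.0) -> np.ndarray:
    """Apply the causal power-line notch (>= 30 dB at the notch frequency)."""
    spec = spec or FilterSpec(notch_enabled=True)
    spec.validate(fs)
    b, a = signal.iirnotch(spec.notch_freq, spec.notch_q, fs=fs)
    return signal.lfilter(b, a, np.asarray(x, dtype=float))


def preprocess(x: np.ndarray, spec: FilterSpec | None = None, fs: float = 128.0) -> np.ndarray:
    """Full EEG conditioning: band-pass, then notch if enabled."""
    spec = spec or FilterSpec()
    y = bandpass(x, spec, fs)
    if spec.notch_enabled:
        y = notch60(y, spec, fs)
    return y


def frequency_response(
    spec: FilterSpec, fs: float, freqs: np.ndarray, include_notch: bool | None = None
) -> np.ndarray:
    """Complex transfer function of the designed chain at the given frequencies (Hz).

    ``include_notch=None`` follows ``spec.notch_enabled``.  Used for
    analytic calibration and as one leg of the dual-route frequency-response
    checks (the other leg measures steady-state sinusoid gain in the time
    domain).
    """
    freqs = np.asarray(freqs, dtype=float)
    _, h = signal.sosfreqz(_bandpass_sos(spec, fs), worN=2 * np.pi * freqs / fs)
    if include_notch is None:
        include_notch = spec.notch_enabled
    if include_notch:
        b, a = signal.iirnotch(spec.notch_freq, spec.notch_q, fs=fs)
        _, hn = signal.freqz(b, a, worN=2 * np.pi * freqs / fs)
        h = h * hn
    return h
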