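"""Synthetic driving-session generator.

Emulates the one-hour monotonous simulated-driving experiment: six
subjects, one 60-minute session each, one bipolar occipital EEG channel
plus a three-axis head-mounted gyroscope at 128 Hz, and one video-scored
drowsiness label per minute.  The generator's defaults reproduce the
experiment's reported per-state feature medians —

* alert:          RBP theta/alpha/beta = 18.2 / 37.9 / 38.6 %, MP = 74.1
* slightly drowsy: RBP theta/alpha/beta = 14.5 / 42.6 / 37.9 %, MP = 168.7

— and its class balance (68 alert / 198 slightly drowsy / 94 mid- or
late-stage minutes out of 360, the last group excluded from binary
analysis).

Mechanism per session:

* the minute-label trajectory is monotone (alert, then slightly drowsy,
  then possibly mid/late), with per-subject durations drawn so cohort
  totals hit the class-balance targets exactly;
* EEG is a sum of three band-limited noise components (theta/alpha/beta
  filtered white noise).  Their per-minute variances are solved from a
  linear system built on the *analytic* frequency responses of the
  synthesis filters and the analysis band-pass chain, so that the
  pipeline-measured expected RBP matches the minute's state target —
  including compensation for movement-artifact contamination;
* gyro is white jitter calibrated to the alert MP target; slightly-drowsy
  minutes add smooth 1-3 s angular-rate bursts (yawns on X, shakes on Y,
  sways on Z) whose amplitude is solved so the window-averaged MP matches
  the drowsy target;
* during bursts the EEG receives additive broadband noise scaled by the
  instantaneous gyro magnitude — electrode-scalp friction artifact — which
  mechanically raises measured beta share and dilutes alpha.

All randomness derives from one integer seed via a per-subject stream, so
any single session is reproducible independent of cohort order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.optimize import brentq

from .features import BandDefinition
from .filters import FilterSpec, frequency_response
from .io import ALERT, DROWSY, EXCLUDED, RawSession, write_session


class ProfileError(ValueError):
    """Raised when a simulation profile cannot be realized."""


@dataclass
class SimProfile:
    """Stated world of the simulated cohort.

    RBP targets are stored as printed medians; they need not sum to
    exactly 100 (medians of ratio features do not) and are normalized to a
    simplex internally for calibration.  MP targets are in gyroscope
    device units.  ``coupling_gain`` is µV of broadband EEG contamination
    per device unit of instantaneous gyro magnitude.
    """

    n_subjects: int = 6
    session_minutes: int = 60
    sample_rate: float = 128.0
    alert_rbp: tuple[float, float, float] = (18.2, 37.9, 38.6)
    drowsy_rbp: tuple[float, float, float] = (14.5, 42.6, 37.9)
    alert_mp: float = 74.1
    drowsy_mp: float = 168.7
    burst_rate: float = 5.0  # mean bursts per slightly-drowsy minute (>=1 enforced)
    burst_duration: tuple[float, float] = (1.0, 3.0)  # s
    coupling_gain: float = 0.005  # µV per gyro device unit
    eeg_std: float = 20.0  # target in-band EEG std, µV (10-100 µV range)
    eeg_clip: float = 200.0  # physiological plausibility bound, µV
    subject_rbp_sd: float = 2.5  # percentage points, per-subject target jitter
    subject_mp_sd: float = 0.12  # lognormal sigma on per-subject MP targets
    minute_rbp_sd: float = 4.0  # percentage points, minute-to-minute vigilance jitter
    minute_mp_sd: float = 0.15  # lognormal sigma, minute-to-minute movement jitter
    alert_fraction: float = 68.0 / 360.0
    midlate_fraction: float = 94.0 / 360.0
    min_alert_minutes: int = 3
    min_slight_minutes: int = 5
    bands: BandDefinition = field(default_factory=BandDefinition)

    def validate(self) -> None:
        for name, t in (("alert_rbp", self.alert_rbp), ("drowsy_rbp", self.drowsy_rbp)):
            if min(t) <= 0:
                raise ProfileError(f"{name} targets must be positive, got {t}")
            if not (90.0 <= sum(t) <= 110.0):
                raise ProfileError(f"{name} targets should sum near 100, got {sum(t):.1f}")
        if self.alert_mp <= 0 or self.drowsy_mp <= 0:
            raise ProfileError("MP targets must be positive")
        if self.drowsy_mp < self.alert_mp:
            raise ProfileError("drowsy MP target below alert baseline is not realizable")
        if not (0.0 <= self.alert_fraction <= 1.0 and 0.0 <= self.midlate_fraction <= 1.0):
            raise ProfileError("state fractions must be probabilities")
        if self.alert_fraction + self.midlate_fraction >= 1.0:
            raise ProfileError("alert + mid/late fractions leave no slightly-drowsy minutes")
        if self.burst_rate < 0 or self.coupling_gain < 0:
            raise ProfileError("rates and gains must be non-negative")
        if self.n_subjects < 1 or self.session_minutes < 1:
            raise ProfileError("need at least one subject and one minute")


def _simplex(target: tuple[float, float, float]) -> np.ndarray:
    t = np.asarray(target, dtype=float)
    return t / t.sum()


def _synthesis_sos(bands: BandDefinition, fs: float) -> list[np.ndarray]:
    return [
        signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        for lo, hi, _ in bands.intervals()
    ]


def _expected_band_powers(
    psd: np.ndarray, freqs: np.ndarray, fs: float, bands: BandDefinition, n: int
) -> np.ndarray:
    """Expected one-sided DFT band powers (per N^2, variance-like units) of a
    stationary Gaussian process with one-sided PSD ``psd`` observed through a
    rectangular n-sample window.

    Works in the lag domain so rectangular-window spectral leakage — which
    redistributes a few percent of band power toward the wide beta band —
    is captured exactly: E|X_b|^2 = sum_tau (n - |tau|) r(tau) e^{-i 2 pi b
    tau / n} with r the autocorrelation implied by the PSD.
    """
    taus = np.arange(n) / fs
    # r(tau) = mean_f psd(f) cos(2 pi f tau); normalization gives r(0) = variance
    r = (psd[None, :] * np.cos(2.0 * np.pi * freqs[None, :] * taus[:, None])).mean(axis=1)
    b = np.arange(n // 2 + 1)
    weights = (n - np.arange(1, n)) * r[1:]
    e_bins = n * r[0] + 2.0 * (
        np.cos(2.0 * np.pi * b[:, None] * np.arange(1, n)[None, :] / n) @ weights
    )
    bin_freqs = b * fs / n
    masks = bands.masks(bin_freqs)
    return np.array([e_bins[mk].sum() for mk in masks]) / n**2


def _calibration_matrices(
    profile: SimProfile, filter_spec: FilterSpec
) -> tuple[np.ndarray, np.ndarray]:
    """(M, W): expected measured band power per unit source variance.

    M[j, i] — synthesis component i (unit variance) into analysis band j;
    W[j] — unit-variance white noise (the movement artifact) into band j.
    Both describe exactly what the feature pipeline measures on 2-s
    rectangular-window epochs after the analysis band-pass chain.
    """
    fs = profile.sample_rate
    n = int(2 * fs)
    freqs = np.linspace(0.0, fs / 2.0, 2049)
    h2 = (
        np.abs(
            frequency_response(filter_spec, fs, freqs, include_notch=filter_spec.notch_enabled)
        )
        ** 2
    )
    M = np.empty((3, 3))
    for i, sos in enumerate(_synthesis_sos(profile.bands, fs)):
        _, s = signal.sosfreqz(sos, worN=2 * np.pi * freqs / fs)
        s2 = np.abs(s) ** 2
        s2 /= s2.mean()  # unit pre-analysis variance
        M[:, i] = _expected_band_powers(s2 * h2, freqs, fs, profile.bands, n)
    W = _expected_band_powers(h2, freqs, fs, profile.bands, n)
    return M, W


def _allocate_states(
    profile: SimProfile, rng: np.random.Generator
) -> list[np.ndarray]:
    """Per-subject monotone minute-state sequences with exact cohort class counts."""
    n, minutes = profile.n_subjects, profile.session_minutes
    total = n * minutes
    n_alert = int(round(profile.alert_fraction * total))
    n_mid = int(round(profile.midlate_fraction * total))
    n_slight = total - n_alert - n_mid
    if n_slight < n * profile.min_slight_minutes or n_alert < n * profile.min_alert_minutes:
        raise ProfileError("state fractions incompatible with per-subject minimums")
    p = np.full(n, 1.0 / n)
    a = rng.multinomial(n_alert, p)
    m = rng.multinomial(n_mid, p)
    for _ in range(10 * total):  # deterministic repair to per-subject minimums
        s = minutes - a - m
        if a.min() >= profile.min_alert_minutes and s.min() >= profile.min_slight_minutes and m.min() >= 0:
            break
        if a.min() < profile.min_alert_minutes:
            i, j = int(a.argmin()), int(a.argmax())
            a[i] += 1
            a[j] -= 1
            continue
        i, k = int(s.argmin()), int(s.argmax())
        if m[i] > 0:
            m[i] -= 1
            m[k] += 1
        else:
            a[i] -= 1
            a[k] += 1
    else:
        raise ProfileError("could not allocate per-subject state durations")
    out = []
    for i in range(n):
        seq = np.concatenate(
            [
                np.full(a[i], ALERT),
                np.full(minutes - a[i] - m[i], DROWSY),
                np.full(m[i], EXCLUDED),
            ]
        )
        out.append(seq.astype(int))
    return out


def _gaussian_pulse(t: np.ndarray, center: float, width: float) -> np.ndarray:
    # unit-peak smooth pulse; width is the ~full duration (4 sigma)
    return np.exp(-0.5 * ((t - center) / (width / 4.0)) ** 2)


def _simulate_gyro(
    profile: SimProfile,
    states: np.ndarray,
    base_sigmas: np.ndarray,
    drowsy_targets: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """White jitter at the per-minute baseline sigma plus calibrated drowsy bursts.

    ``base_sigmas[m]`` is minute m's baseline MP level (alert target times
    subject and minute multipliers); ``drowsy_targets[m]`` the window MP a
    drowsy minute should average to once bursts are added.
    """
    fs = profile.sample_rate
    spm = int(60 * fs)  # samples per minute
    epoch = int(2 * fs)
    n = states.shape[0] * spm
    gyro = rng.normal(0.0, np.sqrt(3.0), size=(3, n))
    gyro *= np.repeat(base_sigmas, spm)[None, :]
    if profile.burst_rate <= 0:
        return gyro
    t_min = np.arange(spm) / fs
    axis_p = np.array([0.5, 0.25, 0.25])  # yawn (X) most frequent, then shake, sway
    lo_w, hi_w = profile.burst_duration
    for minute, state in enumerate(states):
        if state == ALERT:
            continue  # bursts are the drowsy symptom
        sigma_base = base_sigmas[minute]
        target = drowsy_targets[minute]
        n_bursts = max(1, int(rng.poisson(profile.burst_rate)))
        pulses = np.zeros((3, spm))
        for _ in range(n_bursts):
            width = rng.uniform(lo_w, hi_w)
            center = rng.uniform(width / 2.0, 60.0 - width / 2.0)
            axis = rng.choice(3, p=axis_p)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            pulses[axis] += sign * _gaussian_pulse(t_min, center, width)
        pavg = pulses.mean(axis=0)
        v_e = pavg.reshape(-1, epoch).var(axis=1)
        if v_e.max() <= 0:
            continue

        def window_mp(s: float) -> float:
            return float(np.mean(np.sqrt(sigma_base**2 + s * s * v_e))) - target

        hi = 10.0 * target / np.sqrt(v_e.max())
        while window_mp(hi) < 0:
            hi *= 2.0
        s_opt = brentq(window_mp, 0.0, hi, xtol=1e-6)
        gyro[:, minute * spm : (minute + 1) * spm] += s_opt * pulses
    return gyro


def _state_rbp(profile: SimProfile, state: int, jitter: np.ndarray) -> np.ndarray:
    base = profile.alert_rbp if state == ALERT else profile.drowsy_rbp
    t = np.clip(100.0 * _simplex(base) + jitter, 1.0, None)
    return t / t.sum()


def simulate_session(
    profile: SimProfile,
    subject_index: int,
    seed: int,
    minute_states: np.ndarray | None = None,
    filter_spec: FilterSpec | None = None,
) -> RawSession:
    """Generate one subject's session, deterministic given (profile, seed, index).

    ``minute_states`` lets the cohort generator impose the exact-balance
    trajectory; standalone calls draw their own monotone trajectory from
    the profile's state fractions.
    """
    profile.validate()
    filter_spec = filter_spec or FilterSpec()
    fs = profile.sample_rate
    rng = np.random.default_rng([int(seed), int(subject_index)])

    rbp_jitter = rng.normal(0.0, profile.subject_rbp_sd, size=3)
    mp_mult = float(np.exp(rng.normal(0.0, profile.subject_mp_sd)))

    if minute_states is None:
        solo = replace(profile, n_subjects=1)
        minute_states = _allocate_states(solo, rng)[0]
    else:
        minute_states = np.asarray(minute_states, dtype=int)

    minutes = minute_states.shape[0]
    # minute-to-minute vigilance fluctuation around the subject's state targets
    minute_rbp_jitter = rng.normal(0.0, profile.minute_rbp_sd, size=(minutes, 3))
    minute_mp_mult = np.exp(rng.normal(0.0, profile.minute_mp_sd, size=minutes))

    spm = int(60 * fs)
    n = minutes * spm

    # unit-variance band-limited neural components + artifact carrier
    comps = np.empty((3, n))
    for i, sos in enumerate(_synthesis_sos(profile.bands, fs)):
        c = signal.sosfilt(sos, rng.normal(0.0, 1.0, n))
        comps[i] = c / c.std()
    artifact_white = rng.normal(0.0, 1.0, n)

    base_sigmas = profile.alert_mp * mp_mult * minute_mp_mult
    drowsy_targets = profile.drowsy_mp * mp_mult * minute_mp_mult
    gyro = _simulate_gyro(profile, minute_states, base_sigmas, drowsy_targets, rng)
    gmag = np.sqrt((gyro**2).sum(axis=0))

    M, W = _calibration_matrices(profile, filter_spec)
    V = profile.eeg_std**2
    eeg = np.empty(n)
    for minute, state in enumerate(minute_states):
        sl = slice(minute * spm, (minute + 1) * spm)
        # expected artifact variance per analysis band over this minute
        a_var = profile.coupling_gain**2 * float(np.mean(gmag[sl] ** 2))
        A = a_var * W
        t = _state_rbp(
            profile,
            DROWSY if state == EXCLUDED else state,
            rbp_jitter + minute_rbp_jitter[minute],
        )
        v = np.linalg.solve(M, t * (V + A.sum()) - A)
        # a minute-jitter draw may graze zero; only a systematic deficit
        # (artifact power well beyond a band's target share) is an error
        if np.any(v < -0.05 * (V + A.sum())):
            raise ProfileError(
                f"minute {minute}: RBP targets unsatisfiable (artifact power exceeds "
                f"a band's target share; negative component variance {v})"
            )
        v = np.clip(v, 0.0, None)
        eeg[sl] = np.sqrt(v) @ comps[:, sl]
    eeg += profile.coupling_gain * gmag * artifact_white
    np.clip(eeg, -profile.eeg_clip, profile.eeg_clip, out=eeg)

    return RawSession(
        subject_id=f"S{subject_index + 1:02d}",
        eeg=eeg,
        gyro=gyro,
        minute_labels=minute_states,
        sample_rate=fs,
    )


def simulate_cohort(
    profile: SimProfile,
    seed: int,
    out_dir: str | Path | None = None,
    filter_spec: FilterSpec | None = None,
) -> list[RawSession]:
    """Generate the full cohort; optionally write session/label CSV pairs.

    Cohort class totals are exact: round(alert_fraction * total) alert and
    round(midlate_fraction * total) mid/late minutes, the rest slightly
    drowsy (68 / 94 / 198 at the defaults).
    """
    profile.validate()
    alloc_rng = np.random.default_rng([int(seed), 1_000_003])
    states = _allocate_states(profile, alloc_rng)
    sessions = [
        simulate_session(profile, i, seed, minute_states=states[i], filter_spec=filter_spec)
        for i in range(profile.n_subjects)
    ]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s in sessions:
            write_session(s, out / f"{s.subject_id}_session.csv", out / f"{s.subject_id}_labels.csv")
    return sessions
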