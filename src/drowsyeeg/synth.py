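"""Seeded synthetic EEG generator with the statistical structure the
drowsiness pipeline assumes.

The generator emulates 60 s prefrontal (Fp1-A1) recordings at 512 Hz in
which theta (4-8 Hz) and alpha (8-12 Hz) band power rises linearly with a
latent drowsiness level in [0, 1]; the latent level is mapped to a 1-9
KSS rating through equally spaced thresholds with logistic ordinal noise.
Recordings are contaminated with a 50 Hz mains sinusoid and Poisson
eye-blink transients (smooth biphasic pulses, ~0.5 s, energy below 8 Hz)
so that the denoising and artifact-removal stages have work to do.

Everything is deterministic given the config seed: the same config yields
bit-identical signals and manifests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .bands import Band
from .io import EEGRecording


@dataclass(frozen=True)
class BandProfile:
    """Baseline power and drowsiness slope (both in signal-units^2) of one band."""

    band: Band
    baseline: float
    slope: float


#: Default spectral profile.  Powers are variances in (arbitrary) uV^2;
#: theta/alpha carry the drowsiness signal, delta a weaker one, the fast
#: bands none.  Magnitudes give a resting-EEG-like ~10-30 uV trace.
DEFAULT_BAND_PROFILE = (
    BandProfile(Band("delta", 1, 4), 20.0, 4.0),
    BandProfile(Band("theta", 4, 8), 10.0, 10.0),
    BandProfile(Band("alpha_low", 8, 10), 5.0, 6.0),
    BandProfile(Band("alpha_mid", 10, 12), 5.0, 6.0),
    BandProfile(Band("sigma", 12, 14), 4.0, 2.0),
    BandProfile(Band("beta", 14, 26), 4.0, 0.0),
    BandProfile(Band("gamma", 26, 45), 2.0, 0.0),
    BandProfile(Band("high", 55, 100), 1.0, 0.0),
)

#: Latent-drowsiness Beta distributions per session: high on waking and at
#: bedtime, mixed during the day.
SESSION_LATENT_BETA = {
    "morning": (4.0, 2.0),
    "daytime": (1.8, 2.2),
    "night": (5.0, 1.5),
    "task": (2.0, 2.0),
}

SESSION_CYCLE = ("morning", "daytime", "night")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level settings for the synthetic cohort.

    Defaults mirror the development study: 29 subjects recording three
    times a day for five analyzed days (15 recordings each, 435 total),
    60 s at 512 Hz.  ``effect_size`` multiplies every band's drowsiness
    slope; 1.0 is the calibrated default, 0 removes the class signal.
    """

    n_subjects: int = 29
    recordings_per_subject: int = 15
    fs: float = 512.0
    duration: float = 60.0
    band_power_profile: tuple[BandProfile, ...] = DEFAULT_BAND_PROFILE
    line_noise_amp: float = 2.0
    line_freq: float = 50.0
    blink_rate: float = 5.0  # events / minute
    blink_amp: float = 60.0
    effect_size: float = 1.0
    kss_noise_scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.recordings_per_subject <= 0:
            raise ValueError("subject and recording counts must be positive")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.blink_rate < 0 or self.line_noise_amp < 0:
            raise ValueError("blink_rate and line_noise_amp must be >= 0")


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float, band: Band) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band`` (zero-phase)."""
    white = rng.standard_normal(n)
    nyq = fs / 2.0
    high = min(band.high, 0.99 * nyq)
    sos = butter(4, [band.low / nyq, high / nyq], btype="bandpass", output="sos")
    x = sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _blink_pulse(fs: float) -> np.ndarray:
    """Smooth biphasic pulse, ~0.5 s, spectral energy concentrated below 8 Hz."""
    t = np.arange(int(round(0.5 * fs))) / fs - 0.15
    return np.exp(-(t**2) / (2 * 0.05**2)) - 0.7 * np.exp(-((t - 0.15) ** 2) / (2 * 0.07**2))


def simulate_recording(
    latent_drowsiness: float,
    config: SimulationConfig,
    seed: int,
    **metadata,
) -> EEGRecording:
    """Simulate one recording at the given latent drowsiness level.

    The signal is a sum of band-limited Gaussian noise components whose
    power is ``baseline + effect_size * slope * latent`` per band, plus a
    50 Hz sinusoid of amplitude ``line_noise_amp`` and Poisson blink
    transients.  Deterministic given ``seed``.
    """
    if not 0.0 <= latent_drowsiness <= 1.0:
        raise ValueError(f"latent_drowsiness must be in [0, 1], got {latent_drowsiness}")
    rng = np.random.default_rng(seed)
    n = int(round(config.fs * config.duration))
    x = np.zeros(n)
    for prof in config.band_power_profile:
        power = prof.baseline + config.effect_size * prof.slope * latent_drowsiness
        if power <= 0:
            continue
        x += np.sqrt(power) * _band_limited_noise(rng, n, config.fs, prof.band)
    if config.line_noise_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / config.fs
        x += config.line_noise_amp * np.sin(2 * np.pi * config.line_freq * t + phase)
    if config.blink_rate > 0:
        pulse = _blink_pulse(config.fs)
        n_blinks = rng.poisson(config.blink_rate * config.duration / 60.0)
        for _ in range(n_blinks):
            start = rng.integers(0, max(1, n - pulse.size))
            amp = config.blink_amp * rng.uniform(0.7, 1.3)
            x[start : start + pulse.size] += amp * pulse
    return EEGRecording(x, fs=config.fs, **metadata)


def kss_from_latent(
    latent: float, rng: np.random.Generator, noise_scale: float = 0.05
) -> int:
    """Map latent drowsiness in [0, 1] to an ordinal 1-9 KSS rating.

    Eight equally spaced thresholds at j/9 (j = 1..8) on the latent value
    plus logistic response noise; latent 0 maps to KSS 1 and latent 1 to
    KSS >= 7 with high probability at the default noise scale.
    """
    z = latent + rng.logistic(0.0, noise_scale) if noise_scale > 0 else latent
    thresholds = np.arange(1, 9) / 9.0
    return int(1 + np.sum(z > thresholds))


def simulate_dataset(config: SimulationConfig) -> tuple[list[EEGRecording], pd.DataFrame]:
    """Simulate the full cohort: recordings plus a KSS manifest.

    Sessions cycle morning -> daytime -> night; each session draws the
    latent drowsiness from its Beta distribution (morning/night high,
    daytime mixed).  Returns the recordings and a manifest with columns
    recording_id, subject_id, session, kss, latent.
    """
    master = np.random.default_rng(config.seed)
    recordings: list[EEGRecording] = []
    rows = []
    for s in range(config.n_subjects):
        subject_id = f"S{s + 1:02d}"
        for r in range(config.recordings_per_subject):
            session = SESSION_CYCLE[r % len(SESSION_CYCLE)]
            a, b = SESSION_LATENT_BETA[session]
            latent = float(master.beta(a, b))
            kss = kss_from_latent(latent, master, config.kss_noise_scale)
            rec_seed = int(master.integers(0, 2**31))
            recording_id = f"{subject_id}R{r + 1:02d}"
            rec = simulate_recording(
                latent,
                config,
                seed=rec_seed,
                subject_id=subject_id,
                recording_id=recording_id,
                session=session,
                kss=kss,
            )
            recordings.append(rec)
            rows.append(
                {
                    "recording_id": recording_id,
                    "subject_id": subject_id,
                    "session": session,
                    "kss": kss,
                    "latent": latent,
                }
            )
    return recordings, pd.DataFrame(rows)


def simulate_practical_experiment(
    config: SimulationConfig,
    n_subjects: int = 20,
    duration: float = 300.0,
    latent_drowsy_task: float = 0.85,
    latent_wakeful_task: float = 0.25,
    latent_jitter: float = 0.08,
    seed: int | None = None,
) -> tuple[list[EEGRecording], pd.DataFrame]:
    """Simulate the two-condition practical experiment.

    Every subject contributes one 300 s recording per condition: a
    monotonous counting task at high latent drowsiness and an attention-
    demanding card-sorting task at low latent drowsiness (each jittered
    per subject).  Returns recordings plus a manifest with a ``condition``
    column; recordings carry no KSS (they are inference inputs).
    """
    if seed is None:
        seed = config.seed
    master = np.random.default_rng(seed)
    cfg = replace(config, duration=duration)
    recordings: list[EEGRecording] = []
    rows = []
    for s in range(n_subjects):
        subject_id = f"P{s + 1:02d}"
        for condition, base in (
            ("counting", latent_drowsy_task),
            ("wcst", latent_wakeful_task),
        ):
            latent = float(np.clip(base + master.normal(0, latent_jitter), 0.0, 1.0))
            rec_seed = int(master.integers(0, 2**31))
            recording_id = f"{subject_id}_{condition}"
            rec = simulate_recording(
                latent,
                cfg,
                seed=rec_seed,
                subject_id=subject_id,
                recording_id=recording_id,
                session="task",
            )
            recordings.append(rec)
            rows.append(
                {
                    "recording_id": recording_id,
                    "subject_id": subject_id,
                    "session": "task",
                    "kss": None,
                    "condition": condition,
                    "latent": latent,
                }
            )
    return recordings, pd.DataFrame(rows)
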