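"""Synthetic multi-subject gesture cohorts with controllable per-channel quality.

The generator emulates an eight-channel wearable armband protocol: each subject
performs a fixed set of gestures, several repetitions each, with rest periods
in between.  sEMG channels carry amplitude-modulated band-limited Gaussian
noise (the standard surrogate for interference EMG, 20-450 Hz), pFMG channels
carry smooth low-frequency (< 10 Hz) baseline shifts.  Three noise contaminant
types can be injected per channel: powerline interference (a mains-frequency
tone), white Gaussian noise, and motion artifact (band-limited drift below
20 Hz, exactly the band the SMR index penalizes).

A designated subset of "good" channels receives a higher active/rest SNR and a
wider per-gesture amplitude separation than the rest, giving every generated
cohort a known ground-truth quality ordering for selection-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, ValidationError
from .recording import Recording

NOISE_KINDS = ("powerline", "white_gaussian", "motion_artifact")

__all__ = [
    "NOISE_KINDS",
    "NoiseSpec",
    "ChannelSpec",
    "SubjectSpec",
    "CohortSpec",
    "inject_noise",
    "generate_recording",
    "generate_cohort",
]


@dataclass(frozen=True)
class NoiseSpec:
    """One noise contaminant: its kind, RMS amplitude and characteristic frequency.

    ``freq_hz`` is the tone frequency for powerline interference (default 50)
    and the upper drift band edge for motion artifact (default 20); it is
    ignored for white Gaussian noise.
    """

    kind: str
    amplitude: float
    freq_hz: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ConfigurationError(
                f"unknown noise kind {self.kind!r}; expected one of {NOISE_KINDS}"
            )
        if self.amplitude < 0:
            raise ValidationError("noise amplitude must be >= 0")
        if self.freq_hz is not None and self.freq_hz <= 0:
            raise ValidationError("freq_hz must be positive where applicable")


@dataclass(frozen=True)
class ChannelSpec:
    """Per-channel generation settings.

    ``gesture_gain`` scales the active carrier per gesture (it is RMS-normalized
    across gestures at generation time, so only its relative spread matters);
    ``target_snr_db`` is the intended active/rest RMS ratio measured over the
    whole channel.
    """

    gesture_gain: tuple[float, ...]
    noise_specs: tuple[NoiseSpec, ...]
    target_snr_db: float
    modality: str = "sEMG"

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.gesture_gain):
            raise ValidationError("gesture gains must be >= 0")
        if not np.isfinite(self.target_snr_db):
            raise ValidationError("target_snr_db must be finite")


@dataclass(frozen=True)
class SubjectSpec:
    """Fully resolved per-subject recording layout."""

    channels: tuple[ChannelSpec, ...]
    fs: float = 1000.0
    n_gestures: int = 7
    n_repetitions: int = 9
    active_s: float = 1.0
    rest_s: float = 0.5
    subject_id: str = "anon"


@dataclass(frozen=True)
class CohortSpec:
    """Study-level settings for a synthetic cohort.

    Defaults mirror the armband protocol the package targets: 10 subjects,
    8 channels, 7 gestures x 9 repetitions at 1 kHz with 1 s active blocks and
    0.5 s rests, and three engineered good channels that carry a ~16 dB SNR and
    a wide gesture-amplitude separation against ~7 dB / narrow separation for
    the remaining channels (poor channels additionally receive strong motion
    artifact and powerline contamination).
    """

    n_subjects: int = 10
    n_channels: int = 8
    n_gestures: int = 7
    n_repetitions: int = 9
    fs: float = 1000.0
    active_s: float = 1.0
    rest_s: float = 0.5
    good_channels: tuple[int, ...] = (1, 4, 6)
    master_seed: int = 2026
    modality: str = "sEMG"
    snr_db_good: float = 16.0
    snr_db_poor: float = 7.0
    separation_good: float = 0.9
    separation_poor: float = 0.25
    floor_amp: float = 1.0
    motion_amp_good: float = 0.15
    motion_amp_poor: float = 1.0
    powerline_amp_good: float = 0.05
    powerline_amp_poor: float = 0.5
    mains_hz: float = 50.0
    snr_jitter_db: float = 1.0

    def __post_init__(self) -> None:
        bad = [c for c in self.good_channels if not 0 <= c < self.n_channels]
        if bad:
            raise ValidationError(
                f"good_channels {bad} outside 0..{self.n_channels - 1}"
            )
        if self.modality not in ("sEMG", "pFMG"):
            raise ValidationError(f"unsupported cohort modality {self.modality!r}")


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def inject_noise(
    signal: Sequence[float], spec: NoiseSpec, fs: float, seed: int = 0
) -> np.ndarray:
    """Add one noise contaminant to a 1-D signal; output length is unchanged."""
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("inject_noise: input signal must be finite")
    if spec.amplitude == 0:
        return x.copy()
    rng = np.random.default_rng(seed)
    n = len(x)
    if spec.kind == "powerline":
        f = spec.freq_hz if spec.freq_hz is not None else 50.0
        t = np.arange(n) / fs
        phase = rng.uniform(0.0, 2.0 * np.pi)
        noise = spec.amplitude * np.sqrt(2.0) * np.sin(2.0 * np.pi * f * t + phase)
    elif spec.kind == "white_gaussian":
        noise = rng.normal(0.0, spec.amplitude, n)
    else:  # motion_artifact: band-limited drift below freq_hz
        f = spec.freq_hz if spec.freq_hz is not None else 20.0
        sos = sps.butter(4, f, btype="lowpass", fs=fs, output="sos")
        drift = sps.sosfiltfilt(sos, rng.normal(0.0, 1.0, n))
        scale = _rms(drift)
        noise = drift * (spec.amplitude / scale) if scale > 0 else np.zeros(n)
    return x + noise


def _carrier(
    rng: np.random.Generator, n: int, fs: float, modality: str
) -> np.ndarray:
    """Unit-RMS active-burst carrier for one block, smoothly enveloped."""
    if modality == "sEMG":
        hi = min(450.0, 0.45 * fs)
        sos = sps.butter(4, [20.0, hi], btype="bandpass", fs=fs, output="sos")
        y = sps.sosfiltfilt(sos, rng.normal(0.0, 1.0, n))
    else:  # pFMG: smooth gesture-dependent baseline shift, < 10 Hz content
        sos = sps.butter(2, 3.0, btype="lowpass", fs=fs, output="sos")
        wiggle = sps.sosfiltfilt(sos, rng.normal(0.0, 1.0, n))
        w_rms = _rms(wiggle)
        y = 1.0 + 0.25 * (wiggle / w_rms if w_rms > 0 else wiggle)
    env = sps.windows.tukey(n, alpha=0.25)
    y = y * env
    r = _rms(y)
    return y / r if r > 0 else y


def generate_recording(
    spec: SubjectSpec, seed: int = 0, min_active_s: float = 0.2
) -> Recording:
    """Generate one gesture-labeled recording, deterministic given ``seed``.

    Layout: a leading rest block, then for each repetition r = 1..R and gesture
    g = 1..G an active block labeled (g, r) followed by a rest block.  Rest
    samples carry repetition id 0.  The active carrier on each channel is
    scaled so that the channel-wide active/rest RMS ratio matches the channel's
    ``target_snr_db`` when the per-gesture gains are RMS-normalized.
    """
    fs = spec.fs
    n_active = int(round(spec.active_s * fs))
    n_rest = int(round(spec.rest_s * fs))
    if spec.active_s < min_active_s or n_active < 2:
        raise ConfigurationError(
            f"active blocks of {spec.active_s} s are shorter than one analysis "
            f"window ({min_active_s} s): no feature windows would fit"
        )
    if n_rest < 2:
        raise ConfigurationError("rest blocks must span at least 2 samples")
    g_count, r_count = spec.n_gestures, spec.n_repetitions
    for ch in spec.channels:
        if len(ch.gesture_gain) != g_count:
            raise ValidationError(
                f"gesture_gain length {len(ch.gesture_gain)} != n_gestures {g_count}"
            )

    total = n_rest + r_count * g_count * (n_active + n_rest)
    labels = np.zeros(total, dtype=int)
    reps = np.zeros(total, dtype=int)
    blocks: list[tuple[int, int, int]] = []  # (start, gesture, repetition)
    pos = n_rest
    for rep in range(1, r_count + 1):
        for g in range(1, g_count + 1):
            labels[pos : pos + n_active] = g
            reps[pos : pos + n_active] = rep
            blocks.append((pos, g, rep))
            pos += n_active + n_rest

    ss = np.random.SeedSequence(seed)
    channel_seeds = ss.spawn(len(spec.channels))
    data = np.zeros((total, len(spec.channels)))
    for c, ch in enumerate(spec.channels):
        rng = np.random.default_rng(channel_seeds[c])
        # noise floor over the full record
        x = np.zeros(total)
        for ns in ch.noise_specs:
            x = inject_noise(x, ns, fs, seed=int(rng.integers(2**31)))
        noise_rms = float(np.sqrt(sum(ns.amplitude**2 for ns in ch.noise_specs)))
        noise_rms = max(noise_rms, 1e-6)
        # RMS-normalized gesture gains: channel-wide mean-square gain is one
        gains = np.asarray(ch.gesture_gain, dtype=float)
        g_rms = float(np.sqrt(np.mean(np.square(gains))))
        gains = gains / g_rms if g_rms > 0 else gains
        # active carrier amplitude so total active RMS hits the SNR target
        carrier_rms = noise_rms * np.sqrt(
            max(10.0 ** (ch.target_snr_db / 10.0) - 1.0, 1e-12)
        )
        for start, g, _rep in blocks:
            burst = _carrier(rng, n_active, fs, ch.modality)
            x[start : start + n_active] += carrier_rms * gains[g - 1] * burst
        data[:, c] = x

    return Recording(
        data=data,
        fs=fs,
        modality=tuple(ch.modality for ch in spec.channels),
        labels=labels,
        repetitions=reps,
        subject_id=spec.subject_id,
    )


def _subject_spec(cohort: CohortSpec, index: int) -> SubjectSpec:
    """Resolve the per-subject channel specs (deterministic per subject)."""
    rng = np.random.default_rng(np.random.SeedSequence((cohort.master_seed, index, 7919)))
    channels = []
    for c in range(cohort.n_channels):
        good = c in cohort.good_channels
        sep = cohort.separation_good if good else cohort.separation_poor
        profile = rng.permutation(np.linspace(-0.5, 0.5, cohort.n_gestures))
        gains = 1.0 + sep * profile + rng.normal(0.0, 0.03, cohort.n_gestures)
        gains = np.clip(gains, 0.05, None)
        snr_db = (cohort.snr_db_good if good else cohort.snr_db_poor) + rng.uniform(
            -cohort.snr_jitter_db, cohort.snr_jitter_db
        )
        motion = cohort.motion_amp_good if good else cohort.motion_amp_poor
        mains = cohort.powerline_amp_good if good else cohort.powerline_amp_poor
        noise = (
            NoiseSpec("white_gaussian", cohort.floor_amp),
            NoiseSpec("motion_artifact", motion, freq_hz=20.0),
            NoiseSpec("powerline", mains, freq_hz=cohort.mains_hz),
        )
        channels.append(
            ChannelSpec(
                gesture_gain=tuple(gains),
                noise_specs=noise,
                target_snr_db=float(snr_db),
                modality=cohort.modality,
            )
        )
    return SubjectSpec(
        channels=tuple(channels),
        fs=cohort.fs,
        n_gestures=cohort.n_gestures,
        n_repetitions=cohort.n_repetitions,
        active_s=cohort.active_s,
        rest_s=cohort.rest_s,
        subject_id=f"S{index:02d}",
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[Recording], dict]:
    """Generate one recording per subject plus the engineered ground truth.

    Subject ``i`` is generated with seed ``master_seed + i``; the returned
    ground-truth dict records the engineered good channels and each subject's
    per-channel SNR targets (the intended quality ordering).
    """
    if spec.n_subjects < 2:
        raise ValidationError("a cohort needs at least 2 subjects")
    recordings = []
    targets = []
    for i in range(spec.n_subjects):
        subj = _subject_spec(spec, i)
        recordings.append(generate_recording(subj, seed=spec.master_seed + i))
        targets.append([ch.target_snr_db for ch in subj.channels])
    ground_truth = {
        "good_channels": sorted(int(c) for c in spec.good_channels),
        "target_snr_db": targets,
        "subject_ids": [r.subject_id for r in recordings],
        "master_seed": spec.master_seed,
    }
    return recordings, ground_truth
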