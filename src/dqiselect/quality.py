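"""The five per-channel data quality indices (DQIs) and their spectral machinery.

Each channel of a gesture recording is summarized by a 5-vector of indices:

* **SNR** — signal-to-noise ratio: ``20 log10(RMS(active) / RMS(rest))`` in dB.
* **SMR** — signal-to-motion-artifact ratio: total power over power below 20 Hz, dB.
* **OHM** (Ω) — power-spectrum deformation ratio ``sqrt(M2/M0) / (M1/M0)`` built
  from spectral moments; a dimensionless measure of spectral distortion.
* **SHR** — signal-to-high-frequency-noise ratio: total power over power in the
  upper 20 % of the frequency axis, dB.
* **DPR** — maximum-to-minimum drop of the 13-bin mean power density across the
  spectrum, dB; quantifies how pronounced the spectral structure is relative
  to a flat noise floor.

Spectral estimates come from Welch's method (Hann taper, 1 s segments, 50 %
overlap by default).  All ratios are epsilon-guarded so the indices stay finite
on degenerate inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .errors import ConfigurationError, SizingError, ValidationError
from .recording import Recording

EPS = 1e-12
INDEX_NAMES = ("snr", "smr", "ohm", "shr", "dpr")

__all__ = [
    "EPS",
    "INDEX_NAMES",
    "Spectrum",
    "QualityProfile",
    "welch_psd",
    "band_power",
    "snr",
    "smr",
    "spectral_moment",
    "ohm",
    "shr",
    "dpr",
    "profile_recording",
    "aggregate_combo",
]


@dataclass(frozen=True)
class Spectrum:
    """A one-sided power spectral density on a strictly increasing frequency grid."""

    freqs: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "psd", np.asarray(self.psd, dtype=float))
        if self.freqs.shape != self.psd.shape or self.freqs.ndim != 1:
            raise ValidationError("freqs and psd must be 1-D arrays of equal length")
        if len(self.freqs) < 2:
            raise ValidationError("a spectrum needs at least two frequency bins")
        if self.freqs[0] != 0.0:
            raise ValidationError("frequency grid must start at 0 Hz")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValidationError("frequency grid must be strictly increasing")
        if np.any(self.psd < 0):
            raise ValidationError("power spectral density must be non-negative")

    @property
    def f_max(self) -> float:
        return float(self.freqs[-1])


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(np.asarray(x, dtype=float)))))


def welch_psd(
    x: Sequence[float],
    fs: float,
    nperseg: int | None = None,
    overlap: float = 0.5,
) -> Spectrum:
    """Welch estimate of the one-sided PSD.

    ``nperseg`` defaults to one second of samples. Total power
    ``sum(psd) * df`` approximates the signal variance (Parseval).
    """
    x = np.asarray(x, dtype=float)
    if nperseg is None:
        nperseg = int(round(fs))
    if len(x) < nperseg:
        raise SizingError(
            f"signal of {len(x)} samples is shorter than nperseg={nperseg}; "
            f"need at least {nperseg} samples"
        )
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend="constant",
    )
    return Spectrum(freqs=freqs, psd=psd)


def band_power(spec: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal power in ``lo <= f <= hi``; 0 if fewer than two bins fall inside."""
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(spec.psd[mask], spec.freqs[mask]))


def total_power(spec: Spectrum) -> float:
    return float(np.trapezoid(spec.psd, spec.freqs))


def snr(active: Sequence[float], rest: Sequence[float]) -> float:
    """Signal-to-noise ratio in dB: active-segment RMS against rest-segment RMS."""
    active = np.asarray(active, dtype=float)
    rest = np.asarray(rest, dtype=float)
    if active.size == 0 or rest.size == 0:
        raise ValidationError("snr: both active and rest samples must be non-empty")
    return 20.0 * np.log10(max(_rms(active), EPS) / max(_rms(rest), EPS))


def smr(spec: Spectrum, artifact_band_hz: float = 20.0) -> float:
    """Signal-to-motion-artifact ratio in dB: total power over 0-20 Hz power."""
    p_total = total_power(spec)
    p_low = band_power(spec, 0.0, artifact_band_hz)
    return 10.0 * np.log10(max(p_total, EPS) / max(p_low, EPS))


def spectral_moment(spec: Spectrum, n: int) -> float:
    """n-th order spectral moment ``integral f^n psd(f) df`` for n in {0, 1, 2}."""
    if n not in (0, 1, 2):
        raise ConfigurationError(f"spectral moment order must be 0, 1 or 2, got {n}")
    return float(np.trapezoid(spec.freqs**n * spec.psd, spec.freqs))


def ohm(spec: Spectrum, db: bool = False) -> float:
    """Power-spectrum deformation ratio Ω = sqrt(M2/M0) / (M1/M0).

    Returned as the raw dimensionless ratio by default (a pure tone gives
    exactly 1); pass ``db=True`` for ``10 log10(Ω)``.
    """
    m0 = spectral_moment(spec, 0)
    m1 = spectral_moment(spec, 1)
    m2 = spectral_moment(spec, 2)
    if m0 <= EPS or m1 <= EPS:
        warnings.warn("ohm: degenerate (near-zero) spectrum; epsilon-guarded result")
    m0 = max(m0, EPS)
    m1 = max(m1, EPS)
    ratio = float(np.sqrt(max(m2, EPS) / m0) / (m1 / m0))
    return float(10.0 * np.log10(max(ratio, EPS))) if db else ratio


def shr(spec: Spectrum, upper_fraction: float = 0.2) -> float:
    """Signal-to-high-frequency-noise ratio in dB.

    The high-frequency band is the upper ``upper_fraction`` of the frequency
    axis, i.e. ``[0.8 * f_max, f_max]`` by default.
    """
    p_total = total_power(spec)
    p_upper = band_power(spec, (1.0 - upper_fraction) * spec.f_max, spec.f_max)
    return 10.0 * np.log10(max(p_total, EPS) / max(p_upper, EPS))


def dpr(spec: Spectrum, window_bins: int = 13) -> float:
    """Maximum-to-minimum drop in mean power density (MPD), dB.

    A window of ``window_bins`` consecutive bins slides across the spectrum;
    the MPD is the mean density inside the window, and DPR is
    ``10 log10(max MPD / min MPD)`` over all window positions.
    """
    if len(spec.psd) < window_bins:
        raise SizingError(
            f"spectrum has {len(spec.psd)} bins but the sliding window needs "
            f"at least {window_bins}"
        )
    mpd = sliding_window_view(spec.psd, window_bins).mean(axis=1)
    return 10.0 * np.log10(max(float(mpd.max()), EPS) / max(float(mpd.min()), EPS))


# ---------------------------------------------------------------------------
# Per-recording profiles
# ---------------------------------------------------------------------------

@dataclass
class QualityProfile:
    """Per-channel DQI matrix for one subject: rows = channels, columns = INDEX_NAMES."""

    subject_id: str
    values: np.ndarray  # (C, 5)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(INDEX_NAMES):
            raise ValidationError(
                f"values must be (channels x {len(INDEX_NAMES)}), got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("quality indices must all be finite")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values,
            columns=list(INDEX_NAMES),
            index=[f"ch{i}" for i in range(self.n_channels)],
        )


def profile_recording(
    rec: Recording,
    scope: Iterable[int] | None = None,
    nperseg: int | None = None,
    overlap: float = 0.5,
) -> QualityProfile:
    """Compute the five DQIs for every channel of a recording.

    Indices are computed per repetition in ``scope`` (default: every repetition
    present) and then averaged, which keeps DQI estimation on the training
    repetitions only when a train/test split by repetition is in force.  SNR
    compares each repetition's concatenated active samples against the pooled
    rest samples; the four spectral indices are computed from the Welch PSD of
    the concatenated active samples of that repetition.
    """
    rest_mask = rec.labels == 0
    if not np.any(rest_mask):
        raise ValidationError(
            "no rest samples (label 0) in recording: SNR needs a resting baseline -- "
            "record or label rest periods, or widen the scope"
        )
    active_mask = ~rest_mask
    reps_present = np.unique(rec.repetitions[active_mask])
    if scope is None:
        scope_list = [int(r) for r in reps_present]
    else:
        scope_list = sorted(int(r) for r in scope)
    if not scope_list:
        raise ValidationError("scope: at least one repetition id is required")
    missing = set(scope_list) - set(int(r) for r in reps_present)
    if missing:
        raise ValidationError(f"scope: repetitions {sorted(missing)} not present in recording")

    if nperseg is None:
        nperseg = int(round(rec.fs))
    rest = rec.data[rest_mask]

    per_rep = np.empty((len(scope_list), rec.n_channels, len(INDEX_NAMES)))
    for k, rep in enumerate(scope_list):
        sel = active_mask & (rec.repetitions == rep)
        active = rec.data[sel]
        n_eff = min(nperseg, active.shape[0])
        for c in range(rec.n_channels):
            spec = welch_psd(active[:, c], rec.fs, nperseg=n_eff, overlap=overlap)
            per_rep[k, c] = (
                snr(active[:, c], rest[:, c]),
                smr(spec),
                ohm(spec),
                shr(spec),
                dpr(spec),
            )
    return QualityProfile(subject_id=rec.subject_id, values=per_rep.mean(axis=0))


def aggregate_combo(profile: QualityProfile, combo: Sequence[int]) -> np.ndarray:
    """Aggregate a channel combination's DQIs as the per-index mean over its channels."""
    combo = list(combo)
    if not combo:
        raise ValidationError("combo: at least one channel index is required")
    for ch in combo:
        if not 0 <= ch < profile.n_channels:
            raise IndexError(
                f"channel {ch} out of range for profile with {profile.n_channels} channels"
            )
    return profile.values[combo].mean(axis=0)
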