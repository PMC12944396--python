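"""Labeled multi-channel biosignal recordings: data model, I/O, filtering, segmentation.

A :class:`Recording` holds a ``(T, C)`` sample matrix together with per-sample
gesture labels (0 = rest) and repetition ids, a sampling rate, and a per-channel
modality tag (``"sEMG"`` or ``"pFMG"``).  Three on-disk representations are
supported: delimited text with a JSON metadata sidecar, an HDF5 container, and
Ninapro-style MATLAB files (``emg`` / ``stimulus`` / ``repetition`` fields).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError, ValidationError

MODALITIES = ("sEMG", "pFMG")

__all__ = [
    "MODALITIES",
    "Recording",
    "Segment",
    "FilterConfig",
    "read_recording",
    "write_recording",
    "preprocess",
    "segment_by_label",
]


@dataclass
class Recording:
    """A time-aligned multi-channel recording with gesture annotations.

    Parameters
    ----------
    data : ndarray, shape (T, C)
        Raw samples, arbitrary amplitude units.
    fs : float
        Sampling rate in Hz, strictly positive.
    modality : sequence of str
        Per-channel tag, each one of :data:`MODALITIES`.
    labels : ndarray of int, shape (T,)
        Per-sample gesture id; 0 denotes rest.
    repetitions : ndarray of int, shape (T,)
        Per-sample repetition id; >= 1 on active samples, 0 where unassigned
        (typically rest).
    subject_id : str
        Opaque identifier for the subject the recording came from.
    """

    data: np.ndarray
    fs: float
    modality: tuple[str, ...]
    labels: np.ndarray
    repetitions: np.ndarray
    subject_id: str = "anon"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValidationError("data: expected a 2-D (samples x channels) matrix")
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        self.repetitions = np.asarray(self.repetitions, dtype=int).ravel()
        self.modality = tuple(str(m) for m in self.modality)
        t, c = self.data.shape
        if not self.fs > 0:
            raise ValidationError(f"fs: sampling rate must be positive, got {self.fs}")
        if c < 1:
            raise ValidationError("data: at least one channel is required")
        if len(self.modality) != c:
            raise ValidationError(
                f"modality: expected {c} per-channel tags, got {len(self.modality)}"
            )
        for tag in self.modality:
            if tag not in MODALITIES:
                raise ValidationError(
                    f"modality: unknown tag {tag!r}; expected one of {MODALITIES}"
                )
        if len(self.labels) != t:
            raise ValidationError(
                f"labels: expected {t} entries (one per sample), got {len(self.labels)}"
            )
        if len(self.repetitions) != t:
            raise ValidationError(
                f"repetitions: expected {t} entries, got {len(self.repetitions)}"
            )
        bad = (self.labels != 0) & (self.repetitions < 1)
        if np.any(bad):
            raise ValidationError(
                "repetitions: every non-rest sample must carry a repetition id >= 1 "
                f"({int(bad.sum())} offending samples)"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def channel(self, index: int) -> np.ndarray:
        """Return the 1-D sample vector of one channel."""
        return self.data[:, index]

    def equals(self, other: "Recording", rtol: float = 0.0, atol: float = 1e-9) -> bool:
        """Field-by-field equality at numeric tolerance ``atol``."""
        return (
            np.allclose(self.data, other.data, rtol=rtol, atol=atol)
            and float(self.fs) == float(other.fs)
            and self.modality == other.modality
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.repetitions, other.repetitions)
            and self.subject_id == other.subject_id
        )


@dataclass(frozen=True)
class Segment:
    """A maximal run of constant (label, repetition): 0-based, half-open."""

    start: int
    stop: int
    label: int
    repetition: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.stop:
            raise ValidationError(f"segment bounds invalid: [{self.start}, {self.stop})")

    @property
    def length(self) -> int:
        return self.stop - self.start

    @property
    def is_rest(self) -> bool:
        return self.label == 0


def segment_by_label(rec: Recording) -> list[Segment]:
    """Split a recording into maximal runs of constant ``(label, repetition)``.

    The returned segments are ordered, disjoint, and tile ``[0, T)`` exactly.
    An empty recording yields an empty list.
    """
    labels, reps = rec.labels, rec.repetitions
    t = len(labels)
    if t == 0:
        return []
    change = np.flatnonzero((labels[1:] != labels[:-1]) | (reps[1:] != reps[:-1])) + 1
    bounds = [0, *change.tolist(), t]
    return [
        Segment(bounds[i], bounds[i + 1], int(labels[bounds[i]]), int(reps[bounds[i]]))
        for i in range(len(bounds) - 1)
    ]


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterConfig:
    """Zero-phase filtering defaults for the two modalities.

    sEMG channels get a Butterworth band-pass (20-450 Hz, order 4) plus a mains
    notch; pFMG channels get a 10 Hz low-pass matching their 0-10 Hz bandwidth.
    Set ``notch_hz`` to 60.0 for 60 Hz mains, or ``None`` to disable the notch.
    """

    semg_band: tuple[float, float] = (20.0, 450.0)
    semg_order: int = 4
    notch_hz: float | None = 50.0
    notch_q: float = 30.0
    pfmg_cutoff: float = 10.0
    pfmg_order: int = 4


def preprocess(rec: Recording, cfg: FilterConfig = FilterConfig()) -> Recording:
    """Filter each channel according to its modality; annotations are untouched.

    All filters are applied forward-backward (zero phase) so that labels stay
    aligned with the filtered samples.
    """
    nyq = rec.fs / 2.0
    lo, hi = cfg.semg_band
    if not 0 < lo < hi < nyq:
        raise ConfigurationError(
            f"sEMG band {cfg.semg_band} incompatible with fs={rec.fs} (Nyquist {nyq} Hz)"
        )
    if not 0 < cfg.pfmg_cutoff < nyq:
        raise ConfigurationError(
            f"pFMG cutoff {cfg.pfmg_cutoff} Hz must lie below Nyquist ({nyq} Hz)"
        )
    if cfg.notch_hz is not None and not 0 < cfg.notch_hz < nyq:
        raise ConfigurationError(
            f"notch frequency {cfg.notch_hz} Hz must lie below Nyquist ({nyq} Hz)"
        )

    sos_semg = sps.butter(
        cfg.semg_order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos"
    )
    sos_pfmg = sps.butter(
        cfg.pfmg_order, cfg.pfmg_cutoff, btype="lowpass", fs=rec.fs, output="sos"
    )
    if cfg.notch_hz is not None:
        b_notch, a_notch = sps.iirnotch(cfg.notch_hz, cfg.notch_q, fs=rec.fs)

    out = np.empty_like(rec.data)
    # generous padding: the high-Q notch settles slowly and default filtfilt
    # padding leaks edge transients back into the record
    padlen = max(0, min(rec.n_samples - 1, int(rec.fs)))
    for c, tag in enumerate(rec.modality):
        x = rec.data[:, c]
        if tag == "sEMG":
            y = sps.sosfiltfilt(sos_semg, x, padlen=padlen)
            if cfg.notch_hz is not None:
                y = sps.filtfilt(b_notch, a_notch, y, padlen=padlen)
        else:  # pFMG
            y = sps.sosfiltfilt(sos_pfmg, x, padlen=padlen)
        out[:, c] = y
    return dataclasses.replace(rec, data=out)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_DELIMITED_SUFFIXES = {".csv", ".tsv", ".txt"}
_CONTAINER_SUFFIXES = {".h5", ".hdf5"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in _DELIMITED_SUFFIXES:
        return "delimited"
    if suffix in _CONTAINER_SUFFIXES:
        return "container"
    if suffix == ".mat":
        return "ninapro_mat"
    raise ConfigurationError(
        f"cannot infer format from suffix {suffix!r}; pass format= explicitly"
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording to disk in the delimited or container format."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "delimited":
        df = pd.DataFrame(rec.data, columns=[f"ch{i}" for i in range(rec.n_channels)])
        df["label"] = rec.labels
        df["repetition"] = rec.repetitions
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df.to_csv(path, index=False, sep=sep)
        meta = {
            "fs": float(rec.fs),
            "modality": list(rec.modality),
            "subject_id": rec.subject_id,
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    elif fmt == "container":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=rec.data)
            f.create_dataset("labels", data=rec.labels)
            f.create_dataset("repetitions", data=rec.repetitions)
            f.attrs["fs"] = float(rec.fs)
            f.attrs["modality"] = np.array(rec.modality, dtype=h5py.string_dtype())
            f.attrs["subject_id"] = rec.subject_id
    else:
        raise ConfigurationError(f"unsupported write format {fmt!r}")
    return path


def read_recording(
    path: str | Path,
    format: str | None = None,
    *,
    fs: float | None = None,
    modality: Sequence[str] | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Read a recording from any supported on-disk representation.

    For ``ninapro_mat`` files the ``stimulus`` field maps to labels and
    ``repetition`` to repetition ids (``restimulus`` / ``rerepetition`` are
    used as fallbacks); ``fs`` is taken from a ``frequency`` variable when
    present, otherwise it must be supplied.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"recording file not found: {path}")
    fmt = format or _infer_format(path)

    if fmt == "delimited":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValidationError(f"metadata sidecar missing: {sidecar}")
        meta = json.loads(sidecar.read_text())
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep)
        for col in ("label", "repetition"):
            if col not in df.columns:
                raise ValidationError(f"{col}: column missing from {path.name}")
            if df[col].isna().any():
                raise ValidationError(
                    f"{col}: column has {int(df[col].isna().sum())} missing entries "
                    f"for {len(df)} samples"
                )
        ch_cols = sorted(
            (c for c in df.columns if c.startswith("ch") and c[2:].isdigit()),
            key=lambda c: int(c[2:]),
        )
        if not ch_cols:
            raise ValidationError("no channel columns (ch0, ch1, ...) found")
        return Recording(
            data=df[ch_cols].to_numpy(dtype=float),
            fs=float(meta["fs"]),
            modality=tuple(meta["modality"]),
            labels=df["label"].to_numpy(dtype=int),
            repetitions=df["repetition"].to_numpy(dtype=int),
            subject_id=str(meta.get("subject_id", "anon")),
        )

    if fmt == "container":
        import h5py

        with h5py.File(path, "r") as f:
            for name in ("data", "labels", "repetitions"):
                if name not in f:
                    raise ValidationError(f"{name}: dataset missing from {path.name}")
            tags = [
                m.decode() if isinstance(m, bytes) else str(m)
                for m in f.attrs["modality"]
            ]
            sid = f.attrs["subject_id"]
            return Recording(
                data=f["data"][()],
                fs=float(f.attrs["fs"]),
                modality=tuple(tags),
                labels=f["labels"][()],
                repetitions=f["repetitions"][()],
                subject_id=sid.decode() if isinstance(sid, bytes) else str(sid),
            )

    if fmt == "ninapro_mat":
        from scipy.io import loadmat

        mat = loadmat(path)
        if "emg" not in mat:
            raise ValidationError(f"emg: field missing from {path.name}")
        data = np.asarray(mat["emg"], dtype=float)
        labels = _mat_vector(mat, "stimulus", "restimulus", path)
        reps = _mat_vector(mat, "repetition", "rerepetition", path)
        if fs is None:
            if "frequency" in mat:
                fs = float(np.asarray(mat["frequency"]).ravel()[0])
            else:
                raise ValidationError(
                    f"fs: no 'frequency' field in {path.name}; pass fs= explicitly"
                )
        tags = tuple(modality) if modality is not None else ("sEMG",) * data.shape[1]
        return Recording(
            data=data,
            fs=fs,
            modality=tags,
            labels=labels,
            repetitions=reps,
            subject_id=subject_id or path.stem,
        )

    raise ConfigurationError(f"unsupported read format {fmt!r}")


def _mat_vector(mat: dict, primary: str, fallback: str, path: Path) -> np.ndarray:
    for key in (primary, fallback):
        if key in mat:
            return np.asarray(mat[key], dtype=int).ravel()
    raise ValidationError(f"{primary}: field missing from {path.name} (no {fallback} either)")
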