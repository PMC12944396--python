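"""Sliding-window time-domain feature extraction for sEMG and pFMG channels.

sEMG channels yield six features per window — RMS, variance (VAR), mean
absolute value (MAV), simple square integral (SSI), average amplitude change
(AAC) and difference absolute standard deviation value (DASDV) — the standard
myoelectric-control set.  pFMG channels, being slow pressure signals, yield a
single integrated absolute value (IAV).  Windows are cut inside constant
(label, repetition) segments only, so no window ever crosses a repetition or
gesture boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, SizingError, ValidationError
from .recording import Recording, segment_by_label

SEMG_FEATURES = ("rms", "var", "mav", "ssi", "aac", "dasdv")
PFMG_FEATURES = ("iav",)
META_COLUMNS = ("label", "repetition")

__all__ = [
    "SEMG_FEATURES",
    "PFMG_FEATURES",
    "META_COLUMNS",
    "Window",
    "make_windows",
    "extract_features",
    "build_feature_table",
    "feature_columns",
]


@dataclass(frozen=True)
class Window:
    """A half-open sample range with the label/repetition of its parent segment."""

    start: int
    stop: int
    label: int
    repetition: int


def _window_sizes(fs: float, win_ms: float, stride_ms: float) -> tuple[int, int]:
    if not (win_ms >= stride_ms > 0):
        raise ConfigurationError(
            f"need win_ms >= stride_ms > 0, got win_ms={win_ms}, stride_ms={stride_ms}"
        )
    out = []
    for name, ms in (("win_ms", win_ms), ("stride_ms", stride_ms)):
        exact = ms * fs / 1000.0
        if abs(exact - round(exact)) > 1e-9:
            raise ConfigurationError(
                f"{name}={ms} does not give a whole number of samples at fs={fs} Hz "
                f"({exact}); choose fs so that {name}*fs/1000 is an integer"
            )
        out.append(int(round(exact)))
    return out[0], out[1]


def make_windows(
    rec: Recording, win_ms: float = 200.0, stride_ms: float = 40.0
) -> list[Window]:
    """Enumerate sliding windows within each constant (label, repetition) segment.

    A segment of ``L`` samples yields ``floor((L - W) / S) + 1`` windows
    (0 if ``L < W``) where ``W`` and ``S`` are the window and stride lengths in
    samples.
    """
    w, s = _window_sizes(rec.fs, win_ms, stride_ms)
    windows: list[Window] = []
    for seg in segment_by_label(rec):
        length = seg.length
        if length < w:
            continue
        n = (length - w) // s + 1
        for k in range(n):
            start = seg.start + k * s
            windows.append(Window(start, start + w, seg.label, seg.repetition))
    return windows


def _semg_features(sw: np.ndarray) -> np.ndarray:
    """Six time-domain features per row of a (n_windows, W) matrix."""
    diffs = np.diff(sw, axis=1)
    return np.column_stack(
        [
            np.sqrt(np.mean(np.square(sw), axis=1)),  # RMS
            np.var(sw, axis=1, ddof=1),  # VAR (unbiased)
            np.mean(np.abs(sw), axis=1),  # MAV
            np.sum(np.square(sw), axis=1),  # SSI
            np.mean(np.abs(diffs), axis=1),  # AAC
            np.sqrt(np.mean(np.square(diffs), axis=1)),  # DASDV
        ]
    )


def _pfmg_features(sw: np.ndarray) -> np.ndarray:
    return np.sum(np.abs(sw), axis=1)[:, None]  # IAV


def extract_features(window: Sequence[float], modality: str) -> np.ndarray:
    """Feature vector of one window: 6 values for sEMG, 1 (IAV) for pFMG."""
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise SizingError(
            "a window needs at least 2 samples (difference-based features are "
            f"undefined otherwise), got {x.size}"
        )
    sw = x[None, :]
    if modality == "sEMG":
        return _semg_features(sw)[0]
    if modality == "pFMG":
        return _pfmg_features(sw)[0]
    raise ValidationError(f"unknown modality {modality!r}")


def build_feature_table(
    rec: Recording,
    channels: Sequence[int] | None = None,
    win_ms: float = 200.0,
    stride_ms: float = 40.0,
    include_rest: bool = True,
) -> pd.DataFrame:
    """Window the recording and extract per-channel features into a DataFrame.

    Columns are ``ch{i}_{feature}`` in the given channel order, followed by
    ``label`` and ``repetition``.  Rest-labeled windows are retained by default
    (relax-as-a-gesture protocols) and dropped with ``include_rest=False``.
    """
    if channels is None:
        channels = list(range(rec.n_channels))
    channels = list(channels)
    if not channels:
        raise ConfigurationError("at least one channel must be selected")
    for ch in channels:
        if not 0 <= ch < rec.n_channels:
            raise IndexError(f"channel {ch} out of range (recording has {rec.n_channels})")

    windows = make_windows(rec, win_ms=win_ms, stride_ms=stride_ms)
    if not include_rest:
        windows = [w for w in windows if w.label != 0]

    w, _ = _window_sizes(rec.fs, win_ms, stride_ms)
    names: list[str] = []
    for ch in channels:
        feats = SEMG_FEATURES if rec.modality[ch] == "sEMG" else PFMG_FEATURES
        names.extend(f"ch{ch}_{f}" for f in feats)

    if not windows:
        empty = pd.DataFrame(columns=[*names, *META_COLUMNS])
        return empty.astype({"label": int, "repetition": int}, errors="ignore")

    starts = np.array([win.start for win in windows])
    cols: list[np.ndarray] = []
    for ch in channels:
        sw = sliding_window_view(rec.data[:, ch], w)[starts]
        if rec.modality[ch] == "sEMG":
            cols.append(_semg_features(sw))
        else:
            cols.append(_pfmg_features(sw))
    table = pd.DataFrame(np.hstack(cols), columns=names)
    table["label"] = [win.label for win in windows]
    table["repetition"] = [win.repetition for win in windows]
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature (non-metadata) columns of a feature table."""
    return [c for c in table.columns if c not in META_COLUMNS]
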