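"""Gesture recognition: repetition-based splits, seeded random forests, and the
per-combination accuracy table that channel selection consumes.

For an 8-channel recording evaluated over 3-channel combinations, the result is
a :class:`ComboTable` with 56 rows, each carrying the combination's aggregated
DQI 5-vector (computed on the training repetitions only, so selection never
peeks at test data) and its measured test accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ConfigurationError, ValidationError
from .features import META_COLUMNS, build_feature_table, feature_columns
from .quality import INDEX_NAMES, aggregate_combo, profile_recording
from .recording import Recording

__all__ = [
    "ComboTable",
    "split_by_repetition",
    "train_and_score",
    "accuracy_all_combos",
]


@dataclass
class ComboTable:
    """Per-combination DQI vectors and measured accuracies for one subject.

    ``combos`` are sorted tuples of selection-unit indices in lexicographic
    order; ``dqi`` is the matching ``(n_combos, 5)`` matrix (column order
    :data:`~dqiselect.quality.INDEX_NAMES`); ``accuracy`` holds fractions in
    ``[0, 1]``.
    """

    subject_id: str
    combos: list[tuple[int, ...]]
    dqi: np.ndarray
    accuracy: np.ndarray

    def __post_init__(self) -> None:
        self.combos = [tuple(int(c) for c in combo) for combo in self.combos]
        self.dqi = np.asarray(self.dqi, dtype=float)
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        n = len(self.combos)
        if len(set(self.combos)) != n:
            raise ValidationError("combo list contains duplicates")
        if any(tuple(sorted(c)) != c for c in self.combos):
            raise ValidationError("each combo must be a sorted tuple of indices")
        if self.dqi.shape != (n, len(INDEX_NAMES)):
            raise ValidationError(
                f"dqi must be ({n} x {len(INDEX_NAMES)}), got {self.dqi.shape}"
            )
        if self.accuracy.shape != (n,):
            raise ValidationError(f"accuracy must have {n} entries")
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise ValidationError("accuracies must lie in [0, 1]")

    @property
    def n_combos(self) -> int:
        return len(self.combos)

    def to_frame(self) -> pd.DataFrame:
        k = len(self.combos[0]) if self.combos else 0
        frame = pd.DataFrame(self.combos, columns=[f"ch_{'abc'[i] if i < 3 else i}" for i in range(k)])
        for j, name in enumerate(INDEX_NAMES):
            frame[name] = self.dqi[:, j]
        frame["accuracy"] = self.accuracy
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, subject_id: str) -> "ComboTable":
        combo_cols = [c for c in frame.columns if c.startswith("ch_")]
        combos = [tuple(int(v) for v in row) for row in frame[combo_cols].to_numpy()]
        return cls(
            subject_id=subject_id,
            combos=combos,
            dqi=frame[list(INDEX_NAMES)].to_numpy(dtype=float),
            accuracy=frame["accuracy"].to_numpy(dtype=float),
        )


def split_by_repetition(
    table: pd.DataFrame, train_reps: Iterable[int], test_reps: Iterable[int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition feature-table rows by repetition id; no row lands in both splits.

    Rows whose repetition belongs to neither set (e.g. unassigned rest windows
    with repetition 0) are excluded from both.
    """
    train_set = set(int(r) for r in train_reps)
    test_set = set(int(r) for r in test_reps)
    overlap = train_set & test_set
    if overlap:
        raise ConfigurationError(
            f"train and test repetition sets overlap: {sorted(overlap)}"
        )
    if not train_set or not test_set:
        raise ConfigurationError("both repetition sets must be non-empty")
    train = table[table["repetition"].isin(train_set)]
    test = table[table["repetition"].isin(test_set)]
    if train.empty or test.empty:
        raise ValidationError("a split produced an empty partition; check repetition ids")
    return train, test


def train_and_score(
    train: pd.DataFrame, test: pd.DataFrame, seed: int = 0
) -> float:
    """Fit a seeded 100-tree random forest on the training windows and return
    the fraction of correctly classified test windows."""
    if train.empty or test.empty:
        raise ValidationError("train and test tables must both be non-empty")
    cols = feature_columns(train)
    y_train = train["label"].to_numpy()
    if len(np.unique(y_train)) < 2:
        raise ValidationError("training set contains a single class; cannot fit")
    clf = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    clf.fit(train[cols].to_numpy(), y_train)
    pred = clf.predict(test[cols].to_numpy())
    return float(np.mean(pred == test["label"].to_numpy()))


def _resolve_units(
    units: Sequence[Sequence[int]] | None, n_channels: int
) -> list[tuple[int, ...]]:
    if units is None:
        return [(c,) for c in range(n_channels)]
    return [tuple(int(c) for c in u) for u in units]


def accuracy_all_combos(
    rec: Recording,
    train_reps: Iterable[int],
    test_reps: Iterable[int],
    *,
    seed: int = 0,
    k: int = 3,
    units: Sequence[Sequence[int]] | None = None,
    win_ms: float = 200.0,
    stride_ms: float = 40.0,
    include_rest: bool = True,
    nperseg: int | None = None,
) -> ComboTable:
    """Evaluate every k-of-n selection-unit combination of one recording.

    A selection unit is a single channel by default, or a co-located sensor
    group (e.g. an sEMG-pFMG pair) when ``units`` lists channel-index groups.
    For each combination the classifier sees only that combination's feature
    columns; its DQI vector is the mean of the member channels' per-channel
    indices computed on the training repetitions.
    """
    from .selection import enumerate_combos  # local import avoids a module cycle

    units_resolved = _resolve_units(units, rec.n_channels)
    if k > len(units_resolved):
        raise ConfigurationError(
            f"cannot choose {k} of {len(units_resolved)} selection units"
        )
    train_reps = sorted(set(int(r) for r in train_reps))
    table = build_feature_table(
        rec, win_ms=win_ms, stride_ms=stride_ms, include_rest=include_rest
    )
    train, test = split_by_repetition(table, train_reps, test_reps)
    profile = profile_recording(rec, scope=train_reps, nperseg=nperseg)

    combos = enumerate_combos(len(units_resolved), k)
    dqi = np.empty((len(combos), len(INDEX_NAMES)))
    acc = np.empty(len(combos))
    for i, combo in enumerate(combos):
        members = [c for u in combo for c in units_resolved[u]]
        cols = [
            col
            for ch in members
            for col in table.columns
            if col.startswith(f"ch{ch}_")
        ]
        keep = [*cols, *META_COLUMNS]
        acc[i] = train_and_score(train[keep], test[keep], seed=seed)
        dqi[i] = aggregate_combo(profile, members)
    return ComboTable(subject_id=rec.subject_id, combos=combos, dqi=dqi, accuracy=acc)
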