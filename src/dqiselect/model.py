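"""Model/Results front door for DQI-driven channel selection.

Mirrors the fit-and-summarize idiom of statistical modelling packages: build a
:class:`ChannelSelectionModel` from per-subject combination tables (or directly
from recordings), call :meth:`~ChannelSelectionModel.fit`, and read estimates,
uncertainties and diagnostics off the returned
:class:`ChannelSelectionResults`.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .recognize import ComboTable, accuracy_all_combos
from .recording import Recording
from .selection import ALPHA_DEFAULT, SelectionResult, loso_run

__all__ = ["ChannelSelectionModel", "ChannelSelectionResults"]


class ChannelSelectionModel:
    """Leave-one-subject-out channel selection over a cohort of combination tables.

    Parameters
    ----------
    tables : sequence of ComboTable
        One complete table per subject: for every candidate channel
        combination, its aggregated DQI 5-vector and measured accuracy.
    method : {"ml", "correlation"}
        The selection path: accuracy-on-DQI regression, or significance-gated
        correlation weights.
    regressor : {"linear", "forest", "svm"}
        Regressor backing the ML path (ignored for the correlation path).
    alpha : float
        Significance level gating the correlation weights.
    normalize : bool
        Min-max normalize DQIs across combinations before weighting
        (correlation path only).
    """

    def __init__(
        self,
        tables: Sequence[ComboTable],
        method: str = "ml",
        regressor: str = "linear",
        alpha: float = ALPHA_DEFAULT,
        normalize: bool = False,
    ):
        self.tables = list(tables)
        if method not in ("ml", "correlation"):
            raise ConfigurationError(f"unknown method {method!r}")
        self.method = method
        self.regressor = regressor
        self.alpha = alpha
        self.normalize = normalize

    @classmethod
    def from_recordings(
        cls,
        recordings: Sequence[Recording],
        train_reps: Iterable[int],
        test_reps: Iterable[int],
        method: str = "ml",
        seed: int = 0,
        **kwargs,
    ) -> "ChannelSelectionModel":
        """Build the per-subject combination tables from raw recordings.

        Extra keyword arguments are split between the table builder
        (``k``, ``units``, ``win_ms``, ``stride_ms``, ``include_rest``,
        ``nperseg``) and the model constructor (``regressor``, ``alpha``,
        ``normalize``).
        """
        model_keys = {"regressor", "alpha", "normalize"}
        model_kwargs = {k: v for k, v in kwargs.items() if k in model_keys}
        table_kwargs = {k: v for k, v in kwargs.items() if k not in model_keys}
        tables = [
            accuracy_all_combos(rec, train_reps, test_reps, seed=seed, **table_kwargs)
            for rec in recordings
        ]
        return cls(tables, method=method, **model_kwargs)

    def fit(self, seed: int = 0) -> "ChannelSelectionResults":
        """Run the LOSO evaluation and wrap it in a results object."""
        result = loso_run(
            self.tables,
            method=self.method,
            regressor=self.regressor,
            seed=seed,
            alpha=self.alpha,
            normalize=self.normalize,
        )
        return ChannelSelectionResults(self, result)


class ChannelSelectionResults:
    """Fitted LOSO selection: per-fold choices, accuracies, and significance."""

    def __init__(self, model: ChannelSelectionModel, result: SelectionResult):
        self.model = model
        self._result = result

    # -- plain accessors ----------------------------------------------------
    @property
    def method(self) -> str:
        return self._result.method

    @property
    def selected_combos(self) -> list[tuple[int, ...]]:
        return self._result.selected_combos

    @property
    def selected_accuracy(self) -> np.ndarray:
        return self._result.selected_accuracy

    @property
    def random_accuracy(self) -> np.ndarray:
        return self._result.random_accuracy

    @property
    def mean_selected(self) -> float:
        return self._result.mean_selected

    @property
    def mean_random(self) -> float:
        return self._result.mean_random

    @property
    def t_stat(self) -> float:
        return self._result.t_stat

    @property
    def p_value(self) -> float:
        return self._result.p_value

    @property
    def fold_details(self) -> list[dict]:
        return self._result.fold_details

    def to_frame(self) -> pd.DataFrame:
        """One row per held-out subject."""
        return pd.DataFrame(
            {
                "subject_id": self._result.subject_ids,
                "selected_combo": [str(c) for c in self._result.selected_combos],
                "selected_accuracy": self._result.selected_accuracy,
                "random_accuracy": self._result.random_accuracy,
            }
        )

    def to_dict(self) -> dict:
        return self._result.to_dict()

    def summary(self) -> str:
        """Human-readable per-fold table with means and the paired t-test."""
        return self._result.summary()

    def plot(self, ax=None):
        """Bar chart of selected vs random accuracy per held-out subject."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3.2))
        idx = np.arange(len(self._result.subject_ids))
        ax.bar(idx - 0.2, 100 * self.selected_accuracy, width=0.4, label="selected")
        ax.bar(idx + 0.2, 100 * self.random_accuracy, width=0.4, label="random")
        ax.set_xticks(idx, self._result.subject_ids, rotation=45)
        ax.set_ylabel("accuracy [%]")
        ax.set_title(f"{self.method} channel selection (LOSO)")
        ax.legend()
        return ax

    def __repr__(self) -> str:
        return (
            f"<ChannelSelectionResults method={self.method!r} "
            f"mean_selected={self.mean_selected:.3f} mean_random={self.mean_random:.3f} "
            f"p={self.p_value:.3g}>"
        )
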