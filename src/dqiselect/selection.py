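"""Channel-subset selection from data quality indices.

Two selection paths, both evaluated with leave-one-subject-out (LOSO)
cross-validation over a cohort of per-subject :class:`~dqiselect.recognize.ComboTable`s:

* **ML-based** — regress per-combination recognition accuracy on the
  combination's five aggregated DQIs over the training subjects
  (``A = b0 + b1 d1 + ... + b5 d5`` for the linear model; seeded random-forest
  and SVR drop-ins behind the same interface), predict the accuracy of every
  combination of the held-out subject, and pick the argmax.
* **Correlation-based** — Pearson-correlate each DQI with accuracy over the
  training subjects, turn the statistically significant correlations
  (p < 0.05) into signed weights normalized by the sum of their absolute
  values, score every held-out combination by the weighted DQI sum, and pick
  the argmax.

The achieved accuracy of each fold is the held-out subject's *measured*
accuracy for the selected combination.  Baselines: the exact expectation of
uniformly random selection (the mean of all combination accuracies) and a
feature-importance ranking from a forest trained on all channels.  Paired
t-tests across subjects quantify the improvement over random selection.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ValidationError

ALPHA_DEFAULT = 0.05

__all__ = [
    "RegressionModel",
    "FittedRegressor",
    "WeightVector",
    "SelectionResult",
    "enumerate_combos",
    "fit_dqi_accuracy_regression",
    "predict_select",
    "pearson",
    "corr_weights",
    "weighted_select",
    "random_baseline",
    "feature_importance_baseline",
    "paired_ttest",
    "loso_run",
]


def enumerate_combos(n: int = 8, k: int = 3) -> list[tuple[int, ...]]:
    """All k-subsets of {0..n-1} as sorted tuples in lexicographic order."""
    if not 0 < k <= n:
        raise ConfigurationError(f"need 0 < k <= n, got k={k}, n={n}")
    return list(itertools.combinations(range(n), k))


# ---------------------------------------------------------------------------
# ML-based path
# ---------------------------------------------------------------------------

@dataclass
class RegressionModel:
    """Linear DQI-to-accuracy model: intercept, one slope per index, fit diagnostics."""

    intercept: float
    coefs: np.ndarray  # (5,)
    r_squared: float
    n_obs: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.coefs = np.asarray(self.coefs, dtype=float)
        if self.coefs.shape != (5,):
            raise ValidationError(f"expected 5 coefficients, got {self.coefs.shape}")
        if not (np.isfinite(self.intercept) and np.all(np.isfinite(self.coefs))):
            raise ValidationError("regression parameters must be finite")

    def predict(self, dqi: np.ndarray) -> np.ndarray:
        dqi = np.asarray(dqi, dtype=float)
        return self.intercept + dqi @ self.coefs


@dataclass
class FittedRegressor:
    """Opaque wrapper giving non-linear regressors the RegressionModel contract."""

    estimator: object
    n_obs: int

    def predict(self, dqi: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(dqi, dtype=float)))


def fit_dqi_accuracy_regression(
    tables: Sequence, regressor: str = "linear", seed: int = 0
):
    """Fit the accuracy ~ DQI relationship on pooled training-subject tables.

    ``tables`` is a sequence of ComboTables (anything with ``dqi`` and
    ``accuracy`` attributes).  The linear path is ordinary least squares via a
    minimum-norm solve, so a rank-deficient design degrades gracefully (a
    warning is raised and the model flagged degenerate).
    """
    if not tables:
        raise ValidationError("at least one training table is required")
    x = np.vstack([np.asarray(t.dqi, dtype=float) for t in tables])
    y = np.concatenate([np.asarray(t.accuracy, dtype=float) for t in tables])

    if regressor == "linear":
        if len(y) < 6:
            raise ValidationError(
                f"linear fit needs at least 6 pooled rows, got {len(y)}"
            )
        design = np.column_stack([np.ones(len(y)), x])
        params, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        degenerate = rank < design.shape[1]
        if degenerate:
            warnings.warn(
                "rank-deficient DQI design matrix; coefficients are the "
                "minimum-norm solution"
            )
        resid = y - design @ params
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        return RegressionModel(
            intercept=float(params[0]),
            coefs=params[1:],
            r_squared=r2,
            n_obs=len(y),
            degenerate=degenerate,
        )
    if regressor == "forest":
        from sklearn.ensemble import RandomForestRegressor

        est = RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1)
        est.fit(x, y)
        return FittedRegressor(estimator=est, n_obs=len(y))
    if regressor == "svm":
        from sklearn.svm import SVR

        est = SVR()
        est.fit(x, y)
        return FittedRegressor(estimator=est, n_obs=len(y))
    raise ConfigurationError(
        f"unknown regressor {regressor!r}; expected 'linear', 'forest' or 'svm'"
    )


def predict_select(model, combo_dqis: np.ndarray, combos: Sequence[tuple[int, ...]]):
    """Predict accuracy for every combination and return the argmax.

    Ties resolve to the lexicographically smallest combination because the
    combo list is lexicographically ordered and ``argmax`` keeps the first
    maximum.
    """
    combo_dqis = np.asarray(combo_dqis, dtype=float)
    if len(combo_dqis) != len(combos):
        raise ValidationError("one DQI vector per combination is required")
    scores = model.predict(combo_dqis)
    j_star = int(np.argmax(scores))
    return j_star, tuple(combos[j_star])


# ---------------------------------------------------------------------------
# Correlation-based path
# ---------------------------------------------------------------------------

def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValidationError("correlation needs at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined for a zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class WeightVector:
    """Per-index selection weights derived from significance-gated correlations."""

    weights: np.ndarray  # (5,)
    rho: np.ndarray  # (5,)
    pvalues: np.ndarray  # (5,)
    fallback_uniform: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        for name, arr in (("weights", self.weights), ("rho", self.rho), ("pvalues", self.pvalues)):
            if arr.shape != (5,):
                raise ValidationError(f"{name} must have exactly 5 entries")


def corr_weights(
    rho: Sequence[float], pvalues: Sequence[float], alpha: float = ALPHA_DEFAULT
) -> WeightVector:
    """Turn per-index correlations into selection weights.

    Indices whose correlation is significant (p < alpha) get
    ``w_l = rho_l / sum_m |rho_m|`` over the significant set (signs preserved,
    so the absolute weights sum to one); the rest get zero.  If nothing is
    significant the weights fall back to uniform 1/5 with a warning, keeping
    the weighted score usable.
    """
    rho = np.asarray(rho, dtype=float)
    pvalues = np.asarray(pvalues, dtype=float)
    if rho.shape != (5,) or pvalues.shape != (5,):
        raise ValidationError("exactly 5 correlation/p-value pairs are required")
    significant = pvalues < alpha
    weights = np.zeros(5)
    fallback = False
    if significant.any():
        denom = float(np.sum(np.abs(rho[significant])))
        if denom > 0:
            weights[significant] = rho[significant] / denom
        else:
            fallback = True
    else:
        fallback = True
    if fallback:
        warnings.warn(
            "no data quality index is significantly correlated with accuracy; "
            "falling back to uniform weights"
        )
        weights = np.full(5, 0.2)
    return WeightVector(weights=weights, rho=rho, pvalues=pvalues, fallback_uniform=fallback)


def weighted_select(
    weights: WeightVector | Sequence[float],
    combo_dqis: np.ndarray,
    combos: Sequence[tuple[int, ...]],
    normalize: bool = False,
):
    """Score each combination by the weighted DQI sum and return the argmax.

    With ``normalize=True`` each index is min-max scaled across the candidate
    combinations before weighting (useful because the indices mix dB and ratio
    scales); the default applies the weights to the raw values.
    """
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights, dtype=float)
    combo_dqis = np.asarray(combo_dqis, dtype=float)
    if len(combo_dqis) != len(combos):
        raise ValidationError("one DQI vector per combination is required")
    values = combo_dqis
    if normalize:
        lo = values.min(axis=0)
        span = values.max(axis=0) - lo
        span[span == 0] = 1.0
        values = (values - lo) / span
    scores = values @ w
    j_star = int(np.argmax(scores))
    return j_star, tuple(combos[j_star])


# ---------------------------------------------------------------------------
# Baselines and statistics
# ---------------------------------------------------------------------------

def random_baseline(
    table, n_draws: int | None = None, seed: int | None = None
) -> float:
    """Expected accuracy of uniformly random combination choice.

    The default is the exact expectation — the arithmetic mean of all
    combination accuracies, every one of which is already measured.  Passing
    ``n_draws`` switches to a seeded Monte-Carlo mean over that many uniform
    draws.
    """
    acc = np.asarray(table.accuracy, dtype=float)
    if n_draws is None:
        return float(acc.mean())
    rng = np.random.default_rng(seed)
    return float(acc[rng.integers(0, len(acc), size=n_draws)].mean())


def feature_importance_baseline(
    rec,
    train_reps: Iterable[int],
    test_reps: Iterable[int],
    *,
    seed: int = 0,
    k: int = 3,
    units: Sequence[Sequence[int]] | None = None,
    win_ms: float = 200.0,
    stride_ms: float = 40.0,
    include_rest: bool = True,
) -> tuple[tuple[int, ...], float, np.ndarray]:
    """Impurity-importance channel ranking: the standard comparison baseline.

    A seeded forest is trained on the features of *all* selection units; each
    unit's importance is the sum of the impurity importances of its feature
    columns (sklearn normalizes these to total 1).  The top-k units form the
    selected combination, whose accuracy is then measured as usual.
    Returns ``(combo, accuracy, per-unit importances)``.
    """
    from sklearn.ensemble import RandomForestClassifier

    from .features import META_COLUMNS, build_feature_table, feature_columns
    from .recognize import _resolve_units, split_by_repetition, train_and_score

    units_resolved = _resolve_units(units, rec.n_channels)
    if len(units_resolved) < k + 1:
        raise ValidationError(
            f"need more than {k} selection units for a meaningful top-{k} ranking"
        )
    table = build_feature_table(
        rec, win_ms=win_ms, stride_ms=stride_ms, include_rest=include_rest
    )
    train, test = split_by_repetition(table, train_reps, test_reps)
    cols = feature_columns(table)
    clf = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    clf.fit(train[cols].to_numpy(), train["label"].to_numpy())
    importance_by_col = dict(zip(cols, clf.feature_importances_))

    unit_importance = np.zeros(len(units_resolved))
    for u, members in enumerate(units_resolved):
        for ch in members:
            unit_importance[u] += sum(
                v for c, v in importance_by_col.items() if c.startswith(f"ch{ch}_")
            )
    # stable sort: ties resolve to the lower unit index
    top = np.argsort(-unit_importance, kind="stable")[:k]
    combo = tuple(sorted(int(u) for u in top))
    members = [c for u in combo for c in units_resolved[u]]
    keep = [
        *[c for ch in members for c in cols if c.startswith(f"ch{ch}_")],
        *META_COLUMNS,
    ]
    acc = train_and_score(train[keep], test[keep], seed=seed)
    return combo, acc, unit_importance


def paired_ttest(
    selected: Sequence[float], baseline: Sequence[float]
) -> tuple[float, float]:
    """Classical paired t-test on per-subject differences, two-sided p.

    All-zero differences return ``(0.0, 1.0)`` by convention.
    """
    a = np.asarray(selected, dtype=float)
    b = np.asarray(baseline, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired samples must be 1-D and of equal length")
    if len(a) < 2:
        raise ValidationError("paired t-test needs at least 2 subjects")
    if np.allclose(a - b, 0.0):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Leave-one-subject-out evaluation
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Per-fold selections, achieved accuracies, baselines and significance."""

    method: str
    subject_ids: list[str]
    selected_combos: list[tuple[int, ...]]
    selected_accuracy: np.ndarray
    random_accuracy: np.ndarray
    t_stat: float
    p_value: float
    fold_details: list[dict] = field(default_factory=list)

    @property
    def mean_selected(self) -> float:
        return float(np.mean(self.selected_accuracy))

    @property
    def mean_random(self) -> float:
        return float(np.mean(self.random_accuracy))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "subject_ids": self.subject_ids,
            "selected_combos": [list(c) for c in self.selected_combos],
            "selected_accuracy": [float(a) for a in self.selected_accuracy],
            "random_accuracy": [float(a) for a in self.random_accuracy],
            "mean_selected": self.mean_selected,
            "mean_random": self.mean_random,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
        }

    def summary(self) -> str:
        lines = [
            f"LOSO channel selection -- method: {self.method}",
            f"{'subject':>10} {'combo':>12} {'selected %':>11} {'random %':>9}",
        ]
        for sid, combo, acc, rnd in zip(
            self.subject_ids, self.selected_combos, self.selected_accuracy, self.random_accuracy
        ):
            lines.append(
                f"{sid:>10} {str(combo):>12} {100 * acc:>10.2f} {100 * rnd:>8.2f}"
            )
        lines.append(
            f"{'mean':>10} {'':>12} {100 * self.mean_selected:>10.2f} "
            f"{100 * self.mean_random:>8.2f}"
        )
        lines.append(
            f"paired t-test vs random: t = {self.t_stat:.3f}, p = {self.p_value:.4g}"
        )
        return "\n".join(lines)


def loso_run(
    tables: Sequence,
    method: str = "ml",
    regressor: str = "linear",
    seed: int = 0,
    alpha: float = ALPHA_DEFAULT,
    normalize: bool = False,
) -> SelectionResult:
    """Leave-one-subject-out evaluation of one selection method.

    Each subject is held out once; the selector is fitted on the remaining
    subjects' combination tables and the held-out subject's *measured*
    accuracy of the chosen combination is recorded, alongside the random
    baseline (the mean of that subject's combination accuracies).
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValidationError("LOSO needs at least 2 subjects")
    if method not in ("ml", "correlation"):
        raise ConfigurationError(f"unknown method {method!r}; expected 'ml' or 'correlation'")
    ref_combos = tables[0].combos
    for t in tables:
        if t.combos != ref_combos:
            raise ValidationError(
                f"subject {t.subject_id}: combination table incomplete or "
                "ordered differently from the cohort"
            )

    subject_ids: list[str] = []
    combos_sel: list[tuple[int, ...]] = []
    acc_sel: list[float] = []
    acc_rnd: list[float] = []
    details: list[dict] = []
    for i, held_out in enumerate(tables):
        training = tables[:i] + tables[i + 1 :]
        if method == "ml":
            model = fit_dqi_accuracy_regression(training, regressor=regressor, seed=seed)
            j_star, combo = predict_select(model, held_out.dqi, held_out.combos)
            detail = {"regressor": regressor}
            if isinstance(model, RegressionModel):
                detail.update(
                    intercept=model.intercept,
                    coefs=model.coefs.tolist(),
                    r_squared=model.r_squared,
                )
        else:
            pooled_d = np.vstack([t.dqi for t in training])
            pooled_a = np.concatenate([t.accuracy for t in training])
            rho = np.empty(5)
            pvals = np.empty(5)
            for l in range(5):
                rho[l], pvals[l] = pearson(pooled_d[:, l], pooled_a)
            wv = corr_weights(rho, pvals, alpha=alpha)
            j_star, combo = weighted_select(wv, held_out.dqi, held_out.combos, normalize=normalize)
            detail = {
                "weights": wv.weights.tolist(),
                "rho": wv.rho.tolist(),
                "pvalues": wv.pvalues.tolist(),
                "fallback_uniform": wv.fallback_uniform,
            }
        subject_ids.append(held_out.subject_id)
        combos_sel.append(combo)
        acc_sel.append(float(held_out.accuracy[j_star]))
        acc_rnd.append(random_baseline(held_out))
        details.append(detail)

    t_stat, p_value = paired_ttest(acc_sel, acc_rnd)
    return SelectionResult(
        method=method,
        subject_ids=subject_ids,
        selected_combos=combos_sel,
        selected_accuracy=np.asarray(acc_sel),
        random_accuracy=np.asarray(acc_rnd),
        t_stat=t_stat,
        p_value=p_value,
        fold_details=details,
    )
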