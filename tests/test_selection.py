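"""Selection paths, baselines, LOSO evaluation and significance testing."""

import numpy as np
import pytest

from dqiselect import (
    ComboTable,
    ConfigurationError,
    RegressionModel,
    ValidationError,
    corr_weights,
    enumerate_combos,
    feature_importance_baseline,
    fit_dqi_accuracy_regression,
    loso_run,
    paired_ttest,
    pearson,
    predict_select,
    random_baseline,
    weighted_select,
)


def random_table(seed, subject_id="S", n=8, k=3):
    rng = np.random.default_rng(seed)
    combos = enumerate_combos(n, k)
    return ComboTable(
        subject_id=subject_id,
        combos=combos,
        dqi=rng.normal(10, 5, size=(len(combos), 5)),
        accuracy=rng.uniform(0.3, 0.99, len(combos)),
    )


class TestEnumerateCombos:
    def test_counts(self):
        assert len(enumerate_combos(8, 3)) == 56
        assert enumerate_combos(3, 3) == [(0, 1, 2)]

    def test_matches_triple_loop(self):
        expected = [
            (a, b, c)
            for a in range(6)
            for b in range(a + 1, 6)
            for c in range(b + 1, 6)
        ]
        assert enumerate_combos(6, 3) == expected

    def test_k_greater_than_n_rejected(self):
        with pytest.raises(ConfigurationError):
            enumerate_combos(3, 4)


class TestRegression:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(31)
        table = random_table(31)
        table.accuracy = 0.1 + 0.01 * table.dqi[:, 0]
        model = fit_dqi_accuracy_regression([table])
        assert model.intercept == pytest.approx(0.1, abs=1e-8)
        assert model.coefs[0] == pytest.approx(0.01, abs=1e-8)
        assert np.all(np.abs(model.coefs[1:]) < 1e-8)

    def test_constant_accuracy_gives_zero_slopes(self):
        table = random_table(32)
        table.accuracy = np.full(len(table.accuracy), 0.8)
        model = fit_dqi_accuracy_regression([table])
        assert model.intercept == pytest.approx(0.8, abs=1e-8)
        assert np.all(np.abs(model.coefs) < 1e-8)

    def test_matches_normal_equations_oracle(self):
        table = random_table(33)
        model = fit_dqi_accuracy_regression([table])
        x = np.column_stack([np.ones(len(table.accuracy)), table.dqi])
        beta = np.linalg.solve(x.T @ x, x.T @ table.accuracy)
        assert model.intercept == pytest.approx(beta[0], abs=1e-8)
        assert np.allclose(model.coefs, beta[1:], atol=1e-8)

    def test_nonlinear_regressors_share_the_contract(self):
        tables = [random_table(s) for s in (34, 35)]
        for name in ("forest", "svm"):
            model = fit_dqi_accuracy_regression(tables, regressor=name, seed=0)
            pred = model.predict(tables[0].dqi)
            assert pred.shape == (56,)
            assert np.all(np.isfinite(pred))


class TestPredictSelect:
    def test_snr_only_model_selects_max_snr_combo(self):
        table = random_table(41)
        model = RegressionModel(intercept=0.0, coefs=np.array([1.0, 0, 0, 0, 0]),
                                r_squared=1.0, n_obs=56)
        j, combo = predict_select(model, table.dqi, table.combos)
        assert j == int(np.argmax(table.dqi[:, 0]))

    def test_tie_breaks_to_first_lexicographic_combo(self):
        table = random_table(42)
        model = RegressionModel(intercept=0.5, coefs=np.zeros(5), r_squared=0.0, n_obs=56)
        j, combo = predict_select(model, table.dqi, table.combos)
        assert j == 0 and combo == (0, 1, 2)

    def test_matches_bruteforce_argmax(self):
        rng = np.random.default_rng(43)
        for _ in range(20):
            table = random_table(rng.integers(1e6))
            coefs = rng.normal(size=5)
            model = RegressionModel(intercept=rng.normal(), coefs=coefs,
                                    r_squared=0.0, n_obs=56)
            preds = [model.intercept + float(np.dot(coefs, d)) for d in table.dqi]
            j, _ = predict_select(model, table.dqi, table.combos)
            assert j == int(np.argmax(preds))


class TestPearsonAndWeights:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(51)
        x, y = rng.normal(size=50), rng.normal(size=50)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson(x, y)[0] == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson(np.ones(10), np.arange(10.0))

    def test_single_significant_index(self):
        wv = corr_weights([0.6, 0.1, 0.1, 0.1, 0.1], [0.01, 0.5, 0.5, 0.5, 0.5])
        assert np.allclose(wv.weights, [1.0, 0, 0, 0, 0])

    def test_none_significant_falls_back_to_uniform(self):
        with pytest.warns(UserWarning, match="uniform"):
            wv = corr_weights([0.6] * 5, [0.5] * 5)
        assert np.allclose(wv.weights, 0.2)
        assert wv.fallback_uniform

    def test_mixed_sign_normalization_preserves_sign(self):
        rho = [0.5, -0.25, 0.0, 0.0, 0.25]
        p = [0.01, 0.01, 0.5, 0.5, 0.01]
        wv = corr_weights(rho, p)
        assert np.allclose(wv.weights, [0.5, -0.25, 0.0, 0.0, 0.25])
        assert np.sum(np.abs(wv.weights)) == pytest.approx(1.0)


class TestWeightedSelect:
    def test_snr_weight_selects_max_snr(self):
        table = random_table(61)
        j, _ = weighted_select(np.array([1.0, 0, 0, 0, 0]), table.dqi, table.combos)
        assert j == int(np.argmax(table.dqi[:, 0]))

    def test_identical_dqis_break_tie_to_first(self):
        combos = enumerate_combos(5, 3)
        dqi = np.tile(np.arange(5.0), (len(combos), 1))
        j, combo = weighted_select(np.ones(5) / 5, dqi, combos)
        assert j == 0 and combo == (0, 1, 2)

    def test_matches_bruteforce_weighted_sum(self):
        rng = np.random.default_rng(62)
        for _ in range(20):
            table = random_table(rng.integers(1e6))
            w = rng.normal(size=5)
            scores = [float(np.dot(w, d)) for d in table.dqi]
            j, _ = weighted_select(w, table.dqi, table.combos)
            assert j == int(np.argmax(scores))

    def test_minmax_normalization_mode(self):
        table = random_table(63)
        w = np.array([0.5, 0.5, 0, 0, 0])
        lo, hi = table.dqi.min(axis=0), table.dqi.max(axis=0)
        norm = (table.dqi - lo) / np.where(hi - lo == 0, 1, hi - lo)
        expected = int(np.argmax(norm @ w))
        j, _ = weighted_select(w, table.dqi, table.combos, normalize=True)
        assert j == expected


class TestBaselinesAndStats:
    def test_random_baseline_constant(self):
        table = random_table(71)
        table.accuracy = np.full(56, 0.5)
        assert random_baseline(table) == pytest.approx(0.5)

    def test_random_baseline_is_exact_mean(self):
        table = random_table(72)
        assert random_baseline(table) == pytest.approx(float(table.accuracy.mean()))

    def test_monte_carlo_agrees_with_exact(self):
        table = random_table(73)
        exact = random_baseline(table)
        mc = random_baseline(table, n_draws=10_000, seed=1)
        se = float(table.accuracy.std()) / np.sqrt(10_000)
        assert abs(mc - exact) < 3 * se + 1e-6

    def test_paired_ttest_identity(self):
        t, p = paired_ttest([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert (t, p) == (0.0, 1.0)

    def test_paired_ttest_closed_form(self):
        diffs = np.array([0.1, 0.2, 0.3])
        base = np.array([0.5, 0.5, 0.5])
        t, p = paired_ttest(base + diffs, base)
        expected_t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(3))
        assert t == pytest.approx(expected_t, abs=1e-9)
        from scipy.stats import t as tdist

        assert p == pytest.approx(2 * tdist.sf(expected_t, df=2), abs=1e-9)

    def test_swapping_flips_t_sign_only(self):
        rng = np.random.default_rng(74)
        a, b = rng.uniform(size=6), rng.uniform(size=6)
        t1, p1 = paired_ttest(a, b)
        t2, p2 = paired_ttest(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestFeatureImportanceBaseline:
    def test_importances_are_normalized(self, mini_cohort):
        recordings, _ = mini_cohort
        combo, acc, imp = feature_importance_baseline(
            recordings[0], (1, 2, 3), (4,), seed=0
        )
        assert np.sum(imp) == pytest.approx(1.0, abs=1e-9)
        assert 0 <= acc <= 1

    def test_informative_channel_ranks_first(self, rng):
        from tests.conftest import make_subject_spec
        from dqiselect import ChannelSpec, NoiseSpec, SubjectSpec, generate_recording

        # channel 2 carries a strong gesture-dependent amplitude; the rest are noise
        channels = []
        for c in range(4):
            gains = (0.4, 1.0, 1.8) if c == 2 else (1.0, 1.0, 1.0)
            channels.append(
                ChannelSpec(
                    gesture_gain=gains,
                    noise_specs=(NoiseSpec("white_gaussian", 1.0),),
                    target_snr_db=15.0 if c == 2 else 0.5,
                )
            )
        spec = SubjectSpec(channels=tuple(channels), n_gestures=3, n_repetitions=2,
                           active_s=0.8, rest_s=0.4)
        rec = generate_recording(spec, seed=5)
        combo, _, imp = feature_importance_baseline(rec, (1,), (2,), seed=0, k=3)
        assert int(np.argmax(imp)) == 2

    def test_deterministic(self, mini_cohort):
        recordings, _ = mini_cohort
        a = feature_importance_baseline(recordings[1], (1, 2, 3), (4,), seed=2)
        b = feature_importance_baseline(recordings[1], (1, 2, 3), (4,), seed=2)
        assert a[0] == b[0] and a[1] == pytest.approx(b[1])


class TestLoso:
    def _consensus_tables(self, n_subjects=4, best=10):
        """Every subject's table peaks (in accuracy and every DQI) at combo `best`."""
        tables = []
        for s in range(n_subjects):
            rng = np.random.default_rng(100 + s)
            combos = enumerate_combos(8, 3)
            dqi = rng.uniform(0, 1, size=(len(combos), 5))
            acc = rng.uniform(0.4, 0.6, len(combos))
            dqi[best] = 10.0
            acc[best] = 0.95
            # accuracy increases with mean DQI so the regression slope is positive
            acc = 0.3 + 0.5 * dqi.mean(axis=1) / dqi.mean(axis=1).max()
            tables.append(ComboTable(f"S{s}", combos, dqi, acc))
        return tables

    def test_fold_count_equals_subjects(self):
        tables = self._consensus_tables(5)
        res = loso_run(tables, method="ml")
        assert len(res.subject_ids) == 5
        assert len(res.selected_combos) == 5

    @pytest.mark.parametrize("method", ["ml", "correlation"])
    def test_dominating_combo_selected_everywhere(self, method):
        tables = self._consensus_tables()
        res = loso_run(tables, method=method)
        best_combo = tables[0].combos[10]
        assert all(c == best_combo for c in res.selected_combos)

    def test_folds_match_manual_composition(self):
        tables = self._consensus_tables(4)
        res = loso_run(tables, method="ml")
        for i in range(4):
            training = tables[:i] + tables[i + 1 :]
            model = fit_dqi_accuracy_regression(training)
            j, combo = predict_select(model, tables[i].dqi, tables[i].combos)
            assert res.selected_combos[i] == combo
            assert res.selected_accuracy[i] == pytest.approx(tables[i].accuracy[j])
            assert res.random_accuracy[i] == pytest.approx(random_baseline(tables[i]))

    def test_held_out_accuracies_never_enter_fitting(self):
        tables = self._consensus_tables(4)
        res_clean = loso_run(tables, method="ml")
        poisoned = [t for t in tables]
        t0 = poisoned[0]
        poisoned[0] = ComboTable(
            t0.subject_id, t0.combos, t0.dqi, np.zeros_like(t0.accuracy) + 0.001
        )
        res_poisoned = loso_run(poisoned, method="ml")
        assert res_poisoned.selected_combos[0] == res_clean.selected_combos[0]

    def test_incomplete_table_names_subject(self):
        tables = self._consensus_tables(3)
        t = tables[1]
        tables[1] = ComboTable(
            "broken", t.combos[:-1], t.dqi[:-1], t.accuracy[:-1]
        )
        with pytest.raises(ValidationError, match="broken"):
            loso_run(tables)

    def test_means_are_arithmetic_means_of_entries(self):
        tables = self._consensus_tables(4)
        res = loso_run(tables, method="correlation")
        assert res.mean_selected == pytest.approx(float(np.mean(res.selected_accuracy)))
        assert res.mean_random == pytest.approx(float(np.mean(res.random_accuracy)))
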