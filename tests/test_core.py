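import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from superpca import (ClinicalOutcome, ExpressionMatrix, ScoreTable, SplitSpec,
                      ValidationError, cross_validate_threshold, fit_pc,
                      make_folds, make_threshold_grid, project, run_superpc,
                      screen_features, simulate_dataset, split_train_test)
from superpca.core import (cox_lr_statistic, linear_lr_statistic,
                           logistic_lr_statistic)

from conftest import random_instance


# ---------------------------------------------------------------------------
# Splitting and folds


class TestSplit:
    def test_deterministic_disjoint_split(self):
        ids = [f"s{i}" for i in range(10)]
        out = ClinicalOutcome("continuous", ids, value=np.arange(10.0))
        spec = SplitSpec(0.7, seed=4)
        tr1, te1 = split_train_test(ids, out, spec)
        tr2, te2 = split_train_test(ids, out, spec)
        assert (tr1, te1) == (tr2, te2)
        assert len(tr1) == 7 and len(te1) == 3
        assert set(tr1).isdisjoint(te1) and set(tr1) | set(te1) == set(ids)

    def test_stratified_split_preserves_class_shares(self):
        ids = [f"s{i}" for i in range(10)]
        out = ClinicalOutcome("binary", ids,
                              label=np.array([0] * 6 + [1] * 4))
        tr, _ = split_train_test(ids, out, SplitSpec(0.5, seed=1, stratify=True))
        lab = {s: l for s, l in zip(ids, out.label)}
        assert sum(lab[s] == 0 for s in tr) == 3
        assert sum(lab[s] == 1 for s in tr) == 2

    def test_empty_test_set_rejected(self):
        ids = ["a", "b", "c"]
        out = ClinicalOutcome("continuous", ids, value=np.arange(3.0))
        with pytest.raises(ValidationError):
            split_train_test(ids, out, SplitSpec(0.9, seed=0))

    def test_folds_stratify_events(self):
        ids = [f"s{i}" for i in range(20)]
        out = ClinicalOutcome("survival", ids, time=np.arange(1.0, 21.0),
                              event=np.array([1, 0] * 10))
        fa = make_folds(ids, out, 5, seed=0)
        ev = {s: e for s, e in zip(ids, out.event)}
        for f in range(1, 6):
            assert sum(ev[s] for s in fa.samples_in(f)) == 2

    def test_more_folds_than_samples_rejected(self):
        ids = ["a", "b", "c", "d"]
        out = ClinicalOutcome("continuous", ids, value=np.arange(4.0))
        with pytest.raises(ValidationError, match="more folds"):
            make_folds(ids, out, 5, seed=0)


# ---------------------------------------------------------------------------
# Grid and screening


class TestGridAndScreening:
    def test_grid_endpoints_are_documented_quantiles(self):
        t = ScoreTable(list("abcd"), np.array([1.0, -2.0, 3.0, -4.0]))
        grid = make_threshold_grid(t, 2)
        np.testing.assert_allclose(grid, [1.0, np.quantile([1, 2, 3, 4], 0.95)])
        assert grid[1] == pytest.approx(3.85)

    def test_grid_strictly_increasing(self):
        rng = np.random.default_rng(0)
        t = ScoreTable([f"g{i}" for i in range(50)], rng.standard_normal(50))
        grid = make_threshold_grid(t, 15)
        assert np.all(np.diff(grid) > 0)

    def test_single_threshold_rejected(self):
        t = ScoreTable(list("ab"), np.array([1.0, 2.0]))
        with pytest.raises(ValidationError):
            make_threshold_grid(t, 1)

    def test_equal_scores_rejected(self):
        t = ScoreTable(list("abc"), np.array([2.0, -2.0, 2.0]))
        with pytest.raises(ValidationError, match="equal"):
            make_threshold_grid(t, 5)

    def test_screening_uses_strict_absolute_threshold(self):
        t = ScoreTable(["f1", "f2", "f3"], np.array([-3.0, 1.0, 2.0]))
        assert screen_features(t, 1.5) == ["f1", "f3"]
        assert screen_features(t, 0.0) == ["f1", "f2", "f3"]
        with pytest.raises(ValidationError, match="removes all"):
            screen_features(t, 3.0)

    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=30),
           st.floats(0, 5), st.floats(0, 5))
    def test_screening_monotonicity(self, scores, t1, t2):
        """A stricter threshold always selects a subset of a looser one."""
        lo, hi = sorted([t1, t2])
        table = ScoreTable([f"g{i}" for i in range(len(scores))], np.array(scores))
        try:
            kept_hi = set(screen_features(table, hi))
        except ValidationError:
            kept_hi = set()
        try:
            kept_lo = set(screen_features(table, lo))
        except ValidationError:
            kept_lo = set()
        assert kept_hi <= kept_lo


# ---------------------------------------------------------------------------
# PC fit and projection


class TestPCFit:
    def test_rank_one_matrix_recovers_direction(self):
        a = np.array([3.0, -1.0, 2.0])
        b = np.array([1.0, -2.0, 0.5, 0.5])  # centered
        X = ExpressionMatrix(["f1", "f2", "f3"], list("wxyz"), np.outer(a, b))
        m = fit_pc(X)
        np.testing.assert_allclose(np.abs(m.loadings), np.abs(a) / np.linalg.norm(a),
                                   atol=1e-10)
        assert m.loadings[np.argmax(np.abs(m.loadings))] > 0
        pc = project(m, X)
        np.testing.assert_allclose(np.abs(pc / np.linalg.norm(pc)),
                                   np.abs(b / np.linalg.norm(b)), atol=1e-10)

    def test_single_feature_collapses_to_centered_values(self):
        X = ExpressionMatrix(["f"], list("abc"), np.array([[1.0, 2.0, 6.0]]))
        m = fit_pc(X)
        np.testing.assert_array_equal(m.loadings, [1.0])
        np.testing.assert_allclose(project(m, X), [-2.0, -1.0, 3.0])

    @pytest.mark.parametrize("seed", range(4))
    def test_loadings_match_eigendecomposition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = ExpressionMatrix([f"f{i}" for i in range(5)],
                             [f"s{i}" for i in range(8)],
                             rng.standard_normal((5, 8)))
        m = fit_pc(X)
        Xc = X.values - X.values.mean(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(Xc @ Xc.T)
        lead = evecs[:, -1]
        assert min(np.abs(m.loadings - lead).max(),
                   np.abs(m.loadings + lead).max()) < 1e-8
        assert np.linalg.norm(m.loadings) == pytest.approx(1.0, abs=1e-12)

    def test_projection_is_self_consistent_and_centered(self):
        rng = np.random.default_rng(7)
        X = ExpressionMatrix([f"f{i}" for i in range(4)],
                             [f"s{i}" for i in range(6)],
                             rng.standard_normal((4, 6)))
        m = fit_pc(X)
        np.testing.assert_array_equal(project(m, X), project(m, X))
        X0 = ExpressionMatrix(X.feature_ids, ["n1", "n2"],
                              np.repeat(m.center[:, None], 2, axis=1))
        np.testing.assert_allclose(project(m, X0), [0.0, 0.0], atol=1e-14)

    def test_missing_selected_feature_named(self):
        rng = np.random.default_rng(7)
        X = ExpressionMatrix(["f1", "f2"], list("abc"), rng.standard_normal((2, 3)))
        m = fit_pc(X)
        X_new = ExpressionMatrix(["f1"], list("de"), np.ones((1, 2)))
        with pytest.raises(ValidationError, match="f2"):
            project(m, X_new)

    def test_heldout_projection_tracks_latent_factor(self):
        ds = simulate_dataset("continuous", 100, 200, 200, effect=0.0, seed=9)
        half = ds.expression.sample_ids[:50]
        other = ds.expression.sample_ids[50:]
        m = fit_pc(ds.expression.subset_samples(half))
        pc = project(m, ds.expression.subset_samples(other))
        r = np.corrcoef(pc, ds.latent[50:])[0, 1]
        assert abs(r) >= 0.99


# ---------------------------------------------------------------------------
# Held-out LR objectives vs established fitters


class TestLikelihoodRatioObjectives:
    def test_cox_lr_matches_lifelines(self):
        import pandas as pd
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(3)
        n = 40
        z = rng.standard_normal(n)
        time = rng.exponential(np.exp(-0.8 * z)) + 1e-4
        event = rng.integers(0, 2, n)
        event[:5] = 1
        df = pd.DataFrame({"t": time, "e": event, "z": z})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="t", event_col="e")
        expected = cph.log_likelihood_ratio_test().test_statistic
        assert cox_lr_statistic(time, event, z) == pytest.approx(expected, rel=1e-5)

    def test_logistic_lr_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        n = 50
        z = rng.standard_normal(n)
        y = rng.binomial(1, 1 / (1 + np.exp(-z)))
        fit = sm.Logit(y, sm.add_constant(z)).fit(disp=0)
        assert logistic_lr_statistic(y, z) == pytest.approx(fit.llr, rel=1e-6)

    def test_linear_lr_matches_rss_formula(self):
        rng = np.random.default_rng(5)
        n = 30
        z = rng.standard_normal(n)
        y = 0.5 * z + rng.standard_normal(n)
        beta, alpha = np.polyfit(z, y, 1)
        rss1 = np.sum((y - alpha - beta * z) ** 2)
        rss0 = np.sum((y - y.mean()) ** 2)
        assert linear_lr_statistic(y, z) == pytest.approx(n * np.log(rss0 / rss1),
                                                          rel=1e-10)

    def test_degenerate_inputs_give_zero(self):
        z = np.ones(10)
        assert cox_lr_statistic(np.arange(1.0, 11), np.ones(10, int), z) == 0.0
        assert logistic_lr_statistic(np.ones(10), np.arange(10.0)) == 0.0
        assert linear_lr_statistic(np.ones(10), np.arange(10.0)) == 0.0


# ---------------------------------------------------------------------------
# Cross-validation


def _cv_setup(seed=3, n=60, genes=200, signal=15, outcome_type="survival"):
    ds = simulate_dataset(outcome_type, n, genes, signal, effect=2.0, seed=seed)
    from superpca import compute_scores
    folds = make_folds(ds.expression.sample_ids, ds.outcome, 5, seed=seed)
    table = compute_scores(ds.expression, ds.outcome)
    grid = make_threshold_grid(table, 10)
    return ds, table, grid, folds


class TestCrossValidation:
    def test_identical_folds_give_bitwise_identical_result(self):
        ds, _, grid, folds = _cv_setup()
        cv1 = cross_validate_threshold(ds.expression, ds.outcome, grid, folds)
        cv2 = cross_validate_threshold(ds.expression, ds.outcome, grid, folds)
        np.testing.assert_array_equal(cv1.statistics, cv2.statistics)
        assert cv1.optimal_threshold == cv2.optimal_threshold

    def test_strong_signal_recovered_at_optimal_threshold(self):
        """With 15 signal genes among 200 the CV threshold keeps >= 80% of them."""
        ds, table, grid, folds = _cv_setup(seed=3)
        cv = cross_validate_threshold(ds.expression, ds.outcome, grid, folds)
        kept = set(screen_features(table, cv.optimal_threshold))
        recall = len(kept & set(ds.signal_feature_ids)) / len(ds.signal_feature_ids)
        assert recall >= 0.8

    def test_leakage_free_fold_training(self):
        """Corrupting a held-out fold must not touch that fold's training fit."""
        ds, _, grid, folds = _cv_setup(n=40, genes=50, signal=8)
        cv = cross_validate_threshold(ds.expression, ds.outcome, grid, folds)
        corrupt_fold = 2
        bad = ds.expression.values.copy()
        pos = {s: i for i, s in enumerate(ds.expression.sample_ids)}
        for s in folds.samples_in(corrupt_fold):
            bad[:, pos[s]] += 100.0 * np.sign(bad[:, pos[s]] + 0.1)
        X_bad = ExpressionMatrix(ds.expression.feature_ids,
                                 ds.expression.sample_ids, bad)
        cv_bad = cross_validate_threshold(X_bad, ds.outcome, grid, folds)
        # fold-2 screening scores were computed without fold 2: unchanged
        np.testing.assert_array_equal(cv.fold_scores[corrupt_fold],
                                      cv_bad.fold_scores[corrupt_fold])
        # its held-out statistics did see the corrupted samples: changed
        assert not np.allclose(cv.statistics[corrupt_fold - 1],
                               cv_bad.statistics[corrupt_fold - 1])
        # every other fold trains on fold 2, so its scores must move
        other = 1 if corrupt_fold != 1 else 3
        assert not np.allclose(cv.fold_scores[other], cv_bad.fold_scores[other])

    def test_zero_event_fold_rejected_with_advice(self):
        ids = [f"s{i}" for i in range(8)]
        rng = np.random.default_rng(0)
        X = ExpressionMatrix(["g1", "g2"], ids, rng.standard_normal((2, 8)))
        out = ClinicalOutcome("survival", ids, time=np.arange(1.0, 9.0),
                              event=np.array([1, 1, 1, 1, 0, 0, 0, 0]))
        from superpca.io_clinical import FoldAssignment
        folds = FoldAssignment({s: 1 if i < 4 else 2 for i, s in enumerate(ids)})
        t = ScoreTable(["g1", "g2"], np.array([1.0, 2.0]))
        grid = make_threshold_grid(t, 2)
        with pytest.raises(ValidationError, match="stratified folds or fewer"):
            cross_validate_threshold(X, out, grid, folds)


# ---------------------------------------------------------------------------
# End-to-end runs


class TestRunSuperPC:
    @pytest.mark.parametrize("outcome_type", ["survival", "continuous", "binary"])
    def test_repeated_runs_identical(self, outcome_type, tmp_path):
        ds = simulate_dataset(outcome_type, 80, 100, 10, effect=2.0, seed=6)
        outs = []
        for name in ("r1", "r2"):
            run_superpc(ds.expression, ds.outcome, split=SplitSpec(0.67, seed=6),
                        n_thresholds=6, n_folds=4, out_dir=tmp_path / name,
                        make_plots=False)
            outs.append((tmp_path / name / "summary.json").read_bytes())
        assert outs[0] == outs[1]

    def test_replay_from_fold_file_is_bit_identical(self, tmp_path):
        ds = simulate_dataset("survival", 80, 100, 10, effect=2.0, seed=8)
        from superpca import read_fold_ids
        run_superpc(ds.expression, ds.outcome, split=SplitSpec(0.67, seed=8),
                    n_thresholds=6, n_folds=4, out_dir=tmp_path / "a",
                    make_plots=False)
        folds = read_fold_ids(tmp_path / "a" / "folds.tsv")
        run_superpc(ds.expression, ds.outcome, folds=folds,
                    n_thresholds=6, out_dir=tmp_path / "b", make_plots=False)
        for f in ("cv_curve.tsv", "summary.json", "model.json", "predictions.tsv"):
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_test_pc_tracks_latent_factor(self):
        ds = simulate_dataset("survival", 150, 500, 20, effect=2.0, seed=7)
        run = run_superpc(ds.expression, ds.outcome, split=SplitSpec(0.67, seed=7),
                          n_thresholds=20, n_folds=5)
        pos = {s: i for i, s in enumerate(ds.expression.sample_ids)}
        u_test = ds.latent[[pos[s] for s in run.test_ids]]
        assert abs(np.corrcoef(u_test, run.test_pc_scores)[0, 1]) >= 0.8

    def test_split_and_folds_mutually_exclusive(self):
        ds = simulate_dataset("continuous", 20, 10, 2, effect=1.0, seed=0)
        with pytest.raises(ValidationError, match="exactly one"):
            run_superpc(ds.expression, ds.outcome)

    def test_model_json_round_trip(self, tmp_path):
        from superpca import SuperPCModel
        ds = simulate_dataset("continuous", 40, 30, 5, effect=2.0, seed=2)
        run = run_superpc(ds.expression, ds.outcome, split=SplitSpec(0.6, seed=2),
                          n_thresholds=5, n_folds=3, out_dir=tmp_path,
                          make_plots=False)
        back = SuperPCModel.from_json(tmp_path / "model.json")
        np.testing.assert_array_equal(back.loadings, run.model.loadings)
        assert back.feature_ids == run.model.feature_ids
        manifest = json.loads((tmp_path / "summary.json").read_text())
        assert 0.0 <= manifest["p_value"] <= 1.0
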