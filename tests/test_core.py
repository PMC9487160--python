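import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import simulate_record_count
from conftest import ConstantClassifier
from elas.core import (
    BaseClassifierRecord,
    ELASClassifier,
    ELASConfig,
    ELASModel,
    SplitState,
    active_sampling_run,
    draw_balanced_seed,
    expected_record_count,
    fit_elas,
    make_internal_folds,
    select_top_k,
)
from elas.learners import LearnerSpec

FAST_CART = LearnerSpec("cart", grid=[{"max_depth": 3, "min_samples_leaf": 3}])
CART_PARAMS = {"max_depth": 3, "min_samples_leaf": 3}


def small_config(**kw):
    defaults = dict(learner=FAST_CART, n_seed=20, n_batch=10, t_seed=1, k=2,
                    n_folds=2, master_seed=0)
    defaults.update(kw)
    return ELASConfig(**defaults)


class TestConfig:
    def test_odd_n_seed_rejected(self):
        with pytest.raises(ValueError, match="even"):
            small_config(n_seed=51)

    def test_bad_metric_rejected(self):
        with pytest.raises(ValueError, match="selection_metric"):
            small_config(selection_metric="f1")


class TestFolds:
    def test_equal_fold_sizes(self):
        y = np.array([0] * 90 + [1] * 10)
        folds = make_internal_folds(y, 5, 0)
        assert [len(val) for _, val in folds] == [20] * 5

    def test_stratification(self):
        y = np.array([0] * 90 + [1] * 10)
        for _, val in make_internal_folds(y, 5, 0):
            assert y[val].sum() == 2

    def test_partition(self):
        y = np.array([0, 1] * 50)
        folds = make_internal_folds(y, 5, 3)
        all_val = np.concatenate([val for _, val in folds])
        assert sorted(all_val) == list(range(100))
        for pool, val in folds:
            assert set(pool) & set(val) == set()

    def test_small_class_rejected(self):
        y = np.array([0] * 97 + [1] * 3)
        with pytest.raises(ValueError, match="stratified"):
            make_internal_folds(y, 5, 0)


class TestBalancedSeed:
    def test_half_per_class(self, rng):
        labels = np.array([0] * 80 + [1] * 40)
        idx = draw_balanced_seed(labels, 50, rng)
        assert len(idx) == 50
        assert labels[idx].sum() == 25

    def test_no_replacement(self, rng):
        labels = np.array([0] * 30 + [1] * 30)
        idx = draw_balanced_seed(labels, 40, rng)
        assert len(set(idx.tolist())) == 40

    def test_odd_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            draw_balanced_seed(np.array([0, 1] * 30), 51, rng)

    def test_small_minority_rejected(self, rng):
        labels = np.array([0] * 100 + [1] * 20)
        with pytest.raises(ValueError, match="minority"):
            draw_balanced_seed(labels, 50, rng)


def make_state(X, y, n_seed, rng):
    labels = y
    seed_pos = draw_balanced_seed(labels, n_seed, rng)
    keep = np.ones(len(y), dtype=bool)
    keep[seed_pos] = False
    return SplitState(
        internal_val_indices=np.empty(0, dtype=int),
        pool_indices=np.flatnonzero(keep),
        train_data_indices=seed_pos,
        n_train_pool=len(y),
    )


class TestActiveSamplingRun:
    def test_record_count_and_sizes(self, medium_cohort, rng):
        X, y = medium_cohort
        cfg = small_config()
        state = make_state(X, y, cfg.n_seed, rng)
        records = active_sampling_run(X, y, state, FAST_CART, CART_PARAMS,
                                      cfg, rng)
        expected = expected_record_count(200, cfg.n_seed, cfg.n_batch)
        assert len(records) == expected == 19
        for i, rec in enumerate(records):
            assert rec.n_train == cfg.n_seed + cfg.n_batch * i
            assert rec.iteration == i + 1

    def test_short_pool_single_record(self, rng):
        rng2 = np.random.default_rng(1)
        X = rng2.normal(size=(105, 4))
        y = np.array([0] * 53 + [1] * 52)
        cfg = small_config(n_seed=100, n_batch=10)
        state = make_state(X, y, 100, rng)
        records = active_sampling_run(X, y, state, FAST_CART, CART_PARAMS,
                                      cfg, rng)
        assert len(records) == 1  # 5 remaining < batch of 10

    def test_seed_equals_pool_boundary(self, rng):
        rng2 = np.random.default_rng(0)
        X = rng2.normal(size=(20, 3))
        y = np.array([0, 1] * 10)
        cfg = small_config(n_seed=20)
        state = make_state(X, y, 20, rng)
        records = active_sampling_run(X, y, state, FAST_CART, CART_PARAMS,
                                      cfg, rng)
        assert len(records) == 1
        assert records[0].n_train == 20

    def test_disjointness_and_conservation(self, medium_cohort, rng):
        X, y = medium_cohort
        cfg = small_config()
        state = make_state(X, y, cfg.n_seed, rng)
        history = []
        active_sampling_run(X, y, state, FAST_CART, CART_PARAMS, cfg, rng,
                            history=history)
        for snap in history:
            pool = set(snap["pool_indices"].tolist())
            train = set(snap["train_data_indices"].tolist())
            assert pool & train == set()
            assert len(pool) + len(train) == state.n_train_pool

    @given(st.integers(30, 3000), st.integers(1, 50), st.integers(1, 40))
    @settings(max_examples=200, deadline=None)
    def test_record_count_law_vs_loop(self, n_pool, half_seed, n_batch):
        n_seed = 2 * half_seed
        if n_seed > n_pool:
            return
        assert expected_record_count(n_pool, n_seed, n_batch) == \
            simulate_record_count(n_pool, n_seed, n_batch)


class _FixedScoreClassifier:
    """predict_proba yields a fixed positive-probability vector per call."""

    def __init__(self, scores):
        self.scores = np.asarray(scores, float)

    def predict_proba(self, X):
        p = self.scores[: np.atleast_2d(X).shape[0]]
        return np.column_stack([1 - p, p])


class TestSelectTopK:
    def _records(self, score_rows):
        return [
            BaseClassifierRecord(_FixedScoreClassifier(s), iteration=i + 1,
                                 n_train=10 + i)
            for i, s in enumerate(score_rows)
        ]

    def test_k1_is_argmax(self):
        y_val = np.array([0, 0, 1, 1])
        X_val = np.zeros((4, 2))
        rows = [[0.9, 0.8, 0.1, 0.2],   # perfectly wrong
                [0.1, 0.2, 0.9, 0.8],   # perfect
                [0.5, 0.1, 0.6, 0.2]]   # middling
        top = select_top_k(self._records(rows), X_val, y_val, 1)
        assert top[0].iteration == 2
        assert top[0].internal_val_score == pytest.approx(1.0)

    def test_identical_predictions_tie_break_by_iteration(self):
        y_val = np.array([0, 1, 0, 1])
        X_val = np.zeros((4, 2))
        rows = [[0.2, 0.8, 0.3, 0.7]] * 5
        top = select_top_k(self._records(rows), X_val, y_val, 3)
        assert [r.iteration for r in top] == [1, 2, 3]

    def test_agreement_with_brute_force_sort(self, rng):
        y_val = (rng.random(30) < 0.4).astype(int)
        X_val = np.zeros((30, 2))
        rows = [rng.random(30) for _ in range(12)]
        records = self._records(rows)
        top = select_top_k(records, X_val, y_val, 5)
        oracle = sorted(records,
                        key=lambda r: (-r.internal_val_score, r.iteration))[:5]
        assert [r.iteration for r in top] == [r.iteration for r in oracle]

    def test_k_too_large(self):
        y_val = np.array([0, 1])
        with pytest.raises(ValueError, match="exceeds"):
            select_top_k(self._records([[0.1, 0.9]]), np.zeros((2, 2)),
                         y_val, 2)

    def test_single_class_val_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            select_top_k(self._records([[0.1, 0.9]]), np.zeros((2, 2)),
                         np.array([1, 1]), 1)


class TestFitElas:
    def test_member_count_smoke(self, medium_cohort):
        X, y = medium_cohort
        model = fit_elas(X, y, small_config())
        assert len(model.members) == 2 * 1 * 2

    def test_determinism(self, medium_cohort):
        X, y = medium_cohort
        cfg = small_config(master_seed=11)
        m1 = fit_elas(X, y, cfg)
        m2 = fit_elas(X, y, cfg)
        assert [r.internal_val_score for r in m1.members] == \
            [r.internal_val_score for r in m2.members]
        np.testing.assert_array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_infeasible_k_fails_fast(self, medium_cohort):
        X, y = medium_cohort
        with pytest.raises(ValueError, match="k="):
            fit_elas(X, y, small_config(k=50))

    def test_minority_too_small_fails_fast(self, medium_cohort):
        X, y = medium_cohort
        with pytest.raises(ValueError, match="minority"):
            fit_elas(X, y, small_config(n_seed=60))

    def test_internal_val_never_trained_on(self, medium_cohort):
        X, y = medium_cohort
        model = fit_elas(X, y, small_config(), collect_history=True)
        for run in model.history:
            val = set(run["internal_val_indices"].tolist())
            for snap in run["iterations"]:
                train = set(snap["train_data_indices"].tolist())
                pool = set(snap["pool_indices"].tolist())
                assert val & train == set()
                assert val & pool == set()
                assert len(pool) + len(train) == run["n_train_pool"]


class TestPredict:
    def _model_with_members(self, rows):
        members = [BaseClassifierRecord(_FixedScoreClassifier(r), i + 1, 10)
                   for i, r in enumerate(rows)]
        return ELASModel(members=members, config=small_config(),
                         chosen_params={})

    def test_mean_of_constant_members(self):
        model = self._model_with_members([[0.8, 0.8], [0.8, 0.8]])
        p = model.predict_proba(np.zeros((2, 3)))
        np.testing.assert_allclose(p[:, 1], 0.8)

    def test_mean_of_two_members(self):
        model = self._model_with_members([[0.6, 0.6], [0.2, 0.2]])
        p = model.predict_proba(np.zeros((2, 3)))
        np.testing.assert_allclose(p[:, 1], 0.4)

    def test_rows_sum_to_one(self, medium_cohort):
        X, y = medium_cohort
        model = fit_elas(X, y, small_config())
        p = model.predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_permutation_invariance_and_convex_hull(self, rng):
        rows = [rng.random(4) for _ in range(6)]
        model = self._model_with_members(rows)
        p = model.predict_proba(np.zeros((4, 2)))[:, 1]
        rng.shuffle(model.members)
        p_shuffled = model.predict_proba(np.zeros((4, 2)))[:, 1]
        np.testing.assert_allclose(p, p_shuffled, atol=1e-15)
        stacked = np.stack(rows)[:, :4]
        assert (p >= stacked.min(axis=0) - 1e-12).all()
        assert (p <= stacked.max(axis=0) + 1e-12).all()

    def test_predict_threshold(self):
        model = self._model_with_members([[0.9, 0.1]])
        np.testing.assert_array_equal(model.predict(np.zeros((2, 2))), [1, 0])

    def test_save_load_round_trip(self, medium_cohort, tmp_path):
        X, y = medium_cohort
        model = fit_elas(X, y, small_config())
        path = tmp_path / "model.joblib"
        model.save(path)
        back = ELASModel.load(path)
        np.testing.assert_array_equal(model.predict_proba(X),
                                      back.predict_proba(X))


class TestEstimatorContract:
    def test_fit_predict(self, medium_cohort):
        X, y = medium_cohort
        est = ELASClassifier(small_config())
        est.fit(X, y)
        assert est.predict_proba(X).shape == (len(y), 2)
        assert set(est.predict(X).tolist()) <= {0, 1}

    def test_unfitted_raises(self, medium_cohort):
        X, _ = medium_cohort
        with pytest.raises(RuntimeError, match="not fitted"):
            ELASClassifier(small_config()).predict_proba(X)

    def test_overrides(self):
        est = ELASClassifier(small_config(), k=3)
        assert est.config.k == 3
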