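import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from lungcad import (
    FLDModel,
    TrainingBundle,
    fit_fld,
    roc_auc,
    score_candidates,
    sfs_select,
    shortlist_features,
)
from lungcad.selection import FitError, _bundle_merit
from oracles import pair_count_auc


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 1, 2, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_constant_feature_is_chance(self):
        assert roc_auc([5, 5, 5, 5], [0, 0, 1, 1]) == 0.5

    def test_anticorrelated_feature_folds(self):
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 1]
        raw = roc_auc_score(labels, values)
        assert raw < 0.5
        assert roc_auc(values, labels) == pytest.approx(1 - raw, abs=1e-12)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(5, 120))
            values = rng.choice([0.0, 0.5, 1.0, 2.0, rng.normal()], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(values, labels) == pytest.approx(
                pair_count_auc(values, labels), abs=1e-12
            )

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=80)
        labels = rng.integers(0, 2, size=80)
        ref = roc_auc_score(labels, values)
        assert roc_auc(values, labels) == pytest.approx(max(ref, 1 - ref), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestShortlist:
    def test_full_k_reorders_by_auc(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=200).astype(bool)
        X = np.column_stack(
            [rng.normal(size=200), y + rng.normal(scale=0.3, size=200)]
        )
        order = shortlist_features(X, y, 2)
        assert set(order) == {0, 1}
        assert order[0] == 1  # informative feature ranks first

    def test_perfect_feature_dominates_constants(self):
        y = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        X = np.column_stack([np.ones(6), np.ones(6), y.astype(float)])
        assert shortlist_features(X, y, 1)[0] == 2

    def test_planted_auc_order_recovered(self):
        rng = np.random.default_rng(3)
        n = 800
        y = np.repeat([0, 1], n // 2).astype(bool)
        shifts = {0: 1.8, 1: 0.75, 2: 0.0}  # AUC ~ 0.9, 0.7, 0.5
        X = np.column_stack(
            [rng.normal(size=n) + shift * y for shift in shifts.values()]
        )
        aucs = [pair_count_auc(X[:, j], y) for j in range(3)]
        assert aucs[0] > aucs[1] > aucs[2]
        assert list(shortlist_features(X, y, 2)) == [0, 1]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            shortlist_features(np.zeros((4, 2)), [0, 1, 0, 1], 3)


class TestFLD:
    def test_identity_scatter_closed_form(self):
        base = np.array(
            [[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]]
        )
        X = np.vstack([base, base + [2.0, 0.0]])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=bool)
        model = fit_fld(X, y, ridge=0.0)
        w = model.weights / np.linalg.norm(model.weights)
        assert abs(w[0]) == pytest.approx(1.0, abs=1e-9)
        assert abs(w[1]) == pytest.approx(0.0, abs=1e-9)

    def test_duplicated_column_needs_ridge(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        X = np.column_stack([x, x])
        y = rng.integers(0, 2, size=100).astype(bool)
        with pytest.raises(FitError):
            fit_fld(X, y, ridge=0.0)
        model = fit_fld(X, y, ridge=1e-3)
        assert np.all(np.isfinite(model.weights))

    def test_recovers_analytic_direction_on_gaussians(self):
        """w estimated from correlated 2-D Gaussians points along the
        analytic discriminant Sigma^-1 (mu1 - mu0)."""
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        delta = np.array([1.5, 0.5])
        optimal = np.linalg.solve(cov, delta)
        rng = np.random.default_rng(5)
        angles = []
        for _ in range(10):
            X0 = rng.multivariate_normal([0, 0], cov, size=2000)
            X1 = rng.multivariate_normal(delta, cov, size=2000)
            X = np.vstack([X0, X1])
            y = np.repeat([0, 1], 2000).astype(bool)
            model = fit_fld(X, y, ridge=0.0)
            w = model.weights / model.stds  # back to the raw feature scale
            cosang = w @ optimal / (np.linalg.norm(w) * np.linalg.norm(optimal))
            angles.append(np.degrees(np.arccos(np.clip(abs(cosang), -1, 1))))
        assert np.median(angles) < 5.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_fld(np.zeros((4, 2)), [1, 1, 1, 1])

    def test_model_round_trips_through_text_file(self, tmp_path):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 3))
        y = rng.integers(0, 2, size=50).astype(bool)
        model = fit_fld(X, y, feature_names=("a", "b", "c"))
        model.save(tmp_path / "model.txt")
        back = FLDModel.load(tmp_path / "model.txt")
        np.testing.assert_array_equal(back.weights, model.weights)
        assert back.feature_names == model.feature_names
        np.testing.assert_array_equal(
            score_candidates(back, X), score_candidates(model, X)
        )


class TestScoring:
    def test_class_means_order_correctly(self):
        rng = np.random.default_rng(7)
        X0 = rng.normal(size=(200, 3))
        X1 = rng.normal(size=(200, 3)) + [1, 0.5, 0]
        X = np.vstack([X0, X1])
        y = np.repeat([0, 1], 200).astype(bool)
        model = fit_fld(X, y)
        s = score_candidates(model, np.vstack([X0.mean(0), X1.mean(0)]))
        assert s[1] > s[0]

    def test_constant_feature_shift_preserves_ranking(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 2))
        y = rng.integers(0, 2, size=30).astype(bool)
        model = fit_fld(X, y)
        s0 = score_candidates(model, X)
        s1 = score_candidates(model, X + [10.0, 0.0])
        np.testing.assert_allclose(s1 - s0, (s1 - s0)[0], atol=1e-9)
        assert list(np.argsort(s0)) == list(np.argsort(s1))

    def test_empty_matrix_gives_empty_scores(self):
        model = fit_fld(np.array([[0.0], [1.0]]), [0, 1])
        assert score_candidates(model, np.zeros((0, 1))).size == 0

    def test_missing_dataframe_column_raises(self):
        import pandas as pd

        model = fit_fld(np.array([[0.0], [1.0]]), [0, 1], feature_names=("f",))
        with pytest.raises(KeyError):
            score_candidates(model, pd.DataFrame({"g": [1.0]}))


def _synthetic_bundle(seed=9, n_features=10, n_cases=8, cand_per_case=12):
    """Candidates with planted informative features and per-case targets."""
    rng = np.random.default_rng(seed)
    rows, tids = [], []
    offset = 0
    for _ in range(n_cases):
        labels = np.zeros(cand_per_case, dtype=int) - 1
        labels[: 2] = [offset, offset + 1]  # two hits per case
        offset += 2
        X = rng.normal(size=(cand_per_case, n_features))
        hits = labels >= 0
        X[hits, 0] += 2.0  # strongly informative
        X[hits, 1] += 0.8  # weakly informative
        rows.append(X)
        tids.append(labels)
    return TrainingBundle(
        X=np.vstack(rows),
        feature_names=tuple(f"f{j}" for j in range(n_features)),
        target_ids=np.concatenate(tids),
        n_cases=n_cases,
        n_targets=offset,
    )


class TestSFS:
    def test_first_feature_matches_exhaustive_search(self):
        bundle = _synthetic_bundle()
        trace = sfs_select(bundle, max_features=3)
        merits = [
            _bundle_merit(bundle, [j], 1e-3) for j in range(bundle.X.shape[1])
        ]
        assert trace.features[0] == f"f{int(np.argmax(merits))}"
        assert trace.merits[0] == pytest.approx(max(merits))

    def test_max_features_one_equals_exhaustive(self):
        bundle = _synthetic_bundle(seed=10)
        trace = sfs_select(bundle, max_features=1)
        merits = [
            _bundle_merit(bundle, [j], 1e-3) for j in range(bundle.X.shape[1])
        ]
        assert trace.features == [f"f{int(np.argmax(merits))}"]
        assert trace.chosen_size == 1

    def test_duplicate_feature_adds_no_merit(self):
        bundle = _synthetic_bundle(seed=11, n_features=4)
        X = np.column_stack([bundle.X, bundle.X[:, 0]])  # twin of f0
        twin = TrainingBundle(
            X=X,
            feature_names=(*bundle.feature_names, "f0_twin"),
            target_ids=bundle.target_ids,
            n_cases=bundle.n_cases,
            n_targets=bundle.n_targets,
        )
        base = _bundle_merit(twin, [0], 1e-3)
        with_twin = _bundle_merit(twin, [0, 4], 1e-3)
        assert with_twin == pytest.approx(base, abs=1e-9)

    def test_trace_respects_cap_and_plateau(self):
        bundle = _synthetic_bundle(seed=12)
        trace = sfs_select(bundle, max_features=5)
        assert len(trace.features) <= 5
        assert len(trace.merits) == len(trace.features)
        peak = max(trace.merits)
        assert trace.merits[trace.chosen_size - 1] >= peak - 0.05
        if trace.chosen_size > 1:
            assert all(
                m < peak - 0.05 for m in trace.merits[: trace.chosen_size - 1]
            )

    def test_recorded_trace_matches_recomputation(self):
        bundle = _synthetic_bundle(seed=13)
        trace = sfs_select(bundle, max_features=3)
        cols = [int(n[1:]) for n in trace.features]
        for i in range(len(cols)):
            assert trace.merits[i] == pytest.approx(
                _bundle_merit(bundle, cols[: i + 1], 1e-3)
            )
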