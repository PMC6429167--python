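"""Forest training, LOPOCV evaluation, correlation testing and grid search."""

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from moodquant.errors import (
    AlignmentError,
    ParameterError,
    SchemaError,
    UndefinedCorrelationError,
)
from moodquant.features import FEATURE_NAMES, FeatureVector
from moodquant.items import depression_item_indices
from moodquant.model import (
    MTRY_GRID,
    NTREE_GRID,
    REDUCED_MTRY_GRID,
    REDUCED_NTREE_GRID,
    PairedDataset,
    QuantModel,
    Standardizer,
    build_dataset,
    grid_search,
    lopocv,
    pearson_r_pvalue,
    train_rf,
)
from moodquant.qlog import FPCCurve

T0 = datetime(2024, 3, 4, 8)


def _fake_vectors(n_subjects=2, n_sessions=4, channels=("Fp1", "Fp2"), seed=0):
    rng = np.random.default_rng(seed)
    vectors, fpcs = [], {}
    for si in range(n_subjects):
        sid = f"S{si + 1:02d}"
        times, values = [], []
        for k in range(n_sessions):
            t = T0 + timedelta(hours=12 * k)
            latent = float(rng.normal())
            for ch in channels:
                vals = dict(zip(FEATURE_NAMES, rng.normal(size=176).tolist()))
                vals["alpha_psd"] = latent  # one informative feature
                vectors.append(
                    FeatureVector(sid, t, ch, {n: vals[n] for n in FEATURE_NAMES},
                                  level="session", period="morning" if t.hour < 12 else "evening")
                )
            times.append(t)
            values.append(latent)
        loading = np.zeros(40)
        loading[depression_item_indices()[0]] = 1.0
        fpcs[sid] = FPCCurve(sid, times, np.array(values), loading, 1.0)
    return vectors, fpcs


def _toy_dataset(n_subjects=3, n_sessions=8, n_features=5, seed=0, informative=0):
    """Rows where y equals one feature exactly; others are noise."""
    rng = np.random.default_rng(seed)
    names = [f"f{i}" for i in range(n_features)]
    X, y, subjects = [], [], []
    for si in range(n_subjects):
        for _ in range(n_sessions):
            row = rng.normal(size=n_features)
            X.append(row)
            y.append(row[informative])
            subjects.append(f"S{si + 1:02d}")
    return PairedDataset(
        X=pd.DataFrame(X, columns=names),
        y=np.array(y),
        subjects=np.array(subjects, dtype=object),
        session_times=[T0 + timedelta(hours=i) for i in range(len(y))],
        channel_mode="fp1",
    )


class TestBuildDataset:
    def test_concat_mode_counts(self):
        vectors, fpcs = _fake_vectors(n_subjects=2, n_sessions=4)
        ds = build_dataset(vectors, fpcs, "concat")
        assert ds.n_rows == 8
        assert len(ds.feature_names) == 352
        assert all(c.startswith(("fp1__", "fp2__")) for c in ds.feature_names)

    def test_fp1_mode_has_176_columns(self):
        vectors, fpcs = _fake_vectors()
        ds = build_dataset(vectors, fpcs, "fp1")
        assert len(ds.feature_names) == 176

    def test_mean_mode_averages_channels(self):
        vectors, fpcs = _fake_vectors()
        ds = build_dataset(vectors, fpcs, "mean")
        v1 = next(v for v in vectors if v.channel == "Fp1")
        v2 = next(
            v for v in vectors
            if v.channel == "Fp2" and v.session_time == v1.session_time
            and v.subject_id == v1.subject_id
        )
        row = ds.X.iloc[0].to_numpy()
        assert np.allclose(row, (v1.as_array() + v2.as_array()) / 2)

    def test_session_without_diary_dropped_with_count(self):
        vectors, fpcs = _fake_vectors(n_subjects=2, n_sessions=4)
        curve = fpcs["S01"]
        fpcs["S01"] = FPCCurve(
            "S01", curve.session_times[:-1], curve.values[:-1],
            curve.loading_vector, 1.0,
        )
        ds = build_dataset(vectors, fpcs, "concat")
        assert ds.n_rows == 7
        assert ds.n_dropped == 1

    def test_no_matches_rejected(self):
        vectors, _ = _fake_vectors()
        with pytest.raises(AlignmentError):
            build_dataset(vectors, {}, "concat")


class TestTrainPredict:
    def test_full_depth_tree_memorizes_training_rows(self):
        ds = _toy_dataset()
        m = train_rf(ds.X, ds.y, ntree=1, mtry=5, seed=0, bootstrap=False)
        assert np.allclose(m.predict(ds.X), ds.y)

    def test_same_seed_same_trees(self):
        ds = _toy_dataset()
        a = train_rf(ds.X, ds.y, 5, 2, seed=3)
        b = train_rf(ds.X, ds.y, 5, 2, seed=3)
        for ta, tb in zip(a.trees, b.trees):
            assert np.array_equal(ta.feature, tb.feature)
            assert np.array_equal(ta.threshold, tb.threshold)

    def test_splits_prefer_informative_feature(self):
        # only f2 carries signal; the others are pure noise.  The best
        # variance-reducing root split must use f2, and f2 must dominate
        # the split counts (ties deep in the tree may pick noise features).
        ds = _toy_dataset(informative=2, n_sessions=20)
        m = train_rf(ds.X, ds.y, ntree=1, mtry=5, seed=0, bootstrap=False)
        tree = m.trees[0]
        assert int(tree.feature[0]) == 2
        splits = [int(f) for f in tree.feature if f >= 0]
        assert splits.count(2) / len(splits) > 0.5

    def test_forest_prediction_is_mean_of_trees(self):
        ds = _toy_dataset()
        m = train_rf(ds.X, ds.y, 7, 3, seed=1)
        Xs = m.standardizer.transform(ds.X.to_numpy(float))
        per_tree = np.array([[t.predict_one(x) for t in m.trees] for x in Xs])
        assert np.allclose(m.predict(ds.X), per_tree.mean(axis=1))

    def test_prediction_invariant_to_row_order(self):
        ds = _toy_dataset()
        m = train_rf(ds.X, ds.y, 3, 2, seed=2)
        perm = np.random.default_rng(0).permutation(len(ds.X))
        assert np.allclose(m.predict(ds.X.iloc[perm]), m.predict(ds.X)[perm])

    def test_missing_feature_rejected(self):
        ds = _toy_dataset()
        m = train_rf(ds.X, ds.y, 1, 2, seed=0)
        with pytest.raises(SchemaError):
            m.predict(ds.X.drop(columns=["f0"]))

    def test_mtry_exceeding_feature_count_rejected(self):
        ds = _toy_dataset()
        with pytest.raises(ParameterError):
            train_rf(ds.X, ds.y, 1, 99, seed=0)

    def test_json_round_trip(self, tmp_path):
        ds = _toy_dataset()
        m = train_rf(ds.X, ds.y, 3, 2, seed=5)
        m.to_json(tmp_path / "m.json")
        m2 = QuantModel.from_json(tmp_path / "m.json")
        assert np.allclose(m.predict(ds.X), m2.predict(ds.X))
        assert m2.feature_names == m.feature_names


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p = pearson_r_pvalue(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-30

    def test_orthogonal_vectors(self):
        x = np.array([1, -1] * 5, dtype=float)
        y = np.array([1, 1, -1, -1] * 2 + [1, 1], dtype=float)
        y -= y.mean()
        assert abs(np.dot(x, y)) < 1e-12
        r, p = pearson_r_pvalue(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_evaluation_table_convention(self):
        # construct n = 24 samples with sample correlation exactly 0.6096
        rng = np.random.default_rng(0)
        z1 = rng.normal(size=24)
        z2 = rng.normal(size=24)
        z1 -= z1.mean()
        z2 -= z2.mean()
        z2 -= z1 * np.dot(z1, z2) / np.dot(z1, z1)  # orthogonalize
        z1 /= np.linalg.norm(z1)
        z2 /= np.linalg.norm(z2)
        target_r = 0.6096
        y = target_r * z1 + np.sqrt(1 - target_r**2) * z2
        r, p = pearson_r_pvalue(z1, y)
        assert r == pytest.approx(target_r, abs=1e-12)
        assert abs(p - 0.0016) < 0.0005

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r, p = pearson_r_pvalue(x, y)
        r_sp, p_sp = scipy.stats.pearsonr(x, y)
        assert r == pytest.approx(r_sp, rel=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r_pvalue(np.ones(10), np.arange(10.0))


class TestLOPOCV:
    def test_fold_accounting(self):
        ds = _toy_dataset(n_subjects=4, n_sessions=6)
        res = lopocv(ds, 3, 2, seed=0)
        assert len(res.folds) == 4
        assert (res.folds["TrS"] + res.folds["TeS"]).nunique() == 1
        assert res.folds["TeS"].sum() == ds.n_rows

    def test_identical_subjects_give_identical_cc(self):
        rng = np.random.default_rng(3)
        rows = rng.normal(size=(6, 4))
        y = rows[:, 0]
        X = pd.DataFrame(np.vstack([rows, rows]), columns=list("abcd"))
        ds = PairedDataset(
            X=X,
            y=np.concatenate([y, y]),
            subjects=np.array(["S01"] * 6 + ["S02"] * 6, dtype=object),
            session_times=[T0 + timedelta(hours=i) for i in range(12)],
            channel_mode="fp1",
        )
        res = lopocv(ds, 3, 2, seed=1)
        assert res.folds["CC"].iloc[0] == pytest.approx(res.folds["CC"].iloc[1])

    def test_small_subject_skipped(self):
        ds = _toy_dataset(n_subjects=3, n_sessions=6)
        # truncate one subject to 2 sessions
        keep = np.ones(ds.n_rows, dtype=bool)
        idx = np.where(ds.subjects == "S03")[0][2:]
        keep[idx] = False
        ds2 = PairedDataset(
            X=ds.X.loc[keep].reset_index(drop=True),
            y=ds.y[keep],
            subjects=ds.subjects[keep],
            session_times=[t for t, k in zip(ds.session_times, keep) if k],
            channel_mode="fp1",
        )
        res = lopocv(ds2, 2, 2, seed=0)
        assert res.skipped == ["S03"]
        assert len(res.folds) == 2


class TestGridSearch:
    def test_stated_grid_geometry(self):
        assert len(NTREE_GRID) == 50 and NTREE_GRID[0] == 1 and NTREE_GRID[-1] == 491
        assert len(MTRY_GRID) == 20 and MTRY_GRID[0] == 1 and MTRY_GRID[-1] == 96
        assert len(NTREE_GRID) * len(MTRY_GRID) == 1000
        assert set(REDUCED_NTREE_GRID) <= set(NTREE_GRID)
        assert set(REDUCED_MTRY_GRID) <= set(MTRY_GRID)

    def test_winner_on_small_grid(self):
        ds = _toy_dataset(n_subjects=3, n_sessions=10)
        ntree, mtry, grid = grid_search(
            ds, seed=0, ntree_values=(1, 11), mtry_values=(1, 5)
        )
        assert len(grid) == 4
        best = grid.sort_values(
            ["mean_cc", "mean_p"], ascending=[False, True]
        ).iloc[0]
        assert (ntree, mtry) == (best["ntree"], best["mtry"])

    def test_reduced_grid_consistent_with_full_restriction(self):
        ds = _toy_dataset(n_subjects=3, n_sessions=8)
        cells = ((1, 11), (1, 5))
        n1, m1, g1 = grid_search(ds, seed=2, ntree_values=cells[0], mtry_values=cells[1])
        n2, m2, g2 = grid_search(ds, seed=2, ntree_values=cells[0], mtry_values=cells[1])
        assert (n1, m1) == (n2, m2)
        pd.testing.assert_frame_equal(g1, g2)


class TestStandardizer:
    def test_fitted_on_training_rows_only(self):
        # canary: an extreme test-set value must not move the stored stats
        ds = _toy_dataset(n_subjects=3, n_sessions=6)
        train_mask = ds.subjects != "S03"
        X_train = ds.X.loc[train_mask]
        m = train_rf(X_train, ds.y[train_mask], 1, 2, seed=0)
        expected = Standardizer.fit(X_train.to_numpy(float))
        assert np.allclose(m.standardizer.mean, expected.mean)
        assert np.allclose(m.standardizer.sd, expected.sd)
        X_test = ds.X.loc[~train_mask].copy()
        X_test.iloc[0, 0] = 1e6  # canary
        m.predict(X_test)  # must not touch the stored statistics
        assert np.allclose(m.standardizer.mean, expected.mean)

    def test_zero_variance_column_safe(self):
        X = np.ones((10, 3))
        s = Standardizer.fit(X)
        out = s.transform(X)
        assert np.all(np.isfinite(out))
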