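import numpy as np
import pandas as pd
import pytest

from pmgrid.validation import (
    cross_validate,
    decompose_spatial_temporal,
    importance_table,
    make_folds,
    performance_stats,
    season_of,
    seasonal_stats,
)

from conftest import make_sites


def brute_force_decompose(pred, obs, ids):
    """Two-pass oracle: explicit per-monitor means, explicit centering."""
    df = pd.DataFrame({"pred": pred, "obs": obs, "id": ids})
    mp, mo = [], []
    for mid in sorted(df["id"].unique()):
        sub = df[df["id"] == mid]
        mp.append(sub["pred"].mean())
        mo.append(sub["obs"].mean())
    cp, co = [], []
    for _, row in df.iterrows():
        sub = df[df["id"] == row["id"]]
        cp.append(row["pred"] - sub["pred"].mean())
        co.append(row["obs"] - sub["obs"].mean())
    return (np.array(mp), np.array(mo)), (np.array(cp), np.array(co))


class TestMakeFolds:
    sites = make_sites([(i, 0) for i in range(20)])

    def test_twenty_monitors_ten_folds_size_two(self):
        fa = make_folds(self.sites, k=10, seed=0)
        sizes = pd.Series(fa.assignment).value_counts()
        assert (sizes == 2).all()

    def test_partition_is_disjoint_and_complete(self):
        fa = make_folds(self.sites, k=7, seed=1)
        assert set(fa.assignment) == set(self.sites["monitor_id"])
        union = set()
        for f in range(1, 8):
            fold = set(fa.monitors_in(f))
            assert not (union & fold)
            union |= fold
        assert union == set(self.sites["monitor_id"])

    def test_same_seed_reproduces_assignment(self):
        assert make_folds(self.sites, 10, seed=5).assignment == \
            make_folds(self.sites, 10, seed=5).assignment

    def test_fewer_monitors_than_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(self.sites.head(5), k=10, seed=0)


class TestCrossValidate:
    @staticmethod
    def _group_mean_fit(train):
        # Simple deterministic learner: the grand mean of training obs.
        return float(train["obs"].mean())

    @staticmethod
    def _group_mean_predict(model, test):
        return np.full(len(test), model)

    def _data(self, n_monitors=6, n_days=4, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "monitor_id": np.repeat([f"S{i}" for i in range(n_monitors)], n_days),
            "obs": rng.normal(10, 2, n_monitors * n_days),
        })

    def test_prediction_count_equals_observation_count(self):
        data = self._data()
        folds = make_folds(make_sites([(i, 0) for i in range(6)]), k=3, seed=0)
        preds = cross_validate(self._group_mean_fit, self._group_mean_predict,
                               data, folds)
        assert preds.notna().all()
        assert len(preds) == len(data)

    def test_k_equal_n_behaves_as_leave_one_monitor_out(self):
        data = self._data()
        folds = make_folds(make_sites([(i, 0) for i in range(6)]), k=6, seed=0)
        preds = cross_validate(self._group_mean_fit, self._group_mean_predict,
                               data, folds)
        for mid in data["monitor_id"].unique():
            mask = data["monitor_id"] == mid
            expected = data.loc[~mask, "obs"].mean()
            assert np.allclose(preds[mask], expected)

    def test_held_out_rows_cannot_influence_their_own_predictions(self):
        data = self._data()
        folds = make_folds(make_sites([(i, 0) for i in range(6)]), k=3, seed=0)
        base = cross_validate(self._group_mean_fit, self._group_mean_predict,
                              data, folds)
        shifted = data.copy()
        target = "S2"
        shifted.loc[shifted["monitor_id"] == target, "obs"] += 100.0
        new = cross_validate(self._group_mean_fit, self._group_mean_predict,
                             shifted, folds)
        mask = data["monitor_id"] == target
        assert np.allclose(new[mask], base[mask])
        assert not np.allclose(new[~mask], base[~mask])


class TestPerformanceStats:
    def test_identity_prediction(self):
        s = performance_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s.r2 == pytest.approx(1.0)
        assert s.rmse == pytest.approx(0.0)
        assert s.intercept == pytest.approx(0.0, abs=1e-12)
        assert s.slope == pytest.approx(1.0)

    def test_flat_prediction_closed_form(self):
        # obs=(1,2,3), pred=(2,2,2): slope 0, intercept 2, r2 0,
        # rmse = sqrt((1+0+1)/3) = sqrt(2/3).
        s = performance_stats([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert s.slope == pytest.approx(0.0, abs=1e-12)
        assert s.intercept == pytest.approx(2.0)
        assert s.r2 == pytest.approx(0.0)
        assert s.rmse == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_doubled_prediction_closed_form(self):
        obs = np.array([1.0, 2.0, 4.0])
        s = performance_stats(2 * obs, obs)
        assert s.slope == pytest.approx(2.0)
        assert s.r2 == pytest.approx(1.0)
        assert s.rmse == pytest.approx(np.sqrt(np.mean(obs**2)))

    def test_zero_variance_observations_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            performance_stats([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            performance_stats([1.0, 2.0], [1.0, 2.0])


class TestDecomposition:
    def test_identity_scores_one_in_both_domains(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        ids = ["a", "a", "a", "b", "b", "b"]
        spatial, temporal = decompose_spatial_temporal(obs, obs, ids)
        assert spatial.r2 == pytest.approx(1.0)
        assert temporal.r2 == pytest.approx(1.0)

    def test_per_monitor_offsets_vanish_in_temporal_domain(self):
        # pred = obs + c_i: centering removes the offsets entirely.
        obs = np.array([10.0, 12.0, 11.0, 20.0, 22.0, 21.0])
        ids = ["a", "a", "a", "b", "b", "b"]
        pred = obs + np.where(np.array(ids) == "a", 3.0, -2.0)
        spatial, temporal = decompose_spatial_temporal(pred, obs, ids)
        assert temporal.r2 == pytest.approx(1.0)
        assert temporal.rmse == pytest.approx(0.0, abs=1e-12)
        # Spatial points: (11, 14) and (21, 19) -> slope 0.5.
        assert spatial.slope == pytest.approx(0.5)

    def test_temporal_intercept_structurally_zero(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n_mon = rng.integers(2, 8)
            n_day = rng.integers(2, 30)
            ids = np.repeat([f"m{i}" for i in range(n_mon)], n_day)
            obs = rng.uniform(2, 30, n_mon * n_day)
            pred = obs * rng.uniform(0.5, 1.5) + rng.normal(0, 3, obs.size)
            _, temporal = decompose_spatial_temporal(pred, obs, ids)
            assert abs(temporal.intercept) < 1e-6

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        ids = np.repeat([f"m{i}" for i in range(9)], 13)
        obs = rng.uniform(2, 30, ids.size)
        pred = obs + rng.normal(0, 2, ids.size)
        spatial, temporal = decompose_spatial_temporal(pred, obs, ids)
        (mp, mo), (cp, co) = brute_force_decompose(pred, obs, ids)
        want_spatial = performance_stats(mp, mo)
        want_temporal = performance_stats(cp, co)
        for got, want in ((spatial, want_spatial), (temporal, want_temporal)):
            assert got.r2 == pytest.approx(want.r2, abs=1e-10)
            assert got.rmse == pytest.approx(want.rmse, abs=1e-10)
            assert got.intercept == pytest.approx(want.intercept, abs=1e-10)
            assert got.slope == pytest.approx(want.slope, abs=1e-10)

    def test_single_monitor_rejected(self):
        with pytest.raises(ValueError, match="monitor"):
            decompose_spatial_temporal([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                                       ["a", "a", "a"])


class TestSeasonal:
    def _data(self):
        dates = pd.date_range("2016-01-01", "2016-12-31", freq="D")
        n = len(dates)
        rng = np.random.default_rng(3)
        ids = np.tile(["a", "b", "c"], n)
        obs = rng.uniform(4, 20, 3 * n)
        return obs, np.repeat(dates, 3)[: 3 * n], ids

    def test_identity_scores_one_everywhere(self):
        obs, dates, ids = self._data()
        out = seasonal_stats(obs, obs, dates, ids)
        assert set(out) == {"DJF", "MAM", "JJA", "SON"}
        for doms in out.values():
            assert doms["overall"].r2 == pytest.approx(1.0)
            assert doms["temporal"].r2 == pytest.approx(1.0)

    def test_season_partition_sizes_sum_to_n(self):
        obs, dates, ids = self._data()
        out = seasonal_stats(obs, obs, dates, ids)
        assert sum(d["overall"].n for d in out.values()) == len(obs)

    def test_jja_equals_brute_force_month_filter(self):
        obs, dates, ids = self._data()
        rng = np.random.default_rng(4)
        pred = obs + rng.normal(0, 1, obs.size)
        out = seasonal_stats(pred, obs, dates, ids)
        months = pd.DatetimeIndex(dates).month
        jja = np.isin(months, [6, 7, 8])
        want = performance_stats(pred[jja], obs[jja])
        assert out["JJA"]["overall"].r2 == pytest.approx(want.r2)
        assert out["JJA"]["overall"].n == int(jja.sum())

    def test_season_of_mapping(self):
        assert list(season_of(["2016-12-15", "2016-03-01", "2016-07-04",
                               "2016-10-31"])) == ["DJF", "MAM", "JJA", "SON"]


class TestImportance:
    def test_percentages_sum_to_hundred_sorted_and_recover_signal(self):
        from sklearn.ensemble import RandomForestRegressor

        rng = np.random.default_rng(5)
        X = rng.normal(size=(500, 5))
        y = X[:, 2] + rng.normal(0, 0.05, 500)
        rf = RandomForestRegressor(n_estimators=50, random_state=0).fit(X, y)
        table = importance_table(rf)
        assert table["importance_pct"].sum() == pytest.approx(100.0, abs=1e-6)
        assert table["importance_pct"].is_monotonic_decreasing
        assert table.iloc[0]["predictor"] == "x2"

    def test_unfitted_model_rejected(self):
        from sklearn.ensemble import RandomForestRegressor

        with pytest.raises(ValueError):
            importance_table(RandomForestRegressor())
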