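import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bogflux import attribution
from bogflux.attribution import breakpoint, cross_correlation, rda, weekly_aggregate


def _daily_records(start, end):
    time = pd.date_range(start, end, freq="D")
    rng = np.random.default_rng(0)
    return pd.DataFrame({"time": time, "TA": rng.normal(10, 5, len(time)),
                         "P": rng.uniform(0, 5, len(time))})


class TestWeeklyAggregate:
    def test_study_period_bookkeeping(self):
        rec = _daily_records("2016-01-01", "2020-12-31")
        weekly, retained = weekly_aggregate(
            rec, "2016-01-01", "2020-12-31", omit_weeks=[(2016, 1)]
        )
        assert retained == 259

    def test_single_year_no_omission(self):
        rec = _daily_records("2018-01-01", "2018-12-31")
        _, retained = weekly_aggregate(rec, "2018-01-01", "2018-12-31")
        assert retained == 52

    def test_omit_whole_year(self):
        rec = _daily_records("2016-01-01", "2020-12-31")
        omit = [(2017, b) for b in range(1, 53)]
        _, retained = weekly_aggregate(rec, "2016-01-01", "2020-12-31", omit_weeks=omit)
        assert retained == 208

    def test_year_end_days_fold_into_bin_52(self):
        rec = _daily_records("2020-01-01", "2020-12-31")  # leap year, 366 days
        weekly, retained = weekly_aggregate(rec, "2020-01-01", "2020-12-31")
        assert retained == 52
        bins = attribution.week_bin(rec["time"])
        assert bins.max() == 52
        assert (bins == 52).sum() == 9  # days 358..366

    def test_sum_vs_mean_columns(self):
        rec = _daily_records("2019-01-01", "2019-12-31")
        weekly, _ = weekly_aggregate(rec, "2019-01-01", "2019-12-31")
        first = rec.iloc[:7]
        assert weekly["P"].iloc[0] == pytest.approx(first["P"].sum())
        assert weekly["TA"].iloc[0] == pytest.approx(first["TA"].mean())

    def test_empty_period_rejected(self):
        rec = _daily_records("2018-01-01", "2018-12-31")
        with pytest.raises(ValueError):
            weekly_aggregate(rec, "2020-01-01", "2020-12-31")

    @given(st.sets(st.tuples(st.integers(2016, 2019), st.integers(1, 52)), max_size=30))
    @settings(max_examples=25, deadline=None)
    def test_retained_count_formula(self, omit):
        rec = _daily_records("2016-01-01", "2019-12-31")
        _, retained = weekly_aggregate(rec, "2016-01-01", "2019-12-31", omit_weeks=omit)
        assert retained == 52 * 4 - len(omit)


class TestCrossCorrelation:
    def test_pure_shift(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        y = np.roll(x, 3)
        y[:3] = rng.normal(size=3)
        res = cross_correlation(x, y, max_lag=10)
        assert res.best_lag == 3
        assert res.r_at_best > 0.99

    def test_df_is_n_minus_2(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=259)
        y = x + rng.normal(size=259)
        res = cross_correlation(x, y, max_lag=20)
        assert res.df == 257

    def test_symmetry_of_best_lag(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=400)
        y = np.concatenate([rng.normal(size=5), x[:-5]]) + rng.normal(0, 0.05, 400)
        fwd = cross_correlation(x, y, max_lag=12)
        rev = cross_correlation(y, x, max_lag=12)
        assert fwd.best_lag == -rev.best_lag

    def test_ci_contains_r(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        y = 0.6 * x + rng.normal(0, 0.8, 200)
        res = cross_correlation(x, y, max_lag=5)
        lo, hi = res.ci95
        assert lo < res.r_at_best < hi

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            cross_correlation(np.ones(100), np.arange(100.0), max_lag=5)

    def test_lag_range_restriction(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        res = cross_correlation(x, x, max_lag=8, min_lag=0)
        assert (res.r_by_lag["lag"] >= 0).all()
        assert res.best_lag == 0


class TestBreakpoint:
    def _knee_data(self, knee=82.5, n=200, sigma=0.0, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(70.0, 95.0, n)
        y = np.where(x < knee, 2.0 + 0.3 * (x - knee), 2.0) + rng.normal(0, sigma, n)
        return x, y

    def test_noise_free_knee_exact(self):
        x, y = self._knee_data(sigma=1e-9)
        res = breakpoint(y, x, candidate_grid=np.arange(72.0, 93.0, 0.5), n_boot=0)
        assert res.threshold_est == pytest.approx(82.5, abs=0.25)
        assert res.has_breakpoint
        assert res.sse_segmented <= res.sse_linear

    def test_wtd_mapping(self):
        x, y = self._knee_data(sigma=1e-9)
        res = breakpoint(y, x, candidate_grid=np.arange(72.0, 93.0, 0.5), n_boot=0)
        assert res.threshold_wtd == pytest.approx(-8.0, abs=0.25)

    def test_pure_linear_no_breakpoint(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(70.0, 95.0, 300)
        y = 0.1 * x + rng.normal(0, 0.3, 300)
        res = breakpoint(y, x, n_boot=0)
        assert not res.has_breakpoint

    def test_bootstrap_ci_covers_knee(self):
        hits = 0
        for seed in range(10):
            x, y = self._knee_data(knee=80.0, sigma=0.2, seed=seed)
            res = breakpoint(y, x, candidate_grid=np.arange(72.0, 93.0, 0.5),
                             n_boot=150, seed=seed)
            lo, hi = res.bootstrap_ci
            hits += (lo - 1e-9) <= 80.0 <= (hi + 1e-9)
        assert hits >= 9

    def test_consistency_as_noise_vanishes(self):
        errs = []
        for sigma in (0.5, 0.1, 0.01):
            x, y = self._knee_data(sigma=sigma, seed=7, n=400)
            res = breakpoint(y, x, candidate_grid=np.arange(72.0, 93.0, 0.5), n_boot=0)
            errs.append(abs(res.threshold_est - 82.5))
        assert errs[-1] <= errs[0] + 0.5
        assert errs[-1] < 0.5

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            breakpoint(np.ones(10), np.linspace(70, 90, 10))

    def test_far_grid_rejected(self):
        x, y = self._knee_data()
        with pytest.raises(ValueError):
            breakpoint(y, x, candidate_grid=[200.0, 210.0])


class TestRDA:
    def test_exact_linear_fully_explained(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 3))
        B = rng.normal(size=(3, 2))
        Y = X @ B
        res = rda(Y, X)
        assert res.proportion_explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_explains_little(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2000, 2))
        Y = rng.normal(size=(2000, 2))
        res = rda(Y, X)
        assert res.proportion_explained.sum() < 0.01

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(30, 2))
        X = rng.normal(size=(30, 4))

        # independent oracle: eigendecomposition of the fitted covariance
        def _std(M):
            return (M - M.mean(0)) / M.std(0, ddof=1)

        Ys, Xs = _std(Y), _std(X)
        beta = np.linalg.lstsq(Xs, Ys, rcond=None)[0]
        Yhat = Xs @ beta
        cov = Yhat.T @ Yhat / (len(Y) - 1)
        eigval, eigvec = np.linalg.eigh(cov)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        oracle_scores = Yhat @ eigvec

        res = rda(Y, X)
        np.testing.assert_allclose(
            res.proportion_explained, eigval / Ys.var(0, ddof=1).sum(), atol=1e-10
        )
        for a in range(res.constrained_axis_scores.shape[1]):
            got = res.constrained_axis_scores[:, a]
            want = oracle_scores[:, a]
            sign = np.sign(got @ want)
            np.testing.assert_allclose(got, sign * want, atol=1e-8)

    def test_axes_orthonormal(self):
        rng = np.random.default_rng(3)
        res = rda(rng.normal(size=(50, 3)), rng.normal(size=(50, 4)))
        v = res.axes
        np.testing.assert_allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-10)

    def test_variance_conservation(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 3))
        Y = X @ rng.normal(size=(3, 2)) + rng.normal(0, 0.7, size=(80, 2))
        res = rda(Y, X)

        def _std(M):
            return (M - M.mean(0)) / M.std(0, ddof=1)

        Ys, Xs = _std(Y), _std(X)
        beta = np.linalg.lstsq(Xs, Ys, rcond=None)[0]
        resid = Ys - Xs @ beta
        total = Ys.var(0, ddof=1).sum()
        constrained = res.proportion_explained.sum() * total
        assert constrained + resid.var(0, ddof=1).sum() == pytest.approx(total, rel=1e-9)

    def test_proportions_non_increasing(self):
        rng = np.random.default_rng(5)
        res = rda(rng.normal(size=(60, 3)), rng.normal(size=(60, 5)))
        assert (np.diff(res.proportion_explained) <= 1e-12).all()

    def test_collinear_column_dropped(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 2))
        X = np.column_stack([X, X[:, 0] * 2.0])
        Y = rng.normal(size=(40, 2))
        res = rda(Y, X, explanatory_names=["a", "b", "a_copy"])
        assert len(res.dropped_columns) == 1
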