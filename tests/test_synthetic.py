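import dataclasses

import numpy as np
import pandas as pd
import pytest

from bogflux import synthetic
from bogflux.synthetic import CoupledMapConfig, SimConfig


class TestCoupledLogistic:
    def test_determinism(self):
        cfg = CoupledMapConfig(seed=4)
        x1, y1 = synthetic.gen_coupled_logistic(cfg)
        x2, y2 = synthetic.gen_coupled_logistic(cfg)
        np.testing.assert_array_equal(x1, x2)
        np.testing.assert_array_equal(y1, y2)

    def test_length_after_burn_in(self):
        cfg = CoupledMapConfig(n_steps=500, burn_in=120, seed=0)
        x, y = synthetic.gen_coupled_logistic(cfg)
        assert len(x) == len(y) == 380

    def test_trajectories_bounded(self):
        x, y = synthetic.gen_coupled_logistic(CoupledMapConfig(seed=1))
        assert ((x > 0) & (x < 1)).all()
        assert ((y > 0) & (y < 1)).all()

    def test_divergent_parameters_rejected(self):
        with pytest.raises(ValueError, match="left"):
            synthetic.gen_coupled_logistic(
                CoupledMapConfig(r_x=4.5, r_y=3.5, n_steps=200, burn_in=10, seed=0)
            )

    def test_invalid_burn_in_rejected(self):
        with pytest.raises(ValueError):
            CoupledMapConfig(n_steps=100, burn_in=100)

    def test_uncoupled_maps_share_no_information(self):
        """Brute-force nearest-neighbour cross-map as an independent oracle."""
        cfg = CoupledMapConfig(r_x=3.8, r_y=3.6, beta_xy=0.0, beta_yx=0.0,
                               n_steps=600, burn_in=100, seed=9)
        x, y = synthetic.gen_coupled_logistic(cfg)
        assert abs(_brute_cross_map(y, x)) < 0.15
        assert abs(_brute_cross_map(x, y)) < 0.15

    def test_asymmetric_coupling_gives_asymmetric_skill(self):
        cfg = CoupledMapConfig(r_x=3.8, r_y=3.5, beta_xy=0.02, beta_yx=0.1,
                               n_steps=1000, burn_in=100, seed=2)
        x, y = synthetic.gen_coupled_logistic(cfg)
        # x forces y more strongly, so y's history recovers x better
        rho_x_from_y = _brute_cross_map(y, x)
        rho_y_from_x = _brute_cross_map(x, y)
        assert rho_x_from_y > rho_y_from_x


def _brute_cross_map(effect, cause, E=2):
    """Minimal full-library nearest-neighbour cross-map (test oracle)."""
    block = np.column_stack([effect[1:], effect[:-1]])
    target = cause[1:]
    n = len(block)
    preds = np.empty(n)
    for i in range(n):
        d = np.sqrt(((block - block[i]) ** 2).sum(axis=1))
        d[i] = np.inf
        nn = np.argsort(d)[: E + 1]
        w = np.exp(-d[nn] / max(d[nn][0], 1e-12))
        preds[i] = np.dot(w, target[nn]) / w.sum()
    return np.corrcoef(preds, target)[0, 1]


class TestSimConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_years": 0},
            {"swc_threshold": 0.0},
            {"swc_threshold": 100.0},
            {"et_swc_lag": -1},
            {"noise_sd": {"TA": -0.1}},
            {"bucket_capacity": 0.0},
            {"drainage_rate": 0.0},
            {"drainage_rate": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestBogGenerator:
    def test_determinism_bit_identical(self):
        cfg = SimConfig(seed=17)
        a, _ = synthetic.gen_bog_weekly(cfg)
        b, _ = synthetic.gen_bog_weekly(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_shape_and_columns(self, default_bog):
        _, df, _ = default_bog
        assert len(df) == 5 * 52
        for col in ("week_start", "TA", "SW_IN", "VPD", "WS", "USTAR", "H", "LE",
                    "P", "GPP", "RECO", "NEE", "SWC", "WTD", "CO2", "ET"):
            assert col in df.columns

    def test_physical_ranges(self, default_bog):
        _, df, _ = default_bog
        assert df["SWC"].between(0, 100).all()
        assert (df["ET"] >= 0).all()
        assert (df["GPP"] >= 0).all()
        pos = (df["H"] >= 0) & (df["LE"] >= 0)
        ef = df.loc[pos, "LE"] / (df.loc[pos, "LE"] + df.loc[pos, "H"])
        assert ef.between(0, 1).all()

    def test_no_drought_no_stress(self):
        cfg = SimConfig(seed=3, noise_sd={}, drought_years=())
        df, truth = synthetic.gen_bog_weekly(cfg)
        months = pd.DatetimeIndex(df["week_start"]).month
        growing = df.loc[(months >= 4) & (months <= 9)]
        assert (growing["GPP"] > 0).all()
        assert df["SWC"].min() > truth.swc_threshold

    def test_noise_free_lag_scan_recovers_memory(self, quiet_bog):
        """Oracle: exhaustive lag scan on the noise-free output."""
        cfg, df, truth = quiet_bog
        x = df["ET"].to_numpy()
        y = df["SWC"].to_numpy()
        rs = [
            np.corrcoef(x[: len(x) - k or None], y[k:])[0, 1] for k in range(27)
        ]
        assert int(np.argmax(np.abs(rs))) == truth.et_swc_lag == cfg.et_swc_lag

    def test_custom_lag_recovered(self):
        cfg = SimConfig(seed=5, noise_sd={}, et_swc_lag=9)
        df, _ = synthetic.gen_bog_weekly(cfg)
        x, y = df["ET"].to_numpy(), df["SWC"].to_numpy()
        rs = [np.corrcoef(x[: len(x) - k or None], y[k:])[0, 1] for k in range(27)]
        assert int(np.argmax(np.abs(rs))) == 9

    def test_breakpoint_recovery_grid_oracle(self, default_bog):
        """Grid-search piecewise fit on generator output recovers the knee."""
        cfg, df, truth = default_bog
        months = pd.DatetimeIndex(df["week_start"]).month
        gs = df.loc[(months >= 5) & (months <= 9)]
        x = gs["SWC"].to_numpy()
        y = gs["GPP"].to_numpy()
        grid = np.arange(76.0, 92.1, 0.5)
        best_c, best_sse = np.nan, np.inf
        for c in grid:
            if (x < c).sum() < 3 or (x >= c).sum() < 3:
                continue
            design = np.column_stack([np.ones_like(x), x, np.minimum(x - c, 0.0)])
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            sse = np.sum((y - design @ beta) ** 2)
            if sse < best_sse:
                best_c, best_sse = c, sse
        assert best_c == pytest.approx(truth.swc_threshold, abs=2.0)

    def test_swc_wtd_affine_link(self, default_bog):
        _, df, truth = default_bog
        # monotone affine map calibrated at 82.5 % <-> -8 cm
        assert synthetic.swc_to_wtd(82.5) == pytest.approx(-8.0)
        assert synthetic.wtd_to_swc(-8.0) == pytest.approx(82.5)
        assert synthetic.swc_to_wtd(100.0) > synthetic.swc_to_wtd(82.5)

    def test_truth_exposes_implanted_structure(self, default_bog):
        cfg, _, truth = default_bog
        assert truth.et_swc_lag == cfg.et_swc_lag
        assert truth.swc_threshold == cfg.swc_threshold
        assert set(truth.gpp_drivers) == {"SW_IN", "VPD", "SWC"}
        assert "CO2" in truth.independent_channels

    def test_decoupled_gpp_is_driverless(self):
        cfg = SimConfig(seed=2, decouple_gpp=True)
        df, truth = synthetic.gen_bog_weekly(cfg)
        assert truth.gpp_drivers == ()
        # GPP reduces to noise around a constant
        assert df["GPP"].std() < 3 * cfg.noise_sd["GPP"]

    def test_weeks_are_seven_days(self, default_bog):
        _, df, _ = default_bog
        deltas = df["week_start"].diff().dropna().dt.days
        # 7 days within a year; the year rollover resets to Jan 1
        assert set(deltas.unique()) <= {7, 8, 9}
        years = pd.DatetimeIndex(df["week_start"]).year
        assert all((years == y).sum() == 52 for y in range(2016, 2021))
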