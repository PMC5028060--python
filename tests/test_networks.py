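"""Lagged regression and Spearman-partial network estimation."""

import numpy as np
import pandas as pd
import pytest

from esmnet.core import SYMPTOMS, EstimationError, InsufficientDataError, build_lag_pairs
from esmnet.networks import (
    LAG_COLUMNS,
    SymptomNetwork,
    build_design,
    design_from_series,
    estimate_network,
    fit_lagged_regression,
    spearman_partial_from_design,
    spearman_partial_network,
)
from esmnet.simulate import SyntheticConfig, simulate_series


def _synthetic_design(rng, n=200, beta=None, intercept=1.0, noise=0.0):
    """Design frame with y_down generated linearly from the lagged columns."""
    beta = np.zeros(5) if beta is None else np.asarray(beta, float)
    lags = rng.integers(1, 8, size=(n, 5)).astype(float)
    day = rng.integers(1, 300, size=n).astype(float)
    y = intercept + lags @ beta + noise * rng.standard_normal(n)
    df = pd.DataFrame(lags, columns=list(LAG_COLUMNS))
    for s in SYMPTOMS:
        df[s] = rng.integers(1, 8, size=n).astype(float)
    df["down"] = y
    df["calendar_day"] = day
    df["state"] = "stable"
    return df


class TestDesign:
    def test_pair_route_equals_vectorized_route(self, sim_series):
        pairs = build_lag_pairs(sim_series)
        via_pairs = build_design(pairs)
        via_frame = design_from_series(sim_series)
        pd.testing.assert_frame_equal(
            via_pairs.reset_index(drop=True), via_frame.reset_index(drop=True),
            check_dtype=False)

    def test_missing_lagged_item_drops_row(self, sim_series):
        pairs = build_lag_pairs(sim_series)
        n_complete = sum(
            1 for p in pairs
            if all(p.prev.rating(s) is not None for s in SYMPTOMS))
        assert len(build_design(pairs)) == n_complete

    def test_state_filter_restricts_rows(self, sim_series):
        pairs = build_lag_pairs(sim_series)
        full = build_design(pairs, state="full_relapse")
        assert (full["state"] == "full_relapse").all()
        n_by_hand = sum(
            1 for p in pairs if p.state == "full_relapse"
            and all(p.prev.rating(s) is not None for s in SYMPTOMS))
        assert len(full) == n_by_hand


class TestLaggedRegression:
    def test_noise_free_system_recovered_exactly(self, rng):
        beta = np.array([0.5, 0.0, 0.0, 0.0, 0.0])
        design = _synthetic_design(rng, n=50, beta=beta)
        fit = fit_lagged_regression(design, "down")
        assert fit.lag_coef == pytest.approx(beta, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.time_coef == pytest.approx(0.0, abs=1e-10)

    def test_constant_outcome_is_degenerate_with_zero_slopes(self, rng):
        design = _synthetic_design(rng, n=30, beta=np.zeros(5), intercept=4.0)
        fit = fit_lagged_regression(design, "down")
        assert fit.degenerate
        assert (fit.lag_coef == 0).all()
        assert np.isnan(fit.rsquared)

    def test_constant_predictor_names_offending_column(self, rng):
        design = _synthetic_design(rng, n=30, beta=np.zeros(5), noise=1.0)
        design["lag_paranoia"] = 3.0
        with pytest.raises(EstimationError, match="lag_paranoia"):
            fit_lagged_regression(design, "down")

    def test_too_few_rows_raise(self, rng):
        design = _synthetic_design(rng, n=7, noise=1.0)
        with pytest.raises(InsufficientDataError):
            fit_lagged_regression(design, "down")

    def test_row_order_invariance(self, rng):
        design = _synthetic_design(rng, n=100, beta=[0.3, -0.2, 0.1, 0, 0],
                                   noise=1.0)
        shuffled = design.sample(frac=1.0, random_state=0)
        a = fit_lagged_regression(design, "down")
        b = fit_lagged_regression(shuffled, "down")
        assert a.lag_coef == pytest.approx(b.lag_coef, abs=1e-12)

    def test_standardized_coefficients_scale_correctly(self, rng):
        design = _synthetic_design(rng, n=500, beta=[0.4, 0, 0, 0, 0],
                                   noise=1.0)
        raw = fit_lagged_regression(design, "down")
        std = fit_lagged_regression(design, "down", standardize=True)
        scale = (design["lag_down"].std(ddof=1)
                 / design["down"].std(ddof=1))
        assert std.lag_coef[0] == pytest.approx(raw.lag_coef[0] * scale,
                                                abs=1e-10)


class TestEstimateNetwork:
    def test_orientation_source_column_target_row(self, rng):
        # y_down depends on lagged paranoia only -> W[down][paranoia] large
        beta = np.array([0.0, 0.0, 0.6, 0.0, 0.0])
        design = _synthetic_design(rng, n=300, beta=beta, noise=0.5)
        from esmnet.networks import _network_from_design
        net = _network_from_design(design, None, True, False)
        assert net.edge("paranoia", "down") == pytest.approx(0.6, abs=0.1)

    def test_deterministic_given_series(self, sim_series):
        a = estimate_network(sim_series, state="stable")
        b = estimate_network(sim_series, state="stable")
        assert a.equals(b)

    def test_diagonal_truth_recovers_diagonal_dominance(self):
        cfg = SyntheticConfig(
            n_monitored_days=600, state_plan=[], monitored_days_per_week=7,
            A={s: np.eye(5) * 0.4 for s in ("stable", "impending_relapse",
                                            "full_relapse")},
            c={s: np.full(5, 4.0) * 0.6 for s in ("stable",
                                                  "impending_relapse",
                                                  "full_relapse")},
            sigma={s: np.full(5, 1.2) for s in ("stable", "impending_relapse",
                                                "full_relapse")},
        )
        series, _ = simulate_series(cfg, seed=8)
        net = estimate_network(series, state="stable")
        off = net.W[~np.eye(5, dtype=bool)]
        assert (np.diag(net.W) > 0.2).all()
        assert np.abs(off).max() < 0.15

    def test_json_round_trip_and_graphml(self, sim_series, tmp_path):
        import networkx as nx
        net = estimate_network(sim_series, state="stable")
        again = SymptomNetwork.from_json(net.to_json(tmp_path / "n.json"))
        assert net.equals(again)
        assert np.allclose(net.pvalues, again.pvalues, equal_nan=True)
        net.to_graphml(tmp_path / "n.graphml")
        g = nx.read_graphml(tmp_path / "n.graphml")
        assert g.number_of_nodes() == 5
        w = g.get_edge_data("paranoia", "down")["weight"]
        assert w == pytest.approx(net.edge("paranoia", "down"))


class TestSpearmanPartial:
    def test_monotone_deterministic_dependence_gives_unit_correlation(self, rng):
        design = _synthetic_design(rng, n=60, noise=1.0)
        design["down"] = np.exp(design["lag_down"])  # strictly increasing
        net = spearman_partial_from_design(design)
        assert net.edge("down", "down") == pytest.approx(1.0, abs=1e-12)

    def test_invariance_under_monotone_transform(self, rng):
        design = _synthetic_design(rng, n=150, beta=[0.3, 0, -0.2, 0, 0],
                                   noise=1.0)
        base = spearman_partial_from_design(design)
        warped = design.copy()
        warped["lag_paranoia"] = np.exp(warped["lag_paranoia"])
        again = spearman_partial_from_design(warped)
        assert np.allclose(base.W, again.W, atol=1e-12)

    def test_matches_pingouin_reference(self, sim_series):
        pingouin = pytest.importorskip("pingouin")
        design = design_from_series(sim_series, state="stable")
        net = spearman_partial_from_design(design)
        covar_all = [*LAG_COLUMNS, "calendar_day"]
        for i, outcome in enumerate(SYMPTOMS[:3]):
            sub = design.dropna(subset=[outcome])
            for j, source_col in enumerate(LAG_COLUMNS):
                covar = [c for c in covar_all if c != source_col]
                ref = pingouin.partial_corr(sub, x=source_col, y=outcome,
                                            covar=covar, method="spearman")
                assert net.W[i, j] == pytest.approx(float(ref["r"].iloc[0]),
                                                    abs=1e-8)
                assert net.pvalues[i, j] == pytest.approx(
                    float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_zero_variance_column_rejected(self, rng):
        design = _synthetic_design(rng, n=40, noise=1.0)
        design["lag_relaxed"] = 4.0
        with pytest.raises(EstimationError, match="lag_relaxed"):
            spearman_partial_from_design(design)

    def test_series_level_wrapper_matches_design_route(self, sim_series):
        a = spearman_partial_network(sim_series, state="stable")
        b = spearman_partial_from_design(
            design_from_series(sim_series, state="stable"), state="stable")
        assert np.allclose(a.W, b.W)
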