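"""Moran's I, weights selection, design assembly and SAR-error fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, sparse

import oracles
from ecosens import spatial_model as sm
from ecosens.exceptions import DegenerateInputError, InputError


def _grid_coords(n_side):
    rr, cc = np.divmod(np.arange(n_side * n_side), n_side)
    return np.column_stack([rr, cc]).astype(float)


class TestMoransI:
    def test_alternating_path_graph_is_minus_one(self):
        # 6-cell path, adjacent neighbours, row-standardized: Wz = -z
        n = 6
        adj = sparse.diags([np.ones(n - 1), np.ones(n - 1)], [1, -1]).tocsr()
        W = sparse.diags(1.0 / np.asarray(adj.sum(axis=1)).ravel()) @ adj
        values = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        assert sm.morans_i(values, W.tocsr()) == pytest.approx(-1.0)

    def test_smooth_gradient_is_strongly_positive(self):
        coords = _grid_coords(15)
        values = coords[:, 0] + coords[:, 1]
        w = sm.build_weights(coords, [1.5], values)
        assert sm.morans_i(values, w) > 0.5

    def test_constant_values_raise(self):
        coords = _grid_coords(4)
        w = sm.build_weights(coords, [1.5], np.arange(16.0))
        with pytest.raises(DegenerateInputError):
            sm.morans_i(np.ones(16), w)

    def test_permutation_calibration(self):
        """Under exchangeable values, observed I falls inside the central
        95% of the permutation null in ~95% of trials."""
        coords = _grid_coords(10)
        w = sm.build_weights(coords, [1.5], np.arange(100.0))
        rng = np.random.default_rng(6)
        inside = 0
        trials = 40
        for _ in range(trials):
            v = rng.normal(size=100)
            i_obs = sm.morans_i(v, w)
            null = np.array([sm.morans_i(rng.permutation(v), w)
                             for _ in range(199)])
            lo, hi = np.quantile(null, [0.025, 0.975])
            inside += (lo <= i_obs <= hi)
        assert inside / trials >= 0.85


class TestBuildWeights:
    def test_single_candidate_returned_directly(self):
        coords = _grid_coords(6)
        w = sm.build_weights(coords, [2.5], np.arange(36.0))
        assert w.band_distance == 2.5
        assert len(w.scan_table) == 1
        # row standardization
        sums = np.asarray(w.W.sum(axis=1)).ravel()
        assert sums == pytest.approx(np.ones(36))

    def test_coincident_coordinates_raise(self):
        coords = np.zeros((4, 2))
        with pytest.raises(InputError, match="1/d"):
            sm.build_weights(coords, [1.0], np.arange(4.0))

    def test_isolating_band_skipped_with_warning(self):
        coords = _grid_coords(5)
        with pytest.warns(UserWarning, match="isolated"):
            w = sm.build_weights(coords, [0.5, 1.5], np.arange(25.0))
        assert w.band_distance == 1.5
        assert bool(w.scan_table["skipped"].iloc[0])

    def test_scan_prefers_band_near_correlation_range(self):
        """Gaussian-blurred noise has short-range correlation; the scan
        should pick a short band, not the largest candidate (majority vote
        over 20 replicates)."""
        rng = np.random.default_rng(12)
        coords = _grid_coords(20)
        chosen = []
        for _ in range(20):
            field = ndimage.gaussian_filter(rng.normal(size=(20, 20)), 2.0)
            w = sm.build_weights(coords, [1.5, 2.5, 5.0, 10.0], field.ravel())
            chosen.append(w.band_distance)
        counts = pd.Series(chosen).value_counts()
        assert counts.idxmax() in (1.5, 2.5)


def _toy_tables(n=40, two_biomes=False, seed=0):
    rng = np.random.default_rng(seed)
    cells = np.arange(n)
    metrics = pd.DataFrame({
        "cell_id": cells, "row": cells // 8, "col": cells % 8,
        "biome": (["north"] * (n // 2) + ["south"] * (n - n // 2))
                 if two_biomes else ["only"] * n,
        "richness": rng.integers(3, 30, n),
        "ses_pd": rng.normal(size=n), "ses_fric": rng.normal(size=n),
    })
    beta_T = rng.normal(0.4, 0.2, n)
    sensi = pd.DataFrame({
        "cell_id": cells, "scale": "seasonal",
        "beta_T": beta_T, "beta_P": rng.normal(0.2, 0.1, n),
        "ci_T_low": beta_T - 0.1, "ci_T_high": beta_T + 0.1,
        "ci_P_low": -0.1, "ci_P_high": 0.1, "r2": 0.5, "n_obs": 200,
    })
    limiting = pd.DataFrame({
        "cell_id": cells, "scale": "seasonal",
        "label": rng.choice(["temperature-limited", "water-limited"], n),
        "margin": rng.normal(size=n),
    })
    return metrics, sensi, limiting


class TestAssembleDesign:
    def test_single_biome_has_no_biome_columns(self):
        design = sm.assemble_design(*_toy_tables(), "seasonal", "T")
        assert not any(c.startswith("biome[") for c in design.X.columns)
        assert not any(":biome[" in c for c in design.X.columns)

    def test_ci_range_gives_inverse_weight(self):
        design = sm.assemble_design(*_toy_tables(), "seasonal", "T")
        assert design.obs_weights == pytest.approx(np.full(40, 5.0))

    def test_response_is_nonnegative(self):
        design = sm.assemble_design(*_toy_tables(seed=3), "seasonal", "T")
        assert (design.y >= 0).all()

    def test_small_biome_dropped_with_log(self):
        metrics, sensi, limiting = _toy_tables(two_biomes=True)
        metrics.loc[metrics.index[:4], "biome"] = "tiny"
        with pytest.warns(UserWarning, match="tiny"):
            design = sm.assemble_design(metrics, sensi, limiting,
                                        "seasonal", "T")
        assert len(design.y) == 36
        assert len(design.drop_log["small_biome_cells"]) == 4

    def test_undefined_ses_rows_excluded(self):
        metrics, sensi, limiting = _toy_tables()
        metrics.loc[0, "ses_pd"] = np.nan
        design = sm.assemble_design(metrics, sensi, limiting, "seasonal", "T")
        assert 0 not in design.cell_ids
        assert design.drop_log["undefined_ses"] == [0]

    def test_continuous_columns_standardized(self):
        design = sm.assemble_design(*_toy_tables(two_biomes=True),
                                    "seasonal", "T")
        for col in ("richness", "pd_ses", "fric_ses"):
            assert abs(design.X[col].mean()) < 1e-10
            assert design.X[col].std(ddof=1) == pytest.approx(1.0)
        assert any(c.startswith("biome[") for c in design.X.columns)
        assert any(":water_limited" in c for c in design.X.columns)


@pytest.fixture(scope="module")
def sar_problem():
    rng = np.random.default_rng(5)
    coords = _grid_coords(12)
    n = len(coords)
    w = sm.build_weights(coords, [1.5], rng.normal(size=n))
    X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
    obsw = rng.uniform(0.5, 2.0, n)
    A = np.linalg.inv(np.eye(n) - 0.6 * w.W.toarray())
    y = 0.5 + X.to_numpy() @ np.array([0.5, -0.3]) \
        + A @ (rng.normal(0, 0.5, n) / np.sqrt(obsw))
    return y, X, obsw, w


class TestFitSAR:
    def test_lambda_zero_data_reproduce_weighted_ols(self):
        rng = np.random.default_rng(9)
        coords = _grid_coords(20)
        n = len(coords)
        w = sm.build_weights(coords, [1.5], rng.normal(size=n))
        X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        obsw = rng.uniform(0.5, 2.0, n)
        y = 1.0 + X.to_numpy() @ np.array([0.5, -0.3]) \
            + rng.normal(0, 1e-3, n) / np.sqrt(obsw)
        fit = sm.fit_sar_error(y, X, obsw, w)
        sw = np.sqrt(obsw)
        Xc = np.column_stack([np.ones(n), X.to_numpy()])
        wls, *_ = np.linalg.lstsq(Xc * sw[:, None], y * sw, rcond=None)
        assert abs(fit.lam) < 0.2
        assert fit.beta.to_numpy() == pytest.approx(wls, abs=1e-4)

    def test_doubling_observation_weights_changes_nothing(self, sar_problem):
        y, X, obsw, w = sar_problem
        f1 = sm.fit_sar_error(y, X, obsw, w)
        f2 = sm.fit_sar_error(y, X, 2 * obsw, w)
        assert f2.lam == pytest.approx(f1.lam, abs=1e-6)
        assert f2.beta.to_numpy() == pytest.approx(f1.beta.to_numpy(), abs=1e-8)

    def test_loglik_no_worse_than_lambda_zero(self, sar_problem):
        y, X, obsw, w = sar_problem
        fit = sm.fit_sar_error(y, X, obsw, w)
        assert fit.loglik >= fit.loglik_lambda0 - 1e-9

    def test_concentrated_optimum_matches_dense_grid_search(self):
        """Independent oracle: dense slogdet likelihood on a lambda grid
        (step 1e-4) on a small problem."""
        rng = np.random.default_rng(14)
        coords = _grid_coords(7)
        n = len(coords)
        w = sm.build_weights(coords, [1.5], rng.normal(size=n))
        X = pd.DataFrame({"x1": rng.normal(size=n)})
        obsw = rng.uniform(0.5, 2.0, n)
        A = np.linalg.inv(np.eye(n) - 0.5 * w.W.toarray())
        y = 0.2 + 0.7 * X["x1"].to_numpy() \
            + A @ (rng.normal(0, 0.3, n) / np.sqrt(obsw))
        fit = sm.fit_sar_error(y, X, obsw, w)
        lo, hi = fit.lambda_interval
        grid = np.arange(lo + 1e-4, hi, 1e-4)
        Xd = np.column_stack([np.ones(n), X.to_numpy()])
        Wd = w.W.toarray()
        nll = [oracles.sar_negloglik_dense(l, y, Xd, Wd, obsw) for l in grid]
        assert fit.lam == pytest.approx(grid[int(np.argmin(nll))], abs=1e-3)

    def test_lambda_near_boundary_flagged(self):
        # a pure unit-eigenvector response (constant, no intercept in the
        # model) drives the profile likelihood into the upper boundary
        rng = np.random.default_rng(2)
        coords = _grid_coords(10)
        n = len(coords)
        w = sm.build_weights(coords, [1.5], rng.normal(size=n))
        X = pd.DataFrame({"x1": rng.normal(size=n)})
        y = np.ones(n) + rng.normal(0, 1e-6, n)
        with pytest.warns(UserWarning, match="boundary"):
            fit = sm.fit_sar_error(y, X, np.ones(n), w, add_intercept=False)
        assert fit.boundary_flag

    def test_refuses_oversized_problems(self):
        w = sm.SpatialWeights(
            cell_ids=np.arange(sm.MAX_EXACT_N + 1),
            coords=np.zeros((sm.MAX_EXACT_N + 1, 2)),
            W=sparse.eye(sm.MAX_EXACT_N + 1).tocsr(),
            S=sparse.eye(sm.MAX_EXACT_N + 1).tocsr(),
            band_distance=1.0,
            isolated=np.zeros(sm.MAX_EXACT_N + 1, dtype=bool))
        with pytest.raises(InputError, match="exceeds"):
            w.eigenvalues()
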