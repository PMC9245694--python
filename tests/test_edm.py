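"""State-space reconstruction, simplex projection, and S-map regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lakehybrid as lh
from lakehybrid.edm import (
    EmbeddingSpec,
    build_state_matrix,
    interaction_coefficients,
    sequential_embedding_comparison,
    simplex_project,
    smap_forecast,
    theta_scan,
    univariate_spec,
)
from lakehybrid.errors import (
    EmbeddingError,
    InsufficientLibraryError,
    ZeroVarianceError,
)


def logistic_map(n=500, r=3.8, x0=0.4, seed=None):
    if seed is not None:
        x0 = np.random.default_rng(seed).uniform(0.2, 0.8)
    x = np.empty(n + 100)
    x[0] = x0
    for t in range(1, len(x)):
        x[t] = r * x[t - 1] * (1 - x[t - 1])
    return x[100:]


# ---------------------------------------------------------------------------
# Embedding / state matrix
# ---------------------------------------------------------------------------


class TestStateMatrix:
    def test_lagged_rows_by_construction(self):
        df = pd.DataFrame({"x": np.arange(1.0, 11.0)})
        sm = build_state_matrix(df, univariate_spec("x", 3))
        assert sm.valid.sum() == 8
        first = sm.raw[np.flatnonzero(sm.valid)[0]]
        np.testing.assert_allclose(first, [3.0, 2.0, 1.0])
        # normalization: mean 0, sd 1 over valid rows
        vals = sm.values[sm.valid]
        np.testing.assert_allclose(vals.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(vals.std(axis=0), 1, atol=1e-9)

    def test_constant_series_rejected(self):
        df = pd.DataFrame({"x": np.ones(20)})
        with pytest.raises(ZeroVarianceError):
            build_state_matrix(df, univariate_spec("x", 2))

    def test_mixed_variable_row_count(self):
        # 12 points, lag-1 on the second variable masks the first row
        df = pd.DataFrame(
            {"chl": np.arange(12.0), "TP_surf": np.arange(12.0) ** 1.5}
        )
        spec = EmbeddingSpec((("chl", 0), ("TP_surf", 1)), "chl", 1)
        sm = build_state_matrix(df, spec)
        assert sm.valid.sum() == 11

    def test_unknown_variable_rejected(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(EmbeddingError, match="nope"):
            build_state_matrix(df, EmbeddingSpec((("nope", 0),), "x", 1))

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(EmbeddingError):
            EmbeddingSpec((("x", 0), ("x", 0)), "x", 1)


# ---------------------------------------------------------------------------
# Simplex projection
# ---------------------------------------------------------------------------


class TestSimplex:
    def test_noise_free_chaos_is_predictable(self):
        x = logistic_map(500)
        df = pd.DataFrame({"x": x})
        sm = build_state_matrix(df, univariate_spec("x", 2))
        res = simplex_project(sm, x, tp=1, exclusion_radius=2)
        assert res.skill > 0.99

    def test_matches_brute_force_oracle(self, rng):
        """Weighted-neighbor forecast equals a direct enumeration oracle."""
        x = logistic_map(120)
        df = pd.DataFrame({"x": x})
        E, tp = 2, 1
        sm = build_state_matrix(df, univariate_spec("x", E))
        res = simplex_project(sm, x, tp=tp, exclusion_radius=0)
        valid = np.flatnonzero(sm.valid)
        y = np.full(len(x), np.nan)
        y[:-tp] = x[tp:]
        lib = valid[np.isfinite(y[valid])]
        for p in rng.choice(valid, size=10, replace=False):
            cands = [l for l in lib if l != p]
            d = sorted(
                cands, key=lambda l: (np.linalg.norm(sm.values[l] - sm.values[p]), l)
            )[: E + 1]
            dists = np.array([np.linalg.norm(sm.values[l] - sm.values[p]) for l in d])
            w = np.exp(-dists / dists[0]) if dists[0] > 0 else (dists == 0) * 1.0
            expect = np.dot(w, y[d]) / w.sum()
            assert res.predictions[p] == pytest.approx(expect, abs=1e-10)

    def test_iid_noise_has_no_skill(self, rng):
        x = rng.normal(size=500)
        df = pd.DataFrame({"x": x})
        sm = build_state_matrix(df, univariate_spec("x", 3))
        res = simplex_project(sm, x, tp=1, exclusion_radius=3)
        assert abs(res.skill) < 0.15

    def test_zero_distance_neighbor_dominates(self):
        # duplicate state: prediction equals the duplicate's future value
        x = np.array([1.0, 5.0, 2.0, 8.0, 1.0, 5.0, 2.0, 9.0, 3.0, 4.0, 6.0, 7.0])
        df = pd.DataFrame({"x": x})
        sm = build_state_matrix(df, univariate_spec("x", 2))
        # row 5 (states x[5]=5, x[4]=1) duplicates row 1 exactly
        res = simplex_project(
            sm, x, tp=1, pred=np.array([5]), n_neighbors=1, exclusion_radius=0
        )
        assert res.predictions[5] == pytest.approx(x[2])

    def test_insufficient_library_raises(self):
        df = pd.DataFrame({"x": np.arange(6.0)})
        sm = build_state_matrix(df, univariate_spec("x", 4))
        with pytest.raises(InsufficientLibraryError):
            simplex_project(sm, df["x"].to_numpy(), tp=1)

    def test_scale_invariance(self):
        """Scaling/shifting a variable leaves skill unchanged (z-normalized)."""
        x = logistic_map(300)
        a = pd.DataFrame({"x": x})
        b = pd.DataFrame({"x": 37.0 + 1234.5 * x})
        ra = simplex_project(
            build_state_matrix(a, univariate_spec("x", 2)),
            a["x"].to_numpy(), tp=1, exclusion_radius=2,
        )
        rb = simplex_project(
            build_state_matrix(b, univariate_spec("x", 2)),
            b["x"].to_numpy(), tp=1, exclusion_radius=2,
        )
        assert ra.skill == pytest.approx(rb.skill, abs=1e-9)


# ---------------------------------------------------------------------------
# S-map
# ---------------------------------------------------------------------------


class TestSMap:
    def test_theta_zero_equals_global_ols(self, rng):
        """At theta=0 every local fit collapses to one global regression."""
        import statsmodels.api as sm_api

        n = 150
        X = rng.normal(size=(n, 3))
        y = X @ [0.5, -1.2, 0.3] + rng.normal(0, 0.2, n)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["y"] = y
        spec = EmbeddingSpec((("a", 0), ("b", 0), ("c", 0)), "y", 0)
        smx = build_state_matrix(df, spec)
        fit = smap_forecast(smx, df["y"].to_numpy(), theta=0.0, tp=0)
        # oracle: statsmodels OLS of y on raw covariates
        ols = sm_api.OLS(y, sm_api.add_constant(X)).fit()
        coefs = fit.coefficients.dropna()
        # identical at every target time
        assert coefs["a"].std() < 1e-10
        np.testing.assert_allclose(
            coefs.iloc[0][["a", "b", "c"]].to_numpy(), ols.params[1:], atol=1e-8
        )
        np.testing.assert_allclose(
            coefs.iloc[0]["intercept"], ols.params[0], atol=1e-8
        )

    def test_weight_formula(self):
        # w = exp(-theta d / dbar): d = dbar -> exp(-theta); d = 0 -> 1
        theta, d, dbar = 2.0, np.array([0.0, 1.3]), 1.3
        w = np.exp(-theta * d / dbar)
        assert w[0] == 1.0 and w[1] == pytest.approx(np.exp(-2.0))

    def test_linear_generator_unbiased_for_any_theta(self, rng):
        """theta must not bias coefficients when the truth is linear."""
        n = 400
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = np.empty(n)
        y[1:] = 0.7 * x1[:-1] - 0.3 * x2[:-1] + rng.normal(0, 0.05, n - 1)
        y[0] = 0
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        spec = EmbeddingSpec((("x1", 0), ("x2", 0)), "y", 1)
        smx = build_state_matrix(df, spec)
        for theta in (0.0, 2.0):
            fit = smap_forecast(smx, df["y"].to_numpy(), theta=theta, tp=1)
            means = fit.coefficients.dropna()[["x1", "x2"]].mean()
            assert means["x1"] == pytest.approx(0.7, abs=0.05)
            assert means["x2"] == pytest.approx(-0.3, abs=0.05)

    def test_degenerate_library_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0] * 10, "y": np.arange(20.0)})
        spec = EmbeddingSpec((("x", 0),), "y", 1)
        smx = build_state_matrix(df, spec)
        # all even rows coincide in state space; dbar>0 here, so craft a
        # fully degenerate case instead: a two-valued variable still has
        # dbar > 0, so use direct check of the error path via identical rows
        df2 = pd.DataFrame({"x": [1.0, 1.0 + 1e-18] * 10, "y": np.arange(20.0)})
        with pytest.raises(Exception):
            smx2 = build_state_matrix(df2, EmbeddingSpec((("x", 0),), "y", 1))
            smap_forecast(smx2, df2["y"].to_numpy(), theta=1.0, tp=1)


class TestThetaScan:
    def test_linear_null_shows_no_gain(self):
        mar = lh.simulate_mar(np.array([[0.6, 0.2], [0.1, 0.5]]), n=400, seed=3)
        spec = EmbeddingSpec((("x0", 0), ("x1", 0)), "x0", 1)
        smx = build_state_matrix(mar, spec)
        scan = theta_scan(smx, mar["x0"].to_numpy(), tp=1)
        assert scan.delta_rho < 0.03

    def test_nonlinear_lake_gains_from_theta(self, lake_df):
        spec = EmbeddingSpec((("chl", 0), ("TP_surf", 0), ("T_surf", 0)), "chl", 1)
        smx = build_state_matrix(lake_df, spec)
        scan = theta_scan(smx, lake_df["chl"].to_numpy(), tp=1)
        assert scan.best_theta > 0
        assert scan.delta_rho > 0.05

    def test_single_theta_grid(self, lake_df):
        spec = EmbeddingSpec((("DO_B", 0), ("T_surf", 0)), "DO_B", 1)
        smx = build_state_matrix(lake_df, spec)
        scan = theta_scan(smx, lake_df["DO_B"].to_numpy(), theta_grid=(0.0,), tp=1)
        assert len(scan.table) == 1
        assert scan.best_theta == 0.0 and scan.delta_rho == 0.0


class TestEmbeddingComparison:
    def test_informative_drivers_raise_skill(self, lake_df):
        """Phosphorus genuinely drives the bloom: adding it to a physical
        baseline raises best-theta skill, and further additions never cost
        more than estimation noise."""
        comp = sequential_embedding_comparison(
            lake_df,
            "chl",
            ["h_mix", "T_surf", "T_atm", "Q"],
            ["TP_surf", "TP_lake"],
            theta_grid=(0.0, 0.5, 2.0, 5.0, 10.0),
        )
        rho = comp.table["best_rho"].to_numpy()
        assert len(rho) == 3
        assert rho[1] > rho[0] + 0.05
        assert rho[2] >= rho[1] - 0.01
        assert any(v == "TP_surf" for v, _ in comp.best_spec.coordinates)

    def test_biogeochemistry_adds_deep_oxygen_predictability(self, lake_df):
        """Without its own history, deep oxygen is predicted better once
        phosphorus state is added to the physical drivers."""
        comp = sequential_embedding_comparison(
            lake_df,
            "DO_B",
            ["h_mix", "T_surf", "T_atm", "Q"],
            ["TP_lake", "chl"],
            theta_grid=(0.0, 2.0, 10.0),
            include_target=False,
        )
        rho = comp.table["best_rho"].to_numpy()
        assert rho[1] > rho[0] + 0.05

    def test_noise_column_adds_nothing(self, lake_df, rng):
        df = lake_df.copy()
        df["noise"] = rng.normal(size=len(df))
        comp = sequential_embedding_comparison(
            df, "DO_B", ["h_mix", "T_surf"], ["noise"],
            theta_grid=(0.0, 2.0, 10.0),
        )
        rho = comp.table["best_rho"].to_numpy()
        assert abs(rho[1] - rho[0]) < 0.02

    def test_empty_added_vars_is_baseline_only(self, lake_df):
        comp = sequential_embedding_comparison(
            lake_df, "DO_B", ["h_mix", "T_surf"], [], theta_grid=(0.0, 2.0)
        )
        assert len(comp.table) == 1

    def test_overlapping_sets_rejected(self, lake_df):
        with pytest.raises(EmbeddingError):
            sequential_embedding_comparison(lake_df, "DO_B", ["chl"], ["chl"])


class TestInteractionCoefficients:
    def test_theta_zero_coefficients_constant(self, lake_df):
        spec = EmbeddingSpec((("chl", 0), ("TP_surf", 0)), "chl", 1)
        smx = build_state_matrix(lake_df, spec)
        fit = smap_forecast(smx, lake_df["chl"].to_numpy(), theta=0.0, tp=1)
        series = interaction_coefficients(fit, "TP_surf").dropna()
        assert series.std() < 1e-10

    def test_constant_coefficient_recovered(self, rng):
        n = 400
        x = rng.normal(size=n)
        y = np.empty(n)
        y[1:] = 0.8 * x[:-1] + rng.normal(0, 0.05, n - 1)
        y[0] = 0
        df = pd.DataFrame({"x": x, "y": y})
        smx = build_state_matrix(df, EmbeddingSpec((("x", 0),), "y", 1))
        fit = smap_forecast(smx, df["y"].to_numpy(), theta=2.0, tp=1,
                            exclusion_radius=1)
        series = interaction_coefficients(fit, "x").dropna()
        assert series.std() < 0.05
        assert series.mean() == pytest.approx(0.8, abs=0.03)

    def test_unknown_coordinate_rejected(self, lake_df):
        spec = EmbeddingSpec((("chl", 0),), "chl", 1)
        smx = build_state_matrix(lake_df, spec)
        fit = smap_forecast(smx, lake_df["chl"].to_numpy(), theta=0.0, tp=1)
        with pytest.raises(EmbeddingError):
            interaction_coefficients(fit, "TP_surf")


@settings(max_examples=20, deadline=None)
@given(
    theta=st.floats(0.0, 10.0),
    scale=st.floats(0.1, 100.0),
    shift=st.floats(-50.0, 50.0),
)
def test_smap_weights_and_scale_invariance(theta, scale, shift):
    """Weights lie in (0,1], decrease with distance, and skill is invariant
    to affine rescaling of the inputs."""
    d = np.linspace(0, 5, 50)
    dbar = d.mean()
    w = np.exp(-theta * d / dbar)
    assert np.all(w > 0) and np.all(w <= 1.0)
    assert np.all(np.diff(w) <= 1e-12)
    assert w[0] == 1.0  # d = 0
    x = logistic_map(150)
    a = pd.DataFrame({"x": x})
    b = pd.DataFrame({"x": shift + scale * x})
    fa = smap_forecast(
        build_state_matrix(a, univariate_spec("x", 2)),
        a["x"].to_numpy(), theta=theta, tp=1,
    )
    fb = smap_forecast(
        build_state_matrix(b, univariate_spec("x", 2)),
        b["x"].to_numpy(), theta=theta, tp=1,
    )
    assert fa.skill == pytest.approx(fb.skill, abs=1e-9)
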