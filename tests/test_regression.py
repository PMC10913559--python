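"""Multivariate ilr regression, Pillai tests, estimated marginal means."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from timeuse_coda.coda import KAPPA, MVPA_FIRST, close, ilr_transform, pivot_sets
from timeuse_coda.regression import (
    COMPOSITION_COLUMNS,
    PIVOT_SCALE,
    ModelSpec,
    build_design,
    clr_exposure_effect,
    estimated_means,
    fit_coda,
    fit_movement_model,
    manova_pillai,
    pivot_coefficients,
)
from timeuse_coda.simulate import GeneratorConfig, gen_cohort, gen_compositions, plant_from_pivots


def design(rng, n=200):
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    return X, ["intercept", "z", "w"]


def synthetic_parts(rng, X, B_clr, resid_sd=0.3):
    """Compositions from planted clr-scale coefficient rows."""
    V = MVPA_FIRST.contrast_matrix
    coords = X @ (B_clr @ V) + rng.normal(0, resid_sd, (X.shape[0], 3))
    raw = np.exp(coords @ V.T)
    return raw * (KAPPA / raw.sum(axis=1, keepdims=True))


class TestFitCoda:
    def test_noise_free_exact_recovery(self, rng):
        X, names = design(rng)
        B0 = rng.normal(size=(3, 3))
        fit = fit_coda(X @ B0, X, names)
        np.testing.assert_allclose(fit.B, B0, atol=1e-10)
        np.testing.assert_allclose(fit.E, 0.0, atol=1e-18)

    def test_equals_stacked_univariate_fits(self, rng):
        X, names = design(rng)
        Y = X @ rng.normal(size=(3, 3)) + rng.normal(size=(200, 3))
        fit = fit_coda(Y, X, names)
        for j in range(3):
            bj, *_ = np.linalg.lstsq(X, Y[:, j], rcond=None)
            np.testing.assert_allclose(fit.B[:, j], bj, atol=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        n = 100
        z = rng.normal(size=n)
        X = np.column_stack([np.ones(n), z, 2 * z])
        with pytest.raises(np.linalg.LinAlgError, match="dup"):
            fit_coda(rng.normal(size=(n, 3)), X, ["intercept", "z", "dup"])

    def test_too_few_observations(self, rng):
        X, names = design(rng, n=5)
        with pytest.raises(ValueError, match="too small"):
            fit_coda(rng.normal(size=(5, 3)), X, names)


class TestPivotCoefficients:
    def test_zero_sum_identity(self, rng):
        X, names = design(rng)
        parts = synthetic_parts(rng, X, rng.normal(size=(3, 4)) * 0.05)
        table = pivot_coefficients(parts, X, names, "z")
        assert (table["estimate"] / PIVOT_SCALE).sum() == pytest.approx(
            0.0, abs=1e-10
        )

    def test_matches_clr_bridge_route(self, rng):
        X, names = design(rng)
        parts = synthetic_parts(rng, X, rng.normal(size=(3, 4)) * 0.05)
        table = pivot_coefficients(parts, X, names, "z")
        fit = fit_coda(ilr_transform(parts, MVPA_FIRST), X, names)
        bridge = PIVOT_SCALE * clr_exposure_effect(fit, "z")
        np.testing.assert_allclose(table["estimate"], bridge, atol=1e-10)

    def test_null_exposure_ci_coverage(self, rng):
        covered = 0
        reps = 300
        for _ in range(reps):
            n = 120
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            parts = synthetic_parts(
                rng, X, np.vstack([rng.normal(size=4) * 0.1, np.zeros(4)])
            )
            table = pivot_coefficients(parts, X, ["intercept", "z"], "z")
            row = table[table["behaviour"] == "mvpa"].iloc[0]
            covered += row["ci_low"] <= 0 <= row["ci_high"]
        assert 0.90 < covered / reps <= 0.99

    def test_published_quadruples_sum_to_about_zero(self):
        # printed one-vs-rest rows are internally consistent
        for quad in [(0.039, 0.013, -0.044, -0.008), (0.048, 0.015, -0.036, -0.028)]:
            assert abs(sum(quad)) <= 0.0011


class TestManovaPillai:
    def test_single_column_matches_hotelling_t2(self, rng):
        n = 150
        z = rng.normal(size=n)
        X = np.column_stack([np.ones(n), z])
        Y = np.outer(z, [0.1, -0.05, 0.02]) + rng.normal(size=(n, 3))
        res = manova_pillai(Y, X, [1])
        # closed-form Hotelling T^2 for one coefficient vector
        fit = fit_coda(Y, X, ["intercept", "z"])
        b = fit.B[1]
        S = fit.E / fit.dfe
        t2 = b @ np.linalg.solve(S * fit.xtx_inv[1, 1], b)
        F = (fit.dfe - 3 + 1) / (3 * fit.dfe) * t2
        p = stats.f.sf(F, 3, fit.dfe - 3 + 1)
        assert res["p"] == pytest.approx(p, abs=1e-10)
        assert res["F"] == pytest.approx(F, rel=1e-10)

    def test_invariant_across_pivot_bases(self, rng):
        X, names = design(rng)
        parts = synthetic_parts(rng, X, rng.normal(size=(3, 4)) * 0.05)
        ps = [
            manova_pillai(ilr_transform(parts, b), X, [1])["p"]
            for b in pivot_sets()
        ]
        assert max(ps) - min(ps) < 1e-10

    def test_matches_statsmodels_single_term(self, rng):
        sm = pytest.importorskip("statsmodels.multivariate.manova")
        n = 180
        z = rng.normal(size=n)
        w = rng.normal(size=n)
        X = np.column_stack([np.ones(n), z, w])
        Y = np.outer(z, [0.08, 0.0, -0.04]) + rng.normal(size=(n, 3))
        res = manova_pillai(Y, X, [1])
        mv = sm.MANOVA(Y, X)
        table = mv.mv_test(
            hypotheses=[("z", np.array([[0.0, 1.0, 0.0]]), None)]
        ).results["z"]["stat"]
        assert res["V"] == pytest.approx(
            table.loc["Pillai's trace", "Value"], abs=1e-10
        )
        assert res["p"] == pytest.approx(
            table.loc["Pillai's trace", "Pr > F"], abs=1e-10
        )

    def test_matches_statsmodels_multi_column_term(self, rng):
        sm = pytest.importorskip("statsmodels.multivariate.manova")
        n = 220
        g = rng.integers(0, 3, size=n)
        d1, d2 = (g == 1).astype(float), (g == 2).astype(float)
        X = np.column_stack([np.ones(n), d1, d2, rng.normal(size=n)])
        Y = np.outer(d1, [0.2, 0.0, -0.1]) + rng.normal(size=(n, 3))
        res = manova_pillai(Y, X, [1, 2])
        L = np.zeros((2, 4))
        L[0, 1] = L[1, 2] = 1.0
        table = sm.MANOVA(Y, X).mv_test(hypotheses=[("g", L, None)]).results[
            "g"
        ]["stat"]
        assert res["V"] == pytest.approx(
            table.loc["Pillai's trace", "Value"], abs=1e-10
        )
        assert res["p"] == pytest.approx(
            table.loc["Pillai's trace", "Pr > F"], abs=1e-10
        )

    def test_singular_residuals_rejected(self, rng):
        X = np.column_stack([np.ones(5), rng.normal(size=5)])
        with pytest.raises(Exception, match="n too small|singular"):
            manova_pillai(rng.normal(size=(5, 3)), X, [1])


class TestEstimatedMeans:
    def test_zero_effect_constant_composition(self, rng):
        X, names = design(rng)
        B_clr = np.vstack([rng.normal(size=4) * 0.1, np.zeros(4), np.zeros(4)])
        parts = synthetic_parts(rng, X, B_clr, resid_sd=0.0)
        fit = fit_coda(ilr_transform(parts, MVPA_FIRST), X, names)
        grid = estimated_means(fit)
        comps = grid.compositions[list(COMPOSITION_COLUMNS)].to_numpy()
        assert np.ptp(comps, axis=0).max() < 1e-6
        np.testing.assert_allclose(grid.deltas, 0.0, atol=1e-6)

    def test_monotone_when_clr_coefficient_positive(self, rng):
        X, names = design(rng)
        c = np.array([0.06, -0.01, -0.03, -0.02])
        parts = synthetic_parts(rng, X, np.vstack([rng.normal(size=4) * 0.1, c, np.zeros(4)]))
        fit = fit_coda(ilr_transform(parts, MVPA_FIRST), X, names)
        mvpa = estimated_means(fit).compositions["mvpa_min"].to_numpy()
        assert np.all(np.diff(mvpa) > 0)

    def test_planted_coefficients_match_algebraic_oracle(self, rng):
        # EMM at z is proportional to baseline * exp(clr_effect * z), closed
        n = 300
        z = rng.normal(size=n)
        X = np.column_stack([np.ones(n), z])
        x0 = close((71, 344, 488, 537)).as_array()
        c = plant_from_pivots((0.039, 0.013, -0.044, -0.008))
        B_clr = np.vstack([np.log(x0) - np.log(x0).mean(), c])
        parts = synthetic_parts(rng, X, B_clr, resid_sd=0.0)
        fit = fit_coda(ilr_transform(parts, MVPA_FIRST), X, ["intercept", "z"])
        grid = estimated_means(fit, z_values=(-2, -1, 0, 1, 2))
        for zi, row in zip(grid.z_values, grid.compositions[list(COMPOSITION_COLUMNS)].to_numpy()):
            expect = x0 * np.exp(c * zi)
            expect *= KAPPA / expect.sum()
            np.testing.assert_allclose(row, expect, atol=1e-9)

    def test_reference_row_reproduces_intercept_prediction(self, rng):
        X, names = design(rng)
        parts = synthetic_parts(rng, X, rng.normal(size=(3, 4)) * 0.05)
        fit = fit_coda(ilr_transform(parts, MVPA_FIRST), X, names)
        ref = np.array([1.0, 0.0, 0.0])
        grid = estimated_means(fit, z_values=(0.0,), reference=ref)
        from timeuse_coda.coda import ilr_inverse

        expect = ilr_inverse(fit.B[0], basis=MVPA_FIRST).as_array()
        np.testing.assert_allclose(
            grid.compositions[list(COMPOSITION_COLUMNS)].iloc[0], expect, atol=1e-9
        )


@pytest.fixture(scope="module")
def data():
    cfg = GeneratorConfig(
        n=425,
        effects={"involvement": plant_from_pivots((0.039, 0.013, -0.044, -0.008))},
    )
    rng = np.random.default_rng(11)
    cohort, _ = gen_cohort(cfg, rng)
    return gen_compositions(cohort, cfg, rng)


class TestMovementModelEndToEnd:
    def test_design_dummy_codes_against_reference(self, data):
        X, names = build_design(data, ModelSpec("involvement", adjusted=True))
        assert "ethnicity[Chinese]" not in names  # reference level
        assert "ethnicity[Malay]" in names and "ethnicity[Indian]" in names
        assert X[:, 0].min() == X[:, 0].max() == 1.0

    def test_adjusted_fit_structure(self, data):
        fit = fit_movement_model(data, "involvement", adjusted=True)
        assert fit.n == 425
        assert set(fit.pivot_table["behaviour"]) == set(
            ("mvpa", "lpa", "inactivity", "sleep")
        )
        assert 0 <= fit.pillai["p"] <= 1
        assert fit.pillai["df1"] == 3.0

    def test_pillai_detects_planted_effect(self, data):
        fit = fit_movement_model(data, "involvement", adjusted=False)
        assert fit.pillai["p"] < 0.05

    def test_null_exposure_not_significant(self, data):
        fit = fit_movement_model(data, "mobility_barriers", adjusted=False)
        assert fit.pillai["p"] > 0.01  # planted null; generous guard

    def test_missing_exposure_column_rejected(self, data):
        with pytest.raises(ValueError, match="exposure"):
            fit_movement_model(data, "nonexistent")
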