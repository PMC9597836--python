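"""Correlation, stratified regression, model selection and refinement."""

import numpy as np
import pandas as pd
import pytest

from rohbridge.bridge import (
    BridgeModel,
    DegenerateFitError,
    class_table,
    correlate,
    estimate_fped,
    fit_lrm,
    invert_boundary,
    lrm_by_fullgen,
    quartile_exclude,
    refine,
    round3,
    select_model,
    standardized_residuals,
)

GOAT_REFINED = BridgeModel(intercept=-0.03, slope=0.91, r=0.93,
                           r_squared=0.86, n=359, min_fullgen=4,
                           stage="refined", species="goat")
SHEEP_REFINED = BridgeModel(intercept=-0.03, slope=1.02, r=0.985,
                            r_squared=0.97, n=464, min_fullgen=6,
                            stage="refined", species="sheep")


def _table(f_roh, f_ped, fullgen=None, species="sheep", breed="B"):
    n = len(f_roh)
    return pd.DataFrame({
        "id": [f"a{i}" for i in range(n)],
        "species": species if isinstance(species, str) else species,
        "breed": breed,
        "f_ped": f_ped,
        "f_roh": f_roh,
        "f_grm": 0.0,
        "fullgen": fullgen if fullgen is not None else np.zeros(n, dtype=int),
    })


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x)["r"] == pytest.approx(1.0)
        assert correlate(x, -x)["r"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(50), rng.random(50)
        got = correlate(x, y)
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert got["r"] == pytest.approx(r, abs=1e-12)
        from scipy import stats
        t = r * np.sqrt(48 / (1 - r * r))
        p = 2 * stats.t.sf(abs(t), 48)
        assert got["p_value"] == pytest.approx(p, rel=1e-9)

    def test_rejects_tiny_input(self):
        with pytest.raises(ValueError):
            correlate([1, 2], [3, 4])


class TestFit:
    def test_noiseless_recovery(self):
        x = np.linspace(0.0, 0.4, 30)
        m = fit_lrm(_table(x, -0.03 + 0.97 * x))
        assert m.intercept == pytest.approx(-0.03, abs=1e-12)
        assert m.slope == pytest.approx(0.97, abs=1e-12)
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_predictor_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_lrm(_table(np.full(10, 0.1), np.arange(10.0)))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.random(80) * 0.3
        y = -0.02 + 0.9 * x + rng.normal(0, 0.02, 80)
        m = fit_lrm(_table(x, y))
        X = np.column_stack([np.ones(80), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert m.intercept == pytest.approx(beta[0], abs=1e-10)
        assert m.slope == pytest.approx(beta[1], abs=1e-10)
        resid = y - X @ beta
        r2 = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert m.r_squared == pytest.approx(r2, abs=1e-10)
        # univariate OLS: R^2 equals r^2
        assert m.r_squared == pytest.approx(m.r ** 2, abs=1e-10)

    def test_stratified_counts_nested(self):
        rng = np.random.default_rng(2)
        fullgen = rng.integers(0, 9, size=300)
        x = rng.random(300) * 0.3
        t = _table(x, 0.9 * x + rng.normal(0, 0.02, 300), fullgen=fullgen)
        models = lrm_by_fullgen(t, range(0, 9))
        ns = [m.n for m in models if m is not None]
        assert all(a >= b for a, b in zip(ns, ns[1:]))
        assert models[0].n == 300

    def test_k_beyond_max_fullgen_flagged_empty(self):
        t = _table(np.linspace(0, 0.3, 20), np.linspace(0, 0.3, 20),
                   fullgen=np.ones(20, dtype=int))
        models = lrm_by_fullgen(t, range(0, 4))
        assert models[2] is None and models[3] is None


class TestSelection:
    def test_published_stratum_choice(self, table2_models):
        assert select_model(table2_models, "goat").min_fullgen == 4
        assert select_model(table2_models, "sheep").min_fullgen == 6

    def test_single_qualifying_stratum_returned(self, table2_models):
        only = [table2_models[3]]
        assert select_model(only, "sheep").min_fullgen == 3

    def test_no_stratum_with_enough_animals_fatal(self, table2_models):
        with pytest.raises(DegenerateFitError, match="600"):
            select_model(table2_models[8:], "goat")


class TestResiduals:
    def test_all_equal_residuals_give_zero_z(self):
        m = BridgeModel(intercept=0.0, slope=1.0, r=1, r_squared=1, n=5)
        t = _table(np.linspace(0.1, 0.2, 5), np.linspace(0.1, 0.2, 5) - 0.01)
        z = standardized_residuals(m, t)
        np.testing.assert_allclose(z, 0.0)

    def test_z_scores_standardized(self):
        rng = np.random.default_rng(3)
        m = BridgeModel(intercept=0.0, slope=1.0, r=1, r_squared=1, n=40)
        t = _table(rng.random(40), rng.random(40))
        z = standardized_residuals(m, t)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_five_points(self):
        m = BridgeModel(intercept=0.0, slope=1.0, r=1, r_squared=1, n=5)
        t = _table(np.array([0.1, 0.2, 0.3, 0.4, 0.5]),
                   np.array([0.1, 0.1, 0.3, 0.5, 0.5]))
        d = np.array([0.0, 0.1, 0.0, -0.1, 0.0])  # predicted - observed
        z_expect = (d - d.mean()) / d.std(ddof=1)
        np.testing.assert_allclose(standardized_residuals(m, t), z_expect,
                                   atol=1e-12)

    @pytest.mark.parametrize("n,target", [(927, 463), (717, 358)])
    def test_quartile_exclusion_counts(self, n, target):
        rng = np.random.default_rng(n)
        z = rng.normal(size=n)
        assert len(np.unique(z)) == n
        excluded = int((~quartile_exclude(z)).sum())
        assert abs(excluded - target) <= 1

    def test_all_tied_values_keep_everything(self):
        assert quartile_exclude(np.zeros(50)).all()


class TestRefine:
    def test_noiseless_input_unchanged(self):
        x = np.linspace(0.01, 0.4, 50)
        t = _table(x, -0.03 + x, fullgen=np.full(50, 6))
        sel = fit_lrm(t, min_fullgen=6, stage="selected", species="sheep")
        sel = sel.__class__(**{**sel.to_dict(), "r": sel.r})
        ref = refine(sel, t)
        assert ref.intercept == pytest.approx(-0.03, abs=1e-10)
        assert ref.slope == pytest.approx(1.0, abs=1e-10)

    def test_planted_outliers_removed_slope_improves(self):
        rng = np.random.default_rng(4)
        x = rng.random(200) * 0.3
        y = -0.03 + 0.9 * x + rng.normal(0, 0.005, 200)
        y[:20] += rng.choice([-1, 1], 20) * 0.15  # gross pedigree errors
        t = _table(x, y, fullgen=np.full(200, 6))
        sel = fit_lrm(t, min_fullgen=6, stage="selected", species="sheep")
        ref = refine(sel, t)
        assert abs(ref.slope - 0.9) < abs(sel.slope - 0.9)
        assert ref.r_squared >= sel.r_squared

    def test_refined_model_carries_provenance(self):
        x = np.linspace(0.01, 0.4, 40)
        t = _table(x, -0.02 + x + np.sin(x) * 0.01, fullgen=np.full(40, 3))
        sel = fit_lrm(t, min_fullgen=3, stage="selected", species="sheep")
        ref = refine(sel, t)
        assert ref.stage == "refined" and ref.min_fullgen == 3
        assert ref.n < sel.n


class TestEstimation:
    def test_goat_refined_point_estimate(self):
        assert estimate_fped(0.10, GOAT_REFINED) == pytest.approx(0.061)

    def test_sheep_refined_point_estimate(self):
        assert estimate_fped(0.127, SHEEP_REFINED) == pytest.approx(0.09954)

    def test_zero_froh_returns_intercept(self):
        assert estimate_fped(0.0, GOAT_REFINED) == pytest.approx(-0.03)
        assert estimate_fped(0.0, GOAT_REFINED, clamp_at_zero=True) == 0.0

    @pytest.mark.parametrize("model,boundary,expect", [
        (GOAT_REFINED, 0.05, 0.088),
        (GOAT_REFINED, 0.10, 0.143),
        (SHEEP_REFINED, 0.05, 0.078),
        (SHEEP_REFINED, 0.15, 0.176),
    ])
    def test_boundary_inversion_matches_published_ranges(self, model, boundary, expect):
        assert invert_boundary(boundary, model) == expect

    def test_identity_model(self):
        ident = BridgeModel(intercept=0.0, slope=1.0, r=1, r_squared=1, n=3)
        assert invert_boundary(0.123, ident) == pytest.approx(0.123)

    def test_inversion_roundtrip(self):
        for b in (0.0, 0.05, 0.1, 0.2):
            fr = invert_boundary(b, SHEEP_REFINED)
            # agreement limited only by the 3-decimal report rounding
            assert estimate_fped(fr, SHEEP_REFINED) == pytest.approx(
                b, abs=0.0005 * SHEEP_REFINED.slope + 1e-12)

    def test_round3_half_away_from_zero(self):
        assert round3(0.0875) == 0.088
        assert round3(-0.0875) == -0.088
        assert round3(0.1425) == 0.143


class TestClassTable:
    def test_ci_formula_matches_published_row(self):
        # 27 animals, mean 0.293, sd 0.014 -> CI 0.288-0.298
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 27)
        v = (v - v.mean()) / v.std(ddof=1) * 0.014 + 0.293
        t = _table(v, np.zeros(27), breed="Sarda")
        est = np.full(27, 0.26)
        out = class_table(est, t)
        row = out.loc[out["breed"] == "all"].iloc[0]
        assert row["n"] == 27
        assert round3(row["froh_ci_lo"]) == 0.288
        assert round3(row["froh_ci_hi"]) == 0.298

    def test_single_animal_bin_blank_ci(self):
        t = _table([0.162], [0.0], breed="Comisana")
        out = class_table(np.array([0.12]), t)
        row = out.iloc[0]
        assert row["n"] == 1 and np.isnan(row["froh_ci_lo"])

    def test_zero_sd_ci_collapses_to_mean(self):
        t = _table([0.1, 0.1, 0.1], [0.0] * 3)
        out = class_table(np.array([0.07] * 3), t)
        row = out.loc[out["breed"] == "all"].iloc[0]
        assert row["froh_ci_lo"] == pytest.approx(0.1)
        assert row["froh_ci_hi"] - row["froh_ci_lo"] == pytest.approx(0.0, abs=1e-12)

    def test_every_animal_in_exactly_one_bin_and_counts_add_up(self):
        rng = np.random.default_rng(9)
        n = 200
        t = _table(rng.random(n) * 0.35, np.zeros(n),
                   breed=rng.choice(["X", "Y", "Z"], n))
        est = rng.random(n) * 0.3 - 0.02
        out = class_table(est, t)
        alls = out.loc[out["breed"] == "all"]
        assert alls["n"].sum() == n
        for _, arow in alls.iterrows():
            per_breed = out.loc[(out["breed"] != "all")
                                & (out["fped_class_lo"] == arow["fped_class_lo"])]
            assert per_breed["n"].sum() == arow["n"]

    def test_negative_estimates_floor_into_first_bin(self):
        t = _table([0.01, 0.02], [0.0, 0.0])
        out = class_table(np.array([-0.02, 0.01]), t)
        alls = out.loc[out["breed"] == "all"]
        assert len(alls) == 1 and alls.iloc[0]["fped_class_lo"] == 0.0
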