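"""Mixed-model effect sizes, AIC shape selection, variance partitioning."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from warmnet import (
    fit_shape,
    hierarchical_partition,
    link_model,
    lmm_effect_sizes,
)
from warmnet.inference import marginal_r2, significance_stars


@pytest.fixture
def design(topsoil_design):
    return topsoil_design


class TestEffectSizes:
    def test_constant_response(self, design):
        treat, block = design
        est = lmm_effect_sizes(np.full(20, 3.0), treat, block, control=0.0)
        assert (est.table["beta"] == 0).all()
        assert est.chi2 == 0.0 and est.p_value == 1.0

    def test_control_row_is_reference(self, design):
        treat, block = design
        rng = np.random.default_rng(0)
        est = lmm_effect_sizes(rng.normal(size=20), treat, block, control=0.0)
        assert est.table.loc[0.0, "beta"] == 0.0
        assert est.chi2 >= 0.0 and 0.0 <= est.p_value <= 1.0

    def test_unknown_control_rejected(self, design):
        treat, block = design
        with pytest.raises(ValueError):
            lmm_effect_sizes(np.ones(20), treat, block, control=9.9)

    def test_zero_block_variance_matches_ols(self, design):
        treat, block = design
        rng = np.random.default_rng(1)
        levels = [0.0, 0.8, 1.5, 3.0, 4.2]
        truth = dict(zip(levels, [0.0, 1.0, 2.0, 3.0, 1.5]))
        y = np.array([truth[t] for t in treat]) + rng.normal(0, 0.3, 20)
        est = lmm_effect_sizes(y, treat, block, control=0.0)
        X = np.column_stack([np.ones(20)] +
                            [(treat == lv).astype(float) for lv in levels[1:]])
        ols = sm.OLS(y, X).fit()
        assert np.allclose(est.table["beta"].to_numpy()[1:], ols.params[1:],
                           atol=1e-4)

    def test_recovers_planted_effects_on_average(self, design):
        treat, block = design
        levels = [0.0, 0.8, 1.5, 3.0, 4.2]
        truth = dict(zip(levels, [0.0, 1.0, 2.0, 3.0, 1.5]))
        betas = []
        for i in range(60):
            rng = np.random.default_rng(100 + i)
            b_eff = dict(zip([1, 2, 3, 4], rng.normal(0, 0.5, 4)))
            y = (np.array([truth[t] for t in treat])
                 + np.array([b_eff[b] for b in block])
                 + rng.normal(0, 0.5, 20))
            est = lmm_effect_sizes(y, treat, block, control=0.0)
            betas.append(est.table["beta"].to_numpy())
        mean_beta = np.mean(betas, axis=0)
        assert np.abs(mean_beta - [0, 1, 2, 3, 1.5]).max() < 0.2

    def test_stars_convention(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.2) == ""


class TestFitShape:
    def test_exact_linear_selects_linear(self, design):
        treat, block = design
        y = 2.0 + 0.5 * treat
        sel = fit_shape(treat, y, block)
        assert sel.selected == "linear"

    def test_quadratic_with_interior_peak_flags_unimodal(self, design):
        treat, block = design
        rng = np.random.default_rng(2)
        y = -((treat - 2.0) ** 2) + rng.normal(0, 0.1, 20)
        sel = fit_shape(treat, y, block)
        assert sel.selected == "quadratic"
        assert sel.decisive and sel.unimodal

    def test_upward_quadratic_not_unimodal(self, design):
        treat, block = design
        rng = np.random.default_rng(3)
        y = (treat - 2.0) ** 2 + rng.normal(0, 0.1, 20)
        sel = fit_shape(treat, y, block)
        assert sel.selected == "quadratic" and not sel.unimodal

    def test_needs_six_observations(self):
        with pytest.raises(ValueError):
            fit_shape(np.arange(5), np.arange(5))

    def test_degenerate_predictor_skips_quadratic(self):
        x = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 1.0])
        with pytest.warns(UserWarning, match="degenerate"):
            sel = fit_shape(x, np.random.default_rng(0).normal(size=6))
        assert sel.selected == "linear"

    def test_ols_aic_matches_closed_form_gaussian(self):
        # AIC = 2k - 2 loglik with the Gaussian ML likelihood
        rng = np.random.default_rng(4)
        x = np.linspace(0, 4, 12)
        y = 1.0 + 0.3 * x + rng.normal(0, 0.2, 12)
        sel = fit_shape(x, y)  # no blocks -> OLS path
        xc = x - x.mean()
        X = np.column_stack([np.ones_like(x), xc])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        n = len(y)
        sigma2 = np.mean(resid**2)
        llf = -n / 2 * (np.log(2 * np.pi * sigma2) + 1)
        assert sel.aic_linear == pytest.approx(2 * 3 - 2 * llf)


class TestHierarchicalPartition:
    def _problem(self, seed=0, n=24, k=3):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, k)),
                         columns=[f"v{i}" for i in range(k)])
        y = X.iloc[:, 0].to_numpy() + rng.normal(0, 1, n)
        if k > 1:
            y = y + 0.5 * X.iloc[:, 1].to_numpy()
        block = np.repeat([1, 2, 3, 4], n // 4)
        return y, X, block

    def test_single_predictor_gets_full_r2(self):
        y, X, block = self._problem(k=1)
        part = hierarchical_partition(y, X, block)
        assert part.contributions.iloc[0] == pytest.approx(
            part.full_marginal_r2)

    def test_additivity(self):
        y, X, block = self._problem(seed=1, k=4)
        part = hierarchical_partition(y, X, block)
        assert part.contributions.sum() == pytest.approx(
            part.full_marginal_r2, abs=1e-8)

    def test_matches_all_orderings_oracle(self):
        y, X, block = self._problem(seed=2, k=3)
        part = hierarchical_partition(y, X, block)
        Xs = ((X - X.mean()) / X.std()).to_numpy()
        cache = {}

        def r2(S):
            fs = frozenset(S)
            if fs not in cache:
                cache[fs] = marginal_r2(y, Xs[:, sorted(fs)], block)
            return cache[fs]

        k = X.shape[1]
        contrib = np.zeros(k)
        for perm in itertools.permutations(range(k)):
            S = set()
            for j in perm:
                contrib[j] += r2(S | {j}) - r2(S)
                S.add(j)
        contrib /= math.factorial(k)
        assert np.allclose(part.contributions.to_numpy(), contrib, atol=1e-8)

    def test_orthogonal_predictors_get_individual_r2(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        rng = np.random.default_rng(3)
        y = 1.0 * x1 + 0.5 * x2 + rng.normal(0, 1, n)
        block = np.tile([1, 2, 3, 4], n // 4)
        X = pd.DataFrame({"a": x1, "b": x2})
        part = hierarchical_partition(y, X, block)
        ind_a = marginal_r2(y, ((x1 - x1.mean()) / x1.std(ddof=1))[:, None],
                            block)
        ind_b = marginal_r2(y, ((x2 - x2.mean()) / x2.std(ddof=1))[:, None],
                            block)
        assert part.contributions["a"] == pytest.approx(ind_a, abs=0.03)
        assert part.contributions["b"] == pytest.approx(ind_b, abs=0.03)

    def test_identical_predictors_split_evenly(self):
        y, X, block = self._problem(seed=4, k=1)
        X2 = pd.DataFrame({"a": X.iloc[:, 0], "b": X.iloc[:, 0]})
        part = hierarchical_partition(y, X2, block)
        assert part.contributions["a"] == pytest.approx(
            part.contributions["b"])
        assert part.contributions.sum() == pytest.approx(
            part.full_marginal_r2, abs=1e-8)

    def test_predictor_cap(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(30, 14)))
        with pytest.raises(ValueError, match="cap"):
            hierarchical_partition(rng.normal(size=30), X,
                                   np.repeat([1, 2, 3], 10))


class TestLinkModel:
    def test_constant_predictor_rejected(self, design):
        treat, block = design
        with pytest.raises(ValueError, match="degenerate"):
            link_model(np.random.default_rng(0).normal(size=20),
                       np.ones(20), block)

    def test_positive_link_recovered(self, design):
        treat, block = design
        hits = 0
        for i in range(40):
            rng = np.random.default_rng(200 + i)
            x = rng.normal(0, 1, 20)
            b_eff = dict(zip([1, 2, 3, 4], rng.normal(0, 0.3, 4)))
            y = 0.8 * x + np.array([b_eff[b] for b in block]) \
                + rng.normal(0, 0.3, 20)
            res = link_model(y, x, block)
            slope = res.coefficients[1]
            hits += (slope > 0) and (res.slope_p < 0.05)
        assert hits >= 38  # strong signal: nearly always detected

    def test_null_link_ci_coverage(self, design):
        treat, block = design
        covered = 0
        n_sim = 50
        for i in range(n_sim):
            rng = np.random.default_rng(300 + i)
            x = rng.normal(0, 1, 20)
            y = rng.normal(0, 1, 20)
            res = link_model(y, x, block)
            if res.shape.selected == "linear":
                se_ok = res.slope_p >= 0.05
            else:
                se_ok = res.slope_p >= 0.05
            covered += se_ok
        assert covered >= 0.85 * n_sim

    def test_prediction_band_shape(self, design):
        treat, block = design
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 20)
        y = 0.5 * x + rng.normal(0, 0.5, 20)
        res = link_model(y, x, block)
        pred = res.prediction
        assert pred["x"].min() == pytest.approx(x.min())
        assert pred["x"].max() == pytest.approx(x.max())
        assert (pred["ci_low"] <= pred["fit"]).all()
        assert (pred["fit"] <= pred["ci_high"]).all()
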