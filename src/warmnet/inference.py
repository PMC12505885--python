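"""Mixed-model inference layer.

Treatment effect sizes come from Gaussian linear mixed models with the
warming level as a categorical fixed effect (ambient control as reference)
and block random intercepts; the treatment factor is tested with a Wald
type II chi-square, which for a single categorical predictor is the joint
Wald test of all treatment coefficients. Response-shape selection compares
degree-1 and degree-2 fits on the warming-offset axis by maximum-likelihood
AIC (decisive only when the AIC difference exceeds 2). Hierarchical
variance partitioning decomposes the full model's marginal R^2 (fixed-
effects variance over total variance) into per-predictor contributions
averaged over all predictor entry orders. Link models relate the
multinutrient index to network metrics with the same machinery.

Coefficients are reported from REML fits; AIC comparisons use ML fits,
since REML likelihoods are not comparable across fixed-effects structures.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

logger = logging.getLogger(__name__)

MAX_PARTITION_PREDICTORS = 13


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class EffectSizeTable:
    """Per-treatment-level effect sizes from a block random-intercept LMM."""

    response: str
    table: pd.DataFrame  # rows: treatment levels; beta, se, ci_low, ci_high, stars
    chi2: float
    p_value: float
    df: int
    stars: str
    block_variance: float
    control: object


@dataclass
class ShapeSelection:
    """Linear-vs-quadratic AIC comparison on a continuous predictor."""

    aic_linear: float
    aic_quadratic: float
    selected: str
    delta_aic: float
    decisive: bool
    unimodal: bool
    coefficients: dict[str, np.ndarray]


@dataclass
class VariancePartition:
    contributions: pd.Series  # per-predictor share of full-model marginal R^2
    full_marginal_r2: float
    ranking: list[str]
    p_values: pd.Series


@dataclass
class LinkResult:
    response: str
    predictor: str
    shape: ShapeSelection
    coefficients: np.ndarray
    slope_p: float
    prediction: pd.DataFrame = field(repr=False)  # x, fit, ci_low, ci_high


# ---------------------------------------------------------------------------
# fitting helpers


def _fit_lmm(y: np.ndarray, X: np.ndarray, groups: np.ndarray, reml: bool = True,
             stable: bool = False):
    """Random-intercept LMM fit; silences the convergence chatter of small
    designs and falls back across optimizers if needed.

    ``stable=True`` runs two optimizers and keeps the better likelihood;
    the profile likelihood is flat near zero block variance and a single
    optimizer can stop at visibly different variance estimates.
    """
    model = MixedLM(endog=np.asarray(y, dtype=float), exog=np.asarray(X, dtype=float),
                    groups=np.asarray(groups))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml, method="lbfgs")
        except Exception:
            res = model.fit(reml=reml, method="powell")
        if stable:
            try:
                alt = model.fit(reml=reml, method="powell")
                if np.isfinite(alt.llf) and (not np.isfinite(res.llf)
                                             or alt.llf > res.llf + 1e-10):
                    res = alt
            except Exception:
                pass
    return res


def _lmm_aic(res) -> float:
    """AIC = 2k - 2 loglik with k = fixed effects + variance components."""
    k = res.k_fe + res.k_re2 + 1  # +1 for the residual variance
    return 2.0 * k - 2.0 * res.llf


def _block_variance(res) -> float:
    try:
        return float(np.asarray(res.cov_re)[0, 0])
    except Exception:
        return float("nan")


def lmm_effect_sizes(
    response,
    treatment,
    block,
    control=None,
    response_name: str = "response",
) -> EffectSizeTable:
    """Effect size beta per warming level vs control, with Wald type II chi2.

    ``treatment`` may be numeric warming offsets or labels; ``control``
    defaults to the smallest/first level. Zero estimated block variance is
    reported as such (never a silent failure); a constant response yields
    all-zero effects with chi2 = 0.
    """
    y = np.asarray(response, dtype=float)
    treat = pd.Series(np.asarray(treatment), name="treatment")
    groups = np.asarray(block)
    levels = list(pd.unique(np.sort(treat.to_numpy())))
    if control is None:
        control = levels[0]
    if control not in levels:
        raise ValueError(f"control level {control!r} not among treatments")
    others = [lv for lv in levels if lv != control]

    if np.ptp(y) == 0:
        tab = pd.DataFrame(
            {"beta": 0.0, "se": 0.0, "ci_low": 0.0, "ci_high": 0.0, "stars": ""},
            index=pd.Index([control] + others, name="level"),
        )
        return EffectSizeTable(response_name, tab, 0.0, 1.0, len(others), "",
                               0.0, control)

    X = np.column_stack(
        [np.ones(len(y))] + [(treat == lv).to_numpy(dtype=float) for lv in others]
    )
    res = _fit_lmm(y, X, groups, reml=True)
    block_var = _block_variance(res)
    if block_var <= 1e-10:
        logger.info("%s: estimated block variance is 0 (singular random effect); "
                    "coefficients equal the fixed-effects fit", response_name)

    beta = res.fe_params[1:]
    se = res.bse_fe[1:]
    cov = np.asarray(res.cov_params())[1 : 1 + len(others), 1 : 1 + len(others)]
    try:
        chi2 = float(beta @ np.linalg.solve(cov, beta))
    except np.linalg.LinAlgError:
        chi2 = float(beta @ np.linalg.pinv(cov) @ beta)
    df = len(others)
    # Asymptotic chi2 reference is anticonservative with 4 blocks and 20
    # plots; calibrate the p-value against F(df, ddf) with between-within
    # denominator degrees of freedom (statistic itself stays the Wald chi2)
    n_groups = len(np.unique(groups))
    ddf = max(1, len(y) - X.shape[1] - (n_groups - 1))
    p = float(stats.f.sf(chi2 / df, df, ddf))

    z = stats.norm.ppf(0.975)
    per_level_p = 2 * stats.norm.sf(np.abs(beta / np.where(se > 0, se, np.nan)))
    rows = [{"beta": 0.0, "se": 0.0, "ci_low": 0.0, "ci_high": 0.0, "stars": ""}]
    for b, s, pl in zip(beta, se, per_level_p):
        rows.append({"beta": float(b), "se": float(s), "ci_low": float(b - z * s),
                     "ci_high": float(b + z * s), "stars": significance_stars(pl)})
    tab = pd.DataFrame(rows, index=pd.Index([control] + others, name="level"))
    return EffectSizeTable(response_name, tab, chi2, p, df,
                           significance_stars(p), block_var, control)


def fit_shape(x, y, block=None) -> ShapeSelection:
    """Compare linear vs quadratic response shapes by ML AIC.

    With ``block`` given, both candidates are block random-intercept mixed
    models fit by ML; otherwise ordinary least squares. ``unimodal`` is
    True when the quadratic wins, opens downward, and its vertex lies
    strictly inside the observed x range. Degenerate x (fewer than 3
    distinct values) skips the quadratic with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 6:
        raise ValueError("need at least 6 observations for shape selection")
    xc = x - x.mean()  # centering stabilizes the quadratic fit
    X1 = np.column_stack([np.ones_like(x), xc])
    designs = {"linear": X1}
    if np.unique(x).size >= 3:
        designs["quadratic"] = np.column_stack([X1, xc**2])
    else:
        warnings.warn("degenerate predictor: quadratic shape skipped")

    # noiseless data break ML fits (log-likelihood diverges); an exact
    # linear fit needs no quadratic term
    beta_lin, ss_lin, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid_lin = y - X1 @ beta_lin
    if np.allclose(resid_lin, 0.0, atol=1e-10 * max(1.0, np.abs(y).max())):
        return ShapeSelection(-np.inf, np.nan, "linear", np.inf, True, False,
                              {"linear": beta_lin})

    aics, coefs = {}, {}
    for name, X in designs.items():
        if block is not None:
            res = _fit_lmm(y, X, np.asarray(block), reml=False)
            aics[name] = _lmm_aic(res)
            coefs[name] = np.asarray(res.fe_params)
        else:
            res = sm.OLS(y, X).fit()
            # count the residual variance as a parameter so the OLS and
            # mixed-model AIC conventions agree
            aics[name] = float(res.aic) + 2.0
            coefs[name] = np.asarray(res.params)

    if "quadratic" not in designs:
        return ShapeSelection(aics["linear"], np.nan, "linear", np.nan, False,
                              False, coefs)
    selected = min(aics, key=aics.get)
    delta = abs(aics["linear"] - aics["quadratic"])
    unimodal = False
    if selected == "quadratic":
        b1, b2 = coefs["quadratic"][1], coefs["quadratic"][2]
        if b2 < 0:
            vertex = -b1 / (2.0 * b2)
            unimodal = xc.min() < vertex < xc.max()
    return ShapeSelection(aics["linear"], aics["quadratic"], selected, delta,
                          delta > 2.0, unimodal, coefs)


# ---------------------------------------------------------------------------
# hierarchical variance partitioning


def _independent_columns(X: np.ndarray, tol: float = 1e-8) -> list[int]:
    """Greedy left-to-right selection of linearly independent columns."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial, tol=tol) == len(keep) + 1:
            keep.append(j)
    return keep


def marginal_r2(y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> float:
    """Nakagawa-Schielzeth marginal R^2 of a random-intercept LMM.

    var(fixed-effect predictions) / (fixed + block + residual variance).
    An intercept-only model has marginal R^2 = 0 by definition. Collinear
    design columns are reduced before fitting (fitted values unchanged).
    """
    if X.shape[1] == 0:
        return 0.0
    Xi = np.column_stack([np.ones(len(y)), X])
    keep = _independent_columns(Xi)
    res = _fit_lmm(y, Xi[:, keep], groups, reml=False, stable=True)
    fitted = Xi[:, keep] @ res.fe_params
    var_f = float(np.var(fitted, ddof=1))
    var_b = _block_variance(res)
    var_e = float(res.scale)
    return var_f / (var_f + var_b + var_e)


def hierarchical_partition(
    response, predictors: pd.DataFrame, block,
) -> VariancePartition:
    """Average-over-orderings decomposition of the marginal R^2.

    Each predictor's individual contribution is the hierarchy-weighted sum
    over subsets S (not containing it) of the marginal-R^2 increment when
    it enters, with weights w(|S|) = |S|! (k-|S|-1)! / k!. Contributions
    sum to the full model's marginal R^2. Predictors are standardized
    before fitting. Exact enumeration over 2^k subsets; k is capped.
    """
    y = np.asarray(response, dtype=float)
    groups = np.asarray(block)
    names = list(predictors.columns)
    k = len(names)
    if k == 0:
        raise ValueError("need at least one predictor")
    if k > MAX_PARTITION_PREDICTORS:
        raise ValueError(
            f"{k} predictors exceed the exact-enumeration cap "
            f"({MAX_PARTITION_PREDICTORS}); pre-screen the predictor set"
        )
    Xall = predictors.to_numpy(dtype=float)
    sd = Xall.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xall = (Xall - Xall.mean(axis=0)) / sd

    r2: dict[frozenset, float] = {}
    for size in range(k + 1):
        for S in itertools.combinations(range(k), size):
            r2[frozenset(S)] = marginal_r2(y, Xall[:, list(S)], groups)

    contrib = np.zeros(k)
    fact = [math.factorial(i) for i in range(k + 1)]
    for j in range(k):
        rest = [i for i in range(k) if i != j]
        for size in range(k):
            w = fact[size] * fact[k - size - 1] / fact[k]
            for S in itertools.combinations(rest, size):
                fs = frozenset(S)
                contrib[j] += w * (r2[fs | {j}] - r2[fs])

    full = r2[frozenset(range(k))]
    # per-predictor significance from the full mixed model
    Xi = np.column_stack([np.ones(len(y)), Xall])
    keep = _independent_columns(Xi)
    res = _fit_lmm(y, Xi[:, keep], groups, reml=True)
    pvals = pd.Series(np.nan, index=names)
    kept_names = [(["intercept"] + names)[i] for i in keep]
    pz = 2 * stats.norm.sf(np.abs(np.asarray(res.fe_params) / np.asarray(res.bse_fe)))
    for nm, p in zip(kept_names, pz):
        if nm != "intercept":
            pvals[nm] = p

    contributions = pd.Series(contrib, index=names)
    ranking = list(contributions.sort_values(ascending=False).index)
    return VariancePartition(contributions, full, ranking, pvals)


# ---------------------------------------------------------------------------
# metric -> function link models


def link_model(
    mnc, predictor, block, response_name: str = "mnc", predictor_name: str = "metric",
    n_grid: int = 100,
) -> LinkResult:
    """Gaussian random-intercept model linking a metric to the MNC.

    Linear and quadratic candidates are compared by ML AIC (decisive when
    the difference exceeds 2); the selected shape is refit by REML for
    reporting. The prediction curve and 95% confidence band cover the
    observed predictor range only.
    """
    y = np.asarray(mnc, dtype=float)
    x = np.asarray(predictor, dtype=float)
    groups = np.asarray(block)
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: predictor is constant")
    shape = fit_shape(x, y, block=groups)

    xc = x - x.mean()
    if shape.selected == "quadratic":
        X = np.column_stack([np.ones_like(x), xc, xc**2])
    else:
        X = np.column_stack([np.ones_like(x), xc])
    res = _fit_lmm(y, X, groups, reml=True)
    beta = np.asarray(res.fe_params)
    slope_p = float(2 * stats.norm.sf(abs(beta[1] / res.bse_fe[1])))

    grid = np.linspace(x.min(), x.max(), n_grid)
    gc = grid - x.mean()
    Xg = np.column_stack([np.ones_like(grid), gc] +
                         ([gc**2] if shape.selected == "quadratic" else []))
    cov_fe = np.asarray(res.cov_params())[: X.shape[1], : X.shape[1]]
    fit = Xg @ beta
    var = np.clip(np.einsum("ij,jk,ik->i", Xg, cov_fe, Xg), 0.0, None)
    se = np.sqrt(var)
    zq = stats.norm.ppf(0.975)
    pred = pd.DataFrame({"x": grid, "fit": fit,
                         "ci_low": fit - zq * se, "ci_high": fit + zq * se})
    return LinkResult(response_name, predictor_name, shape, beta, slope_p, pred)
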