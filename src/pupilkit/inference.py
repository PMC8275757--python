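"""Regression, correlation, and evidence summaries.

Engines
-------
``bayes``
    Analytic posterior of the normal linear model under the flat
    (uninformative) reference prior ``p(beta, sigma^2) ~ 1/sigma^2``: the
    marginal posterior of each coefficient is a scaled-and-shifted Student t
    centred on the OLS estimate, so posterior means coincide with OLS point
    estimates and credible intervals with confidence intervals — the stated
    behaviour of uninformative-prior Bayesian fits.  No sampling is involved,
    which keeps results exactly reproducible.
``ols``
    Classical OLS via statsmodels (deterministic fallback; identical point
    estimates, intervals from the same t distribution).

Bayes factors use the JZS (Zellner–Siow) default prior, evaluated by
one-dimensional numerical integration; a BIC approximation engine is also
provided.  The engine used is always recorded in the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, special, stats

from .errors import CollinearityError, ConfigError, DataError

logger = logging.getLogger(__name__)

CONDITION_NUMBER_LIMIT = 1e8


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    """Coefficient table plus evidence summaries for one linear model."""

    params: pd.DataFrame  # index: term; estimate, sd, ci_low, ci_high, ci90_low, ci90_high
    engine: str
    n: int
    df_resid: int
    r_squared: float
    sigma: float
    condition_number: float
    scaling: dict[str, tuple[float, float]]
    bayes_factor: float | None = None
    bf_engine: str | None = None

    def estimate(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def interval(self, term: str, level: float = 0.95) -> tuple[float, float]:
        lo, hi = ("ci_low", "ci_high") if level == 0.95 else ("ci90_low", "ci90_high")
        return float(self.params.loc[term, lo]), float(self.params.loc[term, hi])

    def to_dict(self) -> dict:
        return {
            "engine": self.engine,
            "n": self.n,
            "df_resid": self.df_resid,
            "r_squared": self.r_squared,
            "sigma": self.sigma,
            "condition_number": self.condition_number,
            "bayes_factor": self.bayes_factor,
            "bf_engine": self.bf_engine,
            "scaling": {k: list(v) for k, v in self.scaling.items()},
            "coefficients": {
                term: {c: float(row[c]) for c in self.params.columns}
                for term, row in self.params.iterrows()
            },
        }


@dataclass
class CorrelationResult:
    spearman_rho: float
    ci_low: float
    ci_high: float
    pp_positive: float
    r_squared: float
    n: int
    engine: str
    bayes_factor: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class PairedShiftResult:
    mean_difference: float
    ci_low: float
    ci_high: float
    pp_positive: float
    n: int
    bayes_factor: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


def standardize(
    predictors: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Mean-centre and scale the named columns to unit SD (sample, ddof=1).

    Returns the transformed frame and a ``{column: (mean, sd)}`` record of
    the constants so fitted slopes can be mapped back to the raw scale.
    """
    out = predictors.copy()
    constants: dict[str, tuple[float, float]] = {}
    for col in columns if columns is not None else list(predictors.columns):
        x = out[col].to_numpy(dtype=float)
        mu = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            raise DataError(f"predictor {col!r} has zero variance")
        out[col] = (x - mu) / sd
        constants[col] = (mu, sd)
    return out, constants


# ---------------------------------------------------------------------------
# linear model core
# ---------------------------------------------------------------------------


def fit_linear_model(
    y: np.ndarray,
    X: pd.DataFrame,
    engine: str = "bayes",
    bf_method: str | None = "jzs",
    scaling: dict[str, tuple[float, float]] | None = None,
) -> RegressionResult:
    """Fit ``y ~ 1 + X`` and summarize coefficients and evidence.

    ``X`` holds named predictors without an intercept column (one is added).
    """
    if engine not in ("bayes", "ols"):
        raise ConfigError(f"unknown engine {engine!r}")
    y = np.asarray(y, dtype=float)
    n, p = len(y), X.shape[1]
    if n < p + 2:
        raise DataError(f"need at least {p + 2} observations, got {n}")
    design = sm.add_constant(X.astype(float), prepend=True, has_constant="add")
    cond = float(np.linalg.cond(design.to_numpy()))
    if cond > CONDITION_NUMBER_LIMIT:
        raise CollinearityError(cond)

    fit = sm.OLS(y, design).fit()
    nu = int(fit.df_resid)
    est = fit.params
    se = fit.bse
    tq95 = stats.t.ppf(0.975, nu)
    tq90 = stats.t.ppf(0.95, nu)
    if engine == "bayes":
        # flat-prior marginal posterior: t(nu, loc=est, scale=se)
        sd = se * np.sqrt(nu / (nu - 2)) if nu > 2 else se * np.nan
    else:
        sd = se
    params = pd.DataFrame(
        {
            "estimate": est,
            "sd": sd,
            "ci_low": est - tq95 * se,
            "ci_high": est + tq95 * se,
            "ci90_low": est - tq90 * se,
            "ci90_high": est + tq90 * se,
        }
    )
    params.index = ["intercept"] + list(X.columns)

    bf = bf_eng = None
    if bf_method is not None:
        bf = bayes_factor_vs_intercept(y, X, method=bf_method)
        bf_eng = bf_method
    return RegressionResult(
        params=params,
        engine=engine,
        n=n,
        df_resid=nu,
        r_squared=float(fit.rsquared),
        sigma=float(np.sqrt(fit.scale)),
        condition_number=cond,
        scaling=scaling or {},
        bayes_factor=bf,
        bf_engine=bf_eng,
    )


def fit_success_model(
    scores: pd.DataFrame,
    covariates: bool = False,
    engine: str = "bayes",
    include_interaction: bool = True,
    bf_method: str | None = "jzs",
) -> RegressionResult:
    """Regress reappraisal success on standardized PDI, affective distance,
    their interaction, and optionally age + task order.

    Continuous predictors are mean-centred and standardized; the interaction
    is the product of the standardized terms; task order is coded 0/1 with
    emotion-first as reference.
    """
    cols = ["pdi", "affective_distance"] + (["age"] if covariates else [])
    Xs, constants = standardize(scores[cols])
    X = pd.DataFrame(index=scores.index)
    X["pdi"] = Xs["pdi"]
    X["affective_distance"] = Xs["affective_distance"]
    if covariates:
        X["age"] = Xs["age"]
        X["task_order"] = scores["task_order"].astype(float)
    if include_interaction:
        X["pdi_x_affective_distance"] = Xs["pdi"] * Xs["affective_distance"]
    return fit_linear_model(
        scores["rs"].to_numpy(), X, engine=engine, bf_method=bf_method,
        scaling=constants,
    )


def fit_hcs_model(
    scores: pd.DataFrame,
    engine: str = "bayes",
    bf_method: str | None = "jzs",
) -> RegressionResult:
    """Regress health challenge success (percent) on standardized PDI + task order."""
    Xs, constants = standardize(scores[["pdi"]])
    X = pd.DataFrame(index=scores.index)
    X["pdi"] = Xs["pdi"]
    X["task_order"] = scores["task_order"].astype(float)
    return fit_linear_model(
        scores["hcs"].to_numpy(), X, engine=engine, bf_method=bf_method,
        scaling=constants,
    )


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------


def jzs_regression_bf(r_squared: float, n: int, p: int) -> float:
    """JZS Bayes factor for a p-covariate linear model vs intercept-only.

    Zellner–Siow mixture of g-priors: g ~ InverseGamma(1/2, n/2), giving

        BF10 = int (1+g)^((n-p-1)/2) [1+g(1-R^2)]^(-(n-1)/2) pi(g) dg.
    """
    if not (0.0 <= r_squared < 1.0):
        raise DataError("R^2 must lie in [0, 1)")
    if n <= p + 1:
        raise DataError("need n > p + 1 for the JZS Bayes factor")

    log_norm = 0.5 * np.log(n / 2.0) - special.gammaln(0.5)

    def log_integrand(u: float) -> float:
        g = np.exp(u)
        return (
            0.5 * (n - p - 1) * np.log1p(g)
            - 0.5 * (n - 1) * np.log1p(g * (1.0 - r_squared))
            + log_norm
            - 0.5 * u          # -(3/2) log g + log g Jacobian
            - n / (2.0 * g)
        )

    # integrate over u = log g; shift by the max for numerical stability
    us = np.linspace(-12.0, 25.0, 400)
    shift = max(log_integrand(u) for u in us)
    val, _ = integrate.quad(
        lambda u: np.exp(log_integrand(u) - shift), -12.0, 25.0, limit=200
    )
    return float(np.exp(np.log(val) + shift))


def jzs_ttest_bf(t: float, n: int, rscale: float = np.sqrt(2) / 2) -> float:
    """JZS one-sample t Bayes factor (Cauchy prior, scale ``rscale``)."""
    nu = n - 1
    log_h0 = -0.5 * (nu + 1) * np.log1p(t * t / nu)
    b = rscale * rscale / 2.0
    log_norm = 0.5 * np.log(b) - special.gammaln(0.5)

    def log_integrand(u: float) -> float:
        g = np.exp(u)
        return (
            -0.5 * np.log1p(n * g)
            - 0.5 * (nu + 1) * np.log1p(t * t / ((1.0 + n * g) * nu))
            + log_norm
            - 0.5 * u
            - b / g
        )

    us = np.linspace(-15.0, 25.0, 400)
    shift = max(log_integrand(u) for u in us)
    val, _ = integrate.quad(
        lambda u: np.exp(log_integrand(u) - shift), -15.0, 25.0, limit=200
    )
    return float(np.exp(np.log(val) + shift - log_h0))


def bic_bf(y: np.ndarray, X: pd.DataFrame) -> float:
    """BIC-approximation Bayes factor vs the intercept-only model."""
    y = np.asarray(y, dtype=float)
    full = sm.OLS(y, sm.add_constant(X.astype(float), prepend=True)).fit()
    null = sm.OLS(y, np.ones((len(y), 1))).fit()
    return float(np.exp((null.bic - full.bic) / 2.0))


def bayes_factor_vs_intercept(
    y: np.ndarray, X: pd.DataFrame, method: str = "jzs"
) -> float:
    """Evidence for ``y ~ 1 + X`` against ``y ~ 1``.

    Engines disagree numerically by construction; the caller records which
    was used.
    """
    y = np.asarray(y, dtype=float)
    n, p = len(y), X.shape[1]
    if n <= p + 1:
        raise DataError("need n > p + 1 observations for a Bayes factor")
    if method == "bic":
        return bic_bf(y, X)
    if method == "jzs":
        fit = sm.OLS(y, sm.add_constant(X.astype(float), prepend=True)).fit()
        return jzs_regression_bf(float(fit.rsquared), n, p)
    raise ConfigError(f"unknown Bayes factor method {method!r}")


# ---------------------------------------------------------------------------
# rank correlation
# ---------------------------------------------------------------------------


def rank_correlation(
    x: np.ndarray,
    y: np.ndarray,
    engine: str = "analytic",
    n_boot: int = 2000,
    seed: int | None = None,
    compute_bf: bool = True,
) -> CorrelationResult:
    """Spearman rank correlation with credible interval and PP(rho > 0).

    ``analytic``: posterior of atanh(rho) approximated as Normal with SD
    ``1/sqrt(n-3)`` (flat prior on the Fisher-z scale).  ``bootstrap``:
    percentile interval and sign probability over pair resamples.  Ties are
    mid-ranked.  The Bayes factor applies the JZS linear-model default to the
    rank-transformed pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be paired 1-D arrays")
    n = x.size
    if n < 5:
        raise DataError("need at least 5 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DataError("constant vector: rank correlation undefined")

    rho = float(stats.spearmanr(x, y).statistic)

    if engine == "analytic":
        z = np.arctanh(np.clip(rho, -0.999999, 0.999999))
        se = 1.0 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - 1.959964 * se)), float(np.tanh(z + 1.959964 * se)))
        pp = float(stats.norm.cdf(z / se))
    elif engine == "bootstrap":
        rng = np.random.default_rng(seed)
        rhos = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, n, n)
            if np.all(x[idx] == x[idx][0]) or np.all(y[idx] == y[idx][0]):
                rhos[i] = 0.0
                continue
            rhos[i] = stats.spearmanr(x[idx], y[idx]).statistic
        ci = (float(np.quantile(rhos, 0.025)), float(np.quantile(rhos, 0.975)))
        pp = float(np.mean(rhos > 0))
    else:
        raise ConfigError(f"unknown engine {engine!r}")

    bf = None
    if compute_bf:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        r2 = float(np.corrcoef(rx, ry)[0, 1]) ** 2
        bf = jzs_regression_bf(min(r2, 1.0 - 1e-12), n, 1)
    return CorrelationResult(
        spearman_rho=rho,
        ci_low=ci[0],
        ci_high=ci[1],
        pp_positive=pp,
        r_squared=rho * rho,
        n=n,
        engine=engine,
        bayes_factor=bf,
    )


# ---------------------------------------------------------------------------
# paired shift (BEST-style comparison)
# ---------------------------------------------------------------------------


def paired_shift_test(
    ratings_a: np.ndarray, ratings_b: np.ndarray, compute_bf: bool = True
) -> PairedShiftResult:
    """Posterior of the mean paired difference ``a - b`` (noninformative prior).

    Under the flat reference prior the mean difference has a Student-t
    posterior ``t(n-1, loc=mean(d), scale=sd(d)/sqrt(n))``; PP(diff > 0) is
    its upper tail at zero, which equals one minus the one-sided frequentist
    p-value.
    """
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("paired samples must be 1-D arrays of equal length")
    n = a.size
    if n < 3:
        raise DataError("need at least 3 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        pp = 0.5 if mean == 0.0 else (1.0 if mean > 0 else 0.0)
        return PairedShiftResult(mean, mean, mean, pp, n, None)
    scale = sd / np.sqrt(n)
    nu = n - 1
    ci = stats.t.interval(0.95, nu, loc=mean, scale=scale)
    pp = float(stats.t.sf(0.0, nu, loc=mean, scale=scale))
    bf = jzs_ttest_bf(mean / scale, n) if compute_bf else None
    return PairedShiftResult(mean, float(ci[0]), float(ci[1]), pp, n, bf)
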