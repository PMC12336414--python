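"""Comparative models linking acoustic and observer-based measures.

* Poisson log-link GLM of observer population size (corrected AONs) on a
  standardized adult call rate — one model per call type, never both
  together (the two adult rates covary).
* Binomial logit GLM of breeding success (successes, failures per plot) on
  chick call rate, with polynomial degree chosen by AIC (a lower-AIC model
  is preferred only when it beats the simpler one by more than 2).
* The fully autonomous acoustic breeding-success metric: chick call rate
  divided by adult call rate per plot.
* A penalized-spline mixed model of chick call rate against age (8 basis
  functions), with a per-chick random intercept and AR(1) residual
  correlation across consecutive nights — a functional reconstruction of a
  Gaussian log-link GAMM, fit by penalized least squares on the log scale
  with GCV smoothing and moment-based variance components.
* Pearson correlation with its t-test (df = n - 2).

Effects are called significant when their 95% confidence interval excludes
zero.  Continuous predictors are mean-centred and scaled to unit sample
standard deviation before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.interpolate import BSpline

__all__ = [
    "ModelFit",
    "ChickAgeFit",
    "CorrelationResult",
    "standardize",
    "orthogonal_polynomials",
    "fit_glm",
    "fit_abundance_index",
    "select_polynomial",
    "fit_breeding_success",
    "fit_chick_count",
    "acoustic_breeding_success",
    "fit_chick_age_curve",
    "correlate",
]


@dataclass
class ModelFit:
    """One fitted comparative model.

    ``estimate`` and its CI refer to the linear (degree-1) term on the
    standardized predictor; ``coefficients`` holds the full parameter vector
    (intercept first, then orthogonalized polynomial terms).
    """

    response_name: str
    predictor_name: str
    family: str
    degree: int
    estimate: float
    ci_low: float
    ci_high: float
    aic: float
    pseudo_r2: float
    deviance_r2: float
    n: int
    coefficients: np.ndarray = field(default_factory=lambda: np.array([]))
    delta_aic: dict = field(default_factory=dict)
    separation: bool = False

    @property
    def significant(self) -> bool:
        """CI-excludes-zero significance rule."""
        return bool(self.ci_low > 0 or self.ci_high < 0)

    def summary(self) -> str:
        sig = "significant" if self.significant else "not significant"
        return (
            f"{self.response_name} ~ poly({self.predictor_name}, {self.degree}) "
            f"[{self.family}] n={self.n}: estimate={self.estimate:.3f} "
            f"(95% CI {self.ci_low:.3f}, {self.ci_high:.3f}; {sig}), "
            f"AIC={self.aic:.1f}, R2={self.pseudo_r2:.2f}"
        )


@dataclass
class CorrelationResult:
    r: float
    df: int
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def standardize(values) -> np.ndarray:
    """Mean-centre and scale to unit sample SD (ddof=1, as in R's scale)."""
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("cannot standardize a constant input")
    return (x - x.mean()) / x.std(ddof=1)


def orthogonal_polynomials(x, degree: int) -> np.ndarray:
    """Orthonormal polynomial columns of ``x`` up to ``degree`` (no constant).

    QR-orthogonalized against the intercept, like R's poly(); stabilises
    quadratic/cubic fits on small plot counts.
    """
    x = np.asarray(x, dtype=float)
    v = np.vander(x, degree + 1, increasing=True)  # 1, x, x^2, ...
    q, _ = np.linalg.qr(v)
    cols = q[:, 1:]
    # fix signs so the linear column correlates positively with x
    for j in range(cols.shape[1]):
        lead = cols[:, j] @ v[:, j + 1]
        if lead < 0:
            cols[:, j] = -cols[:, j]
    return cols * np.sqrt(len(x))  # unit sample variance per column


_FAMILIES = {
    "poisson_log": lambda: sm.families.Poisson(),
    "binomial_logit": lambda: sm.families.Binomial(),
    "gaussian": lambda: sm.families.Gaussian(),
    "gaussian_log": lambda: sm.families.Gaussian(sm.families.links.Log()),
}


def _response_vector(endog) -> np.ndarray:
    e = np.asarray(endog, dtype=float)
    if e.ndim == 2:  # (successes, failures) -> proportion
        tot = e.sum(axis=1)
        return np.divide(e[:, 0], tot, out=np.zeros(len(e)), where=tot > 0)
    return e


def fit_glm(
    endog,
    predictor,
    family: str,
    degree: int = 1,
    response_name: str = "response",
    predictor_name: str = "predictor",
    standardize_x: bool = True,
) -> ModelFit:
    """Fit one GLM of ``endog`` on polynomial terms of the predictor.

    The predictor is standardized, expanded into orthogonalized polynomial
    columns, and fit with the requested family; Wald 95% CIs.  For the
    linear model the reported estimate is the slope on the standardized
    predictor itself; for higher degrees it is the coefficient on the
    orthogonalized linear term.
    """
    x = np.asarray(predictor, dtype=float)
    if standardize_x:
        x = standardize(x)
    if degree == 1:
        X = x[:, None]
    else:
        X = orthogonal_polynomials(x, degree)
    X = sm.add_constant(X, has_constant="add")

    endog_arr = np.asarray(endog, dtype=float)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(endog_arr, X, family=_FAMILIES[family]()).fit()
        if family == "binomial_logit" and (
            not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > 15)
        ):
            # quasi-separation: refit with a Haldane-style 0.5 correction
            separation = True
            adj = endog_arr + 0.5
            res = sm.GLM(adj, X, family=_FAMILIES[family]()).fit()
        ci = res.conf_int()

    y = _response_vector(endog_arr)
    fitted = np.asarray(res.fittedvalues, dtype=float)
    if np.std(fitted) > 0 and np.std(y) > 0:
        pseudo_r2 = float(np.corrcoef(y, fitted)[0, 1] ** 2)
    else:
        pseudo_r2 = 0.0
    null_dev = res.null_deviance
    dev_r2 = float(1.0 - res.deviance / null_dev) if null_dev > 0 else 0.0

    return ModelFit(
        response_name=response_name,
        predictor_name=predictor_name,
        family=family,
        degree=degree,
        estimate=float(res.params[1]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        aic=float(res.aic),
        pseudo_r2=pseudo_r2,
        deviance_r2=dev_r2,
        n=len(y),
        coefficients=np.asarray(res.params),
        separation=separation,
    )


def select_polynomial(
    endog,
    predictor,
    family: str,
    degrees=(1, 2, 3),
    **kwargs,
) -> ModelFit:
    """Fit each polynomial degree and keep the best by the dAIC > 2 rule.

    Starting from the simplest degree, a more complex model is adopted only
    when its AIC undercuts the current choice by more than 2; ties and small
    improvements keep the simpler model.  dAIC values (relative to the
    chosen model) are attached to the returned fit.
    """
    degrees = sorted(degrees)
    fits = {d: fit_glm(endog, predictor, family, degree=d, **kwargs) for d in degrees}
    chosen = fits[degrees[0]]
    for d in degrees[1:]:
        if fits[d].aic < chosen.aic - 2.0:
            chosen = fits[d]
    chosen.delta_aic = {d: fits[d].aic - chosen.aic for d in degrees}
    return chosen


def fit_abundance_index(
    aons, call_rate, call_type: str = "adult_purr", select: bool = True
) -> ModelFit:
    """Poisson GLM of observer population size on one adult call rate.

    ``aons`` are per-plot AON counts (detection-corrected, rounded to whole
    nests); ``call_rate`` the plot's mean nightly call seconds for a single
    call type (standardized internally).  One call type per model: the two
    adult rates covary, so they are never entered together.
    """
    y = np.asarray(aons, dtype=float)
    if not np.allclose(y, np.round(y)):
        raise ValueError("AON response must be whole counts (round before fitting)")
    fitter = select_polynomial if select else fit_glm
    return fitter(
        y,
        call_rate,
        "poisson_log",
        response_name="aons",
        predictor_name=f"mean_{call_type}_rate",
    )


def fit_chick_count(n_chicks, chick_rate, select: bool = True) -> ModelFit:
    """Poisson GLM of per-plot chick counts on standardized chick call rate."""
    y = np.asarray(n_chicks, dtype=float)
    if not np.allclose(y, np.round(y)):
        raise ValueError("chick counts must be whole numbers")
    fitter = select_polynomial if select else fit_glm
    return fitter(
        y,
        chick_rate,
        "poisson_log",
        response_name="n_chicks",
        predictor_name="mean_chick_rate",
    )


def fit_breeding_success(
    successes, failures, predictor, predictor_name: str = "mean_chick_rate",
    select: bool = True,
) -> ModelFit:
    """Binomial logit GLM of (successes, failures) per plot on a predictor.

    Polynomial degree via the AIC rule.  Complete or quasi-separation is
    flagged and handled with a Haldane 0.5 cell correction.
    """
    endog = np.column_stack([
        np.asarray(successes, dtype=float), np.asarray(failures, dtype=float)
    ])
    if np.any(endog.sum(axis=1) < 1):
        raise ValueError("each plot needs successes + failures >= 1")
    fitter = select_polynomial if select else fit_glm
    return fitter(
        endog,
        predictor,
        "binomial_logit",
        response_name="breeding_success",
        predictor_name=predictor_name,
    )


def acoustic_breeding_success(chick_rate, adult_rate) -> np.ndarray:
    """Autonomous acoustic breeding-success metric: chick rate / adult rate.

    Plots with a zero adult rate yield NaN (with a warning), never a division
    blow-up; a zero chick rate is a genuine 0.
    """
    chick = np.asarray(chick_rate, dtype=float)
    adult = np.asarray(adult_rate, dtype=float)
    zero = adult == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} plot(s) have zero adult call rate; ratio set to NaN",
            stacklevel=2,
        )
    return np.divide(chick, adult, out=np.full_like(chick, np.nan), where=~zero)


# ---------------------------------------------------------------------------
# chick call rate vs age: penalized spline + random intercept + AR(1)
# ---------------------------------------------------------------------------

@dataclass
class ChickAgeFit:
    """Fitted chick-age smooth with variance components.

    The model works on ``z = log(call_rate + offset)``:
    ``z = s(age) + b_chick + e``, with ``b ~ N(0, sigma2_b)`` and ``e``
    AR(1) over consecutive nights within each chick.  R-squared values are
    Nakagawa-style on the link scale: marginal uses the smooth only,
    conditional adds the random intercept.
    """

    knots: int
    coef: np.ndarray
    knot_vector: np.ndarray
    lambda_: float
    offset: float
    sigma2_b: float
    sigma2_e: float
    ar1: float
    marginal_r2: float
    conditional_r2: float
    chick_intercepts: dict
    n_obs: int
    n_chicks: int

    def predict_link(self, age_days) -> np.ndarray:
        """Smooth on the log scale at the given ages (population level)."""
        a = np.clip(np.asarray(age_days, dtype=float), self._lo, self._hi)
        B = BSpline.design_matrix(a, self.knot_vector, 3).toarray()
        return B @ self.coef

    def predict(self, age_days) -> np.ndarray:
        """Fitted call rate (s/night) at the given ages."""
        return np.exp(self.predict_link(age_days)) - self.offset

    _lo: float = 0.0
    _hi: float = 50.0


def _spline_basis(x, k: int):
    """Cubic B-spline basis with ``k`` basis functions, knots at quantiles."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    n_interior = k - 4
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
    else:
        interior = np.array([])
    t = np.concatenate([[lo] * 4, interior, [hi] * 4])
    B = BSpline.design_matrix(x, t, 3).toarray()
    return B, t


def _second_diff_penalty(k: int) -> np.ndarray:
    D = np.diff(np.eye(k), 2, axis=0)
    return D.T @ D


def _gcv_lambda(B, P, z, lambdas) -> float:
    n = len(z)
    BtB = B.T @ B
    Btz = B.T @ z
    best, best_lam = np.inf, lambdas[0]
    for lam in lambdas:
        A = BtB + lam * P
        coef = np.linalg.solve(A, Btz)
        H_diag_sum = np.trace(np.linalg.solve(A, BtB))
        rss = np.sum((z - B @ coef) ** 2)
        gcv = n * rss / (n - H_diag_sum) ** 2
        if gcv < best:
            best, best_lam = gcv, lam
    return best_lam


def fit_chick_age_curve(
    call_rate,
    age_days,
    chick_id,
    night_index=None,
    n_knots: int = 8,
    offset: float = 1.0,
    n_iter: int = 10,
) -> ChickAgeFit:
    """Fit the chick-age calling curve with chick and night structure.

    ``call_rate`` is nightly begging seconds per chick; ``age_days`` the
    chick's age each night; ``chick_id`` groups observations; and
    ``night_index`` orders nights within chicks for the AR(1) term (defaults
    to input order).  The log-scale response is smoothed with a penalized
    cubic spline of ``n_knots`` basis functions (GCV smoothing parameter),
    iterating with moment estimates of the chick-intercept variance and the
    lag-1 residual autocorrelation.

    A single chick drops the random intercept with a warning.
    """
    y = np.asarray(call_rate, dtype=float)
    age = np.asarray(age_days, dtype=float)
    chick = np.asarray(chick_id)
    if np.any(y + offset <= 0):
        raise ValueError("call_rate + offset must be positive for the log scale")
    if night_index is None:
        night_index = np.arange(len(y))
    night = np.asarray(night_index, dtype=float)

    chicks = np.unique(chick)
    if len(chicks) < 2:
        warnings.warn("single chick: random intercept dropped", stacklevel=2)

    z = np.log(y + offset)
    B, t = _spline_basis(age, n_knots)
    P = _second_diff_penalty(B.shape[1])
    lambdas = np.logspace(-3, 5, 25)

    b = np.zeros(len(z))
    sigma2_b, sigma2_e, rho = 0.0, np.var(z), 0.0
    coef = np.zeros(B.shape[1])
    lam = lambdas[0]
    intercepts = {c: 0.0 for c in chicks}

    for _ in range(n_iter):
        resp = z - b
        lam = _gcv_lambda(B, P, resp, lambdas)
        coef = np.linalg.solve(B.T @ B + lam * P, B.T @ resp)
        resid = z - B @ coef

        if len(chicks) >= 2:
            means = np.array([resid[chick == c].mean() for c in chicks])
            counts = np.array([(chick == c).sum() for c in chicks])
            # moment estimate of between-chick variance
            sigma2_b = max(float(means.var(ddof=1) - sigma2_e / counts.mean()), 0.0)
            shrink = counts * sigma2_b / (counts * sigma2_b + sigma2_e)
            blups = shrink * means
            intercepts = dict(zip(chicks, blups))
            b = np.array([intercepts[c] for c in chick])
        eps = resid - b

        # lag-1 autocorrelation over consecutive nights within chicks
        num, den = 0.0, 0.0
        for c in chicks:
            m = chick == c
            order = np.argsort(night[m])
            e = eps[m][order]
            nt = night[m][order]
            if len(e) < 3:
                continue
            adj = np.diff(nt) == 1
            num += np.sum(e[:-1][adj] * e[1:][adj])
            den += np.sum(e[:-1][adj] ** 2)
        rho = float(np.clip(num / den, -0.99, 0.99)) if den > 0 else 0.0
        sigma2_e = float(np.var(eps))

    var_f = float(np.var(B @ coef))
    denom = var_f + sigma2_b + sigma2_e
    marginal = var_f / denom if denom > 0 else 0.0
    conditional = (var_f + sigma2_b) / denom if denom > 0 else 0.0

    fit = ChickAgeFit(
        knots=n_knots,
        coef=coef,
        knot_vector=t,
        lambda_=float(lam),
        offset=offset,
        sigma2_b=float(sigma2_b),
        sigma2_e=float(sigma2_e),
        ar1=rho,
        marginal_r2=float(marginal),
        conditional_r2=float(conditional),
        chick_intercepts={str(k): float(v) for k, v in intercepts.items()},
        n_obs=len(z),
        n_chicks=len(chicks),
    )
    fit._lo, fit._hi = float(age.min()), float(age.max())
    return fit


def correlate(x, y) -> CorrelationResult:
    """Pearson correlation with df = n - 2 and a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), df=len(x) - 2, p=float(p))
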