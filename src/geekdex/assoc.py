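"""Family-clustered association models.

Twins are nested in families, so every regression here carries a random
family intercept and is fitted by maximum likelihood: linear mixed models
through statsmodels MixedLM, and a random-intercept logistic model fitted
by adaptive Gauss-Hermite quadrature (statsmodels offers no ML GLMM).
Inference on fixed effects is Wald-z on the ML fit.

Also provides the surrounding analysis steps: the linear-vs-quadratic
paternal-age likelihood-ratio test, GI-vs-subscale effect comparison,
sensitivity filters (paternal age cap, autism exclusion), the GCSE-
equivalent attainment points helper and the +/-1 s.d. "geek cluster"
group comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import scipy.optimize
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.special import logsumexp
from scipy.stats import chi2, norm

from .errors import ConvergenceError, DomainError

#: covariates of every "adjusted" model (the crude model has none)
ADJUSTED_COVARIATES = ("maternal_age", "ses", "sex", "zygosity")

#: default GCSE grade-point map (top grade A* = 8 ... G = 1) and
#: qualification weights in GCSE equivalents (an A level counts double)
DEFAULT_GRADE_POINTS = {"A*": 8, "A": 7, "B": 6, "C": 5, "D": 4, "E": 3, "F": 2, "G": 1}
QUALIFICATION_WEIGHTS = {"GCSE": 1.0, "A-level": 2.0}


@dataclass
class MixedFit:
    """Result of a family-clustered model fit.

    ``coefficients`` is indexed by term with columns ``beta``, ``se``,
    ``p`` (plus ``or_``, ``or_low``, ``or_high`` for logistic fits).
    """

    coefficients: pd.DataFrame
    n_children: int
    n_families: int
    loglik: float
    random_intercept_var: float
    model: str = ""
    #: covariance matrix of the fixed effects (same order as coefficients)
    fe_cov: np.ndarray | None = None

    def beta(self, term: str) -> float:
        return float(self.coefficients.loc[term, "beta"])

    def se(self, term: str) -> float:
        return float(self.coefficients.loc[term, "se"])

    def p(self, term: str) -> float:
        return float(self.coefficients.loc[term, "p"])


def _formula(outcome: str, fixed_terms) -> str:
    rhs = " + ".join(fixed_terms) if fixed_terms else "1"
    return f"{outcome} ~ {rhs}"


def _check_design(formula: str, cohort: pd.DataFrame) -> None:
    """Reject rank-deficient designs, naming the collinear columns."""
    _, X = patsy.dmatrices(formula, cohort, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X.to_numpy())
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise ValueError(f"rank-deficient design: collinear term(s) {bad}")


def fit_lmm(outcome: str, fixed_terms, cohort: pd.DataFrame, group_col: str = "family_id") -> MixedFit:
    """ML linear mixed model with a single random family intercept.

    Falls back to the boundary solution (OLS fixed effects, zero
    intercept variance) if the variance estimate collapses to the
    boundary and the mixed-model machinery cannot invert its Hessian —
    the two coincide exactly in that case.
    """
    if cohort[group_col].nunique() < 2:
        raise DomainError("need >= 2 families to fit a clustered model")
    missing = [t for t in fixed_terms if t.isidentifier() and t not in cohort.columns]
    if missing:
        raise DomainError(f"fixed term(s) not in cohort: {missing}")
    formula = _formula(outcome, fixed_terms)
    _check_design(formula, cohort)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = smf.mixedlm(formula, cohort, groups=cohort[group_col]).fit(reml=False, disp=False)
            fe = res.fe_params
            se = res.bse_fe
            coefs = pd.DataFrame({"beta": fe, "se": se})
            coefs["p"] = 2.0 * norm.sf(np.abs(coefs["beta"] / coefs["se"]))
            re_var = float(res.cov_re.iloc[0, 0])
            llf = float(res.llf)
            k = len(fe)
            fe_cov = np.asarray(res.cov_params())[:k, :k]
        except (np.linalg.LinAlgError, ValueError):
            ols = smf.ols(formula, cohort).fit()
            coefs = pd.DataFrame({"beta": ols.params, "se": ols.bse})
            coefs["p"] = 2.0 * norm.sf(np.abs(coefs["beta"] / coefs["se"]))
            re_var = 0.0
            llf = float(ols.llf)
            fe_cov = np.asarray(ols.cov_params())
    return MixedFit(
        coefficients=coefs,
        n_children=len(cohort),
        n_families=int(cohort[group_col].nunique()),
        loglik=llf,
        random_intercept_var=re_var,
        model=formula,
        fe_cov=fe_cov,
    )


def _glmm_logistic_loglik(params, X, y, cluster_idx, n_clusters, nodes, log_w):
    """Marginal log-likelihood of a random-intercept logit via Gauss-Hermite."""
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    eta = X @ beta  # (n,)
    lp = eta[:, None] + sigma * nodes[None, :]  # (n, K)
    # log-lik of each child at each node
    ll_obs = np.where(y[:, None] == 1, -np.logaddexp(0.0, -lp), -np.logaddexp(0.0, lp))
    ll_cluster = np.zeros((n_clusters, nodes.size))
    np.add.at(ll_cluster, cluster_idx, ll_obs)
    return float(np.sum(logsumexp(ll_cluster + log_w[None, :], axis=1)))


def fit_logistic_mixed(
    outcome: str,
    fixed_terms,
    cohort: pd.DataFrame,
    group_col: str = "family_id",
    n_quad: int = 25,
) -> MixedFit:
    """ML random-intercept logistic model (adaptive to none: plain GH quadrature).

    Reports odds ratios with Wald 95% CIs alongside the log-odds scale.
    Raises :class:`ConvergenceError` on separation (diverging estimates).
    """
    if cohort[group_col].nunique() < 2:
        raise DomainError("need >= 2 families to fit a clustered model")
    formula = _formula(outcome, fixed_terms)
    _check_design(formula, cohort)
    y_df, X_df = patsy.dmatrices(formula, cohort, return_type="dataframe")
    y = np.asarray(y_df).ravel().astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise DomainError("outcome must be binary (0/1 or bool)")
    X = np.asarray(X_df)
    codes, _ = pd.factorize(cohort[group_col].to_numpy())
    n_clusters = codes.max() + 1

    # probabilists' Gauss-Hermite rule for a standard-normal intercept
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    log_w = np.log(weights) - 0.5 * np.log(2.0 * np.pi)

    start = np.zeros(X.shape[1] + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            start[: X.shape[1]] = sm.Logit(y, X).fit(disp=False, maxiter=100).params
        except Exception:
            pass  # separation or singularity: start from zero, detect post-fit
    if np.any(np.abs(start) > 15.0) or not np.all(np.isfinite(start)):
        raise ConvergenceError(
            "logistic mixed model did not converge: diverging coefficients suggest separation "
            "(outcome constant within a stratum of the design)"
        )
    nll = lambda p: -_glmm_logistic_loglik(p, X, y, codes, n_clusters, nodes, log_w)
    opt = scipy.optimize.minimize(nll, start, method="BFGS", options={"maxiter": 500})
    beta = opt.x[:-1]
    if np.any(np.abs(beta) > 15.0) or not np.all(np.isfinite(beta)):
        raise ConvergenceError(
            "logistic mixed model did not converge: diverging coefficients suggest separation "
            "(outcome constant within a stratum of the design)"
        )
    # observed information via numerical Hessian of the negative loglik
    hess = _num_hessian(nll, opt.x)
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    se = se_all[:-1]
    coefs = pd.DataFrame({"beta": beta, "se": se}, index=X_df.columns)
    coefs["p"] = 2.0 * norm.sf(np.abs(coefs["beta"] / coefs["se"].replace(0.0, np.nan)))
    coefs["or_"] = np.exp(coefs["beta"])
    coefs["or_low"] = np.exp(coefs["beta"] - 1.96 * coefs["se"])
    coefs["or_high"] = np.exp(coefs["beta"] + 1.96 * coefs["se"])
    sigma = float(np.exp(opt.x[-1]))
    return MixedFit(
        coefficients=coefs,
        n_children=len(cohort),
        n_families=int(n_clusters),
        loglik=float(-opt.fun),
        random_intercept_var=sigma**2,
        model=formula + " [logit]",
    )


def _num_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; step scaled per coordinate."""
    k = len(x)
    h = eps * (1.0 + np.abs(x))
    hess = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                val = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
            else:
                val = (f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)) / (4.0 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    return hess


def lrt_quadratic(
    cohort: pd.DataFrame,
    outcome: str = "gi_default",
    age_col: str = "paternal_age",
    covariates=(),
) -> tuple[float, int, float]:
    """Likelihood-ratio test of a quadratic paternal-age term.

    Fits outcome ~ age (+ covariates) with and without a centered
    quadratic term; returns (delta_loglik, df=1, p) with the statistic
    2*delta_loglik referred to chi-square(1).
    """
    df = cohort.copy()
    mu = df[age_col].mean()
    df["_age_c"] = df[age_col] - mu
    df["_age_c2"] = df["_age_c"] ** 2
    fit_lin = fit_lmm(outcome, ["_age_c", *covariates], df)
    fit_quad = fit_lmm(outcome, ["_age_c", "_age_c2", *covariates], df)
    delta = max(fit_quad.loglik - fit_lin.loglik, 0.0)
    p = float(chi2.sf(2.0 * delta, df=1))
    return delta, 1, p


def subscale_vs_gi_comparison(
    cohort: pd.DataFrame,
    age_col: str = "paternal_age",
    covariates=ADJUSTED_COVARIATES,
) -> pd.DataFrame:
    """Adjusted paternal-age effect on z-scored GI and on each z-scored
    subscale, with an identical covariate set, one row per outcome."""
    df = cohort.copy()
    rows = []
    for label, col in [
        ("gi", "gi_default"),
        ("nonverbal_iq", "nonverbal_iq"),
        ("cast_social", "cast_social"),
        ("cast_rrb", "cast_rrb"),
    ]:
        zcol = f"_z_{label}"
        v = df[col].astype(float)
        df[zcol] = (v - v.mean()) / v.std(ddof=0)
        fit = fit_lmm(zcol, [age_col, *covariates], df)
        rows.append(
            {
                "outcome": label,
                "beta": fit.beta(age_col),
                "se": fit.se(age_col),
                "p": fit.p(age_col),
                "z": fit.beta(age_col) / fit.se(age_col),
            }
        )
    return pd.DataFrame(rows).set_index("outcome")


def sensitivity_filters(
    cohort: pd.DataFrame,
    max_paternal_age: float | None = None,
    exclude_autism: bool = False,
) -> pd.DataFrame:
    """Sensitivity subsets: cap on paternal age at conception (whole
    families dropped, both twins together) and/or exclusion of children
    with an autism diagnosis (individuals dropped).  Retained rows are
    returned unmodified."""
    out = cohort
    if max_paternal_age is not None:
        out = out[out["paternal_age"] <= max_paternal_age]
    if exclude_autism:
        out = out[~out["autism_flag"].astype(bool)]
    return out.copy()


def attainment_points(
    exam_records,
    grade_points: dict = DEFAULT_GRADE_POINTS,
    qualification_weights: dict = QUALIFICATION_WEIGHTS,
) -> float:
    """GCSE-equivalent attainment score: sum over exams of grade points
    times qualification weight (GCSE weight 1, A level double)."""
    total = 0.0
    for grade, qualification in exam_records:
        if grade not in grade_points:
            raise DomainError(f"unknown grade symbol {grade!r}; known: {sorted(grade_points)}")
        if qualification not in qualification_weights:
            raise DomainError(f"unknown qualification {qualification!r}; known: {sorted(qualification_weights)}")
        total += grade_points[grade] * qualification_weights[qualification]
    return total


_CLUSTER_GROUPS = ("geek", "high_iq_only", "high_rrb_aloof_only", "sample_mean")


def geek_cluster_groups(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean STEM and Art GCSE counts in the +/-1 s.d. trait clusters.

    Groups: ``geek`` (IQ, aloofness and RRB all > +1 s.d.),
    ``high_iq_only`` (IQ > +1 s.d., aloofness and RRB < -1 s.d.),
    ``high_rrb_aloof_only`` (IQ < -1 s.d., aloofness and RRB > +1 s.d.)
    and the ``sample_mean``.  Higher CAST social score is read as more
    aloof.  Empty groups are reported with n=0 and NaN means.
    """
    z = {}
    for col in ("nonverbal_iq", "cast_social", "cast_rrb"):
        v = cohort[col].astype(float)
        z[col] = (v - v.mean()) / v.std(ddof=0)
    masks = {
        "geek": (z["nonverbal_iq"] > 1) & (z["cast_social"] > 1) & (z["cast_rrb"] > 1),
        "high_iq_only": (z["nonverbal_iq"] > 1) & (z["cast_social"] < -1) & (z["cast_rrb"] < -1),
        "high_rrb_aloof_only": (z["nonverbal_iq"] < -1) & (z["cast_social"] > 1) & (z["cast_rrb"] > 1),
        "sample_mean": pd.Series(True, index=cohort.index),
    }
    rows = []
    for name in _CLUSTER_GROUPS:
        sub = cohort[masks[name]]
        rows.append(
            {
                "group": name,
                "mean_stem_gcses": float(sub["stem_gcses"].mean()) if len(sub) else float("nan"),
                "mean_art_gcses": float(sub["art_gcses"].mean()) if len(sub) else float("nan"),
                "n": int(len(sub)),
            }
        )
    return pd.DataFrame(rows).set_index("group")
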