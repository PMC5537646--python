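"""Full-information maximum-likelihood (FIML) twin models.

Works on a "pairs table": one row per twin pair with columns
``zygosity`` ('MZ'/'DZ'), ``trait1``, ``trait2`` and, for the moderation
model, a family-level ``moderator``.  A missing co-twin (NaN in
``trait2``) contributes its marginal normal likelihood, which is what
makes the estimation full-information.

Models
------
saturated (per zygosity)
    bivariate normal with equal means and variances across twin order;
    the free correlation is the classical twin correlation.
AE / ADE
    structured pair covariance: var = a^2 + d^2 + e^2 for every twin,
    cov = a^2 + d^2 (MZ) and 0.5 a^2 + 0.25 d^2 (DZ).  MZ twins share
    all genetic material; DZ twins share on average half of additive
    effects and a quarter of dominance deviations; E is non-shared by
    definition.
GxE moderation
    family-specific paths a_i = a + beta_a * M_i and e_i = e + beta_e * M_i
    with M the standardized family moderator (here paternal age);
    pair covariance uses a_i^2, e_i^2 with the MZ/DZ sharing
    coefficients.  The trait is expected to be pre-residualized on the
    moderator (see :func:`regress_out_moderator`) so that a mean trend
    does not masquerade as variance moderation.

All models use a single grand mean, quasi-Newton optimization on the raw
path parameters with random restarts, and Wald 95% CIs from the observed
information (numerical Hessian).  Path signs are not identified (only
squares enter the covariance); fits report non-negative paths, flipping
moderation slopes along with their path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
from .errors import ConvergenceError, DomainError

_LOG2PI = np.log(2.0 * np.pi)
_N_RESTARTS = 5


@dataclass
class TwinCorrelations:
    r_mz: float
    r_mz_ci: tuple
    r_dz: float
    r_dz_ci: tuple
    n_mz_pairs: int
    n_dz_pairs: int
    loglik: float


@dataclass
class TwinModelFit:
    model: str  # AE | ADE | GxE
    mean: float
    a: float
    d: float
    e: float
    beta_a: float
    beta_e: float
    std_components: dict  # a2, d2, e2 shares (AE/ADE; empty for GxE)
    loglik: float
    cis: dict  # per-parameter (low, high)
    n_pairs: int


# ---------------------------------------------------------------------------
# likelihood primitives (shared with the test-suite oracles)


def bivariate_pair_loglik(x1, x2, mu, var, cov) -> np.ndarray:
    """Elementwise log-likelihood of twin pairs under a bivariate normal
    with common mean/variance and the given within-pair covariance.
    ``var``/``cov`` may be scalars or per-pair arrays.  NaN in ``x2``
    yields the marginal N(mu, var) log-density of twin 1 (FIML)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    var = np.broadcast_to(np.asarray(var, dtype=float), x1.shape)
    cov = np.broadcast_to(np.asarray(cov, dtype=float), x1.shape)
    det = var**2 - cov**2
    if np.any(var <= 0) or np.any(det <= 0):
        return np.full(x1.shape, -np.inf)
    d1 = x1 - mu
    d2 = x2 - mu
    quad = (var * (d1**2 + d2**2) - 2.0 * cov * d1 * d2) / det
    ll_pair = -_LOG2PI - 0.5 * np.log(det) - 0.5 * quad
    ll_single = -0.5 * (_LOG2PI + np.log(var) + d1**2 / var)
    return np.where(np.isnan(x2), ll_single, ll_pair)


def _split(pairs: pd.DataFrame):
    mz = pairs[pairs["zygosity"] == "MZ"]
    dz = pairs[pairs["zygosity"] == "DZ"]
    return mz, dz


def _sym_arrays(df: pd.DataFrame):
    """Trait arrays with NaN allowed in either slot, normalized so that a
    missing twin always sits in slot 2 (likelihood is order-symmetric)."""
    t1 = df["trait1"].to_numpy(dtype=float)
    t2 = df["trait2"].to_numpy(dtype=float)
    swap = np.isnan(t1) & ~np.isnan(t2)
    t1s = np.where(swap, t2, t1)
    t2s = np.where(swap, t1, t2)
    keep = ~np.isnan(t1s)
    return t1s[keep], t2s[keep], df.index[keep] if hasattr(df, "index") else None


def _prepare(pairs: pd.DataFrame, moderator_col=None):
    """Extract per-zygosity trait arrays once (missing co-twin in slot 2)."""
    out = []
    mz, dz = _split(pairs)
    for sub in (mz, dz):
        x1 = sub["trait1"].to_numpy(dtype=float)
        x2 = sub["trait2"].to_numpy(dtype=float)
        m = sub[moderator_col].to_numpy(dtype=float) if moderator_col else None
        keep = ~(np.isnan(x1) & np.isnan(x2))
        swap = np.isnan(x1) & ~np.isnan(x2)
        x1s = np.where(swap, x2, x1)[keep]
        x2s = np.where(swap, x1, x2)[keep]
        out.append((x1s, x2s, m[keep] if m is not None else None))
    return out


def ade_loglik(pairs: pd.DataFrame, mu: float, a: float, d: float, e: float) -> float:
    """Total FIML log-likelihood of the ADE model (AE when d = 0)."""
    return _ade_loglik_arrays(_prepare(pairs), mu, a, d, e)


def _ade_loglik_arrays(prepared, mu, a, d, e) -> float:
    var = a**2 + d**2 + e**2
    total = 0.0
    for (x1, x2, _), (sa, sd) in zip(prepared, ((1.0, 1.0), (0.5, 0.25))):
        if x1.size == 0:
            continue
        cov = sa * a**2 + sd * d**2
        total += float(np.sum(bivariate_pair_loglik(x1, x2, mu, var, cov)))
    return total


def gxe_loglik(pairs: pd.DataFrame, mu: float, a: float, e: float, beta_a: float, beta_e: float, moderator_col: str = "moderator") -> float:
    """Total FIML log-likelihood of the path-moderation (GxE) model."""
    return _gxe_loglik_arrays(_prepare(pairs, moderator_col), mu, a, e, beta_a, beta_e)


def _gxe_loglik_arrays(prepared, mu, a, e, beta_a, beta_e) -> float:
    total = 0.0
    for (x1, x2, m), sa in zip(prepared, (1.0, 0.5)):
        if x1.size == 0:
            continue
        a_i = a + beta_a * m
        e_i = e + beta_e * m
        var = a_i**2 + e_i**2
        cov = sa * a_i**2
        total += float(np.sum(bivariate_pair_loglik(x1, x2, mu, var, cov)))
    return total


def saturated_loglik(sub: pd.DataFrame, mu: float, sd: float, r: float) -> float:
    """FIML log-likelihood of one zygosity group's saturated model."""
    x1, x2, _ = _sym_arrays(sub)
    return float(np.sum(bivariate_pair_loglik(x1, x2, mu, sd**2, r * sd**2)))


# ---------------------------------------------------------------------------
# numerical machinery


def _num_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    k = len(x)
    h = eps * (1.0 + np.abs(x))
    hess = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        hess[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            val = (f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)) / (4.0 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    return hess


def _wald_cis(nll, x, names) -> dict:
    """95% Wald intervals from the observed information; NaN on failure
    (e.g. boundary optima with singular information)."""
    try:
        hess = _num_hessian(nll, x)
        cov = np.linalg.pinv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except (np.linalg.LinAlgError, ValueError):
        se = np.full(len(x), np.nan)
    return {n: (float(x[i] - 1.96 * se[i]), float(x[i] + 1.96 * se[i])) for i, n in enumerate(names)}


def _optimize(nll, starts, bounds=None):
    best = None
    for s in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = scipy.optimize.minimize(nll, s, method="Nelder-Mead", options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("twin model failed to converge from all restarts")
    return best


def _restart_starts(base: np.ndarray, seed: int, n: int = _N_RESTARTS, scale: float = 0.3):
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7E1]))
    starts = [base]
    for _ in range(n - 1):
        starts.append(base * (1.0 + scale * rng.standard_normal(base.size)) + 0.05 * rng.standard_normal(base.size))
    return starts


# ---------------------------------------------------------------------------
# public fits


def twin_correlations(pairs: pd.DataFrame) -> TwinCorrelations:
    """Saturated FIML twin correlations per zygosity with 95% CIs.

    The correlation is estimated on Fisher's z scale (with the mean and
    log-sd profiled jointly); the CI is a Wald interval on z transformed
    back, so it respects the [-1, 1] bounds.
    """
    mz, dz = _split(pairs)
    results = {}
    total_ll = 0.0
    for name, sub in (("mz", mz), ("dz", dz)):
        n_pairs = int(len(sub))
        if n_pairs < 2:
            raise DomainError(f"zygosity group {name.upper()} has {n_pairs} pairs; need >= 2")
        x1, x2, _ = _sym_arrays(sub)
        both = ~np.isnan(x2)
        stacked = np.concatenate([x1, x2[both]])
        mu0, sd0 = float(np.mean(stacked)), float(np.std(stacked) + 1e-9)
        if both.sum() >= 2:
            r0 = float(np.corrcoef(x1[both], x2[both])[0, 1])
            r0 = np.clip(r0, -0.99, 0.99)
        else:
            r0 = 0.0

        def nll(p, x1=x1, x2=x2):
            mu, log_sd, z = p
            var = np.exp(log_sd) ** 2
            return -float(np.sum(bivariate_pair_loglik(x1, x2, mu, var, np.tanh(z) * var)))

        base = np.array([mu0, np.log(sd0), np.arctanh(r0)])
        best = _optimize(nll, _restart_starts(base, seed=n_pairs))
        mu_hat, log_sd_hat, z_hat = best.x
        cis = _wald_cis(nll, best.x, ["mu", "log_sd", "z"])
        r_hat = float(np.tanh(z_hat))
        r_ci = tuple(float(np.tanh(v)) for v in cis["z"])
        results[name] = (r_hat, r_ci, n_pairs)
        total_ll += -best.fun
    return TwinCorrelations(
        r_mz=results["mz"][0],
        r_mz_ci=results["mz"][1],
        r_dz=results["dz"][0],
        r_dz_ci=results["dz"][1],
        n_mz_pairs=results["mz"][2],
        n_dz_pairs=results["dz"][2],
        loglik=total_ll,
    )


def _path_fit(pairs: pd.DataFrame, with_d: bool, seed: int = 0, extra_starts=()) -> TwinModelFit:
    mz, dz = _split(pairs)
    if len(mz) == 0 or len(dz) == 0:
        raise DomainError("both zygosity groups must be present to separate A from E")
    x1, x2, _ = _sym_arrays(pairs)
    both = ~np.isnan(x2)
    stacked = np.concatenate([x1, x2[both]])
    mu0, v0 = float(np.mean(stacked)), float(np.var(stacked) + 1e-9)

    # moment start from the twin correlations
    def _corr(sub):
        a1, a2, _ = _sym_arrays(sub)
        ok = ~np.isnan(a2)
        return float(np.corrcoef(a1[ok], a2[ok])[0, 1]) if ok.sum() >= 2 else 0.0

    r_mz, r_dz = _corr(mz), _corr(dz)
    a2_0 = float(np.clip((r_mz if not with_d else 4 * r_dz - r_mz) * v0, 0.05 * v0, 0.95 * v0))
    d2_0 = float(np.clip((2 * (r_mz - 2 * r_dz)) * v0, 0.0, 0.9 * v0)) if with_d else 0.0
    e2_0 = max(v0 - a2_0 - d2_0, 0.05 * v0)

    prepared = _prepare(pairs)
    if with_d:
        names = ["mu", "a", "d", "e"]
        base = np.array([mu0, np.sqrt(a2_0), np.sqrt(d2_0) + 1e-3, np.sqrt(e2_0)])
        nll = lambda p: -_ade_loglik_arrays(prepared, p[0], p[1], p[2], p[3])
    else:
        names = ["mu", "a", "e"]
        base = np.array([mu0, np.sqrt(a2_0), np.sqrt(e2_0)])
        nll = lambda p: -_ade_loglik_arrays(prepared, p[0], p[1], 0.0, p[2])

    starts = _restart_starts(base, seed=seed) + [np.asarray(s, dtype=float) for s in extra_starts]
    best = _optimize(nll, starts)
    x = np.abs(best.x)  # path signs unidentified; report magnitudes
    x[0] = best.x[0]
    cis = _wald_cis(nll, best.x, names)
    mu_hat = float(x[0])
    a_hat = float(x[1])
    d_hat = float(x[2]) if with_d else 0.0
    e_hat = float(x[3] if with_d else x[2])
    tot = a_hat**2 + d_hat**2 + e_hat**2
    shares = {"a2": a_hat**2 / tot, "d2": d_hat**2 / tot, "e2": e_hat**2 / tot}
    return TwinModelFit(
        model="ADE" if with_d else "AE",
        mean=mu_hat,
        a=a_hat,
        d=d_hat,
        e=e_hat,
        beta_a=0.0,
        beta_e=0.0,
        std_components=shares,
        loglik=float(-best.fun),
        cis=cis,
        n_pairs=int(len(pairs)),
    )


def fit_ae(pairs: pd.DataFrame, seed: int = 0) -> TwinModelFit:
    """AE decomposition: the A estimate absorbs any dominance, so its
    standardized share is a broad-sense heritability."""
    return _path_fit(pairs, with_d=False, seed=seed)


def fit_ade(pairs: pd.DataFrame, seed: int = 0) -> TwinModelFit:
    """ADE decomposition; the AE optimum is always included among the
    starting points, so the ADE log-likelihood can never fall below AE."""
    ae = fit_ae(pairs, seed=seed)
    return _path_fit(pairs, with_d=True, seed=seed, extra_starts=[[ae.mean, ae.a, 0.0, ae.e]])


def regress_out_moderator(pairs: pd.DataFrame, moderator_col: str = "moderator") -> pd.DataFrame:
    """Residualize both twins' traits on the family moderator by least
    squares (children stacked), removing any mean trend so the GxE model
    sees pure variance moderation.  Returns a copy."""
    if moderator_col not in pairs.columns:
        raise DomainError(f"moderator column {moderator_col!r} missing")
    m = pairs[moderator_col].to_numpy(dtype=float)
    t1 = pairs["trait1"].to_numpy(dtype=float)
    t2 = pairs["trait2"].to_numpy(dtype=float)
    mm = np.concatenate([m, m])
    tt = np.concatenate([t1, t2])
    ok = ~np.isnan(tt)
    X = np.column_stack([np.ones(ok.sum()), mm[ok]])
    coef, *_ = np.linalg.lstsq(X, tt[ok], rcond=None)
    out = pairs.copy()
    out["trait1"] = t1 - (coef[0] + coef[1] * m)
    out["trait2"] = t2 - (coef[0] + coef[1] * m)
    return out


def fit_gxe(pairs: pd.DataFrame, moderator_col: str = "moderator", seed: int = 0, standardize_moderator: bool = True) -> TwinModelFit:
    """AE model with linear path moderation by the family moderator.

    Reports baseline paths a, e and moderation slopes beta_a, beta_e per
    standardized moderator unit.  The moderator is standardized
    internally unless told otherwise; a constant moderator is rejected.
    """
    if moderator_col not in pairs.columns:
        raise DomainError(f"moderator column {moderator_col!r} missing")
    pairs = pairs.copy()
    m = pairs[moderator_col].to_numpy(dtype=float)
    if np.std(m) == 0:
        raise DomainError("degenerate moderator: zero variance")
    if standardize_moderator:
        pairs[moderator_col] = (m - np.mean(m)) / np.std(m)

    ae = fit_ae(pairs, seed=seed)
    names = ["mu", "a", "e", "beta_a", "beta_e"]
    base = np.array([ae.mean, ae.a, ae.e, 0.0, 0.0])
    prepared = _prepare(pairs, moderator_col)
    nll = lambda p: -_gxe_loglik_arrays(prepared, p[0], p[1], p[2], p[3], p[4])
    best = _optimize(nll, _restart_starts(base, seed=seed))
    mu_hat, a_hat, e_hat, ba_hat, be_hat = best.x
    # sign convention: non-negative baseline paths, slopes flipped with them
    if a_hat < 0:
        a_hat, ba_hat = -a_hat, -ba_hat
    if e_hat < 0:
        e_hat, be_hat = -e_hat, -be_hat
    cis = _wald_cis(nll, best.x, names)
    return TwinModelFit(
        model="GxE",
        mean=float(mu_hat),
        a=float(a_hat),
        d=0.0,
        e=float(e_hat),
        beta_a=float(ba_hat),
        beta_e=float(be_hat),
        std_components={},
        loglik=float(-best.fun),
        cis=cis,
        n_pairs=int(len(pairs)),
    )


def moderated_variance_table(fit: TwinModelFit, m_grid=None) -> pd.DataFrame:
    """Genetic, environmental and total variance as functions of the
    moderator: Va(M) = (a + beta_a M)^2, Ve(M) = (e + beta_e M)^2."""
    if m_grid is None:
        m_grid = np.linspace(-2.5, 2.5, 11)
    m = np.asarray(m_grid, dtype=float)
    va = (fit.a + fit.beta_a * m) ** 2
    ve = (fit.e + fit.beta_e * m) ** 2
    return pd.DataFrame({"moderator": m, "Va": va, "Ve": ve, "Vt": va + ve})


def pairs_from_cohort(cohort: pd.DataFrame, trait: str, moderator: str | None = None) -> pd.DataFrame:
    """Pivot a per-child cohort frame into the pairs-table layout."""
    wide = cohort.pivot_table(index="family_id", columns="twin_order", values=trait, aggfunc="first")
    out = pd.DataFrame(
        {
            "trait1": wide.get(1),
            "trait2": wide.get(2),
        }
    )
    fam = cohort.drop_duplicates("family_id").set_index("family_id")
    out["zygosity"] = fam["zygosity"]
    if moderator is not None:
        out["moderator"] = fam[moderator]
    return out.reset_index()
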