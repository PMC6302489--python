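"""Per-feature mixed models for paired/unpaired expression data.

Two model families are supported, both with a fixed treatment effect
and a random subject intercept capturing subject-level confounding
(diet, lifestyle, genetics — anything that shifts both of a subject's
samples):

* **Continuous** (log-intensity, e.g. microarray): the linear mixed
  model ``Y_ij = mu + delta * 1[i = treatment] + Subj_j + eps_ij`` with
  ``Subj_j ~ N(0, sigma2_subj)`` and ``eps_ij ~ N(0, sigma2_err)``.
  The marginal likelihood is Gaussian with 2x2 compound-symmetry
  blocks for paired subjects and is evaluated exactly.

* **Count** (e.g. RNA-Seq): the log-linear negative-binomial mixed
  model ``log E[Y_ij] = offset_ij + mu + delta * 1[i = treatment] +
  Subj_j`` with NB dispersion ``theta`` (variance ``m + m^2 / theta``).
  The subject random effect is integrated out per subject by adaptive
  Gauss-Hermite quadrature.

Both families are fitted by maximum likelihood (not REML), so the same
objective serves fitting, model comparison and the quadrature oracles.
``delta`` is the natural-log fold change of the treatment condition
relative to the reference condition.

Dispersion bookkeeping for the count family follows the two common
conventions: ``theta`` (glmer.nb-style; variance ``m + m^2/theta``)
and ``scale`` = sqrt(k) (GLIMMIX-style) with ``k = 1/theta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, special, stats

from .design import SampleTable
from .errors import NumericalError, ValidationError

_LOG2PI = math.log(2.0 * math.pi)
#: lower bound for log-scale variance/dispersion parameters (a hard
#: floor standing in for zero).
_LOG_FLOOR = -20.0


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LMMParams:
    """Generative parameters of the continuous (linear mixed) model."""

    mu: float
    delta: float
    sigma2_subj: float
    sigma2_err: float

    def __post_init__(self) -> None:
        if self.sigma2_subj < 0:
            raise ValidationError(f"sigma2_subj must be >= 0, got {self.sigma2_subj}")
        if self.sigma2_err <= 0:
            raise ValidationError(f"sigma2_err must be > 0, got {self.sigma2_err}")


@dataclass(frozen=True)
class NBParams:
    """Generative parameters of the count (NB mixed) model.

    ``scale`` is the GLIMMIX-style sqrt(k); the equivalent glmer.nb
    dispersion is ``theta = 1 / k`` so that ``theta * k = 1``.
    """

    mu: float
    delta: float
    sigma2_subj: float
    scale: float

    def __post_init__(self) -> None:
        if self.sigma2_subj < 0:
            raise ValidationError(f"sigma2_subj must be >= 0, got {self.sigma2_subj}")
        if self.scale <= 0:
            raise ValidationError(f"scale must be > 0, got {self.scale}")

    @property
    def k(self) -> float:
        return self.scale**2

    @property
    def theta(self) -> float:
        return 1.0 / self.k


@dataclass
class FitResult:
    """Per-feature fit summary for the treatment-effect test."""

    estimates: dict[str, float]
    se_delta: float
    statistic: float
    df: float
    p_value: float
    converged: bool
    log_likelihood: float
    message: str = ""

    @property
    def delta(self) -> float:
        return self.estimates.get("delta", math.nan)

    @property
    def fold_change(self) -> float:
        return math.exp(self.delta)


# ---------------------------------------------------------------------------
# continuous family
# ---------------------------------------------------------------------------


def _lmm_structure(table: SampleTable):
    pairs = table.pair_indices()
    singles = table.single_indices()
    t = table.treatment_indicator()
    return t, pairs, singles


def _lmm_loglik_arrays(y, t, pairs, singles, mu, delta, s2s, s2e) -> float:
    r = y - (mu + delta * t)
    ll = 0.0
    a = s2s + s2e
    if singles.size:
        rs = r[singles]
        ll += -0.5 * (singles.size * (_LOG2PI + math.log(a)) + np.dot(rs, rs) / a)
    if len(pairs):
        b = s2s
        det = a * a - b * b
        r1 = r[pairs[:, 0]]
        r2 = r[pairs[:, 1]]
        quad = (a * (r1 * r1 + r2 * r2) - 2.0 * b * r1 * r2) / det
        ll += -0.5 * (len(pairs) * (2.0 * _LOG2PI + math.log(det)) + quad.sum())
    return float(ll)


def lmm_loglik(y, table: SampleTable, params: LMMParams) -> float:
    """Exact marginal Gaussian log-likelihood of the random-intercept LMM.

    The likelihood factorizes over subjects: an unpaired subject's
    sample has variance ``sigma2_subj + sigma2_err``; a paired
    subject's two samples share the 2x2 covariance
    ``[[s+e, s], [s, s+e]]`` with ``s = sigma2_subj, e = sigma2_err``.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (table.n_samples,):
        raise ValidationError(
            f"y has shape {y.shape}, expected ({table.n_samples},) matching the table"
        )
    if not np.all(np.isfinite(y)):
        raise ValidationError("y contains non-finite values")
    t, pairs, singles = _lmm_structure(table)
    return _lmm_loglik_arrays(
        y, t, pairs, singles, params.mu, params.delta, params.sigma2_subj, params.sigma2_err
    )


def _lmm_gls(y, t, pairs, singles, s2s, s2e):
    """Profiled GLS at fixed variance components.

    Returns (beta_hat, XtVinvX, profiled log-likelihood).  Design is
    X = [1, treat]; covariance V as in :func:`lmm_loglik`.
    """
    a = s2s + s2e
    A = np.zeros((2, 2))
    c = np.zeros(2)
    logdet = 0.0
    n = y.size
    if singles.size:
        w = 1.0 / a
        ys = y[singles]
        ts = t[singles]
        A += w * np.array(
            [[singles.size, ts.sum()], [ts.sum(), ts.sum()]]
        )
        c += w * np.array([ys.sum(), np.dot(ts, ys)])
        logdet += singles.size * math.log(a)
    if len(pairs):
        b = s2s
        det = a * a - b * b
        w11 = a / det
        w12 = -b / det
        y1 = y[pairs[:, 0]]
        y2 = y[pairs[:, 1]]
        t1 = t[pairs[:, 0]]
        t2 = t[pairs[:, 1]]
        npair = len(pairs)
        # X block per pair: [[1, t1], [1, t2]]
        A[0, 0] += npair * 2.0 * (w11 + w12)
        cross = (w11 * (t1 + t2) + w12 * (t1 + t2)).sum()
        A[0, 1] += cross
        A[1, 0] += cross
        A[1, 1] += (w11 * (t1 * t1 + t2 * t2) + 2.0 * w12 * t1 * t2).sum()
        c[0] += (w11 * (y1 + y2) + w12 * (y1 + y2)).sum()
        c[1] += (w11 * (t1 * y1 + t2 * y2) + w12 * (t1 * y2 + t2 * y1)).sum()
        logdet += npair * math.log(det)
    try:
        beta = np.linalg.solve(A, c)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - singular design
        raise NumericalError(f"singular GLS system: {exc}") from exc
    ll = _lmm_loglik_arrays(y, t, pairs, singles, beta[0], beta[1], s2s, s2e)
    return beta, A, ll


def fit_lmm(y, table: SampleTable, include_random: bool = True) -> FitResult:
    """Fit the continuous model by ML and test the treatment effect.

    With ``include_random=False`` the subject effect is dropped and the
    fit reduces to the classical two-sample comparison (pooled-variance
    t test with ``N - 2`` degrees of freedom) — the "unpaired analysis"
    that ignores any pairing in the data.

    With ``include_random=True`` the variance components are estimated
    by ML on the log scale (floored at ``exp(-20)``), the treatment
    effect by profiled GLS, and the Wald t test uses denominator
    degrees of freedom ``N - 2 - P`` where ``P`` is the number of
    paired subjects: each estimated subject effect effectively costs
    one degree of freedom.  When that df is below 1 the test is
    unavailable (``p_value`` is NaN).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("y contains non-finite values")
    t, pairs, singles = _lmm_structure(table)
    n = table.n_samples
    if y.shape != (n,):
        raise ValidationError(f"y has shape {y.shape}, expected ({n},)")
    n1 = int(t.sum())
    if n1 == 0 or n1 == n:
        raise ValidationError("both conditions must be present to test the TRT effect")
    if table.n_subjects < 3:
        raise ValidationError("need at least 3 subjects")

    if not include_random or len(pairs) == 0:
        # no pairs: sigma2_subj is unidentified and the marginal model
        # reduces to the two-sample comparison
        return _fit_two_sample(y, t, n)

    # moment-based starting values
    beta0 = [y[t == 0].mean(), y[t == 1].mean() - y[t == 0].mean()]
    r0 = y - (beta0[0] + beta0[1] * t)
    r1 = r0[pairs[:, 0]]
    r2 = r0[pairs[:, 1]]
    cov0 = float(np.mean(r1 * r2)) if len(pairs) else 0.0
    var0 = float(np.var(r0))
    s2s0 = min(max(cov0, 1e-3 * max(var0, 1e-6)), 0.95 * var0)
    s2e0 = max(var0 - s2s0, 1e-3 * max(var0, 1e-6))

    def negll(x):
        s2s = math.exp(min(max(x[0], _LOG_FLOOR), 40.0))
        s2e = math.exp(min(max(x[1], _LOG_FLOOR), 40.0))
        _, _, ll = _lmm_gls(y, t, pairs, singles, s2s, s2e)
        return -ll

    x0 = np.array([math.log(max(s2s0, 1e-8)), math.log(max(s2e0, 1e-8))])
    res = optimize.minimize(
        negll,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 600},
    )
    s2s = math.exp(min(max(res.x[0], _LOG_FLOOR), 40.0))
    s2e = math.exp(min(max(res.x[1], _LOG_FLOOR), 40.0))
    beta, A, ll = _lmm_gls(y, t, pairs, singles, s2s, s2e)
    try:
        cov_beta = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"singular information matrix: {exc}") from exc
    se = math.sqrt(max(cov_beta[1, 1], 0.0))
    converged = bool(res.success) and np.isfinite(ll) and se > 0
    df = n - 2 - len(pairs)
    stat = beta[1] / se if se > 0 else math.nan
    if df >= 1 and converged:
        p = 2.0 * stats.t.sf(abs(stat), df)
    else:
        p = math.nan
    return FitResult(
        estimates={
            "mu": float(beta[0]),
            "delta": float(beta[1]),
            "sigma2_subj": s2s if s2s > 2e-9 else 0.0,
            "sigma2_err": s2e,
        },
        se_delta=se,
        statistic=float(stat),
        df=float(df),
        p_value=float(p),
        converged=converged,
        log_likelihood=float(ll),
        message=res.message if not res.success else "",
    )


def _fit_two_sample(y, t, n) -> FitResult:
    """Ordinary two-group least squares (classical pooled t test)."""
    y1 = y[t == 1]
    y0 = y[t == 0]
    n1, n0 = y1.size, y0.size
    delta = float(y1.mean() - y0.mean())
    mu = float(y0.mean())
    df = n - 2
    ss = float(np.sum((y1 - y1.mean()) ** 2) + np.sum((y0 - y0.mean()) ** 2))
    sp2 = ss / df if df > 0 else math.nan
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    stat = delta / se if se > 0 else math.nan
    p = 2.0 * stats.t.sf(abs(stat), df) if df >= 1 else math.nan
    sig2_ml = ss / n
    ll = -0.5 * n * (_LOG2PI + math.log(sig2_ml) + 1.0)
    return FitResult(
        estimates={"mu": mu, "delta": delta, "sigma2_subj": 0.0, "sigma2_err": sp2},
        se_delta=se,
        statistic=float(stat),
        df=float(df),
        p_value=float(p),
        converged=True,
        log_likelihood=float(ll),
    )


# ---------------------------------------------------------------------------
# count family
# ---------------------------------------------------------------------------


def _nb_logpmf(y, log_m, theta):
    """log NB(y; mean m, dispersion theta), with log-mean supplied."""
    m = np.exp(log_m)
    return (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        + theta * (math.log(theta) if np.isscalar(theta) else np.log(theta))
        - (y + theta) * np.log(theta + m)
        + y * log_m
    )


def _check_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if not np.all(np.isfinite(y)):
        raise ValidationError("counts contain non-finite values")
    if np.any(y < 0):
        raise ValidationError("counts must be nonnegative")
    if np.any(y != np.floor(y)):
        raise ValidationError("counts must be integers")
    return y.astype(float)


def _subject_layout(table: SampleTable):
    """Pack observations into (n_subjects, 2) padded arrays.

    Column 1 is masked out for single-sample subjects.
    """
    pairs = table.pair_indices()
    singles = table.single_indices()
    npair, nsing = len(pairs), singles.size
    S = npair + nsing
    idx = np.zeros((S, 2), dtype=int)
    mask = np.zeros((S, 2), dtype=bool)
    if npair:
        idx[:npair] = pairs
        mask[:npair] = True
    if nsing:
        idx[npair:, 0] = singles
        mask[npair:, 0] = True
    return idx, mask


@lru_cache(maxsize=8)
def _hermgauss(n_quad: int):
    x, w = np.polynomial.hermite.hermgauss(n_quad)
    return x, np.log(w) + x**2


def _agh_loglik(y2, eta2, mask, s2s, theta, n_quad, b_start=None):
    """AGH marginal log-likelihood, vectorized over subjects.

    ``y2, eta2`` are (S, 2) padded per-subject arrays; the integrand per
    subject is prod_i NB(y_i; exp(eta_i + b), theta) * phi(b; 0, s2s).
    The mode of the log-integrand is found by Newton — it is strictly
    concave in ``b`` — and the integral evaluated with Gauss-Hermite
    nodes recentred and rescaled at the mode.  ``b_start`` warm-starts
    the mode search (e.g. with the previous optimizer iterate's modes).
    """
    m0 = np.where(mask, 1.0, 0.0)
    yv = np.where(mask, y2, 0.0)
    const = np.where(
        mask,
        special.gammaln(yv + theta)
        - special.gammaln(theta)
        - special.gammaln(yv + 1.0)
        + theta * math.log(theta),
        0.0,
    ).sum(axis=1)

    def grad_hess(b):
        log_m = eta2 + b[:, None]
        m = np.exp(np.clip(log_m, -745.0, 700.0))
        frac = m / (theta + m)
        g = np.sum(m0 * (yv - (yv + theta) * frac), axis=1) - b / s2s
        h = -np.sum(m0 * (yv + theta) * theta * frac / (theta + m), axis=1) - 1.0 / s2s
        return g, h

    b = np.zeros(y2.shape[0]) if b_start is None else b_start.copy()
    for _ in range(50):
        g, h = grad_hess(b)
        # the objective is concave so full Newton is safe; clip guards
        # overflow from extreme starting points
        step = np.clip(g / h, -5.0, 5.0)
        b = b - step
        if np.max(np.abs(step)) < 1e-9:
            break
    g, h = grad_hess(b)
    sd = 1.0 / np.sqrt(-h)

    x, logw = _hermgauss(n_quad)
    nodes = b[:, None] + math.sqrt(2.0) * sd[:, None] * x[None, :]  # (S, K)
    # log-integrand at the nodes, constants factored out of the K axis
    log_m = eta2[:, :, None] + nodes[:, None, :]  # (S, 2, K)
    mK = np.exp(np.clip(log_m, -745.0, 700.0))
    terms = (
        m0[:, :, None] * (yv[:, :, None] * log_m - (yv + theta)[:, :, None] * np.log(theta + mK))
    ).sum(axis=1)
    log_g = (
        terms
        - 0.5 * (nodes**2) / s2s
        + logw[None, :]
    )
    top = log_g.max(axis=1)
    per_subject = top + np.log(np.exp(log_g - top[:, None]).sum(axis=1))
    per_subject += const - 0.5 * math.log(2.0 * math.pi * s2s) + 0.5 * math.log(2.0) + np.log(sd)
    return float(per_subject.sum()), b


def nb_glmm_loglik(
    y, table: SampleTable, params: NBParams, n_quad: int = 15
) -> float:
    """Marginal log-likelihood of the NB mixed model.

    The subject random effect is integrated out per subject by
    adaptive Gauss-Hermite quadrature with ``n_quad`` nodes
    (``n_quad=1`` is the Laplace approximation).  With
    ``sigma2_subj = 0`` the random effect is degenerate and the plain
    NB log-likelihood is returned.
    """
    y = _check_counts(y)
    if y.shape != (table.n_samples,):
        raise ValidationError(f"y has shape {y.shape}, expected ({table.n_samples},)")
    t = table.treatment_indicator()
    eta = table.offsets() + params.mu + params.delta * t
    theta = params.theta
    if params.sigma2_subj < 1e-12:
        return float(_nb_logpmf(y, eta, theta).sum())
    idx, mask = _subject_layout(table)
    y2 = y[idx]
    eta2 = eta[idx]
    ll, _ = _agh_loglik(y2, eta2, mask, params.sigma2_subj, theta, n_quad)
    return ll


# -- fixed-effect design helpers --------------------------------------------


def expand_covariates(table: SampleTable, covariates) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect columns for the named covariates.

    Categorical covariates (non-numeric dtype) are reference-coded with
    the first-observed level as reference; numeric covariates enter
    as-is.  Returns (matrix, column names).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name in covariates or []:
        if name not in table.data.columns:
            raise ValidationError(f"covariate {name!r} not found in sample table")
        col = table.data[name]
        if col.isna().any():
            raise ValidationError(f"covariate {name!r} has missing values")
        if np.issubdtype(np.asarray(col).dtype, np.number):
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
        else:
            levels = list(dict.fromkeys(col))
            for lev in levels[1:]:
                cols.append((col == lev).to_numpy(dtype=float))
                names.append(f"{name}[{lev}]")
    if not cols:
        return np.empty((table.n_samples, 0)), []
    return np.column_stack(cols), names


def _nb_glm_negll_grad(par, y, X, offset):
    """Negative log-likelihood and gradient of the NB GLM, par = (beta, log theta)."""
    beta = par[:-1]
    theta = math.exp(min(max(par[-1], _LOG_FLOOR), 30.0))
    log_m = offset + X @ beta
    m = np.exp(np.clip(log_m, -745.0, 700.0))
    ll = np.sum(_nb_logpmf(y, log_m, theta))
    frac = m / (theta + m)
    gbeta = X.T @ (y - (y + theta) * frac)
    gtheta = theta * np.sum(
        special.digamma(y + theta)
        - special.digamma(theta)
        + math.log(theta)
        + 1.0
        - np.log(theta + m)
        - (y + theta) / (theta + m)
    )
    return -ll, -np.concatenate([gbeta, [gtheta]])


def _fit_nb_glm(y, X, offset):
    """Own ML negative-binomial regression (log link, NB2 dispersion)."""
    # Poisson-flavoured start: regress log(y + 0.5) - offset on X
    z = np.log(y + 0.5) - offset
    beta0, *_ = np.linalg.lstsq(X, z, rcond=None)
    m0 = np.exp(np.clip(offset + X @ beta0, -700, 700))
    resid = (y - m0) ** 2 - m0
    denom = float(np.sum(m0**2))
    k0 = max(float(np.sum(resid)) / denom, 1e-3) if denom > 0 else 1.0
    par0 = np.concatenate([beta0, [math.log(1.0 / k0)]])
    res = optimize.minimize(
        _nb_glm_negll_grad,
        par0,
        args=(y, X, offset),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    beta = res.x[:-1]
    theta = math.exp(min(max(res.x[-1], _LOG_FLOOR), 30.0))
    return beta, theta, -res.fun, res


def fit_nb_glmm(
    y,
    table: SampleTable,
    include_random: bool = True,
    covariates=None,
    n_quad: int = 15,
    precise: bool = False,
) -> FitResult:
    """Fit the NB model by ML and test the treatment effect.

    ``include_random=False`` drops the subject effect and fits a plain
    NB regression (the unpaired analysis), optionally with subject
    covariates as fixed effects; the Wald test of ``delta`` is a z
    test.  ``include_random=True`` additionally estimates the subject
    variance component (profiled on the log scale with a hard floor)
    with the likelihood evaluated by adaptive Gauss-Hermite
    quadrature; the Wald test is a t test with
    ``df = N - rank(X) - P`` for ``P`` paired subjects.
    """
    y = _check_counts(y)
    t = table.treatment_indicator()
    n = table.n_samples
    if y.shape != (n,):
        raise ValidationError(f"y has shape {y.shape}, expected ({n},)")
    if t.sum() in (0, n):
        raise ValidationError("both conditions must be present to test the TRT effect")
    offset = table.offsets()
    Xcov, names = expand_covariates(table, covariates)
    X = np.column_stack([np.ones(n), t, Xcov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("fixed-effect design is rank deficient (separation?)")
    p_fixed = X.shape[1]

    beta_glm, theta_glm, ll_glm, res_glm = _fit_nb_glm(y, X, offset)

    npair = table.n_paired_subjects
    if not include_random or npair == 0:
        m = np.exp(np.clip(offset + X @ beta_glm, -700, 700))
        w = m * theta_glm / (theta_glm + m)  # GLM working weights, log link
        info = X.T @ (X * w[:, None])
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"singular information matrix: {exc}") from exc
        se = math.sqrt(max(cov[1, 1], 0.0))
        stat = beta_glm[1] / se if se > 0 else math.nan
        converged = bool(res_glm.success) and se > 0
        # Wald t with residual df (t -> z as N grows): calibrates the
        # test at small N consistently with the F-based power formula
        df_glm = n - p_fixed
        p = 2.0 * stats.t.sf(abs(stat), df_glm) if (converged and df_glm >= 1) else math.nan
        est = {"mu": float(beta_glm[0]), "delta": float(beta_glm[1]),
               "sigma2_subj": 0.0, "theta": theta_glm, "scale": math.sqrt(1.0 / theta_glm)}
        for nm, b in zip(names, beta_glm[2:]):
            est[nm] = float(b)
        return FitResult(
            estimates=est,
            se_delta=se,
            statistic=float(stat),
            df=float(df_glm),
            p_value=float(p),
            converged=converged,
            log_likelihood=float(ll_glm),
            message="" if res_glm.success else str(res_glm.message),
        )

    idx, mask = _subject_layout(table)
    y2 = y[idx]
    off2 = offset[idx]
    X2 = X[idx]  # (S, 2, p)

    warm = {"b": None}

    def negll(par):
        beta = par[:p_fixed]
        s2s = math.exp(min(max(par[p_fixed], _LOG_FLOOR), 10.0))
        theta = math.exp(min(max(par[p_fixed + 1], _LOG_FLOOR), 30.0))
        eta2 = off2 + np.einsum("sij,j->si", X2, beta)
        if s2s < 1e-10:
            lm = np.where(mask, eta2, 0.0)
            ll = np.where(mask, _nb_logpmf(np.where(mask, y2, 0.0), lm, theta), 0.0).sum()
            return -float(ll)
        ll, b = _agh_loglik(y2, eta2, mask, s2s, theta, n_quad, b_start=warm["b"])
        warm["b"] = b
        return -ll

    # moment start for the subject variance: spread of within-subject
    # mean log residuals around the GLM fit
    eta_glm = offset + X @ beta_glm
    resid = np.log((y + 0.5) / np.exp(eta_glm))
    r2 = resid[idx]
    rbar = np.where(mask, r2, 0.0).sum(axis=1) / mask.sum(axis=1)
    s2s0 = min(max(float(np.var(rbar)), 0.02), 5.0)
    par0 = np.concatenate([beta_glm, [math.log(s2s0), math.log(theta_glm)]])
    xatol, fatol = (1e-6, 1e-10) if precise else (1e-4, 1e-7)
    res = optimize.minimize(
        negll,
        par0,
        method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol, "maxiter": 400 * (p_fixed + 2),
                 "maxfev": 400 * (p_fixed + 2)},
    )
    if precise:  # polish with a restart from the first optimum
        res = optimize.minimize(
            negll, res.x, method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol,
                     "maxiter": 400 * (p_fixed + 2), "maxfev": 400 * (p_fixed + 2)},
        )
    beta = res.x[:p_fixed]
    s2s = math.exp(min(max(res.x[p_fixed], _LOG_FLOOR), 10.0))
    theta = math.exp(min(max(res.x[p_fixed + 1], _LOG_FLOOR), 30.0))
    ll = -float(res.fun)

    # Wald covariance of the fixed effects: central finite-difference
    # Hessian in the beta block at the variance-parameter optimum
    # (fixed effects and variance parameters are asymptotically
    # orthogonal in these models).
    h = 1e-4
    H = np.zeros((p_fixed, p_fixed))
    x_opt = res.x.copy()

    def f_beta(db):
        par = x_opt.copy()
        par[:p_fixed] = par[:p_fixed] + db
        return negll(par)

    f0 = float(res.fun)
    for i in range(p_fixed):
        for j in range(i, p_fixed):
            ei = np.zeros(p_fixed)
            ej = np.zeros(p_fixed)
            ei[i] = h
            ej[j] = h
            if i == j:
                val = (f_beta(ei) - 2.0 * f0 + f_beta(-ei)) / (h * h)
            else:
                val = (
                    f_beta(ei + ej) - f_beta(ei - ej) - f_beta(-ei + ej) + f_beta(-ei - ej)
                ) / (4.0 * h * h)
            H[i, j] = H[j, i] = val
    converged = bool(res.success)
    se = math.nan
    try:
        cov = np.linalg.inv(H)
        if cov[1, 1] > 0:
            se = math.sqrt(cov[1, 1])
    except np.linalg.LinAlgError:
        pass
    if not math.isfinite(se) or se <= 0:
        converged = False
    df = n - p_fixed - npair
    stat = beta[1] / se if (math.isfinite(se) and se > 0) else math.nan
    p = 2.0 * stats.t.sf(abs(stat), df) if (converged and df >= 1) else math.nan
    est = {"mu": float(beta[0]), "delta": float(beta[1]),
           "sigma2_subj": s2s if s2s > 2e-9 else 0.0,
           "theta": theta, "scale": math.sqrt(1.0 / theta)}
    for nm, b in zip(names, beta[2:]):
        est[nm] = float(b)
    return FitResult(
        estimates=est,
        se_delta=float(se),
        statistic=float(stat),
        df=float(df),
        p_value=float(p),
        converged=converged,
        log_likelihood=ll,
        message="" if res.success else str(res.message),
    )


# ---------------------------------------------------------------------------
# multiplicity
# ---------------------------------------------------------------------------


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries propagate as NaN and are excluded from the number of
    tests ``m``.  Adjusted values are monotone in the sorted raw
    p-values, capped at 1, and never below the raw p-value.  Ties are
    broken by stable sort order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out
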