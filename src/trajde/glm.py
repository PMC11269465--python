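"""Polynomial GLMs with offsets for pseudo-bulk trajectory counts.

The model for gene *i* in bin *t* of path *z* is, for two paths and degree 2,

    g(mu) = b0 + b1*t + b2*t^2 + b3*z + b4*t*z + b5*t^2*z + offset

with g = log and a negative-binomial response by default.  The time covariate
is the ordinal binned-pseudotime index, path membership enters through dummy
variables (reference path all-zero) and their interactions with the time
powers, and the offset is the log bin size factor with coefficient fixed at 1.

Fitting is iteratively reweighted least squares (Fisher scoring); the NB
dispersion theta is estimated per gene by alternating a Pearson chi-square
moment match with the IRLS inner loop.  Aliased (rank-deficient) columns are
dropped with a warning and reported as NaN coefficients.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "Term",
    "DesignMatrix",
    "build_design",
    "GLMFit",
    "fit_glm",
    "lrt_pvalue",
    "deviance_r2",
]

THETA_MIN = 1e-3
THETA_MAX = 1e6
MAX_OUTER = 25

FAMILIES = ("nb", "poisson", "gaussian")


@dataclass(frozen=True)
class Term:
    """One design column: pseudotime power and (for interactions/dummies) the
    non-reference path it belongs to."""

    name: str
    power: int          # 0 for intercept / pure dummy
    path: object = None  # None for intercept and pure time terms

    @property
    def is_intercept(self) -> bool:
        return self.power == 0 and self.path is None

    @property
    def involves_path(self) -> bool:
        return self.path is not None


@dataclass
class DesignMatrix:
    """Eq-style polynomial design over (binned pseudotime, path dummies)."""

    X: np.ndarray
    terms: list
    reference: object
    degree: int

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def names(self) -> list:
        return [t.name for t in self.terms]

    def subset(self, keep: list) -> "DesignMatrix":
        """Design restricted to the given term names (intercept always kept)."""
        idx = [i for i, t in enumerate(self.terms)
               if t.is_intercept or t.name in keep]
        return DesignMatrix(
            self.X[:, idx], [self.terms[i] for i in idx], self.reference, self.degree
        )

    def intercept_only(self) -> "DesignMatrix":
        return self.subset([])


def build_design(
    bin_meta: pd.DataFrame,
    degree: int = 3,
    reference_path=None,
) -> DesignMatrix:
    """Build the polynomial + path-dummy design from binned metadata.

    ``bin_meta`` needs columns ``t_index`` and ``path``.  Columns are the
    intercept, t..t^degree, then per non-reference path a dummy z and its
    interactions t^m * z; total (degree+1) * n_paths columns.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    t = bin_meta["t_index"].to_numpy(dtype=float)
    path = bin_meta["path"].to_numpy(dtype=object)
    labels = list(pd.unique(path))
    if len(labels) < 1:
        raise ValueError("need at least one path")
    if reference_path is None:
        reference_path = labels[0]
    if reference_path not in labels:
        raise ValueError(f"reference path {reference_path!r} not present")
    others = [p for p in labels if p != reference_path]

    cols = [np.ones_like(t)]
    terms = [Term("intercept", 0, None)]
    for m in range(1, degree + 1):
        cols.append(t ** m)
        terms.append(Term("t" if m == 1 else f"t{m}", m, None))
    for p in others:
        z = (path == p).astype(float)
        cols.append(z)
        terms.append(Term(f"z[{p}]", 0, p))
        for m in range(1, degree + 1):
            cols.append((t ** m) * z)
            tm = "t" if m == 1 else f"t{m}"
            terms.append(Term(f"{tm}:z[{p}]", m, p))
    return DesignMatrix(np.column_stack(cols), terms, reference_path, degree)


# ---------------------------------------------------------------------------
# families

def _nb_loglik(y, mu, theta):
    mu = np.maximum(mu, 1e-12)
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _nb_deviance(y, mu, theta):
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y + theta) * np.log((y + theta) / (mu + theta))))


def _poisson_loglik(y, mu):
    mu = np.maximum(mu, 1e-12)
    return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))


def _poisson_deviance(y, mu):
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _gaussian_loglik(y, mu):
    n = len(y)
    rss = float(np.sum((y - mu) ** 2))
    s2 = max(rss / n, 1e-300)
    return -0.5 * n * (math.log(2 * math.pi * s2) + 1.0)


# ---------------------------------------------------------------------------
# fitting

@dataclass
class GLMFit:
    """State of a fitted GLM for one gene."""

    coef: np.ndarray            # aligned with design terms; NaN for aliased
    terms: list
    theta: float                # NB size parameter (inf for poisson/gaussian)
    family: str
    link: str
    loglik: float
    deviance: float
    null_deviance: float
    mu: np.ndarray
    converged: bool
    n_iter: int
    rank: int                   # number of estimated mean parameters
    n_obs: int
    poisson_fallback: bool = False
    degenerate: bool = False
    y: np.ndarray | None = None
    X: np.ndarray | None = None
    offset: np.ndarray | None = None


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (QR pivoting)."""
    from scipy.linalg import qr

    if X.shape[1] == 0:
        return np.array([], dtype=int)
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol)) if diag.size else 0
    return np.sort(piv[:rank])


def _irls_log_link(y, X, offset, weight_fn, max_iter=100, tol=1e-10):
    """Fisher scoring for a log-link count model.

    ``weight_fn(mu)`` returns the IRLS working weights mu^2/Var(mu).
    Returns (beta, mu, n_iter, converged).
    """
    n, p = X.shape
    mu = np.maximum(y, 0.0) + np.mean(y) * 0.1 + 0.1
    eta = np.log(mu)
    beta = np.zeros(p)
    converged = False
    dev_old = np.inf
    for it in range(1, max_iter + 1):
        w = weight_fn(mu)
        z = eta - offset + (y - mu) / mu
        wx = X * w[:, None]
        a = X.T @ wx
        b = wx.T @ z
        try:
            beta_new = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(a, b, rcond=None)[0]
        eta = np.clip(X @ beta_new + offset, -30.0, 30.0)
        mu = np.exp(eta)
        crit = float(np.max(np.abs(beta_new - beta))) if it > 1 else np.inf
        beta = beta_new
        # secondary criterion on the working deviance proxy
        dev = float(np.sum((y - mu) ** 2 / np.maximum(mu, 1e-12)))
        if crit < 1e-8 or abs(dev - dev_old) < tol * (abs(dev) + 0.1):
            converged = True
            break
        dev_old = dev
    return beta, mu, it, converged


def _estimate_theta(y, mu, dof):
    """Pearson chi-square moment estimate of the NB size parameter theta.

    Solves sum((y-mu)^2 / (mu + mu^2/theta)) = dof for theta; monotone
    increasing in theta, solved by bracketed root finding on log(theta).
    Returns a value clipped to [THETA_MIN, THETA_MAX].
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    dof = max(dof, 1)
    resid2 = (y - mu) ** 2

    def pearson(log_th):
        th = math.exp(log_th)
        return float(np.sum(resid2 / (mu + mu * mu / th))) - dof

    lo, hi = math.log(THETA_MIN), math.log(THETA_MAX)
    if pearson(hi) <= 0:      # under/equi-dispersed: Poisson-like
        return THETA_MAX
    if pearson(lo) >= 0:      # extreme overdispersion
        return THETA_MIN
    return math.exp(optimize.brentq(pearson, lo, hi, xtol=1e-8))


def fit_glm(
    y: np.ndarray,
    design: DesignMatrix,
    offset: np.ndarray | None = None,
    family: str = "nb",
    theta: float | None = None,
    max_outer: int = MAX_OUTER,
) -> GLMFit:
    """Fit a GLM for one gene's per-bin counts.

    For the NB family, ``theta`` fixes the dispersion; when None it is
    estimated by alternating Pearson moment updates with IRLS (max
    ``max_outer`` outer iterations, theta capped in [1e-3, 1e6]; hitting the
    upper cap falls back to Poisson with ``poisson_fallback`` set).  The
    Gaussian family uses the identity link (for pre-normalised inputs) and
    ignores offsets unless given.  An all-zero response under the log link is
    returned as a flagged degenerate fit, never as converged.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    y = np.asarray(y, dtype=float)
    X_full = design.X
    n, p_full = X_full.shape
    if len(y) != n:
        raise ValueError(f"response length {len(y)} != design rows {n}")
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, dtype=float)
    if not np.all(np.isfinite(offset)):
        raise ValueError("offsets must be finite")

    keep = _independent_columns(X_full)
    if len(keep) < p_full:
        logger.warning(
            "design is rank deficient: dropping %d aliased column(s): %s",
            p_full - len(keep),
            [design.terms[i].name for i in range(p_full) if i not in set(keep)],
        )
    X = X_full[:, keep]
    rank = X.shape[1]

    coef_full = np.full(p_full, np.nan)

    if family == "gaussian":
        resp = y - offset
        beta, *_ = np.linalg.lstsq(X, resp, rcond=None)
        mu = X @ beta + offset
        rss = float(np.sum((y - mu) ** 2))
        ybar = float(np.mean(y))
        null_dev = float(np.sum((y - ybar) ** 2))
        coef_full[keep] = beta
        return GLMFit(
            coef=coef_full, terms=design.terms, theta=np.inf, family=family,
            link="identity", loglik=_gaussian_loglik(y, mu), deviance=rss,
            null_deviance=null_dev, mu=mu, converged=True, n_iter=1, rank=rank,
            n_obs=n, y=y, X=X_full, offset=offset,
        )

    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    degenerate = bool(np.all(y == 0))
    if degenerate:
        # intercept -> -inf under the log link; guard and flag
        mu = np.full(n, 1e-8)
        coef_full[keep] = 0.0
        coef_full[0] = math.log(1e-8)
        ll = _poisson_loglik(y, mu) if family == "poisson" else _nb_loglik(y, mu, 1.0)
        return GLMFit(
            coef=coef_full, terms=design.terms, theta=np.inf, family=family,
            link="log", loglik=ll, deviance=0.0, null_deviance=0.0, mu=mu,
            converged=False, n_iter=0, rank=rank, n_obs=n, degenerate=True,
            y=y, X=X_full, offset=offset,
        )

    ones = np.ones((n, 1))

    def null_deviance_for(theta_val):
        # intercept + offset model; Poisson MLE is closed form, NB needs IRLS
        if family == "poisson" or theta_val is None or theta_val >= THETA_MAX:
            s = np.exp(offset)
            mu0 = s * (y.sum() / s.sum())
            if family == "poisson" or theta_val is None:
                return _poisson_deviance(y, mu0)
            return _nb_deviance(y, mu0, theta_val)
        _, mu0, _, _ = _irls_log_link(
            y, ones, offset, lambda m: m / (1.0 + m / theta_val)
        )
        return _nb_deviance(y, mu0, theta_val)

    if family == "poisson":
        beta, mu, n_iter, conv = _irls_log_link(y, X, offset, lambda m: m)
        coef_full[keep] = beta
        return GLMFit(
            coef=coef_full, terms=design.terms, theta=np.inf, family=family,
            link="log", loglik=_poisson_loglik(y, mu),
            deviance=_poisson_deviance(y, mu),
            null_deviance=null_deviance_for(None), mu=mu, converged=conv,
            n_iter=n_iter, rank=rank, n_obs=n, y=y, X=X_full, offset=offset,
        )

    # negative binomial
    poisson_fallback = False
    total_iter = 0
    if theta is not None:
        th = float(np.clip(theta, THETA_MIN, THETA_MAX))
        beta, mu, n_iter, conv = _irls_log_link(
            y, X, offset, lambda m: m / (1.0 + m / th)
        )
        total_iter = n_iter
    else:
        # init from a Poisson fit, then alternate moment update and IRLS
        beta, mu, n_iter, conv = _irls_log_link(y, X, offset, lambda m: m)
        total_iter += n_iter
        th = _estimate_theta(y, mu, n - rank)
        for _ in range(max_outer):
            beta, mu, n_iter, conv = _irls_log_link(
                y, X, offset, lambda m: m / (1.0 + m / th)
            )
            total_iter += n_iter
            th_new = _estimate_theta(y, mu, n - rank)
            if abs(math.log(th_new) - math.log(th)) < 1e-4:
                th = th_new
                break
            th = th_new
        if th >= THETA_MAX:
            poisson_fallback = True
        if th <= THETA_MIN:
            logger.warning("theta hit lower cap %.0e (extreme overdispersion)", THETA_MIN)

    coef_full[keep] = beta
    return GLMFit(
        coef=coef_full, terms=design.terms, theta=th, family="nb", link="log",
        loglik=_nb_loglik(y, mu, th), deviance=_nb_deviance(y, mu, th),
        null_deviance=null_deviance_for(th), mu=mu, converged=conv,
        n_iter=total_iter, rank=rank, n_obs=n,
        poisson_fallback=poisson_fallback, y=y, X=X_full, offset=offset,
    )


def lrt_pvalue(full: GLMFit, null: GLMFit) -> float:
    """Likelihood-ratio p-value of ``full`` against the nested ``null``.

    The statistic 2*(ll_full - ll_null) is clamped at zero and referred to a
    chi-square with df = difference in estimated mean parameters.  The null
    must be fitted on the same data (and, for NB, with the dispersion shared
    from the full fit so the test compares mean structures only).
    """
    if full.n_obs != null.n_obs or (
        full.y is not None and null.y is not None and not np.array_equal(full.y, null.y)
    ):
        raise ValueError("LRT requires both fits on the same response")
    df = full.rank - null.rank
    if df <= 0:
        return 1.0
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    return float(stats.chi2.sf(stat, df))


def deviance_r2(fit: GLMFit) -> float:
    """Deviance-explained R^2 = 1 - residual/null deviance, clamped to [0,1].

    A constant gene (null deviance 0) has R^2 defined as 0.
    """
    if fit.null_deviance <= 0:
        return 0.0
    return float(np.clip(1.0 - fit.deviance / fit.null_deviance, 0.0, 1.0))
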