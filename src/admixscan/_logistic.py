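"""Maximum-likelihood logistic regression by iteratively reweighted least squares.

Shared numerical core for the admixture-mapping scan and the regional SNP
association tests.  Deliberately small: dense design matrices with at most a
handful of columns, explicit convergence/separation flags instead of
exceptions, Wald inference from the observed information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

#: log-likelihood convergence tolerance
LL_TOL = 1e-8
#: maximum IRLS iterations before flagging non-convergence
MAX_ITER = 50
#: |beta| beyond which the fit is treated as (quasi-)separated
_BETA_DIVERGED = 30.0


@dataclass
class LogisticFit:
    """Result of one logistic ML fit.

    ``beta``/``se``/``p`` are aligned with the columns of the design matrix
    passed in; entries for columns dropped as constant are NaN.  ``converged``
    is False for one-class outcomes, separation, or iteration exhaustion, in
    which case the p-values are NaN.
    """

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    dropped: list[int] = field(default_factory=list)

    def ci(self, level: float = 0.95) -> np.ndarray:
        """Wald confidence intervals, one (lo, hi) row per coefficient."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.beta - z * self.se, self.beta + z * self.se])


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # sum y*eta - log(1+exp(eta)), stable via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticFit:
    """Fit ``logit P(y=1) = X beta`` by IRLS.

    Columns of ``X`` that are constant (zero variance) other than a single
    intercept column are dropped from the fit and reported as NaN; the
    remaining coefficients are those of the reduced model.  A one-class
    outcome or separated fit returns ``converged=False`` with NaN p-values
    rather than raising.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D and aligned with y")
    n, p = X.shape
    nan = np.full(p, np.nan)

    if not (np.any(y == 0) and np.any(y == 1)):
        return LogisticFit(nan, nan.copy(), nan.copy(), np.nan, False, 0, n)

    # keep one intercept-like column, drop any further constant columns
    const = X.std(axis=0) == 0
    keep = []
    seen_const = False
    for j in range(p):
        if const[j]:
            if X[0, j] != 0 and not seen_const:
                keep.append(j)
                seen_const = True
        else:
            keep.append(j)
    dropped = sorted(set(range(p)) - set(keep))
    Xk = X[:, keep]

    beta = np.zeros(len(keep))
    ll_old = _loglik(y, Xk @ beta)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = Xk @ beta
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        xtw = Xk.T * w
        try:
            beta_new = np.linalg.solve(xtw @ Xk, xtw @ z)
        except np.linalg.LinAlgError:
            return LogisticFit(nan, nan.copy(), nan.copy(), np.nan, False, it, n, dropped)
        step = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        ll = _loglik(y, Xk @ beta)
        if not np.isfinite(ll) or np.max(np.abs(beta)) > _BETA_DIVERGED:
            return LogisticFit(nan, nan.copy(), nan.copy(), np.nan, False, it, n, dropped)
        # ll tolerance alone can stop in a flat direction; also require the
        # Newton step itself to have settled
        if abs(ll - ll_old) < LL_TOL and step < 1e-8:
            converged = True
            break
        ll_old = ll

    if not converged:
        return LogisticFit(nan, nan.copy(), nan.copy(), np.nan, False, it, n, dropped)

    mu = special.expit(Xk @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = (Xk.T * w) @ Xk
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return LogisticFit(nan, nan.copy(), nan.copy(), np.nan, False, it, n, dropped)
    se_k = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore"):
        zval = beta / se_k
    p_k = 2.0 * stats.norm.sf(np.abs(zval))

    beta_f, se_f, p_f = nan.copy(), nan.copy(), nan.copy()
    beta_f[keep], se_f[keep], p_f[keep] = beta, se_k, p_k
    return LogisticFit(beta_f, se_f, p_f, _loglik(y, Xk @ beta), True, it, n, dropped)
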