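"""EM estimation of a multivariate normal from incompletely observed data.

Standard missing-data EM: the E-step sweeps each observedness pattern,
computing conditional means of the missing block given the observed block
and the conditional covariance correction; the M-step re-estimates the mean
and (maximum-likelihood, 1/n) covariance.  Convergence is monitored on the
observed-data log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError


@dataclass
class EMResult:
    mean: np.ndarray
    cov: np.ndarray
    n_iter: int
    converged: bool
    loglik: float


def _pattern_groups(observed: np.ndarray) -> dict[tuple, np.ndarray]:
    """Map each distinct observedness pattern to its row indices."""
    groups: dict[tuple, list[int]] = {}
    for i, row in enumerate(observed):
        groups.setdefault(tuple(row.tolist()), []).append(i)
    return {k: np.asarray(v) for k, v in groups.items()}

def em_mvnorm(
    X: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    ridge: float = 1e-8,
) -> EMResult:
    """Fit N(mu, Sigma) by EM to ``X`` (NaN marks missing cells).

    Rows with no observed cell contribute nothing and are dropped.  The
    covariance diagonal is ridge-regularized each M-step to keep restricted
    blocks invertible on near-degenerate data.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DataError("X must be 2-dimensional")
    observed = ~np.isnan(X)
    keep = observed.any(axis=1)
    X, observed = X[keep], observed[keep]
    n, p = X.shape
    if n < 2:
        raise DataError("need at least 2 rows with observed data")

    # init: observed means, diagonal observed variances
    mu = np.nanmean(X, axis=0)
    var = np.nanvar(X, axis=0)
    var[~np.isfinite(var) | (var <= 0)] = 1.0
    sigma = np.diag(var)

    groups = _pattern_groups(observed)
    last_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        ll = 0.0
        for pat, idx in groups.items():
            o = np.asarray(pat, dtype=bool)
            m = ~o
            rows = X[idx]
            xo = rows[:, o]
            mu_o, mu_m = mu[o], mu[m]
            s_oo = sigma[np.ix_(o, o)]
            try:
                s_oo_inv = np.linalg.inv(s_oo)
            except np.linalg.LinAlgError:
                raise DataError(
                    "singular restricted covariance in EM; drop collinear columns"
                ) from None
            resid = xo - mu_o
            # observed-data log-likelihood for this pattern
            sign, logdet = np.linalg.slogdet(s_oo)
            if sign <= 0:
                raise DataError("non-PD restricted covariance in EM; drop collinear columns")
            maha = np.einsum("ij,jk,ik->i", resid, s_oo_inv, resid)
            ll += float(-0.5 * (maha.sum() + len(idx) * (logdet + o.sum() * np.log(2 * np.pi))))
            filled = rows.copy()
            if m.any():
                s_mo = sigma[np.ix_(m, o)]
                beta = s_mo @ s_oo_inv
                cond_mean = mu_m + resid @ beta.T
                filled[:, m] = cond_mean
                cond_cov = sigma[np.ix_(m, m)] - beta @ s_mo.T
                add = np.zeros((p, p))
                add[np.ix_(m, m)] = cond_cov * len(idx)
                sum_xx += add
            sum_x += filled.sum(axis=0)
            sum_xx += filled.T @ filled
        mu = sum_x / n
        sigma = sum_xx / n - np.outer(mu, mu)
        sigma[np.diag_indices_from(sigma)] += ridge
        if abs(ll - last_ll) < tol * max(1.0, abs(ll)):
            converged = True
            break
        last_ll = ll
    return EMResult(mean=mu, cov=sigma, n_iter=it, converged=converged, loglik=ll)


def conditional_fill(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Replace NaNs with conditional expectations under N(mean, cov)."""
    X = np.asarray(X, dtype=float).copy()
    observed = ~np.isnan(X)
    for pat, idx in _pattern_groups(observed).items():
        o = np.asarray(pat, dtype=bool)
        m = ~o
        if not m.any():
            continue
        if not o.any():
            X[np.ix_(idx, np.flatnonzero(m))] = mean[m]
            continue
        s_oo = cov[np.ix_(o, o)]
        beta = cov[np.ix_(m, o)] @ np.linalg.inv(s_oo)
        resid = X[np.ix_(idx, np.flatnonzero(o))] - mean[o]
        X[np.ix_(idx, np.flatnonzero(m))] = mean[m] + resid @ beta.T
    return X
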