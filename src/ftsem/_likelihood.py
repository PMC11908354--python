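"""Numerical kernels for the trio path-model likelihood.

The observed vector per family is x = (F, M, O, ZF, ZM, ZO).  Under the
model x ~ N(mu(theta), Sigma(theta)) i.i.d. across families, so the total
log-likelihood depends on the data only through the sample mean ``m`` and
the divisor-n sample covariance ``S``:

    -2 loglik = n * [ 6 log 2pi + log|Sigma| + tr(Sigma^-1 S)
                      + (m - mu)' Sigma^-1 (m - mu) ]

which makes every objective evaluation O(1) in the sample size.  The
kernels below are numba-jitted when numba is importable and fall back to
plain Python otherwise (same results, slower).

Natural parameter order (length 14), used everywhere in this package:

    0 beta_fe   1 beta_me   2 beta_oe   3 phi      4 mu_g
    5 beta0_f   6 beta0_m   7 beta0_o
    8 sigma2_f  9 sigma2_m 10 sigma2_o 11 sigma_fm 12 sigma_fo 13 sigma_mo

The unconstrained ("free") vector used by the optimizer replaces phi by
log phi and the residual 3x3 by its Cholesky factor with log-diagonal:

    free[3] = log phi;  free[8], free[9], free[10] = log l11, log l22, log l33
    free[11], free[12], free[13] = l21, l31, l32
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


LOG_2PI = float(np.log(2.0 * np.pi))
N_PARAMS = 14

_BIG = 1e300  # returned for infeasible parameter points


@njit(cache=True)
def implied_sigma_mu(th):
    """Model-implied covariance (6x6) and mean (6,) at natural parameters.

    Closed-form path-tracing results; the path-matrix construction in
    :mod:`ftsem.model` is the transparent reference implementation and the
    two are asserted equal in the test suite.
    """
    f = th[0]
    m = th[1]
    o = th[2]
    phi = th[3]
    mu = th[4]
    sigma = np.empty((6, 6))
    # genotype block: Var = phi, parent-offspring covariance phi/2
    sigma[0, 0] = phi
    sigma[1, 1] = phi
    sigma[2, 2] = phi
    sigma[0, 1] = 0.0
    sigma[0, 2] = 0.5 * phi
    sigma[1, 2] = 0.5 * phi
    # genotype-phenotype covariances
    own = phi * (o + 0.5 * (f + m))          # Cov(G, Z) within one person
    half = phi * (0.5 * o + 0.25 * (f + m))  # Cov(O, parental phenotype)
    sigma[0, 3] = own
    sigma[1, 3] = 0.0
    sigma[2, 3] = half
    sigma[0, 4] = 0.0
    sigma[1, 4] = own
    sigma[2, 4] = half
    sigma[0, 5] = phi * (0.5 * o + f)
    sigma[1, 5] = phi * (0.5 * o + m)
    sigma[2, 5] = own
    # phenotype block: common genetic variance + free residual matrix
    gvar = phi * (o * o + f * f + m * m + o * (f + m))
    sigma[3, 3] = gvar + th[8]
    sigma[4, 4] = gvar + th[9]
    sigma[5, 5] = gvar + th[10]
    sigma[3, 4] = th[11]
    sigma[3, 5] = phi * (0.5 * o * o + o * f + 0.25 * o * (f + m)
                         + 0.5 * f * f + 0.5 * f * m) + th[12]
    sigma[4, 5] = phi * (0.5 * o * o + o * m + 0.25 * o * (f + m)
                         + 0.5 * m * m + 0.5 * f * m) + th[13]
    for i in range(6):
        for j in range(i):
            sigma[i, j] = sigma[j, i]
    mu6 = np.empty(6)
    g = (o + f + m) * mu
    mu6[0] = mu
    mu6[1] = mu
    mu6[2] = mu
    mu6[3] = th[5] + g
    mu6[4] = th[6] + g
    mu6[5] = th[7] + g
    return sigma, mu6


@njit(cache=True)
def nll_natural(th, m_obs, s_obs, n):
    """Total negative log-likelihood at natural parameters.

    Returns a large finite penalty when the implied covariance is not
    positive definite, so optimizers can backtrack.
    """
    if not th[3] > 0.0:
        return _BIG
    sigma, mu6 = implied_sigma_mu(th)
    # in-place lower Cholesky of the 6x6
    chol = np.zeros((6, 6))
    for j in range(6):
        d = sigma[j, j]
        for k in range(j):
            d -= chol[j, k] * chol[j, k]
        if d <= 1e-300:
            return _BIG
        chol[j, j] = np.sqrt(d)
        for i in range(j + 1, 6):
            t = sigma[i, j]
            for k in range(j):
                t -= chol[i, k] * chol[j, k]
            chol[i, j] = t / chol[j, j]
    logdet = 0.0
    for j in range(6):
        logdet += np.log(chol[j, j])
    logdet *= 2.0
    # tr(Sigma^-1 S) via two triangular solves per column
    tr = 0.0
    work = np.empty(6)
    for c in range(6):
        for i in range(6):
            t = s_obs[i, c]
            for k in range(i):
                t -= chol[i, k] * work[k]
            work[i] = t / chol[i, i]
        for i in range(5, -1, -1):
            t = work[i]
            for k in range(i + 1, 6):
                t -= chol[k, i] * work[k]
            work[i] = t / chol[i, i]
        tr += work[c]
    # Mahalanobis term for the mean
    for i in range(6):
        work[i] = m_obs[i] - mu6[i]
    quad = 0.0
    for i in range(6):
        t = work[i]
        for k in range(i):
            t -= chol[i, k] * work[k]
        work[i] = t / chol[i, i]
        quad += work[i] * work[i]
    return 0.5 * n * (6.0 * LOG_2PI + logdet + tr + quad)


@njit(cache=True)
def natural_from_free(free):
    """Map the unconstrained optimizer vector to natural parameters."""
    th = np.empty(N_PARAMS)
    th[0] = free[0]
    th[1] = free[1]
    th[2] = free[2]
    th[3] = np.exp(free[3])
    th[4] = free[4]
    th[5] = free[5]
    th[6] = free[6]
    th[7] = free[7]
    l11 = np.exp(free[8])
    l22 = np.exp(free[9])
    l33 = np.exp(free[10])
    l21 = free[11]
    l31 = free[12]
    l32 = free[13]
    th[8] = l11 * l11
    th[9] = l21 * l21 + l22 * l22
    th[10] = l31 * l31 + l32 * l32 + l33 * l33
    th[11] = l11 * l21
    th[12] = l11 * l31
    th[13] = l21 * l31 + l22 * l32
    return th


@njit(cache=True)
def nll_free(free, m_obs, s_obs, n):
    """Negative log-likelihood on the unconstrained scale."""
    for i in (3, 8, 9, 10):
        if free[i] > 40.0 or free[i] < -40.0:
            return _BIG
    return nll_natural(natural_from_free(free), m_obs, s_obs, n)


def free_from_natural(th: np.ndarray) -> np.ndarray:
    """Inverse of :func:`natural_from_free` (Python-side, used once per fit)."""
    th = np.asarray(th, dtype=float)
    resid = np.array([[th[8], th[11], th[12]],
                      [th[11], th[9], th[13]],
                      [th[12], th[13], th[10]]])
    chol = np.linalg.cholesky(resid)
    free = np.empty(N_PARAMS)
    free[:3] = th[:3]
    free[3] = np.log(th[3])
    free[4:8] = th[4:8]
    free[8] = np.log(chol[0, 0])
    free[9] = np.log(chol[1, 1])
    free[10] = np.log(chol[2, 2])
    free[11] = chol[1, 0]
    free[12] = chol[2, 0]
    free[13] = chol[2, 1]
    return free


def observed_information(th: np.ndarray, m_obs: np.ndarray, s_obs: np.ndarray,
                         n: float, rel_step: float = 1e-5) -> np.ndarray:
    """Hessian of the total negative log-likelihood at natural parameters.

    Central finite differences with per-parameter relative step
    ``rel_step * max(1, |theta_i|)``; the optimum is interior so natural-scale
    differentiation is safe.
    """
    th = np.asarray(th, dtype=float)
    k = len(th)
    h = rel_step * np.maximum(np.abs(th), 1.0)
    hess = np.empty((k, k))
    f0 = nll_natural(th, m_obs, s_obs, n)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        fpp = nll_natural(th + ei, m_obs, s_obs, n)
        fmm = nll_natural(th - ei, m_obs, s_obs, n)
        hess[i, i] = (fpp + fmm - 2.0 * f0) / (h[i] * h[i])
        for j in range(i):
            ej = np.zeros(k)
            ej[j] = h[j]
            fpq = nll_natural(th + ei + ej, m_obs, s_obs, n)
            fpm = nll_natural(th + ei - ej, m_obs, s_obs, n)
            fmp = nll_natural(th - ei + ej, m_obs, s_obs, n)
            fmq = nll_natural(th - ei - ej, m_obs, s_obs, n)
            hess[i, j] = hess[j, i] = (fpq - fpm - fmp + fmq) / (4 * h[i] * h[j])
    return hess
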