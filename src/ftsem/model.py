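"""Trio structural-equation model (FT-SEM) for one SNP.

The model treats the six observed variables of a family trio --- genotype
dosages F, M, O and phenotypes ZF, ZM, ZO --- as jointly multivariate
normal with a mean and covariance implied by a path diagram in which

* the four grandparental genotypes are latent, each with variance ``phi``
  and mean ``mu_g``;
* every parent-to-child genotype path coefficient is fixed at 0.5
  (Mendelian inheritance) with a segregation residual of variance
  ``0.5 * phi``, so every genotype variable (latent or observed) has total
  variance ``phi``;
* each person's phenotype loads on their own genotype (``beta_oe``), their
  father's genotype (``beta_fe``) and their mother's genotype (``beta_me``)
  --- the same three coefficients in both generations --- plus an intercept
  and a residual; the three phenotype residuals have a free symmetric
  positive-definite 3x3 covariance that absorbs shared environment and
  unobserved confounders.

Fitting maximizes the 6-variate normal likelihood over the 14 free
parameters; standard errors come from the inverse observed information and
each genetic effect is tested with a Wald z statistic.  Conditioning on
the parental genotypes is what removes the confounding that dynastic
effects and residual population stratification induce in population GWAS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import optimize, stats

from . import _likelihood as lk
from .data import TrioDataset

PARAM_NAMES = (
    "beta_fe", "beta_me", "beta_oe", "phi", "mu_g",
    "beta0_f", "beta0_m", "beta0_o",
    "sigma2_f", "sigma2_m", "sigma2_o",
    "sigma_fm", "sigma_fo", "sigma_mo",
)

EFFECT_INDEX = {"paternal": 0, "maternal": 1, "offspring": 2}

MIN_TRIOS = 50


class EffectEstimate(NamedTuple):
    """One genetic-effect estimate with its Wald test."""

    beta: float
    se: float
    z: float
    p: float


@dataclass
class FTSEMParams:
    """Full parameter vector of the trio path model (natural scale)."""

    beta_fe: float = 0.0
    beta_me: float = 0.0
    beta_oe: float = 0.0
    phi: float = 0.5
    mu_g: float = 1.0
    beta0_f: float = 0.0
    beta0_m: float = 0.0
    beta0_o: float = 0.0
    sigma2_f: float = 1.0
    sigma2_m: float = 1.0
    sigma2_o: float = 1.0
    sigma_fm: float = 0.0
    sigma_fo: float = 0.0
    sigma_mo: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "FTSEMParams":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters")
        return cls(**dict(zip(PARAM_NAMES, arr)))

    @property
    def resid_cov(self) -> np.ndarray:
        """Residual covariance of (ZF, ZM, ZO)."""
        return np.array([
            [self.sigma2_f, self.sigma_fm, self.sigma_fo],
            [self.sigma_fm, self.sigma2_m, self.sigma_mo],
            [self.sigma_fo, self.sigma_mo, self.sigma2_o],
        ])

    def validate(self) -> "FTSEMParams":
        if not self.phi > 0:
            raise ValueError("phi must be positive")
        eig = np.linalg.eigvalsh(self.resid_cov)
        if eig.min() <= 0:
            raise ValueError("residual covariance must be positive definite")
        return self


def implied_moments(params: FTSEMParams) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean (6,) and covariance (6, 6) of (F, M, O, ZF, ZM, ZO).

    Built transparently as ``A K A'`` over the latent vector
    (GF1, GM1, GF2, GM2, sF, sM, sO, eF, eM, eO), where the s terms are the
    Mendelian segregation residuals (variance ``phi / 2``) and the e terms
    the phenotype residuals.  A faster closed-form twin lives in
    :mod:`ftsem._likelihood`; the two are tested for exact agreement.
    """
    params.validate()
    b = params
    a = np.zeros((6, 10))
    a[0, [0, 1, 4]] = 0.5, 0.5, 1.0                       # F
    a[1, [2, 3, 5]] = 0.5, 0.5, 1.0                       # M
    a[2] = 0.5 * a[0] + 0.5 * a[1]
    a[2, 6] = 1.0                                         # O
    a[3] = b.beta_oe * a[0]                               # ZF
    a[3, 0] += b.beta_fe
    a[3, 1] += b.beta_me
    a[3, 7] = 1.0
    a[4] = b.beta_oe * a[1]                               # ZM
    a[4, 2] += b.beta_fe
    a[4, 3] += b.beta_me
    a[4, 8] = 1.0
    a[5] = b.beta_oe * a[2] + b.beta_fe * a[0] + b.beta_me * a[1]  # ZO
    a[5, 9] = 1.0
    k = np.zeros((10, 10))
    np.fill_diagonal(k[:4, :4], b.phi)
    np.fill_diagonal(k[4:7, 4:7], 0.5 * b.phi)
    k[7:, 7:] = b.resid_cov
    cov = a @ k @ a.T
    mean_latent = np.zeros(10)
    mean_latent[:4] = b.mu_g
    mean = a @ mean_latent + np.array(
        [0, 0, 0, b.beta0_f, b.beta0_m, b.beta0_o], dtype=float)
    return mean, cov


def wald_test(estimate: float, se: float) -> tuple[float, float]:
    """Wald z statistic and two-sided standard-normal p-value."""
    if not se > 0:
        raise ValueError("standard error must be positive")
    z = estimate / se
    return z, 2.0 * stats.norm.sf(abs(z))


def start_values(data: TrioDataset) -> FTSEMParams:
    """Moment-based starting values (see :meth:`FTSEM.start_params`)."""
    return FTSEM(data).start_params()


class FTSEM:
    """Maximum-likelihood trio SEM for a single SNP.

    Construct from a :class:`~ftsem.data.TrioDataset` (incomplete trios are
    listwise-deleted) or from precomputed moments via :meth:`from_moments`.
    """

    def __init__(self, data: TrioDataset):
        data = data.complete_cases()
        if data.n_trios < MIN_TRIOS:
            raise ValueError(
                f"need at least {MIN_TRIOS} complete trios, "
                f"got {data.n_trios}")
        self.data = data
        self.nobs = data.n_trios
        self._mean, self._cov = data.moments()

    @classmethod
    def from_moments(cls, mean, cov, nobs: int) -> "FTSEM":
        """Build a model directly from a mean vector and covariance matrix.

        Useful for population-limit checks and for re-fitting published
        moment summaries; ``nobs`` scales the likelihood.
        """
        obj = cls.__new__(cls)
        obj.data = None
        obj.nobs = int(nobs)
        obj._mean = np.asarray(mean, dtype=float).copy()
        obj._cov = np.asarray(cov, dtype=float).copy()
        if obj._mean.shape != (6,) or obj._cov.shape != (6, 6):
            raise ValueError("moments must be a length-6 mean and 6x6 cov")
        return obj

    # -- likelihood ---------------------------------------------------------

    def loglik(self, params: FTSEMParams) -> float:
        """Log-likelihood of the data at ``params``."""
        val = lk.nll_natural(params.to_array(), self._mean, self._cov,
                             float(self.nobs))
        if val >= lk._BIG:
            raise ValueError("implied covariance is singular at params")
        return -float(val)

    def start_params(self) -> FTSEMParams:
        """Moment-based initialization.

        ``phi`` and ``mu_g`` pool the three genotype variances/means; the
        genetic effects solve the (O, F, M) -> ZO normal equations (the
        lm_parent estimator); intercepts match the implied means; the
        residual covariance is the phenotype covariance minus the implied
        genetic part, eigenvalue-clipped to positive definiteness.
        """
        m, s = self._mean, self._cov
        phi = float(np.mean([s[0, 0], s[1, 1], s[2, 2]]))
        if phi < 1e-10:
            raise ValueError("degenerate genotype: SNP is monomorphic")
        mu = float(np.mean(m[:3]))
        pred = [2, 0, 1]  # O, F, M
        sxx = s[np.ix_(pred, pred)]
        sxy = s[pred, 5]
        try:
            beta_oe, beta_fe, beta_me = np.linalg.solve(sxx, sxy)
        except np.linalg.LinAlgError:
            beta_oe, beta_fe, beta_me = np.linalg.lstsq(
                sxx, sxy, rcond=None)[0]
        gsum = (beta_oe + beta_fe + beta_me) * mu
        skeleton = FTSEMParams(
            beta_fe=beta_fe, beta_me=beta_me, beta_oe=beta_oe, phi=phi,
            mu_g=mu, beta0_f=m[3] - gsum, beta0_m=m[4] - gsum,
            beta0_o=m[5] - gsum,
            sigma2_f=1.0, sigma2_m=1.0, sigma2_o=1.0)
        _, implied = implied_moments(FTSEMParams(
            beta_fe=beta_fe, beta_me=beta_me, beta_oe=beta_oe, phi=phi,
            mu_g=mu, sigma2_f=1e-12, sigma2_m=1e-12, sigma2_o=1e-12))
        resid = s[3:, 3:] - implied[3:, 3:]
        resid = 0.5 * (resid + resid.T)
        floor = 1e-3 * float(np.mean(np.diag(s[3:, 3:])) + 1e-12)
        w, v = np.linalg.eigh(resid)
        resid = (v * np.maximum(w, floor)) @ v.T
        skeleton.sigma2_f = resid[0, 0]
        skeleton.sigma2_m = resid[1, 1]
        skeleton.sigma2_o = resid[2, 2]
        skeleton.sigma_fm = resid[0, 1]
        skeleton.sigma_fo = resid[0, 2]
        skeleton.sigma_mo = resid[1, 2]
        return skeleton

    # -- fitting ------------------------------------------------------------

    def fit(self, start_params: FTSEMParams | None = None,
            gtol: float = 1e-7, maxiter: int = 500,
            n_restarts: int = 3) -> "FTSEMResults":
        """Maximize the likelihood by quasi-Newton (BFGS) on the free scale.

        ``phi`` is optimized as log phi and the residual 3x3 through its
        Cholesky factor, so every iterate is feasible.  On failure the start
        is jittered (deterministically) up to ``n_restarts`` times and the
        best optimum is kept.  The returned results carry standard errors
        from the inverse observed information at the optimum.
        """
        if start_params is None:
            start_params = self.start_params()
        free0 = lk.free_from_natural(start_params.to_array())
        m, s, n = self._mean, self._cov, float(self.nobs)

        def objective(free):
            return lk.nll_free(free, m, s, n) / n

        best = None
        n_iter_total = 0
        for attempt in range(n_restarts + 1):
            if attempt == 0:
                free_init = free0
            else:
                jitter_rng = np.random.default_rng(1000 + attempt)
                free_init = free0 + 0.1 * jitter_rng.standard_normal(
                    lk.N_PARAMS)
            res = optimize.minimize(
                objective, free_init, method="BFGS",
                options={"gtol": gtol, "maxiter": maxiter})
            n_iter_total += res.nit
            if best is None or res.fun < best.fun - 1e-12:
                best = res
            if best.success:
                break
        converged = bool(best.success) or \
            float(np.max(np.abs(best.jac))) < 100 * gtol
        theta = lk.natural_from_free(best.x)
        llf = -float(best.fun) * n

        hess = lk.observed_information(theta, m, s, n)
        bse = np.full(lk.N_PARAMS, np.nan)
        vcov = np.full((lk.N_PARAMS, lk.N_PARAMS), np.nan)
        try:
            vcov = np.linalg.inv(hess)
            diag = np.diag(vcov)
            if np.all(diag > 0):
                bse = np.sqrt(diag)
            else:
                converged = False
        except np.linalg.LinAlgError:
            converged = False
        if not converged:
            warnings.warn("FT-SEM fit did not converge cleanly",
                          RuntimeWarning, stacklevel=2)
        return FTSEMResults(
            model=self, params=FTSEMParams.from_array(theta),
            params_array=theta, bse=bse, vcov=vcov, llf=llf,
            converged=converged, n_iter=n_iter_total, nobs=self.nobs)


@dataclass
class FTSEMResults:
    """Estimates, uncertainties and diagnostics from :meth:`FTSEM.fit`."""

    model: FTSEM
    params: FTSEMParams
    params_array: np.ndarray
    bse: np.ndarray
    vcov: np.ndarray
    llf: float
    converged: bool
    n_iter: int
    nobs: int
    method_tag: str = "FTSEM"

    @property
    def effects(self) -> dict[str, EffectEstimate]:
        """Wald estimates for the paternal, maternal and offspring effects."""
        out = {}
        for name, i in EFFECT_INDEX.items():
            beta = float(self.params_array[i])
            se = float(self.bse[i])
            if np.isfinite(se) and se > 0:
                z, p = wald_test(beta, se)
            else:
                z, p = np.nan, np.nan
            out[name] = EffectEstimate(beta, se, z, p)
        return out

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Normal-theory (1 - alpha) intervals, one row per parameter."""
        q = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params_array - q * self.bse,
                                self.params_array + q * self.bse])

    def summary(self) -> str:
        lines = [
            "FT-SEM family-trio model (maximum likelihood)",
            f"  trios: {self.nobs}    log-likelihood: {self.llf:.3f}    "
            f"converged: {self.converged} ({self.n_iter} iterations)",
            "",
            f"  {'parameter':<10}{'estimate':>12}{'std err':>12}"
            f"{'z':>10}{'P>|z|':>12}",
        ]
        effect_rows = {v: k for k, v in EFFECT_INDEX.items()}
        for i, name in enumerate(PARAM_NAMES):
            est, se = self.params_array[i], self.bse[i]
            if i in effect_rows and np.isfinite(se) and se > 0:
                z, p = wald_test(est, se)
                lines.append(f"  {name:<10}{est:>12.4f}{se:>12.4f}"
                             f"{z:>10.3f}{p:>12.3g}")
            else:
                lines.append(f"  {name:<10}{est:>12.4f}{se:>12.4f}"
                             f"{'':>10}{'':>12}")
        return "\n".join(lines)


def fit_ftsem(data: TrioDataset, **fit_kwargs) -> FTSEMResults:
    """Convenience one-call fit: ``FTSEM(data).fit(**fit_kwargs)``."""
    return FTSEM(data).fit(**fit_kwargs)
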