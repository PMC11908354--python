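"""Linear-model comparison estimators for trio GWAS.

Two ordinary-least-squares baselines accompany the trio SEM:

``lm_parent``
    offspring phenotype regressed on the offspring's genotype with both
    parental genotypes as covariates.  Conditioning on (F, M) blocks the
    dynastic and stratification confounding paths, so the offspring
    coefficient is unbiased, at the cost of using the parental phenotypes
    not at all.
``lm``
    offspring phenotype on the offspring genotype alone --- the standard
    population GWAS regression, biased whenever parental genotypes
    confound the association.

Both return classical (non-robust) standard errors and t-based p-values,
the conventional linear-model output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import TrioDataset
from .model import EffectEstimate

_EFFECT_OF_TERM = {"O": "offspring", "F": "paternal", "M": "maternal"}


@dataclass
class OLSResult:
    """Coefficient table and diagnostics for one baseline fit."""

    table: pd.DataFrame  # index: term; columns: beta, se, stat, p
    resid_var: float
    n_used: int
    method_tag: str
    converged: bool = True

    @property
    def effects(self) -> dict[str, EffectEstimate]:
        """Genetic-effect rows keyed offspring/paternal/maternal."""
        out = {}
        for term, name in _EFFECT_OF_TERM.items():
            if term in self.table.index:
                row = self.table.loc[term]
                out[name] = EffectEstimate(float(row["beta"]),
                                           float(row["se"]),
                                           float(row["stat"]),
                                           float(row["p"]))
        return out

    def summary(self) -> str:
        lines = [f"{self.method_tag} (OLS)   n={self.n_used}   "
                 f"residual variance={self.resid_var:.4f}", ""]
        lines.append(self.table.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def _design(data: TrioDataset, terms: list[str],
            covariates: pd.DataFrame | None) -> tuple[pd.DataFrame, np.ndarray]:
    cols = {t: getattr(data, t) for t in terms}
    x = pd.DataFrame(cols)
    if covariates is None:
        if isinstance(data.covariates, pd.DataFrame):
            covariates = data.covariates
        elif isinstance(data.covariates, dict):
            covariates = data.covariates.get("O")
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        x = pd.concat([x, covariates], axis=1)
    y = np.asarray(data.ZO, dtype=float)
    mask = np.isfinite(y) & np.isfinite(x.to_numpy(dtype=float)).all(axis=1)
    return sm.add_constant(x[mask]), y[mask]


def _fit_ols(data: TrioDataset, terms: list[str],
             covariates: pd.DataFrame | None, tag: str,
             min_n: int = 5) -> OLSResult:
    x, y = _design(data, terms, covariates)
    if len(y) < min_n:
        raise ValueError(f"need at least {min_n} complete trios, got {len(y)}")
    xm = x.to_numpy(dtype=float)
    if np.linalg.matrix_rank(xm) < xm.shape[1]:
        raise ValueError("design matrix is rank deficient "
                         "(monomorphic SNP or collinear covariates)")
    res = sm.OLS(y, x).fit()
    table = pd.DataFrame({
        "beta": res.params, "se": res.bse,
        "stat": res.tvalues, "p": res.pvalues,
    })
    return OLSResult(table=table, resid_var=float(res.mse_resid),
                     n_used=int(res.nobs), method_tag=tag)


def fit_lm_parent(data: TrioDataset,
                  covariates: pd.DataFrame | None = None) -> OLSResult:
    """OLS of the offspring phenotype on (O, F, M) plus covariates.

    The O coefficient estimates the offspring effect, F the paternal and M
    the maternal effect.
    """
    return _fit_ols(data, ["O", "F", "M"], covariates, "LM_PARENT")


def fit_lm(data: TrioDataset,
           covariates: pd.DataFrame | None = None) -> OLSResult:
    """OLS of the offspring phenotype on the offspring genotype alone.

    On real data this estimator is usually run on unrelated individuals;
    here it sees the offspring of the trios, which reproduces its
    confounded probability limit under dynastic effects or stratification.
    """
    return _fit_ols(data, ["O"], covariates, "LM")
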