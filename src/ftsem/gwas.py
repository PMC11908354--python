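"""Run trio estimators across many SNPs and emit GWAS summary statistics.

This module orchestrates the per-SNP estimators (trio SEM, lm_parent, lm)
over an assembled trio panel, applies the rank-based inverse normal
transform to phenotypes when requested, and implements the two-tier
significance rule used to screen loci across multiple phenotypes.
Per-SNP failures (monomorphic sites, non-convergence) become flagged
records rather than exceptions, so a long run always completes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import baselines, model
from .data import TrioDataset

logger = logging.getLogger(__name__)

METHODS = ("ftsem", "lm_parent", "lm")


@dataclass
class SummaryStatRecord:
    """One GWAS summary row: one SNP, one effect type, one method."""

    snp_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float
    effect_type: str  # offspring | paternal | maternal
    beta: float
    se: float
    p: float
    n: int
    method_tag: str
    note: str = ""


def inverse_normal_transform(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset 3/8, average ranks).

    Maps value i to the standard-normal quantile of
    ``(r_i - offset) / (n - 2 * offset + 1)``; with the Blom offset the
    denominator is ``n + 1/4``.  Ties receive their average rank, so the
    transform is monotone (strictly so on distinct values).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 3:
        raise ValueError("need a 1-d array of at least 3 values")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if np.ptp(values) == 0:
        raise ValueError("all values identical; transform undefined")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - offset) / (len(values) - 2 * offset + 1))


def residualize_phenotypes(data: TrioDataset) -> TrioDataset:
    """Replace each role's phenotype by its least-squares covariate residual.

    Used before SEM fitting when covariates are present, keeping the
    six-variable model intact; covariates may be a dict keyed by role
    ("F"/"M"/"O") or a single offspring frame.
    """
    cov = data.covariates
    if cov is None:
        return data
    if isinstance(cov, pd.DataFrame):
        cov = {"O": cov}
    out = {}
    for role, pheno in (("F", "ZF"), ("M", "ZM"), ("O", "ZO")):
        z = np.asarray(getattr(data, pheno), dtype=float)
        frame = cov.get(role)
        if frame is None:
            out[pheno] = z
            continue
        x = np.column_stack([np.ones(len(z)), frame.to_numpy(dtype=float)])
        coef, *_ = np.linalg.lstsq(x, z, rcond=None)
        out[pheno] = z - x @ coef
    return TrioDataset(data.F, data.M, data.O,
                       out["ZF"], out["ZM"], out["ZO"],
                       hidden=data.hidden, family_ids=data.family_ids)


def _records_for_fit(result, meta: dict, n: int) -> list[SummaryStatRecord]:
    records = []
    for effect, est in result.effects.items():
        records.append(SummaryStatRecord(
            snp_id=meta["snp"], chromosome=str(meta.get("chr", "NA")),
            position=int(meta.get("pos", 0)),
            effect_allele=meta.get("ea", "A"),
            other_allele=meta.get("oa", "G"),
            eaf=float(meta.get("eaf", np.nan)),
            effect_type=effect, beta=est.beta, se=est.se, p=est.p, n=n,
            method_tag=result.method_tag,
            note="" if getattr(result, "converged", True)
            else "non_converged"))
    return records


def _failure_record(meta: dict, method: str, reason: str,
                    n: int) -> SummaryStatRecord:
    return SummaryStatRecord(
        snp_id=meta["snp"], chromosome=str(meta.get("chr", "NA")),
        position=int(meta.get("pos", 0)), effect_allele=meta.get("ea", "A"),
        other_allele=meta.get("oa", "G"),
        eaf=float(meta.get("eaf", np.nan)), effect_type="offspring",
        beta=np.nan, se=np.nan, p=np.nan, n=n,
        method_tag=method.upper(), note=reason)


def fit_snp(data: TrioDataset, method: str):
    """Fit one estimator to one SNP's trio data."""
    if method == "ftsem":
        return model.FTSEM(residualize_phenotypes(data)).fit()
    if method == "lm_parent":
        return baselines.fit_lm_parent(data)
    if method == "lm":
        return baselines.fit_lm(data)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def run_gwas(panel, method: str = "ftsem",
             int_transform: bool = False) -> list[SummaryStatRecord]:
    """Run one estimator over every SNP of an assembled trio panel.

    ``panel`` is a :class:`ftsem.io.TrioPanel` (or any object exposing
    ``snps``, ``dataset(j)`` and ``eaf(j)``).  The trio SEM and lm_parent
    emit three records per SNP (offspring, paternal, maternal); lm emits
    one.  Failures are returned as flagged records with missing beta/se.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    records: list[SummaryStatRecord] = []
    if int_transform:
        panel = panel.int_transformed()
    for j in range(len(panel.snps)):
        meta = panel.snps.iloc[j].to_dict()
        meta["eaf"] = panel.eaf(j)
        try:
            data = panel.dataset(j)
            result = fit_snp(data, method)
            records.extend(_records_for_fit(result, meta, data.n_trios))
        except Exception as exc:  # per-SNP failures are data, not crashes
            logger.warning("SNP %s (%s): %s", meta.get("snp"), method, exc)
            records.append(_failure_record(meta, method, str(exc),
                                           n=0))
    return records


def significance_select(p_matrix: pd.DataFrame,
                        primary_threshold: float = 1e-5,
                        secondary_threshold: float = 1e-3,
                        ) -> list[tuple[object, object]]:
    """Two-tier screening across phenotypes.

    A (SNP, phenotype) pair is selected when its p-value is strictly below
    the primary threshold and at least one *other* phenotype at the same
    SNP is strictly below the secondary threshold.  ``p_matrix`` has one
    row per SNP and one column per phenotype.
    """
    if p_matrix.shape[1] < 2:
        raise ValueError("need at least two phenotype columns")
    for thr in (primary_threshold, secondary_threshold):
        if not 0.0 < thr < 1.0:
            raise ValueError("thresholds must be in (0, 1)")
    pvals = p_matrix.to_numpy(dtype=float)
    selected = []
    for i, snp in enumerate(p_matrix.index):
        for k, pheno in enumerate(p_matrix.columns):
            if pvals[i, k] < primary_threshold:
                others = np.delete(pvals[i], k)
                if np.nanmin(others) < secondary_threshold:
                    selected.append((snp, pheno))
    return selected
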