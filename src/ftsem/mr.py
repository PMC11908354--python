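"""Two-sample Mendelian randomization on harmonized summary statistics.

Implements the ratio (Wald) estimator, fixed-effect inverse-variance
weighting (IVW), MR-Egger regression, and the weighted-median and
weighted-mode sensitivity estimators, together with allele harmonization
and the F-statistic weak-instrument filter.  Instruments are assumed to be
independent (pre-clumped); no LD-aware correction is applied and the
module says so loudly when run from the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

Z95 = float(stats.norm.ppf(0.975))

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class NoInstrumentsError(ValueError):
    """Raised when filtering or harmonization leaves no usable instrument."""


@dataclass
class HarmonizedInstrument:
    """SNP-exposure and SNP-outcome effects aligned to one effect allele."""

    snp_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float

    def __post_init__(self) -> None:
        if not (self.se_x > 0 and self.se_y > 0):
            raise ValueError("standard errors must be positive")

    @property
    def f_statistic(self) -> float:
        """Single-SNP instrument strength (beta_x / se_x)^2."""
        return (self.beta_x / self.se_x) ** 2


@dataclass
class MRResult:
    """Causal-effect estimate from one MR method."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None


def _result(method: str, estimate: float, se: float, n_snps: int,
            **extra) -> MRResult:
    z = estimate / se
    return MRResult(method=method, estimate=float(estimate), se=float(se),
                    ci_low=float(estimate - Z95 * se),
                    ci_high=float(estimate + Z95 * se),
                    p=float(2 * stats.norm.sf(abs(z))), n_snps=n_snps,
                    **extra)


# -- instrument preparation -------------------------------------------------

def f_statistic_filter(instruments: list[HarmonizedInstrument],
                       f_min: float = 10.0) -> list[HarmonizedInstrument]:
    """Drop weak instruments with single-SNP F below ``f_min``."""
    if not instruments:
        raise NoInstrumentsError("no instruments supplied")
    kept = [inst for inst in instruments if inst.f_statistic >= f_min]
    if not kept:
        raise NoInstrumentsError(
            f"all {len(instruments)} instruments have F < {f_min}")
    return kept


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea.upper()) == oa.upper()


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              ) -> tuple[list[HarmonizedInstrument], dict[str, int]]:
    """Align outcome effects to the exposure's effect allele per SNP.

    Both frames need columns snp, ea, oa, beta, se.  Outcome betas are
    sign-flipped when its effect allele is the exposure's other allele
    (directly or on the opposite strand); strand-ambiguous palindromic
    SNPs (A/T, C/G) and allele-incompatible SNPs are dropped, with a
    per-reason count returned.
    """
    merged = exposure.merge(outcome, on="snp", suffixes=("_x", "_y"))
    if merged.empty:
        raise NoInstrumentsError("no SNPs shared between exposure and "
                                 "outcome summary statistics")
    instruments, reasons = [], {}

    def drop(reason):
        reasons[reason] = reasons.get(reason, 0) + 1

    for _, row in merged.iterrows():
        ea_x, oa_x = str(row["ea_x"]).upper(), str(row["oa_x"]).upper()
        ea_y, oa_y = str(row["ea_y"]).upper(), str(row["oa_y"]).upper()
        if _is_palindromic(ea_x, oa_x) or _is_palindromic(ea_y, oa_y):
            drop("palindromic")
            continue
        flip_y = None
        if (ea_y, oa_y) == (ea_x, oa_x):
            flip_y = False
        elif (ea_y, oa_y) == (oa_x, ea_x):
            flip_y = True
        else:
            comp = (_COMPLEMENT.get(ea_y, "?"), _COMPLEMENT.get(oa_y, "?"))
            if comp == (ea_x, oa_x):
                flip_y = False
            elif comp == (oa_x, ea_x):
                flip_y = True
        if flip_y is None:
            drop("incompatible_alleles")
            continue
        beta_y = -row["beta_y"] if flip_y else row["beta_y"]
        instruments.append(HarmonizedInstrument(
            snp_id=str(row["snp"]), beta_x=float(row["beta_x"]),
            se_x=float(row["se_x"]), beta_y=float(beta_y),
            se_y=float(row["se_y"])))
    if not instruments:
        raise NoInstrumentsError(
            f"harmonization left no instruments (dropped: {reasons})")
    return instruments, reasons


# -- estimators -------------------------------------------------------------

def ratio_estimate(inst: HarmonizedInstrument,
                   second_order: bool = False) -> MRResult:
    """Single-instrument Wald ratio ``beta_y / beta_x``.

    The default standard error is the first-order delta approximation
    ``se_y / |beta_x|``; ``second_order=True`` adds the term propagating
    the exposure uncertainty.
    """
    if inst.beta_x == 0:
        raise ValueError("ratio undefined for beta_x = 0")
    estimate = inst.beta_y / inst.beta_x
    var = (inst.se_y / inst.beta_x) ** 2
    if second_order:
        var += inst.beta_y ** 2 * inst.se_x ** 2 / inst.beta_x ** 4
    return _result("RATIO", estimate, np.sqrt(var), n_snps=1)


def ivw(instruments: list[HarmonizedInstrument]) -> MRResult:
    """Fixed-effect inverse-variance-weighted estimate.

    Weighted least squares of beta_y on beta_x through the origin with
    weights ``1 / se_y^2``; with a single instrument this reduces exactly
    to the ratio estimate.
    """
    if not instruments:
        raise NoInstrumentsError("no instruments supplied")
    bx = np.array([i.beta_x for i in instruments])
    by = np.array([i.beta_y for i in instruments])
    w = np.array([1.0 / i.se_y ** 2 for i in instruments])
    denom = float(np.sum(w * bx * bx))
    if denom <= 0:
        raise ValueError("all instruments have beta_x = 0")
    estimate = float(np.sum(w * bx * by)) / denom
    se = 1.0 / np.sqrt(denom)
    return _result("IVW", estimate, se, n_snps=len(instruments))


def mr_egger(instruments: list[HarmonizedInstrument]) -> MRResult:
    """MR-Egger: weighted regression of beta_y on beta_x with an intercept.

    The slope estimates the causal effect; the intercept (with its p-value)
    tests directional horizontal pleiotropy.  Weights are ``1 / se_y^2``
    with multiplicative residual scaling, the conventional Egger fit.
    """
    if len(instruments) < 3:
        raise NoInstrumentsError("MR-Egger needs at least 3 instruments")
    bx = np.array([i.beta_x for i in instruments])
    by = np.array([i.beta_y for i in instruments])
    w = np.array([1.0 / i.se_y ** 2 for i in instruments])
    if np.ptp(bx) == 0:
        raise ValueError("degenerate design: all beta_x identical")
    design = sm.add_constant(bx)
    fit = sm.WLS(by, design, weights=w).fit()
    return _result("EGGER", float(fit.params[1]), float(fit.bse[1]),
                   n_snps=len(instruments),
                   intercept=float(fit.params[0]),
                   intercept_se=float(fit.bse[0]),
                   intercept_p=float(fit.pvalues[0]))


def _ratio_set(instruments):
    ratios = np.array([i.beta_y / i.beta_x for i in instruments])
    se_ratio = np.array([i.se_y / abs(i.beta_x) for i in instruments])
    return ratios, 1.0 / se_ratio ** 2


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    b, w = ratios[order], weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if cum[0] >= 0.5:
        return float(b[0])
    below = int(np.max(np.flatnonzero(cum < 0.5)))
    if below == len(b) - 1:
        return float(b[-1])
    frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
    return float(b[below] + frac * (b[below + 1] - b[below]))


def _weighted_mode(ratios: np.ndarray, weights: np.ndarray,
                   bandwidth_factor: float) -> float:
    if np.ptp(ratios) == 0:
        return float(ratios[0])
    mad = np.median(np.abs(ratios - np.median(ratios))) * 1.4826
    spread = min(np.std(ratios, ddof=1), mad) if mad > 0 \
        else np.std(ratios, ddof=1)
    h = bandwidth_factor * 0.9 * spread * len(ratios) ** (-1 / 5)
    if h <= 0:
        return float(np.median(ratios))
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    density = (weights[None, :]
               * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)
               ).sum(axis=1)
    return float(grid[np.argmax(density)])


def _bootstrap_se(point_fn, instruments, n_boot: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    bx = np.array([i.beta_x for i in instruments])
    by = np.array([i.beta_y for i in instruments])
    sx = np.array([i.se_x for i in instruments])
    sy = np.array([i.se_y for i in instruments])
    draws = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        bx_b[bx_b == 0] = 1e-12
        by_b = rng.normal(by, sy)
        ratios = by_b / bx_b
        weights = (np.abs(bx_b) / sy) ** 2
        draws[b] = point_fn(ratios, weights)
    return float(np.std(draws, ddof=1))


def weighted_median(instruments: list[HarmonizedInstrument],
                    n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted median of the per-SNP ratio estimates.

    Inverse-variance weights use the first-order ratio variance; the 50th
    weighted percentile is found by the standard interpolation rule.  The
    standard error comes from a seeded parametric bootstrap.
    """
    if len(instruments) < 3:
        raise NoInstrumentsError("weighted median needs >= 3 instruments")
    ratios, weights = _ratio_set(instruments)
    estimate = _weighted_median(ratios, weights)
    se = _bootstrap_se(_weighted_median, instruments, n_boot, seed)
    return _result("WMEDIAN", estimate, se, n_snps=len(instruments))


def weighted_mode(instruments: list[HarmonizedInstrument],
                  bandwidth_factor: float = 1.0, n_boot: int = 1000,
                  seed: int = 0) -> MRResult:
    """Mode of a weighted Gaussian kernel density over the ratio estimates.

    The bandwidth is ``factor * 0.9 * min(SD, 1.4826 MAD) * n^(-1/5)``;
    the standard error comes from a seeded parametric bootstrap.
    """
    if len(instruments) < 3:
        raise NoInstrumentsError("weighted mode needs >= 3 instruments")
    ratios, weights = _ratio_set(instruments)
    estimate = _weighted_mode(ratios, weights, bandwidth_factor)
    se = _bootstrap_se(
        lambda r, w: _weighted_mode(r, w, bandwidth_factor),
        instruments, n_boot, seed)
    return _result("WMODE", estimate, se, n_snps=len(instruments))


_METHOD_FNS = {"ratio": None, "ivw": ivw, "egger": mr_egger,
               "wmedian": weighted_median, "wmode": weighted_mode}


def run_mr(instruments: list[HarmonizedInstrument],
           methods: tuple[str, ...] = ("ivw", "egger", "wmedian", "wmode"),
           ) -> list[MRResult]:
    """Run a set of MR methods on one instrument list."""
    results = []
    for name in methods:
        if name == "ratio":
            if len(instruments) != 1:
                raise ValueError("ratio method requires exactly 1 instrument")
            results.append(ratio_estimate(instruments[0]))
            continue
        if name not in _METHOD_FNS:
            raise ValueError(f"unknown MR method {name!r}")
        try:
            results.append(_METHOD_FNS[name](instruments))
        except NoInstrumentsError as exc:
            logger.warning("%s skipped: %s", name, exc)
    return results


def results_to_frame(results: list[MRResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "method": r.method, "estimate": r.estimate, "se": r.se,
        "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p,
        "n_snps": r.n_snps, "egger_intercept": r.intercept,
        "egger_intercept_p": r.intercept_p} for r in results])
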