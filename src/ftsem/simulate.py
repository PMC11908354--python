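"""Synthetic family-trio generator for the GWAS and MR simulation studies.

Trios are built genetically from the founders down: the four grandparental
genotypes are drawn under Hardy-Weinberg equilibrium at the chosen allele
frequency, the parents (F, M) are formed by Mendelian transmission from
their respective grandparental pairs, and the offspring (O) by transmission
from (F, M).  Phenotypes follow the linear trio model: each person's
phenotype loads on their own genotype, their father's and their mother's
genotype, plus an independent standard-normal confounder per person, an
optional shared stratification variable L (RPS scenario only), and a
trivariate-normal residual with common variance ``1 - PVEsum`` and
exchangeable correlation ``rho``.

Effect sizes are specified through the proportion of phenotypic variance
explained (PVE): ``beta = sqrt(PVE / Var(predictor))``, with
``Var(SNP) = 2 p (1 - p)`` evaluated at the (pooled) allele frequency.

Three confounding scenarios are supported:

``DE``
    dynastic effects: one homogeneous population, nonzero parental effects.
``RPS``
    residual population stratification: a 50/50 mixture of two
    subpopulations with different allele frequencies sharing a trio-level
    variable L that also shifts the phenotype; no parental effects.
``NONE``
    neither source of bias.

Random draws consume a single :class:`numpy.random.Generator` in a fixed,
documented order (subpopulation, grandparental genotypes GF1, GM1, GF2,
GM2, transmissions for F, M, O, confounders UF, UM, UO, residuals), so a
seed fully determines a dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .data import TrioDataset
from .model import FTSEMParams

SCENARIOS = ("DE", "RPS", "NONE")
L_CODINGS = ("levels_1_2", "standardized")


def genotype_variance(maf: float) -> float:
    """Variance ``2 p (1 - p)`` of an additive dosage under HWE."""
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {maf}")
    return 2.0 * maf * (1.0 - maf)


def effect_from_pve(pve: float, var_predictor: float) -> float:
    """Effect size ``sqrt(PVE / Var(predictor))``; zero when PVE is zero."""
    if pve < 0:
        raise ValueError("PVE must be nonnegative")
    if pve == 0:
        return 0.0
    if not var_predictor > 0:
        raise ValueError("predictor variance must be positive")
    return math.sqrt(pve / var_predictor)


def alpha_from_pve(pve_gx: float, pve_gy: float) -> float:
    """Implied causal effect ``sqrt(PVEgy / PVEgx)`` of exposure on outcome.

    ``pve_gx`` is the PVE of the exposure explained by the offspring's
    genotype and ``pve_gy`` the PVE of the outcome attributed to the
    (vertical-pleiotropy) genetic path through the exposure.
    """
    if pve_gy < 0:
        raise ValueError("PVEgy must be nonnegative")
    if pve_gy == 0:
        return 0.0
    if not pve_gx > 0:
        raise ValueError("PVEgx must be positive when PVEgy > 0")
    return math.sqrt(pve_gy / pve_gx)


@dataclass
class SimConfig:
    """Complete description of one synthetic trio cohort.

    ``maf`` is a single frequency for the homogeneous scenarios (DE, NONE)
    and a pair ``(maf1, maf2)`` of subpopulation frequencies for RPS.  The
    five PVE fields give the proportion of each phenotype's variance
    explained by the offspring/paternal/maternal genetic effects, the
    stratification variable L and the person-level confounder U.  ``rho``
    is the exchangeable residual correlation.  ``l_coding`` selects
    Var(L) = 0.25 (levels 1/2, the GWAS convention) or Var(L) = 1
    (standardized, the MR convention).
    """

    scenario: str
    n_trios: int
    maf: float | tuple[float, float] = 0.3
    pve_oe: float = 0.0
    pve_fe: float = 0.0
    pve_me: float = 0.0
    pve_le: float = 0.0
    pve_u: float = 0.0
    rho: float = 0.0
    l_coding: str = "levels_1_2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.l_coding not in L_CODINGS:
            raise ValueError(f"l_coding must be one of {L_CODINGS}")
        if self.n_trios < 1:
            raise ValueError("n_trios must be positive")
        if self.scenario == "RPS":
            if np.ndim(self.maf) != 1 or len(self.maf) != 2:
                raise ValueError("RPS requires a pair of allele frequencies")
            self.maf = (float(self.maf[0]), float(self.maf[1]))
        else:
            if np.ndim(self.maf) != 0:
                raise ValueError(f"{self.scenario} requires a single "
                                 "allele frequency")
            self.maf = float(self.maf)
            if self.pve_le != 0:
                raise ValueError("pve_le is only meaningful under RPS")
        for name in ("pve_oe", "pve_fe", "pve_me", "pve_le", "pve_u"):
            val = getattr(self, name)
            if not 0.0 <= val < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.pve_sum >= 1.0:
            raise ValueError("total PVE must be < 1 (residual variance "
                             "would be nonpositive)")

    # -- derived quantities -------------------------------------------------

    @property
    def pooled_maf(self) -> float:
        """Population allele frequency (mixture average under RPS)."""
        if self.scenario == "RPS":
            return 0.5 * (self.maf[0] + self.maf[1])
        return self.maf

    @property
    def var_snp(self) -> float:
        """Dosage variance at the pooled allele frequency."""
        return genotype_variance(self.pooled_maf)

    @property
    def var_l(self) -> float:
        return 0.25 if self.l_coding == "levels_1_2" else 1.0

    @property
    def pve_sum(self) -> float:
        return (self.pve_oe + self.pve_fe + self.pve_me
                + self.pve_le + self.pve_u)

    def effects(self) -> dict[str, float]:
        """Generative effect sizes implied by the PVE settings."""
        return {
            "oe": effect_from_pve(self.pve_oe, self.var_snp),
            "fe": effect_from_pve(self.pve_fe, self.var_snp),
            "me": effect_from_pve(self.pve_me, self.var_snp),
            "le": effect_from_pve(self.pve_le, self.var_l),
            "ue": effect_from_pve(self.pve_u, 1.0),
        }

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> None:
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if "maf" in payload and isinstance(payload["maf"], list):
            payload["maf"] = tuple(payload["maf"])
        return cls(**payload)


@dataclass
class MRSimPair:
    """Two disjoint half-cohorts for two-sample MR.

    ``sample1`` carries the exposure phenotype, ``sample2`` the outcome;
    ``true_alpha`` is the generating causal effect of exposure on outcome.
    """

    sample1: TrioDataset
    sample2: TrioDataset
    true_alpha: float


# -- genotype machinery -----------------------------------------------------

def sim_founder_genotypes(maf, n: int, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. HWE dosages: Binomial(2, maf) per individual.

    ``maf`` may be a scalar or a per-individual array (used for mixtures).
    """
    if n < 1:
        raise ValueError("n must be positive")
    maf = np.asarray(maf, dtype=float)
    if np.any((maf < 0) | (maf > 1)):
        raise ValueError("allele frequency must be in [0, 1]")
    return rng.binomial(2, maf, size=n).astype(np.int64)


def _transmit_one(genotype: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Alleles transmitted by one parent: 0, 1, or a fair coin for hets."""
    out = (genotype == 2).astype(np.int64)
    het = genotype == 1
    n_het = int(het.sum())
    if n_het:
        out[het] = rng.integers(0, 2, size=n_het)
    return out


def mendelian_transmit(parent1, parent2, rng: np.random.Generator):
    """Child dosage from two parental dosages under Mendelian segregation."""
    scalar = np.ndim(parent1) == 0 and np.ndim(parent2) == 0
    p1 = np.atleast_1d(np.asarray(parent1))
    p2 = np.atleast_1d(np.asarray(parent2))
    for arr in (p1, p2):
        if not np.isin(arr, (0, 1, 2)).all():
            raise ValueError("parental dosages must be in {0, 1, 2}")
    child = _transmit_one(p1.astype(np.int64), rng) \
        + _transmit_one(p2.astype(np.int64), rng)
    return int(child[0]) if scalar else child


def _sim_genotype_block(cfg: SimConfig, rng: np.random.Generator):
    """Grandparents, parents, offspring and (under RPS) the L variable."""
    n = cfg.n_trios
    if cfg.scenario == "RPS":
        subpop = rng.integers(0, 2, size=n)
        maf_i = np.where(subpop == 0, cfg.maf[0], cfg.maf[1])
    else:
        subpop = np.zeros(n, dtype=np.int64)
        maf_i = cfg.maf
    geno = {}
    for name in ("GF1", "GM1", "GF2", "GM2"):
        geno[name] = sim_founder_genotypes(maf_i, n, rng)
    geno["F"] = mendelian_transmit(geno["GF1"], geno["GM1"], rng)
    geno["M"] = mendelian_transmit(geno["GF2"], geno["GM2"], rng)
    geno["O"] = mendelian_transmit(geno["F"], geno["M"], rng)
    if cfg.scenario == "RPS":
        lval = subpop + 1 if cfg.l_coding == "levels_1_2" \
            else 2 * subpop - 1
    else:
        lval = np.zeros(n)
    return geno, lval.astype(float), subpop


def _sim_phenotypes(cfg: SimConfig, geno: dict, lval: np.ndarray,
                    rng: np.random.Generator):
    """Phenotype triplet (ZF, ZM, ZO) plus the hidden confounders."""
    n = cfg.n_trios
    b = cfg.effects()
    u = rng.standard_normal((3, n))
    resid_var = 1.0 - cfg.pve_sum
    resid_cov = resid_var * (
        (1.0 - cfg.rho) * np.eye(3) + cfg.rho * np.ones((3, 3)))
    eps = np.linalg.cholesky(resid_cov) @ rng.standard_normal((3, n))
    shared = b["le"] * lval
    zf = (b["oe"] * geno["F"] + b["fe"] * geno["GF1"]
          + b["me"] * geno["GM1"] + b["ue"] * u[0] + shared + eps[0])
    zm = (b["oe"] * geno["M"] + b["fe"] * geno["GF2"]
          + b["me"] * geno["GM2"] + b["ue"] * u[1] + shared + eps[1])
    zo = (b["oe"] * geno["O"] + b["fe"] * geno["F"]
          + b["me"] * geno["M"] + b["ue"] * u[2] + shared + eps[2])
    return (zf, zm, zo), u


def sim_gwas_dataset(cfg: SimConfig,
                     rng: np.random.Generator | None = None) -> TrioDataset:
    """Generate one trio cohort for the GWAS experiments.

    Hidden generative columns (grandparental genotypes, L, U) are retained
    on the returned dataset for oracle testing; call
    :meth:`~ftsem.data.TrioDataset.public_view` for the analysis view.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    geno, lval, subpop = _sim_genotype_block(cfg, rng)
    (zf, zm, zo), u = _sim_phenotypes(cfg, geno, lval, rng)
    hidden = pd.DataFrame({
        "GF1": geno["GF1"], "GM1": geno["GM1"],
        "GF2": geno["GF2"], "GM2": geno["GM2"],
        "L": lval, "UF": u[0], "UM": u[1], "UO": u[2],
        "subpop": subpop,
    })
    return TrioDataset(geno["F"], geno["M"], geno["O"], zf, zm, zo,
                       hidden=hidden,
                       family_ids=np.arange(cfg.n_trios))


def sim_mr_pair(cfg_x: SimConfig, cfg_y: SimConfig, alpha: float,
                rng: np.random.Generator | None = None) -> MRSimPair:
    """One cohort with exposure and outcome, split into two equal samples.

    The genotype block (and the RPS subpopulation/L assignment) is shared
    between exposure and outcome; the confounders U and residuals are drawn
    independently for the two phenotypes.  Each person's outcome includes
    ``alpha`` times their own exposure.  The cohort is split uniformly at
    random; the first half keeps the exposure only, the second half the
    outcome only.  An odd trailing trio is dropped.
    """
    for attr in ("n_trios", "scenario", "maf", "l_coding"):
        if getattr(cfg_x, attr) != getattr(cfg_y, attr):
            raise ValueError(f"cfg_x and cfg_y disagree on {attr}")
    if rng is None:
        rng = np.random.default_rng(cfg_x.seed)
    geno, lval, subpop = _sim_genotype_block(cfg_x, rng)
    (xf, xm, xo), ux = _sim_phenotypes(cfg_x, geno, lval, rng)
    (yf, ym, yo), uy = _sim_phenotypes(cfg_y, geno, lval, rng)
    yf = yf + alpha * xf
    ym = ym + alpha * xm
    yo = yo + alpha * xo
    n_half = cfg_x.n_trios // 2
    perm = rng.permutation(cfg_x.n_trios)
    idx1, idx2 = perm[:n_half], perm[n_half:2 * n_half]

    def build(idx, zf, zm, zo, u):
        hidden = pd.DataFrame({
            "GF1": geno["GF1"][idx], "GM1": geno["GM1"][idx],
            "GF2": geno["GF2"][idx], "GM2": geno["GM2"][idx],
            "L": lval[idx], "UF": u[0][idx], "UM": u[1][idx],
            "UO": u[2][idx], "subpop": subpop[idx],
        })
        return TrioDataset(geno["F"][idx], geno["M"][idx], geno["O"][idx],
                           zf[idx], zm[idx], zo[idx], hidden=hidden,
                           family_ids=idx)

    return MRSimPair(sample1=build(idx1, xf, xm, xo, ux),
                     sample2=build(idx2, yf, ym, yo, uy),
                     true_alpha=float(alpha))


# -- links to the path model ------------------------------------------------

def true_params(cfg: SimConfig) -> FTSEMParams:
    """The path-model parameters implied by a DE or NONE configuration.

    The per-person confounder U is independent across roles, so it inflates
    only the diagonal of the residual covariance (by ``PVE_U``); the
    generative residual correlation applies to the ``1 - PVEsum`` part.
    Under RPS the single-population path model is misspecified by design
    and no exact parameter vector exists.
    """
    if cfg.scenario == "RPS":
        raise ValueError("RPS is a two-population mixture; the single-"
                         "population path model has no exact parameters")
    b = cfg.effects()
    resid = 1.0 - cfg.pve_sum
    return FTSEMParams(
        beta_fe=b["fe"], beta_me=b["me"], beta_oe=b["oe"],
        phi=cfg.var_snp, mu_g=2.0 * cfg.pooled_maf,
        sigma2_f=resid + cfg.pve_u, sigma2_m=resid + cfg.pve_u,
        sigma2_o=resid + cfg.pve_u,
        sigma_fm=cfg.rho * resid, sigma_fo=cfg.rho * resid,
        sigma_mo=cfg.rho * resid)


# -- study conditions -------------------------------------------------------

def gwas_study_config(scenario: str, n_trios: int, rho: float = 0.6,
                      pve_oe: float = 0.0, seed: int = 0) -> SimConfig:
    """The GWAS simulation conditions for one scenario.

    DE: MAF 0.3 with parental-effect PVE 0.5% each; RPS: subpopulation MAFs
    (0.25, 0.35) with a 5%-PVE stratification variable on the 1/2 coding;
    NONE: MAF 0.3 with no bias source.  All scenarios share a 30%-PVE
    person-level confounder.  ``pve_oe`` is 0 under the null and 0.2%
    under the alternative.
    """
    common = dict(n_trios=n_trios, pve_oe=pve_oe, pve_u=0.3, rho=rho,
                  seed=seed)
    if scenario == "DE":
        return SimConfig("DE", maf=0.3, pve_fe=0.005, pve_me=0.005, **common)
    if scenario == "RPS":
        return SimConfig("RPS", maf=(0.25, 0.35), pve_le=0.05,
                         l_coding="levels_1_2", **common)
    if scenario == "NONE":
        return SimConfig("NONE", maf=0.3, **common)
    raise ValueError(f"unknown scenario {scenario!r}")


def mr_study_configs(scenario: str, n_trios: int, rho: float = 0.6,
                     pve_gy: float = 0.0, seed: int = 0,
                     ) -> tuple[SimConfig, SimConfig, float]:
    """Exposure/outcome simulation conditions for the two-sample MR study.

    The exposure has a strong offspring effect (PVE 10%) and a 20%-PVE
    confounder; the outcome has no direct offspring effect (no horizontal
    pleiotropy), a 30%-PVE confounder, and receives ``alpha`` times the
    exposure with ``alpha = sqrt(PVEgy / 0.10)``.  Under DE the parental
    PVEs are 2.5% (exposure) and 0.4% (outcome); under RPS the standardized
    L has PVE 5% (exposure) and 10% (outcome).  ``n_trios`` is the total
    cohort size before the equal split.
    """
    alpha = alpha_from_pve(0.10, pve_gy)
    common = dict(n_trios=n_trios, rho=rho, seed=seed)
    if scenario == "DE":
        cfg_x = SimConfig("DE", maf=0.3, pve_oe=0.10, pve_fe=0.025,
                          pve_me=0.025, pve_u=0.2, **common)
        cfg_y = SimConfig("DE", maf=0.3, pve_oe=0.0, pve_fe=0.004,
                          pve_me=0.004, pve_u=0.3, **common)
    elif scenario == "RPS":
        cfg_x = SimConfig("RPS", maf=(0.25, 0.35), pve_oe=0.10, pve_le=0.05,
                          pve_u=0.2, l_coding="standardized", **common)
        cfg_y = SimConfig("RPS", maf=(0.25, 0.35), pve_oe=0.0, pve_le=0.10,
                          pve_u=0.3, l_coding="standardized", **common)
    elif scenario == "NONE":
        cfg_x = SimConfig("NONE", maf=0.3, pve_oe=0.10, pve_u=0.2, **common)
        cfg_y = SimConfig("NONE", maf=0.3, pve_oe=0.0, pve_u=0.3, **common)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return cfg_x, cfg_y, alpha
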