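"""Replicated simulation experiments: bias, RMSE, coverage, size and power.

The harness re-creates the package's GWAS and MR simulation studies over a
grid of scenario x sample-size x residual-correlation cells.  Within one
cell every requested method is fitted to the *same* replicate datasets
(common random numbers), so cross-method orderings are paired comparisons.
Non-converged fits are excluded from the metrics and counted; a cell with
more than 5% non-convergence triggers a quality warning.

Metrics per cell, for estimates ``e_r`` with standard errors ``s_r`` and
truth ``t``:

* bias      = mean(e) - t
* rmse      = sqrt(mean((e - t)^2))
* coverage  = fraction of intervals e +- z0.975 s containing t
* width     = mean(2 z0.975 s)
* rejection = fraction with two-sided normal p < alpha (type-I error under
  the null, power under the alternative)
"""

from __future__ import annotations

import warnings
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from . import mr as mrmod
from .baselines import fit_lm, fit_lm_parent
from .model import FTSEM
from .simulate import (SimConfig, effect_from_pve, gwas_study_config,
                       mr_study_configs, sim_gwas_dataset, sim_mr_pair)

Z95 = float(stats.norm.ppf(0.975))

METRIC_COLUMNS = ("method", "scenario", "n", "rho", "truth", "bias", "rmse",
                  "coverage", "mean_ci_width", "rejection_rate",
                  "n_replicates", "n_converged")


def evaluate_estimates(estimates, ses, truth: float,
                       alpha_level: float = 0.05) -> dict:
    """Summarize one cell's replicate estimates against the known truth."""
    estimates = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if len(estimates) == 0:
        raise ValueError("no estimates to evaluate")
    if len(estimates) != len(ses):
        raise ValueError("estimates and ses must have equal length")
    err = estimates - truth
    half = Z95 * ses
    z = estimates / ses
    pvals = 2 * stats.norm.sf(np.abs(z))
    return {
        "truth": float(truth),
        "bias": float(err.mean()),
        "rmse": float(np.sqrt((err ** 2).mean())),
        "coverage": float((np.abs(err) <= half).mean()),
        "mean_ci_width": float((2 * half).mean()),
        "rejection_rate": float((pvals < alpha_level).mean()),
        "n_replicates": len(estimates),
    }


def _replicate_seed(seed: int, cell: int, rep: int) -> int:
    """Deterministic per-replicate seed below 2^31, stateless in ordering."""
    ss = np.random.SeedSequence(entropy=(seed, cell, rep))
    return int(ss.generate_state(1)[0] >> 1)


def _offspring_estimate(method: str, data):
    if method == "ftsem":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = FTSEM(data).fit()
    elif method == "lm_parent":
        res = fit_lm_parent(data)
    elif method == "lm":
        res = fit_lm(data)
    else:
        raise ValueError(f"unknown method {method!r}")
    eff = res.effects["offspring"]
    return eff.beta, eff.se, bool(getattr(res, "converged", True))


def run_scenario_grid(scenarios=("DE", "RPS", "NONE"),
                      sample_sizes=(1000, 2000, 3000), rhos=(0.6,),
                      methods=("ftsem", "lm_parent", "lm"),
                      n_replicates: int = 2000, pve_oe: float = 0.0,
                      seed: int = 0, alpha_level: float = 0.05,
                      ) -> pd.DataFrame:
    """GWAS experiment: offspring-effect metrics per (method, cell).

    ``pve_oe = 0`` reproduces the null experiment (rejection = type-I
    error); ``pve_oe = 0.002`` the alternative (rejection = power).
    """
    rows = []
    for cell, (scenario, n, rho) in enumerate(
            product(scenarios, sample_sizes, rhos)):
        collected = {m: ([], []) for m in methods}
        n_converged = {m: 0 for m in methods}
        truth = effect_from_pve(
            pve_oe, gwas_study_config(scenario, n, rho, pve_oe).var_snp)
        for rep in range(n_replicates):
            cfg = gwas_study_config(
                scenario, n, rho, pve_oe,
                seed=_replicate_seed(seed, cell, rep))
            data = sim_gwas_dataset(cfg).public_view()
            for method in methods:
                try:
                    beta, se, ok = _offspring_estimate(method, data)
                except Exception:
                    ok = False
                if ok:
                    collected[method][0].append(beta)
                    collected[method][1].append(se)
                    n_converged[method] += 1
        for method in methods:
            est, ses = collected[method]
            if n_converged[method] < 0.95 * n_replicates:
                warnings.warn(
                    f"cell ({method}, {scenario}, n={n}, rho={rho}): "
                    f"only {n_converged[method]}/{n_replicates} converged",
                    RuntimeWarning, stacklevel=2)
            metrics = evaluate_estimates(est, ses, truth, alpha_level)
            rows.append({"method": method, "scenario": scenario, "n": n,
                         "rho": rho, **metrics,
                         "n_converged": n_converged[method]})
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def run_mr_grid(scenarios=("DE", "RPS", "NONE"),
                sample_sizes=(2000, 4000, 6000), rhos=(0.6,),
                pipelines=("ftsem", "lm_parent", "lm"),
                n_replicates: int = 2000, pve_gy: float = 0.0,
                seed: int = 0, alpha_level: float = 0.05) -> pd.DataFrame:
    """Two-sample MR experiment: causal-effect metrics per pipeline.

    Each replicate simulates one cohort (``sample_sizes`` are totals before
    the equal split), estimates the SNP-exposure effect on sample 1 and the
    SNP-outcome effect on sample 2 with the pipeline's GWAS method, and
    combines them with the single-instrument ratio (equivalently IVW).
    """
    rows = []
    for cell, (scenario, n, rho) in enumerate(
            product(scenarios, sample_sizes, rhos)):
        collected = {m: ([], []) for m in pipelines}
        n_converged = {m: 0 for m in pipelines}
        truth = mr_study_configs(scenario, n, rho, pve_gy)[2]
        for rep in range(n_replicates):
            cfg_x, cfg_y, alpha = mr_study_configs(
                scenario, n, rho, pve_gy,
                seed=_replicate_seed(seed, cell, rep))
            pair = sim_mr_pair(cfg_x, cfg_y, alpha)
            s1 = pair.sample1.public_view()
            s2 = pair.sample2.public_view()
            for method in pipelines:
                try:
                    bx, sx, ok_x = _offspring_estimate(method, s1)
                    by, sy, ok_y = _offspring_estimate(method, s2)
                    inst = mrmod.HarmonizedInstrument(
                        "snp1", beta_x=bx, se_x=sx, beta_y=by, se_y=sy)
                    res = mrmod.ivw([inst])
                    ok = ok_x and ok_y
                except Exception:
                    ok = False
                if ok:
                    collected[method][0].append(res.estimate)
                    collected[method][1].append(res.se)
                    n_converged[method] += 1
        for method in pipelines:
            est, ses = collected[method]
            if n_converged[method] < 0.95 * n_replicates:
                warnings.warn(
                    f"MR cell ({method}, {scenario}, n={n}): only "
                    f"{n_converged[method]}/{n_replicates} converged",
                    RuntimeWarning, stacklevel=2)
            metrics = evaluate_estimates(est, ses, truth, alpha_level)
            rows.append({"method": method, "scenario": scenario, "n": n,
                         "rho": rho, **metrics,
                         "n_converged": n_converged[method]})
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def plot_metric_panels(table: pd.DataFrame, metric: str, out_path) -> None:
    """One panel per scenario, sample size on the x axis, one line per
    method --- the layout of the simulation figures."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scenarios = list(pd.unique(table["scenario"]))
    fig, axes = plt.subplots(1, len(scenarios),
                             figsize=(4 * len(scenarios), 3.2),
                             squeeze=False)
    for ax, scenario in zip(axes[0], scenarios):
        sub = table[table["scenario"] == scenario]
        for method, grp in sub.groupby("method"):
            grp = grp.sort_values("n")
            ax.plot(grp["n"], grp[metric], marker="o", label=method)
        ax.set_title(scenario)
        ax.set_xlabel("sample size")
        ax.set_ylabel(metric)
    axes[0][-1].legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
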