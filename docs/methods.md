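# Methods

## The trio path model

The unit of analysis is a father–mother–offspring trio with genotype
dosages $F, M, O \in \{0,1,2\}$ at one biallelic SNP and one quantitative
phenotype per member, $Z_F, Z_M, Z_O$.  The six observed variables are
modelled jointly as multivariate normal with moments implied by a path
diagram:

* The four grandparental genotypes $G_{F1}, G_{M1}, G_{F2}, G_{M2}$ are
  latent.  Every genotype variable — latent or observed — has the same
  total variance $\Phi$ and mean $\mu_g$ (one source population; under
  HWE, $\mu_g = 2p$ and $\Phi = 2p(1-p)$, but both are free parameters
  estimated from the data).
* Each parent→child genotype path coefficient is fixed at $1/2$
  (Mendelian inheritance), and each child genotype carries a segregation
  residual constrained to variance $\Phi/2$, which is what keeps the
  total genotype variance equal to $\Phi$ in both generations.
* Each person's phenotype is

  $$Z_i = \beta_0 + \beta_{OE}\,G_{\text{self}} + \beta_{FE}\,G_{\text{father}}
        + \beta_{ME}\,G_{\text{mother}} + \epsilon_i ,$$

  with the *same* three genetic coefficients in both generations
  (offspring effect $\beta_{OE}$, paternal effect $\beta_{FE}$, maternal
  effect $\beta_{ME}$).  For the parents, the "father"/"mother" genotypes
  are the latent grandparental ones.
* The phenotype residuals $(\epsilon_F, \epsilon_M, \epsilon_O)$ have a
  free symmetric positive-definite $3\times 3$ covariance.  Unobserved
  person-level confounders that are independent across family members are
  absorbed into its diagonal; shared family environment appears in the
  off-diagonals.

Because the parental genotypes are conditioned on inside the model, the
confounding paths opened by dynastic effects (parental genotype →
offspring environment → offspring phenotype) and by residual population
stratification (ancestry → allele frequency and phenotype) are blocked;
the unadjusted regression of $Z_O$ on $O$ leaves them open and converges
to $\beta_{OE} + \tfrac12(\beta_{FE}+\beta_{ME})$ plus a
stratification term.

There are 14 free parameters: the three genetic effects, $\Phi$, $\mu_g$,
three intercepts, and the six residual (co)variances.  The observed
moments (6 means, 21 covariances) over-identify them.

## Estimation and inference

The Gaussian log-likelihood of $n$ i.i.d. trios depends on the data only
through the sample mean $\bar{x}$ and the divisor-$n$ covariance $S$:

$$-2\ell(\theta) = n\left[6\log 2\pi + \log|\Sigma(\theta)|
  + \operatorname{tr}\{\Sigma(\theta)^{-1}S\}
  + (\bar{x}-\mu(\theta))^\top \Sigma(\theta)^{-1}(\bar{x}-\mu(\theta))\right],$$

so one objective evaluation costs the same at $n=10^2$ and $n=10^6$.  The
implied $\mu(\theta), \Sigma(\theta)$ are closed-form path-tracing
expressions (the transparent path-matrix construction
$A K A^\top$ is kept alongside and tested for exact agreement).

Numerical choices:

* **Parameterization.** BFGS quasi-Newton on an unconstrained scale:
  $\log\Phi$, and the residual $3\times3$ through its Cholesky factor
  with log-diagonal, so every iterate is feasible.  Gradient tolerance
  $10^{-7}$ on the per-family average objective, at most 500 iterations,
  up to 3 deterministically jittered restarts on failure.
* **Starting values** are moment-based: $\Phi$ and $\mu_g$ pool the three
  genotype variances/means; the genetic effects solve the
  $(O,F,M)\to Z_O$ normal equations (the parent-adjusted OLS estimator);
  the residual covariance is the phenotype covariance minus the implied
  genetic block, eigenvalue-clipped to positive definiteness.  From these
  starts the optimizer typically converges in 15–30 iterations.
* **Standard errors** come from inverting the observed information,
  computed by central finite differences (relative step $10^{-5}$) on the
  natural scale at the optimum, which is interior by construction.  Each
  genetic effect is tested with a Wald $z$ against the standard normal;
  tests are two-sided at 5% throughout.
* **Degenerate inputs.** Monomorphic SNPs are rejected
  ("degenerate genotype"); incomplete trios are listwise-deleted; fewer
  than 50 complete trios is an error.  In multi-SNP runs these become
  flagged records rather than exceptions.
* Genotypes are dosages treated as continuous inside the Gaussian
  likelihood (normal-theory pseudo-ML, the standard SEM treatment);
  Wald inference rests on its asymptotics.  Covariates, when present, are
  removed from each role's phenotype by least squares beforehand, keeping
  the six-variable model intact; putting them in the mean structure is a
  noted alternative that was not implemented.

The OLS baselines (`lm_parent`: $Z_O$ on $O, F, M$; `lm`: $Z_O$ on $O$)
use classical standard errors and $t$ p-values, conventional linear-model
output; at the sample sizes studied the $t$-vs-normal distinction is
immaterial.

## What the simulator emulates

The generator reproduces the simulation studies' conditions exactly:
founders drawn under HWE, Mendelian transmission down two generations,
effect sizes specified through phenotypic variance explained
($\beta = \sqrt{\mathrm{PVE}/\mathrm{Var(predictor)}}$), a standard-normal
confounder per person (independent across roles, common effect), and an
exchangeable residual correlation $\rho$ with residual variance
$1-\mathrm{PVE}_{\text{sum}}$.  Defaults are the study conditions:

| quantity | GWAS experiments | MR experiments |
|---|---|---|
| allele frequency | 0.3 (RPS: 0.25/0.35 mix) | same |
| offspring-effect PVE | 0 (null) or 0.2% → β=0.069 | exposure 10% → 0.488; outcome 0 |
| parental-effect PVE (DE) | 0.5% each → 0.109 | exposure 2.5% → 0.244; outcome 0.4% → 0.098 |
| stratification PVE (RPS) | 5% on L∈{1,2}, Var ¼ → 0.447 | 5%/10% on standardized L → 0.224/0.316 |
| confounder PVE | 30% → 0.548 | exposure 20% → 0.447; outcome 30% → 0.548 |
| residual correlation ρ | 0.6 (0.3 available) | same |
| causal effect α | — | $\sqrt{\mathrm{PVE}_{gy}/\mathrm{PVE}_{gx}}$: 0 or 0.141 |

The two L codings are both exposed because the two experiment families
define L differently (a 1/2-coded indicator in the GWAS runs, variance
0.25; a standardized variable in the MR runs, variance 1); `l_coding`
selects between them.  RPS genotype-effect betas
use Var(SNP) at the pooled frequency 0.3.  Intercepts are zero.  A single
seeded generator is consumed in a documented draw order, so a seed fully
determines a cohort.

What the generator does **not** emulate — and hence what green tests do
not certify about real data: linkage disequilibrium and multi-SNP
genomes, non-integer (imputed) dosages, assortative mating, non-additive
or generation-specific genetic effects, non-Gaussian phenotypes (real
analyses should apply the rank-based inverse normal transform first, as
the GWAS runner offers), genotyping error, and more than two ancestral
strata.  Under RPS even the fitted model is deliberately misspecified
(one genotype mean/variance for a two-population mixture), which is
exactly the robustness property the simulations probe.

## Two-sample MR layer

Per-SNP summary statistics feed the downstream estimators: the Wald ratio
$\hat\beta_Y/\hat\beta_X$ with first-order delta SE $se_Y/|\hat\beta_X|$
(second-order available behind a flag), fixed-effect IVW (weights
$1/se_Y^2$, through the origin; reduces exactly to the ratio for one
instrument — no overdispersion scaling), MR-Egger (weighted with a free
intercept; the intercept tests directional pleiotropy; multiplicative
residual scaling as in the conventional Egger fit), and the weighted
median (interpolated weighted 50th percentile of the per-SNP ratios) and
weighted mode (argmax of a weighted Gaussian KDE over the ratios,
bandwidth $0.9\,\min(\mathrm{SD}, 1.4826\,\mathrm{MAD})\,n^{-1/5}$ times
a tuning factor of 1).  Median/mode standard errors use a seeded
parametric bootstrap, 1,000 replicates by default.  Harmonization aligns
outcome to exposure effect alleles (flipping signs, handling strand
complements), drops palindromic A/T–C/G SNPs, and excludes instruments
with single-SNP $F=(\hat\beta_X/se_X)^2<10$.  Instruments are assumed
independent: LD clumping requires an external reference panel and is out
of scope.

## Simulation harness and problem sizes

The harness runs scenario × sample-size × ρ grids, fitting every method
to the *same* replicate datasets (common random numbers) so cross-method
orderings are paired.  Non-converged fits are excluded and counted, with
a warning above 5%.  The package default is 2,000 replicates per cell —
chosen so a full calibration experiment completes in minutes on one core
while keeping the binomial SE of a 5% rejection rate at 0.49 percentage
points; tolerances in the test suite are stated as multiples of that SE.
Larger replicate counts are a parameter away.  The acceptance script uses
the same 2,000-replicate cells at N=1,000 (size) and N=2,000 (coverage).

## Known limitations

Single offspring per family; main effects only (no dominance or
interactions); multivariate normality assumed for inference; the MR layer
inherits the usual ratio-estimator weak-instrument caveats (mitigated by
the F≥10 filter, not removed); per-SNP fitting is more expensive than a
linear model by roughly two orders of magnitude, though the
sufficient-statistic likelihood keeps it at milliseconds per SNP.
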