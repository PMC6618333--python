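# Methods

This note records the model, the sampler, the simulation harness and the
numerical choices behind `limi`, including the places where the design was
genuinely open and what was decided.

## The joint imputation model

All declared variables are treated as outcomes of an intercept-only
multivariate normal over P working columns,

    z_i = β + ε_i,   ε_i ~ N(0, Ω),

with the column layout and covariance constraints described in the README:
one free column per continuous/count variable, one unit-variance latent per
binary variable, and T−1 unit-variance latents with within-block covariance
0.5 per T-level categorical variable. The binary latent is the differenced
form of the two-latent construction (one latent per level minus the
other), which is what makes a binary variable identifiable with a single
parameterised column. Covariates never appear on the right-hand side: the
joint, intercept-only formulation is what makes the model a valid common
imputation model for any of the substantive analyses run on its output.

Decoding conventions (measure-zero ties included) are deterministic:

- binary: 1 iff z > 0 (an exact zero decodes to 0);
- categorical: latent column j corresponds to the j-th non-reference
  level in ascending order; the decoded level is the one whose latent
  attains the maximum if that maximum is positive (ties broken towards the
  lowest level index), otherwise the reference level. The reference level
  defaults to the last level, so e.g. level 4 of a 4-level variable
  corresponds to an all-negative latent triple.

## Sampler

One sweep performs, in this fixed order:

1. **Latent refresh** for every *observed* binary/categorical cell:
   the block is drawn from its conditional normal given all other working
   columns of the row, repeatedly until it decodes to the observed code.
   Draws are batched (growing chunks of 4→64 proposals per
   still-inconsistent unit), which changes nothing statistically — each
   cell still keeps its first consistent draw — but makes the loop length
   logarithmic in the worst acceptance probability. A cell that exhausts
   1,000 proposals keeps its previous (still consistent) block and the
   event is counted; the long-run fallback rate is asserted to be below
   0.1% of latent draws in the test suite. The cap exists because the
   plain accept-until-consistent loop has no termination guarantee under
   extreme conditional means.
2. **Missing-cell draws**: rows are grouped by missingness pattern (the
   grouping is fixed for the whole run) and, per pattern, the working
   columns of all missing variables are drawn jointly from one
   Schur-complement conditional normal given the observed variables'
   columns. A row with everything missing draws from the unconditional
   model. A single joint draw per row is exact and cheaper than
   cell-by-cell cycling.
3. **β draw** (Gibbs): under a flat prior the full conditional is
   N(column means of z, Ω/N).
4. **Ω update**: element-wise random-walk Metropolis–Hastings over the
   free entries only, in a fixed order, under a flat prior subject to
   positive definiteness. A proposal is rejected outright if the updated
   matrix fails its Cholesky factorisation, otherwise accepted with the
   multivariate-normal residual likelihood ratio. Fixed entries (latent
   variances 1, within-block covariances 0.5) are never proposed, so they
   remain bit-identical over any number of sweeps.

The element-wise update follows the standard single-site scheme for
constrained covariance matrices; since several variants circulate
(truncated proposals, Hastings windows), the variant above — plain
symmetric Gaussian increments plus PD rejection — is the one this package
pins down. Proposal scales start at 0.1 and are adapted only during
burn-in (multiplicative factor 1.5, targeting 30–50% acceptance, counters
reset each 25 sweeps) and frozen afterwards so the retained chain satisfies
detailed balance. The refresh-latents → draw-missing → β → Ω order is one
of several valid Gibbs orders; it is fixed for reproducibility.

**Initialisation.** Missing continuous/count cells are filled with draws
from the observed empirical marginal; latent blocks of observed discrete
cells are rejection-sampled from the constrained standard-normal block
prior (deterministic consistent fallback after 1,000 tries); β starts at
the column means and Ω at the sample covariance projected onto the
constraint mask, with free cross-entries shrunk multiplicatively until the
matrix is positive definite.

**Count scales.** `sqrt` inverts by truncating the working value at 0 and
squaring (the inverse is only monotone on the non-negative axis); `log`
uses log(x+1) when any observed count is 0 (recorded in the run log) and
log(x) otherwise, inverting exactly and truncating at 0. Imputed counts
are never rounded. The `categorical` treatment relabels the distinct
observed counts (at least 3 required) to consecutive levels, imputes with
the unordered algorithm, and maps imputed levels back; imputed values are
therefore confined to observed counts, which is why the treatment is only
sensible for low-mean counts.

**MI workflow defaults** mirror the validation study: M=20 imputed
datasets, burn-in 500 sweeps, 500 sweeps between retained datasets. Each
dataset is decoded from the exact state that produced the last sweep of
its block; observed cells are copied from the input bit-exactly.

## Pooling

`pool()` implements Rubin's rules with the Barnard–Rubin small-sample
degrees of freedom (driven by the complete-data df of the analysis model);
Rubin's original large-sample df is computed and carried alongside. At the
study's N and M the two are near-identical, so summaries are insensitive
to the choice. M=1 is permitted with B:=0 and a warning; with B=0 the
pooled interval reduces to the single-imputation t interval.

## Simulation harness

The harness regenerates nine data-generating scenarios over three
variables (y, x1, x2): the latent-normal matching model; logistic and
linear-with-binary-covariate models at three effect sizes; multinomial,
categorical-covariate, proportional-odds and thresholded-normal-covariate
models; Poisson outcome (large/small mean) and Poisson-covariate models.
Missingness plans combine MCAR with MAR-given-outcome: the matching-model
MAR mechanism is the fixed logistic 1/(1+exp(3−y)) applied to units with
observed y; the remaining scenarios state only "MAR given the outcome at
rate ≈0.2", implemented here as a logistic in the outcome with unit slope
and an intercept calibrated by bisection on the empirical driver
distribution so the expected rate among driver-observed units is 0.2
(complete-record fraction ≈ 0.8³ ≈ 0.51, as intended). MAR flags are never
applied where the driver is missing.

Three analysis methods are compared per replication: the full pre-amputation
data, complete records, and JM-MI with Rubin pooling. Coverage uses nominal
95% t intervals (fitter df for full/CR, pooled df for MI). Replications on
which any requested fit fails (separation, non-convergence) are excluded
jointly for all methods, the count is logged, and a run aborts beyond 5%
failures. Summaries report, per parameter × method: mean estimate, mean
model SE (mSE), empirical SE of estimates (eSE), coverage, and Monte-Carlo
SEs of the mean and coverage. Replication r uses child seed base_seed + r;
identical configurations and seeds give byte-identical tables.

Two generator details deserve explicit statement, because the naive
constructions they replace do not generate valid data:

- **Multinomial scenario.** Applying independent inverse-logits to the
  three linear predictors and setting p1 = 1−p2−p3−p4 yields p1 < 0 for
  every unit at the scenario's coefficient values (three probabilities
  near 0.5 each). The generator therefore uses the baseline-category
  multinomial logit, p_j = exp(Z_j)/(1+Σ exp(Z_k)), whose coefficients are
  exactly the quantities the substantive multinomial fit estimates. Any
  remaining invalid probability is a hard failure, never renormalised.
- **Ordinal scenario.** The proportional-odds generator's first two
  cut-points are equal (0.1, 0.1, −0.6 with shared slopes), so category 2
  has probability exactly zero and never occurs in generated data —
  though it does occur in imputed datasets, since the unordered latent
  model puts positive mass on all four levels. The ordered-logit fitter is
  therefore a hand-written constrained MLE with cut-points parameterised
  through non-negative gaps: with an empty category the maximiser sits on
  the gap=0 boundary and the two adjacent cut-point estimates coincide,
  matching how the full-data rows of the validation tables behave.
  Standard errors come from a finite-difference observed information
  matrix (pseudo-inverted, so boundary solutions stay finite). On
  non-degenerate data the fitter agrees with statsmodels' OrderedModel to
  high precision (tested).

Two further calibration facts are pinned by the reference population
values rather than by the defining equations: the matching-model binary
variable is coded 1 on the negative side of its latent (giving the
reference intercept 2.51 and binary coefficient −0.63 of the linear
analysis model), and the matching-model scenario runs at n=300 per
dataset — the scale at which the reference full-data and complete-records
standard errors (0.24–0.30) and the 0.62 complete-records coverage under
MAR reproduce exactly.

## Problem sizes and what the tests show

The fast analyses (OLS on full data and complete records, mechanism
rates) run at the study scale of 1000 replications. The MCMC-based MI arms
are validated at a reduced scale chosen once — 50 replications, M=5,
burn-in 200, 50 between-imputation sweeps — with comparisons at three
Monte-Carlo standard errors of the scaled run (reference eSE/√50). The
harness runs the full 1000-replication, M=20 configuration through the
same code path via `--nrep 1000`; it simply takes hours of CPU. Scaled-run
means can carry a small finite-M / short-burn-in offset (of the order of a
fraction of a scaled Monte-Carlo SE); at study-scale MCMC settings (M=20,
burn-in 500) the matching-scenario pooled intercept under MCAR reproduces
the reference value (2.50, mSE 0.34) directly.

The synthetic generators emulate exactly the study's data-generating
mechanisms, which is the point of the validation: the matching scenario is
*congenial* (the imputation model is the generating model), and the other
scenarios probe increasing incompatibility (logit vs probit links, general
location structure, ordinality, counts). What passing tests do **not**
show: behaviour with interactions or non-linearities in the substantive
model (imputation ignoring them is invalid; substantive-model-compatible
imputation is out of scope), multilevel/clustered data, informative
priors, or real-data features such as measurement error and non-logistic
missingness. The single-latent thresholded (ordered-probit) representation
of ordinal variables is deliberately not implemented; ordinal data use the
unordered algorithm, and the ordinal scenarios quantify the (negligible)
efficiency cost of that choice.

## Known limitations

- The element-wise MH update mixes slowly for large P or strongly
  correlated residuals; acceptance rates and the per-entry proposal scales
  are exposed in the run log for diagnosis.
- The rejection sampler can hit its 1,000-proposal cap for cells whose
  observed code has vanishing conditional probability (extreme effect
  sizes); the fallback retains the previous consistent block and is
  counted, but a high fallback rate signals an incompatible model.
- Flat priors on Ω's free entries are improper; with very small N the
  posterior may be poorly behaved. The validation scenarios use N ≥ 300.
- `pool()` is scalar; multi-parameter (matrix) pooling rules are not
  provided.
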