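# Methods

## Model and estimation

The core model is a Gaussian linear mixed model for effect sizes with
*known* heteroscedastic residual variances — the standard multilevel
meta-analytic formulation. For $n$ heritability estimates $y$ with
sampling variances $v$ the marginal covariance is

$$V(\theta) = \sigma_u^2 Z_uZ_u^\top + \sigma_a^2 Z_a A Z_a^\top
            + \sigma_s^2 Z_sZ_s^\top + \sigma_e^2 I + \mathrm{diag}(v),$$

where $Z_u$, $Z_a = Z_s$ are study and species incidence matrices and
$A$ is the phylogenetic correlation matrix. Assumptions worth making
explicit: the $v_i$ are treated as exact (their estimation error is
ignored, as is conventional); random effects are Gaussian and mutually
independent across terms; the phylogenetic effect follows a
Brownian-motion-style covariance $\sigma_a^2 A$; and the estimate-level
term $\sigma_e^2 I$ is identified from $\mathrm{diag}(v)$ only because the
$v_i$ are known and heterogeneous.

Variance components are estimated by maximising the restricted
log-likelihood. We use Harville's REML objective *including* the
$\tfrac12\log|X^\top X|$ constant, so reported log-likelihoods are
numerically comparable with the mixed-model meta-analysis software most
readers use (verified to agree with `metafor::rma.mv` to ~1e-6 on fixture
data, along with the components, coefficients and SEs themselves; see
`tests/oracles/metafor_crosscheck.R`).

Numerical choices:

* **Optimiser.** Bound-constrained L-BFGS-B directly on
  $\sigma^2 \ge 0$ with the analytic gradient
  $\partial\ell_R/\partial\sigma_r^2 = -\tfrac12[\mathrm{tr}(PM_r) -
  y^\top P M_r P y]$. Components whose unconstrained optimum would be
  negative land exactly on the zero boundary, matching the
  profile-boundary convention (`0.000` estimates) of standard tools.
* **Starts.** Three deterministic starting points — a method-of-moments
  excess-variance split, the same value un-split, and near-zero — and the
  best resulting optimum is kept. Convergence tolerances: gradient norm
  1e-8, relative objective change 1e-12.
* **Conditioning.** $V$ is always positive definite because
  $\mathrm{diag}(v) \succ 0$; Cholesky factorisations are used throughout
  and no jitter is needed.
* **Weak identifiability.** The phylogeny and species terms share one
  grouping factor; with few species their sum is much better identified
  than either alone. The fitter does not guard against this — it simply
  returns boundary or wide estimates, which is the honest answer.

## Heterogeneity

The typical sampling-error variance uses the Higgins–Thompson summary
$\sigma_m^2 = (k-1)\sum w_i / [(\sum w_i)^2 - \sum w_i^2]$ with
$w_i = 1/v_i$; it equals the common value when all $v_i$ are equal. This
formula is isolated in one function (`typical_sampling_variance`) so an
alternative summary (e.g. mean $v$) can be swapped without touching the
$I^2$ pipeline. $I^2$ and the per-component proportions divide by
$\sigma_u^2+\sigma_a^2+\sigma_s^2+\sigma_e^2+\sigma_m^2$; the proportions
sum to one by construction.

Likelihood-ratio tests drop one random term, refit, and use
$2\Delta\ell_R$ against $\chi^2_1$ — the convention common meta-analytic
software reports, even though the null lies on the boundary. The 50:50
$\chi^2_0{:}\chi^2_1$ mixture (which halves the p-value) is available via
`boundary_mixture=True`.

## Effect-size curation

* Parent–offspring regression slopes convert as mid-parent slope → $h^2$,
  single-parent slope → $2\times$ slope, signs preserved; negative and
  $>1$ estimates are *retained* for all untransformed analyses because
  they are informative about estimation bias.
* When only a 95 % CI is reported, $\mathrm{SE} = (\text{upper limit} -
  \text{estimate})/1.96$, using the upper half-width only; when both SE
  and CI are present the SE wins. Rows with neither are rejected with
  reason `"no SE or CI"`, never silently dropped.
* The Fisher-z sensitivity transform uses $z=\mathrm{arctanh}(h^2)$ with
  variance $1/(n-3)$. The right variance for a *heritability* (rather
  than a correlation) on the z scale is genuinely ambiguous, so the
  variance rule is a pluggable function; $1/(n-3)$ is the default because
  it keys the weight to sample size in the standard way. Records with
  $|h^2|\ge 1$ or missing/tiny $n$ are excluded with recorded reasons;
  the same trimmed row set feeds both the transformed and the
  untransformed "trimmed" sensitivity model.

## Phylogenetic correlation

Topologies are read from Newick (branch lengths in the input are
ignored); Grafen's method assigns node heights
$((k-1)/(n_\text{tips}-1))^\rho$ so the tree is exactly ultrametric with
depth 1, and $A_{ij}$ is the root-to-MRCA depth of each tip pair. The
exponent defaults to $\rho = 1$ (Grafen's own default) and is exposed as
a parameter. Polytomies are handled by the same height rule. Species in
the data but absent from the tree are a hard error listing the offenders
— a partial $A$ would silently misattribute variance.

## Bootstrap

Nonparametric, with two resampling units: individual records (default)
and whole studies (cluster bootstrap; records within a study are
dependent, so this is the conservative option — results are labelled
with the unit). Each replicate rebuilds the model, so the $A$ submatrix
tracks the resampled species. Percentile CIs use the Davison–Hinkley
order statistics $\lceil (R+1)\alpha/2 \rceil$ and
$\lfloor (R+1)(1-\alpha/2) \rfloor$, making tie handling deterministic.
One master seed spawns an independent substream per replicate, so results
are independent of execution order; failed refits are dropped, counted,
and abort the run above a 20 % failure rate.

## Publication-bias tests

The multilevel Egger variant regresses $y_i$ on its sampling variance
$v_i$ with study and species random intercepts and an estimate-level
residual, weighted by the known $v_i$. Regressing on $v_i$ *and*
weighting by it is a deliberate double use: the weights encode the known
error structure while the fixed-effect slope asks whether precision
predicts effect size. An SE-predictor variant is available behind
`predictor="se"`. The time-lag model swaps the predictor for publication
year, centred at its mean so the intercept remains the mean effect at the
average publication date (the slope is unaffected). Funnel-plot
coordinates use *marginal* residuals $y - X\hat\beta$ from the full
moderator meta-regression — they strip moderator structure while keeping
the random-effect spread a funnel is meant to display; conditional
(BLUP-subtracted) residuals are available via
`FitResult.conditional_residuals()`.

## Synthetic data: what it does and does not emulate

The generator draws from exactly the model above, with defaults matching
the structure of the vertebrate telomere-length heritability literature:
18 species, 43 studies, 104 estimates; true components
$\sigma_u^2=0.066$, $\sigma_a^2=0.017$, $\sigma_s^2=0.012$,
$\sigma_e^2=0.005$; grand mean 0.449. Design choices where realism had to
be decided once:

* sampling variances log-uniform on $[5\times10^{-4}, 0.05]$, bracketing
  the literature's typical value of about $10^{-3}$ (log-uniform because
  published SEs span orders of magnitude);
* one dominant species receives ~30 % of studies, and extra estimates
  are allocated proportionally to species weight — emulating the heavy
  human bias of the real literature; every species retains at least one
  study;
* imbalanced moderator frequencies (qPCR 45 %, TRF-Southern 30 %,
  in-gel 15 %, other 10 %; non-specific parental sex 70 %; repeated
  measurements 15 %; artificial settings 65 %), chosen once as a
  plausible human-dominated profile to stress rank checks;
* 5 % of records lack a sample size and publication years are uniform on
  1995–2021, so the trimming and time-lag paths are exercised;
* an optional `censor` hook can suppress records (e.g. small effects with
  large $v$) to generate outcome-reporting bias for power studies.

The generator does **not** emulate telomere biology (assay error models,
attrition, age structure), non-Gaussian effect distributions, moderator
confounding with species, or correlated sampling errors within studies.
Passing recovery tests therefore validates the estimator *under its own
assumptions*; they say nothing about, e.g., robustness to non-Gaussian
study effects.

## Calibration results and a known limitation

The test suite and `scripts/acceptance.py` run simulate-and-refit
experiments at the literature's design size (200 replicates for recovery;
500–1000 replicates for the Egger type-I check; bootstrap $R$ = 1000 —
sizes chosen to make the Monte-Carlo error small relative to the effects
being checked). Component estimates are unbiased within Monte-Carlo error
and the Egger test holds its nominal 5 % level.

One limitation is documented rather than patched: **plug-in Wald
intervals for the mean under-cover at this design size.** With only 18
species and small species-level components, REML frequently truncates
$\hat\sigma_a^2$ or $\hat\sigma_s^2$ at zero; the plug-in SE of
$\hat\beta_0$ then omits real species-level uncertainty, and measured
coverage of the nominal-95 % interval is ~84–87 % (the SE formula itself
is correct: it matches `metafor` exactly, and re-running the experiment
with the *true* components plugged in yields ~94 % coverage on a fixed
design). This is precisely the phenomenon small-sample corrections of the
Knapp–Hartung type address; such corrections are out of scope here, so
users should prefer the bootstrap intervals for inference on the mean
when species-level variance matters.
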