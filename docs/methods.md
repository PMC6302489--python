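# Methods

`pairpower` quantifies the statistical value of paired samples when a
two-condition expression study (tumor vs normal tissue, say) is being
planned: given a budget of `N` samples, how much power is gained by
collecting both conditions from a fraction `q` of subjects instead of
from none?

## Models

Expression of one feature (gene, miRNA, biomarker) in subject `j`
under condition `i` is modeled per family:

**Continuous** (log-intensities, e.g. microarray):

    Y_ij = mu + delta * 1[i = treatment] + Subj_j + eps_ij
    Subj_j ~ N(0, sigma2_subj),   eps_ij ~ N(0, sigma2_err)

**Count** (e.g. RNA-Seq), log-linear negative binomial with a
library-size offset:

    log E[Y_ij] = log(N_ij) + mu + delta * 1[i = treatment] + Subj_j
    Var(Y_ij | Subj_j) = m_ij + k * m_ij^2

`delta` is the natural-log fold change (`delta = ln 1.25 ≈ 0.22` and
`ln 1.5 ≈ 0.41` for the package's default count and continuous
targets).  The random intercept `Subj_j` absorbs every subject-level
confounder — diet, lifestyle, genetics, sample handling — anything
that shifts both of a subject's samples; its variance `sigma2_subj`
is the *strength of confounding*.  For counts the dispersion is
parameterized both ways in use: `theta` (variance `m + m^2/theta`)
and the scale `sqrt(k) = 1/sqrt(theta)`; the default scale is 1.15.

Both models are fitted by maximum likelihood (not REML), so a single
objective serves fitting, nested-model comparisons and the oracle
tests.  The continuous marginal likelihood is evaluated exactly from
the 2x2 compound-symmetry subject blocks.  The count random effect is
integrated out per subject by adaptive Gauss–Hermite quadrature
(default 15 nodes; 1 node gives the Laplace approximation): the mode
of each subject's log-integrand is found by Newton iteration (the
integrand is strictly log-concave) and nodes are recentred and
rescaled there.  Against a 10,001-point fixed-grid integration the
quadrature is accurate to better than 1e-6 on small examples.

### Tests and degrees of freedom

The test of differential expression is a two-sided Wald test of
`delta = 0`.  Its denominator degrees of freedom follow an accounting
in which every paired subject's estimated random effect costs one
residual degree of freedom:

    ddf = N - (number of fixed effects) - P

with `P` the number of paired subjects.  Without the random effect
the continuous fit reduces exactly to the classical pooled two-sample
t test (df `N - 2`), and the count fit to a plain NB regression whose
Wald statistic is referred to a t distribution with residual df
(rather than a normal: at `N <= 50` the normal reference is visibly
anti-conservative, and the t form matches the `F(1, N-2)` power
formula; the two coincide as `N` grows).

Variance components are optimized on the log scale with a hard floor
(`exp(-20)`); fixed effects are profiled by GLS in the continuous
family.  Wald covariance for the count GLMM's fixed effects comes
from a finite-difference Hessian of the quadrature likelihood in the
fixed-effect block, exploiting the asymptotic orthogonality of mean
and variance parameters.  Convergence flags are propagated honestly;
failed fits are excluded from downstream summaries and counted.

## Analytic power: the exemplary-data method

For a design with known variance components, the power of the Wald
test is approximated without simulation:

1. build the design's marginal covariance `V` — continuous: the LMM
   blocks; count: a working covariance on the log scale at random
   effect zero, per-observation variance `1/m + k + sigma2_subj` and
   within-pair covariance `sigma2_subj`, with `m` the expected count
   from a baseline mean (default 100) and the offsets;
2. `Var(delta_hat) = [(X' V^-1 X)^-1]_delta` by blockwise GLS;
3. `ncp = delta^2 / Var(delta_hat)`, and
   `power = P(F(1, ddf, ncp) > F_crit(alpha; 1, ddf))` with
   `ddf = N - 2 - P`.

The noncentral **F** (not a normal approximation) is what makes the
df cost of pairing visible: with near-zero confounding and small `N`,
power *dips* slightly when only ~5% of subjects are paired — the
random effects must be estimated before they pay off — and recovers
once pairing passes roughly 10% or confounding is appreciable.  Cells
with `ddf < 1` or a numerically singular `V` are reported as missing,
never as zero.

Power grids run over total samples, paired fraction, and a
confounder-strength axis: raw `sigma2_subj` (default 0–1.5) for the
continuous family and the *tenth root* of `sigma2_subj` (default
0.5–2.5) for counts.  The tenth-root convention follows the empirical
summaries the defaults are drawn from; note its upper end implies
astronomically large subject variances (`2.5^10 ≈ 9537` on a
log-count scale), and below roughly 1.0 it implies variances that are
negligible against the NB working variance (`k = 1.3225`).  Power
gains from pairing are therefore claimed (and tested) for strengths
where `sigma2_subj` is appreciable; at the axis extremes the method
either saturates or the df accounting dominates.

Continuous-family grids couple the residual variance to the subject
variance by default, `sigma2_err = max(1.73 * sigma2_subj, 0.05)`:
the slope reflects the empirical association between the two
components in the motivating data, and the floor keeps
zero-confounding cells well-posed.  The count baseline mean of 100
is a package default (the motivating study does not report library
sizes or baseline means); power is insensitive to it once `1/m` is
small against `k`.

## Simulation method

`run_simulation` draws `n_biomarkers` features per replicate under
the generative model (default: 1000 biomarkers, 20 differentially
expressed with |effects| uniform on [1, 2], drawn fresh subject
effects per feature), fits the matching model per feature (random
effect included exactly when the design has paired subjects),
BH-adjusts within the replicate at the nominal FDR (default 0.05),
and averages power (true DE rejected / number DE) and realized FDR
(false rejections / max(1, rejections)) over replicates (default
100).  Randomness is counter-based — every (replicate, feature) pair
owns a `SeedSequence((seed, rep, 1, feature))` substream — so results
are bit-reproducible and independent of iteration order.  Effects are
positive by default (two-sided power is symmetric in the sign); a
sign-randomized option exists.  The acceptance checks run this
machinery at desk scale (500 biomarkers, 20 replicates), a problem
size chosen so the whole suite completes on a single workstation
core; the estimator is identical at larger scale.

Simulation and the analytic method agree within Monte-Carlo error at
matched settings *when the fitted model is the generative model*:
everywhere in the continuous family, and in the count family at
paired designs or at negligible subject variance.  A count design
analyzed *without* the random effect while `sigma2_subj` is large is
deliberately misspecified — the NB dispersion cannot absorb a
heavy-tailed lognormal subject effect — and its test is
anti-conservative (measured null rejection up to ~0.3 at
`sigma2_subj = 1.5`).  That regime is a finding about unpaired
analyses, not an approximation failure, and is excluded from the
agreement checks.

## Synthetic cohorts

`generate_cohort` emulates the structure of the motivating colorectal
study: paired subjects plus tumor-only and normal-only subjects
(reference composition 169/22/18, 378 samples), subject-level
covariates drawn from published marginal frequencies (tumor site
100/100; SEER stage 24/72/102/2; MSI 164/36; sex 106/94; age
N(63.9, 10^2)), and log-normal library sizes (median 2e6, log-sd 0.4,
a typical depth profile; the offsets are their natural logs).

`generate_expression` draws per-gene parameters: subject-variance
strengths uniform on a configurable range (count default 0.5–1.2 on
the tenth-root scale — the conservative part of the empirical
envelope; the full 0.5–2.5 envelope is accepted but draws that would
overflow the count model are redrawn and logged, and an entirely
infeasible range raises an error); effects a point mass at zero with
probability `pi0 = 0.5`, otherwise N(0, 0.25^2) truncated to ±2 (most
effects within ±0.5, occasional large ones); count abundances
log-normal around 5e-5 of the library; continuous residual variances
coupled at slope 1.73.  An optional *confounded* mode mixes a
standardized covariate score (MSI, sex, age) into each subject's
random effect so that covariate adjustment in unpaired analyses has
real signal to recover.

What the generator does **not** emulate: gene–gene correlation,
normalization artifacts, batch effects, probe-level structure, and
whatever real-data mechanism attenuates unpaired fold-change
estimates.  Under these generative models both paired and unpaired
estimators of `delta` are unbiased, so the fold-change attenuation
seen in real data does not reproduce here; the exceedance curves are
reported for comparison but no attenuation ordering is asserted.
Passing tests therefore validate the machinery and the design
comparisons, not every empirical pattern of the motivating data.

## Paired vs unpaired comparison

`run_comparison` analyzes one matrix five ways: paired (mixed model
on a core of paired subjects), unpaired-1 (identical samples, random
effect dropped — the analysis, not the data, ignores pairing),
unpaired-2 (a genuinely unpaired subsample built by a two-stage draw:
half the core keeps only tumor, half only normal, then the two
half-core blocks are refilled from tumor-only/normal-only subjects
plus unselected paired subjects), and the two unpaired variants with
subject covariates as fixed effects.  Discoveries are counted at an
FDR threshold after BH within each variant; fold-change exceedance is
the proportion of genes with `|delta_hat| >= ln(threshold)`.  Genes
whose fit fails in one variant are dropped from that variant only.

The headline directional result — the paired analysis discovers more
than either unpaired analysis under subject confounding — is checked
on the continuous family, where every variant's test is exactly
calibrated and discovery counts isolate the design effect.  On count
data the same comparison additionally reflects the unpaired variants'
miscalibration under strong confounding (see above), which can inflate
their discovery totals with false positives.

## Numerical choices and limitations

- Nelder–Mead over (log-)variance parameters with profiled/warm-started
  inner computations; `precise=True` restarts the count optimizer for
  tighter tolerances when exact nested-model agreement matters.
- Ties in BH are broken by stable sort; NaN p-values propagate and are
  excluded from the number of tests.
- Missing power cells are NaN; tables encode missing values as `NA`.
- Degenerate inputs (one condition absent, rank-deficient covariates,
  non-integer counts, odd `N`) are rejected with named errors.
- The df rule `N - 2 - P` is a reasoned reconstruction — the
  motivating analyses do not state their per-gene df — chosen because
  it reproduces the low-pairing power dip; Satterthwaite or
  Kenward–Roger approximations are out of scope.
- Count-family power uses a linearized working covariance at random
  effect zero; it is accurate for moderate `sigma2_subj` and is the
  analogue of pseudo-likelihood contour machinery, not an exact GLMM
  power.
- No information pooling across features (the per-feature mixed model
  is the point of comparison, unlike shrinkage-based DE pipelines,
  which do not accommodate random effects).
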