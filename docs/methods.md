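# Methods

## Trial-level model

A force-matching trial presents a target force *F*_T (newtons) on a
passive finger; the participant reproduces it directly (pressing with
the other hand) or indirectly (driving the motor through a device). The
matching force *F*_M is scored as the mean force in the half-open window
[2.0, 2.5) s of the 3-s reproduction phase; the half-open convention
makes the window unambiguous at any sampling rate.

All non-attenuation processing — tactile perception of target and match,
memory for the target, the comparison that stops the press — is common
to both conditions. For fitting, those components are *not* separately
identifiable from matching forces alone, so they are absorbed into a
per-participant, per-level indirect distribution
F_I ~ Normal(mean_FI, sd_FI), exactly the quantity the indirect
condition measures. The direct condition adds a trial-to-trial
attenuation factor K ~ Normal(mean_K, sd_K):

* subtractive: F_D = K + F_I (normal; skewness identically zero);
* divisive: F_D = K · F_I (product of independent normals).

For the product, mean, variance and skewness follow from the standard
moment algebra of products of independent normals (the third central
moment is 6·mean_K·mean_FI·sd_K²·sd_FI²); the two printed SD forms
(explicit and the δ-form sd_K·sd_FI·√(1+δ_K²+δ_FI²)) agree to machine
precision whenever sd_K > 0, and the explicit form remains defined at
sd_K = 0.

### Skew-normal approximation

The product density has no closed form; the likelihood uses a
skew-normal (ξ, ω, α) matched to the first three moments. The shape
inversion is exact and closed-form: with target skewness γ and
c = (2|γ|/(4−π))^(2/3), the moment relation gives δ² = (π/2)·c/(1+c),
then α = δ/√(1−δ²), ω = sd/√(1−2δ²/π), ξ = mean − ωδ√(2/π). Round-trip
error is at machine precision (the test suite enforces ≤ 1e−8 over
|γ| ≤ 0.99). Requested |γ| above the skew-normal supremum (≈0.9953) is
clipped to 0.995 with a warning rather than erroring, so MCMC proposals
into extreme corners are merely penalized, not fatal.

Accuracy against the exact product density (adaptive quadrature over the
mixing variable, shipped as a test oracle only): the mean absolute
log-density error per observation is below 0.01 wherever the predicted
skewness stays within the regime the fits occupy (|γ| ≲ 0.22,
i.e. δ_K ≳ 8) and grows smoothly to ~0.02–0.03 by |γ| ≈ 0.34. Fitting
always uses the approximation; the quadrature density never enters the
likelihood.

Generative sampling (`sample_direct`, and the posterior predictive
machinery) draws K and F_I exactly and multiplies/adds — never the
skew-normal approximation. Negative draws are retained, not truncated:
the defaults keep Pr(F < 0) negligible and truncation would break the
moment algebra.

## Synthetic cohorts

The generator makes the latent pathway explicit. The remembered target
is m_T = (1−c)·F_T + c·L̄ + memory noise, where L̄ is the mean of the
design's levels and c ∈ [0,1] is a linear contraction — the minimal
model of the contraction-bias signature (indirect slopes < 1 with
intercepts > 0). Output noise adds perceptual, memory and comparison
SDs in quadrature plus a signal-dependent component proportional to the
expected output, reproducing the growth of matching-force SD with
amplitude. Defaults (perceptual 0.08 N, memory 0.10 N, comparison
0.08 N, c = 0.15, signal-dependent coefficient 0.05) were chosen once to
give indirect per-level SDs of ~0.15–0.25 N over 1–3.5 N targets, the
range typical of published force-matching variability; they are
calibration choices, not fitted quantities, since the individual
pathway components are not identifiable from matching forces.

Population structure: per-participant mean_K ~ Normal(1.6, 0.2)
truncated > 0, sd_K ~ half-Normal(0.15), pathway parameters normal
around their defaults with mild spreads truncated to valid ranges.
Trials are blocked by condition with pseudorandom level permutations
within blocks; everything is reproducible from a single seed, and a
YAML sidecar records every participant's generating parameters.

Gain studies simulate the direct condition only: attenuation applies to
the predicted *passive*-finger force, so the passive matching
distribution is gain-invariant and the recorded active-finger force is
passive/gain. Simulated traces ramp to a plateau over 1.5 s; plateau
noise is mean-centered within the scoring window so the window mean
recovers the trial's matching force exactly.

What passing tests on these cohorts do **not** show: robustness to
learning or adaptation across trials, non-normal outlier behaviour,
device-specific biomechanics, or any claim about real participant data —
the generator realizes exactly the distributional assumptions the
models make, so recovery tests certify the estimation machinery, not
the model's empirical truth.

## Hierarchical estimation

Likelihood: indirect trials are Normal(mean_FI[i,ℓ], sd_FI[i,ℓ]); direct
trials use the model-implied normal (subtractive) or moment-matched
skew-normal (divisive). Hierarchy: mean_K_i ~ Normal(pop_mean_K,
pop_sd_mean_K) truncated > 0 for the divisive model (untruncated for
subtractive, where K is an offset in newtons and can credibly be ≤ 0);
sd_K_i ~ half-Normal(pop_scale_sd_K).

Priors (defaults, all configurable through `PriorSpec`): pop_mean_K ~
Normal(1, 1) truncated > 0 (divisive) or Normal(0, 2) (subtractive);
between-participant SD and the sd_K population scale ~ half-Normal(1);
indirect level means ~ Normal(level value, 2 N); indirect SDs ~
half-Normal(1 N). The indirect parameters get these fixed priors rather
than their own population level: they are measured directly by the
indirect trials, and keeping them non-hierarchical makes the
fixed-indirect (gain-study) mode exact rather than approximate. A
sensitivity test doubles every prior scale and requires the population
mean_K median to move < 0.05.

Sampling: adaptive random-walk Metropolis-within-Gibbs over three block
families — per-participant attenuation blocks, per-participant-per-level
indirect blocks, and one population block — each updated with
independent accept/reject decisions (valid because the units are
conditionally independent given the rest of the state). Positive
parameters are sampled on the log scale with the Jacobian included.
Proposal scales adapt every 25 sweeps during burn-in only, toward an
acceptance rate of 0.35 (achieved rates 0.25–0.45). Initialization is
data-driven: empirical per-cell indirect means/SDs, the per-participant
direct/indirect mean ratio (or difference) for mean_K, with per-chain
jitter of 0.05 so chains start dispersed; non-finite starts are
re-drawn up to ten times.

Chain layout defaults to the paper-scale 3 chains × 10,000 kept draws
with thinning 2 after 1,000 burn-in sweeps; the test suite and the
acceptance script use a desk-scale 3 × 2,000 (thin 1) configuration,
chosen so one full fit takes seconds while population-level R̂ stays
below 1.05 on recovery cohorts. Problem sizes in the automated runs
(20-participant recovery cohorts, 8-participant predictive-calibration
cohorts, 30 participants for variability contrasts) are the package's
desk-scale choices; the generator scales to the published cohort sizes.

Diagnostics are implemented in-package and cross-checked against arviz
in tests: split-chain Gelman-Rubin R̂ (NaN with a warning for
zero-variance draws), Geyer initial-monotone-sequence ESS, and the
shortest-interval HDI (ties broken toward the smaller lower bound). DIC
uses D = −2·log L with p_D = D̄ − D(θ̄), θ̄ taken as the posterior mean on
the sampling scale (log scale for positive parameters), matching the
scale the sampler explores; the identity DIC = D̄ + p_D holds to 1e−9 by
construction and is asserted. Group comparisons subtract posterior
draws pairwise (resampling with a seeded generator to a common length
when chains differ), report the median difference and 95% HDI, and
reject a zero difference only when the HDI excludes zero.

The gain-study mode (`fit_gain_condition`) holds the per-level indirect
parameters fixed — plug-in values such as posterior medians from a
reference fit — and samples only the attenuation parameters. Plug-in
medians (rather than propagating the reference posterior) are a
deliberate simplification; they understate indirect-parameter
uncertainty slightly but keep per-gain fits independent.

## Posterior predictive checks

Replicates draw one joint posterior sample per simulation and regenerate
every cell with the exact generative process, preserving trial counts.
The default Bayesian p-value is a per-level signed check: for each
target level, the statistic is the mean matching force pooled across
participants, p_level is the proportion of replicates exceeding the
observed statistic (ties count half), and the reported value averages
p_level within condition. Because the fitted model centers on the
observed level means, a well-specified fit concentrates p near 0.5,
and systematic misfit drives it toward 0 or 1. Deviation-based
alternatives are available by flag: `'mean'`/`'sd'` (mean absolute
deviation of per-cell means/SDs from the ensemble-average prediction —
the quantity predictive-overlay figures display, but anchored to data
the per-cell parameters already track, hence ≈1 for a close fit) and
`'chisq'` (a per-draw standardized discrepancy, approximately uniform
under the model). The p-values are invariant to common rescaling of all
forces.

## Descriptive analyses

Mixed-effects regressions are implemented as a two-stage procedure:
ordinary least squares per participant on per-level summaries (means and
n−1 SDs of matching force), then population inference on the participant
coefficients — mean, t-based 95% CI, and a one-sample JZS Bayes factor
against the reference value (slope vs 1 and intercept vs 0 for force
regressions, slope vs 0 for SD regressions). For balanced designs this
is asymptotically equivalent to a random-coefficient mixed model and
keeps every step inspectable. The direct-vs-indirect comparison pairs
conditions by target level, so its slope estimates mean_K directly
under the divisive model. The JZS factor uses a Cauchy(0, √2/2) prior
on standardized effect size, evaluated by adaptive quadrature of the
noncentral-t mixture; tests cross-check it against the inverse-chi²
g-integral representation to 1e−6.

Quality control mirrors standard practice: participants whose pooled
Pearson correlation between target and matching force is ≤ 0 (or
undefined) are excluded — the threshold is a declared default, since
only the existence of such an exclusion rule is documented for the
original cohorts.

## Numerical and degenerate-input choices

* sd_K = 0 and zero-skew corners route through the explicit moment
  forms, so the divisive model degrades exactly to a scaled normal.
* Non-finite log-likelihoods from wild proposals become −∞ and are
  rejected; NaN acceptance comparisons reject.
* Per-cell SDs are undefined (NaN) for single-trial cells and carried
  as missing through the summaries.
* Sample SDs use the n−1 denominator throughout.
* All randomness flows through `numpy.random.Generator` objects seeded
  explicitly; chains receive independent `SeedSequence` spawns.

## Known limitations

* The skew-normal likelihood loses accuracy for predicted skewness
  beyond ~0.3 (δ_K ≲ 6) — outside the regime of fitted attenuation
  parameters, but a caveat for extreme populations.
* The sampler is a random-walk scheme: adequate for this model's
  dimension (a few hundred parameters), but not competitive with
  gradient-based samplers for much larger cohorts at full chain length.
* Indirect parameters are deliberately non-hierarchical; cohorts with
  very few indirect trials per cell would benefit from partial pooling
  the current model does not provide.
* DIC is the only comparison metric implemented (matching the original
  analysis); WAIC/LOO are out of scope.
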