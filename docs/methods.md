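# Methods

This note documents the models, estimators, numerical choices and known
limitations of `seqmorph`, in the order the pipeline runs.

## Stimulus design

**Model.** Stimuli are 32-token sequences over a 4-symbol alphabet drawn
from a first-order Markov chain. Three condition matrices define the
structure levels; all have uniform marginals, 25% self-transitions on the
diagonal, and theoretical Markov entropies of 0.8113 (high), 1.5613 (mid)
and 2.0 (low) bits. Because every sequence is constrained to exact 8/8/8/8
symbol counts, the zeroth-order Shannon entropy is exactly 2 bits in every
condition, so only transition structure differentiates the conditions.

**Plug-in entropy.** Per-sequence predictability is measured by the plug-in
Markov entropy of the 31 observed bigrams: row probabilities are observed
transition frequencies conditioned on the origin symbol, row weights are the
observed origin frequencies, and 0·log 0 := 0. The estimator is negatively
biased at this length (roughly −0.15 bits for the uniform matrix), which is
why the per-condition acceptance windows sit at or below the theoretical
values.

**Generation.** Rejection sampling: chains start from a uniformly drawn
token (matching the uniform marginals), are extended by row sampling, and
are accepted iff symbol counts are exact *and* the plug-in ME falls in the
condition's closed window. Draws are batched (512 chains per batch, fixed so
seeds reproduce) with a configurable attempt cap (default 10⁶). Uniqueness
of a stimulus set is defined on token strings; collisions are resampled.

**Acceptance windows.** Defaults: mid [1.48, 1.53] and low [1.80, 1.90]
bits. For the high condition, the joint constraint of exact counts and the
near-cyclic matrix couples the per-row self-transition counts, so the
plug-in estimator only attains a coarse lattice of values (…, 0.7617,
0.8230, 0.8599, …) with a gap between 0.78 and 0.81; the default high window
[0.76, 0.83] is therefore the smallest window containing the two achievable
values that bracket the theoretical 0.8113. Accepted-set means are ≈0.79
(high), ≈1.51 (mid) and ≈1.84 (low) bits. The 25% self-repetition proportion
is a property of the transition law (the diagonal), not a per-sequence hard
constraint — enforcing it jointly with exact counts can be infeasible —
and realized per-set rates are reported.

**Audio.** Tokens render to 225-ms envelopes with 15-ms raised-cosine fades
and RMS equalization, followed by 50-ms silences: 8.8 s per sequence at
44.1 kHz, written as 16-bit PCM WAV. One slot (275 ms) is a non-integer
number of samples, so slot boundaries are computed cumulatively to keep the
total duration sample-exact. The default sound bank is four pure tones; it
is a synthetic stand-in, and no acoustic matching of natural recordings is
attempted.

## Rating simulator

Latent-utility model: `u = α_s·z(condition) + ε`, ε standard logistic,
`z = 0/1/2` for low/mid/high, rating = ordinal category of `u` under fixed
cut-points (−1.5, 0, 1.5, 3, 4.5, 6 — spaced by the median subject's
condition step so the three condition means fall mid-bin for an average
subject). By construction the fitted proportional-odds model is correctly
specified with true per-subject slope α_s per unit of structure score.
α_s is log-normal (median 1.5, log-sd 0.5, configurable); with these
defaults and 21 trials per condition, the Spearman correlation between true
α_s and the estimated Wald-χ² index is ≈0.85 on average at n = 18, and
aggregate odds ratios are strongly positive — a deliberately clean
parameter-recovery surface. The simulator does not attempt to match any
real cohort's rating variance, response biases, drift, or lapses; passing
tests demonstrate that the estimators recover a correctly specified
generative model, not that real raters behave this way.

## Proportional-odds inference

**Model.** `P(Y ≤ j | x) = σ(θⱼ − x′β)` over the observed categories only,
with strictly increasing thresholds and shared slopes. With this sign
convention `exp(βₖ)` is the odds ratio of a *higher* category per unit of
predictor k.

**Fitting.** Newton scoring on the analytic gradient and observed Hessian,
with step-halving whenever a step would decrease the likelihood or disorder
the thresholds; convergence at relative log-likelihood change < 1e-8, cap
100 iterations. Starting values: empirical cumulative logits, zero slopes.
A coefficient exceeding 15 on the log-odds scale raises a separation error
(odds ratios beyond e¹⁵ are not meaningful at these sample sizes); singular
information raises a numerical error. Degenerate per-subject fits (single
observed category, separation, non-convergence) are flagged invalid and
excluded from brain-behavior regression with a logged warning.

**Repeated measures.** Inference is cluster-robust: the sandwich
`H⁻¹ (Σ_c g_c g_c′) H⁻¹` over subject-level score sums, with an
independence working model (no working-correlation nuisance parameters;
no small-sample cluster correction is applied). Both the trial-level table
and the per-subject rounded-mean table (round half away from zero) are
supported entry points; the pipeline default is trial-level, because
averaging 21 low-noise simulated trials per condition produces a separated
aggregate table.

**Parallel-lines test.** LR test of the shared-slope model against the
varying-location model. For a full-rank categorical design (distinct
predictor rows = p + 1, the three-condition case) the varying-location
optimum coincides with the saturated-by-pattern multinomial, which is how
it is computed; other designs are rejected rather than approximated.
df = p(J − 2). Simulated size under the proportional-odds generative model
is ≈5% at α = 0.05.

**Other checks.** Tolerance/VIF from regressing each predictor on the
others (balanced three-group dummies give VIF = 4/3 in closed form);
odd/even split-half reliability by presentation order with Spearman-Brown
correction 2r/(1+r), undefined (flagged) below 3 subjects or with
zero-variance halves; Shapiro-Wilk for normality of the index distribution
(constant input is an error).

## Surface statistics

**Smoothing.** One step is `W = I − (τ/d_max)(D − A)` on the vertex graph
(τ = 0.5): symmetric and doubly stochastic, hence exactly mean-preserving
on a closed mesh, positivity-preserving, with eigenvalues in [0, 1] so map
variance is non-increasing. The iteration count for a requested FWHM is
calibrated by diffusing a unit impulse and measuring the geodesic full
width at half maximum of its profile (bin-averaged by distance, linear
interpolation at half maximum); 10-mm FWHM on the default mesh needs ~6
iterations and lands within the 20% calibration band. fwhm = 0 is the
identity; an FWHM beyond the mesh extent is an error.

**Vertex-wise GLM.** At each vertex, OLS of thickness on intercept +
sensitivity + age (+ sex optionally); t with n − p − 1 df, two-sided p.
Zero-residual vertices give t = ±∞ (p → 0) rather than NaN. t-maps are
invariant to thickness rescaling.

**Cluster-extent FWE.** Supra-threshold vertices (two-sided p < 0.05 on
the sensitivity t; both signs computed, components separated by sign;
adjacency = triangle edges) form clusters whose extents are compared to the
permutation null of the *maximum* extent over either sign: the sensitivity
covariate is permuted across subjects (age fixed), the t-map refitted, and
corrected p = (1 + #{null max ≥ observed size})/(n_mc + 1). The extent
threshold is thus derived from the data's own null distribution rather
than imported as a mesh-specific constant, and the permutation null
replaces synthesized-noise Monte-Carlo simulation — a deliberate
methodological substitution with the same max-statistic FWE logic and fewer
distributional assumptions. Empirical FWE on 200 null studies (18 subjects,
2562-vertex icosphere, 200 permutations) is ≈0.04. With spatially coherent
noise the null maximum extent is large, so extent-based power favors
planted effects broader than the noise correlation length (the canonical
planted example uses a 20-mm disc at 0.15 mm per unit sensitivity).

**Mesh test-bed.** The default mesh is a subdivision-4 geodesic icosphere
(2562 vertices, 100-mm diameter) — small enough for desk-scale Monte-Carlo,
with enough vertices for cluster geometry. It has no cortical folding, no
boundary, and uniform vertex density; conclusions about FWE calibration
transfer to real meshes only insofar as the max-statistic permutation logic
is geometry-agnostic.

**Thickness simulator.** thickness = 2.5 mm baseline − 0.01 mm/yr ×
(age − mean age) + planted disc effects + smoothed Gaussian noise
(sd 0.1 mm after renormalization, 12-mm coherence). Noise is renormalized
to unit variance after smoothing so `noise_sd` is the realized per-vertex
sd, not a pre-smoothing one.

## ROI statistics

Per-ROI OLS of the measure on sensitivity + age (+ ICV for volumes, as a
linear covariate, not a ratio; + sex optionally), two-sided p for the
sensitivity slope; Benjamini-Hochberg step-up across the 16 (or 7) ROIs at
q = 0.05 (delegated to statsmodels, verified against hand-computed step-up
examples). The ROI simulator plants proportional ICV scaling and optional
sensitivity effects on plausible per-structure baselines; under fully null
simulations the probability of any BH discovery stays at ≈5%.

## Pipeline

A YAML-serializable config tree drives all stages; every stochastic stage
has an explicit seed (derivable from one master seed, all below 2³¹). Runs
write a manifest with the SHA-256 of every declared output; reruns with the
same config are byte-identical for all TSV outputs. Units project-wide:
mm / mm² / mm³; vertex ids 0-based; entropy windows closed intervals.

## Problem sizes

Defaults mirror the emulated study design: 18 subjects, 21 trials per
condition and category, 21 sequences per structure level, 2562-vertex mesh,
10-mm smoothing, 1000 permutations for single analyses. Calibration runs
(FWE, test size) use 200 replicates × 200 permutations, chosen as the
smallest sizes at which binomial error bands around 5% are informative.

## Known limitations

- The rating simulator's inter-subject variance parameters are chosen for
  testability, not fitted to any cohort.
- The cluster-forming threshold's sidedness is a design choice (two-sided
  with sign-separated clusters); one-sided variants would need a different
  null maximum.
- The parallel-lines test is exact only for full-rank categorical designs.
- No inter-subject surface registration or anatomical labeling is provided;
  maps are assumed vertex-aligned on a shared mesh.
- The sandwich covariance uses no small-sample cluster correction; with 18
  clusters, Wald tests can be mildly liberal.
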