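# Methods

This note documents the models, algorithms and numerical choices behind
`presaccsf`, and what the synthetic study does and does not establish.

## The CSF model and psychometric likelihood

Contrast sensitivity `S` (reciprocal of contrast threshold) as a function of
spatial frequency `sf` (cpd) is a three-parameter log-parabola:

    log10 S(sf) = log10(peakCS) − 4·log10(2) · ((log10 sf − log10 peakSF) / b)²

`peakCS` is the peak sensitivity (dimensionless), `peakSF` the spatial
frequency of the peak (cpd), and `b` the full width at half maximum of the
parabola.  The 4·log10(2) factor makes S fall to peakCS/2 exactly at
log10(peakSF) ± b/2, so `b` is the FWHM measured in log10-SF *decades*.  We
implement the equation literally in decades and expose
`bandwidth_octaves()` (= decades / log10 2) for the more conventional octave
reading; the prior truncation range for `b`, [1, 9], is interpreted on the
same decade scale as the formula.  This is a genuine ambiguity of the
log-parabola literature (some parameterisations insert a log10(2·…)
conversion); we resolve it in favour of the printed formula and document the
conversion rather than changing the model.

The trial likelihood is a Weibull-family psychometric function for a
two-alternative orientation discrimination:

    p(correct | θ, sf, c) = g + (1 − g − λ/2)(1 − exp(−(c·S(sf,θ))^β))

with fixed (never fitted) guess rate g = 0.5, lapse rate λ = 0.04 and slope
β = 2; its range is (0.5, 0.98].  Incorrect responses carry the complementary
probability.

All fitting operates on the log10 parameter vector
θ = (log10 peakCS, log10 peakSF, log10 b), confined to the truncation boxes
[log10 1.05, log10 1050] × [log10 0.1, log10 5] × [log10 1, log10 9].
These boxes are shared by the uniform BIP prior, the discrete parameter
grids, and the hierarchical hyperpriors, which keeps the two fitting stages
consistent.

### Key attributes

From a fitted θ we derive: peak-CS, peak-SF, bandwidth (FWHM), the
cutoff-SF — the larger root of S(sf) = 1, in closed form
log10(cutoff) = log10(peakSF) + b·sqrt(log10(peakCS)/(4·log10 2)), flagged
undefined (NaN) if peakCS < 1 — and the AULCSF, the integral of
max(log10 S, 0) over log10 sf across the tested range 0.5–16 cpd.  Flooring
the integrand at zero makes AULCSF an exact "window of visibility" measure
(area where sensitivity exceeds 1) and gives the analytic value 0 at
peakCS = 1; since the integrand is a clipped parabola, we restrict adaptive
quadrature (relative tolerance 1e-6) to the interval between the two unit
crossings, where it is smooth.

## Adaptive stimulus placement (qCSF)

The stimulus space is 60 contrast levels log-spaced on [0.001, 1] crossed
with 12 spatial frequencies log-spaced on [0.5, 16] cpd (720 candidates).
A discrete posterior over a parameter grid (default 30 × 25 × 15 cells over
the truncation boxes, uniform initial prior) is updated by Bayes' rule after
every included trial, and the next stimulus maximises the one-step expected
reduction in Shannon entropy of that posterior.  We use the greedy
(one-step-ahead) rule; no multi-step lookahead.

Numerically, the expected entropy reduction equals the mutual information
between the response and the parameters, I(θ; r) = H(r) − E_θ[H(r|θ)].  The
per-cell binary response entropies H(r|θ) are precomputed once per grid, so
scoring all 720 candidates costs two matrix–vector products per trial.  Both
routes (the defining posterior-entropy formula and the identity) are
implemented and tested for equality.  Exact ties in the argmax (which occur
only in degenerate cases such as a point-mass posterior) are broken toward
the lowest contrast, then the lowest SF, by ordering the flattened stimulus
array contrast-major.  Entropies are in bits; the base does not affect the
argmax.  Grid resolution and the uniform within-session prior are free
configuration (they are not determined by the experimental design); the
defaults keep per-trial selection well under 50 ms on one CPU.

## Synthetic observers and gaze

The generator emulates the full experiment: 12 participants × 4 cardinal
locations at 6° eccentricity (left/right simulated separately with a shared
ground truth and merged to "horizontal" for analysis) × 2 instructions
(fixation, saccade preparation), 300 included trials per analysis individual
(participant × location × instruction; 72 units).  Trials per individual is
a free design choice (the experiment reports only totals); 300 gives
per-individual posteriors tight enough for the hierarchy to matter without
dominating runtime.

Ground-truth CSFs are built multiplicatively from a population base
(peakCS 40, peakSF 1.3 cpd, bandwidth 2.0 decades — ordinary parafoveal
values for this model family), location factors on peak-CS ordering
horizontal > lower > upper (1.25 / 0.95 / 0.75), presaccadic factors
(peak-CS × 1.40 horizontal vs × 1.15 vertical; peak-SF × 1.25; bandwidth
× 0.85), and lognormal participant noise (SD 0.08 / 0.05 / 0.03 log10 units
per parameter).  These effect sizes are configuration, not code: they define
a population with the qualitative anisotropies and presaccadic effects the
pipeline is meant to detect (no numeric ground truth exists to copy), and
they stay inside the truncation boxes so clamping (which warns) never fires
at the defaults.

Gaze traces are 1 kHz, from 300 ms before cue onset to 900 ms after.
Fixational drift is a Gaussian random walk (step SD 0.0015°/sample — ~0.05°
RMS over a trial).  On saccade trials a minimum-jerk position ramp starts at
a latency drawn per direction from Gaussians whose means are the measured
group means (up 209.2, down 228.0, horizontal 217.2 ms; SD 25 ms); ramp
duration is 21 + 2.2·amplitude ms clipped to 30–50 ms, and the landing point
gets isotropic Gaussian scatter (SD 0.5°).  Any profile with a clear
velocity peak would satisfy the detector; minimum jerk is simply a standard
smooth kinematic.  The generator does *not* model microsaccades, drift with
realistic spectra, blinks, pupil artefacts, head motion, or response-time
structure — so the eye-movement tests establish detector correctness on
clean kinematics, not robustness to messy recordings.

Responses are Bernoulli draws from the psychometric function at the true
parameters; they are therefore perfectly calibrated by construction, which
the suite verifies by decile binning.  Excluded trials are re-presented at
the end of the block and never update the adaptive posterior; a session ends
after the target number of included trials or three times that many
presentations (whichever comes first), so forced-exclusion configurations
terminate.

## Saccade detection and trial inclusion

Saccades are detected offline with a velocity-threshold algorithm in the
Engbert–Kliegl family: sample-to-sample velocity (np.gradient), smoothed
with a centred 20-sample moving average; threshold = median(speed) +
3·σ̂ with σ̂ the MAD-based robust SD (1.4826·MAD) of the smoothed speed;
maximal supra-threshold runs of ≥ 20 ms become events with onset/offset at
the threshold crossings.  We threshold the scalar speed by default (the
elliptic component-wise criterion is available via ``criterion="elliptic"``);
for cardinal saccades the two are practically equivalent.  The robust-SD
estimator is a deliberate reading of a condensed verbal description of the
threshold ("3 standard deviations" about the median of the smoothed
velocity); it is the configurable, documented choice here.

Trial inclusion applies, in order: stable fixation within 1.75° (until the
response phase on fixation trials, until cue onset on saccade trials);
saccade latency within [150, 350] ms of cue onset; landing within 2.25° of
the target centre; onset after stimulus offset (cue + 170 ms).  The first
violated rule labels the trial; a saccade trial with no detected saccade is
labelled `latency_long`.  The online fixation-break abort of the real
experiment is re-expressed as the same offline `refix_abort` rule.

## Two-stage Bayesian fitting

**Stage 1 — BIP.**  Each individual is fit independently: the posterior over
the parameter grid is proportional to the product of trial likelihoods under
a uniform prior on the truncation box.  Per-individual posterior means, SDs
and 3×3 covariances feed the population summaries: `mu0`/`sigma0` are the
across-individual averages of the means and SDs; `Sigma_BIP` is the
between-individual covariance of the posterior means (population spread);
`phi_BIP` is the average within-individual posterior covariance (measurement
uncertainty).  The assignment of the two covariance roles is our explicit
construction (the recipe is not fully pinned down by the source analysis
description); it matches their roles at the population and individual levels
of the hierarchy.  Both are symmetrised and jittered (+1e-8·I, escalating)
to positive definite if needed.

**Stage 2 — HBM.**  The three-level Gaussian hierarchy is

    μ ~ ΠN(mu0_k, sigma0_k) truncated to the boxes,   Σ⁻¹ ~ W(Σ_BIP⁻¹/v, v)
    ρ_i | μ, Σ ~ N(μ, Σ),                              φ⁻¹ ~ W(φ_BIP⁻¹/v, v)
    θ_i | ρ_i, φ ~ N(ρ_i, φ),      r ~ Bernoulli(p(correct | θ_i, sf, c))

with v = 4 and the Wishart convention that W(Y, v) has *expected precision*
v·(scale) = Y, i.e. the prior mean precision equals the BIP-derived
precision.  There is one test per individual (J = 1).  θ and μ are truncated
to the boxes; ρ is left untruncated (it is a latent mean, not a CSF
evaluated on data).  The "mixture of Gaussians" phrasing of the hierarchy is
implemented as this standard generative chain — the unique three-level
Gaussian reading consistent with the model's full parameter list.

Sampling is Metropolis-within-Gibbs, written here rather than delegated to a
PPL so the computation is owned end to end:

* θ_i: random-walk Metropolis, batched over individuals, proposal covariance
  = the individual's BIP posterior covariance, with a per-individual scalar
  step adapted by Robbins–Monro toward 35% acceptance during the adaptation
  phase and frozen afterwards;
* ρ_i, μ: conjugate Gaussian draws (μ truncated by rejection; the box is
  wide relative to the conditional, so rejection virtually never recurses);
* Σ⁻¹, φ⁻¹: conjugate Wishart draws (df v + I, scale from the prior scale
  plus the scatter matrix), via scipy.

Chains start from the BIP means jittered by one BIP posterior SD
(overdispersed starts for an honest between-chain diagnostic).  The
reference schedule is 3 chains × 2,000 retained draws (6,000 total) after
500,000 adaptation and 20,000 burn-in steps; the pipeline's default reduced
schedule keeps the same retained counts with 1,500 adaptation and 1,500
burn-in sweeps and a thinning of 5, chosen so retained chains are well mixed
(all Gelman–Rubin statistics comfortably below the 1.05 criterion on the
default synthetic study) while a full fit of 72 × 300 trials completes in
about a minute on one CPU.  Convergence is assessed per scalar parameter
with the potential scale reduction factor (between/within-chain variance);
the run is flagged, not failed, when any statistic is ≥ 1.05.

Final estimates average each individual's θ over all 6,000 pooled draws;
attributes are computed from the averaged parameters.  On the default
synthetic study the HBM estimates are both accurate (all 72 log10 peak-CS
errors ≤ 0.15) and strictly better than the BIP on mean absolute error —
the shrinkage the hierarchy exists to provide.

Counting parameters explicitly, the full model has 6I + 15 = 447 scalars at
I = 72 (θ and ρ, 3 each per individual, plus μ and the 6 free entries of
each covariance); the flat-CSF null has one constant sensitivity per
individual (72).  The likelihood-ratio test evaluates the full model's
likelihood at the final estimates, the null at the across-SF mean of each
fitted CSF's sensitivity over the 12 tested frequencies, and refers
2·ΔlogL to χ²(447 − 72).  A published count of 453 for a comparable model
does not follow from this parameter list; we report our explicit count.

## Permutation statistics

p values are permutation-based with 1,000 shuffles by default:
p = max(#{null ≥ observed}, 1)/n, giving the exact floor 0.001.  Numerical
ties at the observed value count as ≥ (a 1e-9 relative tolerance), so
enumerable toy problems reproduce exact enumeration.  The repeated-measures
F statistics use the standard within-subject decomposition (verified against
pingouin); the null for a main effect permutes that factor's labels within
each participant × other-factor stratum (exchangeable under that effect's
null even in the presence of the other effect); the interaction null
shuffles all cells within a participant jointly.  Restricted interaction
permutation schemes exist, but with no exact exchangeability available for
interactions we use the simple whole-cell scheme and verify its type-I
calibration empirically (≈5% at α = .05 over 200 null replicates).
Sphericity corrections are unnecessary under a permutation null and are
omitted.  Paired comparisons use sign-flip nulls, two-sided on |t|, with
Cohen's d = mean(diff)/SD(diff); all-zero differences give t = 0, p = 1,
while zero-variance non-zero differences are flagged undefined.
Benjamini–Hochberg FDR correction (statsmodels) is applied within each
attribute's post hoc family.  Bayes factors are out of scope; the result
schema reserves a field.

The presaccadic benefit is the ratio of saccade to fixation sensitivity from
the fitted CSFs, evaluated on 51 log-spaced SFs over 0.5–16 cpd per
participant × location; the per-SF one-way location ANOVA runs on the log
ratio (the location-null hypothesis is the same on either scale, and the log
is symmetric in enhancement/suppression).  The summary reports, per
location, the SF of the peak group-mean log benefit and the group-mean
fixation peak-SF; with a pure upward peak-SF shift the benefit is monotone
increasing in log SF, so its peak sits above the fixation peak-SF.

## Reproducibility and problem sizes

Every random quantity flows from an explicit seed: the pipeline derives
per-stage seeds from the master seed, the experiment spawns one independent
stream per individual (numpy SeedSequence), and MCMC chains are seeded
independently.  Identical seeds reproduce byte-identical CSVs; downstream
stages re-run from persisted artifacts bit-exactly.

Default problem sizes are the study design (12 × 3 × 2 × 300 included
trials; 72 units; 3 × 2,000 retained draws).  The test-suite and the
acceptance script run this full design with the reduced MCMC schedule;
smaller grids and trial counts are used in unit tests where only the logic
is at stake.  The type-I calibration uses 200 replicates at 200 permutations
each — enough to place the rejection rate inside a 99% binomial interval
around 5%.

## Known limitations

* The synthetic generator's effect sizes are invented plumbing; passing
  recovery tests shows the pipeline recovers what it is fed under its own
  model, not that the model is right for human data (responses here are
  generated from the same psychometric family that is fitted).
* Gaze simulation omits microsaccades, blinks and realistic noise spectra;
  detector performance on real recordings will be worse than on these
  traces.
* The BIP grid induces discretisation error (< 0.01 log10 units at the
  default resolution on simulated data, by the doubling test); extremely
  peaked posteriors (very large trial counts) would need finer grids.
* ρ is untruncated and μ truncated per draw; whether the original analysis
  enforced truncation per draw or only at initialisation is unknowable from
  its description.  The choice is inconsequential here because posteriors
  sit far from the box edges.
* J = 1 (one test per individual) is hard-coded into the data layout;
  multi-test designs and condition-structured covariances are out of scope.
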