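# Methods

This note records the model, the estimation procedure, and the design and
numerical choices made where the underlying description left room.

## The paradigm

The reinstatement experiment is encoded as 36 atomic trials:
acquisition (trials 1–3, CS+US), test 1 (trial 4), extinction day 1
(trials 5–23) and day 2 (trials 24–33), test 2 (trial 34), an unsignaled
shock (trial 35, US without CS), and test 3 (trial 36).  The stimulus is a
two-dimensional salience vector: CS = 1 whenever the tone is presented
(all trials except 35), context = 0.2 on every trial.  A 24 h gap between
experimental days maps to 20 abstract time units; consecutive trials within
a day are 1 unit apart.  The intra-day spacing is not dictated by the
experimental description (only the 24 h ↔ 20 units equivalence is); 1 unit
is the package's choice and is configurable.  Day boundaries follow the
experimental calendar, so the boundary between extinction days (trials
23/24) also receives the 20-unit gap even though both trials belong to the
extinction block.

Observed conditioned-response traces (freezing proportions in [0, 1]) are
divided by their per-animal maximum before fitting; the discrimination
index between two test phases is DI = CR(t)/[CR(t)+CR(t′)], an error when
both responses are zero (0/0 carries no behavioural meaning).

## The latent cause model

State per agent: a growing set of latent causes, each with (i) the list of
trials MAP-assigned to it, (ii) per-dimension stimulus sums/counts, and
(iii) an associative weight vector (w_cs, w_context).

Per trial, in order:

1. **Prior.**  Temporally discounted CRP over existing causes (kernel
   (Δτ)^−g applied to each past assigned trial) plus mass α on a new-cause
   slot while fewer than K causes exist.
2. **Stimulus-only posterior and response.**  The posterior given the
   stimulus likelihood alone — Gaussian per dimension with the cause's
   empirical mean and fixed variance σx²; the new-cause slot uses mean 0
   (it has generated no observation) — determines the anticipatory CR:
   CR = P(N(E[r], λ) > θ) with E[r] = Σ_k post_k (w_k·x), using pre-update
   weights.  Freezing is measured during the tone before the outcome, so
   the response must not see the trial's outcome; the within-trial ordering
   is the package's choice, as the source description leaves it open.
3. **EM loop** (a fixed number of iterations): E-step combines the fixed
   prior and stimulus likelihood with the outcome likelihood
   N(r; w_k·x, σr²); the M-step applies the posterior-weighted
   Rescorla–Wagner update w_k ← w_k + η·post_k·(r − w_k·x)·x to every
   cause, including the prospective new cause (which starts each trial at
   w0).  The absence of a shock is treated as an observed outcome r = 0,
   so extinction trials drive weights down through the same update.
4. **Assignment.**  The MAP cause of the final posterior (ties to the
   lowest index) absorbs the trial's stimulus statistics; if the MAP is the
   new-cause slot it is instantiated, keeping the weights it learned within
   the trial.  Letting a cause learn from its very first trial means a
   cause created on a shock trial already carries that association; the
   alternative (resetting to w0 at instantiation) makes acquisition
   essentially silent for agents with a small learning rate and cannot
   produce the strong post-acquisition responding seen in slow-learning
   parameter regimes.

λ is treated as the variance of the response-emission Gaussian (it is
also referred to as a response gain; the emission formula fixes the
interpretation used here).  Everything above is deterministic; the
simulator is bit-reproducible, and a numba-compiled kernel replicates the
reference implementation exactly (tested to ~1e−10 on random parameter
sets across the bound box).

## Estimation

The ten parameters are sampled on a bounded box with a uniform prior; the
two integer parameters (EM iterations, K) are relaxed to the reals and
mapped back with a ceiling both inside the objective and at point-estimate
time ("rounded toward infinity").  The log target is the sum over trials of
the log half-normal density (scale 0.3) of the squared difference between
the simulated and observed CR.

The published bounds/initial-guess table for this estimation is not part of
the available text; the shipped box is chosen wide enough to cover all
reported estimates (α ∈ (0,5], g ∈ [0,2], η ∈ (0,1], EM ∈ {1..10},
w0 ∈ [−0.05,0.05], σr², σx² ∈ (0,5], θ ∈ [0,0.1], λ ∈ (0,0.05],
K ∈ {1..40}); strictly positive parameters get a small positive lower edge.
The initial guess defaults to mid-bounds.  Bounds, guesses and all loop
settings live in a flat key-value config file
(`src/latentcause/config/estimation_defaults.yaml`).

**Sampler.**  Univariate slice sampling swept over the ten coordinates
(Neal 2003): initial bracket width (upper−lower)/50, stepping-out with the
total number of expansions capped (default 4) and split uniformly at random
between the two sides — a capped stepping-out that preserves the correct
invariant distribution — followed by shrinkage, with brackets clamped to
the box.  The cap bounds the cost of coordinates along which the
conditional target is flat (e.g. K whenever it never binds).  Two exact
shortcuts: the objective evaluation aborts once its running total plus the
best-possible remainder is certainly below the slice level (slice sampling
only compares against that level), and updates of θ and λ — which enter
only the response read-out — reuse the expected-shock trace of the
unchanged latent dynamics.

A chain runs 200,000 sweeps by default, retains every 100th, and discards
the first 1000 retained draws as burn-in, leaving 1000 samples.
Convergence is assessed by a split-chain Gelman–Rubin statistic (first vs
second half of the single chain's retained draws; degenerate parameters
yield NaN and count as unconverged).  Point estimates are the centre of the
maximal-count histogram bin at the Shimazaki–Shinomoto optimal width
(exhaustive search over 2–100 bins minimizing
(2·mean(counts) − var(counts))/Δ²; ties prefer the smaller width, and the
lower bin wins count ties).

**Acceptance loop.**  After each round the trace simulated at the point
estimate is scored per trial; a fit is accepted when R̂ < 1.1 for every
parameter and every trial's error likelihood is at least its threshold
(1.0 on acquisition trials, 0.25 on the three test trials, 0.5 elsewhere).
The source description literally reads as terminating when likelihoods are
*smaller* than the thresholds, which would reward bad fits; it is read as a
typo and implemented with the ≥ direction (configurable).  Unaccepted
rounds resume the chain from its last state with the samples kept; an
animal not accepted within 20 rounds is an anomaly.  Seeds: one master seed
per animal, per-round sub-seeds derived via `SeedSequence`.

## Synthetic cohorts

Group centres default to the reported group-level parameter sets of the
four experimental groups (6/12 months × control/knock-in; α centres
2.4/1.1/1.1/1.0) with the reported per-group animal counts (15/12/20/18).
Per-animal parameters multiply the centre by a log-normal jitter (default
10%, keeping positivity), clipped to the estimation bounds with integers
re-rounded.  Observation noise is additive zero-mean Gaussian on the CR
(default sd 0.05), clipped to [0,1], then max-normalized — the same
normalization applied to observed traces.  No freezing-measurement noise
model is given for the original data; truncated Gaussian noise of that
scale is the package's choice of a realistic magnitude.

The generator emulates trial-level freezing proportions only: it does not
model within-session freezing kinetics, preCS (context-only) freezing, or
inter-animal correlations, so tests passing on synthetic cohorts show the
pipeline's correctness and recoverability under the model's own
assumptions, not fidelity to every property of real freezing data.

## Internal-state summaries

Causes are categorized by the trial on which they were first inferred:
acquisition (trials 1–3), extinction block (4–34, i.e. test 1 through
test 2), post-extinction (35–36).  Summaries report, per category, the
cause count, the summed stimulus-only posterior at test 3 (the belief
relevant to the emitted response; the evaluation trial is configurable,
e.g. test 1 for acquisition-cause probes), and the summed w_cs and
w_context at test 3.  Posterior mass on a prospective new cause that was
not instantiated at the evaluation trial is counted toward the category
containing that trial, so the three categories always partition the
probability mass.

## Group statistics

Thin wrappers over scipy with conventions fixed: Mann–Whitney U is reported
as min(U, U′) (label-order invariant, matching the magnitude convention of
the reported statistics), exact p for small tie-free samples and the
tie-corrected normal approximation otherwise; Spearman uses average ranks;
the paired t is the one-sample t of (first − second) against 0 with
Cohen's d of the differences.  ANCOVA and mixed ANOVA are out of scope.

## Desk-scale test protocol and limitations

The test suite runs reduced problem sizes: recovery experiments use n = 6
animals per group, 20,000-sweep chains thinned by 10 (1000 post-burn-in
draws), a single sampling round, and a stepping-out cap of 2 — the same
sampler with cheaper settings.  At the reported group centres the error
likelihood is nearly flat along α over much of the box (small σx² makes an
exactly matching existing cause dominate the mean-zero new-cause stimulus
likelihood, and the response read-out saturates at the test trials where α
shifts the posterior most), so single-trace α estimates at desk scale are
highly variable; group-median comparisons at these sizes are correspondingly
noisy.  Identifiability is materially better in mid-box parameter regimes
(larger σx²), which the recovery property tests also exercise.

Known limitations: single-chain R̂ only (the original analysis also ran one
chain per animal); no particle-filter or full Gibbs posterior over
assignment histories (inference is per-trial with hard-assigned history);
no alternative internal models; estimates are one of possibly many
solutions when the target is multimodal.
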