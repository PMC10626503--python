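# Methods

`evacc` implements a complete analysis chain for studying distributed
evidence accumulation in two-alternative forced-choice (2AFC) contrast
discrimination: synthetic task/spike generation with known ground truth,
single-neuron selectivity statistics, demixed PCA, accumulator microcircuit
models fit as recurrent switching linear dynamical systems (rSLDS), AIC model
comparison, and intrinsic-timescale estimation. This note documents the
models, the parameter choices that matter, the numerical decisions, and the
limits of what the synthetic validation shows.

## Task and synthetic data

Trials follow the 2AFC contrast task: gratings of contrast
{0, 0.25, 0.5, 1} on the left and right screens, signed evidence
`e = c_R − c_L` (nine levels, −1…1 in steps of 0.25), responses left / right
/ nogo, a hit when the higher-contrast side is chosen (nogo is correct only
for blank trials; equal non-zero contrasts reward either turn). Trials are
spaced 2.5 s apart so every trial has a −0.9…−0.1 s baseline window.
Recordings are treated as left-hemisphere, so the contralateral screen is the
right one; contra-preferring neurons load positively on the right-choice
latent (or positively on the single decision variable).

`simulate_accumulator_dataset` drives spikes from an accumulator latent: the
latent starts at 0 at stimulus onset + 0.1 s (a fixed visual-encoding delay),
evolves under the accumulation dynamics with a constant input derived from
the contrasts, commits at the first boundary crossing (which sets choice and
reaction time), freezes into a movement state for 50 ms, and emits Poisson
spikes through a softplus map; between trials the rate is the softplus
baseline. Trials that never cross within 1 s are labeled nogo and fall out of
every reaction-time-filtered analysis.

Default study conditions (one decision per generator family, chosen for
realism and kept fixed):

- single accumulator: `A_acc = 0.98`, `V_acc = 0.05`, `Q_acc = 0.01`
  (per-10 ms step). With boundary ±1 these give ~45% of trials inside the
  0.15–0.5 s reaction-time analysis window and >90% accuracy at full
  contrast.
- independent race: diagonal `A_acc = 0.98`, `V_acc = 0.03`, `Q_acc = 0.01`.
- dependent race: `A_diag = 0.95` with cross-coupling `A_off = +0.1`
  (co-modulated accumulators) and feedforward input mixing `V_off = −0.02`.
  Mutual *inhibition* was deliberately not used as the reference condition:
  with `A_off < 0` the race collapses onto its unstable difference mode and
  becomes empirically indistinguishable from a single accumulator (its sum
  mode is fast and carries almost no variance), so no identification study
  can succeed there. Positive coupling produces correlated accumulators,
  which neither the single model (which forces the two preference groups to
  be anticorrelated) nor the independent race (uncorrelated) can mimic.
- emissions: shared offset `d = 10` (≈10 Hz baseline) and per-neuron gains
  drawn uniformly from 16–24 Hz per latent unit (peak rates ≈30–40 Hz,
  typical of ramping decision neurons). Weaker rates leave the recurrent
  strength and the architecture only weakly identified in 4-neuron
  subpopulations — the likelihood has a near-flat ridge along the
  (persistence, emission-scale) direction.
- the pipeline's demonstration regions use `Q_acc = 0.02`, which yields
  mouse-like psychometric functions (~20–30% wrong-side choices at the
  lowest contrast, `p_wrong ≈ 1/(1+exp(2VB/Q))`); with `Q = 0.01` errors
  surface only as omissions and choice probability is undefined within
  contrast cells.

`make_selectivity_cohort` generates inhomogeneous-Poisson neurons whose rate
after onset+delay is baseline plus gains times (contra contrast, choice side,
signed evidence, outcome sign); it is the fixture generator for the
selectivity and demixing statistics. `make_ar1_population` gives every neuron
an independent stationary AR(1) latent (true timescale `−Δ/ln a`) and
linear-rate Poisson counts; defaults (100 neurons, gain 25 Hz, offset 30 Hz,
5000 trials) were set by a precision analysis so the decay fit resolves
timescales to well under 15% across `a = 0.90–0.99`. An independent latent
per neuron matters: with one shared latent the pooled curve inherits an
irreducible correlation-sampling noise floor that no neuron count averages
away.

## Selectivity statistics

All combined-condition metrics bin spikes at 5 ms, smooth with a causal
half-Gaussian kernel (SD 20 ms), and z-score each neuron against its
−0.9…−0.1 s baseline mean and SD pooled over trials and bins. The auROC
between two samples is the normalized Mann–Whitney U (probability that a
draw from the second sample exceeds one from the first, ties counting ½),
computed with a vectorized tie-aware ranking so the shuffle nulls stay cheap.
Metric groupings: stimulus selectivity (12 choice × left-contrast groups,
contra contrast present vs absent), choice probability (12 unequal contrast
pairs, right vs left choice, −0.3…0.1 s movement-aligned), detect probability
(same pairs, hit vs miss, −0.1…0.3 s), evidence selectivity (each of the 8
upper evidence levels against all lower levels pooled). Conditions are
weighted by trial count; a condition needs at least 3 trials per side.
Significance uses 100 within-group label shuffles, a 2.5–97.5 percentile
band, and a two-significant-neighbors rule (runs of ≥3 bins).

Latency is the first stimulus-epoch time (0–0.5 s) at which the
population-mean rate (100 ms causal boxcar, Go trials with RT 0.15–0.5 s)
differs from the −0.1 s baseline point (Mann–Whitney, p < 0.05, ≥2
significant neighbors). Because the boxcar correlates neighboring bins, the
procedure has an appreciable false-onset rate on stationary data (~20–25% of
cohorts); it is intended for populations with genuine onsets, and the tests
assert its behavior as a rate, not per cohort.

## Demixed PCA and clustering

Trial-averaged rates form a tensor (neurons × 4 contra contrasts ordered
1→0 × hit/miss × time, −0.1…0.3 s at 10 ms); neurons averaging fewer than
one spike between stimulus onset and wheel movement are masked, and empty
cells are imputed with the condition-independent mean. The tensor splits
exactly into condition-independent, stimulus, decision and interaction
marginalizations. Components minimize
`Σ_α ‖X_α − F_α D_α X‖²` by reduced-rank ridge regression (ridge chosen by
generalized cross-validation when not given); a budget of 20 components is
allocated by explained variance with a floor of 2 per marginalization —
without the floor, small noisy cohorts hand every component to the
high-variance stimulus/interaction terms and the decision axis gets none.
Per-neuron `R²_st`/`R²_dt` measure reconstruction of the full (centered)
tensor through each marginalization's components, normalized by deviation
from the neuron's grand mean. Fuzzy C-means (fuzzifier 2, tolerance 1e−6,
≤300 iterations, seeded Dirichlet initialization) groups neurons in the
`(R²_st, R²_dt)` plane; the centroid with the largest st−dt margin is the
stimulus cluster, the smallest the decision cluster, the rest interaction.

A caveat measured on synthetic cohorts: accumulator-driven neurons are
evidence-driven and hence strongly stimulus-coupled in this tensor, so the
clustering does not separate them from stimulus-only neurons the way it
separates large mixed real populations. The pipeline therefore gates its
"DDM-like" screen on significant choice probability, significant evidence
selectivity and an automated ramping criterion (significant positive rate
slope over 0–0.3 s on preferred-choice trials), reporting cluster membership
alongside.

## Accumulator models (rSLDS)

Three architectures share one structure: per-state linear-Gaussian latent
dynamics `x_t ~ N(A_z x_{t−1} + V_z u_t, Q_z)` (offset fixed at 0), discrete
transitions `p(z_t | x_{t−1}) ∝ exp{γ(R x_{t−1} + r_eff(t))}` with γ = 1 and
boundary B = 1, and Poisson emissions `y_t ~ Poisson(softplus(C x_t + d)Δt)`
with the scalar offset shared across neurons. The single accumulator (K = 3,
D = 1) integrates the contrast difference between boundaries ±B; the
independent race (K = 3, D = 2, diagonal dynamics) integrates the two streams
toward +B; the dependent race (K = 5, D = 2, full dynamics) adds positive and
negative crossing states per accumulator, with negative crossings committing
to the opposite side. Movement states have A = I, V = 0 and are sticky
(absorbing) once entered. Collapsing boundaries scale the movement logit
offsets: exponentially, `f(t) = β + (1−β)exp(−t/τ_c)` with τ_c in 10 ms
steps (grid {50, 100} spanning 0.5–1 s), or linearly at rate β per step.

Fitting uses Go trials with unequal contrasts and RT strictly inside
0.15–0.5 s, binned at Δt = 10 ms from stimulus onset + latency (end of the
visual-encoding phase) to wheel movement + 50 ms. The observed movement time
enters the discrete chain as evidence: movement states are only available
from the movement bin on, matching the committed choice.

### Variational Laplace-EM

Each iteration alternates:

1. **Continuous E-step.** The variational factor over each trial's latent
   path is the exact posterior under the expected-dynamics Gaussian prior
   (discrete posterior held fixed) and the Poisson likelihood, sampled by
   elliptical slice sampling with persistent chains (30 kept samples per
   trial per iteration). The latent-to-transition coupling is left out of
   this factor (a structured mean-field choice): including it measurably
   shrinks latent paths and attenuates the recovered recurrent strength,
   while a pure Laplace (mode + curvature) E-step underestimates the
   posterior spread under weak 4-neuron Poisson observations and attenuates
   it further. Sampling the exact structured posterior removes both biases.
2. **Discrete E-step.** Exact forward–backward smoothing at the posterior
   mean path, transition matrices evaluated there, movement evidence applied
   as a mask.
3. **M-step.** Closed-form weighted regressions (from the posterior samples)
   for `A_acc` and `Q_acc` respecting each architecture's structure
   (scalar / diagonal / full), diagonal movement-state noise, and a
   quasi-Newton Poisson-GLM update of `C` and `d` on a thinned sample set.
   `V` and all transition parameters stay fixed; noise variances are floored
   at 1e−5.

Emissions are initialized greedily: offset from the mean rate, signs from
the neurons' choice preferences, then a Poisson GLM against the deterministic
drift paths of the initial dynamics. Starting near the data's emission scale
keeps early iterations off the shallow scale/persistence likelihood ridge.
The reported trace is a Laplace evidence bound (expected log joint at a
Newton-polished mode plus local Gaussian entropy plus discrete entropy);
with Monte-Carlo M-steps it rises to a plateau and then wobbles within a
small fraction of a percent. Initialization grids follow the standard values
per architecture (e.g. single: A ∈ {0.95, 1}, V ∈ {0.01…0.05},
Q ∈ {0.005, 0.01}), extended for the dependent race with the co-modulated
init `A_off = +0.1`; the fit with the best final objective wins.

Parameter-recovery calibration: on model-consistent data (dynamics
conditioned on the state path, `simulate_batch`), 20 replicate fits at 300
trials recover `A_acc = 0.98` with mean ≈0.976 and SD ≈0.006. On
boundary-crossing data the surviving paths are selected for persistence and
recovery shifts upward by ~0.01 — an inherent property of fitting
soft-transition models to first-passage data, not of the optimizer; recovery
studies therefore use the model-consistent generator, while identification
studies and the pipeline use the boundary generator.

## Model comparison

`AIC = 2k − 2·LL`, where `k` counts trainable scalars (accumulation dynamics
and noise per structure, diagonal movement noise, emission weights and the
shared offset: 9 / 17 / 24 for single / independent / dependent race with 4
neurons) and `LL` is the **marginal** spike log-likelihood: per trial,
`log E_prior[p(y|x)]` estimated by importance sampling against the
expected-dynamics Gaussian prior (100 draws, latents integrated out).
Marginalizing is what makes the quantity comparable across latent
dimensionalities — an expected log-likelihood under the posterior rewards
extra latent dimensions for tracking spike noise, and the expected joint
density is not comparable across different latent spaces at all. Verdicts
use AIC differences `Δ_i = AIC_i − AIC_min` with support threshold 10: a
subpopulation has a preferred architecture only when exactly one model has
`Δ < 10`, otherwise it is excluded. Unilateral subpopulations (one preference
side only) are fit with the single accumulator and never enter the
three-way comparison.

Explained variance simulates each trial 100× from the fitted model with the
discrete path pinned to the trial's observed accumulation/movement phases,
smooths data and simulation with a 50 ms causal boxcar, averages within
signed-evidence levels over the window from the fitting start to the median
pre-movement duration, and computes `R² = 1 − Σ(f_data − f_model)²/Σ(f_data −
f̄)²` with the per-neuron grand mean as normalizer: 1 for a perfect match, 0
for the grand-mean predictor, negative below that.

## Integration timescales

Fixed-length 200 ms trials are simulated from the accumulation dynamics with
boundaries disabled, no input, and a stationary start (re-expressed at the
25 ms autocorrelation bin via a fractional matrix power and the discrete
Lyapunov equation). Pearson correlations of binned counts between all bin
pairs, pooled by lag across pairs and neurons, follow
`R(kΔ) = A(exp(−kΔ/τ) + B)`. The fit is bounded trust-region least squares
(A ∈ [0, 1.5], B ∈ [−0.5, 1], τ ∈ (0, 5] s; an unbounded fit always escapes
to the degenerate "straight line" ridge A→∞, B→−1, τ→∞) over four fixed
initializations plus a log-linear data-driven one, best MSE winning. For
simulation-based estimates the offset is pinned to 0: the simulated process
has no component slower than the window by construction, and on a 175 ms lag
span a free offset trades off against τ almost perfectly, making τ ≥ 1 s
unidentifiable. The start lag skips an initial drop only when it is
anomalously large (>3× the median subsequent drop — actual negative
adaptation); an exponential's largest drop is always its first step, so the
unconditional rule would discard the most informative lag of every monotone
curve.

Subpopulation timescales average 50 independently simulated trial-set fits
(1000 trials each by default). Region timescales fit the mean pooled curve,
with a 100-fold subpopulation bootstrap for 95% percentile CIs; pairwise
regions are compared by Wilcoxon rank-sum on the per-subpopulation
timescales with Bonferroni correction (a rank-sum between bootstrap
distributions rejects at a rate set by the arbitrary bootstrap count — on
identical regions it fired 5/5 times). The strength–timescale analysis is
the per-region Pearson correlation between the fitted recurrent strength
(`A_acc`, or the mean diagonal for races) and the subpopulation timescale,
Bonferroni-corrected over regions, requiring ≥3 subpopulations (≥10 for
race-model analyses).

## Pipeline

`run_pipeline` (or the `evacc` CLI: `simulate`, `dpca`, `selectivity`,
`fit`, `compare`, `timescales`, `run-all`) chains the stages through
plain-text artifacts (CSV tables, YAML specs) so any stage can be rerun from
its predecessors' outputs. Defaults follow the standard constants: 100
shuffles, AIC threshold 10, RT window 0.15–0.5 s, subpopulations of 4 drawn
without replacement (20 per region; bilateral iff both preference sides are
present), 50 timescale samples, 100 bootstraps, 25 ms autocorrelation bins,
5 ms selectivity bins, 100/50 ms boxcars. Unknown configuration keys are
rejected by name, and a run manifest records the seed, package version and
every overridden default.

## Problem sizes in the test suite

The automated tests run the full chain at sizes that complete on one CPU in
roughly twenty minutes: parameter recovery uses 20 replicate fits of 300
trials; model identification 4 subpopulations per architecture at 200
trials; the timescale hierarchy 4 regions × 40 subpopulations with 25-sample
subpopulation averages; the strength correlation 30 subpopulations with the
full 50-sample protocol; selectivity calibration 200 neurons × 400 trials
with 100 shuffles. Thresholds are never loosened where a study is scaled
down.

## What the synthetic validation does and does not show

The generators emulate the trial structure, evidence-graded ramping,
boundary-crossing reaction times and tunable selectivity of the task data,
with Poisson spiking throughout. They do not emulate non-Poisson count
dispersion, slow drifts in excitability, correlated noise beyond the shared
latent, multi-area interactions, or wheel kinematics. Passing tests
demonstrate that each estimator recovers what it claims from data obeying
its assumptions at realistic rates and trial counts — not that the real
recordings satisfy those assumptions. Known limitations: recovered recurrent
strength carries a small (~0.005) downward finite-sample offset at 300
trials; timescales beyond ~2 s are at the edge of what a 200 ms window
supports even with the offset pinned; the latency estimator's false-onset
rate on stationary data is material; and architecture identification
degrades gracefully toward "excluded" verdicts when subpopulations mix in
neurons that do not follow the accumulator latent.
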