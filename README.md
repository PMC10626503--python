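# evacc — accumulator microcircuits, selectivity and integration timescales

`evacc` is a Python package for analyzing *distributed evidence
accumulation* in two-alternative forced-choice (2AFC) decision tasks of the
kind used in brain-wide mouse electrophysiology: visual gratings of contrast
{0, 0.25, 0.5, 1} appear on the left/right screens, the animal turns a wheel
toward the higher contrast (or withholds a response), and spiking is recorded
across many regions. The package is aimed at systems neuroscientists who
want to ask, from spike times and trial metadata alone:

- which neurons behave like drift-diffusion (DDM-like) integrators —
  choice-selective cells whose ramping rate is graded by the signed evidence
  `e = c_R − c_L`;
- whether small subpopulations of such neurons are better explained by a
  **single accumulator** (one decision variable integrating the evidence
  difference between boundaries ±B), an **independent race** (two uncoupled
  integrators racing to a bound), or a **dependent race** (coupled
  integrators); and
- on what **timescale** each microcircuit integrates, and how that timescale
  relates to its recurrent strength.

## The models

Accumulators are expressed as recurrent switching linear dynamical systems
(rSLDS) with Poisson emissions. Discrete states `z_t` (accumulation and
wheel-movement states) switch as a function of the continuous decision
variable(s) `x_t`:

    x_t ~ N(A_z x_{t−1} + V_z u_t,  Q_z)                 latent dynamics
    p(z_t | x_{t−1}) ∝ exp{ γ (R x_{t−1} + r_eff(t)) }   boundary-triggered switching
    y_t ~ Poisson( softplus(C x_t + d) Δt )              spike counts

with γ = 1, boundary B = 1 (optionally collapsing linearly or as
`β + (1−β)e^{−t/τ_c}`), and per-architecture structure on (A, V, Q). Only
`A_acc`, `Q_acc`, the movement-state noise and the emission map (C, d) are
trained; inputs `V` and the transition parameters are fixed. Fitting is a
variational Laplace-EM: elliptical-slice sampling of the latent paths
against the expected-dynamics Gaussian prior, exact forward–backward
smoothing of the switching states (with the observed movement time as
evidence), and closed-form / Poisson-GLM M-steps. Architectures are
compared by `AIC = 2k − 2·log p̂(y)` (marginal spike likelihood by Monte
Carlo, latents integrated out) with the Δ < 10 support rule.

Selectivity statistics (stimulus, choice probability CP, detect probability
DP, evidence selectivity ES) are combined-condition auROC measures —
normalized Mann–Whitney U within condition groups that hold the confounded
task variables fixed — with 100-fold shuffle nulls. Demixed PCA decomposes
trial-averaged activity into stimulus/decision/interaction components, and
fuzzy C-means groups neurons by their marginalization R². Integration
timescales come from the exponential decay
`R(kΔ) = A(exp(−kΔ/τ) + B)` of spike-count autocorrelations (Δ = 25 ms) of
model-simulated fixed-length trials, with subpopulation averages, regional
bootstrap CIs and rank-sum comparisons.

Every stage is exercised end to end on synthetic data with known ground
truth from `evacc.synthetic`; see `docs/methods.md` for the generators, the
numerical choices and their limits.

## Worked example

```python
import numpy as np
from evacc import accumulators as acc
from evacc import model_selection as ms
from evacc import synthetic, timescales as ts
from evacc.laplace_em import fit_laplace_em

# a single-accumulator microcircuit driving 4 neurons
spec = acc.build_accumulator(
    "single", init_values={"A_acc": 0.98, "V_acc": 0.05, "Q_acc": 0.01}, seed=5
)
trials = synthetic.make_task_trials(300, seed=1)
dataset = synthetic.simulate_accumulator_dataset(spec, trials, seed=2)

fit = fit_laplace_em(
    dataset, "single",
    init_grid={"A_acc": 0.95, "V_acc": 0.05, "Q_acc": 0.01},
    n_em=10, seed=0,
)
score = ms.aic(fit, n_samples=100, seed=3)
r2 = ms.explained_variance(fit, n_sims=50, seed=4)
tau, tau_sd, _ = ts.subpopulation_timescale(fit.spec, n_samples=20, seed=5)

print(f"recovered A_acc: {fit.spec.A[0, 0, 0]:.3f} (generated with 0.98)")
print(f"AIC: {score.aic:.1f} (k = {score.k} free parameters)")
print(f"evidence-conditioned R^2: {r2:.2f}")
print(f"integration timescale: {tau:.2f} +/- {tau_sd:.2f} s")
```

prints

```
recovered A_acc: 0.983 (generated with 0.98)
AIC: 10307.6 (k = 9 free parameters)
evidence-conditioned R^2: 0.66
integration timescale: 0.64 +/- 0.35 s
```

The fitted recurrent strength matches the generator; the AIC is the score
this model would carry into a three-way architecture comparison (`k` counts
its trainable scalars); R² = 0.66 says the fitted model's evidence-conditioned
firing-rate traces capture two thirds of the data's variance around its
grand mean; and the integration timescale is the decay constant of the
fitted circuit's spike-count autocorrelation (the generator's
`A_acc = 0.98` at 10 ms steps corresponds to τ ≈ 0.5 s).

The same chain runs as a pipeline over many regions and subpopulations from
one config file:

```bash
evacc run-all --config config.yaml --out results/ --seed 7
```

writing per-stage CSV tables (DDM-like screen, fits, AIC comparisons,
regional timescales, strength–timescale correlations) and a run manifest.

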