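"""Goodness of fit and AIC model comparison for fitted accumulators.

The AIC uses a sample-based estimate of the model log-likelihood:
``AIC = 2k - 2 * LL`` with ``k`` the count of trainable scalars and ``LL``
the marginal spike log-likelihood, estimated by Monte-Carlo sampling of
latent paths (100 draws against the dynamics prior, integrating the latents
out).  Marginalizing the latents keeps AICs comparable between architectures
with different latent dimensionality.  Model comparison rescales AICs to
differences from the best model (``Delta_i = AIC_i - AIC_min``) with a
support threshold of 10: a subpopulation has a preferred model only when
exactly one model has ``Delta < 10``; otherwise it is excluded from
architecture claims.

Explained variance compares evidence-conditioned mean firing-rate traces of
the data against traces simulated from the fitted model (100 rollouts per
trial, 50 ms causal boxcar rates), normalized by the data's deviation from
its grand mean; 1 is a perfect match, 0 matches the grand-mean predictor,
and negative values are worse than the grand mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from evacc import accumulators as acc
from evacc.laplace_em import (
    FitResult,
    _choice_movement_state,
    marginal_loglik,
    simulate_counts_batch,
)


@dataclass
class ModelScore:
    """AIC and its Monte-Carlo ingredients for one fitted model."""

    model: str
    aic: float
    k: int
    expected_loglik: float
    mc_se: float
    n_samples: int
    r2: float | None = None


def aic(fit: FitResult, n_samples: int = 100, seed: int | None = None) -> ModelScore:
    """Sample-based Akaike information criterion for a fitted accumulator."""
    est, se = marginal_loglik(fit, n_draws=n_samples, seed=seed)
    k = acc.n_free_parameters(fit.spec)
    return ModelScore(
        model=fit.spec.kind,
        aic=2.0 * k - 2.0 * est,
        k=k,
        expected_loglik=est,
        mc_se=se,
        n_samples=n_samples,
    )


def _boxcar_rates(counts: np.ndarray, dt: float, width: float = 0.05) -> np.ndarray:
    """Causal boxcar firing rates (Hz) along axis 0 of (T, ...) counts."""
    n = max(int(round(width / dt)), 1)
    out = np.zeros_like(counts, dtype=float)
    csum = np.cumsum(counts, axis=0)
    for t in range(counts.shape[0]):
        lo = max(t - n + 1, 0)
        total = csum[t] - (csum[lo - 1] if lo > 0 else 0)
        out[t] = total / ((t - lo + 1) * dt)
    return out


def _evidence_of(u: np.ndarray) -> float:
    return float(u[0] if len(u) == 1 else u[0] - u[1])


def explained_variance(
    fit: FitResult,
    n_sims: int = 100,
    boxcar: float = 0.05,
    seed: int | None = None,
    simulated: dict | None = None,
) -> float:
    """Evidence-conditioned explained variance R^2 of a fitted model.

    Data and model firing rates (50 ms causal boxcar) are averaged across the
    trials of each signed-evidence level over the time set from the start of
    the fitting window (end of latency) to the median pre-movement duration.
    Model traces are simulated per trial with the discrete path pinned to the
    trial's observed accumulation/movement phases.  ``simulated`` optionally
    supplies precomputed model traces keyed like the data ones (used by the
    self-consistency tests).
    """
    batch = fit.trials
    rng = np.random.default_rng(seed)
    dt = batch.dt
    lens = np.array([y.shape[0] - batch.n_post for y in batch.ys])
    t_med = int(np.median(lens))
    if t_med < 1:
        raise ValueError("median pre-movement duration too short")
    n_neurons = batch.ys[0].shape[1]

    levels = sorted({_evidence_of(u) for u in batch.us})
    sums_d = {e: np.zeros((t_med, n_neurons)) for e in levels}
    sums_m = {e: np.zeros((t_med, n_neurons)) for e in levels}
    cnts = {e: np.zeros((t_med, 1)) for e in levels}
    for y, u, choice in zip(batch.ys, batch.us, batch.choices):
        e = _evidence_of(u)
        T_full = y.shape[0]
        T = min(T_full, t_med)
        rates = _boxcar_rates(y, dt, boxcar)[:T]
        sums_d[e][:T] += rates
        cnts[e][:T] += 1.0
        if simulated is None:
            move = _choice_movement_state(fit.spec.kind, choice)
            states = np.zeros(T_full, dtype=int)
            states[T_full - batch.n_post :] = move
            sim = simulate_counts_batch(
                fit.spec, u, T_full, n_sims, rng, states=states
            )
            sim_rates = _boxcar_rates(sim.mean(axis=0), dt, boxcar)[:T]
            sums_m[e][:T] += sim_rates

    f_data = {e: sums_d[e] / np.maximum(cnts[e], 1.0) for e in levels}
    f_model = (
        simulated
        if simulated is not None
        else {e: sums_m[e] / np.maximum(cnts[e], 1.0) for e in levels}
    )
    # grand mean per neuron over all evidence levels and time points
    stacked = np.concatenate([f_data[e] for e in levels])
    gmean = stacked.mean(axis=0, keepdims=True)
    num = sum(float(np.sum((f_data[e] - f_model[e]) ** 2)) for e in levels)
    den = float(np.sum((stacked - gmean) ** 2))
    if den == 0:
        raise ValueError("zero data variance; R^2 undefined")
    return 1.0 - num / den


@dataclass
class ComparisonVerdict:
    """AIC-difference verdict across candidate architectures."""

    deltas: dict[str, float]
    preferred: str | None  # None means excluded (ambiguous support)
    pairwise: dict[str, float] = field(default_factory=dict)
    threshold: float = 10.0

    @property
    def excluded(self) -> bool:
        return self.preferred is None and len(self.deltas) > 1


def compare_models(
    scores: list[ModelScore] | dict[str, ModelScore],
    threshold: float = 10.0,
) -> ComparisonVerdict:
    """Rescale AICs to the best model and apply the support threshold.

    The preferred model is the unique one with ``Delta = 0`` when every other
    model has ``Delta >= threshold``; a subpopulation with more than one model
    under the threshold (including exact ties) is excluded.  A single-model
    input is trivially preferred.
    """
    if isinstance(scores, dict):
        scores = list(scores.values())
    if not scores:
        raise ValueError("need at least one scored model")
    aics = {s.model: s.aic for s in scores}
    amin = min(aics.values())
    deltas = {m: a - amin for m, a in aics.items()}
    supported = [m for m, d in deltas.items() if d < threshold]
    preferred = supported[0] if len(supported) == 1 else None
    if len(deltas) == 1:
        preferred = next(iter(deltas))

    pairwise = {}
    pairs = {
        "delta_si": ("single", "independent_race"),
        "delta_sd": ("single", "dependent_race"),
        "delta_id": ("independent_race", "dependent_race"),
    }
    for name, (a, b) in pairs.items():
        if a in aics and b in aics:
            pairwise[name] = aics[a] - aics[b]
    return ComparisonVerdict(
        deltas=deltas, preferred=preferred, pairwise=pairwise, threshold=threshold
    )
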