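"""Synthetic task and spike-train generators with stored ground truth.

Everything downstream (selectivity, dPCA, accumulator fitting, timescales)
is exercised on data from this module, so each generator records the
parameters and latent variables it used under ``SpikeDataset.ground_truth``.

Conventions: recordings are from the "left hemisphere", so the contralateral
screen is the right one; contra-preferring neurons load positively on the
right-choice latent (or positively on the single decision variable),
ipsi-preferring neurons the opposite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from evacc import accumulators as acc
from evacc.datasets import (
    CONTRAST_LEVELS,
    SpikeDataset,
    outcome_of,
)

#: Inter-trial spacing (s); long enough for the -0.9..-0.1 s baseline window.
TRIAL_SPACING = 2.5


def _contrast_grid(include_equal: bool) -> np.ndarray:
    cells = [
        (cl, cr)
        for cl in CONTRAST_LEVELS
        for cr in CONTRAST_LEVELS
        if include_equal or cl != cr
    ]
    return np.array(cells)


def make_task_trials(
    n_trials: int,
    include_equal_contrast: bool = False,
    rt_range: tuple[float, float] = (0.15, 0.5),
    seed: int | None = None,
    nogo_rate: float = 0.05,
    choice_slope: float = 4.0,
) -> pd.DataFrame:
    """Random 2AFC contrast-task trials with behaviorally plausible outputs.

    Contrast pairs are drawn uniformly over the 4 x 4 grid of levels
    {0, 0.25, 0.5, 1} (minus the four equal-contrast cells when
    ``include_equal_contrast`` is false, leaving 12 cells).  Choices follow a
    logistic psychometric function of the signed evidence with slope
    ``choice_slope``; blank trials are mostly ``nogo``.  Reaction times are
    uniform on ``rt_range``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rt_range[1] <= rt_range[0]:
        raise ValueError("rt_range must be increasing")
    rng = np.random.default_rng(seed)
    grid = _contrast_grid(include_equal_contrast)
    cells = grid[rng.integers(0, len(grid), size=n_trials)]
    cl, cr = cells[:, 0], cells[:, 1]
    evidence = np.round(cr - cl, 2)

    p_right = 1.0 / (1.0 + np.exp(-choice_slope * evidence))
    turn_right = rng.random(n_trials) < p_right
    choice = np.where(turn_right, "right", "left").astype(object)
    blank = (cl == 0) & (cr == 0)
    go_nogo = rng.random(n_trials)
    choice[blank & (go_nogo < 0.8)] = "nogo"
    choice[~blank & (go_nogo < nogo_rate)] = "nogo"

    stim_onset = 1.0 + TRIAL_SPACING * np.arange(n_trials)
    rt = rng.uniform(*rt_range, size=n_trials)
    is_go = choice != "nogo"
    wheel_move = np.where(is_go, stim_onset + rt, np.nan)
    rt = np.where(is_go, rt, np.nan)
    outcome = [outcome_of(a, b, c) for a, b, c in zip(cl, cr, choice)]
    return pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "contrast_left": cl,
            "contrast_right": cr,
            "evidence": evidence,
            "choice": choice,
            "outcome": outcome,
            "stim_onset": stim_onset,
            "wheel_move": wheel_move,
            "reaction_time": rt,
        }
    )


def _spikes_from_segment_rates(
    starts: np.ndarray, durations: np.ndarray, rates: np.ndarray, rng
) -> list[np.ndarray]:
    """Sample piecewise-homogeneous Poisson spike trains.

    ``rates`` is (n_segments, n_neurons) in Hz; returns one sorted spike-time
    array per neuron."""
    counts = rng.poisson(np.clip(rates, 0.0, None) * durations[:, None])
    out = []
    for n in range(rates.shape[1]):
        c = counts[:, n]
        seg = np.repeat(np.arange(len(starts)), c)
        times = starts[seg] + rng.random(c.sum()) * durations[seg]
        out.append(np.sort(times))
    return out


def simulate_accumulator_dataset(
    spec: acc.AccumulatorSpec,
    trials: pd.DataFrame,
    seed: int | None = None,
    onset_delay: float = 0.1,
    max_duration: float = 1.0,
    post_move: float = 0.05,
) -> SpikeDataset:
    """Simulate spike trains whose latent is an accumulator microcircuit.

    Per trial the latent starts at 0 and evolves under the accumulation-state
    dynamics with a constant input derived from the trial's contrasts; the
    first crossing of the (possibly collapsing) boundary sets the choice and
    reaction time, after which the latent freezes into the movement state for
    ``post_move`` seconds.  Trials with no crossing within ``max_duration``
    are labeled ``nogo``.  Spikes are Poisson with rate
    ``softplus(C x + d)``; between trials ``x = 0``, so the baseline rate is
    ``softplus(d)``.

    The choice and timing columns of ``trials`` are overwritten by the
    simulation; ground truth (spec, latent paths, onset delay) is stored.
    """
    if len(trials) == 0:
        raise ValueError("trials must be nonempty")
    rng = np.random.default_rng(seed)
    K, D, _ = spec.shapes
    dt = spec.dt
    max_steps = int(round(max_duration / dt))
    n_post = int(round(post_move / dt))
    chol_acc = np.linalg.cholesky(spec.Q[0])
    chol_move = np.linalg.cholesky(spec.Q[1])

    trials = trials.copy().reset_index(drop=True)
    latents, choices, rts = [], [], []
    for row in trials.itertuples():
        u = acc.input_vector(spec.kind, row.contrast_left, row.contrast_right)
        drift = spec.V[0] @ u
        x = np.zeros(D)
        xs = []
        choice, cross_step = "nogo", None
        for t in range(max_steps):
            x = spec.A[0] @ x + drift + chol_acc @ rng.standard_normal(D)
            xs.append(x.copy())
            b_eff = spec.B * acc.boundary_factor(spec, t)
            state = _crossing_state(spec.kind, x, b_eff)
            if state is not None:
                choice = acc.STATE_CHOICE[spec.kind][state]
                cross_step = t
                break
        if cross_step is not None:
            for _ in range(n_post):
                x = x + chol_move @ rng.standard_normal(D)
                xs.append(x.copy())
            rt = onset_delay + (cross_step + 1) * dt
        else:
            rt = np.nan
        latents.append(np.array(xs))
        choices.append(choice)
        rts.append(rt)

    trials["choice"] = choices
    trials["reaction_time"] = rts
    trials["wheel_move"] = trials["stim_onset"] + trials["reaction_time"]
    trials["outcome"] = [
        outcome_of(r.contrast_left, r.contrast_right, r.choice)
        for r in trials.itertuples()
    ]

    # Piecewise rates: baseline between trials, latent-driven within them.
    seg_starts, seg_durs, seg_rates = [], [], []
    base = acc.softplus(np.zeros(spec.n_neurons) * 0.0 + spec.d)  # Hz
    cursor = 0.0
    session_end = trials["stim_onset"].iloc[-1] + TRIAL_SPACING
    for i, row in enumerate(trials.itertuples()):
        t0 = row.stim_onset + onset_delay
        if t0 > cursor:
            seg_starts.append(cursor)
            seg_durs.append(t0 - cursor)
            seg_rates.append(base)
        xs = latents[i]
        rates = acc.softplus(xs @ spec.C.T + spec.d)  # (T, N) in Hz
        seg_starts.extend(t0 + dt * np.arange(len(xs)))
        seg_durs.extend([dt] * len(xs))
        seg_rates.extend(rates)
        cursor = t0 + dt * len(xs)
    if session_end > cursor:
        seg_starts.append(cursor)
        seg_durs.append(session_end - cursor)
        seg_rates.append(base)

    spikes = _spikes_from_segment_rates(
        np.array(seg_starts), np.array(seg_durs), np.array(seg_rates), rng
    )
    pref = ["contra" if spec.C[n, 0] > 0 else "ipsi" for n in range(spec.n_neurons)]
    neurons = pd.DataFrame(
        {
            "neuron_id": np.arange(spec.n_neurons),
            "region": "synthetic",
            "pref_side": pref,
        }
    )
    gt = {
        "spec": acc.spec_to_dict(spec),
        "onset_delay": onset_delay,
        "latents": [x.tolist() for x in latents],
    }
    return SpikeDataset(spikes=spikes, trials=trials, neurons=neurons, ground_truth=gt)


def _crossing_state(kind: str, x: np.ndarray, b: float) -> int | None:
    """Movement state entered when ``x`` first crosses the boundary, else None."""
    if kind == "single":
        if x[0] >= b:
            return 1
        if x[0] <= -b:
            return 2
        return None
    if kind == "independent_race":
        if x[0] >= b and x[0] >= x[1]:
            return 1
        if x[1] >= b:
            return 2
        return None
    hits = {1: x[0] >= b, 2: x[0] <= -b, 3: x[1] >= b, 4: x[1] <= -b}
    winners = [k for k, v in hits.items() if v]
    return winners[0] if winners else None


def make_selectivity_cohort(
    n_neurons: int,
    tuning: dict | None = None,
    baseline_rate: float = 10.0,
    trials: pd.DataFrame | None = None,
    seed: int | None = None,
    onset_delay: float = 0.05,
    active_duration: float = 0.6,
) -> SpikeDataset:
    """Inhomogeneous-Poisson neurons with controlled task tuning.

    After ``stim_onset + onset_delay`` each neuron's rate is::

        baseline + g_stim * contrast_contra + g_choice * side
                 + g_evid * evidence + g_out * outcome_sign

    with ``side`` +1 for right (contra) choices, -1 for left, 0 for nogo;
    ``outcome_sign`` +1 for hits and -1 for misses; and the contralateral
    screen being the right one.  Rates are clipped at 0 (clip count recorded
    in ground truth).  ``tuning`` maps ``stimulus``/``choice``/``evidence``/
    ``outcome`` to per-neuron gain arrays (Hz per unit); missing entries
    default to 0 (untuned).
    """
    if baseline_rate < 0:
        raise ValueError("baseline_rate must be >= 0")
    rng = np.random.default_rng(seed)
    if trials is None:
        trials = make_task_trials(400, seed=seed)
    tuning = tuning or {}
    gains = {
        key: np.broadcast_to(np.asarray(tuning.get(key, 0.0), float), (n_neurons,))
        for key in ("stimulus", "choice", "evidence", "outcome")
    }
    for g in gains.values():
        if not np.all(np.isfinite(g)):
            raise ValueError("tuning gains must be finite")

    side = trials["choice"].map({"right": 1.0, "left": -1.0, "nogo": 0.0}).to_numpy()
    out_sign = trials["outcome"].map({"hit": 1.0, "miss": -1.0}).to_numpy()
    drive = (
        gains["stimulus"][None, :] * trials["contrast_right"].to_numpy()[:, None]
        + gains["choice"][None, :] * side[:, None]
        + gains["evidence"][None, :] * trials["evidence"].to_numpy()[:, None]
        + gains["outcome"][None, :] * out_sign[:, None]
    )
    active = baseline_rate + drive  # (n_trials, n_neurons)
    n_clipped = int((active < 0).sum())

    onsets = trials["stim_onset"].to_numpy()
    n_trials = len(trials)
    session_end = onsets[-1] + TRIAL_SPACING
    starts, durs, rates = [], [], []
    cursor = 0.0
    for i in range(n_trials):
        t0 = onsets[i] + onset_delay
        starts += [cursor, t0]
        durs += [t0 - cursor, active_duration]
        rates += [np.full(n_neurons, baseline_rate), active[i]]
        cursor = t0 + active_duration
    starts.append(cursor)
    durs.append(session_end - cursor)
    rates.append(np.full(n_neurons, baseline_rate))

    spikes = _spikes_from_segment_rates(
        np.array(starts), np.array(durs), np.array(rates), rng
    )
    neurons = pd.DataFrame(
        {
            "neuron_id": np.arange(n_neurons),
            "region": "synthetic",
            "pref_side": np.where(gains["choice"] >= 0, "contra", "ipsi"),
        }
    )
    gt = {
        "tuning": {k: v.tolist() for k, v in gains.items()},
        "baseline_rate": baseline_rate,
        "onset_delay": onset_delay,
        "true_latency": onset_delay,
        "n_clipped_rates": n_clipped,
    }
    return SpikeDataset(spikes=spikes, trials=trials, neurons=neurons, ground_truth=gt)


def make_ar1_population(
    a: float,
    step: float = 0.025,
    n_trials: int = 1000,
    duration: float = 0.2,
    rate_map: tuple[float, float] = (25.0, 30.0),
    n_neurons: int = 100,
    seed: int | None = None,
) -> SpikeDataset:
    """Fixed-length trials whose latents are stationary AR(1) processes.

    Each neuron carries its own independent latent per trial,
    ``x_t = a x_{t-1} + eps`` with unit innovations and a stationary start,
    so the latent autocorrelation at lag ``k`` is exactly ``a**k`` and the
    true intrinsic timescale is ``-step / ln(a)`` (stored as ground truth).
    Spike counts per bin are Poisson with rate ``offset + gain * x_unit``
    (Hz, clipped at 0) where ``rate_map = (gain, offset)`` and ``x_unit`` is
    the unit-variance latent.
    """
    if not 0 < a < 1:
        raise ValueError("AR(1) coefficient must lie in (0, 1)")
    n_bins = int(round(duration / step))
    if abs(n_bins * step - duration) > 1e-9:
        raise ValueError("duration must be a multiple of step")
    rng = np.random.default_rng(seed)
    gain, offset = rate_map

    sd_stat = 1.0 / np.sqrt(1.0 - a**2)
    x = np.empty((n_trials, n_neurons, n_bins))
    x[:, :, 0] = rng.standard_normal((n_trials, n_neurons)) * sd_stat
    innov = rng.standard_normal((n_trials, n_neurons, n_bins))
    for t in range(1, n_bins):
        x[:, :, t] = a * x[:, :, t - 1] + innov[:, :, t]
    rate = np.clip(offset + gain * x / sd_stat, 0.0, None)  # Hz, unit-variance map
    counts = rng.poisson(rate * step)

    spacing = duration + 1.8 + 0.9  # room for a baseline window
    onsets = 1.0 + spacing * np.arange(n_trials)
    spikes = []
    for n in range(n_neurons):
        c = counts[:, n, :]
        tr, bn = np.nonzero(c)
        reps = c[tr, bn]
        t0 = np.repeat(onsets[tr] + step * bn, reps)
        times = t0 + rng.random(reps.sum()) * step
        spikes.append(np.sort(times))
    trials = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "contrast_left": 0.0,
            "contrast_right": 0.0,
            "evidence": 0.0,
            "choice": "nogo",
            "outcome": "hit",
            "stim_onset": onsets,
            "wheel_move": np.nan,
            "reaction_time": np.nan,
        }
    )
    neurons = pd.DataFrame(
        {
            "neuron_id": np.arange(n_neurons),
            "region": "synthetic",
            "pref_side": "contra",
        }
    )
    gt = {
        "a": a,
        "step": step,
        "duration": duration,
        "true_timescale": -step / np.log(a),
        # latents of the first neuron only (full array would be huge)
        "latents": x[:, 0, :].tolist(),
        "counts_shape": list(counts.shape),
    }
    ds = SpikeDataset(spikes=spikes, trials=trials, neurons=neurons, ground_truth=gt)
    ds.ground_truth["counts"] = counts  # in-memory convenience for analyses
    return ds
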