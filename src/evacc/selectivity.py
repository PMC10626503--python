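"""Combined-condition auROC selectivity, shuffle nulls and latency estimation.

The area under the ROC curve between two spike-count (or z-scored rate)
samples is the normalized Mann-Whitney U statistic: the probability that a
draw from the second sample exceeds a draw from the first, counting ties as
one half.  Because stimulus and choice are strongly correlated by task
design, each selectivity metric computes auROC *within* condition groups that
hold the confounding variables fixed and combines them by a trial-count
weighted average:

``stimulus``
    12 groups (choice x left-contrast level); contralateral (right) contrast
    present vs absent; raw auROC.
``CP`` (choice probability)
    12 unequal contrast-pair groups; right vs left choice, movement aligned;
    ``|auROC - 0.5|``.
``DP`` (detect probability)
    12 unequal contrast-pair groups; hit vs miss in the stimulus epoch;
    ``auROC - 0.5`` (signed).
``ES`` (evidence selectivity)
    9 signed evidence levels; each level vs all lower levels pooled (8
    ordered comparisons); ``|auROC - 0.5|``.

Significance uses a 100-fold trial-label shuffle within the same grouping
structure, a 2.5-97.5 percentile band, and a two-significant-neighbors rule
(only points inside runs of at least three significant bins survive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from evacc.datasets import CONTRAST_LEVELS, EVIDENCE_LEVELS, SpikeDataset

METRICS = ("stimulus", "CP", "DP", "ES")

#: Default alignment event and analysis window (s) per metric.
METRIC_WINDOWS = {
    "stimulus": ("stim_onset", (-0.1, 0.3)),
    "CP": ("wheel_move", (-0.3, 0.1)),
    "DP": ("stim_onset", (-0.1, 0.3)),
    "ES": ("stim_onset", (-0.1, 0.3)),
}

BASELINE_WINDOW = (-0.9, -0.1)
BIN_SIZE = 0.005
SMOOTH_SD = 0.02
MIN_TRIALS_PER_SIDE = 3


# ---------------------------------------------------------------------------
# auROC core

def _rank_with_ties(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) along axis 0 of a 2-D array, ties averaged.

    Vectorized across columns; equivalent to scipy.stats.rankdata per column.
    """
    n, m = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    xs = np.take_along_axis(x, order, axis=0)
    pos = np.arange(n, dtype=float)[:, None]
    new = np.ones((n, m), dtype=bool)
    new[1:] = xs[1:] != xs[:-1]
    # start index of each tie group, forward-filled
    start = np.where(new, pos, 0.0)
    start = np.maximum.accumulate(start, axis=0)
    # end index: backward fill of (position before next group start)
    nxt = np.where(new, pos, np.inf)
    nxt = np.minimum.accumulate(nxt[::-1], axis=0)[::-1]
    end = np.empty((n, m))
    end[:-1] = nxt[1:] - 1.0
    end[-1] = n - 1.0
    end = np.where(np.isfinite(end), end, n - 1.0)
    avg = 0.5 * (start + end) + 1.0
    ranks = np.empty((n, m))
    np.put_along_axis(ranks, order, avg, axis=0)
    return ranks


def auroc_nd(sample_a: np.ndarray, sample_b: np.ndarray) -> np.ndarray:
    """auROC (probability that b exceeds a, 0.5 per tie) along axis 0.

    ``sample_a`` is (n_a, ...) and ``sample_b`` (n_b, ...); the result has the
    trailing shape.
    """
    na, nb = sample_a.shape[0], sample_b.shape[0]
    if na == 0 or nb == 0:
        raise ValueError("auROC samples must be nonempty")
    both = np.concatenate([sample_a, sample_b], axis=0)
    flat = both.reshape(na + nb, -1)
    ranks = _rank_with_ties(flat)
    rb = ranks[na:].sum(axis=0)
    u = rb - nb * (nb + 1) / 2.0
    out = u / (na * nb)
    return out.reshape(both.shape[1:])


def auroc(counts_a, counts_b) -> float:
    """Scalar auROC between two 1-D samples (Mann-Whitney U / (n_a n_b))."""
    a = np.asarray(counts_a, float).reshape(-1, 1)
    b = np.asarray(counts_b, float).reshape(-1, 1)
    return float(auroc_nd(a[:, 0][:, None], b[:, 0][:, None])[0])


# ---------------------------------------------------------------------------
# rate preprocessing

def _half_gaussian_kernel(sd: float, binsize: float) -> np.ndarray:
    n = max(int(np.ceil(4 * sd / binsize)), 1)
    t = np.arange(n + 1) * binsize
    k = np.exp(-0.5 * (t / sd) ** 2)
    return k / k.sum()


def _causal_filter(counts: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal filtering along the last axis (kernel[0] weights the current bin)."""
    n = len(kernel)
    padded = np.concatenate(
        [np.zeros(counts.shape[:-1] + (n - 1,)), counts], axis=-1
    )
    windows = np.lib.stride_tricks.sliding_window_view(padded, n, axis=-1)
    return windows @ kernel[::-1]


def preprocess_rates(
    dataset: SpikeDataset,
    align: str = "stim_onset",
    window: tuple[float, float] = (-0.1, 0.3),
    binsize: float = BIN_SIZE,
    smooth_sd: float = SMOOTH_SD,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed, baseline z-scored firing rates on a common grid.

    Counts are binned at ``binsize`` (half-open bins), smoothed with a causal
    half-Gaussian kernel of SD ``smooth_sd`` and converted to rates; each
    neuron is z-scored by its mean and SD over the stimulus-aligned baseline
    window (-0.9 to -0.1 s) pooled across trials and bins.

    Returns ``(z, t, valid)``; neurons with zero baseline SD are flagged
    invalid and their rows set to NaN.  Trials without the alignment event
    have NaN rows.
    """
    kernel = _half_gaussian_kernel(smooth_sd, binsize)
    counts, t = dataset.bin_counts(align=align, window=window, binsize=binsize)
    rates = _causal_filter(counts, kernel) / binsize
    base_counts, _ = dataset.bin_counts(
        align="stim_onset", window=BASELINE_WINDOW, binsize=binsize
    )
    base_rates = _causal_filter(base_counts, kernel) / binsize
    mu = np.nanmean(base_rates, axis=(0, 2))
    sd = np.nanstd(base_rates, axis=(0, 2))
    valid = sd > 0
    sd_safe = np.where(valid, sd, 1.0)
    z = (rates - mu[None, :, None]) / sd_safe[None, :, None]
    z[:, ~valid, :] = np.nan
    return z, t, valid


# ---------------------------------------------------------------------------
# combined-condition metrics

def _comparisons(trials: pd.DataFrame, metric: str) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-condition (index_a, index_b) trial-index pairs for a metric."""
    out = []
    if metric == "stimulus":
        for ch in ("left", "right", "nogo"):
            for cl in CONTRAST_LEVELS:
                grp = trials[(trials["choice"] == ch) & (trials["contrast_left"] == cl)]
                a = grp.index[grp["contrast_right"] == 0].to_numpy()
                b = grp.index[grp["contrast_right"] > 0].to_numpy()
                out.append((a, b))
    elif metric in ("CP", "DP"):
        for cl in CONTRAST_LEVELS:
            for cr in CONTRAST_LEVELS:
                if cl == cr:
                    continue
                grp = trials[
                    (trials["contrast_left"] == cl) & (trials["contrast_right"] == cr)
                ]
                if metric == "CP":
                    a = grp.index[grp["choice"] == "left"].to_numpy()
                    b = grp.index[grp["choice"] == "right"].to_numpy()
                else:
                    a = grp.index[grp["outcome"] == "miss"].to_numpy()
                    b = grp.index[grp["outcome"] == "hit"].to_numpy()
                out.append((a, b))
    elif metric == "ES":
        ev = np.round(trials["evidence"].to_numpy(), 2)
        for k in range(1, len(EVIDENCE_LEVELS)):
            level = EVIDENCE_LEVELS[k]
            a = trials.index[ev < level - 1e-9].to_numpy()
            b = trials.index[np.abs(ev - level) < 1e-9].to_numpy()
            out.append((a, b))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return out


def _transform(metric: str, value: np.ndarray) -> np.ndarray:
    if metric in ("CP", "ES"):
        return np.abs(value - 0.5)
    if metric == "DP":
        return value - 0.5
    return value


def _metric_values(
    trials: pd.DataFrame,
    rates: np.ndarray,
    metric: str,
    min_trials: int = MIN_TRIALS_PER_SIDE,
) -> np.ndarray:
    """Count-weighted combined-condition auROC, transformed per metric.

    ``rates`` is (n_trials, n_neurons, n_bins); returns (n_neurons, n_bins),
    NaN where every condition was dropped (fewer than ``min_trials`` per side).
    """
    ok_trial = ~np.isnan(rates[:, 0, 0])
    num = np.zeros(rates.shape[1:])
    den = 0.0
    for idx_a, idx_b in _comparisons(trials, metric):
        idx_a = idx_a[ok_trial[idx_a]]
        idx_b = idx_b[ok_trial[idx_b]]
        if len(idx_a) < min_trials or len(idx_b) < min_trials:
            continue
        val = auroc_nd(rates[idx_a], rates[idx_b])
        w = len(idx_a) + len(idx_b)
        num += w * val
        den += w
    if den == 0:
        return np.full(rates.shape[1:], np.nan)
    return _transform(metric, num / den)


def _shuffle_trials(trials: pd.DataFrame, metric: str, rng) -> pd.DataFrame:
    """Permute the comparison labels within the metric's grouping structure."""
    t = trials.copy()
    if metric == "stimulus":
        keys = ["choice", "contrast_left"]
        col = "contrast_right"
    elif metric == "CP":
        keys = ["contrast_left", "contrast_right"]
        col = "choice"
    elif metric == "DP":
        keys = ["contrast_left", "contrast_right"]
        col = "outcome"
    else:  # ES: the partition itself is the grouping; permute globally
        vals = t["evidence"].to_numpy().copy()
        t["evidence"] = vals[rng.permutation(len(vals))]
        return t
    for _, grp in t.groupby(keys, sort=False):
        vals = grp[col].to_numpy()
        t.loc[grp.index, col] = vals[rng.permutation(len(vals))]
    return t


@dataclass
class SelectivityResult:
    """Per-neuron selectivity time series with optional shuffle statistics."""

    metric: str
    values: np.ndarray  # (n_neurons, n_bins)
    times: np.ndarray
    align: str
    window: tuple[float, float]
    shuffle_low: np.ndarray | None = field(repr=False, default=None)
    shuffle_high: np.ndarray | None = field(repr=False, default=None)
    significant: np.ndarray | None = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        n, t = self.values.shape
        sig = (
            self.significant
            if self.significant is not None
            else np.zeros_like(self.values, bool)
        )
        return pd.DataFrame(
            {
                "neuron_id": np.repeat(np.arange(n), t),
                "time": np.tile(self.times, n),
                "value": self.values.ravel(),
                "significant": sig.ravel(),
            }
        )


def combined_condition_selectivity(
    dataset: SpikeDataset,
    metric: str,
    window: tuple[float, float] | None = None,
    align: str | None = None,
    binsize: float = BIN_SIZE,
    min_trials: int = MIN_TRIALS_PER_SIDE,
) -> SelectivityResult:
    """Combined-condition auROC selectivity for every neuron and time bin."""
    d_align, d_window = METRIC_WINDOWS[metric]
    align = align or d_align
    window = window or d_window
    rates, t, _ = preprocess_rates(dataset, align=align, window=window, binsize=binsize)
    values = _metric_values(dataset.trials, rates, metric, min_trials)
    return SelectivityResult(metric, values, t, align, window)


def neighbor_filter(sig: np.ndarray) -> np.ndarray:
    """Keep only significant points with >= 2 significant neighbors, i.e.
    points inside runs of at least three consecutive significant bins."""
    sig = np.asarray(sig, bool)
    if sig.shape[-1] < 3:
        return np.zeros_like(sig)
    ok3 = sig[..., :-2] & sig[..., 1:-1] & sig[..., 2:]
    keep = np.zeros_like(sig)
    keep[..., :-2] |= ok3
    keep[..., 1:-1] |= ok3
    keep[..., 2:] |= ok3
    return keep


def shuffle_significance(
    dataset: SpikeDataset,
    metric: str,
    n_shuffles: int = 100,
    seed: int | None = None,
    window: tuple[float, float] | None = None,
    align: str | None = None,
    binsize: float = BIN_SIZE,
    band: tuple[float, float] = (2.5, 97.5),
    min_trials: int = MIN_TRIALS_PER_SIDE,
) -> SelectivityResult:
    """Selectivity plus a shuffle-null confidence band and significance mask.

    Trial labels are permuted ``n_shuffles`` times within the metric's
    grouping structure; a time point is significant when the observed value
    falls outside the band's percentiles of the shuffle distribution *and*
    lies in a run of at least three such points.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    d_align, d_window = METRIC_WINDOWS[metric]
    align = align or d_align
    window = window or d_window
    rates, t, _ = preprocess_rates(dataset, align=align, window=window, binsize=binsize)
    observed = _metric_values(dataset.trials, rates, metric, min_trials)
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles,) + observed.shape)
    for s in range(n_shuffles):
        shuffled = _shuffle_trials(dataset.trials, metric, rng)
        null[s] = _metric_values(shuffled, rates, metric, min_trials)
    low = np.nanpercentile(null, band[0], axis=0)
    high = np.nanpercentile(null, band[1], axis=0)
    with np.errstate(invalid="ignore"):
        raw = (observed > high) | (observed < low)
    sig = neighbor_filter(raw)
    return SelectivityResult(
        metric, observed, t, align, window,
        shuffle_low=low, shuffle_high=high, significant=sig,
    )


# ---------------------------------------------------------------------------
# latency

@dataclass
class LatencyEstimate:
    """Population accumulation-onset latency relative to stimulus onset."""

    latency: float | None
    p_values: np.ndarray
    times: np.ndarray


def estimate_latency(
    dataset: SpikeDataset,
    rt_range: tuple[float, float] = (0.15, 0.5),
    boxcar: float = 0.1,
    binsize: float = BIN_SIZE,
    alpha: float = 0.05,
) -> LatencyEstimate:
    """First time of significant population-rate change after stimulus onset.

    Go trials with reaction times inside ``rt_range`` are smoothed with a
    causal boxcar of width ``boxcar`` over -0.5..0.5 s, averaged across
    neurons within each trial, and each stimulus-epoch time (0..0.5 s) is
    compared against the baseline point at -0.1 s with a Mann-Whitney test.
    The latency is the first point with p < ``alpha`` that has at least two
    significant neighbors; ``None`` if there is no such point.
    """
    tr = dataset.trials
    keep = (
        (tr["choice"] != "nogo")
        & (tr["reaction_time"] >= rt_range[0])
        & (tr["reaction_time"] <= rt_range[1])
    ).to_numpy()
    if keep.sum() < 2:
        raise ValueError("need at least 2 qualifying Go trials")
    counts, t = dataset.bin_counts(
        align="stim_onset", window=(-0.5, 0.5), binsize=binsize,
        trial_mask=keep,
    )
    n_box = max(int(round(boxcar / binsize)), 1)
    kernel = np.full(n_box, 1.0 / n_box)
    rates = _causal_filter(counts[keep], kernel) / binsize
    pop = rates.mean(axis=1)  # population-average rate per trial
    i_base = int(np.argmin(np.abs(t - (-0.1))))
    base = pop[:, i_base]
    stim_idx = np.where((t >= 0) & (t < 0.5))[0]
    pvals = np.ones(len(stim_idx))
    for j, i in enumerate(stim_idx):
        col = pop[:, i]
        if np.all(col == col[0]) and np.all(base == col[0]):
            pvals[j] = 1.0
            continue
        pvals[j] = stats.mannwhitneyu(col, base, alternative="two-sided").pvalue
    sig = neighbor_filter(pvals < alpha)
    latency = float(t[stim_idx][sig.argmax()]) if sig.any() else None
    return LatencyEstimate(latency=latency, p_values=pvals, times=t[stim_idx])
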