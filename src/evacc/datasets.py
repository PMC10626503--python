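"""Containers and plain-text IO for trial tables and spike datasets.

A *trial table* is a :class:`pandas.DataFrame` with one row per trial and the
columns in :data:`TRIAL_COLUMNS`; times are in seconds on a single session
clock.  A :class:`SpikeDataset` bundles per-neuron spike-time arrays with the
trial table and per-neuron metadata, plus optional generator ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: The four stimulus contrast levels used on each screen.
CONTRAST_LEVELS = (0.0, 0.25, 0.5, 1.0)

#: Signed evidence levels (contrast_right - contrast_left).
EVIDENCE_LEVELS = tuple(np.round(np.arange(-1.0, 1.001, 0.25), 2))

TRIAL_COLUMNS = (
    "trial",
    "contrast_left",
    "contrast_right",
    "evidence",
    "choice",
    "outcome",
    "stim_onset",
    "wheel_move",
    "reaction_time",
)

CHOICES = ("left", "right", "nogo")


def correct_choice(contrast_left: float, contrast_right: float) -> str | None:
    """Rewarded response for a contrast pair.

    The side with the higher contrast is rewarded; ``nogo`` is rewarded only
    when both screens are blank.  Equal non-zero contrasts are a tie: either
    turn is rewarded, encoded here as ``None``.
    """
    if contrast_left == contrast_right == 0:
        return "nogo"
    if contrast_left > contrast_right:
        return "left"
    if contrast_right > contrast_left:
        return "right"
    return None


def outcome_of(contrast_left: float, contrast_right: float, choice: str) -> str:
    """Hit/miss label under the reward rule (ties reward either turn)."""
    target = correct_choice(contrast_left, contrast_right)
    if target is None:
        return "hit" if choice in ("left", "right") else "miss"
    return "hit" if choice == target else "miss"


def validate_trials(trials: pd.DataFrame) -> None:
    """Raise ``ValueError`` if a trial table violates its invariants."""
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    for col in ("contrast_left", "contrast_right"):
        bad = ~trials[col].isin(CONTRAST_LEVELS)
        if bad.any():
            raise ValueError(f"{col} outside {CONTRAST_LEVELS}")
    ev = trials["contrast_right"] - trials["contrast_left"]
    if not np.allclose(trials["evidence"], ev):
        raise ValueError("evidence != contrast_right - contrast_left")
    if not trials["choice"].isin(CHOICES).all():
        raise ValueError("unknown choice label")
    both = trials["wheel_move"].notna() & trials["reaction_time"].notna()
    rt = trials.loc[both, "wheel_move"] - trials.loc[both, "stim_onset"]
    if not np.allclose(trials.loc[both, "reaction_time"], rt):
        raise ValueError("reaction_time != wheel_move - stim_onset")


@dataclass
class SpikeDataset:
    """Spike times per neuron plus the trial table they were recorded under.

    Parameters
    ----------
    spikes
        One sorted, non-negative array of spike times (s) per neuron.
    trials
        Trial table with the :data:`TRIAL_COLUMNS` schema.
    neurons
        Per-neuron metadata; columns ``neuron_id``, ``region``, ``pref_side``
        (``contra``/``ipsi``).
    ground_truth
        Optional generator-side truth (spec parameters, latent paths, true
        latency ...); opaque to the analysis code.
    """

    spikes: list[np.ndarray]
    trials: pd.DataFrame
    neurons: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spikes = [np.asarray(s, dtype=float) for s in self.spikes]
        for s in self.spikes:
            if s.size and (np.any(np.diff(s) < 0) or s[0] < 0):
                raise ValueError("spike times must be sorted and non-negative")
        validate_trials(self.trials)

    @property
    def n_neurons(self) -> int:
        return len(self.spikes)

    def align_times(self, align: str) -> np.ndarray:
        """Per-trial alignment event times (``stim_onset`` or ``wheel_move``)."""
        if align not in ("stim_onset", "wheel_move"):
            raise ValueError(f"unknown alignment event {align!r}")
        return self.trials[align].to_numpy(float)

    def bin_counts(
        self,
        align: str = "stim_onset",
        window: tuple[float, float] = (-0.1, 0.3),
        binsize: float = 0.005,
        trial_mask: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-trial spike counts on a common grid.

        Returns ``(counts, t)`` with ``counts`` of shape
        ``(n_trials, n_neurons, n_bins)`` and ``t`` the left bin edges relative
        to the alignment event.  Bins are half-open ``[t, t + binsize)``.
        Trials whose alignment event is missing get all-NaN rows.
        """
        t0, t1 = window
        if t1 <= t0:
            raise ValueError("window must be increasing")
        n_bins = int(round((t1 - t0) / binsize))
        edges = t0 + binsize * np.arange(n_bins + 1)
        events = self.align_times(align)
        if trial_mask is not None:
            events = np.where(trial_mask, events, np.nan)
        counts = np.full((len(events), self.n_neurons, n_bins), np.nan)
        for i, ev in enumerate(events):
            if not np.isfinite(ev):
                continue
            for n, s in enumerate(self.spikes):
                lo = np.searchsorted(s, ev + edges[0])
                hi = np.searchsorted(s, ev + edges[-1])
                counts[i, n] = np.histogram(s[lo:hi] - ev, bins=edges)[0]
        return counts, edges[:-1]

    def counts_in_window(self, starts: np.ndarray, stops: np.ndarray) -> np.ndarray:
        """Total spike counts per (trial window, neuron); NaN windows -> NaN."""
        out = np.full((len(starts), self.n_neurons), np.nan)
        for i, (a, b) in enumerate(zip(starts, stops)):
            if not (np.isfinite(a) and np.isfinite(b)):
                continue
            for n, s in enumerate(self.spikes):
                out[i, n] = np.searchsorted(s, b) - np.searchsorted(s, a)
        return out


def _yaml_safe(obj):
    """Recursively convert numpy scalars/arrays so yaml.safe_dump accepts them."""
    if isinstance(obj, dict):
        return {str(k): _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_dataset(dataset: SpikeDataset, outdir: str | Path, sep: str = "\t") -> None:
    """Write a dataset as plain text: spikes.tsv, trials.csv, neurons.csv
    and a ground_truth.yaml sidecar (latent paths and other arrays included)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        (nid, t)
        for nid, s in zip(dataset.neurons["neuron_id"], dataset.spikes)
        for t in s
    ]
    pd.DataFrame(rows, columns=["neuron_id", "time_s"]).to_csv(
        outdir / "spikes.tsv", sep=sep, index=False
    )
    dataset.trials.to_csv(outdir / "trials.csv", index=False)
    dataset.neurons.to_csv(outdir / "neurons.csv", index=False)
    with open(outdir / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(_yaml_safe(dataset.ground_truth), fh)


def read_dataset(indir: str | Path) -> SpikeDataset:
    """Read a dataset written by :func:`write_dataset` (TSV or CSV spikes)."""
    indir = Path(indir)
    spk_path = indir / "spikes.tsv"
    spk = pd.read_csv(spk_path, sep=None, engine="python")
    trials = pd.read_csv(indir / "trials.csv")
    neurons = pd.read_csv(indir / "neurons.csv")
    spikes = []
    for nid in neurons["neuron_id"]:
        s = spk.loc[spk["neuron_id"] == nid, "time_s"].to_numpy(float)
        spikes.append(np.sort(s))
    gt_path = indir / "ground_truth.yaml"
    gt = {}
    if gt_path.exists():
        with open(gt_path) as fh:
            gt = yaml.safe_load(fh) or {}
    return SpikeDataset(spikes=spikes, trials=trials, neurons=neurons, ground_truth=gt)
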