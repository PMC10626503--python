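"""Generator contracts: determinism, task structure, ground-truth values."""

import numpy as np
import pandas as pd
import pytest

from evacc import accumulators as acc
from evacc import synthetic
from tests.conftest import SINGLE_GEN


def test_contrast_grid_cells():
    t_no_eq = synthetic.make_task_trials(2000, include_equal_contrast=False, seed=1)
    cells = t_no_eq.groupby(["contrast_left", "contrast_right"]).size()
    assert len(cells) == 12
    assert (t_no_eq["contrast_left"] != t_no_eq["contrast_right"]).all()
    t_eq = synthetic.make_task_trials(4000, include_equal_contrast=True, seed=1)
    assert len(t_eq.groupby(["contrast_left", "contrast_right"]).size()) == 16


def test_task_trials_deterministic_and_validated():
    a = synthetic.make_task_trials(50, seed=7)
    b = synthetic.make_task_trials(50, seed=7)
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(ValueError):
        synthetic.make_task_trials(0)
    with pytest.raises(ValueError):
        synthetic.make_task_trials(10, rt_range=(0.5, 0.2))


def test_accumulator_dataset_deterministic(single_spec, task_trials):
    a = synthetic.simulate_accumulator_dataset(single_spec, task_trials, seed=3)
    b = synthetic.simulate_accumulator_dataset(single_spec, task_trials, seed=3)
    for sa, sb in zip(a.spikes, b.spikes):
        assert np.array_equal(sa, sb)
    pd.testing.assert_frame_equal(a.trials, b.trials)


def test_psychometric_monotonicity(single_spec):
    """P(choose right) is non-decreasing in evidence (binomial margin)."""
    trials = synthetic.make_task_trials(1600, seed=31)
    ds = synthetic.simulate_accumulator_dataset(single_spec, trials, seed=32)
    t = ds.trials
    p = {}
    for e in (0.25, 1.0):
        m = np.isclose(t["evidence"], e)
        p[e] = (t.loc[m, "choice"] == "right").mean()
    n_min = min(np.isclose(t["evidence"], e).sum() for e in p)
    margin = 2.0 / np.sqrt(n_min)
    assert p[1.0] > p[0.25] - margin
    assert p[1.0] > 0.9


def test_chronometric_property(single_spec):
    trials = synthetic.make_task_trials(1200, seed=41)
    ds = synthetic.simulate_accumulator_dataset(single_spec, trials, seed=42)
    t = ds.trials
    rt_strong = t.loc[np.isclose(t["evidence"].abs(), 1.0), "reaction_time"].mean()
    rt_weak = t.loc[np.isclose(t["evidence"].abs(), 0.25), "reaction_time"].mean()
    assert rt_strong < rt_weak


def test_noise_free_limit_deterministic_rt():
    """With vanishing noise, strong rightward evidence always chooses right
    at the first-passage time of the noiseless recursion."""
    spec = acc.build_accumulator(
        "single", init_values={"A_acc": 0.98, "V_acc": 0.05, "Q_acc": 1e-12}, seed=0
    )
    trials = synthetic.make_task_trials(40, seed=5)
    trials["contrast_left"] = 0.0
    trials["contrast_right"] = 1.0
    trials["evidence"] = 1.0
    ds = synthetic.simulate_accumulator_dataset(spec, trials, seed=6, onset_delay=0.1)
    assert (ds.trials["choice"] == "right").all()
    # noiseless recursion x_t = a x_{t-1} + v reaches 1 at a fixed step
    x, steps = 0.0, 0
    while x < 1.0:
        x = 0.98 * x + 0.05
        steps += 1
    expected_rt = 0.1 + steps * spec.dt
    assert np.allclose(ds.trials["reaction_time"], expected_rt, atol=1e-9)


def test_zero_rate_emissions_yield_no_spikes(task_trials):
    spec = acc.build_accumulator(
        "single",
        init_values=SINGLE_GEN,
        emissions=(np.zeros((3, 1)), -500.0),  # softplus(d) ~ 0
        seed=0,
    )
    ds = synthetic.simulate_accumulator_dataset(spec, task_trials, seed=1)
    assert all(len(s) == 0 for s in ds.spikes)


def test_spikes_inside_session(accumulator_dataset):
    end = accumulator_dataset.trials["stim_onset"].iloc[-1] + synthetic.TRIAL_SPACING
    for s in accumulator_dataset.spikes:
        assert s.min() >= 0.0
        assert s.max() <= end


def test_selectivity_cohort_tuning_and_errors(task_trials):
    with pytest.raises(ValueError):
        synthetic.make_selectivity_cohort(2, baseline_rate=-1.0, trials=task_trials)
    with pytest.raises(ValueError):
        synthetic.make_selectivity_cohort(
            2, tuning={"choice": np.array([np.inf, 0.0])}, trials=task_trials
        )
    ds = synthetic.make_selectivity_cohort(
        4, tuning={"stimulus": 10.0}, trials=task_trials, seed=2
    )
    assert ds.n_neurons == 4
    assert ds.ground_truth["true_latency"] == pytest.approx(0.05)
    # tuned neurons fire more after onset on high-contrast trials
    hi = ds.trials["contrast_right"] == 1.0
    counts, _ = ds.bin_counts(window=(0.1, 0.5), binsize=0.4)
    base, _ = ds.bin_counts(window=(-0.5, -0.1), binsize=0.4)
    assert np.nanmean(counts[hi]) > np.nanmean(base[hi])


@pytest.mark.parametrize(
    "a,expected",
    [(0.95, 0.4874), (0.99, 2.4875)],
)
def test_ar1_true_timescale_closed_form(a, expected):
    ds = synthetic.make_ar1_population(a=a, step=0.025, n_trials=30, n_neurons=2,
                                       seed=0)
    assert ds.ground_truth["true_timescale"] == pytest.approx(expected, abs=1e-4)


def test_ar1_latent_lag0_autocorrelation_is_one():
    ds = synthetic.make_ar1_population(a=0.9, n_trials=400, n_neurons=2, seed=1)
    x = np.asarray(ds.ground_truth["latents"])  # (trials, bins), first neuron
    z = (x - x.mean(0)) / x.std(0)
    lag0 = np.mean(z * z, axis=0)
    assert np.allclose(lag0, 1.0, atol=1e-9)


def test_ar1_rejects_nonstationary_coefficient():
    with pytest.raises(ValueError):
        synthetic.make_ar1_population(a=1.0, n_trials=30)
    with pytest.raises(ValueError):
        synthetic.make_ar1_population(a=0.9, n_trials=30, duration=0.21, step=0.025)
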