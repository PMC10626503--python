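"""Autocorrelation pooling, decay fitting, region statistics."""

import numpy as np
import pandas as pd
import pytest

from evacc import accumulators as acc
from evacc import synthetic
from evacc import timescales as ts
from tests.conftest import SINGLE_GEN


def test_independent_counts_have_no_autocorrelation(rng):
    counts = rng.poisson(1.5, size=(600, 5, 8)).astype(float)
    curve = ts.spike_count_autocorrelation(counts)
    assert len(curve.lags) == 7  # 8 bins -> 7 distinct lags
    assert np.all(np.abs(curve.values) < 3.0 / np.sqrt(600))


def test_ar1_counts_decay_monotonically():
    ds = synthetic.make_ar1_population(a=0.9, n_trials=3000, n_neurons=40, seed=2)
    curve = ts.spike_count_autocorrelation(ds)
    assert curve.values[0] > 0.05
    # smooth within noise: strictly decreasing after mild smoothing
    assert curve.values[0] > curve.values[3] > curve.values[6]


def test_autocorrelation_requires_enough_trials(rng):
    with pytest.raises(ValueError):
        ts.spike_count_autocorrelation(rng.poisson(1, (10, 2, 8)).astype(float))


def test_pooling_invariant_to_neuron_and_trial_order(rng):
    counts = rng.poisson(2.0, size=(100, 6, 8)).astype(float)
    base = ts.spike_count_autocorrelation(counts)
    shuffled = counts[rng.permutation(100)][:, rng.permutation(6), :]
    other = ts.spike_count_autocorrelation(shuffled)
    assert np.allclose(
        np.nan_to_num(base.values), np.nan_to_num(other.values), atol=1e-12
    )


def test_noiseless_curve_recovered_exactly():
    lags = np.arange(1, 8)
    vals = 0.8 * (np.exp(-lags * 0.025 / 0.3) + 0.05)
    fit = ts.fit_timescale(
        ts.AutocorrCurve(lags=lags, values=vals, delta=0.025, n_trials=10**6)
    )
    assert fit.amplitude == pytest.approx(0.8, abs=1e-4)
    assert fit.offset == pytest.approx(0.05, abs=1e-4)
    assert fit.tau == pytest.approx(0.3, abs=1e-4)


def test_start_lag_after_sharp_drop():
    lags = np.arange(1, 8)
    vals = np.array([0.9, 0.3, 0.28, 0.26, 0.24, 0.22, 0.2])
    assert ts.choose_start_lag(vals, lags) == 2
    fit = ts.fit_timescale(
        ts.AutocorrCurve(lags=lags, values=vals, delta=0.025, n_trials=1000)
    )
    assert fit.start_lag == 2


def test_subpopulation_timescale_determinism_and_single_sample(single_spec):
    t1 = ts.subpopulation_timescale(single_spec, n_samples=3, n_trials=300, seed=9)
    t2 = ts.subpopulation_timescale(single_spec, n_samples=3, n_trials=300, seed=9)
    assert t1[0] == t2[0]
    tau1, sd1, fits1 = ts.subpopulation_timescale(
        single_spec, n_samples=1, n_trials=300, seed=10
    )
    assert sd1 == 0.0
    assert tau1 == pytest.approx(fits1[0].tau)


def test_timescale_monotone_in_recurrent_strength():
    taus = []
    for a_acc in (0.90, 0.95, 0.99):
        spec = acc.build_accumulator(
            "single", init_values={**SINGLE_GEN, "A_acc": a_acc}, seed=0
        )
        tau, _, _ = ts.subpopulation_timescale(
            spec, n_samples=8, n_trials=800, seed=11
        )
        taus.append(tau)
    assert taus[0] < taus[1] < taus[2]


def test_population_timescale_separates_fast_and_slow_regions(rng):
    curves = {}
    taus = {}
    for name, a_acc in (("fast", 0.93), ("slow", 0.99)):
        spec = acc.build_accumulator(
            "single", init_values={**SINGLE_GEN, "A_acc": a_acc}, seed=0
        )
        curves[name] = [
            ts.spike_count_autocorrelation(
                ts.simulate_fixed_length_counts(spec, 1500, rng=rng)
            )
            for _ in range(12)
        ]
        taus[name] = np.array([
            ts.subpopulation_timescale(spec, n_samples=8, n_trials=800,
                                       seed=100 * hash(name) % 997 + i)[0]
            for i in range(12)
        ])
    res = ts.population_timescale(curves, n_boot=60, seed=12, subpop_taus=taus)
    tab = res.table.set_index("region")
    assert tab.loc["fast", "tau"] < tab.loc["slow", "tau"]
    assert tab.loc["fast", "ci_high"] < tab.loc["slow", "ci_low"]
    assert res.pairwise_p.loc["fast", "slow"] < 0.001


def test_identical_regions_mostly_non_significant(rng):
    """Same generator in both regions: the corrected test stays quiet."""
    spec = acc.build_accumulator("single", init_values=SINGLE_GEN, seed=0)
    hits = 0
    for rep in range(5):
        curves = {
            name: [
                ts.spike_count_autocorrelation(
                    ts.simulate_fixed_length_counts(spec, 1200, rng=rng)
                )
                for _ in range(10)
            ]
            for name in ("a", "b")
        }
        res = ts.population_timescale(curves, n_boot=40, seed=rep)
        hits += res.pairwise_p.loc["a", "b"] < 0.05
    assert hits <= 2


def test_single_subpopulation_region_has_no_ci():
    spec = acc.build_accumulator("single", init_values=SINGLE_GEN, seed=0)
    rng = np.random.default_rng(0)
    curve = ts.spike_count_autocorrelation(
        ts.simulate_fixed_length_counts(spec, 800, rng=rng)
    )
    res = ts.population_timescale({"only": [curve]}, n_boot=20, seed=0)
    row = res.table.iloc[0]
    assert np.isfinite(row["tau"])
    assert np.isnan(row["ci_low"]) and np.isnan(row["ci_high"])


def test_strength_correlation_properties():
    rng = np.random.default_rng(3)
    strengths = np.linspace(0.9, 0.99, 12)
    taus = -0.01 / np.log(strengths) + rng.normal(0, 0.01, 12)
    tab = pd.DataFrame({"region": "r", "strength": strengths, "tau": taus})
    out = ts.strength_timescale_correlation(tab)
    r = out.loc[0, "r"]
    assert r > 0.8
    # Pearson r invariant to affine rescaling of tau
    tab2 = tab.assign(tau=1000.0 * tab["tau"] + 3.0)
    assert ts.strength_timescale_correlation(tab2).loc[0, "r"] == pytest.approx(r)
    # constant strength -> undefined, flagged
    tab3 = tab.assign(strength=0.95)
    out3 = ts.strength_timescale_correlation(tab3)
    assert not out3.loc[0, "tested"]
    assert np.isnan(out3.loc[0, "r"])


def test_recurrent_strength_by_architecture():
    s = acc.build_accumulator("single", init_values={"A_acc": 0.97}, seed=0)
    assert ts.recurrent_strength(s) == pytest.approx(0.97)
    r = acc.build_accumulator("independent_race", init_values={"A_acc": 0.96}, seed=0)
    assert ts.recurrent_strength(r) == pytest.approx(0.96)
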