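"""Accumulator construction, transitions, boundaries, emissions, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evacc import accumulators as acc
from evacc import synthetic
from tests.conftest import DRACE_GEN, IRACE_GEN, SINGLE_GEN


@pytest.mark.parametrize(
    "kind,K,D,M",
    [("single", 3, 1, 1), ("independent_race", 3, 2, 2), ("dependent_race", 5, 2, 2)],
)
def test_architecture_shapes(kind, K, D, M):
    spec = acc.build_accumulator(kind, seed=0)
    assert spec.shapes == (K, D, M)
    assert spec.A.shape == (K, D, D)
    R, r = spec.transition_params
    assert R.shape == (K, D) and r.shape == (K,)


def test_independent_race_is_diagonal():
    spec = acc.build_accumulator("independent_race", init_values=IRACE_GEN, seed=0)
    off = ~np.eye(2, dtype=bool)
    for mat in (spec.A[0], spec.V[0], spec.Q[0]):
        assert np.all(mat[off] == 0)
    with pytest.raises(ValueError):
        acc.build_accumulator("independent_race", init_values={"A_off": -0.1})


def test_dependent_race_off_diagonal_init():
    spec = acc.build_accumulator(
        "dependent_race", init_values={"A_off": -0.05}, seed=0
    )
    assert spec.A[0][0, 1] == pytest.approx(-0.05)
    assert spec.A[0][1, 0] == pytest.approx(-0.05)


def test_movement_states_fixed_dynamics():
    for kind in acc.KINDS:
        spec = acc.build_accumulator(kind, seed=1)
        K, D, _ = spec.shapes
        for k in range(1, K):
            assert np.allclose(spec.A[k], np.eye(D))
            assert np.all(spec.V[k] == 0)


def test_standard_init_grids_contain_reference_values():
    g = acc.INIT_GRIDS["single"]
    assert set(g["A_acc"]) >= {0.95, 1.0}
    assert set(g["V_acc"]) >= {0.01, 0.02, 0.03, 0.04, 0.05}
    assert set(g["Q_acc"]) >= {0.005, 0.01}
    gi = acc.INIT_GRIDS["independent_race"]
    assert set(gi["V_acc"]) >= {0.01, 0.02, 0.03}
    gd = acc.INIT_GRIDS["dependent_race"]
    assert -0.05 in gd["A_off"] and set(gd["V_off"]) >= {-0.01, -0.02, -0.03}
    assert set(acc.COLLAPSE_GRID["beta"]) == {0.3, 0.4, 0.5}
    assert set(acc.COLLAPSE_GRID["tau_c"]) == {50.0, 100.0}


def test_transition_probabilities_at_center_and_boundary():
    spec = acc.build_accumulator("single", seed=0)
    p0 = acc.transition_probs(spec, np.array([0.0]))
    assert np.allclose(p0, [0.5761, 0.2119, 0.2119], atol=2e-4)
    p1 = acc.transition_probs(spec, np.array([1.0]))
    assert np.allclose(p1, [0.4683, 0.4683, 0.0634], atol=2e-4)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    x=st.lists(st.floats(-3, 3, allow_nan=False), min_size=2, max_size=2),
    t=st.integers(0, 200),
    mode=st.sampled_from(["constant", "linear_collapse", "exponential_collapse"]),
    prev=st.integers(0, 4),
)
def test_transition_rows_sum_to_one(x, t, mode, prev):
    spec = acc.build_accumulator("dependent_race", boundary_mode=mode, seed=0)
    p = acc.transition_probs(spec, np.array(x), t, prev_state=prev)
    assert p.shape == (5,)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    assert (p >= 0).all()


def test_collapse_boundary_endpoints_and_curve():
    spec = acc.build_accumulator(
        "single", boundary_mode="exponential_collapse",
        init_values={"beta": 0.3, "tau_c": 50.0}, seed=0,
    )
    t = np.arange(0, 400)
    f = acc.boundary_factor(spec, t)
    assert f[0] == pytest.approx(1.0)
    assert f[-1] == pytest.approx(0.3, abs=0.01)
    for beta in (0.3, 0.4, 0.5):
        for tau_c in (50.0, 100.0):
            s = acc.build_accumulator(
                "single", boundary_mode="exponential_collapse",
                init_values={"beta": beta, "tau_c": tau_c}, seed=0,
            )
            direct = beta + (1 - beta) * np.exp(-t / tau_c)
            assert np.allclose(acc.boundary_factor(s, t), direct, atol=1e-12)


def test_linear_collapse_boundary():
    spec = acc.build_accumulator(
        "single", boundary_mode="linear_collapse", init_values={"beta": 0.01},
        seed=0,
    )
    f = acc.boundary_factor(spec, np.arange(0, 300))
    assert f[0] == pytest.approx(1.0)
    assert np.all(np.diff(f) <= 0)
    assert f[-1] == 0.0  # floored at zero


def test_emission_rate_properties():
    spec = acc.build_accumulator(
        "single", emissions=(np.zeros((4, 1)), 2.0), seed=0
    )
    rate = acc.emission_rate(spec, np.array([[0.3], [5.0]]))
    assert np.allclose(rate, np.log1p(np.exp(2.0)) * spec.dt)
    spec2 = acc.build_accumulator(
        "single", emissions=(np.full((2, 1), 1.5), 0.0), seed=0
    )
    r0 = acc.emission_rate(spec2, np.array([0.0]))
    assert np.allclose(r0, np.log(2.0) * spec2.dt)
    # monotone in the latent for nonnegative weights
    xs = np.linspace(-2, 2, 9)[:, None]
    rates = acc.emission_rate(spec2, xs)
    assert (np.diff(rates[:, 0]) > 0).all()


def test_simulate_noiseless_drift_ramps_and_prefers_right():
    """With Q -> 0 and positive input the latent rises deterministically;
    commitments are still sampled from the softmax, so rightward movement is
    the (strongly) majority outcome rather than a certainty."""
    spec = acc.build_accumulator(
        "single",
        init_values={"A_acc": 0.98, "V_acc": 0.05, "Q_acc": 1e-12},
        seed=0,
    )
    trials = synthetic.make_task_trials(200, seed=1)
    trials["contrast_left"] = 0.0
    trials["contrast_right"] = 1.0
    trials["evidence"] = 1.0
    out = acc.simulate(spec, trials, seed=2)
    for trial in out[:20]:
        x = trial["latents"][:, 0]
        pre_move = trial["states"] == 0
        assert (np.diff(x[pre_move]) > 0).all()
    choices = np.array([t["choice"] for t in out])
    assert (choices == "right").mean() > (choices == "left").mean()


def test_deeper_collapse_shortens_reaction_times():
    trials = synthetic.make_task_trials(1000, seed=3)
    rts = {}
    for beta in (0.3, 0.9):
        spec = acc.build_accumulator(
            "single", boundary_mode="exponential_collapse",
            init_values={**SINGLE_GEN, "beta": beta, "tau_c": 20.0}, seed=0,
        )
        out = acc.simulate(spec, trials, seed=4)
        rts[beta] = np.nanmean([t["rt"] for t in out])
    assert rts[0.3] < rts[0.9]


def test_negative_coupling_anticorrelates_accumulators():
    trials = synthetic.make_task_trials(400, seed=5)
    corr = {}
    for name, a_off in (("coupled", -0.3), ("independent", 0.0)):
        kind = "dependent_race" if a_off else "independent_race"
        iv = dict(A_acc=0.9, V_acc=0.0, Q_acc=0.01)
        if a_off:
            iv["A_off"] = a_off
            iv["V_off"] = 0.0
        spec = acc.build_accumulator(kind, init_values=iv, seed=0)
        spec.B = 1e6  # boundary-free: stay in accumulation
        out = acc.simulate(spec, trials.iloc[:50], seed=6, max_duration=0.5)
        xs = np.vstack([t["latents"] for t in out])
        corr[name] = np.corrcoef(xs[:, 0], xs[:, 1])[0, 1]
    assert corr["coupled"] < corr["independent"] - 0.2


def test_infinite_boundary_never_leaves_accumulation():
    spec = acc.build_accumulator("single", init_values=SINGLE_GEN, seed=0)
    spec.B = 1e9
    trials = synthetic.make_task_trials(20, seed=7)
    out = acc.simulate(spec, trials, seed=8, max_duration=0.3)
    for t in out:
        assert (t["states"] == 0).all()
        assert t["choice"] == "nogo"


def test_spec_serialization_round_trip(tmp_path):
    spec = acc.build_accumulator("dependent_race", init_values=DRACE_GEN,
                                 boundary_mode="exponential_collapse", seed=9)
    path = tmp_path / "spec.yaml"
    acc.save_spec(spec, path)
    back = acc.load_spec(path)
    assert back.kind == spec.kind
    assert np.allclose(back.A, spec.A)
    assert np.allclose(back.C, spec.C)
    assert back.boundary_mode == spec.boundary_mode
    assert back.beta == spec.beta


def test_free_parameter_counts():
    n = 4
    single = acc.build_accumulator("single", n_neurons=n, seed=0)
    irace = acc.build_accumulator("independent_race", n_neurons=n, seed=0)
    drace = acc.build_accumulator("dependent_race", n_neurons=n, seed=0)
    # A_acc + Q_acc + movement noise (diagonal per state) + C + d
    assert acc.n_free_parameters(single) == 1 + 1 + 2 + n + 1
    assert acc.n_free_parameters(irace) == 2 + 2 + 4 + 2 * n + 1
    assert acc.n_free_parameters(drace) == 4 + 3 + 8 + 2 * n + 1


def test_invalid_configurations_rejected():
    with pytest.raises(ValueError):
        acc.build_accumulator("twin")
    with pytest.raises(ValueError):
        acc.build_accumulator("single", boundary_mode="parabolic")
    with pytest.raises(ValueError):
        acc.build_accumulator("single", init_values={"bogus": 1.0})
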