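"""Marginalization identities, demixing recovery, fuzzy C-means."""

import numpy as np
import pandas as pd
import pytest

from evacc import dpca, synthetic
from evacc.pipeline import concat_neurons


@pytest.fixture(scope="module")
def mixed_cohort():
    trials = synthetic.make_task_trials(400, seed=11)
    stim = synthetic.make_selectivity_cohort(
        10, tuning={"stimulus": 14.0}, trials=trials, seed=1
    )
    dec = synthetic.make_selectivity_cohort(
        10, tuning={"outcome": 8.0}, trials=trials, seed=2
    )
    return concat_neurons(stim, dec)


@pytest.fixture(scope="module")
def tensor(mixed_cohort):
    return dpca.build_marginalized_tensor(mixed_cohort)


def test_marginalization_identity(tensor, rng):
    Xc = tensor.X - tensor.X.mean(axis=(1, 2, 3), keepdims=True)
    parts = dpca.marginalize(Xc)
    assert np.allclose(sum(parts.values()), Xc, atol=1e-10)
    # holds for arbitrary tensors too
    Y = rng.standard_normal((5, 4, 2, 7))
    assert np.allclose(sum(dpca.marginalize(Y).values()), Y, atol=1e-12)


def test_silent_neurons_masked(mixed_cohort):
    silent = synthetic.make_selectivity_cohort(
        2, baseline_rate=0.0, trials=mixed_cohort.trials, seed=3
    )
    ds = concat_neurons(mixed_cohort, silent)
    tensor = dpca.build_marginalized_tensor(ds)
    assert tensor.include[:20].all()
    assert not tensor.include[20:].any()


def test_contrast_axis_ordering(tensor, mixed_cohort):
    """Stimulus-tuned neurons' condition-mean rate follows the (1, .5, .25, 0)
    contra-contrast ordering of the tensor's stimulus axis."""
    stim_means = tensor.X[:10].mean(axis=(2, 3))  # (neurons, 4 contrasts)
    assert (np.diff(stim_means, axis=1) < 0).all()


def test_demixing_separates_stimulus_and_decision(tensor):
    res = dpca.fit_dpca(tensor)
    assert res.n_components <= 20
    assert (res.r2_st[:10] > res.r2_dt[:10]).all()
    assert (res.r2_dt[10:] > res.r2_st[10:]).all()
    assert np.nanmax(res.r2_st) <= 1.0 + 1e-9


def test_rank2_stimulus_subspace_recovery(rng):
    """Data from a rank-2 stimulus subspace + noise: the stimulus components
    capture >= 90% of the stimulus-marginalization variance."""
    N, T = 30, 40
    contrast = np.array([1.0, 0.5, 0.25, 0.0])
    t = np.linspace(0, 1, T)
    pat1 = np.outer(contrast - contrast.mean(), np.sin(np.pi * t))
    pat2 = np.outer(contrast**2 - (contrast**2).mean(), t)
    w1, w2 = rng.standard_normal(N), rng.standard_normal(N)
    X = (
        w1[:, None, None, None] * pat1[None, :, None, :] * 5
        + w2[:, None, None, None] * pat2[None, :, None, :] * 5
        + 0.1 * rng.standard_normal((N, 4, 2, T))
    )
    tensor = dpca.MarginalizedTensor(
        X=X, times=t, include=np.ones(N, bool), imputed=np.zeros((4, 2), bool)
    )
    res = dpca.fit_dpca(tensor, ridge=1e-6)
    Xc = X - X.mean(axis=(1, 2, 3), keepdims=True)
    st = dpca.marginalize(Xc)["st"].reshape(N, -1)
    recon = res.encoders["st"] @ (res.decoders["st"] @ Xc.reshape(N, -1))
    captured = 1.0 - np.sum((st - recon) ** 2) / np.sum(st**2)
    assert captured >= 0.90


def test_zero_tensor_zero_loss():
    tensor = dpca.MarginalizedTensor(
        X=np.zeros((6, 4, 2, 10)),
        times=np.arange(10.0),
        include=np.ones(6, bool),
        imputed=np.zeros((4, 2), bool),
    )
    res = dpca.fit_dpca(tensor, ridge=1.0)
    assert res.loss == pytest.approx(0.0, abs=1e-18)


def test_more_components_never_increase_loss(tensor):
    losses = [
        dpca.fit_dpca(tensor, n_components=k, ridge=10.0).loss for k in (8, 14, 20)
    ]
    assert losses[0] >= losses[1] >= losses[2]


def test_r2_endpoints(tensor):
    res = dpca.fit_dpca(tensor)
    # reconstruction equal to the tensor itself -> R^2 = 1
    full = dpca.DpcaResult(
        encoders={a: np.eye(20) for a in ("st", "dt")},
        decoders={a: np.eye(20) for a in ("st", "dt")},
        component_variance={}, ridge=0.0,
    )
    r2_st, r2_dt = dpca.marginalization_r2(full, tensor)
    assert np.allclose(r2_st, 1.0) and np.allclose(r2_dt, 1.0)
    # reconstruction equal to the grand mean (zero in centered coords) -> 0
    null = dpca.DpcaResult(
        encoders={a: np.zeros((20, 0)) for a in ("st", "dt")},
        decoders={a: np.zeros((0, 20)) for a in ("st", "dt")},
        component_variance={}, ridge=0.0,
    )
    r2_st0, r2_dt0 = dpca.marginalization_r2(null, tensor)
    assert np.allclose(r2_st0, 0.0) and np.allclose(r2_dt0, 0.0)


def test_fcm_memberships_and_objective(rng):
    pts = rng.standard_normal((60, 2))
    v, u, obj = dpca.fuzzy_c_means(pts, 3, seed=2)
    assert np.allclose(u.sum(axis=1), 1.0, atol=1e-12)
    assert obj >= 0.0
    # objective non-increasing across iterations: rerun with max_iter sweep
    objs = [dpca.fuzzy_c_means(pts, 3, seed=2, max_iter=m)[2] for m in (2, 5, 50)]
    assert objs[0] >= objs[1] >= objs[2] - 1e-9


def test_fcm_degenerate_identical_points():
    pts = np.ones((10, 2))
    _, u, obj = dpca.fuzzy_c_means(pts, 3, seed=0)
    assert np.allclose(u, 1.0 / 3)
    assert obj == pytest.approx(0.0)


def test_cluster_blobs_label_agreement(rng):
    centers = {"stimulus": (0.8, 0.1), "decision": (0.1, 0.8),
               "interaction": (0.2, 0.2)}
    pts, truth = [], []
    for name, c in centers.items():
        pts.append(rng.normal(c, 0.04, size=(40, 2)))
        truth += [name] * 40
    pts = np.vstack(pts)
    out = dpca.cluster_neurons(pts, seed=3)
    agreement = (out["label"].to_numpy() == np.array(truth)).mean()
    assert agreement >= 0.95


def test_cluster_permutation_invariance(rng):
    pts = np.vstack([
        rng.normal((0.8, 0.1), 0.05, (30, 2)),
        rng.normal((0.1, 0.8), 0.05, (30, 2)),
        rng.normal((0.2, 0.2), 0.05, (30, 2)),
    ])
    perm = rng.permutation(len(pts))
    a = dpca.cluster_neurons(pts, seed=4)
    b = dpca.cluster_neurons(pts[perm], seed=4)
    restored = b["label"].to_numpy()[np.argsort(perm)]
    assert (a["label"].to_numpy() == restored).mean() >= 0.95
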