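"""Demixed PCA of trial-averaged activity and fuzzy grouping of neurons.

Population activity is arranged as a tensor ``X[N, 4, 2, T]`` (neurons x
contralateral contrast levels x decisions x time), decomposed into
condition-independent (``t``), stimulus (``st``), decision (``dt``) and
interaction (``sdt``) marginalizations that sum exactly to the (per-neuron
centered) tensor.  Demixed components are estimated per marginalization by
reduced-rank ridge regression of the marginalized tensor on the full one,
and a fixed budget of components is allocated across marginalizations by
explained variance.  Per-neuron stimulus/decision R-squared values (explained
variance of the *full* tensor through each marginalization's components,
normalized by deviation from the neuron's grand mean) feed a fuzzy C-means
clustering into stimulus / decision / interaction groups; the decision
cluster is the candidate pool for accumulator ("DDM-like") neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from evacc.datasets import SpikeDataset

CONTRA_ORDER = (1.0, 0.5, 0.25, 0.0)
MARGINALIZATIONS = ("t", "st", "dt", "sdt")


@dataclass
class MarginalizedTensor:
    """Trial-averaged activity tensor with marginalization bookkeeping."""

    X: np.ndarray  # (N, 4, 2, T) mean rates, Hz
    times: np.ndarray
    include: np.ndarray  # per-neuron inclusion mask (spike-count screen)
    imputed: np.ndarray  # (4, 2) cells filled with the condition-independent mean

    @property
    def n_neurons(self) -> int:
        return self.X.shape[0]


def build_marginalized_tensor(
    dataset: SpikeDataset,
    window: tuple[float, float] = (-0.1, 0.3),
    binsize: float = 0.01,
    min_mean_count: float = 1.0,
) -> MarginalizedTensor:
    """Average each neuron's rate within contra-contrast x hit/miss cells.

    The contralateral screen is the right one; the contrast axis is ordered
    (1, 0.5, 0.25, 0).  Neurons whose average total spike count between
    stimulus onset and wheel movement is below ``min_mean_count`` are masked
    out.  Empty cells are imputed with the condition-independent mean and
    flagged.
    """
    counts, t = dataset.bin_counts(align="stim_onset", window=window, binsize=binsize)
    rates = counts / binsize
    tr = dataset.trials
    hit = (tr["outcome"] == "hit").to_numpy()
    contra = tr["contrast_right"].to_numpy()

    N = dataset.n_neurons
    T = len(t)
    X = np.full((N, 4, 2, T), np.nan)
    for si, c in enumerate(CONTRA_ORDER):
        for di, is_hit in enumerate((True, False)):
            mask = (contra == c) & (hit == is_hit)
            if mask.any():
                X[:, si, di, :] = np.nanmean(rates[mask], axis=0).reshape(N, T)
    cond_mean = np.nanmean(X, axis=(1, 2))  # (N, T)
    imputed = np.zeros((4, 2), bool)
    for si in range(4):
        for di in range(2):
            if np.isnan(X[:, si, di, :]).all():
                X[:, si, di, :] = cond_mean
                imputed[si, di] = True

    go = tr["wheel_move"].notna().to_numpy()
    starts = tr["stim_onset"].to_numpy()
    stops = tr["wheel_move"].to_numpy()
    rt_counts = dataset.counts_in_window(
        np.where(go, starts, np.nan), np.where(go, stops, np.nan)
    )
    mean_counts = np.nanmean(rt_counts, axis=0) if go.any() else np.zeros(N)
    include = mean_counts >= min_mean_count
    return MarginalizedTensor(X=X, times=t, include=include, imputed=imputed)


def marginalize(X: np.ndarray) -> dict[str, np.ndarray]:
    """Split a (per-neuron centered) tensor into its four marginalizations.

    The parts sum exactly to the input: ``t`` is the mean over stimulus and
    decision, ``st``/``dt`` are the stimulus/decision means with ``t``
    removed, and ``sdt`` is the interaction residual.
    """
    Xt = X.mean(axis=(1, 2), keepdims=True)
    Xst = X.mean(axis=2, keepdims=True) - Xt
    Xdt = X.mean(axis=1, keepdims=True) - Xt
    Xsdt = X - Xt - Xst - Xdt
    full = np.broadcast_to
    shape = X.shape
    return {
        "t": np.ascontiguousarray(full(Xt, shape)),
        "st": np.ascontiguousarray(full(Xst, shape)),
        "dt": np.ascontiguousarray(full(Xdt, shape)),
        "sdt": Xsdt,
    }


@dataclass
class DpcaResult:
    """Demixed components and per-neuron marginalization R-squared values."""

    encoders: dict[str, np.ndarray]  # F_alpha, (N, r_alpha)
    decoders: dict[str, np.ndarray]  # D_alpha, (r_alpha, N)
    component_variance: dict[str, np.ndarray]
    ridge: float
    mean: np.ndarray = field(repr=False, default=None)  # per-neuron grand mean
    loss: float = np.nan
    r2_st: np.ndarray | None = None
    r2_dt: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return sum(f.shape[1] for f in self.encoders.values())


def _gcv_ridge(X: np.ndarray, targets: list[np.ndarray]) -> float:
    """Generalized cross-validation for the shared ridge penalty."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    S = X.shape[1]
    coords = [t_ @ Vt.T for t_ in targets]  # targets in the row space basis
    best, best_lam = np.inf, 1e-6
    for lam in np.geomspace(1e-8, 1e2, 11) * max(s.max() ** 2, 1e-12):
        shrink = s**2 / (s**2 + lam)
        df = shrink.sum()
        rss = 0.0
        for t_, c in zip(targets, coords):
            fitted = (c * shrink) @ Vt
            rss += float(np.sum((t_ - fitted) ** 2))
        gcv = rss / (1.0 - df / S) ** 2
        if gcv < best:
            best, best_lam = gcv, lam
    return best_lam


def fit_dpca(
    tensor: MarginalizedTensor,
    n_components: int = 20,
    ridge: float | None = None,
    min_per_marginalization: int = 2,
) -> DpcaResult:
    """Reduced-rank ridge estimation of demixed components.

    Minimizes ``sum_alpha ||X_alpha - F_alpha D_alpha X||^2`` with an
    optional ridge penalty (chosen by generalized cross-validation when not
    given).  Components are allocated across marginalizations by ranking
    their explained variance, with each marginalization guaranteed
    ``min_per_marginalization`` components (when available) so that a noisy
    interaction term cannot starve a weaker but genuine task axis; at most
    ``n_components`` in total.
    """
    Xfull = tensor.X[tensor.include]
    N = Xfull.shape[0]
    mean = Xfull.mean(axis=(1, 2, 3), keepdims=True)
    Xc = Xfull - mean
    Xmat = Xc.reshape(N, -1)
    parts = marginalize(Xc)
    mats = {a: parts[a].reshape(N, -1) for a in MARGINALIZATIONS}

    if ridge is None:
        ridge = _gcv_ridge(Xmat, list(mats.values()))
    G = Xmat @ Xmat.T + ridge * np.eye(N)
    Ginv = np.linalg.inv(G)

    cand = []  # (variance, alpha, rank within alpha, u vector, d row)
    for a in MARGINALIZATIONS:
        B = mats[a] @ Xmat.T @ Ginv
        proj = B @ Xmat
        U, s, Vt = np.linalg.svd(proj, full_matrices=False)
        r_max = int(np.sum(s > 1e-10 * max(s[0], 1e-30))) if s.size else 0
        for i in range(r_max):
            cand.append((s[i] ** 2, a, i, U[:, i], U[:, i] @ B))
    # reserve the top min_per_marginalization components of each axis, then
    # fill the remaining budget by explained variance
    reserved = [c for c in cand if c[2] < min_per_marginalization]
    rest = sorted(
        (c for c in cand if c[2] >= min_per_marginalization), key=lambda c: -c[0]
    )
    chosen = (reserved + rest)[:n_components]

    encoders, decoders, comp_var = {}, {}, {}
    for a in MARGINALIZATIONS:
        sel = sorted((c for c in chosen if c[1] == a), key=lambda c: c[2])
        encoders[a] = (
            np.stack([c[3] for c in sel], axis=1) if sel else np.zeros((N, 0))
        )
        decoders[a] = (
            np.stack([c[4] for c in sel], axis=0) if sel else np.zeros((0, N))
        )
        comp_var[a] = np.array([c[0] for c in sel])

    loss = 0.0
    for a in MARGINALIZATIONS:
        recon = encoders[a] @ (decoders[a] @ Xmat)
        loss += float(np.sum((mats[a] - recon) ** 2))
    result = DpcaResult(
        encoders=encoders,
        decoders=decoders,
        component_variance=comp_var,
        ridge=float(ridge),
        mean=mean.ravel(),
        loss=loss,
    )
    result.r2_st, result.r2_dt = marginalization_r2(result, tensor)
    return result


def marginalization_r2(
    result: DpcaResult, tensor: MarginalizedTensor
) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron explained variance of the full tensor through the stimulus
    and decision components, normalized by deviation from the neuron's grand
    mean.  Zero-variance neurons get NaN.
    """
    Xfull = tensor.X[tensor.include]
    N = Xfull.shape[0]
    Xc = (Xfull - Xfull.mean(axis=(1, 2, 3), keepdims=True)).reshape(N, -1)
    denom = np.sum(Xc**2, axis=1)
    out = []
    for a in ("st", "dt"):
        recon = result.encoders[a] @ (result.decoders[a] @ Xc)
        num = np.sum((recon - Xc) ** 2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(denom > 0, 1.0 - num / denom, np.nan)
        out.append(r2)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# fuzzy C-means

def fuzzy_c_means(
    points: np.ndarray,
    n_clusters: int,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int | None = 0,
):
    """Standard fuzzy C-means; returns (centroids, memberships, objective).

    Memberships are initialized from a seeded Dirichlet draw; iterations stop
    when the membership matrix changes by less than ``tol`` (max norm).  The
    objective ``sum_ij u_ij^m ||x_i - v_j||^2`` is non-increasing.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    if n < n_clusters:
        raise ValueError("need at least n_clusters points")
    if np.allclose(pts, pts[0]):
        u = np.full((n, n_clusters), 1.0 / n_clusters)
        return pts[:n_clusters].copy(), u, 0.0
    rng = np.random.default_rng(seed)
    u = rng.dirichlet(np.ones(n_clusters), size=n)
    m = fuzzifier
    obj = np.inf
    for _ in range(max_iter):
        um = u**m
        v = (um.T @ pts) / np.maximum(um.sum(axis=0)[:, None], 1e-300)
        d2 = np.sum((pts[:, None, :] - v[None, :, :]) ** 2, axis=2)
        zero = d2 < 1e-30
        d2 = np.maximum(d2, 1e-30)
        u_new = 1.0 / np.sum(
            (d2[:, :, None] / d2[:, None, :]) ** (1.0 / (m - 1.0)), axis=2
        )
        row_zero = zero.any(axis=1)
        if row_zero.any():
            u_new[row_zero] = zero[row_zero] / zero[row_zero].sum(
                axis=1, keepdims=True
            )
        obj = float(np.sum((u_new**m) * d2))
        if np.max(np.abs(u_new - u)) < tol:
            u = u_new
            break
        u = u_new
    return v, u, obj


def cluster_neurons(
    r2_pairs: np.ndarray,
    n_clusters: int = 3,
    fuzzifier: float = 2.0,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Group neurons by (R2_st, R2_dt) via fuzzy C-means.

    Cluster identity follows centroid position: the centroid with the largest
    stimulus-minus-decision margin is ``stimulus``, the largest
    decision-minus-stimulus margin is ``decision``, the rest ``interaction``.
    Returns a frame with columns ``R2_st, R2_dt, label`` and one membership
    column per cluster label.
    """
    pts = np.asarray(r2_pairs, float)
    v, u, _ = fuzzy_c_means(pts, n_clusters, fuzzifier=fuzzifier, seed=seed)
    margin = v[:, 0] - v[:, 1]
    names = np.array(["interaction"] * len(v), dtype=object)
    names[np.argmax(margin)] = "stimulus"
    names[np.argmin(margin)] = "decision"
    labels = names[np.argmax(u, axis=1)]
    df = pd.DataFrame({"R2_st": pts[:, 0], "R2_dt": pts[:, 1], "label": labels})
    seen: set[str] = set()
    for j, nm in enumerate(names):
        col = f"membership_{nm}"
        if col in seen:
            col = f"{col}_{j}"
        seen.add(col)
        df[col] = u[:, j]
    return df
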