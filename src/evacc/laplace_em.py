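"""Variational Laplace-EM for accumulator rSLDS models with Poisson emissions.

Inference alternates per iteration:

1. *Laplace pass* — damped Newton ascent to the mode of the expected
   complete-data log joint of each trial's latent path (dynamics and
   transition terms averaged over the current discrete posterior, Poisson
   emission term exact), with the block-tridiagonal Hessian assembled densely
   (latent paths are short).  This yields the deterministic evidence-bound
   trace used for convergence and initialization ranking.
2. *Continuous E-step* — the variational factor over the latent path is the
   exact posterior under the expected-dynamics Gaussian prior and the Poisson
   likelihood (the latent-to-transition coupling is left to the discrete
   factor — a structured mean-field choice that keeps the latent scale
   calibrated).  Elliptical slice sampling against the Gaussian prior draws
   the posterior samples from which all M-step sufficient statistics are
   computed; chains persist across EM iterations.
3. *Discrete E-step* — exact forward-backward smoothing of the switching
   states at the posterior-mean path, with transition matrices evaluated
   there and movement states sticky (absorbing once entered).
4. *M-step* — closed-form weighted regressions for the accumulation dynamics
   ``A_acc`` and noise ``Q_acc`` (respecting each architecture's structural
   zeros), movement-state noise, and a quasi-Newton Poisson-GLM update of the
   emission weights ``C`` and shared offset ``d`` on the posterior samples.
   Input weights ``V`` and all transition parameters stay fixed.

The reported trace is a Laplace evidence lower bound: expected log joint at
the mode plus the Gaussian entropy of the local quadratic approximation and
the marginal entropy of the discrete posterior.  It is monotone up to the
approximation error of the factorization and the Monte-Carlo M-step.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from evacc import accumulators as acc
from evacc.accumulators import STICKY_LOGIT, AccumulatorSpec
from evacc.datasets import SpikeDataset

_Q_FLOOR = 1e-5


@dataclass
class TrialBatch:
    """Binned spike counts and inputs for the trials entering one fit."""

    ys: list[np.ndarray]  # per trial (T, N) counts
    us: list[np.ndarray]  # per trial (M,) constant input stream
    choices: list[str]
    dt: float
    n_post: int  # movement bins at the end of each trial window

    def __len__(self) -> int:
        return len(self.ys)


def prepare_trials(
    dataset: SpikeDataset,
    kind: str,
    latency: float = 0.1,
    rt_range: tuple[float, float] = (0.15, 0.5),
    dt: float = 0.01,
    post_move: float = 0.05,
) -> TrialBatch:
    """Filter and bin trials for accumulator fitting.

    Keeps Go trials with unequal contrasts and reaction time strictly inside
    ``rt_range``; the per-trial window runs from ``stim_onset + latency``
    (the end of the visual-encoding phase) to ``wheel_move + post_move``,
    binned at ``dt``.
    """
    tr = dataset.trials
    keep = (
        (tr["choice"] != "nogo")
        & (tr["contrast_left"] != tr["contrast_right"])
        & (tr["reaction_time"] > rt_range[0])
        & (tr["reaction_time"] < rt_range[1])
    )
    ys, us, choices = [], [], []
    n_post = int(round(post_move / dt))
    for row in tr[keep].itertuples():
        t0 = row.stim_onset + latency
        t1 = row.wheel_move + post_move
        T = int(np.floor((t1 - t0) / dt))
        if T < n_post + 2:
            continue
        edges = t0 + dt * np.arange(T + 1)
        y = np.empty((T, dataset.n_neurons))
        for n, s in enumerate(dataset.spikes):
            y[:, n] = np.histogram(s, bins=edges)[0]
        ys.append(y)
        us.append(acc.input_vector(kind, row.contrast_left, row.contrast_right))
        choices.append(row.choice)
    return TrialBatch(ys=ys, us=us, choices=choices, dt=dt, n_post=n_post)


@dataclass
class FitResult:
    """Learned accumulator spec plus posterior summaries for one fit."""

    spec: AccumulatorSpec
    elbo_trace: np.ndarray
    latent_means: list[np.ndarray] = field(repr=False, default_factory=list)
    latent_samples: list[np.ndarray] = field(repr=False, default_factory=list)
    state_marginals: list[np.ndarray] = field(repr=False, default_factory=list)
    init_values: dict = field(default_factory=dict)
    converged: bool = False
    trials: TrialBatch | None = field(repr=False, default=None)

    @property
    def log_likelihood(self) -> float:
        return float(self.elbo_trace[-1])


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _safe_ratio(num, den, a, limit=1.0):
    """num/den with the a -> -inf limit substituted (softplus ratios)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(a < -30.0, limit, num / np.maximum(den, 1e-300))


def _choice_movement_state(kind: str, choice: str) -> int:
    for state, ch in acc.STATE_CHOICE[kind].items():
        if ch == choice:
            return state
    raise ValueError(f"no movement state for choice {choice!r}")


class _SpecCache:
    """Per-EM-iteration precomputations shared across trials."""

    def __init__(self, spec: AccumulatorSpec, max_T: int):
        K = spec.shapes[0]
        self.Qinv = np.stack([np.linalg.inv(spec.Q[k]) for k in range(K)])
        self.logdetQ = np.array(
            [np.linalg.slogdet(spec.Q[k])[1] for k in range(K)]
        )
        R, r = spec.transition_params
        self.R = R
        f = acc.boundary_factor(spec, np.arange(max_T))
        # effective transition offsets per step: boundary rows scale with f(t)
        self.r_eff = np.where(r[None, :] != 0, r[None, :] * f[:, None], 0.0)


class _TrialWorker:
    """Per-trial E-steps: Laplace mode, slice-sampled posterior, smoothing."""

    def __init__(self, y: np.ndarray, u: np.ndarray, choice: str, n_post: int):
        self.y = y
        self.u = u
        self.T = y.shape[0]
        self.choice = choice
        self.n_post = n_post
        self.x: np.ndarray | None = None  # posterior-mean path (T, D)
        self.omega: np.ndarray | None = None  # discrete marginals (T, K)
        self.samples: np.ndarray | None = None  # (n_keep, T, D)
        self._chain: np.ndarray | None = None  # persistent sampler state
        self._lyf: float | None = None

    def init_posteriors(self, spec: AccumulatorSpec) -> None:
        K, D, _ = spec.shapes
        T = self.T
        self.x = np.zeros((T, D))
        # The wheel-movement time is observed: before it the chain is in the
        # accumulation state, from it on in a movement state consistent with
        # the committed choice.  This evidence enters smoothing as a mask.
        allowed = np.zeros((T, K), dtype=bool)
        allowed[: T - self.n_post, 0] = True
        for state, ch in acc.STATE_CHOICE[spec.kind].items():
            if ch == self.choice:
                allowed[T - self.n_post :, state] = True
        self.state_mask = allowed
        omega = np.zeros((T, K))
        omega[:, 0] = 1.0
        move = _choice_movement_state(spec.kind, self.choice)
        omega[T - self.n_post :, :] = 0.0
        omega[T - self.n_post :, move] = 1.0
        self.omega = omega

    def _transition_logits(self, spec, cache, x_prev):
        return spec.gamma * (x_prev @ cache.R.T + cache.r_eff[: self.T])

    @property
    def _log_y_fact(self) -> float:
        if self._lyf is None:
            self._lyf = float(np.sum(gammaln(self.y + 1.0)))
        return self._lyf

    def _poisson_ll(self, spec, x_flat: np.ndarray) -> float:
        x = x_flat.reshape(self.T, -1)
        lam = np.maximum(_softplus(x @ spec.C.T + spec.d) * spec.dt, 1e-300)
        return float(np.sum(self.y * np.log(lam) - lam)) - self._log_y_fact

    def _objective(self, spec, cache, x, want_derivs: bool):
        """Expected log joint at x; optionally its gradient and Hessian blocks."""
        K, D, _ = spec.shapes
        T = self.T
        omega = self.omega
        x_prev = np.vstack([np.zeros(D), x[:-1]])
        val = 0.0
        grad = np.zeros((T, D)) if want_derivs else None
        diag = np.zeros((T, D, D)) if want_derivs else None
        off = np.zeros((max(T - 1, 0), D, D)) if want_derivs else None

        # dynamics, averaged over the discrete posterior
        for k in range(K):
            w = omega[:, k]
            if not np.any(w > 1e-12):
                continue
            Qinv = cache.Qinv[k]
            b = spec.V[k] @ self.u
            resid = x - x_prev @ spec.A[k].T - b
            rq = resid @ Qinv
            val += -0.5 * float(w @ np.einsum("td,td->t", resid, rq))
            val += -0.5 * w.sum() * (cache.logdetQ[k] + D * np.log(2 * np.pi))
            if want_derivs:
                grad += -(w[:, None] * rq)
                back = (w[:, None] * rq) @ spec.A[k]
                grad[:-1] += back[1:]
                diag += -w[:, None, None] * Qinv
                AQA = spec.A[k].T @ Qinv @ spec.A[k]
                diag[:-1] += -w[1:, None, None] * AQA
                off += w[1:, None, None] * (spec.A[k].T @ Qinv)

        # transitions: z_t | x_{t-1}; weight by P(z_{t-1} = acc), z_0 = acc
        if spec.gamma != 0.0:
            R = cache.R
            logits = self._transition_logits(spec, cache, x_prev)
            lse = logsumexp(logits, axis=1)
            w_prev = np.concatenate([[1.0], omega[:-1, 0]])
            val += float(w_prev @ (np.einsum("tk,tk->t", omega, logits) - lse))
            if want_derivs:
                pi = np.exp(logits - lse[:, None])
                gtr = spec.gamma * ((omega - pi) @ R)  # wrt x_{t-1}
                grad[:-1] += w_prev[1:, None] * gtr[1:]
                piR = pi @ R
                S = np.einsum("tk,kd,ke->tde", pi, R, R) - np.einsum(
                    "td,te->tde", piR, piR
                )
                diag[:-1] += -(spec.gamma**2) * w_prev[1:, None, None] * S[1:]

        # Poisson emissions
        a = x @ spec.C.T + spec.d
        sp = _softplus(a)
        sig = _sigmoid(a)
        lam = np.maximum(sp * spec.dt, 1e-300)
        val += float(np.sum(self.y * np.log(lam) - lam)) - self._log_y_fact
        if want_derivs and np.any(spec.C != 0):
            ratio = _safe_ratio(sig, sp, a)
            g = self.y * ratio - sig * spec.dt
            grad += g @ spec.C
            dsig = sig * (1.0 - sig)
            h = self.y * (_safe_ratio(dsig, sp, a) - ratio**2) - dsig * spec.dt
            diag += np.einsum("tn,nd,ne->tde", h, spec.C, spec.C)
        return val, grad, diag, off

    @staticmethod
    def _assemble(diag, off):
        T, D = diag.shape[0], diag.shape[1]
        H = np.zeros((T, D, T, D))
        idx = np.arange(T)
        H[idx, :, idx, :] = diag
        if T > 1:
            H[idx[:-1], :, idx[1:], :] = off
            H[idx[1:], :, idx[:-1], :] = np.transpose(off, (0, 2, 1))
        return H.reshape(T * D, T * D)

    @staticmethod
    def _chol_damped(negH):
        lam = 1e-8
        n = negH.shape[0]
        for _ in range(14):
            try:
                return cho_factor(negH + lam * np.eye(n))
            except np.linalg.LinAlgError:
                lam = max(lam * 10.0, 1e-6)
        raise np.linalg.LinAlgError("Hessian damping failed")

    def laplace_value(self, spec, cache, max_newton: int = 2):
        """Laplace evidence contribution: expected log joint at the local
        mode (a few warm-started Newton steps from the sampled posterior
        mean) plus the Gaussian entropy of the quadratic approximation.
        Updates ``self.x`` to the polished mode."""
        T, D = self.T, spec.shapes[1]
        x = self.x
        val, grad, diag, off = self._objective(spec, cache, x, True)
        for _ in range(max_newton):
            g = grad.ravel()
            if np.max(np.abs(g)) < 1e-7:
                break
            cf = self._chol_damped(-self._assemble(diag, off))
            step = cho_solve(cf, g).reshape(T, D)
            improved = False
            for scale in 2.0 ** -np.arange(9.0):
                x_new = x + scale * step
                val_new = self._objective(spec, cache, x_new, False)[0]
                if val_new > val:
                    x, val = x_new, val_new
                    improved = True
                    break
            if not improved:
                break
            _, grad, diag, off = self._objective(spec, cache, x, True)
        cf = self._chol_damped(-self._assemble(diag, off))
        logdet_sigma = -2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        self.x = x
        return val, logdet_sigma

    def ess_step(
        self, spec, spec_prior, cache_prior, rng, n_keep: int = 30, n_burn: int = 3
    ) -> np.ndarray:
        """Elliptical slice sampling of the latent path.

        The target is the exact posterior under the expected-dynamics
        Gaussian prior (discrete posterior held fixed) and the Poisson
        likelihood; the chain persists across EM iterations.  Returns the
        kept samples (n_keep, T, D) and updates ``self.x`` to their mean.
        """
        T, D = self.T, spec.shapes[1]
        _, g0, dg, off = self._objective(
            spec_prior, cache_prior, np.zeros((T, D)), True
        )
        P = -self._assemble(dg, off)
        Lc = cholesky(P + 1e-10 * np.eye(T * D), lower=True)
        mu = cho_solve((Lc, True), g0.ravel())

        n_iter = n_burn + n_keep
        zs = rng.standard_normal((T * D, n_iter))
        nus = solve_triangular(Lc.T, zs, lower=False).T  # prior-cov draws

        x = self._chain if self._chain is not None else mu.copy()
        ll = self._poisson_ll(spec, x)
        kept = np.empty((n_keep, T * D))
        for i in range(n_iter):
            nu = nus[i]
            logy = ll + np.log(rng.random())
            theta = rng.uniform(0.0, 2.0 * np.pi)
            lo, hi = theta - 2.0 * np.pi, theta
            centered = x - mu
            while True:
                x_prop = mu + centered * np.cos(theta) + nu * np.sin(theta)
                ll_prop = self._poisson_ll(spec, x_prop)
                if ll_prop > logy:
                    break
                if theta < 0:
                    lo = theta
                else:
                    hi = theta
                theta = rng.uniform(lo, hi)
            x, ll = x_prop, ll_prop
            if i >= n_burn:
                kept[i - n_burn] = x
        self._chain = x
        self.samples = kept.reshape(n_keep, T, D)
        self.x = self.samples.mean(axis=0)
        return self.samples

    def forward_backward(self, spec, cache) -> np.ndarray:
        """Exact discrete-state smoothing at the posterior mean (scaled form)."""
        K, D, _ = spec.shapes
        T = self.T
        x = self.x
        x_prev = np.vstack([np.zeros(D), x[:-1]])
        ll = np.zeros((T, K))
        for k in range(K):
            b = spec.V[k] @ self.u
            resid = x - x_prev @ spec.A[k].T - b
            ll[:, k] = -0.5 * (
                np.einsum("td,de,te->t", resid, cache.Qinv[k], resid)
                + cache.logdetQ[k]
                + D * np.log(2 * np.pi)
            )
        logits = self._transition_logits(spec, cache, x_prev)
        logP = np.repeat(logits[:, None, :], K, axis=1)  # (T, src, dst)
        for i in range(1, K):
            logP[:, i, i] += STICKY_LOGIT
        P = np.exp(logP - logP.max(axis=2, keepdims=True))
        P /= P.sum(axis=2, keepdims=True)

        ll = np.where(self.state_mask, ll, -np.inf)  # observed-movement evidence
        like = np.exp(ll - ll.max(axis=1, keepdims=True))
        alpha = np.zeros((T, K))
        a0 = P[0, 0] * like[0]
        alpha[0] = a0 / a0.sum()
        for t in range(1, T):
            a = (alpha[t - 1] @ P[t]) * like[t]
            alpha[t] = a / a.sum()
        beta = np.ones((T, K))
        for t in range(T - 2, -1, -1):
            b = P[t + 1] @ (like[t + 1] * beta[t + 1])
            beta[t] = b / b.sum()
        post = alpha * beta
        post /= post.sum(axis=1, keepdims=True)
        self.omega = post
        return post


class _PathView:
    """Minimal worker stand-in exposing (samples, y) for the emission GLM."""

    def __init__(self, samples: np.ndarray, y: np.ndarray):
        self.samples = samples
        self.y = y


def _init_emissions(batch: TrialBatch, spec: AccumulatorSpec, pref_sides) -> None:
    """Greedy emission initialization.

    The offset starts at the softplus inverse of the mean rate and the
    weights at unit magnitude with each neuron's choice-preference sign; both
    are then refined by a Poisson GLM against the deterministic drift paths
    of the initial dynamics.  Starting near the data's emission scale keeps
    the early EM iterations from traversing the shallow scale/persistence
    ridge of the likelihood.
    """
    mean_rate = max(float(np.mean([y.mean() for y in batch.ys]) / batch.dt), 0.1)
    d0 = np.log(np.expm1(mean_rate)) if mean_rate < 30 else mean_rate
    N, D = spec.C.shape
    C0 = np.zeros((N, D))
    for n in range(N):
        contra = pref_sides[n] == "contra"
        if D == 1:
            C0[n, 0] = 1.0 if contra else -1.0
        else:
            C0[n, 0 if contra else 1] = 1.0
    spec.C = C0
    spec.d = float(d0)

    views = []
    for y, u in zip(batch.ys, batch.us):
        T = y.shape[0]
        x = np.zeros(D)
        path = np.empty((T, D))
        for t in range(T):
            x = spec.A[0] @ x + spec.V[0] @ u
            path[t] = x
        views.append(_PathView(path[None], y))
    _mstep_emissions(spec, views)


def _mstep_dynamics(spec: AccumulatorSpec, workers) -> None:
    """Weighted-regression updates of A_acc, Q_acc and movement noise from the
    posterior samples, respecting each architecture's structure."""
    K, D, _ = spec.shapes
    zeros = lambda: np.zeros((D, D))  # noqa: E731
    stats = [
        dict(Sxx=zeros(), Sxp=zeros(), Spp=zeros(), Sxb=zeros(), Spb=zeros(),
             Sbb=zeros(), W=0.0)
        for _ in range(K)
    ]
    for w in workers:
        S = w.samples  # (n, T, D)
        n = S.shape[0]
        Sp = np.concatenate([np.zeros((n, 1, D)), S[:, :-1]], axis=1)
        Exx = np.einsum("std,ste->tde", S, S) / n
        Exp = np.einsum("std,ste->tde", S, Sp) / n
        Epp = np.einsum("std,ste->tde", Sp, Sp) / n
        m = S.mean(axis=0)
        m_prev = Sp.mean(axis=0)
        for k in range(K):
            wk = w.omega[:, k]
            if not np.any(wk > 1e-12):
                continue
            b = spec.V[k] @ w.u
            st = stats[k]
            st["Sxx"] += np.einsum("t,tde->de", wk, Exx)
            st["Sxp"] += np.einsum("t,tde->de", wk, Exp)
            st["Spp"] += np.einsum("t,tde->de", wk, Epp)
            st["Sxb"] += np.outer(wk @ m, b)
            st["Spb"] += np.outer(wk @ m_prev, b)
            st["Sbb"] += wk.sum() * np.outer(b, b)
            st["W"] += wk.sum()

    st = stats[0]
    if st["W"] > 1e-8:
        Sxp_adj = st["Sxp"] - st["Spb"].T  # E[(x_t - b) x_{t-1}']
        if spec.kind == "single":
            A = np.array([[Sxp_adj[0, 0] / max(st["Spp"][0, 0], 1e-12)]])
        elif spec.kind == "independent_race":
            A = np.diag(np.diag(Sxp_adj) / np.maximum(np.diag(st["Spp"]), 1e-12))
        else:
            A = Sxp_adj @ np.linalg.inv(st["Spp"] + 1e-9 * np.eye(D))
        Q = (
            st["Sxx"]
            - st["Sxp"] @ A.T
            - A @ st["Sxp"].T
            + A @ st["Spp"] @ A.T
            - st["Sxb"]
            - st["Sxb"].T
            + A @ st["Spb"]
            + st["Spb"].T @ A.T
            + st["Sbb"]
        ) / st["W"]
        Q = 0.5 * (Q + Q.T)
        if spec.kind in ("single", "independent_race"):
            Q = np.diag(np.maximum(np.diag(Q), _Q_FLOOR))
        else:
            evals, evecs = np.linalg.eigh(Q)
            Q = (evecs * np.maximum(evals, _Q_FLOOR)) @ evecs.T
        spec.A[0] = A
        spec.Q[0] = Q

    for k in range(1, K):  # movement: A = I fixed, diagonal noise
        st = stats[k]
        if st["W"] < 1e-6:
            continue
        Q = (st["Sxx"] - st["Sxp"] - st["Sxp"].T + st["Spp"]) / st["W"]
        spec.Q[k] = np.diag(np.maximum(np.diag(Q), _Q_FLOOR))


def _mstep_emissions(spec: AccumulatorSpec, workers, max_samples: int = 10) -> None:
    """Poisson-GLM update of C, d on the posterior samples.

    Fitting against samples (rather than the posterior mean alone) keeps the
    expected rate honest about posterior uncertainty, anchoring the joint
    latent/emission scale.  At most ``max_samples`` evenly spaced samples per
    trial enter the design matrix (the GLM is over a handful of parameters,
    so a thinned sample set is ample)."""
    xs, ys = [], []
    for w in workers:
        s = w.samples
        if s.shape[0] > max_samples:
            s = s[:: max(s.shape[0] // max_samples, 1)][:max_samples]
        xs.append(s.reshape(-1, s.shape[2]))
        ys.append(np.tile(w.y, (s.shape[0], 1)))
    X = np.vstack(xs)
    Y = np.vstack(ys)
    N, D = spec.C.shape
    dt = spec.dt

    def negll(theta):
        C = theta[: N * D].reshape(N, D)
        d = theta[-1]
        a = X @ C.T + d
        sp = _softplus(a)
        sig = _sigmoid(a)
        lam = np.maximum(sp * dt, 1e-300)
        val = np.sum(Y * np.log(lam) - lam)
        g = Y * _safe_ratio(sig, sp, a) - sig * dt
        return -val, -np.concatenate([(g.T @ X).ravel(), [g.sum()]])

    theta0 = np.concatenate([spec.C.ravel(), [spec.d]])
    f0 = negll(theta0)[0]
    res = minimize(negll, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 60})
    theta = res.x if res.fun <= f0 else theta0
    spec.C = theta[: N * D].reshape(N, D)
    spec.d = float(theta[-1])


def _entropy(p: np.ndarray) -> float:
    q = np.clip(p, 1e-12, 1.0)
    return float(-np.sum(p * np.log(q)))


def fit_laplace_em(
    dataset_or_batch,
    model_kind: str,
    boundary_mode: str = "constant",
    init_grid: list[dict] | dict | None = None,
    latency: float = 0.1,
    n_em: int = 25,
    tol: float = 1e-6,
    dt: float = 0.01,
    rt_range: tuple[float, float] = (0.15, 0.5),
    n_mc: int = 30,
    n_final_samples: int = 100,
    seed: int | None = 0,
    verbose: bool = False,
) -> FitResult:
    """Fit one accumulator architecture to a subpopulation's spike data.

    ``dataset_or_batch`` is a :class:`SpikeDataset` (trials are filtered and
    binned with :func:`prepare_trials`) or a ready :class:`TrialBatch`.
    ``init_grid`` lists initial-value dicts (see
    :func:`evacc.accumulators.build_accumulator`); the cartesian product of
    :data:`evacc.accumulators.INIT_GRIDS` is searched when omitted.  The fit
    with maximum final objective across initializations is returned.
    ``n_mc`` posterior samples per trial feed each M-step;
    ``n_final_samples`` are drawn after convergence for downstream
    goodness-of-fit estimates.
    """
    if isinstance(dataset_or_batch, SpikeDataset):
        batch = prepare_trials(
            dataset_or_batch, model_kind, latency=latency, rt_range=rt_range, dt=dt
        )
        pref = list(dataset_or_batch.neurons["pref_side"])
    else:
        batch = dataset_or_batch
        pref = None
    if len(batch) == 0:
        raise ValueError("no trials left after filtering")
    n_neurons = batch.ys[0].shape[1]
    if pref is None:
        half = n_neurons // 2
        pref = ["contra"] * half + ["ipsi"] * (n_neurons - half)

    if init_grid is None:
        grid_def = acc.INIT_GRIDS[model_kind]
        keys = list(grid_def)
        init_grid = [
            dict(zip(keys, combo))
            for combo in itertools.product(*(grid_def[k] for k in keys))
        ]
    elif isinstance(init_grid, dict):
        init_grid = [init_grid]

    best: FitResult | None = None
    for init in init_grid:
        result = _run_em(
            batch, model_kind, boundary_mode, init, pref, n_neurons, n_em, tol,
            n_mc, n_final_samples, seed, verbose,
        )
        if best is None or result.log_likelihood > best.log_likelihood:
            best = result
    return best


def _prior_view(spec: AccumulatorSpec, max_T: int):
    """A copy of the parameter set whose objective reduces to the
    expected-dynamics Gaussian prior (no emissions, no transition coupling)."""
    spec0 = spec.copy()
    spec0.C = np.zeros_like(spec0.C)
    spec0.gamma = 0.0
    return spec0, _SpecCache(spec0, max_T)


def _run_em(batch, model_kind, boundary_mode, init, pref, n_neurons, n_em, tol,
            n_mc, n_final_samples, seed, verbose) -> FitResult:
    spec = acc.build_accumulator(
        model_kind,
        boundary_mode=boundary_mode,
        init_values=init,
        n_neurons=n_neurons,
        dt=batch.dt,
    )
    _init_emissions(batch, spec, pref)
    workers = [
        _TrialWorker(y, u, c, batch.n_post)
        for y, u, c in zip(batch.ys, batch.us, batch.choices)
    ]
    for w in workers:
        w.init_posteriors(spec)
    max_T = max(w.T for w in workers)
    D = spec.shapes[1]
    rng = np.random.default_rng(seed)

    trace: list[float] = []
    converged = False
    for it in range(n_em):
        cache = _SpecCache(spec, max_T)
        spec0, cache0 = _prior_view(spec, max_T)
        elbo = 0.0
        n_burn = 10 if it == 0 else 2
        for w in workers:
            w.ess_step(spec, spec0, cache0, rng, n_keep=n_mc, n_burn=n_burn)
            val, logdet_sigma = w.laplace_value(spec, cache)
            gauss_ent = 0.5 * (logdet_sigma + w.T * D * (1.0 + np.log(2 * np.pi)))
            w.forward_backward(spec, cache)
            elbo += val + gauss_ent + _entropy(w.omega)
        trace.append(elbo)
        if verbose:
            print(f"  EM iter {it}: elbo={elbo:.2f}")
        if it > 0 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-1]):
            converged = True
            break
        _mstep_dynamics(spec, workers)
        _mstep_emissions(spec, workers)

    # final posterior draws at the learned parameters for goodness of fit
    cache = _SpecCache(spec, max_T)
    spec0, cache0 = _prior_view(spec, max_T)
    for w in workers:
        w.ess_step(spec, spec0, cache0, rng, n_keep=n_final_samples, n_burn=5)
        w.forward_backward(spec, cache)

    return FitResult(
        spec=spec,
        elbo_trace=np.array(trace),
        latent_means=[w.x.copy() for w in workers],
        latent_samples=[w.samples for w in workers],
        state_marginals=[w.omega.copy() for w in workers],
        init_values=dict(init),
        converged=converged,
        trials=batch,
    )


def posterior_loglik_samples(
    fit: FitResult, n_samples: int = 100, seed: int | None = None,
    joint: bool = True,
) -> np.ndarray:
    """Monte-Carlo samples of the model log-likelihood under the posterior.

    Latent paths are drawn from each trial's posterior; for every sample the
    log density ``log p(y, x, z | theta)`` (expected over the discrete
    posterior) is accumulated across trials.  With ``joint=False`` only the
    emission term ``log p(y | x, theta)`` is used — that variant rewards
    extra latent dimensions without charging their dynamics cost and is kept
    for diagnostics only.
    """
    rng = np.random.default_rng(seed)
    spec = fit.spec
    batch = fit.trials
    max_T = max(y.shape[0] for y in batch.ys)
    cache = _SpecCache(spec, max_T)
    totals = np.zeros(n_samples)
    for samples, omega, y, u in zip(
        fit.latent_samples, fit.state_marginals, batch.ys, batch.us
    ):
        n_avail = samples.shape[0]
        idx = (
            np.arange(n_samples) % n_avail
            if n_samples <= n_avail
            else rng.integers(0, n_avail, n_samples)
        )
        xs = samples[idx]
        if joint:
            totals += _joint_density_samples(spec, cache, omega, y, u, xs)
        else:
            lam = np.maximum(_softplus(xs @ spec.C.T + spec.d) * spec.dt, 1e-300)
            totals += np.sum(y[None] * np.log(lam) - lam, axis=(1, 2)) - np.sum(
                gammaln(y + 1.0)
            )
    return totals


def marginal_loglik(
    fit: FitResult,
    n_draws: int = 100,
    seed: int | None = None,
    n_se_groups: int = 4,
) -> tuple[float, float]:
    """Importance-sampled marginal spike log-likelihood of a fitted model.

    Per trial, ``log p(y | z_path, theta) = log E_prior[p(y | x, theta)]``
    with latent paths integrated out against the expected-dynamics Gaussian
    prior (the discrete path is pinned by the observed movement evidence).
    Unlike an expected log-likelihood under the posterior, this quantity is
    comparable across architectures with different latent dimensionality: a
    richer latent space is not rewarded for posterior flexibility.

    Returns ``(estimate, mc_se)``; the Monte-Carlo standard error comes from
    splitting the draws into ``n_se_groups`` independent groups.
    """
    rng = np.random.default_rng(seed)
    spec = fit.spec
    batch = fit.trials
    D = spec.shapes[1]
    max_T = max(y.shape[0] for y in batch.ys)
    spec0, cache0 = _prior_view(spec, max_T)
    group = max(n_draws // n_se_groups, 1)
    totals = np.zeros(n_se_groups)
    for y, u, choice, omega in zip(
        batch.ys, batch.us, batch.choices, fit.state_marginals
    ):
        w = _TrialWorker(y, u, choice, batch.n_post)
        w.init_posteriors(spec)
        w.omega = omega
        T = w.T
        _, g0, dg, off = w._objective(spec0, cache0, np.zeros((T, D)), True)
        P = -w._assemble(dg, off)
        Lc = cholesky(P + 1e-10 * np.eye(T * D), lower=True)
        mu = cho_solve((Lc, True), g0.ravel())
        zs = rng.standard_normal((T * D, group * n_se_groups))
        X = (mu[:, None] + solve_triangular(Lc.T, zs, lower=False)).T
        X = X.reshape(group * n_se_groups, T, D)
        lam = np.maximum(_softplus(X @ spec.C.T + spec.d) * spec.dt, 1e-300)
        pois = np.sum(y[None] * np.log(lam) - lam, axis=(1, 2)) - float(
            np.sum(gammaln(y + 1.0))
        )
        for gi in range(n_se_groups):
            chunk = pois[gi * group : (gi + 1) * group]
            totals[gi] += logsumexp(chunk) - np.log(group)
    est = float(totals.mean())
    se = float(totals.std(ddof=1) / np.sqrt(n_se_groups))
    return est, se


def _joint_density_samples(
    spec: AccumulatorSpec,
    cache: _SpecCache,
    omega: np.ndarray,
    y: np.ndarray,
    u: np.ndarray,
    xs: np.ndarray,
) -> np.ndarray:
    """log p(y, x, z | theta), expected over q(z), for a batch of latent paths.

    ``xs`` is (S, T, D); returns (S,).  Mirrors the per-trial objective but
    vectorized across samples."""
    S, T, D = xs.shape
    K = spec.shapes[0]
    xp = np.concatenate([np.zeros((S, 1, D)), xs[:, :-1]], axis=1)
    vals = np.zeros(S)
    for k in range(K):
        w = omega[:, k]
        if not np.any(w > 1e-12):
            continue
        b = spec.V[k] @ u
        resid = xs - xp @ spec.A[k].T - b
        quad = np.einsum("std,de,ste->st", resid, cache.Qinv[k], resid)
        vals += -0.5 * (quad @ w) - 0.5 * w.sum() * (
            cache.logdetQ[k] + D * np.log(2 * np.pi)
        )
    if spec.gamma != 0.0:
        logits = spec.gamma * (xp @ cache.R.T + cache.r_eff[:T])  # (S, T, K)
        lse = logsumexp(logits, axis=2)
        w_prev = np.concatenate([[1.0], omega[:-1, 0]])
        vals += (np.einsum("stk,tk->st", logits, omega) - lse) @ w_prev
    lam = np.maximum(_softplus(xs @ spec.C.T + spec.d) * spec.dt, 1e-300)
    vals += np.sum(y[None] * np.log(lam) - lam, axis=(1, 2)) - float(
        np.sum(gammaln(y + 1.0))
    )
    return vals


def simulate_batch(
    spec: AccumulatorSpec,
    n_trials: int,
    seed: int | None = None,
    pre_move_bins: tuple[int, int] = (10, 40),
    post_move: float = 0.05,
) -> TrialBatch:
    """Simulate a ready-to-fit trial batch conditioned on its state path.

    Per trial the discrete path is an accumulation phase of uniformly drawn
    length followed by ``post_move`` seconds of movement; the latent evolves
    under the corresponding state dynamics with a contrast-pair input drawn
    uniformly from the 12 unequal cells, and counts are Poisson.  The
    committed choice is the side of the dominant accumulator at the switch.

    This is the rSLDS generative model conditioned on the observed-state
    evidence used in fitting, which makes it the appropriate data source for
    parameter-recovery studies (a boundary-crossing generator conditions the
    surviving paths on the first-passage event and biases persistence
    upward).
    """
    rng = np.random.default_rng(seed)
    K, D, _ = spec.shapes
    n_post = int(round(post_move / spec.dt))
    chol_acc = np.linalg.cholesky(spec.Q[0])
    chol_move = np.linalg.cholesky(spec.Q[1])
    cells = [
        (cl, cr)
        for cl in (0.0, 0.25, 0.5, 1.0)
        for cr in (0.0, 0.25, 0.5, 1.0)
        if cl != cr
    ]
    ys, us, choices = [], [], []
    for _ in range(n_trials):
        cl, cr = cells[rng.integers(len(cells))]
        u = acc.input_vector(spec.kind, cl, cr)
        t_pre = int(rng.integers(pre_move_bins[0], pre_move_bins[1] + 1))
        x = np.zeros(D)
        xs = []
        for _t in range(t_pre):
            x = spec.A[0] @ x + spec.V[0] @ u + chol_acc @ rng.standard_normal(D)
            xs.append(x.copy())
        if D == 1:
            choice = "right" if x[0] >= 0 else "left"
        else:
            choice = "right" if x[0] >= x[1] else "left"
        for _t in range(n_post):
            x = x + chol_move @ rng.standard_normal(D)
            xs.append(x.copy())
        xs = np.asarray(xs)
        lam = np.maximum(_softplus(xs @ spec.C.T + spec.d) * spec.dt, 1e-300)
        ys.append(rng.poisson(lam).astype(float))
        us.append(u)
        choices.append(choice)
    return TrialBatch(ys=ys, us=us, choices=choices, dt=spec.dt, n_post=n_post)


def simulate_counts(spec: AccumulatorSpec, u: np.ndarray, T: int, rng) -> np.ndarray:
    """Generative rollout of the fitted rSLDS for ``T`` bins (no early stop)."""
    return simulate_counts_batch(spec, u, T, 1, rng)[0]


def simulate_counts_batch(
    spec: AccumulatorSpec,
    u: np.ndarray,
    T: int,
    n_sims: int,
    rng,
    states: np.ndarray | None = None,
) -> np.ndarray:
    """``n_sims`` parallel generative rollouts; returns (n_sims, T, N) counts.

    When ``states`` (length T) is given, the discrete path is pinned to it —
    used to replay a trial under its observed accumulation/movement phases —
    otherwise states are sampled from the recurrent transition model.
    """
    K, D, _ = spec.shapes
    chol = np.stack([np.linalg.cholesky(spec.Q[k]) for k in range(K)])
    Vu = spec.V @ u  # (K, D)
    x = np.zeros((n_sims, D))
    z = np.zeros(n_sims, dtype=int)
    out = np.zeros((n_sims, T, spec.C.shape[0]))
    sims = np.arange(n_sims)
    for t in range(T):
        if states is not None:
            z = np.full(n_sims, int(states[t]))
        else:
            logits = acc.transition_logits(spec, x, t)  # (n_sims, K)
            logits[sims, z] += np.where(z != 0, STICKY_LOGIT, 0.0)
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            z = (p.cumsum(axis=1) < rng.random((n_sims, 1))).sum(axis=1)
        eps = rng.standard_normal((n_sims, D))
        x = (
            np.einsum("sde,se->sd", spec.A[z], x)
            + Vu[z]
            + np.einsum("sde,se->sd", chol[z], eps)
        )
        out[:, t, :] = rng.poisson(acc.emission_rate(spec, x))
    return out
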