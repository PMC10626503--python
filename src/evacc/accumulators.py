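"""Accumulator microcircuits as recurrent switching linear dynamical systems.

Three architectures are supported, each a reformulation of an rSLDS with
Poisson spike-count emissions:

``single``
    One decision variable ``x`` integrating the difference of the two input
    streams between boundaries at ``±B``; discrete states: accumulation,
    right-wheel-movement (x -> +B), left-wheel-movement (x -> -B).
``independent_race``
    Two uncoupled integrators, one per input stream, racing to a boundary at
    ``+B``; states: accumulation, right movement, left movement.
``dependent_race``
    Two fully coupled integrators (mutual/feedforward connections in the
    accumulation dynamics) with boundaries at ``±B`` each; five states:
    accumulation plus positive/negative crossings of either accumulator.

Dynamics per state ``z``:  x_t ~ N(A_z x_{t-1} + V_z u_t, Q_z), with the
offset term fixed at zero.  Discrete transitions are a softmax over
``gamma * (R x_{t-1} + r_eff(t))`` where ``r_eff`` encodes a constant,
linearly collapsing, or exponentially collapsing boundary.  Emissions are
``y_t ~ Poisson(softplus(C x_t + d) * dt)`` with the scalar offset ``d``
shared across neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

KINDS = ("single", "independent_race", "dependent_race")

#: (n discrete states K, latent dim D, input dim M) per architecture.
KIND_SHAPES = {
    "single": (3, 1, 1),
    "independent_race": (3, 2, 2),
    "dependent_race": (5, 2, 2),
}

STATE_NAMES = {
    "single": ("acc", "rwm", "lwm"),
    "independent_race": ("acc", "rwm", "lwm"),
    "dependent_race": ("acc", "prwm", "nrwm", "plwm", "nlwm"),
}

#: Choice committed when a movement state is entered.  Negative-boundary
#: crossings of an accumulator commit to the *opposite* side.
STATE_CHOICE = {
    "single": {1: "right", 2: "left"},
    "independent_race": {1: "right", 2: "left"},
    "dependent_race": {1: "right", 2: "left", 3: "left", 4: "right"},
}

BOUNDARY_MODES = ("constant", "linear_collapse", "exponential_collapse")

#: Logit added for staying in an already-entered movement state, making
#: movement states absorbing in simulation and strongly sticky in inference.
STICKY_LOGIT = 50.0


def softplus(x):
    return np.logaddexp(0.0, x)


def _transition_structure(kind: str, B: float) -> tuple[np.ndarray, np.ndarray]:
    """Recurrence weights R (K x D) and offsets r (K) of the discrete
    transition softmax for each architecture."""
    if kind == "single":
        R = np.array([[0.0], [1.0], [-1.0]])
        r = np.array([0.0, -B, -B])
    elif kind == "independent_race":
        R = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        r = np.array([0.0, -B, -B])
    else:  # dependent_race
        R = np.array(
            [[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]]
        )
        r = np.array([0.0, -B, -B, -B, -B])
    return R, r


@dataclass
class AccumulatorSpec:
    """Full parameterization of one accumulator microcircuit."""

    kind: str
    A: np.ndarray  # (K, D, D) per-state dynamics
    V: np.ndarray  # (K, D, M) per-state input weights
    Q: np.ndarray  # (K, D, D) per-state noise covariance
    C: np.ndarray  # (N, D) emission weights
    d: float = 10.0  # shared emission offset (softplus(d) = baseline rate, Hz)
    dt: float = 0.01  # emission/dynamics bin width (s)
    gamma: float = 1.0
    B: float = 1.0
    boundary_mode: str = "constant"
    beta: float = 0.5  # boundary offset (exp) or collapse rate (linear)
    tau_c: float = 100.0  # collapse time constant, in time *steps*

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown accumulator kind {self.kind!r}")
        if self.boundary_mode not in BOUNDARY_MODES:
            raise ValueError(f"unknown boundary mode {self.boundary_mode!r}")
        K, D, M = KIND_SHAPES[self.kind]
        self.A = np.asarray(self.A, float).reshape(K, D, D)
        self.V = np.asarray(self.V, float).reshape(K, D, M)
        self.Q = np.asarray(self.Q, float).reshape(K, D, D)
        self.C = np.atleast_2d(np.asarray(self.C, float))
        if self.C.shape[1] != D:
            raise ValueError("emission weights C must be (n_neurons, D)")
        if self.kind == "independent_race":
            for mat in (self.A[0], self.V[0], self.Q[0]):
                if np.any(mat[~np.eye(D, dtype=bool)] != 0):
                    raise ValueError(
                        "independent race requires diagonal A_acc, V_acc, Q_acc"
                    )
        for k in range(1, K):
            if not np.allclose(self.A[k], np.eye(D)) or np.any(self.V[k] != 0):
                raise ValueError("movement states must have A = I, V = 0")

    @property
    def shapes(self) -> tuple[int, int, int]:
        return KIND_SHAPES[self.kind]

    @property
    def n_neurons(self) -> int:
        return self.C.shape[0]

    @property
    def state_names(self) -> tuple[str, ...]:
        return STATE_NAMES[self.kind]

    @property
    def transition_params(self) -> tuple[np.ndarray, np.ndarray]:
        return _transition_structure(self.kind, self.B)

    def copy(self) -> "AccumulatorSpec":
        return replace(
            self, A=self.A.copy(), V=self.V.copy(), Q=self.Q.copy(), C=self.C.copy()
        )


def build_accumulator(
    kind: str,
    boundary_mode: str = "constant",
    init_values: dict | None = None,
    n_neurons: int = 4,
    emissions: tuple[np.ndarray, float] | None = None,
    dt: float = 0.01,
    seed: int | None = None,
) -> AccumulatorSpec:
    """Construct an accumulator spec of the given architecture.

    ``init_values`` may override ``A_acc`` (scalar or diagonal value),
    ``A_off`` (off-diagonal coupling, dependent race only), ``V_acc``,
    ``V_off``, ``Q_acc``, ``Q_move``, ``beta``, ``tau_c``.  Values default to
    the middle of the standard initialization grids (see
    :data:`INIT_GRIDS`).  Emission weights default to a split cohort: half
    the neurons load positively on the right-preferring latent, half on the
    left (negatively on the single latent), with magnitudes drawn uniformly
    from 16-24 Hz per latent unit over a ~10 Hz baseline (peak rates around
    30-40 Hz, typical of ramping decision neurons) — strong enough for the
    latent scale and structure to be well determined in 4-neuron
    subpopulations.
    """
    if kind not in KIND_SHAPES:
        raise ValueError(f"unknown accumulator kind {kind!r}")
    K, D, M = KIND_SHAPES[kind]
    iv = dict(init_values or {})
    a_diag = iv.pop("A_acc", 0.95)
    a_off = iv.pop("A_off", -0.05 if kind == "dependent_race" else 0.0)
    v_diag = iv.pop("V_acc", 0.03 if kind == "single" else 0.02)
    v_off = iv.pop("V_off", -0.02 if kind == "dependent_race" else 0.0)
    q_acc = iv.pop("Q_acc", 0.01)
    q_move = iv.pop("Q_move", q_acc)
    beta = iv.pop("beta", 0.5)
    tau_c = iv.pop("tau_c", 100.0)
    if iv:
        raise ValueError(f"unknown init values: {sorted(iv)}")
    if kind != "dependent_race" and (a_off != 0.0 or v_off != 0.0):
        raise ValueError("off-diagonal couplings require the dependent race")

    A = np.tile(np.eye(D), (K, 1, 1))
    V = np.zeros((K, D, M))
    Q = np.zeros((K, D, D))
    A[0] = np.diag(np.full(D, float(a_diag)))
    V[0] = np.diag(np.full(min(D, M), float(v_diag))) if D > 1 else [[v_diag]]
    if kind == "dependent_race":
        off = ~np.eye(D, dtype=bool)
        A[0][off] = a_off
        V[0][off] = v_off
    Q[0] = np.eye(D) * q_acc
    for k in range(1, K):
        Q[k] = np.eye(D) * q_move

    if emissions is not None:
        C, d = emissions
    else:
        rng = np.random.default_rng(seed)
        mags = rng.uniform(16.0, 24.0, size=n_neurons)
        C = np.zeros((n_neurons, D))
        half = n_neurons // 2
        if D == 1:
            C[:, 0] = mags
            C[half:, 0] *= -1  # ipsi-preferring load negatively
        else:
            C[:half, 0] = mags[:half]  # contra -> right accumulator
            C[half:, 1] = mags[half:]  # ipsi -> left accumulator
        d = 10.0
    return AccumulatorSpec(
        kind=kind,
        A=A,
        V=V,
        Q=Q,
        C=np.asarray(C, float),
        d=float(d),
        dt=dt,
        boundary_mode=boundary_mode,
        beta=float(beta),
        tau_c=float(tau_c),
    )


#: Standard initialization grids searched during fitting, per architecture.
INIT_GRIDS = {
    "single": {"A_acc": (0.95, 1.0), "V_acc": (0.01, 0.02, 0.03, 0.04, 0.05),
               "Q_acc": (0.005, 0.01)},
    "independent_race": {"A_acc": (0.95, 1.0), "V_acc": (0.01, 0.02, 0.03),
                         "Q_acc": (0.005, 0.01)},
    "dependent_race": {"A_acc": (0.95, 1.0), "V_acc": (0.01, 0.02, 0.03),
                       "Q_acc": (0.01,), "A_off": (-0.05, 0.1),
                       "V_off": (-0.01, -0.02, -0.03)},
}

#: Initialization grid for collapsing-boundary parameters.
COLLAPSE_GRID = {"beta": (0.3, 0.4, 0.5), "tau_c": (50.0, 100.0)}


def boundary_factor(spec: AccumulatorSpec, t: int | np.ndarray) -> np.ndarray:
    """Multiplier f(t) on the effective boundary at step ``t``.

    ``f(0) = 1``;  exponential collapse decays to ``beta``; a linear collapse
    shrinks the boundary at rate ``beta`` per step (floored at 0); a constant
    boundary returns 1.
    """
    t = np.asarray(t, float)
    if spec.boundary_mode == "constant":
        return np.ones_like(t)
    if spec.boundary_mode == "linear_collapse":
        return np.maximum(1.0 - spec.beta * t / spec.B, 0.0)
    return spec.beta + (1.0 - spec.beta) * np.exp(-t / spec.tau_c)


def transition_logits(spec: AccumulatorSpec, x: np.ndarray, t: int = 0) -> np.ndarray:
    """Unnormalized log transition probabilities gamma*(R x + r_eff(t)).

    ``x`` may be (..., D); the result is (..., K).  The accumulation-state
    logit is 0; each movement-state logit is the signed accumulator value
    minus the (possibly collapsed) boundary.
    """
    R, r = spec.transition_params
    f = boundary_factor(spec, t)
    r_eff = np.where(r != 0, r * f, 0.0)
    x = np.asarray(x, float)
    return spec.gamma * (x @ R.T + r_eff)


def transition_probs(
    spec: AccumulatorSpec, x: np.ndarray, t: int = 0, prev_state: int | None = None
) -> np.ndarray:
    """Probability vector over the K discrete states given the latent ``x``.

    When ``prev_state`` is a movement state, a large self-logit keeps the
    chain there (movement states are absorbing once entered)."""
    logits = transition_logits(spec, x, t)
    if prev_state is not None and prev_state != 0:
        logits = logits.copy()
        logits[..., prev_state] += STICKY_LOGIT
    logits = logits - logits.max(axis=-1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=-1, keepdims=True)


def emission_rate(spec: AccumulatorSpec, x: np.ndarray) -> np.ndarray:
    """Expected spike counts per bin, softplus(C x + d) * dt; x is (..., D)."""
    return softplus(np.asarray(x, float) @ spec.C.T + spec.d) * spec.dt


def input_vector(spec_kind: str, contrast_left: float, contrast_right: float) -> np.ndarray:
    """Constant input stream u for a trial: signed difference for the single
    accumulator, the (right, left) contrast pair for race models."""
    if spec_kind == "single":
        return np.array([contrast_right - contrast_left])
    return np.array([contrast_right, contrast_left])


def simulate(
    spec: AccumulatorSpec,
    trials,
    seed: int | None = None,
    max_duration: float = 1.0,
    post_move: float = 0.05,
) -> list[dict]:
    """Simulate the full generative recursion per trial.

    Starting at ``x_0 = 0`` in the accumulation state, each step samples the
    discrete state from :func:`transition_probs`, then the latent from that
    state's Gaussian dynamics, then Poisson counts from the emission rate.
    A trial ends ``post_move`` seconds after first entering a movement state,
    or is labeled ``nogo`` after ``max_duration`` with no commitment.

    Returns one dict per trial with keys ``latents`` (T, D), ``states`` (T,),
    ``counts`` (T, N), ``choice``, ``rt`` (s or NaN).
    """
    rng = np.random.default_rng(seed)
    K, D, M = spec.shapes
    max_steps = int(round(max_duration / spec.dt))
    n_post = int(round(post_move / spec.dt))
    chol = [np.linalg.cholesky(spec.Q[k]) for k in range(K)]
    out = []
    for row in trials.itertuples():
        u = input_vector(spec.kind, row.contrast_left, row.contrast_right)
        x = np.zeros(D)
        z = 0
        xs, zs, ys = [], [], []
        choice, rt = "nogo", np.nan
        move_at = None
        for t in range(max_steps + n_post):
            p = transition_probs(spec, x, t, prev_state=z)
            z = int(rng.choice(K, p=p))
            x = spec.A[z] @ x + spec.V[z] @ u + chol[z] @ rng.standard_normal(D)
            y = rng.poisson(emission_rate(spec, x))
            xs.append(x.copy())
            zs.append(z)
            ys.append(y)
            if move_at is None and z != 0:
                move_at = t
                choice = STATE_CHOICE[spec.kind][z]
                rt = (t + 1) * spec.dt
            if move_at is not None and t - move_at >= n_post - 1:
                break
            if move_at is None and t >= max_steps - 1:
                break
        out.append(
            {
                "latents": np.array(xs),
                "states": np.array(zs, dtype=int),
                "counts": np.array(ys),
                "choice": choice,
                "rt": rt,
            }
        )
    return out


def n_free_parameters(spec: AccumulatorSpec) -> int:
    """Count of trainable scalars: accumulation dynamics A_acc and noise
    Q_acc (respecting the architecture's structural zeros/symmetry),
    movement-state noise (diagonal), emission weights C and shared offset d.
    The input weights V are fixed, as are all transition parameters."""
    K, D, _ = spec.shapes
    N = spec.n_neurons
    if spec.kind == "single":
        k_A, k_Q = 1, 1
    elif spec.kind == "independent_race":
        k_A, k_Q = D, D
    else:
        k_A, k_Q = D * D, D * (D + 1) // 2
    k_move = (K - 1) * D  # diagonal noise per movement state
    return k_A + k_Q + k_move + N * D + 1


def spec_to_dict(spec: AccumulatorSpec) -> dict:
    return {
        "kind": spec.kind,
        "A": spec.A.tolist(),
        "V": spec.V.tolist(),
        "Q": spec.Q.tolist(),
        "C": spec.C.tolist(),
        "d": float(spec.d),
        "dt": float(spec.dt),
        "gamma": float(spec.gamma),
        "B": float(spec.B),
        "boundary_mode": spec.boundary_mode,
        "beta": float(spec.beta),
        "tau_c": float(spec.tau_c),
    }


def spec_from_dict(data: dict) -> AccumulatorSpec:
    data = dict(data)
    for key in ("A", "V", "Q", "C"):
        data[key] = np.asarray(data[key], float)
    return AccumulatorSpec(**data)


def save_spec(spec: AccumulatorSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh)


def load_spec(path: str | Path) -> AccumulatorSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
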