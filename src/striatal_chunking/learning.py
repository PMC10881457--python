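"""Readout learning: mutual teaching signals and FORCE/RLS training.

Each population has a linear readout ``z = w^T r`` trained online with
the FORCE algorithm (recursive least squares).  The training target of
population *i* is derived from the *other* population's readout: the
partner's output is standardized by a running normalizer, squashed, and
(optionally) rectified,

    f_i(t) = [tanh(zhat_j(t) / beta)]_+ ,   i != j,

and the error driving the RLS update is

    e_i(t) = z_i(t) - kappa_i f_i(t).

With ``kappa = 1`` on both sides the two populations are trained toward
consensus on their shared, input-locked response components; negative
``kappa`` turns the partner's output into a repulsive target and
produces competitive dynamics.  Rectification of ``f`` is lifted in the
kappa-sweep experiment so the teaching signal can go negative.

The recurrent, self-feedback and input matrices are non-plastic; only
``w`` changes, and only during the training window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .network import (
    ContractError,
    ReservoirParams,
    WeightSet,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TeachingConfig",
    "TrainingConfig",
    "RLSState",
    "NormalizerState",
    "TrainingDivergenceError",
    "NumericalError",
    "readout",
    "normalize",
    "teaching_signal",
    "error",
    "rls_update",
    "train_pair",
    "TrainResult",
]

#: Readouts beyond this magnitude abort training as diverged.
DIVERGENCE_LIMIT = 1.0e6

#: Interval (steps) at which P is re-symmetrized against float drift.
_P_SYMMETRIZE_EVERY = 1000


class TrainingDivergenceError(RuntimeError):
    """A readout diverged during training."""


class NumericalError(RuntimeError):
    """The RLS inverse-correlation matrix lost positive-definiteness."""


@dataclass(frozen=True)
class TeachingConfig:
    """Cross-population teaching-signal parameters.

    ``kappa_1``/``kappa_2`` weight the teaching signal in each
    population's error (in [-1, 1]); ``beta`` divides the normalized
    partner output inside the tanh squashing; ``rectify`` applies the
    threshold-linear ``[x]_+`` to the teaching signal (lifted in the
    kappa-sweep experiment).
    """

    kappa_1: float = 1.0
    kappa_2: float = 1.0
    beta: float = 3.0
    rectify: bool = True

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        for name in ("kappa_1", "kappa_2"):
            if not (-1.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [-1, 1]")


@dataclass(frozen=True)
class TrainingConfig:
    """FORCE training-schedule parameters.

    ``alpha`` is the FORCE regularization / learning-rate constant: the
    RLS inverse-correlation matrix starts at ``P(0) = I / alpha``.
    ``t_train_ms`` bounds the window ``[0, t_train_ms)`` in which the
    readouts are updated (``None`` trains over the whole stream);
    ``t_test_ms`` is the length of the fresh post-training stream on
    which metrics are computed.
    """

    alpha: float = 100.0
    t_train_ms: float | None = 10_000.0
    t_test_ms: float = 10_000.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.t_train_ms is not None and self.t_train_ms < 0:
            raise ValueError("t_train_ms must be non-negative")
        if self.t_test_ms <= 0:
            raise ValueError("t_test_ms must be positive")


@dataclass
class RLSState:
    """Inverse-correlation matrix and schedule of one RLS learner."""

    P: np.ndarray
    alpha: float

    @classmethod
    def create(cls, n: int, alpha: float) -> "RLSState":
        return cls(P=np.eye(n) / alpha, alpha=alpha)


@dataclass
class NormalizerState:
    """Exponential running standardizer of a readout trace.

    Mean and variance are tracked as bias-corrected exponential moving
    averages (the accumulated window weight is carried alongside and
    divided out), so the statistics are unbiased from the first steps
    even when the window is long relative to the stream seen so far.
    The variance floor ``eps`` keeps the standardized value finite for
    constant streams.  The default window (10 s) is long compared to
    the inter-chunk interval: a window near the inter-chunk scale
    absorbs each chunk response into the running mean and washes the
    teaching signal out, while a long window standardizes against the
    stream's long-run statistics.
    """

    mean: float = 0.0
    var: float = 0.0
    weight: float = 0.0  # accumulated EMA weight for bias correction
    time_constant: float = 10_000.0
    eps: float = 1.0e-6

    def __post_init__(self) -> None:
        if self.time_constant <= 0:
            raise ValueError("time_constant must be positive")
        if self.var < 0:
            raise ValueError("running variance must be non-negative")

    @property
    def running_mean(self) -> float:
        """Bias-corrected mean estimate."""
        return self.mean / self.weight if self.weight > 0 else 0.0

    @property
    def running_var(self) -> float:
        """Bias-corrected variance estimate."""
        return self.var / self.weight if self.weight > 0 else 0.0


def readout(w: np.ndarray, r_sub: np.ndarray) -> float:
    """Instantaneous linear readout ``z = w^T r``."""
    if np.shape(w) != np.shape(r_sub):
        raise ContractError("readout weight and rate subvector lengths differ")
    return float(np.dot(w, r_sub))


def normalize(z: float, state: NormalizerState, dt: float) -> float:
    """Update the running statistics with ``z`` and return ``zhat``.

    Mean and squared deviation are exponential moving averages with
    rate ``dt / time_constant``, divided by the accumulated window
    weight (bias correction); the returned value is
    ``(z - mean) / sqrt(var + eps)`` using the updated statistics.
    """
    a = min(dt / state.time_constant, 1.0)
    state.weight += a * (1.0 - state.weight)
    state.mean += a * (z - state.mean)
    mu = state.mean / state.weight
    state.var += a * ((z - mu) ** 2 - state.var)
    return (z - mu) / math.sqrt(state.var / state.weight + state.eps)


def teaching_signal(z_hat_other: float, cfg: TeachingConfig) -> float:
    """Teaching signal ``f = [tanh(zhat_other / beta)]_+`` (or unrectified)."""
    f = math.tanh(z_hat_other / cfg.beta)
    if cfg.rectify and f < 0.0:
        return 0.0
    return f


def error(z_i: float, f_i: float, kappa_i: float) -> float:
    """Error signal ``e_i = z_i - kappa_i f_i`` driving the RLS update."""
    return z_i - kappa_i * f_i


def rls_update(
    rls: RLSState, w: np.ndarray, r_sub: np.ndarray, e: float
) -> tuple[RLSState, np.ndarray]:
    """One recursive-least-squares step.

    ``P <- P - (P r)(P r)^T / (1 + r^T P r)`` followed by
    ``w <- w - e k`` with the gain ``k = P_new r = P r / (1 + r^T P r)``.
    ``P`` is updated in place even when ``e`` is zero.
    """
    Pr = rls.P @ r_sub
    rPr = float(r_sub @ Pr)
    if rPr < 0:
        raise NumericalError("inverse-correlation matrix lost positive-definiteness")
    k = Pr / (1.0 + rPr)
    rls.P -= np.outer(k, Pr)
    return rls, w - e * k


@dataclass
class TrainResult:
    """Outcome of co-training a pair of populations."""

    weights_1: WeightSet
    weights_2: WeightSet
    z_train_1: np.ndarray
    z_train_2: np.ndarray
    normalizer_1: NormalizerState
    normalizer_2: NormalizerState
    rls_1: RLSState
    rls_2: RLSState


def train_pair(
    weights_1: WeightSet,
    weights_2: WeightSet,
    params_1: ReservoirParams,
    params_2: ReservoirParams,
    teaching_cfg: TeachingConfig,
    rls_cfg: TrainingConfig,
    input_signal,
    seed: int | np.random.SeedSequence,
    normalizer_time_constant: float = 10_000.0,
) -> TrainResult:
    """Co-simulate both populations on a shared stream and train readouts.

    At every timestep of the training window each population's readout
    is updated by RLS toward the other population's normalized,
    optionally rectified output.  After ``t_train_ms`` the weights are
    frozen while the simulation continues (if the stream is longer).
    Input weights must share the stream's width; the two populations may
    have different sizes and time constants but must share ``dt``.

    The per-trial randomness (initial states and process noise of both
    populations) is derived from ``seed`` via independent sub-streams.

    Returns a :class:`TrainResult` with trained weight copies and the
    training readout traces.
    """
    if params_1.dt != params_2.dt:
        raise ContractError("populations must share the integration timestep")
    if input_signal.dt != params_1.dt:
        raise ContractError("input timestep does not match params.dt")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    init_1, init_2, noise_1, noise_2 = [np.random.default_rng(c) for c in ss.spawn(4)]

    dt = params_1.dt
    T = input_signal.n_steps
    t_train = rls_cfg.t_train_ms if rls_cfg.t_train_ms is not None else T * dt
    train_steps = min(T, int(round(t_train / dt)))
    steps = input_signal.step_characters

    pops = []
    for wset, pp, init_rng, noise_rng in (
        (weights_1, params_1, init_1, noise_1),
        (weights_2, params_2, init_2, noise_2),
    ):
        if wset.input.shape[1] != input_signal.n_inputs:
            raise ContractError("input width does not match input weight matrix")
        N = pp.n_neurons
        n = pp.n_readout
        x = init_rng.normal(0.0, 0.5, N)
        pops.append(
            dict(
                params=pp,
                J=wset.recurrent,
                fb=wset.feedback,
                Jin=wset.input,
                w=wset.readout.copy(),
                idx=wset.readout_index,
                n=n,
                x=x,
                r=np.tanh(x),
                drive=np.empty(N),
                P=np.eye(n) / rls_cfg.alpha,
                Pr=np.empty(n),
                outer=np.empty((n, n)),
                norm=NormalizerState(time_constant=normalizer_time_constant),
                noise=noise_rng,
                a=dt / pp.tau,
                g=pp.recurrent_gain,
                h=pp.feedback_gain,
                ns=pp.noise_increment_std if pp.noise_std > 0 else 0.0,
                trace=np.empty(T),
            )
        )
    p1, p2 = pops
    kappas = (teaching_cfg.kappa_1, teaching_cfg.kappa_2)
    beta = teaching_cfg.beta
    rectify = teaching_cfg.rectify

    for t in range(T):
        z_hats = [0.0, 0.0]
        zs = [0.0, 0.0]
        for i, p in enumerate(pops):
            r = p["r"]
            r_sub = r[: p["n"]]
            z = float(p["w"] @ r_sub)
            if not math.isfinite(z) or abs(z) > DIVERGENCE_LIMIT:
                raise TrainingDivergenceError(
                    f"population {i + 1} readout diverged at t={t * dt} ms"
                )
            zs[i] = z
            p["trace"][t] = z
            # bias-corrected exponential running standardization of the
            # readout (same formulas as normalize())
            norm = p["norm"]
            a_n = min(dt / norm.time_constant, 1.0)
            norm.weight += a_n * (1.0 - norm.weight)
            norm.mean += a_n * (z - norm.mean)
            mu = norm.mean / norm.weight
            norm.var += a_n * ((z - mu) ** 2 - norm.var)
            z_hats[i] = (z - mu) / math.sqrt(norm.var / norm.weight + norm.eps)

        if t < train_steps:
            for i, p in enumerate(pops):
                f = math.tanh(z_hats[1 - i] / beta)
                if rectify and f < 0.0:
                    f = 0.0
                e = zs[i] - kappas[i] * f
                r_sub = p["r"][: p["n"]]
                P = p["P"]
                Pr = p["Pr"]
                np.dot(P, r_sub, out=Pr)
                rPr = float(r_sub @ Pr)
                if rPr < 0:
                    raise NumericalError(
                        f"population {i + 1}: r^T P r < 0 at t={t * dt} ms"
                    )
                Pr /= math.sqrt(1.0 + rPr)
                np.outer(Pr, Pr, out=p["outer"])
                P -= p["outer"]
                # gain k = P_new r = Pr_scaled / sqrt(1 + rPr)
                p["w"] -= (e / math.sqrt(1.0 + rPr)) * Pr
            if (t + 1) % _P_SYMMETRIZE_EVERY == 0:
                for p in pops:
                    P = p["P"]
                    P += P.T
                    P *= 0.5

        for i, p in enumerate(pops):
            drive = p["drive"]
            np.dot(p["J"], p["r"], out=drive)
            if p["g"] != 1.0:
                drive *= p["g"]
            drive += (p["h"] * zs[i]) * p["fb"]
            drive += p["Jin"][:, steps[t]]
            x = p["x"]
            x += p["a"] * (drive - x)
            if p["ns"]:
                x += p["ns"] * p["noise"].standard_normal(x.size)
            np.tanh(x, out=p["r"])

    out_sets = []
    for wset, p in ((weights_1, p1), (weights_2, p2)):
        trained = wset.copy()
        trained.readout = p["w"]
        out_sets.append(trained)
    return TrainResult(
        weights_1=out_sets[0],
        weights_2=out_sets[1],
        z_train_1=p1["trace"],
        z_train_2=p2["trace"],
        normalizer_1=p1["norm"],
        normalizer_2=p2["norm"],
        rls_1=RLSState(P=p1["P"], alpha=rls_cfg.alpha),
        rls_2=RLSState(P=p2["P"], alpha=rls_cfg.alpha),
    )
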