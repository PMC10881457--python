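"""Reservoir construction and stochastic rate dynamics.

Each striatal population is a reservoir of ``N`` rate neurons with leaky
dynamics

    tau dx_i/dt = -x_i + g Σ_j J^rec_ij r_j + h J^fb_i z + Σ_mu J^in_i,mu I_mu
                  + sigma xi_i(t),        r_i = tanh(x_i),

integrated by Euler–Maruyama at a fixed timestep (1 ms by default):

    x <- x + (dt/tau) (-x + drive) + (sigma/tau) sqrt(dt) N(0,1).

``g`` scales the fixed recurrent matrix (chaotic-reservoir scaling
``J^rec_ij ~ N(0, 1/(p N))`` on a Bernoulli(p) mask), ``h`` scales the
fixed self-feedback vector carrying the population's own readout ``z``
back into the network, and the input matrix carries the one-hot
character currents.  Only the readout vector ``w`` is plastic (trained
in :mod:`striatal_chunking.learning`); the recurrent, self-feedback and
input weights are frozen at construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ReservoirParams",
    "WeightSet",
    "ReservoirState",
    "PopulationTrace",
    "ContractError",
    "ConstructionError",
    "IntegrationError",
    "init_weights",
    "step",
    "run_population",
]

#: Readouts beyond this magnitude abort a run as diverged.
DIVERGENCE_LIMIT = 1.0e6


class ConstructionError(ValueError):
    """Weight matrices cannot be built from the given parameters."""


class ContractError(ValueError):
    """Dimension mismatch between weights, state, or inputs."""


class IntegrationError(RuntimeError):
    """The state became non-finite or diverged during integration."""


@dataclass(frozen=True)
class ReservoirParams:
    """Structural and dynamical parameters of one population.

    Parameters
    ----------
    n_neurons
        Reservoir size ``N``.
    n_readout
        Number of reservoir neurons the readout connects to (``n <= N``;
        the first ``n`` neurons by default).
    tau
        Membrane time constant in ms.
    recurrent_gain
        Gain ``g`` on the recurrent matrix.
    feedback_gain
        Gain ``h`` on the readout self-feedback vector.
    p_recurrent
        Connection probability of the recurrent matrix.
    p3
        Connection probability of the self-feedback and input matrices.
        Sweeps of a single common connection probability set
        ``p_recurrent`` and ``p3`` jointly.
    noise_std
        Standard deviation ``sigma`` of the Wiener noise.
    dt
        Integration timestep in ms.
    noise_scaling
        ``"tau"`` places the noise increment inside the 1/tau factor,
        matching the membrane equation as written; ``"plain"`` adds
        ``sigma sqrt(dt)`` directly.
    """

    n_neurons: int = 300
    n_readout: int = 300
    tau: float = 10.0
    recurrent_gain: float = 1.5
    feedback_gain: float = 1.0
    p_recurrent: float = 1.0
    p3: float = 1.0
    noise_std: float = 0.3
    dt: float = 1.0
    noise_scaling: Literal["tau", "plain"] = "tau"

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ConstructionError("n_neurons must be at least 1")
        if not (1 <= self.n_readout <= self.n_neurons):
            raise ConstructionError("need 1 <= n_readout <= n_neurons")
        if self.tau <= 0 or self.dt <= 0:
            raise ConstructionError("tau and dt must be positive")
        for name in ("p_recurrent", "p3"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConstructionError(f"{name} must lie in [0, 1]")
        if self.noise_std < 0:
            raise ConstructionError("noise_std must be non-negative")
        if self.noise_scaling not in ("tau", "plain"):
            raise ConstructionError("noise_scaling must be 'tau' or 'plain'")

    @property
    def connection_probabilities(self) -> tuple[float, float, float]:
        """Sampling probabilities for (recurrent, feedback, input) weights."""
        return (self.p_recurrent, self.p3, self.p3)

    @property
    def noise_increment_std(self) -> float:
        """Per-step noise standard deviation under the chosen discretization."""
        if self.noise_scaling == "tau":
            return self.noise_std / self.tau * math.sqrt(self.dt)
        return self.noise_std * math.sqrt(self.dt)


@dataclass
class WeightSet:
    """Sampled connection matrices and the plastic readout vector."""

    recurrent: np.ndarray  # (N, N)
    feedback: np.ndarray  # (N,)
    input: np.ndarray  # (N, N_I)
    readout: np.ndarray  # (n,)
    readout_index: np.ndarray  # (n,) int

    def copy(self) -> "WeightSet":
        return WeightSet(
            recurrent=self.recurrent,
            feedback=self.feedback,
            input=self.input,
            readout=self.readout.copy(),
            readout_index=self.readout_index,
        )


@dataclass
class ReservoirState:
    """Instantaneous state of one population."""

    x: np.ndarray
    r: np.ndarray
    z: float
    t: float = 0.0


@dataclass
class PopulationTrace:
    """Time courses produced by :func:`run_population`."""

    z: np.ndarray
    rates: np.ndarray | None = None
    rate_stride: int = 0


def init_weights(
    params: ReservoirParams,
    n_inputs: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> WeightSet:
    """Sample a frozen weight set.

    Recurrent entries are nonzero with probability ``p_recurrent`` and
    drawn ``N(0, 1/(p N))`` — the standard scaling that keeps the
    recurrent spectral radius near ``g``.  Input entries are nonzero
    with probability ``p3`` and drawn uniformly on ``[-1, 1]``.
    Self-feedback entries are nonzero with probability ``p3`` and drawn
    uniformly on ``[0, 1]``: the self-feedback loop stands for a
    population-level re-excitation (the cholinergic feedback the gain
    ``h`` summarizes), so its weights are non-negative — with
    sign-symmetric feedback the gain acts as signal-dependent noise
    rather than recency, and loses its modeled meaning.  The readout
    starts at small random values
    ``N(0, 1/n)``: the readout target of each population is a function
    of the other's readout, so an exactly silent readout is a fixed
    point of training and a small random start is required to break it.
    """
    if n_inputs < 1:
        raise ConstructionError("n_inputs must be at least 1")
    rng = np.random.default_rng(seed)
    N = params.n_neurons
    n = params.n_readout
    p = params.p_recurrent

    if p > 0:
        scale = 1.0 / math.sqrt(p * N)
        recurrent = rng.normal(0.0, scale, (N, N))
        recurrent *= rng.random((N, N)) < p
    else:
        recurrent = np.zeros((N, N))

    p_fb, p_in = params.p3, params.p3
    feedback = rng.uniform(0.0, 1.0, N)
    feedback *= rng.random(N) < p_fb
    inputs = rng.uniform(-1.0, 1.0, (N, n_inputs))
    inputs *= rng.random((N, n_inputs)) < p_in

    readout = rng.normal(0.0, 1.0 / math.sqrt(n), n)
    return WeightSet(
        recurrent=recurrent,
        feedback=feedback,
        input=inputs,
        readout=readout,
        readout_index=np.arange(n),
    )


def initial_state(
    params: ReservoirParams,
    weights: WeightSet,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> ReservoirState:
    """Draw the initial membrane state ``x(0) ~ N(0, 0.5^2)`` per neuron."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 0.5, params.n_neurons)
    r = np.tanh(x)
    z = float(weights.readout @ r[weights.readout_index])
    return ReservoirState(x=x, r=r, z=z, t=0.0)


def step(
    state: ReservoirState,
    input_row: np.ndarray,
    z_feedback: float,
    params: ReservoirParams,
    weights: WeightSet,
    noise_draw: np.ndarray,
) -> ReservoirState:
    """One Euler–Maruyama update of the membrane equation.

    ``z_feedback`` is the readout value fed through the self-feedback
    vector; during closed-loop operation it is the population's own
    readout at the current time.
    """
    N = params.n_neurons
    if state.x.shape != (N,) or noise_draw.shape != (N,):
        raise ContractError("state/noise dimension does not match n_neurons")
    if weights.recurrent.shape != (N, N) or weights.feedback.shape != (N,):
        raise ContractError("weight dimensions do not match n_neurons")
    if weights.input.shape[1] != np.shape(input_row)[0]:
        raise ContractError("input row length does not match input matrix")

    a = params.dt / params.tau
    drive = (
        params.recurrent_gain * (weights.recurrent @ state.r)
        + params.feedback_gain * weights.feedback * z_feedback
        + weights.input @ input_row
    )
    x = state.x + a * (drive - state.x)
    if params.noise_std > 0:
        x = x + params.noise_increment_std * noise_draw
    if not np.all(np.isfinite(x)):
        raise IntegrationError(f"non-finite state at t={state.t + params.dt} ms")
    r = np.tanh(x)
    z = float(weights.readout @ r[weights.readout_index])
    return ReservoirState(x=x, r=r, z=z, t=state.t + params.dt)


def run_population(
    weights: WeightSet,
    params: ReservoirParams,
    input_signal,
    seed: int | np.random.SeedSequence | np.random.Generator,
    z_source: np.ndarray | None = None,
    record_rates: int = 0,
) -> PopulationTrace:
    """Integrate one population over a full input stream, readout frozen.

    The readout ``z(t) = w^T r(t)`` is computed from the current state
    at every step and fed back through the self-feedback vector for the
    next update (or replaced by ``z_source[t]`` when an external
    feedback trace is supplied).  The returned trace holds ``z(t)``
    sampled before each update, aligned with the input timestep.

    ``record_rates``: if > 0, keep every that-many-th rate vector.
    """
    if input_signal.dt != params.dt:
        raise ContractError(
            f"input timestep {input_signal.dt} ms != params.dt {params.dt} ms"
        )
    if input_signal.n_inputs != weights.input.shape[1]:
        raise ContractError("input width does not match input weight matrix")

    T = input_signal.n_steps
    zs = np.empty(T)
    rates = None
    if record_rates > 0:
        rates = np.empty(((T + record_rates - 1) // record_rates, params.n_neurons))
    if T == 0:
        return PopulationTrace(z=zs, rates=rates, rate_stride=record_rates)
    if z_source is not None and len(z_source) < T:
        raise ContractError("z_source shorter than the input stream")

    rng = np.random.default_rng(seed)
    N = params.n_neurons
    n = params.n_readout
    x = rng.normal(0.0, 0.5, N)
    r = np.tanh(x)

    J = weights.recurrent
    fb = weights.feedback
    Jin = weights.input
    w = weights.readout
    idx = weights.readout_index
    contiguous = idx.size == n and idx[0] == 0 and idx[-1] == n - 1
    g = params.recurrent_gain
    h = params.feedback_gain
    a = params.dt / params.tau
    ns = params.noise_increment_std if params.noise_std > 0 else 0.0
    steps = input_signal.step_characters

    drive = np.empty(N)
    for t in range(T):
        r_sub = r[:n] if contiguous else r[idx]
        z = float(w @ r_sub)
        if not math.isfinite(z) or abs(z) > DIVERGENCE_LIMIT:
            raise IntegrationError(f"readout diverged at t={t * params.dt} ms")
        zs[t] = z
        if rates is not None and t % record_rates == 0:
            rates[t // record_rates] = r
        zfb = z if z_source is None else float(z_source[t])
        np.dot(J, r, out=drive)
        if g != 1.0:
            drive *= g
        drive += (h * zfb) * fb
        drive += Jin[:, steps[t]]
        x += a * (drive - x)
        if ns:
            x += ns * rng.standard_normal(N)
        np.tanh(x, out=r)
    if not np.all(np.isfinite(x)):
        raise IntegrationError(f"non-finite state at end of run (t={T * params.dt} ms)")
    return PopulationTrace(z=zs, rates=rates, rate_stride=record_rates)
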