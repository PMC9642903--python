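"""Minimal Neural Engineering Framework (NEF) substrate.

An *ensemble* of spiking rectified-linear neurons encodes a scalar x through
tuning curves a_i(x) = max(0, alpha_i e_i x / radius + J^b_i), where e_i is
the +-1 encoder, alpha_i the gain and J^b_i the bias current.  Linear
decoders d_i obtained by regularized least squares reconstruct x (or any
target function of x) from low-pass filtered spike trains.  Dynamics
dx/dt = f(x) + u are realized with a first-order synapse of time constant
tau_syn by decoding tau_syn * f(x) + x on the recurrent connection and
feeding tau_syn * u on the input connection.

Spike generation is a deterministic integrate-to-threshold realization of
the rectified-linear rate: a per-neuron accumulator integrates rate * dt and
emits unit-area spikes on crossing 1.  Initial accumulator phases are drawn
uniformly (from the ensemble seed) so the population does not fire a
synchronized first volley.  Runs are therefore bit-reproducible from the
ensemble seed without Poisson draws.

Gain/bias distributions follow common NEF practice: intercepts uniform on
(-1, 0.95) of the radius, maximum rates uniform on (100, 200) events/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import sparse as sp


@dataclass(frozen=True)
class EnsembleSpec:
    """Population parameters of one scalar ensemble."""

    n_neurons: int = 20
    radius: float = 1.0
    seed: int = 0
    intercept_low: float = -1.0
    intercept_high: float = 0.95
    max_rate_low: float = 100.0
    max_rate_high: float = 200.0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if not self.intercept_low < self.intercept_high < 1.0:
            raise ValueError("need intercept_low < intercept_high < 1")
        if not 0 < self.max_rate_low < self.max_rate_high:
            raise ValueError("need 0 < max_rate_low < max_rate_high")


@dataclass(frozen=True)
class SynapseSpec:
    """First-order low-pass synapse (tau_syn) and simulation step (dt), seconds."""

    tau_syn: float = 0.005
    dt: float = 0.001

    def __post_init__(self) -> None:
        if not self.tau_syn > 0 or not self.dt > 0:
            raise ValueError("tau_syn and dt must be positive")
        if self.dt > self.tau_syn:
            raise ValueError("dt must not exceed tau_syn")


@dataclass
class DecoderSet:
    """Least-squares decoding weights for one ensemble."""

    decoders: np.ndarray  # (n_neurons,)
    regularization: float


def _tuning_parameters(spec: EnsembleSpec, rng: np.random.Generator):
    """Sample encoders, gains and biases so each neuron's rectified-linear
    tuning curve crosses zero at its intercept and reaches its max rate at
    the preferred end of [-radius, +radius]."""
    n = spec.n_neurons
    encoders = rng.choice([-1.0, 1.0], size=n)
    intercepts = rng.uniform(spec.intercept_low, spec.intercept_high, size=n)
    max_rates = rng.uniform(spec.max_rate_low, spec.max_rate_high, size=n)
    gains = max_rates / (1.0 - intercepts)
    biases = -intercepts * gains
    return encoders, gains, biases


class Ensemble:
    """A realized scalar ensemble: seeded tuning parameters and rate curves."""

    def __init__(self, spec: EnsembleSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.encoders, self.gains, self.biases = _tuning_parameters(spec, rng)

    @property
    def n_neurons(self) -> int:
        return self.spec.n_neurons

    @property
    def radius(self) -> float:
        return self.spec.radius

    def rates(self, x) -> np.ndarray:
        """Static firing rates (events/s) for represented value(s) x.

        Shape: x.shape + (n_neurons,); nonnegative everywhere.
        """
        x = np.asarray(x, dtype=float)
        drive = self.gains * self.encoders * (x[..., None] / self.radius) + self.biases
        return np.maximum(0.0, drive)


def build_ensemble(spec: EnsembleSpec) -> Ensemble:
    """Realize an ensemble from its spec (deterministic in the seed)."""
    return Ensemble(spec)


def default_eval_points(radius: float, n: int = 500) -> np.ndarray:
    return np.linspace(-radius, radius, n)


def solve_decoders(
    ensemble: Ensemble,
    target_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    eval_points: Optional[np.ndarray] = None,
    regularization: float = 0.01,
) -> DecoderSet:
    """Regularized least-squares decoders for target_fn (default: identity).

    Minimizes ||A d - f(x)||^2 + (reg * max|A|)^2 * n_eval * ||d||^2 over the
    evaluation points, the standard NEF ridge formulation.  Falls back to a
    pseudo-inverse (with a warning) if the Gram matrix is singular.
    """
    if eval_points is None:
        eval_points = default_eval_points(ensemble.radius)
    eval_points = np.asarray(eval_points, dtype=float)
    if eval_points.size < ensemble.n_neurons:
        raise ValueError("need at least n_neurons evaluation points")
    targets = eval_points if target_fn is None else target_fn(eval_points)

    activities = ensemble.rates(eval_points)  # (E, n)
    sigma = regularization * np.max(np.abs(activities))
    gram = activities.T @ activities + (sigma**2 * eval_points.size) * np.eye(
        ensemble.n_neurons
    )
    rhs = activities.T @ targets
    try:
        decoders = np.linalg.solve(gram, rhs)
    except np.linalg.LinAlgError:
        warnings.warn("rank-deficient activity matrix; using pseudo-inverse")
        decoders = np.linalg.pinv(gram) @ rhs
    return DecoderSet(decoders=decoders, regularization=regularization)


def decode_rates(ensemble: Ensemble, decoders: DecoderSet, x) -> np.ndarray:
    """Rate-mode (non-spiking) decode: the oracle the spiking run approximates."""
    return ensemble.rates(x) @ decoders.decoders


def simulate_spiking(
    ensemble: Ensemble,
    decoders: DecoderSet,
    input_signal,
    T: float,
    synapse: SynapseSpec = SynapseSpec(),
) -> tuple[np.ndarray, np.ndarray]:
    """Open-loop spiking simulation of one ensemble.

    ``input_signal`` is a constant or a callable t -> x.  Returns
    ``(times, decoded)`` where decoded[k] is the synapse-filtered spike
    decode at time times[k].  The time average of the decode of a constant
    converges to the rate-mode value within a noise band shrinking with
    neuron count and averaging time.
    """
    if T < 3 * synapse.tau_syn:
        warnings.warn("T is short relative to tau_syn; decode will be transient")
    n_steps = int(round(T / synapse.dt))
    dt = synapse.dt
    decay = np.exp(-dt / synapse.tau_syn)
    x_of_t = input_signal if callable(input_signal) else (lambda t: input_signal)

    # desynchronized initial spike phases, reproducible from the seed
    v = np.random.default_rng((ensemble.spec.seed, 0x5BE)).random(ensemble.n_neurons)
    filt = np.zeros(ensemble.n_neurons)
    times = (np.arange(n_steps) + 1) * dt
    decoded = np.empty(n_steps)
    d = decoders.decoders
    for k in range(n_steps):
        rate = ensemble.rates(x_of_t(times[k]))
        v += rate * dt
        spikes = np.floor(v)
        v -= spikes
        filt = decay * filt + (1.0 - decay) * (spikes / dt)
        decoded[k] = filt @ d
    return times, decoded


# ---------------------------------------------------------------------------
# Vectorized grids of ensembles and recurrent dynamics
# ---------------------------------------------------------------------------


class EnsembleGrid:
    """P independent scalar ensembles with shared spec, vectorized.

    Used to host one ensemble per pixel; all tuning parameters are drawn
    from a single seeded generator so the grid is reproducible as a whole.
    """

    def __init__(self, n_ensembles: int, spec: EnsembleSpec):
        if n_ensembles < 1:
            raise ValueError("need at least one ensemble")
        self.n_ensembles = n_ensembles
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        n = spec.n_neurons
        self.encoders = rng.choice([-1.0, 1.0], size=(n_ensembles, n))
        intercepts = rng.uniform(spec.intercept_low, spec.intercept_high, size=(n_ensembles, n))
        max_rates = rng.uniform(spec.max_rate_low, spec.max_rate_high, size=(n_ensembles, n))
        self.gains = max_rates / (1.0 - intercepts)
        self.biases = -intercepts * self.gains

    @property
    def radius(self) -> float:
        return self.spec.radius

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Static rates for a per-ensemble value vector x of shape (P,)."""
        drive = self.gains * self.encoders * (x[:, None] / self.radius) + self.biases
        return np.maximum(0.0, drive)

    def solve_identity_decoders(
        self,
        n_eval: int = 200,
        regularization: float = 0.01,
        chunk: int = 1024,
    ) -> np.ndarray:
        """Batched identity decoders, shape (P, n_neurons)."""
        xe = default_eval_points(self.radius, n_eval)  # (E,)
        n = self.spec.n_neurons
        out = np.empty((self.n_ensembles, n))
        for lo in range(0, self.n_ensembles, chunk):
            hi = min(lo + chunk, self.n_ensembles)
            drive = (
                self.gains[lo:hi, None, :]
                * self.encoders[lo:hi, None, :]
                * (xe[None, :, None] / self.radius)
                + self.biases[lo:hi, None, :]
            )
            acts = np.maximum(0.0, drive)  # (p, E, n)
            sigma = regularization * np.max(np.abs(acts))
            gram = np.einsum("pen,pem->pnm", acts, acts) + (
                sigma**2 * n_eval
            ) * np.eye(n)
            rhs = np.einsum("pen,e->pn", acts, xe)
            out[lo:hi] = np.linalg.solve(gram, rhs[..., None])[..., 0]
        return out


@dataclass
class RecurrentNetwork:
    """A grid of ensembles wired to realize dx/dt = A x + b + u(t).

    Following the NEF dynamics principle, the recurrent connection decodes
    tau_syn * (A x + b) + x and the input connection injects tau_syn * u,
    so the represented state follows the target linear dynamics regardless
    of the synaptic time constant.
    """

    grid: EnsembleGrid
    A: "sp.spmatrix | np.ndarray"
    b: np.ndarray
    synapse: SynapseSpec
    decoders: np.ndarray = field(init=False)
    W_rec: "sp.spmatrix | np.ndarray" = field(init=False)

    def __post_init__(self) -> None:
        P = self.grid.n_ensembles
        if self.A.shape != (P, P):
            raise ValueError("A must be (P, P)")
        self.b = np.broadcast_to(np.asarray(self.b, dtype=float), (P,)).copy()
        self.decoders = self.grid.solve_identity_decoders()
        eye = sp.identity(P, format="csr") if sp.issparse(self.A) else np.eye(P)
        self.W_rec = self.synapse.tau_syn * self.A + eye
        self._stability_check()

    def _stability_check(self) -> None:
        """Warn on an unstable recurrent stencil (some Re(lambda) > 0)."""
        try:
            if sp.issparse(self.A):
                if self.A.shape[0] <= 2:
                    lam_max = float(np.max(np.real(np.linalg.eigvals(self.A.toarray()))))
                else:
                    lam_max = float(
                        np.real(
                            sp.linalg.eigs(
                                self.A.astype(float), k=1, which="LR", return_eigenvectors=False
                            )[0]
                        )
                    )
            else:
                lam_max = float(np.max(np.real(np.linalg.eigvals(np.asarray(self.A)))))
        except Exception:
            return
        if lam_max > 1e-9:
            warnings.warn(
                f"recurrent dynamics matrix has an unstable mode (Re lambda = {lam_max:.3g})"
            )

    def run(
        self,
        T: float,
        u: Optional[np.ndarray] = None,
        record_every: int = 1,
        x0: Optional[np.ndarray] = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Simulate for T seconds; returns (times, decoded states).

        ``u`` is a constant external input vector (P,).  The network starts
        at rest (zero synaptic state) unless ``x0`` seeds the filters.
        """
        dt = self.synapse.dt
        n_steps = int(round(T / dt))
        decay = np.exp(-dt / self.synapse.tau_syn)
        P = self.grid.n_ensembles
        u_vec = np.zeros(P) if u is None else np.asarray(u, dtype=float)
        drive_const = self.synapse.tau_syn * (self.b + u_vec)

        # desynchronized initial spike phases, reproducible from the seed
        v = np.random.default_rng((self.grid.spec.seed, 0x5BE)).random(
            (P, self.grid.spec.n_neurons)
        )
        filt = np.zeros_like(v)
        xhat = np.zeros(P) if x0 is None else np.asarray(x0, dtype=float).copy()

        n_rec = n_steps // record_every
        times = np.empty(n_rec)
        states = np.empty((n_rec, P))
        j = 0
        for k in range(n_steps):
            j_in = self.W_rec @ xhat + drive_const
            rate = self.grid.rates(j_in)
            v += rate * dt
            spikes = np.floor(v)
            v -= spikes
            filt = decay * filt + (1.0 - decay) * (spikes / dt)
            xhat = np.einsum("pn,pn->p", filt, self.decoders)
            if (k + 1) % record_every == 0:
                times[j] = (k + 1) * dt
                states[j] = xhat
                j += 1
        return times, states


def build_recurrent_dynamics(
    A,
    b=0.0,
    n_state: Optional[int] = None,
    ensemble_spec: EnsembleSpec = EnsembleSpec(),
    synapse: SynapseSpec = SynapseSpec(),
) -> RecurrentNetwork:
    """Wire a grid of scalar ensembles to realize dx/dt = A x + b + u."""
    A = sp.csr_matrix(A) if sp.issparse(A) else np.atleast_2d(np.asarray(A, dtype=float))
    P = A.shape[0] if n_state is None else n_state
    grid = EnsembleGrid(P, ensemble_spec)
    return RecurrentNetwork(grid=grid, A=A, b=np.asarray(b, dtype=float), synapse=synapse)
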