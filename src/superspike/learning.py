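"""The SuperSpike three-factor learning rule.

The weight change for synapse ``j -> i`` is the chunked integral of the
product of a per-neuron error/feedback signal with a per-synapse eligibility
trace,

    dw_ij / dt  ~  e_i(t) * [ alpha * ( sigma'(U_i) (eps * S_j) ) ](t),

where ``sigma'(U) = (1 + beta |U - theta|)^-2`` is the surrogate derivative
of a fast sigmoid of the membrane voltage (maximal at threshold, strictly
positive everywhere, so learning proceeds even from a completely silent
network), ``eps * S_j`` is the kernel-filtered presynaptic spike train read
at the synapse (i.e. after the axonal delay), and ``alpha`` is the van
Rossum smoothing kernel acting as an eligibility filter that bridges the
delay between a coincidence and the error signal it caused.

Error signals come in two flavours: precise-timing mode, where
``e_i = alpha * (target_i - output_i)`` vanishes only on a grid-exact match,
and classification mode, where erroneous spikes inject negative impulses
immediately and a missed response window injects a positive impulse at the
window end.  Hidden layers receive the output errors through symmetric
(transposed feedforward), fixed random, or uniform all-one feedback
coefficients; the error is never passed through the spiking nonlinearity
(straight-through credit assignment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigurationError, NeuronParams
from .kernels import KernelParams, TraceState, trace_step

__all__ = [
    "SurrogateParams",
    "FeedbackSpec",
    "ErrorState",
    "RegularizerParams",
    "SynapseMatrix",
    "surrogate_derivative",
    "hebbian_coincidence",
    "eligibility_step",
    "output_error_step",
    "ClassificationWindow",
    "classification_error_step",
    "feedback_signals",
    "accumulate_update",
    "apply_update",
    "regularizer_term",
    "update_rate_estimate",
]

#: presynaptic traces below this value are treated as exact zeros
TRACE_CUTOFF = 1e-30


@dataclass(frozen=True)
class SurrogateParams:
    """Steepness of the fast sigmoid surrogate around threshold (per mV)."""

    beta_per_mV: float = 1.0

    def __post_init__(self) -> None:
        if self.beta_per_mV <= 0:
            raise ConfigurationError("beta_per_mV must be > 0")


def surrogate_derivative(U, params: NeuronParams, s: SurrogateParams = SurrogateParams()):
    """Surrogate spike derivative ``(1 + beta |U - theta|)^-2``.

    Equals 1 at threshold, decays symmetrically away from it, and is strictly
    positive everywhere — the non-vanishing surrogate gradient.
    """
    h = 1.0 + s.beta_per_mV * np.abs(np.asarray(U, dtype=np.float64) - params.threshold_mV)
    out = 1.0 / (h * h)
    return float(out) if np.ndim(U) == 0 else out


@dataclass
class FeedbackSpec:
    """Credit-assignment mode for hidden units.

    ``symmetric`` uses the transposed feedforward output weights, ``random``
    a fixed coefficient matrix drawn once from N(0, 1) at initialization,
    ``uniform`` sets every coefficient to one.
    """

    mode: str = "symmetric"
    B: np.ndarray | None = None
    seed: int | None = None

    MODES = ("symmetric", "random", "uniform")

    @classmethod
    def create(cls, mode: str, n_hidden: int, n_out: int, seed: int = 0) -> "FeedbackSpec":
        if mode not in cls.MODES:
            raise ConfigurationError(f"unknown feedback mode {mode!r}")
        B = None
        if mode == "random":
            B = np.random.default_rng(seed).standard_normal((n_hidden, n_out))
        return cls(mode=mode, B=B, seed=seed)


@dataclass
class ErrorState:
    """Per-output kernel-filtered error signal ``e_i``."""

    trace: TraceState
    mode: str = "precise_timing"  # or "classification"

    @classmethod
    def zeros(cls, n_out: int, mode: str = "precise_timing") -> "ErrorState":
        return cls(TraceState.zeros(n_out), mode)

    @property
    def e(self) -> np.ndarray:
        return self.trace.slow


@dataclass(frozen=True)
class RegularizerParams:
    """Heterosynaptic activity-dependent weight decay.

    Subtracts ``rho * w_ij * nu_bar_i ** exponent_a`` inside the update
    accumulator, where ``nu_bar_i`` is an exponential moving average (time
    constant ``tau_avg_ms``) of the postsynaptic firing rate in Hz.  Keeps
    hidden firing rates from running away under random feedback.
    """

    rho: float = 0.0
    exponent_a: float = 2.0
    tau_avg_ms: float = 1000.0

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ConfigurationError("rho must be >= 0")
        if self.exponent_a < 0:
            raise ConfigurationError("exponent_a must be >= 0")
        if self.tau_avg_ms <= 0:
            raise ConfigurationError("tau_avg_ms must be > 0")


@dataclass
class SynapseMatrix:
    """Weights plus per-synapse learning state for one connection block.

    ``elig`` holds the two-stage eligibility filter (``elig.slow`` is the
    lambda trace entering the update), ``m`` the chunked update accumulator,
    ``v`` the second-moment upper estimate used by the per-parameter
    learning-rate schedules.
    """

    w: np.ndarray
    w_min: float = -0.1
    w_max: float = 0.1
    elig: TraceState = None
    m: np.ndarray = None
    v: np.ndarray = None

    def __post_init__(self) -> None:
        if self.w_min > self.w_max:
            raise ConfigurationError("w_min must be <= w_max")
        if self.elig is None:
            self.elig = TraceState.zeros(self.w.shape)
        if self.m is None:
            self.m = np.zeros_like(self.w)
        if self.v is None:
            self.v = np.zeros_like(self.w)

    @property
    def shape(self) -> tuple[int, int]:
        return self.w.shape

    @classmethod
    def uniform_init(
        cls, n_pre: int, n_post: int, scale: float, rng: np.random.Generator, w_min=-0.1, w_max=0.1
    ) -> "SynapseMatrix":
        return cls(w=scale * rng.uniform(0.0, 1.0, size=(n_pre, n_post)), w_min=w_min, w_max=w_max)


# -- per-step operations ---------------------------------------------------


def hebbian_coincidence(
    presyn_slow: np.ndarray,
    U_post: np.ndarray,
    params: NeuronParams,
    s: SurrogateParams = SurrogateParams(),
    cutoff: float = TRACE_CUTOFF,
) -> np.ndarray:
    """Outer product of delayed presynaptic traces with surrogate derivatives.

    ``presyn_slow`` must be the trace of the presynaptic train *as seen at
    the synapse*, i.e. read with a lag compensating the axonal delay (drive
    the trace with delivered spikes, or read it ``delay_steps`` late).
    Entries with presynaptic trace below ``cutoff`` are exact zeros.
    """
    pre = np.where(presyn_slow >= cutoff, presyn_slow, 0.0)
    return np.outer(pre, surrogate_derivative(U_post, params, s))


def eligibility_step(
    syn: SynapseMatrix, hebbian: np.ndarray, k_alpha: KernelParams, dt_ms: float
) -> SynapseMatrix:
    """Filter the per-synapse Hebbian product through the eligibility kernel."""
    trace_step(syn.elig, hebbian, k_alpha, dt_ms)
    return syn


def output_error_step(
    err: ErrorState,
    output_spikes: np.ndarray,
    target_spikes: np.ndarray,
    k_alpha: KernelParams,
    dt_ms: float,
) -> ErrorState:
    """Precise-timing error: ``e = alpha * (target - output)`` updated online."""
    impulses = np.asarray(target_spikes, dtype=np.float64) - output_spikes
    trace_step(err.trace, impulses, k_alpha, dt_ms)
    return err


@dataclass
class ClassificationWindow:
    """One stimulus-aligned response window for classification error signals."""

    t0_ms: float
    t1_ms: float
    correct_unit: int
    hit: bool = False


def classification_error_step(
    err: ErrorState,
    output_spikes: np.ndarray,
    t_ms: float,
    window: ClassificationWindow | None,
    k_alpha: KernelParams,
    dt_ms: float,
) -> ErrorState:
    """Classification-mode error update for one step.

    Every spike of a wrong unit — or any spike outside a window — injects a
    negative unit impulse at spike time; if the correct unit stays silent
    through its window, a positive unit impulse is injected exactly at the
    window end.  Correct in-window spikes generate no error.  ``window`` is
    the window covering ``t_ms`` (None outside windows); the caller is
    responsible for never presenting overlapping windows.
    """
    impulses = -np.asarray(output_spikes, dtype=np.float64)
    if window is not None and window.t0_ms <= t_ms < window.t1_ms:
        u = window.correct_unit
        if output_spikes[u] > 0:
            window.hit = True
            impulses[u] = 0.0
    if window is not None and window.t1_ms <= t_ms < window.t1_ms + dt_ms and not window.hit:
        impulses[window.correct_unit] += 1.0
    trace_step(err.trace, impulses, k_alpha, dt_ms)
    return err


def feedback_signals(
    output_errors: np.ndarray, W_out: np.ndarray, spec: FeedbackSpec
) -> np.ndarray:
    """Hidden-layer feedback ``delta_h`` from the output errors.

    Symmetric: ``W_out @ e`` (transposed feedforward weights); random:
    ``B @ e`` with the fixed coefficient matrix; uniform: ``sum_i e_i`` for
    every hidden unit.  Straight-through: no spiking nonlinearity applied.
    """
    e = np.asarray(output_errors, dtype=np.float64)
    if spec.mode == "symmetric":
        if W_out.shape[1] != e.shape[0]:
            raise ConfigurationError("feedback shape mismatch")
        return W_out @ e
    if spec.mode == "random":
        if spec.B is None or spec.B.shape[1] != e.shape[0]:
            raise ConfigurationError("random feedback matrix missing or mismatched")
        return spec.B @ e
    if spec.mode == "uniform":
        return np.full(W_out.shape[0], e.sum())
    raise ConfigurationError(f"unknown feedback mode {spec.mode!r}")


def accumulate_update(
    syn: SynapseMatrix,
    feedback: np.ndarray,
    dt_ms: float,
    reg: RegularizerParams | None = None,
    nu_bar: np.ndarray | None = None,
) -> SynapseMatrix:
    """Integrate the three-factor product into the chunk accumulator.

    ``m_ij += dt * delta_i * lambda_ij`` with time in seconds; with
    regularization, additionally ``m_ij -= dt * rho * w_ij * g(nu_bar_i)``.
    """
    dt_s = dt_ms / 1000.0
    syn.m += dt_s * syn.elig.slow * np.asarray(feedback, dtype=np.float64)[None, :]
    if reg is not None and reg.rho > 0:
        syn.m -= dt_s * regularizer_term(syn.w, nu_bar, reg)
    return syn


def regularizer_term(w: np.ndarray, nu_bar: np.ndarray, p: RegularizerParams) -> np.ndarray:
    """Heterosynaptic decay ``rho * w_ij * nu_bar_i ** a`` (per second)."""
    if p.exponent_a < 0:
        raise ConfigurationError("exponent_a must be >= 0")
    g = np.asarray(nu_bar, dtype=np.float64) ** p.exponent_a
    return p.rho * w * g[None, :]


def update_rate_estimate(
    nu_bar: np.ndarray, post_spikes: np.ndarray, tau_avg_ms: float, dt_ms: float
) -> np.ndarray:
    """Exponential moving average of the postsynaptic firing rate (Hz).

    A stationary Poisson train of rate f drives ``nu_bar`` to f in
    expectation: each spike adds ``1 / tau_avg`` (in 1/s) and the estimate
    decays with ``tau_avg``.
    """
    decay = np.exp(-dt_ms / tau_avg_ms)
    return nu_bar * decay + np.asarray(post_spikes, dtype=np.float64) * (1000.0 / tau_avg_ms)


def apply_update(syn: SynapseMatrix, rates: np.ndarray | float) -> SynapseMatrix:
    """Apply the accumulated chunk update with per-synapse rates and clip.

    ``w_ij <- clip(w_ij + r_ij m_ij, w_min, w_max)``; the accumulator is
    reset to zero.
    """
    syn.w = np.clip(syn.w + rates * syn.m, syn.w_min, syn.w_max)
    syn.m = np.zeros_like(syn.m)
    return syn
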