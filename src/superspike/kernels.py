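"""Causal double-exponential kernels and their online two-stage filters.

Two kernels drive everything in this package: the PSP kernel (the shape a
single presynaptic spike imprints on the membrane) and the van Rossum
smoothing kernel used for the spike-train cost and the eligibility traces.
Both are the same normalized causal double exponential

    kappa(t) = N * (exp(-t / tau_decay) - exp(-t / tau_rise)),  t >= 0,

which can be evaluated online by exponential filtering twice: a fast stage
with ``tau_rise`` feeding a slow stage with ``tau_decay``.  The discrete
two-stage update used here is *exact*: after an impulse of weight 1 in step
``k``, the slow stage read after step ``n`` equals ``kappa((n - k + 1) dt)``
to machine precision, so the online trace is identical to a direct
convolution of the grid-aligned impulse train with the kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "KernelParams",
    "TraceState",
    "kernel_eval",
    "trace_step",
    "filter_spike_train",
    "van_rossum_distance",
]


class KernelError(ValueError):
    pass


@dataclass(frozen=True)
class KernelParams:
    """Double-exponential kernel parameters.

    ``normalize`` selects the convention for the scalar prefactor N:
    ``"peak"`` makes the kernel maximum equal one (the default, so error and
    eligibility amplitudes are directly interpretable), ``"integral"`` makes
    the time integral equal one millisecond-normalized.
    """

    tau_rise_ms: float = 5.0
    tau_decay_ms: float = 10.0
    normalize: str = "peak"

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise_ms < self.tau_decay_ms:
            raise KernelError("require 0 < tau_rise_ms < tau_decay_ms")
        if self.normalize not in ("peak", "integral"):
            raise KernelError("normalize must be 'peak' or 'integral'")

    @property
    def peak_time_ms(self) -> float:
        """Analytic maximum of the un-normalized kernel."""
        tr, td = self.tau_rise_ms, self.tau_decay_ms
        return tr * td / (td - tr) * np.log(td / tr)

    @property
    def normalization(self) -> float:
        tr, td = self.tau_rise_ms, self.tau_decay_ms
        if self.normalize == "peak":
            ts = self.peak_time_ms
            return 1.0 / (np.exp(-ts / td) - np.exp(-ts / tr))
        return 1.0 / (td - tr)  # integral = (td - tr) ms for the raw kernel

    def decay_factors(self, dt_ms: float) -> tuple[float, float]:
        """Per-step decay multipliers ``(a_rise, a_decay)``."""
        return float(np.exp(-dt_ms / self.tau_rise_ms)), float(np.exp(-dt_ms / self.tau_decay_ms))

    def stage_coupling(self, dt_ms: float) -> float:
        """Fast-to-slow coupling making the discrete filter exactly match the kernel.

        With ``fast' = a_r fast + x`` and ``slow' = a_d slow + c fast'``, the
        impulse response of ``slow`` is ``c (a_d^{n+1} - a_r^{n+1})/(a_d - a_r)``,
        so ``c = N (a_d - a_r)`` yields kernel samples exactly.
        """
        a_r, a_d = self.decay_factors(dt_ms)
        return self.normalization * (a_d - a_r)


def kernel_eval(t_ms, k: KernelParams):
    """Evaluate the normalized causal kernel at time(s) ``t_ms`` (0 for t < 0)."""
    t = np.asarray(t_ms, dtype=np.float64)
    out = k.normalization * (np.exp(-t / k.tau_decay_ms) - np.exp(-t / k.tau_rise_ms))
    out = np.where(t >= 0, out, 0.0)
    if np.ndim(t_ms) == 0:
        return float(out)
    return out


@dataclass
class TraceState:
    """State of a two-stage exponential filter over an array of elements."""

    fast: np.ndarray
    slow: np.ndarray

    @classmethod
    def zeros(cls, shape) -> "TraceState":
        return cls(np.zeros(shape), np.zeros(shape))

    def copy(self) -> "TraceState":
        return TraceState(self.fast.copy(), self.slow.copy())


def trace_step(state: TraceState, impulses, k: KernelParams, dt_ms: float) -> TraceState:
    """Advance the two-stage filter by one step, adding per-element impulses.

    Mutates and returns ``state``; reading ``state.slow`` after the call gives
    the kernel-filtered impulse train at the end of the step.
    """
    a_r, a_d = k.decay_factors(dt_ms)
    c = k.stage_coupling(dt_ms)
    state.fast *= a_r
    state.fast += impulses
    state.slow *= a_d
    state.slow += c * state.fast
    if not (np.all(np.isfinite(state.fast)) and np.all(np.isfinite(state.slow))):
        raise FloatingPointError("non-finite trace state")
    return state


def filter_spike_train(dense: np.ndarray, k: KernelParams, dt_ms: float) -> np.ndarray:
    """Kernel-filter a dense ``(n_steps, n_units)`` impulse array along time.

    Vectorized equivalent of calling :func:`trace_step` once per row; row
    ``n`` of the result is the slow stage read after step ``n``.
    """
    a_r, a_d = k.decay_factors(dt_ms)
    c = k.stage_coupling(dt_ms)
    x = np.asarray(dense, dtype=np.float64)
    fast = lfilter([1.0], [1.0, -a_r], x, axis=0)
    return lfilter([c], [1.0, -a_d], fast, axis=0)


def van_rossum_distance(
    a, b, k: KernelParams | None = None, dt_ms: float = 0.1
) -> tuple[np.ndarray, float]:
    """Van Rossum distance between two spike rasters.

    Convolves the signed difference train with the kernel and integrates half
    the squared result over time (in seconds):
    ``D_i = 1/2 * integral (kappa * (a_i - b_i))^2 dt``.

    Returns ``(per_unit, total)``.  Symmetric, non-negative, and zero exactly
    when the two rasters coincide on the ``dt`` grid.
    """
    if k is None:
        k = KernelParams()
    if a.n_units != b.n_units or a.duration_ms != b.duration_ms:
        raise KernelError("rasters must share n_units and duration_ms")
    diff = a.to_dense(dt_ms).astype(np.float64) - b.to_dense(dt_ms)
    e = filter_spike_train(diff, k, dt_ms)
    per_unit = 0.5 * np.sum(e * e, axis=0) * (dt_ms / 1000.0)
    return per_unit, float(per_unit.sum())
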