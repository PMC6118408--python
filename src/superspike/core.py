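"""Clock-driven simulation of current-based leaky integrate-and-fire layers.

The membrane of neuron ``i`` obeys

    tau_mem dU_i/dt = (U_rest - U_i) + kappa * I_i(t)
    tau_syn dI_i/dt = -I_i,    I_i += w_ji at each spike delivery,

with a hard threshold: when ``U_i`` reaches ``theta`` at the end of a step the
neuron emits a spike, the voltage is clamped to rest for the refractory
period (the synaptic current keeps evolving), and the spike is delivered to
downstream synapses after a fixed axonal delay.

Both equations are linear between deliveries, so each ``dt`` step uses the
exact exponential solution of the coupled pair rather than an Euler update —
unconditionally stable and exact for grid-aligned deliveries.

Units: voltages in mV, times in ms.  Synaptic weights are dimensionless; the
coupling ``current_scale_mV`` (default 1000) converts the summed synaptic
current into membrane drive, so a lone weight ``w`` produces a PSP with peak
amplitude ``~250 w`` mV for the default time constants.  This reproduces the
conventional volt-scale weight units of reference simulators, under which
the default weight bounds of +-0.1 are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import SpikeRaster

__all__ = ["NeuronParams", "LayerState", "init_layer", "step_layer", "propagate", "run_network"]


class ConfigurationError(ValueError):
    pass


class NumericalError(FloatingPointError):
    pass


@dataclass(frozen=True)
class NeuronParams:
    """LIF neuron constants (voltages mV, times ms)."""

    threshold_mV: float = -50.0
    rest_mV: float = -60.0
    tau_mem_ms: float = 10.0
    tau_syn_ms: float = 5.0
    tau_ref_ms: float = 5.0
    axonal_delay_ms: float = 0.8
    dt_ms: float = 0.1
    current_scale_mV: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("tau_mem_ms", "tau_syn_ms", "tau_ref_ms"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.threshold_mV <= self.rest_mV:
            raise ConfigurationError("threshold_mV must exceed rest_mV")
        if self.dt_ms <= 0 or self.dt_ms > self.tau_syn_ms / 10.0 + 1e-12:
            raise ConfigurationError("require 0 < dt_ms <= tau_syn_ms / 10")
        if self.tau_mem_ms == self.tau_syn_ms:
            raise ConfigurationError("tau_mem_ms and tau_syn_ms must differ")
        ratio = self.axonal_delay_ms / self.dt_ms
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError("axonal_delay_ms must be an integer multiple of dt_ms")

    # derived step constants -------------------------------------------------

    @property
    def delay_steps(self) -> int:
        return int(round(self.axonal_delay_ms / self.dt_ms))

    @property
    def ref_steps(self) -> int:
        return int(round(self.tau_ref_ms / self.dt_ms))

    @property
    def decay_mem(self) -> float:
        return float(np.exp(-self.dt_ms / self.tau_mem_ms))

    @property
    def decay_syn(self) -> float:
        return float(np.exp(-self.dt_ms / self.tau_syn_ms))

    @property
    def coupling(self) -> float:
        """Particular-solution coefficient of the exact voltage update.

        For drive ``I0 exp(-t/tau_syn)`` the voltage particular solution is
        ``c * I0 exp(-t/tau_syn)`` with ``c = kappa tau_syn/(tau_syn - tau_mem)``.
        """
        return self.current_scale_mV * self.tau_syn_ms / (self.tau_syn_ms - self.tau_mem_ms)


@dataclass
class LayerState:
    """Per-neuron dynamic state of one LIF layer.

    ``pending`` is the axonal delay line: a ring buffer of spike indicators,
    one row per delay step; row ``(step % delay_steps)`` holds the spikes
    emitted ``delay_steps`` ago and due for delivery at the current step.
    """

    U: np.ndarray
    I_syn: np.ndarray
    ref_remaining: np.ndarray  # int steps
    pending: np.ndarray  # (max(delay_steps, 1), n_units) uint8

    @property
    def n_units(self) -> int:
        return self.U.shape[0]


def init_layer(n_units: int, params: NeuronParams) -> LayerState:
    """A quiescent layer: voltage at rest, no current, empty delay line."""
    if n_units < 1:
        raise ConfigurationError("n_units must be >= 1")
    return LayerState(
        U=np.full(n_units, params.rest_mV, dtype=np.float64),
        I_syn=np.zeros(n_units),
        ref_remaining=np.zeros(n_units, dtype=np.int64),
        pending=np.zeros((max(params.delay_steps, 1), n_units), dtype=np.uint8),
    )


def step_layer(
    state: LayerState, incoming: np.ndarray, params: NeuronParams
) -> tuple[LayerState, np.ndarray]:
    """Advance one layer by one ``dt`` step.

    ``incoming`` is the per-neuron summed weighted current jump delivered at
    the start of the step (already delay-resolved).  Returns the mutated
    state and the array of ids that spiked this step.

    The voltage of refractory neurons stays clamped at rest while their
    synaptic current keeps evolving; non-refractory neurons follow the exact
    exponential solution of the coupled linear ODEs; units at or above
    threshold at the end of the step spike and are reset.
    """
    p = params
    I0 = state.I_syn + incoming
    refractory = state.ref_remaining > 0
    drive = p.coupling * I0
    U_new = p.rest_mV + (state.U - p.rest_mV - drive) * p.decay_mem + drive * p.decay_syn
    U_new[refractory] = p.rest_mV
    state.ref_remaining[refractory] -= 1
    state.I_syn = I0 * p.decay_syn
    if not (np.all(np.isfinite(U_new)) and np.all(np.isfinite(state.I_syn))):
        bad = int(np.flatnonzero(~(np.isfinite(U_new) & np.isfinite(state.I_syn)))[0])
        raise NumericalError(f"non-finite membrane state in unit {bad}")
    spiking = (~refractory) & (U_new >= p.threshold_mV)
    U_new[spiking] = p.rest_mV
    state.ref_remaining[spiking] = p.ref_steps
    state.U = U_new
    return state, np.flatnonzero(spiking)


def propagate(emitted_ids: np.ndarray, t_now_ms: float, params: NeuronParams):
    """Schedule deliveries for spikes emitted at ``t_now_ms``.

    Returns a list of ``(delivery_time_ms, unit_id)`` pairs, one per spike,
    each ``axonal_delay_ms`` after emission.
    """
    return [(t_now_ms + params.axonal_delay_ms, int(i)) for i in np.atleast_1d(emitted_ids)]


def run_network(
    input_raster: SpikeRaster,
    layers: list[tuple[np.ndarray, LayerState]],
    params: NeuronParams,
    hooks=None,
) -> list[SpikeRaster]:
    """Run a feedforward stack of LIF layers driven by an input raster.

    ``layers`` is a list of ``(weight_matrix, state)`` pairs; weight matrix
    ``l`` has shape ``(n_pre, n_post)`` connecting the previous population
    (the input for ``l = 0``) to layer ``l``.  Spikes propagate with the
    axonal delay, applied uniformly between all populations (a zero delay
    delivers within the same step, layers being updated in feedforward
    order).  Fully deterministic: identical inputs, weights and initial
    states reproduce identical rasters.

    ``hooks``, if given, is a callable ``hooks(step, states)`` invoked after
    every step (used for voltage monitoring).
    """
    p = params
    sizes = [input_raster.n_units] + [st.n_units for _, st in layers]
    for idx, (w, _) in enumerate(layers):
        if w.shape != (sizes[idx], sizes[idx + 1]):
            raise ConfigurationError(
                f"layer {idx}: weight shape {w.shape} != {(sizes[idx], sizes[idx + 1])}"
            )
    dense_in = input_raster.to_dense(p.dt_ms)
    n_steps = dense_in.shape[0]
    d = p.delay_steps
    # delay line for the input population (input units are pure event sources)
    in_pending = np.zeros((max(d, 1), input_raster.n_units), dtype=np.uint8)
    events: list[list[tuple[float, int]]] = [[] for _ in layers]
    for step in range(n_steps):
        ptr = step % max(d, 1)
        if d > 0:
            delivered_prev = in_pending[ptr].astype(np.float64)
            in_pending[ptr] = dense_in[step]
        else:
            delivered_prev = dense_in[step].astype(np.float64)
        for idx, (w, st) in enumerate(layers):
            incoming = delivered_prev @ w
            st, spiked = step_layer(st, incoming, p)
            spike_vec = np.zeros(st.n_units, dtype=np.uint8)
            spike_vec[spiked] = 1
            for i in spiked:
                events[idx].append((step * p.dt_ms, int(i)))
            if d > 0:
                delivered_prev = st.pending[ptr].astype(np.float64)
                st.pending[ptr] = spike_vec
            else:
                delivered_prev = spike_vec.astype(np.float64)
        if hooks is not None:
            hooks(step, [st for _, st in layers])
    return [
        SpikeRaster.from_events(ev, st.n_units, input_raster.duration_ms)
        for ev, (_, st) in zip(events, layers)
    ]
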