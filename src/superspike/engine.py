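"""Fused clock-driven training engine.

This module executes the same per-step operations as the modular API
(`core`, `kernels`, `learning`, `optimizers`) — exact-exponential LIF
updates, delayed spike propagation, two-stage presynaptic/eligibility/error
filters, three-factor accumulation and chunked weight updates — in a single
numba-compiled loop over time steps.  The benchmark tasks need millions of
0.1 ms steps with dense per-synapse state, which makes a fused kernel the
appropriate execution strategy; the test suite asserts step-for-step
equivalence between this engine and the composed modular operations.

Architecture: ``input -> (optional hidden) -> output``, current-based LIF
everywhere past the input (input units are pure event sources), one global
axonal delay between populations.  Presynaptic traces are driven by
*delivered* spikes, which realizes the delay compensation of the Hebbian
term.  The surrogate derivative is evaluated on the end-of-step membrane
voltage before any spike reset, so the coincidence term is maximal at spike
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .core import ConfigurationError, NeuronParams
from .kernels import KernelParams
from .learning import FeedbackSpec, RegularizerParams, SurrogateParams, TRACE_CUTOFF
from .optimizers import OptimizerParams
from .raster import SpikeRaster

__all__ = ["Network", "silent_uniform_init"]

_FB = {"symmetric": 0, "random": 1, "uniform": 2}
_OPT = {"fixed": 0, "rmsprop": 1, "rmaxprop": 2}
_ERR = {"precise_timing": 0, "classification": 1}


@njit(cache=True)
def _simulate(
    n_steps, step_offset, n_in, n_hid, n_out,
    learn, learn_hidden, linear_rule, error_mode, feedback_mode, opt_mode,
    e_mem, e_syn, c_u, theta, urest, ref_steps, delay_steps,
    a_r, a_d, c_stage,
    beta, dt_s, steps_per_chunk, r0, gamma, eps_opt, w_min, w_max,
    rho, reg_exp, a_nu, nu_incr, cutoff, e_cost,
    in_spk, tgt_spk, win_label, win_start, win_end_label,
    W_h, m_h, v_h, W_o, m_o, v_o, B,
    U_h, I_h, ref_h, U_o, I_o, ref_o,
    rb_in, rb_h,
    tr_in_f, tr_in_s, tr_h_f, tr_h_s,
    el_h_f, el_h_s, el_o_f, el_o_s,
    err_f, err_s,
    nu_h, scratch_flags, cost_state,
    hid_spk_out, out_spk_out, cost_trace,
):
    has_hidden = n_hid > 0
    sp_h = np.zeros(n_hid)
    sp_o = np.zeros(n_out)
    spike_h = np.zeros(n_hid)
    spike_o = np.zeros(n_out)
    fb = np.zeros(n_hid)
    imp = np.zeros(n_out)
    for t in range(n_steps):
        ptr = (step_offset + t) % delay_steps
        # --- deliveries due this step (emitted delay_steps ago) ---
        deliv_in = rb_in[ptr].copy()
        rb_in[ptr] = in_spk[t]
        if has_hidden:
            deliv_h = rb_h[ptr].copy()
        else:
            deliv_h = np.zeros(0)

        # --- presynaptic traces driven at delivery time ---
        for j in range(n_in):
            f = tr_in_f[j] * a_r + deliv_in[j]
            tr_in_f[j] = f
            s = tr_in_s[j] * a_d + c_stage * f
            tr_in_s[j] = 0.0 if s < cutoff else s
        if has_hidden:
            for j in range(n_hid):
                f = tr_h_f[j] * a_r + deliv_h[j]
                tr_h_f[j] = f
                s = tr_h_s[j] * a_d + c_stage * f
                tr_h_s[j] = 0.0 if s < cutoff else s

        # --- hidden-layer dynamics ---
        if has_hidden:
            for j in range(n_in):
                dj = deliv_in[j]
                if dj > 0:
                    for i in range(n_hid):
                        I_h[i] += W_h[j, i] * dj
            for i in range(n_hid):
                spike_h[i] = 0.0
                if ref_h[i] > 0:
                    U_h[i] = urest
                    ref_h[i] -= 1
                else:
                    drive = c_u * I_h[i]
                    u = urest + (U_h[i] - urest - drive) * e_mem + drive * e_syn
                    if u >= theta:
                        spike_h[i] = 1.0
                        ref_h[i] = ref_steps
                        u = urest
                        hid_spk_out[t, i] = 1
                    U_h[i] = u
                I_h[i] *= e_syn
                if not np.isfinite(U_h[i]) or not np.isfinite(I_h[i]):
                    raise FloatingPointError("non-finite hidden membrane state")
                if linear_rule:
                    sp_h[i] = 1.0
                else:
                    h = 1.0 + beta * abs(U_h[i] - theta)
                    sp_h[i] = 1.0 / (h * h)
                rb_h[ptr, i] = spike_h[i]

        # --- output-layer dynamics ---
        pre_o = deliv_h if has_hidden else deliv_in
        n_pre_o = n_hid if has_hidden else n_in
        for j in range(n_pre_o):
            dj = pre_o[j]
            if dj > 0:
                for i in range(n_out):
                    I_o[i] += W_o[j, i] * dj
        for i in range(n_out):
            spike_o[i] = 0.0
            if ref_o[i] > 0:
                U_o[i] = urest
                ref_o[i] -= 1
            else:
                drive = c_u * I_o[i]
                u = urest + (U_o[i] - urest - drive) * e_mem + drive * e_syn
                if u >= theta:
                    spike_o[i] = 1.0
                    ref_o[i] = ref_steps
                    u = urest
                    out_spk_out[t, i] = 1
                U_o[i] = u
            I_o[i] *= e_syn
            if not np.isfinite(U_o[i]) or not np.isfinite(I_o[i]):
                raise FloatingPointError("non-finite output membrane state")
            if linear_rule:
                sp_o[i] = 1.0
            else:
                h = 1.0 + beta * abs(U_o[i] - theta)
                sp_o[i] = 1.0 / (h * h)

        # --- error impulses ---
        if error_mode == 0:
            for i in range(n_out):
                imp[i] = float(tgt_spk[t, i]) - spike_o[i]
        else:
            if win_start[t] != 0:
                scratch_flags[0] = 0
            lab = win_label[t]
            for i in range(n_out):
                imp[i] = 0.0
                if spike_o[i] > 0:
                    if lab >= 0 and i == lab:
                        scratch_flags[0] = 1
                    else:
                        imp[i] = -spike_o[i]
            endlab = win_end_label[t]
            if endlab >= 0 and scratch_flags[0] == 0:
                imp[endlab] += 1.0
        sq = 0.0
        for i in range(n_out):
            f = err_f[i] * a_r + imp[i]
            err_f[i] = f
            e = err_s[i] * a_d + c_stage * f
            err_s[i] = e
            sq += e * e
        cost_state[0] = cost_state[0] * e_cost + (1.0 - e_cost) * sq / n_out
        cost_trace[t] = cost_state[0]

        if learn:
            # --- feedback to hidden units ---
            if has_hidden:
                esum = 0.0
                for i in range(n_out):
                    esum += err_s[i]
                for hh in range(n_hid):
                    if feedback_mode == 0:
                        acc = 0.0
                        for i in range(n_out):
                            acc += W_o[hh, i] * err_s[i]
                        fb[hh] = acc
                    elif feedback_mode == 1:
                        acc = 0.0
                        for i in range(n_out):
                            acc += B[hh, i] * err_s[i]
                        fb[hh] = acc
                    else:
                        fb[hh] = esum

                # regularizer rate estimate and per-neuron decay factor
                for i in range(n_hid):
                    nu_h[i] = nu_h[i] * a_nu + spike_h[i] * nu_incr
                reg_g = np.zeros(n_hid)
                if rho > 0.0:
                    for i in range(n_hid):
                        reg_g[i] = rho * nu_h[i] ** reg_exp

                # --- hidden-weight eligibility + accumulation ---
                if learn_hidden:
                    for j in range(n_in):
                        pj = tr_in_s[j]
                        active = pj >= cutoff
                        for i in range(n_hid):
                            f = el_h_f[j, i] * a_r
                            if active:
                                f += pj * sp_h[i]
                            el_h_f[j, i] = f
                            s = el_h_s[j, i] * a_d + c_stage * f
                            el_h_s[j, i] = s
                            dm = fb[i] * s - reg_g[i] * W_h[j, i]
                            m_h[j, i] += dt_s * dm

            # --- output-weight eligibility + accumulation ---
            pre_tr = tr_h_s if has_hidden else tr_in_s
            for j in range(n_pre_o):
                pj = pre_tr[j]
                active = pj >= cutoff
                for i in range(n_out):
                    f = el_o_f[j, i] * a_r
                    if active:
                        f += pj * sp_o[i]
                    el_o_f[j, i] = f
                    s = el_o_s[j, i] * a_d + c_stage * f
                    el_o_s[j, i] = s
                    m_o[j, i] += dt_s * err_s[i] * s

            # --- chunked weight update ---
            gstep = step_offset + t + 1
            if gstep % steps_per_chunk == 0:
                if has_hidden and learn_hidden:
                    for j in range(n_in):
                        for i in range(n_hid):
                            mm = m_h[j, i]
                            if opt_mode == 2:
                                vv = gamma * v_h[j, i]
                                if mm * mm > vv:
                                    vv = mm * mm
                                v_h[j, i] = vv
                            elif opt_mode == 1:
                                v_h[j, i] = gamma * v_h[j, i] + (1.0 - gamma) * mm * mm
                            if opt_mode == 0:
                                rr = r0
                            else:
                                rr = r0 / (np.sqrt(v_h[j, i]) + eps_opt)
                            w = W_h[j, i] + rr * mm
                            if w > w_max:
                                w = w_max
                            elif w < w_min:
                                w = w_min
                            W_h[j, i] = w
                            m_h[j, i] = 0.0
                for j in range(n_pre_o):
                    for i in range(n_out):
                        mm = m_o[j, i]
                        if opt_mode == 2:
                            vv = gamma * v_o[j, i]
                            if mm * mm > vv:
                                vv = mm * mm
                            v_o[j, i] = vv
                        elif opt_mode == 1:
                            v_o[j, i] = gamma * v_o[j, i] + (1.0 - gamma) * mm * mm
                        if opt_mode == 0:
                            rr = r0
                        else:
                            rr = r0 / (np.sqrt(v_o[j, i]) + eps_opt)
                        w = W_o[j, i] + rr * mm
                        if w > w_max:
                            w = w_max
                        elif w < w_min:
                            w = w_min
                        W_o[j, i] = w
                        m_o[j, i] = 0.0


@dataclass
class Network:
    """A trainable one- or two-layer LIF network with full learning state.

    Holds weights, membrane/trace/eligibility state and optimizer moments;
    :meth:`run` advances the simulation over a dense input chunk, optionally
    learning online, and records spikes and the smoothed cost.
    """

    n_in: int
    n_hidden: int  # 0 for a network without hidden units
    n_out: int
    params: NeuronParams = field(default_factory=NeuronParams)
    kernel: KernelParams = field(default_factory=KernelParams)
    surrogate: SurrogateParams = field(default_factory=SurrogateParams)
    feedback: FeedbackSpec | None = None
    optimizer: OptimizerParams = field(default_factory=OptimizerParams)
    regularizer: RegularizerParams = field(default_factory=RegularizerParams)
    t_b_ms: float = 500.0
    cost_tau_ms: float = 10_000.0
    error_mode: str = "precise_timing"
    learn_hidden: bool = True
    linear_rule: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.params
        if self.n_in < 1 or self.n_out < 1 or self.n_hidden < 0:
            raise ConfigurationError("population sizes must be positive (n_hidden may be 0)")
        if p.delay_steps < 1:
            raise ConfigurationError("the fused engine requires axonal_delay_ms >= dt_ms")
        if self.error_mode not in _ERR:
            raise ConfigurationError(f"unknown error mode {self.error_mode!r}")
        if self.feedback is None:
            self.feedback = FeedbackSpec.create(
                "symmetric", max(self.n_hidden, 1), self.n_out, self.seed
            )
        if self.feedback.mode == "random" and self.feedback.B is None:
            raise ConfigurationError("random feedback requires a coefficient matrix")
        steps = self.t_b_ms / p.dt_ms
        if abs(steps - round(steps)) > 1e-9:
            raise ConfigurationError("t_b_ms must be an integer multiple of dt_ms")
        self.steps_per_chunk = int(round(steps))

        rng = np.random.default_rng(self.seed)
        n_pre_o = self.n_hidden if self.n_hidden else self.n_in
        self.W_h = np.zeros((self.n_in, max(self.n_hidden, 1)))
        self.W_o = np.zeros((n_pre_o, self.n_out))
        self.w_min, self.w_max = -0.1, 0.1
        self.B = (
            self.feedback.B
            if self.feedback.B is not None
            else np.zeros((max(self.n_hidden, 1), self.n_out))
        )
        self.global_step = 0
        self.reset_state()
        self.reset_learning_state()
        self._rng = rng

    # -- state management --------------------------------------------------

    def reset_state(self) -> None:
        """Reset dynamic state (voltages, currents, traces, delay lines)."""
        p = self.params
        nh = max(self.n_hidden, 1)
        self.U_h = np.full(nh, p.rest_mV)
        self.I_h = np.zeros(nh)
        self.ref_h = np.zeros(nh, dtype=np.int64)
        self.U_o = np.full(self.n_out, p.rest_mV)
        self.I_o = np.zeros(self.n_out)
        self.ref_o = np.zeros(self.n_out, dtype=np.int64)
        self.rb_in = np.zeros((p.delay_steps, self.n_in))
        self.rb_h = np.zeros((p.delay_steps, nh))
        self.tr_in_f = np.zeros(self.n_in)
        self.tr_in_s = np.zeros(self.n_in)
        self.tr_h_f = np.zeros(nh)
        self.tr_h_s = np.zeros(nh)
        self.err_f = np.zeros(self.n_out)
        self.err_s = np.zeros(self.n_out)
        self.cost_state = np.zeros(1)
        self.scratch_flags = np.zeros(1, dtype=np.int64)
        self.global_step = 0

    def reset_learning_state(self) -> None:
        nh = max(self.n_hidden, 1)
        n_pre_o = self.n_hidden if self.n_hidden else self.n_in
        self.el_h_f = np.zeros((self.n_in, nh))
        self.el_h_s = np.zeros((self.n_in, nh))
        self.el_o_f = np.zeros((n_pre_o, self.n_out))
        self.el_o_s = np.zeros((n_pre_o, self.n_out))
        self.m_h = np.zeros((self.n_in, nh))
        self.v_h = np.zeros((self.n_in, nh))
        self.m_o = np.zeros((n_pre_o, self.n_out))
        self.v_o = np.zeros((n_pre_o, self.n_out))
        self.nu_h = np.zeros(nh)

    @property
    def smoothed_cost(self) -> float:
        """Root of the moving-average squared error (10 s time constant)."""
        return float(np.sqrt(self.cost_state[0]))

    # -- execution ---------------------------------------------------------

    def run(
        self,
        in_dense: np.ndarray,
        tgt_dense: np.ndarray | None = None,
        windows: list[tuple[float, float, int]] | None = None,
        t0_ms: float = 0.0,
        learn: bool = False,
        r0: float | None = None,
    ) -> dict:
        """Advance the network over one dense input chunk.

        ``in_dense`` is ``(n_steps, n_in)``; for precise-timing mode supply
        ``tgt_dense`` ``(n_steps, n_out)``, for classification mode supply
        ``windows`` as ``(t0_ms, t1_ms, correct_unit)`` triples in absolute
        chunk time (``t0_ms`` is the chunk's start time).  Returns dense
        hidden/output spike arrays and the per-step smoothed cost.
        """
        p = self.params
        n_steps = in_dense.shape[0]
        if in_dense.shape[1] != self.n_in:
            raise ConfigurationError("input width mismatch")
        if tgt_dense is None:
            tgt_dense = np.zeros((n_steps, self.n_out), dtype=np.uint8)
        elif tgt_dense.shape != (n_steps, self.n_out):
            raise ConfigurationError("target shape mismatch")
        win_label = np.full(n_steps, -1, dtype=np.int64)
        win_start = np.zeros(n_steps, dtype=np.int64)
        win_end_label = np.full(n_steps, -1, dtype=np.int64)
        if windows is not None:
            prev_end = -np.inf
            for w0, w1, lab in windows:
                if lab < 0 or lab >= self.n_out:
                    raise ConfigurationError("window label out of range")
                if w0 < prev_end:
                    raise ConfigurationError("overlapping classification windows")
                prev_end = w1
                s0 = int(round((w0 - t0_ms) / p.dt_ms))
                s1 = int(round((w1 - t0_ms) / p.dt_ms))
                if s1 < 0 or s0 >= n_steps:
                    continue
                lo, hi = max(s0, 0), min(s1, n_steps)
                win_label[lo:hi] = lab
                if 0 <= s0 < n_steps:
                    win_start[s0] = 1
                if 0 <= s1 < n_steps:
                    win_end_label[s1] = lab
        hid_spk = np.zeros((n_steps, max(self.n_hidden, 1)), dtype=np.uint8)
        out_spk = np.zeros((n_steps, self.n_out), dtype=np.uint8)
        cost_trace = np.zeros(n_steps)
        a_r, a_d = self.kernel.decay_factors(p.dt_ms)
        c_stage = self.kernel.stage_coupling(p.dt_ms)
        opt = self.optimizer
        reg = self.regularizer
        _simulate(
            n_steps, self.global_step, self.n_in, self.n_hidden, self.n_out,
            learn, self.learn_hidden, self.linear_rule,
            _ERR[self.error_mode], _FB[self.feedback.mode], _OPT[opt.mode],
            p.decay_mem, p.decay_syn, p.coupling, p.threshold_mV, p.rest_mV,
            p.ref_steps, p.delay_steps,
            a_r, a_d, c_stage,
            self.surrogate.beta_per_mV, p.dt_ms / 1000.0, self.steps_per_chunk,
            opt.r0 if r0 is None else r0, opt.gamma, opt.epsilon, self.w_min, self.w_max,
            reg.rho, reg.exponent_a,
            float(np.exp(-p.dt_ms / reg.tau_avg_ms)), 1000.0 / reg.tau_avg_ms,
            TRACE_CUTOFF, float(np.exp(-p.dt_ms / self.cost_tau_ms)),
            np.ascontiguousarray(in_dense, dtype=np.float64),
            np.ascontiguousarray(tgt_dense, dtype=np.float64),
            win_label, win_start, win_end_label,
            self.W_h, self.m_h, self.v_h, self.W_o, self.m_o, self.v_o,
            np.ascontiguousarray(self.B, dtype=np.float64),
            self.U_h, self.I_h, self.ref_h, self.U_o, self.I_o, self.ref_o,
            self.rb_in, self.rb_h,
            self.tr_in_f, self.tr_in_s, self.tr_h_f, self.tr_h_s,
            self.el_h_f, self.el_h_s, self.el_o_f, self.el_o_s,
            self.err_f, self.err_s,
            self.nu_h, self.scratch_flags, self.cost_state,
            hid_spk, out_spk, cost_trace,
        )
        self.global_step += n_steps
        return {"hidden": hid_spk, "output": out_spk, "cost": cost_trace}

    def output_raster(self, out_spk: np.ndarray, duration_ms: float) -> SpikeRaster:
        return SpikeRaster.from_dense(out_spk, self.params.dt_ms, duration_ms)


def silent_uniform_init(
    net: Network,
    probe_dense: np.ndarray,
    rng: np.random.Generator,
    scale: float = 0.02,
    min_scale: float = 1e-6,
) -> float:
    """Initialize feedforward weights uniformly, halving until the net is silent.

    Draws ``U(0, 1)`` variates once per weight, scales them by ``scale`` and
    runs a learning-free dry run over ``probe_dense``; if any hidden or
    output unit fires, the scale is halved and the dry run repeated.
    Returns the accepted scale.  This realizes the initial condition of the
    precise-timing experiments, where neither hidden nor output units fire a
    single spike before training.
    """
    u_h = rng.uniform(0.0, 1.0, size=net.W_h.shape)
    u_o = rng.uniform(0.0, 1.0, size=net.W_o.shape)
    while scale >= min_scale:
        net.W_h[:] = scale * u_h
        net.W_o[:] = scale * u_o
        net.reset_state()
        res = net.run(probe_dense, learn=False)
        n_spikes = int(res["output"].sum()) + (int(res["hidden"].sum()) if net.n_hidden else 0)
        if n_spikes == 0:
            net.reset_state()
            return scale
        scale *= 0.5
    raise ConfigurationError("could not find a silent initialization")
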