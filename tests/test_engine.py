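"""Equivalence of the fused training engine with the composed modular API.

The engine must be an execution strategy, not a different model: with
learning off it reproduces `run_network` rasters exactly, and with learning
on its weight trajectories match a step-by-step composition of the modular
operations (traces, Hebbian products, eligibility filters, error signals,
feedback, chunked updates) to floating-point accuracy.
"""

import numpy as np
import pytest

from superspike.core import NeuronParams, init_layer, run_network, step_layer
from superspike.engine import Network, silent_uniform_init
from superspike.kernels import KernelParams, TraceState, trace_step
from superspike.learning import (
    ClassificationWindow,
    ErrorState,
    FeedbackSpec,
    RegularizerParams,
    SurrogateParams,
    SynapseMatrix,
    accumulate_update,
    apply_update,
    classification_error_step,
    eligibility_step,
    feedback_signals,
    hebbian_coincidence,
    output_error_step,
    update_rate_estimate,
)
from superspike.optimizers import OptimizerParams, per_param_rate, second_moment_step
from superspike.raster import SpikeRaster


def modular_train(
    p: NeuronParams,
    kernel: KernelParams,
    W_h: np.ndarray | None,
    W_o: np.ndarray,
    fb_spec: FeedbackSpec,
    opt: OptimizerParams,
    t_b_steps: int,
    in_dense: np.ndarray,
    tgt_dense: np.ndarray | None = None,
    windows: list[ClassificationWindow] | None = None,
    reg: RegularizerParams | None = None,
):
    """Reference trainer composed purely from the modular operations."""
    s = SurrogateParams()
    n_steps, n_in = in_dense.shape
    n_hid = 0 if W_h is None else W_h.shape[1]
    n_out = W_o.shape[1]
    d = p.delay_steps
    rb_in = np.zeros((d, n_in))
    rb_h = np.zeros((d, max(n_hid, 1)))
    tr_in = TraceState.zeros(n_in)
    tr_h = TraceState.zeros(max(n_hid, 1))
    st_h = init_layer(n_hid, p) if n_hid else None
    st_o = init_layer(n_out, p)
    syn_h = SynapseMatrix(w=W_h.copy()) if n_hid else None
    syn_o = SynapseMatrix(w=W_o.copy())
    err = ErrorState.zeros(n_out)
    nu = np.zeros(max(n_hid, 1))
    out_spikes = np.zeros((n_steps, n_out), dtype=np.uint8)
    for t in range(n_steps):
        ptr = t % d
        deliv_in = rb_in[ptr].copy()
        rb_in[ptr] = in_dense[t]
        deliv_h = rb_h[ptr].copy()
        trace_step(tr_in, deliv_in, kernel, p.dt_ms)
        trace_step(tr_h, deliv_h, kernel, p.dt_ms)
        if n_hid:
            st_h, spk_h = step_layer(st_h, deliv_in @ syn_h.w, p)
            spike_h = np.zeros(n_hid)
            spike_h[spk_h] = 1.0
            rb_h[ptr] = spike_h
        pre_o = deliv_h if n_hid else deliv_in
        st_o, spk_o = step_layer(st_o, pre_o @ syn_o.w, p)
        spike_o = np.zeros(n_out)
        spike_o[spk_o] = 1.0
        out_spikes[t] = spike_o
        t_ms = t * p.dt_ms
        if windows is not None:
            win = next((w for w in windows if w.t0_ms <= t_ms <= w.t1_ms), None)
            classification_error_step(err, spike_o, t_ms, win, kernel, p.dt_ms)
        else:
            output_error_step(err, spike_o, tgt_dense[t], kernel, p.dt_ms)
        if n_hid:
            fb = feedback_signals(err.e, syn_o.w, fb_spec)
            nu = update_rate_estimate(nu, spike_h, 1000.0, p.dt_ms)
            h = hebbian_coincidence(tr_in.slow, st_h.U, p, s)
            eligibility_step(syn_h, h, kernel, p.dt_ms)
            accumulate_update(syn_h, fb, p.dt_ms, reg, nu)
        h_o = hebbian_coincidence((tr_h if n_hid else tr_in).slow, st_o.U, p, s)
        eligibility_step(syn_o, h_o, kernel, p.dt_ms)
        accumulate_update(syn_o, err.e, p.dt_ms)
        if (t + 1) % t_b_steps == 0:
            for syn in ([syn_h] if n_hid else []) + [syn_o]:
                syn.v = second_moment_step(syn.v, syn.m, opt)
                apply_update(syn, per_param_rate(syn.v, opt))
    return (syn_h.w if n_hid else None), syn_o.w, out_spikes


def _make_net(n_in, n_hid, n_out, fb_mode="symmetric", error_mode="precise_timing", **kw):
    reg = kw.pop("regularizer", RegularizerParams())
    net = Network(
        n_in=n_in,
        n_hidden=n_hid,
        n_out=n_out,
        feedback=FeedbackSpec.create(fb_mode, max(n_hid, 1), n_out, seed=5),
        optimizer=OptimizerParams(r0=5e-3, mode="rmaxprop"),
        regularizer=reg,
        t_b_ms=100.0,
        error_mode=error_mode,
        seed=3,
        **kw,
    )
    return net


def test_engine_without_learning_matches_run_network(rng):
    p = NeuronParams()
    in_dense = (rng.random((4000, 20)) < 0.01).astype(np.uint8)
    W_h = rng.uniform(0, 0.08, (20, 3))
    W_o = rng.uniform(0, 0.1, (3, 2))
    net = _make_net(20, 3, 2)
    net.W_h[:] = W_h
    net.W_o[:] = W_o
    res = net.run(in_dense.astype(np.float64), learn=False)
    inp = SpikeRaster.from_dense(in_dense, p.dt_ms)
    rasters = run_network(inp, [(W_h, init_layer(3, p)), (W_o, init_layer(2, p))], p)
    assert np.array_equal(res["hidden"], rasters[0].to_dense(p.dt_ms))
    assert np.array_equal(res["output"], rasters[1].to_dense(p.dt_ms))


@pytest.mark.parametrize("fb_mode", ["symmetric", "random", "uniform"])
def test_engine_learning_matches_modular_composition(fb_mode, rng):
    """3000 learning steps with hidden layer: identical weight trajectories."""
    p = NeuronParams()
    n_in, n_hid, n_out = 12, 3, 2
    in_dense = (rng.random((3000, n_in)) < 0.004).astype(np.float64)
    tgt_dense = (rng.random((3000, n_out)) < 0.001).astype(np.float64)
    W_h = rng.uniform(0, 0.08, (n_in, n_hid))
    W_o = rng.uniform(0, 0.1, (n_hid, n_out))
    net = _make_net(n_in, n_hid, n_out, fb_mode)
    net.W_h[:] = W_h
    net.W_o[:] = W_o
    net.run(in_dense, tgt_dense, learn=True)
    ref_Wh, ref_Wo, ref_out = modular_train(
        p, KernelParams(), W_h, W_o, net.feedback,
        OptimizerParams(r0=5e-3, mode="rmaxprop"), 1000, in_dense, tgt_dense,
    )
    np.testing.assert_allclose(net.W_h, ref_Wh, rtol=1e-9, atol=1e-12)
    np.testing.assert_allclose(net.W_o, ref_Wo, rtol=1e-9, atol=1e-12)


def test_engine_with_regularizer_matches_modular(rng):
    p = NeuronParams()
    n_in, n_hid, n_out = 10, 3, 1
    in_dense = (rng.random((2000, n_in)) < 0.01).astype(np.float64)
    tgt_dense = (rng.random((2000, n_out)) < 0.002).astype(np.float64)
    W_h = rng.uniform(0, 0.09, (n_in, n_hid))
    W_o = rng.uniform(0, 0.1, (n_hid, n_out))
    reg = RegularizerParams(rho=1e-3, exponent_a=2.0, tau_avg_ms=1000.0)
    net = _make_net(n_in, n_hid, n_out, "symmetric", regularizer=reg)
    net.W_h[:] = W_h
    net.W_o[:] = W_o
    net.run(in_dense, tgt_dense, learn=True)
    ref_Wh, ref_Wo, _ = modular_train(
        p, KernelParams(), W_h, W_o, net.feedback,
        OptimizerParams(r0=5e-3, mode="rmaxprop"), 1000, in_dense, tgt_dense, reg=reg,
    )
    np.testing.assert_allclose(net.W_h, ref_Wh, rtol=1e-9, atol=1e-12)
    np.testing.assert_allclose(net.W_o, ref_Wo, rtol=1e-9, atol=1e-12)


def test_engine_classification_matches_modular(rng):
    p = NeuronParams()
    n_in, n_hid, n_out = 10, 3, 2
    in_dense = (rng.random((3000, n_in)) < 0.01).astype(np.float64)
    W_h = rng.uniform(0, 0.09, (n_in, n_hid))
    W_o = rng.uniform(0, 0.1, (n_hid, n_out))
    wins = [(20.0, 45.0, 0), (90.0, 115.0, 1), (170.0, 195.0, 0), (260.0, 285.0, 1)]
    net = _make_net(n_in, n_hid, n_out, "uniform", error_mode="classification")
    net.W_h[:] = W_h
    net.W_o[:] = W_o
    net.run(in_dense, windows=wins, learn=True)
    ref_Wh, ref_Wo, _ = modular_train(
        p, KernelParams(), W_h, W_o, net.feedback,
        OptimizerParams(r0=5e-3, mode="rmaxprop"), 1000, in_dense,
        windows=[ClassificationWindow(a, b, u) for a, b, u in wins],
    )
    np.testing.assert_allclose(net.W_h, ref_Wh, rtol=1e-9, atol=1e-12)
    np.testing.assert_allclose(net.W_o, ref_Wo, rtol=1e-9, atol=1e-12)


def test_engine_is_bit_deterministic(rng):
    in_dense = (rng.random((5000, 15)) < 0.01).astype(np.float64)
    tgt_dense = (rng.random((5000, 1)) < 0.002).astype(np.float64)

    def go():
        net = _make_net(15, 4, 1, "random")
        silent_uniform_init(net, in_dense, np.random.default_rng(11), 0.02)
        res = net.run(in_dense, tgt_dense, learn=True)
        return net.W_h.copy(), net.W_o.copy(), res["output"].copy()

    a, b = go(), go()
    assert np.array_equal(a[0], b[0])
    assert np.array_equal(a[1], b[1])
    assert np.array_equal(a[2], b[2])


def test_silent_init_is_silent(rng):
    in_dense = (rng.random((5000, 50)) < 0.005).astype(np.float64)
    net = _make_net(50, 4, 1)
    scale = silent_uniform_init(net, in_dense, np.random.default_rng(2), 0.05)
    res = net.run(in_dense, learn=False)
    assert res["output"].sum() == 0 and res["hidden"].sum() == 0
    assert 0 < scale <= 0.05


def test_gradient_sign_correctness(rng):
    """Quiescent output, active inputs, non-empty target: every synapse whose
    presynaptic spikes precede a target spike inside the kernel support
    accumulates a positive update (learning pushes voltage up at targets)."""
    p = NeuronParams()
    n_in, n_steps = 30, 5000
    in_dense = (rng.random((n_steps, n_in)) < 0.002).astype(np.float64)
    tgt = np.zeros((n_steps, 1))
    tgt[int(250 / p.dt_ms), 0] = 1.0
    net = Network(n_in=n_in, n_hidden=0, n_out=1, t_b_ms=1000.0, seed=0)
    net.W_o[:] = 0.0  # output can never spike
    net.run(in_dense, tgt, learn=True)
    # apply never happened mid-run only at multiples of t_b; read accumulator
    t_tgt = 250.0
    for j in range(n_in):
        spikes = np.flatnonzero(in_dense[:, j]) * p.dt_ms
        preceding = spikes[(spikes < t_tgt) & (spikes > t_tgt - 50.0)]
        if preceding.size:
            assert net.m_o[j, 0] > 0, f"synapse {j} should have positive drive"
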