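# Methods

## Model

The simulator implements current-based leaky integrate-and-fire (LIF)
neurons on a fixed clock.  For neuron *i*,

```
tau_mem dU_i/dt = (U_rest - U_i) + kappa I_i(t)
tau_syn dI_i/dt = -I_i ,          I_i += w_ji  at each spike delivery,
```

with a hard threshold theta: when `U_i >= theta` at the end of a step the
neuron spikes, its voltage is clamped to `U_rest` for the refractory period
`tau_ref` (the synaptic current keeps evolving), and the spike reaches
downstream synapses after a fixed axonal delay.  Defaults: `theta = -50 mV`,
`U_rest = -60 mV`, `tau_mem = 10 ms`, `tau_syn = 5 ms`, `tau_ref = 5 ms`,
delay `0.8 ms`, step `dt = 0.1 ms`.  The refractory duration is an
assumption (the value is configurable); the remaining constants are the
standard parameter set for this model class.

Both equations are linear between deliveries, so each step applies the
exact exponential solution of the coupled pair instead of an Euler update.
This is unconditionally stable at `dt = 0.1 ms` and reproduces the
spike-response-model picture exactly: one delivery of weight `w` produces
the closed-form PSP `kappa w tau_syn/(tau_syn - tau_mem) (exp(-t/tau_syn) -
exp(-t/tau_mem))`.  A fine-grid Euler integration is kept as a test oracle
(agreement within 0.1 mV over 1 s of random input).

**Weight units.**  Weights are dimensionless and bounded in `[-0.1, 0.1]`.
The coupling `kappa = current_scale_mV = 1000` converts summed synaptic
current into membrane drive, so `w = 0.1` produces a PSP peaking at 25 mV
and `w = 0.01` at 2.5 mV.  This is the conventional volt-scale weight unit
of reference LIF simulators, under which the default bounds are meaningful:
a single near-maximal synapse can drive a postsynaptic spike, while typical
learned weights sit one to two orders of magnitude lower.

## Kernels and online traces

All filtering uses the normalized causal double exponential
`kappa(t) = N (exp(-t/tau_decay) - exp(-t/tau_rise))` with `tau_rise =
tau_syn = 5 ms` and `tau_decay = tau_mem = 10 ms` — the PSP shape — for the
presynaptic traces, the eligibility traces and the van Rossum error kernel
alike.  `N` normalizes the peak to one by default (configurable to unit
integral); unit peak makes error and eligibility amplitudes directly
interpretable as "fractions of one spike".

Online realization: exponential filtering twice (fast stage `tau_rise`,
slow stage `tau_decay`).  The discrete stage coupling is chosen as
`c = N (a_d - a_r)` with `a_x = exp(-dt/tau_x)`, which makes the discrete
impulse response *exactly* equal to kernel samples: after an impulse in
step `k`, the slow stage read after step `n` is `kappa((n-k+1) dt)` to
machine precision.  The online trace is therefore identical to direct
convolution (the tests assert agreement at 1e-14), and the van Rossum
distance evaluated on the grid matches its closed form for isolated spikes
to ~1e-9.

The van Rossum distance is `D = 1/2 sum_i integral (kappa * (a_i - b_i))^2 dt`
with time in seconds.  On the grid it is zero exactly when two rasters
coincide cell by cell.

## The learning rule

The weight change for synapse `j -> i` integrates a three-factor product:

```
m_ij += dt  e_i(t)  [ alpha * ( sigma'(U_i) (eps * S_j) ) ](t)
```

- `sigma'(U) = (1 + beta |U - theta|)^-2` is the surrogate derivative of a
  fast sigmoid of the membrane voltage, maximal (=1) at threshold and
  strictly positive everywhere, so silent units still receive gradient.
  `beta = 1 /mV` by default.  The voltage entering `sigma'` is the
  end-of-step value after any reset; since the voltage hugs the threshold
  in the steps before a spike, coincidence detection is preserved.
- `eps * S_j` is the presynaptic trace.  Traces are driven by *delivered*
  spikes, which implements the delay compensation between the Hebbian
  product and the axonal delay.  Trace values below 1e-30 are treated as
  exact zeros and skipped in the outer product.
- `alpha` filtering of the Hebbian product is the per-synapse eligibility
  trace, long enough (kernel support tens of ms) to bridge the latency of
  causally related error signals.

Error signals: in precise-timing mode `e_i = alpha * (target_i - output_i)`
computed online; it vanishes only when output and target match grid-exactly.
In classification mode, each erroneous spike (wrong unit inside a response
window, or any unit outside every window) injects a negative unit impulse
at spike time, and a missed window injects a positive unit impulse into the
correct unit exactly at the window end; the positive and negative impulse
magnitudes are equal (the asymmetric alternative is unstated in the
protocol this follows, and equal magnitudes are the neutral choice).

Hidden units receive `delta = W e` (symmetric), `delta = B e` with a fixed
`B ~ N(0, 1)` drawn once (random), or `delta = sum_i e_i` (uniform).  The
error is never passed through the spiking nonlinearity or its surrogate —
straight-through credit assignment.

Updates are applied in chunks of `t_b = 0.5 s`: at each boundary
`w += r * m` (clipped to the bounds), `m` resets to zero.  The per-parameter
rate is `r = r0 / (sqrt(v) + 1e-8)` where `v <- max(gamma v, m^2)`
(RMaxProp; `v` is the discounted running maximum of the squared chunk
gradient, an upper estimate of its non-centred second moment) or the
RMSprop moving average, or a fixed `r0`.  `gamma = exp(-t_b / 10 s)` makes
the forgetting timescale explicit.  Note that the RMaxProp `v` does *not*
dominate the RMSprop `v` pointwise for arbitrary gradient histories (after
a high plateau the average can transiently exceed the decayed maximum);
the guaranteed property, asserted by the tests, is that `v` equals
`max_k gamma^k m_{n-k}^2` and hence upper-bounds every discounted squared
gradient.

Regularization (used with random feedback on the hardest task): a
heterosynaptic decay `m_ij -= dt rho w_ij nu_i^a` inside the same
accumulator, where `nu_i` is an exponential moving average of the
postsynaptic firing rate (Hz, time constant 1 s default) and `a = 2` by
default.  `a = 0` removes the activity dependence (a deliberately worse
control); `rho` is task-tuned.

**Initialization.**  Feedforward weights are drawn once as `U(0, scale)`
and the scale is halved until a learning-free dry run produces no hidden or
output spike; the precise-timing experiments start from genuinely silent
networks.

## Execution strategy

The modular API (`core`, `kernels`, `learning`, `optimizers`) defines one
step of every operation in plain numpy.  The benchmark tasks need 10^6-10^7
steps with dense per-synapse state, so `engine.Network` fuses the identical
per-step operations into a single numba-compiled loop.  The test suite
asserts equivalence: with learning off the engine reproduces `run_network`
rasters exactly, and with learning on its weight trajectories match the
composed modular operations to 1e-9 relative in all feedback modes, with
and without regularization, in both error modes.  Everything is
deterministic given (configuration, seed); reruns are bit-identical.

## Synthetic stimuli

The generators reproduce the benchmark conditions: frozen Poisson trains
(one fixed draw, tiled across trials; default input rate 10 Hz where the
protocol leaves it open), equidistant single-unit targets (spikes centred
in sub-intervals — the phase convention avoids spikes at t = 0), jittered
XOR pattern sets (three equal non-overlapping unit sets; one fixed random
firing offset per unit inside a 10 ms window; label = parity of feature-set
presence), presentation streams (uniform-random inter-stimulus gaps of
50-200 ms with 4 Hz Poisson background on all inputs, response windows
outlasting each bout by 15 ms), and long frozen Poisson target rasters for
the pattern-transformation task.

What the generators do *not* emulate: trial-to-trial input variability
(inputs are frozen by design), correlations between input units, conduction
heterogeneity, or any receptor/conductance dynamics.  Passing tests
demonstrate the learning rule's behaviour under the stated benchmark
statistics, not robustness to natural stimulus variability.

## Problem sizes and tuned values

The package's default experiment sizes are chosen so each task trains in
minutes on one CPU core: single-neuron and multilayer timing tasks use 100
inputs, 500 ms trials and <= 500 trials; the XOR task uses 8 hidden units
and a few thousand presentations; the pattern-transformation task is run
scaled down (100 inputs -> 16-32 hidden -> 20 outputs, 1 s pattern, 300 s
training with two 10x learning-rate reductions) rather than at the
full-size 100-output / 3.5 s / 1000 s configuration, which the experiments
module supports but which is not exercised by the test suite.

Base learning rates are task-tuned by log-grid search (the procedure the
rule prescribes for `r0`): `1e-3` for the timing and XOR tasks, `3e-3` for
the scaled pattern task.  These values, the input rates and the regularizer
strength grid are configuration, not claims about any reference
implementation's exact numbers.

The benchmark drivers (`superspike.benchmarks`) apply two measurement
conventions.  Final costs are read on the *frozen* network: learning is
switched off after training and the 10 s moving-average cost is allowed to
settle, so the number reflects the trained deterministic network rather
than the tail of the training fluctuations.  The single-output timing
benchmark runs a small `(r0, annealing)` grid per stimulus and keeps the
best run — grid-searching the base rate is part of the protocol, and
convergence of this nonconvex spike-time optimization depends on the frozen
input draw: some draws stall a few milliseconds off target in a local
minimum under every rate tried.  The XOR driver stops training early once
100 consecutive presentations have been answered correctly.

## Known limitations

- Feedforward stacks with at most one hidden layer in the fused engine
  (the modular `run_network` accepts arbitrary depth); no recurrence.
- Dense O(N_pre x N_post) eligibility state; no sparse fast path.
- The eligibility approximation drops the reset-kernel correction, so the
  rule's gradient interpretation degrades at high postsynaptic rates —
  visible in the random-feedback runaway regime the regularizer exists to
  control.
- Classification windows may not overlap for the same unit; streams are
  generated with positive gaps so this cannot occur internally.
- `axonal_delay_ms` must be a positive multiple of `dt` in the fused
  engine; the modular path also supports zero delay (same-step delivery in
  feedforward order).
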