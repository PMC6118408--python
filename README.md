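# superspike

Supervised learning of **spatiotemporal spike-pattern transformations** in
multilayer networks of deterministic leaky integrate-and-fire (LIF)
neurons, via the SuperSpike surrogate-gradient three-factor rule.

Spiking neurons are non-differentiable at spike times and have zero
derivative everywhere else, so gradient descent on a spike-train cost
cannot be applied directly — and rules that differentiate firing times
cannot start from a silent network.  This package trains networks that
*begin completely silent* to emit precisely timed output spike trains, by
minimizing the van Rossum distance

```
C = 1/2 ∫ ( α ∗ (Ŝ_i − S_i) )² dt
```

between target trains `Ŝ_i` and output trains `S_i` smoothed with a causal
double-exponential kernel `α`.  The weight update for synapse `j → i` is a
voltage-based nonlinear Hebbian three-factor rule with per-synapse
eligibility traces,

```
Δw_ij ∝ ∫ e_i(t) · [ α ∗ ( σ'(U_i) (ε ∗ S_j) ) ](t) dt
```

where `σ'(U) = (1 + β|U − ϑ|)⁻²` is the surrogate derivative of a fast
sigmoid of the membrane voltage (maximal at the firing threshold ϑ,
strictly positive everywhere), `ε ∗ S_j` is the PSP-filtered presynaptic
train, and `e_i = α ∗ (Ŝ_i − S_i)` is the output error signal.  Hidden
layers receive `e` through **symmetric** (transposed feedforward),
**fixed random** (feedback alignment), or **uniform** all-one feedback
coefficients, never through the spiking nonlinearity (straight-through).
Updates are accumulated in half-second chunks and scaled by per-parameter
**RMaxProp** learning rates `r₀ / (√v + ε)` with `v ← max(γv, m²)`.

Intended users: computational neuroscientists and researchers studying
biologically plausible credit assignment, spike-metric-based supervised
learning, or surrogate gradients in clock-driven SNN simulation.

## Worked example

Train one LIF output neuron, starting silent, on 100 frozen 10 Hz Poisson
inputs against a target of five equidistant spikes over 500 ms
(`examples/single_neuron_precise_timing.py`):

```python
from superspike import ExperimentConfig, run_single_neuron_task

cfg = ExperimentConfig(task="single_neuron", seed=1, n_trials=300, r0=1e-3)
res = run_single_neuron_task(cfg)
```

Output:

```
target spike times (ms):  [ 50. 150. 250. 350. 450.]
learned spike times (ms): [ 50.  149.8 250.  349.2 449.6]
max timing error: 0.80 ms
smoothed RMS cost: peak 0.266 -> final 0.0735
```

After 300 trials the neuron emits exactly the five target spikes, each
within a millisecond of its target time.  The cost is the online
root-mean-square of the van Rossum error signal (10 s moving average): it
rises from zero as the first erroneous spikes appear, peaks, and decays
toward zero as output and target converge on the 0.1 ms simulation grid.

Other entry points, one script per capability, live in `examples/`:
multilayer training under the three feedback modes, the spiking XOR
(nonlinearly separable — unsolvable without a hidden layer), the
spatiotemporal pattern-transformation benchmark with firing-rate
regularization, and the kernel/distance machinery.  A thin CLI wraps the
same runners: `superspike run xor --seed 3 --out out/`,
`superspike sweep --task single_neuron --grid 1e-4,1e-3,1e-2`,
`superspike stats out/output.ras --n-units 2 --duration-ms 1000`.

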