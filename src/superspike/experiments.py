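"""End-to-end benchmark experiments, online cost monitoring and statistics.

Four tasks are provided, mirroring the canonical supervised spike-learning
protocols:

``single_neuron``
    One LIF output trained on 100 frozen Poisson inputs against a target of
    five equidistant spikes over 500 ms, starting from a silent network.
``hidden_layer``
    The same task with a small LIF hidden layer, trained under symmetric,
    random or uniform error feedback.
``xor``
    A nonlinearly separable spiking exclusive-or: four jittered input
    patterns in two classes, presented in random order over 4 Hz background
    activity; two readout units must answer within a response window.
``pattern_transform``
    Many outputs learn a long frozen-Poisson spatiotemporal target from
    cyclically repeating frozen-Poisson input — the regime that separates
    the feedback strategies.

Every experiment is a pure function of its configuration (seeded);
re-running reproduces curves bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import ConfigurationError, NeuronParams
from .engine import Network, silent_uniform_init
from .kernels import KernelParams
from .learning import FeedbackSpec, RegularizerParams, SurrogateParams
from .optimizers import OptimizerParams
from .raster import SpikeRaster
from .stimuli import (
    StimulusStream,
    build_stream,
    equidistant_target,
    frozen_poisson,
    make_xor_patterns,
    poisson_target_pattern,
)

__all__ = [
    "ExperimentConfig",
    "LearningCurve",
    "FiringStats",
    "CostMonitor",
    "cost_monitor_step",
    "firing_statistics",
    "run_single_neuron_task",
    "run_hidden_layer_task",
    "run_xor_task",
    "run_pattern_task",
    "run_task",
    "write_curve",
    "read_curve",
    "write_weights",
    "read_weights",
]

TASKS = ("single_neuron", "hidden_layer", "xor", "pattern_transform")


@dataclass
class ExperimentConfig:
    """One complete seeded description of a benchmark task."""

    task: str = "single_neuron"
    n_input: int = 100
    n_hidden: int = 0
    n_output: int = 1
    seed: int = 0

    # stimulus
    input_rate_Hz: float = 10.0
    trial_duration_ms: float = 500.0
    n_trials: int = 500
    target_spikes: int = 5
    # classification stream
    n_presentations: int = 400
    background_rate_Hz: float = 4.0
    isi_range_ms: tuple = (50.0, 200.0)
    jitter_window_ms: float = 10.0
    window_slack_ms: float = 15.0
    # pattern task
    pattern_duration_ms: float = 1000.0
    target_rate_Hz: float = 10.0
    train_duration_s: float = 200.0
    anneal_steps: int = 0  # number of x0.1 learning-rate reductions
    eval_trials: int = 1  # frozen (learning-off) trials appended after training

    # rule parameters
    feedback_mode: str = "symmetric"
    r0: float = 1e-3
    optimizer_mode: str = "rmaxprop"
    t_b_ms: float = 500.0
    beta_per_mV: float = 1.0
    rho: float = 0.0
    exponent_a: float = 2.0
    tau_avg_ms: float = 1000.0
    learn_hidden: bool = True
    linear_rule: bool = False
    w_init_scale: float = 0.02

    neuron: NeuronParams = field(default_factory=NeuronParams)
    kernel: KernelParams = field(default_factory=KernelParams)

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ConfigurationError(f"unknown task {self.task!r}")
        if min(self.n_input, self.n_output) < 1 or self.n_hidden < 0:
            raise ConfigurationError("population sizes must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "neuron" in d and isinstance(d["neuron"], dict):
            d["neuron"] = NeuronParams(**d["neuron"])
        if "kernel" in d and isinstance(d["kernel"], dict):
            d["kernel"] = KernelParams(**d["kernel"])
        if "isi_range_ms" in d:
            d["isi_range_ms"] = tuple(d["isi_range_ms"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class LearningCurve:
    """Smoothed RMS cost sampled over training time."""

    time_s: np.ndarray
    cost: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time_s) <= 0):
            raise ConfigurationError("time_s must be strictly increasing")
        if np.any(self.cost < 0):
            raise ConfigurationError("cost must be non-negative")

    @property
    def final_cost(self) -> float:
        return float(self.cost[-1])


@dataclass
class FiringStats:
    """Per-unit firing rates, pooled ISI distribution and per-unit CV of ISI."""

    rates_Hz: np.ndarray
    isis_ms: np.ndarray
    cv_isi: dict  # unit -> CV, only for units with >= 2 ISIs


class CostMonitor:
    """Online root-mean-square cost from a moving average (default 10 s)."""

    def __init__(self, tau_ms: float = 10_000.0, dt_ms: float = 0.1):
        self.decay = float(np.exp(-dt_ms / tau_ms))
        self.state = 0.0

    def step(self, squared_error: float) -> float:
        self.state = self.state * self.decay + (1.0 - self.decay) * squared_error
        return float(np.sqrt(self.state))

    @property
    def cost(self) -> float:
        return float(np.sqrt(self.state))


def cost_monitor_step(state: float, squared_error: float, dt_ms: float, tau_ms: float = 10_000.0):
    """Functional form of :class:`CostMonitor`: returns ``(state, rms_cost)``."""
    decay = np.exp(-dt_ms / tau_ms)
    state = state * decay + (1.0 - decay) * squared_error
    return state, float(np.sqrt(state))


def firing_statistics(raster: SpikeRaster, duration_ms: float | None = None) -> FiringStats:
    """Rates, interspike intervals and CV of ISI for every unit of a raster."""
    dur = raster.duration_ms if duration_ms is None else duration_ms
    if dur <= 0:
        raise ConfigurationError("duration must be > 0")
    rates = raster.counts() / (dur / 1000.0)
    isis, cv = [], {}
    for u in range(raster.n_units):
        t = raster.spikes_of(u)
        if t.size >= 2:
            d = np.diff(t)
            isis.append(d)
            if d.size >= 2:
                cv[u] = float(d.std() / d.mean())
    all_isis = np.concatenate(isis) if isis else np.zeros(0)
    return FiringStats(rates_Hz=rates, isis_ms=all_isis, cv_isi=cv)


# -- task construction helpers --------------------------------------------


def _build_network(cfg: ExperimentConfig, error_mode: str) -> Network:
    fb = FeedbackSpec.create(
        cfg.feedback_mode, max(cfg.n_hidden, 1), cfg.n_output, seed=cfg.seed + 101
    )
    return Network(
        n_in=cfg.n_input,
        n_hidden=cfg.n_hidden,
        n_out=cfg.n_output,
        params=cfg.neuron,
        kernel=cfg.kernel,
        surrogate=SurrogateParams(cfg.beta_per_mV),
        feedback=fb,
        optimizer=OptimizerParams(r0=cfg.r0, mode=cfg.optimizer_mode),
        regularizer=RegularizerParams(cfg.rho, cfg.exponent_a, cfg.tau_avg_ms),
        t_b_ms=cfg.t_b_ms,
        error_mode=error_mode,
        learn_hidden=cfg.learn_hidden,
        linear_rule=cfg.linear_rule,
        seed=cfg.seed,
    )


def _timing_task(cfg: ExperimentConfig) -> dict:
    """Shared driver for the precise-timing tasks (with or without hidden layer)."""
    p = cfg.neuron
    inp = frozen_poisson(cfg.n_input, cfg.trial_duration_ms, cfg.input_rate_Hz, seed=cfg.seed, dt_ms=p.dt_ms)
    tgt = equidistant_target(cfg.target_spikes, cfg.trial_duration_ms, dt_ms=p.dt_ms)
    dense_in = inp.to_dense(p.dt_ms)
    dense_tgt = tgt.to_dense(p.dt_ms)
    net = _build_network(cfg, "precise_timing")
    silent_uniform_init(net, dense_in, np.random.default_rng(cfg.seed + 7), cfg.w_init_scale)

    times, costs = [], []
    trial_s = cfg.trial_duration_ms / 1000.0
    spike_trials = []
    last = None
    boundaries = (
        {int(round(cfg.n_trials * (k + 1) / (cfg.anneal_steps + 1))) for k in range(cfg.anneal_steps)}
        if cfg.anneal_steps
        else set()
    )
    r0 = cfg.r0
    for trial in range(cfg.n_trials):
        if trial in boundaries:
            r0 *= 0.1
        res = net.run(dense_in, dense_tgt, learn=True, r0=r0)
        times.append((trial + 1) * trial_s)
        costs.append(float(np.sqrt(res["cost"][-1])))
        spike_trials.append(np.flatnonzero(res["output"][:, 0]) * p.dt_ms)
        last = res
    # frozen evaluation: learning off; with several trials the 10 s cost
    # average settles onto the deterministic final network's own error
    eval_res = None
    for _ in range(max(cfg.eval_trials, 1)):
        eval_res = net.run(dense_in, dense_tgt, learn=False)
    out_raster = SpikeRaster.from_dense(eval_res["output"], p.dt_ms, cfg.trial_duration_ms)
    hid_raster = (
        SpikeRaster.from_dense(eval_res["hidden"], p.dt_ms, cfg.trial_duration_ms)
        if cfg.n_hidden
        else None
    )
    return {
        "curve": LearningCurve(np.array(times), np.array(costs)),
        "frozen_cost": float(np.sqrt(eval_res["cost"][-1])),
        "output_raster": out_raster,
        "hidden_raster": hid_raster,
        "target": tgt,
        "input": inp,
        "per_trial_output_times": spike_trials,
        "network": net,
        "last": last,
    }


def run_single_neuron_task(cfg: ExperimentConfig) -> dict:
    """Train one output on frozen Poisson input against the equidistant target."""
    if cfg.task != "single_neuron":
        raise ConfigurationError("cfg.task must be 'single_neuron'")
    if cfg.n_hidden:
        raise ConfigurationError("single_neuron task has no hidden layer")
    return _timing_task(cfg)


def run_hidden_layer_task(cfg: ExperimentConfig) -> dict:
    """The same precise-timing task with a LIF hidden layer and feedback choice.

    The returned dict flags the known failure mode of random feedback: runs
    whose feedback coefficients are all negative.
    """
    if cfg.task != "hidden_layer":
        raise ConfigurationError("cfg.task must be 'hidden_layer'")
    if cfg.n_hidden < 1:
        raise ConfigurationError("hidden_layer task needs n_hidden >= 1")
    out = _timing_task(cfg)
    net: Network = out["network"]
    if net.feedback.mode == "random":
        out["all_negative_feedback"] = bool(np.all(net.feedback.B < 0))
    return out


def run_xor_task(cfg: ExperimentConfig, stop_on_perfect_streak: int = 0) -> dict:
    """Train on the jittered spiking XOR stream; returns the accuracy trace.

    A presentation counts as correct when the right readout spikes inside
    its response window and the wrong readout stays silent throughout it.
    With ``stop_on_perfect_streak = n > 0``, training stops as soon as the
    last ``n`` scored presentations were all correct.
    """
    if cfg.task != "xor":
        raise ConfigurationError("cfg.task must be 'xor'")
    if cfg.n_output != 2:
        raise ConfigurationError("xor task uses exactly two readout units")
    p = cfg.neuron
    pset = make_xor_patterns(cfg.n_input, cfg.jitter_window_ms, seed=cfg.seed, dt_ms=p.dt_ms)
    stream = build_stream(
        pset,
        cfg.n_presentations,
        background_rate_Hz=cfg.background_rate_Hz,
        isi_range_ms=cfg.isi_range_ms,
        window_slack_ms=cfg.window_slack_ms,
        seed=cfg.seed + 1,
        dt_ms=p.dt_ms,
    )
    dense = stream.raster.to_dense(p.dt_ms)
    net = _build_network(cfg, "classification")
    probe = dense[: min(dense.shape[0], int(5000 / p.dt_ms))]
    silent_uniform_init(net, probe, np.random.default_rng(cfg.seed + 7), cfg.w_init_scale)

    chunk = 50_000  # steps per engine call (5 s)
    n_steps = dense.shape[0]
    out_spk = np.zeros((n_steps, cfg.n_output), dtype=np.uint8)
    hid_spk = np.zeros((n_steps, max(cfg.n_hidden, 1)), dtype=np.uint8)
    costs, times = [], []
    done_steps = n_steps
    for s0 in range(0, n_steps, chunk):
        s1 = min(s0 + chunk, n_steps)
        wins = [
            (w0, w1, lab)
            for (w0, w1, lab) in stream.windows
            if w1 >= s0 * p.dt_ms and w0 < s1 * p.dt_ms
        ]
        res = net.run(dense[s0:s1], windows=wins, t0_ms=s0 * p.dt_ms, learn=True)
        out_spk[s0:s1] = res["output"]
        hid_spk[s0:s1] = res["hidden"]
        times.append(s1 * p.dt_ms / 1000.0)
        costs.append(float(np.sqrt(res["cost"][-1])))
        if stop_on_perfect_streak:
            scored = _score_windows(
                out_spk, stream, p.dt_ms, before_step=s1
            )
            if (
                scored.size >= stop_on_perfect_streak
                and scored[-stop_on_perfect_streak:].all()
            ):
                done_steps = s1
                break

    stream = _truncate_stream(stream, done_steps * p.dt_ms)
    out_spk = out_spk[:done_steps]
    hid_spk = hid_spk[:done_steps]
    correct = _score_windows(out_spk, stream, p.dt_ms)
    acc_trace = np.cumsum(correct) / (np.arange(correct.size) + 1)
    return {
        "curve": LearningCurve(np.array(times), np.array(costs)),
        "correct": correct,
        "accuracy_trace": acc_trace,
        "final_accuracy": float(correct[-100:].mean()) if correct.size >= 100 else float(correct.mean()),
        "perfect_tail": _longest_correct_tail(correct),
        "stream": stream,
        "output_spikes": out_spk,
        "hidden_spikes": hid_spk,
        "network": net,
    }


def _score_windows(
    out_spk: np.ndarray, stream: StimulusStream, dt_ms: float, before_step: int | None = None
) -> np.ndarray:
    """Score each completed response window (hit by the right unit, no wrong spike)."""
    lim = out_spk.shape[0] if before_step is None else before_step
    scores = []
    for w0, w1, lab in stream.windows:
        s0, s1 = int(round(w0 / dt_ms)), int(round(w1 / dt_ms))
        if s1 > lim:
            break
        seg = out_spk[s0:s1]
        scores.append(bool(seg[:, lab].any() and not seg[:, 1 - lab].any()))
    return np.array(scores, dtype=bool)


def _truncate_stream(stream: StimulusStream, t_ms: float) -> StimulusStream:
    keep = [k for k, (w0, w1, _) in enumerate(stream.windows) if w1 <= t_ms]
    return StimulusStream(
        stream.raster,
        tuple(stream.schedule[k] for k in keep),
        tuple(stream.labels[k] for k in keep),
        tuple(stream.windows[k] for k in keep),
        stream.background_rate_Hz,
        stream.window_slack_ms,
    )


def _longest_correct_tail(correct: np.ndarray) -> int:
    n = 0
    for c in correct[::-1]:
        if not c:
            break
        n += 1
    return n


def run_pattern_task(cfg: ExperimentConfig) -> dict:
    """Learn a long frozen-Poisson spatiotemporal target, cyclically repeated.

    Supports the staged learning-rate annealing (``anneal_steps`` reductions
    by 10x at equal fractions of the training budget) and the two controls:
    ``learn_hidden=False`` (fixed hidden weights) and ``linear_rule=True``
    (no voltage nonlinearity).  Returns the learning curve, hidden firing
    statistics and the final van Rossum-style smoothed cost.
    """
    if cfg.task != "pattern_transform":
        raise ConfigurationError("cfg.task must be 'pattern_transform'")
    p = cfg.neuron
    inp = frozen_poisson(cfg.n_input, cfg.pattern_duration_ms, cfg.input_rate_Hz, seed=cfg.seed, dt_ms=p.dt_ms)
    tgt = poisson_target_pattern(
        cfg.n_output, cfg.pattern_duration_ms, cfg.target_rate_Hz, seed=cfg.seed + 1, dt_ms=p.dt_ms
    )
    dense_in = inp.to_dense(p.dt_ms)
    dense_tgt = tgt.to_dense(p.dt_ms)
    net = _build_network(cfg, "precise_timing")
    silent_uniform_init(net, dense_in, np.random.default_rng(cfg.seed + 7), cfg.w_init_scale)

    n_cycles = int(round(cfg.train_duration_s * 1000.0 / cfg.pattern_duration_ms))
    cycle_s = cfg.pattern_duration_ms / 1000.0
    boundaries = (
        [int(round(n_cycles * (k + 1) / (cfg.anneal_steps + 1))) for k in range(cfg.anneal_steps)]
        if cfg.anneal_steps
        else []
    )
    r0 = cfg.r0
    times, costs = [], []
    last = None
    for cycle in range(n_cycles):
        if cycle in boundaries:
            r0 *= 0.1
        last = net.run(dense_in, dense_tgt, learn=True, r0=r0)
        times.append((cycle + 1) * cycle_s)
        costs.append(float(np.sqrt(last["cost"][-1])))
    eval_res = net.run(dense_in, dense_tgt, learn=False)
    hid_raster = SpikeRaster.from_dense(eval_res["hidden"], p.dt_ms, cfg.pattern_duration_ms)
    out_raster = SpikeRaster.from_dense(eval_res["output"], p.dt_ms, cfg.pattern_duration_ms)
    return {
        "curve": LearningCurve(np.array(times), np.array(costs)),
        "final_cost": float(np.sqrt(eval_res["cost"][-1])),
        "hidden_stats": firing_statistics(hid_raster),
        "output_raster": out_raster,
        "hidden_raster": hid_raster,
        "target": tgt,
        "network": net,
    }


def run_task(cfg: ExperimentConfig) -> dict:
    """Dispatch a configuration to its task runner."""
    return {
        "single_neuron": run_single_neuron_task,
        "hidden_layer": run_hidden_layer_task,
        "xor": run_xor_task,
        "pattern_transform": run_pattern_task,
    }[cfg.task](cfg)


# -- curve / weight I/O ----------------------------------------------------


def write_curve(curve: LearningCurve, path: str | Path) -> None:
    arr = np.column_stack([curve.time_s, curve.cost])
    np.savetxt(path, arr, delimiter=",", header="time_s,cost", comments="")


def read_curve(path: str | Path) -> LearningCurve:
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return LearningCurve(arr[:, 0], arr[:, 1])


def write_weights(path: str | Path, **matrices: np.ndarray) -> None:
    """Save weight matrices as whitespace text (one ``# name`` block each)."""
    with open(path, "w") as fh:
        for name, w in matrices.items():
            fh.write(f"# {name} {w.shape[0]} {w.shape[1]}\n")
            np.savetxt(fh, w)


def read_weights(path: str | Path) -> dict:
    out = {}
    name, rows = None, []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if name is not None:
                out[name] = np.array(rows)
            parts = line[1:].split()
            name, rows = parts[0], []
        elif line.strip():
            rows.append([float(x) for x in line.split()])
    if name is not None:
        out[name] = np.array(rows)
    return out
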