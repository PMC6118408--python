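"""Benchmark drivers: the four headline experiments with their measurements.

These functions run each experiment from scratch at the package's scaled
default conditions and return the quantities the experiments are judged by
(spike counts, timing errors, cost ratios, accuracies, firing rates).  The
base learning rate of the precise-timing task is grid-searched per run —
the protocol this rule prescribes — and final costs are measured on the
frozen network with learning switched off, so they reflect the trained
network rather than the tail of the training noise.

Both the acceptance script and the acceptance tests call these drivers;
everything is deterministic given the base seed.
"""

from __future__ import annotations

import numpy as np

from .experiments import ExperimentConfig, run_hidden_layer_task, run_pattern_task, run_single_neuron_task, run_xor_task
from .learning import FeedbackSpec

__all__ = [
    "single_neuron_benchmark",
    "multilayer_benchmark",
    "xor_benchmark",
    "pattern_benchmark",
    "regularizer_benchmark",
]

#: (r0, anneal_steps) candidates for the timing tasks' grid search
TIMING_GRID = ((1e-3, 0), (5e-4, 1), (2e-3, 0), (3e-4, 2), (1.5e-3, 1), (7e-4, 0))


def _timing_metrics(res) -> dict:
    out = res["output_raster"].times_ms
    tgt = res["target"].times_ms
    if out.size:
        timing_err = float(np.abs(out[:, None] - tgt[None, :]).min(axis=1).max())
    else:
        timing_err = float("inf")
    peak = float(res["curve"].cost.max())
    return {
        "n_spikes": int(out.size),
        "n_target": int(tgt.size),
        "max_timing_error_ms": timing_err,
        "cost_ratio": res["frozen_cost"] / peak if peak > 0 else 0.0,
        "peak_cost": peak,
        "frozen_cost": res["frozen_cost"],
    }


def single_neuron_benchmark(seed: int, n_trials: int = 500, grid=TIMING_GRID) -> dict:
    """Single-output precise-timing task with per-run r0 grid search.

    Runs the grid in order and keeps the configuration with the lowest
    frozen cost, stopping early once a run reproduces the target exactly
    enough (all five spikes within the grid tolerance and near-zero cost).
    """
    best = None
    for r0, anneal in grid:
        cfg = ExperimentConfig(
            task="single_neuron", seed=seed, n_trials=n_trials, r0=r0,
            anneal_steps=anneal, eval_trials=60,
        )
        m = _timing_metrics(run_single_neuron_task(cfg))
        m["r0"] = r0
        m["anneal_steps"] = anneal
        if best is None or m["frozen_cost"] < best["frozen_cost"]:
            best = m
        if (
            m["n_spikes"] == m["n_target"]
            and m["max_timing_error_ms"] <= 0.5
            and m["cost_ratio"] < 0.02
        ):
            break
    return best


def _mixed_sign_seeds(base: int, n_hidden: int, count: int) -> list[int]:
    """First ``count`` seeds >= base whose random feedback vector has mixed signs."""
    out, s = [], base
    while len(out) < count:
        B = FeedbackSpec.create("random", n_hidden, 1, seed=s + 101).B
        if not (B < 0).all():
            out.append(s)
        s += 1
    return out


def _all_negative_seed(base: int, n_hidden: int) -> int:
    s = base
    while True:
        B = FeedbackSpec.create("random", n_hidden, 1, seed=s + 101).B
        if (B < 0).all():
            return s
        s += 1


def multilayer_benchmark(seed: int, n_trials: int = 500) -> dict:
    """Hidden-layer timing task under symmetric and random feedback.

    Measures convergence for symmetric feedback (three seeds), for random
    feedback with mixed-sign coefficients (four seeds), and for the known
    failure mode where every feedback coefficient is negative (one seed,
    located by inspecting the fixed coefficients, which are drawn at
    initialization).  Also reports how often the all-negative configuration
    arises for 4 versus 8 hidden units across many coefficient draws.
    """

    def run(s, fb, nh=4):
        cfg = ExperimentConfig(
            task="hidden_layer", seed=s, n_hidden=nh, n_trials=n_trials,
            feedback_mode=fb, r0=1e-3, eval_trials=60,
        )
        return _timing_metrics(run_hidden_layer_task(cfg))

    sym = [run(seed + k, "symmetric") for k in range(3)]
    mixed_seeds = _mixed_sign_seeds(seed, 4, 4)
    mixed = [run(s, "random") for s in mixed_seeds]
    neg_seed = _all_negative_seed(seed, 4)
    negative = run(neg_seed, "random")

    draws = 400
    rng_base = seed + 101
    f4 = np.mean(
        [(FeedbackSpec.create("random", 4, 1, seed=rng_base + k).B < 0).all() for k in range(draws)]
    )
    f8 = np.mean(
        [(FeedbackSpec.create("random", 8, 1, seed=rng_base + k).B < 0).all() for k in range(draws)]
    )
    return {
        "symmetric": sym,
        "mixed": mixed,
        "all_negative": negative,
        "allneg_frequency_4_hidden": float(f4),
        "allneg_frequency_8_hidden": float(f8),
    }


def xor_benchmark(
    seed: int,
    hidden_seeds: int = 5,
    control_seeds: int = 5,
    n_presentations: int = 3000,
    control_presentations: int = 1000,
) -> dict:
    """Spiking XOR: hidden network vs the no-hidden-layer control.

    The hidden network (8 units, random feedback) trains until it has
    produced 100 consecutive correct responses (or the presentation budget
    runs out); the control trains for a fixed budget and its longest
    correct streak is recorded.
    """

    def longest(c: np.ndarray) -> int:
        best = cur = 0
        for x in c:
            cur = cur + 1 if x else 0
            best = max(best, cur)
        return best

    hidden = []
    for k in range(hidden_seeds):
        cfg = ExperimentConfig(
            task="xor", seed=seed + k, n_hidden=8, n_output=2,
            n_presentations=n_presentations, feedback_mode="random", r0=1e-3,
        )
        res = run_xor_task(cfg, stop_on_perfect_streak=100)
        c = res["correct"]
        hidden.append(
            {
                "longest_streak": longest(c),
                "final_accuracy": float(c[-100:].mean()) if c.size >= 100 else float(c.mean()),
                "presentations": int(c.size),
            }
        )
    control = []
    for k in range(control_seeds):
        cfg = ExperimentConfig(
            task="xor", seed=seed + k, n_hidden=0, n_output=2,
            n_presentations=control_presentations, feedback_mode="symmetric", r0=1e-3,
        )
        res = run_xor_task(cfg)
        c = res["correct"]
        control.append(
            {
                "longest_streak": longest(c),
                "final_accuracy": float(c[-100:].mean()),
            }
        )
    return {"hidden": hidden, "control": control}


def _pattern(seed, fb, nh, rho=0.0, a=2.0, dur=300.0, r0=3e-3):
    cfg = ExperimentConfig(
        task="pattern_transform", seed=seed, n_hidden=nh, n_output=20,
        train_duration_s=dur, feedback_mode=fb, r0=r0, anneal_steps=2,
        rho=rho, exponent_a=a,
    )
    res = run_pattern_task(cfg)
    return {
        "final_cost": res["final_cost"],
        "mean_hidden_rate_Hz": float(res["hidden_stats"].rates_Hz.mean()),
        "mean_cv_isi": float(np.mean(list(res["hidden_stats"].cv_isi.values())))
        if res["hidden_stats"].cv_isi
        else float("nan"),
    }


def pattern_benchmark(seed: int, reg_seeds: int = 3) -> dict:
    """Pattern transformation: feedback orderings, width scaling, regularizer.

    Width scaling uses symmetric feedback over 8/16/32 hidden units; the
    random-feedback and regularized-random comparisons are paired over
    ``reg_seeds`` base seeds because their margins are seed-noisy.
    """
    width = {nh: _pattern(seed, "symmetric", nh) for nh in (8, 16, 32)}
    random_runs = [_pattern(seed + k, "random", 32) for k in range(reg_seeds)]
    reg_runs = [_pattern(seed + k, "random", 32, rho=3e-3) for k in range(reg_seeds)]
    return {
        "symmetric_8": width[8],
        "symmetric_16": width[16],
        "symmetric_32": width[32],
        "random_32": random_runs,
        "random_32_regularized": reg_runs,
    }


def regularizer_benchmark(seed: int, pair_seeds: int = 2) -> dict:
    """Regularizer behaviour: rate suppression with rho, exponent comparison.

    Mean hidden rates are measured along a rho grid (exponent 2), and the
    activity-dependent exponent is compared with the activity-independent
    control (a = 0) at a matched strong rho, paired over seeds.
    """
    rho_grid = (0.0, 3e-4, 3e-3, 3e-2)
    rates = {rho: _pattern(seed, "random", 32, rho=rho)["mean_hidden_rate_Hz"] for rho in rho_grid}
    a2 = [_pattern(seed + k, "random", 32, rho=3e-2, a=2.0)["final_cost"] for k in range(pair_seeds)]
    a0 = [_pattern(seed + k, "random", 32, rho=3e-2, a=0.0)["final_cost"] for k in range(pair_seeds)]
    return {
        "rho_grid": rho_grid,
        "rates_by_rho": rates,
        "cost_activity_dependent": a2,
        "cost_activity_independent": a0,
    }
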