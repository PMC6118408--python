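"""Seeded generators for every stimulus and target used by the benchmark tasks.

All generators are pure functions of their parameters and seed: the same
call always returns the identical raster ("frozen" noise).  Spike times are
generated directly on the simulation grid (at most one spike per unit per
``dt`` cell), which is the natural clock-driven realization of a Poisson
process at these rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import ConfigurationError
from .raster import SpikeRaster

__all__ = [
    "frozen_poisson",
    "equidistant_target",
    "PatternSet",
    "make_xor_patterns",
    "StimulusStream",
    "build_stream",
    "poisson_target_pattern",
    "write_stream",
    "read_stream",
]


def frozen_poisson(
    n_units: int, duration_ms: float, rate_Hz: float, seed: int, dt_ms: float = 0.1
) -> SpikeRaster:
    """One fixed draw of independent Poisson spike trains.

    Each grid cell spikes independently with probability ``rate * dt``;
    repetition across trials is achieved by tiling the returned raster.
    """
    if rate_Hz < 0:
        raise ConfigurationError("rate_Hz must be >= 0")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration_ms / dt_ms))
    p = rate_Hz * dt_ms / 1000.0
    dense = rng.random((n_steps, n_units)) < p
    return SpikeRaster.from_dense(dense.astype(np.uint8), dt_ms, duration_ms)


def equidistant_target(n_spikes: int, duration_ms: float, dt_ms: float = 0.1) -> SpikeRaster:
    """A single-unit target of ``n_spikes`` equidistant spikes.

    Spikes are centred in their sub-intervals, at ``(k + 1/2) duration / n``,
    snapped to the grid — so neither the very first nor the very last grid
    cell ever holds a target spike.
    """
    if n_spikes < 1:
        raise ConfigurationError("n_spikes must be >= 1")
    if n_spikes * dt_ms > duration_ms:
        raise ConfigurationError("too many spikes for the duration at this dt")
    times = (np.arange(n_spikes) + 0.5) * duration_ms / n_spikes
    times = np.round(times / dt_ms) * dt_ms
    return SpikeRaster(times, np.zeros(n_spikes, dtype=np.int64), 1, duration_ms)


@dataclass(frozen=True)
class PatternSet:
    """Jittered spatiotemporal pattern classes for the spiking XOR task.

    The input population is split into three non-overlapping sets: a
    reference set present in every pattern (the time anchor) and two feature
    sets A and B.  Each member unit carries one fixed random firing offset
    inside the jitter window; the four patterns are {ref, ref+A, ref+B,
    ref+A+B} and the label is the parity of {A, B} presence — an exclusive-or
    whose effective dimension is two by construction.
    """

    patterns: tuple
    labels: tuple
    ref_ids: np.ndarray
    a_ids: np.ndarray
    b_ids: np.ndarray
    jitter_window_ms: float

    @property
    def n_units(self) -> int:
        return self.patterns[0].n_units

    @property
    def n_classes(self) -> int:
        return len(set(self.labels))


def make_xor_patterns(n_units: int, jitter_window_ms: float = 10.0, seed: int = 0, dt_ms: float = 0.1) -> PatternSet:
    if n_units < 3:
        raise ConfigurationError("need at least 3 input units")
    rng = np.random.default_rng(seed)
    ids = np.arange(n_units)
    third = n_units // 3
    ref_ids, a_ids, b_ids = ids[:third], ids[third : 2 * third], ids[2 * third :]
    if set(ref_ids) & set(a_ids) or set(ref_ids) & set(b_ids) or set(a_ids) & set(b_ids):
        raise AssertionError("unit sets overlap")  # internal error
    n_cells = max(int(round(jitter_window_ms / dt_ms)) - 1, 1)
    offsets = np.round(rng.integers(0, n_cells + 1, size=n_units) * dt_ms, 6)
    patterns, labels = [], []
    for has_a in (False, True):
        for has_b in (False, True):
            active = [ref_ids]
            if has_a:
                active.append(a_ids)
            if has_b:
                active.append(b_ids)
            act = np.concatenate(active)
            snippet = SpikeRaster(offsets[act], act.astype(np.int64), n_units, jitter_window_ms)
            patterns.append(snippet)
            labels.append((int(has_a) + int(has_b)) % 2)
    return PatternSet(tuple(patterns), tuple(labels), ref_ids, a_ids, b_ids, jitter_window_ms)


@dataclass(frozen=True)
class StimulusStream:
    """A pattern presentation stream with background activity and windows.

    ``schedule`` lists ``(onset_ms, pattern_id)`` with strictly increasing
    onsets; ``windows`` lists the response windows ``(t0_ms, t1_ms, label)``
    aligned to each presentation and outlasting the stimulus by
    ``window_slack_ms``.
    """

    raster: SpikeRaster
    schedule: tuple
    labels: tuple
    windows: tuple
    background_rate_Hz: float
    window_slack_ms: float


def build_stream(
    pset: PatternSet,
    n_presentations: int,
    background_rate_Hz: float = 4.0,
    isi_range_ms: tuple[float, float] = (50.0, 200.0),
    window_slack_ms: float = 15.0,
    seed: int = 0,
    dt_ms: float = 0.1,
) -> StimulusStream:
    """Random-order pattern presentations separated by stochastic background.

    Patterns appear in uniformly random order with uniform-random
    inter-stimulus gaps from ``isi_range_ms`` during which *all* input units
    fire Poisson background at ``background_rate_Hz``.
    """
    lo, hi = isi_range_ms
    if lo <= 0 or hi < lo:
        raise ConfigurationError("isi_range_ms must be positive with lo <= hi")
    rng = np.random.default_rng(seed)
    order = rng.integers(0, len(pset.patterns), size=n_presentations)
    gaps = rng.uniform(lo, hi, size=n_presentations + 1)
    bout = pset.jitter_window_ms
    onsets = np.round((np.cumsum(gaps[:-1] + bout) - bout) / dt_ms) * dt_ms
    duration = float(np.round((onsets[-1] + bout + gaps[-1]) / dt_ms) * dt_ms)

    n_steps = int(round(duration / dt_ms))
    n_units = pset.n_units
    dense = np.zeros((n_steps, n_units), dtype=np.uint8)
    # background only between bouts
    p_bg = background_rate_Hz * dt_ms / 1000.0
    in_bout = np.zeros(n_steps, dtype=bool)
    bout_steps = int(round(bout / dt_ms))
    for onset in onsets:
        s0 = int(round(onset / dt_ms))
        in_bout[s0 : s0 + bout_steps] = True
    bg = rng.random((n_steps, n_units)) < p_bg
    bg[in_bout] = False
    dense |= bg.astype(np.uint8)
    schedule, labels, windows = [], [], []
    for onset, pid in zip(onsets, order):
        snippet = pset.patterns[pid].to_dense(dt_ms)
        s0 = int(round(onset / dt_ms))
        dense[s0 : s0 + snippet.shape[0]] |= snippet.astype(bool)
        schedule.append((float(onset), int(pid)))
        labels.append(pset.labels[pid])
        windows.append((float(onset), float(onset + bout + window_slack_ms), int(pset.labels[pid])))
    raster = SpikeRaster.from_dense(dense, dt_ms, duration)
    return StimulusStream(
        raster, tuple(schedule), tuple(labels), tuple(windows), background_rate_Hz, window_slack_ms
    )


def poisson_target_pattern(
    n_units: int, duration_ms: float, rate_Hz: float, seed: int, dt_ms: float = 0.1
) -> SpikeRaster:
    """A frozen Poisson target raster for the pattern-transformation task.

    Identical semantics to :func:`frozen_poisson`; cyclically tiled during
    training so the network learns a repeating spatiotemporal output.
    """
    return frozen_poisson(n_units, duration_ms, rate_Hz, seed, dt_ms)


# -- stream sidecar I/O ----------------------------------------------------


def write_stream(stream: StimulusStream, ras_path: str | Path, json_path: str | Path) -> None:
    from .raster import write_ras

    write_ras(stream.raster, ras_path)
    meta = {
        "n_units": stream.raster.n_units,
        "duration_ms": stream.raster.duration_ms,
        "schedule": [list(s) for s in stream.schedule],
        "labels": list(stream.labels),
        "windows": [list(w) for w in stream.windows],
        "background_rate_Hz": stream.background_rate_Hz,
        "window_slack_ms": stream.window_slack_ms,
    }
    Path(json_path).write_text(json.dumps(meta, indent=1))


def read_stream(ras_path: str | Path, json_path: str | Path) -> StimulusStream:
    from .raster import read_ras

    meta = json.loads(Path(json_path).read_text())
    raster = read_ras(ras_path, meta["n_units"], meta["duration_ms"])
    return StimulusStream(
        raster,
        tuple((float(t), int(p)) for t, p in meta["schedule"]),
        tuple(int(x) for x in meta["labels"]),
        tuple((float(a), float(b), int(c)) for a, b, c in meta["windows"]),
        meta["background_rate_Hz"],
        meta["window_slack_ms"],
    )
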