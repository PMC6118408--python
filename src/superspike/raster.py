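"""Spike rasters: timestamped spike events for a neuron population.

A :class:`SpikeRaster` is the universal currency of the package — inputs,
hidden/output activity and supervision targets are all rasters.  Events are
kept sorted by ``(time, unit)`` and are aligned to the simulation grid only
when converted to a dense representation.

The on-disk text format is the whitespace-separated RAS dialect used by
several spiking-network simulators: one event per line, ``time_seconds
unit_id``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["SpikeRaster", "read_ras", "write_ras", "read_hdf5", "write_hdf5"]


class RasterError(ValueError):
    """Raised for malformed raster data or files."""


@dataclass(frozen=True)
class SpikeRaster:
    """An ordered list of spike events ``(time_ms, unit_id)`` for a population.

    Parameters
    ----------
    times_ms:
        Event times in milliseconds, sorted ascending; ties broken by unit id.
    units:
        Integer unit ids, same length as ``times_ms``.
    n_units:
        Number of units in the population (ids range over ``[0, n_units)``).
    duration_ms:
        Length of the observation window; all events satisfy
        ``0 <= t < duration_ms``.
    """

    times_ms: np.ndarray
    units: np.ndarray
    n_units: int
    duration_ms: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=np.float64)
        u = np.asarray(self.units, dtype=np.int64)
        if t.shape != u.shape or t.ndim != 1:
            raise RasterError("times and units must be 1-d arrays of equal length")
        if self.n_units < 1:
            raise RasterError("n_units must be >= 1")
        if self.duration_ms <= 0:
            raise RasterError("duration_ms must be > 0")
        order = np.lexsort((u, t))
        t, u = t[order], u[order]
        if t.size:
            if t[0] < 0 or t[-1] >= self.duration_ms:
                raise RasterError("event times must lie in [0, duration_ms)")
            if u.min() < 0 or u.max() >= self.n_units:
                raise RasterError("unit ids must lie in [0, n_units)")
            dup = (np.diff(t) == 0) & (np.diff(u) == 0)
            if dup.any():
                raise RasterError("duplicate (time, unit) events")
        object.__setattr__(self, "times_ms", t)
        object.__setattr__(self, "units", u)

    # -- constructors -----------------------------------------------------

    @classmethod
    def empty(cls, n_units: int, duration_ms: float) -> "SpikeRaster":
        z = np.zeros(0)
        return cls(z, z.astype(np.int64), n_units, duration_ms)

    @classmethod
    def from_events(cls, events, n_units: int, duration_ms: float) -> "SpikeRaster":
        """Build from an iterable of ``(time_ms, unit_id)`` pairs."""
        ev = list(events)
        if not ev:
            return cls.empty(n_units, duration_ms)
        t = np.array([e[0] for e in ev], dtype=np.float64)
        u = np.array([e[1] for e in ev], dtype=np.int64)
        return cls(t, u, n_units, duration_ms)

    @classmethod
    def from_dense(cls, dense: np.ndarray, dt_ms: float, duration_ms: float | None = None) -> "SpikeRaster":
        """Inverse of :meth:`to_dense` (one event per nonzero grid cell)."""
        steps, units = np.nonzero(dense)
        dur = duration_ms if duration_ms is not None else dense.shape[0] * dt_ms
        return cls(steps * dt_ms, units.astype(np.int64), dense.shape[1], dur)

    # -- views ------------------------------------------------------------

    @property
    def n_events(self) -> int:
        return int(self.times_ms.size)

    def to_dense(self, dt_ms: float) -> np.ndarray:
        """Bin events onto the simulation grid.

        Returns a ``(n_steps, n_units)`` uint8 array of per-cell spike counts;
        an event at time ``t`` lands in step ``floor(t / dt)``.
        """
        n_steps = int(round(self.duration_ms / dt_ms))
        dense = np.zeros((n_steps, self.n_units), dtype=np.uint8)
        if self.n_events:
            steps = np.floor(self.times_ms / dt_ms + 1e-9).astype(np.int64)
            steps = np.minimum(steps, n_steps - 1)
            np.add.at(dense, (steps, self.units), 1)
        return dense

    def spikes_of(self, unit: int) -> np.ndarray:
        return self.times_ms[self.units == unit]

    def counts(self) -> np.ndarray:
        """Spike count per unit."""
        return np.bincount(self.units, minlength=self.n_units)

    def tile(self, n_repeats: int) -> "SpikeRaster":
        """Repeat the raster cyclically ``n_repeats`` times."""
        if n_repeats < 1:
            raise RasterError("n_repeats must be >= 1")
        t = np.concatenate([self.times_ms + k * self.duration_ms for k in range(n_repeats)])
        u = np.tile(self.units, n_repeats)
        return SpikeRaster(t, u, self.n_units, self.duration_ms * n_repeats)

    def shift(self, offset_ms: float, duration_ms: float) -> "SpikeRaster":
        """Place this raster at ``offset_ms`` inside a longer window."""
        return SpikeRaster(self.times_ms + offset_ms, self.units, self.n_units, duration_ms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeRaster):
            return NotImplemented
        return (
            self.n_units == other.n_units
            and self.duration_ms == other.duration_ms
            and np.array_equal(self.times_ms, other.times_ms)
            and np.array_equal(self.units, other.units)
        )


# -- text / HDF5 I/O -------------------------------------------------------


def write_ras(raster: SpikeRaster, path: str | Path) -> None:
    """Write a raster as RAS text: one ``time_seconds unit_id`` per line."""
    with open(path, "w") as fh:
        for t, u in zip(raster.times_ms, raster.units):
            fh.write(f"{t / 1000.0:.6f} {int(u)}\n")


def read_ras(path: str | Path, n_units: int, duration_ms: float) -> SpikeRaster:
    """Read a RAS text file.  Malformed lines raise with the line number."""
    times, units = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                t_s = float(parts[0])
                u = int(parts[1])
            except (IndexError, ValueError) as exc:
                raise RasterError(f"{path}:{lineno}: malformed RAS line {line!r}") from exc
            if not 0 <= u < n_units:
                raise RasterError(f"{path}:{lineno}: unit id {u} out of range [0, {n_units})")
            times.append(t_s * 1000.0)
            units.append(u)
    return SpikeRaster(np.array(times), np.array(units, dtype=np.int64), n_units, duration_ms)


def write_hdf5(raster: SpikeRaster, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("times_ms", data=raster.times_ms)
        fh.create_dataset("units", data=raster.units)
        fh.attrs["n_units"] = raster.n_units
        fh.attrs["duration_ms"] = raster.duration_ms


def read_hdf5(path: str | Path) -> SpikeRaster:
    import h5py

    with h5py.File(path, "r") as fh:
        return SpikeRaster(
            fh["times_ms"][:],
            fh["units"][:],
            int(fh.attrs["n_units"]),
            float(fh.attrs["duration_ms"]),
        )
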