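"""Per-parameter learning-rate schedules: fixed, RMSprop, and RMaxProp.

RMaxProp keeps, per synapse, an *upper* estimate of the non-centred second
moment of the chunked gradient, ``v <- max(gamma v, m^2)``, instead of
RMSprop's moving average ``v <- gamma v + (1 - gamma) m^2``.  The per
parameter rate is ``r0 / (sqrt(v) + eps)``, which makes training far less
sensitive to the choice of ``r0`` than a fixed global rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigurationError

__all__ = ["OptimizerParams", "second_moment_step", "per_param_rate", "gamma_from_timescale", "r0_grid"]


def gamma_from_timescale(t_b_s: float = 0.5, tau_gamma_s: float = 10.0) -> float:
    """Decay factor giving the second-moment estimate a characteristic timescale.

    One chunk of length ``t_b`` multiplies ``v`` by ``gamma``; choosing
    ``gamma = exp(-t_b / tau_gamma)`` makes the forgetting timescale
    ``tau_gamma`` explicit (default 10 s).
    """
    return float(np.exp(-t_b_s / tau_gamma_s))


@dataclass(frozen=True)
class OptimizerParams:
    r0: float = 1e-3
    gamma: float = gamma_from_timescale()
    epsilon: float = 1e-8
    mode: str = "rmaxprop"

    MODES = ("fixed", "rmsprop", "rmaxprop")

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ConfigurationError("r0 must be > 0")
        if not 0 < self.gamma < 1:
            raise ConfigurationError("gamma must be in (0, 1)")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be > 0")
        if self.mode not in self.MODES:
            raise ConfigurationError(f"unknown optimizer mode {self.mode!r}")


def second_moment_step(v: np.ndarray, m_chunk: np.ndarray, p: OptimizerParams) -> np.ndarray:
    """Update the second-moment estimate from one chunk's accumulated gradient."""
    if p.mode == "rmaxprop":
        return np.maximum(p.gamma * v, m_chunk * m_chunk)
    if p.mode == "rmsprop":
        return p.gamma * v + (1.0 - p.gamma) * m_chunk * m_chunk
    return v


def per_param_rate(v: np.ndarray, p: OptimizerParams):
    """Per-synapse learning rate: ``r0`` (fixed) or ``r0 / (sqrt(v) + eps)``."""
    if p.mode == "fixed":
        return p.r0
    return p.r0 / (np.sqrt(v) + p.epsilon)


def r0_grid(n_per_decade: int = 2, lo: float = 1e-4, hi: float = 1e-1) -> np.ndarray:
    """Log-spaced base-rate grid for the grid-search procedure."""
    n = int(round(np.log10(hi / lo) * n_per_decade)) + 1
    return np.logspace(np.log10(lo), np.log10(hi), n)
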