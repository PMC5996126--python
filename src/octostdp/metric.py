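"""Delay-compensation quality metric η.

A synapse compensates the traveling-wave delay when its total delay —
cochlear traveling-wave delay t_TW plus dendritic delay t_D — equals the
target T (0.5 ms, the dendritic transmission time).  η scores a weight
configuration by a weight-normalized sum of Gaussians:

    η = Σ_n W_n · exp(−(T − t_TW,n − t_D,n)² / 2σ²) / Σ_n W_n

σ (70 µs) sets how sharply mistimed synapses are penalized.  η ∈ [0, 1]:
1 means all synaptic weight sits on perfectly compensating synapses, and the
normalization makes η invariant to uniform rescaling of the weights, so
configurations with different total drive are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell import SynapsePopulation

__all__ = ["MetricParams", "UndefinedMetricError", "eta"]


@dataclass(frozen=True)
class MetricParams:
    t_target: float = 0.5e-3  # target total delay T (s)
    sigma: float = 70e-6      # Gaussian penalty width (s)

    def __post_init__(self):
        if self.t_target <= 0 or self.sigma <= 0:
            raise ValueError("t_target and sigma must be strictly positive")


class UndefinedMetricError(ValueError):
    """η is 0/0 when every weight is zero; callers must handle this case."""


def eta(
    synapses: SynapsePopulation,
    fiber_delays: np.ndarray,
    params: MetricParams = MetricParams(),
) -> float:
    """Weight-normalized Gaussian compensation score of a synapse population.

    ``fiber_delays`` is the per-fiber traveling-wave delay array (s), indexed
    by the synapses' fiber indices.

    Raises :class:`UndefinedMetricError` if all weights are zero.
    """
    fiber_delays = np.asarray(fiber_delays, dtype=float)
    if synapses.fiber_index.max() >= fiber_delays.size:
        raise ValueError(
            f"synapses reference fiber {int(synapses.fiber_index.max())} but only "
            f"{fiber_delays.size} fiber delays were given"
        )
    w = synapses.weight
    w_sum = w.sum()
    if w_sum <= 0.0:
        raise UndefinedMetricError(
            "eta is undefined (0/0) when all synaptic weights are zero"
        )
    total_delay = fiber_delays[synapses.fiber_index] + synapses.t_dendritic
    mismatch = params.t_target - total_delay
    score = np.exp(-(mismatch**2) / (2.0 * params.sigma**2))
    return float(np.dot(w, score) / w_sum)
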