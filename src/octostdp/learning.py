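"""The learning loop: epochs of stimulation, simulation, and weight updates.

One learning run is a sequence of independent 50 ms epochs.  Each epoch:

1. a fresh click-evoked raster is drawn (new spike realization, same fiber
   population),
2. the octopus cell integrates it with the current weights,
3. the STDP + homeostasis update is computed from that epoch's somatic
   arrivals and output spikes and applied once, with clipping to [0, W_max].

Weights start at zero, so the first epochs are silent and purely homeostatic;
once the cell begins to spike, STDP differentiates the synapses.  The run is
a pure function of (population, stimulus, parameters, seeds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell import CellParams, SynapsePopulation, assign_synapses, run_epoch
from .frontend import ClickStimulus, FiberPopulation, generate_raster
from .metric import MetricParams, UndefinedMetricError, eta
from .plasticity import EpochPairing, PlasticityParams, apply_epoch_update

__all__ = ["LearningResult", "derive_seed", "simulate_learning"]

_SEED_MOD = 2**31  # keep derived seeds in signed-32-bit range


def derive_seed(*entropy: int) -> int:
    """Derive a deterministic child seed (< 2^31) from a tuple of integers."""
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % _SEED_MOD)


@dataclass
class LearningResult:
    """Output of one learning run.

    ``log`` has one row per epoch with columns
    ``epoch,n_post,max_dvdt_v_per_s,eta,mean_w,min_w,max_w`` (η is NaN while
    all weights are zero).  ``snapshots[e]`` is the weight vector after epoch
    e's update when snapshot recording is on.
    """

    population: FiberPopulation
    synapses: SynapsePopulation
    log: pd.DataFrame
    snapshots: list = field(default_factory=list)

    @property
    def final_eta(self) -> float:
        return float(self.log["eta"].iloc[-1])

    @property
    def all_silent(self) -> bool:
        """True if the weights never left zero (η undefined throughout)."""
        return bool(np.isnan(self.log["eta"].iloc[-1]))


def _safe_eta(synapses, population, metric_params):
    try:
        return eta(synapses, population.t_tw, metric_params)
    except UndefinedMetricError:
        return float("nan")


def simulate_learning(
    population: FiberPopulation,
    stimulus: ClickStimulus,
    cell_params: CellParams,
    plasticity_params: PlasticityParams,
    metric_params: MetricParams = MetricParams(),
    n_epochs: int = 10,
    synapses_per_fiber: int = 3,
    max_dendritic_delay: float = 0.5e-3,
    placement_seed: int = 0,
    raster_seed: int = 1,
    synapses: SynapsePopulation | None = None,
    record_snapshots: bool = False,
) -> LearningResult:
    """Run ``n_epochs`` of stimulation + plasticity and return the history.

    A fresh random synapse placement is drawn from ``placement_seed`` unless
    an explicit ``synapses`` population is supplied; epoch e's raster seed is
    derived deterministically from ``(raster_seed, e)``.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be at least 1")
    if synapses is None:
        synapses = assign_synapses(
            n_fibers=population.n_fibers,
            synapses_per_fiber=synapses_per_fiber,
            max_dendritic_delay=max_dendritic_delay,
            seed=placement_seed,
            w_max=plasticity_params.w_max,
        )
    rows = []
    snapshots: list[np.ndarray] = []
    for epoch in range(n_epochs):
        raster = generate_raster(
            population, stimulus, seed=derive_seed(raster_seed, epoch)
        )
        trace = run_epoch(cell_params, synapses, raster)
        pairing = EpochPairing(
            pre_times=trace.arrival_times, post_times=trace.spike_times
        )
        synapses = apply_epoch_update(synapses, pairing, plasticity_params)
        rows.append({
            "epoch": epoch,
            "n_post": trace.n_spikes,
            "max_dvdt_v_per_s": trace.max_dvdt,
            "eta": _safe_eta(synapses, population, metric_params),
            "mean_w": float(synapses.weight.mean()),
            "min_w": float(synapses.weight.min()),
            "max_w": float(synapses.weight.max()),
        })
        if record_snapshots:
            snapshots.append(synapses.weight.copy())
    return LearningResult(
        population=population,
        synapses=synapses,
        log=pd.DataFrame(rows),
        snapshots=snapshots,
    )
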