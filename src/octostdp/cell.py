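"""Single-compartment octopus-cell model.

The cell is a conductance-based leaky integrate-and-fire unit with one twist
that defines octopus-cell physiology: the spike is initiated not when the
membrane potential V crosses a voltage threshold, but when its *rate of
change* dV/dt exceeds a rate threshold κ (10 mV/ms) over one time step.  With
a very leaky membrane (τ_m = C_m/g_leak ≈ 0.3 ms) this makes the cell a
coincidence detector: only a steep, synchronous barrage of EPSPs can move V
fast enough to fire it.

Membrane dynamics:

    C_m dV/dt = g_leak (V_L − V) + g_ex (E_ex − V)
    τ_ex dg_ex/dt = −g_ex

g_ex is incremented by W_j · g_unit when a spike from synapse j's fiber
*arrives at the soma*, i.e. the fiber spike time plus that synapse's dendritic
delay t_D — the dendrite is a pure delay line.  After a spike, V resets to
V_L and spike initiation is suppressed for an absolute refractory period.

Numerics: forward Euler for V at dt = 10 µs; the stiff conductance decay uses
the exact per-step factor exp(−dt/τ_ex).  dV/dt is the one-step backward
difference evaluated after each update.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .frontend import SpikeRaster

__all__ = [
    "CellParams",
    "SynapsePopulation",
    "CellTrace",
    "assign_synapses",
    "quantize_to_grid",
    "somatic_arrival_times",
    "run_epoch",
    "write_trace",
    "write_spikes",
]


@dataclass(frozen=True)
class CellParams:
    """Biophysical constants, SI units throughout.

    ``tau_ex`` is the one constant without a published value; the default
    0.3 ms matches the membrane time constant scale and is echoed in all run
    logs so it can be audited and overridden.
    """

    c_m: float = 43e-12          # membrane capacitance (F)
    g_leak: float = 143e-9       # leak conductance (S); 7 MΩ input resistance
    v_leak: float = -65e-3       # leak reversal potential (V)
    e_ex: float = 0.0            # excitatory reversal potential (V)
    kappa: float = 10.0          # dV/dt spike threshold (V/s) = 10 mV/ms
    tau_ex: float = 0.3e-3       # synaptic conductance decay (s)
    g_unit: float = 1e-9         # conductance increment per unit weight (S)
    t_refractory: float = 1.1e-3  # absolute refractory period (s)
    dt: float = 10e-6            # integration step (s)

    def __post_init__(self):
        for name in ("c_m", "g_leak", "tau_ex", "g_unit", "dt", "kappa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.t_refractory < self.dt:
            raise ValueError("t_refractory must be at least one time step")

    @property
    def tau_membrane(self) -> float:
        return self.c_m / self.g_leak


@dataclass(frozen=True)
class SynapsePopulation:
    """Per-synapse source fiber, dendritic delay and weight.

    Weights are dimensionless; each unit of weight contributes ``g_unit`` of
    conductance per presynaptic spike.  ``w_max`` records the ceiling the
    weights are supposed to respect (enforced by the plasticity update).
    """

    fiber_index: np.ndarray
    t_dendritic: np.ndarray
    weight: np.ndarray
    max_dendritic_delay: float = 0.5e-3
    w_max: float | None = None

    def __post_init__(self):
        fi = np.asarray(self.fiber_index, dtype=np.int64)
        td = np.asarray(self.t_dendritic, dtype=float)
        w = np.asarray(self.weight, dtype=float)
        object.__setattr__(self, "fiber_index", fi)
        object.__setattr__(self, "t_dendritic", td)
        object.__setattr__(self, "weight", w)
        if not (fi.shape == td.shape == w.shape) or fi.ndim != 1:
            raise ValueError("fiber_index, t_dendritic, weight must be equal-length 1-D")
        if fi.size == 0:
            raise ValueError("need at least one synapse")
        if fi.min() < 0:
            raise ValueError("fiber indices must be non-negative")
        if td.min() < 0 or td.max() > self.max_dendritic_delay:
            raise ValueError(
                f"dendritic delays must lie in [0, {self.max_dendritic_delay}]"
            )
        if w.min() < 0:
            raise ValueError("weights must be non-negative")
        if self.w_max is not None and w.max() > self.w_max:
            raise ValueError(f"weights exceed w_max = {self.w_max}")

    @property
    def n_synapses(self) -> int:
        return self.fiber_index.size

    def with_weights(self, weight: np.ndarray) -> "SynapsePopulation":
        return replace(self, weight=np.asarray(weight, dtype=float))


def assign_synapses(
    n_fibers: int = 400,
    synapses_per_fiber: int = 3,
    max_dendritic_delay: float = 0.5e-3,
    seed: int = 0,
    w_max: float | None = None,
) -> SynapsePopulation:
    """Place ``synapses_per_fiber`` synapses per fiber at random dendritic
    locations (delays uniform on [0, max_dendritic_delay]); weights start at 0.

    The default 400 × 3 = 1200 synapses is the standard connectivity.
    """
    if n_fibers < 1 or synapses_per_fiber < 1:
        raise ValueError("counts must be positive")
    if max_dendritic_delay <= 0:
        raise ValueError("max_dendritic_delay must be positive")
    rng = np.random.default_rng(int(seed))
    n = n_fibers * synapses_per_fiber
    return SynapsePopulation(
        fiber_index=np.repeat(np.arange(n_fibers), synapses_per_fiber),
        t_dendritic=rng.uniform(0.0, max_dendritic_delay, n),
        weight=np.zeros(n),
        max_dendritic_delay=max_dendritic_delay,
        w_max=w_max,
    )


def quantize_to_grid(t, dt: float):
    """Snap times to the nearest dt grid point; half-step ties round earlier."""
    return np.ceil(np.asarray(t, dtype=float) / dt - 0.5) * dt


def somatic_arrival_times(
    raster: SpikeRaster,
    synapses: SynapsePopulation,
    dt: float = 10e-6,
) -> list[np.ndarray]:
    """Per-synapse somatic arrival times: fiber spike + dendritic delay,
    quantized to the integration grid.

    These arrival times are what both the conductance increments and the
    plasticity rule's t_pre refer to.
    """
    if synapses.fiber_index.max() >= raster.n_fibers:
        raise ValueError(
            f"synapses reference fiber {int(synapses.fiber_index.max())} but the "
            f"raster has only {raster.n_fibers} fibers"
        )
    by_fiber = raster.events_by_fiber()
    out = []
    for f, td in zip(synapses.fiber_index, synapses.t_dendritic):
        out.append(quantize_to_grid(by_fiber[f] + td, dt))
    return out


@dataclass(frozen=True)
class CellTrace:
    """Simulated state of one epoch on the integration grid.

    ``time[i] = i*dt`` for i = 0..n_steps; V, g_ex, dV/dt have one entry per
    grid point.  ``arrival_times`` are the per-synapse somatic arrivals used,
    exposed so the plasticity rule pairs against exactly the same times.
    """

    time: np.ndarray
    v: np.ndarray
    g_ex: np.ndarray
    dvdt: np.ndarray
    spike_times: np.ndarray
    arrival_times: list[np.ndarray]

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    @property
    def max_dvdt(self) -> float:
        return float(self.dvdt.max()) if self.dvdt.size else 0.0


@njit(cache=False)
def _integrate(g_inc, dt, c_m, g_leak, v_leak, e_ex, kappa, decay, refrac_steps,
               v_init):
    n = g_inc.shape[0] - 1  # number of steps; state indices 0..n
    v = np.empty(n + 1)
    g = np.empty(n + 1)
    dvdt = np.empty(n + 1)
    v[0] = v_init
    g[0] = g_inc[0]
    dvdt[0] = 0.0
    spikes = np.empty(n // (refrac_steps + 1) + 1, np.int64)
    n_spikes = 0
    last_spike = -(refrac_steps + 1)
    for i in range(1, n + 1):
        gi = g[i - 1] * decay + g_inc[i]
        vi = v[i - 1] + dt * (g_leak * (v_leak - v[i - 1]) + gi * (e_ex - v[i - 1])) / c_m
        if not np.isfinite(vi):
            return v, g, dvdt, spikes[:n_spikes], i  # abort with step index
        d = (vi - v[i - 1]) / dt
        if d > kappa and (i - last_spike) > refrac_steps:
            spikes[n_spikes] = i
            n_spikes += 1
            last_spike = i
            vi = v_leak
        v[i] = vi
        g[i] = gi
        dvdt[i] = d
    return v, g, dvdt, spikes[:n_spikes], -1


def run_epoch(
    params: CellParams,
    synapses: SynapsePopulation,
    raster: SpikeRaster,
    v_init: float | None = None,
) -> CellTrace:
    """Integrate one epoch of input and return the full state trace.

    Spike rule: when the one-step backward difference (V_new − V_old)/dt
    exceeds κ and the cell is past its refractory period, a spike is recorded
    at that step and V resets to V_L.  During the refractory period V and
    g_ex keep evolving; only the threshold test is suppressed, resuming at
    the first step after the period has fully elapsed.

    ``v_init`` overrides the initial membrane potential (default V_L), which
    is how a passive-relaxation experiment is set up.
    """
    dt = params.dt
    n_steps = int(round(raster.duration / dt))
    if n_steps < 1:
        raise ValueError("raster duration shorter than one time step")
    arrivals = somatic_arrival_times(raster, synapses, dt)

    g_inc = np.zeros(n_steps + 1)
    idx_parts = []
    w_parts = []
    for j, arr in enumerate(arrivals):
        if arr.size:
            idx_parts.append(np.rint(arr / dt).astype(np.int64))
            w_parts.append(np.full(arr.size, synapses.weight[j] * params.g_unit))
    if idx_parts:
        idx = np.concatenate(idx_parts)
        if idx.max() > n_steps:
            raise ValueError("somatic arrival falls beyond the epoch grid")
        np.add.at(g_inc, idx, np.concatenate(w_parts))

    decay = float(np.exp(-dt / params.tau_ex))
    refrac_steps = int(round(params.t_refractory / dt))
    v, g, dvdt, spike_steps, bad_step = _integrate(
        g_inc, dt, params.c_m, params.g_leak, params.v_leak, params.e_ex,
        params.kappa, decay, refrac_steps,
        params.v_leak if v_init is None else float(v_init),
    )
    if bad_step >= 0:
        raise FloatingPointError(
            f"non-finite membrane state at step {bad_step} (t = {bad_step * dt} s)"
        )
    return CellTrace(
        time=np.arange(n_steps + 1) * dt,
        v=v,
        g_ex=g,
        dvdt=dvdt,
        spike_times=spike_steps * dt,
        arrival_times=arrivals,
    )


def write_trace(trace: CellTrace, path) -> None:
    """Export the state trace as CSV ``time_s,V_v,gex_s,dvdt_v_per_s``."""
    import pandas as pd

    pd.DataFrame({
        "time_s": trace.time,
        "V_v": trace.v,
        "gex_s": trace.g_ex,
        "dvdt_v_per_s": trace.dvdt,
    }).to_csv(path, index=False, float_format="%.12g")


def write_spikes(trace: CellTrace, path) -> None:
    """Export output spike times as CSV ``spike_time_s``."""
    import pandas as pd

    pd.DataFrame({"spike_time_s": trace.spike_times}).to_csv(
        path, index=False, float_format="%.12g"
    )
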