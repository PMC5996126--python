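"""Epoch-batched synaptic plasticity: all-to-all pair STDP plus homeostasis.

Two rules cooperate to select delay-compensating synapses:

* **STDP** (per synapse): every (presynaptic somatic arrival, postsynaptic
  spike) pair within the epoch contributes an additive weight change.  With
  Δt = t_pre − t_post,

      ΔW = +Δw̄₊ · exp(−|Δt|/τ₊)   if Δt < 0   (pre leads: potentiation)
      ΔW = −Δw̄₋ · exp(−|Δt|/τ₋)   if Δt > 0   (pre lags:  depression)
      ΔW = 0                        if Δt = 0

  t_pre is the *somatic arrival* time (fiber spike + dendritic delay), so the
  rule sees each synapse through its own delay line — this is what lets it
  select synapses whose total delay matches the target.

* **Homeostasis** (uniform across synapses): if the cell fired fewer than R
  spikes in the epoch every weight rises by δ₊, if more, every weight falls
  by δ₋.  Starting from all-zero weights this is what bootstraps activity so
  STDP has postsynaptic spikes to work with.

Updates are accumulated over one 50 ms epoch, applied once at epoch end, and
clipped to [0, W_max].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell import SynapsePopulation

__all__ = [
    "PlasticityParams",
    "EpochPairing",
    "stdp_delta",
    "stdp_epoch_accumulate",
    "homeostasis_delta",
    "apply_epoch_update",
]


@dataclass(frozen=True)
class PlasticityParams:
    """STDP window and homeostasis meta-parameters (the GA's search space).

    The defaults are a converged parameter set selected by this package's own
    genetic search under the default click protocol: a narrow potentiation
    window (tens of µs, matching the causal window of the dV/dt spike
    trigger), a depression window long enough that spikes also depress input
    from neighbouring clicks (a slow erosion of unselected synapses), and a
    small homeostatic increment so the cell approaches its firing threshold
    gently.  They are a demonstration model, not measured physiology.
    """

    dw_plus: float = 3.519      # max potentiation per pair (weight units)
    dw_minus: float = 0.9876    # max depression per pair
    tau_plus: float = 4.014e-5  # potentiation window time constant (s)
    tau_minus: float = 9.896e-3  # depression window time constant (s)
    delta_plus: float = 0.004068  # homeostatic increment when under-firing
    delta_minus: float = 0.02327  # homeostatic decrement when over-firing
    r_target: int = 4           # target spikes per 50 ms epoch
    w_max: float = 0.1115       # weight ceiling

    def __post_init__(self):
        if min(self.dw_plus, self.dw_minus, self.delta_plus, self.delta_minus) < 0:
            raise ValueError("plasticity magnitudes must be non-negative")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP time constants must be strictly positive")
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")
        if self.r_target < 0 or int(self.r_target) != self.r_target:
            raise ValueError("r_target must be a non-negative integer")


@dataclass(frozen=True)
class EpochPairing:
    """Event times of one epoch, as the plasticity rule sees them.

    ``pre_times[j]`` are synapse j's somatic arrival times (sorted ascending);
    ``post_times`` are the cell's output spike times.
    """

    pre_times: list
    post_times: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "post_times", np.asarray(self.post_times, dtype=float)
        )

    @property
    def n_post(self) -> int:
        return self.post_times.size

    @property
    def n_synapses(self) -> int:
        return len(self.pre_times)


def stdp_delta(dt_pre_minus_post, params: PlasticityParams):
    """STDP weight change for a single pre/post time difference (vectorized).

    Strict inequalities on both branches: an exactly coincident pair (Δt = 0)
    contributes nothing.
    """
    dt = np.asarray(dt_pre_minus_post, dtype=float)
    if not np.all(np.isfinite(dt)):
        raise ValueError("time differences must be finite")
    out = np.zeros_like(dt)
    neg = dt < 0
    pos = dt > 0
    out[neg] = params.dw_plus * np.exp(dt[neg] / params.tau_plus)
    out[pos] = -params.dw_minus * np.exp(-dt[pos] / params.tau_minus)
    return out if out.ndim else float(out)


def stdp_epoch_accumulate(pairing: EpochPairing, params: PlasticityParams) -> np.ndarray:
    """Per-synapse STDP change: the sum of :func:`stdp_delta` over all
    (pre, post) pairs of the epoch.

    Summation order is fixed — by synapse, then pre time ascending, then post
    time ascending, accumulated sequentially — so the result is bit-identical
    to a brute-force double loop in that order.
    """
    n_syn = pairing.n_synapses
    d_w = np.zeros(n_syn)
    post = np.sort(pairing.post_times)
    if post.size == 0:
        return d_w
    for j in range(n_syn):
        pre = np.sort(np.asarray(pairing.pre_times[j], dtype=float))
        if pre.size == 0:
            continue
        deltas = stdp_delta(pre[:, None] - post[None, :], params)
        # cumsum is a sequential left-to-right reduction; ravel() order is
        # (pre, post), matching the documented order exactly.
        d_w[j] = np.cumsum(deltas.ravel())[-1]
    return d_w


def homeostasis_delta(n_post: int, params: PlasticityParams) -> float:
    """Uniform weight change from the epoch's output spike count.

    +δ₊ below target, −δ₋ above, 0 exactly at target (the rule's branches are
    strict inequalities; equality is declared a no-op).
    """
    if n_post < 0:
        raise ValueError("n_post must be non-negative")
    if n_post < params.r_target:
        return params.delta_plus
    if n_post > params.r_target:
        return -params.delta_minus
    return 0.0


def apply_epoch_update(
    synapses: SynapsePopulation,
    pairing: EpochPairing,
    params: PlasticityParams,
) -> SynapsePopulation:
    """End-of-epoch weight update: W ← clip(W + ΔW_STDP + ΔW_homeo, 0, W_max)."""
    if pairing.n_synapses != synapses.n_synapses:
        raise ValueError(
            f"pairing has {pairing.n_synapses} synapses, population has "
            f"{synapses.n_synapses}"
        )
    d_w = stdp_epoch_accumulate(pairing, params)
    d_w += homeostasis_delta(pairing.n_post, params)
    new_w = np.clip(synapses.weight + d_w, 0.0, params.w_max)
    return SynapsePopulation(
        fiber_index=synapses.fiber_index,
        t_dendritic=synapses.t_dendritic,
        weight=new_w,
        max_dendritic_delay=synapses.max_dendritic_delay,
        w_max=params.w_max,
    )
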