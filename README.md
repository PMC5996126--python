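# octostdp

Octopus cells are monaural neurons of the posteroventral cochlear nucleus that
fire a single, precisely timed action potential at the onset of broadband
sounds.  This is paradoxical at first sight: their input — hundreds of
auditory-nerve fibers (ANFs) spanning a wide band of characteristic
frequencies (CFs) — is *temporally diffuse*, because the cochlear traveling
wave reaches low-CF places of the basilar membrane roughly 0.5 ms later than
high-CF places.  The accepted resolution is that the octopus cell's dendrite
acts as a delay line: synapses from early-firing (high-CF) fibers sit
distally and accrue a long dendritic delay, late-firing (low-CF) fibers
connect proximally, and the two delays cancel so that all inputs arrive at
the soma together.

`octostdp` is a proof-of-principle simulator showing that this finely tuned
synaptic arrangement need not be hard-wired: starting from *random* synapse
placements and zero weights, spike-timing-dependent plasticity (STDP) plus a
homeostatic firing-rate rule can *select* the delay-compensating subset of
synapses, using nothing but the circuit's own activity.

## Model

* **Frontend** — 400 ANFs with log-spaced CFs from 6 to 20 kHz.  A parametric
  traveling-wave delay map assigns each fiber a latency, spanning 0.5 ms
  across the array.  Click trains (4 clicks per 50 ms epoch) evoke one
  jittered spike per fiber per click.  Rasters can also be imported from CSV
  (e.g. from a full auditory-periphery model).
* **Octopus cell** — a conductance-based leaky integrate-and-fire neuron
  (C_m = 43 pF, g_leak = 143 nS, V_L = −65 mV, E_ex = 0 mV) with two
  octopus-cell signatures: spikes are triggered by a threshold on the *rate
  of change* of the membrane potential, dV/dt > κ = 10 mV/ms over one 10 µs
  step, and an absolute refractory period of 1.1 ms caps firing near 900 Hz.
  Each of 1200 synapses (3 per fiber) has a dendritic delay drawn uniformly
  on [0, 0.5 ms]; the dendrite is modeled as a pure delay.
* **Plasticity** — all-to-all pair-based additive STDP on the *somatic
  arrival times* (fiber spike + dendritic delay):
  ΔW = +Δw̄₊·exp(−|Δt|/τ₊) when the input leads the output spike and
  −Δw̄₋·exp(−|Δt|/τ₋) when it lags, plus a uniform homeostatic step (+δ₊
  below, −δ₋ above a target of R = 4 spikes per epoch).  Updates apply once
  per 50 ms epoch, clipped to [0, W_max].
* **Quality metric** — η ∈ [0, 1], a weight-normalized Gaussian score of how
  closely each synapse's total delay t_TW + t_D matches the target
  T = 0.5 ms (σ = 70 µs).  Random equal-weight configurations score ≈ 0.31
  here; η above that means the weights have selected compensating synapses.
* **Meta-parameter search** — an elitist genetic algorithm over the
  physiological ranges of (Δw̄₊, Δw̄₋, τ₊, τ₋, δ₊, δ₋, W_max): the top-2
  models are copied unchanged each generation, children inherit each
  parameter from a random parent and receive cubic-compressed mutation
  noise, and fitness is the final η after 10 learning epochs on a fresh
  random connectivity.

## Worked example

A learning run with the default (search-selected) plasticity parameters:

```sh
$ octostdp learn --outdir runs/demo
final eta = 0.5090 after 10 epochs -> runs/demo
```

The per-epoch log (`runs/demo/learning_log.csv`) shows the mechanism.
Weights start at zero, so the cell is silent and homeostasis ramps all
weights uniformly (+δ₊ per epoch) while the peak dV/dt climbs toward κ:

```
epoch,n_post,max_dvdt_v_per_s,eta,mean_w,...
0,0,0,0.3059,0.0041,...
4,0,5.18,0.3059,0.0203,...
8,0,9.82,0.3059,0.0366,...
9,4,18.19,0.5090,0.0171,...
```

At epoch 9 the cell starts firing (4 spikes = one per click, the homeostatic
target) and STDP immediately differentiates the synapses: η jumps from the
homogeneous baseline 0.306 to 0.509 — the surviving weight sits on synapses
whose dendritic delay compensates the traveling-wave delay.

The before/after comparison replays one epoch with the learned weights and
with homogeneous weights carrying the *same total* synaptic drive:

```sh
$ octostdp before-after --outdir runs/ba
before: 0 spikes, max dV/dt 5.3 V/s; after: 4 spikes, max dV/dt 16.4 V/s
```

Timing selectivity, not total drive, is what pushes the cell over its
dV/dt threshold: the homogeneous arm never reaches κ = 10 V/s.

The meta-parameter search itself (scaled down; the full protocol is 100
generations):

```sh
octostdp search --generations 25 --seed 1 --history runs/search.json
```

## Layout

```
src/octostdp/
  frontend.py     ANF populations, click stimuli, spike rasters, CSV I/O
  cell.py         LIF octopus cell with dV/dt threshold (numba kernel)
  plasticity.py   STDP window, homeostasis, epoch update
  metric.py       compensation metric eta
  learning.py     the epoch loop
  search.py       elitist genetic algorithm
  experiments.py  learning / before-after / tau+ sweep drivers, config I/O
  cli.py          `octostdp` command-line interface
docs/methods.md   modelling and numerical details
```
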