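"""Elitist genetic search over STDP/homeostasis meta-parameters.

There is no experimental measurement of STDP parameters in octopus cells, so
the learning-rule meta-parameters are selected by a simple elitist genetic
algorithm whose fitness is the delay-compensation metric η after a 10-epoch
learning run.  Each generation:

* the two highest-η models (the elites) are copied unchanged,
* each child inherits every parameter from a uniformly chosen parent,
* each inherited value receives compressed noise: x ~ U(0,1) is mapped
  through y = 4(x − 0.5)³ + 0.5 and the perturbation (y − 0.5)·(hi − lo) is
  added (in log10 coordinates for log-scaled parameters), then clipped to the
  bounds.  The cubic compression makes small changes frequent and large ones
  rare.

Every model is evaluated on a *fresh* random synapse placement and fresh
rasters, so fitness is noisy across generations by design.  The whole search
is a pure function of (space, config, master_seed), and the history is
persisted as JSON after every generation so interrupted runs resume.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .learning import derive_seed, simulate_learning
from .plasticity import PlasticityParams

__all__ = [
    "ParamSpec",
    "SearchSpace",
    "Genome",
    "GenerationRecord",
    "EvalConfig",
    "default_space",
    "mutate",
    "sample_genome",
    "spawn_generation",
    "evaluate",
    "run_search",
]


@dataclass(frozen=True)
class ParamSpec:
    """One searchable meta-parameter: bounds, mutation coordinate, freezing."""

    name: str
    low: float
    high: float
    scale: str = "linear"  # "linear" | "log10"
    frozen: bool = False
    frozen_value: float | None = None

    def __post_init__(self):
        if self.low >= self.high:
            raise ValueError(f"{self.name}: need low < high")
        if self.scale not in ("linear", "log10"):
            raise ValueError(f"{self.name}: scale must be 'linear' or 'log10'")
        if self.scale == "log10" and self.low <= 0:
            raise ValueError(f"{self.name}: log10 scale needs positive bounds")
        if self.frozen and self.frozen_value is None:
            raise ValueError(f"{self.name}: frozen parameter needs a value")


@dataclass(frozen=True)
class SearchSpace:
    params: tuple

    def __post_init__(self):
        object.__setattr__(self, "params", tuple(self.params))
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in search space")

    @property
    def searchable(self) -> tuple:
        return tuple(p for p in self.params if not p.frozen)

    def freeze(self, **values: float) -> "SearchSpace":
        """Return a copy with the named parameters pinned to fixed values."""
        known = {p.name for p in self.params}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown parameters to freeze: {sorted(unknown)}")
        return SearchSpace(tuple(
            replace(p, frozen=True, frozen_value=float(values[p.name]))
            if p.name in values else p
            for p in self.params
        ))


def default_space(dw_ceiling: float = 10.0) -> SearchSpace:
    """The standard physiological search bounds.

    STDP magnitudes 0–``dw_ceiling`` (10 by default, raised to 20 for the τ₊
    sweep where the magnitude saturated at 10), window time constants
    20 µs–20 ms (mutated in log10 since they span three decades), homeostatic
    steps 0–0.03 and weight ceiling 0.01–0.2.
    """
    return SearchSpace((
        ParamSpec("dw_plus", 0.0, dw_ceiling),
        ParamSpec("dw_minus", 0.0, dw_ceiling),
        ParamSpec("tau_plus", 20e-6, 20e-3, scale="log10"),
        ParamSpec("tau_minus", 20e-6, 20e-3, scale="log10"),
        ParamSpec("delta_plus", 0.0, 0.03),
        ParamSpec("delta_minus", 0.0, 0.03),
        ParamSpec("w_max", 0.01, 0.2),
    ))


@dataclass(frozen=True)
class Genome:
    """One meta-parameter vector plus its provenance in the search."""

    values: dict
    generation: int = 0
    parents: tuple | None = None

    def to_plasticity_params(self, r_target: int = 4) -> PlasticityParams:
        return PlasticityParams(r_target=r_target, **self.values)


def _compress(x: float) -> float:
    """Cubic noise compression: U(0,1) → [0,1], fixed point at 0.5."""
    return 4.0 * (x - 0.5) ** 3 + 0.5


def mutate(value: float, spec: ParamSpec, rng: np.random.Generator) -> float:
    """Perturb one value with compressed noise scaled to the parameter range."""
    y = _compress(float(rng.random()))
    if spec.scale == "log10":
        lo, hi = np.log10(spec.low), np.log10(spec.high)
        v = 10.0 ** (np.log10(value) + (y - 0.5) * (hi - lo))
        # clip in linear coordinates: the log10 round-trip of a bound can
        # land one ulp outside it
        return float(np.clip(v, spec.low, spec.high))
    v = value + (y - 0.5) * (spec.high - spec.low)
    return float(np.clip(v, spec.low, spec.high))


def sample_genome(space: SearchSpace, rng: np.random.Generator,
                  generation: int = 0) -> Genome:
    """Sample uniformly within bounds (log-uniform for log10 parameters)."""
    values = {}
    for p in space.params:
        if p.frozen:
            values[p.name] = float(p.frozen_value)
        elif p.scale == "log10":
            lo, hi = np.log10(p.low), np.log10(p.high)
            values[p.name] = float(10.0 ** rng.uniform(lo, hi))
        else:
            values[p.name] = float(rng.uniform(p.low, p.high))
    return Genome(values=values, generation=generation)


def spawn_generation(
    elites: list,
    n_children: int,
    space: SearchSpace,
    rng: np.random.Generator,
    generation: int = 0,
    mutation: bool = True,
) -> list:
    """Breed ``n_children`` mutated children from 2 elites; append the elites
    unchanged.  Output size = n_children + 2."""
    if len(elites) != 2:
        raise ValueError(f"expected exactly 2 elites, got {len(elites)}")
    out = []
    for _ in range(n_children):
        values = {}
        parents = []
        for p in space.params:
            if p.frozen:
                values[p.name] = float(p.frozen_value)
                continue
            k = int(rng.integers(2))
            parents.append(k)
            v = elites[k].values[p.name]
            values[p.name] = mutate(v, p, rng) if mutation else float(v)
        out.append(Genome(values=values, generation=generation,
                          parents=tuple(parents)))
    for e in elites:
        out.append(replace(e, generation=generation, parents=None))
    return out


@dataclass(frozen=True)
class EvalConfig:
    """What one fitness evaluation runs: the study conditions of a model.

    Defaults are the standard protocol — 400 fibers spanning 6–20 kHz with a
    0.5 ms delay span, 3 synapses/fiber, 10 epochs of 4 clicks in 50 ms.
    """

    n_fibers: int = 400
    cf_min: float = 6000.0
    cf_max: float = 20000.0
    delay_model: str = "log-linear"
    delay_span: float = 0.5e-3
    n_epochs: int = 10
    synapses_per_fiber: int = 3
    max_dendritic_delay: float = 0.5e-3
    r_target: int = 4
    stimulus: "object" = None       # ClickStimulus; default built lazily
    cell_params: "object" = None    # CellParams; default built lazily

    def resolved(self):
        from .cell import CellParams
        from .frontend import ClickStimulus, build_population

        pop = build_population(self.n_fibers, self.cf_min, self.cf_max,
                               self.delay_model, self.delay_span)
        stim = self.stimulus if self.stimulus is not None else ClickStimulus()
        cp = self.cell_params if self.cell_params is not None else CellParams()
        return pop, stim, cp


@dataclass(frozen=True)
class EvalResult:
    eta: float
    all_silent: bool

    @property
    def fitness(self) -> float:
        """η, with the undefined all-silent case scored 0 so search proceeds."""
        return 0.0 if self.all_silent else self.eta


def evaluate(genome: Genome, config: EvalConfig, seed: int) -> EvalResult:
    """Fitness of one genome: final η after a fresh 10-epoch learning run.

    The synapse placement and the rasters are resampled from ``seed``, so the
    same genome generally scores differently under different seeds.
    """
    pop, stim, cell_params = config.resolved()
    result = simulate_learning(
        population=pop,
        stimulus=stim,
        cell_params=cell_params,
        plasticity_params=genome.to_plasticity_params(config.r_target),
        n_epochs=config.n_epochs,
        synapses_per_fiber=config.synapses_per_fiber,
        max_dendritic_delay=config.max_dendritic_delay,
        placement_seed=derive_seed(seed, 0),
        raster_seed=derive_seed(seed, 1),
    )
    return EvalResult(eta=result.final_eta, all_silent=result.all_silent)


@dataclass(frozen=True)
class GenerationRecord:
    generation: int
    genomes: tuple
    seeds: tuple
    etas: tuple          # fitness per model (0 for all-silent models)
    silent_flags: tuple
    elite_indices: tuple  # top-2 by fitness, ties broken by lower index

    def elites(self) -> list:
        return [self.genomes[i] for i in self.elite_indices]

    def best_eta(self) -> float:
        return float(self.etas[self.elite_indices[0]])


def _select_elites(etas) -> tuple:
    order = np.argsort(-np.asarray(etas), kind="stable")  # stable → lower index wins ties
    return int(order[0]), int(order[1])


def _record_to_json(rec: GenerationRecord) -> dict:
    return {
        "generation": rec.generation,
        "genomes": [g.values for g in rec.genomes],
        "seeds": list(rec.seeds),
        "etas": list(rec.etas),
        "silent_flags": list(rec.silent_flags),
        "elite_indices": list(rec.elite_indices),
    }


def _record_from_json(d: dict) -> GenerationRecord:
    return GenerationRecord(
        generation=int(d["generation"]),
        genomes=tuple(Genome(values=v, generation=int(d["generation"]))
                      for v in d["genomes"]),
        seeds=tuple(int(s) for s in d["seeds"]),
        etas=tuple(float(e) for e in d["etas"]),
        silent_flags=tuple(bool(f) for f in d["silent_flags"]),
        elite_indices=tuple(int(i) for i in d["elite_indices"]),
    )


def save_history(records: list, path) -> None:
    """Atomically persist the search history as JSON."""
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        json.dump([_record_to_json(r) for r in records], fh, indent=1)
    os.replace(tmp, path)


def load_history(path) -> list:
    with open(path) as fh:
        return [_record_from_json(d) for d in json.load(fh)]


def run_search(
    space: SearchSpace,
    n_generations: int = 100,
    n_children: int = 15,
    config: EvalConfig = EvalConfig(),
    master_seed: int = 0,
    history_path=None,
    progress: bool = False,
) -> list:
    """Run the elitist GA and return one :class:`GenerationRecord` per
    generation.

    Per-generation RNG streams and per-model evaluation seeds are derived
    from ``master_seed`` alone, so the search is reproducible and — when
    ``history_path`` points at a partial history from the same settings —
    resumable without replaying completed generations.
    """
    if n_generations < 1 or n_children < 1:
        raise ValueError("n_generations and n_children must be positive")
    records: list[GenerationRecord] = []
    if history_path is not None and os.path.exists(history_path):
        records = load_history(history_path)[:n_generations]

    pop_size = n_children + 2
    for gen in range(len(records), n_generations):
        rng = np.random.default_rng(derive_seed(master_seed, gen, 0))
        if gen == 0:
            genomes = [sample_genome(space, rng) for _ in range(pop_size)]
        else:
            genomes = spawn_generation(
                records[-1].elites(), n_children, space, rng, generation=gen
            )
        seeds = tuple(derive_seed(master_seed, gen, 1 + i) for i in range(pop_size))
        results = [evaluate(g, config, s) for g, s in zip(genomes, seeds)]
        etas = tuple(r.fitness for r in results)
        rec = GenerationRecord(
            generation=gen,
            genomes=tuple(genomes),
            seeds=seeds,
            etas=etas,
            silent_flags=tuple(r.all_silent for r in results),
            elite_indices=_select_elites(etas),
        )
        records.append(rec)
        if history_path is not None:
            save_history(records, history_path)
        if progress:
            print(f"generation {gen:3d}: best eta = {rec.best_eta():.4f}")
    return records


def history_to_frame(records: list):
    """Flatten a search history to a DataFrame (one row per model)."""
    import pandas as pd

    rows = []
    for rec in records:
        for i, (g, s, e, f) in enumerate(
            zip(rec.genomes, rec.seeds, rec.etas, rec.silent_flags)
        ):
            rows.append({"generation": rec.generation, "model": i, "seed": s,
                         "eta": e, "silent": f,
                         "is_elite": i in rec.elite_indices, **g.values})
    return pd.DataFrame(rows)
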