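"""Host-level generational loop with carrying-capacity selection.

Each generation the live population is doubled (every host replicates,
offspring inheriting the parent's survival likelihood L and a copy of its
genome), every candidate undergoes background mutation and the TE
lifecycle, lethally hit hosts are removed, and the pool then competes for
the carrying capacity C: candidate i survives with probability

    P(s_i) = min(1, L(s_i) / sum_j L(s_j) * C)

With likelihoods near their initial value of 1 and a doubled pool,
sum L ~ 2C and P ~ 1/2; a single host carrying a fresh beneficial bump of
magnitude Me survives with ~(1+Me)/2 — the closed forms in
:mod:`teworld.analytics`.

A run ends in one of three outcomes: TE_EXTINCT (no active copies left
anywhere), HOST_EXTINCT (no live hosts), or PERSIST (both still present
when the generation budget runs out).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .effects import (EffectModel, TERates, apply_insertion_effect,
                      draw_effect, make_effect_model, transpose_step)
from .genome import Genome, new_genome


class Outcome(Enum):
    TE_EXTINCT = "TE_EXTINCT"
    HOST_EXTINCT = "HOST_EXTINCT"
    PERSIST = "PERSIST"


class PopulationExtinct(Exception):
    """Raised internally when no live host remains."""


@dataclass
class Host:
    host_id: int
    likelihood: float
    genome: Genome
    alive: bool = True

    def __post_init__(self):
        if self.likelihood < 0:
            raise ValueError("survival likelihood must be >= 0")


@dataclass
class HostMutationModel:
    """Background (non-TE) mutation: a Poisson-distributed count of gene
    hits per host per generation, each classified and applied exactly like
    a genic TE insertion."""

    corrected_mutation_rate: float

    def __post_init__(self):
        if self.corrected_mutation_rate < 0:
            raise ValueError("mutation rate must be >= 0")


@dataclass
class Population:
    hosts: list[Host]
    carrying_capacity: int
    generation: int = 0
    _next_host_id: int = 0

    @property
    def live_hosts(self) -> list[Host]:
        return [h for h in self.hosts if h.alive]

    @property
    def n_live(self) -> int:
        return sum(1 for h in self.hosts if h.alive)

    @property
    def n_active_tes(self) -> int:
        return sum(h.genome.n_active_tes for h in self.hosts if h.alive)

    def new_host_id(self) -> int:
        i = self._next_host_id
        self._next_host_id = i + 1
        return i


@dataclass
class OutcomeRecord:
    """Per-run summary: the three-way classification plus trajectory."""

    outcome: Outcome
    terminal_generation: int
    peak_te_count: int
    final_n_hosts: int
    final_n_active_tes: int
    trajectory: list[dict] = field(default_factory=list)
    config: Optional[dict] = None

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trajectory,
                            columns=["generation", "n_hosts", "n_active_tes",
                                     "mean_L", "n_disrupted_genes"])

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome.value,
            "terminal_generation": self.terminal_generation,
            "peak_te_count": self.peak_te_count,
            "final_n_hosts": self.final_n_hosts,
            "final_n_active_tes": self.final_n_active_tes,
        }


def survival_probability(l_i: float, sum_l: float, c: int) -> float:
    """Carrying-capacity survival probability min(1, L_i / sum L * C).

    Any uniform effect-magnitude adjustment is already folded into L_i, so
    summing the probabilities over the pool gives exactly C (before
    clamping).  ``sum_l == 0`` signals an extinct pool.
    """
    if l_i < 0:
        raise ValueError("likelihood must be >= 0")
    if c < 1:
        return 0.0
    if sum_l <= 0:
        raise PopulationExtinct("total survival likelihood is zero")
    return min(1.0, l_i / sum_l * c)


def replicate_hosts(population: Population, rng: np.random.Generator
                    ) -> list[Host]:
    """Double the population: each live host yields one offspring with the
    parent's likelihood and an independent copy of the genome.  Returns the
    candidate pool (parents + offspring)."""
    live = population.live_hosts
    if not live:
        raise PopulationExtinct("no live hosts to replicate")
    pool = list(live)
    for parent in live:
        pool.append(Host(population.new_host_id(), parent.likelihood,
                         parent.genome.copy()))
    return pool


def background_mutation_step(host: Host, model: HostMutationModel,
                             effect_model: EffectModel,
                             rng: np.random.Generator) -> None:
    """Apply a Poisson number of background gene mutations to one host."""
    if model.corrected_mutation_rate == 0:
        return
    n_events = rng.poisson(model.corrected_mutation_rate)
    for _ in range(n_events):
        effect = draw_effect(effect_model, rng)
        new_l, lethal = apply_insertion_effect(host.likelihood, effect,
                                               effect_model, rng)
        host.likelihood = new_l
        if lethal:
            host.alive = False


def selection_step(pool: list[Host], c: int, rng: np.random.Generator,
                   mode: str = "bernoulli") -> list[Host]:
    """Competition for the carrying capacity.

    ``bernoulli`` (default): each candidate survives independently with
    min(1, L_i/sum L * C) — the per-individual probability reading.
    ``exact``: draw exactly min(C, pool size) survivors without
    replacement, weighted by L.
    """
    live = [h for h in pool if h.alive]
    if c < 1 or not live:
        return []
    ls = np.array([h.likelihood for h in live])
    sum_l = float(ls.sum())
    if sum_l <= 0:
        raise PopulationExtinct("total survival likelihood is zero")
    if mode == "bernoulli":
        p = np.minimum(1.0, ls / sum_l * c)
        keep = rng.random(len(live)) < p
        return [h for h, k in zip(live, keep) if k]
    if mode == "exact":
        k = min(c, len(live))
        idx = rng.choice(len(live), size=k, replace=False, p=ls / sum_l)
        return [live[i] for i in sorted(idx)]
    raise ValueError(f"unknown selection mode {mode!r}")


def _init_population(config: SimulationConfig,
                     rng: np.random.Generator) -> Population:
    pop = Population(hosts=[], carrying_capacity=config.carrying_capacity)
    for _ in range(config.carrying_capacity):
        g = new_genome(config.gene_count, config.gene_length, config.te_length,
                       config.initial_te_count, config.intergenic_length, rng)
        pop.hosts.append(Host(pop.new_host_id(), 1.0, g))
    return pop


def run_generation(population: Population, config: SimulationConfig,
                   rng: np.random.Generator) -> Population:
    """One full cycle: replicate, mutate, transpose, select."""
    effect_model = make_effect_model(config.bp, config.mutation_effect,
                                     config.p_lethal, config.p_deleterious,
                                     config.mode)
    rates = TERates(config.te_excision_rate, config.te_death_rate,
                    config.te_progeny)
    mut_model = HostMutationModel(config.corrected_mutation_rate)

    pool = replicate_hosts(population, rng)
    n_parents = len(pool) // 2
    for i, host in enumerate(pool):
        if not config.step_parents and i < n_parents:
            continue
        background_mutation_step(host, mut_model, effect_model, rng)
        res = transpose_step(host.genome, host.likelihood, rates, effect_model,
                             config.insertion_bias, rng,
                             config.dead_te_retains_bp,
                             config.inactivate_nested_target)
        host.likelihood = res.likelihood
        if res.lethal:
            host.alive = False
    survivors = selection_step(pool, config.carrying_capacity, rng,
                               config.selection_mode)
    population.hosts = survivors
    population.generation += 1
    return population


def _snapshot(pop: Population) -> dict:
    live = pop.live_hosts
    return {
        "generation": pop.generation,
        "n_hosts": len(live),
        "n_active_tes": sum(h.genome.n_active_tes for h in live),
        "mean_L": float(np.mean([h.likelihood for h in live])) if live else 0.0,
        "n_disrupted_genes": sum(len(h.genome.disrupted_genes) for h in live),
    }


def run_simulation(config: SimulationConfig,
                   rng: Optional[np.random.Generator] = None) -> OutcomeRecord:
    """Run one simulation to its outcome.

    Iterates generations until the active TE census hits zero (TE_EXTINCT),
    the host population dies out (HOST_EXTINCT), or the generation budget
    ``g_max`` is exhausted with both still present (PERSIST).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = _init_population(config, rng)
    trajectory = [_snapshot(pop)] if config.record_trajectory else []
    peak = pop.n_active_tes

    def record(outcome: Outcome) -> OutcomeRecord:
        return OutcomeRecord(outcome, pop.generation, peak, pop.n_live,
                             pop.n_active_tes, trajectory, config.to_dict())

    if pop.n_live == 0:
        return record(Outcome.HOST_EXTINCT)
    while pop.generation < config.g_max:
        if pop.n_active_tes == 0:
            return record(Outcome.TE_EXTINCT)
        try:
            run_generation(pop, config, rng)
        except PopulationExtinct:
            pop.hosts = []
        if config.record_trajectory:
            trajectory.append(_snapshot(pop))
        peak = max(peak, pop.n_active_tes)
        if pop.n_live == 0:
            return record(Outcome.HOST_EXTINCT)
    if pop.n_active_tes == 0:
        return record(Outcome.TE_EXTINCT)
    return record(Outcome.PERSIST)


def trajectory_tsv(record: OutcomeRecord) -> str:
    """Render a run's trajectory as TSV."""
    return record.trajectory_frame().to_csv(sep="\t", index=False)
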