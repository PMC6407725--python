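"""Genetic-algorithm engine for medium compositions.

Populations of bit-string individuals are evolved by fitness-proportional
(roulette-wheel) selection, single-point crossover, and independent per-bit
mutation.  The engine is experiment-in-the-loop: :class:`Campaign` exposes an
ask/tell interface in which ``ask()`` yields an unscored generation to be
assayed (on a real plate reader or the synthetic simulator) and ``tell()``
returns the measured fitness values, after which the next generation can be
bred.  All randomness flows through one seeded generator whose state is
serialized with the campaign, so wet-lab-paced runs are resumable and
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .encoding import ParameterSpace, bits_to_str, str_to_bits
from .errors import (
    DegeneratePopulationError,
    InfeasibleDesignError,
    ReconciliationError,
    StateError,
    ValidationError,
)

__all__ = [
    "GAConfig",
    "Individual",
    "Generation",
    "init_generation",
    "roulette_select",
    "crossover",
    "mutate",
    "next_generation",
    "Campaign",
]


@dataclass(frozen=True)
class GAConfig:
    """Run configuration.

    Defaults follow the campaign design this package reimplements: 30 unique
    medium compositions per generation (a 96-well plate in triplicate plus
    controls), 95% crossover probability, 2% per-bit mutation rate,
    roulette-wheel selection, no elitism.
    """

    population_size: int = 30
    crossover_prob: float = 0.95
    mutation_rate: float = 0.02
    selection: str = "roulette"
    fitness_scaling: str = "window"
    seed: int = 0
    elitism: int = 0
    max_redraw_attempts: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ValidationError(f"crossover_prob {self.crossover_prob} not in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValidationError(f"mutation_rate {self.mutation_rate} not in [0, 1]")
        if self.population_size < 2:
            raise ValidationError("population_size must be >= 2")
        if self.selection != "roulette":
            raise ValidationError(f"unknown selection scheme {self.selection!r}")
        if self.fitness_scaling not in ("window", "raw"):
            raise ValidationError(f"unknown fitness scaling {self.fitness_scaling!r}")
        if self.elitism not in (0, 1):
            raise ValidationError("elitism must be 0 or 1")

    def to_dict(self) -> dict:
        return {
            "population_size": self.population_size,
            "crossover_prob": self.crossover_prob,
            "mutation_rate": self.mutation_rate,
            "selection": self.selection,
            "fitness_scaling": self.fitness_scaling,
            "seed": self.seed,
            "elitism": self.elitism,
            "max_redraw_attempts": self.max_redraw_attempts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GAConfig":
        return cls(**d)


@dataclass
class Individual:
    """One unique medium composition (a 'treatment')."""

    chromosome: np.ndarray
    concentrations: np.ndarray
    treatment_id: str = ""
    fitness: float | None = None

    @classmethod
    def from_chromosome(
        cls, chromosome: np.ndarray, space: ParameterSpace, treatment_id: str = ""
    ) -> "Individual":
        chromosome = np.asarray(chromosome, dtype=np.uint8)
        return cls(
            chromosome=chromosome,
            concentrations=space.decode_chromosome(chromosome),
            treatment_id=treatment_id,
        )

    @property
    def key(self) -> str:
        return bits_to_str(self.chromosome)

    def to_dict(self) -> dict:
        return {
            "chromosome": self.key,
            "concentrations": [float(c) for c in self.concentrations],
            "treatment_id": self.treatment_id,
            "fitness": self.fitness,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Individual":
        ind = cls(
            chromosome=str_to_bits(d["chromosome"]),
            concentrations=np.array(d["concentrations"], dtype=float),
            treatment_id=d["treatment_id"],
        )
        ind.fitness = d["fitness"]
        return ind


@dataclass
class Generation:
    """A scored or pending population plus its reproduction provenance."""

    index: int
    individuals: list[Individual]
    rng_state: dict | None = None
    parent_log: list[dict] = field(default_factory=list)

    @property
    def scored(self) -> bool:
        return all(ind.fitness is not None for ind in self.individuals)

    @property
    def fitnesses(self) -> np.ndarray:
        if not self.scored:
            raise StateError(f"generation {self.index} has unscored individuals")
        return np.array([ind.fitness for ind in self.individuals], dtype=float)

    def best(self) -> Individual:
        return self.individuals[int(np.argmax(self.fitnesses))]

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "individuals": [ind.to_dict() for ind in self.individuals],
            "rng_state": self.rng_state,
            "parent_log": self.parent_log,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Generation":
        return cls(
            index=d["index"],
            individuals=[Individual.from_dict(x) for x in d["individuals"]],
            rng_state=d["rng_state"],
            parent_log=d["parent_log"],
        )


def _treatment_id(gen_index: int, i: int) -> str:
    return f"{gen_index}-{i + 1}"


def init_generation(
    space: ParameterSpace, config: GAConfig, rng: np.random.Generator | None = None
) -> Generation:
    """Uniform-random first generation of unique chromosomes."""
    if space.chromosome_length == 0:
        raise ValidationError("parameter space has no optimizable component")
    if 2 ** space.chromosome_length < config.population_size:
        raise InfeasibleDesignError(
            f"chromosome space of {2 ** space.chromosome_length} cannot hold "
            f"{config.population_size} unique individuals"
        )
    rng = np.random.default_rng(config.seed) if rng is None else rng
    seen: set[str] = set()
    individuals: list[Individual] = []
    attempts = 0
    while len(individuals) < config.population_size:
        bits = rng.integers(0, 2, size=space.chromosome_length, dtype=np.uint8)
        key = bits_to_str(bits)
        if key in seen:
            attempts += 1
            if attempts > config.max_redraw_attempts:
                raise DegeneratePopulationError(
                    "could not draw enough unique random chromosomes"
                )
            continue
        seen.add(key)
        individuals.append(
            Individual.from_chromosome(bits, space, _treatment_id(1, len(individuals)))
        )
    return Generation(index=1, individuals=individuals)


def _wheel(population: Sequence[Individual], scaling: str = "raw") -> np.ndarray:
    """Normalized selection probabilities after the non-negativity floor.

    ``raw`` divides each floored fitness by the population total.  ``window``
    first subtracts the population minimum, which restores selection pressure
    when all fitness values sit in a narrow band well above zero (typical of
    RIMA values, which cluster around 1); an all-equal population then falls
    back to uniform selection.
    """
    fits = []
    for ind in population:
        if ind.fitness is None:
            raise StateError(f"individual {ind.treatment_id!r} has no fitness")
        fits.append(max(float(ind.fitness), 0.0))
    fits = np.array(fits)
    if scaling == "window":
        fits = fits - fits.min()
        if fits.sum() <= 0.0:
            return np.full(len(fits), 1.0 / len(fits))
        return fits / fits.sum()
    total = fits.sum()
    if total <= 0.0:
        raise DegeneratePopulationError("all fitness values are 0 after flooring")
    return fits / total


def roulette_select(
    population: Generation | Sequence[Individual],
    rng: np.random.Generator,
    scaling: str = "raw",
) -> Individual:
    """Draw one individual with probability proportional to (floored) fitness."""
    individuals = (
        population.individuals if isinstance(population, Generation) else list(population)
    )
    p = _wheel(individuals, scaling)
    return individuals[int(rng.choice(len(individuals), p=p))]


def crossover(
    parent_a: Individual,
    parent_b: Individual,
    config: GAConfig,
    rng: np.random.Generator,
    space: ParameterSpace,
) -> tuple[Individual, Individual, int | None]:
    """Single-point crossover with probability ``crossover_prob``.

    Returns the two offspring and the cut position (bits beyond the cut are
    exchanged), or ``None`` when no crossover event occurred.
    """
    a, b = parent_a.chromosome, parent_b.chromosome
    if a.size != b.size:
        raise ValidationError("parents have different chromosome lengths")
    cut: int | None = None
    if a.size >= 2 and rng.random() < config.crossover_prob:
        cut = int(rng.integers(1, a.size))
        a = np.concatenate([a[:cut], b[cut:]])
        b = np.concatenate([parent_b.chromosome[:cut], parent_a.chromosome[cut:]])
    return (
        Individual.from_chromosome(a.copy(), space),
        Individual.from_chromosome(b.copy(), space),
        cut,
    )


def mutate(
    individual: Individual,
    config: GAConfig,
    rng: np.random.Generator,
    space: ParameterSpace,
) -> tuple[Individual, list[int]]:
    """Flip each bit independently with probability ``mutation_rate``."""
    flips = rng.random(individual.chromosome.size) < config.mutation_rate
    positions = [int(i) for i in np.flatnonzero(flips)]
    chromosome = individual.chromosome ^ flips.astype(np.uint8)
    return Individual.from_chromosome(chromosome, space), positions


def next_generation(
    current: Generation,
    config: GAConfig,
    space: ParameterSpace,
    rng: np.random.Generator,
) -> Generation:
    """Breed a new generation of unique offspring from a fully scored one.

    Pairs of parents are drawn by roulette wheel (fitness scaled per
    ``config.fitness_scaling``), recombined, and mutated;
    offspring duplicating an already accepted chromosome are rejected and
    redrawn (the campaign design calls for unique medium compositions).  With
    ``elitism=1`` the best current individual is carried over unchanged.
    """
    if not current.scored:
        raise StateError(f"generation {current.index} is not fully scored")
    seen: set[str] = set()
    offspring: list[Individual] = []
    log: list[dict] = []

    def _admit(ind: Individual, record: dict) -> None:
        ind.treatment_id = _treatment_id(current.index + 1, len(offspring))
        record["treatment_id"] = ind.treatment_id
        seen.add(ind.key)
        offspring.append(ind)
        log.append(record)

    if config.elitism:
        elite = current.best()
        _admit(
            Individual.from_chromosome(elite.chromosome.copy(), space),
            {"parents": [elite.treatment_id], "crossover_point": None,
             "mutated_bits": [], "elite": True},
        )

    attempts = 0
    while len(offspring) < config.population_size:
        pa = roulette_select(current, rng, scaling=config.fitness_scaling)
        pb = roulette_select(current, rng, scaling=config.fitness_scaling)
        child_a, child_b, cut = crossover(pa, pb, config, rng, space)
        for child in (child_a, child_b):
            if len(offspring) >= config.population_size:
                break
            mutated, flipped = mutate(child, config, rng, space)
            if mutated.key in seen:
                attempts += 1
                if attempts > config.max_redraw_attempts:
                    raise DegeneratePopulationError(
                        "could not breed enough unique offspring after "
                        f"{config.max_redraw_attempts} rejections; consider a "
                        "higher mutation rate"
                    )
                continue
            _admit(
                mutated,
                {"parents": [pa.treatment_id, pb.treatment_id],
                 "crossover_point": cut, "mutated_bits": flipped},
            )
    return Generation(index=current.index + 1, individuals=offspring, parent_log=log)


class Campaign:
    """Ask/tell driver holding the space, config, RNG, and all generations.

    ``ask()`` returns the current unscored generation (breeding it first if
    needed); ``tell()`` accepts a fitness table covering exactly its
    treatments and freezes it.  The whole campaign state round-trips through
    JSON so a run can pause between wet-lab generations.
    """

    def __init__(self, space: ParameterSpace, config: GAConfig):
        self.space = space
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.generations: list[Generation] = []
        self.current: Generation | None = None

    # -- ask/tell -------------------------------------------------------------

    def ask(self) -> Generation:
        if self.current is None:
            if not self.generations:
                self.current = init_generation(self.space, self.config, self.rng)
            else:
                self.current = next_generation(
                    self.generations[-1], self.config, self.space, self.rng
                )
            self.current.rng_state = self.rng.bit_generator.state
        return self.current

    def tell(self, results: Mapping[str, float] | pd.DataFrame) -> Generation:
        if self.current is None:
            raise StateError("no pending generation: call ask() first")
        if isinstance(results, pd.DataFrame):
            if "treatment_id" not in results.columns or "fitness" not in results.columns:
                raise ReconciliationError(
                    "results table needs 'treatment_id' and 'fitness' columns"
                )
            ids = results["treatment_id"].astype(str)
            dup = ids[ids.duplicated()].tolist()
            if dup:
                raise ReconciliationError(f"duplicated treatment ids in results: {dup}")
            results = dict(zip(ids, results["fitness"].astype(float)))
        expected = {ind.treatment_id for ind in self.current.individuals}
        got = set(results)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ReconciliationError(
                f"results do not match pending treatments; missing={missing} extra={extra}"
            )
        for ind in self.current.individuals:
            ind.fitness = max(float(results[ind.treatment_id]), 0.0)
        frozen = self.current
        self.generations.append(frozen)
        self.current = None
        return frozen

    def stagnation(self) -> float | None:
        """Relative change in best fitness between the last two scored generations."""
        if len(self.generations) < 2:
            return None
        prev = self.generations[-2].fitnesses.max()
        last = self.generations[-1].fitnesses.max()
        if prev == 0:
            return None
        return (last - prev) / prev

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "space": self.space.to_dict(),
            "config": self.config.to_dict(),
            "rng_state": _jsonable_state(self.rng.bit_generator.state),
            "generations": [g.to_dict() for g in self.generations],
            "current": self.current.to_dict() if self.current is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Campaign":
        camp = cls(ParameterSpace.from_dict(d["space"]), GAConfig.from_dict(d["config"]))
        camp.rng.bit_generator.state = d["rng_state"]
        camp.generations = [Generation.from_dict(g) for g in d["generations"]]
        camp.current = (
            Generation.from_dict(d["current"]) if d["current"] is not None else None
        )
        return camp

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "Campaign":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _jsonable_state(state: dict) -> dict:
    # PCG64 state holds plain ints; deep-copy through JSON-compatible types.
    return json.loads(json.dumps(state))
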