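"""Coalescent simulation of microsatellite loci under bounded stepwise
mutation and piecewise-constant demography.

This is the study's synthetic-data generator.  Each locus is an unlinked
microsatellite evolving under a single-step mutation model whose allele
state is confined to ``k_max`` labels: a mutation that would step outside
``[0, k_max - 1]`` is discarded (the state does not change).  Genealogies
follow the Kingman coalescent with per-generation pairwise rate ``1/(2N)``
within each epoch of a backward-in-time, piecewise-constant diploid
population-size history.

The default study design is 24 loci crossing four mutation rates
(1e-4, 2e-4, 5e-4, 1e-3 per generation) with six allelic-state caps
(3, 6, 9, 12, 15, 20), simulated in four diploid populations of 10,000:
a constant-size control (``P_C``) and three that pass through a
20-generation bottleneck of 500, 50 or 20 individuals followed by 20
generations back at 10,000 before the whole population is sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import simulate_locus_states
from .popdata import LocusSpec, PopulationSample

MUTATION_RATES = (0.0001, 0.0002, 0.0005, 0.001)
ALLELE_CAPS = (3, 6, 9, 12, 15, 20)
SCENARIO_NAMES = ("P_C", "P_500", "P_50", "P_20")

__all__ = [
    "MUTATION_RATES",
    "ALLELE_CAPS",
    "SCENARIO_NAMES",
    "Demography",
    "SimulationConfig",
    "default_loci",
    "default_scenarios",
    "simulate_locus",
    "simulate_population",
    "child_seed",
]


@dataclass(frozen=True)
class Demography:
    """Piecewise-constant diploid size history, backward in time.

    ``epochs`` is an ordered list of ``(duration_in_generations, N)`` pairs
    starting at the sampling time; the final epoch must have infinite
    duration.
    """

    epochs: tuple[tuple[float, int], ...]

    def __post_init__(self):
        if not self.epochs:
            raise ValueError("at least one epoch required")
        for d, n in self.epochs[:-1]:
            if not (d > 0 and math.isfinite(d)):
                raise ValueError("non-final epoch durations must be finite and > 0")
            if n < 1:
                raise ValueError("population sizes must be >= 1")
        d_last, n_last = self.epochs[-1]
        if math.isfinite(d_last):
            raise ValueError("final epoch must have unbounded duration")
        if n_last < 1:
            raise ValueError("population sizes must be >= 1")

    def _arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative epoch end times and sizes for the compiled kernel."""
        ends = np.cumsum([d for d, _ in self.epochs]).astype(np.float64)
        sizes = np.array([n for _, n in self.epochs], dtype=np.float64)
        return ends, sizes

    @classmethod
    def constant(cls, n: int) -> "Demography":
        return cls(epochs=((math.inf, n),))

    @classmethod
    def bottleneck(
        cls,
        n_present: int,
        n_bottleneck: int,
        n_ancestral: int,
        recovery_generations: float = 20.0,
        bottleneck_generations: float = 20.0,
    ) -> "Demography":
        """Backward in time: ``recovery_generations`` at the present size,
        ``bottleneck_generations`` at the reduced size, ancestral size
        thereafter."""
        return cls(
            epochs=(
                (recovery_generations, n_present),
                (bottleneck_generations, n_bottleneck),
                (math.inf, n_ancestral),
            )
        )


def default_loci() -> list[LocusSpec]:
    """The 24-locus design: L01..L24, mutation rate varying across rows of
    four, allelic-state cap across the six columns within a row."""
    loci = []
    i = 0
    for mu in MUTATION_RATES:
        for cap in ALLELE_CAPS:
            i += 1
            loci.append(LocusSpec(name=f"L{i:02d}", mu=mu, k_max=cap))
    return loci


def default_scenarios(
    pop_size: int = 10_000, bottlenecks: tuple[int, ...] = (500, 50, 20)
) -> dict[str, Demography]:
    """The four demographic scenarios: constant control plus three
    20-generation bottlenecks with 20 generations of recovery."""
    scenarios = {"P_C": Demography.constant(pop_size)}
    for nb in bottlenecks:
        scenarios[f"P_{nb}"] = Demography.bottleneck(pop_size, nb, pop_size)
    return scenarios


@dataclass
class SimulationConfig:
    """Full experiment configuration (defaults are the study design)."""

    loci: list[LocusSpec] = field(default_factory=default_loci)
    scenarios: dict[str, Demography] = field(default_factory=default_scenarios)
    pop_size: int = 10_000
    sample_sizes: tuple[int, ...] = (5, 20, 80, 200)
    n_resamples: int = 500
    n_replicates: int = 1000
    sd_comparison_pairs: int = 100_000
    master_seed: int = 0
    boundary: str = "discard"  # range-constraint rule: discard | reflect

    def __post_init__(self):
        if any(ns > self.pop_size for ns in self.sample_sizes):
            raise ValueError("sample sizes cannot exceed the population size")
        if self.n_resamples < 2:
            raise ValueError("need at least 2 resamples")
        if self.boundary not in ("discard", "reflect"):
            raise ValueError("boundary must be 'discard' or 'reflect'")


def child_seed(master_seed: int, *key: int) -> int:
    """Derive an independent 31-bit child seed from a master seed and an
    integer key path (counter-based, order-independent)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _simulate_locus_seeded(
    demography: Demography,
    locus: LocusSpec,
    n_copies: int,
    seed: int,
    boundary: str = "discard",
) -> np.ndarray:
    if n_copies < 2:
        raise ValueError("need at least 2 gene copies to build a genealogy")
    if boundary not in ("discard", "reflect"):
        raise ValueError("boundary must be 'discard' or 'reflect'")
    ends, sizes = demography._arrays()
    return simulate_locus_states(
        n_copies, ends, sizes, locus.mu, locus.k_max, locus.k_max // 2, seed,
        boundary == "reflect",
    )


def simulate_locus(
    demography: Demography,
    locus: LocusSpec,
    n_copies: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate the allele states of ``n_copies`` gene copies at one locus.

    The genealogy is a Kingman coalescent through ``demography``; mutations
    are a Poisson process at rate ``locus.mu`` per generation on every
    branch, each stepping the state +/-1 within ``[0, locus.k_max - 1]``
    (out-of-range steps discarded).  The root state is ``k_max // 2`` so the
    bounded walk starts centred.
    """
    seed = int(rng.integers(0, 2**31 - 1))
    return _simulate_locus_seeded(demography, locus, n_copies, seed)


def simulate_population(
    demography: Demography,
    loci: list[LocusSpec],
    n_individuals: int,
    rng: np.random.Generator,
) -> PopulationSample:
    """Simulate unlinked loci and pair consecutive gene copies into diploid
    genotypes (coalescent tip labels are exchangeable, so consecutive
    pairing is a random union of gametes)."""
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    geno = np.empty((n_individuals, len(loci), 2), dtype=np.int32)
    for j, locus in enumerate(loci):
        states = simulate_locus(demography, locus, 2 * n_individuals, rng)
        geno[:, j, :] = states.reshape(n_individuals, 2)
    return PopulationSample(population="sim", genotypes=geno, loci=[l.name for l in loci])


def _simulate_population_seeded(
    demography: Demography,
    loci: list[LocusSpec],
    n_individuals: int,
    master_seed: int,
    *key: int,
    boundary: str = "discard",
) -> PopulationSample:
    """Population simulation with per-locus counter-derived seeds, so any
    (replicate, scenario, locus) simulation is reproducible in isolation."""
    geno = np.empty((n_individuals, len(loci), 2), dtype=np.int32)
    for j, locus in enumerate(loci):
        seed = child_seed(master_seed, *key, j)
        states = _simulate_locus_seeded(
            demography, locus, 2 * n_individuals, seed, boundary
        )
        geno[:, j, :] = states.reshape(n_individuals, 2)
    return PopulationSample(population="sim", genotypes=geno, loci=[l.name for l in loci])
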