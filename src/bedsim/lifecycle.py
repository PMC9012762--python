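"""One generation of the population life cycle.

The modelled population is panmictic with discrete, non-overlapping
generations.  Each generation: virgin adults mate randomly (with a
mate-finding Allee effect at low male numbers and, in sBED, terminator males
killing mated females), surviving mothers lay Poisson clutches whose eggs
inherit gametes under homing conversion, eggs suffer unintended-viability and
resistance-lethality mortality, larvae suffer density-dependent
(Beverton–Holt) mortality, and survivors become virgin adults of random sex.

The engine book-keeps integer counts per genotype rather than individual
animals.  Every stage is an exact distributional aggregation of the
per-individual process: binomial gates for per-female Bernoulli events,
multinomial draws for mate sets, and Poisson superposition/thinning for egg
production (a mother's Poisson clutch split uniformly over her ``k`` mates is
a set of independent Poisson(λ/k) counts per mate; terminator survival
factorises over mates, so a surviving mother's mates remain i.i.d. from the
kill-tilted male distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import lgamma, log

import numpy as np
from scipy.special import expit

from .fitness_effects import (
    DesignConfig,
    egg_survival_probability,
    mother_fecundity_factor,
    terminator_kill_probability,
    unintended_reproductive_factor,
)
from .genetics import (
    ALLELES,
    Genotype,
    all_genotypes,
    genotype_index,
    offspring_distribution,
)


@dataclass(frozen=True)
class PopulationConfig:
    """Demographic parameters of the target population.

    Parameters
    ----------
    fecundity:
        Expected fertile eggs per mother (Poisson mean), before drive costs.
    larval_survival:
        Density-independent larval-to-adult survival.  Together with
        fecundity this sets the low-density growth rate
        ``Rm = fecundity × larval_survival / 2`` (expected adult daughters
        per adult female without competition) and the critical genetic load
        ``Lc = 1 − 1/Rm``.
    carrying_capacity:
        Equilibrium adult population size K.
    critical_population_size:
        Virgin-male count at which the mate-finding Allee effect halves both
        the probability of mating and the expected mate number.
    polyandry_degree:
        Maximum (and modal) number of mates per female; mate numbers follow a
        Poisson(2 × polyandry_degree) truncated to {1..polyandry_degree}.
    max_generations:
        Default simulation horizon.
    allee_argument:
        Which census the Allee sigmoid reads: all virgin ``"adults"``
        (default — the sigmoid is a function of the population size) or
        virgin ``"males"`` only.
    """

    fecundity: float = 48.0
    larval_survival: float = 0.5
    carrying_capacity: int = 50_000
    critical_population_size: float = 250.0
    polyandry_degree: int = 3
    max_generations: int = 36
    allee_argument: str = "adults"

    def __post_init__(self) -> None:
        if self.fecundity <= 0:
            raise ValueError("fecundity must be positive")
        if not (0.0 < self.larval_survival <= 1.0):
            raise ValueError("larval_survival must be in (0, 1]")
        if self.larval_survival <= 2.0 / self.fecundity:
            raise ValueError(
                "larval_survival must exceed 2/fecundity (Rm must exceed 1, "
                "otherwise the population cannot replace itself)"
            )
        if self.carrying_capacity <= 0:
            raise ValueError("carrying_capacity must be positive")
        if self.critical_population_size < 0:
            raise ValueError("critical_population_size must be >= 0")
        if int(self.polyandry_degree) != self.polyandry_degree or self.polyandry_degree < 1:
            raise ValueError("polyandry_degree must be an integer >= 1")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.allee_argument not in ("males", "adults"):
            raise ValueError("allee_argument must be 'males' or 'adults'")

    @property
    def rm(self) -> float:
        """Low-density growth rate Rm = F·Ls/2."""
        return self.fecundity * self.larval_survival / 2.0

    @property
    def critical_load(self) -> float:
        """Critical genetic load Lc = 1 − 1/Rm."""
        return 1.0 - 1.0 / self.rm

    @property
    def n50(self) -> float:
        """Beverton–Holt half-saturation constant K/(Ls − 2/F)."""
        return self.carrying_capacity / (self.larval_survival - 2.0 / self.fecundity)

    def with_(self, **overrides) -> "PopulationConfig":
        return replace(self, **overrides)


def allee_factor(count: float, critical: float) -> float:
    """Mate-finding Allee multiplier: a logistic sigmoid of the virgin-adult
    census, equal to 0.5 at the critical population size and saturating to 1
    at large counts.  Scales both the probability that a female mates (CM)
    and the expected number of mates (NM).

    A critical size of 0 disables the effect entirely (factor 1 at any
    census) rather than leaving the residual ≥ 0.5 sigmoid floor.
    """
    if count < 0 or critical < 0:
        raise ValueError("counts must be non-negative")
    if critical == 0:
        return 1.0
    return float(expit(0.01 * (count - critical)))


def mate_count_pmf(polyandry_degree: int, nm: float) -> np.ndarray:
    """Pmf of mates per mating female on {1..P}.

    Poisson with mean ``2·P·nm`` truncated to {1..P}; ``nm`` is the Allee
    number-of-mates multiplier (1 far from the threshold).
    """
    P = int(polyandry_degree)
    if P < 1:
        raise ValueError("polyandry_degree must be >= 1")
    if not (0.0 < nm <= 1.0):
        raise ValueError("nm must be in (0, 1]")
    lam = 2.0 * P * nm
    k = np.arange(1, P + 1)
    logw = k * log(lam) - np.array([lgamma(x + 1) for x in k])
    w = np.exp(logw - logw.max())
    return w / w.sum()


def sample_mate_count(polyandry_degree: int, nm: float, rng: np.random.Generator) -> int:
    """Draw one female's mate count from the truncated Poisson."""
    pmf = mate_count_pmf(polyandry_degree, nm)
    return int(rng.choice(np.arange(1, polyandry_degree + 1), p=pmf))


def beverton_holt_survival(n_larvae: int, cfg: PopulationConfig) -> float:
    """Larval survival probability Ls·N50/(N + N50).

    Compensatory density dependence with half-saturation
    ``N50 = K/(Ls − 2/F)``: survival tends to the density-independent rate
    Ls as N→0 and the expected adult output has a fixed point at the
    carrying capacity K.
    """
    if n_larvae < 0:
        raise ValueError("n_larvae must be >= 0")
    n50 = cfg.n50
    return cfg.larval_survival * n50 / (n_larvae + n50)


def genetic_load(
    virgin_female_count: int, viable_larval_eggs: int, cfg: PopulationConfig
) -> float:
    """Realised genetic load of one generation.

    The proportional reduction, relative to Rm, of expected adult daughters
    per virgin female with density-dependent mortality excluded:
    ``1 − (0.5 · Ls · viable_larval_eggs / females) / Rm``.  Zero in
    expectation for a drive-free population; 1 when reproduction fails
    entirely (returned, flagged, when there are no females).
    """
    if virgin_female_count <= 0:
        return 1.0
    w = 0.5 * cfg.larval_survival * viable_larval_eggs / virgin_female_count
    return 1.0 - w / cfg.rm


@dataclass
class PopulationState:
    """Counts of virgin adults per genotype at one generation."""

    generation: int
    females: np.ndarray  # int64, length = number of genotypes
    males: np.ndarray

    def __post_init__(self) -> None:
        self.females = np.asarray(self.females, dtype=np.int64)
        self.males = np.asarray(self.males, dtype=np.int64)
        if self.females.shape != self.males.shape:
            raise ValueError("female and male count vectors must have equal length")
        if (self.females < 0).any() or (self.males < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total_females(self) -> int:
        return int(self.females.sum())

    @property
    def total_males(self) -> int:
        return int(self.males.sum())

    @property
    def total_adults(self) -> int:
        return self.total_females + self.total_males

    @classmethod
    def from_counts(
        cls,
        n_loci: int,
        females: dict[str, int],
        males: dict[str, int],
        generation: int = 0,
    ) -> "PopulationState":
        """Build a state from ``{"DW/WW": count, ...}`` style mappings."""
        size = 6**n_loci
        f = np.zeros(size, dtype=np.int64)
        m = np.zeros(size, dtype=np.int64)
        for target, mapping in ((f, females), (m, males)):
            for s, n in mapping.items():
                g = Genotype.from_string(s)
                if g.n_loci != n_loci:
                    raise ValueError(f"genotype {s!r} has wrong locus count")
                target[genotype_index(g)] += n
        return cls(generation=generation, females=f, males=m)


@dataclass(frozen=True)
class GenerationRecord:
    """Summary of the virgin-adult cohort of one generation."""

    generation: int
    adults: int
    relative_size: float
    allele_frequencies: np.ndarray  # (n_loci, 3) in W, D, R order
    genetic_load: float
    collapsed: bool


@dataclass
class MatingResult:
    """Aggregated outcome of the mating stage.

    ``mother_counts[g, k-1]`` is the number of surviving mothers of genotype
    ``g`` with ``k`` mates; ``mate_counts[g, k-1, f]`` the total number of
    their mate slots held by males of genotype ``f``.  Each mother carries
    equal sperm shares from all her mates.
    """

    mother_counts: np.ndarray  # (G, P) int64
    mate_counts: np.ndarray  # (G, P, G) int64
    n_candidates: int = 0
    n_killed: int = 0

    @property
    def n_mothers(self) -> int:
        return int(self.mother_counts.sum())


class Simulation:
    """Precomputed per-genotype tables plus the stage operators for one
    (design, population) configuration."""

    def __init__(self, design: DesignConfig, population: PopulationConfig):
        self.design = design
        self.population = population
        self.genotypes: tuple[Genotype, ...] = all_genotypes(design.n_loci)
        G = len(self.genotypes)
        self.n_genotypes = G
        h, r = design.homing_efficiency, design.resistance_formation

        self.fecundity_factor = np.array(
            [mother_fecundity_factor(g, design) for g in self.genotypes]
        )
        self.male_weight = np.array(
            [
                unintended_reproductive_factor(g, design.unintended_reproductive_cost)
                for g in self.genotypes
            ]
        )
        self.kill_probability = np.array(
            [terminator_kill_probability(g, design) for g in self.genotypes]
        )
        self.egg_survival = np.array(
            [egg_survival_probability(g, design) for g in self.genotypes]
        )
        # offspring[m, f, e]: genotype distribution of an egg of mother m, father f
        self.offspring = np.zeros((G, G, G))
        for i, gm in enumerate(self.genotypes):
            for j, gf in enumerate(self.genotypes):
                for child, p in offspring_distribution(gm, gf, h, r).items():
                    self.offspring[i, j, genotype_index(child)] = p
        # allele_counts[locus, allele, g]: copies of each allele in genotype g
        self.allele_counts = np.zeros((design.n_loci, 3, G))
        for gi, g in enumerate(self.genotypes):
            for locus, lg in enumerate(g.loci):
                for ai, allele in enumerate(ALLELES):
                    self.allele_counts[locus, ai, gi] = lg.count(allele)

    # ------------------------------------------------------------------ #

    def allele_frequencies(self, state: PopulationState) -> np.ndarray:
        """Per-locus W/D/R frequencies among virgin adults, shape (n_loci, 3)."""
        counts = state.females + state.males
        total = 2.0 * counts.sum()
        if total == 0:
            return np.full((self.design.n_loci, 3), np.nan)
        return (self.allele_counts @ counts) / total

    def mating_stage(self, state: PopulationState, rng: np.random.Generator) -> MatingResult:
        """Random mating with Allee gating and terminator kills.

        Each virgin female becomes a mating candidate with probability CM,
        draws a truncated-Poisson mate count (mean scaled by NM), and picks
        mates with replacement from the male pool weighted by the unintended
        reproductive cost.  In sBED each mate independently kills her with
        his terminator kill probability; killed females leave no offspring.
        """
        cfg = self.population
        P = int(cfg.polyandry_degree)
        G = self.n_genotypes
        empty = MatingResult(
            mother_counts=np.zeros((G, P), dtype=np.int64),
            mate_counts=np.zeros((G, P, G), dtype=np.int64),
        )
        if state.total_females == 0 or state.total_males == 0:
            return empty

        census = state.total_males if cfg.allee_argument == "males" else state.total_adults
        a = allee_factor(census, cfg.critical_population_size)
        cm = nm = a

        candidates = rng.binomial(state.females, cm)
        n_candidates = int(candidates.sum())
        if n_candidates == 0:
            return replace(empty, n_candidates=0)

        # mate counts per candidate: truncated Poisson(2·P·nm) on {1..P}
        pmf = mate_count_pmf(P, nm)
        n_gk = rng.multinomial(candidates, pmf)  # (G, P)

        weights = state.males * self.male_weight
        total_w = weights.sum()
        if total_w <= 0.0:
            return replace(empty, n_candidates=n_candidates, n_killed=0)
        q = weights / total_w
        per_mate_survival = float(np.clip(q @ (1.0 - self.kill_probability), 0.0, 1.0))

        k_arr = np.arange(1, P + 1)
        if per_mate_survival <= 0.0:
            return replace(empty, n_candidates=n_candidates, n_killed=n_candidates)
        mothers = rng.binomial(n_gk, per_mate_survival**k_arr)  # (G, P)
        n_killed = int(n_gk.sum() - mothers.sum())

        # surviving mothers' mates are i.i.d. from the kill-tilted distribution
        q_tilted = q * (1.0 - self.kill_probability) / per_mate_survival
        q_tilted = q_tilted / q_tilted.sum()
        mate_counts = rng.multinomial(mothers * k_arr, q_tilted)  # (G, P, G)
        return MatingResult(
            mother_counts=mothers,
            mate_counts=mate_counts,
            n_candidates=n_candidates,
            n_killed=n_killed,
        )

    def reproduction_stage(
        self, mating: MatingResult, rng: np.random.Generator
    ) -> np.ndarray:
        """Egg counts per genotype from the mothers' Poisson clutches.

        A mother's clutch is Poisson with mean fecundity × her fecundity
        multiplier; each egg takes its maternal gamete from her genotype and
        its paternal gamete from a uniformly chosen mate (equal sperm
        shares).  Aggregated as Poisson superposition over (mother genotype,
        father genotype) pairings, which is distributionally identical to
        per-egg sampling.
        """
        lam = self.population.fecundity * self.fecundity_factor  # per mother genotype
        k_arr = np.arange(1, self.population.polyandry_degree + 1)
        # expected eggs per mate slot: lam[g]/k for a mother with k mates
        pair_rate = np.einsum(
            "gkf,g,k->gf", mating.mate_counts, lam, 1.0 / k_arr
        )
        egg_rate = np.einsum("gf,gfe->e", pair_rate, self.offspring)
        return rng.poisson(egg_rate).astype(np.int64)

    def generation_step(
        self, state: PopulationState, rng: np.random.Generator
    ) -> tuple[PopulationState, GenerationRecord]:
        """Advance one full generation; returns the next virgin-adult state
        and its summary record.

        The record's ``collapsed`` flag fires exactly when no female becomes
        a mother, no mother produces viable eggs (eggs surviving to the
        larval stage), or no larva survives to become an adult virgin
        female.
        """
        cfg = self.population
        G = self.n_genotypes
        n_virgin_females = state.total_females

        mating = self.mating_stage(state, rng)
        if mating.n_mothers == 0:
            return self._collapse(state, n_viable=0)

        eggs = self.reproduction_stage(mating, rng)
        viable = rng.binomial(eggs, self.egg_survival)
        n_viable = int(viable.sum())
        load = genetic_load(n_virgin_females, n_viable, cfg)
        if n_viable == 0:
            return self._collapse(state, n_viable=0)

        p_surv = beverton_holt_survival(n_viable, cfg)
        adults = rng.binomial(viable, p_surv)
        females = rng.binomial(adults, 0.5)
        males = adults - females

        next_state = PopulationState(
            generation=state.generation + 1, females=females, males=males
        )
        collapsed = next_state.total_females == 0
        record = GenerationRecord(
            generation=next_state.generation,
            adults=next_state.total_adults,
            relative_size=next_state.total_adults / cfg.carrying_capacity,
            allele_frequencies=self.allele_frequencies(next_state),
            genetic_load=load,
            collapsed=collapsed,
        )
        return next_state, record

    def _collapse(
        self, state: PopulationState, n_viable: int
    ) -> tuple[PopulationState, GenerationRecord]:
        G = self.n_genotypes
        zero = np.zeros(G, dtype=np.int64)
        next_state = PopulationState(
            generation=state.generation + 1, females=zero, males=zero.copy()
        )
        record = GenerationRecord(
            generation=next_state.generation,
            adults=0,
            relative_size=0.0,
            allele_frequencies=np.full((self.design.n_loci, 3), np.nan),
            genetic_load=genetic_load(state.total_females, n_viable, self.population),
            collapsed=True,
        )
        return next_state, record
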