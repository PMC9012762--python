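"""Release scenarios, replicate execution, and parameter sweeps.

A scenario starts from a wild-type population in equilibrium at carrying
capacity (equal sex ratio) into which transgenic males are released at
generation zero: homozygous for one construct each in BED designs (AAbb and
aaBB cohorts), drive heterozygous (Cc) in single-drive designs.  Replicates
run independently up to a horizon; a replicate's population is *eliminated*
when a generation collapses (no mothers, no viable eggs, or no adult
daughters).  The headline metric is the fast elimination rate: the percentage
of replicates eliminated within 36 generations of release.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .fitness_effects import DesignConfig
from .genetics import Genotype, genotype_index
from .lifecycle import PopulationConfig, PopulationState, Simulation


@dataclass(frozen=True)
class ReleaseScheme:
    """Single- or multi-bout release of transgenic males.

    ``males_per_drive`` males are released per drive construct at each listed
    generation (two cohorts in BED designs, one in SD designs), joining the
    virgin male pool.
    """

    males_per_drive: int = 250
    generations: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if self.males_per_drive < 0:
            raise ValueError("males_per_drive must be >= 0")
        if any(g < 0 for g in self.generations):
            raise ValueError("release generations must be >= 0")

    def release_counts(self, design: DesignConfig) -> np.ndarray:
        """Released-male counts per genotype for one bout."""
        counts = np.zeros(6**design.n_loci, dtype=np.int64)
        if design.n_loci == 2:
            cohorts = ("DD/WW", "WW/DD")  # AAbb and aaBB homozygotes
        else:
            cohorts = ("DW",)  # Cc heterozygotes
        for s in cohorts:
            counts[genotype_index(Genotype.from_string(s))] += self.males_per_drive
        return counts

    def with_(self, **overrides) -> "ReleaseScheme":
        return replace(self, **overrides)


def initialize_population(
    population: PopulationConfig, design: DesignConfig, release: ReleaseScheme
) -> PopulationState:
    """Wild-type equilibrium at K (equal sexes) plus any generation-0 bout."""
    G = 6**design.n_loci
    females = np.zeros(G, dtype=np.int64)
    males = np.zeros(G, dtype=np.int64)
    K = population.carrying_capacity
    females[0] = K // 2
    males[0] = K - K // 2
    if 0 in release.generations:
        males += release.release_counts(design)
    return PopulationState(generation=0, females=females, males=males)


@dataclass
class ReplicateSummary:
    """Per-generation trajectories and elimination summary of one scenario.

    Trajectory arrays have shape ``(n_reps, horizon + 1)`` indexed by
    generation (0 = census at release).  After a replicate collapses its
    adult counts are 0 and its load/frequency entries are NaN.
    """

    design: DesignConfig
    population: PopulationConfig
    release: ReleaseScheme
    n_reps: int
    horizon: int
    seed: int
    elimination_generation: np.ndarray  # float, NaN when not eliminated
    adults: np.ndarray  # (n_reps, horizon+1) int64
    genetic_load: np.ndarray  # (n_reps, horizon+1) float, NaN at gen 0
    allele_frequencies: np.ndarray  # (n_reps, horizon+1, n_loci, 3)

    @property
    def relative_size(self) -> np.ndarray:
        return self.adults / self.population.carrying_capacity

    @property
    def eliminated(self) -> np.ndarray:
        return ~np.isnan(self.elimination_generation)

    def fast_elimination_rate(self, within: int | None = None) -> float:
        """Percentage of replicates eliminated within ``within`` generations
        (default: the scenario horizon)."""
        within = self.horizon if within is None else within
        g = self.elimination_generation
        return 100.0 * float(np.mean(self.eliminated & (g <= within)))

    def elimination_rate_between(self, lo: int, hi: int) -> float:
        """Percentage of replicates with collapse generation in (lo, hi]."""
        g = np.where(self.eliminated, self.elimination_generation, -1.0)
        return 100.0 * float(np.mean((g > lo) & (g <= hi)))

    def mean_elimination_generation(self) -> float:
        """Mean collapse generation among eliminated replicates."""
        if not self.eliminated.any():
            return float("nan")
        return float(np.nanmean(self.elimination_generation))

    def mean_adults(self, generation: int) -> float:
        """Mean adult count at one generation (collapsed replicates count 0)."""
        return float(self.adults[:, generation].mean())

    def mean_relative_size(self, generations: slice | list[int]) -> float:
        """Mean relative population size over a generation range."""
        return float(self.relative_size[:, generations].mean())

    def mean_load(self, generations: slice | list[int]) -> float:
        """Mean genetic load over a generation range (surviving replicates)."""
        return float(np.nanmean(self.genetic_load[:, generations]))

    def envelope(self) -> pd.DataFrame:
        """Per-generation mean/min/max of adults and mean load."""
        rel = self.relative_size
        return pd.DataFrame(
            {
                "generation": np.arange(self.horizon + 1),
                "mean_adults": self.adults.mean(axis=0),
                "min_adults": self.adults.min(axis=0),
                "max_adults": self.adults.max(axis=0),
                "mean_relative_size": rel.mean(axis=0),
                "mean_load": np.nanmean(
                    np.where(np.isnan(self.genetic_load), np.nan, self.genetic_load),
                    axis=0,
                ),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-replicate trajectories, truncated at collapse."""
        rows = []
        n_loci = self.design.n_loci
        for rep in range(self.n_reps):
            elim = self.elimination_generation[rep]
            last = int(elim) if not np.isnan(elim) else self.horizon
            for gen in range(last + 1):
                row = {
                    "replicate": rep,
                    "generation": gen,
                    "adults": int(self.adults[rep, gen]),
                    "relative_size": self.adults[rep, gen]
                    / self.population.carrying_capacity,
                    "genetic_load": self.genetic_load[rep, gen],
                    "collapsed": bool(not np.isnan(elim) and gen == last),
                }
                for locus in range(n_loci):
                    for ai, name in enumerate("WDR"):
                        row[f"freq_{name}_locus{locus + 1}"] = self.allele_frequencies[
                            rep, gen, locus, ai
                        ]
                rows.append(row)
        return pd.DataFrame(rows)


def run_replicates(
    design: DesignConfig,
    population: PopulationConfig,
    release: ReleaseScheme | None = None,
    n_reps: int = 100,
    horizon: int | None = None,
    seed: int | np.random.SeedSequence = 0,
    progress=None,
) -> ReplicateSummary:
    """Run independent replicate simulations of one release scenario.

    Each replicate draws from its own stream spawned from ``seed``; results
    are bit-reproducible for a given seed.  ``progress``, if given, is called
    with the replicate index after each replicate finishes.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    release = release if release is not None else ReleaseScheme()
    horizon = population.max_generations if horizon is None else horizon
    sim = Simulation(design, population)
    G = sim.n_genotypes
    n_loci = design.n_loci

    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    streams = root.spawn(n_reps)

    adults = np.zeros((n_reps, horizon + 1), dtype=np.int64)
    load = np.full((n_reps, horizon + 1), np.nan)
    freqs = np.full((n_reps, horizon + 1, n_loci, 3), np.nan)
    elim = np.full(n_reps, np.nan)

    later_bouts = sorted(g for g in release.generations if g > 0)
    for rep in range(n_reps):
        rng = np.random.default_rng(streams[rep])
        state = initialize_population(population, design, release)
        adults[rep, 0] = state.total_adults
        freqs[rep, 0] = sim.allele_frequencies(state)
        for _ in range(horizon):
            if state.generation in later_bouts:
                state.males = state.males + release.release_counts(design)
            state, rec = sim.generation_step(state, rng)
            g = rec.generation
            adults[rep, g] = rec.adults
            load[rep, g] = rec.genetic_load
            if not rec.collapsed:
                freqs[rep, g] = rec.allele_frequencies
            if rec.collapsed:
                elim[rep] = g
                break
        if progress is not None:
            progress(rep)

    seed_int = root.entropy if isinstance(root.entropy, int) else 0
    return ReplicateSummary(
        design=design,
        population=population,
        release=release,
        n_reps=n_reps,
        horizon=horizon,
        seed=int(seed_int),
        elimination_generation=elim,
        adults=adults,
        genetic_load=load,
        allele_frequencies=freqs,
    )


def derived_quantities(population: PopulationConfig) -> dict[str, float]:
    """Low-density growth rate Rm, critical load Lc, and Beverton–Holt N50."""
    return {
        "Rm": population.rm,
        "Lc": population.critical_load,
        "N50": population.n50,
    }


def homing_cost_grid(
    design: DesignConfig,
    population: PopulationConfig,
    h_values,
    cost_values,
    release: ReleaseScheme | None = None,
    n_reps: int = 100,
    horizon: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fast-elimination-rate grid over homing efficiency × unintended costs.

    For each cell the resistance formation rate is set to half the complement
    of homing efficiency, ``r = (1 - h)/2``, and both unintended costs
    (reproductive and viability) are set to the cost value.
    """
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(list(h_values)) * len(list(cost_values)))
    rows = []
    i = 0
    for h in h_values:
        for c in cost_values:
            cfg = design.with_(
                homing_efficiency=h,
                resistance_formation=(1.0 - h) / 2.0,
                unintended_reproductive_cost=c,
                unintended_viability_cost=c,
            )
            summary = run_replicates(
                cfg, population, release, n_reps=n_reps, horizon=horizon,
                seed=streams[i],
            )
            rows.append(
                {
                    "homing_efficiency": h,
                    "unintended_fitness_costs": c,
                    "fast_elimination_rate": summary.fast_elimination_rate(),
                    "mean_elimination_generation": summary.mean_elimination_generation(),
                }
            )
            i += 1
    return pd.DataFrame(rows)


#: Parameters accepted by :func:`scalar_sweep` and where they live.
_SWEEPABLE = {
    "dominance_degree": "design",
    "terminator_efficiency": "design",
    "resistance_functionality": "design",
    "homing_efficiency": "design",
    "fecundity": "population",
    "rm": "population",
    "polyandry_degree": "population",
    "critical_population_size": "population",
    "release_size": "release",
}


def scalar_sweep(
    parameter: str,
    values,
    design: DesignConfig,
    population: PopulationConfig,
    release: ReleaseScheme | None = None,
    n_reps: int = 100,
    horizon: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One-parameter sweep; one scenario summary row per value.

    ``rm`` sweeps adjust fecundity via ``F = 2·Rm/Ls``; ``release_size`` is
    the number of released males per drive construct.
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(
            f"unknown sweep parameter {parameter!r}; "
            f"expected one of {sorted(_SWEEPABLE)}"
        )
    release = release if release is not None else ReleaseScheme()
    values = list(values)
    streams = np.random.SeedSequence(seed).spawn(len(values))
    rows = []
    for stream, v in zip(streams, values):
        d, p, rel = design, population, release
        where = _SWEEPABLE[parameter]
        if where == "design":
            d = design.with_(**{parameter: v})
        elif parameter == "rm":
            p = population.with_(fecundity=2.0 * v / population.larval_survival)
        elif parameter == "polyandry_degree":
            p = population.with_(polyandry_degree=int(v))
        elif parameter == "release_size":
            rel = release.with_(males_per_drive=int(v))
        else:
            p = population.with_(**{parameter: v})
        summary = run_replicates(d, p, rel, n_reps=n_reps, horizon=horizon, seed=stream)
        rows.append(
            {
                "parameter": parameter,
                "value": v,
                "fast_elimination_rate": summary.fast_elimination_rate(),
                "mean_elimination_generation": summary.mean_elimination_generation(),
            }
        )
    return pd.DataFrame(rows)
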