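"""Life-cycle stages: Allee effect, polyandry, reproduction, density
dependence, collapse detection, and the aggregated-engine equivalence."""

import numpy as np
import pytest
from scipy.stats import chisquare

from bedsim.fitness_effects import DesignConfig
from bedsim.genetics import Genotype, offspring_distribution
from bedsim.lifecycle import (
    PopulationConfig,
    PopulationState,
    Simulation,
    allee_factor,
    beverton_holt_survival,
    genetic_load,
    mate_count_pmf,
    sample_mate_count,
)


class TestAlleeFactor:
    def test_half_at_critical_size(self):
        assert allee_factor(250, 250) == pytest.approx(0.5)

    def test_saturates_at_large_counts(self):
        assert allee_factor(50_000, 250) == pytest.approx(1.0, abs=1e-12)

    def test_value_at_zero_count(self):
        assert allee_factor(0, 250) == pytest.approx(1 - 1 / (1 + np.exp(-2.5)))
        assert allee_factor(0, 250) == pytest.approx(0.07585818, abs=1e-7)

    def test_zero_critical_disables_the_effect(self):
        for count in (0, 10, 250, 50_000):
            assert allee_factor(count, 0) == 1.0

    def test_strictly_increasing_in_count(self):
        counts = np.linspace(0, 2000, 50)
        vals = [allee_factor(c, 250) for c in counts]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            allee_factor(-1, 250)


class TestMateCounts:
    def test_truncated_poisson_pmf_at_default_polyandry(self):
        # lambda = 6 truncated to {1,2,3}: weights 6:18:36
        assert mate_count_pmf(3, 1.0) == pytest.approx([0.1, 0.3, 0.6])

    def test_monandry_is_degenerate(self):
        assert mate_count_pmf(1, 1.0) == pytest.approx([1.0])
        rng = np.random.default_rng(0)
        assert all(sample_mate_count(1, 1.0, rng) == 1 for _ in range(20))

    def test_low_allee_concentrates_on_single_mating(self):
        pmf = mate_count_pmf(3, 1e-6)
        assert pmf[0] > 0.999

    def test_sample_within_support(self, rng):
        draws = [sample_mate_count(3, 0.8, rng) for _ in range(200)]
        assert set(draws) <= {1, 2, 3}

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            mate_count_pmf(0, 1.0)
        with pytest.raises(ValueError):
            mate_count_pmf(3, 0.0)


class TestBevertonHolt:
    def test_half_saturation_constant_and_equilibrium(self):
        cfg = PopulationConfig()  # F=48, Ls=0.5, K=50000
        assert cfg.n50 == pytest.approx(109090.90909, abs=1e-4)
        # at the wild-type equilibrium egg output, survival is exactly 2/F
        n_eggs = cfg.carrying_capacity // 2 * 48
        s = beverton_holt_survival(n_eggs, cfg)
        assert s == pytest.approx(1 / 24)
        assert n_eggs * s == pytest.approx(cfg.carrying_capacity)

    def test_density_independent_limit(self):
        cfg = PopulationConfig()
        assert beverton_holt_survival(0, cfg) == pytest.approx(cfg.larval_survival)

    def test_half_survival_at_n50(self):
        cfg = PopulationConfig()
        assert beverton_holt_survival(int(cfg.n50), cfg) == pytest.approx(
            cfg.larval_survival / 2, rel=1e-5
        )

    def test_strictly_decreasing_in_density(self):
        cfg = PopulationConfig()
        ns = np.linspace(0, 5e6, 40).astype(int)
        vals = [beverton_holt_survival(n, cfg) for n in ns]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_population_below_replacement_rejected(self):
        with pytest.raises(ValueError):
            PopulationConfig(fecundity=4.0, larval_survival=0.5)  # Ls <= 2/F


class TestGeneticLoad:
    def test_zero_at_wild_type_expectation(self):
        cfg = PopulationConfig()
        # equilibrium: each female yields F viable eggs in expectation
        assert genetic_load(1000, 1000 * 48, cfg) == pytest.approx(0.0)

    def test_one_when_reproduction_fails(self):
        cfg = PopulationConfig()
        assert genetic_load(1000, 0, cfg) == 1.0
        assert genetic_load(0, 0, cfg) == 1.0

    def test_critical_load_from_defaults(self):
        cfg = PopulationConfig()
        assert cfg.rm == 12.0
        assert cfg.critical_load == pytest.approx(1 - 1 / 12)


def _wild_state(n_loci: int, n_f: int, n_m: int) -> PopulationState:
    wt = "WW" if n_loci == 1 else "WW/WW"
    return PopulationState.from_counts(n_loci, {wt: n_f}, {wt: n_m})


class TestGenerationStep:
    def test_drive_free_population_fluctuates_around_carrying_capacity(self):
        """Stochastic Beverton-Holt equilibrium: 30 replicates at K=5000 stay
        within 3 standard errors of K over 36 generations, and allele
        frequencies remain pure wild type."""
        pop = PopulationConfig(carrying_capacity=5000, critical_population_size=25)
        sim = Simulation(DesignConfig.preset("sBED", "RS"), pop)
        means = []
        for rep in range(30):
            rng = np.random.default_rng(1000 + rep)
            state = _wild_state(2, 2500, 2500)
            sizes = []
            for _ in range(36):
                state, rec = sim.generation_step(state, rng)
                sizes.append(rec.adults)
                assert not rec.collapsed
                assert rec.allele_frequencies[:, 0] == pytest.approx([1.0, 1.0])
            means.append(np.mean(sizes))
        mean, se = np.mean(means), np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(mean - 5000) < 3 * max(se, 1.0)

    def test_drive_free_load_is_zero_in_expectation(self):
        pop = PopulationConfig(carrying_capacity=5000, critical_population_size=25)
        sim = Simulation(DesignConfig.preset("ffSD", "IS"), pop)
        rng = np.random.default_rng(7)
        loads = []
        state = _wild_state(1, 2500, 2500)
        for _ in range(36):
            state, rec = sim.generation_step(state, rng)
            loads.append(rec.genetic_load)
            assert rec.genetic_load <= 1.0
        assert abs(np.mean(loads)) < 0.01

    def test_collapse_when_no_males(self):
        sim = Simulation(DesignConfig.preset("ffSD", "RS"), PopulationConfig())
        state = PopulationState.from_counts(1, {"WW": 1000}, {})
        _, rec = sim.generation_step(state, np.random.default_rng(0))
        assert rec.collapsed and rec.adults == 0 and rec.genetic_load == 1.0

    def test_collapse_when_all_males_are_perfect_terminators(self):
        cfg = DesignConfig.preset("sBED", "IS", terminator_efficiency=1.0)
        sim = Simulation(cfg, PopulationConfig(carrying_capacity=2000))
        state = PopulationState.from_counts(2, {"WW/WW": 1000}, {"DD/DD": 1000})
        _, rec = sim.generation_step(state, np.random.default_rng(1))
        assert rec.collapsed

    def test_collapse_when_all_mothers_sterile(self):
        cfg = DesignConfig.preset("ffBED", "IS")  # AABB mothers sterile
        sim = Simulation(cfg, PopulationConfig(carrying_capacity=2000))
        state = PopulationState.from_counts(2, {"DD/DD": 1000}, {"WW/WW": 1000})
        _, rec = sim.generation_step(state, np.random.default_rng(2))
        assert rec.collapsed and rec.genetic_load == 1.0

    def test_no_collapse_in_healthy_population(self):
        sim = Simulation(DesignConfig.preset("sBED", "RS"),
                         PopulationConfig(carrying_capacity=2000))
        state = _wild_state(2, 1000, 1000)
        _, rec = sim.generation_step(state, np.random.default_rng(3))
        assert not rec.collapsed and rec.adults > 0

    def test_terminator_mating_kills_reduce_mothers(self):
        """With perfect terminators at half the male pool, far fewer mothers
        survive mating than with wild-type males only."""
        cfg = DesignConfig.preset("sBED", "IS", terminator_efficiency=1.0)
        pop = PopulationConfig(carrying_capacity=4000)
        sim = Simulation(cfg, pop)
        rng = np.random.default_rng(11)
        state = PopulationState.from_counts(
            2, {"WW/WW": 2000}, {"WW/WW": 1000, "DD/DD": 1000}
        )
        mating = sim.mating_stage(state, rng)
        # each mate is a terminator w.p. ~1/2, mate counts 1-3 -> survival
        # E[0.5^k] with pmf (0.1, 0.3, 0.6) = 0.2
        assert mating.n_mothers / mating.n_candidates == pytest.approx(0.2, abs=0.05)


class TestAggregatedSamplingEquivalence:
    def test_egg_genotypes_match_exact_cross_distribution(self):
        """Goodness of fit of aggregated multinomial egg generation against
        the exact offspring distribution for a 200-mother instance."""
        cfg = DesignConfig(design="ffSD", homing_efficiency=0.9,
                           resistance_formation=0.05, intended_fecundity_cost=1.0)
        pop = PopulationConfig(carrying_capacity=400, critical_population_size=0)
        sim = Simulation(cfg, pop)
        rng = np.random.default_rng(42)
        state = PopulationState.from_counts(1, {"DW": 200}, {"WW": 200})
        mating = sim.mating_stage(state, rng)
        eggs = sim.reproduction_stage(mating, rng)
        expected_dist = offspring_distribution(
            Genotype.from_string("DW"), Genotype.from_string("WW"), 0.9, 0.05
        )
        # {WW: 0.025, WD: 0.95, WR: 0.025}
        idx = {str(g): p for g, p in expected_dist.items()}
        observed = np.array([eggs[0], eggs[1], eggs[2]])  # WW, WD, WR
        assert eggs[3:].sum() == 0
        expected = np.array([idx["WW"], idx["WD"], idx["WR"]]) * observed.sum()
        stat, p = chisquare(observed, expected)
        assert p > 1e-3

    def test_mate_count_distribution_matches_truncated_poisson(self):
        cfg = DesignConfig.preset("sBED", "IS", terminator_efficiency=0.0)
        pop = PopulationConfig(carrying_capacity=40_000, critical_population_size=0)
        sim = Simulation(cfg, pop)
        rng = np.random.default_rng(5)
        state = _wild_state(2, 20_000, 20_000)
        mating = sim.mating_stage(state, rng)
        counts = mating.mother_counts.sum(axis=0)
        stat, p = chisquare(counts, mate_count_pmf(3, 1.0) * counts.sum())
        assert p > 1e-3


def test_reproduction_scales_with_fecundity_factors():
    """Sterile mothers lay nothing; wild-type mothers lay ~F eggs each."""
    cfg = DesignConfig.preset("ffSD", "IS")
    pop = PopulationConfig(carrying_capacity=1000, critical_population_size=0)
    sim = Simulation(cfg, pop)
    rng = np.random.default_rng(9)
    sterile = PopulationState.from_counts(1, {"DD": 500}, {"WW": 500})
    eggs = sim.reproduction_stage(sim.mating_stage(sterile, rng), rng)
    assert eggs.sum() == 0
    wild = _wild_state(1, 500, 500)
    mating = sim.mating_stage(wild, rng)
    eggs = sim.reproduction_stage(mating, rng)
    per_mother = eggs.sum() / mating.n_mothers
    assert per_mother == pytest.approx(48, rel=0.05)
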