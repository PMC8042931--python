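"""Generational loop: survival equation, doubling, selection, outcomes."""

import numpy as np
import pytest

from teworld.analytics import one_generation_survival
from teworld.config import SimulationConfig
from teworld.effects import make_effect_model
from teworld.genome import new_genome
from teworld.population import (Host, HostMutationModel, Outcome, Population,
                                PopulationExtinct, background_mutation_step,
                                replicate_hosts, run_generation,
                                run_simulation, selection_step,
                                survival_probability)


def _host(hid, likelihood=1.0, tes=0, rng=None):
    g = new_genome(5, 100, 50, initial_te_count=tes,
                   intergenic_length=500, rng=rng)
    return Host(hid, likelihood, g)


class TestSurvivalProbability:
    @pytest.mark.parametrize("me, expected", [(0.1, 0.55), (0.01, 0.505)])
    @pytest.mark.parametrize("c", [10, 100, 1000])
    def test_beneficiary_closed_form(self, me, expected, c):
        # L = 1+Me against a pool of total likelihood 2C
        assert survival_probability(1 + me, 2 * c, c) == pytest.approx(expected)
        assert one_generation_survival(me) == pytest.approx(expected)

    def test_null_host_is_one_half(self):
        assert survival_probability(1.0, 2 * 50, 50) == pytest.approx(0.5)

    def test_sole_candidate_single_slot_clamps_to_one(self):
        assert survival_probability(3.0, 3.0, 1) == 1.0

    def test_zero_pool_likelihood_signals_extinction(self):
        with pytest.raises(PopulationExtinct):
            survival_probability(0.0, 0.0, 10)

    def test_zero_capacity(self):
        assert survival_probability(1.0, 2.0, 0) == 0.0


class TestReplicateHosts:
    def test_pool_doubles(self, rng):
        pop = Population([_host(i) for i in range(10)], carrying_capacity=10,
                         _next_host_id=10)
        pool = replicate_hosts(pop, rng)
        assert len(pool) == 20

    def test_offspring_inherit_baseline_likelihood(self, rng):
        pop = Population([_host(0, likelihood=1.2)], carrying_capacity=5,
                         _next_host_id=1)
        pool = replicate_hosts(pop, rng)
        assert pool[1].likelihood == 1.2

    def test_offspring_genome_is_isolated(self, rng):
        pop = Population([_host(0)], carrying_capacity=5, _next_host_id=1)
        pool = replicate_hosts(pop, rng)
        pool[1].genome.insert_te(3)
        assert pool[0].genome.n_tes == 0

    def test_empty_population_signals_extinction(self, rng):
        pop = Population([], carrying_capacity=5)
        with pytest.raises(PopulationExtinct):
            replicate_hosts(pop, rng)


class TestSelectionStep:
    def test_homogeneous_pool_mean_survivors_is_c(self):
        c, trials = 100, 200
        counts = []
        for i in range(trials):
            r = np.random.default_rng(i)
            pool = [_host(j) for j in range(2 * c)]
            counts.append(len(selection_step(pool, c, r)))
        # each of 2C candidates survives w.p. 1/2
        sd = np.sqrt(2 * c * 0.25 / trials)
        assert abs(np.mean(counts) - c) < 4 * sd

    def test_single_candidate_clamped_probability(self, rng):
        pool = [_host(0)]
        assert len(selection_step(pool, 5, rng)) == 1

    def test_zero_capacity_kills_pool(self, rng):
        pool = [_host(i) for i in range(4)]
        assert selection_step(pool, 0, rng) == []

    def test_exact_mode_draws_exactly_c(self, rng):
        pool = [_host(i) for i in range(40)]
        survivors = selection_step(pool, 10, rng, mode="exact")
        assert len(survivors) == 10

    def test_dead_hosts_excluded(self, rng):
        pool = [_host(i) for i in range(10)]
        for h in pool[:5]:
            h.alive = False
        survivors = selection_step(pool, 100, rng)
        assert len(survivors) == 5  # clamp at p=1 for the 5 live ones

    def test_higher_likelihood_never_hurts(self):
        # matched-seed monotonicity: raising one host's L cannot lose a
        # selection it would otherwise have won
        for seed in range(50):
            outcomes = []
            for l_focal in (1.0, 1.1):
                r = np.random.default_rng(seed)
                pool = [_host(j) for j in range(20)]
                pool[0].likelihood = l_focal
                survivors = selection_step(pool, 10, r)
                outcomes.append(any(h.host_id == 0 for h in survivors))
            assert outcomes[1] or not outcomes[0]


class TestBackgroundMutation:
    def test_zero_rate_is_noop(self, rng):
        h = _host(0)
        background_mutation_step(h, HostMutationModel(0.0),
                                 make_effect_model(0.2, 0.1), rng)
        assert h.likelihood == 1.0 and h.alive

    def test_poisson_event_count_mean(self):
        # pure-beneficial fixed-magnitude model: every event multiplies L by
        # 1.1, so the event count per host is log(L)/log(1.1)
        from teworld.effects import MagnitudeMode
        rate, n = 1.0, 10_000
        m = make_effect_model(0.5, 0.1, p_lethal=0.0, p_deleterious=0.0,
                              magnitude_mode=MagnitudeMode.FIXED)
        r = np.random.default_rng(9)
        counts = []
        for _ in range(n):
            h = _host(0)
            background_mutation_step(h, HostMutationModel(rate), m, r)
            counts.append(round(np.log(h.likelihood) / np.log(1.1)))
        # beneficial events are the Poisson(rate) stream thinned by bp=0.5
        expect = rate * m.p_beneficial
        assert abs(np.mean(counts) - expect) < 4 * np.sqrt(expect / n)

    def test_lethal_only_channel_with_zero_effect(self):
        r = np.random.default_rng(4)
        m = make_effect_model(0.0, 0.0)
        h = _host(0)
        background_mutation_step(h, HostMutationModel(50.0), m, r)
        assert h.likelihood == 1.0       # Me=0: no L change possible
        assert not h.alive               # ~50 events, 30% lethal each


class TestRunGeneration:
    def test_null_dynamics_holds_population_near_capacity(self):
        cfg = SimulationConfig(carrying_capacity=100, te_excision_rate=0.0,
                               te_death_rate=0.0, corrected_mutation_rate=0.0,
                               initial_te_count=1, g_max=10, seed=1)
        rng = np.random.default_rng(cfg.seed)
        from teworld.population import _init_population
        pop = _init_population(cfg, rng)
        for _ in range(5):
            run_generation(pop, cfg, rng)
        assert 60 <= pop.n_live <= 200
        assert pop.n_active_tes == pop.n_live  # one inert TE per host
        assert all(h.likelihood == 1.0 for h in pop.live_hosts)

    def test_certain_te_death_clears_census(self):
        cfg = SimulationConfig(carrying_capacity=30, te_death_rate=1.0,
                               corrected_mutation_rate=0.0, seed=2)
        rng = np.random.default_rng(cfg.seed)
        from teworld.population import _init_population
        pop = _init_population(cfg, rng)
        run_generation(pop, cfg, rng)
        assert pop.n_active_tes == 0

    def test_generation_counter_increments(self, rng):
        cfg = SimulationConfig(carrying_capacity=10, seed=3)
        from teworld.population import _init_population
        pop = _init_population(cfg, rng)
        g0 = pop.generation
        run_generation(pop, cfg, rng)
        assert pop.generation == g0 + 1


class TestRunSimulation:
    def test_pure_death_process_ends_te_extinct(self):
        cfg = SimulationConfig(carrying_capacity=30, te_excision_rate=0.0,
                               te_death_rate=0.2, corrected_mutation_rate=0.0,
                               g_max=300, seed=5)
        rec = run_simulation(cfg)
        assert rec.outcome is Outcome.TE_EXTINCT
        assert rec.final_n_active_tes == 0

    def test_zero_budget_with_tes_and_hosts_persists(self):
        cfg = SimulationConfig(carrying_capacity=10, g_max=0, seed=6)
        rec = run_simulation(cfg)
        assert rec.outcome is Outcome.PERSIST
        assert rec.terminal_generation == 0

    def test_zero_capacity_is_host_extinct(self):
        cfg = SimulationConfig(carrying_capacity=0, g_max=10, seed=7)
        rec = run_simulation(cfg)
        assert rec.outcome is Outcome.HOST_EXTINCT

    def test_aggressive_transposition_small_pop_kills_hosts(self):
        # all-genic genome, lethal-heavy hits, tiny population
        outcomes = []
        for seed in range(20):
            cfg = SimulationConfig(carrying_capacity=8, gene_count=50,
                                   intergenic_length=100, te_excision_rate=1.0,
                                   te_progeny=3, te_death_rate=0.0,
                                   corrected_mutation_rate=0.0, bp=0.0,
                                   insertion_bias=1.0, g_max=100, seed=seed)
            outcomes.append(run_simulation(cfg).outcome)
        assert (sum(o is Outcome.HOST_EXTINCT for o in outcomes)
                > len(outcomes) / 2)

    def test_bit_identical_trajectory_under_same_seed(self):
        cfg = SimulationConfig(carrying_capacity=40, g_max=30, seed=11)
        a, b = run_simulation(cfg), run_simulation(cfg)
        assert a.trajectory == b.trajectory
        assert a.to_dict() == b.to_dict()

    def test_trajectory_columns(self):
        cfg = SimulationConfig(carrying_capacity=20, g_max=5, seed=12)
        df = run_simulation(cfg).trajectory_frame()
        assert list(df.columns) == ["generation", "n_hosts", "n_active_tes",
                                    "mean_L", "n_disrupted_genes"]
        assert len(df) >= 1


class TestTrends:
    def test_mean_likelihood_nondecreasing_without_loss_channels(self):
        # only beneficial/neutral genic hits: mean L cannot trend down
        cfg = SimulationConfig(carrying_capacity=30, gene_count=100, bp=0.2,
                               p_lethal=0.0, p_deleterious=0.0,
                               te_excision_rate=0.15, te_death_rate=0.0,
                               corrected_mutation_rate=0.1, g_max=25, seed=13)
        df = run_simulation(cfg).trajectory_frame()
        assert df["mean_L"].iloc[-1] >= df["mean_L"].iloc[0]
        assert (df["mean_L"].diff().dropna() >= -1e-9).mean() > 0.8

    def test_likelihoods_start_at_one_and_stay_without_hits(self):
        cfg = SimulationConfig(carrying_capacity=30, te_excision_rate=0.0,
                               te_death_rate=0.0, corrected_mutation_rate=0.0,
                               g_max=20, seed=14)
        df = run_simulation(cfg).trajectory_frame()
        assert (df["mean_L"] == 1.0).all()
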