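"""Wright-Fisher chromosome-length simulator: bookkeeping, selection, regimes."""

import numpy as np
import pytest
from scipy import stats

from degenexp.wfsim import (
    Chromosome,
    SimConfig,
    SizeDist,
    fitness,
    mutate,
    new_chromosome,
    next_generation,
    run_replicate,
    run_scenario,
    scenario_config,
)


class TestMutate:
    def test_zero_rates_leave_chromosome_unchanged(self, rng):
        cfg = SimConfig(mu_ins=0.0, mu_del=0.0, F0=10, element_bp=1000, L0=100_000)
        c = new_chromosome(cfg)
        assert mutate(c, cfg, rng) is c or mutate(c, cfg, rng) == c

    def test_forced_insertion_bookkeeping(self):
        cfg = SimConfig(L0=100_000, F0=0, ins_size=SizeDist("fixed", 10_000))
        c = Chromosome(length=100_000, elements=((20_000, 25_000), (60_000, 65_000)))
        rng = np.random.default_rng(5)
        # force the position by trying until it lands between the elements
        for _ in range(200):
            c2 = mutate(c, cfg, rng, n_ins=1, n_del=0, n_ect=0)
            pos_shifted = c2.elements[-1][0] - c.elements[-1][0]
            if len(c2.elements) == 2 and c2.elements[0] == (20_000, 25_000):
                break
        assert c2.length == 110_000
        assert pos_shifted in (0, 10_000)

    def test_insertion_inside_element_disrupts_and_costs(self):
        cfg = SimConfig(L0=100_000, F0=0, s_ins=0.01,
                        ins_size=SizeDist("fixed", 5000))
        c = Chromosome(length=100_000, elements=((0, 100_000),))
        rng = np.random.default_rng(0)
        c2 = mutate(c, cfg, rng, n_ins=1, n_del=0, n_ect=0)
        assert c2.elements == ()
        assert c2.disrupted_ins == 1
        assert c2.fitness == pytest.approx(0.99)

    def test_deletion_clipped_at_min_length(self):
        cfg = SimConfig(L0=5000, F0=0, del_size=SizeDist("fixed", 100_000))
        c = Chromosome(length=5000, elements=())
        rng = np.random.default_rng(1)
        log = []
        c2 = mutate(c, cfg, rng, n_ins=0, n_del=1, n_ect=0, event_log=log)
        assert c2.length >= 1000
        assert c2.length == 5000 - log[0][1]

    def test_event_log_replay_is_exact(self):
        """10^5 random events: final length equals L0 + sum(ins) - sum(del)."""
        cfg = SimConfig(L0=1_000_000, F0=50, element_bp=2000,
                        ins_size=SizeDist("exponential", 4000),
                        del_size=SizeDist("exponential", 4000),
                        s_ins=0.001, s_del=0.01)
        c = new_chromosome(cfg)
        rng = np.random.default_rng(2)
        log = []
        for _ in range(1000):
            c = mutate(c, cfg, rng, n_ins=50, n_del=50, n_ect=0, event_log=log)
        assert len(log) == 100_000
        net = sum(s for t, s in log if t == "INS") - sum(
            s for t, s in log if t == "DEL"
        )
        assert c.length == cfg.L0 + net
        assert c.length == cfg.L0 + c.sum_ins - c.sum_del


class TestFitness:
    def test_untouched_chromosome_has_fitness_one(self):
        cfg = SimConfig(F0=20, element_bp=1000, L0=100_000, s_del=0.1)
        assert fitness(new_chromosome(cfg), cfg) == 1.0

    def test_single_element_loss_single_factor(self):
        cfg = SimConfig(s_del=0.1)
        c = Chromosome(length=10_000, elements=(), disrupted_del=1, fitness=0.9)
        assert fitness(c, cfg) == pytest.approx(0.9)

    def test_k_losses_match_log_space_accumulation(self):
        cfg = SimConfig(s_del=0.07)
        for k in (1, 3, 10, 40):
            c = Chromosome(length=10_000, elements=(), disrupted_del=k,
                           fitness=(1 - 0.07) ** k)
            expect = np.exp(k * np.log(1 - 0.07))
            assert fitness(c, cfg) == pytest.approx(expect, rel=1e-12)

    def test_incremental_fitness_matches_recomputation(self):
        cfg = SimConfig(L0=200_000, F0=40, element_bp=2000,
                        s_ins=0.004, s_del=0.03,
                        del_size=SizeDist("exponential", 6000))
        c = new_chromosome(cfg)
        rng = np.random.default_rng(3)
        for _ in range(50):
            c = mutate(c, cfg, rng, n_ins=2, n_del=2, n_ect=0)
        assert c.fitness == pytest.approx(fitness(c, cfg), rel=1e-9)


class TestSelection:
    def test_neutral_reproduction_is_uniform_multinomial(self):
        cfg = SimConfig(N=50, mu_ins=0.0, mu_del=0.0, L0=10_000)
        pop = [Chromosome(length=10_000 + i, elements=()) for i in range(50)]
        rng = np.random.default_rng(4)
        counts = np.zeros(50)
        for _ in range(400):
            off = next_generation(pop, cfg, rng)
            for c in off:
                counts[c.length - 10_000] += 1
        freq = counts / counts.sum()
        # every parent drawn with roughly equal frequency
        assert abs(freq.mean() - 1 / 50) < 1e-12
        assert freq.max() < 3 / 50

    def test_fixation_probability_matches_2s(self):
        """A single variant with advantage s in N=500 haploids fixes with
        probability ~2s (diffusion approximation), within Monte-Carlo error."""
        N = 500
        for s, reps, seed in ((0.05, 600, 42), (0.01, 1000, 43)):
            cfg = SimConfig(N=N, T=1, L0=100_000, mu_ins=0, mu_del=0, s_del=s)
            resident = Chromosome(length=100_000, elements=(), disrupted_del=1,
                                  fitness=1 - s)
            mutant = Chromosome(length=100_000, elements=())
            rng = np.random.default_rng(seed)
            fixed = 0
            for _ in range(reps):
                pop = [mutant] + [resident] * (N - 1)
                for _ in range(10 * N):
                    pop = next_generation(pop, cfg, rng)
                    f = sum(c.fitness == 1.0 for c in pop)
                    if f == 0 or f == N:
                        break
                fixed += f == N
            p_hat = fixed / reps
            mc_sd = np.sqrt(2 * s * (1 - 2 * s) / reps)
            assert abs(p_hat - 2 * s) < 3.5 * mc_sd

    def test_fixed_seed_reproduces_trajectory(self):
        cfg = scenario_config("drift", N=30, T=50, replicates=2, seed=9)
        a = run_scenario(cfg)
        b = run_scenario(cfg)
        assert np.array_equal(a.mean_length, b.mean_length)
        assert np.array_equal(a.final_lengths, b.final_lengths)


class TestRegimes:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(N=1)
        with pytest.raises(ValueError):
            SimConfig(s_del=1.0)
        with pytest.raises(ValueError):
            SimConfig(F0=300, element_bp=5000, L0=1_000_000)

    def test_expansion_regime_grows_at_reduced_scale(self):
        cfg = scenario_config("expansion", N=100, T=400, replicates=8, seed=5)
        traj = run_scenario(cfg)
        assert traj.mean_final_change > 0
        assert traj.sign_test("greater") < 0.05

    def test_drift_regime_unbiased_at_reduced_scale(self):
        cfg = scenario_config("drift", N=100, T=400, replicates=30, seed=6)
        traj = run_scenario(cfg)
        ch = traj.final_lengths - cfg.L0
        se = ch.std(ddof=1) / np.sqrt(len(ch))
        assert abs(ch.mean()) < 3 * se

    def test_shrinkage_regime_contracts_at_reduced_scale(self):
        cfg = scenario_config("shrinkage", N=100, T=400, replicates=8, seed=7)
        traj = run_scenario(cfg)
        assert traj.mean_final_change < 0
        assert traj.sign_test("less") < 0.05

    def test_growth_rate_declines_with_intact_elements(self):
        """Degeneration feedback: as intact functional elements are lost the
        deletion brake weakens and mean growth slows toward drift."""
        cfg = SimConfig(N=100, T=4000, L0=500_000, F0=60, element_bp=5000,
                        mu_ins=0.1, mu_del=0.1, s_ins=0.001, s_del=0.01,
                        ins_size=SizeDist("exponential", 5000.0),
                        del_size=SizeDist("exponential", 5000.0),
                        replicates=10, seed=7)
        traj = run_scenario(cfg)
        growth = np.diff(traj.mean_length.mean(axis=0))
        intact = traj.mean_intact.mean(axis=0)
        epochs = growth.reshape(10, -1).mean(axis=1)
        intact_ep = intact[1:].reshape(10, -1).mean(axis=1)
        assert intact_ep[-1] < 0.2 * intact_ep[0]  # elements really erode
        assert epochs[5:].mean() < epochs[:5].mean()  # growth slows
        rho, _ = stats.spearmanr(intact_ep, epochs)
        assert rho > 0  # growth tracks the remaining functional content

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            scenario_config("implosion")


def test_run_replicate_reports_initial_state():
    cfg = SimConfig(N=20, T=10, L0=50_000, F0=5, element_bp=1000)
    rng = np.random.default_rng(11)
    ml, md, mi, mf, pop = run_replicate(cfg, rng)
    assert ml[0] == 50_000 and mi[0] == 5 and mf[0] == 1.0
    assert len(pop) == 20
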