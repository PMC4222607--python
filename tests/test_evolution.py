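"""Selection models, Wright-Fisher operators and full evolutionary runs."""

import math

import numpy as np
import pytest
from scipy import stats

from threshnet import (Attractor, EvolutionConfig, Population,
                       SelectionModel, evolve, find_attractor, fitness,
                       founding_population, mutate, recombine,
                       wright_fisher_select)
from threshnet.netgen import random_networks, random_state, random_states


def _fixed_point(state):
    return Attractor(transient_length=0,
                     cycle=np.array([state], dtype=np.int8))


def _two_cycle(n=4):
    a = np.ones(n, dtype=np.int8)
    return Attractor(transient_length=0, cycle=np.stack([a, -a]))


class TestSelectionModelValidation:
    def test_no_target_forbids_target(self):
        with pytest.raises(ValueError):
            SelectionModel(model_id=1, sigma=math.inf,
                           target=np.ones(4, dtype=int))

    def test_cycle_model_needs_l_opt_at_least_two(self):
        with pytest.raises(ValueError):
            SelectionModel.cycle(1)

    def test_stability_model_needs_l_opt_one(self):
        with pytest.raises(ValueError):
            SelectionModel(model_id=1, l_opt=2)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            SelectionModel(model_id=5)


class TestFitness:
    def test_fixed_point_on_target_has_fitness_one(self):
        s = np.array([1, -1, 1, -1], dtype=np.int8)
        model = SelectionModel.stability_target(target=s)
        assert fitness(_fixed_point(s), model) == 1.0

    def test_cycles_are_lethal_under_stability_selection(self):
        assert fitness(_two_cycle(), SelectionModel.no_target()) == 0.0
        s = np.ones(4, dtype=np.int8)
        assert fitness(_two_cycle(), SelectionModel.stability_target(s)) == 0.0

    def test_exponential_decay_with_hamming_distance(self):
        """d = 0.5 at sigma = 0.1 gives exp(-5)."""
        s = np.array([1, 1, -1, -1], dtype=np.int8)
        target = np.array([1, 1, 1, 1], dtype=np.int8)
        model = SelectionModel.stability_target(target=target, sigma=0.1)
        assert fitness(_fixed_point(s), model) == pytest.approx(
            math.exp(-5), rel=1e-12)

    def test_no_target_fixed_point_fitness_is_exactly_one(self):
        assert fitness(_fixed_point(np.ones(4, dtype=np.int8)),
                       SelectionModel.no_target()) == 1.0

    def test_cycle_model_scores_only_matching_length(self):
        m = SelectionModel.cycle(2)
        assert fitness(_two_cycle(), m) == 1.0
        # fixed points count as "else", not as cycles of the right length
        assert fitness(_fixed_point(np.ones(4, dtype=np.int8)), m) == 0.0

    def test_attractor_target_takes_best_state_of_cycle(self):
        target = np.ones(4, dtype=np.int8)
        model = SelectionModel.attractor_target(target=target, sigma=0.1)
        # the all-on state is in the cycle, so d_min = 0
        assert fitness(_two_cycle(), model) == 1.0

    def test_neutral_model_is_flat(self):
        assert fitness(_two_cycle(), SelectionModel.neutral()) == 1.0


class TestWrightFisherSelect:
    def test_sole_survivor_takes_over(self, rng):
        pop = Population(random_networks(4, 10, rng),
                         random_states(4, 10, rng))
        f = np.zeros(10)
        f[3] = 2.0
        out = wright_fisher_select(pop, f, rng)
        assert out.size == 10
        assert (out.networks == pop.networks[3]).all()

    def test_population_size_conserved(self, rng):
        pop = Population(random_networks(4, 33, rng),
                         random_states(4, 33, rng))
        out = wright_fisher_select(pop, np.ones(33), rng)
        assert out.size == 33

    def test_equal_fitness_sampling_is_uniform_multinomial(self, rng):
        n = 40
        nets = random_networks(6, n, rng)  # distinct, so organisms are tagged
        lookup = {W.tobytes(): k for k, W in enumerate(nets)}
        assert len(lookup) == n
        pop = Population(nets, random_states(6, n, rng))
        counts = np.zeros(n)
        rounds = 300
        for _ in range(rounds):
            out = wright_fisher_select(pop, np.ones(n), rng)
            for W in out.networks:
                counts[lookup[W.tobytes()]] += 1
        chi = stats.chisquare(counts, f_exp=np.full(n, rounds))
        assert chi.pvalue > 1e-4

    def test_all_zero_fitness_rescues_uniformly(self, rng, caplog):
        pop = Population(random_networks(4, 20, rng),
                         random_states(4, 20, rng))
        import logging
        with caplog.at_level(logging.INFO, logger="threshnet.evolution"):
            out = wright_fisher_select(pop, np.zeros(20), rng)
        assert out.size == 20
        assert any("zero" in r.message for r in caplog.records)


class TestMutate:
    def test_zero_rate_is_identity(self, rng):
        pop = Population(random_networks(10, 30, rng),
                         random_states(10, 30, rng))
        out = mutate(pop, 0.0, rng)
        assert (out.networks == pop.networks).all()

    def test_per_entry_flip_rate(self, rng):
        """mu = 0.1 over N**2 = 100 entries means 0.001 per entry."""
        n_org, rounds = 1000, 10
        pop = Population(random_networks(10, n_org, rng),
                         random_states(10, n_org, rng))
        flips = 0
        cur = pop
        for _ in range(rounds):
            new = mutate(cur, 0.1, rng)
            flips += (new.networks != cur.networks).sum()
            cur = new
        total = n_org * 100 * rounds  # 1e6 entry-generations
        # expectation 1000 flips, 4 sigma band ~ +/-127
        assert abs(flips - total * 0.001) < 130

    def test_sparse_zero_entries_never_mutate(self, rng):
        from threshnet import sparse_regular_network
        W = np.stack([sparse_regular_network(10, 2, rng) for _ in range(200)])
        pop = Population(W, random_states(10, 200, rng))
        out = mutate(pop, 1.0, rng)
        assert ((W == 0) == (out.networks == 0)).all()

    def test_bad_rate_raises(self, rng):
        pop = Population(random_networks(4, 2, rng), random_states(4, 2, rng))
        with pytest.raises(ValueError):
            mutate(pop, 1.5, rng)


class TestRecombine:
    def test_identical_parents_give_identical_offspring(self, rng):
        W = np.tile(random_networks(6, 1, rng), (10, 1, 1))
        pop = Population(W, random_states(6, 10, rng))
        out = recombine(pop, rng)
        assert (out.networks == W).all()

    def test_every_row_comes_from_a_parent(self, rng):
        pop = Population(random_networks(8, 20, rng),
                         random_states(8, 20, rng))
        parents = {W.tobytes() for W in pop.networks}
        parent_rows = np.concatenate([pop.networks[:, i, :] for i in range(8)])
        row_set = {r.tobytes() for r in parent_rows}
        out = recombine(pop, rng)
        for W in out.networks:
            for row in W:
                assert row.tobytes() in row_set

    def test_pairwise_row_complementarity(self, rng):
        """Within a pair, each parental row i lands in exactly one child."""
        n = 30
        pop = Population(random_networks(6, n, rng), random_states(6, n, rng))
        out = recombine(pop, rng)
        # per row index, the multiset of rows across the population is
        # unchanged (offspring permute parental rows between pair members)
        for i in range(6):
            before = sorted(r.tobytes() for r in pop.networks[:, i, :])
            after = sorted(r.tobytes() for r in out.networks[:, i, :])
            assert before == after

    def test_odd_population_raises(self, rng):
        pop = Population(random_networks(4, 5, rng), random_states(4, 5, rng))
        with pytest.raises(ValueError):
            recombine(pop, rng)


class TestFoundingPopulation:
    def test_default_founding_is_random_with_shared_state(self):
        cfg = EvolutionConfig(generations=1, n=200, seed=0)
        pop = founding_population(cfg, np.random.default_rng(0))
        assert pop.size == 200
        assert (pop.initial_states == pop.initial_states[0]).all()
        p = (np.diagonal(pop.networks, axis1=1, axis2=2) > 0).mean()
        assert abs(p - 0.5) < 0.08

    def test_composed_founding_measures_exactly(self):
        cfg = EvolutionConfig(generations=1, n=50, p0=0.9, q0=0.9, seed=0)
        pop = founding_population(cfg, np.random.default_rng(0))
        diag = np.diagonal(pop.networks, axis1=1, axis2=2)
        assert ((diag > 0).sum(axis=1) == 9).all()
        off = pop.networks[:, ~np.eye(10, dtype=bool)]
        assert ((off > 0).sum(axis=1) == 81).all()


class TestEvolve:
    def test_seeded_runs_are_bit_reproducible(self):
        cfg = EvolutionConfig(generations=30, n=50, z=2, seed=77)
        a = evolve(cfg, SelectionModel.no_target())
        b = evolve(cfg, SelectionModel.no_target())
        assert a.records.equals(b.records)
        for pa, pb in zip(a.final_populations, b.final_populations):
            assert (pa.networks == pb.networks).all()

    def test_population_size_and_support_preserved(self):
        cfg = EvolutionConfig(generations=40, n=100, z=2, seed=3)
        res = evolve(cfg, SelectionModel.no_target())
        for pop in res.final_populations:
            assert pop.size == 100
            assert np.isin(pop.networks, (-1, 1)).all()

    def test_sparse_in_degree_frozen_through_evolution(self):
        """Mutation flips signs only; recombination exchanges whole rows.

        Each row therefore keeps exactly `degree` non-zero entries forever
        (column degrees are only regular at founding, since rows from
        different parents mix).
        """
        cfg = EvolutionConfig(generations=40, n=50, z=1, seed=3, sparse=True)
        res = evolve(cfg, SelectionModel.no_target())
        W = res.final_populations[0].networks
        assert ((W != 0).sum(axis=2) == 2).all()
        assert np.isin(W, (-1, 0, 1)).all()

    def test_stability_selection_raises_autoregulation(self):
        cfg = EvolutionConfig(generations=80, n=100, z=3, seed=21,
                              record_r=[0])
        res = evolve(cfg, SelectionModel.no_target())
        sm = res.set_mean()
        assert sm["p"].iloc[0] == pytest.approx(0.5, abs=0.1)
        assert sm["p"].max() > 0.75

    def test_cycle_selection_lowers_autoregulation(self):
        cfg = EvolutionConfig(generations=200, n=100, z=3, seed=22,
                              record_r=[0])
        res = evolve(cfg, SelectionModel.cycle(2))
        assert res.set_mean()["p"].iloc[-1] < 0.45

    def test_neutral_model_drifts_around_half(self):
        cfg = EvolutionConfig(generations=200, n=200, z=4, seed=23,
                              record_r=[0])
        res = evolve(cfg, SelectionModel.neutral())
        sm = res.set_mean()
        assert np.abs(sm["p"] - 0.5).max() < 0.1

    def test_snapshots_and_robustness_schedule(self):
        cfg = EvolutionConfig(generations=20, n=50, z=2, seed=5,
                              snapshot_generations=[0, 20],
                              record_robustness=[20], record_r=[0, 20])
        res = evolve(cfg, SelectionModel.no_target())
        assert set(res.snapshots) == {0, 20}
        assert res.snapshots[0].shape == (100, 10, 10)
        last = res.records[res.records.t == 20]
        assert np.isfinite(last["viability"]).any()

    def test_target_model_runs_and_fitness_bounded(self):
        cfg = EvolutionConfig(generations=30, n=50, z=2, seed=6,
                              record_r=[0])
        res = evolve(cfg, SelectionModel.stability_target(sigma=0.1))
        mf = res.records["mean_fitness"]
        assert ((0 <= mf) & (mf <= 1)).all()

    def test_attractor_target_model_runs(self):
        cfg = EvolutionConfig(generations=15, n=40, z=1, seed=8,
                              record_r=[0])
        res = evolve(cfg, SelectionModel.attractor_target(sigma=0.1))
        assert (res.records["mean_fitness"] > 0).all()
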