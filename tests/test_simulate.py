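"""Individual-based gene-flow simulator: initialization, pairing,
reproduction, dispersal and whole-scenario behavior."""

import numpy as np
import pytest

from genescape import (
    CostDistanceMatrix,
    NodeSet,
    ScenarioConfig,
    calibrate_kernel,
    disperse_and_settle,
    form_pairs,
    initialize_population,
    reproduce,
    run_scenario,
)
from genescape.simulate import FEMALE, MALE, Population

from conftest import make_population


def line_nodes(n, spacing=10_000.0, occupied=None):
    occ = occupied if occupied is not None else np.ones(n, dtype=bool)
    return NodeSet(np.arange(n), np.arange(n) * spacing + 500.0, np.full(n, 500.0),
                   occupied_at_init=occ)


def euclid_cost(nodes):
    d = np.abs(nodes.x[:, None] - nodes.x[None, :])
    return CostDistanceMatrix(nodes.node_id, d.astype(float))


class TestInitialization:
    def test_two_individuals_per_occupied_node(self, rng):
        occ = np.zeros(50, dtype=bool)
        occ[:40] = True
        nodes = line_nodes(50, occupied=occ)
        pop = initialize_population(nodes, ScenarioConfig(), rng)
        assert len(pop) == 80
        counts = pop.node_counts(50)
        assert np.all(counts[:40] == 2) and np.all(counts[40:] == 0)

    def test_initial_heterozygosity_near_one_minus_inverse_k(self, rng):
        """Uniform allele draws from k=10 alleles give expected He = 0.9."""
        nodes = line_nodes(200)
        pop = initialize_population(nodes, ScenarioConfig(), rng)
        het = (pop.genotype[:, :, 0] != pop.genotype[:, :, 1]).mean()
        assert het == pytest.approx(0.9, abs=3 * np.sqrt(0.9 * 0.1 / pop.genotype[:, :, 0].size))

    def test_sex_ratio_balanced_across_seeds(self):
        nodes = line_nodes(100)
        fracs = [initialize_population(nodes, ScenarioConfig(), np.random.default_rng(s)).sex.mean()
                 for s in range(20)]
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.03)


class TestFormPairs:
    def test_single_pair(self, rng):
        pop = make_population([[(0, 0)], [(1, 1)]], sexes=[FEMALE, MALE], nodes=[0, 1])
        f, m = form_pairs(pop, euclid_cost(line_nodes(2)).d, rng)
        assert len(f) == 1 and pop.sex[f[0]] == FEMALE and pop.sex[m[0]] == MALE

    def test_monogamy_two_females_one_male(self, rng):
        pop = make_population([[(0, 0)], [(1, 1)], [(2, 2)]],
                              sexes=[FEMALE, FEMALE, MALE], nodes=[0, 1, 2])
        f, m = form_pairs(pop, euclid_cost(line_nodes(3)).d, rng)
        assert len(f) == 1

    def test_greedy_nearest_oracle_small_configuration(self):
        """3 females x 3 males with a hand-built distance matrix: for every
        seed, pairing must equal the greedy-nearest result for that seed's
        female processing order."""
        cost = np.array([
            [0, 1, 9, 2, 8, 7],
            [1, 0, 5, 3, 2, 6],
            [9, 5, 0, 7, 4, 1],
            [2, 3, 7, 0, 9, 9],
            [8, 2, 4, 9, 0, 9],
            [7, 6, 1, 9, 9, 0],
        ], dtype=float)
        sexes = [FEMALE, FEMALE, FEMALE, MALE, MALE, MALE]
        pop = make_population([[(0, 0)]] * 6, sexes=sexes, nodes=list(range(6)))
        for seed in range(6):
            rng1, rng2 = np.random.default_rng(seed), np.random.default_rng(seed)
            f, m = form_pairs(pop, cost, rng1)
            # independent greedy oracle over the same processing order
            order = rng2.permutation(np.array([0, 1, 2]))
            taken, expected = set(), {}
            for fi in order:
                males = [j for j in (3, 4, 5) if j not in taken]
                best = min(males, key=lambda j: (cost[fi, j], j))
                taken.add(best)
                expected[fi] = best
            assert dict(zip(f, m)) == expected

    def test_tie_breaks_to_lower_node_id(self, rng):
        cost = np.array([[0, 5, 5], [5, 0, 9], [5, 9, 0]], dtype=float)
        pop = make_population([[(0, 0)]] * 3, sexes=[FEMALE, MALE, MALE], nodes=[0, 2, 1])
        f, m = form_pairs(pop, cost, rng)
        assert pop.node[m[0]] == 1  # equidistant males: lower node index wins

    def test_unreachable_males_skipped(self, rng):
        cost = np.array([[0, np.inf], [np.inf, 0]])
        pop = make_population([[(0, 0)], [(1, 1)]], sexes=[FEMALE, MALE], nodes=[0, 1])
        f, m = form_pairs(pop, cost, rng)
        assert len(f) == 0

    def test_no_males_empty_pairing(self, rng):
        pop = make_population([[(0, 0)], [(1, 1)]], sexes=[FEMALE, FEMALE], nodes=[0, 1])
        f, m = form_pairs(pop, euclid_cost(line_nodes(2)).d, rng)
        assert len(f) == 0 and len(m) == 0


class TestReproduce:
    def test_homozygous_parents_force_offspring_genotype(self, rng):
        pop = make_population([[(3, 3)] * 5, [(3, 3)] * 5], sexes=[FEMALE, MALE], nodes=[0, 0])
        off = reproduce(pop, (np.array([0]), np.array([1])), ScenarioConfig(), rng)
        assert np.all(off.genotype == 3)

    def test_mendelian_segregation_frequencies(self, rng):
        """A/B x A/B -> 1/4 AA, 1/2 AB, 1/4 BB."""
        pop = make_population([[(0, 1)], [(0, 1)]], sexes=[FEMALE, MALE], nodes=[0, 0])
        cfg = ScenarioConfig(fecundity_mean=10_000.0)
        off = reproduce(pop, (np.array([0]), np.array([1])), cfg, rng)
        g = off.genotype[:, 0, :].sum(axis=1)  # 0 = AA, 1 = AB, 2 = BB
        n = len(g)
        for val, expected in [(0, 0.25), (1, 0.5), (2, 0.25)]:
            frac = (g == val).mean()
            assert abs(frac - expected) < 3 * np.sqrt(expected * (1 - expected) / n)

    def test_poisson_fecundity_mean(self, rng):
        n_pairs = 10_000
        geno = [[(0, 0)]] * (2 * n_pairs)
        sexes = [FEMALE] * n_pairs + [MALE] * n_pairs
        pop = make_population(geno, sexes=sexes, nodes=np.zeros(2 * n_pairs, dtype=int))
        pairs = (np.arange(n_pairs), np.arange(n_pairs, 2 * n_pairs))
        off = reproduce(pop, pairs, ScenarioConfig(), rng)
        mean = len(off) / n_pairs
        se = np.sqrt(3.8 / n_pairs)
        assert abs(mean - 3.8) < 3 * se

    def test_offspring_natal_node_is_mothers(self, rng):
        pop = make_population([[(0, 0)], [(1, 1)]], sexes=[FEMALE, MALE], nodes=[4, 7])
        off = reproduce(pop, (np.array([0]), np.array([1])), ScenarioConfig(), rng)
        assert np.all(off.node == 4)


class TestDisperseAndSettle:
    def test_destination_distribution_matches_kernel_weights(self):
        """Single offspring on a 5-node toy: chi-square goodness of fit of
        the settlement distribution against the kernel multinomial."""
        nodes = line_nodes(5, spacing=20_000.0)
        cost = euclid_cost(nodes)
        kernel = calibrate_kernel(300_000.0)
        w = kernel.probability(cost.d[0])
        p_expected = w / w.sum()
        counts = np.zeros(5)
        n_rep = 10_000
        rng = np.random.default_rng(0)
        for _ in range(n_rep):
            off = make_population([[(0, 0)]], sexes=[FEMALE], nodes=[0])
            settled = disperse_and_settle(off, 5, cost.d, kernel, rng)
            counts[settled.node[0]] += 1
        chi2 = np.sum((counts - n_rep * p_expected) ** 2 / (n_rep * p_expected))
        from scipy.stats import chi2 as chi2_dist
        assert chi2 < chi2_dist.ppf(0.999, df=4)

    def test_capacity_conservation_when_oversubscribed(self, rng):
        nodes = line_nodes(3, spacing=1000.0)
        cost = euclid_cost(nodes)
        kernel = calibrate_kernel(300_000.0)
        off = make_population([[(0, 0)]] * 20, sexes=[FEMALE] * 20, nodes=[0] * 20)
        settled = disperse_and_settle(off, 3, cost.d, kernel, rng)
        assert len(settled) == 6  # 3 nodes x capacity 2
        assert settled.node_counts(3).max() <= 2

    def test_truncation_keeps_offspring_at_natal_node(self, rng):
        nodes = line_nodes(4, spacing=50_000.0)
        cost = euclid_cost(nodes)
        from genescape.dispersal import DispersalKernel
        kernel = DispersalKernel(max_cost=10_000.0, rate=1e-4)  # no other node reachable
        off = make_population([[(0, 0)]] * 3, sexes=[FEMALE] * 3,
                              nodes=[0, 1, 2])
        settled = disperse_and_settle(off, 4, cost.d, kernel, rng)
        assert np.array_equal(np.sort(settled.node), [0, 1, 2])

    def test_offspring_with_no_reachable_slot_die(self, rng):
        cost = np.array([[0.0, np.inf], [np.inf, 0.0]])
        from genescape.dispersal import DispersalKernel
        kernel = DispersalKernel(max_cost=5_000.0, rate=1e-4)
        off = make_population([[(0, 0)]] * 5, sexes=[FEMALE] * 5, nodes=[0] * 5)
        settled = disperse_and_settle(off, 2, cost, kernel, rng)
        assert len(settled) == 2  # only the natal node's two slots fill


class TestRunScenario:
    def scenario(self, **kw):
        defaults = dict(n_generations=10, n_runs=2, seed=5)
        defaults.update(kw)
        return ScenarioConfig(**defaults)

    def test_reproducible_given_seed(self):
        nodes = line_nodes(20, spacing=5000.0)
        cost = euclid_cost(nodes)
        a = run_scenario(self.scenario(), nodes, cost)
        b = run_scenario(self.scenario(), nodes, cost)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.final.genotype, rb.final.genotype)
            assert np.array_equal(ra.occupancy, rb.occupancy)

    def test_occupancy_never_exceeds_capacity(self):
        nodes = line_nodes(15, spacing=5000.0)
        results = run_scenario(self.scenario(), nodes, euclid_cost(nodes))
        for r in results:
            assert r.occupancy.max() <= 2

    def test_allele_conservation_no_mutation(self):
        """No allele identifier may appear that was absent in the founders."""
        nodes = line_nodes(10, spacing=5000.0)
        cfg = self.scenario(n_runs=1, n_generations=15)
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0)))
        founders = initialize_population(nodes, cfg, rng)
        results = run_scenario(cfg, nodes, euclid_cost(nodes))
        final = results[0].final
        for l in range(cfg.n_loci):
            assert set(np.unique(final.genotype[:, l, :])) <= set(np.unique(founders.genotype[:, l, :]))

    def test_isolation_switch_only_changes_cost_matrix(self):
        """IBD vs IBR configs with the same seed differ only through the
        distance matrix they are run on."""
        nodes = line_nodes(12, spacing=5000.0)
        cost = euclid_cost(nodes)
        a = run_scenario(self.scenario(isolation="IBD"), nodes, cost)
        b = run_scenario(self.scenario(isolation="IBR"), nodes, cost)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.final.genotype, rb.final.genotype)

    def test_heterozygosity_declines_under_drift(self):
        """In a closed population, run-mean He must trend downward over
        generations (regression slope <= 0, allowing sampling noise)."""
        nodes = line_nodes(10, spacing=2000.0)
        cost = euclid_cost(nodes)
        cfg = self.scenario(n_runs=5, n_generations=30, seed=2)
        slopes = []
        for run in range(cfg.n_runs):
            rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, run)))
            pop = initialize_population(nodes, cfg, rng)
            kernel = cfg.kernel()
            weights = kernel.probability(cost.d)
            he = []
            for gen in range(cfg.n_generations):
                pairs = form_pairs(pop, cost.d, rng, node_ids=nodes.node_id)
                off = reproduce(pop, pairs, cfg, rng)
                pop = disperse_and_settle(off, len(nodes), cost.d, kernel, rng, weights=weights)
                if len(pop) == 0:
                    break
                p_counts = np.zeros((cfg.n_loci, cfg.n_alleles))
                for c in range(2):
                    np.add.at(p_counts, (np.broadcast_to(np.arange(cfg.n_loci), pop.genotype[:, :, c].shape), pop.genotype[:, :, c]), 1)
                p = p_counts / p_counts.sum(axis=1, keepdims=True)
                he.append(np.mean(1 - (p**2).sum(axis=1)))
            slopes.append(np.polyfit(np.arange(len(he)), he, 1)[0])
        assert np.mean(slopes) <= 0

    def test_parents_existed_in_previous_generation(self, rng):
        nodes = line_nodes(8, spacing=3000.0)
        cost = euclid_cost(nodes)
        cfg = self.scenario()
        pop = initialize_population(nodes, cfg, rng)
        kernel = cfg.kernel()
        for _ in range(5):
            prev_ids = set(pop.ids)
            pairs = form_pairs(pop, cost.d, rng, node_ids=nodes.node_id)
            off = reproduce(pop, pairs, cfg, rng)
            assert set(off.parents.ravel()) <= prev_ids
            pop = disperse_and_settle(off, len(nodes), cost.d, kernel, rng)
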