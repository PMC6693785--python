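"""Fitness-landscape generators: structure, rates, peaks, serialization."""

import math

import numpy as np
import pytest

from cpmpaths.landscapes import (
    BirthRateAssignmentParams,
    DagOfRestrictions,
    FitnessLandscape,
    assign_birth_rates,
    fitness_graph_from_dag,
    generate_random_dag,
    genotype_from_str,
    genotype_to_str,
    landscape_stats,
    local_maxima_landscape,
    prune_to_local_maxima,
    representable_landscape,
    rmf_landscape,
)

from _oracles import brute_force_accessible


class TestRandomDag:
    def test_single_gene_attaches_to_root(self, rng):
        dag = generate_random_dag(1, 0.7, rng)
        assert dag.parent_masks == (0,)

    def test_zero_density_gives_empty_poset(self, rng):
        dag = generate_random_dag(4, 0.0, rng)
        assert dag.parent_masks == (0, 0, 0, 0)
        assert fitness_graph_from_dag(dag).paths_to_sinks() == math.factorial(4)

    @pytest.mark.parametrize("seed", range(5))
    def test_structural_invariants_and_determinism(self, seed):
        a = generate_random_dag(7, 0.3, np.random.default_rng(seed))
        b = generate_random_dag(7, 0.3, np.random.default_rng(seed))
        assert a.parent_masks == b.parent_masks  # same seed, same DAG
        # acyclicity is validated in the constructor; every gene reachable
        # from Root holds by construction (parentless genes attach to Root)
        assert len(a.parent_masks) == 7

    def test_invalid_arguments(self, rng):
        with pytest.raises(ValueError):
            generate_random_dag(0, 0.5, rng)
        with pytest.raises(ValueError):
            generate_random_dag(3, 1.5, rng)


class TestFitnessGraphFromDag:
    def test_fig1_dag_has_ten_accessible_genotypes(self, fig1_graph):
        assert len(fig1_graph.nodes) == 10

    def test_fig1_excludes_genotype_1001(self, fig1_graph):
        assert genotype_from_str("1001") not in fig1_graph.nodes

    def test_empty_poset_seven_genes(self, rng):
        dag = DagOfRestrictions(7, (0,) * 7)
        fg = fitness_graph_from_dag(dag)
        assert len(fg.nodes) == 2**7
        assert fg.paths_to_sinks() == math.factorial(7)  # 5040

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 7))
        dag = generate_random_dag(K, float(rng.uniform(0, 0.8)), rng)
        fg = fitness_graph_from_dag(dag)
        assert set(fg.nodes) == brute_force_accessible(dag.parent_masks)
        # every accessible pair differing by one added mutation is an edge
        for u in fg.nodes:
            expected = {
                u | (1 << i)
                for i in range(K)
                if not (u >> i) & 1 and (u | (1 << i)) in fg.nodes
            }
            assert set(fg.out_edges.get(u, ())) == expected


class TestBirthRates:
    def test_wild_type_rate_one_and_inaccessible_zero(self, fig1_graph, rng):
        L = assign_birth_rates(fig1_graph, rng=rng)
        assert L.rate(0) == 1.0
        assert L.rate(genotype_from_str("1001")) == 0.0

    def test_rates_strictly_increase_along_edges(self, rng):
        for _ in range(20):
            L = representable_landscape(5, 0.4, rng)
            for u, children in L.graph.out_edges.items():
                for v in children:
                    assert L.rate(v) > L.rate(u)

    def test_multiplier_bounds(self, fig1_graph, rng):
        L = assign_birth_rates(fig1_graph, rng=rng)
        parents = L.graph.in_edges()
        for g in L.graph.nodes:
            if g == 0:
                continue
            mx = max(L.rate(p) for p in parents[g])
            assert 1.01 * mx <= L.rate(g) <= 1.19 * mx

    def test_mean_multiplicative_increment_near_point_one(self):
        rng = np.random.default_rng(99)
        incs = []
        for _ in range(300):
            L = representable_landscape(5, 0.3, rng)
            parents = L.graph.in_edges()
            for g in L.graph.nodes:
                if g:
                    mx = max(L.rate(p) for p in parents[g])
                    incs.append(L.rate(g) / mx - 1.0)
        # U(1.01, 1.19) has mean 0.1 and sd 0.18/sqrt(12)
        se = 0.18 / math.sqrt(12) / math.sqrt(len(incs))
        assert abs(np.mean(incs) - 0.1) < 4 * se

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            BirthRateAssignmentParams(lo=0.9, hi=1.1)


class TestPruning:
    def test_zero_fraction_returns_graph_unchanged(self, fig1_graph, rng):
        assert prune_to_local_maxima(fig1_graph, 0.0, rng=rng) is fig1_graph

    @pytest.mark.parametrize("seed", range(10))
    def test_nodes_kept_and_reachability_preserved(self, seed):
        rng = np.random.default_rng(seed)
        fg = fitness_graph_from_dag(generate_random_dag(6, 0.2, rng))
        pruned = prune_to_local_maxima(fg, 0.5, n_tries=10, rng=rng)
        assert pruned.nodes == fg.nodes
        assert pruned.reachable_from_wild_type() == fg.nodes
        assert len(pruned.sinks()) >= len(fg.sinks())

    def test_fig1_reachability(self, fig1_graph, rng):
        pruned = prune_to_local_maxima(fig1_graph, 0.6, n_tries=50, rng=rng)
        assert len(pruned.reachable_from_wild_type()) == 10


class TestRmf:
    def test_additive_only_is_single_peaked(self, rng):
        L = rmf_landscape(5, slope_c=0.2, hoc_sd=0.0, rng=rng)
        ref = L.rmf_params["reference"]
        # rate strictly decreasing in Hamming distance from the reference
        for g, r in L.birth_rate.items():
            d = bin(g ^ ref).count("1")
            assert math.isclose(
                math.log(r) - math.log(L.rate(0)),
                -0.2 * d + 0.2 * bin(ref).count("1"),
                rel_tol=1e-9,
            )
        assert landscape_stats(L)["n_local_maxima"] == 1

    def test_reference_is_global_maximum(self, rng):
        for _ in range(10):
            L = rmf_landscape(5, 0.05, 0.08, rng)
            ref = L.rmf_params["reference"]
            assert L.rate(ref) == max(L.birth_rate.values())

    def test_pure_hoc_local_maxima_fraction(self):
        # House of Cards: P(local max among itself and K neighbors) = 1/(K+1)
        rng = np.random.default_rng(7)
        K = 4
        counts = [
            landscape_stats(rmf_landscape(K, 0.0, 1.0, rng))["n_local_maxima"]
            for _ in range(1200)
        ]
        expected = 2**K / (K + 1)  # 3.2 for K=4
        se = np.std(counts) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_invalid_params(self, rng):
        with pytest.raises(ValueError):
            rmf_landscape(4, 0.0, 0.0, rng)


class TestStatsAndSerialization:
    def test_representable_has_single_maximum_at_full_genotype(self, rng):
        for _ in range(10):
            L = representable_landscape(6, 0.4, rng)
            stats = landscape_stats(L)
            assert stats["n_local_maxima"] == 1
            assert stats["max_genotype_sizes"] == [6]

    def test_local_maxima_kind_has_multiple_peaks(self, rng):
        L = local_maxima_landscape(6, 0.2, 0.6, n_tries=30, rng=rng)
        assert landscape_stats(L)["n_local_maxima"] >= 2

    def test_same_seed_identical_serialization(self):
        a = representable_landscape(6, 0.3, np.random.default_rng(5)).to_json()
        b = representable_landscape(6, 0.3, np.random.default_rng(5)).to_json()
        assert a == b

    def test_json_roundtrip(self, rng):
        for maker in (
            lambda: representable_landscape(5, 0.3, rng),
            lambda: local_maxima_landscape(5, 0.3, rng=rng),
            lambda: rmf_landscape(5, 0.05, 0.05, rng),
        ):
            L = maker()
            back = FitnessLandscape.from_json(L.to_json())
            assert back.birth_rate == L.birth_rate
            assert back.kind == L.kind
            if L.graph is not None:
                assert back.graph.out_edges == L.graph.out_edges

    def test_genotype_string_conventions(self):
        # "1010" = first and third genes mutated
        assert genotype_from_str("1010") == 0b0101
        assert genotype_to_str(0b0101, 4) == "1010"
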