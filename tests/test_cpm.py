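"""Oncogenetic tree and conjunctive Bayesian network fitting."""

import logging
import math

import numpy as np
import pandas as pd
import pytest

from cpmpaths.cpm import (
    AnnealSchedule,
    ConjunctiveBayesianNetwork,
    ExternalCpmAdapter,
    OncogeneticTree,
    cbn_loglik,
    fit_cbn,
    fit_ot,
    generate_from_cbn,
)
from cpmpaths.detection import CrossSectionalDataset

DIAMOND = (0, 0b0001, 0b0001, 0b0110)  # g1 -> g2, g1 -> g3, {g2,g3} -> g4
NAMES4 = ["g1", "g2", "g3", "g4"]

SMALL_SCHEDULE = AnnealSchedule(restarts=2, steps=400, em_iters=1, final_em_iters=50)


def cbn_data(masks, rates, eps, n, seed, names=None):
    names = names or [f"g{i + 1}" for i in range(len(masks))]
    model = ExternalCpmAdapter(names, masks, list(rates), eps)
    return generate_from_cbn(model, n, np.random.default_rng(seed))


class TestOncogeneticTree:
    def test_chain_recovered_from_noiseless_chain_data(self):
        ds = cbn_data((0, 1, 2), [3.0, 2.0, 1.5], 0.0, 2000, 0)
        results = OncogeneticTree(ds).fit()
        assert results.parents == [-1, 0, 1]

    def test_independent_equal_marginals_give_star(self):
        # truly independent Bernoulli features: no pairwise association, so
        # every feature attaches directly under the root
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(
            (rng.random((5000, 3)) < 0.45).astype(int), columns=["a", "b", "c"]
        )
        results = OncogeneticTree(CrossSectionalDataset(mat)).fit()
        assert results.parents == [-1, -1, -1]

    def test_deterministic_given_dataset(self):
        ds = cbn_data(DIAMOND, [1.0] * 4, 0.05, 500, 2)
        a, b = OncogeneticTree(ds).fit(), OncogeneticTree(ds).fit()
        assert a.parents == b.parents and a.edge_weights == b.edge_weights

    def test_output_is_spanning_arborescence(self):
        for seed in range(5):
            ds = cbn_data(DIAMOND, [0.5, 1.0, 2.0, 1.0], 0.1, 300, seed)
            results = OncogeneticTree(ds).fit()
            # every feature has exactly one parent; parent links are acyclic
            assert len(results.parents) == 4
            for j in range(4):
                seen = set()
                node = j
                while node != -1:
                    assert node not in seen
                    seen.add(node)
                    node = results.parents[node]

    def test_degenerate_column_clamped_with_warning(self, caplog):
        mat = pd.DataFrame({"a": [1, 0, 1, 0], "b": [0, 0, 0, 0]})
        with caplog.at_level(logging.WARNING):
            results = OncogeneticTree(CrossSectionalDataset(mat)).fit()
        assert "degenerate" in caplog.text
        assert results.parents[1] == -1  # never-mutated feature off the root

    def test_edge_weights_are_conditional_probabilities(self):
        ds = cbn_data((0, 1), [2.0, 2.0], 0.0, 4000, 3)
        results = OncogeneticTree(ds).fit()
        X = ds.matrix.to_numpy()
        p1 = X[:, 0].mean()
        p12 = (X[:, 0] & X[:, 1]).mean()
        assert results.edge_weights[1] == pytest.approx(p12 / p1, abs=1e-9)


class TestCbnLikelihood:
    def test_single_feature_closed_form(self):
        ds = cbn_data((0,), [2.0], 0.0, 1000, 4, names=["x"])
        cbn = ConjunctiveBayesianNetwork(ds)
        k = int(ds.matrix["x"].sum())
        expected = k * math.log(2 / 3) + (1000 - k) * math.log(1 / 3)
        assert cbn.loglik((0,), [2.0], 0.0) == pytest.approx(expected)

    def test_zero_eps_incompatible_observation_gives_minus_inf(self):
        mat = pd.DataFrame({"a": [0, 1], "b": [1, 0]})  # b without a
        cbn = ConjunctiveBayesianNetwork(CrossSectionalDataset(mat))
        chain = (0, 0b01)  # a -> b
        assert cbn.loglik(chain, [1.0, 1.0], 0.0) == -math.inf

    def test_em_never_decreases_loglik(self):
        ds = cbn_data(DIAMOND, [1.0] * 4, 0.05, 500, 5)
        cbn = ConjunctiveBayesianNetwork(ds)
        from cpmpaths.cpm import _Lattice

        lattice = _Lattice(DIAMOND)
        lam = np.ones(4)
        eps = 0.2
        lls = []
        for _ in range(15):
            lam, eps, ll = cbn._em(lattice, lam, eps, iters=1)
            lls.append(ll)
        assert all(b >= a - 1e-7 for a, b in zip(lls, lls[1:]))

    def test_matches_monte_carlo_estimate_on_three_genes(self):
        # forward sampling with 1e6 draws as the independent oracle
        masks, lam, eps = (0, 1, 1), [1.5, 0.8, 1.2], 0.1
        rng = np.random.default_rng(6)
        big = generate_from_cbn(
            ExternalCpmAdapter(["a", "b", "c"], masks, lam, eps), 10**6, rng
        )
        codes = big.matrix.to_numpy() @ (1 << np.arange(3))
        freq = np.bincount(codes, minlength=8) / len(codes)
        cbn = ConjunctiveBayesianNetwork(
            CrossSectionalDataset(
                pd.DataFrame(
                    [[(g >> i) & 1 for i in range(3)] for g in range(8)],
                    columns=["a", "b", "c"],
                )
            )
        )
        ll = cbn.loglik(masks, lam, eps)  # log P for each of the 8 genotypes
        # recompute per-genotype probabilities exactly and compare to MC
        from cpmpaths.cpm import _Lattice

        lattice = _Lattice(masks)
        G = lattice.green(np.array(lam))
        p_true = np.zeros(8)
        for idx, s in enumerate(lattice.states):
            p_true[s] = G[0, idx]
        # convolve with the error model
        p_obs = np.zeros(8)
        for x in range(8):
            for s in lattice.states:
                d = bin(x ^ int(s)).count("1")
                p_obs[x] += p_true[s] * eps**d * (1 - eps) ** (3 - d)
        se = np.sqrt(p_obs * (1 - p_obs) / 10**6)
        assert np.all(np.abs(freq - p_obs) < 3.5 * se + 1e-9)

    def test_true_model_beats_perturbed_poset_on_large_data(self):
        ds = cbn_data(DIAMOND, [1.0] * 4, 0.05, 5000, 7)
        cbn = ConjunctiveBayesianNetwork(ds)
        ll_true = cbn.loglik(DIAMOND, [1.0] * 4, 0.05)
        perturbed = (0, 0, 0b0001, 0b0110)  # drop g1 -> g2
        ll_pert = cbn.loglik(perturbed, [1.0] * 4, 0.05)
        assert ll_true > ll_pert


class TestCbnFit:
    def test_empty_poset_recovered_for_independent_features(self):
        ds = cbn_data((0, 0, 0), [1.0, 2.0, 0.7], 0.05, 3000, 8)
        results = ConjunctiveBayesianNetwork(ds).fit(
            schedule=SMALL_SCHEDULE, seed=8
        )
        assert results.parent_masks == (0, 0, 0)

    def test_diamond_poset_recovered(self):
        ds = cbn_data(DIAMOND, [1.0] * 4, 0.05, 2000, 9)
        results = ConjunctiveBayesianNetwork(ds).fit(
            schedule=SMALL_SCHEDULE, seed=9
        )
        assert results.parent_masks == DIAMOND

    def test_fit_loglik_at_least_empty_poset(self):
        ds = cbn_data(DIAMOND, [1.0] * 4, 0.05, 800, 10)
        cbn = ConjunctiveBayesianNetwork(ds)
        full = cbn.fit(schedule=SMALL_SCHEDULE, seed=10)
        empty = cbn.fit_fixed()  # EM on the empty poset
        assert full.loglik >= empty.loglik - 1e-7

    def test_zero_step_budget_returns_empty_poset_em(self):
        ds = cbn_data((0, 1), [1.0, 1.0], 0.05, 400, 11)
        results = ConjunctiveBayesianNetwork(ds).fit(
            schedule=AnnealSchedule(restarts=1, steps=0, final_em_iters=30),
            seed=11,
        )
        assert results.parent_masks == (0, 0)

    def test_structure_recovery_improves_with_sample_size(self):
        hits = {}
        for n in (100, 1000):
            ok = 0
            for rep in range(5):
                ds = cbn_data(DIAMOND, [1.0] * 4, 0.05, n, 100 + rep)
                res = ConjunctiveBayesianNetwork(ds).fit(
                    schedule=SMALL_SCHEDULE, seed=rep
                )
                ok += res.parent_masks == DIAMOND
            hits[n] = ok
        assert hits[1000] >= hits[100]

    def test_degenerate_columns_reattached(self):
        mat = cbn_data((0, 1), [1.0, 1.0], 0.0, 300, 12).matrix
        mat["always"] = 1
        mat["never"] = 0
        results = ConjunctiveBayesianNetwork(
            CrossSectionalDataset(mat)
        ).fit(schedule=SMALL_SCHEDULE, seed=12)
        assert results.rates[2] >= 1e5  # 'always' effectively instantaneous
        assert results.rates[3] <= 1e-5  # 'never' effectively rate zero
        assert results.parent_masks[2] == results.parent_masks[3] == 0

    def test_summary_mentions_fit_dimensions(self):
        ds = cbn_data((0, 1), [1.0, 1.0], 0.05, 200, 13)
        res = ConjunctiveBayesianNetwork(ds).fit(schedule=SMALL_SCHEDULE, seed=13)
        text = res.summary()
        assert "n = 200" in text and "K = 2" in text


class TestGenerateFromCbn:
    def test_zero_eps_rows_respect_poset(self):
        ds = cbn_data(DIAMOND, [1.0] * 4, 0.0, 500, 14)
        X = ds.matrix.to_numpy()
        for row in X:
            g = sum(int(b) << i for i, b in enumerate(row))
            for j in range(4):
                if (g >> j) & 1:
                    assert (DIAMOND[j] & g) == DIAMOND[j]

    def test_single_feature_marginal_is_lambda_over_one_plus_lambda(self):
        ds = cbn_data((0,), [1.0], 0.0, 40000, 15)
        assert ds.matrix.iloc[:, 0].mean() == pytest.approx(0.5, abs=0.01)

    def test_huge_rates_give_all_ones(self):
        ds = cbn_data((0, 1), [1e9, 1e9], 0.0, 50, 16)
        assert ds.matrix.to_numpy().all()

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            cbn_data((0,), [1.0], 0.0, 0, 17)


class TestWrappersAndAdapters:
    def test_functional_wrappers(self):
        ds = cbn_data((0, 1), [1.0, 1.0], 0.05, 300, 18)
        assert fit_ot(ds).parents == OncogeneticTree(ds).fit().parents
        res = fit_cbn(ds, schedule=SMALL_SCHEDULE, seed=18)
        assert cbn_loglik(res, ds) == pytest.approx(res.loglik)

    def test_adapter_from_edges(self):
        ad = ExternalCpmAdapter.from_edges(
            ["a", "b", "c"], [("a", "b"), ("a", "c")], {"a": 2.0, "b": 1.0, "c": 1.0}
        )
        assert ad.parent_masks == (0, 1, 1)
        assert ad.rates == [2.0, 1.0, 1.0]
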