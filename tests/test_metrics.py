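"""JS divergence, entropies, and the unequal-length comparison procedure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpmpaths.metrics import (
    compare_path_distributions,
    js_divergence,
    most_common_lod_recovered,
    path_entropy,
)
from cpmpaths.paths import PathDistribution, uniform_path_distribution

from _oracles import oracle_compare, random_mixed_length_instance, scipy_js


def dist(d):
    return PathDistribution(d)


class TestPathEntropy:
    def test_single_path_zero(self):
        assert path_entropy(dist({("a",): 1.0})).entropy == 0.0

    def test_equiprobable_identities(self):
        # 25 equiprobable paths -> 3.2 nats; 400 -> 6.0 nats
        s25 = path_entropy(uniform_path_distribution([(f"p{i}",) for i in range(25)]))
        s400 = path_entropy(uniform_path_distribution([(f"p{i}",) for i in range(400)]))
        assert round(s25.entropy, 1) == 3.2
        assert round(s400.entropy, 1) == 6.0
        assert s25.n_equivalent_paths == pytest.approx(25.0)

    def test_two_equal_paths(self):
        s = path_entropy(dist({("a",): 0.5, ("b",): 0.5}))
        assert s.entropy == pytest.approx(math.log(2))

    @pytest.mark.parametrize("n", [1, 2, 7, 64, 1000, 10000])
    def test_uniform_entropy_is_log_n(self, n):
        d = uniform_path_distribution([(f"p{i}",) for i in range(n)])
        assert path_entropy(d).entropy == pytest.approx(math.log(n))


class TestJsDivergence:
    def test_identical_distributions(self):
        d = dist({("a", "b"): 0.25, ("b", "a"): 0.75})
        assert js_divergence(d, d) == 0.0

    def test_disjoint_supports(self):
        assert js_divergence(dist({("a",): 1.0}), dist({("b",): 1.0})) == 1.0

    def test_half_overlap_value(self):
        p = dist({("a",): 0.5, ("b",): 0.5})
        q = dist({("a",): 0.5, ("c",): 0.5})
        assert js_divergence(p, q) == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 10**6))
    def test_symmetric_bounded_and_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 8))
        support = [(f"s{i}",) for i in range(n + 2)]
        p_raw = rng.dirichlet(np.ones(n + 2))
        q_raw = rng.dirichlet(np.ones(n + 2))
        # knock out some entries to create partial overlap
        p_raw[rng.random(n + 2) < 0.3] = 0
        q_raw[rng.random(n + 2) < 0.3] = 0
        if p_raw.sum() == 0 or q_raw.sum() == 0:
            return
        p_raw, q_raw = p_raw / p_raw.sum(), q_raw / q_raw.sum()
        P = dist({s: float(v) for s, v in zip(support, p_raw) if v > 0})
        Q = dist({s: float(v) for s, v in zip(support, q_raw) if v > 0})
        a, b = js_divergence(P, Q), js_divergence(Q, P)
        assert a == pytest.approx(b)
        assert 0.0 <= a <= 1.0
        union = sorted(set(P.probs) | set(Q.probs))
        assert a == pytest.approx(
            scipy_js([P[s] for s in union], [Q[s] for s in union]), abs=1e-9
        )


class TestCompareEqualLengths:
    def test_reduces_to_plain_statistics(self):
        lod = dist({("a", "b"): 0.7, ("b", "a"): 0.3})
        cpm = dist({("a", "b"): 0.2, ("c", "a"): 0.8})
        r = compare_path_distributions(lod, cpm)
        assert r.js == pytest.approx(js_divergence(lod, cpm))
        assert r.one_minus_recall == pytest.approx(0.3)
        assert r.one_minus_precision == pytest.approx(0.8)
        assert r.weights == {2: pytest.approx(1.0)}

    @pytest.mark.parametrize("seed", range(50))
    def test_random_equal_length_instances_match_plain(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            lod, cpm = random_mixed_length_instance(rng)
            (k_c,) = {len(p) for p in cpm}
            lod = {p[:k_c]: v for p, v in lod.items() if len(p) >= k_c}
            if lod:
                break
        total = sum(lod.values())
        lod = {p: v / total for p, v in lod.items()}
        L, C = dist(lod), dist(cpm)
        r = compare_path_distributions(L, C)
        assert r.js == pytest.approx(js_divergence(L, C), abs=1e-12)


class TestCompareUnequalLengths:
    def test_worked_prefix_example(self):
        # one LOD of three mutations vs a CPM predicting its 2-mutation
        # prefix: a third of the LOD flow is unaccounted for
        r = compare_path_distributions(
            dist({("a", "b", "c"): 1.0}), dist({("a", "b"): 1.0})
        )
        assert r.js == pytest.approx(0.19087, abs=1e-4)
        assert r.one_minus_recall == pytest.approx(1 / 3)
        assert r.one_minus_precision == 0.0

    def test_no_shared_prefixes_saturates_all_statistics(self):
        r = compare_path_distributions(
            dist({("a", "b", "c"): 1.0}), dist({("x", "y"): 1.0})
        )
        assert (r.js, r.one_minus_recall, r.one_minus_precision) == (1.0, 1.0, 1.0)

    @pytest.mark.parametrize("seed", range(500))
    def test_matches_literal_transcription_oracle(self, seed):
        lod, cpm = random_mixed_length_instance(np.random.default_rng(seed))
        r = compare_path_distributions(dist(lod), dist(cpm))
        js_o, rec_o, prec_o = oracle_compare(lod, cpm)
        assert r.js == pytest.approx(js_o, abs=1e-9)
        assert r.one_minus_recall == pytest.approx(rec_o, abs=1e-9)
        assert r.one_minus_precision == pytest.approx(prec_o, abs=1e-9)

    def test_group_weights_are_lod_length_frequencies(self):
        lod = dist({("a",): 0.25, ("a", "b"): 0.5, ("b", "a"): 0.25})
        r = compare_path_distributions(lod, dist({("a", "b"): 1.0}))
        assert r.weights[1] == pytest.approx(0.25)
        assert r.weights[2] == pytest.approx(0.75)
        assert math.fsum(r.weights.values()) == pytest.approx(1.0)

    def test_recall_precision_zero_with_large_js(self):
        # both error statistics can be 0 while the distributions disagree
        # almost completely on shared support
        lod = dist({("a", "b"): 0.999, ("b", "a"): 0.001})
        cpm = dist({("a", "b"): 0.001, ("b", "a"): 0.999})
        r = compare_path_distributions(lod, cpm)
        assert r.one_minus_recall == 0.0
        assert r.one_minus_precision == 0.0
        assert r.js > 0.9

    def test_unnormalized_mode_runs_and_reduces_identically_when_equal(self):
        lod = dist({("a", "b"): 0.7, ("b", "a"): 0.3})
        cpm = dist({("a", "b"): 1.0})
        a = compare_path_distributions(lod, cpm, renormalize=True)
        b = compare_path_distributions(lod, cpm, renormalize=False)
        # single length group with w_k = 1: both modes coincide
        assert a.js == pytest.approx(b.js)

    def test_unnormalized_mode_differs_on_mixed_lengths(self):
        lod = dist({("a",): 0.7, ("a", "b"): 0.3})
        cpm = dist({("a", "b"): 1.0})
        a = compare_path_distributions(lod, cpm, renormalize=True)
        b = compare_path_distributions(lod, cpm, renormalize=False)
        assert a.js != pytest.approx(b.js)

    def test_cpm_side_must_be_equal_length(self):
        with pytest.raises(ValueError):
            compare_path_distributions(
                dist({("a",): 1.0}), dist({("a",): 0.5, ("a", "b"): 0.5})
            )


class TestMostCommonLod:
    def test_verbatim_presence(self):
        lod = dist({("a", "b"): 0.9, ("b", "a"): 0.1})
        assert most_common_lod_recovered(lod, {("a", "b")}) == 1

    def test_prefix_inclusion_counts(self):
        lod = dist({("a",): 0.9, ("b",): 0.1})
        assert most_common_lod_recovered(lod, {("a", "b")}) == 1

    def test_unmatched_modal_path(self):
        lod = dist({("c", "a"): 0.9, ("a", "b"): 0.1})
        assert most_common_lod_recovered(lod, {("a", "b"), ("b", "a")}) == 0

    def test_tied_modal_paths_count_if_any_matches(self):
        lod = dist({("c", "d"): 0.5, ("a", "b"): 0.5})
        assert most_common_lod_recovered(lod, {("a", "b")}) == 1
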