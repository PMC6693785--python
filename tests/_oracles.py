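"""Independent straight-line oracles used to cross-check the package.

These deliberately re-derive results with different code paths (scipy's
Jensen-Shannon distance, brute-force enumeration, literal transcription of
the unequal-length comparison procedure) and must stay independent of the
implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.spatial.distance import jensenshannon


def brute_force_accessible(parent_masks: tuple[int, ...]) -> set[int]:
    """All genotypes satisfying the AND rule, tested one by one."""
    K = len(parent_masks)
    out = set()
    for g in range(1 << K):
        ok = True
        for j in range(K):
            if (g >> j) & 1 and (parent_masks[j] & g) != parent_masks[j]:
                ok = False
        if ok:
            out.add(g)
    return out


def brute_force_linear_extensions(parent_masks: tuple[int, ...]) -> set[tuple[int, ...]]:
    """Linear extensions by filtering all K! permutations."""
    K = len(parent_masks)
    out = set()
    for perm in itertools.permutations(range(K)):
        done = 0
        ok = True
        for j in perm:
            if (parent_masks[j] & done) != parent_masks[j]:
                ok = False
                break
            done |= 1 << j
        if ok:
            out.add(perm)
    return out


def brute_force_step_weights(
    parent_masks: tuple[int, ...], weights: list[float]
) -> dict[tuple[int, ...], float]:
    """Path probabilities by evaluating every permutation's step products."""
    K = len(parent_masks)
    probs: dict[tuple[int, ...], float] = {}
    for perm in brute_force_linear_extensions(parent_masks):
        p = 1.0
        done = 0
        for j in perm:
            avail = [
                a
                for a in range(K)
                if not (done >> a) & 1 and (parent_masks[a] & done) == parent_masks[a]
            ]
            p *= weights[j] / sum(weights[a] for a in avail)
            done |= 1 << j
        probs[perm] = p
    return probs


def scipy_js(p: list[float], q: list[float]) -> float:
    """Scaled JS divergence via scipy's JS *distance* (its square)."""
    return float(jensenshannon(np.asarray(p), np.asarray(q), base=2) ** 2)


def oracle_compare(
    lod_probs: dict[tuple, float], cpm_probs: dict[tuple, float]
) -> tuple[float, float, float]:
    """Literal transcription of the unequal-length comparison procedure.

    Returns (JS, 1-recall, 1-precision).  LOD groups are renormalized to
    conditional distributions; per-group statistics are combined with the
    weights w_k (LOD frequency of terminal length k).
    """
    K_C_set = {len(p) for p in cpm_probs}
    assert len(K_C_set) == 1
    (K_C,) = K_C_set

    js_total = recall_total = precision_total = 0.0
    for k in sorted({len(p) for p in lod_probs}):
        group = {p: v for p, v in lod_probs.items() if len(p) == k}
        w_k = sum(group.values())
        cond = {p: v / w_k for p, v in group.items()}

        if k == K_C:
            support = sorted(set(cond) | set(cpm_probs))
            P = [cond.get(s, 0.0) for s in support]
            Q = [cpm_probs.get(s, 0.0) for s in support]
            js = scipy_js(P, Q)
            rec = sum(v for p, v in cond.items() if p not in cpm_probs)
            prec = sum(v for p, v in cpm_probs.items() if p not in cond)
        elif k < K_C:
            # CPM paths are longer; each LOD path may be the prefix of
            # several CPM paths, whose matched fraction is k / K_C
            P, Q = [], []
            unmatched_q = 0.0
            rec = 0.0
            for i, p_i in cond.items():
                matched = sum(
                    q for j, q in cpm_probs.items() if j[: k] == i
                )
                P.append(p_i)
                Q.append(matched * k / K_C)
                if matched == 0.0:
                    rec += p_i
            for j, q_j in cpm_probs.items():
                if any(j[:k] == i for i in cond):
                    unmatched_q += q_j * (K_C - k) / K_C
                else:
                    unmatched_q += q_j
            P.append(0.0)
            Q.append(unmatched_q)
            prec = unmatched_q
            js = scipy_js(P, Q)
        else:
            # LOD paths are longer; their matched fraction is K_C / k
            P, Q = [], []
            prec = 0.0
            for j, q_j in cpm_probs.items():
                matched = sum(
                    v for i, v in cond.items() if i[: K_C] == j
                )
                P.append(matched * K_C / k)
                Q.append(q_j)
                if matched == 0.0:
                    prec += q_j
            unmatched_p = 0.0
            for i, p_i in cond.items():
                if i[:K_C] in cpm_probs:
                    unmatched_p += p_i * (k - K_C) / k
                else:
                    unmatched_p += p_i
            P.append(unmatched_p)
            Q.append(0.0)
            rec = unmatched_p
            js = scipy_js(P, Q)

        js_total += w_k * js
        recall_total += w_k * rec
        precision_total += w_k * prec
    return js_total, recall_total, precision_total


def random_mixed_length_instance(rng: np.random.Generator, max_features: int = 6):
    """A random (lod_probs, cpm_probs) pair with mixed LOD lengths."""
    K = int(rng.integers(2, max_features + 1))
    features = tuple(f"g{i}" for i in range(K))
    K_C = int(rng.integers(1, K + 1))
    cpm_features = list(rng.permutation(features)[:K_C])
    all_cpm = list(itertools.permutations(cpm_features))
    n_cpm = int(rng.integers(1, min(len(all_cpm), 6) + 1))
    idx = rng.choice(len(all_cpm), size=n_cpm, replace=False)
    cpm_support = [all_cpm[i] for i in idx]
    q = rng.dirichlet(np.ones(n_cpm))
    cpm_probs = {tuple(p): float(v) for p, v in zip(cpm_support, q)}

    lod_support = set()
    n_lod = int(rng.integers(1, 7))
    for _ in range(n_lod):
        if rng.random() < 0.5 and cpm_support:
            # relate to a CPM path: truncate or extend it
            base = list(cpm_support[int(rng.integers(len(cpm_support)))])
            if rng.random() < 0.5 and len(base) > 1:
                base = base[: int(rng.integers(1, len(base)))]
            else:
                extra = [f for f in features if f not in base]
                rng.shuffle(extra)
                base = base + extra[: int(rng.integers(0, len(extra) + 1))]
            lod_support.add(tuple(base))
        else:
            length = int(rng.integers(1, K + 1))
            lod_support.add(tuple(rng.permutation(features)[:length]))
    lod_support = sorted(lod_support)
    p = rng.dirichlet(np.ones(len(lod_support)))
    lod_probs = {tuple(s): float(v) for s, v in zip(lod_support, p)}
    return lod_probs, cpm_probs
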