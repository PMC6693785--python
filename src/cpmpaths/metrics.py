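"""Performance and predictability statistics for path distributions.

Four statistics compare a true (LOD-derived) path distribution ``p`` with a
CPM-predicted one ``q``:

* **JS** — Jensen-Shannon divergence with base-2 logarithms, so it lies in
  [0, 1]: 0 means identical distributions, 1 disjoint supports.  Defined on
  the union of the supports, so it handles paths present in only one side.
* **1 - recall** = P(not-DAG | LOD): the LOD probability mass on paths (or
  fractions of paths) the CPM does not allow.
* **1 - precision** = P(not-LOD | DAG): the CPM probability mass on paths
  (or fractions of paths) evolution never took.
* **S_p / S_c** — Shannon entropy (natural log) of the LOD / CPM path
  distribution, the measure of evolutionary unpredictability; exp(S) is the
  equivalent number of equiprobable paths.

When LOD paths end at different numbers of mutations than the CPM paths
(which all end at the fully mutated genotype, length ``K_C``), the
comparison groups LODs by terminal length ``k`` and prefix-matches each
group against the CPM paths, splitting the longer side's probability into a
matched fraction ``min(k, K_C)/max(k, K_C)`` and an unaccounted remainder;
per-group statistics are then combined with weights ``w_k``, the LOD
frequency of each terminal length.  With all lengths equal this reduces
exactly to the plain JS / recall / precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .paths import Path, PathDistribution

__all__ = [
    "DiversityResult",
    "ComparisonResult",
    "path_entropy",
    "js_divergence",
    "compare_path_distributions",
    "most_common_lod_recovered",
]


@dataclass(frozen=True)
class DiversityResult:
    """Entropy of a path distribution, in nats."""

    entropy: float

    @property
    def n_equivalent_paths(self) -> float:
        """exp(S): the number of equiprobable paths with this entropy."""
        return math.exp(self.entropy)

    def __float__(self) -> float:
        return self.entropy


def path_entropy(dist: PathDistribution) -> DiversityResult:
    """Shannon entropy -sum p ln p (natural log; 0 ln 0 = 0)."""
    s = -math.fsum(p * math.log(p) for p in dist.probs.values() if p > 0)
    return DiversityResult(max(s, 0.0))


def _js_from_vectors(p: list[float], q: list[float]) -> float:
    """Base-2 JS of two aligned non-negative vectors."""
    js = 0.0
    for a, b in zip(p, q):
        m = 0.5 * (a + b)
        if a > 0:
            js += 0.5 * a * math.log2(a / m)
        if b > 0:
            js += 0.5 * b * math.log2(b / m)
    return min(max(js, 0.0), 1.0)


def js_divergence(P: PathDistribution, Q: PathDistribution) -> float:
    """Scaled (base-2) Jensen-Shannon divergence over the union support."""
    support = set(P.probs) | set(Q.probs)
    return _js_from_vectors(
        [P[s] for s in sorted(support)], [Q[s] for s in sorted(support)]
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of comparing a LOD distribution with a CPM prediction."""

    js: float
    one_minus_recall: float
    one_minus_precision: float
    weights: dict[int, float]  # terminal length k -> w_k
    mcl_recovered: int  # 1 iff the most common LOD is matched by the CPM

    def as_dict(self) -> dict[str, float]:
        return {
            "js": self.js,
            "one_minus_recall": self.one_minus_recall,
            "one_minus_precision": self.one_minus_precision,
            "mcl": float(self.mcl_recovered),
        }


def _paths_match(a: Path, b: Path) -> bool:
    """Unequal-length inclusion rule: identical up to the shorter length."""
    k = min(len(a), len(b))
    return a[:k] == b[:k]


def _compare_group(
    lod_probs: Mapping[Path, float],
    cpm: PathDistribution,
    k: int,
    K_C: int,
) -> tuple[float, float, float]:
    """(js, 1-recall, 1-precision) for LOD paths of one terminal length k."""
    if k == K_C:
        support = set(lod_probs) | set(cpm.probs)
        p_vec = [lod_probs.get(s, 0.0) for s in sorted(support)]
        q_vec = [cpm[s] for s in sorted(support)]
        js = _js_from_vectors(p_vec, q_vec)
        recall_miss = math.fsum(
            p for path, p in lod_probs.items() if path not in cpm.probs
        )
        prec_miss = math.fsum(
            q for path, q in cpm.probs.items() if path not in lod_probs
        )
        return js, recall_miss, prec_miss

    p_entries: list[float] = []
    q_entries: list[float] = []
    if k < K_C:
        # CPM paths are longer: group them by their k-prefix and split each
        # matched class into an accounted fraction k/K_C and a remainder.
        classes: dict[Path, float] = {}
        for path, q in cpm.probs.items():
            pref = path[:k]
            classes[pref] = classes.get(pref, 0.0) + q
        frac = k / K_C if K_C else 0.0
        q_unmatched = 0.0
        recall_miss = 0.0
        prec_miss = 0.0
        for path, p in lod_probs.items():
            q_c = classes.pop(path, None)
            if q_c is None:
                p_entries.append(p)  # LOD path the CPM never reaches
                q_entries.append(0.0)
                recall_miss += p
            else:
                p_entries.append(p)
                q_entries.append(q_c * frac)
                q_unmatched += q_c * (1.0 - frac)
                prec_miss += q_c * (1.0 - frac)
        for q_c in classes.values():  # CPM prefixes evolution never took
            q_unmatched += q_c
            prec_miss += q_c
        if q_unmatched > 0:
            p_entries.append(0.0)
            q_entries.append(q_unmatched)
    else:
        # LOD paths are longer: group them by their K_C-prefix; a class
        # matching a CPM path accounts for it fully, but a fraction
        # (k - K_C)/k of the LOD flow remains unaccounted for.
        classes = {}
        for path, p in lod_probs.items():
            pref = path[:K_C]
            classes[pref] = classes.get(pref, 0.0) + p
        frac = K_C / k if k else 0.0
        p_unmatched = 0.0
        recall_miss = 0.0
        prec_miss = 0.0
        matched_cpm: set[Path] = set()
        for pref, p_c in classes.items():
            if pref in cpm.probs:
                matched_cpm.add(pref)
                p_entries.append(p_c * frac)
                q_entries.append(cpm.probs[pref])
                p_unmatched += p_c * (1.0 - frac)
                recall_miss += p_c * (1.0 - frac)
            else:
                p_unmatched += p_c
                recall_miss += p_c
        for path, q in cpm.probs.items():
            if path not in matched_cpm:
                p_entries.append(0.0)
                q_entries.append(q)
                prec_miss += q
        if p_unmatched > 0:
            p_entries.append(p_unmatched)
            q_entries.append(0.0)
    js = _js_from_vectors(p_entries, q_entries)
    return js, recall_miss, prec_miss


def compare_path_distributions(
    lod_dist: PathDistribution,
    cpm_dist: PathDistribution,
    renormalize: bool = True,
) -> ComparisonResult:
    """Weighted-by-terminal-length comparison of LOD vs CPM paths.

    ``renormalize=True`` (default) compares, at each terminal length ``k``,
    the conditional LOD distribution (renormalized to sum to 1) against the
    full CPM distribution.  ``renormalize=False`` keeps the raw LOD flows
    within each group (so the LOD side of each per-group comparison sums to
    ``w_k``); it is provided as the alternative reading of the procedure.
    Either way the final statistics are the w_k-weighted sums of the
    per-group ones, and both reduce to the plain statistics when every LOD
    path has the CPM length.
    """
    lengths = cpm_dist.lengths()
    if len(lengths) != 1:
        raise ValueError("CPM path distribution must have equal-length paths")
    (K_C,) = lengths

    groups: dict[int, dict[Path, float]] = {}
    for path, p in lod_dist.probs.items():
        groups.setdefault(len(path), {})[path] = p
    weights = {k: math.fsum(g.values()) for k, g in sorted(groups.items())}

    js = recall_miss = prec_miss = 0.0
    for k, group in sorted(groups.items()):
        w_k = weights[k]
        if w_k <= 0:
            continue
        probs = (
            {p: v / w_k for p, v in group.items()} if renormalize else group
        )
        js_k, rm_k, pm_k = _compare_group(probs, cpm_dist, k, K_C)
        js += w_k * js_k
        recall_miss += w_k * rm_k
        prec_miss += w_k * pm_k

    mcl = most_common_lod_recovered(lod_dist, set(cpm_dist.probs))
    return ComparisonResult(
        js=min(max(js, 0.0), 1.0),
        one_minus_recall=min(max(recall_miss, 0.0), 1.0),
        one_minus_precision=min(max(prec_miss, 0.0), 1.0),
        weights=weights,
        mcl_recovered=mcl,
    )


def most_common_lod_recovered(
    lod_dist: PathDistribution, cpm_paths: Iterable[Path]
) -> int:
    """1 iff some modal LOD path is prefix-matched by a CPM path.

    When several LOD paths tie for the top frequency, recovery counts if any
    of them is matched.
    """
    cpm_paths = list(cpm_paths)
    if not cpm_paths:
        raise ValueError("CPM path set must be non-empty")
    best = max(lod_dist.probs.values())
    modal = [p for p, q in lod_dist.probs.items() if q == best]
    for m in modal:
        if any(_paths_match(m, c) for c in cpm_paths):
            return 1
    return 0
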