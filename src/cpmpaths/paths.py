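"""Mutational paths to the maximum and probability distributions over them.

A *path* is the order in which features are acquired, written as a tuple of
feature labels.  For a CPM fit (or a true DAG of restrictions) the set of
paths to the maximum is the set of linear extensions of the poset — the
source-to-sink paths of its fitness graph — and every such path ends at the
fully mutated genotype, so all CPM paths share one length.  Lines of descent
from simulations give an empirical distribution whose paths may differ in
length (they end wherever evolution fixated).

CBN fits are converted to probability-weighted paths with the competing-
exponentials rule: at each step the next feature is chosen among the
currently available ones (poset parents satisfied, not yet mutated) with
probability lambda_j / sum(lambda_available).  OT fits use the edge weights,
by default normalized proportionally among the available features at each
step.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Sequence

from .evolution import LOD
from .landscapes import DagOfRestrictions

__all__ = [
    "Path",
    "PathDistribution",
    "TooManyPathsError",
    "iter_paths",
    "paths_from_model",
    "weight_paths_cbn",
    "weight_paths_ot",
    "uniform_path_distribution",
    "lod_path_distribution",
]

Path = tuple[str, ...]

DEFAULT_PATH_CAP = 1_000_000


class TooManyPathsError(RuntimeError):
    """Enumeration exceeded the cap; use the lazy iterator instead."""


@dataclass
class PathDistribution:
    """Probability distribution over mutational paths."""

    probs: dict[Path, float]

    def __post_init__(self) -> None:
        if not self.probs:
            raise ValueError("path distribution must be non-empty")
        if any(p < 0 for p in self.probs.values()):
            raise ValueError("probabilities must be non-negative")
        total = math.fsum(self.probs.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"probabilities must sum to 1 (got {total!r})")

    def __iter__(self) -> Iterator[Path]:
        return iter(self.probs)

    def __len__(self) -> int:
        return len(self.probs)

    def __getitem__(self, path: Path) -> float:
        return self.probs.get(path, 0.0)

    @property
    def support(self) -> set[Path]:
        return {p for p, q in self.probs.items() if q > 0}

    def lengths(self) -> set[int]:
        return {len(p) for p in self.probs}

    def modal_path(self) -> Path:
        """Most probable path; ties broken lexicographically."""
        best = max(self.probs.values())
        return min(p for p, q in self.probs.items() if q == best)

    def to_tsv(self) -> str:
        lines = ["path\tprobability"]
        for p in sorted(self.probs, key=lambda q: (-self.probs[q], q)):
            lines.append(">".join(p) + f"\t{self.probs[p]!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "PathDistribution":
        probs: dict[Path, float] = {}
        lines = [ln for ln in text.splitlines() if ln.strip()]
        for ln in lines[1:]:
            path_s, prob_s = ln.split("\t")
            probs[tuple(path_s.split(">"))] = float(prob_s)
        return cls(probs)


# ---------------------------------------------------------------------------
# poset plumbing: anything with .feature_names + .parent_masks, or a DAG
# ---------------------------------------------------------------------------


def _as_poset(model) -> tuple[list[str], tuple[int, ...]]:
    if isinstance(model, DagOfRestrictions):
        return [f"g{i + 1}" for i in range(model.n_genes)], model.parent_masks
    names = getattr(model, "feature_names", None)
    masks = getattr(model, "parent_masks", None)
    if names is None or masks is None:
        raise TypeError(
            "model must be a DagOfRestrictions or expose "
            "feature_names/parent_masks"
        )
    return list(names), tuple(masks)


def iter_paths(model) -> Iterator[Path]:
    """Lazily enumerate the linear extensions of a poset/tree model."""
    labels, masks = _as_poset(model)
    K = len(labels)
    full = (1 << K) - 1
    prefix: list[str] = []

    def rec(done: int) -> Iterator[Path]:
        if done == full:
            yield tuple(prefix)
            return
        for j in range(K):
            bit = 1 << j
            if not done & bit and masks[j] & done == masks[j]:
                prefix.append(labels[j])
                yield from rec(done | bit)
                prefix.pop()

    return rec(0)


def paths_from_model(model, cap: int = DEFAULT_PATH_CAP) -> set[Path]:
    """All paths to the maximum encoded by a CPM fit or DAG of restrictions."""
    out: set[Path] = set()
    for path in iter_paths(model):
        out.add(path)
        if len(out) > cap:
            raise TooManyPathsError(
                f"more than {cap} paths; stream them with iter_paths() instead"
            )
    return out


def _weighted_paths(
    labels: Sequence[str],
    masks: Sequence[int],
    step_weight: Callable[[int], float],
    cap: int,
) -> PathDistribution:
    """DFS accumulating per-step probabilities proportional to step_weight."""
    K = len(labels)
    full = (1 << K) - 1
    probs: dict[Path, float] = {}
    prefix: list[str] = []

    def rec(done: int, acc: float) -> None:
        if done == full:
            probs[tuple(prefix)] = acc
            if len(probs) > cap:
                raise TooManyPathsError(
                    f"more than {cap} paths; raise cap or stream paths"
                )
            return
        avail = [
            j
            for j in range(K)
            if not done & (1 << j) and masks[j] & done == masks[j]
        ]
        total = sum(step_weight(j) for j in avail)
        for j in avail:
            prefix.append(labels[j])
            rec(done | (1 << j), acc * step_weight(j) / total)
            prefix.pop()

    rec(0, 1.0)
    return PathDistribution(probs)


def weight_paths_cbn(model, cap: int = DEFAULT_PATH_CAP) -> PathDistribution:
    """Competing-exponentials path probabilities from a CBN fit.

    With waiting-time rates lambda_j, the probability that feature j is the
    next to occur among the available set A is lambda_j / sum_{a in A}
    lambda_a (the minimum of independent exponentials); a path's probability
    is the product of its step probabilities.
    """
    labels, masks = _as_poset(model)
    lam = list(getattr(model, "rates"))
    if len(lam) != len(labels):
        raise ValueError("rates length must match feature count")
    return _weighted_paths(labels, masks, lambda j: lam[j], cap)


def weight_paths_ot(
    model, mode: str = "proportional", cap: int = DEFAULT_PATH_CAP
) -> PathDistribution:
    """Path probabilities from an oncogenetic-tree fit's edge weights.

    ``proportional`` (default): at each genotype the transition probability
    to each available feature is its edge weight normalized over the
    available features.  ``product``: a path's unnormalized score is the
    plain product of its edge weights, normalized over all paths at the end
    (an independent-occurrence reading of the weights).  Both modes give the
    same answer for trees where exactly one feature is available at each
    step, and coincide up to normalization on stars.
    """
    labels, masks = _as_poset(model)
    w = list(getattr(model, "edge_weights"))
    if len(w) != len(labels):
        raise ValueError("edge_weights length must match feature count")
    if mode == "proportional":
        return _weighted_paths(labels, masks, lambda j: w[j], cap)
    if mode == "product":
        scores: dict[Path, float] = {}
        for path in iter_paths(model):
            idx = {lab: j for j, lab in enumerate(labels)}
            scores[path] = math.prod(w[idx[lab]] for lab in path)
            if len(scores) > cap:
                raise TooManyPathsError(f"more than {cap} paths")
        total = math.fsum(scores.values())
        return PathDistribution({p: s / total for p, s in scores.items()})
    raise ValueError("mode must be 'proportional' or 'product'")


def uniform_path_distribution(paths: Iterable[Path]) -> PathDistribution:
    """Equal probability on every path (the fallback for CPMs that cannot
    produce probability-weighted paths)."""
    paths = list(paths)
    if not paths:
        raise ValueError("path set must be non-empty")
    q = 1.0 / len(paths)
    return PathDistribution({tuple(p): q for p in paths})


def lod_path_distribution(
    lods: Sequence[LOD], feature_names: Sequence[str] | None = None
) -> PathDistribution:
    """Empirical distribution of lines of descent (relative frequencies)."""
    if not lods:
        raise ValueError("LOD list must be non-empty")
    if feature_names is None:
        feature_names = [f"g{i + 1}" for i in range(lods[0].n_genes)]
    counts = Counter(
        tuple(feature_names[i] for i in lod.gene_order()) for lod in lods
    )
    n = len(lods)
    return PathDistribution({p: c / n for p, c in counts.items()})
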