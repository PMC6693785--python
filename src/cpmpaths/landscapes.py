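"""Random fitness landscapes for tumor progression simulations.

Three families of landscapes over K driver genes are provided, all mapping
genotypes to clonal birth rates:

* **representable** — derived from a random DAG of restrictions (conjunctive
  "AND" semantics: a gene can only mutate once all of its parents have).
  Accessible genotypes and accessible mutational paths coincide exactly with
  those of the DAG, and the fully mutated genotype is the single fitness
  maximum.
* **local_maxima** — same construction, but a random subset of fitness-graph
  edges is removed (keeping every accessible genotype reachable from the wild
  type) before birth rates are assigned, which introduces additional fitness
  peaks.
* **rmf** — Rough Mount Fuji: an additive slope toward a randomly chosen
  reference genotype plus an independent House-of-Cards noise term; every
  genotype has positive birth rate and the landscape is typically rugged.

Genotypes are represented as integer bitmasks; bit ``i`` set means gene ``i``
is mutated.  The string form ``"1010"`` (first and third genes mutated) puts
gene 0 in the leftmost character.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

MAX_GENES = 14  # 2^K genotype enumeration; keep desk-scale

__all__ = [
    "MAX_GENES",
    "genotype_to_str",
    "genotype_from_str",
    "DagOfRestrictions",
    "FitnessGraph",
    "BirthRateAssignmentParams",
    "FitnessLandscape",
    "generate_random_dag",
    "fitness_graph_from_dag",
    "assign_birth_rates",
    "prune_to_local_maxima",
    "rmf_landscape",
    "representable_landscape",
    "local_maxima_landscape",
    "landscape_stats",
]


def genotype_to_str(g: int, n_genes: int) -> str:
    """Bitmask -> ``"0101"`` style string (leftmost char = gene 0)."""
    return "".join("1" if (g >> i) & 1 else "0" for i in range(n_genes))


def genotype_from_str(s: str) -> int:
    """``"0101"`` style string -> bitmask."""
    return sum(1 << i for i, ch in enumerate(s) if ch == "1")


def _popcount(g: int) -> int:
    return int(g).bit_count()


@dataclass(frozen=True)
class DagOfRestrictions:
    """DAG over genes; an edge i -> j means i must mutate before j can.

    Multiple parents are conjunctive (AND): *all* parents of a gene must be
    mutated before the gene can mutate.  Genes with no parents depend only on
    the implicit Root.
    """

    n_genes: int
    parent_masks: tuple[int, ...]  # parent_masks[j] = bitmask of parents of j

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if len(self.parent_masks) != self.n_genes:
            raise ValueError("parent_masks length must equal n_genes")
        for j, m in enumerate(self.parent_masks):
            if (m >> j) & 1:
                raise ValueError(f"self-edge on gene {j}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Kahn's algorithm over gene-level edges
        indeg = [_popcount(m) for m in self.parent_masks]
        queue = [j for j, d in enumerate(indeg) if d == 0]
        seen = 0
        children = self.children_lists()
        while queue:
            u = queue.pop()
            seen += 1
            for v in children[u]:
                indeg[v] -= 1
                if indeg[v] == 0:
                    queue.append(v)
        if seen != self.n_genes:
            raise ValueError("DAG of restrictions contains a cycle")

    def children_lists(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_genes)]
        for j, m in enumerate(self.parent_masks):
            for i in range(self.n_genes):
                if (m >> i) & 1:
                    out[i].append(j)
        return out

    @property
    def edges(self) -> set[tuple[int, int]]:
        """Set of explicit gene -> gene edges (Root edges are implicit)."""
        return {
            (i, j)
            for j, m in enumerate(self.parent_masks)
            for i in range(self.n_genes)
            if (m >> i) & 1
        }

    def genotype_allowed(self, g: int) -> bool:
        """True iff every mutated gene has all its parents mutated."""
        for j in range(self.n_genes):
            if (g >> j) & 1 and (self.parent_masks[j] & g) != self.parent_masks[j]:
                return False
        return True

    # --- export -----------------------------------------------------------
    def to_networkx(self):
        import networkx as nx

        G = nx.DiGraph()
        G.add_node("Root")
        for j in range(self.n_genes):
            G.add_node(f"g{j + 1}")
        for j, m in enumerate(self.parent_masks):
            if m == 0:
                G.add_edge("Root", f"g{j + 1}")
            else:
                for i in range(self.n_genes):
                    if (m >> i) & 1:
                        G.add_edge(f"g{i + 1}", f"g{j + 1}")
        return G

    def to_dot(self) -> str:
        lines = ["digraph restrictions {"]
        for j, m in enumerate(self.parent_masks):
            if m == 0:
                lines.append(f'  Root -> "g{j + 1}";')
            else:
                for i in range(self.n_genes):
                    if (m >> i) & 1:
                        lines.append(f'  "g{i + 1}" -> "g{j + 1}";')
        lines.append("}")
        return "\n".join(lines)

    def to_edge_list(self) -> str:
        """TSV edge list, one ``parent\tchild`` per line (Root explicit)."""
        rows = []
        for j, m in enumerate(self.parent_masks):
            if m == 0:
                rows.append(f"Root\tg{j + 1}")
            else:
                for i in range(self.n_genes):
                    if (m >> i) & 1:
                        rows.append(f"g{i + 1}\tg{j + 1}")
        return "\n".join(rows) + "\n"


@dataclass
class FitnessGraph:
    """Directed graph over accessible genotypes.

    Edges connect genotype pairs that differ by exactly one added mutation and
    encode the allowed uphill moves.  The wild type (all zeros) is always a
    node and every node is reachable from it.
    """

    n_genes: int
    nodes: frozenset[int]
    out_edges: dict[int, tuple[int, ...]]  # node -> children (sorted)

    def __post_init__(self) -> None:
        if 0 not in self.nodes:
            raise ValueError("wild type must be a node of the fitness graph")

    def in_edges(self) -> dict[int, tuple[int, ...]]:
        parents: dict[int, list[int]] = {g: [] for g in self.nodes}
        for u, vs in self.out_edges.items():
            for v in vs:
                parents[v].append(u)
        return {g: tuple(sorted(ps)) for g, ps in parents.items()}

    def sinks(self) -> frozenset[int]:
        return frozenset(g for g in self.nodes if not self.out_edges.get(g))

    def reachable_from_wild_type(self) -> frozenset[int]:
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in self.out_edges.get(u, ()):
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return frozenset(seen)

    def n_edges(self) -> int:
        return sum(len(v) for v in self.out_edges.values())

    def paths_to_sinks(self) -> int:
        """Number of distinct source-to-sink paths (dynamic program)."""
        order = sorted(self.nodes, key=_popcount, reverse=True)
        counts: dict[int, int] = {}
        for g in order:
            children = self.out_edges.get(g, ())
            counts[g] = 1 if not children else sum(counts[c] for c in children)
        return counts[0]


@dataclass(frozen=True)
class BirthRateAssignmentParams:
    """Uniform multiplier bounds for the iterative birth-rate assignment."""

    lo: float = 1.01
    hi: float = 1.19

    def __post_init__(self) -> None:
        if not (1.0 < self.lo < self.hi):
            raise ValueError("require 1 < lo < hi")


@dataclass
class FitnessLandscape:
    """Genotype -> birth-rate map with provenance.

    ``birth_rate`` stores only genotypes with positive rate; all others have
    rate exactly 0 (for DAG-derived kinds these are the genotypes that violate
    the restrictions).  The wild type always has rate 1.
    """

    n_genes: int
    birth_rate: dict[int, float]
    kind: str  # representable | local_maxima | rmf
    graph: FitnessGraph | None = None  # DAG-derived kinds
    dag: DagOfRestrictions | None = None
    rmf_params: dict | None = None  # reference, slope_c, hoc_sd

    def rate(self, g: int) -> float:
        return self.birth_rate.get(g, 0.0)

    def accessible_genotypes(self) -> frozenset[int]:
        if self.kind == "rmf":
            return self._rmf_accessible()
        assert self.graph is not None
        return self.graph.nodes

    def _rmf_accessible(self) -> frozenset[int]:
        # genotypes on some monotonically fitness-increasing forward path
        acc = {0}
        order = sorted(self.birth_rate, key=_popcount)
        for g in order:
            if g in acc:
                continue
            r = self.birth_rate[g]
            for i in range(self.n_genes):
                if (g >> i) & 1:
                    p = g & ~(1 << i)
                    if p in acc and self.birth_rate[p] < r:
                        acc.add(g)
                        break
        return frozenset(acc)

    def local_maxima(self) -> frozenset[int]:
        """Genotypes with positive rate and no fitter allowed neighbor.

        Allowed transitions are fitness-graph edges for DAG-derived kinds; for
        RMF landscapes all K single-mutation (Hamming) neighbors are compared,
        the classic local-peak definition on a complete landscape.
        """
        if self.kind == "rmf":
            maxima = []
            for g, r in self.birth_rate.items():
                fitter = False
                for i in range(self.n_genes):
                    if self.birth_rate[g ^ (1 << i)] > r:
                        fitter = True
                        break
                if not fitter:
                    maxima.append(g)
            return frozenset(maxima)
        assert self.graph is not None
        return self.graph.sinks()

    def evolutionary_traps(self) -> frozenset[int]:
        """Genotypes from which no forward mutation increases fitness.

        These are the absorbing states of no-back-mutation evolution: for
        DAG-derived kinds, the fitness-graph sinks; for RMF, genotypes with no
        fitter forward (mutation-adding) neighbor.  Every local maximum is a
        trap; under RMF a trap need not be a (Hamming) local maximum.
        """
        if self.kind != "rmf":
            assert self.graph is not None
            return self.graph.sinks()
        traps = []
        for g, r in self.birth_rate.items():
            fitter = False
            for i in range(self.n_genes):
                if not (g >> i) & 1 and self.birth_rate[g | (1 << i)] > r:
                    fitter = True
                    break
            if not fitter:
                traps.append(g)
        return frozenset(traps)

    # --- serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload: dict = {
            "n_genes": self.n_genes,
            "kind": self.kind,
            "birth_rate": {
                genotype_to_str(g, self.n_genes): r
                for g, r in sorted(self.birth_rate.items())
            },
        }
        if self.graph is not None:
            payload["graph_edges"] = [
                [genotype_to_str(u, self.n_genes), genotype_to_str(v, self.n_genes)]
                for u in sorted(self.graph.nodes)
                for v in self.graph.out_edges.get(u, ())
            ]
        if self.dag is not None:
            payload["dag_parent_masks"] = list(self.dag.parent_masks)
        if self.rmf_params is not None:
            payload["rmf_params"] = {
                "reference": genotype_to_str(
                    self.rmf_params["reference"], self.n_genes
                ),
                "slope_c": self.rmf_params["slope_c"],
                "hoc_sd": self.rmf_params["hoc_sd"],
            }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FitnessLandscape":
        payload = json.loads(text)
        K = payload["n_genes"]
        rates = {
            genotype_from_str(s): r for s, r in payload["birth_rate"].items()
        }
        graph = None
        if "graph_edges" in payload:
            edges = [
                (genotype_from_str(u), genotype_from_str(v))
                for u, v in payload["graph_edges"]
            ]
            nodes = frozenset(rates)
            out: dict[int, list[int]] = {g: [] for g in nodes}
            for u, v in edges:
                out[u].append(v)
            graph = FitnessGraph(
                K, nodes, {g: tuple(sorted(c)) for g, c in out.items()}
            )
        dag = None
        if "dag_parent_masks" in payload:
            dag = DagOfRestrictions(K, tuple(payload["dag_parent_masks"]))
        rmf_params = None
        if "rmf_params" in payload:
            rp = payload["rmf_params"]
            rmf_params = {
                "reference": genotype_from_str(rp["reference"]),
                "slope_c": rp["slope_c"],
                "hoc_sd": rp["hoc_sd"],
            }
        return cls(K, rates, payload["kind"], graph, dag, rmf_params)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_random_dag(
    n_genes: int, density: float, rng: np.random.Generator
) -> DagOfRestrictions:
    """Draw a random DAG of restrictions.

    A uniform random topological order of the genes is drawn, then every
    forward gene -> gene edge is included independently with probability
    ``density``.  Genes left without parents depend only on the implicit Root,
    so every gene is reachable from Root by construction.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_genes > MAX_GENES:
        raise ValueError(f"n_genes must be <= {MAX_GENES}")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    order = rng.permutation(n_genes)
    masks = [0] * n_genes
    for b in range(1, n_genes):
        j = int(order[b])
        for a in range(b):
            if rng.random() < density:
                masks[j] |= 1 << int(order[a])
    return DagOfRestrictions(n_genes, tuple(masks))


def fitness_graph_from_dag(dag: DagOfRestrictions) -> FitnessGraph:
    """All genotypes compatible with the restrictions, joined by single-gene
    additions.  Under conjunctive semantics every compatible genotype is
    reachable from the wild type."""
    K = dag.n_genes
    nodes = [g for g in range(1 << K) if dag.genotype_allowed(g)]
    node_set = frozenset(nodes)
    out: dict[int, list[int]] = {g: [] for g in nodes}
    for g in nodes:
        for i in range(K):
            if not (g >> i) & 1:
                child = g | (1 << i)
                if child in node_set:
                    out[g].append(child)
    return FitnessGraph(K, node_set, {g: tuple(c) for g, c in out.items()})


def _iterative_rates(
    fgraph: FitnessGraph,
    params: BirthRateAssignmentParams,
    rng: np.random.Generator,
) -> dict[int, float]:
    parents = fgraph.in_edges()
    rates: dict[int, float] = {0: 1.0}
    for g in sorted(fgraph.nodes, key=_popcount):
        if g == 0:
            continue
        max_parent = max(rates[p] for p in parents[g])
        rates[g] = max_parent * rng.uniform(params.lo, params.hi)
    return rates


def assign_birth_rates(
    fgraph: FitnessGraph,
    params: BirthRateAssignmentParams | None = None,
    rng: np.random.Generator | None = None,
    kind: str = "representable",
    dag: DagOfRestrictions | None = None,
) -> FitnessLandscape:
    """Iterative birth-rate assignment on a fitness graph.

    The wild type gets rate 1; each descendant's rate is the maximum rate
    among its in-neighbors times an independent U(lo, hi) draw, giving an
    average multiplicative fitness increase of (lo + hi)/2 - 1 per step
    (0.1 with the defaults).  Genotypes absent from the graph have rate 0.
    """
    if params is None:
        params = BirthRateAssignmentParams()
    if rng is None:
        rng = np.random.default_rng()
    rates = _iterative_rates(fgraph, params, rng)
    return FitnessLandscape(fgraph.n_genes, rates, kind, fgraph, dag)


def prune_to_local_maxima(
    fgraph: FitnessGraph,
    removal_fraction: float = 0.5,
    n_tries: int = 50,
    rng: np.random.Generator | None = None,
) -> FitnessGraph:
    """Remove fitness-graph edges to create extra fitness peaks.

    Each try shuffles the edges and removes them one at a time, keeping a
    removal only if every genotype stays reachable from the wild type, until
    ``removal_fraction`` of the edges have been processed.  Among ``n_tries``
    independent prunings the one producing the most out-degree-0 nodes
    (candidate fitness maxima) is returned.  Nodes are never removed.
    """
    if not 0.0 <= removal_fraction < 1.0:
        raise ValueError("removal_fraction must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    if removal_fraction == 0.0 or fgraph.n_edges() == 0:
        return fgraph
    all_edges = [
        (u, v) for u in sorted(fgraph.nodes) for v in fgraph.out_edges.get(u, ())
    ]
    n_process = int(round(removal_fraction * len(all_edges)))
    best: FitnessGraph = fgraph
    best_sinks = len(fgraph.sinks())
    for _ in range(n_tries):
        out = {g: set(vs) for g, vs in fgraph.out_edges.items()}
        order = rng.permutation(len(all_edges))
        for idx in order[:n_process]:
            u, v = all_edges[int(idx)]
            out[u].discard(v)
            cand = FitnessGraph(
                fgraph.n_genes,
                fgraph.nodes,
                {g: tuple(sorted(vs)) for g, vs in out.items()},
            )
            if len(cand.reachable_from_wild_type()) != len(fgraph.nodes):
                out[u].add(v)  # undo: would disconnect a genotype
        cand = FitnessGraph(
            fgraph.n_genes,
            fgraph.nodes,
            {g: tuple(sorted(vs)) for g, vs in out.items()},
        )
        n_sinks = len(cand.sinks())
        if n_sinks > best_sinks:
            best, best_sinks = cand, n_sinks
    return best


def representable_landscape(
    n_genes: int,
    density: float = 0.3,
    rng: np.random.Generator | None = None,
    params: BirthRateAssignmentParams | None = None,
    dag: DagOfRestrictions | None = None,
) -> FitnessLandscape:
    """Random DAG -> fitness graph -> iterative birth rates; single peak."""
    if rng is None:
        rng = np.random.default_rng()
    if dag is None:
        dag = generate_random_dag(n_genes, density, rng)
    graph = fitness_graph_from_dag(dag)
    return assign_birth_rates(graph, params, rng, kind="representable", dag=dag)


def local_maxima_landscape(
    n_genes: int,
    density: float = 0.3,
    removal_fraction: float = 0.5,
    n_tries: int = 50,
    rng: np.random.Generator | None = None,
    params: BirthRateAssignmentParams | None = None,
    dag: DagOfRestrictions | None = None,
) -> FitnessLandscape:
    """Like :func:`representable_landscape` but with fitness-graph edges pruned
    (before rate assignment) to introduce extra fitness maxima."""
    if rng is None:
        rng = np.random.default_rng()
    if dag is None:
        dag = generate_random_dag(n_genes, density, rng)
    graph = prune_to_local_maxima(
        fitness_graph_from_dag(dag), removal_fraction, n_tries, rng
    )
    return assign_birth_rates(graph, params, rng, kind="local_maxima", dag=dag)


def rmf_landscape(
    n_genes: int,
    slope_c: float = 0.05,
    hoc_sd: float = 0.05,
    rng: np.random.Generator | None = None,
    max_redraws: int = 1000,
) -> FitnessLandscape:
    """Rough Mount Fuji landscape on all 2^K genotypes.

    log birth rate = -slope_c * d(g, reference) + eps_g, with eps_g iid
    Normal(0, hoc_sd^2) and d the Hamming distance to a uniformly chosen
    reference genotype.  The draw is repeated until the reference is the
    unique global maximum, then rates are rescaled so the wild type has
    rate 1.  slope_c = 0 gives a pure House of Cards landscape; hoc_sd = 0 a
    purely additive (single-peaked) one.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_genes > MAX_GENES:
        raise ValueError(f"n_genes must be <= {MAX_GENES}")
    if slope_c < 0 or hoc_sd < 0 or (slope_c == 0 and hoc_sd == 0):
        raise ValueError("need slope_c >= 0, hoc_sd >= 0, not both 0")
    if rng is None:
        rng = np.random.default_rng()
    K = n_genes
    genos = np.arange(1 << K, dtype=np.uint32)
    bits = ((genos[:, None] >> np.arange(K)) & 1).astype(np.int8)
    for _ in range(max_redraws):
        reference = int(rng.integers(1 << K))
        ref_bits = (reference >> np.arange(K)) & 1
        hamming = np.abs(bits - ref_bits).sum(axis=1)
        log_rate = -slope_c * hamming + (
            rng.normal(0.0, hoc_sd, size=1 << K) if hoc_sd > 0 else 0.0
        )
        order = np.argsort(log_rate)
        if int(genos[order[-1]]) == reference and (
            hoc_sd == 0 or log_rate[order[-1]] > log_rate[order[-2]]
        ):
            log_rate = log_rate - log_rate[0]  # wild type -> rate 1
            rates = {int(g): float(np.exp(lr)) for g, lr in zip(genos, log_rate)}
            return FitnessLandscape(
                K,
                rates,
                "rmf",
                rmf_params={
                    "reference": reference,
                    "slope_c": slope_c,
                    "hoc_sd": hoc_sd,
                },
            )
    raise RuntimeError("could not draw an RMF landscape with a unique maximum")


def landscape_stats(landscape: FitnessLandscape) -> dict:
    """Summary statistics: accessible genotypes, local maxima, peak sizes."""
    maxima = landscape.local_maxima()
    return {
        "n_accessible": len(landscape.accessible_genotypes()),
        "n_local_maxima": len(maxima),
        "max_genotype_sizes": sorted(_popcount(g) for g in maxima),
    }
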