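"""Stochastic clonal evolution on a fitness landscape, run to fixation.

The model is a continuous-time multi-type birth-death process with
logistic-like density dependence: every clone of genotype ``g`` has birth
rate ``b(g)`` given by the landscape, and all cells share the death rate
``D(N) = log(1 + N / Kc)`` where ``N`` is the total population size.  ``Kc``
is chosen so that the wild-type population starts at its demographic
equilibrium (``D(N0) = b(wild type) = 1``).  On each birth, every unmutated
gene mutates independently with its per-gene rate; offspring whose genotype
has birth rate 0 are never added to the population, and back mutations do
not occur.  A run ends when an evolutionary-trap genotype (a fitness-graph
sink, or, for RMF landscapes, a genotype with no fitter forward neighbor)
holds at least a fraction ``theta`` of the population.

Numerics: the process is advanced by Poisson tau-leaping over clones.  When
the population is monomorphic (a single clone, the common situation while
waiting for the next successful mutant) the simulator jumps directly to the
next viable mutation event instead of leaping through the demographic
equilibrium, which is what makes batch runs desk-scale.  Each clone records
the clone it arose from, so the Line of Descent (LOD) is the actual ancestry
of the most populated clone at the final time, not a first-arrival
approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .landscapes import FitnessLandscape, genotype_to_str

__all__ = [
    "MutationRegime",
    "SimulationConfig",
    "Trajectory",
    "LOD",
    "SimulationError",
    "simulate_to_fixation",
    "extract_lod",
    "batch_simulate",
    "lods_to_tsv",
]

COMMON_MUTATION_RATE = 1e-5  # per gene per cell division


class SimulationError(RuntimeError):
    """Run could not be completed (time guard exhausted across restarts)."""


@dataclass(frozen=True)
class MutationRegime:
    """Per-gene mutation rates.

    ``constant`` uses a common rate of 1e-5 for every gene; ``variable``
    draws iid rates log-uniformly between (1/5)*1e-5 and 5*1e-5, so the
    largest possible ratio between rates is 25, the arithmetic mean of the
    sampling distribution is 1.5e-5 and its geometric mean 1e-5.
    """

    kind: str
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "variable"):
            raise ValueError("kind must be 'constant' or 'variable'")
        if any(r <= 0 for r in self.rates):
            raise ValueError("all mutation rates must be positive")

    @classmethod
    def constant(
        cls, n_genes: int, rate: float = COMMON_MUTATION_RATE
    ) -> "MutationRegime":
        return cls("constant", (rate,) * n_genes)

    @classmethod
    def variable(
        cls,
        n_genes: int,
        rng: np.random.Generator,
        base_rate: float = COMMON_MUTATION_RATE,
        spread: float = 5.0,
    ) -> "MutationRegime":
        lo, hi = math.log(base_rate / spread), math.log(base_rate * spread)
        rates = np.exp(rng.uniform(lo, hi, size=n_genes))
        return cls("variable", tuple(float(r) for r in rates))


@dataclass
class SimulationConfig:
    """Tunables of a single evolutionary run.

    initial_size: cells at tumor initiation (study values 2000, 50000, 1e6).
    theta: fixation threshold, the population fraction one trap genotype
        must reach to end the run (0.5 < theta <= 1).
    tau: tau-leap step, in units of 1/wild-type birth rate.
    max_time: per-attempt time guard; exceeding it triggers a restart with a
        fresh random stream, up to max_restarts attempts.
    snapshot_interval / snapshot_rel_change: a snapshot is recorded at fixed
        time intervals and additionally whenever the population size has
        changed by the given relative amount since the last snapshot.
    """

    initial_size: int = 2000
    theta: float = 0.99
    tau: float = 0.25
    max_time: float = 1e6
    max_restarts: int = 20
    snapshot_interval: float = 25.0
    snapshot_rel_change: float = 0.05
    fixation_check_every: int = 8

    def __post_init__(self) -> None:
        if self.initial_size < 1:
            raise ValueError("initial_size must be >= 1")
        if not (0.5 < self.theta <= 1.0):
            raise ValueError("theta must satisfy 0.5 < theta <= 1")

    @property
    def carrying_parameter(self) -> float:
        """Kc such that D(initial_size) = 1, the wild-type birth rate."""
        return self.initial_size / (math.e - 1.0)


@dataclass
class Snapshot:
    time: float
    size: int
    abundance: dict[int, int]  # genotype -> total cells

    def most_abundant_genotype(self) -> int:
        # deterministic tie-break: smallest genotype among maxima
        best = max(self.abundance.values())
        return min(g for g, n in self.abundance.items() if n == best)


@dataclass
class Trajectory:
    """Result of one run: snapshots plus the full clone genealogy."""

    n_genes: int
    snapshots: list[Snapshot]
    clone_genotype: list[int]  # clone id -> genotype
    clone_parent: list[int]  # clone id -> parent clone id (-1 for founder)
    final_counts: dict[int, int]  # clone id -> cells at final time
    fixated_genotype: int
    final_time: float
    n_restarts: int = 0

    def genotypes_seen(self) -> frozenset[int]:
        return frozenset(self.clone_genotype)


@dataclass(frozen=True)
class LOD:
    """Line of Descent: genotype sequence from wild type to the fixated
    genotype, each step adding exactly one mutation."""

    genotypes: tuple[int, ...]
    n_genes: int

    def __post_init__(self) -> None:
        if not self.genotypes or self.genotypes[0] != 0:
            raise ValueError("LOD must start at the wild type")
        for a, b in zip(self.genotypes, self.genotypes[1:]):
            extra = b & ~a
            if b & a != a or extra.bit_count() != 1:
                raise ValueError("LOD steps must add exactly one mutation")

    def gene_order(self) -> tuple[int, ...]:
        """Genes in order of acquisition (0-based indices)."""
        return tuple(
            (b & ~a).bit_length() - 1
            for a, b in zip(self.genotypes, self.genotypes[1:])
        )

    def __len__(self) -> int:
        return len(self.genotypes) - 1

    def __str__(self) -> str:
        return " -> ".join(genotype_to_str(g, self.n_genes) for g in self.genotypes)


class _Landscape_tables:
    """Per-landscape lookup tables shared across runs."""

    def __init__(self, landscape: FitnessLandscape, regime: MutationRegime):
        K = landscape.n_genes
        if len(regime.rates) != K:
            raise ValueError("mutation regime size does not match landscape")
        size = 1 << K
        self.rate = np.zeros(size)
        for g, r in landscape.birth_rate.items():
            self.rate[g] = r
        mu = np.asarray(regime.rates)
        # probability that a birth carries a (single) mutation
        self.pmut = np.zeros(size)
        # viable mutation targets and their conditional probabilities
        self.targets: list[tuple[np.ndarray, np.ndarray]] = []
        for g in range(size):
            unmut = [i for i in range(K) if not (g >> i) & 1]
            p_any = 1.0 - np.prod([1.0 - mu[i] for i in unmut]) if unmut else 0.0
            self.pmut[g] = p_any
            if unmut:
                w = mu[unmut]
                children = np.array([g | (1 << i) for i in unmut])
                self.targets.append((children, np.cumsum(w) / w.sum()))
            else:
                self.targets.append((np.empty(0, dtype=int), np.empty(0)))
        # rate of *viable* mutant production per birth (used by the leap)
        self.pmut_viable = np.zeros(size)
        for g in range(size):
            children, _ = self.targets[g]
            viable = [int(c) for c in children if self.rate[c] > 0]
            self.pmut_viable[g] = (
                mu[[(c ^ g).bit_length() - 1 for c in viable]].sum()
                if viable
                else 0.0
            )
        self.absorbing = np.zeros(size, dtype=bool)
        for g in landscape.evolutionary_traps():
            self.absorbing[g] = True
        self.size = size


class _Extinct(Exception):
    pass


class _TimedOut(Exception):
    pass


def _run_once(
    tables: _Landscape_tables,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Trajectory:
    tau = config.tau
    Kc = config.carrying_parameter
    theta = config.theta

    # clone genealogy (append-only) and active-clone arrays
    hist_geno: list[int] = [0]
    hist_parent: list[int] = [-1]
    ids = np.array([0], dtype=np.int64)
    counts = np.array([config.initial_size], dtype=np.int64)
    geno = np.array([0], dtype=np.int64)
    brate = tables.rate[geno]
    pmut = tables.pmut[geno]
    # clone lookup for merging mutants with same (parent, genotype)
    live_index: dict[tuple[int, int], int] = {(-1, 0): 0}

    t = 0.0
    snapshots: list[Snapshot] = []
    next_snap = 0.0
    last_snap_N = -1
    step = 0

    def record_snapshot(at: float, N: int) -> None:
        nonlocal next_snap, last_snap_N
        ab: dict[int, int] = {}
        for g, n in zip(geno, counts):
            if n > 0:
                ab[int(g)] = ab.get(int(g), 0) + int(n)
        snapshots.append(Snapshot(at, int(N), ab))
        next_snap = at + config.snapshot_interval
        last_snap_N = int(N)

    def spawn(parent_pos: int, child_geno: int, n: int = 1) -> None:
        nonlocal ids, counts, geno, brate, pmut, live_index
        parent_id = int(ids[parent_pos])
        key = (parent_id, child_geno)
        pos = live_index.get(key)
        if pos is not None:
            counts[pos] += n
            return
        hist_geno.append(child_geno)
        hist_parent.append(parent_id)
        cid = len(hist_geno) - 1
        ids = np.append(ids, cid)
        counts = np.append(counts, n)
        geno = np.append(geno, child_geno)
        brate = np.append(brate, tables.rate[child_geno])
        pmut = np.append(pmut, tables.pmut[child_geno])
        live_index[key] = len(ids) - 1

    def compact() -> None:
        nonlocal ids, counts, geno, brate, pmut, live_index
        keep = counts > 0
        if keep.all():
            return
        ids, counts, geno = ids[keep], counts[keep], geno[keep]
        brate, pmut = brate[keep], pmut[keep]
        live_index = {
            (hist_parent[int(cid)], int(g)): pos
            for pos, (cid, g) in enumerate(zip(ids, geno))
        }

    record_snapshot(0.0, config.initial_size)

    while True:
        N = int(counts.sum())
        if N == 0:
            raise _Extinct
        if t >= config.max_time:
            raise _TimedOut

        alive = counts > 0
        n_alive = int(alive.sum())

        # --- fixation check ---------------------------------------------
        if step % config.fixation_check_every == 0 or n_alive == 1:
            per_geno = np.bincount(geno, weights=counts, minlength=tables.size)
            winner = np.argmax(np.where(tables.absorbing, per_geno, 0.0))
            if tables.absorbing[winner] and per_geno[winner] >= theta * N:
                record_snapshot(t, N)
                return Trajectory(
                    n_genes=int(np.log2(tables.size)),
                    snapshots=snapshots,
                    clone_genotype=hist_geno,
                    clone_parent=hist_parent,
                    final_counts={
                        int(cid): int(n)
                        for cid, n in zip(ids, counts)
                        if n > 0
                    },
                    fixated_genotype=int(winner),
                    final_time=t,
                )

        # --- monomorphic leap: jump to the next viable mutation ----------
        if n_alive == 1:
            pos = int(np.nonzero(alive)[0][0])
            g = int(geno[pos])
            n = int(counts[pos])
            mut_rate = n * brate[pos] * tables.pmut_viable[g]
            if mut_rate <= 0:
                raise _TimedOut  # stuck in a non-absorbing dead end
            dt = rng.exponential(1.0 / mut_rate)
            t_new = min(t + dt, config.max_time)
            while next_snap < t_new:
                record_snapshot(next_snap, N)
            t = t_new
            if t + 1e-12 >= config.max_time:
                continue  # will raise _TimedOut at loop head
            # one viable mutant cell
            children, cum = tables.targets[g]
            viable = tables.rate[children] > 0
            w = np.diff(np.concatenate(([0.0], cum)))[viable]
            child = int(children[viable][int(rng.choice(len(w), p=w / w.sum()))])
            counts[pos] -= 1 if counts[pos] > 1 else 0
            spawn(pos, child)
            step += 1
            continue

        # --- tau-leap over clones ----------------------------------------
        D = math.log1p(N / Kc)
        births = rng.poisson(counts * brate * tau)
        n_mut = rng.binomial(births, pmut[: len(births)])
        deaths = rng.poisson(counts * (D * tau))
        counts = counts + (births - n_mut) - np.minimum(deaths, counts + births - n_mut)
        if n_mut.any():
            for pos in np.nonzero(n_mut)[0]:
                g = int(geno[pos])
                children, cum = tables.targets[g]
                for _ in range(int(n_mut[pos])):
                    child = int(children[np.searchsorted(cum, rng.random())])
                    if tables.rate[child] > 0:
                        spawn(int(pos), child)
        t += tau
        step += 1

        if t >= next_snap or (
            last_snap_N > 0
            and abs(int(counts.sum()) - last_snap_N)
            >= config.snapshot_rel_change * last_snap_N
        ):
            record_snapshot(t, int(counts.sum()))
        if len(counts) > 64 and (counts == 0).sum() > len(counts) // 2:
            compact()


def simulate_to_fixation(
    landscape: FitnessLandscape,
    config: SimulationConfig | None = None,
    regime: MutationRegime | None = None,
    rng: np.random.Generator | None = None,
    _tables: _Landscape_tables | None = None,
) -> Trajectory:
    """Run one evolutionary process until a trap genotype fixates.

    Extinction or exceeding the time guard restarts the run with a fresh
    random substream (up to ``config.max_restarts`` attempts).
    """
    if config is None:
        config = SimulationConfig()
    if regime is None:
        regime = MutationRegime.constant(landscape.n_genes)
    if rng is None:
        rng = np.random.default_rng()
    tables = _tables if _tables is not None else _Landscape_tables(landscape, regime)
    if not tables.absorbing.any():
        raise ValueError("landscape has no evolutionary trap reachable")
    n_restarts = 0
    while True:
        try:
            traj = _run_once(tables, config, rng)
            traj.n_restarts = n_restarts
            return traj
        except (_Extinct, _TimedOut):
            n_restarts += 1
            if n_restarts > config.max_restarts:
                raise SimulationError(
                    "run failed after "
                    f"{config.max_restarts} restarts (extinction or time guard)"
                )


def extract_lod(trajectory: Trajectory) -> LOD:
    """Trace the ancestry of the most populated clone of the fixated
    genotype back to the wild type."""
    if not trajectory.final_counts:
        raise ValueError("trajectory has no final population")
    candidates = [
        (n, -cid)
        for cid, n in trajectory.final_counts.items()
        if trajectory.clone_genotype[cid] == trajectory.fixated_genotype
    ]
    if not candidates:  # fall back to the overall most populated clone
        candidates = [(n, -cid) for cid, n in trajectory.final_counts.items()]
    _, neg_cid = max(candidates)
    cid = -neg_cid
    genos = []
    while cid != -1:
        genos.append(trajectory.clone_genotype[cid])
        cid = trajectory.clone_parent[cid]
    return LOD(tuple(reversed(genos)), trajectory.n_genes)


@dataclass
class BatchResult:
    lods: list[LOD]
    trajectories: list[Trajectory]
    all_genes_covered: bool


def batch_simulate(
    landscape: FitnessLandscape,
    config: SimulationConfig | None = None,
    regime: MutationRegime | None = None,
    n_runs: int = 1000,
    rng: np.random.Generator | None = None,
    keep_trajectories: bool = True,
) -> BatchResult:
    """Run ``n_runs`` independent evolutionary processes.

    ``all_genes_covered`` reports whether every gene appeared mutated in at
    least one instantiated genotype across the runs; callers should discard
    the landscape and regenerate when it is False (no exception is raised).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if config is None:
        config = SimulationConfig()
    if regime is None:
        regime = MutationRegime.constant(landscape.n_genes)
    if rng is None:
        rng = np.random.default_rng()
    tables = _Landscape_tables(landscape, regime)
    lods: list[LOD] = []
    trajectories: list[Trajectory] = []
    seen = 0
    for _ in range(n_runs):
        traj = simulate_to_fixation(landscape, config, regime, rng, _tables=tables)
        lods.append(extract_lod(traj))
        for g in traj.genotypes_seen():
            seen |= g
        if keep_trajectories:
            trajectories.append(traj)
    covered = seen == (1 << landscape.n_genes) - 1
    return BatchResult(lods, trajectories, covered)


def lods_to_tsv(lods: list[LOD]) -> str:
    """One distinct path per row: genes in acquisition order and a count."""
    from collections import Counter

    counter = Counter(lod.gene_order() for lod in lods)
    lines = ["path\tcount"]
    for order, n in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])):
        lines.append(">".join(f"g{i + 1}" for i in order) + f"\t{n}")
    return "\n".join(lines) + "\n"
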