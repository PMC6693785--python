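"""Cancer progression models fitted to cross-sectional binary data.

Two CPMs are implemented, both presented as model classes whose ``fit()``
returns a results object (estimates, log-likelihood, ``summary()``):

* :class:`OncogeneticTree` (OT) — order restrictions representable as a
  rooted tree.  Pairwise weights combining marginal and joint mutation
  frequencies are maximized by a maximum-weight branching (Edmonds'
  arborescence), and each edge carries the estimated conditional probability
  of the child event given its parent, interpretable as the probability of
  transition along the edge by the time of observation.

* :class:`ConjunctiveBayesianNetwork` (CBN) — a poset of conjunctive (AND)
  restrictions with exponential waiting times: once all of a feature's poset
  parents have occurred, the feature occurs at rate ``lambda_j``; the tumor
  is observed at an Exp(1) sampling time (the standard identifiability
  convention) and each recorded bit is flipped with probability ``eps``
  (symmetric observation error).  The genotype distribution is computed
  exactly from the continuous-time Markov chain on the lattice of
  poset-compatible genotypes, ``lambda`` and ``eps`` are estimated with EM,
  and the poset structure is searched by simulated annealing over
  add/delete/swap moves on cover relations, keeping the best visited state.

``ExternalCpmAdapter`` lets outputs of third-party CPM tools (MCCBN, CAPRI,
CAPRESE) enter the downstream path machinery as a (DAG, optional rates)
pair without reimplementing those tools.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import CrossSectionalDataset
from .landscapes import DagOfRestrictions

logger = logging.getLogger(__name__)

__all__ = [
    "OncogeneticTree",
    "OncogeneticTreeResults",
    "ConjunctiveBayesianNetwork",
    "CBNResults",
    "AnnealSchedule",
    "ExternalCpmAdapter",
    "fit_ot",
    "fit_cbn",
    "cbn_loglik",
    "generate_from_cbn",
    "OtModel",
    "CbnModel",
]

_LAM_MIN, _LAM_MAX = 1e-6, 1e6
_EPS_MIN, _EPS_MAX = 1e-6, 0.499


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, CrossSectionalDataset):
        return data.matrix
    if isinstance(data, pd.DataFrame):
        return data
    raise TypeError("data must be a CrossSectionalDataset or DataFrame")


def _popcount_array(a: np.ndarray) -> np.ndarray:
    out = np.zeros_like(a)
    v = a.copy()
    while v.any():
        out += v & 1
        v >>= 1
    return out


# ---------------------------------------------------------------------------
# Oncogenetic tree
# ---------------------------------------------------------------------------


@dataclass
class OncogeneticTreeResults:
    """Fitted oncogenetic tree.

    ``parents[j]`` is the index of feature j's parent, or -1 for the root;
    ``edge_weights[j]`` is the estimated conditional probability of event j
    given its parent event by the time of observation.
    """

    feature_names: list[str]
    parents: list[int]
    edge_weights: list[float]
    branching_weights: list[float]
    n_obs: int

    @property
    def parent_masks(self) -> tuple[int, ...]:
        return tuple(
            0 if p < 0 else (1 << p) for p in self.parents
        )

    def as_dag(self) -> DagOfRestrictions:
        return DagOfRestrictions(len(self.feature_names), self.parent_masks)

    def paths(self, cap: int | None = None):
        from .paths import DEFAULT_PATH_CAP, paths_from_model

        return paths_from_model(self, cap or DEFAULT_PATH_CAP)

    def path_distribution(self, mode: str = "proportional"):
        from .paths import weight_paths_ot

        return weight_paths_ot(self, mode=mode)

    def summary(self) -> str:
        lines = [
            "Oncogenetic tree (maximum-weight branching)",
            f"  n = {self.n_obs} subjects, K = {len(self.feature_names)} features",
            "",
            f"  {'feature':<12}{'parent':<12}{'P(child|parent)':>16}",
        ]
        for j, name in enumerate(self.feature_names):
            parent = "Root" if self.parents[j] < 0 else self.feature_names[self.parents[j]]
            lines.append(f"  {name:<12}{parent:<12}{self.edge_weights[j]:>16.4f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "ot",
                "features": self.feature_names,
                "parents": self.parents,
                "edge_weights": self.edge_weights,
                "n_obs": self.n_obs,
            },
            indent=1,
        )

    def to_dot(self) -> str:
        lines = ["digraph ot {"]
        for j, name in enumerate(self.feature_names):
            parent = "Root" if self.parents[j] < 0 else self.feature_names[self.parents[j]]
            lines.append(
                f'  "{parent}" -> "{name}" [label="{self.edge_weights[j]:.3f}"];'
            )
        lines.append("}")
        return "\n".join(lines)


class OncogeneticTree:
    """Oncogenetic tree model for a binary subjects x features matrix."""

    def __init__(self, data):
        self.data = _as_frame(data)
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        if self.data.shape[1] < 1:
            raise ValueError("need at least 1 feature")

    def fit(self) -> OncogeneticTreeResults:
        import networkx as nx

        X = self.data.to_numpy(dtype=float)
        n, K = X.shape
        names = list(self.data.columns)
        clamp = 0.5 / n
        p = X.mean(axis=0)
        degenerate = (p <= 0.0) | (p >= 1.0)
        if degenerate.any():
            logger.warning(
                "degenerate columns (frequency 0 or 1) clamped: %s",
                [names[j] for j in np.nonzero(degenerate)[0]],
            )
        p = np.clip(p, clamp, 1.0 - clamp)
        # joint frequencies; an unobserved pair is clamped to the product of
        # the marginal clamps so it signals repulsion, not association
        pj = np.clip((X.T @ X) / n, clamp * clamp, None)

        G = nx.DiGraph()
        root = -1
        for j in range(K):
            # weight of attaching j directly under the root
            G.add_edge(root, j, weight=float(-np.log(1.0 + p[j])))
        for i in range(K):
            for j in range(K):
                if i == j:
                    continue
                w = math.log(p[i] / (p[i] + p[j]) * pj[i, j] / (p[i] * p[j]))
                G.add_edge(i, j, weight=w)
        # the root has no in-edges, so the maximum branching spanning all
        # nodes is an arborescence rooted there
        tree = nx.maximum_spanning_arborescence(G, attr="weight")
        parents = [next(iter(tree.pred[j])) for j in range(K)]
        edge_w, branch_w = [], []
        for j in range(K):
            i = parents[j]
            branch_w.append(float(G[i][j]["weight"]))
            cond = p[j] if i == root else min(pj[i, j] / p[i], 1.0)
            edge_w.append(float(cond))
        return OncogeneticTreeResults(names, parents, edge_w, branch_w, n)


# ---------------------------------------------------------------------------
# Conjunctive Bayesian network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule for the poset search."""

    restarts: int = 4
    steps: int = 2000
    t_initial: float = 10.0
    t_final: float = 0.1
    em_iters: int = 2  # EM refinements per proposal (warm started)
    final_em_iters: int = 100


class _Lattice:
    """CTMC machinery on the lattice of poset-compatible genotypes."""

    def __init__(self, parent_masks: tuple[int, ...]):
        self.K = len(parent_masks)
        self.masks = parent_masks
        states = []
        for g in range(1 << self.K):
            ok = True
            for j in range(self.K):
                if (g >> j) & 1 and (parent_masks[j] & g) != parent_masks[j]:
                    ok = False
                    break
            if ok:
                states.append(g)
        self.states = np.array(states, dtype=np.int64)
        self.index = {int(g): i for i, g in enumerate(states)}
        S = len(states)
        # enabled[i] = list of (gene j, target state index)
        self.enabled: list[list[tuple[int, int]]] = []
        for g in states:
            row = []
            for j in range(self.K):
                if not (g >> j) & 1 and (parent_masks[j] & g) == parent_masks[j]:
                    row.append((j, self.index[int(g) | (1 << j)]))
            self.enabled.append(row)
        self.S = S

    def green(self, lam: np.ndarray) -> np.ndarray:
        """G = (I - Q)^-1 for the chain killed at rate 1 (Exp(1) sampling).

        G[a, b] is the expected time spent in state b starting from a before
        observation; row 0 of G is the genotype distribution at observation.
        """
        A = np.eye(self.S)
        for i, row in enumerate(self.enabled):
            tot = 0.0
            for j, tgt in row:
                A[i, tgt] -= lam[j]
                tot += lam[j]
            A[i, i] += tot
        return np.linalg.inv(A)


def _distinct_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    K = X.shape[1]
    codes = X @ (1 << np.arange(K, dtype=np.int64))
    uniq, counts = np.unique(codes, return_counts=True)
    return uniq.astype(np.int64), counts.astype(float)


@dataclass
class CBNResults:
    """Fitted conjunctive Bayesian network.

    ``parent_masks`` is the transitive reduction of the estimated poset
    (cover relations); ``rates`` are the per-feature waiting-time parameters
    lambda_j relative to the Exp(1) observation time; ``eps`` the symmetric
    observation-error probability.
    """

    feature_names: list[str]
    parent_masks: tuple[int, ...]
    rates: list[float]
    eps: float
    loglik: float
    n_obs: int
    penalty: str | None = None
    score: float | None = None  # penalized score if penalty used

    def as_dag(self) -> DagOfRestrictions:
        return DagOfRestrictions(len(self.feature_names), self.parent_masks)

    def paths(self, cap: int | None = None):
        from .paths import DEFAULT_PATH_CAP, paths_from_model

        return paths_from_model(self, cap or DEFAULT_PATH_CAP)

    def path_distribution(self):
        from .paths import weight_paths_cbn

        return weight_paths_cbn(self)

    def simulate(self, n: int, rng: np.random.Generator) -> CrossSectionalDataset:
        return generate_from_cbn(self, n, rng)

    def summary(self) -> str:
        lines = [
            "Conjunctive Bayesian network (annealed poset + EM)",
            f"  n = {self.n_obs} subjects, K = {len(self.feature_names)} features",
            f"  log-likelihood = {self.loglik:.3f}   eps = {self.eps:.4f}",
            "",
            f"  {'feature':<12}{'parents':<20}{'lambda':>10}",
        ]
        for j, name in enumerate(self.feature_names):
            ps = [
                self.feature_names[i]
                for i in range(len(self.feature_names))
                if (self.parent_masks[j] >> i) & 1
            ]
            lines.append(
                f"  {name:<12}{','.join(ps) if ps else 'Root':<20}"
                f"{self.rates[j]:>10.4f}"
            )
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "cbn",
                "features": self.feature_names,
                "parent_masks": list(self.parent_masks),
                "rates": self.rates,
                "eps": self.eps,
                "loglik": self.loglik,
                "n_obs": self.n_obs,
            },
            indent=1,
        )

    def to_dot(self) -> str:
        lines = ["digraph cbn {"]
        for j, name in enumerate(self.feature_names):
            if self.parent_masks[j] == 0:
                lines.append(f'  Root -> "{name}";')
            for i in range(len(self.feature_names)):
                if (self.parent_masks[j] >> i) & 1:
                    lines.append(f'  "{self.feature_names[i]}" -> "{name}";')
        lines.append("}")
        return "\n".join(lines)


def _transitive_reduction(masks: tuple[int, ...]) -> tuple[int, ...]:
    K = len(masks)
    # ancestors via fixpoint
    anc = list(masks)
    changed = True
    while changed:
        changed = False
        for j in range(K):
            new = anc[j]
            for i in range(K):
                if (anc[j] >> i) & 1:
                    new |= anc[i]
            if new != anc[j]:
                anc[j] = new
                changed = True
    red = []
    for j in range(K):
        m = masks[j]
        keep = 0
        for i in range(K):
            if (m >> i) & 1:
                # drop i if it is an ancestor of another parent of j
                implied = any(
                    (m >> h) & 1 and h != i and (anc[h] >> i) & 1
                    for h in range(K)
                )
                if not implied:
                    keep |= 1 << i
        red.append(keep)
    return tuple(red)


def _transitive_closure(masks: tuple[int, ...]) -> tuple[int, ...]:
    anc = list(masks)
    changed = True
    while changed:
        changed = False
        for j in range(len(masks)):
            new = anc[j]
            for i in range(len(masks)):
                if (anc[j] >> i) & 1:
                    new |= anc[i]
            if new != anc[j]:
                anc[j] = new
                changed = True
    return tuple(anc)


class ConjunctiveBayesianNetwork:
    """CBN model (H-CBN style) for a binary subjects x features matrix.

    Parameters
    ----------
    data : CrossSectionalDataset or DataFrame
    penalty : None or "bic"
        None (default) searches by pure maximum likelihood; "bic" subtracts
        0.5 log(n) per free parameter (edges + K rates + eps).
    """

    def __init__(self, data, penalty: str | None = None):
        frame = _as_frame(data)
        if frame.shape[1] > 14:
            raise ValueError("CBN fitting limited to K <= 14 features")
        if penalty not in (None, "bic"):
            raise ValueError("penalty must be None or 'bic'")
        self.penalty = penalty
        self.feature_names = list(frame.columns)
        X = frame.to_numpy(dtype=np.int64)
        self.n, K_all = X.shape
        freqs = X.mean(axis=0)
        self._degenerate_zero = [j for j in range(K_all) if freqs[j] <= 0.0]
        self._degenerate_one = [j for j in range(K_all) if freqs[j] >= 1.0]
        self._active = [
            j
            for j in range(K_all)
            if j not in self._degenerate_zero and j not in self._degenerate_one
        ]
        if len(self._active) < K_all:
            logger.warning(
                "degenerate columns excluded from structure search: %s",
                [self.feature_names[j] for j in set(range(K_all)) - set(self._active)],
            )
        self.K_all = K_all
        self.K = len(self._active)
        self._X = X[:, self._active]
        self._codes, self._counts = _distinct_rows(self._X)
        self._freq_active = freqs[self._active]

    # --- exact likelihood machinery --------------------------------------
    def _error_matrix(self, lattice: _Lattice, eps: float) -> np.ndarray:
        D = _popcount_array(self._codes[:, None] ^ lattice.states[None, :])
        if eps <= 0.0:
            return (D == 0).astype(float)
        return (eps**D) * ((1.0 - eps) ** (self.K - D))

    def _loglik_arrays(
        self, lattice: _Lattice, lam: np.ndarray, eps: float
    ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
        G = lattice.green(lam)
        p = np.clip(G[0], 0.0, None)
        E = self._error_matrix(lattice, eps)
        like = E @ p
        with np.errstate(divide="ignore"):
            ll = float(self._counts @ np.log(like))
        return ll, G, p, E

    def loglik(
        self, parent_masks: tuple[int, ...], lam, eps: float
    ) -> float:
        """Exact log-likelihood of (poset, lambda, eps) on the active data.

        eps = 0 with observations incompatible with the poset yields -inf.
        """
        lattice = _Lattice(tuple(parent_masks))
        lam = np.asarray(lam, dtype=float)
        ll, *_ = self._loglik_arrays(lattice, lam, eps)
        return ll

    def _em(
        self,
        lattice: _Lattice,
        lam: np.ndarray,
        eps: float,
        iters: int,
        fix_eps: bool = False,
    ) -> tuple[np.ndarray, float, float]:
        """EM on (lambda, eps) for a fixed poset; returns updated params and
        the final log-likelihood (never decreasing across iterations)."""
        ll = -np.inf
        for _ in range(max(iters, 1)):
            ll, G, p, E = self._loglik_arrays(lattice, lam, eps)
            L = E * p[None, :]
            denom = L.sum(axis=1)
            ok = denom > 0
            if not ok.any():
                break
            R = np.zeros_like(L)
            R[ok] = L[ok] / denom[ok, None]
            w = self._counts @ R  # expected end-state counts
            n_eff = w.sum()
            if n_eff <= 0:
                break
            if not fix_eps:
                D = _popcount_array(
                    self._codes[:, None] ^ lattice.states[None, :]
                )
                flips = float(self._counts @ (R * D).sum(axis=1))
                eps = float(
                    np.clip(flips / (n_eff * self.K), _EPS_MIN, _EPS_MAX)
                )
            # lambda M-step from expected firings / expected enabled time
            G0 = G[0]
            new_lam = lam.copy()
            for j in range(self.K):
                rows = [
                    i for i, en in enumerate(lattice.enabled) if any(
                        jj == j for jj, _ in en
                    )
                ]
                if not rows:
                    continue
                occ = G0[rows] @ G[rows, :]  # E[enabled time ^ end state]
                with np.errstate(divide="ignore", invalid="ignore"):
                    cond = np.where(G0 > 0, occ / G0, 0.0)
                fires = float(w @ ((lattice.states >> j) & 1))
                t_enabled = float(w @ cond)
                if t_enabled > 0:
                    new_lam[j] = np.clip(fires / t_enabled, _LAM_MIN, _LAM_MAX)
            lam = new_lam
        ll, *_ = self._loglik_arrays(lattice, lam, eps)
        return lam, eps, ll

    def fit_fixed(
        self,
        parent_masks: tuple[int, ...] | None = None,
        em_iters: int = 100,
        eps0: float = 0.05,
        fix_eps: bool = False,
    ) -> CBNResults:
        """EM fit of lambda and eps for a known poset (no structure search)."""
        if parent_masks is None:
            parent_masks = (0,) * self.K
        lattice = _Lattice(tuple(parent_masks))
        lam = np.clip(
            self._freq_active / np.clip(1.0 - self._freq_active, 1e-12, None),
            _LAM_MIN,
            _LAM_MAX,
        )
        lam, eps, ll = self._em(lattice, lam, eps0, em_iters, fix_eps)
        return self._expand_results(tuple(parent_masks), lam, eps, ll)

    def _score(self, ll: float, masks: tuple[int, ...]) -> float:
        if self.penalty == "bic":
            n_edges = sum(int(m).bit_count() for m in masks)
            return ll - 0.5 * math.log(self.n) * (n_edges + self.K + 1)
        return ll

    def fit(
        self,
        schedule: AnnealSchedule | None = None,
        rng: np.random.Generator | None = None,
        seed: int | None = None,
        eps0: float = 0.05,
        fix_eps: bool = False,
    ) -> CBNResults:
        """Simulated-annealing poset search with nested EM.

        The best penalized-likelihood state visited across all restarts
        (including the initial empty poset) is returned, with a final full
        EM polish.  A zero-step schedule therefore returns the EM fit of the
        empty poset.
        """
        if schedule is None:
            schedule = AnnealSchedule()
        if rng is None:
            rng = np.random.default_rng(seed)
        if self.K == 0:
            return self._expand_results((), np.empty(0), eps0, 0.0)

        empty = (0,) * self.K
        lat0 = _Lattice(empty)
        lam0 = np.clip(
            self._freq_active / np.clip(1.0 - self._freq_active, 1e-12, None),
            _LAM_MIN,
            _LAM_MAX,
        )
        lam0, eps_best, ll = self._em(
            lat0, lam0, eps0, schedule.final_em_iters, fix_eps
        )
        best = (self._score(ll, empty), empty, lam0.copy(), eps_best, ll)

        for restart in range(max(schedule.restarts, 1)):
            masks = empty
            lam, eps = lam0.copy(), best[3]
            if restart > 0:  # diversify: random sprinkling of edges
                masks = self._random_poset(rng)
                lam = lam0.copy()
            cur_ll = self._em_for(masks, lam, eps, schedule.em_iters, fix_eps)
            lam, eps, cur_ll = cur_ll
            cur_score = self._score(cur_ll, masks)
            T0, T1 = schedule.t_initial, schedule.t_final
            for step in range(schedule.steps):
                T = T0 * (T1 / T0) ** (step / max(schedule.steps - 1, 1))
                prop = self._propose(masks, rng)
                if prop is None:
                    continue
                p_lam, p_eps, p_ll = self._em_for(
                    prop, lam, eps, schedule.em_iters, fix_eps
                )
                p_score = self._score(p_ll, prop)
                delta = p_score - cur_score
                if delta >= 0 or rng.random() < math.exp(delta / T):
                    masks, lam, eps = prop, p_lam, p_eps
                    cur_ll, cur_score = p_ll, p_score
                    if cur_score > best[0]:
                        best = (cur_score, masks, lam.copy(), eps, cur_ll)

        _, masks, lam, eps, _ = best
        lam, eps, ll = self._em(
            _Lattice(masks), lam, eps, schedule.final_em_iters, fix_eps
        )
        return self._expand_results(masks, lam, eps, ll)

    def _em_for(self, masks, lam, eps, iters, fix_eps):
        return self._em(_Lattice(tuple(masks)), np.asarray(lam, float), eps, iters, fix_eps)

    def _random_poset(self, rng: np.random.Generator) -> tuple[int, ...]:
        order = rng.permutation(self.K)
        masks = [0] * self.K
        for b in range(1, self.K):
            j = int(order[b])
            for a in range(b):
                if rng.random() < 0.2:
                    masks[j] |= 1 << int(order[a])
        return tuple(masks)

    def _propose(
        self, masks: tuple[int, ...], rng: np.random.Generator
    ) -> tuple[int, ...] | None:
        K = self.K
        existing = [
            (i, j) for j in range(K) for i in range(K) if (masks[j] >> i) & 1
        ]
        move = rng.integers(3)
        new = list(masks)
        if move == 0 or (move == 2 and not existing):  # add a random edge
            i, j = rng.integers(K), rng.integers(K)
            if i == j or (masks[j] >> i) & 1:
                return None
            new[j] |= 1 << int(i)
        elif move == 1:  # delete a random existing edge
            if not existing:
                return None
            i, j = existing[int(rng.integers(len(existing)))]
            new[j] &= ~(1 << i)
        else:  # swap (reverse) a random existing edge
            i, j = existing[int(rng.integers(len(existing)))]
            new[j] &= ~(1 << i)
            new[i] |= 1 << j
        try:
            DagOfRestrictions(K, tuple(new))
        except ValueError:
            return None
        return tuple(new)

    def _expand_results(
        self, masks: tuple[int, ...], lam: np.ndarray, eps: float, ll: float
    ) -> CBNResults:
        """Re-attach degenerate columns as isolated always/never features."""
        masks = _transitive_reduction(masks)
        full_masks = [0] * self.K_all
        full_lam = [0.0] * self.K_all
        active_pos = {a: i for i, a in enumerate(self._active)}
        for a, i in active_pos.items():
            m = 0
            for a2, i2 in active_pos.items():
                if (masks[i] >> i2) & 1:
                    m |= 1 << a2
            full_masks[a] = m
            full_lam[a] = float(lam[i])
        for j in self._degenerate_zero:
            full_lam[j] = _LAM_MIN  # never observed: effectively rate 0
        for j in self._degenerate_one:
            full_lam[j] = _LAM_MAX  # always present: effectively instantaneous
        return CBNResults(
            feature_names=self.feature_names,
            parent_masks=tuple(full_masks),
            rates=full_lam,
            eps=float(eps),
            loglik=ll,
            n_obs=self.n,
            penalty=self.penalty,
            score=self._score(ll, masks),
        )


# ---------------------------------------------------------------------------
# forward sampling and adapters
# ---------------------------------------------------------------------------


def generate_from_cbn(
    model: CBNResults | "ExternalCpmAdapter",
    n: int,
    rng: np.random.Generator,
) -> CrossSectionalDataset:
    """Forward-sample subjects from a CBN.

    Feature j's occurrence time is the maximum of its parents' times plus an
    Exp(lambda_j) wait; the recorded genotype is the set of features occurred
    before an Exp(1) observation time, with each bit then flipped with
    probability eps.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = list(model.feature_names)
    masks = tuple(model.parent_masks)
    lam = np.asarray(list(model.rates), dtype=float)
    eps = float(getattr(model, "eps", 0.0))
    K = len(names)
    order = _topological_order(masks)
    X = np.zeros((n, K), dtype=np.int8)
    obs_t = rng.exponential(1.0, size=n)
    times = np.empty((n, K))
    for j in order:
        parent_t = np.zeros(n)
        for i in range(K):
            if (masks[j] >> i) & 1:
                parent_t = np.maximum(parent_t, times[:, i])
        times[:, j] = parent_t + rng.exponential(1.0 / lam[j], size=n)
    X[:] = (times <= obs_t[:, None]).astype(np.int8)
    if eps > 0:
        flips = rng.random((n, K)) < eps
        X = np.where(flips, 1 - X, X).astype(np.int8)
    return CrossSectionalDataset(
        pd.DataFrame(X, columns=names), {"source": "cbn_forward_sample"}
    )


def _topological_order(masks: tuple[int, ...]) -> list[int]:
    K = len(masks)
    done = 0
    order: list[int] = []
    while len(order) < K:
        progressed = False
        for j in range(K):
            if not (done >> j) & 1 and (masks[j] & done) == masks[j]:
                order.append(j)
                done |= 1 << j
                progressed = True
        if not progressed:
            raise ValueError("poset contains a cycle")
    return order


@dataclass
class ExternalCpmAdapter:
    """Plug third-party CPM output (a DAG, optional rates) into the path
    machinery without reimplementing the tool."""

    feature_names: list[str]
    parent_masks: tuple[int, ...]
    rates: list[float] | None = None
    eps: float = 0.0

    @classmethod
    def from_edges(
        cls,
        feature_names: list[str],
        edges: list[tuple[str, str]],
        rates: dict[str, float] | None = None,
        eps: float = 0.0,
    ) -> "ExternalCpmAdapter":
        idx = {name: j for j, name in enumerate(feature_names)}
        masks = [0] * len(feature_names)
        for a, b in edges:
            masks[idx[b]] |= 1 << idx[a]
        DagOfRestrictions(len(feature_names), tuple(masks))  # validates
        rate_list = (
            [rates[n] for n in feature_names] if rates is not None else None
        )
        return cls(feature_names, tuple(masks), rate_list, eps)


# ---------------------------------------------------------------------------
# functional wrappers (spec-style operation names)
# ---------------------------------------------------------------------------

OtModel = OncogeneticTreeResults
CbnModel = CBNResults


def fit_ot(dataset) -> OncogeneticTreeResults:
    return OncogeneticTree(dataset).fit()


def fit_cbn(
    dataset,
    schedule: AnnealSchedule | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    penalty: str | None = None,
) -> CBNResults:
    return ConjunctiveBayesianNetwork(dataset, penalty=penalty).fit(
        schedule=schedule, rng=rng, seed=seed
    )


def cbn_loglik(model: CBNResults, dataset) -> float:
    """Exact log-likelihood of a fitted CBN on a dataset (same features)."""
    frame = _as_frame(dataset)
    if list(frame.columns) != list(model.feature_names):
        raise ValueError("dataset features do not match the model")
    cbn = ConjunctiveBayesianNetwork(frame)
    if cbn.K != cbn.K_all:
        raise ValueError("cbn_loglik requires non-degenerate columns")
    return cbn.loglik(model.parent_masks, model.rates, model.eps)
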