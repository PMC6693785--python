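"""Turn simulated trajectories into cross-sectional mutation data.

Each simulated tumor contributes one observation.  A detection regime is a
Beta distribution on (rescaled) log tumor size: ``uniform`` = B(1, 1),
``large`` = B(5, 3) (samples enriched in late, large tumors) and ``small`` =
B(3, 5) (early, small tumors).  For every trajectory a beta deviate is drawn,
rescaled to the range of log population sizes pooled across all snapshots of
the batch, the snapshot whose log size is closest to the target is selected,
and the genotype of its most abundant clone is returned.  The resulting
genotypes form a subjects x genes binary matrix, which can then be split into
non-overlapping data sets of the study's sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evolution import Trajectory

__all__ = [
    "DetectionRegime",
    "CrossSectionalDataset",
    "sample_detection",
    "build_dataset",
    "split_nonoverlapping",
    "top_features",
    "InsufficientSamplesError",
]


@dataclass(frozen=True)
class DetectionRegime:
    """Named Beta(alpha, beta) law for when tumors are detected."""

    name: str
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta parameters must be positive")

    @classmethod
    def uniform(cls) -> "DetectionRegime":
        return cls("uniform", 1.0, 1.0)

    @classmethod
    def large(cls) -> "DetectionRegime":
        return cls("large", 5.0, 3.0)

    @classmethod
    def small(cls) -> "DetectionRegime":
        return cls("small", 3.0, 5.0)

    @classmethod
    def by_name(cls, name: str) -> "DetectionRegime":
        try:
            return {"uniform": cls.uniform, "large": cls.large, "small": cls.small}[
                name
            ]()
        except KeyError:
            raise ValueError(f"unknown detection regime {name!r}") from None


STANDARD_REGIMES = ("uniform", "large", "small")


@dataclass
class CrossSectionalDataset:
    """Binary subjects x features matrix with provenance metadata."""

    matrix: pd.DataFrame  # 0/1 ints, columns = feature names
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("dataset entries must be 0/1")
        if self.matrix.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        self.matrix = self.matrix.astype(np.int8)

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.matrix.columns)

    def frequencies(self) -> pd.Series:
        return self.matrix.mean(axis=0)

    # --- CSV I/O (comma-separated, header row, no row names) -------------
    def to_csv(self, path_or_buf=None):
        return self.matrix.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, provenance: dict | None = None):
        df = pd.read_csv(path_or_buf)
        return cls(df, provenance or {})


def sample_detection(
    trajectories: list[Trajectory],
    regime: DetectionRegime,
    rng: np.random.Generator,
    pooled: bool = True,
) -> list[int]:
    """One genotype per trajectory under the given detection regime.

    With ``pooled=True`` (default) the beta deviates are rescaled to the
    [min, max] of log population sizes pooled across all snapshots of all
    trajectories; with ``pooled=False`` each trajectory uses its own range.
    """
    if not trajectories:
        raise ValueError("trajectory list must be non-empty")
    for traj in trajectories:
        if not traj.snapshots:
            raise ValueError("every trajectory needs at least one snapshot")
    log_sizes = [
        np.log([s.size for s in traj.snapshots]) for traj in trajectories
    ]
    if pooled:
        lo = min(float(ls.min()) for ls in log_sizes)
        hi = max(float(ls.max()) for ls in log_sizes)
    deviates = rng.beta(regime.alpha, regime.beta, size=len(trajectories))
    genotypes: list[int] = []
    for traj, ls, u in zip(trajectories, log_sizes, deviates):
        if not pooled:
            lo, hi = float(ls.min()), float(ls.max())
        target = lo + u * (hi - lo)
        idx = int(np.argmin(np.abs(ls - target)))  # argmin takes earliest tie
        genotypes.append(traj.snapshots[idx].most_abundant_genotype())
    return genotypes


def build_dataset(
    genotypes: list[int],
    n_genes: int,
    feature_names: list[str] | None = None,
    provenance: dict | None = None,
) -> CrossSectionalDataset:
    """Stack genotype bitmasks into a binary matrix (row order preserved).

    Columns for genes never mutated are retained as all-zero columns.
    """
    if feature_names is None:
        feature_names = [f"g{i + 1}" for i in range(n_genes)]
    if len(feature_names) != n_genes:
        raise ValueError("feature_names length must equal n_genes")
    arr = np.zeros((len(genotypes), n_genes), dtype=np.int8)
    for r, g in enumerate(genotypes):
        if g >= (1 << n_genes):
            raise ValueError(f"genotype {g} does not fit in {n_genes} genes")
        for i in range(n_genes):
            arr[r, i] = (g >> i) & 1
    return CrossSectionalDataset(
        pd.DataFrame(arr, columns=feature_names), provenance or {}
    )


class InsufficientSamplesError(ValueError):
    pass


def split_nonoverlapping(
    dataset: CrossSectionalDataset,
    sizes: list[int],
    n_splits: int = 5,
    rng: np.random.Generator | None = None,
) -> dict[int, list[CrossSectionalDataset]]:
    """For each sample size, draw ``n_splits`` pairwise-disjoint subsets.

    Subsets are drawn without replacement from a fresh permutation of the
    rows for each size, so within a size the splits never share a subject.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = dataset.n_subjects
    for s in sizes:
        if n_splits * s > n:
            raise InsufficientSamplesError(
                f"cannot draw {n_splits} disjoint subsets of size {s} "
                f"from {n} subjects"
            )
    out: dict[int, list[CrossSectionalDataset]] = {}
    for s in sizes:
        perm = rng.permutation(n)
        subsets = []
        for k in range(n_splits):
            rows = np.sort(perm[k * s : (k + 1) * s])
            prov = dict(dataset.provenance)
            prov.update({"split": k + 1, "sample_size": s})
            subsets.append(
                CrossSectionalDataset(
                    dataset.matrix.iloc[rows].reset_index(drop=True), prov
                )
            )
        out[s] = subsets
    return out


def top_features(
    dataset: CrossSectionalDataset, threshold: int
) -> CrossSectionalDataset:
    """Keep the ``threshold`` most frequently mutated features.

    Ties are broken by column order (earlier column wins), deterministically.
    Datasets with no more features than the threshold are returned unchanged.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if dataset.n_features <= threshold:
        return dataset
    freqs = dataset.frequencies().to_numpy()
    # stable sort on negated frequency preserves column order among ties
    keep = np.sort(np.argsort(-freqs, kind="stable")[:threshold])
    prov = dict(dataset.provenance)
    prov["feature_threshold"] = threshold
    return CrossSectionalDataset(dataset.matrix.iloc[:, keep], prov)
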