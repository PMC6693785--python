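"""Bootstrap reliability of inferred path distributions (JS_o,b).

The truth is unknown for real cross-sectional data, so reliability is
assessed by refitting the CPM on case-resampled bootstrap replicates of the
data and averaging the Jensen-Shannon divergence between the path
distribution from the original fit and each bootstrap fit.  Large JS_o,b
means the inferred distribution of paths to the maximum is unstable and
should not be trusted; small JS_o,b indicates stability, not accuracy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .detection import CrossSectionalDataset, top_features
from .metrics import compare_path_distributions
from .paths import PathDistribution

logger = logging.getLogger(__name__)

__all__ = ["ReliabilityResult", "bootstrap_jsob"]


@dataclass
class ReliabilityResult:
    """Mean and per-replicate JS between original and bootstrap fits."""

    js_ob: float
    replicate_js: list[float]
    B: int
    n_failed: int
    original_entropy: float  # S_c of the original fit's path distribution

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")

    def to_tsv(self) -> str:
        lines = [
            "statistic\tvalue",
            f"js_ob\t{self.js_ob!r}",
            f"B\t{self.B}",
            f"n_failed\t{self.n_failed}",
            f"s_c\t{self.original_entropy!r}",
        ]
        for b, v in enumerate(self.replicate_js):
            lines.append(f"js_replicate_{b + 1}\t{v!r}")
        return "\n".join(lines) + "\n"


def bootstrap_jsob(
    dataset: CrossSectionalDataset,
    fitter: Callable[[CrossSectionalDataset], object],
    weighter: Callable[[object], PathDistribution],
    B: int = 100,
    rng: np.random.Generator | None = None,
    feature_threshold: int | None = None,
) -> ReliabilityResult:
    """Average JS between the original fit and ``B`` bootstrap refits.

    Subjects are resampled with replacement at the original sample size; the
    full fit (structure and parameters) is repeated on each replicate.  If
    ``feature_threshold`` is given, the most-common-feature selection is
    applied to the original data before fitting and the same selected
    columns are used for every replicate.  A fitter failure on a replicate
    is recorded and skipped; ``js_ob`` averages the completed replicates.
    """
    if rng is None:
        rng = np.random.default_rng()
    if feature_threshold is not None:
        dataset = top_features(dataset, feature_threshold)
    original_model = fitter(dataset)
    original_dist = weighter(original_model)
    from .metrics import path_entropy

    s_c = path_entropy(original_dist).entropy

    n = dataset.n_subjects
    seeds = rng.integers(0, 2**31 - 1, size=B)
    values: list[float] = []
    n_failed = 0
    for b in range(B):
        sub_rng = np.random.default_rng(int(seeds[b]))
        rows = sub_rng.integers(0, n, size=n)
        replicate = CrossSectionalDataset(
            dataset.matrix.iloc[rows].reset_index(drop=True),
            dict(dataset.provenance, bootstrap=b + 1),
        )
        try:
            model_b = fitter(replicate)
            dist_b = weighter(model_b)
        except Exception as exc:  # noqa: BLE001 - failures are data, not bugs
            logger.warning("bootstrap replicate %d failed: %s", b + 1, exc)
            n_failed += 1
            continue
        values.append(
            compare_path_distributions(original_dist, dist_b).js
        )
    js_ob = float(np.mean(values)) if values else math.nan
    return ReliabilityResult(js_ob, values, B, n_failed, s_c)
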