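"""Factorial benchmark: design enumeration, execution, and summaries.

The study crosses number of genes x landscape kind x initial population
size x mutation regime x random landscape replicates; each simulated batch
is sampled under three detection regimes and split into non-overlapping
data sets of several sample sizes, each analyzed by each CPM.  At full
scale this is 1260 landscapes (2 x 3 x 3 x 2 x 35) and 56700 data sets
(1260 x 3 detection regimes x 3 sample sizes x 5 splits) with 20000
evolutionary runs per landscape.  The desk scale keeps the pipeline and
factor semantics but runs 7 genes, one initial size, fewer replicates and
runs per landscape, so a full sweep fits on a single workstation; every
reduction is visible in the emitted design table.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import detection as det
from . import evolution as evo
from . import landscapes as lsc
from .cpm import AnnealSchedule, ConjunctiveBayesianNetwork, OncogeneticTree
from .metrics import compare_path_distributions, path_entropy
from .paths import lod_path_distribution, paths_from_model, uniform_path_distribution

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentDesign",
    "BenchmarkConfig",
    "enumerate_design",
    "run_benchmark",
    "summarize_results",
    "FULL_SCALE",
    "DESK_SCALE",
]

FULL_SCALE = {
    "n_genes": (7, 10),
    "kinds": ("representable", "local_maxima", "rmf"),
    "initial_sizes": (2000, 50000, 1_000_000),
    "mutation_regimes": ("constant", "variable"),
    "n_replicates": 35,
    "detection_regimes": ("uniform", "large", "small"),
    "sample_sizes": (50, 200, 4000),
    "n_splits": 5,
    "n_runs": 20000,
}

DESK_SCALE = {
    "n_genes": (7,),
    "kinds": ("representable", "local_maxima", "rmf"),
    "initial_sizes": (2000,),
    "mutation_regimes": ("constant",),
    "n_replicates": 5,
    "detection_regimes": ("uniform", "large", "small"),
    "sample_sizes": (50, 200, 1000),
    "n_splits": 5,
    "n_runs": 1000,
}


@dataclass
class ExperimentDesign:
    """Landscape-level and dataset-level tables of the factorial design."""

    scale: str
    factors: dict
    landscapes: pd.DataFrame  # one row per landscape configuration replicate
    datasets: pd.DataFrame  # x detection x sample size x split

    def n_landscapes(self) -> int:
        return len(self.landscapes)

    def n_datasets(self) -> int:
        return len(self.datasets)


def enumerate_design(
    scale: str = "desk", overrides: dict | None = None
) -> ExperimentDesign:
    """Enumerate the factorial design at ``full`` or ``desk`` scale.

    Full scale reproduces the study's counts exactly: 1260 landscape rows
    and 56700 dataset rows.  ``overrides`` replaces individual factor
    settings (e.g. fewer replicates) without touching the crossing itself.
    """
    if scale not in ("full", "desk"):
        raise ValueError("scale must be 'full' or 'desk'")
    factors = dict(FULL_SCALE if scale == "full" else DESK_SCALE)
    if overrides:
        factors.update(overrides)
    rows = []
    lid = 0
    for K, kind, N0, regime in itertools.product(
        factors["n_genes"],
        factors["kinds"],
        factors["initial_sizes"],
        factors["mutation_regimes"],
    ):
        for rep in range(1, factors["n_replicates"] + 1):
            rows.append(
                {
                    "landscape_id": lid,
                    "n_genes": K,
                    "kind": kind,
                    "initial_size": N0,
                    "mutation_regime": regime,
                    "replicate": rep,
                    "n_runs": factors["n_runs"],
                }
            )
            lid += 1
    landscapes = pd.DataFrame(rows)
    ds_rows = []
    for _, lrow in landscapes.iterrows():
        for regime, size, split in itertools.product(
            factors["detection_regimes"],
            factors["sample_sizes"],
            range(1, factors["n_splits"] + 1),
        ):
            ds_rows.append(
                {
                    "landscape_id": lrow["landscape_id"],
                    "detection": regime,
                    "sample_size": size,
                    "split": split,
                }
            )
    return ExperimentDesign(scale, factors, landscapes, pd.DataFrame(ds_rows))


@dataclass
class BenchmarkConfig:
    """Execution knobs for :func:`run_benchmark`."""

    cpms: tuple[str, ...] = ("cbn", "ot")
    weightings: tuple[str, ...] = ("probability", "uniform")
    dag_density: float = 0.3
    removal_fraction: float = 0.5
    rmf_slope: float = 0.05
    rmf_hoc_sd: float = 0.05
    theta: float = 0.99
    tau: float = 0.25
    cbn_schedule: AnnealSchedule = field(
        default_factory=lambda: AnnealSchedule(
            restarts=2, steps=400, em_iters=1, final_em_iters=50
        )
    )
    max_landscape_tries: int = 10

    @classmethod
    def from_file(cls, path: str) -> "BenchmarkConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        sched = payload.pop("cbn_schedule", None)
        cfg = cls(**payload)
        if sched:
            cfg.cbn_schedule = AnnealSchedule(**sched)
        return cfg


def _make_landscape(kind, K, config, rng):
    if kind == "representable":
        return lsc.representable_landscape(K, config.dag_density, rng)
    if kind == "local_maxima":
        return lsc.local_maxima_landscape(
            K, config.dag_density, config.removal_fraction, rng=rng
        )
    if kind == "rmf":
        return lsc.rmf_landscape(K, config.rmf_slope, config.rmf_hoc_sd, rng)
    raise ValueError(f"unknown landscape kind {kind!r}")


def _simulate_landscape(lrow, config, seed):
    """Generate a landscape (regenerating on gene-coverage failure) and run
    the evolutionary batch for one design row."""
    K = int(lrow["n_genes"])
    sim_cfg = evo.SimulationConfig(
        initial_size=int(lrow["initial_size"]),
        theta=config.theta,
        tau=config.tau,
    )
    seed = list(np.atleast_1d(seed))
    for attempt in range(config.max_landscape_tries):
        rng = np.random.default_rng([*seed, attempt])
        landscape = _make_landscape(lrow["kind"], K, config, rng)
        regime = (
            evo.MutationRegime.constant(K)
            if lrow["mutation_regime"] == "constant"
            else evo.MutationRegime.variable(K, rng)
        )
        batch = evo.batch_simulate(
            landscape, sim_cfg, regime, int(lrow["n_runs"]), rng
        )
        if batch.all_genes_covered:
            return landscape, batch, rng
        logger.info(
            "landscape %s attempt %d: gene coverage failed, regenerating",
            lrow["landscape_id"],
            attempt + 1,
        )
    raise RuntimeError(
        f"no gene-covering landscape after {config.max_landscape_tries} tries"
    )


def _fit_and_distributions(cpm, dataset, config, rng):
    """Fit one CPM and return {weighting: PathDistribution}."""
    out = {}
    if cpm == "ot":
        results = OncogeneticTree(dataset).fit()
        if "probability" in config.weightings:
            out["probability"] = results.path_distribution()
        if "uniform" in config.weightings:
            out["uniform"] = uniform_path_distribution(paths_from_model(results))
    elif cpm == "cbn":
        results = ConjunctiveBayesianNetwork(dataset).fit(
            schedule=config.cbn_schedule, rng=rng
        )
        if "probability" in config.weightings:
            out["probability"] = results.path_distribution()
        if "uniform" in config.weightings:
            out["uniform"] = uniform_path_distribution(paths_from_model(results))
    else:
        raise ValueError(f"unknown CPM {cpm!r}")
    return out


def run_benchmark(
    design: ExperimentDesign,
    config: BenchmarkConfig | None = None,
    master_seed: int = 0,
    log_path: str | None = None,
) -> pd.DataFrame:
    """Execute the pipeline for every design row; one result row per
    (dataset row x CPM x weighting).

    Fully reproducible from ``master_seed``: every landscape row derives an
    independent seed stream, so execution order does not matter.  Individual
    fit failures are flagged and the run continues.  With ``log_path`` a
    JSON-lines structured log (seed, landscape id, timing, failure count)
    is written, one record per landscape row.
    """
    import json
    import time

    if config is None:
        config = BenchmarkConfig()
    results = []
    log_fh = open(log_path, "w") if log_path else None
    for _, lrow in design.landscapes.iterrows():
        lid = int(lrow["landscape_id"])
        t_start = time.perf_counter()
        n_failures = 0
        try:
            landscape, batch, rng = _simulate_landscape(
                lrow, config, [master_seed, lid]
            )
        except Exception as exc:  # noqa: BLE001
            logger.error("landscape %d failed: %s", lid, exc)
            if log_fh:
                log_fh.write(
                    json.dumps(
                        {
                            "landscape_id": lid,
                            "seed": [master_seed, lid],
                            "error": str(exc),
                        }
                    )
                    + "\n"
                )
            continue
        lod_dist = lod_path_distribution(batch.lods)
        s_p = path_entropy(lod_dist).entropy
        ds_rows = design.datasets[design.datasets["landscape_id"] == lid]
        for regime_name in ds_rows["detection"].unique():
            regime = det.DetectionRegime.by_name(regime_name)
            genotypes = det.sample_detection(batch.trajectories, regime, rng)
            pool = det.build_dataset(
                genotypes,
                int(lrow["n_genes"]),
                provenance={"landscape_id": lid, "detection": regime_name},
            )
            sub = ds_rows[ds_rows["detection"] == regime_name]
            sizes = sorted(sub["sample_size"].unique())
            n_splits = int(sub["split"].max())
            splits = det.split_nonoverlapping(pool, sizes, n_splits, rng)
            for size in sizes:
                for split_idx, dataset in enumerate(splits[size], start=1):
                    for cpm in config.cpms:
                        base = {
                            **{
                                k: lrow[k]
                                for k in (
                                    "landscape_id",
                                    "n_genes",
                                    "kind",
                                    "initial_size",
                                    "mutation_regime",
                                    "replicate",
                                )
                            },
                            "detection": regime_name,
                            "sample_size": size,
                            "split": split_idx,
                            "cpm": cpm,
                            "s_p": s_p,
                        }
                        try:
                            dists = _fit_and_distributions(
                                cpm, dataset, config, rng
                            )
                        except Exception as exc:  # noqa: BLE001
                            logger.warning(
                                "fit failed (landscape %d, %s, n=%d, "
                                "split %d, %s): %s",
                                lid,
                                regime_name,
                                size,
                                split_idx,
                                cpm,
                                exc,
                            )
                            results.append(
                                {**base, "weighting": None, "error": str(exc)}
                            )
                            n_failures += 1
                            continue
                        for weighting, dist in dists.items():
                            comp = compare_path_distributions(lod_dist, dist)
                            results.append(
                                {
                                    **base,
                                    "weighting": weighting,
                                    "js": comp.js,
                                    "one_minus_recall": comp.one_minus_recall,
                                    "one_minus_precision": comp.one_minus_precision,
                                    "mcl": comp.mcl_recovered,
                                    "s_c": path_entropy(dist).entropy,
                                    "error": None,
                                }
                            )
        if log_fh:
            log_fh.write(
                json.dumps(
                    {
                        "landscape_id": lid,
                        "seed": [master_seed, lid],
                        "kind": str(lrow["kind"]),
                        "n_runs": int(lrow["n_runs"]),
                        "seconds": round(time.perf_counter() - t_start, 3),
                        "fit_failures": n_failures,
                    }
                )
                + "\n"
            )
            log_fh.flush()
    if log_fh:
        log_fh.close()
    return pd.DataFrame(results)


METRIC_COLS = ["js", "one_minus_recall", "one_minus_precision", "mcl", "s_c"]


def summarize_results(rows: pd.DataFrame) -> pd.DataFrame:
    """Split-averaged summary per (kind x detection x sample size x CPM x
    weighting): the response for each landscape is the mean over its splits,
    then means and SDs are taken across landscapes."""
    if rows.empty:
        raise ValueError("result table is empty")
    ok = rows[rows["error"].isna()].copy()
    ok["sc_sp_ratio"] = ok["s_c"] / ok["s_p"]
    per_landscape = (
        ok.groupby(
            [
                "kind",
                "detection",
                "sample_size",
                "cpm",
                "weighting",
                "landscape_id",
            ],
            as_index=False,
        )[METRIC_COLS + ["s_p", "sc_sp_ratio"]]
        .mean()
    )
    agg = per_landscape.groupby(
        ["kind", "detection", "sample_size", "cpm", "weighting"], as_index=False
    ).agg(
        **{
            f"{c}_mean": (c, "mean")
            for c in METRIC_COLS + ["s_p", "sc_sp_ratio"]
        },
        **{f"{c}_sd": (c, "std") for c in METRIC_COLS},
        n_landscapes=("landscape_id", "nunique"),
    )
    return agg
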