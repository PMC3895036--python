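"""Experiment orchestration: seed fan-out, end-to-end runs, test fixtures.

A single master seed fans out into named substreams (pool generation,
optimizer, hypervolume Monte Carlo) so components can be re-run in
isolation; every output directory carries the config hash and seeds in a
JSON metadata file, making any result regenerable from config + seed alone.
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, config_hash, save_config
from .dynamics import BiomassCurve, SimConfig, UncertaintyModel
from .hexgrid import (
    AreaDistribution,
    HexLandscape,
    LandscapePool,
    build_grid,
    generate_landscape,
    generate_pool,
)
from .moea import (
    NSGA2Result,
    OptimizerConfig,
    RegimeProblem,
    decode,
    nsga2_run,
)
from .objectives import ObjectiveVector
from .postprocess import ParetoFrontier, standardize_and_score

__all__ = [
    "substream",
    "build_pool",
    "run_optimization",
    "run_experiment",
    "Fixtures",
    "make_fixtures",
]

log = logging.getLogger("fuelscape")

# named substreams of the master seed
_STREAMS = {"pool": 0, "optimizer": 1, "fixtures": 2, "rescan": 3, "sweep": 4}


def substream(master_seed: int, name: str, index: int = 0) -> np.random.SeedSequence:
    """Named child seed of the master seed (documented fan-out)."""
    return np.random.SeedSequence(master_seed, spawn_key=(_STREAMS[name], index))


def sim_config_from(config: RunConfig) -> SimConfig:
    return SimConfig(
        horizon=config.horizon,
        burn_in=config.burn_in,
        replicates=config.replicates,
        curve=BiomassCurve(b_max=config.biomass_max, rate=config.biomass_rate),
    )


def build_pool(config: RunConfig) -> LandscapePool:
    seed = int(substream(config.seed, "pool").generate_state(1)[0] % 2**31)
    return generate_pool(
        n=config.pool_size,
        n_rows=config.grid_rows,
        n_cols=config.grid_cols,
        dist=AreaDistribution(config.area_mean, config.area_variance),
        base_seed=seed,
        max_age=config.initial_age_max,
    )


def run_optimization(
    config: RunConfig, pool: LandscapePool | None = None
) -> tuple[ParetoFrontier, NSGA2Result]:
    """Optimize one strategy (k = config.n_groups); returns frontier + raw result."""
    pool = pool or build_pool(config)
    problem = RegimeProblem(
        pool=pool,
        model=UncertaintyModel(shape=config.uncertainty_shape),
        sim_config=sim_config_from(config),
        n_groups=config.n_groups,
    )
    opt = OptimizerConfig(
        population=config.population,
        generations=config.generations,
        crossover_prob=config.crossover_prob,
        mutation_prob=config.mutation_prob,
        crossover_eta=config.crossover_eta,
        mutation_eta=config.mutation_eta,
        hv_samples=config.hv_samples,
    )
    rng = np.random.default_rng(substream(config.seed, "optimizer"))
    xl, xu = problem.bounds
    result = nsga2_run(problem, xl, xu, opt, rng)
    frontier = ParetoFrontier(
        regimes=[decode(x, config.n_groups) for x in result.front_X],
        objectives=[ObjectiveVector.from_canonical(f) for f in result.front_F],
        genes=result.front_X,
        ranks=np.ones(len(result.front_X), dtype=np.int64),
        crowding=result.crowding[result.ranks == 1],
    )
    return frontier, result


def run_experiment(config: RunConfig, outdir: str | Path) -> Path:
    """End-to-end pipeline: pool -> optimization -> scoring -> exports.

    Writes frontier.csv, hypervolume.csv, scores.csv, config.yaml and
    metadata.json into ``outdir``.  A failure leaves a machine-readable
    error.json instead of partial silence.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        pool = build_pool(config)
        log.info("pool of %d landscapes generated", len(pool))
        frontier, result = run_optimization(config, pool)
        for gen, hv in enumerate(result.hypervolume_series):
            log.info("generation %d hypervolume %.6g", gen, hv)
        frontier.to_csv(outdir / "frontier.csv")
        pd.DataFrame(
            {
                "generation": np.arange(len(result.hypervolume_series)),
                "hypervolume": result.hypervolume_series,
            }
        ).to_csv(outdir / "hypervolume.csv", index=False)
        score = standardize_and_score(frontier)
        scores = frontier.to_dataframe()
        scores["distance_to_ideal"] = score.distance
        scores.to_csv(outdir / "scores.csv", index=False)
        save_config(config, outdir / "config.yaml")
        with open(outdir / "metadata.json", "w") as fh:
            json.dump(
                {
                    "config_hash": config_hash(config),
                    "master_seed": config.seed,
                    "n_evaluations": result.n_evaluations,
                    "n_frontier": len(frontier),
                    "reference_point": result.reference_point.tolist(),
                },
                fh,
                indent=2,
            )
    except Exception as exc:  # pragma: no cover - exercised via error manifest test
        with open(outdir / "error.json", "w") as fh:
            json.dump(
                {"error": str(exc), "traceback": traceback.format_exc()}, fh, indent=2
            )
        raise
    return outdir


@dataclass
class Fixtures:
    """Deterministic small test fixtures regenerated from one seed."""

    landscape_5x5: HexLandscape
    landscape_10x10: HexLandscape
    objective_points: np.ndarray  # (20, 6) random canonical vectors
    objective_ranks: np.ndarray  # brute-force nondominated ranks


def _brute_force_ranks(F: np.ndarray) -> np.ndarray:
    """Iterative-removal nondominated ranking (independent O(n^2 k) oracle)."""
    n = len(F)
    ranks = np.zeros(n, dtype=np.int64)
    remaining = list(range(n))
    r = 1
    while remaining:
        front = []
        for i in remaining:
            dominated = False
            for j in remaining:
                if j == i:
                    continue
                if np.all(F[j] <= F[i]) and np.any(F[j] < F[i]):
                    dominated = True
                    break
            if not dominated:
                front.append(i)
        for i in front:
            ranks[i] = r
        remaining = [i for i in remaining if i not in front]
        r += 1
    return ranks


def make_fixtures(seed: int = 0) -> Fixtures:
    rng = np.random.default_rng(substream(seed, "fixtures"))
    dist = AreaDistribution(5.0, 10.0)  # small holdings so tiny grids get several owners
    ls5 = generate_landscape(build_grid(5, 5), dist, rng, landscape_id=0)
    ls10 = generate_landscape(build_grid(10, 10), dist, rng, landscape_id=1)
    points = rng.random((20, 6))
    return Fixtures(
        landscape_5x5=ls5,
        landscape_10x10=ls10,
        objective_points=points,
        objective_ranks=_brute_force_ranks(points),
    )
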