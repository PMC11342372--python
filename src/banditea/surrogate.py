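"""Gaussian surrogate of per-cluster EA output and learning-parameter tuning.

Running a real evolutionary algorithm for every candidate parameter set is
prohibitively expensive, so each cluster's EA output is modelled as a normal
distribution fitted to the run-minimum energies of repeated EA runs started
from that cluster: one Gaussian draw stands in for the minimum energy of one
50-iteration EA run.

A surrogate *trial* proceeds in batches: the agent selects ``batch_size``
clusters with replacement, one draw is made per selection, and the trial
stops as a success the moment a draw falls below the energy threshold
``e_min``; otherwise the agent's weights are updated with the batch's draws
and the next batch begins, up to ``max_batches``.  Iterations accrue in draw
order (success on draw j of batch k is credited at iteration
``k * batch_size * iters_per_run + j * iters_per_run``), so a full trial
spans at most ``batch_size * iters_per_run * max_batches`` iterations
(5000 at the defaults).

Parameter combinations are scored by the area under the cumulative success
curve over many independent trials, and a grid search ranks integer
combinations by that area.  Reproducibility: trial t of combo i uses the RNG
substream spawned from ``(master_seed, i, t)``, so results are identical
regardless of evaluation order or worker count.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .agent import LearningParams, init_agent, select, update

__all__ = [
    "ClusterModel",
    "TrialConfig",
    "TrialResult",
    "SuccessCurve",
    "load_cluster_models",
    "save_cluster_models",
    "draw_run_minimum",
    "run_trial",
    "run_trials",
    "cumulative_success_curve",
    "success_area",
    "evaluate_combo",
    "default_grid_ranges",
    "grid_search",
]

#: Default success threshold in eV for the packaged 9-cluster models.
DEFAULT_E_MIN = -560.0


@dataclass(frozen=True)
class ClusterModel:
    """Normal model (mean, sd in eV) of a cluster's EA run-minimum energies."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")


def load_cluster_models(path: str | Path | None = None) -> list[ClusterModel]:
    """Read per-cluster (mean, sd) models from CSV.

    With no path, loads the packaged 9-cluster reference table fitted to 100
    EA runs per cluster of quinoline-like (C9H7N) structures.
    """
    import pandas as pd

    if path is None:
        from importlib.resources import files

        path = files("banditea.data") / "table1_cluster_models.csv"
        df = pd.read_csv(path.open())  # type: ignore[union-attr]
    else:
        df = pd.read_csv(path)
    required = {"mean_eV", "sd_eV"}
    if not required.issubset(df.columns):
        raise ValueError(f"cluster-model CSV needs columns {sorted(required)}")
    if "cluster_id" in df.columns:
        df = df.sort_values("cluster_id")
    return [ClusterModel(float(r.mean_eV), float(r.sd_eV)) for r in df.itertuples()]


def save_cluster_models(models: Sequence[ClusterModel], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "cluster_id": np.arange(1, len(models) + 1),
            "mean_eV": [m.mean for m in models],
            "sd_eV": [m.sd for m in models],
        }
    ).to_csv(path, index=False)


@dataclass(frozen=True)
class TrialConfig:
    """Batch/trial bookkeeping for surrogate simulations.

    ``batch_size`` selections per batch, each representing an EA run of
    ``iters_per_run`` iterations; at most ``max_batches`` batches per trial;
    ``e_min`` is the success threshold in eV and ``n_trials`` the number of
    trials per parameter combination.
    """

    batch_size: int = 5
    iters_per_run: int = 50
    max_batches: int = 20
    e_min: float = DEFAULT_E_MIN
    n_trials: int = 100

    def __post_init__(self) -> None:
        for name in ("batch_size", "iters_per_run", "max_batches", "n_trials"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not math.isfinite(self.e_min):
            raise ValueError("e_min must be finite")

    @property
    def max_iterations(self) -> int:
        return self.batch_size * self.iters_per_run * self.max_batches


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one surrogate trial."""

    success_iteration: int | None
    batches_run: int


@dataclass
class SuccessCurve:
    """Fraction of trials succeeded by each iteration 1..max_iter (step function)."""

    values: np.ndarray
    max_iter: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.max_iter:
            raise ValueError("curve length must equal max_iter")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("curve values must lie in [0, 1]")
        if np.any(np.diff(self.values) < 0):
            raise ValueError("curve must be non-decreasing")

    def at(self, iteration: int) -> float:
        if iteration < 1:
            return 0.0
        return float(self.values[min(iteration, self.max_iter) - 1])


def draw_run_minimum(model: ClusterModel, rng: np.random.Generator) -> float:
    """One Gaussian draw: the minimum energy of one simulated EA run (eV)."""
    return float(rng.normal(model.mean, model.sd))


def run_trial(
    models: Sequence[ClusterModel],
    params: LearningParams,
    cfg: TrialConfig,
    rng: np.random.Generator,
) -> TrialResult:
    """Simulate one surrogate EA trial with a fresh agent.

    Per batch: select ``batch_size`` clusters with replacement, draw one
    run-minimum per selection in order; the first draw strictly below
    ``e_min`` ends the trial as a success, credited at the end of the run in
    which it occurred.  Otherwise the agent is updated with the batch's
    draws and the next batch begins.
    """
    if not models:
        raise ValueError("need at least one cluster model")
    agent = init_agent(len(models))
    iters_per_batch = cfg.batch_size * cfg.iters_per_run
    for batch in range(cfg.max_batches):
        ids = select(agent, cfg.batch_size, rng)
        results: list[tuple[int, float]] = []
        for j, cid in enumerate(ids, start=1):
            energy = draw_run_minimum(models[cid], rng)
            if energy < cfg.e_min:
                return TrialResult(
                    success_iteration=batch * iters_per_batch + j * cfg.iters_per_run,
                    batches_run=batch + 1,
                )
            results.append((cid, energy))
        update(agent, results, params)
    return TrialResult(success_iteration=None, batches_run=cfg.max_batches)


def _child_rng(seed: int | np.random.SeedSequence, key: tuple[int, ...]) -> np.random.Generator:
    if isinstance(seed, np.random.SeedSequence):
        entropy = seed.entropy
    else:
        entropy = seed
    return np.random.default_rng(np.random.SeedSequence(entropy, spawn_key=key))


def run_trials(
    models: Sequence[ClusterModel],
    params: LearningParams,
    cfg: TrialConfig,
    seed: int,
    key: tuple[int, ...] = (),
) -> list[TrialResult]:
    """Run ``cfg.n_trials`` independent trials on per-trial RNG substreams."""
    return [
        run_trial(models, params, cfg, _child_rng(seed, key + (t,)))
        for t in range(cfg.n_trials)
    ]


def cumulative_success_curve(
    results: Sequence[TrialResult], max_iter: int
) -> SuccessCurve:
    """Step function: at iteration x, the fraction of trials with
    ``success_iteration <= x``."""
    if not results:
        raise ValueError("need at least one trial result")
    counts = np.zeros(max_iter + 1)
    for r in results:
        if r.success_iteration is not None and r.success_iteration <= max_iter:
            counts[r.success_iteration] += 1
    values = np.cumsum(counts)[1:] / len(results)
    return SuccessCurve(values=values, max_iter=max_iter)


def success_area(curve: SuccessCurve) -> float:
    """Area under the cumulative success curve.

    Computed as the per-iteration step sum over [0, max_iter], so a curve
    identically 1 over 5000 iterations has the maximal area 5000.  Absolute
    areas depend on ``e_min``; only orderings between parameter combinations
    are meaningful.
    """
    return float(curve.values.sum())


def evaluate_combo(
    models: Sequence[ClusterModel],
    params: LearningParams,
    cfg: TrialConfig,
    seed: int,
    key: tuple[int, ...] = (),
) -> float:
    """Mean-performance score of one parameter combination: the success area
    over ``cfg.n_trials`` independent trials.  Deterministic for a fixed seed."""
    results = run_trials(models, params, cfg, seed, key)
    curve = cumulative_success_curve(results, cfg.max_iterations)
    return success_area(curve)


def default_grid_ranges(stride: int = 1) -> tuple[range, range, range, range]:
    """The full tuning grid: a in [0,80), b in [0,40), c in [0,20), d in [0,90).

    Half-open tops: the full stride-1 grid enumerates 80*40*20*90 = 5,760,000
    integer combinations.
    """
    return (range(0, 80, stride), range(0, 40, stride),
            range(0, 20, stride), range(0, 90, stride))


def grid_search(
    models: Sequence[ClusterModel],
    ranges: Sequence[Iterable[float]],
    cfg: TrialConfig,
    seed: int,
    workers: int = 1,
) -> list[tuple[LearningParams, float]]:
    """Evaluate every (a, b, c, d) combination and rank by success area.

    ``ranges`` is a 4-tuple of value iterables for a, b, c, d.  Combo i is
    evaluated on RNG substreams spawned from ``(seed, i, trial)``, so the
    ranking is reproducible and independent of ``workers``.  Returns
    ``(params, area)`` pairs sorted by area descending (ties keep grid
    order).
    """
    ranges = [list(r) for r in ranges]
    if len(ranges) != 4 or any(len(r) == 0 for r in ranges):
        raise ValueError("need non-empty value ranges for all four parameters")
    combos = [LearningParams(*vals) for vals in product(*ranges)]

    def score(i: int, p: LearningParams) -> float:
        return evaluate_combo(models, p, cfg, seed, key=(i,))

    if workers > 1:
        from joblib import Parallel, delayed

        areas = Parallel(n_jobs=workers)(
            delayed(score)(i, p) for i, p in enumerate(combos)
        )
    else:
        areas = [score(i, p) for i, p in enumerate(combos)]
    order = sorted(range(len(combos)), key=lambda i: (-areas[i], i))
    return [(combos[i], float(areas[i])) for i in order]
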