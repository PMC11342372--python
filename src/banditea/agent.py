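"""The reinforcement-learning cluster-selection agent.

Clusters are the arms of a multi-armed bandit.  Each cluster carries a
positive selection weight (initially 100); clusters are sampled with
probability proportional to weight, with replacement.  After a batch of
evolutionary-algorithm runs reports one run-minimum energy per selection,
weights are updated by four rules parameterised by (A, B, C, D):

1. +A if the selection produced an energy strictly below the best seen
   anywhere before the batch *and* that energy is the batch minimum
   (reward for the most favourable structure overall);
2. +B if it produced an energy strictly below its own cluster's previous
   best (reward for in-cluster progress; stacks with rule 1);
3. -C if rule 2 did not fire (penalty for stagnation);
4. -(selections[c] / total_selections) * D always (overselection penalty:
   the more often a cluster has been chosen, the harsher the penalty).

Weights are clamped at a floor (default 1) so no cluster's probability ever
reaches zero.  Rules compare against the bests recorded *at batch start*;
the bests are committed only after all rules are applied, so the update is
order-independent within a batch.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "LearningParams",
    "AgentState",
    "init_agent",
    "selection_probabilities",
    "select",
    "update",
]

DEFAULT_INITIAL_WEIGHT = 100.0
DEFAULT_WEIGHT_FLOOR = 1.0


@dataclass(frozen=True)
class LearningParams:
    """The four weight-update parameters (all non-negative).

    a rewards the best-overall output, b the best-in-own-cluster output,
    c penalises a selection with no in-cluster improvement, d scales the
    overselection penalty.  The tuned optimum for a 9-cluster system with
    initial weights 100 is (79, 3, 19, 68).
    """

    a: float = 79.0
    b: float = 3.0
    c: float = 19.0
    d: float = 68.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise ValueError(f"learning parameter {name} must be >= 0")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class AgentState:
    """Per-cluster weights, selection counts, and best energies seen."""

    weights: np.ndarray
    selections: np.ndarray
    total_selections: int
    best_per_cluster: np.ndarray
    best_overall: float
    weight_floor: float = DEFAULT_WEIGHT_FLOOR

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.selections = np.asarray(self.selections, dtype=int)
        self.best_per_cluster = np.asarray(self.best_per_cluster, dtype=float)

    @property
    def n_clusters(self) -> int:
        return self.weights.size

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "weights": self.weights.tolist(),
                "selections": self.selections.tolist(),
                "total_selections": self.total_selections,
                "best_per_cluster": [
                    None if math.isinf(v) else v for v in self.best_per_cluster
                ],
                "best_overall": None if math.isinf(self.best_overall) else self.best_overall,
                "weight_floor": self.weight_floor,
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, payload: str) -> "AgentState":
        d = json.loads(payload)
        return cls(
            weights=np.array(d["weights"]),
            selections=np.array(d["selections"]),
            total_selections=int(d["total_selections"]),
            best_per_cluster=np.array(
                [math.inf if v is None else v for v in d["best_per_cluster"]]
            ),
            best_overall=math.inf if d["best_overall"] is None else d["best_overall"],
            weight_floor=float(d.get("weight_floor", DEFAULT_WEIGHT_FLOOR)),
        )


def init_agent(
    n_clusters: int,
    initial_weight: float = DEFAULT_INITIAL_WEIGHT,
    weight_floor: float = DEFAULT_WEIGHT_FLOOR,
) -> AgentState:
    """Fresh agent: uniform weights, zero counts, infinite bests."""
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    if initial_weight < weight_floor:
        raise ValueError("initial_weight must be >= weight_floor")
    return AgentState(
        weights=np.full(n_clusters, float(initial_weight)),
        selections=np.zeros(n_clusters, dtype=int),
        total_selections=0,
        best_per_cluster=np.full(n_clusters, math.inf),
        best_overall=math.inf,
        weight_floor=weight_floor,
    )


def selection_probabilities(state: AgentState) -> np.ndarray:
    """Weights normalised to a probability vector."""
    total = float(state.weights.sum())
    if state.n_clusters < 1:
        raise ValueError("agent has no clusters")
    if np.any(state.weights < 0) or total <= 0:
        raise ValueError("weights must be non-negative with a positive sum")
    return state.weights / total


def select(state: AgentState, k: int, rng: np.random.Generator) -> list[int]:
    """Draw ``k`` cluster ids with replacement, updating selection counts."""
    if k < 1:
        raise ValueError("k must be >= 1")
    probs = selection_probabilities(state)
    ids = rng.choice(state.n_clusters, size=k, replace=True, p=probs)
    for cid in ids:
        state.selections[cid] += 1
    state.total_selections += k
    return [int(c) for c in ids]


def update(
    state: AgentState,
    results: Sequence[tuple[int, float]],
    params: LearningParams,
) -> AgentState:
    """Apply the four-rule weight update for one batch of results.

    ``results`` holds one ``(cluster_id, run_minimum_energy)`` entry per
    selection in the batch.  Mutates and returns ``state``.  An empty batch
    is a no-op.
    """
    if not results:
        return state
    if state.total_selections < 1:
        raise ValueError("update requires selections to have been recorded first")
    for cid, _ in results:
        if not (0 <= cid < state.n_clusters):
            raise ValueError(f"cluster id {cid} out of range")
    start_overall = state.best_overall
    start_cluster = state.best_per_cluster.copy()
    batch_min = min(energy for _, energy in results)
    for cid, energy in results:
        w = float(state.weights[cid])
        improved_cluster = energy < start_cluster[cid]
        if energy < start_overall and energy == batch_min:
            w += params.a
        if improved_cluster:
            w += params.b
        else:
            w -= params.c
        w -= (state.selections[cid] / state.total_selections) * params.d
        state.weights[cid] = max(w, state.weight_floor)
    for cid, energy in results:
        if energy < state.best_per_cluster[cid]:
            state.best_per_cluster[cid] = energy
        if energy < state.best_overall:
            state.best_overall = energy
    return state
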