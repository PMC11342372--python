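"""Cut-and-splice evolutionary algorithm with bandit-guided cluster selection.

Parents are drawn from a population with probability proportional to
``F_i * U_i``: a fitness ``F = (1/2) * (1 - tanh(2 rho - 1))`` with
``rho = (E - E_lo) / (E_hi - E_lo)`` mapping the population's energy span to
(0, 1) (lower energy -> higher fitness), and a uniqueness factor
``U = 1 / sqrt(1 + n_i) * 1 / sqrt(1 + m_i)`` that decays with the number of
pairings ``n_i`` a member has participated in and the number of structural
lookalikes ``m_i`` it has accumulated.

Crossover cuts both parents with a randomly oriented plane through their
(common) centre of mass, splices one side of each, and repairs the
stoichiometry: element surplus is removed farthest-from-plane first, deficit
is refilled with random unused parent atoms.  A child violating the
minimum-separation rule is rejected and the splice retried with a new plane.

Two drivers are provided: a clustered EA in which the bandit agent allocates
fixed-length EA runs across per-cluster parent populations that are re-curated
between selections with an energy-spacing rule (three curation methods), and
an unclustered baseline with one growing population.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .agent import AgentState, LearningParams, init_agent, select, update
from .fingerprints import (
    Fingerprint,
    FingerprintConfig,
    MissingElementError,
    baseline_fingerprint,
    combine_distances,
    cosine_distance,
    fingerprint,
)
from .structures import (
    COVALENT_RADII,
    BuildError,
    CalculatorError,
    Structure,
    build_structure,
    stoichiometry_of,
)

__all__ = [
    "CrossoverError",
    "EaConfig",
    "CurationConfig",
    "Member",
    "Population",
    "fitness",
    "uniqueness",
    "select_parents",
    "cut_and_splice",
    "ea_run",
    "energy_spacing_filter",
    "curate_parents",
    "clustered_ea",
    "unclustered_ea",
    "random_search",
    "RunRecord",
]


class CrossoverError(RuntimeError):
    """Cut-and-splice failed to produce a clash-free child within the retry budget."""


@dataclass(frozen=True)
class EaConfig:
    """Knobs of the EA inner loop.

    ``iterations`` per EA run and ``selections`` (cluster selections per
    clustered run) multiply to the total iteration budget, 5000 at the
    defaults.  Offspring must keep every atom pair at least ``min_sep_frac``
    of the covalent-radius sum apart.  Relaxation stops after
    ``relax_max_steps`` steps or when the largest force drops below
    ``relax_force_tol`` (eV/Angstrom).  An offspring closer than
    ``similarity_threshold`` (combined fingerprint distance) to an existing
    member counts as that member's lookalike instead of entering the
    population.
    """

    iterations: int = 50
    selections: int = 100
    min_sep_frac: float = 0.70
    relax_max_steps: int = 100
    relax_force_tol: float = 0.05
    crossover_max_retries: int = 50
    similarity_threshold: float = 0.005
    fingerprint: FingerprintConfig = field(default_factory=FingerprintConfig)

    def __post_init__(self) -> None:
        for name in ("iterations", "selections", "relax_max_steps", "crossover_max_retries"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.min_sep_frac < 1):
            raise ValueError("min_sep_frac must lie in (0, 1)")


@dataclass(frozen=True)
class CurationConfig:
    """Parent-curation settings: method 1, 2 or 3; energy spacing ``delta_e``
    in eV; target parent-population size."""

    method: int = 1
    delta_e: float = 0.3
    target_size: int = 20

    def __post_init__(self) -> None:
        if self.method not in (1, 2, 3):
            raise ValueError("curation method must be 1, 2 or 3")
        if self.delta_e <= 0:
            raise ValueError("delta_e must be > 0")
        if self.target_size < 2:
            raise ValueError("target_size must be >= 2")


# ---------------------------------------------------------------------------
# Population, fitness, uniqueness, parent selection
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class Member:
    structure: Structure
    n_pairings: int = 0
    n_lookalikes: int = 0
    _fps: list[Fingerprint] | None = None

    @property
    def energy(self) -> float:
        if self.structure.energy is None:
            raise ValueError("population member has no energy")
        return self.structure.energy


def _member_fps(m: Member, cfg: FingerprintConfig) -> list[Fingerprint]:
    if m._fps is None:
        m._fps = _fps_with_fallback(m.structure, cfg)
    return m._fps


def _fps_with_fallback(s: Structure, cfg: FingerprintConfig) -> list[Fingerprint]:
    fps = []
    for pair in cfg.pairs:
        try:
            fps.append(fingerprint(s, pair, cfg))
        except MissingElementError:
            fps.append(baseline_fingerprint(pair, cfg))
    return fps


def _fps_distance(a: list[Fingerprint], b: list[Fingerprint], cfg: FingerprintConfig) -> float:
    return combine_distances(
        [cosine_distance(x, y, half_complement=cfg.half_complement) for x, y in zip(a, b)]
    )


@dataclass
class Population:
    """Energy-sorted pool of members with pairing/lookalike bookkeeping."""

    members: list[Member]
    capacity: int | None = None

    def __post_init__(self) -> None:
        for m in self.members:
            _ = m.energy  # force the energies-set invariant
        self.sort()
        if self.capacity is not None and len(self.members) > self.capacity:
            raise ValueError("population exceeds capacity")

    @classmethod
    def from_structures(
        cls, structures: Sequence[Structure], capacity: int | None = None
    ) -> "Population":
        return cls([Member(s) for s in structures], capacity=capacity)

    def sort(self) -> None:
        self.members.sort(key=lambda m: m.energy)

    def energies(self) -> np.ndarray:
        return np.array([m.energy for m in self.members])

    @property
    def best(self) -> Member:
        return self.members[0]

    @property
    def weakest(self) -> Member:
        return self.members[-1]

    def __len__(self) -> int:
        return len(self.members)


def fitness(energy: float, e_lo: float, e_hi: float) -> float:
    """Half-tanh fitness: F = (1/2) * (1 - tanh(2 rho - 1)).

    ``rho`` linearly maps [e_lo, e_hi] (population min/max energy) onto
    [0, 1]; F is strictly decreasing in energy.  A degenerate population
    (e_hi == e_lo) gets F = 0.5 for every member.
    """
    if e_hi < e_lo:
        raise ValueError("e_hi must be >= e_lo")
    if e_hi == e_lo:
        return 0.5
    rho = (energy - e_lo) / (e_hi - e_lo)
    return 0.5 * (1.0 - math.tanh(2.0 * rho - 1.0))


def uniqueness(n_pairings: int, n_lookalikes: int) -> float:
    """U = 1/sqrt(1 + n) * 1/sqrt(1 + m); equals 1 for a fresh member and
    tends to 0 as either count grows."""
    if n_pairings < 0 or n_lookalikes < 0:
        raise ValueError("counts must be non-negative")
    return 1.0 / math.sqrt(1.0 + n_pairings) / math.sqrt(1.0 + n_lookalikes)


def _selection_weights(pop: Population) -> np.ndarray:
    e = pop.energies()
    e_lo, e_hi = float(e.min()), float(e.max())
    return np.array(
        [
            fitness(m.energy, e_lo, e_hi) * uniqueness(m.n_pairings, m.n_lookalikes)
            for m in pop.members
        ]
    )


def select_parents(pop: Population, rng: np.random.Generator) -> tuple[Member, Member]:
    """Draw two distinct members with probability proportional to F_i * U_i;
    increments each parent's pairing count."""
    if len(pop) < 2:
        raise ValueError("parent selection requires at least 2 members")
    w = _selection_weights(pop)
    total = w.sum()
    if total <= 0:
        raise ValueError("all selection weights vanished")
    p = w / total
    first = int(rng.choice(len(pop), p=p))
    w2 = w.copy()
    w2[first] = 0.0
    total2 = w2.sum()
    if total2 <= 0:
        # every other member has zero weight; fall back to uniform over the rest
        w2 = np.ones_like(w2)
        w2[first] = 0.0
        total2 = w2.sum()
    second = int(rng.choice(len(pop), p=w2 / total2))
    m1, m2 = pop.members[first], pop.members[second]
    m1.n_pairings += 1
    m2.n_pairings += 1
    return m1, m2


# ---------------------------------------------------------------------------
# Cut-and-splice crossover
# ---------------------------------------------------------------------------


def _min_separation_ok(symbols: Sequence[str], coords: np.ndarray, frac: float) -> bool:
    n = len(symbols)
    radii = np.array([COVALENT_RADII[s] for s in symbols])
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    limits = frac * (radii[:, None] + radii[None, :])
    iu = np.triu_indices(n, k=1)
    return bool(np.all(d[iu] >= limits[iu]))


def cut_and_splice(
    p1: Structure,
    p2: Structure,
    target: dict[str, int] | None = None,
    min_sep_frac: float = 0.70,
    rng: np.random.Generator | None = None,
    max_retries: int = 50,
) -> Structure:
    """Create a child by splicing the parents across a random plane.

    Both parents are translated so their centres of mass coincide at the
    origin; a random plane through the origin keeps p1's atoms on its
    positive side and p2's atoms on its negative side.  Element surplus
    relative to ``target`` (default: p1's stoichiometry) is removed
    farthest-from-plane first; deficit is refilled by randomly drawn unused
    parent atoms of that element.  A child with any atom pair closer than
    ``min_sep_frac`` of the covalent-radius sum is rejected and the splice
    retried with a fresh plane; :class:`CrossoverError` after ``max_retries``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if max_retries < 1:
        raise ValueError("max_retries must be >= 1")
    if target is None:
        target = p1.stoichiometry()
    for parent in (p1, p2):
        if parent.stoichiometry() != dict(target):
            raise ValueError("both parents must have the target stoichiometry")
    c1 = p1.coords - p1.coords.mean(axis=0)
    c2 = p2.coords - p2.coords.mean(axis=0)
    for _ in range(max_retries):
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        side1 = c1 @ normal  # signed plane distances
        side2 = c2 @ normal
        symbols: list[str] = []
        coords: list[np.ndarray] = []
        plane_dist: list[float] = []
        unused: dict[str, list[np.ndarray]] = {el: [] for el in target}
        for sym, xyz, sd in zip(p1.symbols, c1, side1):
            if sd >= 0:
                symbols.append(sym)
                coords.append(xyz)
                plane_dist.append(abs(sd))
            else:
                unused[sym].append(xyz)
        for sym, xyz, sd in zip(p2.symbols, c2, side2):
            if sd < 0:
                symbols.append(sym)
                coords.append(xyz)
                plane_dist.append(abs(sd))
            else:
                unused[sym].append(xyz)
        # Stoichiometry repair.
        for el, want in target.items():
            have = [i for i, s in enumerate(symbols) if s == el]
            if len(have) > want:
                # drop the surplus atoms farthest from the dividing plane
                have.sort(key=lambda i: plane_dist[i], reverse=True)
                drop = set(have[: len(have) - want])
                symbols = [s for i, s in enumerate(symbols) if i not in drop]
                coords = [c for i, c in enumerate(coords) if i not in drop]
                plane_dist = [d for i, d in enumerate(plane_dist) if i not in drop]
            elif len(have) < want:
                pool = unused[el]
                take = rng.permutation(len(pool))[: want - len(have)]
                for i in take:
                    symbols.append(el)
                    coords.append(pool[int(i)])
                    plane_dist.append(0.0)
        arr = np.array(coords)
        if stoichiometry_of(symbols) != dict(target):
            continue  # pathological split; retry
        if _min_separation_ok(symbols, arr, min_sep_frac):
            return Structure(tuple(symbols), arr)
    raise CrossoverError(f"no clash-free child within {max_retries} splices")


# ---------------------------------------------------------------------------
# EA inner loop
# ---------------------------------------------------------------------------


def ea_run(
    pop: Population,
    calc,
    n_iter: int,
    cfg: EaConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Population, list[Structure]]:
    """Run ``n_iter`` swap-only EA iterations on a fixed-size population.

    Each iteration selects two parents, splices, relaxes the child, and
    replaces the weakest member iff the child is strictly more favourable.
    Children structurally indistinguishable from an existing member (combined
    fingerprint distance below the similarity threshold) are rejected and
    counted as that member's lookalike.  Failed splices and calculator
    failures consume the iteration.  Returns the final population and the
    log of every relaxed offspring.
    """
    if cfg is None:
        cfg = EaConfig()
    if rng is None:
        rng = np.random.default_rng()
    if len(pop) < 2:
        raise ValueError("ea_run needs at least 2 members")
    offspring_log: list[Structure] = []
    target = pop.members[0].structure.stoichiometry()
    for _ in range(n_iter):
        m1, m2 = select_parents(pop, rng)
        try:
            child = cut_and_splice(
                m1.structure,
                m2.structure,
                target,
                min_sep_frac=cfg.min_sep_frac,
                rng=rng,
                max_retries=cfg.crossover_max_retries,
            )
        except CrossoverError:
            continue
        try:
            child = calc.relax(child, cfg.relax_max_steps, cfg.relax_force_tol)
        except CalculatorError:
            continue
        offspring_log.append(child)
        child_fps = _fps_with_fallback(child, cfg.fingerprint)
        lookalike = None
        for m in pop.members:
            if (
                _fps_distance(child_fps, _member_fps(m, cfg.fingerprint), cfg.fingerprint)
                < cfg.similarity_threshold
            ):
                lookalike = m
                break
        if lookalike is not None:
            lookalike.n_lookalikes += 1
            continue
        weakest = pop.weakest
        if child.energy < weakest.energy:
            pop.members[-1] = Member(child, _fps=child_fps)
            pop.sort()
    return pop, offspring_log


# ---------------------------------------------------------------------------
# Parent curation
# ---------------------------------------------------------------------------


def energy_spacing_filter(
    energies: Sequence[float], method: int, delta_e: float
) -> list[int]:
    """Indices (into the ascending-sorted ``energies``) kept by the
    energy-spacing rule, before any padding or truncation.

    Method 1 keeps an entry iff no *other* entry lies within +/- delta_e of
    it; methods 2 and 3 keep the running-lowest entry whose energy exceeds
    the last kept energy by more than delta_e.
    """
    if method not in (1, 2, 3):
        raise ValueError("method must be 1, 2 or 3")
    e = np.asarray(energies, dtype=float)
    if np.any(np.diff(e) < 0):
        raise ValueError("energies must be sorted ascending")
    kept: list[int] = []
    if method == 1:
        for i, val in enumerate(e):
            neighbours = np.abs(e - val) <= delta_e
            neighbours[i] = False
            if not neighbours.any():
                kept.append(i)
    else:
        last: float | None = None
        for i, val in enumerate(e):
            if last is None or val - last > delta_e:
                kept.append(i)
                last = float(val)
    return kept


def curate_parents(
    prev_parents: Sequence[Structure],
    offspring_pool: Sequence[Structure],
    cfg: CurationConfig,
) -> list[Structure]:
    """Form the next parent population under the energy-spacing rule.

    The candidate pool is ``offspring_pool`` together with ``prev_parents``
    (for methods 1/2 the caller passes the previous run's offspring; for
    method 3, every offspring the cluster has ever produced).  Candidates are
    scanned in ascending energy:

    * method 1 keeps a molecule iff **no other** pool molecule lies within
      +/- delta_e of its energy;
    * methods 2/3 keep the running-lowest molecule whose energy exceeds the
      last kept energy by more than delta_e.

    If fewer than ``target_size`` survive, the lowest-energy excluded
    candidates pad the list; the result is truncated to ``target_size``.
    """
    pool = [s for s in list(offspring_pool) + list(prev_parents)]
    if not pool:
        raise ValueError("curation pool is empty")
    for s in pool:
        if s.energy is None:
            raise ValueError("curation pool contains a structure without energy")
    pool.sort(key=lambda s: s.energy)
    energies = [s.energy for s in pool]
    kept_idx = energy_spacing_filter(energies, cfg.method, cfg.delta_e)
    kept = [pool[i] for i in kept_idx]
    if len(kept) < cfg.target_size:
        excluded = [pool[i] for i in range(len(pool)) if i not in set(kept_idx)]
        pad = excluded[: cfg.target_size - len(kept)]
        kept = sorted(kept + pad, key=lambda s: s.energy)
    return kept[: cfg.target_size]


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------


@dataclass
class RunRecord:
    """Log of one driver run."""

    kind: str
    entries: list[dict]
    best_energy: float
    best_structure: Structure | None
    total_iterations: int
    success_iteration: int | None = None

    def running_minimum(self) -> list[float]:
        out: list[float] = []
        cur = math.inf
        for e in self.entries:
            val = e.get("run_min", e.get("offspring_energy"))
            if val is not None:
                cur = min(cur, val)
            out.append(cur)
        return out


def _ensure_energies(structures: Sequence[Structure], calc, cfg: EaConfig) -> list[Structure]:
    out = []
    for s in structures:
        if s.energy is None:
            out.append(calc.relax(s, cfg.relax_max_steps, cfg.relax_force_tol))
        else:
            out.append(s)
    return out


def clustered_ea(
    clusters: Sequence[Sequence[Structure]],
    params: LearningParams,
    curation: CurationConfig,
    calc,
    cfg: EaConfig | None = None,
    rng: np.random.Generator | None = None,
    success_energy: float | None = None,
) -> RunRecord:
    """Bandit-guided clustered EA driver.

    Initialises each cluster's parent population with ``target_size``
    randomly drawn (and, if needed, relaxed) members, then performs up to
    ``cfg.selections`` cluster selections.  Each selection runs
    ``cfg.iterations`` EA iterations on the chosen cluster's curated parents,
    feeds the run-minimum energy back to the agent, and re-curates that
    cluster's parents.  Stops early once a structure beats
    ``success_energy``.
    """
    if cfg is None:
        cfg = EaConfig()
    if rng is None:
        rng = np.random.default_rng()
    n_clusters = len(clusters)
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    tsize = curation.target_size
    parents: list[list[Structure]] = []
    for ci, members in enumerate(clusters):
        if len(members) < tsize:
            raise ValueError(f"cluster {ci} has {len(members)} < {tsize} members")
        pick = rng.choice(len(members), size=tsize, replace=False)
        parents.append(_ensure_energies([members[int(i)] for i in pick], calc, cfg))
    all_offspring: list[list[Structure]] = [[] for _ in range(n_clusters)]
    agent = init_agent(n_clusters)
    best_energy = math.inf
    best_structure: Structure | None = None
    for group in parents:
        for s in group:
            if s.energy < best_energy:
                best_energy, best_structure = s.energy, s
    entries: list[dict] = []
    success_iteration = None
    total_iterations = 0
    for sel in range(cfg.selections):
        cid = select(agent, 1, rng)[0]
        pop = Population.from_structures(parents[cid], capacity=tsize)
        pop, offspring = ea_run(pop, calc, cfg.iterations, cfg, rng)
        total_iterations += cfg.iterations
        run_min = min((s.energy for s in offspring), default=math.inf)
        update(agent, [(cid, run_min)], params)
        for s in offspring:
            if s.energy < best_energy:
                best_energy, best_structure = s.energy, s
        pool = offspring if curation.method in (1, 2) else all_offspring[cid] + offspring
        all_offspring[cid].extend(offspring)
        parents[cid] = curate_parents(parents[cid], pool, curation)
        entries.append(
            {
                "selection": sel,
                "cluster": cid,
                "run_min": None if math.isinf(run_min) else run_min,
                "best_so_far": best_energy,
                "weights": agent.weights.tolist(),
            }
        )
        if success_energy is not None and best_energy < success_energy:
            success_iteration = total_iterations
            break
    return RunRecord(
        kind="clustered",
        entries=entries,
        best_energy=best_energy,
        best_structure=best_structure,
        total_iterations=total_iterations,
        success_iteration=success_iteration,
    )


def unclustered_ea(
    library: Sequence[Structure],
    calc,
    n_iter: int,
    rng: np.random.Generator | None = None,
    cfg: EaConfig | None = None,
) -> RunRecord:
    """Baseline EA: one growing population seeded with the whole library.

    Every relaxed offspring is appended to the population (no replacement),
    and parent selection uses the same fitness/uniqueness weighting.
    """
    if cfg is None:
        cfg = EaConfig()
    if rng is None:
        rng = np.random.default_rng()
    if not library:
        raise ValueError("library must be non-empty")
    structures = _ensure_energies(library, calc, cfg)
    pop = Population.from_structures(structures, capacity=None)
    best_energy = pop.best.energy
    best_structure = pop.best.structure
    target = structures[0].stoichiometry()
    entries: list[dict] = []
    for it in range(n_iter):
        m1, m2 = select_parents(pop, rng)
        entry: dict = {"iteration": it, "offspring_energy": None}
        try:
            child = cut_and_splice(
                m1.structure, m2.structure, target,
                min_sep_frac=cfg.min_sep_frac, rng=rng,
                max_retries=cfg.crossover_max_retries,
            )
            child = calc.relax(child, cfg.relax_max_steps, cfg.relax_force_tol)
            pop.members.append(Member(child))
            pop.sort()
            entry["offspring_energy"] = child.energy
            if child.energy < best_energy:
                best_energy, best_structure = child.energy, child
        except (CrossoverError, CalculatorError):
            pass
        entry["running_min"] = best_energy
        entries.append(entry)
    return RunRecord(
        kind="unclustered",
        entries=entries,
        best_energy=best_energy,
        best_structure=best_structure,
        total_iterations=n_iter,
    )


def random_search(
    stoichiometry: dict[str, int],
    calc,
    n_evals: int,
    rng: np.random.Generator | None = None,
    cfg: EaConfig | None = None,
    hyb_weights=None,
) -> RunRecord:
    """Iteration-matched baseline: relax ``n_evals`` fresh random builds and
    keep the best."""
    if cfg is None:
        cfg = EaConfig()
    if rng is None:
        rng = np.random.default_rng()
    best_energy = math.inf
    best_structure: Structure | None = None
    entries: list[dict] = []
    for it in range(n_evals):
        try:
            s = build_structure(stoichiometry, hyb_weights=hyb_weights, rng=rng)
            s = calc.relax(s, cfg.relax_max_steps, cfg.relax_force_tol)
        except (BuildError, CalculatorError):
            entries.append({"iteration": it, "offspring_energy": None,
                            "running_min": best_energy})
            continue
        if s.energy < best_energy:
            best_energy, best_structure = s.energy, s
        entries.append({"iteration": it, "offspring_energy": s.energy,
                        "running_min": best_energy})
    return RunRecord(
        kind="random",
        entries=entries,
        best_energy=best_energy,
        best_structure=best_structure,
        total_iterations=n_evals,
    )
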