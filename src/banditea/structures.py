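"""Molecular structures, multi-frame XYZ I/O, a random atom-by-atom builder,
and a toy pairwise energy calculator.

The unit of currency throughout the package is a :class:`Structure`: an
ordered list of element symbols plus Cartesian coordinates in Angstrom, with
an optional total energy in eV.  Structures are built atom-by-atom: each new
atom is attached to an open bonding slot of an already-placed atom at a
distance equal to the sum of the two covalent radii, with the slot geometry
dictated by an assigned hybridization (sp linear, sp2 trigonal planar, sp3
tetrahedral; hydrogen is terminal).  A build is rejected and restarted
whenever any two atoms come closer than 70% of the sum of their covalent
radii.

Energetics are provided by :class:`ToyCalculator`, a deterministic all-pairs
Morse potential.  It stands behind the same ``evaluate``/``relax`` contract a
quantum calculator would, so the evolutionary-algorithm drivers are agnostic
to the energy backend.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "COVALENT_RADII",
    "Structure",
    "StructureError",
    "XYZParseError",
    "BuildError",
    "CalculatorError",
    "stoichiometry_of",
    "parse_formula",
    "read_xyz",
    "write_xyz",
    "min_pair_separation",
    "build_structure",
    "toy_energy",
    "toy_forces",
    "ToyCalculator",
]

# Single-bond covalent radii in Angstrom (Cordero-style values, frozen here).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "B": 0.84,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "Si": 1.11,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
}

#: Fraction of the covalent-radius sum below which two atoms clash.
CLASH_FRACTION = 0.70


class StructureError(ValueError):
    """Invalid structure contents (unknown element, bad coordinates, ...)."""


class XYZParseError(ValueError):
    """Malformed multi-frame XYZ input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class BuildError(RuntimeError):
    """Atom-by-atom builder exhausted its restart budget."""


class CalculatorError(RuntimeError):
    """Energy or force evaluation failed for a candidate structure."""


@dataclass(eq=False)
class Structure:
    """One molecule: element symbols, coordinates (Angstrom), optional energy (eV).

    Identity semantics (no value equality): coordinates are arrays and
    structures are routinely near-duplicates; compare geometries explicitly
    via fingerprints or coordinates instead.
    """

    symbols: tuple[str, ...]
    coords: np.ndarray
    energy: float | None = None

    def __post_init__(self) -> None:
        self.symbols = tuple(str(s) for s in self.symbols)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.symbols) != self.coords.shape[0]:
            raise StructureError(
                f"{len(self.symbols)} symbols but {self.coords.shape[0]} coordinate triples"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        unknown = set(self.symbols) - COVALENT_RADII.keys()
        if unknown:
            raise StructureError(f"elements without covalent radii: {sorted(unknown)}")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def copy(self) -> "Structure":
        return Structure(self.symbols, self.coords.copy(), self.energy)

    def with_energy(self, energy: float) -> "Structure":
        return Structure(self.symbols, self.coords.copy(), float(energy))

    def stoichiometry(self) -> dict[str, int]:
        return stoichiometry_of(self.symbols)


def stoichiometry_of(symbols: Iterable[str]) -> dict[str, int]:
    """Element -> count mapping for an iterable of symbols."""
    counts: dict[str, int] = {}
    for s in symbols:
        counts[s] = counts.get(s, 0) + 1
    return counts


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula such as ``C9H7N`` into a stoichiometry."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise StructureError(f"cannot parse formula {formula!r}")
        pos = m.end()
        if not m.group(1):
            raise StructureError(f"cannot parse formula {formula!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula) or not counts:
        raise StructureError(f"cannot parse formula {formula!r}")
    if sum(counts.values()) <= 0:
        raise StructureError("stoichiometry counts must sum to a positive number")
    return counts


# ---------------------------------------------------------------------------
# Multi-frame XYZ I/O
# ---------------------------------------------------------------------------

_ENERGY_RE = re.compile(r"energy=([-+0-9.eE]+)")


def read_xyz(path: str | Path) -> list[Structure]:
    """Read a multi-frame XYZ file.

    Dialect: line 1 atom count, line 2 free-form comment (an ``energy=<float>``
    token, if present, is parsed into ``Structure.energy``), then one
    ``Symbol x y z`` line per atom.  Frames repeat back-to-back.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Structure] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(f"expected atom count, got {lines[i]!r}", i + 1)
        if n <= 0:
            raise XYZParseError(f"non-positive atom count {n}", i + 1)
        if i + 1 + n >= len(lines) + 1 and i + 1 >= len(lines):
            raise XYZParseError("missing comment line", i + 2)
        if i + 2 + n > len(lines):
            raise XYZParseError(
                f"declared {n} atoms but file ends after {len(lines) - i - 2} atom lines",
                len(lines),
            )
        comment = lines[i + 1]
        energy = None
        m = _ENERGY_RE.search(comment)
        if m:
            energy = float(m.group(1))
        symbols: list[str] = []
        coords: list[list[float]] = []
        for k in range(n):
            ln = i + 2 + k
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZParseError(f"expected 'Symbol x y z', got {lines[ln]!r}", ln + 1)
            symbols.append(parts[0])
            try:
                coords.append([float(p) for p in parts[1:4]])
            except ValueError:
                raise XYZParseError(f"bad coordinate in {lines[ln]!r}", ln + 1)
        try:
            frames.append(Structure(tuple(symbols), np.array(coords), energy))
        except StructureError as exc:
            raise XYZParseError(str(exc), i + 3)
        i += 2 + n
    return frames


def write_xyz(path: str | Path, structures: Sequence[Structure] | Structure) -> None:
    """Write one or more structures as multi-frame XYZ (energy in the comment)."""
    if isinstance(structures, Structure):
        structures = [structures]
    out: list[str] = []
    for s in structures:
        out.append(str(s.n_atoms))
        out.append(f"energy={s.energy:.10f}" if s.energy is not None else "")
        for sym, (x, y, z) in zip(s.symbols, s.coords):
            out.append(f"{sym} {x:.10f} {y:.10f} {z:.10f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _pair_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def min_pair_separation(s: Structure) -> float:
    """Minimum Euclidean distance over all atom pairs (Angstrom)."""
    if s.n_atoms < 2:
        raise StructureError("min_pair_separation requires at least 2 atoms")
    d = _pair_distances(s.coords)
    iu = np.triu_indices(s.n_atoms, k=1)
    return float(d[iu].min())


def clash_free(symbols: Sequence[str], coords: np.ndarray,
               fraction: float = CLASH_FRACTION) -> bool:
    """True iff no atom pair is closer than ``fraction`` x covalent-radius sum."""
    n = len(symbols)
    if n < 2:
        return True
    radii = np.array([COVALENT_RADII[s] for s in symbols])
    limits = fraction * (radii[:, None] + radii[None, :])
    d = _pair_distances(np.asarray(coords, dtype=float))
    iu = np.triu_indices(n, k=1)
    return bool(np.all(d[iu] >= limits[iu]))


# ---------------------------------------------------------------------------
# Atom-by-atom builder
# ---------------------------------------------------------------------------

# Ideal bonding-slot directions per hybridization, in a local frame.  The
# first slot is the one consumed by the bond back to the anchor atom.
_SQ = 1.0 / math.sqrt(3.0)
_HYB_DIRECTIONS: dict[str, np.ndarray] = {
    "sp": np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]]),
    "sp2": np.array(
        [
            [1.0, 0.0, 0.0],
            [-0.5, math.sqrt(3.0) / 2.0, 0.0],
            [-0.5, -math.sqrt(3.0) / 2.0, 0.0],
        ]
    ),
    "sp3": np.array([[_SQ, _SQ, _SQ], [_SQ, -_SQ, -_SQ], [-_SQ, _SQ, -_SQ], [-_SQ, -_SQ, _SQ]]),
}

_DEFAULT_HYB_WEIGHTS = {"sp": 1.0 / 3.0, "sp2": 1.0 / 3.0, "sp3": 1.0 / 3.0}


def _rotation_aligning(direction: np.ndarray, rng: np.random.Generator) -> Rotation:
    """Rotation taking the local +x axis onto ``direction`` with a random roll."""
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(x, direction)
    norm = np.linalg.norm(v)
    dot = float(np.clip(np.dot(x, direction), -1.0, 1.0))
    if norm < 1e-12:
        base = Rotation.identity() if dot > 0 else Rotation.from_rotvec(math.pi * np.array([0.0, 0.0, 1.0]))
    else:
        base = Rotation.from_rotvec(math.acos(dot) * v / norm)
    roll = Rotation.from_rotvec(rng.uniform(0.0, 2.0 * math.pi) * direction)
    return roll * base


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def build_structure(
    stoichiometry: Mapping[str, int],
    hyb_weights: Mapping[str, Mapping[str, float]] | Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
    max_restarts: int = 1000,
    clash_fraction: float = CLASH_FRACTION,
) -> Structure:
    """Build a random structure with the requested stoichiometry atom-by-atom.

    Atoms are placed in random order.  Each non-hydrogen atom gets a
    hybridization drawn from ``hyb_weights`` (per-element mapping, or one
    mapping shared by all heavy elements; default: equal likelihood of
    sp/sp2/sp3), which defines its open bonding slots.  A new atom is attached
    to a randomly chosen open slot at the covalent-radius sum; if it lands
    within ``clash_fraction`` of the covalent-radius sum of any placed atom,
    the whole build restarts.  Raises :class:`BuildError` once ``max_restarts``
    attempts are exhausted.
    """
    if rng is None:
        rng = np.random.default_rng()
    if max_restarts < 1:
        raise ValueError("max_restarts must be >= 1")
    counts = {el: int(n) for el, n in stoichiometry.items() if int(n) > 0}
    if not counts:
        raise StructureError("stoichiometry counts must sum to a positive number")
    unknown = set(counts) - COVALENT_RADII.keys()
    if unknown:
        raise StructureError(f"elements without covalent radii: {sorted(unknown)}")
    pool = [el for el, n in counts.items() for _ in range(n)]

    def weights_for(element: str) -> dict[str, float]:
        if hyb_weights is None:
            return _DEFAULT_HYB_WEIGHTS
        w = hyb_weights.get(element, None) if all(
            isinstance(v, Mapping) for v in hyb_weights.values()
        ) else hyb_weights
        if w is None:
            return _DEFAULT_HYB_WEIGHTS
        total = float(sum(w.values()))
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(f"hybridization weights for {element} sum to {total}, not 1")
        return dict(w)  # type: ignore[arg-type]

    for _ in range(max_restarts):
        order = list(pool)
        rng.shuffle(order)
        symbols: list[str] = []
        coords: list[np.ndarray] = []
        # Open slots: (position of anchor atom, unit direction, anchor radius).
        slots: list[tuple[np.ndarray, np.ndarray, float]] = []
        failed = False
        for sym in order:
            r_new = COVALENT_RADII[sym]
            if not symbols:
                pos = np.zeros(3)
            else:
                if not slots:
                    failed = True
                    break
                k = rng.integers(len(slots))
                anchor_pos, direction, r_anchor = slots.pop(int(k))
                pos = anchor_pos + direction * (r_anchor + r_new)
                # Clash rule: 70% of the covalent-radius sum, against all atoms.
                placed = np.array(coords)
                d = np.linalg.norm(placed - pos, axis=1)
                limits = clash_fraction * (
                    np.array([COVALENT_RADII[s] for s in symbols]) + r_new
                )
                if np.any(d < limits):
                    failed = True
                    break
            symbols.append(sym)
            coords.append(pos)
            if sym != "H":
                w = weights_for(sym)
                kinds = sorted(w)
                probs = np.array([w[k] for k in kinds])
                kind = kinds[int(rng.choice(len(kinds), p=probs / probs.sum()))]
                local = _HYB_DIRECTIONS[kind]
                if len(symbols) == 1:
                    rot = _rotation_aligning(_random_unit_vector(rng), rng)
                    dirs = rot.apply(local)
                else:
                    # First local slot points back along the new bond.
                    rot = _rotation_aligning(-direction, rng)
                    dirs = rot.apply(local)[1:]
                for dvec in dirs:
                    slots.append((pos, dvec, r_new))
        if failed:
            continue
        return Structure(tuple(symbols), np.array(coords))
    raise BuildError(
        f"could not build {counts} within {max_restarts} restarts"
    )


# ---------------------------------------------------------------------------
# Toy pairwise Morse potential
# ---------------------------------------------------------------------------

#: Morse well depths in eV per unordered element pair (loosely bond-energy
#: shaped; frozen constants of the toy potential, not physical claims).
MORSE_DE: dict[frozenset, float] = {
    frozenset(["C"]): 3.6,
    frozenset(["C", "H"]): 3.5,
    frozenset(["C", "N"]): 3.0,
    frozenset(["H"]): 2.2,
    frozenset(["H", "N"]): 3.1,
    frozenset(["N"]): 2.0,
}

#: Morse range parameter in 1/Angstrom, shared by all pairs.  At ~1.5 A
#: equilibrium distances this gives a reduced range rho = a*r0 of ~4.5,
#: i.e. wells narrow enough that the potential-energy surface is rugged and
#: multi-funnelled (the regime where global-optimisation strategy matters),
#: rather than the single compact-blob funnel of long-ranged pair potentials.
MORSE_A = 3.0


_MORSE_TABLE_CACHE: dict[tuple[str, ...], tuple[np.ndarray, np.ndarray]] = {}


def _morse_tables(symbols: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    key_sym = tuple(symbols)
    cached = _MORSE_TABLE_CACHE.get(key_sym)
    if cached is not None:
        return cached
    n = len(symbols)
    de = np.empty((n, n))
    r0 = np.empty((n, n))
    for i, si in enumerate(symbols):
        for j, sj in enumerate(symbols):
            key = frozenset([si, sj])
            if key not in MORSE_DE:
                raise StructureError(f"toy potential has no parameters for pair {si}-{sj}")
            de[i, j] = MORSE_DE[key]
            r0[i, j] = COVALENT_RADII[si] + COVALENT_RADII[sj]
    if len(_MORSE_TABLE_CACHE) < 4096:
        _MORSE_TABLE_CACHE[key_sym] = (de, r0)
    return de, r0


def _energy_raw(coords: np.ndarray, de: np.ndarray, r0: np.ndarray,
                iu: tuple[np.ndarray, np.ndarray]) -> float:
    diff = coords[iu[0]] - coords[iu[1]]
    d = np.sqrt((diff**2).sum(axis=-1))
    dr = d - r0[iu]
    return float(np.sum(de[iu] * (np.exp(-2.0 * MORSE_A * dr) - 2.0 * np.exp(-MORSE_A * dr))))


def _forces_raw(coords: np.ndarray, de: np.ndarray, r0: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(d, np.inf)
    dr = d - r0
    dedr = 2.0 * MORSE_A * de * (np.exp(-MORSE_A * dr) - np.exp(-2.0 * MORSE_A * dr))
    coef = dedr / d
    return -(coef[:, :, None] * diff).sum(axis=1)


def toy_energy(s: Structure) -> float:
    """All-pairs Morse energy in eV.

    Each pair contributes ``De * (exp(-2a(r - r0)) - 2 exp(-a(r - r0)))`` with
    ``r0`` the covalent-radius sum, so a pair at its equilibrium distance
    contributes exactly ``-De``.  Deterministic, permutation and rigid-motion
    invariant.
    """
    if s.n_atoms < 1:
        raise StructureError("empty structure")
    if s.n_atoms == 1:
        _morse_tables(s.symbols)  # still validate the element
        return 0.0
    de, r0 = _morse_tables(s.symbols)
    iu = np.triu_indices(s.n_atoms, k=1)
    return _energy_raw(s.coords, de, r0, iu)


def toy_forces(s: Structure) -> np.ndarray:
    """Analytic forces (eV/Angstrom), negative gradient of :func:`toy_energy`."""
    de, r0 = _morse_tables(s.symbols)
    return _forces_raw(s.coords, de, r0)


class ToyCalculator:
    """Deterministic Morse-potential calculator with a quench-style relaxer.

    ``relax`` performs steepest descent with a backtracking line search, so the
    energy never increases; it stops after ``max_steps`` accepted steps or once
    the largest per-atom force norm falls below ``force_tol``.
    """

    def __init__(self, initial_step: float = 0.05, min_step: float = 1e-7):
        self.initial_step = initial_step
        self.min_step = min_step

    def evaluate(self, s: Structure) -> float:
        try:
            return toy_energy(s)
        except StructureError as exc:
            raise CalculatorError(str(exc)) from exc

    def relax(self, s: Structure, max_steps: int = 100, force_tol: float = 0.05) -> Structure:
        try:
            de, r0 = _morse_tables(s.symbols)
        except StructureError as exc:
            raise CalculatorError(str(exc)) from exc
        iu = np.triu_indices(s.n_atoms, k=1)
        coords = s.coords.copy()
        energy = _energy_raw(coords, de, r0, iu)
        step = self.initial_step
        for _ in range(max_steps):
            forces = _forces_raw(coords, de, r0)
            fmax = float(np.linalg.norm(forces, axis=1).max())
            if fmax < force_tol:
                break
            # Backtracking: shrink the step until the energy decreases.
            direction = forces / max(fmax, 1e-12)
            accepted = False
            while step >= self.min_step:
                trial = coords + step * direction
                e_trial = _energy_raw(trial, de, r0, iu)
                if e_trial < energy:
                    coords, energy = trial, e_trial
                    step = min(step * 1.5, 0.5)
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break
        return Structure(s.symbols, coords, energy)
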