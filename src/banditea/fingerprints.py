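"""Pairwise radial-distribution fingerprints and inter-structure distances.

A fingerprint for an element pair (A, B) is a binned radial distribution over
[0, r_max): every A-B interatomic distance R contributes a Gaussian of width
``delta`` centred at R, integrated over each bin of width ``bin_width`` and
weighted by ``v_uc / (4 pi R^2 N_A N_B bin_width)``; the baseline is shifted
by -1 so a bin with no nearby pair tends to -1.  Two structures are compared
by the cosine distance between their fingerprints per element pair, and the
per-pair distances are combined in quadrature (they contribute equally).

For hydrocarbon-nitrogen chemistries only the C-C and C-N fingerprints are
used by default; hydrogen contributions are treated as redundant.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import ndtr

from .structures import Structure

__all__ = [
    "FingerprintConfig",
    "Fingerprint",
    "MissingElementError",
    "fingerprint",
    "baseline_fingerprint",
    "cosine_distance",
    "combine_distances",
    "structure_distance",
    "distance_matrix",
    "distance_matrix_to_csv",
]


class MissingElementError(ValueError):
    """The structure lacks the atoms needed for the requested pair."""


@dataclass(frozen=True)
class FingerprintConfig:
    """Parameters of the radial-distribution fingerprint.

    delta
        Gaussian kernel width in Angstrom (default 0.2).
    bin_width
        Histogram bin size in Angstrom (default 0.5).
    r_max
        Radial cutoff in Angstrom (default 8.0); must be an integral number
        of bins.
    v_uc
        Scaling volume in Angstrom^3.  Because the -1 baseline is not scaled
        by v_uc, this sets the peak-to-baseline ratio of the fingerprint and
        hence the scale of cosine distances.  The default is the volume of
        the r_max sphere, (4/3) pi r_max^3 (~2145 A^3 at r_max = 8), which
        puts peaks at order unity against the baseline and distances between
        distinct small organic molecules on the few-times-0.01 scale that
        the 0.026 clustering threshold assumes.  Pass ``None`` to use this
        r_max-derived default.
    tail_sigmas
        Gaussian tails are truncated at +/- this many kernel widths
        (default 4; < 1e-4 of the mass is discarded).
    pairs
        Element pairs entering the combined structure distance.
    half_complement
        If True (default) the cosine distance is (1 - cos)/2, bounded [0, 1];
        if False, 1 - cos.
    """

    delta: float = 0.2
    bin_width: float = 0.5
    r_max: float = 8.0
    v_uc: float | None = None
    tail_sigmas: float = 4.0
    pairs: tuple[tuple[str, str], ...] = (("C", "C"), ("C", "N"))
    half_complement: bool = True

    def __post_init__(self) -> None:
        if self.v_uc is None:
            object.__setattr__(self, "v_uc", 4.0 / 3.0 * math.pi * self.r_max**3)
        for name in ("delta", "bin_width", "r_max", "v_uc", "tail_sigmas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        ratio = self.r_max / self.bin_width
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("r_max must be an integral number of bins")

    @property
    def n_bins(self) -> int:
        return int(round(self.r_max / self.bin_width))

    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.r_max, self.n_bins + 1)

    def bin_midpoints(self) -> np.ndarray:
        edges = self.bin_edges()
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class Fingerprint:
    """Binned radial-distribution values for one ordered element pair."""

    pair: tuple[str, str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.pair = (str(self.pair[0]), str(self.pair[1]))
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fingerprint values must be finite")


def baseline_fingerprint(pair: tuple[str, str], cfg: FingerprintConfig) -> Fingerprint:
    """The empty-sum fingerprint: every bin at the -1 baseline."""
    return Fingerprint(pair, -np.ones(cfg.n_bins))


def _pair_distance_list(s: Structure, pair: tuple[str, str]) -> tuple[np.ndarray, int, int]:
    a, b = pair
    ia = [i for i, sym in enumerate(s.symbols) if sym == a]
    ib = [i for i, sym in enumerate(s.symbols) if sym == b]
    if a == b:
        if len(ia) < 2:
            raise MissingElementError(f"need >= 2 {a} atoms for the {a}-{b} fingerprint")
        pos = s.coords[ia]
        diff = pos[:, None, :] - pos[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
        iu = np.triu_indices(len(ia), k=1)
        # ordered pairs (i, j) and (j, i) both enter the double sum
        return np.repeat(d[iu], 2), len(ia), len(ia)
    if not ia or not ib:
        missing = a if not ia else b
        raise MissingElementError(f"no {missing} atoms for the {a}-{b} fingerprint")
    diff = s.coords[ia][:, None, :] - s.coords[ib][None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1)).ravel()
    return d, len(ia), len(ib)


def fingerprint(s: Structure, pair: tuple[str, str],
                cfg: FingerprintConfig | None = None) -> Fingerprint:
    """Radial-distribution fingerprint of ``s`` for one element pair."""
    if cfg is None:
        cfg = FingerprintConfig()
    dists, n_a, n_b = _pair_distance_list(s, pair)
    edges = cfg.bin_edges()
    values = -np.ones(cfg.n_bins)
    support = cfg.tail_sigmas * cfg.delta
    keep = dists <= cfg.r_max + support
    dists = dists[keep]
    if dists.size:
        w = cfg.v_uc / (4.0 * math.pi * dists**2 * n_a * n_b * cfg.bin_width)
        cdf = ndtr((edges[None, :] - dists[:, None]) / cfg.delta)
        mass = np.diff(cdf, axis=1)
        # truncate tails: zero any bin lying entirely outside +/- support
        lo, hi = edges[:-1][None, :], edges[1:][None, :]
        outside = (hi < dists[:, None] - support) | (lo > dists[:, None] + support)
        mass[outside] = 0.0
        values += (w[:, None] * mass).sum(axis=0)
    return Fingerprint(tuple(pair), values)


def cosine_distance(f1: Fingerprint, f2: Fingerprint,
                    half_complement: bool = True) -> float:
    """Cosine dissimilarity between two same-pair fingerprints.

    With ``half_complement`` (the default) this is ``(1 - cos theta) / 2``,
    bounded in [0, 1]; otherwise ``1 - cos theta``.
    """
    if f1.pair != f2.pair:
        raise ValueError(f"fingerprint pairs differ: {f1.pair} vs {f2.pair}")
    if f1.values.shape != f2.values.shape:
        raise ValueError("fingerprint lengths differ")
    n1 = float(np.linalg.norm(f1.values))
    n2 = float(np.linalg.norm(f2.values))
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("cosine distance undefined for a zero fingerprint")
    cos = float(np.dot(f1.values, f2.values) / (n1 * n2))
    cos = max(-1.0, min(1.0, cos))
    d = (1.0 - cos) / 2.0 if half_complement else 1.0 - cos
    return max(0.0, d)


def combine_distances(per_pair: Sequence[float]) -> float:
    """Combine per-pair cosine distances in quadrature (equal weighting)."""
    return float(math.sqrt(sum(d * d for d in per_pair)))


def _fingerprints_with_fallback(s: Structure, cfg: FingerprintConfig) -> list[Fingerprint]:
    """Fingerprints for every configured pair; a missing *second* element of a
    pair falls back to the all-baseline fingerprint.  If every pair is
    missing, the structure is unfingerprintable."""
    fps: list[Fingerprint] = []
    n_missing = 0
    for pair in cfg.pairs:
        try:
            fps.append(fingerprint(s, pair, cfg))
        except MissingElementError:
            fps.append(baseline_fingerprint(pair, cfg))
            n_missing += 1
    if n_missing == len(cfg.pairs):
        raise MissingElementError(
            f"structure has none of the configured fingerprint pairs {cfg.pairs}"
        )
    return fps


def structure_distance(s1: Structure, s2: Structure,
                       cfg: FingerprintConfig | None = None) -> float:
    """Combined fingerprint distance between two structures."""
    if cfg is None:
        cfg = FingerprintConfig()
    f1 = _fingerprints_with_fallback(s1, cfg)
    f2 = _fingerprints_with_fallback(s2, cfg)
    per_pair = [
        cosine_distance(a, b, half_complement=cfg.half_complement)
        for a, b in zip(f1, f2)
    ]
    return combine_distances(per_pair)


def distance_matrix(structures: Sequence[Structure],
                    cfg: FingerprintConfig | None = None) -> np.ndarray:
    """Symmetric matrix of combined distances, fingerprinting each structure once."""
    if cfg is None:
        cfg = FingerprintConfig()
    if len(structures) < 2:
        raise ValueError("distance_matrix requires at least 2 structures")
    all_fps: list[list[Fingerprint]] = []
    for idx, s in enumerate(structures):
        try:
            all_fps.append(_fingerprints_with_fallback(s, cfg))
        except MissingElementError as exc:
            raise ValueError(f"structure {idx} is unfingerprintable: {exc}") from exc
    n = len(structures)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            per_pair = [
                cosine_distance(a, b, half_complement=cfg.half_complement)
                for a, b in zip(all_fps[i], all_fps[j])
            ]
            d[i, j] = d[j, i] = combine_distances(per_pair)
    return d


def distance_matrix_to_csv(d: np.ndarray, path: str | Path) -> None:
    """Write a distance matrix as CSV with a header row of structure indices."""
    import pandas as pd

    n = d.shape[0]
    pd.DataFrame(d, columns=[str(i) for i in range(n)]).to_csv(path, index=False)
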