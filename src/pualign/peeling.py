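"""Protein Peeling: divisive segmentation of a chain into Protein Units.

A Protein Unit (PU) is a contiguous, compact fragment with dense internal
contacts and sparse contacts to the rest of the chain. Peeling works solely
from the contact-probability matrix (Cα distances pushed through a logistic)
and repeatedly splits one unit into 2 or 3 sub-units at the cut(s) with the
highest partition index, producing a series of nested partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.special import expit

DEFAULT_D0_CONTACT = 8.0  # Å, logistic midpoint
DEFAULT_SLOPE = 1.5  # Å, logistic width
DEFAULT_MIN_PU_SIZE = 15  # residues
DEFAULT_PI_MIN = 0.2  # stop splitting below this partition index

#: PU counts admitted at each exploration level.
LEVEL_PU_COUNTS = {1: (2, 3), 2: (4, 5), 3: (6,), 4: (7,)}


@dataclass(frozen=True)
class ContactMatrix:
    """Symmetric per-residue-pair contact probabilities in [0, 1]."""

    probs: np.ndarray = field(repr=False)
    d0_contact: float = DEFAULT_D0_CONTACT
    slope: float = DEFAULT_SLOPE

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("probs must be square")
        # integral image for O(1) block sums, cached alongside
        cum = np.zeros((p.shape[0] + 1, p.shape[1] + 1))
        np.cumsum(np.cumsum(p, axis=0), axis=1, out=cum[1:, 1:])
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "_cum", cum)

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    def block_sum(self, i0: int, i1: int, j0: int, j1: int) -> float:
        """Sum of probs over rows [i0, i1) and columns [j0, j1)."""
        c = self._cum
        return float(c[i1, j1] - c[i0, j1] - c[i1, j0] + c[i0, j0])


@dataclass(frozen=True)
class ProteinUnit:
    """Contiguous residue interval [start, end), 0-based half-open."""

    start: int
    end: int
    pu_id: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PeelingLevel:
    """One partition of [0, N) into contiguous Protein Units."""

    units: tuple[ProteinUnit, ...]
    depth: int
    partition_quality: float

    def __post_init__(self) -> None:
        prev = 0
        for u in self.units:
            if u.start != prev:
                raise ValueError("units must tile the chain contiguously")
            prev = u.end

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def boundaries(self) -> tuple[int, ...]:
        """Interior cut positions."""
        return tuple(u.end for u in self.units[:-1])


def contact_probability_matrix(trace, d0_contact: float = DEFAULT_D0_CONTACT,
                               slope: float = DEFAULT_SLOPE) -> ContactMatrix:
    """Logistic contact probabilities from Cα distances.

    probs[i, j] = 1 / (1 + exp((dist(i, j) − d0_contact) / slope)); the
    diagonal is set to 1 by convention.
    """
    if d0_contact <= 0 or slope <= 0:
        raise ValueError("d0_contact and slope must be positive")
    coords = trace.coords
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    dists = squareform(pdist(coords))
    probs = expit((d0_contact - dists) / slope)
    np.fill_diagonal(probs, 1.0)
    return ContactMatrix(probs=probs, d0_contact=d0_contact, slope=slope)


def _pairwise_pi(cm: ContactMatrix, a: tuple[int, int], b: tuple[int, int]) -> float:
    k_cross = cm.block_sum(a[0], a[1], b[0], b[1])
    k_aa = cm.block_sum(a[0], a[1], a[0], a[1])
    k_bb = cm.block_sum(b[0], b[1], b[0], b[1])
    pi = 1.0 - (k_cross * k_cross) / (k_aa * k_bb)
    return float(min(1.0, max(0.0, pi)))


def partition_index(cm: ContactMatrix, segments: list[tuple[int, int]],
                    min_pu_size: int = DEFAULT_MIN_PU_SIZE) -> float:
    """Structural independence of a proposed 2- or 3-way split.

    For two segments A, B: PI = 1 − K(A,B)² / (K(A,A)·K(B,B)) where K sums
    contact probabilities over the index block. For three segments the
    minimum pairwise PI is returned. High PI means the sub-units share few
    contacts, i.e. the cut is clean.
    """
    if len(segments) not in (2, 3):
        raise ValueError("segments must contain 2 or 3 intervals")
    for s, e in segments:
        if e - s < min_pu_size:
            raise ValueError("segment shorter than min_pu_size")
    for (s1, e1), (s2, _) in zip(segments, segments[1:]):
        if e1 != s2:
            raise ValueError("segments must be contiguous")
    if len(segments) == 2:
        return _pairwise_pi(cm, segments[0], segments[1])
    return min(_pairwise_pi(cm, a, b)
               for i, a in enumerate(segments) for b in segments[i + 1:])


def _best_split(cm: ContactMatrix, unit: ProteinUnit, min_pu_size: int,
                allow_three: bool):
    """Best 2- or 3-way split of ``unit``: (pi, cuts) or None.

    Ties go to 2-way over 3-way, then to the cut (midpoint of cuts for 3-way)
    closest to the unit midpoint, then to the leftmost cut.
    """
    s, e = unit.start, unit.end
    mid = (s + e) / 2.0
    best = None  # (pi, n_way, dist_to_mid, cuts)
    if e - s >= 2 * min_pu_size:
        for c in range(s + min_pu_size, e - min_pu_size + 1):
            pi = _pairwise_pi(cm, (s, c), (c, e))
            key = (-pi, 2, abs(c - mid), c)
            if best is None or key < best[0]:
                best = (key, (c,))
    if allow_three and e - s >= 3 * min_pu_size:
        for c1 in range(s + min_pu_size, e - 2 * min_pu_size + 1):
            for c2 in range(c1 + min_pu_size, e - min_pu_size + 1):
                pi = partition_index(cm, [(s, c1), (c1, c2), (c2, e)], min_pu_size)
                key = (-pi, 3, abs((c1 + c2) / 2.0 - mid), c1)
                if best is None or key < best[0]:
                    best = (key, (c1, c2))
    if best is None:
        return None
    return -best[0][0], best[1]


def peel(trace, max_units: int = 7, min_pu_size: int = DEFAULT_MIN_PU_SIZE,
         d0_contact: float = DEFAULT_D0_CONTACT, slope: float = DEFAULT_SLOPE,
         pi_min: float = DEFAULT_PI_MIN) -> list[PeelingLevel]:
    """Top-down divisive clustering of a chain into nested PU partitions.

    Level 0 is the whole chain; each subsequent level replaces exactly one
    unit by its best 2- or 3-way split (the unit × cut combination with the
    highest partition index). Splitting stops when the unit count reaches
    ``max_units`` or no remaining split reaches ``pi_min``.
    """
    n = len(trace)
    levels = [PeelingLevel(units=(ProteinUnit(0, n, 0),), depth=0,
                           partition_quality=1.0)]
    if n < 2 * min_pu_size:
        return levels
    cm = contact_probability_matrix(trace, d0_contact, slope)

    while levels[-1].n_units < max_units:
        current = levels[-1]
        budget = max_units - current.n_units
        best = None  # (pi, unit_index, cuts)
        for ui, unit in enumerate(current.units):
            res = _best_split(cm, unit, min_pu_size,
                              allow_three=budget >= 2)
            if res is None:
                continue
            pi, cuts = res
            cand = (pi, -len(cuts), ui)  # prefer higher PI, then 2-way, then left unit
            if best is None or cand > best[0]:
                best = (cand, ui, cuts)
        if best is None or best[0][0] < pi_min:
            break
        _, ui, cuts = best
        unit = current.units[ui]
        bounds = [unit.start, *cuts, unit.end]
        new_units = list(current.units[:ui])
        new_units += [ProteinUnit(a, b) for a, b in zip(bounds, bounds[1:])]
        new_units += list(current.units[ui + 1:])
        new_units = [ProteinUnit(u.start, u.end, pu_id=i)
                     for i, u in enumerate(new_units)]
        levels.append(PeelingLevel(units=tuple(new_units), depth=current.depth + 1,
                                   partition_quality=best[0][0]))
    return levels


def select_level(levels: list[PeelingLevel], exploration_level: int) -> list[PeelingLevel]:
    """Peeling levels admitted at an exploration level.

    Exploration level 1 admits partitions of 2 or 3 PUs, level 2 admits 4 or
    5, level 3 admits 6 and level 4 admits 7. When the chain could not be
    peeled that far, the deepest available partition(s) are returned with a
    warning.
    """
    if exploration_level not in LEVEL_PU_COUNTS:
        raise ValueError("exploration_level must be in 1..4")
    allowed = LEVEL_PU_COUNTS[exploration_level]
    picked = [lv for lv in levels if lv.n_units in allowed]
    if picked:
        return picked
    deepest = max(lv.n_units for lv in levels)
    if deepest >= min(allowed):
        # deeper partitions exist but none with an admitted count (e.g. a
        # 3-way split jumped over it); nothing sensible to substitute
        return []
    warnings.warn(
        f"chain peeled to at most {deepest} units; exploration level "
        f"{exploration_level} requests {allowed} — using the deepest level",
        stacklevel=2,
    )
    return [lv for lv in levels if lv.n_units == deepest]


def peeling_table(levels: list[PeelingLevel], trace) -> str:
    """TSV dump of peeling levels (1-based author numbering)."""
    rows = ["depth\tn_units\tpartition_index\tunit_bounds"]
    for lv in levels:
        bounds = ";".join(
            f"{trace.residues[u.start][0]}-{trace.residues[u.end - 1][0]}"
            for u in lv.units)
        rows.append(f"{lv.depth}\t{lv.n_units}\t{lv.partition_quality:.4f}\t{bounds}")
    return "\n".join(rows) + "\n"
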