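"""Order exploration: align Protein Units in every order, both directions.

One *strategy* is an ordering of the PUs of one peeling level: PUs are fitted
to the target one by one, each restricted to the target residues not consumed
by the previously placed PUs. All orders are explored depth-first with
memoization of PU-vs-mask alignments and admissible branch-and-bound pruning,
the whole procedure is repeated with query and target swapped, and the
alignment with the highest TM-score (normalized by the shorter chain) wins.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .peeling import (
    DEFAULT_D0_CONTACT,
    DEFAULT_MIN_PU_SIZE,
    DEFAULT_PI_MIN,
    DEFAULT_SLOPE,
    LEVEL_PU_COUNTS,
    ProteinUnit,
    peel,
    select_level,
)
from .rigid_core import PUAlignment, align_pu_to_target
from .scoring import (
    QUERY_AS_PEELED,
    TARGET_AS_PEELED,
    GlobalAlignment,
    flexible_alignment_from_units,
    optimize_tm,
    tm_d0,
    tm_from_distances,
    tm_score,
)

logger = logging.getLogger(__name__)


@dataclass
class ExplorationStats:
    """Counters for the branch-and-bound search (testing/diagnostics)."""

    aligner_calls: int = 0
    cache_hits: int = 0
    branches_pruned: int = 0
    strategies_completed: int = 0


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of a full flexible alignment run.

    ``per_level`` maps exploration level -> best alignment found *at* that
    level (either direction); ``best`` is the cumulative optimum over levels
    1..n and both directions. ``swap_delta`` is |TM(query peeled) −
    TM(target peeled)| per level — large values flag pairs where swapping the
    roles was decisive.
    """

    best: GlobalAlignment
    per_level: dict[int, GlobalAlignment] = field(default_factory=dict)
    swap_delta: dict[int, float] = field(default_factory=dict)

    def best_up_to(self, level: int) -> GlobalAlignment:
        cands = [ga for lv, ga in self.per_level.items() if lv <= level]
        if not cands:
            return self.best
        return max(cands, key=lambda g: g.tm_score)


class _MemoAligner:
    """align_pu_to_target memoized on (pu_id, exact target mask)."""

    def __init__(self, peeled, target, min_pu_size: int, stats: ExplorationStats):
        self.peeled = peeled
        self.target = target
        self.min_pu_size = min_pu_size
        self.stats = stats
        self._cache: dict[tuple[int, bytes], PUAlignment] = {}

    def __call__(self, pu: ProteinUnit, mask: np.ndarray) -> PUAlignment:
        key = (pu.pu_id, mask.tobytes())
        hit = self._cache.get(key)
        if hit is not None:
            self.stats.cache_hits += 1
            return hit
        self.stats.aligner_calls += 1
        pua = align_pu_to_target(self.peeled.slice(pu.start, pu.end), self.target,
                                 mask, pu=pu, min_pu_size=self.min_pu_size)
        self._cache[key] = pua
        return pua


def run_strategy(pus_in_order: list[ProteinUnit], peeled, target,
                 direction: str = QUERY_AS_PEELED, exploration_depth: int = 0,
                 min_pu_size: int = DEFAULT_MIN_PU_SIZE,
                 aligner=None) -> GlobalAlignment:
    """Align the PUs in the given order, consuming target residues as we go.

    Each PU sees only the target residues left unconsumed by its
    predecessors; a PU that cannot be placed contributes nothing. The final
    score is the flexible TM (per-PU transforms) normalized by the shorter
    chain.
    """
    L_norm = min(len(peeled), len(target))
    if aligner is None:
        aligner = _MemoAligner(peeled, target, min_pu_size, ExplorationStats())
    mask = np.zeros(len(target), dtype=bool)
    placed: list[PUAlignment] = []
    for pu in pus_in_order:
        pua = aligner(pu, mask)
        if pua.is_empty:
            logger.debug("PU %d yielded an empty alignment; skipped", pu.pu_id)
            continue
        mask = mask.copy()
        mask[pua.mapping.target_indices] = True
        placed.append(pua)
    return flexible_alignment_from_units(placed, direction, exploration_depth, L_norm)


def explore_orders(pus: list[ProteinUnit], peeled, target,
                   direction: str = QUERY_AS_PEELED, exploration_depth: int = 0,
                   min_pu_size: int = DEFAULT_MIN_PU_SIZE,
                   stats: ExplorationStats | None = None,
                   prune: bool = True) -> GlobalAlignment:
    """Best alignment over all orders of the given PUs (branch and bound).

    Equivalent to the best :func:`run_strategy` over all |PUs|! orders.
    PU-vs-mask alignments are memoized so orders sharing a prefix reuse work;
    a branch is pruned when even placing every remaining residue at distance
    zero could not beat the incumbent (an admissible bound, so pruning never
    changes the result). Ties keep the first completed strategy in
    lexicographic PU-id order.
    """
    if not 1 <= len(pus) <= 7:
        raise ValueError("explore_orders handles 1..7 PUs")
    if stats is None:
        stats = ExplorationStats()
    L_norm = min(len(peeled), len(target))
    d0 = tm_d0(L_norm)
    aligner = _MemoAligner(peeled, target, min_pu_size, stats)

    order = sorted(pus, key=lambda u: u.pu_id)
    best: dict = {"tm_sum": -1.0, "placed": None}

    def dfs(remaining: list[ProteinUnit], mask: np.ndarray,
            placed: list[PUAlignment], tm_sum: float) -> None:
        if not remaining:
            stats.strategies_completed += 1
            if tm_sum > best["tm_sum"] + 1e-12:
                best["tm_sum"] = tm_sum
                best["placed"] = list(placed)
            return
        if prune:
            headroom = min(sum(len(u) for u in remaining), int((~mask).sum()))
            if tm_sum + headroom <= best["tm_sum"] + 1e-12:
                stats.branches_pruned += 1
                return
        for k, pu in enumerate(remaining):
            pua = aligner(pu, mask)
            rest = remaining[:k] + remaining[k + 1:]
            if pua.is_empty:
                dfs(rest, mask, placed, tm_sum)
                continue
            new_mask = mask.copy()
            new_mask[pua.mapping.target_indices] = True
            contrib = float(np.sum(1.0 / (1.0 + (pua.pair_distances / d0) ** 2)))
            placed.append(pua)
            dfs(rest, new_mask, placed, tm_sum + contrib)
            placed.pop()

    dfs(order, np.zeros(len(target), dtype=bool), [], 0.0)
    placed = best["placed"] or []
    return flexible_alignment_from_units(placed, direction, exploration_depth, L_norm)


def explore_orders_bruteforce(pus, peeled, target, direction=QUERY_AS_PEELED,
                              exploration_depth: int = 0,
                              min_pu_size: int = DEFAULT_MIN_PU_SIZE) -> GlobalAlignment:
    """Plain enumeration of every PU order, no memoization or pruning.

    Independent oracle for :func:`explore_orders` on small inputs.
    """
    best = None
    for perm in itertools.permutations(sorted(pus, key=lambda u: u.pu_id)):
        stats = ExplorationStats()
        aligner = _MemoAligner(peeled, target, min_pu_size, stats)
        aligner._cache = _NoCache()  # defeat memoization: every call recomputed
        ga = run_strategy(list(perm), peeled, target, direction,
                          exploration_depth, min_pu_size, aligner=aligner)
        if best is None or ga.tm_score > best.tm_score + 1e-12:
            best = ga
    return best


class _NoCache(dict):
    def __setitem__(self, key, value):  # drop everything
        pass


def rigid_align(query, target) -> GlobalAlignment:
    """Single-PU rigid alignment of the whole query onto the whole target.

    The order-preserving inner aligner runs with an empty mask and the result
    is polished with the single-transform TM-score search.
    """
    L_norm = min(len(query), len(target))
    whole = ProteinUnit(0, len(query), 0)
    mask = np.zeros(len(target), dtype=bool)
    pua = align_pu_to_target(query.coords, target, mask, pu=whole,
                             min_pu_size=min(DEFAULT_MIN_PU_SIZE, L_norm))
    if pua.is_empty:
        return flexible_alignment_from_units([], QUERY_AS_PEELED, 0, L_norm)
    tr, tm = optimize_tm(pua.mapping, query, target, L_norm)
    d = np.linalg.norm(tr.apply(query.coords[pua.mapping.query_indices])
                       - target.coords[pua.mapping.target_indices], axis=1)
    polished = PUAlignment(pu=whole, mapping=pua.mapping, transform=tr,
                           local_tm=tm, pair_distances=d)
    best = max([pua, polished],
               key=lambda p: tm_from_distances(p.pair_distances, L_norm))
    return flexible_alignment_from_units([best], QUERY_AS_PEELED, 0, L_norm)


def flexible_align(query, target, exploration_level: int = 2,
                   min_pu_size: int = DEFAULT_MIN_PU_SIZE,
                   d0_contact: float = DEFAULT_D0_CONTACT,
                   slope: float = DEFAULT_SLOPE,
                   pi_min: float = DEFAULT_PI_MIN) -> AlignmentResult:
    """Full flexible alignment of two chains.

    For each direction (peel the query / peel the target) and each peeling
    level admitted at exploration levels 1..``exploration_level``, every PU
    order is explored; the returned ``best`` maximizes the TM-score
    normalized by the shorter chain over all of it. Chains too short to peel
    fall back to a plain rigid alignment (with a warning).
    """
    if exploration_level not in LEVEL_PU_COUNTS:
        raise ValueError("exploration_level must be in 1..4")
    L_norm = min(len(query), len(target))
    max_units = max(LEVEL_PU_COUNTS[exploration_level])

    per_level: dict[int, GlobalAlignment] = {}
    swap_delta: dict[int, float] = {}
    candidates: list[GlobalAlignment] = []

    directions = [(QUERY_AS_PEELED, query, target), (TARGET_AS_PEELED, target, query)]
    peelable = {
        d: len(peeled) >= 2 * min_pu_size for d, peeled, _ in directions
    }
    if not any(peelable.values()):
        warnings.warn("both chains too short to peel; returning a rigid alignment",
                      stacklevel=2)
        return AlignmentResult(best=rigid_align(query, target))

    levels_by_dir = {}
    for d, peeled, _ in directions:
        if peelable[d]:
            levels_by_dir[d] = peel(peeled, max_units=max_units,
                                    min_pu_size=min_pu_size,
                                    d0_contact=d0_contact, slope=slope,
                                    pi_min=pi_min)

    for lvl in range(1, exploration_level + 1):
        dir_best: dict[str, GlobalAlignment] = {}
        for d, peeled, other in directions:
            if not peelable[d]:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                admitted = select_level(levels_by_dir[d], lvl)
            for plevel in sorted(admitted, key=lambda lv: lv.n_units):
                ga = explore_orders(list(plevel.units), peeled, other,
                                    direction=d, exploration_depth=lvl,
                                    min_pu_size=min_pu_size)
                candidates.append(ga)
                if d not in dir_best or ga.tm_score > dir_best[d].tm_score + 1e-12:
                    dir_best[d] = ga
        if dir_best:
            per_level[lvl] = max(
                dir_best.values(),
                key=lambda g: (g.tm_score, g.direction == QUERY_AS_PEELED))
        if len(dir_best) == 2:
            swap_delta[lvl] = abs(dir_best[QUERY_AS_PEELED].tm_score
                                  - dir_best[TARGET_AS_PEELED].tm_score)

    if not candidates:
        warnings.warn("no admissible peeling level; returning a rigid alignment",
                      stacklevel=2)
        return AlignmentResult(best=rigid_align(query, target))

    # ties: fewer PUs first, then query-as-peeled, then discovery order
    best = candidates[0]
    for ga in candidates[1:]:
        if (ga.tm_score, -ga.n_units, ga.direction == QUERY_AS_PEELED) > \
           (best.tm_score + 1e-12, -best.n_units, best.direction == QUERY_AS_PEELED):
            best = ga
    assert best.L_norm == L_norm
    return AlignmentResult(best=best, per_level=per_level, swap_delta=swap_delta)
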