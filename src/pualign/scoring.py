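"""TM-score, RMSD and reference-alignment agreement.

All scores are Cα-based. The TM-score is always normalized by the length of
the shorter chain; a flexible alignment's TM keeps each Protein Unit under its
own rigid transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .rigid_core import PUAlignment, ResidueMapping, RigidTransform, kabsch

QUERY_AS_PEELED = "query_as_peeled"
TARGET_AS_PEELED = "target_as_peeled"


def tm_d0(L: int) -> float:
    """Length-dependent TM-score distance scale d0(L), in Å.

    d0 = 1.24·(L−15)^(1/3) − 1.8 for L > 21, clamped at 0.5 Å below that
    (short chains would otherwise give a vanishing or negative scale).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if L <= 21:
        return 0.5
    return max(0.5, 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8)


def _pair_distances(pairs: np.ndarray, query, target,
                    transform_per_pair) -> np.ndarray:
    q = query.coords[pairs[:, 0]]
    t = target.coords[pairs[:, 1]]
    if isinstance(transform_per_pair, RigidTransform):
        moved = transform_per_pair.apply(q)
    else:
        transforms = list(transform_per_pair)
        if len(transforms) != len(pairs):
            raise ValueError("one transform per pair required")
        moved = np.array([tr.apply(x[None, :])[0] for tr, x in zip(transforms, q)])
    return np.linalg.norm(moved - t, axis=1)


def tm_score(mapping, query, target, transform_per_pair, L_norm: int) -> float:
    """TM-score of a residue mapping under the given transform(s).

    TM = (1/L_norm) Σ 1/(1 + (d_i/d0(L_norm))²) over mapped pairs, where d_i
    is the post-transform Cα distance of pair i; unmapped residues contribute
    nothing. ``transform_per_pair`` is either one rigid transform for all
    pairs or a sequence with one transform per pair (flexible scoring).
    """
    pairs = np.asarray(
        mapping.pairs if isinstance(mapping, ResidueMapping) else mapping, dtype=int)
    if pairs.size == 0:
        return 0.0
    d = _pair_distances(pairs.reshape(-1, 2), query, target, transform_per_pair)
    d0 = tm_d0(L_norm)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_norm)


def tm_from_distances(distances: np.ndarray, L_norm: int) -> float:
    """TM-score from precomputed per-pair Cα distances."""
    if len(distances) == 0:
        return 0.0
    d0 = tm_d0(L_norm)
    return float(np.sum(1.0 / (1.0 + (np.asarray(distances) / d0) ** 2)) / L_norm)


def optimize_tm(mapping, query, target,
                L_norm: int | None = None) -> tuple[RigidTransform, float]:
    """Best single rigid transform for a fixed residue mapping, by TM-score.

    Standard TM-score search: superpose on seed fragments of the mapping of
    lengths {L, L/2, L/4, 4}, then iteratively re-superpose on the pairs
    closer than d0·f for growing cutoff factors f until the selection is
    stable; the plain all-pair Kabsch fit is among the candidates, so the
    returned score is never below it.
    """
    pairs = np.asarray(
        mapping.pairs if isinstance(mapping, ResidueMapping) else mapping,
        dtype=int).reshape(-1, 2)
    if L_norm is None:
        L_norm = min(len(query), len(target))
    if len(pairs) == 0:
        return RigidTransform.identity(), 0.0
    q = query.coords[pairs[:, 0]]
    t = target.coords[pairs[:, 1]]
    K = len(pairs)
    if K < 3:
        tr = RigidTransform.identity()
        return tr, tm_from_distances(np.linalg.norm(tr.apply(q) - t, axis=1), L_norm)

    d0 = tm_d0(L_norm)

    def score_of(tr: RigidTransform) -> float:
        return tm_from_distances(np.linalg.norm(tr.apply(q) - t, axis=1), L_norm)

    candidates: list[RigidTransform] = []
    frag_lengths = sorted({K, max(3, K // 2), max(3, K // 4), min(4, K)}, reverse=True)
    for L_frag in frag_lengths:
        if L_frag < 3:
            continue
        stride = max(1, L_frag // 2)
        for s in range(0, K - L_frag + 1, stride):
            tr, _ = kabsch(q[s:s + L_frag], t[s:s + L_frag])
            candidates.append(tr)

    best_tr, best_tm = None, -1.0
    for tr in candidates:
        # distance-cutoff refinement
        for f in (1.0, 1.5, 2.0, 3.0, 4.0):
            prev_sel = None
            for _ in range(20):
                d = np.linalg.norm(tr.apply(q) - t, axis=1)
                sel = d < d0 * f
                if sel.sum() < 3:
                    break
                key = sel.tobytes()
                if key == prev_sel:
                    break
                prev_sel = key
                tr, _ = kabsch(q[sel], t[sel])
            tm = score_of(tr)
            if tm > best_tm:
                best_tm, best_tr = tm, tr
    return best_tr, best_tm


@dataclass(frozen=True)
class GlobalAlignment:
    """Flexible alignment of query onto target: one rigid transform per PU.

    ``pu_alignments`` are in the peeled chain's frame: when ``direction`` is
    ``query_as_peeled`` their mapping pairs are (query index, target index)
    and transforms move query coordinates onto the target; when the target
    was peeled, pairs are (target index, query index) and transforms move
    target coordinates.
    """

    pu_alignments: tuple[PUAlignment, ...]
    direction: str
    exploration_depth: int
    tm_score: float
    rmsd_aligned: float
    coverage: float
    L_norm: int = 0

    def __post_init__(self) -> None:
        if self.direction not in (QUERY_AS_PEELED, TARGET_AS_PEELED):
            raise ValueError("unknown direction")
        seen: set[int] = set()
        for pua in self.pu_alignments:
            tset = set(int(t) for t in pua.mapping.target_indices)
            if seen & tset:
                raise ValueError("PU target index sets must be disjoint")
            seen |= tset

    @property
    def n_units(self) -> int:
        return len(self.pu_alignments)

    @property
    def n_aligned(self) -> int:
        return sum(len(p.mapping) for p in self.pu_alignments)

    def pairs_query_target(self) -> list[tuple[int, int]]:
        """All aligned residue pairs as (query index, target index)."""
        out: list[tuple[int, int]] = []
        for pua in self.pu_alignments:
            for a, b in pua.mapping.pairs:
                out.append((a, b) if self.direction == QUERY_AS_PEELED else (b, a))
        return sorted(out)

    def query_frame_units(self) -> list[PUAlignment]:
        """PU alignments re-expressed so transforms move query coordinates.

        For target-as-peeled alignments each PU's transform is inverted and
        its mapping pairs swapped to (query index, target index).
        """
        if self.direction == QUERY_AS_PEELED:
            return list(self.pu_alignments)
        from .peeling import ProteinUnit

        out = []
        for pua in self.pu_alignments:
            pairs = tuple(sorted((b, a) for a, b in pua.mapping.pairs))
            qidx = [p[0] for p in pairs]
            unit = ProteinUnit(min(qidx), max(qidx) + 1, pua.pu.pu_id) if qidx else pua.pu
            # pair_distances reordered to match the sorted query-frame pairs
            order = np.argsort([b for a, b in pua.mapping.pairs]) \
                if len(pairs) else np.empty(0, dtype=int)
            out.append(PUAlignment(
                pu=unit, mapping=ResidueMapping(pairs),
                transform=pua.transform.inverse(), local_tm=pua.local_tm,
                pair_distances=np.asarray(pua.pair_distances)[order]
                if len(pairs) else np.empty(0)))
        return out

    def all_pair_distances(self) -> np.ndarray:
        if not self.pu_alignments:
            return np.empty(0)
        parts = [p.pair_distances for p in self.pu_alignments if len(p.mapping)]
        return np.concatenate(parts) if parts else np.empty(0)


def flexible_alignment_from_units(pu_alignments: Sequence[PUAlignment],
                                  direction: str, exploration_depth: int,
                                  L_norm: int) -> GlobalAlignment:
    """Assemble a GlobalAlignment and score it with per-PU transforms."""
    pu_alignments = tuple(p for p in pu_alignments if not p.is_empty)
    d = (np.concatenate([p.pair_distances for p in pu_alignments])
         if pu_alignments else np.empty(0))
    tm = tm_from_distances(d, L_norm)
    rmsd = float(np.sqrt(np.mean(d ** 2))) if len(d) else float("nan")
    return GlobalAlignment(
        pu_alignments=pu_alignments, direction=direction,
        exploration_depth=exploration_depth, tm_score=tm, rmsd_aligned=rmsd,
        coverage=len(d) / L_norm, L_norm=L_norm)


def reference_agreement(candidate: GlobalAlignment,
                        reference: Iterable[tuple[int, int]],
                        shift_tolerance: int = 0) -> float:
    """Percentage of reference residue pairs found in the candidate.

    Exact pair matching by default (a reference pair counts only if the
    candidate aligns exactly those two residues); ``shift_tolerance`` s
    relaxes the target side to ±s residues, as some benchmark evaluations do.
    """
    ref = list(reference)
    if not ref:
        raise ValueError("reference alignment is empty")
    cand = dict(candidate.pairs_query_target())
    hits = 0
    for q, t in ref:
        ct = cand.get(q)
        if ct is not None and abs(ct - t) <= shift_tolerance:
            hits += 1
    return 100.0 * hits / len(ref)
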