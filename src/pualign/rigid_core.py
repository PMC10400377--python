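"""Rigid-body machinery: Kabsch superposition and the inner rigid aligner.

The inner aligner fits one Protein Unit onto the still-unconsumed portion of
the target chain: gapless threading seeds, then alternating dynamic
programming (bounded Cα-distance pair score, affine gaps, consumed target
columns unavailable) and Kabsch re-superposition until the residue mapping is
stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

NEG = -1e18
_FORBIDDEN = -1e9  # match score at masked target columns

# affine gap penalties, in units of the bounded pair score (which is <= 1)
GAP_OPEN = 0.6
GAP_EXT = 0.05

DEFAULT_MIN_PU_SIZE = 15


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation followed by translation: x -> R x + t."""

    rotation: np.ndarray = field(repr=False)
    translation: np.ndarray = field(repr=False)
    degenerate: bool = False  # point set was (near-)collinear

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation,
                              degenerate=self.degenerate)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


@dataclass(frozen=True)
class ResidueMapping:
    """One-to-one residue correspondence, order-preserving on both sides."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        q = [p[0] for p in self.pairs]
        t = [p[1] for p in self.pairs]
        if any(b <= a for a, b in zip(q, q[1:])):
            raise ValueError("query indices must be strictly increasing")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("target indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def query_indices(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def target_indices(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)


@dataclass(frozen=True)
class PUAlignment:
    """Result of fitting one Protein Unit onto the masked target.

    ``mapping`` pairs are (peeled-chain index, target index), both global and
    0-based; ``pair_distances`` are the post-transform Cα distances in Å.
    """

    pu: "object"  # ProteinUnit; kept loose to avoid an import cycle
    mapping: ResidueMapping
    transform: RigidTransform
    local_tm: float
    pair_distances: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    @property
    def is_empty(self) -> bool:
        return len(self.mapping) == 0

    @classmethod
    def empty(cls, pu) -> "PUAlignment":
        return cls(pu=pu, mapping=ResidueMapping(()), transform=RigidTransform.identity(),
                   local_tm=0.0)


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares optimal superposition of ``moving`` onto ``fixed``.

    Returns the proper rigid transform (reflections excluded) minimizing the
    RMSD between the transformed moving set and the fixed set, and that RMSD.
    Near-collinear point sets are handled by the usual SVD sign correction and
    flagged ``degenerate`` on the returned transform.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("moving and fixed must both be (K, 3)")
    if moving.shape[0] < 3:
        raise ValueError("at least 3 point pairs are required")
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    H = (moving - cm).T @ (fixed - cf)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    scale = max(S[0], 1e-12)
    degenerate = bool(S[1] / scale < 1e-8 or S[2] / scale < 1e-8)
    t = cf - R @ cm
    tr = RigidTransform(R, t, degenerate=degenerate)
    diff = tr.apply(moving) - fixed
    rmsd = float(np.sqrt((diff ** 2).sum() / moving.shape[0]))
    return tr, rmsd


@njit(cache=True)
def _gotoh(score, open_t, ext_t, open_q, ext_q):  # pragma: no cover - jit
    """Affine-gap DP with free end gaps; per-column target-skip penalties.

    Returns the matched (query, target) index pairs of the best-scoring path.
    """
    P, T = score.shape
    H = np.zeros((P + 1, T + 1))
    E = np.full((P + 1, T + 1), NEG)
    F = np.full((P + 1, T + 1), NEG)
    ptrH = np.zeros((P + 1, T + 1), dtype=np.int8)
    ptrE = np.zeros((P + 1, T + 1), dtype=np.int8)
    ptrF = np.zeros((P + 1, T + 1), dtype=np.int8)
    E[0, 1:] = 0.0  # free leading skip of target
    F[1:, 0] = 0.0  # free leading skip of query

    best = NEG
    bi = 0
    bj = 0
    for i in range(1, P + 1):
        for j in range(1, T + 1):
            eh = H[i, j - 1] - open_t[j - 1]
            ee = E[i, j - 1] - ext_t[j - 1]
            if eh >= ee:
                E[i, j] = eh
                ptrE[i, j] = 0
            else:
                E[i, j] = ee
                ptrE[i, j] = 1
            fh = H[i - 1, j] - open_q
            ff = F[i - 1, j] - ext_q
            if fh >= ff:
                F[i, j] = fh
                ptrF[i, j] = 0
            else:
                F[i, j] = ff
                ptrF[i, j] = 1
            m = H[i - 1, j - 1] + score[i - 1, j - 1]
            h = m
            p = 0
            if E[i, j] > h:
                h = E[i, j]
                p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            H[i, j] = h
            ptrH[i, j] = p
            # free trailing gaps: best path ends on a match cell
            if p == 0 and m > best:
                best = m
                bi = i
                bj = j

    npairs = 0
    qi = np.empty(min(P, T), dtype=np.int64)
    ti = np.empty(min(P, T), dtype=np.int64)
    if best <= _FORBIDDEN / 2:
        return qi[:0], ti[:0]
    i, j = bi, bj
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 and j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                qi[npairs] = i - 1
                ti[npairs] = j - 1
                npairs += 1
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 1:
            state = 0 if ptrE[i, j] == 0 else 1
            j -= 1
        else:
            state = 0 if ptrF[i, j] == 0 else 2
            i -= 1
    return qi[:npairs][::-1].copy(), ti[:npairs][::-1].copy()


def _tm_d0(L: int) -> float:
    # deferred to scoring.tm_d0 publicly; duplicated here would risk drift
    from .scoring import tm_d0

    return tm_d0(L)


def _pair_score_matrix(pu_xyz: np.ndarray, target_xyz: np.ndarray,
                       mask: np.ndarray, d0: float) -> np.ndarray:
    d2 = cdist(pu_xyz, target_xyz, "sqeuclidean")
    score = 1.0 / (1.0 + d2 / (d0 * d0))
    score[:, mask] = _FORBIDDEN
    return score


def _dp_round(pu_xyz, target_xyz, mask, d0, open_t, ext_t):
    score = _pair_score_matrix(pu_xyz, target_xyz, mask, d0)
    qi, ti = _gotoh(score, open_t, ext_t, GAP_OPEN, GAP_EXT)
    return qi, ti


def _unmasked_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) intervals of consecutive unmasked residues."""
    runs = []
    start = None
    for j, m in enumerate(mask):
        if not m and start is None:
            start = j
        elif m and start is not None:
            runs.append((start, j))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def _pick_seeds(scored: list[tuple[float, int, RigidTransform]],
                n_best: int, stride: int) -> list[RigidTransform]:
    """Lowest-RMSD seeds plus a strided coverage subset, in stable order."""
    by_rmsd = sorted(scored, key=lambda s: (s[0], s[1]))[:n_best]
    keep = {s[1] for s in by_rmsd}
    keep.update(s[1] for s in scored[::max(1, stride)])
    return [tr for _, order, tr in scored if order in keep]


def _seed_transforms(pu_xyz: np.ndarray, target_xyz: np.ndarray,
                     runs: list[tuple[int, int]]) -> list[RigidTransform]:
    """Gapless threading seeds: full-window superpositions over every
    unmasked run, plus 8-residue fragment seeds.

    Every window is scored by Kabsch RMSD; the best-fitting windows are kept
    (they catch exact registers, which matters for periodic structures) along
    with a strided subset for coverage.
    """
    P = pu_xyz.shape[0]
    order = 0
    full: list[tuple[float, int, RigidTransform]] = []
    for rs, re in runs:
        R = re - rs
        W = min(P, R)
        if W < 3:
            continue
        for ts in range(rs, re - W + 1):
            tr, rmsd = kabsch(pu_xyz[:W], target_xyz[ts:ts + W])
            full.append((rmsd, order, tr))
            order += 1
            if W < P:  # anchor the PU tail as well when the run is short
                tr, rmsd = kabsch(pu_xyz[P - W:], target_xyz[ts:ts + W])
                full.append((rmsd, order, tr))
                order += 1
    seeds = _pick_seeds(full, n_best=5, stride=max(1, min(P, 12) // 2)) if full else []

    frag = 8
    if P >= frag:
        frags: list[tuple[float, int, RigidTransform]] = []
        pu_offsets = sorted({0, (P - frag) // 2, P - frag})
        for rs, re in runs:
            if re - rs < frag:
                continue
            for ts in range(rs, re - frag + 1, 2):
                for qs in pu_offsets:
                    tr, rmsd = kabsch(pu_xyz[qs:qs + frag], target_xyz[ts:ts + frag])
                    frags.append((rmsd, order, tr))
                    order += 1
        seeds.extend(_pick_seeds(frags, n_best=10, stride=6))
    return seeds


def align_pu_to_target(pu_coords: np.ndarray, target, mask: np.ndarray,
                       pu=None, min_pu_size: int = DEFAULT_MIN_PU_SIZE,
                       max_iter: int = 30) -> PUAlignment:
    """Fit one Protein Unit onto the unmasked portion of the target.

    Parameters
    ----------
    pu_coords:
        (P, 3) Cα coordinates of the PU (a contiguous slice of the peeled
        chain).
    target:
        Target :class:`~pualign.structure_io.CaTrace`.
    mask:
        Boolean vector over target residues; ``True`` marks residues already
        consumed by previously placed PUs, unavailable here.
    pu:
        Optional :class:`~pualign.peeling.ProteinUnit` used to offset mapping
        indices into peeled-chain coordinates and label the result.

    Returns
    -------
    PUAlignment
        Order-preserving mapping onto unmasked target residues with the rigid
        transform that realizes it; empty (local_tm 0) when fewer than
        ``min_pu_size`` target residues remain unmasked, which signals the
        order explorer to prune the branch.
    """
    pu_xyz = np.asarray(pu_coords, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    target_xyz = target.coords
    P = pu_xyz.shape[0]
    n_unmasked = int((~mask).sum())
    offset = pu.start if pu is not None else 0
    from .peeling import ProteinUnit

    pu_obj = pu if pu is not None else ProteinUnit(0, P, 0)
    if n_unmasked < min_pu_size or P < 3:
        return PUAlignment.empty(pu_obj)

    d0 = max(0.5, _tm_d0(min(P, n_unmasked)))
    l_norm = min(P, n_unmasked)
    open_t = np.where(mask, 0.0, GAP_OPEN)
    ext_t = np.where(mask, 0.0, GAP_EXT)

    runs = _unmasked_runs(mask)
    seeds = _seed_transforms(pu_xyz, target_xyz, runs)
    if not seeds:
        return PUAlignment.empty(pu_obj)

    best_tm = -1.0
    best: tuple[np.ndarray, np.ndarray, RigidTransform, np.ndarray] | None = None
    for seed in seeds:
        tr = seed
        prev_pairs: tuple | None = None
        seed_best_tm = -1.0
        seed_best = None
        for _ in range(max_iter):
            moved = tr.apply(pu_xyz)
            qi, ti = _dp_round(moved, target_xyz, mask, d0, open_t, ext_t)
            if len(qi) < 3:
                break
            tr, _ = kabsch(pu_xyz[qi], target_xyz[ti])
            d = np.linalg.norm(tr.apply(pu_xyz[qi]) - target_xyz[ti], axis=1)
            tm = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm)
            if tm > seed_best_tm + 1e-12:
                seed_best_tm = tm
                seed_best = (qi, ti, tr, d)
            else:
                break  # no strict improvement: converged
            key = (qi.tobytes(), ti.tobytes())
            if key == prev_pairs:
                break
            prev_pairs = key
        if seed_best is not None and seed_best_tm > best_tm + 1e-12:
            best_tm = seed_best_tm
            best = seed_best

    if best is None:
        return PUAlignment.empty(pu_obj)
    qi, ti, tr, d = best
    assert not mask[ti].any(), "mapping returned a masked target residue"
    pairs = tuple((int(q) + offset, int(t)) for q, t in zip(qi, ti))
    return PUAlignment(pu=pu_obj, mapping=ResidueMapping(pairs), transform=tr,
                       local_tm=best_tm, pair_distances=d)
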