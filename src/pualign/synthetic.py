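"""Synthetic Cα traces with known ground truth.

Generators for the structural situations a flexible aligner must handle —
circular permutations, hinge bends, insertions and repeats — built from ideal
helices and compact globular random walks. Every generator is deterministic
given its seed, and every ground-truth mapping is a bijection over the
residues both constructs share.

These traces are Cα-level caricatures: bond geometry is realistic (3.8 Å
steps) but there is no excluded volume, no side chains, and no secondary
structure beyond the helical segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import CaTrace

CA_STEP = 3.8  # Å, consecutive Cα distance
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å

DEFAULT_NOISE_SIGMA = 0.3  # Å, small enough that ground truth stays recoverable


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic structure pair."""

    kind: str  # helix | two_domain | circular_permutation | hinge_bend | insertion | repeat
    lengths: tuple[int, ...] = (40, 40)
    angle: float = 45.0
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    seed: int = 0


def trace_from_coords(coords: np.ndarray, chain_id: str = "A",
                      sequence: str | None = None) -> CaTrace:
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    seq = sequence or "A" * n
    residues = tuple((i + 1, "", seq[i]) for i in range(n))
    return CaTrace(chain_id=chain_id, residues=residues, coords=coords)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via QR of a Gaussian matrix."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _add_noise(coords: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma <= 0:
        return coords
    return coords + rng.normal(scale=sigma, size=coords.shape)


def make_helix(n: int, seed: int = 0, noise_sigma: float = 0.0) -> CaTrace:
    """Ideal α-helix Cα trace: 1.5 Å rise, 100°/residue, 2.3 Å radius."""
    if n < 4:
        raise ValueError("n must be >= 4")
    rng = np.random.default_rng(seed)
    i = np.arange(n)
    theta = np.deg2rad(HELIX_TWIST) * i
    coords = np.column_stack([
        HELIX_RADIUS * np.cos(theta),
        HELIX_RADIUS * np.sin(theta),
        HELIX_RISE * i,
    ])
    return trace_from_coords(_add_noise(coords, noise_sigma, rng))


def _globule(n: int, rng: np.random.Generator) -> np.ndarray:
    """Compact self-returning random walk: 3.8 Å steps biased back toward the
    centroid once outside a radius scaling as n^(1/3)."""
    radius = 3.0 * n ** (1.0 / 3.0)
    coords = np.zeros((n, 3))
    pos = np.zeros(3)
    for i in range(1, n):
        step = rng.normal(size=3)
        if np.linalg.norm(pos) > radius:
            step = step - 0.9 * pos / np.linalg.norm(pos) * np.linalg.norm(step)
        step = step / np.linalg.norm(step) * CA_STEP
        pos = pos + step
        coords[i] = pos
    return coords


def make_globule(n: int, seed: int = 0, noise_sigma: float = 0.0) -> CaTrace:
    """Compact globular domain (random walk confined to a sphere)."""
    if n < 4:
        raise ValueError("n must be >= 4")
    rng = np.random.default_rng(seed)
    return trace_from_coords(_add_noise(_globule(n, rng), noise_sigma, rng))


def make_two_domain(n1: int, n2: int, seed: int = 0,
                    noise_sigma: float = 0.0, separation: float = 16.0) -> CaTrace:
    """Two compact domains joined end to end, centroids ``separation`` Å apart.

    The separation default (16 Å, i.e. twice the 8 Å contact midpoint) keeps
    cross-domain contact probabilities low so peeling finds the junction.
    """
    rng = np.random.default_rng(seed)
    d1 = _globule(n1, rng)
    d2 = _globule(n2, rng) @ _random_rotation(rng).T
    # place domain 2 so its first residue continues the chain at one CA step,
    # pushed outward from domain 1's centroid
    away = d1[-1] - d1.mean(axis=0)
    away = away / max(np.linalg.norm(away), 1e-9)
    shift = d1[-1] + away * CA_STEP - d2[0]
    d2 = d2 + shift
    # stretch until the centroids are separated enough
    for _ in range(50):
        gap = d2.mean(axis=0) - d1.mean(axis=0)
        if np.linalg.norm(gap) >= separation:
            break
        d2 = d2 + away * 1.0
    coords = np.vstack([d1, d2])
    return trace_from_coords(_add_noise(coords, noise_sigma, rng))


def make_circular_permutation(base: CaTrace, cut: int, seed: int = 0,
                              noise_sigma: float = 0.0,
                              min_part: int = 4) -> tuple[CaTrace, list[tuple[int, int]]]:
    """Swap the chain halves around ``cut`` and re-orient the whole.

    The new trace is concat(base[cut:], base[:cut]); both halves keep their
    internal geometry, are re-oriented together by one random rigid motion
    (each half is rigid relative to the other up to the new junction), and the
    second half is translated so the junction is one CA step long. Ground
    truth maps each source residue to its position in the permuted chain, as
    (base index, permuted index) pairs.
    """
    n = len(base)
    if not (min_part <= cut <= n - min_part):
        raise ValueError("cut out of range")
    rng = np.random.default_rng(seed)
    half1 = base.coords[cut:].copy()  # becomes the new N-terminal part
    half2 = base.coords[:cut].copy()
    # independent re-orientation of the halves
    R1, R2 = _random_rotation(rng), _random_rotation(rng)
    half1 = (half1 - half1.mean(axis=0)) @ R1.T
    half2 = (half2 - half2.mean(axis=0)) @ R2.T
    # join: start of half2 one CA step beyond the end of half1, pointing away
    away = half1[-1] - half1.mean(axis=0)
    away = away / max(np.linalg.norm(away), 1e-9)
    half2 = half2 + (half1[-1] + away * CA_STEP - half2[0])
    coords = _add_noise(np.vstack([half1, half2]), noise_sigma, rng)
    permuted = trace_from_coords(coords, chain_id="B")
    ground_truth = [(cut + i, i) for i in range(n - cut)] + \
                   [(i, (n - cut) + i) for i in range(cut)]
    return permuted, sorted(ground_truth)


def make_hinge_bend(base: CaTrace, hinge: int, angle: float, seed: int = 0,
                    noise_sigma: float = 0.0) -> tuple[CaTrace, list[tuple[int, int]]]:
    """Rotate the part of the chain after ``hinge`` about the hinge residue.

    Residues past the hinge are rotated by ``angle`` degrees about a random
    axis through the hinge Cα, so both parts stay internally rigid and the
    chain stays connected. Ground truth is the identity mapping.
    """
    n = len(base)
    if not (0 < hinge < n):
        raise ValueError("hinge must split the chain")
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    theta = np.deg2rad(angle)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
    center = base.coords[hinge]
    coords = base.coords.copy()
    coords[hinge:] = (coords[hinge:] - center) @ R.T + center
    coords = _add_noise(coords, noise_sigma, rng)
    bent = trace_from_coords(coords, chain_id="B")
    return bent, [(i, i) for i in range(n)]


def make_insertion(base: CaTrace, at: int, length: int, seed: int = 0,
                   noise_sigma: float = 0.0) -> tuple[CaTrace, list[tuple[int, int]]]:
    """Insert a helical excursion of ``length`` residues at position ``at``.

    Ground truth maps each base residue to its shifted position.
    """
    if not (0 < at < len(base)):
        raise ValueError("insertion point must be interior")
    rng = np.random.default_rng(seed)
    helix = make_helix(max(4, length), seed=seed).coords[:length]
    anchor = base.coords[at - 1]
    direction = anchor - base.coords.mean(axis=0)
    direction /= max(np.linalg.norm(direction), 1e-9)
    helix = helix @ _random_rotation(rng).T
    helix = helix + (anchor + direction * CA_STEP - helix[0])
    coords = np.vstack([base.coords[:at], helix, base.coords[at:]])
    coords = _add_noise(coords, noise_sigma, rng)
    new = trace_from_coords(coords, chain_id="B")
    gt = [(i, i) for i in range(at)] + \
         [(i, i + length) for i in range(at, len(base))]
    return new, gt


def make_repeat(unit: CaTrace, n_copies: int, seed: int = 0,
                noise_sigma: float = 0.0) -> CaTrace:
    """Tandem repeat: rigid copies of ``unit`` chained end to end."""
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    rng = np.random.default_rng(seed)
    blocks = [unit.coords.copy()]
    for _ in range(n_copies - 1):
        prev = blocks[-1]
        nxt = unit.coords @ _random_rotation(rng).T
        away = prev[-1] - prev.mean(axis=0)
        away /= max(np.linalg.norm(away), 1e-9)
        nxt = nxt + (prev[-1] + away * CA_STEP - nxt[0])
        blocks.append(nxt)
    coords = _add_noise(np.vstack(blocks), noise_sigma, rng)
    return trace_from_coords(coords)


def build_fixture(spec: FixtureSpec):
    """Build (query, target, ground_truth) for a FixtureSpec.

    ``ground_truth`` is a list of (query index, target index) pairs, or None
    for kinds without a paired construct.
    """
    rng = np.random.default_rng(spec.seed)
    sub = int(rng.integers(0, 2 ** 31 - 1))
    if spec.kind == "helix":
        return make_helix(spec.lengths[0], seed=spec.seed,
                          noise_sigma=spec.noise_sigma), None, None
    if spec.kind == "two_domain":
        return make_two_domain(*spec.lengths[:2], seed=spec.seed,
                               noise_sigma=spec.noise_sigma), None, None
    base = make_two_domain(*spec.lengths[:2], seed=spec.seed)
    if spec.kind == "circular_permutation":
        permuted, gt = make_circular_permutation(
            base, cut=spec.lengths[0], seed=sub, noise_sigma=spec.noise_sigma)
        return base, permuted, gt
    if spec.kind == "hinge_bend":
        bent, gt = make_hinge_bend(base, hinge=spec.lengths[0], angle=spec.angle,
                                   seed=sub, noise_sigma=spec.noise_sigma)
        return base, bent, gt
    if spec.kind == "insertion":
        ins_len = spec.lengths[2] if len(spec.lengths) > 2 else 12
        new, gt = make_insertion(base, at=spec.lengths[0], length=ins_len,
                                 seed=sub, noise_sigma=spec.noise_sigma)
        return base, new, gt
    if spec.kind == "repeat":
        unit = make_globule(spec.lengths[0], seed=spec.seed)
        rep = make_repeat(unit, n_copies=max(2, spec.lengths[1] // spec.lengths[0]),
                          seed=sub, noise_sigma=spec.noise_sigma)
        return unit, rep, None
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
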