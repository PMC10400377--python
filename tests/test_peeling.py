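import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pualign.peeling import (
    ContactMatrix,
    ProteinUnit,
    PeelingLevel,
    contact_probability_matrix,
    partition_index,
    peel,
    select_level,
)
from pualign.synthetic import make_globule, make_helix, make_two_domain, trace_from_coords
from tests.conftest import random_rigid


def scalar_logistic(d, d0, slope):
    return 1.0 / (1.0 + math.exp((d - d0) / slope))


class TestContactMatrix:
    def test_midpoint_distance_gives_half(self):
        coords = np.array([[0, 0, 0], [8.0, 0, 0], [40.0, 0, 0]])
        cm = contact_probability_matrix(trace_from_coords(coords), 8.0, 1.5)
        assert cm.probs[0, 1] == pytest.approx(0.5)

    def test_zero_distance_near_one(self):
        coords = np.array([[0, 0, 0], [0, 0, 0], [40.0, 0, 0]])
        cm = contact_probability_matrix(trace_from_coords(coords), 8.0, 1.5)
        assert cm.probs[0, 1] == pytest.approx(scalar_logistic(0, 8.0, 1.5))
        assert cm.probs[0, 1] > 0.99

    def test_collinear_points_match_scalar_evaluation(self):
        coords = np.array([[3.8 * i, 0, 0] for i in range(4)], dtype=float)
        cm = contact_probability_matrix(trace_from_coords(coords), 8.0, 1.5)
        for i in range(4):
            for j in range(4):
                expected = (1.0 if i == j
                            else scalar_logistic(3.8 * abs(i - j), 8.0, 1.5))
                assert cm.probs[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_bounded_and_diagonal_one(self):
        cm = contact_probability_matrix(make_globule(30, seed=3))
        np.testing.assert_allclose(cm.probs, cm.probs.T)
        assert np.all((cm.probs >= 0) & (cm.probs <= 1))
        np.testing.assert_allclose(np.diag(cm.probs), 1.0)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_rotation_invariance(self, seed):
        trace = make_globule(25, seed=seed)
        rng = np.random.default_rng(seed + 1)
        R, t = random_rigid(rng)
        rotated = trace_from_coords(trace.coords @ R.T + t)
        cm1 = contact_probability_matrix(trace)
        cm2 = contact_probability_matrix(rotated)
        np.testing.assert_allclose(cm1.probs, cm2.probs, atol=1e-9)


class TestPartitionIndex:
    def test_block_diagonal_gives_one(self):
        n = 20
        probs = np.zeros((n, n))
        probs[:10, :10] = 0.8
        probs[10:, 10:] = 0.8
        np.fill_diagonal(probs, 1.0)
        cm = ContactMatrix(probs=probs)
        assert partition_index(cm, [(0, 10), (10, 20)], min_pu_size=5) == 1.0

    def test_matches_bruteforce_scan_on_uniform_matrix(self):
        n = 30
        probs = np.full((n, n), 0.3)
        np.fill_diagonal(probs, 1.0)
        cm = ContactMatrix(probs=probs)

        def brute_pi(c):  # scalar-loop oracle
            k_cross = sum(probs[i, j] for i in range(0, c) for j in range(c, n))
            k_aa = sum(probs[i, j] for i in range(0, c) for j in range(0, c))
            k_bb = sum(probs[i, j] for i in range(c, n) for j in range(c, n))
            return 1.0 - k_cross ** 2 / (k_aa * k_bb)

        cuts = range(5, n - 5 + 1)
        pis = {c: partition_index(cm, [(0, c), (c, n)], min_pu_size=5) for c in cuts}
        for c in cuts:
            assert pis[c] == pytest.approx(brute_pi(c), abs=1e-10)
        best = max(cuts, key=lambda c: pis[c])
        brute_best = max(cuts, key=brute_pi)
        assert pis[best] == pytest.approx(brute_pi(brute_best), abs=1e-10)

    def test_bounds_and_three_way(self):
        cm = contact_probability_matrix(make_globule(45, seed=9))
        pi2 = partition_index(cm, [(0, 20), (20, 45)], min_pu_size=10)
        pi3 = partition_index(cm, [(0, 15), (15, 30), (30, 45)], min_pu_size=10)
        assert 0.0 <= pi2 <= 1.0
        assert 0.0 <= pi3 <= 1.0

    def test_short_segment_rejected(self):
        cm = contact_probability_matrix(make_globule(40, seed=0))
        with pytest.raises(ValueError, match="min_pu_size"):
            partition_index(cm, [(0, 5), (5, 40)], min_pu_size=15)


class TestPeel:
    def test_linker_between_helices_is_cut(self):
        # two ideal 20-residue helices joined by a 4-residue extended linker
        h1 = make_helix(20).coords
        rng = np.random.default_rng(5)
        direction = np.array([1.0, 0.8, 0.2])
        direction /= np.linalg.norm(direction)
        linker = np.array([h1[-1] + direction * 3.8 * (i + 1) for i in range(4)])
        R, _ = random_rigid(rng)
        h2 = make_helix(20).coords @ R.T
        h2 = h2 + (linker[-1] + direction * 3.8 - h2[0])
        trace = trace_from_coords(np.vstack([h1, linker, h2]))
        levels = peel(trace, max_units=2)
        cut = levels[1].boundaries[0]
        assert 18 <= cut <= 26  # linker spans indices 20..23, +/- 2

    def test_first_cut_matches_exhaustive_scan(self):
        for seed in range(5):
            trace = make_two_domain(25, 25, seed=seed)
            n = len(trace)
            levels = peel(trace, max_units=2)
            if len(levels) < 2 or levels[1].n_units != 2:
                continue
            cm = contact_probability_matrix(trace)
            pis = {c: partition_index(cm, [(0, c), (c, n)])
                   for c in range(15, n - 15 + 1)}
            best_pi = max(pis.values())
            assert pis[levels[1].boundaries[0]] == pytest.approx(best_pi, abs=1e-12)

    def test_too_short_chain_returns_single_level(self):
        levels = peel(make_globule(20, seed=0), min_pu_size=15)
        assert len(levels) == 1
        assert levels[0].n_units == 1

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(st.integers(0, 10 ** 6), st.integers(45, 100))
    def test_tiling_nestedness_and_monotone_counts(self, seed, n):
        trace = make_globule(n, seed=seed)
        levels = peel(trace, max_units=7)
        for lv in levels:
            assert lv.units[0].start == 0 and lv.units[-1].end == n
            for a, b in zip(lv.units, lv.units[1:]):
                assert a.end == b.start
        for prev, nxt in zip(levels, levels[1:]):
            assert set(prev.boundaries) <= set(nxt.boundaries)  # nested
            assert nxt.n_units - prev.n_units in (1, 2)
            assert all(len(u) >= 15 for u in nxt.units)


class TestSelectLevel:
    def _fake_levels(self, counts, n=200):
        levels = []
        for depth, c in enumerate(counts):
            bounds = np.linspace(0, n, c + 1).astype(int)
            units = tuple(ProteinUnit(a, b, i)
                          for i, (a, b) in enumerate(zip(bounds, bounds[1:])))
            levels.append(PeelingLevel(units=units, depth=depth,
                                       partition_quality=1.0))
        return levels

    def test_level1_admits_2_and_3_units(self):
        levels = self._fake_levels([1, 2, 3, 4, 5])
        picked = select_level(levels, 1)
        assert sorted(lv.n_units for lv in picked) == [2, 3]

    def test_level4_admits_7_units(self):
        levels = self._fake_levels([1, 2, 3, 4, 5, 6, 7])
        picked = select_level(levels, 4)
        assert [lv.n_units for lv in picked] == [7]

    def test_fallback_to_deepest_with_warning(self):
        levels = self._fake_levels([1, 2, 3, 4, 5])
        with pytest.warns(UserWarning, match="deepest"):
            picked = select_level(levels, 3)
        assert [lv.n_units for lv in picked] == [5]
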