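"""Unit and property tests for the MIC / PCC / eMIC kernel."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emicconn import (
    DegenerateInputError,
    GridPartition,
    PairedSample,
    SearchBudgetError,
    emic,
    grid_mutual_information,
    mic,
    mic_oracle,
    normalized_grid_score,
    pcc,
)
from emicconn.association import resolution_budget


def _plugin_mi(cells):
    """Independent plug-in MI oracle over (col, row) cell assignments."""
    n = len(cells)
    joint = Counter(cells)
    px = Counter(c for c, _ in cells)
    py = Counter(r for _, r in cells)

    def h(counter):
        return -sum((c / n) * math.log2(c / n) for c in counter.values())

    return h(px) + h(py) - h(joint)


class TestGridMutualInformation:
    def test_deterministic_diagonal_is_one_bit(self):
        x = np.r_[np.full(50, 0.2), np.full(50, 0.8)]
        y = np.r_[np.full(50, 0.2), np.full(50, 0.8)]
        grid = GridPartition([0.5], [0.5])
        assert grid_mutual_information(PairedSample(x, y), grid) == pytest.approx(1.0)

    def test_uniform_occupancy_is_independent(self):
        pts = [(a, b) for a in (0.2, 0.8) for b in (0.2, 0.8) for _ in range(25)]
        x, y = map(np.array, zip(*pts))
        grid = GridPartition([0.5], [0.5])
        assert grid_mutual_information(PairedSample(x, y), grid) == pytest.approx(0.0)

    def test_eight_points_match_plugin_entropy_oracle(self):
        x = np.array([0.1, 0.2, 0.45, 0.5, 0.55, 0.8, 0.85, 0.9])
        y = np.array([0.3, 0.7, 0.2, 0.9, 0.25, 0.8, 0.1, 0.6])
        grid = GridPartition(x_edges=[0.4, 0.7], y_edges=[0.5])  # 3 cols x 2 rows
        cells = [
            (int(np.searchsorted([0.4, 0.7], xi, side="right")),
             int(np.searchsorted([0.5], yi, side="right")))
            for xi, yi in zip(x, y)
        ]
        expected = _plugin_mi(cells)
        got = grid_mutual_information(PairedSample(x, y), grid)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_rejects_degenerate_grids_and_samples(self):
        with pytest.raises(ValueError):
            GridPartition([], [0.5])
        with pytest.raises(ValueError):
            GridPartition([0.5, 0.4], [0.5])
        with pytest.raises(ValueError):
            PairedSample(np.arange(3), np.arange(3))


class TestNormalizedGridScore:
    def test_noiseless_identity_two_by_two(self):
        x = np.linspace(0.0, 1.0, 50)
        assert normalized_grid_score(PairedSample(x, x), 2, 2) == pytest.approx(1.0)

    def test_independent_sample_scores_low(self):
        rng = np.random.default_rng(3)
        s = PairedSample(rng.standard_normal(50), rng.standard_normal(50))
        assert normalized_grid_score(s, 2, 2, exhaustive=True) < 0.2

    @pytest.mark.parametrize("shape", [(2, 2), (2, 3), (3, 2)])
    def test_matches_exhaustive_cut_enumeration_small_n(self, shape):
        """The exact search equals direct enumeration of all cut placements."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(6, 11))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            s = PairedSample(x, y)
            nx, ny = shape
            xs, ys = np.sort(x), np.sort(y)
            best = 0.0
            for xc in itertools.combinations(range(1, n), nx - 1):
                for yc in itertools.combinations(range(1, n), ny - 1):
                    xe = [(xs[c - 1] + xs[c]) / 2 for c in xc]
                    ye = [(ys[c - 1] + ys[c]) / 2 for c in yc]
                    v = grid_mutual_information(s, GridPartition(xe, ye))
                    best = max(best, v)
            expected = best / math.log2(min(nx, ny))
            got = normalized_grid_score(s, nx, ny, exhaustive=True)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_refuses_oversized_grids(self):
        rng = np.random.default_rng(0)
        s = PairedSample(rng.standard_normal(30), rng.standard_normal(30))
        with pytest.raises(SearchBudgetError):
            normalized_grid_score(s, 100, 100, max_cells=1024)


class TestMic:
    def test_resolution_budget_floor(self):
        assert resolution_budget(100) == 15
        assert resolution_budget(175) == 22
        assert resolution_budget(10) == 4  # floor(10**0.6) = 3, floored at 4

    def test_noiseless_monotone_saturates(self):
        x = np.linspace(0, 1, 100)
        assert mic(x, x) == pytest.approx(1.0)
        assert mic(x, np.exp(x)) == pytest.approx(1.0)

    def test_noiseless_parabola_saturates(self):
        x = np.linspace(-1, 1, 200)
        assert mic(x, x**2) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry_exact(self, rng):
        for _ in range(5):
            a = rng.standard_normal(80)
            b = rng.standard_normal(80)
            assert mic(a, b) == mic(b, a)

    def test_rank_invariance_under_increasing_transforms(self, rng):
        a = rng.standard_normal(90)
        b = 0.6 * a + 0.8 * rng.standard_normal(90)
        m0 = mic(a, b)
        assert abs(mic(np.exp(a), b) - m0) <= 1e-12
        assert abs(mic(a, b**3) - m0) <= 1e-12
        assert abs(mic(2.0 * a + 3.0, 0.5 * b - 1.0) - m0) <= 1e-12

    def test_range_bound_on_noisy_pairs(self, rng):
        for _ in range(20):
            v = mic(rng.standard_normal(60), rng.standard_normal(60))
            assert 0.0 <= v <= 1.0

    def test_degenerate_input_raises(self):
        with pytest.raises(DegenerateInputError):
            mic(np.ones(20), np.arange(20.0))

    def test_null_mic_decreases_with_sample_size(self):
        """Median MIC of independent pairs shrinks as n grows."""
        medians = []
        for n in (50, 175, 500):
            rng = np.random.default_rng(n)
            vals = [
                mic(rng.standard_normal(n), rng.standard_normal(n))
                for _ in range(400)
            ]
            medians.append(np.median(vals))
        assert medians[0] > medians[1] > medians[2]


class TestOracleEquivalence:
    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_exact_search_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        if seed % 3 == 0:  # exercise ties
            x = rng.integers(0, 4, n).astype(float)
            y = rng.integers(0, 3, n).astype(float)
        else:
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        assert abs(mic(x, y, exhaustive=True) - mic_oracle(x, y)) <= 1e-12

    def test_oracle_refuses_large_samples(self, rng):
        with pytest.raises(SearchBudgetError):
            mic_oracle(rng.standard_normal(11), rng.standard_normal(11))

    def test_tied_sample_has_defined_value(self):
        # cuts may fall only between distinct values
        x = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        y = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        assert mic(x, y, exhaustive=True) == pytest.approx(mic_oracle(x, y), abs=1e-12)


class TestPccAndEmic:
    def test_pcc_reference_values(self, rng):
        x = rng.standard_normal(50)
        assert pcc(x, 2.0 * x + 3.0) == pytest.approx(1.0)
        assert pcc(x, -x) == pytest.approx(-1.0)
        xs = np.linspace(-1, 1, 101)
        assert pcc(xs, xs**2) == pytest.approx(0.0, abs=1e-12)

    def test_pcc_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pcc(np.zeros(10), np.arange(10.0))

    def test_emic_identity_and_saturation(self, rng):
        x = np.linspace(0, 1, 100)
        s = emic(x, x)
        assert s.emic == pytest.approx(0.0, abs=1e-12)
        xs = np.linspace(-1, 1, 200)
        s2 = emic(xs, xs**2)
        assert s2.pcc == pytest.approx(0.0, abs=1e-9)
        assert s2.mic == pytest.approx(1.0, abs=1e-9)
        assert s2.emic == pytest.approx(1.0, abs=1e-9)
        for _ in range(10):
            a, b = rng.standard_normal(70), rng.standard_normal(70)
            sc = emic(a, b)
            assert sc.pcc_squared == pytest.approx(sc.pcc**2, abs=1e-15)
            assert sc.emic + sc.pcc_squared == pytest.approx(sc.mic, abs=1e-12)

    def test_independent_pair_emic_near_zero(self):
        rng = np.random.default_rng(99)
        worst = max(
            abs(emic(rng.standard_normal(175), rng.standard_normal(175)).emic)
            for _ in range(50)
        )
        assert worst < 0.35
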