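"""Boundary derivation, the Victor-Purpura metric, and grid optimization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thetaflex.segmentation import (
    DegenerateBaselineError, R_THRESH_GRID, W_S_GRID, derive_boundaries,
    optimize_parameters, phoneme_distribution, postsynaptic_trace,
    syllable_midpoints, vp_distance,
)
from thetaflex.synthetic_speech import Transcription
from vp_oracle import vp_bruteforce


class TestPostsynapticTrace:
    def test_single_spike_kernel_shift_invariant(self):
        t1, P1 = postsynaptic_trace([[500.0]], 2000.0, w_s=50.0)
        t2, P2 = postsynaptic_trace([[900.0]], 2000.0, w_s=50.0)
        assert P1.max() == pytest.approx(P2.max(), rel=1e-6)
        assert t1[np.argmax(P1)] - 500.0 == pytest.approx(
            t2[np.argmax(P2)] - 900.0, abs=1.0)

    def test_linearity_two_simultaneous_spikes(self):
        _, P1 = postsynaptic_trace([[500.0]], 1500.0, w_s=50.0)
        _, P2 = postsynaptic_trace([[500.0], [500.0]], 1500.0, w_s=50.0)
        assert np.allclose(P2, 2.0 * P1)

    def test_exponential_decay_constant(self):
        # w_s = 50 -> decay constant 10 ms (before Gaussian smoothing)
        t, P = postsynaptic_trace([[500.0]], 1500.0, w_s=50.0, sigma=1e-9)
        i0 = np.argmax(P)
        i1 = i0 + 10
        assert P[i1] / P[i0] == pytest.approx(math.exp(-1.0), rel=0.05)

    def test_empty_trains_zero(self):
        _, P = postsynaptic_trace([[], []], 1000.0, w_s=50.0)
        assert np.all(P == 0.0)


class TestDeriveBoundaries:
    @staticmethod
    def _pulse_trace(candidates, height=2.0):
        t = np.arange(0.0, 2001.0, 1.0)
        P = np.zeros_like(t)
        P[(t >= 100) & (t <= 900)] = 1.0  # baseline activity
        for c in candidates:
            P[(t >= c) & (t < c + 5)] = height
        return t, P

    def test_refractory_removal_rule(self):
        # candidates {1100, 1110, 1150}: 1110 removed (follows 1100 by
        # 10 ms), 1150 retained (follows retained 1100 by 50 ms)
        t, P = self._pulse_trace([1100.0, 1110.0, 1150.0])
        bs = derive_boundaries(t, P, 1.5)
        assert list(bs.times) == [1100.0, 1150.0]

    def test_threshold_from_baseline_max(self):
        t, P = self._pulse_trace([1200.0])
        bs = derive_boundaries(t, P, 0.5)
        assert bs.threshold == pytest.approx(0.5)

    def test_no_crossings_empty(self):
        t, P = self._pulse_trace([])
        bs = derive_boundaries(t, P, 1.5)
        assert bs.times.size == 0

    def test_doubling_threshold_never_adds_boundaries(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 3000.0, 1.0)
        P = np.abs(rng.normal(1.0, 0.5, t.size))
        n_low = derive_boundaries(t, P, 0.4).times.size
        n_high = derive_boundaries(t, P, 0.8).times.size
        assert n_high <= n_low

    def test_degenerate_baseline_rejected(self):
        t = np.arange(0.0, 2000.0, 1.0)
        P = np.where(t > 1500, 1.0, 0.0)
        with pytest.raises(DegenerateBaselineError):
            derive_boundaries(t, P, 0.5)


class TestSyllableMidpoints:
    def test_successive_averages(self):
        assert list(syllable_midpoints([0.0, 200.0, 500.0])) == [100.0, 350.0]

    def test_count_is_n_minus_one(self):
        b = np.sort(np.random.default_rng(1).uniform(0, 1000, 9))
        assert syllable_midpoints(b).size == 8

    def test_needs_two(self):
        with pytest.raises(ValueError):
            syllable_midpoints([100.0])


class TestVPDistance:
    def test_single_shifted_boundary(self):
        s = vp_distance([100.0], [110.0], tau=50.0)
        assert s.d == pytest.approx(0.2)
        assert s.matches == 1
        assert s.D == pytest.approx(math.log(0.2))

    def test_identical_sets_flagged_perfect(self):
        s = vp_distance([0.0, 200.0], [0.0, 200.0], tau=50.0)
        assert s.d == 0.0
        assert s.D == -math.inf

    def test_large_tau_limit_counts_difference(self):
        s = vp_distance([1.0, 2.0, 3.0], [4.0], tau=1e9)
        assert s.d == pytest.approx(abs(3 - 1), abs=1e-6)

    def test_small_tau_limit_counts_union(self):
        s = vp_distance([1.0, 2.0, 3.0], [4.0], tau=1e-9)
        assert s.d == pytest.approx(3 + 1)
        assert s.D == math.inf  # no sub-unit-cost move exists

    def test_deleting_matched_midpoint_costs_one(self):
        m = [100.0, 300.0, 500.0]
        t = [105.0, 295.0, 505.0]
        full = vp_distance(m, t, tau=50.0)
        dropped = vp_distance(m, t[:-1], tau=50.0)
        assert dropped.d == pytest.approx(full.d - 0.1 + 1.0)

    @given(st.lists(st.integers(0, 9), min_size=0, max_size=4),
           st.lists(st.integers(0, 9), min_size=0, max_size=4),
           st.sampled_from([0.5, 2.0, 5.0]))
    @settings(max_examples=150, deadline=None)
    def test_matches_bruteforce_oracle(self, m, t, tau):
        m = sorted(set(m))
        t = sorted(set(t))
        d_oracle, k_oracle = vp_bruteforce(m, t, tau)
        s = vp_distance(m, t, tau=tau)
        assert s.d == pytest.approx(d_oracle, abs=1e-9)
        assert s.matches == k_oracle

    @given(st.lists(st.floats(0, 1000, allow_nan=False), min_size=1,
                    max_size=5),
           st.lists(st.floats(0, 1000, allow_nan=False), min_size=1,
                    max_size=5))
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_tau_monotonicity(self, m, t):
        a = vp_distance(m, t, tau=30.0)
        b = vp_distance(t, m, tau=30.0)
        assert a.d == pytest.approx(b.d, abs=1e-9)
        wide = vp_distance(m, t, tau=300.0)
        assert wide.d <= a.d + 1e-9

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            vp_distance([1.0], [2.0], tau=0.0)


class TestOptimizeParameters:
    def test_grid_shape(self):
        assert len(W_S_GRID) == 11
        assert len(R_THRESH_GRID) == 7
        assert W_S_GRID[0] == 25 and W_S_GRID[-1] == 75
        assert R_THRESH_GRID[0] == pytest.approx(1 / 3)
        assert R_THRESH_GRID[-1] == pytest.approx(2 / 3)

    def test_single_cell_grid_returns_it(self):
        run = dict(spike_trains=[[500.0, 1200.0, 1400.0]] * 16,
                   duration=2000.0, midpoints=np.array([1200.0, 1400.0]))
        w, r, surface = optimize_parameters([run], w_s_grid=[50],
                                            r_thresh_grid=[0.5])
        assert (w, r) == (50.0, 0.5)
        assert len(surface) == 1

    def test_planted_optimum_recovered(self):
        # spikes exactly at midpoints: any threshold that transfers those
        # crossings wins; construct baseline so only r = 0.5 crosses cleanly
        rng = np.random.default_rng(3)
        runs = []
        for _ in range(3):
            mids = 1200.0 + np.arange(6) * 220.0
            trains = [list(mids + rng.normal(0, 2.0, mids.size))
                      for _ in range(16)]
            # sparse baseline spiking before onset
            for tr in trains[:4]:
                tr.append(500.0)
            runs.append(dict(spike_trains=trains, duration=2800.0,
                             midpoints=mids))
        w, r, surface = optimize_parameters(runs)
        best = surface.loc[surface.score.idxmin()]
        assert best.score < 0  # every boundary matches a distinct midpoint


class TestPhonemeDistribution:
    @staticmethod
    def _transcription():
        phonemes = [(0.0, 100.0, "s_0", "stop"),
                    (100.0, 300.0, "v_0", "vowel"),
                    (300.0, 400.0, "f_1", "fricative"),
                    (400.0, 600.0, "v_1", "vowel")]
        return Transcription(phonemes=phonemes,
                             syllable_boundaries=np.array([0.0, 300.0, 600.0]))

    def test_all_vowel_boundaries(self):
        dist = phoneme_distribution([150.0, 500.0], self._transcription())
        assert dist["vowel"] == 1.0

    def test_proportions_sum_to_one(self):
        dist = phoneme_distribution([50.0, 150.0, 350.0, 500.0],
                                    self._transcription())
        assert dist.sum() == pytest.approx(1.0)
        assert dist["stop"] == pytest.approx(0.25)

    def test_outside_boundary_is_other(self):
        dist = phoneme_distribution([900.0], self._transcription())
        assert dist["other"] == 1.0
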