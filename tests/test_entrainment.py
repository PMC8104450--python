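"""Phase extraction, the spike-rate-adjusted PLV, and delay-based estimates."""

import math

import numpy as np
import pytest

from thetaflex.entrainment import (
    PhaseSeries, delay_estimated_plv, is_locked, lower_limit_from_delay,
    morlet_phase, piecewise_pulse_phase, plv, prespike_activations,
    prespike_regression, pulse_width_to_frequency,
    spectral_peak_frequencies, speech_phase,
)
from thetaflex.stimuli import periodic_pulse_train


def _circular_corr(a, b):
    """Concentration of the phase difference between two phase series."""
    return np.abs(np.mean(np.exp(1j * (a - b))))


class TestMorletPhase:
    def test_cosine_phase_zero_at_peaks(self):
        dt, f = 1.0, 5.0
        t = np.arange(0, 6000.0, dt)
        sig = np.cos(2 * np.pi * f * t / 1000.0)
        ph = morlet_phase(sig, f, dt)
        # t = 3000 ms is a cosine peak well inside the valid region
        i = 3000
        assert ph.valid[i]
        assert abs(ph.phase[i]) < 1e-6

    def test_cosine_phase_tracks_true_phase(self):
        dt, f = 1.0, 4.0
        t = np.arange(0, 8000.0, dt)
        sig = np.cos(2 * np.pi * f * t / 1000.0)
        ph = morlet_phase(sig, f, dt)
        true = np.angle(np.exp(1j * 2 * np.pi * f * t / 1000.0))
        corr = _circular_corr(ph.phase[ph.valid], true[ph.valid])
        assert corr > 0.99

    def test_constant_signal_flagged(self):
        ph = morlet_phase(np.ones(5000), 5.0, 1.0)
        assert not ph.valid.any()

    def test_edges_flagged_invalid(self):
        ph = morlet_phase(np.cos(np.arange(5000) * 0.03), 5.0, 1.0)
        assert not ph.valid[0] and not ph.valid[-1]

    def test_bad_frequency_rejected(self):
        with pytest.raises(ValueError):
            morlet_phase(np.ones(100), -1.0, 1.0)


class TestPiecewisePhase:
    def test_quarter_turn_across_support(self):
        t = np.arange(0, 400.0, 0.1)
        ph = piecewise_pulse_phase([(100.0, 150.0)], t)
        assert ph.at(np.array([150.0]))[0] - ph.at(np.array([100.0]))[0] == \
            pytest.approx(math.pi / 2)

    def test_three_quarter_turn_across_gap(self):
        t = np.arange(0, 500.0, 0.1)
        ph = piecewise_pulse_phase([(100.0, 150.0), (300.0, 350.0)], t)
        assert ph.at(np.array([300.0]))[0] - ph.at(np.array([150.0]))[0] == \
            pytest.approx(3 * math.pi / 2)

    def test_full_cycle_per_pulse_and_monotone(self):
        t = np.arange(0, 2000.0, 0.5)
        supports = [(200.0 * i + 100.0, 200.0 * i + 150.0) for i in range(8)]
        ph = piecewise_pulse_phase(supports, t)
        assert np.all(np.diff(ph.phase) > 0)
        assert ph.at(np.array([supports[-1][1]]))[0] == \
            pytest.approx(2 * math.pi * 8)

    def test_matches_morlet_phase_for_periodic_train(self):
        dt = 0.5
        sig = periodic_pulse_train(5.0, 10000.0, 1.0, dt)
        t = np.arange(sig.trace.size) * dt
        pw = piecewise_pulse_phase(sig.supports, t)
        mo = morlet_phase(sig.trace, 5.0, dt)
        sel = mo.valid
        wrapped = np.angle(np.exp(1j * pw.phase[sel]))
        corr = _circular_corr(wrapped, mo.phase[sel])
        assert corr > 0.95

    def test_overlapping_supports_rejected(self):
        t = np.arange(0, 100.0, 1.0)
        with pytest.raises(ValueError):
            piecewise_pulse_phase([(10.0, 30.0), (20.0, 40.0)], t)


class TestSpeechPhase:
    def test_peak_selection_skips_delta_bulk(self):
        dt = 1.0
        t = np.arange(0, 10000.0, dt)
        sig = sum(a * np.cos(2 * np.pi * f * t / 1000.0)
                  for a, f in [(4.0, 1.5), (3.0, 4.0), (2.0, 6.0), (1.5, 8.0)])
        freqs = spectral_peak_frequencies(sig, dt)
        assert len(freqs) == 3
        assert sorted(round(f) for f in freqs) == [4, 6, 8]

    def test_pure_tone_fallback(self):
        dt = 1.0
        t = np.arange(0, 10000.0, dt)
        sig = np.cos(2 * np.pi * 1.5 * t / 1000.0)
        ph = speech_phase(sig, dt)
        assert len(ph.params["freqs"]) >= 1
        assert ph.params["freqs"][0] == pytest.approx(1.5, abs=0.3)

    def test_syllabic_envelope_dominant_mode(self):
        # 7 Hz bump train: dominant selected mode within 0.5 Hz of 7
        dt = 1.0
        t = np.arange(0, 10000.0, dt)
        sig = np.zeros_like(t)
        for c in np.arange(500.0, 9500.0, 1000.0 / 7.0):
            sig += np.exp(-0.5 * ((t - c) / 25.0) ** 2)
        ph = speech_phase(sig, dt)
        assert min(abs(f - 7.0) for f in ph.params["freqs"]) < 0.5

    def test_too_short_envelope_rejected(self):
        with pytest.raises(ValueError):
            speech_phase(np.ones(500), 1.0)


class TestPLV:
    @staticmethod
    def _series(phases, times=None):
        t = np.arange(phases.size, dtype=float)
        return PhaseSeries(t=t, phase=phases, method="morlet",
                           valid=np.ones(phases.size, dtype=bool))

    @pytest.mark.parametrize("n", [2, 5, 50])
    def test_identical_phases_give_one(self, n):
        ph = self._series(np.full(1000, 1.234))
        res = plv(np.linspace(10, 900, n), ph)
        assert res.plv == pytest.approx(1.0)

    def test_two_antiphase_spikes_give_minus_one(self):
        phases = np.zeros(1000)
        phases[500:] = math.pi
        res = plv(np.array([100.0, 700.0]), self._series(phases))
        assert res.plv == pytest.approx(-1.0)

    def test_single_spike_flagged_undefined(self):
        res = plv(np.array([100.0]), self._series(np.zeros(1000)))
        assert not res.defined

    @pytest.mark.parametrize("n", [5, 50, 500])
    def test_uniform_phases_expectation_zero(self, n):
        # the defining property of the spike-rate adjustment
        rng = np.random.default_rng(42)
        vals = []
        for _ in range(1000):
            ph = rng.uniform(-math.pi, math.pi, n)
            mrv = np.abs(np.exp(-1j * ph).mean())
            vals.append((n * mrv ** 2 - 1) / (n - 1))
        se = np.std(vals) / math.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se

    def test_lock_criterion(self):
        from thetaflex.entrainment import PLVResult
        good = PLVResult(0.7, 100, 0.8 + 0j, 1.0)
        weak = PLVResult(0.3, 100, 0.5 + 0j, 1.0)
        sparse = PLVResult(0.7, 100, 0.8 + 0j, 0.5)
        assert is_locked(good)
        assert not is_locked(weak)
        assert not is_locked(sparse)
        assert is_locked(sparse, spc_min=None)


class TestDelayEstimate:
    def test_constant_delay_inverts(self):
        assert lower_limit_from_delay(0.4) == pytest.approx(2.5)

    def test_synaptic_inhibition_closed_form(self):
        # delay = (1/4)(1/f) + 1/7 binds at f* = 21/4 = 5.25 Hz
        f_star = lower_limit_from_delay(lambda f: 0.25 / f + 1.0 / 7.0)
        assert f_star == pytest.approx(5.25, abs=1e-9)

    def test_indicator_map(self):
        grid = np.array([1.0, 2.0, 5.0, 10.0])
        assert np.array_equal(delay_estimated_plv(0.25, grid),
                              [0.0, 0.0, 1.0, 1.0])

    def test_censored_delay_locks_everywhere(self):
        grid = np.array([0.5, 1.0, 5.0])
        assert np.all(delay_estimated_plv(0.1, grid, censored=True) == 1.0)

    def test_width_frequency_map(self):
        # a duty-1/4 pulse of width w corresponds to f = 1/(4w)
        assert pulse_width_to_frequency(50.0) == pytest.approx(5.0)

    def test_invalid_delay_rejected(self):
        with pytest.raises(ValueError):
            lower_limit_from_delay(0.0)


class TestPrespike:
    def test_constant_gate_zero_differences(self, ms_tonic_trace):
        df = prespike_activations(ms_tonic_trace, ["s_SOM_RS"])
        # MS has no SOM cell: the synapse gate stays exactly 0
        assert np.all(df["s_SOM_RS"] == 0.0)
        assert np.all(df["d_s_SOM_RS"] == 0.0)
        assert np.all(df["d2_s_SOM_RS"] == 0.0)

    def test_support_exclusion_drops_forced_spikes(self, ms_tonic_trace):
        spikes = ms_tonic_trace.spikes
        window = (spikes[3] - 1.0, spikes[5] + 1.0)
        df = prespike_activations(ms_tonic_trace, ["q"],
                                  exclude_supports=[window])
        assert len(df) == spikes.size - 3

    def test_regression_requires_points(self):
        import pandas as pd
        df = pd.DataFrame({"x": [0.0, 1.0], "y": [0.0, 1.0]})
        with pytest.raises(ValueError):
            prespike_regression(df, "x", "y")
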