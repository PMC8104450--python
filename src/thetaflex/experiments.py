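"""Config-driven experiment orchestration: sweeps, probes, and surrogates.

Each runner executes a grid of independent simulation cells (model x
stimulus x gain x seed), computes phase-locking or segmentation measures,
and returns a long-format DataFrame; every row carries the seed and step
size so any cell can be reproduced in isolation.  Runtimes scale linearly
with grid size and simulation length; reduced grids and shorter durations
are the intended way to iterate quickly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .neuron_models import MODEL_NAMES, build_model
from .simulator import DEFAULT_DT, integrate, spike_triggered_pulse_probe
from .stimuli import (bandwidth_row, periodic_pulse_train, varied_pulse_train)
from .entrainment import (is_locked, lower_limit_from_delay, morlet_phase,
                          piecewise_pulse_phase, plv, speech_phase)
from .segmentation import (W_S_GRID, R_THRESH_GRID, derive_boundaries,
                           optimize_parameters, phoneme_distribution,
                           postsynaptic_trace, vp_distance)
from .synthetic_speech import generate_sentence

PHASE_STRIDE = 100   # phase extraction on a grid decimated to ~1 ms


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment grid."""

    experiment: str
    models: tuple = MODEL_NAMES
    frequencies: tuple = ()
    gains: tuple = (1.0,)
    rows: tuple = ()
    seeds: tuple = (1, 2, 3)
    duration: float = 30000.0
    dt: float = DEFAULT_DT
    analysis_start: float = 1000.0

    def validate(self):
        if not self.models or not self.gains or not self.seeds:
            raise ValueError("every grid dimension must be non-empty")
        return self

    def manifest(self) -> str:
        return json.dumps(asdict(self), default=list, sort_keys=True)


def _periodic_cell(model: str, freq: float, gain: float, seed: int,
                   duration: float, dt: float,
                   analysis_start: float) -> dict:
    cfg = build_model(model)
    stim = periodic_pulse_train(freq, duration, gain, dt)
    tr = integrate(cfg, stim, duration, dt, seed=seed, record_stride=PHASE_STRIDE)
    ph = morlet_phase(stim.trace[::PHASE_STRIDE], freq, dt * PHASE_STRIDE)
    # discard the transient second alongside wavelet edges
    ph.valid &= ph.t >= analysis_start
    res = plv(tr.spikes, ph)
    return dict(model=model, frequency=freq, gain=gain, seed=seed,
                plv=res.plv, spikes_per_cycle=res.spikes_per_cycle,
                n_spikes=res.n_spikes, dt=dt,
                locked=is_locked(res),
                locked_plv_only=is_locked(res, spc_min=None))


def run_periodic_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Spike-rate-adjusted PLV over (model, frequency, gain, seed) cells."""
    config.validate()
    rows = []
    for model in config.models:
        for freq in config.frequencies:
            for gain in config.gains:
                for seed in config.seeds:
                    rows.append(_periodic_cell(model, freq, gain, seed,
                                               config.duration, config.dt,
                                               config.analysis_start))
    return pd.DataFrame(rows)


def run_varied_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """PLV against quasi-rhythmic trains over bandwidth rows."""
    config.validate()
    out = []
    for model in config.models:
        cfg = build_model(model)
        for k in config.rows:
            row = bandwidth_row(k)
            for gain in config.gains:
                for seed in config.seeds:
                    stim = varied_pulse_train(row, config.duration, gain,
                                              config.dt, seed=seed)
                    tr = integrate(cfg, stim, config.duration, config.dt,
                                   seed=seed + 10000,
                                   record_stride=PHASE_STRIDE)
                    t = np.arange(stim.trace[::PHASE_STRIDE].size) * config.dt * PHASE_STRIDE
                    ph = piecewise_pulse_phase(stim.supports, t)
                    ph.valid &= t >= config.analysis_start
                    res = plv(tr.spikes, ph)
                    out.append(dict(model=model, bandwidth=row.bandwidth,
                                    row=k, gain=gain, seed=seed,
                                    plv=res.plv,
                                    spikes_per_cycle=res.spikes_per_cycle,
                                    n_spikes=res.n_spikes, dt=config.dt,
                                    locked=is_locked(res)))
    return pd.DataFrame(out)


def lowest_locked_frequency(df: pd.DataFrame, column: str = "locked",
                            min_seeds: int | None = None) -> float:
    """Lowest frequency locked at any gain by majority vote over seeds."""
    locked_freqs = []
    for (freq, gain), grp in df.groupby(["frequency", "gain"]):
        votes = grp[column].sum()
        need = (len(grp) // 2 + 1) if min_seeds is None else min_seeds
        if votes >= need:
            locked_freqs.append(freq)
    return min(locked_freqs) if locked_freqs else math.inf


def run_delay_probe(config: ExperimentConfig,
                    pulse_durations=(50.0,)) -> pd.DataFrame:
    """Spike-triggered single-pulse delays and Eq.-style locking predictions."""
    config.validate()
    rows = []
    for model in config.models:
        cfg = build_model(model)
        for width in pulse_durations:
            for gain in config.gains:
                for seed in config.seeds:
                    pr = spike_triggered_pulse_probe(
                        cfg, gain, pulse_duration=width, dt=config.dt,
                        seed=seed)
                    f_star = (math.nan if pr.censored
                              else lower_limit_from_delay(pr.delay))
                    rows.append(dict(model=model, pulse_width=width,
                                     gain=gain, seed=seed, delay=pr.delay,
                                     censored=pr.censored,
                                     predicted_f_star=f_star, dt=config.dt))
    return pd.DataFrame(rows)


def run_speech_surrogate(config: ExperimentConfig, n_syllables: int = 10,
                         syllable_rate: float = 5.0, noise_level: float = 0.05,
                         jitter_sigma: float = 0.3, n_sentences: int = 3,
                         profile_width: float = 2.0,
                         nucleus_width: float = 0.15,
                         consonant_level: float = 0.3,
                         w_s_grid=W_S_GRID, r_thresh_grid=R_THRESH_GRID,
                         optimize: bool = True):
    """Drive 16 unconnected model copies with synthetic speech envelopes.

    For each (model, gain, sentence): 16 parameter-identical, unconnected
    copies each receive one channel envelope as input current; per-channel
    speech-phase PLV and the full segmentation pipeline are computed.
    Returns (plv_table, segmentation_table, optimized_params).
    """
    config.validate()
    plv_rows, seg_runs = [], []
    for model in config.models:
        cfg = build_model(model)
        for s_idx in range(n_sentences):
            sent = generate_sentence(n_syllables, syllable_rate,
                                     noise_level=noise_level,
                                     jitter_sigma=jitter_sigma,
                                     profile_width=profile_width,
                                     nucleus_width=nucleus_width,
                                     consonant_level=consonant_level,
                                     seed=1000 + s_idx, dt=config.dt)
            duration = sent.duration
            midpoints = sent.transcription.syllable_midpoints
            stride = max(1, int(round(1.0 / config.dt)))
            for gain in config.gains:
                trains = []
                for ch in range(sent.envelopes.shape[0]):
                    env = sent.envelopes[ch] * gain
                    tr = integrate(cfg, env, duration, config.dt,
                                   seed=config.seeds[0] + 100 * ch,
                                   record_stride=10000)
                    trains.append(tr.spikes)
                    if gain > 0 and env.max() > 0:
                        try:
                            ph = speech_phase(env[::stride],
                                              config.dt * stride)
                            res = plv(tr.spikes, ph)
                            plv_rows.append(dict(
                                model=model, sentence=s_idx, channel=ch,
                                channel_khz=sent.channel_freqs[ch],
                                gain=gain, plv=res.plv,
                                n_spikes=res.n_spikes))
                        except ValueError:
                            pass
                seg_runs.append(dict(model=model, sentence=s_idx, gain=gain,
                                     spike_trains=trains, duration=duration,
                                     midpoints=midpoints, group=gain,
                                     transcription=sent.transcription))
    plv_df = pd.DataFrame(plv_rows)
    seg_rows, best_params = [], {}
    for model in config.models:
        runs = [r for r in seg_runs if r["model"] == model]
        if optimize:
            w_s, r_th, _ = optimize_parameters(runs, w_s_grid, r_thresh_grid)
        else:
            w_s, r_th = w_s_grid[0], r_thresh_grid[0]
        best_params[model] = (w_s, r_th)
        for run in runs:
            t, P = postsynaptic_trace(run["spike_trains"], run["duration"], w_s)
            try:
                bset = derive_boundaries(t, P, r_th, w_s=w_s)
            except Exception:
                continue
            score = vp_distance(bset.times, run["midpoints"])
            dist = phoneme_distribution(bset, run["transcription"])
            seg_rows.append(dict(model=model, sentence=run["sentence"],
                                 gain=run["gain"], w_s=w_s, r_thresh=r_th,
                                 n_boundaries=score.n_m,
                                 n_midpoints=score.n_t, d=score.d,
                                 matches=score.matches, D=score.D,
                                 vowel_fraction=dist["vowel"]))
    return plv_df, pd.DataFrame(seg_rows), best_params
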