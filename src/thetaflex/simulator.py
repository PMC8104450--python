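"""Fixed-step stochastic integration of the oscillator models.

Explicit Euler (Euler-Maruyama for the white-noise component of the tonic
drive) at a default step of 0.01 ms.  The tonic drive ramps linearly over the
first ``tau_trans`` = 500 ms; time-varying stimuli are injected into the RS
cell only.  Spikes are detected inline as upward threshold crossings (0 mV,
2 ms refractory) with linearly interpolated crossing times, and a snapshot of
the full state over the three steps preceding each RS spike is kept for the
pre-spike gating-variable analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .neuron_models import (
    IDX, N_STATE, STATE_NAMES, ModelConfig, _rhs, initial_state,
)

DEFAULT_DT = 0.01  # ms
SPIKE_THRESHOLD = 0.0  # mV
REFRACTORY = 2.0  # ms


class IntegrationError(RuntimeError):
    """Numerical blow-up (|V| > 200 mV) during integration."""


@dataclass
class SimulationTrace:
    """Result of one simulation run.

    ``states`` is sampled every ``record_stride`` steps; ``prespike`` holds,
    for each RS spike, the full state at one, two, and three integration
    steps before the detected threshold crossing (shape n_spikes x 3 x 13).
    """

    t: np.ndarray
    states: np.ndarray
    stim: np.ndarray
    spikes: np.ndarray       # RS spike times, ms
    spikes_som: np.ndarray   # SOM spike times, ms
    prespike: np.ndarray
    dt: float
    record_stride: int
    duration: float
    seed: int
    config: ModelConfig

    @property
    def V(self) -> np.ndarray:
        return self.states[:, IDX["V"]]

    def state(self, name: str) -> np.ndarray:
        return self.states[:, IDX[name]]

    def save_spikes(self, path) -> None:
        np.savetxt(path, self.spikes, fmt="%.4f")

    def save_states(self, path) -> None:
        header = "t," + ",".join(STATE_NAMES)
        np.savetxt(path, np.column_stack([self.t, self.states]),
                   delimiter=",", header=header, comments="")


@njit(cache=True)
def _run(p, y0, stim, dt, n_steps, noise, stride, rec,
         thresh, refr, spk_rs, spk_som, prespike):
    """Core integration loop.  Returns (n_rs, n_som, error_step)."""
    y = y0.copy()
    dydt = np.empty(N_STATE)
    prev1 = y0.copy()
    prev2 = y0.copy()
    prev3 = y0.copy()
    g_app = p[9]
    p_noise = p[10]
    tau_trans = p[11]
    sqrt_dt = math.sqrt(dt)
    n_rs = 0
    n_som = 0
    last_rs = -1e12
    last_som = -1e12
    max_rs = spk_rs.shape[0]
    max_som = spk_som.shape[0]
    nrec = rec.shape[0]
    for k in range(n_steps):
        if k % stride == 0:
            j = k // stride
            if j < nrec:
                for i in range(N_STATE):
                    rec[j, i] = y[i]
        t = k * dt
        ramp = t / tau_trans if t <= tau_trans else 1.0
        # tonic drive + stimulus; noise enters as g_app * p_noise * dW/dt
        I = g_app * ramp + stim[k]
        v_old = y[0]
        v_old_som = y[8]
        _rhs(y, p, I, dydt)
        for i in range(N_STATE):
            y[i] += dt * dydt[i]
        y[0] += g_app * p_noise * noise[k] * sqrt_dt / p[0]
        # clip gates to their invariant ranges against Euler overshoot
        for i in range(1, 7):
            if y[i] < 0.0:
                y[i] = 0.0
            elif y[i] > 1.0:
                y[i] = 1.0
        if y[7] < 0.0:
            y[7] = 0.0
        for i in range(9, 13):
            if y[i] < 0.0:
                y[i] = 0.0
            elif y[i] > 1.0:
                y[i] = 1.0
        t_new = (k + 1) * dt
        if abs(y[0]) > 200.0 or abs(y[8]) > 200.0:
            return n_rs, n_som, k
        if v_old < thresh <= y[0] and t_new - last_rs >= refr:
            frac = (thresh - v_old) / (y[0] - v_old)
            ts = t + frac * dt
            if n_rs < max_rs:
                spk_rs[n_rs] = ts
                for i in range(N_STATE):
                    prespike[n_rs, 0, i] = prev1[i]
                    prespike[n_rs, 1, i] = prev2[i]
                    prespike[n_rs, 2, i] = prev3[i]
            n_rs += 1
            last_rs = ts
        if v_old_som < thresh <= y[8] and t_new - last_som >= refr:
            frac = (thresh - v_old_som) / (y[8] - v_old_som)
            ts = t + frac * dt
            if n_som < max_som:
                spk_som[n_som] = ts
            n_som += 1
            last_som = ts
        for i in range(N_STATE):
            prev3[i] = prev2[i]
            prev2[i] = prev1[i]
            prev1[i] = y[i]
    if n_steps % stride == 0 and n_steps // stride < nrec:
        j = n_steps // stride
        for i in range(N_STATE):
            rec[j, i] = y[i]
    return n_rs, n_som, -1


def integrate(config: ModelConfig, stimulus=None, duration: float = 6000.0,
              dt: float = DEFAULT_DT, seed: int = 0, record_stride: int = 1,
              threshold: float = SPIKE_THRESHOLD,
              refractory: float = REFRACTORY) -> SimulationTrace:
    """Simulate one model for ``duration`` ms.

    ``stimulus`` may be ``None``, a raw current array sampled at ``dt``, or a
    :class:`~thetaflex.stimuli.StimulusSignal` (its trace is used).  The
    stimulus current is added to the RS cell only.  Reproducible given
    ``seed``; the same seed yields bit-identical traces.
    """
    if dt > 0.05:
        raise ValueError("dt must be <= 0.05 ms for stability of fast Na dynamics")
    n_steps = int(round(duration / dt))
    stim_arr = np.zeros(n_steps)
    if stimulus is not None:
        trace = stimulus.trace if hasattr(stimulus, "supports") else stimulus
        trace = np.asarray(trace, dtype=float)
        m = min(n_steps, trace.shape[0])
        stim_arr[:m] = trace[:m]
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n_steps) if config.p_noise > 0 else np.zeros(n_steps)
    y0 = initial_state(config)
    p = config.to_array()
    stride = int(record_stride)
    n_rec = n_steps // stride + 1
    rec = np.empty((n_rec, N_STATE))
    max_spk = int(duration / refractory) + 2
    spk_rs = np.empty(max_spk)
    spk_som = np.empty(max_spk)
    prespike = np.zeros((max_spk, 3, N_STATE))
    n_rs, n_som, err = _run(p, y0, stim_arr, dt, n_steps, noise, stride, rec,
                            threshold, refractory, spk_rs, spk_som, prespike)
    if err >= 0:
        raise IntegrationError(
            f"voltage blow-up at step {err} (t = {err * dt:.3f} ms)")
    t = np.arange(n_rec) * dt * stride
    return SimulationTrace(
        t=t, states=rec, stim=stim_arr[::stride][:n_rec].copy(),
        spikes=spk_rs[:n_rs].copy(), spikes_som=spk_som[:n_som].copy(),
        prespike=prespike[:n_rs].copy(), dt=dt, record_stride=stride,
        duration=duration, seed=seed, config=config,
    )


def detect_spikes(V: np.ndarray, t: np.ndarray,
                  threshold: float = SPIKE_THRESHOLD,
                  refractory: float = REFRACTORY) -> np.ndarray:
    """Upward threshold crossings with a refractory period.

    Standalone detector for externally supplied voltage traces; crossing
    times are linearly interpolated between samples.
    """
    V = np.asarray(V, dtype=float)
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("voltage trace contains non-finite values")
    above = V >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:])
    times = []
    last = -np.inf
    for i in idx:
        frac = (threshold - V[i]) / (V[i + 1] - V[i])
        ts = t[i] + frac * (t[i + 1] - t[i])
        if ts - last >= refractory:
            times.append(ts)
            last = ts
    return np.asarray(times)


def firing_rate(trace: SimulationTrace, t_start: float = 1000.0,
                t_end: float | None = None) -> float:
    """Mean RS firing rate in Hz over [t_start, t_end] ms."""
    if t_end is None:
        t_end = trace.duration
    n = np.count_nonzero((trace.spikes >= t_start) & (trace.spikes < t_end))
    return 1000.0 * n / (t_end - t_start)


# -- F-I characterization ---------------------------------------------------

THETA_ISI = (1000.0 / 12.0, 250.0)   # ms: ISIs in [83, 250) ms are theta-scale


@dataclass
class FICurvePoint:
    I_app: float
    rate: float          # Hz, over the analysis window
    rhythm: str          # quiescent / delta / MMO / theta / other


def classify_rhythm(isis: np.ndarray, minor_fraction: float = 0.2) -> str:
    """Rhythm class from the inter-spike-interval distribution.

    Intervals are binned into theta-scale ([83, 250) ms), delta-scale
    (>= 250 ms), and faster-than-theta.  MMOs — doublets spaced a theta
    period apart recurring at a delta rate — show substantial mass at BOTH
    the theta and delta scales (each >= ``minor_fraction``); otherwise the
    dominant scale names the class (fast-dominant spiking is "other").
    """
    isis = np.asarray(isis, dtype=float)
    if isis.size < 2:
        return "quiescent"
    frac_theta = np.mean((isis >= THETA_ISI[0]) & (isis < THETA_ISI[1]))
    frac_delta = np.mean(isis >= THETA_ISI[1])
    frac_fast = 1.0 - frac_theta - frac_delta
    if frac_theta >= minor_fraction and frac_delta >= minor_fraction:
        return "MMO"
    dominant = max(("theta", frac_theta), ("delta", frac_delta),
                   ("other", frac_fast), key=lambda kv: kv[1])[0]
    return dominant


def fi_curve(config: ModelConfig, drive_levels, duration: float = 6000.0,
             dt: float = DEFAULT_DT, seed: int = 0,
             analysis_start: float = 1000.0) -> list[FICurvePoint]:
    """Firing rate and rhythm class per tonic-drive level.

    Each level replaces the configured drive magnitude; the rate is measured
    over the final 5 s of a 6 s simulation (transient omitted).
    """
    drive_levels = list(drive_levels)
    if len(drive_levels) < 2:
        raise ValueError("need at least 2 drive levels")
    points = []
    for lvl in drive_levels:
        cfg = ModelConfig(**{**config.to_dict(), "g_app": float(lvl)})
        tr = integrate(cfg, None, duration, dt, seed, record_stride=100)
        spk = tr.spikes[tr.spikes >= analysis_start]
        rate = 1000.0 * spk.size / (duration - analysis_start)
        rhythm = "quiescent" if spk.size < 2 else classify_rhythm(np.diff(spk))
        points.append(FICurvePoint(I_app=float(lvl), rate=rate, rhythm=rhythm))
    return points


# -- single-pulse delay probe ----------------------------------------------

@dataclass
class ProbeResult:
    """Spike-triggered single-pulse probe outcome.

    ``delay`` is the time (s) from pulse onset to the first RS spike after
    the pulse ends; ``censored`` marks runs with no post-pulse spike.
    """

    delay: float
    censored: bool
    pulse_onset: float       # ms
    pulse_duration: float    # ms
    trace_pulsed: SimulationTrace
    trace_free: SimulationTrace


def spike_triggered_pulse_probe(config: ModelConfig, pulse_gain: float,
                                transient: float = 2000.0,
                                pulse_duration: float = 50.0,
                                post_window: float = 3000.0,
                                dt: float = DEFAULT_DT, seed: int = 0,
                                shape: float = 25.0) -> ProbeResult:
    """Probe the post-input spiking delay with one spike-triggered pulse.

    A pulse of the periodic-train pulse form (width ``pulse_duration``,
    squareness ``shape``) starts at the first RS spike after ``transient`` ms.
    The pulse integral equals ``pulse_gain`` x 4 x width, i.e. one pulse of a
    duty-cycle-1/4 periodic train normalized to mean current ``pulse_gain``.
    The unpulsed and pulsed runs share a seed, so their noise paths match.
    """
    from .stimuli import single_pulse

    duration = transient + pulse_duration + post_window
    free = integrate(config, None, duration, dt, seed, record_stride=10)
    after = free.spikes[free.spikes > transient]
    if after.size == 0:
        raise IntegrationError("model does not spike after the transient; "
                               "cannot trigger the probe pulse")
    onset = float(after[0])
    n_steps = int(round(duration / dt))
    stim = single_pulse(onset, pulse_duration, shape, dt, n_steps)
    stim *= pulse_gain * 4.0 * pulse_duration / max(np.trapezoid(stim, dx=dt), 1e-300)
    pulsed = integrate(config, stim, duration, dt, seed, record_stride=10)
    offset = onset + pulse_duration
    post = pulsed.spikes[pulsed.spikes > offset]
    if post.size == 0:
        delay = (duration - onset) / 1000.0
        censored = True
    else:
        delay = (post[0] - onset) / 1000.0
        censored = False
    return ProbeResult(delay=delay, censored=censored, pulse_onset=onset,
                       pulse_duration=pulse_duration,
                       trace_pulsed=pulsed, trace_free=free)
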