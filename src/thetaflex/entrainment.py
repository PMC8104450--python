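"""Input-phase extraction and spike-rate-adjusted phase-locking analysis.

Three phase-extraction methods cover the three input families:

* ``morlet_phase`` -- angle of a complex Morlet convolution at the input
  frequency (periodic pulse trains);
* ``piecewise_pulse_phase`` -- piecewise-linear phase anchored on pulse
  supports, advancing pi/2 across each pulse and 3pi/2 across each
  inter-pulse gap (quasi-rhythmic trains, where wavelet/Hilbert phase is
  unreliable);
* ``speech_phase`` -- sum of Morlet convolutions at the three main
  theta-band spectral modes of an amplitude envelope (multitaper peak
  selection).

Phase-locking is quantified by the spike-rate-adjusted PLV,

    PLV = (n_s |MRV|^2 - 1) / (n_s - 1),   MRV = (1/n_s) sum_k exp(-i phi(t_k)),

whose expectation is ~0 under uniform spike phases regardless of the spike
count n_s — the adjustment that makes PLV comparable across firing rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.optimize import brentq
from scipy.stats import linregress


@dataclass
class PhaseSeries:
    """Instantaneous input phase over a time grid (radians).

    ``valid`` masks the region where the estimate is trustworthy (edge
    effects are discarded for wavelet methods).  ``wrapped`` phases lie in
    (-pi, pi]; the piecewise method stores unwrapped, non-decreasing phase.
    """

    t: np.ndarray
    phase: np.ndarray
    method: str
    valid: np.ndarray
    params: dict = field(default_factory=dict)

    def at(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.t, self.phase)

    def valid_window(self) -> tuple[float, float]:
        idx = np.flatnonzero(self.valid)
        if idx.size == 0:
            return (np.nan, np.nan)
        return (self.t[idx[0]], self.t[idx[-1]])

    def cycles_in_valid(self) -> float:
        """Total phase advance over the valid region, in cycles."""
        ph = self.phase[self.valid]
        if ph.size < 2:
            return 0.0
        if self.method == "piecewise-pulse":
            adv = ph[-1] - ph[0]
        else:
            adv = np.unwrap(ph)[-1] - np.unwrap(ph)[0]
        return adv / (2.0 * math.pi)


def morlet_wavelet(freq: float, dt: float, n_cycles: float = 7.0) -> np.ndarray:
    """Complex Morlet, ``n_cycles`` long, sampled at ``dt`` ms."""
    sigma_t = 1000.0 * n_cycles / (2.0 * math.pi * freq)  # ms
    half = 0.5 * n_cycles * 1000.0 / freq                 # ms
    t = np.arange(-half, half + dt, dt)
    return np.exp(2j * math.pi * freq * t / 1000.0 - (t / sigma_t) ** 2 / 2.0)


def morlet_phase(sig: np.ndarray, freq: float, dt: float,
                 n_cycles: float = 7.0) -> PhaseSeries:
    """Phase as the angle of a complex Morlet convolution at ``freq`` Hz.

    Half a wavelet length at each end is flagged invalid (edge effects).
    For a pure cosine at ``freq`` the extracted phase is 0 at the peaks.
    """
    if freq <= 0:
        raise ValueError("frequency must be positive")
    sig = np.asarray(sig, dtype=float)
    w = morlet_wavelet(freq, dt, n_cycles)
    if sig.size < w.size:
        raise ValueError("signal shorter than the analysis wavelet")
    conv = sps.fftconvolve(sig - sig.mean(), w, mode="same")
    amp = np.abs(conv)
    phase = np.angle(conv)
    valid = np.ones(sig.size, dtype=bool)
    edge = w.size // 2
    valid[:edge] = False
    valid[sig.size - edge:] = False
    # flat signal: zero analytic amplitude, phase meaningless
    valid &= amp > 1e-12 * max(amp.max(), 1e-300)
    t = np.arange(sig.size) * dt
    return PhaseSeries(t=t, phase=phase, method="morlet", valid=valid,
                       params=dict(freq=freq, n_cycles=n_cycles))


def piecewise_pulse_phase(supports, t: np.ndarray) -> PhaseSeries:
    """Piecewise-linear pulse-train phase anchored on supports.

    phi(0) = 0; the phase gains 3pi/2 across each inter-support gap and
    pi/2 across each support [a_i, b_i], so one full cycle accrues per
    pulse.  Anchor values: phi(a_i) = 2pi (i-1) + 3pi/2, phi(b_i) = 2pi i.
    Beyond the last support the phase is extrapolated at the mean cycle
    rate.  The result is non-decreasing (strictly increasing between
    anchors) and left unwrapped.
    """
    supports = list(supports)
    t = np.asarray(t, dtype=float)
    if not supports:
        raise ValueError("no pulse supports given")
    xs = [0.0]
    ys = [0.0]
    for i, (a, b) in enumerate(supports):
        if a <= xs[-1]:
            raise ValueError("supports must be disjoint and increasing")
        if b <= a:
            raise ValueError("support offset must exceed onset")
        xs.extend([a, b])
        ys.extend([2.0 * math.pi * i + 1.5 * math.pi,
                   2.0 * math.pi * (i + 1)])
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    phase = np.interp(t, xs, ys)
    # extrapolate past the last anchor at the mean cycle rate
    beyond = t > xs[-1]
    if np.any(beyond) and xs[-1] > 0:
        rate = ys[-1] / xs[-1]
        phase[beyond] = ys[-1] + rate * (t[beyond] - xs[-1])
    valid = np.ones(t.size, dtype=bool)
    return PhaseSeries(t=t, phase=phase, method="piecewise-pulse",
                       valid=valid, params=dict(n_pulses=len(supports)))


# -- speech-envelope phase --------------------------------------------------

def multitaper_psd(sig: np.ndarray, dt: float, nw: float = 4.0,
                   n_tapers: int | None = None):
    """Thomson multitaper power spectrum (frequencies in Hz)."""
    sig = np.asarray(sig, dtype=float)
    n = sig.size
    if n_tapers is None:
        n_tapers = int(2 * nw) - 1
    tapers = sps.windows.dpss(n, nw, Kmax=n_tapers)
    fs = 1000.0 / dt
    psd = np.zeros(n // 2 + 1)
    x = sig - sig.mean()
    for tp in tapers:
        spec = np.fft.rfft(tp * x)
        psd += np.abs(spec) ** 2
    psd /= n_tapers
    freqs = np.fft.rfftfreq(n, d=dt / 1000.0)
    return freqs, psd


def spectral_peak_frequencies(sig: np.ndarray, dt: float,
                              min_separation: float = 2.0, n_modes: int = 3,
                              theta_band: tuple = (3.0, 13.0),
                              f_max: float = 50.0, nw: float = 4.0):
    """Main theta-band oscillatory modes of a signal's multitaper spectrum.

    Spectral peaks are constrained to lie >= ``min_separation`` Hz apart;
    the ``n_modes`` most powerful peaks inside ``theta_band`` are returned
    (equivalently, with the dominant delta-band bulk peak of natural
    envelopes excluded, the next-largest peaks).  If the band holds no peak,
    all available peaks are returned as a logged fallback; a pure tone thus
    yields its own frequency.
    """
    freqs, psd = multitaper_psd(sig, dt, nw=nw)
    sel = freqs <= f_max
    freqs, psd = freqs[sel], psd[sel]
    pk, _ = sps.find_peaks(psd)
    order = pk[np.argsort(psd[pk])[::-1]]
    chosen = []
    for i in order:
        if all(abs(freqs[i] - freqs[j]) >= min_separation for j in chosen):
            chosen.append(i)
    in_band = [freqs[i] for i in chosen
               if theta_band[0] <= freqs[i] <= theta_band[1]]
    if in_band:
        return in_band[:n_modes]
    # fallback: no theta-band peak (e.g. a single slow or fast tone)
    if chosen:
        return [freqs[i] for i in chosen[:n_modes]]
    return [float(freqs[np.argmax(psd)])]


def speech_phase(envelope: np.ndarray, dt: float, n_cycles: float = 7.0,
                 nw: float = 4.0) -> PhaseSeries:
    """Theta-mode phase of an amplitude envelope.

    The three most powerful theta-band multitaper spectral peaks (>= 2 Hz
    apart; equivalently the largest peaks once the dominant delta-band bulk
    of natural envelopes is excluded) give the main oscillatory modes; the
    envelope is convolved with Morlet wavelets at those frequencies, the
    complex series summed, and the phase taken as the angle of the sum.
    """
    envelope = np.asarray(envelope, dtype=float)
    if envelope.size * dt < 2000.0:
        raise ValueError("envelope must be at least 2 s long")
    freqs = spectral_peak_frequencies(envelope, dt, nw=nw)
    x = envelope - envelope.mean()
    total = np.zeros(envelope.size, dtype=complex)
    max_edge = 0
    for f in freqs:
        w = morlet_wavelet(f, dt, n_cycles)
        if w.size > envelope.size:
            continue
        total += sps.fftconvolve(x, w, mode="same")
        max_edge = max(max_edge, w.size // 2)
    valid = np.ones(envelope.size, dtype=bool)
    if max_edge:
        valid[:max_edge] = False
        valid[envelope.size - max_edge:] = False
    t = np.arange(envelope.size) * dt
    return PhaseSeries(t=t, phase=np.angle(total), method="speech-multipeak",
                       valid=valid, params=dict(freqs=freqs, nw=nw))


# -- phase-locking value ----------------------------------------------------

@dataclass
class PLVResult:
    """Spike-rate-adjusted phase-locking value.

    ``plv`` lies in [-1/(n_s-1), 1]; it is NaN (``defined`` False) when
    fewer than two spikes fall in the valid phase region.
    """

    plv: float
    n_spikes: int
    mrv: complex
    spikes_per_cycle: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.plv)


def plv(spike_times: np.ndarray, phase: PhaseSeries) -> PLVResult:
    """Spike-rate-adjusted PLV of spikes against an input phase series."""
    spike_times = np.asarray(spike_times, dtype=float)
    lo, hi = phase.valid_window()
    if math.isnan(lo):
        return PLVResult(math.nan, 0, complex(math.nan), math.nan)
    spk = spike_times[(spike_times >= lo) & (spike_times <= hi)]
    cycles = phase.cycles_in_valid()
    n = spk.size
    if n <= 1:
        return PLVResult(math.nan, int(n), complex(math.nan),
                         n / cycles if cycles > 0 else math.nan)
    ph = phase.at(spk)
    mrv = np.exp(-1j * ph).mean()
    val = (n * abs(mrv) ** 2 - 1.0) / (n - 1.0)
    spc = n / cycles if cycles > 0 else math.nan
    return PLVResult(float(val), int(n), complex(mrv), float(spc))


# "appreciable phase-locking" criterion (dotted-contour convention)
PLV_LOCKED = 0.5
SPIKES_PER_CYCLE_LOCKED = 0.9


def is_locked(res: PLVResult, plv_min: float = PLV_LOCKED,
              spc_min: float | None = SPIKES_PER_CYCLE_LOCKED) -> bool:
    """Locking criterion: PLV >= 0.5 with >= 0.9 spikes per input cycle.

    Pass ``spc_min=None`` to apply the PLV part only (relevant above the
    intrinsic frequency, where locking can occur with < 1 spike/cycle).
    """
    if not res.defined:
        return False
    if res.plv < plv_min:
        return False
    if spc_min is not None and not (res.spikes_per_cycle >= spc_min):
        return False
    return True


# -- delay-based phase-locking estimate -------------------------------------

def lower_limit_from_delay(D, f_lo: float = 0.05, f_hi: float = 50.0) -> float:
    """Lower frequency limit f* of phase-locking implied by a spiking delay.

    Locking at frequency f requires the post-input delay to cover a full
    period: 1/f <= D.  For a constant delay D (seconds) this gives
    f* = 1/D.  ``D`` may also be a callable D(f) (delay depending on the
    pulse width, hence on f), in which case the binding frequency solves
    1/f = D(f).
    """
    if callable(D):
        g = lambda f: D(f) - 1.0 / f
        return float(brentq(g, f_lo, f_hi, xtol=1e-12))
    if D <= 0:
        raise ValueError("delay must be positive")
    return 1.0 / D


def delay_estimated_plv(D: float, frequencies, censored: bool = False) -> np.ndarray:
    """Binary locking indicator over a frequency grid from one delay D (s).

    Predicts locking at f iff 1/f <= D.  A right-censored delay (no
    post-pulse spike observed) predicts locking at every tested frequency
    down to the censoring bound.
    """
    frequencies = np.asarray(frequencies, dtype=float)
    if censored:
        return np.ones_like(frequencies)
    return (1.0 / frequencies <= D).astype(float)


def pulse_width_to_frequency(width_ms: float) -> float:
    """Periodic-train frequency whose duty-1/4 pulse has this width."""
    return 250.0 / width_ms


def delay_locking_map(delays_by_width: dict, frequencies) -> pd.DataFrame:
    """Fraction of probe repeats predicting locking, per (width, frequency).

    ``delays_by_width`` maps pulse width (ms) to a list of (delay_s,
    censored) pairs over seeds; the soft map averages the binary indicator
    over seeds.
    """
    rows = []
    for width, delays in delays_by_width.items():
        f_probe = pulse_width_to_frequency(width)
        for f in frequencies:
            frac = float(np.mean([
                delay_estimated_plv(d, [f], censored=c)[0]
                for d, c in delays]))
            rows.append(dict(pulse_width=width, probe_frequency=f_probe,
                             frequency=f, p_locked=frac))
    return pd.DataFrame(rows)


# -- pre-spike gating-variable analyses -------------------------------------

def prespike_activations(trace, variables, exclude_supports=None) -> pd.DataFrame:
    """Per-spike pre-spike gate values with backward differences.

    For each retained RS spike, reports each requested state variable one
    integration step before the detected crossing, plus first and second
    backward differences.  Spikes whose time lies inside a pulse support
    ("forced" spikes) are excluded when ``exclude_supports`` is given.
    """
    from .neuron_models import IDX

    spikes = trace.spikes
    pre = trace.prespike
    if spikes.size == 0:
        raise ValueError("trace contains no spikes")
    keep = np.ones(spikes.size, dtype=bool)
    if exclude_supports:
        for a, b in exclude_supports:
            keep &= ~((spikes >= a) & (spikes <= b))
    data = {"spike_time": spikes[keep]}
    for name in variables:
        i = IDX[name]
        x1 = pre[keep, 0, i]   # one step before
        x2 = pre[keep, 1, i]
        x3 = pre[keep, 2, i]
        data[name] = x1
        data[f"d_{name}"] = x1 - x2
        data[f"d2_{name}"] = x1 - 2.0 * x2 + x3
    return pd.DataFrame(data)


def prespike_regression(df: pd.DataFrame, x: str, y: str,
                        x_max: float | None = None,
                        trim_mad: float | None = 5.0):
    """Linear regression of pre-spike ``y`` on pre-spike ``x``.

    ``x_max`` drops points with x above a cutoff (e.g. excluding spikes with
    inhibitory-synapse activation > 0.1); ``trim_mad`` removes gross
    outliers beyond median +/- k MAD in either coordinate before fitting.
    Returns the scipy ``linregress`` result.
    """
    xs = df[x].to_numpy(dtype=float)
    ys = df[y].to_numpy(dtype=float)
    keep = np.isfinite(xs) & np.isfinite(ys)
    if x_max is not None:
        keep &= xs <= x_max
    if trim_mad is not None:
        for arr in (xs, ys):
            med = np.median(arr[keep])
            mad = np.median(np.abs(arr[keep] - med))
            if mad > 0:
                keep &= np.abs(arr - med) <= trim_mad * mad
    if keep.sum() < 3:
        raise ValueError("too few pre-spike points for regression")
    return linregress(xs[keep], ys[keep])
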